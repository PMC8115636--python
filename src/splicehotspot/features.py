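"""Feature extraction for exonic SNVs, organized in four groups.

Every feature carries exactly one group tag — ``mutation`` (the base
change itself), ``motif`` (local sequence-score changes: hexamer
cis-element deltas and splice-site score deltas), ``exon`` (properties of
the host exon: splice-site usage, length, mean hexamer score, wild-type
splicing outcome) or ``transcript`` (exon count, gene length).  The group
partition is what the ablation protocol in :mod:`splicehotspot.classifier`
manipulates.

Variants are reported on the + strand of the genome; sequence-derived
features are evaluated in transcript orientation, so mirroring a gene to
the other strand leaves its features unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import Annotation
from .synthetic import BASES, revcomp

# splice-site scoring windows (exonic, intronic) in transcript orientation
DONOR_EXONIC, DONOR_INTRONIC = 3, 6
ACCEPTOR_INTRONIC, ACCEPTOR_EXONIC = 20, 3

MUTATION_GROUP, MOTIF_GROUP, EXON_GROUP, TRANSCRIPT_GROUP = (
    "mutation", "motif", "exon", "transcript",
)

SUBSTITUTIONS = [
    f"{a}to{b}" for a in BASES for b in BASES if a != b
]


def enumerate_exonic_snvs(exon: pd.Series | dict,
                          genome: dict[str, str]) -> pd.DataFrame:
    """All 3 x length possible SNVs of one exon, on the + genome strand."""
    chrom, start, end = exon["chrom"], int(exon["start"]), int(exon["end"])
    strand, exon_id = exon["strand"], exon["exon_id"]
    seq = genome[chrom]
    if start < 0 or end > len(seq):
        raise ValueError(f"exon {exon_id} outside genome bounds")
    rows = []
    for pos in range(start, end):
        ref = seq[pos]
        for alt in BASES:
            if alt != ref:
                rows.append((f"{exon_id}:{pos}{ref}>{alt}", exon_id, chrom,
                             pos, ref, alt, strand))
    return pd.DataFrame(
        rows,
        columns=["variant_id", "exon_id", "chrom", "pos", "ref", "alt",
                 "strand"],
    )


def apply_variant(seq: str, pos: int, alt: str) -> str:
    return seq[:pos] + alt + seq[pos + 1:]


class PwmSpliceScorer:
    """Log-odds position weight matrices for donor and acceptor windows.

    Built from the annotation's own splice sites against a uniform
    background; a drop-in replacement implementing ``donor_score`` /
    ``acceptor_score`` over the same windows (e.g. MaxEnt tables) can be
    substituted anywhere this default is accepted.
    """

    name = "pwm"

    def __init__(self, donor_matrix: np.ndarray, acceptor_matrix: np.ndarray):
        self.donor_matrix = donor_matrix          # (9, 4) log-odds
        self.acceptor_matrix = acceptor_matrix    # (23, 4)

    @classmethod
    def from_annotation(cls, annotation: Annotation, genome: dict[str, str],
                        pseudocount: float = 0.5) -> "PwmSpliceScorer":
        donor_windows, acceptor_windows = [], []
        for site in annotation.splice_sites():
            w = extract_site_window(site.chrom, site.pos, site.side,
                                    site.strand, genome)
            if w is None:
                continue
            (donor_windows if site.side == "donor" else acceptor_windows).append(w)
        if not donor_windows or not acceptor_windows:
            raise ValueError("annotation yields no scorable splice windows")

        def logodds(windows: list[str], width: int) -> np.ndarray:
            counts = np.full((width, 4), pseudocount)
            for w in windows:
                for i, b in enumerate(w):
                    if b in BASES:
                        counts[i, BASES.index(b)] += 1
            freqs = counts / counts.sum(axis=1, keepdims=True)
            return np.log2(freqs / 0.25)

        return cls(logodds(donor_windows, 9), logodds(acceptor_windows, 23))

    def _score(self, window: str, matrix: np.ndarray) -> float:
        if len(window) != matrix.shape[0]:
            raise ValueError(
                f"window length {len(window)} != {matrix.shape[0]}"
            )
        return float(
            sum(
                matrix[i, BASES.index(b)]
                for i, b in enumerate(window) if b in BASES
            )
        )

    def donor_score(self, window: str) -> float:
        return self._score(window, self.donor_matrix)

    def acceptor_score(self, window: str) -> float:
        return self._score(window, self.acceptor_matrix)


def extract_site_window(chrom: str, pos: int, side: str, strand: str,
                        genome: dict[str, str]) -> str | None:
    """Splice-site window in transcript orientation (None if off the end).

    Donor: 3 exonic + 6 intronic bases; acceptor: 20 intronic + 3 exonic.
    """
    seq = genome[chrom]
    if side == "donor":
        lo, hi = (pos - 3, pos + 6) if strand == "+" else (pos - 6, pos + 3)
    else:
        lo, hi = (pos - 20, pos + 3) if strand == "+" else (pos - 3, pos + 20)
    if lo < 0 or hi > len(seq):
        return None
    w = seq[lo:hi]
    return w if strand == "+" else revcomp(w)


def load_hexamer_table(table: pd.DataFrame | dict[str, float]) -> dict[str, float]:
    if isinstance(table, dict):
        return table
    return dict(zip(table["hexamer"], table["score"]))


def motif_delta_features(variant, genome: dict[str, str],
                         hexamers: dict[str, float]) -> dict[str, float]:
    """Sum and mean of hexamer-score changes over the <=6 windows covering
    the variant.  Windows extending past the exon use genomic (intronic)
    sequence; windows off the chromosome end are skipped."""
    seq = genome[variant.chrom]
    pos, alt, strand = int(variant.pos), variant.alt, variant.strand
    deltas = []
    for i in range(6):
        lo = pos - 5 + i
        if lo < 0 or lo + 6 > len(seq):
            continue
        wt = seq[lo:lo + 6]
        mut = wt[:pos - lo] + alt + wt[pos - lo + 1:]
        if strand == "-":
            wt, mut = revcomp(wt), revcomp(mut)
        deltas.append(hexamers.get(mut, 0.0) - hexamers.get(wt, 0.0))
    if not deltas or variant.ref not in BASES:
        return {"hex_delta_sum": np.nan, "hex_delta_mean": np.nan}
    return {
        "hex_delta_sum": float(np.sum(deltas)),
        "hex_delta_mean": float(np.mean(deltas)),
    }


def _exon_site_positions(exon) -> tuple[int, int]:
    """(donor boundary, acceptor boundary) of an exon row."""
    if exon["strand"] == "+":
        return int(exon["end"]), int(exon["start"])
    return int(exon["start"]), int(exon["end"])


def splice_site_delta_features(variant, exon, genome: dict[str, str],
                               scorer) -> dict[str, float]:
    """Mutant - wild-type splice-site score for the exon's two windows;
    zero when the variant lies outside both windows."""
    donor_pos, acceptor_pos = _exon_site_positions(exon)
    chrom, strand = variant.chrom, variant.strand
    pos, alt = int(variant.pos), variant.alt
    out = {"donor_delta": 0.0, "acceptor_delta": 0.0}
    for side, spos, key in (("donor", donor_pos, "donor_delta"),
                            ("acceptor", acceptor_pos, "acceptor_delta")):
        if side == "donor":
            lo, hi = (spos - 3, spos + 6) if strand == "+" else (spos - 6, spos + 3)
        else:
            lo, hi = (spos - 20, spos + 3) if strand == "+" else (spos - 3, spos + 20)
        if not lo <= pos < hi:
            continue
        wt = extract_site_window(chrom, spos, side, strand, genome)
        if wt is None:
            continue
        mut_genome = {chrom: apply_variant(genome[chrom], pos, alt)}
        mut = extract_site_window(chrom, spos, side, strand, mut_genome)
        score = scorer.donor_score if side == "donor" else scorer.acceptor_score
        out[key] = score(mut) - score(wt)
    return out


def mean_exon_hexamer_score(exon, genome: dict[str, str],
                            hexamers: dict[str, float]) -> float:
    """Mean score over the exon's L-5 exonic hexamers (transcript strand)."""
    seq = genome[exon["chrom"]][int(exon["start"]):int(exon["end"])]
    if exon["strand"] == "-":
        seq = revcomp(seq)
    if len(seq) < 6:
        return np.nan
    return float(
        np.mean([hexamers.get(seq[i:i + 6], 0.0)
                 for i in range(len(seq) - 5)])
    )


def exon_transcript_features(exon, annotation: Annotation,
                             usage: pd.DataFrame | None,
                             genome: dict[str, str],
                             hexamers: dict[str, float],
                             wt_splicing: float | None = None) -> dict[str, float]:
    """Exon-group and transcript-group features for one exon row."""
    donor_pos, acceptor_pos = _exon_site_positions(exon)
    du = au = np.nan
    if usage is not None:
        idx = usage.set_index(["chrom", "pos", "side", "strand"])["usage"]
        du = idx.get((exon["chrom"], donor_pos, "donor", exon["strand"]), np.nan)
        au = idx.get((exon["chrom"], acceptor_pos, "acceptor", exon["strand"]),
                     np.nan)
    t = annotation.transcripts.get(exon["transcript_id"])
    gene = annotation.genes.get(exon["gene_id"])
    feats = {
        "donor_usage": float(du),
        "acceptor_usage": float(au),
        "exon_length": float(int(exon["end"]) - int(exon["start"])),
        "exon_mean_hexamer": mean_exon_hexamer_score(exon, genome, hexamers),
        "n_exons": float(len(t.exons)) if t else np.nan,
        "gene_length": float(gene.length) if gene else np.nan,
    }
    if wt_splicing is not None:
        feats["wt_splicing"] = float(wt_splicing)
    return feats


def mutation_features(variant, structure_scorer=None) -> dict[str, float]:
    """One-hot of the 12 substitution types, in transcript orientation,
    plus optional hybridization indicators from a structure plugin."""
    ref, alt = variant.ref, variant.alt
    if variant.strand == "-":
        ref, alt = revcomp(ref), revcomp(alt)
    feats = {f"sub_{s}": 0.0 for s in SUBSTITUTIONS}
    key = f"sub_{ref}to{alt}"
    if key in feats:
        feats[key] = 1.0
    if structure_scorer is not None:
        feats.update(structure_scorer(variant))
    return feats


@dataclass
class FeatureTable:
    """Feature matrix plus the group tag of every feature."""

    frame: pd.DataFrame          # index variant_id; feature columns only
    groups: dict[str, str]       # feature name -> group
    meta: pd.DataFrame           # variant_id, exon_id, pos, ref, alt, ...

    def features_in_group(self, group: str) -> list[str]:
        return [f for f, g in self.groups.items() if g == group]


def build_feature_table(
    variants: pd.DataFrame,
    exons: pd.DataFrame,
    annotation: Annotation,
    genome: dict[str, str],
    hexamer_table: pd.DataFrame | dict[str, float],
    usage: pd.DataFrame | None = None,
    wt_splicing: dict[str, float] | None = None,
    scorer=None,
    structure_scorer=None,
) -> FeatureTable:
    """Extract the full grouped feature matrix for a variant table.

    ``variants`` needs variant_id, exon_id, chrom, pos, ref?, alt, strand;
    ``exons`` is the exon registry (exon_id, chrom, start, end, strand,
    transcript_id, gene_id).  ``wt_splicing`` optionally maps exon_id to the
    wild-type splicing outcome measured in the splicing assay.
    """
    hexamers = load_hexamer_table(hexamer_table)
    if scorer is None:
        scorer = PwmSpliceScorer.from_annotation(annotation, genome)
    exon_idx = exons.set_index("exon_id")
    exon_cache: dict[str, dict[str, float]] = {}
    rows = []
    groups: dict[str, str] = {}
    variants = variants.copy()
    if "ref" not in variants.columns:
        variants["ref"] = [
            genome[r.chrom][int(r.pos)] for r in variants.itertuples()
        ]
    for v in variants.itertuples(index=False):
        exon = exon_idx.loc[v.exon_id]
        feats: dict[str, float] = {}
        mf = mutation_features(v, structure_scorer)
        feats.update(mf)
        groups.update({k: MUTATION_GROUP for k in mf})
        hf = motif_delta_features(v, genome, hexamers)
        sf = splice_site_delta_features(v, exon, genome, scorer)
        feats.update(hf)
        feats.update(sf)
        groups.update({k: MOTIF_GROUP for k in (*hf, *sf)})
        if v.exon_id not in exon_cache:
            wt = wt_splicing.get(v.exon_id) if wt_splicing else None
            exon_cache[v.exon_id] = exon_transcript_features(
                exon, annotation, usage, genome, hexamers, wt
            )
        ef = exon_cache[v.exon_id]
        feats.update(ef)
        for k in ef:
            groups[k] = TRANSCRIPT_GROUP if k in ("n_exons", "gene_length") \
                else EXON_GROUP
        rows.append(feats)
    frame = pd.DataFrame(rows, index=variants["variant_id"].to_numpy())
    meta_cols = [c for c in ("variant_id", "exon_id", "chrom", "pos",
                             "ref", "alt", "strand") if c in variants.columns]
    return FeatureTable(frame, groups, variants[meta_cols].copy())
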