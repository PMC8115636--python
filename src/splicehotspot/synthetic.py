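"""Synthetic data with planted ground truth for every pipeline stage.

The generator builds multi-exon gene models on both strands, writes them in
standard formats (GTF, FASTA, STAR junction tables, TSV, BED, VCF) and
records the planted truth so downstream estimators can be validated.

Junction reads come from an isoform mixture per gene: a canonical isoform,
exon-skipping isoforms (strong skip weights on designated hotspot exons) and
occasional donor/acceptor-extension isoforms that create annotated cryptic
sites inside introns.  Each isoform junction receives Poisson counts
proportional to its mixture weight.  The planted usage stored per splice
site is the exact expected A/(A+B+C) under that mixture, computed by a
small stand-alone enumerator so it is independent of the analysis code it
validates.

Disrupting MaPSy variants, functional RBP peaks and depleted population
variants are all planted per exon *after* hotspot status is assigned, so
exon properties — not variant properties — drive every downstream signal.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import Annotation, Exon, Gene, Junction, Transcript, write_gtf
from . import io as shio

BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")

# rng stream ids, one per generator, all derived from config.seed
_STREAMS = {
    "annotation": 1, "junctions": 2, "mapsy": 3, "rbp": 4,
    "variants": 5, "minigene": 6, "hexamers": 7, "hi": 8,
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _default_minigene_grid() -> list[tuple[float, float]]:
    # 7 test-exon groups x 8 flanking efficiencies (8 species per sample)
    tests = np.round(np.linspace(0.08, 0.92, 7), 3)
    flanks = np.round(np.linspace(0.10, 0.94, 8), 3)
    return [(float(t), float(f)) for t in tests for f in flanks]


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with the study's default values."""

    seed: int = 0
    n_genes: int = 40
    exons_per_gene: tuple[int, int] = (3, 6)
    exon_length: tuple[int, int] = (60, 150)
    intron_length: tuple[int, int] = (80, 300)
    read_depth: float = 200.0            # mean junction reads per site
    n_cell_lines: int = 4
    n_replicates: int = 2
    hotspot_fraction: float = 0.2
    disrupt_prob_hotspot: float = 0.85
    disrupt_prob_background: float = 0.03
    effect_size: float = 2.5             # mean |log2 allelic ratio| if disrupting
    n_mapsy_variants: int = 400
    mapsy_depth: float = 300.0
    n_rbps: int = 8
    n_functional_peaks: int = 200
    n_nonfunctional_peaks: int = 400
    n_unlabeled_peaks: int = 40
    functional_cluster_strength: float = 3.0
    variant_rate: float = 0.08           # population variants per exonic base
    variant_depletion: float = 0.3
    minigene_grid: list[tuple[float, float]] = field(
        default_factory=_default_minigene_grid
    )
    minigene_depth: int = 2000
    minigene_alpha: float = -1.0
    minigene_beta_t: float = 4.0
    competition_beta: float = 6.0
    minigene_tau: float | None = None    # default: 2nd-of-7 group boundary

    def validate(self) -> None:
        for name in ("exons_per_gene", "exon_length", "intron_length"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"degenerate range for {name}: ({lo}, {hi})")
        if self.exons_per_gene[0] < 2:
            raise ValueError("genes need at least 2 exons to have junctions")
        for name in ("hotspot_fraction", "disrupt_prob_hotspot",
                     "disrupt_prob_background", "variant_depletion"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.read_depth <= 0:
            raise ValueError("read_depth must be positive")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if not self.minigene_grid:
            raise ValueError("minigene_grid must not be empty")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])

    def tau(self) -> float:
        """Competition threshold: boundary after the 2nd-weakest test group."""
        if self.minigene_tau is not None:
            return self.minigene_tau
        tests = sorted({t for t, _ in self.minigene_grid})
        if len(tests) < 3:
            return float(tests[-1]) + 0.01
        return float((tests[1] + tests[2]) / 2)


@dataclass
class ExonInfo:
    exon_id: str
    gene_id: str
    transcript_id: str
    chrom: str
    start: int
    end: int
    strand: str
    index: int          # 1-based position in the canonical transcript
    n_exons: int
    internal: bool
    hotspot: bool
    inclusion: float    # planted canonical-isoform inclusion of this exon


@dataclass
class GroundTruth:
    """Planted parameters for every simulated entity."""

    site_usage: dict[tuple[str, int, str, str], float] = field(default_factory=dict)
    exons: dict[str, ExonInfo] = field(default_factory=dict)
    hotspot_exons: dict[str, bool] = field(default_factory=dict)
    variant_disrupting: dict[str, bool] = field(default_factory=dict)
    peak_functional: dict[str, bool] = field(default_factory=dict)
    minigene_inclusion: dict[str, float] = field(default_factory=dict)
    junction_weights: dict[Junction, float] = field(default_factory=dict)
    transcript_weights: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "site_usage": [
                list(k) + [v] for k, v in sorted(self.site_usage.items())
            ],
            "exons": {
                k: dataclasses.asdict(v) for k, v in sorted(self.exons.items())
            },
            "hotspot_exons": dict(sorted(self.hotspot_exons.items())),
            "variant_disrupting": dict(sorted(self.variant_disrupting.items())),
            "peak_functional": dict(sorted(self.peak_functional.items())),
            "minigene_inclusion": dict(sorted(self.minigene_inclusion.items())),
            "junction_weights": [
                [j.chrom, j.start, j.end, j.strand, w]
                for j, w in sorted(
                    self.junction_weights.items(),
                    key=lambda kv: (kv[0].chrom, kv[0].start, kv[0].end),
                )
            ],
            "transcript_weights": dict(sorted(self.transcript_weights.items())),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# --- sequence motifs planted at splice sites (transcript orientation) -----

def _pos_probs(weights: dict[str, float]) -> np.ndarray:
    p = np.array([weights.get(b, 0.0) for b in BASES], dtype=float)
    rest = (1.0 - p.sum()) / (p == 0).sum() if (p == 0).any() else 0.0
    p[p == 0] = rest
    return p / p.sum()

_DONOR_PROBS = [  # 3 exonic + 6 intronic, consensus (C/A)AG | GTAAGT
    _pos_probs({"C": 0.35, "A": 0.35}), _pos_probs({"A": 0.60}),
    _pos_probs({"G": 0.80}),
    _pos_probs({"G": 0.95}), _pos_probs({"T": 0.95}),
    _pos_probs({"A": 0.60}), _pos_probs({"A": 0.70}),
    _pos_probs({"G": 0.80}), _pos_probs({"T": 0.50}),
]
_PYRIMIDINE = _pos_probs({"C": 0.30, "T": 0.45, "A": 0.15, "G": 0.10})
_ACCEPTOR_PROBS = (  # 20 intronic + 3 exonic, ...YYYYYYYYYYNCAG | G
    [_PYRIMIDINE] * 16
    + [_pos_probs({"C": 0.65, "T": 0.25}), _pos_probs({"A": 0.90}),
       _pos_probs({"G": 0.95})]
    + [_pos_probs({"G": 0.50}), _pos_probs({}), _pos_probs({})]
)
# last intronic positions are ...CAG; keep the invariant AG strongly planted
_ACCEPTOR_PROBS[17] = _pos_probs({"A": 0.95})


def _sample_motif(rng: np.random.Generator, probs: list[np.ndarray]) -> str:
    return "".join(BASES[rng.choice(4, p=p)] for p in probs)


# --- gene construction ----------------------------------------------------

def _build_gene_sequence(rng: np.random.Generator,
                         offsets: list[tuple[int, int]],
                         length: int) -> str:
    seq = list(rng.choice(list(BASES), size=length))
    for k, (s, e) in enumerate(offsets):
        if k < len(offsets) - 1:          # donor at exon end
            motif = _sample_motif(rng, _DONOR_PROBS)
            seq[e - 3:e + 6] = list(motif)
        if k > 0:                          # acceptor at exon start
            motif = _sample_motif(rng, _ACCEPTOR_PROBS)
            seq[s - 20:s + 3] = list(motif)
    return "".join(seq)


def simulate_annotation(
    config: SimulationConfig,
) -> tuple[Annotation, dict[str, str], GroundTruth]:
    """Simulate gene models, genome sequence and the isoform mixture."""
    config.validate()
    rng = config.rng("annotation")
    truth = GroundTruth()
    genes: dict[str, Gene] = {}
    genome: dict[str, list[str]] = {}
    genes_per_chrom = 10
    cursor: dict[str, int] = {}

    for gi in range(config.n_genes):
        gene_id = f"gene{gi + 1:03d}"
        chrom = f"chr{gi // genes_per_chrom + 1}"
        genome.setdefault(chrom, [])
        cursor.setdefault(chrom, 0)
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(config.exons_per_gene[0],
                                   config.exons_per_gene[1] + 1))
        ex_lens = rng.integers(config.exon_length[0],
                               config.exon_length[1] + 1, size=n_exons)
        in_lens = rng.integers(config.intron_length[0],
                               config.intron_length[1] + 1, size=n_exons - 1)
        offsets, off = [], 0
        for k in range(n_exons):
            offsets.append((off, off + int(ex_lens[k])))
            off += int(ex_lens[k])
            if k < n_exons - 1:
                off += int(in_lens[k])
        glen = off
        tx_seq = _build_gene_sequence(rng, offsets, glen)

        # hotspot flags and isoform weights
        skip_weights: dict[int, float] = {}
        hot_flags: dict[int, bool] = {}
        for k in range(1, n_exons + 1):
            internal = 1 < k < n_exons
            hot = bool(internal and rng.random() < config.hotspot_fraction)
            hot_flags[k] = hot
            if hot:
                skip_weights[k] = float(rng.uniform(0.25, 0.55))
            elif internal and rng.random() < 0.3:
                skip_weights[k] = float(rng.uniform(0.02, 0.10))
        ext_donor: dict[int, tuple[int, float]] = {}
        ext_acceptor: dict[int, tuple[int, float]] = {}
        for intron_idx in range(n_exons - 1):
            u = rng.random()
            delta = int(min(in_lens[intron_idx] - 30, 18))
            if delta < 4:
                continue
            if u < 0.25:
                ext_donor[intron_idx] = (delta, float(rng.uniform(0.03, 0.10)))
            elif u < 0.50:
                ext_acceptor[intron_idx] = (delta, float(rng.uniform(0.03, 0.10)))
        total_alt = sum(skip_weights.values()) \
            + sum(w for _, w in ext_donor.values()) \
            + sum(w for _, w in ext_acceptor.values())
        if total_alt > 0.7:  # keep the canonical isoform dominant
            scale = 0.7 / total_alt
            skip_weights = {k: w * scale for k, w in skip_weights.items()}
            ext_donor = {k: (d, w * scale) for k, (d, w) in ext_donor.items()}
            ext_acceptor = {k: (d, w * scale)
                            for k, (d, w) in ext_acceptor.items()}
            total_alt = 0.7
        w_canonical = 1.0 - total_alt

        gstart = cursor[chrom]
        gend = gstart + glen
        cursor[chrom] = gend + 400
        genome[chrom].append(tx_seq if strand == "+" else revcomp(tx_seq))
        genome[chrom].append("".join(rng.choice(list(BASES), size=400)))

        def to_genomic(o1: int, o2: int) -> tuple[int, int]:
            if strand == "+":
                return gstart + o1, gstart + o2
            return gend - o2, gend - o1

        gene = Gene(gene_id, chrom, strand)

        def add_transcript(tid: str, ex_offsets: list[tuple[int, int]],
                           weight: float) -> None:
            t = Transcript(tid, gene_id, chrom, strand)
            for o1, o2 in ex_offsets:
                g1, g2 = to_genomic(o1, o2)
                t.exons.append(Exon(chrom, g1, g2, strand))
            gene.transcripts[tid] = t
            truth.transcript_weights[tid] = weight
            for j in t.junctions():
                truth.junction_weights[j] = (
                    truth.junction_weights.get(j, 0.0) + weight
                )

        tid0 = f"{gene_id}.t1"
        add_transcript(tid0, offsets, w_canonical)
        for k, w in skip_weights.items():
            skipped = [o for i, o in enumerate(offsets, 1) if i != k]
            add_transcript(f"{gene_id}.skip{k}", skipped, w)
        for intron_idx, (delta, w) in ext_donor.items():
            mod = list(offsets)
            s, e = mod[intron_idx]
            mod[intron_idx] = (s, e + delta)
            add_transcript(f"{gene_id}.extd{intron_idx + 1}", mod, w)
        for intron_idx, (delta, w) in ext_acceptor.items():
            mod = list(offsets)
            s, e = mod[intron_idx + 1]
            mod[intron_idx + 1] = (s - delta, e)
            add_transcript(f"{gene_id}.exta{intron_idx + 1}", mod, w)

        genes[gene_id] = gene
        for k, (o1, o2) in enumerate(offsets, 1):
            g1, g2 = to_genomic(o1, o2)
            exon_id = f"{gene_id}:exon{k}"
            inclusion = 1.0 - skip_weights.get(k, 0.0)
            info = ExonInfo(
                exon_id, gene_id, tid0, chrom, g1, g2, strand, k,
                n_exons, 1 < k < n_exons, hot_flags[k], inclusion,
            )
            truth.exons[exon_id] = info
            truth.hotspot_exons[exon_id] = hot_flags[k]

    genome_seqs = {c: "".join(parts) for c, parts in genome.items()}
    annotation = Annotation(genes)
    truth.site_usage = _expected_usage(truth.junction_weights)
    return annotation, genome_seqs, truth


def _expected_usage(
    weights: dict[Junction, float],
) -> dict[tuple[str, int, str, str], float]:
    """Exact expected A/(A+B+C) per splice site under the isoform mixture.

    Deliberately a stand-alone enumeration (not the analysis module's
    classifier) so planted values can cross-check it.
    """
    sites: set[tuple[str, int, str, str]] = set()
    flanks: dict[tuple[str, int, str, str], set[tuple[int, int]]] = {}
    for j in weights:
        d = (j.chrom, j.donor_boundary, "donor", j.strand)
        a = (j.chrom, j.acceptor_boundary, "acceptor", j.strand)
        sites.update((d, a))
        flanks.setdefault(d, set()).add((j.start, j.end))
        flanks.setdefault(a, set()).add((j.start, j.end))
    usage = {}
    for site in sites:
        chrom, pos, side, strand = site
        a = b = c = 0.0
        for j, w in weights.items():
            if j.chrom != chrom or j.strand != strand:
                continue
            own_end = j.donor_boundary if side == "donor" else j.acceptor_boundary
            if own_end == pos:
                a += w
            elif j.start < pos < j.end:
                b += w
            elif any(s < own_end < e for s, e in flanks[site]):
                c += w
        usage[site] = a / (a + b + c)
    return usage


def simulate_junction_reads(
    annotation: Annotation,
    truth: GroundTruth,
    config: SimulationConfig,
    cell_line: str = "cell1",
    replicate: int = 1,
) -> pd.DataFrame:
    """Poisson junction counts for one replicate of one cell line."""
    if config.read_depth <= 0:
        raise ValueError("read_depth must be positive")
    rng = np.random.default_rng(
        [config.seed, _STREAMS["junctions"],
         zlib.crc32(cell_line.encode()) % (2 ** 31), replicate]
    )
    rows = []
    for j in sorted(truth.junction_weights,
                    key=lambda j: (j.chrom, j.start, j.end, j.strand)):
        w = truth.junction_weights[j]
        n = int(rng.poisson(config.read_depth * w))
        if n > 0:
            rows.append((j.chrom, j.start, j.end, j.strand, n))
    return shio.junction_frame(rows, sample_id=f"{cell_line}_rep{replicate}")


def simulate_junction_samples(
    annotation: Annotation, truth: GroundTruth, config: SimulationConfig,
) -> dict[str, dict[int, pd.DataFrame]]:
    """All (cell line, replicate) junction tables."""
    out: dict[str, dict[int, pd.DataFrame]] = {}
    for c in range(config.n_cell_lines):
        cell = f"cell{c + 1}"
        out[cell] = {
            r: simulate_junction_reads(annotation, truth, config, cell, r)
            for r in range(1, config.n_replicates + 1)
        }
    return out


def simulate_mapsy(
    annotation: Annotation, truth: GroundTruth, config: SimulationConfig,
    genome: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Allele count table with exon-level susceptibility structure.

    Internal exons receive 2-6 assayed variants each until the configured
    total is reached.  A variant is planted as disrupting with probability
    ``disrupt_prob_hotspot`` (mildly graded by the exon's planted inclusion)
    in hotspot exons, else ``disrupt_prob_background``.  Disrupting variants
    get |log2 allelic ratio| ~ N(effect_size, 0.4), mostly negative;
    non-disrupting ones ~ N(0, 0.15).  Input counts are Poisson at
    ``mapsy_depth``; output counts are Poisson at a rate shifted by the true
    ratio.
    """
    config.validate()
    rng = config.rng("mapsy")
    internal = [e for e in truth.exons.values() if e.internal]
    order = rng.permutation(len(internal))
    rows = []
    vid = 0
    for idx in order:
        if vid >= config.n_mapsy_variants:
            break
        exon = internal[idx]
        k = int(rng.integers(2, 7))
        positions = rng.choice(exon.end - exon.start,
                               size=min(k, exon.end - exon.start),
                               replace=False)
        wt_rate = 0.25 + 0.65 * exon.inclusion
        # one characteristic effect per exon: variants in the same exon
        # shift splicing similarly (mostly towards more skipping)
        if config.effect_size > 0:
            exon_effect = max(1.6, rng.normal(config.effect_size, 0.4))
            if rng.random() < 0.8:
                exon_effect = -exon_effect
        else:
            exon_effect = 0.0
        for off in positions:
            vid += 1
            variant_id = f"var{vid:05d}"
            if exon.hotspot:
                p = config.disrupt_prob_hotspot * (1.15 - 0.4 * exon.inclusion)
            else:
                p = config.disrupt_prob_background
            disrupting = bool(rng.random() < min(0.98, max(0.0, p)))
            if disrupting and config.effect_size > 0:
                ar = rng.normal(exon_effect, 0.25)
            else:
                ar = rng.normal(0.0, 0.15)
            m_i = int(rng.poisson(config.mapsy_depth))
            w_i = int(rng.poisson(config.mapsy_depth))
            w_o = int(rng.poisson(config.mapsy_depth * wt_rate))
            m_o = int(rng.poisson(config.mapsy_depth * wt_rate * 2.0 ** ar))
            pos = int(exon.start + off)
            ref = genome[exon.chrom][pos] if genome else None
            alt = BASES[rng.integers(4)]
            while alt == ref:
                alt = BASES[rng.integers(4)]
            rows.append((variant_id, exon.exon_id, m_o, m_i, w_o, w_i,
                         exon.chrom, pos, alt, exon.strand))
            truth.variant_disrupting[variant_id] = disrupting
    return pd.DataFrame(
        rows,
        columns=["variant_id", "exon_id", "m_o", "m_i", "w_o", "w_i",
                 "chrom", "pos", "alt", "strand"],
    )


def _exon_window(info: ExonInfo, truth: GroundTruth) -> tuple[int, int]:
    """Genomic window from the end of the upstream exon to the start of the
    downstream exon (transcript orientation), truncated at transcript ends."""
    sibs = {
        e.index: e for e in truth.exons.values()
        if e.transcript_id == info.transcript_id
    }
    lo = min(e.start for e in sibs.values())
    hi = max(e.end for e in sibs.values())
    if info.strand == "+":
        up, down = sibs.get(info.index - 1), sibs.get(info.index + 1)
        return (up.end if up else lo), (down.start if down else hi)
    up, down = sibs.get(info.index - 1), sibs.get(info.index + 1)
    return (down.end if down else lo), (up.start if up else hi)


def simulate_rbp_data(
    annotation: Annotation, truth: GroundTruth, config: SimulationConfig,
    cell_line: str = "K562",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binding peaks plus a knockdown differential-splicing table.

    Functional peaks land in exon windows with probability proportional to
    ``exp(functional_cluster_strength x hotspot_flag)``; each (exon, RBP)
    pair holding a functional peak gets a knockdown row with FDR < 0.1,
    non-functional pairs get FDR in [0.2, 1).  Non-functional peaks share
    the functional length distribution.
    """
    config.validate()
    if config.n_rbps <= 0:
        raise ValueError("n_rbps must be positive")
    rng = np.random.default_rng(
        [config.seed, _STREAMS["rbp"], zlib.crc32(cell_line.encode()) % (2 ** 31)]
    )
    internal = sorted(
        (e for e in truth.exons.values() if e.internal),
        key=lambda e: e.exon_id,
    )
    w = np.array([
        np.exp(config.functional_cluster_strength * float(e.hotspot))
        for e in internal
    ])
    w = w / w.sum()
    rbps = [f"RBP{i + 1:02d}" for i in range(config.n_rbps)]
    functional_pairs: set[tuple[str, str]] = set()
    peak_rows = []

    def place_peak(info: ExonInfo, rbp: str, peak_id: str) -> tuple:
        # peaks sit in the exon body: each body lies in exactly one exon's
        # window, so planted labels are unambiguous
        length = int(rng.integers(20, 61))
        length = min(length, max(5, info.end - info.start - 1))
        start = int(rng.integers(info.start, max(info.start + 1,
                                                 info.end - length)))
        return (peak_id, rbp, cell_line, info.chrom, start, start + length,
                info.strand, info.exon_id)

    pid = 0
    for _ in range(config.n_functional_peaks):
        pid += 1
        info = internal[rng.choice(len(internal), p=w)]
        rbp = rbps[rng.integers(config.n_rbps)]
        peak_id = f"{cell_line}.peak{pid:05d}"
        peak_rows.append(place_peak(info, rbp, peak_id))
        functional_pairs.add((info.exon_id, rbp))
        truth.peak_functional[peak_id] = True
    for _ in range(config.n_nonfunctional_peaks):
        pid += 1
        for _try in range(50):
            info = internal[rng.integers(len(internal))]
            rbp = rbps[rng.integers(config.n_rbps)]
            if (info.exon_id, rbp) not in functional_pairs:
                break
        peak_id = f"{cell_line}.peak{pid:05d}"
        peak_rows.append(place_peak(info, rbp, peak_id))
        truth.peak_functional[peak_id] = False
    # unlabeled peaks: an RBP absent from the knockdown table
    for _ in range(config.n_unlabeled_peaks):
        pid += 1
        info = internal[rng.integers(len(internal))]
        peak_id = f"{cell_line}.peak{pid:05d}"
        peak_rows.append(place_peak(info, "RBPX", peak_id))

    peaks = pd.DataFrame(
        peak_rows,
        columns=["peak_id", "rbp_id", "cell_line", "chrom", "start", "end",
                 "strand", "host_exon_hint"],
    )
    kd_rows = []
    for info in internal:
        for rbp in rbps:
            functional = (info.exon_id, rbp) in functional_pairs
            if functional:
                fdr = float(rng.uniform(0.0, 0.1))
                dpsi = float(rng.uniform(0.1, 0.5)) * (
                    -1 if rng.random() < 0.7 else 1
                )
            else:
                fdr = float(rng.uniform(0.2, 1.0))
                dpsi = float(rng.normal(0.0, 0.02))
            kd_rows.append((info.chrom, info.start, info.end, info.strand,
                            rbp, cell_line, dpsi, fdr))
    knockdown = pd.DataFrame(
        kd_rows,
        columns=["chrom", "exonStart_0base", "exonEnd", "strand", "rbp_id",
                 "cell_line", "delta_psi", "fdr"],
    )
    return peaks, knockdown


def simulate_population_variants(
    annotation: Annotation, truth: GroundTruth, config: SimulationConfig,
    genome: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Poisson population variants, depleted in hotspot exons."""
    config.validate()
    rng = config.rng("variants")
    rows = []
    for exon_id in sorted(truth.exons):
        info = truth.exons[exon_id]
        rate = config.variant_rate * (
            config.variant_depletion if info.hotspot else 1.0
        )
        n = int(rng.poisson(rate * (info.end - info.start)))
        n = min(n, info.end - info.start)
        if n == 0:
            continue
        offsets = rng.choice(info.end - info.start, size=n, replace=False)
        for off in sorted(int(o) for o in offsets):
            pos = info.start + off
            ref = genome[info.chrom][pos] if genome else "N"
            alt = BASES[rng.integers(4)]
            while alt == ref:
                alt = BASES[rng.integers(4)]
            rows.append((info.chrom, pos, ref, alt))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


_CHAINS = {
    "both_included": "E1>TEST;TEST>FLANK;FLANK>E4",
    "test_skipped": "E1>FLANK;FLANK>E4",
    "flank_skipped": "E1>TEST;TEST>E4",
    "both_skipped": "E1>E4",
}


def _sigmoid(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-x)))


def minigene_inclusion_probability(config: SimulationConfig, s_t: float,
                                   s_f: float) -> float:
    """Planted test-exon inclusion under the flank-competition model.

    logit P(include) = alpha + beta_t*s_t - beta_f*max(0, tau - s_t)*s_f:
    a stronger flanking exon suppresses inclusion, but only for test exons
    weaker than the threshold tau.
    """
    tau = config.tau()
    logit = (
        config.minigene_alpha
        + config.minigene_beta_t * s_t
        - config.competition_beta * max(0.0, tau - s_t) * s_f
    )
    return _sigmoid(logit)


def simulate_minigene(
    config: SimulationConfig, truth: GroundTruth | None = None,
) -> pd.DataFrame:
    """Read table for the 4-exon minigene competition assay.

    One species per (test efficiency, flank efficiency) pair; reads are
    multinomial over the four distinguishable isoforms, assuming the test
    and flanking exons are included independently given their efficiencies.
    """
    config.validate()
    rng = config.rng("minigene")
    tests = sorted({t for t, _ in config.minigene_grid})
    group_of = {t: i + 1 for i, t in enumerate(tests)}
    rows = []
    for s_t, s_f in config.minigene_grid:
        gid = group_of[s_t]
        sid = f"g{gid}_f{s_f:g}"
        p_t = minigene_inclusion_probability(config, s_t, s_f)
        p_f = _sigmoid(config.minigene_alpha + config.minigene_beta_t * s_f)
        probs = [p_t * p_f, (1 - p_t) * p_f, p_t * (1 - p_f),
                 (1 - p_t) * (1 - p_f)]
        counts = rng.multinomial(config.minigene_depth, probs)
        if truth is not None:
            truth.minigene_inclusion[sid] = p_t
        for iso, n in zip(_CHAINS, counts):
            rows.append((sid, gid, s_t, s_f, _CHAINS[iso], int(n)))
    return pd.DataFrame(
        rows,
        columns=["species_id", "group_id", "test_efficiency",
                 "flank_efficiency", "chain", "count"],
    )


def simulate_hexamer_table(config: SimulationConfig) -> pd.DataFrame:
    """A hexamer score table with planted enhancer/silencer structure."""
    rng = config.rng("hexamers")
    import itertools

    mers = ["".join(p) for p in itertools.product(BASES, repeat=6)]
    scores = rng.normal(0.0, 0.5, size=len(mers))
    strong = rng.choice(len(mers), size=200, replace=False)
    scores[strong[:100]] += 2.0   # enhancers
    scores[strong[100:]] -= 2.0   # silencers
    return pd.DataFrame({"hexamer": mers, "score": np.round(scores, 4)})


def simulate_hi_scores(config: SimulationConfig,
                       annotation: Annotation) -> pd.DataFrame:
    """Gene-level haploinsufficiency scores, uniform on [0, 1]."""
    rng = config.rng("hi")
    gene_ids = sorted(annotation.genes)
    return pd.DataFrame(
        {"gene_id": gene_ids,
         "hi_score": np.round(rng.uniform(0, 1, size=len(gene_ids)), 4)}
    )


def exon_frame(truth: GroundTruth) -> pd.DataFrame:
    """The exon registry as the DataFrame the analysis modules consume."""
    rows = [
        (e.exon_id, e.gene_id, e.transcript_id, e.chrom, e.start, e.end,
         e.strand, e.index, e.internal, e.hotspot)
        for e in sorted(truth.exons.values(), key=lambda e: e.exon_id)
    ]
    return pd.DataFrame(
        rows,
        columns=["exon_id", "gene_id", "transcript_id", "chrom", "start",
                 "end", "strand", "index", "internal", "hotspot"],
    )


def write_dataset(config: SimulationConfig, outdir: str | Path) -> Path:
    """Generate and write the full synthetic dataset tree."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation, genome, truth = simulate_annotation(config)
    write_gtf(annotation, outdir / "annotation.gtf")
    shio.write_fasta(genome, outdir / "genome.fa")
    jdir = outdir / "junctions"
    jdir.mkdir(exist_ok=True)
    for cell, reps in simulate_junction_samples(annotation, truth, config).items():
        for rep, table in reps.items():
            shio.write_star_sj(table, jdir / f"{cell}_rep{rep}.tsv")
    mapsy = simulate_mapsy(annotation, truth, config, genome)
    mapsy.to_csv(outdir / "mapsy.tsv", sep="\t", index=False)
    peaks, knockdown = simulate_rbp_data(annotation, truth, config)
    shio.write_bed_peaks(peaks, outdir / "peaks.bed")
    knockdown.to_csv(outdir / "knockdown.tsv", sep="\t", index=False)
    variants = simulate_population_variants(annotation, truth, config, genome)
    shio.write_vcf(
        variants, outdir / "variants.vcf",
        contigs={c: len(s) for c, s in genome.items()},
    )
    simulate_minigene(config, truth).to_csv(
        outdir / "minigene.tsv", sep="\t", index=False
    )
    simulate_hexamer_table(config).to_csv(
        outdir / "hexamers.tsv", sep="\t", index=False
    )
    simulate_hi_scores(config, annotation).to_csv(
        outdir / "hi_scores.tsv", sep="\t", index=False
    )
    exon_frame(truth).to_csv(outdir / "exons.tsv", sep="\t", index=False)
    truth.to_json(outdir / "ground_truth.json")
    return outdir
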