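"""Splice-site usage from exon-exon junction reads.

For an annotated splice site, junction reads fall in three categories:

* **A** — the junction uses the site as one of its sides,
* **B** — the junction spans the site (both ends strictly beyond it in
  transcript orientation),
* **C** — for a donor (acceptor), the junction's donor (acceptor) end lies
  strictly inside an annotated intron downstream (upstream) of the site.

Usage is ``A / (A + B + C)``; the denominator approximates every read that
had the opportunity to use the site.  Categories are mutually exclusive with
precedence A > B > C.  Sites with no evidence (A+B+C = 0) are *undefined*,
not zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import Annotation, Junction, SpliceSite
from .io import JUNCTION_COLUMNS


@dataclass
class UsageRecord:
    site: SpliceSite
    A: int
    B: int
    C: int
    usage: float | None

    @property
    def defined(self) -> bool:
        return self.usage is not None


@dataclass
class SwitchScoreRecord:
    exon_id: str
    psi_by_condition: dict[str, float]
    switch_score: float
    insufficient_conditions: bool = False


def filter_annotated_junctions(junctions: pd.DataFrame,
                               annotation: Annotation) -> pd.DataFrame:
    """Keep junctions whose *both* ends match annotated splice sites.

    The donor end must coincide with an annotated donor boundary and the
    acceptor end with an annotated acceptor boundary on the same chromosome
    and strand.  Junctions with strand "." match a site on either strand.
    Counts are unchanged.
    """
    sites = annotation.site_set()
    if not sites:
        raise ValueError("annotation contains no splice sites")
    donors = {(s.chrom, s.strand, s.pos) for s in sites if s.side == "donor"}
    acceptors = {(s.chrom, s.strand, s.pos) for s in sites if s.side == "acceptor"}

    def keep(row) -> bool:
        strands = "+-" if row.strand == "." else row.strand
        for st in strands:
            d = row.start if st == "+" else row.end
            a = row.end if st == "+" else row.start
            if (row.chrom, st, d) in donors and (row.chrom, st, a) in acceptors:
                return True
        return False

    mask = [keep(r) for r in junctions.itertuples(index=False)]
    return junctions.loc[mask].reset_index(drop=True)


def collapse_replicates(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Sum junction counts over replicate tables."""
    if not tables:
        raise ValueError("no replicate tables given")
    chrom_sets = [set(t["chrom"]) for t in tables if len(t)]
    for i in range(1, len(chrom_sets)):
        if chrom_sets[i] and chrom_sets[0] and not (chrom_sets[i] & chrom_sets[0]):
            raise ValueError(
                "replicate tables share no chromosomes; are they from the "
                "same genome?"
            )
    cat = pd.concat(tables, ignore_index=True)
    out = (
        cat.groupby(["chrom", "start", "end", "strand"], as_index=False)["count"]
        .sum()
        .sort_values(["chrom", "start", "end"], kind="mergesort")
        .reset_index(drop=True)
    )
    out["sample_id"] = "collapsed"
    return out[JUNCTION_COLUMNS]


def classify_junction_for_site(site: SpliceSite, junction: Junction,
                               annotation: Annotation) -> str | None:
    """Assign a junction to category A, B, C or None for one site."""
    if junction.chrom != site.chrom:
        return None
    if junction.strand not in (".", site.strand):
        return None
    flanks = annotation.flanking_introns(site)
    if not flanks:
        raise ValueError(f"site {site} has no annotated flanking intron")
    p = site.pos
    if site.strand == "+":
        donor_end, acceptor_end = junction.start, junction.end
    else:
        donor_end, acceptor_end = junction.end, junction.start
    # A: junction uses the site as its same-side end
    if site.side == "donor" and donor_end == p:
        return "A"
    if site.side == "acceptor" and acceptor_end == p:
        return "A"
    # B: strict spanning; genomic containment is strand-symmetric
    if junction.start < p < junction.end:
        return "B"
    # C: same-side end strictly inside a flanking intron
    end = donor_end if site.side == "donor" else acceptor_end
    for s, e in flanks:
        if s < end < e:
            return "C"
    return None


def compute_usage(site: SpliceSite, junctions: pd.DataFrame,
                  annotation: Annotation) -> UsageRecord:
    """Category counts and usage for one site from a junction table."""
    a = b = c = 0
    for r in junctions.itertuples(index=False):
        cat = classify_junction_for_site(
            site, Junction(r.chrom, int(r.start), int(r.end), r.strand),
            annotation,
        )
        if cat == "A":
            a += int(r.count)
        elif cat == "B":
            b += int(r.count)
        elif cat == "C":
            c += int(r.count)
    total = a + b + c
    usage = a / total if total > 0 else None
    return UsageRecord(site, a, b, c, usage)


def _candidate_mask(p: int, lo: int, hi: int, starts: np.ndarray,
                    ends: np.ndarray) -> np.ndarray:
    span = (starts <= p) & (ends >= p)
    near = ((starts >= lo) & (starts <= hi)) | ((ends >= lo) & (ends <= hi))
    return span | near


def usage_table(annotation: Annotation,
                junctions: pd.DataFrame | list[pd.DataFrame]) -> pd.DataFrame:
    """Usage for every annotated site, per sample.

    Returns a frame with columns chrom, pos, side, strand, sample_id,
    A, B, C, usage (NaN when undefined), ordered by (chrom, pos, side).
    """
    if isinstance(junctions, list):
        junctions = pd.concat(junctions, ignore_index=True)
    rows = []
    sites = annotation.splice_sites()
    for sample_id, table in junctions.groupby("sample_id"):
        by_chrom = {c: g for c, g in table.groupby("chrom")}
        for site in sites:
            sub = by_chrom.get(site.chrom)
            if sub is None or not len(sub):
                rows.append((site.chrom, site.pos, site.side, site.strand,
                             sample_id, 0, 0, 0, np.nan))
                continue
            flanks = annotation.flanking_introns(site)
            lo = min(s for s, _ in flanks)
            hi = max(e for _, e in flanks)
            lo, hi = min(lo, site.pos), max(hi, site.pos)
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            mask = _candidate_mask(site.pos, lo, hi, starts, ends)
            rec = compute_usage(site, sub.loc[mask], annotation)
            rows.append((site.chrom, site.pos, site.side, site.strand,
                         sample_id, rec.A, rec.B, rec.C,
                         np.nan if rec.usage is None else rec.usage))
    out = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "side", "strand", "sample_id",
                 "A", "B", "C", "usage"],
    )
    return out.sort_values(
        ["sample_id", "chrom", "pos", "side"], kind="mergesort"
    ).reset_index(drop=True)


DEFAULT_VARIANCE_THRESHOLD = 0.001


def averaged_track(usage_tables: dict[str, pd.DataFrame],
                   variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD,
                   min_defined_fraction: float = 0.5) -> pd.DataFrame:
    """Cross-cell-line mean usage, limited to low-variance sites.

    Per site the mean and (population) variance of usage across cell lines
    are computed over the lines where usage is defined; sites defined in
    fewer than ``min_defined_fraction`` of lines, or fewer than two lines,
    are dropped; of the rest only sites with variance strictly below
    ``variance_threshold`` are emitted.
    """
    if len(usage_tables) < 2:
        raise ValueError("averaged track requires at least two cell lines")
    n_lines = len(usage_tables)
    frames = []
    for line, tbl in usage_tables.items():
        t = tbl[["chrom", "pos", "side", "strand", "usage"]].copy()
        t["cell_line"] = line
        frames.append(t)
    cat = pd.concat(frames, ignore_index=True).dropna(subset=["usage"])
    grp = cat.groupby(["chrom", "pos", "side", "strand"])["usage"]
    stat = grp.agg(
        mean_usage="mean",
        variance=lambda v: float(np.var(v, ddof=0)),
        n_defined="count",
    ).reset_index()
    stat = stat[
        (stat["n_defined"] >= 2)
        & (stat["n_defined"] >= min_defined_fraction * n_lines)
        & (stat["variance"] < variance_threshold)
    ]
    return stat.sort_values(["chrom", "pos", "side"],
                            kind="mergesort").reset_index(drop=True)


def write_track_bed(track: pd.DataFrame, path: str | Path) -> None:
    """Export the averaged track as BED6 (score = 1000 x mean usage)."""
    with open(path, "w") as fh:
        for r in track.itertuples(index=False):
            score = int(round(1000 * r.mean_usage))
            name = f"{r.side}{r.strand}"
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.pos + 1}\t{name}\t{score}\t{r.strand}\n"
            )


def switch_score(exon_id: str,
                 psi_by_condition: dict[str, float]) -> SwitchScoreRecord:
    """Maximum pairwise |PSI difference| across conditions.

    Equals max(PSI) - min(PSI); zero (with a flag) below two conditions.
    """
    vals = list(psi_by_condition.values())
    for v in vals:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"PSI outside [0, 1]: {v}")
    if len(vals) < 2:
        return SwitchScoreRecord(exon_id, dict(psi_by_condition), 0.0, True)
    return SwitchScoreRecord(
        exon_id, dict(psi_by_condition), max(vals) - min(vals), False
    )
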