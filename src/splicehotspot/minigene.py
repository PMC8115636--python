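"""Minigene isoform classification and the ESCo association test.

The 4-exon reporter construct is a constant first exon, a test exon, a
flanking exon and a constant last exon; the four distinguishable spliced
isoforms are both-included, test-skipped, flank-skipped and both-skipped.
ESCo (enhancement by suppression of competitors) shows up as test-exon
skipping that *increases* with the splicing efficiency of the flanking
exon — so the per-group test is a positive Spearman association between
skipping rate and flank efficiency, with a seeded permutation p-value
because groups are small (typically 8 species).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

CONSTRUCT = ("E1", "TEST", "FLANK", "E4")
ISOFORMS = ("both_included", "test_skipped", "flank_skipped", "both_skipped")


def classify_isoform(chain: str,
                     construct: tuple[str, ...] = CONSTRUCT) -> str:
    """Isoform category of one junction chain, or "unassignable".

    A chain is a ';'-separated list of 'donorExon>acceptorExon' junctions.
    It must start at the first constant exon, end at the last, proceed
    strictly forward through the construct and be contiguous; anything
    else — unknown exons, gaps, reversals, emptiness — is unassignable.
    """
    if not chain or not chain.strip():
        return "unassignable"
    order = {name: i for i, name in enumerate(construct)}
    path = []
    for link in chain.split(";"):
        if ">" not in link:
            return "unassignable"
        a, b = link.split(">", 1)
        if a not in order or b not in order or order[b] <= order[a]:
            return "unassignable"
        if path and path[-1] != a:
            return "unassignable"
        if not path:
            path.append(a)
        path.append(b)
    if path[0] != construct[0] or path[-1] != construct[-1]:
        return "unassignable"
    test_in = construct[1] in path
    flank_in = construct[2] in path
    if test_in and flank_in:
        return "both_included"
    if flank_in:
        return "test_skipped"
    if test_in:
        return "flank_skipped"
    return "both_skipped"


def summarize_reads(reads: pd.DataFrame,
                    construct: tuple[str, ...] = CONSTRUCT) -> pd.DataFrame:
    """Per-species isoform counts from a chain-level read table.

    ``reads`` needs species_id, chain, count; species metadata columns
    (group_id, test_efficiency, flank_efficiency) are carried through.
    Reads whose chain is unassignable are tallied separately so that
    assigned + unassignable = total.
    """
    reads = reads.copy()
    reads["isoform"] = [classify_isoform(c, construct) for c in reads["chain"]]
    meta_cols = [c for c in ("group_id", "test_efficiency", "flank_efficiency")
                 if c in reads.columns]
    pivot = (
        reads.pivot_table(index="species_id", columns="isoform",
                          values="count", aggfunc="sum", fill_value=0)
        .reindex(columns=[*ISOFORMS, "unassignable"], fill_value=0)
        .reset_index()
    )
    if meta_cols:
        meta = reads.drop_duplicates("species_id")[["species_id", *meta_cols]]
        pivot = pivot.merge(meta, on="species_id")
    pivot.columns.name = None
    return pivot


@dataclass
class SkippingRate:
    rate: float
    ci_low: float
    ci_high: float
    n: int


def skipping_rate(counts: pd.Series | dict) -> SkippingRate:
    """Test-exon skipping proportion with a Wilson interval.

    Skipped = test-skipped + both-skipped, over all assigned reads.
    """
    total = sum(int(counts[i]) for i in ISOFORMS)
    if total <= 0:
        raise ValueError("no assigned reads for species")
    skipped = int(counts["test_skipped"]) + int(counts["both_skipped"])
    lo, hi = proportion_confint(skipped, total, method="wilson")
    return SkippingRate(skipped / total, float(lo), float(hi), total)


def add_skipping_rates(species_counts: pd.DataFrame) -> pd.DataFrame:
    out = species_counts.copy()
    rates = [skipping_rate(r) for _, r in out.iterrows()]
    out["skip_rate"] = [r.rate for r in rates]
    out["skip_ci_low"] = [r.ci_low for r in rates]
    out["skip_ci_high"] = [r.ci_high for r in rates]
    return out


def _permutation_spearman(x: np.ndarray, y: np.ndarray, n_perm: int,
                          rng: np.random.Generator) -> tuple[float, float]:
    """One-sided (positive) permutation p for the Spearman correlation.

    Spearman rho is the Pearson correlation of (average) ranks, so the
    permutation distribution is computed vectorized on rank matrices.
    """
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum())
    if denom == 0:  # constant ranks on either side
        return 0.0, 1.0
    rho = float((rx_c * ry_c).sum() / denom)
    perms = rng.permuted(
        np.broadcast_to(ry_c, (n_perm, len(ry_c))).copy(), axis=1
    )
    null = perms @ rx_c / denom
    p = float((1 + (null >= rho).sum()) / (1 + n_perm))
    return rho, p


def esco_test(species_counts: pd.DataFrame, n_permutations: int = 10_000,
              seed: int | None = None,
              alpha: float = 0.05) -> pd.DataFrame:
    """Per-group association of test-exon skipping with flank efficiency.

    For each library group (one test exon paired with all flanking exons),
    the Spearman correlation of skipping rate versus flank efficiency is
    tested one-sided (positive) by permutation.  ESCo is called when the
    correlation is positive and p < alpha; groups with fewer than 3
    species are flagged untestable.
    """
    if "skip_rate" not in species_counts.columns:
        species_counts = add_skipping_rates(species_counts)
    rng = np.random.default_rng(seed)
    rows = []
    for gid, grp in species_counts.groupby("group_id"):
        if len(grp) < 3:
            rows.append((gid, len(grp), np.nan, np.nan, False, False))
            continue
        rho, p = _permutation_spearman(
            grp["flank_efficiency"].to_numpy(),
            grp["skip_rate"].to_numpy(),
            n_permutations, rng,
        )
        rows.append((gid, len(grp), rho, p, bool(rho > 0 and p < alpha), True))
    return pd.DataFrame(
        rows,
        columns=["group_id", "n_species", "spearman_rho", "p_value",
                 "esco_detected", "testable"],
    )
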