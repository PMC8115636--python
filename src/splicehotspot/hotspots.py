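"""Hotspot-exon calling and variant-tolerance validation.

An exon is a hotspot when strictly more than 10% of its 3L possible SNVs
are predicted splice-disrupting (classifier score strictly above 0.5).
Hotspots are validated against population-variant data: truly susceptible
exons should tolerate fewer variants per base (distinct observed variants /
exon length) than size-matched non-hotspot exons from the same genes, with
an optional restriction to genes above the median haploinsufficiency (HI)
score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

HOTSPOT_PROPORTION_CUTOFF = 0.10
SCORE_CUTOFF = 0.5


def is_hotspot(n_disrupting: int, n_possible: int,
               proportion_cutoff: float = HOTSPOT_PROPORTION_CUTOFF) -> bool:
    """The hotspot rule: strictly more than 10% of all possible exonic
    SNVs predicted splice-disrupting."""
    if n_possible <= 0:
        raise ValueError("n_possible must be positive")
    return n_disrupting / n_possible > proportion_cutoff


def call_hotspots(scores: pd.DataFrame, exons: pd.DataFrame,
                  proportion_cutoff: float = HOTSPOT_PROPORTION_CUTOFF,
                  score_cutoff: float = SCORE_CUTOFF) -> pd.DataFrame:
    """Hotspot calls from per-SNV scores.

    ``scores`` needs exon_id and score, with one row per possible SNV;
    exons whose score count differs from 3 x length are flagged uncallable.
    Both thresholds are strict inequalities.
    """
    lengths = (
        exons.set_index("exon_id")
        .eval("end - start")
        .astype(int)
    )
    grp = scores.groupby("exon_id")["score"]
    n_scored = grp.count()
    n_disrupting = grp.apply(lambda s: int((s > score_cutoff).sum()))
    rows = []
    for exon_id in lengths.index:
        n_possible = 3 * int(lengths[exon_id])
        ns = int(n_scored.get(exon_id, 0))
        nd = int(n_disrupting.get(exon_id, 0))
        callable_ = ns == n_possible
        proportion = nd / n_possible if n_possible else np.nan
        hot = bool(
            callable_
            and is_hotspot(nd, n_possible, proportion_cutoff)
        )
        rows.append(
            (exon_id, n_possible, ns, nd, proportion, hot, callable_)
        )
    return pd.DataFrame(
        rows,
        columns=["exon_id", "n_possible", "n_scored", "n_disrupting",
                 "proportion", "hotspot", "callable"],
    )


def variants_per_base(variants: pd.DataFrame,
                      exons: pd.DataFrame) -> pd.DataFrame:
    """Distinct observed variants per exonic base.

    Variants are distinct by (position, alt allele); a variant is assigned
    to every exon whose interval contains it.
    """
    v = variants.drop_duplicates(["chrom", "pos", "alt"])
    rows = []
    by_chrom = {c: g for c, g in v.groupby("chrom")}
    for e in exons.itertuples(index=False):
        sub = by_chrom.get(e.chrom)
        if sub is None:
            n = 0
        else:
            n = int(((sub["pos"] >= e.start) & (sub["pos"] < e.end)).sum())
        length = int(e.end - e.start)
        rows.append((e.exon_id, n, length, n / length))
    return pd.DataFrame(
        rows,
        columns=["exon_id", "n_observed_variants", "length_bp",
                 "variants_per_base"],
    )


def assign_hi(exons: pd.DataFrame, hi_scores: pd.DataFrame,
              transcript_weights: dict[str, float] | None = None,
              exon_transcripts: dict[str, list[str]] | None = None,
              transcript_genes: dict[str, str] | None = None) -> pd.Series:
    """Per-exon HI score via the exon's dominant transcript.

    Each exon inherits the HI score of the gene of the transcript it is
    most often transcribed in, where dominance comes from the supplied
    transcript usage weights (ties broken lexicographically by transcript
    id).  Without weights or a multi-transcript mapping, the registry's own
    transcript column is used.  Exons whose gene has no score get NaN.
    """
    hi = hi_scores.set_index("gene_id")["hi_score"]
    out = {}
    for e in exons.itertuples(index=False):
        candidates = (
            exon_transcripts.get(e.exon_id, [e.transcript_id])
            if exon_transcripts else [e.transcript_id]
        )
        if transcript_weights:
            top_w = max(transcript_weights.get(t, 0.0) for t in candidates)
            best = sorted(
                t for t in candidates
                if transcript_weights.get(t, 0.0) == top_w
            )[0]
        else:
            best = sorted(candidates)[0]
        gene = (
            transcript_genes.get(best) if transcript_genes else e.gene_id
        )
        out[e.exon_id] = float(hi.get(gene, np.nan))
    return pd.Series(out, name="hi_score")


def hi_median_filter(exon_table: pd.DataFrame,
                     gene_column: str = "gene_id",
                     score_column: str = "hi_score",
                     median: float | None = None) -> pd.DataFrame:
    """Drop exons whose HI score is below the median over genes.

    By default the median is computed across the distinct genes present in
    the input (one score per gene), not across exons.  Pass ``median`` to
    filter against a fixed threshold instead — re-deriving the median from
    an already-filtered table would tighten the cut on every application.
    """
    if median is None:
        per_gene = exon_table.drop_duplicates(gene_column)[score_column]
        median = float(per_gene.median())
    return exon_table[exon_table[score_column] >= median].reset_index(drop=True)


@dataclass
class ToleranceComparison:
    n_hotspot: int
    t_statistic: float
    p_value: float
    mean_vpb_hotspot: float
    mean_vpb_control: float
    mean_length_hotspot: float
    mean_length_control: float
    hi_filtered: bool


def _greedy_size_match(hotspot: pd.DataFrame, pool: pd.DataFrame,
                       rng: np.random.Generator) -> pd.DataFrame:
    """For each hotspot exon pick the unused pool exon of closest length."""
    order = rng.permutation(len(hotspot))  # seeded order breaks length ties
    pool = pool.reset_index(drop=True)
    available = np.ones(len(pool), dtype=bool)
    pool_len = pool["length_bp"].to_numpy()
    picks = []
    for i in order:
        target = hotspot.iloc[int(i)]["length_bp"]
        cand = np.where(available)[0]
        best = cand[np.argmin(np.abs(pool_len[cand] - target))]
        available[best] = False
        picks.append(best)
    return pool.iloc[picks]


def tolerance_comparison(
    exons: pd.DataFrame,
    hotspot_flags: pd.Series,
    tolerance: pd.DataFrame,
    seed: int | None = None,
    hi_scores: pd.Series | None = None,
) -> dict[str, ToleranceComparison]:
    """Down-sampled, size-matched variants-per-base comparison.

    Controls are non-hotspot exons drawn from the genes that contain the
    hotspot exons, greedily matched on length without replacement; the
    one-sided Welch t test asks whether hotspot exons carry fewer variants
    per base.  Run on all exons and, when HI scores are supplied, again
    after the HI median filter.
    """
    results = {}
    for label, filtered in (("unfiltered", False), ("hi_filtered", True)):
        if filtered and hi_scores is None:
            continue
        tbl = exons.merge(tolerance, on="exon_id")
        tbl["hotspot"] = tbl["exon_id"].map(hotspot_flags).astype(bool)
        if filtered:
            tbl["hi_score"] = tbl["exon_id"].map(hi_scores)
            tbl = tbl.dropna(subset=["hi_score"])
            tbl = hi_median_filter(tbl)
        hot = tbl[tbl["hotspot"]]
        genes = set(hot["gene_id"])
        pool = tbl[~tbl["hotspot"] & tbl["gene_id"].isin(genes)]
        if hot.empty or pool.empty:
            raise ValueError("both hotspot and control groups must be non-empty")
        if len(pool) < len(hot):
            raise ValueError(
                f"control pool smaller than hotspot set by {len(hot) - len(pool)}"
            )
        rng = np.random.default_rng(seed)
        control = _greedy_size_match(hot, pool, rng)
        t, p = stats.ttest_ind(
            hot["variants_per_base"], control["variants_per_base"],
            equal_var=False, alternative="less",
        )
        results[label] = ToleranceComparison(
            n_hotspot=len(hot),
            t_statistic=float(t),
            p_value=float(p),
            mean_vpb_hotspot=float(hot["variants_per_base"].mean()),
            mean_vpb_control=float(control["variants_per_base"].mean()),
            mean_length_hotspot=float(hot["length_bp"].mean()),
            mean_length_control=float(control["length_bp"].mean()),
            hi_filtered=filtered,
        )
    return results


def cutoff_sweep(scores: pd.DataFrame, tolerance: pd.DataFrame,
                 exons: pd.DataFrame,
                 cutoffs: list[float],
                 retention_floor: float = 0.01,
                 score_cutoff: float = SCORE_CUTOFF) -> tuple[pd.DataFrame, float]:
    """Variants-per-base separation across proportion cutoffs.

    Per cutoff: the hotspot count and the mean variants-per-base difference
    (non-hotspot minus hotspot).  The selected cutoff maximizes the
    difference among cutoffs retaining at least ``retention_floor`` of the
    exons as hotspots.
    """
    merged = tolerance.set_index("exon_id")
    base = call_hotspots(scores, exons, proportion_cutoff=-1.0,
                         score_cutoff=score_cutoff)
    base = base.set_index("exon_id")
    rows = []
    n_total = len(base)
    for cut in cutoffs:
        hot_ids = base.index[base["proportion"] > cut]
        cold_ids = base.index.difference(hot_ids)
        n_hot = len(hot_ids)
        vh = merged.loc[merged.index.intersection(hot_ids), "variants_per_base"]
        vc = merged.loc[merged.index.intersection(cold_ids), "variants_per_base"]
        diff = (
            float(vc.mean() - vh.mean()) if len(vh) and len(vc) else np.nan
        )
        rows.append((cut, n_hot, diff))
    report = pd.DataFrame(rows, columns=["cutoff", "n_hotspot", "vpb_difference"])
    ok = report[report["n_hotspot"] >= retention_floor * n_total].dropna(
        subset=["vpb_difference"]
    )
    selected = float(
        ok.loc[ok["vpb_difference"].idxmax(), "cutoff"]
    ) if len(ok) else float("nan")
    return report, selected
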