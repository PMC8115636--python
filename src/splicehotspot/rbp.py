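"""Functional RBP binding sites and the sampled sites-per-exon null.

A binding peak is *functional* for an exon when it falls inside the exon's
window (from the end of the upstream exon to the start of the downstream
exon, exon body included) and knockdown of the peak's RBP changes that
exon's splicing at FDR < 0.1.  Whether functional sites pile up in
particular exons is judged against a null built by repeatedly drawing the
same number of sites, without replacement, from the non-functional pool —
a sampling scheme that carries all sequence and expression biases of real
peaks into the expectation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mapsy import ConditionalProbResult, conditional_probabilities

FDR_THRESHOLD = 0.1


@dataclass
class ExonWindow:
    exon_id: str
    chrom: str
    start: int
    end: int
    strand: str
    single_exon: bool = False


def exon_windows(exons: pd.DataFrame) -> pd.DataFrame:
    """Window per exon: (upstream exon end, downstream exon start).

    ``exons`` is the registry (exon_id, chrom, start, end, strand,
    transcript_id).  First/last exons are truncated at the transcript
    boundary on the missing side; single-exon transcripts collapse to the
    exon itself and are flagged.
    """
    rows = []
    for _, grp in exons.groupby("transcript_id"):
        g = grp.sort_values("start").reset_index(drop=True)
        t_start, t_end = int(g["start"].min()), int(g["end"].max())
        for i, r in g.iterrows():
            left = int(g.loc[i - 1, "end"]) if i > 0 else t_start
            right = int(g.loc[i + 1, "start"]) if i < len(g) - 1 else t_end
            rows.append((r["exon_id"], r["chrom"], left, right, r["strand"],
                         len(g) == 1))
    return pd.DataFrame(
        rows,
        columns=["exon_id", "chrom", "window_start", "window_end", "strand",
                 "single_exon"],
    )


def label_functional_sites(
    peaks: pd.DataFrame,
    splicing_changes: pd.DataFrame,
    exons: pd.DataFrame,
    fdr_threshold: float = FDR_THRESHOLD,
) -> pd.DataFrame:
    """Label every (peak, exon-window) overlap as functional or not.

    A peak labels an exon when their intervals overlap, the knockdown table
    has a row for that exon and the peak's RBP in the peak's cell line, and
    the label is functional iff that row's FDR < ``fdr_threshold``.  Peaks
    overlapping no tested exon window appear in no label row; a peak whose
    RBP is absent from the knockdown table triggers a warning.  One row per
    (peak, exon) pair is emitted.
    """
    peaks = peaks.copy()
    if "peak_id" not in peaks.columns:
        peaks["peak_id"] = [f"peak{i:06d}" for i in range(len(peaks))]
    windows = exon_windows(exons)
    exon_coords = exons.set_index("exon_id")[["chrom", "start", "end"]]
    kd = splicing_changes.copy()
    kd["exon_id"] = _match_exons(kd, exon_coords)
    kd = kd.dropna(subset=["exon_id"])
    kd_idx = {
        (r.exon_id, r.rbp_id, r.cell_line): r.fdr
        for r in kd.itertuples(index=False)
    }
    kd_rbps = set(kd["rbp_id"])
    missing_rbps = set(peaks["rbp_id"]) - kd_rbps
    if missing_rbps:
        warnings.warn(
            "peaks for RBPs absent from the knockdown table are left "
            f"unlabeled: {sorted(missing_rbps)}"
        )
    rows = []
    win_by_chrom = {c: g for c, g in windows.groupby("chrom")}
    for p in peaks.itertuples(index=False):
        wins = win_by_chrom.get(p.chrom)
        if wins is None:
            continue
        hit = wins[(wins["window_start"] < p.end) & (wins["window_end"] > p.start)]
        for w in hit.itertuples(index=False):
            key = (w.exon_id, p.rbp_id, p.cell_line)
            if key not in kd_idx:
                continue
            rows.append(
                (p.peak_id, p.rbp_id, p.cell_line, p.chrom, p.start, p.end,
                 w.exon_id, bool(kd_idx[key] < fdr_threshold))
            )
    return pd.DataFrame(
        rows,
        columns=["peak_id", "rbp_id", "cell_line", "chrom", "start", "end",
                 "host_exon_id", "functional"],
    )


def _match_exons(kd: pd.DataFrame, exon_coords: pd.DataFrame) -> list:
    """Map knockdown rows (exonStart_0base/exonEnd) onto exon ids."""
    lookup = {
        (r["chrom"], int(r["start"]), int(r["end"])): exon_id
        for exon_id, r in exon_coords.iterrows()
    }
    out = []
    start_col = "exonStart_0base" if "exonStart_0base" in kd.columns else "start"
    end_col = "exonEnd" if "exonEnd" in kd.columns else "end"
    for r in kd.itertuples(index=False):
        out.append(
            lookup.get((r.chrom, getattr(r, start_col), getattr(r, end_col)))
        )
    return out


def sites_per_exon(labels: pd.DataFrame,
                   functional_only: bool = True) -> pd.Series:
    """Distinct RBPs per exon (not raw peak counts)."""
    t = labels[labels["functional"]] if functional_only else labels
    if t.empty:
        return pd.Series(dtype=int)
    return t.groupby("host_exon_id")["rbp_id"].nunique()


def _histogram(counts: pd.Series, max_k: int | None = None) -> pd.Series:
    h = counts.value_counts().sort_index()
    if max_k is not None:
        h = h.reindex(range(1, max_k + 1), fill_value=0)
    return h


def expected_distribution(
    nonfunctional_labels: pd.DataFrame,
    n_draw: int,
    n_iter: int = 1000,
    seed: int | None = None,
    count: str = "rbps",
) -> pd.DataFrame:
    """Null sites-per-exon histogram from the non-functional pool.

    Each iteration draws ``n_draw`` sites without replacement and tallies
    how many exons hold k sites; the mean and SEM (SD over iterations /
    sqrt(n_iter)) per k are returned.  ``count`` selects whether k counts
    distinct RBPs per exon (default, matching the observed statistic) or
    raw peaks.
    """
    pool = nonfunctional_labels.reset_index(drop=True)
    if len(pool) < n_draw:
        raise ValueError(
            f"non-functional pool ({len(pool)}) smaller than draw ({n_draw})"
        )
    rng = np.random.default_rng(seed)
    exon_ids = pool["host_exon_id"].to_numpy()
    rbp_ids = pool["rbp_id"].to_numpy()
    hists = []
    max_k = 0
    for _ in range(n_iter):
        take = rng.choice(len(pool), size=n_draw, replace=False)
        df = pd.DataFrame({"exon": exon_ids[take], "rbp": rbp_ids[take]})
        if count == "rbps":
            per_exon = df.groupby("exon")["rbp"].nunique()
        elif count == "peaks":
            per_exon = df.groupby("exon")["rbp"].count()
        else:
            raise ValueError(f"unknown count mode {count!r}")
        h = per_exon.value_counts().sort_index()
        hists.append(h)
        max_k = max(max_k, int(h.index.max()))
    mat = np.zeros((n_iter, max_k))
    for i, h in enumerate(hists):
        for k, v in h.items():
            mat[i, int(k) - 1] = v
    return pd.DataFrame(
        {
            "k": np.arange(1, max_k + 1),
            "expected_exons": mat.mean(axis=0),
            "expected_sem": mat.std(axis=0, ddof=1) / np.sqrt(n_iter),
        }
    )


def enrichment(observed: pd.Series, expected: pd.DataFrame) -> pd.DataFrame:
    """Observed / expected exon counts per k (inf where expected is 0)."""
    obs_hist = _histogram(observed)
    ks = sorted(set(obs_hist.index) | set(expected["k"]))
    exp_idx = expected.set_index("k")
    rows = []
    for k in ks:
        o = int(obs_hist.get(k, 0))
        e = float(exp_idx["expected_exons"].get(k, 0.0))
        sem = float(exp_idx["expected_sem"].get(k, np.nan))
        if e > 0:
            ratio = o / e
        else:
            ratio = np.inf if o > 0 else np.nan
        rows.append((int(k), o, e, sem, ratio))
    return pd.DataFrame(
        rows,
        columns=["k", "observed_exons", "expected_exons", "expected_sem",
                 "enrichment"],
    )


def eclip_conditional(labels: pd.DataFrame, mode: str = "exhaustive",
                      seed: int | None = None,
                      n_repeats: int = 1000) -> ConditionalProbResult:
    """Conditional functional probability over binding sites in one exon.

    Sites are deduplicated to (exon, RBP) units; the pair-sampling contract
    matches the variant-level conditional probabilities.
    """
    units = (
        labels.drop_duplicates(["host_exon_id", "rbp_id"])
        .rename(columns={"host_exon_id": "exon_id"})
    )
    return conditional_probabilities(
        units, mode=mode, seed=seed, n_repeats=n_repeats,
        label_column="functional",
    )
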