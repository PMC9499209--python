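"""AUROC evaluation, the two baseline scoring procedures, and rank-based
cross-method comparison (Friedman test with Nemenyi post-hoc)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .motifs import MPBS

__all__ = [
    "EvalResult",
    "auroc",
    "fps_baseline_scores",
    "footprint_overlap_scores",
    "rank_compare",
    "RankComparison",
]


@dataclass(frozen=True)
class EvalResult:
    tf_name: str
    method: str
    auroc: float
    n_bound: int
    n_unbound: int
    replicate: int = 0

    def __post_init__(self):
        if not np.isfinite(self.auroc):
            raise ValueError("non-finite AUROC")


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUROC; tied scores contribute 1/2."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both classes present")
    ranks = stats.rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def fps_baseline_scores(
    mpbss: list[MPBS], footprint_tracks: dict[str, np.ndarray]
) -> np.ndarray:
    """Mean footprint score over [start, end) of each MPBS.

    ``footprint_tracks`` maps chromosome -> per-base footprint-score array.
    """
    out = np.empty(len(mpbss))
    for i, m in enumerate(mpbss):
        track = footprint_tracks[m.chrom]
        out[i] = track[m.start : m.end].mean()
    return out


def footprint_overlap_scores(
    mpbss: list[MPBS], footprint_regions: list[tuple[str, int, int]]
) -> np.ndarray:
    """PWM score, plus the maximum PWM score if the MPBS overlaps (>= 1 bp)
    any footprint region; overlapping sites thereby outrank all others."""
    raw = np.array([m.pwm_score for m in mpbss], dtype=np.float64)
    if len(mpbss) == 0:
        return raw
    max_score = raw.max()
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in footprint_regions:
        by_chrom.setdefault(chrom, []).append((start, end))
    out = raw.copy()
    for i, m in enumerate(mpbss):
        for start, end in by_chrom.get(m.chrom, ()):
            if m.start < end and start < m.end:
                out[i] += max_score
                break
    return out


@dataclass
class RankComparison:
    mean_ranks: pd.Series  # method -> mean rank over TFs
    per_tf_ranks: pd.DataFrame  # TF x method mean rank over replicates
    friedman_statistic: float
    friedman_pvalue: float
    nemenyi_pvalues: pd.DataFrame  # method x method pairwise


def _nemenyi(per_tf_ranks: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Nemenyi post-hoc p-values from a blocks x treatments rank table."""
    n, k = per_tf_ranks.shape
    mean_ranks = per_tf_ranks.mean(axis=0)
    denom = np.sqrt(k * (k + 1) / (6.0 * n))
    methods = list(per_tf_ranks.columns)
    pvals = pd.DataFrame(np.ones((k, k)), index=methods, columns=methods)
    for i in range(k):
        for j in range(i + 1, k):
            q = abs(mean_ranks.iloc[i] - mean_ranks.iloc[j]) / denom * np.sqrt(2)
            p = float(stats.studentized_range.sf(q, k, np.inf))
            pvals.iloc[i, j] = pvals.iloc[j, i] = p
    return pvals


def rank_compare(results: list[EvalResult]) -> RankComparison:
    """Rank methods per TF per replicate (rank 1 = highest AUROC, ties get
    average ranks), average ranks over replicates, then run the Friedman
    chi-square over TFs x methods with Nemenyi pairwise post-hoc tests."""
    df = pd.DataFrame([r.__dict__ for r in results])
    methods = sorted(df["method"].unique())
    tfs = sorted(df["tf_name"].unique())
    replicates = sorted(df["replicate"].unique())
    pivot = df.pivot_table(
        index=["tf_name", "replicate"], columns="method", values="auroc"
    )
    expected = {(tf, rep) for tf in tfs for rep in replicates}
    missing = expected - set(pivot.index) | (
        set() if not pivot.isna().any().any() else {"na"}
    )
    if missing or pivot.isna().any().any():
        raise ValueError("rank_compare requires every (TF, method, replicate) cell")
    # rank within each (TF, replicate): higher AUROC -> lower rank number
    ranks = pivot.apply(
        lambda row: stats.rankdata(-row.values), axis=1, result_type="broadcast"
    )
    per_tf = ranks.groupby(level="tf_name").mean()[methods]
    mean_ranks = per_tf.mean(axis=0)
    # Friedman over TFs (blocks), using replicate-averaged AUROCs
    auroc_by_tf = df.pivot_table(index="tf_name", columns="method", values="auroc")
    with np.errstate(invalid="ignore"):
        fr_stat, fr_p = stats.friedmanchisquare(
            *[auroc_by_tf[m].values for m in methods]
        )
    if np.isnan(fr_stat):  # scipy's tie correction degenerates on all-ties
        fr_stat, fr_p = 0.0, 1.0
    return RankComparison(
        mean_ranks=mean_ranks,
        per_tf_ranks=per_tf,
        friedman_statistic=float(fr_stat),
        friedman_pvalue=float(fr_p),
        nemenyi_pvalues=_nemenyi(per_tf),
    )
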