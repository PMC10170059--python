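"""Coefficient-of-variation screening of candidate reference genes.

A reference (housekeeping) gene should be expressed at a usable level and
vary little across biological conditions. Screening therefore works on
log2(TPM) after averaging biological replicates on the TPM scale, and keeps
genes that satisfy all of

    mean log2(TPM)  >  min_mean_log2tpm   (default 5; ≤ 5 is excluded),
    SD   log2(TPM)  <  max_sd_log2tpm     (default 1),
    CV = SD / mean  <  max_cv             (default 0.2),

with the sample (n−1) standard deviation across conditions. Genes with any
non-positive TPM after replicate averaging are excluded outright
(``nonpositive_tpm``): a gene that is undetectable in some condition cannot
normalize qPCR there, and a pseudocount would distort CV near the cut-offs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io_core import ExpressionMatrix

__all__ = [
    "ScreenConfig",
    "ScreenResult",
    "collapse_replicates",
    "gene_log_stats",
    "screen_candidates",
    "top_candidates",
    "intersect_candidates",
    "summary_line",
]

STATS_COLUMNS = [
    "gene_id",
    "mean_log2tpm",
    "sd_log2tpm",
    "cv",
    "n_conditions",
    "excluded_reason",
]


@dataclass
class ScreenConfig:
    """Thresholds of the three screening filters; all strict inequalities."""

    min_mean_log2tpm: float = 5.0
    max_sd_log2tpm: float = 1.0
    max_cv: float = 0.2
    top_n: int = 10

    def __post_init__(self) -> None:
        if min(self.min_mean_log2tpm, self.max_sd_log2tpm, self.max_cv) <= 0:
            raise ValueError("all screening thresholds must be > 0")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")


@dataclass
class ScreenResult:
    stats: pd.DataFrame  # STATS_COLUMNS, one row per gene, input order
    candidates: list[str] = field(default_factory=list)  # sorted by (cv, gene_id)
    n_total: int = 0
    n_candidates: int = 0

    @property
    def fraction_candidates(self) -> float:
        """Candidates as a percentage of all screened genes."""
        return 100.0 * self.n_candidates / self.n_total


def collapse_replicates(m: ExpressionMatrix) -> ExpressionMatrix:
    """Average biological replicates on the TPM scale, one column per condition.

    Condition column order follows first appearance in the sample order, so
    the operation never reorders what the sample sheet laid out.
    """
    conds = m.conditions
    cols = {}
    for c in conds:
        members = [s for s in m.sample_ids if m.condition_of_sample[s] == c]
        cols[c] = m.values[members].mean(axis=1)
    collapsed = pd.DataFrame(cols, index=m.values.index)
    return ExpressionMatrix(collapsed, {c: c for c in conds})


def gene_log_stats(m: ExpressionMatrix, collapse: bool = True) -> pd.DataFrame:
    """Per-gene mean, SD and CV of log2(TPM) across conditions.

    Returns a DataFrame with :data:`STATS_COLUMNS` in the matrix's gene
    order. Genes with any TPM ≤ 0 get ``excluded_reason="nonpositive_tpm"``
    and NaN statistics; all other genes get ``excluded_reason="none"`` here
    (filters are applied later by :func:`screen_candidates`).
    """
    if collapse:
        m = collapse_replicates(m)
    vals = m.values
    if vals.shape[1] < 2:
        raise ValueError("CV undefined with fewer than 2 conditions")
    arr = vals.to_numpy(dtype=float)
    n_cond = vals.shape[1]

    nonpos = (arr <= 0).any(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2 = np.log2(np.where(arr > 0, arr, np.nan))
    mean = log2.mean(axis=1)
    sd = log2.std(axis=1, ddof=1)
    cv = np.where(mean != 0, sd / mean, np.nan)

    mean[nonpos] = np.nan
    sd[nonpos] = np.nan
    cv[nonpos] = np.nan

    return pd.DataFrame(
        {
            "gene_id": vals.index,
            "mean_log2tpm": mean,
            "sd_log2tpm": sd,
            "cv": cv,
            "n_conditions": n_cond,
            "excluded_reason": np.where(nonpos, "nonpositive_tpm", "none"),
        }
    ).reset_index(drop=True)


def screen_candidates(
    stats: pd.DataFrame, cfg: ScreenConfig | None = None
) -> ScreenResult:
    """Apply the three filters and report the candidate set.

    The first failing filter, in the order low_expression → high_sd →
    high_cv, is recorded as the exclusion reason; ``nonpositive_tpm`` from
    the stats stage is preserved. Candidates come back sorted by ascending
    CV with lexicographic gene id as the tie-break.
    """
    if stats is None or len(stats) == 0:
        raise ValueError("no gene statistics to screen")
    cfg = cfg or ScreenConfig()
    out = stats.copy()

    reasons = out["excluded_reason"].to_numpy(dtype=object).copy()
    mean = out["mean_log2tpm"].to_numpy(dtype=float)
    sd = out["sd_log2tpm"].to_numpy(dtype=float)
    cv = out["cv"].to_numpy(dtype=float)

    scorable = reasons == "none"
    low = scorable & ~(mean > cfg.min_mean_log2tpm)
    reasons[low] = "low_expression"
    high_sd = scorable & ~low & ~(sd < cfg.max_sd_log2tpm)
    reasons[high_sd] = "high_sd"
    high_cv = scorable & ~low & ~high_sd & ~(cv < cfg.max_cv)
    reasons[high_cv] = "high_cv"
    out["excluded_reason"] = reasons

    passing = out.loc[reasons == "none", ["gene_id", "cv"]]
    ordered = passing.sort_values(["cv", "gene_id"], kind="mergesort")
    candidates = list(ordered["gene_id"])
    return ScreenResult(
        stats=out,
        candidates=candidates,
        n_total=len(out),
        n_candidates=len(candidates),
    )


def top_candidates(result: ScreenResult, n: int | None = None) -> pd.DataFrame:
    """The ``n`` lowest-CV candidates with their statistics, best first."""
    if n is None:
        n = ScreenConfig().top_n
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > result.n_candidates:
        warnings.warn(
            f"requested top {n} but only {result.n_candidates} candidates pass",
            stacklevel=2,
        )
        n = result.n_candidates
    chosen = result.candidates[:n]
    stats = result.stats.set_index("gene_id").loc[chosen].reset_index()
    return stats


def summary_line(n_candidates: int, n_total: int) -> str:
    """Human-readable screening summary, percentage to two decimals."""
    pct = 100.0 * n_candidates / n_total
    return f"{n_candidates} ({pct:.2f}%) of {n_total}"


def intersect_candidates(
    results: Mapping[str, "ScreenResult | Iterable[str]"],
) -> dict:
    """Venn-partition counts for 2 or 3 labelled candidate sets.

    Returns ``{"regions": {labels-tuple: exclusive count},
    "intersections": {labels-tuple: plain |∩| count}}`` where tuples are
    sorted label subsets. ``regions`` partitions the union (the numbers a
    Venn diagram displays); ``intersections`` are the unpartitioned overlap
    sizes for every subset of ≥ 2 labels.
    """
    if not 2 <= len(results) <= 3:
        raise ValueError("intersect_candidates takes 2 or 3 labelled results")
    sets = {
        label: set(r.candidates) if isinstance(r, ScreenResult) else set(r)
        for label, r in results.items()
    }
    labels = list(sets)
    regions: dict[tuple, int] = {}
    for k in range(1, len(labels) + 1):
        from itertools import combinations

        for combo in combinations(labels, k):
            inside = set.intersection(*(sets[l] for l in combo))
            outside = set.union(set(), *(sets[l] for l in labels if l not in combo))
            regions[tuple(sorted(combo))] = len(inside - outside)
    intersections = {
        key: len(set.intersection(*(sets[l] for l in key)))
        for key in regions
        if len(key) >= 2
    }
    return {"regions": regions, "intersections": intersections}
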