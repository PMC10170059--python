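"""Four RT-qPCR expression-stability statistics on a candidate gene panel.

Given a gene × sample Ct matrix, the panel is scored by:

* **geNorm** — M value: the mean, over all partner genes, of the SD of the
  pairwise log2 expression ratio across samples; genes are eliminated
  iteratively (highest M first) and the pairwise variation V(n→n+1)
  measures the effect of adding an (n+1)-th gene to the normalization
  factor (the per-sample geometric mean of the n most stable genes).
* **NormFinder** — model-based decomposition of log-scale expression into
  intra-group variance and (shrunken) inter-group deviation; the stability
  value combines both. Ungrouped data fall back to the simple measure: the
  SD of sample-centered values with a bias correction for the gene count.
* **BestKeeper** — descriptive statistics of raw Ct (the headline dispersion
  statistic here is the sample SD of Ct) plus each gene's Pearson
  correlation with the BestKeeper index, the per-sample geometric mean of
  Ct over the whole panel.
* **ΔCt method** — each gene's mean, over all partners, of the sample SD of
  the pairwise Ct difference.

Lower scores mean more stable for all four methods; each result object
carries a ``ranks`` Series (1 = most stable, average ranks for ties).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_core import CtMatrix

__all__ = [
    "QuantityMatrix",
    "GenormResult",
    "NormfinderResult",
    "BestkeeperResult",
    "DeltaCtResult",
    "ct_to_quantity",
    "genorm",
    "normfinder",
    "bestkeeper",
    "delta_ct",
]


def _complete_case(ct: CtMatrix, context: str) -> pd.DataFrame:
    """Drop genes with any missing Ct, warning with the count dropped."""
    vals = ct.values
    bad = vals.isna().any(axis=1)
    if bad.any():
        warnings.warn(
            f"{context}: dropped {int(bad.sum())} gene(s) with missing Ct "
            "(complete-case analysis)",
            stacklevel=3,
        )
        vals = vals.loc[~bad]
    return vals


@dataclass
class QuantityMatrix:
    """Relative quantities Q = E^(minCt − Ct), calibrated so max(Q) = 1 per gene."""

    values: pd.DataFrame
    efficiency: float = 2.0

    def __post_init__(self) -> None:
        if (self.values.to_numpy() <= 0).any():
            raise ValueError("relative quantities must be strictly positive")


def ct_to_quantity(ct: CtMatrix, efficiency: float = 2.0) -> QuantityMatrix:
    """Convert Ct to relative quantities with amplification efficiency E.

    E = 2 assumes perfect doubling per cycle. Each gene is calibrated to its
    own lowest Ct (highest expression), giving per-gene max(Q) = 1.
    """
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    vals = _complete_case(ct, "ct_to_quantity")
    arr = vals.to_numpy(dtype=float)
    q = efficiency ** (arr.min(axis=1, keepdims=True) - arr)
    return QuantityMatrix(
        pd.DataFrame(q, index=vals.index, columns=vals.columns), efficiency
    )


# ---------------------------------------------------------------------------
# geNorm


@dataclass
class GenormResult:
    m_values: pd.Series  # first-round M per gene
    exclusion_order: list[str]  # removed first → last (length G−2)
    ranks: pd.Series  # 1.5/1.5 for the final untied pair, then 3, 4, ...
    pairwise_variation: pd.Series  # index "V2/3", ... value SD(log2 NFn/NFn+1)
    stability_order: list[str] = field(default_factory=list)  # most stable first

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.m_values.index,
                "m_value": self.m_values.to_numpy(),
                "rank": self.ranks.reindex(self.m_values.index).to_numpy(),
            }
        )


def _genorm_m(logq: pd.DataFrame) -> pd.Series:
    """M_j = mean over partners k≠j of SD across samples of log2(Q_j/Q_k)."""
    arr = logq.to_numpy(dtype=float)
    g = arr.shape[0]
    # pairwise SD of differences; vectorized over partner axis
    diffs = arr[:, None, :] - arr[None, :, :]  # g × g × samples
    sd = diffs.std(axis=2, ddof=1)
    m = sd.sum(axis=1) / (g - 1)  # diagonal contributes 0
    return pd.Series(m, index=logq.index)


def genorm(q: QuantityMatrix) -> GenormResult:
    """geNorm M values, stepwise exclusion ranking and pairwise variation V.

    The two genes remaining after stepwise exclusion cannot be ordered by
    the method and share rank 1.5. Ties in M during exclusion are broken by
    removing the lexicographically larger gene id, for determinism.
    """
    vals = q.values
    genes = list(vals.index)
    G = len(genes)
    if G < 3:
        raise ValueError("geNorm requires at least 3 genes")
    if vals.shape[1] < 2:
        raise ValueError("geNorm requires at least 2 samples")
    logq = np.log2(vals)

    m_first = _genorm_m(logq)

    remaining = list(genes)
    exclusion: list[str] = []
    while len(remaining) > 2:
        m = _genorm_m(logq.loc[remaining])
        worst = max(remaining, key=lambda gname: (m[gname], gname))
        exclusion.append(worst)
        remaining.remove(worst)

    # most stable first: the untied final pair (id order), then reverse exclusion
    stability_order = sorted(remaining) + exclusion[::-1]
    ranks = pd.Series(index=vals.index, dtype=float)
    ranks[remaining] = 1.5
    for pos, gname in enumerate(exclusion[::-1]):
        ranks[gname] = 3 + pos

    # pairwise variation V(n→n+1) from normalization factors
    v = {}
    logq_ordered = logq.loc[stability_order].to_numpy()
    for n in range(2, G):
        nf_n = logq_ordered[:n].mean(axis=0)  # log2 of geometric mean
        nf_n1 = logq_ordered[: n + 1].mean(axis=0)
        v[f"V{n}/{n + 1}"] = float(np.std(nf_n - nf_n1, ddof=1))
    return GenormResult(
        m_values=m_first,
        exclusion_order=exclusion,
        ranks=ranks,
        pairwise_variation=pd.Series(v),
        stability_order=stability_order,
    )


# ---------------------------------------------------------------------------
# NormFinder


@dataclass
class NormfinderResult:
    rho: pd.Series  # stability value, lower = more stable
    sigma2: pd.Series  # intragroup variance estimate (mean over groups)
    d: pd.DataFrame | None  # gene × group intergroup deviation (grouped mode)
    mode: str  # "grouped" | "ungrouped"
    ranks: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.rho.index,
                "stability": self.rho.to_numpy(),
                "rank": self.ranks.reindex(self.rho.index).to_numpy(),
            }
        )


def _gene_count_corrected_var(z: np.ndarray, denom_df: int) -> np.ndarray:
    """Unbiased per-gene variances from row residuals of a centered matrix.

    Centering each sample on its gene average leaks 2/n of every gene's own
    variance plus 1/n² of the panel total into the residuals; solving the
    moment equations gives the correction below (n = gene count).
    """
    n = z.shape[0]
    s2 = (z**2).sum(axis=1) / denom_df
    total = s2.sum() / (1 - 1 / n)  # unbiased estimate of Σσ²
    sigma2 = (s2 - total / n**2) / (1 - 2 / n)
    return np.clip(sigma2, 0.0, None)


def normfinder(
    ct: CtMatrix,
    groups: dict[str, str] | None = None,
    efficiency: float = 2.0,
) -> NormfinderResult:
    """NormFinder stability values on log2-scale expression.

    Ct is mapped to the log2 quantity scale as −Ct·log2(E); all statistics
    are invariant to the per-gene additive calibration, so no explicit
    quantity conversion is needed. With ``groups`` (≥2 groups, each ≥2
    samples) the full model is fitted: per-group intra-group variances with
    the gene-count bias correction, inter-group deviations d shrunk toward
    zero by their estimated signal/(signal+noise) ratio, and

        stability(gene) = mean over groups of |d̃_ig| + sqrt(σ̂²_ig / n_g),

    i.e. the shrunken inter-group deviation plus the intra-group variation's
    contribution to the uncertainty of the group mean. Without groups the
    simple measure is returned: the bias-corrected SD of the gene's
    sample-centered log quantities.
    """
    groups = groups if groups is not None else ct.group_of_sample
    vals = _complete_case(ct, "normfinder")
    genes = list(vals.index)
    n = len(genes)
    if n < 3:
        raise ValueError("NormFinder requires at least 3 genes")
    y = -vals.to_numpy(dtype=float) * np.log2(efficiency)  # log2 quantity scale

    if groups is None:
        if y.shape[1] < 3:
            raise ValueError("ungrouped NormFinder requires at least 3 samples")
        z = y - y.mean(axis=0, keepdims=True)  # sample-centered
        z = z - z.mean(axis=1, keepdims=True)
        sigma2 = _gene_count_corrected_var(z, denom_df=y.shape[1] - 1)
        rho = pd.Series(np.sqrt(sigma2), index=genes)
        result = NormfinderResult(
            rho=rho, sigma2=pd.Series(sigma2, index=genes), d=None, mode="ungrouped"
        )
        result.ranks = result.rho.rank(method="average")
        return result

    labels = [groups[s] for s in vals.columns]
    group_names = sorted(set(labels))
    if len(group_names) < 2:
        raise ValueError("grouped NormFinder requires at least 2 groups")
    cols = {gname: [i for i, l in enumerate(labels) if l == gname] for gname in group_names}
    sizes = {gname: len(ix) for gname, ix in cols.items()}
    small = [gname for gname, k in sizes.items() if k < 2]
    if small:
        raise ValueError(f"groups with fewer than 2 samples: {small}")

    G = len(group_names)
    sigma2 = np.empty((n, G))
    gene_group_mean = np.empty((n, G))
    for j, gname in enumerate(group_names):
        block = y[:, cols[gname]]
        gene_group_mean[:, j] = block.mean(axis=1)
        z = block - block.mean(axis=0, keepdims=True)
        z = z - z.mean(axis=1, keepdims=True)
        sigma2[:, j] = _gene_count_corrected_var(z, denom_df=sizes[gname] - 1)

    # inter-group deviation: gene-by-group interaction of the group means
    centered = gene_group_mean - gene_group_mean.mean(axis=0, keepdims=True)
    d = centered - centered.mean(axis=1, keepdims=True)

    ng = np.array([sizes[gname] for gname in group_names], dtype=float)
    samp_var = sigma2 / ng  # sampling variance of each d̂
    gamma2 = max(0.0, (d**2).sum() / ((n - 1) * (G - 1)) - samp_var.mean())
    with np.errstate(divide="ignore", invalid="ignore"):
        shrink = np.where(gamma2 + samp_var > 0, gamma2 / (gamma2 + samp_var), 0.0)
    d_tilde = d * shrink
    rho_ig = np.abs(d_tilde) + np.sqrt(samp_var)
    rho = pd.Series(rho_ig.mean(axis=1), index=genes)

    result = NormfinderResult(
        rho=rho,
        sigma2=pd.Series(sigma2.mean(axis=1), index=genes),
        d=pd.DataFrame(d_tilde, index=genes, columns=group_names),
        mode="grouped",
    )
    result.ranks = result.rho.rank(method="average")
    return result


# ---------------------------------------------------------------------------
# BestKeeper


@dataclass
class BestkeeperResult:
    stats: pd.DataFrame  # per-gene descriptives + r vs index + p
    index: pd.Series  # per-sample geometric mean of Ct
    ranks: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def table(self) -> pd.DataFrame:
        out = self.stats.copy()
        out["rank"] = self.ranks.reindex(out["gene_id"]).to_numpy()
        return out


def bestkeeper(ct: CtMatrix) -> BestkeeperResult:
    """BestKeeper descriptives, index correlation and SD-based ranking.

    Genes with SD(Ct) > 1 cycle are flagged inconsistent (the tool's
    conventional cut-off for genes too variable to keep). A zero-variance
    gene has no defined correlation with the index; r and p are reported
    missing and the gene is ranked by SD alone (SD = 0 ranks first).
    """
    vals = _complete_case(ct, "bestkeeper")
    if vals.shape[0] < 2:
        raise ValueError("BestKeeper requires at least 2 genes")
    if vals.shape[1] < 3:
        raise ValueError("BestKeeper requires at least 3 samples")
    arr = vals.to_numpy(dtype=float)
    if (arr <= 0).any():
        raise ValueError("BestKeeper requires Ct > 0 (geometric mean)")

    index = np.exp(np.log(arr).mean(axis=0))  # per-sample geometric mean of Ct
    mean = arr.mean(axis=1)
    sd = arr.std(axis=1, ddof=1)
    r = np.full(len(vals), np.nan)
    p = np.full(len(vals), np.nan)
    for i in range(len(vals)):
        if sd[i] > 0 and np.std(index) > 0:
            r[i], p[i] = sps.pearsonr(arr[i], index)
    stats = pd.DataFrame(
        {
            "gene_id": vals.index,
            "mean_ct": mean,
            "geo_mean_ct": np.exp(np.log(arr).mean(axis=1)),
            "min_ct": arr.min(axis=1),
            "max_ct": arr.max(axis=1),
            "sd_ct": sd,
            "cv_pct": 100.0 * sd / mean,
            "r_index": r,
            "p_value": p,
            "inconsistent": sd > 1.0,
        }
    ).reset_index(drop=True)
    ranks = pd.Series(sd, index=vals.index).rank(method="average")
    return BestkeeperResult(
        stats=stats, index=pd.Series(index, index=vals.columns), ranks=ranks
    )


# ---------------------------------------------------------------------------
# comparative ΔCt


@dataclass
class DeltaCtResult:
    scores: pd.Series  # mean pairwise SD per gene
    pairwise_sd: pd.DataFrame  # symmetric gene × gene table, 0 diagonal
    ranks: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.scores.index,
                "mean_pairwise_sd": self.scores.to_numpy(),
                "rank": self.ranks.reindex(self.scores.index).to_numpy(),
            }
        )


def delta_ct(ct: CtMatrix) -> DeltaCtResult:
    """Comparative ΔCt stability: mean SD of pairwise Ct differences.

    Missing wells are handled pairwise complete-case: each gene pair uses
    the samples where both genes were measured (a warning reports how many
    pairs lost samples). Pairs with fewer than 2 shared samples contribute
    nothing to either gene's mean.
    """
    vals = ct.values
    genes = list(vals.index)
    G = len(genes)
    if G < 2:
        raise ValueError("ΔCt method requires at least 2 genes")
    arr = vals.to_numpy(dtype=float)
    present = ~np.isnan(arr)

    sd = np.zeros((G, G))
    incomplete = 0
    for j in range(G):
        for k in range(j + 1, G):
            both = present[j] & present[k]
            nb = int(both.sum())
            if nb < both.size:
                incomplete += 1
            if nb < 2:
                sd[j, k] = sd[k, j] = np.nan
                continue
            diff = arr[j, both] - arr[k, both]
            sd[j, k] = sd[k, j] = diff.std(ddof=1)
    if incomplete:
        warnings.warn(
            f"delta_ct: {incomplete} gene pair(s) computed on a reduced "
            "sample set (pairwise complete-case)",
            stacklevel=2,
        )
    table = pd.DataFrame(sd, index=genes, columns=genes)
    off_diag = table.where(~np.eye(G, dtype=bool))
    scores = off_diag.mean(axis=1, skipna=True)
    result = DeltaCtResult(scores=scores, pairwise_sd=table)
    result.ranks = scores.rank(method="average")
    return result
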