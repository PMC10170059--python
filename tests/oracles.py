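"""Independent brute-force oracles, kept deliberately naive.

Everything here is written with explicit Python loops and the textbook
formulas, so that agreement with the package is a genuine cross-check and
not a reimplementation of the same code path.
"""

from __future__ import annotations

import math
import statistics

import numpy as np


def mean_sd_cv_log2(tpm_row):
    """Per-gene log2 statistics by direct enumeration (sample SD)."""
    logs = [math.log2(v) for v in tpm_row]
    mu = sum(logs) / len(logs)
    sd = statistics.stdev(logs)
    return mu, sd, sd / mu


def condition_means(values, sample_conditions):
    """Per-condition arithmetic means of a single gene's TPM row."""
    out = {}
    for cond in dict.fromkeys(sample_conditions):
        vals = [v for v, c in zip(values, sample_conditions) if c == cond]
        out[cond] = sum(vals) / len(vals)
    return out


def genorm_m(quantities):
    """M values by the double-loop definition on a gene × sample array."""
    q = np.asarray(quantities, dtype=float)
    g = q.shape[0]
    m = []
    for j in range(g):
        sds = []
        for k in range(g):
            if k == j:
                continue
            ratios = [math.log2(q[j, s] / q[k, s]) for s in range(q.shape[1])]
            sds.append(statistics.stdev(ratios))
        m.append(sum(sds) / len(sds))
    return np.array(m)


def genorm_v(quantities, stability_order, index_of):
    """Pairwise variation V(n→n+1) from explicit normalization factors."""
    q = np.asarray(quantities, dtype=float)
    out = []
    for n in range(2, q.shape[0]):
        top_n = [index_of[g] for g in stability_order[:n]]
        top_n1 = [index_of[g] for g in stability_order[: n + 1]]
        ratios = []
        for s in range(q.shape[1]):
            nf_n = math.prod(q[i, s] for i in top_n) ** (1 / n)
            nf_n1 = math.prod(q[i, s] for i in top_n1) ** (1 / (n + 1))
            ratios.append(math.log2(nf_n / nf_n1))
        out.append(statistics.stdev(ratios))
    return np.array(out)


def bestkeeper_stats(ct):
    """Descriptives, index and Pearson r by explicit formulas."""
    ct = np.asarray(ct, dtype=float)
    g, n = ct.shape
    index = [math.prod(ct[:, s]) ** (1 / g) for s in range(n)]
    rows = []
    for j in range(g):
        x = list(ct[j])
        mean = sum(x) / n
        sd = statistics.stdev(x)
        xm = mean
        im = sum(index) / n
        num = sum((a - xm) * (b - im) for a, b in zip(x, index))
        den = math.sqrt(
            sum((a - xm) ** 2 for a in x) * sum((b - im) ** 2 for b in index)
        )
        r = num / den if den > 0 else float("nan")
        rows.append(
            {
                "mean": mean,
                "geo_mean": math.prod(x) ** (1 / n),
                "min": min(x),
                "max": max(x),
                "sd": sd,
                "cv_pct": 100 * sd / mean,
                "r": r,
            }
        )
    return rows, index


def delta_ct_scores(ct):
    """Mean pairwise SD of Ct differences, double loop."""
    ct = np.asarray(ct, dtype=float)
    g = ct.shape[0]
    scores = []
    for j in range(g):
        sds = []
        for k in range(g):
            if k == j:
                continue
            diffs = [ct[j, s] - ct[k, s] for s in range(ct.shape[1])]
            sds.append(statistics.stdev(diffs))
        scores.append(sum(sds) / len(sds))
    return np.array(scores)


def ols(x, y):
    """Closed-form normal equations: slope, intercept, R², p-value."""
    import scipy.stats

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    sxy = float(((x - xm) * (y - ym)).sum())
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - intercept - slope * x
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - ym) ** 2).sum())
    r2 = 1 - ss_res / ss_tot
    f = (ss_tot - ss_res) / (ss_res / (n - 2))
    p = float(scipy.stats.f.sf(f, 1, n - 2))
    return slope, intercept, r2, p


def geometric_mean_ranks(ranks):
    """Product-then-root geometric mean of a rank tuple."""
    prod = math.prod(ranks)
    return prod ** (1 / len(ranks))
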