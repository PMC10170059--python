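"""Synthetic expression and Ct data with the structure the pipeline assumes.

The generator emulates bulk RNA-seq experiments of the kind the screening
stage consumes: a multi-condition design (developmental stages, tissues or
stress timepoints) with a few biological replicates per condition, where a
minority of genes is stably expressed on the log2(TPM) scale and the rest
shift with condition. Expression noise is log-normal (Normal on log2), the
scale the whole analysis operates on.

Ct values for a qPCR panel are generated from the global linear calibration
Ct = ct_slope · log2(TPM) + ct_intercept plus independent Gaussian cycle
noise, optionally with per-gene, per-group Ct shifts to create inter-group
structure for grouped NormFinder.

All randomness flows from the single integer ``seed`` in the spec through
one ``numpy.random.Generator``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_core import CtMatrix, ExpressionMatrix, SampleSheet

__all__ = [
    "SyntheticSpec",
    "simulate_expression",
    "simulate_ct",
    "simulate_calibration_pairs",
    "sample_sheet_for",
]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study.

    Defaults mirror a nine-condition developmental series with three
    biological replicates. ``fraction_stable`` genes draw per-condition
    log2 values with SD in ``stable_sd_range`` (well inside the SD < 1 and
    CV < 0.2 screening cut-offs); the rest use ``unstable_sd_range``. Ct
    coefficients default to the transcriptome→qPCR calibration line
    (−0.5405, 34.51); ``ct_noise_sd`` of 2.5 cycles reproduces the weakly
    correlated scatter seen when pooling many genes and samples.
    """

    n_genes: int = 2000
    n_conditions: int = 9
    n_replicates: int = 3
    fraction_stable: float = 0.1
    stable_sd_range: tuple[float, float] = (0.01, 0.15)
    unstable_sd_range: tuple[float, float] = (1.2, 3.0)
    mean_log2tpm_range: tuple[float, float] = (6.0, 18.0)
    replicate_noise_sd: float = 0.1
    ct_slope: float = -0.5405
    ct_intercept: float = 34.51
    ct_noise_sd: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_stable <= 1.0:
            raise ValueError("fraction_stable must be within [0, 1]")
        for lo, hi in (self.stable_sd_range, self.unstable_sd_range):
            if lo < 0 or hi < lo:
                raise ValueError("SD ranges must be non-negative and ordered")
        if self.replicate_noise_sd < 0 or self.ct_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if min(self.n_genes, self.n_conditions, self.n_replicates) < 1:
            raise ValueError("design dimensions must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def to_dict(self) -> dict:
        return asdict(self)


def _sample_ids(spec: SyntheticSpec) -> tuple[list[str], dict[str, str]]:
    samples, cond_of = [], {}
    for c in range(1, spec.n_conditions + 1):
        for r in range(1, spec.n_replicates + 1):
            sid = f"c{c:02d}_r{r}"
            samples.append(sid)
            cond_of[sid] = f"c{c:02d}"
    return samples, cond_of


def sample_sheet_for(m: ExpressionMatrix) -> SampleSheet:
    """Sample sheet (sample_id, condition, replicate) matching a matrix."""
    counter: dict[str, int] = {}
    rows = []
    for s in m.sample_ids:
        cond = m.condition_of_sample[s]
        counter[cond] = counter.get(cond, 0) + 1
        rows.append({"sample_id": s, "condition": cond, "replicate": counter[cond]})
    return SampleSheet(pd.DataFrame(rows))


def simulate_expression(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple[ExpressionMatrix, dict[str, str]]:
    """Simulate a TPM matrix plus per-gene truth labels {stable, unstable}.

    Per gene: a baseline μ ~ U(mean_log2tpm_range); per-condition log2
    values are Gaussian draws recentered and rescaled so the realized
    condition-level mean is exactly μ and the realized SD exactly the value
    drawn from the class's SD range (stable genes additionally guarded so
    the SD stays below both 1 and 0.2·μ). Targeting the realized dispersion
    makes the screening outcome hold by construction rather than only in
    expectation: labels describe what the gene's log2 profile actually does.
    Replicate technical noise N(0, replicate_noise_sd) is added afterwards;
    TPM = 2^value.
    """
    rng = rng or spec.rng()
    genes = [f"gene{g + 1:05d}" for g in range(spec.n_genes)]
    n_stable = int(round(spec.fraction_stable * spec.n_genes))
    stable_idx = set(rng.choice(spec.n_genes, size=n_stable, replace=False).tolist())
    truth = {
        g: ("stable" if i in stable_idx else "unstable") for i, g in enumerate(genes)
    }

    samples, cond_of = _sample_ids(spec)
    log2 = np.empty((spec.n_genes, len(samples)))
    mu = rng.uniform(*spec.mean_log2tpm_range, size=spec.n_genes)
    for i in range(spec.n_genes):
        if i in stable_idx:
            lo, hi = spec.stable_sd_range
            hi = min(hi, 1.0, 0.2 * mu[i])  # CV/SD guard, binding only for tiny μ
            sd = rng.uniform(lo, max(lo, hi))
        else:
            sd = rng.uniform(*spec.unstable_sd_range)
        z = rng.normal(0.0, 1.0, size=spec.n_conditions)
        if spec.n_conditions >= 2 and z.std(ddof=1) > 0:
            z = (z - z.mean()) / z.std(ddof=1)  # realized SD = sd exactly
        cond_vals = mu[i] + sd * z
        per_sample = np.repeat(cond_vals, spec.n_replicates)
        log2[i] = per_sample + rng.normal(0, spec.replicate_noise_sd, len(samples))
    tpm = np.exp2(log2)
    m = ExpressionMatrix(pd.DataFrame(tpm, index=genes, columns=samples), cond_of)
    return m, truth


def simulate_ct(
    expr: ExpressionMatrix,
    spec: SyntheticSpec,
    panel: Sequence[str],
    rng: np.random.Generator | None = None,
    group_of_sample: Mapping[str, str] | None = None,
    group_shifts: Mapping[str, Mapping[str, float]] | None = None,
    ct_noise_sd: float | None = None,
) -> CtMatrix:
    """Ct table for a gene panel from the calibration line plus cycle noise.

    ``group_shifts`` (gene → group → Ct offset) injects inter-group
    expression differences for grouped designs; it requires
    ``group_of_sample``. ``ct_noise_sd`` overrides the spec's global value,
    e.g. to model within-panel technical noise rather than cross-study
    scatter.
    """
    rng = rng or spec.rng()
    missing = [g for g in panel if g not in set(expr.gene_ids)]
    if missing:
        raise ValueError(f"panel genes absent from expression matrix: {missing}")
    sub = expr.values.loc[list(panel)]
    if (sub.to_numpy() <= 0).any():
        raise ValueError("panel TPM must be positive")
    noise_sd = spec.ct_noise_sd if ct_noise_sd is None else ct_noise_sd
    ct = spec.ct_intercept + spec.ct_slope * np.log2(sub.to_numpy())
    ct = ct + rng.normal(0, noise_sd, ct.shape)
    if group_shifts is not None:
        if group_of_sample is None:
            raise ValueError("group_shifts requires group_of_sample")
        for i, g in enumerate(panel):
            if g in group_shifts:
                shift = np.array(
                    [group_shifts[g].get(group_of_sample[s], 0.0) for s in sub.columns]
                )
                ct[i] += shift
    groups = dict(group_of_sample) if group_of_sample is not None else None
    return CtMatrix(pd.DataFrame(ct, index=list(panel), columns=sub.columns), groups)


def simulate_calibration_pairs(
    spec: SyntheticSpec,
    n_pairs: int = 5000,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Paired (log2_tpm, ct) observations from the generative calibration line."""
    rng = rng or spec.rng()
    x = rng.uniform(*spec.mean_log2tpm_range, size=n_pairs)
    ct = spec.ct_intercept + spec.ct_slope * x + rng.normal(0, spec.ct_noise_sd, n_pairs)
    return pd.DataFrame({"log2_tpm": x, "ct": ct})
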