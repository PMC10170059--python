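"""Linear calibration between transcriptome expression and RT-qPCR Ct.

Across a panel of genes and samples, Ct falls roughly linearly with
log2(TPM) (each doubling of template saves about half a cycle of PCR), so an
ordinary least-squares line

    Ct = β₁ · log2(TPM) + β₀

fitted on paired observations lets Ct be anticipated from transcriptome data
before running any qPCR. The slope significance is the regression F-test,
which for a single predictor equals the two-sided t-test on β₁.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["LinearFit", "fit_tpm_ct", "predict_ct", "save_fit", "load_fit"]


@dataclass
class LinearFit:
    slope: float  # Ct per log2(TPM) unit
    intercept: float  # Ct at TPM = 1
    r_squared: float
    p_value: float  # F(1, n−2) test on the slope
    n: int


def fit_tpm_ct(log2_tpm, ct=None) -> LinearFit:
    """OLS fit of Ct on log2(TPM).

    Accepts either two 1-D arrays or a single (n, 2) array / sequence of
    ``(log2tpm, ct)`` pairs. Requires n ≥ 3 and non-constant x.
    """
    if ct is None:
        pairs = np.asarray(log2_tpm, dtype=float)
        if pairs.ndim != 2 or pairs.shape[1] != 2:
            raise ValueError("expected (n, 2) array of (log2tpm, ct) pairs")
        x, y = pairs[:, 0], pairs[:, 1]
    else:
        x = np.asarray(log2_tpm, dtype=float)
        y = np.asarray(ct, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("log2_tpm and ct must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points to fit and test the line")
    if np.ptp(x) == 0:
        raise ValueError("log2(TPM) values are all identical; slope undefined")
    res = sps.linregress(x, y)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(x),
    )


def predict_ct(fit: LinearFit, tpm: float) -> float:
    """Expected Ct for a TPM value under a fitted calibration line."""
    if tpm <= 0:
        raise ValueError("TPM must be positive to take log2")
    return fit.intercept + fit.slope * float(np.log2(tpm))


def save_fit(fit: LinearFit, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(asdict(fit), fh, indent=0)
        fh.write("\n")


def load_fit(path) -> LinearFit:
    with open(path, encoding="utf-8") as fh:
        return LinearFit(**json.load(fh))
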