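"""Scale transforms and covariate residualization.

The analysis-ready values are produced in a fixed order: beta-values are
mapped to the M-value scale (log2 of the methylated/unmethylated ratio),
residualized on sample-level covariates by ordinary least squares, and then
rank inverse normal transformed (RINT) per CpG so that downstream mixed
models see approximately Gaussian outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TransformedMatrix",
    "beta_to_m",
    "m_to_beta",
    "residualize_covariates",
    "rank_inverse_normal",
    "build_design_matrix",
]

SCALE_TAGS = ("beta", "m", "residual-m", "rint")


@dataclass
class TransformedMatrix:
    """A CpG x sample value matrix carrying the scale it lives on."""

    values: pd.DataFrame
    scale_tag: str

    def __post_init__(self):
        if self.scale_tag not in SCALE_TAGS:
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")

    @property
    def array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


def _as_frame(values) -> pd.DataFrame:
    if isinstance(values, TransformedMatrix):
        return values.values
    if isinstance(values, pd.DataFrame):
        return values
    return pd.DataFrame(np.asarray(values, dtype=float))


def beta_to_m(beta, clip_epsilon: float = 1e-6) -> TransformedMatrix:
    """M = log2(beta / (1 - beta)) after clipping beta into [eps, 1-eps].

    Clipping keeps the log-ratio finite for betas that were rounded to
    exactly 0 or 1.  The map is strictly increasing on (0, 1).
    """
    if not (0.0 < clip_epsilon < 0.5):
        raise ValueError("clip_epsilon must lie in (0, 0.5)")
    frame = _as_frame(beta)
    arr = frame.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("beta matrix contains non-finite values")
    clipped = np.clip(arr, clip_epsilon, 1.0 - clip_epsilon)
    m = np.log2(clipped / (1.0 - clipped))
    return TransformedMatrix(pd.DataFrame(m, index=frame.index, columns=frame.columns), "m")


def m_to_beta(m) -> TransformedMatrix:
    """Inverse of :func:`beta_to_m` inside the clip range: beta = 2^M/(1+2^M)."""
    frame = _as_frame(m)
    arr = frame.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("M-value matrix contains non-finite values")
    # expit formulation is numerically stable for large |M|
    beta = stats.logistic.cdf(arr * np.log(2.0))
    return TransformedMatrix(pd.DataFrame(beta, index=frame.index, columns=frame.columns), "beta")


def build_design_matrix(
    samples: pd.DataFrame, covariates: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """Intercept + named covariate columns, with categoricals dummy-coded.

    A covariate name must be a column of ``samples``; non-numeric columns are
    expanded into treatment-coded indicators (first level dropped).  Missing
    per-sample values are rejected: covariates are either present for all
    samples of a dataset or not used at all.
    """
    columns: list[np.ndarray] = [np.ones(len(samples))]
    names: list[str] = ["intercept"]
    for cov in covariates:
        if cov not in samples.columns:
            raise ValueError(f"covariate {cov!r} not present in sample sheet")
        col = samples[cov]
        if col.isna().any():
            raise ValueError(f"covariate {cov!r} has missing per-sample values")
        if pd.api.types.is_numeric_dtype(col):
            columns.append(col.to_numpy(dtype=float))
            names.append(cov)
        else:
            dummies = pd.get_dummies(col.astype(str), prefix=cov, drop_first=True)
            for name in dummies.columns:
                columns.append(dummies[name].to_numpy(dtype=float))
                names.append(name)
    X = np.column_stack(columns)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns linearly dependent on their predecessors
        bad = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) == np.linalg.matrix_rank(X[:, :j]):
                bad.append(names[j])
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    return X, names


def residualize_covariates(
    values, samples: pd.DataFrame, covariates: Sequence[str]
) -> TransformedMatrix:
    """Replace each CpG row by its OLS residual on intercept + covariates.

    With an empty covariate list this reduces to per-CpG mean centring.  The
    operation is idempotent and leaves residuals orthogonal to the design.
    """
    frame = _as_frame(values)
    X, _ = build_design_matrix(samples.loc[frame.columns], covariates)
    Y = frame.to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y - (X @ coef).T
    return TransformedMatrix(
        pd.DataFrame(resid, index=frame.index, columns=frame.columns), "residual-m"
    )


def rank_inverse_normal(values, offset: float = 0.375) -> TransformedMatrix:
    """Per-CpG rank inverse normal transform with the Blom offset.

    The value with (average, for ties) rank r among n maps to
    ``Phi^-1((r - offset) / (n - 2*offset + 1))``.  Constant rows carry no
    rank information and are rejected with their CpG ids.
    """
    frame = _as_frame(values)
    arr = frame.to_numpy(dtype=float)
    n = arr.shape[1]
    if n < 3:
        raise ValueError("rank inverse normal transform needs n >= 3 samples")
    constant = np.ptp(arr, axis=1) == 0
    if constant.any():
        bad = frame.index[constant].tolist()
        raise ValueError(f"constant rows cannot be rank-transformed: {bad[:5]}")
    ranks = stats.rankdata(arr, axis=1, method="average")
    quantiles = (ranks - offset) / (n - 2.0 * offset + 1.0)
    z = stats.norm.ppf(quantiles)
    return TransformedMatrix(pd.DataFrame(z, index=frame.index, columns=frame.columns), "rint")
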