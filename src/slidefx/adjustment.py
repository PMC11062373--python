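"""Slide-effect adjustment methods.

Four adjustments are provided, matching the strategies commonly compared in
EWAS practice:

* ``combat`` — parametric empirical-Bayes location/scale batch correction.
  Each CpG is standardized, per-slide means and variances are shrunk toward
  their across-CpG priors (normal prior for means, inverse-gamma for
  variances, both moment-matched), and the data are back-transformed.
* ``combat_high`` — ComBat run separately within a susceptible CpG stratum
  and its complement, then re-merged; shrinking the strata separately keeps
  the strong, mutually aligned slide effects of susceptible CpGs from being
  averaged away against the bulk of unaffected CpGs.
* ``pc`` — the top-k sample-space principal component scores of the
  CpG-centred matrix, for use as regression covariates.
* ``pc_high`` — the same scores computed on the susceptible-CpG submatrix
  only; with a shared low-rank slide factor a single such covariate can
  absorb slide effects genome-wide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "AdjustmentOutput",
    "combat_adjust",
    "combat_stratified_adjust",
    "pc_covariates",
    "construct_slide_covariate",
]

_EB_CONV = 1e-6
_EB_MAX_ITER = 10_000


@dataclass
class AdjustmentOutput:
    """Either a corrected matrix (ComBat variants) or covariate scores (PC)."""

    method_tag: str
    corrected: Optional[pd.DataFrame] = None
    covariates: Optional[pd.DataFrame] = None

    def __post_init__(self):
        if self.method_tag == "plain":
            ok = self.corrected is None and self.covariates is None
        else:
            ok = (self.corrected is None) != (self.covariates is None)
        if not ok:
            raise ValueError("exactly one of corrected/covariates must be set")


def _batch_codes(values: pd.DataFrame, batch_of) -> tuple[list[str], np.ndarray]:
    batch_of = pd.Series(batch_of).astype(str)
    labels = batch_of.reindex(values.columns)
    if labels.isna().any():
        missing = values.columns[labels.isna()].tolist()
        raise ValueError(f"samples without batch label: {missing[:5]}")
    order = list(dict.fromkeys(labels))
    code_of = {b: i for i, b in enumerate(order)}
    return order, np.array([code_of[b] for b in labels], dtype=np.intp)


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = float(np.mean(delta_hat)), float(np.var(delta_hat, ddof=1))
    return (2.0 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = float(np.mean(delta_hat)), float(np.var(delta_hat, ddof=1))
    return (m * s2 + m**3) / s2


def _eb_solve(z_batch, gamma_hat, delta_hat, gamma_bar, t2, a, b):
    """Iterate the conditional posterior means for one batch to convergence."""
    n = z_batch.shape[1]
    g_old = gamma_hat.copy()
    d_old = delta_hat.copy()
    for _ in range(_EB_MAX_ITER):
        g_new = (n * t2 * gamma_hat + d_old * gamma_bar) / (n * t2 + d_old)
        sum2 = np.sum((z_batch - g_new[:, None]) ** 2, axis=1)
        d_new = (b + 0.5 * sum2) / (n / 2.0 + a - 1.0)
        change = max(
            float(np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12))),
            float(np.max(np.abs(d_new - d_old) / np.maximum(d_old, 1e-12))),
        )
        g_old, d_old = g_new, d_new
        if change < _EB_CONV:
            break
    return g_old, d_old


def combat_adjust(values: pd.DataFrame, batch_of) -> AdjustmentOutput:
    """Parametric empirical-Bayes batch correction of an M-value matrix.

    ``values`` is CpG x sample; ``batch_of`` maps sample id -> batch
    (slide).  No covariate design is used: the input is expected to be
    residualized already.  With a single batch the input is returned
    unchanged (there is no batch contrast to remove).
    """
    values = pd.DataFrame(values)
    order, codes = _batch_codes(values, batch_of)
    if len(order) == 1:
        return AdjustmentOutput("combat", corrected=values.copy())
    arr = values.to_numpy(dtype=float)
    n_total = arr.shape[1]
    n_b = np.bincount(codes, minlength=len(order)).astype(float)
    if (n_b < 2).any():
        bad = [order[i] for i in np.flatnonzero(n_b < 2)]
        raise ValueError(f"batches with a single sample: {bad}")
    const = np.ptp(arr, axis=1) == 0
    if const.any():
        bad = values.index[const].tolist()
        raise ValueError(f"constant CpGs cannot be ComBat-adjusted: {bad[:5]}")

    # --- standardization: batch-mean model fit, pooled variance (1/N) ----
    batch_means = np.stack(
        [arr[:, codes == i].mean(axis=1) for i in range(len(order))], axis=1
    )  # G x K
    grand = batch_means @ (n_b / n_total)
    fitted = batch_means[:, codes]
    var_pooled = np.mean((arr - fitted) ** 2, axis=1)
    if np.any(var_pooled <= 0):
        bad = values.index[var_pooled <= 0].tolist()
        raise ValueError(f"CpGs with zero pooled variance: {bad[:5]}")
    sd = np.sqrt(var_pooled)
    z = (arr - grand[:, None]) / sd[:, None]

    # --- EB shrinkage of per-batch means and variances -------------------
    gamma_star = np.empty_like(batch_means)
    delta_star = np.empty_like(batch_means)
    for i in range(len(order)):
        zb = z[:, codes == i]
        gamma_hat = zb.mean(axis=1)
        delta_hat = zb.var(axis=1, ddof=1)
        gamma_bar = float(np.mean(gamma_hat))
        t2 = float(np.var(gamma_hat, ddof=1))
        a, b = _aprior(delta_hat), _bprior(delta_hat)
        gamma_star[:, i], delta_star[:, i] = _eb_solve(
            zb, gamma_hat, delta_hat, gamma_bar, t2, a, b
        )

    adjusted = (z - gamma_star[:, codes]) / np.sqrt(delta_star[:, codes])
    corrected = adjusted * sd[:, None] + grand[:, None]
    return AdjustmentOutput(
        "combat",
        corrected=pd.DataFrame(corrected, index=values.index, columns=values.columns),
    )


def combat_stratified_adjust(values: pd.DataFrame, batch_of, strata) -> AdjustmentOutput:
    """ComBat applied independently within a CpG stratum and its complement.

    ``strata`` is a per-CpG boolean flag (True = susceptible stratum).  Rows
    are re-merged in the original order.  If either stratum is empty the
    call falls back to a single ComBat run with a warning.
    """
    values = pd.DataFrame(values)
    flags = pd.Series(strata).reindex(values.index)
    if flags.isna().any():
        missing = values.index[flags.isna()].tolist()
        raise ValueError(f"CpGs without stratum flag: {missing[:5]}")
    flags = flags.astype(bool)
    if flags.all() or (~flags).all():
        warnings.warn("one stratum is empty; falling back to a single ComBat run")
        out = combat_adjust(values, batch_of)
        return AdjustmentOutput("combat_high", corrected=out.corrected)
    parts = []
    for flag in (True, False):
        sub = values.loc[flags == flag]
        parts.append(combat_adjust(sub, batch_of).corrected)
    merged = pd.concat(parts).loc[values.index]
    return AdjustmentOutput("combat_high", corrected=merged)


def pc_covariates(values: pd.DataFrame, k: int) -> AdjustmentOutput:
    """Top-k sample-space principal component scores as covariates.

    PCA is performed on the CpG-centred (row-centred) matrix via SVD, so the
    returned sample scores have exactly zero mean, are mutually orthogonal,
    and are ordered by decreasing variance.  Signs follow the convention
    that each component's CpG loading sum is >= 0.
    """
    values = pd.DataFrame(values)
    g, n = values.shape
    max_k = min(g, n) - 1
    if not (1 <= k <= max_k):
        raise ValueError(f"k={k} outside the feasible range 1..{max_k}")
    arr = values.to_numpy(dtype=float)
    centred = arr - arr.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    u, s, vt = u[:, :k], s[:k], vt[:k]
    signs = np.where(u.sum(axis=0) >= 0, 1.0, -1.0)
    scores = (vt.T * s) * signs
    frame = pd.DataFrame(
        scores, index=values.columns, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return AdjustmentOutput("pc_10" if k == 10 else f"pc_{k}", covariates=frame)


def construct_slide_covariate(values: pd.DataFrame, shigh_flags, k: int = 1) -> AdjustmentOutput:
    """PC scores computed on the susceptible (flagged) CpG submatrix only."""
    values = pd.DataFrame(values)
    flags = pd.Series(shigh_flags).reindex(values.index).fillna(False).astype(bool)
    n_flagged = int(flags.sum())
    if n_flagged < 2:
        raise ValueError(f"need >= 2 flagged CpGs, got {n_flagged}")
    out = pc_covariates(values.loc[flags], k)
    return AdjustmentOutput("pc_high", covariates=out.covariates)
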