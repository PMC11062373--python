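"""Odd/even-chromosome simulation study of slide-effect adjustment.

Autosomal CpGs are split by chromosome-number parity.  Fitted slide
effects for CpGs on even chromosomes (Ceven) are reduced to their first
principal component, which drives a simulated phenotype

    y_i = z_i + f_{s(i)},   z_i ~ N(0, 1),

where f is the (unit-variance) per-slide factor.  Association testing then
uses CpGs on odd chromosomes (Codd) only, under five strategies: plain
linear regression, regression with the top-10 methylome-wide PCs (PC_10),
regression with the first PC of susceptible CpGs (PC_high), ComBat
correction, and stratified ComBat (ComBat_high).  Because the phenotype is
pure slide effect plus noise, every rejection is a false positive; the
empirical rejection rate at level alpha and the genomic inflation factor
summarize how well each strategy protects the type-I error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .adjustment import (
    combat_adjust,
    combat_stratified_adjust,
    construct_slide_covariate,
    pc_covariates,
)
from .core_io import MethylationDataset
from .set_structure import SET_LABELS
from .transforms import beta_to_m, rank_inverse_normal, residualize_covariates
from .variance_components import blup_matrix, decompose_all

__all__ = [
    "SimStudySpec",
    "SimulationStudyResult",
    "APPROACHES",
    "split_odd_even",
    "build_phenotype_factor",
    "simulate_phenotype",
    "run_association_scan",
    "summarize_type1",
    "lambda_gc",
]

APPROACHES = ("plain", "pc_10", "pc_high", "combat", "combat_high")

# theoretical null median of a 1-df chi-squared
_CHI2_MEDIAN = float(stats.chi2.ppf(0.5, 1))


@dataclass
class SimStudySpec:
    """Design of one simulation run."""

    n_tests_per_set: int = 10_000
    alpha: float = 0.05
    approaches: Sequence[str] = APPROACHES
    scale: str = "rint"
    seed: int = 0
    n_pc: int = 10
    #: also scan the Shigh CpGs as a pseudo-set of their own
    include_shigh_set: bool = True

    def __post_init__(self):
        if self.n_tests_per_set < 1:
            raise ValueError("n_tests_per_set must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0,1)")
        unknown = set(self.approaches) - set(APPROACHES)
        if unknown:
            raise ValueError(f"unknown approaches: {sorted(unknown)}")
        if self.scale not in ("rint", "m"):
            raise ValueError("scale must be 'rint' or 'm'")


@dataclass
class SimulationStudyResult:
    """Per-(approach, set) p-value collections with type-I error summaries."""

    pvalues: dict  # (approach, set_label) -> ndarray
    type1: pd.DataFrame  # approach x set rejection rate at alpha
    lambda_gc: pd.DataFrame  # approach x set genomic inflation
    alpha: float
    qq_data: dict = field(default_factory=dict)  # (approach, set) -> (expected, observed)


def split_odd_even(annotations: pd.DataFrame) -> tuple[pd.Index, pd.Index]:
    """Partition autosomal CpGs by chromosome-number parity; X is excluded."""
    chrom = annotations["chromosome"].astype(str)
    autosomal = chrom.str.fullmatch(r"\d+")
    nums = pd.to_numeric(chrom.where(autosomal), errors="coerce")
    codd = annotations.index[nums % 2 == 1]
    ceven = annotations.index[nums % 2 == 0]
    return codd, ceven


def build_phenotype_factor(
    blups_even: pd.DataFrame, standardize: bool = True
) -> pd.Series:
    """First principal component, per slide, of the centred fitted effects.

    The score sign follows the loading-sum convention.  With
    ``standardize=True`` the score is rescaled *downward* to unit variance
    across slides when its natural scale exceeds it, so the simulated
    phenotype mixes slide effect and noise in at most equal parts; a
    negligible slide factor (as when slide effects are absent) is left at
    its natural small scale rather than amplified into an artificial batch
    signal.
    """
    if blups_even.shape[0] < 2 or blups_even.shape[1] < 2:
        raise ValueError("need >= 2 slides and >= 2 CpGs")
    arr = blups_even.to_numpy(dtype=float)
    centred = arr - arr.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[0] <= 0:
        raise ValueError("fitted-effect matrix has rank 0")
    score = u[:, 0] * s[0]
    if vt[0].sum() < 0:
        score = -score
    if standardize:
        score = score / max(score.std(ddof=1), 1.0)
    return pd.Series(score, index=blups_even.index, name="phenotype_factor")


def simulate_phenotype(factor: pd.Series, slide_of, rng: np.random.Generator) -> np.ndarray:
    """y_i = z_i + factor[slide(i)] with fresh iid standard-normal z."""
    slide_of = pd.Series(slide_of).astype(str)
    missing = sorted(set(slide_of) - set(factor.index))
    if missing:
        raise ValueError(f"slides without a factor value: {missing[:5]}")
    base = factor.loc[slide_of].to_numpy(dtype=float)
    return base + rng.standard_normal(base.size)


def summarize_type1(pvalues, alpha: float) -> tuple[float, tuple[float, float]]:
    """Empirical rejection rate with an exact (Clopper-Pearson) 95% CI."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value collection")
    k = int(np.sum(p < alpha))
    n = p.size
    lo = 0.0 if k == 0 else float(stats.beta.ppf(0.025, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(0.975, k + 1, n - k))
    return k / n, (lo, hi)


def lambda_gc(pvalues) -> float:
    """Genomic inflation: median observed chi-squared over its null median."""
    p = np.asarray(pvalues, dtype=float)
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / _CHI2_MEDIAN)


def _residualizer(covariates: Optional[np.ndarray], n: int) -> np.ndarray:
    """Projection onto the orthogonal complement of [1, covariates]."""
    if covariates is None or covariates.size == 0:
        X = np.ones((n, 1))
    else:
        X = np.column_stack([np.ones(n), covariates])
    q, _ = np.linalg.qr(X)
    return np.eye(n) - q @ q.T


def _scan_pvalues(
    predictor_matrix: np.ndarray,
    row_pool: np.ndarray,
    covariates: Optional[np.ndarray],
    factor: pd.Series,
    slide_of: pd.Series,
    n_tests: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized association scan: fresh phenotype per draw, OLS t-test."""
    n = predictor_matrix.shape[1]
    k = 0 if covariates is None else covariates.shape[1]
    M = _residualizer(covariates, n)
    idx = rng.integers(0, row_pool.size, size=n_tests)
    X = predictor_matrix[row_pool[idx]] @ M.T
    base = factor.loc[slide_of].to_numpy(dtype=float)
    Z = rng.standard_normal((n_tests, n))
    Y = (Z + base[None, :]) @ M.T
    sxx = np.einsum("ij,ij->i", X, X)
    syy = np.einsum("ij,ij->i", Y, Y)
    sxy = np.einsum("ij,ij->i", X, Y)
    df = n - 2 - k
    r2 = sxy**2 / np.maximum(sxx * syy, 1e-300)
    r2 = np.clip(r2, 0.0, 1.0 - 1e-15)
    tstat2 = df * r2 / (1.0 - r2)
    pvals = stats.f.sf(tstat2, 1, df)  # == two-sided t test on the slope
    return pvals


def run_association_scan(
    dataset: MethylationDataset,
    partition: pd.DataFrame,
    spec: SimStudySpec,
    shigh_flags,
    covariate_names: Sequence[str] = (),
    decompositions=None,
    phenotype_factor: Optional[pd.Series] = None,
) -> SimulationStudyResult:
    """Run the five-approach odd/even type-I error study on one dataset.

    ``partition`` is the set table (from :func:`slidefx.set_structure.build_partition`
    or ``partition_cpg_sets``); ``shigh_flags`` marks the susceptible CpGs
    used by PC_high / ComBat_high.  The phenotype factor is built from
    fitted slide effects of even-chromosome CpGs only, while every
    adjustment and every association test touches odd-chromosome CpGs only.
    ``decompositions`` may carry precomputed per-CpG fits (as returned by
    :func:`slidefx.variance_components.decompose_all`) to avoid refitting.
    A known per-slide ``phenotype_factor`` may be supplied instead of
    estimating one — e.g. an all-zero factor for a null-calibration
    experiment in which slide effects are absent by construction.
    """
    rng = np.random.default_rng(spec.seed)
    samples = dataset.samples
    slide_of = dataset.slide_of

    m = beta_to_m(dataset.beta)
    resid = residualize_covariates(m, samples, covariate_names)
    rint = rank_inverse_normal(resid)
    scan_matrix = rint if spec.scale == "rint" else resid

    codd, ceven = split_odd_even(dataset.annotations)
    if len(codd) == 0 or len(ceven) == 0:
        raise ValueError("both odd and even autosomal CpGs are required")

    # phenotype factor from Ceven fitted slide effects only
    if phenotype_factor is not None:
        factor = phenotype_factor.reindex(pd.unique(slide_of))
        if factor.isna().any():
            raise ValueError("phenotype_factor does not cover all slides")
    else:
        if decompositions is None:
            # the mixed model always runs on the RINT scale
            fits_even = decompose_all(rint.values.loc[ceven], samples)
        else:
            by_id = {f.cpg_id: f for f in decompositions}
            fits_even = [by_id[c] for c in ceven if c in by_id]
        factor = build_phenotype_factor(blup_matrix(fits_even))

    # odd-chromosome working matrices
    values_codd = scan_matrix.values.loc[codd]
    resid_codd = resid.values.loc[codd]
    flags = pd.Series(shigh_flags).reindex(codd).fillna(False).astype(bool)

    prepared: dict[str, tuple[pd.DataFrame, Optional[np.ndarray]]] = {}
    for approach in spec.approaches:
        if approach == "plain":
            prepared[approach] = (values_codd, None)
        elif approach == "pc_10":
            cov = pc_covariates(values_codd, spec.n_pc).covariates
            prepared[approach] = (values_codd, cov.to_numpy())
        elif approach == "pc_high":
            cov = construct_slide_covariate(values_codd, flags, k=1).covariates
            prepared[approach] = (values_codd, cov.to_numpy())
        elif approach in ("combat", "combat_high"):
            # correction acts on the M-value scale, then moves to the scan scale
            if approach == "combat":
                corrected = combat_adjust(resid_codd, slide_of).corrected
            else:
                corrected = combat_stratified_adjust(resid_codd, slide_of, flags).corrected
            if spec.scale == "rint":
                corrected = rank_inverse_normal(corrected).values
            prepared[approach] = (corrected, None)

    # draw pools per set, restricted to Codd
    part_codd = partition.loc[partition.index.intersection(codd)]
    pools: dict[str, np.ndarray] = {}
    pos_of = {c: i for i, c in enumerate(codd)}
    for label in SET_LABELS:
        ids = part_codd.index[part_codd["set_label"] == label]
        if len(ids) == 0:
            warnings.warn(f"set {label} is empty on odd chromosomes; skipped")
            continue
        pools[label] = np.array([pos_of[c] for c in ids], dtype=np.intp)
    if spec.include_shigh_set and flags.any():
        pools["Shigh"] = np.flatnonzero(flags.to_numpy()).astype(np.intp)

    pvalues: dict = {}
    qq_data: dict = {}
    for approach in spec.approaches:
        matrix, cov = prepared[approach]
        arr = matrix.to_numpy(dtype=float)
        for label, pool in pools.items():
            p = _scan_pvalues(
                arr, pool, cov, factor, slide_of, spec.n_tests_per_set, rng
            )
            pvalues[(approach, label)] = p
            srt = np.sort(p)
            expected = (np.arange(1, p.size + 1) - 0.5) / p.size
            qq_data[(approach, label)] = (-np.log10(expected), -np.log10(srt))

    set_order = [l for l in list(SET_LABELS) + ["Shigh"] if l in pools]
    type1 = pd.DataFrame(
        {
            label: [float(np.mean(pvalues[(a, label)] < spec.alpha)) for a in spec.approaches]
            for label in set_order
        },
        index=pd.Index(spec.approaches, name="approach"),
    )
    lam = pd.DataFrame(
        {label: [lambda_gc(pvalues[(a, label)]) for a in spec.approaches] for label in set_order},
        index=pd.Index(spec.approaches, name="approach"),
    )
    return SimulationStudyResult(
        pvalues=pvalues, type1=type1, lambda_gc=lam, alpha=spec.alpha, qq_data=qq_data
    )
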