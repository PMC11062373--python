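"""End-to-end study drivers combining the pipeline stages.

These functions wire the stages together the way the analyses are meant to
be run: generate (or accept) a dataset, build analysis-ready values
(beta -> M -> covariate residuals -> RINT), fit the per-CpG slide variance
components, construct the susceptibility partition, and run the
odd/even-chromosome type-I-error scan.  The problem sizes default to desk
scale: one cohort of 60 slides x 8 samples and a few tens of thousands of
CpGs, preserving the composition of the full array rather than its size.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .adjustment import construct_slide_covariate
from .core_io import MethylationDataset
from .set_structure import build_partition
from .simulation_study import SimStudySpec, run_association_scan, split_odd_even
from .synthetic_data import GeneratorSpec, simulate_methylation_dataset
from .transforms import (
    TransformedMatrix,
    beta_to_m,
    rank_inverse_normal,
    residualize_covariates,
)
from .variance_components import decompose_all, decompositions_to_frame

__all__ = [
    "analysis_values",
    "estimate_fractions",
    "slide_effect_study",
    "null_calibration_study",
    "covariate_transfer",
]


def analysis_values(
    dataset: MethylationDataset, covariates: Sequence[str] = ()
) -> tuple[TransformedMatrix, TransformedMatrix]:
    """Analysis-ready value matrices: (residual M-values, RINT values)."""
    m = beta_to_m(dataset.beta)
    resid = residualize_covariates(m, dataset.samples, covariates)
    rint = rank_inverse_normal(resid)
    return resid, rint


def estimate_fractions(dataset: MethylationDataset, covariates: Sequence[str] = ()):
    """Per-CpG REML fits on the RINT scale plus their tabular view."""
    _, rint = analysis_values(dataset, covariates)
    fits = decompose_all(rint, dataset.samples)
    return fits, decompositions_to_frame(fits)


def slide_effect_study(
    n_cpgs: int = 40_000,
    seed: int = 0,
    n_tests: int = 2_000,
    scale: str = "rint",
    spec: Optional[GeneratorSpec] = None,
) -> dict:
    """One-cohort slide-effect study: generate, decompose, partition, scan.

    The partition and the susceptible-set flag are estimated from the data
    itself (single cohort, so the Shigh rule reduces to a 60% threshold);
    the scan then compares the five adjustment approaches at ``n_tests``
    draws per set.
    """
    if spec is None:
        spec = GeneratorSpec(n_cpgs=n_cpgs, seed=seed)
    dataset, truth = simulate_methylation_dataset(spec)
    fits, table = estimate_fractions(dataset)
    partition = build_partition(
        table[["fraction"]].rename(columns={"fraction": "cohort0"}), min_cohorts=1
    )
    scan_spec = SimStudySpec(n_tests_per_set=n_tests, scale=scale, seed=seed)
    result = run_association_scan(
        dataset, partition, scan_spec, partition["in_shigh"], decompositions=fits
    )
    return {
        "spec": spec,
        "dataset": dataset,
        "truth": truth,
        "fits": fits,
        "fractions": table,
        "partition": partition,
        "scan": result,
    }


def null_calibration_study(
    n_cpgs: int = 4_000, seed: int = 0, n_tests: int = 2_000
) -> dict:
    """Type-I error study with slide effects absent by construction.

    All true slide-variance fractions are zero, so the true first principal
    component of slide effects is zero and the phenotype reduces to pure
    standard-normal noise.  The susceptible-set flag needed by the *-high
    approaches is taken as the top estimated fractions (an arbitrary null
    subset).
    """
    spec = GeneratorSpec(n_cpgs=n_cpgs, fixed_fractions=[0.0], seed=seed)
    dataset, truth = simulate_methylation_dataset(spec)
    fits, table = estimate_fractions(dataset)
    partition = build_partition(
        table[["fraction"]].rename(columns={"fraction": "cohort0"}), min_cohorts=1
    )
    flags = pd.Series(False, index=partition.index)
    flags.loc[table["fraction"].nlargest(max(50, n_cpgs // 40)).index] = True
    zero_factor = pd.Series(0.0, index=pd.Index(dataset.slides))
    scan_spec = SimStudySpec(
        n_tests_per_set=n_tests, seed=seed, include_shigh_set=False
    )
    result = run_association_scan(
        dataset,
        partition,
        scan_spec,
        flags,
        decompositions=fits,
        phenotype_factor=zero_factor,
    )
    return {"dataset": dataset, "truth": truth, "partition": partition, "scan": result}


def covariate_transfer(study: dict) -> dict:
    """Cross-chromosome transfer of the susceptible-set covariate.

    Builds the single slide covariate from even-chromosome susceptible CpGs
    and measures, on the M-value scale, how much slide-attributable
    variance it removes from the *odd*-chromosome susceptible CpGs it never
    saw.  Returns per-CpG reductions and their median.
    """
    dataset: MethylationDataset = study["dataset"]
    truth = study["truth"]
    partition = study["partition"]
    resid, _ = analysis_values(dataset)
    codd, ceven = split_odd_even(dataset.annotations)

    flags_even = partition["in_shigh"].reindex(ceven).fillna(False).astype(bool)
    covariate = construct_slide_covariate(
        resid.values.loc[ceven], flags_even, k=1
    ).covariates.to_numpy()

    target = [c for c in codd if truth.true_fraction.get(c, 0.0) >= 0.6]
    before = resid.values.loc[target]
    X = np.column_stack([np.ones(dataset.n_samples), covariate])
    arr = before.to_numpy()
    coef, *_ = np.linalg.lstsq(X, arr.T, rcond=None)
    after = pd.DataFrame(arr - (X @ coef).T, index=before.index, columns=before.columns)

    fits_before = decompose_all(before, dataset.samples)
    fits_after = decompose_all(after, dataset.samples)
    vs_before = np.array([f.var_slide for f in fits_before])
    vs_after = np.array([f.var_slide for f in fits_after])
    keep = vs_before > 0
    reduction = 1.0 - vs_after[keep] / vs_before[keep]
    return {
        "reduction": reduction,
        "median_reduction": float(np.median(reduction)),
        "n_cpgs": int(keep.sum()),
    }
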