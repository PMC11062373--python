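"""Synthetic EPIC-like methylation data with ground-truth slide structure.

The generator works on the M-value scale.  For CpG j and sample i on slide
s(i):

    m_ij = baseline_j + covariate terms
           + loading_j * u_{s(i)}          (shared slide factor)
           + c_j * v_{s(i),j}              (CpG-specific slide noise)
           + sum_k w_jk * eta_{k,i}        (latent sample-level factors)
           + e_ij                          (iid residual)

``u_s``, ``v_{s,j}``, ``eta_{k,i}`` and ``e_ij`` are standard normal; the
loading and noise scales are calibrated so the slide-attributable share of
total variance equals the per-CpG target fraction exactly.  Susceptible
CpGs (target fraction >= 0.6) load on the single shared factor ``u`` with a
sign tied to their baseline methylation class — positive for
high-methylation CpGs, negative for low — which reproduces the two-cluster
joint pattern of slide effects seen on real arrays.

The latent sample-level factors emulate unmodelled biological
heterogeneity (genetic background, residual cell-composition variation):
they create large structured variance directions that dominate the sample
covariance the way biology dominates a real methylome.  They are
independent of slides, so they inflate nothing; their role is to make the
top methylome-wide principal components track biology rather than the
slide factor, as observed in practice.

Betas are obtained by the inverse M-value map, so the round trip through
the analysis pipeline's beta->M step is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core_io import MethylationDataset
from .transforms import m_to_beta

__all__ = [
    "GeneratorSpec",
    "GroundTruth",
    "simulate_methylation_dataset",
    "assign_cohorts",
    "DEFAULT_BIN_MIX",
    "BIN_RANGES",
]

#: marginal composition of the five variance-fraction bins typical of blood
#: EPIC data (the vast majority of CpGs show little slide variance; strong,
#: consistently susceptible CpGs are rare)
DEFAULT_BIN_MIX = (0.30688, 0.45338, 0.19652, 0.04116, 0.00206)

#: target-fraction range per bin; the top bin is capped below 1 so the
#: residual variance never degenerates
BIN_RANGES = ((0.0, 0.2), (0.2, 0.4), (0.4, 0.6), (0.6, 0.8), (0.8, 0.97))

_SET_LABELS = ("S0-20", "S20-40", "S40-60", "S60-80", "S80-100")

#: fraction at and above which a CpG loads on the shared slide factor
SUSCEPTIBLE_FRACTION = 0.6


@dataclass
class GeneratorSpec:
    """Study conditions for the synthetic generator.

    Defaults emulate a single blood-based EPIC cohort at desk scale:
    60 slides of 8 samples (~480 arrays), bin composition as on real
    arrays, a dominant shared slide factor for susceptible CpGs
    (``shared_factor_share``), susceptible CpGs skewed toward high baseline
    methylation, and latent sample-level heterogeneity absorbing most of
    the non-slide variance.
    """

    n_slides: int = 60
    samples_per_slide: int = 8
    n_cpgs: int = 10_000
    bin_mix: Sequence[float] = DEFAULT_BIN_MIX
    shared_factor_share: float = 0.95
    high_meth_share: float = 0.6
    covariate_effects: Optional[dict] = None
    chromosome_layout: int = 22
    n_latent_factors: int = 14
    latent_share: float = 0.55
    total_sd_m: float = 0.5
    seed: int = 0
    #: optional explicit per-CpG target fractions (cycled over CpGs);
    #: overrides bin_mix when set
    fixed_fractions: Optional[Sequence[float]] = None

    def __post_init__(self):
        mix = np.asarray(self.bin_mix, dtype=float)
        if mix.size != 5 or np.any(mix < 0) or not np.isclose(mix.sum(), 1.0, atol=1e-6):
            raise ValueError("bin_mix must be 5 non-negative proportions summing to 1")
        self.bin_mix = tuple(mix / mix.sum())
        if self.n_slides < 2:
            raise ValueError("need at least 2 slides")
        for name in ("shared_factor_share", "high_meth_share", "latent_share"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0,1]")
        if self.fixed_fractions is not None:
            fr = np.asarray(self.fixed_fractions, dtype=float)
            if np.any((fr < 0) | (fr >= 1.0)):
                raise ValueError(
                    "fixed_fractions must lie in [0, 1); a fraction of exactly 1 "
                    "leaves no residual variance to calibrate against"
                )


@dataclass
class GroundTruth:
    """Latent quantities behind a generated cohort."""

    true_fraction: pd.Series  # per CpG
    shared_factor: pd.Series  # per slide (u_s)
    loading: pd.Series  # per CpG signed loading on u
    baseline_m: pd.Series
    set_label_true: pd.Series
    median_class_true: pd.Series = field(default=None)


def _shared_cpg_params(spec: GeneratorSpec, rng: np.random.Generator) -> dict:
    """CpG-level parameters shared across cohorts of one universe."""
    n = spec.n_cpgs
    if spec.fixed_fractions is not None:
        fr = np.asarray(spec.fixed_fractions, dtype=float)
        fraction = np.resize(fr, n)
        edges = np.array([r[0] for r in BIN_RANGES[1:]])
        bins = np.searchsorted(edges, fraction, side="right")
    else:
        bins = rng.choice(5, size=n, p=np.asarray(spec.bin_mix))
        lo = np.array([BIN_RANGES[b][0] for b in bins])
        hi = np.array([BIN_RANGES[b][1] for b in bins])
        fraction = rng.uniform(lo, hi)
    susceptible = fraction >= SUSCEPTIBLE_FRACTION

    p_high = np.where(susceptible, spec.high_meth_share, 0.5)
    is_high = rng.uniform(size=n) < p_high
    magnitude = np.clip(rng.normal(2.0, 0.5, size=n), 0.8, None)
    baseline = np.where(is_high, magnitude, -magnitude)

    total_var = spec.total_sd_m**2
    slide_var = fraction * total_var
    shared_var = np.where(susceptible, spec.shared_factor_share * slide_var, 0.0)
    sign = np.where(is_high, 1.0, -1.0)
    loading = sign * np.sqrt(shared_var)
    slide_noise_sd = np.sqrt(slide_var - shared_var)

    nonslide_var = (1.0 - fraction) * total_var
    latent_var = spec.latent_share * nonslide_var
    resid_sd = np.sqrt(nonslide_var - latent_var)
    if spec.n_latent_factors > 0:
        w = rng.normal(size=(n, spec.n_latent_factors))
        norms = np.sqrt(np.sum(w**2, axis=1, keepdims=True))
        w = w / np.maximum(norms, 1e-300) * np.sqrt(latent_var)[:, None]
    else:
        w = np.zeros((n, 0))
        resid_sd = np.sqrt(nonslide_var)

    cpg_ids = pd.Index([f"cg{j:08d}" for j in range(n)], name="cpg_id")
    layout = max(1, min(spec.chromosome_layout, 22))
    chrom = np.array([str(j % layout + 1) for j in range(n)], dtype=object)
    position = 1_000_000 + (np.arange(n) // layout) * 5_000
    annotations = pd.DataFrame(
        {"chromosome": chrom, "position": position}, index=cpg_ids
    )
    return {
        "cpg_ids": cpg_ids,
        "annotations": annotations,
        "fraction": fraction,
        "bins": bins,
        "baseline": baseline,
        "loading": loading,
        "slide_noise_sd": slide_noise_sd,
        "latent_loadings": w,
        "resid_sd": resid_sd,
        "is_high": is_high,
    }


def _covariate_terms(
    spec: GeneratorSpec, rng: np.random.Generator, n_samples: int, n_cpgs: int
):
    """Optional sample covariates and their additive M-scale contribution."""
    effects = spec.covariate_effects or {}
    columns: dict[str, np.ndarray] = {}
    contribution = np.zeros((n_cpgs, n_samples))
    total_sd = spec.total_sd_m

    def add(standardized: np.ndarray, size: float):
        coef = rng.normal(0.0, size * total_sd, size=n_cpgs)
        nonlocal contribution
        contribution = contribution + coef[:, None] * standardized[None, :]

    if "age" in effects:
        age = rng.normal(45.0, 10.0, size=n_samples)
        columns["age"] = np.round(age, 1)
        add((age - age.mean()) / age.std(), float(effects["age"]))
    if "sex" in effects:
        sex_num = rng.integers(0, 2, size=n_samples)
        columns["sex"] = np.where(sex_num == 1, "M", "F")
        z = (sex_num - sex_num.mean()) / max(sex_num.std(), 1e-12)
        add(z, float(effects["sex"]))
    if "cell_props" in effects:
        props = rng.dirichlet([6.0, 3.0, 1.0], size=n_samples)
        for k in range(props.shape[1]):
            columns[f"cell_{k}"] = props[:, k]
        for k in range(props.shape[1] - 1):  # last column is redundant
            col = props[:, k]
            add((col - col.mean()) / col.std(), float(effects["cell_props"]))
    return columns, contribution


def _realize_cohort(
    spec: GeneratorSpec, shared: dict, rng: np.random.Generator, tag: str
) -> tuple[MethylationDataset, GroundTruth]:
    n_cpgs = spec.n_cpgs
    n_samples = spec.n_slides * spec.samples_per_slide
    slide_idx = np.repeat(np.arange(spec.n_slides), spec.samples_per_slide)
    slide_ids = [f"{tag}sl{i:03d}" for i in range(spec.n_slides)]
    sample_ids = [f"{tag}s{i:04d}" for i in range(n_samples)]

    u = rng.normal(size=spec.n_slides)
    v = rng.normal(size=(spec.n_slides, n_cpgs))
    eta = rng.normal(size=(spec.n_latent_factors, n_samples))
    resid = rng.normal(size=(n_cpgs, n_samples)) * shared["resid_sd"][:, None]
    cov_columns, cov_terms = _covariate_terms(spec, rng, n_samples, n_cpgs)

    m = (
        shared["baseline"][:, None]
        + cov_terms
        + shared["loading"][:, None] * u[slide_idx][None, :]
        + (shared["slide_noise_sd"][:, None] * v.T)[:, slide_idx]
        + shared["latent_loadings"] @ eta
        + resid
    )
    beta = m_to_beta(m).values
    beta.index = shared["cpg_ids"]
    beta.columns = pd.Index(sample_ids, name="sample_id")

    sheet = pd.DataFrame(
        {"slide_id": [slide_ids[i] for i in slide_idx], **cov_columns},
        index=beta.columns,
    )
    dataset = MethylationDataset(
        beta=beta, annotations=shared["annotations"].copy(), samples=sheet
    )
    truth = GroundTruth(
        true_fraction=pd.Series(shared["fraction"], index=shared["cpg_ids"], name="true_fraction"),
        shared_factor=pd.Series(u, index=pd.Index(slide_ids, name="slide_id"), name="shared_factor"),
        loading=pd.Series(shared["loading"], index=shared["cpg_ids"], name="loading"),
        baseline_m=pd.Series(shared["baseline"], index=shared["cpg_ids"], name="baseline_m"),
        set_label_true=pd.Series(
            np.asarray(_SET_LABELS, dtype=object)[shared["bins"]],
            index=shared["cpg_ids"],
            name="set_label_true",
        ),
        median_class_true=pd.Series(
            np.where(shared["is_high"], "high", "low"),
            index=shared["cpg_ids"],
            name="median_class_true",
        ),
    )
    return dataset, truth


def assign_cohorts(
    spec: GeneratorSpec, n_cohorts: int
) -> list[tuple[MethylationDataset, GroundTruth]]:
    """Generate cohorts sharing CpG susceptibility but with independent slides.

    The CpG-level structure (target fractions, loading signs, baselines,
    latent loadings) is drawn once per universe from a dedicated seed
    stream; each cohort then realizes its own slides, samples, and noise
    from an independent child stream, so adding cohorts never perturbs
    earlier ones.
    """
    if n_cohorts < 1:
        raise ValueError("n_cohorts must be >= 1")
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(n_cohorts + 1)
    shared = _shared_cpg_params(spec, np.random.default_rng(children[0]))
    out = []
    for c in range(n_cohorts):
        rng = np.random.default_rng(children[c + 1])
        tag = f"c{c}_" if n_cohorts > 1 else ""
        out.append(_realize_cohort(spec, shared, rng, tag))
    return out


def simulate_methylation_dataset(
    spec: GeneratorSpec,
) -> tuple[MethylationDataset, GroundTruth]:
    """Generate a single cohort (see :func:`assign_cohorts`)."""
    return assign_cohorts(spec, 1)[0]
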