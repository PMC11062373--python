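"""Susceptibility set construction and joint-structure analysis.

CpGs are binned by the maximum, across cohorts, of the slide-explained
variance fraction into the disjoint sets S0-20 ... S80-100 (lower bin edge
inclusive, so a fraction of exactly 0.80 lands in S80-100).  The
consistently susceptible set Shigh collects CpGs whose fraction reaches a
threshold (default 60%) in a minimum number of cohorts (default 7 of 9).

The joint distribution of slide effects is analysed by PCA of the
slide x CpG matrix of fitted random effects, with CpGs classified by
median methylation level (beta above/below 50%), plus correlation
summaries, a basepair-radius neighbour enrichment test, and the chi-squared
/ ANOVA enrichment tests used for set comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .transforms import TransformedMatrix

__all__ = [
    "SET_LABELS",
    "CpGSetPartition",
    "SlideEffectPCA",
    "partition_cpg_sets",
    "define_shigh",
    "build_partition",
    "pca_slide_effects",
    "classify_median_methylation",
    "cpg_correlation_summary",
    "neighbor_slide_enrichment",
    "enrichment_chisq",
    "enrichment_anova",
]

SET_LABELS = ("S0-20", "S20-40", "S40-60", "S60-80", "S80-100")

#: alias kept for readers thinking in terms of the result tables
CpGSetPartition = pd.DataFrame


def _as_fraction_frame(fractions) -> pd.DataFrame:
    frame = pd.DataFrame(fractions)
    arr = frame.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        if np.nanmin(arr) < 0 or np.nanmax(arr) > 1:
            raise ValueError("fractions must lie in [0,1] (or be missing)")
    return frame


def _labels_from_max(max_fraction: np.ndarray, edges: Sequence[float]) -> np.ndarray:
    edges = np.asarray(edges, dtype=float)
    if len(edges) + 1 != len(SET_LABELS):
        raise ValueError("expected 4 interior edges for the five canonical sets")
    # lower edge inclusive: bin k covers [edge_{k-1}, edge_k), top bin closed at 1
    idx = np.searchsorted(edges, max_fraction, side="right")
    return np.asarray(SET_LABELS, dtype=object)[idx]


def partition_cpg_sets(
    fractions_by_cohort, edges: Sequence[float] = (0.2, 0.4, 0.6, 0.8)
) -> pd.DataFrame:
    """Assign every assessed CpG to exactly one variance-explained set.

    ``fractions_by_cohort`` is a CpG x cohort table of slide-variance
    fractions; missing entries mark cohorts where the CpG had no valid fit.
    The set label is driven solely by the per-CpG maximum over valid
    cohorts.  CpGs missing in every cohort are excluded (with a warning).
    """
    frame = _as_fraction_frame(fractions_by_cohort)
    valid = frame.notna()
    n_valid = valid.sum(axis=1)
    if (n_valid == 0).any():
        dropped = frame.index[n_valid == 0].tolist()
        warnings.warn(f"excluding {len(dropped)} CpGs with no valid fit in any cohort")
        frame = frame.loc[n_valid > 0]
        n_valid = n_valid.loc[frame.index]
    max_fraction = frame.max(axis=1, skipna=True)
    out = pd.DataFrame(
        {
            "set_label": _labels_from_max(max_fraction.to_numpy(), edges),
            "max_fraction": max_fraction,
            "n_valid_cohorts": n_valid.astype(int),
        },
        index=frame.index.rename("cpg_id"),
    )
    return out


def define_shigh(
    fractions_by_cohort, threshold: float = 0.60, min_cohorts: int = 7
) -> pd.Series:
    """Flag CpGs reaching ``threshold`` (inclusive) in >= ``min_cohorts`` cohorts.

    Only cohorts with a valid fit are counted.  Returns a boolean Series;
    the per-CpG count is available as ``result.attrs['n_above']``.
    """
    frame = _as_fraction_frame(fractions_by_cohort)
    if min_cohorts > frame.shape[1]:
        raise ValueError(
            f"min_cohorts={min_cohorts} exceeds the {frame.shape[1]} cohorts provided"
        )
    if min_cohorts < 1:
        raise ValueError("min_cohorts must be >= 1")
    above = (frame >= threshold) & frame.notna()
    n_above = above.sum(axis=1).astype(int)
    flags = (n_above >= min_cohorts).rename("in_shigh")
    flags.attrs["n_above"] = n_above
    return flags


def build_partition(fractions_by_cohort, config=None, **kwargs) -> pd.DataFrame:
    """Full partition table: set label, Shigh flag, max fraction, cohort count."""
    if config is not None:
        kwargs.setdefault("edges", config.set_edges)
        kwargs.setdefault("threshold", config.shigh_threshold)
        kwargs.setdefault("min_cohorts", config.shigh_min_cohorts)
    edges = kwargs.pop("edges", (0.2, 0.4, 0.6, 0.8))
    threshold = kwargs.pop("threshold", 0.60)
    min_cohorts = kwargs.pop("min_cohorts", 7)
    if kwargs:
        raise TypeError(f"unexpected arguments: {sorted(kwargs)}")
    part = partition_cpg_sets(fractions_by_cohort, edges=edges)
    flags = define_shigh(fractions_by_cohort, threshold=threshold, min_cohorts=min_cohorts)
    part["in_shigh"] = flags.reindex(part.index).fillna(False)
    part["n_cohorts_above_threshold"] = (
        flags.attrs["n_above"].reindex(part.index).fillna(0).astype(int)
    )
    return part[["set_label", "in_shigh", "max_fraction", "n_cohorts_above_threshold"]]


# ---------------------------------------------------------------------------
# PCA of fitted slide effects
# ---------------------------------------------------------------------------


@dataclass
class SlideEffectPCA:
    """Principal components of the slide x CpG matrix of fitted random effects."""

    scores: pd.DataFrame  # slide x component
    loadings: pd.DataFrame  # CpG x component
    var_explained: np.ndarray
    median_class: Optional[pd.Series] = None


def pca_slide_effects(
    blups: pd.DataFrame,
    n_components: Optional[int] = None,
    median_class: Optional[pd.Series] = None,
) -> SlideEffectPCA:
    """SVD-based PCA of per-CpG-centred fitted slide effects.

    Columns (CpGs) are centred across slides before decomposition; no
    variance scaling is applied since the fitted effects already share the
    RINT-derived scale.  Loading signs are fixed so each component's loading
    sum is >= 0, making serialized output deterministic.
    """
    if blups.shape[0] < 2 or blups.shape[1] < 2:
        raise ValueError("need at least 2 slides and 2 CpGs")
    arr = blups.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("fitted-effect matrix contains missing entries; drop flagged CpGs first")
    max_rank = min(arr.shape[0] - 1, arr.shape[1])
    if n_components is None:
        n_components = max_rank
    if n_components > max_rank:
        raise ValueError(f"requested {n_components} components, rank allows {max_rank}")
    centred = arr - arr.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    total = float(np.sum(s**2))
    if total <= 0:
        raise ValueError("degenerate (all-zero) fitted-effect matrix")
    k = n_components
    u, s, vt = u[:, :k], s[:k], vt[:k]
    signs = np.where(vt.sum(axis=1) >= 0, 1.0, -1.0)
    u = u * signs
    vt = vt * signs[:, None]
    comp_names = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(u * s, index=blups.index, columns=comp_names)
    loadings = pd.DataFrame(vt.T, index=blups.columns, columns=comp_names)
    var_explained = (s**2) / total
    if median_class is not None:
        median_class = median_class.reindex(blups.columns)
    return SlideEffectPCA(scores, loadings, var_explained, median_class)


def classify_median_methylation(beta, cpg_subset=None) -> pd.Series:
    """Per-CpG class: 'high' iff median beta >= 0.5, else 'low'.

    A median of exactly 50% counts as high (the low class is strictly
    below 50%).
    """
    frame = beta.values if isinstance(beta, TransformedMatrix) else pd.DataFrame(beta)
    if cpg_subset is not None:
        frame = frame.loc[cpg_subset]
    arr = frame.to_numpy(dtype=float)
    if arr.size and (np.nanmin(arr) < 0 or np.nanmax(arr) > 1):
        raise ValueError("beta values outside [0,1]")
    med = np.median(arr, axis=1)
    return pd.Series(np.where(med >= 0.5, "high", "low"), index=frame.index, name="median_class")


# ---------------------------------------------------------------------------
# correlation / enrichment analyses
# ---------------------------------------------------------------------------


def cpg_correlation_summary(values, cpg_subset=None):
    """Pairwise Pearson correlations of CpG rows plus |r| quartiles.

    Zero-variance rows are excluded with a warning.  Returns
    ``(correlation DataFrame, summary dict)`` where the summary holds the
    quartiles of the absolute off-diagonal correlations.
    """
    frame = values.values if isinstance(values, TransformedMatrix) else pd.DataFrame(values)
    if cpg_subset is not None:
        frame = frame.loc[cpg_subset]
    arr = frame.to_numpy(dtype=float)
    keep = arr.std(axis=1) > 0
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} zero-variance rows from correlation")
        frame = frame.loc[keep]
        arr = arr[keep]
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 non-constant CpGs")
    corr = np.corrcoef(arr)
    iu = np.triu_indices_from(corr, k=1)
    absr = np.abs(corr[iu])
    summary = {
        "q25": float(np.percentile(absr, 25)),
        "median": float(np.percentile(absr, 50)),
        "q75": float(np.percentile(absr, 75)),
        "n_pairs": int(absr.size),
    }
    return pd.DataFrame(corr, index=frame.index, columns=frame.index), summary


def neighbor_slide_enrichment(
    partition: pd.DataFrame,
    annotations: pd.DataFrame,
    radius_bp: int = 100,
) -> dict:
    """Rank-sum test: slide fractions of Shigh neighbours vs the baseline.

    Neighbours are non-Shigh CpGs within ``radius_bp`` (inclusive endpoints)
    of at least one Shigh CpG on the same chromosome; the baseline is every
    remaining non-Shigh CpG.  Returns the two-sided Wilcoxon rank-sum
    statistic and p-value with both group medians.
    """
    if radius_bp <= 0:
        raise ValueError("radius_bp must be positive")
    if "in_shigh" not in partition.columns:
        raise ValueError("partition table lacks an 'in_shigh' column")
    common = partition.index.intersection(annotations.index)
    part = partition.loc[common]
    ann = annotations.loc[common]
    shigh_ids = part.index[part["in_shigh"].astype(bool)]
    if len(shigh_ids) == 0:
        raise ValueError("no Shigh CpGs in partition")
    neighbour_mask = pd.Series(False, index=part.index)
    for chrom, chrom_ann in ann.groupby("chromosome", sort=False):
        pos = chrom_ann["position"].to_numpy(dtype=np.int64)
        ids = chrom_ann.index
        anchor = part.loc[ids, "in_shigh"].to_numpy(dtype=bool)
        if not anchor.any():
            continue
        anchor_pos = np.sort(pos[anchor])
        lo = np.searchsorted(anchor_pos, pos - radius_bp, side="left")
        hi = np.searchsorted(anchor_pos, pos + radius_bp, side="right")
        near = hi > lo
        neighbour_mask.loc[ids[near & ~anchor]] = True
    is_shigh = part["in_shigh"].astype(bool)
    neighbours = part.loc[neighbour_mask & ~is_shigh, "max_fraction"].to_numpy()
    baseline = part.loc[~neighbour_mask & ~is_shigh, "max_fraction"].to_numpy()
    if neighbours.size == 0:
        raise ValueError(f"no neighbours found within {radius_bp} bp of Shigh CpGs")
    stat, pvalue = stats.ranksums(neighbours, baseline)
    return {
        "statistic": float(stat),
        "pvalue": float(pvalue),
        "median_neighbors": float(np.median(neighbours)),
        "median_baseline": float(np.median(baseline)),
        "n_neighbors": int(neighbours.size),
        "n_baseline": int(baseline.size),
    }


def enrichment_chisq(counts) -> tuple[float, float]:
    """Pearson chi-squared test (no continuity correction) on a 2 x K table."""
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    expected = stats.contingency.expected_freq(table)
    if np.any(expected <= 0):
        raise ValueError("chi-squared test requires all expected counts > 0")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def enrichment_anova(values, groups) -> tuple[float, float]:
    """One-way ANOVA of a per-CpG quantity across set labels."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must align")
    samples = [values[groups == g] for g in pd.unique(groups)]
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    small = [i for i, s in enumerate(samples) if s.size < 2]
    if small:
        raise ValueError("every group needs at least 2 members")
    stat, p = stats.f_oneway(*samples)
    return float(stat), float(p)
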