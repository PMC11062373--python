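"""Domain containers, file I/O, and configuration.

The central container is :class:`MethylationDataset`: a CpG-by-sample matrix of
beta-values together with CpG annotations (chromosome, position) and a sample
sheet (slide assignment plus optional covariates).  All tables are exchanged as
tab-separated UTF-8 text with a header row and row labels in the first column,
which is the least-common-denominator layout of GEO-style matrix exports.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CpGAnnotation",
    "SampleRecord",
    "MethylationDataset",
    "AnalysisConfig",
    "DatasetError",
    "read_methylation_dataset",
    "write_methylation_dataset",
    "read_table",
    "write_table",
]

#: chromosome vocabulary: autosomes 1..22 plus X
ALLOWED_CHROMOSOMES = tuple(str(i) for i in range(1, 23)) + ("X",)

_CHR_PREFIX = re.compile(r"^chr", re.IGNORECASE)


class DatasetError(ValueError):
    """Raised when an input table violates a dataset invariant."""


def _canonical_chromosome(token: str) -> str:
    token = _CHR_PREFIX.sub("", str(token).strip())
    if token not in ALLOWED_CHROMOSOMES:
        raise DatasetError(
            f"chromosome {token!r} not in allowed vocabulary 1..22, X"
        )
    return token


@dataclass(frozen=True)
class CpGAnnotation:
    """Location of a single CpG probe (1-based position, no 'chr' prefix)."""

    cpg_id: str
    chromosome: str
    position: int

    def __post_init__(self):
        object.__setattr__(self, "chromosome", _canonical_chromosome(self.chromosome))
        if self.position < 1:
            raise DatasetError(f"{self.cpg_id}: position must be >= 1")


@dataclass
class SampleRecord:
    """One array sample with its slide assignment and optional covariates."""

    sample_id: str
    slide_id: str
    age: Optional[float] = None
    sex: Optional[str] = None
    race: Optional[str] = None
    cell_props: Optional[Sequence[float]] = None

    def __post_init__(self):
        if not self.slide_id:
            raise DatasetError(f"{self.sample_id}: missing slide_id")
        if self.cell_props is not None:
            props = np.asarray(self.cell_props, dtype=float)
            if np.any((props < 0) | (props > 1)):
                raise DatasetError(f"{self.sample_id}: cell proportions outside [0,1]")


@dataclass
class MethylationDataset:
    """Beta-value matrix plus aligned CpG annotations and sample sheet.

    Parameters
    ----------
    beta
        CpG x sample DataFrame of beta-values in [0, 1]; index holds CpG ids,
        columns hold sample ids.
    annotations
        DataFrame indexed by CpG id with columns ``chromosome`` and
        ``position``, aligned to the rows of ``beta``.
    samples
        DataFrame indexed by sample id with a mandatory ``slide_id`` column
        and any covariate columns, aligned to the columns of ``beta``.
    """

    beta: pd.DataFrame
    annotations: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        beta, ann, samp = self.beta, self.annotations, self.samples
        if beta.index.has_duplicates:
            dups = beta.index[beta.index.duplicated()].unique().tolist()
            raise DatasetError(f"duplicate CpG ids: {dups[:5]}")
        if samp.index.has_duplicates:
            dups = samp.index[samp.index.duplicated()].unique().tolist()
            raise DatasetError(f"duplicate sample ids: {dups[:5]}")
        if "slide_id" not in samp.columns:
            raise DatasetError("sample sheet lacks a 'slide_id' column")
        if not beta.index.equals(ann.index):
            raise DatasetError("beta rows and annotation rows are not aligned")
        if not beta.columns.equals(samp.index):
            raise DatasetError("beta columns and sample sheet rows are not aligned")
        values = beta.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise DatasetError("beta matrix contains non-finite values")
        if values.size and (values.min() < 0.0 or values.max() > 1.0):
            bad = beta.index[np.any((values < 0) | (values > 1), axis=1)].tolist()
            raise DatasetError(f"beta values outside [0,1] for CpGs {bad[:5]}")
        ann["chromosome"] = [_canonical_chromosome(c) for c in ann["chromosome"]]
        if (ann["position"] < 1).any():
            raise DatasetError("annotation positions must be >= 1 (1-based)")
        slides = samp["slide_id"].astype(str)
        if slides.isna().any() or (slides == "").any():
            raise DatasetError("every sample needs a slide_id")
        if slides.nunique() < 2:
            raise DatasetError("dataset must contain at least 2 slides")
        for col in samp.columns:
            if col.startswith("cell"):
                vals = samp[col].to_numpy(dtype=float)
                if np.any((vals < 0) | (vals > 1)):
                    raise DatasetError(f"cell proportion column {col} outside [0,1]")

    # -- convenience ------------------------------------------------------
    @property
    def n_cpgs(self) -> int:
        return self.beta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    @property
    def slide_of(self) -> pd.Series:
        """sample id -> slide id mapping, in sample-sheet order."""
        return self.samples["slide_id"].astype(str)

    @property
    def slides(self) -> list[str]:
        """Slide ids in order of first appearance in the sample sheet."""
        return list(dict.fromkeys(self.slide_of))

    def annotation_records(self) -> list[CpGAnnotation]:
        return [
            CpGAnnotation(cpg, row.chromosome, int(row.position))
            for cpg, row in self.annotations.iterrows()
        ]


@dataclass
class AnalysisConfig:
    """Tunable analysis parameters with field-standard defaults.

    ``set_edges`` are the interior boundaries of the variance-explained bins
    (20/40/60/80%); ``shigh_threshold``/``shigh_min_cohorts`` define the
    consistently-susceptible set (>= 60% explained variance in >= 7 cohorts).
    """

    rint_offset: float = 0.375
    beta_clip_epsilon: float = 1e-6
    set_edges: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8)
    shigh_threshold: float = 0.60
    shigh_min_cohorts: int = 7
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        edges = tuple(float(e) for e in self.set_edges)
        if any(not (0.0 < e < 1.0) for e in edges) or list(edges) != sorted(set(edges)):
            raise ValueError("set_edges must be strictly increasing within (0,1)")
        self.set_edges = edges
        if not (0.0 < self.shigh_threshold < 1.0):
            raise ValueError("shigh_threshold must lie in (0,1)")
        if self.shigh_min_cohorts < 1:
            raise ValueError("shigh_min_cohorts must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0,1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "set_edges" in raw:
            raw["set_edges"] = tuple(raw["set_edges"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["set_edges"] = list(data["set_edges"])
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_FLOAT_FORMAT = "%.17g"


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV table written by :func:`write_table` (first column = index)."""
    return pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")


def write_table(obj, path: str | Path) -> None:
    """Write a tabular result as TSV with deterministic column order.

    Accepts a DataFrame or anything with a ``to_frame()`` method producing
    one.  Floats are serialized with 17 significant digits, which round
    trips float64 values exactly.
    """
    if hasattr(obj, "to_frame") and not isinstance(obj, pd.DataFrame):
        obj = obj.to_frame()
    if not isinstance(obj, pd.DataFrame):
        raise TypeError(f"cannot serialize {type(obj).__name__} as a table")
    obj.to_csv(path, sep="\t", float_format=_FLOAT_FORMAT)


def _check_id_match(kind_a: str, ids_a: Iterable[str], kind_b: str, ids_b: Iterable[str]):
    a, b = set(ids_a), set(ids_b)
    if a != b:
        missing = sorted(a - b)[:10]
        extra = sorted(b - a)[:10]
        raise DatasetError(
            f"id mismatch between {kind_a} and {kind_b}: "
            f"only in {kind_a}: {missing}; only in {kind_b}: {extra}"
        )


def read_methylation_dataset(
    beta_path: str | Path,
    annotation_path: str | Path,
    samplesheet_path: str | Path,
) -> MethylationDataset:
    """Load and validate a dataset from three TSV files.

    Rows and columns of the beta matrix are reordered to match the annotation
    and sample-sheet order; any id mismatch between files is reported with the
    offending ids.
    """
    beta = pd.read_csv(beta_path, sep="\t", index_col=0, float_precision="round_trip")
    ann = pd.read_csv(annotation_path, sep="\t", index_col=0, dtype={"chromosome": str})
    sheet = pd.read_csv(samplesheet_path, sep="\t", index_col=0)
    beta.index = beta.index.astype(str)
    ann.index = ann.index.astype(str)
    sheet.index = sheet.index.astype(str)
    if "slide_id" not in sheet.columns:
        raise DatasetError("sample sheet lacks a 'slide_id' column")
    _check_id_match("beta matrix rows", beta.index, "annotation", ann.index)
    _check_id_match("beta matrix columns", beta.columns, "sample sheet", sheet.index)
    beta = beta.loc[ann.index, sheet.index]
    return MethylationDataset(beta=beta, annotations=ann, samples=sheet)


def write_methylation_dataset(
    dataset: MethylationDataset,
    beta_path: str | Path,
    annotation_path: str | Path,
    samplesheet_path: str | Path,
) -> None:
    """Write the three TSV files read back by :func:`read_methylation_dataset`."""
    # %.17g guarantees a float64-exact beta round trip
    dataset.beta.to_csv(beta_path, sep="\t", float_format="%.17g")
    dataset.annotations.to_csv(annotation_path, sep="\t")
    dataset.samples.to_csv(samplesheet_path, sep="\t")
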