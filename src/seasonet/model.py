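"""Core data model shared across the pipeline.

The unit of analysis is an expression time series measured in one
*condition* — a (tissue, season) pair such as cortex/dry — over an ordered
set of sampling timepoints.  Intensities are dimensionless relative values
(band intensity normalised against a reference gene), hence nonnegative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TISSUES = ("cortex", "parenchyma", "leaf")
SEASONS = ("wet", "dry")

#: Short labels used in reports, e.g. cortex/dry -> "C-Dry".
_TISSUE_ABBREV = {"cortex": "C", "parenchyma": "P", "leaf": "L"}


@dataclass(frozen=True, order=True)
class ConditionKey:
    """One analysis condition: a tissue sampled across one seasonal crop."""

    tissue: str
    season: str

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}; expected one of {TISSUES}")
        if self.season not in SEASONS:
            raise ValueError(f"unknown season {self.season!r}; expected one of {SEASONS}")

    @property
    def label(self) -> str:
        return f"{_TISSUE_ABBREV[self.tissue]}-{self.season.capitalize()}"

    @property
    def is_root(self) -> bool:
        return self.tissue in ("cortex", "parenchyma")


ROOT_CONDITIONS = tuple(
    ConditionKey(t, s) for s in SEASONS for t in ("cortex", "parenchyma")
)
LEAF_CONDITIONS = tuple(ConditionKey("leaf", s) for s in SEASONS)
ALL_CONDITIONS = ROOT_CONDITIONS + LEAF_CONDITIONS


@dataclass
class ExpressionMatrix:
    """Genes x ordered timepoints of relative intensities for one condition.

    ``values`` is indexed by gene id with integer timepoint columns in
    sampling order.  Every gene must have a complete series and every value
    must be nonnegative.
    """

    condition: ConditionKey
    values: pd.DataFrame
    dates: list[str] | None = None

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError(f"{self.condition.label}: missing values in expression matrix")
        if (self.values.to_numpy() < 0).any():
            bad = self.values.index[(self.values < 0).any(axis=1)].tolist()
            raise ValueError(f"{self.condition.label}: negative intensities for genes {bad}")
        if self.values.shape[1] < 1:
            raise ValueError(f"{self.condition.label}: matrix has no timepoints")
        if self.values.index.duplicated().any():
            raise ValueError(f"{self.condition.label}: duplicate gene ids")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def timepoints(self) -> list[int]:
        return list(self.values.columns)

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    def series(self, gene: str) -> np.ndarray:
        return self.values.loc[gene].to_numpy(dtype=float)


@dataclass(frozen=True)
class GeneAnnotation:
    """Functional annotation for one gene; TF family only for TFs."""

    id: str
    description: str = ""
    is_tf: bool = False
    tf_family: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("empty gene id")
        if self.tf_family and not self.is_tf:
            raise ValueError(f"{self.id}: tf_family {self.tf_family!r} given but is_tf is false")


@dataclass
class PrecipitationSeries:
    """Rainfall (mm) per sampling interval, ordered like an expression matrix."""

    timepoints: list[int]
    values: np.ndarray
    season: str | None = None
    dates: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.timepoints) != len(self.values):
            raise ValueError("precipitation timepoints and values differ in length")
        if (self.values < 0).any():
            raise ValueError("negative precipitation")


@dataclass(frozen=True)
class CisElement:
    """A cis-regulatory element: IUPAC consensus bound by one TF family."""

    name: str
    tf_family: str
    consensus: str

    def __post_init__(self) -> None:
        from .promoter import IUPAC  # deferred: promoter owns the alphabet

        bad = set(self.consensus.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"element {self.name}: invalid IUPAC letters {sorted(bad)}")
        if len(self.consensus) < 4:
            raise ValueError(f"element {self.name}: consensus shorter than 4 bases")


@dataclass
class AnnotationSet:
    """Annotation list plus the derived TF id set and family lookup."""

    annotations: list[GeneAnnotation] = field(default_factory=list)

    @property
    def tf_set(self) -> set[str]:
        return {a.id for a in self.annotations if a.is_tf}

    @property
    def family_map(self) -> dict[str, str]:
        return {a.id: a.tf_family for a in self.annotations if a.is_tf and a.tf_family}

    def get(self, gene: str) -> GeneAnnotation:
        for a in self.annotations:
            if a.id == gene:
                return a
        return GeneAnnotation(id=gene)
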