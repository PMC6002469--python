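"""Shared domain types for the phenotypic-profiling pipeline.

The pipeline moves through three in-memory representations:

* well-level measurements (:class:`WellRecord`) — one row per well and
  feature, the per-well median of a feature across segmented cells (or a
  plate-reader signal for viability plates);
* fitted concentration–response summaries (:class:`ModelFit`), one per
  (chemical, feature) pair, carrying the selected model and its maximum
  response Δmax;
* the Δmax matrix (:class:`DeltaMatrix`), features × chemicals, the input
  to profiling and classification.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WellRole",
    "FeatureKind",
    "ToxClass",
    "ModelKind",
    "WellRecord",
    "ChemicalAnnotation",
    "DeltaMatrix",
    "ConcentrationResponse",
    "ModelFit",
    "CELL_COUNT_FEATURE",
]

#: Conventional id of the cell-count feature (F1); always fraction-kind.
CELL_COUNT_FEATURE = "cell_count"


class WellRole(str, enum.Enum):
    TREATMENT = "treatment"
    SOLVENT_CONTROL = "solvent_control"
    POSITIVE_CONTROL = "positive_control"
    NO_CELL_CONTROL = "no_cell_control"


class FeatureKind(str, enum.Enum):
    """How a feature's control-normalised response Δ is expressed.

    ``log_ratio``: Δ(x) = log2(r̃(x)/r̃(0)) — all phenotypic features.
    ``fraction``:  Δ(x) = r̃(x)/r̃(0), untransformed — cell count and
    viability, whose responses are read as a surviving fraction.
    """

    LOG_RATIO = "log_ratio"
    FRACTION = "fraction"


class ToxClass(str, enum.Enum):
    PULMONOTOXIC = "pulmonotoxic"
    NON_PULMONOTOXIC = "non_pulmonotoxic"
    TEST = "test"


class ModelKind(str, enum.Enum):
    """Candidate concentration–response models.

    ``model1_up``: log-logistic sigmoid rising from 0 to a plateau α.
    ``model2_down``: the mirrored sigmoid falling to a plateau (α′ ≤ 0 on
    the log-ratio scale; for fraction features, decaying from α′ toward 0).
    ``model3_null``: Δ ≡ 0, no parameters.
    ``constant``: Δ ≡ α″, replaces the null model for fraction features.
    """

    MODEL1_UP = "model1_up"
    MODEL2_DOWN = "model2_down"
    MODEL3_NULL = "model3_null"
    CONSTANT = "constant"


@dataclass(frozen=True)
class WellRecord:
    plate_id: str
    well_id: str
    chemical_id: str
    concentration: float  # µM; 0 for solvent controls
    role: WellRole
    feature_id: str
    value: float

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError(
                f"concentration must be >= 0, got {self.concentration} "
                f"({self.chemical_id}/{self.well_id})"
            )
        if (self.role is WellRole.SOLVENT_CONTROL) != (self.concentration == 0):
            if self.role is not WellRole.NO_CELL_CONTROL:
                raise ValueError(
                    "solvent_control role must coincide with concentration 0 "
                    f"({self.chemical_id}/{self.well_id}: role={self.role.value}, "
                    f"concentration={self.concentration})"
                )
        if not math.isfinite(self.value):
            raise ValueError(
                f"non-finite value for {self.chemical_id}/{self.feature_id} "
                f"in well {self.well_id}"
            )


@dataclass(frozen=True)
class ChemicalAnnotation:
    chemical_id: str
    name: str
    tox_class: ToxClass
    solvent: str  # DMSO, ethanol or water
    max_concentration: float  # µM, 2000 or 1000

    def __post_init__(self) -> None:
        if self.max_concentration not in (1000.0, 2000.0):
            raise ValueError(
                f"max_concentration must be 1000 or 2000 µM, got "
                f"{self.max_concentration} for {self.chemical_id}"
            )


@dataclass
class DeltaMatrix:
    """Features × chemicals matrix of maximum responses Δmax.

    ``values[i, j]`` is the selected model's response at the evaluation
    concentration for feature ``feature_ids[i]`` under chemical
    ``chemical_ids[j]``. Log-ratio features are in log2 units; fraction
    features (cell count, viability) are control-relative fractions.
    """

    feature_ids: list[str]
    chemical_ids: list[str]
    values: np.ndarray
    feature_kind: dict[str, FeatureKind] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.chemical_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.feature_ids)} features x {len(self.chemical_ids)} chemicals"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicated feature ids")
        if len(set(self.chemical_ids)) != len(self.chemical_ids):
            raise ValueError("duplicated chemical ids")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))
            coords = [
                (self.feature_ids[i], self.chemical_ids[j]) for i, j in bad[:5]
            ]
            raise ValueError(f"non-finite / missing matrix entries at {coords}")
        for fid in self.feature_ids:
            self.feature_kind.setdefault(
                fid,
                FeatureKind.FRACTION
                if fid == CELL_COUNT_FEATURE
                else FeatureKind.LOG_RATIO,
            )
        for fid, kind in self.feature_kind.items():
            if kind is FeatureKind.FRACTION and fid in self.feature_ids:
                row = self.values[self.feature_ids.index(fid)]
                if np.any(row < 0):
                    raise ValueError(f"fraction-kind feature {fid} has negative entries")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, feature_id: str) -> np.ndarray:
        return self.values[self.feature_ids.index(feature_id)]

    def column(self, chemical_id: str) -> np.ndarray:
        return self.values[:, self.chemical_ids.index(chemical_id)]

    def subset_chemicals(self, chemical_ids: list[str]) -> "DeltaMatrix":
        idx = [self.chemical_ids.index(c) for c in chemical_ids]
        return DeltaMatrix(
            feature_ids=list(self.feature_ids),
            chemical_ids=list(chemical_ids),
            values=self.values[:, idx].copy(),
            feature_kind=dict(self.feature_kind),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.chemical_ids
        )


@dataclass
class ConcentrationResponse:
    """Control-normalised responses Δ(x) for one (chemical, feature) pair."""

    chemical_id: str
    feature_id: str
    feature_kind: FeatureKind
    baseline: float  # r̃(0), median over solvent-control wells
    points: list[tuple[float, float]]  # (concentration µM, Δ(x))

    def __post_init__(self) -> None:
        concs = [x for x, _ in self.points]
        if len(self.points) < 6:
            raise ValueError(
                f"need >= 6 concentrations for {self.chemical_id}/{self.feature_id}, "
                f"got {len(self.points)}"
            )
        if min(concs) <= 0 or len(set(concs)) != len(concs):
            raise ValueError("concentrations must be strictly positive and distinct")
        if self.feature_kind is FeatureKind.FRACTION and any(
            d < 0 for _, d in self.points
        ):
            raise ValueError("fraction-kind Δ must be >= 0")

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([x for x, _ in self.points])

    @property
    def deltas(self) -> np.ndarray:
        return np.array([d for _, d in self.points])


@dataclass
class ModelFit:
    """One fitted candidate model with its goodness-of-fit bookkeeping.

    ``D`` counts fitted parameters (3 for the sigmoids, 1 for the constant
    model, 0 for the null model); ``rss`` is the residual sum of squares
    over the ``m`` concentration points; ``delta_max`` is the fitted curve
    evaluated at the evaluation concentration (2000 µM by default).
    """

    kind: ModelKind
    params: tuple[float, ...]
    D: int
    residuals: np.ndarray
    m: int
    rss: float
    aic: float = math.nan
    delta_max: float = math.nan
    converged: bool = True

    def __post_init__(self) -> None:
        expected_D = {
            ModelKind.MODEL1_UP: 3,
            ModelKind.MODEL2_DOWN: 3,
            ModelKind.MODEL3_NULL: 0,
            ModelKind.CONSTANT: 1,
        }[self.kind]
        if self.D != expected_D:
            raise ValueError(f"{self.kind.value} must have D={expected_D}, got {self.D}")
        if not math.isclose(
            self.rss, float(np.sum(np.square(self.residuals))), rel_tol=1e-9, abs_tol=1e-12
        ):
            raise ValueError("rss must equal the sum of squared residuals")
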