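"""Seeded generators emulating the screening study's data structure.

The main generator produces a well-level table with the study's design:
7 two-fold-diluted concentrations (2000 → 31.3 µM; optionally
1000 → 15.7 µM for designated chemicals), 4 technical replicates per
condition, solvent-control wells, and per-(chemical, feature)
ground-truth concentration–response models. One planted feature carries
the class signal (a larger log2 plateau for pulmonotoxic chemicals than
for non-pulmonotoxic ones); designated "no cell" chemicals kill nearly
all cells at every dose at or above 125 µM.

Feature values are generated as ``baseline · 2^(Δ_model(x) + ε)`` with
ε ~ Normal(0, noise_sd) on the log2 scale; cell counts are Poisson
around the model-implied mean when noise is on, and exact means when
``noise_sd == 0`` so that noiseless parameter-recovery checks are exact.
Per-(chemical, feature) substreams are derived by stable hashing, so
adding a chemical never perturbs another chemical's draws.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .datatypes import (
    CELL_COUNT_FEATURE,
    ChemicalAnnotation,
    FeatureKind,
    ModelKind,
    ToxClass,
    WellRecord,
    WellRole,
)
from .doseresponse import model_curve

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_study",
    "simulate_viability_plate",
    "simulate_autofluorescence_pixels",
    "simulate_comet_medians",
    "CONCENTRATIONS_HIGH",
    "CONCENTRATIONS_LOW",
]

#: Standard dilution series, µM (top dose 2000).
CONCENTRATIONS_HIGH = (2000.0, 1000.0, 500.0, 250.0, 125.0, 62.5, 31.3)
#: Reduced series for chemicals toxic at the standard top dose.
CONCENTRATIONS_LOW = (1000.0, 500.0, 250.0, 125.0, 62.5, 31.3, 15.7)

_SOLVENTS = ("DMSO", "ethanol", "water")


@dataclass
class SimulationConfig:
    """Study-design parameters for :func:`simulate_study`.

    Defaults mirror the reference study: 13 pulmonotoxic / 20
    non-pulmonotoxic / 17 unannotated test chemicals, 166 features
    (165 phenotypic + cell count), 7 doses, 4 technical replicates,
    planted log2 effect 1.5 vs 0.1, log2 noise SD 0.15, ~2500 cells per
    control well.
    """

    n_chemicals_per_class: dict[str, int] = field(
        default_factory=lambda: {"pulmonotoxic": 13, "non_pulmonotoxic": 20, "test": 17}
    )
    n_features: int = 166
    concentrations: tuple[float, ...] = CONCENTRATIONS_HIGH
    n_replicates: int = 4
    planted_feature_id: str = "feat_001"
    effect_size_toxic: float = 1.5
    effect_size_nontoxic: float = 0.1
    noise_sd: float = 0.15
    nc_chemical_ids: tuple[str, ...] = ("tox_01", "tox_02")
    low_dose_chemical_ids: tuple[str, ...] = ()
    baseline_cells_per_well: int = 2500
    null_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        concs = list(self.concentrations)
        if len(concs) < 6 or any(b >= a for a, b in zip(concs, concs[1:])):
            raise ValueError("concentrations must be strictly decreasing, length >= 6")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.planted_feature_id not in self.feature_ids():
            raise ValueError(
                f"planted_feature_id {self.planted_feature_id!r} outside the "
                f"{self.n_features}-feature panel"
            )

    def feature_ids(self) -> list[str]:
        # feature 0 is the cell count; the rest are phenotypic features
        return [CELL_COUNT_FEATURE] + [
            f"feat_{i:03d}" for i in range(1, self.n_features)
        ]

    def chemical_ids(self) -> dict[str, list[str]]:
        return {
            "pulmonotoxic": [
                f"tox_{i + 1:02d}"
                for i in range(self.n_chemicals_per_class.get("pulmonotoxic", 0))
            ],
            "non_pulmonotoxic": [
                f"ntx_{i + 1:02d}"
                for i in range(self.n_chemicals_per_class.get("non_pulmonotoxic", 0))
            ],
            "test": [
                f"tst_{i + 1:02d}"
                for i in range(self.n_chemicals_per_class.get("test", 0))
            ],
        }


@dataclass
class GroundTruth:
    """Every drawn generating parameter, keyed by (chemical_id, feature_id)."""

    model_kind: dict[tuple[str, str], ModelKind] = field(default_factory=dict)
    params: dict[tuple[str, str], tuple[float, ...]] = field(default_factory=dict)
    feature_kind: dict[str, FeatureKind] = field(default_factory=dict)
    baseline: dict[tuple[str, str], float] = field(default_factory=dict)
    test_is_toxic: dict[str, bool] = field(default_factory=dict)
    nc_chemicals: tuple[str, ...] = ()

    def delta_at(self, chemical_id: str, feature_id: str, x: float) -> float:
        kind = self.model_kind[(chemical_id, feature_id)]
        fk = self.feature_kind[feature_id]
        return float(
            model_curve(kind, self.params[(chemical_id, feature_id)], [x], fk)[0]
        )


def _substream(seed: int, *tokens: str) -> np.random.Generator:
    """Independent RNG stream keyed by seed and string tokens.

    Stable across runs and insensitive to the order other streams are
    consumed in (adding a chemical does not shift another's draws).
    """
    digest = hashlib.sha256(("|".join(tokens) + f"|{seed}").encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def _draw_cell_model(
    cfg: SimulationConfig, chem: str, is_nc: bool, rng: np.random.Generator
) -> tuple[ModelKind, tuple[float, ...]]:
    if is_nc:
        # steep kill curve: relative count << 30% at every dose >= 125 µM
        return ModelKind.MODEL2_DOWN, (1.0, 6.0, 30.0)
    u = rng.uniform()
    if u < 0.5:
        return ModelKind.CONSTANT, (float(rng.uniform(0.9, 1.05)),)
    # mild dose-dependent decline, bottoming out well above the NC cut
    plateau = 1.0
    slope = float(rng.uniform(1.0, 3.0))
    ec = float(rng.uniform(1500.0, 8000.0))
    return ModelKind.MODEL2_DOWN, (plateau, slope, ec)


def _draw_feature_model(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[ModelKind, tuple[float, ...]]:
    if rng.uniform() < cfg.null_fraction:
        return ModelKind.MODEL3_NULL, ()
    concs = np.asarray(cfg.concentrations)
    slope = float(rng.uniform(1.0, 5.0))
    ec = float(np.exp(rng.uniform(np.log(concs.min() * 2), np.log(concs.max() / 2))))
    size = float(rng.uniform(0.4, 1.5))
    if rng.uniform() < 0.5:
        return ModelKind.MODEL1_UP, (size, slope, ec)
    return ModelKind.MODEL2_DOWN, (-size, slope, ec)


def simulate_study(
    config: SimulationConfig,
) -> tuple[list[WellRecord], list[ChemicalAnnotation], GroundTruth]:
    """Generate a complete well-level study with known ground truth.

    Returns well records (treated + solvent controls), chemical
    annotations, and the :class:`GroundTruth` holding every drawn model.
    Half of the test chemicals (ground truth only — their annotation is
    ``test``) behave like pulmonotoxic chemicals on the planted feature.
    """
    ids = config.chemical_ids()
    all_chems = ids["pulmonotoxic"] + ids["non_pulmonotoxic"] + ids["test"]
    missing_nc = [c for c in config.nc_chemical_ids if c not in all_chems]
    if missing_nc:
        raise ValueError(f"nc_chemical_ids not among simulated chemicals: {missing_nc}")
    feature_ids = config.feature_ids()
    truth = GroundTruth(nc_chemicals=tuple(config.nc_chemical_ids))
    for fid in feature_ids:
        truth.feature_kind[fid] = (
            FeatureKind.FRACTION if fid == CELL_COUNT_FEATURE else FeatureKind.LOG_RATIO
        )

    annotations: list[ChemicalAnnotation] = []
    for cls, chems in ids.items():
        for k, chem in enumerate(chems):
            annotations.append(
                ChemicalAnnotation(
                    chemical_id=chem,
                    name=chem,
                    tox_class=ToxClass(cls),
                    solvent=_SOLVENTS[k % len(_SOLVENTS)],
                    max_concentration=(
                        1000.0 if chem in config.low_dose_chemical_ids else 2000.0
                    ),
                )
            )

    for i, chem in enumerate(ids["test"]):
        truth.test_is_toxic[chem] = i % 2 == 0  # alternate toxic-like/benign

    wells: list[WellRecord] = []
    for ann in annotations:
        chem = ann.chemical_id
        toxic_like = ann.tox_class is ToxClass.PULMONOTOXIC or truth.test_is_toxic.get(
            chem, False
        )
        concs = (
            CONCENTRATIONS_LOW
            if chem in config.low_dose_chemical_ids
            else config.concentrations
        )
        for fid in feature_ids:
            rng = _substream(config.seed, "study", chem, fid)
            if fid == CELL_COUNT_FEATURE:
                kind, params = _draw_cell_model(
                    config, chem, chem in config.nc_chemical_ids, rng
                )
                baseline = float(config.baseline_cells_per_well)
            elif fid == config.planted_feature_id:
                effect = (
                    config.effect_size_toxic
                    if toxic_like
                    else config.effect_size_nontoxic
                )
                kind, params = ModelKind.MODEL1_UP, (effect, 2.0, 250.0)
                baseline = 100.0
            else:
                kind, params = _draw_feature_model(config, rng)
                baseline = float(np.exp(rng.uniform(np.log(10.0), np.log(1000.0))))
            truth.model_kind[(chem, fid)] = kind
            truth.params[(chem, fid)] = params
            truth.baseline[(chem, fid)] = baseline

            fk = truth.feature_kind[fid]
            model_delta = model_curve(kind, params, np.asarray(concs), fk)
            for ci, (x, dm) in enumerate(zip(concs, model_delta)):
                for rep in range(config.n_replicates):
                    eps = (
                        float(rng.normal(0.0, config.noise_sd))
                        if config.noise_sd > 0
                        else 0.0
                    )
                    if fk is FeatureKind.FRACTION:
                        mean = baseline * dm * 2.0**eps
                        value = (
                            float(rng.poisson(max(mean, 0.0)))
                            if config.noise_sd > 0
                            else float(mean)
                        )
                    else:
                        value = baseline * 2.0 ** (dm + eps)
                    wells.append(
                        WellRecord(
                            plate_id=f"plate_{ci % 4 + 1}",
                            well_id=f"{chem}_c{ci}_r{rep}",
                            chemical_id=chem,
                            concentration=float(x),
                            role=WellRole.TREATMENT,
                            feature_id=fid,
                            value=value,
                        )
                    )
            # solvent-control wells at concentration 0 (the chemical's solvent)
            for rep in range(config.n_replicates):
                eps = (
                    float(rng.normal(0.0, config.noise_sd))
                    if config.noise_sd > 0
                    else 0.0
                )
                if fk is FeatureKind.FRACTION:
                    mean = baseline * 2.0**eps
                    value = (
                        float(rng.poisson(mean)) if config.noise_sd > 0 else float(mean)
                    )
                else:
                    value = baseline * 2.0**eps
                wells.append(
                    WellRecord(
                        plate_id="plate_ctrl",
                        well_id=f"{chem}_ctrl_r{rep}",
                        chemical_id=chem,
                        concentration=0.0,
                        role=WellRole.SOLVENT_CONTROL,
                        feature_id=fid,
                        value=value,
                    )
                )
    return wells, annotations, truth


# ---------------------------------------------------------------------------
# viability plates


def simulate_viability_plate(
    config: SimulationConfig,
    contamination: dict | None = None,
) -> list[WellRecord]:
    """Plate-reader-like viability signals with optional injected outliers.

    Five technical replicates per condition, no-cell control wells (pure
    background) and solvent controls. ``contamination`` may specify
    ``background`` (signal offset, default 50), ``cv`` (clean relative
    spread, default 0.05) and ``outliers`` — a list of
    ``(chemical_id, concentration, replicate, multiplier)`` tuples whose
    wells are multiplied to create high-CoV groups at known locations.
    """
    contamination = dict(contamination or {})
    background = float(contamination.get("background", 50.0))
    cv = float(contamination.get("cv", 0.05))
    outliers = list(contamination.get("outliers", []))
    n_rep = 5
    ids = config.chemical_ids()
    chems = ids["pulmonotoxic"] + ids["non_pulmonotoxic"] + ids["test"]
    signal0 = 1000.0

    wells: list[WellRecord] = []
    rng = _substream(config.seed, "viability", "no_cell")
    for rep in range(n_rep):
        wells.append(
            WellRecord(
                plate_id="viab_plate",
                well_id=f"nocell_r{rep}",
                chemical_id="__no_cell__",
                concentration=0.0,
                role=WellRole.NO_CELL_CONTROL,
                feature_id="viability",
                value=background * (1.0 + rng.normal(0.0, cv / 5)),
            )
        )
    outlier_map = {(c, float(x), r): m for c, x, r, m in outliers}
    for chem in chems:
        rng = _substream(config.seed, "viability", chem)
        is_nc = chem in config.nc_chemical_ids
        for rep in range(n_rep):
            mult = outlier_map.get((chem, 0.0, rep), 1.0)
            wells.append(
                WellRecord(
                    plate_id="viab_plate",
                    well_id=f"{chem}_ctrl_r{rep}",
                    chemical_id=chem,
                    concentration=0.0,
                    role=WellRole.SOLVENT_CONTROL,
                    feature_id="viability",
                    value=(background + signal0 * (1.0 + rng.normal(0.0, cv))) * mult,
                )
            )
        for x in config.concentrations:
            frac = (
                float(model_curve(ModelKind.MODEL2_DOWN, (1.0, 6.0, 30.0), [x],
                                  FeatureKind.FRACTION)[0])
                if is_nc
                else 1.0
            )
            for rep in range(n_rep):
                mult = outlier_map.get((chem, float(x), rep), 1.0)
                signal = background + signal0 * frac * (1.0 + rng.normal(0.0, cv))
                wells.append(
                    WellRecord(
                        plate_id="viab_plate",
                        well_id=f"{chem}_c{x:g}_r{rep}",
                        chemical_id=chem,
                        concentration=float(x),
                        role=WellRole.TREATMENT,
                        feature_id="viability",
                        value=signal * mult,
                    )
                )
    return wells


# ---------------------------------------------------------------------------
# autofluorescence pixels


def simulate_autofluorescence_pixels(
    fbr_target: float, n_fore: int = 10000, n_back: int = 10000, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-value pools whose FBR equals ``fbr_target`` by construction.

    Background pixels are drawn around a camera offset; foreground pixels
    are rescaled so that their empirical 99.9th percentile is exactly
    ``2^fbr_target`` times the empirical background median.
    """
    if n_fore < 1000 or n_back < 1000:
        raise ValueError("need >= 1000 pixels per region")
    if not np.isfinite(fbr_target):
        raise ValueError("fbr_target must be finite")
    rng = _substream(seed, "autofluorescence")
    back = rng.normal(500.0, 40.0, size=n_back).clip(min=1.0)
    fore = rng.gamma(shape=2.0, scale=1.0, size=n_fore) + 0.2
    target_p999 = float(np.median(back)) * 2.0**fbr_target
    fore *= target_p999 / np.percentile(fore, 99.9)
    return fore, back


# ---------------------------------------------------------------------------
# comet-assay replicate medians


def simulate_comet_medians(
    condition_means: dict[str, float],
    n_replicates: int = 4,
    sd: float = 1.0,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Per-condition replicate median %-tail-DNA values.

    Medians are Normal(mean, sd) truncated to [0, 100]; ``sd == 0``
    returns the condition means exactly.
    """
    out: dict[str, np.ndarray] = {}
    for cond, mean in condition_means.items():
        if not 0.0 <= mean <= 100.0:
            raise ValueError(f"condition mean must be within [0, 100], got {mean}")
        rng = _substream(seed, "comet", cond)
        draws = np.full(n_replicates, float(mean))
        if sd > 0:
            draws = draws + rng.normal(0.0, sd, size=n_replicates)
        out[cond] = np.clip(draws, 0.0, 100.0)
    return out
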