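"""End-to-end orchestration: fit → profile → screen → train → predict.

A :class:`PipelineConfig` (YAML-loadable) names the inputs and the
analysis variants; :func:`run_pipeline` executes the stages in order and
writes every artifact into a run directory together with the config and
a log. All randomness flows from the single top-level seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, doseresponse, profiling
from .datatypes import CELL_COUNT_FEATURE, ToxClass
from .io import load_study, write_delta_matrix, write_table

__all__ = ["PipelineConfig", "run_pipeline", "nc_flags_from_wells"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    wells_path: str
    annotations_path: str
    out_dir: str
    aic_variant: str = "standard"
    nc_count_threshold: float = 0.30
    nc_concentration_floor: float = 125.0
    folds: int = 10
    seed: int = 0
    repeats: int = 1
    c_grid: tuple[float, ...] = classify.C_GRID_DEFAULT
    bioactivity_scale: str = "ratio"
    welch: bool = False
    include_cell_count_input: bool = False  # F1 as an extra margin-classifier input
    x_eval: float = doseresponse.X_EVAL_DEFAULT

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        missing = [
            k for k in ("wells_path", "annotations_path", "out_dir") if k not in raw
        ]
        if missing:
            raise ValueError(f"config missing required field(s): {missing}")
        if "c_grid" in raw:
            raw["c_grid"] = tuple(float(c) for c in raw["c_grid"])
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def nc_flags_from_wells(
    wells, annotations, params: classify.NCRuleParams
) -> dict[str, bool]:
    """Apply the NC rule to every chemical's relative cell counts."""
    flags = {}
    for ann in annotations:
        counts = doseresponse.relative_cell_counts(wells, ann.chemical_id)
        flags[ann.chemical_id] = classify.call_nc(counts, params)
    return flags


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full analysis and return the populated run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_log = out / "run.log"
    handler = logging.FileHandler(run_log, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("hipptox")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    stamp = {"config": asdict(config), "config_hash": config.digest()}
    try:
        wells, annotations = load_study(config.wells_path, config.annotations_path)
        log.info("loaded %d well records, %d chemicals", len(wells), len(annotations))

        nc_params = classify.NCRuleParams(
            config.nc_count_threshold, config.nc_concentration_floor
        )
        nc_flags = nc_flags_from_wells(wells, annotations, nc_params)
        log.info("NC chemicals: %s", sorted(c for c, f in nc_flags.items() if f))

        matrix, report = doseresponse.build_delta_matrix(
            wells, annotations, variant=config.aic_variant, x_eval=config.x_eval
        )
        write_delta_matrix(matrix, out / "deltamax.csv")
        with open(out / "fits.json", "w") as fh:
            json.dump(
                {
                    f"{c}|{f}": {
                        "model": report.selected_kind[(c, f)].value,
                        "params": list(report.params[(c, f)]),
                        "rss": report.rss[(c, f)],
                        "aic": report.aic[(c, f)],
                    }
                    for (c, f) in report.selected_kind
                },
                fh,
                indent=1,
            )
        log.info(
            "fitted %d cells (%d extrapolated beyond top dose)",
            len(report.selected_kind),
            len(report.extrapolated),
        )

        nc_list = [c for c, f in nc_flags.items() if f]
        calls = profiling.call_bioactivity(
            matrix, exclude_nc=nc_list, scale=config.bioactivity_scale
        )
        write_table(
            pd.DataFrame(
                {
                    "chemical_id": [c.chemical_id for c in calls],
                    "n_changed_features": [c.n_changed_features for c in calls],
                    "n_features_total": [c.n_features_total for c in calls],
                    "bioactive": [c.bioactive for c in calls],
                }
            ),
            out / "bioactivity.csv",
        )
        log.info("bioactive: %d / %d non-NC chemicals",
                 sum(c.bioactive for c in calls), len(calls))

        labels = {
            a.chemical_id: a.tox_class is ToxClass.PULMONOTOXIC
            for a in annotations
            if a.tox_class is not ToxClass.TEST
        }
        screen_features = [f for f in matrix.feature_ids if f != CELL_COUNT_FEATURE]
        ranking = classify.screen_features(
            matrix,
            labels,
            nc_flags,
            folds=config.folds,
            seed=config.seed,
            repeats=config.repeats,
            feature_ids=screen_features,
        )
        write_table(
            pd.DataFrame(
                ranking,
                columns=[
                    "feature_id",
                    "balanced_accuracy",
                    "sensitivity",
                    "specificity",
                ],
            ),
            out / "ranking.csv",
        )
        best_feature = ranking[0][0]
        log.info("best feature: %s (balanced accuracy %.1f%%)", best_feature, ranking[0][1])

        model_features = [best_feature] + (
            [CELL_COUNT_FEATURE] if config.include_cell_count_input else []
        )
        model = classify.train_cascade(
            matrix,
            labels,
            model_features,
            nc_flags,
            C_grid=config.c_grid,
            seed=config.seed,
            nc_params=nc_params,
        )
        with open(out / "model.json", "w") as fh:
            json.dump(
                {
                    "config_hash": config.digest(),
                    "feature_ids": model.feature_ids,
                    "scaler": {f: list(s) for f, s in model.scaler.items()},
                    "weights": model.weights.tolist(),
                    "bias": model.bias,
                    "C": model.C,
                    "nc_params": {
                        "count_threshold": nc_params.count_threshold,
                        "concentration_floor": nc_params.concentration_floor,
                    },
                },
                fh,
                indent=1,
            )

        test_chems = [
            a.chemical_id for a in annotations if a.tox_class is ToxClass.TEST
        ]
        predictions = []
        for chem in test_chems:
            values = {
                f: float(matrix.row(f)[matrix.chemical_ids.index(chem)])
                for f in model.feature_ids
            }
            predictions.append(
                (chem, classify.predict_cascade(model, values, nc_flags[chem]))
            )
        if predictions:
            write_table(
                pd.DataFrame(
                    {
                        "chemical_id": [c for c, _ in predictions],
                        "prediction": [
                            "positive" if p else "negative" for _, p in predictions
                        ],
                    }
                ),
                out / "predictions.csv",
            )
            log.info(
                "test-set positives: %d / %d",
                sum(p for _, p in predictions),
                len(predictions),
            )
        with open(out / "run.json", "w") as fh:
            json.dump(stamp, fh, indent=1)
    finally:
        root.removeHandler(handler)
        handler.close()
    return out
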