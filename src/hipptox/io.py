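"""Readers and writers for the pipeline's tabular formats.

Wells table (long format, one row per well × feature):
``plate_id, well_id, chemical_id, concentration_uM, role, feature_id, value``.

Annotations table:
``chemical_id, name, tox_class, solvent, max_concentration_uM``.

Δmax matrix: CSV with features as rows and a header row of chemical ids
(orientation auto-detected against the annotation table when available),
plus XLSX import for supplementary spreadsheets.
"""

from __future__ import annotations

import logging
import unicodedata
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    CELL_COUNT_FEATURE,
    ChemicalAnnotation,
    DeltaMatrix,
    FeatureKind,
    ToxClass,
    WellRecord,
    WellRole,
)

__all__ = [
    "load_study",
    "load_delta_matrix",
    "write_table",
    "write_delta_matrix",
    "normalize_identifier",
]

log = logging.getLogger(__name__)

WELLS_COLUMNS = [
    "plate_id",
    "well_id",
    "chemical_id",
    "concentration_uM",
    "role",
    "feature_id",
    "value",
]
ANNOTATION_COLUMNS = [
    "chemical_id",
    "name",
    "tox_class",
    "solvent",
    "max_concentration_uM",
]

# Typographic characters that show up in supplementary chemical names
# (primes vs apostrophes, non-breaking spaces, en dashes).
_CHAR_MAP = str.maketrans(
    {
        "’": "'",
        "‘": "'",
        "′": "'",
        " ": " ",
        "–": "-",
        "−": "-",
    }
)


class SchemaError(ValueError):
    """A table is missing required columns or has unparseable cells."""


def normalize_identifier(raw: str) -> str:
    """Canonicalise a chemical/feature identifier.

    NFC-normalises unicode and maps typographic primes/dashes to ASCII so
    that e.g. ``2,4′-DDT`` and ``2,4'-DDT`` collide to one id.
    Identifiers remain case-sensitive.
    """
    return unicodedata.normalize("NFC", str(raw)).translate(_CHAR_MAP).strip()


def _require_columns(df: pd.DataFrame, required: list[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _parse_numeric(df: pd.DataFrame, column: str, path: Path) -> pd.Series:
    parsed = pd.to_numeric(df[column], errors="coerce")
    bad = parsed.isna() & df[column].notna()
    if bad.any():
        rows = (df.index[bad] + 2).tolist()[:5]  # +2: header and 1-based
        raise SchemaError(f"{path}: non-numeric '{column}' at file row(s) {rows}")
    if parsed.isna().any():
        rows = (df.index[parsed.isna()] + 2).tolist()[:5]
        raise SchemaError(f"{path}: empty '{column}' at file row(s) {rows}")
    return parsed.astype(float)


def load_study(
    wells_path: str | Path, annotations_path: str | Path
) -> tuple[list[WellRecord], list[ChemicalAnnotation]]:
    """Load and validate a well-level study (wells + chemical annotations).

    Raises :class:`SchemaError` for missing columns or unparseable values,
    and ``ValueError`` when the wells table references chemicals absent
    from the annotation table.
    """
    wells_path, annotations_path = Path(wells_path), Path(annotations_path)
    ann_df = pd.read_csv(annotations_path, dtype=str)
    _require_columns(ann_df, ANNOTATION_COLUMNS, annotations_path)
    ann_df["max_concentration_uM"] = _parse_numeric(
        ann_df, "max_concentration_uM", annotations_path
    )
    annotations = [
        ChemicalAnnotation(
            chemical_id=normalize_identifier(r.chemical_id),
            name=str(r.name_),
            tox_class=ToxClass(r.tox_class),
            solvent=str(r.solvent),
            max_concentration=float(r.max_concentration_uM),
        )
        for r in ann_df.rename(columns={"name": "name_"}).itertuples(index=False)
    ]
    seen: set[str] = set()
    for a in annotations:
        if a.chemical_id in seen:
            raise ValueError(f"chemical {a.chemical_id} annotated more than once")
        seen.add(a.chemical_id)

    wells_df = pd.read_csv(wells_path, dtype=str)
    _require_columns(wells_df, WELLS_COLUMNS, wells_path)
    wells_df["concentration_uM"] = _parse_numeric(
        wells_df, "concentration_uM", wells_path
    )
    wells_df["value"] = _parse_numeric(wells_df, "value", wells_path)
    records = [
        WellRecord(
            plate_id=str(r.plate_id),
            well_id=str(r.well_id),
            chemical_id=normalize_identifier(r.chemical_id),
            concentration=float(r.concentration_uM),
            role=WellRole(r.role),
            feature_id=normalize_identifier(r.feature_id),
            value=float(r.value),
        )
        for r in wells_df.itertuples(index=False)
    ]
    unknown = sorted(
        {r.chemical_id for r in records}
        - seen
        - {"__solvent__"}  # shared solvent-control pseudo-chemical
    )
    if unknown:
        raise ValueError(
            f"wells table references chemicals absent from annotations: {unknown}"
        )
    return records, annotations


def wells_to_frame(records: list[WellRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "plate_id": [r.plate_id for r in records],
            "well_id": [r.well_id for r in records],
            "chemical_id": [r.chemical_id for r in records],
            "concentration_uM": [r.concentration for r in records],
            "role": [r.role.value for r in records],
            "feature_id": [r.feature_id for r in records],
            "value": [r.value for r in records],
        }
    )


def annotations_to_frame(annotations: list[ChemicalAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chemical_id": [a.chemical_id for a in annotations],
            "name": [a.name for a in annotations],
            "tox_class": [a.tox_class.value for a in annotations],
            "solvent": [a.solvent for a in annotations],
            "max_concentration_uM": [a.max_concentration for a in annotations],
        }
    )


def write_table(records, path: str | Path) -> Path:
    """Write a tabular result to CSV with deterministic column order.

    Accepts a DataFrame, a list of :class:`WellRecord`, a list of
    :class:`ChemicalAnnotation`, or a :class:`DeltaMatrix`. Floats are
    written with the shortest lossless representation, so read∘write is
    the identity. Refuses empty input and creates no file in that case.
    """
    path = Path(path)
    if isinstance(records, DeltaMatrix):
        return write_delta_matrix(records, path)
    if isinstance(records, list) and records and isinstance(records[0], WellRecord):
        df = wells_to_frame(records)
    elif (
        isinstance(records, list)
        and records
        and isinstance(records[0], ChemicalAnnotation)
    ):
        df = annotations_to_frame(records)
    elif isinstance(records, pd.DataFrame):
        df = records
    else:
        raise ValueError("empty or unsupported input; nothing written")
    if df.empty:
        raise ValueError("empty table; nothing written")
    df.to_csv(path, index=False, encoding="utf-8")
    return path


def write_delta_matrix(matrix: DeltaMatrix, path: str | Path) -> Path:
    path = Path(path)
    df = matrix.to_frame()
    df.index.name = "feature_id"
    df.to_csv(path, encoding="utf-8")
    return path


def load_delta_matrix(
    path: str | Path,
    dialect: str | None = None,
    annotations: list[ChemicalAnnotation] | None = None,
    orientation: str = "auto",
    fraction_features: tuple[str, ...] = (CELL_COUNT_FEATURE,),
    sheet: int | str = 0,
) -> DeltaMatrix:
    """Load a Δmax matrix from CSV or XLSX.

    Orientation (features-as-rows vs chemicals-as-rows) is auto-detected
    by matching the header row against known chemical ids from
    ``annotations``; ``orientation`` in {"features_rows", "chemicals_rows"}
    overrides. The cell-count row is tagged fraction-kind.
    """
    path = Path(path)
    if dialect is None:
        dialect = "xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv"
    if dialect == "xlsx":
        df = pd.read_excel(path, sheet_name=sheet, index_col=0)
    else:
        df = pd.read_csv(path, index_col=0)
    if df.isna().any().any():
        bad = [
            (str(df.index[i]), str(df.columns[j]))
            for i, j in zip(*np.where(df.isna().to_numpy()))
        ][:5]
        raise ValueError(f"{path}: empty matrix cells at {bad}")
    df.index = [normalize_identifier(i) for i in df.index]
    df.columns = [normalize_identifier(c) for c in df.columns]

    if orientation == "auto":
        if annotations:
            known = {a.chemical_id for a in annotations}
            cols_hit = len(known.intersection(df.columns))
            rows_hit = len(known.intersection(df.index))
            orientation = "features_rows" if cols_hit >= rows_hit else "chemicals_rows"
        elif any(f in df.index for f in fraction_features):
            orientation = "features_rows"
        elif any(f in df.columns for f in fraction_features):
            orientation = "chemicals_rows"
        else:
            # last resort: the study has more features than chemicals
            orientation = (
                "features_rows" if df.shape[0] >= df.shape[1] else "chemicals_rows"
            )
        log.info("delta-matrix orientation auto-detected: %s", orientation)
    if orientation == "chemicals_rows":
        df = df.T
    feature_ids = list(df.index)
    chemical_ids = list(df.columns)
    if len(set(feature_ids)) != len(feature_ids):
        raise ValueError(f"{path}: duplicated feature ids")
    if len(set(chemical_ids)) != len(chemical_ids):
        raise ValueError(f"{path}: duplicated chemical ids")
    kinds = {
        f: FeatureKind.FRACTION if f in fraction_features else FeatureKind.LOG_RATIO
        for f in feature_ids
    }
    return DeltaMatrix(
        feature_ids=feature_ids,
        chemical_ids=chemical_ids,
        values=df.to_numpy(dtype=float),
        feature_kind=kinds,
    )
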