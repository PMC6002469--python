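"""Chemical-level profiling of the Δmax matrix.

Bioactivity calls (a chemical is bioactive when at least 30% change is
seen in at least 5% of the measured features), feature-variability
filtering by unscaled median absolute deviation, and Ward hierarchical
clustering of chemicals or features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .datatypes import DeltaMatrix, FeatureKind

__all__ = ["BioactivityCall", "call_bioactivity", "mad_filter", "cluster_ward"]

#: Fold-change magnitude counted as a "change" (30%).
FOLD_CHANGE = 1.3
#: Fraction of features that must change for a bioactivity call (5%).
BIOACTIVE_FRACTION = 0.05


@dataclass(frozen=True)
class BioactivityCall:
    chemical_id: str
    n_changed_features: int
    n_features_total: int
    bioactive: bool


def _changed_mask(
    matrix: DeltaMatrix, scale: str = "ratio"
) -> np.ndarray:
    """Boolean features × chemicals mask of ≥ 30% changes.

    On the default ratio scale a 30% change means a treated/control ratio
    ≥ 1.3 (increase) or ≤ 0.7 (decrease), each direction on its own ratio
    bound: Δ ≥ log2(1.3) or Δ ≤ log2(0.7). Fraction features change when
    |Δ − 1| ≥ 0.3. ``scale="log2"`` applies |Δ| ≥ 0.3 directly to
    log-ratio features instead — a sensitivity-analysis variant.
    """
    up = np.log2(FOLD_CHANGE)
    down = np.log2(1.0 - (FOLD_CHANGE - 1.0))
    mask = np.zeros(matrix.values.shape, dtype=bool)
    for i, fid in enumerate(matrix.feature_ids):
        row = matrix.values[i]
        if matrix.feature_kind[fid] is FeatureKind.FRACTION:
            mask[i] = np.abs(row - 1.0) >= FOLD_CHANGE - 1.0
        elif scale == "log2":
            mask[i] = np.abs(row) >= FOLD_CHANGE - 1.0
        else:
            mask[i] = (row >= up) | (row <= down)
    return mask


def call_bioactivity(
    matrix: DeltaMatrix,
    exclude_nc: list[str] | tuple[str, ...] = (),
    scale: str = "ratio",
) -> list[BioactivityCall]:
    """Bioactivity calls over the matrix's chemicals, NC chemicals excluded.

    The denominator is the full measured-feature panel (phenotypic
    features plus cell count).
    """
    if matrix.values.size == 0:
        raise ValueError("empty matrix")
    mask = _changed_mask(matrix, scale)
    n_total = len(matrix.feature_ids)
    calls = []
    for j, chem in enumerate(matrix.chemical_ids):
        if chem in exclude_nc:
            continue
        n_changed = int(mask[:, j].sum())
        calls.append(
            BioactivityCall(
                chemical_id=chem,
                n_changed_features=n_changed,
                n_features_total=n_total,
                bioactive=n_changed / n_total >= BIOACTIVE_FRACTION,
            )
        )
    return calls


def mad_filter(matrix: DeltaMatrix, threshold: float = 0.05) -> DeltaMatrix:
    """Keep features whose unscaled MAD across chemicals exceeds ``threshold``.

    MAD here is median(|Δ − median(Δ)|) with no 1.4826 consistency
    constant; the conventional 0.05 cut is on the raw Δ scale.
    """
    if len(matrix.chemical_ids) < 2:
        raise ValueError("need >= 2 chemicals")
    med = np.median(matrix.values, axis=1, keepdims=True)
    mad = np.median(np.abs(matrix.values - med), axis=1)
    keep = mad > threshold
    kept_ids = [f for f, k in zip(matrix.feature_ids, keep) if k]
    return DeltaMatrix(
        feature_ids=kept_ids,
        chemical_ids=list(matrix.chemical_ids),
        values=matrix.values[keep].copy(),
        feature_kind={f: matrix.feature_kind[f] for f in kept_ids},
    )


def cluster_ward(
    matrix: DeltaMatrix, axis: str = "chemicals"
) -> tuple[np.ndarray, list[str]]:
    """Ward agglomerative clustering on Euclidean distances.

    Returns the scipy linkage matrix (merge list with heights) and the
    dendrogram leaf order as ids. Items are presented to the linkage in
    sorted-id order, which fixes the smallest-index tie-break and makes
    the dendrogram invariant to input ordering.
    """
    if axis == "chemicals":
        ids = list(matrix.chemical_ids)
        data = matrix.values.T
    elif axis == "features":
        ids = list(matrix.feature_ids)
        data = matrix.values
    else:
        raise ValueError(f"axis must be 'chemicals' or 'features', got {axis!r}")
    if len(ids) < 2:
        raise ValueError("need >= 2 items to cluster")
    order = np.argsort(np.array(ids, dtype=object))
    ids_sorted = [ids[i] for i in order]
    Z = linkage(pdist(data[order], metric="euclidean"), method="ward")
    leaf_ids = [ids_sorted[i] for i in leaves_list(Z)]
    return Z, leaf_ids
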