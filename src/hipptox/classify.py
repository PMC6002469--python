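"""Cascade pulmonotoxicity classifier and its evaluation protocol.

The cascade applies two rules in succession (cell count first):

1. *No-cell (NC) rule* — a chemical whose relative cell count stays
   below 30% of the solvent control at every tested concentration at or
   above 125 µM is called positive outright.
2. *Maximum-margin rule* — remaining chemicals are classified by a
   linear support-vector machine on the selected feature(s), with each
   feature linearly rescaled to [−1, 1] using training-set extremes and
   the misclassification cost C chosen from {10^0 … 10^5} by an inner
   stratified 5-fold grid search.

Performance is estimated with stratified tenfold cross-validation;
sensitivity is computed over the pulmonotoxic class, specificity over
the non-pulmonotoxic class, and balanced accuracy is their mean. NC
chemicals take part in cross-validation as unconditional positive
predictions and never enter margin training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import LinearSVC

from .datatypes import DeltaMatrix

__all__ = [
    "NCRuleParams",
    "CascadeModel",
    "CVResult",
    "call_nc",
    "fit_feature_scaler",
    "apply_scaler",
    "train_cascade",
    "predict_cascade",
    "crossvalidate_feature",
    "crossvalidate_features",
    "screen_features",
    "select_multifeature_rfe",
    "compute_metrics",
]

C_GRID_DEFAULT = (1.0, 1e1, 1e2, 1e3, 1e4, 1e5)


@dataclass(frozen=True)
class NCRuleParams:
    count_threshold: float = 0.30
    concentration_floor: float = 125.0

    def __post_init__(self) -> None:
        if not 0.0 < self.count_threshold < 1.0:
            raise ValueError("count_threshold must be in (0, 1)")


def call_nc(relative_counts: dict[float, float], params: NCRuleParams = NCRuleParams()) -> bool:
    """True iff relative cell count < threshold at *every* dose ≥ the floor."""
    tested = {x: f for x, f in relative_counts.items() if x >= params.concentration_floor}
    if not tested:
        raise ValueError(
            f"no tested concentrations at or above {params.concentration_floor} µM"
        )
    return all(f < params.count_threshold for f in tested.values())


# ---------------------------------------------------------------------------
# feature scaling


def fit_feature_scaler(values) -> tuple[float, float]:
    """Training-set (min, max) of one feature; constant features map to 0."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no training values")
    return float(values.min()), float(values.max())


def apply_scaler(scaler: tuple[float, float], value):
    """Linear map sending [train min, train max] → [−1, 1], unclamped.

    A degenerate (constant-feature) scaler maps everything to 0.
    """
    lo, hi = scaler
    value = np.asarray(value, dtype=float)
    if hi <= lo:
        return np.zeros_like(value)
    return 2.0 * (value - lo) / (hi - lo) - 1.0


# ---------------------------------------------------------------------------
# cascade model


@dataclass
class CascadeModel:
    nc_params: NCRuleParams
    feature_ids: list[str]
    scaler: dict[str, tuple[float, float]]
    weights: np.ndarray
    bias: float
    C: float

    def decision_value(self, feature_values: dict[str, float]) -> float:
        x = np.array(
            [
                apply_scaler(self.scaler[f], feature_values[f])
                for f in self.feature_ids
            ],
            dtype=float,
        )
        return float(self.weights @ x + self.bias)


def _stratified_folds(
    chems: list[str], labels: dict[str, bool], n_folds: int, seed: int
) -> dict[str, int]:
    """Deterministic stratified fold assignment.

    Chemicals are shuffled within class by the seed and dealt round-robin
    to the folds, so class proportions are as even as 13/20-style counts
    allow.
    """
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    for cls in (True, False):
        members = sorted(c for c in chems if labels[c] is cls)
        rng.shuffle(members)
        for i, c in enumerate(members):
            assignment[c] = i % n_folds
    return assignment


def _fit_svm(X: np.ndarray, y: np.ndarray, C: float) -> LinearSVC:
    # liblinear with an L2-regularized bias term (bias-as-augmented-feature
    # semantics); deterministic given the data
    clf = LinearSVC(C=C, max_iter=20000, random_state=0, dual=False, tol=1e-6)
    clf.fit(X, y)
    return clf


def train_cascade(
    matrix: DeltaMatrix,
    labels: dict[str, bool],
    feature_ids: list[str],
    nc_flags: dict[str, bool],
    C_grid: tuple[float, ...] = C_GRID_DEFAULT,
    seed: int = 0,
    nc_params: NCRuleParams = NCRuleParams(),
    inner_folds: int = 5,
) -> CascadeModel:
    """Train the cascade on labelled training chemicals.

    NC-flagged chemicals are excluded from margin training (the NC rule
    already assigns them positive). The cost C is chosen by an inner
    stratified cross-validation on the training chemicals (pooled
    balanced accuracy; ties to the smallest C), then the winner is refit
    on all non-NC training chemicals. Scaler coefficients come from
    training data only.
    """
    train_chems = [c for c in matrix.chemical_ids if c in labels and not nc_flags.get(c, False)]
    n_pos = sum(labels[c] for c in train_chems)
    n_neg = len(train_chems) - n_pos
    if n_pos < 2 or n_neg < 2:
        raise ValueError(
            f"need >= 2 training chemicals per class after NC exclusion "
            f"(got {n_pos} positive, {n_neg} negative)"
        )
    raw = {
        c: {f: float(matrix.values[matrix.feature_ids.index(f), matrix.chemical_ids.index(c)]) for f in feature_ids}
        for c in train_chems
    }
    y_all = {c: int(labels[c]) for c in train_chems}

    k = min(inner_folds, n_pos, n_neg)
    best_C = None
    best_score = -np.inf
    if k >= 2 and len(C_grid) > 1:
        folds = _stratified_folds(train_chems, labels, k, seed)
        for C in sorted(C_grid):
            preds: dict[str, bool] = {}
            for fold in range(k):
                tr = [c for c in train_chems if folds[c] != fold]
                te = [c for c in train_chems if folds[c] == fold]
                if len({y_all[c] for c in tr}) < 2 or not te:
                    continue
                scaler = {
                    f: fit_feature_scaler([raw[c][f] for c in tr]) for f in feature_ids
                }
                X_tr = np.array(
                    [[apply_scaler(scaler[f], raw[c][f]) for f in feature_ids] for c in tr]
                )
                clf = _fit_svm(X_tr, np.array([y_all[c] for c in tr]), C)
                X_te = np.array(
                    [[apply_scaler(scaler[f], raw[c][f]) for f in feature_ids] for c in te]
                )
                for c, d in zip(te, clf.decision_function(X_te)):
                    preds[c] = bool(d >= 0)
            if not preds:
                continue
            ba, _, _ = compute_metrics(preds, {c: labels[c] for c in preds})
            if ba > best_score + 1e-12:
                best_score, best_C = ba, C
    if best_C is None:
        best_C = sorted(C_grid)[0]

    scaler = {f: fit_feature_scaler([raw[c][f] for c in train_chems]) for f in feature_ids}
    X = np.array(
        [[apply_scaler(scaler[f], raw[c][f]) for f in feature_ids] for c in train_chems]
    )
    clf = _fit_svm(X, np.array([y_all[c] for c in train_chems]), best_C)
    return CascadeModel(
        nc_params=nc_params,
        feature_ids=list(feature_ids),
        scaler=scaler,
        weights=np.asarray(clf.coef_, dtype=float).ravel(),
        bias=float(clf.intercept_[0]),
        C=float(best_C),
    )


def predict_cascade(
    model: CascadeModel, feature_values: dict[str, float], nc_flag: bool
) -> bool:
    """Cascade prediction: NC wins; otherwise sign of the margin rule.

    A decision value of exactly 0 is called positive — at the boundary
    the screen favours sensitivity.
    """
    if nc_flag:
        return True
    missing = [f for f in model.feature_ids if f not in feature_values]
    if missing:
        raise KeyError(f"missing feature value(s) for prediction: {missing}")
    return model.decision_value(feature_values) >= 0


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CVResult:
    feature_ids: list[str]
    fold_assignments: dict[str, int]
    predictions: dict[str, bool]
    balanced_accuracy: float  # %
    sensitivity: float  # %
    specificity: float  # %
    per_fold_C: list[float] = field(default_factory=list)
    repeats: int = 1


def crossvalidate_features(
    matrix: DeltaMatrix,
    labels: dict[str, bool],
    nc_flags: dict[str, bool],
    feature_ids: list[str],
    folds: int = 10,
    seed: int = 0,
    repeats: int = 1,
    C_grid: tuple[float, ...] = C_GRID_DEFAULT,
    nc_params: NCRuleParams = NCRuleParams(),
) -> CVResult:
    """Stratified k-fold cross-validation of the cascade on a feature set.

    NC chemicals are predicted positive in whatever fold they land in and
    are excluded from every training set. ``repeats > 1`` averages the
    three metrics over independent fold seeds (derived from ``seed``).
    """
    chems = [c for c in matrix.chemical_ids if c in labels]
    n_pos = sum(labels[c] for c in chems)
    n_neg = len(chems) - n_pos
    if min(n_pos, n_neg) < 1 or folds > len(chems):
        raise ValueError("infeasible fold configuration for the given labels")
    metrics = []
    last: CVResult | None = None
    for rep in range(repeats):
        rep_seed = seed + 7919 * rep
        assignment = _stratified_folds(chems, labels, folds, rep_seed)
        predictions: dict[str, bool] = {}
        per_fold_C: list[float] = []
        for fold in range(folds):
            held_out = [c for c in chems if assignment[c] == fold]
            if not held_out:
                continue
            train = [c for c in chems if assignment[c] != fold]
            sub = matrix.subset_chemicals(
                [c for c in matrix.chemical_ids if c in train]
            )
            model = train_cascade(
                sub,
                {c: labels[c] for c in train},
                feature_ids,
                nc_flags,
                C_grid=C_grid,
                seed=rep_seed + fold,
                nc_params=nc_params,
            )
            per_fold_C.append(model.C)
            for c in held_out:
                values = {
                    f: float(
                        matrix.values[
                            matrix.feature_ids.index(f), matrix.chemical_ids.index(c)
                        ]
                    )
                    for f in feature_ids
                }
                predictions[c] = predict_cascade(
                    model, values, nc_flags.get(c, False)
                )
        ba, sens, spec = compute_metrics(predictions, {c: labels[c] for c in chems})
        metrics.append((ba, sens, spec))
        last = CVResult(
            feature_ids=list(feature_ids),
            fold_assignments=assignment,
            predictions=predictions,
            balanced_accuracy=ba,
            sensitivity=sens,
            specificity=spec,
            per_fold_C=per_fold_C,
            repeats=repeats,
        )
    mean = np.mean(np.array(metrics), axis=0)
    assert last is not None
    last.balanced_accuracy, last.sensitivity, last.specificity = (
        float(mean[0]),
        float(mean[1]),
        float(mean[2]),
    )
    return last


def crossvalidate_feature(
    matrix: DeltaMatrix,
    labels: dict[str, bool],
    nc_flags: dict[str, bool],
    feature_id: str,
    folds: int = 10,
    seed: int = 0,
    repeats: int = 1,
    **kwargs,
) -> CVResult:
    """Single-feature wrapper around :func:`crossvalidate_features`."""
    return crossvalidate_features(
        matrix, labels, nc_flags, [feature_id], folds=folds, seed=seed,
        repeats=repeats, **kwargs,
    )


def screen_features(
    matrix: DeltaMatrix,
    labels: dict[str, bool],
    nc_flags: dict[str, bool],
    folds: int = 10,
    seed: int = 0,
    repeats: int = 1,
    feature_ids: list[str] | None = None,
) -> list[tuple[str, float, float, float]]:
    """Cross-validate every feature and rank by balanced accuracy.

    Returns (feature_id, balanced accuracy %, sensitivity %,
    specificity %) tuples sorted descending by balanced accuracy, ties by
    sensitivity then feature id.
    """
    if feature_ids is None:
        feature_ids = list(matrix.feature_ids)
    rows = []
    for fid in feature_ids:
        res = crossvalidate_feature(
            matrix, labels, nc_flags, fid, folds=folds, seed=seed, repeats=repeats
        )
        rows.append((fid, res.balanced_accuracy, res.sensitivity, res.specificity))
    rows.sort(key=lambda r: (-r[1], -r[2], r[0]))
    return rows


def select_multifeature_rfe(
    matrix: DeltaMatrix,
    labels: dict[str, bool],
    nc_flags: dict[str, bool],
    max_features: int,
    folds: int = 10,
    seed: int = 0,
) -> list[tuple[list[str], float]]:
    """Recursive feature elimination with per-set-size CV scores.

    Starting from all features (capped at ``max_features``), the linear
    classifier is refit on the non-NC labelled chemicals and the feature
    with the smallest absolute weight is dropped, recording the
    cross-validated balanced accuracy of each nested set. Returns
    (feature set, balanced accuracy %) from largest to smallest set.
    """
    current = list(matrix.feature_ids)[:max_features]
    out: list[tuple[list[str], float]] = []
    while current:
        res = crossvalidate_features(
            matrix, labels, nc_flags, current, folds=folds, seed=seed
        )
        out.append((list(current), res.balanced_accuracy))
        if len(current) == 1:
            break
        model = train_cascade(matrix, labels, current, nc_flags, seed=seed)
        drop = int(np.argmin(np.abs(model.weights)))
        current = [f for i, f in enumerate(current) if i != drop]
    return out


def compute_metrics(
    predictions: dict[str, bool], labels: dict[str, bool]
) -> tuple[float, float, float]:
    """(balanced accuracy, sensitivity, specificity), each in percent.

    Sensitivity = TP/(TP+FN) over the positive class, specificity =
    TN/(TN+FP) over the negative class; balanced accuracy is their mean.
    """
    missing = [c for c in labels if c not in predictions]
    if missing:
        raise ValueError(f"missing predictions for {missing[:5]}")
    tp = sum(1 for c, y in labels.items() if y and predictions[c])
    fn = sum(1 for c, y in labels.items() if y and not predictions[c])
    tn = sum(1 for c, y in labels.items() if not y and not predictions[c])
    fp = sum(1 for c, y in labels.items() if not y and predictions[c])
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("each class needs at least one labelled chemical")
    sens = 100.0 * tp / (tp + fn)
    spec = 100.0 * tn / (tn + fp)
    return (sens + spec) / 2.0, sens, spec
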