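"""Concentration–response modelling and maximum-response extraction.

For each (chemical, feature) pair the control-normalised response

    Δ(x) = log2(r̃(x) / r̃(0))        (phenotypic features)
    Δ(x) = r̃(x) / r̃(0)              (cell count and viability)

is computed from per-well medians, where r̃(x) is the median across all
wells treated at concentration x and r̃(0) the median across the
chemical's solvent-control wells. Three candidate models are fit by
least squares:

    up-sigmoid    Δ(x) = α − α / (1 + exp(β (log x − log γ)))
    down-sigmoid  Δ(x) = α′ / (1 + exp(−β′ (log x − log γ′)))
    null          Δ(x) = 0                               (log-ratio features)
    constant      Δ(x) = α″                              (fraction features)

The two sigmoids are the same log-logistic family; here the up model is
constrained to a non-negative plateau and the down model to a
non-positive plateau (for fraction features, a decay from plateau α′ ≥ 0
toward 0), so model kind encodes response direction. The best model is
selected by AIC and its value at the highest evaluation concentration
(2000 µM) is the pair's maximum response Δmax.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .datatypes import (
    CELL_COUNT_FEATURE,
    ChemicalAnnotation,
    ConcentrationResponse,
    DeltaMatrix,
    FeatureKind,
    ModelFit,
    ModelKind,
    WellRecord,
    WellRole,
)

__all__ = [
    "compute_delta",
    "fit_candidate_models",
    "aic",
    "select_model",
    "delta_max",
    "evaluate_model",
    "build_delta_matrix",
    "relative_cell_counts",
    "FitReport",
]

log = logging.getLogger(__name__)

#: Evaluation concentration for Δmax (highest sampled dose, µM).
X_EVAL_DEFAULT = 2000.0

_RSS_FLOOR = 1e-300  # keeps log(rss/m) finite for perfect fits
_BETA_MAX = 50.0


class DegenerateControlError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


class ModelSelectionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Δ(x) computation


def compute_delta(
    wells: list[WellRecord],
    chemical_id: str,
    feature_id: str,
    feature_kind: FeatureKind,
    solvent_controls: list[WellRecord] | None = None,
) -> ConcentrationResponse:
    """Control-normalised responses for one (chemical, feature) pair.

    Solvent-control wells may be supplied separately (shared controls per
    solvent); otherwise the chemical's own concentration-0 wells are used.
    Replicate wells at a concentration are pooled before the median.
    """
    treated: dict[float, list[float]] = {}
    controls: list[float] = []
    for r in wells:
        if r.feature_id != feature_id:
            continue
        if r.chemical_id == chemical_id and r.role is WellRole.TREATMENT:
            treated.setdefault(r.concentration, []).append(r.value)
        elif (
            solvent_controls is None
            and r.chemical_id == chemical_id
            and r.role is WellRole.SOLVENT_CONTROL
        ):
            controls.append(r.value)
    if solvent_controls is not None:
        controls = [
            r.value
            for r in solvent_controls
            if r.feature_id == feature_id and r.role is WellRole.SOLVENT_CONTROL
        ]
    if not controls:
        raise InsufficientDataError(
            f"no solvent-control wells for {chemical_id}/{feature_id}"
        )
    if len(treated) < 6:
        raise InsufficientDataError(
            f"{chemical_id}/{feature_id}: {len(treated)} concentrations, need >= 6"
        )
    baseline = float(np.median(controls))
    if baseline <= 0:
        raise DegenerateControlError(
            f"{chemical_id}/{feature_id}: control median {baseline} <= 0"
        )
    points = []
    for x in sorted(treated):
        r_x = float(np.median(treated[x]))
        if feature_kind is FeatureKind.LOG_RATIO:
            if r_x <= 0:
                raise DegenerateControlError(
                    f"{chemical_id}/{feature_id}: non-positive median at {x} µM"
                )
            delta = float(np.log2(r_x / baseline))
        else:
            delta = r_x / baseline
        points.append((float(x), delta))
    return ConcentrationResponse(
        chemical_id=chemical_id,
        feature_id=feature_id,
        feature_kind=feature_kind,
        baseline=baseline,
        points=points,
    )


# ---------------------------------------------------------------------------
# model evaluation


def evaluate_model(
    kind: ModelKind,
    params: tuple[float, ...],
    x,
    feature_kind: FeatureKind = FeatureKind.LOG_RATIO,
) -> np.ndarray:
    """Evaluate a candidate model's Δ(x) at concentrations ``x`` (µM)."""
    return model_curve(kind, params, x, feature_kind)


def _sigmoid_up(x: np.ndarray, plateau: float, slope: float, ec: float) -> np.ndarray:
    u = np.clip(slope * (np.log(x) - np.log(ec)), -700, 700)
    return plateau - plateau / (1.0 + np.exp(u))


def _sigmoid_down_log(x: np.ndarray, plateau: float, slope: float, ec: float) -> np.ndarray:
    # α′ / (1 + exp(−β′(log x − log γ′))): 0 → α′ (plateau ≤ 0 here)
    u = np.clip(-slope * (np.log(x) - np.log(ec)), -700, 700)
    return plateau / (1.0 + np.exp(u))


def _sigmoid_decay(x: np.ndarray, plateau: float, slope: float, ec: float) -> np.ndarray:
    # fraction-kind kill curve: α′ → 0 with increasing dose
    u = np.clip(slope * (np.log(x) - np.log(ec)), -700, 700)
    return plateau / (1.0 + np.exp(u))


def model2_curve(x, plateau: float, slope: float, ec: float) -> np.ndarray:
    """The down-model formula Δ = α′/(1+exp(−β′(log x − log γ′)))."""
    x = np.asarray(x, dtype=float)
    u = np.clip(-slope * (np.log(x) - np.log(ec)), -700, 700)
    return plateau / (1.0 + np.exp(u))


def model_curve(kind: ModelKind, params: tuple[float, ...], x, feature_kind: FeatureKind = FeatureKind.LOG_RATIO) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if kind is ModelKind.MODEL3_NULL:
        return np.zeros_like(x)
    if kind is ModelKind.CONSTANT:
        return np.full_like(x, params[0])
    plateau, slope, ec = params
    if kind is ModelKind.MODEL1_UP:
        return _sigmoid_up(x, plateau, slope, ec)
    if feature_kind is FeatureKind.FRACTION:
        return _sigmoid_decay(x, plateau, slope, ec)
    return _sigmoid_down_log(x, plateau, slope, ec)


# ---------------------------------------------------------------------------
# least-squares fitting


def _gamma_bounds(concs: np.ndarray) -> tuple[float, float]:
    return float(concs.min() / 20.0), float(concs.max() * 20.0)


def _fit_sigmoid(
    concs: np.ndarray,
    deltas: np.ndarray,
    curve,
    plateau_bounds: tuple[float, float],
    sign: float = 1.0,
) -> tuple[tuple[float, float, float], np.ndarray, float, bool]:
    """Bounded least squares with deterministic multi-start.

    For fixed (β, γ) the model is linear in the plateau, so a coarse grid
    over (β, log γ) with the analytic plateau supplies the starting
    points; the best grid points are refined with ``least_squares``.
    """
    lo_g, hi_g = _gamma_bounds(concs)
    betas = np.array([0.5, 1.0, 2.0, 4.0, 8.0, 16.0])
    gammas = np.exp(np.linspace(np.log(lo_g), np.log(hi_g), 12))
    # vectorized grid: unit-plateau curves for every (β, γ), analytic plateau
    bb, gg = np.meshgrid(betas, gammas, indexing="ij")
    bases = curve(concs[None, :], 1.0, bb.reshape(-1, 1), gg.reshape(-1, 1))
    denom = np.einsum("ij,ij->i", bases, bases)
    valid = denom > 1e-12
    alphas = np.zeros(len(denom))
    alphas[valid] = (bases[valid] @ deltas) / denom[valid]
    alphas = np.clip(alphas, plateau_bounds[0], plateau_bounds[1])
    resid_grid = alphas[:, None] * bases - deltas[None, :]
    rss_grid = np.einsum("ij,ij->i", resid_grid, resid_grid)
    rss_grid[~valid] = np.inf
    order = np.argsort(rss_grid)
    starts = [
        (float(rss_grid[i]), float(alphas[i]), float(bb.ravel()[i]), float(gg.ravel()[i]))
        for i in order[:2]
        if np.isfinite(rss_grid[i])
    ]
    # optimize in (plateau, β, ln γ): log-γ keeps the problem conditioned
    # when the inflection sits outside the tested range. All branches are
    # a·σ(±β(ln x − ln γ)), so the Jacobian is analytic.
    lower = np.array([plateau_bounds[0], 1e-6, np.log(lo_g)])
    upper = np.array([plateau_bounds[1], _BETA_MAX, np.log(hi_g)])
    logx = np.log(concs)

    def residual(p):
        return curve(concs, p[0], p[1], np.exp(p[2])) - deltas

    def jacobian(p):
        a, b, t = p
        u = np.clip(sign * b * (logx - t), -700, 700)
        z = 1.0 / (1.0 + np.exp(-u))
        zz = z * (1.0 - z)
        return np.column_stack(
            [z, a * zz * sign * (logx - t), -a * zz * sign * b]
        )

    best = None
    for _, a, b, g in starts:
        x0 = np.clip([a if abs(a) > 1e-9 else 1e-6, b, np.log(g)], lower, upper)
        try:
            sol = least_squares(
                residual, x0, jac=jacobian, bounds=(lower, upper),
                xtol=1e-11, ftol=1e-11, max_nfev=40,
            )
            # fits that hit the budget while still improving materially
            # (flat-valley curves converging to near-zero rss) get more
            # rounds; noisy fits stuck polishing the last fraction of a
            # percent do not
            rounds, prev = 0, np.inf
            while sol.status == 0 and rounds < 8:
                rss_now = float(sol.fun @ sol.fun)
                if not (rss_now < 1e-4 or rss_now < 0.99 * prev):
                    break
                prev = rss_now
                sol = least_squares(
                    residual, sol.x, jac=jacobian, bounds=(lower, upper),
                    xtol=1e-11, ftol=1e-11, max_nfev=60,
                )
                rounds += 1
        except Exception:  # noqa: BLE001 — optimizer failure flagged, not raised
            continue
        rss = float(sol.fun @ sol.fun)
        if best is None or rss < best[2]:
            params = (float(sol.x[0]), float(sol.x[1]), float(np.exp(sol.x[2])))
            best = (params, sol.fun.copy(), rss)
    if best is None:
        # all refinements failed: fall back to best grid point
        if not starts:
            return (0.0, 1.0, float(np.median(concs))), deltas.copy(), float(
                deltas @ deltas
            ), False
        rss0, a, b, g = starts[0]
        resid = curve(concs, a, b, g) - deltas
        return (a, b, g), resid, rss0, False
    params, resid, rss = best
    return params, resid, rss, True


def fit_candidate_models(cr: ConcentrationResponse) -> list[ModelFit]:
    """Fit all candidate models for one concentration–response series.

    Log-ratio features get the up-sigmoid, the down-sigmoid and the null
    model; fraction features get the decay sigmoid and the constant model
    (the up model is not used and the null model is replaced). A model
    whose optimizer fails on every start is returned with
    ``converged=False`` rather than dropped.
    """
    concs = cr.concentrations
    deltas = cr.deltas
    m = len(concs)
    fits: list[ModelFit] = []
    big = float(max(10.0, 5 * np.max(np.abs(deltas)) + 10.0))

    if cr.feature_kind is FeatureKind.LOG_RATIO:
        params, resid, rss, ok = _fit_sigmoid(concs, deltas, _sigmoid_up, (0.0, big))
        fits.append(
            ModelFit(
                kind=ModelKind.MODEL1_UP,
                params=params,
                D=3,
                residuals=resid,
                m=m,
                rss=rss,
                converged=ok,
            )
        )
        params, resid, rss, ok = _fit_sigmoid(
            concs, deltas, _sigmoid_down_log, (-big, 0.0)
        )
        fits.append(
            ModelFit(
                kind=ModelKind.MODEL2_DOWN,
                params=params,
                D=3,
                residuals=resid,
                m=m,
                rss=rss,
                converged=ok,
            )
        )
        fits.append(
            ModelFit(
                kind=ModelKind.MODEL3_NULL,
                params=(),
                D=0,
                residuals=-deltas,
                m=m,
                rss=float(deltas @ deltas),
            )
        )
    else:
        params, resid, rss, ok = _fit_sigmoid(
            concs, deltas, _sigmoid_decay, (0.0, big), sign=-1.0
        )
        fits.append(
            ModelFit(
                kind=ModelKind.MODEL2_DOWN,
                params=params,
                D=3,
                residuals=resid,
                m=m,
                rss=rss,
                converged=ok,
            )
        )
        a2 = float(np.mean(deltas))
        resid = a2 - deltas
        fits.append(
            ModelFit(
                kind=ModelKind.CONSTANT,
                params=(a2,),
                D=1,
                residuals=resid,
                m=m,
                rss=float(resid @ resid),
            )
        )
    for f in fits:
        f.aic = aic(f)
    return fits


# ---------------------------------------------------------------------------
# AIC and selection


def aic(fit: ModelFit, variant: str = "standard") -> float:
    """Akaike information criterion of a least-squares fit.

    ``standard``: m·ln(rss/m) + 2D — the Gaussian-likelihood AIC up to a
    constant; lower is better. ``as_printed``: 2(D − ln(rss/m)), a
    typographical variant retained for audit only (it rewards worse fits
    when minimized). rss/m is floored to keep the log finite.
    """
    ratio = max(fit.rss / fit.m, _RSS_FLOOR)
    if variant == "standard":
        return float(fit.m * np.log(ratio) + 2 * fit.D)
    if variant == "as_printed":
        return float(2.0 * (fit.D - np.log(ratio)))
    raise ValueError(f"unknown AIC variant {variant!r}")


_TIE_ORDER = {
    ModelKind.MODEL3_NULL: 0,
    ModelKind.CONSTANT: 1,
    ModelKind.MODEL2_DOWN: 2,
    ModelKind.MODEL1_UP: 3,
}


#: rss/m below this is numerically a perfect fit; such fits tie on AIC and
#: the smaller-D rule decides (a plateau-saturated sigmoid can reproduce a
#: constant to exactly 0 rss while the constant's own mean leaves ~1e-32).
_MACHINE_RSS = 1e-24


def select_model(fits: list[ModelFit], variant: str = "standard") -> ModelFit:
    """Pick the AIC-minimizing fit (best-fit-wins semantics).

    Ordering always uses the standard AIC form; ties — including
    numerical ties between perfect fits — go to the fit with fewer
    parameters, then to the null/constant model. Requires at least two
    converged fits.
    """
    usable = [f for f in fits if f.converged]
    if len(usable) < 2:
        raise ModelSelectionError("fewer than 2 successful fits")

    def order_key(item):
        i, f = item
        ratio = max(f.rss / f.m, _MACHINE_RSS)
        return (round(f.m * float(np.log(ratio)) + 2 * f.D, 9), f.D, _TIE_ORDER[f.kind], i)

    return min(enumerate(usable), key=order_key)[1]


def delta_max(
    fit: ModelFit,
    x_eval: float = X_EVAL_DEFAULT,
    feature_kind: FeatureKind = FeatureKind.LOG_RATIO,
) -> float:
    """Fitted-model response at the evaluation concentration (stored on the fit)."""
    value = float(model_curve(fit.kind, fit.params, np.array([x_eval]), feature_kind)[0])
    fit.delta_max = value
    return value


# ---------------------------------------------------------------------------
# matrix assembly


@dataclass
class FitReport:
    """Per-cell fit log produced by :func:`build_delta_matrix`."""

    selected_kind: dict[tuple[str, str], ModelKind] = field(default_factory=dict)
    params: dict[tuple[str, str], tuple[float, ...]] = field(default_factory=dict)
    rss: dict[tuple[str, str], float] = field(default_factory=dict)
    aic: dict[tuple[str, str], float] = field(default_factory=dict)
    extrapolated: list[tuple[str, str]] = field(default_factory=list)
    failures: dict[tuple[str, str], str] = field(default_factory=dict)


def build_delta_matrix(
    wells: list[WellRecord],
    annotations: list[ChemicalAnnotation],
    feature_ids: list[str] | None = None,
    variant: str = "standard",
    x_eval: float = X_EVAL_DEFAULT,
) -> tuple[DeltaMatrix, FitReport]:
    """Fit every (chemical, feature) pair and assemble the Δmax matrix.

    Chemicals whose top dose is below ``x_eval`` are evaluated by model
    extrapolation and flagged in the report. Per-cell failures are
    collected in the report; the matrix is only built when complete.
    """
    if feature_ids is None:
        feature_ids = sorted({r.feature_id for r in wells})
    chem_ids = [a.chemical_id for a in annotations]
    top_dose = {a.chemical_id: a.max_concentration for a in annotations}
    report = FitReport()
    values = np.full((len(feature_ids), len(chem_ids)), np.nan)

    # index wells once: (chemical, feature) -> treated; (chemical, feature) -> controls
    by_cell: dict[tuple[str, str], list[WellRecord]] = {}
    for r in sorted(wells, key=lambda w: (w.chemical_id, w.feature_id, w.concentration, w.well_id)):
        by_cell.setdefault((r.chemical_id, r.feature_id), []).append(r)

    for j, chem in enumerate(chem_ids):
        for i, feat in enumerate(feature_ids):
            kind = (
                FeatureKind.FRACTION
                if feat == CELL_COUNT_FEATURE
                else FeatureKind.LOG_RATIO
            )
            cell_wells = by_cell.get((chem, feat), [])
            try:
                cr = compute_delta(cell_wells, chem, feat, kind)
                fits = fit_candidate_models(cr)
                best = select_model(fits, variant)
                values[i, j] = delta_max(best, x_eval, kind)
            except Exception as exc:  # noqa: BLE001 — collected, reported together
                report.failures[(chem, feat)] = str(exc)
                continue
            report.selected_kind[(chem, feat)] = best.kind
            report.params[(chem, feat)] = best.params
            report.rss[(chem, feat)] = best.rss
            report.aic[(chem, feat)] = best.aic
            if top_dose.get(chem, x_eval) < x_eval:
                report.extrapolated.append((chem, feat))
    if report.failures:
        sample = list(report.failures.items())[:5]
        raise ModelSelectionError(
            f"{len(report.failures)} (chemical, feature) fits failed, e.g. {sample}"
        )
    kinds = {
        f: FeatureKind.FRACTION if f == CELL_COUNT_FEATURE else FeatureKind.LOG_RATIO
        for f in feature_ids
    }
    matrix = DeltaMatrix(
        feature_ids=list(feature_ids),
        chemical_ids=list(chem_ids),
        values=values,
        feature_kind=kinds,
    )
    return matrix, report


def relative_cell_counts(
    wells: list[WellRecord], chemical_id: str
) -> dict[float, float]:
    """Treated/control median cell-count fraction at each concentration."""
    cr = compute_delta(
        [w for w in wells if w.feature_id == CELL_COUNT_FEATURE],
        chemical_id,
        CELL_COUNT_FEATURE,
        FeatureKind.FRACTION,
    )
    return {x: d for x, d in cr.points}
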