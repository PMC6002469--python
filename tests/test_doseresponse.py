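"""Concentration-response computation, model fitting, AIC selection, Δmax."""

from __future__ import annotations

import numpy as np
import pytest

import hipptox as h
from hipptox.datatypes import FeatureKind, ModelKind, WellRecord, WellRole
from hipptox.doseresponse import (
    _sigmoid_down_log,
    _sigmoid_up,
    aic,
    fit_candidate_models,
    model_curve,
    select_model,
)

CONCS = np.array([2000.0, 1000.0, 500.0, 250.0, 125.0, 62.5, 31.3])


def _wells(chem, feat, treated: dict, controls: list) -> list[WellRecord]:
    out = []
    for x, vals in treated.items():
        for i, v in enumerate(vals):
            out.append(
                WellRecord("p", f"{chem}{x}_{i}", chem, x, WellRole.TREATMENT, feat, v)
            )
    for i, v in enumerate(controls):
        out.append(
            WellRecord("p", f"{chem}c{i}", chem, 0.0, WellRole.SOLVENT_CONTROL, feat, v)
        )
    return out


class TestComputeDelta:
    def test_identity_response_gives_zero_delta(self):
        treated = {x: [100.0, 100.0] for x in CONCS}
        cr = h.compute_delta(
            _wells("a", "f", treated, [100.0] * 3), "a", "f", FeatureKind.LOG_RATIO
        )
        assert np.allclose(cr.deltas, 0.0)

    def test_hand_median_log_oracle(self):
        # treated median 25, control median 100 → Δ = log2(25/100) = −2
        treated = {x: [25.0, 25.0, 27.0, 23.0] for x in CONCS}
        cr = h.compute_delta(
            _wells("a", "f", treated, [90.0, 100.0, 110.0]),
            "a",
            "f",
            FeatureKind.LOG_RATIO,
        )
        assert np.allclose(cr.deltas, -2.0)
        assert cr.baseline == 100.0

    def test_fraction_kind_is_untransformed(self):
        treated = {x: [50.0] for x in CONCS}
        cr = h.compute_delta(
            _wells("a", "cell_count", treated, [100.0]),
            "a",
            "cell_count",
            FeatureKind.FRACTION,
        )
        assert np.allclose(cr.deltas, 0.5)

    def test_errors_on_degenerate_control_and_sparse_data(self):
        treated = {x: [50.0] for x in CONCS}
        with pytest.raises(ValueError, match="control"):
            h.compute_delta(
                _wells("a", "f", treated, [0.0]), "a", "f", FeatureKind.LOG_RATIO
            )
        few = {x: [50.0] for x in CONCS[:4]}
        with pytest.raises(ValueError, match="concentrations"):
            h.compute_delta(
                _wells("a", "f", few, [100.0]), "a", "f", FeatureKind.LOG_RATIO
            )


def _cr_from_deltas(deltas, kind=FeatureKind.LOG_RATIO):
    return h.ConcentrationResponse(
        chemical_id="a",
        feature_id="f",
        feature_kind=kind,
        baseline=100.0,
        points=list(zip(CONCS.tolist(), np.asarray(deltas, dtype=float).tolist())),
    )


class TestFitting:
    def test_null_data_gives_zero_rss_null_model(self):
        fits = fit_candidate_models(_cr_from_deltas(np.zeros(7)))
        null = next(f for f in fits if f.kind is ModelKind.MODEL3_NULL)
        assert null.rss == 0.0
        assert select_model(fits).kind is ModelKind.MODEL3_NULL

    def test_noiseless_sigmoid_parameters_recovered(self):
        # the printed down-model formula with a positive plateau is an
        # increasing curve; the up model recovers the same parameters
        deltas = h.model2_curve(CONCS, 1.5, 2.0, 250.0)
        fits = fit_candidate_models(_cr_from_deltas(deltas))
        best = select_model(fits)
        assert best.kind is ModelKind.MODEL1_UP
        np.testing.assert_allclose(best.params, (1.5, 2.0, 250.0), rtol=1e-3)
        # a genuinely downward curve is recovered by the down model
        deltas = _sigmoid_down_log(CONCS, -1.2, 3.0, 400.0)
        best = select_model(fit_candidate_models(_cr_from_deltas(deltas)))
        assert best.kind is ModelKind.MODEL2_DOWN
        np.testing.assert_allclose(best.params, (-1.2, 3.0, 400.0), rtol=1e-3)

    def test_constant_offset_fit_by_sigmoid_plateau(self):
        # noiseless Δ ≡ 0.8 (log-ratio): the sigmoid reaches its plateau
        # well below the tested range and attains rss ≈ 0
        fits = fit_candidate_models(_cr_from_deltas(np.full(7, 0.8)))
        up = next(f for f in fits if f.kind is ModelKind.MODEL1_UP)
        assert up.rss < 1e-10

    def test_fraction_features_use_decay_and_constant_models(self):
        deltas = model_curve(
            ModelKind.MODEL2_DOWN, (1.0, 4.0, 200.0), CONCS, FeatureKind.FRACTION
        )
        fits = fit_candidate_models(_cr_from_deltas(deltas, FeatureKind.FRACTION))
        assert {f.kind for f in fits} == {ModelKind.MODEL2_DOWN, ModelKind.CONSTANT}
        best = select_model(fits)
        assert best.kind is ModelKind.MODEL2_DOWN
        np.testing.assert_allclose(best.params, (1.0, 4.0, 200.0), rtol=1e-3)

    def test_least_squares_beats_dense_grid_oracle(self):
        # brute-force grid over (α, β, γ) as the independent optimum bound
        rng = np.random.default_rng(0)
        deltas = _sigmoid_up(CONCS, 1.1, 2.7, 300.0) + rng.normal(0, 0.05, 7)
        fits = fit_candidate_models(_cr_from_deltas(deltas))
        up = next(f for f in fits if f.kind is ModelKind.MODEL1_UP)
        alphas = np.linspace(0.0, 3.0, 40)
        betas = np.linspace(0.5, 10.0, 40)
        gammas = np.exp(np.linspace(np.log(31.3 / 20), np.log(2000 * 20), 60))
        best_grid = np.inf
        for a in alphas:
            for b in betas:
                resid = a * _sigmoid_up(CONCS, 1.0, b, gammas[:, None]).T - deltas[:, None]
                best_grid = min(best_grid, float(np.min(np.sum(resid**2, axis=0))))
        assert up.rss <= best_grid + 1e-9

    def test_refined_fit_never_worse_than_grid_start(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            deltas = rng.normal(0, 0.6, 7)
            fits = fit_candidate_models(_cr_from_deltas(deltas))
            for f in fits:
                if f.kind is ModelKind.MODEL3_NULL:
                    continue
                # the sigmoids must fit at least as well as the flat curve
                # at their own plateau limit (best-so-far monotone)
                assert f.rss <= float(deltas @ deltas) + 1e-9


class TestAIC:
    def test_closed_forms(self):
        fit = h.ModelFit(
            kind=ModelKind.MODEL1_UP,
            params=(1, 1, 1),
            D=3,
            residuals=np.ones(7),
            m=7,
            rss=7.0,
        )
        assert aic(fit) == pytest.approx(6.0)  # ln(rss/m)=0 → 2D
        fit.rss, fit.residuals = 0.04, np.full(7, np.sqrt(0.04 / 7))
        fit = h.ModelFit(
            kind=ModelKind.MODEL1_UP,
            params=(1, 1, 1),
            D=3,
            residuals=np.full(7, np.sqrt(0.04 / 7)),
            m=7,
            rss=0.04,
        )
        assert aic(fit) == pytest.approx(7 * np.log(0.04 / 7) + 6)
        assert aic(fit, "as_printed") == pytest.approx(2 * (3 - np.log(0.04 / 7)))

    def test_monotone_in_rss_at_fixed_D(self):
        def mk(rss):
            r = np.sqrt(rss / 7)
            return h.ModelFit(
                kind=ModelKind.MODEL1_UP,
                params=(1, 1, 1),
                D=3,
                residuals=np.full(7, r),
                m=7,
                rss=rss,
            )

        assert aic(mk(0.01)) < aic(mk(0.02))

    def test_zero_rss_is_floored_finite(self):
        fit = h.ModelFit(
            kind=ModelKind.MODEL3_NULL, params=(), D=0, residuals=np.zeros(7), m=7, rss=0.0
        )
        assert np.isfinite(aic(fit))


class TestSelection:
    def test_tie_breaks_toward_fewer_parameters(self):
        resid = np.zeros(7)
        sig = h.ModelFit(
            kind=ModelKind.MODEL1_UP, params=(0.0, 1, 100), D=3, residuals=resid, m=7, rss=0.0
        )
        null = h.ModelFit(
            kind=ModelKind.MODEL3_NULL, params=(), D=0, residuals=resid, m=7, rss=0.0
        )
        assert select_model([sig, null]).kind is ModelKind.MODEL3_NULL

    def test_selection_needs_two_converged_fits(self):
        only = h.ModelFit(
            kind=ModelKind.MODEL3_NULL, params=(), D=0, residuals=np.zeros(7), m=7, rss=0.0
        )
        with pytest.raises(ValueError):
            select_model([only])


class TestDeltaMax:
    def test_null_model_is_zero_everywhere(self):
        fit = h.ModelFit(
            kind=ModelKind.MODEL3_NULL, params=(), D=0, residuals=np.zeros(7), m=7, rss=0.0
        )
        assert h.delta_max(fit, 2000.0) == 0.0
        assert h.delta_max(fit, 123.0) == 0.0

    def test_closed_form_at_2000(self):
        # α′/(1+(2000/250)^−2) with α′=1.5 → 96/65
        assert h.model2_curve(2000.0, 1.5, 2.0, 250.0) == pytest.approx(96 / 65, rel=1e-12)

    def test_logistic_midpoint_symmetry(self):
        # at x = γ the up model sits at half its plateau: α − α/2
        fit = h.ModelFit(
            kind=ModelKind.MODEL1_UP,
            params=(2.0, 3.0, 500.0),
            D=3,
            residuals=np.zeros(7),
            m=7,
            rss=0.0,
        )
        assert h.delta_max(fit, 500.0) == pytest.approx(1.0, rel=1e-12)

    def test_up_model_delta_max_bounded_by_plateau(self):
        for a in (0.5, 1.5, 3.0):
            fit = h.ModelFit(
                kind=ModelKind.MODEL1_UP,
                params=(a, 2.0, 250.0),
                D=3,
                residuals=np.zeros(7),
                m=7,
                rss=0.0,
            )
            val = h.delta_max(fit, 2000.0)
            assert 0.0 <= val <= a


class TestBuildMatrix:
    def test_matrix_matches_ground_truth(self, noiseless_study, noiseless_matrix):
        _, wells, annotations, truth = noiseless_study
        matrix, report = noiseless_matrix
        assert matrix.shape == (8, 14)
        for i, f in enumerate(matrix.feature_ids):
            for j, c in enumerate(matrix.chemical_ids):
                expected = truth.delta_at(c, f, 2000.0)
                assert matrix.values[i, j] == pytest.approx(expected, abs=2e-3)

    def test_row_order_invariance(self, noiseless_study):
        _, wells, annotations, _ = noiseless_study
        m1, _ = h.build_delta_matrix(wells, annotations)
        m2, _ = h.build_delta_matrix(list(reversed(wells)), annotations)
        np.testing.assert_allclose(m1.values, m2.values, rtol=1e-9)

    def test_extrapolation_flagged_for_low_top_dose(self):
        cfg = h.SimulationConfig(
            n_chemicals_per_class={"pulmonotoxic": 2, "non_pulmonotoxic": 2, "test": 0},
            n_features=3,
            noise_sd=0.0,
            nc_chemical_ids=(),
            low_dose_chemical_ids=("tox_01",),
            seed=2,
        )
        wells, annotations, _ = h.simulate_study(cfg)
        _, report = h.build_delta_matrix(wells, annotations)
        flagged_chems = {c for c, _ in report.extrapolated}
        assert flagged_chems == {"tox_01"}
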