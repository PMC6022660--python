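"""Self-modelling regression: normalization, curves, shifts and the full fit."""

import numpy as np
import pandas as pd
import pytest

from dpscore import (
    LongitudinalDataset,
    ProgressionConfig,
    ProgressionModel,
    SimulationConfig,
    dps_table,
    estimate_subject_linear_effects,
    estimate_time_shift,
    fit_monotone_curve,
    fit_progression_model,
    simulate_cohort,
    znormalize,
)
from dpscore.progression import SubjectTrajectoryParams, _best_shift


def make_dataset(rows):
    return LongitudinalDataset(pd.DataFrame(
        rows, columns=["subject_id", "biomarker_id", "time_years", "value"]))


def sigmoid(t):
    return 1.0 / (1.0 + np.exp(-np.asarray(t, float)))


@pytest.fixture(scope="module")
def sigmoid_curve():
    ts = np.linspace(-12, 12, 200)
    return fit_monotone_curve(np.column_stack([ts, sigmoid(ts)]), "increasing",
                              n_interior_knots=20, biomarker_id="b")


class TestZnormalize:
    def test_unit_controls_leave_values_unchanged(self):
        data = make_dataset([("c1", "b", 0.0, -1.0), ("c1", "b", 1.0, 0.0),
                             ("c2", "b", 0.0, 1.0), ("s", "b", 0.0, 2.0)])
        out, stats = znormalize(data, {"c1", "c2"})
        assert stats.mu["b"] == pytest.approx(0.0)
        assert stats.sigma["b"] == pytest.approx(1.0)
        pd.testing.assert_frame_equal(out.records, data.records)

    def test_control_midpoint_maps_to_zero(self):
        data = make_dataset([("c", "b", 0.0, 10.0), ("c", "b", 1.0, 20.0),
                             ("s", "b", 0.0, 15.0)])
        out, stats = znormalize(data, {"c"})
        assert stats.mu["b"] == pytest.approx(15.0)
        assert stats.sigma["b"] == pytest.approx(np.sqrt(50.0))
        s_val = out.records.loc[out.records.subject_id == "s", "value"].iloc[0]
        assert s_val == pytest.approx(0.0, abs=1e-12)

    def test_transformed_controls_have_zero_mean_unit_sd(self, rng):
        rows = [("c%d" % i, "b", t, rng.normal(5, 2))
                for i in range(10) for t in (0.0, 1.0)]
        rows += [("s", "b", 0.0, 1.0)]
        out, _ = znormalize(make_dataset(rows), {f"c{i}" for i in range(10)})
        ctrl = out.records[out.records.subject_id.str.startswith("c")]["value"]
        assert ctrl.mean() == pytest.approx(0.0, abs=1e-10)
        assert ctrl.std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_degenerate_controls_rejected(self):
        flat = make_dataset([("c", "b", 0.0, 1.0), ("c", "b", 1.0, 1.0)])
        with pytest.raises(ValueError, match="variance"):
            znormalize(flat, {"c"})
        with pytest.raises(ValueError, match="control ids"):
            znormalize(flat, {"nope"})


class TestMonotoneCurve:
    def test_noise_free_sigmoid_recovered(self):
        ts = np.linspace(-6, 6, 50)
        curve = fit_monotone_curve(np.column_stack([ts, sigmoid(ts)]), "increasing")
        assert np.max(np.abs(curve(ts) - sigmoid(ts))) < 0.01

    def test_constant_data_gives_constant_curve(self):
        ts = np.linspace(0, 5, 10)
        curve = fit_monotone_curve(np.column_stack([ts, np.full(10, 3.0)]), "increasing")
        assert np.allclose(curve(np.linspace(0, 5, 100)), 3.0, atol=1e-6)

    def test_wrong_direction_still_respects_constraint(self):
        ts = np.linspace(0, 5, 30)
        curve = fit_monotone_curve(np.column_stack([ts, ts]), "decreasing")
        vals = curve(np.linspace(0, 5, 1000))
        assert (np.diff(vals) <= 1e-10).all()

    def test_monotone_on_dense_grid(self):
        rng = np.random.default_rng(0)
        ts = np.sort(rng.uniform(-5, 5, 80))
        ys = sigmoid(ts) + rng.normal(0, 0.2, 80)
        curve = fit_monotone_curve(np.column_stack([ts, ys]), "increasing")
        vals = curve(np.linspace(*curve.support, 1000))
        assert (np.diff(vals) >= -1e-10).all()

    @pytest.mark.parametrize("points,direction,match", [
        ([(0, 1), (0, 2), (0, 3), (0, 4)], "increasing", "time range"),
        ([(0, 1), (1, 2), (2, 3)], "increasing", "at least 4"),
        ([(0, 1), (1, 2), (2, 3), (3, 4)], "sideways", "direction"),
    ])
    def test_invalid_inputs_rejected(self, points, direction, match):
        with pytest.raises(ValueError, match=match):
            fit_monotone_curve(points, direction)


class TestTimeShift:
    def test_exact_shift_recovered(self, sigmoid_curve):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        records = pd.DataFrame({"subject_id": "s", "biomarker_id": "b",
                                "time_years": t, "value": sigmoid_curve(t + 2.0)})
        gamma = estimate_time_shift(records, [sigmoid_curve], bounds=(-10, 10))
        assert gamma == pytest.approx(2.0, abs=1e-3)

    def test_flat_curve_tie_broken_to_smallest_shift(self):
        ts = np.linspace(0, 5, 10)
        flat = fit_monotone_curve(np.column_stack([ts, np.ones(10)]), "increasing")
        records = pd.DataFrame({"subject_id": "s", "biomarker_id": flat.biomarker_id,
                                "time_years": [0.0, 1.0], "value": [1.0, 1.0]})
        gamma = estimate_time_shift(records, {flat.biomarker_id: flat}, bounds=(-10, 10))
        assert gamma == pytest.approx(0.0, abs=1e-9)

    def test_matches_dense_grid_search(self, sigmoid_curve, rng):
        bounds = (-8.0, 8.0)
        dense = np.arange(bounds[0], bounds[1] + 1e-9, 1e-3)
        for _ in range(10):
            t = np.sort(rng.uniform(0, 4, 5))
            v = sigmoid_curve(t + rng.uniform(-6, 6)) + rng.normal(0, 0.1, 5)
            records = pd.DataFrame({"subject_id": "s", "biomarker_id": "b",
                                    "time_years": t, "value": v})
            est = estimate_time_shift(records, [sigmoid_curve], bounds=bounds)
            objs = ((v[:, None] - sigmoid_curve(t[:, None] + dense[None, :])) ** 2).sum(axis=0)
            assert abs(est - dense[np.argmin(objs)]) <= 2e-3

    def test_bad_inputs_rejected(self, sigmoid_curve):
        records = pd.DataFrame({"subject_id": "s", "biomarker_id": "other",
                                "time_years": [0.0], "value": [1.0]})
        with pytest.raises(ValueError, match="no records"):
            estimate_time_shift(records, [sigmoid_curve])
        with pytest.raises(ValueError, match="bounds"):
            estimate_time_shift(records, [sigmoid_curve], bounds=(5, -5))


class TestLinearEffects:
    def _records(self, t, v):
        return pd.DataFrame({"subject_id": "s", "biomarker_id": "b",
                             "time_years": t, "value": v})

    def test_constant_residual_goes_to_intercept(self, sigmoid_curve):
        t = np.array([0.0, 1.0, 2.0])
        v = sigmoid_curve(t) + 0.5
        eff = estimate_subject_linear_effects(self._records(t, v), [sigmoid_curve],
                                              gamma=0.0, ridge=0.0)
        a0, a1 = eff["b"]
        assert a0 == pytest.approx(0.5, abs=1e-9)
        assert a1 == pytest.approx(0.0, abs=1e-9)

    def test_linear_residual_goes_to_slope(self, sigmoid_curve):
        t = np.array([0.0, 1.0, 2.0])
        v = sigmoid_curve(t) + 0.1 * t
        eff = estimate_subject_linear_effects(self._records(t, v), [sigmoid_curve],
                                              gamma=0.0, ridge=0.0)
        assert eff["b"][1] == pytest.approx(0.1, abs=1e-9)

    def test_infinite_shrinkage_kills_effects(self, sigmoid_curve):
        t = np.array([0.0, 1.0, 2.0])
        v = sigmoid_curve(t) + 0.5 + 0.3 * t
        eff = estimate_subject_linear_effects(self._records(t, v), [sigmoid_curve],
                                              gamma=0.0, ridge=1e12)
        assert abs(eff["b"][0]) < 1e-9 and abs(eff["b"][1]) < 1e-9


@pytest.fixture(scope="module")
def fitted_small_cohort():
    cfg = SimulationConfig(n_subjects=80, noise_sd=0.15, alpha0_sd=0.1,
                           alpha1_sd=0.02, missing_rate=0.05, seed=21)
    data, truth, _ = simulate_cohort(cfg)
    model = fit_progression_model(data, config=ProgressionConfig(max_iter=120))
    return data, truth, model


class TestProgressionFit:
    def test_shift_recovery_on_small_cohort(self, fitted_small_cohort):
        _, truth, model = fitted_small_cohort
        est = model.gamma_series()
        true = truth.subjects.set_index("subject_id")["gamma"].loc[est.index]
        corr = np.corrcoef(est - est.mean(), true - true.mean())[0, 1]
        assert corr >= 0.9

    def test_objective_trace_non_increasing(self, fitted_small_cohort):
        _, _, model = fitted_small_cohort
        trace = np.asarray(model.objective_trace)
        assert (np.diff(trace) <= 1e-8).all()

    def test_gammas_centered(self, fitted_small_cohort):
        _, _, model = fitted_small_cohort
        assert abs(model.gamma_series().mean()) < 1e-6

    def test_fitted_curves_are_monotone(self, fitted_small_cohort):
        _, _, model = fitted_small_cohort
        for curve in model.curves.values():
            vals = curve(np.linspace(*curve.support, 1000))
            diffs = np.diff(vals)
            assert (diffs >= -1e-9).all() or (diffs <= 1e-9).all()

    def test_subject_missing_one_biomarker_still_scored(self):
        cfg = SimulationConfig(n_subjects=40, noise_sd=0.1, alpha0_sd=0.0,
                               alpha1_sd=0.0, missing_rate=0.0, seed=33)
        data, _, _ = simulate_cohort(cfg)
        drop = (data.records.subject_id == "S0000") & \
               (data.records.biomarker_id == "amyloid_suvr")
        pruned = LongitudinalDataset(data.records[~drop])
        model = fit_progression_model(pruned, config=ProgressionConfig(max_iter=40))
        assert "S0000" in model.gamma_series().index

    def test_shift_equivariance_under_time_translation(self):
        cfg = SimulationConfig(n_subjects=40, noise_sd=0.1, alpha0_sd=0.0,
                               alpha1_sd=0.0, missing_rate=0.0, seed=37)
        data, _, _ = simulate_cohort(cfg)
        shifted = data.records.copy()
        shifted["time_years"] += 2.0
        pcfg = ProgressionConfig(recenter=False, max_iter=30, scale_search=False,
                                 polish_tail_fraction=0.0)
        g0 = fit_progression_model(data, config=pcfg).gamma_series()
        g1 = fit_progression_model(LongitudinalDataset(shifted), config=pcfg).gamma_series()
        # per-subject equality is disturbed by frame-dependent tie-breaking
        # on the plateaus; the cohort frame itself must shift by exactly -c
        assert (g1 - g0).mean() == pytest.approx(-2.0, abs=0.1)

    def test_time_shift_estimator_equivariant(self, sigmoid_curve, rng):
        """Shifting visit times by c moves the estimated shift by exactly -c."""
        for _ in range(5):
            t = np.sort(rng.uniform(0, 4, 5))
            v = sigmoid_curve(t + rng.uniform(-4, 4)) + rng.normal(0, 0.05, 5)
            rec = pd.DataFrame({"subject_id": "s", "biomarker_id": "b",
                                "time_years": t, "value": v})
            rec2 = rec.assign(time_years=t + 2.0)
            gA = estimate_time_shift(rec, [sigmoid_curve], bounds=(-10, 10))
            gB = estimate_time_shift(rec2, [sigmoid_curve], bounds=(-10, 10))
            assert gB == pytest.approx(gA - 2.0, abs=2e-3)


class TestDpsTable:
    def _model(self, gammas):
        subs = [SubjectTrajectoryParams(f"s{i}", g) for i, g in enumerate(gammas)]
        return ProgressionModel(curves={}, subjects=subs, normalization=None,
                                rss_trace=[1.0], objective_trace=[1.0],
                                n_iterations=1, converged=True)

    def test_returns_exact_gammas(self):
        table = dps_table(self._model([-1.0, 0.0, 1.0]))
        assert list(table["dps_years"]) == [-1.0, 0.0, 1.0]
        assert len(table) == 3

    def test_mean_zero_for_centered_model(self):
        table = dps_table(self._model([-2.0, -1.0, 3.0]))
        # mean-zero holds for fitted (re-centred) models; here we only check
        # the table reproduces the stored shifts verbatim
        assert table["dps_years"].sum() == pytest.approx(0.0, abs=1e-6)

    def test_empty_model_rejected(self):
        with pytest.raises(ValueError, match="no fitted subjects"):
            dps_table(self._model([]))
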