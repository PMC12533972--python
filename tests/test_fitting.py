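"""Fitting tests: heuristic estimates, error function, bounded Nelder-Mead."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import myoregen as mr

# printed reference values for the heuristic initial estimates and their
# 100-fold search bounds (5 significant digits)
PRINTED_INITIALS = {
    "cNMd": 1.0000e-03,
    "cM1Md": 1.0000e-04,
    "cNin": 3.3333e-02,
    "cNout": 1.0000e00,
    "cM1Nd": 1.0000e-04,
    "cMin": 5.0000e00,
    "cMM1": 3.3333e-05,
    "cMout": 1.0000e00,
    "cM1M2": 1.0000e03,
    "cM1M2inhib": 1.0000e03,
    "cM2out": 1.0000e00,
    "cQSCN": 1.0000e-03,
    "cQSCMd": 3.3333e-05,
    "cASCM2": 1.0000e-04,
    "cASCpro": 1.0000e-04,
    "cASCdiff": 1.0000e-04,
    "cMcout": 1.0000e00,
}


class TestHeuristicEstimates:
    def test_all_seventeen_initials_match_printed_values(self):
        spec = mr.heuristic_initial_estimates()
        for name, printed in PRINTED_INITIALS.items():
            value = spec.initial[list(spec.names).index(name)]
            assert value == pytest.approx(printed, rel=5e-5), name

    @pytest.mark.parametrize(
        "name, expected",
        [
            ("cNMd", 1.0 / 1000.0),       # bilinear: one over peak neutrophils
            ("cNin", 1000.0 / 30000.0),   # influx: needed flux over damage level
            ("cM1Md", 1.0 / 10000.0),     # bilinear: one over peak M1
        ],
    )
    def test_heuristic_rules_give_exact_fractions(self, name, expected):
        spec = mr.heuristic_initial_estimates()
        assert spec.initial[list(spec.names).index(name)] == expected

    def test_bounds_are_one_hundred_fold_around_initials(self):
        spec = mr.heuristic_initial_estimates()
        np.testing.assert_allclose(spec.lower, spec.initial / 100.0, rtol=1e-12)
        np.testing.assert_allclose(spec.upper, spec.initial * 100.0, rtol=1e-12)
        i = list(spec.names).index("cNout")
        assert spec.lower[i] == pytest.approx(1.0000e-02)
        assert spec.upper[i] == pytest.approx(1.0000e02)

    def test_missing_scale_assumption_names_the_parameter(self):
        import types

        with pytest.raises(TypeError):
            mr.heuristic_initial_estimates({"not_a_scale": 1.0})
        incomplete = types.SimpleNamespace(peak_n=1000.0)  # lacks peak_m1 etc.
        with pytest.raises(mr.ValidationError, match="cM1Md"):
            mr.heuristic_initial_estimates(incomplete)

    def test_custom_scales_propagate(self):
        spec = mr.heuristic_initial_estimates(mr.HeuristicScales(peak_n=2000.0))
        assert spec.initial[list(spec.names).index("cNMd")] == 1.0 / 2000.0


class TestParameterSpec:
    def test_invalid_bounds_rejected(self):
        good = mr.heuristic_initial_estimates()
        with pytest.raises(mr.ValidationError):
            mr.ParameterSpec(initial=good.initial, lower=good.upper, upper=good.lower)
        with pytest.raises(mr.ValidationError):
            mr.ParameterSpec(
                initial=good.initial, lower=np.zeros(17), upper=good.upper
            )

    def test_frame_export_has_table_columns(self):
        df = mr.heuristic_initial_estimates().to_frame()
        assert list(df.columns) == ["parameter", "initial", "lower", "upper"]
        assert len(df) == 17


def toy_targets(values):
    """CalibratedTargets from {(cell_type, day): target} with no dead cells."""
    rows = [
        {"day": d, "cell_type": ct, "target": v, "sd": 0.0, "scale_factor": np.nan}
        for (ct, d), v in values.items()
    ]
    return mr.CalibratedTargets(frame=pd.DataFrame(rows))


def stub_simulator(table):
    """Simulator stub returning fixed per-(day, type) values."""

    def sim(params, initial, days):
        out = np.zeros((len(days), len(mr.STATE_ORDER)))
        for (ct, d), v in table.items():
            out[list(days).index(d), mr.STATE_ORDER.index(ct)] = v
        return out

    return sim


class TestErrorFunction:
    def test_perfect_stub_simulation_gives_zero_error(
        self, optimized_params, initial_state
    ):
        values = {("N", 1.0): 1000.0, ("M1", 2.0): 7000.0}
        e = mr.error(
            optimized_params,
            toy_targets(values),
            initial_state,
            simulator=stub_simulator(values),
        )
        assert e == 0.0

    def test_two_by_two_toy_matches_hand_arithmetic(self, optimized_params, initial_state):
        targets = toy_targets({("N", 1.0): 100.0, ("N", 2.0): 50.0, ("M", 1.0): 10.0, ("M", 2.0): 40.0})
        sim = stub_simulator({("N", 1.0): 110.0, ("N", 2.0): 45.0, ("M", 1.0): 12.0, ("M", 2.0): 30.0})
        # per type: sum |sim - T| / max_d T = (10 + 5)/100 + (2 + 10)/40
        expected = 15.0 / 100.0 + 12.0 / 40.0
        e = mr.error(optimized_params, targets, initial_state, simulator=sim)
        assert e == pytest.approx(expected, rel=1e-12)

    def test_error_is_linear_in_deviations(self, optimized_params, initial_state):
        targets = toy_targets({("N", 1.0): 100.0, ("M", 1.0): 10.0})
        sim1 = stub_simulator({("N", 1.0): 110.0, ("M", 1.0): 14.0})
        sim2 = stub_simulator({("N", 1.0): 120.0, ("M", 1.0): 18.0})  # doubled deviations
        e1 = mr.error(optimized_params, targets, initial_state, simulator=sim1)
        e2 = mr.error(optimized_params, targets, initial_state, simulator=sim2)
        assert e2 == pytest.approx(2.0 * e1, rel=1e-12)

    def test_invariant_to_row_order_of_target_table(self, optimized_params, initial_state):
        frame = toy_targets(
            {("N", 1.0): 100.0, ("N", 2.0): 50.0, ("QSC", 1.0): 10.0, ("QSC", 7.0): 40.0}
        ).frame
        shuffled = mr.CalibratedTargets(frame=frame.sample(frac=1.0, random_state=3))
        e1 = mr.error(optimized_params, mr.CalibratedTargets(frame=frame), initial_state)
        e2 = mr.error(optimized_params, shuffled, initial_state)
        assert e1 == pytest.approx(e2, rel=1e-12)

    def test_dead_cell_day7_terms_enter_with_unit_normalization(
        self, optimized_params, initial_state, noise_free_targets
    ):
        e_with = mr.error(optimized_params, noise_free_targets, initial_state)
        e_without = mr.error(
            optimized_params, noise_free_targets, initial_state, include_dead_cells=False
        )
        traj = mr.simulate(optimized_params, initial_state, grid="observation")
        dead = abs(traj.get("Md")[-1] - 1.0) + abs(traj.get("Nd")[-1] - 1.0)
        assert e_with - e_without == pytest.approx(dead, abs=1e-6)

    def test_all_zero_targets_for_a_type_rejected(self, optimized_params, initial_state):
        with pytest.raises(mr.ValidationError):
            mr.error(optimized_params, toy_targets({("N", 1.0): 0.0}), initial_state)


class TestFit:
    def test_degenerate_bounds_return_initial_estimate_unchanged(
        self, noise_free_targets, initial_state
    ):
        base = mr.heuristic_initial_estimates()
        spec = mr.ParameterSpec(initial=base.initial, lower=base.initial, upper=base.initial)
        res = mr.fit(spec, noise_free_targets, initial_state)
        np.testing.assert_array_equal(res.params.to_array(), base.initial)
        assert res.converged and res.n_evaluations == 1

    def test_fit_is_deterministic(self, noise_free_targets, initial_state):
        kw = dict(maxfev=300)
        r1 = mr.fit(None, noise_free_targets, initial_state, **kw)
        r2 = mr.fit(None, noise_free_targets, initial_state, **kw)
        np.testing.assert_array_equal(r1.params.to_array(), r2.params.to_array())
        assert r1.error == r2.error and r1.n_evaluations == r2.n_evaluations

    def test_self_consistency_recovers_near_zero_error(self, self_consistency_fit, noise_free_targets, initial_state):
        """Fitting targets generated by the model itself must collapse E.

        The generating parameters give E ~ 0 (only the fixed dead-cell
        day-7 terms remain), so bounded Nelder-Mead from the heuristic
        initial estimates must reduce the starting error by >= 95%.
        """
        res = self_consistency_fit
        e0 = mr.error(res.spec.initial_parameters(), noise_free_targets, initial_state)
        assert res.error <= e0
        assert res.error <= 0.05 * e0

    def test_fitted_parameters_respect_bounds(self, self_consistency_fit):
        res = self_consistency_fit
        assert np.all(res.params.to_array() >= res.spec.lower)
        assert np.all(res.params.to_array() <= res.spec.upper)

    def test_error_trace_is_monotone_best_so_far(self, self_consistency_fit):
        trace = self_consistency_fit.trace
        assert trace.size == self_consistency_fit.n_evaluations
        assert np.all(np.diff(trace) <= 0.0 + 1e-15)
        assert trace[-1] == pytest.approx(self_consistency_fit.error, rel=1e-9)

    def test_result_table_has_table1_layout(self, self_consistency_fit):
        df = self_consistency_fit.to_frame()
        assert list(df.columns) == ["parameter", "initial", "lower", "upper", "optimized"]
        assert len(df) == 17

    def test_estimator_predict_simulates_with_fitted_parameters(
        self, noise_free_targets, initial_state
    ):
        fitter = mr.RegenerationModelFitter(maxfev=200)
        fitter.fit(noise_free_targets, initial_state=initial_state)
        traj = fitter.predict(grid="observation")
        expected = mr.simulate(fitter.params_, initial_state, grid="observation")
        np.testing.assert_array_equal(traj.states, expected.states)
        assert fitter.score() == -fitter.error_

    def test_log_scale_fit_stays_within_bounds(self, noise_free_targets, initial_state):
        res = mr.fit(None, noise_free_targets, initial_state, maxfev=300, log_scale=True)
        assert np.all(res.params.to_array() >= res.spec.lower)
        assert np.all(res.params.to_array() <= res.spec.upper)
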