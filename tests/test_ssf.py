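import numpy as np
import pandas as pd
import pytest
from scipy import stats

from connectscape.ssf import (LENGTH_ADJUSTMENT, TRAVEL_THRESHOLDS,
                              SeparationError, SSFModel, StepSet, aicc_select,
                              filter_travel, fit_clogit, make_steps,
                              predict_suitability, sample_random_steps,
                              _clogit_loglik, _clogit_parts)
from connectscape.synthetic import Track, simulate_ssf_track


def _track(points, start="2020-01-01", freq="1h"):
    times = pd.date_range(start, periods=len(points), freq=freq)
    return Track("t", pd.DataFrame({"timestamp": times,
                                    "x": [p[0] for p in points],
                                    "y": [p[1] for p in points]}))


def _stepset_from_arrays(x, case, stratum, covname="v", **kw):
    df = pd.DataFrame({"stratum": stratum, "case": case, covname: x,
                       "x_start": 0.0, "y_start": 0.0, "x_end": 0.0,
                       "y_end": 0.0, "length": 1.0})
    defaults = dict(covariates=[covname], K=int(pd.Series(case).eq(0).sum()
                                                // pd.Series(stratum).nunique()))
    defaults.update(kw)
    return StepSet(df, **defaults)


from tests_helpers import simulate_strata as _simulate_strata  # noqa: E402


class TestMakeSteps:
    def test_three_four_five_step(self):
        steps = make_steps(_track([(0, 0), (3, 4)]))
        assert len(steps) == 1
        assert steps["length"].iloc[0] == pytest.approx(5.0)

    def test_collinear_fixes_have_zero_turn(self):
        steps = make_steps(_track([(0, 0), (100, 0), (200, 0)]))
        assert steps["turn_angle"].iloc[1] == pytest.approx(0.0)
        assert np.isnan(steps["turn_angle"].iloc[0])

    def test_gap_drops_bridging_step(self):
        times = pd.to_datetime(["2020-01-01 00:00", "2020-01-01 01:00",
                                "2020-01-01 02:00", "2020-01-01 05:00",
                                "2020-01-01 06:00"])
        tr = Track("t", pd.DataFrame({"timestamp": times,
                                      "x": [0, 10, 20, 30, 40],
                                      "y": [0, 0, 0, 0, 0]}))
        steps = make_steps(tr, tolerance=300.0)
        # 5 fixes, one 3 h gap: steps = fixes - gaps - 1 = 3
        assert len(steps) == 3

    def test_turn_angle_nan_after_gap(self):
        times = pd.to_datetime(["2020-01-01 00:00", "2020-01-01 01:00",
                                "2020-01-01 04:00", "2020-01-01 05:00"])
        tr = Track("t", pd.DataFrame({"timestamp": times,
                                      "x": [0, 10, 20, 30], "y": [0] * 4}))
        steps = make_steps(tr, tolerance=300.0)
        assert steps["turn_angle"].isna().all()

    def test_too_few_fixes(self):
        with pytest.raises(ValueError):
            make_steps(_track([(0, 0)]))


class TestSampleRandomSteps:
    def test_complete_strata_have_k_plus_one_steps(self, small_stack, prepared):
        tr = simulate_ssf_track(small_stack, {"FCOV": 0.3}, (1.8, 60.0), 60,
                                small_stack.grid.cell_center(40, 40), seed=5)
        ss = sample_random_steps(make_steps(tr), prepared, K=100, seed=6)
        sizes = ss.steps.groupby("stratum").size()
        assert (sizes <= 101).all() and (sizes == 101).sum() > 0
        assert (ss.steps.groupby("stratum")["case"].sum() == 1).all()

    def test_fixed_seed_reproducible(self, small_stack, prepared):
        tr = simulate_ssf_track(small_stack, {"FCOV": 0.3}, (1.8, 60.0), 40,
                                small_stack.grid.cell_center(40, 40), seed=5)
        obs = make_steps(tr)
        a = sample_random_steps(obs, prepared, K=20, seed=9)
        b = sample_random_steps(obs, prepared, K=20, seed=9)
        pd.testing.assert_frame_equal(a.steps, b.steps)

    def test_control_lengths_follow_fitted_gamma(self, small_stack, prepared):
        tr = simulate_ssf_track(small_stack, {"FCOV": 0.0}, (1.8, 60.0), 60,
                                small_stack.grid.cell_center(40, 40), seed=7)
        ss = sample_random_steps(make_steps(tr), prepared, K=100, seed=8)
        ctl = ss.steps.loc[ss.steps["case"] == 0, "length"].to_numpy()
        shape_k, scale_k = ss.gamma_params
        p = stats.kstest(ctl, "gamma", args=(shape_k, 0, scale_k)).pvalue
        assert p > 0.01

    def test_degenerate_lengths_rejected(self, prepared):
        obs = pd.DataFrame({"stratum": range(6), "x_start": 0.0, "y_start": 0.0,
                            "x_end": 10.0, "y_end": 0.0, "length": 10.0,
                            "turn_angle": 0.0})
        with pytest.raises(ValueError, match="gamma"):
            sample_random_steps(obs, prepared, K=5, seed=1)


class TestFilterTravel:
    def test_zero_threshold_is_identity(self):
        ss = _simulate_strata([0.5], 10, 5, seed=3)
        out = filter_travel(ss, 0.0)
        assert out.n_strata == ss.n_strata and out.mode == "Travel"

    def test_threshold_drops_whole_strata(self):
        ss = _simulate_strata([0.5], 3, 4, seed=4)
        obs_idx = ss.steps["case"] == 1
        ss.steps.loc[obs_idx, "length"] = [50.0, 150.0, 250.0]
        out = filter_travel(ss, 150.0)
        assert out.n_strata == 2
        assert (out.steps.groupby("stratum").size() == 5).all()

    def test_species_thresholds_are_the_published_ones(self):
        assert TRAVEL_THRESHOLDS == {"ocelot": 100.0,
                                     "white_lipped_peccary": 150.0,
                                     "puma": 200.0}

    def test_all_removed_is_an_error(self):
        ss = _simulate_strata([0.5], 3, 4, seed=4)
        with pytest.raises(ValueError):
            filter_travel(ss, 1e9)


class TestFitClogit:
    def test_null_loglik_is_minus_n_log_k_plus_one(self):
        K, N = 7, 25
        ss = _simulate_strata([0.8], N, K, seed=11)
        X, starts, case = _clogit_parts(ss, ss.covariates)
        ll0, _, _ = _clogit_loglik(np.zeros(1), X, starts, case)
        assert ll0 == pytest.approx(-N * np.log(K + 1))

    def test_symmetric_two_strata_mle_is_zero_vs_grid_search(self):
        x = [1.0, 0.0, 0.0, 1.0]
        ss = _stepset_from_arrays(x, [1, 0, 1, 0], [0, 0, 1, 1])
        m = fit_clogit(ss)
        assert m.beta["v"] == pytest.approx(0.0, abs=1e-6)
        # independent 1-D grid-search oracle on the analytic likelihood
        grid = np.linspace(-3, 3, 2001)
        ll = [np.log(np.exp(b) / (np.exp(b) + 1)) + np.log(1 / (1 + np.exp(b)))
              for b in grid]
        assert abs(grid[int(np.argmax(ll))]) < 0.01

    def test_fitted_loglik_never_below_null(self):
        ss = _simulate_strata([0.4, -0.7], 100, 10, seed=12)
        m = fit_clogit(ss)
        assert m.loglik >= -100 * np.log(11) - 1e-9

    def test_information_matrix_positive_definite(self):
        ss = _simulate_strata([0.4, -0.7], 100, 10, seed=12)
        m = fit_clogit(ss)
        assert (np.linalg.eigvalsh(np.linalg.inv(m.vcov)) > 0).all()

    def test_invariance_to_stratum_constant_offset(self):
        ss = _simulate_strata([0.6], 50, 8, seed=13)
        m0 = fit_clogit(ss)
        shifted = ss.steps.copy()
        offsets = {s: o for s, o in enumerate(
            np.random.default_rng(1).normal(0, 5, ss.n_strata))}
        shifted["v0"] = shifted["v0"] + shifted["stratum"].map(offsets)
        m1 = fit_clogit(StepSet(shifted, ss.covariates, K=ss.K))
        assert m1.beta["v0"] == pytest.approx(m0.beta["v0"], abs=1e-5)

    def test_complete_separation_detected(self):
        n = 20
        x = np.tile([1.0, 0.0, 0.0], n)
        case = np.tile([1, 0, 0], n)
        stratum = np.repeat(range(n), 3)
        ss = _stepset_from_arrays(x, case, stratum)
        with pytest.raises(SeparationError):
            fit_clogit(ss)

    def test_constant_within_stratum_covariate_rejected(self):
        ss = _simulate_strata([0.5], 10, 4, seed=14)
        ss.steps["flat"] = ss.steps["stratum"].astype(float)
        with pytest.raises(ValueError, match="flat"):
            fit_clogit(ss, ["v0", "flat"])

    def test_matches_statsmodels_conditional_logit(self):
        sm = pytest.importorskip("statsmodels.api")
        ss = _simulate_strata([0.5, -0.3], 150, 10, seed=15)
        mine = fit_clogit(ss)
        ref = sm.ConditionalLogit(
            ss.steps["case"].to_numpy(),
            ss.steps[["v0", "v1"]].to_numpy(),
            groups=ss.steps["stratum"].to_numpy()).fit(disp=0, method="newton",
                                                       tol=1e-10)
        np.testing.assert_allclose(mine.beta.to_numpy(), ref.params, atol=1e-6)
        np.testing.assert_allclose(mine.se.to_numpy(), ref.bse, atol=1e-6)

    def test_wald_interval_coverage_on_simulated_strata(self):
        truth = np.array([0.5, -0.8])
        covered = 0
        reps = 20
        for rep in range(reps):
            ss = _simulate_strata(truth, 1000, 100, seed=100 + rep)
            m = fit_clogit(ss)
            lo = m.beta.to_numpy() - 1.96 * m.se.to_numpy()
            hi = m.beta.to_numpy() + 1.96 * m.se.to_numpy()
            covered += ((lo <= truth) & (truth <= hi)).sum()
        assert covered / (reps * truth.size) >= 0.90


class TestAiccSelect:
    def test_single_candidate_returned(self):
        ss = _simulate_strata([0.5], 50, 5, seed=16)
        best, table = aicc_select(ss, [["v0"]])
        assert best.covariates == ["v0"] and len(table) == 1

    def test_duplicate_candidate_ties_to_listed_order(self):
        ss = _simulate_strata([0.5], 50, 5, seed=17)
        best, table = aicc_select(ss, [["v0"], ["v0"]])
        ok = table[table["AICc"].notna()]
        assert ok["dAICc"].iloc[1] == pytest.approx(0.0)
        assert ok.sort_values(["AICc", "k", "order"]).iloc[0]["order"] == 0

    def test_true_model_beats_overfit_in_most_replicates(self):
        wins = 0
        reps = 20
        for rep in range(reps):
            rng = np.random.default_rng(200 + rep)
            ss = _simulate_strata([0.8], 300, 10, seed=int(rng.integers(2**31)))
            ss.steps["noise"] = rng.standard_normal(len(ss.steps))
            ss.covariates = ["v0", "noise"]
            best, _ = aicc_select(ss, [["v0"], ["v0", "noise"]])
            wins += best.covariates == ["v0"]
        assert wins >= 0.7 * reps

    def test_failed_candidate_recorded_not_fatal(self):
        ss = _simulate_strata([0.5], 30, 5, seed=18)
        ss.steps["flat"] = 1.0
        best, table = aicc_select(ss, [["flat"], ["v0"]])
        assert best.covariates == ["v0"]
        assert (table["error"] != "").sum() == 1


class TestPredictSuitability:
    def test_zero_coefficients_is_degenerate(self, prepared):
        m = SSFModel(beta=pd.Series({"FCOV": 0.0}), se=pd.Series({"FCOV": 1.0}),
                     vcov=np.eye(1), loglik=0.0, aicc=0.0, n_strata=10,
                     covariates=["FCOV"])
        with pytest.raises(ValueError, match="constant"):
            predict_suitability(m, prepared)

    def test_linear_ramp_is_affinely_rescaled(self, prepared):
        from connectscape.covariates import PreparedStack
        from connectscape.raster import CovariateStack, Raster

        ramp = Raster(np.tile(np.linspace(-2, 2, 50), (50, 1)), cell_size=30.0)
        ps = PreparedStack(CovariateStack({"v": ramp}), {"v": 0.0}, {"v": 1.0})
        m = SSFModel(beta=pd.Series({"v": 1.0}), se=pd.Series({"v": 1.0}),
                     vcov=np.eye(1), loglik=0.0, aicc=0.0, n_strata=10,
                     covariates=["v"])
        out = predict_suitability(m, ps)
        expected = (ramp.data - ramp.data.min()) / np.ptp(ramp.data)
        np.testing.assert_allclose(out.data, expected, atol=1e-12)

    def test_output_attains_zero_and_one(self, prepared):
        m = SSFModel(beta=pd.Series({"FCOV": 0.4, "DWPA": -0.2}),
                     se=pd.Series({"FCOV": 1.0, "DWPA": 1.0}), vcov=np.eye(2),
                     loglik=0.0, aicc=0.0, n_strata=10,
                     covariates=["FCOV", "DWPA"])
        out = predict_suitability(m, prepared)
        valid = out.data[~np.isnan(out.data)]
        assert valid.min() == 0.0 and valid.max() == 1.0

    def test_three_cell_toy_matches_hand_arithmetic(self):
        # puma all-data coefficients on hand-set standardized covariates
        from connectscape.covariates import PreparedStack
        from connectscape.raster import CovariateStack, Raster

        layers = {
            "elevation": [[-1.0, 0.0, 1.0]],
            "loss": [[0.5, -0.5, 0.0]],
            "FCOV": [[1.0, 1.0, -1.0]],
            "DWPA": [[0.0, 2.0, -0.5]],
        }
        stack = CovariateStack({k: Raster(np.array(v), cell_size=30.0)
                                for k, v in layers.items()})
        ps = PreparedStack(stack, {k: 0.0 for k in layers},
                           {k: 1.0 for k in layers})
        beta = {"elevation": -0.26, "loss": 0.47, "FCOV": 0.10, "DWPA": 1.22}
        m = SSFModel(beta=pd.Series(beta), se=pd.Series(beta), vcov=np.eye(4),
                     loglik=0.0, aicc=0.0, n_strata=10,
                     covariates=list(beta))
        out = predict_suitability(m, ps)
        raw = np.array([
            -0.26 * -1.0 + 0.47 * 0.5 + 0.10 * 1.0 + 1.22 * 0.0,
            -0.26 * 0.0 + 0.47 * -0.5 + 0.10 * 1.0 + 1.22 * 2.0,
            -0.26 * 1.0 + 0.47 * 0.0 + 0.10 * -1.0 + 1.22 * -0.5,
        ])
        expected = (raw - raw.min()) / np.ptp(raw)
        np.testing.assert_allclose(out.data[0], expected, atol=1e-12)
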