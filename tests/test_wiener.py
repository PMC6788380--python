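import numpy as np
import pytest

from gaitdyn import wiener


def independent_r2(y, yhat):
    """Independent implementation of 1 - SSres/SStot for the oracle check."""
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    return 1.0 - np.sum((y - yhat) ** 2) / np.sum((y - np.mean(y)) ** 2)


class TestFitWiener:
    def test_recovers_exact_lagged_combination(self, rng):
        x = rng.standard_normal((400, 1))
        y = np.zeros(400)
        y[3:] = 2 * x[3:, 0] - x[:-3, 0]
        filt = wiener.fit_wiener(x, y, order=10)
        coef = filt.coefficients[:, 0, 0]
        expect = np.zeros(10)
        expect[0] = 2.0
        expect[3] = -1.0
        assert np.allclose(coef, expect, atol=1e-8)
        assert abs(filt.intercept[0]) < 1e-8
        pred = wiener.predict(filt, x)
        assert wiener.score_r2(y[9:], pred[9:, 0])[0] == pytest.approx(1.0, abs=1e-10)

    def test_zero_inputs_intercept_is_target_mean(self, rng):
        x = np.zeros((100, 2))
        y = rng.standard_normal(100) + 5.0
        with pytest.warns(UserWarning, match="rank-deficient"):
            filt = wiener.fit_wiener(x, y, order=10)
        assert np.allclose(filt.coefficients, 0.0, atol=1e-8)
        assert filt.intercept[0] == pytest.approx(y[9:].mean())

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.standard_normal((200, 3))
        y = rng.standard_normal((200, 2))
        filt = wiener.fit_wiener(x, y, order=10)
        D, valid = wiener.lagged_design(x, 10)
        A = np.hstack([D[valid], np.ones((valid.sum(), 1))])
        sol_oracle = np.linalg.solve(A.T @ A, A.T @ y[valid])
        sol = np.vstack([filt.coefficients.reshape(30, 2), filt.intercept])
        assert np.allclose(sol, sol_oracle, atol=1e-8)


class TestPredict:
    def test_zero_filter_outputs_intercept(self):
        filt = wiener.WienerFilter(
            coefficients=np.zeros((10, 2, 1)), intercept=np.array([3.5]),
            fitted=True,
        )
        out = wiener.predict(filt, np.ones((20, 2)))
        assert np.allclose(out, 3.5)

    def test_time_invariance_under_shift(self, rng):
        x = rng.standard_normal((120, 2))
        y = (x[:, 0] + 0.5 * x[:, 1])
        filt = wiener.fit_wiener(x, y, order=10)
        shifted = np.roll(x, 5, axis=0)
        out = wiener.predict(filt, x)
        out_shift = wiener.predict(filt, shifted)
        assert np.allclose(out_shift[14:], np.roll(out, 5)[14:], atol=1e-10)

    def test_feature_mismatch(self, rng):
        filt = wiener.fit_wiener(rng.standard_normal((50, 2)), rng.standard_normal(50))
        with pytest.raises(ValueError, match="mismatch"):
            wiener.predict(filt, rng.standard_normal((50, 3)))

    def test_unfitted_rejected(self):
        filt = wiener.WienerFilter(np.zeros((10, 1, 1)), np.zeros(1))
        with pytest.raises(ValueError, match="not fitted"):
            wiener.predict(filt, np.zeros((10, 1)))


class TestScoreR2:
    def test_perfect_prediction(self):
        y = np.arange(10.0)
        assert wiener.score_r2(y, y)[0] == 1.0

    def test_mean_prediction_scores_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        yhat = np.full(4, y.mean())
        assert wiener.score_r2(y, yhat)[0] == pytest.approx(0.0)

    def test_worked_example(self):
        y = np.array([0.0, 1.0, 2.0, 3.0])
        yhat = np.array([0.5, 1.5, 1.5, 2.5])
        assert wiener.score_r2(y, yhat)[0] == pytest.approx(0.8)

    def test_can_be_negative(self):
        y = np.array([0.0, 1.0, 0.0, 1.0])
        yhat = np.array([5.0, -5.0, 5.0, -5.0])
        assert wiener.score_r2(y, yhat)[0] < 0

    def test_constant_true_signal_nan_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = wiener.score_r2(np.ones(5), np.arange(5.0))
        assert np.isnan(out[0])

    def test_matches_independent_implementation(self, rng):
        for _ in range(20):
            y = rng.standard_normal(37)
            yhat = y + 0.3 * rng.standard_normal(37)
            assert wiener.score_r2(y, yhat)[0] == pytest.approx(
                independent_r2(y, yhat), abs=1e-12
            )


class TestPartitionFolds:
    def test_partition_property(self):
        blocks = wiener.partition_folds(47, 10, seed=3)
        sizes = [len(b) for b in blocks]
        assert sum(sizes) == 47
        assert max(sizes) - min(sizes) <= 1
        assert sizes == sorted(sizes, reverse=True)  # remainder to earliest
        all_ids = np.sort(np.concatenate(blocks))
        assert np.array_equal(all_ids, np.arange(47))

    def test_deterministic(self):
        a = wiener.partition_folds(30, 10, seed=7)
        b = wiener.partition_folds(30, 10, seed=7)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_too_few_trials(self):
        with pytest.raises(ValueError):
            wiener.partition_folds(5, 10, seed=0)


class TestRunCV:
    def test_deterministic_given_seed(self, small_session):
        spec = wiener.DecoderSpec(method="fp")
        a = wiener.run_cv(small_session, spec, folds=5, seed=4)
        b = wiener.run_cv(small_session, spec, folds=5, seed=4)
        for ra, rb in zip(a, b):
            assert ra.trial_scores.equals(rb.trial_scores)

    def test_each_trial_tested_exactly_once(self, small_session):
        spec = wiener.DecoderSpec(method="fp")
        res = wiener.run_cv(small_session, spec, folds=5, seed=4)
        tested = sorted(i for r in res for i in r.trial_scores.index)
        assert tested == list(range(len(small_session.trials)))

    def test_no_test_fold_leakage_tags(self, small_session):
        res = wiener.run_cv(small_session, wiener.DecoderSpec(method="fp"),
                            folds=5, seed=0)
        for r in res:
            assert set(r.trial_scores.index).isdisjoint(r.train_trial_ids)

    def test_high_snr_fp_ceiling(self):
        # deterministic latents + strong firing: decoding from spikes is
        # limited only by the Poisson noise floor, so every kinematic
        # variable should be recovered almost perfectly
        from gaitdyn import synthetic as syn

        cfg = syn.GroundTruthConfig(
            n_units=50, latent_dim=4, n_trials_per_condition=30,
            conditions=[("TRM", 4.0)], gait_period_range=(0.6, 0.6),
            kinematic_noise_sd=0.0, base_log_rate_range=(0.9, 1.2),
            loading_scale=0.45, latent_noise_sd=1e-4, start_noise_sd=1e-4,
            seed=5,
        )
        s = syn.generate_session(cfg)
        res = wiener.run_cv(s, wiener.DecoderSpec(method="fp"), folds=10, seed=0)
        mean = wiener.session_mean_r2(res)
        # angle sines/cosines are nonlinear in the latents, so they sit a
        # bit below the linear-readout variables even at this SNR
        assert mean.drop("gait_phase").min() > 0.7
        assert mean[[c for c in mean.index if c.endswith(("_x", "_y"))]].min() > 0.9
        assert mean["gait_phase"] > 0.5

    def test_kinematics_scored_only_with_kinematics(self, small_session):
        res = wiener.run_cv(small_session, wiener.DecoderSpec(method="fp"),
                            folds=5, seed=1)
        for r in res:
            for trial_id, row in r.trial_scores.iterrows():
                tr = small_session.trials[trial_id]
                kin_vals = row.drop("gait_phase")
                if tr.has_kinematics:
                    assert kin_vals.notna().all()
                else:
                    assert kin_vals.isna().all()
                assert np.isfinite(row["gait_phase"])

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            wiener.DecoderSpec(method="ridge")

    def test_dims_required_for_reducers(self):
        with pytest.raises(ValueError, match="dims"):
            wiener.DecoderSpec(method="pca")


class TestDimSweep:
    def test_single_dim_plateau_absent(self, small_session):
        res = wiener.dim_sweep(small_session, "pca", dims=[2], folds=5, seed=0)
        assert res.plateau_dim is None

    def test_consistency_with_direct_run(self, small_session):
        res = wiener.dim_sweep(small_session, "pca", dims=[2, 4], folds=5, seed=0)
        direct = wiener.run_cv(
            small_session, wiener.DecoderSpec(method="pca", dims=4),
            folds=5, seed=0,
        )
        assert res.mean_r2[1] == pytest.approx(
            float(wiener.session_mean_r2(direct).mean()), abs=1e-12
        )

    def test_bad_method(self, small_session):
        with pytest.raises(ValueError):
            wiener.dim_sweep(small_session, "fp", dims=[1, 2])

    def test_plds_plateau_near_true_dimension(self):
        # true latent dimension 4: decoding gain flattens between 3 and 6
        from gaitdyn import synthetic as syn

        cfg = syn.GroundTruthConfig(
            n_units=16, latent_dim=4, n_trials_per_condition=25,
            conditions=[("TRM", 4.0)], gait_period_range=(0.5, 0.7),
            base_log_rate_range=(-1.2, -0.3), loading_scale=0.45,
            latent_noise_sd=0.04, kinematic_noise_sd=0.002, seed=9,
        )
        s = syn.generate_session(cfg)
        res = wiener.dim_sweep(
            s, "plds", dims=[2, 3, 4, 5, 6], folds=3, seed=0,
            plds_kw=dict(max_iter=8, tol=1e-5),
        )
        assert res.plateau_dim is not None and 3 <= res.plateau_dim <= 6
        assert len(res.loglik) == 5
        # held-out evidence also flattens: late gains are much smaller than
        # the first increment
        gains = np.diff(res.loglik)
        assert gains[-1] < 0.5 * gains[0]
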