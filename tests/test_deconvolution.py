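import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import sparse

import blinkdeconv as bd
from blinkdeconv import deconvolution as dc
from blinkdeconv.pipeline import excluded_timepoints


def _design_from_dense(X):
    p = X.shape[1]
    labels = pd.DataFrame({"set": ["x"] * p, "lag_ms": np.arange(p) * 4.0})
    return dc.DesignMatrix(X=sparse.csr_matrix(X), labels=labels,
                           excluded=np.zeros(X.shape[0], bool), rate=250.0,
                           set_slices={"x": slice(0, p)},
                           event_times={"x": []})


class TestDesignMatrix:
    def test_fir_window_column_counts(self):
        # [0, 1500) ms at 4 ms bins and [-250, 500) with the trailing
        # partial bin discarded
        assert dc.n_lags((0.0, 1500.0), 4.0) == 375
        assert dc.n_lags((-250.0, 500.0), 4.0) == 187

    def test_built_matrix_has_one_pulse_per_event_per_lag(self, quiet_session):
        hfb, events = quiet_session
        spec = dc.DesignSpec(tuple(dc.interruption_sets(["gap"], "onset",
                                                        False)), rate=250.0)
        design = dc.build_design_matrix(events, spec, hfb.n_samples)
        n_gaps = len(events[(events["kind"] == "gap") &
                            events["category"].isin(["face", "nonface"])])
        cols = np.asarray(design.X.sum(axis=0)).ravel()
        # interior lags: one pulse per event (edge lags may clip)
        assert cols.max() == n_gaps
        assert np.median(cols) == n_gaps

    def test_design_exports_as_sparse_triplets(self, quiet_session, tmp_path):
        hfb, events = quiet_session
        spec = dc.DesignSpec(tuple(dc.interruption_sets(["gap"], "onset",
                                                        False)), rate=250.0)
        design = dc.build_design_matrix(events, spec, hfb.n_samples)
        path = tmp_path / "design.tsv"
        dc.export_design_triplets(design, path)
        back = pd.read_csv(path, sep="\t")
        assert len(back) == design.X.nnz
        assert back["value"].sum() == design.X.sum()

    def test_excluded_timepoints_become_unit_dummy_columns(self):
        spec = dc.DesignSpec((dc.PredictorSet("s", times_s=(0.1,),
                                              window_ms=(0.0, 40.0)),),
                             rate=250.0)
        excl = np.zeros(100, bool)
        excl[[5, 50, 99]] = True
        design = dc.build_design_matrix(pd.DataFrame(), spec, 100, excl)
        Xd = design.with_dummies()
        assert Xd.shape[1] == design.n_columns + 3
        dummies = Xd[:, design.n_columns:].toarray()
        assert (dummies.sum(axis=0) == 1).all()
        assert set(np.flatnonzero(dummies.any(axis=1))) == {5, 50, 99}


class TestOls:
    def test_identity_design_returns_y(self):
        y = np.array([3.0, -1.0, 2.0])
        fit = dc.fit_ols(_design_from_dense(np.eye(3)), y)
        np.testing.assert_allclose(fit.beta, y, atol=1e-12)

    def test_ones_column_returns_the_mean(self):
        fit = dc.fit_ols(_design_from_dense(np.ones((3, 1))),
                         np.array([0.0, 0.0, 3.0]))
        assert fit.beta[0] == pytest.approx(1.0)

    def test_random_design_matches_normal_equations_oracle(self, rng):
        X = rng.standard_normal((50, 5))
        y = rng.standard_normal(50)
        fit = dc.fit_ols(_design_from_dense(X), y)
        oracle = np.linalg.pinv(X) @ y
        np.testing.assert_allclose(fit.beta, oracle, atol=1e-8)

    def test_residuals_are_orthogonal_to_the_design(self, rng):
        X = rng.standard_normal((60, 4))
        fit = dc.fit_ols(_design_from_dense(X), rng.standard_normal(60))
        np.testing.assert_allclose(X.T @ fit.residuals, 0.0, atol=1e-9)

    def test_leverages_are_bounded_and_sum_to_rank(self, rng):
        X = rng.standard_normal((40, 6))
        fit = dc.fit_ols(_design_from_dense(X), rng.standard_normal(40))
        h = fit.leverage
        assert np.all(h >= -1e-12) and np.all(h <= 1 + 1e-12)
        assert h.sum() == pytest.approx(6.0)

    def test_singular_design_lists_offending_columns(self):
        X = np.zeros((10, 3))
        X[:, 0] = 1.0
        X[:, 1] = 1.0  # duplicate of column 0
        X[::2, 2] = 1.0
        with pytest.raises(dc.SingularDesignError) as err:
            dc.fit_ols(_design_from_dense(X), np.zeros(10))
        assert len(err.value.columns) == 1
        fit = dc.fit_ols(_design_from_dense(X), np.arange(10.0),
                         drop_collinear=True)
        assert len(fit.dropped_columns) == 1


class TestHc3:
    def test_hand_evaluated_ones_column_example(self):
        fit = dc.fit_ols(_design_from_dense(np.ones((3, 1))),
                         np.array([0.0, 0.0, 3.0]))
        se = dc.hc3_standard_errors(fit)
        assert se[0] == pytest.approx(np.sqrt(1.5), abs=1e-12)

    def test_matches_independent_sandwich_implementation(self, rng):
        for _ in range(3):
            X = rng.standard_normal((50, 5))
            y = X @ rng.standard_normal(5) + rng.standard_normal(50) * \
                (1 + np.abs(X[:, 0]))
            fit = dc.fit_ols(_design_from_dense(X), y)
            se = dc.hc3_standard_errors(fit)
            oracle = sm.OLS(y, X).fit(cov_type="HC3").bse
            np.testing.assert_allclose(se, oracle, atol=1e-8)

    def test_perfect_fit_gives_zero_se(self, rng):
        X = rng.standard_normal((30, 2))
        y = X @ np.array([1.5, -2.0])  # no noise
        fit = dc.fit_ols(_design_from_dense(X), y)
        np.testing.assert_allclose(dc.hc3_standard_errors(fit), 0.0,
                                   atol=1e-10)

    def test_homoskedastic_large_n_agrees_with_classical_se(self, rng):
        X = rng.standard_normal((5000, 3))
        y = X @ np.ones(3) + rng.standard_normal(5000)
        fit = dc.fit_ols(_design_from_dense(X), y)
        se = dc.hc3_standard_errors(fit)
        classical = sm.OLS(y, X).fit().bse
        assert np.all(np.abs(se / classical - 1) < 0.1)

    def test_saturated_design_raises(self):
        X = np.eye(3)
        fit = dc.fit_ols(_design_from_dense(X), np.arange(3.0))
        with pytest.raises(dc.SaturatedDesignError):
            dc.hc3_standard_errors(fit)


class TestTimepointTests:
    def _fit_with(self, beta, se):
        beta = np.asarray(beta, float)
        p = beta.size
        labels = pd.DataFrame({"set": ["x"] * p, "lag_ms": np.arange(p) * 4.0})
        fit = dc.DeconvolvedResponse(
            beta=beta, labels=labels, residuals=np.zeros(p),
            leverage=np.zeros(p), included=np.ones(p, bool),
            xtx_inv=np.eye(p), design=None, se=np.asarray(se, float))
        return fit

    def test_zero_beta_has_p_one(self):
        out = dc.test_timepoints(self._fit_with([0.0], [1.0]))
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_z_at_the_97_5_quantile_gives_p_05(self):
        out = dc.test_timepoints(self._fit_with([1.959964], [1.0]))
        assert out["p"].iloc[0] == pytest.approx(0.05, abs=1e-6)

    def test_null_deconvolution_controls_fdr(self):
        # flat interruption kernels: FDR-significant lags should be rare
        cfg = bd.SimulationConfig(
            n_blocks=4, voluntary_block_fraction=0.0,
            spontaneous_blink_prob=0.0,
            category_probs=(("face", 0.5), ("nonface", 0.5), ("animal", 0.0)),
            noise=bd.synthetic.NoiseModel(sd=5.0))
        truth = bd.GroundTruth.null(1, stim_window_ms=(0.0, 600.0),
                                    inter_window_ms=(-100.0, 300.0))
        spec = dc.DesignSpec(tuple(
            dc.stimulus_sets(False, (0.0, 600.0)) +
            dc.interruption_sets(["gap"], "onset", False, (-100.0, 300.0))),
            rate=250.0)
        fracs = []
        for seed in range(6):
            hfb, ev = bd.synthetic.generate_hfb_session(
                cfg.replace(seed=seed), truth)
            fit = dc.deconvolve(hfb.values[0], ev, spec)
            out = dc.test_timepoints(fit, q=0.05)
            gap = out[out["set"] == "gap"]
            fracs.append(gap["significant"].mean())
        assert np.mean(fracs) <= 0.05


class TestTemplateSubtraction:
    def test_noiseless_world_matches_deconvolution_off_overlap(self):
        # isolated interruptions: template-subtracted averaging and the
        # deconvolved trace see the same kernel
        cfg = bd.SimulationConfig(
            n_blocks=6, seed=2, noise=bd.synthetic.NoiseModel(kind="none"),
            gap_fraction=0.3, voluntary_block_fraction=0.0,
            spontaneous_blink_prob=0.0,
            category_probs=(("face", 0.5), ("nonface", 0.5), ("animal", 0.0)))
        truth = bd.GroundTruth.from_rois(["V1"])
        for el in truth.electrodes:
            for t in el.reappearance_kernels:
                el.reappearance_kernels[t][:] = 0.0
        hfb, ev = bd.synthetic.generate_hfb_session(cfg, truth)
        y = hfb.values[0]
        avg = dc.template_subtract_average(y, ev, 250.0, lock="onset",
                                           window_ms=(-250.0, 500.0))
        spec = dc.DesignSpec(tuple(
            dc.stimulus_sets(True) +
            dc.interruption_sets(["gap"], "onset", False)), rate=250.0)
        fit = dc.deconvolve(y, ev, spec, standard_errors=False)
        _, beta, _ = fit.trace("gap")
        kernel = truth.electrodes[0].disappearance_kernels["gap"]
        np.testing.assert_allclose(beta, kernel, atol=1e-9)
        # averaging agrees wherever stimulus overlap cancels (most lags)
        close = np.abs(avg.mean - kernel) < 0.5
        assert close.mean() > 0.8

    def test_zero_events_give_empty_output(self, quiet_session):
        hfb, events = quiet_session
        avg = dc.template_subtract_average(
            hfb.values[0], events, 250.0, event_times_s=np.array([]))
        assert avg.n == 0 and avg.mean.size == 0


class TestRelabelRefitter:
    def test_refit_equals_direct_ols_with_exclusions(self, noisy_session):
        cfg, truth, hfb, events = noisy_session
        y = hfb.values[0]
        n = y.size
        excl = excluded_timepoints(events, n, 250.0)
        excl[5000:5200] = True
        fixed_spec = dc.DesignSpec(tuple(
            dc.stimulus_sets(False) +
            dc.interruption_sets(["voluntary"], "onset", False)), rate=250.0)
        fixed = dc.build_design_matrix(events, fixed_spec, n, excl)
        sel = events["category"].isin(["face", "nonface"])
        gaps = events[(events["kind"] == "gap") & sel]
        spont = events[(events["kind"] == "blink") &
                       (events["subtype"] == "spontaneous") & sel]
        pooled = pd.concat([gaps, spont])
        refit = dc.RelabelRefitter(fixed, pooled["onset_s"].to_numpy(),
                                   (-250.0, 500.0), y=y)
        is_gap = np.concatenate([np.ones(len(gaps), bool),
                                 np.zeros(len(spont), bool)])
        betas = refit.betas(np.where(is_gap, 0, 1), 2)
        full_spec = dc.DesignSpec(tuple(
            dc.stimulus_sets(False) +
            dc.interruption_sets(["gap", "spontaneous", "voluntary"],
                                 "onset", False)), rate=250.0)
        direct = dc.deconvolve(y, events, full_spec, excluded=excl,
                               standard_errors=False)
        np.testing.assert_allclose(betas[0], direct.trace("gap")[1],
                                   atol=1e-9)
        np.testing.assert_allclose(betas[1], direct.trace("spontaneous")[1],
                                   atol=1e-9)

    def test_relabeling_is_symmetric_under_label_swap(self, noisy_session):
        cfg, truth, hfb, events = noisy_session
        y = hfb.values[0]
        fixed = dc.build_design_matrix(
            events, dc.DesignSpec(tuple(dc.stimulus_sets(False)), rate=250.0),
            y.size)
        sel = events["category"].isin(["face", "nonface"])
        gaps = events[(events["kind"] == "gap") & sel]
        refit = dc.RelabelRefitter(fixed, gaps["onset_s"].to_numpy(),
                                   (-250.0, 500.0), y=y)
        k = len(gaps) // 2
        assign = np.array([0] * k + [1] * (len(gaps) - k))
        b1 = refit.betas(assign, 2)
        b2 = refit.betas(1 - assign, 2)
        np.testing.assert_allclose(b1[0], b2[1], atol=1e-10)
        np.testing.assert_allclose(b1[1], b2[0], atol=1e-10)
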