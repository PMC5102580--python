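import numpy as np
import pandas as pd
import pytest
from scipy import stats as sct

import blinkdeconv as bd
from blinkdeconv.events import COLUMNS
from blinkdeconv.signal_hfb import extract_hfb, RawRecording
from blinkdeconv.synthetic import (InvalidConfigError, NoiseModel,
                                   SMOOTHERSTEP_PEAK_ACCEL_U, ar1_noise,
                                   amplitude_modulated_carrier,
                                   generate_hfb_session,
                                   generate_ocular_channels,
                                   generate_raw_session, generate_schedule)


class TestSchedule:
    def test_full_session_has_320_stimuli_at_exact_1s_pace(self):
        cfg = bd.SimulationConfig(seed=1)  # 32 blocks x 10 trials
        table = generate_schedule(cfg)
        stim = table[table["kind"] == "stimulus"]
        assert len(stim) == 320
        for _, block in stim.groupby("block_index"):
            ioi = np.diff(np.sort(block["onset_s"].to_numpy()))
            assert np.all(ioi == 1.0)  # exact, not approximate

    def test_no_voluntary_blocks_means_no_voluntary_blinks(self):
        cfg = bd.SimulationConfig(voluntary_block_fraction=0.0, seed=2)
        table = generate_schedule(cfg)
        assert not ((table["kind"] == "blink") &
                    (table["subtype"] == "voluntary")).any()

    def test_gap_count_within_binomial_99_interval_across_seeds(self):
        # all blocks are gap blocks; each trial draws a gap w.p. 0.6
        cfg = bd.SimulationConfig(n_blocks=2, voluntary_block_fraction=0.0,
                                  spontaneous_blink_prob=0.0)
        n = cfg.n_blocks * cfg.trials_per_block
        lo = sct.binom.ppf(0.005, n, cfg.gap_fraction)
        hi = sct.binom.ppf(0.995, n, cfg.gap_fraction)
        for seed in range(5):
            table = generate_schedule(cfg.replace(seed=seed))
            count = int((table["kind"] == "gap").sum())
            assert lo <= count <= hi

    def test_identical_seed_gives_identical_schedule_and_noise(self):
        cfg = bd.SimulationConfig(n_blocks=4, seed=9)
        truth = bd.GroundTruth.from_rois(["V1"])
        t1 = generate_schedule(cfg)
        t2 = generate_schedule(cfg)
        pd.testing.assert_frame_equal(t1, t2)
        h1, _ = generate_hfb_session(cfg, truth)
        h2, _ = generate_hfb_session(cfg, truth)
        assert np.array_equal(h1.values, h2.values)

    def test_interruptions_lie_within_their_trials(self):
        cfg = bd.SimulationConfig(n_blocks=8, seed=4)
        table = generate_schedule(cfg)
        stim = table[table["kind"] == "stimulus"].set_index("trial_index")
        inter = table[table["kind"] != "stimulus"]
        assert (inter["onset_s"] < inter["offset_s"]).all()
        trial_on = stim.loc[inter["trial_index"], "onset_s"].to_numpy()
        assert np.all(inter["onset_s"].to_numpy() >= trial_on)
        assert np.all(inter["offset_s"].to_numpy() <= trial_on + 1.0 + 1e-9)

    def test_gap_latency_beyond_period_is_rejected(self):
        cfg = bd.SimulationConfig(gap_latencies_ms=(350.0, 1100.0))
        with pytest.raises(InvalidConfigError):
            generate_schedule(cfg)


class TestHfbSession:
    def _one_event_schedule(self, onset, offset, kind="gap"):
        return pd.DataFrame(
            [(onset, offset, kind, "face",
              "black" if kind == "gap" else "spontaneous",
              "abrupt" if kind == "gap" else "NA", 0, 0)], columns=COLUMNS)

    def test_single_isolated_event_reproduces_kernel_exactly(self):
        cfg = bd.SimulationConfig(n_blocks=1, noise=NoiseModel(kind="none"))
        truth = bd.GroundTruth.from_rois(["V1"])
        sched = self._one_event_schedule(4.0, 4.15)
        hfb, _ = generate_hfb_session(cfg, truth, schedule=sched)
        el = truth.electrodes[0]
        i_on = int(4.0 * 250) + int(truth.inter_window_ms[0] / 4)
        seg = hfb.values[0, i_on:i_on + el.disappearance_kernels["gap"].size]
        expected = el.disappearance_kernels["gap"].copy()
        # reappearance kernel overlaps the tail of the disappearance window
        i_off = int(round(4.15 * 250)) + int(truth.inter_window_ms[0] / 4)
        rel = i_off - i_on
        expected[rel:] += el.reappearance_kernels["gap"][:expected.size - rel]
        np.testing.assert_allclose(seg, expected, atol=1e-12)

    def test_two_overlapping_events_superpose_linearly(self):
        cfg = bd.SimulationConfig(n_blocks=1, noise=NoiseModel(kind="none"))
        truth = bd.GroundTruth.from_rois(["V1"])
        s1 = self._one_event_schedule(4.0, 4.15)
        s2 = self._one_event_schedule(4.2, 4.35)
        both = pd.concat([s1, s2], ignore_index=True)
        h1, _ = generate_hfb_session(cfg, truth, schedule=s1)
        h2, _ = generate_hfb_session(cfg, truth, schedule=s2)
        h12, _ = generate_hfb_session(cfg, truth, schedule=both)
        np.testing.assert_allclose(h12.values, h1.values + h2.values,
                                   atol=1e-12)

    def test_ar1_noise_autocorrelation_matches_coefficient(self, rng):
        x = ar1_noise(rng, 100_000, 0.9, 5.0)
        x = x - x.mean()
        r1 = (x[1:] @ x[:-1]) / (x @ x)
        assert abs(r1 - 0.9) < 0.05


def _smooth(x, k):
    return np.convolve(x, np.ones(k) / k, mode="same")


class TestRawSession:
    # the stochastic narrowband carrier has intrinsic envelope noise, so the
    # extracted HFB is lightly smoothed before comparison with the modulator

    def test_flat_modulation_gives_flat_envelope(self):
        cfg = bd.SimulationConfig(n_blocks=1, trials_per_block=5, seed=0)
        truth = bd.GroundTruth.null(1, with_stimulus=False)
        rec, _ = generate_raw_session(cfg, truth, modulation_depth=0.0)
        hfb = extract_hfb(rec)
        k = int(0.4 * hfb.rate)
        smooth = _smooth(hfb.values[0], k)[700:-700]
        assert smooth.std() / smooth.mean() < 0.1

    def test_slow_modulator_is_recovered_by_envelope_extraction(self, rng):
        rate, n = 500.0, 30_000
        t = np.arange(n) / rate
        modulator = 1.0 + 0.8 * np.sin(2 * np.pi * 2.0 * t)
        sig = amplitude_modulated_carrier(rate, n, (70.0, 150.0), modulator, rng)
        rec = RawRecording(sig[None, :], rate, ["c0"])
        hfb = extract_hfb(rec)
        m2 = modulator[::2][: hfb.n_samples]
        env = _smooth(hfb.values[0], 50)
        r = np.corrcoef(env[500:-500], m2[500:-500])[0, 1]
        assert r > 0.9

    def test_out_of_band_modulation_leaks_nothing_into_hfb(self, rng):
        rate, n = 500.0, 30_000
        t = np.arange(n) / rate
        modulator = 1.0 + 0.5 * np.sin(2 * np.pi * 30.0 * t)
        sig = amplitude_modulated_carrier(rate, n, (35.0, 45.0), modulator, rng)
        sig = sig + 0.1 * rng.standard_normal(n)
        rec = RawRecording(sig[None, :], rate, ["c0"])
        hfb = extract_hfb(rec)
        m2 = modulator[::2][: hfb.n_samples]
        env = _smooth(hfb.values[0], 25)
        r = np.corrcoef(env[500:-500], m2[500:-500])[0, 1]
        assert abs(r) < 0.1


class TestOcularChannels:
    def test_no_blinks_means_no_missing_pupil_samples(self):
        cfg = bd.SimulationConfig(n_blocks=2, voluntary_block_fraction=0.0,
                                  spontaneous_blink_prob=0.0, seed=3)
        sched = generate_schedule(cfg)
        oc = generate_ocular_channels(cfg, sched)
        assert np.isfinite(oc.pupil).all()

    def _single_blink(self, duration_s=0.15):
        cfg = bd.SimulationConfig(n_blocks=1, seed=0)
        sched = pd.DataFrame(
            [(4.0, 4.0 + 1.0, "stimulus", "face", "NA", "NA", 0, 0),
             (4.3, 4.3 + duration_s, "blink", "face", "spontaneous", "NA", 0, 0)],
            columns=COLUMNS)
        oc = generate_ocular_channels(cfg, sched, np.random.default_rng(5),
                                      eog_noise_sd=0.0, drift_amp_uv=0.0,
                                      pupil_noise_sd=0.0)
        return cfg, sched, oc

    def test_eog_trapezoid_half_height_support_matches_duration(self):
        _, _, oc = self._single_blink(0.15)
        height = oc.eog.max()
        support = (oc.eog > height / 2).sum() / oc.rate
        assert abs(support - 0.15) <= 0.010

    def test_peak_pupil_deceleration_precedes_full_signal_loss(self):
        _, _, oc = self._single_blink(0.15)
        lost = np.flatnonzero(~np.isfinite(oc.pupil))
        # finite-difference oracle on the constructed closing ramp
        valid = np.isfinite(oc.pupil)
        p = np.where(valid, oc.pupil, 0.0)
        d2 = np.diff(p, 2)
        pre = slice(0, lost[0] - 2)
        t_peak = np.argmin(d2[pre])
        assert t_peak < lost[0]
        # the scheduled onset is the analytic peak-acceleration point
        assert abs(t_peak / oc.rate - 4.3) < 0.01

    def test_peak_acceleration_point_is_the_analytic_smootherstep_root(self):
        u = np.linspace(0, 1, 100_001)
        f = u**3 * (u * (6 * u - 15) + 10)
        d2 = np.diff(f, 2)
        u_peak = u[1 + np.argmax(d2)]
        assert abs(u_peak - SMOOTHERSTEP_PEAK_ACCEL_U) < 1e-3
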