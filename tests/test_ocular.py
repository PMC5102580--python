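import numpy as np
import pandas as pd
import pytest

import blinkdeconv as bd
from blinkdeconv.events import COLUMNS
from blinkdeconv.ocular import (DEFAULT_EOG_THRESHOLD_PERCENT, AlignmentError,
                                BlinkEvent, TimingFailureError,
                                UnterminatedBlinkError,
                                calibrate_eog_threshold, detect_blinks_pupil,
                                fit_eog_blink, match_events,
                                threshold_crossings, time_blink_eog,
                                time_blink_pupil)
from blinkdeconv.synthetic import generate_ocular_channels


def _schedule_with_blinks(blinks):
    """blinks: list of (onset_s, offset_s)."""
    rows = [(4.0, 5.0, "stimulus", "face", "NA", "NA", 0, 0)]
    for k, (on, off) in enumerate(blinks):
        rows.append((on, off, "blink", "face", "spontaneous", "NA", k, 0))
    return pd.DataFrame(rows, columns=COLUMNS)


def _ocular(blinks, seed=5, **kw):
    cfg = bd.SimulationConfig(n_blocks=2, seed=0)
    sched = _schedule_with_blinks(blinks)
    return generate_ocular_channels(cfg, sched, np.random.default_rng(seed),
                                    **kw)


class TestDetection:
    def test_clean_traces_detect_nothing(self):
        oc = _ocular([])
        res = detect_blinks_pupil(oc.pupil, oc.eog, oc.rate)
        assert res.blinks == [] and res.ambiguous_intervals == []

    def test_blink_present_in_both_channels_is_detected_once(self):
        oc = _ocular([(4.3, 4.45)])
        res = detect_blinks_pupil(oc.pupil, oc.eog, oc.rate)
        assert len(res.blinks) == 1
        assert res.ambiguous_intervals == []

    def test_pupil_dropout_without_eog_artifact_is_flagged_ambiguous(self):
        oc = _ocular([])
        pupil = oc.pupil.copy()
        pupil[3000:3100] = np.nan   # tracking dropout, no EOG artifact
        res = detect_blinks_pupil(pupil, oc.eog, oc.rate)
        assert res.blinks == []
        assert len(res.ambiguous_intervals) == 1

    def test_misaligned_traces_raise(self):
        with pytest.raises(AlignmentError):
            detect_blinks_pupil(np.zeros(100), np.zeros(99), 500.0)


class TestPupilTiming:
    def test_onset_matches_finite_difference_oracle_and_schedule(self):
        oc = _ocular([(4.3, 4.45)], pupil_noise_sd=0.0)
        losses = np.flatnonzero(~np.isfinite(oc.pupil))
        on, off = time_blink_pupil(oc.pupil, oc.rate,
                                   (losses[0], losses[-1] + 1))
        # oracle: most negative second difference of the closing ramp
        p = np.where(np.isfinite(oc.pupil), oc.pupil, 0.0)
        d2 = np.diff(p, 2)
        pre = slice(losses[0] - 100, losses[0] - 5)
        oracle = (pre.start + np.argmin(d2[pre]) + 1) / oc.rate
        assert abs(on - oracle) <= 1.5 / oc.rate
        assert abs(on - 4.3) < 0.012
        assert abs(off - 4.45) < 0.012

    def test_instantaneous_dropout_uses_last_valid_sample(self):
        rate = 500.0
        pupil = np.full(4000, 1000.0)
        pupil[2000:2100] = np.nan    # step loss with no closing ramp
        on, off = time_blink_pupil(pupil, rate, (2000, 2100))
        assert on == pytest.approx(1999 / rate)

    def test_symmetric_ramps_recover_occlusion_duration(self):
        for dur in (0.12, 0.2, 0.3):
            oc = _ocular([(4.3, 4.3 + dur)], pupil_noise_sd=0.0)
            losses = np.flatnonzero(~np.isfinite(oc.pupil))
            on, off = time_blink_pupil(oc.pupil, oc.rate,
                                       (losses[0], losses[-1] + 1))
            assert abs((off - on) - dur) <= 2.5 / oc.rate

    def test_unterminated_loss_raises(self):
        pupil = np.full(1000, 1000.0)
        pupil[500:] = np.nan
        with pytest.raises(UnterminatedBlinkError):
            time_blink_pupil(pupil, 500.0, (500, 1000))


class TestEogTiming:
    def _trapezoid_trace(self, rng, drift=True, height=100.0, rise=0.04,
                         sustain=0.08):
        rate, n = 500.0, 2000
        t = np.arange(n) / rate
        on, off = 2.0, 2.0 + rise + sustain  # half-height crossings
        up = np.clip((t - (on - rise / 2)) / rise, 0, 1)
        down = np.clip(((off + rise / 2) - t) / rise, 0, 1)
        trap = height * np.minimum(up, down)
        base = 8.0 * (t - 2.0) ** 3 - 5.0 * (t - 2.0) if drift else 0.0
        return t, trap + base + 0.5 * rng.standard_normal(n), rate, on, off

    def test_trapezoid_with_cubic_drift_is_timed_within_8ms(self, rng):
        _, eog, rate, on, off = self._trapezoid_trace(rng)
        got_on, got_off = time_blink_eog(eog, rate, 2.05, threshold_uv=50.0)
        assert abs(got_on - on) <= 0.008
        assert abs(got_off - off) <= 0.008

    def test_pure_polynomial_has_no_crossing(self, rng):
        rate, n = 500.0, 2000
        t = np.arange(n) / rate
        eog = 20.0 * (t - 2.0) ** 2 + 0.2 * rng.standard_normal(n)
        with pytest.raises(TimingFailureError):
            time_blink_eog(eog, rate, 2.0, threshold_uv=50.0)

    def test_zero_drift_yields_negligible_polynomial(self, rng):
        _, eog, rate, _, _ = self._trapezoid_trace(rng, drift=False)
        fit = fit_eog_blink(eog, rate, 2.05)
        assert np.abs(fit.baseline).max() < 0.01 * fit.params[4]


class TestCalibration:
    def test_rectangular_artifacts_return_smallest_fraction(self):
        # noiseless rectangles spanning the true duration: every threshold
        # inside (0, height) recovers the duration exactly
        rate = 500.0
        eog = np.zeros(5000)
        blinks = []
        for k, (on, dur) in enumerate([(2.0, 0.15), (5.0, 0.2), (8.0, 0.12)]):
            i0, i1 = int(on * rate), int((on + dur) * rate)
            eog[i0:i1] = 100.0
            blinks.append(BlinkEvent(on, on + dur))
        eog = np.concatenate([eog, np.zeros(2000)])
        sess = [{"eog": eog, "rate": rate, "blinks": blinks}]
        frac = calibrate_eog_threshold(sess, grid=np.arange(5.0, 100.0, 5.0))
        assert frac == 5.0

    def test_trapezoid_artifacts_recover_gridsearch_optimum(self, rng):
        # the generator's trapezoid crosses half height exactly at the blink
        # onset/offset, so the calibrated fraction should sit near 50%
        cfg = bd.SimulationConfig(n_blocks=2, seed=0)
        blink_times = [(3.0 + k * 1.0, 3.0 + k * 1.0 + 0.12 + 0.02 * k)
                       for k in range(6)]
        sched = _schedule_with_blinks(blink_times)
        oc = generate_ocular_channels(cfg, sched, np.random.default_rng(2),
                                      eog_noise_sd=0.5, drift_amp_uv=5.0)
        blinks = [BlinkEvent(on, off) for on, off in blink_times]
        sess = [{"eog": oc.eog, "rate": oc.rate, "blinks": blinks}]
        grid = np.arange(5.0, 100.0, 5.0)
        frac = calibrate_eog_threshold(sess, grid=grid)

        # independent grid-search oracle on the raw constructed artifacts
        med = np.median([100.0])  # generator height scale, uniform 0.8-1.2
        errs = []
        for f in grid:
            thr = f / 100.0 * med
            diffs = []
            for on, off in blink_times:
                i = np.arange(len(oc.eog)) / oc.rate
                above = (oc.eog > thr) & (i > on - 0.3) & (i < off + 0.3)
                if above.any():
                    k0, k1 = np.flatnonzero(above)[[0, -1]]
                    diffs.append(abs((k1 - k0) / oc.rate - (off - on)))
            errs.append(np.mean(diffs) if diffs else np.inf)
        oracle = grid[int(np.argmin(errs))]
        assert abs(frac - oracle) <= 10.0

    def test_default_fraction_is_22_percent(self):
        assert DEFAULT_EOG_THRESHOLD_PERCENT == 22.0


class TestMatching:
    def test_latency_matching_pairs_within_tolerance_only(self):
        res = match_events([350.0, 550.0, 750.0], [360.0, 540.0, 900.0],
                           tolerance_ms=50.0)
        pairs = set(zip(res.gap_indices, res.blink_indices))
        assert pairs == {(0, 0), (1, 1)}
        assert res.n_pairs == 2 and not res.flagged

    def test_identical_lists_pair_fully_with_zero_mean_difference(self):
        vals = [100.0, 300.0, 700.0]
        res = match_events(vals, vals, tolerance_ms=15.0)
        assert res.n_pairs == 3
        assert res.mean_gap == res.mean_blink

    def test_no_eligible_pairing_flags_exclusion(self):
        res = match_events([100.0], [200.0], tolerance_ms=50.0)
        assert res.n_pairs == 0 and res.flagged

    def test_empty_inputs_are_not_an_error(self):
        res = match_events([], [120.0], tolerance_ms=50.0)
        assert res.n_pairs == 0 and not res.flagged

    def test_matching_is_a_matching_and_respects_tolerance(self, rng):
        for _ in range(20):
            g = rng.uniform(0, 1000, rng.integers(1, 12))
            b = rng.uniform(0, 1000, rng.integers(1, 12))
            res = match_events(g, b, tolerance_ms=50.0)
            assert len(set(res.gap_indices)) == res.n_pairs
            assert len(set(res.blink_indices)) == res.n_pairs
            assert all(abs(d) <= 50.0 for d in res.pair_differences)
            if res.n_pairs:
                assert abs(res.mean_gap - res.mean_blink) <= 50.0
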