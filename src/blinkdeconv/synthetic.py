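"""Synthetic ECoG sessions with known ground truth.

Emulates the interrupted-stimulation task: object images shown at 1 Hz in
10-trial blocks separated by 3 s gray-screen baselines; in gap blocks, 60% of
trials carry a 100-200 ms blank ("gap") at 350/550/750 ms after stimulus
onset; in voluntary-blink blocks the subject blinks about once per second;
spontaneous blinks occur in the remaining trials. Ground-truth per-electrode
response kernels (stimulus response, disappearance dip, reappearance
overshoot) are linearly superposed to form high-frequency-broadband (HFB)
traces, so FIR deconvolution can be validated exactly. A raw-fidelity tier
synthesizes 500 Hz field potentials whose 70-150 Hz amplitude follows the
HFB profile, and an ocular tier synthesizes pupil-size and EOG channels with
blink artifacts.

Two fidelity tiers keep tests cheap: ``generate_hfb_session`` produces
percent-change HFB directly (exactly linear in events); ``generate_raw_session``
produces raw voltage for testing the envelope-extraction front end.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .events import COLUMNS, empty_table
from .signal_hfb import HFBTimecourse, RawRecording

__all__ = [
    "NoiseModel",
    "TruncatedLogNormal",
    "SimulationConfig",
    "ElectrodeTruth",
    "GroundTruth",
    "InvalidConfigError",
    "generate_schedule",
    "generate_hfb_session",
    "generate_raw_session",
    "generate_ocular_channels",
    "ar1_noise",
    "one_over_f_noise",
    "amplitude_modulated_carrier",
    "baseline_intervals_for",
]

# Location of the peak |second derivative| of the quintic smootherstep
# 6u^5 - 15u^4 + 10u^3, at u = (6 - 2*sqrt(3)) / 12 (root of f''' = 0).
SMOOTHERSTEP_PEAK_ACCEL_U = (6.0 - 2.0 * np.sqrt(3.0)) / 12.0


class InvalidConfigError(ValueError):
    """Simulation configuration violates its invariants."""


def _smootherstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * u * (u * (6.0 * u - 15.0) + 10.0)


@dataclass(frozen=True)
class NoiseModel:
    """Additive noise on the HFB trace (percent-change units).

    ``ar1``: first-order autoregressive process with stationary SD ``sd``;
    positive autocorrelation mimics real HFB. ``one_over_f``: spectrum
    shaped as f**(-exponent/2) in amplitude, scaled to SD ``sd``.
    """

    kind: str = "ar1"  # 'ar1' | 'one_over_f' | 'none'
    ar_coef: float = 0.9
    sd: float = 5.0
    exponent: float = 1.0

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "none" or self.sd == 0:
            return np.zeros(n)
        if self.kind == "ar1":
            return ar1_noise(rng, n, self.ar_coef, self.sd)
        if self.kind == "one_over_f":
            return one_over_f_noise(rng, n, self.exponent, self.sd)
        raise InvalidConfigError(f"unknown noise kind {self.kind!r}")


def ar1_noise(rng: np.random.Generator, n: int, coef: float, sd: float) -> np.ndarray:
    """Stationary AR(1) noise: x_t = coef*x_{t-1} + eps, Var(x) = sd**2."""
    if not (-1.0 < coef < 1.0):
        raise InvalidConfigError("AR(1) coefficient must lie in (-1, 1)")
    eps = rng.standard_normal(n) * sd * np.sqrt(1.0 - coef**2)
    return sps.lfilter([1.0], [1.0, -coef], eps)


def one_over_f_noise(rng: np.random.Generator, n: int, exponent: float, sd: float) -> np.ndarray:
    """Colored noise with amplitude spectrum ~ f**(-exponent/2)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


@dataclass(frozen=True)
class TruncatedLogNormal:
    """Log-normal truncated to [lo_ms, hi_ms], parameterized by its median."""

    median_ms: float
    sigma: float
    lo_ms: float
    hi_ms: float

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        mu = np.log(self.median_ms)
        out = np.empty(n)
        todo = np.arange(n)
        # rejection sampling; acceptance region is wide for the defaults
        for _ in range(1000):
            if todo.size == 0:
                break
            draw = rng.lognormal(mu, self.sigma, todo.size)
            ok = (draw >= self.lo_ms) & (draw <= self.hi_ms)
            out[todo[ok]] = draw[ok]
            todo = todo[~ok]
        if todo.size:
            out[todo] = np.clip(
                rng.lognormal(mu, self.sigma, todo.size), self.lo_ms, self.hi_ms
            )
        return out


@dataclass(frozen=True)
class SimulationConfig:
    n_blocks: int = 32
    trials_per_block: int = 10
    stimulus_period_ms: float = 1000.0
    interblock_blank_ms: float = 3000.0
    gap_latencies_ms: tuple = (350.0, 550.0, 750.0)
    gap_fraction: float = 0.6
    gap_duration_range_ms: tuple = (100.0, 200.0)
    blink_latency: TruncatedLogNormal = TruncatedLogNormal(450.0, 0.5, 50.0, 900.0)
    blink_duration: TruncatedLogNormal = TruncatedLogNormal(150.0, 0.35, 80.0, 400.0)
    voluntary_block_fraction: float = 12.0 / 32.0
    voluntary_blink_prob: float = 0.9
    spontaneous_blink_prob: float = 0.2
    category_probs: tuple = (("face", 0.2), ("nonface", 0.6), ("animal", 0.2))
    gap_condition_scale: tuple = ()  # e.g. (("gray", 0.8), ("gradual", 0.9))
    noise: NoiseModel = NoiseModel()
    sampling_rate_raw: float = 500.0
    hfb_rate: float = 250.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise InvalidConfigError("need at least one block and one trial")
        if any(not (0 <= g < self.stimulus_period_ms) for g in self.gap_latencies_ms):
            raise InvalidConfigError("gap latencies must lie in [0, stimulus_period)")
        lo, hi = self.gap_duration_range_ms
        if lo <= 0 or hi < lo:
            raise InvalidConfigError("gap durations must be positive and ordered")
        if not (0 <= self.voluntary_block_fraction <= 1):
            raise InvalidConfigError("voluntary_block_fraction must be in [0, 1]")
        if not (0 <= self.gap_fraction <= 1):
            raise InvalidConfigError("gap_fraction must be in [0, 1]")
        probs = dict(self.category_probs)
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise InvalidConfigError("category probabilities must sum to 1")

    # timeline helpers -----------------------------------------------------
    @property
    def block_duration_s(self) -> float:
        return self.trials_per_block * self.stimulus_period_ms / 1000.0

    @property
    def blank_s(self) -> float:
        return self.interblock_blank_ms / 1000.0

    def block_start_s(self, b: int) -> float:
        return self.blank_s + b * (self.block_duration_s + self.blank_s)

    @property
    def session_duration_s(self) -> float:
        return self.block_start_s(self.n_blocks)

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


def baseline_intervals_for(config: SimulationConfig, settle_s: float = 1.6):
    """Inter-block gray-screen intervals usable as 0% baseline.

    The first ``settle_s`` of each blank is trimmed: responses to the last
    stimulus (1.5 s FIR window) bleed into the blank.
    """
    out = [(0.2, config.blank_s - 0.05)]
    for b in range(config.n_blocks):
        end = config.block_start_s(b) + config.block_duration_s
        out.append((end + settle_s, end + config.blank_s - 0.05))
    return [iv for iv in out if iv[1] > iv[0]]


# ---------------------------------------------------------------------------
# ground truth kernels
# ---------------------------------------------------------------------------

def _bump(lags_s: np.ndarray, amp: float, peak_s: float, width_s: float,
          onset_s: float = 0.0) -> np.ndarray:
    k = amp * np.exp(-0.5 * ((lags_s - peak_s) / width_s) ** 2)
    k[lags_s < onset_s] = 0.0
    return k


def stimulus_kernel(lags_s: np.ndarray, peak_amp: float = 25.0,
                    sustained_amp: float = 8.0) -> np.ndarray:
    """Transient-plus-decaying-sustained visual response, percent change."""
    transient = _bump(lags_s, peak_amp, 0.15, 0.05, onset_s=0.04)
    ramp = 1.0 / (1.0 + np.exp(-(lags_s - 0.12) / 0.02))
    sustained = sustained_amp * ramp * np.exp(-np.maximum(lags_s - 0.12, 0) / 0.9)
    sustained[lags_s < 0.04] = 0.0
    return transient + sustained


def dip_kernel(lags_s: np.ndarray, amp: float = -12.0) -> np.ndarray:
    """Disappearance-locked activation dip (negative bump after onset)."""
    return _bump(lags_s, amp, 0.12, 0.05, onset_s=0.03)


def overshoot_kernel(lags_s: np.ndarray, amp: float = 15.0) -> np.ndarray:
    """Reappearance-locked overshoot (positive bump after offset)."""
    return _bump(lags_s, amp, 0.14, 0.055, onset_s=0.03)


@dataclass
class ElectrodeTruth:
    """Ground-truth kernels for one electrode, on 4 ms lag grids."""

    name: str
    roi: str
    stimulus_kernels: dict      # category -> array over stim_window
    disappearance_kernels: dict  # interruption type -> array over inter_window
    reappearance_kernels: dict   # interruption type -> array over inter_window


@dataclass
class GroundTruth:
    electrodes: list
    stim_window_ms: tuple = (0.0, 1500.0)
    inter_window_ms: tuple = (-250.0, 500.0)
    bin_ms: float = 4.0

    @property
    def n_electrodes(self) -> int:
        return len(self.electrodes)

    def lags_s(self, window_ms) -> np.ndarray:
        n = int(np.floor((window_ms[1] - window_ms[0]) / self.bin_ms))
        return (window_ms[0] + self.bin_ms * np.arange(n)) / 1000.0

    @classmethod
    def from_rois(cls, rois: Sequence[str], *,
                  stim_window_ms=(0.0, 1500.0), inter_window_ms=(-250.0, 500.0),
                  bin_ms: float = 4.0,
                  face_gain: float = 1.6,
                  gap_overshoot: float = 15.0, blink_overshoot: float = 15.0,
                  gap_dip: float = -12.0, blink_dip: float = -12.0,
                  highlevel_blink_overshoot: float = 0.0,
                  early_blink_dip_scale: float = 1.3) -> "GroundTruth":
        """Canonical truth encoding the published qualitative morphology.

        Early retinotopic sites (V1-V4, VO) dip and overshoot for every
        interruption type, with blink dips slightly deeper than gap dips.
        High-level sites (FC / N-FC) overshoot for gaps only
        (``highlevel_blink_overshoot`` defaults to 0) and show shallow dips.
        """
        self = cls(electrodes=[], stim_window_ms=tuple(stim_window_ms),
                   inter_window_ms=tuple(inter_window_ms), bin_ms=bin_ms)
        s_lags = self.lags_s(self.stim_window_ms)
        i_lags = self.lags_s(self.inter_window_ms)
        early = {"V1", "V2", "V3", "V4", "VO"}
        for i, roi in enumerate(rois):
            if roi in early:
                stim = {
                    "face": stimulus_kernel(s_lags),
                    "nonface": stimulus_kernel(s_lags),
                    "animal": stimulus_kernel(s_lags),
                }
                dis = {
                    "gap": dip_kernel(i_lags, gap_dip),
                    "voluntary": dip_kernel(i_lags, blink_dip * early_blink_dip_scale),
                    "spontaneous": dip_kernel(i_lags, blink_dip * early_blink_dip_scale),
                }
                rea = {
                    "gap": overshoot_kernel(i_lags, gap_overshoot),
                    "voluntary": overshoot_kernel(i_lags, blink_overshoot),
                    "spontaneous": overshoot_kernel(i_lags, blink_overshoot),
                }
            else:  # high-level: FC / N-FC
                face_amp = 25.0 * (face_gain if roi == "FC" else 1.0)
                stim = {
                    "face": stimulus_kernel(s_lags, peak_amp=face_amp),
                    "nonface": stimulus_kernel(s_lags),
                    "animal": stimulus_kernel(s_lags),
                }
                dis = {
                    "gap": dip_kernel(i_lags, 0.4 * gap_dip),
                    "voluntary": dip_kernel(i_lags, 0.4 * blink_dip),
                    "spontaneous": dip_kernel(i_lags, 0.4 * blink_dip),
                }
                rea = {
                    "gap": overshoot_kernel(i_lags, gap_overshoot),
                    "voluntary": overshoot_kernel(i_lags, highlevel_blink_overshoot),
                    "spontaneous": overshoot_kernel(i_lags, highlevel_blink_overshoot),
                }
            self.electrodes.append(ElectrodeTruth(
                name=f"e{i:03d}_{roi}", roi=roi, stimulus_kernels=stim,
                disappearance_kernels=dis, reappearance_kernels=rea))
        return self

    @classmethod
    def null(cls, n_electrodes: int, *, with_stimulus: bool = True,
             stim_window_ms=(0.0, 1000.0), inter_window_ms=(-100.0, 400.0),
             bin_ms: float = 4.0) -> "GroundTruth":
        """Flat interruption kernels: gaps and blinks are exchangeable."""
        self = cls(electrodes=[], stim_window_ms=tuple(stim_window_ms),
                   inter_window_ms=tuple(inter_window_ms), bin_ms=bin_ms)
        s_lags = self.lags_s(self.stim_window_ms)
        zeros = np.zeros(self.lags_s(self.inter_window_ms).size)
        stim = stimulus_kernel(s_lags) if with_stimulus else np.zeros_like(s_lags)
        for i in range(n_electrodes):
            self.electrodes.append(ElectrodeTruth(
                name=f"null{i:03d}", roi="unassigned",
                stimulus_kernels={c: stim.copy() for c in ("face", "nonface", "animal")},
                disappearance_kernels={t: zeros.copy() for t in ("gap", "voluntary", "spontaneous")},
                reappearance_kernels={t: zeros.copy() for t in ("gap", "voluntary", "spontaneous")},
            ))
        return self


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------

def generate_schedule(config: SimulationConfig,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw a block-structured event table from the task model.

    Blocks are either gap blocks (60% of trials carry one gap at one of the
    configured latencies) or voluntary-blink blocks (about one blink per
    second). Spontaneous blinks land only in gap-free trials, so a gap and a
    blink never overlap within a trial. Animal trials are labeled for
    downstream exclusion.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    period = config.stimulus_period_ms / 1000.0
    n_vol = int(round(config.voluntary_block_fraction * config.n_blocks))
    vol_blocks = set(rng.choice(config.n_blocks, size=n_vol, replace=False).tolist())
    cats, probs = zip(*config.category_probs)
    rows = []
    trial = 0
    for b in range(config.n_blocks):
        t0 = config.block_start_s(b)
        for i in range(config.trials_per_block):
            onset = t0 + i * period
            category = str(rng.choice(cats, p=probs))
            rows.append((onset, onset + period, "stimulus", category,
                         "NA", "NA", trial, b))
            if b in vol_blocks:
                if rng.random() < config.voluntary_blink_prob:
                    rows.append(_blink_row(config, rng, onset, category,
                                           "voluntary", trial, b))
            else:
                if rng.random() < config.gap_fraction:
                    lat = float(rng.choice(config.gap_latencies_ms)) / 1000.0
                    lo, hi = config.gap_duration_range_ms
                    dur = rng.uniform(lo, hi) / 1000.0
                    lum = "black" if rng.random() < 0.5 else "gray"
                    ramp = "abrupt" if rng.random() < 0.5 else "gradual"
                    rows.append((onset + lat, onset + lat + dur, "gap",
                                 category, lum, ramp, trial, b))
                elif rng.random() < config.spontaneous_blink_prob:
                    rows.append(_blink_row(config, rng, onset, category,
                                           "spontaneous", trial, b))
            trial += 1
    table = pd.DataFrame(rows, columns=COLUMNS) if rows else empty_table()
    return table.sort_values(["onset_s", "kind"], kind="stable").reset_index(drop=True)


def _blink_row(config, rng, trial_onset, category, subtype, trial, block):
    period = config.stimulus_period_ms
    lat = config.blink_latency.sample(rng, 1)[0]
    dur = config.blink_duration.sample(rng, 1)[0]
    lat = min(lat, period - dur - 10.0)  # keep the blink inside its trial
    lat = max(lat, 0.0)
    on = trial_onset + lat / 1000.0
    return (on, on + dur / 1000.0, "blink", category, subtype, "NA", trial, block)


# ---------------------------------------------------------------------------
# HFB-level session (exactly linear in events)
# ---------------------------------------------------------------------------

def generate_hfb_session(config: SimulationConfig, truth: GroundTruth,
                         rng: np.random.Generator | None = None,
                         schedule: pd.DataFrame | None = None):
    """Superpose ground-truth kernels at event times, add noise.

    Returns ``(HFBTimecourse, events)``. The noiseless trace is exactly the
    sum of lagged kernels, so deconvolution recovery can be checked to
    numerical precision.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if schedule is None:
        schedule = generate_schedule(config, rng)
    rate = config.hfb_rate
    n = int(round(config.session_duration_s * rate))
    scale = dict(config.gap_condition_scale)
    values = np.zeros((truth.n_electrodes, n))
    stim_start = int(round(truth.stim_window_ms[0] / truth.bin_ms))
    int_start = int(round(truth.inter_window_ms[0] / truth.bin_ms))

    stim = schedule[schedule["kind"] == "stimulus"]
    inters = schedule[schedule["kind"] != "stimulus"]
    for c, el in enumerate(truth.electrodes):
        tr = values[c]
        for _, ev in stim.iterrows():
            k = el.stimulus_kernels[ev["category"]]
            _add_kernel(tr, k, int(round(ev["onset_s"] * rate)) + stim_start)
        for _, ev in inters.iterrows():
            itype = ev["subtype"] if ev["kind"] == "blink" else "gap"
            gain = 1.0
            if ev["kind"] == "gap":
                gain *= scale.get(ev["subtype"], 1.0) * scale.get(ev["ramp"], 1.0)
            _add_kernel(tr, gain * el.disappearance_kernels[itype],
                        int(round(ev["onset_s"] * rate)) + int_start)
            _add_kernel(tr, gain * el.reappearance_kernels[itype],
                        int(round(ev["offset_s"] * rate)) + int_start)
        tr += config.noise.sample(rng, n)

    hfb = HFBTimecourse(
        values=values, rate=rate,
        channel_names=[el.name for el in truth.electrodes],
        rejection_mask=np.zeros(n, dtype=bool),
        baseline_intervals=baseline_intervals_for(config),
    )
    return hfb, schedule


def _add_kernel(trace: np.ndarray, kernel: np.ndarray, i0: int) -> None:
    i1 = i0 + kernel.size
    k0 = max(0, -i0)
    k1 = kernel.size - max(0, i1 - trace.size)
    if k1 > k0:
        trace[i0 + k0:i0 + k1] += kernel[k0:k1]


# ---------------------------------------------------------------------------
# raw-level session
# ---------------------------------------------------------------------------

def amplitude_modulated_carrier(rate: float, n: int, band, modulator: np.ndarray,
                                rng: np.random.Generator) -> np.ndarray:
    """Band-limited noise carrier whose instantaneous amplitude follows
    ``modulator`` (must be non-negative, length ``n``)."""
    taps = sps.firwin(251, band, pass_zero=False, fs=rate)
    carrier = sps.filtfilt(taps, [1.0], rng.standard_normal(n))
    carrier /= np.abs(sps.hilbert(carrier)).mean()
    return modulator * carrier


def generate_raw_session(config: SimulationConfig, truth: GroundTruth,
                         rng: np.random.Generator | None = None,
                         schedule: pd.DataFrame | None = None,
                         *, carrier_rms_uv: float = 8.0,
                         background_rms_uv: float = 20.0,
                         modulation_depth: float = 1.0):
    """Raw 500 Hz voltages: 1/f background plus a 70-150 Hz carrier whose
    amplitude tracks the (noise-free) ground-truth HFB profile.

    Returns ``(RawRecording, events)``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if schedule is None:
        schedule = generate_schedule(config, rng)
    quiet = config.replace(noise=NoiseModel(kind="none"))
    hfb, _ = generate_hfb_session(quiet, truth, rng, schedule=schedule)
    rate = config.sampling_rate_raw
    up = int(round(rate / config.hfb_rate))
    n = hfb.values.shape[1] * up
    samples = np.zeros((truth.n_electrodes, n))
    for c in range(truth.n_electrodes):
        profile = np.repeat(hfb.values[c], up)
        amp = np.maximum(1.0 + modulation_depth * profile / 100.0, 0.0)
        carrier = amplitude_modulated_carrier(rate, n, (70.0, 150.0), amp, rng)
        background = one_over_f_noise(rng, n, 1.0, background_rms_uv)
        samples[c] = background + carrier_rms_uv * carrier
    rec = RawRecording(samples=samples, rate=rate,
                       channel_names=[el.name for el in truth.electrodes])
    return rec, schedule


# ---------------------------------------------------------------------------
# ocular channels
# ---------------------------------------------------------------------------

@dataclass
class OcularTraces:
    pupil: np.ndarray      # arbitrary units; NaN while tracking is lost
    eog: np.ndarray        # microvolts
    rate: float
    true_onsets_s: np.ndarray
    true_offsets_s: np.ndarray


def generate_ocular_channels(config: SimulationConfig, schedule: pd.DataFrame,
                             rng: np.random.Generator | None = None,
                             *, rate: float = 500.0, ramp_ms: float = 40.0,
                             pupil_baseline: float = 1000.0,
                             pupil_noise_sd: float = 1.0,
                             eog_height_uv: float = 100.0,
                             eog_rise_ms: float = 40.0,
                             eog_noise_sd: float = 2.0,
                             drift_amp_uv: float = 30.0) -> OcularTraces:
    """Pupil-size and EOG traces with blink artifacts at the scheduled times.

    Pupil closing/opening ramps follow a quintic smootherstep whose peak
    |acceleration| lands exactly on the scheduled blink onset/offset, so the
    peak-acceleration timing rule recovers the schedule. Tracking is lost
    (NaN) while the lid covers the pupil. The EOG trace is a slow drift plus
    a per-blink trapezoid whose half-height support spans the blink.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n = int(round(config.session_duration_s * rate))
    t = np.arange(n) / rate
    ramp = ramp_ms / 1000.0
    u_star = SMOOTHERSTEP_PEAK_ACCEL_U

    pupil = pupil_baseline + pupil_noise_sd * rng.standard_normal(n)
    drift = one_over_f_noise(rng, n, 2.0, drift_amp_uv)
    taps = sps.firwin(501, 0.8, fs=rate)
    drift = sps.filtfilt(taps, [1.0], drift)
    eog = drift + eog_noise_sd * rng.standard_normal(n)

    blinks = schedule[schedule["kind"] == "blink"]
    onsets = blinks["onset_s"].to_numpy()
    offsets = blinks["offset_s"].to_numpy()
    for on, off in zip(onsets, offsets):
        c0 = on - u_star * ramp          # closing ramp start
        r0 = off - u_star * ramp         # reopening ramp start
        _apply_ramp(pupil, t, c0, ramp, closing=True)
        _apply_ramp(pupil, t, r0, ramp, closing=False)
        lost = (t >= c0 + ramp) & (t < r0)
        pupil[lost] = np.nan
        height = eog_height_uv * rng.uniform(0.8, 1.2)
        eog += _trapezoid(t, on, off, eog_rise_ms / 1000.0, height)
    return OcularTraces(pupil=pupil, eog=eog, rate=rate,
                        true_onsets_s=onsets, true_offsets_s=offsets)


def _apply_ramp(pupil, t, start, ramp, closing):
    sel = (t >= start) & (t < start + ramp)
    u = (t[sel] - start) / ramp
    f = _smootherstep(u)
    frac = (1.0 - f) if closing else f
    pupil[sel] = pupil[sel] * frac


def _trapezoid(t, on, off, rise, height):
    """Trapezoid with half-height crossings at ``on`` and ``off``."""
    up = np.clip((t - (on - rise / 2)) / rise, 0.0, 1.0)
    down = np.clip(((off + rise / 2) - t) / rise, 0.0, 1.0)
    return height * np.minimum(up, down)
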