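"""Blink detection and timing from pupil and EOG traces; event matching.

A blink is registered only when a pupil-tracking loss co-occurs with an EOG
artifact (within a configurable window); pupil losses without EOG support
are treated as tracking dropouts and flag their interval as ambiguous.
Timing follows the pupil: blink onset is the peak acceleration of the
pupil-size decrease before signal loss (falling back to the last valid
sample for instantaneous dropouts), and blink offset is the peak
acceleration of the increase after reacquisition.

For sessions without eye tracking, EOG-based timing fits each +-750 ms
peri-blink segment with a fifth-degree polynomial baseline plus a trapezoid
artifact model, removes the baseline, and thresholds the residual; the
threshold is a fraction of the session's median spontaneous-artifact
amplitude, calibrated on sessions that have both modalities (22% when no
calibration data are available).

Gap/blink matching pairs events iteratively under a tolerance (50 ms onset
latency or 15 ms duration), each iteration choosing the eligible pair that
brings the paired-subset means closest together.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize as spo

DEFAULT_EOG_THRESHOLD_PERCENT = 22.0


class AlignmentError(ValueError):
    pass


class UnterminatedBlinkError(ValueError):
    pass


class TimingFailureError(ValueError):
    pass


class NoDataError(ValueError):
    pass


@dataclass
class BlinkEvent:
    onset_s: float
    offset_s: float
    subtype: str = "spontaneous"   # spontaneous | voluntary
    source: str = "pupil"          # pupil | eog
    trial_index: int = -1

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class DetectionResult:
    blinks: list
    ambiguous_intervals: list      # (start_s, end_s) pupil losses w/o EOG


# ---------------------------------------------------------------------------
# pupil-based detection and timing
# ---------------------------------------------------------------------------

def _smooth(x: np.ndarray, rate: float, width_ms: float = 10.0) -> np.ndarray:
    k = max(1, int(round(width_ms / 1000.0 * rate)))
    if k <= 1:
        return x
    kernel = np.ones(k) / k
    return np.convolve(x, kernel, mode="same")


def _second_derivative(x: np.ndarray, rate: float) -> np.ndarray:
    """Central-difference second derivative of the 10 ms-smoothed trace."""
    xs = _smooth(x, rate)
    d2 = np.empty_like(xs)
    d2[1:-1] = xs[2:] - 2 * xs[1:-1] + xs[:-2]
    d2[0] = d2[-1] = 0.0
    return d2 * rate * rate


def _loss_runs(lost: np.ndarray):
    """[start, end) index pairs of contiguous True runs."""
    padded = np.concatenate([[False], lost, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[::2], edges[1::2]))


def find_pupil_losses(pupil: np.ndarray, *, min_duration_samples: int = 3):
    lost = ~np.isfinite(pupil) | (pupil <= 0)
    return [(a, b) for a, b in _loss_runs(lost) if b - a >= min_duration_samples]


def time_blink_pupil(pupil: np.ndarray, rate: float, loss,
                     *, search_ms: float = 120.0,
                     peak_z: float = 5.0):
    """(onset_s, offset_s) of one blink from a pupil-loss interval.

    ``loss`` is the [start, end) sample pair of the tracking loss. Onset is
    the most negative second derivative in the window preceding the loss
    (the peak acceleration of the decrease); without a clear peak — an
    instantaneous dropout — the last valid pre-loss sample. Offset is the
    mirrored rule after reacquisition. Raises
    :class:`UnterminatedBlinkError` when the recording ends mid-loss.
    """
    i0, i1 = loss
    n = pupil.size
    if i1 >= n:
        raise UnterminatedBlinkError("signal loss extends to recording end")
    w = int(round(search_ms / 1000.0 * rate))
    d2 = _second_derivative(np.nan_to_num(pupil, nan=0.0), rate)
    valid = np.isfinite(pupil) & (pupil > 0)
    scale = 1.4826 * np.median(np.abs(d2[valid] - np.median(d2[valid]))) \
        if valid.any() else 0.0

    pre = np.arange(max(0, i0 - w), i0)
    pre = pre[valid[pre]]
    # drop samples whose smoothing window touches the loss
    pre = pre[pre < i0 - max(1, int(round(0.01 * rate)))]
    if pre.size >= 3 and d2[pre].min() < -peak_z * scale:
        onset = pre[np.argmin(d2[pre])] / rate
    else:
        last_valid = np.flatnonzero(valid[:i0])
        if last_valid.size == 0:
            raise TimingFailureError("no valid sample before loss")
        onset = last_valid[-1] / rate

    post = np.arange(i1, min(n, i1 + w))
    post = post[valid[post]]
    post = post[post > i1 + max(1, int(round(0.01 * rate)))]
    if post.size >= 3 and d2[post].max() > peak_z * scale:
        offset = post[np.argmax(d2[post])] / rate
    else:
        first_valid = np.flatnonzero(valid[i1:])
        if first_valid.size == 0:
            raise UnterminatedBlinkError("no reacquisition before recording end")
        offset = (i1 + first_valid[0]) / rate
    return onset, offset


def detect_blinks_pupil(pupil: np.ndarray, eog: np.ndarray, rate: float,
                        *, co_window_ms: float = 100.0,
                        eog_z: float = 5.0) -> DetectionResult:
    """Pupil-loss candidates confirmed by a concurrent EOG artifact.

    The artifact score is a robust z of the EOG after removing a 1 s
    moving-average baseline — blink artifacts are fast relative to the slow
    periocular drift, which would otherwise swamp the scale estimate.
    """
    if pupil.shape != eog.shape:
        raise AlignmentError("pupil and EOG traces must be time-aligned")
    losses = find_pupil_losses(pupil)
    from scipy.ndimage import uniform_filter1d
    resid = eog - uniform_filter1d(eog, size=max(3, int(round(rate))))
    mad = 1.4826 * np.median(np.abs(resid - np.median(resid)))
    z = (resid - np.median(resid)) / (mad if mad > 0 else 1.0)
    pad = int(round(co_window_ms / 1000.0 * rate))
    blinks, ambiguous = [], []
    for a, b in losses:
        lo, hi = max(0, a - pad), min(eog.size, b + pad)
        if np.abs(z[lo:hi]).max() < eog_z:
            ambiguous.append((a / rate, b / rate))
            continue
        try:
            on, off = time_blink_pupil(pupil, rate, (a, b))
        except (UnterminatedBlinkError, TimingFailureError):
            ambiguous.append((a / rate, b / rate))
            continue
        blinks.append(BlinkEvent(onset_s=on, offset_s=off, source="pupil"))
    return DetectionResult(blinks=blinks, ambiguous_intervals=ambiguous)


# ---------------------------------------------------------------------------
# EOG-based timing
# ---------------------------------------------------------------------------

def _trapezoid(t, t_on, rise, plateau, fall, height):
    up = np.clip((t - t_on) / max(rise, 1e-4), 0.0, 1.0)
    down = np.clip(((t_on + rise + plateau + fall) - t) / max(fall, 1e-4), 0.0, 1.0)
    return height * np.minimum(up, down)


@dataclass
class EogFit:
    t: np.ndarray              # segment times, absolute seconds
    cleaned: np.ndarray        # segment minus fitted polynomial baseline
    baseline: np.ndarray
    params: np.ndarray         # t_on, rise, plateau, fall, height
    poly_coef: np.ndarray
    cost: float


def fit_eog_blink(eog: np.ndarray, rate: float, approx_time_s: float,
                  *, window_ms: float = 750.0, n_starts: int = 3,
                  rng=None) -> EogFit:
    """Fit polynomial(5) baseline + trapezoid around one blink.

    The polynomial is solved linearly for each trapezoid (variable
    projection); the five trapezoid parameters are optimized by bounded
    nonlinear least squares from ``n_starts`` initial onsets.
    """
    n = eog.size
    half = int(round(window_ms / 1000.0 * rate))
    c = int(round(approx_time_s * rate))
    i0, i1 = max(0, c - half), min(n, c + half)
    seg = eog[i0:i1].astype(float)
    t = np.arange(i0, i1) / rate
    tn = np.linspace(-1.0, 1.0, seg.size)         # scaled axis for the poly
    V = np.polynomial.polynomial.polyvander(tn, 5)

    amp = np.percentile(np.abs(seg - np.median(seg)), 99)
    span = t[-1] - t[0]

    def residual(p):
        trap = _trapezoid(t, *p)
        b = seg - trap
        coef, *_ = np.linalg.lstsq(V, b, rcond=None)
        return b - V @ coef

    lo = [t[0], 0.005, 0.0, 0.005, 0.0]
    hi = [t[-1] - 0.02, 0.25, span, 0.25, 20.0 * max(amp, 1.0)]
    best = None
    offsets = np.linspace(-0.12, 0.08, n_starts)
    for dt in offsets:
        p0 = [np.clip(approx_time_s + dt, lo[0], hi[0]), 0.04, 0.1, 0.04,
              max(amp, 1.0)]
        try:
            sol = spo.least_squares(residual, p0, bounds=(lo, hi))
        except ValueError:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success and best.cost == np.inf:
        raise TimingFailureError("trapezoid fit failed to converge")
    trap = _trapezoid(t, *best.x)
    coef, *_ = np.linalg.lstsq(V, seg - trap, rcond=None)
    baseline = V @ coef
    return EogFit(t=t, cleaned=seg - baseline, baseline=baseline,
                  params=best.x, poly_coef=coef, cost=float(best.cost))


def threshold_crossings(t: np.ndarray, cleaned: np.ndarray,
                        threshold: float):
    """First up-crossing and the first subsequent down-crossing."""
    above = cleaned > threshold
    if not above.any():
        raise TimingFailureError("no threshold crossing")
    k0 = int(np.argmax(above))
    rest = np.flatnonzero(~above[k0:])
    if rest.size == 0:
        raise TimingFailureError("no down-crossing after onset")
    k1 = k0 + int(rest[0])
    return float(t[k0]), float(t[k1])


def time_blink_eog(eog: np.ndarray, rate: float, approx_time_s: float,
                   threshold_uv: float, *, window_ms: float = 750.0):
    """(onset_s, offset_s) from the baseline-removed EOG artifact."""
    fit = fit_eog_blink(eog, rate, approx_time_s, window_ms=window_ms)
    return threshold_crossings(fit.t, fit.cleaned, threshold_uv)


def calibrate_eog_threshold(sessions, *, grid=None) -> float:
    """Threshold fraction (percent of the median spontaneous-artifact
    amplitude) that best predicts pupil-derived blink durations.

    ``sessions`` is a list of dicts with keys ``eog``, ``rate`` and
    ``blinks`` (pupil-timed :class:`BlinkEvent` list). The peri-blink
    trapezoid+polynomial fit is computed once per blink; the fraction grid
    is scanned on the cleaned traces. Ties return the smallest fraction.
    """
    if grid is None:
        grid = np.arange(1.0, 100.0)
    fits = []          # (session idx, fit, pupil duration)
    med_amp = {}
    for s, sess in enumerate(sessions):
        amps = []
        for ev in sess["blinks"]:
            mid = 0.5 * (ev.onset_s + ev.offset_s)
            try:
                fit = fit_eog_blink(sess["eog"], sess["rate"], mid)
            except TimingFailureError:
                continue
            fits.append((s, fit, ev.duration_s))
            amps.append(fit.params[4])
        if amps:
            med_amp[s] = float(np.median(amps))
    if not fits:
        raise NoDataError("no blinks available for calibration")

    errs = np.full(len(grid), np.inf)
    for gi, frac in enumerate(grid):
        diffs = []
        for s, fit, dur in fits:
            thr = frac / 100.0 * med_amp[s]
            try:
                on, off = threshold_crossings(fit.t, fit.cleaned, thr)
            except TimingFailureError:
                continue
            diffs.append(abs((off - on) - dur))
        if diffs:
            errs[gi] = float(np.mean(diffs))
    best = int(np.argmin(errs))    # argmin takes the first (smallest) on ties
    return float(grid[best])


# ---------------------------------------------------------------------------
# gap/blink matching
# ---------------------------------------------------------------------------

@dataclass
class MatchResult:
    gap_indices: list = field(default_factory=list)
    blink_indices: list = field(default_factory=list)
    pair_differences: list = field(default_factory=list)   # gap - blink, ms
    mean_gap: float = np.nan
    mean_blink: float = np.nan
    flagged: bool = False          # True when nothing could be paired

    @property
    def n_pairs(self) -> int:
        return len(self.gap_indices)


def match_events(gap_values, blink_values, *, tolerance_ms: float,
                 mode: str = "latency") -> MatchResult:
    """Iterative gap-blink pairing under a per-pair tolerance.

    ``gap_values`` / ``blink_values`` are onset latencies or durations in
    milliseconds (``mode`` is descriptive only; the tolerance carries the
    convention: 50 ms for latency, 15 ms for duration). Each iteration pairs
    the eligible gap-blink pair that minimizes the absolute difference of
    the paired-subset means after inclusion; ties break on the smallest
    per-pair difference, then the earliest gap. Returns equal-sized subsets;
    empty inputs give an empty (unflagged) result, non-empty inputs with no
    eligible pairing give an empty flagged result.
    """
    gaps = np.asarray(gap_values, dtype=float)
    blinks = np.asarray(blink_values, dtype=float)
    res = MatchResult()
    if gaps.size == 0 or blinks.size == 0:
        return res
    free_g = list(range(gaps.size))
    free_b = list(range(blinks.size))
    sum_g = sum_b = 0.0
    while True:
        best = None
        k = len(res.gap_indices) + 1
        for gi in free_g:
            for bi in free_b:
                d = abs(gaps[gi] - blinks[bi])
                if d > tolerance_ms:
                    continue
                crit = abs((sum_g + gaps[gi]) / k - (sum_b + blinks[bi]) / k)
                key = (crit, d, gaps[gi], gi, bi)
                if best is None or key < best:
                    best = key
        if best is None:
            break
        _, _, _, gi, bi = best
        res.gap_indices.append(gi)
        res.blink_indices.append(bi)
        res.pair_differences.append(gaps[gi] - blinks[bi])
        sum_g += gaps[gi]
        sum_b += blinks[bi]
        free_g.remove(gi)
        free_b.remove(bi)
    if res.n_pairs:
        res.mean_gap = sum_g / res.n_pairs
        res.mean_blink = sum_b / res.n_pairs
    else:
        res.flagged = True
    return res
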