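"""Raw-signal preprocessing into normalized high-frequency-broadband (HFB).

The HFB envelope is the 70-150 Hz amplitude of the field potential, a proxy
for aggregate local spiking. Extraction follows the eight-band scheme: the
range is tiled by eight contiguous 10 Hz bands, each band-passed with a
zero-phase (forward-backward) least-squares FIR filter, rectified via the
magnitude of its analytic signal, normalized by its own temporal mean (which
equalizes the bands' weights against the 1/f spectrum), and the eight
normalized envelopes are averaged and downsampled to 250 Hz. Percent-change
units are obtained by dividing by the mean over inter-block gray-screen
baselines: x -> 100*(x/b - 1), so the baseline sits at 0%.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.fft import next_fast_len


class InsufficientChannelsError(ValueError):
    pass


class TooShortError(ValueError):
    pass


class NoBaselineError(ValueError):
    pass


@dataclass
class RawRecording:
    """Multichannel continuous voltage (channels x time, microvolts)."""

    samples: np.ndarray
    rate: float
    channel_names: list
    excluded_channels: set = field(default_factory=set)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    def included_indices(self) -> np.ndarray:
        return np.array([i for i, name in enumerate(self.channel_names)
                         if name not in self.excluded_channels], dtype=int)


@dataclass
class HFBTimecourse:
    """Per-channel HFB envelope with a shared rejection mask.

    ``values`` are percent signal change after :func:`baseline_normalize`
    (unit-mean envelope before it). ``rejection_mask`` is True at timepoints
    excluded by the outlier scan; trials intersecting masked points are
    dropped downstream.
    """

    values: np.ndarray
    rate: float
    channel_names: list
    rejection_mask: np.ndarray = None
    baseline_intervals: list = field(default_factory=list)

    def __post_init__(self):
        if self.rejection_mask is None:
            self.rejection_mask = np.zeros(self.values.shape[1], dtype=bool)
        if self.rejection_mask.shape[0] != self.values.shape[1]:
            raise ValueError("mask length must equal time length")

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate

    def baseline_sample_mask(self) -> np.ndarray:
        m = np.zeros(self.n_samples, dtype=bool)
        for a, b in self.baseline_intervals:
            m[int(np.ceil(a * self.rate)):int(np.floor(b * self.rate))] = True
        return m


def common_average_reference(rec: RawRecording) -> RawRecording:
    """Subtract the across-channel mean of non-excluded channels.

    Recomputable after channel exclusion: excluded channels contribute
    nothing to the reference but are themselves re-referenced (and flagged).
    """
    idx = rec.included_indices()
    if idx.size < 2:
        raise InsufficientChannelsError(
            "common average reference needs at least 2 non-excluded channels")
    car = rec.samples[idx].mean(axis=0)
    return RawRecording(samples=rec.samples - car, rate=rec.rate,
                        channel_names=list(rec.channel_names),
                        excluded_channels=set(rec.excluded_channels))


def notch_filter(rec: RawRecording, freq: float = 60.0, q: float = 35.0) -> RawRecording:
    """Zero-phase IIR notch to remove line noise."""
    b, a = sps.iirnotch(freq, q, fs=rec.rate)
    out = sps.filtfilt(b, a, rec.samples, axis=1)
    return RawRecording(out, rec.rate, list(rec.channel_names),
                        set(rec.excluded_channels))


def resample_to(rec: RawRecording, rate: float) -> RawRecording:
    """Polyphase resampling, e.g. 512 Hz acquisitions to the 500 Hz grid."""
    if rec.rate == rate:
        return rec
    from fractions import Fraction
    frac = Fraction(rate / rec.rate).limit_denominator(1000)
    out = sps.resample_poly(rec.samples, frac.numerator, frac.denominator, axis=1)
    return RawRecording(out, rate, list(rec.channel_names),
                        set(rec.excluded_channels))


def band_edges(low: float = 70.0, high: float = 150.0, n_bands: int = 8):
    edges = np.linspace(low, high, n_bands + 1)
    return [(edges[i], edges[i + 1]) for i in range(n_bands)]


def _bandpass_taps(lo: float, hi: float, rate: float, transition: float = 2.0):
    # two-pass least-squares FIR; the length must resolve the transition
    # bandwidth, else neighboring 10 Hz bands leak into each other
    numtaps = int(round(3.3 * rate / transition))
    if numtaps % 2 == 0:
        numtaps += 1
    nyq = rate / 2.0
    bands = [0.0, max(lo - transition, 0.1), lo, hi, min(hi + transition, nyq - 0.1), nyq]
    desired = [0, 0, 1, 1, 0, 0]
    return sps.firls(numtaps, bands, desired, fs=rate)


def _two_pass_fir(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Forward-backward FIR filtering (zero phase, squared magnitude
    response) via FFT, with reflected padding at the edges."""
    n = x.shape[-1]
    pad = min(3 * taps.size, n - 1)
    xp = np.concatenate([x[..., pad:0:-1], x, x[..., -2:-pad - 2:-1]], axis=-1)
    nfft = next_fast_len(xp.shape[-1])
    H = np.fft.rfft(taps, nfft)
    out = np.fft.irfft(np.fft.rfft(xp, n=nfft, axis=-1) * (H * H.conj()).real,
                       n=nfft, axis=-1)
    return out[..., pad: pad + n]


def extract_hfb(rec: RawRecording, *, low: float = 70.0, high: float = 150.0,
                n_bands: int = 8, out_rate: float = 250.0,
                transition: float = 2.0) -> HFBTimecourse:
    """Eight-band Hilbert HFB envelope, unit mean per channel.

    Expects a notch-filtered recording at 500 Hz. For each 10 Hz band:
    zero-phase band-pass, analytic-signal magnitude, division by its own
    temporal mean; bands are averaged and the result decimated to
    ``out_rate``. Output mean is ~1 before baseline normalization.
    """
    if rec.rate % out_rate != 0:
        raise ValueError("output rate must divide the input rate")
    bands = band_edges(low, high, n_bands)
    taps0 = _bandpass_taps(bands[0][0], bands[0][1], rec.rate, transition)
    min_len = 3 * len(taps0)
    if rec.n_samples <= min_len:
        raise TooShortError(
            f"recording of {rec.n_samples} samples shorter than filter warm-up "
            f"({min_len} samples)")
    nfft = next_fast_len(rec.n_samples)
    # per-band means exclude the filter warm-up edges, which carry
    # transients unrelated to the signal
    margin = min(min_len, rec.n_samples // 4)
    core = slice(margin, rec.n_samples - margin)
    acc = np.zeros_like(rec.samples, dtype=float)
    for lo, hi in bands:
        taps = _bandpass_taps(lo, hi, rec.rate, transition)
        bp = _two_pass_fir(rec.samples, taps)
        env = np.abs(sps.hilbert(bp, N=nfft, axis=1)[:, : rec.n_samples])
        env /= env[:, core].mean(axis=1, keepdims=True)
        acc += env
    acc /= n_bands
    q = int(rec.rate // out_rate)
    if q > 1:
        acc = sps.decimate(acc, q, ftype="fir", zero_phase=True, axis=1)
    return HFBTimecourse(values=acc, rate=out_rate,
                         channel_names=list(rec.channel_names))


def reject_outliers(hfb: HFBTimecourse, *, threshold: float = 2.0,
                    dilate_ms: float = 200.0,
                    prior_mask: np.ndarray | None = None) -> np.ndarray:
    """Widespread-artifact scan on the HFB derivative.

    Per channel the first difference is z-normalized (whole-recording mean
    and SD, excluding ``prior_mask`` points) and rectified; timepoints where
    the across-channel median exceeds ``threshold`` are marked, together with
    everything within ``dilate_ms``. The across-channel median makes the scan
    robust to a single misbehaving channel.
    """
    x = hfb.values
    n_ch, n = x.shape
    if n_ch < 2:
        warnings.warn("outlier scan on a single channel: median is the "
                      "channel itself", stacklevel=2)
    d = np.diff(x, axis=1, prepend=x[:, :1])
    keep = np.ones(n, dtype=bool) if prior_mask is None else ~prior_mask
    mu = d[:, keep].mean(axis=1, keepdims=True)
    sd = d[:, keep].std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = np.abs((d - mu) / sd)
    med = np.median(z, axis=0)
    mask = med > threshold
    if mask.any():
        half = int(round(dilate_ms / 1000.0 * hfb.rate))
        kernel = np.ones(2 * half + 1, dtype=bool)
        mask = np.convolve(mask, kernel, mode="same") > 0
    return mask


def baseline_normalize(hfb: HFBTimecourse, baseline_intervals=None) -> HFBTimecourse:
    """Rescale to percent signal change with the gray-screen baseline at 0%."""
    intervals = baseline_intervals if baseline_intervals is not None \
        else hfb.baseline_intervals
    if not intervals:
        raise NoBaselineError("no baseline intervals supplied")
    tmp = HFBTimecourse(hfb.values, hfb.rate, hfb.channel_names,
                        hfb.rejection_mask, list(intervals))
    sel = tmp.baseline_sample_mask() & ~hfb.rejection_mask
    if not sel.any():
        raise NoBaselineError("baseline intervals empty after mask exclusion")
    b = hfb.values[:, sel].mean(axis=1, keepdims=True)
    if np.any(b <= 0):
        raise NoBaselineError("non-positive baseline mean")
    out = 100.0 * (hfb.values / b - 1.0)
    return HFBTimecourse(values=out, rate=hfb.rate,
                         channel_names=list(hfb.channel_names),
                         rejection_mask=hfb.rejection_mask.copy(),
                         baseline_intervals=list(intervals))


def preprocess(rec: RawRecording, baseline_intervals, *, notch: float = 60.0,
               car: bool = True) -> HFBTimecourse:
    """CAR -> notch -> eight-band HFB -> outlier scan -> percent change."""
    if rec.rate not in (500.0, 512.0):
        raise ValueError("expected a 500 or 512 Hz acquisition")
    rec = resample_to(rec, 500.0)
    if car:
        rec = common_average_reference(rec)
    if notch:
        rec = notch_filter(rec, notch)
    hfb = extract_hfb(rec)
    hfb.baseline_intervals = list(baseline_intervals)
    hfb.rejection_mask = reject_outliers(hfb)
    return baseline_normalize(hfb)


# ---------------------------------------------------------------------------
# flat binary container with sidecar text header
# ---------------------------------------------------------------------------

def save_signals(path_prefix, values: np.ndarray, rate: float, channel_names) -> None:
    """Write ``<prefix>.bin`` (float32, channel-major) + ``<prefix>.json``."""
    arr = np.asarray(values, dtype=np.float32)
    arr.tofile(f"{path_prefix}.bin")
    header = {"rate": rate, "channels": list(channel_names),
              "n_samples": int(arr.shape[1]), "dtype": "float32",
              "order": "channel-major"}
    with open(f"{path_prefix}.json", "w") as fh:
        json.dump(header, fh, indent=1)


def load_signals(path_prefix):
    with open(f"{path_prefix}.json") as fh:
        header = json.load(fh)
    arr = np.fromfile(f"{path_prefix}.bin", dtype=np.float32)
    arr = arr.reshape(len(header["channels"]), header["n_samples"])
    return arr.astype(float), header["rate"], header["channels"]
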