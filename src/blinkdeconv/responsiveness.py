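"""Electrode screening: visual responsiveness, face selectivity, ROI labels.

An electrode is visually responsive when its mean HFB in the 50-350 ms
post-stimulus window exceeds the gray-screen baseline by a Wilcoxon rank-sum
test (Bonferroni-corrected within patient, p < 0.05) AND by at least two
baseline standard deviations (Glass' delta >= 2, computed from the
maximally responding category). Face-selective electrodes respond more
strongly to faces than to every other category (one-sided rank-sum, p < 0.05
per contrast, uncorrected) and are assigned to the FC region regardless of
anatomy; other electrodes keep the anatomical ROI label supplied in the
metadata.

Baseline observations entering the rank-sum test and the Glass' delta SD are
per-baseline-interval means rather than raw samples, to avoid the inflated n
of autocorrelated samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sct

from .signal_hfb import HFBTimecourse

ROI_LABELS = {"V1", "V2", "V3", "V4", "VO", "FC", "N-FC", "unassigned"}
EARLY_ROIS = ("V1", "V2", "V3", "V4", "VO")


class NoTrialsError(ValueError):
    pass


class InsufficientTrialsError(ValueError):
    pass


class InvalidRoiError(ValueError):
    pass


@dataclass
class ResponsivenessResult:
    electrode: str
    p_value: float            # rank-sum vs baseline, Bonferroni-corrected
    p_raw: float
    glass_delta: float        # baseline-SD units, best category
    best_category: str
    selected: bool
    face_selective: bool = False
    face_p: float = np.nan
    roi: str | None = None


def eligible_trials(events: pd.DataFrame, *, window_s=(0.05, 0.35),
                    guard_s: float = 0.10) -> pd.DataFrame:
    """Stimulus trials with no interruption inside the response window or
    the preceding guard period, animal trials excluded."""
    stim = events[(events["kind"] == "stimulus") &
                  (events["category"] != "animal")]
    inter = events[events["kind"] != "stimulus"]
    if len(inter):
        i_on = inter["onset_s"].to_numpy()
        i_off = inter["offset_s"].to_numpy()
        lo = stim["onset_s"].to_numpy() + window_s[0] - guard_s
        hi = stim["onset_s"].to_numpy() + window_s[1]
        overlap = (i_on[None, :] < hi[:, None]) & (i_off[None, :] > lo[:, None])
        stim = stim[~overlap.any(axis=1)]
    return stim


def _trial_means(y: np.ndarray, rate: float, onsets_s: np.ndarray,
                 window_s, mask: np.ndarray) -> np.ndarray:
    out = []
    for t in onsets_s:
        i0 = int(round((t + window_s[0]) * rate))
        i1 = int(round((t + window_s[1]) * rate))
        if i0 < 0 or i1 > y.size:
            out.append(np.nan)
            continue
        seg_mask = mask[i0:i1]
        out.append(np.nan if seg_mask.any() else y[i0:i1].mean())
    return np.asarray(out)


def _baseline_interval_means(y: np.ndarray, hfb: HFBTimecourse) -> np.ndarray:
    vals = []
    for a, b in hfb.baseline_intervals:
        i0, i1 = int(np.ceil(a * hfb.rate)), int(np.floor(b * hfb.rate))
        sel = ~hfb.rejection_mask[i0:i1]
        if sel.any():
            vals.append(y[i0:i1][sel].mean())
    return np.asarray(vals)


def score_visual_responsiveness(hfb: HFBTimecourse, events: pd.DataFrame,
                                *, window_s=(0.05, 0.35),
                                alpha: float = 0.05,
                                glass_min: float = 2.0) -> list:
    """Screen every channel; Bonferroni correction spans the patient's
    channels. Returns one :class:`ResponsivenessResult` per channel."""
    trials = eligible_trials(events, window_s=window_s)
    if len(trials) == 0:
        raise NoTrialsError("no eligible trials after interruption filtering")
    n_elec = hfb.values.shape[0]
    results = []
    onsets = trials["onset_s"].to_numpy()
    cats = trials["category"].to_numpy()
    for c in range(n_elec):
        y = hfb.values[c]
        tm = _trial_means(y, hfb.rate, onsets, window_s, hfb.rejection_mask)
        ok = ~np.isnan(tm)
        base = _baseline_interval_means(y, hfb)
        if ok.sum() == 0 or base.size == 0:
            raise NoTrialsError("no usable trials or baseline intervals")
        stat = sct.mannwhitneyu(tm[ok], base, alternative="two-sided")
        p_corr = min(1.0, stat.pvalue * n_elec)
        cat_means = {cat: tm[ok & (cats == cat)].mean()
                     for cat in np.unique(cats[ok])}
        best = max(cat_means, key=cat_means.get)
        sd = base.std(ddof=1) if base.size > 1 else np.nan
        delta = (cat_means[best] - base.mean()) / sd if sd and sd > 0 else np.nan
        results.append(ResponsivenessResult(
            electrode=hfb.channel_names[c], p_value=p_corr, p_raw=stat.pvalue,
            glass_delta=float(delta), best_category=str(best),
            selected=bool(p_corr < alpha and delta >= glass_min)))
    return results


def score_face_selectivity(hfb: HFBTimecourse, events: pd.DataFrame,
                           results: list, *, window_s=(0.05, 0.35),
                           alpha: float = 0.05) -> list:
    """Flag electrodes responding more strongly to faces than to every other
    category (one-sided rank-sum per contrast, uncorrected)."""
    trials = eligible_trials(events, window_s=window_s)
    onsets = trials["onset_s"].to_numpy()
    cats = trials["category"].to_numpy()
    others = [c for c in np.unique(cats) if c != "face"]
    for c, res in enumerate(results):
        if not res.selected:
            res.face_selective = False
            continue
        y = hfb.values[c]
        tm = _trial_means(y, hfb.rate, onsets, window_s, hfb.rejection_mask)
        ok = ~np.isnan(tm)
        face = tm[ok & (cats == "face")]
        ps = []
        for other in others:
            oth = tm[ok & (cats == other)]
            if face.size < 2 or oth.size < 2:
                raise InsufficientTrialsError(
                    f"category with <2 trials in face contrast vs {other}")
            ps.append(sct.mannwhitneyu(face, oth, alternative="greater").pvalue)
        res.face_p = float(max(ps)) if ps else np.nan
        res.face_selective = bool(ps) and all(p < alpha for p in ps)
    return results


def assign_rois(metadata: pd.DataFrame, results: list | None = None) -> pd.Series:
    """Final ROI labels: the functional face-selective criterion precedes
    anatomy; 'unassigned' electrodes are kept for electrode-level maps but
    excluded from ROI-level analyses by the caller."""
    if len(metadata) == 0:
        return pd.Series(dtype=object)
    bad = set(metadata["roi"]) - ROI_LABELS
    if bad:
        raise InvalidRoiError(f"unknown ROI labels: {sorted(bad)}")
    roi = metadata["roi"].copy()
    if results is not None:
        fs = {r.electrode for r in results if r.face_selective}
        roi[metadata["electrode"].isin(fs)] = "FC"
    if results is not None:
        by_name = dict(zip(metadata["electrode"], roi))
        for r in results:
            r.roi = by_name.get(r.electrode)
    return roi


def results_table(results: list) -> pd.DataFrame:
    """Per-electrode screening table (TSV-ready)."""
    return pd.DataFrame([vars(r) for r in results])
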