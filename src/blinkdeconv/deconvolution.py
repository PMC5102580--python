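"""FIR deconvolution of overlapping event-locked HFB responses.

Stimuli arrive at 1 Hz while their responses last 1.5 s, and interruptions
(gaps, blinks) ride on top of them, so event-locked averages are biased by
response overlap. The timecourse is therefore modeled as a sum of finite
impulse response (FIR) contributions: each predictor set is a train of
non-overlapping 4 ms unit pulses spanning a lag window relative to its
events, and ordinary least squares unmixes the per-lag contributions of all
events simultaneously:

    beta = (X'X)^-1 X'y

Standard errors use the HC3 heteroskedasticity-consistent sandwich

    cov = (X'X)^-1 X' diag[e_i^2 / (1 - h_ii)^2] X (X'X)^-1

where e_i are residuals and h_ii the leverages (diagonal of the hat matrix),
so the error bar at each lag reflects the variability of the samples that
actually informed it.

Excluded timepoints (animal trials, artifact-masked samples, breaks) are
handled by row deletion, which is algebraically identical to giving each
excluded timepoint its own dummy nuisance predictor; the dummy-column form
can be materialized explicitly with :meth:`DesignMatrix.with_dummies`.

Onset-locked (disappearance) and offset-locked (reappearance) interruption
predictors are fitted in separate models — a combined model is nearly
collinear because interruption durations are short relative to the lag
windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import sparse
from scipy import stats as sct


class SingularDesignError(ValueError):
    def __init__(self, msg, columns=None):
        super().__init__(msg)
        self.columns = columns or []


class SaturatedDesignError(ValueError):
    pass


# ---------------------------------------------------------------------------
# design specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PredictorSet:
    """One FIR predictor set: an event selector plus a lag window.

    ``kind`` is 'stimulus', 'gap', 'blink' or 'custom' (with explicit
    ``times_s``); ``lock`` chooses onset- or offset-locking. The window is
    half-open [start, end) ms, tiled by the model's bin width; a trailing
    partial bin is discarded.
    """

    name: str
    kind: str = "custom"
    categories: tuple | None = None
    subtypes: tuple | None = None
    lock: str = "onset"
    window_ms: tuple = (0.0, 1500.0)
    times_s: tuple | None = None

    def select_times(self, events: pd.DataFrame) -> np.ndarray:
        if self.times_s is not None:
            return np.asarray(self.times_s, dtype=float)
        ev = events[events["kind"] == ("blink" if self.kind in
                                       ("blink", "spontaneous", "voluntary")
                                       else self.kind)]
        if self.kind in ("spontaneous", "voluntary"):
            ev = ev[ev["subtype"] == self.kind]
        if self.subtypes is not None:
            ev = ev[ev["subtype"].isin(self.subtypes)]
        if self.categories is not None:
            ev = ev[ev["category"].isin(self.categories)]
        col = "onset_s" if self.lock == "onset" else "offset_s"
        return ev[col].to_numpy(dtype=float)


@dataclass(frozen=True)
class DesignSpec:
    predictor_sets: tuple
    rate: float = 250.0

    @property
    def bin_ms(self) -> float:
        return 1000.0 / self.rate


def n_lags(window_ms, bin_ms: float) -> int:
    """Number of complete bins tiling the half-open window."""
    return int(np.floor((window_ms[1] - window_ms[0]) / bin_ms + 1e-9))


def lag_grid_ms(window_ms, bin_ms: float) -> np.ndarray:
    return window_ms[0] + bin_ms * np.arange(n_lags(window_ms, bin_ms))


def stimulus_sets(split_by_category: bool = True,
                  window_ms=(0.0, 1500.0)) -> list:
    if split_by_category:
        return [
            PredictorSet("stim_face", "stimulus", categories=("face",),
                         window_ms=window_ms),
            PredictorSet("stim_nonface", "stimulus", categories=("nonface",),
                         window_ms=window_ms),
        ]
    return [PredictorSet("stim", "stimulus", categories=("face", "nonface"),
                         window_ms=window_ms)]


def interruption_sets(types=("gap", "spontaneous"), lock: str = "onset",
                      split_by_category: bool = True,
                      window_ms=(-250.0, 500.0)) -> list:
    out = []
    for t in types:
        if split_by_category:
            for cat in ("face", "nonface"):
                out.append(PredictorSet(f"{t}_{cat}", t, categories=(cat,),
                                        lock=lock, window_ms=window_ms))
        else:
            out.append(PredictorSet(t, t, categories=("face", "nonface"),
                                    lock=lock, window_ms=window_ms))
    return out


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    X: sparse.csr_matrix               # timepoints x FIR predictors (0/1)
    labels: pd.DataFrame               # columns: set, lag_ms
    excluded: np.ndarray               # boolean per timepoint
    rate: float
    set_slices: dict                   # set name -> slice into columns
    event_times: dict                  # set name -> onset/offset times used

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]

    def with_dummies(self) -> sparse.csr_matrix:
        """FIR columns plus one unit-vector dummy column per excluded
        timepoint (the explicit nuisance-predictor formulation)."""
        idx = np.flatnonzero(self.excluded)
        if idx.size == 0:
            return self.X
        n = self.X.shape[0]
        dummies = sparse.csr_matrix(
            (np.ones(idx.size), (idx, np.arange(idx.size))),
            shape=(n, idx.size))
        return sparse.hstack([self.X, dummies], format="csr")


def export_design_triplets(design: DesignMatrix, path) -> None:
    """Write the FIR design as sparse triplets (timepoint, set, lag_ms,
    value) in tab-separated text, for external audit."""
    coo = design.X.tocoo()
    table = pd.DataFrame({
        "timepoint": coo.row,
        "set": design.labels["set"].to_numpy()[coo.col],
        "lag_ms": design.labels["lag_ms"].to_numpy()[coo.col],
        "value": coo.data,
    }).sort_values(["timepoint", "set", "lag_ms"])
    table.to_csv(path, sep="\t", index=False)


def build_design_matrix(events: pd.DataFrame, spec: DesignSpec,
                        n_timepoints: int,
                        excluded: np.ndarray | None = None) -> DesignMatrix:
    """Assemble the sparse FIR design matrix for an HFB timeline."""
    rate, bin_ms = spec.rate, spec.bin_ms
    if excluded is None:
        excluded = np.zeros(n_timepoints, dtype=bool)
    rows, cols = [], []
    labels_set, labels_lag = [], []
    set_slices, event_times = {}, {}
    col0 = 0
    for pset in spec.predictor_sets:
        L = n_lags(pset.window_ms, bin_ms)
        lags = lag_grid_ms(pset.window_ms, bin_ms)
        start_bin = int(round(pset.window_ms[0] / bin_ms))
        times = pset.select_times(events)
        event_times[pset.name] = times
        samp = np.round(times * rate).astype(int)[:, None] + \
            (start_bin + np.arange(L))[None, :]
        lagcol = np.broadcast_to(np.arange(L), samp.shape)
        ok = (samp >= 0) & (samp < n_timepoints)
        rows.append(samp[ok])
        cols.append(col0 + lagcol[ok])
        labels_set.extend([pset.name] * L)
        labels_lag.extend(lags.tolist())
        set_slices[pset.name] = slice(col0, col0 + L)
        col0 += L
    rows = np.concatenate(rows) if rows else np.array([], dtype=int)
    cols = np.concatenate(cols) if cols else np.array([], dtype=int)
    X = sparse.csr_matrix((np.ones(rows.size), (rows, cols)),
                          shape=(n_timepoints, col0))
    labels = pd.DataFrame({"set": labels_set, "lag_ms": labels_lag})
    return DesignMatrix(X=X, labels=labels, excluded=np.asarray(excluded, bool),
                        rate=rate, set_slices=set_slices,
                        event_times=event_times)


# ---------------------------------------------------------------------------
# OLS + HC3
# ---------------------------------------------------------------------------

@dataclass
class DeconvolvedResponse:
    beta: np.ndarray
    labels: pd.DataFrame
    residuals: np.ndarray          # zero at excluded timepoints
    leverage: np.ndarray           # per included timepoint (0 elsewhere)
    included: np.ndarray           # boolean per timepoint
    xtx_inv: np.ndarray
    design: DesignMatrix
    se: np.ndarray | None = None
    n_events: dict = field(default_factory=dict)
    dropped_columns: list = field(default_factory=list)

    def trace(self, set_name: str):
        """(lags_ms, beta, se) for one predictor set."""
        sel = (self.labels["set"] == set_name).to_numpy()
        lags = self.labels.loc[sel, "lag_ms"].to_numpy()
        se = self.se[sel] if self.se is not None else None
        return lags, self.beta[sel], se


def _leverages(Xr: sparse.csr_matrix, A: np.ndarray) -> np.ndarray:
    """h_ii = x_i' A x_i row-wise, exploiting very sparse rows."""
    Xr = Xr.tocsr()
    nnz = np.diff(Xr.indptr)
    K = int(nnz.max()) if nnz.size else 0
    if K == 0:
        return np.zeros(Xr.shape[0])
    n = Xr.shape[0]
    idx = np.zeros((n, K), dtype=int)
    val = np.zeros((n, K))
    rows = np.repeat(np.arange(n), nnz)
    pos = np.concatenate([np.arange(c) for c in nnz]) if nnz.any() else \
        np.array([], dtype=int)
    idx[rows, pos] = Xr.indices
    val[rows, pos] = Xr.data
    G = A[idx[:, :, None], idx[:, None, :]]
    return np.einsum("nk,nl,nkl->n", val, val, G)


def fit_ols(design: DesignMatrix, y: np.ndarray,
            drop_collinear: bool = False) -> DeconvolvedResponse:
    """Ordinary least squares on the included timepoints.

    Raises :class:`SingularDesignError` (listing the offending columns) on a
    rank-deficient design unless ``drop_collinear`` is set, in which case
    exactly-collinear columns are dropped with their labels recorded.
    """
    include = ~design.excluded
    Xr = design.X[include]
    yr = np.asarray(y, dtype=float)[include]
    keep = np.arange(design.n_columns)
    dropped = []

    empty = np.asarray((Xr.multiply(Xr)).sum(axis=0)).ravel() == 0
    if empty.any():
        names = design.labels.index[empty].tolist()
        if not drop_collinear:
            raise SingularDesignError(
                f"{empty.sum()} predictor columns have no events in range",
                columns=design.labels[empty].to_records(index=False).tolist())
        dropped.extend(np.flatnonzero(empty).tolist())
        keep = np.flatnonzero(~empty)
        Xr = Xr[:, keep]

    XtX = np.asarray((Xr.T @ Xr).todense())
    Xty = Xr.T @ yr
    try:
        cf = sla.cho_factor(XtX)
        beta_k = sla.cho_solve(cf, Xty)
        A = sla.cho_solve(cf, np.eye(XtX.shape[0]))
    except np.linalg.LinAlgError:
        # identify dependent columns via pivoted QR of the Gram matrix
        _, R, piv = sla.qr(XtX, pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * XtX.shape[0] * np.finfo(float).eps
        rank = int((diag > tol).sum())
        bad = sorted(piv[rank:].tolist())
        cols = design.labels.iloc[keep[bad]]
        if not drop_collinear:
            raise SingularDesignError(
                f"design is rank deficient ({len(bad)} dependent columns)",
                columns=cols.to_records(index=False).tolist())
        dropped.extend(keep[bad].tolist())
        good = sorted(piv[:rank].tolist())
        keep = keep[good]
        Xr = design.X[include][:, keep]
        XtX = np.asarray((Xr.T @ Xr).todense())
        Xty = Xr.T @ yr
        cf = sla.cho_factor(XtX)
        beta_k = sla.cho_solve(cf, Xty)
        A = sla.cho_solve(cf, np.eye(XtX.shape[0]))

    beta = np.zeros(design.n_columns)
    beta[keep] = beta_k
    resid = np.zeros(y.shape[0])
    resid[include] = yr - Xr @ beta_k
    lev = np.zeros(y.shape[0])
    lev[include] = _leverages(Xr, A)
    A_full = np.zeros((design.n_columns, design.n_columns))
    A_full[np.ix_(keep, keep)] = A
    return DeconvolvedResponse(
        beta=beta, labels=design.labels, residuals=resid, leverage=lev,
        included=include, xtx_inv=A_full, design=design,
        n_events={k: len(v) for k, v in design.event_times.items()},
        dropped_columns=dropped)


def hc3_standard_errors(fit: DeconvolvedResponse) -> np.ndarray:
    """HC3 sandwich standard errors; also stored on the fit.

    Raises :class:`SaturatedDesignError` if any leverage reaches 1 (a
    timepoint fitted exactly by its own predictor has no residual
    information).
    """
    inc = fit.included
    h = fit.leverage[inc]
    if np.any(h >= 1.0 - 1e-10):
        raise SaturatedDesignError("leverage of 1 encountered (saturated design)")
    e = fit.residuals[inc]
    w = (e / (1.0 - h)) ** 2
    Xr = fit.design.X[inc]
    meat = np.asarray((Xr.multiply(w[:, None]).T @ Xr).todense())
    cov = fit.xtx_inv @ meat @ fit.xtx_inv
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    fit.se = se
    return se


def test_timepoints(fit: DeconvolvedResponse, q: float = 0.05) -> pd.DataFrame:
    """Per-lag z-tests (beta/se vs standard normal), FDR-adjusted in time
    within each predictor set; significance at level ``q``."""
    from .inference import fdr_adjust
    if fit.se is None:
        hc3_standard_errors(fit)
    se = fit.se.copy()
    z = np.divide(fit.beta, se, out=np.zeros_like(fit.beta), where=se > 0)
    p = 2.0 * sct.norm.sf(np.abs(z))
    # zero-variance lags: a perfect fit carries no sampling noise
    p[se == 0] = np.where(fit.beta[se == 0] == 0, 1.0, 0.0)
    out = fit.labels.copy()
    out["beta"] = fit.beta
    out["se"] = se
    out["z"] = z
    out["p"] = p
    out["p_fdr"] = np.nan
    for name in out["set"].unique():
        sel = out["set"] == name
        out.loc[sel, "p_fdr"] = fdr_adjust(out.loc[sel, "p"].to_numpy())
    out["significant"] = out["p_fdr"] < q
    return out


def deconvolve(y: np.ndarray, events: pd.DataFrame, spec: DesignSpec,
               excluded: np.ndarray | None = None,
               drop_collinear: bool = False,
               standard_errors: bool = True) -> DeconvolvedResponse:
    """Build the design for one electrode, fit OLS, attach HC3 errors."""
    design = build_design_matrix(events, spec, len(y), excluded)
    fit = fit_ols(design, y, drop_collinear=drop_collinear)
    if standard_errors:
        hc3_standard_errors(fit)
    return fit


# ---------------------------------------------------------------------------
# template-subtraction alternative (and the naive average)
# ---------------------------------------------------------------------------

@dataclass
class EventLockedAverage:
    lags_ms: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n: int


class NoTemplateError(ValueError):
    pass


def template_subtract_average(y: np.ndarray, events: pd.DataFrame, rate: float,
                              *, lock: str = "onset",
                              window_ms=(-250.0, 500.0),
                              event_times_s: np.ndarray | None = None,
                              subtract_template: bool = True,
                              trial_duration_ms: float = 1000.0
                              ) -> EventLockedAverage:
    """Event-locked averaging after subtracting the uninterrupted-trial
    response template (the simple alternative to deconvolution).

    A per-category template is the mean trace of trials containing no gap or
    blink; it is subtracted from every trial of its category before segments
    locked to the interruption events (or to explicit ``event_times_s``,
    e.g. pseudo-events) are averaged. With ``subtract_template=False`` this
    is the naive event-related average, whose overlap bias the deconvolution
    removes.
    """
    y = np.asarray(y, dtype=float)
    stim = events[(events["kind"] == "stimulus") &
                  (events["category"] != "animal")]
    resid = y.copy()
    if subtract_template:
        interrupted = set(events.loc[events["kind"] != "stimulus",
                                     "trial_index"])
        clean = stim[~stim["trial_index"].isin(interrupted)]
        L_tr = int(round(trial_duration_ms / 1000.0 * rate))
        templates = {}
        for cat, grp in clean.groupby("category"):
            segs = [y[i0:i0 + L_tr]
                    for i0 in np.round(grp["onset_s"].to_numpy() * rate).astype(int)
                    if i0 >= 0 and i0 + L_tr <= y.size]
            if segs:
                templates[cat] = np.mean(segs, axis=0)
        if not templates:
            raise NoTemplateError("no uninterrupted trials to form a template")
        for _, tr in stim.iterrows():
            tpl = templates.get(tr["category"])
            if tpl is None:
                continue
            i0 = int(round(tr["onset_s"] * rate))
            if 0 <= i0 and i0 + L_tr <= resid.size:
                resid[i0:i0 + L_tr] -= tpl

    if event_times_s is None:
        inter = events[events["kind"] != "stimulus"]
        col = "onset_s" if lock == "onset" else "offset_s"
        event_times_s = inter[col].to_numpy(dtype=float)
    bin_ms = 1000.0 / rate
    L = n_lags(window_ms, bin_ms)
    lags = lag_grid_ms(window_ms, bin_ms)
    start_bin = int(round(window_ms[0] / bin_ms))
    segs = []
    for t in np.asarray(event_times_s, dtype=float):
        i0 = int(round(t * rate)) + start_bin
        if i0 >= 0 and i0 + L <= resid.size:
            segs.append(resid[i0:i0 + L])
    if not segs:
        return EventLockedAverage(lags, np.array([]), np.array([]), 0)
    segs = np.asarray(segs)
    mean = segs.mean(axis=0)
    sem = segs.std(axis=0, ddof=1) / np.sqrt(segs.shape[0]) \
        if segs.shape[0] > 1 else np.full(L, np.nan)
    return EventLockedAverage(lags, mean, sem, segs.shape[0])


# ---------------------------------------------------------------------------
# fast exact refitting under event relabeling
# ---------------------------------------------------------------------------

class RelabelRefitter:
    """Exact OLS refits when only the grouping of interruption events changes.

    Permutation tests and split-half estimation refit the same model many
    times with the identical stimulus block and the identical pool of
    interruption event times — only the assignment of events to predictor
    sets changes. By Frisch-Waugh-Lovell, the interruption coefficients
    solve the stimulus-projected normal equations, whose ingredients are
    sums over events of precomputable per-event blocks. Each refit then
    costs one small dense solve instead of a full design rebuild.

    Results are exact: they match :func:`fit_ols` on the corresponding full
    design to numerical precision (asserted in the test suite).
    """

    def __init__(self, fixed_design: DesignMatrix,
                 event_times_s: np.ndarray, window_ms,
                 y: np.ndarray | None = None,
                 categories: np.ndarray | None = None):
        X = fixed_design.X
        include = ~fixed_design.excluded
        rate, bin_ms = fixed_design.rate, 1000.0 / fixed_design.rate
        n = X.shape[0]
        self.n = n
        self.include = include
        self.rate = rate
        self.window_ms = tuple(window_ms)
        self.lags_ms = lag_grid_ms(window_ms, bin_ms)
        L = self.lags_ms.size
        self.L = L
        start_bin = int(round(window_ms[0] / bin_ms))
        t_samp = np.round(np.asarray(event_times_s, float) * rate).astype(int)
        self.event_times_s = np.asarray(event_times_s, float)
        self.categories = categories
        E = t_samp.size
        self.n_events = E

        samp = t_samp[:, None] + (start_bin + np.arange(L))[None, :]
        valid = (samp >= 0) & (samp < n)
        samp_c = np.clip(samp, 0, n - 1)
        valid &= include[samp_c]
        self.valid = valid
        self._samp_c = samp_c

        self.Xr = X.multiply(include[:, None].astype(float)).tocsr()
        pS = X.shape[1]
        self.pS = pS
        XtX = np.asarray((self.Xr.T @ self.Xr).todense())
        self.A_S = sla.inv(XtX)

        # per-event stacks of fixed-design rows at the pulse times
        flat = self.Xr[samp_c.ravel()].toarray().reshape(E, L, pS)
        self.R = np.where(valid[:, :, None], flat, 0.0)
        self._R_flat = self.R.reshape(E, L * pS)
        self._RA_flat = (self.R @ self.A_S).reshape(E, L * pS)

        self.Y = None
        self.c_Sy = None
        if y is not None:
            self.set_y(y)

        # pairwise pulse coincidences: events closer than the window overlap
        valid = self.valid
        pairs = []
        for i in range(E):
            for j in range(i, E):
                d = t_samp[j] - t_samp[i]
                if abs(d) >= L:
                    continue
                # u_i[l] coincides with u_j[l'] when l = l' + d
                lp = np.arange(max(0, -d), min(L, L - d))
                vals = (valid[i, lp + d] & valid[j, lp]).astype(float)
                if vals.any():
                    pairs.append((i, j, d, lp, vals))
        self.pairs = pairs

    def set_y(self, y: np.ndarray) -> "RelabelRefitter":
        """Attach (or swap) the response vector; the expensive per-session
        precomputation is shared across electrodes."""
        y = np.asarray(y, dtype=float)
        ym = np.where(self.include, y, 0.0)
        self.Y = np.where(self.valid, ym[self._samp_c], 0.0)   # (E, L)
        self.c_Sy = self.A_S @ (self.Xr.T @ ym)
        return self

    def betas(self, assignment: np.ndarray, n_groups: int) -> np.ndarray:
        """Interruption-set coefficients for one relabeling.

        ``assignment`` maps each event to a group (predictor set); events
        with a negative assignment are left out. Returns an array of shape
        (n_groups, n_lags).
        """
        L, k = self.L, n_groups
        assignment = np.asarray(assignment)
        G = np.zeros((k, self.n_events))
        for g in range(k):
            G[g, assignment == g] = 1.0
        D = (G @ self._R_flat).reshape(k * L, self.pS)
        Yv = (G @ self.Y).ravel()
        C = np.zeros((k * L, k * L))
        for i, j, d, lp, vals in self.pairs:
            gi, gj = assignment[i], assignment[j]
            if gi < 0 or gj < 0:
                continue
            rows = gi * L + lp + d
            cols = gj * L + lp
            np.add.at(C, (rows, cols), vals)
            if i != j:
                np.add.at(C, (cols, rows), vals)
        W = (G @ self._RA_flat).reshape(k * L, self.pS)
        C -= W @ D.T
        rhs = Yv - D @ self.c_Sy
        try:
            beta = sla.solve(C, rhs, assume_a="pos")
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(C, rhs, rcond=None)[0]
        return beta.reshape(k, L)
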