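"""Within-electrode permutation tests, ROI randomization test, FDR.

The gap-vs-blink contrast at each electrode is tested by permutation:
gap/blink labels are shuffled over the pooled interruption events — keeping
the counts of gaps and blinks within face trials and within non-face trials
fixed — the model is re-deconvolved, and the component difference is
recomputed, giving the empirical null of the observed difference. P-values
use the add-one rule p = (b+1)/(m+1) where b counts permutations at least as
extreme; two-tailed values double the smaller tail.

Across regions of interest, non-uniformity of the proportion of significant
electrodes is tested by a randomization test of independence on the Pearson
statistic chi2 = sum (O_i - E_i)^2 / E_i with E_i = n_i * (sum O / sum n),
against a null built by randomly re-assigning the significant flags across
electrodes with the per-ROI totals fixed (multivariate hypergeometric).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .components import find_extreme_cluster, integrate_interval
from .deconvolution import RelabelRefitter


class DegenerateStrataError(ValueError):
    pass


class InvalidCountsError(ValueError):
    pass


def permutation_p(b: int, m: int) -> float:
    """Add-one permutation p-value (b+1)/(m+1)."""
    if m < 1:
        raise ValueError("need at least one permutation")
    if not (0 <= b <= m):
        raise ValueError("b must lie in [0, m]")
    return (b + 1) / (m + 1)


def two_tailed(p_upper: float, p_lower: float) -> float:
    return min(1.0, 2.0 * min(p_upper, p_lower))


@dataclass
class PermutationResult:
    electrode: str
    component: str                 # dip | overshoot
    contrast: str                  # e.g. gap_vs_spontaneous
    observed: float                # gap minus blink component difference
    b_upper: int
    m: int
    p_upper: float
    p_lower: float
    p_two_tailed: float
    p_fdr: float = np.nan


def permutation_component_test(refitter: RelabelRefitter,
                               is_gap: np.ndarray, component: str,
                               m: int = 2000,
                               rng: np.random.Generator | None = None,
                               strata: np.ndarray | None = None,
                               electrode: str = "",
                               contrast: str = "gap_vs_blink",
                               search_start_ms: float = 0.0,
                               degenerate: str = "raise") -> PermutationResult:
    """Stratified label-permutation test of a gap-vs-blink component.

    ``refitter`` holds the pooled gap+blink events over a fixed background
    model (stimulus and any other event types); ``is_gap`` flags the true
    labels. Per permutation the labels are shuffled within strata (face /
    non-face trials), the two predictor sets re-deconvolved exactly, and the
    plugin component difference recomputed.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    is_gap = np.asarray(is_gap, dtype=bool)
    if strata is None:
        strata = np.zeros(is_gap.size, dtype=int)
    strata = np.asarray(strata)
    shuffle_strata = []
    for s in np.unique(strata):
        sel = strata == s
        if is_gap[sel].all() or (~is_gap[sel]).all():
            if degenerate == "raise":
                raise DegenerateStrataError(
                    f"stratum {s!r} contains only one event type")
            # 'fix': the stratum keeps its true labels in every permutation
        else:
            shuffle_strata.append(s)

    sign = +1 if component == "overshoot" else -1

    def diff(labels: np.ndarray) -> float:
        betas = refitter.betas(np.where(labels, 0, 1), 2)
        vals = []
        for g in range(2):
            c = find_extreme_cluster(refitter.lags_ms, betas[g], sign,
                                     search_start_ms)
            vals.append(c.integral)
        return vals[0] - vals[1]

    observed = diff(is_gap)
    null = np.empty(m)
    labels = is_gap.copy()
    for i in range(m):
        for s in shuffle_strata:
            sel = np.flatnonzero(strata == s)
            labels[sel] = is_gap[sel][rng.permutation(sel.size)]
        null[i] = diff(labels)
    b_upper = int((null >= observed).sum())
    b_lower = int((null <= observed).sum())
    p_up = permutation_p(b_upper, m)
    p_lo = permutation_p(b_lower, m)
    return PermutationResult(
        electrode=electrode, component=component, contrast=contrast,
        observed=observed, b_upper=b_upper, m=m, p_upper=p_up, p_lower=p_lo,
        p_two_tailed=two_tailed(p_up, p_lo))


def chi2_inhomogeneity(O, n) -> float:
    """Pearson statistic for non-uniform proportions across ROIs.

    E_i = n_i * (sum O / sum n); ROIs with E_i = 0 and O_i = 0 contribute 0.
    """
    O = np.asarray(O, dtype=float)
    n = np.asarray(n, dtype=float)
    if O.shape != n.shape:
        raise InvalidCountsError("O and n must have the same length")
    if np.any(n <= 0):
        raise InvalidCountsError("every ROI must contain electrodes")
    if np.any(O < 0) or np.any(O > n) or O.sum() > n.sum():
        raise InvalidCountsError("counts out of range")
    rate = O.sum() / n.sum()
    E = n * rate
    if rate == 0:
        return 0.0
    return float(((O - E) ** 2 / E).sum())


@dataclass
class IndependenceTestResult:
    observed_counts: np.ndarray
    totals: np.ndarray
    chi2_observed: float
    null_chi2: np.ndarray
    p_empirical: float


def randomization_independence_test(O, n, m: int = 10000,
                                    seed: int | np.random.Generator = 0
                                    ) -> IndependenceTestResult:
    """Empirical-null chi-square test of uniform effect occurrence.

    Null draws reassign the sum(O) significant flags across the sum(n)
    electrodes while keeping the per-ROI electrode totals fixed — a
    multivariate hypergeometric reallocation. p = (#{chi2_null >= chi2_obs}
    + 1) / (m + 1).
    """
    O = np.asarray(O, dtype=int)
    n = np.asarray(n, dtype=int)
    chi2_obs = chi2_inhomogeneity(O, n)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(n, int(O.sum()), size=m)
    rate = O.sum() / n.sum()
    E = n * rate
    if rate == 0:
        null = np.zeros(m)
    else:
        null = ((draws - E) ** 2 / E).sum(axis=1)
    b = int((null >= chi2_obs - 1e-12).sum())
    return IndependenceTestResult(
        observed_counts=O, totals=n, chi2_observed=chi2_obs, null_chi2=null,
        p_empirical=permutation_p(b, m))


def fdr_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fdr_across_electrodes(results: list) -> pd.DataFrame:
    """Attach FDR-adjusted two-tailed p-values across a set of
    per-electrode permutation results (one row each)."""
    if not results:
        return pd.DataFrame()
    df = pd.DataFrame([vars(r) for r in results])
    df["p_fdr"] = fdr_adjust(df["p_two_tailed"].to_numpy())
    for r, adj in zip(results, df["p_fdr"]):
        r.p_fdr = float(adj)
    return df
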