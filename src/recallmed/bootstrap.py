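"""Bias-corrected and accelerated (BCa) bootstrap machinery.

The BCa interval adjusts plain percentile endpoints by a bias-correction
constant z0 (the normal quantile of the fraction of replicates below the
observed statistic) and an acceleration constant a (from the jackknife
third-moment skewness formula), then reads off the empirical quantiles at the
adjusted levels.  Hypothesis tests use the bootstrap standard error with a
normal approximation.

Resample indices are generated once per run from the seed and shared across
all statistics evaluated on the same cohort, so interleaving statistics never
perturbs the replicate stream.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

__all__ = ["BcaInterval", "BootstrapPlan", "bca_ci", "boot_se_test"]


@dataclass
class BcaInterval:
    point: float
    lo: float
    hi: float
    level: float
    B: int
    z0: float
    a: float
    method_used: str  # "bca" or "percentile_fallback"


class BootstrapPlan:
    """A reusable set of resample index rows (optionally within-stratum).

    Stratified runs resample within each stratum so stratum sizes are
    preserved, as in gender-stratified tables.
    """

    def __init__(self, n: int, B: int, seed: int,
                 strata: np.ndarray | None = None) -> None:
        if B < 2:
            raise ValueError("B must be at least 2")
        rng = np.random.default_rng(seed)
        if strata is None:
            self.indices = rng.integers(0, n, size=(B, n))
        else:
            strata = np.asarray(strata)
            idx = np.empty((B, n), dtype=np.int64)
            for s in np.unique(strata):
                pos = np.flatnonzero(strata == s)
                draw = rng.integers(0, len(pos), size=(B, len(pos)))
                idx[:, pos] = pos[draw]
            self.indices = idx
        self.n = n
        self.B = B
        self.seed = seed


def _type1_quantile(sorted_vals: np.ndarray, q: float) -> float:
    """Nearest-order-statistic (type-1) quantile for determinism."""
    B = len(sorted_vals)
    k = int(np.ceil(q * B)) - 1
    return float(sorted_vals[min(max(k, 0), B - 1)])


def _jackknife_groups(n: int, max_groups: int = 200) -> list[np.ndarray]:
    """Leave-one-out for n <= max_groups, delete-block otherwise."""
    if n <= max_groups:
        return [np.delete(np.arange(n), i) for i in range(n)]
    bounds = np.linspace(0, n, max_groups + 1).astype(int)
    all_idx = np.arange(n)
    return [np.concatenate([all_idx[:lo], all_idx[hi:]])
            for lo, hi in zip(bounds[:-1], bounds[1:])]


def _acceleration(theta_jack: np.ndarray) -> float:
    d = theta_jack.mean() - theta_jack
    denom = (d**2).sum() ** 1.5
    if denom == 0:
        return 0.0
    return float((d**3).sum() / (6 * denom))


def _bca_from_replicates(point: float, thetas: np.ndarray,
                         theta_jack: np.ndarray, level: float) -> BcaInterval:
    B = len(thetas)
    srt = np.sort(thetas)
    alpha = (1 - level) / 2
    if np.ptp(thetas) == 0:
        warnings.warn("degenerate bootstrap distribution; percentile fallback",
                      stacklevel=3)
        return BcaInterval(point, float(srt[0]), float(srt[-1]), level, B,
                           0.0, 0.0, "percentile_fallback")
    prop = np.mean(thetas < point)
    if prop == 0 or prop == 1:
        warnings.warn("all replicates on one side of the estimate; "
                      "percentile fallback", stacklevel=3)
        return BcaInterval(point, _type1_quantile(srt, alpha),
                           _type1_quantile(srt, 1 - alpha), level, B,
                           np.inf if prop == 1 else -np.inf, 0.0,
                           "percentile_fallback")
    z0 = float(ndtri(prop))
    a = _acceleration(theta_jack)
    z_lo, z_hi = ndtri(alpha), ndtri(1 - alpha)
    a1 = float(ndtr(z0 + (z0 + z_lo) / (1 - a * (z0 + z_lo))))
    a2 = float(ndtr(z0 + (z0 + z_hi) / (1 - a * (z0 + z_hi))))
    return BcaInterval(point, _type1_quantile(srt, a1),
                       _type1_quantile(srt, a2), level, B, z0, a, "bca")


def bca_ci(statistic, cohort: pd.DataFrame, B: int = 500, level: float = 0.99,
           seed: int = 0, strata: str | None = None,
           plan: BootstrapPlan | None = None) -> BcaInterval:
    """BCa confidence interval for ``statistic(cohort) -> float``.

    Subjects (rows) are resampled ``B`` times; pass ``strata`` to resample
    within the levels of that column.  A precomputed :class:`BootstrapPlan`
    may be supplied to share resample indices across statistics.
    """
    n = len(cohort)
    point = float(statistic(cohort))
    if not np.isfinite(point):
        raise ValueError("statistic is not finite on the observed cohort")
    if plan is None:
        svals = cohort[strata].to_numpy() if strata else None
        plan = BootstrapPlan(n, B, seed, strata=svals)
    thetas = np.array([float(statistic(cohort.iloc[row]))
                       for row in plan.indices])
    theta_jack = np.array([float(statistic(cohort.iloc[keep]))
                           for keep in _jackknife_groups(n)])
    return _bca_from_replicates(point, thetas, theta_jack, level)


def boot_se_test(statistic, cohort: pd.DataFrame, B: int = 500, seed: int = 0,
                 null_value: float = 0.0,
                 plan: BootstrapPlan | None = None
                 ) -> tuple[float, float, float]:
    """Bootstrap-SE hypothesis test: ``z = (point − null) / sd(replicates)``,
    two-sided normal p."""
    if (plan.B if plan is not None else B) < 50:
        raise ValueError("B must be at least 50 for a bootstrap SE test")
    n = len(cohort)
    point = float(statistic(cohort))
    if plan is None:
        plan = BootstrapPlan(n, B, seed)
    thetas = np.array([float(statistic(cohort.iloc[row]))
                       for row in plan.indices])
    se = float(thetas.std(ddof=1))
    if se == 0:
        warnings.warn("zero bootstrap SE; p undefined", stacklevel=2)
        return se, np.nan, np.nan
    z = (point - null_value) / se
    p = float(2 * (1 - ndtr(abs(z))))
    return se, float(z), p
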