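"""Quantifying differential recall bias.

When a retrospective exposure is reported at two waves, and the later report
is contaminated by the subject's current health, effect estimates based on
the later report are inflated.  The bias is quantified as the % difference
between estimates based on the early (T4) and late (T6) reports:

    %diff TE = [(DE.T6 + IE.T6) − (DE.T4 + IE.T4)] / (DE.T6 + IE.T6) × 100
    %diff DE = [(TE.T6 − IE.T6) − (TE.T4 − IE.T4)] / (TE.T6 − IE.T6) × 100

with the presumed-more-contaminated (T6) estimate in the denominator.  By the
identity TE = DE + IE these are (TE.T6 − TE.T4)/TE.T6 and
(DE.T6 − DE.T4)/DE.T6.  Contrasts of relative risks use the log-RR scale;
contrasts of linear model-ladder coefficients use the identity scale with the
less-adjusted estimate in the denominator.  Inference is by bootstrap:
subjects are resampled once per replicate, both the T4- and T6-based model
sets are refit on the same resample, the CI is BCa, and the p-value is a
normal approximation on the bootstrap SE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .bootstrap import BcaInterval, BootstrapPlan, _bca_from_replicates, \
    _jackknife_groups
from .mediation import EffectDecomposition, _decomp_stats, decompose

__all__ = ["RecallBiasContrast", "pct_diff_total", "pct_diff_direct",
           "pct_diff_log_rr", "pct_attenuation_linear", "contrast_inference",
           "recall_bias_table"]


@dataclass
class RecallBiasContrast:
    """A % difference between two estimates of the same quantity."""

    quantity: str  # total_effect | direct_effect | rr_log_scale | linear_attenuation
    estimate_t4: float  # earlier / more-adjusted estimate
    estimate_t6: float  # later / less-adjusted estimate (denominator)
    pct_difference: float
    ci: BcaInterval | None = None
    p_value: float = np.nan


def _pct(numer_new: float, numer_old: float, label: str) -> float:
    if abs(numer_new) < 1e-12:
        warnings.warn(f"{label}: zero denominator; % difference undefined",
                      stacklevel=3)
        return np.nan
    return (numer_new - numer_old) / numer_new * 100


def pct_diff_total(decomp_t4: EffectDecomposition,
                   decomp_t6: EffectDecomposition) -> RecallBiasContrast:
    """% difference in total effects between the two exposure reports."""
    te4 = decomp_t4.direct_effect + decomp_t4.indirect_effect
    te6 = decomp_t6.direct_effect + decomp_t6.indirect_effect
    assert abs(te4 - decomp_t4.total_effect) < 1e-10
    assert abs(te6 - decomp_t6.total_effect) < 1e-10
    return RecallBiasContrast("total_effect", te4, te6,
                              _pct(te6, te4, "total effect"))


def pct_diff_direct(decomp_t4: EffectDecomposition,
                    decomp_t6: EffectDecomposition) -> RecallBiasContrast:
    """% difference in direct effects between the two exposure reports."""
    de4 = decomp_t4.total_effect - decomp_t4.indirect_effect
    de6 = decomp_t6.total_effect - decomp_t6.indirect_effect
    assert abs(de4 - decomp_t4.direct_effect) < 1e-10
    assert abs(de6 - decomp_t6.direct_effect) < 1e-10
    return RecallBiasContrast("direct_effect", de4, de6,
                              _pct(de6, de4, "direct effect"))


def pct_diff_log_rr(rr_t4: float, rr_t6: float) -> RecallBiasContrast:
    """% difference between two relative risks, on the log-RR scale.

    ``(ln RR.T6 − ln RR.T4) / ln RR.T6 × 100`` — the comparison scale on
    which printed RR pairs reconcile with their printed % differences.
    """
    if rr_t4 <= 0 or rr_t6 <= 0:
        raise ValueError("relative risks must be positive")
    l4, l6 = np.log(rr_t4), np.log(rr_t6)
    if abs(l6) < 1e-12:
        warnings.warn("RR.T6 = 1: zero log denominator; % difference undefined",
                      stacklevel=2)
        return RecallBiasContrast("rr_log_scale", rr_t4, rr_t6, np.nan)
    return RecallBiasContrast("rr_log_scale", rr_t4, rr_t6,
                              float((l6 - l4) / l6 * 100))


def pct_attenuation_linear(beta_less_adjusted: float,
                           beta_more_adjusted: float) -> RecallBiasContrast:
    """Attenuation of a linear coefficient after adding an adjustment term,
    as a % of the less-adjusted (presumed more contaminated) estimate."""
    return RecallBiasContrast(
        "linear_attenuation", beta_more_adjusted, beta_less_adjusted,
        _pct(beta_less_adjusted, beta_more_adjusted, "linear attenuation"))


def contrast_inference(contrast_fn, cohort: pd.DataFrame, B: int = 500,
                       level: float = 0.99, seed: int = 0,
                       quantity: str = "contrast") -> RecallBiasContrast:
    """Bootstrap CI and p-value for an arbitrary % contrast of a cohort.

    ``contrast_fn(cohort) -> (estimate_t4, estimate_t6, pct)``; subjects are
    resampled once per replicate so the two estimates stay paired.  The
    p-value tests pct = 0 via z = pct / bootstrap SE.
    """
    if B <= 0:
        raise ValueError("B must be positive")
    n = len(cohort)
    e4, e6, point = contrast_fn(cohort)
    plan = BootstrapPlan(n, B, seed)
    pcts = np.array([contrast_fn(cohort.iloc[rows])[2]
                     for rows in plan.indices], dtype=float)
    jack = np.array([contrast_fn(cohort.iloc[keep])[2]
                     for keep in _jackknife_groups(n)], dtype=float)
    ok = np.isfinite(pcts)
    ci = _bca_from_replicates(float(point), pcts[ok], jack[np.isfinite(jack)],
                              level)
    se = pcts[ok].std(ddof=1)
    if se == 0 or not np.isfinite(point):
        warnings.warn("degenerate bootstrap distribution; p undefined",
                      stacklevel=2)
        p = np.nan
    else:
        p = float(2 * (1 - ndtr(abs(point) / se)))
    return RecallBiasContrast(quantity, float(e4), float(e6), float(point),
                              ci, p)


def recall_bias_table(cohort: pd.DataFrame, outcome: str,
                      confounders: tuple[str, ...] = (),
                      mediators: tuple[str, ...] = ("psych_abuse", "phys_abuse"),
                      wave_columns: tuple[str, str] = ("cses_t4", "cses_t6"),
                      B: int = 500, level: float = 0.99, seed: int = 0
                      ) -> dict[str, RecallBiasContrast]:
    """% differences in total and direct effects between the two exposure
    reports, with paired-bootstrap BCa CIs and p-values.

    Refits all four models (total and direct, per wave) on each resample.
    """
    w4, w6 = wave_columns
    cols = [outcome, w4, w6, *confounders, *mediators]
    data = cohort[cols].dropna().reset_index(drop=True)
    n = len(data)
    y = data[outcome].to_numpy(dtype=float)
    ones = np.ones(n)
    conf = [data[c].to_numpy(dtype=float) for c in confounders]
    meds = [data[m].to_numpy(dtype=float) for m in mediators]
    designs = {}
    for wave, col in (("t4", w4), ("t6", w6)):
        Xt = np.column_stack([ones, data[col].to_numpy(dtype=float), *conf])
        Xd = np.column_stack([Xt, *meds])
        designs[wave] = (Xt, Xd)

    def stats_at(rows: np.ndarray | None) -> np.ndarray:
        out = []
        for wave in ("t4", "t6"):
            Xt, Xd = designs[wave]
            out.append(_decomp_stats(y, Xt, Xd, rows)[:2])  # TE, DE
        (te4, de4), (te6, de6) = out
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p_te = _pct(te6, te4, "TE")
            p_de = _pct(de6, de4, "DE")
        return np.array([te4, de4, te6, de6, p_te, p_de])

    point = stats_at(None)
    plan = BootstrapPlan(n, B, seed)
    reps = np.vstack([stats_at(rows) for rows in plan.indices])
    jack = np.vstack([stats_at(keep) for keep in _jackknife_groups(n)])

    result = {}
    for name, j, e4_i, e6_i in (("total_effect", 4, 0, 2),
                                ("direct_effect", 5, 1, 3)):
        col, jcol = reps[:, j], jack[:, j]
        ok = np.isfinite(col)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ci = _bca_from_replicates(float(point[j]), col[ok],
                                      jcol[np.isfinite(jcol)], level)
        se = col[ok].std(ddof=1)
        p = (float(2 * (1 - ndtr(abs(point[j]) / se)))
             if se > 0 and np.isfinite(point[j]) else np.nan)
        result[name] = RecallBiasContrast(name, float(point[e4_i]),
                                          float(point[e6_i]), float(point[j]),
                                          ci, p)
    return result
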