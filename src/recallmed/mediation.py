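"""Difference-method mediation analysis.

The total effect (TE) is the exposure coefficient from the outcome model
adjusted for confounders only; the direct effect (DE) additionally adjusts
for the mediators; the indirect effect is their difference,

    IE = TE − DE,

and the proportion mediated is

    PM(%) = (TE − DE) / (DE + IE) × 100,

algebraically identical to IE/TE × 100.  Both mediators (psychological and
physical childhood abuse) enter the direct model jointly.  Confidence
intervals come from the BCa bootstrap, resampling subjects once per replicate
and refitting both models on the same resample so the TE − DE difference is
computed within-pair.

Validity rests on no exposure–mediator or mediator–mediator multiplicative
interaction (screened separately) and no exposure-induced mediator–outcome
confounder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bootstrap import BcaInterval, BootstrapPlan, _bca_from_replicates, \
    _jackknife_groups
from .regression import FitResult, ModelSpec, fit_ols, fit_poisson_rr

__all__ = ["EffectDecomposition", "decompose", "run_model_ladder",
           "point_decomposition", "mediation_table"]

PM_EPSILON = 1e-6


@dataclass
class EffectDecomposition:
    """Total, direct and indirect effect with proportion mediated."""

    total_effect: float
    direct_effect: float
    indirect_effect: float
    proportion_mediated: float  # percent; NaN when TE ~ 0
    exposure_wave: str = ""
    outcome_name: str = ""
    ci: dict = field(default_factory=dict)  # quantity -> BcaInterval

    def __post_init__(self) -> None:
        resid = self.total_effect - self.direct_effect - self.indirect_effect
        if abs(resid) > 1e-10:
            raise ValueError("indirect effect must equal total minus direct")

    def to_dict(self) -> dict:
        return {"exposure_wave": self.exposure_wave,
                "outcome": self.outcome_name,
                "total_effect": self.total_effect,
                "direct_effect": self.direct_effect,
                "indirect_effect": self.indirect_effect,
                "proportion_mediated_pct": self.proportion_mediated}


def decompose(total_fit_beta: float, direct_fit_beta: float,
              exposure_wave: str = "", outcome_name: str = ""
              ) -> EffectDecomposition:
    """Point decomposition of a total and a direct exposure coefficient."""
    te = float(total_fit_beta)
    de = float(direct_fit_beta)
    ie = te - de
    if abs(de + ie) < PM_EPSILON:
        warnings.warn("total effect near zero; proportion mediated undefined",
                      stacklevel=2)
        pm = np.nan
    else:
        pm = (te - de) / (de + ie) * 100
        if pm < 0 or pm > 100:
            warnings.warn(
                f"inconsistent mediation: proportion mediated {pm:.1f}% "
                "outside [0, 100] (opposite-signed direct and indirect paths)",
                stacklevel=2)
    return EffectDecomposition(te, de, ie, pm, exposure_wave, outcome_name)


def run_model_ladder(cohort: pd.DataFrame,
                     ladder: list[tuple[str, ModelSpec]]
                     ) -> list[tuple[str, ModelSpec, FitResult]]:
    """Fit a nested sequence of models (each term set a superset of the last)
    and return (label, spec, fit) triples."""
    prev: set[str] = set()
    out = []
    for label, spec in ladder:
        terms = set(spec.terms)
        if not prev <= terms:
            raise ValueError(f"ladder model {label!r} is not a superset of "
                             "the previous model's terms")
        prev = terms
        fitter = fit_poisson_rr if spec.family == "poisson_robust" else fit_ols
        try:
            fit = fitter(cohort, spec)
        except Exception as exc:
            raise RuntimeError(f"model {label!r} failed: {exc}") from exc
        out.append((label, spec, fit))
    return out


def _ols_coef(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.linalg.lstsq(X, y, rcond=None)[0]


def _decomp_stats(y: np.ndarray, Xt: np.ndarray, Xd: np.ndarray,
                  rows: np.ndarray | None = None) -> np.ndarray:
    """(TE, DE, IE, PM) from the total/direct designs, optionally resampled.

    The exposure is column 1 of both designs (after the intercept)."""
    if rows is not None:
        y, Xt, Xd = y[rows], Xt[rows], Xd[rows]
    te = _ols_coef(Xt, y)[1]
    de = _ols_coef(Xd, y)[1]
    ie = te - de
    pm = (te - de) / (de + ie) * 100 if abs(de + ie) >= PM_EPSILON else np.nan
    return np.array([te, de, ie, pm])


def point_decomposition(cohort: pd.DataFrame, exposure: str, outcome: str,
                        mediators: tuple[str, ...] = ("psych_abuse",
                                                      "phys_abuse"),
                        confounders: tuple[str, ...] = ()
                        ) -> EffectDecomposition:
    """Decomposition point estimates without bootstrap intervals."""
    cols = [outcome, exposure, *confounders, *mediators]
    data = cohort[cols].dropna()
    y = data[outcome].to_numpy(dtype=float)
    ones = np.ones(len(data))
    Xt = np.column_stack([ones] + [data[c].to_numpy(dtype=float)
                                   for c in (exposure, *confounders)])
    Xd = np.column_stack([Xt] + [data[m].to_numpy(dtype=float)
                                 for m in mediators])
    te, de, _, _ = _decomp_stats(y, Xt, Xd)
    dec = decompose(te, de, outcome_name=outcome)
    dec.exposure_wave = exposure
    return dec


def mediation_table(cohort: pd.DataFrame, exposure: str, outcome: str,
                    mediators: tuple[str, ...] = ("psych_abuse", "phys_abuse"),
                    confounders: tuple[str, ...] = (),
                    B: int = 500, level: float = 0.99, seed: int = 0
                    ) -> EffectDecomposition:
    """Difference-method decomposition with BCa bootstrap intervals.

    Total model: ``outcome ~ exposure + confounders``; direct model adds both
    mediators jointly.  Each bootstrap replicate resamples subjects once and
    refits both models on that resample.
    """
    if B < 100:
        warnings.warn("fewer than 100 bootstrap replicates: BCa intervals "
                      "will be unstable", stacklevel=2)
    cols = [outcome, exposure, *confounders, *mediators]
    data = cohort[cols].dropna()
    n = len(data)
    y = data[outcome].to_numpy(dtype=float)
    ones = np.ones(n)
    Xt = np.column_stack([ones] + [data[c].to_numpy(dtype=float)
                                   for c in (exposure, *confounders)])
    Xd = np.column_stack([Xt] + [data[m].to_numpy(dtype=float)
                                 for m in mediators])

    point = _decomp_stats(y, Xt, Xd)
    # cross-check the fast path against the regression backend
    te_fit = fit_ols(data, ModelSpec(outcome, (exposure,), tuple(confounders),
                                     "ols", level))
    assert abs(te_fit.coef(exposure) - point[0]) < 1e-8

    plan = BootstrapPlan(n, B, seed)
    thetas = np.vstack([_decomp_stats(y, Xt, Xd, rows)
                        for rows in plan.indices])
    jack = np.vstack([_decomp_stats(y, Xt, Xd, keep)
                      for keep in _jackknife_groups(n)])

    names = ("total_effect", "direct_effect", "indirect_effect",
             "proportion_mediated")
    cis: dict[str, BcaInterval] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j, name in enumerate(names):
            col = thetas[:, j]
            jcol = jack[:, j]
            if np.isnan(point[j]) or np.isnan(col).all():
                continue
            ok = ~np.isnan(col)
            cis[name] = _bca_from_replicates(float(point[j]), col[ok],
                                             jcol[~np.isnan(jcol)], level)
    dec = decompose(point[0], point[1], outcome_name=outcome)
    dec.exposure_wave = exposure
    dec.ci = cis
    return dec
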