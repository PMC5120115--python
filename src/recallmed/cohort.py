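"""Synthetic cohort generator.

Emulates a two-wave cohort in which an ordinal 4-category childhood
socioeconomic status (CSES, 1 = very good .. 4 = very difficult) is reported
retrospectively at two waves: the earlier report (T4) carries nondifferential
±1-category misclassification, while the later report (T6) is additionally
contaminated by the subject's current health — less healthy subjects are more
likely to recall their childhood finances one category worse.  Two correlated
binary childhood-abuse mediators are driven by true CSES, and three continuous
outcomes on the [0, 10] worst-is-10 scale are driven by CSES, the mediators,
confounders and gender interactions.

The causal structure contains no exposure-induced mediator–outcome confounder
(a requirement of difference-method mediation), which
:func:`dependency_edges` exposes as a machine-checkable edge list.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .scoring import weighted_kappa

__all__ = [
    "SimulationParams",
    "generate_cohort",
    "apply_recall_model",
    "induce_missingness",
    "calibrate_misclassification",
    "dependency_edges",
    "write_cohort",
    "read_cohort",
]

OUTCOME_NAMES = ("mental_health", "general_health", "well_being")
CONFOUNDERS = ("mother_psych_history", "father_psych_history",
               "passive_smoke", "in_country_age1")


@dataclass
class SimulationParams:
    """All coefficients of the data-generating process.

    Defaults describe a cohort resembling the motivating two-wave survey:
    54% women aged 25–74, confounder prevalences (maternal/paternal
    psychological-problem history, childhood passive smoke, living in the
    country at age 1), a CSES distribution with ~34% in the two worst
    categories, abuse risks rising ~1.6–1.9-fold per CSES category with
    marginal prevalences near 8% (psychological) and 5% (physical), and
    outcome effects of ~0.15 per CSES category and 0.3–0.4 per abuse flag.
    """

    n: int = 10_000
    seed: int = 0
    p_female: float = 0.54
    age_range: tuple[int, int] = (25, 74)
    confounder_prevalences: tuple[float, float, float, float] = (
        0.065, 0.025, 0.735, 0.979)
    cses_category_probs: tuple[float, float, float, float] = (
        0.037, 0.626, 0.313, 0.024)
    # Cumulative log-odds shifts of worse CSES per confounder (proportional
    # odds); exposure is allowed to depend on family-background confounders.
    cses_confounder_log_or: tuple[float, float, float, float] = (
        0.4, 0.4, 0.2, 0.0)
    log_rr_psych: float = float(np.log(1.85))
    log_rr_phys: float = float(np.log(1.60))
    baseline_abuse_risk: tuple[float, float] = (0.033, 0.028)
    mediator_coupling: float = 3.5  # log odds ratio of abuse co-occurrence
    outcome_intercept: float = 3.0
    beta_direct: float = 0.15
    beta_psych: float = 0.4
    beta_phys: float = 0.3
    beta_confounders: tuple[float, float, float, float] = (0.5, 0.5, 0.1, 0.0)
    beta_female: float = 0.25
    # products female×(cses-1), female×psych, female×phys
    gender_interaction_terms: tuple[float, float, float] = (0.05, 0.15, 0.05)
    beta_age: float = 0.0
    noise_sd: float = 1.2
    # Calibrated once (see calibrate_misclassification) so the early report's
    # weighted kappa against the truth is ~0.63 under the default CSES mix.
    p_misclass_t4: float = 0.26
    delta_recall: float = 0.5  # log-odds of worse T6 recall per outcome SD
    delta_recall_t4: float = 0.0  # off by default: T4 assumed nondifferential
    abuse_overreport_delta_psych_female: float = 0.0
    abuse_overreport_delta_phys_male: float = 0.0
    missing_rates: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("n must be at least 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        probs = np.asarray(self.cses_category_probs, dtype=float)
        if probs.shape != (4,) or np.any(probs < 0) or abs(probs.sum() - 1) > 1e-8:
            raise ValueError("cses_category_probs must be 4 probabilities summing to 1")
        for name in ("p_female", "p_misclass_t4"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for v in list(self.confounder_prevalences) + list(self.baseline_abuse_risk):
            if not 0 <= v <= 1:
                raise ValueError("prevalences and baseline risks must be in [0, 1]")
        for base, log_rr, label in (
            (self.baseline_abuse_risk[0], self.log_rr_psych, "psychological"),
            (self.baseline_abuse_risk[1], self.log_rr_phys, "physical"),
        ):
            if base * np.exp(3 * log_rr) > 1:
                raise ValueError(
                    f"{label} abuse risk exceeds 1 at the worst CSES category; "
                    "lower baseline_abuse_risk or the log RR")
        for rate in self.missing_rates.values():
            if not 0 <= rate <= 1:
                raise ValueError("missing rates must be in [0, 1]")

    def replace(self, **kw) -> "SimulationParams":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["age_range"] = list(d["age_range"])
        return d


def _null_params(**kw) -> SimulationParams:
    """All effect coefficients zero: a fully null data-generating process."""
    base = SimulationParams(
        cses_confounder_log_or=(0, 0, 0, 0),
        log_rr_psych=0.0, log_rr_phys=0.0, mediator_coupling=0.0,
        beta_direct=0.0, beta_psych=0.0, beta_phys=0.0,
        beta_confounders=(0, 0, 0, 0), beta_female=0.0,
        gender_interaction_terms=(0, 0, 0),
        p_misclass_t4=0.0, delta_recall=0.0,
    )
    return base.replace(**kw)


SimulationParams.null = staticmethod(_null_params)


def _plackett_joint(p1: np.ndarray, p2: np.ndarray, log_or: float) -> np.ndarray:
    """P(both = 1) for two Bernoullis with given marginals and odds ratio."""
    psi = np.exp(log_or)
    if abs(psi - 1) < 1e-12:
        return p1 * p2
    s = 1 + (p1 + p2) * (psi - 1)
    return (s - np.sqrt(s**2 - 4 * psi * (psi - 1) * p1 * p2)) / (2 * (psi - 1))


def apply_recall_model(cses_true: np.ndarray, outcome_z: np.ndarray,
                       params: SimulationParams, seed: int
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Produce the two retrospective CSES reports.

    The early report flips ±1 category with probability ``p_misclass_t4``
    (symmetric, clamped to 1..4), independent of health.  The later report
    shifts one category worse with probability ``expit(kappa0 +
    delta_recall·z)`` and one better with probability ``expit(kappa0 −
    delta_recall·z)``, where ``z`` is the standardized latent outcome and
    ``kappa0`` is set so the marginal shift probability at z = 0 equals
    ``p_misclass_t4``.
    """
    cses_true = np.asarray(cses_true)
    if np.any((cses_true < 1) | (cses_true > 4)):
        raise ValueError("cses_true must lie in 1..4")
    rng = np.random.default_rng(seed)
    n = len(cses_true)

    def shifted(delta: float) -> np.ndarray:
        if params.p_misclass_t4 <= 0:
            return cses_true.copy()
        kappa0 = logit(params.p_misclass_t4 / 2)
        p_up = expit(kappa0 + delta * outcome_z)    # worse recall
        p_down = expit(kappa0 - delta * outcome_z)  # better recall
        total = p_up + p_down
        over = total > 1
        if np.any(over):  # extreme delta: renormalize to keep a valid draw
            p_up = np.where(over, p_up / total, p_up)
            p_down = np.where(over, p_down / total, p_down)
        u = rng.random(n)
        step = np.where(u < p_up, 1, np.where(u < p_up + p_down, -1, 0))
        return np.clip(cses_true + step, 1, 4)

    cses_t4 = shifted(params.delta_recall_t4)
    cses_t6 = shifted(params.delta_recall)
    return cses_t4, cses_t6


def generate_cohort(params: SimulationParams) -> pd.DataFrame:
    """Draw a cohort table from the data-generating process.

    Deterministic given ``params.seed``.  Columns: id, female, age, the four
    confounder indicators, cses_true, cses_t4, cses_t6, psych_abuse,
    phys_abuse (plus ``*_true`` twins when differential mediator reporting is
    on), abuse_freq, and the three outcomes with their latent (pre-clipping)
    values.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n

    female = (rng.random(n) < params.p_female).astype(int)
    lo, hi = params.age_range
    age = rng.integers(lo, hi + 1, size=n)
    conf = {name: (rng.random(n) < prev).astype(int)
            for name, prev in zip(CONFOUNDERS, params.confounder_prevalences)}
    conf_mat = np.column_stack([conf[c] for c in CONFOUNDERS])

    # True CSES: proportional-odds draw; confounders shift the cumulative
    # log-odds toward worse categories.
    probs = np.asarray(params.cses_category_probs)
    cum = np.cumsum(probs)[:3]
    shift = conf_mat @ np.asarray(params.cses_confounder_log_or)
    # P(cses <= k | shift) = expit(logit(cum_k) - shift)
    cum_i = expit(logit(cum)[None, :] - shift[:, None])
    u = rng.random(n)
    cses_true = 1 + (u[:, None] > cum_i).sum(axis=1)

    # Mediators: risks exponential in CSES category, joint draw with a
    # log-odds-ratio coupling (preserves both marginal RRs).
    p_psych = np.minimum(
        params.baseline_abuse_risk[0] * np.exp(params.log_rr_psych * (cses_true - 1)), 1.0)
    p_phys = np.minimum(
        params.baseline_abuse_risk[1] * np.exp(params.log_rr_phys * (cses_true - 1)), 1.0)
    p11 = _plackett_joint(p_psych, p_phys, params.mediator_coupling)
    u1, u2 = rng.random(n), rng.random(n)
    psych = (u1 < p_psych).astype(int)
    p_phys_given = np.where(psych == 1, p11 / np.maximum(p_psych, 1e-300),
                            (p_phys - p11) / np.maximum(1 - p_psych, 1e-300))
    phys = (u2 < p_phys_given).astype(int)

    # Outcomes: shared structural part plus independent noise per outcome.
    g = params.gender_interaction_terms
    linpred = (params.outcome_intercept
               + params.beta_direct * (cses_true - 1)
               + params.beta_psych * psych
               + params.beta_phys * phys
               + conf_mat @ np.asarray(params.beta_confounders)
               + params.beta_female * female
               + g[0] * female * (cses_true - 1)
               + g[1] * female * psych
               + g[2] * female * phys
               + params.beta_age * (age - age.mean()))
    data = {
        "id": np.arange(n), "female": female, "age": age, **conf,
        "cses_true": cses_true,
        "psych_abuse": psych, "phys_abuse": phys,
    }
    latents = {}
    for name in OUTCOME_NAMES:
        latent = linpred + rng.normal(0, params.noise_sd, n)
        clipped = np.clip(latent, 0.0, 10.0)
        frac = float(np.mean(latent != clipped))
        if frac > 0.01:
            warnings.warn(
                f"{name}: {frac:.1%} of outcomes clipped to [0, 10]",
                stacklevel=2)
        latents[name] = latent
        data[name] = clipped
        data[f"{name}_latent"] = latent

    # Recall contamination uses the standardized latent overall health state
    # (mean of the three latent outcomes), not the clipped scores.
    composite = np.mean([latents[o] for o in OUTCOME_NAMES], axis=0)
    sd = composite.std()
    z = (composite - composite.mean()) / (sd if sd > 0 else 1.0)
    recall_seed = int(np.random.default_rng(params.seed + 1).integers(2**31))
    cses_t4, cses_t6 = apply_recall_model(cses_true, z, params, recall_seed)
    data["cses_t4"] = cses_t4
    data["cses_t6"] = cses_t6

    # Optional differential mediator reporting (off by default).
    if params.abuse_overreport_delta_psych_female or params.abuse_overreport_delta_phys_male:
        data["psych_abuse_true"] = psych.copy()
        data["phys_abuse_true"] = phys.copy()
        p_flip_psych = expit(-4 + params.abuse_overreport_delta_psych_female * z) * female
        p_flip_phys = expit(-4 + params.abuse_overreport_delta_phys_male * z) * (1 - female)
        data["psych_abuse"] = np.maximum(psych, (rng.random(n) < p_flip_psych).astype(int))
        data["phys_abuse"] = np.maximum(phys, (rng.random(n) < p_flip_phys).astype(int))

    data["abuse_freq"] = data["psych_abuse"] + data["phys_abuse"]
    cohort = pd.DataFrame(data)

    if params.missing_rates:
        miss_seed = int(np.random.default_rng(params.seed + 2).integers(2**31))
        cohort = induce_missingness(cohort, params.missing_rates, miss_seed)
    return cohort


def induce_missingness(cohort: pd.DataFrame, missing_rates: dict,
                       seed: int) -> pd.DataFrame:
    """Blank cells missing-at-random.

    Missingness probability depends on fully observed covariates (gender and
    standardized age) through a logistic model whose intercept is solved so
    the marginal rate matches the requested rate; it never depends on the
    value being blanked.
    """
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    z_age = (cohort["age"] - cohort["age"].mean()) / max(cohort["age"].std(), 1e-12)
    driver = 0.5 * cohort["female"].to_numpy() + 0.3 * z_age.to_numpy()
    for col, rate in missing_rates.items():
        if not 0 <= rate <= 1:
            raise ValueError(f"missing rate for {col} outside [0, 1]")
        if col not in cohort.columns:
            raise KeyError(f"no column {col!r} in cohort")
        if rate == 0:
            continue
        if rate == 1:
            out[col] = np.nan
            continue
        lo_b, hi_b = -20.0, 20.0
        for _ in range(80):  # bisection on the intercept
            mid = (lo_b + hi_b) / 2
            if expit(mid + driver).mean() < rate:
                lo_b = mid
            else:
                hi_b = mid
        p = expit((lo_b + hi_b) / 2 + driver)
        mask = rng.random(len(cohort)) < p
        out[col] = out[col].astype(float).mask(mask)
    return out


def calibrate_misclassification(target_kappa: float, params: SimulationParams,
                                n: int = 20_000, seed: int = 0,
                                tol: float = 0.005, max_iter: int = 30) -> float:
    """Find ``p_misclass_t4`` giving a requested weighted kappa between the
    early report and the truth, by bisection on a large simulated draw."""
    probs = np.asarray(params.cses_category_probs)
    rng = np.random.default_rng(seed)
    cses_true = rng.choice([1, 2, 3, 4], size=n, p=probs)
    z = np.zeros(n)

    def kappa_at(p: float) -> float:
        trial = params.replace(p_misclass_t4=p, delta_recall_t4=0.0)
        t4, _ = apply_recall_model(cses_true, z, trial, seed + 1)
        return weighted_kappa(cses_true, t4)

    lo_p, hi_p = 1e-4, 0.95
    for _ in range(max_iter):
        mid = (lo_p + hi_p) / 2
        k = kappa_at(mid)
        if abs(k - target_kappa) < tol:
            return mid
        if k > target_kappa:  # too little error, increase misclassification
            lo_p = mid
        else:
            hi_p = mid
    return (lo_p + hi_p) / 2


def dependency_edges(params: SimulationParams | None = None) -> list[tuple[str, str, str]]:
    """The data-generating process's dependency graph.

    Returns (parent, child, kind) triples; kind is ``"causal"`` for directed
    structural edges and ``"bidirected"`` for the mediator co-occurrence
    (shared unmeasured liability, not caused by the exposure).
    """
    edges = []
    for c in CONFOUNDERS:
        edges.append((c, "cses_true", "causal"))
        for o in OUTCOME_NAMES:
            edges.append((c, o, "causal"))
    for m in ("psych_abuse", "phys_abuse"):
        edges.append(("cses_true", m, "causal"))
        for o in OUTCOME_NAMES:
            edges.append((m, o, "causal"))
    for o in OUTCOME_NAMES:
        edges.append(("cses_true", o, "causal"))
        edges.append(("female", o, "causal"))
        edges.append((o, "cses_t6", "causal"))  # recall contamination
    edges.append(("cses_true", "cses_t4", "causal"))
    edges.append(("cses_true", "cses_t6", "causal"))
    edges.append(("psych_abuse", "phys_abuse", "bidirected"))
    return edges


def write_cohort(cohort: pd.DataFrame, path: str | Path,
                 params: SimulationParams | None = None) -> None:
    """Write a cohort CSV with a sidecar JSON metadata file."""
    path = Path(path)
    cohort.to_csv(path, index=False, float_format="%.10g")
    meta = {"n_rows": len(cohort), "columns": list(cohort.columns)}
    if params is not None:
        meta["params"] = params.to_dict()
        meta["seed"] = params.seed
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))


def read_cohort(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read a cohort CSV (and its sidecar metadata, if present)."""
    path = Path(path)
    cohort = pd.read_csv(path)
    meta_path = path.with_suffix(".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return cohort, meta
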