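"""Outcome construction from patient-reported instruments, plus reliability
statistics.

Three adult outcomes are built, each linearly rescaled onto [0, 10] with 10
the *worst* state so that effect estimates are directly comparable:

* mental health — sum of the ten 4-point SCL-10 anxiety/depression items;
* general health — EQ-5D-3L health-state utility under a country tariff
  (UK time-trade-off value set by default), reversed and rescaled;
* well-being — sum of the first three 7-point SWLS life-satisfaction items,
  reversed so that low satisfaction scores high.

Reliability helpers (:func:`cronbach_alpha`, :func:`weighted_kappa`) cover the
internal-consistency and test–retest statistics reported for such scales.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "TariffTable",
    "ScaledOutcome",
    "load_uk_tariff",
    "score_scl10",
    "score_swls",
    "eq5d_utility",
    "rescale_general_health",
    "cronbach_alpha",
    "weighted_kappa",
]

EQ5D_DIMENSIONS = ("MO", "SC", "UA", "PD", "AD")


@dataclass(frozen=True)
class ScaledOutcome:
    """A named outcome value on the common [0, 10] worst-is-10 scale."""

    name: str
    value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 10.0 + 1e-12):
            raise ValueError(f"{self.name} score {self.value!r} outside [0, 10]")


@dataclass(frozen=True)
class TariffTable:
    """EQ-5D-3L additive tariff.

    ``utility = full_health_value − constant·1[any level > 1]
    − Σ level decrements − n3_term·1[any level = 3]``.
    """

    full_health_value: float
    any_dysfunction_constant: float
    level2_decrement: dict[str, float]
    level3_decrement: dict[str, float]
    worst_level_extra_term: float
    min_utility: float

    def __post_init__(self) -> None:
        for dim in EQ5D_DIMENSIONS:
            if dim not in self.level2_decrement or dim not in self.level3_decrement:
                raise ValueError(f"tariff missing decrements for dimension {dim}")
            d2, d3 = self.level2_decrement[dim], self.level3_decrement[dim]
            if d2 < 0 or d3 < 0:
                raise ValueError(f"negative decrement for dimension {dim}")
            if d3 < d2:
                raise ValueError(f"level-3 decrement below level-2 for {dim}")
        if self.any_dysfunction_constant < 0 or self.worst_level_extra_term < 0:
            raise ValueError("tariff constants must be non-negative")
        if self.min_utility >= self.full_health_value:
            raise ValueError("min_utility must be below full_health_value")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TariffTable":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "TariffTable":
        return cls(
            full_health_value=float(raw.get("full_health_value", 1.0)),
            any_dysfunction_constant=float(raw["constant"]),
            level2_decrement={d: float(raw[f"{d}2"]) for d in EQ5D_DIMENSIONS},
            level3_decrement={d: float(raw[f"{d}3"]) for d in EQ5D_DIMENSIONS},
            worst_level_extra_term=float(raw["N3"]),
            min_utility=float(raw["min_utility"]),
        )


def load_uk_tariff() -> TariffTable:
    """The UK EQ-5D-3L time-trade-off value set shipped with the package."""
    ref = resources.files("recallmed").joinpath("tariffs/uk_tto.yaml")
    return TariffTable.from_dict(yaml.safe_load(ref.read_text()))


def _check_items(items, n_items: int, lo: int, hi: int, label: str) -> np.ndarray:
    arr = np.asarray(items)
    if arr.shape != (n_items,):
        raise ValueError(f"{label} expects {n_items} items, got shape {arr.shape}")
    if not np.all(arr == np.floor(arr)):
        raise ValueError(f"{label} items must be whole numbers")
    for i, v in enumerate(arr):
        if not (lo <= v <= hi):
            raise ValueError(f"{label} item {i + 1} level {v} outside [{lo}, {hi}]")
    return arr.astype(int)


def score_scl10(items) -> ScaledOutcome:
    """Mental-health score from ten SCL-10 items (each 1..4).

    The item sum (range 10..40) is mapped affinely onto [0, 10], 10 being the
    worst mental health.
    """
    arr = _check_items(items, 10, 1, 4, "SCL-10")
    value = (arr.sum() - 10) / 30 * 10
    return ScaledOutcome("mental_health", float(value))


def score_swls(items) -> ScaledOutcome:
    """Well-being score from the first three SWLS items (each 1..7).

    The item sum (range 3..21) is reversed and mapped onto [0, 10], 10 being
    the lowest well-being.
    """
    arr = _check_items(items, 3, 1, 7, "SWLS")
    value = (21 - arr.sum()) / 18 * 10
    return ScaledOutcome("well_being", float(value))


def parse_eq5d_state(state) -> np.ndarray:
    """Accept a 5-digit string like ``"11223"`` or a length-5 sequence."""
    if isinstance(state, str):
        if len(state) != 5 or not state.isdigit():
            raise ValueError(f"EQ-5D state string must be 5 digits, got {state!r}")
        state = [int(ch) for ch in state]
    return _check_items(state, 5, 1, 3, "EQ-5D")


def eq5d_utility(state, tariff: TariffTable) -> float:
    """Tariff utility of an EQ-5D-3L health state (1 = full health)."""
    levels = parse_eq5d_state(state)
    u = tariff.full_health_value
    if np.any(levels > 1):
        u -= tariff.any_dysfunction_constant
    for dim, level in zip(EQ5D_DIMENSIONS, levels):
        if level == 2:
            u -= tariff.level2_decrement[dim]
        elif level == 3:
            u -= tariff.level3_decrement[dim]
    if np.any(levels == 3):
        u -= tariff.worst_level_extra_term
    return float(u)


def rescale_general_health(utility: float, tariff: TariffTable) -> ScaledOutcome:
    """Map a tariff utility onto [0, 10] with 10 the lowest general health.

    Anchored at the tariff's theoretical range [min_utility, full_health_value]
    so that the transform is reproducible without reference to any sample.
    """
    lo, hi = tariff.min_utility, tariff.full_health_value
    if not (lo - 1e-12 <= utility <= hi + 1e-12):
        raise ValueError(f"utility {utility} outside tariff range [{lo}, {hi}]")
    value = (hi - utility) / (hi - lo) * 10
    return ScaledOutcome("general_health", float(np.clip(value, 0.0, 10.0)))


def cronbach_alpha(item_matrix) -> tuple[float, float]:
    """Cronbach's alpha and the mean inter-item correlation.

    ``alpha = k/(k−1) · (1 − Σ item variances / variance of row sums)``; the
    mean inter-item correlation averages the k(k−1)/2 pairwise Pearson
    correlations.
    """
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("item matrix must be 2-dimensional (subjects × items)")
    n, k = x.shape
    if k < 2 or n < 3:
        raise ValueError("need at least 2 items and 3 subjects")
    item_var = x.var(axis=0, ddof=1)
    if np.any(item_var == 0):
        bad = int(np.flatnonzero(item_var == 0)[0])
        raise ValueError(f"item column {bad} is constant; correlation undefined")
    total_var = x.sum(axis=1).var(ddof=1)
    alpha = k / (k - 1) * (1 - item_var.sum() / total_var)
    corr = np.corrcoef(x, rowvar=False)
    iu = np.triu_indices(k, 1)
    return float(alpha), float(corr[iu].mean())


def weighted_kappa(x, y, weights: str = "linear") -> float:
    """Weighted Cohen's kappa between two ordinal ratings.

    ``kappa = 1 − Σ w_ij O_ij / Σ w_ij E_ij`` with disagreement weights
    ``w_ij = |i−j|`` (linear, default) or ``(i−j)²`` (quadratic), O the
    observed and E the chance-expected contingency proportions.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("ratings must be 1-d vectors of equal length")
    cats = np.unique(np.concatenate([x, y]))
    if len(np.unique(x)) < 2 and len(np.unique(y)) < 2:
        raise ValueError("no variation in either rating vector")
    k = len(cats)
    idx = {c: i for i, c in enumerate(cats)}
    obs = np.zeros((k, k))
    for xi, yi in zip(x, y):
        obs[idx[xi], idx[yi]] += 1
    obs /= obs.sum()
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0))
    diff = np.subtract.outer(np.arange(k), np.arange(k))
    if weights == "linear":
        w = np.abs(diff).astype(float)
    elif weights == "quadratic":
        w = diff.astype(float) ** 2
    else:
        raise ValueError(f"unknown weight scheme {weights!r}")
    return float(1.0 - (w * obs).sum() / (w * exp).sum())
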