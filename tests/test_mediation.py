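"""Difference-method decomposition and model ladders."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from recallmed import (ModelSpec, SimulationParams, decompose, fit_ols,
                       generate_cohort, mediation_table, point_decomposition,
                       run_model_ladder)
from tests.conftest import ADJUST


def test_decompose_worked_example():
    """A 0.18 total and 0.15 direct effect leave a 0.03 indirect effect and
    16.67% mediated (on these two-decimal inputs)."""
    dec = decompose(0.18, 0.15)
    assert dec.indirect_effect == pytest.approx(0.03)
    assert dec.proportion_mediated == pytest.approx(100 / 6, abs=1e-9)


def test_decompose_no_mediation():
    dec = decompose(0.25, 0.25)
    assert dec.indirect_effect == 0.0
    assert dec.proportion_mediated == 0.0


def test_decompose_near_zero_total_is_undefined():
    with pytest.warns(UserWarning, match="undefined"):
        dec = decompose(1e-9, 5e-10)
    assert np.isnan(dec.proportion_mediated)


def test_decompose_inconsistent_mediation_is_signed_not_truncated():
    with pytest.warns(UserWarning, match="inconsistent"):
        dec = decompose(0.10, 0.15)
    assert dec.proportion_mediated == pytest.approx(-50.0)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.floats(-5, 5), st.floats(-5, 5), st.floats(0.01, 100))
def test_decomposition_identity_and_scale_invariance(te, de, scale):
    if abs(te) < 1e-3:
        te += 1e-2
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dec = decompose(te, de)
        scaled = decompose(scale * te, scale * de)
    assert dec.total_effect == pytest.approx(
        dec.direct_effect + dec.indirect_effect, abs=1e-12)
    # proportion mediated is invariant to rescaling the outcome units
    assert scaled.proportion_mediated == pytest.approx(
        dec.proportion_mediated, rel=1e-9, abs=1e-9)


def test_degenerate_ladder_equals_direct_fit(studylike_cohort):
    spec = ModelSpec("mental_health", ("cses_t4",))
    [(label, _, fit)] = run_model_ladder(studylike_cohort, [("m1", spec)])
    direct = fit_ols(studylike_cohort, spec)
    assert np.allclose(fit.coefficients, direct.coefficients)


def test_ladder_requires_nested_terms(studylike_cohort):
    ladder = [
        ("m1", ModelSpec("mental_health", ("cses_t4",), ("age",))),
        ("m2", ModelSpec("mental_health", ("cses_t4",))),
    ]
    with pytest.raises(ValueError, match="superset"):
        run_model_ladder(studylike_cohort, ladder)


def test_confounding_inflates_the_unadjusted_estimate():
    """With family-background confounders opening a back door into the
    exposure, the unadjusted exposure estimate exceeds the adjusted one."""
    p = SimulationParams(n=20_000, seed=13,
                         cses_confounder_log_or=(2.0, 2.0, 0, 0),
                         beta_confounders=(1.5, 1.5, 0, 0),
                         confounder_prevalences=(0.3, 0.3, 0.735, 0.979))
    c = generate_cohort(p)
    ladder = [
        ("m1", ModelSpec("mental_health", ("cses_true",))),
        ("m2", ModelSpec("mental_health", ("cses_true",),
                         ("mother_psych_history", "father_psych_history"))),
    ]
    fits = run_model_ladder(c, ladder)
    b1 = fits[0][2].coef("cses_true")
    b2 = fits[1][2].coef("cses_true")
    assert abs(b1) > abs(b2)


def test_null_mediation_has_pm_ci_spanning_zero():
    p = SimulationParams(n=6000, seed=17, beta_psych=0.0, beta_phys=0.0,
                         gender_interaction_terms=(0.05, 0, 0))
    c = generate_cohort(p)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dec = mediation_table(c, "cses_true", "mental_health",
                              confounders=ADJUST, B=300, seed=2)
    iv = dec.ci["indirect_effect"]
    assert iv.lo <= 0.0 <= iv.hi
    assert abs(dec.indirect_effect) < 0.02


def test_mediation_recovers_enumerated_effects(recovery_cohort,
                                               recovery_params):
    """The decomposition on the latent (unclipped) outcome recovers the
    analytic effects implied by the generating process, computed by
    category enumeration."""
    from tests.conftest import implied_effects
    te_true, de_true, ie_true = implied_effects(recovery_params)
    dec = point_decomposition(recovery_cohort, "cses_true",
                              "mental_health_latent", confounders=ADJUST)
    se = fit_ols(recovery_cohort,
                 ModelSpec("mental_health_latent", ("cses_true",), ADJUST),
                 robust=True).se("cses_true")
    assert dec.total_effect == pytest.approx(te_true, abs=3 * se)
    assert dec.direct_effect == pytest.approx(de_true, abs=3 * se)
    assert dec.indirect_effect == pytest.approx(ie_true, abs=3 * se)


def test_cross_sectional_exposure_inflates_effects(studylike_cohort):
    """The headline recall-bias pattern: the late, outcome-contaminated
    report yields larger total and direct effects and a smaller proportion
    mediated than the early report."""
    decs = {}
    for wave in ("cses_t4", "cses_t6"):
        decs[wave] = point_decomposition(studylike_cohort, wave,
                                         "mental_health", confounders=ADJUST)
    assert decs["cses_t6"].total_effect > decs["cses_t4"].total_effect
    assert decs["cses_t6"].direct_effect > decs["cses_t4"].direct_effect
    assert decs["cses_t6"].proportion_mediated < decs["cses_t4"].proportion_mediated


def test_mediation_table_identity_holds_on_bootstrap_output(studylike_cohort):
    dec = mediation_table(studylike_cohort, "cses_t4", "mental_health",
                          confounders=ADJUST, B=150, seed=3)
    assert dec.indirect_effect == pytest.approx(
        dec.total_effect - dec.direct_effect, abs=1e-12)
    for name in ("total_effect", "direct_effect", "indirect_effect"):
        iv = dec.ci[name]
        assert iv.lo <= getattr(dec, name) <= iv.hi


def test_mediation_table_warns_on_tiny_bootstrap(studylike_cohort):
    with pytest.warns(UserWarning, match="fewer than 100"):
        mediation_table(studylike_cohort.head(300), "cses_t4",
                        "mental_health", B=60, seed=0)
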