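"""The synthetic data-generating process and its recall-contamination model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from recallmed import (ModelSpec, SimulationParams, apply_recall_model,
                       calibrate_misclassification, dependency_edges, fit_ols,
                       fit_poisson_rr, generate_cohort, induce_missingness,
                       read_cohort, weighted_kappa, write_cohort)


def test_generation_is_bit_reproducible():
    p = SimulationParams(n=800, seed=42)
    a, b = generate_cohort(p), generate_cohort(p)
    pd.testing.assert_frame_equal(a, b)


def test_null_process_has_no_effects_and_exact_recall():
    p = SimulationParams.null(n=6000, seed=3)
    c = generate_cohort(p)
    assert (c.cses_t4 == c.cses_true).all()
    assert (c.cses_t6 == c.cses_true).all()
    for exposure in ("cses_true", "cses_t4", "cses_t6"):
        fit = fit_ols(c, ModelSpec("mental_health", (exposure,)))
        assert abs(fit.coef(exposure)) < 4 * fit.se(exposure)


def test_abuse_risk_structure_and_coupling(recovery_cohort, recovery_params):
    c, p = recovery_cohort, recovery_params
    # marginal prevalences near the targets implied by the DGP
    probs = np.asarray(p.cses_category_probs)
    for col, base, log_rr in (("psych_abuse", 0.033, p.log_rr_psych),
                              ("phys_abuse", 0.028, p.log_rr_phys)):
        target = (probs * base * np.exp(log_rr * np.arange(4))).sum()
        assert c[col].mean() == pytest.approx(target, abs=0.012)
    # strong positive co-occurrence
    both = ((c.psych_abuse == 1) & (c.phys_abuse == 1)).mean()
    assert both > 2 * c.psych_abuse.mean() * c.phys_abuse.mean()
    assert (c.abuse_freq == c.psych_abuse + c.phys_abuse).all()


def test_mediator_rr_recovery(recovery_cohort):
    """Modified-Poisson RR of psychological abuse per category covers the
    generating RR of 1.85 at n = 10,000."""
    fit = fit_poisson_rr(recovery_cohort,
                         ModelSpec("psych_abuse", ("cses_true",),
                                   family="poisson_robust"))
    lo, hi = fit.rr_ci("cses_true")
    assert lo < 1.85 < hi


def test_risk_overflow_raises():
    p = SimulationParams(baseline_abuse_risk=(0.5, 0.028),
                         log_rr_psych=np.log(3.0))
    with pytest.raises(ValueError, match="lower baseline"):
        p.validate()


def test_recall_model_null_contamination_is_outcome_independent():
    rng = np.random.default_rng(0)
    n = 10_000
    cses = rng.choice([1, 2, 3, 4], n, p=[0.05, 0.6, 0.3, 0.05])
    z = rng.normal(size=n)
    p = SimulationParams(delta_recall=0.0, p_misclass_t4=0.2)
    _, t6 = apply_recall_model(cses, z, p, seed=1)
    r = np.corrcoef(z, t6 - cses)[0, 1]
    assert abs(r) < 0.03


def test_recall_model_contamination_tracks_outcome():
    rng = np.random.default_rng(0)
    n = 10_000
    cses = rng.choice([1, 2, 3, 4], n, p=[0.05, 0.6, 0.3, 0.05])
    z = rng.normal(size=n)
    p = SimulationParams(delta_recall=0.8, p_misclass_t4=0.2)
    _, t6 = apply_recall_model(cses, z, p, seed=1)
    assert np.corrcoef(z, t6 - cses)[0, 1] > 0.05


def test_t6_error_independent_of_outcome_tertile_when_null():
    """With no differential slope, the distribution of the recall error is
    the same in every outcome tertile (chi-square screen over seeds)."""
    pvals = []
    for seed in range(10):
        c = generate_cohort(SimulationParams(n=5000, seed=seed,
                                             delta_recall=0.0))
        err = (c.cses_t6 - c.cses_true).to_numpy()
        tert = pd.qcut(c.mental_health_latent, 3, labels=False)
        table = pd.crosstab(err, tert)
        pvals.append(stats.chi2_contingency(table)[1])
    assert np.mean(np.array(pvals) < 0.05) <= 0.3


def test_misclassification_calibration_hits_kappa_target():
    params = SimulationParams()
    p = calibrate_misclassification(0.63, params, n=20_000, seed=0)
    trial = params.replace(n=20_000, seed=11, p_misclass_t4=p)
    c = generate_cohort(trial)
    assert weighted_kappa(c.cses_true, c.cses_t4) == pytest.approx(0.63, abs=0.05)


def test_missingness_rates_and_mar_structure():
    c = generate_cohort(SimulationParams(n=10_000, seed=5))
    same = induce_missingness(c, {}, seed=1)
    pd.testing.assert_frame_equal(same, c)
    gone = induce_missingness(c, {"well_being": 1.0}, seed=1)
    assert gone.well_being.isna().all()
    m = induce_missingness(c, {"mental_health": 0.2}, seed=1)
    frac = m.mental_health.isna().mean()
    assert frac == pytest.approx(0.2, abs=0.02)
    by_gender = m.groupby("female").apply(
        lambda g: g.mental_health.isna().mean(), include_groups=False)
    assert abs(by_gender[1] - by_gender[0]) > 0.02  # depends on covariates
    with pytest.raises(ValueError):
        induce_missingness(c, {"mental_health": 1.2}, seed=1)


def test_no_intermediate_confounder_in_dependency_graph():
    """No node caused by the exposure is an ancestor of both a mediator and
    an outcome — the structural requirement of difference-method mediation."""
    import networkx as nx
    edges = dependency_edges()
    g = nx.DiGraph((a, b) for a, b, kind in edges if kind == "causal")
    mediators = {"psych_abuse", "phys_abuse"}
    outcomes = {"mental_health", "general_health", "well_being"}
    for node in nx.descendants(g, "cses_true"):
        desc = nx.descendants(g, node)
        assert not (desc & mediators and desc & outcomes), node


def test_cohort_io_roundtrip(tmp_path):
    p = SimulationParams(n=200, seed=9)
    c = generate_cohort(p)
    path = tmp_path / "cohort.csv"
    write_cohort(c, path, p)
    back, meta = read_cohort(path)
    assert meta["params"]["n"] == 200 and meta["seed"] == 9
    pd.testing.assert_series_equal(back.cses_t6, c.cses_t6)
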