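import numpy as np
import pandas as pd
import pytest

from recallmed import SimulationParams, generate_cohort

ADJUST = ("age", "mother_psych_history", "father_psych_history",
          "passive_smoke", "in_country_age1")


@pytest.fixture(scope="session")
def studylike_cohort() -> pd.DataFrame:
    """Moderate cohort under the default (study-like) generator settings."""
    return generate_cohort(SimulationParams(n=4000, seed=123))


@pytest.fixture(scope="session")
def recovery_params() -> SimulationParams:
    """A clean parameter-recovery configuration: known direct and mediator
    paths, no confounder->exposure arrows and no gender interactions, so the
    decomposition's estimands have closed forms by category enumeration."""
    return SimulationParams(
        n=10_000, seed=7,
        cses_confounder_log_or=(0, 0, 0, 0),
        gender_interaction_terms=(0, 0, 0),
        log_rr_psych=float(np.log(1.85)), log_rr_phys=float(np.log(1.60)),
        beta_direct=0.15, beta_psych=0.4, beta_phys=0.3,
    )


@pytest.fixture(scope="session")
def recovery_cohort(recovery_params) -> pd.DataFrame:
    return generate_cohort(recovery_params)


def implied_effects(params: SimulationParams) -> tuple[float, float, float]:
    """Analytic (TE, DE, IE) implied by the generating process, by
    enumeration over the four exposure categories.

    Valid when confounders and gender do not load on the exposure: the
    adjusted total effect is then the probability-weighted least-squares
    slope of E[Y | category] on the category score, and the direct effect is
    the structural exposure coefficient.
    """
    probs = np.asarray(params.cses_category_probs)
    cats = np.arange(1, 5, dtype=float)
    p_psych = np.minimum(
        params.baseline_abuse_risk[0] * np.exp(params.log_rr_psych * (cats - 1)), 1)
    p_phys = np.minimum(
        params.baseline_abuse_risk[1] * np.exp(params.log_rr_phys * (cats - 1)), 1)
    ey = (params.beta_direct * (cats - 1)
          + params.beta_psych * p_psych + params.beta_phys * p_phys)
    cbar = (probs * cats).sum()
    te = (probs * (cats - cbar) * ey).sum() / (probs * (cats - cbar) ** 2).sum()
    de = params.beta_direct
    return float(te), de, float(te - de)
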