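import numpy as np
import pandas as pd
import pytest

from tmesig import (CohortSpec, FeatureMatrix, SurvivalData,
                    planted_scores, simulate_cell_fractions,
                    simulate_survival)

PLANTED_RESISTANCE = {"proliferating_tumor": 1.0, "granulocyte": 1.0,
                      "vessel": 1.0}


def make_cohort(n=200, seed=1, planted=None, **kw):
    """Fraction matrix + PH survival with planted resistance cell types."""
    spec = CohortSpec(n_patients=n, seed=seed,
                      planted_resistance=planted or PLANTED_RESISTANCE, **kw)
    fractions = simulate_cell_fractions(spec)["tumor"]
    surv = simulate_survival(planted_scores(fractions, spec), spec)
    return fractions, surv, spec


@pytest.fixture(scope="session")
def cohort():
    return make_cohort(n=200, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_survival(n, rng, censor_frac=0.3):
    """Generic exponential survival with independent censoring."""
    t_event = rng.exponential(10.0, n)
    t_cens = rng.exponential(10.0 / censor_frac * (1 - censor_frac), n) \
        if censor_frac > 0 else np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return SurvivalData(time, event, np.array([f"P{i}" for i in range(n)]))
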