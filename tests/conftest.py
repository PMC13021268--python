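import warnings

import pytest

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

import fourps as fp
from fourps.mcmc import SamplerSettings


@pytest.fixture(scope="session")
def instrument():
    return fp.build_default_instrument()


@pytest.fixture(scope="session")
def default_map():
    return fp.default_scoring_map()


@pytest.fixture(scope="session")
def light_sampler():
    """Reduced sampler settings to keep replicate studies fast in CI.

    Diagnostic thresholds for 'usable' may not be met at this size; the
    posterior summaries are accurate enough for the statistical checks.
    """
    return SamplerSettings(chains=8, draws=1200, warmup=500, seed=0)


@pytest.fixture(scope="session")
def effect_cohort():
    """Two-arm clustered cohort with a known positive concordance effect."""
    config = fp.SimulationConfig(seed=11, concordance_effect=0.6)
    cohort, truth = fp.simulate_trial(config)
    return cohort, truth


@pytest.fixture(scope="session")
def effect_scored(effect_cohort):
    cohort, _ = effect_cohort
    return fp.score_cohort(cohort)


@pytest.fixture(scope="session")
def small_cohort():
    config = fp.SimulationConfig(n_respondents=60, n_sites=3, seed=5)
    cohort, _ = fp.simulate_trial(config)
    return cohort
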