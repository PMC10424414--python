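import numpy as np
import pytest

from fmtforge import ga, predictor, synth
from fmtforge.predictor import PredictionTask


@pytest.fixture(scope="session")
def cohort400():
    """Reference synthetic cohort: 100 donors x 4 recipients, strong donor
    effect (delta=0.7, rho=0.1), single 7-day timepoint."""
    cfg = synth.SynthConfig(n_donors=100, recipients_per_donor=4, seed=7)
    return synth.generate_cohort(cfg)


@pytest.fixture(scope="session")
def shannon_cnn(cohort400):
    """Taxonomy-image CNN trained on the reference cohort for the Shannon task."""
    return predictor.fit(PredictionTask("shannon"), cohort400, "imic_cnn", seed=0)


@pytest.fixture(scope="session")
def donor_pool(cohort400):
    """Donor pool expanded to 2083 profiles from the cohort's 100 donors."""
    return ga.expand_pool(cohort400.donors, 2083, seed=1)


@pytest.fixture(scope="session")
def ga_runs(shannon_cnn, donor_pool):
    """Five 60-generation Shannon-maximization GA runs (gamma=0)."""
    runs = []
    for seed in range(5):
        cfg = ga.GAConfig(seed=seed, gamma=0.0, max_generations=60)
        runs.append(ga.run(cfg, shannon_cnn, donor_pool))
    return runs


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
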