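import logging

import numpy as np
import pytest

from exoscreen.preprocess import filter_features, harmonize_strata, normalize_cpm
from exoscreen.simulate import simulate_cohort

logging.getLogger("exoscreen").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cohort():
    """Compact planted cohort shared across tests: 40 cases / 110 controls,
    400 features, 3 planted biomarkers at the default effect sizes."""
    return simulate_cohort(n_case=40, n_control=110, n_features=400,
                           n_planted=3, seed=7)


@pytest.fixture(scope="session")
def small_processed(small_cohort):
    counts, meta, feats, truth = small_cohort
    filtered = filter_features(counts)
    feats_f = feats.aligned_to(filtered.feature_ids)
    norm = harmonize_strata(normalize_cpm(filtered), feats_f)
    return filtered, norm, meta, feats_f, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
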