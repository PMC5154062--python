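import numpy as np
import pytest

from ifnstab.synthetic import SyntheticCohortConfig, generate_cohort
from ifnstab.score import compute_ifn_score


@pytest.fixture(scope="session")
def null_cohort():
    """Full-size null cohort: no treatment effect on expression."""
    cfg = SyntheticCohortConfig(seed=123)
    expr, cohort, truth = generate_cohort(cfg)
    return expr, cohort, truth


@pytest.fixture(scope="session")
def null_scores(null_cohort):
    expr, _, _ = null_cohort
    return compute_ifn_score(expr)


@pytest.fixture()
def rng():
    return np.random.default_rng(20160912)


from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")
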