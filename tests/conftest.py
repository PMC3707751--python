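import numpy as np
import pytest

from coxsig import GenePanel, SimConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Default-condition synthetic cohort (225 patients, 32 genes)."""
    return generate_cohort(SimConfig(seed=11))


@pytest.fixture(scope="session")
def big_cohort():
    """Large cohort for parameter-recovery checks."""
    return generate_cohort(SimConfig(seed=12, n_patients=2000))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_plain_config(seed=0, n=225, betas=None, **kw):
    """Uncorrelated-gene, no-clinical-hazard configuration: each gene is
    an independent N(mean, 1.8^2) draw and only ``betas`` carry hazard.
    The baseline hazard is raised to keep the ~30% event fraction the
    default configuration reaches partly through its clinical effects."""
    kw.setdefault("baseline_hazard_os", 0.0032)
    kw.setdefault("baseline_hazard_dfs", 0.0037)
    return SimConfig(
        seed=seed, n_patients=n, loadings={}, marginal_sd=1.8,
        er_factor_weight=0.0, true_beta_os=betas or {},
        true_beta_dfs=betas or {}, lrba_residual_beta=0.0,
        use_clinical_hazard=False, **kw)


@pytest.fixture
def plain_config_factory():
    return make_plain_config


def random_survival(rng, n, censor_frac=0.3):
    """Small random right-censored dataset for property sweeps."""
    times = np.round(rng.exponential(10, n), 1)  # rounding creates ties
    events = (rng.random(n) > censor_frac).astype(float)
    if events.sum() == 0:
        events[rng.integers(n)] = 1.0
    return times, events
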