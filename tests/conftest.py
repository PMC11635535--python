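import math

import pytest

from ckdplatform import DomainConfig, PlatformConfig, TruthParams, simulate_cohort


@pytest.fixture(scope="session")
def platform():
    return PlatformConfig()


@pytest.fixture(scope="session")
def domain():
    return DomainConfig()


@pytest.fixture(scope="session")
def fast_domain():
    """Small, quickly accruing domain for simulation-heavy tests."""
    return DomainConfig(max_per_arm=150, accrual_rate=50.0)


@pytest.fixture(scope="session")
def null_truth():
    return TruthParams()


@pytest.fixture(scope="session")
def effect_truth():
    """Worked-example-like effective treatment: slope +1.3, UACR -31.2%."""
    return TruthParams(chronic_slope_effect=1.3, uacr_log_effect=math.log(0.688))


@pytest.fixture(scope="session")
def noise_free_truth():
    return TruthParams(
        chronic_slope_effect=1.3,
        residual_sd=0.0,
        uacr_log_residual_sd=0.0,
        slope_sd_between=1.0,
        placebo_slope_mean=-3.0,
        dropout_rate=0.0,
    )


@pytest.fixture(scope="session")
def small_cohort(fast_domain, platform, effect_truth):
    """One balanced, dropout-free cohort shared by read-only tests."""
    truth = TruthParams(
        chronic_slope_effect=1.3,
        uacr_log_effect=math.log(0.688),
        dropout_rate=0.0,
    )
    return simulate_cohort(fast_domain, platform, truth, 4242, block_size=2)
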