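import numpy as np
import pytest

from calyxatp import (
    BaseParams,
    FailureRateSeries,
    TrainConsumption,
    failure_rate_from_atp,
    printed_base_params,
    relative_atp_closed_form,
)


@pytest.fixture(scope="session")
def base() -> BaseParams:
    """Fitted shared parameters for the mature OxPhos-blocked condition."""
    return printed_base_params()


@pytest.fixture(scope="session")
def train1_tc(base) -> TrainConsumption:
    return TrainConsumption.constant(base.gamma_1)


def noise_free_train1_series(base: BaseParams, duration: float = 150.0,
                             bin_dt: float = 1.0) -> FailureRateSeries:
    """Exact model failure curve on bin centers (the fitting oracle)."""
    t = np.arange(bin_dt / 2.0, duration, bin_dt)
    atp = relative_atp_closed_form(t, base.gamma_b, base.gamma_1)
    return FailureRateSeries(
        train_index=1, times=t,
        failure_pct=failure_rate_from_atp(atp, base.K_rel, base.h))


@pytest.fixture(scope="session")
def train1_series(base) -> FailureRateSeries:
    return noise_free_train1_series(base)
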