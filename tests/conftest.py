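import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fermflux as ff

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    # the shared fixtures are stateless, so reuse across examples is safe
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("suite")

# Reported whole-run cofactor table (mol per mol glucose): columns for the
# CO2-limited (1% sparge) and CO2-replete (20% sparge) batch conditions and
# their difference, in SUMMARY_FIELDS order.
TABLE_LOW_CO2 = {
    "accoa": 0.79,
    "fd_pfor_only": 0.62,
    "fd_total": 1.09,
    "nadh": -1.99,
    "nadph": -0.23,
    "total_redox": -1.13,
    "atp_ak_only": 0.56,
    "atp_eq": 2.16,
}
TABLE_HIGH_CO2 = {
    "accoa": 0.73,
    "fd_pfor_only": 0.20,
    "fd_total": 0.84,
    "nadh": -2.25,
    "nadph": -0.05,
    "total_redox": -1.45,
    "atp_ak_only": 0.68,
    "atp_eq": 2.34,
}
TABLE_DIFFERENCE = {
    "accoa": 0.05,
    "fd_pfor_only": 0.42,
    "fd_total": 0.26,
    "nadh": 0.25,
    "nadph": -0.18,
    "total_redox": 0.33,
    "atp_ak_only": -0.13,
    "atp_eq": -0.18,
}


@pytest.fixture
def model():
    return ff.build_default_model()


@pytest.fixture
def low_profile():
    """Yield profile of the CO2-limited (1% sparge) batch condition."""
    return ff.YieldProfile(
        yields=dict(ff.BATCH_YIELDS_LOW_CO2),
        glucose_consumed=1.0,
        meta=ff.ConditionMeta(label="1% CO2", co2_fraction=0.01, gas_flow_l_per_h=1.0),
    )


@pytest.fixture
def high_profile():
    """Yield profile of the CO2-replete (20% sparge) batch condition."""
    return ff.YieldProfile(
        yields=dict(ff.BATCH_YIELDS_HIGH_CO2),
        glucose_consumed=1.0,
        meta=ff.ConditionMeta(label="20% CO2", co2_fraction=0.20, gas_flow_l_per_h=1.0),
    )


def random_feasible_fluxes(rng: np.random.Generator) -> ff.FluxVector:
    """A random flux vector satisfying feasibility and acetyl-CoA closure."""
    while True:
        succ, lac, ace, eth = rng.uniform(0.0, 1.0, size=4)
        if 3.0 * (succ + lac + ace + eth) <= 6.0:
            break
    pfl = rng.uniform(0.0, ace + eth)
    return ff.FluxVector(
        succinate=succ,
        lactate=lac,
        acetate=ace,
        ethanol=eth,
        pfl=pfl,
        pfor=ace + eth - pfl,
    )
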