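import numpy as np
import pytest

from mpuncert import BalanceSpec, DryWeightRecord, MCSettings, PortionMass, RandomEffects, SampleRecord, SystematicEffects


@pytest.fixture
def balance():
    """A well-behaved analytical balance: E_M = 0.01 g, s_r = 0.005 g."""
    return BalanceSpec(max_admissible_error=0.01, repeatability_sd=0.005, repeatability_df=9)


@pytest.fixture
def random_effects_t():
    """Pooled random-effects variance for the combined (T) parameter."""
    return RandomEffects(var_lambda_r=5.98)


@pytest.fixture
def systematic_effects_t():
    """Combined-parameter recovery statistics: n_mean = 3.97 of 5 added, Var(n) = 0.0372, M = 36."""
    return SystematicEffects(
        mean_recovered=3.97,
        var_recovered=0.0372,
        var_mean_recovered=0.0372 / 36,
        correction_factor=(5 - 3.97) / 3.97,
        added_per_unit=5,
    )


@pytest.fixture
def sample_t():
    """100 g wet portion, dry fraction 0.5, 10 particles observed."""
    return SampleRecord(
        sample_id="S01",
        campaign="RA1",
        parameter="T",
        count=10,
        portion=PortionMass(100.0),
        dry_record=DryWeightRecord(m_petri=20.0, m_initial_gross=120.0, m_final_gross=70.0),
    )


@pytest.fixture
def settings():
    return MCSettings(n_draws=49_999, seed=1)
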