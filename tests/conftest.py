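import pytest

from wetlandilp import (
    GeneratorConfig,
    IntervalLinearProgram,
    calibrate_case_study_fixture,
    generate_scenario,
)


@pytest.fixture(scope="session")
def toy_max_ilp():
    """max [2,3]·x  s.t.  x <= [4,5], x >= 0 — solvable by hand: f=[8,15]."""
    return IntervalLinearProgram(
        sense="maximize", c=[(2, 3)], A=[[(1, 1)]], b=[(4, 5)], row_senses=["le"]
    )


@pytest.fixture(scope="session")
def toy_min_ilp():
    """min [2,3]·x  s.t.  x >= [4,5], x >= 0 — mirror case: f=[8,15]."""
    return IntervalLinearProgram(
        sense="minimize", c=[(2, 3)], A=[[(1, 1)]], b=[(4, 5)], row_senses=["ge"]
    )


@pytest.fixture(scope="session")
def calibrated_scenario():
    return calibrate_case_study_fixture()


@pytest.fixture(scope="session")
def small_scenario():
    """Six-measure random feasible scenario with 10% interval half-width."""
    return generate_scenario(GeneratorConfig(n_measures=6, interval_half_width=0.1, seed=11))
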