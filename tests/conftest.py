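import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from trpkin import synthetic as syn
from trpkin.fitting import global_fit, problem_from_traces as build_problem

settings.register_profile(
    "ci", deadline=None, max_examples=25, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def radical_scenario():
    """Six-power radical scenario at the bench conditions, with truth."""
    return syn.gen_radical_traces(syn.RadicalTraceSpec(seed=7))


@pytest.fixture(scope="session")
def radical_problem(radical_scenario):
    traces, truth = radical_scenario
    return build_problem(traces, truth)


@pytest.fixture(scope="session")
def radical_fit(radical_problem):
    return global_fit(radical_problem)


@pytest.fixture(scope="session")
def true_free(radical_scenario):
    _, truth = radical_scenario
    return {
        k: truth["rates"][k] for k in ("k_ET", "k_deprot", "k_back", "k_decay_prime")
    }
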