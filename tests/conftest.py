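import numpy as np
import pytest

from glygolgi.golgi_ssa import EnzymeParameterSet


@pytest.fixture(scope="session")
def cho_params() -> EnzymeParameterSet:
    from glygolgi.synthetic_data import cho_baseline_parameters

    return cho_baseline_parameters()


@pytest.fixture(scope="session")
def recovery_params() -> EnzymeParameterSet:
    """Baseline with every enzyme rate-limiting (all activities identifiable)."""
    from glygolgi.synthetic_data import abc_recovery_parameters

    return abc_recovery_parameters()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def total_variation(p: dict, q: dict) -> float:
    names = set(p) | set(q)
    return 0.5 * sum(abs(p.get(n, 0.0) - q.get(n, 0.0)) for n in names)
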