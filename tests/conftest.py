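import numpy as np
import pytest

from redoxcell import kinetic_model as km


@pytest.fixture(scope="session")
def default_net():
    return km.default_network()


@pytest.fixture(scope="session")
def resting_state(default_net):
    """Drug-free steady state of the default model."""
    return km.equilibrate(default_net)


@pytest.fixture(scope="session")
def fast_settings():
    """Adaptive-step settings for throughput-sensitive tests."""
    return km.SolverSettings(t_end=7200.0, max_step=None, atol=1e-12, rtol=1e-6)


@pytest.fixture(scope="session")
def dosed_state(default_net, resting_state):
    """Resting state plus the default 10 uM extracellular drug dose."""
    y0 = resting_state.copy()
    y0[default_net.species_index("blap_ext")] = 1e-5
    return y0


def toy_network(reactions, species, parameters, **kwargs):
    """Small helper to declare throwaway networks in tests."""
    config = {
        "compartments": kwargs.get(
            "compartments", {"extracellular": 1e-9, "cytosol": 1e-12}
        ),
        "membrane_area_factor": kwargs.get("membrane_area_factor", 1.0),
        "parameters": parameters,
        "species": species,
        "reactions": reactions,
        "solver": kwargs.get("solver", {"t_end": 100.0, "max_step": None}),
        "moieties": kwargs.get("moieties", {}),
    }
    return km.build_network(config)


# derandomize hypothesis so property tests are reproducible everywhere
try:
    from hypothesis import settings as _hyp_settings

    _hyp_settings.register_profile("deterministic", derandomize=True)
    _hyp_settings.load_profile("deterministic")
except ImportError:  # pragma: no cover
    pass
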