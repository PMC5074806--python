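import numpy as np
import pytest

from ubcphase import granular_network as gn
from ubcphase import synthetic_data as sd
from ubcphase.receptor_kinetics import default_rate_constants
from ubcphase.stimulus_protocols import Protocol


@pytest.fixture(scope="session")
def rates():
    """Reference four-state rate constants with calibrated recovery rate."""
    return default_rate_constants()


@pytest.fixture(scope="session")
def ubc_pool():
    """Surrogate recorded-UBC tuning-curve pool."""
    curves, _ = sd.make_ubc_population(seed=101)
    return curves


@pytest.fixture(scope="session")
def network_runs(ubc_pool):
    """Full-size granular-layer runs (with and without UBCs, matched seed).

    Session-scoped: these are the long simulations behind the network-level
    and learning-level checks.
    """
    cfg = gn.NetworkConfig()
    prot = Protocol(f_mod=1.0)
    no_ubc = gn.run_network(cfg, prot, seed=11, with_ubc=False)
    with_ubc = gn.run_network(cfg, prot, seed=11, with_ubc=True,
                              ubc_pool=ubc_pool)
    return {"config": cfg, "protocol": prot, "no_ubc": no_ubc,
            "with_ubc": with_ubc}


@pytest.fixture(scope="session")
def epsc_dataset():
    """Small surrogate EPSC dataset with hidden ground truth."""
    traces, truths = sd.make_epsc_dataset(6, seed=3)
    return traces, truths
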