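"""Shared fixtures.

Expensive Brownian-dynamics runs are session-scoped so that several
tests can share one trajectory.  The scaled study geometry used
throughout keeps the molecular density of the reference condition
(500 molecules on a 300-nm disk) while reducing the molecule count to
100 (disk radius 134 nm = 300·sqrt(100/500)).
"""

import numpy as np
import pytest

from syxsim.bd_engine import run
from syxsim.model_core import SimulationConfig

#: density-preserving scaled geometry
SCALED_N = 100
SCALED_RADIUS = 134.0


def scaled_config(e_a: float, n_steps: int, sample_stride: int,
                  rng_seed: int, **kw) -> SimulationConfig:
    return SimulationConfig(
        n_molecules=SCALED_N, domain_radius=SCALED_RADIUS, e_a=e_a,
        n_steps=n_steps, sample_stride=sample_stride, rng_seed=rng_seed, **kw)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def equilibrium_runs():
    """20-ms scaled runs at the outside (4.0) and AZ (4.4) energies.

    Sampled every 25 μs; used for coverage and as equilibrated starting
    configurations for the seeded assays.
    """
    out = {}
    for ea in (4.0, 4.4):
        cfg = scaled_config(ea, n_steps=4_000_000, sample_stride=5_000,
                            rng_seed=int(ea * 10))
        out[ea] = run(cfg)
    return out


@pytest.fixture(scope="session")
def kinetics_run():
    """Scaled run at E_a = 4.0 sampled every 10 μs for exit kinetics."""
    cfg = scaled_config(4.0, n_steps=4_000_000, sample_stride=2_000,
                        rng_seed=77)
    return run(cfg)
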