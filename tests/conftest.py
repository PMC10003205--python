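import numpy as np
import pytest

import cgbilayer as cg
from cgbilayer.engine import EngineConfig, maxwell_velocities
from cgbilayer.system import System


@pytest.fixture(scope="session")
def ff():
    return cg.default_forcefield()


def make_two_beads(r, bead_type="C1", box=60.0):
    """Two uncharged beads a distance r apart in a cubic box."""
    return System(
        coords=np.array([[10.0, 10.0, 10.0], [10.0 + r, 10.0, 10.0]]),
        velocities=np.zeros((2, 3)),
        types=np.array([bead_type, bead_type], dtype=object),
        charges=np.zeros(2),
        masses=np.full(2, 72.0),
        mol_index=np.array([0, 1]),
        species=[bead_type, bead_type],
        box=np.array([box] * 3),
    )


def make_lj_gas(n=64, box=40.0, seed=5, temperature=310.0):
    """Jittered lattice of apolar beads with Maxwell-Boltzmann velocities."""
    m = int(np.ceil(n ** (1 / 3)))
    pts = [
        ((i + 0.5) * box / m, (j + 0.5) * box / m, (k + 0.5) * box / m)
        for i in range(m)
        for j in range(m)
        for k in range(m)
    ][:n]
    rng = np.random.default_rng(seed)
    coords = np.array(pts) + rng.uniform(-0.5, 0.5, (n, 3))
    s = System(
        coords=coords,
        velocities=np.zeros((n, 3)),
        types=np.array(["C1"] * n, dtype=object),
        charges=np.zeros(n),
        masses=np.full(n, 72.0),
        mol_index=np.arange(n),
        species=["X"] * n,
        box=np.array([box] * 3),
    )
    maxwell_velocities(s, temperature, seed)
    return s


NO_COULOMB = dict(coulomb="none")
NVE = dict(thermostat="none", barostat="none", coulomb="none")


def nve_config(**kw):
    return EngineConfig(**{**NVE, **kw})
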