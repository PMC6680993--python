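import numpy as np
import pytest

from nucleomc.model_core import (
    ForceField,
    McSchedule,
    SystemConfig,
    build_system,
)


@pytest.fixture(scope="session")
def small_mixed_state():
    """A small but fully featured system: short charged chain, two dimers,
    two crowders, counterions — exercises every energy term."""
    cfg = SystemConfig(
        n_dna=8, n_hns=2, n_crow=2, z_crow=-3, r_cell=40.0, seed=7,
        eps_pp=1.0,
    )
    return cfg, build_system(cfg), ForceField.from_config(cfg)


@pytest.fixture(scope="session")
def tiny_chain_state():
    """10-monomer charged chain with its counterions in a small cell."""
    cfg = SystemConfig(n_dna=10, r_cell=40.0, seed=3)
    return cfg, build_system(cfg), ForceField.from_config(cfg)


def make_schedule(**kw) -> McSchedule:
    base = dict(equil_sweeps=100, prod_sweeps=1000, n_subbatches=10,
                sample_stride=10, seed=0)
    base.update(kw)
    return McSchedule(**base)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
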