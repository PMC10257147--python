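import numpy as np
import pytest

from toccsl_sim import CellGeometry, OligomerSpecies, init_ensemble


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_dimer_ensemble():
    """A small cell fully covered by the default aperture footprint."""
    geom = CellGeometry(L=6.0, density=300.0)
    return init_ensemble(geom, [OligomerSpecies("dimer", 2, 0.0, 1.0)], seed=42)


def make_ensemble(positions, n, m, L=21.0, D=0.5):
    """Hand-built ensemble-like snapshot for detection/density tests."""
    from toccsl_sim.scenario import Snapshot

    positions = np.asarray(positions, dtype=float)
    n = np.asarray(n, dtype=np.int16)
    m = np.asarray(m, dtype=np.int16)
    return Snapshot(
        L=L,
        t=0.0,
        positions=positions,
        n=n,
        m=m,
        D=np.full(len(n), D),
    )
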