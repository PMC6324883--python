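import numpy as np
import pytest

import xlinktrap.docking as dk
import xlinktrap.pipeline as pl
import xlinktrap.simephys as se


@pytest.fixture(scope="session")
def toy_tetramer():
    return pl.make_toy_tetramer(separation=15.0)


@pytest.fixture(scope="session")
def burial_system():
    fixed, mobile = pl.make_burial_toy()
    assembly = dk._assemble(fixed, mobile)
    f, m, frame = dk.split_dimers(assembly, ["A"], ["C"])
    return f, m, frame


@pytest.fixture(scope="session")
def gating():
    return se.GatingModel()


def random_structure(rng, n=50, box=12.0):
    """A blob of carbon atoms for geometric property checks."""
    from xlinktrap.structgeo import Structure
    xyz = rng.uniform(-box / 2, box / 2, size=(n, 3))
    return Structure(np.array(["C"] * n),
                     np.array([f"C{i}" for i in range(n)]),
                     np.arange(1, n + 1), np.array(["UNK"] * n),
                     np.array(["A"] * n), xyz, np.full(n, 1.70))
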