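"""Shared fixtures: small generator specs and frames, reference cells.

The small fibril keeps the default residue rise (~0.29 nm) by shrinking the
D-period together with the chain length, so all bonded-geometry invariants
of the full-size model hold at ~1/10 the atom count.
"""

import warnings

import numpy as np
import pytest

from fibrilmetrics.core import Frame, Trajectory
from fibrilmetrics.pbc import TriclinicCell
from fibrilmetrics.synthetic import FibrilSpec, build_microfibril

warnings.filterwarnings("ignore", category=UserWarning, module="MDAnalysis")


@pytest.fixture(scope="session")
def small_spec():
    return FibrilSpec(dband=6.7, residues_per_chain=102, seed=7)


@pytest.fixture(scope="session")
def small_frame(small_spec):
    return build_microfibril(small_spec)


@pytest.fixture(scope="session")
def default_spec():
    return FibrilSpec(seed=11)


@pytest.fixture(scope="session")
def default_frame(default_spec):
    return build_microfibril(default_spec)


@pytest.fixture
def skewed_cell():
    return TriclinicCell([4.0, 0.0, 0.0], [1.8, 3.6, 0.0], [-1.5, 1.2, 6.0])


@pytest.fixture
def ortho_cell():
    return TriclinicCell([10.0, 0.0, 0.0], [0.0, 10.0, 0.0], [0.0, 0.0, 10.0])


def toy_frame(positions, names=None, elements=None, resids=None, chains=None,
              resnames=None, cell=None):
    """Hand-rolled frame builder for constructed test cases."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if names is None:
        names = ["X"] * n
    if elements is None:
        elements = ["C"] * n
    if resids is None:
        resids = np.arange(1, n + 1)
    if chains is None:
        chains = ["A"] * n
    if resnames is None:
        resnames = ["UNK"] * n
    if cell is None:
        cell = TriclinicCell([10, 0, 0], [0, 10, 0], [0, 0, 10])
    masses = np.array([{"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999}
                       .get(e, 12.0) for e in elements])
    return Frame(
        names=np.array(names, dtype="U6"),
        elements=np.array(elements, dtype="U2"),
        resnames=np.array(resnames, dtype="U6"),
        resids=np.array(resids, dtype=np.int64),
        chains=np.array(chains, dtype="U8"),
        positions=positions,
        masses=masses,
        cell=cell,
    )
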