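"""In-memory containers for structures and trajectories.

A :class:`Frame` is a struct-of-arrays snapshot (names, residues, chains,
positions, masses) plus its triclinic cell; a :class:`Trajectory` is an
ordered list of frames sharing one atom identity list, with times in ns.
Coordinates are Cartesian nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np

from .pbc import TriclinicCell

__all__ = ["AtomRecord", "Frame", "Trajectory", "ELEMENT_MASSES", "element_from_name", "mass_of"]

# monoisotopic-ish average masses, amu
ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "NA": 22.990,
    "CL": 35.45,
    "MG": 24.305,
    "K": 39.098,
    "CA": 40.078,  # the element calcium, not the alpha carbon
}

_FALLBACK_MASS = 12.0


def element_from_name(name: str) -> str:
    """Infer the element from an atom name (PDB-style heuristics).

    Leading digits are stripped; two-letter elements are recognised only when
    the name itself is a known two-letter symbol (CL, NA, ...), otherwise the
    first letter wins (so "CA" in a protein residue is carbon).
    """
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    upper = stripped.upper()
    if upper in ("CL", "NA", "MG") and len(name.strip()) == len(upper):
        return upper
    return upper[0]


def mass_of(element: str) -> float:
    return ELEMENT_MASSES.get(element.upper(), _FALLBACK_MASS)


class AtomRecord(NamedTuple):
    """One atom: identity plus position (nm) and mass (amu)."""

    atom_name: str
    element: str
    residue_name: str
    residue_index: int  # 1-based, per chain
    chain_id: str
    position: np.ndarray
    mass: float


@dataclass
class Frame:
    """A structure snapshot: parallel per-atom arrays plus the cell.

    ``aux`` carries optional per-atom provenance emitted by the synthetic
    generator (lateral site centres, segment indices); analyses must not
    require it.
    """

    names: np.ndarray
    elements: np.ndarray
    resnames: np.ndarray
    resids: np.ndarray
    chains: np.ndarray
    positions: np.ndarray
    masses: np.ndarray
    cell: TriclinicCell
    aux: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.names)
        self.positions = np.asarray(self.positions, dtype=float).reshape(n, 3)
        self.masses = np.asarray(self.masses, dtype=float)
        for arr_name in ("elements", "resnames", "resids", "chains", "masses"):
            if len(getattr(self, arr_name)) != n:
                raise ValueError(f"length mismatch in per-atom array '{arr_name}'")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def atom(self, i: int) -> AtomRecord:
        return AtomRecord(
            str(self.names[i]),
            str(self.elements[i]),
            str(self.resnames[i]),
            int(self.resids[i]),
            str(self.chains[i]),
            self.positions[i],
            float(self.masses[i]),
        )

    def copy(self, positions=None, cell=None) -> "Frame":
        return Frame(
            names=self.names.copy(),
            elements=self.elements.copy(),
            resnames=self.resnames.copy(),
            resids=self.resids.copy(),
            chains=self.chains.copy(),
            positions=self.positions.copy() if positions is None else np.asarray(positions, float),
            masses=self.masses.copy(),
            cell=self.cell if cell is None else cell,
            aux={k: (v.copy() if hasattr(v, "copy") else v) for k, v in self.aux.items()},
        )

    def residue_keys(self) -> np.ndarray:
        """Structured array of (chain, resid) per atom."""
        out = np.empty(self.n_atoms, dtype=[("chain", "U8"), ("resid", "i8")])
        out["chain"] = self.chains
        out["resid"] = self.resids
        return out

    def same_identity(self, other: "Frame") -> bool:
        return (
            self.n_atoms == other.n_atoms
            and bool(np.all(self.names == other.names))
            and bool(np.all(self.chains == other.chains))
            and bool(np.all(self.resids == other.resids))
        )


@dataclass
class Trajectory:
    """Ordered frames with strictly increasing times (ns).

    All frames must share one atom identity list; cells may vary per frame
    (constant-pressure runs breathe).
    """

    frames: list
    times: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if len(self.frames) != len(self.times):
            raise ValueError("one time per frame required")
        if len(self.frames) == 0:
            raise ValueError("trajectory needs at least one frame")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        first = self.frames[0]
        for k, fr in enumerate(self.frames[1:], start=1):
            if fr.n_atoms != first.n_atoms:
                raise ValueError(
                    f"atom-count mismatch at frame {k}: "
                    f"{fr.n_atoms} vs {first.n_atoms}"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return Trajectory(self.frames[i], self.times[i])
        return self.frames[i]

    @classmethod
    def from_frame(cls, frame: Frame, time_ns: float = 0.0) -> "Trajectory":
        return cls([frame], np.array([time_ns]))
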