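"""Geometric hydrogen-bond detection under triclinic periodicity.

A hydrogen bond is purely geometric here: donor-acceptor distance below
``d_max`` (default 0.35 nm) and the angle at the donor between the
donor->acceptor and donor->hydrogen vectors below ``theta_max`` (default
30 degrees), both strict inequalities.  Distances use the minimum-image
convention; the integer lattice shift of the nearest acceptor image
classifies the bond: a nonzero shift between two protein atoms is an
inter-monomer bond (partner is a periodic image, i.e. a neighbouring
monomer of the infinite fibril), a zero shift is intra-chain or
inter-chain-intra-monomer, and bonds involving water are protein-water.

Donor/acceptor assignment is template driven: donors are N/O heavy atoms
with a resolvable hydrogen (by name template, falling back to any hydrogen
of the residue within a small search radius), acceptors are all oxygens
plus template-listed nitrogens.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy import stats

from .core import Frame, Trajectory
from .mechanics import block_average
from .pbc import LatticeShift, TriclinicCell, min_image_disp_batch, wrap_to_cell

__all__ = [
    "HBondCriterion",
    "HBondEvent",
    "DonorAcceptorTable",
    "ResidueHBondProfile",
    "ProfileComparison",
    "assign_donors_acceptors",
    "detect_hbonds",
    "count_intermonomer",
    "residue_probabilities",
    "protein_water_count",
    "compare_probabilities",
    "percent_drop",
    "load_hbond_templates",
]


def load_hbond_templates(path=None) -> dict:
    if path is None:
        src = resources.files("fibrilmetrics.data").joinpath("hbond_templates.json")
        with src.open() as fh:
            return json.load(fh)
    with open(path) as fh:
        return json.load(fh)


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric criterion: d(D, A) < d_max (nm) and angle(D->A, D->H) < theta_max (deg)."""

    d_max: float = 0.35
    theta_max: float = 30.0

    def __post_init__(self):
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        if not 0.0 < self.theta_max < 180.0:
            raise ValueError("theta_max must be in (0, 180)")


@dataclass(frozen=True)
class HBondEvent:
    donor: int
    hydrogen: int
    acceptor: int
    frame_index: int
    shift: LatticeShift
    klass: str  # intra-chain | inter-chain-intra-monomer | inter-monomer | protein-water


@dataclass
class DonorAcceptorTable:
    """Aligned donor/hydrogen index arrays plus acceptor indices.

    A donor heavy atom with two hydrogens (water) appears once per hydrogen.
    ``excluded_donors`` lists nitrogen atoms for which no hydrogen could be
    resolved (reported, excluded from detection).
    """

    donors: np.ndarray
    hydrogens: np.ndarray
    acceptors: np.ndarray
    is_water: np.ndarray  # per-atom flag, full frame length
    excluded_donors: list = field(default_factory=list)


def assign_donors_acceptors(frame: Frame, templates: dict | None = None) -> DonorAcceptorTable:
    """Template-driven donor/acceptor assignment for one frame.

    Donors: N and O heavy atoms with a hydrogen in the same residue, found
    by the name template or (fallback) by proximity within the template's
    search radius.  Acceptors: every oxygen plus per-residue template extras.
    Nitrogens with no resolvable hydrogen are excluded with a warning.
    """
    if templates is None:
        templates = load_hbond_templates()
    hyd_of = templates["hydrogen_of"]
    extra_acc = templates.get("extra_acceptors", {})
    water_resnames = set(templates.get("water_resnames", []))
    search_r = float(templates.get("hydrogen_search_radius_nm", 0.12))

    is_water = np.isin(frame.resnames, sorted(water_resnames))
    donors, hydrogens, acceptors, excluded = [], [], [], []

    keys = frame.residue_keys()
    order = np.argsort(keys, kind="stable")
    keys_sorted = keys[order]
    boundaries = np.nonzero(keys_sorted[1:] != keys_sorted[:-1])[0] + 1
    groups = np.split(order, boundaries)

    for sel in groups:
        names = frame.names[sel]
        elems = frame.elements[sel]
        h_local = sel[elems == "H"]
        resname = str(frame.resnames[sel[0]])
        # first pass: name-template hydrogen assignment (a hydrogen has one
        # covalent parent; template claims win over proximity)
        h_of_heavy: dict = {}
        claimed: set = set()
        for local_i, idx in enumerate(sel):
            if elems[local_i] not in ("N", "O"):
                continue
            found = []
            for hname in hyd_of.get(str(names[local_i]), ()):
                found.extend(int(j) for j in sel[names == hname])
            if found:
                h_of_heavy[int(idx)] = found
                claimed.update(found)
        unclaimed = np.array([j for j in h_local if int(j) not in claimed], dtype=int)
        for local_i, idx in enumerate(sel):
            el = elems[local_i]
            name = str(names[local_i])
            if el == "O":
                acceptors.append(idx)
            elif el == "N" and name in extra_acc.get(resname, ()):
                acceptors.append(idx)
            if el not in ("N", "O"):
                continue
            h_found = h_of_heavy.get(int(idx), [])
            if not h_found and len(unclaimed):
                d = np.linalg.norm(
                    frame.positions[unclaimed] - frame.positions[idx], axis=1
                )
                h_found = [int(j) for j in unclaimed[d < search_r]]
            if h_found:
                for j in h_found:
                    donors.append(idx)
                    hydrogens.append(j)
            elif el == "N" and name not in extra_acc.get(resname, ()):
                excluded.append(int(idx))
    if excluded:
        warnings.warn(
            f"{len(excluded)} nitrogen donor(s) without resolvable hydrogen excluded"
        )
    return DonorAcceptorTable(
        donors=np.array(donors, dtype=int),
        hydrogens=np.array(hydrogens, dtype=int),
        acceptors=np.array(acceptors, dtype=int),
        is_water=is_water,
        excluded_donors=excluded,
    )


def monomer_image_offsets(frame: Frame) -> np.ndarray:
    """Integer lattice offset of each stored atom relative to the unwrapped
    molecule, ``n`` with ``stored = unwrapped + n @ M``.

    A monomer spanning several cells is stored wrapped, so a raw minimum-
    image shift between two of its atoms can be a wrapping artifact: the
    physically meaningful lattice shift between monomer *copies* is
    ``raw_shift + n_partner - n_self``.  Offsets come from generator
    provenance when available, else from the covalent-walk unwrap; for
    systems whose connectivity cannot be decoded (disconnected test
    constructions) all offsets are zero and raw shifts are used as-is.
    """
    if "z_unwrapped" in frame.aux and "site_center" in frame.aux:
        ref = np.column_stack([frame.aux["site_center"], frame.aux["z_unwrapped"]])
        frac = frame.cell.fractional(frame.positions - ref)
        return np.round(frac).astype(int)
    try:
        from .metrics import unwrap_molecule  # deferred: metrics imports hbonds

        unwrapped = unwrap_molecule(frame)
    except ValueError:
        return np.zeros((frame.n_atoms, 3), dtype=int)
    frac = frame.cell.fractional(frame.positions - unwrapped)
    return np.round(frac).astype(int)


# ---------------------------------------------------------------------------
# neighbour-pair engine
# ---------------------------------------------------------------------------

_BRUTE_LIMIT = 400_000


def _canonical_rotation(cell: TriclinicCell):
    """Rotation taking the cell to the lower-triangular (a along x) form."""
    from MDAnalysis.lib import mdamath

    box = mdamath.triclinic_box(*cell.matrix)
    m_canon = mdamath.triclinic_vectors(box.astype(np.float64)).astype(np.float64)
    rot = np.linalg.inv(cell.matrix) @ m_canon
    return rot, box


def neighbor_pairs(pos_a, pos_b, cell: TriclinicCell, cutoff: float):
    """Candidate index pairs (i, j) with min-image distance possibly below
    ``cutoff``; callers re-filter with exact float64 arithmetic.

    Small problems use the exact vectorized minimum-image search; large ones
    a grid search (MDAnalysis ``capped_distance``) in the rotated canonical
    frame with a small cutoff slack to absorb single-precision round-off.
    """
    pos_a = np.atleast_2d(pos_a)
    pos_b = np.atleast_2d(pos_b)
    na, nb = len(pos_a), len(pos_b)
    if na == 0 or nb == 0:
        return np.empty((0, 2), dtype=int)
    if na * nb <= _BRUTE_LIMIT:
        ii, jj = np.meshgrid(np.arange(na), np.arange(nb), indexing="ij")
        ii, jj = ii.ravel(), jj.ravel()
        disp, _ = min_image_disp_batch(pos_a[ii], pos_b[jj], cell)
        keep = np.einsum("ij,ij->i", disp, disp) < cutoff**2
        return np.column_stack([ii[keep], jj[keep]])
    from MDAnalysis.lib.distances import capped_distance

    rot, box = _canonical_rotation(cell)
    canon_cell = TriclinicCell(*(cell.matrix @ rot))
    a = wrap_to_cell(pos_a @ rot, canon_cell).astype(np.float32)
    b = wrap_to_cell(pos_b @ rot, canon_cell).astype(np.float32)
    pairs = capped_distance(
        a, b, max_cutoff=cutoff * 1.02 + 1e-3, box=box.astype(np.float32),
        return_distances=False,
    )
    return np.asarray(pairs, dtype=int).reshape(-1, 2)


def detect_hbonds(frame: Frame, criterion: HBondCriterion | None = None,
                  cell: TriclinicCell | None = None,
                  table: DonorAcceptorTable | None = None,
                  templates: dict | None = None,
                  frame_index: int = 0,
                  image_offsets: np.ndarray | None = None) -> list:
    """All hydrogen-bond events in one frame under the geometric criterion.

    Donor-acceptor pairs within the same residue are excluded (which also
    drops the degenerate donor == acceptor case).  Water-water bonds are out
    of scope and skipped.  The recorded event shift is the monomer-relative
    lattice shift (see :func:`monomer_image_offsets`): nonzero means the
    partner is a periodic image, i.e. a neighbouring monomer.
    """
    if criterion is None:
        criterion = HBondCriterion()
    if cell is None:
        cell = frame.cell
    if table is None:
        table = assign_donors_acceptors(frame, templates)
    if image_offsets is None:
        image_offsets = monomer_image_offsets(frame)
    if len(table.donors) == 0 or len(table.acceptors) == 0:
        return []

    pos = frame.positions
    cand = neighbor_pairs(pos[table.donors], pos[table.acceptors], cell, criterion.d_max)
    if len(cand) == 0:
        return []
    d_idx = table.donors[cand[:, 0]]
    h_idx = table.hydrogens[cand[:, 0]]
    a_idx = table.acceptors[cand[:, 1]]

    # exclude same-residue pairs
    same_res = (frame.chains[d_idx] == frame.chains[a_idx]) & (
        frame.resids[d_idx] == frame.resids[a_idx]
    )
    keep = ~same_res
    d_idx, h_idx, a_idx = d_idx[keep], h_idx[keep], a_idx[keep]
    if len(d_idx) == 0:
        return []

    da, shifts = min_image_disp_batch(pos[d_idx], pos[a_idx], cell)
    dist = np.linalg.norm(da, axis=1)
    keep = dist < criterion.d_max
    d_idx, h_idx, a_idx = d_idx[keep], h_idx[keep], a_idx[keep]
    da, shifts, dist = da[keep], shifts[keep], dist[keep]
    if len(d_idx) == 0:
        return []

    dh, _ = min_image_disp_batch(pos[d_idx], pos[h_idx], cell)
    dh_norm = np.linalg.norm(dh, axis=1)
    cosang = np.einsum("ij,ij->i", da, dh) / np.maximum(dist * dh_norm, 1e-300)
    cos_max = np.cos(np.deg2rad(criterion.theta_max))
    keep = cosang > cos_max  # strict: angle strictly below theta_max
    d_idx, h_idx, a_idx, shifts = d_idx[keep], h_idx[keep], a_idx[keep], shifts[keep]

    # monomer-relative shift: correct the raw shift for the wrap offsets of
    # the two stored atoms
    shifts = shifts + image_offsets[a_idx] - image_offsets[d_idx]

    events = []
    for d, h, a, sh in zip(d_idx, h_idx, a_idx, shifts):
        dw, aw = bool(table.is_water[d]), bool(table.is_water[a])
        if dw and aw:
            continue  # water-water out of scope
        shift = LatticeShift(int(sh[0]), int(sh[1]), int(sh[2]))
        if dw or aw:
            klass = "protein-water"
        elif not shift.is_zero:
            klass = "inter-monomer"
        elif frame.chains[d] == frame.chains[a]:
            klass = "intra-chain"
        else:
            klass = "inter-chain-intra-monomer"
        events.append(HBondEvent(int(d), int(h), int(a), frame_index, shift, klass))
    return events


def _per_frame_events(traj: Trajectory, criterion, templates):
    """Yield (frame_index, frame, events); the donor/acceptor table and the
    wrap-image offsets are derived once (atom identity and image
    registration are constant across a trajectory)."""
    table = assign_donors_acceptors(traj.frames[0], templates)
    offsets = monomer_image_offsets(traj.frames[0])
    for k, fr in enumerate(traj.frames):
        yield k, fr, detect_hbonds(fr, criterion, table=table, frame_index=k,
                                   image_offsets=offsets)


def count_intermonomer(traj: Trajectory, criterion: HBondCriterion | None = None,
                       templates: dict | None = None, n_blocks: int | None = None):
    """Mean +- block-averaged SE of the per-frame inter-monomer H-bond count
    (per unit cell, i.e. per D-band unit of the infinite fibril)."""
    if traj.n_frames < 2:
        raise ValueError("standard error needs at least 2 frames")
    counts = []
    for _, _, events in _per_frame_events(traj, criterion, templates):
        counts.append(sum(1 for e in events if e.klass == "inter-monomer"))
    if n_blocks is None:
        n_blocks = min(10, len(counts))
    return block_average(np.array(counts, dtype=float), n_blocks)


@dataclass
class ResidueHBondProfile:
    """Per-residue probability of engaging in >=1 inter-monomer hydrogen bond
    in a frame.  A residue engages if any of its atoms is the donor, the
    donor's hydrogen, or the acceptor of an inter-monomer event."""

    probabilities: dict  # (chain, resid) -> p in [0, 1]
    n_frames: int = 0

    def __post_init__(self):
        for key, p in self.probabilities.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1] for residue {key}")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("chain\tresid\tprobability\n")
            for (chain, resid), p in sorted(self.probabilities.items()):
                fh.write(f"{chain}\t{resid}\t{p:.6f}\n")

    @classmethod
    def from_tsv(cls, path) -> "ResidueHBondProfile":
        probs = {}
        with open(path) as fh:
            next(fh)
            for line in fh:
                chain, resid, p = line.rstrip("\n").split("\t")
                probs[(chain, int(resid))] = float(p)
        return cls(probs)


def residue_probabilities(traj: Trajectory, criterion: HBondCriterion | None = None,
                          templates: dict | None = None) -> ResidueHBondProfile:
    """Fraction of frames in which each protein residue takes part in at
    least one inter-monomer hydrogen bond.  Residues never involved get
    p = 0 (the profile covers every protein residue)."""
    if templates is None:
        templates = load_hbond_templates()
    water_resnames = set(templates.get("water_resnames", []))
    first = traj.frames[0]
    protein = ~np.isin(first.resnames, sorted(water_resnames))
    all_keys = {
        (str(c), int(r))
        for c, r in zip(first.chains[protein], first.resids[protein])
    }
    frame_hits = {key: 0 for key in all_keys}
    for _, fr, events in _per_frame_events(traj, criterion, templates):
        touched = set()
        for e in events:
            if e.klass != "inter-monomer":
                continue
            for atom in (e.donor, e.hydrogen, e.acceptor):
                touched.add((str(fr.chains[atom]), int(fr.resids[atom])))
        for key in touched:
            frame_hits[key] += 1
    n = traj.n_frames
    return ResidueHBondProfile(
        {key: hits / n for key, hits in frame_hits.items()}, n_frames=n
    )


def protein_water_count(traj: Trajectory, criterion: HBondCriterion | None = None,
                        templates: dict | None = None, n_blocks: int | None = None):
    """Mean +- block SE of per-frame protein-water hydrogen bonds (either
    donation direction).  Returns (0, 0) with a warning when no water is
    present."""
    if templates is None:
        templates = load_hbond_templates()
    water_resnames = set(templates.get("water_resnames", []))
    if not np.any(np.isin(traj.frames[0].resnames, sorted(water_resnames))):
        warnings.warn("no water in system; protein-water count is 0")
        return 0.0, 0.0
    counts = []
    for _, _, events in _per_frame_events(traj, criterion, templates):
        counts.append(sum(1 for e in events if e.klass == "protein-water"))
    if n_blocks is None:
        n_blocks = min(10, len(counts))
    return block_average(np.array(counts, dtype=float), n_blocks)


@dataclass
class ProfileComparison:
    delta: dict  # (chain, resid) -> p_B - p_A
    n_decreased: int
    n_increased: int
    pearson_r: float


def compare_probabilities(profile_a: ResidueHBondProfile,
                          profile_b: ResidueHBondProfile) -> ProfileComparison:
    """Per-residue probability change B - A, counts of strict decreases and
    increases, and the Pearson correlation of the two profiles.

    The residue sets must match exactly (residue naming differences between
    hydroxylation states do not enter: keys are (chain, index)).  A constant
    profile makes the correlation undefined; NaN is returned with a warning.
    """
    keys_a = set(profile_a.probabilities)
    keys_b = set(profile_b.probabilities)
    if keys_a != keys_b:
        diff = sorted(keys_a ^ keys_b)
        shown = ", ".join(f"{c}:{r}" for c, r in diff[:10])
        raise ValueError(
            f"residue sets differ in {len(diff)} entries: {shown}"
            + ("..." if len(diff) > 10 else "")
        )
    keys = sorted(keys_a)
    pa = np.array([profile_a.probabilities[k] for k in keys])
    pb = np.array([profile_b.probabilities[k] for k in keys])
    delta = pb - pa
    if pa.std() == 0.0 or pb.std() == 0.0:
        warnings.warn("constant profile: Pearson correlation undefined (NaN)")
        r = float("nan")
    else:
        r = float(stats.pearsonr(pa, pb).statistic)
    return ProfileComparison(
        delta={k: float(d) for k, d in zip(keys, delta)},
        n_decreased=int(np.sum(delta < 0)),
        n_increased=int(np.sum(delta > 0)),
        pearson_r=r,
    )


def percent_drop(before: float, after: float) -> float:
    """Percent reduction 100 * (before - after) / before."""
    if before == 0:
        raise ValueError("undefined percent drop from zero")
    return 100.0 * (before - after) / before
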