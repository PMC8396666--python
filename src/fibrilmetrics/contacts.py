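"""Persistent residue contact maps under periodicity.

Two residues are in contact in a frame when any of their heavy atoms
(element != H) are within the cutoff (default 0.6 nm) of each other under
the minimum-image convention; a pair is retained when it is in contact for
strictly more than half of the frames.  The lattice shift of the closest
atom pair labels the contact: a nonzero shift in the majority of qualifying
frames marks an inter-monomer contact (the partner is a periodic image).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Frame, Trajectory
from .hbonds import load_hbond_templates, monomer_image_offsets, neighbor_pairs
from .pbc import min_image_disp_batch

__all__ = ["ContactPair", "ContactMap", "persistent_contacts", "compare_maps", "MapComparison"]


def _canonical_key(res_a, res_b):
    return tuple(sorted([res_a, res_b]))


@dataclass(frozen=True)
class ContactPair:
    residues: tuple  # ((chain, resid), (chain, resid)), canonically ordered
    label: str  # inter-monomer | intra-monomer
    persistence: float  # fraction of frames in contact, in (persistence_min, 1]

    def __post_init__(self):
        if not 0.0 < self.persistence <= 1.0:
            raise ValueError("persistence must be in (0, 1]")


@dataclass
class ContactMap:
    """Retained contact pairs keyed by canonical residue pair."""

    pairs: dict  # key -> ContactPair
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.pairs)

    def keys(self):
        return self.pairs.keys()

    def inter_monomer(self) -> "ContactMap":
        return ContactMap(
            {k: p for k, p in self.pairs.items() if p.label == "inter-monomer"},
            self.provenance,
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("chainA\tresA\tchainB\tresB\tlabel\tpersistence\n")
            for key in sorted(self.pairs):
                p = self.pairs[key]
                (ca, ra), (cb, rb) = key
                fh.write(f"{ca}\t{ra}\t{cb}\t{rb}\t{p.label}\t{p.persistence:.6f}\n")

    @classmethod
    def from_tsv(cls, path) -> "ContactMap":
        pairs = {}
        with open(path) as fh:
            next(fh)
            for line in fh:
                ca, ra, cb, rb, label, pers = line.rstrip("\n").split("\t")
                key = _canonical_key((ca, int(ra)), (cb, int(rb)))
                pairs[key] = ContactPair(key, label, float(pers))
        return cls(pairs, provenance=str(path))


def persistent_contacts(traj: Trajectory, cutoff: float = 0.6,
                        persistence_min: float = 0.5,
                        templates: dict | None = None) -> ContactMap:
    """Residue pairs whose closest heavy-atom minimum-image distance is below
    ``cutoff`` in strictly more than ``persistence_min`` of the frames.

    Water residues are ignored; same-residue pairs are excluded by
    construction.  Sequence neighbours are *not* excluded.  When a pair
    contacts simultaneously through two images it still counts once per
    frame; the shift of the closest atom pair decides the per-frame
    inter/intra flag, and the majority over qualifying frames decides the
    label (ties fall to intra-monomer).
    """
    if traj.n_frames < 2:
        raise ValueError("persistence needs at least 2 frames")
    if templates is None:
        templates = load_hbond_templates()
    water = set(templates.get("water_resnames", []))
    first = traj.frames[0]
    heavy = np.nonzero(
        (first.elements != "H") & ~np.isin(first.resnames, sorted(water))
    )[0]
    if len(heavy) == 0:
        raise ValueError("no heavy atoms in system")

    # integer residue codes for vectorized pair reduction
    res_keys_arr = np.empty(len(heavy), dtype=object)
    seen: dict = {}
    codes = np.empty(len(heavy), dtype=np.int64)
    for k, (c, r) in enumerate(zip(first.chains[heavy], first.resids[heavy])):
        key = (str(c), int(r))
        res_keys_arr[k] = key
        codes[k] = seen.setdefault(key, len(seen))
    code_to_key = {v: k for k, v in seen.items()}
    n_res = len(seen)
    n_frames = traj.n_frames
    # wrap-image offsets of the stored representation (constant across the
    # trajectory); inter/intra labels use monomer-relative shifts
    offsets = monomer_image_offsets(first)[heavy]

    qual_keys, inter_keys = [], []
    for fr in traj.frames:
        pos = fr.positions[heavy]
        cand = neighbor_pairs(pos, pos, fr.cell, cutoff)
        cand = cand[cand[:, 0] < cand[:, 1]]
        if len(cand) == 0:
            continue
        disp, shifts = min_image_disp_batch(pos[cand[:, 0]], pos[cand[:, 1]], fr.cell)
        dist = np.linalg.norm(disp, axis=1)
        ok = dist < cutoff
        cand, shifts, dist = cand[ok], shifts[ok], dist[ok]
        ca, cb = codes[cand[:, 0]], codes[cand[:, 1]]
        diff = ca != cb  # same-residue pairs excluded by construction
        lo, hi = np.minimum(ca, cb)[diff], np.maximum(ca, cb)[diff]
        pair_code = lo * n_res + hi
        relative = shifts + offsets[cand[:, 1]] - offsets[cand[:, 0]]
        nonzero = np.any(relative[diff] != 0, axis=1)
        dist = dist[diff]
        # closest atom pair per residue pair this frame decides the flag
        order = np.lexsort((dist, pair_code))
        uniq, first_idx = np.unique(pair_code[order], return_index=True)
        qual_keys.append(uniq)
        inter_keys.append(uniq[nonzero[order][first_idx]])

    if not qual_keys:
        return ContactMap({})
    all_q, q_counts = np.unique(np.concatenate(qual_keys), return_counts=True)
    all_i, i_counts = np.unique(np.concatenate(inter_keys), return_counts=True)
    inter_lookup = dict(zip(all_i.tolist(), i_counts.tolist()))

    pairs = {}
    for pc, q in zip(all_q.tolist(), q_counts.tolist()):
        persistence = q / n_frames
        if persistence <= persistence_min:
            continue
        key = _canonical_key(code_to_key[pc // n_res], code_to_key[pc % n_res])
        label = "inter-monomer" if 2 * inter_lookup.get(pc, 0) > q else "intra-monomer"
        pairs[key] = ContactPair(key, label, persistence)
    return ContactMap(pairs)


@dataclass
class MapComparison:
    common: set
    unique_a: set
    unique_b: set
    label_changes: dict = field(default_factory=dict)  # key -> (label_a, label_b)

    @property
    def n_common(self) -> int:
        return len(self.common)

    @property
    def n_unique_a(self) -> int:
        return len(self.unique_a)

    @property
    def n_unique_b(self) -> int:
        return len(self.unique_b)


def compare_maps(map_a: ContactMap, map_b: ContactMap) -> MapComparison:
    """Set intersection/differences of canonical pair keys.

    Labels are ignored for identity; pairs common to both maps but with
    different inter/intra labels are reported in ``label_changes``.
    """
    ka, kb = set(map_a.keys()), set(map_b.keys())
    common = ka & kb
    changes = {
        k: (map_a.pairs[k].label, map_b.pairs[k].label)
        for k in common
        if map_a.pairs[k].label != map_b.pairs[k].label
    }
    return MapComparison(common, ka - kb, kb - ka, changes)
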