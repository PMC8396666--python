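"""Structure/trajectory I/O and the de-hydroxylation structure edit.

File handling is delegated to MDAnalysis (PDB with CRYST1 and MODEL/ENDMDL,
GRO including the 9-number triclinic box line); this module maps between
MDAnalysis universes and the package's nm-based :class:`~fibrilmetrics.core.Frame`
containers.

Two dialect quirks are handled here rather than upstream:

* chain identifiers longer than one character (the heterotrimer chains are
  labelled ``a1a``, ``a1b``, ``a2``) are mapped to single PDB characters via
  an emitted JSON sidecar, and mapped back on read;
* multi-model PDB files may carry one CRYST1 per MODEL (constant-pressure
  trajectories breathe); a light text scan assigns per-frame cells when more
  than one CRYST1 is present.
"""

from __future__ import annotations

import json
import os
import warnings
from importlib import resources
from pathlib import Path

import numpy as np

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda
    from MDAnalysis.lib import mdamath

from .core import Frame, Trajectory, element_from_name, mass_of
from .pbc import InvalidCellError, TriclinicCell

__all__ = [
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "dehydroxylate",
    "load_dehydroxylation_templates",
    "DehydroxylationReport",
]

NM_PER_ANGSTROM = 0.1

_CHAIN_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789abcdefghijklmnopqrstuvwxyz"

_KNOWN_RESNAMES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP "
    "TYR VAL HYP LYZ HYL SOL HOH WAT TIP3 SPC NA CL MG K".split()
)


def _load_packaged_json(name: str) -> dict:
    with resources.files("fibrilmetrics.data").joinpath(name).open() as fh:
        return json.load(fh)


def load_dehydroxylation_templates(path=None) -> dict:
    """Default edit templates (HYP -> PRO etc.), or a user-supplied JSON."""
    if path is None:
        return _load_packaged_json("dehydroxylation_templates.json")
    with open(path) as fh:
        return json.load(fh)


def _cell_from_dimensions(dim) -> TriclinicCell:
    """MDAnalysis [lx, ly, lz, alpha, beta, gamma] (Angstrom) -> cell in nm."""
    if dim is None or not np.all(np.asarray(dim)[:3] > 0):
        raise InvalidCellError(
            "structure carries no usable cell (missing/zero CRYST1 or box line); "
            "supply one explicitly"
        )
    tri = mdamath.triclinic_vectors(np.asarray(dim, dtype=np.float64)) * NM_PER_ANGSTROM
    return TriclinicCell(*tri)


def _dimensions_from_cell(cell: TriclinicCell) -> np.ndarray:
    return np.asarray(
        mdamath.triclinic_box(*(cell.matrix / NM_PER_ANGSTROM)), dtype=np.float64
    )


def _chain_mapping_path(path) -> Path:
    p = Path(path)
    return p.with_name(p.name + ".chains.json")


def _encode_chains(chains) -> tuple[np.ndarray, dict]:
    """Map arbitrary chain labels onto single characters, preserving
    single-character labels as-is where possible."""
    labels = list(dict.fromkeys(str(c) for c in chains))
    mapping = {}
    used = set()
    for lab in labels:
        if len(lab) == 1 and lab not in used:
            mapping[lab] = lab
            used.add(lab)
    for lab in labels:
        if lab in mapping:
            continue
        char = next(c for c in _CHAIN_ALPHABET if c not in used)
        mapping[lab] = char
        used.add(char)
    encoded = np.array([mapping[str(c)] for c in chains], dtype="U1")
    return encoded, mapping


def _frame_from_universe(u, cell=None) -> Frame:
    atoms = u.atoms
    names = np.array([a.name for a in atoms], dtype="U6")
    try:
        chains = np.array([a.chainID for a in atoms], dtype="U8")
    except (mda.exceptions.NoDataError, AttributeError):
        chains = np.array([a.segid or "A" for a in atoms], dtype="U8")
    resnames = np.array([a.resname for a in atoms], dtype="U6")
    resids = np.array([a.resid for a in atoms], dtype=np.int64)
    elements = np.array([element_from_name(n) for n in names], dtype="U2")
    unknown = [e for e in np.unique(elements) if e.upper() not in
               ("H", "C", "N", "O", "S", "P", "NA", "CL", "MG", "K")]
    if unknown:
        warnings.warn(f"unknown elements {unknown}; assigning fallback mass 12 amu")
    odd_res = sorted(set(np.unique(resnames)) - _KNOWN_RESNAMES)
    if odd_res:
        warnings.warn(f"unknown residue names retained: {odd_res}")
    masses = np.array([mass_of(e) for e in elements])
    if cell is None:
        cell = _cell_from_dimensions(u.dimensions)
    return Frame(
        names=names,
        elements=elements,
        resnames=resnames,
        resids=resids,
        chains=chains,
        positions=atoms.positions.astype(np.float64) * NM_PER_ANGSTROM,
        masses=masses,
        cell=cell,
    )


def _apply_chain_mapping(frame: Frame, path) -> Frame:
    mpath = _chain_mapping_path(path)
    if mpath.exists():
        with open(mpath) as fh:
            mapping = json.load(fh)
        reverse = {v: k for k, v in mapping.items()}
        frame.chains = np.array(
            [reverse.get(str(c), str(c)) for c in frame.chains], dtype="U8"
        )
    return frame


def _detect_format(path, fmt=None) -> str:
    if fmt is not None:
        return fmt.upper()
    ext = Path(path).suffix.lower().lstrip(".")
    if ext in ("pdb", "ent"):
        return "PDB"
    if ext == "gro":
        return "GRO"
    raise ValueError(f"cannot infer structure format from '{path}'; pass format=")


def read_structure(path, format=None, cell: TriclinicCell | None = None) -> Frame:
    """Read a single structure (PDB or GRO) into a Frame, converting to nm.

    PDB files must carry a CRYST1 record unless ``cell`` is supplied.
    Unknown residue names are retained (a warning is emitted for unknown
    elements only, since masses matter downstream).
    """
    fmt = _detect_format(path, format)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path), format=fmt)
    frame = _frame_from_universe(u, cell=cell)
    return _apply_chain_mapping(frame, path)


def _universe_from_frame(frame: Frame, chains_encoded) -> "mda.Universe":
    n = frame.n_atoms
    if n == 0:
        u = mda.Universe.empty(0, trajectory=True)
        u.dimensions = _dimensions_from_cell(frame.cell)
        return u
    # residue grouping: consecutive runs of (chain, resid)
    keys = list(zip(frame.chains.tolist(), frame.resids.tolist()))
    resindex = np.zeros(n, dtype=int)
    res_resids, res_resnames, res_chain = [], [], []
    current = None
    ridx = -1
    for i, key in enumerate(keys):
        if key != current:
            ridx += 1
            current = key
            res_resids.append(int(frame.resids[i]))
            res_resnames.append(str(frame.resnames[i]))
            res_chain.append(str(chains_encoded[i]))
        resindex[i] = ridx
    n_res = ridx + 1
    u = mda.Universe.empty(
        n, n_residues=n_res, n_segments=1,
        atom_resindex=resindex, residue_segindex=np.zeros(n_res, dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", frame.names.tolist())
    u.add_TopologyAttr("resnames", res_resnames)
    u.add_TopologyAttr("resids", res_resids)
    u.add_TopologyAttr("chainIDs", [str(c) for c in chains_encoded])
    u.add_TopologyAttr("elements", frame.elements.tolist())
    u.add_TopologyAttr("occupancies", np.ones(n))
    u.add_TopologyAttr("tempfactors", np.zeros(n))
    u.atoms.positions = frame.positions / NM_PER_ANGSTROM
    u.dimensions = _dimensions_from_cell(frame.cell)
    return u


def _write_chain_mapping(frame, chains_encoded, path):
    mapping = {}
    for orig, enc in zip(frame.chains, chains_encoded):
        mapping[str(orig)] = str(enc)
    if any(k != v for k, v in mapping.items()):
        with open(_chain_mapping_path(path), "w") as fh:
            json.dump(mapping, fh, indent=1, sort_keys=True)


def write_structure(frame: Frame, path, format=None) -> None:
    """Write a Frame as PDB (Angstrom, CRYST1) or GRO (nm, triclinic box).

    Chain labels longer than one character are encoded to single characters;
    the mapping is written next to the file as ``<name>.chains.json`` and is
    transparently applied by :func:`read_structure`.
    """
    fmt = _detect_format(path, format)
    for name in frame.names:
        if len(str(name)) > 5:
            raise ValueError(f"atom name '{name}' not encodable in {fmt}")
    chains_encoded, _ = _encode_chains(frame.chains) if frame.n_atoms else (frame.chains, {})
    u = _universe_from_frame(frame, chains_encoded)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if u.atoms.n_atoms == 0:
            # emit a minimal header-only file
            if fmt == "PDB":
                dim = _dimensions_from_cell(frame.cell)
                with open(path, "w") as fh:
                    fh.write(
                        "CRYST1%9.3f%9.3f%9.3f%7.2f%7.2f%7.2f P 1           1\nEND\n"
                        % tuple(dim)
                    )
            else:
                box = mdamath.triclinic_vectors(_dimensions_from_cell(frame.cell)) * NM_PER_ANGSTROM
                line = _gro_box_line(box)
                with open(path, "w") as fh:
                    fh.write("empty structure\n    0\n" + line)
            return
        u.atoms.write(str(path))
    if frame.n_atoms:
        _write_chain_mapping(frame, chains_encoded, path)


def _gro_box_line(box_matrix) -> str:
    v1, v2, v3 = box_matrix
    vals = [v1[0], v2[1], v3[2], v1[1], v1[2], v2[0], v2[2], v3[0], v3[1]]
    if all(abs(v) < 1e-12 for v in vals[3:]):
        vals = vals[:3]
    return " ".join(f"{v:10.5f}" for v in vals) + "\n"


def _scan_pdb_cryst1(path) -> list:
    """Per-MODEL CRYST1 records (Angstrom dimension tuples), in file order."""
    cells = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("CRYST1"):
                vals = [float(line[6 + 9 * i: 15 + 9 * i]) for i in range(3)]
                angs = [float(line[33 + 7 * i: 40 + 7 * i]) for i in range(3)]
                cells.append(np.array(vals + angs))
    return cells


def read_trajectory(path, format=None, times=None, dt_ns=1.0,
                    cell: TriclinicCell | None = None) -> Trajectory:
    """Read a multi-model PDB (or single structure) as a Trajectory.

    Per-MODEL CRYST1 records are honoured when present; otherwise the single
    cell applies to every frame.  ``times`` (ns) overrides the default
    uniform grid ``0, dt_ns, 2*dt_ns, ...``.
    """
    fmt = _detect_format(path, format)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path), format=fmt)
    per_model_cells = None
    if fmt == "PDB" and cell is None:
        cryst = _scan_pdb_cryst1(path)
        if len(cryst) > 1:
            if len(cryst) != len(u.trajectory):
                raise ValueError(
                    f"found {len(cryst)} CRYST1 records for {len(u.trajectory)} models"
                )
            per_model_cells = [_cell_from_dimensions(c) for c in cryst]
        elif len(cryst) == 1:
            # the stock reader drops a header CRYST1 for multi-model files
            cell = _cell_from_dimensions(cryst[0])
    frames = []
    for k, ts in enumerate(u.trajectory):
        fcell = cell
        if per_model_cells is not None:
            fcell = per_model_cells[k]
        fr = _frame_from_universe(u, cell=fcell)
        fr = _apply_chain_mapping(fr, path)
        frames.append(fr)
    for k, fr in enumerate(frames[1:], start=1):
        if not fr.same_identity(frames[0]):
            raise ValueError(f"atom identity mismatch between frame 0 and frame {k}")
    if times is None:
        times = np.arange(len(frames)) * dt_ns
    return Trajectory(frames, times)


def write_trajectory(traj: Trajectory, path, format=None) -> None:
    """Write a Trajectory as a multi-model PDB.

    If cells vary across frames, a CRYST1 record is inserted before each
    MODEL in a post-pass (the stock writer emits a single header CRYST1).
    """
    fmt = _detect_format(path, format)
    if fmt != "PDB":
        raise ValueError("trajectory container format is multi-model PDB")
    first = traj.frames[0]
    chains_encoded, _ = _encode_chains(first.chains)
    u = _universe_from_frame(first, chains_encoded)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), multiframe=True, n_atoms=first.n_atoms) as w:
            for fr in traj.frames:
                u.atoms.positions = fr.positions / NM_PER_ANGSTROM
                u.dimensions = _dimensions_from_cell(fr.cell)
                w.write(u.atoms)
    _write_chain_mapping(first, chains_encoded, path)
    cells = [fr.cell.matrix for fr in traj.frames]
    if any(not np.allclose(c, cells[0]) for c in cells[1:]):
        _insert_per_model_cryst1(path, traj)


def _insert_per_model_cryst1(path, traj: Trajectory) -> None:
    with open(path) as fh:
        lines = fh.readlines()
    out = []
    model_idx = 0
    for line in lines:
        if line.startswith("CRYST1"):
            continue  # drop the single header record
        if line.startswith("MODEL"):
            dim = _dimensions_from_cell(traj.frames[model_idx].cell)
            out.append(
                "CRYST1%9.3f%9.3f%9.3f%7.2f%7.2f%7.2f P 1           1\n" % tuple(dim)
            )
            model_idx += 1
        out.append(line)
    with open(path, "w") as fh:
        fh.writelines(out)


# ---------------------------------------------------------------------------
# de-hydroxylation edit
# ---------------------------------------------------------------------------

class DehydroxylationReport:
    """Per-residue record of the edit: which atoms were removed and what the
    residue was renamed to."""

    def __init__(self):
        self.entries = []  # (chain, resid, old_resname, new_resname, removed atom names)

    def add(self, chain, resid, old, new, removed):
        self.entries.append((str(chain), int(resid), str(old), str(new), list(removed)))

    @property
    def n_edited(self) -> int:
        return len(self.entries)

    @property
    def n_atoms_removed(self) -> int:
        return sum(len(e[4]) for e in self.entries)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("chain\tresid\told_resname\tnew_resname\tatoms_removed\n")
            for chain, resid, old, new, removed in self.entries:
                fh.write(f"{chain}\t{resid}\t{old}\t{new}\t{','.join(removed)}\n")


def dehydroxylate(frame: Frame, templates: dict | None = None):
    """Remove hydroxyl groups from hydroxylated residues and rename them.

    Default templates: HYP -> PRO dropping OD1/HD1, hydroxylysine dialects
    (LYZ, HYL) -> LYS dropping the hydroxyl oxygen and its hydrogen.
    Surviving atoms keep their coordinates untouched; the edit is idempotent
    because edited residues no longer match any template.

    Returns ``(edited_frame, report)``.

    Raises ``ValueError`` if a residue matches a template but lacks the named
    hydroxyl atoms (naming dialect mismatch should fail loudly, not silently
    skip the edit).
    """
    if templates is None:
        templates = load_dehydroxylation_templates()
    keep = np.ones(frame.n_atoms, dtype=bool)
    resnames = frame.resnames.copy()
    names = frame.names.copy()
    report = DehydroxylationReport()

    keys = frame.residue_keys()
    # stable order of first appearance
    _, first_idx = np.unique(keys, return_index=True)
    for start in sorted(first_idx):
        key = keys[start]
        resname = str(frame.resnames[start])
        if resname not in templates:
            continue
        rule = templates[resname]
        sel = np.nonzero(keys == key)[0]
        res_names = {str(frame.names[i]): i for i in sel}
        missing = [a for a in rule["delete_atoms"] if a not in res_names]
        if missing:
            raise ValueError(
                f"residue {key['chain']}:{int(key['resid'])} ({resname}) matches an "
                f"edit template but lacks hydroxyl atom(s) {missing}"
            )
        removed = []
        for a in rule["delete_atoms"]:
            keep[res_names[a]] = False
            removed.append(a)
        for old_name, new_name in rule.get("rename_atoms", {}).items():
            if old_name in res_names:
                names[res_names[old_name]] = new_name
        resnames[sel] = rule["rename_to"]
        report.add(key["chain"], key["resid"], resname, rule["rename_to"], removed)

    edited = Frame(
        names=names[keep],
        elements=frame.elements[keep].copy(),
        resnames=resnames[keep],
        resids=frame.resids[keep].copy(),
        chains=frame.chains[keep].copy(),
        positions=frame.positions[keep].copy(),
        masses=frame.masses[keep].copy(),
        cell=frame.cell,
        aux={k: (np.asarray(v)[keep].copy() if np.ndim(v) and len(v) == frame.n_atoms else v)
             for k, v in frame.aux.items()},
    )
    return edited, report
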