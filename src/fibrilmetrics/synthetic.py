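"""Idealized D-periodic collagen microfibril generator with known ground truth.

The model follows the Hodge-Petruska picture of a D-banded fibril: one
triple-helix monomer of axial extent ``monomer_length_D * dband`` (default
4.46 D with D = 67 nm) lives in a triclinic cell whose longest lattice
constant is one D-period, and neighbouring monomers are its periodic images,
axially staggered by D.  The monomer is threaded through ``n_lateral_sites``
lateral positions, one per successive D-segment, so a cross-section of the
wrapped cell shows five chain segments in the overlap region and four in the
gap region; the ideal gap length is ``n_lateral_sites - monomer_length_D``
D-periods (0.54 D by default).

The triple helix itself is coarse: per residue the three chains carry the
five backbone-like atoms N, H, CA, C, O wound at ``helix_radius`` about a
common local axis (default radius 0.70/sqrt(3) nm so the monomer width,
the largest N-N distance in a cross-sectional rung, is exactly 0.70 nm),
plus an OD1/HD1 pseudo-hydroxyl on hydroxylated residues.  Chains share
residue indexing with a one-residue axial offset per chain, so matched rungs
sit at identical axial coordinates with chain phases exactly 120 degrees
apart.  The terminal stretches of each chain taper onto the local axis — a
crude stand-in for the non-helical telopeptides — which also makes the
end-to-end observable exactly affine under applied strain.

None of this is meant as physics: the generator emulates the statistical
structure the analyses assume (periodicity, segment registration, H-bond
geometry, known modulus/slippage), with ground truth that is self-defined
rather than fitted to any real trajectory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .core import Frame, Trajectory, mass_of
from .mechanics import StressSeries
from .pbc import TriclinicCell, wrap_to_cell

__all__ = [
    "FibrilSpec",
    "StrainSpec",
    "StressSeriesSpec",
    "build_microfibril",
    "make_trajectory",
    "apply_strain",
    "gen_stress_series",
    "plant_boundary_hbonds",
    "ground_truth",
]

CHAIN_IDS = ("a1a", "a1b", "a2")  # heterotrimer labels: two alpha-1, one alpha-2

# (name, element, sub-z fraction of one rise, radial offset from helix radius)
_BACKBONE_ATOMS = (
    ("N", "N", 0.00, 0.00),
    ("H", "H", 0.00, 0.10),
    ("CA", "C", 0.35, 0.00),
    ("C", "C", 0.65, 0.00),
    ("O", "O", 0.65, 0.12),
)
_HYDROXYL_ATOMS = (
    ("OD1", "O", 0.35, 0.14),
    ("HD1", "H", 0.35, 0.24),
)


@dataclass
class FibrilSpec:
    """Parameters of the ideal staggered microfibril.

    Lengths in nm.  ``monomer_length_D`` and ``stagger_D`` are in units of
    the D-period; ``hydroxyl_fraction`` is the fraction of all residues
    carrying a pseudo-hydroxyl (drawn as an exact count among non-glycine
    positions).
    """

    dband: float = 67.0
    monomer_length_D: float = 4.46
    stagger_D: float = 1.0
    n_lateral_sites: int = 5
    helix_radius: float = 0.70 / np.sqrt(3.0)
    residues_per_chain: int = 1014
    hydroxyl_fraction: float = 0.10
    axial_rise_per_triplet: float | None = None  # overrides residues_per_chain
    noise_sigma: float = 0.01
    seed: int = 0
    # lateral packing (quasi-hexagonal scale, not crystallographic)
    lateral_a: float = 4.0
    lateral_b: float = 4.0
    lateral_skew: float = 0.5  # x-component of the b vector
    site_circle_radius: float = 1.5
    helix_pitch: float = 8.5  # supercoil pitch, nm
    transition_width: float = 1.5  # axial window smoothing lateral-site hops
    taper_fraction: float = 0.03  # terminal (telopeptide-like) on-axis taper
    lysine_every: int = 12  # every Nth X-position residue is a lysine

    def __post_init__(self):
        if not 0.0 < self.monomer_length_D < self.n_lateral_sites:
            raise ValueError(
                "monomer_length_D must lie in (0, n_lateral_sites): "
                f"got {self.monomer_length_D} with {self.n_lateral_sites} sites "
                "(no gap region possible otherwise)"
            )
        if self.stagger_D != 1.0:
            raise NotImplementedError(
                "axial stagger is realized by the lattice constant itself; "
                "only stagger_D = 1.0 is supported"
            )
        if self.dband <= 0 or self.helix_radius <= 0:
            raise ValueError("dband and helix_radius must be positive")
        if not 0.0 <= self.hydroxyl_fraction < 1.0:
            raise ValueError("hydroxyl_fraction must be in [0, 1)")
        if self.axial_rise_per_triplet is not None:
            rise = self.axial_rise_per_triplet / 3.0
            self.residues_per_chain = int(round(self.monomer_extent / rise)) - 2
        if self.residues_per_chain < 30:
            raise ValueError("need at least 30 residues per chain")

    @property
    def monomer_extent(self) -> float:
        """Axial extent of the monomer, nm (= monomer_length_D * dband)."""
        return self.monomer_length_D * self.dband

    @property
    def rise_per_residue(self) -> float:
        # chains share one flush axial grid of residues_per_chain rungs; the
        # last atom (sub-rise 0.65 into the final rung, plus a small guard)
        # lands just inside monomer_extent so the occupied density ends on
        # the ideal gap boundary
        return self.monomer_extent / (self.residues_per_chain - 0.3)

    @property
    def ideal_gap_fraction_D(self) -> float:
        """Gap length in D-periods of the ideal arrangement."""
        return self.n_lateral_sites - self.monomer_length_D

    def cell(self) -> TriclinicCell:
        return TriclinicCell(
            [self.lateral_a, 0.0, 0.0],
            [self.lateral_skew, self.lateral_b, 0.0],
            [0.0, 0.0, self.dband],
        )

    def lateral_site_centers(self) -> np.ndarray:
        """(n_sites, 2) lateral positions on a circle at the cell centre."""
        centre = (np.array([self.lateral_a, 0.0]) + np.array([self.lateral_skew, self.lateral_b])) / 2.0
        ang = 2.0 * np.pi * np.arange(self.n_lateral_sites) / self.n_lateral_sites
        return centre[None, :] + self.site_circle_radius * np.stack(
            [np.cos(ang), np.sin(ang)], axis=1
        )


@dataclass
class StrainSpec:
    """Applied axial strain with monomer slippage.

    ``slippage`` f in [0, 1] is the fraction of cell elongation taken up by
    monomers sliding past each other rather than stretching, so the
    noiseless generator output satisfies L/L0 - 1 = (1 - f) * epsilon
    exactly.  ``width_contraction`` is the fractional reduction of the helix
    radius per unit strain (triple-helix windings tighten as they stretch).
    """

    epsilon: float
    slippage: float = 0.0
    width_contraction: float = 0.3

    def __post_init__(self):
        if self.epsilon <= -1.0:
            raise ValueError("strain must be > -1")
        if not 0.0 <= self.slippage <= 1.0:
            raise ValueError("slippage fraction must be in [0, 1]")


@dataclass
class StressSeriesSpec:
    """Synthetic axial-stress time series with known modulus.

    sigma(t) = sigma0 + E * eps * (1 - exp(-t / tau_eq)) + AR(1) noise,
    so the asymptotic mean is sigma0 + E * eps.
    """

    modulus_E: float = 500.0  # MPa
    epsilon: float = 0.0
    tau_eq: float = 10.0  # ns
    noise_sd: float = 2.0  # MPa, AR(1) innovation sd
    ar1_coeff: float = 0.8
    n_points: int = 1000
    dt: float = 0.1  # ns
    sigma0: float = 0.1  # MPa

    def __post_init__(self):
        if self.tau_eq <= 0:
            raise ValueError("tau_eq must be positive")
        if not 0.0 <= self.ar1_coeff < 1.0:
            raise ValueError("ar1_coeff must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _site_centers_at(z: np.ndarray, spec: FibrilSpec) -> np.ndarray:
    """Lateral site centre followed by the molecule at axial coordinate z.

    Piecewise constant per D-segment, with a smoothstep transition of width
    ``transition_width`` centred on each segment boundary so that bonded
    atoms never jump more than a fraction of a bond length.
    """
    centers = spec.lateral_site_centers()
    D = spec.dband
    w = spec.transition_width
    k = np.clip(np.floor(z / D).astype(int), 0, spec.n_lateral_sites - 1)
    out = centers[k].astype(float).copy()
    # blend across boundary m*D for m = 1..n_sites-1
    for m in range(1, spec.n_lateral_sites):
        lo, hi = m * D - w / 2.0, m * D + w / 2.0
        sel = (z > lo) & (z < hi)
        if not np.any(sel):
            continue
        s = _smoothstep((z[sel] - lo) / w)[:, None]
        out[sel] = (1.0 - s) * centers[m - 1] + s * centers[m]
    return out


def _taper_factor(res_index: np.ndarray, n_res: int, fraction: float) -> np.ndarray:
    """Radius multiplier tapering the chain termini onto the local axis."""
    k = max(2, int(round(fraction * n_res)))
    i = res_index.astype(float)  # 1-based
    from_start = (i - 1.0) / k
    from_end = (n_res - i) / k
    return np.clip(np.minimum(from_start, from_end), 0.0, 1.0)


def _residue_names_and_flags(spec: FibrilSpec, rng: np.random.Generator):
    """GXY residue naming plus an exact-count draw of hydroxylation flags."""
    n = spec.residues_per_chain
    total = 3 * n
    base = np.empty(total, dtype="U3")
    pos = np.arange(total) % 3  # 0 = G, 1 = X, 2 = Y
    base[pos == 0] = "GLY"
    base[pos == 1] = "PRO"
    base[pos == 2] = "PRO"
    x_idx = np.nonzero(pos == 1)[0]
    if spec.lysine_every > 0:
        base[x_idx[:: spec.lysine_every]] = "LYS"
    eligible = np.nonzero(base != "GLY")[0]
    n_flag = int(round(spec.hydroxyl_fraction * total))
    if n_flag > len(eligible):
        raise ValueError("hydroxyl_fraction too high for the GXY pattern")
    flagged = np.zeros(total, dtype=bool)
    if n_flag:
        flagged[rng.choice(eligible, size=n_flag, replace=False)] = True
    names = base.copy()
    names[flagged & (base == "PRO")] = "HYP"
    names[flagged & (base == "LYS")] = "LYZ"
    return names.reshape(3, n), flagged.reshape(3, n)


def build_microfibril(spec: FibrilSpec | None = None) -> Frame:
    """Build one noiseless triple-helix monomer wrapped into its D-cell.

    Returns a :class:`Frame` whose periodic images realize the stagger-D
    arrangement.  ``frame.aux`` records per-atom provenance: the unwrapped
    axial coordinate, the lateral site centre, the D-segment index, and the
    hydroxylation flags — used by :func:`apply_strain` for exact strain
    ground truth and available to tests; analyses never require it.
    """
    if spec is None:
        spec = FibrilSpec()
    rng = np.random.default_rng(spec.seed)
    resnames_by_chain, flags_by_chain = _residue_names_and_flags(spec, rng)

    rise = spec.rise_per_residue
    n_res = spec.residues_per_chain

    # chains share one flush axial grid; the canonical one-residue stagger
    # lives in the indexing: the rung at z = (j-1)*rise holds residue j+2 of
    # chain a1a, j+1 of a1b and j of a2, so matched rungs sit at identical
    # axial coordinates with chain phases exactly 120 degrees apart
    names, elements, resnames, resids, chains = [], [], [], [], []
    z_list, radial_offsets, phase_chain, res_of_atom = [], [], [], []
    for c, chain_id in enumerate(CHAIN_IDS):
        for j in range(1, n_res + 1):
            resname = resnames_by_chain[c, j - 1]
            atoms = _BACKBONE_ATOMS + (_HYDROXYL_ATOMS if resname in ("HYP", "LYZ") else ())
            z_res = (j - 1) * rise
            resid = j + 2 - c
            for (aname, elem, subz, dr) in atoms:
                names.append(aname)
                elements.append(elem)
                resnames.append(resname)
                resids.append(resid)
                chains.append(chain_id)
                z_list.append(z_res + subz * rise)
                radial_offsets.append(dr)
                phase_chain.append(c)
                res_of_atom.append(j)

    z = np.array(z_list)
    dr = np.array(radial_offsets)
    cidx = np.array(phase_chain)
    ridx = np.array(res_of_atom)

    taper = _taper_factor(ridx, n_res, spec.taper_fraction)
    radius = taper * spec.helix_radius + dr
    phase = 2.0 * np.pi * z / spec.helix_pitch + 2.0 * np.pi * cidx / 3.0
    centers = _site_centers_at(z, spec)
    lateral = centers + radius[:, None] * np.stack([np.cos(phase), np.sin(phase)], axis=1)
    positions = np.column_stack([lateral, z])

    cell = spec.cell()
    wrapped = wrap_to_cell(positions, cell)

    elements = np.array(elements, dtype="U2")
    frame = Frame(
        names=np.array(names, dtype="U6"),
        elements=elements,
        resnames=np.array(resnames, dtype="U6"),
        resids=np.array(resids, dtype=np.int64),
        chains=np.array(chains, dtype="U8"),
        positions=wrapped,
        masses=np.array([mass_of(e) for e in elements]),
        cell=cell,
        aux={
            "z_unwrapped": z,
            "site_center": centers,
            "segment": np.clip(np.floor(z / spec.dband).astype(int), 0,
                               spec.n_lateral_sites - 1),
            "spec": spec,
        },
    )
    return frame


def make_trajectory(frame: Frame, n_frames: int, noise_sigma: float | None = None,
                    seed: int = 0, dt_ns: float = 1.0,
                    first_frame_noiseless: bool = True) -> Trajectory:
    """Trajectory of i.i.d. isotropic Gaussian displacements about ``frame``.

    Stands in for the equilibrated analysis window of a long run: no drift,
    no correlated modes, just per-atom positional jitter of std
    ``noise_sigma`` (nm).  Noisy frames are deliberately not re-wrapped so
    the atom-to-image assignment is frame-independent.  Deterministic for a
    fixed seed.
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    if noise_sigma is None:
        spec = frame.aux.get("spec")
        noise_sigma = spec.noise_sigma if spec is not None else 0.0
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    rng = np.random.default_rng(seed)
    frames = []
    for k in range(n_frames):
        if noise_sigma == 0.0 or (k == 0 and first_frame_noiseless):
            frames.append(frame.copy())
        else:
            disp = rng.normal(0.0, noise_sigma, size=frame.positions.shape)
            frames.append(frame.copy(positions=frame.positions + disp))
    return Trajectory(frames, np.arange(n_frames) * dt_ns)


def apply_strain(frame: Frame, strain: StrainSpec) -> Frame:
    """Strained copy of a generator frame.

    The axial lattice constant scales by (1 + eps).  The molecule elongates
    by the monomer strain eps_m = (1 - f) * eps: axial coordinates and
    lateral site centres scale by (1 + eps_m) (slippage is thus a rigid
    re-registration of D-segments against the cell), while helix offsets
    about the site centres scale by (1 - width_contraction * eps), the
    winding tightening that accompanies stretch.  On generator frames
    (``aux`` present) this makes L/L0 - 1 = (1 - f) * eps exact; on generic
    frames a warning-free fallback scales all lateral coordinates by the
    width factor only.
    """
    eps = strain.epsilon
    eps_m = (1.0 - strain.slippage) * eps
    wfac = 1.0 - strain.width_contraction * eps
    cell = frame.cell
    axis_idx = cell.longest_axis_index()
    m = cell.matrix.copy()
    m[axis_idx] *= 1.0 + eps
    new_cell = TriclinicCell(*m)

    out = frame.copy(cell=new_cell)
    if "site_center" in frame.aux and "z_unwrapped" in frame.aux:
        z = frame.aux["z_unwrapped"] * (1.0 + eps_m)
        centers = frame.aux["site_center"] * (1.0 + eps_m)
        # helix offsets about the site centres, recovered by min image (the
        # wrapped representation differs from the build geometry only by
        # lattice translations, which min image removes)
        from .pbc import min_image_disp_batch
        ref = np.column_stack([frame.aux["site_center"], frame.aux["z_unwrapped"]])
        disp, _ = min_image_disp_batch(ref, frame.positions, cell)
        offsets = disp[:, :2]
        new_lateral = centers + offsets * wfac
        new_positions = np.column_stack([new_lateral, z])
        out.positions = wrap_to_cell(new_positions, new_cell)
        out.aux["z_unwrapped"] = z
        out.aux["site_center"] = centers
    else:
        axis = m[axis_idx] / np.linalg.norm(m[axis_idx])
        pos = frame.positions
        z_comp = pos @ axis
        lat = pos - z_comp[:, None] * axis
        out.positions = lat * wfac + (z_comp * (1.0 + eps_m))[:, None] * axis
    return out


def gen_stress_series(spec: StressSeriesSpec, seed: int = 0) -> StressSeries:
    """Synthetic axial-stress series with known modulus (see spec docstring).

    AR(1) noise is initialized from its stationary distribution, so the
    equilibrated tail is stationary about sigma0 + E * eps.
    """
    rng = np.random.default_rng(seed)
    t = spec.dt * np.arange(1, spec.n_points + 1)
    relax = spec.sigma0 + spec.modulus_E * spec.epsilon * (1.0 - np.exp(-t / spec.tau_eq))
    if spec.noise_sd > 0:
        rho = spec.ar1_coeff
        innov = rng.normal(0.0, spec.noise_sd, size=spec.n_points)
        noise = np.empty(spec.n_points)
        noise[0] = rng.normal(0.0, spec.noise_sd / np.sqrt(1.0 - rho**2))
        for i in range(1, spec.n_points):
            noise[i] = rho * noise[i - 1] + innov[i]
        relax = relax + noise
    return StressSeries(t, relax, sigma0=spec.sigma0)


def plant_boundary_hbonds(frame: Frame, n_pairs: int):
    """Reposition hydroxyl groups to plant exactly ``n_pairs`` inter-monomer
    hydrogen bonds across the axial cell boundary.

    For each pair, the OD1/HD1 of one hydroxylated residue (the donor) and of
    another (the acceptor) are moved to a laterally free strip of the cell:
    the acceptor OD1 sits just above the bottom face, the donor OD1 just
    below the top face, 0.29 nm apart through the boundary, with the donor
    HD1 aligned along the donor-acceptor axis (angle 0).  Because the bond is
    hydroxyl-mediated, de-hydroxylation removes it.

    The moved hydroxyls break the covalent-walk geometry of their residues,
    so frames edited this way are for H-bond bookkeeping, not for end-to-end
    or width analysis.  Returns ``(frame, pairs)`` with the (chain, resid)
    keys of donor and acceptor residues.
    """
    frame = frame.copy()
    axis_idx = frame.cell.longest_axis_index()
    if axis_idx != 2 or abs(frame.cell.matrix[2][0]) > 1e-9 or abs(frame.cell.matrix[2][1]) > 1e-9:
        raise ValueError("planting assumes a c-axial cell from the generator")
    D = frame.cell.matrix[2][2]
    hydroxyl = np.nonzero((frame.names == "OD1"))[0]
    if len(hydroxyl) < 2 * n_pairs:
        raise ValueError(f"need at least {2 * n_pairs} hydroxylated residues")
    spec = frame.aux.get("spec")
    if spec is None:
        raise ValueError("planting needs a generator frame (spec provenance)")
    # lateral spots with clearance from every site-centre image: no
    # incidental bond can involve a planted atom
    centers = spec.lateral_site_centers()
    lat = frame.cell.matrix[:2, :2]
    images = np.concatenate([
        centers + np.array([i, j], dtype=float) @ lat
        for i in (-1, 0, 1) for j in (-1, 0, 1)
    ])
    clearance = spec.helix_radius + 0.24 + 0.35 + 0.1  # atoms + cutoff + margin
    spots = []
    for gx in np.arange(0.3, spec.lateral_a, 0.2):
        for gy in np.arange(0.3, spec.lateral_b, 0.2):
            cand = np.array([gx, gy])
            if np.min(np.linalg.norm(images - cand, axis=1)) < clearance:
                continue
            if spots and np.min(
                np.linalg.norm(np.array(spots) - cand, axis=1)
            ) < 0.8:
                continue
            spots.append(cand)
    if len(spots) < n_pairs:
        raise ValueError(
            f"only {len(spots)} clear lateral spots for {n_pairs} planted pairs"
        )
    pairs = []
    for j in range(n_pairs):
        od1_d = hydroxyl[2 * j]
        od1_a = hydroxyl[2 * j + 1]
        hd1_d = od1_d + 1  # HD1 follows OD1 in build order
        hd1_a = od1_a + 1
        lx, ly = spots[j]
        a_pos = np.array([lx, ly, 0.16])
        d_pos = np.array([lx, ly, 0.16 - 0.29 + D])
        frame.positions[od1_a] = a_pos
        frame.positions[hd1_a] = a_pos + np.array([0.10, 0.0, 0.0])  # points sideways
        frame.positions[od1_d] = d_pos
        frame.positions[hd1_d] = d_pos + np.array([0.0, 0.0, 0.10])  # toward acceptor image
        # keep provenance consistent: moved atoms are stored unwrapped
        if "z_unwrapped" in frame.aux:
            for idx in (od1_a, hd1_a, od1_d, hd1_d):
                frame.aux["z_unwrapped"][idx] = frame.positions[idx][2]
                frame.aux["site_center"][idx] = frame.positions[idx][:2]
        pairs.append((
            (str(frame.chains[od1_d]), int(frame.resids[od1_d])),
            (str(frame.chains[od1_a]), int(frame.resids[od1_a])),
        ))
    return frame, pairs


def ground_truth(spec: FibrilSpec) -> dict:
    """Self-defined ground truth of the generator, for provenance JSON.

    The built end-to-end length is analytic: axially the N-terminal N
    centroid sits at z = 0 and the C-terminal C centroid at (n - 0.35)
    rises; laterally both centroids sit exactly on their segment site
    centres (the terminal taper places terminal backbone atoms on the local
    axis), so L0 is the hypotenuse of the axial span and the first-to-last
    lateral site chord.
    """
    rise = spec.rise_per_residue
    centers = spec.lateral_site_centers()
    axial = (spec.residues_per_chain - 0.35) * rise
    chord = float(np.linalg.norm(centers[-1] - centers[0]))
    return {
        "dband_nm": spec.dband,
        "gap_fraction_D": spec.ideal_gap_fraction_D,
        "monomer_width_nm": float(spec.helix_radius * np.sqrt(3.0)),
        "monomer_extent_nm": spec.monomer_extent,
        "end_to_end_nm": float(np.hypot(axial, chord)),
        "residues_per_chain": spec.residues_per_chain,
        "hydroxyl_fraction": spec.hydroxyl_fraction,
        "seed": spec.seed,
    }
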