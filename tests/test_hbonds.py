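"""Geometric hydrogen-bond detection against a 27-image brute-force oracle."""

import itertools
import warnings

import numpy as np
import pytest

from fibrilmetrics.core import Trajectory
from fibrilmetrics.hbonds import (
    HBondCriterion,
    ResidueHBondProfile,
    assign_donors_acceptors,
    compare_probabilities,
    count_intermonomer,
    detect_hbonds,
    percent_drop,
    protein_water_count,
    residue_probabilities,
)
from fibrilmetrics.pbc import TriclinicCell
from fibrilmetrics.synthetic import plant_boundary_hbonds

from conftest import toy_frame


def make_triplet_frame(n_triplets, cell, rng):
    """Random donor/hydrogen/acceptor triplets, one residue each."""
    centers = rng.uniform(0, 1, size=(n_triplets, 3)) @ cell.matrix
    h_off = rng.normal(size=(n_triplets, 3))
    h_off = 0.10 * h_off / np.linalg.norm(h_off, axis=1, keepdims=True)
    # acceptor kept > 0.12 nm away from the hydrogen so it never reads as a
    # hydroxyl-like donor itself
    a_off = rng.normal(size=(n_triplets, 3))
    a_off = rng.uniform(0.25, 0.5, size=(n_triplets, 1)) * (
        a_off / np.linalg.norm(a_off, axis=1, keepdims=True)
    )
    positions, names, elements, resids = [], [], [], []
    for i in range(n_triplets):
        positions += [centers[i], centers[i] + h_off[i], centers[i] + a_off[i]]
        names += ["N", "H", "O"]
        elements += ["N", "H", "O"]
        resids += [i + 1] * 3
    return toy_frame(positions, names=names, elements=elements, resids=resids,
                     resnames=["GLY"] * (3 * n_triplets), cell=cell)


def brute_force_events(frame, criterion):
    """Independent oracle: every donor-acceptor pair over all 27 images,
    evaluated directly from the criterion definition."""
    donors = np.nonzero(frame.names == "N")[0]
    hydros = np.nonzero(frame.names == "H")[0]
    acceptors = np.nonzero(frame.names == "O")[0]
    h_of = {d: h for d, h in zip(donors, hydros)}
    shifts = np.array(list(itertools.product((-1, 0, 1), repeat=3)))
    found = set()
    for d in donors:
        for a in acceptors:
            if frame.resids[d] == frame.resids[a]:
                continue
            images = frame.positions[a] + shifts @ frame.cell.matrix
            dists = np.linalg.norm(images - frame.positions[d], axis=1)
            k = np.argmin(dists)
            if dists[k] >= criterion.d_max:
                continue
            da = images[k] - frame.positions[d]
            dh = frame.positions[h_of[d]] - frame.positions[d]
            cosang = da @ dh / (np.linalg.norm(da) * np.linalg.norm(dh))
            angle = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            if angle < criterion.theta_max:
                found.add((int(d), int(a), tuple(int(s) for s in shifts[k])))
    return found


class TestCriterion:
    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            HBondCriterion(d_max=-0.1)
        with pytest.raises(ValueError):
            HBondCriterion(theta_max=200)


def collinear_frame(d_da, cell=None):
    """Donor at origin, hydrogen and acceptor collinear along +x."""
    return toy_frame(
        positions=[[1.0, 1, 1], [1.1, 1, 1], [1.0 + d_da, 1, 1]],
        names=["N", "H", "O"],
        elements=["N", "H", "O"],
        resids=[1, 1, 2],
        resnames=["GLY", "GLY", "GLY"],
        cell=cell,
    )


class TestDetect:
    def test_collinear_bond_detected(self):
        events = detect_hbonds(collinear_frame(0.29))
        assert len(events) == 1
        assert events[0].klass == "intra-chain"

    def test_distance_boundary_excluded(self):
        assert detect_hbonds(collinear_frame(0.36)) == []
        # the 0.35 boundary itself is excluded ("smaller than")
        assert detect_hbonds(collinear_frame(0.35)) == []

    def test_angle_threshold_strict(self):
        def angled(theta_deg):
            t = np.radians(theta_deg)
            return toy_frame(
                positions=[[1.0, 1, 1],
                           [1.0 + 0.1 * np.cos(t), 1 + 0.1 * np.sin(t), 1],
                           [1.29, 1, 1]],
                names=["N", "H", "O"],
                elements=["N", "H", "O"],
                resids=[1, 1, 2],
                resnames=["GLY"] * 3,
            )
        assert len(detect_hbonds(angled(29.9))) == 1
        assert detect_hbonds(angled(30.0)) == []
        assert detect_hbonds(angled(30.1)) == []

    def test_same_residue_pairs_excluded(self):
        frame = toy_frame(
            positions=[[1, 1, 1], [1.1, 1, 1], [1.3, 1, 1]],
            names=["N", "H", "O"],
            elements=["N", "H", "O"],
            resids=[1, 1, 1],
            resnames=["GLY"] * 3,
        )
        assert detect_hbonds(frame) == []

    def test_matches_brute_force_oracle(self):
        cell = TriclinicCell([2.8, 0, 0], [1.1, 2.6, 0], [-0.9, 0.8, 3.4])
        rng = np.random.default_rng(17)
        crit = HBondCriterion()
        total = 0
        for rep in range(3):
            frame = make_triplet_frame(500, cell, rng)
            events = detect_hbonds(frame, crit)
            got = {(e.donor, e.acceptor, tuple(e.shift)) for e in events}
            expected = brute_force_events(frame, crit)
            assert got == expected
            total += len(expected)
        assert total > 50  # the suite actually exercises bonds

    def test_cross_boundary_bond_is_intermonomer(self):
        # disconnected fragments (spacer breaks the covalent walk): the raw
        # minimum-image shift across the axial boundary is the class
        cell = TriclinicCell([4, 0, 0], [0, 4, 0], [0, 0, 6.0])
        frame = toy_frame(
            positions=[[1, 1, 5.9], [1, 1, 6.0], [3, 3, 3], [1, 1, 0.2]],
            names=["N", "H", "C", "O"],
            elements=["N", "H", "C", "O"],
            resids=[1, 1, 2, 3],
            resnames=["GLY"] * 4,
            cell=cell,
        )
        events = detect_hbonds(frame)
        assert len(events) == 1
        assert events[0].klass == "inter-monomer"
        assert tuple(events[0].shift) == (0, 0, 1)

    def test_wrapped_covalent_neighbours_not_intermonomer(self, small_frame):
        """Residues straddling the wrap boundary are same-monomer contacts:
        the monomer-relative shift removes the wrapping artifact."""
        from fibrilmetrics.pbc import TriclinicCell as TC

        events = detect_hbonds(small_frame)
        assert all(e.klass != "inter-monomer" or not tuple(e.shift) == (0, 0, 0)
                   for e in events)
        # backbone amide-to-carbonyl contacts across the boundary stay
        # intra-chain even though their raw min-image shift is nonzero
        frac_z = small_frame.cell.fractional(small_frame.positions)[:, 2]
        boundary_events = [
            e for e in events
            if min(frac_z[e.donor], frac_z[e.acceptor]) < 0.05
            and max(frac_z[e.donor], frac_z[e.acceptor]) > 0.95
        ]
        assert boundary_events  # the geometry does produce such contacts
        assert all(e.klass == "intra-chain" for e in boundary_events)


class TestAssign:
    def test_backbone_donor_and_acceptor(self):
        frame = toy_frame(
            positions=[[1, 1, 1], [1.1, 1, 1], [1.2, 1, 1], [1.35, 1, 1],
                       [1.45, 1, 1]],
            names=["N", "H", "CA", "C", "O"],
            elements=["N", "H", "C", "C", "O"],
            resids=[1] * 5,
            resnames=["GLY"] * 5,
        )
        table = assign_donors_acceptors(frame)
        assert list(frame.names[table.donors]) == ["N"]
        assert list(frame.names[table.acceptors]) == ["O"]

    def test_hydroxyl_is_donor_and_acceptor(self):
        frame = toy_frame(
            positions=[[1, 1, 1], [1.1, 1, 1], [1.2, 1, 1], [1.3, 1, 1],
                       [1.4, 1, 1], [1.5, 1, 1], [1.6, 1, 1]],
            names=["N", "H", "CA", "C", "O", "OD1", "HD1"],
            elements=["N", "H", "C", "C", "O", "O", "H"],
            resids=[1] * 7,
            resnames=["HYP"] * 7,
        )
        table = assign_donors_acceptors(frame)
        donor_names = set(frame.names[table.donors])
        acceptor_names = set(frame.names[table.acceptors])
        assert donor_names == {"N", "OD1"}
        assert acceptor_names == {"O", "OD1"}

    def test_donor_count_on_fibril(self, small_frame):
        table = assign_donors_acceptors(small_frame)
        n_backbone = int(np.sum(small_frame.names == "N"))
        k_hydroxyl = int(np.sum(small_frame.names == "OD1"))
        assert len(table.donors) == n_backbone + k_hydroxyl

    def test_nitrogen_without_hydrogen_warns(self):
        frame = toy_frame(
            positions=[[1, 1, 1], [1.4, 1, 1]],
            names=["N", "O"],
            elements=["N", "O"],
            resids=[1, 2],
            resnames=["GLY", "GLY"],
        )
        with pytest.warns(UserWarning, match="without resolvable hydrogen"):
            table = assign_donors_acceptors(frame)
        assert len(table.donors) == 0
        assert table.excluded_donors


class TestCounting:
    def test_no_cross_image_bonds_zero(self, small_frame):
        from fibrilmetrics.io import dehydroxylate
        from fibrilmetrics.synthetic import make_trajectory

        # enlarge the lateral cell so no image contact survives
        iso = small_frame.copy(cell=TriclinicCell([12, 0, 0], [0, 12, 0], [0, 0, 6.7]))
        traj = make_trajectory(iso, 3, noise_sigma=0.0)
        mean, se = count_intermonomer(traj)
        assert (mean, se) == (0.0, 0.0)

    def test_planted_bonds_counted_every_frame(self, small_frame):
        from fibrilmetrics.synthetic import make_trajectory

        base = [e for e in detect_hbonds(small_frame) if e.klass == "inter-monomer"]
        planted, _ = plant_boundary_hbonds(small_frame, 4)
        traj = make_trajectory(planted, 3, noise_sigma=0.0)
        mean, se = count_intermonomer(traj)
        assert mean == len(base) + 4
        assert se == 0.0

    def test_concatenation_invariance(self, small_frame):
        from fibrilmetrics.synthetic import make_trajectory

        planted, _ = plant_boundary_hbonds(small_frame, 2)
        traj = make_trajectory(planted, 3, noise_sigma=0.01, seed=5)
        doubled = Trajectory(traj.frames + [f.copy() for f in traj.frames],
                             np.arange(6, dtype=float))
        m1, _ = count_intermonomer(traj)
        m2, _ = count_intermonomer(doubled)
        assert m1 == pytest.approx(m2)

    def test_single_frame_rejected(self, small_frame):
        with pytest.raises(ValueError):
            count_intermonomer(Trajectory.from_frame(small_frame))


class TestProbabilities:
    def test_always_half_and_never(self, small_frame):
        planted, pairs = plant_boundary_hbonds(small_frame, 2)
        # bond present in exactly half of the frames
        traj = Trajectory([planted, small_frame.copy()], [0.0, 1.0])
        profile = residue_probabilities(traj)
        donor_res = pairs[0][0]
        assert profile.probabilities[donor_res] == pytest.approx(0.5)
        always = Trajectory([planted, planted.copy()], [0.0, 1.0])
        assert residue_probabilities(always).probabilities[donor_res] == 1.0
        # an uninvolved residue has p = 0 but is present in the profile
        quiet = [k for k, p in profile.probabilities.items() if p == 0.0]
        assert quiet

    def test_profile_covers_all_protein_residues(self, small_frame, small_spec):
        profile = residue_probabilities(
            Trajectory([small_frame, small_frame.copy()], [0.0, 1.0])
        )
        assert len(profile.probabilities) == 3 * small_spec.residues_per_chain


class TestProteinWater:
    def test_no_water_warns_zero(self, small_frame):
        traj = Trajectory([small_frame, small_frame.copy()], [0.0, 1.0])
        with pytest.warns(UserWarning, match="no water"):
            assert protein_water_count(traj) == (0.0, 0.0)

    def water_frame(self, order=("OW", "HW1", "HW2")):
        """One backbone carbonyl plus one water donating to it."""
        water_pos = {"OW": [1.3, 1, 1], "HW1": [1.2, 1, 1], "HW2": [1.35, 1.09, 1]}
        positions = [[1.0, 1, 1]] + [water_pos[n] for n in order]
        return toy_frame(
            positions=positions,
            names=["O"] + list(order),
            elements=["O"] + [n[0] for n in order],
            resids=[1] + [2] * 3,
            resnames=["GLY"] + ["SOL"] * 3,
        )

    def test_one_planted_protein_water_bond(self):
        frame = self.water_frame()
        traj = Trajectory([frame, frame.copy()], [0.0, 1.0])
        mean, se = protein_water_count(traj)
        assert (mean, se) == (1.0, 0.0)

    def test_water_order_invariance(self):
        a = self.water_frame(("OW", "HW1", "HW2"))
        b = self.water_frame(("OW", "HW2", "HW1"))
        ta = Trajectory([a, a.copy()], [0.0, 1.0])
        tb = Trajectory([b, b.copy()], [0.0, 1.0])
        assert protein_water_count(ta) == protein_water_count(tb)


class TestCompare:
    def test_identical_profiles(self):
        p = ResidueHBondProfile({("A", 1): 0.2, ("A", 2): 0.8, ("A", 3): 0.5})
        cmp = compare_probabilities(p, ResidueHBondProfile(dict(p.probabilities)))
        assert cmp.n_decreased == 0 and cmp.n_increased == 0
        assert cmp.pearson_r == pytest.approx(1.0)
        assert all(d == 0 for d in cmp.delta.values())

    def test_hand_computed_example(self):
        keys = [("A", 1), ("A", 2), ("A", 3), ("A", 4)]
        pa = ResidueHBondProfile(dict(zip(keys, [0.1, 0.9, 0.5, 0.2])))
        pb = ResidueHBondProfile({k: 1.0 - v for k, v in pa.probabilities.items()})
        cmp = compare_probabilities(pa, pb)
        deltas = [cmp.delta[k] for k in keys]
        assert deltas == pytest.approx([0.8, -0.8, 0.0, 0.6])
        assert (cmp.n_decreased, cmp.n_increased) == (1, 2)
        assert cmp.pearson_r == pytest.approx(-1.0)

    def test_constant_profile_nan_with_warning(self):
        pa = ResidueHBondProfile({("A", 1): 0.5, ("A", 2): 0.5})
        pb = ResidueHBondProfile({("A", 1): 0.1, ("A", 2): 0.9})
        with pytest.warns(UserWarning, match="constant"):
            cmp = compare_probabilities(pa, pb)
        assert np.isnan(cmp.pearson_r)

    def test_residue_set_mismatch_listed(self):
        pa = ResidueHBondProfile({("A", 1): 0.5})
        pb = ResidueHBondProfile({("A", 2): 0.5})
        with pytest.raises(ValueError, match="A:1"):
            compare_probabilities(pa, pb)


def test_percent_drop():
    assert percent_drop(200.0, 150.0) == pytest.approx(25.0)
    with pytest.raises(ValueError):
        percent_drop(0.0, 1.0)
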