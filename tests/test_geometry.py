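import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from membind import geometry
from membind.core import AnalysisConfig, Frame, MembindError, TrajectoryEnsemble
from membind.synthetic import (
    SyntheticSpec,
    build_hairpin,
    build_peptide,
    generate_binding_ensemble,
    place_at_distance,
)
from conftest import make_point_system


def brute_min_image(p, q, box):
    """27-periodic-image oracle."""
    best = np.inf
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                shift = np.array([dx, dy, dz]) * box
                best = min(best, np.linalg.norm(q + shift - p))
    return best


class TestMinImage:
    def test_zero_for_identical(self):
        box = np.array([6.0, 6.0, 6.0])
        assert geometry.min_image_distance([1, 2, 3], [1, 2, 3], box) == 0.0

    def test_wrap_example(self):
        box = np.array([6.0, 6.0, 6.0])
        d = geometry.min_image_distance([0, 0, 0], [0, 0, 5.4], box)
        assert d == pytest.approx(0.6, abs=1e-12)

    def test_matches_27_image_oracle(self):
        rng = np.random.default_rng(42)
        box = np.array([4.0, 5.0, 6.0])
        for _ in range(200):
            p = rng.uniform(0, 1, 3) * box
            q = rng.uniform(0, 1, 3) * box
            assert geometry.min_image_distance(p, q, box) == pytest.approx(
                brute_min_image(p, q, box), abs=1e-12
            )

    @given(
        st.lists(st.floats(-10, 10), min_size=6, max_size=6),
        st.lists(st.floats(0.5, 8.0), min_size=3, max_size=3),
    )
    @settings(max_examples=50, deadline=None)
    def test_never_exceeds_half_diagonal(self, pq, box):
        p, q = np.array(pq[:3]), np.array(pq[3:])
        box = np.array(box)
        d = geometry.min_image_distance(p, q, box)
        assert d <= np.linalg.norm(box / 2) + 1e-9


class TestCenterOfMass:
    def test_equal_masses(self):
        com = geometry.center_of_mass(
            np.array([[0.0, 0, 0], [0, 0, 2.0]]), np.array([1.0, 1.0])
        )
        assert com[2] == pytest.approx(1.0)

    def test_weighted(self):
        com = geometry.center_of_mass(
            np.array([[0.0, 0, 0], [0, 0, 4.0]]), np.array([1.0, 3.0])
        )
        assert com[2] == pytest.approx(3.0)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(5, 3))
        masses = rng.uniform(1, 10, 5)
        shift = np.array([1.0, -2.0, 0.5])
        c0 = geometry.center_of_mass(coords, masses)
        c1 = geometry.center_of_mass(coords + shift, masses)
        assert np.allclose(c1 - c0, shift)

    def test_empty_raises(self):
        with pytest.raises(MembindError):
            geometry.center_of_mass(np.empty((0, 3)), np.empty(0))


@pytest.fixture(scope="module")
def traj():
    spec = SyntheticSpec(seed=2, n_frames=2, model_template="unbound",
                         n_waters=0)
    return generate_binding_ensemble(spec)[0]


class TestPeptideBilayerDistance:

    def test_planted_distance(self, traj):
        frame = place_at_distance(traj, 0, 3.2)
        d = geometry.peptide_bilayer_distance(traj.topology, frame)
        assert d == pytest.approx(3.2, abs=1e-6)

    def test_initial_placement_five_01(self, traj):
        frame = place_at_distance(traj, 0, 5.01)
        d = geometry.peptide_bilayer_distance(traj.topology, frame)
        assert d == pytest.approx(5.01, abs=1e-6)

    def test_zero_when_coms_coincide(self, traj):
        frame = place_at_distance(traj, 0, 0.0)
        d = geometry.peptide_bilayer_distance(traj.topology, frame)
        assert d == pytest.approx(0.0, abs=1e-9)


class TestResidueDepths:
    def test_sign_convention(self, config):
        # single-residue "peptide" above a fake bilayer COM
        system = make_point_system(
            [[0, 0, 4.5], [0, 0, 2.0]],
            groups=["peptide", "lipid_POPC"],
            residues=[1, 41],
        )
        frame = Frame(np.array([[0, 0, 4.5], [0, 0, 2.0]]),
                      box=np.array([10.0, 10.0, 10.0]))
        prof = geometry.residue_depths(system, frame, config)
        assert prof.depths[0] == pytest.approx(0.5)

    def test_buried_negative(self, config):
        system = make_point_system(
            [[0, 0, 3.5], [0, 0, 2.0]],
            groups=["peptide", "lipid_POPC"],
            residues=[1, 41],
        )
        frame = Frame(np.array([[0, 0, 3.5], [0, 0, 2.0]]),
                      box=np.array([10.0, 10.0, 10.0]))
        prof = geometry.residue_depths(system, frame, config)
        assert prof.depths[0] == pytest.approx(-0.5)

    def test_identity_with_half_thickness(self, config):
        spec = SyntheticSpec(seed=3, n_frames=1, model_template="model4")
        traj, _ = generate_binding_ensemble(spec)
        frame = traj.frames[0]
        prof = geometry.residue_depths(traj.topology, frame, config)
        z_bil = geometry.group_com(
            traj.topology, frame, np.flatnonzero(traj.topology.bilayer_mask)
        )[2]
        for resid, depth in zip(prof.residue_ids, prof.depths):
            idx = traj.topology.peptide_residue_atoms(int(resid))
            z_res = geometry.group_com(traj.topology, frame, idx)[2]
            assert depth + config.half_thickness == pytest.approx(
                abs(z_res - z_bil), abs=1e-12
            )

    def test_planted_model3_ct_buried(self, config):
        spec = SyntheticSpec(seed=5, n_frames=3, model_template="model3")
        traj, _ = generate_binding_ensemble(spec)
        prof = geometry.residue_depths(traj.topology, traj.frames[0], config)
        ct = [
            d for r, d in zip(prof.residue_ids, prof.depths)
            if traj.topology.region_of(int(r)) == "CT"
        ]
        assert np.mean(np.array(ct) < 0) >= 0.5


def _two_group_frame(pos_a, pos_b, box):
    n_a, n_b = len(pos_a), len(pos_b)
    system = make_point_system(
        list(pos_a) + list(pos_b),
        groups=["peptide"] * n_a + ["lipid_POPC"] * n_b,
        residues=[1] * n_a + [41] * n_b,
    )
    frame = Frame(np.vstack([pos_a, pos_b]), box=np.asarray(box, dtype=float))
    return system, frame


class TestCountContacts:
    def test_below_cutoff(self, config):
        system, frame = _two_group_frame(
            [[0, 0, 0]], [[0, 0, 0.49]], [10, 10, 10]
        )
        assert geometry.count_contacts(system, frame, config).n_contacts == 1

    def test_above_cutoff(self, config):
        system, frame = _two_group_frame(
            [[0, 0, 0]], [[0, 0, 0.51]], [10, 10, 10]
        )
        assert geometry.count_contacts(system, frame, config).n_contacts == 0

    def test_cutoff_closed(self, config):
        system, frame = _two_group_frame(
            [[0, 0, 0]], [[0, 0, 0.5]], [10, 10, 10]
        )
        assert geometry.count_contacts(system, frame, config).n_contacts == 1

    def test_hydrogens_excluded(self, config):
        system = make_point_system(
            [[0, 0, 0], [0, 0, 0.2]],
            groups=["peptide", "lipid_POPC"],
            residues=[1, 41],
            elements=["H", "C"],
        )
        frame = Frame(np.array([[0.0, 0, 0], [0, 0, 0.2]]),
                      box=np.array([10.0, 10.0, 10.0]))
        assert geometry.count_contacts(system, frame, config).n_contacts == 0

    def test_symmetry(self, config):
        rng = np.random.default_rng(1)
        system, frame = _two_group_frame(
            rng.uniform(0, 3, (40, 3)), rng.uniform(0, 3, (40, 3)), [3, 3, 3]
        )
        a = system.peptide_heavy_indices
        b = system.bilayer_heavy_indices
        ab = geometry.count_contacts(system, frame, config, a, b).n_contacts
        ba = geometry.count_contacts(system, frame, config, b, a).n_contacts
        assert ab == ba

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(2)
        system, frame = _two_group_frame(
            rng.uniform(0, 4, (50, 3)), rng.uniform(0, 4, (50, 3)), [4, 4, 4]
        )
        counts = [
            geometry.count_contacts(
                system, frame, AnalysisConfig(contact_cutoff=c)
            ).n_contacts
            for c in (0.3, 0.5, 0.8, 1.2)
        ]
        assert counts == sorted(counts)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_cell_list_equals_brute_force(self, config, seed):
        rng = np.random.default_rng(seed)
        box = np.array([3.0, 3.5, 4.0])
        pos_a = rng.uniform(-1, 5, (60, 3))
        pos_b = rng.uniform(-1, 5, (60, 3))
        system, frame = _two_group_frame(pos_a, pos_b, box)
        fast = geometry.count_contacts(system, frame, config).n_contacts
        slow = geometry.brute_force_contacts(system, frame, config)
        # independent O(N^2) oracle
        d = np.linalg.norm(
            geometry.min_image_displacement(
                pos_a[:, None, :], pos_b[None, :, :], box
            ),
            axis=-1,
        )
        oracle = int((d <= config.contact_cutoff).sum())
        assert fast == slow == oracle


class TestContactFractions:
    def test_quarter(self, config):
        pos_far = [[0, 0, 3.0]]
        pos_near = [[0, 0, 0.4]]
        frames = []
        system = make_point_system(
            [[0, 0, 0], [0, 0, 0]],
            groups=["peptide", "lipid_POPC"], residues=[1, 41],
        )
        for pa in (pos_near, pos_far, pos_far, pos_far):
            frames.append(
                Frame(np.array([pa[0], [0.0, 0, 0]]),
                      box=np.array([10.0, 10, 10]))
            )
        traj = TrajectoryEnsemble(topology=system, frames=frames)
        _, fractions, mean = geometry.contact_fractions(traj, config)
        assert fractions[0] == pytest.approx(0.25)
        assert mean == pytest.approx(0.25)

    def test_planted_persistent_contact(self, config):
        spec = SyntheticSpec(seed=8, n_frames=5, model_template="model3")
        traj, _ = generate_binding_ensemble(spec)
        resids, fractions, _ = geometry.contact_fractions(traj, config)
        by_res = dict(zip(resids.astype(int), fractions))
        # the planted CT tail touches the bilayer in every frame
        assert max(by_res[r] for r in range(30, 41)) == pytest.approx(1.0)


class TestResidueContactMap:
    @pytest.fixture(scope="class")
    def big_frame_box(self):
        return np.array([50.0, 50.0, 50.0])

    def test_extended_chain_band(self, config, big_frame_box):
        from membind.core import build_system

        bp = build_peptide("A" * 12, ss_template="strand")
        system = build_system(bp.records)
        traj = TrajectoryEnsemble(
            topology=system,
            frames=[Frame(bp.coordinates, box=big_frame_box)],
        )
        m = geometry.residue_contact_map(traj, config)
        off = [m[i, j] for i in range(12) for j in range(12) if abs(i - j) > 2]
        near = [m[i, i + 1] for i in range(11)]
        assert min(near) == 1.0
        assert max(off) == 0.0

    def test_hairpin_antidiagonal(self, config, big_frame_box):
        from membind.core import build_system

        bp = build_hairpin("A" * 20, (2, 9), (12, 19))
        system = build_system(bp.records)
        traj = TrajectoryEnsemble(
            topology=system,
            frames=[Frame(bp.coordinates, box=big_frame_box)],
        )
        m = geometry.residue_contact_map(traj, config)
        anti = [m[i - 1, 20 - i] for i in range(2, 10)]
        assert min(anti) == 1.0

    def test_symmetric_unit_diagonal(self, config, big_frame_box):
        from membind.core import build_system

        bp = build_peptide("A" * 10, ss_template="coil", seed=3)
        system = build_system(bp.records)
        traj = TrajectoryEnsemble(
            topology=system,
            frames=[Frame(bp.coordinates, box=big_frame_box)],
        )
        m = geometry.residue_contact_map(traj, config)
        assert np.array_equal(m, m.T)
        assert np.all(np.diag(m) == 1.0)


class TestTopLongrangePairs:
    def test_planted_pair_ranks_first(self, config):
        m = np.zeros((40, 40))
        m[1, 29] = m[29, 1] = 0.9
        m[0, 1] = m[1, 0] = 0.99  # short range, excluded
        pairs = geometry.top_longrange_pairs(m, 3, config)
        assert pairs[0][:2] == (2, 30)

    def test_min_separation_excludes(self, config):
        m = np.zeros((10, 10))
        m[0, 2] = m[2, 0] = 1.0  # |i-j| = 2 < 3
        pairs = geometry.top_longrange_pairs(m, 5, config)
        assert all(p[2] == 0.0 for p in pairs)

    def test_ties_lexicographic_and_k_capped(self, config):
        m = np.full((6, 6), 0.5)
        pairs = geometry.top_longrange_pairs(m, 100, config)
        expected = [
            (i + 1, j + 1) for i in range(6) for j in range(i + 3, 6)
        ]
        assert [p[:2] for p in pairs] == expected


class TestKabschRmsd:
    def test_identical_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(8, 3))
        assert geometry.kabsch_rmsd(x, x) <= 1e-10

    def test_rigid_motion_zero(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(10, 3))
        rot = Rotation.from_euler("xyz", [90, 30, -45], degrees=True)
        y = rot.apply(x) + np.array([1.0, -2.0, 3.0])
        assert geometry.kabsch_rmsd(x, y) <= 1e-9

    def test_invariant_under_proper_motion_of_either(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(7, 3))
        y = x + rng.normal(scale=0.1, size=(7, 3))
        base = geometry.kabsch_rmsd(x, y)
        for seed in range(5):
            rot = Rotation.random(rng=np.random.default_rng(seed))
            moved = rot.apply(y) + rng.normal(size=3)
            assert geometry.kabsch_rmsd(x, moved) == pytest.approx(
                base, abs=1e-9
            )

    def test_matches_rotation_grid_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(10, 3))
        y = x.copy()
        y[0] += np.array([0.3, -0.2, 0.1])  # one displaced atom
        rot = Rotation.from_euler("zyx", [25, -40, 60], degrees=True)
        y = rot.apply(y) + np.array([0.5, 0.5, -1.0])
        got = geometry.kabsch_rmsd(x, y)
        oracle = _grid_rmsd_oracle(x, y)
        assert got == pytest.approx(oracle, abs=1e-3)
        assert got <= oracle + 1e-9  # closed form is the true minimum

    def test_count_mismatch_raises(self):
        with pytest.raises(MembindError):
            geometry.kabsch_rmsd(np.zeros((4, 3)), np.zeros((5, 3)))

    def test_collinear_rejected(self):
        line = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(MembindError):
            geometry.kabsch_rmsd(line, line)


def _grid_rmsd_oracle(x, y):
    """Brute-force minimum RMSD over rotations: coarse Euler grid followed
    by Nelder-Mead refinement.  Independent of the closed-form path."""
    from scipy.optimize import minimize

    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)

    def rmsd_for(angles):
        rot = Rotation.from_euler("zyx", angles)
        diff = rot.apply(yc) - xc
        return float(np.sqrt((diff ** 2).sum() / len(xc)))

    best, best_angles = np.inf, None
    grid = np.deg2rad(np.arange(0, 360, 30))
    half = np.deg2rad(np.arange(-90, 91, 30))
    for a in grid:
        for b in half:
            for c in grid:
                v = rmsd_for([a, b, c])
                if v < best:
                    best, best_angles = v, [a, b, c]
    res = minimize(rmsd_for, best_angles, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000})
    return min(best, float(res.fun))
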