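import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_slice, random_rigid_transform
from mabdyn import geometry
from mabdyn.core_io import Topology
from mabdyn.synthetic_data import ToyAntibodySpec, make_toy_antibody


def transformed(traj, rot, trans):
    return traj.coordinates @ rot.T + trans


class TestFcFrame:
    def test_constructed_orthogonal_layout(self, toy_system):
        _, ann, traj = toy_system
        frame = geometry.build_fc_frame(traj.coordinates[0], traj.topology, ann)
        np.testing.assert_allclose(frame.origin, [0, 0, 0], atol=1e-12)
        np.testing.assert_allclose(frame.z, [0, 0, 1], atol=1e-12)
        np.testing.assert_allclose(frame.x, [1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(frame.y, [0, 1, 0], atol=1e-12)

    def test_axes_rotate_with_system(self, toy_system, rng):
        _, ann, traj = toy_system
        rot, trans = random_rigid_transform(rng)
        f0 = geometry.build_fc_frame(traj.coordinates[0], traj.topology, ann)
        f1 = geometry.build_fc_frame(traj.coordinates[0] @ rot.T + trans, traj.topology, ann)
        for ax in ("x", "y", "z"):
            np.testing.assert_allclose(getattr(f1, ax), rot @ getattr(f0, ax), atol=1e-9)

    def test_orthonormality_sweep(self, rng):
        for _ in range(100):
            spec = ToyAntibodySpec(
                theta1=float(rng.uniform(20, 160)),
                theta2=float(rng.uniform(20, 160)),
                phi1=float(rng.uniform(-179, 179)),
                phi2=float(rng.uniform(-179, 179)),
                n_frames=1,
                noise_sigma=0.2,
                seed=int(rng.integers(1 << 31)),
            )
            ann, traj = make_toy_antibody(spec)
            f = geometry.build_fc_frame(traj.coordinates[0], traj.topology, ann)
            assert abs(np.dot(f.x, f.z)) < 1e-10
            assert abs(np.dot(f.y, f.z)) < 1e-10
            assert abs(np.dot(f.x, f.y)) < 1e-10
            assert np.linalg.det(np.stack([f.x, f.y, f.z])) == pytest.approx(1.0)


class TestSphericalAngles:
    def test_construction_inverse_exact(self):
        spec = ToyAntibodySpec(theta1=70.0, theta2=70.0, phi1=25.0, phi2=-130.0, n_frames=5)
        ann, traj = make_toy_antibody(spec)
        for f in range(traj.n_frames):
            a = geometry.fab_spherical_angles(traj.coordinates[f], traj.topology, ann)
            assert a["theta1"] == pytest.approx(70.0, abs=1e-6)
            assert a["theta2"] == pytest.approx(70.0, abs=1e-6)
            assert a["phi1"] == pytest.approx(25.0, abs=1e-6)
            assert a["phi2"] == pytest.approx(-130.0, abs=1e-6)

    def test_t_shape_scenario_recovered(self):
        # one arm near the equator-crossing regime, the other below it
        spec = ToyAntibodySpec(theta1=95.0, theta2=70.0, n_frames=3)
        ann, traj = make_toy_antibody(spec)
        a = geometry.fab_spherical_angles(traj.coordinates[0], traj.topology, ann)
        assert a["theta1"] == pytest.approx(95.0, abs=1e-6)
        assert a["theta2"] == pytest.approx(70.0, abs=1e-6)

    def test_pole_reports_zero_phi_with_flag(self):
        spec = ToyAntibodySpec(theta1=0.0, theta2=70.0, n_frames=1)
        ann, traj = make_toy_antibody(spec)
        a = geometry.fab_spherical_angles(traj.coordinates[0], traj.topology, ann)
        assert a["theta1"] == pytest.approx(0.0, abs=1e-6)
        assert a["phi1"] == 0.0
        assert a["phi1_at_pole"] is True
        assert a["phi2_at_pole"] is False

    def test_equator_case(self):
        spec = ToyAntibodySpec(theta1=90.0, theta2=90.0, phi1=0.0, phi2=90.0, n_frames=1)
        ann, traj = make_toy_antibody(spec)
        a = geometry.fab_spherical_angles(traj.coordinates[0], traj.topology, ann)
        assert a["theta1"] == pytest.approx(90.0, abs=1e-6)
        assert a["phi1"] == pytest.approx(0.0, abs=1e-6)
        assert a["phi2"] == pytest.approx(90.0, abs=1e-6)

    def test_rigid_invariance(self, toy_system, rng):
        _, ann, traj = toy_system
        ref = geometry.fab_spherical_angles(traj.coordinates[0], traj.topology, ann)
        for _ in range(5):
            rot, trans = random_rigid_transform(rng)
            moved = traj.coordinates[0] @ rot.T + trans
            got = geometry.fab_spherical_angles(moved, traj.topology, ann)
            for key in ("theta1", "theta2", "phi1", "phi2"):
                assert got[key] == pytest.approx(ref[key], abs=1e-6)


class TestClassifyShape:
    @pytest.mark.parametrize(
        "t1,t2,expected",
        [(70.0, 70.0, "Y"), (95.0, 70.0, "T"), (90.0, 10.0, "T"), (89.999, 89.999, "Y")],
    )
    def test_examples(self, t1, t2, expected):
        assert geometry.classify_shape(t1, t2) == expected

    def test_boundary_flip_at_90(self):
        labels = [geometry.classify_shape(t, 70.0) for t in np.arange(0.0, 181.0)]
        flips = [i for i in range(1, len(labels)) if labels[i] != labels[i - 1]]
        assert flips == [90]

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            geometry.classify_shape(-1.0, 50.0)

    @given(st.floats(0, 180), st.floats(0, 180))
    def test_rule_property(self, t1, t2):
        label = geometry.classify_shape(t1, t2)
        assert label == ("Y" if t1 < 90 and t2 < 90 else "T")


class TestDeltaPhi:
    def test_constant_series(self):
        out = geometry.delta_phi(np.full(10, 42.0))
        np.testing.assert_array_equal(out, np.zeros(10))

    def test_simple_arithmetic(self):
        out = geometry.delta_phi(np.array([10.0, -60.0]), unwrap=False)
        assert out[1] == pytest.approx(-70.0)

    def test_continuous_rotation_through_seam(self):
        # continuous +300-degree rotation crossing the +-180 seam
        true_track = np.linspace(100.0, 400.0, 61)
        wrapped = (true_track + 180.0) % 360.0 - 180.0
        out = geometry.delta_phi(wrapped, unwrap=True)
        np.testing.assert_allclose(out, true_track - true_track[0], atol=1e-9)
        assert out[-1] == pytest.approx(300.0)

    def test_raw_mode_stays_wrapped(self):
        wrapped = (np.linspace(0.0, 300.0, 31) + 180.0) % 360.0 - 180.0
        out = geometry.delta_phi(wrapped, unwrap=False)
        assert np.all(out > -180.0) and np.all(out <= 180.0)

    def test_empty_series(self):
        with pytest.raises(ValueError):
            geometry.delta_phi(np.array([]))


def _three_point_top():
    return Topology(
        atom_names=np.asarray(["CA", "SG", "CA"], dtype=object),
        resids=np.asarray([34, 228, 34], dtype=np.int64),
        resnames=np.asarray(["VAL", "CYS", "VAL"], dtype=object),
        chain_ids=np.asarray(["C", "C", "D"], dtype=object),
        elements=np.asarray(["C", "S", "C"], dtype=object),
    )


def _three_point_ann():
    from mabdyn.core_io import AnnotatedSystem

    return AnnotatedSystem(
        chain_map={"LC1": "A", "LC2": "B", "HC1": "C", "HC2": "D"},
        domain_ranges={},
        anchors={
            "fab1_apex": {"chain": "HC1", "resid": 34, "atom": "CA"},
            "fab2_apex": {"chain": "HC2", "resid": 34, "atom": "CA"},
            "hinge_pivot": {"chain": "HC1", "resid": 228, "atom": "SG"},
        },
    )


class TestInterFabAngle:
    def test_collinear(self):
        top, ann = _three_point_top(), _three_point_ann()
        xyz = np.array([[-1.0, 0, 0], [0, 0, 0], [1.0, 0, 0]])
        assert geometry.inter_fab_angle(xyz, top, ann) == pytest.approx(180.0)

    def test_right_angle(self):
        top, ann = _three_point_top(), _three_point_ann()
        xyz = np.array([[1.0, 0, 0], [0, 0, 0], [0, 1.0, 0]])
        assert geometry.inter_fab_angle(xyz, top, ann) == pytest.approx(90.0)

    def test_against_dot_product_oracle(self, rng):
        top, ann = _three_point_top(), _three_point_ann()
        for _ in range(1000):
            xyz = rng.uniform(-10, 10, size=(3, 3))
            a, v, b = xyz
            if min(np.linalg.norm(a - v), np.linalg.norm(b - v)) < 1e-3:
                continue
            u1 = (a - v) / np.linalg.norm(a - v)
            u2 = (b - v) / np.linalg.norm(b - v)
            oracle = np.degrees(np.arccos(np.clip(np.dot(u1, u2), -1, 1)))
            assert geometry.inter_fab_angle(xyz, top, ann) == pytest.approx(oracle, abs=1e-9)

    def test_coincident_anchors(self):
        top, ann = _three_point_top(), _three_point_ann()
        xyz = np.zeros((3, 3))
        with pytest.raises(ValueError, match="coincident"):
            geometry.inter_fab_angle(xyz, top, ann)

    def test_toy_antibody_matches_analytic(self):
        spec = ToyAntibodySpec(theta1=70.0, theta2=70.0, phi1=30.0, phi2=150.0, n_frames=1)
        ann, traj = make_toy_antibody(spec)
        got = geometry.inter_fab_angle(traj.coordinates[0], traj.topology, ann)
        u1 = np.array([np.sin(np.radians(70)) * np.cos(np.radians(30)),
                       np.sin(np.radians(70)) * np.sin(np.radians(30)), np.cos(np.radians(70))])
        u2 = np.array([np.sin(np.radians(70)) * np.cos(np.radians(150)),
                       np.sin(np.radians(70)) * np.sin(np.radians(150)), np.cos(np.radians(70))])
        expected = np.degrees(np.arccos(np.dot(u1, u2)))
        assert got == pytest.approx(expected, abs=1e-9)


class TestCh2Distance:
    def test_toy_construction(self, toy_system):
        _, ann, traj = toy_system
        # site residues are mirror images across x; centroid separation is 10
        assert geometry.ch2_distance(traj.coordinates[0], traj.topology, ann) == pytest.approx(10.0)

    def test_matches_euclidean_oracle(self, toy_system, rng):
        _, ann, traj = toy_system
        top = traj.topology
        xyz = traj.coordinates[0].copy()
        for _ in range(20):
            xyz = xyz + rng.uniform(-5, 5, size=xyz.shape)
            i1 = ann.anchor_residue_atoms(top, "fc_glyco_site_1")
            i2 = ann.anchor_residue_atoms(top, "fc_glyco_site_2")
            oracle = np.linalg.norm(xyz[i1].mean(axis=0) - xyz[i2].mean(axis=0))
            assert geometry.ch2_distance(xyz, top, ann) == pytest.approx(oracle, abs=1e-12)

    def test_degenerate_zero(self, toy_system):
        _, ann, traj = toy_system
        top = traj.topology
        xyz = traj.coordinates[0].copy()
        i1 = ann.anchor_residue_atoms(top, "fc_glyco_site_1")
        i2 = ann.anchor_residue_atoms(top, "fc_glyco_site_2")
        xyz[i2] = xyz[i1]
        assert geometry.ch2_distance(xyz, top, ann) == pytest.approx(0.0)


class TestGlycanDistance:
    def test_min_atom_construction(self, toy_system, rng):
        _, ann, traj = toy_system
        top = traj.topology
        xyz = traj.coordinates[0].copy()
        g1 = ann.glycan_atoms(top, "fc_glycan_1")
        g2 = ann.glycan_atoms(top, "fc_glycan_2")
        # place the closest atom pair at exactly 3.0 A
        xyz[g1] = rng.uniform(20, 30, size=(len(g1), 3))
        xyz[g2] = rng.uniform(-30, -20, size=(len(g2), 3))
        xyz[g1[0]] = [0.0, 0.0, 0.0]
        xyz[g2[0]] = [3.0, 0.0, 0.0]
        got = geometry.glycan_min_distance(xyz, top, ann, mode="min-heavy-atom")
        assert got == pytest.approx(3.0)

    def test_modes_match_brute_force(self, toy_system, rng):
        _, ann, traj = toy_system
        top = traj.topology
        g1 = ann.glycan_atoms(top, "fc_glycan_1")
        g2 = ann.glycan_atoms(top, "fc_glycan_2")
        for _ in range(25):
            xyz = traj.coordinates[0].copy()
            xyz[g1] = rng.uniform(-15, 15, size=(len(g1), 3))
            xyz[g2] = rng.uniform(-15, 15, size=(len(g2), 3))
            brute_min = min(
                np.linalg.norm(xyz[i] - xyz[j]) for i in g1 for j in g2
            )
            brute_com = np.linalg.norm(xyz[g1].mean(axis=0) - xyz[g2].mean(axis=0))
            got_min = geometry.glycan_min_distance(xyz, top, ann, mode="min-heavy-atom")
            got_com = geometry.glycan_min_distance(xyz, top, ann, mode="center-of-mass")
            assert got_min == pytest.approx(brute_min, abs=1e-12)
            assert got_com == pytest.approx(brute_com, abs=1e-12)

    def test_min_atom_below_com_for_compact_chains(self, toy_system):
        # holds for non-interpenetrating compact chains such as the toy
        # glycans (not for arbitrary overlapping point clouds)
        _, ann, traj = toy_system
        for f in range(traj.n_frames):
            got_min = geometry.glycan_min_distance(
                traj.coordinates[f], traj.topology, ann, mode="min-heavy-atom"
            )
            got_com = geometry.glycan_min_distance(
                traj.coordinates[f], traj.topology, ann, mode="center-of-mass"
            )
            assert got_min <= got_com + 1e-12


class TestDescriptorTable:
    def test_all_columns_present(self, toy_system):
        _, ann, traj = toy_system
        df = geometry.compute_descriptors(traj, ann)
        for col in ("frame", "theta1", "theta2", "phi1", "phi2", "dphi1", "dphi2",
                    "inter_fab_angle", "ch2_distance", "glycan_min_distance", "shape_label"):
            assert col in df.columns
        assert len(df) == traj.n_frames
        assert set(df["shape_label"]) == {"Y"}

    def test_rigid_invariance_whole_table(self, toy_system, rng):
        _, ann, traj = toy_system
        ref = geometry.compute_descriptors(traj, ann)
        rot, trans = random_rigid_transform(rng)
        moved = make_slice(traj.topology, traj.coordinates @ rot.T + trans)
        got = geometry.compute_descriptors(moved, ann)
        for col in ("theta1", "theta2", "phi1", "phi2", "inter_fab_angle",
                    "ch2_distance", "glycan_min_distance"):
            np.testing.assert_allclose(got[col], ref[col], atol=1e-6)
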