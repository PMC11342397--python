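import numpy as np
import pytest

from conftest import make_slice
from mabdyn import interactions as ia
from mabdyn.core_io import Topology
from mabdyn.synthetic_data import (
    antiparallel_sheet,
    hbond_triad,
    ideal_helix,
    single_sphere,
    two_spheres,
)


def _cloud_top(n, element="C", resname="LIG"):
    return Topology(
        atom_names=np.asarray([f"C{i}" for i in range(n)], dtype=object),
        resids=np.arange(1, n + 1),
        resnames=np.asarray([resname] * n, dtype=object),
        chain_ids=np.asarray(["A"] * n, dtype=object),
        elements=np.asarray([element] * n, dtype=object),
    )


class TestContacts:
    def _pair_traj(self, distance):
        top = _cloud_top(2)
        xyz = np.array([[[0.0, 0, 0], [distance, 0, 0]]])
        return make_slice(top, xyz)

    def test_pair_inside_cutoff(self):
        counts = ia.count_contacts(self._pair_traj(3.9), np.array([0]), np.array([1]))
        np.testing.assert_array_equal(counts, [1])

    def test_pair_outside_cutoff(self):
        counts = ia.count_contacts(self._pair_traj(4.1), np.array([0]), np.array([1]))
        np.testing.assert_array_equal(counts, [0])

    def test_brute_force_oracle(self, rng):
        top = _cloud_top(40)
        xyz = rng.uniform(0, 15, size=(3, 40, 3))
        traj = make_slice(top, xyz)
        a, b = np.arange(20), np.arange(20, 40)
        counts = ia.count_contacts(traj, a, b, cutoff=4.0)
        for f in range(3):
            brute = sum(
                1 for i in a for j in b if np.linalg.norm(xyz[f, i] - xyz[f, j]) < 4.0
            )
            assert counts[f] == brute

    def test_symmetric_in_group_order(self, rng):
        top = _cloud_top(20)
        traj = make_slice(top, rng.uniform(0, 10, size=(2, 20, 3)))
        a, b = np.arange(10), np.arange(10, 20)
        np.testing.assert_array_equal(
            ia.count_contacts(traj, a, b), ia.count_contacts(traj, b, a)
        )

    def test_empty_group_rejected(self):
        traj = self._pair_traj(3.0)
        with pytest.raises(ValueError, match="non-empty"):
            ia.count_contacts(traj, np.array([], dtype=int), np.array([1]))

    def test_overlapping_groups_rejected(self):
        traj = self._pair_traj(3.0)
        with pytest.raises(ValueError, match="disjoint"):
            ia.count_contacts(traj, np.array([0, 1]), np.array([1]))


class TestHydrogenBonds:
    def test_ideal_triad_every_frame(self):
        top, xyz = hbond_triad(1.8, 180.0)
        traj = make_slice(top, np.stack([xyz] * 10))
        records = ia.hydrogen_bonds(traj)
        assert len(records) == 1
        assert records[0].frequency == 1.0
        assert (records[0].donor, records[0].hydrogen, records[0].acceptor) == (0, 1, 2)

    def test_one_percent_cutoff_drops_rare_bond(self):
        top, bonded = hbond_triad(1.8, 180.0)
        _, broken = hbond_triad(6.0, 180.0)
        frames = np.stack([bonded] + [broken] * 199)  # occupancy 0.5%
        records = ia.hydrogen_bonds(make_slice(top, frames), freq_cutoff=0.01)
        assert records == []
        kept = ia.hydrogen_bonds(make_slice(top, frames), freq_cutoff=0.001)
        assert len(kept) == 1 and kept[0].frequency == pytest.approx(0.005)

    def test_right_angle_never_detected(self):
        top, xyz = hbond_triad(1.8, 90.0)
        assert ia.hydrogen_bonds(make_slice(top, np.stack([xyz] * 5))) == []

    def test_angle_threshold_boundary(self):
        top, accepted = hbond_triad(1.8, 150.0)
        records = ia.hydrogen_bonds(make_slice(top, accepted))
        assert len(records) == 1
        top, rejected = hbond_triad(1.8, 110.0)
        assert ia.hydrogen_bonds(make_slice(top, rejected)) == []

    def test_frequency_invariant_to_frame_order(self, rng):
        top, bonded = hbond_triad(1.8, 180.0)
        _, broken = hbond_triad(6.0, 180.0)
        frames = np.stack([bonded] * 30 + [broken] * 70)
        perm = rng.permutation(100)
        r1 = ia.hydrogen_bonds(make_slice(top, frames))
        r2 = ia.hydrogen_bonds(make_slice(top, frames[perm]))
        assert [r.frequency for r in r1] == [r.frequency for r in r2]

    def test_no_hydrogens_reported(self):
        top = _cloud_top(3)
        with pytest.raises(ValueError, match="no hydrogens"):
            ia.hydrogen_bonds(make_slice(top, np.zeros((1, 3, 3))))


class TestSecondaryStructure:
    def test_helix(self):
        top, xyz = ideal_helix(14)
        codes, freq = ia.secondary_structure(make_slice(top, xyz))
        assert (codes.iloc[0, 3:-2] == "H").all()

    def test_sheet(self):
        top, xyz = antiparallel_sheet(8)
        codes, _ = ia.secondary_structure(make_slice(top, xyz))
        row = "".join(codes.iloc[0, 1:])
        assert set(row[1:7]) == {"E"}
        assert set(row[9:15]) == {"E"}

    def test_two_residue_chain_is_coil(self):
        top, xyz = ideal_helix(4)
        sub = slice(0, 8)  # first two residues only
        small_top = top.select(np.arange(8))
        codes, freq = ia.secondary_structure(make_slice(small_top, xyz[sub]))
        assert set(codes.iloc[0, 1:]) <= {"-", "S", "T"}
        assert not (codes.iloc[0, 1:].isin(["H", "G", "I", "E", "B"])).any()

    def test_missing_backbone_raises(self):
        top = _cloud_top(10)
        with pytest.raises(ValueError, match="backbone"):
            ia.secondary_structure(make_slice(top, np.zeros((1, 10, 3))))

    def test_frequency_table_sums_to_100(self):
        top, xyz = ideal_helix(10)
        _, freq = ia.secondary_structure(make_slice(top, np.stack([xyz] * 3)))
        sums = freq.drop(columns="residue").sum(axis=1)
        np.testing.assert_allclose(sums, 100.0)


class TestSasa:
    def test_single_sphere_analytic(self):
        top, xyz = single_sphere()
        df = ia.sasa(make_slice(top, xyz), radii=np.array([1.5]))
        exact = 4 * np.pi * (1.5 + 1.4) ** 2
        assert df.iloc[0, 1] == pytest.approx(exact, rel=0.01)

    def test_buried_atom_zero(self, rng):
        # central atom caged by 26 tight neighbors
        offsets = [
            np.array([i, j, k], dtype=float)
            for i in (-1, 0, 1)
            for j in (-1, 0, 1)
            for k in (-1, 0, 1)
            if (i, j, k) != (0, 0, 0)
        ]
        xyz = np.vstack([[0.0, 0.0, 0.0]] + [2.0 * o / np.linalg.norm(o) for o in offsets])
        top = _cloud_top(len(xyz))
        df = ia.sasa(make_slice(top, xyz[None]))
        per_atom = ia.sasa_frame(xyz, ia.atom_radii(top))
        assert per_atom[0] == 0.0

    def test_two_sphere_closed_form(self):
        r = ia.VDW_RADII["C"] + 1.4  # expanded radius 3.1
        for sep in (2.0, 3.5, 5.0):
            top, xyz = two_spheres(sep)
            df = ia.sasa(make_slice(top, xyz))
            # equal spheres: each loses a cap of height h = r - sep/2
            h = r - sep / 2
            exact_each = 4 * np.pi * r**2 - 2 * np.pi * r * h
            got = df.iloc[0, 1:].to_numpy(dtype=float)
            np.testing.assert_allclose(got, exact_each, rtol=0.015)

    def test_monotone_under_added_atoms(self, rng):
        xyz5 = rng.uniform(0, 6, size=(5, 3))
        xyz8 = np.vstack([xyz5, rng.uniform(0, 6, size=(3, 3))])
        a5 = ia.sasa_frame(xyz5, np.full(5, 1.7))
        a8 = ia.sasa_frame(xyz8, np.full(8, 1.7))
        assert (a8[:5] <= a5 + 1e-9).all()

    def test_unknown_element_warns(self):
        top = _cloud_top(1, element="Zz")
        with pytest.warns(UserWarning, match="unknown element"):
            ia.atom_radii(top)


def _patch_top(resnames, with_cb=True):
    names, resids, rn, chains, elements = [], [], [], [], []
    for i, r in enumerate(resnames):
        names.append("CA")
        resids.append(i + 1)
        rn.append(r)
        chains.append("A")
        elements.append("C")
        if with_cb and r != "GLY":
            names.append("CB")
            resids.append(i + 1)
            rn.append(r)
            chains.append("A")
            elements.append("C")
    return Topology(
        atom_names=np.asarray(names, dtype=object),
        resids=np.asarray(resids, dtype=np.int64),
        resnames=np.asarray(rn, dtype=object),
        chain_ids=np.asarray(chains, dtype=object),
        elements=np.asarray(elements, dtype=object),
    )


class TestSurfacePatches:
    def test_singleton_hydrophobic_patch(self):
        top = _patch_top(["LEU"])
        xyz = np.array([[0.0, 0, 0], [1.5, 0, 0]])
        ps = ia.surface_patches(xyz, top, {"A1": 120.0})
        assert len(ps.patches) == 1
        patch = ps.patches[0]
        assert patch.kind == "hydrophobic"
        assert patch.area == pytest.approx(120.0)

    def test_two_close_leucines_merge(self):
        top = _patch_top(["LEU", "LEU"])
        xyz = np.array([[0.0, 0, 0], [1.5, 0, 0], [6.0, 0, 0], [7.5, 0, 0]])
        ps = ia.surface_patches(xyz, top, {"A1": 100.0, "A2": 110.0}, adjacency_cutoff=8.0)
        assert len(ps.patches) == 1
        assert ps.patches[0].area == pytest.approx(210.0)
        # connectivity oracle: CB-CB distance 6.0 <= 8.0
        assert sorted(ps.patches[0].residues) == ["A1", "A2"]

    def test_distant_leucines_split(self):
        top = _patch_top(["LEU", "LEU"])
        xyz = np.array([[0.0, 0, 0], [1.5, 0, 0], [20.0, 0, 0], [21.5, 0, 0]])
        ps = ia.surface_patches(xyz, top, {"A1": 100.0, "A2": 110.0}, adjacency_cutoff=8.0)
        assert len(ps.patches) == 2

    def test_buried_residues_excluded(self):
        top = _patch_top(["LEU", "ARG"])
        xyz = np.array([[0.0, 0, 0], [1.5, 0, 0], [6.0, 0, 0], [7.5, 0, 0]])
        ps = ia.surface_patches(xyz, top, {"A1": 1.0, "A2": 1.0})
        assert ps.patches == []

    def test_classes_never_mix(self):
        top = _patch_top(["LEU", "ARG"])
        xyz = np.array([[0.0, 0, 0], [1.5, 0, 0], [3.0, 0, 0], [4.5, 0, 0]])
        ps = ia.surface_patches(xyz, top, {"A1": 120.0, "A2": 150.0})
        kinds = sorted(p.kind for p in ps.patches)
        assert kinds == ["hydrophobic", "positive"]

    def test_area_bounded_by_total_exposed(self, rng):
        resnames = ["LEU", "VAL", "ARG", "GLU", "LYS", "ILE"]
        top = _patch_top(resnames)
        xyz = rng.uniform(0, 25, size=(top.n_atoms, 3))
        sasa_map = {f"A{i + 1}": float(rng.uniform(0, 200)) for i in range(6)}
        ps = ia.surface_patches(xyz, top, sasa_map)
        for kind in ("hydrophobic", "positive", "negative"):
            exposed_total = sum(
                v
                for k, v in sasa_map.items()
                if ia.classify_residue(resnames[int(k[1:]) - 1]) == kind
            )
            assert ps.total_area(kind) <= exposed_total + 1e-9
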