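"""Calculators: distances, bonded-geometry histograms and rigid
superposition against independent oracles."""

import math

import numpy as np
import pytest

from structmine.calc import (
    DegeneracyError,
    GeometryStats,
    UndefinedDistanceError,
    alpha_carbon_trace,
    angle_bin,
    bond_bin,
    bond_geometry,
    count_group_names,
    kabsch_superpose,
    min_group_distance,
)
from structmine.model import SelectionSet, StructmineError
from structmine.select import select_peptides

from .conftest import (
    atom,
    entry_of,
    fixture_entry,
    quaternion_superpose_rmsd,
    simple_group,
)


def all_groups(entry):
    return SelectionSet(entry.pdb_id, tuple(range(len(entry.groups))))


class TestMinGroupDistance:
    def test_three_four_five_triangle(self):
        a = simple_group("A", "NON-POLYMER", [atom("C1", "C", 0, 0, 0)], seq_id=1)
        b = simple_group("B", "NON-POLYMER", [atom("C1", "C", 3, 4, 0)], seq_id=2)
        entry = entry_of([a, b])
        assert min_group_distance(entry, 0, 1) == pytest.approx(5.0)

    def test_identical_coordinates(self):
        a = simple_group("A", "NON-POLYMER", [atom("C1", "C", 1, 2, 3)], seq_id=1)
        b = simple_group("B", "NON-POLYMER", [atom("C1", "C", 1, 2, 3)], seq_id=2)
        entry = entry_of([a, b])
        assert min_group_distance(entry, 0, 1) == 0.0

    def test_symmetry_and_brute_force(self):
        rng = np.random.default_rng(12)
        mk = lambda name, seq: simple_group(
            name, "NON-POLYMER",
            [atom(f"C{i}", "C", *p) for i, p in enumerate(rng.uniform(-15, 15, (30, 3)))],
            seq_id=seq,
        )
        entry = entry_of([mk("AAA", 1), mk("BBB", 2)])
        d = min_group_distance(entry, 0, 1)
        assert d == min_group_distance(entry, 1, 0)
        pts_a = np.array([(a.x, a.y, a.z) for a in entry.groups[0].atoms])
        pts_b = np.array([(a.x, a.y, a.z) for a in entry.groups[1].atoms])
        oracle = min(
            math.dist(p, q) for p in pts_a.tolist() for q in pts_b.tolist()
        )
        assert d == pytest.approx(oracle, abs=1e-12)

    def test_no_heavy_atoms_is_an_error(self):
        hydrogens = simple_group(
            "HHH", "NON-POLYMER", [atom("H1", "H", 0, 0, 0)], seq_id=1
        )
        other = simple_group("B", "NON-POLYMER", [atom("C1", "C", 3, 0, 0)], seq_id=2)
        entry = entry_of([hydrogens, other])
        with pytest.raises(UndefinedDistanceError):
            min_group_distance(entry, 0, 1)


class TestBondGeometry:
    def test_right_angle(self):
        g = simple_group(
            "XYZ", "NON-POLYMER",
            [atom("A", "C", 1, 0, 0), atom("B", "C", 0, 0, 0), atom("C", "C", 0, 1, 0)],
            seq_id=1, bonds=[(0, 1, 1), (1, 2, 1)],
        )
        entry = entry_of([g])
        stats = bond_geometry(entry, all_groups(entry))
        assert stats.n_bonds == 2
        assert stats.n_angles == 1
        ((key, edge),) = stats.angle_hist
        assert key == ("C", "C", "C")
        assert edge == 90.0

    def test_collinear_angle(self):
        g = simple_group(
            "XYZ", "NON-POLYMER",
            [atom("A", "N", -1, 0, 0), atom("B", "C", 0, 0, 0), atom("C", "O", 1, 0, 0)],
            seq_id=1, bonds=[(0, 1, 1), (1, 2, 1)],
        )
        entry = entry_of([g])
        stats = bond_geometry(entry, all_groups(entry))
        ((key, edge),) = stats.angle_hist
        assert key == ("N", "C", "O")  # flanks sorted around the centre
        assert edge == 180.0

    def test_fixture_counts_match_naive_recomputation(self):
        entry = fixture_entry(6, n_ligands=1, n_waters=0, n_metals=0)
        sel = all_groups(entry)
        stats = bond_geometry(entry, sel)

        # independent loop over the bond lists
        bonds = []
        for gi in sel.indices:
            for i, j, _ in entry.groups[gi].bonds:
                bonds.append(((gi, i), (gi, j)))
        for (gi, ai), (gj, aj), _ in entry.inter_group_bonds:
            bonds.append(((gi, ai), (gj, aj)))
        assert stats.n_bonds == len(bonds)

        pos = lambda n: np.array(
            (
                entry.groups[n[0]].atoms[n[1]].x,
                entry.groups[n[0]].atoms[n[1]].y,
                entry.groups[n[0]].atoms[n[1]].z,
            )
        )
        el = lambda n: entry.groups[n[0]].atoms[n[1]].element
        naive_bond_hist: dict = {}
        for a, b in bonds:
            d = float(np.linalg.norm(pos(a) - pos(b)))
            pair = tuple(sorted((el(a), el(b))))
            key = (pair, math.floor(d / 0.01) * 0.01)
            naive_bond_hist[key] = naive_bond_hist.get(key, 0) + 1
        assert stats.bond_length_hist == naive_bond_hist

        # angles: every unordered pair of bonds sharing an endpoint
        from collections import defaultdict

        adj = defaultdict(list)
        for a, b in bonds:
            adj[a].append(b)
            adj[b].append(a)
        naive_n_angles = sum(
            len(nbrs) * (len(nbrs) - 1) // 2 for nbrs in adj.values()
        )
        assert stats.n_angles == naive_n_angles
        assert sum(stats.angle_hist.values()) == stats.n_angles
        assert sum(stats.bond_length_hist.values()) == stats.n_bonds

    def test_group_order_invariance(self):
        entry = fixture_entry(14, n_ligands=2, n_waters=0)
        sel = all_groups(entry)
        stats = bond_geometry(entry, sel)
        # histograms over a sub-selection merge to the full result when
        # no bonds cross the split
        lig_idx = [i for i, g in enumerate(entry.groups) if g.name.startswith("LG")]
        rest_idx = [i for i in sel.indices if i not in lig_idx]
        merged = bond_geometry(
            entry, SelectionSet.from_indices(entry.pdb_id, lig_idx)
        ).merge(bond_geometry(entry, SelectionSet.from_indices(entry.pdb_id, rest_idx)))
        assert merged.bond_length_hist == stats.bond_length_hist
        assert merged.angle_hist == stats.angle_hist

    def test_tsv_rows_sorted(self):
        entry = fixture_entry(15)
        rows = bond_geometry(entry, all_groups(entry)).to_rows()
        assert rows == sorted(rows)

    def test_bins_left_closed(self):
        assert bond_bin(1.529999) == pytest.approx(1.52)
        assert bond_bin(1.53) == pytest.approx(1.53)
        assert angle_bin(109.999) == 109.0
        assert angle_bin(110.0) == 110.0


class TestKabsch:
    @staticmethod
    def rotation_about_z(deg):
        t = math.radians(deg)
        return np.array(
            [[math.cos(t), -math.sin(t), 0], [math.sin(t), math.cos(t), 0], [0, 0, 1]]
        )

    def test_identity_on_equal_inputs(self):
        pts = np.random.default_rng(1).normal(size=(10, 3)) * 5
        sup = kabsch_superpose(pts, pts)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-9)

    def test_recovers_applied_rigid_motion(self):
        ref = np.random.default_rng(2).normal(size=(25, 3)) * 8
        rot = self.rotation_about_z(90)
        mov = ref @ rot.T + np.array([1.0, 2.0, 3.0])
        sup = kabsch_superpose(ref, mov)
        assert sup.rmsd <= 1e-9
        np.testing.assert_allclose(sup.rotation, rot.T, atol=1e-9)
        np.testing.assert_allclose(sup.apply(mov), ref, atol=1e-8)

    def test_rotation_is_proper_and_orthonormal(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(size=(50, 3)) * 5
        mov = ref + rng.normal(scale=1.5, size=ref.shape)
        sup = kabsch_superpose(ref, mov)
        np.testing.assert_allclose(sup.rotation.T @ sup.rotation, np.eye(3), atol=1e-9)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_agrees_with_quaternion_oracle_under_noise(self):
        rng = np.random.default_rng(4)
        ref = rng.normal(size=(50, 3)) * 10
        rot = self.rotation_about_z(37.5)
        mov = ref @ rot.T + rng.normal(scale=0.5, size=ref.shape) + [4, -2, 7]
        sup = kabsch_superpose(ref, mov)
        assert sup.rmsd == pytest.approx(quaternion_superpose_rmsd(ref, mov), abs=1e-6)

    def test_rmsd_invariant_under_shared_rigid_motion(self):
        rng = np.random.default_rng(5)
        ref = rng.normal(size=(30, 3)) * 6
        mov = ref + rng.normal(scale=0.8, size=ref.shape)
        base = kabsch_superpose(ref, mov).rmsd
        rot = self.rotation_about_z(123.0)
        shift = np.array([-9.0, 4.0, 11.0])
        moved = kabsch_superpose(ref @ rot.T + shift, mov @ rot.T + shift).rmsd
        assert moved == pytest.approx(base, abs=1e-9)

    def test_rmsd_never_exceeds_raw_rmsd(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            ref = rng.normal(size=(20, 3)) * 4
            mov = ref @ self.rotation_about_z(rng.uniform(0, 180)).T + rng.normal(
                scale=1.0, size=ref.shape
            )
            raw = float(np.sqrt(((ref - mov) ** 2).sum() / len(ref)))
            assert kabsch_superpose(ref, mov).rmsd <= raw + 1e-12

    def test_reflection_not_allowed(self):
        # mirror image: best proper rotation leaves nonzero rmsd
        rng = np.random.default_rng(7)
        ref = rng.normal(size=(20, 3)) * 5
        mirrored = ref * np.array([-1.0, 1.0, 1.0])
        sup = kabsch_superpose(ref, mirrored)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)
        assert sup.rmsd > 0.1

    def test_degenerate_inputs_rejected(self):
        line = np.array([[float(i), 0.0, 0.0] for i in range(5)])
        with pytest.raises(DegeneracyError):
            kabsch_superpose(line, line)
        same = np.zeros((4, 3))
        with pytest.raises(DegeneracyError):
            kabsch_superpose(same, same)
        with pytest.raises(StructmineError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))
        with pytest.raises(StructmineError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestAlphaCarbonTrace:
    def test_five_residue_helix(self):
        entry = fixture_entry(
            20, residues_per_chain=5, n_ligands=0, n_waters=0, n_metals=0
        )
        trace = alpha_carbon_trace(entry, select_peptides(entry))
        assert trace.shape == (5, 3)
        # consecutive CA spacing near the generator's 3.8 A ideal
        gaps = np.linalg.norm(np.diff(trace, axis=0), axis=1)
        assert np.all((gaps > 2.5) & (gaps < 5.0))

    def test_ligand_only_selection_is_degenerate(self):
        entry = fixture_entry(21, n_ligands=1, n_waters=0)
        lig = SelectionSet.from_indices(
            entry.pdb_id,
            (i for i, g in enumerate(entry.groups) if g.name == "LG0"),
        )
        with pytest.raises(DegeneracyError):
            alpha_carbon_trace(entry, lig)

    def test_groups_without_ca_are_skipped(self):
        entry = fixture_entry(
            22, residues_per_chain=10, n_ligands=0, n_waters=0, n_metals=0
        )
        # strip CA from three residues
        stripped = []
        for i, g in enumerate(entry.groups):
            if i in (1, 4, 7):
                atoms = tuple(a for a in g.atoms if a.name != "CA")
                bonds = ()  # bonds referenced CA; drop them for this probe
                stripped.append(
                    type(g)(name=g.name, comp_type=g.comp_type, seq_id=g.seq_id,
                            chain_index=g.chain_index, atoms=atoms, bonds=bonds)
                )
            else:
                stripped.append(g)
        probe = entry_of(stripped, pdb_id=entry.pdb_id, n_chains=len(entry.chain_ids))
        trace = alpha_carbon_trace(probe, select_peptides(probe))
        assert trace.shape == (7, 3)

    def test_calcium_ion_not_mistaken_for_alpha_carbon(self):
        entry = fixture_entry(23, residues_per_chain=4, n_ligands=0, n_metals=0, n_waters=0)
        calcium = simple_group(
            "CA", "NON-POLYMER", [atom("CA", "CA", 0, 0, 0)],
            seq_id=301, chain_index=len(entry.chain_ids),
        )
        probe = entry_of(
            list(entry.groups) + [calcium],
            pdb_id=entry.pdb_id,
            n_chains=len(entry.chain_ids) + 1,
        )
        sel = SelectionSet(probe.pdb_id, tuple(range(len(probe.groups))))
        trace = alpha_carbon_trace(probe, sel)
        assert trace.shape == (4, 3)


class TestCountGroupNames:
    def test_multiset_counts(self):
        groups = [
            simple_group("HOH", "NON-POLYMER", [atom("O", "O", 0, 0, 0)], seq_id=1),
            simple_group("HOH", "NON-POLYMER", [atom("O", "O", 5, 0, 0)], seq_id=2),
            simple_group("LIG", "NON-POLYMER", [atom("C1", "C", 10, 0, 0)], seq_id=3),
        ]
        entry = entry_of(groups)
        assert count_group_names(entry, all_groups(entry)) == {"HOH": 2, "LIG": 1}
        assert count_group_names(entry, SelectionSet.empty(entry.pdb_id)) == {}

    def test_tally_oracle(self):
        entry = fixture_entry(24, n_waters=5, n_metals=2)
        sel = all_groups(entry)
        oracle: dict = {}
        for gi in sel.indices:
            oracle[entry.groups[gi].name] = oracle.get(entry.groups[gi].name, 0) + 1
        assert count_group_names(entry, sel) == oracle


class TestGeometryStatsMerge:
    def test_merge_is_commutative_and_identity(self):
        a = bond_geometry(fixture_entry(25), all_groups(fixture_entry(25)))
        b = bond_geometry(fixture_entry(26), all_groups(fixture_entry(26)))
        ab = a.merge(b)
        ba = b.merge(a)
        assert ab.bond_length_hist == ba.bond_length_hist
        assert ab.n_angles == ba.n_angles
        empty = GeometryStats()
        assert a.merge(empty).bond_length_hist == a.bond_length_hist
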