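"""Geometry primitives: PDB round-trip, superposition, clashes, SASA, mass."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_strategies
from scipy.spatial.transform import Rotation

from conftest import chain_from_coords, make_atom
from nbselect.structio import (
    AtomSelection,
    ComplexModel,
    VDW_RADII,
    buried_sasa,
    chain_molecular_weight,
    clash_metrics,
    kabsch_superpose,
    read_pdb,
    selection_rmsd,
    shrake_rupley_sasa,
    write_pdb,
)

GROUPS = {"A": "ligand", "B": "receptor"}


class TestReadWritePdb:
    def test_toy_two_chain_file(self, toy_pdb_path):
        models = read_pdb(toy_pdb_path, GROUPS)
        assert len(models) == 1
        cm = models[0]
        assert len(cm.group_atoms("ligand")) == 5
        assert len(cm.group_atoms("receptor")) == 5
        assert len(cm.atoms) == 10

    def test_missing_chain_is_named(self, toy_pdb_path):
        with pytest.raises(ValueError, match="Z"):
            read_pdb(toy_pdb_path, {"A": "ligand", "Z": "receptor"})

    def test_multi_model_yields_one_complex_per_model(self, tmp_path):
        chain = chain_from_coords(np.random.default_rng(0).normal(size=(6, 3)) * 5)
        models = [
            ComplexModel(groups={"ligand": [chain]}, model_no=i + 1) for i in range(3)
        ]
        path = tmp_path / "multi.pdb"
        write_pdb(models, path)
        back = read_pdb(path, {"A": "ligand"})
        assert len(back) == 3
        topologies = {
            tuple((r.res_seq, r.res_name) for r in m.group_chain("ligand").residues)
            for m in back
        }
        assert len(topologies) == 1

    def test_round_trip_preserves_fields_to_3_decimals(self, tmp_path):
        rng = np.random.default_rng(42)
        chain = chain_from_coords(rng.uniform(-40, 40, size=(8, 3)), chain_id="Q")
        path = tmp_path / "rt.pdb"
        write_pdb([ComplexModel(groups={"ligand": [chain]})], path)
        back = read_pdb(path, {"Q": "ligand"})[0].group_chain("ligand")
        assert [r.res_seq for r in back.residues] == [r.res_seq for r in chain.residues]
        assert back.chain_id == "Q"
        np.testing.assert_allclose(
            np.array([a.xyz for a in back.atoms]),
            np.array([a.xyz for a in chain.atoms]),
            atol=5e-4,
        )


class TestKabsch:
    def test_identity(self):
        pts = np.random.default_rng(1).normal(size=(5, 3))
        rot, trans, rmsd = kabsch_superpose(pts, pts)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(trans, 0.0, atol=1e-10)
        assert rmsd < 1e-10

    def test_translation_invariance(self):
        pts = np.random.default_rng(2).normal(size=(6, 3))
        _, _, rmsd = kabsch_superpose(pts + np.array([5.0, 0, 0]), pts)
        assert rmsd < 1e-10

    def test_recovers_known_rotation(self):
        ref = np.array([[0.0, 0, 0], [3, 0, 0], [0, 2, 0], [1, 1, 4]])
        rz90 = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 1]])
        mobile = ref @ rz90.T
        rot, _, rmsd = kabsch_superpose(mobile, ref)
        # recovered rotation must undo the applied one
        np.testing.assert_allclose(rot, rz90.T, atol=1e-8)
        assert rmsd < 1e-8
        assert np.isclose(np.linalg.det(rot), 1.0)

    def test_agrees_with_scipy_align_vectors(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(size=(12, 3)) * 4
        mob = ref @ Rotation.random(random_state=5).as_matrix().T + [1, -2, 3]
        mob += rng.normal(scale=0.3, size=mob.shape)
        rot, _, rmsd = kabsch_superpose(mob, ref)
        r_scipy, rssd = Rotation.align_vectors(
            ref - ref.mean(0), mob - mob.mean(0)
        )
        np.testing.assert_allclose(rot, r_scipy.as_matrix(), atol=1e-8)
        np.testing.assert_allclose(rmsd, rssd / np.sqrt(len(ref)), atol=1e-8)

    def test_errors(self):
        with pytest.raises(ValueError, match="3 points"):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError, match="degenerate"):
            kabsch_superpose(line, line)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st_strategies.integers(0, 10_000))
    def test_rigid_transform_invariance(self, seed):
        """RMSD after superposition is unchanged by any proper rigid motion
        applied to the mobile set beforehand."""
        rng = np.random.default_rng(seed)
        ref = rng.normal(size=(8, 3)) * 3
        mob = ref + rng.normal(scale=0.5, size=ref.shape)
        _, _, rmsd0 = kabsch_superpose(mob, ref)
        rot = Rotation.random(random_state=seed).as_matrix()
        _, _, rmsd1 = kabsch_superpose(mob @ rot.T + rng.uniform(-9, 9, 3), ref)
        assert np.isclose(rmsd0, rmsd1, atol=1e-9)


class TestSelectionRmsd:
    def test_identical_models_zero(self):
        chain = chain_from_coords(np.random.default_rng(0).normal(size=(5, 3)))
        sel = AtomSelection([(1, 5)])
        assert selection_rmsd(chain, chain, sel) == 0.0

    def test_hand_arithmetic_two_atoms(self):
        a = chain_from_coords([[0, 0, 0], [10, 0, 0]])
        b = chain_from_coords([[3, 0, 0], [10, 4, 0]])
        sel = AtomSelection([(1, 2)])
        assert selection_rmsd(a, b, sel) == pytest.approx(np.sqrt((9 + 16) / 2), abs=1e-4)

    def test_ca_filter_excludes_side_chain_displacement(self):
        from nbselect.structio import ChainModel, Residue

        def residue(res_seq, ca, cb):
            return Residue(
                "ALA",
                res_seq,
                [
                    make_atom(2 * res_seq, ca, res_seq=res_seq),
                    make_atom(2 * res_seq + 1, cb, res_seq=res_seq, atom_name="CB"),
                ],
            )

        a = ChainModel("A", [residue(1, [0, 0, 0], [1, 0, 0])])
        b = ChainModel("A", [residue(1, [0, 0, 0], [9, 0, 0])])  # side chain moved
        assert selection_rmsd(a, b, AtomSelection([(1, 1)], ("CA",))) == 0.0
        assert selection_rmsd(a, b, AtomSelection([(1, 1)], None)) > 0.0

    def test_empty_selection_errors(self):
        chain = chain_from_coords([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(ValueError, match="0 atoms"):
            selection_rmsd(chain, chain, AtomSelection([(50, 60)]))


def brute_force_clashes(atoms_a, atoms_b, threshold=0.4):
    """O(n²) reference clash count from the radius table."""
    count = 0
    for a in atoms_a:
        for b in atoms_b:
            cutoff = VDW_RADII[a.element] + VDW_RADII[b.element] - threshold
            if np.linalg.norm(a.xyz - b.xyz) < cutoff:
                count += 1
    return count


class TestClashMetrics:
    def test_far_apart_no_contact(self):
        a = [make_atom(1, [0, 0, 0])]
        b = [make_atom(2, [10, 0, 0])]
        assert clash_metrics(a, b) == (0, 0.0)

    def test_two_carbons_at_overlap_boundary(self):
        # 2.9 A apart: overlap 0.5 >= 0.4 -> one clash
        a = [make_atom(1, [0, 0, 0])]
        b = [make_atom(2, [2.9, 0, 0])]
        count, score = clash_metrics(a, b)
        assert count == 1 and score == 1000.0
        # 3.05 A apart: overlap 0.35 < 0.4 -> none
        assert clash_metrics(a, [make_atom(2, [3.05, 0, 0])])[0] == 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_random_clouds(self, seed):
        rng = np.random.default_rng(seed)
        elements = list(VDW_RADII)
        a = [
            make_atom(i, rng.uniform(0, 15, 3), element=elements[rng.integers(5)])
            for i in range(120)
        ]
        b = [
            make_atom(i, rng.uniform(0, 15, 3), element=elements[rng.integers(5)])
            for i in range(150)
        ]
        count, score = clash_metrics(a, b)
        assert count == brute_force_clashes(a, b)
        assert score == pytest.approx(1000.0 * count / len(a))
        # pair set is symmetric; only the normalization changes
        count_ba, score_ba = clash_metrics(b, a)
        assert count_ba == count
        assert score_ba == pytest.approx(1000.0 * count / len(b))

    def test_unknown_element_is_named(self):
        a = [make_atom(1, [0, 0, 0], element="XX")]
        with pytest.raises(ValueError, match="XX"):
            clash_metrics(a, [make_atom(2, [1, 0, 0])])


class TestSasa:
    def test_isolated_carbon_matches_sphere_area(self):
        atom = make_atom(1, [0, 0, 0])
        expected = 4 * np.pi * (1.7 + 1.4) ** 2  # 120.76
        assert shrake_rupley_sasa([atom]) == pytest.approx(expected, rel=0.01)

    def test_no_burial_when_far_apart(self):
        a = [make_atom(1, [0, 0, 0])]
        b = [make_atom(2, [50, 0, 0])]
        assert abs(buried_sasa(a, b)) < 1.0

    @pytest.mark.parametrize("d", [1.0, 2.0, 3.0, 4.5])
    def test_two_sphere_burial_matches_cap_formula(self, d):
        # equal spheres radius R = r_C + probe; buried area = 2 * 2*pi*R*h,
        # cap height h = R - d/2
        r = 1.7 + 1.4
        a = [make_atom(1, [0, 0, 0])]
        b = [make_atom(2, [d, 0, 0])]
        analytic = 2 * (2 * np.pi * r * (r - d / 2))
        assert buried_sasa(a, b) == pytest.approx(analytic, rel=0.02)

    def test_nonnegative_on_random_cluster(self):
        rng = np.random.default_rng(7)
        atoms = [make_atom(i, rng.uniform(0, 8, 3)) for i in range(30)]
        assert buried_sasa(atoms[:15], atoms[15:]) >= -1e-6


class TestMolecularWeight:
    def test_hand_summed_values(self):
        assert chain_molecular_weight("GG") == pytest.approx(132.12, abs=0.01)
        assert chain_molecular_weight("A") == pytest.approx(89.09, abs=0.01)

    def test_nanobody_sized_chain_below_20_kda(self):
        from nbselect.fixtures import NANOBODY_TEMPLATE

        assert len(NANOBODY_TEMPLATE) == 120
        assert chain_molecular_weight(NANOBODY_TEMPLATE) < 20000

    def test_errors(self):
        with pytest.raises(ValueError, match="empty"):
            chain_molecular_weight("")
        with pytest.raises(ValueError, match="B"):
            chain_molecular_weight("ABC")
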