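"""Geometry features vs brute-force oracles; rigid-motion invariance."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from varmode import structfeat
from varmode.structfeat import (
    Atom,
    Residue,
    StructureModel,
    com_distance,
    parse_pdb,
    proximal_variant_counts,
    residue_contacts,
    residue_feature_table,
    rsa,
    secondary_structure,
    shrake_rupley_sasa,
)
from varmode.simulate import gen_backbone, gen_structure


def chain_from_coords(coords, names=None):
    coords = np.asarray(coords, dtype=float)
    residues = [
        Residue(i + 1, (names or ["ALA"] * len(coords))[i],
                (Atom("CA", "C", c, 80.0),))
        for i, c in enumerate(coords)
    ]
    return StructureModel(residues)


class TestParsePdb:
    def test_roundtrip_coordinates(self):
        text = gen_structure(25, seed=1)
        model = parse_pdb(text)
        assert model.n_residues == 25
        again = parse_pdb(text)
        np.testing.assert_allclose(model.ca_coords, again.ca_coords, atol=1e-3)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            parse_pdb("END\n")

    def test_bfactor_becomes_plddt(self):
        model = parse_pdb(gen_structure(10, seed=2))
        assert ((model.plddt >= 0) & (model.plddt <= 100)).all()

    def test_residue_without_ca_excluded(self):
        lines = [
            "ATOM      1  CA  ALA A   1      0.000   0.000   0.000  1.00 90.00           C",
            "ATOM      2  CB  ALA A   2      5.000   0.000   0.000  1.00 90.00           C",
        ]
        with pytest.warns(UserWarning, match="no CA"):
            model = parse_pdb("\n".join(lines) + "\nEND\n")
        assert model.n_residues == 1


class TestContacts:
    def test_collinear_forced_counts(self):
        model = chain_from_coords([[0, 0, 0], [10, 0, 0], [20, 0, 0]])
        assert residue_contacts(model, cutoff=12.0).tolist() == [1, 2, 1]

    def test_single_residue_zero(self):
        model = chain_from_coords([[0, 0, 0]])
        assert residue_contacts(model).tolist() == [0]

    def test_cutoff_boundary_inclusive(self):
        model = chain_from_coords([[0, 0, 0], [12.0, 0, 0]])
        assert residue_contacts(model, cutoff=12.0).tolist() == [1, 1]

    def test_matches_brute_force(self, chain50):
        counts = residue_contacts(chain50, cutoff=12.0)
        ca = chain50.ca_coords
        oracle = [
            sum(
                1
                for j in range(len(ca))
                if j != i and np.linalg.norm(ca[i] - ca[j]) <= 12.0
            )
            for i in range(len(ca))
        ]
        assert counts.tolist() == oracle


class TestComDistance:
    def test_two_equal_mass_atoms(self):
        model = StructureModel(
            [
                Residue(1, "GLY", (Atom("CA", "C", np.zeros(3), 50.0),
                                   Atom("CB", "C", np.array([2.0, 0, 0]), 50.0))),
            ]
        )
        assert com_distance(model)[0] == pytest.approx(1.0)

    def test_translation_invariance(self, chain50):
        shifted = chain50.transformed(translation=np.array([10.0, -3.0, 7.0]))
        np.testing.assert_allclose(
            com_distance(chain50), com_distance(shifted), rtol=1e-9, atol=1e-9
        )

    def test_matches_direct_formula(self, chain50):
        from varmode.constants import ATOMIC_MASSES, DEFAULT_ATOMIC_MASS

        coords, atoms = chain50.all_atoms()
        masses = np.array(
            [ATOMIC_MASSES.get(a.element, DEFAULT_ATOMIC_MASS) for a in atoms]
        )
        com = (coords * masses[:, None]).sum(0) / masses.sum()
        oracle = np.linalg.norm(chain50.ca_coords - com, axis=1)
        np.testing.assert_allclose(com_distance(chain50), oracle, rtol=1e-6)

    def test_unknown_element_warns(self):
        model = StructureModel(
            [Residue(1, "ALA", (Atom("CA", "ZZ", np.zeros(3), 1.0),))]
        )
        with pytest.warns(UserWarning, match="unknown element"):
            com_distance(model)


class TestProximalCounts:
    def test_k_exceeding_chain_uses_all_others(self):
        model = chain_from_coords(np.arange(15).reshape(5, 3))
        vmap = {i: (1, 2) for i in range(1, 6)}
        out = proximal_variant_counts(model, vmap, k=9)
        assert (out == [4, 8]).all()

    def test_all_zero_map(self, chain50):
        out = proximal_variant_counts(chain50, {}, k=9)
        assert (out == 0).all()

    def test_matches_brute_force(self, chain50):
        rng = np.random.default_rng(3)
        vmap = {
            int(i): (int(rng.integers(0, 5)), int(rng.integers(0, 5)))
            for i in chain50.indices
        }
        out = proximal_variant_counts(chain50, vmap, k=9)
        ca = chain50.ca_coords
        idx = chain50.indices
        d = cdist(ca, ca)
        for i in range(len(idx)):
            others = [j for j in range(len(idx)) if j != i]
            others.sort(key=lambda j: (d[i, j], idx[j]))
            nearest = others[:9]
            expected = np.sum([vmap[int(idx[j])] for j in nearest], axis=0)
            assert (out[i] == expected).all()

    def test_negative_counts_rejected(self, chain50):
        with pytest.raises(ValueError):
            proximal_variant_counts(chain50, {1: (-1, 0)})


class TestSasaRsa:
    def test_isolated_sphere_analytic(self):
        model = StructureModel(
            [Residue(1, "ALA", (Atom("CA", "C", np.zeros(3), 1.0),))]
        )
        area = shrake_rupley_sasa(model, probe_radius=1.4)[0]
        r = 1.70 + 1.4
        assert area == pytest.approx(4 * np.pi * r**2, rel=1e-6)

    def test_burial_boundary(self):
        from varmode.features import categorize, rsa_rule

        assert categorize(0.19, rsa_rule()) == "buried"
        assert categorize(0.20, rsa_rule()) == "exposed"

    def test_agrees_with_dense_sampling(self, chain50):
        coarse, _ = rsa(chain50, n_sphere_points=960)
        dense, _ = rsa(chain50, n_sphere_points=9600)
        assert np.abs(coarse - dense).max() < 0.05

    def test_low_contact_residues_more_exposed(self, chain50):
        # Solvent accessibility should fall with packing: the ten
        # least-contacted residues are on average more exposed than the
        # ten most-contacted ones.
        values, _ = rsa(chain50)
        contacts = residue_contacts(chain50)
        order = np.argsort(contacts)
        assert values[order[:10]].mean() > values[order[-10:]].mean()

    def test_rotation_invariance(self, chain50):
        R = Rotation.from_euler("xyz", [30, -60, 110], degrees=True).as_matrix()
        rotated = chain50.transformed(rotation=R, translation=np.array([5.0, 5, 5]))
        v1, b1 = rsa(chain50)
        v2, b2 = rsa(rotated)
        assert np.abs(v1 - v2).max() < 0.02
        assert b1 == b2


class TestSecondaryStructure:
    def test_ideal_helix(self):
        model = parse_pdb(gen_backbone(12, -60.0, -45.0))
        ss = secondary_structure(model)
        assert ss[0] == "C" and ss[-1] == "C"
        assert all(s == "H" for s in ss[1:-1])

    def test_extended_chain_never_helix(self):
        model = parse_pdb(gen_backbone(12, -135.0, 135.0))
        assert "H" not in secondary_structure(model)
        assert "E" in secondary_structure(model)

    def test_two_residues_all_coil(self):
        model = parse_pdb(gen_backbone(2, -60.0, -45.0))
        assert secondary_structure(model) == ["C", "C"]

    def test_ca_only_chain_is_coil(self, chain50):
        assert set(secondary_structure(chain50)) == {"C"}


class TestFeatureTable:
    def test_complete_table(self, chain50):
        table = residue_feature_table(chain50, {1: (3, 4)}, protein_id="P1")
        assert len(table) == 50
        assert set(table["burial"]) <= {"buried", "exposed"}
        assert (table["contacts"] <= 49).all()
        assert (table["rsa"] >= 0).all() and (table["rsa"] <= 1).all()

    def test_rigid_motion_leaves_features_unchanged(self, chain50):
        R = Rotation.from_euler("zyx", [45, 10, -20], degrees=True).as_matrix()
        moved = chain50.transformed(rotation=R, translation=np.array([-4.0, 2, 9]))
        t1 = residue_feature_table(chain50, {5: (1, 1)})
        t2 = residue_feature_table(moved, {5: (1, 1)})
        assert t1["contacts"].tolist() == t2["contacts"].tolist()
        np.testing.assert_allclose(t1["com_distance"], t2["com_distance"], atol=1e-9)
        assert (t1["n_proximal_pathogenic"] == t2["n_proximal_pathogenic"]).all()
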