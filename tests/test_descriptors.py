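import numpy as np
import pytest
from rdkit import Chem
from scipy.linalg import expm

from cytoqsar.chem import parse_structure
from cytoqsar.descriptors import (
    DescriptorConfig,
    Featurizer,
    QnaGrid,
    UnsupportedElementError,
    WHOLEMOL_LABELS,
    adjacency_matrix,
    assemble_matrix,
    mna_atom_strings,
    mna_descriptors,
    qna_atom_values,
    wholemol_descriptors,
)


def _shuffled(smiles: str, seed: int) -> str:
    mol = Chem.MolFromSmiles(smiles)
    perm = np.random.default_rng(seed).permutation(mol.GetNumAtoms()).tolist()
    return Chem.MolToSmiles(Chem.RenumberAtoms(mol, perm), canonical=False)


class TestMna:
    def test_single_atom_level0(self):
        assert len(mna_atom_strings(parse_structure("C"), 0)) == 1

    def test_isomorphism_invariance(self):
        a = mna_descriptors(parse_structure("CCO"), 2)
        b = mna_descriptors(parse_structure("OCC"), 2)
        assert a == b

    def test_ethanol_level1_terminal_atoms_differ(self):
        strings = mna_atom_strings(parse_structure("CCO"), 1)
        assert len(strings) == 3
        # CH3 and OH are both terminal but carry different types
        assert strings[0] != strings[2]

    def test_multiset_size_equals_heavy_atoms_per_level(self):
        mol = parse_structure("CC(=O)Oc1ccccc1C(=O)O")
        for level in range(4):
            assert len(mna_atom_strings(mol, level)) == mol.n_atoms

    @pytest.mark.parametrize("smiles", ["CCO", "c1ccccc1", "CC(=O)Oc1ccccc1C(=O)O"])
    def test_permutation_invariance(self, smiles):
        base = mna_descriptors(parse_structure(smiles), 2)
        for seed in range(5):
            assert mna_descriptors(parse_structure(_shuffled(smiles, seed)), 2) == base


class TestQna:
    def test_isolated_atom_closed_form(self):
        from cytoqsar.descriptors import _EA_EV, _IP_EV

        vals = qna_atom_values(parse_structure("C"))
        ip, ea = _IP_EV["C"], _EA_EV["C"]
        b2 = 1.0 / (ip - ea)
        a = 0.5 * (ip + ea)
        assert vals[0, 0] == pytest.approx(b2, rel=1e-12)
        assert vals[0, 1] == pytest.approx(b2 * a, rel=1e-12)

    def test_symmetric_atoms_equal(self):
        vals = qna_atom_values(parse_structure("CC"))
        assert np.allclose(vals[0], vals[1])

    @pytest.mark.parametrize(
        "smiles",
        ["CCO", "c1ccccc1", "CC(=O)Oc1ccccc1C(=O)O",
         "CCCCCCCCCCCCCCCCCCCCCCCCCCCCCC"],  # 30 heavy atoms
    )
    def test_series_matches_dense_matrix_exponential(self, smiles):
        """Truncated propagation series vs an independent dense expm oracle."""
        mol = parse_structure(smiles)
        from cytoqsar.descriptors import _ab_values

        a, b = _ab_values(mol)
        m = expm(-0.5 * adjacency_matrix(mol))
        p_oracle = b * (m @ b)
        q_oracle = b * (m @ (b * a))
        vals = qna_atom_values(mol)
        assert np.max(np.abs(vals[:, 0] - p_oracle)) < 1e-6
        assert np.max(np.abs(vals[:, 1] - q_oracle)) < 1e-6

    def test_unsupported_element(self):
        with pytest.raises(UnsupportedElementError):
            qna_atom_values(parse_structure("[Se]1CCCC1"))

    def test_permutation_invariant_multiset(self):
        base = np.sort(qna_atom_values(parse_structure("CCO")), axis=0)
        other = np.sort(qna_atom_values(parse_structure(_shuffled("CCO", 1))), axis=0)
        assert np.allclose(base, other)


class TestQnaGrid:
    def test_atoms_at_one_center(self):
        grid = QnaGrid(p_edges=(0.0, 1.0), q_edges=(0.0, 1.0), resolution=3)
        pc, qc = grid.centers()
        vals = np.array([[pc[1], qc[1]]] * 4)  # all atoms at the central bump
        feats = grid.features(vals)
        center_idx = 1 * 3 + 1
        assert feats[center_idx] == pytest.approx(1.0)
        # neighbouring bumps overlap (sigma = grid spacing): the corner bump
        # sees the central atoms at one spacing per axis, exp(-1)
        assert feats[0] == pytest.approx(np.exp(-1.0), rel=1e-9)
        assert feats.argmax() == center_idx

    def test_hand_evaluated_two_atom_toy(self):
        grid = QnaGrid(p_edges=(0.0, 2.0), q_edges=(0.0, 2.0), resolution=2)
        sp, sq = grid.sigmas()  # spacing = 2.0 on both axes
        vals = np.array([[0.0, 0.0], [2.0, 2.0]])
        feats = grid.features(vals)

        def bump(p, q, cp, cq):
            return np.exp(-0.5 * ((p - cp) / sp) ** 2) * np.exp(-0.5 * ((q - cq) / sq) ** 2)

        expected_00 = 0.5 * (bump(0, 0, 0, 0) + bump(2, 2, 0, 0))
        assert feats[0] == pytest.approx(expected_00, rel=1e-12)

    def test_atom_order_invariance(self):
        grid = QnaGrid(p_edges=(0.0, 1.0), q_edges=(0.0, 1.0), resolution=4)
        vals = np.random.default_rng(0).uniform(0, 1, size=(6, 2))
        assert np.allclose(grid.features(vals), grid.features(vals[::-1]))


class TestWholeMolecule:
    def test_benzene(self):
        d = dict(zip(WHOLEMOL_LABELS, wholemol_descriptors(parse_structure("c1ccccc1"))))
        assert d["n_aromatic_atoms"] == 6
        assert d["n_halogen_atoms"] == 0

    def test_chloroform(self):
        d = dict(zip(WHOLEMOL_LABELS, wholemol_descriptors(parse_structure("ClC(Cl)Cl"))))
        assert d["n_halogen_atoms"] == 3

    def test_pentane_topological_length(self):
        d = dict(zip(WHOLEMOL_LABELS, wholemol_descriptors(parse_structure("CCCCC"))))
        assert d["topological_length"] == 4

    def test_counts_nonnegative_and_weight_positive(self, synthetic_dataset):
        for smiles in synthetic_dataset.ground_truth.smiles.head(20):
            d = wholemol_descriptors(parse_structure(smiles))
            assert d[WHOLEMOL_LABELS.index("molecular_weight")] > 0
            for label in WHOLEMOL_LABELS:
                if label.startswith("n_") or label == "topological_length":
                    value = d[WHOLEMOL_LABELS.index(label)]
                    assert value >= 0 and value == int(value)


class TestAssembleMatrix:
    def test_wholemol_only_has_ten_raw_columns(self, training_set):
        feat = Featurizer(config=DescriptorConfig(families=frozenset({"wholemol"})))
        feat.fit(training_set.molecules())
        _, labels = feat._raw_matrix(training_set.molecules()[:2])
        assert len(labels) == 10

    def test_standardization(self, training_set):
        x, labels, _ = assemble_matrix(
            training_set.molecules(), DescriptorConfig(mna_top_k=64, qna_resolution=4)
        )
        assert np.allclose(x.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(x.std(axis=0), 1.0, atol=1e-9)
        assert len(labels) == x.shape[1]

    def test_query_time_consistency(self, training_set):
        mols = training_set.molecules()
        x, _, feat = assemble_matrix(mols, DescriptorConfig(mna_top_k=64, qna_resolution=4))
        assert np.array_equal(feat.transform([mols[7]])[0], x[7])

    def test_repeated_calls_bit_identical(self, training_set):
        mols = training_set.molecules()[:30]
        cfg = DescriptorConfig(mna_top_k=32, qna_resolution=4)
        x1, _, _ = assemble_matrix(mols, cfg)
        x2, _, _ = assemble_matrix(mols, cfg)
        assert np.array_equal(x1, x2)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            DescriptorConfig(families=frozenset())
        with pytest.raises(ValueError):
            DescriptorConfig(mna_level=5)
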