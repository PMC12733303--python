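import numpy as np
import pytest

from cytoqsar.chem import parse_structure
from cytoqsar.descriptors import DescriptorConfig
from cytoqsar.engine import (
    krr_loo_residuals,
    loo_q2,
    median_pairwise_width,
    predict_single,
    rbf_fit,
    ridge_loo_residuals,
    ridge_weights,
    scr_select,
    train_single_model,
    _augment,
    _gaussian_kernel,
)


class TestScrSelect:
    def test_recovers_informative_column(self, rng):
        x = rng.normal(size=(60, 10))
        y = 2.0 * x[:, 3] + 0.01 * rng.normal(size=60)
        selected, _, q2 = scr_select(x, y, lam=0.1, min_features=1)
        assert 3 in selected
        assert q2 > 0.9

    def test_constant_target_guard(self, rng):
        x = rng.normal(size=(30, 5))
        y = np.full(30, 5.0)
        _, _, q2 = scr_select(x, y, lam=0.1, min_features=1)
        assert q2 == 0.0

    def test_collinear_duplicate_column_is_redundant(self, rng):
        x = rng.normal(size=(50, 6))
        y = x[:, 0] - x[:, 1] + 0.05 * rng.normal(size=50)
        x_dup = np.column_stack([x, x[:, 5]])  # duplicate a pure-noise column
        sel_a, _, q2_a = scr_select(x, y, lam=0.1, min_features=2)
        sel_b, _, q2_b = scr_select(x_dup, y, lam=0.1, min_features=2)
        assert set(sel_a) == set(sel_b)  # duplicate never enters the best subset
        assert abs(q2_a - q2_b) <= 1e-9

    def test_refuses_tiny_sets(self, rng):
        with pytest.raises(ValueError):
            scr_select(rng.normal(size=(5, 3)), rng.normal(size=5))

    def test_deterministic(self, rng):
        x = rng.normal(size=(40, 8))
        y = x[:, 1] + rng.normal(size=40)
        a = scr_select(x, y, lam=0.1)
        b = scr_select(x, y, lam=0.1)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestLooOracles:
    def test_ridge_loo_equals_explicit_refit(self, rng):
        """Hat-matrix shortcut vs refit-without-i, to 1e-8."""
        for n, d, lam in [(20, 4, 0.1), (50, 10, 1.0), (30, 6, 0.01)]:
            x = rng.normal(size=(n, d))
            y = x @ rng.normal(size=d) + rng.normal(size=n)
            xa = _augment(x)
            shortcut = ridge_loo_residuals(xa, y, lam)
            explicit = np.empty(n)
            for i in range(n):
                keep = np.arange(n) != i
                w = ridge_weights(xa[keep], y[keep], lam)
                explicit[i] = y[i] - xa[i] @ w
            assert np.max(np.abs(shortcut - explicit)) < 1e-8

    def test_krr_loo_equals_explicit_refit(self, rng):
        for n, lam in [(25, 0.1), (40, 1.0)]:
            x = rng.normal(size=(n, 3))
            y = np.sin(x[:, 0]) + 0.1 * rng.normal(size=n)
            width = median_pairwise_width(x)
            yc = y - y.mean()  # offset fixed across refits
            k = _gaussian_kernel(x, x, width)
            shortcut = krr_loo_residuals(k, yc, lam)
            explicit = np.empty(n)
            for i in range(n):
                keep = np.arange(n) != i
                ksub = k[np.ix_(keep, keep)]
                alpha = np.linalg.solve(ksub + lam * np.eye(n - 1), yc[keep])
                explicit[i] = yc[i] - k[i, keep] @ alpha
            assert np.max(np.abs(shortcut - explicit)) < 1e-8


class TestRbfFit:
    def test_interpolation_limit(self, rng):
        x = rng.normal(size=(15, 3))
        y = rng.normal(size=15)
        centers, width, alpha, offset = rbf_fit(x, y, lam_out=1e-10)
        k = _gaussian_kernel(x, centers, width)
        assert np.max(np.abs(offset + k @ alpha - y)) < 1e-6

    def test_constant_target(self, rng):
        x = rng.normal(size=(12, 2))
        y = np.full(12, 5.0)
        centers, width, alpha, offset = rbf_fit(x, y, lam_out=0.1)
        k = _gaussian_kernel(rng.normal(size=(5, 2)), centers, width)
        assert np.allclose(offset + k @ alpha, 5.0)

    def test_width_fallback_on_degenerate_geometry(self):
        x = np.zeros((8, 2))
        assert median_pairwise_width(x) == 1.0

    def test_monotone_regularization(self, rng):
        x = rng.normal(size=(40, 4))
        y = x[:, 0] + 0.3 * rng.normal(size=40)
        r2s = []
        for lam in (0.01, 0.1, 1.0, 10.0):
            centers, width, alpha, offset = rbf_fit(x, y, lam_out=lam)
            yhat = offset + _gaussian_kernel(x, centers, width) @ alpha
            r2s.append(1 - np.sum((y - yhat) ** 2) / np.sum((y - y.mean()) ** 2))
        assert all(a >= b - 1e-12 for a, b in zip(r2s, r2s[1:]))


@pytest.fixture(scope="module")
def model(training_set):
    return train_single_model(
        training_set.molecules(),
        np.asarray(training_set.p_values()),
        DescriptorConfig(mna_top_k=128, qna_resolution=4),
    )


class TestSingleModel:

    def test_synthetic_additive_quality(self, model):
        """Training R2 > LOO Q2 > 0, both comfortably high on the additive fixture."""
        assert model.r2_train > model.q2_loo > 0
        assert model.q2_loo > 0.8 and model.r2_lmo > 0.8

    def test_self_prediction_reproducible(self, model, training_set):
        a = model.predict_molecules(training_set.molecules()[:5])
        b = model.predict_molecules(training_set.molecules()[:5])
        assert np.array_equal(a, b)

    def test_prediction_invariant_to_atom_reordering(self, model, training_set):
        from rdkit import Chem

        smiles = training_set.molecules()[0].source
        base = Chem.MolFromSmiles(smiles)
        perm = np.random.default_rng(0).permutation(base.GetNumAtoms()).tolist()
        shuffled = Chem.MolToSmiles(Chem.RenumberAtoms(base, perm), canonical=False)
        p1 = predict_single(model, parse_structure(smiles))
        p2 = predict_single(model, parse_structure(shuffled))
        assert p1 == pytest.approx(p2, abs=1e-10)

    def test_determinism_across_retrains(self, training_set):
        cfg = DescriptorConfig(mna_top_k=64, qna_resolution=4)
        mols = training_set.molecules()[:60]
        y = np.asarray(training_set.p_values()[:60])
        m1 = train_single_model(mols, y, cfg)
        m2 = train_single_model(mols, y, cfg)
        assert np.array_equal(m1.alpha, m2.alpha)
        assert np.array_equal(m1.selected, m2.selected)
        assert m1.r2_train == m2.r2_train

    def test_kernel_at_distance_zero(self, rng):
        """A query equal to a single isolated center sees a unit kernel."""
        x = np.array([[0.0, 0.0]])
        y = np.array([7.0])
        centers, width, alpha, offset = rbf_fit(x, y, lam_out=0.0, width=1.0)
        assert offset + alpha[0] * 1.0 == pytest.approx(7.0)


class TestSerialization:
    def test_bundle_roundtrip_bit_identical(self, consensus_model, training_set, tmp_path):
        from cytoqsar.bundle import load_bundle, save_bundle

        save_bundle(consensus_model, tmp_path / "bundle")
        loaded = load_bundle(tmp_path / "bundle")
        mols = training_set.molecules()[:10]
        for orig, new in zip(consensus_model.models, loaded.models):
            assert np.array_equal(orig.predict_molecules(mols), new.predict_molecules(mols))
        assert loaded.consensus_rmse == consensus_model.consensus_rmse

    def test_vocab_hash_mismatch_detected(self, consensus_model, tmp_path):
        import json

        from cytoqsar.bundle import load_bundle, save_bundle

        out = save_bundle(consensus_model, tmp_path / "bundle")
        path = out / "model_000.json"
        blob = json.loads(path.read_text())
        blob["featurizer"]["vocab_hash"] = "0" * 16
        path.write_text(json.dumps(blob))
        with pytest.raises(ValueError, match="hash mismatch"):
            load_bundle(out)
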