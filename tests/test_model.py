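"""Message-passing model: baseline identity, invariances, loss contract,
training determinism, persistence."""

import numpy as np
import pandas as pd
import pytest
from rdkit import Chem

from bdekit.featurize import Vocabulary, build_graph
from bdekit.model import (
    BDEPredictor,
    _backward,
    _forward,
    _init_params,
    _pack,
    class_mean_bdes,
    masked_edge_mae,
)
from bdekit.synthetic import DEFAULT_BASE_BDE, gen_molecules


class TestClassMeans:
    def test_examples(self):
        df = pd.DataFrame({"bond_type": ["C-H"], "bde_kcal_mol": [100.0]})
        assert class_mean_bdes(df) == ({"C-H": 100.0}, 100.0)
        df = pd.DataFrame({"bond_type": ["C-H", "C-H"],
                           "bde_kcal_mol": [90.0, 110.0]})
        assert class_mean_bdes(df)[0]["C-H"] == 100.0
        df = pd.DataFrame({"bond_type": ["C-H", "C-C"],
                           "bde_kcal_mol": [100.0, 80.0]})
        means, global_mean = class_mean_bdes(df)
        assert means == {"C-H": 100.0, "C-C": 80.0}
        assert global_mean == 90.0

    def test_empty_dataset(self):
        with pytest.raises(ValueError):
            class_mean_bdes(pd.DataFrame(columns=["bond_type", "bde_kcal_mol"]))


class TestMaskedLoss:
    def test_perfect_predictions(self):
        y = np.array([100.0, 100.0])
        assert masked_edge_mae(y, y, np.array([True, True])) == 0.0

    def test_symmetric_errors_average(self):
        preds = np.array([101.0, 99.0])
        labels = np.array([100.0, 100.0])
        assert masked_edge_mae(preds, labels, np.array([True, True])) == 1.0

    def test_unlabeled_bonds_never_contribute(self):
        labels = np.array([100.0, 100.0, np.nan, np.nan])
        mask = np.isfinite(labels)
        a = masked_edge_mae(np.array([99.0, 99.0, 0.0, 0.0]), labels, mask)
        b = masked_edge_mae(np.array([99.0, 99.0, 1e6, -1e6]), labels, mask)
        assert a == b == 1.0

    def test_all_masked_is_an_error(self):
        with pytest.raises(ValueError):
            masked_edge_mae(np.zeros(2), np.full(2, np.nan),
                            np.array([False, False]))


class TestForward:
    def test_zero_head_gives_exact_class_means(self):
        """The output head starts at zero, so an untrained model predicts
        exactly the per-class mean for every bond."""
        mols = gen_molecules(20, max_heavy=7, seed=9)
        graphs = [build_graph(r.smiles) for r in mols]
        vocab = Vocabulary.fit(graphs)
        model = BDEPredictor(state_dim=16, n_blocks=2, seed=1)
        model.init_baseline(DEFAULT_BASE_BDE, vocab=vocab)
        preds = model.predict([r.smiles for r in mols])
        expected = preds["bond_type"].map(DEFAULT_BASE_BDE)
        assert (preds["bde_pred"] == expected).all()

    def test_methane_symmetry(self, small_model):
        preds = small_model.predict("C")
        assert len(preds) == 4
        assert preds["bde_pred"].nunique() == 1

    def test_permutation_invariance(self, small_model):
        mol = Chem.MolFromSmiles("CC(C)CO")
        ref = small_model.predict("CC(C)CO")["bde_pred"].to_numpy()
        for _ in range(4):
            rand = Chem.MolToSmiles(mol, doRandom=True)
            got = small_model.predict(rand)["bde_pred"].to_numpy()
            assert np.abs(got - ref).max() <= 1e-5

    def test_embedding_shape(self, small_model):
        preds = small_model.predict("CCO", return_embeddings=True)
        assert all(e.shape == (32,) for e in preds["embedding"])


class TestGradients:
    def test_backward_matches_numerical_gradient(self):
        """Full-model analytic gradients agree with central differences."""
        graphs = [build_graph(s) for s in ("CCO", "CNC")]
        vocab = Vocabulary.fit(graphs)
        for g in graphs:
            vocab.encode(g)
        batch = _pack(graphs, {"C-H": 99.0, "C-C": 85.0, "C-O": 85.0,
                               "O-H": 105.0, "C-N": 80.0, "N-H": 93.0},
                      90.0, [{0: 84.0, 2: 100.0}, {0: 80.5, 3: 92.0}])
        rng = np.random.default_rng(0)
        d, nb = 6, 2
        params, buffers = _init_params(rng, vocab.n_atom_classes,
                                       vocab.n_bond_classes, d, nb)
        params = {k: v.astype(np.float64) for k, v in params.items()}
        params["out_w"] = rng.normal(0, 0.1, size=(d, 1))
        params["out_b"] = rng.normal(0, 0.1, size=1)
        buffers = {k: v.astype(np.float64) for k, v in buffers.items()}

        def loss_at(p):
            buf = {k: v.copy() for k, v in buffers.items()}
            y, _ = _forward(p, buf, batch, nb, True)
            return masked_edge_mae(y, batch.labels, batch.mask)

        buf = {k: v.copy() for k, v in buffers.items()}
        y, ctx = _forward(params, buf, batch, nb, True)
        d_scalar = np.where(batch.mask, np.sign(y - batch.labels),
                            0.0) / batch.mask.sum()
        grads = _backward(params, batch, nb, d_scalar, ctx)
        eps = 1e-6
        for key, p in params.items():
            flat = p.ravel()
            for i in rng.choice(flat.size, size=min(4, flat.size),
                                replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp = loss_at(params)
                flat[i] = orig - eps
                lm = loss_at(params)
                flat[i] = orig
                numeric = (lp - lm) / (2 * eps)
                assert abs(numeric - grads[key].ravel()[i]) <= 1e-6, key


class TestTraining:
    def _constant_dataset(self):
        rows = []
        for rec in gen_molecules(30, max_heavy=5, seed=21):
            from bdekit.chem import enumerate_cleavages
            for cl in enumerate_cleavages(rec):
                rows.append({"parent_smiles": cl.parent,
                             "bond_index": cl.bond_index,
                             "bond_type": cl.bond_type,
                             "bde_kcal_mol": 100.0})
        return pd.DataFrame(rows)

    def test_constant_labels_learned_quickly(self):
        """With every label at 100 the class-mean baseline is already
        exact, so validation MAE must collapse almost immediately."""
        df = self._constant_dataset()
        model = BDEPredictor(state_dim=16, n_blocks=2, epochs=10,
                             batch_size=16, seed=0)
        model.fit(df)
        assert model.best_val_mae_ < 0.1

    def test_same_seed_identical_history(self, small_dataset):
        df = small_dataset[small_dataset.split == "train"]
        val = small_dataset[small_dataset.split == "dev"]
        kwargs = dict(state_dim=16, n_blocks=2, epochs=3, batch_size=32,
                      seed=42)
        h1 = BDEPredictor(**kwargs).fit(df, val).history_
        h2 = BDEPredictor(**kwargs).fit(df, val).history_
        pd.testing.assert_frame_equal(h1, h2)

    def test_unlabeled_bonds_do_not_change_training(self, small_dataset):
        """Dropping labels from some bonds (masking them) must not change
        the loss contribution of the labeled rest."""
        df = small_dataset[small_dataset.split == "train"]
        val = small_dataset[small_dataset.split == "dev"]
        kwargs = dict(state_dim=16, n_blocks=2, epochs=2, batch_size=32,
                      seed=7)
        full = BDEPredictor(**kwargs).fit(df, val)
        # keep one labeled bond per molecule
        thinned = df.groupby("parent_smiles", as_index=False).first()
        thin = BDEPredictor(**kwargs).fit(thinned, val)
        assert np.isfinite(thin.best_val_mae_)
        assert len(full.history_) == len(thin.history_)


class TestPersistence:
    def test_save_load_round_trip(self, small_model, tmp_path):
        path = str(tmp_path / "model.bdekit")
        small_model.save(path)
        restored = BDEPredictor.load(path)
        for s in ("CCO", "CC(C)O"):
            a = small_model.predict(s)["bde_pred"].to_numpy()
            b = restored.predict(s)["bde_pred"].to_numpy()
            np.testing.assert_array_equal(a, b)
        assert restored.class_mean_ == small_model.class_mean_

    def test_wrong_schema_rejected(self, tmp_path):
        import json
        import zipfile
        path = str(tmp_path / "bad.bdekit")
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("meta.json", json.dumps({"format_version": 999}))
        with pytest.raises(ValueError, match="format"):
            BDEPredictor.load(path)
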