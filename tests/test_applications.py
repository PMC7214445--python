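"""Weakest-bond site classifier and radical-fragment YSI regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bdekit.applications import (
    RadicalYSIRegressor,
    RankDeficientError,
    candidate_sites,
    fit_ysi,
    loo_cv_ysi,
    metabolism_examples_from_frame,
    roc_from_tolerance_sweep,
    weakest_bond,
)


class TestWeakestBond:
    def test_argmin_and_ties(self):
        assert weakest_bond({0: 100.0, 1: 90.0}) == (1, 90.0)
        assert weakest_bond({0: 90.0, 1: 90.0, 2: 90.0}) == (0, 90.0)
        assert weakest_bond({5: 80.0}) == (5, 80.0)

    def test_empty_error(self):
        with pytest.raises(ValueError):
            weakest_bond({})


class TestCandidateSites:
    def test_examples(self):
        bdes = {0: 100.0, 1: 90.0, 2: 91.0}
        assert candidate_sites(bdes, 1.5) == {1, 2}
        assert candidate_sites(bdes, 0.0) == {1}
        assert candidate_sites(bdes, np.inf) == {0, 1, 2}

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            candidate_sites({0: 1.0}, -0.1)

    @settings(deadline=None, max_examples=50)
    @given(st.dictionaries(st.integers(0, 20),
                           st.floats(50, 150), min_size=1, max_size=10),
           st.floats(0, 10), st.floats(0, 10))
    def test_monotone_in_tolerance(self, bdes, t1, t2):
        lo, hi = sorted((t1, t2))
        assert candidate_sites(bdes, lo) <= candidate_sites(bdes, hi)


class TestROC:
    def test_perfect_labels_auc_one(self):
        rng = np.random.default_rng(0)
        dataset = []
        for _ in range(50):
            bdes = {i: float(v) for i, v in
                    enumerate(rng.uniform(85, 110, rng.integers(3, 8)))}
            site, _ = weakest_bond(bdes)
            dataset.append({"smiles": "x", "ch_bdes": bdes,
                            "site_bonds": {site}})
        assert roc_from_tolerance_sweep(dataset).auc == pytest.approx(1.0)

    def test_single_molecule_curve(self):
        ds = [{"smiles": "x", "ch_bdes": {0: 90.0, 1: 95.0, 2: 100.0},
               "site_bonds": {0}}]
        roc = roc_from_tolerance_sweep(ds)
        # at tolerance 0 the weakest bond alone is positive: TPR 1, FPR 0
        assert roc.tpr[0] == 1.0 and roc.fpr[0] == 0.0
        assert roc.auc == pytest.approx(1.0)

    def test_shift_invariance(self):
        """Adding a constant to one molecule's BDEs never changes the
        curve: only within-molecule gaps matter."""
        rng = np.random.default_rng(1)
        dataset = []
        for _ in range(20):
            bdes = {i: float(v) for i, v in
                    enumerate(rng.uniform(85, 110, 5))}
            dataset.append({"smiles": "x", "ch_bdes": bdes,
                            "site_bonds": {int(rng.integers(0, 5))}})
        base = roc_from_tolerance_sweep(dataset).auc
        shifted = [dict(ex, ch_bdes={b: v + 37.0 for b, v in
                                     ex["ch_bdes"].items()})
                   if i == 3 else ex for i, ex in enumerate(dataset)]
        assert roc_from_tolerance_sweep(shifted).auc == pytest.approx(base)

    def test_roc_monotone(self):
        rng = np.random.default_rng(2)
        dataset = []
        for _ in range(30):
            bdes = {i: float(v) for i, v in enumerate(rng.uniform(85, 110, 6))}
            dataset.append({"smiles": "x", "ch_bdes": bdes,
                            "site_bonds": {int(rng.integers(0, 6))}})
        roc = roc_from_tolerance_sweep(dataset)
        assert (np.diff(roc.tpr) >= 0).all()
        assert (np.diff(roc.fpr) >= 0).all()
        assert 0.0 <= roc.auc <= 1.0

    def test_missing_site_rejected(self):
        with pytest.raises(ValueError):
            roc_from_tolerance_sweep(
                [{"smiles": "x", "ch_bdes": {0: 90.0}, "site_bonds": set()}])

    def test_frame_grouping(self):
        df = pd.DataFrame({
            "smiles": ["a", "a", "b", "b"],
            "bond_index": [0, 1, 0, 1],
            "bde_kcal_mol": [90.0, 95.0, 88.0, 99.0],
            "is_site": [True, False, False, True],
        })
        examples = metabolism_examples_from_frame(df)
        assert examples[0]["site_bonds"] == {0}
        assert examples[1]["site_bonds"] == {1}


def _ysi_frame(rng, weights, n, sigma=1.0, noise=False):
    radicals = list(weights)
    rows = []
    for i in range(n):
        r1, r2 = rng.choice(radicals, 2)
        y = weights[r1] + weights[r2]
        if noise:
            y += rng.normal(0, sigma)
        rows.append({"smiles": f"m{i}", "radical1": r1, "radical2": r2,
                     "ysi": y, "ysi_std": sigma})
    return pd.DataFrame(rows)


class TestYSIFit:
    def test_exact_recovery(self):
        rng = np.random.default_rng(0)
        weights = {f"r{i}": float(w) for i, w in
                   enumerate(rng.uniform(0, 100, 6))}
        df = _ysi_frame(rng, weights, 40)
        model = fit_ysi(df)
        for r in model.kept_radicals_:
            assert model.weights_[r] == pytest.approx(weights[r], abs=1e-8)

    def test_symmetric_molecule(self):
        df = pd.DataFrame({
            "smiles": ["mm", "mm2", "me"],
            "radical1": ["[CH3]", "[CH3]", "[CH3]"],
            "radical2": ["[CH3]", "[CH3]", "CC[O]"],
        })
        df["ysi"] = [60.0, 60.0, 75.0]
        df["ysi_std"] = 1.0
        model = RadicalYSIRegressor(min_support=2).fit(df)
        assert model.weights_["[CH3]"] == pytest.approx(30.0)

    def test_matches_normal_equations(self):
        """The lstsq solution equals the explicit weighted
        normal-equations solution on a dense 20-molecule instance."""
        rng = np.random.default_rng(3)
        weights = {f"r{i}": float(w) for i, w in
                   enumerate(rng.uniform(0, 100, 5))}
        df = _ysi_frame(rng, weights, 20, sigma=2.0, noise=True)
        model = fit_ysi(df)
        kept = model.kept_radicals_
        sub = df[df.radical1.isin(kept) & df.radical2.isin(kept)]
        X = model._design(sub.reset_index(drop=True), kept)
        w2 = 1.0 / sub["ysi_std"].to_numpy() ** 2
        beta = np.linalg.solve(X.T @ (X * w2[:, None]),
                               X.T @ (sub["ysi"].to_numpy() * w2))
        np.testing.assert_allclose([model.weights_[r] for r in kept], beta,
                                   atol=1e-9)

    def test_low_support_radicals_dropped_with_warning(self):
        rng = np.random.default_rng(4)
        weights = {f"r{i}": 10.0 * i for i in range(3)}
        df = _ysi_frame(rng, weights, 12)
        df.loc[len(df)] = {"smiles": "odd", "radical1": "rare",
                           "radical2": "r0", "ysi": 5.0, "ysi_std": 1.0}
        with pytest.warns(UserWarning, match="excluding"):
            model = fit_ysi(df)
        assert "rare" not in model.weights_

    def test_rank_deficiency_reported(self):
        # two radicals that only ever appear together are aliased
        df = pd.DataFrame({
            "smiles": ["a", "b"],
            "radical1": ["r1", "r1"], "radical2": ["r2", "r2"],
            "ysi": [10.0, 10.0], "ysi_std": [1.0, 1.0],
        })
        with pytest.raises(RankDeficientError):
            fit_ysi(df)

    def test_sigma_must_be_positive(self):
        df = pd.DataFrame({"smiles": ["a"], "radical1": ["r"],
                           "radical2": ["r"], "ysi": [1.0], "ysi_std": [0.0]})
        with pytest.raises(ValueError):
            fit_ysi(df)


class TestLOOCV:
    def test_noiseless_predictions_exact(self):
        rng = np.random.default_rng(5)
        weights = {f"r{i}": float(w) for i, w in
                   enumerate(rng.uniform(0, 100, 4))}
        df = _ysi_frame(rng, weights, 30)
        preds, loss = loo_cv_ysi(df)
        assert len(preds) == 30
        exact = preds.loc[preds.available, "ysi_pred"] - \
            preds.loc[preds.available, "ysi"]
        assert np.abs(exact).max() < 1e-8
        assert loss == pytest.approx(0.0, abs=1e-12)

    def test_loss_decreases_with_noise(self):
        rng = np.random.default_rng(6)
        weights = {f"r{i}": float(w) for i, w in
                   enumerate(rng.uniform(0, 100, 4))}
        losses = []
        for sigma in (4.0, 0.5):
            seed_losses = []
            for seed in range(5):
                r = np.random.default_rng(seed)
                df = _ysi_frame(r, weights, 30, sigma=1.0, noise=False)
                df["ysi"] += r.normal(0, sigma, len(df))
                _, loss = loo_cv_ysi(df)
                seed_losses.append(loss)
            losses.append(np.mean(seed_losses))
        assert losses[1] < losses[0]
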