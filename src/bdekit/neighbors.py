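"""Nearest-neighbor interpretation of BDE predictions.

A prediction is trustworthy when the query bond sits close, in the
network's final-layer embedding space, to training bonds with consistent
labels.  The 128-dimensional final edge states of all labeled training
bonds are reduced to 10 dimensions by PCA (mean-centered, no whitening)
and queries are answered by Euclidean nearest-neighbor search in that
space, ties broken by corpus order.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)


class BondEmbeddingIndex(BaseEstimator):
    """PCA-projected index of training-bond embeddings.

    Parameters
    ----------
    n_components : int
        Output dimensionality of the PCA projection.
    k : int
        Default number of neighbors returned by :meth:`nearest_bonds`.
    """

    def __init__(self, n_components: int = 10, k: int = 10):
        self.n_components = n_components
        self.k = k

    def fit(self, model, training_bonds: pd.DataFrame):
        """Build the index from a fitted :class:`BDEPredictor` and a table
        of labeled bonds (columns ``parent_smiles, bond_index,
        bde_kcal_mol``)."""
        if len(training_bonds) < self.n_components:
            raise ValueError(
                f"corpus of {len(training_bonds)} bonds is smaller than "
                f"n_components={self.n_components}")
        embeddings = model.bond_embeddings(training_bonds)
        self.pca_ = PCA(n_components=self.n_components)
        self.corpus_ = self.pca_.fit_transform(embeddings)
        self.refs_ = training_bonds.reset_index(drop=True)[
            ["parent_smiles", "bond_index", "bde_kcal_mol"]
        ].copy()
        if "bond_type" in training_bonds.columns:
            self.refs_["bond_type"] = training_bonds["bond_type"].to_numpy()
        logger.info(
            "bond embedding index: %d bonds, %.1f%% variance in %d components",
            len(self.refs_),
            100 * self.pca_.explained_variance_ratio_.sum(),
            self.n_components,
        )
        return self

    def nearest_bonds(self, model, query_smiles: str, query_bond: int,
                      k: Optional[int] = None) -> pd.DataFrame:
        """The *k* corpus bonds closest to one query bond.

        Returns a frame ranked by ascending Euclidean distance in the
        projected space (ties broken by corpus order) with columns
        ``rank, parent_smiles, bond_index, bde_kcal_mol, distance``.
        """
        k = self.k if k is None else k
        if k > len(self.refs_):
            raise ValueError(f"k={k} exceeds corpus size {len(self.refs_)}")
        query = pd.DataFrame({"parent_smiles": [query_smiles],
                              "bond_index": [query_bond]})
        emb = model.bond_embeddings(query)
        proj = self.pca_.transform(emb)
        dist = cdist(proj, self.corpus_)[0]
        order = np.argsort(dist, kind="stable")[:k]
        out = self.refs_.iloc[order].reset_index(drop=True)
        out.insert(0, "rank", np.arange(1, k + 1))
        out["distance"] = dist[order]
        return out


def build_index(model, training_bonds: pd.DataFrame,
                n_components: int = 10) -> BondEmbeddingIndex:
    """Functional wrapper over :class:`BondEmbeddingIndex.fit`."""
    return BondEmbeddingIndex(n_components=n_components).fit(model, training_bonds)


def nearest_bonds(index: BondEmbeddingIndex, model, query_smiles: str,
                  query_bond: int, k: int = 10) -> pd.DataFrame:
    """Functional wrapper over :meth:`BondEmbeddingIndex.nearest_bonds`."""
    return index.nearest_bonds(model, query_smiles, query_bond, k=k)
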