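"""Directed-edge message-passing network for bond dissociation enthalpies.

The model embeds atom and bond classes into ``state_dim``-dimensional
vectors and refines them through ``n_blocks`` message-passing blocks.  In
each block, states are batch-normalized, bond states are updated from the
states of their two endpoint atoms, and atom states are then updated by
summing transformed messages over their incident directed edges; residual
connections wrap both updates.  The final edge state is reduced by a
linear head to a scalar which is added to the mean BDE of the bond's type
class, so an untrained (zero) head already predicts the class-mean
baseline.  During training each directed edge is scored separately
against the bond label; at prediction time the two directions are
averaged.

Exposed as :class:`BDEPredictor`, a scikit-learn style estimator.
"""

from __future__ import annotations

import copy
import io
import json
import logging
import zipfile
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, RegressorMixin

from . import nn
from .featurize import MolGraph, Vocabulary, build_graph

logger = logging.getLogger(__name__)

_FORMAT_VERSION = 1


class NumericError(RuntimeError):
    """Raised when a non-finite activation or loss is encountered."""


@dataclass
class Batch:
    """A set of molecule graphs packed into one disjoint graph."""

    atom_ids: np.ndarray        # (n_atoms,)
    edge_ids: np.ndarray        # (n_edges,)
    src: np.ndarray             # (n_edges,) source atom of each edge
    dst: np.ndarray             # (n_edges,) target atom of each edge
    g_src: sp.csr_matrix        # (n_edges, n_atoms) selection by source
    g_dst: sp.csr_matrix        # (n_edges, n_atoms) selection by target
    class_mean_edge: np.ndarray  # (n_edges,) per-edge class-mean baseline
    labels: np.ndarray          # (n_edges,) NaN where unlabeled
    mask: np.ndarray            # (n_edges,) bool, True where labeled
    bond_types: list            # per bond
    mol_slices: list            # (smiles, bond_lo, bond_hi) per molecule
    graphs: list


def _pack(graphs: Sequence[MolGraph], class_mean: dict, global_mean: float,
          labels_per_mol: Optional[Sequence[dict]] = None) -> Batch:
    atom_ids, edge_ids, src, dst = [], [], [], []
    cmeans, labels, bond_types, mol_slices = [], [], [], []
    offset = 0
    bond_lo = 0
    for gi, g in enumerate(graphs):
        if g.atom_class_ids is None:
            raise RuntimeError("graph must be encoded against a vocabulary")
        atom_ids.append(g.atom_class_ids)
        edge_ids.append(g.edge_class_ids)
        src.append(g.edges[:, 0] + offset)
        dst.append(g.edges[:, 1] + offset)
        lab = labels_per_mol[gi] if labels_per_mol is not None else {}
        for b, btype in enumerate(g.bond_types):
            cm = class_mean.get(btype, global_mean)
            cmeans.extend((cm, cm))
            y = lab.get(b, np.nan)
            labels.extend((y, y))
            bond_types.append(btype)
        mol_slices.append((g.smiles, bond_lo, bond_lo + g.n_bonds))
        bond_lo += g.n_bonds
        offset += g.n_atoms
    atom_ids = np.concatenate(atom_ids)
    edge_ids = np.concatenate(edge_ids)
    src = np.concatenate(src)
    dst = np.concatenate(dst)
    n_edges, n_atoms = src.size, atom_ids.size
    ones = np.ones(n_edges, dtype=np.float32)
    rows = np.arange(n_edges)
    g_src = sp.csr_matrix((ones, (rows, src)), shape=(n_edges, n_atoms))
    g_dst = sp.csr_matrix((ones, (rows, dst)), shape=(n_edges, n_atoms))
    labels = np.asarray(labels, dtype=np.float64)
    return Batch(
        atom_ids=atom_ids, edge_ids=edge_ids, src=src, dst=dst,
        g_src=g_src, g_dst=g_dst,
        class_mean_edge=np.asarray(cmeans, dtype=np.float64),
        labels=labels, mask=np.isfinite(labels),
        bond_types=bond_types, mol_slices=mol_slices, graphs=list(graphs),
    )


def class_mean_bdes(labels: pd.DataFrame) -> tuple:
    """Per-bond-type mean BDE and the global mean, from a table with
    columns ``bond_type`` and ``bde_kcal_mol``."""
    if len(labels) == 0:
        raise ValueError("empty dataset: cannot compute class means")
    means = labels.groupby("bond_type")["bde_kcal_mol"].mean().to_dict()
    return means, float(labels["bde_kcal_mol"].mean())


def masked_edge_mae(predictions: np.ndarray, labels: np.ndarray,
                    mask: np.ndarray) -> float:
    """Mean absolute error over labeled directed edges (each labeled bond
    contributes its two directions)."""
    if not mask.any():
        raise ValueError("all bonds masked: no labeled edges in batch")
    return float(np.abs(predictions[mask] - labels[mask]).mean())


def _init_params(rng: np.random.Generator, n_atom_classes: int,
                 n_bond_classes: int, d: int, n_blocks: int,
                 edge_mlp_layers: int = 1) -> tuple:
    params = {
        "atom_embed": nn.embedding_init(rng, n_atom_classes, d),
        "bond_embed": nn.embedding_init(rng, n_bond_classes, d),
        "out_w": np.zeros((d, 1), dtype=np.float32),
        "out_b": np.zeros(1, dtype=np.float32),
    }
    buffers = {}
    for k in range(n_blocks):
        params[f"b{k}_bn_a_gamma"] = np.ones(d, dtype=np.float32)
        params[f"b{k}_bn_a_beta"] = np.zeros(d, dtype=np.float32)
        params[f"b{k}_bn_e_gamma"] = np.ones(d, dtype=np.float32)
        params[f"b{k}_bn_e_beta"] = np.zeros(d, dtype=np.float32)
        params[f"b{k}_W_e"] = nn.glorot_uniform(rng, (3 * d, d))
        params[f"b{k}_b_e"] = np.zeros(d, dtype=np.float32)
        if edge_mlp_layers == 2:
            params[f"b{k}_W_e2"] = nn.glorot_uniform(rng, (d, d))
            params[f"b{k}_b_e2"] = np.zeros(d, dtype=np.float32)
        params[f"b{k}_W_a"] = nn.glorot_uniform(rng, (d, d))
        params[f"b{k}_b_a"] = np.zeros(d, dtype=np.float32)
        buffers[f"b{k}_bn_a_mean"] = np.zeros(d, dtype=np.float32)
        buffers[f"b{k}_bn_a_var"] = np.ones(d, dtype=np.float32)
        buffers[f"b{k}_bn_e_mean"] = np.zeros(d, dtype=np.float32)
        buffers[f"b{k}_bn_e_var"] = np.ones(d, dtype=np.float32)
    return params, buffers


def _forward(params: dict, buffers: dict, batch: Batch, n_blocks: int,
             training: bool):
    """Run the network; returns (edge_scalars, caches).

    ``edge_scalars`` already include the class-mean baseline.
    """
    a = params["atom_embed"][batch.atom_ids]
    e = params["bond_embed"][batch.edge_ids]
    caches = []
    for k in range(n_blocks):
        an, cache_a = nn.batchnorm_forward(
            a, params[f"b{k}_bn_a_gamma"], params[f"b{k}_bn_a_beta"],
            buffers[f"b{k}_bn_a_mean"], buffers[f"b{k}_bn_a_var"], training)
        en, cache_e = nn.batchnorm_forward(
            e, params[f"b{k}_bn_e_gamma"], params[f"b{k}_bn_e_beta"],
            buffers[f"b{k}_bn_e_mean"], buffers[f"b{k}_bn_e_var"], training)
        h = np.concatenate([an[batch.src], an[batch.dst], en], axis=1)
        z_pre = h @ params[f"b{k}_W_e"] + params[f"b{k}_b_e"]
        z1 = nn.relu(z_pre)
        if f"b{k}_W_e2" in params:
            z2_pre = z1 @ params[f"b{k}_W_e2"] + params[f"b{k}_b_e2"]
            z = nn.relu(z2_pre)
        else:
            z2_pre, z = None, z1
        e = e + z
        m_pre = z @ params[f"b{k}_W_a"] + params[f"b{k}_b_a"]
        m = nn.relu(m_pre)
        a = a + batch.g_dst.T @ m
        if training:
            caches.append((cache_a, cache_e, h, z_pre, z1, z2_pre, z, m_pre))
        if not np.isfinite(e).all():
            raise NumericError(f"non-finite bond state in block {k}")
    scalar = (e @ params["out_w"]).ravel() + params["out_b"][0]
    edge_scalars = scalar.astype(np.float64) + batch.class_mean_edge
    return edge_scalars, (caches, a, e)


def _backward(params: dict, batch: Batch, n_blocks: int, d_scalar: np.ndarray,
              ctx) -> dict:
    caches, _a_final, e_final = ctx
    d = params["out_w"].shape[0]
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    d_scalar = d_scalar.astype(e_final.dtype)
    grads["out_w"] = e_final.T @ d_scalar[:, None]
    grads["out_b"] = np.array([d_scalar.sum()], dtype=e_final.dtype)
    de = d_scalar[:, None] * params["out_w"].T
    da = np.zeros((batch.atom_ids.size, d), dtype=np.float32)
    for k in reversed(range(n_blocks)):
        cache_a, cache_e, h, z_pre, z1, z2_pre, z, m_pre = caches[k]
        # atom update: a_out = a_in + G_dst^T @ relu(z @ W_a + b_a)
        dm = batch.g_dst @ da
        dm_pre = nn.relu_backward(dm, m_pre)
        grads[f"b{k}_W_a"] = z.T @ dm_pre
        grads[f"b{k}_b_a"] = dm_pre.sum(axis=0)
        dz = dm_pre @ params[f"b{k}_W_a"].T
        # bond update: e_out = e_in + edge MLP(h)
        dz += de
        if z2_pre is not None:
            dz2_pre = nn.relu_backward(dz, z2_pre)
            grads[f"b{k}_W_e2"] = z1.T @ dz2_pre
            grads[f"b{k}_b_e2"] = dz2_pre.sum(axis=0)
            dz = dz2_pre @ params[f"b{k}_W_e2"].T
        dz_pre = nn.relu_backward(dz, z_pre)
        grads[f"b{k}_W_e"] = h.T @ dz_pre
        grads[f"b{k}_b_e"] = dz_pre.sum(axis=0)
        dh = dz_pre @ params[f"b{k}_W_e"].T
        dan = batch.g_src.T @ dh[:, :d] + batch.g_dst.T @ dh[:, d:2 * d]
        den = dh[:, 2 * d:]
        dan_in, dga, dba = nn.batchnorm_backward(dan, cache_a)
        den_in, dge, dbe = nn.batchnorm_backward(den, cache_e)
        grads[f"b{k}_bn_a_gamma"] = dga
        grads[f"b{k}_bn_a_beta"] = dba
        grads[f"b{k}_bn_e_gamma"] = dge
        grads[f"b{k}_bn_e_beta"] = dbe
        da = da + dan_in
        de = de + den_in
    np.add.at(grads["atom_embed"], batch.atom_ids, da)
    np.add.at(grads["bond_embed"], batch.edge_ids, de)
    return grads


class BDEPredictor(BaseEstimator, RegressorMixin):
    """Predict homolytic BDEs (kcal/mol) for every acyclic single bond of
    a molecule given only its SMILES.

    Parameters
    ----------
    state_dim : int
        Width of atom/bond state vectors (one shared width).
    n_blocks : int
        Number of message-passing blocks.
    lr, lr_decay : float
        ADAM learning rate and inverse-time decay per update step.
    batch_size : int
        Molecules per training batch.
    epochs : int
        Training epochs; the returned model is the best-validation state.
    val_fraction : float
        Fraction of training molecules held out for validation when no
        explicit validation set is passed to :meth:`fit`.
    seed : int
        Seed controlling initialization and batching; two fits with the
        same seed and data are identical.
    """

    def __init__(self, state_dim: int = 128, n_blocks: int = 6,
                 lr: float = 1e-3, lr_decay: float = 1e-5,
                 batch_size: int = 128, epochs: int = 500,
                 val_fraction: float = 0.1, edge_mlp_layers: int = 1,
                 seed: int = 0):
        self.state_dim = state_dim
        self.n_blocks = n_blocks
        self.lr = lr
        self.lr_decay = lr_decay
        self.batch_size = batch_size
        self.epochs = epochs
        self.val_fraction = val_fraction
        self.edge_mlp_layers = edge_mlp_layers
        self.seed = seed

    # ------------------------------------------------------------------
    def _graphs_and_labels(self, df: pd.DataFrame, vocab: Optional[Vocabulary]):
        """Group a labeled bond table by molecule into encoded graphs and
        per-molecule ``{bond_index: bde}`` dicts."""
        graphs, labels = [], []
        for smiles, grp in df.groupby("parent_smiles", sort=True):
            g = build_graph(smiles)
            if vocab is not None:
                vocab.encode(g)
            graphs.append(g)
            labels.append(dict(zip(grp["bond_index"].astype(int),
                                   grp["bde_kcal_mol"].astype(float))))
        return graphs, labels

    def fit(self, X: pd.DataFrame, X_val: Optional[pd.DataFrame] = None):
        """Train on a bond table with columns ``parent_smiles``,
        ``bond_index``, ``bond_type``, ``bde_kcal_mol``."""
        df = X.copy()
        if "bond_type" not in df.columns:
            raise ValueError("training table requires a bond_type column")
        rng = np.random.default_rng(self.seed)

        if X_val is None:
            mols = np.array(sorted(df["parent_smiles"].unique()))
            rng.shuffle(mols)
            n_val = max(1, int(round(self.val_fraction * len(mols))))
            val_mols = set(mols[:n_val])
            df_val = df[df["parent_smiles"].isin(val_mols)]
            df_train = df[~df["parent_smiles"].isin(val_mols)]
        else:
            df_train, df_val = df, X_val.copy()

        train_graphs, train_labels = self._graphs_and_labels(df_train, None)
        vocab = Vocabulary.fit(train_graphs)
        for g in train_graphs:
            vocab.encode(g)
        val_graphs, val_labels = self._graphs_and_labels(df_val, vocab)

        class_mean, global_mean = class_mean_bdes(df_train)
        self.vocab_ = vocab
        self.class_mean_ = class_mean
        self.global_mean_ = global_mean

        params, buffers = _init_params(
            rng, vocab.n_atom_classes, vocab.n_bond_classes,
            self.state_dim, self.n_blocks, self.edge_mlp_layers)

        # fixed batch composition (shuffled once); batch order reshuffled
        # each epoch so batch-norm statistics do not lock to one ordering
        order = rng.permutation(len(train_graphs))
        batches = []
        for lo in range(0, len(order), self.batch_size):
            idx = order[lo:lo + self.batch_size]
            batches.append(_pack([train_graphs[i] for i in idx],
                                 class_mean, global_mean,
                                 [train_labels[i] for i in idx]))
        val_batch = _pack(val_graphs, class_mean, global_mean, val_labels)

        opt = nn.Adam(params, lr=self.lr, decay=self.lr_decay)
        history = []
        best = (np.inf, None, None)
        for epoch in range(self.epochs):
            epoch_losses = []
            for bi in rng.permutation(len(batches)):
                batch = batches[bi]
                y, ctx = _forward(params, buffers, batch, self.n_blocks, True)
                resid = y - batch.labels
                loss = masked_edge_mae(y, batch.labels, batch.mask)
                if not np.isfinite(loss):
                    raise NumericError(f"training diverged at epoch {epoch}")
                n_lab = int(batch.mask.sum())
                d_scalar = np.where(batch.mask, np.sign(resid), 0.0) / n_lab
                grads = _backward(params, batch, self.n_blocks, d_scalar, ctx)
                opt.step(params, grads)
                epoch_losses.append(loss)
            val_mae = self._eval_mae(params, buffers, val_batch)
            history.append({"epoch": epoch,
                            "train_mae": float(np.mean(epoch_losses)),
                            "val_mae": val_mae})
            if val_mae < best[0]:
                best = (val_mae, copy.deepcopy(params), copy.deepcopy(buffers))
        self.params_ = best[1] if best[1] is not None else params
        self.buffers_ = best[2] if best[2] is not None else buffers
        self.best_val_mae_ = best[0]
        self.history_ = pd.DataFrame(history)
        return self

    def _eval_mae(self, params, buffers, batch: Batch) -> float:
        """Per-bond MAE (two directions averaged) over labeled bonds."""
        y, _ = _forward(params, buffers, batch, self.n_blocks, False)
        bond_pred = 0.5 * (y[0::2] + y[1::2])
        bond_label = batch.labels[0::2]
        mask = np.isfinite(bond_label)
        return float(np.abs(bond_pred[mask] - bond_label[mask]).mean())

    # ------------------------------------------------------------------
    def _require_fitted(self):
        if not hasattr(self, "params_"):
            raise RuntimeError("BDEPredictor is not fitted")

    def init_baseline(self, class_mean: Dict[str, float],
                      global_mean: Optional[float] = None,
                      vocab: Optional[Vocabulary] = None,
                      graphs: Optional[Sequence[MolGraph]] = None):
        """Initialize an untrained model whose predictions are exactly the
        per-class mean BDEs (the zero output head makes the network's
        contribution vanish)."""
        rng = np.random.default_rng(self.seed)
        if vocab is None:
            vocab = Vocabulary.fit(graphs or [])
        self.vocab_ = vocab
        self.class_mean_ = dict(class_mean)
        self.global_mean_ = (global_mean if global_mean is not None
                             else float(np.mean(list(class_mean.values()))))
        self.params_, self.buffers_ = _init_params(
            rng, vocab.n_atom_classes, vocab.n_bond_classes,
            self.state_dim, self.n_blocks, self.edge_mlp_layers)
        self.history_ = pd.DataFrame()
        return self

    def predict(self, smiles: "str | Sequence[str]",
                return_embeddings: bool = False) -> pd.DataFrame:
        """Predict BDEs for every bond of one or more molecules.

        Returns a frame with columns ``parent_smiles, bond_index,
        bond_type, bde_pred`` (plus ``embedding`` when requested: the
        final edge state of the canonical-direction edge).
        """
        self._require_fitted()
        single = isinstance(smiles, str)
        smiles_list = [smiles] if single else list(smiles)
        graphs = []
        for s in smiles_list:
            g = build_graph(s)
            self.vocab_.encode(g)
            if (g.atom_class_ids == 0).any() or (g.edge_class_ids == 0).any():
                logger.warning("out-of-vocabulary atom/bond classes in %s", s)
            graphs.append(g)
        batch = _pack(graphs, self.class_mean_, self.global_mean_)
        y, (_, _, e_final) = _forward(
            self.params_, self.buffers_, batch, self.n_blocks, False)
        bond_pred = 0.5 * (y[0::2] + y[1::2])
        rows = []
        bond_offset = 0
        edge_offset = 0
        for g, (smi, lo, hi) in zip(batch.graphs, batch.mol_slices):
            for b in range(g.n_bonds):
                row = {
                    "parent_smiles": smi,
                    "bond_index": b,
                    "bond_type": g.bond_types[b],
                    "bde_pred": bond_pred[lo + b],
                }
                if return_embeddings:
                    row["embedding"] = e_final[edge_offset + g.canonical_edge(b)].copy()
                rows.append(row)
            bond_offset += g.n_bonds
            edge_offset += g.n_edges
        return pd.DataFrame(rows)

    def bond_embeddings(self, bonds: pd.DataFrame) -> np.ndarray:
        """Final-layer edge states for rows of (parent_smiles, bond_index)."""
        self._require_fitted()
        preds = self.predict(bonds["parent_smiles"].unique(),
                             return_embeddings=True)
        lookup = {(r.parent_smiles, r.bond_index): r.embedding
                  for r in preds.itertuples()}
        keys = [
            (build_graph(s).smiles, int(b))
            for s, b in zip(bonds["parent_smiles"], bonds["bond_index"])
        ]
        return np.stack([lookup[k] for k in keys])

    # ------------------------------------------------------------------
    def save(self, path: str) -> None:
        """Serialize the fitted model (arrays + JSON metadata) to a single
        zip archive."""
        self._require_fitted()
        meta = {
            "format_version": _FORMAT_VERSION,
            "config": {k: getattr(self, k) for k in (
                "state_dim", "n_blocks", "lr", "lr_decay", "batch_size",
                "epochs", "val_fraction", "edge_mlp_layers", "seed")},
            "class_mean": self.class_mean_,
            "global_mean": self.global_mean_,
            "vocab": self.vocab_.to_dict(),
        }
        buf = io.BytesIO()
        np.savez(buf, **self.params_, **{f"buf_{k}": v
                                         for k, v in self.buffers_.items()})
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("meta.json", json.dumps(meta))
            zf.writestr("arrays.npz", buf.getvalue())

    @classmethod
    def load(cls, path: str) -> "BDEPredictor":
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            if meta.get("format_version") != _FORMAT_VERSION:
                raise ValueError(
                    f"unsupported model format: {meta.get('format_version')}")
            arrays = np.load(io.BytesIO(zf.read("arrays.npz")))
            model = cls(**meta["config"])
            model.params_ = {k: arrays[k] for k in arrays.files
                             if not k.startswith("buf_")}
            model.buffers_ = {k[4:]: arrays[k] for k in arrays.files
                              if k.startswith("buf_")}
        model.class_mean_ = meta["class_mean"]
        model.global_mean_ = meta["global_mean"]
        model.vocab_ = Vocabulary.from_dict(meta["vocab"])
        model.history_ = pd.DataFrame()
        return model
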