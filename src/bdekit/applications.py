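"""Downstream models driven by BDE predictions.

Two applications of the weakest-bond principle:

* **Site-of-metabolism classification.**  Cytochrome-P450 oxidation of a
  drug correlates with its weakest C-H bond, so bonds within an energy
  tolerance of the molecule's minimum BDE are flagged as candidate sites.
  Sweeping the tolerance traces a ROC curve over all bonds pooled across
  molecules.

* **Sooting-tendency (YSI) regression.**  A fuel molecule's yield sooting
  index is modeled as the sum of two per-radical weights, one for each
  radical formed at its weakest bond, fitted by weighted least squares
  (weights 1/sigma^2 from the experimental uncertainties, no intercept).
  Only radicals produced by at least two molecules are identifiable and
  kept.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# site-of-metabolism classification


def weakest_bond(bdes: Mapping[int, float]) -> Tuple[int, float]:
    """Bond id and BDE of the weakest bond; ties go to the smallest id."""
    if not bdes:
        raise ValueError("empty BDE map")
    bond = min(sorted(bdes), key=lambda b: (bdes[b], b))
    return bond, bdes[bond]


def candidate_sites(bdes: Mapping[int, float], tolerance: float) -> Set[int]:
    """Bonds within *tolerance* kcal/mol of the molecule's weakest bond."""
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    _, minimum = weakest_bond(bdes)
    return {b for b, v in bdes.items() if v <= minimum + tolerance}


@dataclass
class ROCResult:
    """ROC of the tolerance-sweep classifier over pooled bonds."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    auc: float


def roc_from_tolerance_sweep(dataset: Sequence[dict]) -> ROCResult:
    """Sweep the energy tolerance and score the candidate-site classifier.

    *dataset* holds dicts with ``ch_bdes`` ({bond id: kcal/mol}) and
    ``site_bonds`` (non-empty set of labeled bond ids).  Bonds are pooled
    across molecules; for each tolerance on the grid of all distinct
    within-molecule BDE gaps, a bond is positive iff it lies within the
    tolerance of its own molecule's minimum.  AUC is the trapezoidal area
    under (FPR, TPR) with endpoints (0,0) and (1,1).
    """
    gaps, labels = [], []
    for ex in dataset:
        bdes = ex["ch_bdes"]
        sites = set(ex["site_bonds"])
        if not sites:
            raise ValueError(f"molecule {ex.get('smiles')!r} has no labeled site")
        if not sites <= set(bdes):
            raise ValueError(
                f"site bonds {sites} not among scored bonds of {ex.get('smiles')!r}")
        _, minimum = weakest_bond(bdes)
        for b, v in bdes.items():
            gaps.append(v - minimum)
            labels.append(b in sites)
    gaps = np.asarray(gaps)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    thresholds = np.unique(gaps)
    tpr, fpr, precision, recall = [], [], [], []
    for tau in thresholds:
        pred = gaps <= tau
        tp = int((pred & labels).sum())
        fp = int((pred & ~labels).sum())
        tpr.append(tp / n_pos if n_pos else 0.0)
        fpr.append(fp / n_neg if n_neg else 0.0)
        precision.append(tp / pred.sum() if pred.any() else 1.0)
        recall.append(tp / n_pos if n_pos else 0.0)
    fpr_c = np.concatenate([[0.0], fpr, [1.0]])
    tpr_c = np.concatenate([[0.0], tpr, [1.0]])
    auc = float(np.trapezoid(tpr_c, fpr_c))
    return ROCResult(
        thresholds=thresholds, tpr=np.asarray(tpr), fpr=np.asarray(fpr),
        precision=np.asarray(precision), recall=np.asarray(recall), auc=auc,
    )


def metabolism_examples_from_frame(df: pd.DataFrame) -> List[dict]:
    """Group a CSV-shaped table (columns ``smiles, bond_index,
    bde_kcal_mol, is_site``) into per-molecule examples."""
    out = []
    for smiles, grp in df.groupby("smiles", sort=False):
        bdes = dict(zip(grp["bond_index"].astype(int),
                        grp["bde_kcal_mol"].astype(float)))
        sites = set(grp.loc[grp["is_site"].astype(bool), "bond_index"].astype(int))
        out.append({"smiles": smiles, "ch_bdes": bdes, "site_bonds": sites})
    return out


# ----------------------------------------------------------------------
# YSI radical-fragment regression


class RankDeficientError(ValueError):
    """Raised when the radical design matrix is not full column rank."""


class RadicalYSIRegressor(BaseEstimator, RegressorMixin):
    """Weighted least-squares YSI model over weakest-bond radical pairs.

    Each molecule is represented by only two parameters — the weights of
    the two radicals formed at its weakest bond — so the design row is
    the count of each kept radical in the pair (2 when the pair is
    symmetric) and there is no intercept.  The fit minimizes
    ``sum_i (ysi_i - x_i @ w)^2 / sigma_i^2``.

    Parameters
    ----------
    min_support : int
        Minimum number of molecules a radical must appear in to receive a
        weight; molecules containing a rarer radical are excluded (with a
        warning).
    """

    def __init__(self, min_support: int = 2):
        self.min_support = min_support

    def _design(self, df: pd.DataFrame, radicals: List[str]) -> np.ndarray:
        col = {r: i for i, r in enumerate(radicals)}
        X = np.zeros((len(df), len(radicals)))
        for row_i, (r1, r2) in enumerate(zip(df["radical1"], df["radical2"])):
            X[row_i, col[r1]] += 1.0
            X[row_i, col[r2]] += 1.0
        return X

    def fit(self, X: pd.DataFrame, y=None):
        """Fit on a table with columns ``radical1, radical2, ysi,
        ysi_std`` (one row per molecule)."""
        df = X.reset_index(drop=True)
        if (df["ysi_std"] <= 0).any():
            raise ValueError("ysi_std must be positive")
        counts = pd.concat([df["radical1"], df["radical2"]]).value_counts()
        kept = sorted(counts[counts >= self.min_support].index)
        keep_row = (df["radical1"].isin(kept) & df["radical2"].isin(kept))
        n_dropped = int((~keep_row).sum())
        if n_dropped:
            warnings.warn(
                f"excluding {n_dropped} molecules containing radicals seen in "
                f"fewer than {self.min_support} molecules")
        df = df[keep_row].reset_index(drop=True)
        Xd = self._design(df, kept)
        rank = np.linalg.matrix_rank(Xd)
        if rank < len(kept):
            _, _, vt = np.linalg.svd(Xd)
            aliased = [kept[i] for i in np.argsort(np.abs(vt[-1]))[::-1][:3]]
            raise RankDeficientError(
                f"design matrix rank {rank} < {len(kept)} radicals; "
                f"aliased radicals include {aliased}")
        w = 1.0 / df["ysi_std"].to_numpy()
        sol, res, *_ = np.linalg.lstsq(Xd * w[:, None],
                                       df["ysi"].to_numpy() * w, rcond=None)
        self.kept_radicals_ = kept
        self.weights_ = dict(zip(kept, map(float, sol)))
        fitted = Xd @ sol
        self.residual_norm_ = float(np.linalg.norm(
            (df["ysi"].to_numpy() - fitted) * w))
        self.n_fit_ = len(df)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Predicted YSI = sum of the two radical weights; NaN when a
        radical has no fitted weight."""
        out = np.empty(len(X))
        for i, (r1, r2) in enumerate(zip(X["radical1"], X["radical2"])):
            w1 = self.weights_.get(r1)
            w2 = self.weights_.get(r2)
            out[i] = np.nan if w1 is None or w2 is None else w1 + w2
        return out

    def standard_errors(self, X: pd.DataFrame) -> Dict[str, float]:
        """Analytic WLS standard errors of the radical weights, assuming
        the stored ``ysi_std`` are the true noise scales."""
        df = X[X["radical1"].isin(self.kept_radicals_)
               & X["radical2"].isin(self.kept_radicals_)]
        Xd = self._design(df.reset_index(drop=True), self.kept_radicals_)
        w2 = 1.0 / df["ysi_std"].to_numpy() ** 2
        cov = np.linalg.inv(Xd.T @ (Xd * w2[:, None]))
        return dict(zip(self.kept_radicals_, np.sqrt(np.diag(cov))))


def fit_ysi(dataset: pd.DataFrame, min_support: int = 2) -> RadicalYSIRegressor:
    """Functional wrapper over :class:`RadicalYSIRegressor`."""
    return RadicalYSIRegressor(min_support=min_support).fit(dataset)


def loo_cv_ysi(dataset: pd.DataFrame, min_support: int = 2) -> Tuple[pd.DataFrame, float]:
    """Leave-one-out cross-validation of the YSI model.

    Each fold removes one molecule, refits on the remainder and predicts
    the held-out value.  Folds where the held-out molecule's radicals lose
    identifiability (support below *min_support* or a rank-deficient
    design) are marked unavailable.  Returns (per-molecule frame with
    columns ``smiles, ysi, ysi_std, ysi_pred, available``, weighted
    squared loss over available folds).
    """
    df = dataset.reset_index(drop=True)
    preds = np.full(len(df), np.nan)
    for i in range(len(df)):
        rest = df.drop(index=i)
        model = RadicalYSIRegressor(min_support=min_support)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(rest)
            pred = model.predict(df.iloc[[i]])[0]
        except (RankDeficientError, np.linalg.LinAlgError):
            continue
        preds[i] = pred
    available = np.isfinite(preds)
    loss = float(np.nansum(
        ((preds - df["ysi"].to_numpy()) / df["ysi_std"].to_numpy())[available] ** 2
    ))
    out = df[["smiles", "ysi", "ysi_std"]].copy() if "smiles" in df.columns \
        else df[["ysi", "ysi_std"]].copy()
    out["ysi_pred"] = preds
    out["available"] = available
    return out, loss
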