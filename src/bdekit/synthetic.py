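"""Synthetic molecules and ground-truth labels for desk-scale experiments.

Real BDE labels come from quantum chemistry; running such calculations is
far outside desk scale, so this module provides a *learnability fixture*:
random valence-valid C/H/O/N molecules plus a deterministic BDE oracle
whose value depends only on the bond-type class and on the radius-2
environment of the cleaved bond.  Because the oracle is graph-local, a
six-block message-passing network can represent it exactly, which lets
the training pipeline be exercised end to end with known ground truth.

The oracle is base[bond_type] + f(environment) + Gaussian noise, where f
maps a salt-free 64-bit hash of the canonical radius-2 fragment SMILES
uniformly onto [-env_amplitude, +env_amplitude].  Base values sit near
textbook bond strengths so that e.g. O-H bonds are strong and O-O bonds
weak, but the oracle makes no claim to real thermochemistry.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem import MoleculeRecord, all_cleavages, enumerate_cleavages, mol_with_hs

#: default class base values, kcal/mol, ordered like typical bond strengths
DEFAULT_BASE_BDE = {
    "C-H": 99.0, "C-C": 85.0, "N-H": 93.0, "C-N": 80.0, "C-O": 85.0,
    "O-H": 105.0, "N-O": 55.0, "N-N": 65.0, "O-O": 45.0,
}

_MAX_VALENCE = {"C": 4, "N": 3, "O": 2}


@dataclass
class SyntheticOracleParams:
    """Parameters of the synthetic BDE oracle."""

    base_bde: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BASE_BDE))
    env_amplitude: float = 5.0
    noise_sigma: float = 0.0
    seed: int = 0


def _hash64(text: str) -> int:
    """Stable salt-free 64-bit hash (process-independent)."""
    return int.from_bytes(hashlib.sha256(text.encode()).digest()[:8], "big")


def env_offset(parent_smiles: str, bond_index: int, amplitude: float) -> float:
    """Deterministic environment term: hash of the canonical radius-2
    fragment around the bond's endpoints, uniform on [-amplitude, +amplitude]."""
    molh = mol_with_hs(parent_smiles)
    bond = molh.GetBondWithIdx(bond_index)
    a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
    dmat = Chem.GetDistanceMatrix(molh)
    env_atoms = sorted(
        i for i in range(molh.GetNumAtoms())
        if min(dmat[i, a], dmat[i, b]) <= 2
    )
    marked = Chem.Mol(molh)
    for idx in (a, b):
        marked.GetAtomWithIdx(idx).SetAtomMapNum(1)
    env = Chem.MolFragmentToSmiles(marked, atomsToUse=env_atoms, canonical=True)
    u = _hash64(env) / 2.0 ** 64
    return amplitude * (2.0 * u - 1.0)


def oracle_bde(params: SyntheticOracleParams, parent_smiles: str,
               bond_index: int, bond_type: str) -> float:
    """Ground-truth BDE of one cleavage under the synthetic oracle."""
    value = params.base_bde[bond_type]
    value += env_offset(parent_smiles, bond_index, params.env_amplitude)
    if params.noise_sigma > 0:
        noise_rng = np.random.default_rng(
            [params.seed, _hash64(f"{parent_smiles}|{bond_index}") % 2 ** 63]
        )
        value += noise_rng.normal(0.0, params.noise_sigma)
    return float(value)


def _random_molecule(rng: np.random.Generator, max_heavy: int,
                     ring_prob: float, double_bond_prob: float) -> Optional[str]:
    """One random valence-respecting heavy-atom tree (optionally closed
    into a single ring, optionally with double bonds); implicit hydrogens
    complete the valences."""
    n_heavy = int(rng.integers(1, max_heavy + 1))
    symbols = rng.choice(["C", "N", "O"], size=n_heavy, p=[0.7, 0.15, 0.15])
    rw = Chem.RWMol()
    free = []
    for sym in symbols:
        idx = rw.AddAtom(Chem.Atom(sym))
        free.append(_MAX_VALENCE[sym])
    for i in range(1, n_heavy):
        candidates = [j for j in range(i) if free[j] > 0]
        if not candidates:
            return None
        j = int(rng.choice(candidates))
        rw.AddBond(i, j, Chem.BondType.SINGLE)
        free[i] -= 1
        free[j] -= 1
    if n_heavy >= 3 and rng.random() < ring_prob:
        pairs = [
            (i, j) for i in range(n_heavy) for j in range(i + 1, n_heavy)
            if free[i] > 0 and free[j] > 0 and rw.GetBondBetweenAtoms(i, j) is None
        ]
        if pairs:
            i, j = pairs[int(rng.integers(len(pairs)))]
            rw.AddBond(i, j, Chem.BondType.SINGLE)
            free[i] -= 1
            free[j] -= 1
    for bond in rw.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if free[i] > 0 and free[j] > 0 and rng.random() < double_bond_prob:
            bond.SetBondType(Chem.BondType.DOUBLE)
            free[i] -= 1
            free[j] -= 1
    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return Chem.MolToSmiles(mol)


def gen_molecules(n: int, max_heavy: int = 9, seed: int = 0,
                  ring_prob: float = 0.2,
                  double_bond_prob: float = 0.15) -> List[MoleculeRecord]:
    """Generate *n* unique random C/H/O/N molecules with at most
    *max_heavy* heavy atoms.  Deterministic per seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    seen = set()
    out: List[MoleculeRecord] = []
    while len(out) < n:
        smiles = _random_molecule(rng, max_heavy, ring_prob, double_bond_prob)
        if smiles is None or smiles in seen:
            continue
        seen.add(smiles)
        out.append(MoleculeRecord.from_smiles(smiles))
    return out


def gen_bde_dataset(params: SyntheticOracleParams, n_train: int = 2000,
                    n_dev: int = 250, n_test: int = 250,
                    max_heavy: int = 9) -> pd.DataFrame:
    """Labeled cleavage table over generated molecules, split by parent
    molecule (never by bond) into train/dev/test.

    Columns: parent_smiles, bond_index, bond_type, radical1, radical2,
    bde_kcal_mol, split.
    """
    total = n_train + n_dev + n_test
    records = gen_molecules(total, max_heavy=max_heavy, seed=params.seed)
    rng = np.random.default_rng(params.seed + 1)
    order = rng.permutation(total)
    split = np.empty(total, dtype=object)
    split[order[:n_train]] = "train"
    split[order[n_train:n_train + n_dev]] = "dev"
    split[order[n_train + n_dev:]] = "test"
    rows = []
    for rec, sp in zip(records, split):
        for cl in enumerate_cleavages(rec):
            rows.append({
                "parent_smiles": cl.parent,
                "bond_index": cl.bond_index,
                "bond_type": cl.bond_type,
                "radical1": cl.radical1,
                "radical2": cl.radical2,
                "bde_kcal_mol": oracle_bde(params, cl.parent, cl.bond_index,
                                           cl.bond_type),
                "split": sp,
            })
    return pd.DataFrame(rows)


def gen_metabolism_dataset(n: int, label_noise: float = 0.0, seed: int = 0,
                           params: Optional[SyntheticOracleParams] = None,
                           max_heavy: int = 9) -> List[dict]:
    """Molecules with per-C-H-bond oracle BDEs and a labeled metabolic
    site: the weakest C-H bond, relabeled to a uniformly random C-H bond
    with probability *label_noise*.

    Returns dicts with keys smiles, ch_bdes ({bond_index: kcal/mol}) and
    site_bonds (set of bond indices).  An unflipped label is the full
    argmin set (all bonds exactly tied at the minimum — symmetric
    environments give identical oracle values, and a perfect labeler
    cannot distinguish them); a flipped label is one uniformly random
    bond.
    """
    params = params or SyntheticOracleParams(seed=seed)
    rng = np.random.default_rng(seed + 7)
    out = []
    pool = gen_molecules(4 * n + 20, max_heavy=max_heavy, seed=seed)
    for rec in pool:
        if len(out) >= n:
            break
        ch = {
            cl.bond_index: oracle_bde(params, cl.parent, cl.bond_index,
                                      cl.bond_type)
            for cl in enumerate_cleavages(rec) if cl.bond_type == "C-H"
        }
        if len(ch) < 2:
            continue
        if rng.random() < label_noise:
            sites = {int(rng.choice(sorted(ch)))}
        else:
            minimum = min(ch.values())
            sites = {b for b, v in ch.items() if v == minimum}
        out.append({"smiles": rec.smiles, "ch_bdes": ch, "site_bonds": sites})
    if len(out) < n:
        raise RuntimeError("could not generate enough molecules with >=2 C-H bonds")
    return out


def weakest_bond_radicals(rec: MoleculeRecord,
                          params: SyntheticOracleParams) -> Optional[tuple]:
    """Radical pair of the molecule's weakest valid cleavage under the
    noiseless oracle."""
    cleavages = enumerate_cleavages(rec)
    if not cleavages:
        return None
    noiseless = SyntheticOracleParams(
        base_bde=params.base_bde, env_amplitude=params.env_amplitude,
        noise_sigma=0.0, seed=params.seed)
    best = min(
        cleavages,
        key=lambda cl: (oracle_bde(noiseless, cl.parent, cl.bond_index,
                                   cl.bond_type), cl.bond_index),
    )
    return best.radical1, best.radical2


def gen_ysi_dataset(n: int, radical_weights: Optional[Dict[str, float]] = None,
                    noise: float = 0.0, seed: int = 0,
                    max_heavy: int = 7) -> tuple:
    """Sooting-tendency dataset: each molecule's value is the sum of the
    weights of the two radicals from its weakest bond, plus Gaussian
    noise.  Only molecules whose radicals each appear in >=2 molecules are
    kept, mirroring the support rule of the regression (so at most *n*
    rows are returned).

    Returns (DataFrame[smiles, radical1, radical2, ysi, ysi_std],
    radical_weights dict actually used).
    """
    params = SyntheticOracleParams(seed=seed)
    rng = np.random.default_rng(seed + 13)
    pool = gen_molecules(6 * n + 40, max_heavy=max_heavy, seed=seed)
    rows = []
    for rec in pool:
        pair = weakest_bond_radicals(rec, params)
        if pair is None:
            continue
        rows.append({"smiles": rec.smiles, "radical1": pair[0],
                     "radical2": pair[1]})
    df = pd.DataFrame(rows).head(n)
    # iteratively keep only molecules whose radicals have support >= 2
    # (truncation first, so the rule holds on the returned rows)
    while True:
        counts = pd.concat([df["radical1"], df["radical2"]]).value_counts()
        ok = df["radical1"].map(counts).ge(2) & df["radical2"].map(counts).ge(2)
        if ok.all():
            break
        df = df[ok]
    df = df.reset_index(drop=True)
    if radical_weights is None:
        radicals = sorted(set(df["radical1"]) | set(df["radical2"]))
        radical_weights = {
            r: float(w) for r, w in zip(radicals,
                                        rng.uniform(0.0, 100.0, len(radicals)))
        }
    sigma = np.full(len(df), noise if noise > 0 else 1.0)
    values = (
        df["radical1"].map(radical_weights).to_numpy()
        + df["radical2"].map(radical_weights).to_numpy()
    )
    if noise > 0:
        values = values + rng.normal(0.0, sigma)
    df["ysi"] = values
    df["ysi_std"] = sigma
    return df, radical_weights
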