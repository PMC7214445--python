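"""Categorical graph representation of molecules for the message-passing network.

Atoms and bonds are mapped to discrete classes.  An atom class is the
tuple (element, chirality tag, aromaticity, smallest-ring-size bucket,
degree including hydrogens, number of bonded hydrogens); a bond class is
(start element, end element, ring-size bucket).  Each bond contributes two
directional edges pointing in opposite directions, so messages can flow
both ways and each direction carries its own state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from rdkit import Chem

from .chem import mol_with_hs

RING_BUCKETS = ("none", "3", "4", "5", "6+")


class VocabularyError(RuntimeError):
    """Raised when encoding against a vocabulary in the wrong state."""


def _ring_bucket(sizes) -> str:
    """Bucket the smallest ring size into {none, 3, 4, 5, 6+}."""
    sizes = list(sizes)
    if not sizes:
        return "none"
    smallest = min(sizes)
    return str(smallest) if smallest in (3, 4, 5) else "6+"


_CHIRAL_TAGS = {
    Chem.ChiralType.CHI_TETRAHEDRAL_CW: "CW",
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW: "CCW",
}


def atom_class_key(molh: Chem.Mol, atom_index: int) -> tuple:
    """Class key of one atom of the explicit-hydrogen graph."""
    atom = molh.GetAtomWithIdx(atom_index)
    ring_sizes = [len(r) for r in molh.GetRingInfo().AtomRings() if atom_index in r]
    n_h = sum(1 for n in atom.GetNeighbors() if n.GetSymbol() == "H")
    return (
        atom.GetSymbol(),
        _CHIRAL_TAGS.get(atom.GetChiralTag(), "none"),
        atom.GetIsAromatic(),
        _ring_bucket(ring_sizes),
        atom.GetDegree(),
        n_h,
    )


def bond_class_key(molh: Chem.Mol, bond_index: int, forward: bool = True) -> tuple:
    """Class key of one directional edge: (start symbol, end symbol,
    ring bucket).  Reversing the direction swaps the symbols."""
    bond = molh.GetBondWithIdx(bond_index)
    ring_sizes = [len(r) for r in molh.GetRingInfo().BondRings() if bond_index in r]
    a, b = bond.GetBeginAtom().GetSymbol(), bond.GetEndAtom().GetSymbol()
    if not forward:
        a, b = b, a
    return (a, b, _ring_bucket(ring_sizes))


@dataclass
class MolGraph:
    """Directed-edge graph of one molecule.

    Edges ``2*i`` and ``2*i + 1`` are the forward and reverse direction of
    bond ``i``; ``reverse_edge`` is therefore the involution ``e ^ 1``.
    """

    smiles: str
    n_atoms: int
    edges: np.ndarray          # (n_edges, 2) int: source, target atom
    atom_keys: list
    edge_keys: list
    bond_types: list           # per bond, chem.bond_type_label strings
    atom_class_ids: Optional[np.ndarray] = None
    edge_class_ids: Optional[np.ndarray] = None

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    @property
    def n_bonds(self) -> int:
        return self.n_edges // 2

    def bond_of_edge(self, edge: int) -> int:
        return edge // 2

    def reverse_edge(self, edge: int) -> int:
        return edge ^ 1

    def canonical_edge(self, bond: int) -> int:
        """The directed edge of *bond* whose source atom has the lower
        canonical index (used when exporting one embedding per bond)."""
        e = 2 * bond
        return e if self.edges[e, 0] < self.edges[e, 1] else e + 1


def build_graph(smiles: str) -> MolGraph:
    """Build the explicit-hydrogen directed-edge graph of *smiles* in
    canonical atom order (independent of how the input SMILES is written)."""
    from .chem import bond_type_label

    molh = mol_with_hs(smiles)
    canonical = Chem.MolToSmiles(Chem.RemoveHs(Chem.Mol(molh)))
    n_atoms = molh.GetNumAtoms()
    atom_keys = [atom_class_key(molh, i) for i in range(n_atoms)]
    edges = []
    edge_keys = []
    bond_types = []
    for bond in molh.GetBonds():
        i = bond.GetIdx()
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        edges.append((a, b))
        edge_keys.append(bond_class_key(molh, i, forward=True))
        edges.append((b, a))
        edge_keys.append(bond_class_key(molh, i, forward=False))
        bond_types.append(
            bond_type_label(bond.GetBeginAtom().GetSymbol(), bond.GetEndAtom().GetSymbol())
        )
    return MolGraph(
        smiles=canonical,
        n_atoms=n_atoms,
        edges=np.asarray(edges, dtype=np.int64).reshape(-1, 2),
        atom_keys=atom_keys,
        edge_keys=edge_keys,
        bond_types=bond_types,
    )


@dataclass
class Vocabulary:
    """Dense integer ids for atom and bond class keys.

    Id 0 is reserved in both tables for classes never seen in training;
    its embedding row is still learnable, so prediction stays total on
    out-of-vocabulary chemistry (flagged via logging by callers).
    """

    atom_ids: dict = field(default_factory=dict)
    bond_ids: dict = field(default_factory=dict)
    frozen: bool = False

    @property
    def n_atom_classes(self) -> int:
        return len(self.atom_ids) + 1

    @property
    def n_bond_classes(self) -> int:
        return len(self.bond_ids) + 1

    def add_graph(self, graph: MolGraph) -> None:
        if self.frozen:
            raise VocabularyError("cannot add classes to a frozen vocabulary")
        for key in graph.atom_keys:
            self.atom_ids.setdefault(key, len(self.atom_ids) + 1)
        for key in graph.edge_keys:
            self.bond_ids.setdefault(key, len(self.bond_ids) + 1)

    def freeze(self) -> "Vocabulary":
        self.frozen = True
        return self

    def encode(self, graph: MolGraph) -> MolGraph:
        """Resolve class keys to integer ids in place (and return the graph).

        Unknown keys map to the reserved id 0.  The vocabulary must be
        frozen: encoding against a still-mutable vocabulary at inference
        would silently depend on insertion order.
        """
        if not self.frozen:
            raise VocabularyError("vocabulary must be frozen before encoding")
        graph.atom_class_ids = np.asarray(
            [self.atom_ids.get(k, 0) for k in graph.atom_keys], dtype=np.int64
        )
        graph.edge_class_ids = np.asarray(
            [self.bond_ids.get(k, 0) for k in graph.edge_keys], dtype=np.int64
        )
        return graph

    @classmethod
    def fit(cls, graphs) -> "Vocabulary":
        vocab = cls()
        for g in graphs:
            vocab.add_graph(g)
        return vocab.freeze()

    def to_dict(self) -> dict:
        return {
            "atom_ids": [[list(map(str, k)), v] for k, v in self.atom_ids.items()],
            "bond_ids": [[list(map(str, k)), v] for k, v in self.bond_ids.items()],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "Vocabulary":
        def _atom_key(parts):
            sym, chir, arom, ring, deg, nh = parts
            return (sym, chir, arom == "True", ring, int(deg), int(nh))

        def _bond_key(parts):
            return tuple(parts)

        vocab = cls(
            atom_ids={_atom_key(k): v for k, v in data["atom_ids"]},
            bond_ids={_bond_key(k): v for k, v in data["bond_ids"]},
        )
        return vocab.freeze()
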