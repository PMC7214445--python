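"""Enumeration of homolytic bond dissociations for closed-shell C/H/O/N molecules.

Every single bond outside a ring can be cleaved homolytically,

    A-B  ->  A. + B.

yielding two open-shell radicals.  This module canonicalizes parent
molecules, cleaves bonds on the explicit-hydrogen graph (so C-H
dissociations correspond to real edges), labels each cleavage with its
bond-type class, removes duplicate cleavages arising from molecular
symmetry, and omits dissociations that would create a new stereocenter
(cleaving within a diastereotopic group produces radicals whose relative
configuration is undefined, so such reactions have no single well-defined
enthalpy).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd
from rdkit import Chem

ALLOWED_ELEMENTS = frozenset({"C", "H", "N", "O"})

#: ordering used in bond-type labels: C first, then N, then O, H always last
_ELEMENT_PRIORITY = {"C": 0, "N": 1, "O": 2, "H": 3}

#: the nine bond-type classes reachable from C/H/N/O single bonds
BOND_TYPE_LABELS = (
    "C-H", "C-C", "N-H", "C-N", "C-O", "O-H", "N-O", "N-N", "O-O",
)


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed."""


class DomainError(ValueError):
    """Raised for molecules outside the supported domain (charged,
    open-shell, or containing elements other than C/H/N/O)."""


class InvalidBondError(ValueError):
    """Raised when a bond index does not address a cleavable
    (acyclic, single) bond."""


def canonicalize(smiles: str) -> str:
    """Return the canonical isomeric SMILES for *smiles*.

    Idempotent: feeding the output back in returns the identical string.
    Stereo descriptors are preserved.
    """
    mol = Chem.MolFromSmiles(smiles, sanitize=True)
    if mol is None:
        raise SmilesParseError(f"unparsable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def mol_with_hs(smiles: str) -> Chem.Mol:
    """Parse *smiles* and return the explicit-hydrogen molecule in a
    canonical, input-order-independent atom ordering.

    The molecule is first canonicalized, then re-parsed (atom order then
    follows the canonical SMILES string) and hydrogens are appended in
    heavy-atom order.  Bond indices on the returned molecule are the bond
    indices used throughout the package.
    """
    canonical = canonicalize(smiles)
    mol = Chem.MolFromSmiles(canonical)
    molh = Chem.AddHs(mol)
    Chem.AssignStereochemistry(molh, cleanIt=True, force=True)
    return molh


@dataclass(frozen=True)
class MoleculeRecord:
    """A neutral, closed-shell parent molecule."""

    smiles: str
    n_heavy: int
    formula: dict = field(hash=False, compare=False, default_factory=dict)

    @classmethod
    def from_smiles(cls, smiles: str) -> "MoleculeRecord":
        canonical = canonicalize(smiles)
        mol = Chem.MolFromSmiles(canonical)
        molh = Chem.AddHs(mol)
        formula: dict = {}
        for atom in molh.GetAtoms():
            sym = atom.GetSymbol()
            if sym not in ALLOWED_ELEMENTS:
                raise DomainError(
                    f"element {sym!r} outside C/H/N/O domain in {smiles!r}"
                )
            if atom.GetFormalCharge() != 0:
                raise DomainError(f"charged atom in {smiles!r}")
            if atom.GetNumRadicalElectrons() != 0:
                raise DomainError(f"open-shell input {smiles!r}")
            formula[sym] = formula.get(sym, 0) + 1
        n_heavy = mol.GetNumHeavyAtoms()
        if n_heavy < 1:
            raise DomainError(f"no heavy atoms in {smiles!r}")
        return cls(smiles=canonical, n_heavy=n_heavy, formula=formula)


@dataclass(frozen=True)
class BondCleavage:
    """One homolysis event of a single acyclic bond.

    ``radical1``/``radical2`` are stored in lexicographic order of their
    canonical SMILES.  ``is_valid`` is False when the cleavage is omitted
    by the new-stereocenter rule.
    """

    parent: str
    bond_index: int
    bond_type: str
    radical1: str
    radical2: str
    bde: Optional[float] = None
    is_valid: bool = True

    @property
    def key(self) -> tuple:
        return (self.parent, self.radical1, self.radical2, self.bond_type)


def bond_type_label(symbol_a: str, symbol_b: str) -> str:
    """Class label for a bond between two elements: symbols joined by '-',
    ordered C before N before O, with H always last (giving the nine
    classes C-H, C-C, N-H, C-N, C-O, O-H, N-O, N-N, O-O)."""
    for sym in (symbol_a, symbol_b):
        if sym not in ALLOWED_ELEMENTS:
            raise DomainError(f"element {sym!r} outside C/H/N/O domain")
    a, b = sorted((symbol_a, symbol_b), key=_ELEMENT_PRIORITY.__getitem__)
    return f"{a}-{b}"


def _cleavable(bond: Chem.Bond) -> bool:
    return (bond.GetBondType() == Chem.BondType.SINGLE) and not bond.IsInRing()


def _fragment_on_bond(molh: Chem.Mol, bond_index: int) -> Chem.Mol:
    """Remove bond *bond_index* and put one radical electron on each
    former partner.  Atom indices are preserved."""
    bond = molh.GetBondWithIdx(bond_index)
    rw = Chem.RWMol(molh)
    a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
    rw.RemoveBond(a, b)
    for idx in (a, b):
        atom = rw.GetAtomWithIdx(idx)
        atom.SetNumRadicalElectrons(atom.GetNumRadicalElectrons() + 1)
        atom.SetNoImplicit(True)
    frag = rw.GetMol()
    Chem.SanitizeMol(frag)
    return frag


def cleave_bond(mol: "MoleculeRecord | str", bond_index: int) -> tuple:
    """Homolytically cleave bond *bond_index* of the explicit-hydrogen
    graph; return the two canonical radical SMILES in lexicographic order.

    Cleaving a C-H bond yields ``[H]`` as one fragment.
    """
    smiles = mol.smiles if isinstance(mol, MoleculeRecord) else mol
    molh = mol_with_hs(smiles)
    if bond_index < 0 or bond_index >= molh.GetNumBonds():
        raise InvalidBondError(f"bond index {bond_index} out of range")
    bond = molh.GetBondWithIdx(bond_index)
    if not _cleavable(bond):
        raise InvalidBondError(
            f"bond {bond_index} of {smiles!r} is not an acyclic single bond"
        )
    frag = _fragment_on_bond(molh, bond_index)
    pieces = Chem.GetMolFrags(frag, asMols=True, sanitizeFrags=True)
    if len(pieces) != 2:  # pragma: no cover - acyclic bond guarantees two
        raise InvalidBondError(f"cleaving bond {bond_index} did not yield 2 fragments")
    # suppress hydrogens in the output SMILES; a bare H radical stays [H]
    pieces = [Chem.RemoveHs(p) if p.GetNumHeavyAtoms() else p for p in pieces]
    r1, r2 = sorted(Chem.MolToSmiles(p) for p in pieces)
    return r1, r2


def _potential_stereocenters(mol: Chem.Mol) -> set:
    """Atom indices of assignable tetrahedral stereocenters, counting
    unassigned potential centers."""
    centers = Chem.FindMolChiralCenters(
        mol, includeUnassigned=True, useLegacyImplementation=False
    )
    return {idx for idx, _tag in centers}


def creates_new_stereocenter(mol: "MoleculeRecord | str", bond_index: int) -> bool:
    """True when either radical fragment gains an assignable stereocenter
    that the parent did not have at the corresponding atoms.

    Cleaving within a diastereotopic group (e.g. one methyl of a gem-
    dimethyl carbinol) turns the attachment carbon into a new center.
    """
    smiles = mol.smiles if isinstance(mol, MoleculeRecord) else mol
    molh = mol_with_hs(smiles)
    bond = molh.GetBondWithIdx(bond_index)
    if not _cleavable(bond):
        raise InvalidBondError(
            f"bond {bond_index} of {smiles!r} is not an acyclic single bond"
        )
    parent_centers = _potential_stereocenters(molh)
    frag = _fragment_on_bond(molh, bond_index)
    Chem.AssignStereochemistry(frag, cleanIt=True, force=True)
    frag_centers = _potential_stereocenters(frag)
    for piece in Chem.GetMolFrags(frag):
        atoms = set(piece)
        if len(frag_centers & atoms) > len(parent_centers & atoms):
            return True
    return False


def all_cleavages(mol: "MoleculeRecord | str") -> list:
    """One :class:`BondCleavage` candidate per acyclic single bond of the
    explicit-hydrogen graph, in bond-index order, stereo rule applied."""
    record = mol if isinstance(mol, MoleculeRecord) else MoleculeRecord.from_smiles(mol)
    molh = mol_with_hs(record.smiles)
    out = []
    for bond in molh.GetBonds():
        if not _cleavable(bond):
            continue
        idx = bond.GetIdx()
        r1, r2 = cleave_bond(record, idx)
        label = bond_type_label(
            bond.GetBeginAtom().GetSymbol(), bond.GetEndAtom().GetSymbol()
        )
        valid = not creates_new_stereocenter(record, idx)
        out.append(
            BondCleavage(
                parent=record.smiles,
                bond_index=idx,
                bond_type=label,
                radical1=r1,
                radical2=r2,
                is_valid=valid,
            )
        )
    return out


def enumerate_cleavages(mol: "MoleculeRecord | str") -> list:
    """Unique valid cleavages of a molecule.

    Duplicates are collapsed by the key (parent, sorted radical pair,
    bond type); the representative kept is the lowest bond index.
    Cleavages omitted by the stereocenter rule do not count.
    """
    seen = set()
    unique = []
    for cl in all_cleavages(mol):
        if not cl.is_valid:
            continue
        if cl.key in seen:
            continue
        seen.add(cl.key)
        unique.append(cl)
    return unique


def cleavages_to_frame(cleavages: Iterable[BondCleavage]) -> pd.DataFrame:
    rows = [
        {
            "parent_smiles": c.parent,
            "bond_index": c.bond_index,
            "bond_type": c.bond_type,
            "radical1": c.radical1,
            "radical2": c.radical2,
            "is_valid": c.is_valid,
            **({"bde_kcal_mol": c.bde} if c.bde is not None else {}),
        }
        for c in cleavages
    ]
    return pd.DataFrame(rows)


def read_smiles_input(path_or_buffer) -> list:
    """Read SMILES from a plain-text file (one per line) or a CSV with a
    ``smiles`` column."""
    if isinstance(path_or_buffer, (str,)):
        with open(path_or_buffer) as fh:
            text = fh.read()
    else:
        text = path_or_buffer.read()
    first_line = text.splitlines()[0] if text.strip() else ""
    if "smiles" in [c.strip().lower() for c in first_line.split(",")]:
        df = pd.read_csv(io.StringIO(text))
        col = [c for c in df.columns if c.strip().lower() == "smiles"][0]
        return [str(s) for s in df[col]]
    return [line.strip() for line in text.splitlines() if line.strip()]
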