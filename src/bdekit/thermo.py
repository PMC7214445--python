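"""BDE assembly from species enthalpies and statistical QC screens.

No quantum chemistry is run here: the functions consume externally
supplied enthalpy/geometry records (e.g. parsed from electronic-structure
output) and implement the bookkeeping and quality-control layer around
them — reaction-enthalpy assembly, Boltzmann conformer averaging,
Lewis-structure connectivity checks against covalent radii, a
per-composition enthalpy outlier screen, and convergence-flag filtering.

Units are kcal/mol throughout; a Hartree converter is provided for I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

#: gas constant, kcal mol^-1 K^-1
R_KCAL = 1.987204e-3

#: 1 Hartree in kcal/mol
HARTREE_TO_KCAL = 627.509

#: single-bond covalent radii (Angstrom), Cordero et al. 2008
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66,
}

#: tolerance added to the covalent-radii sum in the connectivity check
CONNECTIVITY_SLACK = 0.4

#: convergence flags a calculation must carry to pass QC
REQUIRED_QC_FLAGS = frozenset({
    "ok_termination", "no_imaginary_freq", "connectivity_ok",
    "stable_wavefunction",
})

_FAIL_REASONS = {
    "ok_termination": "failed termination",
    "no_imaginary_freq": "imaginary frequency",
    "connectivity_ok": "decomposed",
    "stable_wavefunction": "unstable wavefunction",
}


def hartree_to_kcal(value: float) -> float:
    return value * HARTREE_TO_KCAL


@dataclass
class SpeciesEnthalpy:
    """Enthalpy record of one species at 298 K."""

    smiles: str
    h_kcal_mol: float
    qc_flags: Set[str] = field(default_factory=set)
    formula: Optional[Dict[str, int]] = None


@dataclass
class ConformerEnsemble:
    """Per-conformer enthalpies of one species; index 0 is the conformer
    derived from the force-field global minimum."""

    smiles: str
    conformer_h: List[float]


@dataclass
class GeometryRecord:
    """Cartesian geometry plus the bonds expected from the Lewis structure."""

    symbols: List[str]
    coordinates: np.ndarray            # (n_atoms, 3), Angstrom
    expected_bonds: List[Tuple[int, int]]

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (len(self.symbols), 3):
            raise ValueError("coordinate count must equal atom count")


def bde_from_enthalpies(parent: "SpeciesEnthalpy | float",
                        r1: "SpeciesEnthalpy | float",
                        r2: "SpeciesEnthalpy | float") -> float:
    """Reaction enthalpy of A-B -> A. + B. at 298 K:
    h(A.) + h(B.) - h(A-B), kcal/mol."""
    def _h(x):
        return x.h_kcal_mol if isinstance(x, SpeciesEnthalpy) else float(x)
    return _h(r1) + _h(r2) - _h(parent)


def boltzmann_enthalpy(ens: ConformerEnsemble,
                       T: float = 298.15) -> Tuple[float, float]:
    """Boltzmann-weighted ensemble enthalpy at temperature *T* and the gap
    to the first conformer.

    Returns ``(<H>, <H> - H_0)`` where
    ``<H> = sum_i h_i exp(-h_i/RT) / sum_i exp(-h_i/RT)``.  Energies are
    shifted by their minimum before exponentiation for stability.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    h = np.asarray(ens.conformer_h, dtype=float)
    if h.size == 0:
        raise ValueError(f"empty conformer ensemble for {ens.smiles!r}")
    shifted = h - h.min()
    weights = np.exp(-shifted / (R_KCAL * T))
    avg = float((h * weights).sum() / weights.sum())
    return avg, avg - float(h[0])


def check_connectivity(geom: GeometryRecord,
                       radii: Optional[Dict[str, float]] = None
                       ) -> Tuple[bool, pd.DataFrame]:
    """Check that every Lewis-structure bond is shorter than the sum of
    covalent radii plus 0.4 Angstrom (a longer bond means the structure
    decomposed or rearranged during optimization).

    Returns (all_intact, per-bond report).
    """
    radii = radii if radii is not None else COVALENT_RADII
    rows = []
    for a, b in geom.expected_bonds:
        for idx in (a, b):
            if geom.symbols[idx] not in radii:
                raise KeyError(f"no covalent radius for {geom.symbols[idx]!r}")
        length = float(np.linalg.norm(geom.coordinates[a] - geom.coordinates[b]))
        threshold = radii[geom.symbols[a]] + radii[geom.symbols[b]] + CONNECTIVITY_SLACK
        rows.append({
            "atom_a": a, "atom_b": b,
            "symbol_a": geom.symbols[a], "symbol_b": geom.symbols[b],
            "length": length, "threshold": threshold,
            "intact": length < threshold,
        })
    report = pd.DataFrame(rows, columns=[
        "atom_a", "atom_b", "symbol_a", "symbol_b", "length", "threshold",
        "intact"])
    return bool(report["intact"].all()) if len(report) else True, report


def formula_outlier_screen(records: Sequence[SpeciesEnthalpy]) -> List[bool]:
    """Flag species whose enthalpy is anomalous for their elemental
    composition.

    A least-squares fit of enthalpy on element counts (nC, nH, nN, nO,
    with intercept) is computed over all records; a record is flagged when
    its absolute residual exceeds 3 x IQR of the residuals
    (linear-interpolation quartiles).  Requires at least 5 records and a
    non-degenerate composition design.
    """
    if len(records) < 5:
        raise ValueError("outlier screen requires at least 5 records")
    elements = ("C", "H", "N", "O")
    X = np.array([
        [1.0] + [float((r.formula or {}).get(el, 0)) for el in elements]
        for r in records
    ])
    y = np.array([r.h_kcal_mol for r in records], dtype=float)
    if np.allclose(X[:, 1:], X[0, 1:]):
        raise ValueError("degenerate design: all records share one composition")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    q1, q3 = np.percentile(resid, [25, 75])
    iqr = q3 - q1
    # absolute floor so a perfectly linear dataset (IQR at rounding error)
    # does not flag everything on float noise
    return list(np.abs(resid) > 3.0 * iqr + 1e-9)


def qc_filter(record: SpeciesEnthalpy) -> Tuple[bool, List[str]]:
    """Pass iff all four convergence flags are present; otherwise return
    the human-readable reasons for rejection."""
    missing = REQUIRED_QC_FLAGS - set(record.qc_flags)
    reasons = sorted(_FAIL_REASONS[f] for f in missing)
    return not missing, reasons


def read_xyz(path_or_buffer) -> Tuple[List[str], np.ndarray]:
    """Read a single-geometry XYZ file: atom count line, comment line,
    then one `symbol x y z` line per atom."""
    if isinstance(path_or_buffer, str):
        with open(path_or_buffer) as fh:
            lines = fh.read().splitlines()
    else:
        lines = path_or_buffer.read().splitlines()
    n = int(lines[0].split()[0])
    symbols, coords = [], []
    for line in lines[2:2 + n]:
        parts = line.split()
        symbols.append(parts[0])
        coords.append([float(x) for x in parts[1:4]])
    return symbols, np.asarray(coords)


def read_enthalpy_table(path_or_buffer) -> List[SpeciesEnthalpy]:
    """Read a CSV of species enthalpies: columns ``smiles, h_kcal_mol``
    plus optional boolean flag columns named after the QC flags."""
    df = pd.read_csv(path_or_buffer)
    out = []
    for row in df.itertuples():
        flags = {f for f in REQUIRED_QC_FLAGS
                 if hasattr(row, f) and bool(getattr(row, f))}
        out.append(SpeciesEnthalpy(smiles=row.smiles,
                                   h_kcal_mol=float(row.h_kcal_mol),
                                   qc_flags=flags))
    return out


def read_conformer_table(path_or_buffer) -> List[ConformerEnsemble]:
    """Read a CSV of conformer enthalpies: columns ``smiles,
    conformer_id, h_kcal_mol``; conformer 0 is the force-field minimum."""
    df = pd.read_csv(path_or_buffer)
    out = []
    for smiles, grp in df.groupby("smiles", sort=False):
        grp = grp.sort_values("conformer_id")
        out.append(ConformerEnsemble(smiles=smiles,
                                     conformer_h=list(grp["h_kcal_mol"])))
    return out
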