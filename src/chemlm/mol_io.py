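"""Molecular graph I/O: SMILES parsing, adjacency matrices, QED labels, CSV tables.

The molecular graph convention throughout the package is heavy atoms only
(implicit hydrogens excluded), with atoms ordered by first appearance in the
SMILES string so that the i-th atomic token of the tokenizer aligns with row i
of the adjacency matrix.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import QED

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.error")

__all__ = [
    "Molecule",
    "ParseError",
    "parse_smiles",
    "adjacency",
    "qed_from_desirabilities",
    "qed_desirabilities",
    "qed_label",
    "read_molecule_table",
    "read_smiles_list",
]


class ParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


@dataclass(frozen=True)
class Molecule:
    """Heavy-atom molecular graph parsed from a SMILES string.

    Atoms are ordered by first appearance in the SMILES; bonds are unordered
    index pairs stored once with i < j.
    """

    smiles: str
    atoms: tuple[str, ...]
    bonds: frozenset[tuple[int, int]] = field(repr=False)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


def parse_smiles(smiles: str) -> Molecule:
    """Parse a SMILES string into a heavy-atom :class:`Molecule`.

    RDKit keeps atom indices in SMILES appearance order, which this package
    relies on for token/atom alignment.

    Raises
    ------
    ParseError
        If the string is empty or not valid SMILES.
    """
    if not smiles or not smiles.strip():
        raise ParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"invalid SMILES: {smiles!r}")
    atoms = tuple(a.GetSymbol() for a in mol.GetAtoms())
    bonds = frozenset(
        (min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
         max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        for b in mol.GetBonds()
    )
    return Molecule(smiles=smiles, atoms=atoms, bonds=bonds)


def adjacency(mol: Molecule) -> np.ndarray:
    """Binary symmetric heavy-atom adjacency matrix A (zero diagonal).

    Bond order and aromaticity are not encoded: A[i, j] = 1 whenever atoms i
    and j share any bond.
    """
    n = mol.n_atoms
    a = np.zeros((n, n), dtype=np.float64)
    for i, j in mol.bonds:
        a[i, j] = 1.0
        a[j, i] = 1.0
    return a


def qed_from_desirabilities(d) -> float:
    """Geometric mean of per-property desirability values.

    QED = exp( (1/n) * sum_i ln d_i ), each d_i in (0, 1].
    """
    d = np.asarray(d, dtype=np.float64)
    if d.size == 0:
        raise ValueError("need at least one desirability value")
    if np.any(d <= 0.0):
        raise ValueError("desirability values must be positive (log undefined)")
    if np.any(d > 1.0):
        raise ValueError("desirability values must be <= 1")
    return float(math.exp(np.mean(np.log(d))))


def qed_desirabilities(mol: Molecule) -> np.ndarray:
    """The eight standard QED property desirabilities for a molecule.

    Properties (MW, ALOGP, HBA, HBD, PSA, ROTB, AROM, ALERTS) and their
    asymmetric-double-sigmoid desirability functions are delegated to RDKit.
    """
    rd = Chem.MolFromSmiles(mol.smiles)
    if rd is None:
        raise ParseError(f"invalid SMILES: {mol.smiles!r}")
    props = QED.properties(rd)
    d = np.array(
        [QED.ads(value, QED.adsParameters[name])
         for name, value in props._asdict().items()],
        dtype=np.float64,
    )
    return np.clip(d, 1e-12, 1.0)


def qed_label(mol: Molecule) -> float:
    """Drug-likeness label: unweighted geometric mean of the 8 desirabilities."""
    return qed_from_desirabilities(qed_desirabilities(mol))


def read_molecule_table(
    path,
    smiles_column: str = "smiles",
    label_columns: list[str] | None = None,
) -> list[tuple[Molecule, np.ndarray]]:
    """Read a CSV of SMILES with optional per-task label columns.

    Rows whose SMILES fail to parse are dropped (count logged). Missing label
    cells are preserved as NaN so multi-task datasets with gaps survive intact.

    Returns a list of (Molecule, labels) pairs; labels is a float array of
    length ``len(label_columns)`` (empty array when no labels requested).
    """
    try:
        df = pd.read_csv(path)
    except FileNotFoundError as exc:
        raise FileNotFoundError(f"molecule table not found: {path}") from exc
    if smiles_column not in df.columns:
        raise KeyError(f"SMILES column {smiles_column!r} not in {list(df.columns)}")
    label_columns = label_columns or []
    for col in label_columns:
        if col not in df.columns:
            raise KeyError(f"label column {col!r} not in {list(df.columns)}")

    records: list[tuple[Molecule, np.ndarray]] = []
    n_dropped = 0
    for _, row in df.iterrows():
        try:
            mol = parse_smiles(str(row[smiles_column]))
        except ParseError:
            n_dropped += 1
            continue
        labels = np.array([float(row[c]) if pd.notna(row[c]) else np.nan
                           for c in label_columns], dtype=np.float64)
        records.append((mol, labels))
    if n_dropped:
        logger.warning("dropped %d unparseable SMILES rows from %s", n_dropped, path)
    return records


def read_smiles_list(path) -> list[str]:
    """Read a plain-text SMILES corpus, one molecule per line."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
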