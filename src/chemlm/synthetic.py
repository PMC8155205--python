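"""Synthetic small-molecule fixtures: valid SMILES and labeled toy tasks.

The generator grows random heavy-atom trees over a small organic alphabet
under a fixed valence budget (C:4, N:3, O:2, S:2, F/Cl/Br:1), optionally
closes one ring and optionally upgrades one bond to a double bond, then
emits SMILES through RDKit so every string is guaranteed valid. It stands in
for a real unlabeled corpus at desk scale; it makes no attempt to emulate
the property distributions of a screening library.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from . import mol_io

__all__ = [
    "GeneratorConfig", "generate_molecules",
    "make_classification_task", "make_regression_task",
    "CLASSIFICATION_RULES", "generate_classification_dataset",
]

VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "F": 1, "Cl": 1, "Br": 1}


@dataclass(frozen=True)
class GeneratorConfig:
    n_molecules: int = 100
    seed: int = 0
    alphabet: tuple[str, ...] = ("C", "N", "O", "S", "F", "Cl", "Br")
    weights: tuple[float, ...] = (0.60, 0.12, 0.15, 0.05, 0.04, 0.03, 0.01)
    min_heavy_atoms: int = 4
    max_heavy_atoms: int = 12
    ring_probability: float = 0.5
    double_bond_probability: float = 0.3

    def __post_init__(self):
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.max_heavy_atoms < max(3, self.min_heavy_atoms):
            raise ValueError("max_heavy_atoms too small to build molecules")
        unknown = set(self.alphabet) - set(VALENCE)
        if unknown:
            raise ValueError(f"no valence entry for {sorted(unknown)}")


def _sample_molecule(cfg: GeneratorConfig, rng: np.random.Generator) -> str | None:
    n = int(rng.integers(cfg.min_heavy_atoms, cfg.max_heavy_atoms + 1))
    weights = np.asarray(cfg.weights) / np.sum(cfg.weights)
    # first atom must be able to grow a tree
    backbone = [a for a in cfg.alphabet if VALENCE[a] >= 2]
    symbols = [str(rng.choice(backbone))]
    bonds: list[tuple[int, int, int]] = []  # (i, j, order)
    free = [VALENCE[symbols[0]]]
    for _ in range(1, n):
        sym = str(rng.choice(cfg.alphabet, p=weights))
        open_slots = [i for i, f in enumerate(free) if f >= 1]
        if not open_slots:
            break
        parent = int(rng.choice(open_slots))
        idx = len(symbols)
        symbols.append(sym)
        free.append(VALENCE[sym] - 1)
        free[parent] -= 1
        bonds.append((parent, idx, 1))

    adjacent = {(min(i, j), max(i, j)) for i, j, _ in bonds}
    if rng.random() < cfg.ring_probability:
        candidates = [
            (i, j) for i in range(len(symbols)) for j in range(i + 1, len(symbols))
            if free[i] >= 1 and free[j] >= 1 and (i, j) not in adjacent
        ]
        if candidates:
            i, j = candidates[int(rng.integers(len(candidates)))]
            bonds.append((i, j, 1))
            free[i] -= 1
            free[j] -= 1
    if rng.random() < cfg.double_bond_probability:
        upgradable = [b for b, (i, j, order) in enumerate(bonds)
                      if order == 1 and free[i] >= 1 and free[j] >= 1]
        if upgradable:
            b = upgradable[int(rng.integers(len(upgradable)))]
            i, j, _ = bonds[b]
            bonds[b] = (i, j, 2)
            free[i] -= 1
            free[j] -= 1

    mol = Chem.RWMol()
    for sym in symbols:
        mol.AddAtom(Chem.Atom(sym))
    order_map = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE}
    for i, j, order in bonds:
        mol.AddBond(i, j, order_map[order])
    try:
        Chem.SanitizeMol(mol)
    except Exception:  # valence table should prevent this; belt and braces
        return None
    return Chem.MolToSmiles(mol)


def generate_molecules(cfg: GeneratorConfig) -> list[str]:
    """Deterministic list of ``cfg.n_molecules`` distinct valid SMILES."""
    rng = np.random.default_rng(cfg.seed)
    seen: set[str] = set()
    out: list[str] = []
    attempts = 0
    cap = 200 * cfg.n_molecules
    while len(out) < cfg.n_molecules and attempts < cap:
        attempts += 1
        smiles = _sample_molecule(cfg, rng)
        if smiles is None or smiles in seen:
            continue
        seen.add(smiles)
        out.append(smiles)
    if len(out) < cfg.n_molecules:
        raise RuntimeError(
            f"could only generate {len(out)}/{cfg.n_molecules} distinct molecules; "
            "widen max_heavy_atoms or the alphabet"
        )
    return out


# -- labeled toy tasks -------------------------------------------------------

def _has_ring(smiles: str) -> bool:
    rd = Chem.MolFromSmiles(smiles)
    if rd is None:
        raise mol_io.ParseError(f"invalid SMILES: {smiles!r}")
    return rd.GetRingInfo().NumRings() > 0

def _contains_halogen(smiles: str) -> bool:
    return any(a in ("F", "Cl", "Br", "I")
               for a in mol_io.parse_smiles(smiles).atoms)

def _heteroatom_count(smiles: str) -> int:
    return sum(a != "C" for a in mol_io.parse_smiles(smiles).atoms)


CLASSIFICATION_RULES = {
    "has_ring": _has_ring,
    "contains_halogen": _contains_halogen,
    "heteroatom_ge_2": lambda s: _heteroatom_count(s) >= 2,
    "heteroatom_ge_3": lambda s: _heteroatom_count(s) >= 3,
}


def make_classification_task(molecules: list[str],
                             rules: str | list[str]) -> pd.DataFrame:
    """Binary labels from structural rules; one column per rule.

    Raises if any rule yields a single class on the given molecules.
    """
    if isinstance(rules, str):
        rules = [rules]
    df = pd.DataFrame({"smiles": molecules})
    for rule in rules:
        if rule not in CLASSIFICATION_RULES:
            raise KeyError(f"unknown rule {rule!r}; choose from "
                           f"{sorted(CLASSIFICATION_RULES)}")
        labels = np.array([float(CLASSIFICATION_RULES[rule](s))
                           for s in molecules])
        if labels.min() == labels.max():
            raise ValueError(f"rule {rule!r} produced a single class")
        df[rule] = labels
    return df


def generate_classification_dataset(cfg: GeneratorConfig,
                                    rules: str | list[str],
                                    max_resamples: int = 20) -> pd.DataFrame:
    """Generate molecules and label them, resampling with a shifted seed until
    every rule has both classes present."""
    last_err: Exception | None = None
    for shift in range(max_resamples):
        molecules = generate_molecules(
            GeneratorConfig(**{**cfg.__dict__, "seed": cfg.seed + shift}))
        try:
            return make_classification_task(molecules, rules)
        except ValueError as err:
            last_err = err
    raise ValueError(f"could not obtain both classes: {last_err}")


def make_regression_task(molecules: list[str], noise_sd: float = 0.5,
                         seed: int = 0) -> pd.DataFrame:
    """Regression target: heavy-atom count plus seeded Gaussian noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    counts = np.array([mol_io.parse_smiles(s).n_atoms for s in molecules],
                      dtype=np.float64)
    noise = rng.normal(0.0, noise_sd, size=len(molecules)) if noise_sd > 0 \
        else np.zeros(len(molecules))
    return pd.DataFrame({"smiles": molecules, "target": counts + noise})
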