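"""Compound fixtures, structure parsing, and constitutional descriptors.

The 22 library compounds ship as a packaged CSV
(``fluoroqspr/data/compounds.csv``) with their structures (SMILES), series
metadata and the experimental logD(7.4) / conjugate-acid pKa values, stored
to two decimals exactly as reported.  Missing measurements are empty cells
(never 0): the two water-unstable compounds (21, 22) have no logD, and a few
pKa / logD slots whose printed values could not be transcribed reliably are
left empty as well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

from . import tpsa as _tpsa
from .errors import ParseError

RDLogger.DisableLog("rdApp.*")

SERIES = ("methyl", "ethyl")
SULFUR_STATES = ("thioether", "sulfone")

#: compound ids whose pKa appears only in a figure panel and could not be
#: cross-checked against the running text.
UNVERIFIED_PKA_IDS = frozenset({2, 4, 7})

#: compounds that decomposed in aqueous media; logD is experimentally absent.
WATER_UNSTABLE_IDS = frozenset({21, 22})


@dataclass(frozen=True)
class Compound:
    """One pyridine derivative of the library."""

    id: int
    name: str
    smiles: str
    series: str
    sulfur_state: str
    logd_exp: float | None = None
    pka_exp: float | None = None

    def __post_init__(self) -> None:
        if self.series not in SERIES:
            raise ValueError(f"unknown series {self.series!r}")
        if self.sulfur_state not in SULFUR_STATES:
            raise ValueError(f"unknown sulfur state {self.sulfur_state!r}")

    @property
    def mol(self) -> Chem.Mol:
        return parse_structure(self.smiles)

    @property
    def n_fluorine(self) -> int:
        return count_fluorines(self)


def parse_structure(smiles: str) -> Chem.Mol:
    """Parse a SMILES string into an RDKit molecule (deterministic).

    Raises
    ------
    ParseError
        For malformed input; the message carries the offending token
        (the longest prefix that still parses marks the break point).
    """
    if not isinstance(smiles, str) or not smiles:
        raise ParseError(f"empty or non-string SMILES: {smiles!r}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        # locate the break point: longest prefix accepted by the grammar
        bad = smiles
        for i in range(len(smiles), 0, -1):
            if Chem.MolFromSmiles(smiles[:i], sanitize=False) is not None:
                bad = smiles[i : i + 1] or smiles[i - 1 :]
                break
        raise ParseError(f"cannot parse SMILES {smiles!r}: offending token {bad!r}")
    return mol


def count_fluorines(compound: Compound | Chem.Mol | str) -> int:
    """Number of fluorine atoms (the ``#F`` descriptor)."""
    mol = _as_mol(compound)
    return sum(1 for a in mol.GetAtoms() if a.GetSymbol() == "F")


def constitutional_descriptors(compound: Compound | Chem.Mol | str) -> dict[str, float]:
    """Constitutional/topological descriptor vector for one structure.

    Returns total atom count (H included), heavy-atom count, ``#F``,
    molecular weight and the fragment-contribution TPSA.
    """
    mol = _as_mol(compound)
    mol_h = Chem.AddHs(mol)
    return {
        "n_atoms": float(mol_h.GetNumAtoms()),
        "n_heavy": float(mol.GetNumHeavyAtoms()),
        "#F": float(count_fluorines(mol)),
        "MW": float(Descriptors.MolWt(mol)),
        "TPSA": float(_tpsa.tpsa(mol)),
    }


def _as_mol(obj: Compound | Chem.Mol | str) -> Chem.Mol:
    if isinstance(obj, Compound):
        return obj.mol
    if isinstance(obj, str):
        return parse_structure(obj)
    return obj


def load_library(path: str | Path | None = None) -> list[Compound]:
    """Load compounds from ``path`` or the packaged fixture CSV."""
    if path is None:
        with resources.files("fluoroqspr.data").joinpath("compounds.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    compounds = []
    for row in df.itertuples(index=False):
        compounds.append(
            Compound(
                id=int(row.id),
                name=str(row.name),
                smiles=str(row.smiles),
                series=str(row.series),
                sulfur_state=str(row.sulfur_state),
                logd_exp=_maybe(row.logd_exp),
                pka_exp=_maybe(row.pka_exp),
            )
        )
    validate_library(compounds)
    return compounds


def _maybe(x) -> float | None:
    try:
        x = float(x)
    except (TypeError, ValueError):
        return None
    return None if math.isnan(x) else x


def validate_library(compounds: list[Compound]) -> None:
    """Check the structural invariants of a compound set."""
    for c in compounds:
        mol = c.mol
        n_s = sum(1 for a in mol.GetAtoms() if a.GetSymbol() == "S")
        if n_s != 1:
            raise ValueError(f"compound {c.id}: expected exactly one S, found {n_s}")
        s_atom = next(a for a in mol.GetAtoms() if a.GetSymbol() == "S")
        n_o_on_s = sum(1 for nb in s_atom.GetNeighbors() if nb.GetSymbol() == "O")
        expected_o = 2 if c.sulfur_state == "sulfone" else 0
        if n_o_on_s != expected_o:
            raise ValueError(
                f"compound {c.id}: {c.sulfur_state} must carry {expected_o} O on S, "
                f"found {n_o_on_s}"
            )
        if c.id in WATER_UNSTABLE_IDS and c.logd_exp is not None:
            raise ValueError(f"compound {c.id} is water-unstable; logd_exp must be absent")


def library_table(compounds: list[Compound] | None = None) -> pd.DataFrame:
    """Constitutional descriptors for each compound, indexed by compound id."""
    compounds = compounds if compounds is not None else load_library()
    rows = {c.id: constitutional_descriptors(c) for c in compounds}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "compound_id"
    return df
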