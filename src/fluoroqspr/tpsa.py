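"""Topological polar surface area from an explicit fragment-contribution table.

The table is deliberately restricted to the atom environments occurring in the
2-(thio/sulfonylalkyl)pyridine library: aromatic ring nitrogen, divalent
thioether sulfur, sulfonyl sulfur and its double-bonded oxygens, plus the
non-polar atoms (C, H, F) which contribute 0 by definition.  Any polar atom
(N, O, S, P) falling outside these environments raises ``ContributionError``
rather than being silently counted as 0.
"""

from __future__ import annotations

from rdkit import Chem

from .errors import ContributionError

#: Contribution (A^2) per atom environment key.  Values are the published
#: fragment contributions for these environments (N/O set plus the extended
#: S entries).
CONTRIBUTIONS: dict[str, float] = {
    # polar environments present in the library
    "N_arom_2conn_0H": 12.89,   # pyridine-type ring nitrogen
    "S_2conn_0H_allsingle": 25.30,  # thioether -S-
    "S_4conn_2dbl": 8.38,       # sulfonyl S(=O)(=O)
    "O_1conn_dbl": 17.07,       # sulfonyl =O
    # non-polar atoms: explicit zeros, never looked-up implicitly
    "C": 0.0,
    "H": 0.0,
    "F": 0.0,
}

_POLAR_ELEMENTS = {"N", "O", "S", "P"}


def atom_environment(atom: Chem.Atom) -> str:
    """Classify an atom into a contribution-table key.

    Raises
    ------
    ContributionError
        If the atom is polar (N/O/S/P) but its environment has no entry.
    """
    sym = atom.GetSymbol()
    if sym not in _POLAR_ELEMENTS:
        if sym in CONTRIBUTIONS:
            return sym
        raise ContributionError(
            f"no contribution entry for element {sym!r} (atom idx {atom.GetIdx()})"
        )
    n_conn = atom.GetDegree()
    n_h = atom.GetTotalNumHs()
    bonds = [b.GetBondType() for b in atom.GetBonds()]
    n_dbl = sum(1 for b in bonds if b == Chem.BondType.DOUBLE)
    if sym == "N" and atom.GetIsAromatic() and n_conn == 2 and n_h == 0:
        return "N_arom_2conn_0H"
    if (
        sym == "S"
        and not atom.GetIsAromatic()
        and n_conn == 2
        and n_h == 0
        and all(b == Chem.BondType.SINGLE for b in bonds)
    ):
        return "S_2conn_0H_allsingle"
    if sym == "S" and n_conn == 4 and n_dbl == 2:
        return "S_4conn_2dbl"
    if sym == "O" and n_conn == 1 and n_dbl == 1:
        return "O_1conn_dbl"
    raise ContributionError(
        f"polar atom {sym!r} (idx {atom.GetIdx()}, {n_conn} connections, "
        f"{n_h} H, {n_dbl} double bonds) has no contribution entry"
    )


def tpsa(mol: Chem.Mol) -> float:
    """Sum fragment contributions over all atoms of ``mol``."""
    return sum(CONTRIBUTIONS[atom_environment(a)] for a in mol.GetAtoms())
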