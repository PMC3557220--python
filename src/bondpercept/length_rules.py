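"""Length rules: classify every still-unfixed bond by its length.

For a bond between elements with a reference entry (L1 = single threshold,
L2 = double threshold) the classification is a strict-< cascade, each step
tried only if the previous failed:

    L < L2          -> order 2 (definite double)
    L < L2 + 0.05   -> code 5 (unsure, leaning double)
    L < L1 - 0.04   -> code 4 (unsure)
    L < L1          -> code 6 (unsure, leaning single)
    otherwise       -> order 1 (definite single)

Bonds involving hydrogen or a halogen are definite singles (the oxoacid
cases were already handled by the hard rules), and element pairs missing
from the table fall straight to code 4.
"""

from __future__ import annotations

from .model import Bond, HALOGENS, Molecule
from .tables import LengthTable

PROVISIONAL_DOUBLE_MARGIN = 0.05   # L2 + 0.05 -> code 5
PROVISIONAL_SINGLE_MARGIN = 0.04   # L1 - 0.04 -> code 4 / 6 split


def classify_by_length(element_i: str, element_j: str, length: float,
                       table: LengthTable) -> int:
    """Bond-type code (1, 2, 4, 5 or 6) for an unfixed bond."""
    if "H" in (element_i, element_j):
        return 1
    if element_i in HALOGENS or element_j in HALOGENS:
        return 1
    entry = table.lookup(element_i, element_j)
    if entry is None:
        return 4
    l1, l2 = entry
    # derived thresholds are rounded so the decimal breakpoints are bit-exact
    # (1.33 + 0.05 must compare as 1.38, not 1.3800000000000001)
    if length < l2:
        return 2
    if length < round(l2 + PROVISIONAL_DOUBLE_MARGIN, 6):
        return 5
    if length < round(l1 - PROVISIONAL_SINGLE_MARGIN, 6):
        return 4
    if length < l1:
        return 6
    return 1


def apply_length_rules(mol: Molecule, table: LengthTable) -> Molecule:
    for bond in mol.bonds:
        if bond.fixed:
            continue
        code = classify_by_length(mol.atoms[bond.i].element,
                                  mol.atoms[bond.j].element,
                                  bond.length, table)
        if code in (1, 2):
            bond.fix(code, "length")
        else:
            bond.code = code
            bond.provenance = "length:provisional"
    return mol
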