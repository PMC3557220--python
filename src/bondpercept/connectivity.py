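"""Sigma-framework detection from raw coordinates, plus over-connection repair.

A bond is created between atoms i and j iff

    0.8 < d_ij < r_i + r_j + 0.4        (strict, Angstrom)

with r the single-bond covalent radii.  The 0.4 A margin admits stretched
bonds in poorly refined structures; the absolute 0.8 A floor rejects
coincident or colliding atoms.  Every created bond starts as an unfixed
single; bonds touching an element outside the supported set are pinned at
order 1 immediately.

Over-connection repair then removes, for every C/N/P/S atom with more than
four neighbours, the longest incident bond until the degree drops to four.
Other elements are left alone here — their spurious contacts are handled by
the final valence repair pass.
"""

from __future__ import annotations

from scipy.spatial import cKDTree

from .model import Molecule
from .tables import RadiiTable, ValenceTable

#: Elements whose connection count is capped at this stage; other elements
#: are handled only by the final valence repair.
OVERCONNECTION_ELEMENTS = frozenset({"C", "N", "P", "S"})

DEFAULT_LOWER_CUTOFF = 0.8
DEFAULT_UPPER_MARGIN = 0.4


def detect_bonds(mol: Molecule, radii: RadiiTable,
                 lower_cutoff: float = DEFAULT_LOWER_CUTOFF,
                 upper_margin: float = DEFAULT_UPPER_MARGIN) -> Molecule:
    """Create the initial bond set from the distance criterion.

    Uses a k-d tree to restrict the candidate pairs; the accepted set is
    identical to the naive all-pairs scan because every pair within the
    largest possible upper bound is re-tested exactly.
    """
    if len(mol.atoms) == 0:
        raise ValueError("detect_bonds: molecule has no atoms")
    if mol.bonds:
        raise ValueError("detect_bonds: molecule already has bonds")

    coords = mol.coords_of(range(len(mol.atoms)))
    rad = [radii.get(a.element) for a in mol.atoms]
    rmax = max(rad) if rad else 0.0
    tree = cKDTree(coords)
    for i, j in sorted(map(tuple, tree.query_pairs(2.0 * rmax + upper_margin))):
        if i > j:
            i, j = j, i
        d = float(((coords[i] - coords[j]) ** 2).sum() ** 0.5)
        if not (lower_cutoff < d < rad[i] + rad[j] + upper_margin):
            continue
        bond = mol.create_bond(i, j, code=1, fixed=False)
        if mol.atoms[i].inert or mol.atoms[j].inert:
            bond.fix(1, "inert-element")

    for atom in mol.atoms:
        if mol.degree(atom.index) == 0:
            mol.warn(f"atom {atom.index} ({atom.element}) has no bonds")
    return mol


def correct_overconnection(mol: Molecule, valences: ValenceTable) -> Molecule:
    """Remove the longest incident bond of every over-connected C/N/P/S atom,
    repeatedly, until its degree is back within the element's limit.

    Equal-length ties are broken by removing the lexicographically larger
    (i, j) pair; atoms are visited in ascending index order.
    """
    for atom in mol.atoms:
        if atom.element not in OVERCONNECTION_ELEMENTS:
            continue
        limit = valences.max_connections(atom.element)
        while mol.degree(atom.index) > limit:
            worst = max(mol.incident_bonds(atom.index),
                        key=lambda b: (round(b.length, 6), b.key))
            mol.remove_bond(*worst.key)
            mol.warn(
                f"over-connected {atom.element}{atom.index}: removed bond "
                f"{worst.key} ({worst.length:.2f} A)")
    return mol
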