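"""Final repair pass: delete spurious single bonds at over-valent atoms.

After typing, an atom may exceed its element's maximum valence (iCon, the
sum of its incident bond orders, too large) — typically a spurious contact
that the distance criterion accepted.  Only single bonds are candidates for
deletion: a bond typed double or triple earned that order from a reliable
length or geometry signal.  The longest incident single bond is removed,
repeatedly, until the atom is back within its ceiling; if no single bond is
left while still over-valent, a warning is recorded and the structure is
emitted as-is.
"""

from __future__ import annotations

from .model import Molecule
from .tables import ValenceTable


def fix_overvalence(mol: Molecule, valences: ValenceTable) -> Molecule:
    for atom in mol.atoms:
        if atom.element not in valences:
            continue  # inert elements have no meaningful valence ceiling
        while True:
            n_oxy = sum(1 for n in mol.neighbors(atom.index)
                        if mol.atoms[n].element == "O")
            ceiling = valences.effective_max_valence(atom.element, n_oxy)
            icon = mol.total_order(atom.index)
            if icon <= ceiling:
                break
            singles = [b for b in mol.incident_bonds(atom.index)
                       if not b.provisional and b.code == 1]
            if not singles:
                mol.warn(
                    f"atom {atom.index} ({atom.element}) over-valent "
                    f"(iCon={icon} > {ceiling}) with no removable single bond")
                break
            worst = max(singles, key=lambda b: (round(b.length, 6), b.key))
            mol.remove_bond(*worst.key)
            mol.warn(
                f"over-valent {atom.element}{atom.index}: removed single bond "
                f"{worst.key} ({worst.length:.2f} A)")
    return mol
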