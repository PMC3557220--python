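"""Hard rules: unambiguous chemistry keyed on an atom's connection count.

The four rule families fire in order of increasing degree.  They only ever
*fix* bonds at definite orders (1/2/3) and never touch a bond that an earlier
rule already fixed, so a second pass is a no-op.

Degree 1: terminal H and halogens bond singly; terminal S on P and terminal
N on S are double (phosphine sulfides, S-nitroso-type groups); any other
terminal atom — notably carbonyl-type oxygen — is left for later rules.

Degree 2: divalent O and S always bond singly (ethers, thioethers, water).
For other elements a near-linear arrangement (angle > 175 deg) signals an sp
centre; three sub-models assign a triple (when the far atom continues a
linear chain, e.g. alkynes), a terminal double (cyanide-like far atom), or a
cumulated double pair (CO2-like), whichever first fits the already-fixed
bonds.

Degree 3: N/P (and S/Cl/Br/I) carrying terminal oxygens are oxoacid centres
and get the acid model; N/P without them pyramidalize to all-single.  For
carbon the plane statistic decides: puckered (cos > 0.25) means sp3 and
all-single, planar means one of four small sp2 patterns (carboxylate,
carbonyl, thiocarbonyl, guanidinium-like CN3) — everything a pattern does not
determine stays open for the length and conjugation rules.

Degree 4: tetra-coordinate C/N is saturated; tetra-coordinate P/S/Cl/Br/I is
an oxoacid centre (sulfone, phosphate, perchlorate, ...).

The acid model assigns double bonds to a centre's terminal oxygens, shortest
bond first, up to the element's spare valence (max valence minus degree),
and single bonds to everything else around the centre.
"""

from __future__ import annotations

from .geometry import atom_plane_cos, bond_angle
from .model import Bond, HALOGENS, Molecule
from .tables import ValenceTable

DEFAULT_PLANARITY_COS = 0.25
DEFAULT_LINEAR_ANGLE = 175.0


def _try_fix(bond: Bond, order: int, provenance: str) -> bool:
    """Fix the bond unless that would contradict an earlier assignment."""
    if bond.fixed:
        return bond.code == order
    bond.fix(order, provenance)
    return True


def _terminal_neighbors(mol: Molecule, center: int, element: str) -> list[int]:
    return [n for n in mol.neighbors(center)
            if mol.atoms[n].element == element and mol.degree(n) == 1]


def _acid_model(mol: Molecule, center: int, valences: ValenceTable,
                provenance: str) -> None:
    atom = mol.atoms[center]
    terminal_o = _terminal_neighbors(mol, center, "O")
    ceiling = valences.effective_max_valence(atom.element, len(terminal_o))
    allowance = max(ceiling - mol.degree(center), 0)
    # round the length key so bonds equal up to float noise tie-break by index
    doubles = sorted(terminal_o,
                     key=lambda n: (round(mol.bond(center, n).length, 6), n)
                     )[:allowance]
    for n in mol.neighbors(center):
        order = 2 if n in doubles else 1
        _try_fix(mol.bond(center, n), order, provenance)


def apply_degree1(mol: Molecule) -> Molecule:
    for atom in mol.atoms:
        if mol.degree(atom.index) != 1:
            continue
        bond = mol.incident_bonds(atom.index)[0]
        nbr = mol.atoms[bond.other(atom.index)]
        if atom.element == "H" or atom.element in HALOGENS:
            _try_fix(bond, 1, "hard1:terminal-H/halogen")
        elif atom.element == "S" and nbr.element == "P":
            _try_fix(bond, 2, "hard1:S=P")
        elif atom.element == "N" and nbr.element == "S":
            _try_fix(bond, 2, "hard1:N=S")
        # anything else (e.g. carbonyl O) is left for later rules
    return mol


def _linear_models(mol: Molecule, center: int, j: int, k: int,
                   linear_angle: float) -> None:
    """The three sp-centre sub-models, tried in order until one fits."""
    b_ij = mol.bond(center, j)
    b_ik = mol.bond(center, k)

    # (a) triple bond: a neighbour that is itself a linear 2-connected atom
    # makes the bond to it the middle of three collinear bonds
    for m in (j, k):
        if mol.degree(m) != 2:
            continue
        far = next(n for n in mol.neighbors(m) if n != center)
        far_angle = bond_angle(mol.atoms[m].coords,
                               mol.atoms[center].coords,
                               mol.atoms[far].coords)
        if far_angle <= linear_angle:
            continue
        b_mid = mol.bond(center, m)
        b_out = b_ik if m == j else b_ij
        if (not b_mid.fixed or b_mid.code == 3) and \
           (not b_out.fixed or b_out.code == 1):
            _try_fix(b_mid, 3, "hard2:linear-triple")
            _try_fix(b_out, 1, "hard2:linear-triple")
            return

    # (b) cyanide-like: far atom of the lower-degree branch is C or N
    if mol.atoms[k].element in ("C", "N"):
        if (not b_ij.fixed or b_ij.code == 1) and \
           (not b_ik.fixed or b_ik.code == 2):
            _try_fix(b_ij, 1, "hard2:linear-double")
            _try_fix(b_ik, 2, "hard2:linear-double")
            return

    # (c) cumulated doubles (CO2-like)
    if (not b_ij.fixed or b_ij.code == 2) and \
       (not b_ik.fixed or b_ik.code == 2):
        _try_fix(b_ij, 2, "hard2:linear-cumulene")
        _try_fix(b_ik, 2, "hard2:linear-cumulene")


def apply_degree2(mol: Molecule,
                  linear_angle: float = DEFAULT_LINEAR_ANGLE) -> Molecule:
    for atom in mol.atoms:
        if mol.degree(atom.index) != 2:
            continue
        if atom.element in ("O", "S"):
            # divalent O/S: both bonds single
            for bond in mol.incident_bonds(atom.index):
                _try_fix(bond, 1, "hard2:divalent-O/S")
            continue
        j, k = sorted(mol.neighbors(atom.index),
                      key=lambda n: (-mol.degree(n), n))
        if mol.degree(j) == 1:
            continue  # both neighbours terminal: nothing to infer
        angle = bond_angle(atom.coords, mol.atoms[j].coords, mol.atoms[k].coords)
        if angle > linear_angle:
            _linear_models(mol, atom.index, j, k, linear_angle)
    return mol


def apply_degree3(mol: Molecule, valences: ValenceTable,
                  planarity_cos: float = DEFAULT_PLANARITY_COS) -> Molecule:
    for atom in mol.atoms:
        if mol.degree(atom.index) != 3:
            continue
        el = atom.element
        has_terminal_o = bool(_terminal_neighbors(mol, atom.index, "O"))
        if el in ("N", "P"):
            if has_terminal_o:
                _acid_model(mol, atom.index, valences, "hard3:acid")
            else:
                for bond in mol.incident_bonds(atom.index):
                    _try_fix(bond, 1, "hard3:pyramidal-N/P")
        elif el == "S" or el in HALOGENS:
            if has_terminal_o:
                _acid_model(mol, atom.index, valences, "hard3:acid")
        elif el == "C":
            if atom_plane_cos(mol, atom.index) > planarity_cos:
                for bond in mol.incident_bonds(atom.index):
                    _try_fix(bond, 1, "hard3:puckered-C")
            else:
                _carbon_patterns(mol, atom.index)
    return mol


def _carbon_patterns(mol: Molecule, center: int) -> None:
    """Small sp2-carbon patterns (planar, degree 3)."""
    terminal_o = _terminal_neighbors(mol, center, "O")
    terminal_s = _terminal_neighbors(mol, center, "S")
    nbr_elements = [mol.atoms[n].element for n in mol.neighbors(center)]
    if len(terminal_o) >= 2:
        # carboxylate-like: shortest terminal O bond is the double
        double = min(terminal_o, key=lambda n: (mol.bond(center, n).length, n))
        for n in mol.neighbors(center):
            _try_fix(mol.bond(center, n), 2 if n == double else 1,
                     "hard3:carboxylate")
    elif len(terminal_o) == 1:
        for n in mol.neighbors(center):
            _try_fix(mol.bond(center, n), 2 if n == terminal_o[0] else 1,
                     "hard3:carbonyl")
    elif len(terminal_s) == 1:
        for n in mol.neighbors(center):
            _try_fix(mol.bond(center, n), 2 if n == terminal_s[0] else 1,
                     "hard3:thiocarbonyl")
    elif nbr_elements == ["N", "N", "N"]:
        # guanidinium-like CN3: ambiguous, resolved by the conjugation rules
        pass


def apply_degree4(mol: Molecule, valences: ValenceTable) -> Molecule:
    for atom in mol.atoms:
        if mol.degree(atom.index) != 4:
            continue
        if atom.element in ("C", "N"):
            for bond in mol.incident_bonds(atom.index):
                _try_fix(bond, 1, "hard4:saturated")
        elif atom.element in ("P", "S") or atom.element in HALOGENS:
            _acid_model(mol, atom.index, valences, "hard4:acid")
    return mol


def apply_hard_rules(mol: Molecule, valences: ValenceTable,
                     planarity_cos: float = DEFAULT_PLANARITY_COS,
                     linear_angle: float = DEFAULT_LINEAR_ANGLE) -> Molecule:
    apply_degree1(mol)
    apply_degree2(mol, linear_angle)
    apply_degree3(mol, valences, planarity_cos)
    apply_degree4(mol, valences)
    return mol
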