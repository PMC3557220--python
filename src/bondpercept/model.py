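"""Domain types shared by every stage of the perception pipeline.

A molecule here is deliberately minimal: atoms carry only an element symbol
and Cartesian coordinates (all in Angstrom), bonds carry a length, a bond-type
code and a ``fixed`` flag.  Codes 1/2/3 are definite orders (single, double,
triple); codes 4/5/6 are provisional states produced by the length rules
(4 = unsure, 5 = unsure but leaning double, 6 = unsure but leaning single)
and must all be resolved before a structure may be written out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Elements whose bonds the rules actually reason about.  Anything else is
#: treated as inert: its bonds are created by the distance criterion but
#: immediately pinned at order 1.
SUPPORTED_ELEMENTS = frozenset({"H", "C", "N", "O", "F", "P", "S", "CL", "BR", "I"})

HALOGENS = frozenset({"F", "CL", "BR", "I"})

DEFINITE_CODES = frozenset({1, 2, 3})
PROVISIONAL_CODES = frozenset({4, 5, 6})

_ATOMIC_NUMBERS = {
    "H": 1, "B": 5, "C": 6, "N": 7, "O": 8, "F": 9, "NA": 11, "MG": 12,
    "SI": 14, "P": 15, "S": 16, "CL": 17, "K": 19, "CA": 20, "FE": 26,
    "ZN": 30, "SE": 34, "BR": 35, "I": 53,
}


def normalize_element(symbol: str) -> str:
    """Uppercase-normalize an element symbol (``' c'`` -> ``'C'``)."""
    sym = symbol.strip().upper()
    if not sym or not sym.isalpha():
        raise ValueError(f"not an element symbol: {symbol!r}")
    return sym


def atomic_number(element: str) -> int:
    """Atomic number of a normalized symbol; unknown elements sort last."""
    return _ATOMIC_NUMBERS.get(element, 999)


@dataclass
class Atom:
    """One atom: 0-based index, normalized element symbol, coordinates in A."""

    index: int
    element: str
    coords: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.element = normalize_element(self.element)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.index}: coords must be 3 finite numbers")

    @property
    def inert(self) -> bool:
        """True for elements the rules do not type (bonds pinned at 1)."""
        return self.element not in SUPPORTED_ELEMENTS


@dataclass
class Bond:
    """An unordered atom pair; canonicalized so that ``i < j``."""

    i: int
    j: int
    length: float
    code: int = 1
    fixed: bool = False
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("bond endpoints must differ")
        if self.i > self.j:
            self.i, self.j = self.j, self.i
        if self.length <= 0 or not math.isfinite(self.length):
            raise ValueError("bond length must be positive and finite")
        self._check_code()

    def _check_code(self) -> None:
        if self.code not in DEFINITE_CODES | PROVISIONAL_CODES:
            raise ValueError(f"bond code must be in 1..6, got {self.code}")
        if self.fixed and self.code not in DEFINITE_CODES:
            raise ValueError("a fixed bond must have a definite order (1/2/3)")

    @property
    def key(self) -> tuple[int, int]:
        return (self.i, self.j)

    @property
    def provisional(self) -> bool:
        return self.code in PROVISIONAL_CODES

    def other(self, idx: int) -> int:
        if idx == self.i:
            return self.j
        if idx == self.j:
            return self.i
        raise ValueError(f"atom {idx} is not an endpoint of bond {self.key}")

    def fix(self, order: int, provenance: str = "") -> None:
        """Pin the bond at a definite order.  Re-fixing to the same order is a
        no-op; changing a fixed order raises."""
        if order not in DEFINITE_CODES:
            raise ValueError(f"order must be 1, 2 or 3, got {order}")
        if self.fixed and self.code != order:
            raise ValueError(
                f"bond {self.key} already fixed at {self.code}, refusing {order}"
            )
        already = self.fixed
        self.code = order
        self.fixed = True
        if provenance and not already:
            self.provenance = provenance


class Molecule:
    """Atom list + bond list + adjacency view; the pipeline's mutable state."""

    def __init__(self, atoms: list[Atom], bonds: list[Bond] | None = None,
                 provenance: str = ""):
        self.atoms = list(atoms)
        self.provenance = provenance
        self.warnings: list[str] = []
        self._bonds: dict[tuple[int, int], Bond] = {}
        self._adjacency: dict[int, set[int]] = {a.index: set() for a in self.atoms}
        for b in bonds or []:
            self.add_bond(b)

    # -- construction -----------------------------------------------------
    @classmethod
    def from_arrays(cls, elements: list[str], coords, provenance: str = "") -> "Molecule":
        coords = np.asarray(coords, dtype=float)
        atoms = [Atom(i, el, xyz) for i, (el, xyz) in enumerate(zip(elements, coords))]
        return cls(atoms, provenance=provenance)

    def add_bond(self, bond: Bond) -> Bond:
        if bond.key in self._bonds:
            raise ValueError(f"duplicate bond {bond.key}")
        n = len(self.atoms)
        if not (0 <= bond.i < n and 0 <= bond.j < n):
            raise ValueError(f"bond {bond.key} references a missing atom")
        self._bonds[bond.key] = bond
        self._adjacency[bond.i].add(bond.j)
        self._adjacency[bond.j].add(bond.i)
        return bond

    def create_bond(self, i: int, j: int, **kwargs) -> Bond:
        length = float(np.linalg.norm(self.atoms[i].coords - self.atoms[j].coords))
        return self.add_bond(Bond(i, j, length, **kwargs))

    def remove_bond(self, i: int, j: int) -> Bond:
        key = (min(i, j), max(i, j))
        bond = self._bonds.pop(key)
        self._adjacency[key[0]].discard(key[1])
        self._adjacency[key[1]].discard(key[0])
        return bond

    # -- views ------------------------------------------------------------
    @property
    def bonds(self) -> list[Bond]:
        """Bonds in canonical (i, j) order."""
        return [self._bonds[k] for k in sorted(self._bonds)]

    def bond(self, i: int, j: int) -> Bond:
        return self._bonds[(min(i, j), max(i, j))]

    def has_bond(self, i: int, j: int) -> bool:
        return (min(i, j), max(i, j)) in self._bonds

    def neighbors(self, i: int) -> list[int]:
        return sorted(self._adjacency[i])

    def degree(self, i: int) -> int:
        """C_i of the rules: the number of atoms bonded to atom i."""
        return len(self._adjacency[i])

    def incident_bonds(self, i: int) -> list[Bond]:
        return [self.bond(i, j) for j in self.neighbors(i)]

    def adjacent_bonds(self, bond: Bond) -> list[Bond]:
        """Bonds sharing an endpoint with *bond* (the bond itself excluded)."""
        out = []
        for end in bond.key:
            for other in self.incident_bonds(end):
                if other.key != bond.key:
                    out.append(other)
        return out

    def total_order(self, i: int) -> int:
        """iCon: the sum of incident bond orders (provisional codes count as
        their optimistic definite value is unknown, so they are excluded)."""
        return sum(b.code for b in self.incident_bonds(i) if not b.provisional)

    def coords_of(self, indices) -> np.ndarray:
        return np.array([self.atoms[i].coords for i in indices])

    def warn(self, message: str) -> None:
        self.warnings.append(message)

    def __len__(self) -> int:
        return len(self.atoms)

    def __repr__(self) -> str:
        return (f"Molecule({len(self.atoms)} atoms, {len(self._bonds)} bonds, "
                f"provenance={self.provenance!r})")
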