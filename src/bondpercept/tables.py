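"""Parameter tables: covalent radii, reference bond lengths, valence limits.

All three ship as editable plain-text files under ``bondpercept/data`` and can
be overridden from the CLI.  Lookups are order-independent in the element
pair.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .model import HALOGENS, normalize_element

_DATA = resources.files("bondpercept") / "data"


def _iter_rows(text: str):
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if line:
            yield lineno, line.split()


class RadiiTable:
    """Element -> single-bond covalent radius (Angstrom)."""

    def __init__(self, radii: dict[str, float]):
        self.radii = {normalize_element(k): float(v) for k, v in radii.items()}
        for el, r in self.radii.items():
            if not 0.2 < r < 2.5:
                raise ValueError(f"radius for {el} out of range (0.2, 2.5): {r}")
        missing = {"H", "C", "N", "O", "F", "P", "S", "CL", "BR", "I"} - set(self.radii)
        if missing:
            raise ValueError(f"radii table lacks required elements: {sorted(missing)}")

    @classmethod
    def from_file(cls, path: str | Path | None = None) -> "RadiiTable":
        text = (Path(path).read_text() if path
                else (_DATA / "radii.txt").read_text())
        radii = {}
        for lineno, fields in _iter_rows(text):
            if len(fields) != 2:
                raise ValueError(f"radii table line {lineno}: expected 'EL radius'")
            radii[fields[0]] = float(fields[1])
        return cls(radii)

    def __getitem__(self, element: str) -> float:
        return self.radii[normalize_element(element)]

    def get(self, element: str, default: float = 0.77) -> float:
        """Radius with a carbon-like fallback for unlisted (inert) elements."""
        return self.radii.get(normalize_element(element), default)


class LengthTable:
    """Unordered element pair -> (L1 single threshold, L2 double threshold)."""

    def __init__(self, entries: dict[tuple[str, str], tuple[float, float]]):
        self.entries: dict[frozenset, tuple[float, float]] = {}
        for (a, b), (l1, l2) in entries.items():
            a, b = normalize_element(a), normalize_element(b)
            if not l2 < l1:
                raise ValueError(f"{a}-{b}: need L2 < L1, got L1={l1}, L2={l2}")
            self.entries[frozenset((a, b))] = (float(l1), float(l2))

    @classmethod
    def from_file(cls, path: str | Path | None = None) -> "LengthTable":
        text = (Path(path).read_text() if path
                else (_DATA / "bond_lengths.txt").read_text())
        entries = {}
        for lineno, fields in _iter_rows(text):
            if len(fields) != 3 or "-" not in fields[0]:
                raise ValueError(
                    f"length table line {lineno}: expected 'A-B L1 L2'")
            a, b = fields[0].split("-", 1)
            entries[(a, b)] = (float(fields[1]), float(fields[2]))
        return cls(entries)

    def lookup(self, a: str, b: str) -> tuple[float, float] | None:
        return self.entries.get(
            frozenset((normalize_element(a), normalize_element(b))))

    def __contains__(self, pair) -> bool:
        return self.lookup(*pair) is not None


class ValenceTable:
    """Element -> (max connection count, max valence)."""

    def __init__(self, entries: dict[str, tuple[int, int]]):
        self.entries = {}
        for el, (conn, val) in entries.items():
            el = normalize_element(el)
            if not val >= conn >= 1:
                raise ValueError(
                    f"{el}: need max_valence >= max_connections >= 1")
            self.entries[el] = (int(conn), int(val))

    @classmethod
    def from_file(cls, path: str | Path | None = None) -> "ValenceTable":
        text = (Path(path).read_text() if path
                else (_DATA / "valences.txt").read_text())
        entries = {}
        for lineno, fields in _iter_rows(text):
            if len(fields) != 3:
                raise ValueError(
                    f"valence table line {lineno}: expected 'EL conn valence'")
            entries[fields[0]] = (int(fields[1]), int(fields[2]))
        return cls(entries)

    def max_connections(self, element: str) -> int:
        return self.entries[normalize_element(element)][0]

    def max_valence(self, element: str) -> int:
        return self.entries[normalize_element(element)][1]

    def effective_max_valence(self, element: str, oxygen_neighbors: int) -> int:
        """Valence ceiling used by the acid models and the final repair pass.

        Cl/Br/I normally cap at 1, but inside a perceived halogen oxoacid
        (terminal oxygens attached) the ceiling is raised to 7 so that e.g.
        perchlorate keeps its three Cl=O double bonds.
        """
        element = normalize_element(element)
        if element in HALOGENS and element != "F" and oxygen_neighbors >= 1:
            return 7
        return self.max_valence(element)

    def __contains__(self, element: str) -> bool:
        return normalize_element(element) in self.entries


def default_tables(radii_file=None, length_file=None, valence_file=None):
    """The three bundled tables, each optionally overridden by a file path."""
    return (RadiiTable.from_file(radii_file),
            LengthTable.from_file(length_file),
            ValenceTable.from_file(valence_file))
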