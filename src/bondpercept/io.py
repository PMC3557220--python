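"""Readers (PDB via gemmi, XYZ) and writers (SDF V2000, MOL2, PDB).

Readers produce bond-less molecules: connectivity is always re-derived from
the coordinates by the pipeline (CONECT records are ignored unless
explicitly requested).  Writers refuse molecules that still carry
provisional bond codes — an incomplete pipeline is a bug, not an output.
"""

from __future__ import annotations

from pathlib import Path

import gemmi
import numpy as np

from .model import Atom, Bond, Molecule, _ATOMIC_NUMBERS, normalize_element

_TWO_LETTER = {el for el in _ATOMIC_NUMBERS if len(el) == 2}


def display_symbol(element: str) -> str:
    """'CL' -> 'Cl' for output formats that expect mixed case."""
    el = normalize_element(element)
    return el.capitalize()


def _element_from_name(name: str) -> str:
    """Infer the element from a PDB atom name such as 'CL1' or ' CA '."""
    letters = "".join(ch for ch in name.strip().upper() if ch.isalpha())
    if letters[:2] in _TWO_LETTER:
        return letters[:2]
    if letters[:1] in _ATOMIC_NUMBERS:
        return letters[:1]
    raise ValueError(f"cannot infer element from atom name {name!r}")


def read_pdb(path: str | Path, use_conect: bool = False) -> Molecule:
    """Read ATOM/HETATM records of the first model; first altloc kept.

    The element comes from columns 77-78 when present, otherwise it is
    inferred from the atom name.  No bonds are created unless
    ``use_conect=True``, in which case CONECT records are turned into
    unfixed single bonds.
    """
    path = Path(path)
    try:
        structure = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"{path}: unparseable PDB file: {exc}") from exc

    atoms: list[Atom] = []
    serial_to_index: dict[int, int] = {}
    if len(structure) == 0:
        raise ValueError(f"{path}: no models in file")
    model = structure[0]
    for chain in model:
        for residue in chain:
            for atom in residue:
                if atom.altloc not in ("\0", "", "A"):
                    continue
                el_name = atom.element.name
                element = (el_name if el_name and el_name != "X"
                           else _element_from_name(atom.name))
                idx = len(atoms)
                atoms.append(Atom(idx, element,
                                  np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                                  name=atom.name))
                serial_to_index[atom.serial] = idx
    if not atoms:
        raise ValueError(f"{path}: no ATOM/HETATM records found")

    mol = Molecule(atoms, provenance=f"{path.name} (pdb)")
    if use_conect:
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.startswith("CONECT"):
                continue
            try:
                serials = [int(line[s:s + 5])
                           for s in range(6, min(len(line), 31), 5)
                           if line[s:s + 5].strip()]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad CONECT record") from exc
            origin = serials[0]
            for target in serials[1:]:
                if origin in serial_to_index and target in serial_to_index:
                    i, j = serial_to_index[origin], serial_to_index[target]
                    if i != j and not mol.has_bond(i, j):
                        mol.create_bond(i, j, code=1, fixed=False)
    return mol


def read_xyz(path: str | Path) -> Molecule:
    """Standard XYZ: count line, comment line, ``element x y z`` rows."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].strip():
        raise ValueError(f"{path}: empty XYZ file")
    try:
        count = int(lines[0].split()[0])
    except ValueError as exc:
        raise ValueError(f"{path}:1: expected an atom count") from exc
    rows = [ln for ln in lines[2:2 + count]]
    body = [ln for ln in lines[2:] if ln.strip()]
    if len(body) != count or len(rows) < count:
        raise ValueError(
            f"{path}: count line says {count} atoms but found {len(body)} rows")
    atoms = []
    for offset, line in enumerate(rows):
        fields = line.split()
        if len(fields) < 4:
            raise ValueError(f"{path}:{offset + 3}: expected 'element x y z'")
        atoms.append(Atom(offset, fields[0],
                          np.array([float(x) for x in fields[1:4]])))
    return Molecule(atoms, provenance=f"{path.name} (xyz)")


def _require_definite(mol: Molecule, what: str) -> None:
    bad = [b.key for b in mol.bonds if b.provisional]
    if bad:
        raise ValueError(
            f"cannot write {what}: pipeline incomplete, provisional bonds "
            f"remain at {bad}")


def write_sdf(mol: Molecule, path: str | Path, name: str = "") -> None:
    """Write a single V2000 MOL record (atom order preserved, 1-based)."""
    _require_definite(mol, "SDF")
    lines = [name or mol.provenance or "molecule",
             "  bondpercept 3D",
             "",
             f"{len(mol.atoms):3d}{len(mol.bonds):3d}  0  0  0  0  0  0  0  0999 V2000"]
    for atom in mol.atoms:
        x, y, z = atom.coords
        lines.append(f"{x:10.4f}{y:10.4f}{z:10.4f} {display_symbol(atom.element):<3s}"
                     " 0  0  0  0  0  0  0  0  0  0  0  0")
    for bond in mol.bonds:
        lines.append(f"{bond.i + 1:3d}{bond.j + 1:3d}{bond.code:3d}  0")
    lines += ["M  END", "$$$$", ""]
    Path(path).write_text("\n".join(lines))


def write_mol2(mol: Molecule, path: str | Path, name: str = "") -> None:
    """Write a Tripos MOL2 file with plain element atom types."""
    _require_definite(mol, "MOL2")
    lines = ["@<TRIPOS>MOLECULE",
             name or mol.provenance or "molecule",
             f"{len(mol.atoms)} {len(mol.bonds)} 0 0 0",
             "SMALL",
             "NO_CHARGES",
             "",
             "@<TRIPOS>ATOM"]
    counters: dict[str, int] = {}
    for atom in mol.atoms:
        el = display_symbol(atom.element)
        counters[el] = counters.get(el, 0) + 1
        atom_name = atom.name.strip() or f"{el}{counters[el]}"
        x, y, z = atom.coords
        lines.append(f"{atom.index + 1:>7d} {atom_name:<8s}"
                     f"{x:10.4f}{y:10.4f}{z:10.4f} {el:<5s} 1 LIG")
    lines.append("@<TRIPOS>BOND")
    for n, bond in enumerate(mol.bonds, start=1):
        lines.append(f"{n:>6d}{bond.i + 1:>6d}{bond.j + 1:>6d} {bond.code}")
    lines.append("")
    Path(path).write_text("\n".join(lines))


def write_pdb(mol: Molecule, path: str | Path, residue_name: str = "LIG") -> None:
    """Write the atoms as HETATM records (used by ``fixtures --emit``)."""
    counters: dict[str, int] = {}
    lines = []
    for atom in mol.atoms:
        el = display_symbol(atom.element)
        counters[el] = counters.get(el, 0) + 1
        atom_name = atom.name.strip() or f"{el.upper()}{counters[el]}"
        name_field = f" {atom_name:<3s}" if len(atom_name) < 4 else f"{atom_name:<4s}"
        x, y, z = atom.coords
        lines.append(
            f"HETATM{atom.index + 1:5d} {name_field}{residue_name:>4s} A   1    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {el.upper():>2s}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
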