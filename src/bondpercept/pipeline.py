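"""End-to-end perception: detect -> repair -> hard -> length -> conjugation
-> valence fix, with a machine-readable report of what happened.

The stage order follows the algorithm's flow chart and is not iterated:
each stage sees the state the previous one left behind, and the valence
repair at the end does not loop back into re-perception.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from . import connectivity, hard_rules, length_rules, valence_fix
from .conjugation import (DEFAULT_ANGLE_TOLERANCE, DEFAULT_EDGE_PLANARITY_COS,
                          DEFAULT_MAX_STATES, DEFAULT_PLANARITY_COS_CONJ,
                          GroupTrace, resolve_conjugation)
from .io import read_pdb, read_xyz
from .model import Molecule
from .tables import LengthTable, RadiiTable, ValenceTable, default_tables


@dataclass
class PerceptionOptions:
    lower_cutoff: float = connectivity.DEFAULT_LOWER_CUTOFF
    upper_margin: float = connectivity.DEFAULT_UPPER_MARGIN
    planarity_cos: float = hard_rules.DEFAULT_PLANARITY_COS
    linear_angle: float = hard_rules.DEFAULT_LINEAR_ANGLE
    planarity_cos_conj: float = DEFAULT_PLANARITY_COS_CONJ
    edge_planarity_cos: float = DEFAULT_EDGE_PLANARITY_COS
    angle_tolerance: float = DEFAULT_ANGLE_TOLERANCE
    max_states: int = DEFAULT_MAX_STATES


@dataclass
class PerceptionReport:
    """Per-bond provenance, warnings and summary counts for one molecule."""

    provenance: str = ""
    bond_records: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    order_counts: dict[int, int] = field(default_factory=dict)
    groups: list[GroupTrace] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "input": self.provenance,
            "bonds": self.bond_records,
            "warnings": list(self.warnings),
            "order_counts": {str(k): v
                             for k, v in sorted(self.order_counts.items())},
            "conjugation_groups": [
                {
                    "bonds": [list(k) for k in g.keys],
                    "method": g.method,
                    "isomer_entropies": [iso.entropy for iso in g.isomers],
                    "selected_entropy": (g.selected.entropy
                                         if g.selected else None),
                }
                for g in self.groups
            ],
        }


def _resolve_tables(radii, lengths, valences):
    if radii is None or lengths is None or valences is None:
        d_radii, d_lengths, d_valences = default_tables()
        radii = radii or d_radii
        lengths = lengths or d_lengths
        valences = valences or d_valences
    return radii, lengths, valences


def _type_and_report(mol: Molecule, lengths: LengthTable,
                     valences: ValenceTable,
                     opts: PerceptionOptions) -> tuple[Molecule, PerceptionReport]:
    """Stages downstream of connectivity, shared by both entry points."""
    connectivity.correct_overconnection(mol, valences)
    hard_rules.apply_hard_rules(mol, valences, opts.planarity_cos,
                                opts.linear_angle)
    length_rules.apply_length_rules(mol, lengths)
    group_trace: list[GroupTrace] = []
    resolve_conjugation(mol, valences, opts.planarity_cos_conj,
                        opts.edge_planarity_cos, opts.angle_tolerance,
                        opts.max_states, trace=group_trace)
    valence_fix.fix_overvalence(mol, valences)

    report = PerceptionReport(provenance=mol.provenance,
                              warnings=list(mol.warnings),
                              groups=group_trace)
    for bond in mol.bonds:
        report.order_counts[bond.code] = report.order_counts.get(bond.code, 0) + 1
        report.bond_records.append({
            "atoms": list(bond.key),
            "elements": [mol.atoms[bond.i].element, mol.atoms[bond.j].element],
            "length": round(bond.length, 4),
            "order": bond.code,
            "assigned_by": bond.provenance,
        })
    return mol, report


def perceive_molecule(mol: Molecule,
                      radii: RadiiTable | None = None,
                      lengths: LengthTable | None = None,
                      valences: ValenceTable | None = None,
                      options: PerceptionOptions | None = None,
                      ) -> tuple[Molecule, PerceptionReport]:
    """Run the full pipeline on a bond-less molecule."""
    opts = options or PerceptionOptions()
    radii, lengths, valences = _resolve_tables(radii, lengths, valences)
    connectivity.detect_bonds(mol, radii, opts.lower_cutoff, opts.upper_margin)
    return _type_and_report(mol, lengths, valences, opts)


def perceive_preconnected(mol: Molecule,
                          lengths: LengthTable | None = None,
                          valences: ValenceTable | None = None,
                          options: PerceptionOptions | None = None,
                          ) -> tuple[Molecule, PerceptionReport]:
    """Pipeline variant for input that already carries connectivity
    (e.g. CONECT records); detection is skipped, typing runs as usual."""
    opts = options or PerceptionOptions()
    _, lengths, valences = _resolve_tables(None, lengths, valences)
    for bond in mol.bonds:
        if mol.atoms[bond.i].inert or mol.atoms[bond.j].inert:
            bond.fix(1, "inert-element")
    return _type_and_report(mol, lengths, valences, opts)


def perceive_file(path: str | Path, fmt: str | None = None,
                  use_conect: bool = False,
                  **kwargs) -> tuple[Molecule, PerceptionReport]:
    """Read a PDB or XYZ file (format by extension unless given) and perceive."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "pdb":
        mol = read_pdb(path, use_conect=use_conect)
        if use_conect and mol.bonds:
            kwargs.pop("radii", None)
            return perceive_preconnected(mol, **kwargs)
    elif fmt == "xyz":
        mol = read_xyz(path)
    else:
        raise ValueError(f"unsupported input format: {fmt!r}")
    return perceive_molecule(mol, **kwargs)
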