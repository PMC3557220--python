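"""Degree-keyed hard rules: terminal atoms, sp centres, acid models,
planarity-gated carbon patterns."""

import math

import numpy as np
import pytest

from bondpercept import (apply_degree1, apply_degree2, apply_degree3,
                         apply_degree4, apply_hard_rules, build_fixture,
                         detect_bonds)
from bondpercept.geometry import atom_plane_cos
from bondpercept.model import Molecule


def bonded(elements, coords):
    mol = Molecule.from_arrays(elements, coords)
    return mol


def chain(mol, *pairs):
    for i, j in pairs:
        mol.create_bond(i, j)
    return mol


# -- degree 1 ----------------------------------------------------------------

def test_terminal_hydrogen_fixed_single():
    mol = chain(bonded(["C", "H"], [[0, 0, 0], [1.09, 0, 0]]), (0, 1))
    apply_degree1(mol)
    assert mol.bond(0, 1).fixed and mol.bond(0, 1).code == 1


def test_terminal_sulfur_on_phosphorus_is_double():
    mol = chain(bonded(["P", "S"], [[0, 0, 0], [1.95, 0, 0]]), (0, 1))
    apply_degree1(mol)
    assert mol.bond(0, 1).code == 2 and mol.bond(0, 1).fixed


def test_terminal_nitrogen_on_sulfur_is_double():
    mol = chain(bonded(["S", "N"], [[0, 0, 0], [1.55, 0, 0]]), (0, 1))
    apply_degree1(mol)
    assert mol.bond(0, 1).code == 2


def test_terminal_oxygen_left_unfixed():
    mol = chain(bonded(["C", "O"], [[0, 0, 0], [1.21, 0, 0]]), (0, 1))
    apply_degree1(mol)
    assert not mol.bond(0, 1).fixed


# -- degree 2 ----------------------------------------------------------------

def test_divalent_oxygen_bonds_single():
    # water-like: H-O-C
    mol = chain(bonded(["H", "O", "C"],
                       [[-0.96, 0, 0], [0, 0, 0], [1.0, 1.0, 0]]),
                (0, 1), (1, 2))
    apply_degree1(mol)
    apply_degree2(mol)
    assert mol.bond(0, 1).code == 1 and mol.bond(1, 2).code == 1
    assert mol.bond(1, 2).fixed


def test_internal_alkyne_gets_triple_then_single():
    fx = build_fixture("acetylene")
    mol, _ = _through_hard(fx)
    assert mol.bond(0, 1).code == 3
    assert all(mol.bond(*b.key).code == 1
               for b in mol.bonds if b.key != (0, 1))


def test_propyne_triple_assignment_is_atom_order_independent():
    fx = build_fixture("propyne")
    mol, _ = _through_hard(fx)
    assert mol.bond(1, 2).code == 3 and mol.bond(0, 1).code == 1


def test_cumulated_double_model():
    # HN=C=O: the linear centre where neither the triple nor the
    # terminal-C/N model applies takes two doubles
    fx = build_fixture("isocyanic_acid")
    mol, _ = _through_hard(fx)
    assert mol.bond(0, 1).code == 2 and mol.bond(1, 2).code == 2


def test_both_neighbors_terminal_skips_linear_analysis():
    # O=C=O at this stage: both neighbours are terminal, rule 2 passes
    fx = build_fixture("carbon_dioxide")
    mol = fx.molecule
    from bondpercept import default_tables
    radii, _, valences = default_tables()
    detect_bonds(mol, radii)
    apply_hard_rules(mol, valences)
    assert not mol.bond(0, 1).fixed and not mol.bond(1, 2).fixed


def _through_hard(fx):
    from bondpercept import default_tables
    radii, lengths, valences = default_tables()
    mol = fx.molecule
    detect_bonds(mol, radii)
    apply_hard_rules(mol, valences)
    return mol, valences


# -- degree 3 ----------------------------------------------------------------

def test_nitro_acid_model():
    fx = build_fixture("nitrobenzene")
    mol, _ = _through_hard(fx)
    orders = sorted(mol.bond(6, o).code for o in (7, 8))
    assert orders == [1, 2]           # one N=O, one N-O
    assert mol.bond(0, 6).code == 1   # N-C single


def test_pyramidal_carbon_all_single(valences):
    # degree-3 C with plane statistic just above the 0.25 gate
    h = 0.15
    coords = [[0, 0, h]] + [
        [1.5 * math.cos(a), 1.5 * math.sin(a), 0]
        for a in np.radians([90, 210, 330])]
    mol = chain(bonded(["C", "C", "C", "C"], coords), (0, 1), (0, 2), (0, 3))
    stat = atom_plane_cos(mol, 0)
    assert 0.25 < stat < 0.5
    apply_degree3(mol, valences)
    assert all(b.fixed and b.code == 1 for b in mol.incident_bonds(0))


def test_planar_carbon_with_three_carbons_left_open(valences):
    coords = [[0, 0, 0]] + [
        [1.5 * math.cos(a), 1.5 * math.sin(a), 0]
        for a in np.radians([90, 210, 330])]
    mol = chain(bonded(["C", "C", "C", "C"], coords), (0, 1), (0, 2), (0, 3))
    apply_degree3(mol, valences)
    assert not any(b.fixed for b in mol.incident_bonds(0))


def test_carboxylate_pattern():
    fx = build_fixture("acetate")
    mol, _ = _through_hard(fx)
    assert mol.bond(1, 2).code == 2 and mol.bond(1, 3).code == 1
    assert mol.bond(0, 1).code == 1


def test_carbonyl_pattern():
    fx = build_fixture("acetone")
    mol, _ = _through_hard(fx)
    assert mol.bond(0, 1).code == 2 or mol.bond(0, 1).code == 1
    # the terminal O bond is the double
    o_bond = [b for b in mol.incident_bonds(0)
              if mol.atoms[b.other(0)].element == "O"]
    assert o_bond[0].code == 2


def test_guanidine_degree3_nitrogen_fixes_singles():
    fx = build_fixture("guanidine")
    mol, _ = _through_hard(fx)
    assert mol.bond(0, 2).code == 1 and mol.bond(0, 3).code == 1
    assert not mol.bond(0, 1).fixed  # the C=N resolves by length rules


# -- degree 4 ----------------------------------------------------------------

def test_saturated_carbon_all_single():
    fx = build_fixture("cyclohexane")
    mol, _ = _through_hard(fx)
    assert all(b.fixed and b.code == 1 for b in mol.bonds)


def test_sulfone_two_doubles():
    fx = build_fixture("dimethyl_sulfone")
    mol, _ = _through_hard(fx)
    orders = sorted(b.code for b in mol.incident_bonds(0))
    assert orders == [1, 1, 2, 2]


def test_phosphonate_one_double():
    fx = build_fixture("methylphosphonate")
    mol, _ = _through_hard(fx)
    orders = sorted(b.code for b in mol.incident_bonds(0))  # P is atom 0
    assert orders == [1, 1, 1, 2]


def test_perchlorate_three_doubles():
    fx = build_fixture("perchlorate")
    mol, _ = _through_hard(fx)
    orders = sorted(b.code for b in mol.incident_bonds(0))
    assert orders == [1, 2, 2, 2]


# -- global properties -------------------------------------------------------

@pytest.mark.parametrize("name", ["benzene", "acetic_acid", "nitrobenzene",
                                  "propyne", "urea", "methanesulfonate"])
def test_hard_rules_idempotent(name, valences):
    fx = build_fixture(name)
    mol, _ = _through_hard(fx)
    before = [(b.key, b.code, b.fixed) for b in mol.bonds]
    apply_hard_rules(mol, valences)
    assert [(b.key, b.code, b.fixed) for b in mol.bonds] == before


@pytest.mark.parametrize("name", ["benzamidine", "acetamide", "thiophene"])
def test_hard_rules_definite_codes_only(name):
    fx = build_fixture(name)
    mol, _ = _through_hard(fx)
    for b in mol.bonds:
        if b.fixed:
            assert b.code in (1, 2, 3)
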