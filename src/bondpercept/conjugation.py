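"""Conjugation rules: resolve provisional bonds (codes 4/5/6).

The still-unfixed bonds after the length rules are mostly aromatic or
conjugated.  They are handled in four steps:

1. *Planarity filter.*  Each provisional bond is tested on its local group
   (both endpoints plus all their neighbours).  A plane-deviation cosine
   above 0.50 means the neighbourhood is simply not flat — the bond is a
   single.  A code-6 bond (leaning single) between two at-least-2-connected
   atoms is already dropped to single above 0.2.

2. *Group partition.*  The surviving provisional bonds are split into
   connected groups (bonds adjacent iff they share an atom) and each group
   is resolved as a unit.

3. *Small groups.*  Singleton groups are decided by local context (adjacent
   double bonds, planarity, and the 120-degree angle statistic
   BA = min_j |angle(bond, bond_j) - 120|).  Two-bond groups go through a
   small decision table that returns a code 0/1/2/4/5 decoded as
   O12 = 1 + return // 2, O23 = 1 + return % 2 (4/5 re-dispatch one bond to
   the singleton rule).  NOTE: this decision table is the least-determined
   part of the rule set; the conditions used here are a reconstruction kept
   consistent with the decode formula (see docs/methods.md).

4. *Isomer enumeration.*  Larger groups are kekulized: terminal nitrogens
   are forced single, a deterministic propagation rule runs to a fixed
   point, and the remaining bonds are branched on (set to 2, re-propagate)
   in ascending bond order.  Every complete assignment that respects the
   per-atom valence ceilings is collected as one isomer, the "bond entropy"
   (the number of single bonds flanked by at least two continuing double
   bonds) is computed for each, and the highest-entropy isomer wins; ties go
   to the first one generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .geometry import bond_plane_cos, min_angle_deviation_from_120
from .model import Bond, Molecule
from .tables import ValenceTable

DEFAULT_PLANARITY_COS_CONJ = 0.50
DEFAULT_EDGE_PLANARITY_COS = 0.2
DEFAULT_ANGLE_TOLERANCE = 3.0
DEFAULT_MAX_STATES = 2 ** 20

BondKey = tuple[int, int]


@dataclass
class ConjugationGroup:
    """A connected set of provisional bonds, resolved as a unit."""

    bonds: list[Bond]

    @property
    def keys(self) -> list[BondKey]:
        return [b.key for b in self.bonds]

    @property
    def atoms(self) -> set[int]:
        out: set[int] = set()
        for b in self.bonds:
            out.update(b.key)
        return out

    def __len__(self) -> int:
        return len(self.bonds)


@dataclass
class IsomerAssignment:
    """One complete order assignment for a group plus its entropy score."""

    orders: dict[BondKey, int]
    entropy: int = 0


# ---------------------------------------------------------------------------
# step 1: planarity filter
# ---------------------------------------------------------------------------

def planarity_filter(mol: Molecule,
                     planarity_cos: float = DEFAULT_PLANARITY_COS_CONJ,
                     edge_cos: float = DEFAULT_EDGE_PLANARITY_COS) -> Molecule:
    for bond in mol.bonds:
        if not bond.provisional:
            continue
        value = bond_plane_cos(mol, bond)
        if value > planarity_cos:
            bond.fix(1, "conj:nonplanar")
        elif (bond.code == 6 and value > edge_cos
              and mol.degree(bond.i) >= 2 and mol.degree(bond.j) >= 2):
            bond.fix(1, "conj:nonplanar-lean-single")
    return mol


# ---------------------------------------------------------------------------
# step 2: group partition
# ---------------------------------------------------------------------------

def partition_groups(mol: Molecule) -> list[ConjugationGroup]:
    provisional = [b for b in mol.bonds if b.provisional]
    graph = nx.Graph()
    graph.add_nodes_from(b.key for b in provisional)
    by_atom: dict[int, list[BondKey]] = {}
    for b in provisional:
        for end in b.key:
            by_atom.setdefault(end, []).append(b.key)
    for keys in by_atom.values():
        for other in keys[1:]:
            graph.add_edge(keys[0], other)
    groups = [ConjugationGroup(sorted((mol.bond(*k) for k in comp),
                                      key=lambda b: b.key))
              for comp in nx.connected_components(graph)]
    groups.sort(key=lambda g: min(g.atoms))
    return groups


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def _touches_multiple(mol: Molecule, bond: Bond) -> bool:
    """True if any adjacent bond carries a definite order >= 2.  A triple
    counts: a bond sharing an sp carbon cannot be a double as well."""
    return any(not b.provisional and b.code >= 2
               for b in mol.adjacent_bonds(bond))


def _atom_has_multiple(mol: Molecule, index: int) -> bool:
    return any(not b.provisional and b.code >= 2
               for b in mol.incident_bonds(index))


# ---------------------------------------------------------------------------
# step 3a: singleton groups
# ---------------------------------------------------------------------------

def fix_singleton(mol: Molecule, bond: Bond,
                  angle_tolerance: float = DEFAULT_ANGLE_TOLERANCE,
                  edge_cos: float = DEFAULT_EDGE_PLANARITY_COS) -> Molecule:
    def angle_says_double() -> bool:
        return (bond.code == 5 and
                min_angle_deviation_from_120(mol, bond) < angle_tolerance)

    if _touches_multiple(mol, bond):
        bond.fix(1, "conj:next-to-double")
    elif len(mol.adjacent_bonds(bond)) <= 1:
        # edge-of-structure bond: a 3-atom neighbourhood is trivially planar,
        # so the 120-degree statistic decides instead
        bond.fix(2 if angle_says_double() else 1, "conj:edge-angle")
    elif bond_plane_cos(mol, bond) < edge_cos:
        bond.fix(2, "conj:planar-singleton")
    else:
        bond.fix(2 if angle_says_double() else 1, "conj:angle")
    return mol


# ---------------------------------------------------------------------------
# step 3b: two-bond groups (reconstructed decision table)
# ---------------------------------------------------------------------------

def _pair_return_code(mol: Molecule, b12: Bond, b23: Bond,
                      a1: int, a2: int, a3: int) -> int | None:
    codes = (b12.code, b23.code)
    no_adjacent_double = not any(_atom_has_multiple(mol, a) for a in (a1, a2, a3))
    if no_adjacent_double and set(codes) == {5, 6}:
        return 2 if b12.code == 5 else 1
    third = [b for b in mol.incident_bonds(a2) if b.key not in (b12.key, b23.key)]
    if (any(not b.provisional and b.code == 1 for b in third)
            and (b12.code == 5) != (b23.code == 5)):
        return 2 if b12.code == 5 else 1
    if b12.code == 4 and b23.code > 4:
        return 4
    if b12.code > 4 and b23.code == 4:
        return 5
    if codes == (4, 4) and mol.degree(a1) == 1 and mol.degree(a3) > 1:
        return 0
    return None


def fix_pair(mol: Molecule, group: ConjugationGroup,
             angle_tolerance: float = DEFAULT_ANGLE_TOLERANCE,
             edge_cos: float = DEFAULT_EDGE_PLANARITY_COS) -> bool:
    """Resolve a two-bond group; returns False to fall through to the
    isomer machinery when no pattern matches."""
    b12, b23 = group.bonds
    shared = set(b12.key) & set(b23.key)
    a2 = shared.pop()
    a1, a3 = b12.other(a2), b23.other(a2)
    ret = _pair_return_code(mol, b12, b23, a1, a2, a3)
    if ret is None:
        return False
    if ret in (0, 1, 2):
        b12.fix(1 + ret // 2, "conj:pair")
        b23.fix(1 + ret % 2, "conj:pair")
    elif ret == 4:
        b12.fix(1, "conj:pair")
        fix_singleton(mol, b23, angle_tolerance, edge_cos)
    else:  # ret == 5
        b23.fix(1, "conj:pair")
        fix_singleton(mol, b12, angle_tolerance, edge_cos)
    return True


# ---------------------------------------------------------------------------
# step 4: isomer enumeration and entropy selection
# ---------------------------------------------------------------------------

class _GroupSearch:
    """Seed-and-propagate kekulization of one conjugation group."""

    def __init__(self, mol: Molecule, group: ConjugationGroup,
                 valences: ValenceTable,
                 angle_tolerance: float = DEFAULT_ANGLE_TOLERANCE,
                 max_states: int = DEFAULT_MAX_STATES):
        self.mol = mol
        self.group = group
        self.valences = valences
        self.angle_tolerance = angle_tolerance
        self.max_states = max_states
        self.keys = group.keys
        self.bonds = {b.key: b for b in group.bonds}
        self.states_visited = 0
        self.truncated = False
        # per-atom fixed-order baseline and valence ceiling
        self.base_order: dict[int, int] = {}
        self.ceiling: dict[int, int] = {}
        for a in group.atoms | {n for b in group.bonds for e in b.key
                                for n in mol.neighbors(e)}:
            atom = mol.atoms[a]
            self.base_order[a] = sum(b.code for b in mol.incident_bonds(a)
                                     if not b.provisional)
            n_oxy = sum(1 for n in mol.neighbors(a)
                        if mol.atoms[n].element == "O")
            try:
                self.ceiling[a] = valences.effective_max_valence(
                    atom.element, n_oxy)
            except KeyError:
                self.ceiling[a] = 8  # inert elements: effectively unlimited

    # -- state helpers ---------------------------------------------------
    def _order(self, key: BondKey, state: dict) -> int | None:
        bond = self.mol.bond(*key)
        if not bond.provisional:
            return bond.code
        return state.get(key)

    def _atom_total(self, a: int, state: dict) -> tuple[int, int]:
        """(known total order, number of undetermined incident group bonds)."""
        total, open_ = self.base_order[a], 0
        for b in self.mol.incident_bonds(a):
            if b.provisional:
                v = state.get(b.key)
                if v is None:
                    open_ += 1
                else:
                    total += v
        return total, open_

    def _valence_ok(self, state: dict) -> bool:
        for a in self.group.atoms:
            total, open_ = self._atom_total(a, state)
            # undetermined bonds contribute at least order 1
            if total + open_ > self.ceiling[a]:
                return False
        return True

    # -- the deterministic propagation rule ------------------------------
    def _propagate(self, state: dict) -> bool:
        """Run the fixed-point rule; returns False on a valence dead end."""
        changed = True
        while changed:
            changed = False
            for key in self.keys:
                if state.get(key) is not None:
                    continue
                bond = self.bonds[key]
                # next to a known multiple bond -> single
                if any((o := self._order(b.key, state)) is not None and o >= 2
                       for b in self.mol.adjacent_bonds(bond)):
                    state[key] = 1
                    changed = True
                    continue
                # endpoint with exactly three bonds, the other two single
                for end in key:
                    others = [b for b in self.mol.incident_bonds(end)
                              if b.key != key]
                    if len(others) != 2:
                        continue
                    orders = [self._order(b.key, state) for b in others]
                    if orders != [1, 1]:
                        continue
                    if bond.code == 5:
                        state[key] = 2
                        changed = True
                    elif min_angle_deviation_from_120(self.mol, bond) \
                            > self.angle_tolerance:
                        state[key] = 1
                        changed = True
                    break
            if not self._valence_ok(state):
                return False
        return True

    # -- search ----------------------------------------------------------
    def enumerate(self) -> list[IsomerAssignment]:
        initial: dict[BondKey, int] = {}
        # terminal nitrogens: amine-like by default, force single
        for key in self.keys:
            for end in key:
                atom = self.mol.atoms[end]
                if atom.element == "N" and self.mol.degree(end) == 1:
                    initial[key] = 1
        isomers: list[IsomerAssignment] = []
        seen: set[frozenset] = set()

        def dfs(state: dict) -> None:
            self.states_visited += 1
            if self.states_visited > self.max_states:
                self.truncated = True
                return
            state = dict(state)
            if not self._propagate(state):
                return
            open_keys = [k for k in self.keys if state.get(k) is None]
            if not open_keys:
                sig = frozenset(state.items())
                if sig not in seen:
                    seen.add(sig)
                    isomers.append(IsomerAssignment(dict(state)))
                return
            for key in open_keys:
                if self.truncated:
                    return
                branch = dict(state)
                branch[key] = 2
                dfs(branch)

        dfs(initial)
        if self.truncated:
            self.mol.warn(
                f"conjugation group {self.keys[0]}...: search truncated at "
                f"{self.max_states} states")
        for iso in isomers:
            iso.entropy = bond_entropy(self.mol, self.group, iso.orders)
        return isomers


def enumerate_isomers(mol: Molecule, group: ConjugationGroup,
                      valences: ValenceTable,
                      angle_tolerance: float = DEFAULT_ANGLE_TOLERANCE,
                      max_states: int = DEFAULT_MAX_STATES
                      ) -> list[IsomerAssignment]:
    return _GroupSearch(mol, group, valences, angle_tolerance,
                        max_states).enumerate()


def bond_entropy(mol: Molecule, group: ConjugationGroup,
                 orders: dict[BondKey, int]) -> int:
    """Number of group bonds assigned single that sit between at least two
    double bonds, each of which continues into at least one further bond."""

    def order_of(bond: Bond) -> int | None:
        # the assignment under scoring takes precedence over molecule state,
        # so alternative hypotheses can be scored on a resolved molecule
        if bond.key in orders:
            return orders[bond.key]
        if not bond.provisional:
            return bond.code
        return None

    count = 0
    for key in group.keys:
        bond = mol.bond(*key)
        if order_of(bond) != 1:
            continue
        qualifying = 0
        for adj in mol.adjacent_bonds(bond):
            if order_of(adj) != 2:
                continue
            continues = any(other.key != bond.key
                            for other in mol.adjacent_bonds(adj))
            if continues:
                qualifying += 1
        if qualifying >= 2:
            count += 1
    return count


def select_isomer(isomers: list[IsomerAssignment]) -> IsomerAssignment:
    """Highest entropy wins; ties go to the earliest-generated isomer."""
    if not isomers:
        raise ValueError("select_isomer: empty isomer list")
    return max(isomers, key=lambda iso: iso.entropy)  # max is stable on ties


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class GroupTrace:
    keys: list[BondKey]
    size: int
    method: str
    isomers: list[IsomerAssignment] = field(default_factory=list)
    selected: IsomerAssignment | None = None


def resolve_conjugation(mol: Molecule, valences: ValenceTable,
                        planarity_cos: float = DEFAULT_PLANARITY_COS_CONJ,
                        edge_cos: float = DEFAULT_EDGE_PLANARITY_COS,
                        angle_tolerance: float = DEFAULT_ANGLE_TOLERANCE,
                        max_states: int = DEFAULT_MAX_STATES,
                        trace: list[GroupTrace] | None = None) -> Molecule:
    planarity_filter(mol, planarity_cos, edge_cos)
    for group in partition_groups(mol):
        record = GroupTrace(group.keys, len(group), "")
        if len(group) == 1:
            record.method = "singleton"
            fix_singleton(mol, group.bonds[0], angle_tolerance, edge_cos)
        elif len(group) == 2 and fix_pair(mol, group, angle_tolerance,
                                          edge_cos):
            record.method = "pair-table"
        else:
            record.method = "isomer-enumeration"
            isomers = enumerate_isomers(mol, group, valences,
                                        angle_tolerance, max_states)
            if not isomers:
                mol.warn(f"group {group.keys}: no consistent kekulization, "
                         f"falling back to all-single")
                for bond in group.bonds:
                    bond.fix(1, "conj:fallback")
            else:
                best = select_isomer(isomers)
                ties = sum(1 for iso in isomers
                           if iso.entropy == best.entropy)
                if ties > 1:
                    mol.warn(f"group {group.keys}: {ties} isomers tie at "
                             f"entropy {best.entropy}; kept the first")
                for key, order in best.orders.items():
                    mol.bond(*key).fix(order, "conj:isomer")
                record.isomers = isomers
                record.selected = best
        if trace is not None:
            trace.append(record)
    return mol
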