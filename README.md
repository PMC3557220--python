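# bondpercept

Rule-based perception of covalent connectivity and bond orders for small
organic molecules, from nothing but 3D coordinates and element identities.

Crystallographic ligands usually arrive without hydrogens and without bond
type information: a PDB `HETATM` block says *where* the atoms are, not *how*
they are bonded. Before such a structure can be used in force-field
simulations or docking, every bond must be found and typed single, double or
triple. `bondpercept` does this automatically, with an emphasis on tolerance
to the coordinate errors typical of medium-resolution X-ray structures, and
it works whether or not hydrogens are present.

## The algorithm

Atoms are denoted *A<sub>i</sub>* with coordinates **x**<sub>i</sub>,
coordination number *C<sub>i</sub>*, and bond orders *O<sub>ij</sub>*.
Perception proceeds through fixed stages:

1. **Connectivity.** A bond *b<sub>ij</sub>* exists iff
   0.8 Å < *d<sub>ij</sub>* < *r<sub>i</sub>* + *r<sub>j</sub>* + 0.4 Å,
   with *r* the single-bond covalent radii (Cordero 2008 values, shipped as
   an editable table). The absolute 0.8 Å floor rejects colliding atoms.
   Over-connected C/N/P/S atoms (*C<sub>i</sub>* > 4) then lose their longest
   bonds.
2. **Hard rules**, keyed on *C<sub>i</sub>*: terminal H/halogens bond singly;
   divalent O/S bond singly; near-linear sp centres (angle > 175°) take
   triple, terminal-double or cumulated-double models; trivalent centres are
   split by a plane-deviation statistic cos φ (0 for planar sp², larger when
   puckered; gate 0.25) into sp³ all-single carbons versus small sp²
   patterns (carboxylate, carbonyl, thiocarbonyl, CN₃); oxoacid centres
   (nitro, sulfone, phosphate, perchlorate, …) get double bonds to terminal
   oxygens up to the element's spare valence, shortest bonds first.
3. **Length rules.** Each remaining bond is compared against per-pair
   reference lengths (L1 = single, L2 = double; e.g. C–C 1.49/1.33 Å) in a
   strict cascade: `< L2` ⇒ double; `< L2+0.05` ⇒ code 5 (unsure, leaning
   double); `< L1−0.04` ⇒ code 4 (unsure); `< L1` ⇒ code 6 (unsure, leaning
   single); else single.
4. **Conjugation rules.** Provisional bonds whose neighbourhood is far from
   planar (cos φ > 0.50, or > 0.2 for code 6) become single. The survivors —
   typically aromatic systems — are partitioned into connected groups and
   kekulized: terminal nitrogens go single, a propagation rule runs to a
   fixed point (a bond next to a double is single; a code-5 bond at an
   otherwise-saturated sp² centre is double; a bond deviating more than 3°
   from 120° geometry is single), and remaining bonds are branched on. Every
   complete, valence-consistent assignment is one *Kekulé isomer*; the
   winner maximizes the **bond entropy** — the number of single bonds
   flanked by at least two continuing double bonds (3 for either benzene
   Kekulé form) — with ties broken by generation order.
5. **Valence repair.** Any atom whose summed bond order exceeds its maximum
   valence loses its longest *single* bonds until consistent.

Output is SDF (V2000) and/or MOL2 with orders 1/2/3, plus a JSON report
recording which rule fixed each bond.

## Worked example

The package ships a deterministic catalog of 40+ ideal-geometry molecules
with reference bond orders (no downloads needed). Perceiving benzene from a
bare PDB file:

```
$ bondpercept fixtures --emit benzene benzene.pdb
wrote benzene.pdb (12 atoms)
$ bondpercept perceive benzene.pdb --out-sdf benzene.sdf --trace
benzene.pdb: 12 atoms, 12 bonds (9 x order 1, 3 x order 2)
warning: group [(0, 1), (0, 5), (1, 2), (2, 3), (3, 4), (4, 5)]: 2 isomers tie at entropy 3; kept the first
group [(0, 1), (0, 5), (1, 2), (2, 3), (3, 4), (4, 5)] [isomer-enumeration] isomers=5 entropies=[3, 0, 3, 0, 0] selected=3
wrote benzene.sdf
```

All twelve bonds were found from coordinates alone; the ring became one
conjugation group whose two Kekulé forms tie at entropy 3 (the partial
assignments score 0), and the first-generated form — alternating 2/1/2/1/2/1
— was written out. From Python:

```python
from bondpercept import build_fixture, perceive_molecule

mol, report = perceive_molecule(build_fixture("acetic_acid").molecule)
for rec in report.bond_records:
    i, j = rec["atoms"]
    print(f"{rec['elements'][0]}{i}-{rec['elements'][1]}{j}: "
          f"order {rec['order']}  ({rec['length']:.2f} A, {rec['assigned_by']})")
```

prints

```
C0-C1: order 1  (1.52 A, hard3:carbonyl)
C0-H4: order 1  (1.09 A, hard1:terminal-H/halogen)
C0-H5: order 1  (1.09 A, hard1:terminal-H/halogen)
C0-H6: order 1  (1.09 A, hard1:terminal-H/halogen)
C1-O2: order 2  (1.21 A, hard3:carbonyl)
C1-O3: order 1  (1.36 A, hard2:divalent-O/S)
O3-H7: order 1  (0.97 A, hard1:terminal-H/halogen)
```

— the carboxyl carbon matched the carbonyl pattern (C=O double, the rest
single), the hydroxyl oxygen was typed by the divalent-oxygen rule, and the
hydrogens by the terminal-atom rule.

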