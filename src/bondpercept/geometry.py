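"""Geometric primitives used by the typing rules.

Two quantities drive every geometric decision in the pipeline:

* the bond angle at a vertex (degrees), and
* the plane-deviation cosine of a point group — a dimensionless statistic in
  [0, 1] that is exactly 0 for a coplanar arrangement and grows as the group
  puckers out of a common plane.

The plane statistic walks the point list cyclically: for every window of four
consecutive points (p, q, r, s with q the pivot) it forms the normal of the
plane spanned by (p - q) and (r - q) and takes |cos| of the angle between
that normal and (s - q); the group value is the maximum over all windows.
Degenerate windows (collinear pivot rays or a zero fourth vector) are
skipped.  The absolute value is used because the sign of the normal is an
orientation artifact, and the point order is the ascending atom index so the
value is reproducible; any cyclic rotation of the list yields the same window
set and hence the same value.
"""

from __future__ import annotations

import numpy as np

from .model import Molecule, Bond

_EPS = 1e-10


def bond_angle(xi, xj, xk) -> float:
    """Angle at vertex ``xi`` between the rays to ``xj`` and ``xk``, degrees."""
    xi, xj, xk = (np.asarray(p, dtype=float) for p in (xi, xj, xk))
    u = xj - xi
    v = xk - xi
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < _EPS or nv < _EPS:
        raise ValueError("bond_angle: zero-length ray at the vertex")
    c = float(np.dot(u, v) / (nu * nv))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def plane_cos(points) -> float:
    """Maximum plane-deviation |cos| over cyclic 4-point windows.

    Fewer than four distinct points are always coplanar and return 0.
    Raises if every window is degenerate (e.g. all points collinear).
    """
    pts = np.asarray(points, dtype=float)
    # fewer than 4 distinct positions: trivially coplanar
    if len(np.unique(np.round(pts, 9), axis=0)) < 4:
        return 0.0
    k = len(pts)
    best = None
    for i in range(k):
        q = pts[i]
        a1 = pts[(i - 1) % k] - q
        a2 = pts[(i + 1) % k] - q
        a3 = pts[(i + 2) % k] - q
        n = np.cross(a1, a2)
        nn = np.linalg.norm(n)
        na3 = np.linalg.norm(a3)
        if nn < _EPS or na3 < _EPS:
            continue
        c = abs(float(np.dot(n, a3))) / (nn * na3)
        best = c if best is None else max(best, c)
    if best is None:
        raise ValueError("plane_cos: all windows degenerate (collinear points)")
    return min(best, 1.0)


def atom_plane_cos(mol: Molecule, index: int) -> float:
    """Plane statistic for an atom and its neighbours (>= 3 required)."""
    nbrs = mol.neighbors(index)
    if len(nbrs) < 3:
        raise ValueError(f"atom {index}: plane test needs >= 3 neighbours")
    group = sorted([index, *nbrs])
    return plane_cos(mol.coords_of(group))


def bond_plane_cos(mol: Molecule, bond: Bond) -> float:
    """Plane statistic for a bond's local group: both endpoints plus all of
    their neighbours.  Fewer than four distinct atoms count as planar."""
    group = set(bond.key)
    group.update(mol.neighbors(bond.i))
    group.update(mol.neighbors(bond.j))
    if len(group) < 4:
        return 0.0
    return plane_cos(mol.coords_of(sorted(group)))


def min_angle_deviation_from_120(mol: Molecule, bond: Bond) -> float:
    """BA of the conjugation rules: min over adjacent bonds of
    ``|angle(bond, adjacent) - 120|`` in degrees.

    The angle between two bonds sharing atom ``a`` is the bond angle at ``a``
    between the two far endpoints.  Returns ``inf`` when the bond has no
    adjacent bonds.
    """
    best = float("inf")
    for shared in bond.key:
        far_self = bond.other(shared)
        for nbr in mol.neighbors(shared):
            if nbr == far_self:
                continue
            ang = bond_angle(mol.atoms[shared].coords,
                             mol.atoms[far_self].coords,
                             mol.atoms[nbr].coords)
            best = min(best, abs(ang - 120.0))
    return best
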