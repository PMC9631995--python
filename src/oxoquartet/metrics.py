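"""Structural metrics for quartets and quadruplex cores.

Implements the quantities used to characterize oxoG-quartet geometry:

* neighboring/diagonal O6-O6 ring distances;
* the inscribed-sphere cavity diameter of a quartet plane (the largest
  sphere that fits the central ion channel opening once van der Waals
  radii are accounted for);
* hydrogen-bond geometry (H...A, D...A, D-H...A angle);
* base-stacking overlap areas between consecutive planes (convex-polygon
  projection, exocyclic atoms included);
* helical step parameters (rise and glycosidic twist);
* quartet planarity RMSD.

All metrics accept a :class:`~oxoquartet.quartets.Quartet`, a
:class:`~oxoquartet.core.CoreModel`, or an explicit-coordinate
:class:`~oxoquartet.core.StructureModel` (e.g. read from PDB), and are
invariant under global rigid motion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import MultiPoint

from .core import CoreModel, Residue, StructureModel
from .quartets import Quartet
from .templates import N_H_BOND_LENGTH, vdw_radius

__all__ = [
    "HBondGeometry",
    "StepMetrics",
    "o6_ring_distances",
    "cavity_diameter",
    "hbond_geometry",
    "stacking_overlap",
    "step_parameters",
    "planarity_rmsd",
]


@dataclass(frozen=True)
class HBondGeometry:
    d_HA: float
    d_DA: float
    theta_DHA: float  # degrees


@dataclass(frozen=True)
class StepMetrics:
    stacking_surface: float  # A^2
    rise: float  # A
    twist: float  # degrees


# ---------------------------------------------------------------------------
# Input normalization
# ---------------------------------------------------------------------------


def _quartet_plane(quartet: Quartet) -> list[Residue]:
    tmpl = quartet.template
    elements = {a.name: a.element for a in tmpl.atoms}
    out = []
    for k in range(4):
        coords = quartet.base_coordinates(k)
        out.append(
            Residue(
                chain="ABCD"[k],
                number=1,
                resname="Q",
                atoms=dict(zip(tmpl.atom_names, coords)),
                elements=elements,
                plane=0,
            )
        )
    return out


def _as_structure(obj) -> StructureModel:
    if isinstance(obj, StructureModel):
        return obj
    if isinstance(obj, CoreModel):
        return obj.to_structure()
    if isinstance(obj, Quartet):
        return StructureModel(residues=_quartet_plane(obj))
    raise TypeError(f"cannot interpret {type(obj).__name__} as a structure")


def _plane_residues(obj, k: int = 0) -> list[Residue]:
    return _as_structure(obj).plane(k)


def _heavy_coords(residues) -> np.ndarray:
    pts = []
    for r in residues:
        for _, p in r.heavy_items():
            pts.append(p)
    return np.array(pts)


def _ring_order(residues: list[Residue], anchor: str = "O6") -> list[Residue]:
    """Order the four residues of a plane cyclically by azimuth about the
    plane centroid (projection onto the best-fit plane)."""
    if len(residues) != 4:
        raise ValueError(f"a quartet plane needs 4 residues, got {len(residues)}")
    pts = _heavy_coords(residues)
    centroid = pts.mean(axis=0)
    normal = _plane_normal(pts)
    e1 = _any_perpendicular(normal)
    e2 = np.cross(normal, e1)

    def azimuth(r: Residue) -> float:
        ref = r.atoms.get(anchor)
        if ref is None:
            ref = np.mean([p for _, p in r.heavy_items()], axis=0)
        v = ref - centroid
        return float(np.arctan2(v @ e2, v @ e1))

    return sorted(residues, key=azimuth)


def _plane_normal(pts: np.ndarray) -> np.ndarray:
    c = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    n = vt[-1]
    return n if n[2] >= 0 else -n


def _any_perpendicular(n: np.ndarray) -> np.ndarray:
    trial = np.array([1.0, 0.0, 0.0])
    if abs(n @ trial) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    v = trial - (trial @ n) * n
    return v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# Ring distances and cavity
# ---------------------------------------------------------------------------


def o6_ring_distances(quartet, k: int = 0) -> tuple[float, float]:
    """(neighboring, diagonal) O6-O6 distances of a quartet plane (A),
    each averaged over the ring."""
    residues = _plane_residues(quartet, k)
    for r in residues:
        if "O6" not in r.atoms:
            raise KeyError(f"residue {r.chain}{r.number} has no O6 atom")
    ordered = _ring_order(residues)
    o6 = [r.atoms["O6"] for r in ordered]
    neighboring = float(
        np.mean([np.linalg.norm(o6[i] - o6[(i + 1) % 4]) for i in range(4)])
    )
    diagonal = float(
        np.mean([np.linalg.norm(o6[0] - o6[2]), np.linalg.norm(o6[1] - o6[3])])
    )
    return neighboring, diagonal


def cavity_diameter(quartet, k: int = 0) -> float:
    """Maximum diameter (A) of a sphere fitting the central cavity opening.

    Computed as twice the minimum over heavy atoms of (perpendicular
    distance from the plane's 4-fold axis minus the atom's van der Waals
    radius), floored at zero.  For canonical G/oxoG quartets the minimum
    is attained by the four O6 atoms, so this reduces to
    ``diagonal O6-O6 - 2 r_vdw(O)``.
    """
    residues = _plane_residues(quartet, k)
    pts = _heavy_coords(residues)
    radii = np.array(
        [vdw_radius(r.elements[n]) for r in residues for n, _ in r.heavy_items()]
    )
    centroid = pts.mean(axis=0)
    normal = _plane_normal(pts)
    rel = pts - centroid
    # distance from the axis line (centroid, normal)
    along = rel @ normal
    perp = rel - np.outer(along, normal)
    dist = np.linalg.norm(perp, axis=1)
    return float(max(0.0, 2.0 * np.min(dist - radii)))


# ---------------------------------------------------------------------------
# Hydrogen-bond geometry
# ---------------------------------------------------------------------------


def _pos(x) -> np.ndarray:
    if hasattr(x, "position"):
        return np.asarray(x.position, float)
    return np.asarray(x, float).reshape(3)


def hbond_geometry(donor, hydrogen, acceptor) -> HBondGeometry:
    """Hydrogen-bond geometry from donor heavy atom, hydrogen, acceptor.

    Accepts :class:`~oxoquartet.templates.Atom` objects or raw positions.
    The donor-hydrogen pair must be covalently bonded (<= 1.2 A).
    """
    d, h, a = _pos(donor), _pos(hydrogen), _pos(acceptor)
    d_dh = float(np.linalg.norm(d - h))
    if d_dh > 1.2:
        raise ValueError(
            f"donor-hydrogen distance {d_dh:.2f} A exceeds covalent bond range"
        )
    d_ha = float(np.linalg.norm(h - a))
    d_da = float(np.linalg.norm(d - a))
    v1, v2 = d - h, a - h
    cos_t = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    theta = float(np.degrees(np.arccos(np.clip(cos_t, -1.0, 1.0))))
    return HBondGeometry(d_HA=d_ha, d_DA=d_da, theta_DHA=theta)


# ---------------------------------------------------------------------------
# Stacking overlap
# ---------------------------------------------------------------------------

#: atoms excluded from the stacking polygon (pseudo-atoms, hydrogens are
#: excluded by element)
_NON_BASE_ATOMS = {"C1'"}


def base_polygon_points(residue: Residue) -> np.ndarray:
    """Heavy base atoms (ring plus exocyclic substituents) of a residue."""
    return np.array(
        [p for n, p in residue.heavy_items() if n not in _NON_BASE_ATOMS]
    )


def _project_polygon(points: np.ndarray, origin, e1, e2):
    uv = np.column_stack([(points - origin) @ e1, (points - origin) @ e2])
    return MultiPoint(uv).convex_hull


def stacking_overlap(core, k: int, selector="mean") -> float:
    """Projected stacking overlap area (A^2) across step *k*.

    Heavy base atoms (exocyclic atoms included) of the two stacked bases
    are projected onto the mean plane between quartets *k* and *k+1*; each
    base becomes the convex polygon of its projected atom centers and the
    polygon intersection area is returned.  ``selector`` is a strand index
    (0..3, by plane ring order) for a single base pair, or ``"mean"`` for
    the average over the four strands.
    """
    struct = _as_structure(core)
    if not 0 <= k < struct.n_planes - 1:
        raise IndexError(f"step index {k} out of range (0..{struct.n_planes - 2})")
    lower = _ring_order(struct.plane(k))
    upper_res = struct.plane(k + 1)
    low_pts = _heavy_coords(lower)
    up_pts = _heavy_coords(upper_res)
    # mean plane between the two quartet planes
    n1 = _plane_normal(low_pts)
    n2 = _plane_normal(up_pts)
    normal = n1 + n2
    normal /= np.linalg.norm(normal)
    origin = 0.5 * (low_pts.mean(axis=0) + up_pts.mean(axis=0))
    e1 = _any_perpendicular(normal)
    e2 = np.cross(normal, e1)

    # pair bases across the step by strand (chain) identity where
    # available, else by nearest centroid
    def partner(res: Residue) -> Residue:
        same_chain = [r for r in upper_res if r.chain == res.chain]
        if len(same_chain) == 1:
            return same_chain[0]
        c = base_polygon_points(res).mean(axis=0)
        return min(
            upper_res,
            key=lambda r: np.linalg.norm(base_polygon_points(r).mean(axis=0) - c),
        )

    areas = []
    for res in lower:
        poly1 = _project_polygon(base_polygon_points(res), origin, e1, e2)
        poly2 = _project_polygon(base_polygon_points(partner(res)), origin, e1, e2)
        areas.append(float(poly1.intersection(poly2).area))
    if selector == "mean":
        return float(np.mean(areas))
    s = int(selector)
    if not 0 <= s < 4:
        raise IndexError("strand selector must be 0..3 or 'mean'")
    return areas[s]


# ---------------------------------------------------------------------------
# Step parameters
# ---------------------------------------------------------------------------


def _helical_axis(struct: StructureModel) -> tuple[np.ndarray, list[np.ndarray]]:
    """(axis unit vector, plane centroids); axis points 5' -> 3'."""
    centroids = [
        _heavy_coords(struct.plane(k)).mean(axis=0) for k in range(struct.n_planes)
    ]
    pts = np.array(centroids)
    if len(pts) == 1:
        return _plane_normal(_heavy_coords(struct.plane(0))), centroids
    c = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    axis = vt[0]
    if axis @ (pts[-1] - pts[0]) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis), centroids


def _glycosidic_vectors(residues: list[Residue]) -> list[np.ndarray]:
    out = []
    for r in residues:
        gly = "N9" if "N9" in r.atoms else "N1"
        if "C1'" not in r.atoms:
            raise KeyError(f"residue {r.chain}{r.number} has no C1' pseudo-atom")
        out.append(r.atoms["C1'"] - r.atoms[gly])
    return out


def step_parameters(core, k: int) -> tuple[float, float]:
    """(rise A, twist deg) of step *k*.

    Rise is the centroid separation projected on the mean helical axis;
    twist is the mean signed rotation of the glycosidic (N9 -> C1')
    vectors between the two planes, projected onto the plane normal to
    the axis.
    """
    struct = _as_structure(core)
    if not 0 <= k < struct.n_planes - 1:
        raise IndexError(f"step index {k} out of range (0..{struct.n_planes - 2})")
    axis, centroids = _helical_axis(struct)
    rise = float((centroids[k + 1] - centroids[k]) @ axis)

    lower = _ring_order(struct.plane(k))
    upper = _ring_order(struct.plane(k + 1))

    def pair(res):
        same = [r for r in upper if r.chain == res.chain]
        return same[0] if len(same) == 1 else min(
            upper,
            key=lambda r: np.linalg.norm(
                np.mean([p for _, p in r.heavy_items()], axis=0)
                - np.mean([p for _, p in res.heavy_items()], axis=0)
            ),
        )

    angles = []
    for res in lower:
        (v1,) = _glycosidic_vectors([res])
        (v2,) = _glycosidic_vectors([pair(res)])
        p1 = v1 - (v1 @ axis) * axis
        p2 = v2 - (v2 @ axis) * axis
        sin_t = np.cross(p1, p2) @ axis
        cos_t = p1 @ p2
        angles.append(np.arctan2(sin_t, cos_t))
    # circular mean keeps +-180 deg twists consistent
    twist = float(np.degrees(np.arctan2(np.mean(np.sin(angles)), np.mean(np.cos(angles)))))
    return rise, twist


# ---------------------------------------------------------------------------
# Planarity
# ---------------------------------------------------------------------------


def planarity_rmsd(quartet, k: int = 0) -> float:
    """RMSD (A) of the plane's heavy atoms from their best-fit plane."""
    pts = _heavy_coords(_plane_residues(quartet, k))
    if len(pts) < 3:
        raise ValueError("planarity requires at least 3 atoms")
    rel = pts - pts.mean(axis=0)
    normal = _plane_normal(pts)
    dev = rel @ normal
    return float(np.sqrt(np.mean(dev**2)))
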