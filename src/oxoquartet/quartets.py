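"""C4-symmetric planar quartet construction.

A quartet is parameterized by the rigid in-plane placement (x, y, rotation)
of a single base; the other three bases are exact 90-degree copies about
the +z axis.  Fourfold symmetry is imposed, not discovered — NMR of the
tetramolecular quadruplexes this package models shows a single symmetric
species.  Two construction modes are offered:

``hbond_target``
    Least-squares fit of the three in-plane degrees of freedom minimizing
    squared deviations of the cyclic H...A hydrogen-bond distances from
    their targets plus a linearity penalty on the D-H...A angles.

``ring_size``
    Start from the hydrogen-bond fit, then shift the base radially (along
    the axis->O6 direction) so that the neighboring O6-O6 distance equals
    the requested value exactly, preserving the fitted base orientation.

For any C4 quartet the diagonal O6-O6 distance is exactly sqrt(2) times
the neighboring one: with O6 of base 0 at in-plane position ``a``,
``|a - R90 a| = sqrt(2)|a|`` and ``|a - R180 a| = 2|a|``.

Hydrogen-bond directionality.  In the canonical Hoogsteen G-quartet both
donors of a base (N1-H1, N2-H2) sit on its Watson-Crick edge and donate to
the *same* neighbor's Hoogsteen edge (O6, N7).  In the oxoG-quartet the
two bonds joining an adjacent pair of bases run in opposite directions:
N1-H1 of base *i* donates to O8 of base *i+1*, while N7-H7 of base *i+1*
donates back to O6 of base *i* — the oxidized Hoogsteen edge is both
acceptor (O8) and donor (H7).  :class:`HBondScheme` therefore carries a
per-pair direction flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import least_squares

from .templates import BaseId, BaseTemplate

__all__ = [
    "HBondScheme",
    "Quartet",
    "build_quartet",
    "solve_placement_residual",
    "default_scheme",
    "OXOG_QUARTET_SCHEME",
    "G_HOOGSTEEN_SCHEME",
    "InfeasibleGeometryError",
    "SchemeMismatchError",
]


class InfeasibleGeometryError(RuntimeError):
    """No C4 placement reached an acceptable fit residual."""

    def __init__(self, residual: float):
        super().__init__(
            f"no feasible C4 placement: best fit residual {residual:.4f} A^2"
        )
        self.residual = residual


class SchemeMismatchError(ValueError):
    """Hydrogen-bond scheme names atoms the template does not provide."""


@dataclass(frozen=True)
class HBondScheme:
    """Cyclic donor/acceptor pairing between adjacent quartet bases.

    ``pairs[p] = (donor_heavy, acceptor)``.  ``directions[p] = +1`` places
    the donor on base *i* and the acceptor on base *i+1 (mod 4)*;
    ``-1`` reverses the roles (donor on *i+1*, acceptor on *i*).
    ``target_HA`` holds one H...A target distance (Angstrom) per pair.
    """

    pairs: tuple[tuple[str, str], ...]
    target_HA: tuple[float, ...]
    directions: tuple[int, ...] | None = None
    linearity_weight: float = 0.1  # A^2/rad^2

    def __post_init__(self):
        object.__setattr__(self, "pairs", tuple(tuple(p) for p in self.pairs))
        object.__setattr__(self, "target_HA", tuple(float(t) for t in self.target_HA))
        dirs = self.directions
        if dirs is None:
            dirs = tuple(1 for _ in self.pairs)
        object.__setattr__(self, "directions", tuple(int(d) for d in dirs))
        if len(self.target_HA) != len(self.pairs):
            raise ValueError("one H...A target required per scheme pair")
        if len(self.directions) != len(self.pairs):
            raise ValueError("one direction flag required per scheme pair")
        if any(t <= 0 for t in self.target_HA):
            raise ValueError("H...A targets must be positive")
        if any(d not in (-1, 1) for d in self.directions):
            raise ValueError("directions must be +1 or -1")

    def reversed_cycle(self) -> "HBondScheme":
        """The same pairing traversed in the opposite cyclic direction.

        A quartet built from an in-plane-mirrored template is the original
        quartet viewed from its other face; the donor -> acceptor sense
        around the ring reverses accordingly.
        """
        return HBondScheme(
            pairs=self.pairs,
            target_HA=self.target_HA,
            directions=tuple(-d for d in self.directions),
            linearity_weight=self.linearity_weight,
        )

    def validate(self, template: BaseTemplate) -> None:
        for donor, acceptor in self.pairs:
            if donor not in template.donor_heavy_atoms:
                raise SchemeMismatchError(
                    f"{donor!r} is not a donor of the "
                    f"{template.base_id.value} template"
                )
            if acceptor not in template.acceptors:
                raise SchemeMismatchError(
                    f"{acceptor!r} is not an acceptor of the "
                    f"{template.base_id.value} template"
                )


#: oxoG-quartet pairing (N1-H1...O8 forward, N7-H7...O6 reciprocal), with
#: the no-cation DFT H...A distances as default targets.
OXOG_QUARTET_SCHEME = HBondScheme(
    pairs=(("N1", "O8"), ("N7", "O6")),
    target_HA=(1.92, 1.76),
    directions=(1, -1),
)

#: Canonical Hoogsteen G-quartet pairing: N1-H1...O6 and N2-H2...N7.
G_HOOGSTEEN_SCHEME = HBondScheme(
    pairs=(("N1", "O6"), ("N2", "N7")),
    target_HA=(1.90, 2.00),
    directions=(1, 1),
)


def default_scheme(template: BaseTemplate) -> HBondScheme:
    if template.base_id is BaseId.OXOG:
        scheme = OXOG_QUARTET_SCHEME
    elif template.base_id is BaseId.G:
        scheme = G_HOOGSTEEN_SCHEME
    else:
        raise SchemeMismatchError(
            f"no default quartet scheme for base {template.base_id.value}"
        )
    return scheme.reversed_cycle() if template.mirrored else scheme


def _rotz(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


_R90 = _rotz(np.pi / 2)


@dataclass(frozen=True, eq=False)
class Quartet:
    """Four rigid bases under exact C4 symmetry about +z.

    ``transform0 = (x, y, rot)``: base 0 is the template rotated by *rot*
    (radians) about +z then translated by (x, y) in-plane; base k is base 0
    rotated by 90k degrees.  Bases are numbered counterclockwise viewed
    from +z (the 5' side).
    """

    template: BaseTemplate
    transform0: tuple[float, float, float]
    cation: tuple[str, np.ndarray] | None = None

    def __post_init__(self):
        object.__setattr__(
            self, "transform0", tuple(float(v) for v in self.transform0)
        )

    def _base0(self) -> np.ndarray:
        x, y, rot = self.transform0
        coords = self.template.coordinates() @ _rotz(rot).T
        coords[:, 0] += x
        coords[:, 1] += y
        return coords

    def base_coordinates(self, k: int) -> np.ndarray:
        """(n_atoms, 3) coordinates of base *k* (k = 0..3)."""
        if not 0 <= k <= 3:
            raise IndexError("base index must be 0..3")
        return self._base0() @ _rotz(k * np.pi / 2).T

    def atom_position(self, k: int, name: str) -> np.ndarray:
        names = self.template.atom_names
        if name not in names:
            raise KeyError(f"template has no atom {name!r}")
        return self.base_coordinates(k)[names.index(name)]

    def residues(self) -> list[dict[str, np.ndarray]]:
        """Four name -> position dicts, counterclockwise viewed from +z."""
        names = self.template.atom_names
        return [dict(zip(names, self.base_coordinates(k))) for k in range(4)]

    def with_cation(self, element: str, position=None) -> "Quartet":
        pos = np.zeros(3) if position is None else np.asarray(position, float)
        return Quartet(self.template, self.transform0, (element, pos))


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _scheme_indices(template: BaseTemplate, scheme: HBondScheme):
    """Per pair: (donor idx, hydrogen idx candidates, acceptor idx, direction)."""
    names = list(template.atom_names)
    out = []
    for (donor, acceptor), direction in zip(scheme.pairs, scheme.directions):
        h_candidates = tuple(names.index(h) for h in template.donor_hydrogens(donor))
        out.append((names.index(donor), h_candidates, names.index(acceptor), direction))
    return out


def _edge_terms(donor_base, acceptor_base, di, h_cands, ai, target):
    """(distance deviation, linearity deviation) for one H-bond."""
    a_pos = acceptor_base[ai]
    # A donor with two hydrogens (amino) engages the one nearer the acceptor.
    hi = min(h_cands, key=lambda h: np.linalg.norm(donor_base[h] - a_pos))
    h_pos = donor_base[hi]
    d_pos = donor_base[di]
    d_ha = np.linalg.norm(h_pos - a_pos)
    v1 = d_pos - h_pos
    v2 = a_pos - h_pos
    cos_t = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    theta = np.arccos(np.clip(cos_t, -1.0, 1.0))
    return d_ha - target, np.pi - theta


def _objective_bases(bases, indices, targets, weight):
    """Mean per-edge objective for four explicit bases (cyclic order)."""
    total = 0.0
    for k in range(4):
        for (di, h_cands, ai, direction), target in zip(indices, targets):
            if direction > 0:
                dd, da = _edge_terms(bases[k], bases[(k + 1) % 4], di, h_cands, ai, target)
            else:
                dd, da = _edge_terms(bases[(k + 1) % 4], bases[k], di, h_cands, ai, target)
            total += dd * dd + weight * da * da
    return total / 4.0


_FIT_TOLERANCE = 0.10  # A^2; feasible fits land far below


@lru_cache(maxsize=64)
def _fit_hbond_cached(template: BaseTemplate, scheme: HBondScheme, targets) -> Quartet:
    indices = _scheme_indices(template, scheme)
    tmpl = template.coordinates()
    weight = scheme.linearity_weight

    def residual_vec(params):
        x, y, rot = params
        coords0 = tmpl @ _rotz(rot).T
        coords0[:, 0] += x
        coords0[:, 1] += y
        coords1 = coords0 @ _R90.T
        out = []
        for (di, h_cands, ai, direction), target in zip(indices, targets):
            if direction > 0:
                dd, da = _edge_terms(coords0, coords1, di, h_cands, ai, target)
            else:
                dd, da = _edge_terms(coords1, coords0, di, h_cands, ai, target)
            out.append(dd)
            out.append(np.sqrt(weight) * da)
        return np.array(out)

    def objective(params):
        r = residual_vec(params)
        return float(r @ r)

    # Deterministic dense grid over (rotation, x, y), vectorized over the
    # translation grid at each rotation, followed by local least-squares
    # refinement of the best basins.  Ties break toward smaller rotation.
    xs = np.arange(-7.0, 7.0 + 1e-9, 0.5)
    tx, ty = np.meshgrid(xs, xs, indexing="ij")
    tgrid = np.column_stack([tx.ravel(), ty.ravel()])  # (nt, 2)
    candidates = []
    for rot_deg in range(0, 360, 4):
        rot = np.radians(rot_deg)
        R = _rotz(rot)
        c0 = tmpl @ R.T
        score = np.zeros(len(tgrid))
        for (di, h_cands, ai, direction), target in zip(indices, targets):
            pair_scores = []
            for hi in h_cands:
                if direction > 0:
                    # donor base untranslated-by-R90; acceptor on R90 copy
                    h0, d0, a0 = c0[hi, :2], c0[di, :2], (c0[ai] @ _R90.T)[:2]
                    M = np.eye(2) - _R90[:2, :2]
                else:
                    h0, d0, a0 = (
                        (c0[hi] @ _R90.T)[:2],
                        (c0[di] @ _R90.T)[:2],
                        c0[ai, :2],
                    )
                    M = _R90[:2, :2] - np.eye(2)
                # H - A = (h0 - a0) + M t ; D - H is translation-independent
                ha = (h0 - a0) + tgrid @ M.T
                dist = np.linalg.norm(ha, axis=1)
                u = d0 - h0
                u = u / np.linalg.norm(u)
                cos_t = -(ha @ u) / np.maximum(dist, 1e-12)
                theta = np.arccos(np.clip(cos_t, -1.0, 1.0))
                pair_scores.append((dist - target) ** 2 + weight * (np.pi - theta) ** 2)
            score += np.minimum.reduce(pair_scores)
        j = int(np.argmin(score))
        candidates.append((float(score[j]), rot_deg, (tgrid[j, 0], tgrid[j, 1], rot)))
    candidates.sort(key=lambda c: (c[0], c[1]))
    best = None
    for _, _, start in candidates[:8]:
        sol = least_squares(residual_vec, np.array(start), xtol=1e-15, ftol=1e-15)
        val = objective(sol.x)
        if best is None or val < best[0] - 1e-12:
            best = (val, sol.x)
    final, params = best
    if final > _FIT_TOLERANCE:
        raise InfeasibleGeometryError(final)
    return Quartet(template=template, transform0=tuple(params))


def _fit_hbond(template, scheme, targets) -> Quartet:
    return _fit_hbond_cached(template, scheme, tuple(targets))


def build_quartet(
    template: BaseTemplate,
    scheme: HBondScheme | None = None,
    mode: str = "hbond_target",
    value=None,
) -> Quartet:
    """Construct a C4-symmetric quartet from *template*.

    Parameters
    ----------
    scheme:
        Hydrogen-bond scheme; defaults to the canonical scheme for the
        template's base.
    mode:
        ``"hbond_target"`` fits the H...A distances (to *value* if given,
        else to ``scheme.target_HA``); ``"ring_size"`` additionally shifts
        the base radially so the neighboring O6-O6 distance equals *value*
        exactly, preserving the fitted orientation.
    """
    if scheme is None:
        scheme = default_scheme(template)
    scheme.validate(template)

    if mode == "hbond_target":
        if value is None:
            targets = scheme.target_HA
        else:
            targets = tuple(float(v) for v in np.atleast_1d(value))
            if len(targets) != len(scheme.pairs):
                raise ValueError(
                    f"expected {len(scheme.pairs)} H...A targets, got {len(targets)}"
                )
        return _fit_hbond(template, scheme, targets)

    if mode == "ring_size":
        if value is None:
            raise ValueError("ring_size mode requires a neighboring O6-O6 distance")
        val = np.atleast_1d(value)
        if len(val) != 1:
            raise ValueError("ring_size mode requires a single neighboring O6-O6 distance")
        if not template.has_atom("O6"):
            raise SchemeMismatchError(
                f"{template.base_id.value} template has no O6; cannot set ring size"
            )
        base = _fit_hbond(template, scheme, scheme.target_HA)
        return _rescale_ring(base, float(val[0]))

    raise ValueError(f"unknown build mode {mode!r}")


def _rescale_ring(quartet: Quartet, neighboring_o6: float) -> Quartet:
    if neighboring_o6 < 0:
        raise ValueError("neighboring O6-O6 distance must be >= 0")
    names = quartet.template.atom_names
    o6 = quartet.base_coordinates(0)[names.index("O6")]
    r_now = float(np.hypot(o6[0], o6[1]))
    r_target = neighboring_o6 / np.sqrt(2.0)
    if r_now < 1e-12:
        raise InfeasibleGeometryError(float("inf"))
    shift = (r_target / r_now - 1.0) * o6[:2]
    x, y, rot = quartet.transform0
    return Quartet(quartet.template, (x + shift[0], y + shift[1], rot), quartet.cation)


def solve_placement_residual(
    quartet_or_bases, scheme: HBondScheme, template: BaseTemplate | None = None
) -> float:
    """Objective value (A^2-scale) of a quartet under *scheme*.

    Zero iff every H...A target is met with perfectly linear D-H...A bonds.
    Accepts either a :class:`Quartet` or an explicit list of four
    (n_atoms, 3) coordinate arrays in template atom order (cyclic order),
    in which case the mean per-edge objective is returned — this lets
    off-symmetry arrangements be scored with the same functional.
    Invariant under global rigid motion.
    """
    if isinstance(quartet_or_bases, Quartet):
        template = quartet_or_bases.template
        scheme.validate(template)
        bases = [quartet_or_bases.base_coordinates(k) for k in range(4)]
    else:
        if template is None:
            raise ValueError("explicit bases require the template argument")
        scheme.validate(template)
        bases = [np.asarray(b, float) for b in quartet_or_bases]
        if len(bases) != 4:
            raise ValueError("expected four bases")
    indices = _scheme_indices(template, scheme)
    return float(
        _objective_bases(bases, indices, scheme.target_HA, scheme.linearity_weight)
    )
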