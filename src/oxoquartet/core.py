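"""Tetramolecular parallel quadruplex core assembly.

A :class:`CoreModel` stacks C4-symmetric quartet planes 5'->3' along +z
with per-step rise and twist, tracks per-plane glycosidic flags (all-*anti*
G planes, all-*syn* oxoG planes), holds monovalent cations at in-plane or
inter-plane sites, and can carry unpaired thymine overhang stubs at the
strand termini.

Twist convention: the step twist is the mean rotation of the glycosidic
(N9 -> C1') vectors between consecutive planes about the helical axis.
When consecutive planes hold different quartet types the internal frame
rotation applied at assembly is corrected by the difference of the two
quartets' intrinsic glycosidic azimuths, so that the twist requested at
assembly is exactly the twist measured by
:func:`oxoquartet.metrics.step_parameters` for any core.

The *syn* flag of an oxoG plane is realized by building that plane from
the in-plane-mirrored base template (the base presents its opposite face
to the 5' side), which also reverses the cyclic hydrogen-bond sense —
the geometric signature of an all-syn quartet in a parallel quadruplex.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .quartets import Quartet, _rotz, build_quartet, default_scheme
from .templates import BaseId, get_template

__all__ = [
    "CationSite",
    "Residue",
    "StructureModel",
    "CoreModel",
    "assemble_core",
    "make_sequence_core",
    "place_cation",
    "enumerate_cation_sites",
    "DEFAULT_STEPS",
    "SequenceError",
]

#: Default (rise A, twist deg) per step type.  G-G uses canonical parallel
#: quadruplex values; steps flanking an oxoG plane use the mean step
#: statistics of restrained-annealing ensembles of the oxoG analogues.
DEFAULT_STEPS: dict[str, tuple[float, float]] = {
    "GG": (3.13, 30.0),
    "GX": (2.94, 26.23),
    "XG": (3.21, 26.52),
    "XX": (3.13, 30.0),
}

#: Neighboring O6-O6 ring size used for G planes in sequence cores: the
#: average experimental G-quartet value.
G_PLANE_RING_SIZE = 3.15

_OVERHANG_RISE = 4.0  # A; extended spacing for unpaired thymine stubs

_CHAIN_IDS = ("A", "B", "C", "D")

_RESNAME = {BaseId.G: "DG", BaseId.OXOG: "8OG", BaseId.T: "DT"}

_CATION_RESNAME = {"Na": "NA", "K": "K", "Cs": "CS"}


class SequenceError(ValueError):
    """Invalid quadruplex-forming sequence."""


@dataclass(frozen=True)
class CationSite:
    """``in_plane(k)`` or ``between(k, k+1)`` cation localization site."""

    kind: str  # "in_plane" | "between"
    k: int
    k2: int | None = None

    def __post_init__(self):
        if self.kind not in ("in_plane", "between"):
            raise ValueError(f"unknown cation site kind {self.kind!r}")
        if self.kind == "between":
            k2 = self.k + 1 if self.k2 is None else self.k2
            object.__setattr__(self, "k2", k2)
            if k2 != self.k + 1:
                raise ValueError("between-site planes must be consecutive")

    def validate(self, n_planes: int) -> None:
        if not 0 <= self.k < n_planes:
            raise IndexError(f"plane index {self.k} out of range (0..{n_planes - 1})")
        if self.kind == "between" and not 0 <= self.k2 < n_planes:
            raise IndexError(f"plane index {self.k2} out of range (0..{n_planes - 1})")


@dataclass
class Residue:
    """One placed nucleotide: named atom coordinates plus bookkeeping."""

    chain: str
    number: int
    resname: str
    atoms: dict[str, np.ndarray]
    elements: dict[str, str]
    flag: str | None = None  # "syn" | "anti" | None
    plane: int | None = None  # quartet plane index, None for overhang stubs

    def copy(self) -> "Residue":
        return Residue(
            chain=self.chain,
            number=self.number,
            resname=self.resname,
            atoms={k: np.array(v) for k, v in self.atoms.items()},
            elements=dict(self.elements),
            flag=self.flag,
            plane=self.plane,
        )

    def heavy_items(self):
        return [(n, p) for n, p in self.atoms.items() if self.elements[n] != "H"]


@dataclass
class StructureModel:
    """Explicit-coordinate quadruplex model (planes need not be ideal)."""

    residues: list[Residue]
    cations: list[tuple[str, np.ndarray]] = field(default_factory=list)

    @property
    def n_planes(self) -> int:
        planes = [r.plane for r in self.residues if r.plane is not None]
        return max(planes) + 1 if planes else 0

    def plane(self, k: int) -> list[Residue]:
        out = [r for r in self.residues if r.plane == k]
        if not out:
            raise IndexError(f"no residues in plane {k}")
        return out

    def strand(self, chain: str) -> list[Residue]:
        return sorted(
            (r for r in self.residues if r.chain == chain), key=lambda r: r.number
        )

    @property
    def chains(self) -> list[str]:
        seen = []
        for r in self.residues:
            if r.chain not in seen:
                seen.append(r.chain)
        return seen

    def coordinates(self) -> np.ndarray:
        return np.concatenate(
            [np.array([p for p in r.atoms.values()]) for r in self.residues]
        )

    def copy(self) -> "StructureModel":
        return StructureModel(
            residues=[r.copy() for r in self.residues],
            cations=[(e, np.array(p)) for e, p in self.cations],
        )

    def transform(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Rigidly transformed copy (x -> R x + t)."""
        out = self.copy()
        for r in out.residues:
            for name in r.atoms:
                r.atoms[name] = rotation @ r.atoms[name] + translation
        out.cations = [(e, rotation @ p + translation) for e, p in out.cations]
        return out


def _glycosidic_azimuth(quartet: Quartet) -> float:
    """Azimuth of base 0's N9 -> C1' vector (radians, about +z)."""
    tmpl = quartet.template
    n9 = quartet.atom_position(0, tmpl.glycosidic_atom)
    c1 = quartet.atom_position(0, "C1'")
    v = c1 - n9
    return float(np.arctan2(v[1], v[0]))


@dataclass
class CoreModel:
    """Stacked quartet planes with step geometry, flags, cations, overhangs."""

    planes: list[Quartet]
    steps: list[tuple[float, float]]
    flags: list[str] = field(default_factory=list)
    cations: list[tuple[str, CationSite]] = field(default_factory=list)
    overhangs: tuple[int, int] = (0, 0)  # (5' T count, 3' T count)
    sequence: str | None = None

    def __post_init__(self):
        if len(self.steps) != len(self.planes) - 1:
            raise ValueError(
                f"need {len(self.planes) - 1} steps for {len(self.planes)} planes, "
                f"got {len(self.steps)}"
            )
        if any(rise <= 0 for rise, _ in self.steps):
            raise ValueError("all rise values must be positive")
        if not self.flags:
            self.flags = ["anti"] * len(self.planes)
        if len(self.flags) != len(self.planes):
            raise ValueError("one glycosidic flag required per plane")

    # -- frames ----------------------------------------------------------

    @property
    def n_planes(self) -> int:
        return len(self.planes)

    def plane_frames(self) -> list[tuple[float, float]]:
        """(z, frame rotation) per plane; plane 0 at the origin.

        The frame rotation applied between planes is the requested twist
        corrected by the difference of intrinsic glycosidic azimuths, so
        the measured glycosidic twist equals the requested step twist.
        """
        z = 0.0
        phi = 0.0
        frames = [(z, phi)]
        for k, (rise, twist) in enumerate(self.steps):
            alpha_low = _glycosidic_azimuth(self.planes[k])
            alpha_high = _glycosidic_azimuth(self.planes[k + 1])
            z += rise
            phi += np.radians(twist) - (alpha_high - alpha_low)
            frames.append((z, phi))
        return frames

    def plane_centroid(self, k: int) -> np.ndarray:
        z, _ = self.plane_frames()[k]
        return np.array([0.0, 0.0, z])

    def cation_position(self, site: CationSite) -> np.ndarray:
        site.validate(self.n_planes)
        if site.kind == "in_plane":
            return self.plane_centroid(site.k)
        return 0.5 * (self.plane_centroid(site.k) + self.plane_centroid(site.k2))

    # -- realization -----------------------------------------------------

    def to_structure(self) -> StructureModel:
        """Place every residue in the global frame, 5'->3' per strand."""
        frames = self.plane_frames()
        n5, n3 = self.overhangs
        residues: list[Residue] = []
        t_template = get_template(BaseId.T)

        def _terminal_c1(plane_idx: int, strand: int) -> np.ndarray:
            q = self.planes[plane_idx]
            z, phi = frames[plane_idx]
            c1 = q.atom_position(strand, "C1'") @ _rotz(phi).T
            return c1 + np.array([0.0, 0.0, z])

        for s, chain in enumerate(_CHAIN_IDS):
            number = 0
            # 5' thymine stubs, extended below plane 0
            ref5 = _terminal_c1(0, s) if n5 else None
            for i in range(n5):
                number += 1
                steps_away = n5 - i
                residues.append(
                    _place_stub(t_template, chain, number, ref5, -steps_away)
                )
            for k, quartet in enumerate(self.planes):
                number += 1
                z, phi = frames[k]
                coords = quartet.base_coordinates(s) @ _rotz(phi).T
                coords = coords + np.array([0.0, 0.0, z])
                names = quartet.template.atom_names
                residues.append(
                    Residue(
                        chain=chain,
                        number=number,
                        resname=_RESNAME[quartet.template.base_id],
                        atoms=dict(zip(names, coords)),
                        elements={
                            a.name: a.element for a in quartet.template.atoms
                        },
                        flag=self.flags[k],
                        plane=k,
                    )
                )
            # 3' thymine stubs above the last plane
            ref3 = _terminal_c1(self.n_planes - 1, s) if n3 else None
            for i in range(n3):
                number += 1
                residues.append(
                    _place_stub(t_template, chain, number, ref3, i + 1)
                )
        cations = [
            (element, self.cation_position(site)) for element, site in self.cations
        ]
        return StructureModel(residues=residues, cations=cations)

    @property
    def n_residues(self) -> int:
        n5, n3 = self.overhangs
        return 4 * (self.n_planes + n5 + n3)


_OVERHANG_TWIST = np.radians(30.0)


def _place_stub(template, chain, number, ref_c1, steps_away: int) -> Residue:
    """Place a thymine stub continuing a strand helically from *ref_c1*.

    The stub's C1' keeps the terminal residue's backbone radius, advanced
    by 30 degrees of twist and 4.0 A of extended rise per step away from
    the core (negative *steps_away* extends the 5' side).  Consecutive
    C1'-C1' separations stay in the backbone-plausible range.
    """
    radius = float(np.hypot(ref_c1[0], ref_c1[1]))
    azimuth = float(np.arctan2(ref_c1[1], ref_c1[0])) + steps_away * _OVERHANG_TWIST
    z = ref_c1[2] + steps_away * _OVERHANG_RISE
    pos = np.array([radius * np.cos(azimuth), radius * np.sin(azimuth), z])
    coords = template.coordinates() - template.position("C1'")
    coords = coords @ _rotz(azimuth).T + pos
    return Residue(
        chain=chain,
        number=number,
        resname="DT",
        atoms=dict(zip(template.atom_names, coords)),
        elements={a.name: a.element for a in template.atoms},
        flag="anti",
        plane=None,
    )


def assemble_core(
    planes: list[Quartet],
    steps: list[tuple[float, float]],
    flags: list[str] | None = None,
    overhangs: tuple[int, int] = (0, 0),
) -> CoreModel:
    """Stack *planes* with the given (rise A, twist deg) steps."""
    return CoreModel(
        planes=list(planes),
        steps=[(float(r), float(t)) for r, t in steps],
        flags=list(flags) if flags else [],
        overhangs=overhangs,
    )


def _plane_letter(ch: str) -> str:
    return "X" if ch == "X" else "G"


def make_sequence_core(
    sequence: str,
    steps: list[tuple[float, float]] | None = None,
    g_ring_size: float = G_PLANE_RING_SIZE,
) -> CoreModel:
    """Build a tetramolecular core from a strand sequence over {T, G, X}.

    ``X`` denotes 8-oxoguanine.  Each G/X position becomes one quartet
    plane: G planes are canonical Hoogsteen quartets flagged *anti* (ring
    size set to the experimental G-quartet average), X planes are
    oxoG-quartets built from the mirrored template and flagged *syn*.
    Leading/trailing thymines become unpaired overhang stubs.
    """
    seq = sequence.upper()
    bad = set(seq) - set("TGX")
    if bad:
        raise SequenceError(
            f"invalid character(s) {sorted(bad)} in sequence {sequence!r}; "
            "expected letters T, G, X"
        )
    core_part = seq.strip("T")
    if "T" in core_part:
        raise SequenceError(
            f"thymines are only supported as 5'/3' overhangs, got {sequence!r}"
        )
    if len(core_part) < 2:
        raise SequenceError(
            f"sequence {sequence!r} has fewer than 2 consecutive quartet-forming "
            "positions (G/X)"
        )
    n5 = len(seq) - len(seq.lstrip("T"))
    n3 = len(seq) - len(seq.rstrip("T"))

    planes: list[Quartet] = []
    flags: list[str] = []
    for ch in core_part:
        if ch == "G":
            template = get_template(BaseId.G)
            q = build_quartet(template, mode="ring_size", value=g_ring_size)
            flags.append("anti")
        else:
            template = get_template(BaseId.OXOG).flipped()
            q = build_quartet(template, default_scheme(template))
            flags.append("syn")
        planes.append(q)

    if steps is None:
        steps = []
        for a, b in zip(core_part, core_part[1:]):
            steps.append(DEFAULT_STEPS[_plane_letter(a) + _plane_letter(b)])
    return CoreModel(
        planes=planes,
        steps=[(float(r), float(t)) for r, t in steps],
        flags=flags,
        overhangs=(n5, n3),
        sequence=seq,
    )


def place_cation(core: CoreModel, site: CationSite, element: str) -> CoreModel:
    """Return a copy of *core* with a cation at *site*."""
    if element not in _CATION_RESNAME:
        raise ValueError(
            f"unsupported cation element {element!r}; expected one of "
            f"{sorted(_CATION_RESNAME)}"
        )
    site.validate(core.n_planes)
    out = copy.copy(core)
    out.cations = list(core.cations) + [(element, site)]
    return out


def enumerate_cation_sites(core: CoreModel) -> list[CationSite]:
    """All in-plane and between-plane sites of *core* (n + (n-1) sites)."""
    n = core.n_planes
    sites = [CationSite("in_plane", k) for k in range(n)]
    sites += [CationSite("between", k, k + 1) for k in range(n - 1)]
    return sites
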