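"""Idealized planar nucleobase templates.

The package models quartets and quadruplex cores at the rigid-base level:
every nucleobase is a planar, internally rigid unit with explicit hydrogen
positions and a C1' pseudo-atom marking the glycosidic attachment.  Base
ring geometry follows the standard small-molecule reference coordinates for
nucleic-acid bases (the consensus heavy-atom frames used throughout
nucleic-acid model building), with hydrogens placed in-plane along external
bond bisectors.  8-Oxoguanine is derived from guanine by adding the C8
carbonyl oxygen (O8) and the N7 proton (H7) and removing the aromatic H8 —
the 8-keto tautomer, which dominates in solution.

Bond-length conventions
-----------------------
* N-H donors: 1.03 Angstrom.  This value is forced by internal consistency
  of near-linear hydrogen-bond geometry (D...A = H...A + 1.03 for a linear
  bond, e.g. 2.95 = 1.92 + 1.03).
* C-H: 1.09 Angstrom; C8=O8 carbonyl: 1.23 Angstrom.

Van der Waals radii come from the Bondi compilation; with r(O) = 1.52 A the
inscribed-sphere cavity diameters of G- and oxoG-quartets computed by
:mod:`oxoquartet.metrics` reproduce the values derived from diagonal O6-O6
distances exactly.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = [
    "BaseId",
    "Atom",
    "BaseTemplate",
    "get_template",
    "vdw_radius",
    "BONDI_VDW",
    "UnknownBaseError",
    "UnknownElementError",
    "N_H_BOND_LENGTH",
]

#: Donor N-H bond length (Angstrom), shared package-wide.
N_H_BOND_LENGTH = 1.03
_C_H_BOND_LENGTH = 1.09
_C_O_CARBONYL = 1.23

#: Bondi van der Waals radii (Angstrom) for the elements the package touches.
BONDI_VDW: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "P": 1.80,
    "Na": 2.27,
    "K": 2.75,
    "Cs": 3.43,
}


class UnknownBaseError(ValueError):
    """Raised for a base identifier outside {G, OXOG, T}."""


class UnknownElementError(ValueError):
    """Raised for an element missing from the van der Waals radius table."""


def vdw_radius(element: str) -> float:
    """Return the Bondi van der Waals radius of *element* in Angstrom."""
    try:
        return BONDI_VDW[element]
    except KeyError:
        raise UnknownElementError(
            f"no van der Waals radius tabulated for element {element!r}"
        ) from None


class BaseId(enum.Enum):
    G = "G"
    OXOG = "OXOG"
    T = "T"


@dataclass(frozen=True, eq=False)
class Atom:
    """A named atom with a fixed position and a Bondi radius."""

    name: str
    element: str
    position: np.ndarray
    vdw_radius: float

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float).reshape(3).copy()
        pos.flags.writeable = False
        object.__setattr__(self, "position", pos)
        if self.element not in BONDI_VDW:
            raise UnknownElementError(
                f"atom {self.name}: element {self.element!r} not in radius table"
            )
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.name}: vdw_radius must be positive")


@dataclass(frozen=True, eq=False)
class BaseTemplate:
    """A rigid planar nucleobase with donor/acceptor annotations.

    All atoms lie in the z = 0 plane.  ``donors`` pairs each donor heavy
    atom with one of its hydrogens; ``acceptors`` lists acceptor heavy
    atoms.  ``c1_attachment`` is the C1' pseudo-atom position together with
    the in-plane unit vector of the glycosidic bond (N9 -> C1' for purines,
    N1 -> C1' for thymine).
    """

    base_id: BaseId
    atoms: tuple[Atom, ...]
    donors: tuple[tuple[str, str], ...]
    acceptors: tuple[str, ...]
    glycosidic_atom: str
    c1_attachment: tuple[np.ndarray, np.ndarray]
    mirrored: bool = False

    def __post_init__(self):
        pos, direction = self.c1_attachment
        pos = np.asarray(pos, float).reshape(3).copy()
        direction = np.asarray(direction, float).reshape(3).copy()
        pos.flags.writeable = False
        direction.flags.writeable = False
        object.__setattr__(self, "c1_attachment", (pos, direction))

    # -- lookups ---------------------------------------------------------

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"{self.base_id.value} template has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def position(self, name: str) -> np.ndarray:
        return self.atom(name).position

    @property
    def atom_names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.atoms)

    @property
    def donor_heavy_atoms(self) -> tuple[str, ...]:
        return tuple(d for d, _ in self.donors)

    def donor_hydrogens(self, heavy: str) -> tuple[str, ...]:
        """All hydrogens bonded to the donor heavy atom *heavy*."""
        hs = tuple(h for d, h in self.donors if d == heavy)
        if not hs:
            raise KeyError(
                f"{self.base_id.value} template: {heavy!r} is not a donor"
            )
        return hs

    def heavy_atoms(self) -> tuple[Atom, ...]:
        return tuple(a for a in self.atoms if a.element != "H")

    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) array of template coordinates."""
        return np.array([a.position for a in self.atoms])

    # -- derived templates ----------------------------------------------

    def flipped(self) -> "BaseTemplate":
        """The template mirrored in-plane (y -> -y).

        A planar base rotated 180 degrees about an in-plane axis presents
        its opposite face; in a rigid planar model this is an in-plane
        mirror.  Used to realize *syn* residues geometrically: a syn base
        in a parallel quadruplex shows the opposite face to the 5' side
        relative to an anti base.
        """
        flip = np.array([1.0, -1.0, 1.0])
        atoms = tuple(
            Atom(a.name, a.element, a.position * flip, a.vdw_radius)
            for a in self.atoms
        )
        pos, direction = self.c1_attachment
        return BaseTemplate(
            base_id=self.base_id,
            atoms=atoms,
            donors=self.donors,
            acceptors=self.acceptors,
            glycosidic_atom=self.glycosidic_atom,
            c1_attachment=(pos * flip, direction * flip),
            mirrored=not self.mirrored,
        )


# ---------------------------------------------------------------------------
# Reference heavy-atom coordinates (standard base frames, z = 0)
# ---------------------------------------------------------------------------

_G_HEAVY = {
    "C1'": (-2.477, 5.399),
    "N9": (-1.289, 4.551),
    "C8": (0.023, 4.962),
    "N7": (0.870, 3.969),
    "C5": (0.071, 2.833),
    "C6": (0.424, 1.460),
    "O6": (1.554, 0.955),
    "N1": (-0.700, 0.641),
    "C2": (-1.999, 1.087),
    "N2": (-2.949, 0.139),
    "N3": (-2.342, 2.364),
    "C4": (-1.265, 3.177),
}

_T_HEAVY = {
    "C1'": (-2.481, 5.354),
    "N1": (-1.284, 4.500),
    "C2": (-1.462, 3.135),
    "O2": (-2.562, 2.608),
    "N3": (-0.298, 2.407),
    "C4": (0.994, 2.897),
    "O4": (1.944, 2.119),
    "C5": (1.106, 4.338),
    "C7": (2.466, 4.961),
    "C6": (-0.024, 5.057),
}


def _v(xy) -> np.ndarray:
    return np.array([xy[0], xy[1], 0.0])


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _bisector_substituent(center, n1, n2, length) -> np.ndarray:
    """Position of a substituent on *center* along the external bisector
    of the center->n1 / center->n2 bond directions."""
    d = -(_unit(n1 - center) + _unit(n2 - center))
    return center + length * _unit(d)


def _rot2(deg: float) -> np.ndarray:
    t = np.radians(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _amino_hydrogens(n_pos, c_pos):
    """The two in-plane hydrogens of an sp2 amino group N bonded to C."""
    v = _unit(c_pos - n_pos)
    h1 = n_pos + N_H_BOND_LENGTH * (_rot2(120.0) @ v)
    h2 = n_pos + N_H_BOND_LENGTH * (_rot2(-120.0) @ v)
    return h1, h2


def _element_of(name: str) -> str:
    return name[0]


def _build_guanine() -> BaseTemplate:
    p = {k: _v(xy) for k, xy in _G_HEAVY.items()}
    p["H1"] = _bisector_substituent(p["N1"], p["C2"], p["C6"], N_H_BOND_LENGTH)
    p["H21"], p["H22"] = _amino_hydrogens(p["N2"], p["C2"])
    p["H8"] = _bisector_substituent(p["C8"], p["N7"], p["N9"], _C_H_BOND_LENGTH)
    order = [
        "N9", "C8", "H8", "N7", "C5", "C6", "O6", "N1", "H1",
        "C2", "N2", "H21", "H22", "N3", "C4", "C1'",
    ]
    atoms = tuple(
        Atom(n, _element_of(n), p[n], vdw_radius(_element_of(n))) for n in order
    )
    return BaseTemplate(
        base_id=BaseId.G,
        atoms=atoms,
        donors=(("N1", "H1"), ("N2", "H21"), ("N2", "H22")),
        acceptors=("O6", "N7", "N3"),
        glycosidic_atom="N9",
        c1_attachment=(p["C1'"], _unit(p["C1'"] - p["N9"])),
    )


def _build_oxoguanine() -> BaseTemplate:
    p = {k: _v(xy) for k, xy in _G_HEAVY.items()}
    p["H1"] = _bisector_substituent(p["N1"], p["C2"], p["C6"], N_H_BOND_LENGTH)
    p["H21"], p["H22"] = _amino_hydrogens(p["N2"], p["C2"])
    # 8-oxo substitution: C8 carbonyl oxygen replaces H8, N7 is protonated.
    p["O8"] = _bisector_substituent(p["C8"], p["N7"], p["N9"], _C_O_CARBONYL)
    p["H7"] = _bisector_substituent(p["N7"], p["C5"], p["C8"], N_H_BOND_LENGTH)
    order = [
        "N9", "C8", "O8", "N7", "H7", "C5", "C6", "O6", "N1", "H1",
        "C2", "N2", "H21", "H22", "N3", "C4", "C1'",
    ]
    atoms = tuple(
        Atom(n, _element_of(n), p[n], vdw_radius(_element_of(n))) for n in order
    )
    return BaseTemplate(
        base_id=BaseId.OXOG,
        atoms=atoms,
        donors=(("N1", "H1"), ("N7", "H7"), ("N2", "H21"), ("N2", "H22")),
        acceptors=("O6", "O8", "N3"),
        glycosidic_atom="N9",
        c1_attachment=(p["C1'"], _unit(p["C1'"] - p["N9"])),
    )


def _build_thymine() -> BaseTemplate:
    # Overhang bookkeeping stub only; no pairing geometry is modelled.
    p = {k: _v(xy) for k, xy in _T_HEAVY.items()}
    p["H3"] = _bisector_substituent(p["N3"], p["C2"], p["C4"], N_H_BOND_LENGTH)
    order = ["N1", "C2", "O2", "N3", "H3", "C4", "O4", "C5", "C7", "C6", "C1'"]
    atoms = tuple(
        Atom(n, _element_of(n), p[n], vdw_radius(_element_of(n))) for n in order
    )
    return BaseTemplate(
        base_id=BaseId.T,
        atoms=atoms,
        donors=(("N3", "H3"),),
        acceptors=("O2", "O4"),
        glycosidic_atom="N1",
        c1_attachment=(p["C1'"], _unit(p["C1'"] - p["N1"])),
    )


@lru_cache(maxsize=None)
def get_template(base_id: BaseId | str) -> BaseTemplate:
    """Return the immutable template for *base_id* (``G``, ``OXOG`` or ``T``).

    Repeated calls return the identical object; geometry is deterministic.
    """
    if isinstance(base_id, str):
        try:
            base_id = BaseId[base_id.upper()]
        except KeyError:
            raise UnknownBaseError(f"unknown base {base_id!r}") from None
    if not isinstance(base_id, BaseId):
        raise UnknownBaseError(f"unknown base {base_id!r}")
    if base_id is BaseId.G:
        return _build_guanine()
    if base_id is BaseId.OXOG:
        return _build_oxoguanine()
    if base_id is BaseId.T:
        return _build_thymine()
    raise UnknownBaseError(f"unknown base {base_id!r}")
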