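"""Restrained rigid-base simulated annealing.

A desk-scale surrogate of restrained simulated-annealing model building:
every residue (base + C1' pseudo-atom) is an internally rigid body with
six degrees of freedom, moved by Metropolis Monte Carlo under a restraint
energy, with a three-phase temperature schedule (hot plateau, cooling to
an intermediate temperature, cooling to near zero — mirroring a
1000 K / 300 K / 0 K protocol).  Many independent runs are launched from
randomized starts and the lowest-energy structures are selected.

The energy is a pure restraint energy (no force field):

* flat-bottom harmonic distance restraints — zero within
  ``target +/- half-width``, ``k * excess**2`` outside.  Hydrogen-bond
  restraints use k = 20 kcal/mol/A^2, the force constant of the
  annealing protocol this package emulates;
* orientation restraints — ``k * theta**2`` on the tilt of a residue's
  base-plane normal away from the helical axis, with
  k = 200 kcal/mol/rad^2 (the glycosidic-torsion force constant; with
  rigid bases and no sugar atoms the chi restraint maps onto keeping a
  residue's placed face, i.e. its syn/anti sense, fixed);
* connectivity restraints — backbone-plausibility ranges on consecutive
  C1'-C1' distances within a strand, expressed as flat-bottom restraints.

Runs are fully seeded: the same schedule seed reproduces the ensemble
bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .core import CoreModel, StructureModel, make_sequence_core
from .quartets import _rotz

__all__ = [
    "DistanceRestraint",
    "OrientationRestraint",
    "RestraintSet",
    "AnnealSchedule",
    "AnnealResult",
    "default_restraints",
    "restraint_energy",
    "anneal",
    "UnresolvableSelectorError",
]

#: kcal/(mol K)
_GAS_CONSTANT = 0.0019872041

#: hydrogen-bond / torsion force constants of the emulated protocol
HBOND_FORCE_CONSTANT = 20.0  # kcal/mol/A^2
TORSION_FORCE_CONSTANT = 200.0  # kcal/mol/rad^2

#: backbone-plausibility range for consecutive C1'-C1' (A)
CONNECTIVITY_RANGE = (3.5, 7.0)


class UnresolvableSelectorError(KeyError):
    """An atom/residue selector does not resolve in the model."""


@dataclass(frozen=True)
class DistanceRestraint:
    """Flat-bottom harmonic distance restraint between two atoms.

    Selectors are ``"chain:resnum:atomname"`` strings.  The energy is zero
    for ``|d - target| <= half_width`` and ``k * (|d - target| -
    half_width)**2`` outside.
    """

    sel_i: str
    sel_j: str
    target: float
    k: float = HBOND_FORCE_CONSTANT
    half_width: float = 0.1
    kind: str = "hbond"  # "hbond" | "connectivity" | "stacking"

    def __post_init__(self):
        if self.k < 0 or self.half_width < 0:
            raise ValueError("force constant and flat half-width must be >= 0")


@dataclass(frozen=True)
class OrientationRestraint:
    """Harmonic restraint on the tilt of a residue's base normal."""

    sel: str  # "chain:resnum"
    target_flag: str  # "syn" | "anti"
    k: float = TORSION_FORCE_CONSTANT

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("force constant must be >= 0")
        if self.target_flag not in ("syn", "anti"):
            raise ValueError("target_flag must be 'syn' or 'anti'")


@dataclass
class RestraintSet:
    distances: list[DistanceRestraint] = field(default_factory=list)
    orientations: list[OrientationRestraint] = field(default_factory=list)

    def hbond_restraints(self) -> list[DistanceRestraint]:
        return [r for r in self.distances if r.kind == "hbond"]

    # -- serialization ---------------------------------------------------

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "distances": [asdict(r) for r in self.distances],
                "orientations": [asdict(r) for r in self.orientations],
            },
            sort_keys=False,
        )

    @classmethod
    def from_yaml(cls, text: str) -> "RestraintSet":
        data = yaml.safe_load(text)
        return cls(
            distances=[DistanceRestraint(**d) for d in data.get("distances", [])],
            orientations=[
                OrientationRestraint(**d) for d in data.get("orientations", [])
            ],
        )


@dataclass(frozen=True)
class AnnealSchedule:
    """Three-phase annealing schedule.

    ``phase_steps`` are Monte-Carlo sweep counts for (hot plateau,
    cooling T_hot -> T_mid, cooling T_mid -> ~0); the 1:2:2 default
    mirrors the 200/400/400 ps phase durations of the emulated protocol
    at a desk-scale sweep budget.  ``n_runs`` independent runs are
    launched and the ``n_select`` lowest-energy models returned.
    """

    T_hot: float = 1000.0
    T_mid: float = 300.0
    phase_steps: tuple[int, int, int] = (200, 400, 400)
    n_runs: int = 100
    n_select: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.T_hot < 0 or self.T_mid < 0:
            raise ValueError("temperatures must be >= 0")
        if self.T_mid > self.T_hot:
            raise ValueError("T_mid must not exceed T_hot")
        if self.n_select > self.n_runs:
            raise ValueError("n_select must not exceed n_runs")
        if any(s < 0 for s in self.phase_steps) or len(self.phase_steps) != 3:
            raise ValueError("phase_steps must be three non-negative sweep counts")

    def temperatures(self) -> np.ndarray:
        """Per-sweep temperature sequence (geometric interpolation)."""
        n1, n2, n3 = self.phase_steps
        t_floor = 1.0
        hot = np.full(n1, self.T_hot)
        if self.T_hot > 0 and self.T_mid > 0:
            cool1 = self.T_hot * (self.T_mid / self.T_hot) ** (
                np.arange(1, n2 + 1) / max(n2, 1)
            )
            cool2 = self.T_mid * (t_floor / self.T_mid) ** (
                np.arange(1, n3 + 1) / max(n3, 1)
            )
        else:
            cool1 = np.full(n2, self.T_mid)
            cool2 = np.zeros(n3)
        return np.concatenate([hot, cool1, cool2])


@dataclass
class AnnealResult:
    models: list[StructureModel]
    energies: list[float]
    run_indices: list[int]
    all_energies: list[float]


# ---------------------------------------------------------------------------
# Selector resolution
# ---------------------------------------------------------------------------


def _residue_key(sel: str) -> tuple[str, int]:
    parts = sel.split(":")
    if len(parts) < 2:
        raise UnresolvableSelectorError(f"malformed selector {sel!r}")
    return parts[0], int(parts[1])


class _Layout:
    """Flat coordinate layout of a StructureModel for fast energy math."""

    def __init__(self, struct: StructureModel):
        self.struct = struct
        self.atom_index: dict[tuple[str, int, str], int] = {}
        coords = []
        self.res_slices: list[slice] = []
        self.res_keys: dict[tuple[str, int], int] = {}
        for ri, res in enumerate(struct.residues):
            start = len(coords)
            for name, pos in res.atoms.items():
                self.atom_index[(res.chain, res.number, name)] = len(coords)
                coords.append(pos)
            self.res_slices.append(slice(start, len(coords)))
            self.res_keys[(res.chain, res.number)] = ri
        self.coords = np.array(coords)

    def atom(self, sel: str) -> int:
        parts = sel.split(":")
        if len(parts) != 3:
            raise UnresolvableSelectorError(f"malformed atom selector {sel!r}")
        key = (parts[0], int(parts[1]), parts[2])
        try:
            return self.atom_index[key]
        except KeyError:
            raise UnresolvableSelectorError(
                f"selector {sel!r} does not resolve to an atom"
            ) from None

    def residue(self, sel: str) -> int:
        key = _residue_key(sel)
        try:
            return self.res_keys[key]
        except KeyError:
            raise UnresolvableSelectorError(
                f"selector {sel!r} does not resolve to a residue"
            ) from None

    def residue_of_atom(self, ai: int) -> int:
        for ri, sl in enumerate(self.res_slices):
            if sl.start <= ai < sl.stop:
                return ri
        raise IndexError(ai)


def _compile(struct: StructureModel, restraints: RestraintSet):
    layout = _Layout(struct)
    di = np.array([layout.atom(r.sel_i) for r in restraints.distances], dtype=int)
    dj = np.array([layout.atom(r.sel_j) for r in restraints.distances], dtype=int)
    target = np.array([r.target for r in restraints.distances])
    hw = np.array([r.half_width for r in restraints.distances])
    kk = np.array([r.k for r in restraints.distances])
    ori_res = np.full(len(struct.residues), -1.0)
    for o in restraints.orientations:
        ori_res[layout.residue(o.sel)] = max(ori_res[layout.residue(o.sel)], 0.0) + o.k
    return layout, (di, dj, target, hw, kk), ori_res


def _distance_energy(coords, di, dj, target, hw, kk) -> float:
    if len(di) == 0:
        return 0.0
    d = np.linalg.norm(coords[di] - coords[dj], axis=1)
    excess = np.maximum(np.abs(d - target) - hw, 0.0)
    return float(np.sum(kk * excess**2))


def restraint_energy(model, restraints: RestraintSet) -> float:
    """Total restraint energy (kcal/mol) of *model*; >= 0.

    Orientation restraints measure the angle between a residue's base
    normal and the +z axis (the helical axis of assembled cores); a
    residue built in its target orientation contributes zero.
    """
    struct = model.to_structure() if isinstance(model, CoreModel) else model
    layout, dist, ori_res = _compile(struct, restraints)
    energy = _distance_energy(layout.coords, *dist)
    for ri, k in enumerate(ori_res):
        if k >= 0:
            energy += k * _normal_tilt(layout.coords[layout.res_slices[ri]]) ** 2
    return energy


def _plane_normal_of(res_coords: np.ndarray) -> np.ndarray:
    rel = res_coords - res_coords.mean(axis=0)
    _, _, vt = np.linalg.svd(rel, full_matrices=False)
    return vt[-1]


def _tilt_of(normal: np.ndarray) -> float:
    cos_t = abs(normal[2]) / np.linalg.norm(normal)
    return float(np.arccos(np.clip(cos_t, -1.0, 1.0)))


def _normal_tilt(res_coords: np.ndarray) -> float:
    """Angle (rad) between the residue plane normal and +z."""
    return _tilt_of(_plane_normal_of(res_coords))


# ---------------------------------------------------------------------------
# Default restraints
# ---------------------------------------------------------------------------


def default_restraints(core: CoreModel) -> RestraintSet:
    """Generate the standard restraint set for a built core.

    * hydrogen-bond H...A distances of every quartet edge, at the scheme
      targets actually realized by the builder (half-width 0.1 A);
    * orientation restraints on every quartet residue;
    * connectivity ranges on consecutive C1'-C1' pairs per strand;
    * stacking-separation anchors (same-strand N9-N9 across each step, at
      the ideal-model distance +/- 0.5 A) standing in for the stacking
      forces a full force field would provide.
    """
    struct = core.to_structure()
    distances: list[DistanceRestraint] = []
    orientations: list[OrientationRestraint] = []

    from .quartets import _scheme_indices, default_scheme  # local import

    n5, _ = core.overhangs
    chains = struct.chains[:4]
    for k, quartet in enumerate(core.planes):
        scheme = default_scheme(quartet.template)
        names = quartet.template.atom_names
        resnum = n5 + k + 1
        plane_res = {r.chain: r for r in struct.plane(k)}
        for (di, h_cands, ai, direction), target in zip(
            _scheme_indices(quartet.template, scheme), scheme.target_HA
        ):
            for s in range(4):
                donor_chain = chains[s] if direction > 0 else chains[(s + 1) % 4]
                accept_chain = chains[(s + 1) % 4] if direction > 0 else chains[s]
                donor_res = plane_res[donor_chain]
                accept_res = plane_res[accept_chain]
                a_pos = accept_res.atoms[names[ai]]
                h_name = min(
                    (names[h] for h in h_cands),
                    key=lambda h: float(np.linalg.norm(donor_res.atoms[h] - a_pos)),
                )
                # Scheme target where the built plane realizes it; the
                # built distance for ring-size-constrained planes whose
                # H-bonds were shifted away from the scheme target.
                built = float(np.linalg.norm(donor_res.atoms[h_name] - a_pos))
                eff_target = float(target) if abs(built - target) <= 0.1 else built
                distances.append(
                    DistanceRestraint(
                        sel_i=f"{donor_chain}:{resnum}:{h_name}",
                        sel_j=f"{accept_chain}:{resnum}:{names[ai]}",
                        target=eff_target,
                        k=HBOND_FORCE_CONSTANT,
                        half_width=0.1,
                        kind="hbond",
                    )
                )
        for chain in chains:
            orientations.append(
                OrientationRestraint(
                    sel=f"{chain}:{resnum}", target_flag=core.flags[k]
                )
            )

    lo, hi = CONNECTIVITY_RANGE
    mid, half = (lo + hi) / 2.0, (hi - lo) / 2.0
    for chain in chains:
        strand = struct.strand(chain)
        for r1, r2 in zip(strand, strand[1:]):
            distances.append(
                DistanceRestraint(
                    sel_i=f"{chain}:{r1.number}:C1'",
                    sel_j=f"{chain}:{r2.number}:C1'",
                    target=mid,
                    k=HBOND_FORCE_CONSTANT,
                    half_width=half,
                    kind="connectivity",
                )
            )
            if r1.plane is not None and r2.plane is not None:
                # two anchors per step at different ring azimuths pin the
                # relative plane rotation as well as the rise
                for anchor in ("N9", "C2"):
                    d0 = float(np.linalg.norm(r1.atoms[anchor] - r2.atoms[anchor]))
                    distances.append(
                        DistanceRestraint(
                            sel_i=f"{chain}:{r1.number}:{anchor}",
                            sel_j=f"{chain}:{r2.number}:{anchor}",
                            target=d0,
                            k=HBOND_FORCE_CONSTANT,
                            half_width=0.3,
                            kind="stacking",
                        )
                    )
    return RestraintSet(distances=distances, orientations=orientations)


# ---------------------------------------------------------------------------
# Annealing
# ---------------------------------------------------------------------------


def _random_rotation(rng: np.random.Generator, angle_sigma: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.normal(0.0, angle_sigma)
    return _axis_angle(axis, angle)


def _axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    x, y, z = axis
    K = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return np.eye(3) + s * K + (1 - c) * (K @ K)


class _Sampler:
    """One Metropolis run over per-residue rigid-body moves."""

    # base move amplitudes at 300 K
    TRANS_SIGMA = 0.2  # A
    ROT_SIGMA = np.radians(5.0)

    def __init__(self, struct, restraints, rng):
        self.layout, self.dist, self.ori_res = _compile(struct, restraints)
        self.coords = self.layout.coords.copy()
        self.rng = rng
        n_res = len(struct.residues)
        di, dj = self.dist[0], self.dist[1]
        res_of_atom = np.empty(len(self.coords), dtype=int)
        for ri, sl in enumerate(self.layout.res_slices):
            res_of_atom[sl] = ri
        # distance restraints touching each residue
        self.res_restraints = [
            np.where((res_of_atom[di] == ri) | (res_of_atom[dj] == ri))[0]
            for ri in range(n_res)
        ]
        # residues that any restraint touches are mobile
        self.mobile = [
            ri
            for ri in range(n_res)
            if len(self.res_restraints[ri]) or self.ori_res[ri] >= 0
        ]
        # Rigid residues: track each base normal and rotate it with the
        # residue instead of refitting a plane at every move.
        self.normals = np.zeros((n_res, 3))
        for ri, sl in enumerate(self.layout.res_slices):
            if self.ori_res[ri] >= 0:
                self.normals[ri] = _plane_normal_of(self.coords[sl])

    def _partial_distance_energy(self, coords, idx) -> float:
        if len(idx) == 0:
            return 0.0
        di, dj, target, hw, kk = self.dist
        d = np.linalg.norm(coords[di[idx]] - coords[dj[idx]], axis=1)
        excess = np.maximum(np.abs(d - target[idx]) - hw[idx], 0.0)
        return float(np.sum(kk[idx] * excess**2))

    def randomize_start(self, trans_sigma: float, rot_sigma: float) -> None:
        if trans_sigma == 0 and rot_sigma == 0:
            return
        for ri in self.mobile:
            sl = self.layout.res_slices[ri]
            block = self.coords[sl]
            centroid = block.mean(axis=0)
            R = _random_rotation(self.rng, rot_sigma)
            t = self.rng.normal(0.0, trans_sigma, size=3)
            self.coords[sl] = (block - centroid) @ R.T + centroid + t
            if self.ori_res[ri] >= 0:
                self.normals[ri] = R @ self.normals[ri]

    def sweep(self, temperature: float) -> None:
        scale = float(np.clip(np.sqrt(max(temperature, 1e-6) / 300.0), 0.3, 2.0))
        beta = (
            1.0 / (_GAS_CONSTANT * temperature) if temperature > 0 else np.inf
        )
        for ri in self.mobile:
            sl = self.layout.res_slices[ri]
            idx = self.res_restraints[ri]
            old_block = self.coords[sl].copy()
            e_old = self._partial_distance_energy(self.coords, idx)
            k_ori = self.ori_res[ri]
            if k_ori >= 0:
                e_old += k_ori * _tilt_of(self.normals[ri]) ** 2
            centroid = old_block.mean(axis=0)
            R = _random_rotation(self.rng, self.ROT_SIGMA * scale)
            t = self.rng.normal(0.0, self.TRANS_SIGMA * scale, size=3)
            self.coords[sl] = (old_block - centroid) @ R.T + centroid + t
            e_new = self._partial_distance_energy(self.coords, idx)
            new_normal = None
            if k_ori >= 0:
                new_normal = R @ self.normals[ri]
                e_new += k_ori * _tilt_of(new_normal) ** 2
            delta = e_new - e_old
            # strict downhill threshold so numerically-flat moves are not
            # accepted at T = 0 (Metropolis covers them for T > 0)
            accept = delta < -1e-9 or (
                np.isfinite(beta) and self.rng.random() < np.exp(-beta * delta)
            )
            if accept:
                if new_normal is not None:
                    self.normals[ri] = new_normal
            else:
                self.coords[sl] = old_block

    def total_energy(self) -> float:
        e = self._partial_distance_energy(self.coords, np.arange(len(self.dist[0])))
        for ri, k in enumerate(self.ori_res):
            if k >= 0:
                e += k * _normal_tilt(self.coords[self.layout.res_slices[ri]]) ** 2
        return e

    def to_structure(self) -> StructureModel:
        out = self.layout.struct.copy()
        i = 0
        for res in out.residues:
            for name in res.atoms:
                res.atoms[name] = self.coords[i].copy()
                i += 1
        return out


def anneal(
    spec,
    restraints: RestraintSet | None = None,
    schedule: AnnealSchedule | None = None,
) -> AnnealResult:
    """Run seeded restrained annealing and select the lowest-energy models.

    *spec* is a sequence string (over T/G/X) or a built
    :class:`~oxoquartet.core.CoreModel`.  Each of ``schedule.n_runs``
    Metropolis runs starts from an independently randomized copy of the
    built model (randomization amplitude scales with sqrt(T_hot/1000),
    emulating random starting velocities); the ``n_select`` lowest-energy
    final structures are returned sorted by energy, ties broken by run
    index.  Identical seeds give identical ensembles.
    """
    if isinstance(spec, str):
        core = make_sequence_core(spec)
    elif isinstance(spec, CoreModel):
        core = spec
    else:
        raise TypeError("spec must be a sequence string or CoreModel")
    if restraints is None:
        restraints = default_restraints(core)
    if schedule is None:
        schedule = AnnealSchedule()

    struct0 = core.to_structure()
    temperatures = schedule.temperatures()
    amp = float(np.sqrt(schedule.T_hot / 1000.0))
    seed_seq = np.random.SeedSequence(schedule.seed)
    children = seed_seq.spawn(schedule.n_runs)

    results = []
    for run, child in enumerate(children):
        rng = np.random.default_rng(child)
        sampler = _Sampler(struct0, restraints, rng)
        sampler.randomize_start(0.5 * amp, np.radians(10.0) * amp)
        for T in temperatures:
            sampler.sweep(T)
        # deterministic zero-temperature polish
        for _ in range(20):
            sampler.sweep(0.0)
        results.append((sampler.total_energy(), run, sampler.to_structure()))

    results.sort(key=lambda r: (r[0], r[1]))
    selected = results[: schedule.n_select]
    return AnnealResult(
        models=[m for _, _, m in selected],
        energies=[e for e, _, _ in selected],
        run_indices=[r for _, r, _ in selected],
        all_energies=[e for e, _, _ in sorted(results, key=lambda r: r[1])],
    )
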