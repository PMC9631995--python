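"""Synthetic structures and fixtures.

Provides seeded coordinate perturbation (a stand-in for experimental/
simulation ensembles, whose coordinates are not publicly deposited) and a
deterministic suite of small PDB fixtures covering every analysis stage:
ideal G- and oxoG-quartets at reference ring geometries, the four
oxoG-substituted d(TG4T) analogue cores, and a noise-perturbed ensemble.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import CoreModel, StructureModel, make_sequence_core
from .pdbio import write_ensemble, write_pdb
from .quartets import build_quartet
from .templates import BaseId, get_template

__all__ = ["PerturbSpec", "perturb", "make_fixture_suite", "ANALOGUE_SEQUENCES"]

#: The oxoG analogues of d(TG4T): oxoG at tract positions 2-5.
ANALOGUE_SEQUENCES: dict[str, str] = {
    "odn2": "TXGGGT",
    "odn3": "TGXGGT",
    "odn4": "TGGXGT",
    "odn5": "TGGGXT",
}

#: Table-reference neighboring O6-O6 ring sizes (A) for oxoG-quartets:
#: no cation, in-plane K+, in-plane Na+.
OXOG_RING_SIZES: dict[str, tuple[float, str | None]] = {
    "nocation": (4.04, None),
    "k": (3.87, "K"),
    "na": (3.72, "Na"),
}

G_REFERENCE_RING_SIZE = 3.15

_ENSEMBLE_SIGMA = 0.25
_ENSEMBLE_SIZE = 100
_ENSEMBLE_SEED = 42


@dataclass(frozen=True)
class PerturbSpec:
    """Isotropic Gaussian perturbation: per-atom (default) or rigid
    per-residue translation (``rigid_only``), seeded."""

    sigma: float  # A
    seed: int
    rigid_only: bool = False

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def perturb(model, spec: PerturbSpec) -> StructureModel:
    """Seeded Gaussian perturbation of *model*; sigma = 0 is the identity."""
    struct = model.to_structure() if isinstance(model, CoreModel) else model
    out = struct.copy()
    if spec.sigma == 0:
        return out
    rng = np.random.default_rng(spec.seed)
    if spec.rigid_only:
        for res in out.residues:
            shift = rng.normal(0.0, spec.sigma, size=3)
            for name in res.atoms:
                res.atoms[name] = res.atoms[name] + shift
        out.cations = [
            (e, p + rng.normal(0.0, spec.sigma, size=3)) for e, p in out.cations
        ]
    else:
        for res in out.residues:
            for name in res.atoms:
                res.atoms[name] = res.atoms[name] + rng.normal(
                    0.0, spec.sigma, size=3
                )
        out.cations = [
            (e, p + rng.normal(0.0, spec.sigma, size=3)) for e, p in out.cations
        ]
    return out


def _quartet_structure(quartet) -> StructureModel:
    from .core import assemble_core

    core = assemble_core([quartet], [])
    core.flags = ["syn" if quartet.template.base_id is BaseId.OXOG else "anti"]
    struct = core.to_structure()
    if quartet.cation is not None:
        element, pos = quartet.cation
        struct.cations.append((element, np.array(pos, float)))
    return struct


def make_fixture_suite(out_dir: str | os.PathLike) -> dict[str, Path]:
    """Write the deterministic PDB fixture suite into *out_dir*.

    Contents: an ideal G-quartet at the experimental reference ring size;
    ideal oxoG-quartets at each tabulated ring geometry (with the
    corresponding in-plane cation where one applies); the four oxoG
    analogue cores; and a 100-member Gaussian-perturbed ensemble of the
    centrally substituted analogue (sigma 0.25 A, fixed seed).
    Regeneration is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    g_quartet = build_quartet(
        get_template(BaseId.G), mode="ring_size", value=G_REFERENCE_RING_SIZE
    )
    paths["g_quartet"] = out_dir / "g_quartet_3p15.pdb"
    write_pdb(_quartet_structure(g_quartet), paths["g_quartet"])

    oxo_template = get_template(BaseId.OXOG)
    for label, (ring, cation) in OXOG_RING_SIZES.items():
        q = build_quartet(oxo_template, mode="ring_size", value=ring)
        if cation is not None:
            q = q.with_cation(cation)
        key = f"oxog_quartet_{label}"
        paths[key] = out_dir / f"{key}.pdb"
        write_pdb(_quartet_structure(q), paths[key])

    for name, seq in ANALOGUE_SEQUENCES.items():
        core = make_sequence_core(seq)
        paths[name] = out_dir / f"{name}_core.pdb"
        write_pdb(core, paths[name])

    reference = make_sequence_core(ANALOGUE_SEQUENCES["odn4"]).to_structure()
    members = [
        perturb(reference, PerturbSpec(sigma=_ENSEMBLE_SIGMA, seed=_ENSEMBLE_SEED + i))
        for i in range(_ENSEMBLE_SIZE)
    ]
    paths["ensemble"] = out_dir / "odn4_perturbed_ensemble.pdb"
    write_ensemble(members, paths["ensemble"])
    return paths
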