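# Methods

## Rigid-base model

Every nucleobase is an internally rigid, planar unit: the standard
small-molecule heavy-atom frame of the base, explicit in-plane hydrogens,
and a C1′ pseudo-atom marking the glycosidic attachment. No sugar or
phosphate atoms are modelled. 8-Oxoguanine is derived from guanine by
adding the C8 carbonyl oxygen (C=O 1.23 Å, in-plane, along the external
N7/N9 bisector) and the N7 proton, and removing the aromatic H8; the
8-keto tautomer is assumed throughout (the 8-hydroxy tautomer is a minor
species in water). The thymine template is a bookkeeping stub for strand
overhangs; no thymine pairing is modelled.

Two bond-length conventions matter downstream and are fixed package-wide:

* **N–H = 1.03 Å** for all donors. This is forced by internal consistency
  of near-linear hydrogen bonds: D···A = H···A + d(N–H) under linearity,
  and the tabulated pairs (1.92, 2.95) and (1.76, 2.78 ≈ 2.79) Å both
  imply d(N–H) ≈ 1.03 Å.
* **Bondi van der Waals radii** (O = 1.52 Å, N = 1.55 Å, …). The oxygen
  value reproduces both printed cavity diameters exactly:
  5.72 − 2×1.52 = 2.68 and 4.50 − 2×1.52 = 1.46 Å.

## Quartet construction

A quartet has three degrees of freedom: the in-plane placement
(x, y, rotation) of base 0; bases 1–3 are exact 90° copies about +z. C4
symmetry is imposed rather than discovered, because the NMR observables
the model explains come from a single fourfold-symmetric species. A
consequence used as an internal invariant is that the diagonal O6–O6
distance is exactly √2 times the neighboring one.

**Hydrogen-bond schemes.** A scheme lists (donor, acceptor) pairs between
adjacent bases with one H···A target each. Unlike the canonical Hoogsteen
G-quartet — where both donors of a base sit on its Watson–Crick edge and
donate to the same neighbour — the oxoG scheme is *reciprocal*: N1–H1 of
base *i* donates to O8 of base *i+1* while N7–H7 of base *i+1* donates
back to O6 of base *i*. Schemes therefore carry a per-pair direction
flag. (A single-direction oxoG scheme is geometrically infeasible: the
best C4 placement leaves ~1 Å residuals, because N1/H1 and N7/H7 sit on
opposite edges of the base.)

**Fitting.** `hbond_target` mode minimizes
Σ(d(H···A) − target)² + w·Σ(π − θ(D–H···A))² with w = 0.1 Å²/rad²,
over the three placement DOF. Initialization is a deterministic dense
grid (rotation every 4°, translations on a 0.5 Å grid over ±7 Å,
vectorized), followed by least-squares refinement of the eight best
basins; ties break toward the smaller grid rotation. There is no random
state; repeated builds are bit-identical. Amino donors (two hydrogens)
engage whichever hydrogen is closer to the acceptor. A fit whose final
objective exceeds 0.1 Å² raises an infeasibility error carrying the
residual; feasible chemistries land orders of magnitude below (oxoG:
1.6×10⁻³ Å², i.e. H-bonds within 0.02 Å of target and ~168–174° angles).

`ring_size` mode takes the fitted orientation and shifts the base
radially along the axis→O6 direction so the neighboring O6–O6 distance is
met exactly. This preserves the fitted base orientation while letting the
ring be set to any tabulated geometry (3.72 / 3.87 / 4.04 Å for
Na⁺-bound / K⁺-bound / free oxoG-quartets; 3.15 Å for the G-quartet
reference). Free-fit values: the oxoG quartet converges to neighboring
O6–O6 = 3.86 Å (inside the tabulated range); the canonical G scheme at
(1.90, 2.00) Å targets gives 3.41 Å, slightly wider than the 3.15 Å
experimental average — G planes in sequence cores are therefore built in
ring-size mode at 3.15 Å.

## Cores, syn/anti, and steps

`make_sequence_core` turns a strand sequence over {T, G, X} into a
4-stranded parallel core: one quartet plane per G/X, thymines only as
5′/3′ overhang stubs. G planes are flagged *anti*, oxoG planes *syn* —
8-substituted purines strongly prefer syn, and the all-syn assignment is
what the H2′/C2′ chemical-shift signature supports. The syn flag is
realized geometrically by building the plane from the in-plane-mirrored
base template: a planar base rotated 180° about an in-plane axis presents
its opposite face, which in a rigid planar model is a 2D mirror (this
also mirrors the C1′ pseudo-atom; a "C1′-only" mirror would be a no-op
since C1′ lies on the glycosidic axis). Mirroring reverses the cyclic
hydrogen-bond sense around the ring, so the default scheme flips its
direction flags for mirrored templates; the resulting quartet is the
exact mirror image of the unmirrored one (identical fit residual).

**Steps.** Defaults are rise 3.13 Å / twist 30° for G–G steps (canonical
parallel-quadruplex values) and the ensemble means for oxoG-adjacent
steps: 2.94 Å / 26.23° into an oxoG plane, 3.21 Å / 26.52° out of one.
The step twist is *defined* on the glycosidic (N9→C1′) vectors, which are
well defined for both anti and syn residues. Because different plane
types have different intrinsic glycosidic azimuths, assembly applies a
frame rotation corrected by that azimuth difference, so the twist
measured by `step_parameters` equals the requested twist for any core —
the assembly↔extraction round trip is exact (1e-6) without the extractor
knowing plane types. Rise is the centroid separation projected on the
mean helical axis (best-fit line through plane centroids).

One geometric consequence of the mirrored syn plane: at the
syn-oxoG→anti-G junction the consecutive C1′–C1′ distance is 3.77 Å,
slightly below the 4 Å typical backbone minimum; the package uses
3.5–7.0 Å as its backbone-plausibility (connectivity) range. All other
steps fall between 5.2 and 6.0 Å.

**Cations** occupy either a plane centroid (`in_plane(k)`) or the
midpoint between adjacent centroids (`between(k, k+1)`); a 4-plane core
has 4 + 3 = 7 sites. Both localization modes matter physically: the
wider oxoG-quartet channel makes in-plane binding of Na⁺ and even K⁺
feasible, and slow hopping between such sites is the proposed origin of
doubled NMR resonances in cores with a sandwiched oxoG-quartet.

## Metrics

* **Cavity diameter** — generalized to all heavy atoms: twice the minimum
  over heavy atoms of (perpendicular distance from the plane's axis −
  Bondi radius), floored at 0. For canonical G/oxoG quartets the four O6
  atoms attain the minimum, so the metric reduces exactly to
  diagonal − 2 r(O); the generalization makes it robust on perturbed or
  read-in structures. The axis is the best-fit plane normal through the
  heavy-atom centroid.
* **Stacking overlap** — heavy base atoms (exocyclic substituents
  included, C1′ excluded) of the two stacked bases are projected onto the
  mean plane between the two quartets; each base becomes the convex
  polygon of its projected atom centers and the polygon intersection area
  is computed by clipping (shapely). Atom centers, not vdW disks, match
  the 1–8 Ų magnitude of published per-step stacking surfaces; the exact
  algorithm behind published values is not specified, so only orderings
  and ballparks are asserted. A seeded Monte-Carlo point-sampling
  estimate (10⁶ points) agrees with the clipping area within 1 %.
* **H-bond geometry** — Euclidean distances and the D–H···A angle at H;
  the donor–hydrogen pair must be covalently bonded (≤ 1.2 Å).
* **Planarity** — RMSD of heavy atoms from the SVD best-fit plane.

All metrics are invariant under global rigid motion (property-tested with
seeded random rotations) and accept ideal quartets, assembled cores, or
structures read back from PDB.

## Restrained annealing

A surrogate for restrained simulated-annealing model building at desk
scale. Degrees of freedom: per-residue rigid-body moves (random rotation
about the residue centroid plus translation); no internal base
flexibility. The energy is purely restraint-based:

| term | form | default |
| --- | --- | --- |
| hydrogen bond | flat-bottom harmonic on H···A | k = 20 kcal mol⁻¹ Å⁻², half-width 0.1 Å |
| orientation | k·θ², θ = tilt of base normal from +z | k = 200 kcal mol⁻¹ rad⁻² |
| connectivity | flat range on consecutive C1′–C1′ | 3.5–7.0 Å, k = 20 |
| stacking anchor | flat-bottom on same-strand N9–N9 and C2–C2 across each step | built-model distance ± 0.3 Å, k = 20 |

The two force constants are those of the annealing protocol this package
emulates. With rigid bases and no sugar, the χ-torsion restraints of that
protocol map onto the orientation term: it penalizes flipping a residue's
presented face, i.e. changing its syn/anti sense. The stacking anchors
stand in for the van-der-Waals stacking a full force field would provide;
without them the relative plane twist is underdetermined (flat to ±15°)
and ensembles do not converge. H-bond restraint targets are the scheme
targets where the built plane realizes them, else the built distance
(ring-size-constrained G planes); a freshly built core has exactly zero
restraint energy.

Schedule: three phases — hot plateau at 1000 K, geometric cooling to
300 K, geometric cooling to ~0 K — with sweep counts (200, 400, 400) in
the 1:2:2 ratio of the emulated protocol's phase durations, sized so that
the standard 100-run protocol on a 6-residue-per-strand core completes in
a few minutes on one CPU. Move amplitudes are 0.2 Å / 5° at 300 K,
scaled by √(T/300) and clipped to [0.3, 2]; each run ends with 20
strictly-downhill sweeps. Start structures are the built core with
per-residue random displacements (0.5 Å, 10°) scaled by √(T_hot/1000),
emulating random starting velocities — a T_hot = 0 schedule therefore
reproduces the input exactly. 100 independent seeded runs are launched
(seed sequence spawning; bit-reproducible) and the 10 lowest-energy
models selected, ties broken by run index.

Pilot-frozen convergence figures (seed 1, standard schedule): selected
energies < 0.1 kcal/mol, every H-bond restraint within half-width
+ 0.2 Å, pairwise heavy-atom RMSD of the selected models ≤ 2.5 Å after
superposition on the quartet core (overhang stubs are restrained only by
connectivity and legitimately fan out, as flexible termini do in NMR
ensembles). Annealed ensembles of the centrally substituted analogue
reproduce the stacking asymmetry of the sandwiched oxoG-quartet — mean
5′ (G→oxoG) overlap well above mean 3′ (oxoG→G) overlap — which the
idealized built core already shows (8.3 vs 3.7 Ų).

## Exchange lifetimes

For two species in slow exchange, the resonance splitting
Δν = Δδ(ppm)·f(MHz) bounds the interconversion rate. Two conventions are
exposed: τ = 1/Δν (default; 0.34 ppm at 800 MHz → 3.68 ms) and the
equal-population coalescence expression τ = √2/(π·Δν) (same inputs →
1.66 ms). The reciprocal-splitting form is the default because it matches
the reported ~3.6 ms figure for that splitting; which formula underlies
the reported number is not stated, so both are provided and the choice is
documented rather than asserted.

## Synthetic data

`perturb` adds seeded isotropic Gaussian noise per atom (or rigid
per-residue translations with `rigid_only`, preserving internal
geometry); σ = 0 is the bitwise identity. The fixture suite (σ = 0.25 Å,
100 members, seed 42 — frozen so downstream statistical tests are
reproducible) emulates coordinate scatter around an idealized core, i.e.
a stand-in for an undeposited simulation ensemble. It does **not**
emulate correlated motions, backbone physics, solvent or cation dynamics
— so passing tests demonstrate the metrics' and annealer's correctness
and robustness to coordinate noise, not agreement with any particular
experimental ensemble.

## Numerical choices and limitations

* Builder tolerance 0.1 Å² (infeasibility threshold); fit refinement to
  machine precision; the √2 diagonal relation is asserted at 1e-9 Å.
* PDB coordinates round-trip at the format's 0.001 Å precision; twist
  recovered from a written file is accurate to ~0.03° (coordinate
  rounding), while in-memory round trips are exact to 1e-6.
* Degenerate inputs: a zero-size ring gives (0, 0) O6 distances and a
  zero cavity; cavity values floor at 0; ties in the builder grid break
  deterministically.
* Absolute stacking surfaces, absolute H···A distances of optimized
  structures, melting temperatures, and spectra are outside the model's
  reach: the first two depend on undeposited coordinates/level of theory
  (tabulated values are used as *inputs*), the last two require
  thermodynamics and spectroscopy the rigid-base model does not contain.
* The annealer is a restraint optimizer, not MD: no electrostatics,
  solvent, cation dynamics, or kinetics.
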