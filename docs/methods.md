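# Methods

`groovebinder` re-implements, at desk scale and without any neural
network, the non-neural computational core of a helical-peptide binder
design workflow: parametric generation of groove-shaped five-helix
scaffolds that cradle an α-helical target, threading of peptide sequences
onto the bound helix with hydrophobic-interface filtering, the interface
and compactness metrics used as losses and gates, and a simulated-annealing
sequence optimizer driven by a pluggable structure-prediction oracle.

## Crick-parameterized helix generation

Cα coordinates follow the Crick generating equations for a minor helix of
radius R1 winding at ω1 deg/residue around a superhelical circle of radius
R0 traversed at ω0 deg/residue:

    x(t) = R0 cos(ω0 t + φ0) + R1 cos(ω0 t + φ0) cos(ω1 t + φ1)
           − R1 cos α sin(ω0 t + φ0) sin(ω1 t + φ1)
    y(t) = R0 sin(ω0 t + φ0) + R1 sin(ω0 t + φ0) cos(ω1 t + φ1)
           + R1 cos α cos(ω0 t + φ0) sin(ω1 t + φ1)
    z(t) = d cos α · t − R1 sin α sin(ω1 t + φ1)

with the pitch angle α fixed by sin α = R0·ω0/d, where d is the rise per
residue along the minor-helix axis.  Parameters with |R0·ω0| ≥ d have no
real pitch angle and are rejected at construction.  Defaults are the
canonical coiled-coil values d = 1.51 Å, R1 = 2.26 Å, ω1 = 102.85°/res for
supercoiled helices and 100°/res (with d = 1.5 Å) for ideal straight
helices; all are configurable, since they are conventions of the
parameterization rather than measured constants.  Angles are degrees at
every interface and converted to radians exactly once.

Only Cα positions come from the generating equations.  N, C and O are
completed by superimposing a three-residue ideal α-helix template (built by
natural-extension placement from standard bond lengths/angles, φ = −57.8°,
ψ = −47.0°) onto each local Cα triplet and copying the central residue's
atoms; terminal residues borrow the end triplets.  A helix with sense = −1
is generated and then rotated 180° about the radial axis through its own
centroid — a proper rotation, so chirality is preserved and the helix keeps
its azimuth while running antiparallel.

Helix axes are estimated per sliding window of four Cα atoms: the local
axis direction comes from successive second-difference (inward-normal)
vectors, and the axis point is a linear least-squares circle centre in the
plane perpendicular to that direction.  The inter-helix neighbour distance
is the mean closest approach between two fitted axis polylines over their
overlapping span, symmetrized over both directions.

## Groove-scaffold sampling

A candidate is three groove helices at azimuths 90°/180°/270° around an
imaginary central target helix (the slot, on +z), plus two buttressing
helices in the 135°/225° gaps, leaving the 0° face open.  Senses alternate
around the arc so azimuthally adjacent helices are antiparallel, which
keeps loopable termini at matching heights.

Per candidate the sampler draws: helix lengths uniform in [15, 19];
a supercoil magnitude |ω0| from a truncated exponential on [0, 4]°/res with
density ∝ exp(0.5·|ω0|), favouring strongly supercoiled bundles; an
average neighbour distance from N(9.5 Å, 0.7 Å) (typical native
helix-packing values); per-helix distances from the much tighter
N(average, 0.25 Å); minor-helix phases uniform in [0°, 360°); z-offsets
uniform in [−3, 3] Å; and buttress tilts uniform in [−15°, +15°] about the
azimuthal tangent.  The supercoil cap of 4°/res keeps the pitch angle below
~35° at the sampled radii — the native coiled-coil regime — so Cα–Cα steps
stay protein-like (3.7–3.9 Å) across the whole library; larger ranges
remain available through configuration.

Groove helices share the sampled ω0 and use their sampled distance as
superhelical radius; the supercoil twist is centred by shifting φ0 by
−ω0(L−1)/2 so each helix sits at its nominal azimuth at mid-height.
Buttresses use the same parameterization moved radially outwards: their
radius is solved so the sampled spacing is realized against the adjacent
groove pair, and their ω0 is pitch-matched — the same azimuth advance per
Å of rise as the bundle — because copying ω0 verbatim at a larger radius
either leaves the pitch-angle domain or makes adjacent axes converge along
z.  Pitch-matching is always solvable (the relation runs through a
tangent, not a sine).

Acceptance applies exactly two structural gates: no Cα pair between
*non-adjacent* helices closer than the clash cutoff (4 Å), and no scaffold
Cα within the clash cutoff of the slot cylinder (radius 2.3 Å) — the
latter guarantees a clash-free dock of any helical target on the slot
axis.  Rejection is a value with a reason code, never an exception, and
the library records the average-distance draw of every attempt so the
sampling law can be audited against raw draws.  Because the slot gate
preferentially rejects tight bundles, the *accepted* candidates' mean
spacing sits ~0.2 Å above the configured mean; the draw record is the
unbiased quantity.

## Loop closure

Closure is geometric.  Connection plans enumerate all visit orders and
per-helix directions (reversal rebuilds the backbone along the reversed Cα
trace, preserving chirality), keep plans whose every junction gap is at
most loop_len_max·3.8 Å + 2 Å, and rank them by total gap.  Each junction
loop places its Cα atoms on a circular arc between the fixed termini with
arc length (L+1)·3.8 Å — reflex arcs are handled — trying several bulge
directions (radially outward first) and accepting the first whose steps
stay within [3.6, 4.0] Å and which sweeps no closer than 3.5 Å to the
scaffold.  Full backbone atoms are completed by the same ideal-template
fitting; helix Cα coordinates are preserved exactly, helix N/C/O likewise
except the junction-facing carbonyl/amide atoms, which take the chain-wide
build (and are snapped onto the bond vector at 1.329 Å where kinked
junction triplets would otherwise break the peptide bond).  The final
clash check covers only pairs involving loop residues: closure must not
*add* contacts, while helix–helix packing was already gated at sampling.

More supercoiled bundles spread their termini further apart and fail
closure more often; a seeded sweep over pinned |ω0| values shows the
failure rate rising monotonically (roughly 0.15 → 0.95 from 0.5°/res to
5°/res at default geometry).

## Peptide threading

Threading enumerates all registers × both orientations of a peptide on the
slot helix (offset ascending, parallel first).  Contacts use Cβ proxies
built from backbone N/Cα/C at ideal tetrahedral geometry (the standard
−0.5827·(b×c) + 0.5680·b − 0.5407·c construction; glycine falls back to
Cα).  A position scores if its residue is in {A,V,L,I,M,F,W,Y} and its
proxy lies within 8 Å of any scaffold proxy; both the set and the cutoff
are configuration, since neither is a measured constant.  Ranking is by
count descending with ties broken by offset then orientation.

## Interface metrics

* **Radius of gyration** — RMS distance of atoms from the unweighted
  centroid.  The normalized form divides by the radius of a sphere of
  volume n·V_res with V_res = 110 Å³ (a documented default for "volume
  related to the length"); a uniform ball then scores √(3/5) ≈ 0.775.
  The guiding-potential form returns the analytic gradient
  (x_i − centroid)/(N·rg), zero-sum by construction, with a cubic decay
  weight w0·(t/T)³ for denoising-style trajectories where t counts down
  from T (the potential matters most early, while the quaternary
  arrangement is still forming).
* **Distogram contact probability** — per (target, binder) pair the
  probability mass below 8 Å, with a straddling bin counted fractionally
  by linear interpolation; per target residue the maximum over binder
  residues (the per-pair aggregation is unspecified in the source
  procedure; max — "best single partner" — is the documented choice),
  averaged over target residues.
* **Interface pAE** — mean of both off-diagonal inter-chain blocks of the
  pairwise aligned-error matrix.
* **Shape complementarity (Sc)** — Lawrence–Colman statistic on dot
  surfaces: points sampled at 5 pts/Å² on van der Waals spheres, pruned to
  the solvent-exposed part, radial normals.  Interface patches are points
  within 1.5 Å of the opposing surface; each patch point scores
  exp(−0.5·d²)·(n̂_a·(−n̂_b)) against its nearest opposing patch point, and
  Sc is the mean of the two per-side medians.  The dot surface omits the
  reentrant (probe-rolled) part of the molecular surface, so absolute
  values on irregular surfaces carry a few hundredths of sampling
  uncertainty — hence the ±0.02 symmetry/invariance tolerance.
* **Contact molecular surface** — one-sided distance-weighted area: each
  binder-surface point contributes its represented area times
  exp(−d²/4 Å²), truncated at 5 Å, with d the gap to the partner surface.
  Linear in patch area by construction.
* **SASA** — Shrake–Rupley with a 1.4 Å probe and 960 test points/atom.

## Hallucination engine

The optimizer holds the target sequence fixed and anneals a binder of
fixed length (campaign lengths 60–100).  The seed sequence and all
replacement letters are drawn from the BLOSUM62 background amino-acid
frequencies.  Proposals mutate k distinct positions drawn from the
lowest-50%-pLDDT binder positions (ties included, so a flat profile makes
every position eligible; k shrinks if fewer are eligible); the eligible
set refreshes only after accepted steps, avoiding churn on rejects.  The
default schedule is 1250 steps × 3 mutations, 2500 × 2, 1250 × 1 — 5000
total — with temperature 0.01·2^(−step/500) and the Metropolis rule.

The loss folds maximized quantities as (1 − x) with documented
normalizations — pLDDT/100, pAE/31 Å — under relative weights
1 (pLDDT) : 1 (pTM) : 0.1 (rg) : 3 (contact) : 5 (interface pAE):

    L = 1·(1 − pLDDT/100) + 1·(1 − pTM) + 0.1·rg_norm
        + 3·(1 − P_contact) + 5·(pAE_inter/31)

Absolute loss values therefore depend on these normalizations; the
relative weights are the meaningful quantity.  The binder and target reach
the oracle as one sequence with the chain break encoded as a +32 jump in
the residue position index, applied only in the oracle adapter.

Two deterministic toy oracles make the optimizer fully testable offline.
`PlantedOracle` has a separable landscape whose unique optimum is a known
sequence (every tensor improves monotonically with per-position matches),
so global-optimum recovery is verifiable by per-position enumeration.
`HashOracle` derives tensors from a cryptographic hash of the sequence —
a rugged, memoryless landscape for mechanics and reproducibility tests.
What passing these tests shows: the annealer, schedule, bookkeeping and
loss plumbing are correct.  What they do not show: anything about real
structure-prediction landscapes, which are smoother and correlated;
plugging in a real predictor is exactly the oracle contract's purpose.

## Filtering

Gates compare metrics with {<, >, ≤, ≥} exactly as written — boundary
values fail strict gates — and failed records list every violated gate.
Gate application is composable (sequential subsets equal the union), and
ranking is a stable sort with ties broken by design id.  External metrics
(e.g. Rosetta ddG) are consumed as numbers, never computed here.

## Numerical choices and degenerate inputs

Backbone sanity: Cα–Cα steps in [3.6, 4.0] Å, peptide C–N in [1.2, 1.5] Å.
Axis fitting needs ≥ 4 residues and raises on collinear traces.  Empty
atom sets, empty inter-chain blocks, distograms with no bin edge below
8 Å, separated interfaces, and out-of-range schedule steps all raise typed
errors; sampling rejection and loop-closure failure are values.  All
randomness flows through seeded `numpy` generators; every sampled value is
recorded in candidate provenance, and full annealing runs are bitwise
reproducible per seed.

## Problem sizes

The test-suite and the reproduction script run the pipeline at desk scale:
libraries of 60–300 candidates, loop-closure sweeps of 25 candidates per
supercoil value, 10–20 annealing runs of the full 5000-step schedule
against the planted oracle, and 10⁴ Metropolis trials.  These sizes give
stable statistics for every property checked while keeping a full run in
minutes on one CPU; library-scale campaigns (10⁵ scaffolds) use the same
code paths unchanged.

## Known limitations

No side chains, hydrogens or energetics are modelled; scaffolds are
backbone-level poly-alanine.  Loop closure is arc interpolation, not
fragment- or kinematics-based, and makes no Ramachandran claim for loop
residues.  The dot-surface Sc/CMS implementations approximate the Connolly
surface (no reentrant patches), so absolute values are comparable between
structures scored by this package but may differ systematically from
implementations built on full molecular surfaces.  The accepted-library
spacing bias described above is inherent to rejection sampling against the
slot-clearance invariant.
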