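# Methods

This note records the models the package implements, the conventions and
defaults it chooses where the underlying experimental literature is silent,
and what its synthetic fixtures do and do not establish about real data.

## Coordinate conventions and the pore frame

All analyses work in a pore-aligned frame: the origin is the mass-weighted
centroid of the lower-gate selection (default `resid 394-398 and heavy`,
the S6 bundle crossing in HCN1 author numbering) and the +z axis points
from there toward the selectivity-filter selection
(`resid 358-361 and heavy`), i.e. extracellular. Author residue numbering
of the deposited model is authoritative throughout; nothing is renumbered.
Centroids use heavy atoms with standard atomic masses — cryo-EM models
carry no hydrogens, so including them would change nothing for real inputs;
a Cα-only gate centroid is available by passing `gate_expr="resid 394-398
and ca"`. As a sanity check the gate→filter axis is compared with the
principal axis of the combined selection and a warning is raised when they
disagree by more than 5° (a tetramer's pore axis should be close to both).

Alternate conformers collapse to the highest-occupancy copy (ties keep the
first listed), which makes structure reading deterministic.

## Inscribed-sphere pore profiling

At each z slice the profiler maximises the clearance
`f(c) = min_i (|c - x_i| - R_i)` over in-plane centres `c`. The maximiser
is simulated annealing (default 2000 steps, start temperature 1.0,
geometric cooling 0.995, fixed seed 0, all echoed into the output metadata)
seeded from the previous slice's centre, marching outward from the gate
plane in both directions, followed by a Nelder–Mead polish. The search is
confined to within 2 Å of the marching seed per slice; without this bound
the planar maximum escapes through the channel wall into bulk solvent at
wide or terminal slices. Slices with no atoms within 15 Å are reported at
the 15 Å bulk cap and flagged unconverged. On ring-pore fixtures the
profile agrees with the analytic inscribed radius, and with brute-force
planar grid search, to well below the 0.05 Å tolerance used in tests.

"Diameter" always means twice the inscribed-sphere radius (the
solvent-accessible-pathway convention), not an atom-centre distance.
Constrictions for a named residue are located as the nearest local radius
minimum within ±2 Å of the residue's side-chain centroid z (grid
boundaries count when they are one-sided minima; when no candidate exists
the window minimum is used). The window and all defaults are configurable.

Two radius sets ship: `simple` (C 1.85, N 1.75, O 1.65, S 2.00, P 2.10,
H 1.00 Å), the default, and `bondi` (C 1.70, N 1.55, O 1.52, S 1.80,
P 1.80, H 1.20 Å). Sub-Å agreement with any published gate diameter
depends on this choice, so validation output reports both.

## Permeation counting and conductance

Ion traces are the ion's pore-frame axial coordinate z(t) and radial
offset r(t). For coordinate trajectories the frame is rebuilt per frame
(the protein drifts), the projected z is unwrapped per ion across periodic
images, and r is the perpendicular distance to the axis.

A permeation event is a complete traversal: the three-compartment state
machine (above / pore / below, default interfaces ±18 Å — approximate
membrane boundaries, configurable and always echoed) only records an event
when an ion that entered the pore from one outer compartment reaches the
other. Entry thresholds are offset inward by a hysteresis (default 2 Å) so
that sub-threshold rattling can never create events; re-entries to the same
side and traversals still in progress at the trace end count nothing.
Counting is per-ion and independent — no knock-on pairing logic is
attempted, because event counts, not mechanisms, are the target.

Conductance is `g = N·e/(T·|V|)` per replica with
`e = 1.602176634×10⁻¹⁹ C`, summarised as the arithmetic mean across
replicas. The default spread is the population standard deviation: for the
worked example {5, 4, 6} events / 500 ns / 500 mV it gives
3.20 ± 0.52 pS, and a "±0.5" printed with such a mean is consistent with
this convention (sample SD would give 0.64, SEM 0.37; both are available
and labelled, since summary conventions are rarely stated).

For periodic-domain traces, `net_crossings` folds the unwrapped coordinate
back into the cell and counts signed traversals; the outer compartments
must be several step-displacements thick or boundary-jumping traversals are
missed (the helper's docstring states this).

## The Langevin trace generator

The generator abstracts an applied-field permeation simulation without any
MD engine: non-interacting cations follow overdamped dynamics
`z ← z + (D·F/kT)·dt + sqrt(2·D·dt)·η` in a periodic cell (default 140 Å,
matching the ~140 Å simulation-box height of the emulated design), with
the field force `q·V/span` acting only inside the membrane span (default
±18 Å) and an optional piecewise-linear intrinsic PMF. Defaults mirror the
emulated study conditions: −500 mV, 500 ns, K⁺ charge +1e, 298 K. The
diffusion constant defaults to the bulk K⁺ value 196 Å²/ns — a documented
stand-in, not a fitted quantity. kT uses R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹
(0.5922 kcal/mol at 298 K) and q·V maps 500 mV to 11.53 kcal/mol. The
stability bound dt ≤ 0.01·span²/D is enforced with a suggested dt in the
error message.

The returned `expected_crossings_per_ion` is the drift closed form
`v̄·T/L` with `v̄ = D·q·V/(kT·L)` (spatial average of the drift velocity).
Spatial and temporal averages coincide only when the force is uniform over
the domain; with the default narrow span, transport through the force-free
region is diffusion-limited and the value is a linear-response estimate
only. Flux-recovery tests therefore use a span covering essentially the
whole domain (99 of 100 Å at 26 mV), the regime where the closed form is
exact — that choice validates the counting machinery, not channel
energetics.

## PMF by Boltzmann inversion

`F(z) = -kT·ln(ρ(z)/ρ_ref)` over uniform z bins of the in-cylinder ion
density, zero-referenced to the mean over a stated window; empty bins are
masked, never imputed. By default no field-tilt correction is applied —
matching the common practice of directly inverting applied-field densities
— but a profile measured under a field is then a field-tilted profile, not
an equilibrium PMF. The optional linear correction removes the field term:
with the force convention above the field contributes `-q·V·(z-z_ref)/span`
to the tilted profile, so the correction adds `q·V·(z-z_ref)/span` back
(verified on Metropolis samples of a pure linear potential, whose corrected
profile is flat). Recovery tests use an independent Metropolis sampler of a
known double-barrier profile with flat 2 kcal/mol plateaus (plateaus avoid
bin-averaging bias at an apex); 10⁶ samples recover both barriers within
0.1 kcal/mol.

## Hydration, coordination, hydrogen bonds

Hydration is the mean count of water oxygens (resnames HOH/WAT/TIP3/SOL
families) inside an axial cylinder of default radius 12 Å, per z bin; bins
with mean < 1 are flagged dry to express wetting/dewetting. Coordination is
the count of water oxygens within 3.5 Å of the ion — near the first
K⁺–O radial-distribution minimum; no cutoff is universal, so it is a
parameter — and "waters lost" at a site is bulk mean minus site mean.

Hydrogen bonds use the common geometric criterion: donor–acceptor heavy
distance ≤ 3.5 Å and, when the donor carries a hydrogen, best D–H···A
angle ≥ 150°; hydrogen-free models (cryo-EM) fall back to distance-only
with a warning. Each bond is credited to both partner groups, so a closed
ring of hydroxyls each donating once averages 2.0 bonds per group. Any
published per-side-chain H-bond average depends on the unstated criterion
and crediting convention behind it, so such numbers are treated as
context, not as validation targets.

## Superposition, RMSD/RMSF, helix geometry

Superposition is the uniform-weight least-squares (Kabsch) transform over
atoms paired by (chain, residue, name); unmatched atoms raise a pairing
error rather than being dropped. The solver is cross-checked in tests
against a hierarchically refined orientation-grid search to 10⁻³ Å.
Trajectory frames align by default on the transmembrane-helix backbone
ranges (residues 140–166, 173–195, 209–242, 253–287, 297–324, 369–401).
RMSF is `sqrt(⟨|r_i − ⟨r_i⟩|²⟩)` after alignment, with an optional
chain-average over symmetry-equivalent residues matched by (resid, name);
mismatches are reported, not silently dropped. Isotropic σ-jitter recovers
RMSF = σ√3 within 2% at 10⁴ frames when the alignment selection is large
(a rigid-body fit absorbs ~6/(3N) of the variance, so small selections
bias RMSF low).

Helix segment axes are the principal component of one-turn-smoothed Cα
positions (4-residue moving average). Raw-Cα PCA carries a 2–3°
phase-dependent tilt on ~15-residue segments because the Cα spiral is not
symmetric over non-integer turn counts; smoothing collapses the spiral
onto the axis and recovers generated bends to <0.3°. The bend angle is
`arccos(axis_a·axis_b)` with both axes oriented N→C; segment boundaries
are caller-chosen (no automatic kink detection).

A residue is α-helical iff its available backbone dihedrals fall in
φ ∈ [−100°, −30°], ψ ∈ [−80°, −5°] AND it participates in an i→i+4
carbonyl–amide contact on either side (O(i)···N(i+4) or O(i−4)···N(i)
≤ 3.5 Å); residues lacking both i±4 partners use dihedrals alone, and
missing backbone atoms mark a residue indeterminate. Accepting the
acceptor-side contact is deliberate: a donor-only criterion marks the last
~4 helical residues before an unwound tail non-helical (their i+4 partners
are in the tail), overstating the unwinding; with both sides the generator's
tail length is recovered exactly for tails ≥ 2 residues. Non-helical run
lengths are also reported in helical turns (length/3.6). This is a
documented, configurable convention — published "unwound" assignments come
from model building, not a stated algorithm.

The helix generator builds backbones atom-by-atom from standard internal
coordinates (N–CA 1.458, CA–C 1.525, C–N 1.329, C=O 1.231 Å; τ angles
111.2/116.2/121.7°; ω = 180°) at (φ, ψ) = (−57°, −47°) helical or
(−120°, 130°) extended, then rigidly rotates the post-kink segment about an
axis through the kink Cα perpendicular to the pre-kink helix axis. A rigid
kink perturbs the junction residue's φ, so exact-unwinding fixtures use an
unkinked helix; bend-recovery fixtures use a kinked one.

## Boltzmann activation fits

`G/Gmax = 1/(1+exp((V−V½)/k))` by nonlinear least squares, Gmax fixed to 1
for normalized data (free-Gmax mode exists for raw tails).
Auto-initialisation: V½ at the sampled voltage nearest half-amplitude,
k = 8 mV. At least 4 distinct voltages are required; flat data raise a
degenerate-fit error. On the standard −20…−110 mV conditioning grid the
noiseless fit is exact and the V½ bias under 2% noise is <0.05 mV over
100 seeds.

## Synthetic data: what it does and does not establish

Every generator returns its ground truth with the data and is bit-stable
under a fixed seed. The fixtures establish algorithmic correctness:
geometry (ring pores, ideal helices), stochastic closed forms (free
diffusion MSD, drift flux, Boltzmann inversion), and counting logic. They
do not emulate protein flexibility, ion–ion correlations (the generator's
ions are non-interacting by design), explicit solvent, or force-field
physics — so passing tests demonstrate that the analyses measure what they
claim on data with known answers, not that any particular channel has a
particular conductance. Conclusions about real structures additionally
require the deposited coordinate files, which are not redistributed here;
the test that consumes them reports exactly what to download and where to
put it.

## Problem sizes and numerical choices

Default analysis scales were chosen to resolve each quantity comfortably:
pore profiles at 0.25 Å steps; flux recovery over 20 seeds × 6 ions ×
150 ns (2 SE criterion); PMF inversion at 10⁶ Metropolis samples in 0.5 Å
bins; RMSF closed form at 10⁴ frames; Boltzmann Monte-Carlo over 100
seeds. Ties in altloc occupancy keep the first conformer; empty selections
warn rather than fail; zero-count density bins are masked; annealing seeds
default to 0 and are always echoed in outputs, so identical configs and
seeds reproduce outputs byte-for-byte.

## Known limitations

- The profiler's confinement to 2 Å per marching step assumes a continuous
  pore; a pathway that jumps discontinuously between slices would need a
  larger `max_shift`.
- The event counter needs outer compartments thicker than typical per-step
  displacements; heavily subsampled traces can alias traversals.
- The PMF inversion assumes the sampled density is stationary; it performs
  no reweighting (no WHAM/umbrella estimators).
- Chain-averaged RMSF assumes symmetry-equivalent numbering across chains
  (true for C4 tetramers).
- mmCIF output uses a minimal atom_site representation; entity/assembly
  metadata are not preserved.
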