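# Methods

This note records the models, conventions and numerical choices behind
the package, and what the synthetic-data tests do and do not establish
about real trajectories.

## Backbone substate model

A dinucleotide step is BI when ε − ζ < 0 and BII when ε − ζ > 0, with
ε = C4′(i)–C3′(i)–O3′(i)–P(i+1) and ζ = C3′(i)–O3′(i)–P(i+1)–O5′(i+1),
both strands processed 5′→3′ and the step named after its 5′ residue.
The measure-zero boundary ε − ζ = 0 is assigned to BI; the choice is
arbitrary and documented rather than consequential.  Torsions follow
the IUPAC sign convention (cis = 0°, right-hand rule about the central
bond); ε and ζ are reported in [0°, 360°) and ε − ζ wrapped to
(−180°, +180°].

Free-energy profiles use Boltzmann inversion, F = −k_B T ln p, with
k_B = 0.0019872041 kcal/(mol·K), default T = 300 K and default 5° bins
over (−180°, 180°].  Occupied bins are anchored so min F = 0; empty
bins carry NaN, never 0.  Errors are standard errors of per-block F
over five contiguous frame blocks, each block anchored at the global
minimum bin so block offsets cancel.  Basin free energies integrate
raw counts on either side of 0° (not exp(−F) round trips), so
population and free-energy bookkeeping agree to machine precision.

Pooled population statistics default to a "central segment" of steps,
mirroring how central-sequence averages are formed for a 15-mer
(steps 6–9); the analysis drivers use the generator's steps 1–4 as
that segment.

## Interaction masking in parm7 topologies

The editor parses the %FLAG/%FORMAT parm7 dialect into an ordered
section map, interpreting only what it needs (pointers, names,
residues, charges, LJ tables) and carrying everything else verbatim —
bonded-term tables are never evaluated.  Charges are exposed in
elementary-charge units (file scale 18.2223).

Charge masking zeroes the methyl charges (C7, H71–H73) and applies a
per-residue redistribution map (atom name → increment in e).  The map
must balance the removed charge to 10⁻⁶ e; `balanced_redistribution`
builds an exactly balancing map at run time because published
force-field variants describe redistribution onto the demethylated
analog without printing values — shipped defaults are therefore
placeholders, and user maps override them.

vdW masking is per-pair: every atom type occurring in the methyl or
partner selection is duplicated into a fresh type, the full triangular
A/B coefficient table is rebuilt with the original values, and only
the methyl-partner cross entries are zeroed.  Because 1–4 scaled
interactions index the same type-pair tables, masked 1–4 vdW vanishes
too; bonded terms are untouched.  Re-applying a spec detects
already-zero cross terms and already-zero methyl charges and does
nothing, making masking idempotent.  Partner catalogs: all-water
(residues WAT/HOH), the 5′-neighbor sugar C2′/H2′/H2′′, or the
5′-neighbor base (non-backbone atoms).  10-12 hydrogen-bond pair types
are rejected rather than silently mishandled.

Validation checks pointer/section-length consistency, type-index and
coefficient-index ranges, NONBONDED_PARM_INDEX symmetry and finiteness;
the writer refuses invalid topologies.  The independent check on the
editor is a brute-force 12-6 evaluation (A/r¹² − B/r⁶) straight from
the raw sections, asserting exact zeros on masked pairs and ≤ 10⁻¹⁰
kcal/mol drift elsewhere; `mdtraj.load_prmtop` serves as the external
reference parser.

## Synthetic ensembles

`TwoStateBackboneModel` draws (ε, ζ) from wrapped Gaussians around
BI (190°, 265°) and BII (245°, 175°) centers — the canonical
trans/gauche⁻ vs gauche⁻/trans assignments; exact centers are free
parameters — with 12° widths.  Wrapped Gaussians were chosen over von
Mises because basin widths are ≪ 40°, where wrapping corrections are
negligible and the Gaussian mixture admits closed-form checks.

Substate labels form a binary chain with field probabilities p_j =
P(BII at step j) and a pairwise Gibbs factor exp(−κ) on adjacent
simultaneous BII.  Sampling is exact (backward transfer-matrix
messages, forward draws), so a two-step chain is exactly the 4-state
pair model used as the enumeration oracle.  Note that for κ > 0 the
*realized* marginals sit below the field p_j (the penalty removes
probability mass from BII–BII states); population-recovery checks
therefore use κ = 0, and the analysis drivers report realized
populations.

`HelicalMixtureModel` draws the six step parameters from a joint
Gaussian (defaults: means (0, 0, 3.38 Å, 0, 0, 36°), SDs
(0.5, 0.7, 0.3 Å, 3.5°, 6°, 7.2°), diagonal) and replaces twist with a
substate-conditional Gaussian — σ(BI) = 7.2°, σ(BII) = 6.2°, equal
36° means by default.  This reproduces the stiffening-by-BII
mechanism: with equal means the cumulative variance is the
population-weighted mixture variance, so raising P(BII) narrows the
cumulative twist distribution and raises the apparent twist stiffness.
A mixture with ~11% BII gives a cumulative σ ≈ 7.1°.

The generator emulates the statistical structure of backbone and
helical fluctuations — two-basin ε/ζ, neighbor anti-correlation,
conditional twist laws — but not their dynamics (no autocorrelation in
time, frames are i.i.d.), not α/β/γ/χ substates, and not
sequence-specific covariance beyond the configured parameters.
Passing tests demonstrate that the *analyses* are correct and
well-calibrated under these conditions; they do not re-derive any
MD-based result.

## Idealized duplex builder

Bases are planar templates in a base-fixed standard frame (C1′ at
(−2.477, 5.402, 0), glycosidic N at (−1.291, 4.498, 0)); purine and
pyrimidine ring geometries are shared across bases and exocyclic
substituents are placed on exterior bisectors.  Base pairs stack by
per-step twist/rise about the global z axis; strand II is the
complementary template rotated 180° about x, which makes the strands
antiparallel and chemically equivalent (residue j of chain B pairs
with residue N+1−j of chain A, both chains numbered 5′→3′).

Each nucleotide carries a deoxyribose built by a Cremer–Pople
construction (planar pentagon plus out-of-plane displacements) whose
phase offset is solved numerically so the measured
Altona–Sundaralingam phase hits the preset (C2′-endo 162° by default,
C3′-endo 18° available) — the solve is cached per (phase, amplitude).
The backbone is attached by internal coordinates; the free torsion set
(χ = −67.5°, γ = 29.7°, β = 141.6°, δ = 93.9°, plus the exocyclic C5′
placement) was calibrated once by least squares against four targets —
ε = 190°, ζ = 265° (the BI basin), O3′–P junction distance 1.60 Å and
tetrahedral junction angles — under soft fiber-B priors, then frozen
as the package default.  The calibrated geometry yields ε − ζ ≈ −75°
uniformly, a closed backbone, a methyl-to-C2′(5′-sugar) distance of
~3.6 Å, and an unformed H6···O3′ contact, i.e. a self-consistent BI
conformation.  The builder's closure guarantee covers the rigid-body
step parameters (twist 20–40°, rise 3.0–3.6 Å re-measured exactly,
because measurement fits the same base templates); backbone torsions
beyond ε/ζ are idealized, not fiber-exact.

## Helical mechanics

Base frames are fitted by Kabsch superposition of the template ring
atoms; pair frames average the two base frames after flipping strand
II's y/z axes, with SVD re-orthonormalization.  Step parameters follow
the mid-frame construction: the bending angle Γ between pair z axes is
split symmetrically about the hinge, twist is measured between the
unbent x axes, roll/tilt are Γcos φ / Γsin φ with φ the hinge phase
from the mid-frame y axis, and shift/slide/rise are the origin
displacement in mid-frame coordinates.  Twist is right-handed
positive.  The exact inverse (`step_rotation`) reconstructs the
relative rotation from (tilt, roll, twist) and is verified by round
trip to 10⁻⁸ degrees.

Segment aggregation: segment twist = mean step twist; segment stretch
= mean step rise; segment bend = angle between the base-pair normals
bounding the segment, computed from fitted frames when available and
otherwise by composing the per-step rotations (the two paths agree
exactly on constructed geometry).  These scalar definitions are
deliberately isolated behind the aggregation operator so alternatives
can be swapped.

Stiffness: K = k_B T C⁻¹ with C the sample covariance (ddof = 1);
units propagate per element (kcal/mol/deg², kcal/mol/Å², and mixed
off-diagonals).  A covariance condition number above 10¹² raises with
a diagnostic rather than returning a garbage inverse.  The default
segment variable set is (twist, stretch, bend); per-step 6×6 analysis
uses the same operator.  Relative changes are reported mode-wise,
100·(K_mod − K_ref)/K_ref on the diagonal, alongside equilibrium-mean
changes.

Gaussianity diagnostics guard the harmonic premise: a 2-vs-1-component
Gaussian-mixture BIC contrast (flagging only when ΔBIC > 10 *and* the
components separate by > 1 pooled SD — calibrated to < 5% false
positives on Gaussian input) plus skew/kurtosis normality z-scores and
a degenerate-variance flag.

## Geometry analyses

Pseudorotation uses the Altona–Sundaralingam five-torsion formula,
tan P = ((ν4+ν1)−(ν3+ν0))/(2ν2(sin 36° + sin 72°)), amplitude
τ_m = ν2/cos P, phase wrapped to [0°, 360°); near-planar rings
(amplitude < 1°) return NaN phase.  Weak C–H···O hydrogen bonds
default to H···O ≤ 2.7 Å, C···O ≤ 3.5 Å and C–H···O angle ≥ 120° —
weak-donor literature values, configurable, since the detection
thresholds are not themselves part of the masking methodology.
Hydrogen positions are taken from the input coordinates; no hydrogens
are rebuilt.  Methyl centers are mass-weighted (C 12.011, H 1.008)
with an unweighted option for sensitivity checks.  Density maps are
joint histograms normalized to total mass 1, whose marginals equal the
1-D histograms by construction.  Conditional pucker statistics use
circular means and block-resampled errors.

## Pipeline and determinism

A run is a two-condition comparison (reference vs modified), because
every headline quantity of the masking methodology is a difference
between such runs.  All randomness derives from one run seed through
`numpy.random.SeedSequence`; per-condition seeds stay below 2³¹.
Reports store populations, ΔG/ΔΔG, conditional twist statistics and
stiffness diagonals, plus a provenance block (seed, config digest,
version), and every report number is recomputable from the stored
CSVs.  Re-running a config with the same seed reproduces byte-identical
artifacts.

## Problem sizes

Statistical checks use 10⁵ frames for population/σ recovery and 10⁶
samples for free-energy profile and ΔΔG accuracy — sizes at which
binomial/χ² sampling error sits comfortably inside the asserted
tolerances (e.g. the ΔΔG standard error at 10⁶ samples is
≈ 0.007 kcal/mol against a 0.1 kcal/mol band).  The analysis drivers
use 4 steps × 2·10⁴ frames per condition, enough for ~0.1–0.2
percentage-point population errors.

## Known limitations

- The prmtop editor supports the standard parm7 dialect without
  CHAMBER extensions or 10-12 hydrogen-bond terms.
- Redistribution defaults are placeholders; faithful demethylated-
  analog charge sets must be supplied by the user.
- The duplex builder is idealized: correct topology, pucker and BI
  backbone, but not a refined force-field geometry; it supports
  per-step twist/rise, not roll/slide targets.
- Synthetic frames are temporally uncorrelated, so transition/dwell
  statistics on generated data exercise bookkeeping, not kinetics.
- Segment bend/stretch scalar definitions are package choices among
  several reasonable ones and are isolated for substitution.
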