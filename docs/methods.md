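# Methods

`spisim` simulates a single-particle imaging (SPI) experiment at an X-ray
free-electron laser from end to end, at a scale that runs on one desk-class
CPU: stochastic SASE pulses, per-atom radiation damage, time-integrated
noisy diffraction on an ideal photon-counting detector, orientation recovery
with expand–maximize–compress (EMC), and a run-to-run consistency metric
σ_v over independent EMC reconstructions.  This note records the models,
their assumptions, the parameters that matter, and the choices made where
the design was genuinely open.

## SASE pulse emulator (`spisim.pulse`)

SASE radiation is chaotic light: the temporal intensity is a train of random
spikes of width the coherence time under a smooth envelope, fluctuating shot
to shot.  We use the standard partial-coherence model: complex white
Gaussian noise, filtered with a Gaussian kernel whose width is set by the
coherence time (default 0.25 fs, the order of the SASE coherence time near
5 keV), multiplied by a Gaussian amplitude envelope of the nominal FWHM, and
squared.  Each pulse is renormalized so its trapezoid integral equals the
nominal photon number exactly; the working settings are 1×10¹¹, 5×10¹¹ and
1×10¹² photons at 3, 9 and 30 fs and 4.96 keV.  The time grid spans three
times the FWHM (matching the damage-simulation window) with 100 samples by
default.

Consequences of these choices:

* the *shape* fluctuates shot to shot (spike positions, heights) but the
  *pulse energy* does not — per-pulse renormalization pins it;
* instantaneous intensity statistics are near-exponential
  (variance/mean² ≈ 1 at fine sampling), the signature of a chaotic source;
* the ensemble mean converges to the Gaussian envelope.

Spectral fine structure, wavefront curvature, pointing jitter and hit
statistics are out of scope; every molecule is assumed fully exposed to the
brightest part of the focus.

**Fluence calibration.** The focal spot is a free parameter of the study
conditions (it is not fixed by the pulse parameters).  `BeamConditions`
converts photons per pulse to fluence via the effective area 2πσ² of a
Gaussian focus.  The default focus FWHM is 200 nm, chosen once so that with
physical photoabsorption cross sections the 3 fs / 1×10¹¹-photon setting
reproduces the reference damage levels — heavy-species (S, Fe) ionization
below 30% and sub-0.1 Å mean displacement — and not revisited.  This gives
a 3 fs fluence of ≈2.2×10⁴ photons/Å².  The focus is recorded in every run
manifest.

## Sample handling (`spisim.sample`)

Structures are element symbols plus coordinates, recentred on the centroid
so rigid rotations act about the sample centre.  PDB input goes through
gemmi; occupancies and B-factors are ignored and alternate locations keep
conformer A (single-model scattering target).  Hydrogens are kept when
present (flag to drop).  Solvent is ignored throughout.

Because tests must not download structures, `generate_pseudo_protein`
builds a synthetic stand-in: atoms uniform in a sphere with a 1 Å minimum
pair distance and protein-like non-hydrogen stoichiometry
(C 0.55 / N 0.15 / O 0.25 / S 0.04 / Fe 0.01 by default, an iron–sulfur
protein flavour).  The standard desk-scale fixture is 500 atoms in a 20 Å
sphere; a ~4400-atom, 32 Å variant emulates a small-protein target.  What
the pseudo-protein does *not* reproduce: covalent geometry, secondary
structure, realistic pair correlations — so speckle statistics are those of
a random cloud, not a folded chain.  All damage and orientation conclusions
here are about counting statistics and kinetics, which survive that
simplification; absolute speckle contrast does not.

Random orientations use the Shoemake subgroup construction (uniform on
SO(3)); quaternions are scalar-first with the q ↔ −q ambiguity resolved to
a non-negative scalar part.

## Radiation-damage emulator (`spisim.damage`)

This module is a declared emulator of an atomistic MD damage code, not a
reimplementation: electrons are counts, not particles, and ion motion is
mean-field.  Per fine time step (snapshot spacing / ≥10, refined
automatically so no per-step event probability exceeds 0.05):

* **Photoionization**: probability σ_ph·(z/Z)·Φ(t)·Δt per atom, with
  bundled subshell-summed cross sections at 4.96 keV and the neutral cross
  section scaled by the bound fraction z/Z for ions.  A single inner-shell
  hole per atom is tracked; a new hole cannot form until the previous one
  relaxes.  (Fe's K edge lies above 4.96 keV, so its large cross section and
  0.55 fs lifetime describe L-shell ionization.)
* **Auger relaxation**: each hole decays after an exponentially distributed
  delay with the species lifetime (O 4.9 fs, C 10.7 fs anchors), ejecting a
  second electron.  With the Auger channel disabled, holes relax instantly
  without emission (radiative limit) — this gives the exact rate-equation
  chain used as a unit-test oracle.
* **Escape vs trapping**: an ejected electron escapes if its kinetic energy
  (per-species photo/Auger energies; 20 eV for secondaries) exceeds the
  Coulomb barrier e²·Q_net/R of the currently escaped charge at the sample
  radius; otherwise it joins the trapped cloud n_free.
* **Impact ionization**: trapped electrons drive further ionization with
  rate k·n_free·z per atom.  k is the emulator's single calibration
  parameter; its default 3×10⁻⁶ fs⁻¹ was set once so a 30 fs run on the
  ~4400-atom sample strips carbon to ≈50%, the qualitative reference
  behaviour, and then left alone.
* **Coulomb expansion**: ions feel a radial mean-field force from the net
  enclosed charge (ion charge inside their radius minus the enclosed share
  of the trapped cloud, softened at 1 Å), integrated with velocity-Verlet.

Charge is conserved exactly (Σ(Z−z) = trapped + escaped at every snapshot);
trajectories store 100 snapshots over three FWHM.  Not modelled:
recombination, explicit electron dynamics, plasma temperature, the
crystalline environment.  The trapping threshold scales with sample radius,
so damage levels on the 500-atom fixture are *milder* than on a real-size
sample at the same fluence — fixture-based bounds are conservative for
ionization avalanches.

The displacement summary averages |Δr| by default (RMS by flag): which
average the reference plots used is not stated, and the choice only shifts
curves by a few tens of percent.

## Diffraction (`spisim.diffraction`)

Pixel q-vectors live on the Ewald sphere, q = k(ŝ−ẑ) with
|q| = 4π sin(θ)/λ; solid angle is pixel_area·cos³(2θ)/L² and the Thomson
cross section carries a linear-horizontal polarization factor 1−(x/r)².
The working detector is 80×80 pixels of 1200 µm at 130 mm, beam centre
between the four central pixels; the mid-edge half-period resolution π/|q|
is 3.6 Å.  The expected count in pixel j sums over trajectory snapshots

    n0_j = Σ_i Φ(t_i)Δt · r_e²·P_j · [|F(q_j,t_i)|² + S(q_j,t_i) + N(t_i)] · ΔΩ_j

with F the coherent sum of neutral Cromer–Mann form factors scaled by
z/Z (exact q→0 electron count for ions), S = Σ z(1−(f/Z)²) the
one-parameter bound-incoherent approximation (swappable; tabulated
incoherent scattering functions would be the refinement), and N the flat
contribution of the *trapped* electrons only — escaped electrons have left
the interaction region.  Compton wavelength shift is ignored (counts, not
energy-resolved).  Poisson noise is applied per pixel.

Numerical choices: the per-pattern phase factors exp(iq·r) are cached
between snapshots and recomputed only when an atom has moved more than
0.1 Å (worst-case phase error ~0.1 rad at the detector edge; a tolerance of
0 forces exact evaluation).  When snapshots are strided for speed, each
retained snapshot carries the pulse fluence *integrated* over its stride
window, so the spiky SASE profile is never aliased; only the slowly varying
damage state is subsampled.  Desk-scale runs use every 10th snapshot, which
reproduces full-grid patterns to ~0.1%.

## EMC orientation recovery (`spisim.emc`)

Rotations are discretized by barycentric subdivision of the 600-cell:
level n gives 10(5n³+n) rotations (60 at level 1) with uniform quadrature
weights.  The diffraction volume is an 81³ cubic grid (for the default
detector) with voxel spacing equal to the small-angle pixel q-increment;
pixels whose rotated q falls outside are clamped and counted.  Expand is
trilinear interpolation along each rotated Ewald slice (indices and weights
precomputed once per geometry+level); maximize uses the Poisson
log-likelihood with log-sum-exp stabilization and tomogram flooring at
1e-10; compress scatters tomograms back with the transpose interpolation,
each tomogram weighted by the posterior mass its rotation collected (so
empty rotations do not dilute the model), followed by Friedel
symmetrization.  No per-pattern fluence scaling is applied inside EMC — the
photon-count rescalings are explicit analysis steps.  Iteration stops when
the relative RMS voxel change stays below `tol` (default 1e-3) in two
consecutive iterations.

Sparse CSR pattern algebra is used automatically below 25% pixel occupancy.
Because the global orientation of an EMC volume is a gauge freedom,
volume comparisons first align over the rotation set and then polish with a
continuous local search; the discrete search alone leaves up to half an
angular gap (~0.1 rad at level 3) of residual misorientation, which caps
correlations near 0.9 on structured volumes.

Known limitation: with the interpolation pair, expand∘compress is not
exactly idempotent, so even noiseless degenerate inputs take a few extra
sweeps to relax; the likelihood is monotone for the pure EM update and, in
practice, for the full loop after the first iterations.

## Consistency metric and rescalings (`spisim.metrics`)

σ_v: per voxel, the RMS deviation of the N run intensities about their mean
(1/N population convention — it is a figure of merit, not an estimator;
flag for 1/(N−1)), normalized by the mean, then averaged over voxels of
each resolution shell (default width: one pixel q-increment).  Zero-mean
voxels are excluded and counted; the per-shell RMS spread of the voxel CVs
supplies the error bars.  Volumes are rotationally pre-aligned to the first
run by default (the reference computation's choice is unknown; both
behaviours are implemented and recorded in the report).  σ_v = 0 means
identical runs; values near 1 mean run-to-run variation as large as the
signal (for reference, N independent exponential intensities give ≈0.9 at
N = 5 — the estimator's finite-N expectation — saturating to 1 as N grows).

The two rescaling experiments mirror the reference analysis: a single
global factor matching the mean total photon count, and per-pattern factors
s_d = [μ_t + (c_d−μ_s)·σ_t/σ_s]/c_d matching mean and centred RMS of the
totals simultaneously.  Both operate on the Poissonized counts.  Mid-pulse
for the bound-electron summary is the intensity-weighted median time,
robust for asymmetric SASE profiles.

## Orchestration and problem sizes (`spisim.pipeline`)

The default configuration mirrors the reference ensembles — 40 pulses × 25
trajectories = 1000 damage runs, 200 patterns per trajectory (each with a
fresh uniform rotation and noise seed, reusing its trajectory's pulse), 5
EMC runs.  Tests and the acceptance script run reduced ensembles as the
package's standard desk-scale setting: damage statistics on the 500-atom /
20 Å fixture; the pulse-duration comparison on a 1500-atom / 28 Å fixture
with 5 pulses × 5 trajectories × 50 patterns per duration, a 40×40
detector of 2400 µm pixels (same q-range and edge resolution as the full
80×80 geometry at half the sampling rate — the 56 Å sample's speckles stay
oversampled ~2.4×), snapshot stride 10, and EMC at level 2 with up to 50
iterations, 4–5 runs per condition.  The fixture size is chosen so the
per-pattern detected photons sit in the reference regime (≈7 at 3 fs, ≈32
at 9 fs, ratio ≈4.7).

At this scale the comparison reproduces, and the tests assert, that
σ_v(3 fs) lies above σ_v(9 fs) across resolution shells and that the
mean-only count rescaling of the 3 fs patterns leaves their σ_v above the
9 fs curve.  One full-scale behaviour does *not* carry over: with ~10³
patterns the 3 fs data do not pin pattern orientations, so rescaling the
counts (which only sharpens the Poisson posteriors) makes independent EMC
runs diverge rather than reconciling the 3 fs and 9 fs curves — at the
reference's 2×10⁵-pattern scale the volume is overdetermined and σ_v is
governed by posterior sharpness alone, which rescaling does emulate.  The
corresponding mean+rms check is kept in the suite at its full-scale
expectation and fails at desk scale; absolute σ_v magnitudes are reported,
not asserted.

Seeding is counter-based: a master seed spawns per-stage, per-item
`SeedSequence` streams recorded in the manifest, so reruns are
bit-identical and stages are independently reproducible.
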