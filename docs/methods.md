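# Methods

`memhairpin` re-implements, as a tested library plus analysis drivers,
the computational characterisation of how an ESCRT-III-type α1-3
helical hairpin binds PC/PG lipid membranes: contact-based binding
detection and kinetics, per-residue occupancy with bootstrap intervals,
binding-state-conditioned conformational observables, Laurdan-GP/Hill
affinity fitting, and surface-coverage arithmetic.  Because no
trajectories or raw fluorescence curves are available to ship, every
stage runs on synthetic inputs with known ground truth; this note
records the models, the defaults and why, and what the synthetic data
do and do not establish.

## Contact definition and binding kinetics

A contact is a (protein heavy atom, membrane heavy atom) pair within
**0.4 nm**, with minimum-image wrapping in x,y only (membranes are
z-oriented slabs; z stays unwrapped).  Ties at exactly the cutoff count
(closed boundary).  The per-frame pair count deliberately does not
deduplicate multiple membrane partners of one protein atom; per-residue
analysis instead uses the boolean "any contact" flag.  Neighbour search
uses a periodic KD-tree; an all-pairs loop is kept alongside purely as a
test oracle, and integer equality between the two routes is asserted on
randomized configurations.

Binding is *sustained* contact: a run of frames with ≥ **5** contacts
lasting ≥ **5 ns** switches the state to bound at the run's first frame;
after a binding event, a run with < 5 contacts lasting ≥ **0.5 ns**
switches to unbound at its first frame.  Trajectories start unbound and
unbinding can only follow binding.  A run of k frames is counted as
k·dt of time; this convention (rather than (k−1)·dt) is configurable in
principle but fixed here, and it makes the 0.5 ns unbinding dwell equal
to one frame whenever dt ≥ 0.5 ns.  The first-binding time is the time
of the first frame of the qualifying run.  These thresholds are
intentionally conservative — transient touches are not binding events —
and the two-state reading ignores partial attachment.

## Occupancy and the BCa bootstrap

A residue's fractional occupancy is the fraction of analysed frames in
which it has at least one membrane contact.  Replicas are the
statistical unit: occupancies are computed per replica and averaged,
and the 95% confidence interval comes from a bias-corrected accelerated
(BCa) bootstrap with 1000 resamples **over replicas** — frames are
autocorrelated, so resampling frames would understate the error.  A
pooled variant (all frames divided together) is available for unequal
replica lengths.  The BCa interval itself is SciPy's; degenerate input
(all replica values equal) short-circuits to a zero-width interval, and
an undefined acceleration (all jackknife values equal) falls back to
the plain percentile interval with a logged notice.  A Monte-Carlo
experiment (Normal(0,1), n = 20, 500 repetitions) keeps empirical
coverage of the mean near the nominal level; the acceptance band
[0.91, 0.985] reflects the known small-sample anti-conservatism of BCa.

## Essential-dynamics PCA

PCA runs on backbone (N, CA, C, O) atoms of the analysed residue span
with the mobile C-terminal tail excluded (fragment bookkeeping:
residues 26–156, PCA span 26–151 for the full-size fragment).  Frames
are superposed by Kabsch's SVD method (reflections corrected by a sign
flip of the smallest singular direction) onto an iteratively refined
mean structure — refit until the mean moves < 1e-6 nm RMSD — then the
covariance of the 3N fitted coordinates is diagonalized.  A single-pass
fit to the first frame is available.  Eigenvector signs follow the
largest-magnitude-component-positive convention so projections are
reproducible.  Projections superpose each new frame on the model mean
before centring and dotting with the eigenvector, so training
projections have zero mean and variance λ_k exactly.

The synthetic trajectories are rigid-body motion plus isotropic
per-atom jitter, so their PCA spectrum is nearly flat: PC1 carries well
under 1% of the variance at desk scale.  That is the correct answer for
this generator, not a defect — the generator has no internal collective
mode, and the PC1-dominated spectra seen on real conformational
ensembles (tens of percent) are not reproducible from it.  The PCA
machinery is instead validated against dense/sklearn decompositions and
exact rank/trace identities.

## Helix assignment

Helicity is Kabsch–Sander α assignment, re-implemented rather than
shelled out: a backbone hydrogen bond CO(i)→NH(j) exists when

    E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) < −0.5 kcal/mol

with distances in Å; any distance below 0.5 Å is treated as a clash
(bond assigned), prolines and chain-initial residues never donate, and
a missing amide H is reconstructed 0.1 nm from N along the preceding
residue's O→C direction.  Two consecutive i→i+4 turns (at i−1 and i)
make residues i..i+3 α-helical; only class α counts as "helical" by
default, with 3₁₀ and π available as switches because reference DSSP
tools differ in what their helical tally includes.  On an ideal
poly-alanine helix the count matches mdtraj's DSSP exactly (18 of 20
residues); on irregular structures small differences from other DSSP
implementations are expected.

## SASA

Shrake–Rupley with a 0.14 nm probe: for each atom, the fraction of 960
Fibonacci-lattice points on the probe-expanded sphere not buried inside
any neighbour's expanded sphere, times the sphere area.  Radii are
Bondi (C 0.170, N 0.155, O 0.152, S 0.180, H 0.120, P 0.180 nm);
GROMACS-family tools use different radii tables, so absolute values
differ by a few percent between implementations — the quantities used
downstream are internal comparisons (bound vs. unbound), which are
insensitive to the table.  Quadrature accuracy is checked against the
closed forms for an isolated sphere and for two overlapping equal
spheres (≤1% error at 960 points).

## State-conditioned distributions

Per-frame observables (PC1 projection, helical count, total and
per-residue SASA) are split by the bound/unbound label and summarised
with Gaussian KDEs under Scott's rule; the helical-count summary uses a
bandwidth multiplier of 2 because integer counts under-smooth.  An
empty partition yields no KDE and is flagged rather than an error.

## Synthetic data: what is emulated, and what is not

* **Structures.**  Ideal helices are built by internal-coordinate (NeRF)
  chaining with standard backbone geometry (N–CA 0.1458, CA–C 0.1525,
  C–N 0.1329, C=O 0.1231 nm; φ = −57°, ψ = −47°, ω = 180° by default);
  recomputing dihedrals from the coordinates returns the inputs to
  1e-4°.  The hairpin is two antiparallel ideal helices at 1 nm lateral
  offset joined by a crude extended loop — a topology fixture, not a
  model of the real fold.  The membrane is a jittered square lattice of
  pseudo-lipids at 0.75 nm² per head group, three head beads at the
  surface plus tail beads below, with PG lipids assigned by seeded
  shuffle.
* **Binding dynamics.**  The peptide is rigid, laid flat, and performs
  overdamped Brownian motion in z (Euler–Maruyama, 50 substeps per
  0.1 ns frame, D_z = 0.05 nm²/ns) in a flat-bottomed super-Gaussian
  surface well U(g) = −depth·exp(−((g−0.08)/0.10)⁴) (g = gap above the
  head groups, nm), with reflecting walls at g = 0.05 and at a 2.2 nm
  ceiling, plus 0.02 nm per-atom jitter.  The shape matters: inside the
  well the peptide diffuses freely across the contact-rich zone
  (g ≲ 0.2 nm, where the pair count stays above the binding threshold),
  and leaving costs the full depth, so the mean residence time scales
  like exp(depth/kT)·w²/D ≈ 0.2 ns·e^(depth/kT).  At 0 kT residence
  (~0.2 ns) never reaches the 5 ns dwell; at 2 kT it does occasionally;
  at 5 kT nearly every approach binds.  PG composition enters only as a
  multiplicative well depth (depth × PG fraction), mirroring the
  monotone charge dependence without any electrostatics.  Replicas are
  released 2 nm above the membrane, as in the emulated setup, and run
  200 ns (2000 frames); 20 replicas per condition give 4 μs cumulative
  sampling per composition.  The numbers D_z, ceiling and well geometry
  were fixed once from these residence/arrival-time estimates so that
  the three depths separate kinetically within a 200 ns run.
* **Abstract kinetics.**  A two-state Markov chain with Poisson contact
  counts per state provides exact latent ground truth for the state
  machine; in the well-separated regime (μ_bound ≥ 15, μ_unbound ≤ 1,
  dwells ≫ thresholds) frame-label recovery exceeds 95%.
  Over-dispersed counts are out of scope.
* **Binding curves.**  GP values follow the Hill model over the
  0.125–16 μM doubling series with additive Gaussian noise; noise-free
  curves refit to 1e-6 relative.

Passing tests on these generators demonstrate that the *analysis* is
correct under known truth; they do not demonstrate anything about real
bilayer chemistry, peptide flexibility upon binding, or absolute
affinities.

## Spectroscopy conventions

GP = (I440 − I490)/(I440 + I490); intensities at 440/490 nm are the
nearest sampled wavelength within ±1 nm, else linearly interpolated.
Emission spectra are normalized to the mean lipid-free (apo) intensity
over 333–337 nm inclusive.  Hill fits are unweighted nonlinear least
squares (replicate-weighted optional) with initialisation GP0 = first
point, ΔGP = signed range, K_D = geometric-median concentration, n = 1,
bounds K_D > 0 and n ∈ [0.25, 8]; n can be fixed, since published fits
do not always float it.  Fits flag rather than raise: fewer than 5
points, unresolved amplitude, K_D outside the measured range, K_D
standard error above 100%, or optimizer failure all set
`low_confidence`.  Thermal melts map ellipticity at 222 nm affinely to
−1 at 20 °C and 0 at 96 °C, anchors taken at the nearest measured
temperatures.

## Coverage arithmetic and RSA

The footprint calculation rounds per leaflet and then multiplies by the
leaflet count (10×2/0.75 = 26.67 → 27 → 54), matching the convention of
the printed pair; the exact value is always co-reported.  The RSA
simulator inserts rectangles at uniform random positions (and
orientations, unless axis-aligned) into a periodic square box,
rejecting overlaps by a separating-axis test against minimum-image
displacements, with a spatial hash for neighbour lookup and a
consecutive-failure stopping rule.  Axis-aligned unit squares reach the
known jamming coverage ≈ 0.562 from below as the failure threshold
grows.  The simulator is exploratory: the ≈20% literature figure for
3:1 rectangles comes from an adsorption model, not plain RSA jamming,
so no equality with it is asserted anywhere.

## Problem sizes and numerical choices

Desk-scale defaults throughout: a 14+4+14-residue hairpin over a 12×12
slab, 200 ns replicas at 0.1 ns frames, 8 replicas for occupancy, 4 for
PCA, SASA on 50 subsampled frames at 96 sphere points (960 for
accuracy checks).  Degenerate inputs are explicit: zero-variance PCA
sets a flag and projection raises; empty atom selections warn (contact
selections error, since a contact count without atoms is meaningless);
equal melt anchors and zero GP denominators raise.  All generators are
pure functions of (spec, seed) via `numpy.random.default_rng`; the same
seed reproduces trajectories bitwise.

## Known limitations

Rigid-body dynamics cannot show binding-induced unfolding or hairpin
bending; the membrane is static and chemistry-free; orientational
diffusion of the peptide is reduced to a fixed flat initial orientation;
PBC handling is orthorhombic x,y minimum image only; and K_D values
from real titrations depend on curve quality in ways the clean
synthetic curves only partially emulate (the noise-calibration test
tracks this at one noise level).
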