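# Methods

This note documents the models, estimators and numerical choices behind
`dnarelay`, in the order a user meets them: the Brownian-dynamics engine,
the trajectory analysis, the elasticity and kinetics estimators, the
cell-level quantification, and the synthetic-data generators that stand in
for the microscopy and plate-reader raw data.

## The physical picture

During chromosome segregation in *Caulobacter crescentus*, the ParB/*parS*
partition complex is translocated from near midcell to the new pole.  ParA-ATP
dimers bind nonspecific chromosomal DNA; ParB, concentrated several hundred
micromolar inside the partition complex, stimulates ParA ATP hydrolysis on
contact, releasing the dimer from the DNA.  Because the chromosome is an
elastic medium, a DNA-bound dimer is not static: it fluctuates around a tether
point with the amplitude of the underlying chromosomal locus.  The DNA-relay
hypothesis is that a fluctuating dimer captured by the complex in a stretched
state pulls the complex toward the dimer's anchor; since free dimers
preferentially rebind DNA on the new-pole side of the complex (the observed
intracellular ParA gradient), successive capture-pull-release cycles relay the
complex poleward without any filament or motor.

## Brownian-dynamics engine (`dnarelay.bd`, `dnarelay._kernels`)

**Geometry and agents.** The cell is a reflective 2-D rectangle
`[0, l0] x [-w0/2, w0/2]` (default 2.5 x 0.4 um), old pole at x = 0.  The
partition complex is a disk of radius `R_PC` = 50 nm; ParA-ATP dimers are
disks of radius `R_ParA` = 2 nm.  A run starts with the complex at
(0.8, 0) um and all `n_ParA` = 90 dimers DNA-bound, anchors drawn from the
rebinding density below.

**Integrator.** Positions advance by the second-order overdamped scheme

    x(t+dt) = x(t) + R0 + (D/kT) F dt + (D^2/2(kT)^2) F F' dt^2 + (D/kT) F' R1

with the correlated Gaussian pair Var(R0) = 2 D dt, Var(R1) = (2/3) D dt^3,
Cov(R0 R1) = D dt^2, sampled via the conditional law R1 | R0 = (dt/2) R0 +
sqrt(D dt^3/6) Z.  Forces are per-axis harmonic restoring forces
F = -k_sp (x - x_eq), F' = -k_sp, with k_sp/kT = 1/sigma^2 per axis
(sigma_long = 0.06 um along x, sigma_short = 0.04 um along y).  Only the
ratio k_sp/kT enters the dynamics; the absolute temperature (default 303 K)
matters solely when forces are reported in pN.  With the restoring sign the
scheme reproduces the exact Ornstein-Uhlenbeck propagator coefficient
1 - th dt + th^2 dt^2/2 (th = D/sigma^2), and its stationary distribution
matches the Boltzmann Gaussian to O(dt^3) — the integrator-validation tests
check the noise covariance, the free-diffusion MSD slope, and the stationary
density (KS test) directly.

**State machine.** A dimer is `dna_bound`, `pc_bound`, or `free`:

* capture: a DNA-bound dimer whose center comes within `R_PC + R_ParA` of the
  complex center is captured immediately (boundary contact counts);
* release: a captured dimer is released by ParB-stimulated hydrolysis after an
  exponential dwell of mean `1/k_cat` (default 33.3 s; drawn at capture, so
  the statistics are independent of dt);
* rebinding: a free dimer rebinds DNA after an exponential wait of mean
  `tau_db` (default 1/0.03 s) at a position drawn from the linear density
  P(x) = 2 (x - x_PC)/(l - x_PC)^2 between the complex and the new pole
  (inverse CDF `x_PC + (l - x_PC) sqrt(u)`), uniform across the cell width;
  the anchor is set to the rebinding position.

**The three models.**

* `diffusion`: the complex diffuses with `D_PC` = 1e-4 um^2/s; no dimers.
* `diffusion_binding`: dimers are immobile and exert no force; while bound to
  at least one of them the complex is stalled (a rigid bond to an immobile
  tether transmits no displacement), resuming free diffusion on release.
  This is the Brownian-ratchet null model: binding alone yields trapping,
  not transport, and in ensembles of ~50-1000 runs no trajectory completes
  the 1-um fast-phase distance within 30 min.
* `dna_relay`: DNA-bound dimers fluctuate in their harmonic wells with
  `D_A` = 0.01 um^2/s (the measured locus diffusivity extrapolated to the
  1-ms step); captured dimers ride with the complex while their stretched
  tethers pull it (force sum over attachments, F' = -n_AB k_sp); the model
  translocates most runs in 10-30 simulated minutes.

A run terminates at `t_fin` (2000 s) or on first contact with the absorbing
target `x_finish` (default 2.5 um = the new-pole wall; the target and the box
length are independently configurable).  Ensembles hold early-finished runs
at `x_finish` for averaging, so the completion fraction is non-decreasing.

**Numerical acceleration (exact and approximate).** Inside the compiled
kernel, (i) the linear spring force of a DNA-bound dimer lets the four-term
update plus correlated noise collapse algebraically to a single-Gaussian OU
map — the identical jointly-Gaussian law, one draw instead of two; (ii)
dimers whose anchor is farther than `active_window` (default 0.5 um >
8 sigma_long + capture radius) from the complex along x are frozen and
resampled from their stationary Boltzmann distribution when the complex
approaches.  The probability that a tether ever exceeds the window during a
run is ~1e-3, and `active_window >= l0` disables the approximation entirely.
dt must satisfy `dt <= 0.1 min(sigma^2)/D_A` (refused otherwise); the
forceless models tolerate coarser steps (acceptance ensembles use 5 ms for
diffusion-binding), since no tether dynamics are integrated there.

**Determinism.** A master seed plus run index feeds
`numpy.random.SeedSequence((seed, run_index))`, whose first draw seeds the
kernel RNG; identical (config, seed) reproduces byte-identical trajectories.

## Trajectory analysis (`dnarelay.trajectory`)

**Linking.** With at most two spots per cell per frame, each frame's
assignment minimises the summed displacement to the tracks' last known
positions; single-spot frames inherit the nearer label, gaps stay NaN.
Spots are pre-sorted by (x, y) within a frame, making the result invariant
to input order; exact ties keep the sorted labelling.

**Fast-phase detection.** The long-axis trace is interpolated onto its
uniform frame grid, smoothed by a moving average (window 5 frames,
configurable), and its curvature measured with the wide-stencil second
difference `x[i+w] - 2 x[i] + x[i-w]` — a smoothed second derivative whose
extrema coincide exactly with the change points of an ideal
flat/ramp/flat trajectory.  The run is the (curvature peak, trough) pair,
each exceeding 4 robust SDs of the localization-noise floor (estimated from
the raw lag-1 second difference, which linear stretches leave untouched),
that covers the greatest travelled distance; candidate runs shorter than
0.25 um are rejected, protecting against pure-noise traces.  On synthetic
movies at the study's design (20-s frames, ~73 nm ramp step vs 20 nm
localization noise) the detected change points fall within +-2 frames of
the generator's truth.

**Slow-phase segments** (used for D_PC estimation): segment 1 = single-spot
frames at least 320 nm from the old pole, before duplication; segment 2 =
the pole-proximal complex from 60 s after visible separation (first frame
with both spots >= 0.25 um apart, ~2x the localization SD) until it returns
within 320 nm of the pole; segment 3 = the pole-distal complex's longest
contiguous stretch confined within a 500-nm window along the long axis.
All thresholds are configurable; the window scan is tested against an
O(n^2) reference.

**Diffusion estimation.** The Gaussian method fits a zero-mean normal to
1-D displacements and converts Var = 2 D dt (the 1-D physics convention;
an alternative `slope` convention, D = slope of MSD vs t, is exposed
because published MSD fits are sometimes quoted that way — the two differ
by exactly a factor of two).  The MSD method regresses the first four
time-averaged MSD lags with a free offset that absorbs the
localization-noise floor (intercept 2 sigma_loc^2 for a static emitter).

## Locus elasticity and derived quantities (`dnarelay.fluctuation`)

Deviations from each trajectory's own mean (cancelling cell-to-cell
equilibrium variability; minimum 5 frames) are pooled and fitted per axis
with zero-mean Gaussians — the Boltzmann distribution of a harmonic well,
P(dx) ~ exp(-k_sp dx^2 / 2 kT), so 1/sigma^2 = k_sp/kT.  Maximum-likelihood
(sigma = RMS deviation) is the default; a binned least-squares variant is
provided since the two differ slightly in their error estimates.  Finite
2-s sampling of the OU process slightly underestimates sigma; no correction
is applied, and at D_A = 0.01 um^2/s the frame-to-frame correlation is
~0.01, making the bias negligible against the 5% recovery tolerance.

Derived quantities: spring constants k = kT/sigma^2 (0.001 and 0.003 pN/nm
at the measured 64 and 38 nm, 1 s.f.); the drag force F = v kT / D_PC
needed to move the complex at its observed 3 nm/s (~0.1 pN); the
characteristic elastic force k_sp sigma (~0.06 pN) — the two agreeing
within a factor ~2 is the mechanism's consistency argument; the optimal
tether attachment time sigma_long^2 / D_PC = 36 s, whose inverse (~0.03 1/s)
matches the measured hydrolysis rate; the effective diffusivity of
subdiffusive loci D = D_app dt^(alpha-1); and upper bounds on a hypothetical
ParA filament (n/4.4 x 12 nm for a nucleoprotein helix; n x 6.4 nm
back-to-back, the per-dimer length chosen to match the crystal-structure
long dimension at the printed rounding).  Significant-figure rounding is a
reporting helper only and never feeds further computation.

## ATPase kinetics (`dnarelay.kinetics`)

Initial velocities are OLS slopes of A340 time courses over a configurable
window, corrected by subtracting the matched no-enzyme control slope
(idempotent); rising absorbance is flagged.  An NADH standard curve
(uM per absorbance unit) converts slopes to ADP production rates (uM/hr),
and division by [ParA] gives the specific activity in 1/hr, with values
below the 0.5 1/hr assay baseline reported as a "< baseline" sentinel.
Substrate dependences are fitted with v = Vmax S/(K + S) by
Levenberg-Marquardt (initialised at Vmax0 = max v, K0 = median S, positive
bounds); the ParA titration is fitted through the origin by default
(proportionality), with a free intercept available.  Because the raw plate
data are unpublished, correctness is established by parameter recovery on
synthetic designs generated at the published constants, not by re-deriving
those constants from data.

## Cell-level quantification (`dnarelay.quantify`)

Concentration arithmetic is exact: c = N / (N_A V); DNA concentration
4e6 bp x 650 Da/bp in 0.25 fL = 17 mg/ml.  The partition fraction ranks a
cell's segments by fluorescence density, takes the mean of the lowest
decile (ceil(0.1 n) segments, ties broken by segment index) as the
freely-diffusing concentration, scales by total area and reports
1 - diffuse/total — invariant to intensity scaling.  Population
autofluorescence splits use a two-component Gaussian mixture (EM, sklearn),
components ordered by mean, reported as collapsed when the means are closer
than the sum of the SDs (the unimodality boundary for equal-SD components).
Aspect ratios come from the ellipse with matching second central moments
(axis length 4 sqrt(eigenvalue); AR = sqrt(lambda_max/lambda_min)),
rotation- and translation-invariant, with AR > 1.5 flagging a decompacted
complex and degenerate point sets flagged rather than scored.

## Synthetic data (`dnarelay.synthetic`)

Every generator is deterministic in its seed and returns a ground-truth
sidecar; recovery tests compare against the sidecar, never against
hard-coded numbers.  Defaults are the study conditions: locus movies at 2-s
frames for 180 s over 641 cells with sigma = (64, 38) nm and D_A = 0.01
um^2/s, integrated with the package's own scheme at 10-ms substeps (no
extra localization noise: the experimental sigma already folds it in, and
the generator's sigma is defined as the observed SD); two-spot segregation
movies at 20-s frames with a 1.0-um run at 220 nm/min between flat slow and
anchored phases, 20-nm localization noise throughout (the slow phase is
confined at the noise scale by default — `D_slow` adds diffusive wander for
realism studies, at the cost of change-point identifiability); Michaelis-
Menten tables with multiplicative noise; linear NADH time courses with
matched controls; segment profiles built as focus fraction + uniform
background; elliptical Gaussian point clouds.

What the generators do **not** emulate: uneven illumination and segmentation
errors, spot-detection failures and false positives, cell growth during the
movie, coupled-assay lag phases, plate effects, and pixelation.  Passing
recovery tests therefore demonstrates estimator correctness under the
models' own assumptions, not robustness to every artifact of real data.

## Problem sizes

The simulation ensembles used by the tests and by `scripts/acceptance.py`
are scaled-down versions of the full study (which averaged 1024 runs):
50 diffusion-binding runs (5-ms steps, forceless model) and 25 DNA-relay
runs per hydrolysis rate (1-ms steps), sizes at which the qualitative
contrasts — zero ratchet crossings, majority relay completion, the k_cat
optimum — are reproducible for any seed.

## Known limitations

* 2-D only; no explicit chromosome polymer, no freely-diffusing ParA
  monomer dynamics (uniform-rebinding approximation), no filament models,
  no PopZ/TipN anchoring mechanics.
* The ParA gradient is imposed through the rebinding density rather than
  emerging from a reaction-diffusion field.
* The diffusion-binding model's stall-while-bound reading is the package's
  interpretation of a ratchet with rigid, immobile tethers; a finite-drag
  variant would interpolate between it and pure diffusion.
* Fast-phase detection assumes a single dominant run per trace, as in the
  study's analysis of pole-reaching trajectories.
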