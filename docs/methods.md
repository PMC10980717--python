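# Methods

`plectolab` implements the quantitative analysis behind a correlative
optical-tweezers / electromagnetic-tweezers / fluorescence experiment on
single supercoiled DNA molecules, together with a synthetic-data layer
that stands in for the instrument.  This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
data do and do not establish.

## Units and constants

Internal units are pN, nm, s, K; energies in pN·nm with
kB = 0.0138 pN·nm/K.  Default temperature is 310 K (the bead-local
temperature is elevated by NIR absorption; see Thermal below).  B-DNA
geometry: helical repeat 10.5 bp/turn, rise 0.34 nm/bp — used but
configurable everywhere.  Sequence-energy calculations (SIDD) use
kcal/mol internally, with R = 1.987×10⁻³ kcal/mol/K.

## Synthetic data (`synthdata`)

Every generator returns its parameter set as a `GroundTruth` record so
recovery tests are self-describing, and is bit-reproducible under a
fixed seed.

* **Trapped bead**: exact discrete Ornstein-Uhlenbeck update
  (exponential decay with matched stationary variance), not Euler, so
  there is no time-step bias: the stationary variance is kBT/k and the
  spectrum is Lorentzian with f_c = k/(2πγ), γ = 6πηR, at any Δt.
* **Driven rotor**: overdamped rotor with drag γ_θ = 8πηR³; the
  steady-state response to a sinusoidal drive lags by
  φ = arctan(2πf·γ_θ/k_θ), small-angle slope 2πγ_θ/k_θ per Hz.
* **Force-extension**: Marko-Siggia force with multiplicative Gaussian
  force noise, sampled on 0.1–0.95 of the contour length.
* **Hat curves**: piecewise-linear extension vs turns — symmetric
  buckling on both twist signs below the critical force, a
  constant-extension plateau on the undertwist side at/above it; two
  time-ordered segments give drift correction its anchors.
* **Tether movies**: a uniform-intensity line plus 2-D Gaussian puncta
  each carrying its bp fraction of the tether photon budget, diffusing
  1-D along the axis with reflective ends; Poisson shot noise plus
  Gaussian read noise; 16-bit, origin top-left, pixel centres at
  integer coordinates, default 55 nm/px.
* **Base-pair grids**: Gaussian angular parameters (propeller −12°±8°,
  opening 2°±4°, buckle 0°±6° by default) with H-bond flags; planted
  bubbles clear the flag and displace all three parameters by 4
  baseline s.d. (comfortably past the 2 s.d. calling threshold).
* **Force clamp** (simulation only): discrete loop repositioning the
  stage by the force error over the trap stiffness plus integral and
  derivative terms.  The experiment quotes a ~1 s response and a
  ±0.1 pN band but no gains; defaults (kp = 0.016, ki = 0.008 at
  100 Hz) were chosen to give a ≈0.7–1 s settling time.  A
  proportional-only loop with gain 1/stiffness corrects a step in one
  update, which the tests pin down.
* `gen_brownian_track` supplies pure Brownian 2-D tracks for the
  MSD-estimator statistics; full image rendering is validated
  separately on small stacks.

What the generators do **not** emulate: photobleaching/blinking, EMCCD
gain statistics, 3-D PSFs, QPD nonlinearity, aliasing filters, or
mechanical drift of real stages beyond the piecewise-linear model.
Recovery tests on these synthetics therefore establish estimator
correctness under the assumed noise models, not robustness to every
instrumental artefact.

## Calibration (`calibration`)

Power spectra are Welch-averaged (2¹³-sample Hann segments, 50%
overlap, no per-segment detrending — detrending strips genuine power
below 1/T_segment and breaks the Parseval check).  The Lorentzian
S(f) = A/(f_c²+f²) is fitted with relative residuals (spectral errors
scale with the mean); stiffness follows from k = 2πf_c·γ.  A corner
frequency pinned to the fit-band edge or with >50% standard error is
reported as "no knee" (white-noise input).

Rotor phase uses the time-reversed-correlation estimator: the
band-passed response convolved with itself peaks where
ω·τ = 2φ (mod 2π), encoding twice the phase with reduced noise; the
π-ambiguity and sign are resolved against a quadrature projection onto
the drive channel.  Lag of the response behind the drive is positive.
Angular stiffness comes from a linear regression of phase vs drive
frequency, k_θ = 2π·8πηR³/|slope| — the 2π converts the per-Hz slope
to per-angular-frequency, and is required to reproduce the quoted
1.1×10³ pN·nm/rad from the 0.429 rad/Hz gradient.  The regression is
restricted to the small-angle regime (|φ| < 0.7 rad); the residual
arctan curvature biases the round-trip recovery by ≲4%, inside the 5%
band the tests enforce.

## DNA mechanics (`mechanics`)

The elasticity model is the inextensible Marko-Siggia interpolation;
forces in this instrument stay below ~10 pN, so no stretch-modulus
term is warranted.  Fits are plain least squares with the constraint
Lc > max(x); parameter errors come from a subsample bootstrap (1% of
points, 1000 replicates by default).

Supercoiling density is applied turns over the helical turns of the
torsionally active region — for the 15.6 kbp construct that is the
14.6 kbp centre (the 500 bp handles are multiply attached), which
reproduces σ = 0.14 and 0.11 for ±200 and +150 rotations.  Torque per
rotation is τ = C/L with C = 410 pN·nm; the cumulative torque is
linear in turns.  (The source experiment also quotes ±1.6 pN·nm after
200 rotations, which is mutually inconsistent with its own
τ = C/L = 0.08 pN·nm/turn; this package follows τ = C/L.)

Drift correction is piecewise linear between anchor epochs — times at
which the system revisits a common reference state (σ = 0 between
hat-curve segments).  Anchor displacements that deviate from a single
linear trend by more than a tolerance flag under-fitting (e.g.
quadratic drift).  Hat-curve symmetry is scored as
Σ|d₊−d₋| / Σ max(d₊,d₋) over matched |turn| bins of the per-sign
extension drops: 0 for a mirror-symmetric curve, 1 for a one-sided
plateau; the asymmetry label threshold (0.25) is configuration, as is
the buckling detector (two-segment piecewise-linear change point;
buckled when the post/pre fluctuation ratio ≥ 1.5).  The experiment
reports phenomena, not detector settings, so these defaults are the
package's own.

## Puncta (`puncta`)

Detection is local maxima above a robust background, refined by 2-D
Gaussian least squares; fits more elongated than 2.5:1 are discarded
as ridge maxima of the tether line itself.  Localisation precision
comes from the fit covariance (≈1–2 nm at the synthetic SNR; the
20 nm figure of the source experiment is an upper bound the tests use).
Linking is greedy nearest-neighbour without gap closing — appropriate
for the few, well-separated puncta this assay produces; ambiguous
links are tie-broken by intensity similarity and flagged.

Punctum bp content divides the background-corrected punctum sum (a
disc, minus the median per-column tether-line intensity measured away
from the punctum) by the background-corrected whole-tether band sum.
Reported rmsd values are per-frame (lag-1) displacements projected on
and normal to the tether axis; the diffusion coefficient comes from an
origin-constrained regression of MSD against 4·lag·δt over lags 1–5.
These two summaries need not satisfy rmsd² = 4Dδt on confined or
noisy data — deliberately, mirroring how such tables are reported.
The MSD estimator is unbiased on noise-free Brownian tracks (the
recovery tests use those); a lag-independent localisation-noise offset
would bias any origin-constrained fit, which is a known limitation of
the estimator class, not of this implementation.

## Sequence site prediction (`sitepredict`)

**Intrinsic curvature** uses the dinucleotide wedge model (twist /
wedge / direction table of Bolshoy et al., PNAS 88:2312, 1991):
deflection vectors rotated by the accumulated helical phase are summed
over a sliding window (default 63 bp ≈ 6 turns) and reported as
degrees per helical turn.  The wedge is applied at the mid-step phase,
which makes the profile invariant under reverse complementation up to
the one-bp parity of an even window.

**Plectoneme placement** is a curvature-driven tip model: the tip loop
(75 bp) must bend through 2π/l, and local intrinsic curvature offsets
that cost, E_tip = (kBT·P/2)·l·(κ_loop−κ_local)².  The per-bp density
is the Boltzmann weight of E_tip averaged over plectoneme sizes that
fit, normalised to 1.  Averaging (rather than summing) over sizes
means the size cutoff — 8300/6700/1900 bp by supercoiling regime,
values taken as data from experimental bp-content estimates — bounds
the admissible states without imprinting an artificial mid-sequence
bias: a uniform-curvature sequence yields a uniform density.  The
model is a reconstruction in spirit of the published curvature
approach, validated on constructions (phased A-tract cassettes move
the mode to within ±200 bp of the planted curvature peak); absolute
energies are not meaningful, peak positions are.

**SIDD-type opening profiles**: equilibrium statistical mechanics of
strand separation under negative superhelicity.  States are the closed
duplex plus at most two disjoint open runs; a state pays an initiation
cost a per run (10.84 kcal/mol), copolymeric separation energies
(b_AT = 0.26, b_GC = 1.30 kcal/mol, calibrated near 310 K / 0.1 M
salt), and a residual-stress term (K/2)·α_r² with K = 2200·RT/N per
turn², where the linking difference α = σN/h (h = 10.4) partitions
between duplex untwisting of open bp, interstrand winding of the open
strands (torsional stiffness C = 3.6 kcal/mol/rad², minimised
analytically, giving an effective K_eff(n) = K·C/(C+Kn/4π²)), and
residual stress.  All states within 12 kcal/mol of the minimum are
Boltzmann-summed; two-run states are enumerated from energy-pruned
candidate runs.  The single-run path is verified bp-by-bp against an
independent exhaustive enumeration to 1e-10 relative.  The two-run
limit is consistent with the initiation cost making a single bubble
dominant at these stresses.  `salt_M` is recorded metadata; other
ionic conditions are expressed by overriding the energy parameters.
Known limitation (inherited from the model class): torsional stress is
assumed partitioned into twist, so opening is over-predicted wherever
plectonemes absorb writhe, and curvature does not feed back on
opening.

Expected bubble size is the Boltzmann-weighted mean open-run length,
taken from the run-length distribution accumulated during the state
sum.  Profile comparison min-max normalises both inputs, optionally
cubic-spline smooths a measured trace, finds peaks by prominence, and
reports nearest-peak offsets as % of sequence length.

## Trajectory bubbles and restraints (`bubbles`, `restraints`)

A bp is *disrupted* in a frame when its WC H-bond flag is absent AND
all three angular parameters deviate ≥ 2 s.d. from the relaxed-DNA
baseline (global mean/s.d. excluding 2 terminal bp per end).  The
conservative AND reading was chosen because the defining phrase is
ambiguous; OR is available as `angular_mode="any"`.  Maximal runs of
≥ 3 disrupted bp are candidate bubbles; candidates sharing ≥ 1 bp in
consecutive frames are one event, a full-frame gap ends it (the
persistence-bridging rule is this package's own); events longer than
1 ns are calls.  The caller is verified exactly against a naive
run-scan oracle on small grids.  Prevalence is the percentage of
frames in the final 400 ns containing a bubble; its error is a
bootstrap s.d. over 200 resamples of 1% of frames.  Convergence of an
end-to-end series is declared when the running mean drifts < 2% over
its final quarter.

The restraint generator emits, for a core duplex plus a 60 bp GC
buffer (mobile end) and 2 GC bp (fixed end): positional anchors on the
fixed-end O3′/O5′; per-strand linear distance restraints toward
reference points A/B with slope equal to the requested force
(0.0144 kcal/mol/Å per pN); θ₁/θ₂ angle pairs per lateral axis; one
ψ ≥ 90° excluded-volume angle per bulk phosphorus and per strand end;
one anti-bending dihedral per complementary buffer phosphorus pair;
and two coplanarity dihedrals (first mobile core bp, next-to-last
fixed bp) that lock the torsion in.  For a 50 bp core (L = 112) that
is 4 + 2 + 4 + 2L + 62 = 296 records, a count the tests freeze.
Reference points sit on the tether axis at a configurable 20 Å
standoff — their exact placement is not published and only needs to be
axial.  Output is AMBER-style RST text (dummy-atom indices left as
placeholders, since they depend on topology numbering) and neutral
JSON.  No simulation is run; the specification is validated
structurally.

## Thermal model (`thermal`)

The bead absorbs laser power in a ~100 nm magnetite shell just inside
its surface.  Analytically (infinite bath): the interior is isothermal
at Ts = T∞ + P/(4πk_w R) and the exterior excess decays as R/r.  With
Ts = 45 °C, T∞ = 25 °C, R = 1.5 µm this spans 45→29.6 °C over 0–5 µm,
mean ≈ 37.3 °C — the physiologically convenient window.

The numeric solver is finite-volume on an axisymmetric (ρ,z)
rectilinear grid (25 nm cells around the bead, geometric stretching to
10R), harmonic-mean face conductivities, shell source smoothed by 5×5
sub-cell volume fractions so the staircase sphere does not imprint on
the interior (interior s.d. < 0.01 °C).  Discrete conservation is
exact; the flux through a control box around the bead matches the
absorbed power to float precision.  For the uniform-conductivity
control (k_glass = k_water) the far boundary uses the matched 1/r
Dirichlet value and the solution agrees with the analytic profile to
0.3% (2% is the enforced bound); refining the grid and the stretch
factor together reduces the deviation superlinearly.

With a conducting coverslip (k_glass = 1.0 > k_water = 0.6 W/m/K,
literature defaults — not measured values) temperatures drop near the
glass and everywhere relative to the control.  Note: in this model
class the conducting half-space *steepens* the lateral decay of the
excess temperature (the image source partially cancels), rather than
flattening it; a shallower-than-1/x apparent decay therefore cannot be
attributed to glass conduction alone and likely reflects additional
geometry of the original measurement (wax particles on the surface,
bead nearly touching).  The tests assert the robust directional facts
only.

Wax-interface inversion exploits that the analytic profile is linear
in Ts: closed-form least squares on (distance, melting-T) pairs,
case-resampling bootstrap CI for ≥ 3 observations.  The alkane melting
points shipped in `ALKANE_MELTING_POINTS_C` are standard reference
values (synthetic stand-ins, marked as such), not measurements.
Ambient temperature defaults to 25 °C (climate-controlled room).

## Problem sizes

Default test and acceptance workloads are desk-scale by design: 8 s
trap traces at 50 kHz, 60 s rotor records, 10–41-frame 48×64 movies,
500-point force-extension curves with 1000-track MSD ensembles,
≤ 120 bp exhaustive SIDD oracles plus the 300 bp printed sequence,
20 bp × 100–500-frame bubble grids, and ~2×10⁴-cell thermal meshes.
These sizes make every check exact or statistically decisive while the
whole suite runs in well under a minute of compute per module.
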