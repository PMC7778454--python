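# Methods

## Phantom geometry and forward models

The head is a four-shell concentric sphere — brain, CSF, skull and scalp
with outer radii 80/82/87/92 mm and relative conductivities
1 : 5 : 1/80 : 1 (brain : CSF : skull : scalp; the skull is 80× more
resistive than scalp and brain, CSF 5× more conductive). Sources live on
the outer brain surface ("cortical shell", radius 80 mm) as a Fibonacci
lattice of radially oriented dipoles; the default resolution is 1000
voxels (~9 mm spacing). An 8-mm activation spot therefore usually
contains a single voxel; spot membership snaps to the nearest voxel so a
spot is never empty. This resolution keeps every end-to-end experiment
(simulation plus per-timestep ReML inversion) cheap enough that the
randomized assessments run in minutes; all spatial error numbers should
be read at this grid scale.

**EEG.** Scalp potentials are computed with the exact Legendre-series
solution for a dipole inside a multilayer sphere: for each harmonic order
the radial two-point boundary-value problem across the shells is solved
directly (continuity of potential and radial current at each interface,
zero normal current at the scalp), so truncation is the only
approximation. The series is truncated at 60 terms by default; the ratio
of the last to the largest term magnitude is recorded on the leadfield
(`truncation_tol`, ~2×10⁻⁴ for cortical sources). The homogeneous limit
reduces to the classical closed-form single-sphere potential, which the
tests use as an independent oracle (agreement to <10⁻⁶ relative for
sufficiently deep dipoles). Leadfields are average-referenced.

**DOT.** Continuous-wave Rytov sensitivities are built from
diffusion-approximation Green's functions of a homogeneous semi-infinite
medium tangent to the optode patch: each point keeps its
azimuthal-equidistant tangent coordinates and its radial depth below the
scalp sphere. Both optode terminals are modelled as isotropic point
sources at depth 1/μs′ with an extrapolated zero boundary at −2D, which
makes source–detector reciprocity exact. Per-voxel sensitivity is
G(rs→r)·G(r→rd)/G(rs→rd) × nominal voxel volume; chromophore columns are
scaled by decadic hemoglobin extinction coefficients (Gratzer/Prahl
table, packaged in `data/hemoglobin_extinction.yaml`), so the Jacobian
maps [ΔHbO; ΔHb] directly to ΔOD. Optical properties default to
brain-like μa = 0.0178/0.0186 mm⁻¹ and μs′ = 1.25/1.10 mm⁻¹ at
750/850 nm and are config-overridable. This analytic substitution keeps
the spatial low-pass and "banana"-shaped sensitivity structure the fusion
method exploits while removing any atlas or FEM toolbox dependency; it
does not model scalp/skull optical layering or sulcal geometry.

**Sensor layouts.** EEG uses standard 10–20/10–10 angular positions (from
MNE-Python's bundled template, sphere-fit and projected to the scalp
shell) in 32- and 64-channel montages. The regular DOT grid is a 4×4
checkerboard of 8 sources and 8 detectors at 21 mm pitch over the right
hemisphere at 45° elevation, whose 24 nearest-neighbour pairs form the
channels (separations within 17–27 mm); a variant adds one extra detector
beyond the +u grid edge contributing exactly two channels (26 total).
The high-density grid is a 7×7 checkerboard at 10.5 mm pitch with all
pairs between 7.5 and 29 mm as channels (overlapping measurements). The
published grid coordinates of comparable systems are not reproduced;
only channel counts and distance ranges constrain the layout, so it is
parametric.

## Simulation protocol

A 30 s block contains 100 trials at 200 ms spacing in the first 20 s;
within each trial spot A is stimulated at 0 ms and spot B 50 ms later.
Each stimulus is an impulse in a per-spot event train. The *same* train
is convolved with two kernels:

- electrical: unit-peak Gaussian bell, peak 50 ms post-stimulus, FWHM
  40 ms (so the two per-trial responses cross at equal amplitude at
  75 ms), sampled at 1000 Hz;
- hemodynamic: unit-peak canonical double-gamma (peak 6 s, undershoot
  16 s, ratio 1/6), sampled at 10 Hz. ΔHb = −ΔHbO/3 (opposed sign, 3:1
  peak ratio).

Sampling rates are package choices (millisecond EEG peaks, sub-second
optical sampling). I.i.d. Gaussian background activity is added to all
voxels at each sample: std 1/20 of the maximum evoked electrical
amplitude, and 4× / 2× the maximum evoked ΔHbO / ΔHb amplitude. These
ratios are interpreted relative to the **single-event** response maximum
(the kernel peak): for the electrical responses the per-event and
whole-train maxima coincide (no overlap at 200 ms spacing), and for the
slow hemodynamics the single-event response is the physiologically
meaningful scale — scaling to the 100-trial superposition plateau (~17×
larger) would drown the optical data entirely. Sensor noise is Gaussian
with variance set per modality (and per DOT wavelength) to
(max |clean signal|)²/SNR, with SNRs 10 (EEG), 10 (750 nm) and 20
(850 nm); "clean" includes the background brain activity, which is
signal at the sensors.

The generator emulates evoked responses, spatially white background
activity and white sensor noise. It does not emulate 1/f EEG spectra,
physiological oscillations (cardiac/respiratory/Mayer waves), motion
artifacts, nonlinear neurovascular coupling, or spatially correlated
background — so passing tests demonstrate the algorithmic behaviour of
the fusion under the stated noise model, not performance on real
recordings.

## Reconstruction

EEG is trial-averaged before inversion. DOT is low-pass filtered at 1 Hz
(order-2 Butterworth, zero-phase so hemodynamic peak latencies are not
shifted) and averaged over a 2–25 s post-onset response window (the
averaging window is configurable; the early seconds are excluded because
the hemodynamic response has not risen yet).

ReML maximizes the marginal likelihood of
cov(Y) = H C_P Hᵀ + C_N by Fisher scoring on log-coefficients with
Levenberg–Marquardt damping (step rejection keeps the accepted objective
non-decreasing), tol 10⁻⁶ relative, max 128 iterations, coefficients
initialised so each component's assembled trace receives an equal share
of the data variance, and 10⁻¹⁰×mean-diagonal jitter before every
factorization. Multi-column Y is treated as i.i.d. realisations. ReML is
applied independently to each time step of the averaged EEG trial, with
hyperparameters re-estimated per step. With fixed identity components the
estimator reduces exactly to Tikhonov regularisation, which the tests
exploit as an oracle.

The DOT-prior weighting q = 1 − exp(−(β′ + a)/b) is applied to the
max-normalised HbO map with threshold k = 0.1 (on the normalised scale,
where the threshold is meaningful); a controls the baseline variance
allowed everywhere (0.1; 0.25 for the 64-channel montage) and b the
dynamic range. An optional spatial-smoothness prior replaces the identity
chromophore blocks with G_ij = exp(−‖ri−rj‖²/σ²); the exponent is
negative — the only positive-semidefinite reading — with σ = 2.5 mm by
convention, which at the default 9-mm grid spacing is effectively the
identity.

The projection-prior baseline skips tomography: channel-wise ΔHbO from
the modified Beer–Lambert law (differential pathlength factors 6.0 at
750 nm and 5.0 at 850 nm, config-overridable), placed at each channel's
source–detector midpoint projected radially to the cortical shell and
interpolated with a Gaussian kernel (σ = 15 mm, of order the channel
spacing), then passed through the same weighting.

## Metrics

Valid voxels are those with |amplitude| ≥ half the map maximum
(inclusive). Bias is the distance from their unweighted centre of mass to
the true centre, spread the mean-square distance to that centre of mass,
BSM = √(bias² + spread). Absolute values are used because EEG
reconstructions are signed. For two-spot maps, valid voxels are assigned
to the nearer true centre (ties to A, deterministically); an empty side
flags that spot as undetected and the other spot is scored on the whole
set. When both sides are populated but the voxels form a single connected
activation (single-linkage components at twice the median grid spacing),
that one activation is scored against both true centres with the
identical valid set — distinguishing "one blob straddling both" from
"two separate blobs", which a pure nearest-centre partition cannot do.
An undetected spot carries NaN bias/spread/BSM and each spot's bias is
always measured against its own true centre.

## Scenarios and measurements

Preset two-source scenarios reproduce four qualitative regimes: both
spots covered by the grid and away from electrodes (the default,
25 mm/50 ms separation), both spots straddling the C4 electrode (23 mm),
the same with 64 channels and a = 0.25, and spot B placed 45 mm along
the patch axis — beyond the grid's sensitive region — at 35 mm separation,
with and without the extra detector. Spot placements are expressed in the
optode-patch tangent frame (cortical-arc mm).

The randomized assessment samples activation locations uniformly over
the rectangle covered by the optode grid (plus a 10 mm margin) on the
cortical shell; two-spot mode rejection-samples pairs 20–30 mm apart
inside that region. Improvement is counted per run by direct BSM
comparison (all four cells in two-spot mode); one-sided two-sample
t-tests on the BSM distributions are reported as summary statistics
only, since the distributions are phantom-specific.

Peak latencies of reconstructed time courses are measured after Gaussian
smoothing with σ = 5 ms — matched to the 40-ms-FWHM neural response
bandwidth — with parabolic refinement of the discrete maximum; unsmoothed
argmax picking is jittered by several ms by per-timestep estimation
noise.

All randomness flows from a single integer seed through
`numpy.random.SeedSequence` spawning, making every experiment, CSV and
JSON output bit-reproducible.

## Known limitations

- Spherical geometry and a homogeneous optical half-space: no sulci, no
  layered optics, no depth-varying sensitivity beyond the analytic
  profiles; absolute BSM values are not comparable to atlas-based
  numbers, only directions and orderings are meaningful.
- The 1000-voxel grid quantizes localization error at ~9 mm; spots are
  effectively point sources.
- The semi-infinite optical model keeps weak lateral sensitivity beyond
  the optode grid, so "outside the grid" is a graded rather than sharp
  notion; the out-of-grid preset places the spot where that sensitivity
  is negligible.
- Per-timestep hyperparameter re-estimation makes adjacent-timestep maps
  statistically independent; no temporal smoothness is imposed on the
  reconstruction.
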