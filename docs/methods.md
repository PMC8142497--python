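# Methods

`greyblood` is an in-silico implementation of a free-breathing, ECG-triggered
3D grey-blood phase-sensitive inversion-recovery (PSIR) late-gadolinium-
enhancement (LGE) framework with dual-echo Dixon water/fat separation and
image-navigator (iNAV) respiratory motion correction. Every stage operates
on simulated data with a known ground truth, so each claim the pipeline
makes — motion recovery, undersampled reconstruction fidelity, water/fat
separation exactness, polarity correctness — is tested against an
independent reference.

## Signal model

Two ECG-triggered volumes are acquired in interleaved heartbeats: an
IR-prepared spoiled-GRE volume (flip angle 25°) and a non-prepared reference
volume (5°), both with a dual-echo bipolar readout at TR/TE1/TE2 =
6.41/2.38/4.76 ms, 16 phase encodes (segments) per heartbeat at 60 bpm, and
a 14-echo low-flip (3°) 2D coronal iNAV played immediately before each
readout train. The longitudinal magnetization is propagated by the exact
single-pool recursion

    inversion:   Mz -> -eta * Mz            (IR beat, eta = inversion efficiency)
    excitation:  Mz -> Mz * cos(alpha)
    recovery:    Mz -> 1 + (Mz - 1) * exp(-t/T1)

under perfect spoiling; TI is the inversion-to-k-space-centre delay
(centric segment ordering). The acquisition simulator applies the
steady-state segment train (dummy cycles are assumed played before data
collection), so every shot of a volume carries the same per-segment
contrast weights. The transverse signal of tissue with proton density rho
and fat fraction f at echo time TE is

    s(TE) = rho * Mz * sin(alpha) * exp(-TE/T2*) * [(1-f) + f * exp(2*pi*i*df*TE)]

with a single fat peak at df = -1/(2*TE1) = -210.08 Hz, which makes echo 1
exactly out-of-phase and echo 2 in-phase. The recursion is validated to
1e-6 against an independent brute-force integrator that advances the Bloch
relaxation ODE in 0.01 ms RK4 steps, and the TI search (`find_null_ti`,
bisection on the steady-state centre-segment Mz) reproduces TI = T1·ln 2 in
the ideal-IR limit to better than 0.5 ms.

## Digital phantoms and study conditions

Two geometries: a seven-vial T1 phantom (T1 = 2883, 1259, 587, 384, 279,
217, 198 ms — a gadolinium dilution series in which the 587/384/279 ms vials
play post-contrast myocardium, blood and scar) and a cardiac-like short-axis
cylinder (blood pool radius 22 mm, 12 mm myocardial wall, a 70° transmural
scar wedge, a 6 mm epicardial fat rim with fat fraction 0.9) at 2 mm
isotropic resolution on a 64³ grid. Phantom construction is deterministic;
compartments partition the support.

Coil sensitivities are smooth synthetic complex fields: rational-decay
magnitudes centred on a ring of coils around the object, alternating
between two rings offset along z (a chest/spine-like arrangement — a single
coplanar ring encodes one phase-encode direction only and makes 2D
undersampling nearly unresolvable), with slowly varying seeded phase. Only
smoothness and linear independence matter to SENSE; electromagnetic
fidelity is out of scope.

Respiration is a superior-inferior sinusoid with a left-right component and
optional drift: d_SI(t) = A·(1-cos(2πt/T))/2 + drift·t, d_LR = k·d_SI,
sampled once per heartbeat. Defaults: A = 8 mm, T = 3.7 s, k = 0.3,
drift = 0. The period is deliberately incommensurate with the 1 s RR
interval: a 4 s period phase-locks to the two-beat interleave so each
volume would sample only two aliased motion states (the reference volume a
single constant displacement), an unrealistically benign degenerate case.
The model is a stand-in for breathing, not an inference about any patient
population; it produces the translational, slowly varying displacement that
the correction method assumes. Default noise is complex Gaussian at SNR 30
(99th-percentile reference-image magnitude over the per-component noise
std). What the generator does *not* emulate: cardiac bulk motion
(acquisition is taken as mid-diastolic), anterior-posterior/rotational/
non-rigid respiratory motion, anatomy beyond the compartment geometry,
B1 inhomogeneity, multi-peak fat. Passing tests therefore demonstrate the
pipeline's correctness under its own assumptions, not robustness to
violations of them.

A rigid translation is applied to the composite coil-weighted signal as an
exact k-space phase ramp (equivalently, the coils co-move with the object).
This is the signal model under which a linear phase shift is the exact
inverse of respiratory displacement — the same assumption the iNAV
correction itself makes. Simulating static coils over a moving object would
add a coil-modulation error that the correction cannot remove by design.

## VD-CASPR sampling

The ky-kz phase-encode plane is covered by spiral-like arms of
`segments_per_beat` points each: arm n is rotated by the golden angle
(≈137.51°) from arm n-1, its points sit at radii stratified over the
variable-density radial profile (fully sampled disc of radius 8% of k-max;
(1-r)² taper floored at 0.25 outside), are snapped to the nearest free
Cartesian cell, and are played centre-to-periphery (centric). Each arm is
acquired twice in consecutive heartbeats (IR then REF), so both volumes
cover identical locations and the schedule is interleaved beat-by-beat.

Two numerical choices matter here. First, the density floor: tapering to
zero abandons outer k-space, which no reconstruction can recover —
thinning it instead leaves the restoration to the parallel-imaging inverse.
Second, the generative (arm-first) construction rather than independent
weighted cell draws: iid selection leaves local k-space holes that make the
unregularized normal equations effectively singular (measured 13% NRMSE at
R=3 where the low-discrepancy arm pattern achieves 2%). Fully sampled
schedules use the same arm construction with more heartbeats, as the real
sequence would. Achieved acceleration is within [0.95R, R] of the request.

## Motion estimation and correction

Each shot's iNAV is a zero-filled reconstruction of the 14 central ky lines
of the coronal projection, at the out-of-phase echo (fat-water contrast is
then identical between IR and REF beats). A first template-matching pass
against the first shot ranks the coarse SI positions; the shot at the 5th
percentile is the end-expiration reference (an operational definition — the
minimum itself is noise-sensitive). The reference's central-half ROI is
matched in every navigator by normalized cross-correlation over a ±20 mm
window with 3-point parabolic sub-pixel refinement; displacements are
differences of sub-pixel peak positions, which cancels the template-
placement convention exactly. Shots with peak correlation below 0.3 are
flagged low-confidence but still corrected — no shot is ever discarded, so
respiratory scan efficiency is 100% by construction, and the pipeline
asserts it on every run.

Correction multiplies each shot's samples (both echoes and the navigator
lines) by the phase ramp that translates the image back to the reference
position; IR and REF shots use their own volume's estimates. The correction
is pure phase (magnitudes untouched).

## Reconstruction

Coil sensitivities are estimated from the Hann-apodized central disc
(radius 0.25 of k-max — wider than the fully sampled centre; the variable
density is near-complete there and apodization suppresses the residual
aliasing) of the motion-corrected in-phase reference volume, lightly
smoothed and normalized to unit root-sum-of-squares inside an object mask
(RSS ≥ 5% of maximum). One set of maps serves all four reconstructions, so
the common low-resolution phase they carry cancels in every inter-volume
and inter-echo phase difference used downstream.

Each echo/volume is reconstructed by conjugate gradients on the
regularization-free SENSE normal equations (M·F·S with centered unitary
FFTs; 15 iterations or relative data residual < 1e-6 by default). CG on the
normal equations minimizes the data residual over the Krylov space, so the
tracked residual is non-increasing. The operators pass an adjointness test
at 1e-10 and the solver matches a dense pseudo-inverse on a small two-coil
R=2 system at 1e-6.

Rigid 6-DOF registration (magnitude NCC; phase-correlation translation
initialization; Powell refinement; linear resampling) aligns the other
three volumes to IR echo 1. A transform is applied only when it improves
NCC by more than 1e-2: on multi-contrast echo pairs, smaller gains are
produced by contrast differences (fat-water cancellation on the
out-of-phase echo) on *perfectly aligned* volumes, whereas a genuine
misalignment of half a voxel or more gains well over 1e-2. Resampling an
already-aligned volume only blurs it.

## Dixon separation and PSIR

The B0 map is estimated from the inter-echo phase with the magnitude-cue
strategy: each voxel has a water-dominant and a fat-dominant candidate
(π apart); candidates and 2π wraps are assigned by confidence-ordered
(in-phase magnitude), 6-connected region growing that picks the candidate
closest to the mean of already-assigned neighbours, seeded at the
highest-confidence voxel with the minimal-|ψ| convention; the result is
smoothed with a 3-voxel box. With the field map, the demodulated echoes
separate algebraically: W = (|s2'| + ρ)/2, F = (|s2'| - ρ)/2 with ρ the
signed out-of-phase projection onto the in-phase coil phase; W + F = |s2'|
exactly on noiseless data, and negatives (noise or T2*-decay mismatch
between echoes) are clipped at zero. An optional pre-correction removes a
global linear echo-2 phase slope along the readout (bipolar readout errors)
estimated from the object-average inter-voxel phase increment.

Polarity is recovered *before* separation (separation destroys it): the
intermediate PSIR between the in-phase IR and REF volumes uses the
low-pass-filtered reference phase (Gaussian FWHM 8 voxels) as background
phase and the low-pass-filtered reference magnitude (FWHM 16 voxels, plus
epsilon = 5% of its mean) as surface-coil normalization; polarity =
sign of Re(IR·e^{-iθ})/(B+ε) with sign(0) → +1. The signed grey-blood
volume is polarity × IR water magnitude — an exact identity asserted on
every run — and the complementary fat volume comes from the reference
dataset. Display maps [-max|psir|, +max|psir|] linearly to [0, 1], so
nulled tissue (blood at the blood-nulling TI) renders mid-grey.

## Evaluation

Contrast ratio is the ratio of ROI means on the display-normalized volume;
CNR is the ROI-mean difference over the standard deviation of a noise ROI
drawn in unlabelled voxels inside the reconstruction support (outside it, a
sensitivity-masked SENSE output is identically zero). These formulas are
package definitions — measured scanner values of the same names are not
comparable targets. Bland-Altman agreement returns the mean difference and
bias ± 1.96·SD limits.

Ground-truth definitions used by the test suite:

- *Polarity truth*: the sign of the steady-state centre-segment Mz per
  tissue, from the Bloch recursion; voxels whose water-weighted signal
  magnitude is near zero (nulled tissue) have no meaningful sign and are
  excluded, as are voxels within 2 voxels of a compartment boundary.
- *Reconstruction fidelity*: the encoded image (coil-combined analytic
  phantom at centre-segment contrast), compared on the object support.
  The 64³/8-coil/R=3 noiseless reconstruction is within 2% NRMSE of it.
- *End-to-end motion recovery*: the motion-corrupted run is scored against
  the identically sampled static run. A fully sampled reference is *not*
  used for this comparison because segmented-IR acquisitions with different
  schedules apply genuinely different per-segment contrast filters across
  k-space radius (for myocardium near its null the Mz train changes sign
  within a single readout train); that physics floor (~5%) is not a
  reconstruction error. The fully sampled, static, single-coil degenerate
  case must still match the ideal direct reconstruction to < 1%.

The end-to-end check runs the 64³ cardiac phantom, 8 coils, R = 3, 8 mm
breathing, at a TI midway between the blood- and myocardium-null times so
every compartment is sign-definite: polarity accuracy ≥ 99%, signed water
NRMSE < 5% (measured ≈ 3.7%), bit-identical outputs under a fixed seed.
The grey-blood contrast experiment runs the identical phantom pipeline at
the computed blood-null and myocardium-null TIs (64×64×32 slab) and
reproduces the expected ordering: scar-blood contrast ratio strictly
higher with blood nulling, myocardium dark / blood grey / scar bright in
≥ 99% of compartment interiors.

Problem sizes in the default test and acceptance runs (64³ end-to-end,
64×64×32 contrast pair, 32³ module-level recon tests) were chosen as the
smallest grids on which all spatial scales of the method (fully sampled
centre, variable-density taper, iNAV low-pass, erosion margins) remain
separated.

## Known limitations

- Translational SI/LR motion only, estimated from 2D projections; through-
  plane (AP), rotational and non-rigid motion are out of scope.
- Single-peak fat model; two-point (not multi-echo) Dixon; no R2*.
- The B0 estimator's global water/fat identity comes from a minimal-field
  seed assumption; an object whose strongest voxel is fat-dominant under a
  large uniform off-resonance could be globally swapped.
- Steady-state segment weighting assumes dummy heartbeats before
  acquisition; the initial transient is not simulated.
- Unregularized SENSE only; no compressed-sensing or low-rank variants.
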