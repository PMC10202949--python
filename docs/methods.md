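# Methods

This note records the models, numerical choices and calibrations behind
`hpcsi`, and what the synthetic data can and cannot establish.

## Kinetic model

Hyperpolarized [1-¹³C]pyruvate (P), [1-¹³C]lactate (L) and co-injected
[¹³C]urea (U) longitudinal magnetizations follow the two-site exchange
system

    dP/dt = u_p(t) − (R1_pyr + λ_RF + kPL)·P + kLP·L
    dL/dt =  kPL·P − (R1_lac + λ_RF + kLP)·L
    dU/dt = u_u(t) − (R1_urea + λ_RF)·U

with a boxcar delivery u(t) of 12 s duration (the i.v. injection
window) and λ_RF = −ln(cos θ)/TR the continuous-equivalent loss from
repeated excitation.  With θ = 10° and TR = 60 ms, λ_RF ≈ 0.255 s⁻¹ and
dominates relaxation; the continuous approximation is accurate because
each 4-s frame contains 64 excitations.  kLP defaults to 0: the
readouts of interest never invoke back-conversion, and the closed form
below requires it.

Integrating dL/dt from injection to infinity with L(0) = L(∞) = 0 gives
the precursor–product identity

    AUC_lac / AUC_pyr = kPL / (R1_lac + λ_RF),

the analytic oracle the quantification pipeline is tested against.  The
measured ratio is linear in kPL, which is also what makes designed
fold-changes transfer from kPL to the imaging readout.

Defaults: R1_pyr = R1_lac = 1/30 s⁻¹ and R1_urea = 1/20 s⁻¹, typical in
vivo values at 14.1 T.  The ODEs are solved per smooth segment
(bolus edges split the time axis) with adaptive RK45 at rtol 1e-8; the
test oracle is an independently coded fixed-step RK4 at 1 ms.

`TwoSiteExchangeModel.fit()` estimates kPL (and the delivery amplitude)
by nonlinear least squares against both metabolite time courses, all
other parameters held at their initialization.  On noiseless
model-generated data recovery is exact to ~1e-12 s⁻¹.  In the
Monte-Carlo noise study, "frame-SNR 20" is referenced to the lactate
peak: lactate carries the kPL information, and an SNR referenced to the
~11× larger pyruvate peak would leave lactate at SNR < 2, where no
estimator recovers 10% accuracy from 15 frames.  At lactate SNR 20 the
median |relative error| is ≈ 1%.

## CSI forward model

Acquisition constants: 14.1 T (¹³C at B0 × 10.7084 ≈ 151 MHz), 8×8
matrix over 24×24 mm², 5 mm slice, 2500 Hz spectral width with 128
points, TR 60 ms, flip 10°, one frame per 4 s, 15 frames.  The carrier
sits at 173 ppm; the urea/pyruvate/lactate span (≈21 ppm ≈ 3.2 kHz)
exceeds the window, so apparent positions are wrapped:
urea +914.6 Hz, pyruvate −302.0 Hz, lactate −914.6 Hz.  All downstream
processing works with these aliased offsets, which remain separated by
many linewidths.

Each voxel contributes one FID per frame,
s(t_k) = Σ_m Mz_m·sinθ·exp(2πi f_m t_k − π·FWHM_m·t_k) (default FWHM
20 Hz), sampled at the frame midpoint.  The 64 phase encodes of a frame
are not simulated individually; their cumulative signal depletion is
folded into λ_RF.  Phase encoding is a unitary 2D spatial DFT and
complex Gaussian noise (SD `noise_sigma` per component) is added in
k-space.  Not modelled: coil sensitivity, B0 inhomogeneity,
echo-time/first-order phase (TE 1.2 ms treated as zero-phase),
chemical-shift displacement.

## Quantification pipeline

1. **Zero-fill** spatial k-space ×2 (8×8 → 16×16), zeros placed
   symmetrically around the k-space center, amplitude rescaled so the
   reconstruction at original voxel centers is exactly preserved
   (frozen by a round-trip test).
2. **Reconstruct** by inverse unitary 2D DFT.
3. **Sum over frames** in the complex domain; apodize (default 10 Hz
   exponential line broadening — a Lorentzian convolution that leaves
   every line's AUC invariant); halve the first FID point so the DFT
   approximates the continuous transform by the trapezoid rule (this
   removes the constant spectral pedestal); zero-fill the FID ×4 in
   time (the raw 19.5 Hz/bin grid samples a 20 Hz line only ~2× per
   width, too coarsely for a stable lineshape fit); estimate the
   zero-order phase from the *integrated* dominant peak (dispersion is
   odd about the line center and cancels in the sum, unlike the phase
   of the generally off-center maximum bin) and keep the real part.
   Magnitude mode is available as a fallback.
4. **Fit** the three lines simultaneously with a constant baseline.
   The lineshape is the *periodized* Lorentzian
   L(f) = (πγ/SW)·sinh(c)/(cosh(c) − cos(2π(f−f0)/SW)), c = 2πγ/SW —
   the closed form (Poisson summation) of a Lorentzian whose tails
   alias on the finite spectral window.  Its area over one spectral
   period is exactly π·A·γ, it reduces to the textbook Lorentzian as
   SW → ∞, and it is what discrete FID sampling actually produces;
   fitting the unperiodized shape instead leaves an unmodelled tail
   floor that biases weak peaks.  Centers are initialized at nominal
   apparent offsets and bounded within ±1 ppm, half-widths within
   [1, 100] Hz, amplitudes ≥ 0.  Solved by trust-region least squares
   with an analytic Jacobian; parameter covariance comes from the
   Jacobian at the optimum, and the AUC uncertainty by first-order
   propagation through π·A·γ.
5. **Readouts**: lac/pyr = AUC_lac/AUC_pyr, flagged unreliable when
   AUC_pyr < 5× its own standard error; nUrea = voxel urea AUC over the
   mean urea AUC of the vascular-reference voxels; ROI values are
   arithmetic means over reliable masked voxels.
6. **z-scores**: per voxel across all animals, z = (x_i − µ)/σ with the
   sample (n−1) standard deviation; zero-spread voxels are masked.
7. **Heatmaps**: corner-aligned bilinear interpolation to anatomical
   resolution (16 → 256 preserves voxel centers exactly every 17th
   pixel).

Against the kinetic closed form the noiseless end-to-end ratio is high
by ≈5–7% across kPL ∈ [0.005, 0.08] s⁻¹.  The bias comes from the
finite 60 s acquisition window and the 4-s midpoint sampling of the
dynamics, not from the spectral fit, and it is characterized (and
bounded at 10%) by the acceptance tests.  Because it is nearly
multiplicative, group fold-changes are affected only at the percent
level.

## Cohort generator

One latent Gaussian "inflammation burden" b per animal drives
everything: log-kPL rises linearly in b (brain voxels only; vascular
voxels keep kPL = 0), the ordinal 0–6 disability score follows an
ordered-logit link (with a fixed all-mass-at-zero law for arms designed
to show no impairment), the enhancing-lesion volume and nine ex vivo
markers follow linear links with Gaussian noise truncated at zero.  For
two linear readouts of the latent the implied correlation is available
in closed form, which the tests exploit.  Animals reaching score 4 are
recorded at 4 and flagged censored (euthanasia rule).

A per-animal lognormal delivery scale (SD 0.15, unit mean) multiplies
both injected-compound amplitudes, emulating polarization and transfer
variability; it cancels in lac/pyr and nUrea by construction, which is
exactly why those ratio readouts are used.

The calibrated preset (`presets/cpz_eae.yaml`) encodes a four-arm
design — control (n=14), disease (n=12), disease+DMF (n=11),
disease+FTY720 (n=14) — with designed contrasts: lac/pyr 2.1× up in
disease, 1.31×/1.35× decreases under the two treatments (implemented
through group burden means and the log-kPL slope ln 2.1), mean
disability scores 2.6/1.1/0/0 (logit offsets calibrated by root
finding on the censored expectation), enhancing volume 5.2×/3.0×/1.0×
relative to a 0.3 mm³ control baseline, and marker fold-changes (PDH
8.1× down, Iba1 7×, CD68 25×, CD3 455×, PDK1 95×, GFAP 3.5× up, etc.).
The printed treatment responses are not jointly monotone in any single
latent ordering (PDH recovers more under DMF than FTY720 while lac/pyr
recovers less; CD68 responds to DMF only), so group-level link
intercepts carry the designed means while the shared latent slope
carries within-group correlation; the strict burden-monotonicity
property therefore holds for shared-link specs, not for the preset's
marker means.  Within-group marker slopes and noise are proportional
to the group mean (0.3 and 0.15 respectively), keeping spreads
realistic across markers whose scales span three orders of magnitude.
Distributional families (lognormal kPL, Gaussian markers) are artifact
choices; only group means ± s.e.m. are constrained by the emulated
design.

## Contrast-enhanced T1 endpoint

Pre/post pairs are single 256×256 slices (20×20 mm² FOV, 0.8 mm
thickness; voxel 0.00488 mm³): a unit-intensity elliptical brain over a
dim exterior, circular lesions scaled by (1 + enhancement fraction,
default 0.5) in the post image, Gaussian noise on both.  Segmentation:
relative difference d = (post−pre)/max(pre, ε) thresholded at
mean + k·SD of a normal-tissue reference region; k = 3 by default (the
study preset uses k = 4 so that false positives — ≈0.13 mm³ of brain at
k = 3 — do not compress the designed control-baseline folds).  Volume
is exactly voxel count × voxel volume.  Control arms carry a small true
enhancing volume (physiological vascular/ventricular enhancement) so
that fold-changes over control are ratios of designed quantities rather
than of segmentation noise floors.

## Statistics

ANOVA + Tukey HSD (studentized-range adjusted, via statsmodels) and
Kruskal–Wallis + pairwise two-sided Mann–Whitney with the two-stage
step-up FDR of Benjamini, Krieger & Yekutieli (Definition 6: stage 1 BH
at q′ = q/(1+q); stage 2 BH at q′·m/m̂0) are both available; which
family applies to which endpoint is configuration, with the ordinal
disability score defaulting to the rank-based family.  The BKY
implementation is checked exactly against both a brute-force
enumeration of the definition and statsmodels' independent
implementation.  Adjusted p-values are q-specific, with
(adjusted ≤ q) ⇔ rejected.  Fold-changes are ratios of group means;
"x-fold decrease" under treatment is (untreated mean)/(treated mean).

Associations: disability-score and enhancement-volume rows are
per-animal Pearson correlations; enzyme/immunofluorescence rows are
simple linear regressions on the four group means, because in the
emulated design the marker assays come from different animal subsets
than the imaging and only group-level pairing exists.

## Problem sizes and determinism

Default test and acceptance runs use the study at its designed sizes
(51 animals) or 50 per arm for Monte-Carlo fold recovery; spectral
fitting covers the masked (brain ∪ ROI ∪ vascular) voxels of the
zero-filled grid.  These sizes give fold-change standard errors of a
few percent, adequate for the self-consistency checks performed.  All
randomness flows from a single master seed through
`numpy.random.default_rng`; equal seeds reproduce k-space data, tables
and CSV outputs byte for byte.

## Limitations

The simulator omits coil/B0 effects, partial-volume anatomy beyond the
block phantom, physiologic urea kinetics beyond delivery+decay, and
longitudinal disease trajectories.  Passing tests therefore establish
the correctness and calibration of the *analysis machinery* under the
stated generative model, not the biological fidelity of that model;
real-data use requires user-supplied masks and will face lineshape and
phase imperfections the simulator deliberately keeps clean.
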