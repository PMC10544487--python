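# Methods

This note records the models behind `rttag`, the defaults and why they were
chosen, and what the desk-scale validation does and does not demonstrate.

## Digital phantom and ground-truth strain

The phantom is a 2-D short-axis slice: a myocardial annulus (end-diastolic
endocardial radius Ri₀ = 20 mm, epicardial Ro₀ = 35 mm) around a blood
pool, on a 176 × 176 grid of 2.0 mm pixels (matching the protocol matrix).
Tissue values are literature-typical for 3 T: myocardium T1/T2 =
1400/45 ms, blood 1900/250 ms, fat 380/100 ms with a −440 Hz chemical
shift; proton densities 0.8 / 0.9 / 1.0. Proton-density maps carry a
1.5-pixel linear partial-volume ramp at every tissue edge; with hard edges,
pull-back interpolation loses several percent of the myocardial integral,
with the ramp the loss stays below 2 %.

Contraction is an incompressible radial map. The inner radius follows
Ri(t) = Ri₀(1 + g(t)·κ) with a raised-cosine activation g(t) that rises
from 0 to 1 over the systolic fraction (0.35 of the cycle) and returns
smoothly; the outer radius preserves wall cross-sectional area exactly.
Contraction onset is delayed 50 ms after the trigger (electromechanical
delay): imaging starts 38 ms after the trigger, and without the delay the
first imaged frame would already carry ≈ −0.01 strain, which would bias
every downstream peak-strain estimate.

**Mid-wall strain is defined materially.** κ is solved in closed form so
that the material circle starting at r_m0 = (Ri₀+Ro₀)/2 = 27.5 mm reaches
r_m(t_es)/r_m0 − 1 = `gcs_peak` (default −0.18) at end-systole. Note that
under an incompressible radial map a material mid-wall point does *not*
stay at the instantaneous geometric mid-radius (Ri+Ro)/2 — at the defaults
the geometric mid-radius ratio would be −0.18 while the material one is
−0.158, or vice versa. Tag tracking measures material points, so the
material definition is the one for which ground truth, `true_gcs`, and the
perimeter of tracked contour points agree to numerical precision.

Optional confounders (rigid respiratory drift, torsion, an epicardial fat
ring, blood-signal suppression) default to off/neutral.

## Sequence simulation

Magnetization is tracked per isochromat in the material frame (Mxy complex,
Mz real) with exact rotation operators and interval-wise T1/T2 relaxation
plus off-resonance precession. The trigger plays: fat saturation (spectral
band ±150 Hz around the fat shift, 110° tip, transverse spoiling, 5.1 ms),
the 1-3-4-3-1 SPAMM block (sub-pulse flips proportional to the weights,
total 90°; inter-pulse gradient lobes impart 2π·x/d_tag of transverse
phase; final crusher; 19.8 ms block duration so that fat-sat + SPAMM +
ramp-up = 38 ms), then five ramp-up pulses with flips α·i/5 at TR spacing.
The readout applies ±30° phase-alternated pulses every TR = 2.62 ms,
samples the echo at TE = 1.1 ms, warps the instantaneous transverse
magnetization to its spatial position (bicubic pull-back at 1 ms
granularity) and takes one phase-encode line of the centered unitary 2-D
FFT. Tag fading and the approach to the bSSFP steady state are emergent,
not imposed; the closed-form steady state
M₀ sinα (1−E1)/(1 − (E1−E2)cosα − E1E2) (after-pulse convention) is used
only as a test oracle.

Frame pacing: the nominal temporal resolution is lines-per-frame × TR =
11 × 2.62 = 28.8 ms and sets the frames-per-window bookkeeping (69 frames
in the 2 s short-axis window, 41 in the 1.2 s two-chamber window). The
sampling plan's per-frame line count (15 at the defaults) sets the actual
per-frame duration in the simulation; the two are deliberately independent
knobs because the printed protocol does not reconcile them.

A "snapshot" acquisition mode evolves the Bloch state identically but
builds each frame's complete k-space from the object frozen at the frame
centre. It serves as the motion-frozen, fully sampled comparator — the
role a breath-hold ECG-segmented acquisition plays in vivo. A literal
fully sampled real-time acquisition would need 176 × 2.62 ≈ 461 ms per
frame and is not a meaningful reference.

Multi-coil acquisition multiplies the object by simulated receive
sensitivities (smooth complex Gaussian profiles on a ring, RSS-normalized)
before the FFT; reconstruction then uses the SENSE-style data term.

## Sampling and reconstruction

Masks retain the central ⌈N/T⌉ PE lines (T = 2) and sample
max(center, round(band/R)) lines per frame: 4 always-on central
calibration lines plus uniformly random band lines drawn without
replacement, redrawn independently per frame (temporal incoherence).
Nominal acceleration is accounted as T × R = 12.

CS solves ½‖M F x − y‖² + λ‖Ψ_d x‖₁ per frame on the truncated-band grid
(acquired pixels 4.0 × 2.0 mm) with a monotone FISTA; Ψ_d are the detail
coefficients of an orthogonal Daubechies-4 wavelet (periodized, 3 levels),
soft-thresholded on the complex magnitude; the approximation band is not
penalized. λ is relative to the per-frame peak k-space magnitude; the
default 1e-3 comes from the packaged sweep (`scripts/calibrate_lambda.py`)
that minimizes RMSE against the fully sampled reference on a seeded static
tagged fixture. SSIM was also computed but prefers the unregularized
zero-filled solution (it scores aliasing as texture), so RMSE was used.
An optional temporal mode replaces the spatial wavelet with joint x-f
(temporal-Fourier) sparsity over the whole frame stack; on the static
fixture it cuts RMSE by ~70 % versus zero-filling, where per-frame spatial
CS manages ~15 %.

Zero-padding restores the full PE matrix by symmetric spectral padding;
low-frequency coefficients are preserved exactly (truncation inverts it
bit-exactly) and no amplitude rescaling is applied, so Parseval energy is
unchanged. The learned enhancer is a single real 2-D convolution kernel
(11 × 5, identity-initialized) trained by gradient descent on
magnitude-normalized (reference, degraded) frame pairs with an
autocorrelation-scaled step. A linear shift-invariant kernel cannot
recreate the truncated outer-band frequencies — on synthesized blur pairs
its optimum is the identity — but trained on aligned static-phantom pairs
(snapshot reference vs CS + zero-pad recon) it learns to undo the
within-band CS attenuation, including the tag harmonic. It is a
desk-scale stand-in for a deep resolution-enhancement network, not a
reproduction of one.

## Strain analysis

Two orthogonal line-tag acquisitions per slice (tags along x and along y,
each perpendicular to its own PE axis) provide the two displacement
components; grid tagging is unsupported by design because outer-PE
truncation destroys the second grid harmonic. The first harmonic is
isolated with a raised-cosine bandpass of half-width 0.7/d_tag centered at
1/d_tag along the tag axis, clipped at the sampled bandwidth. The width
covers the deformation sidebands of a 15 mm wall (~0.53/d_tag at 8 mm
tags); narrower windows (e.g. 0.4/d_tag) demonstrably truncate them and
underestimate peak strain by ~0.015 even on fully sampled data. The
bandpassed spectrum is zero-padded 2× along the tag axis before the
inverse transform — exact sinc interpolation that keeps the carrier
resolved even at 6 mm tags on 2 mm pixels.

Tracking solves, per point and frame, wrapped-phase constancy
(φx, φy)(p) = reference pair by a 2-D Newton iteration seeded from the
previous frame: steps clamped to d_tag/2 (no tag jumping), damped 0.5× in
the second half of the 20-iteration budget (the bilinear Jacobian is only
piecewise continuous and undamped Newton can limit-cycle), convergence at
1e-3 rad residual. Phase gradients use averaged one-pixel wrapped
differences; two-pixel central differences would sit exactly on the π
ambiguity of the default carrier (π/2 per 2 mm pixel). Non-converged
points are flagged, never interpolated.

GCS(t) is the closed-polygon perimeter ratio over the converged subset of
contour points (the same subset at t and 0). The default simulated
mid-wall contour has 48 points (~3.6 mm arcs): independent per-point
tracking noise inflates the perimeter by ~ε²/ℓ per segment, so denser
contours trade polygon fidelity for noise inflation; 48 balances the two
for a 27.5 mm radius. The analysis window is truncated at the first frame
whose tag harmonic falls below 5 % of the DC peak (tag fading reaches that
point ~1.2 s into the 2 s window at 60 bpm, well past peak systole). Peak
GCS is the most negative value of the curve; per-slice peaks average into
the global value.

## Agreement statistics

Implemented from the ANOVA / closed-form definitions: Pearson r (graded
above 0.8 very strong / 0.7 good / 0.6 moderate / 0.3 fair, left-open
bands); through-origin regression slope Σxy/Σx² with a t(n−1) confidence
interval; ICC(2,1) — two-way random effects, absolute agreement, single
measurement — with the F-based 95 % CI (verified against an independent
ANOVA implementation to 1e-10); within-subject CoV = (SD of paired
differences/√2)/|grand mean| × 100; SEM = SD·√(1−ICC) with SD from the
first scan and MDC = SEM·√2·1.96; Bland–Altman mean difference ±1.96 SD.
ICC reliability bands: <0.5 poor, 0.5–0.75 moderate, 0.75–0.9 good, >0.9
excellent; when the point estimate and the CI upper bound fall in
different bands the grade is reported as a range ("good to excellent"),
matching the convention of reporting the estimate alongside its upper
plausibility.

## Experiments and what the validation shows

Cohort drivers simulate subjects with jittered peak strain (uniform
−0.22…−0.14), radii (Ri₀ 18–22, Ro₀ 33–37 mm) and heart rate (rest 55–75,
post-exercise 85–115 bpm), all derived deterministically from a master
seed. The real-time arm uses an 8-coil simulated array (clinical hardware
is a multi-channel array; single-coil remains the recon default) and adds
complex Gaussian k-space noise of SD 0.004 on the unit-M0 scale (image
SNR ≈ 10–15 at the bSSFP signal level of ~0.08·M0 — "moderate"). The
reference arm is the fully sampled snapshot acquisition. Experiments
default to a 96-pixel matrix and a 700 ms window so a cohort runs in
minutes; the repeatability suite runs 8 subjects, the agreement suite 5.

Two systematic effects are worth knowing:

* The real-time 12× arm under-reads peak strain by ~5–10 % relative to the
  motion-frozen reference even without noise — intra-frame motion, PE
  truncation and residual undersampling artifact all smooth the harmonic
  phase. The toolkit reproduces the qualitative behaviour seen in vivo,
  where real-time tagging regresses on segmented tagging with a slope
  below unity, and the tests assert the measured regime (slope 0.85–1.05)
  rather than perfect agreement.
* Six-millimetre tags on 2 mm acquired pixels sit at the technique's
  resolution-limited minimum spacing; recovery there is mask-realization
  sensitive (errors 0.01–0.045). The tag-spacing sweep therefore runs at
  1.5 mm pixels, and the 6 mm case is asserted as a median over three
  mask seeds.

The phantom deliberately omits: through-plane motion, papillary muscles,
blood flow (tags in the pool persist rather than washing out), coil-map
estimation error, trajectory imperfections and physiological heart-rate
variability. Passing tests show the pipeline is internally consistent and
recovers known strain under these idealized conditions; they do not show
robustness to the full complexity of in-vivo data.

## Numerical conventions

Centered, orthonormal FFTs throughout (DC at index N//2); physical
coordinate of pixel i is (i − N/2)·Δ so the annulus centre coincides with
the FFT centre. Degenerate inputs raise `ValueError` (inverted radii,
non-positive tag spacing, constant sequences, zero ICC variance, fewer
than 24 contour points). FISTA falls back to a plain monotone gradient
step whenever the momentum step would raise the objective, and reports
per-frame objective traces; non-converged solves return the best iterate
with `converged=False`.
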