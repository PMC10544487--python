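# rttag — simulation and analysis of highly accelerated real-time myocardial tagging MRI

Real-time SPAMM tagging makes it possible to measure myocardial deformation
without breath-holds or ECG gating — for example immediately after in-room
exercise — but only if a whole tagged frame can be acquired in under ~30 ms.
One published route to that speed combines a balanced SSFP readout with a
12-fold accelerated Cartesian acquisition: the outer half of the
phase-encode (PE) spectrum is never sampled (2×) and the retained band is
randomly undersampled (6×), with tag lines placed perpendicular to PE so
their spectral harmonics survive the truncation. `rttag` rebuilds that
entire measurement chain at desk scale as testable code:

* **phantom** — a short-axis left-ventricle annulus with an analytic,
  incompressible contraction. The material mid-wall circle of reference
  radius r_m = (Ri₀+Ro₀)/2 contracts so that its peak circumferential
  strain is exactly the configured `gcs_peak` (default −0.18), giving every
  downstream stage an exact ground truth.
* **sequence** — Bloch-level simulation of the sequence: spectrally
  selective fat saturation (5.1 ms, 110°), binomial 1-3-4-3-1 SPAMM
  preparation (8 mm tag spacing), five linearly increasing ramp-up pulses,
  then a phase-cycled bSSFP readout (TR/TE 2.62/1.1 ms, 30°, 176×176,
  28.8 ms temporal resolution) that fills one PE line per TR from the
  moving phantom. Tag fading emerges from the magnetization history.
* **sampling** — seeded per-frame PE masks implementing the 2× truncation
  + 6× incoherent random undersampling (nominal acceleration 2 × 6 = 12).
* **recon** — zero-filled baseline, monotone-FISTA compressed sensing
  (orthogonal db4 wavelet sparsity; optional temporal x-f joint sparsity;
  optional SENSE-style multi-coil data term), spectral zero-padding back to
  the full PE matrix, and a small trainable convolutional deblurring model.
* **strain** — harmonic-phase (HARP) analysis: raised-cosine bandpass
  around the first tag harmonic, Newton phase-constancy tracking of
  mid-wall contour points from two orthogonal line-tag acquisitions, and
  mid-wall global circumferential strain GCS(t) = P(t)/P(0) − 1 from the
  tracked polygon perimeter.
* **stats** — Pearson r with ordinal grading, zero-intercept regression
  with t-based CI, ICC(2,1) with F-based CI and graded reliability,
  within-subject CoV, SEM / minimal detectable change
  (MDC = SD·√(1−ICC)·√2·1.96), and Bland–Altman limits of agreement.
* **workbench** — cohort drivers mirroring the clinical study designs:
  scan/re-scan repeatability and reference-vs-real-time agreement over
  simulated subjects with jittered contractility, geometry and heart rate,
  plus the exercise target-heart-rate helper (220 − age) × 0.85.

## Worked example

```python
import numpy as np
from rttag import (PhantomConfig, build_phantom, SequenceProtocol,
                   make_sampling_plan, acquire_series, timing_summary,
                   cs_recon, zero_pad_enhance, measure_gcs, circle_contour)

cfg = PhantomConfig()                      # 176 px, 2 mm, gcs_peak = -0.18
tissue, motion = build_phantom(cfg)
prot_x = SequenceProtocol(tag_axis="col")  # vertical tag lines
prot_y = SequenceProtocol(tag_axis="row")  # horizontal tag lines
frames = timing_summary(prot_x).frames_per_window   # 69 frames in 2 s

plan_x = make_sampling_plan(176, 2, 6, frames, seed=11)   # 12x
plan_y = make_sampling_plan(176, 2, 6, frames, seed=12)
ks_x = acquire_series(tissue, motion, prot_x, plan_x)
ks_y = acquire_series(tissue, motion, prot_y, plan_y)

sx = zero_pad_enhance(cs_recon(ks_x, plan_x, iterations=40), 176)
sy = zero_pad_enhance(cs_recon(ks_y, plan_y, iterations=40), 176)
curve, _ = measure_gcs(sx, sy, circle_contour(27.5, 48), prot_x.d_tag)
print(f"peak mid-wall GCS: {np.nanmin(curve.gcs):+.4f}")
```

Output:

```
peak mid-wall GCS: -0.1741
```

i.e. the full 12×-accelerated pipeline recovers the programmed peak strain
of −0.18 to within 0.006 on the noise-free default phantom — tracking
error, residual undersampling artifact and the ~38 ms trigger-to-imaging
delay account for the difference. A fully sampled motion-frozen reference
recovers −0.1806.

The `rttag` console script exposes the same pipeline from the shell
(`rttag simulate`, `rttag recon`, `rttag strain`, `rttag stats`,
`rttag experiment`); see `rttag --help`.

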