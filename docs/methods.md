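# Methods

## Signal model

The package treats a high-speed video of beating cilia as a stack of
grayscale frames `I(x, y, t)` sampled at `fps` Hz. Beating cilia modulate
the light reaching each pixel approximately periodically, so the pixel model
underlying both the estimators and the synthetic generator is

    I(x, y, t) = B(x, y) + Σ_r M_r(x, y) · A_r · sin(2π f_r t / fps + φ_r(x, y)) + ε

with a static background `B`, region masks `M_r` with beat frequency `f_r`
and amplitude `A_r`, a metachronal phase ramp `φ_r` (neighboring cilia beat
with a spatial phase lag; modeled as a linear ramp of stated wavelength and
direction), and i.i.d. Gaussian sensor noise `ε ~ N(0, σ²)`, followed by
quantization to the sensor bit depth (round half away from zero, clip to
`[0, 2^bits − 1]` — stated so tests can be bit-exact) and, optionally,
per-frame cumulative translation (drift). Per-pixel signal-to-noise ratio is
`A²/(2σ²)`.

## Spectral estimation

Per-pixel spectra use the first `N` frames (default 1000 — a typical
analysis window at 500 fps), per-pixel mean removal, a rectangular window,
and the one-sided normalization `|DFT|²/N` with doubling of non-DC,
non-Nyquist bins, under which `Σ_f P(f) = N · var(x)` per pixel (Parseval).
No taper is applied: the estimators locate a peak rather than estimate band
power, and the rectangular window keeps on-grid lines exactly on one bin,
which the test suite exploits. Pixels are analyzed independently; no spatial
smoothing of the PSD is applied.

The analysis band defaults to 1–30 Hz: below 1 Hz live DC and drift
leakage, above 30 Hz nothing physiological; clinical beat frequencies
(~8–12 Hz) sit well inside. All argmax tie-breaks go to the lowest
frequency, for determinism.

* **Mean-PSD peak**: pixel-averaged PSD, argmax within the band. Because
  power scales with `A²`, regions with larger intensity swings dominate:
  two equal-area regions at amplitudes 20 and 10 put the peak on the
  higher-amplitude region's frequency.
* **Dominant-frequency map / histogram**: per-pixel argmax within the band;
  pixels with temporal variance below `variance_floor` are undefined
  (default floor 0 — every pixel analyzed, since no principled mask rule
  exists without segmentation). Histogram bins are centered on multiples of
  the bin width (default: the grid spacing), so on-grid frequencies land on
  bin centers; the reported CBF is the modal bin center, with the pixel
  median and weighted mean emitted alongside since the choice of summary is
  a convention, not a fact about the data.
* Reported spectral values are grid frequencies (resolution `fps/N`,
  0.5 Hz at the defaults). A quadratic peak-interpolation refinement exists
  but is off by default: sub-bin precision from three-point parabolas is
  easy to over-read on noisy data.

## Manual-count emulation

The observer protocol is mapped onto the ROI-mean intensity trace: smoothing
by a centered moving average (default width 5 frames), local maxima with a
minimum prominence (default 10 % of the smoothed peak-to-peak range) as
"maximal bend" landmarks, `frames_elapsed` from the first landmark to the
tenth-following one, and the closed form `CBF = fps/frames_elapsed × 10`.
The defaults are exposed and logged; they are detector parameters, not
claims about observer behavior — the ROI-mean trace is a declared proxy for
what a human watches. For integer-period traces the emulation is exact;
otherwise landmark rounding bounds the error by ≈ `f²/(fps · n_beats)`
(~0.017 Hz at 9.2 Hz, 500 fps, 10 beats). Sampled sinusoid maxima that fall
between frames make individual landmark spacings jitter by one frame; the
10-beat span averages this out.

## Stabilization

Registration is translation-only against a fixed reference frame (default:
first frame), estimated by phase correlation — not consecutive-pairwise
chaining, which accumulates error in the estimate itself. Estimated shifts
are rounded to integers by default, applied as exact index remaps, and the
output is cropped to the maximal region valid in every registered frame, so
no fill values enter the spectra (fill would add broadband artifacts).
Subpixel refinement (upsampled cross-correlation plus bilinear warping) is
available behind a flag. Phase correlation needs static texture to lock
onto; on a featureless background the estimate is undefined, which is why
the synthetic drift fixtures use a textured background (as a real cell field
is). Wraparound ambiguity limits detectable displacement to half the frame;
drift large enough to empty the overlap region is an error, not a silent
crop.

Motion extraction subtracts each pixel's temporal mean image, removing the
static background exactly and touching only the DC bin of the spectrum.

## Cohort statistics

Long-format input: one row per (subject, recording, method) with a CBF in
Hz. Per method and group the report computes the median and IQR; quartiles
use inclusive linear interpolation, and the rule is stated in the report
metadata because conventions differ visibly at small n. The "actual median
difference" is control minus case. Routing: one-sample Kolmogorov–Smirnov
against a normal with the sample's own mean/SD (no Lilliefors correction),
normal at p > 0.05; Welch's *t* (unequal variances, Welch–Satterthwaite df)
when both groups pass, else a one-sample Wilcoxon signed-rank test of the
case group's values against the control group's median — the hypothesized
value that makes a one-sample test a two-cohort comparison. The Wilcoxon
p-value is exact by dynamic-programming enumeration over signed mid-ranks up
to n = 25 (correct under ties, where textbook tables are not), normal
approximation with continuity and tie corrections above. Correlations
against the manual method are computed on per-recording pairs (no
per-subject averaging), Pearson when the routing flag is parametric,
Spearman otherwise, pooled across groups and also per group.

Statistics whose preconditions fail on the data at hand (n < 5 for KS, zero
variance, constant pairs) are reported as `None` with a note; descriptive
summaries are always produced. This lets degenerate but legitimate inputs —
e.g. a summary-level table carrying one constant value per arm — flow
through the report builder.

## Synthetic cohorts and the validation study

`simulate_cohort` draws each recording's true CBF from its group's
distribution — point mass, `normal(mean, σ)`, `normal_iqr(median, IQR)`
with `σ = IQR/1.349` (cohorts in this field are summarized by medians and
IQRs, so the generator accepts exactly those), or uniform — and renders each
recording with a centered ciliated rectangle covering half the field. One
study seed fans out to per-recording child seeds via
`numpy.random.SeedSequence.spawn`; a fast path emits only ROI-mean traces,
and a lazy path renders frames on first use so a cohort never holds all
frames in memory.

The standard validation study (`validation_cohort_config`) is a 50-recording
two-group cohort: 30 patient recordings (6 subjects × 5) at
CBF ~ N(9.2, 0.5) Hz and 20 controls (4 subjects × 5) at N(11.1, 0.5) Hz —
the slow-vs-normal separation characteristic of a motile-ciliopathy cohort —
rendered at 500 fps, 1000 frames, 40 × 40 px, amplitude 20 over noise σ = 4
(SNR 12.5). The 40 × 40 field keeps a full 50-recording run in seconds
while leaving ~800 ciliated pixels per recording, far more than the spectral
averaging needs.

### What the generator does not emulate

Real recordings contain non-sinusoidal beat waveforms (harmonics), mucus and
debris occlusion, focus drift, illumination flicker, heterogeneous per-cell
frequencies within a patch, and observer variability in ROI placement.
Passing tests therefore demonstrate correctness of the numerics and the
protocol arithmetic under the stated model — not robustness to everything a
clinical sample can do. The cohort-level conclusions (group separation,
method agreement) are upper bounds: synthetic noise is the only error
source, so correlations near 0.99 here correspond to substantially lower
values on patient data.

## Numerical and design choices

* RAW interchange is defined as headerless frame-major unsigned
  little-endian samples plus a plain-text `key: value` sidecar (width,
  height, bit depth, fps, frame count) — the simplest bit-exact carrier for
  camera dumps that have no self-describing header. 8- and 16-bit payloads
  are both supported.
* PNG sequences order by the numeric suffix in the file name, never by
  directory listing; color inputs collapse by Rec. 601 luma weights (a
  degenerate path for monochrome cameras, but inputs must not crash).
* fps is user-supplied metadata for TIFF/PNG sources; no vendor tags are
  parsed.
* Drift in the simulator is realized by rendering on a canvas padded by the
  drift extent and moving the sampling window, so no fill values enter the
  frames and integer drift is exactly invertible — which is what makes the
  stabilization recovery tests equality tests rather than tolerance tests.
* Frame rotation by multiples of 90° is an index permutation (lossless);
  other angles use bilinear interpolation with zero fill.
* The per-method analysis settings (frames, band) are applied identically
  across methods in the pipeline, so method comparisons are on the same
  inputs by construction; per-recording failures are logged and counted,
  never silently dropped.

## Known limitations

* Translation-only registration cannot correct rotation or deformation of
  the sample; the transform class is a deliberate scope boundary.
* The histogram estimator reports the modal bin, which is sensitive to bin
  placement for near-tied modes; median and weighted mean are emitted for
  that reason.
* The emulated manual count operates on the ROI-mean trace; where cilia
  within the ROI beat at different frequencies the trace superposes them and
  the landmark detector follows the dominant component.
* The exact Wilcoxon enumeration is O(n · Σrank), fine to n = 25; beyond
  that the normal approximation is used (agreement within 0.01 at n = 20 is
  covered by tests).
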