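# Methods

## Scope and intent

`synergidca` quantifies synergid-cell calcium oscillations from ratiometric
(YFP/CFP) FRET time-lapse imaging of pollen tube reception. Because raw
confocal recordings of these events are not bundled with the package, every
stage is exercised against a synthetic data generator with explicit ground
truth: the generator is first-class, tested code, and all quantitative
claims in the test suite are claims about the method's behaviour under the
generator's stated conditions.

## Trace model

A ratio trace is

    ratio(t) = b + Σₖ Aₖ · g(t − tₖ) + ε(t)

- **Baseline** `b = 1.0` ratio units. The absolute ratio scale of YC3.60
  traces is instrument-dependent and no absolute calibration is attempted;
  all downstream statistics are either relative (prominences, intervals) or
  compared only across schemes simulated on the same scale.
- **Transient kernel** `g` is a causal difference of exponentials with rise
  5 s and decay 20 s, normalised to unit peak so `Aₖ` is the transient
  amplitude in ratio units. The waveform of a synergid calcium transient is
  not characterised at 10 s sampling; this kernel was chosen as the
  simplest causal shape whose transients are resolvable at the 10 s frame
  interval.
- **Onsets** `tₖ` follow a renewal process with gamma-distributed
  inter-transient intervals, shape 4, mean set by the genotype preset.
  Shape 4 (CV = 0.5) gives the visibly quasi-periodic but irregular
  oscillations seen in recorded traces; a Poisson process (shape 1) looks
  too erratic and a near-deterministic clock (shape ≫ 10) too regular.
- **Amplitudes** `Aₖ` are lognormal with preset mean and CV 0.3.
- **Baseline noise** `ε(t)` is Gaussian with stationary SD 0.02 ratio
  units, temporally correlated by a Gaussian smoothing kernel of σ = 1.5
  frames (15 s at the 10 s interval), renormalised analytically so the
  stationary SD is exact. The correlation reflects what ROI-averaged ratio
  baselines actually do: averaging hundreds of pixels suppresses white shot
  noise, and the residual wobble (focus drift, cytoplasmic movement) is
  slow. This matters for detection: the trace-relative prominence
  thresholds (below) assume the noise floor of a trace occupies a narrow
  prominence band, which is true for smooth baselines and false for
  frame-white noise. With white noise of the same SD, the 5× rule admits
  large numbers of false transients on sparsely oscillating traces.
- **Duration** is drawn uniformly from 16–58 min, the observed range of
  pollen tube–synergid interaction times; acquisition uses a 10 s frame
  interval with 6 pre-contact baseline frames and t = 0 at the first
  post-contact frame.
- **Terminal burst**: with preset probability the interaction ends in
  rupture, modelled as a final transient of 3× the mean amplitude placed
  30 s before trace end; in a simulated synergid pair the burst appears in
  the receptive cell and, simultaneously and at equal amplitude, in its
  sister cell (calcium floods the surviving synergid at rupture).

Interval draws, amplitude draws, duration, noise and the burst decision use
independent child streams of one master seed, so trace-level ground truth
is invariant to image-noise settings.

## Genotype presets

Only the wild-type frequency (one transient per minute) is a published
number; the other presets make the published qualitative contrasts
quantitative and are deliberately conservative:

| preset                 | mean interval | amplitude (× wild type) | burst p |
|------------------------|--------------:|------------------------:|--------:|
| `wildtype`             |          60 s |            1.0 (= 0.5)  |     0.7 |
| `fer_lre_female`       |        1200 s |                    0.25 |     0.0 |
| `myb_pollen`           |         120 s |                    0.8  |     0.0 |
| `interspecific_lyrata` |          60 s |                    0.8  |     0.0 |
| `interspecific_pumila` |          60 s |                    1.0  |     0.0 |

The *fer*/*lre* preset encodes "an occasional transient, markedly less
intense"; the *myb* preset a clearly lower frequency at comparable
intensity; the interspecific presets share the wild-type frequency, with
*A. lyrata* slightly less intense and *O. pumila* indistinguishable. Only
orderings across schemes are asserted anywhere, never absolute amplitudes.

## Imaging scene

Each frame places two hexagonal synergid cells in a 64×96 px field. Inside
a cell the CFP expectation is `cfp_gain·B(x,y)` and the YFP expectation
`yfp_gain·B(x,y)·ratio(t)`, where `B` is a smoothed distance-to-wall
profile spanning 0.6–1.0 — expression is fairly uniform within a cell, and
the gentle gradient keeps intensity curvature below the bright-outlier
threshold of the extraction defaults so the cleanup passes are no-ops on
clean data. The pollen tube is a Gaussian blob in the RED channel moving
from the field edge to the micropylar gap between the cells; a configurable
fraction of RED is added to CFP and YFP (spectral bleed-through). Scene
motion (cumulative per-frame drift) is applied to the expectation, then
detector effects: Poisson shot noise (scaled by counts-per-photon),
Gaussian read noise, and salt-and-pepper speckle. The measurement ROIs
returned with a render are inset 3 px from the cell outline, as a user
would draw them, which also keeps small median-filter footprints inside the
cell.

Stacks are written as multi-page TIFF (T→C page order, CFP/YFP/RED,
uint16 by default) with a YAML sidecar carrying channel roles and the frame
interval; ROIs are YAML polygon files (0-based pixel coordinates, origin
top-left, pixel-centre membership).

## Extraction chain

Pipeline order is **drift → pollen subtraction → cleanup → ratio**.

- **Drift correction** registers every frame to frame 0 by the translation
  maximising cross-correlation of the CFP channel (phase correlation,
  1/10 px upsampling); the same offset is applied to all channels. All-zero
  frames produce a warning and zero offset.
- **Pollen subtraction**: `CFP′ = max(CFP − k·RED, 0)` and likewise YFP.
  The default coefficient k = 1 subtracts the recorded pollen fluorescence
  directly; when the true bleed fraction is known (as for rendered scenes)
  k equal to that fraction removes the contamination exactly.
- **Cleanup**: per frame and channel, a bright-outlier pass (replace a
  pixel by its (2r+1)² neighbourhood median only if it exceeds that median
  by > 50 counts; r = 2) followed by a 3×3 median despeckle, reflection
  padding at edges. Cleanup acts on channel images *before* ratioing
  because median-filtering a ratio image near a vanishing denominator is
  unstable; a `clean_after_ratio` switch restores the post-ratio variant
  for fidelity experiments. Because both passes are order statistics and
  YFP is pixelwise proportional to CFP inside a cell, cleanup is exactly
  ratio-preserving on noiseless renders.
- **Ratio**: per-pixel `YFP / max(CFP, floor)` averaged over the ROI (the
  ratio-image convention; an ROI-mean-ratio alternative is a config
  switch), floor = 1 count. Frames with > 50 % of ROI pixels at the floor
  are flagged low-signal rather than dropped. The time axis is shifted so
  the annotated contact frame is t = 0; contact is input metadata, not
  computed, since in practice it is set by red-channel tracking, first
  transient, or synergid deformation depending on the cross.

## Peak detection

Prominence of a local maximum is its height above the larger of the two
reference troughs separating it from higher terrain: scan outward until a
strictly higher sample or the trace end, take the minimum of each scanned
span (nearest minimum on ties). Flat plateaus count once, at their centre
sample (left-centre on even plateaus); endpoints are never peaks. A
`tie="inclusive"` switch makes equal-height samples terminate the scan, for
users who read "equal or greater" literally; the default matches the
standard prominence algorithm, under which equal-height peaks merge via the
plateau rule only when adjacent.

Detection is trace-relative: with m the minimum prominence among all local
maxima of the trace, amplitude analyses retain prominence > 1.1·m and
frequency analyses > 5·m. Consequences, by design: the minimum-prominence
peak is always excluded; a trace with a single local maximum retains
nothing (a `keep_singleton` escape hatch exists, off by default); there is
no absolute threshold or extra smoothing — noise control comes entirely
from the multiplier, and the lenient 1.1× rule intentionally admits small
noise blips so that weakly oscillating traces still contribute points.
Per-peak intensity defaults to absolute height (ratio at the peak), with
prominence as the alternative convention; both are reported.

`min_separation_s` defaults to 0 (no published minimum separation); when
set, the more prominent peak of a violating pair wins greedily.

## Cohort statistics

The observational unit is the peak: per-trace values are pooled across the
replicates of a crossing scheme, reproducing the published peak-count
design (which is pseudoreplicated — peaks within a trace are correlated; a
`per_trace_mean` flag provides replicate-level pooling for users who want
it). Traces are ranked by mean retained-peak prominence (peakless traces
rank 0, stable order on ties) and the representative trace is the
⌈n/2⌉-th of the ascending order (lower median on even n). Boxplot
summaries use linear-interpolation quartiles, whiskers at the most extreme
datum within 1.5·IQR of the box, and notches at median ± 1.57·IQR/√n.
Schemes are compared by classical one-way ANOVA at α = 0.05 with Tukey HSD
post-hoc pairwise comparisons (the specific post-hoc procedure is a
declared choice; any multiple-comparison-of-means method could be swapped
in).

## Problem sizes and numerical choices

The test suite and acceptance script run the study at the sizes the
analysis design calls for — 10 replicates per scheme at full 16–58 min
durations for trace-level statistics — while imaging round-trips use
shorter (2.5–5 min) renders, which exercise every pixel-level code path
identically at a fraction of the cost. Monte-Carlo rate checks use 200
replicates of a fixed 600 s trace. Noiseless round-trip exactness is
asserted at 10⁻⁶ relative error (achieved: ~10⁻¹⁴); drift recovery at
±0.5 px (phase correlation upsampling is 0.1 px); renewal-rate recovery at
±15 % (the gamma renewal process undershoots t/μ by (CV²−1)/2 ≈ 0.4
transients per trace, well inside that band).

## Known limitations

- The generator emulates oscillation statistics and imaging artifacts, not
  biology: no photobleaching, chromatic aberration or 3-D optics; no
  pollen-tube growth mechanics or synergid deformation; cell geometry is
  static. Passing tests show the measurement chain recovers known inputs
  under these conditions, not that the presets are calibrated to any real
  cross beyond the wild-type frequency and the published orderings.
- Amplitude scales are uncalibrated; only cross-scheme orderings are
  meaningful.
- The trace-relative 5× rule depends on the noise floor occupying a narrow
  prominence band; on data with frame-white noise it admits false
  transients on sparse traces, and users analysing such data should smooth
  or clean at the image stage first.
- Pooling peaks across traces understates between-replicate variance in
  the ANOVA; use `per_trace_mean` for conservative inference.
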