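# Methods

`respiquant` quantifies four read-outs of respiratory motor circuit
function in perinatal mice: phrenic-nerve burst output, breathing
behaviour from whole-body plethysmography, phrenic motor neuron soma
topography, and dendritic orientation. This note documents the models
behind each stage, the parameters that matter, what the synthetic-data
generators do and do not emulate, and the numerical choices made where
the underlying experimental workflows leave the design open.

## Phrenic-nerve burst analysis

Suction-electrode recordings of the phrenic nerve are multi-unit voltage
traces (arbitrary-but-consistent µV; absolute gain is not calibrated).
The trace is mean-subtracted and rectified, then two envelopes are
derived, both with causal rectangular windows (zero-padded at the start):

* a **detection envelope**: moving average over `smooth_s` (default
  50 ms), robust to the gaps between individual motor-unit spikes;
* an **amplitude envelope**: moving time-integral over `window_s`
  (default 2 s, long enough to span an entire burst), in µV·s.

**Burst definition.** The baseline is the median of the detection
envelope; the threshold adds `threshold_k` (default 4) robust standard
deviations (1.4826 × MAD). Supra-threshold epochs separated by less than
`merge_gap_s` (default 1 s) are merged, with the pause counted as part of
the burst; merged events shorter than `min_duration_s` (default 50 ms)
are discarded. Because the causal moving average smears epoch edges by up
to `smooth_s`, each epoch's bounds are refined to threshold crossings of
the *unsmoothed* rectified trace before merging; on a rectangular test
burst this recovers onset and offset to one sample. The threshold
constant `k` is a calibrated parameter of this implementation, not a
published value — the source workflows do not state their baseline
estimator. MAD = 0 (flat envelope) falls back to a machine-epsilon-scaled
threshold so that an exactly quiet trace yields no bursts.

**Burst metrics.** Burst *activity* is the maximum of the integrated
envelope within the burst (for a rectangular burst of amplitude A and
duration d < 2 s this equals A·d exactly); *normalized activity over
time* divides each burst's activity by its duration. Up to `max_bursts`
(default 7) bursts, spaced evenly through the recording, enter the
amplitude metrics (a seeded random-selection mode is available);
frequency uses every detected burst over the recording duration.
Frequency is reported but is intrinsically variable in perinatal
preparations, so no stability statistics are built on it.

**Disinhibited spinal activity.** Under GABA_A/glycine blockade the
nerve expresses long, low-amplitude spinal-network events alongside
respiratory bursts. Events are partitioned purely by duration
(`spinal_min_duration_s`, default 2 s); spinal output is summarised as
total event duration as % of recording time plus the mean normalized
activity of the events.

## Plethysmography

Flow traces (ml/s) follow the convention that inspiration is negative.
Breaths are delimited by zero crossings, but raw sign changes shatter
under noise, so segmentation uses a Schmitt trigger: inspiration is
confirmed when flow falls below −h, expiration when it rises above +h,
with the phase boundary refined back to the enclosed zero crossing. The
default h is twice a robust noise-SD estimate (scaled MAD of first
differences). A candidate breath whose *mean* inspiratory deflection
stays within the band (|∫flow| < h × inspiratory duration) is rejected
as noise — without this, rare noise excursions below −h during pauses
register as phantom breaths, which matters most in gasping traces with
long quiet gaps. Terminal cycles whose inspiration never completes are
dropped.

Tidal volume (TV) is the magnitude of the trapezoidal integral of flow
over the inspiratory phase. Breathing frequency is period-based
(60·n / Σ periods of the analysed breaths), which remains correct when
resting breaths are selected from discontinuous quiet epochs; minute
ventilation = frequency × mean TV holds exactly by construction.
Resting-breath selection excludes breaths overlapping a movement-artifact
mask and *flags* (rather than silently passes) selections below
`min_breaths` (default 10). Per-animal metrics can be expressed as fold
of the mean of two littermate controls. Chamber physics
(pressure-to-flow calibration) is out of scope; inputs are already
flow-calibrated.

## Soma topography

Coordinates are relative to the midpoint of the spinal cord midline
(x = 0, y = 0), x mediolateral and y ventrodorsal with **dorsal
positive** — a ventral shift is Δy < 0. Sections are pooled by isotropic
rescaling onto a standardized cord in which the midline-to-lateral-edge
distance is 390 µm (the e13.5 empirical reference); scaling uses the
mediolateral half-width only, the one dimension with a stated reference.
Left-side somas (negative x in raw tables) are mirrored onto the right
hemicord and both sides are pooled. Half-widths are applied at
per-embryo granularity (scalar or embryo→half-width mapping): the fixed
table schema carries no section identifier, and the synthetic generator
distorts all of an embryo's sections equally.

Group topography is a **fixed-bandwidth isotropic Gaussian KDE**
(default bandwidth 15 µm, 10 µm cells, grid padded by three bandwidths)
renormalized to integrate to 1. Groups are compared by the Pearson
correlation of density grids co-evaluated on a common lattice — the
published "correlation analysis of positional coordinates" does not
state its estimator, so this density-grid correlation is one defensible
interpretation, chosen because it is scale-aware and separates
same-position from shifted groups cleanly; it is labelled as such in
outputs. Statistical units for group tests are per-embryo mean
positions, never individual somas.

## Dendritic orientation

A radial grid of eight 45° octants is centred on the phrenic cell-body
cluster. Zero degrees is the ray from the midline through the centre of
the cell bodies (pointing laterally); angles increase counterclockwise
toward dorsal, and left-hemicord images are mirrored automatically so
the frame is side-invariant. Cell-body fluorescence is deleted by
zeroing a disc of `body_radius_um` (strict inequality: a pixel exactly
at the radius survives; the masked disc is also excluded from profile
sums, so intensity added strictly inside it can never change fractions).
Integrated intensity ("IntDen" — the plain pixel sum) per octant is
divided by the total unmasked intensity; octant boundaries are half-open
([45k°, 45(k+1)°), boundary angles to the higher octant). Region
summaries: dorsolateral = 0–90°, ventral = 180–225° plus 315–360°.
No background subtraction is applied by default. The grid's outer extent
defaults to the full image (configurable `outer_radius_um`).

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *structure* of each modality with known
ground truth; they are phenomenological, with no biophysical model of
rhythm generation.

* **Nerve traces** — bursts of Poisson motor-unit spikes (biphasic 1 ms
  sine templates, not delta functions, so rectification behaves like
  real multi-unit data; lognormal amplitude jitter, random polarity) on
  Gaussian noise. Defaults encode a clean suction recording: 40 µV mean
  spike amplitude, 300 Hz within-burst unit rate, 0.6 s bursts, 8 s mean
  period with CV 0.3 (burst timing is irregular in perinatal
  preparations), 0.2 µV noise SD, 5 kHz sampling. 5 kHz rather than an
  acquisition-grade 50 kHz keeps desk-scale runtimes; envelope analysis
  is insensitive above ~2× the 3 kHz analogue band edge. `amplitude_scale`
  multiplies every spike amplitude (< 1 emulates reduced recruitment);
  the within-burst waveform therefore scales exactly linearly, but the
  2 s integral also carries the (unscaled) noise floor, so the measured
  activity reduction for scale s sits slightly below 100(1−s)% — about
  65–69% for s = 0.3 under the defaults. Not emulated: electrode drift,
  movement artifacts, single-unit identity, respiratory-rate maturation.
* **Flow traces** — one negative and one positive half-sine per breath,
  each rescaled on the sample grid so the discrete trapezoidal area
  equals the breath's tidal volume *exactly* (closed-form oracle for TV
  tests). Defaults: 150 breaths/min, CV 0.1, 0.05 ml TV, inspiratory
  fraction 0.35, 0.005 ml/s noise, 1 kHz sampling. Gasp mode stretches
  roughly a third of cycles 2–5× and deepens them 1.5–2.5×. Not
  emulated: sighs/apneas as distinct event classes, chamber resonance,
  baseline drift.
* **Soma tables** — per-embryo 2D Gaussian clusters (default centroid
  (240, −140) µm, SD 40 µm, 3 embryos × 400 somas) at
  `centroid + shift`, written raw: scaled by measured-half-width/390 and
  with left somas negated, so standardization must invert the distortion
  (round-trip tested to float tolerance). Not emulated: rostrocaudal
  structure, section-to-section size variation within an embryo,
  non-Gaussian pool shapes.
* **Dendrite images** — background + clipped Gaussian noise + cell-body
  disc + angular rays, each ray depositing its configured total
  intensity in a Gaussian angular band (a von-Mises-like profile) out to
  its radial extent, normalized over in-bounds pixels (clipping beyond
  the image edge is warned about). Not emulated: branching, fasciculation
  texture, depth attenuation.

Passing tests therefore demonstrate correctness of the *quantification*
pipeline under controlled conditions — detection boundaries, closed-form
identities, parameter recovery — not robustness to every artifact of
real recordings; thresholds (`threshold_k`, hysteresis) remain the
knobs a user would tune on real data.

## Statistics

Groups are compared with the unpaired two-tailed Student's t-test
(pooled variance; Welch behind a flag), df = n_A + n_B − 2, on
per-animal values. Zero pooled variance with equal means returns t = 0,
p = 1; with unequal means it is rejected as degenerate. Significance
stars at 0.05/0.01/0.001/0.0001; no multiple-testing correction is
applied (none is applied in the workflows this mirrors). Proportion
summaries report both the unweighted per-animal mean percentage and the
pooled (summed-counts) percentage. Box summaries use linear-interpolation
quartiles plus the mean.

## Problem sizes and tolerances

The test and acceptance workloads are sized for a single CPU: burst
parameter-recovery uses 20 traces of 60 s per arm; topography recovery
uses 10 repeated cohorts of 3 embryos × 400 somas; density comparisons
use 500-soma single-embryo groups on a 20 µm bandwidth; dendrite checks
use 256×256 fields. Closed-form identities are asserted to one or two
sample periods (envelope integrals), 0.1% (half-sine tidal volume), or
1% (sector symmetry); stochastic recoveries use the generator's known
sampling error (±10 percentage points for the activity reduction,
±10 µm for the 40 µm shift, r > 0.9 / r < 0.5 for density
correlations).

## Known limitations

* The burst threshold and the breath-inclusion heuristic are calibrated
  to the synthetic conditions; real recordings may need different
  `threshold_k` / hysteresis values.
* Density-grid correlation is an interpretation of an under-specified
  published statistic; its numeric values depend on bandwidth and grid.
* Octant fractions are pixelation-limited near the centre; very small
  body radii (a few pixels) make sector boundaries coarse.
* The spinal/respiratory partition is duration-only; amplitude is not
  used even though spinal events are also lower-amplitude.
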