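# Methods

## Scope and data model

`segfcs` operates on XT line-scan carpets: `counts[channel, line, pixel]`
with two photon-counting channels that split the same fluorescence 50/50.
Time is discretized at the line time (1/line frequency); a line is treated
as sampled instantaneously, so pixel dwell within a line is ignored.  Pixels
and lines are 0-based; line *k* maps to time *k*·line_time.  Metadata
(frequency, pixel size, damage-strip pixel range, damage line range) lives in
a JSON sidecar or explicit config, never in TIFF tags, because tag
conventions are vendor specific.

## Segmentation and zone selection

The carpet is partitioned along time into equal segments per column; the
analysis window starts by default at the first line after damage induction,
and remainder lines after the last full segment are discarded so all
segments share one duration (their correlation curves are then comparable).
The per-segment mean intensity map (columns × segments) is normalized *per
temporal row*: each row is divided by its maximum across columns.  This
highlights relative intensity variation along the scanned line in every row,
so the damage strip is selectable even late in strongly bleached
acquisitions; the alternative (per-column normalization) would flatten
exactly the spatial contrast the map exists to show.  Rows that are entirely
zero are flagged and left at zero.

Classification: a post-damage segment is IN when its normalized intensity is
≥ `in_threshold` (default 0.8) and its column lies in the damage pixel
range; OUT when normalized intensity ≤ `out_threshold` (default 0.5) and its
column is at least one full strip width away from the strip; everything else
is EXCLUDED, as is any segment overlapping the damage-induction lines.  The
thresholds are explicit configuration with logged provenance; a manual label
matrix can replace the automatic rule.  Empty IN or OUT selections raise an
error naming the thresholds.

## Correlation estimator

Per segment, G(τ) at lag k lines is the cross-channel product averaged over
the overlapping range, normalized by the product of the two *segment-local*
channel means, minus one.  Segment-local normalization is the core of
segmented FCS: fluctuations slower than the segment (bleaching, stage or
damage-region motion) are removed from the correlation.  The estimate is
symmetrized over the two shift directions, making it independent of which
channel is shifted.  Lags follow either a linear grid (used by the
brute-force oracle tests) or a multi-tau scheme (default: 8 points per
octave, series binned by 2 per octave, from one line time up to a quarter of
the segment duration — the cap bounds estimator variance).  Zone curves are
plain averages over the selected segments with the across-segment standard
error; segments with fewer than `min_photons` (default 100) detected photons
in either channel are skipped, since the shot-noise error of their G
estimate exceeds order unity and they would only add noise to the average.
Note the across-segment s.e.m. treats segments as independent; columns
closer than the detection-spot diameter share particles, so the s.e.m. is
optimistic by roughly the square root of the number of columns per spot.

## Models and fitting

Correlation models (all with a free offset G(∞)): 2D diffusion
G(∞)+G(1+4Dτ/w₀²)⁻¹, binding G(∞)+G·exp(−τ/τ_B), and their two-component
mixture with F_B = 1−F_D.  The 2D form assumes the axial detection extent is
much larger than the lateral waist w₀.  w₀ is a calibration input (default
0.3 µm in simulations, a typical high-NA confocal value, not an instrument
measurement) and is never fitted.  Fits use bounded trust-region least
squares (lmfit/`least_squares`), parameters non-negative, F_D ∈ [0, 1], the
offset bounded below by −1.  Initialization: offset from the tail mean,
amplitude from the first fitted lag, D from the half-decay lag, τ_B from the
1/e crossing, F_D = 0.5.  The binding model defaults to the restricted range
τ > 20 ms so the fast diffusive decay does not contaminate the dwell-time
estimate.  Weighting is off by default; optional 1/sem² weighting applies
when a curve averages ≥ 4 segments.  Non-convergence raises an error
carrying the residual norm — a failed fit is never returned as numbers.

Kinetics: the damage-region trace is the per-line mean of the channel-summed
counts over the damage pixel range, block-averaged (`bin` lines, default 64).
The accumulation fit holds t_D fixed (known from metadata) and *includes the
pre-damage baseline samples in the fitted window*, where the model is
constant: with a free baseline y_B, the rise-only window leaves y_B and
τ_ACC nearly unidentifiable under realistic noise.  The rise window ends at
the trace maximum by default (overridable).  The decay fit starts at the
trace maximum by default with t₀ fixed.  Characteristic times are bounded
above at 10× the fitted window span; beyond that they are unidentifiable and
the bound keeps pathological fits from returning astronomically large
values.

## Synthetic carpets

The simulator is 2D (x–y plane, matching the 2D fit model): point emitters
take Gaussian steps of per-axis variance 2·D·Δt with reflective walls, the
box extending 6·w₀ beyond the scanned line on each side so the walls do not
deplete the focal region.  After the damage-on time, free particles inside
the strip (an x-interval; default the centred 25-pixel range) bind with
probability 1−exp(−k_on Δt) per line; bound particles are immobile and
unbind with probability 1−exp(−Δt/τ_B).  Binding capacity is unlimited —
accumulation kinetics emerge from k_on/k_off supply dynamics rather than a
prescribed schedule, which keeps the kinetics fits independently testable
against the closed-form trace generator.  Expected photons at pixel p from
particle i are brightness·power·exp(−2((x_p−x_i)²+y_i²)/w₀²); pixel counts
are Poisson draws split per pixel by a binomial into the two channels.
Because the beam sweeps every x position once per line, a particle's
bleaching exposure over one line is governed by its distance from the
scanned line: the per-line bleaching hazard is
bleach_rate·power·exp(−2y_i²/w₀²)·Δt, irreversible.  One seeded stream
drives initial positions and all dynamics; runs are bit-reproducible.

Default parameters mirror the targeted acquisition (1400 Hz, 128 pixels of
97 nm, damage after 1024 lines) and the measured biology (D = 3.8 µm²/s,
τ_B = 0.8 s); k_on = 20 s⁻¹ and bleach_rate = 0.05 s⁻¹ (beam centre, unit
power) are simulator choices — k_on deep enough that the strip visibly
accumulates, bleaching slow enough per dwell that dwell-time estimates are
not truncated (see below).

What the simulator does *not* emulate: axial (3D) detection, triplet/blinking
photophysics, detector afterpulsing, anomalous diffusion, motion of the
damage region, finite binding-site capacity, and PARylation-driven changes
in binding over time.  Passing recovery tests therefore demonstrate
estimator correctness under the stated model, not robustness to every
artifact of live-cell data.

## Benchmark studies (problem sizes)

The validation studies in `segfcs.benchmarks` scale the 5-minute protocol
down to what each estimate needs, keeping the protocol geometry:

* **Diffusion recovery** — D ∈ {1, 3.8, 10} µm²/s, 10 runs each: 23-s
  homogeneous carpets (64 pixels, 150 particles), 16 segments of ~1.46 s,
  ACF averaged over all segments, one-component diffusion fit.  Median |ΔD|/D
  is reported; segments of 1.46 s resolve decays up to ~0.36 s lag, ample for
  τ_D = w₀²/4D ≤ 22.5 ms.
* **Binding recovery** — τ_B ∈ {0.5, 0.8, 1.6} s, 10 runs each: binding-strip
  carpets (128 pixels, 250 particles, no bleaching) cut into 6 segments of
  32·τ_B so the exponential is equally resolved in every condition (max lag
  8·τ_B); automatic IN/OUT selection, binding fit on τ > 20 ms.  The binding
  rate is k_on = 5 s⁻¹: dwell-time *recovery* (apparent ≈ microscopic
  residence) requires that a particle usually escapes the detection spot
  after unbinding — at high k_on the same molecule rebinds within the spot
  and the measured residence time genuinely exceeds the single-event dwell
  time.  For τ_B = 0.8 s the two-component mixture is also fitted in both
  zones for the F_B contrast.
* **Kinetics recovery** — 20 noisy closed-form traces per condition with the
  low-power truths τ_ACC = 5.1 s and τ_DEC = 90 s, noise 5% of the rise
  amplitude.
* **Power ladder** — powers ×1/×2/×4/×8, 5 runs each: 200-s carpets with
  k_on = 50 s⁻¹, τ_B = 0.4 s, bleach_rate = 0.05 s⁻¹.  Trace fits give the
  apparent τ_ACC (fixed 30-s window, so intermediate-power bleaching visibly
  shortens the apparent rise) and τ_DEC (post-peak); the IN-zone dwell time
  is fitted once per power on segment ACFs pooled over the 5 runs (the
  analogue of combining cells), on a fixed early window of 8 × 8-s segments
  starting 15 s after damage, after the recruitment transient and before the
  high-power acquisitions are fully depleted.  The bleach rate is chosen so
  that bleach-per-dwell (bleach_rate·power·τ_B ≤ 0.16 at ×8) stays well
  below 1: in that regime — the regime the measured dwell-time stability
  across powers implies — bleaching drives the intensity decay without
  truncating individual binding events, and τ_B is made shorter than the
  package default so it is well resolved inside 8-s segments.

## Numerical and design choices

* Cross-correlation symmetrization (both shift directions averaged): the
  correlation definition is direction-asymmetric on finite segments; the
  average removes the asymmetry at no cost.
* Multi-tau binning uses photon-count sums; normalized G is invariant to the
  within-bin scale.
* Fit idempotence: refitting from a converged solution reproduces it to
  better than 1e-9.
* Zones are fitted independently; no parameter is shared or constrained
  between IN and OUT.
* Degenerate inputs fail loudly: zero-mean channels, empty selections,
  too-short segments, conflicting segmentation requests and unknown config
  keys all raise errors naming the offending quantity.
* The pipeline is deterministic given the configuration and seed; CSV
  artifacts are byte-identical across reruns.

## Known limitations

* Per-fit standard errors describe a single curve fit and are not comparable
  to across-cell standard deviations.
* The across-segment s.e.m. underestimates uncertainty when adjacent columns
  are averaged (see above); tests that rely on the s.e.m. subsample columns.
* The damage region is assumed stationary in x; motion correction is out of
  scope.
* Dwell times approaching the maximum lag (segment duration / 4) are
  recovered with growing bias; choose segments ≥ 10·τ_B where possible.
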