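# Methods

This note documents the models and procedures implemented in `dyadcoord`,
the parameters that matter and their defaults, the numerical conventions,
what the synthetic-data generator does and does not emulate, and the design
choices made where the design was genuinely open.

## Setting and data model

Two participants (A and B) improvise with their hands on a square table
under an aerial camera. Markerless pose estimation yields, per video frame,
`(x, y, likelihood)` for each of four markers: A-left, A-right, B-left,
B-right. The nominal session is 15 min at 60 Hz (54,000 frames), divided
into five 3-min blocks of varying eyes-open/closed conditions
(closed/closed, open/open, open/closed, closed/open, open/open). Coordinates
are in pixels throughout; no pixel-to-cm calibration is applied (the 85 × 85
cm table size is metadata only), since every downstream measure is either
rank-based or normalized.

## Track conditioning

Samples whose tracker likelihood falls below the p-cutoff (default 0.6) are
treated as missing and bridged by 1-D linear interpolation between the
nearest retained samples (edge gaps take the nearest retained value). We
interpolate rather than drop frames to preserve the fixed 60 Hz grid that
every windowed computation assumes. Coordinates are then median-filtered
with a centered 5-frame window (~83 ms) — the smallest symmetric window that
removes single-frame tracker glitches; the window is configurable. The
cutoff is applied before the median filter so the filter never averages over
known-bad coordinates; the opposite ordering is available by calling the two
operations directly.

## Speed preprocessing

Speed at frame f−1 is the Euclidean displacement between consecutive frames
divided by the frame interval, giving n−1 samples for n frames. Speed (not
velocity) deliberately discards movement direction and form, keeping only
temporal coherence. Preprocessing is three steps, in a fixed order:

1. **Trim** to `expected_frames − 1` samples, dropping surplus from the end;
   shorter series raise an error rather than being padded.
2. **Outlier removal**: samples more than 3 local SDs from the local mean,
   both computed over a centered 1-s window (forced odd: 61 samples at
   60 Hz; SD uses the n−1 normalization), are replaced by linear
   interpolation between the nearest retained neighbours. Statistics are
   computed on the raw series in a single pass. Zero-variance windows flag
   nothing (avoids 0/0). Edge outliers with no neighbour on one side take
   the nearest retained value. The replaced fraction is recorded per series.
3. **Smoothing**: centered moving mean, 0.5-s window (30 samples), with
   shrunken windows at the edges.

The order matters and is tested: smoothing first would smear spikes into
their neighbourhood before detection.

## Maximum correlation vector

Rolling Spearman correlation (average ranks for ties, so each window equals
`scipy.stats.spearmanr` on that window) is computed over centered 5-s
(300-sample) windows at every sample for the four between-participant hand
pairings. Positions whose window overruns an edge, or in which either
series has zero within-window variance, are undefined (NaN). The MCV is the
pointwise maximum over the four pairings (undefined only where all four
are), with the winning pairing recorded. The implementation ranks all
windows vectorially and is verified against a per-window scipy recomputation
to 1e−10.

## Data-sliding significance test

Within a rated moment, surrogate series are built by cutting one
participant's speed series at a uniformly random point in the moment and
swapping the two pieces. Conventions:

- Both hands of the slid participant (default A; configurable — the test is
  asymmetric in principle) are slid **jointly at one cut**, preserving that
  participant's intra-body coupling; only the cross-dyad alignment is
  destroyed.
- 1,000 slides per moment; all defined shuffled MCV values are **pooled
  across slides**, and the threshold is the 95th percentile of the pool
  (linear interpolation between order statistics). Pooling, rather than
  taking per-slide maxima, estimates the distribution of shuffled MCV values
  at a time point, which is the quantity the observed MCV trace is compared
  with.
- The RNG seed is recorded in the output. A moment in which every window is
  degenerate (e.g. perfectly constant speeds) has no threshold and raises a
  dedicated error.

Because a slid series is a rotation of the original, its windows are
circular windows of the original series; ranks are therefore precomputed
once per hand over all circular windows and each slide reduces to an index
shift, making 1,000 slides on a 30-s moment take ~2 s.

## Evidence classifier

For a moment and threshold y (default 0.5), `e_high = Σ (MCV(t) − y)·Δt`
over defined samples above y, `e_low = Σ (y − MCV(t))·Δt` below; the larger
evidence wins. Ties (including the measure-zero case `e_high = e_low`) go
to *high*: the intended application prefers over-detecting candidate
moments of connection. Classification is invariant to uniform time
rescaling, and raising y can only shift evidence from high to low.
Moments must span at least 10 s (enforced at construction and at CSV
parse), must lie within the session, and may overrun the n−1-sample speed
grid by at most the one sample lost to differencing.

Evaluation against human ratings is moment-level by default (one
prediction per rated moment, positive class = high). A sample-level
granularity (every defined MCV sample inside a rated moment scored as
high iff MCV > y) is provided as an alternative; the two answer different
questions and are not interchangeable.

## Normalized symbolic transfer entropy

Ordinal symbolization maps the delay-embedded vector
`(x_t, x_{t+τ}, …, x_{t+(m−1)τ})` to the lexicographic index of its rank
permutation; ties rank the earlier position lower. Ties matter here because
joint stillness produces runs of near-equal smoothed speeds; position-based
tie-breaking keeps the symbol map deterministic.

The plug-in estimate `STE(X→Y) = Σ p(y_{t+δ}, y_t, x_t) ·
log₂[p(y_{t+δ}|y_t, x_t) / p(y_{t+δ}|y_t)]` is computed from empirical
triplet counts over the m! = 6 symbols. Normalization subtracts the mean
STE over `n_shuffles` (default 10, seeded) uniform permutations of the
source symbol sequence and divides by the empirical conditional entropy
`H(y_{t+δ}|y_t)` of the target, yielding values in [−1, 1]; a constant
target (zero conditional entropy) maps to 0 by convention. The shuffle term
removes the small positive bias of the plug-in estimator attributable to
source signal characteristics; the entropy denominator makes values
comparable across signal pairs with different target autocorrelation.

Windowed analysis uses 2-s windows stepped by 0.5 s over the session span
(1,797 windows for a 15-min session). Within each window, both directions
are computed for every between-participant hand pairing (the same four as
the MCV) and every delay τ ∈ {6…15} samples (100–250 ms at 60 Hz) with
prediction step δ = τ — one parameter controls both, treating τ as the
prediction range. The per-window directed value is the **maximum** over
pairings and delays (configurable to the mean over τ), mirroring the MCV's
max-over-pairings logic and the common practice of selecting the most
informative delay. Raw NSTE (possibly slightly negative after bias
subtraction) is reported as-is; values are floored at 0 only inside the
asymmetry ratio `(a − b)/(a + b)` (0/0 → 0), which keeps the index bounded
and antisymmetric.

A 2-s window yields ~100 symbols against a 6×6 conditioning space, so
single-window estimates are noisy; this is why values are bias-corrected,
why the asymmetry index is interpreted over runs of windows rather than
single windows, and why display smoothing (mean over non-overlapping 3-s
bins) exists for plots.

## Synthetic dyad sessions

The generator scripts episodes of three modes over a session and returns a
pose track plus ground truth:

- **coupled**: each follower-hand speed is
  `α · (leader-hand speed delayed by lag) + (1 − α) · own noise`
  (defaults α = 0.9, lag = 150 ms; left drives left, right drives right);
- **independent**: all four hands follow their own latent dynamics;
- **stillness**: speeds near zero (default SD 2 px/s), dominated by a small
  *shared* slow component — settling and tremor transmitted through the
  shared table surface — plus tiny independent jitter.

Latent speeds are folded AR(1) processes (lag-1 correlation 0.9 at 60 Hz,
i.e. ~0.17-s correlation time, scaled to ~60–80 px/s in movement episodes)
— speeds are generated directly because every estimator consumes speed.
Positions integrate speed along slowly drifting headings with reflection at
the table bounds, so the coordinate track encodes the scripted speeds
exactly (verified to 1e−9); likelihoods sit near 0.95 with rare (0.5%)
dropouts below 0.6 to exercise the conditioning path. Identical seeds
reproduce the track bit-exactly.

The shared stillness component is a deliberate modelling choice: joint
stillness is high coordination by definition, and the shared micromotion
makes near-constant speed pairs rank-correlate highly instead of degenerating
to zero-variance windows (an independent-jitter stillness, which exercises
the degenerate path instead, is available by setting the shared amplitude
down). What the generator does **not** emulate: biomechanics (no arm-length
or reach constraints), movement form (headings are arbitrary), call--
and-response or mimicry structure, rater noise, or realistic pose-tracker
error correlations. Passing the end-to-end tests therefore shows that the
pipeline recovers the constructs it defines under its own assumptions —
clean unidirectional lagged coupling and genuinely independent movement —
not that it reaches any particular accuracy on real video.

## Numerical conventions

- Centered windows throughout; edges are undefined (correlations) or use
  shrunken windows (means/medians), as stated per operation.
- Percentiles use linear interpolation between order statistics.
- All randomness flows through explicit seeds (`numpy.random.default_rng`);
  pipeline outputs record the seed and a config hash, and reruns are
  byte-identical.
- Floating outputs are written at full precision; rounding happens only in
  human-readable displays.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run on synthetic sessions of
30–180 s (20 seeds for the stochastic checks: direction recovery pools
~1,100 windows, classification covers 60 moments) and oracle fixtures of
1,000 samples — sizes at which every estimator already operates in its
intended regime while the whole suite stays fast.

## Known limitations

- The evidence classifier is biased toward high coordination by its tie
  rule and by the max-over-pairings construction of the MCV; on real data
  this shows up as more false positives than false negatives.
- Windowed NSTE at 2 s is variance-limited; directional conclusions should
  rest on sustained asymmetry, not single windows.
- The data-sliding test conditions on the moment's own data; very short
  moments (near the 10-s minimum) give thresholds from few effective
  windows.
- Sub-cutoff coordinate gaps are linearly interpolated, which deflates
  speed inside long gaps; the per-marker missing mask is retained so users
  can censor heavily-dropped stretches.
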