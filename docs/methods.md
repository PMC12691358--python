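# Methods

## The model

A barn's headgate row is divided into six sections (ids 1–6; 1–3 on the
left side of the pen, 4–6 on the right), each served by three sprinklers
drawing 2.83 L/min while on. The sprinkler controller is purely
temperature-driven: above 22.2 °C each sprinkler runs 1 min per 15-min
cycle; above 32.2 °C, 1 min per 5-min cycle. Annual on-time per sprinkler
in a band is therefore

    on_minutes = days × hours/day × (60 / period_min) × on_min .

With the climate profile used throughout (123 days above the low threshold
averaging 10 h/day; 7 days above the high threshold averaging 7 h/day) this
gives 4920 and 588 min per sprinkler per year.

An occupancy-aware controller would skip a section's share of each cycle
while that section is empty. The expected annual skippable time per section
and band is modelled as the product

    savings_s = mean_empty_s × n_sprinklers × scale × freq × days

- `mean_empty_s` — mean duration of a section's empty intervals, estimated
  from detection footage;
- `scale` — daily sprinkler-on minutes divided by observed footage minutes.
  Footage is chunk-sampled (1 min kept per 15-min window) so one observed
  minute stands for one sprinkler cycle; the ratio enters at *printed*
  precision (600/105 → 5.71, 600/90 → 6.7, 420/105 → 4) because the annual
  figures are stated at that precision and are only reproducible with the
  rounded factors. The convention implemented: integers stay exact, a
  single-digit repeating decimal is shown to one place, anything else to
  two places.
- `freq` — 1 in the low band; 3 in the high band (the 5-min cycle fires
  three times as often as the 15-min cycle);
- `days` — band-specific day count.

A scenario combines both bands and applies a fixed rounding convention,
chosen to make the arithmetic self-consistent at the stated precision:
per-section minutes are truncated (⌊s/60⌋), barn-wide minutes are
minutes × 6 sections, and liters are minutes × 2.83 rounded to the nearest
liter. Under this convention the best scenario (71 s mean empty, scales
5.71/4) yields 2791 min/section, 16,746 min and 47,391 L per year; the worst
(41 s, scales 6.7/4) yields 1861 min/section, 11,166 min and 31,600 L.

A known internal inconsistency in the source material for per-section
*consumption* (41,904.5 L per section implies a flow of ≈2.839 L/min rather
than 2.83, and the high-band 1669.37 L omits the ×3 sprinkler factor) is
documented here and not reproduced; `consumption_liters` uses the stated
2.83 L/min consistently (4920 min × 2.83 × 3 = 41,770.8 L per section).

## Occupancy extraction

Detections arrive as per-frame records (camera, frame, time, class ∈
{cow, empty}, top-left bbox corner, size, confidence). A record belongs to
the section whose rectangle contains its **top-left corner** — the point
the detector logs — with ties on shared edges broken to the lowest box id;
center-based assignment is available behind `use_center=True`. Maximal runs
of identical class become intervals, each frame contributing 1/fps s.
Frame gaps up to `gap_merge_s` (default 1.0 s, absorbing single-frame
detector dropouts) extend the current run; longer gaps split it. Empty
durations are summarized per section by arithmetic mean and *population*
SD (÷n, so a single interval reports SD 0 rather than NaN); per-section
empty intervals are pooled, not averaged per chunk first. Occupied plus
empty time equals covered stream time exactly (up to float rounding, which
a 10⁻⁹/fps tolerance in the run-length coder absorbs).

## Synthetic data

The generator emulates what the analysis assumes about real footage and no
more. Each section alternates occupied/empty dwells; dwell distributions
are configurable (exponential, lognormal with mean+CV, fixed) and default
to **exponential**, the one-parameter memoryless choice consistent with
the empty-duration summaries the pipeline consumes (SD ≈ mean). The
initial state is Bernoulli(0.5) per section unless fixed. The default
occupied-dwell mean is 180 s, a realistic feeding-bout scale; results
downstream depend on it only through the number of empty intervals
observed. A zero-noise stream emits exactly one record per section per
frame whose class equals the truth state; noise adds per-frame misses,
per-frame false positives (uniform class, corner in a random section),
class flips, and uniform bbox-corner jitter, each calibrated so empirical
rates match configured rates to binomial error. The generator does **not**
model cow identity, social behaviour/bunching, lighting, camera
contamination, or spatially correlated detector failure — so passing tests
demonstrate correctness of the accounting chain given detections, not
detector robustness on real farms.

Climate tables expand a two-band (days, mean hours/day) summary into a
per-day table whose re-summary equals the input exactly; optional seeded
jitter varies daily hours in mean-preserving pairs. The two bands are kept
independent, as in the source tallies.

## Dewarp geometry

Output (rectilinear) pixels at radius r_out from the image center view the
scene at θ = atan(r_out / f_rect), f_rect = (W/2)/tan(PFOV/2); the source
fisheye samples that ray at radius P(θ) with P the lens projection scaled
so θ = FOV/2 meets the fisheye circle (radius min(w,h)/2). Equidistant
(r = fθ) is the default model — the usual assumption for surveillance
fisheyes, and configurable because the actual lens model is not knowable
from the data. Pixel centers sit at integer coordinates (center at
(n−1)/2), origin top-left. Resampling uses scipy.ndimage.map_coordinates,
bilinear by default, nearest for exactness tests; out-of-domain pixels take
`fill_value`. PFOV ≥ 180° is rejected (the rectilinear tangent diverges).
The forward warp applies the exact inverse geometry, enabling round-trip
tests on generated checkerboards: the central 60% must return with mean
absolute error below an interpolation tolerance (edges blur; interiors
agree). Output size defaults to the input size.

## Statistics

- **Cohen's κ** = (p_o − p_e)/(1 − p_e) with p_e from marginal products.
  The degenerate case p_e = 1 (both raters constant and identical) returns
  κ = 1 with a `degenerate` flag instead of NaN arithmetic.
- **Confusion matrices** carry a background class: unmatched predictions
  count against the background row, unmatched truths against the
  background column.
- **Average precision** matches predictions to truths greedily in
  descending confidence (each truth at most once, IoU ≥ 0.5 by default)
  and integrates the all-points-interpolated precision envelope over
  recall; mAP is the arithmetic mean over classes. The IoU threshold is
  configurable; a class with predictions but no truth scores 0 and is
  flagged.
- **Duration models** use treatment coding (human rater and first video as
  reference levels), interaction columns as products of main-effect
  columns, and classical OLS inference (statsmodels under the hood, with
  rank-deficiency reported by naming collinear columns). Backward
  elimination drops whole factors by partial F-test, largest p-value above
  α = 0.05 first (ties by term order), keeping main effects while any
  interaction containing them survives. The outcome transform (identity or
  √) is configurable since the duration scale is convention-dependent.

## Problem sizes and numerical choices

The end-to-end check simulates twenty independent 105-min streams over six
sections at 5 frames/s with zero detector noise, 71-s exponential empty
dwells and 180-s occupied dwells (~150 empty intervals per stream), runs
them through section assignment → interval extraction → summary → savings,
and compares the across-seed mean of annual liters to the best-scenario
figure; per-stream sampling error is ≈7%, the 20-seed mean ≈1.6%. Five
frames per second preserves interval boundaries to 0.2 s — two orders of
magnitude below the 71-s mean being estimated — while keeping each run to
~190k records. The SE-calibration test uses an orthonormal 10⁴×3 design
with 800 replicates so its 10% band sits ≈4σ from the Monte-Carlo spread.

## Limitations

The savings product is a first-order expectation: it assumes empty spells
are detected with no latency, ignores partial cycles, and treats the
chunked-footage scale as exact. The detector-quality figures obtainable
from real farm footage (mAP, κ against a human rater, fitted duration
coefficients) depend on data this package does not ship; those modules are
validated by closed forms, independent oracles and parameter-recovery
simulations instead.
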