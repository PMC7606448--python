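# Methods

## Pipeline model

`histocart` operates downstream (and upstream) of a per-tile binary
classifier which it deliberately does not implement: any callable mapping a
tile image to a 0/1 call satisfies the predictor contract. The pipeline
assumes:

1. slides are available at a fixed magnification (nominally ×20) and are
   tiled into non-overlapping 512×512 patches; partial edge remainders are
   **dropped**, not padded — padding would fabricate tissue;
2. a tile is background when the fraction of near-white pixels (all three
   RGB channels ≥ 220/255) exceeds 0.5, with strict "more than" semantics:
   a tile at exactly 0.5 is kept. The whiteness cutoff is configurable;
   220 matches common practice for H&E white background;
3. slide-level supervision is weak: every retained tile inherits its
   parent slide's binary label. Labels come from bulk expression
   percentiles (average-rank / n convention), with only the distribution
   extremes (percentile < 0.2 or > 0.8) entering model development.
   The [0.2, 0.8] band is set aside for out-of-distribution (OOD)
   evaluation; the boundary percentiles 0.2 and 0.8 go to OOD (closed
   interval — conservative for training). OOD-near is the next decile
   tier, [0.2, 0.3] ∪ [0.7, 0.8]. Because development labels are undefined
   inside the band, OOD slides additionally carry a median-split label
   (`label_median`) for evaluation purposes.

## Splits

Subjects, not slides, are split, so slides from one subject never straddle
sets. One test draw (10% of subjects, `floor`) is made before any trait is
processed and is therefore identical across traits and rounds. The
remaining pool is re-partitioned independently five times into validation
(1/9 of the pool = 10% of the cohort, `floor`, remainder to train) and
train. The five rounds are plain re-partitions without replacement:
train and validation must be disjoint for validation-based model selection
to be meaningful, and the 80/10 arithmetic implies partitioning.
`expected_training_count(n) = floor(n · 0.8 · 0.4)` reproduces the
inclusion-criterion arithmetic (761 → 243, 469 → 150); a small epsilon
guards the floor against binary-fraction rounding.

## Scoring and ensembling

The slide score is the exact fraction of retained tiles predicted
positive. Slide-level AUC uses the midrank (Mann–Whitney) formulation —
ties count ½ — which equals exhaustive pairwise enumeration; the test
suite asserts that equality against a brute-force oracle. Ensembles are
fixed at three members (the top three of five rounds by validation AUC,
ties toward the lower round index): an odd panel admits no tied votes, and
the ensemble predicts per tile by majority. Slides with failed per-tile
predictions are flagged incomplete and excluded from AUC with a logged
warning. Score–percentile association uses Spearman rank correlation with
Benjamini–Hochberg FDR adjustment across traits.

## Cartographies and combination encoding

A molecular cartography places each retained tile's prediction at its grid
position; background tiles are missing (`NA` in files, NaN in memory).
Layers stack only when slide, shape and missing-mask agree exactly.
The combination index at a tile is the binary encoding of its
positive-trait subset over the **declared trait order** (bit t set iff
trait t positive): index 0 is the all-negative tile and C = 2^T − 1 is the
largest index. Heterogeneity maps are usually described by named categories ("A only",
"B only", "Both"); files and palettes need a canonical encoding, and
binary encoding makes layer removal a bit-mask projection (tested).
The default two-trait palette follows the field's convention: one color
per single trait, a blend for Both, light gray for all-negative, white for
missing; larger trait counts get evenly spaced hues.

## The heterogeneity index

HTI = − Σ p_i log_C(p_i), with 0·log 0 := 0 by continuity and C computed
from the declared trait count, never from the combinations observed.
Two conventions were genuinely open:

- **Denominator of p_i.** Default `positive_tiles`: p is the conditional
  distribution over tiles positive for ≥ 1 trait, so Σp = 1 and the
  uniform-thirds example yields exactly 1 regardless of how many
  all-negative tiles the slide carries. `all_tiles` mode (denominator =
  all non-missing tiles) is retained as an explicit flag.
- **No positive tiles.** In `positive_tiles` mode the distribution has
  empty support; the index is reported as NaN (`UndefinedHTIError` at the
  low level) and such slides are excluded from stratification with a
  logged count, rather than being silently assigned 0.

For C = 1 (a single trait) only one combination exists and the index is 0
by definition. Values are clipped to [0, 1] against ~1e-16 rounding.

## Survival analysis

Patients are represented by one slide: the DX1 diagnostic slide when
present, otherwise the lexicographically first slide with a warning.
Eligibility for a two-trait analysis is restricted to slides that never
entered either trait's model development: the shared test slides plus
slides designated OOD for **both** traits. Stratification is by threshold:
HTI > high_thr → high, ≤ low_thr → low; with distinct thresholds (e.g.
0.3/0.7) the middle band is excluded. Kaplan–Meier estimation and the
log-rank test are delegated to lifelines (product-limit estimator,
log-transformed Greenwood 95% bands — bounded in [0, 1] — and the
chi-square Mantel–Haenszel statistic with 1 df); the test suite checks the
statistic against an independent hand-accumulated hypergeometric oracle
and the estimator against the empirical survivor function. Ties between
events and censorings at one time follow the standard convention
(censoring after events).

## Synthetic data

The generator emulates the statistical structure the pipeline assumes, not
its visual appearance:

- **Planted slides.** A combination composition is apportioned to tiles by
  largest-remainder rounding (exact when p_i·N is integral) and laid out
  as contiguous bands (`blocks`), a uniform shuffle (`random`), or an
  ordered row-major fill (`gradient`). The three patterns are conventions
  for exercising spatial code paths — no claim is made about real clonal
  geometry, and HTI is composition-only, so the pattern never affects it.
- **Tile images.** Each tile is a solid patch of its combination's color
  (±10 pixel noise, clipped below the whiteness threshold), so a nearest-
  color predictor recovers the planted truth exactly; designated
  background tiles get ~80% near-white pixels and are removed by the
  default filter. No nuclear/stromal texture, stain variation or scanner
  artifacts are synthesized — tests passing here show the plumbing and the
  statistics are correct, not that any real classifier is accurate.
- **Noisy oracle.** Per (tile, trait), the true membership bit is flipped
  independently with probability `flip_prob` — a tunable stand-in for an
  imperfect classifier.
- **Cohorts.** Planted HTI ~ U(0, 1); survival times exponential with
  hazard h₀·exp(β·HTI), h₀ = ln 2 / 60 months (a baseline median survival
  of 60 months, typical of mixed-stage carcinoma cohorts); independent
  uniform censoring on [0, 120] months yields roughly 40–60% observed
  events; 10% of subjects carry a second (DX2) slide so the DX1 rule is
  exercised without dominating the cohort.

## Problem sizes and numerical choices

The test suite runs planted-recovery checks on grids up to 64×64 and
Monte-Carlo calibration of the log-rank test on 1000 replicate null
cohorts of 120 subjects (type-I error required to land in (0.03, 0.07) at
α = 0.05) plus 100 replicate cohorts of 400 subjects at hazard coefficient
2 for power; these sizes make the full suite complete in well under a
minute of statistical computation while leaving the binomial error of the
calibration estimate at ~0.007. All randomness flows through
`numpy.random.default_rng` seeds; ties are broken deterministically
(lexicographic or lower-index) everywhere.

## Known limitations

- No WSI pyramid parsing or magnification handling: inputs are assumed
  pre-extracted at the target zoom.
- No stain normalization, artifact or pen-mark detection.
- HTI ignores spatial arrangement by construction; two slides with equal
  composition but different clonal geometry receive the same index.
- The predictor contract accepts hard binary calls only; calibrated
  probabilities are out of scope.
- Cox regression, competing risks and multivariable adjustment are out of
  scope; the survival module is KM + log-rank only.
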