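# Methods

This note documents the models, parameter choices and numerical decisions
behind `scrollclick`, and what the synthetic-data pipeline can and cannot
show about real scrolling behavior.

## Task model

Coordinates are screen heights: y = 0 is the bottom edge, y = 1 the top
edge; all lengths are in these units. The scrollable object is a vertical
line of uniformly spaced numbered squares, centered at x = 0.5 with a
clickable strip of half-width `line_half_width`; the center of square *t*
sits at `0.5 + (center_number − t) · square_edge` plus the current line
offset. Two presets encode the experimental apparatus:

| parameter | exp1 | exp2 |
|---|---|---|
| squares / edge | 9 / 0.20 | 11 / 0.14 |
| numbers (top→bottom) | 1–9 | 10–20 |
| centered number | 5 | 15 |
| initially visible | 3–7 | 12–18 |
| snap tolerance | 0.02 | 0.014 |
| vertical starts | −0.4, 0, +0.4 | 0 |
| horizontal start offset | ±0.4 | ±0.29 |

While the button is held on the strip, the line moves in synchrony with
the cursor, so a click at y can move the line down by at most y and up by
at most 1 − y. The *one-go interval* for a displacement d is therefore
`{y : y ≥ |d|}` (down) or `{y : y ≤ 1 − d}` (up), intersected with the
on-screen extent of the line. `scroll_path_cost` prices a click under a
no-unnecessary-movement policy: drag to the border, release, travel to the
re-click position in the line's *new* clickable extent that minimizes the
remaining path, repeat; drags sum exactly to |d|, so cost ≥ |d| with
equality exactly on the one-go interval. Drag capacity is limited only by
the screen border; physical mouse-pad limits are not modeled. Clicks
exactly on the border y ∈ {0, 1} are allowed.

The inducer-eccentricity predictor codes (0.14, 0.43, 0.71) used by the
mixed model imply a square spacing of ≈ 1/7 rather than the printed 0.14;
the geometry uses 0.14 exactly and the mixed model uses the printed codes.

## Strategies

`minimal_path_click` minimizes `hypot(gap, start_y − y) + scroll_path_cost(y, d)`
over a 0.001 grid of click positions (below any behavioral precision of
interest); exact ties are broken toward the start height, then toward the
screen center, which reproduces the click-at-your-own-height geometry
wherever the start height lies inside the one-go interval.

The two-component `heuristic` formalizes a verbal account as the linear
model

```
e* = e0 + k·(|d| − m_t)          direction + amplitude component
e  = (1 − λ)·e* + λ·e_prev       hysteresis blend
y  = 0.5 − sign(d)·e + ε,        ε ~ N(0, noise_sd), clipped to [0, 1]
```

with the task-context mean amplitude updated by exponential smoothing,
`m_{t+1} = (1 − α)·m_t + α·|d_t|`. Defaults (all overridable):
e₀ = 0.25 (mid-range eccentricity), k = 0.5 (a 100-px larger scroll moves
the click only 50 px further out), λ = 0.3, α = 0.1, noise_sd = 0.07
(matching the reported ~7%-of-screen-height between-participant spread).
The linear form, the convex hysteresis blend and the smoothing context are
this package's formalization choices; parameter-recovery tests treat all
of them as free parameters. Direction-specific base eccentricities
(`base_eccentricity_up/down`) are exposed but default to equal. Because
the hysteresis term feeds on the *observed* previous eccentricity, the
model is linear in observables and `fit_heuristic_params` recovers
(e₀, k, λ) by ordinary least squares on the click stream (α assumed
known); zero displacement never occurs in either design and strategies
raise on it rather than guess.

Context initialization at each block start: m₀ equals the design mean |d|
of the block (a participant's calibrated expectation of task demand) and
e_prev starts at e₀ (neutral). Context does not carry across blocks.

## Synthetic participants

The design generators enumerate each factorial exactly (Exp 1: every
target × vertical × horizontal combination once per block, 8 blocks;
Exp 2: each (target, side) pair four times per subblock, 3 subblocks, the
three eccentricity block types in uniformly random order per participant —
the original counterbalancing scheme is unspecified, so plain
randomization is used).

The motor model is not part of the studied task and is deliberately
minimal: drags aim at the exact completion point (or the border when out
of reach) with signal-dependent Gaussian endpoint noise — SD =
`drag_sd · drag_length / 0.5`, i.e. `drag_sd` (default 0.02) is the
endpoint SD of a half-screen drag. If the release leaves the target
outside the snap tolerance, corrective re-clicks (< 0.1 units residual)
aim at the on-line point nearest the screen center, substantive ones at
the nearest point with sufficient capacity; segment durations are
0.2 s + 1.0 s per unit distance, and the start square is clicked 0.5 s
after trial onset. These constants produce the qualitative mix of
substantive and corrective submovements and trial durations safely below
the 10-s exclusion bound. Between-participant variability, when enabled,
applies normal offsets to e₀ (SD 0.05) and k (SD 0.1).

What passing tests on these data do **not** show: the generator has no
trial-to-trial drift other than the modeled hysteresis/context terms, no
input-device heterogeneity (mouse vs touchpad), no Fitts-style
speed–accuracy coupling, and noise magnitudes are assumptions rather than
estimates. Conclusions about the *pipeline* (correct geometry, statistics,
power machinery, recoverable parameters) transfer to real data;
conclusions about effect sizes do not.

## Reduction

`initial_click_y` is the cursor height of the first click on the line;
`final_cursor_y` the height at the last release; `n_submovements` the
number of line click/release pairs (the single-drag trial counts as one);
`response_time` runs from target onset (the start-square release) to the
final release, while the 10-s exclusion window runs from start-square
onset (trial time zero). Both printed thresholds are applied with strict
inequality exactly as stated ("less than 0.1 units", "exceeded 10 s").

## Statistics

`rm_anova_gg` implements the fully within-participant factorial ANOVA of
arbitrary order directly on participant × cell cubes: classical
sums-of-squares via inclusion–exclusion over marginal means, each effect
tested against its effect-by-subject interaction. The Greenhouse–Geisser
epsilon of an effect is computed from the covariance of orthonormal
(Helmert) contrast scores of the cells averaged over the other factors,
ε = tr(S)²/(d·tr(S²)), clamped to [1/d, 1]; p values always use the
corrected degrees of freedom, including when ε ≈ 1. Generalized η² uses
all subject-related variance components in the denominator (the standard
definition for fully within designs). The implementation is validated
against a definitional loop-based oracle (1e−8) and cross-checked against
pingouin for two-way designs; pingouin's interaction epsilon uses a
different approximation that its own output flags as inaccurate, so the
interaction ε is validated against the contrast-basis oracle instead.

`consecutive_contrasts` runs paired t tests between adjacent factor
levels with d_z = t/√n; a zero-variance difference is flagged degenerate
rather than reported as an unbounded statistic.

The hysteresis mixed model regresses trial-level click positions on the
signed current amplitude, scroll direction (−0.5 down / +0.5 up), the
start position (exp1: −0.4, 0, 0.4) or inducer eccentricity (exp2: 0.14,
0.43, 0.71), the previous click position, and the direction-signed
previous click eccentricity centered on 0.25 (half its [0, 0.5] range).
First trials of blocks are dropped, as are trials whose own or preceding
duration exceeds 10 s. Estimation uses REML via statsmodels' MixedLM with
by-participant random slopes for all predictors; the random-effect
covariance is unstructured by default and falls back to (or can be set
to) a diagonal structure when the unstructured fit is singular or fails
to converge — the fallback is recorded in the result's notes. Per-
predictor F statistics are squared t ratios with one numerator df; the
denominator df uses a group-count approximation (n_participants − 1),
which is where Satterthwaite-type approximations land for
within-participant predictors carrying random slopes. VIFs are computed
on the centered fixed-design columns (after the stated coding); marginal
and conditional R² follow the variance-partition formulation
(fixed / fixed + random / + residual).

## Power simulations

**Exp 1.** Each synthetic participant contributes one data point per cell
of the 3 × 8 grid: the minimal-path prediction plus independent
N(0, noise_sd), clipped to the screen, so data points are uncorrelated
across participants; no trial-level simulation is involved. Each
replicate runs the two-way GG-corrected ANOVA at α = .05; power per
effect is the rejection fraction. Probed noise SDs are 0.20 and 0.40
screen heights.

**Exp 2.** The original design-stage simulation drew from each empirical
participant's per-target trial mean and SD, which require the raw study
data. The package instead defines an explicit surrogate, used and stated
as such: test-target means 0.5 ± 0.28 (targets 13 and 17 sit 0.28 units
from the center, and clicks mirror the required scroll), trial SD 0.07
(the reported between-participant spread reused as the surrogate scale),
8 test trials per target per subblock, 3 subblocks. The hypothetical
inducer-eccentricity effect moves clicks away from the center by
`(level − 1) · effect_size · ramp` with level 0/1/2 for low/medium/high
blocks and a ramp growing linearly from 0 at block start to 1 at block
end (test trials assumed evenly spread within subblocks). Whether the
original analysis included subblock as a factor is unstated, so both the
2 × 3 interaction and the 2 × 3 × 3 three-way term are reported.

Monte-Carlo standard errors are √(p(1−p)/n_reps); results are
reproducible bit-for-bit given (seed, config). The acceptance script runs
1000 replicates per condition, which keeps each power estimate's MC SE
below 1.6 percentage points and the full script under a minute on one
CPU.

## Numerical and interface choices

* Optimization grid 0.001 for `minimal_path_click` (tie-breaks as above).
* All randomness flows from a single master seed; per-stage child seeds
  are derived from the stage name (Knuth multiplicative hash + CRC32,
  kept below 2³¹), so adding a stage never perturbs earlier stages.
* Trial-log CSVs format floats with shortest-round-trip `repr`, making
  write → read → write byte-identical.
* Run configs reject unknown keys before any computation; a seed is
  mandatory for any stochastic run.

## Known limitations

* The heuristic's functional form is one of many consistent with the
  verbal two-component account; only its qualitative signatures (direction
  dominance, partial amplitude adjustment, eccentricity-based hysteresis,
  context adaptation) are empirically grounded.
* The Exp 2 power surrogate is not equivalent to resampling empirical
  participants; its trial SD and mean eccentricity are documented
  assumptions.
* The denominator-df approximation for mixed-model F tests is a
  group-count rule, not a full Satterthwaite computation; p values for
  predictors with weak random-slope variance are conservative.
* Horizontal scrolling, wheel/gesture input, 2-D panning and
  publication-style figure regeneration are out of scope.
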