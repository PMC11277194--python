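# Methods

This note documents the models, numerical choices and limitations of
`gepcast` at the level of detail a maintainer or reviewer needs.

## Genome representation and decoding

A gene is a symbol string of head length *h* and tail length
*t = h(n−1)+1*, where *n* is the largest function arity (2 for the
default function set).  Heads may contain functions or terminals;
tails contain terminals only.  This head/tail rule makes every string
decodable: breadth-first filling attaches symbols as children of
pending nodes in queue order until all function nodes are saturated,
and the worst case (a head of all binary functions) consumes exactly
*t* tail terminals.  Symbols after the used prefix remain in the
genome as dormant material and participate in all genetic operators —
standard GEP semantics that lets neutral variation accumulate.

Terminals are named `x1..x14` and map positionally onto the feature
columns (six monthly temperatures, six monthly rainfalls, accumulated
temperature, annual precipitation).  Chromosomes hold five genes by
default, joined by the associative `+` link; multigene addition acts
as a built-in ensemble of subexpressions.

**Protected evaluation.**  Division by zero, `Ln` of a non-positive
value, `Sqrt` of a negative and floating overflow all produce a
non-finite value (NaN/inf) that propagates to the chromosome value for
that fitness case.  We deliberately do *not* substitute a constant
(e.g. the common `x/0 := 1` convention): substitution silently rewards
expressions that exploit the substitution value, whereas a non-finite
flag simply eliminates the individual for that case.  The engine maps
any non-finite prediction to a `-inf` fitness sentinel, so such
individuals lose every selection tournament but the run continues.

## Fitness and the evolution loop

Default fitness is negated training MSE (maximization form).  The
selection-range alternatives are implemented as
`Σ_j (M − |C_ij − T_j| / |T_j|)` (relative) and `Σ_j (M − |C_ij − T_j|)`
(absolute) with selection range *M* defaulting to 100.  Absolute-value
bars are applied to the error term in both forms: without them an
overshooting predictor would enjoy unbounded fitness, which cannot be
the intent of a selection-range criterion.  Relative mode refuses
zero targets.

Each generation applies, in fixed order: truncation selection (the
worst ⌊N/4⌋ individuals replaced by copies of the best ⌊N/4⌋; ties
broken by insertion order via stable sort), per-symbol point mutation
(rate 0.044), head-segment inversion (0.1), IS transposition (0.1),
RIS transposition (0.1), gene transposition (0.1), then one-point
(0.3), two-point (0.3) and whole-gene (0.1) recombination over a fresh
random non-repeating pairing per operator family.  The published
parameterization names the operator families and their rates but not
their scheduling; one population-wide pass per family per generation
is our choice, and all rates are configurable.  The best-ever
individual is written over the last population slot every generation
(elitism), which makes the best-fitness trace non-decreasing by
construction.

Operator mechanics where the family name alone underdetermines them:

* *Inversion* reverses a random contiguous segment strictly inside one
  gene's head.  Head positions admit both symbol kinds, so reversal
  preserves validity; tails are never touched.
* *IS transposition* copies a segment of length 1–3 starting anywhere
  in the chromosome into a non-root head position of a random gene,
  shifting the head right and truncating at the head boundary.  *RIS*
  is identical except the segment must start with a function symbol
  (scanning downstream from a random head position; no function → no-op)
  and inserts at the root.
* Termination is a fixed generation budget (default 1000).  An
  optional plateau stop (best fitness improving < 1e−8 for 50
  consecutive generations) exists but is off by default, since a fixed
  budget is the reference behaviour and plateau detection interacts
  with elitism-induced long flats.

## Hyperparameter search

The binary codec maps length-*L* strings onto the uniform lattice over
`[x_min, x_max]` with step `(x_max − x_min)/(2^L − 1)`; decoding treats
the leftmost bit as most significant, so all-zeros ↦ `x_min` and
all-ones ↦ `x_max` exactly.

The real-coded GA uses convex-blend crossover
`x_i' = (1−a) x_i + a x_j` (one `a ~ U(0,1)` per pair; the integer
variant rounds), applied to a random perfect matching of the
population at rate 0.9, and masked bounded mutation at rate 0.1: per
coordinate, mask bit 0 contracts toward the lower bound
(`x' = x − (x − x_min) b`) and mask bit 1 moves toward the upper bound
(`x' = x + (x_max − x) b`).  The upward branch is written in
sign-corrected form: the naive mirrored expression
`x − (x_max − x) b` can leave the feasible box (it is available behind
`literal_upper_branch=True` for comparison, with a test demonstrating
the violation).  Convergence follows the
`|fitmax_{k+1} − fitmax_k| < ε` criterion; ε defaults to 0 (disabled)
because elitism produces long exact plateaus that would otherwise
trigger an immediate stop — callers who want the criterion set ε
explicitly.

Grid search evaluates every (C, γ) pair by k-fold cross-validated MSE
(seeded shuffled folds by default; contiguous chronological blocks
optionally, for time-indexed data where shuffling is arguable).  Ties
break toward smaller C, then smaller γ, preferring the smoother model.
Default grids are log-spaced: C ∈ 2^−2..2^8, γ ∈ 2^−10..2^2.

## SVR stage

Fitting delegates to libsvm (through scikit-learn) with tolerance
tightened to 1e−8 so refits are reproducible and sample-order
invariant to high precision; a test checks agreement with an
independently solved dual QP (SLSQP) to 1e−4 on a small problem.  The
fitted model is stored explicitly (support points, dual coefficients,
bias) and prediction is a plain kernel expansion, which makes the
plain-text model bundle self-contained.  Defaults C = 10, γ = 0.001
follow the tuned reference configuration; the tube width ε defaults to
0.1 as a standard choice and is exposed in `SvrParams`.  Multi-class
SVM classification is deliberately absent: the pipeline is
regression-based throughout, with discretization as the final step.

## Hybrid pipeline

Stage one regresses the numeric level on the normalized features;
stage two fits the training residuals; prediction is the exact sum of
the stages (a tested decomposition identity).  Discretization uses the
0.5 threshold — fractional parts above 0.5 round to the next level,
below stay — with the boundary case of exactly .5 rounding *up* (the
threshold rule is stated with strict inequalities only, so the
boundary needed a deterministic choice), then clamps to [1, 3].

Features are the 14 same-year columns by default.  Whether prior-year
summer rainfall should enter as distinct columns is genuinely open
(the documented correlation is with the *previous* year's rainfall,
but the record schema is per-year); both are supported —
`add_lagged_rain` appends `rain_{jul,aug,sep}_prev` columns and
`fit_hybrid(..., feature_columns=FEATURE_COLUMNS + LAGGED_RAIN_COLUMNS)`
uses them — with same-year as the default.

Normalization is min-max to [0, 1] fitted on training rows only; test
rows may map outside [0, 1] and are not clipped.  Constant features
are an error rather than a silent degenerate scale.

## Synthetic data generator

The generator emulates the historical record's structure, not its
values.  Climate features are independent seasonal Gaussians with
means and spreads matching the magnitudes of the central-Shaanxi
record (January ≈ 1.5 ± 1.5 °C through July ≈ 27.5 ± 1.2 °C; July
rainfall ≈ 100 ± 40 mm; accumulated temperature ≈ 5450 ± 110 °C·d;
rainfall truncated at zero and everything recorded at 0.1 precision).
The ordinal level comes from thresholding a latent severity score

    s_t = 2.0 − 0.6·z(winter temp_t) + 0.6·z(prev-year summer rain_t)
          + 0.2·sin(annual precip_t / 150) + N(0, 0.3)

at cut-points (1.5, 2.5).  The standardization z(·) uses the
generator's own population moments, so the planted effect sizes are
exact by construction.  The effect sizes were chosen once to give
clearly detectable but noisy structure: the implied level correlations
are about −0.6 with winter temperature and +0.55 with prior-year
rain, and the default cut-points put roughly 30/40/30 % of years in
levels 1/2/3.  A burn-in year supplies the first year's rainfall lag.
Generator parameters are attached to the returned table and
serializable as a JSON sidecar for recovery tests.

What the generator does *not* emulate: between-year autocorrelation
(years are exchangeable given their climate), correlation among
climate variables within a year, trends or regime changes, and any
non-climatic driver (resistant varieties, farming systems, source
population).  Passing tests on this process therefore demonstrate that
the pipeline recovers planted climate–severity structure of realistic
strength — not that it would attain any particular accuracy on the
real historical record.

## Problem sizes in the test suite

Tests run the evolution loop at 40–300 generations with population 30
(the planted-formula recovery uses the full 300; multi-seed checks use
40), 78-year synthetic tables, and exhaustive enumerations where the
domain is small (all 2^L codes for L ≤ 10; all confusion tables with
counts ≤ 6; all 5^6 binary-function heads).  These sizes were chosen
so each property is exercised at a scale where failure would be
informative rather than lost in stochastic slack.

## Known limitations

* The GEP stage has no constant-creation mechanism (no random
  numerical constants), so expressions are built purely from the
  features; the SVR stage compensates in practice.
* Two operator names that sometimes appear alongside this operator
  family — "extraction" and "adjustment" — have no standard published
  mechanism and are not implemented.
* `fitness_cases` in relative mode is undefined for zero targets by
  construction; callers with zero-valued targets should use absolute
  or MSE mode.
* The CLI covers single fits and forecasts; no multi-step-ahead
  forecasting, probabilistic level forecasts, or plotting beyond the
  fitness-trace log.
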