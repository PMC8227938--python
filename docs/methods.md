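# Methods

## The estimation problem

Thermal proteome profiling (TPP) measures, for thousands of proteins at
once, the fold change of soluble protein remaining at each of 6–10
temperatures, relative to the lowest temperature measured. Each (run,
protein, temperature) cell is observed once — there are no biological
replicates — so per-protein estimates of the melting temperature Tm are
noisy, and a fraction of curves ("non-melters") carry no usable melting
signal at all. `bayesmelt` estimates Tm for every protein by partial
pooling: proteins from the same run (one organism × extraction method)
share run-level curve parameters, so noisy or ruined curves borrow
strength from their neighbours instead of producing absurd point
estimates or no estimate at all.

## Model

Fold change at temperature T (°C) follows the sigmoid

    f(L, a, b, T) = (1 − L) / (1 + exp(b − a/T)) + L

with lower plateau L ∈ [0, 1), steepness scale a > 0 (°C) and offset
b > 0 (dimensionless). The curve is strictly decreasing in T for valid
parameters and crosses its midpoint (1 + L)/2 exactly at Tm = a/b. The
a/T parameterization (rather than a logistic directly in T) makes both
parameters positive for any denaturation-shaped curve, which is what the
hierarchy's truncation relies on. Temperatures are °C throughout; no
Kelvin conversion is applied anywhere.

The hierarchy, with all Normal scale parameters given as standard
deviations:

| level | prior | role |
| --- | --- | --- |
| global | a_l ~ Normal(500, 1), b_l ~ Normal(10, 1) | cross-run curve locations (Tm scale ≈ 50 °C) |
| run | a_r ~ Normal(a_l, 10) truncated > 0; b_r ~ Normal(b_l, 1) truncated > 0 | per-organism melting regime |
| protein | δ_a ~ Normal(0, 3), δ_b ~ Normal(0, 1); a_p = a_r + δ_a, b_p = b_r + δ_b | per-protein deviation |
| plateau | L_e ~ Exponential(mean 30) per run; L_p ~ Exponential(rate L_e) | experiment-driven lower bounds |
| noise | σ_p ~ HalfCauchy(1) | per-protein homoskedastic sd |
| data | y ~ Normal(f(L_p, a_p, b_p, T), σ_p) | single-replicate fold changes |

Choices that were genuinely open:

- **Plateau hyper-rate.** The exponential hyperprior on L_e uses mean 30,
  so conditional plateau means are around 1/30 ≈ 0.03 — the magnitude of
  real fold-change floors. A rate that put L_p's prior mean far above 1
  would be inconsistent with a lower bound of a curve living in [0, 1].
  The mean is exposed as `plateau_rate_prior_mean`.
- **Per-run vs global plateau rate.** Experimental conditions mainly set
  the measurement floor, so each run gets its own L_e by default;
  `per_run_plateau=False` collapses to one global rate.
- **No truncation at the protein level.** a_p and b_p are untruncated
  sums; with offsets of sd 3 and 1 against locations near 500 and 10, a
  non-positive draw is a > 100σ event. A fit-time diagnostic counts and
  warns about any such draw (none have been observed).
- **Truncated Normals are properly renormalized** (division by
  Φ(loc/sd)), so the joint density is exact, not proportional, and the
  term-by-term oracle test can demand 1e−8 agreement.

## Inference

The joint density and its analytic gradient are implemented directly
over an unconstrained parameterization (log transforms with Jacobians
for all positive parameters). The gradient is verified against central
finite differences in the test suite, and the unconstrained density
against the natural-space density plus Jacobians.

Two engines operate on that density:

- **NUTS** (default at desk scale): No-U-Turn Sampler with
  dual-averaging step-size adaptation (target acceptance 0.8, max tree
  depth 10) and a diagonal mass matrix estimated from the first half of
  warmup, after which step-size adaptation restarts. Divergent
  transitions after warmup are counted and surfaced in `diagnostics_`.
- **ADVI** (default above `auto_advi_threshold = 5000` observations,
  mirroring the large-data regime the method exists for): fully
  factorized Gaussian in the unconstrained space, single-sample
  reparameterization gradients, Adam at learning rate 0.01, 200 000
  steps by default. The exponentially smoothed ELBO trace is recorded so
  convergence can be inspected; a persistently non-finite objective
  raises a `FitError` carrying the trace.

Both engines are exercised on an exact factorized Gaussian target in the
unit tests, where their moments must match the closed form. Mean-field
ADVI underestimates posterior variance by construction; the acceptance
suite checks that its mean Tm sd is below NUTS's on the same data while
the posterior means agree.

All derived quantities — Tm, posterior curve bands — are computed per
joint draw and summarised afterwards. Ratios and the nonlinear link are
Jensen-sensitive, so means of parameters are never pushed through either.

## Separate-fit baseline and quality control

The comparison baseline fits each protein independently with
`scipy.optimize.curve_fit` over (L, a, b), bounds L ∈ [0, 1] and
a, b > 0. Initialization is deterministic and data-driven: L₀ = clipped
min(y), Tm₀ = the observed temperature whose y is closest to the
midpoint (1 + L₀)/2, b₀ = 10, a₀ = b₀·Tm₀ — so failures are
reproducible. Non-convergence is a flagged outcome, not an exception.

QC declares a melter when the fit converged, fitted L ≤ 0.3 and
R² ≥ 0.8 (R² against the protein's own mean). The normalized area under
the curve (trapezoid area divided by the temperature span, ≈ 1 for a
flat curve at 1) is always reported. These thresholds and the nAUC
definition are configurable stand-ins for the TPP protocol's published
convention, which is not reproduced here; comparisons against original
pass/fail labels are out of scope. "Imputed" everywhere means
`qc_pass = False` under this rule.

## Decision operators

Given per-protein Tm draws: re-measurement ranking = posterior sd,
descending; threshold exceedance = fraction of draws above the
threshold (strictly; equal to 1 − the empirical CDF with the
right-continuous convention); probability of superiority
P(Tm_i > Tm_j) = fraction of *paired* joint draws with ties counted ½,
which makes P(i,j) + P(j,i) = 1 and P(i,i) = ½ exact identities. The
pairwise ranking reports both the mean pairwise superiority over all
rivals (primary) and P(best) — the per-draw argmax frequency with ties
splitting credit — because either reading of "most probably superior"
is defensible. `direction="min"` flips comparisons for
smaller-is-better objectives. Score ties are broken lexicographically
by protein key.

## Synthetic data

The generator samples the hierarchy forward and adds homoskedastic
Gaussian noise, exactly matching the model's likelihood so parameter
recovery is a clean test of inference, not of model mismatch. Defaults
define the standard benchmark used throughout the tests and the
acceptance script: 2 runs × 20 proteins × 10 temperatures evenly spaced
over 37–67 °C, noise sd 0.05 (fold-change units), 20% of each run's
proteins corrupted. These sizes keep a full NUTS fit around a minute on
one CPU while leaving 32 clean proteins for recovery/coverage statistics.
Specifics:

- The plateau hyper-rate is pinned to its prior mean (30) by default;
  `plateau_rate="sample"` draws it per run, and plateau draws ≥ 0.95 are
  resampled so every curve stays a valid fold-change curve.
- Corruption modes: `flat` (y ≈ 1 everywhere — no melting signal),
  `scrambled` (y permuted across temperatures — pure noise with the
  right marginal), `high-noise` (noise re-drawn at a stated multiple).
  The benchmark uses `scrambled`, the harshest no-signal regime that
  still has a realistic value range. Corrupted proteins keep their
  ground-truth Tm so imputation can be scored.
- Negative simulated fold changes are kept by default (the likelihood
  is an unbounded Normal; clipping would bias recovery tests);
  `clip_negative=True` clips at 0 for realism.

What the generator does *not* emulate: peptide-level quantification,
missingness patterns of real TPP data, batch effects, or heteroskedastic
noise. Passing tests therefore demonstrate correct inference under the
model's own assumptions, not robustness to real-data violations of them.

## Tolerances and benchmark results

Tolerances asserted in the acceptance tests were fixed once from a long
reference run on the standard benchmark (NUTS: warmup 1500, 2000 draws;
ADVI: 200 000 steps) and then frozen with margin:

- clean-protein Tm RMSE < 2 °C (reference: ≈ 0.5 °C);
- 94% equal-tailed intervals cover the truth at a rate consistent with
  nominal under an exact binomial test at α = 0.001 (reference: 32/32);
- every corrupted protein's posterior-mean Tm inside its run's
  clean-protein span, and mean posterior sd of corrupted ≫ clean
  (reference: 4.7 vs 0.8 °C);
- Bayesian-vs-MLE mean residual within ±0.5 °C on QC-passing proteins
  (reference: 0.16 °C), positive rank correlation of |residual| with
  posterior sd (reference: 0.76);
- ADVI mean Tm sd ≤ NUTS mean Tm sd (reference ratio 0.88), mean
  |ΔTm| < 1.5 °C (reference: 0.53 °C).

The routine test suite uses shorter fits (NUTS warmup 600 / 600 draws;
ADVI 30 000 steps) that reproduce these properties well inside the
frozen tolerances.

## Numerical notes

- The logistic is evaluated with `scipy.special.expit`
  (overflow-safe); extreme warmup states that overflow elsewhere are
  treated as zero-probability points and rejected by the samplers.
- CSV round trips are exact: files are written with shortest-repr float
  formatting and read with round-trip float parsing, so
  write → read → write is byte-identical (asserted in tests).
- Quantiles everywhere (summary tables, curve bands) use linear
  interpolation between order statistics; credible intervals default to
  94% equal-tailed.
- A protein observed at fewer than 2 distinct temperatures is dropped at
  validation with a warning; separate fits need ≥ 3 points and otherwise
  return an "underdetermined" failure flag.

## Known limitations

The model treats runs as fully independent, including cells vs lysate
runs of the same organism; the noise model is homoskedastic Gaussian per
protein; mean-field ADVI underestimates variance and therefore mutes
exactly the distribution tails that the superiority/exceedance decisions
use (prefer NUTS when the data size allows); and imputed Tm values are
only as good as the assumption that every protein eventually melts like
its run-mates.
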