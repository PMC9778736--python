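# Methods

`mpuncert` evaluates the measurement uncertainty of microplastic
contamination in sediment — particles per kilogram of dry sediment,
written ω (kg⁻¹) — by a bottom-up (component-wise) uncertainty budget
combined with Monte Carlo simulation. The measurand is the contamination of
the *analysed sample*: field-sampling variability is deliberately outside
the model.

## The measurement model

One analysis yields an observed particle count `C` (a natural number), the
nominal wet portion mass `m` (g), and three Petri-dish weighings for the
dry-weight fraction `W_d = (m_F − m_P)/(m_I − m_P)`. Per Monte Carlo draw

```
ω = (C_r + Δ) / (m · W_d / 1000)        [kg⁻¹]
```

* `C_r` — the observed count with its random counting error: a
  Poisson-lognormal variate with `E(λ_r) = C` and `Var(λ_r)` estimated
  from duplicate analyses.
* `Δ` — the integer loss-correction term: a Poisson-lognormal variate with
  `E(λ_s) = C·F`, where `F = (A − n̄)/n̄` is the spike-recovery correction
  factor, so the corrected count `C(1 + F) = C·A/n̄` applies the inverse
  mean recovery.
* `m · W_d` — the dry portion mass with weighing uncertainty.

The simulated ω distribution is summarised as `mode; [P0.5; P99.5]` — the
histogram mode is the best estimate and the 0.5th/99.5th percentiles bound
the 99 % confidence interval. Two results are metrologically equivalent
when zero lies inside the same percentile interval of their simulated
difference.

## Poisson-lognormal counts

The Poisson mean λ is treated as lognormal, moment-matched on the natural
scale: `σ² = ln(1 + Var/E²)`, `μ = ln E − σ²/2`. Sampling draws
`λ = exp(Normal(μ, σ²))` and then `Poisson(λ)`; the draw order (normals
first, then Poisson variates) is fixed so runs are bit-reproducible for a
given `numpy` generator. The matching targets the mean; a median-matched
variant (`μ = ln E`) would shift every λ draw down by `σ²/2` and is not
offered. For testing, a numerical pmf oracle integrates the Poisson pmf
against the lognormal density by adaptive quadrature over `ln λ` on
`μ ± 10σ` (tail mass < 1e-12).

A zero observed count is a legal degenerate case: both count terms collapse
to a point mass at zero (the lognormal is undefined at `E = 0`), so the
result is exactly zero with zero-width interval — "not distinguishable from
no contamination". This understates the uncertainty of a zero count and is
a documented limitation, not an error.

## Random effects from duplicates

`Var(λ_r) = Var(d(C))/2`, half the variance of the signed count differences
of duplicated samples, since a difference of two iid Poisson counts has
twice the single-count variance. The default uses the mean-subtracted
sample variance with a (k−1) denominator; `center="zero"` selects the
classical duplicate formula `Σd²/(2k)`, which assumes zero mean difference
and is invariant to globally swapping the replicate columns. At least two
pairs are required; the estimate pools all duplicated samples of one
parameter.

## Systematic effects from spikes

Each spike unit receives `A` particles (default 5, per polymer); `n` are
recovered. With `M` units, `n̄` and the (M−1)-denominator `Var(n)` give
`Var(n̄) = Var(n)/M` and `F = (A − n̄)/n̄`. For a combined parameter
spanning several polymers the spike lists concatenate, so `M` is
units × polymers, each unit normalised to its own `A`. First-order
propagation of `λ_s = C(A/n̄ − 1)` with `C`, `A` exact gives

```
Var(λ_s) = C² (A/n̄²)² Var(n̄).
```

Limitation: for `X ~ Normal(μ, σ²)`, `Var(1/X) = (σ²/μ⁴)(1 + 8 CV² + …)`,
so the first-order result undershoots by about `8·CV(n̄)²` relative —
negligible at CV ≈ 1 % (combined-parameter regime) but ≈ 0.8 % at CV ≈ 3 %
and ≈ 12 % at CV ≈ 12 % (a poorly recovered polymer with few spike units).
The tests verify both the small-CV agreement with a sampling oracle and the
`8·CV²` law of the discrepancy. Recovery is not truncated: a correction
factor below zero (over-recovery) would only raise a warning, though the
strict `n ≤ A` input validation makes it unreachable in practice.

## Weighing

Balance uncertainty has a rectangular systematic component of half-width
`E_M` (standard uncertainty `E_M/√3`) and a repeatability sd `s_r` with
stated degrees of freedom (default df = 9, a typical 10-replicate balance
check). A mass by difference draws each component twice, independently per
reading — the budget deliberately does not cancel a shared balance bias,
which is what produces the triangular density of the simulated dry mass:

```
m* = m + U₁ + U₂ + s_r(T₁ + T₂),   U ~ Uniform(±E_M),  T ~ t(df)
```

Its sd is `sqrt(2E_M²/3 + 2s_r²·df/(df−2))` — the closed-form combination
with the Student-t variance inflation. `df ≤ 2` with `s_r > 0` is rejected
(infinite variance). The dry portion mass simulates `m`, `(m_F − m_P)` and
`(m_I − m_P)` independently (both differences contain `m_P`, but they are
treated as two independent difference measurements) and returns
`m*·num*/den*`; non-positive draws are rejected and redrawn, with a warning
above 0.1 % rejections. Oven drying is assumed to contribute negligible
uncertainty. Masses are validated against the method's 8–100 g working
range (warning outside).

## Monte Carlo settings and summaries

Defaults: 49,999 draws (the odd count puts the 0.5th/99.5th order-statistic
positions `p(n−1)+1` nearly on integers), percentiles by linear
interpolation between order statistics, and the mode as the midpoint of the
most populated of 200 equal-width bins over the draw range (lowest bin wins
ties). When a single exact value holds at least half of the modal bin's
draws — a point mass, e.g. the zeros of a barely contaminated sample — that
value is reported instead of the bin midpoint, preserving "mode = 0 ⇒
indistinguishable from no contamination". All three knobs are exposed in
`MCSettings`.

Comparisons subtract the two draw vectors element-wise; the vectors must be
drawn from independent streams (no common random numbers — the simulated
differences are noisy but symmetric, as intended) and equal in length (no
silent truncation). Campaign means average the draw vectors element-wise,
so the mean of k similar samples has roughly 1/√k the interval width.

Percentile seed-stability (< 5 % relative between runs) holds for well
contaminated samples (counts of a few tens). At low counts the ω
distribution is a train of narrow clusters, one per integer corrected
count, and the 0.5th percentile can flip between adjacent clusters when the
CDF crosses 0.5 % near a cluster boundary — a real feature of a discrete
measurand, not Monte Carlo error; P99.5 is stable throughout.

## Synthetic data

The generators emulate the validation design with known truth: 12 sediments
in duplicate, 12 spike units of 5 particles, recoveries around 0.7–0.8,
portions of ~50 g with dry fraction 0.6, and a well-behaved analytical
balance (E_M = 0.01 g, s_r = 0.005 g). Particle loss is binomial thinning
(each particle survives with probability R independently), so
`n ~ Binomial(A, R)`, `F → (1−R)/R`. Duplicate pairs share their
per-portion λ, so between-portion heterogeneity cancels in the difference,
exactly as the duplicate estimator assumes. The truth table
(`sample_id, true_omega_kg`) is written beside the dataset, never inside
it. Not emulated: spectroscopic misidentification, analytical blank
contamination, non-binomial (clumped) particle loss, and within-campaign
contamination gradients — passing coverage tests therefore show the budget
is self-consistent under its own assumptions, not that real recoveries are
binomial.

Problem sizes used in the test suite and acceptance script — 500-pair /
500-unit estimator-recovery experiments, 300-sample coverage runs at
49,999 draws, 200-repetition equivalence experiments — were chosen to make
the Monte Carlo error small relative to the tolerances being checked.

## Numerical and design choices

* Percentile convention, bin count and draw count are configuration, not
  constants; the defaults reproduce a spreadsheet-style histogram mode.
* Effects estimation requires every sample parameter to appear in both
  validation files; a missing parameter aborts the pipeline with an
  actionable message rather than silently assuming zero correction.
* The pipeline spawns one child generator per sample from the configured
  seed (`numpy` `SeedSequence`), making `results.csv` byte-identical across
  reruns and independent of sample order within a spawn.
* CSV schemas embed units in column names (`m_g`, `mode_kg`) to prevent
  g↔kg mistakes; machine outputs keep full float precision
  (`float_precision="round_trip"` on read), while the human report rounds
  to integer kg⁻¹.
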