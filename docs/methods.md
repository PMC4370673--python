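# Methods

This note records the models implemented in `bellwether`, the defaults
and why they were chosen, the numerical choices that matter, and what
the synthetic-data generator does and does not emulate.

## Annual detectability and its calibration

Annual detectability — the probability that a single visit to an
occupied pond detects the species in a given year — is modelled as a
Beta(α, β) random variable. With only two years of measured detection
probabilities available, the distribution is identified by two
quantile constraints: the observed values are placed at the
percentiles where those years fall within a longer abundance record.
The shipped preset puts 0.17 at the 9th percentile and 0.41 at the
91st (an 11-year record in which the two measured seasons were the
second-lowest and highest years; 2/11 ≈ 0.18 and 10/11 ≈ 0.91 bracket
those plotting positions). Solving F(0.17) = 0.09 and F(0.41) = 0.91
gives α ≈ 7.06, β ≈ 17.70, mean ≈ 0.285.

Two equations in two unknowns are solved by Nelder–Mead minimisation
of the summed squared CDF residuals in log-parameter space (positivity
by construction), started from a method-of-moments fit to a normal
approximation through the anchors. The default acceptance tolerance on
each residual is 1e−6; failure to reach it raises with the final
residuals. The fit is a left inverse of quantile evaluation: for
shapes in [0.5, 20]² the round trip through the (0.09, 0.91) quantiles
recovers the parameters to better than 0.1% (property-tested). How a
raw abundance series should be converted to detection probabilities
before anchoring is outside the package's scope; the anchors are the
interface.

## The allocate-or-wait rule

With `y` study years remaining (current year included) and observed
bellwether output `q`, the probability that no remaining year beats
the current one is `p_best = F(q)^(y−1)` — each future year is an
independent beta draw that must fall below `q`. The budget is released
when `p_best` strictly exceeds a threshold, default 0.4; the final
year always allocates since `p_best = 1`. The strict inequality is
deliberate (equality waits). Campaign outcomes are insensitive to the
threshold over 0.2–0.6 (tested at < 10% relative change), which is why
the default is not treated as a tuning parameter. A two-threshold
variant (full budget above an upper threshold, a fixed fraction of it
in a middle band) is available; the band fraction is a free parameter
with default 0.5 and similarly small influence.

## Campaign simulator

Each campaign has `total_budget` single-visit surveys (default 400) to
spend within `horizon_years` (default 5). Candidate ponds form an
unbounded pool — every survey visits a fresh pond, occupied
independently with probability 0.2 — because the aim is to maximise
*new* site discoveries, not to revisit. A year's detectability at pond
i is the weighted average `p_i = c·g + (1−c)·l_i` of one shared global
draw and an independent local draw, both from the calibrated beta.
This literal linear mixing shrinks the marginal variance of `p_i` at
intermediate `c` by a factor `c² + (1−c)²`; the implied between-pond
correlation within a year is `c²/(c²+(1−c)²)` (verified against brute
force). A mixture preserving the beta marginal at every `c` would be
an alternative; the linear form is the one implemented because it is
the plain reading of a weighted average of the two components.

Bellwether ponds are known-occupied sites disjoint from the candidate
pool. Each year until allocation, each bellwether pond costs one
survey from the budget and its realised detectability is observed
without error (larval density standing in for detectability; no
observation-noise model); multiple bellwether observations are
aggregated by their mean. After a full allocation the campaign ends —
no further bellwether costs accrue. The non-adaptive design splits the
budget evenly over the years, remainder to the earliest years.

Two execution paths exist. `simulate_campaign` is the explicit
mechanic: per-pond occupancy draws, per-pond local draws, one
Bernoulli detection trial per surveyed pond. `simulate_campaigns` and
`run_grid` vectorise over replicates using an exact marginalisation:
conditional on the year's global draw `g`, the local draws are i.i.d.,
so the detection count in a block of `b` surveys is exactly
Binomial(b, occupancy · (c·g + (1−c)·μ)) with μ the beta mean. This is
a distributional identity, not an approximation; a test checks the two
paths agree. The grid sweep (correlation 0–1 in steps of 0.05 ×
bellwether counts 0–10, 10,000 replicates per cell) runs in seconds
and gives each cell its own `SeedSequence` substream, so results are
reproducible bit-for-bit from one seed and cells are independent.

Reference-scenario outcomes (10,000 replicates): non-adaptive mean
≈ 22.8 detected ponds (analytically, 400 × 0.2 × 0.285 = 22.8); one
bellwether at full correlation ≈ 29.2; best grid cell improves on the
non-adaptive mean by ≈ 28%. More than one bellwether pond never helps
beyond Monte-Carlo noise, and at zero correlation adapting can only
lose the bellwether overhead — both asserted as test invariants rather
than read off a figure.

## Censored time-to-detection model

Surveys run until first detection or a 30-minute cap; undetected
surveys are right-censored at 30. The accelerated failure time model
is `log T = x'β + σε` with ε standard Gumbel-minimum (Weibull),
standard normal (log-normal) or Gumbel with σ ≡ 1 (exponential).
Weibull is the default family — the conventional default for
parametric survival regression — with the others as options; the
exponential family also supplies a closed-form oracle (censored MLE of
the mean = total observed time / number of events) used in the tests.

Fitting maximises the censored log-likelihood with analytic gradients
(BFGS, Nelder–Mead fallback); standard errors come from the
finite-difference Hessian at the optimum. The in-package fit agrees
with lifelines' `WeibullAFTFitter` to ~1e−4 on shared problems (kept
as an independent cross-check in the test suite) and is roughly 20×
faster, which is what makes the permutation machinery below practical;
it also provides the exponential *regression* family that lifelines
does not.

Ponds never yielding a detection are excluded before the primary fit —
the survival framework assumes every survey would eventually succeed,
and all-censored ponds more plausibly reflect wrong historical records
or extinct populations. The filter returns both partitions so the
all-pond sensitivity fit can be run; on synthetic tables with this
censoring structure the all-pond fit inflates every predicted mean but
preserves the category ordering (tested).

Model selection enumerates all subsets of the main effects (method,
year, window, observer) together with every subset of the two-way
interactions whose parents are included — 113 candidates for four main
effects — and returns the minimum-AIC fit (AIC = 2k − 2 log L,
counting the scale parameter; ties break to fewer parameters, then
lexicographic term order).

Predicted mean time to detection per category uses marginal
standardisation: each record's focal covariate is forced to the
category, model-implied means (e.g. exp(x'β)·Γ(1+σ) for Weibull) are
averaged over the empirical covariate distribution, and the delta
method on the ML covariance gives the standard error. Predictions are
unbounded when a category is entirely censored; the fit warns.

The permutation test statistic for a focal covariate is the ratio of
the maximum to the minimum predicted mean TTD across its categories
(≥ 1 by construction, one-sided). Null resamples shuffle the focal
labels across records — all other columns held fixed as collected —
and refit the same model: by default the focal main effect plus the
other minimum-AIC terms (a one-covariate refit is available by passing
`terms` explicitly). p is the proportion of resamples with a statistic
at least as large as observed; failed refits are dropped, counted, and
warned about above 1%. An exhaustive mode enumerates all distinct
label arrangements for small tables and is tested against an
independent brute-force enumeration; on 200 null datasets the sampled
p-values stay within a 1% Kolmogorov–Smirnov band of uniformity.
Repeated surveys of a pond are treated as independent (no pond frailty
term).

Survival curves are population-averaged: per-record S(t) with the
focal category forced, averaged over records. Curves start at 1, are
non-increasing, and the category with the smaller predicted mean lies
lower.

## Synthetic survey generator

The generator emulates the study design, not any particular data set:
32 ponds × 2 years × 3 seasonal windows, one of 3 methods per
pond-window, methods balanced across windows by distributing the 6
method orderings over ponds in counts of 5 or 6, each pond keeping its
order in both years; 2 observers assigned at random per visit;
30-minute censoring. Times come from the Weibull AFT model with
multiplicative factors per covariate level, plus a configurable
fraction of never-detectable ponds that are always censored. The
`FIELDLIKE_PARAMS` preset (baseline mean 9 min in the reference cell,
year factor 2.8, method factors up to 1.7, window factors ≈ 1.3, no
observer effect, shape 1.1, 47% never-detectable) is tuned only
qualitatively: a year effect dominating the method effect and roughly
half the ponds excluded by the ever-detected filter. It is synthetic
throughout — it reproduces design structure and effect *ordering*, not
any real measurements — so tests passing on it demonstrate correctness
of the machinery, not field validity. Real-data features it does not
emulate: pond-level heterogeneity in detectability (beyond the
never-detectable class), between-year correlation within ponds,
observer–pond confounding, and rounded or heaped field times.

`generate_bellwether_history` draws i.i.d. annual detectabilities from
a given beta — a stand-in for a long-term monitoring series — and
round-trips through the calibrator (empirical 9th/91st percentiles →
refit) to its generating parameters at large n.

## Problem sizes and numerical choices

Simulation tests and the acceptance script use 10,000 replicates per
configuration, the same as the study grid; the full 231-cell sweep
takes ~8 s. The permutation-uniformity property uses 200 small null
datasets at 59 resamples each, enough for the KS bound while keeping
the whole suite around two minutes. Calibration tolerance is 1e−6 on
each CDF residual; AFT convergence is judged by BFGS gradient norm
(1e−8) with a Nelder–Mead polish on failure; z-scores in the Gumbel
likelihood are clipped at ±700 before exponentiation to avoid
overflow in degenerate fits.

## Known limitations

- The linear detectability mixture shrinks marginal variance at
  intermediate correlation (see above); interior grid cells therefore
  depend on this modelling choice, though the endpoints (c = 0, 1) do
  not.
- No Bayesian updating of (α, β) from accumulating bellwether
  observations; the calibrated distribution is fixed for the campaign.
- No spatial structure, metapopulation dynamics, or revisit designs in
  the simulator; no occupancy-model estimation from simulated data.
- The survival module offers no Cox or Kaplan–Meier estimation and no
  random effects; inference treats records as independent.
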