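# Methods

## Model

hierpsy fits two-stage hierarchical probit models to forced-choice
discrimination data. At the first stage, subject $i$ in condition $h$
responds at stimulus level $x_j$ with

$$Y_{ij}^h \sim \mathrm{Binomial}(n_{ij}^h, \pi_{ij}^h), \qquad
\Phi^{-1}(\pi_{ij}^h) = \alpha_i^h + \beta_i^h x_j ,$$

equivalently, in the PSE–slope parameterization used by default,
$\Phi^{-1}(\pi_{ij}^h) = \beta_i^h\,(x_j - \mathrm{pse}_i^h)$ with
$\mathrm{pse}_i^h = -\alpha_i^h/\beta_i^h$. The two forms give identical
likelihoods on matched parameter paths (tested); the PSE–slope form makes
the quantity of scientific interest a sampled parameter rather than a
derived ratio. Responses are assumed conditionally independent given the
subject's curve; the binomial coefficient is included in all reported
log-likelihoods so values are comparable between per-trial and aggregated
representations of the same data up to the fixed multinomial constant.

At the second stage, subject parameters are exchangeable normal draws
around population locations. **Every normal distribution in the package is
parameterized by mean and precision** (inverse variance), and all Gamma
distributions by shape and rate — the convention of the BUGS/JAGS model
language this model family is usually written in. The default hyperpriors
are

| parameter | prior | role |
|---|---|---|
| $\tau_{\mathrm{pse}}^h$, $\tau_\beta^h$ | Gamma(1, 0.001) | between-subject precisions |
| $\mathrm{PSE}^h$, $b^h$ | Normal(0, $\sigma$) | population locations |
| $\sigma_{\mathrm{pse}}$, $\sigma_b$ | Gamma(1, 0.01) | precisions of the location priors |

Gamma(1, rate) is an exponential with mean 1/rate: these priors favour
large precisions a priori and are only weakly informative once a handful of
subjects inform $\tau$; the data dominate the location posteriors entirely
in all shipped designs. Population prior means are fixed at 0.

Model variants differ only in indexing, built by `build_model`:

* `intercept_slope` / `pse_slope` — per-condition populations and
  precisions;
* `per_subject_precision` — first-stage precisions indexed by subject
  ($\tau_{\mathrm{pse},i}$, $\tau_{b,i}$), letting individual reliability
  differ;
* `grouped` — populations and precisions indexed by (group, condition) for
  multi-group designs (e.g. clinical groups);
* `build_joint_model` — two studies fitted jointly, current population
  locations given normal priors centred at the historical ones (slope
  centre multiplied by a conversion factor, below); the posterior
  second-stage precisions then quantify between-study agreement. In this
  variant all precision hyperpriors default to Gamma(1, 0.01).

## Power prior

With a historical study $D_0$ and weight $a_0 \in [0,1]$, the prior for the
current study is $\pi(\theta \mid D_0, a_0) \propto L(\theta \mid
D_0)^{a_0}\, \pi_0(\theta)$. Concretely the package builds one joint
parameter space in which the two studies **share the population locations**
(subject-level parameters and first-stage precisions are study-specific,
since the observers differ) and the historical log-likelihood enters
multiplied by $a_0$. At $a_0 = 0$ the historical block is data-free and
integrates out of the shared-parameter marginal; at $a_0 = 1$ the two
studies are pooled. Both identities hold as exact log-density statements
and are tested to machine precision, as is affinity of the log posterior in
$a_0$.

Because psychometric slopes scale with the stimulus range probed
(Weber-type behaviour), the shared slope location is mapped onto the
historical study through a **conversion factor** $c$: historical subject
slopes are centred at $b^h/c$. The default is $c = \bar x / \bar x_0$, the
ratio of mean current to mean historical stimulus. The orientation of this
ratio is a genuine modelling choice — an argument from slopes inversely
proportional to stimulus magnitude would motivate the reciprocal — so the
factor is a single explicit configuration value (`conversion=`), never
inferred silently. Grid selection of $a_0$ (`select_a0`, CLI `power-grid`)
minimizes the width of the population-PSE credible interval, breaking ties
toward larger $a_0$ (more borrowing at equal uncertainty).

## Sampling

The sampler is an adaptive Metropolis-within-Gibbs scheme written for this
model family, exploiting two structural facts: only subject-level curve
parameters touch the likelihood, and every other node is conditionally
conjugate (linear-Gaussian locations, gamma precisions).

Per iteration:

1. **Subject locations** — random-walk Metropolis, one proposal per
   parameter, vectorized across all (subject, condition) blocks; blocks
   share no cells or prior terms, so their accept/reject decisions are
   independent given the rest.
2. **Translation moves** — for each population location $L$, propose
   shifting $L$ and every child whose prior mean references it by a common
   $\delta$ (scaled by the child's mean coefficient). Child deviations are
   invariant, so the move is governed by the likelihood; it removes the
   slow joint drift that component-wise updates suffer when a first-stage
   precision is large and subjects are pinned to their population location.
3. **Population locations** — exact conjugate normal Gibbs draws.
4. **Precisions** (all $\tau$ and $\sigma$) — exact conjugate gamma Gibbs
   draws.

Proposal scales adapt toward 0.44 acceptance in windows of 25 iterations
during warmup only; post-warmup the scales are frozen, so the retained
chain is a valid Markov chain for the stated posterior. Defaults are 4
chains × 5000 warmup + 5000 kept iterations, thinning 1 (chain settings are
a package choice; no external defaults exist for this model family).

Initial states are drawn generatively from the hyperpriors per chain
(precisions first, then locations parent-before-child); a precision draw
below $10^{-8}$ is replaced by its prior mean to avoid overflowing location
draws. One master seed deterministically spawns per-chain generators;
identical (seed, config, data, spec) reproduce draws bit-identically.
Success probabilities are clamped to $[10^{-12}, 1-10^{-12}]$ inside the
likelihood so saturated curves keep finite log terms.

`sample_logposterior` exposes the same adaptive random-walk core for
arbitrary low-dimensional log densities; the test suite uses it to verify
the sampler against closed-form conjugate posteriors (normal–normal and
beta–binomial), in addition to parameter-recovery and credible-interval
coverage checks on data simulated from the hierarchy itself.

## Diagnostics and summaries

R-hat is the split, rank-normalized statistic: chains are halved, ranks are
taken over the pooled draws, mapped through the normal quantile function
(offset (r − 3/8)/(S + 1/4)), and the classical between/within variance
ratio is computed; the reported value is the maximum of this bulk statistic
and the same computed on draws folded about their median (tail behaviour).
Identical constant chains return 1 by convention. The statistic agrees with
an independent implementation and with a plain split-R-hat on well-mixed
chains; note that for pathologically separated chains the rank-normalized
form saturates (≈1.7 for two arbitrarily distant chains) where the plain
variance ratio diverges — both are far above any conventional threshold.

Summaries pool draws across chains: mean, sd, median, and central credible
intervals from empirical percentiles with linear interpolation (the 95%
interval of draws 1..100 is (3.475, 97.525)). Under the intercept–slope
parameterization, PSE summaries are computed from the per-draw stream
$-\alpha/\beta$, never from the ratio of summaries.

## Comparison metrics

* **lppd** $= \sum_i \log\bigl(S^{-1}\sum_s p(y_i\mid\theta_s)\bigr)$ over
  observation cells, computed with a numerically stable log-sum-exp. The
  parenthetical Monte Carlo error is the standard deviation of per-chain
  lppd values — a spread diagnostic, not a formal standard error.
* **Log-likelihood at posterior means**, at two effects levels: the
  *individual* level plugs in each subject's posterior-mean curve; the
  *overall* level applies the population posterior-mean curve of the
  cell's (group, condition) to every cell. This is the only reading that
  yields the two rows per model that comparison tables carry.
* **Sum of squared errors** $= \sum_i (y_i/n_i - \hat\pi_i)^2$ with
  $\hat\pi$ from posterior-mean parameters at either effects level.
  Individual-level SSE is smaller than overall-level SSE on average
  whenever real between-subject variance exists (tested).
* **Posterior overlap** — both samples are histogrammed on their common
  range with `n_bins` equal-width bins (default 50), each normalized to
  unit area; the overlap is the summed bin-wise minimum density times bin
  width. It is symmetric, lies in [0, 1], and matches the closed form
  $2\Phi(-\tfrac12) \approx 0.617$ for unit-shifted unit normals at large
  sample size. Sensitivity to binning is real; `n_bins` is exposed.
* Comparison tables carry exactly the columns `model, effects, loglik,
  lppd, lppd_mc_error, sse, pse_ci_low, pse_ci_high, ci_width`; the
  reported population-PSE interval is that of the first-listed group and
  condition unless another parameter is requested.

## Synthetic data

The generator (`simulate`) draws from exactly the hierarchy the models
assume: subject parameters from the population normals (precisions above
$10^{12}$ collapse subjects onto the population values), then binomial
counts per design cell. Two presets emulate the package's reference study
layouts:

* `touch_vibrations` — 9 observers, 2 masking conditions, 7 speeds evenly
  spaced over 1.0–16.0 cm/s, 40 repetitions per cell (560 trials each);
* `touch_diabetes` — 3 groups × 20 observers, 2 masking conditions, 5
  speeds evenly spaced over 0.6–6.4 cm/s, reference 3.4 cm/s, 12
  repetitions per cell (120 trials each; only the total is published — the
  even per-cell split is our choice).

Exact stimulus grids of the original studies are not published; evenly
spaced grids between the stated endpoints are an emulation, not a
reproduction. The named truths (`preset_truth`) put the no-masking curves
across roughly (0.1, 0.9) over the grid, reduce slopes under masking and
with tactile dysfunction, and set unbiased PSEs (3.4 cm/s at the clinical
design's reference). Between-subject precisions (25 for PSE, 100–400 for
slope) give realistic heterogeneity of a few tenths of a cm/s in PSE and
~20% in slope.

What the generator does **not** emulate: lapses and finite asymptotes,
adaptive/staircase stimulus placement, sequential learning or fatigue,
shared trial-order effects, and any stimulus-scale transformation. Passing
recovery tests therefore demonstrate correctness of the inference under the
model's own assumptions, not robustness to their violation in real data.

## Problem sizes and numerical choices

Test fits use deliberately reduced chain lengths (hundreds to a few
thousand iterations, 2–4 chains) and reduced designs (4–9 subjects for
repeated-fit checks; the full 20-subject control group for the
convergence and recovery checks); the acceptance script uses the default
4 × (5000 + 5000) configuration on the full control-group design. With 120
trials per participant the *empirical* PSE of a simulated control group has
a realization standard deviation of roughly 0.1 cm/s around the true 3.4;
the acceptance script therefore averages the two (equally unbiased)
condition-level population-PSE posterior means into its single reported
value.

Degenerate inputs: a flat curve has no PSE (`pse_from_params` raises at
$\beta = 0$); the JND requires $\beta > 0$; non-positive precisions make
the log prior $-\infty$ (rejected by the sampler, never raised); subjects
observed at a single stimulus level are flagged as slope-unidentifiable by
`validate_trials`; an empty current table in a two-study model reduces the
posterior to the historical model's.

## Known limitations

* Probit link only; the link is an isolated function but no alternates are
  wired through.
* No lapse/guess-rate parameters — saturating curves are handled only by
  probability clamping.
* Stimulus values are used on the scale provided; no automatic log or
  z-transform. PSEs and slopes inherit that scale, and the power-prior
  conversion factor is the only cross-scale device.
* Under Gamma(1, 0.001) precision priors, $\tau$ is weakly identified when
  per-subject estimation noise exceeds true between-subject spread; its
  posterior then rides the prior toward large values. Population locations
  remain well identified (the regime is effectively complete pooling).
* The power prior shares population locations across studies wholesale;
  if the studies genuinely differ in bias, borrowing shifts the current
  estimates — the $a_0$ grid is the instrument for noticing that.
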