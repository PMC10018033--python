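# hierpsy

Bayesian hierarchical probit models for fitting psychometric functions to
two-interval forced-choice data, with power-prior borrowing from historical
studies.

## The problem

In a two-interval forced-choice experiment an observer compares a comparison
stimulus of magnitude $x$ (e.g. surface speed in cm/s) against a reference
and reports, say, which one moved faster. The probability of a "faster"
response follows a sigmoid psychometric function; under a probit link,

$$Y_{ij} \sim \mathrm{Binomial}(n_{ij},\,\pi_{ij}), \qquad
\Phi^{-1}(\pi_{ij}) = \alpha_i + \beta_i x_{ij},$$

for subject $i$ at stimulus $x_{ij}$. Two summaries matter: the **point of
subjective equality** $\mathrm{PSE}_i = -\alpha_i/\beta_i$, the stimulus at
which responses are at chance (its deviation from the reference measures
response bias), and the slope $\beta_i$, whose inverse scales the **just
noticeable difference** ($\mathrm{JND} = \Phi^{-1}(0.75)/\beta$), the
precision of the observer.

Fitting each observer separately wastes the information they share; pooling
them naively misstates the uncertainty. hierpsy fits the two-stage
hierarchy the way mixed models do, but fully Bayesian: subject curves are
exchangeable draws from population distributions,

$$\mathrm{pse}_i^h \sim \mathcal N(\mathrm{PSE}^h, \tau_{\mathrm{pse}}^h),
\qquad \beta_i^h \sim \mathcal N(b^h, \tau_\beta^h),$$

(superscript $h$ indexes an experimental condition such as masking
vibration on/off; second arguments are **precisions**), with
$\mathcal N(0,\sigma)$ priors on the population locations and
Gamma(1, 0.001) / Gamma(1, 0.01) hyperpriors on the first- and second-stage
precisions. Posterior draws give credible intervals for population and
subject parameters alike.

When a comparable earlier study exists, its data $D_0$ can inform the
current fit through a **power prior**,

$$\pi(\theta \mid D_0, a_0) \propto L(\theta \mid D_0)^{a_0}\,\pi_0(\theta),
\qquad a_0 \in [0, 1],$$

where $a_0 = 0$ ignores and $a_0 = 1$ fully pools the historical study; a
grid over $a_0$, scored by the width of the population-PSE credible
interval, selects how much to borrow. A slope conversion factor maps
historical slopes across stimulus ranges (Weber-type scaling).

The toolkit includes the comparison metrics used with such models: log
pointwise predictive density (lppd), sum of squared errors at the subject
and population level, credible-interval widths, the histogram-overlap
statistic between two posteriors, and split rank-normalized R-hat
convergence diagnostics. Sampling uses an adaptive Metropolis-within-Gibbs
scheme written for this model family (conjugate Gibbs updates for all
locations and precisions that do not touch the likelihood; details in
`docs/methods.md`).

## Worked example

Simulate a masking-vibration study (9 observers, 7 speeds from 1 to
16 cm/s, 40 repetitions per cell, with/without masking vibration) from the
package's generative presets, and fit the PSE–slope parameterization:

```python
from hierpsy import (
    ChainConfig, build_model, jnd_from_slope, lppd, posterior_overlap,
    preset_design, preset_truth, run_chains, simulate_study,
    summarize_posterior,
)

design = preset_design("touch_vibrations")
truth = preset_truth("touch_vibrations")        # PSE 6.0; slopes 0.26 / 0.17
table, _ = simulate_study(design, truth, seed=21)

spec = build_model("pse_slope")
config = ChainConfig(n_chains=4, n_iterations=2000, n_warmup=2000, seed=0)
draws = run_chains(spec, table, config)

summary = summarize_posterior(draws, spec=spec)
print(summary.loc[["PSE[cond=vib0]", "PSE[cond=vib1]",
                   "b[cond=vib0]", "b[cond=vib1]"],
                  ["mean", "sd", "ci_low", "ci_high", "rhat"]].round(3))

value, mc_error = lppd(draws, spec, table)
print(f"lppd = {value:.1f} (mc error {mc_error:.2f})")
overlap = posterior_overlap(draws.pooled("b[cond=vib0]"),
                            draws.pooled("b[cond=vib1]"))
print(f"slope overlap (vib0 vs vib1) = {overlap:.3f}")
print(f"JND without masking = "
      f"{jnd_from_slope(summary.loc['b[cond=vib0]', 'mean']):.2f} cm/s")
```

Output:

```
                 mean     sd  ci_low  ci_high   rhat
parameter
PSE[cond=vib0]  6.039  0.229   5.583    6.515  1.003
PSE[cond=vib1]  5.675  0.321   5.029    6.290  1.007
b[cond=vib0]    0.269  0.020   0.228    0.310  1.002
b[cond=vib1]    0.166  0.017   0.132    0.201  1.001
lppd = -260.0 (mc error 1.95)
slope overlap (vib0 vs vib1) = 0.011
JND without masking = 2.51 cm/s
```

The fit recovers the generating truth: population PSEs near 6.0 cm/s in
both conditions (no bias from masking), a markedly lower slope with masking
vibration (0.166 vs 0.269, posterior overlap ~0.01 — the distributions are
essentially disjoint, so masking degrades precision), and R-hat at 1.00 for
every population parameter. The JND of 2.5 cm/s is the speed difference an
average observer resolves at the 75% point.

The same pipeline is scriptable from the shell:

```
hierpsy simulate --preset touch_diabetes --seed 1 --out runs/sim
hierpsy fit --data runs/sim/data.csv --model grouped --seed 1 --out runs/fit
hierpsy power-grid --data current.csv --historical old.csv \
    --a0-grid 0,0.1,0.2,0.3,0.4,0.5,0.6,0.7,0.8,0.9,1 --out runs/grid
```

`fit` writes the draws (CSV + provenance sidecar), a posterior summary with
R-hat per parameter, and a comparison row; `power-grid` writes one row per
a0 and the selection under the minimum-CI-width criterion.

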