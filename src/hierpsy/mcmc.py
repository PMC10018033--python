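"""Posterior sampling, convergence diagnostics and posterior summaries.

The sampler is an adaptive Metropolis-within-Gibbs scheme tailored to the
hierarchical probit structure:

* subject-level curve parameters (the only likelihood-bearing nodes) are
  updated by component-wise random-walk Metropolis, vectorized across
  subjects — the (subject, condition) blocks share no cells and no prior
  terms, so their accept/reject decisions are independent given the rest;
* population locations are linear-Gaussian given everything else and are
  updated by exact conjugate normal Gibbs draws;
* all precisions (gamma hyperpriors throughout) are updated by exact
  conjugate gamma Gibbs draws.

Per-parameter proposal scales adapt toward a 0.44 acceptance rate during
warmup and are frozen afterwards, so the post-warmup chain is a valid
Markov chain targeting ``exp(log posterior)``.  A single master seed
deterministically derives one stream per chain; identical (seed, config,
data, spec) yield bit-identical draws.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.stats import rankdata

from .data import TrialTable
from .models import CompiledModel, ModelSpec, PowerPriorSpec, compile_model

__all__ = [
    "ChainConfig",
    "PosteriorDraws",
    "run_chains",
    "gelman_rubin",
    "summarize_posterior",
    "sample_logposterior",
]

_TARGET_ACCEPT = 0.44  # optimal for component-wise random walk


@dataclass(frozen=True)
class ChainConfig:
    """MCMC run settings.

    ``n_iterations`` counts post-warmup iterations; every ``thinning``-th of
    them is stored, so ``n_iterations // thinning`` draws are kept per
    chain.  At least two chains are required so that R-hat is defined.
    """

    n_chains: int = 4
    n_iterations: int = 5000
    n_warmup: int = 5000
    thinning: int = 1
    seed: int = 0
    init_scale: float = 0.2
    adapt_window: int = 25

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("n_chains must be >= 2 (R-hat needs multiple chains)")
        if self.n_iterations < 1 or self.n_warmup < 0:
            raise ValueError("n_iterations must be >= 1 and n_warmup >= 0")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if not self.init_scale > 0:
            raise ValueError("init_scale must be positive")

    @property
    def n_kept(self) -> int:
        return self.n_iterations // self.thinning


@dataclass
class PosteriorDraws:
    """MCMC output: (chain, iteration, parameter) array with provenance."""

    names: list[str]
    array: np.ndarray  # (n_chains, n_kept, n_params)
    config: ChainConfig
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.array.ndim != 3 or self.array.shape[2] != len(self.names):
            raise ValueError("draw array must be (chains, iterations, parameters)")
        self._index = {nm: i for i, nm in enumerate(self.names)}

    @property
    def n_chains(self) -> int:
        return self.array.shape[0]

    @property
    def n_draws(self) -> int:
        return self.array.shape[1]

    def get(self, name: str) -> np.ndarray:
        """Draws of one parameter, shape (chains, iterations)."""
        try:
            return self.array[:, :, self._index[name]]
        except KeyError:
            raise KeyError(f"no parameter {name!r} in draws") from None

    def pooled(self, name: str) -> np.ndarray:
        """Draws of one parameter pooled across chains, 1-D."""
        return self.get(name).reshape(-1)

    def matrix(self) -> np.ndarray:
        """All draws pooled across chains, shape (S, n_params)."""
        return self.array.reshape(-1, self.array.shape[2])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in range(self.n_chains):
            df = pd.DataFrame(self.array[c], columns=self.names)
            df.insert(0, "iteration", np.arange(self.n_draws))
            df.insert(0, "chain", c)
            rows.append(df)
        return pd.concat(rows, ignore_index=True)

    def save(self, directory: str | Path) -> None:
        """Persist as draws.csv plus a JSON provenance sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(directory / "draws.csv", index=False, float_format="%.17g")
        sidecar = {"config": asdict(self.config), "provenance": self.provenance}
        (directory / "draws.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "PosteriorDraws":
        directory = Path(directory)
        df = pd.read_csv(directory / "draws.csv")
        sidecar = json.loads((directory / "draws.json").read_text())
        names = [c for c in df.columns if c not in ("chain", "iteration")]
        chains = sorted(df["chain"].unique())
        arr = np.stack([df[df["chain"] == c][names].to_numpy() for c in chains])
        return cls(
            names=names,
            array=arr,
            config=ChainConfig(**sidecar["config"]),
            provenance=sidecar.get("provenance", {}),
        )


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------


def _initial_state(cm: CompiledModel, rng: np.random.Generator) -> np.ndarray:
    """Generative initialization: draw every node from its prior.

    Precisions come first (gamma hyperpriors), then locations in
    parent-before-child order.  A precision draw too small to give a sane
    location scale is replaced by its prior mean.
    """
    v = np.zeros(cm.n_params)
    for g in range(len(cm.gn_idx)):
        j = int(cm.gn_idx[g])
        draw = rng.gamma(cm.gn_shape[g], 1.0 / cm.gn_rate[g])
        if not np.isfinite(draw) or draw <= 1e-8:
            draw = cm.gn_shape[g] / cm.gn_rate[g]
        v[j] = draw
    ve = np.concatenate([v, [0.0, 1.0]])
    for k in range(len(cm.nn_child)):
        m = ve[cm.nn_midx[k]] * cm.nn_mscale[k] + cm.nn_mconst[k]
        prec = max(float(ve[cm.nn_pidx[k]] * cm.nn_pconst[k]), 1e-8)
        child = int(cm.nn_child[k])
        v[child] = m + rng.standard_normal() / math.sqrt(prec)
        ve[child] = v[child]
    return v


class _MHBlock:
    """Vectorized random-walk Metropolis over one family of subject locations."""

    def __init__(self, cm: CompiledModel, which: int, init_scale: float):
        self.cm = cm
        self.which = which  # 1 -> loc1 (pse/alpha), 2 -> loc2 (beta)
        self.idxs = cm.subject_loc1 if which == 1 else cm.subject_loc2
        self.block = cm.cell_block1 if which == 1 else cm.cell_block2
        nodes = np.asarray([cm.prior_node_of[int(i)] for i in self.idxs], dtype=np.intp)
        self.pm_idx = cm.nn_midx[nodes]
        self.pm_scale = cm.nn_mscale[nodes]
        self.pm_const = cm.nn_mconst[nodes]
        self.pp_idx = cm.nn_pidx[nodes]
        self.K = len(self.idxs)
        self.scales = np.full(self.K, init_scale)
        self.accepts = np.zeros(self.K)

    def _cell_logpmf_prop(self, v: np.ndarray, prop: np.ndarray) -> np.ndarray:
        cm = self.cm
        x = cm.cell_x
        if cm.is_pse:
            if self.which == 1:
                eta = v[cm.cell_i2] * (x - prop[self.block])
            else:
                eta = prop[self.block] * (x - v[cm.cell_i1])
        else:
            if self.which == 1:
                eta = prop[self.block] + v[cm.cell_i2] * x
            else:
                eta = v[cm.cell_i1] + prop[self.block] * x
        from .models import PROB_CLAMP

        p = np.clip(ndtr(eta), PROB_CLAMP, 1.0 - PROB_CLAMP)
        return cm.cell_lgamma + cm.cell_y * np.log(p) + (cm.cell_n - cm.cell_y) * np.log1p(-p)

    def step(self, v: np.ndarray, ll_cell: np.ndarray, rng: np.random.Generator) -> None:
        cm = self.cm
        cur = v[self.idxs]
        prop = cur + self.scales * rng.standard_normal(self.K)
        llp = self._cell_logpmf_prop(v, prop)
        delta = np.bincount(
            self.block, weights=cm.cell_w * (llp - ll_cell), minlength=self.K
        )
        ve = np.concatenate([v, [0.0, 1.0]])
        m = ve[self.pm_idx] * self.pm_scale + self.pm_const
        prec = ve[self.pp_idx]
        delta += -0.5 * prec * ((prop - m) ** 2 - (cur - m) ** 2)
        acc = np.log(rng.uniform(size=self.K)) < delta
        v[self.idxs[acc]] = prop[acc]
        cell_acc = acc[self.block]
        ll_cell[cell_acc] = llp[cell_acc]
        self.accepts += acc

    def adapt(self, window: int) -> None:
        rate = self.accepts / window
        self.scales *= np.exp(rate - _TARGET_ACCEPT)
        np.clip(self.scales, 1e-4, 50.0, out=self.scales)
        self.accepts[:] = 0.0


class _TranslationMoves:
    """Joint shifts of a population location together with its children.

    Component-wise updates mix slowly when a first-stage precision is large:
    subjects are tied tightly to their population location and the whole
    cluster can only drift. A translation move proposes ``L -> L + delta``
    and ``child -> child + s_child * delta`` for every node whose prior mean
    references ``L`` (scale ``s_child``), leaving all child deviations
    invariant; the accept ratio is driven by the likelihood plus the few
    prior terms that do change.  One adaptive scalar scale per population
    location.
    """

    def __init__(self, cm: CompiledModel, init_scale: float):
        self.cm = cm
        empty = np.asarray([], dtype=np.intp)
        self.moves = []
        for j in cm.pop_locs:
            j = int(j)
            ks = cm.mean_children.get(j, empty)
            params = np.concatenate([[j], cm.nn_child[ks]]).astype(np.intp)
            scales = np.concatenate([[1.0], cm.nn_mscale[ks]])
            self.moves.append((params, scales))
        self.K = len(self.moves)
        self.scales = np.full(self.K, init_scale)
        self.accepts = np.zeros(self.K)

    def step(self, v: np.ndarray, ll_cell: np.ndarray, rng: np.random.Generator) -> None:
        cm = self.cm
        for k, (params, scales) in enumerate(self.moves):
            delta = self.scales[k] * rng.standard_normal()
            vp = v.copy()
            vp[params] += scales * delta
            llp = cm.cell_logpmf(vp)
            d = float(np.dot(cm.cell_w, llp - ll_cell))
            d += cm.logprior(vp) - cm.logprior(v)
            if math.log(rng.uniform()) < d:
                v[params] = vp[params]
                ll_cell[:] = llp
                self.accepts[k] += 1

    def adapt(self, window: int) -> None:
        rate = self.accepts / window
        self.scales *= np.exp(rate - _TARGET_ACCEPT)
        np.clip(self.scales, 1e-4, 50.0, out=self.scales)
        self.accepts[:] = 0.0


class _GibbsEngine:
    """Precomputed conjugate updates for population locations and precisions."""

    def __init__(self, cm: CompiledModel):
        self.cm = cm
        empty = np.asarray([], dtype=np.intp)
        self.loc_updates = []
        for j in cm.pop_locs:
            j = int(j)
            k0 = cm.prior_node_of[j]
            ks = cm.mean_children.get(j, empty)
            self.loc_updates.append(
                (
                    j,
                    cm.nn_midx[k0], cm.nn_mscale[k0], cm.nn_mconst[k0], cm.nn_pidx[k0],
                    cm.nn_child[ks], cm.nn_mscale[ks], cm.nn_mconst[ks], cm.nn_pidx[ks],
                )
            )
        self.prec_updates = []
        for g in range(len(cm.gn_idx)):
            j = int(cm.gn_idx[g])
            ks = cm.prec_children.get(j, empty)
            self.prec_updates.append(
                (
                    j,
                    cm.gn_shape[g] + 0.5 * len(ks),
                    cm.gn_rate[g],
                    cm.nn_child[ks], cm.nn_midx[ks], cm.nn_mscale[ks], cm.nn_mconst[ks],
                )
            )

    def step(self, v: np.ndarray, rng: np.random.Generator) -> None:
        ve = np.concatenate([v, [0.0, 1.0]])
        for j, m0i, m0s, m0c, p0i, ch, cs, cc, cp in self.loc_updates:
            m0 = ve[m0i] * m0s + m0c
            p0 = ve[p0i]
            prk = ve[cp]
            P = p0 + float(np.sum(cs * cs * prk))
            M = (p0 * m0 + float(np.sum(cs * prk * (ve[ch] - cc)))) / P
            val = M + rng.standard_normal() / math.sqrt(P)
            v[j] = val
            ve[j] = val
        for j, shape, rate0, ch, mi, ms, mc, in self.prec_updates:
            m = ve[mi] * ms + mc
            rate = rate0 + 0.5 * float(np.sum((ve[ch] - m) ** 2))
            val = rng.gamma(shape, 1.0 / rate)
            v[j] = val
            ve[j] = val


def run_chains(
    spec: ModelSpec,
    data: TrialTable,
    config: ChainConfig,
    power: PowerPriorSpec | None = None,
    historical: TrialTable | None = None,
    init: Mapping[str, float] | None = None,
) -> PosteriorDraws:
    """Sample the posterior of ``spec`` fitted to ``data``.

    With ``power`` given, the target is the power-prior posterior (the
    historical likelihood enters at weight ``a0``); with a joint spec, pass
    the historical table via ``historical``.  Initial states are drawn from
    the hyperpriors independently per chain unless ``init`` provides a full
    named parameter set (used for every chain).
    """
    cm = compile_model(spec, data, historical=historical, power=power)
    n_total = config.n_warmup + config.n_iterations
    kept = config.n_kept
    out = np.empty((config.n_chains, kept, cm.n_params))

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    init_vec = cm.pack(init) if init is not None else None

    for c in range(config.n_chains):
        rng = np.random.default_rng(seeds[c])
        v = None
        for _attempt in range(20):
            cand = init_vec.copy() if init_vec is not None else _initial_state(cm, rng)
            if np.isfinite(cm.logpost(cand)):
                v = cand
                break
        if v is None:
            raise RuntimeError(
                "initialization failure: log posterior non-finite at every attempted "
                f"initial state (chain {c}); check the data/model structure"
            )
        mh1 = _MHBlock(cm, 1, config.init_scale)
        mh2 = _MHBlock(cm, 2, config.init_scale)
        trans = _TranslationMoves(cm, config.init_scale)
        gibbs = _GibbsEngine(cm)
        ll_cell = cm.cell_logpmf(v)
        k = 0
        for t in range(n_total):
            mh1.step(v, ll_cell, rng)
            mh2.step(v, ll_cell, rng)
            trans.step(v, ll_cell, rng)
            gibbs.step(v, rng)
            warm = t < config.n_warmup
            if warm and (t + 1) % config.adapt_window == 0:
                mh1.adapt(config.adapt_window)
                mh2.adapt(config.adapt_window)
                trans.adapt(config.adapt_window)
            if not warm:
                s = t - config.n_warmup
                if (s + 1) % config.thinning == 0 and k < kept:
                    out[c, k] = v
                    k += 1

    provenance = {
        "sampler": "adaptive random-walk Metropolis within Gibbs",
        "spec_digest": cm.spec.digest(),
        "data_digest": cm.data_digest(),
        "variant": spec.variant or spec.parameterization,
        "a0": power.a0 if power is not None else None,
    }
    return PosteriorDraws(names=list(cm.names), array=out, config=config, provenance=provenance)


# ---------------------------------------------------------------------------
# generic component-wise sampler (small problems, arbitrary log densities)
# ---------------------------------------------------------------------------


def sample_logposterior(
    logpost: Callable[[np.ndarray], float],
    x0: Sequence[float],
    config: ChainConfig,
) -> np.ndarray:
    """Adaptive component-wise random-walk Metropolis on a raw log density.

    A small general-purpose sampler sharing the adaptation rule of the main
    engine; useful for low-dimensional targets with known closed forms.
    Returns an array of shape (n_chains, kept, d).
    """
    x0 = np.asarray(x0, dtype=float)
    d = x0.size
    kept = config.n_kept
    out = np.empty((config.n_chains, kept, d))
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    for c in range(config.n_chains):
        rng = np.random.default_rng(seeds[c])
        x = x0.copy()
        lp = float(logpost(x))
        if not np.isfinite(lp):
            raise ValueError("log density non-finite at the initial state")
        scales = np.full(d, config.init_scale)
        accepts = np.zeros(d)
        k = 0
        n_total = config.n_warmup + config.n_iterations
        for t in range(n_total):
            for i in range(d):
                prop = x.copy()
                prop[i] += scales[i] * rng.standard_normal()
                lp_prop = float(logpost(prop))
                if math.log(rng.uniform()) < lp_prop - lp:
                    x, lp = prop, lp_prop
                    accepts[i] += 1
            warm = t < config.n_warmup
            if warm and (t + 1) % config.adapt_window == 0:
                rate = accepts / config.adapt_window
                scales *= np.exp(rate - _TARGET_ACCEPT)
                np.clip(scales, 1e-6, 100.0, out=scales)
                accepts[:] = 0.0
            if not warm:
                s = t - config.n_warmup
                if (s + 1) % config.thinning == 0 and k < kept:
                    out[c, k] = x
                    k += 1
    return out


# ---------------------------------------------------------------------------
# diagnostics and summaries
# ---------------------------------------------------------------------------


def _split_halves(x: np.ndarray) -> np.ndarray:
    n = x.shape[1] // 2
    return np.concatenate([x[:, :n], x[:, x.shape[1] - n:]], axis=0)


def _basic_rhat(x: np.ndarray) -> float:
    m, n = x.shape
    chain_means = x.mean(axis=1)
    w = float(x.var(axis=1, ddof=1).mean())
    b = n * float(chain_means.var(ddof=1))
    if w <= 0.0:
        return 1.0 if b <= 0.0 else math.inf
    var_plus = (n - 1) / n * w + b / n
    return math.sqrt(var_plus / w)


def _rank_normal(x: np.ndarray) -> np.ndarray:
    r = rankdata(x, method="average").reshape(x.shape)
    return ndtri((r - 0.375) / (x.size + 0.25))


def _rhat_one(x: np.ndarray) -> float:
    """Split, rank-normalized R-hat (max of bulk and folded statistics)."""
    if np.ptp(x) == 0.0:
        return 1.0  # identical constant chains, by convention
    bulk = _basic_rhat(_split_halves(_rank_normal(x)))
    folded = _basic_rhat(_split_halves(_rank_normal(np.abs(x - np.median(x)))))
    return max(bulk, folded)


def gelman_rubin(draws: PosteriorDraws | np.ndarray, names: Sequence[str] | None = None):
    """Per-parameter convergence statistic R-hat.

    The ratio of between-chain to within-chain variability, computed on
    split, rank-normalized chains (the bulk statistic) and on folded draws
    (the tail statistic); the larger of the two is reported.  Values near 1
    (conventionally within 1 +/- 0.1) indicate convergence.

    Accepts :class:`PosteriorDraws` (returns a dict name -> R-hat) or a
    raw (chains, iterations) array for a single parameter (returns float).
    """
    if isinstance(draws, PosteriorDraws):
        arr = draws.array
        if arr.shape[0] < 2:
            raise ValueError("R-hat requires n_chains >= 2")
        if arr.shape[1] < 4:
            raise ValueError("R-hat requires at least 4 post-warmup iterations")
        names = names if names is not None else draws.names
        return {nm: _rhat_one(draws.get(nm)) for nm in names}
    arr = np.asarray(draws, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a (chains, iterations) array")
    if arr.shape[0] < 2:
        raise ValueError("R-hat requires n_chains >= 2")
    if arr.shape[1] < 4:
        raise ValueError("R-hat requires at least 4 post-warmup iterations")
    return _rhat_one(arr)


def _derived_pse_streams(draws: PosteriorDraws) -> dict[str, np.ndarray]:
    """Per-draw PSE streams from intercept/slope pairs (pse = -alpha/beta)."""
    out: dict[str, np.ndarray] = {}
    pairs = [
        ("alpha[", "beta[", "pse["),
        ("alpha0[", "beta0[", "pse0["),
        ("a[", "b[", "PSE["),
        ("a0[", "b0[", "PSE0["),
    ]
    for nm in draws.names:
        for apre, bpre, out_pre in pairs:
            if nm.startswith(apre):
                partner = bpre + nm[len(apre):]
                if partner in draws.names:
                    alpha = draws.get(nm)
                    beta = draws.get(partner)
                    with np.errstate(divide="ignore", invalid="ignore"):
                        out[out_pre + nm[len(apre):]] = -alpha / beta
                break
    return out


def summarize_posterior(
    draws: PosteriorDraws, level: float = 0.95, spec: ModelSpec | None = None
) -> pd.DataFrame:
    """Posterior summary table pooled across chains.

    Per parameter: mean, sd, median, central credible interval at ``level``
    (empirical percentiles, linear interpolation) and R-hat.  When ``spec``
    uses the intercept--slope parameterization, derived PSE rows are added,
    summarizing the transformed per-draw stream ``-alpha/beta`` (never the
    ratio of summaries).
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    if draws.n_draws == 0:
        raise ValueError("empty draws")
    lo_q = 100.0 * (1.0 - level) / 2.0
    hi_q = 100.0 - lo_q

    streams: dict[str, np.ndarray] = {nm: draws.get(nm) for nm in draws.names}
    if spec is not None and spec.parameterization == "intercept_slope":
        streams.update(_derived_pse_streams(draws))

    rows = []
    multi = draws.n_chains >= 2 and draws.n_draws >= 4
    for nm, x in streams.items():
        pooled = x.reshape(-1)
        lo, med, hi = np.percentile(pooled, [lo_q, 50.0, hi_q])
        rows.append(
            {
                "parameter": nm,
                "mean": float(pooled.mean()),
                "sd": float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0,
                "median": float(med),
                "ci_low": float(lo),
                "ci_high": float(hi),
                "rhat": _rhat_one(x) if multi else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")
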