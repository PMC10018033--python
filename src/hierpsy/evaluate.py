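"""Model comparison and posterior-similarity metrics.

Implements the comparison toolkit used throughout the package: pointwise
predictive density (lppd), sum of squared errors at the individual and
population level, log-likelihood at posterior means, credible-interval
widths for the population PSE, the histogram-overlap statistic between two
posterior samples, and grid selection of the power-prior weight ``a0`` by
minimum credible-interval width.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp, ndtr

from .data import TrialTable
from .mcmc import PosteriorDraws
from .models import PROB_CLAMP, CompiledModel, ModelSpec, compile_model

__all__ = [
    "ComparisonRow",
    "lppd",
    "sum_squared_errors",
    "loglik_at_posterior_means",
    "population_pse_interval",
    "posterior_overlap",
    "compare_models",
    "select_a0",
    "COMPARISON_COLUMNS",
]

COMPARISON_COLUMNS = [
    "model",
    "effects",
    "loglik",
    "lppd",
    "lppd_mc_error",
    "sse",
    "pse_ci_low",
    "pse_ci_high",
    "ci_width",
]


@dataclass(frozen=True)
class ComparisonRow:
    """One line of a comparison table (one model at one effects level)."""

    model: str
    effects: str  # "individual" | "overall"
    loglik: float
    lppd: float
    lppd_mc_error: float
    sse: float
    pse_ci_low: float
    pse_ci_high: float
    ci_width: float


def _columns_for(cm: CompiledModel, draws: PosteriorDraws) -> np.ndarray:
    """Map compiled-model parameter order onto draw columns."""
    try:
        return np.asarray([draws._index[nm] for nm in cm.names], dtype=np.intp)
    except KeyError as e:
        raise KeyError(f"draws are missing parameter {e.args[0]!r} required by the model") from None


def _cell_logpmf_matrix(cm: CompiledModel, vmat: np.ndarray) -> np.ndarray:
    """Binomial log-pmf for every (draw, cell) pair; vmat is (S, n_params)."""
    a = vmat[:, cm.cell_i1]
    b = vmat[:, cm.cell_i2]
    x = cm.cell_x
    eta = b * (x - a) if cm.is_pse else a + b * x
    p = np.clip(ndtr(eta), PROB_CLAMP, 1.0 - PROB_CLAMP)
    y, n = cm.cell_y, cm.cell_n
    return cm.cell_lgamma + y * np.log(p) + (n - y) * np.log1p(-p)


def lppd(
    draws: PosteriorDraws, spec: ModelSpec, data: TrialTable
) -> tuple[float, float]:
    """Log pointwise predictive density and its Monte Carlo error.

    For each observation cell ``i``, ``log p(y_i | y)`` is estimated as the
    log of the posterior-draw average of the binomial likelihood,
    ``log( S^-1 sum_s p(y_i | theta_s) )``, and the lppd is the sum over
    cells.  The Monte Carlo error is the standard deviation of the per-chain
    lppd values (a spread, not a formal standard error).  Cells whose
    averaged likelihood underflows to zero contribute ``-inf`` and trigger a
    warning.
    """
    cm = compile_model(spec, data)
    cols = _columns_for(cm, draws)
    n_chains, n_draws = draws.n_chains, draws.n_draws

    per_chain = np.empty(n_chains)
    percell_chain = np.empty((n_chains, len(cm.cell_x)))
    for c in range(n_chains):
        lp = _cell_logpmf_matrix(cm, draws.array[c][:, cols])
        percell_chain[c] = logsumexp(lp, axis=0) - np.log(n_draws)
        per_chain[c] = percell_chain[c].sum()
    # pooled over all draws: logsumexp of the per-chain pieces
    percell = logsumexp(percell_chain + np.log(n_draws), axis=0) - np.log(n_chains * n_draws)
    if np.any(np.isneginf(percell)):
        bad = int(np.sum(np.isneginf(percell)))
        warnings.warn(
            f"lppd: {bad} cell(s) have zero averaged likelihood (-inf term)",
            RuntimeWarning,
            stacklevel=2,
        )
    value = float(percell.sum())
    mc_error = float(np.std(per_chain, ddof=1)) if n_chains > 1 else 0.0
    return value, mc_error


def _point_probs(cm: CompiledModel, draws: PosteriorDraws, level: str) -> np.ndarray:
    """Fitted cell probabilities at posterior-mean parameters.

    ``individual`` evaluates each subject's own posterior-mean curve;
    ``overall`` applies the posterior-mean population curve of the cell's
    (group, condition) to every cell.
    """
    means = {nm: float(draws.pooled(nm).mean()) for nm in draws.names}
    x = cm.cell_x
    if level == "individual":
        a = np.asarray([means[cm.names[i]] for i in cm.cell_i1])
        b = np.asarray([means[cm.names[i]] for i in cm.cell_i2])
    elif level == "overall":
        pop = cm.pop_param_names()
        # cell -> population key of its subject
        subj_names = cm.subject_param_names()
        loc1_of = {idx: key for key, nm in subj_names["loc1"].items() for idx in [cm.index_of(nm)]}
        a_list, b_list = [], []
        for i in cm.cell_i1:
            subj, cond = loc1_of[int(i)]
            gk = cm.subject_group.get(subj) if cm.spec.grouping == "by_group" else None
            a_list.append(means[pop["loc1"][(gk, cond)]])
            b_list.append(means[pop["loc2"][(gk, cond)]])
        a, b = np.asarray(a_list), np.asarray(b_list)
    else:
        raise ValueError(f"unknown effects level {level!r}")
    eta = b * (x - a) if cm.is_pse else a + b * x
    return np.clip(ndtr(eta), PROB_CLAMP, 1.0 - PROB_CLAMP)


def loglik_at_posterior_means(
    draws: PosteriorDraws, spec: ModelSpec, data: TrialTable, level: str = "individual"
) -> float:
    """Total binomial log-likelihood at the posterior-mean parameters.

    The ``individual`` level uses each subject's posterior-mean curve, the
    ``overall`` level the population posterior-mean curve — the two rows the
    comparison tables report per model.
    """
    cm = compile_model(spec, data)
    _columns_for(cm, draws)  # structural check
    p = _point_probs(cm, draws, level)
    y, n = cm.cell_y, cm.cell_n
    ll = cm.cell_lgamma + y * np.log(p) + (n - y) * np.log1p(-p)
    return float(ll.sum())


def sum_squared_errors(
    draws: PosteriorDraws, spec: ModelSpec, data: TrialTable, level: str = "individual"
) -> float:
    """Sum over cells of (observed proportion - fitted probability)^2.

    Observed proportions are successes/trials per cell; fitted
    probabilities come from posterior-mean parameters at the requested
    effects level (see :func:`loglik_at_posterior_means`).
    """
    cm = compile_model(spec, data)
    _columns_for(cm, draws)
    p = _point_probs(cm, draws, level)
    obs = cm.cell_y / cm.cell_n
    return float(np.sum((obs - p) ** 2))


def population_pse_interval(
    draws: PosteriorDraws,
    spec: ModelSpec,
    data: TrialTable,
    level: float = 0.95,
    pse_param: str | None = None,
) -> tuple[float, float, float, str]:
    """Central credible interval of the population PSE.

    By default the reported parameter is the population PSE of the
    first-listed group and condition (``PSE[cond=...]`` under the
    pse--slope parameterization, the per-draw ``-a/b`` stream under
    intercept--slope); pass ``pse_param`` to summarize another one.
    Returns (low, high, width, parameter name).
    """
    cm = compile_model(spec, data)
    pop = cm.pop_param_names()
    first_key = next(iter(pop["loc1"]))
    if spec.parameterization == "pse_slope":
        name = pse_param or pop["loc1"][first_key]
        stream = draws.pooled(name)
    else:
        a_name = pse_param or pop["loc1"][first_key]
        b_name = pop["loc2"][first_key if pse_param is None else _partner_key(pop, pse_param)]
        with np.errstate(divide="ignore", invalid="ignore"):
            stream = -draws.pooled(a_name) / draws.pooled(b_name)
        name = "PSE<-" + a_name
    lo_q = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(stream, [lo_q, 100.0 - lo_q])
    return float(lo), float(hi), float(hi - lo), name


def _partner_key(pop: dict, a_name: str):
    for key, nm in pop["loc1"].items():
        if nm == a_name:
            return key
    raise KeyError(f"{a_name!r} is not a population location of this model")


def posterior_overlap(samples_a, samples_b, n_bins: int = 50) -> float:
    """Shared area of two normalized posterior histograms, in [0, 1].

    Histograms are built on the common range (overall min to overall max)
    with ``n_bins`` equal-width bins, each normalized to unit area; the
    overlap is the summed bin-wise minimum density times the bin width.
    Symmetric in its arguments; 1 for identical samples, 0 for disjoint
    supports.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    a = np.asarray(samples_a, dtype=float).ravel()
    b = np.asarray(samples_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both sample vectors must be non-empty")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if lo == hi:  # all mass at one point in both samples
        return 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    da, _ = np.histogram(a, bins=edges, density=True)
    db, _ = np.histogram(b, bins=edges, density=True)
    width = edges[1] - edges[0]
    return float(np.minimum(da, db).sum() * width)


def compare_models(
    fits: Sequence[tuple[str, PosteriorDraws, ModelSpec, TrialTable]],
    level: float = 0.95,
) -> pd.DataFrame:
    """Comparison table: an (individual, overall) row pair per fitted model.

    Mirrors the layout of the package's comparison tables: the individual
    row carries the log-likelihood at posterior-mean subject parameters,
    the lppd with its Monte Carlo error and the individual-level SSE; the
    overall row carries the population-level log-likelihood and SSE plus
    the population-PSE credible interval and width.
    """
    if len(fits) < 1:
        raise ValueError("need at least one fit to compare")
    rows = []
    for label, draws, spec, data in fits:
        val, err = lppd(draws, spec, data)
        lo, hi, width, _ = population_pse_interval(draws, spec, data, level=level)
        rows.append(
            ComparisonRow(
                model=label,
                effects="individual",
                loglik=loglik_at_posterior_means(draws, spec, data, "individual"),
                lppd=val,
                lppd_mc_error=err,
                sse=sum_squared_errors(draws, spec, data, "individual"),
                pse_ci_low=np.nan,
                pse_ci_high=np.nan,
                ci_width=np.nan,
            )
        )
        rows.append(
            ComparisonRow(
                model=label,
                effects="overall",
                loglik=loglik_at_posterior_means(draws, spec, data, "overall"),
                lppd=np.nan,
                lppd_mc_error=np.nan,
                sse=sum_squared_errors(draws, spec, data, "overall"),
                pse_ci_low=lo,
                pse_ci_high=hi,
                ci_width=width,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows], columns=COMPARISON_COLUMNS)


def select_a0(grid_fits: Mapping[float, object], criterion: str = "min_ci_width") -> float:
    """Choose the power-prior weight from a fitted grid.

    ``grid_fits`` maps each ``a0`` to either a numeric overall-PSE credible
    interval width or any object exposing ``ci_width`` (attribute or key).
    The minimum-width criterion returns the ``a0`` with the narrowest
    interval; ties break toward the larger ``a0`` (more borrowing at equal
    uncertainty).
    """
    if criterion != "min_ci_width":
        raise ValueError(f"unknown criterion {criterion!r}")
    if len(grid_fits) < 2:
        raise ValueError("need a grid of >= 2 a0 values")

    def width_of(v) -> float:
        if isinstance(v, (int, float, np.floating)):
            return float(v)
        if hasattr(v, "ci_width"):
            return float(v.ci_width)
        return float(v["ci_width"])

    best_a0, best_w = None, np.inf
    for a0 in sorted(grid_fits):
        w = width_of(grid_fits[a0])
        if w < best_w or (w == best_w):  # ties -> larger a0 (ascending scan)
            best_a0, best_w = float(a0), w
    return best_a0
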