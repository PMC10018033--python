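"""Probit psychometric function: response probabilities, PSE, JND, curves.

The psychometric function maps stimulus magnitude ``x`` to the probability of
one of the two forced-choice responses through a probit link,

    p(x) = Phi(alpha + beta * x),

with ``Phi`` the standard normal CDF.  The point of subjective equality
(PSE) is the stimulus at which p = 0.5, i.e. ``-alpha/beta``; the just
noticeable difference (JND) is inversely proportional to the slope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import ndtr, ndtri

__all__ = [
    "CurveParams",
    "probit_response_prob",
    "pse_from_params",
    "jnd_from_slope",
    "predict_curve",
]

#: z-score of the 75th percentile; JND = Z_75 / beta (half the 25%-75%
#: interquartile span of the fitted curve).
Z_75 = float(ndtri(0.75))


@dataclass(frozen=True)
class CurveParams:
    """Intercept and slope of the probit linear predictor.

    Parameters
    ----------
    alpha
        Intercept, in probit units.
    beta
        Slope, in probit units per stimulus unit.  May be any sign, but the
        PSE is undefined at ``beta == 0``.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.alpha) and np.isfinite(self.beta)):
            raise ValueError("curve parameters must be finite")


def probit_response_prob(params: CurveParams, x) -> float | np.ndarray:
    """Probability of the indexed response at stimulus value(s) ``x``.

    Equals ``Phi(alpha + beta * x)``; strictly increasing in ``x`` for
    positive slope.
    """
    x = np.asarray(x, dtype=float)
    out = ndtr(params.alpha + params.beta * x)
    return float(out) if out.ndim == 0 else out


def pse_from_params(params: CurveParams) -> float:
    """Point of subjective equality, ``-alpha / beta``.

    The stimulus value at which the response probability is exactly 0.5.

    Raises
    ------
    ValueError
        If ``beta`` is zero (the curve is flat; no stimulus yields 0.5).
    """
    if params.beta == 0.0:
        raise ValueError("degenerate slope: PSE undefined for beta = 0")
    return -params.alpha / params.beta


def jnd_from_slope(beta: float) -> float:
    """Just noticeable difference under the probit convention.

    Returns ``Phi^{-1}(0.75) / beta`` (~ ``0.67449 / beta``): half the
    stimulus span between the 25% and 75% points of the fitted curve.
    Larger slopes mean finer discrimination, hence a smaller JND.
    """
    if not beta > 0:
        raise ValueError("JND undefined for non-positive slope")
    return Z_75 / beta


def predict_curve(params: CurveParams, grid: Sequence[float]) -> np.ndarray:
    """Response probabilities evaluated elementwise on a stimulus grid."""
    grid = np.asarray(grid, dtype=float)
    if grid.size and not np.all(np.isfinite(grid)):
        raise ValueError("stimulus grid must be finite")
    return ndtr(params.alpha + params.beta * grid)
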