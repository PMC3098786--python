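"""Average-power-rate (APR) estimation and the early-stop decision.

The achieved APR (detected fraction of truly non-null genes) is estimated by
a plug-in chain: pi0 from the upper tail of the p-value distribution, the
expected false-positive count as pi0 * d * alpha', and d1 as d * (1 - pi0),
giving apr_hat = (R - fp_hat) / d1_hat, clipped to [0, 1].  alpha' is the
BH-equivalent raw-p threshold, so a look with zero rejections always
estimates zero power.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import UnivariateSpline

from .error_control import bh_alpha, reject_bh

logger = logging.getLogger(__name__)

VARIANT_FIXED = "fixed-theta"
VARIANT_SMOOTHER = "smoother"

_SMOOTHER_GRID = np.round(np.arange(0.0, 0.95, 0.05), 2)  # 0.00 .. 0.90


@dataclass(frozen=True)
class AprEstimate:
    pi0_hat: float
    fp_hat: float
    d1_hat: float
    apr_hat: float
    variant: str
    alpha_prime: float
    r: int


def estimate_pi0(p: np.ndarray, theta: float = 0.5) -> float:
    """Tail estimator of the true-null fraction: |{p > theta}| / ((1-theta) d).

    theta trades bias (small theta contaminates the tail with non-null
    p-values) against variance; the result is clipped to (1/d, 1].
    """
    if not 0.0 < theta < 1.0:
        raise ValueError("theta must be in (0, 1)")
    p = np.asarray(p, dtype=float)
    d = len(p)
    if d == 0:
        raise ValueError("p must be nonempty")
    pi0 = np.sum(p > theta) / ((1.0 - theta) * d)
    return float(np.clip(pi0, 1.0 / d, 1.0))


def estimate_pi0_smoother(p: np.ndarray) -> float:
    """Smoother variant: extrapolate pi0_hat(theta) to theta = 0.9 by spline.

    Evaluates the tail estimator on the grid 0.00, 0.05, ..., 0.90, fits a
    cubic smoothing spline and takes its value at the right end, where the
    bias of the tail estimator vanishes.  The result is clipped to the grid
    range and then to (1/d, 1].
    """
    p = np.asarray(p, dtype=float)
    d = len(p)
    if d == 0:
        raise ValueError("p must be nonempty")
    grid = np.array(
        [np.sum(p > t) / ((1.0 - t) * d) for t in _SMOOTHER_GRID]
    )
    try:
        spline = UnivariateSpline(_SMOOTHER_GRID, grid, k=3)
        pi0 = float(spline(_SMOOTHER_GRID[-1]))
    except Exception:  # pragma: no cover - scipy fit failure is exotic
        pi0 = np.nan
    if not np.isfinite(pi0):
        logger.warning("degenerate pi0 smoother fit; falling back to theta = 0.5")
        return estimate_pi0(p, 0.5)
    pi0 = float(np.clip(pi0, grid.min(), grid.max()))
    return float(np.clip(pi0, 1.0 / d, 1.0))


def estimate_apr(
    p: np.ndarray,
    alpha: float,
    pi0_method: str = VARIANT_FIXED,
    theta: float = 0.5,
) -> AprEstimate:
    """Plug-in APR estimate from one look's raw p-values at FDR level alpha."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    p = np.asarray(p, dtype=float)
    d = len(p)
    r = len(reject_bh(p, alpha))
    alpha_prime = bh_alpha(p, alpha)
    if pi0_method == VARIANT_FIXED:
        pi0 = estimate_pi0(p, theta)
    elif pi0_method == VARIANT_SMOOTHER:
        pi0 = estimate_pi0_smoother(p)
    else:
        raise ValueError(f"unknown pi0 method: {pi0_method!r}")
    fp_hat = pi0 * d * alpha_prime
    d1_hat = d * (1.0 - pi0)
    if r == 0 or d1_hat <= 0.0:
        apr = 0.0
    else:
        apr = float(np.clip((r - fp_hat) / d1_hat, 0.0, 1.0))
    return AprEstimate(
        pi0_hat=pi0,
        fp_hat=fp_hat,
        d1_hat=d1_hat,
        apr_hat=apr,
        variant=pi0_method,
        alpha_prime=alpha_prime,
        r=r,
    )


def check_stop(
    estimate: AprEstimate, threshold: float, inclusive: bool = True
) -> bool:
    """Stop decision: estimated APR reaches the pre-specified level.

    Inclusive comparison by default so a threshold of 1.0 is attainable.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    if inclusive:
        return estimate.apr_hat >= threshold
    return estimate.apr_hat > threshold
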