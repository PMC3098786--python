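"""Benjamini-Hochberg adjustment and truth-aware error/power metrics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic_cohort import EffectVector


@dataclass(frozen=True)
class TestDecisionSummary:
    """Confusion counts of one analysis against the known effect vector.

    FDP is FP/R with the convention FDP = 0 when R = 0; the true average
    power rate is TP/d1, defined as 0 when d1 = 0.
    """

    r: int
    fp: int
    tp: int
    fn: int
    tn: int
    fdp: float
    apr_true: float


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Step-up BH adjusted p-values; rejection at level a iff adjusted <= a."""
    p = np.asarray(p, dtype=float)
    d = len(p)
    order = np.argsort(p, kind="stable")
    scaled = p[order] * d / np.arange(1, d + 1)
    adjusted_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    adjusted = np.empty(d)
    adjusted[order] = adjusted_sorted
    return adjusted


def by_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Yekutieli variant: BH with the harmonic-sum penalty."""
    p = np.asarray(p, dtype=float)
    c = np.sum(1.0 / np.arange(1, len(p) + 1))
    return np.minimum(1.0, bh_adjust(p) * c)


def bh_alpha(p: np.ndarray, alpha: float) -> float:
    """The data-dependent raw-p threshold equivalent to BH at level alpha.

    Returns (k*/d)*alpha for the largest k* with p_(k*) <= (k*/d)*alpha, or
    0.0 when no k qualifies; {p <= bh_alpha} is exactly the BH rejection set.
    """
    p_sorted = np.sort(np.asarray(p, dtype=float))
    d = len(p_sorted)
    thresholds = np.arange(1, d + 1) / d * alpha
    qualifying = np.nonzero(p_sorted <= thresholds)[0]
    if qualifying.size == 0:
        return 0.0
    return float(thresholds[qualifying[-1]])


def reject_bh(p: np.ndarray, alpha: float, conservative: bool = False) -> np.ndarray:
    """Indices of BH (or BY, if ``conservative``) rejections at level alpha.

    Uses the raw-p step-up rule p_(k) <= (k/d) alpha directly, which agrees
    with thresholding at ``bh_alpha`` exactly (including at floating-point
    boundaries, where comparing adjusted p-values can flip).
    """
    p = np.asarray(p, dtype=float)
    d = len(p)
    factor = np.sum(1.0 / np.arange(1, d + 1)) if conservative else 1.0
    order = np.argsort(p, kind="stable")
    thresholds = np.arange(1, d + 1) / (d * factor) * alpha
    qualifying = np.nonzero(p[order] <= thresholds)[0]
    if qualifying.size == 0:
        return np.array([], dtype=int)
    k = qualifying[-1] + 1
    return np.sort(order[:k])


def confusion_metrics(reject: np.ndarray, truth: EffectVector) -> TestDecisionSummary:
    """Count TP/FP/FN/TN of a rejection set against the effect vector."""
    reject = np.asarray(reject, dtype=int)
    if reject.size and (reject.min() < 0 or reject.max() >= truth.d):
        raise ValueError("rejection indices out of range")
    is_alt = np.zeros(truth.d, dtype=bool)
    is_alt[truth.alt_set] = True
    r = int(reject.size)
    tp = int(np.sum(is_alt[reject]))
    fp = r - tp
    d1 = truth.d1
    fn = d1 - tp
    tn = truth.d0 - fp
    fdp = fp / r if r > 0 else 0.0
    apr_true = tp / d1 if d1 > 0 else 0.0
    return TestDecisionSummary(r=r, fp=fp, tp=tp, fn=fn, tn=tn,
                               fdp=fdp, apr_true=apr_true)
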