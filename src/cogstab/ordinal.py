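"""Normal-ogive graded response model primitives.

An ordinal indicator with categories ``0..K-1`` is generated by cutting a
continuous latent response ``Y* = eta + epsilon`` (``epsilon ~ N(0, 1)``) at
``K - 1`` strictly increasing thresholds ``kappa_1 < ... < kappa_{K-1}``:

    P(Y = k | eta) = Phi(kappa_{k+1} - eta) - Phi(kappa_k - eta)

with ``kappa_0 = -inf`` and ``kappa_K = +inf``.  These probabilities are the
measurement kernel shared by the latent state and latent state-trait models.
"""

from __future__ import annotations

import numpy as np
from scipy.special import log_ndtr, ndtr

__all__ = [
    "validate_thresholds",
    "grm_probs",
    "grm_logpmf",
]


def validate_thresholds(thresholds: np.ndarray) -> np.ndarray:
    """Return thresholds as a 1-D float array, raising if not strictly increasing."""
    kappa = np.asarray(thresholds, dtype=float).ravel()
    if kappa.size == 0:
        raise ValueError("at least one threshold is required (>= 2 categories)")
    if not np.all(np.isfinite(kappa)):
        raise ValueError("thresholds must be finite")
    if np.any(np.diff(kappa) <= 0):
        raise ValueError(f"thresholds must be strictly increasing, got {kappa}")
    return kappa


def grm_probs(eta, thresholds) -> np.ndarray:
    """Category probabilities of the graded response model.

    Parameters
    ----------
    eta : array_like
        Latent ability values, any shape ``S``.
    thresholds : array_like
        ``K - 1`` strictly increasing cut points.

    Returns
    -------
    ndarray with shape ``S + (K,)``; rows sum to 1.
    """
    kappa = validate_thresholds(thresholds)
    eta = np.asarray(eta, dtype=float)
    # CDF at interior cut points, padded with 0 and 1 for the outer bounds.
    cdf = ndtr(kappa - eta[..., None])
    lower = np.concatenate([np.zeros(eta.shape + (1,)), cdf], axis=-1)
    upper = np.concatenate([cdf, np.ones(eta.shape + (1,))], axis=-1)
    return np.clip(upper - lower, 0.0, 1.0)


def _log_phi_diff(a, b):
    """log(Phi(b) - Phi(a)) for b > a, stable in both tails."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    # Work on the side where the CDF values are small: Phi(b)-Phi(a) =
    # Phi(-a)-Phi(-b).  Reflect whenever the interval sits in the upper tail.
    flip = (a + b) > 0
    lo = np.where(flip, -b, a)
    hi = np.where(flip, -a, b)
    log_hi = log_ndtr(hi)
    log_lo = log_ndtr(lo)
    with np.errstate(invalid="ignore"):
        out = log_hi + np.log1p(-np.exp(np.minimum(log_lo - log_hi, -1e-300)))
    # a == -inf (bottom category): plain log CDF
    out = np.where(np.isneginf(lo), log_hi, out)
    return out


def grm_logpmf(category, eta, thresholds) -> np.ndarray:
    """Log probability ``log P(Y = category | eta)``; numerically stable in the tails.

    ``category`` and ``eta`` broadcast against each other.
    """
    kappa = validate_thresholds(thresholds)
    k = np.asarray(category)
    if np.any((k < 0) | (k > kappa.size)):
        raise ValueError(f"categories must lie in 0..{kappa.size}")
    padded = np.concatenate([[-np.inf], kappa, [np.inf]])
    eta = np.asarray(eta, dtype=float)
    lower = padded[k] - eta
    upper = padded[k + 1] - eta
    return _log_phi_diff(lower, upper)
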