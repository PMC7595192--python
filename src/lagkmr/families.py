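"""Closed-form moments, entropies and samplers for the variational families."""

from __future__ import annotations

import numpy as np
from scipy.special import digamma, gammaln


def invgauss_e_x(mu: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """E[X] for X ~ InverseGaussian(mean mu, shape lam)."""
    return np.asarray(mu, dtype=float)


def invgauss_e_inv(mu: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """E[1/X] for X ~ InverseGaussian(mean mu, shape lam)."""
    return 1.0 / np.asarray(mu, dtype=float) + 1.0 / np.asarray(lam, dtype=float)


def gamma_entropy(shape: float, rate: float) -> float:
    """Differential entropy of Gamma(shape, rate)."""
    return shape - np.log(rate) + gammaln(shape) + (1.0 - shape) * digamma(shape)


def invgamma_entropy(shape: float, rate: float) -> float:
    """Differential entropy of InverseGamma(shape, rate)."""
    return shape + np.log(rate) + gammaln(shape) - (1.0 + shape) * digamma(shape)


def sample_invgauss(rng: np.random.Generator, mu, lam):
    """Inverse-Gaussian draws with guards at extreme mean/shape ratios.

    Uses the Michael-Schucany-Haas transformation (numpy's ``wald``); the
    mean is floored and capped so near-degenerate conditionals (quadratic
    forms underflowing to ~0) cannot produce non-finite draws.
    """
    mu = np.clip(np.asarray(mu, dtype=float), 1e-10, 1e10)
    lam = float(lam)
    if not np.isfinite(lam) or lam <= 0:
        raise ValueError(f"inverse-Gaussian shape must be positive, got {lam}")
    return rng.wald(mu, lam)
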