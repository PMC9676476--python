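"""Expected-improvement acquisition and next-candidate selection.

EI(x) = E[max(f(x) - f*, 0)] under the GP posterior, with the closed
form Delta * Phi(Delta/sigma) + sigma * phi(Delta/sigma), where
Delta = mu(x) - f* and f* is the incumbent (best observed value). The
first term rewards high expected quality, the second high uncertainty.
At sigma = 0 the limit max(Delta, 0) is returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .gp import GPSurrogate

__all__ = ["expected_improvement", "select_next", "AcquisitionResult",
           "EmptyPoolError"]


class EmptyPoolError(RuntimeError):
    """No unevaluated candidates remain; the quit logic should fire."""


@dataclass(frozen=True)
class AcquisitionResult:
    """Outcome of one acquisition step over a candidate pool."""

    index: int                 # position in the candidate pool
    chosen: np.ndarray         # encoded vector
    ei_value: float            # max EI over the pool
    mean: float                # posterior mean at the choice
    sd: float                  # posterior sd at the choice
    pool_size: int


def expected_improvement(mean, sd, f_best: float):
    """Closed-form EI; vectorized over `mean` and `sd`.

    Parameters
    ----------
    mean, sd : float or ndarray
        Posterior mean and standard deviation (sd >= 0).
    f_best : float
        Incumbent value.
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if np.any(sd < 0):
        raise ValueError("standard deviation must be nonnegative")
    delta = mean - f_best
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, delta / np.where(sd > 0, sd, 1.0), 0.0)
        ei = np.where(sd > 0,
                      delta * norm.cdf(z) + sd * norm.pdf(z),
                      np.maximum(delta, 0.0))
    ei = np.maximum(ei, 0.0)
    return float(ei) if ei.ndim == 0 else ei


def select_next(state: GPSurrogate, candidates: np.ndarray,
                f_best: float) -> AcquisitionResult:
    """Pick the candidate maximizing EI; ties go to the smallest index.

    `candidates` must already exclude evaluated points; an empty pool
    raises :class:`EmptyPoolError` for the caller's quit logic.
    """
    candidates = np.atleast_2d(np.asarray(candidates, dtype=float))
    if candidates.shape[0] == 0:
        raise EmptyPoolError("candidate pool is empty")
    mu, var = state.posterior(candidates)
    sd = np.sqrt(var)
    ei = expected_improvement(mu, sd, f_best)
    i = int(np.argmax(ei))  # argmax returns the first maximum: deterministic
    return AcquisitionResult(index=i, chosen=candidates[i],
                             ei_value=float(ei[i]), mean=float(mu[i]),
                             sd=float(sd[i]), pool_size=candidates.shape[0])
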