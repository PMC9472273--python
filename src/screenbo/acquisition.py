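"""Acquisition metrics: score and rank untested candidates.

Five metrics over the surrogate prediction (mu, sigma):

- greedy: mu — purely exploitative.
- ucb:    mu + beta * sigma (upper confidence bound, beta defaults to 2).
- ei:     expected improvement over the incumbent f* with margin epsilon.
- pi:     probability of improvement over f* + epsilon.
- random: i.i.d. uniform scores (the paired baseline arm).

Batch selection is deliberately naive top-k: candidates are scored
independently of each other, with ties broken by ascending molecule id so
rankings are deterministic and identical across acquisition arms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .surrogate import SurrogatePrediction

__all__ = [
    "METRICS",
    "AcquisitionConfig",
    "score_greedy",
    "score_ucb",
    "score_ei",
    "score_pi",
    "score_random",
    "score_candidates",
    "rank_candidates",
]

METRICS = ("greedy", "ucb", "ei", "pi", "random")

DEFAULT_BETA = 2.0
DEFAULT_EPSILON = 0.01


@dataclass(frozen=True)
class AcquisitionConfig:
    """Metric name plus its tunables (beta for UCB; epsilon and f* for EI/PI)."""

    metric: str = "greedy"
    beta: float = DEFAULT_BETA
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self):
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}; expected one of {METRICS}")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")


def score_greedy(pred: SurrogatePrediction) -> np.ndarray:
    return np.array(pred.mu, dtype=float, copy=True)


def score_ucb(pred: SurrogatePrediction, beta: float = DEFAULT_BETA) -> np.ndarray:
    if beta < 0:
        raise ValueError("beta must be >= 0")
    return pred.mu + beta * pred.sigma


def score_ei(pred: SurrogatePrediction, f_star: float, epsilon: float = DEFAULT_EPSILON) -> np.ndarray:
    """Expected improvement E[max(Y - f* - eps, 0)] for Y ~ N(mu, sigma^2).

    With z = (mu - f* - eps) / sigma the closed form is
    (mu - f* - eps) * Phi(z) + sigma * phi(z); at sigma = 0 it degenerates to
    the deterministic improvement max(mu - f* - eps, 0).
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    improvement = pred.mu - f_star - epsilon
    scores = np.maximum(improvement, 0.0)
    positive = pred.sigma > 0
    if np.any(positive):
        imp = improvement[positive]
        sig = pred.sigma[positive]
        z = imp / sig
        scores[positive] = imp * norm.cdf(z) + sig * norm.pdf(z)
    return scores


def score_pi(pred: SurrogatePrediction, f_star: float, epsilon: float = DEFAULT_EPSILON) -> np.ndarray:
    """Probability of improvement P(Y > f* + eps) for Y ~ N(mu, sigma^2).

    At sigma = 0 the probability degenerates to the step 1{mu > f* + eps}.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    improvement = pred.mu - f_star - epsilon
    scores = (improvement > 0).astype(float)
    positive = pred.sigma > 0
    if np.any(positive):
        scores[positive] = norm.cdf(improvement[positive] / pred.sigma[positive])
    return scores


def score_random(pool_size: int, seed) -> np.ndarray:
    """I.i.d. uniform scores; `seed` may be an int or an entropy sequence."""
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.uniform(size=pool_size)


def score_candidates(
    pred: SurrogatePrediction | None,
    config: AcquisitionConfig,
    f_star: float | None = None,
    pool_size: int | None = None,
    random_seed=None,
) -> np.ndarray:
    """Dispatch to the configured metric."""
    if config.metric == "random":
        if pool_size is None:
            raise ValueError("random metric needs pool_size")
        return score_random(pool_size, random_seed)
    if pred is None:
        raise ValueError(f"metric {config.metric!r} needs a surrogate prediction")
    if config.metric == "greedy":
        return score_greedy(pred)
    if config.metric == "ucb":
        return score_ucb(pred, config.beta)
    if f_star is None:
        raise ValueError(f"metric {config.metric!r} needs the incumbent f*")
    if config.metric == "ei":
        return score_ei(pred, f_star, config.epsilon)
    return score_pi(pred, f_star, config.epsilon)


def rank_candidates(scores, exclude, k: int) -> np.ndarray:
    """Top-k candidate ids by descending score, skipping already-measured ids.

    `exclude` is a boolean mask over the pool or an iterable of molecule ids.
    Ties are broken by ascending molecule id.  Returns min(k, remaining) ids.
    """
    scores = np.asarray(scores, dtype=float)
    if k < 0:
        raise ValueError("k must be >= 0")
    if isinstance(exclude, np.ndarray) and exclude.dtype == bool:
        mask = exclude
        if mask.shape != scores.shape:
            raise ValueError("exclude mask must align with scores")
    else:
        mask = np.zeros(scores.shape, dtype=bool)
        excl = np.asarray(list(exclude), dtype=int)
        if excl.size:
            mask[excl] = True
    candidates = np.flatnonzero(~mask)
    if candidates.size == 0 or k == 0:
        return np.empty(0, dtype=int)
    # lexsort: primary key last — descending score, then ascending id
    order = np.lexsort((candidates, -scores[candidates]))
    return candidates[order[:k]]
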