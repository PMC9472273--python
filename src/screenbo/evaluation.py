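"""Summaries over campaign traces: hit curves, enrichment, retest analysis.

Enrichment is always computed against the *paired* random arm — the random
campaign run under the same seed, hence the same initial batch and the same
noise realisation — so the ratio isolates the effect of the acquisition
metric.  The retest ceiling gives the analytic upper bound on the fraction of
hits that can ever be recognised as active when each test independently
identifies a hit with probability ``a`` and at most ``n`` retests are
allowed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .campaign import CampaignTrace

__all__ = [
    "EnrichmentResult",
    "RetestComparison",
    "hit_curves",
    "checkpoint_index",
    "enrichment_factor",
    "mean_enrichment",
    "misidentified_hit_fraction",
    "retest_ceiling",
    "retest_win_rate",
    "summarize_arm",
]


def hit_curves(trace: CampaignTrace, library=None) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative (hits, true_hits) per batch, unique molecules.

    With ``library`` given the curves are recounted from scratch by replaying
    the trace's measurement log against the library's true activities and the
    recorded hit threshold; otherwise the recorded per-batch counters are
    returned.  A hit is an acquired molecule whose *true* activity reaches
    the threshold; a true hit additionally has at least one *measured* value
    at or above it.
    """
    if library is None:
        return trace.hits(), trace.true_hits()
    threshold = trace.config["hit_threshold"]
    active = library.true_activities >= threshold
    tested = np.zeros(len(library), dtype=bool)
    best = np.full(len(library), -np.inf)
    hits, true_hits = [], []
    for batch in trace.batches:
        for mid, value, _rep in batch.measurements:
            tested[mid] = True
            best[mid] = max(best[mid], value)
        hits.append(int(np.sum(tested & active)))
        true_hits.append(int(np.sum(active & (best >= threshold))))
    return np.array(hits, dtype=int), np.array(true_hits, dtype=int)


def checkpoint_index(trace: CampaignTrace, checkpoint) -> int:
    """Resolve a checkpoint to a batch index.

    An integer is a batch index directly (0 = the initial random batch).  A
    float in (0, 1) is a fraction of the pool: the first batch at which the
    cumulative number of measurements reaches that fraction.
    """
    n_batches = len(trace.batches)
    if isinstance(checkpoint, float) and 0 < checkpoint < 1:
        target = checkpoint * trace.config["pool_size"]
        total = 0
        for i, batch in enumerate(trace.batches):
            total += len(batch.measurements)
            if total >= target:
                return i
        raise ValueError(f"trace never reaches pool fraction {checkpoint}")
    idx = int(checkpoint)
    if not 0 <= idx < n_batches:
        raise ValueError(f"checkpoint {checkpoint} outside the trace's {n_batches} batches")
    return idx


def enrichment_factor(
    arm_trace: CampaignTrace,
    random_trace: CampaignTrace,
    checkpoint,
    use_true_hits: bool = False,
) -> float:
    """Hits (or true hits) of an arm divided by the paired random arm's.

    NaN when the random arm found nothing at the checkpoint (undefined
    ratio); aggregators skip such runs.
    """
    curve = lambda t: hit_curves(t)[1 if use_true_hits else 0]
    i = checkpoint_index(arm_trace, checkpoint)
    j = checkpoint_index(random_trace, checkpoint)
    denom = curve(random_trace)[j]
    if denom == 0:
        return math.nan
    return float(curve(arm_trace)[i]) / float(denom)


def mean_enrichment(arm_traces, random_traces, checkpoint, use_true_hits: bool = False) -> float:
    """Mean over paired runs of the per-run enrichment ratio (NaN runs dropped)."""
    ratios = [
        enrichment_factor(a, r, checkpoint, use_true_hits)
        for a, r in zip(arm_traces, random_traces, strict=True)
    ]
    ratios = [r for r in ratios if not math.isnan(r)]
    if not ratios:
        return math.nan
    return float(np.mean(ratios))


@dataclass(frozen=True)
class EnrichmentResult:
    """Across-run summary of one arm at one checkpoint."""

    checkpoint: object
    metric: str
    hits_mean: float
    hits_std: float
    true_hits_mean: float
    true_hits_std: float
    enrichment_factor: float
    enrichment_factor_true_hits: float


def summarize_arm(metric: str, arm_traces, random_traces, checkpoint) -> EnrichmentResult:
    hits = np.array([hit_curves(t)[0][checkpoint_index(t, checkpoint)] for t in arm_traces], dtype=float)
    true = np.array([hit_curves(t)[1][checkpoint_index(t, checkpoint)] for t in arm_traces], dtype=float)
    return EnrichmentResult(
        checkpoint=checkpoint,
        metric=metric,
        hits_mean=float(hits.mean()),
        hits_std=float(hits.std()),
        true_hits_mean=float(true.mean()),
        true_hits_std=float(true.std()),
        enrichment_factor=mean_enrichment(arm_traces, random_traces, checkpoint, use_true_hits=False),
        enrichment_factor_true_hits=mean_enrichment(arm_traces, random_traces, checkpoint, use_true_hits=True),
    )


def misidentified_hit_fraction(trace: CampaignTrace, checkpoint=None) -> float:
    """Fraction of acquired hits never measured at or above the threshold.

    ``1 - true_hits / hits`` at the checkpoint (default: the final recorded
    batch); NaN when no hit was acquired.
    """
    hits, true_hits = hit_curves(trace)
    i = len(trace.batches) - 1 if checkpoint is None else checkpoint_index(trace, checkpoint)
    if hits[i] == 0:
        return math.nan
    return 1.0 - float(true_hits[i]) / float(hits[i])


def retest_ceiling(a: float, n: int) -> float:
    """Maximum identifiable fraction of hits: ``1 - (1 - a)^(n + 1)``.

    ``a`` is the probability a hit is correctly identified by a single test
    and ``n`` the maximum number of retests allowed; with ``a = 0.6`` one
    retest lifts the ceiling from 60% to 84%.
    """
    if not 0.0 <= a <= 1.0:
        raise ValueError("a must be in [0, 1]")
    if n < 0:
        raise ValueError("n must be >= 0")
    return 1.0 - (1.0 - a) ** (n + 1)


@dataclass(frozen=True)
class RetestComparison:
    """Win/draw/loss tally of retests-vs-no-retests across datasets.

    Percentages are shares of *all* datasets; draws are excluded from the
    displayed shares, so win and loss percentages need not sum to 100.
    """

    wins: int
    draws: int
    losses: int

    @property
    def n_datasets(self) -> int:
        return self.wins + self.draws + self.losses

    @property
    def win_percentage(self) -> float:
        return 100.0 * self.wins / self.n_datasets

    @property
    def loss_percentage(self) -> float:
        return 100.0 * self.losses / self.n_datasets


def retest_win_rate(paired_true_hits) -> RetestComparison:
    """Classify each dataset by mean true hits with vs without retests.

    ``paired_true_hits`` is a sequence of ``(with_retests, without_retests)``
    mean true-hit counts, one pair per dataset, already evaluated at the
    checkpoint of interest.
    """
    wins = draws = losses = 0
    for with_r, without_r in paired_true_hits:
        if with_r > without_r:
            wins += 1
        elif with_r < without_r:
            losses += 1
        else:
            draws += 1
    return RetestComparison(wins=wins, draws=draws, losses=losses)
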