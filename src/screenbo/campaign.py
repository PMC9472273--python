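"""Batched active-learning campaigns, with and without retests.

A campaign starts from a uniformly random initial batch, then alternates
surrogate refits with top-k acquisition until the number of measurements
exceeds half the pool (the stopping rule).  With retests enabled, molecules
that were predicted active but measured inactive are queued and re-measured
in the next batch, displacing new selections one-for-one so every batch costs
exactly `batch_size` measurements.  Both the original and the retest value
enter the training set — neither measurement is more trustworthy than the
other, as both are draws from the same noise distribution.

Pairing design: the initial random batch and the noise stream depend only on
the run seed, never on the acquisition metric, so arms run under the same
seed are directly comparable (paired) and any (molecule, replicate) both arms
happen to measure receives the identical value.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .acquisition import (
    DEFAULT_BETA,
    DEFAULT_EPSILON,
    METRICS,
    AcquisitionConfig,
    rank_candidates,
    score_candidates,
)
from .library import (
    DEFAULT_NOISE_FORM,
    MeasurementOracle,
    NoiseModel,
    ScreeningLibrary,
    compute_hit_threshold,
)
from .surrogate import DEFAULT_UNCERTAINTY, RandomForestSurrogate, TrainingSet, fit_surrogate

__all__ = [
    "RetestPolicy",
    "CampaignConfig",
    "BatchOutcome",
    "CampaignTrace",
    "n_active_learning_batches",
    "flag_retests",
    "run_campaign",
    "run_campaign_without_retests",
    "run_campaign_with_retests",
]

# Stream tags keeping the run's independent randomness sources (initial batch,
# random-metric scores, forest seeds) from colliding in seed space.
_INIT_TAG = 11
_RANDOM_METRIC_TAG = 13
_FOREST_TAG = 17

RETEST_KINDS = ("none", "basic", "uncertainty_augmented")


@dataclass(frozen=True)
class RetestPolicy:
    """Rule deciding which just-measured molecules are queued for re-measurement.

    kind
        ``"none"``: never retest.  ``"basic"``: retest a molecule whose
        predicted activity was at or above the hit threshold but whose
        measured value fell below it.  ``"uncertainty_augmented"``: as basic,
        but the eligibility test is ``value + uncertainty_weight * sigma >=
        threshold`` — designed for rare-hit settings where few predictions
        clear the threshold on their own.
    max_retests_per_molecule
        Cap on re-measurements of one molecule (default 1).
    uncertainty_weight
        Weight on sigma in the augmented rule (default 0.1).
    basis
        Which activity value the augmented rule inflates: the model's
        ``"predicted"`` mean (default; generalises the basic rule) or the
        just-``"measured"`` value.
    """

    kind: str = "none"
    max_retests_per_molecule: int = 1
    uncertainty_weight: float = 0.1
    basis: str = "predicted"

    def __post_init__(self):
        if self.kind not in RETEST_KINDS:
            raise ValueError(f"unknown retest kind {self.kind!r}; expected one of {RETEST_KINDS}")
        if self.max_retests_per_molecule < 0:
            raise ValueError("max_retests_per_molecule must be >= 0")
        if self.uncertainty_weight < 0:
            raise ValueError("uncertainty_weight must be >= 0")
        if self.basis not in ("predicted", "measured"):
            raise ValueError("basis must be 'predicted' or 'measured'")


@dataclass(frozen=True)
class CampaignConfig:
    """All knobs of one campaign arm.

    Defaults are the canonical study conditions: batches of 100, top-10%
    hits, a 100-tree forest, beta=2 and epsilon=0.01, stop once measurements
    exceed half the pool.  ``max_batches`` optionally truncates the loop
    (e.g. to inspect the state after 8 active-learning batches).
    """

    batch_size: int = 100
    hit_quantile: float = 0.10
    alpha: float = 0.0
    metric: str = "greedy"
    retest_policy: RetestPolicy = field(default_factory=RetestPolicy)
    n_runs: int = 10
    stop_fraction: float = 0.5
    n_trees: int = 100
    beta: float = DEFAULT_BETA
    epsilon: float = DEFAULT_EPSILON
    max_batches: int | None = None
    noise_form: str = DEFAULT_NOISE_FORM
    uncertainty: str = DEFAULT_UNCERTAINTY

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0 < self.stop_fraction <= 1:
            raise ValueError("stop_fraction must be in (0, 1]")
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")

    def acquisition(self) -> AcquisitionConfig:
        return AcquisitionConfig(metric=self.metric, beta=self.beta, epsilon=self.epsilon)


@dataclass
class BatchOutcome:
    """Per-batch record: what was selected, measured, retested, and found."""

    batch_index: int
    new_ids: list[int]
    retest_ids: list[int]
    measurements: list[tuple[int, float, int]]  # (molecule_id, value, replicate)
    cumulative_hits: int
    cumulative_true_hits: int
    n_retests_queued: int


@dataclass
class CampaignTrace:
    """Full record of one campaign run; reconstructs the hit curves exactly."""

    config: dict
    run_seed: int
    batches: list[BatchOutcome]

    @property
    def total_measurements(self) -> int:
        return sum(len(b.measurements) for b in self.batches)

    def hits(self) -> np.ndarray:
        return np.array([b.cumulative_hits for b in self.batches], dtype=int)

    def true_hits(self) -> np.ndarray:
        return np.array([b.cumulative_true_hits for b in self.batches], dtype=int)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "batch_index": [b.batch_index for b in self.batches],
                "hits": self.hits(),
                "true_hits": self.true_hits(),
                "n_retests": [len(b.retest_ids) for b in self.batches],
            }
        )

    # -- serialization: one header line, then one JSON object per batch -----
    def to_jsonl(self, path) -> Path:
        path = Path(path)
        with path.open("w") as fh:
            header = {"config": self.config, "run_seed": self.run_seed}
            fh.write(json.dumps(header, sort_keys=True) + "\n")
            for b in self.batches:
                fh.write(json.dumps(asdict(b), sort_keys=True) + "\n")
        return path

    @classmethod
    def from_jsonl(cls, path) -> "CampaignTrace":
        lines = Path(path).read_text().splitlines()
        header = json.loads(lines[0])
        batches = []
        for line in lines[1:]:
            raw = json.loads(line)
            raw["measurements"] = [tuple(m) for m in raw["measurements"]]
            batches.append(BatchOutcome(**raw))
        return cls(config=header["config"], run_seed=header["run_seed"], batches=batches)


def n_active_learning_batches(pool_size: int, batch_size: int, stop_fraction: float = 0.5) -> int:
    """Number of acquisition batches after the initial random batch.

    Batches repeat until the total number of measurements exceeds
    ``stop_fraction * pool_size``: the result is the smallest k with
    ``(k + 1) * batch_size > stop_fraction * pool_size`` (the ``+1`` counts
    the initial random batch).  E.g. a 5100-entry pool with batches of 100
    yields 25 active-learning batches after the initial one.
    """
    if not 0 < stop_fraction <= 1:
        raise ValueError("stop_fraction must be in (0, 1]")
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    if pool_size <= batch_size:
        raise ValueError("pool must be larger than one batch")
    bound = stop_fraction * pool_size
    k = 0
    while (k + 1) * batch_size <= bound:
        k += 1
    return k


def flag_retests(
    molecule_ids,
    mu,
    sigma,
    measured,
    hit_threshold: float,
    policy: RetestPolicy,
    retest_counts,
) -> list[int]:
    """Which just-measured molecules should be queued for re-measurement.

    Arrays are aligned over the just-measured batch; ``retest_counts[i]`` is
    how many times molecule ``i`` has already been retested.  A molecule is
    never retested once any measurement reached the threshold (it is already
    recorded active), nor beyond the per-molecule cap.  Ids return in batch
    order.
    """
    if policy.kind == "none":
        return []
    out: list[int] = []
    for i, mid in enumerate(molecule_ids):
        if measured[i] >= hit_threshold:
            continue
        if retest_counts[i] >= policy.max_retests_per_molecule:
            continue
        if policy.kind == "basic":
            eligible = mu[i] >= hit_threshold
        else:  # uncertainty_augmented
            base = mu[i] if policy.basis == "predicted" else measured[i]
            eligible = base + policy.uncertainty_weight * sigma[i] >= hit_threshold
        if eligible:
            out.append(int(mid))
    return out


def _forest_seed(run_seed: int, batch_index: int) -> int:
    return int(np.random.default_rng([run_seed, _FOREST_TAG, batch_index]).integers(2**31))


def _run_engine(library: ScreeningLibrary, config: CampaignConfig, run_seed: int, with_retests: bool) -> CampaignTrace:
    n = len(library)
    batch_size = config.batch_size
    if library.label_based_hits:
        threshold = library.hit_threshold
    else:
        threshold = compute_hit_threshold(library, config.hit_quantile)
    active = library.true_activities >= threshold

    noise = NoiseModel.for_library(library, config.alpha, base_seed=run_seed, form=config.noise_form)
    oracle = MeasurementOracle(library, noise)
    acq = config.acquisition()

    measured_count = np.zeros(n, dtype=int)  # measurements per molecule so far
    best_measured = np.full(n, -np.inf)
    training = TrainingSet()
    retest_queue: list[int] = []
    batches: list[BatchOutcome] = []

    def record(batch_index, new_ids, retest_ids, measurements, n_queued):
        tested = measured_count > 0
        batches.append(
            BatchOutcome(
                batch_index=batch_index,
                new_ids=[int(i) for i in new_ids],
                retest_ids=[int(i) for i in retest_ids],
                measurements=[(int(m.molecule_id), float(m.measured_value), int(m.replicate_index)) for m in measurements],
                cumulative_hits=int(np.sum(tested & active)),
                cumulative_true_hits=int(np.sum(active & (best_measured >= threshold))),
                n_retests_queued=n_queued,
            )
        )

    def take_measurements(ids, replicates, batch_index):
        ms = oracle.measure_many(ids, replicates, batch_index=batch_index)
        for m in ms:
            measured_count[m.molecule_id] += 1
            if m.measured_value > best_measured[m.molecule_id]:
                best_measured[m.molecule_id] = m.measured_value
            training.add(m.molecule_id, library.features[m.molecule_id], m.measured_value)
        return ms

    # Initial uniformly random batch — shared across acquisition arms of a run.
    init_rng = np.random.default_rng([run_seed, _INIT_TAG])
    initial_ids = init_rng.choice(n, size=batch_size, replace=False)
    ms = take_measurements(initial_ids, [0] * batch_size, batch_index=0)
    # No model existed when the initial batch was selected, so no predictions
    # are available and no retests are flagged from it.
    record(0, initial_ids, [], ms, 0)

    n_batches = n_active_learning_batches(n, batch_size, config.stop_fraction)
    if config.max_batches is not None:
        n_batches = min(n_batches, config.max_batches)

    for b in range(1, n_batches + 1):
        if with_retests:
            n_retest = min(len(retest_queue), batch_size)
            retest_ids = retest_queue[:n_retest]
            retest_queue = retest_queue[n_retest:]  # overflow carries over
        else:
            retest_ids = []
        n_new = batch_size - len(retest_ids)

        # The random baseline without retests needs no surrogate at all.
        need_model = acq.metric != "random" or with_retests
        pred = None
        if need_model:
            model = fit_surrogate(
                training,
                n_trees=config.n_trees,
                seed=_forest_seed(run_seed, b),
                uncertainty=config.uncertainty,
            )
            pred = model.predict(library.features)

        f_star = training.incumbent
        scores = score_candidates(
            pred,
            acq,
            f_star=f_star,
            pool_size=n,
            random_seed=[run_seed, _RANDOM_METRIC_TAG, b],
        )
        new_ids = rank_candidates(scores, measured_count > 0, n_new)

        new_ms = take_measurements(new_ids, [0] * len(new_ids), batch_index=b)
        retest_ms = take_measurements(retest_ids, [measured_count[i] for i in retest_ids], batch_index=b)
        batch_ms = new_ms + retest_ms

        flagged: list[int] = []
        if with_retests and config.retest_policy.kind != "none":
            batch_ids = [m.molecule_id for m in batch_ms]
            # "Predicted" means the prediction of the model that selected this
            # batch (the pre-measurement model), not of the refit model.
            flagged = flag_retests(
                batch_ids,
                pred.mu[batch_ids],
                pred.sigma[batch_ids],
                [m.measured_value for m in batch_ms],
                threshold,
                config.retest_policy,
                [measured_count[i] - 1 for i in batch_ids],
            )
            retest_queue.extend(flagged)

        record(b, new_ids, retest_ids, batch_ms, len(flagged))

    snapshot = asdict(config)
    snapshot["retest_policy"] = asdict(config.retest_policy)
    snapshot["pool_size"] = n
    snapshot["hit_threshold"] = threshold
    return CampaignTrace(config=snapshot, run_seed=int(run_seed), batches=batches)


def run_campaign_without_retests(library: ScreeningLibrary, config: CampaignConfig, run_seed: int) -> CampaignTrace:
    """One campaign run in which no molecule is ever measured twice."""
    return _run_engine(library, config, run_seed, with_retests=False)


def run_campaign_with_retests(library: ScreeningLibrary, config: CampaignConfig, run_seed: int) -> CampaignTrace:
    """One campaign run with the configured retest policy active."""
    if config.retest_policy.kind == "none":
        raise ValueError("run_campaign_with_retests requires a retest policy other than 'none'")
    return _run_engine(library, config, run_seed, with_retests=True)


def run_campaign(library: ScreeningLibrary, config: CampaignConfig, run_seed: int) -> CampaignTrace:
    """Dispatch on the configured retest policy kind."""
    if config.retest_policy.kind == "none":
        return run_campaign_without_retests(library, config, run_seed)
    return run_campaign_with_retests(library, config, run_seed)
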