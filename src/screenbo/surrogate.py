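"""Tree-ensemble surrogate: per-candidate predicted mean and uncertainty.

The QSAR surrogate is a 100-tree random-forest regressor refit from scratch
after every batch (no warm start).  Defaults follow the standard forest
configuration for regression: all features considered at each split,
squared-error split criterion, leaves may hold a single sample.  The
predictive mean is the average of per-tree predictions.

The uncertainty estimator is a pluggable strategy:

- ``"tree_variance"`` (default): the population *variance* of the per-tree
  predictions.  Because the variance carries squared activity units, it
  dominates the acquisition score on pools whose activity scale is large
  (UCB and EI then behave near-randomly there) and vanishes on pools with a
  small activity scale (UCB then tracks greedy) — the behaviour observed in
  the reference screening study this package reproduces.
- ``"tree_std"``: the population standard deviation of per-tree predictions,
  the conventional ensemble uncertainty in the same units as the activity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestRegressor

__all__ = [
    "TrainingSet",
    "SurrogatePrediction",
    "RandomForestSurrogate",
    "fit_surrogate",
    "predict",
]


class TrainingSet:
    """Ordered collection of (molecule_id, features, measured_value) entries.

    Duplicates by molecule_id are allowed and expected: a retested molecule
    contributes one entry per replicate, each with its own measured value, and
    all entries enter the bootstrap pool as independent rows (no averaging).
    """

    def __init__(self):
        self._ids: list[int] = []
        self._rows: list[np.ndarray] = []
        self._values: list[float] = []

    def add(self, molecule_id: int, features, measured_value: float) -> None:
        features = np.asarray(features, dtype=float)
        if self._rows and features.shape != self._rows[0].shape:
            raise ValueError("feature vector length differs from earlier entries")
        self._ids.append(int(molecule_id))
        self._rows.append(features)
        self._values.append(float(measured_value))

    def extend(self, molecule_ids, feature_matrix, measured_values) -> None:
        for mid, row, val in zip(molecule_ids, feature_matrix, measured_values, strict=True):
            self.add(mid, row, val)

    def __len__(self) -> int:
        return len(self._ids)

    @property
    def molecule_ids(self) -> np.ndarray:
        return np.asarray(self._ids, dtype=int)

    @property
    def X(self) -> np.ndarray:
        return np.vstack(self._rows) if self._rows else np.empty((0, 0))

    @property
    def y(self) -> np.ndarray:
        return np.asarray(self._values, dtype=float)

    @property
    def incumbent(self) -> float:
        """f*: the best (maximum) measured activity observed so far."""
        if not self._values:
            raise ValueError("training set is empty")
        return max(self._values)


@dataclass(frozen=True)
class SurrogatePrediction:
    """Per-candidate predicted mean mu and uncertainty sigma (same units)."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        if self.mu.shape != self.sigma.shape:
            raise ValueError("mu and sigma must be aligned")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be non-negative")


UNCERTAINTY_STRATEGIES = ("tree_variance", "tree_std")
DEFAULT_UNCERTAINTY = "tree_variance"


class RandomForestSurrogate:
    """Bootstrap ensemble of regression trees with spread-based uncertainty."""

    def __init__(self, n_trees: int = 100, seed: int | None = None, uncertainty: str = DEFAULT_UNCERTAINTY):
        if n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if uncertainty not in UNCERTAINTY_STRATEGIES:
            raise ValueError(f"unknown uncertainty strategy {uncertainty!r}; expected one of {UNCERTAINTY_STRATEGIES}")
        self.n_trees = n_trees
        self.seed = seed
        self.uncertainty = uncertainty
        self._forest: RandomForestRegressor | None = None
        self._n_features: int | None = None

    def fit(self, X, y) -> "RandomForestSurrogate":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("training set must be a non-empty 2-D feature matrix")
        if y.shape != (X.shape[0],):
            raise ValueError("targets must align with feature rows")
        forest = RandomForestRegressor(
            n_estimators=self.n_trees,
            max_features=1.0,
            criterion="squared_error",
            min_samples_leaf=1,
            random_state=self.seed,
        )
        forest.fit(X, y)
        self._forest = forest
        self._n_features = X.shape[1]
        return self

    def per_tree(self, X) -> np.ndarray:
        """(n_trees, n_candidates) matrix of individual tree predictions."""
        if self._forest is None:
            raise ValueError("surrogate is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self._n_features:
            raise ValueError(
                f"candidate feature width {X.shape[1] if X.ndim == 2 else '?'} "
                f"does not match training width {self._n_features}"
            )
        return np.stack([tree.predict(X) for tree in self._forest.estimators_])

    def predict(self, X) -> SurrogatePrediction:
        per_tree = self.per_tree(X)
        spread = per_tree.std(axis=0)
        if self.uncertainty == "tree_variance":
            spread = spread * spread
        return SurrogatePrediction(mu=per_tree.mean(axis=0), sigma=spread)


def fit_surrogate(
    training: TrainingSet,
    n_trees: int = 100,
    seed: int | None = None,
    uncertainty: str = DEFAULT_UNCERTAINTY,
) -> RandomForestSurrogate:
    if len(training) == 0:
        raise ValueError("cannot fit a surrogate on an empty training set")
    return RandomForestSurrogate(n_trees=n_trees, seed=seed, uncertainty=uncertainty).fit(training.X, training.y)


def predict(model: RandomForestSurrogate, candidates) -> SurrogatePrediction:
    return model.predict(candidates)
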