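"""Hold-out partitioning and rational train/validation division.

The dataset is first cut randomly into modelling and hold-out sets
(80:20); the modelling set is then divided 75:25 into training and
validation either randomly or by one of three rational (representative,
distance-driven) methods:

* Kennard-Stone — sequential max-min Euclidean selection starting from
  the most distant pair;
* k-means — cluster with k chosen by the elbow of the within-cluster
  sum of squares over k = 2..20, then sample training points
  proportionally from every cluster;
* Kohonen self-organizing map — hexagonal-topology SOM with learning
  rate decaying over [0.01, 0.05]; records are mapped to best-matching
  units and training points sampled proportionally per occupied unit.

All three operate on the standardized, imputed feature matrix with
one-hot categoricals included.  The hold-out cut is always random and
never touches splitter fitting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from npskin.datamodel import DatasetError

SPLIT_METHODS = ("random", "kennard_stone", "kmeans", "som")


@dataclass
class SplitAssignment:
    """Disjoint hold-out / train / validation id sets with provenance."""

    holdout_ids: list
    train_ids: list
    validation_ids: list
    method: str
    seed: int
    parameters: dict = field(default_factory=dict)

    def __post_init__(self):
        sets = [set(self.holdout_ids), set(self.train_ids), set(self.validation_ids)]
        total = sum(len(s) for s in sets)
        if len(set().union(*sets)) != total:
            raise DatasetError("partitions overlap")


def holdout_split(ids, fraction: float = 0.2, seed: int = 0):
    """Random modelling / hold-out cut; |holdout| = round(fraction * n)."""
    ids = list(ids)
    if not (0.0 < fraction < 1.0):
        raise DatasetError("fraction must be in (0, 1)")
    if len(ids) < 5:
        raise DatasetError("need at least 5 records to split")
    n_hold = int(round(fraction * len(ids)))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    holdout = [ids[i] for i in sorted(perm[:n_hold])]
    modeling = [ids[i] for i in sorted(perm[n_hold:])]
    return modeling, holdout


def kennard_stone(X: np.ndarray, n_select: int) -> list[int]:
    """Ordered Kennard-Stone selection of ``n_select`` row indices.

    The first two picks are a maximal-distance pair; every further pick
    maximizes its minimum distance to the already-selected set.  Ties
    break toward the lowest row index, making the output deterministic.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if np.isnan(X).any():
        raise DatasetError("Kennard-Stone requires a complete (imputed) matrix")
    if not (2 <= n_select <= n):
        raise DatasetError(f"n_select must be in [2, {n}]")
    D = cdist(X, X)
    # argmax on the flattened matrix returns the first (lowest-index) pair
    i, j = np.unravel_index(np.argmax(D), D.shape)
    selected = [min(i, j), max(i, j)]
    min_dist = np.minimum(D[selected[0]], D[selected[1]])
    min_dist[selected] = -np.inf
    while len(selected) < n_select:
        k = int(np.argmax(min_dist))
        selected.append(k)
        min_dist = np.minimum(min_dist, D[k])
        min_dist[k] = -np.inf
    return selected


def _proportional_sample(groups: np.ndarray, train_fraction: float, rng) -> np.ndarray:
    """Boolean train mask drawing ~train_fraction per group, >= 1 each."""
    train = np.zeros(len(groups), dtype=bool)
    for g in np.unique(groups):
        idx = np.where(groups == g)[0]
        k = max(1, int(round(train_fraction * len(idx))))
        train[rng.choice(idx, size=min(k, len(idx)), replace=False)] = True
    return train


def elbow_k(X: np.ndarray, k_range=range(2, 21), seed: int = 0) -> tuple[int, np.ndarray]:
    """Elbow choice of k: largest second difference of the WSS curve."""
    ks = [k for k in k_range if k <= len(X)]
    wss = []
    for k in ks:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
        wss.append(km.inertia_)
    wss = np.asarray(wss)
    if len(ks) < 3:
        return ks[0], wss
    second = wss[:-2] - 2 * wss[1:-1] + wss[2:]
    return ks[1 + int(np.argmax(second))], wss


def split_modeling(
    method: str,
    X: np.ndarray,
    ids,
    train_fraction: float = 0.75,
    seed: int = 0,
    **params,
) -> SplitAssignment:
    """Divide the modelling set into train / validation by ``method``."""
    ids = list(ids)
    X = np.asarray(X, dtype=float)
    if len(ids) != X.shape[0]:
        raise DatasetError("ids and X length mismatch")
    rng = np.random.default_rng(seed)

    if method == "random":
        n_train = int(round(train_fraction * len(ids)))
        perm = rng.permutation(len(ids))
        train_idx = set(perm[:n_train].tolist())
    elif method == "kennard_stone":
        n_train = int(round(train_fraction * len(ids)))
        train_idx = set(kennard_stone(X, n_train))
    elif method == "kmeans":
        if np.allclose(X, X[0]):
            warnings.warn("degenerate matrix: all rows identical, forcing k=1")
            k, wss = 1, np.array([0.0])
            labels = np.zeros(len(ids), dtype=int)
        else:
            k_range = params.get("k_range", range(2, 21))
            k, wss = elbow_k(X, k_range=k_range, seed=seed)
            labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(X)
        params = {**params, "k": int(k)}
        train_idx = set(np.where(
            _proportional_sample(labels, train_fraction, rng)
        )[0].tolist())
    elif method == "som":
        side = params.get("grid_side") or math.ceil(math.sqrt(5 * math.sqrt(len(ids))))
        som = SelfOrganizingMap(
            grid=(side, side),
            alpha_range=params.get("alpha_range", (0.01, 0.05)),
            seed=seed,
        )
        som.fit(X)
        units = som.best_matching_units(X)
        params = {**params, "grid_side": side}
        train_idx = set(np.where(
            _proportional_sample(units, train_fraction, rng)
        )[0].tolist())
    else:
        raise DatasetError(f"unknown split method {method!r}")

    return SplitAssignment(
        holdout_ids=[],
        train_ids=[ids[i] for i in sorted(train_idx)],
        validation_ids=[ids[i] for i in sorted(set(range(len(ids))) - train_idx)],
        method=method,
        seed=seed,
        parameters=params,
    )


class SelfOrganizingMap:
    """Minimal Kohonen SOM on a hexagonal grid.

    Unit centres sit on an offset hexagonal lattice; the learning rate
    decays linearly from the top to the bottom of ``alpha_range`` and
    the Gaussian neighbourhood radius shrinks from half the grid
    diagonal to 0.5 over training.
    """

    def __init__(self, grid=(6, 6), alpha_range=(0.01, 0.05), n_epochs: int = 20,
                 seed: int = 0):
        gx, gy = grid
        if gx < 1 or gy < 1:
            raise DatasetError("empty SOM grid")
        self.grid = (gx, gy)
        self.alpha_range = (min(alpha_range), max(alpha_range))
        self.n_epochs = n_epochs
        self.seed = seed
        # hexagonal unit positions: odd rows offset by half a cell
        pos = []
        for j in range(gy):
            for i in range(gx):
                pos.append((i + 0.5 * (j % 2), j * math.sqrt(3.0) / 2.0))
        self.positions = np.asarray(pos)
        self.weights_: np.ndarray | None = None
        self.qe_trace_: list[float] = []

    def fit(self, X: np.ndarray) -> "SelfOrganizingMap":
        X = np.asarray(X, dtype=float)
        n_units = len(self.positions)
        if len(X) < n_units:
            raise DatasetError(
                f"need at least {n_units} records for a {self.grid} grid"
            )
        rng = np.random.default_rng(self.seed)
        init = rng.choice(len(X), size=n_units, replace=False)
        W = X[init].copy() + 1e-6 * rng.standard_normal((n_units, X.shape[1]))
        a_lo, a_hi = self.alpha_range
        sigma0 = max(self.positions.max(axis=0).max() / 2.0, 0.5)
        grid_d2 = cdist(self.positions, self.positions) ** 2
        self.qe_trace_ = []
        for epoch in range(self.n_epochs):
            t = epoch / max(self.n_epochs - 1, 1)
            alpha = a_hi + (a_lo - a_hi) * t
            sigma = sigma0 + (0.5 - sigma0) * t
            order = rng.permutation(len(X))
            for idx in order:
                x = X[idx]
                bmu = int(np.argmin(((W - x) ** 2).sum(axis=1)))
                h = np.exp(-grid_d2[bmu] / (2.0 * sigma * sigma))
                W += alpha * h[:, None] * (x - W)
            qe = float(np.mean(np.sqrt(
                ((X[:, None, :] - W[None, :, :]) ** 2).sum(axis=2).min(axis=1)
            )))
            self.qe_trace_.append(qe)
        self.weights_ = W
        return self

    def best_matching_units(self, X: np.ndarray) -> np.ndarray:
        if self.weights_ is None:
            raise DatasetError("SOM not fitted")
        return np.argmin(cdist(np.asarray(X, float), self.weights_), axis=1)

    def quantization_error(self, X: np.ndarray) -> float:
        d = cdist(np.asarray(X, float), self.weights_).min(axis=1)
        return float(d.mean())
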