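"""Network training: k-means center selection, width, weights, error loop.

Centers are picked by plain k-means on the continuous feature vectors:
initial centers are k distinct training samples drawn by a seeded stream,
then nearest-center assignment (ties to the lowest center index) alternates
with member-mean updates until the largest center displacement falls below a
tolerance.  An empty cluster is re-seeded to the sample farthest from its
nearest surviving center.

Two training modes share the clustering/width stage and differ in how the
output weights are obtained:

* ``closed_form`` — one ridge-stabilized least-squares solve; the reference
  solution and the default.
* ``iterative`` — weights start at zero and are refined by gradient descent
  on the mean-squared error with fixed centers and width, logging the error
  as it decays.  This exists to expose a training curve (rapid early drop,
  then a plateau); its fixed point is the closed-form solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .core import (
    DEFAULT_RIDGE,
    RBFNetwork,
    compute_sigma,
    fit_output_weights,
    hidden_activations,
    mse_error,
)
from .exceptions import DegenerateCentersError, InputError, TrainingError
from .features import PixelSample

__all__ = [
    "ClusterState",
    "TrainingLog",
    "init_centers",
    "assign_clusters",
    "update_centers",
    "kmeans",
    "default_hidden_count",
    "train",
]


@dataclass
class ClusterState:
    """One k-means iterate: centers, sample assignments, member counts."""

    centers: np.ndarray        # (k, m)
    assignments: np.ndarray    # (E,) cluster index per sample
    iteration: int
    member_counts: np.ndarray  # (k,)


@dataclass
class TrainingLog:
    """Error trajectory of a training run."""

    records: list[tuple[int, float]] = field(default_factory=list)
    converged: bool = False
    final_error: float = float("nan")

    @property
    def iterations(self) -> np.ndarray:
        return np.asarray([i for i, _ in self.records], dtype=int)

    @property
    def errors(self) -> np.ndarray:
        return np.asarray([u for _, u in self.records], dtype=float)

    def append(self, iteration: int, error: float) -> None:
        if self.records and iteration <= self.records[-1][0]:
            raise InputError("iteration counts must be strictly increasing")
        self.records.append((int(iteration), float(error)))

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.records, columns=["iteration", "error"]).to_csv(
            path, index=False
        )


def init_centers(samples, k: int, seed: int | np.random.Generator) -> np.ndarray:
    """k distinct sample rows, drawn without replacement by a seeded stream."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if k < 2:
        raise DegenerateCentersError(f"need k >= 2, got {k}")
    distinct = np.unique(samples, axis=0)
    if len(distinct) < k:
        raise DegenerateCentersError(
            f"only {len(distinct)} distinct samples for k={k} centers"
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    pick = rng.choice(len(distinct), size=k, replace=False)
    return distinct[pick].copy()


def assign_clusters(samples, centers) -> np.ndarray:
    """Nearest-center assignment by Euclidean distance; ties go to the
    lowest center index (argmin's first-minimum rule)."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if samples.size == 0 or centers.size == 0:
        raise InputError("samples and centers must be nonempty")
    return cdist(samples, centers).argmin(axis=1)


def update_centers(samples, assignments, previous_centers) -> np.ndarray:
    """Member-mean update; empty clusters re-seed to the sample farthest
    from its nearest nonempty updated center."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    assignments = np.asarray(assignments, dtype=int)
    previous_centers = np.atleast_2d(np.asarray(previous_centers, dtype=float))
    k = previous_centers.shape[0]
    new_centers = previous_centers.copy()
    empty: list[int] = []
    for i in range(k):
        members = samples[assignments == i]
        if len(members):
            new_centers[i] = members.mean(axis=0)
        else:
            empty.append(i)
    if empty:
        nonempty = [i for i in range(k) if i not in empty]
        taken: set[int] = set()
        for i in empty:
            d = cdist(samples, new_centers[nonempty]).min(axis=1)
            order = np.argsort(-d)
            pick = next(int(j) for j in order if int(j) not in taken)
            taken.add(pick)
            new_centers[i] = samples[pick]
    return new_centers


def _sse(samples: np.ndarray, centers: np.ndarray, assignments: np.ndarray) -> float:
    return float(np.sum((samples - centers[assignments]) ** 2))


def kmeans(
    samples,
    k: int,
    seed: int | np.random.Generator = 0,
    max_iter: int = 300,
    tol: float = 1e-9,
    n_init: int = 1,
) -> tuple[np.ndarray, int]:
    """Lloyd iterations until the largest center displacement is <= tol.

    ``n_init`` restarts run from independent seeded initializations and the
    centers with the lowest within-cluster sum of squares win.  Returns the
    final centers and the number of iterations of the winning run.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if max_iter < 1:
        raise InputError("max_iter must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    best: tuple[float, np.ndarray, int] | None = None
    for _ in range(max(1, n_init)):
        centers = init_centers(samples, k, rng)
        iteration = 0
        for iteration in range(1, max_iter + 1):
            assignments = assign_clusters(samples, centers)
            new_centers = update_centers(samples, assignments, centers)
            shift = float(np.linalg.norm(new_centers - centers, axis=1).max())
            centers = new_centers
            if shift <= tol:
                break
        assignments = assign_clusters(samples, centers)
        sse = _sse(samples, centers, assignments)
        if best is None or sse < best[0]:
            best = (sse, centers, iteration)
    assert best is not None
    return best[1], best[2]


def default_hidden_count(n_samples: int) -> int:
    """Default hidden-layer size: ceil(sqrt(E)), clamped to [2, E]."""
    return int(min(max(2, np.ceil(np.sqrt(n_samples))), n_samples))


def train(
    train_set: PixelSample,
    g: int | None = None,
    seed: int = 0,
    mode: str = "closed_form",
    epochs: int = 2000,
    lr: float | None = None,
    target_error: float | None = None,
    ridge: float = DEFAULT_RIDGE,
    tol: float = 1e-9,
    log_every: int = 10,
    n_init: int = 1,
    palette: dict[int, tuple[int, int, int]] | None = None,
) -> tuple[RBFNetwork, TrainingLog]:
    """Fit an RBF classifier to a labelled pixel sample.

    Pipeline: k-means on the feature rows picks the g centers, the shared
    width follows from the maximum center separation, the hidden activation
    matrix is formed, and the output weights are solved (``closed_form``) or
    descended (``iterative``).  All randomness flows from ``seed`` through
    named substreams, one per stage.

    Returns the fitted network and a :class:`TrainingLog`; in closed-form
    mode the log holds the single final error.
    """
    if train_set.features is None or train_set.targets is None:
        raise InputError("train_set must carry features and one-hot targets")
    X = np.asarray(train_set.features, dtype=float)
    T = np.asarray(train_set.targets, dtype=float)
    E, m = X.shape
    n = T.shape[1]
    if g is None:
        g = default_hidden_count(E)
    if g < 2:
        raise InputError(f"need g >= 2 hidden nodes, got {g}")
    if mode not in ("closed_form", "iterative"):
        raise InputError(f"unknown mode {mode!r}")

    # independent seeded streams per stage, all derived from one integer
    centers_rng = np.random.default_rng([int(seed), 0])
    try:
        centers, _ = kmeans(X, g, seed=centers_rng, tol=tol, n_init=n_init)
        sigma = compute_sigma(centers)
    except DegenerateCentersError as exc:
        raise TrainingError(f"degenerate clustering: {exc}") from exc

    A = hidden_activations(X, centers, sigma)
    log = TrainingLog()

    if mode == "closed_form":
        W = fit_output_weights(A, T, ridge=ridge)
        U = mse_error(A @ W, T)
        log.append(1, U)
        log.converged = True
        log.final_error = U
    else:
        if epochs < 1:
            raise InputError("epochs must be >= 1")
        if lr is None:
            # largest step with guaranteed monotone descent: 1/L where
            # L = lambda_max(A^T A) / E is the Lipschitz constant of grad U
            L = float(np.linalg.norm(A, 2) ** 2) / E
            lr = 1.0 / L if L > 0 else 1.0
        W = np.zeros((g, n))
        U = mse_error(A @ W, T)
        log.append(0, U)
        for epoch in range(1, epochs + 1):
            grad = A.T @ (A @ W - T) / E
            W = W - lr * grad
            if epoch % log_every == 0 or epoch == epochs:
                U = mse_error(A @ W, T)
                log.append(epoch, U)
                if target_error is not None and U <= target_error:
                    log.converged = True
                    break
        log.final_error = log.records[-1][1]
        if target_error is None:
            log.converged = True

    network = RBFNetwork(
        centers=centers,
        sigma=sigma,
        weights=W,
        n_classes=n,
        feature_dim=m,
        palette=palette,
        scaling=train_set.scaling,
        class_values=train_set.class_values,
    )
    if network.palette is None:
        from .segmentation import default_palette

        network.palette = default_palette(n)
    return network, log
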