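"""Mathematical core of the RBF network.

The network has three layers.  The input layer passes the m-dimensional
feature vector through unchanged.  Each of the g hidden nodes is a Gaussian
radial basis unit centered at a prototype point c_i; all nodes share one
width

    sigma = c_max / sqrt(2 g),

where c_max is the maximum pairwise Euclidean distance among the centers.
This classic heuristic keeps the Gaussians neither needle-sharp nor so flat
that they all overlap.  The output layer is linear: for a sample x the raw
class scores are

    y_j = sum_i  w_ij * exp(-||x - c_i||^2 / (2 sigma^2)),

and the g-by-n weight matrix w is the least-squares minimizer of the
mean-squared error against one-hot targets,

    U = sum_e ||Y_e - D_e||^2 / (2 E),

optionally ridge-stabilized.  With one center per training sample and a
nonsingular activation matrix the fit interpolates the targets exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .exceptions import (
    DegenerateCentersError,
    InputError,
    SingularActivationsError,
)
from .features import FeatureScaling

__all__ = [
    "RBFNetwork",
    "gaussian_activation",
    "compute_sigma",
    "hidden_activations",
    "forward",
    "fit_output_weights",
    "mse_error",
]

#: absolute tolerance for "activation equals 1 at the center"
CENTER_ATOL = 1e-12

#: default ridge used to stabilize the normal-equation solve
DEFAULT_RIDGE = 1e-8


def gaussian_activation(x, c, sigma: float) -> float:
    """Gaussian radial basis response exp(-||x - c||^2 / (2 sigma^2)).

    Strictly decreasing in the distance ||x - c||, equal to 1 exactly when
    the input coincides with the center.
    """
    if sigma <= 0:
        raise InputError(f"sigma must be positive, got {sigma}")
    x = np.atleast_1d(np.asarray(x, dtype=float))
    c = np.atleast_1d(np.asarray(c, dtype=float))
    if x.shape != c.shape:
        raise InputError(f"dimension mismatch: {x.shape} vs {c.shape}")
    d2 = float(np.sum((x - c) ** 2))
    return float(np.exp(-d2 / (2.0 * sigma**2)))


def compute_sigma(centers) -> float:
    """Shared Gaussian width c_max / sqrt(2 g) for a set of g centers.

    Undefined for fewer than two centers or coincident centers (c_max = 0);
    both raise :class:`DegenerateCentersError`, which signals that the
    clustering stage produced an unusable center set.
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    g = centers.shape[0]
    if g < 2:
        raise DegenerateCentersError(f"need at least 2 centers, got {g}")
    c_max = float(pdist(centers).max())
    if c_max == 0.0:
        raise DegenerateCentersError("all centers coincide (c_max = 0)")
    return c_max / np.sqrt(2.0 * g)


def hidden_activations(X, centers, sigma: float) -> np.ndarray:
    """E-by-g matrix of Gaussian responses R(||X_e - c_i||), entries in (0, 1]."""
    if sigma <= 0:
        raise InputError(f"sigma must be positive, got {sigma}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if X.shape[1] != centers.shape[1]:
        raise InputError(
            f"feature dimension mismatch: samples have {X.shape[1]}, "
            f"centers have {centers.shape[1]}"
        )
    d2 = cdist(X, centers, metric="sqeuclidean")
    return np.exp(-d2 / (2.0 * sigma**2))


def fit_output_weights(
    activations, targets, ridge: float = DEFAULT_RIDGE
) -> np.ndarray:
    """Least-squares solve for the hidden-to-output weight matrix.

    Minimizes sum_e ||A_e w - D_e||^2 (+ ridge * ||w||_F^2 when ridge > 0)
    via an orthogonal-decomposition solve on the (optionally ridge-augmented)
    system.  With ridge = 0 and a rank-deficient activation matrix the
    minimizer is not unique and :class:`SingularActivationsError` is raised.
    """
    A = np.atleast_2d(np.asarray(activations, dtype=float))
    T = np.atleast_2d(np.asarray(targets, dtype=float))
    if A.shape[0] != T.shape[0]:
        raise InputError(
            f"activations have {A.shape[0]} rows but targets have {T.shape[0]}"
        )
    if ridge < 0:
        raise InputError("ridge must be nonnegative")
    g = A.shape[1]
    if ridge > 0:
        A_aug = np.vstack([A, np.sqrt(ridge) * np.eye(g)])
        T_aug = np.vstack([T, np.zeros((g, T.shape[1]))])
        w, *_ = np.linalg.lstsq(A_aug, T_aug, rcond=None)
        return w
    w, _, rank, _ = np.linalg.lstsq(A, T, rcond=None)
    if rank < g:
        raise SingularActivationsError(
            f"activation matrix has rank {rank} < {g}; "
            "pass ridge > 0 to stabilize the solve"
        )
    return w


def mse_error(outputs, targets) -> float:
    """Mean-squared training error U = sum_e ||Y_e - D_e||^2 / (2 E)."""
    Y = np.atleast_2d(np.asarray(outputs, dtype=float))
    D = np.atleast_2d(np.asarray(targets, dtype=float))
    if Y.shape != D.shape:
        raise InputError(f"shape mismatch: outputs {Y.shape} vs targets {D.shape}")
    E = Y.shape[0]
    if E == 0:
        raise InputError("error is undefined for zero samples")
    return float(np.sum((Y - D) ** 2) / (2.0 * E))


@dataclass
class RBFNetwork:
    """A fitted RBF classifier: centers, shared width, linear output weights.

    ``palette`` maps class index to an RGB triple for rendering; ``scaling``
    holds the feature-normalization constants of the training image so that
    inference reproduces the training-time feature mapping.
    """

    centers: np.ndarray            # (g, m)
    sigma: float
    weights: np.ndarray            # (g, n)
    n_classes: int
    feature_dim: int
    palette: dict[int, tuple[int, int, int]] | None = None
    scaling: FeatureScaling | None = None
    class_values: np.ndarray | None = None  # label value per output column

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=float))
        g, m = self.centers.shape
        if g < 2:
            raise DegenerateCentersError(f"need at least 2 centers, got {g}")
        if self.sigma <= 0:
            raise InputError(f"sigma must be positive, got {self.sigma}")
        if m != self.feature_dim:
            raise InputError(
                f"centers have dimension {m}, expected feature_dim={self.feature_dim}"
            )
        if self.weights.shape != (g, self.n_classes):
            raise InputError(
                f"weights must be {(g, self.n_classes)}, got {self.weights.shape}"
            )

    @property
    def g(self) -> int:
        return self.centers.shape[0]

    def activations(self, X) -> np.ndarray:
        return hidden_activations(X, self.centers, self.sigma)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "feature_dim": int(self.feature_dim),
            "n_classes": int(self.n_classes),
            "sigma": float(self.sigma),
            "centers": self.centers.tolist(),
            "weights": self.weights.tolist(),
            "palette": (
                None
                if self.palette is None
                else {str(k): list(map(int, v)) for k, v in self.palette.items()}
            ),
            "feature_scaling": (
                None if self.scaling is None else self.scaling.to_dict()
            ),
            "class_values": (
                None
                if self.class_values is None
                else np.asarray(self.class_values).tolist()
            ),
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RBFNetwork":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        doc = json.loads(text)
        palette = doc.get("palette")
        if palette is not None:
            palette = {int(k): tuple(v) for k, v in palette.items()}
        scaling = doc.get("feature_scaling")
        if scaling is not None:
            scaling = FeatureScaling.from_dict(scaling)
        class_values = doc.get("class_values")
        if class_values is not None:
            class_values = np.asarray(class_values)
        return cls(
            centers=np.asarray(doc["centers"], dtype=float),
            sigma=float(doc["sigma"]),
            weights=np.asarray(doc["weights"], dtype=float),
            n_classes=int(doc["n_classes"]),
            feature_dim=int(doc["feature_dim"]),
            palette=palette,
            scaling=scaling,
            class_values=class_values,
        )


def forward(network: RBFNetwork, x) -> tuple[np.ndarray, np.ndarray]:
    """Raw class scores and a probability-like normalized copy.

    Raw scores are the linear combination of hidden activations; they are
    what classification argmaxes over.  The normalized copy clips negatives
    to zero and rescales to the simplex; when the clipped sum is zero (all
    raw scores nonpositive) it falls back to the uniform vector.  Where the
    normalization is defined it preserves the argmax.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    raw = network.activations(np.atleast_2d(x)) @ network.weights
    clipped = np.clip(raw, 0.0, None)
    sums = clipped.sum(axis=1, keepdims=True)
    uniform = np.full_like(raw, 1.0 / network.n_classes)
    with np.errstate(invalid="ignore", divide="ignore"):
        normalized = np.where(sums > 0, clipped / np.where(sums > 0, sums, 1.0), uniform)
    if single:
        return raw[0], normalized[0]
    return raw, normalized
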