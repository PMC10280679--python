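"""Gaussian radial-basis-function network for anxiety-state classification.

One hidden unit per anxiety class (k = 3 by default), each computing
``R_j(x) = exp(-||x - c_j||^2 / (2 sigma_j^2))``, and a single scalar output
``y(x) = sum_j w_j R_j(x)``.  The scalar output is matched against integer
class codes via the squared-error objective ``xi = 1/2 sum_q e_q^2`` with
``e_q = d_q - y(x_q)``, and all three parameter families (weights, centers,
widths) are trained by batch gradient descent:

* ``d xi / d w_j     = - sum_q e_q R_j(x_q)``
* ``d xi / d c_j     = - sum_q e_q (w_j / sigma_j^2) R_j(x_q) (x_q - c_j)``
* ``d xi / d sigma_j = - sum_q e_q (w_j / sigma_j^3) ||x_q - c_j||^2 R_j(x_q)``

Initialization uses per-class statistics: centers at the class means,
widths at the mean distance of class members to their center, and weights
from solving the k-by-k linear system built from one representative sample
per class (the one nearest its class center).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .data_model import DEFAULT_CLASS_CODES, AnxietyClass, Dataset, RiskLevel

__all__ = [
    "RBFNetwork",
    "TrainConfig",
    "TrainResult",
    "Gradients",
    "gaussian_activation",
    "forward",
    "total_error",
    "gradients",
    "update_step",
    "init_network",
    "train",
    "predict_risk",
    "predict_class",
    "save_network",
    "load_network",
]


@dataclass(frozen=True)
class RBFNetwork:
    """Trained or in-training network parameters.

    ``centers`` is ``(k, d)``; ``widths`` and ``weights`` are ``(k,)``.
    Hidden units are ordered by ascending class code.
    """

    centers: np.ndarray
    widths: np.ndarray
    weights: np.ndarray
    class_codes: dict[AnxietyClass, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_CODES)
    )

    def __post_init__(self) -> None:
        centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        widths = np.asarray(self.widths, dtype=float).ravel()
        weights = np.asarray(self.weights, dtype=float).ravel()
        if not (len(centers) == len(widths) == len(weights)):
            raise ValueError("centers, widths and weights disagree on k")
        if np.any(widths <= 0):
            raise ValueError("widths must be strictly positive")
        codes = sorted(self.class_codes.values())
        if len(set(codes)) != len(codes):
            raise ValueError("class codes must be distinct")
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "widths", widths)
        object.__setattr__(self, "weights", weights)

    @property
    def k(self) -> int:
        return len(self.widths)

    @property
    def d(self) -> int:
        return self.centers.shape[1]

    def activations(self, X: np.ndarray) -> np.ndarray:
        """``(n, k)`` matrix of hidden-unit outputs."""
        X = _as_matrix(X, self.d)
        sq = ((X[:, None, :] - self.centers[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-sq / (2.0 * self.widths[None, :] ** 2))


@dataclass(frozen=True)
class TrainConfig:
    """Learning rates, stopping rule and numeric guards.

    ``epsilon=None`` resolves to ``0.02 * N`` at training time (mean squared
    error of 0.04 per sample).  The weight rate is deliberately larger than
    the center/width rates so the basis stays anchored near the class
    statistics it was initialized from.
    """

    eta_weights: float = 0.01
    eta_centers: float = 1e-4
    eta_widths: float = 1e-4
    epsilon: float | None = None
    max_iter: int = 5000
    sigma_min: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("eta_weights", "eta_centers", "eta_widths"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.epsilon is not None and self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.max_iter < 0:
            raise ValueError("max_iter must be >= 0")
        if self.sigma_min <= 0:
            raise ValueError("sigma_min must be positive")

    def resolve_epsilon(self, n_samples: int) -> float:
        return self.epsilon if self.epsilon is not None else 0.02 * n_samples


@dataclass(frozen=True)
class Gradients:
    weights: np.ndarray  # (k,)
    centers: np.ndarray  # (k, d)
    widths: np.ndarray   # (k,)


@dataclass(frozen=True)
class TrainResult:
    network: RBFNetwork
    converged: bool
    iterations: int
    error_trace: tuple[float, ...]


def _as_matrix(X, d: int | None = None) -> np.ndarray:
    if isinstance(X, Dataset):
        X = X.values
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if d is not None and X.shape[1] != d:
        raise ValueError(f"expected {d}-dimensional samples, got {X.shape[1]}")
    return X


# ---------------------------------------------------------------------------
# forward pass
# ---------------------------------------------------------------------------

def gaussian_activation(x: np.ndarray, center: np.ndarray, width: float) -> float:
    """``exp(-||x - c||^2 / (2 sigma^2))``, in ``(0, 1]``."""
    if width <= 0:
        raise ValueError("width must be strictly positive")
    x = np.asarray(x, dtype=float).ravel()
    center = np.asarray(center, dtype=float).ravel()
    if x.shape != center.shape:
        raise ValueError("sample and center dimensions disagree")
    sq = float(((x - center) ** 2).sum())
    return float(np.exp(-sq / (2.0 * width**2)))


def forward(net: RBFNetwork, x: np.ndarray) -> float:
    """Scalar network output ``y(x) = sum_j w_j R_j(x)``."""
    return float(net.activations(_as_matrix(x, net.d))[0] @ net.weights)


def forward_batch(net: RBFNetwork, X: np.ndarray) -> np.ndarray:
    return net.activations(X) @ net.weights


def total_error(net: RBFNetwork, X: np.ndarray, targets: Sequence[float]) -> float:
    """Squared-error objective ``1/2 sum_q (d_q - y(x_q))^2``."""
    X = _as_matrix(X, net.d)
    targets = np.asarray(targets, dtype=float).ravel()
    if len(X) != len(targets):
        raise ValueError("sample and target counts disagree")
    if len(X) == 0:
        raise ValueError("empty batch")
    e = targets - forward_batch(net, X)
    return float(0.5 * (e**2).sum())


# ---------------------------------------------------------------------------
# gradients and updates
# ---------------------------------------------------------------------------

def gradients(net: RBFNetwork, X: np.ndarray, targets: Sequence[float]) -> Gradients:
    """Analytic batch gradients of the objective for all parameter families."""
    X = _as_matrix(X, net.d)
    targets = np.asarray(targets, dtype=float).ravel()
    if len(X) != len(targets):
        raise ValueError("sample and target counts disagree")
    R = net.activations(X)                      # (n, k)
    e = targets - R @ net.weights               # (n,)
    diff = X[:, None, :] - net.centers[None, :, :]   # (n, k, d)
    sq = (diff**2).sum(axis=2)                  # (n, k)
    g_w = -(e[:, None] * R).sum(axis=0)
    coef = e[:, None] * R * net.weights[None, :]     # (n, k)
    g_c = -((coef / net.widths[None, :] ** 2)[:, :, None] * diff).sum(axis=0)
    g_s = -((coef / net.widths[None, :] ** 3) * sq).sum(axis=0)
    return Gradients(weights=g_w, centers=g_c, widths=g_s)


def update_step(net: RBFNetwork, grads: Gradients, config: TrainConfig) -> RBFNetwork:
    """One gradient-descent step; widths are floored at ``sigma_min``."""
    return replace(
        net,
        weights=net.weights - config.eta_weights * grads.weights,
        centers=net.centers - config.eta_centers * grads.centers,
        widths=np.maximum(
            net.widths - config.eta_widths * grads.widths, config.sigma_min
        ),
    )


# ---------------------------------------------------------------------------
# initialization and training
# ---------------------------------------------------------------------------

def targets_from_labels(
    labels: Sequence[AnxietyClass], class_codes: dict[AnxietyClass, int]
) -> np.ndarray:
    try:
        return np.array([class_codes[lab] for lab in labels], dtype=float)
    except KeyError as exc:
        raise ValueError(f"label {exc.args[0]!r} has no class code") from None


def init_network(
    X: np.ndarray,
    labels: Sequence[AnxietyClass],
    class_codes: dict[AnxietyClass, int] | None = None,
    sigma_min: float = 1e-3,
) -> RBFNetwork:
    """Class-statistics initialization.

    Centers: per-class sample means.  Widths: mean Euclidean distance of
    class members to their center, floored at ``sigma_min``.  Weights: exact
    solution of the k-by-k system built from one representative per class
    (nearest to its center), with a tiny-ridge least-squares fallback.
    """
    class_codes = dict(class_codes or DEFAULT_CLASS_CODES)
    X = _as_matrix(X)
    labels = list(labels)
    if len(labels) != len(X):
        raise ValueError("sample and label counts disagree")
    order = sorted(class_codes, key=class_codes.get)
    centers, widths, reps, codes = [], [], [], []
    for cls in order:
        rows = [i for i, lab in enumerate(labels) if lab == cls]
        if not rows:
            raise ValueError(f"class {cls.value!r} has no samples")
        pts = X[rows]
        c = pts.mean(axis=0)
        centers.append(c)
        widths.append(max(float(np.linalg.norm(pts - c, axis=1).mean()), sigma_min))
        reps.append(pts[int(np.argmin(np.linalg.norm(pts - c, axis=1)))])
        codes.append(class_codes[cls])
    net = RBFNetwork(
        centers=np.array(centers),
        widths=np.array(widths),
        weights=np.zeros(len(order)),
        class_codes=class_codes,
    )
    R = net.activations(np.array(reps))
    d = np.array(codes, dtype=float)
    try:
        w = np.linalg.solve(R, d)
    except np.linalg.LinAlgError:
        k = len(order)
        w = np.linalg.solve(R.T @ R + 1e-8 * np.eye(k), R.T @ d)
    return replace(net, weights=w)


def train(
    X: np.ndarray,
    labels: Sequence[AnxietyClass],
    config: TrainConfig | None = None,
    class_codes: dict[AnxietyClass, int] | None = None,
) -> TrainResult:
    """Full training loop: initialize, then batch gradient descent.

    Each iteration computes the batch objective; training stops as soon as
    it falls below the tolerance (``converged=True``) or after ``max_iter``
    iterations (``converged=False``).  Deterministic: samples are presented
    in dataset order and there is no stochastic element.
    """
    config = config or TrainConfig()
    X = _as_matrix(X)
    net = init_network(X, labels, class_codes, sigma_min=config.sigma_min)
    targets = targets_from_labels(labels, net.class_codes)
    eps = config.resolve_epsilon(len(X))
    xi = total_error(net, X, targets)
    trace = [xi]
    if xi < eps:
        return TrainResult(net, True, 0, tuple(trace))
    for t in range(1, config.max_iter + 1):
        net = update_step(net, gradients(net, X, targets), config)
        xi = total_error(net, X, targets)
        trace.append(xi)
        if xi < eps:
            return TrainResult(net, True, t, tuple(trace))
    return TrainResult(net, False, config.max_iter, tuple(trace))


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def predict_risk(net: RBFNetwork, x: np.ndarray) -> RiskLevel:
    """Round the scalar output (half up) and clip to {1, 2, 3}."""
    y = forward(net, x)
    return RiskLevel(int(np.clip(np.floor(y + 0.5), 1, 3)))


def predict_class(net: RBFNetwork, x: np.ndarray) -> AnxietyClass:
    """Inverse of the class-code mapping applied to the risk prediction."""
    code_to_class = {v: k for k, v in net.class_codes.items()}
    return code_to_class[int(predict_risk(net, x))]


def predict_class_batch(net: RBFNetwork, X: np.ndarray) -> list[AnxietyClass]:
    y = forward_batch(net, X)
    codes = np.clip(np.floor(y + 0.5), 1, 3).astype(int)
    code_to_class = {v: k for k, v in net.class_codes.items()}
    return [code_to_class[int(c)] for c in codes]


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def network_to_dict(net: RBFNetwork, metadata: dict | None = None) -> dict:
    out = {
        "k": net.k,
        "d": net.d,
        "centers": net.centers.tolist(),
        "widths": net.widths.tolist(),
        "weights": net.weights.tolist(),
        "class_codes": {cls.value: code for cls, code in net.class_codes.items()},
    }
    if metadata:
        out["metadata"] = metadata
    return out


def network_from_dict(data: dict) -> RBFNetwork:
    return RBFNetwork(
        centers=np.array(data["centers"], dtype=float),
        widths=np.array(data["widths"], dtype=float),
        weights=np.array(data["weights"], dtype=float),
        class_codes={
            AnxietyClass(name): int(code)
            for name, code in data["class_codes"].items()
        },
    )


def save_network(
    net: RBFNetwork, path: str | Path, metadata: dict | None = None
) -> None:
    Path(path).write_text(json.dumps(network_to_dict(net, metadata), indent=2))


def load_network(path: str | Path) -> RBFNetwork:
    return network_from_dict(json.loads(Path(path).read_text()))
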