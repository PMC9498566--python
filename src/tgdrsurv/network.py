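"""One-hidden-layer Cox network: forward propagation and exact backprop.

The network maps a covariate vector z to a log hazard ratio

    theta = W2' tanh(W1 z + b),

with h hidden nodes, so W1 is h x p, W2 and b are length h.  The loss is
the negative Cox log partial likelihood of the scores theta; gradients
are computed by explicit backpropagation (no autodiff) so that the
per-entry gradient matrices are first-class objects the thresholded
optimizer can mask.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .survival import CoxPartialLikelihood, SurvivalDataset

__all__ = ["NetworkParams", "GradientSet", "forward", "backward"]


@dataclass
class NetworkParams:
    """Weights of the one-hidden-layer Cox network.

    W1 : (h, p) input-to-hidden weights
    W2 : (h,)   hidden-to-output weights
    b  : (h,)   hidden bias
    """

    W1: np.ndarray
    W2: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.W1 = np.atleast_2d(np.asarray(self.W1, dtype=float))
        self.W2 = np.asarray(self.W2, dtype=float).ravel()
        self.b = np.asarray(self.b, dtype=float).ravel()
        h = self.W1.shape[0]
        if self.W2.size != h or self.b.size != h:
            raise ValueError(
                f"inconsistent shapes: W1 is {self.W1.shape}, "
                f"W2 has {self.W2.size}, b has {self.b.size}"
            )
        for name, arr in (("W1", self.W1), ("W2", self.W2), ("b", self.b)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")

    @property
    def h(self) -> int:
        return self.W1.shape[0]

    @property
    def p(self) -> int:
        return self.W1.shape[1]

    def copy(self) -> "NetworkParams":
        return NetworkParams(self.W1.copy(), self.W2.copy(), self.b.copy())

    def to_json(self, path) -> None:
        """Plain-text checkpoint with shapes and values."""
        obj = {
            "h": self.h,
            "p": self.p,
            "W1": self.W1.tolist(),
            "W2": self.W2.tolist(),
            "b": self.b.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "NetworkParams":
        with open(path) as fh:
            obj = json.load(fh)
        params = cls(np.array(obj["W1"]), np.array(obj["W2"]), np.array(obj["b"]))
        if params.h != obj["h"] or params.p != obj["p"]:
            raise ValueError("checkpoint shape metadata does not match values")
        return params


@dataclass
class GradientSet:
    """Gradients of the log partial likelihood w.r.t. W1, W2, b.

    Sign convention: adding alpha * dW increases the likelihood
    (ascent direction, i.e. the negative gradient of the loss).
    """

    dW1: np.ndarray
    dW2: np.ndarray
    db: np.ndarray


def hidden_activations(params: NetworkParams, Z: np.ndarray) -> np.ndarray:
    """tanh(W1 z_i + b) for every sample; shape (N, h)."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[1] != params.p:
        raise ValueError(
            f"covariate matrix has {Z.shape[1]} columns, network expects {params.p}"
        )
    return np.tanh(Z @ params.W1.T + params.b)


def forward(params: NetworkParams, data: SurvivalDataset | np.ndarray) -> np.ndarray:
    """Risk scores theta_i = W2' tanh(W1 z_i + b)."""
    Z = data.Z if isinstance(data, SurvivalDataset) else data
    return hidden_activations(params, Z) @ params.W2


def backward(
    params: NetworkParams,
    data: SurvivalDataset,
    plik: CoxPartialLikelihood | None = None,
) -> GradientSet:
    """Exact gradient of the log partial likelihood w.r.t. all weights.

    Chain rule through tanh (derivative 1 - tanh^2) composed with the
    score-level gradient of the partial likelihood.  ``plik`` may carry a
    precomputed sort of the dataset, reused across fitting iterations.
    """
    if plik is None:
        plik = CoxPartialLikelihood(data)
    A = hidden_activations(params, data.Z)  # (N, h)
    theta = A @ params.W2
    g = plik.gradient(theta)  # (N,) d l / d theta
    dW2 = A.T @ g
    dH = (g[:, None] * params.W2[None, :]) * (1.0 - A * A)  # (N, h)
    dW1 = dH.T @ data.Z
    db = dH.sum(axis=0)
    return GradientSet(dW1=dW1, dW2=dW2, db=db)
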