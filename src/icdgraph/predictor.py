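"""Attention + MLP prediction head and the sharpening transform.

Each propagated feature matrix is pushed through two concurrent branches:

* an attention branch — single-head additive (GAT-style) attention with a
  masked softmax over graph neighbors (self included), producing
  neighbor-weighted value features that are projected to class logits;
* an MLP branch — a 2-layer perceptron applied to each node independently.

Branch logits are summed and activated with a row softmax (single-label
mode) or per-label sigmoid (multi-label mode, suited to diagnostic coding
where a node carries several codes).  Dropout (default 0.5) is applied to
the input and hidden layer during training only.

The forward/backward passes are written directly in numpy; gradients are
exact (checked against finite differences in the test-suite).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .graph import Graph, ValidationError

__all__ = ["AttMLPPredictor", "sharpen", "sharpen_bernoulli"]

_LEAK = 0.2  # LeakyReLU slope on raw attention scores


def _softmax_rows(E: np.ndarray) -> np.ndarray:
    E = E - E.max(axis=1, keepdims=True)
    P = np.exp(E)
    return P / P.sum(axis=1, keepdims=True)


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class AttMLPPredictor:
    """Dual attention/MLP head mapping (n, d) features to (n, C) probabilities.

    Parameters
    ----------
    n_features, n_labels : input and output widths.
    hidden : hidden width of both branches (default 128).
    mode : ``"softmax"`` for single-label rows, ``"sigmoid"`` for multi-label.
    dropout : drop probability on input and hidden activations in training.
    use_attention : disable the attention branch (plain MLP head), used by
        the domain-adaptation pipeline where features are pre-propagated.
    """

    def __init__(
        self,
        n_features: int,
        n_labels: int,
        hidden: int = 128,
        mode: str = "sigmoid",
        dropout: float = 0.5,
        use_attention: bool = True,
        seed: int = 0,
    ):
        if mode not in ("softmax", "sigmoid"):
            raise ValidationError(f"mode must be 'softmax' or 'sigmoid', got {mode!r}")
        self.n_features = n_features
        self.n_labels = n_labels
        self.hidden = hidden
        self.mode = mode
        self.dropout = float(dropout)
        self.use_attention = use_attention
        rng = np.random.default_rng(seed)
        d, h, C = n_features, hidden, n_labels
        self.params: dict[str, np.ndarray] = {
            "wq": _xavier(rng, d, 1, (d,)),
            "wk": _xavier(rng, d, 1, (d,)),
            "Wv": _xavier(rng, d, h, (d, h)),
            "Wo": _xavier(rng, h, C, (h, C)),
            "W1": _xavier(rng, d, h, (d, h)),
            "b1": np.zeros(h),
            "W2": _xavier(rng, h, C, (h, C)),
            "b2": np.zeros(C),
        }

    # -- neighborhood mask --------------------------------------------
    @staticmethod
    def neighbor_mask(graph: Graph) -> np.ndarray:
        """Boolean (n, n) mask of graph neighbors including self."""
        A = graph.adjacency.toarray() if sp.issparse(graph.adjacency) else graph.adjacency
        return (np.asarray(A) > 0) | np.eye(A.shape[0], dtype=bool)

    # -- forward -------------------------------------------------------
    def forward(
        self,
        X_bar: np.ndarray,
        mask: np.ndarray | None = None,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ):
        """Return (Z, cache); Z is (n, C) probabilities."""
        p = self.params
        X = np.asarray(X_bar, dtype=float)
        if X.shape[1] != self.n_features:
            raise ValidationError(
                f"expected {self.n_features} features, got {X.shape[1]}"
            )
        cache: dict = {"train": train}

        if train and self.dropout > 0:
            if rng is None:
                rng = np.random.default_rng(0)
            m_in = (rng.random(X.shape) >= self.dropout) / (1 - self.dropout)
        else:
            m_in = None
        Xin = X * m_in if m_in is not None else X
        cache["Xin"], cache["m_in"] = Xin, m_in

        # MLP branch
        H1pre = Xin @ p["W1"] + p["b1"]
        H1 = np.maximum(H1pre, 0.0)
        if train and self.dropout > 0:
            m_h = (rng.random(H1.shape) >= self.dropout) / (1 - self.dropout)
        else:
            m_h = None
        H1d = H1 * m_h if m_h is not None else H1
        logits = H1d @ p["W2"] + p["b2"]
        cache.update(H1pre=H1pre, H1d=H1d, m_h=m_h)

        # attention branch
        if self.use_attention:
            if mask is None:
                raise ValidationError("attention branch requires a neighbor mask")
            q = Xin @ p["wq"]
            k = Xin @ p["wk"]
            Eraw = q[:, None] + k[None, :]
            E = np.where(Eraw > 0, Eraw, _LEAK * Eraw)
            E = np.where(mask, E, -np.inf)
            Al = _softmax_rows(E)
            V = Xin @ p["Wv"]
            Hatt = Al @ V
            logits = logits + Hatt @ p["Wo"]
            cache.update(Eraw=Eraw, mask=mask, Al=Al, V=V, Hatt=Hatt)

        if self.mode == "softmax":
            Z = _softmax_rows(logits)
        else:
            Z = 1.0 / (1.0 + np.exp(-logits))
        cache["logits"], cache["Z"] = logits, Z
        return Z, cache

    # -- backward ------------------------------------------------------
    def backward(self, dlogits: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        """Parameter gradients given dLoss/dlogits."""
        p = self.params
        Xin = cache["Xin"]
        g = {k: np.zeros_like(v) for k, v in p.items()}

        # MLP branch
        g["W2"] = cache["H1d"].T @ dlogits
        g["b2"] = dlogits.sum(axis=0)
        dH1d = dlogits @ p["W2"].T
        if cache["m_h"] is not None:
            dH1d = dH1d * cache["m_h"]
        dH1pre = dH1d * (cache["H1pre"] > 0)
        g["W1"] = Xin.T @ dH1pre
        g["b1"] = dH1pre.sum(axis=0)

        if self.use_attention:
            Al, V = cache["Al"], cache["V"]
            g["Wo"] = cache["Hatt"].T @ dlogits
            dHatt = dlogits @ p["Wo"].T
            dAl = dHatt @ V.T
            dV = Al.T @ dHatt
            g["Wv"] = Xin.T @ dV
            # masked-softmax backward, rows
            dE = Al * (dAl - (dAl * Al).sum(axis=1, keepdims=True))
            dE = np.where(cache["mask"], dE, 0.0)
            dEraw = dE * np.where(cache["Eraw"] > 0, 1.0, _LEAK)
            dq = dEraw.sum(axis=1)
            dk = dEraw.sum(axis=0)
            g["wq"] = Xin.T @ dq
            g["wk"] = Xin.T @ dk
        return g

    def dlogits_from_dZ(self, dZ: np.ndarray, cache: dict) -> np.ndarray:
        """Chain dLoss/dZ through the output activation."""
        Z = cache["Z"]
        if self.mode == "softmax":
            return Z * (dZ - (dZ * Z).sum(axis=1, keepdims=True))
        return dZ * Z * (1.0 - Z)

    # -- persistence ---------------------------------------------------
    def save(self, path) -> None:
        np.savez(
            path,
            __meta__=np.array(
                [self.n_features, self.n_labels, self.hidden,
                 1 if self.mode == "sigmoid" else 0,
                 1 if self.use_attention else 0],
            ),
            __dropout__=np.array([self.dropout]),
            **self.params,
        )

    @classmethod
    def load(cls, path) -> "AttMLPPredictor":
        data = np.load(path)
        d, C, h, sig, att = (int(v) for v in data["__meta__"])
        obj = cls(
            d, C, hidden=h,
            mode="sigmoid" if sig else "softmax",
            dropout=float(data["__dropout__"][0]),
            use_attention=bool(att),
        )
        for k in obj.params:
            obj.params[k] = data[k]
        return obj

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}


def sharpen(Z: np.ndarray, T: float) -> np.ndarray:
    """Temperature sharpening of probability rows: Z_ij^(1/T), renormalized.

    T=1 is the identity; T -> 0 approaches a one-hot argmax.
    """
    if T <= 0:
        raise ValidationError(f"temperature must be positive, got {T}")
    Z = np.asarray(Z, dtype=float)
    if np.any(Z < 0):
        raise ValidationError("sharpen requires non-negative probabilities")
    rowsum = Z.sum(axis=1)
    if np.any(rowsum == 0):
        raise ValidationError("sharpen received a row of all zeros")
    # work in log-space for numerical stability at small T
    with np.errstate(divide="ignore"):
        logZ = np.where(Z > 0, np.log(np.maximum(Z, 1e-300)), -np.inf)
    P = logZ / T
    P = P - P.max(axis=1, keepdims=True)
    out = np.exp(P)
    out[np.isneginf(P)] = 0.0
    return out / out.sum(axis=1, keepdims=True)


def sharpen_bernoulli(P: np.ndarray, T: float) -> np.ndarray:
    """Sharpen each sigmoid probability via its Bernoulli pair (p, 1-p)."""
    if T <= 0:
        raise ValidationError(f"temperature must be positive, got {T}")
    P = np.asarray(P, dtype=float)
    a = P ** (1.0 / T)
    b = (1.0 - P) ** (1.0 / T)
    return a / (a + b)
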