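"""Stochastic feature perturbation and random propagation.

Two perturbation modes are provided.  *DropNode* zeroes entire node feature
rows with probability ``delta`` and rescales survivors by ``1/(1-delta)`` so
the perturbed matrix is unbiased for the original (E[X_tilde] = X); it
leaves graph topology untouched, which distinguishes it from edge-dropping
schemes.  *Dropout* applies the same Bernoulli mask-and-rescale per element.

The module also carries the closed-form variance oracles for the propagated
one-column output ``A_bar @ X_tilde @ W`` in the binary single-layer
setting, used to verify that random propagation acts as a graph- and
uncertainty-weighted regularizer:

* DropNode (row mask):  Var_i = d/(1-d) * sum_j (x_j . W)^2 * A_bar_ij^2
* dropout (element mask): Var_i = d/(1-d) * sum_j A_bar_ij^2 * sum_f (X_jf W_f)^2

and the corresponding consistency-regularization functional
``R_DN = d/(1-d) * sum_i sum_j (x_j . W)^2 z_i^2 (1-z_i)^2 A_bar_ij^2``,
which vanishes for confident predictions (z in {0,1}) and peaks at z=0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import Graph, PropagationOperator, ValidationError

__all__ = [
    "AugmentedBatch",
    "dropnode",
    "dropout_elements",
    "random_propagate",
    "analytic_variance_dropnode",
    "analytic_variance_dropout",
    "regularizer_dropnode",
]

MODES = ("dropnode", "dropout", "none")


def _check_delta(delta: float) -> float:
    if not 0.0 <= delta < 1.0:
        raise ValidationError(f"delta must lie in [0, 1), got {delta}")
    return float(delta)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def dropnode(X: np.ndarray, delta: float, seed) -> np.ndarray:
    """Zero entire rows w.p. ``delta``; scale survivors by ``1/(1-delta)``.

    At inference callers pass ``delta=0`` so features are unchanged.
    """
    delta = _check_delta(delta)
    X = np.asarray(X, dtype=float)
    if delta == 0.0:
        return X.copy()
    rng = _rng(seed)
    keep = rng.random(X.shape[0]) >= delta
    return X * (keep[:, None] / (1.0 - delta))


def dropout_elements(X: np.ndarray, delta: float, seed) -> np.ndarray:
    """Per-element Bernoulli(1-delta) mask with ``1/(1-delta)`` rescaling."""
    delta = _check_delta(delta)
    X = np.asarray(X, dtype=float)
    if delta == 0.0:
        return X.copy()
    rng = _rng(seed)
    keep = rng.random(X.shape) >= delta
    return X * (keep / (1.0 - delta))


@dataclass
class AugmentedBatch:
    """S perturbed-and-propagated views of one feature matrix."""

    S: int
    delta: float
    mode: str
    seed: int
    X_tilde_list: list = field(default_factory=list)
    X_bar_list: list = field(default_factory=list)


def random_propagate(
    graph: Graph,
    op: PropagationOperator,
    S: int,
    delta: float,
    mode: str = "dropnode",
    seed: int = 0,
) -> AugmentedBatch:
    """Draw S independent perturbations of X and propagate each with A_bar.

    Augmentations use independent child streams spawned from one root seed,
    so a batch is bit-reproducible and its members mutually independent.
    """
    if S < 1:
        raise ValidationError(f"S must be >= 1, got {S}")
    if mode not in MODES:
        raise ValidationError(f"mode must be one of {MODES}, got {mode!r}")
    X = graph.features
    if X.shape[0] != op.n:
        raise ValidationError(
            f"feature rows ({X.shape[0]}) do not match operator size ({op.n})"
        )
    batch = AugmentedBatch(S=S, delta=float(delta), mode=mode, seed=int(seed))
    streams = np.random.SeedSequence(seed).spawn(S)
    for s in range(S):
        rng = np.random.default_rng(streams[s])
        if mode == "dropnode":
            Xt = dropnode(X, delta, rng)
        elif mode == "dropout":
            Xt = dropout_elements(X, delta, rng)
        else:
            Xt = X.copy()
        batch.X_tilde_list.append(Xt)
        batch.X_bar_list.append(op.apply_bar(Xt))
    return batch


def _bar_dense(op: PropagationOperator) -> np.ndarray:
    if op.A_bar is not None:
        return op.A_bar
    return op.apply_bar(np.eye(op.n))


def analytic_variance_dropnode(
    op: PropagationOperator, X: np.ndarray, W: np.ndarray, delta: float
) -> np.ndarray:
    """Per-node variance of (A_bar X_tilde W)_i under row masking."""
    delta = _check_delta(delta)
    X = np.asarray(X, dtype=float)
    W = np.asarray(W, dtype=float).ravel()
    xw2 = (X @ W) ** 2  # (n,)
    Ab2 = _bar_dense(op) ** 2
    return (delta / (1.0 - delta)) * (Ab2 @ xw2)


def analytic_variance_dropout(
    op: PropagationOperator, X: np.ndarray, W: np.ndarray, delta: float
) -> np.ndarray:
    """Per-node variance of (A_bar X_tilde W)_i under element masking."""
    delta = _check_delta(delta)
    X = np.asarray(X, dtype=float)
    W = np.asarray(W, dtype=float).ravel()
    per_row = ((X * W[None, :]) ** 2).sum(axis=1)  # sum_f (X_jf W_f)^2
    Ab2 = _bar_dense(op) ** 2
    return (delta / (1.0 - delta)) * (Ab2 @ per_row)


def regularizer_dropnode(
    op: PropagationOperator,
    X: np.ndarray,
    W: np.ndarray,
    z: np.ndarray,
    delta: float,
) -> float:
    """Consistency-regularization functional for DropNode perturbation.

    Weighs each node's propagated feature variance by its classification
    uncertainty z_i^2 (1-z_i)^2.
    """
    delta = _check_delta(delta)
    z = np.asarray(z, dtype=float).ravel()
    if np.any(z < 0) or np.any(z > 1):
        raise ValidationError("z entries must lie in [0, 1]")
    var = analytic_variance_dropnode(op, X, W, delta)
    return float(np.sum(z**2 * (1.0 - z) ** 2 * var))
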