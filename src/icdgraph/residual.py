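"""Residual propagation with closed-form fixed point, and depth-adaptive layers.

The residual update ``H^{(l+1)} = (1-alpha) A_hat H^{(l)} + alpha H^{(0)}``
mixes propagated features with the initial embedding at every step.  Because
the symmetric normalization keeps the spectral radius of ``A_hat`` at most
1, the map is a contraction with factor (1-alpha) and converges to the
unique fixed point ``H^inf = alpha (I - (1-alpha) A_hat)^{-1} H^{(0)}`` at an
exponential rate — deep propagation without collapsing node representations
onto each other (over-smoothing).

The depth-adaptive variant replaces the constant alpha with a per-layer
coefficient and adds shared/per-layer weight matrices:
``H^{(l)} = (1-alpha_l) A_hat H^{(l-1)} W_1 + alpha_l H^{(0)} W_l``.
The literal coefficient ``log(l/(l+1)) + eps`` is negative for small eps, so
an invalid mixing weight; both the literal (clipped) schedule and a
sign-corrected positive schedule ``eps + log((l+1)/l)`` are provided, the
positive one being the default (monotone decreasing toward eps with depth,
preserving the decreasing-residual-influence intent while staying in (0,1)).
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.sparse as sp

from .graph import PropagationOperator, ValidationError

__all__ = [
    "mmrp_step",
    "mmrp_iterate",
    "mmrp_fixed_point",
    "dmrm_alpha_schedule",
    "dmrm_forward",
    "mean_pairwise_distance",
]

CLIP_LO = 1e-3


def _ahat(A_hat):
    if isinstance(A_hat, PropagationOperator):
        return A_hat.A_hat
    return A_hat


def _check_alpha(alpha: float) -> float:
    if alpha == 1.0:
        warnings.warn("alpha=1 disables propagation (residual-only mode)", stacklevel=3)
        return 1.0
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha must lie in (0, 1), got {alpha}")
    return float(alpha)


def mmrp_step(H_l: np.ndarray, H0: np.ndarray, A_hat, alpha: float) -> np.ndarray:
    """One residual-propagation update."""
    alpha = _check_alpha(alpha)
    A = _ahat(A_hat)
    return (1.0 - alpha) * (A @ H_l) + alpha * H0


def mmrp_iterate(H0: np.ndarray, A_hat, alpha: float, n_steps: int) -> list[np.ndarray]:
    """Iterates [H^(0), H^(1), ..., H^(n_steps)]."""
    H = np.asarray(H0, dtype=float)
    out = [H]
    for _ in range(n_steps):
        H = mmrp_step(H, H0, A_hat, alpha)
        out.append(H)
    return out


def mmrp_fixed_point(H0: np.ndarray, A_hat, alpha: float) -> np.ndarray:
    """Direct solve of H = (1-alpha) A_hat H + alpha H0."""
    alpha = _check_alpha(alpha)
    A = _ahat(A_hat)
    A = A.toarray() if sp.issparse(A) else np.asarray(A, dtype=float)
    n = A.shape[0]
    H0 = np.asarray(H0, dtype=float)
    return alpha * np.linalg.solve(np.eye(n) - (1.0 - alpha) * A, H0)


def dmrm_alpha_schedule(
    l: int, epsilon: float, variant: str = "positive", clip_lo: float = CLIP_LO
) -> float:
    """Layer coefficient alpha_l for the depth-adaptive recurrence.

    ``as_printed``: log(l/(l+1)) + epsilon, clipped into [clip_lo, 1-clip_lo]
    (the unclipped value is negative for small epsilon).
    ``positive``: epsilon + log((l+1)/l), strictly decreasing toward epsilon.
    """
    if l < 1:
        raise ValidationError(f"layer index must be >= 1, got {l}")
    if variant == "as_printed":
        raw = np.log(l / (l + 1.0)) + epsilon
        return float(np.clip(raw, clip_lo, 1.0 - clip_lo))
    if variant == "positive":
        return float(epsilon + np.log((l + 1.0) / l))
    raise ValidationError(f"unknown schedule variant {variant!r}")


def dmrm_forward(
    H0: np.ndarray,
    A_hat,
    W1: np.ndarray | None,
    W_list: list[np.ndarray] | None,
    epsilon: float = 0.01,
    L_depth: int = 1,
    variant: str = "positive",
) -> np.ndarray:
    """Depth-adaptive residual recurrence for ``L_depth`` layers.

    ``W1`` is shared across layers, ``W_list[l-1]`` is the per-layer residual
    weight; both default to identities.  ``L_depth=0`` returns ``H0``.
    """
    H0 = np.asarray(H0, dtype=float)
    if L_depth == 0:
        return H0.copy()
    A = _ahat(A_hat)
    d = H0.shape[1]
    if W1 is None:
        W1 = np.eye(d)
    if W_list is None:
        W_list = [np.eye(d) for _ in range(L_depth)]
    if len(W_list) != L_depth:
        raise ValidationError(
            f"need {L_depth} per-layer weights, got {len(W_list)}"
        )
    H = H0
    for l in range(1, L_depth + 1):
        a_l = dmrm_alpha_schedule(l, epsilon, variant)
        H = (1.0 - a_l) * (A @ H) @ W1 + a_l * H0 @ W_list[l - 1]
    return H


def mean_pairwise_distance(H: np.ndarray) -> float:
    """Mean Euclidean distance between all node pairs (over-smoothing gauge)."""
    H = np.asarray(H, dtype=float)
    sq = (H**2).sum(axis=1)
    D2 = sq[:, None] + sq[None, :] - 2.0 * (H @ H.T)
    np.maximum(D2, 0.0, out=D2)
    n = H.shape[0]
    iu = np.triu_indices(n, k=1)
    return float(np.sqrt(D2[iu]).mean())
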