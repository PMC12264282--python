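"""Consistency-regularized semi-supervised training.

The objective is ``L = L_sup + lambda * L_con``:

* ``L_sup`` — cross-entropy of each of the S augmented predictions against
  the labeled nodes, averaged over augmentations.  In single-label
  (softmax) mode this is the printed form -(1/S) sum_s sum_i Y_i^T log Z_i;
  in multi-label (sigmoid) mode each label contributes its Bernoulli pair,
  i.e. full binary cross-entropy per label.
* ``L_con`` — mean squared distance between each augmented prediction and
  the (optionally temperature-sharpened) augmentation mean, summed over
  every node, labeled or not.  The target mean is treated as a constant
  (stop-gradient), a standard stabilization for consistency targets.

Training is full-graph Adam with early stopping on validation micro-F1.
Ablation modes reproduce the study configurations: ``full`` (S stochastic
augmentations + consistency), ``no_cr`` (lambda = 0), ``no_dn`` (a single
shared perturbation per epoch, which silences the consistency term), and
``no_cr_no_dn`` (deterministic propagation, purely supervised).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .graph import Graph, PropagationOperator, ValidationError, build_operator
from .metrics import f1_scores
from .perturb import analytic_variance_dropnode, dropnode
from .predictor import AttMLPPredictor, sharpen, sharpen_bernoulli

__all__ = [
    "TrainConfig",
    "LossReport",
    "Adam",
    "supervised_loss",
    "consistency_loss",
    "train",
    "theoretical_loss_gap",
]

EPS_LOG = 1e-12
ABLATIONS = ("full", "no_cr", "no_dn", "no_cr_no_dn")


@dataclass
class TrainConfig:
    strategy: str = "M2"
    K: int = 4
    S: int = 2
    delta: float = 0.2
    lam: float = 1.0
    temperature: float = 0.5
    hidden: int = 128
    dropout: float = 0.5
    mode: str = "softmax"  # "softmax" single-label, "sigmoid" multi-label
    lr: float = 1e-3
    weight_decay: float = 0.0
    epochs: int = 100
    patience: int = 10
    seed: int = 0


@dataclass
class LossReport:
    """Per-epoch loss decomposition; L_total = L_sup + lambda * L_con."""

    lam: float
    l_sup: list[float] = field(default_factory=list)
    l_con: list[float] = field(default_factory=list)
    val_f1: list[float] = field(default_factory=list)
    best_epoch: int = -1

    @property
    def l_total(self) -> list[float]:
        return [s + self.lam * c for s, c in zip(self.l_sup, self.l_con)]


class Adam:
    """Adam over a dict of named parameter arrays."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.lr, self.eps, self.weight_decay = lr, eps, weight_decay
        self.b1, self.b2 = betas
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads) -> None:
        self.t += 1
        for k in params:
            g = grads[k]
            if self.weight_decay:
                g = g + self.weight_decay * params[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def supervised_loss(Y, Z_list, train_mask, mode: str = "softmax") -> float:
    """-(1/S) sum_s sum_{i in train} Y_i^T log Z_i^(s) (Bernoulli-pair
    expansion per label in sigmoid mode)."""
    train_mask = np.asarray(train_mask, dtype=int)
    if train_mask.size == 0:
        raise ValidationError("supervised loss needs a non-empty train mask")
    Y = np.asarray(Y, dtype=float)[train_mask]
    total = 0.0
    for Z in Z_list:
        Zt = np.clip(np.asarray(Z, dtype=float)[train_mask], EPS_LOG, 1.0)
        if mode == "softmax":
            total += -np.sum(Y * np.log(Zt))
        else:
            Zt = np.clip(Zt, EPS_LOG, 1.0 - EPS_LOG)
            total += -np.sum(Y * np.log(Zt) + (1.0 - Y) * np.log(1.0 - Zt))
    return float(total / len(Z_list))


def consistency_loss(Z_list, target=None) -> float:
    """(1/S) sum_s sum_i ||target_i - Z_i^(s)||^2, target = augmentation mean
    unless supplied (e.g. the sharpened mean)."""
    Zs = [np.asarray(Z, dtype=float) for Z in Z_list]
    if target is None:
        target = np.mean(Zs, axis=0)
    return float(np.mean([np.sum((target - Z) ** 2) for Z in Zs]))


def _val_score(predictor, op, graph, mask_nodes, mode) -> float:
    Z, _ = predictor.forward(op.apply_bar(graph.features),
                             mask=predictor.neighbor_mask(graph), train=False)
    Zv, Yv = Z[mask_nodes], graph.labels[mask_nodes]
    if mode == "softmax":
        pred = np.zeros_like(Yv)
        pred[np.arange(len(Zv)), Zv.argmax(axis=1)] = 1
    else:
        pred = (Zv >= 0.5).astype(int)
    return f1_scores(pred, Yv)[1]


def train(
    graph: Graph,
    config: TrainConfig,
    op: PropagationOperator | None = None,
    ablation: str = "full",
    predictor: AttMLPPredictor | None = None,
):
    """Train the attention+MLP head under the chosen ablation.

    Returns ``(predictor, LossReport)`` with the best-validation parameters
    restored.  Deterministic given ``config.seed``.
    """
    if ablation not in ABLATIONS:
        raise ValidationError(f"unknown ablation {ablation!r}; expected {ABLATIONS}")
    cfg = config
    if ablation in ("no_cr", "no_cr_no_dn"):
        cfg = replace(cfg, lam=0.0)
    if op is None:
        op = build_operator(graph, cfg.strategy, cfg.K)
    if predictor is None:
        predictor = AttMLPPredictor(
            graph.n_features, graph.n_labels, hidden=cfg.hidden,
            mode=cfg.mode, dropout=cfg.dropout, seed=cfg.seed,
        )
    nbr_mask = predictor.neighbor_mask(graph)
    opt = Adam(predictor.params, lr=cfg.lr, weight_decay=cfg.weight_decay)
    report = LossReport(lam=cfg.lam)
    train_idx = graph.train_mask
    if train_idx.size == 0:
        raise ValidationError("training requires a non-empty train mask")
    X, Y = graph.features, graph.labels.astype(float)
    best_val, best_params, patience_left = -np.inf, predictor.copy_params(), cfg.patience

    for epoch in range(cfg.epochs):
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, epoch)))
        # build augmentations per the ablation mode
        if ablation == "no_cr_no_dn":
            X_bars = [op.apply_bar(X)]
        elif ablation == "no_dn":
            Xt = dropnode(X, cfg.delta, rng)
            X_bars = [op.apply_bar(Xt)] * cfg.S
        else:
            X_bars = [op.apply_bar(dropnode(X, cfg.delta, rng)) for _ in range(cfg.S)]
        S = len(X_bars)

        Zs, caches = [], []
        for Xb in X_bars:
            Z, cache = predictor.forward(Xb, mask=nbr_mask, train=True, rng=rng)
            Zs.append(Z)
            caches.append(cache)

        # consistency target: sharpened augmentation mean, stop-gradient
        Zbar = np.mean(Zs, axis=0)
        if cfg.mode == "softmax":
            target = sharpen(Zbar, cfg.temperature)
        else:
            target = sharpen_bernoulli(Zbar, cfg.temperature)

        l_sup = supervised_loss(Y, Zs, train_idx, cfg.mode)
        l_con = consistency_loss(Zs, target)
        if not np.isfinite(l_sup + l_con):
            raise RuntimeError(
                f"non-finite loss at epoch {epoch}: L_sup={l_sup}, L_con={l_con}"
            )

        # Gradients are normalized per labeled node (supervised term) and per
        # node (consistency term) so the trade-off weight is independent of
        # graph size and labeled fraction; the reported losses keep the
        # plain-sum form.
        m, n = train_idx.size, X.shape[0]
        grads = {k: np.zeros_like(v) for k, v in predictor.params.items()}
        for Z, cache in zip(Zs, caches):
            dlogits = np.zeros_like(Z)
            # supervised term: d/dlogits of CE is (Z - Y) on labeled rows
            dlogits[train_idx] = (Z[train_idx] - Y[train_idx]) / (S * m)
            if cfg.lam > 0:
                dZ = cfg.lam * 2.0 * (Z - target) / (S * n)
                dlogits = dlogits + predictor.dlogits_from_dZ(dZ, cache)
            gs = predictor.backward(dlogits, cache)
            for k in grads:
                grads[k] += gs[k]
        opt.step(predictor.params, grads)

        val = _val_score(predictor, op, graph, graph.val_mask, cfg.mode) \
            if graph.val_mask.size else -l_sup
        report.l_sup.append(l_sup)
        report.l_con.append(l_con)
        report.val_f1.append(val)
        if val > best_val:
            best_val, best_params = val, predictor.copy_params()
            report.best_epoch = epoch
            patience_left = cfg.patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break
    predictor.params = best_params
    return predictor, report


def theoretical_loss_gap(
    op: PropagationOperator,
    X: np.ndarray,
    W: np.ndarray,
    y: np.ndarray,
    delta: float,
    n_draws: int = 50_000,
    seed: int = 0,
):
    """Perturbed-loss expectation vs its quadratic approximation.

    Binary single-layer setting: z = sigmoid(A_bar X W).  Returns
    ``(mc_mean, approx)`` where ``mc_mean`` is the Monte-Carlo expectation of
    the DropNode-perturbed cross-entropy and
    ``approx = L_orig + (1/2) sum_i z_i (1 - z_i) Var_i`` with the
    closed-form DropNode variance.
    """
    X = np.asarray(X, dtype=float)
    W = np.asarray(W, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    A_bar = op.A_bar if op.A_bar is not None else op.apply_bar(np.eye(op.n))
    a = A_bar @ (X @ W)
    z = 1.0 / (1.0 + np.exp(-a))
    L_orig = float(np.sum(-y * np.log(np.clip(z, EPS_LOG, 1)) -
                          (1 - y) * np.log(np.clip(1 - z, EPS_LOG, 1))))
    var = analytic_variance_dropnode(op, X, W, delta)
    approx = L_orig + 0.5 * float(np.sum(z * (1.0 - z) * var))

    rng = np.random.default_rng(seed)
    xw = X @ W  # (n,)
    if delta == 0.0:
        return L_orig, approx
    keep = rng.random((n_draws, X.shape[0])) >= delta  # (draws, n)
    a_tilde = (keep * xw[None, :] / (1.0 - delta)) @ A_bar.T
    # stable BCE in the logit: -y*a + log(1 + e^a)
    L_draws = np.sum(np.logaddexp(0.0, a_tilde) - y[None, :] * a_tilde, axis=1)
    return float(L_draws.mean()), approx
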