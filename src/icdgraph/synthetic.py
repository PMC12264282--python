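"""Synthetic ICD-like benchmark generators.

Produces every input the framework consumes, emulating the structure of
clinical diagnostic-coding graphs without any clinical text:

* a rooted label taxonomy whose pairwise co-occurrence probability decays
  with tree distance (labels near each other in the hierarchy co-occur);
* a homophilous multi-label graph: node label sets sampled from the
  taxonomy co-occurrence, edges drawn with probability increasing in
  label-set overlap (strength ``h``), Gaussian label-keyed features (or an
  optional Poisson count mode resembling bag-of-words), and sparse
  train/val/test masks;
* a domain-shifted twin (feature mean shift, variance rescale, partial edge
  rewiring) for adaptation experiments;
* a random-edge adversarial attack that adds fake edges among non-edges.

Everything is fully determined by the config seed; regeneration is
byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import scipy.sparse as sp

from .graph import Graph, ValidationError

__all__ = [
    "SynthConfig",
    "generate_taxonomy",
    "generate_multilabel_graph",
    "domain_shift",
    "random_edge_attack",
]

COOC_DECAY = 0.5  # co-occurrence probability per unit of tree distance
HOMOPHILY_BOOST = 9.0  # edge-weight multiplier for label-sharing pairs


@dataclass
class SynthConfig:
    """Study conditions for the packaged benchmark.

    Defaults give the standard benchmark: 500 nodes, 20 labels in a depth-3
    taxonomy, 64 Gaussian features, homophily 0.8, 10% labeled.
    """

    n_nodes: int = 500
    n_labels: int = 20
    taxonomy_depth: int = 3
    labels_per_node: float = 3.0
    homophily: float = 0.8
    n_features: int = 64
    feature_noise: float = 1.0
    labeled_fraction: float = 0.1
    val_fraction: float = 0.15
    avg_degree: float = 10.0
    feature_mode: str = "gaussian"  # or "counts" (Poisson bag-of-words-like)
    # child prototypes inherit the parent prototype plus a deviation of this
    # relative scale, so taxonomy-adjacent labels have similar feature
    # profiles (nearby diagnostic codes describe similar conditions).
    # proto_decay = 0 draws independent prototypes instead — flat class
    # semantics as in citation-network topic labels.
    proto_decay: float = 0.6
    shift_mean: float = 0.0
    shift_var_scale: float = 1.0
    shift_edge_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("homophily", "labeled_fraction", "val_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.labeled_fraction == 0:
            raise ValidationError("labeled_fraction must be positive")
        if self.labels_per_node < 1:
            raise ValidationError("labels_per_node must be >= 1")
        if self.feature_mode not in ("gaussian", "counts"):
            raise ValidationError(f"unknown feature_mode {self.feature_mode!r}")

    def as_dict(self) -> dict:
        return asdict(self)


def generate_taxonomy(C: int, depth: int, seed: int = 0):
    """Random rooted label tree plus its co-occurrence matrix.

    Returns ``(parent, cooc)`` where ``parent[i]`` is the parent label of i
    (-1 for the root) and ``cooc[i, j] = COOC_DECAY ** tree_distance(i, j)``
    with a unit diagonal — co-occurrence decays with taxonomy distance.
    """
    if C < 2:
        raise ValidationError(f"need at least 2 labels, got {C}")
    if depth < 1 or depth > int(np.log2(C)) + 2:
        raise ValidationError(
            f"taxonomy depth must lie in [1, log2(C)+2], got {depth}"
        )
    rng = np.random.default_rng(seed)
    parent = np.full(C, -1, dtype=int)
    node_depth = np.zeros(C, dtype=int)
    for i in range(1, C):
        candidates = np.flatnonzero(node_depth[:i] < depth)
        p = int(rng.choice(candidates))
        parent[i] = p
        node_depth[i] = node_depth[p] + 1
    # all-pairs tree distance by BFS from each label
    adj = [[] for _ in range(C)]
    for i in range(1, C):
        adj[i].append(parent[i])
        adj[parent[i]].append(i)
    dist = np.full((C, C), -1, dtype=int)
    for s in range(C):
        dist[s, s] = 0
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if dist[s, v] < 0:
                        dist[s, v] = dist[s, u] + 1
                        nxt.append(v)
            frontier = nxt
    cooc = COOC_DECAY ** dist.astype(float)
    np.fill_diagonal(cooc, 1.0)
    return parent, cooc


def _sample_labels(rng, C, cooc, n, mean_labels):
    Y = np.zeros((n, C), dtype=int)
    primary = rng.integers(0, C, size=n)
    Y[np.arange(n), primary] = 1
    if mean_labels > 1:
        extra_mean = mean_labels - 1.0
        for i in range(n):
            k = min(rng.poisson(extra_mean), C - 1)
            if k == 0:
                continue
            w = cooc[primary[i]].copy()
            w[primary[i]] = 0.0
            w = w / w.sum()
            extras = rng.choice(C, size=k, replace=False, p=w)
            Y[i, extras] = 1
    return Y


def _weighted_sample_pairs(rng, weights, m):
    """Exact weighted sampling of m items without replacement (Gumbel top-k)."""
    keys = np.where(weights > 0, np.log(np.maximum(weights, 1e-300)), -np.inf)
    keys = keys + rng.gumbel(size=weights.shape)
    if np.isfinite(keys).sum() < m:
        raise ValidationError("not enough admissible node pairs for requested edges")
    return np.argpartition(-keys, m - 1)[:m]


def generate_multilabel_graph(config: SynthConfig) -> Graph:
    """Homophilous multi-label graph with planted taxonomy structure."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, C, d = config.n_nodes, config.n_labels, config.n_features
    parent, cooc = generate_taxonomy(C, config.taxonomy_depth, config.seed)
    Y = _sample_labels(rng, C, cooc, n, config.labels_per_node)

    # edges: weight (1-h) for any pair plus an h-scaled boost for label
    # overlap.  HOMOPHILY_BOOST sets how strongly h translates into
    # same-label edges; the default makes h=0.8 yield roughly the 0.8
    # same-label edge fraction typical of citation networks.
    iu, ju = np.triu_indices(n, k=1)
    overlap = (Y[iu] & Y[ju]).sum(axis=1)
    h = config.homophily
    boost = HOMOPHILY_BOOST * np.where(overlap > 0, 1.0 + 0.25 * (overlap - 1), 0.0)
    w = (1.0 - h) + h * boost
    m = int(round(n * config.avg_degree / 2))
    chosen = _weighted_sample_pairs(rng, w, m)
    rows = np.concatenate([iu[chosen], ju[chosen]])
    cols = np.concatenate([ju[chosen], iu[chosen]])
    A = sp.csr_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))

    # features: mean of the node's label prototypes + Gaussian noise.
    # With proto_decay > 0 prototypes are sampled by a walk down the
    # taxonomy so related labels share feature structure (labels are
    # ordered with parent[i] < i); proto_decay = 0 gives independent
    # prototypes.
    prototypes = np.zeros((C, d))
    for c_idx in range(C):
        if parent[c_idx] < 0 or config.proto_decay == 0:
            prototypes[c_idx] = rng.normal(0.0, 2.0, size=d)
        else:
            prototypes[c_idx] = prototypes[parent[c_idx]] + rng.normal(
                0.0, 2.0 * config.proto_decay, size=d
            )
    counts = Y.sum(axis=1, keepdims=True)
    mean_profile = (Y @ prototypes) / counts
    if config.feature_mode == "gaussian":
        X = mean_profile + config.feature_noise * rng.normal(size=(n, d))
    else:
        lam = np.log1p(np.exp(mean_profile))
        X = rng.poisson(lam).astype(float)

    order = rng.permutation(n)
    n_train = int(round(config.labeled_fraction * n))
    n_val = int(round(config.val_fraction * n))
    train = np.sort(order[:n_train])
    val = np.sort(order[n_train : n_train + n_val])
    test = np.sort(order[n_train + n_val :])
    return Graph(
        adjacency=A, features=X, labels=Y,
        train_mask=train, val_mask=val, test_mask=test,
    )


def domain_shift(
    graph: Graph,
    mean_shift=0.0,
    var_scale: float = 1.0,
    edge_rewire_rate: float = 0.0,
    seed: int = 0,
) -> Graph:
    """Domain-shifted twin: feature shift/rescale plus partial edge rewiring.

    Exactly ``round(edge_rewire_rate * |E|)`` edges are removed and the same
    number of fresh non-edges added; labels and masks are preserved.
    """
    rng = np.random.default_rng(seed)
    g = graph.copy()
    g.features = g.features * var_scale + np.asarray(mean_shift)
    if edge_rewire_rate > 0:
        edges = sorted(g.edge_set())
        k = int(round(edge_rewire_rate * len(edges)))
        if k > 0:
            drop_idx = rng.choice(len(edges), size=k, replace=False)
            dropped = {edges[i] for i in drop_idx}
            kept = [e for e in edges if e not in dropped]
            new_edges = _draw_non_edges(rng, g.n_nodes, set(edges), k)
            all_edges = kept + new_edges
            rows = np.array([e[0] for e in all_edges] + [e[1] for e in all_edges])
            cols = np.array([e[1] for e in all_edges] + [e[0] for e in all_edges])
            g.adjacency = sp.csr_matrix(
                (np.ones(rows.size), (rows, cols)), shape=(g.n_nodes, g.n_nodes)
            )
    return Graph(
        adjacency=g.adjacency, features=g.features, labels=g.labels,
        train_mask=g.train_mask, val_mask=g.val_mask, test_mask=g.test_mask,
    )


def _draw_non_edges(rng, n, forbidden: set, k: int) -> list[tuple[int, int]]:
    max_edges = n * (n - 1) // 2
    if max_edges - len(forbidden) < k:
        raise ValidationError("not enough non-edges available")
    out: list[tuple[int, int]] = []
    seen = set(forbidden)
    while len(out) < k:
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        e = (int(min(i, j)), int(max(i, j)))
        if e in seen:
            continue
        seen.add(e)
        out.append(e)
    return out


def random_edge_attack(graph: Graph, rate: float, seed: int = 0) -> Graph:
    """Adversarial perturbation adding ``round(rate * |E|)`` fake edges.

    New edges are drawn uniformly among current non-edges; original edges
    are untouched.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValidationError(f"attack rate must lie in [0, 1], got {rate}")
    rng = np.random.default_rng(seed)
    g = graph.copy()
    edges = g.edge_set()
    k = int(round(rate * len(edges)))
    if k == 0:
        return g
    new_edges = _draw_non_edges(rng, g.n_nodes, edges, k)
    all_edges = sorted(edges) + new_edges
    rows = np.array([e[0] for e in all_edges] + [e[1] for e in all_edges])
    cols = np.array([e[1] for e in all_edges] + [e[0] for e in all_edges])
    A = sp.csr_matrix((np.ones(rows.size), (rows, cols)), shape=(g.n_nodes, g.n_nodes))
    return Graph(
        adjacency=A, features=g.features, labels=g.labels,
        train_mask=g.train_mask, val_mask=g.val_mask, test_mask=g.test_mask,
    )
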