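# icdgraph

Robust semi-supervised multi-label node classification on sparse graphs,
built for the structure of clinical diagnostic (ICD) coding: a few labeled
nodes, a hierarchical label vocabulary with strong co-occurrence structure,
noisy graph topology, and distribution shift between institutions.

The library combines five pieces:

1. **Mixed-order stochastic propagation.** Features are perturbed by
   *DropNode* (whole node rows zeroed with probability δ and survivors
   rescaled by 1/(1−δ), so E[X̃] = X) and propagated with the mixed-order
   operator Ā = (1/(K+1)) Σₖ Âᵏ, where Â = (D+I)^{−1/2}(A+I)(D+I)^{−1/2}.
   The spectral radius of Â is provably ≤ 1, so deep propagation is stable.
2. **Attention + MLP prediction head** over the propagated features, with a
   masked softmax over graph neighbors — written in plain numpy with exact
   hand-derived gradients (verified against finite differences).
3. **Consistency-regularized training.** S augmented predictions are fit to
   the labels (L_sup) and pulled toward their sharpened mean (L_con);
   the objective is L = L_sup + λ·L_con. In closed form, this penalizes
   R_DN = δ/(1−δ) Σᵢⱼ (xⱼᵀW)² zᵢ²(1−zᵢ)² Āᵢⱼ² — prediction variance weighted
   by classification uncertainty and multi-hop topology.
4. **Residual embeddings.** H^(l+1) = (1−α)ÂH^(l) + αH^(0) contracts at rate
   (1−α) to the closed-form fixed point α(I−(1−α)Â)^{−1}H^(0), resisting
   over-smoothing; a depth-adaptive variant uses per-layer coefficients.
5. **Label-graph generation and domain adaptation.** A REINFORCE-trained
   Bernoulli policy builds a label dependency graph edge-by-edge with a
   downstream-performance reward, and a Wasserstein-1 critic with gradient
   penalty adversarially aligns source/target feature distributions.

Everything runs on synthetic ICD-like benchmarks produced by the built-in
generator (taxonomy with distance-decaying co-occurrence, homophilous
multi-label graphs, domain-shifted twins, random-edge attacks); no clinical
data is required or included.

## Worked example

```python
from icdgraph import (SynthConfig, generate_multilabel_graph,
                      build_operator, TrainConfig, train,
                      evaluate_predictions)

graph = generate_multilabel_graph(SynthConfig(n_nodes=300, n_labels=10,
                                              labels_per_node=1.0,
                                              proto_decay=0.0,
                                              feature_noise=3.5,
                                              avg_degree=4.0, seed=0))
cfg = TrainConfig(mode="softmax", hidden=64, S=4, epochs=300, patience=50)
op = build_operator(graph, cfg.strategy, cfg.K)
model, report = train(graph, cfg, op=op)

Z, _ = model.forward(op.apply_bar(graph.features),
                     mask=model.neighbor_mask(graph))
rep = evaluate_predictions(Z[graph.test_mask], graph.labels[graph.test_mask],
                           single_label=True)
print(f"test accuracy {rep.accuracy:.3f}, micro-F1 {rep.f1_micro:.3f}")
```

prints

```
test accuracy 0.902, micro-F1 0.902
```

— the model classifies ~90% of test nodes correctly with only 30 labeled
nodes, because propagation pools evidence over the homophilous graph.
Ablations on the packaged benchmark (5 seeds) show the expected ordering:
full model 0.820 ≥ without consistency regularization 0.813 ≥ without
consistency and DropNode 0.771 mean test accuracy
(`icdgraph.experiments.ablation_experiment()`).

## Command line

```bash
icdgraph generate --preset default --seed 0 --out data/
icdgraph train --config run.yaml --data data/ --out run/
icdgraph evaluate --data data/ --model run/model.npz --k 5
icdgraph attack --data data/ --rate 0.1 --out data_attacked/
icdgraph adapt --config run.yaml --source data/ --out adapted/
icdgraph labelgraph --data data/ --out label_edges.tsv
```

Datasets are directories of plain-text files: `adjacency.mtx` (Matrix
Market; a two-column `edges.tsv` is also accepted), `features.tsv`,
`labels.tsv` (binary indicators), `masks.tsv` (`node<TAB>split`), and a
`manifest.yaml` holding the generating config and seed, from which the
directory is fully reproducible.

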