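# Methods

This note documents the models implemented in `icdgraph`, the parameter
choices that matter, what the synthetic generators do and do not emulate,
and the numerical decisions taken where the design was genuinely open.

## Propagation model

The normalized adjacency is Â = (D+I)^{−1/2}(A+I)(D+I)^{−1/2} (strategy
M2). Adding the identity before normalization makes isolated nodes
well-defined and, by a Rayleigh-quotient argument, bounds every eigenvalue
of Â in [−1, 1]; the vector v with vᵢ = √(dᵢ+1) is an exact eigenvector
with eigenvalue 1. Alternative strategies are M1 (A+I, no scaling), M3
(row-stochastic), and M4 — an adaptive variant that rescales M2 by a
per-node gate g = σ(w₀·log(d+1) + w₁·‖x‖). The adaptive rule is not pinned
down by any formula we consider authoritative; the gate is a minimal
realization (degree- and embedding-aware, strictly positive, identity-like
for moderate degrees) and is flagged as such.

Mixed-order propagation averages powers 0..K of Â (default K=4). It is
computed by K sparse products — against an identity when the graph is
small enough to materialize the result (≤ 2,000 nodes), directly against
the feature matrix otherwise — never by dense matrix powers.

## Stochastic augmentation and its closed-form effect

DropNode zeroes entire feature rows with probability δ (default 0.2) and
rescales survivors by 1/(1−δ); element-wise dropout is the per-entry
analogue. Both are unbiased for X. For a single-column linear readout the
propagated output variance has closed form

* row mask: Varᵢ = δ/(1−δ) Σⱼ (xⱼᵀW)² Āᵢⱼ²
* element mask: Varᵢ = δ/(1−δ) Σⱼ Āᵢⱼ² Σ_f (X_jf W_f)²

and the induced consistency regularizer is
R_DN = δ/(1−δ) Σᵢⱼ (xⱼᵀW)² zᵢ²(1−zᵢ)² Āᵢⱼ². The two variances differ by a
Cauchy–Schwarz-type gap ((xᵀW)² vs Σ(x_f W_f)²); both are verified against
20,000-draw Monte-Carlo simulations in the test-suite. The perturbed
supervised loss satisfies E[L_sup] ≈ L_orig + ½ Σ zᵢ(1−zᵢ)Varᵢ; the
quadratic approximation is within 10% for δ ≤ 0.3 on random instances and
degrades as δ → 1 (measured, not asserted, at δ = 0.8).

## Prediction head and training

The head has two concurrent branches on the propagated features: a
single-head additive attention with masked softmax over graph neighbors
(self included, GAT-style decomposed scores with LeakyReLU 0.2) and a
2-layer MLP; class logits are summed, then passed through a row softmax
(single-label) or per-label sigmoids (multi-label). Hidden width 128,
dropout 0.5 on input and hidden activations, Xavier-uniform init. All
forward/backward passes are hand-written numpy; gradient correctness is
enforced by finite-difference tests.

Training minimizes L = L_sup + λ·L_con with Adam (lr 1e−3, λ = 1, early
stopping on validation micro-F1). The consistency target is the
temperature-sharpened mean of the S augmented predictions (T = 0.5),
treated as a constant (stop-gradient), with per-label Bernoulli sharpening
in sigmoid mode. Two normalization decisions matter:

* **Loss reporting vs optimization.** The reported losses are plain sums
  (L_sup over labeled nodes, L_con over all nodes). The optimizer, however,
  scales the supervised gradient by 1/m (labeled nodes) and the consistency
  gradient by 1/n (all nodes). With raw sums and λ = 1 the consistency term
  outweighs the supervised one by the unlabeled/labeled ratio and training
  collapses onto a few classes; per-node normalization is the standard
  practice in this model family and keeps λ's meaning size-independent.
* **Multi-label supervised loss.** Each label contributes its full
  Bernoulli pair y·log z + (1−y)·log(1−z). A positives-only cross-entropy
  under sigmoid outputs is degenerate (optimum all-ones).

Ablation modes: `full` (S stochastic augmentations + consistency), `no_cr`
(λ=0), `no_dn` (one shared perturbation per epoch), `no_cr_no_dn`
(deterministic propagation, purely supervised).

## Residual embeddings

MMRP: H^(l+1) = (1−α)ÂH^(l) + αH^(0), a contraction with factor (1−α)
whose fixed point α(I−(1−α)Â)^{−1}H^(0) is computed by direct solve and
checked against iteration to 1e−8. The depth-adaptive variant (DMRM) uses
per-layer coefficients α_l with a shared weight W₁ and per-layer residual
weights. The printed coefficient log(l/(l+1)) + ε is negative for small ε
and therefore not a valid mixing weight; both the literal schedule (clipped
into [1e−3, 1−1e−3]) and a sign-corrected variant ε + log((l+1)/l)
(monotone decreasing toward ε) are provided, the positive variant being the
default. The over-smoothing diagnostic (mean pairwise embedding distance
after 32 steps, residual vs plain propagation) is part of the test-suite.

## Label-graph generation

A linear-sigmoid policy decides, for a candidate label pair, whether the
edge is present; the graph transition is deterministic given the action.
Context features: standardized empirical co-occurrence of the pair, current
degrees, edge density, and taxonomy-depth difference when available. The
co-occurrence feature is standardized against the off-diagonal distribution
so the policy bias and the co-occurrence weight act on decorrelated
directions (without this, the bias collapses to reject-all before the
informative direction is found). Candidate pairs are drawn half uniformly,
half co-occurrence-weighted — edge sampling that cuts redundant exploration
of implausible pairs. Returns are discounted at γ = 0.9; the REINFORCE
estimator is exact (verified unbiased on an enumerable one-step bandit to
3 standard errors at 100,000 episodes, and against finite differences of
the closed-form objective). A mean-return baseline and advantage
normalization are training aids that rescale but never re-sign the update;
both are off wherever the raw estimator's properties are asserted.

The downstream reward is Δ(proxy score) − β·Δ|edges| (β default 0.01).
The proxy is a frozen nearest-centroid model: label prototypes (mean
training features per label) are propagated once over the row-normalized
candidate label graph and scored by pooled rank-AUC on validation labels.
Smoothing along genuinely co-occurring labels denoises prototypes;
spurious edges contaminate them.

**Honest limitation.** Under this performance-based reward the policy
recovers a *high-precision subgraph* of the planted taxonomy, not the full
tree: measured over seeds, recovered-edge precision is ~0.75 against a 0.10
chance rate, but recall stays low (edge-F1 ≈ 0.2–0.7 per seed) because the
absolute reward of adding most true edges is near zero — the downstream
proxy barely improves when a single correct edge is added, and even an
ideal threshold-on-co-occurrence rule tops out near F1 0.75–0.80 given the
overlap between tree-adjacent and distance-2 co-occurrence values.

## Wasserstein domain adaptation

The Kantorovich dual W₁(μ,ν) = sup_{f∈Lip₁} E_μ f − E_ν f is approximated
by a critic f(x) = vᵀtanh(Wx+b) + uᵀx + c trained with a two-sided gradient
penalty (‖∇f‖−1)² at random source/target interpolates (weight 10). The
linear bypass u is essential: a bounded tanh network cannot represent the
large affine transport potentials produced by mean-type domain shifts. All
parameter gradients, including the penalty's (which involves the tanh
second derivative), are closed-form. The equilibrium slope exceeds 1 by
roughly 1/(2·gp_weight); the Lipschitz surrogate check therefore uses a
firmer penalty weight. On shifted 1-D Gaussians the trained critic matches
the exact sorted-pairing W1 oracle within 15% on held-out samples.

The generator G maps target embeddings (post-propagation) toward the
source distribution. Default G is translation-only, identity-initialized;
the full affine map is available behind a flag but, trained adversarially
at a few hundred samples, tends to align marginals while scrambling class
structure. The adaptation weight α (default 0.1) multiplies the generator
step size — Adam is invariant to pure loss scaling, so weighting the loss
itself would be a no-op — and α = 0 leaves the generator exactly at
identity (source-only transfer). When target validation labels exist the
generator is restored to its best-validation state.

## Synthetic benchmarks

The generator produces: a random rooted label taxonomy with co-occurrence
decaying as 0.5^(tree distance); node label sets (uniform primary label +
Poisson extras weighted by co-occurrence); edges drawn by exact weighted
sampling without replacement (Gumbel top-k) with weight (1−h) + h·9·(label
overlap boost) — calibrated so h = 0.8 yields the ~0.8 same-label edge
fraction of citation networks; Gaussian features keyed to label prototypes
(plus an optional Poisson count mode); and train/val/test masks at the
labeled fraction. Everything is a deterministic function of the config
seed.

Label prototypes come in two regimes. With `proto_decay > 0` (default 0.6)
a child label's prototype inherits its parent's plus a scaled deviation —
the ICD-like regime where nearby codes describe similar conditions, and the
regime in which label-graph smoothing can help. With `proto_decay = 0`
prototypes are independent — flat topic-style classes as in citation
networks.

The packaged single-label benchmark (300 nodes, 10 labels, 32 features,
flat prototypes, feature noise 3.5, average degree 4, homophily 0.8, 10%
labeled, S = 4, epochs 300 / patience 50) is calibrated against public
citation-network statistics: feature-only accuracy ≈ 0.55, same-class edge
fraction ≈ 0.8, average degree ≈ 4. On it, five-seed means reproduce the
three directional claims: ablation ordering (full ≥ no-CR ≥ no-CR&DN),
smaller accuracy drop under a 10% random-edge poisoning attack with
consistency than without, and a smaller validation−training loss gap with
augmentation + consistency than without. Under the hierarchical-prototype
regime sibling classes are intrinsically confusable and these orderings are
not expected (and not asserted); passing tests on the flat benchmark say
nothing about hierarchical-feature data in this respect.

What the generator does not emulate: clinical text and its featurization,
realistic ICD code frequency skew, label noise, multi-relational edges, and
semantic (non-smooth) domain shifts. Results on these benchmarks
demonstrate mechanism, not clinical performance.

## Numerical choices

* Probabilities are floored at 1e−12 inside logs; sharpening works in log
  space (stable at T → 0).
* Random streams: every stochastic component takes a seed; augmentations
  use independent child streams spawned from one root seed; per-epoch
  randomness derives from (seed, epoch).
* The mixed-order matrix is materialized densely only below 2,000 nodes.
* Early stopping keeps the best-validation parameter copy; training aborts
  with a diagnostic on non-finite loss.
* Metric conventions: macro-AUC skips single-class columns and reports the
  count skipped; F1 binarizes sigmoid scores at 0.5; P@k breaks score ties
  by ascending label index.
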