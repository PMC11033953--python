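# Methods

## Model

`snolink` predicts snoRNA–disease associations by link prediction on the
bipartite association graph. The design follows the LightGCN family of
collaborative-filtering graph convolutions: node features are nothing but
trainable ID embeddings, propagation is pure degree-normalized neighbor
averaging (no weight matrices, nonlinearities, attention or self-loops
inside the propagation), and the final representation averages all layers.
The assumption behind this choice is that for association data the *only*
signal is the topology; feature transforms mostly add capacity to overfit
a graph with ~10³ edges.

The distinctive component is a learned partition of the snoRNA side.
The premise is biological: snoRNAs with similar disease neighborhoods tend
to act through shared mechanisms, so high-order information should flow
between similar snoRNAs and *not* across unrelated groups that merely share
a hub disease. Concretely:

1. **First-order pass** on the full graph (symmetric normalization
   1/(√deg·√deg)). Degree-0 nodes aggregate to zero but keep their layer-0
   embedding in the final average, so cold nodes remain scoreable.
2. **Subgraph generation.** Each snoRNA's layer-0 and layer-1 embeddings are
   summed, linearly transformed, passed through LeakyReLU, then through a
   2-layer MLP with N_s output logits; the argmax (ties to the lowest
   index) is the snoRNA's subgraph. The snoRNA brings all of its disease
   edges into the subgraph, so its within-subgraph degree equals its full
   degree, while a disease splits into one subgraph-local embedding per
   subgraph it appears in.
3. **High-order passes** inside subgraphs only, normalizing the disease
   side by the *restricted* degree |N_ds|. The disease's layer embedding is
   the sum of its subgraph-local embeddings. The layer-1 subgraph-local
   disease embeddings (needed to start the recursion) are the restriction
   of the full-graph first-order update with full-graph normalization, so
   the cross-subgraph sum reproduces the first-order disease embedding
   exactly and the single-subgraph model collapses to plain LightGCN to
   machine precision (a tested invariant, and the ablation baseline).
4. **Scoring**: average layers 0..K per node family; score = inner product.

## Training

Bayesian Personalized Ranking: per epoch, every observed pair (r, d⁺)
is paired with a uniformly sampled unobserved disease d⁻ for the same
snoRNA, and the loss is mean softplus(−(ŷ_rd⁺ − ŷ_rd⁻)) plus
λ · (mean squared L2 norm of the triplet's layer-0 embeddings). The
regularized set is the batch's ego embeddings, the convention of the
LightGCN/BPR literature; regularizing the generator's weight matrices at
full λ was tried and rejected — at λ = 0.1 the weight-decay term dominates
the ranking term by an order of magnitude, drives the MLP logits to zero
and collapses all snoRNAs into one subgraph.

Optimization is full-batch Adam (datasets in this domain have ~10³
positives; full batches make runs deterministic given a seed). A mini-batch
size is available for larger data.

### Differentiating the argmax

The subgraph assignment is discrete, and the ranking loss is the only
objective, so the generator must learn through the assignment itself. Two
mechanisms make this work, both standard for learned discrete routing:

- **Straight-through Gumbel-softmax.** During training the assignment is
  *sampled*: Gumbel noise (scaled by the temperature T) perturbs the logits
  before the argmax, which draws the subgraph from softmax(O/T). The
  forward pass uses the hard sample; the backward pass scales each
  snoRNA's contribution to subgraph propagation by
  g_r = 1 + (p_sel − stopgrad(p_sel)) with p_sel the soft probability of
  the selected subgraph, so d(loss)/d(g_r) flows into the MLP. Evaluation
  always uses the deterministic argmax.
- **Routing load balance.** A term coeff · N_s · Σ_s f_s P_s (f_s =
  fraction of snoRNAs routed to s, treated as constant; P_s = mean soft
  probability) is added to the training objective. Without it the router
  has a winner-take-all attractor: every snoRNA's surrogate gradient
  reinforces whichever subgraph it currently occupies through the shared
  MLP rows, and within a few hundred epochs all snoRNAs share one subgraph,
  silently degenerating the model to plain LightGCN. The term is minimal
  (value 1) exactly at uniform routing, appropriate because the method
  targets groups of comparable size; strongly unbalanced group structure
  would warrant lowering the coefficient.

A pure `hard` mode (no surrogate; the generator is frozen at its random
initialization) is kept for ablation and for exact gradient checking,
since in that mode the training objective is differentiable everywhere off
the LeakyReLU kinks and argmax boundaries.

## Defaults

| parameter | default | origin |
|---|---|---|
| propagation depth K | 2 | sensitivity analysis of the method's source |
| subgraph count N_s | 4 | sensitivity analysis of the method's source |
| learning rate | 0.001 | sensitivity analysis of the method's source |
| regularization λ | 0.1 | sensitivity analysis of the method's source |
| embedding dim L | 64 | LightGCN convention; not pinned by the source |
| MLP hidden width | L | unstated; matches the embedding width |
| LeakyReLU slope | 0.01 | unstated; framework convention |
| temperature T | 0.5 | chosen for sharp routing: at T=0.5 the planted-block recovery below succeeds on 10/10 seeds, at T=1 on ~8/10, at T=2 routing collapses |
| balance coeff | 0.5 | smallest tried value that prevents router collapse on all planted seeds (0.1 marginal, 2.0 destabilizes) |
| epochs | 1000 | unstated; loss and held-out AUC plateau well before this on ~10³-edge graphs |
| embedding init | normal(0, 0.1); Xavier-uniform MLP weights, zero biases | LightGCN convention |
| 8:2 split rule | round(0.8·n) train | reproduces the reference counts 876/219 for 1095 pairs |
| noise count | round(fraction·n) of the full association set | matches the 1%/5% protocol |

## Synthetic data

`generate_planted` emulates the model's core premise: B blocks of snoRNAs
and diseases; a within-block cell is an association with probability p_in
(default 0.6), a cross-block cell with p_out (default 0.02); defaults are
4 blocks of 10 snoRNAs × 8 diseases. Nodes left with no association are
re-sampled once and otherwise dropped (an isolated node is inert under
propagation and breaks ranking metrics). True block labels are returned so
subgraph recovery can be scored with the adjusted Rand index.

What the generator does **not** emulate, and what passing tests therefore
do not show about real data: heavy-tailed degree distributions (real
disease hubs touch half the snoRNAs), overlapping/non-exclusive groupings,
name noise and curation artifacts, and heterogeneity among unassociated
snoRNAs. Two measurable consequences:

- Within a block, a held-out positive is statistically exchangeable with an
  unobserved within-block cell — no scorer can separate them beyond chance
  — so held-out AUC on planted data is capped around 0.87–0.94 depending on
  the draw (an oracle given the true blocks averages AUC ≈ 0.90 under the
  default settings). Trained models here sit within a few hundredths of
  that oracle; real curated data do not have this artificial ceiling.
- The lowest-ranked candidates for a disease are the most anti-aligned
  *block* — itself a perfectly coherent embedding cluster — so the
  "top candidates are mutually similar, bottom candidates are not" contrast
  seen on real data appears on planted data as "top candidates are
  block-pure and tighter than any cross-block mixture", which is what the
  interpretability tests assert.

## Evaluation protocol

Held-out positives are ranked against all (snoRNA, disease) cells absent
from both train and test ("all" negative policy; a balanced random sample
is available). Accuracy needs a decision rule for an unbounded inner
product, so it thresholds σ(score) at 0.5 on a balanced sampled negative
set. Embeddings are always propagated on the training graph only; held-out
edges never enter message passing, including inside cross-validation. The
noise study injects round(fraction·n) false pairs into either the training
edges or the test positives and additionally audits the injected pairs'
own scores against the σ-threshold.

## Numerical notes

- The BPR loss uses the softplus form log(1+e^(−x)); no overflow for any
  score gap.
- Propagation is scipy.sparse CSR matrix products; the backward pass is the
  exact adjoint (transposed products), verified against central finite
  differences to ~1e-10 on small instances.
- Degree-0 nodes: normalization weights exist only on edges, so no division
  by zero arises anywhere.
- Checkpoints are NumPy `.npz` archives with a JSON metadata blob; exported
  embedding TSVs use float hex notation so reload is bitwise exact.

## Known limitations

- The router's load-balance prior favors near-uniform subgraph sizes.
- Assignment is recomputed every forward pass; it can oscillate for
  snoRNAs genuinely between groups (the Gumbel noise makes this explicit
  exploration rather than silent instability).
- Nodes appearing only in the test set are scored from their layer-0
  embeddings alone (never trained against an association), which is the
  honest cold-start behavior but means their rankings are uninformative.
- Training is CPU-bound dense/sparse linear algebra; it is sized for the
  ~500×100-node graphs of this domain, not for millions of edges.
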