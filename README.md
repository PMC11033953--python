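# snolink

Interpretable graph-convolutional prediction of snoRNA–disease associations.

Small nucleolar RNAs (snoRNAs) guide chemical modification of rRNA and are
increasingly implicated in disease, but experimentally validating individual
snoRNA–disease links is slow and expensive. Given a curated table of known
associations, `snolink` ranks the unobserved snoRNA–disease pairs so that
likely associations surface first, and does so with an *interpretable*
mechanism: it learns to group snoRNAs with similar disease neighborhoods into
subgraphs and confines high-order message passing within those groups.

The package is a library first (`import snolink`), with short narrative
scripts under `examples/` and a thin `snolink` command-line wrapper.

## Model

Known associations form a bipartite graph G = (V_r, V_d, E) with snoRNA
nodes V_r, disease nodes V_d and one edge per association. Every node gets a
trainable embedding e⁰ ∈ R^L. Propagation is LightGCN-style — no feature
transforms or nonlinearities, only symmetrically normalized neighbor
aggregation:

    e_r¹ = Σ_{d ∈ N_r}  e_d⁰ / (√|N_r| √|N_d|)        (first-order layer)

After this first pass, a generator fuses each snoRNA's layer-0 and layer-1
embeddings, F_r = LeakyReLU(W₁(e_r⁰ + e_r¹) + b₁), feeds them through a
2-layer MLP, and assigns the snoRNA to the subgraph with the largest logit.
A snoRNA takes all of its diseases into its subgraph, so a disease d can
live in several subgraphs, with one subgraph-local embedding e_ds per
subgraph. Higher-order layers propagate only within subgraphs,

    e_r^{k+1} = Σ_{d ∈ N_r}  e_ds^k / (√|N_r| √|N_ds|)
    e_ds^{k+1} = Σ_{r ∈ N_ds} e_r^k / (√|N_ds| √|N_r|)
    e_d^k     = Σ_{s ∋ d} e_ds^k ,

where N_ds is d's neighbor set restricted to subgraph s. Final embeddings
average layers 0..K, and the association score is the inner product
ŷ_rd = e_r · e_d. Training minimizes the Bayesian Personalized Ranking loss
over triplets (r, d⁺, d⁻) with L2 regularization of the triplet's layer-0
embeddings; the discrete subgraph assignment trains end-to-end through a
straight-through Gumbel-softmax estimator with a small routing
load-balancing term (see `docs/methods.md`).

With a single subgraph (or the `ablation_lightgcn` flag) the model reduces
exactly to plain LightGCN, which is the built-in ablation baseline.

Everything is NumPy/SciPy; gradients are derived by hand and verified
against finite differences in the test suite.

## Worked example

```python
import snolink as sl

table, blocks = sl.generate_planted(sl.PlantedConfig(seed=0))
plan = sl.split_pairs(table, ratio=0.8, seed=0)
graph_train = sl.build_graph(table, plan.train_pairs)

model_config = sl.ModelConfig()          # L=64, K=2, 4 subgraphs
fitted = sl.train(model_config, sl.TrainConfig(seed=0), graph_train)

result = sl.evaluate_split(fitted.params, model_config, graph_train,
                           table.pair_indices()[plan.test_pairs], seed=0)
fwd = sl.forward(fitted.params, graph_train, model_config)
ari = sl.assignment_recovery_score(fwd.assignment.snorna_to_sub, blocks)
```

Running `python examples/01_train_and_evaluate.py` (exactly this workflow)
prints:

```
data: 40 snoRNAs x 32 diseases, 220 associations
split: 176 train / 44 test pairs
training: loss 1.364 -> 1.120 over 1000 epochs
held-out AUC 0.896  AUPR 0.242  accuracy 0.841
subgraph-recovery ARI 1.000  (sizes [10, 10, 10, 10])
```

The synthetic table plants four groups of snoRNAs that share disease
neighborhoods. AUC is the probability that a held-out association outranks
a random unobserved pair (negatives are all unobserved cells, so AUPR's
baseline is the ~3% positive prevalence, not 0.5). The ARI of 1.0 means the
learned subgraph assignment recovered the four planted groups exactly —
the interpretable part of the model working as intended.

`examples/03_noise_sensitivity.py` reproduces the robustness experiment
(false associations injected into train vs test):

```
target    fraction     AUC    AUPR     acc  flagged
baseline      0.00   0.896   0.242   0.841  -
train         0.01   0.895   0.246   0.841  -
train         0.05   0.892   0.249   0.818  -
test          0.01   0.868   0.234   0.837  100%
test          0.05   0.817   0.223   0.782  91%
```

Training-side noise barely moves the metrics (subgraph-restricted
propagation contains it) while test-side noise lowers them directly — yet
the model itself scores ≥ 91% of the injected false pairs below the
decision threshold ("flagged").

The same workflows run from the shell:

```bash
snolink simulate --out-dir data --seed 0
snolink train --data data/associations.tsv --out-dir run --seed 0
snolink predict --checkpoint run/checkpoint.npz --data data/associations.tsv \
                --disease dis01 --top-n 10 --out-dir pred
```

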