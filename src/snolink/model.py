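"""Embedding propagation model with a learned subgraph generator.

The model is a LightGCN-style graph convolution on the snoRNA-disease
bipartite graph: no feature transforms or nonlinearities inside propagation,
only degree-normalized neighbor aggregation and a final average over layers.
Its distinctive piece is a learned partition of the snoRNAs: after the
first-order pass, each snoRNA's layer-0 and layer-1 embeddings are fused
through a linear map + LeakyReLU, a 2-layer MLP produces a logit per
subgraph, and the argmax picks the snoRNA's subgraph.  All higher-order
propagation is then confined within subgraphs: a disease keeps one embedding
per subgraph it appears in (through its snoRNA neighbors), and those
per-subgraph embeddings are summed to form the disease's layer embedding.

The argmax is non-differentiable; in ``straight_through`` mode the forward
pass uses the hard assignment while the backward pass routes gradient through
the softmax probability of the selected subgraph, so the generator trains
end-to-end from the ranking loss alone.  ``hard`` mode cuts that path (the
generator is then effectively frozen), which is useful for ablation and for
exact finite-difference checks.

Everything is NumPy/SciPy; :func:`backward` is the hand-derived reverse-mode
gradient of the forward pass and is verified against central finite
differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import scipy.sparse as sp

from .graph import BipartiteGraph, SubgraphPartition, normalized_adjacency, subgraph_views

EMBED_INIT_STD = 0.1


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the propagation model.

    embed_dim
        Size L of every node embedding (default 64, the LightGCN convention).
    n_layers
        Total propagation depth K; the first-order pass counts as layer 1 and
        subgraph-restricted passes as layers 2..K.  The layer combination
        averages layers 0..K.  Default 2.
    n_subgraphs
        Number of subgraphs N_s the generator may use (default 4).
    mlp_hidden
        Hidden width of the generator MLP; None means embed_dim.
    leaky_slope
        Negative slope of every LeakyReLU (default 0.01).
    ablation_lightgcn
        If True, skip the subgraph generator entirely and run K plain
        LightGCN layers on the full graph.
    assignment_mode
        "straight_through" (default) or "hard"; see module docstring.
    temperature
        Softmax temperature of the straight-through relaxation.
    """

    embed_dim: int = 64
    n_layers: int = 2
    n_subgraphs: int = 4
    mlp_hidden: int | None = None
    leaky_slope: float = 0.01
    ablation_lightgcn: bool = False
    assignment_mode: str = "straight_through"
    temperature: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.n_subgraphs < 1:
            raise ValueError("n_subgraphs must be >= 1")
        if self.embed_dim < 1:
            raise ValueError("embed_dim must be >= 1")
        if self.assignment_mode not in ("hard", "straight_through"):
            raise ValueError("assignment_mode must be 'hard' or 'straight_through'")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def hidden_dim(self) -> int:
        return self.embed_dim if self.mlp_hidden is None else self.mlp_hidden


@dataclass
class Parameters:
    """All trainable arrays: layer-0 embeddings and the generator weights."""

    e_r0: np.ndarray  # (N, L) snoRNA layer-0 embeddings
    e_d0: np.ndarray  # (M, L) disease layer-0 embeddings
    fuse_weight: np.ndarray  # W1 (L, L)
    fuse_bias: np.ndarray  # b1 (L,)
    mlp1_weight: np.ndarray  # W2 (H, L)
    mlp1_bias: np.ndarray  # b2 (H,)
    mlp2_weight: np.ndarray  # W3 (N_s, H)
    mlp2_bias: np.ndarray  # b3 (N_s,)

    _NAMES = (
        "e_r0", "e_d0", "fuse_weight", "fuse_bias",
        "mlp1_weight", "mlp1_bias", "mlp2_weight", "mlp2_bias",
    )

    def names(self) -> tuple[str, ...]:
        return self._NAMES

    def as_dict(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in self.names()}

    def copy(self) -> "Parameters":
        return Parameters(**{k: v.copy() for k, v in self.as_dict().items()})


@dataclass(frozen=True)
class SubgraphAssignment:
    """Hard snoRNA->subgraph map plus the training-time soft relaxation."""

    snorna_to_sub: np.ndarray  # (N,) ids in [0, n_subgraphs)
    n_subgraphs: int
    soft_weights: np.ndarray | None = None  # (N, N_s) softmax rows

    def __post_init__(self) -> None:
        if self.soft_weights is not None and not np.allclose(
            self.soft_weights.sum(axis=1), 1.0, atol=1e-6
        ):
            raise ValueError("soft_weights rows must sum to 1")


@dataclass
class EmbeddingState:
    """Per-layer embeddings for both node families.

    ``disease_sub_layers[k][s]`` holds the subgraph-local disease matrix
    e_ds^{k+1} (index k corresponds to layer k+1; layer 0 has no subgraph
    decomposition).  For every layer >= 1 produced under a partition,
    summing e_ds over subgraphs reproduces the disease layer embedding.
    """

    snorna_layers: list[np.ndarray]
    disease_layers: list[np.ndarray]
    disease_sub_layers: list[list[np.ndarray]] = field(default_factory=list)

    @property
    def n_layers(self) -> int:
        return len(self.snorna_layers) - 1


def _xavier_uniform(rng: np.random.Generator, fan_out: int, fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=(fan_out, fan_in))


def init_embeddings(n_snorna: int, n_disease: int, embed_dim: int, seed: int) -> EmbeddingState:
    """Layer-0 lookup tables, entries i.i.d. normal(0, 0.1)."""
    if min(n_snorna, n_disease, embed_dim) < 1:
        raise ValueError("n_snorna, n_disease and embed_dim must be >= 1")
    rng = np.random.default_rng(seed)
    e_r0 = rng.normal(0.0, EMBED_INIT_STD, size=(n_snorna, embed_dim))
    e_d0 = rng.normal(0.0, EMBED_INIT_STD, size=(n_disease, embed_dim))
    return EmbeddingState(snorna_layers=[e_r0], disease_layers=[e_d0])


def init_parameters(n_snorna: int, n_disease: int, config: ModelConfig, seed: int | None = None) -> Parameters:
    """Embeddings normal(0, 0.1); generator weights Xavier-uniform, zero biases."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    state = init_embeddings(n_snorna, n_disease, config.embed_dim, seed)
    L, H, S = config.embed_dim, config.hidden_dim, config.n_subgraphs
    return Parameters(
        e_r0=state.snorna_layers[0],
        e_d0=state.disease_layers[0],
        fuse_weight=_xavier_uniform(rng, L, L),
        fuse_bias=np.zeros(L),
        mlp1_weight=_xavier_uniform(rng, H, L),
        mlp1_bias=np.zeros(H),
        mlp2_weight=_xavier_uniform(rng, S, H),
        mlp2_bias=np.zeros(S),
    )


def _leaky_relu(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x >= 0, x, slope * x)


def _leaky_relu_grad(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x >= 0, 1.0, slope)


def _softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def propagate_first_order(
    e_r0: np.ndarray, e_d0: np.ndarray, graph: BipartiteGraph
) -> tuple[np.ndarray, np.ndarray]:
    """First-order neighbor aggregation on the full graph.

    e_r^1[r] = sum_{d in N_r} e_d^0[d] / (sqrt|N_r| sqrt|N_d|), and
    symmetrically for diseases.  Degree-0 rows come out zero.
    """
    a_hat = normalized_adjacency(graph)
    return a_hat @ e_d0, a_hat.T @ e_r0


def fuse_features(
    e_r0: np.ndarray, e_r1: np.ndarray, params: Parameters, slope: float = 0.01
) -> np.ndarray:
    """F[r] = LeakyReLU(W1 (e_r^0[r] + e_r^1[r]) + b1)."""
    x = e_r0 + e_r1
    return _leaky_relu(x @ params.fuse_weight.T + params.fuse_bias, slope)


def assign_subgraphs(
    fused: np.ndarray,
    params: Parameters,
    mode: str = "straight_through",
    temperature: float = 1.0,
    slope: float = 0.01,
) -> SubgraphAssignment:
    """Run the 2-layer MLP and take the argmax logit as the subgraph id.

    Ties break to the lowest index.  In straight_through mode the softmax of
    the logits (at the given temperature) is kept as the soft relaxation.
    """
    hidden = _leaky_relu(fused @ params.mlp1_weight.T + params.mlp1_bias, slope)
    logits = hidden @ params.mlp2_weight.T + params.mlp2_bias
    hard = np.argmax(logits, axis=1)
    soft = _softmax(logits / temperature) if mode == "straight_through" else None
    return SubgraphAssignment(
        snorna_to_sub=hard, n_subgraphs=logits.shape[1], soft_weights=soft
    )


def propagate_high_order(
    e_r_k: np.ndarray,
    d_sub_k: list[np.ndarray],
    partition: SubgraphPartition,
    assignment: np.ndarray | None = None,
) -> tuple[np.ndarray, list[np.ndarray], np.ndarray]:
    """One subgraph-restricted propagation step (layer k -> k+1).

    Within each subgraph s:
      e_ds^{k+1}[d] = sum_{r in N_ds} e_r^k[r] / (sqrt|N_ds| sqrt|N_r|)
      e_r^{k+1}[r]  = sum_{d in N_r} e_ds^k[d] / (sqrt|N_r| sqrt|N_ds|)
    and the disease layer embedding is the cross-subgraph sum of e_ds^{k+1}.

    Passing ``assignment`` asserts the partition was built from it; a stale
    partition raises.
    """
    if assignment is not None and not np.array_equal(partition.assignment, assignment):
        raise ValueError("stale subgraph partition: assignment has changed")
    if len(d_sub_k) != partition.n_subgraphs:
        raise ValueError("d_sub_k must have one matrix per subgraph")
    e_r_next = np.zeros_like(e_r_k)
    d_sub_next: list[np.ndarray] = []
    for s, mat in enumerate(partition.inter_matrices):
        e_r_next += mat.T @ d_sub_k[s]
        d_sub_next.append(mat @ e_r_k)
    e_d_next = np.sum(d_sub_next, axis=0) if d_sub_next else np.zeros_like(d_sub_k[0])
    return e_r_next, d_sub_next, e_d_next


def combine_layers(layers: Iterable[np.ndarray]) -> np.ndarray:
    """Final embedding: arithmetic mean of layers 0..K."""
    layers = list(layers)
    return np.sum(layers, axis=0) / len(layers)


def score(e_r: np.ndarray, e_d: np.ndarray, r: int, d: int) -> float:
    """Predicted association score: inner product of final embeddings."""
    return float(e_r[r] @ e_d[d])


def score_all(e_r: np.ndarray, e_d: np.ndarray) -> np.ndarray:
    """Dense score matrix, shape (n_snorna, n_disease)."""
    return e_r @ e_d.T


@dataclass
class ForwardResult:
    """Final embeddings plus everything needed for the backward pass."""

    e_r: np.ndarray
    e_d: np.ndarray
    assignment: SubgraphAssignment
    state: EmbeddingState
    cache: dict


def forward(
    params: Parameters,
    graph: BipartiteGraph,
    config: ModelConfig,
    rng: np.random.Generator | None = None,
) -> ForwardResult:
    """Full pipeline: first-order pass, subgraph assignment, K-1 restricted
    passes, layer combination.  With ``ablation_lightgcn`` the generator is
    skipped and K plain LightGCN layers run on the full graph.

    Passing ``rng`` (training-time, straight_through mode only) perturbs the
    assignment logits with Gumbel noise before the argmax, i.e. the subgraph
    is SAMPLED from softmax(O/T) instead of maximized.  The stochastic
    exploration is what lets the generator escape the all-in-one-subgraph
    attractor of deterministic straight-through training; evaluation calls
    omit ``rng`` and are deterministic."""
    K = config.n_layers
    a_hat = normalized_adjacency(graph)
    e_r_layers = [params.e_r0]
    e_d_layers = [params.e_d0]
    cache: dict = {"a_hat": a_hat, "config": config}

    if config.ablation_lightgcn:
        for _ in range(K):
            e_r_layers.append(a_hat @ e_d_layers[-1])
            e_d_layers.append(a_hat.T @ e_r_layers[-2])
        assignment = SubgraphAssignment(
            snorna_to_sub=np.zeros(graph.n_snorna, dtype=np.int64), n_subgraphs=1
        )
        state = EmbeddingState(snorna_layers=e_r_layers, disease_layers=e_d_layers)
        cache["mode"] = "ablation"
        return ForwardResult(
            e_r=combine_layers(e_r_layers),
            e_d=combine_layers(e_d_layers),
            assignment=assignment,
            state=state,
            cache=cache,
        )

    # layer 1: full-graph first-order aggregation
    e_r1 = a_hat @ params.e_d0
    e_d1 = a_hat.T @ params.e_r0
    e_r_layers.append(e_r1)
    e_d_layers.append(e_d1)

    # subgraph generator: fuse, 2-layer MLP, argmax
    x = params.e_r0 + e_r1
    z1 = x @ params.fuse_weight.T + params.fuse_bias
    fused = _leaky_relu(z1, config.leaky_slope)
    z2 = fused @ params.mlp1_weight.T + params.mlp1_bias
    hidden = _leaky_relu(z2, config.leaky_slope)
    logits = hidden @ params.mlp2_weight.T + params.mlp2_bias
    decision_logits = logits
    if rng is not None and config.assignment_mode == "straight_through":
        gumbel = -np.log(-np.log(rng.uniform(1e-12, 1.0, size=logits.shape)))
        decision_logits = logits + config.temperature * gumbel
    hard = np.argmax(decision_logits, axis=1)
    soft = (
        _softmax(decision_logits / config.temperature)
        if config.assignment_mode == "straight_through"
        else None
    )
    assignment = SubgraphAssignment(
        snorna_to_sub=hard, n_subgraphs=config.n_subgraphs, soft_weights=soft
    )
    partition = subgraph_views(graph, hard, config.n_subgraphs)

    # layer-1 subgraph-local disease embeddings: restriction of the full-graph
    # first-order update, so that their cross-subgraph sum equals e_d^1 exactly
    d_sub = [mat @ params.e_r0 for mat in partition.first_order_matrices]
    d_sub_layers = [d_sub]

    for _ in range(K - 1):
        e_r_next, d_sub, e_d_next = propagate_high_order(
            e_r_layers[-1], d_sub_layers[-1], partition
        )
        e_r_layers.append(e_r_next)
        e_d_layers.append(e_d_next)
        d_sub_layers.append(d_sub)

    state = EmbeddingState(
        snorna_layers=e_r_layers,
        disease_layers=e_d_layers,
        disease_sub_layers=d_sub_layers,
    )
    cache.update(
        mode="subgraph",
        partition=partition,
        x=x,
        z1=z1,
        fused=fused,
        z2=z2,
        hidden=hidden,
        logits=logits,
        assignment=assignment,
        state=state,
    )
    return ForwardResult(
        e_r=combine_layers(e_r_layers),
        e_d=combine_layers(e_d_layers),
        assignment=assignment,
        state=state,
        cache=cache,
    )


def zero_gradients(params: Parameters) -> dict[str, np.ndarray]:
    return {name: np.zeros_like(arr) for name, arr in params.as_dict().items()}


def backward(
    params: Parameters,
    result: ForwardResult,
    grad_e_r: np.ndarray,
    grad_e_d: np.ndarray,
    extra_logit_grad: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Reverse-mode gradient of the forward pass.

    Takes gradients w.r.t. the FINAL (layer-combined) embeddings and returns
    gradients for every trainable array.  In straight_through mode the
    assignment surrogate routes d(loss)/d(g_r) into the generator MLP, where
    g_r is the (forward value 1) soft probability of the selected subgraph.
    ``extra_logit_grad`` lets auxiliary objectives defined directly on the
    assignment logits (e.g. the routing load balance used in training)
    contribute their gradient; it is ignored in ablation mode.
    """
    cache = result.cache
    config: ModelConfig = cache["config"]
    a_hat = cache["a_hat"]
    K = config.n_layers
    grads = zero_gradients(params)
    c = 1.0 / (K + 1)

    state = result.state
    g_er = [c * grad_e_r.copy() for _ in range(K + 1)]
    g_ed = [c * grad_e_d.copy() for _ in range(K + 1)]

    if cache["mode"] == "ablation":
        # e_r^{k} = A e_d^{k-1}; e_d^{k} = A^T e_r^{k-1}
        for k in range(K, 0, -1):
            g_ed[k - 1] += a_hat.T @ g_er[k]
            g_er[k - 1] += a_hat @ g_ed[k]
        grads["e_r0"] += g_er[0]
        grads["e_d0"] += g_ed[0]
        return grads

    partition: SubgraphPartition = cache["partition"]
    S = partition.n_subgraphs
    N = params.e_r0.shape[0]
    g_rescale = np.zeros(N)  # d loss / d g_r, the straight-through scalar

    # gradients of subgraph-local disease matrices, per layer 1..K
    g_dsub: dict[int, list[np.ndarray]] = {
        k: [np.zeros_like(params.e_d0) for _ in range(S)] for k in range(1, K + 1)
    }
    # high-order layers K..2:
    #   e_r^{k} = sum_s B_s^T D_s^{k-1};  D_s^{k} = B_s (g * e_r^{k-1});
    #   e_d^{k} = sum_s D_s^{k}
    for k in range(K, 1, -1):
        for s, mat in enumerate(partition.inter_matrices):
            g_dsub[k - 1][s] += mat @ g_er[k]
            g_dsub[k][s] += g_ed[k]
            u = mat.T @ g_dsub[k][s]
            g_er[k - 1] += u
            g_rescale += np.sum(u * state.snorna_layers[k - 1], axis=1)
    # layer-1 subgraph-local diseases: D_s^1 = C_s (g * e_r^0)
    for s, mat in enumerate(partition.first_order_matrices):
        u = mat.T @ g_dsub[1][s]
        g_er[0] += u
        g_rescale += np.sum(u * state.snorna_layers[0], axis=1)

    # straight-through surrogate: g_r = p[r, sel_r] (treated as 1 in forward)
    if config.assignment_mode == "straight_through":
        soft = result.assignment.soft_weights
        sel = result.assignment.snorna_to_sub
        p_sel = soft[np.arange(N), sel]
        one_hot = np.zeros_like(soft)
        one_hot[np.arange(N), sel] = 1.0
        d_logits = (
            (g_rescale * p_sel)[:, None] * (one_hot - soft) / config.temperature
        )
    else:
        d_logits = np.zeros((N, S))
    if extra_logit_grad is not None:
        d_logits = d_logits + extra_logit_grad

    # generator MLP backward
    hidden, z2, fused, z1, x = (
        cache["hidden"], cache["z2"], cache["fused"], cache["z1"], cache["x"],
    )
    grads["mlp2_weight"] += d_logits.T @ hidden
    grads["mlp2_bias"] += d_logits.sum(axis=0)
    g_hidden = d_logits @ params.mlp2_weight
    g_z2 = g_hidden * _leaky_relu_grad(z2, config.leaky_slope)
    grads["mlp1_weight"] += g_z2.T @ fused
    grads["mlp1_bias"] += g_z2.sum(axis=0)
    g_fused = g_z2 @ params.mlp1_weight
    g_z1 = g_fused * _leaky_relu_grad(z1, config.leaky_slope)
    grads["fuse_weight"] += g_z1.T @ x
    grads["fuse_bias"] += g_z1.sum(axis=0)
    g_x = g_z1 @ params.fuse_weight
    g_er[0] += g_x
    g_er[1] += g_x

    # first-order layer: e_r^1 = A e_d^0; e_d^1 = A^T e_r^0
    g_ed[0] += a_hat.T @ g_er[1]
    g_er[0] += a_hat @ g_ed[1]

    grads["e_r0"] += g_er[0]
    grads["e_d0"] += g_ed[0]
    return grads


def save_checkpoint(
    path: str | Path, params: Parameters, config: ModelConfig, seed: int | None = None
) -> None:
    """Single-archive checkpoint: every parameter matrix plus the config."""
    meta = {"config": asdict(config), "seed": seed}
    np.savez(
        Path(path),
        __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **params.as_dict(),
    )


def load_checkpoint(path: str | Path) -> tuple[Parameters, ModelConfig, int | None]:
    with np.load(Path(path)) as archive:
        meta = json.loads(archive["__meta__"].tobytes().decode())
        params = Parameters(**{name: archive[name] for name in Parameters._NAMES})
    return params, ModelConfig(**meta["config"]), meta["seed"]


def export_embeddings_tsv(
    path: str | Path, e_r: np.ndarray, e_d: np.ndarray, snorna_names: list[str], disease_names: list[str]
) -> None:
    """Final embeddings as TSV: node name, family, L coordinate columns."""
    dim = e_r.shape[1]
    with Path(path).open("w") as fh:
        fh.write("node\tfamily\t" + "\t".join(f"dim{i}" for i in range(dim)) + "\n")
        for name, row in zip(snorna_names, e_r):
            fh.write(name + "\tsnorna\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
        for name, row in zip(disease_names, e_d):
            fh.write(name + "\tdisease\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
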