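"""Bayesian Personalized Ranking training with negative sampling.

Each training instance is a triplet (r, d+, d-): snoRNA r, one of its known
diseases d+, and a uniformly sampled disease d- it is NOT associated with in
the training graph.  The loss pushes the score of the observed pair above the
unobserved one:

    L = mean_t  -ln sigma(y[r,d+] - y[r,d-])  +  lambda * reg

computed in the numerically stable softplus form.  The regularizer is the
squared L2 norm of the triplet's layer-0 (ego) embeddings averaged per
triplet (the LightGCN convention).

In straight-through mode the training objective additionally carries a small
load-balancing term on the subgraph routing,

    balance = coeff * N_s * sum_s f_s * P_s

with f_s the fraction of snoRNAs currently routed to subgraph s and P_s the
mean soft routing probability of s.  Without it the router has a
winner-take-all attractor: every snoRNA's surrogate gradient reinforces its
current subgraph through the shared MLP rows, and all snoRNAs collapse into
a single subgraph early in training, degenerating the model to plain
LightGCN.  The term is minimal exactly at uniform routing and adds gradient
only through the soft probabilities.

Optimization is full-batch Adam by default (the association data this method
targets are small, ~1e3 positives); a mini-batch size can be set.  The
learning rate 0.001 and lambda 0.1 defaults follow the reference sensitivity
analysis; the epoch budget, optimizer, balance coefficient and embedding
dimension are not pinned by it and are ordinary conventions, all
configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .graph import BipartiteGraph
from .model import (
    ForwardResult,
    ModelConfig,
    Parameters,
    backward,
    forward,
    init_parameters,
    zero_gradients,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 0.001
    lambda_reg: float = 0.1
    epochs: int = 1000
    batch_size: int | None = None  # None = full batch
    balance_coeff: float = 0.5
    neg_per_pos: int = 1
    early_stop_patience: int | None = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be nonnegative")
        if self.balance_coeff < 0:
            raise ValueError("balance_coeff must be nonnegative")
        if self.epochs < 0:
            raise ValueError("epochs must be nonnegative")


@dataclass(frozen=True)
class Triplets:
    """Parallel index arrays: (r, d_pos, d_neg) per training instance."""

    snorna: np.ndarray
    d_pos: np.ndarray
    d_neg: np.ndarray

    def __len__(self) -> int:
        return len(self.snorna)


def sample_triplets(
    graph: BipartiteGraph, rng: np.random.Generator, neg_per_pos: int = 1
) -> Triplets:
    """One pass over all training positives; d- uniform over diseases not in N_r.

    A snoRNA associated with every disease has no valid negative; its
    positives are skipped with a warning.
    """
    m = graph.n_disease
    complements: dict[int, np.ndarray] = {}
    full_rows: set[int] = set()
    for r in np.unique(graph.edge_snorna):
        comp = np.setdiff1d(np.arange(m), graph.nbrs_of_snorna(r), assume_unique=False)
        if len(comp) == 0:
            full_rows.add(int(r))
            logger.warning("snoRNA %d is associated with all diseases; skipped", r)
        else:
            complements[int(r)] = comp

    rs, dps, dns = [], [], []
    for r, d in zip(graph.edge_snorna, graph.edge_disease):
        if int(r) in full_rows:
            continue
        comp = complements[int(r)]
        for _ in range(neg_per_pos):
            rs.append(r)
            dps.append(d)
            dns.append(rng.choice(comp))
    return Triplets(
        snorna=np.array(rs, dtype=np.int64),
        d_pos=np.array(dps, dtype=np.int64),
        d_neg=np.array(dns, dtype=np.int64),
    )


def bpr_loss(
    scores_pos: np.ndarray,
    scores_neg: np.ndarray,
    reg_term: float = 0.0,
    lam: float = 0.0,
) -> float:
    """mean_t softplus(-(y+ - y-)) + lam * reg_term."""
    scores_pos = np.asarray(scores_pos, dtype=float)
    scores_neg = np.asarray(scores_neg, dtype=float)
    if scores_pos.shape != scores_neg.shape:
        raise ValueError("score vectors must have equal length")
    diff = scores_pos - scores_neg
    return float(np.mean(np.logaddexp(0.0, -diff)) + lam * reg_term)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def bpr_gradients(
    result: ForwardResult,
    params: Parameters,
    triplets: Triplets,
    lam: float,
) -> tuple[float, dict[str, np.ndarray], np.ndarray, np.ndarray]:
    """Loss value, direct parameter gradients (regularizer), and gradients
    w.r.t. the final embeddings, for one batch of triplets."""
    e_r, e_d = result.e_r, result.e_d
    r, dp, dn = triplets.snorna, triplets.d_pos, triplets.d_neg
    n_t = len(triplets)

    diff = np.sum(e_r[r] * (e_d[dp] - e_d[dn]), axis=1)
    reg = (
        np.sum(params.e_r0[r] ** 2)
        + np.sum(params.e_d0[dp] ** 2)
        + np.sum(params.e_d0[dn] ** 2)
    ) / n_t
    loss = float(np.mean(np.logaddexp(0.0, -diff)) + lam * reg)

    d_diff = -_sigmoid(-diff) / n_t  # d loss / d diff_t
    grad_e_r = np.zeros_like(e_r)
    grad_e_d = np.zeros_like(e_d)
    np.add.at(grad_e_r, r, d_diff[:, None] * (e_d[dp] - e_d[dn]))
    np.add.at(grad_e_d, dp, d_diff[:, None] * e_r[r])
    np.add.at(grad_e_d, dn, -d_diff[:, None] * e_r[r])

    direct = zero_gradients(params)
    coeff = 2.0 * lam / n_t
    np.add.at(direct["e_r0"], r, coeff * params.e_r0[r])
    np.add.at(direct["e_d0"], dp, coeff * params.e_d0[dp])
    np.add.at(direct["e_d0"], dn, coeff * params.e_d0[dn])
    return loss, direct, grad_e_r, grad_e_d


def routing_balance(
    result: ForwardResult, temperature: float
) -> tuple[float, np.ndarray]:
    """Load-balance value N_s * sum_s f_s P_s and its logit gradient.

    ``f_s`` is the routed fraction (through the non-differentiable argmax,
    treated as constant) and ``P_s`` the mean soft probability; the gradient
    flows through P_s only.  The value is minimized (at 1.0) by uniform
    routing.
    """
    assignment = result.assignment
    soft = assignment.soft_weights
    if soft is None:
        raise ValueError("routing balance needs straight_through soft weights")
    n, s = soft.shape
    frac = np.bincount(assignment.snorna_to_sub, minlength=s) / n
    value = float(s * np.sum(frac * soft.mean(axis=0)))
    # d value / d logits via the softmax Jacobian at temperature T
    d_logits = (s / (n * temperature)) * soft * (
        frac[None, :] - (soft * frac[None, :]).sum(axis=1, keepdims=True)
    )
    return value, d_logits


class Adam:
    """Standard Adam over the named parameter arrays."""

    def __init__(self, params: Parameters, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = zero_gradients(params)
        self.v = zero_gradients(params)

    def step(self, params: Parameters, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for name, g in grads.items():
            self.m[name] = self.beta1 * self.m[name] + (1 - self.beta1) * g
            self.v[name] = self.beta2 * self.v[name] + (1 - self.beta2) * g * g
            m_hat = self.m[name] / (1 - self.beta1 ** self.t)
            v_hat = self.v[name] / (1 - self.beta2 ** self.t)
            arr = getattr(params, name)
            arr -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


@dataclass
class TrainResult:
    params: Parameters
    history: list[dict]
    config: ModelConfig
    train_config: TrainConfig


def train(
    model_config: ModelConfig,
    train_config: TrainConfig,
    graph: BipartiteGraph,
    params: Parameters | None = None,
    val_pairs: np.ndarray | None = None,
) -> TrainResult:
    """Full training loop: per epoch, forward -> triplet sampling -> BPR
    gradient -> hand-derived backward -> Adam update.

    ``val_pairs`` (shape (n, 2) of held-out (r, d) positives) enables early
    stopping on validation AUC with the configured patience; without it the
    fixed epoch budget runs to the end.  Deterministic for a given seed up to
    floating-point reduction order.
    """
    if graph.n_edges == 0:
        raise ValueError("training graph has no edges")
    rng = np.random.default_rng(train_config.seed)
    if params is None:
        params = init_parameters(graph.n_snorna, graph.n_disease, model_config)
    optimizer = Adam(params, lr=train_config.lr)
    history: list[dict] = []
    best_val, best_params, patience_left = -np.inf, None, train_config.early_stop_patience

    val_mask = None
    if val_pairs is not None:
        from .evaluation import auc_score  # local import to avoid cycle

        val_mask = np.zeros((graph.n_snorna, graph.n_disease), dtype=bool)
        val_mask[val_pairs[:, 0], val_pairs[:, 1]] = True
        train_mask = np.zeros_like(val_mask)
        train_mask[graph.edge_snorna, graph.edge_disease] = True

    for epoch in range(train_config.epochs):
        triplets = sample_triplets(graph, rng, train_config.neg_per_pos)
        order = rng.permutation(len(triplets))
        bs = train_config.batch_size or len(triplets)
        epoch_loss, n_batches = 0.0, 0
        result = None
        for start in range(0, len(triplets), bs):
            batch = Triplets(
                snorna=triplets.snorna[order[start : start + bs]],
                d_pos=triplets.d_pos[order[start : start + bs]],
                d_neg=triplets.d_neg[order[start : start + bs]],
            )
            result = forward(params, graph, model_config, rng=rng)
            loss, grads, g_er, g_ed = bpr_gradients(
                result, params, batch, train_config.lambda_reg
            )
            extra_logit_grad = None
            if (
                train_config.balance_coeff > 0
                and not model_config.ablation_lightgcn
                and model_config.assignment_mode == "straight_through"
                and model_config.n_subgraphs > 1
            ):
                value, d_logits = routing_balance(result, model_config.temperature)
                loss += train_config.balance_coeff * value
                extra_logit_grad = train_config.balance_coeff * d_logits
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss {loss} at epoch {epoch}; "
                    "check learning rate and regularization"
                )
            back = backward(params, result, g_er, g_ed, extra_logit_grad)
            for name in back:
                grads[name] += back[name]
            optimizer.step(params, grads)
            epoch_loss += loss
            n_batches += 1
        record = {"epoch": epoch, "loss": epoch_loss / n_batches}

        if val_mask is not None:
            result = forward(params, graph, model_config)
            scores = result.e_r @ result.e_d.T
            neg = ~(val_mask | train_mask)
            labels = np.concatenate(
                [np.ones(val_mask.sum()), np.zeros(neg.sum())]
            )
            vals = np.concatenate([scores[val_mask], scores[neg]])
            record["val_auc"] = auc_score(vals, labels)
            if record["val_auc"] > best_val:
                best_val = record["val_auc"]
                best_params = params.copy()
                patience_left = train_config.early_stop_patience
            elif train_config.early_stop_patience is not None:
                patience_left -= 1
                if patience_left <= 0:
                    history.append(record)
                    logger.info("early stop at epoch %d (best val AUC %.4f)", epoch, best_val)
                    params = best_params
                    break
        history.append(record)
    else:
        if val_mask is not None and best_params is not None:
            params = best_params

    return TrainResult(
        params=params, history=history, config=model_config, train_config=train_config
    )


def write_history_tsv(history: list[dict], path) -> None:
    """Per-epoch training log (epoch, loss, optional val AUC)."""
    from pathlib import Path

    keys = ["epoch", "loss"] + (["val_auc"] if any("val_auc" in h for h in history) else [])
    with Path(path).open("w") as fh:
        fh.write("\t".join(keys) + "\n")
        for rec in history:
            fh.write("\t".join(str(rec.get(k, "")) for k in keys) + "\n")
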