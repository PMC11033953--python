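"""Metrics and experiment harnesses: held-out evaluation, k-fold CV,
noise-sensitivity study, top-n candidate ranking.

Link-prediction convention: the positives of an evaluation are the held-out
association pairs; the negatives default to every (snoRNA, disease) cell that
is observed in neither the training nor the test set.  Accuracy additionally
needs a decision rule for an unbounded inner-product score, so it is computed
on a balanced sampled negative set after squashing scores through the
logistic sigma and thresholding at 0.5.  Test-time embeddings are always
propagated on the TRAINING graph only, so held-out edges never leak into the
message passing.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .data import AssociationTable, SplitPlan, inject_noise, make_folds, split_pairs
from .graph import BipartiteGraph, build_graph
from .model import ModelConfig, Parameters, forward, score_all
from .training import TrainConfig, TrainResult, train


def _check_labels(labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if len(labels) == 0 or labels.min() == labels.max():
        raise ValueError("labels must contain at least one positive and one negative")


def auc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve (equals the Mann-Whitney statistic; ties 1/2)."""
    _check_labels(labels)
    return float(roc_auc_score(labels, scores))


def aupr_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve via step interpolation."""
    _check_labels(labels)
    return float(average_precision_score(labels, scores))


def accuracy_from_scores(scores: np.ndarray, labels: np.ndarray) -> float:
    """Fraction correct after thresholding sigma(score) at 0.5 (score >= 0)."""
    _check_labels(labels)
    predicted = np.asarray(scores) >= 0.0
    return float(np.mean(predicted == np.asarray(labels).astype(bool)))


@dataclass(frozen=True)
class EvalResult:
    auc: float
    aupr: float
    accuracy: float

    def __post_init__(self) -> None:
        for value in (self.auc, self.aupr, self.accuracy):
            if not 0.0 <= value <= 1.0:
                raise ValueError("metrics must lie in [0, 1]")


@dataclass(frozen=True)
class CVResult:
    folds: tuple[EvalResult, ...]
    mean: EvalResult


def _mean_result(folds: list[EvalResult]) -> EvalResult:
    return EvalResult(
        auc=float(np.mean([f.auc for f in folds])),
        aupr=float(np.mean([f.aupr for f in folds])),
        accuracy=float(np.mean([f.accuracy for f in folds])),
    )


def evaluate_split(
    params: Parameters,
    model_config: ModelConfig,
    graph_train: BipartiteGraph,
    test_pairs: np.ndarray,
    neg_policy: str = "all",
    seed: int = 0,
) -> EvalResult:
    """Score a trained model on held-out positives.

    ``test_pairs`` is an (n, 2) array of (snoRNA, disease) index pairs.
    ``neg_policy`` selects the negative set for AUC/AUPR: "all" uses every
    cell absent from train and test, "balanced" a random sample of the same
    size as the positives.  Accuracy always uses the balanced set.
    """
    test_pairs = np.asarray(test_pairs)
    if len(test_pairs) == 0:
        raise ValueError("test set is empty")
    if neg_policy not in ("all", "balanced"):
        raise ValueError("neg_policy must be 'all' or 'balanced'")

    result = forward(params, graph_train, model_config)
    scores = score_all(result.e_r, result.e_d)

    pos_mask = np.zeros(scores.shape, dtype=bool)
    pos_mask[test_pairs[:, 0], test_pairs[:, 1]] = True
    train_mask = np.zeros(scores.shape, dtype=bool)
    train_mask[graph_train.edge_snorna, graph_train.edge_disease] = True
    neg_mask = ~(pos_mask | train_mask)

    pos_scores = scores[pos_mask]
    all_neg_scores = scores[neg_mask]
    rng = np.random.default_rng(seed)
    n_bal = min(len(pos_scores), len(all_neg_scores))
    balanced_neg = rng.choice(all_neg_scores, size=n_bal, replace=False)

    rank_neg = balanced_neg if neg_policy == "balanced" else all_neg_scores
    rank_scores = np.concatenate([pos_scores, rank_neg])
    rank_labels = np.concatenate([np.ones(len(pos_scores)), np.zeros(len(rank_neg))])
    acc_scores = np.concatenate([pos_scores, balanced_neg])
    acc_labels = np.concatenate([np.ones(len(pos_scores)), np.zeros(n_bal)])
    return EvalResult(
        auc=auc_score(rank_scores, rank_labels),
        aupr=aupr_score(rank_scores, rank_labels),
        accuracy=accuracy_from_scores(acc_scores, acc_labels),
    )


def cross_validate(
    model_config: ModelConfig,
    train_config: TrainConfig,
    table: AssociationTable,
    k: int = 5,
    seed: int = 0,
    neg_policy: str = "all",
) -> CVResult:
    """k-fold cross-validation over association pairs; the mean over folds is
    the headline result.  Each fold's model trains only on the other folds'
    edges, so no fold's test pair ever enters its training graph."""
    plan = make_folds(table, k, seed)
    idx = table.pair_indices()
    results: list[EvalResult] = []
    for f, fold in enumerate(plan.folds):
        train_pairs = np.concatenate([other for g, other in enumerate(plan.folds) if g != f])
        graph_train = build_graph(table, train_pairs)
        fitted = train(model_config, train_config, graph_train)
        results.append(
            evaluate_split(
                fitted.params, model_config, graph_train, idx[fold],
                neg_policy=neg_policy, seed=seed + f,
            )
        )
    return CVResult(folds=tuple(results), mean=_mean_result(results))


@dataclass(frozen=True)
class NoiseRun:
    target: str  # "train" or "test" (or "baseline")
    fraction: float
    result: EvalResult
    # fraction of injected test pairs scored below the decision threshold
    # (they are known false positives, so higher is better); None for
    # baseline and train-side injections
    audit_flagged_fraction: float | None = None


def noise_sensitivity(
    model_config: ModelConfig,
    train_config: TrainConfig,
    table: AssociationTable,
    fractions: tuple[float, ...] = (0.01, 0.05),
    targets: tuple[str, ...] = ("train", "test"),
    ratio: float = 0.8,
    seed: int = 0,
    neg_policy: str = "all",
) -> list[NoiseRun]:
    """Baseline plus each (target, fraction) perturbation of one fixed split.

    False associations equal to ``fraction`` of the total pair count are
    injected either into the training edges (the model trains on corrupted
    data, evaluation unchanged) or into the test positives (evaluation is
    corrupted).  For test-side injections the audit reports how many injected
    pairs the model scores below the sigma-0.5 threshold.
    """
    plan = split_pairs(table, ratio, seed)
    idx = table.pair_indices()

    def _run(tbl: AssociationTable, pl: SplitPlan, injected: np.ndarray, target: str):
        graph_train = build_graph(tbl, pl.train_pairs)
        fitted = train(model_config, train_config, graph_train)
        res = evaluate_split(
            fitted.params, model_config, graph_train, tbl.pair_indices()[pl.test_pairs],
            neg_policy=neg_policy, seed=seed,
        )
        audit = None
        if target == "test" and len(injected):
            fwd = forward(fitted.params, graph_train, model_config)
            scores = score_all(fwd.e_r, fwd.e_d)
            inj = tbl.pair_indices()[injected]
            audit = float(np.mean(scores[inj[:, 0], inj[:, 1]] < 0.0))
        return res, audit

    baseline, _ = _run(table, plan, np.empty(0, dtype=np.int64), "baseline")
    runs = [NoiseRun(target="baseline", fraction=0.0, result=baseline)]
    for target in targets:
        for fraction in fractions:
            noisy = inject_noise(table, fraction, target, plan, seed=seed + 1)
            res, audit = _run(noisy.table, noisy.plan, noisy.injected_pairs, target)
            runs.append(
                NoiseRun(target=target, fraction=fraction, result=res,
                         audit_flagged_fraction=audit)
            )
    return runs


def write_noise_tsv(runs: list[NoiseRun], path) -> None:
    from pathlib import Path

    with Path(path).open("w") as fh:
        fh.write("target\tfraction\tauc\taupr\taccuracy\taudit_flagged_fraction\n")
        for run in runs:
            audit = "" if run.audit_flagged_fraction is None else f"{run.audit_flagged_fraction:.4f}"
            fh.write(
                f"{run.target}\t{run.fraction}\t{run.result.auc:.4f}\t"
                f"{run.result.aupr:.4f}\t{run.result.accuracy:.4f}\t{audit}\n"
            )


@dataclass(frozen=True)
class RankedPredictions:
    """Descending-score candidate snoRNAs for one query disease."""

    disease: str
    snornas: tuple[str, ...]
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(a < b for a, b in zip(self.scores, self.scores[1:])):
            raise ValueError("scores must be non-increasing")


def rank_candidates(
    e_r: np.ndarray,
    e_d: np.ndarray,
    table: AssociationTable,
    graph_train: BipartiteGraph,
    query: str,
    top_n: int | None = None,
) -> RankedPredictions:
    """Rank snoRNAs without a known training edge to the query disease.

    Stable descending sort with index tie-break; an unknown disease name
    raises with close-match suggestions.
    """
    if query not in table.disease_index:
        close = difflib.get_close_matches(query, table.disease_index, n=5, cutoff=0.3)
        raise KeyError(f"unknown disease {query!r}; close matches: {close}")
    d = table.disease_index[query]
    known = set(graph_train.nbrs_of_disease(d).tolist())
    candidates = np.array(
        [r for r in range(table.n_snorna) if r not in known], dtype=np.int64
    )
    cand_scores = score_all(e_r, e_d)[candidates, d]
    order = np.argsort(-cand_scores, kind="stable")
    if top_n is not None:
        order = order[:top_n]
    names = table.snorna_names
    return RankedPredictions(
        disease=query,
        snornas=tuple(names[candidates[i]] for i in order),
        scores=tuple(float(cand_scores[i]) for i in order),
    )


def write_ranked_tsv(ranked: RankedPredictions, path) -> None:
    from pathlib import Path

    with Path(path).open("w") as fh:
        fh.write("rank\tsnorna\tdisease\tscore\n")
        for i, (name, value) in enumerate(zip(ranked.snornas, ranked.scores), start=1):
            fh.write(f"{i}\t{name}\t{ranked.disease}\t{value:.6g}\n")
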