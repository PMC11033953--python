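"""Embedding-space interpretability analyses.

The subgraph generator is meant to group snoRNAs with similar disease
neighborhoods, so a trained model should give the top-ranked candidate
snoRNAs of a disease mutually similar embeddings while bottom-ranked
candidates stay dissimilar.  This module computes those cosine-similarity
matrices and exports embeddings for external 2-D projection (e.g. t-SNE).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.metrics.pairwise import cosine_similarity as _sk_cosine

from .data import AssociationTable
from .evaluation import rank_candidates
from .graph import BipartiteGraph
from .model import score_all


def cosine_similarity_matrix(embeddings: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity; entries in [-1, 1], diagonal exactly 1."""
    embeddings = np.asarray(embeddings, dtype=float)
    norms = np.linalg.norm(embeddings, axis=1)
    zero = np.flatnonzero(norms == 0)
    if len(zero):
        raise ValueError(f"zero-norm embedding rows at indices {zero.tolist()}")
    sim = np.clip(_sk_cosine(embeddings), -1.0, 1.0)
    np.fill_diagonal(sim, 1.0)
    return sim


def off_diagonal_mean(matrix: np.ndarray) -> float:
    """Mean of the off-diagonal entries; 0.0 for a 1x1 matrix."""
    n = matrix.shape[0]
    if n < 2:
        return 0.0
    return float((matrix.sum() - np.trace(matrix)) / (n * (n - 1)))


@dataclass(frozen=True)
class TopBottomSimilarity:
    disease: str
    top_snornas: tuple[str, ...]
    bottom_snornas: tuple[str, ...]
    top_matrix: np.ndarray
    bottom_matrix: np.ndarray
    top_mean: float
    bottom_mean: float


def top_bottom_similarity(
    e_r: np.ndarray,
    e_d: np.ndarray,
    table: AssociationTable,
    graph_train: BipartiteGraph,
    disease: str,
    k: int = 10,
) -> TopBottomSimilarity:
    """Cosine matrices of the k highest- and k lowest-scored candidate
    snoRNAs for one disease, with their off-diagonal means as summaries."""
    ranked = rank_candidates(e_r, e_d, table, graph_train, disease)
    if len(ranked.snornas) < 2 * k:
        raise ValueError(
            f"need at least {2 * k} candidates, have {len(ranked.snornas)}"
        )
    top_names = ranked.snornas[:k]
    bottom_names = ranked.snornas[-k:]
    top_idx = [table.snorna_index[name] for name in top_names]
    bottom_idx = [table.snorna_index[name] for name in bottom_names]
    top_matrix = cosine_similarity_matrix(e_r[top_idx])
    bottom_matrix = cosine_similarity_matrix(e_r[bottom_idx])
    return TopBottomSimilarity(
        disease=disease,
        top_snornas=top_names,
        bottom_snornas=bottom_names,
        top_matrix=top_matrix,
        bottom_matrix=bottom_matrix,
        top_mean=off_diagonal_mean(top_matrix),
        bottom_mean=off_diagonal_mean(bottom_matrix),
    )


def export_embeddings(
    path: str | Path,
    embeddings: np.ndarray,
    names: list[str],
    families: list[str],
    groups: list[str] | None = None,
) -> None:
    """TSV export: node name, family, optional group label, coordinates.

    The full float precision is preserved so a reload reproduces downstream
    matrices bitwise.
    """
    embeddings = np.asarray(embeddings)
    if len(names) != len(embeddings) or len(families) != len(embeddings):
        raise ValueError("names/families must match embedding rows")
    dim = embeddings.shape[1] if embeddings.size else 0
    header = ["node", "family"] + (["group"] if groups is not None else [])
    header += [f"dim{i}" for i in range(dim)]
    with Path(path).open("w") as fh:
        fh.write("\t".join(header) + "\n")
        for i, row in enumerate(embeddings):
            cells = [names[i], families[i]]
            if groups is not None:
                cells.append(groups[i])
            cells += [row[j].hex() for j in range(dim)]
            fh.write("\t".join(cells) + "\n")


def load_embeddings(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Inverse of :func:`export_embeddings` (group column ignored if present)."""
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        has_group = "group" in header
        first_dim = 3 if has_group else 2
        names, families, rows = [], [], []
        for line in fh:
            cells = line.rstrip("\n").split("\t")
            names.append(cells[0])
            families.append(cells[1])
            rows.append([float.fromhex(c) for c in cells[first_dim:]])
    dim = len(header) - first_dim
    arr = np.array(rows) if rows else np.empty((0, dim))
    return arr, names, families


def similarity_heatmap_tsv(matrix: np.ndarray, names: tuple[str, ...], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("\t" + "\t".join(names) + "\n")
        for name, row in zip(names, matrix):
            fh.write(name + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def plot_similarity_heatmaps(result: TopBottomSimilarity, path: str | Path) -> None:
    """Optional rendering of the two heatmaps side by side (needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4.5))
    for ax, matrix, names, title in (
        (axes[0], result.top_matrix, result.top_snornas, "top-ranked"),
        (axes[1], result.bottom_matrix, result.bottom_snornas, "bottom-ranked"),
    ):
        im = ax.imshow(matrix, vmin=-1, vmax=1, cmap="RdBu_r")
        ax.set_title(f"{result.disease}: {title}")
        ax.set_xticks(range(len(names)), names, rotation=90, fontsize=6)
        ax.set_yticks(range(len(names)), names, fontsize=6)
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
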