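"""Association tables, train/test splits, cross-validation folds, noise injection.

The central container is :class:`AssociationTable`, the named edge list of the
bipartite snoRNA-disease graph together with bidirectional name<->index maps.
It realizes the binary association matrix ``SD``: ``SD[r, d] = 1`` iff the pair
(snoRNA ``r``, disease ``d``) is present.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_DELIMITERS = {"tsv": "\t", "csv": ","}

# header detection: exact field names only, so that real snoRNA identifiers
# (which often start with "SNO") are never mistaken for a header
_SNORNA_HEADERS = {"snorna", "sno_rna", "rna", "snorna_name", "name"}
_DISEASE_HEADERS = {"disease", "disease_name"}


@dataclass(frozen=True)
class AssociationTable:
    """De-duplicated snoRNA-disease pairs with first-appearance index maps."""

    pairs: tuple[tuple[str, str], ...]
    snorna_index: dict[str, int]
    disease_index: dict[str, int]

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate (snoRNA, disease) pairs")
        for name_map, side in ((self.snorna_index, 0), (self.disease_index, 1)):
            if sorted(name_map.values()) != list(range(len(name_map))):
                raise ValueError("index map is not a bijection onto [0, n)")
            for pair in self.pairs:
                if pair[side] not in name_map:
                    raise ValueError(f"name {pair[side]!r} missing from index map")

    @property
    def n_snorna(self) -> int:
        return len(self.snorna_index)

    @property
    def n_disease(self) -> int:
        return len(self.disease_index)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def snorna_names(self) -> list[str]:
        names = [""] * self.n_snorna
        for name, i in self.snorna_index.items():
            names[i] = name
        return names

    @property
    def disease_names(self) -> list[str]:
        names = [""] * self.n_disease
        for name, j in self.disease_index.items():
            names[j] = name
        return names

    def pair_indices(self) -> np.ndarray:
        """Integer pairs, shape (n_pairs, 2): column 0 snoRNA, column 1 disease."""
        if not self.pairs:
            return np.empty((0, 2), dtype=np.int64)
        return np.array(
            [(self.snorna_index[r], self.disease_index[d]) for r, d in self.pairs],
            dtype=np.int64,
        )

    def to_dense(self) -> np.ndarray:
        """The binary association matrix SD, shape (n_snorna, n_disease)."""
        sd = np.zeros((self.n_snorna, self.n_disease), dtype=np.int8)
        idx = self.pair_indices()
        sd[idx[:, 0], idx[:, 1]] = 1
        return sd

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "AssociationTable":
        """Build a table from raw pairs, dropping duplicates (logged) and
        assigning indices in first-appearance order."""
        seen: set[tuple[str, str]] = set()
        kept: list[tuple[str, str]] = []
        snorna_index: dict[str, int] = {}
        disease_index: dict[str, int] = {}
        n_dup = 0
        for r, d in pairs:
            if (r, d) in seen:
                n_dup += 1
                continue
            seen.add((r, d))
            kept.append((r, d))
            snorna_index.setdefault(r, len(snorna_index))
            disease_index.setdefault(d, len(disease_index))
        if n_dup:
            logger.info("dropped %d duplicate association pairs", n_dup)
        return cls(tuple(kept), snorna_index, disease_index)


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint train/test partition of pair indices of one table."""

    train_pairs: np.ndarray
    test_pairs: np.ndarray
    ratio: float
    seed: int

    def __post_init__(self) -> None:
        train = set(self.train_pairs.tolist())
        test = set(self.test_pairs.tolist())
        if train & test:
            raise ValueError("train/test pair sets overlap")


@dataclass(frozen=True)
class FoldPlan:
    """Near-equal disjoint folds covering all pair indices."""

    folds: tuple[np.ndarray, ...]
    seed: int


@dataclass(frozen=True)
class NoiseInjection:
    """Result of adding false-positive pairs to one partition.

    ``table`` extends the original table with the injected pairs; ``plan``
    points into the extended table; ``injected_pairs`` are the new pair
    indices so their predictions can be audited afterwards.
    """

    table: AssociationTable
    plan: SplitPlan
    injected_pairs: np.ndarray


def load_associations(path: str | Path, dialect: str = "tsv") -> AssociationTable:
    """Read a two-column (snoRNA, disease) edge list; extra columns ignored.

    Duplicates are dropped with a logged count and indices follow first
    appearance, so loading is deterministic for a given file.
    """
    if dialect not in _DELIMITERS:
        raise ValueError(f"dialect must be one of {sorted(_DELIMITERS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pairs: list[tuple[str, str]] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter=_DELIMITERS[dialect])
        for lineno, row in enumerate(reader, start=1):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}:{lineno}: expected >=2 columns, got {len(row)}")
            r, d = row[0].strip(), row[1].strip()
            if lineno == 1 and r.lower() in _SNORNA_HEADERS and d.lower() in _DISEASE_HEADERS:
                continue
            if not r or not d:
                raise ValueError(f"{path}:{lineno}: empty snoRNA or disease name")
            pairs.append((r, d))
    if not pairs:
        raise ValueError(f"{path}: no association rows found")
    return AssociationTable.from_pairs(pairs)


def write_associations(table: AssociationTable, path: str | Path, dialect: str = "tsv") -> None:
    """Write the de-duplicated pair list; round-trips through load_associations."""
    if dialect not in _DELIMITERS:
        raise ValueError(f"dialect must be one of {sorted(_DELIMITERS)}")
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=_DELIMITERS[dialect])
        writer.writerow(["snorna", "disease"])
        writer.writerows(table.pairs)


def load_association_matrix(path: str | Path) -> AssociationTable:
    """Read a dense 0/1 matrix CSV (rows snoRNAs, columns diseases, both named)."""
    frame = pd.read_csv(path, index_col=0)
    rows, cols = np.nonzero(frame.to_numpy() != 0)
    pairs = [(str(frame.index[i]), str(frame.columns[j])) for i, j in zip(rows, cols)]
    if not pairs:
        raise ValueError(f"{path}: association matrix has no nonzero entries")
    return AssociationTable.from_pairs(pairs)


def split_pairs(table: AssociationTable, ratio: float, seed: int) -> SplitPlan:
    """Random train/test split; |train| = round(ratio * n).

    round(0.8 * 1095) = 876 reproduces the reference 8:2 split counts.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie strictly between 0 and 1")
    n = table.n_pairs
    n_train = int(round(ratio * n))
    if n_train == 0 or n_train == n:
        raise ValueError(f"ratio {ratio} yields an empty partition for {n} pairs")
    perm = np.random.default_rng(seed).permutation(n)
    return SplitPlan(
        train_pairs=np.sort(perm[:n_train]),
        test_pairs=np.sort(perm[n_train:]),
        ratio=ratio,
        seed=seed,
    )


def make_folds(table: AssociationTable, k: int, seed: int) -> FoldPlan:
    """Random partition into k folds whose sizes differ by at most one."""
    n = table.n_pairs
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} pairs")
    perm = np.random.default_rng(seed).permutation(n)
    folds = tuple(np.sort(part) for part in np.array_split(perm, k))
    return FoldPlan(folds=folds, seed=seed)


def inject_noise(
    table: AssociationTable,
    fraction: float,
    target: str,
    plan: SplitPlan,
    seed: int,
) -> NoiseInjection:
    """Add round(fraction * n_pairs) false associations to one partition.

    The injected pairs are sampled uniformly from the non-associated cells of
    SD, appended to the table, and added to the chosen partition of the plan.
    They are returned separately so the audit of their predicted scores (they
    are known false positives) stays possible.
    """
    if target not in ("train", "test"):
        raise ValueError("target must be 'train' or 'test'")
    if fraction < 0:
        raise ValueError("fraction must be nonnegative")
    n_inject = int(round(fraction * table.n_pairs))
    if n_inject == 0:
        return NoiseInjection(table=table, plan=plan, injected_pairs=np.empty(0, dtype=np.int64))

    n, m = table.n_snorna, table.n_disease
    occupied = {r * m + d for r, d in table.pair_indices()}
    free = np.array([c for c in range(n * m) if c not in occupied], dtype=np.int64)
    if len(free) < n_inject:
        raise ValueError(f"only {len(free)} non-associated cells, need {n_inject}")
    chosen = np.random.default_rng(seed).choice(free, size=n_inject, replace=False)

    snorna_names = table.snorna_names
    disease_names = table.disease_names
    new_pairs = list(table.pairs) + [
        (snorna_names[c // m], disease_names[c % m]) for c in chosen
    ]
    new_table = AssociationTable(
        tuple(new_pairs), dict(table.snorna_index), dict(table.disease_index)
    )
    injected = np.arange(table.n_pairs, table.n_pairs + n_inject, dtype=np.int64)
    if target == "train":
        new_plan = replace(plan, train_pairs=np.sort(np.concatenate([plan.train_pairs, injected])))
    else:
        new_plan = replace(plan, test_pairs=np.sort(np.concatenate([plan.test_pairs, injected])))
    return NoiseInjection(table=new_table, plan=new_plan, injected_pairs=injected)


def write_split_manifest(plan: SplitPlan, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["pair_index", "partition"])
        for i in plan.train_pairs:
            writer.writerow([int(i), "train"])
        for i in plan.test_pairs:
            writer.writerow([int(i), "test"])


def write_fold_manifest(plan: FoldPlan, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["pair_index", "fold"])
        for f, fold in enumerate(plan.folds):
            for i in fold:
                writer.writerow([int(i), f])
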