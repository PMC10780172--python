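"""Association data handling: pair lists, adjacency matrices, splits.

The central object is :class:`AssociationDataset`, a named binary bipartite
matrix ``A`` (rows = miRNAs, columns = diseases) with ``A[i, j] = 1`` iff a
validated association between miRNA ``i`` and disease ``j`` is known.
Everything downstream (view construction, training, evaluation) consumes this
object. Internal indexing is 0-based; in the joint node space miRNAs occupy
``[0, m)`` and diseases ``[m, m + n)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AssociationDataset",
    "DatasetStats",
    "FoldSplit",
    "read_association_list",
    "write_association_list",
    "read_adjacency_csv",
    "dataset_stats",
    "sample_negatives",
    "kfold_split",
    "mask_test_edges",
]


@dataclass
class AssociationDataset:
    """A named binary miRNA-disease association matrix.

    Parameters
    ----------
    mirna_names : list of str
        Unique miRNA identifiers, row order of ``A``.
    disease_names : list of str
        Unique disease identifiers, column order of ``A``.
    A : ndarray of shape (m, n)
        Binary association matrix.
    """

    mirna_names: list[str]
    disease_names: list[str]
    A: np.ndarray

    def __post_init__(self):
        self.A = np.asarray(self.A)
        if self.A.ndim != 2:
            raise ValueError("A must be a 2-D matrix")
        if self.A.shape != (len(self.mirna_names), len(self.disease_names)):
            raise ValueError(
                f"A has shape {self.A.shape}, expected "
                f"({len(self.mirna_names)}, {len(self.disease_names)})"
            )
        if len(set(self.mirna_names)) != len(self.mirna_names):
            raise ValueError("duplicate miRNA names")
        if len(set(self.disease_names)) != len(self.disease_names):
            raise ValueError("duplicate disease names")
        vals = np.unique(self.A)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("A must be binary (0/1)")
        self.A = self.A.astype(np.int8)

    @property
    def m(self) -> int:
        return len(self.mirna_names)

    @property
    def n(self) -> int:
        return len(self.disease_names)

    @property
    def n_known(self) -> int:
        return int(self.A.sum())

    def positive_pairs(self) -> list[tuple[int, int]]:
        """All (i, j) with A[i, j] = 1, row-major order."""
        ii, jj = np.nonzero(self.A)
        return list(zip(ii.tolist(), jj.tolist()))

    def disease_index(self, name: str) -> int:
        try:
            return self.disease_names.index(name)
        except ValueError:
            raise KeyError(f"unknown disease: {name!r}") from None

    def copy(self) -> "AssociationDataset":
        return AssociationDataset(
            list(self.mirna_names), list(self.disease_names), self.A.copy()
        )


@dataclass
class DatasetStats:
    """Summary counts for an association dataset.

    ``sparse_ratio`` is known/(m*n), reported rounded to 4 decimals.
    """

    n_mirna: int
    n_disease: int
    known: int
    unknown: int
    sparse_ratio: float

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


@dataclass
class FoldSplit:
    """A k-fold partition of labeled (i, j, label) pairs."""

    k: int
    folds: list[list[tuple[int, int, int]]]
    seed: int

    def train_test(self, fold: int):
        """Return (train_pairs, test_pairs) for the given held-out fold."""
        test = self.folds[fold]
        train = [p for f, pairs in enumerate(self.folds) if f != fold for p in pairs]
        return train, test

    def to_json(self) -> str:
        return json.dumps(
            {"k": self.k, "seed": self.seed,
             "folds": [[list(t) for t in f] for f in self.folds]},
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "FoldSplit":
        d = json.loads(text)
        folds = [[tuple(t) for t in f] for f in d["folds"]]
        return cls(k=d["k"], folds=folds, seed=d["seed"])


def read_association_list(
    path, delimiter: str = "\t", header: bool = False
) -> AssociationDataset:
    """Read a two-column (miRNA, disease) pair list into a dataset.

    Duplicate pairs are collapsed; name order is first-appearance order.
    Name matching is exact and case-preserving.
    """
    mirnas: dict[str, int] = {}
    diseases: dict[str, int] = {}
    pairs: set[tuple[int, int]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split(delimiter)
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ValueError(
                    f"{path}: line {lineno}: expected at least 2 fields "
                    f"separated by {delimiter!r}"
                )
            mi, dz = fields[0].strip(), fields[1].strip()
            i = mirnas.setdefault(mi, len(mirnas))
            j = diseases.setdefault(dz, len(diseases))
            pairs.add((i, j))
    if not pairs:
        raise ValueError(f"{path}: no associations found")
    A = np.zeros((len(mirnas), len(diseases)), dtype=np.int8)
    for i, j in pairs:
        A[i, j] = 1
    return AssociationDataset(list(mirnas), list(diseases), A)


def write_association_list(ds: AssociationDataset, path, delimiter: str = "\t"):
    """Write the dataset's positive pairs as a two-column list."""
    with open(path, "w") as fh:
        for i, j in ds.positive_pairs():
            fh.write(f"{ds.mirna_names[i]}{delimiter}{ds.disease_names[j]}\n")


def read_adjacency_csv(path) -> AssociationDataset:
    """Read a dense adjacency CSV (header row/column carry the names)."""
    df = pd.read_csv(path, index_col=0)
    return AssociationDataset(
        [str(x) for x in df.index], [str(c) for c in df.columns], df.to_numpy()
    )


def dataset_stats(ds: AssociationDataset) -> DatasetStats:
    """Counts of known/unknown associations and the sparse ratio."""
    total = ds.m * ds.n
    known = ds.n_known
    return DatasetStats(
        n_mirna=ds.m,
        n_disease=ds.n,
        known=known,
        unknown=total - known,
        sparse_ratio=round(known / total, 4),
    )


def sample_negatives(
    ds: AssociationDataset, ratio: float = 1.0, seed: int = 0
) -> list[tuple[int, int]]:
    """Sample ``floor(ratio * known)`` unknown cells uniformly without replacement.

    Negatives are drawn once over the full unknown set (the cross-validation
    driver then splits them into folds together with the positives).
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    known = ds.n_known
    want = int(np.floor(ratio * known))
    zeros = np.flatnonzero(ds.A.ravel() == 0)
    if want > zeros.size:
        raise ValueError(
            f"not enough negatives: need {want}, only {zeros.size} unknown cells"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(zeros, size=want, replace=False)
    ii, jj = np.unravel_index(np.sort(chosen), ds.A.shape)
    return list(zip(ii.tolist(), jj.tolist()))


def kfold_split(
    pos: list[tuple[int, int]],
    neg: list[tuple[int, int]],
    k: int,
    seed: int = 0,
) -> FoldSplit:
    """Stratified k-fold partition of labeled pairs.

    Positives and negatives are shuffled and dealt separately so each fold's
    label balance is within +-1 of proportional; the larger negative chunks
    are paired with the smaller positive chunks so total fold sizes differ by
    at most 1.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(pos) + len(neg) < k:
        raise ValueError(f"k={k} exceeds sample count {len(pos) + len(neg)}")
    rng = np.random.default_rng(seed)
    pos = [tuple(p) for p in pos]
    neg = [tuple(p) for p in neg]
    pos_idx = rng.permutation(len(pos))
    neg_idx = rng.permutation(len(neg))
    pos_chunks = np.array_split(pos_idx, k)
    neg_chunks = np.array_split(neg_idx, k)[::-1]
    folds = []
    for pc, nc in zip(pos_chunks, neg_chunks):
        fold = [(pos[i][0], pos[i][1], 1) for i in pc] + [
            (neg[i][0], neg[i][1], 0) for i in nc
        ]
        order = rng.permutation(len(fold))
        folds.append([fold[i] for i in order])
    return FoldSplit(k=k, folds=folds, seed=seed)


def mask_test_edges(
    ds: AssociationDataset, test_pos: list[tuple[int, int]]
) -> AssociationDataset:
    """Copy of the dataset with the given known associations zeroed.

    Used for leakage control: a fold's held-out positives must not appear in
    any adjacency the model trains on.
    """
    out = ds.copy()
    for i, j in test_pos:
        if out.A[i, j] != 1:
            raise ValueError(f"pair ({i}, {j}) is not a known association")
        out.A[i, j] = 0
    return out
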