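"""Association matrix container, edge-list I/O, and labelled pair sampling.

The central object is the binary miRNA x disease adjacency matrix ``Y``:
``Y[i, j] == 1`` means the association between miRNA ``i`` and disease ``j``
is experimentally supported; ``0`` means unobserved (not necessarily absent).
Rows are always miRNAs and columns are always diseases.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AssociationDataset",
    "LabeledPairSet",
    "load_association_edges",
    "load_adjacency_csv",
    "sample_negatives",
]


@dataclasses.dataclass(frozen=True)
class AssociationDataset:
    """Binary miRNA-disease association matrix with identifier indices.

    Parameters
    ----------
    mirna_ids
        Ordered unique miRNA identifiers (row labels of ``Y``).
    disease_ids
        Ordered unique disease identifiers (column labels of ``Y``).
    Y
        Binary matrix of shape ``(len(mirna_ids), len(disease_ids))``.
    """

    mirna_ids: tuple[str, ...]
    disease_ids: tuple[str, ...]
    Y: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mirna_ids", tuple(self.mirna_ids))
        object.__setattr__(self, "disease_ids", tuple(self.disease_ids))
        Y = np.asarray(self.Y)
        if Y.ndim != 2:
            raise ValueError(f"Y must be 2-D, got shape {Y.shape}")
        if Y.shape != (len(self.mirna_ids), len(self.disease_ids)):
            raise ValueError(
                f"Y shape {Y.shape} does not match id lists "
                f"({len(self.mirna_ids)} miRNAs, {len(self.disease_ids)} diseases)"
            )
        if len(set(self.mirna_ids)) != len(self.mirna_ids):
            raise ValueError("duplicate miRNA identifiers")
        if len(set(self.disease_ids)) != len(self.disease_ids):
            raise ValueError("duplicate disease identifiers")
        if Y.size and not np.isin(Y, (0, 1)).all():
            raise ValueError("Y entries must be exactly 0 or 1")
        object.__setattr__(self, "Y", Y.astype(np.int8))

    @property
    def n_mirna(self) -> int:
        return len(self.mirna_ids)

    @property
    def n_disease(self) -> int:
        return len(self.disease_ids)

    @property
    def n_positives(self) -> int:
        return int(self.Y.sum())

    @property
    def density(self) -> float:
        """Fraction of cells that are 1 (edge count / cell count)."""
        if self.Y.size == 0:
            return 0.0
        return float(self.Y.sum()) / self.Y.size

    def mirna_index(self, mirna_id: str) -> int:
        return self.mirna_ids.index(mirna_id)

    def disease_index(self, disease_id: str) -> int:
        return self.disease_ids.index(disease_id)

    def with_matrix(self, Y: np.ndarray) -> "AssociationDataset":
        """Same identifiers, different matrix (e.g. after masking)."""
        return AssociationDataset(self.mirna_ids, self.disease_ids, Y)

    def to_edge_list(self, path: str | Path, sep: str = "\t") -> None:
        """Write the positive cells as a ``mirna_id, disease_id`` table."""
        rows, cols = np.nonzero(self.Y)
        pd.DataFrame(
            {
                "mirna_id": [self.mirna_ids[i] for i in rows],
                "disease_id": [self.disease_ids[j] for j in cols],
            }
        ).to_csv(path, sep=sep, index=False)

    def to_adjacency_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            self.Y, index=list(self.mirna_ids), columns=list(self.disease_ids)
        ).to_csv(path)


@dataclasses.dataclass(frozen=True)
class LabeledPairSet:
    """Labelled (miRNA index, disease index) pairs with provenance.

    ``provenance[r]`` is ``"known_positive"`` or ``"sampled_negative"`` for
    row ``r`` of ``pairs``; labels are consistent with provenance.
    """

    pairs: np.ndarray  # (n, 3) int array: mirna_index, disease_index, label
    provenance: tuple[str, ...]

    def __post_init__(self) -> None:
        pairs = np.asarray(self.pairs, dtype=np.int64).reshape(-1, 3)
        if len(pairs) != len(self.provenance):
            raise ValueError("provenance length does not match pair count")
        keys = set(map(tuple, pairs[:, :2]))
        if len(keys) != len(pairs):
            raise ValueError("duplicate (miRNA, disease) pairs")
        for row, tag in zip(pairs, self.provenance):
            expected = 1 if tag == "known_positive" else 0
            if row[2] != expected:
                raise ValueError(f"label {row[2]} inconsistent with provenance {tag!r}")
        object.__setattr__(self, "pairs", pairs)
        object.__setattr__(self, "provenance", tuple(self.provenance))

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def labels(self) -> np.ndarray:
        return self.pairs[:, 2]

    @property
    def n_positives(self) -> int:
        return int(self.labels.sum())

    @property
    def n_negatives(self) -> int:
        return len(self) - self.n_positives

    def subset(self, indices: np.ndarray) -> "LabeledPairSet":
        indices = np.asarray(indices)
        return LabeledPairSet(
            self.pairs[indices], tuple(self.provenance[i] for i in indices)
        )


def _read_edge_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["mirna_id", "disease_id"])
    if df.empty and not {"mirna_id", "disease_id"} <= set(df.columns):
        return pd.DataFrame(columns=["mirna_id", "disease_id"])
    missing = {"mirna_id", "disease_id"} - set(df.columns)
    if missing:
        raise ValueError(
            f"edge list {path} must have header columns mirna_id, disease_id "
            f"(missing {sorted(missing)})"
        )
    return df


def load_association_edges(
    path: str | Path,
    mirna_universe: Sequence[str] | None = None,
    disease_universe: Sequence[str] | None = None,
) -> AssociationDataset:
    """Load an edge list (TSV/CSV with header) into an association matrix.

    The file must have columns ``mirna_id`` and ``disease_id`` and may have a
    binary ``label`` column; rows without a label (or with label 1) become 1
    cells. Identifier universes default to the sorted distinct ids observed.

    Raises
    ------
    ValueError
        If a pair appears with conflicting labels, or an id falls outside a
        supplied universe.
    """
    df = _read_edge_table(path)
    if "label" in df.columns:
        labels = df["label"].astype(int)
    else:
        labels = pd.Series(np.ones(len(df), dtype=int), index=df.index)

    seen: dict[tuple[str, str], int] = {}
    for (m, d), lab in zip(zip(df.get("mirna_id", []), df.get("disease_id", [])), labels):
        if not m or not d or pd.isna(m) or pd.isna(d):
            raise ValueError(f"empty identifier in edge list {path}")
        key = (m, d)
        if key in seen and seen[key] != lab:
            raise ValueError(f"conflicting labels for pair ({m!r}, {d!r})")
        seen[key] = int(lab)

    observed_m = sorted({m for m, _ in seen})
    observed_d = sorted({d for _, d in seen})
    mirna_ids = list(mirna_universe) if mirna_universe is not None else observed_m
    disease_ids = list(disease_universe) if disease_universe is not None else observed_d

    m_index = {m: i for i, m in enumerate(mirna_ids)}
    d_index = {d: j for j, d in enumerate(disease_ids)}
    for m, d in seen:
        if m not in m_index:
            raise ValueError(f"miRNA id {m!r} not in supplied universe")
        if d not in d_index:
            raise ValueError(f"disease id {d!r} not in supplied universe")

    Y = np.zeros((len(mirna_ids), len(disease_ids)), dtype=np.int8)
    for (m, d), lab in seen.items():
        if lab == 1:
            Y[m_index[m], d_index[d]] = 1
    return AssociationDataset(tuple(mirna_ids), tuple(disease_ids), Y)


def load_adjacency_csv(path: str | Path) -> AssociationDataset:
    """Load a dense adjacency CSV (disease ids in header, miRNA ids in col 0)."""
    df = pd.read_csv(path, index_col=0)
    return AssociationDataset(
        tuple(str(i) for i in df.index),
        tuple(str(c) for c in df.columns),
        df.to_numpy(),
    )


def sample_negatives(
    dataset: AssociationDataset,
    n_negatives: int | None = None,
    seed: int = 0,
) -> LabeledPairSet:
    """All known positives plus uniformly sampled unobserved pairs as negatives.

    ``n_negatives`` defaults to the number of positives (a balanced set).
    Sampling is uniform without replacement over the zero cells of ``Y`` and
    reproducible for a fixed ``seed``.
    """
    pos = np.argwhere(dataset.Y == 1)
    zeros = np.argwhere(dataset.Y == 0)
    if n_negatives is None:
        n_negatives = len(pos)
    if n_negatives > len(zeros):
        raise ValueError(
            f"requested {n_negatives} negatives but only {len(zeros)} zero cells exist"
        )
    rng = np.random.default_rng(seed)
    chosen = zeros[rng.choice(len(zeros), size=n_negatives, replace=False)]
    pairs = np.vstack(
        [
            np.column_stack([pos, np.ones(len(pos), dtype=np.int64)]),
            np.column_stack([chosen, np.zeros(len(chosen), dtype=np.int64)]),
        ]
    )
    provenance = ("known_positive",) * len(pos) + ("sampled_negative",) * len(chosen)
    return LabeledPairSet(pairs, provenance)
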