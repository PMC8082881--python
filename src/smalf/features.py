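"""Per-pair feature fusion: latent codes concatenated with similarity profiles.

A (miRNA i, disease j) pair is represented by stacking the miRNA's latent
code with its full functional-similarity row, then the disease's latent code
with its full semantic-similarity row:

    [ latent_m[i] | FS[i, :] | latent_d[j] | SS[j, :] ]

On the reference data (latent 64, 495 miRNAs, 383 diseases) this gives a
559-dimensional miRNA block, a 447-dimensional disease block, and a
1006-dimensional fused vector. Missing similarity entries stay NaN.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .core_data import LabeledPairSet
from .latent import LatentFeatures
from .similarity import SimilarityMatrix

__all__ = ["PairFeatureTable", "build_pair_vector", "build_feature_table", "FEATURE_MODES"]

FEATURE_MODES = ("combined", "similarity_only", "latent_only")


@dataclasses.dataclass(frozen=True)
class PairFeatureTable:
    """Feature matrix for labelled pairs, with block offsets recorded.

    ``block_offsets`` maps block name -> (start, stop) column slice of ``X``;
    block order is [mirna_latent | mirna_similarity | disease_latent |
    disease_similarity], restricted to the blocks the mode selects.
    """

    X: np.ndarray
    y: np.ndarray
    pair_ids: tuple[tuple[str, str], ...]
    block_offsets: dict[str, tuple[int, int]]
    mode: str

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=int)
        if X.shape[0] != len(y) or X.shape[0] != len(self.pair_ids):
            raise ValueError("row count mismatch between X, y and pair ids")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "pair_ids", tuple(map(tuple, self.pair_ids)))

    def __len__(self) -> int:
        return len(self.y)

    @property
    def width(self) -> int:
        return self.X.shape[1]

    def block(self, name: str) -> np.ndarray:
        start, stop = self.block_offsets[name]
        return self.X[:, start:stop]

    def to_csv(self, path: str | Path) -> None:
        """Write the table as CSV plus a JSON sidecar with block metadata."""
        import pandas as pd

        path = Path(path)
        df = pd.DataFrame(self.X)
        df.insert(0, "mirna_id", [m for m, _ in self.pair_ids])
        df.insert(1, "disease_id", [d for _, d in self.pair_ids])
        df.insert(2, "label", self.y)
        df.to_csv(path, index=False)
        sidecar = {
            "mode": self.mode,
            "block_offsets": {k: list(v) for k, v in self.block_offsets.items()},
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(sidecar, indent=1))


def _check_alignment(
    latent_m: LatentFeatures, FS: SimilarityMatrix,
    latent_d: LatentFeatures, SS: SimilarityMatrix,
) -> None:
    for name, a, b in (
        ("miRNA", latent_m.ids, FS.ids),
        ("disease", latent_d.ids, SS.ids),
    ):
        if tuple(a) != tuple(b):
            mismatch = next(
                (i for i, (x, y) in enumerate(zip(a, b)) if x != y), min(len(a), len(b))
            )
            raise ValueError(
                f"{name} id order mismatch between latent features and similarity "
                f"matrix at position {mismatch}"
            )


def _blocks_for_mode(mode: str) -> tuple[str, ...]:
    if mode == "combined":
        return ("mirna_latent", "mirna_similarity", "disease_latent", "disease_similarity")
    if mode == "similarity_only":
        return ("mirna_similarity", "disease_similarity")
    if mode == "latent_only":
        return ("mirna_latent", "disease_latent")
    raise ValueError(f"unknown feature mode {mode!r}; expected one of {FEATURE_MODES}")


def build_pair_vector(
    m_index: int,
    d_index: int,
    latent_m: LatentFeatures,
    FS: SimilarityMatrix,
    latent_d: LatentFeatures,
    SS: SimilarityMatrix,
) -> np.ndarray:
    """Fused feature vector for one (miRNA, disease) pair (combined mode)."""
    _check_alignment(latent_m, FS, latent_d, SS)
    return np.concatenate(
        [
            latent_m.Z[m_index],
            FS.values[m_index],
            latent_d.Z[d_index],
            SS.values[d_index],
        ]
    )


def build_feature_table(
    pairs: LabeledPairSet,
    latent_m: LatentFeatures,
    FS: SimilarityMatrix,
    latent_d: LatentFeatures,
    SS: SimilarityMatrix,
    mode: str = "combined",
) -> PairFeatureTable:
    """Feature table for a labelled pair set; row order follows pair order."""
    blocks = _blocks_for_mode(mode)
    _check_alignment(latent_m, FS, latent_d, SS)
    mi = pairs.pairs[:, 0]
    dj = pairs.pairs[:, 1]
    sources = {
        "mirna_latent": latent_m.Z[mi],
        "mirna_similarity": FS.values[mi],
        "disease_latent": latent_d.Z[dj],
        "disease_similarity": SS.values[dj],
    }
    parts = [sources[b] for b in blocks]
    offsets: dict[str, tuple[int, int]] = {}
    start = 0
    for b, part in zip(blocks, parts):
        offsets[b] = (start, start + part.shape[1])
        start += part.shape[1]
    X = np.hstack(parts) if parts else np.empty((len(pairs), 0))
    pair_ids = tuple(
        (latent_m.ids[i], latent_d.ids[j]) for i, j in zip(mi, dj)
    )
    return PairFeatureTable(X, pairs.labels.copy(), pair_ids, offsets, mode)
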