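"""Metrics, k-fold cross-validation of the full pipeline, and candidate ranking.

AUC is the rank statistic (probability that a random positive outscores a
random negative, ties counted half); AUPR is the precision-recall integral.
Cross-validation splits the labelled pairs into k near-equal random folds.
Two leakage regimes are provided:

``masked``
    test-fold positives are zeroed in Y before latent-feature training and
    functional-similarity computation, so no test information reaches any
    training artifact (the honest evaluation);
``paper``
    latent features and functional similarity are computed once from the
    full Y, matching the pipeline description in which feature construction
    precedes the split.

The classifier itself is always trained on the training folds only.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .classifier import ClassifierConfig, train_classifier, predict_scores
from .core_data import AssociationDataset, LabeledPairSet, sample_negatives
from .features import build_feature_table
from .latent import AutoencoderConfig, encode, split_original_features, train_stacked_autoencoder
from .similarity import DiseaseDAG, SimilarityMatrix, disease_similarity_matrix, mirna_similarity_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "MetricsReport",
    "CVResult",
    "RankedCandidates",
    "compute_metrics",
    "kfold_split",
    "cross_validate",
    "rank_candidates_for_disease",
]

METRIC_NAMES = ("auc", "aupr", "precision", "recall", "f1", "accuracy")


@dataclasses.dataclass(frozen=True)
class MetricsReport:
    auc: float
    aupr: float
    precision: float
    recall: float
    f1: float
    accuracy: float
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class CVResult:
    """Per-fold metrics plus their mean and standard deviation."""

    fold_reports: tuple[MetricsReport, ...]
    fold_assignment: np.ndarray
    seed: int
    config: dict

    @property
    def k(self) -> int:
        return len(self.fold_reports)

    def mean(self, metric: str) -> float:
        return float(np.mean([getattr(r, metric) for r in self.fold_reports]))

    def std(self, metric: str) -> float:
        return float(np.std([getattr(r, metric) for r in self.fold_reports], ddof=1))

    def summary(self) -> dict:
        return {
            m: {"mean": self.mean(m), "std": self.std(m)} for m in METRIC_NAMES
        }

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "config": self.config,
            "summary": self.summary(),
            "folds": [r.as_dict() for r in self.fold_reports],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclasses.dataclass(frozen=True)
class RankedCandidates:
    """Scored candidate miRNAs for one disease, best first."""

    disease_id: str
    candidates: tuple[tuple[str, float], ...]  # every scored (mirna_id, score), non-increasing
    excluded: tuple[str, ...]
    top_n: int = 10

    def __post_init__(self) -> None:
        names = {m for m, _ in self.candidates}
        if names & set(self.excluded):
            raise ValueError("candidates overlap the excluded set")
        scores = [s for _, s in self.candidates]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError("candidate scores must be non-increasing")

    @property
    def n_candidates(self) -> int:
        return len(self.candidates)

    def top(self, n: int | None = None) -> tuple[tuple[str, float], ...]:
        return self.candidates[: (self.top_n if n is None else n)]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("rank\tmirna_id\tscore\n")
            for rank, (m, s) in enumerate(self.candidates, start=1):
                fh.write(f"{rank}\t{m}\t{s:.6f}\n")


def compute_metrics(
    labels: Sequence[int], scores: Sequence[float], threshold: float = 0.5
) -> MetricsReport:
    """ROC/PR areas and thresholded confusion-count metrics.

    A score >= ``threshold`` predicts a positive. Raises on single-class
    labels (AUC undefined).
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC is undefined for single-class labels")
    auc = float(roc_auc_score(labels, scores))
    aupr = float(average_precision_score(labels, scores))
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    accuracy = (tp + tn) / len(labels)
    return MetricsReport(auc, aupr, precision, recall, f1, accuracy, threshold, tp, fp, tn, fn)


def kfold_split(pairs: LabeledPairSet, k: int = 5, seed: int = 0) -> np.ndarray:
    """Random partition of the pairs into k near-equal folds (sizes differ <= 1)."""
    if k < 2:
        raise ValueError(f"k must be at least 2, got {k}")
    n = len(pairs)
    if n < k:
        raise ValueError(f"cannot split {n} pairs into {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    for fold, chunk in enumerate(np.array_split(order, k)):
        assignment[chunk] = fold
    return assignment


def _sub_seed(seed: int, *salt: int) -> int:
    return int(np.random.SeedSequence([seed, *salt]).generate_state(1)[0] % (2**31))


def _train_tower_features(
    dataset: AssociationDataset, ae_config: AutoencoderConfig | None, seed: int
):
    """Latent features for both towers of a (possibly masked) dataset."""
    M, Dt = split_original_features(dataset)
    feats = []
    for tower, (Xmat, ids) in enumerate(
        [(M, dataset.mirna_ids), (Dt, dataset.disease_ids)]
    ):
        cfg = ae_config if ae_config is not None else AutoencoderConfig.scaled(Xmat.shape[1])
        cfg = dataclasses.replace(cfg, seed=_sub_seed(seed, tower, cfg.seed))
        model = train_stacked_autoencoder(Xmat, cfg)
        feats.append(encode(model, Xmat, ids))
    return feats[0], feats[1]


def cross_validate(
    dataset: AssociationDataset,
    dag: DiseaseDAG,
    ae_config: AutoencoderConfig | None = None,
    clf_config: ClassifierConfig | None = None,
    mode: str = "combined",
    k: int = 5,
    seed: int = 0,
    leakage_mode: str = "masked",
    delta: float = 0.5,
    n_negatives: int | None = None,
    pairs: LabeledPairSet | None = None,
) -> CVResult:
    """k-fold cross-validation of the full pipeline.

    Pairs (all positives plus sampled negatives) are split into k folds; per
    fold the similarity and latent features are rebuilt from a masked Y
    (``leakage_mode='masked'``) or reused from the full Y (``'paper'``), the
    classifier is fitted on the training folds and scored on the test fold.
    """
    if leakage_mode not in ("masked", "paper"):
        raise ValueError(f"unknown leakage_mode {leakage_mode!r}")
    if clf_config is None:
        clf_config = ClassifierConfig(seed=_sub_seed(seed, 999))
    if pairs is None:
        pairs = sample_negatives(dataset, n_negatives=n_negatives, seed=_sub_seed(seed, 1))
    assignment = kfold_split(pairs, k=k, seed=_sub_seed(seed, 2))

    SS = disease_similarity_matrix(dag, list(dataset.disease_ids), delta=delta)

    if leakage_mode == "paper":
        full_latent_m, full_latent_d = _train_tower_features(dataset, ae_config, seed)
        full_FS = mirna_similarity_matrix(dataset, SS)

    reports = []
    for fold in range(k):
        test_idx = np.nonzero(assignment == fold)[0]
        train_idx = np.nonzero(assignment != fold)[0]
        if leakage_mode == "masked":
            Y_masked = dataset.Y.copy()
            test_pairs = pairs.pairs[test_idx]
            pos_mask = test_pairs[:, 2] == 1
            Y_masked[test_pairs[pos_mask, 0], test_pairs[pos_mask, 1]] = 0
            masked_ds = dataset.with_matrix(Y_masked)
            latent_m, latent_d = _train_tower_features(
                masked_ds, ae_config, _sub_seed(seed, 10 + fold)
            )
            FS = mirna_similarity_matrix(masked_ds, SS)
        else:
            latent_m, latent_d = full_latent_m, full_latent_d
            FS = full_FS

        train_table = build_feature_table(
            pairs.subset(train_idx), latent_m, FS, latent_d, SS, mode=mode
        )
        test_table = build_feature_table(
            pairs.subset(test_idx), latent_m, FS, latent_d, SS, mode=mode
        )
        fold_clf = dataclasses.replace(clf_config, seed=_sub_seed(seed, 100 + fold))
        model = train_classifier(train_table, fold_clf)
        scores = predict_scores(model, test_table)
        reports.append(compute_metrics(test_table.y, scores))
        logger.info("fold %d/%d: AUC %.4f", fold + 1, k, reports[-1].auc)

    config = {
        "mode": mode,
        "k": k,
        "leakage_mode": leakage_mode,
        "delta": delta,
        "classifier": dataclasses.asdict(clf_config),
        "autoencoder": dataclasses.asdict(ae_config) if ae_config is not None else "scaled-default",
    }
    return CVResult(tuple(reports), assignment, seed, config)


def rank_candidates_for_disease(
    dataset: AssociationDataset,
    dag: DiseaseDAG,
    disease_id: str,
    ae_config: AutoencoderConfig | None = None,
    clf_config: ClassifierConfig | None = None,
    mode: str = "combined",
    delta: float = 0.5,
    top_n: int = 10,
    seed: int = 0,
    n_negatives: int | None = None,
) -> RankedCandidates:
    """Leave-one-disease-out candidate ranking.

    All miRNAs known to associate with ``disease_id`` are removed from the
    candidate set and their entries zeroed in Y; the pipeline is retrained on
    the remaining associations and every unassociated miRNA is scored for the
    disease. Training negatives are sampled from zero cells outside the query
    disease's column so candidate cells are never trained on.
    """
    j = dataset.disease_index(disease_id)
    known = np.nonzero(dataset.Y[:, j])[0]
    candidates_idx = np.nonzero(dataset.Y[:, j] == 0)[0]
    if len(candidates_idx) == 0:
        raise ValueError(f"every miRNA is already associated with {disease_id!r}")

    Y_loo = dataset.Y.copy()
    Y_loo[:, j] = 0
    loo_ds = dataset.with_matrix(Y_loo)

    # training pairs: positives of the masked matrix + negatives outside column j
    pos = np.argwhere(Y_loo == 1)
    zeros = np.argwhere(Y_loo == 0)
    zeros = zeros[zeros[:, 1] != j]
    n_neg = len(pos) if n_negatives is None else n_negatives
    if n_neg > len(zeros):
        raise ValueError("not enough zero cells outside the query column for negatives")
    rng = np.random.default_rng(_sub_seed(seed, 3))
    neg = zeros[rng.choice(len(zeros), size=n_neg, replace=False)]
    pairs = LabeledPairSet(
        np.vstack(
            [
                np.column_stack([pos, np.ones(len(pos), dtype=np.int64)]),
                np.column_stack([neg, np.zeros(len(neg), dtype=np.int64)]),
            ]
        ),
        ("known_positive",) * len(pos) + ("sampled_negative",) * len(neg),
    )

    SS = disease_similarity_matrix(dag, list(dataset.disease_ids), delta=delta)
    latent_m, latent_d = _train_tower_features(loo_ds, ae_config, _sub_seed(seed, 4))
    FS = mirna_similarity_matrix(loo_ds, SS)

    train_table = build_feature_table(pairs, latent_m, FS, latent_d, SS, mode=mode)
    if clf_config is None:
        clf_config = ClassifierConfig(seed=_sub_seed(seed, 5))
    model = train_classifier(train_table, clf_config)

    cand_pairs = LabeledPairSet(
        np.column_stack(
            [candidates_idx, np.full(len(candidates_idx), j), np.zeros(len(candidates_idx), dtype=np.int64)]
        ),
        ("sampled_negative",) * len(candidates_idx),
    )
    cand_table = build_feature_table(cand_pairs, latent_m, FS, latent_d, SS, mode=mode)
    scores = predict_scores(model, cand_table)
    order = np.argsort(-scores, kind="stable")
    ranked = tuple(
        (dataset.mirna_ids[candidates_idx[i]], float(scores[i])) for i in order
    )
    return RankedCandidates(
        disease_id=disease_id,
        candidates=ranked,
        excluded=tuple(dataset.mirna_ids[i] for i in known),
        top_n=top_n,
    )
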