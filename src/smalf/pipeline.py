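"""End-to-end orchestration: resolved configs in, run directory out."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import yaml

from .classifier import ClassifierConfig
from .core_data import load_association_edges
from .evaluation import cross_validate, rank_candidates_for_disease
from .latent import AutoencoderConfig
from .similarity import DiseaseDAG, disease_similarity_matrix, mirna_similarity_matrix

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Fully serializable description of one pipeline run."""

    assoc_path: str
    dag_path: str
    annotation_path: str | None = None
    out_dir: str = "smalf_run"
    delta: float = 0.5
    mode: str = "combined"
    leakage_mode: str = "masked"
    folds: int = 5
    seed: int = 0
    classifier: str = "gbdt"
    latent_dim: int | None = None  # None -> architecture scaled to input width
    rank_disease: str | None = None
    top_n: int = 10

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


def run_pipeline(config: RunConfig) -> Path:
    """Run similarity -> latent -> fusion -> classifier -> CV (and optionally rank).

    Writes similarity matrices, the CV result JSON, the resolved config and a
    stage-timing manifest into ``config.out_dir``; returns that directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def stage(name: str):
        logger.info("stage: %s", name)
        return _Timer(name, timings)

    for path in (config.assoc_path, config.dag_path):
        if not Path(path).exists():
            raise FileNotFoundError(f"input file not found: {path}")
    if config.annotation_path is not None and not Path(config.annotation_path).exists():
        raise FileNotFoundError(f"input file not found: {config.annotation_path}")

    with stage("load"):
        dataset = load_association_edges(config.assoc_path)
        dag = DiseaseDAG.read_tsv(config.dag_path, config.annotation_path)

    with stage("similarity"):
        SS = disease_similarity_matrix(dag, list(dataset.disease_ids), delta=config.delta)
        SS.to_csv(out / "disease_semantic_similarity.csv")
        FS = mirna_similarity_matrix(dataset, SS)
        FS.to_csv(out / "mirna_functional_similarity.csv")

    ae_config = None
    if config.latent_dim is not None:
        ae_config = AutoencoderConfig(
            latent_dim=config.latent_dim,
            hidden_dims=(4 * config.latent_dim, config.latent_dim),
            seed=config.seed,
        )
    clf_config = ClassifierConfig(kind=config.classifier, seed=config.seed)

    with stage("cross_validation"):
        result = cross_validate(
            dataset,
            dag,
            ae_config=ae_config,
            clf_config=clf_config,
            mode=config.mode,
            k=config.folds,
            seed=config.seed,
            leakage_mode=config.leakage_mode,
            delta=config.delta,
        )
        result.to_json(out / "cv_result.json")

    if config.rank_disease is not None:
        with stage("rank"):
            ranked = rank_candidates_for_disease(
                dataset,
                dag,
                config.rank_disease,
                ae_config=ae_config,
                clf_config=clf_config,
                mode=config.mode,
                delta=config.delta,
                top_n=config.top_n,
                seed=config.seed,
            )
            ranked.to_tsv(out / f"candidates_{config.rank_disease}.tsv")

    config.to_yaml(out / "resolved_config.yaml")
    (out / "manifest.json").write_text(
        json.dumps({"seed": config.seed, "stage_seconds": timings}, indent=1)
    )
    return out


class _Timer:
    def __init__(self, name: str, sink: dict[str, float]):
        self.name, self.sink = name, sink

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, *exc):
        self.sink[self.name] = round(time.perf_counter() - self.t0, 3)
        return False
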