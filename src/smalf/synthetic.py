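"""Synthetic association datasets with planted block structure and a disease DAG.

The generator plants a stochastic block model on the bipartite miRNA-disease
graph: each miRNA and each disease belongs to one of ``k`` blocks, and a pair
is associated with probability ``p_in`` when the blocks match and ``p_out``
otherwise, with ``p_in : p_out`` fixed (20:1 by default) and both solved so
the expected density matches ``target_density``. This yields low-rank
structure for the autoencoder to compress. A random rooted DAG is built over
the diseases with one subtree per block, so DAG-based semantic similarity
correlates with block identity and the similarity features carry signal too.

A fraction of generated positives is withheld (set to 0 in Y) as held-out
truths for ranking experiments, and independent label-flip noise is applied.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import networkx as nx
import numpy as np

from .core_data import AssociationDataset
from .similarity import DiseaseDAG

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate_synthetic_dataset", "generate_random_dag"]


@dataclasses.dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; defaults emulate a sparse real association matrix."""

    n_mirna: int = 150
    n_disease: int = 100
    k: int = 4
    target_density: float = 0.03
    p_ratio: float = 20.0  # p_in / p_out
    noise_rate: float = 0.01
    holdout_fraction: float = 0.1
    dag_depth: int = 4
    dag_branching: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.target_density < 1:
            raise ValueError("target_density must lie in (0, 1)")
        if self.k > min(self.n_mirna, self.n_disease):
            raise ValueError("k exceeds the smaller side of the matrix")


@dataclasses.dataclass(frozen=True)
class SyntheticDataset:
    """Generated dataset plus its ground truth."""

    dataset: AssociationDataset
    dag: DiseaseDAG
    mirna_blocks: np.ndarray
    disease_blocks: np.ndarray
    held_out_positives: tuple[tuple[int, int], ...]  # (mirna_idx, disease_idx), 0 in Y
    config: SyntheticConfig

    def write(self, out_dir: str | Path) -> None:
        """Write edge list, DAG edges and annotation in the dialects the loaders read."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.dataset.to_edge_list(out / "associations.tsv")
        with open(out / "dag.tsv", "w") as fh:
            for parent, child in sorted(self.dag.graph.edges):
                fh.write(f"{parent}\t{child}\n")
        with open(out / "annotation.tsv", "w") as fh:
            for d in self.dataset.disease_ids:
                for t in self.dag.terms_for(d):
                    fh.write(f"{d}\t{t}\n")
        with open(out / "held_out_positives.tsv", "w") as fh:
            fh.write("mirna_id\tdisease_id\n")
            for i, j in self.held_out_positives:
                fh.write(f"{self.dataset.mirna_ids[i]}\t{self.dataset.disease_ids[j]}\n")


def generate_random_dag(
    n_terms: int,
    depth: int = 4,
    branching: int = 3,
    seed: int = 0,
    term_ids: list[str] | None = None,
    extra_edge_prob: float = 0.0,
) -> DiseaseDAG:
    """Single-rooted random DAG; every term reachable from the root.

    Nodes are attached one by one to a uniformly chosen existing parent whose
    depth is below ``depth``, preferring parents with fewer than ``branching``
    children. With ``extra_edge_prob`` > 0, additional cross edges from
    strictly shallower nodes are added (keeping the graph acyclic).
    """
    if n_terms < 1:
        raise ValueError("n_terms must be at least 1")
    rng = np.random.default_rng(seed)
    ids = term_ids if term_ids is not None else [f"t{i}" for i in range(n_terms)]
    if len(ids) != n_terms:
        raise ValueError("term_ids length does not match n_terms")
    g = nx.DiGraph()
    g.add_node(ids[0])
    node_depth = {ids[0]: 0}
    for node in ids[1:]:
        eligible = [u for u in g.nodes if node_depth[u] < depth]
        preferred = [u for u in eligible if g.out_degree(u) < branching]
        pool = preferred or eligible
        parent = pool[rng.integers(len(pool))]
        g.add_edge(parent, node)
        node_depth[node] = node_depth[parent] + 1
        if extra_edge_prob > 0:
            shallower = [u for u in g.nodes if node_depth[u] < node_depth[node] and u != parent]
            if shallower and rng.random() < extra_edge_prob:
                g.add_edge(shallower[rng.integers(len(shallower))], node)
    return DiseaseDAG(g)


def _block_dag(
    disease_ids: tuple[str, ...],
    disease_blocks: np.ndarray,
    k: int,
    depth: int,
    branching: int,
    rng: np.random.Generator,
) -> DiseaseDAG:
    """Rooted DAG with one subtree per block; disease terms live in their subtree."""
    g = nx.DiGraph()
    root = "root"
    g.add_node(root)
    node_depth = {root: 0}
    for b in range(k):
        block_root = f"block_{b}"
        g.add_edge(root, block_root)
        node_depth[block_root] = 1
        members = [disease_ids[j] for j in np.nonzero(disease_blocks == b)[0]]
        attachable = [block_root]
        for node in members:
            preferred = [u for u in attachable if g.out_degree(u) < branching]
            pool = preferred or attachable
            parent = pool[rng.integers(len(pool))]
            g.add_edge(parent, node)
            node_depth[node] = node_depth[parent] + 1
            if node_depth[node] < depth:
                attachable.append(node)
    annotation = {d: (d,) for d in disease_ids}
    return DiseaseDAG(g, annotation)


def generate_synthetic_dataset(config: SyntheticConfig | None = None, **overrides) -> SyntheticDataset:
    """Generate a planted-block association dataset with a matching disease DAG.

    Reproducible for a fixed ``config.seed``; raises if the requested density
    is infeasible for the block ratio.
    """
    if config is None:
        config = SyntheticConfig(**overrides)
    elif overrides:
        config = dataclasses.replace(config, **overrides)
    rng = np.random.default_rng(config.seed)

    mirna_ids = tuple(f"mirna_{i:03d}" for i in range(config.n_mirna))
    disease_ids = tuple(f"disease_{j:03d}" for j in range(config.n_disease))
    mirna_blocks = rng.integers(config.k, size=config.n_mirna)
    disease_blocks = rng.integers(config.k, size=config.n_disease)

    same = mirna_blocks[:, None] == disease_blocks[None, :]
    f_same = same.mean()
    # target_density refers to the delivered matrix: invert the expected effect
    # of label-flip noise and positive holdout on the base block-model density
    r, h = config.noise_rate, config.holdout_fraction
    base_density = (config.target_density / (1.0 - h) - r) / (1.0 - 2.0 * r)
    if base_density <= 0:
        raise ValueError(
            f"target density {config.target_density} infeasible under noise_rate {r}"
        )
    # base_density = f_same * p_in + (1 - f_same) * p_out with p_in = ratio * p_out
    p_out = base_density / (f_same * config.p_ratio + (1.0 - f_same))
    p_in = config.p_ratio * p_out
    if p_in > 1.0:
        raise ValueError(
            f"target density {config.target_density} infeasible: implied p_in={p_in:.3f} > 1"
        )

    probs = np.where(same, p_in, p_out)
    Y = (rng.random(probs.shape) < probs).astype(np.int8)
    if config.noise_rate > 0:
        flips = rng.random(Y.shape) < config.noise_rate
        Y = np.where(flips, 1 - Y, Y).astype(np.int8)

    ones = np.argwhere(Y == 1)
    n_holdout = int(round(config.holdout_fraction * len(ones)))
    held_out: tuple[tuple[int, int], ...] = ()
    if n_holdout:
        chosen = ones[rng.choice(len(ones), size=n_holdout, replace=False)]
        Y[chosen[:, 0], chosen[:, 1]] = 0
        held_out = tuple((int(i), int(j)) for i, j in chosen)

    dag = _block_dag(
        disease_ids, disease_blocks, config.k, config.dag_depth, config.dag_branching, rng
    )
    dataset = AssociationDataset(mirna_ids, disease_ids, Y)
    return SyntheticDataset(dataset, dag, mirna_blocks, disease_blocks, held_out, config)
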