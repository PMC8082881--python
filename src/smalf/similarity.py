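"""Disease semantic similarity over an ontology DAG and miRNA functional similarity.

Disease similarity follows the decayed-contribution scheme commonly used with
MeSH descriptor hierarchies: each disease term ``D`` induces a sub-DAG of its
ancestors; an ancestor ``d`` contributes ``1`` if ``d == D`` and otherwise the
maximum over its children (within the sub-DAG) of ``delta`` times the child's
contribution. The semantic value ``DV(D)`` is the sum of contributions, and
the similarity between two terms is the sum of their shared ancestors'
contributions normalised by ``DV(d_i) + DV(d_j)``.

miRNA functional similarity is the best-match average (BMA) of the disease
semantic similarities between the two miRNAs' associated disease sets.

Missing values (diseases absent from the DAG, miRNAs with no associations)
are represented as NaN, never silently as 0 — downstream gradient boosting
handles them natively.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .core_data import AssociationDataset

logger = logging.getLogger(__name__)

__all__ = [
    "DiseaseDAG",
    "ContributionMap",
    "SimilarityMatrix",
    "semantic_contributions",
    "disease_semantic_similarity",
    "disease_similarity_matrix",
    "mirna_functional_similarity",
    "mirna_similarity_matrix",
]


@dataclasses.dataclass(frozen=True)
class DiseaseDAG:
    """Rooted DAG(s) over disease terms, edges directed parent -> child.

    ``annotation`` maps dataset disease ids to one or more DAG term ids;
    when omitted, disease ids are assumed to be term ids themselves.
    """

    graph: nx.DiGraph
    annotation: Mapping[str, tuple[str, ...]] | None = None

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise ValueError(f"disease DAG contains a cycle: {cycle}")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        terms: Iterable[str] | None = None,
        annotation: Mapping[str, Sequence[str]] | None = None,
    ) -> "DiseaseDAG":
        g = nx.DiGraph()
        if terms is not None:
            g.add_nodes_from(terms)
        g.add_edges_from(edges)
        ann = (
            {k: tuple(v) for k, v in annotation.items()} if annotation is not None else None
        )
        return cls(g, ann)

    @classmethod
    def read_tsv(
        cls, path: str | Path, annotation_path: str | Path | None = None
    ) -> "DiseaseDAG":
        """Read ``parent<TAB>child`` edges, optionally ``disease<TAB>term`` annotation."""
        edges_df = pd.read_csv(path, sep="\t", header=None, names=["parent", "child"], dtype=str)
        annotation = None
        if annotation_path is not None:
            ann_df = pd.read_csv(
                annotation_path, sep="\t", header=None, names=["disease", "term"], dtype=str
            )
            annotation = {
                str(d): tuple(sub["term"]) for d, sub in ann_df.groupby("disease", sort=True)
            }
        return cls.from_edges(zip(edges_df["parent"], edges_df["child"]), annotation=annotation)

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def terms_for(self, disease_id: str) -> tuple[str, ...]:
        """DAG terms annotated to a dataset disease id (empty if unmapped)."""
        if self.annotation is not None:
            return tuple(t for t in self.annotation.get(disease_id, ()) if t in self.graph)
        return (disease_id,) if disease_id in self.graph else ()

    def ancestor_closure(self, term: str) -> set[str]:
        """T(term): the term and all its ancestors."""
        if term not in self.graph:
            raise KeyError(f"term {term!r} not in the disease DAG")
        return nx.ancestors(self.graph, term) | {term}


@dataclasses.dataclass(frozen=True)
class ContributionMap:
    """Decayed contributions of every ancestor of ``focus`` to ``focus``."""

    focus: str
    contributions: Mapping[str, float]
    semantic_value: float


@dataclasses.dataclass(frozen=True)
class SimilarityMatrix:
    """Square symmetric similarity matrix in [0, 1]; NaN marks missing."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "ids", tuple(self.ids))
        values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if values.shape != (n, n):
            raise ValueError(f"values shape {values.shape} does not match {n} ids")
        finite = np.isfinite(values)
        if finite.any() and ((values[finite] < -1e-12) | (values[finite] > 1 + 1e-12)).any():
            raise ValueError("similarity values must lie in [0, 1]")
        with np.errstate(invalid="ignore"):
            asym = np.nanmax(np.abs(values - values.T), initial=0.0)
        if asym > 1e-9:
            raise ValueError(f"similarity matrix not symmetric (max deviation {asym:g})")
        object.__setattr__(self, "values", values)

    def row(self, identifier: str) -> np.ndarray:
        return self.values[self.ids.index(identifier)]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids)).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(tuple(str(i) for i in df.index), df.to_numpy(dtype=float))


def semantic_contributions(dag: DiseaseDAG, D: str, delta: float = 0.5) -> ContributionMap:
    """Contribution of each ancestor of ``D`` to ``D`` under decay ``delta``.

    The focus term contributes 1; any other ancestor ``d`` contributes the
    maximum over its children inside the ancestor closure of ``delta`` times
    the child's contribution. The semantic value is the sum over the closure.
    """
    if not 0 < delta < 1:
        raise ValueError(f"delta must lie in (0, 1), got {delta}")
    closure = dag.ancestor_closure(D)  # raises KeyError if absent
    contributions: dict[str, float] = {D: 1.0}

    def value(d: str) -> float:
        if d in contributions:
            return contributions[d]
        children = sorted(c for c in dag.graph.successors(d) if c in closure)
        v = max(delta * value(c) for c in children)
        contributions[d] = v
        return v

    # Iterate in reverse topological order of the closure so recursion depth
    # stays shallow even on deep DAGs.
    for d in reversed(list(nx.topological_sort(dag.graph.subgraph(closure)))):
        value(d)
    return ContributionMap(D, contributions, float(sum(contributions.values())))


def disease_semantic_similarity(
    dag: DiseaseDAG, d_i: str, d_j: str, delta: float = 0.5
) -> float:
    """Shared-ancestor contribution sum normalised by the two semantic values."""
    ci = semantic_contributions(dag, d_i, delta)
    cj = semantic_contributions(dag, d_j, delta)
    shared = set(ci.contributions) & set(cj.contributions)
    numer = sum(ci.contributions[t] + cj.contributions[t] for t in shared)
    return numer / (ci.semantic_value + cj.semantic_value)


def disease_similarity_matrix(
    dag: DiseaseDAG, disease_ids: Sequence[str], delta: float = 0.5
) -> SimilarityMatrix:
    """Pairwise semantic similarity for a list of dataset disease ids.

    Diseases annotated to several DAG terms take the maximum pairwise term
    similarity. Diseases with no DAG term get NaN off-diagonal and 1 on the
    diagonal.
    """
    if len(disease_ids) == 0:
        raise ValueError("disease id list is empty")
    term_lists = [dag.terms_for(d) for d in disease_ids]
    unmapped = [d for d, ts in zip(disease_ids, term_lists) if not ts]
    if unmapped:
        logger.warning(
            "%d disease(s) have no DAG term and get missing similarities: %s",
            len(unmapped), unmapped[:5],
        )
    cmaps = {
        t: semantic_contributions(dag, t, delta)
        for ts in term_lists
        for t in ts
    }

    def term_ss(a: str, b: str) -> float:
        ca, cb = cmaps[a], cmaps[b]
        shared = set(ca.contributions) & set(cb.contributions)
        numer = sum(ca.contributions[t] + cb.contributions[t] for t in shared)
        return numer / (ca.semantic_value + cb.semantic_value)

    n = len(disease_ids)
    values = np.full((n, n), np.nan)
    np.fill_diagonal(values, 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            if term_lists[i] and term_lists[j]:
                values[i, j] = values[j, i] = max(
                    term_ss(a, b) for a in term_lists[i] for b in term_lists[j]
                )
    return SimilarityMatrix(tuple(disease_ids), values)


def _bma(sub: np.ndarray) -> float:
    """Best-match average over an |D_i| x |D_j| block of disease similarities."""
    with np.errstate(all="ignore"):
        row_best = np.nanmax(sub, axis=1)
        col_best = np.nanmax(sub, axis=0)
    terms = np.concatenate([row_best, col_best])
    valid = np.isfinite(terms)
    if not valid.any():
        return np.nan
    return float(terms[valid].sum() / valid.sum())


def mirna_functional_similarity(
    dataset: AssociationDataset, SS: SimilarityMatrix, m_i: int, m_j: int
) -> float:
    """BMA similarity between two miRNAs' associated disease sets.

    Returns NaN (a missing marker, not 0) when either miRNA has no
    associated disease.
    """
    if tuple(SS.ids) != dataset.disease_ids:
        raise ValueError("disease similarity matrix ids do not match the dataset")
    di = np.nonzero(dataset.Y[m_i])[0]
    dj = np.nonzero(dataset.Y[m_j])[0]
    if len(di) == 0 or len(dj) == 0:
        logger.warning(
            "miRNA %s has no associated diseases; functional similarity is missing",
            dataset.mirna_ids[m_i if len(di) == 0 else m_j],
        )
        return np.nan
    if m_i == m_j:
        return 1.0
    return _bma(SS.values[np.ix_(di, dj)])


def mirna_similarity_matrix(
    dataset: AssociationDataset, SS: SimilarityMatrix
) -> SimilarityMatrix:
    """Full pairwise miRNA functional similarity matrix (NaN where undefined)."""
    if tuple(SS.ids) != dataset.disease_ids:
        raise ValueError("disease similarity matrix ids do not match the dataset")
    n = dataset.n_mirna
    disease_sets = [np.nonzero(dataset.Y[i])[0] for i in range(n)]
    empty = [i for i, ds in enumerate(disease_sets) if len(ds) == 0]
    if empty:
        logger.warning(
            "%d miRNA(s) have no associations; their functional similarities are missing",
            len(empty),
        )
    values = np.full((n, n), np.nan)
    np.fill_diagonal(values, 1.0)
    for i in range(n):
        if len(disease_sets[i]) == 0:
            continue
        for j in range(i + 1, n):
            if len(disease_sets[j]) == 0:
                continue
            values[i, j] = values[j, i] = _bma(
                SS.values[np.ix_(disease_sets[i], disease_sets[j])]
            )
    return SimilarityMatrix(dataset.mirna_ids, values)
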