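"""Shared fixtures: small hand-built graphs and seeded random generators."""

from __future__ import annotations

import numpy as np
import pytest

from goranker import AnnotationSet, OntologyGraph
from goranker.scores import ScoreMatrix


def make_graph(parents: dict[str, set[str]], ns: str = "MF") -> OntologyGraph:
    """Build a single-namespace graph from a parent mapping."""
    return OntologyGraph(
        namespace_of={t: ns for t in parents},
        parents_of={t: frozenset(ps) for t, ps in parents.items()},
    )


@pytest.fixture
def chain_graph() -> OntologyGraph:
    """r <- a <- leaf."""
    return make_graph({"GO:0000001": set(), "GO:0000002": {"GO:0000001"},
                       "GO:0000003": {"GO:0000002"}})


@pytest.fixture
def diamond_graph() -> OntologyGraph:
    """r <- a, r <- b, a <- c, b <- c."""
    return make_graph(
        {
            "GO:0000001": set(),
            "GO:0000002": {"GO:0000001"},
            "GO:0000003": {"GO:0000001"},
            "GO:0000004": {"GO:0000002", "GO:0000003"},
        }
    )


def random_dag(rng: np.random.Generator, n_terms: int | None = None):
    """Random rooted single-namespace parent mapping (<= 30 terms)."""
    n = n_terms or int(rng.integers(3, 31))
    terms = [f"GO:{i:07d}" for i in range(1, n + 1)]
    parents: dict[str, set[str]] = {terms[0]: set()}
    for i in range(1, n):
        k = int(rng.integers(1, min(i, 2) + 1))
        idx = rng.choice(i, size=k, replace=False)
        parents[terms[i]] = {terms[j] for j in idx}
    return parents


def random_annotations(
    rng: np.random.Generator, terms: list[str], n_proteins: int = 6
) -> AnnotationSet:
    out = {}
    for i in range(n_proteins):
        k = int(rng.integers(1, min(4, len(terms)) + 1))
        idx = rng.choice(len(terms), size=k, replace=False)
        out[f"P{i}"] = {terms[j] for j in idx}
    return AnnotationSet(out)


def random_instance(rng: np.random.Generator, max_proteins: int = 8, max_terms: int = 15):
    """A random evaluation instance: truth sets, sparse scores, ia values."""
    n_p = int(rng.integers(2, max_proteins + 1))
    n_t = int(rng.integers(3, max_terms + 1))
    terms = [f"GO:{i:07d}" for i in range(1, n_t + 1)]
    truth = {}
    pred = {}
    for i in range(n_p):
        p = f"P{i}"
        k = int(rng.integers(1, n_t + 1))
        truth[p] = {terms[j] for j in rng.choice(n_t, size=k, replace=False)}
        m = int(rng.integers(0, n_t + 1))
        row = {
            terms[j]: float(np.round(rng.uniform(0.01, 1.0), 3))
            for j in rng.choice(n_t, size=m, replace=False)
        }
        if row:
            pred[p] = row
    ia = {t: float(np.round(rng.uniform(0.0, 3.0), 3)) for t in terms}
    return truth, pred, ia


def to_matrix(pred: dict[str, dict[str, float]], source: str = "test") -> ScoreMatrix:
    return ScoreMatrix(pred, source=source)
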