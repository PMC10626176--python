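"""Component predictors.

Five predictors map a query protein to GO-term scores in (0, 1]:

* **naive** — the training-corpus frequency of each term, identical for
  every query; the floor any useful method must beat.
* **blast_knn** — bitscore-weighted vote over the query's top homology hits
  into the annotated training set.
* **lr** on k-mer features, domain features or pooled embeddings — one
  independent L2-regularised one-vs-rest logistic model per sufficiently
  frequent term.
* **net_knn** — weight-normalised vote over the query's direct neighbours
  in a protein network.

All outputs are :class:`~goranker.scores.ScoreMatrix` instances restricted
to one namespace; scores below a small sparsity floor are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from .annotations import AnnotationSet
from .exceptions import ConfigError, FitError, ValidationError
from .features import EmbeddingMatrix, FeatureTable
from .scores import ScoreMatrix

logger = logging.getLogger(__name__)

#: Predicted scores below this are dropped from sparse outputs; the floor
#: sits just below the lowest threshold of the evaluation grid.
SCORE_FLOOR = 0.01

DEFAULT_TOP_K_HITS = 50
DEFAULT_MIN_TRAIN_COUNT = 10


class Hit(NamedTuple):
    query: str
    subject: str
    identity: float  # fraction in [0, 1]
    bitscore: float


@dataclass
class HitTable:
    """Homology hits, held per query in bitscore-descending order."""

    by_query: dict[str, list[Hit]]

    @classmethod
    def from_hits(cls, hits: Iterable[Hit]) -> "HitTable":
        by_query: dict[str, list[Hit]] = {}
        for h in hits:
            if h.bitscore <= 0:
                raise ValidationError(f"bitscore must be positive: {h}")
            if not 0.0 <= h.identity <= 1.0:
                raise ValidationError(f"identity outside [0, 1]: {h}")
            by_query.setdefault(h.query, []).append(h)
        for q in by_query:
            by_query[q].sort(key=lambda h: (-h.bitscore, h.subject))
        return cls(by_query)

    def queries(self) -> set[str]:
        return set(self.by_query)

    def max_identity(self, train_proteins: Iterable[str]) -> dict[str, float]:
        """Best identity per query against a training-protein set."""
        train = set(train_proteins)
        out: dict[str, float] = {}
        for q, hits in self.by_query.items():
            ids = [h.identity for h in hits if h.subject in train and h.subject != q]
            if ids:
                out[q] = max(ids)
        return out


def read_hit_table(path_or_handle) -> HitTable:
    """BLAST tabular (outfmt 6 style): qseqid sseqid pident ... bitscore.

    Only the first, second, third and last columns are used; percent
    identity is converted to a fraction.
    """
    df = pd.read_csv(path_or_handle, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 4:
        raise ValidationError("hit table needs >= 4 columns")
    return HitTable.from_hits(
        Hit(
            query=row.iloc[0],
            subject=row.iloc[1],
            identity=float(row.iloc[2]) / 100.0,
            bitscore=float(row.iloc[-1]),
        )
        for _, row in df.iterrows()
    )


def write_hit_table(hits: HitTable, handle) -> None:
    for q in sorted(hits.by_query):
        for h in hits.by_query[q]:
            handle.write(
                f"{h.query}\t{h.subject}\t{h.identity * 100:.1f}\t0\t0\t0\t"
                f"0\t0\t0\t0\t0.0\t{h.bitscore:.1f}\n"
            )


# -------------------------------------------------------------------- naive
def fit_naive(train: AnnotationSet) -> dict[str, float]:
    """Per-term prior = fraction of training proteins annotated with it."""
    if not train:
        raise FitError("empty training set")
    n = len(train.proteins)
    return {t: c / n for t, c in sorted(train.counts().items())}

def predict_naive(priors: Mapping[str, float], proteins: Iterable[str]) -> ScoreMatrix:
    out = ScoreMatrix(source="naive")
    row = {t: p for t, p in priors.items() if p > 0.0}
    for protein in proteins:
        out.set_row(protein, row)
    return out


# ---------------------------------------------------------------- blast-knn
def predict_blast_knn(
    hits: HitTable,
    train: AnnotationSet,
    top_k: int = DEFAULT_TOP_K_HITS,
) -> ScoreMatrix:
    """Bitscore-weighted annotation transfer from top homology hits.

    For query q with retained hits H (the ``top_k`` highest-bitscore hits
    whose subjects carry training annotations, self-hits excluded)::

        score(q, t) = sum_{h in H, t in ann(subject(h))} bits(h) / sum_{h in H} bits(h)

    Queries with no retained hit are absent from the output.
    """
    if top_k < 1:
        raise ConfigError(f"top_k must be >= 1, got {top_k}")
    out = ScoreMatrix(source="blast_knn")
    for query, qhits in hits.by_query.items():
        retained = [
            h for h in qhits if h.subject != query and h.subject in train.by_protein
        ][:top_k]
        if not retained:
            continue
        denom = sum(h.bitscore for h in retained)
        votes: dict[str, float] = {}
        for h in retained:
            for t in train.by_protein[h.subject]:
                votes[t] = votes.get(t, 0.0) + h.bitscore
        out.set_row(query, {t: min(1.0, v / denom) for t, v in votes.items()})
    return out


# ---------------------------------------------------------------------- LR
@dataclass
class LrModel:
    """One-vs-rest logistic models over a fixed feature space."""

    terms: list[str]
    weights: np.ndarray  # (n_terms, n_features)
    intercepts: np.ndarray  # (n_terms,)
    n_features: int
    min_train_count: int
    source: str = "lr"

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.weights)) and np.all(np.isfinite(self.intercepts))):
            raise ValidationError("non-finite LR parameters")


def _design(features: FeatureTable | EmbeddingMatrix, accessions: Sequence[str]):
    return features.design_matrix(accessions)


def fit_lr(
    features: FeatureTable | EmbeddingMatrix,
    train: AnnotationSet,
    min_train_count: int = DEFAULT_MIN_TRAIN_COUNT,
    regularization: float = 1.0,
    source: str = "lr",
) -> LrModel:
    """Fit one regularised logistic model per sufficiently frequent term.

    Positives for term t are the training proteins annotated with t; all
    other training proteins of the namespace are negatives.  Terms with
    fewer than ``min_train_count`` positives, or with no negatives, are
    skipped.
    """
    if min_train_count < 1:
        raise ConfigError("min_train_count must be >= 1")
    proteins = sorted(p for p in train.proteins if p in features)
    missing = train.proteins - set(proteins)
    if missing:
        logger.warning("%d training proteins lack features", len(missing))
    if not proteins:
        raise FitError("no training protein has features")
    X = _design(features, proteins)
    n_features = X.shape[1]

    terms: list[str] = []
    weights: list[np.ndarray] = []
    intercepts: list[float] = []
    for term, count in sorted(train.counts().items()):
        y = np.fromiter(
            (1 if train.has(p, term) else 0 for p in proteins), dtype=int
        )
        pos = int(y.sum())
        if pos < min_train_count:
            continue
        if pos == len(proteins):
            logger.warning("term %s has no negatives; skipped", term)
            continue
        # L2 penalty (the solver default) at strength C=regularization
        clf = LogisticRegression(C=regularization, solver="lbfgs", max_iter=1000)
        clf.fit(X, y)
        terms.append(term)
        weights.append(clf.coef_[0])
        intercepts.append(float(clf.intercept_[0]))

    return LrModel(
        terms=terms,
        weights=np.array(weights) if weights else np.zeros((0, n_features)),
        intercepts=np.array(intercepts),
        n_features=n_features,
        min_train_count=min_train_count,
        source=source,
    )


def predict_lr(
    model: LrModel,
    features: FeatureTable | EmbeddingMatrix,
    proteins: Sequence[str] | None = None,
    floor: float = SCORE_FLOOR,
) -> ScoreMatrix:
    """Logistic scores for every modelled term; entries below ``floor`` drop."""
    if proteins is None:
        proteins = [a for a in features.accessions]
    proteins = [p for p in proteins if p in features]
    out = ScoreMatrix(source=model.source)
    if not proteins or not model.terms:
        return out
    X = _design(features, proteins)
    if X.shape[1] != model.n_features:
        raise ValidationError(
            f"feature dimension {X.shape[1]} != model dimension {model.n_features}"
        )
    if sparse.issparse(X):
        linear = np.asarray(X @ model.weights.T) + model.intercepts
    else:
        linear = X @ model.weights.T + model.intercepts
    probs = expit(linear)
    for i, protein in enumerate(proteins):
        row = {
            model.terms[j]: float(probs[i, j])
            for j in range(len(model.terms))
            if probs[i, j] >= floor
        }
        out.set_row(protein, row)
    return out


# ------------------------------------------------------------------ net-knn
@dataclass
class Network:
    """Undirected weighted protein network; weights in (0, 1]."""

    edges: dict[str, dict[str, float]] = field(default_factory=dict)

    @classmethod
    def from_edge_list(cls, triples: Iterable[tuple[str, str, float]]) -> "Network":
        net = cls()
        for a, b, w in triples:
            if w < 0:
                raise ValidationError(f"negative edge weight: {a} {b} {w}")
            if w == 0 or a == b:
                continue
            if w > 1:
                raise ValidationError(f"edge weight above 1: {a} {b} {w}")
            net.edges.setdefault(a, {})[b] = float(w)
            net.edges.setdefault(b, {})[a] = float(w)
        return net

    def neighbors(self, protein: str) -> dict[str, float]:
        return dict(self.edges.get(protein, {}))


def read_network(path_or_handle, scale: float = 1.0) -> Network:
    """Three-column TSV edge list; STRING-style 0-1000 weights pass
    ``scale=1000`` to land in (0, 1]."""
    df = pd.read_csv(path_or_handle, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 3:
        raise ValidationError("network file needs 3 columns")
    return Network.from_edge_list(
        (row.iloc[0], row.iloc[1], float(row.iloc[2]) / scale)
        for _, row in df.iterrows()
    )


def write_network(net: Network, handle) -> None:
    seen = set()
    for a in sorted(net.edges):
        for b, w in sorted(net.edges[a].items()):
            if (b, a) in seen:
                continue
            seen.add((a, b))
            handle.write(f"{a}\t{b}\t{w:.6f}\n")


def predict_net_knn(
    network: Network,
    train: AnnotationSet,
    queries: Iterable[str] | None = None,
) -> ScoreMatrix:
    """Weight-normalised neighbour voting over direct network neighbours.

    ``score(q, t)`` is the weight fraction of q's annotated neighbours that
    carry t; queries with no annotated neighbour are absent.
    """
    out = ScoreMatrix(source="net_knn")
    if queries is None:
        queries = sorted(network.edges)
    for q in queries:
        annotated = {
            v: w for v, w in network.neighbors(q).items() if v in train.by_protein
        }
        if not annotated:
            continue
        denom = sum(annotated.values())
        votes: dict[str, float] = {}
        for v, w in annotated.items():
            for t in train.by_protein[v]:
                votes[t] = votes.get(t, 0.0) + w
        out.set_row(q, {t: min(1.0, v / denom) for t, v in votes.items()})
    return out
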