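"""Learning-to-rank ensemble over component predictors.

Candidate (protein, term) pairs are pooled from each component's per-protein
top-k terms; each candidate's feature vector is the tuple of component
scores (0 where a component is silent).  A pairwise gradient-boosted ranking
model (LambdaMART-style, grouped by protein) is trained on the validation
split of the time-split benchmark, where the relevance label is membership
in the propagated truth.  A linear logistic stacker serves as the
configurable alternative and as the fallback for degenerate candidate
pools; if labels are constant the ensemble degrades to the mean of the
component scores.

Raw ranking scores are scale-free, so predictions are min-max normalised
per protein into (0, 1] before the hierarchy is enforced with
score propagation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lightgbm import LGBMRanker
from sklearn.linear_model import LogisticRegression

from .exceptions import FitError, ValidationError
from .ontology import OntologyGraph, propagate_scores
from .scores import ScoreMatrix

logger = logging.getLogger(__name__)

#: Floor for the per-protein min-max normalisation: the weakest candidate of
#: a protein keeps this score instead of vanishing from the sparse matrix.
NORM_FLOOR = 0.001


@dataclass
class LtrConfig:
    learner: str = "gbm"  # "gbm" | "logistic" | "mean"
    top_k_per_component: int = 100
    seed: int = 17
    n_estimators: int = 200
    num_leaves: int = 15
    learning_rate: float = 0.1
    min_child_samples: int = 5
    #: pools smaller than this (groups or positives) use the logistic fallback
    min_groups: int = 10
    min_positives: int = 5


@dataclass
class CandidateSet:
    """Candidate (protein, term) pairs with component-score features."""

    component_names: list[str]
    pairs: list[tuple[str, str]]
    features: np.ndarray  # (n_pairs, n_components)
    labels: np.ndarray | None = None  # 1 = pair in propagated truth

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.shape != (len(self.pairs), len(self.component_names)):
            raise ValidationError("candidate feature shape mismatch")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape[0] != len(self.pairs):
                raise ValidationError("candidate label length mismatch")

    def __len__(self) -> int:
        return len(self.pairs)

    def group_sizes(self) -> list[int]:
        """Run lengths of consecutive pairs sharing a protein (pairs are
        kept sorted by protein)."""
        sizes: list[int] = []
        last: str | None = None
        for protein, _ in self.pairs:
            if protein != last:
                sizes.append(1)
                last = protein
            else:
                sizes[-1] += 1
        return sizes

    def with_labels(self, truth) -> "CandidateSet":
        labels = np.fromiter(
            (1 if truth.has(p, t) else 0 for p, t in self.pairs), dtype=int
        )
        return CandidateSet(self.component_names, self.pairs, self.features, labels)


def select_candidates(
    component_matrices: Sequence[ScoreMatrix],
    top_k_per_component: int = 100,
) -> CandidateSet:
    """Union of each protein's top-k terms per component, with features.

    Per component and protein, the ``top_k_per_component`` highest-scoring
    terms (ties broken by term id) enter the pool; the feature vector of a
    pair holds every component's score for it, 0 where absent.
    """
    names = [m.source or f"component{i}" for i, m in enumerate(component_matrices)]
    if not component_matrices or all(not m for m in component_matrices):
        logger.warning("no component scores; empty candidate set")
        return CandidateSet(names, [], np.zeros((0, len(names))))
    proteins = sorted(set().union(*(m.proteins for m in component_matrices)))
    pairs: list[tuple[str, str]] = []
    for protein in proteins:
        terms: set[str] = set()
        for m in component_matrices:
            row = m.row(protein)
            top = sorted(row.items(), key=lambda kv: (-kv[1], kv[0]))
            terms.update(t for t, _ in top[:top_k_per_component])
        pairs.extend((protein, t) for t in sorted(terms))
    features = np.array(
        [[m.get(p, t) for m in component_matrices] for p, t in pairs]
    )
    return CandidateSet(names, pairs, features)


# ------------------------------------------------------------------- models
class _MeanModel:
    kind = "mean"

    def predict(self, X: np.ndarray) -> np.ndarray:
        return X.mean(axis=1)


class _LogisticStacker:
    kind = "logistic"

    def __init__(self, clf: LogisticRegression) -> None:
        self._clf = clf

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._clf.decision_function(X)


class _GbmRanker:
    kind = "gbm"

    def __init__(self, booster: LGBMRanker, feature_names: list[str]) -> None:
        self._booster = booster
        self._feature_names = feature_names

    def predict(self, X: np.ndarray) -> np.ndarray:
        frame = pd.DataFrame(X, columns=self._feature_names)
        return self._booster.predict(frame)


@dataclass
class LtrModel:
    """A trained ranking model with its component ordering."""

    component_names: list[str]
    config: LtrConfig
    _inner: object = field(default=None, repr=False)

    def predict_raw(self, candidates: CandidateSet) -> np.ndarray:
        if candidates.component_names != self.component_names:
            raise ValidationError(
                f"component ordering mismatch: model {self.component_names}, "
                f"candidates {candidates.component_names}"
            )
        if not len(candidates):
            return np.zeros(0)
        scores = np.asarray(self._inner.predict(candidates.features), dtype=float)
        if not np.all(np.isfinite(scores)):
            raise ValidationError("ranking model produced non-finite scores")
        return scores

    @property
    def kind(self) -> str:
        return self._inner.kind


def train_ltr(candidates: CandidateSet, config: LtrConfig | None = None) -> LtrModel:
    """Fit the ranking model on a labeled candidate pool.

    Uses the configured learner; degrades to logistic stacking when the pool
    is too small for pairwise ranking, and to the mean of components when
    the labels are constant.  Deterministic given ``config.seed``.
    """
    config = config or LtrConfig()
    if candidates.labels is None:
        raise FitError("train_ltr needs labeled candidates")
    y = candidates.labels
    if len(candidates) == 0:
        raise FitError("empty candidate pool")
    if y.min() == y.max():
        logger.warning("constant relevance labels; using mean-of-components")
        return LtrModel(candidates.component_names, config, _MeanModel())
    if len(candidates.component_names) == 1:
        # a single component: the ensemble is that component's ranking
        return LtrModel(candidates.component_names, config, _MeanModel())

    groups = candidates.group_sizes()
    n_pos = int(y.sum())
    learner = config.learner
    if learner == "gbm" and (
        len(groups) < config.min_groups or n_pos < config.min_positives
    ):
        logger.warning(
            "degenerate pool (%d groups, %d positives); logistic fallback",
            len(groups),
            n_pos,
        )
        learner = "logistic"

    if learner == "mean":
        inner: object = _MeanModel()
    elif learner == "logistic":
        clf = LogisticRegression(C=1.0, solver="lbfgs", max_iter=1000)
        clf.fit(candidates.features, y)
        inner = _LogisticStacker(clf)
    elif learner == "gbm":
        ranker = LGBMRanker(
            objective="lambdarank",
            n_estimators=config.n_estimators,
            num_leaves=config.num_leaves,
            learning_rate=config.learning_rate,
            min_child_samples=config.min_child_samples,
            random_state=config.seed,
            deterministic=True,
            force_row_wise=True,
            n_jobs=1,
            verbose=-1,
        )
        names = list(candidates.component_names)
        ranker.fit(pd.DataFrame(candidates.features, columns=names), y, group=groups)
        inner = _GbmRanker(ranker, names)
    else:
        raise FitError(f"unknown learner {config.learner!r}")
    return LtrModel(candidates.component_names, config, inner)


def predict_ensemble(
    model: LtrModel,
    candidates: CandidateSet,
    graph: OntologyGraph,
) -> ScoreMatrix:
    """Score candidates, normalise per protein into (0, 1], enforce hierarchy.

    Min-max normalisation maps each protein's strongest candidate to 1.0;
    a protein whose candidates all tie maps them all to 1.0.  The weakest
    candidate is floored at a small positive value so it stays in the
    sparse matrix.
    """
    raw = model.predict_raw(candidates)
    out = ScoreMatrix(source="ensemble")
    by_protein: dict[str, dict[str, float]] = {}
    for (protein, term), score in zip(candidates.pairs, raw):
        by_protein.setdefault(protein, {})[term] = float(score)
    for protein, row in by_protein.items():
        lo, hi = min(row.values()), max(row.values())
        if hi > lo:
            norm = {
                t: max((s - lo) / (hi - lo), NORM_FLOOR) for t, s in row.items()
            }
        else:
            norm = {t: 1.0 for t in row}
        out.set_row(protein, norm)
    return propagate_scores(graph, out)
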