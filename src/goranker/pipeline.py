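"""End-to-end workflow: fit components, train the ranking ensemble,
predict and evaluate.

This module wires the library together the way the command-line interface
uses it: components are fitted per namespace on the training split of a
time-split benchmark; the ranking ensemble is trained on candidates scored
for the validation proteins (never on training-split annotations); the
resulting :class:`Predictor` artifact carries everything prediction needs,
including the training annotations that the homology- and network-voting
components consume at query time.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .annotations import (
    AnnotationSet,
    BenchmarkSplit,
    group_terms_by_count,
)
from .components import (
    DEFAULT_MIN_TRAIN_COUNT,
    DEFAULT_TOP_K_HITS,
    HitTable,
    LrModel,
    Network,
    fit_lr,
    fit_naive,
    predict_blast_knn,
    predict_lr,
    predict_naive,
    predict_net_knn,
)
from .ensemble import (
    CandidateSet,
    LtrConfig,
    LtrModel,
    predict_ensemble,
    select_candidates,
    train_ltr,
)
from .evaluation import MetricConfig, fmax
from .exceptions import ConfigError
from .features import (
    EmbeddingMatrix,
    FeatureTable,
    SequenceRecord,
    kmer_feature_table,
)
from .ontology import ICTable, OntologyGraph, information_accretion, propagate_scores
from .scores import ScoreMatrix

logger = logging.getLogger(__name__)

ALL_COMPONENTS = ("naive", "blast_knn", "lr_kmer", "lr_embed", "net_knn")


@dataclass(frozen=True)
class PipelineConfig:
    components: tuple[str, ...] = ALL_COMPONENTS
    kmer_k: int = 3
    top_k_hits: int = DEFAULT_TOP_K_HITS
    min_train_count: int = DEFAULT_MIN_TRAIN_COUNT
    regularization: float = 1.0
    ltr: LtrConfig = field(default_factory=LtrConfig)
    seed: int = 17

    def __post_init__(self) -> None:
        unknown = set(self.components) - set(ALL_COMPONENTS)
        if unknown:
            raise ConfigError(f"unknown components: {sorted(unknown)}")
        if not self.components:
            raise ConfigError("at least one component must be enabled")


@dataclass
class StudyInputs:
    """Everything a study needs besides annotations: the ontology plus the
    per-protein feature sources each enabled component consumes."""

    graph: OntologyGraph
    sequences: list[SequenceRecord] = field(default_factory=list)
    embeddings: EmbeddingMatrix | None = None
    hits: HitTable | None = None
    network: Network | None = None

    def require(self, components: Iterable[str]) -> None:
        needs = {
            "blast_knn": self.hits,
            "lr_kmer": self.sequences or None,
            "lr_embed": self.embeddings,
            "net_knn": self.network,
        }
        for c in components:
            if c in needs and needs[c] is None:
                raise ConfigError(f"component {c!r} enabled but its input is missing")


@dataclass
class Predictor:
    """The trained artifact: per-namespace component models + ranking model."""

    graph: OntologyGraph
    config: PipelineConfig
    train: AnnotationSet  # propagated, all namespaces
    namespaces: list[str]
    priors: dict[str, dict[str, float]] = field(default_factory=dict)
    lr_kmer: dict[str, LrModel] = field(default_factory=dict)
    lr_embed: dict[str, LrModel] = field(default_factory=dict)
    kmer_vocabulary: list[str] = field(default_factory=list)
    ltr: dict[str, LtrModel] = field(default_factory=dict)
    ic: dict[str, ICTable] = field(default_factory=dict)
    term_groups: dict[str, dict[str, str]] = field(default_factory=dict)
    validation_fmax: dict[str, dict[str, float]] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh, protocol=4)

    @classmethod
    def load(cls, path: str | Path) -> "Predictor":
        with open(path, "rb") as fh:
            obj = pickle.load(fh)
        if not isinstance(obj, cls):
            raise ConfigError(f"{path} is not a predictor artifact")
        return obj


def _kmer_table(
    sequences: Sequence[SequenceRecord], k: int, vocabulary: Sequence[str] | None
) -> FeatureTable:
    return kmer_feature_table(sequences, k=k, vocabulary=vocabulary)


def predict_components(
    predictor: Predictor,
    inputs: StudyInputs,
    queries: Sequence[str],
    ns: str,
) -> list[ScoreMatrix]:
    """Run every enabled component on the queries, hierarchy-propagated.

    Components are returned in the fixed configuration order so candidate
    feature vectors line up with the trained ranking model.
    """
    graph = predictor.graph
    train_ns = predictor.train.restrict_namespace(graph, ns)
    cfg = predictor.config
    matrices: list[ScoreMatrix] = []
    for component in cfg.components:
        if component == "naive":
            m = predict_naive(predictor.priors[ns], queries)
        elif component == "blast_knn":
            m = predict_blast_knn(inputs.hits, train_ns, top_k=cfg.top_k_hits)
            m = _restrict(m, queries, source="blast_knn")
        elif component == "lr_kmer":
            seqs = [s for s in inputs.sequences if s.accession in set(queries)]
            table = _kmer_table(seqs, cfg.kmer_k, predictor.kmer_vocabulary)
            m = predict_lr(predictor.lr_kmer[ns], table)
            m.source = "lr_kmer"
        elif component == "lr_embed":
            m = predict_lr(
                predictor.lr_embed[ns],
                inputs.embeddings,
                proteins=[q for q in queries if q in inputs.embeddings],
            )
            m.source = "lr_embed"
        elif component == "net_knn":
            m = predict_net_knn(inputs.network, train_ns, queries=queries)
        else:  # pragma: no cover - guarded by PipelineConfig
            raise ConfigError(component)
        propagated = propagate_scores(graph, m)
        propagated.source = m.source
        propagated.namespace = ns
        matrices.append(propagated)
    return matrices


def _restrict(m: ScoreMatrix, queries: Sequence[str], source: str) -> ScoreMatrix:
    qs = set(queries)
    out = ScoreMatrix(source=source)
    for p, row in m.rows():
        if p in qs:
            out.set_row(p, row)
    return out


def fit_predictor(
    inputs: StudyInputs,
    split: BenchmarkSplit,
    config: PipelineConfig | None = None,
    namespaces: Sequence[str] | None = None,
) -> Predictor:
    """Fit components on the training split and the ranker on validation.

    The per-namespace validation Fmax of every component and of the
    ensemble is recorded in ``validation_fmax`` (the training log).
    """
    config = config or PipelineConfig()
    inputs.require(config.components)
    graph = inputs.graph
    namespaces = list(namespaces or sorted(set(graph.namespace_of.values())))

    predictor = Predictor(
        graph=graph,
        config=config,
        train=split.train,
        namespaces=namespaces,
    )

    train_proteins = sorted(split.train.proteins)
    train_seqs = [s for s in inputs.sequences if s.accession in set(train_proteins)]
    if "lr_kmer" in config.components:
        train_table = _kmer_table(train_seqs, config.kmer_k, None)
        predictor.kmer_vocabulary = list(train_table.columns)

    for ns in namespaces:
        train_ns = split.train.restrict_namespace(graph, ns)
        if not train_ns:
            raise ConfigError(f"no training annotations in namespace {ns}")
        predictor.ic[ns] = information_accretion(graph, train_ns)
        predictor.term_groups[ns] = group_terms_by_count(train_ns)
        if "naive" in config.components:
            predictor.priors[ns] = fit_naive(train_ns)
        if "lr_kmer" in config.components:
            predictor.lr_kmer[ns] = fit_lr(
                train_table,
                train_ns,
                min_train_count=config.min_train_count,
                regularization=config.regularization,
                source="lr_kmer",
            )
        if "lr_embed" in config.components:
            predictor.lr_embed[ns] = fit_lr(
                inputs.embeddings,
                train_ns,
                min_train_count=config.min_train_count,
                regularization=config.regularization,
                source="lr_embed",
            )

        # ---- ranking model on the validation split
        val_proteins = sorted(split.validation_proteins.get(ns, ()))
        val_truth = split.validation_truth.get(ns, AnnotationSet())
        matrices = predict_components(predictor, inputs, val_proteins, ns)
        candidates = select_candidates(
            matrices, top_k_per_component=config.ltr.top_k_per_component
        ).with_labels(val_truth)
        ltr_config = replace(config.ltr, seed=config.seed)
        predictor.ltr[ns] = train_ltr(candidates, ltr_config)

        # training log: per-component and ensemble validation Fmax
        metric_cfg = MetricConfig(roots=graph.root_terms(), namespace=ns)
        log: dict[str, float] = {}
        if val_truth:
            for m in matrices:
                try:
                    log[m.source] = fmax(val_truth, m, metric_cfg)[0]
                except Exception:  # noqa: BLE001 - silent components stay absent
                    log[m.source] = 0.0
            ens = predict_ensemble(predictor.ltr[ns], candidates, graph)
            log["ensemble"] = fmax(val_truth, ens, metric_cfg)[0]
        predictor.validation_fmax[ns] = log
        logger.info("validation Fmax [%s]: %s", ns, log)
    return predictor


def predict(
    predictor: Predictor,
    inputs: StudyInputs,
    queries: Sequence[str],
    ns: str,
) -> tuple[ScoreMatrix, list[ScoreMatrix]]:
    """Ensemble + component predictions for a query set in one namespace.

    Returns ``(ensemble_matrix, component_matrices)``; proteins with no
    candidate from any component are absent from the ensemble matrix.
    """
    matrices = predict_components(predictor, inputs, queries, ns)
    candidates = select_candidates(
        matrices, top_k_per_component=predictor.config.ltr.top_k_per_component
    )
    ensemble = predict_ensemble(predictor.ltr[ns], candidates, predictor.graph)
    ensemble.namespace = ns
    return ensemble, matrices
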