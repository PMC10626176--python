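"""CAFA-style evaluation of GO-term predictions.

Protein-centric metrics scan a fixed score-threshold grid
``tau in {0.01, 0.02, ..., 1.00}`` with the rule *score >= tau predicts*:

* **Fmax** — the maximum over tau of ``2*pr*rc/(pr+rc)``, where precision
  is averaged over proteins with at least one prediction at tau and recall
  over all evaluated proteins.
* **Smin** — the minimum over tau of ``sqrt(ru^2 + mi^2)``, where remaining
  uncertainty ``ru`` sums the information accretion of missed true terms and
  misinformation ``mi`` sums that of wrongly predicted terms, both averaged
  over proteins.

Pair-centric **AUPRC** pools all (protein, term) pairs over a finite
universe (terms present in the propagated truth or in predictions) and
integrates precision over achieved recall on the same grid (step rule /
average-precision form).  Term-centric **M-AUPRC** averages per-term column
AUPRC within annotation-frequency groups.

Root terms are always true after propagation and are excluded from scoring.
Confidence intervals come from protein-level bootstrap resampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np

from .annotations import AnnotationSet
from .exceptions import EvaluationError, ValidationError
from .ontology import ICTable
from .scores import ScoreMatrix

#: The evaluation threshold grid: 0.01 to 1.00 in steps of 0.01.
DEFAULT_GRID: tuple[float, ...] = tuple(round(i / 100, 2) for i in range(1, 101))


@dataclass(frozen=True)
class MetricConfig:
    """Threshold grid plus the root terms to exclude from scoring."""

    thresholds: tuple[float, ...] = DEFAULT_GRID
    roots: frozenset[str] = frozenset()
    namespace: str | None = None

    def __post_init__(self) -> None:
        ts = self.thresholds
        if not ts or any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValidationError("threshold grid must be strictly increasing")
        if ts[0] <= 0 or ts[-1] > 1:
            raise ValidationError("threshold grid must lie in (0, 1]")


def _prepare(
    truth: AnnotationSet, pred: ScoreMatrix, cfg: MetricConfig
) -> tuple[list[str], dict[str, set[str]], dict[str, dict[str, float]]]:
    """Drop roots, fix the evaluated protein list, and freeze rows."""
    roots = cfg.roots
    truth_rows = {
        p: {t for t in ts if t not in roots}
        for p, ts in truth.by_protein.items()
    }
    truth_rows = {p: ts for p, ts in truth_rows.items() if ts}
    if not truth_rows:
        raise EvaluationError("empty truth after root exclusion")
    proteins = sorted(truth_rows)
    pred_rows = {
        p: {t: s for t, s in pred.row(p).items() if t not in roots}
        for p in proteins
    }
    return proteins, truth_rows, pred_rows


# ----------------------------------------------------------------------- Fmax
def fmax(
    truth: AnnotationSet, pred: ScoreMatrix, cfg: MetricConfig
) -> tuple[float, float]:
    """Maximum protein-centric F1 over the threshold grid.

    Returns ``(Fmax, tau*)`` where ``tau*`` is the smallest optimising
    threshold.  Precision at tau averages over proteins with >= 1 predicted
    term; recall averages over all evaluated proteins.
    """
    proteins, truth_rows, pred_rows = _prepare(truth, pred, cfg)
    best, best_tau = 0.0, cfg.thresholds[0]
    for tau in cfg.thresholds:
        pr_sum, pr_n, rc_sum = 0.0, 0, 0.0
        for p in proteins:
            predicted = {t for t, s in pred_rows[p].items() if s >= tau}
            tp = len(predicted & truth_rows[p])
            if predicted:
                pr_sum += tp / len(predicted)
                pr_n += 1
            rc_sum += tp / len(truth_rows[p])
        if pr_n == 0:
            continue
        pr = pr_sum / pr_n
        rc = rc_sum / len(proteins)
        if pr + rc > 0:
            f = 2 * pr * rc / (pr + rc)
            if f > best:
                best, best_tau = f, tau
    return best, best_tau


# ----------------------------------------------------------------------- Smin
def smin(
    truth: AnnotationSet,
    pred: ScoreMatrix,
    ic: ICTable,
    cfg: MetricConfig,
) -> tuple[float, float]:
    """Minimum semantic distance over the threshold grid.

    Returns ``(Smin, tau*)``.  Every term in the truth or the predictions
    must have an information-accretion value.
    """
    proteins, truth_rows, pred_rows = _prepare(truth, pred, cfg)
    for p in proteins:
        for t in truth_rows[p] | set(pred_rows[p]):
            if t not in ic:
                raise ValidationError(f"no information accretion for {t}")
    best, best_tau = math.inf, cfg.thresholds[0]
    n = len(proteins)
    for tau in cfg.thresholds:
        ru, mi = 0.0, 0.0
        for p in proteins:
            predicted = {t for t, s in pred_rows[p].items() if s >= tau}
            ru += sum(ic[t] for t in truth_rows[p] - predicted)
            mi += sum(ic[t] for t in predicted - truth_rows[p])
        s = math.hypot(ru / n, mi / n)
        if s < best:
            best, best_tau = s, tau
    return best, best_tau


# ---------------------------------------------------------------------- AUPRC
def _grid_average_precision(
    scores: np.ndarray, positive: np.ndarray, n_pos: int, grid: Iterable[float]
) -> float:
    """Step-rule area: precision at each achieved recall over the tau grid.

    ``scores``/``positive`` describe the pairs with a stored (non-zero)
    prediction; pairs scored 0 are never predicted on the grid but still
    count in ``n_pos`` through the caller.
    """
    ap, prev_rc = 0.0, 0.0
    for tau in sorted(grid, reverse=True):
        mask = scores >= tau
        npred = int(mask.sum())
        if npred == 0:
            continue
        tp = int((mask & positive).sum())
        pr = tp / npred
        rc = tp / n_pos
        if rc > prev_rc:
            ap += (rc - prev_rc) * pr
            prev_rc = rc
    return ap


def micro_auprc(
    truth: AnnotationSet, pred: ScoreMatrix, cfg: MetricConfig
) -> float:
    """Pair-pooled AUPRC over the namespace's finite candidate universe.

    The universe is every (evaluated protein, term) pair for terms appearing
    in the propagated truth or in the predictions (roots excluded); pairs
    absent from the prediction matrix score 0.
    """
    proteins, truth_rows, pred_rows = _prepare(truth, pred, cfg)
    universe_terms = set().union(*truth_rows.values())
    for p in proteins:
        universe_terms.update(pred_rows[p])
    n_pos = sum(len(ts) for ts in truth_rows.values())
    if n_pos == 0:
        raise EvaluationError("no positive (protein, term) pair")
    scores, positive = [], []
    for p in proteins:
        for t, s in pred_rows[p].items():
            if t in universe_terms:
                scores.append(s)
                positive.append(t in truth_rows[p])
    return _grid_average_precision(
        np.array(scores), np.array(positive, dtype=bool), n_pos, cfg.thresholds
    )


def term_auprc(
    truth: AnnotationSet, pred: ScoreMatrix, term: str, cfg: MetricConfig
) -> float:
    """AUPRC of one term's column over all evaluated proteins."""
    proteins, truth_rows, pred_rows = _prepare(truth, pred, cfg)
    n_pos = sum(1 for p in proteins if term in truth_rows[p])
    if n_pos == 0:
        raise EvaluationError(f"term {term} has no test positives")
    scores = np.array([pred_rows[p].get(term, 0.0) for p in proteins])
    positive = np.array([term in truth_rows[p] for p in proteins])
    mask = scores > 0.0
    return _grid_average_precision(scores[mask], positive[mask], n_pos, cfg.thresholds)


def m_auprc_by_group(
    truth: AnnotationSet,
    pred: ScoreMatrix,
    groups: Mapping[str, str],
    cfg: MetricConfig,
) -> dict[str, float]:
    """Term-centric AUPRC averaged (unweighted) within frequency groups.

    Terms with no test positives are excluded; groups left empty after the
    exclusion are omitted from the result.
    """
    proteins, truth_rows, _ = _prepare(truth, pred, cfg)
    test_terms = set().union(*truth_rows.values())
    per_group: dict[str, list[float]] = {}
    for term, group in sorted(groups.items()):
        if term in cfg.roots or term not in test_terms:
            continue
        per_group.setdefault(group, []).append(term_auprc(truth, pred, term, cfg))
    return {g: float(np.mean(vs)) for g, vs in sorted(per_group.items()) if vs}


# ------------------------------------------------------------------ bootstrap
def bootstrap_ci(
    metric: Callable[[AnnotationSet, ScoreMatrix], float],
    truth: AnnotationSet,
    pred: ScoreMatrix,
    iterations: int = 100,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Protein-level bootstrap percentile interval of an evaluation metric.

    Proteins are resampled with replacement; duplicated draws keep their
    multiplicity (each copy counts).  Replicates on which the metric is
    undefined are redrawn, capped at ``10 * iterations`` total draws.
    """
    proteins = sorted(truth.proteins)
    if len(proteins) < 2:
        raise EvaluationError("bootstrap needs >= 2 proteins")
    rng = np.random.default_rng(seed)
    values: list[float] = []
    draws = 0
    while len(values) < iterations:
        if draws >= 10 * iterations:
            raise EvaluationError("too many degenerate bootstrap replicates")
        draws += 1
        sample = rng.choice(proteins, size=len(proteins), replace=True)
        rep_truth: dict[str, set[str]] = {}
        rep_pred = ScoreMatrix(source=pred.source, namespace=pred.namespace)
        for k, p in enumerate(sample):
            alias = f"{p}::{k}"
            rep_truth[alias] = set(truth.by_protein[p])
            rep_pred.set_row(alias, pred.row(p))
        try:
            values.append(metric(AnnotationSet(rep_truth), rep_pred))
        except EvaluationError:
            continue
    lo_q = 100 * (1 - level) / 2
    arr = np.array(values)
    return float(np.percentile(arr, lo_q)), float(np.percentile(arr, 100 - lo_q))


# -------------------------------------------------------------------- report
@dataclass
class EvaluationReport:
    """All headline metrics for one (method, namespace) pair."""

    method: str
    namespace: str
    fmax: float
    fmax_tau: float
    smin: float | None = None
    smin_tau: float | None = None
    auprc: float | None = None
    m_auprc: dict[str, float] = field(default_factory=dict)
    intervals: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out: dict = {
            "method": self.method,
            "namespace": self.namespace,
            "fmax": self.fmax,
            "fmax_tau": self.fmax_tau,
        }
        if self.smin is not None:
            out["smin"] = self.smin
            out["smin_tau"] = self.smin_tau
        if self.auprc is not None:
            out["auprc"] = self.auprc
        if self.m_auprc:
            out["m_auprc"] = dict(self.m_auprc)
        if self.intervals:
            out["intervals"] = {k: list(v) for k, v in self.intervals.items()}
        return out

    def rows(self) -> list[tuple[str, str, str, float]]:
        rows = [
            (self.method, self.namespace, "fmax", self.fmax),
            (self.method, self.namespace, "fmax_tau", self.fmax_tau),
        ]
        if self.smin is not None:
            rows.append((self.method, self.namespace, "smin", self.smin))
            rows.append((self.method, self.namespace, "smin_tau", self.smin_tau))
        if self.auprc is not None:
            rows.append((self.method, self.namespace, "auprc", self.auprc))
        for group, value in sorted(self.m_auprc.items()):
            rows.append((self.method, self.namespace, f"m_auprc[{group}]", value))
        for name, (lo, hi) in sorted(self.intervals.items()):
            rows.append((self.method, self.namespace, f"{name}_ci_low", lo))
            rows.append((self.method, self.namespace, f"{name}_ci_high", hi))
        return rows


def evaluate(
    truth: AnnotationSet,
    pred: ScoreMatrix,
    cfg: MetricConfig,
    *,
    method: str = "",
    ic: ICTable | None = None,
    groups: Mapping[str, str] | None = None,
    bootstrap_iterations: int = 0,
    bootstrap_level: float = 0.95,
    seed: int = 0,
) -> EvaluationReport:
    """Compute Fmax (always), plus Smin / AUPRC / M-AUPRC / CIs on request."""
    f, f_tau = fmax(truth, pred, cfg)
    report = EvaluationReport(
        method=method or pred.source,
        namespace=cfg.namespace or (pred.namespace or ""),
        fmax=f,
        fmax_tau=f_tau,
    )
    if ic is not None:
        report.smin, report.smin_tau = smin(truth, pred, ic, cfg)
    report.auprc = micro_auprc(truth, pred, cfg)
    if groups:
        report.m_auprc = m_auprc_by_group(truth, pred, groups, cfg)
    if bootstrap_iterations:
        report.intervals["fmax"] = bootstrap_ci(
            lambda t, m: fmax(t, m, cfg)[0],
            truth,
            pred,
            iterations=bootstrap_iterations,
            level=bootstrap_level,
            seed=seed,
        )
        if ic is not None:
            report.intervals["smin"] = bootstrap_ci(
                lambda t, m: smin(t, m, ic, cfg)[0],
                truth,
                pred,
                iterations=bootstrap_iterations,
                level=bootstrap_level,
                seed=seed + 1,
            )
    return report


def write_report_tsv(reports: Iterable[EvaluationReport], handle) -> None:
    handle.write("method\tnamespace\tmetric\tvalue\n")
    for report in reports:
        for method, ns, metric, value in report.rows():
            handle.write(f"{method}\t{ns}\t{metric}\t{value:.6f}\n")
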