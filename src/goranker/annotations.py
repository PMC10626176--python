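"""GO annotations: GAF input, evidence filtering, time-split benchmark
construction and the stratifications used in evaluation.

The benchmark protocol is the CAFA-style time split: models are trained on
all experimental annotations dated before ``t0``; the validation set is the
proteins that gained their *first* experimental annotation in a namespace
during ``[t0, t1)`` while being no- or limited-knowledge at ``t0``; the test
set is the proteins that gained their first annotation in a namespace during
``[t1, t2)`` while being no-knowledge (no experimental annotation in *any*
namespace) at ``t1``.

Knowledge status is assessed per namespace and ignores bare root-term
annotations, which are uninformative and added automatically by true-path
propagation.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence, TextIO

from .exceptions import ConfigError, ParseError, ValidationError
from .ontology import OntologyGraph, propagate_labels

logger = logging.getLogger(__name__)

#: Experimental evidence codes (CAFA convention).
EXPERIMENTAL_CODES = frozenset(
    {"EXP", "IDA", "IPI", "IMP", "IGI", "IEP", "TAS", "IC"}
)

#: All recognised GO evidence codes (experimental, curated and electronic).
KNOWN_EVIDENCE_CODES = EXPERIMENTAL_CODES | frozenset(
    {
        "HTP", "HDA", "HMP", "HGI", "HEP",
        "IBA", "IBD", "IKR", "IRD",
        "ISS", "ISO", "ISA", "ISM", "IGC", "RCA",
        "NAS", "ND", "IEA",
    }
)

NO_KNOWLEDGE = "no-knowledge"
LIMITED_KNOWLEDGE = "limited-knowledge"
ANNOTATED = "annotated"


class AnnotationRecord(NamedTuple):
    """One GAF row: a dated, evidence-coded protein-to-term assignment."""

    protein: str
    term: str
    evidence: str
    date: dt.date
    taxon: str | None = None


class AnnotationSet:
    """Protein -> set-of-terms mapping, closable under the true-path rule."""

    __slots__ = ("by_protein",)

    def __init__(self, by_protein: Mapping[str, Iterable[str]] | None = None):
        self.by_protein: dict[str, set[str]] = {
            p: set(ts) for p, ts in (by_protein or {}).items() if ts
        }

    @classmethod
    def from_records(cls, records: Iterable[AnnotationRecord]) -> "AnnotationSet":
        out: dict[str, set[str]] = {}
        for rec in records:
            out.setdefault(rec.protein, set()).add(rec.term)
        return cls(out)

    @property
    def proteins(self) -> set[str]:
        return set(self.by_protein)

    def terms(self) -> set[str]:
        out: set[str] = set()
        for ts in self.by_protein.values():
            out |= ts
        return out

    def get(self, protein: str) -> set[str]:
        return set(self.by_protein.get(protein, ()))

    def has(self, protein: str, term: str) -> bool:
        return term in self.by_protein.get(protein, ())

    def counts(self) -> dict[str, int]:
        """Number of annotated proteins per term."""
        out: dict[str, int] = {}
        for ts in self.by_protein.values():
            for t in ts:
                out[t] = out.get(t, 0) + 1
        return out

    def restrict(
        self,
        proteins: Iterable[str] | None = None,
        terms: Iterable[str] | None = None,
    ) -> "AnnotationSet":
        ps = set(proteins) if proteins is not None else None
        ts = set(terms) if terms is not None else None
        out: dict[str, set[str]] = {}
        for p, pts in self.by_protein.items():
            if ps is not None and p not in ps:
                continue
            kept = pts & ts if ts is not None else set(pts)
            if kept:
                out[p] = kept
        return AnnotationSet(out)

    def restrict_namespace(self, graph: OntologyGraph, ns: str) -> "AnnotationSet":
        return self.restrict(terms=graph.namespace_terms(ns))

    def __len__(self) -> int:
        return sum(len(ts) for ts in self.by_protein.values())

    def __bool__(self) -> bool:
        return bool(self.by_protein)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        return self.by_protein == other.by_protein

    def __repr__(self) -> str:  # pragma: no cover
        return f"AnnotationSet(proteins={len(self.by_protein)}, pairs={len(self)})"


# ----------------------------------------------------------------------- GAF
_GAF_COLUMNS = 17


def read_gaf(stream: TextIO | Iterable[str]) -> list[AnnotationRecord]:
    """Read a GAF 2.x body into annotation records.

    Comment lines start with ``!``.  Rows whose qualifier column contains
    ``NOT`` are negative assertions and are dropped.  Columns used: 2
    (accession), 4 (qualifier), 5 (GO id), 7 (evidence), 13 (taxon), 15
    (date, YYYYMMDD).
    """
    records: list[AnnotationRecord] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("!"):
            continue
        fields = line.split("\t")
        if len(fields) != _GAF_COLUMNS:
            raise ParseError(
                f"line {lineno}: expected {_GAF_COLUMNS} tab-separated "
                f"columns, got {len(fields)}"
            )
        qualifier = fields[3]
        if "NOT" in qualifier.split("|"):
            continue
        try:
            date = dt.datetime.strptime(fields[13], "%Y%m%d").date()
        except ValueError as exc:
            raise ParseError(f"line {lineno}: bad date {fields[13]!r}") from exc
        taxon = fields[12].removeprefix("taxon:") or None
        records.append(
            AnnotationRecord(
                protein=fields[1],
                term=fields[4],
                evidence=fields[6],
                date=date,
                taxon=taxon,
            )
        )
    return records


def write_gaf(records: Iterable[AnnotationRecord], stream: TextIO) -> None:
    """Write records as a minimal GAF 2.2 body (round-trips with read_gaf)."""
    stream.write("!gaf-version: 2.2\n")
    for rec in records:
        fields = [""] * _GAF_COLUMNS
        fields[0] = "UniProtKB"
        fields[1] = rec.protein
        fields[2] = rec.protein
        fields[3] = "enables"
        fields[4] = rec.term
        fields[5] = "GO_REF:0000000"
        fields[6] = rec.evidence
        fields[8] = "F"
        fields[11] = "protein"
        fields[12] = f"taxon:{rec.taxon or '0'}"
        fields[13] = rec.date.strftime("%Y%m%d")
        fields[14] = "GOA"
        stream.write("\t".join(fields) + "\n")


def filter_experimental(
    records: Iterable[AnnotationRecord],
    codes: frozenset[str] | set[str] = EXPERIMENTAL_CODES,
) -> list[AnnotationRecord]:
    """Keep records whose evidence code is in ``codes``."""
    return [r for r in records if r.evidence in codes]


# ---------------------------------------------------------------- time split
@dataclass
class BenchmarkSplit:
    """Train/validation/test partition produced by the time-split protocol.

    ``validation_proteins``/``test_proteins`` map a namespace code to the
    proteins evaluated in that namespace; ``validation_truth``/``test_truth``
    hold their propagated window annotations restricted to the namespace.
    ``status_of`` records the knowledge status of each (protein, namespace)
    at the relevant cutoff.
    """

    train: AnnotationSet
    validation_proteins: dict[str, set[str]]
    validation_truth: dict[str, AnnotationSet]
    test_proteins: dict[str, set[str]]
    test_truth: dict[str, AnnotationSet]
    status_of: dict[tuple[str, str], str] = field(default_factory=dict)

    def train_namespace(self, graph: OntologyGraph, ns: str) -> AnnotationSet:
        return self.train.restrict_namespace(graph, ns)


def _informative(records: Sequence[AnnotationRecord], graph: OntologyGraph):
    """Drop records to root terms or unknown/obsolete terms."""
    roots = graph.root_terms()
    kept = []
    for rec in records:
        if rec.term in graph.obsolete:
            continue
        if rec.term not in graph:
            logger.warning("dropping annotation to unknown term %s", rec.term)
            continue
        if graph.resolve(rec.term) in roots:
            continue
        kept.append(rec)
    return kept


def build_time_split(
    records: Sequence[AnnotationRecord],
    t0: dt.date,
    t1: dt.date,
    t2: dt.date,
    graph: OntologyGraph,
) -> BenchmarkSplit:
    """Construct the CAFA-style time-split benchmark.

    Parameters
    ----------
    records
        Experimental-evidence annotation records (pre-filtered).
    t0, t1, t2
        Window boundaries: train < t0, validation in [t0, t1), test in
        [t1, t2).  All intervals are half-open.
    """
    if not (t0 < t1 < t2):
        raise ConfigError(f"dates must increase: {t0}, {t1}, {t2}")

    records = _informative(records, graph)
    namespaces = sorted(set(graph.namespace_of.values()))

    # first experimental annotation date per (protein, namespace)
    first_in_ns: dict[tuple[str, str], dt.date] = {}
    for rec in records:
        key = (rec.protein, graph.namespace(rec.term))
        if key not in first_in_ns or rec.date < first_in_ns[key]:
            first_in_ns[key] = rec.date

    def status(protein: str, ns: str, cutoff: dt.date) -> str:
        dates = [
            d for (p, n), d in first_in_ns.items() if p == protein and d < cutoff
        ]
        if not dates:
            return NO_KNOWLEDGE
        if first_in_ns.get((protein, ns), t2) < cutoff:
            return ANNOTATED
        return LIMITED_KNOWLEDGE

    train_records = [r for r in records if r.date < t0]
    train = propagate_labels(graph, AnnotationSet.from_records(train_records))

    validation_proteins: dict[str, set[str]] = {ns: set() for ns in namespaces}
    test_proteins: dict[str, set[str]] = {ns: set() for ns in namespaces}
    status_of: dict[tuple[str, str], str] = {}

    proteins = {r.protein for r in records}
    for protein in proteins:
        for ns in namespaces:
            first = first_in_ns.get((protein, ns))
            if first is None:
                continue
            if t0 <= first < t1:
                st = status(protein, ns, t0)
                if st in (NO_KNOWLEDGE, LIMITED_KNOWLEDGE):
                    validation_proteins[ns].add(protein)
                    status_of[(protein, ns)] = st
            elif t1 <= first < t2:
                st = status(protein, ns, t1)
                if st == NO_KNOWLEDGE:
                    test_proteins[ns].add(protein)
                    status_of[(protein, ns)] = st

    def window_truth(
        members: dict[str, set[str]], lo: dt.date, hi: dt.date
    ) -> dict[str, AnnotationSet]:
        window = [r for r in records if lo <= r.date < hi]
        raw = AnnotationSet.from_records(window)
        closed = propagate_labels(graph, raw)
        return {
            ns: closed.restrict(
                proteins=members[ns], terms=graph.namespace_terms(ns)
            )
            for ns in namespaces
        }

    return BenchmarkSplit(
        train=train,
        validation_proteins=validation_proteins,
        validation_truth=window_truth(validation_proteins, t0, t1),
        test_proteins=test_proteins,
        test_truth=window_truth(test_proteins, t1, t2),
        status_of=status_of,
    )


# ------------------------------------------------------------- stratification
DEFAULT_GROUP_BOUNDS: tuple[tuple[int, int | None], ...] = (
    (10, 30),
    (31, 100),
    (101, None),
)


def group_label(lo: int, hi: int | None) -> str:
    return f"{lo}-{hi}" if hi is not None else f">{lo - 1}"


def group_terms_by_count(
    annotations: AnnotationSet,
    boundaries: Sequence[tuple[int, int | None]] = DEFAULT_GROUP_BOUNDS,
) -> dict[str, str]:
    """Assign each term to an annotation-frequency group.

    With the default boundaries the groups are ``10-30``, ``31-100`` and
    ``>100`` annotated proteins (inclusive ranges); terms below the lowest
    bound are left unassigned.
    """
    groups: dict[str, str] = {}
    for term, n in annotations.counts().items():
        for lo, hi in boundaries:
            if n >= lo and (hi is None or n <= hi):
                groups[term] = group_label(lo, hi)
                break
    return groups


def flag_difficult(
    identity: Mapping[str, float],
    threshold: float = 0.6,
    proteins: Iterable[str] | None = None,
) -> set[str]:
    """Proteins whose best identity to any training protein is below threshold.

    ``identity`` maps each protein to its maximum sequence identity (a
    fraction in [0, 1]) against the training set; proteins in ``proteins``
    that are absent from the table had no hit at all and are difficult by
    definition.
    """
    for p, v in identity.items():
        if not 0.0 <= v <= 1.0:
            raise ValidationError(f"identity {v} for {p} outside [0, 1]")
    universe = set(proteins) if proteins is not None else set(identity)
    return {p for p in universe if identity.get(p, -1.0) < threshold}
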