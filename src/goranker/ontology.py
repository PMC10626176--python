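"""Gene Ontology DAG: parsing, hierarchy queries, true-path propagation and
information accretion.

The ontology is held per study as a single :class:`OntologyGraph` covering the
three GO namespaces — molecular function (MF), biological process (BP) and
cellular component (CC).  Parent edges are the union of ``is_a`` and
``part_of`` relations; other relations (``regulates`` and friends) are
ignored, following common CAFA practice.  Every query (ancestors, depth,
propagation) stays inside a namespace because edges never cross namespaces.

Annotation and score propagation implement the *true-path rule*: an
annotation to a term implies annotation to all of its ancestors, and a
prediction score for a term is a lower bound on the score of every ancestor.

Information accretion ``ia(t) = -log2 P(t | parents(t))`` is estimated from a
propagated annotation corpus and weights the Smin metric; the conditional
form (rather than the plain ``-log2 P(t)``) is the CAFA convention.
"""

from __future__ import annotations

import io
import logging
import math
import re
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

import obonet

from .exceptions import ParseError, ValidationError

logger = logging.getLogger(__name__)

#: Mapping from OBO namespace names to the two-letter codes used throughout.
NAMESPACE_CODES = {
    "molecular_function": "MF",
    "biological_process": "BP",
    "cellular_component": "CC",
}
NAMESPACE_NAMES = {v: k for k, v in NAMESPACE_CODES.items()}

#: Relations treated as parent edges.
PARENT_RELATIONS = ("is_a", "part_of")


@dataclass
class OntologyGraph:
    """A parsed GO DAG with per-namespace roots and lazy hierarchy caches.

    Parameters
    ----------
    namespace_of
        Term identifier -> namespace code (``MF``/``BP``/``CC``).  The key
        set defines the non-obsolete terms of the graph.
    parents_of
        Term -> set of direct parents via ``is_a``/``part_of``.  Roots map
        to the empty set.
    names
        Term -> human-readable name (may be empty for synthetic graphs).
    obsolete
        Identifiers of obsolete terms; excluded from all queries.
    alt_ids
        Secondary identifier -> canonical identifier.
    """

    namespace_of: dict[str, str]
    parents_of: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)
    obsolete: frozenset[str] = frozenset()
    alt_ids: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.parents_of = {t: frozenset(ps) for t, ps in self.parents_of.items()}
        for term in self.namespace_of:
            self.parents_of.setdefault(term, frozenset())
        self._check_invariants()
        self.roots: dict[str, str] = {}
        for term, parents in self.parents_of.items():
            if term in self.namespace_of and not parents:
                ns = self.namespace_of[term]
                if ns in self.roots:
                    raise ValidationError(
                        f"namespace {ns} has multiple roots: "
                        f"{self.roots[ns]}, {term}"
                    )
                self.roots[ns] = term
        self._children: dict[str, set[str]] | None = None
        self._ancestors: dict[str, frozenset[str]] = {}
        self._descendants: dict[str, frozenset[str]] = {}
        self._depth: dict[str, int] = {}

    # ------------------------------------------------------------------ basic
    @property
    def terms(self) -> set[str]:
        return set(self.namespace_of)

    def __contains__(self, term: str) -> bool:
        return term in self.namespace_of or term in self.alt_ids

    def __len__(self) -> int:
        return len(self.namespace_of)

    def resolve(self, term: str) -> str:
        """Map an identifier (possibly an alt_id) to its canonical form."""
        if term in self.namespace_of:
            return term
        if term in self.alt_ids:
            return self.alt_ids[term]
        raise ValidationError(f"unknown term: {term!r}")

    def namespace(self, term: str) -> str:
        return self.namespace_of[self.resolve(term)]

    def root_terms(self) -> frozenset[str]:
        return frozenset(self.roots.values())

    def is_root(self, term: str) -> bool:
        return self.resolve(term) in self.roots.values()

    def namespace_terms(self, ns: str) -> set[str]:
        return {t for t, n in self.namespace_of.items() if n == ns}

    def parents(self, term: str) -> frozenset[str]:
        return self.parents_of[self.resolve(term)]

    def children(self, term: str) -> frozenset[str]:
        if self._children is None:
            ch: dict[str, set[str]] = {t: set() for t in self.namespace_of}
            for t, parents in self.parents_of.items():
                for p in parents:
                    ch[p].add(t)
            self._children = ch
        return frozenset(self._children[self.resolve(term)])

    def leaves(self, ns: str) -> set[str]:
        """Terms of a namespace without children."""
        return {t for t in self.namespace_terms(ns) if not self.children(t)}

    # --------------------------------------------------------------- hierarchy
    def ancestors(self, term: str) -> frozenset[str]:
        """All terms reachable via parent edges, excluding ``term`` itself."""
        term = self.resolve(term)
        cached = self._ancestors.get(term)
        if cached is None:
            out: set[str] = set()
            stack = list(self.parents_of[term])
            while stack:
                t = stack.pop()
                if t not in out:
                    out.add(t)
                    stack.extend(self.parents_of[t])
            cached = self._ancestors[term] = frozenset(out)
        return cached

    def descendants(self, term: str) -> frozenset[str]:
        """All terms from which ``term`` is reachable, excluding itself."""
        term = self.resolve(term)
        cached = self._descendants.get(term)
        if cached is None:
            out: set[str] = set()
            stack = list(self.children(term))
            while stack:
                t = stack.pop()
                if t not in out:
                    out.add(t)
                    stack.extend(self.children(t))
            cached = self._descendants[term] = frozenset(out)
        return cached

    def depth(self, term: str) -> int:
        """Length of the shortest parent-edge path to the namespace root."""
        term = self.resolve(term)
        if term not in self._depth:
            # BFS upward; memoises every term on the popped frontier.
            seen = {term: 0}
            queue = deque([term])
            while queue:
                t = queue.popleft()
                if not self.parents_of[t]:  # reached the root
                    self._depth[term] = seen[t]
                    break
                for p in self.parents_of[t]:
                    if p not in seen:
                        seen[p] = seen[t] + 1
                        queue.append(p)
        return self._depth[term]

    # ------------------------------------------------------------- validation
    def _check_invariants(self) -> None:
        ns_of = self.namespace_of
        for term, parents in self.parents_of.items():
            for p in parents:
                if p not in ns_of:
                    raise ValidationError(f"{term} has unknown parent {p}")
                if ns_of[p] != ns_of.get(term):
                    raise ValidationError(
                        f"cross-namespace edge {term} -> {p}"
                    )
        # acyclicity by iterative DFS with colouring
        WHITE, GREY, BLACK = 0, 1, 2
        colour = dict.fromkeys(ns_of, WHITE)
        for start in ns_of:
            if colour[start] != WHITE:
                continue
            stack: list[tuple[str, Iterable[str]]] = [
                (start, iter(self.parents_of[start]))
            ]
            colour[start] = GREY
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if colour[p] == GREY:
                        raise ValidationError(f"cycle through {p}")
                    if colour[p] == WHITE:
                        colour[p] = GREY
                        stack.append((p, iter(self.parents_of[p])))
                        advanced = True
                        break
                if not advanced:
                    colour[node] = BLACK
                    stack.pop()


# --------------------------------------------------------------------- parse
_TERM_ID = re.compile(r"GO:\d{7}$")


def parse_obo(stream: TextIO | str) -> OntologyGraph:
    """Parse an OBO 1.2 document into an :class:`OntologyGraph`.

    ``is_a`` and ``relationship: part_of`` lines become parent edges;
    ``alt_id`` lines become alias entries; stanzas with ``is_obsolete: true``
    are recorded in :attr:`OntologyGraph.obsolete` and excluded from the term
    set.  Edges whose endpoints lie in different namespaces are dropped with
    a warning (real GO releases contain a handful of these).

    Raises
    ------
    ParseError
        If the document is not parseable as OBO.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    text = stream.read()
    _prescan_stanzas(text)
    try:
        graph = obonet.read_obo(io.StringIO(text), ignore_obsolete=False)
    except Exception as exc:  # pragma: no cover - obonet internal failures
        raise ParseError(f"OBO parse failed: {exc}") from exc

    namespace_of: dict[str, str] = {}
    names: dict[str, str] = {}
    obsolete: set[str] = set()
    alt_ids: dict[str, str] = {}
    for term, data in graph.nodes(data=True):
        if str(data.get("is_obsolete", "")).lower() == "true":
            obsolete.add(term)
            continue
        ns = data.get("namespace")
        if ns not in NAMESPACE_CODES:
            raise ParseError(f"term {term} has missing/unknown namespace {ns!r}")
        namespace_of[term] = NAMESPACE_CODES[ns]
        names[term] = data.get("name", "")
        for alt in data.get("alt_id", []):
            alt_ids[alt] = term

    parents: dict[str, set[str]] = {t: set() for t in namespace_of}
    for child, parent, relation in graph.edges(keys=True):
        if relation not in PARENT_RELATIONS:
            continue
        if child in obsolete or parent in obsolete:
            continue
        if child not in namespace_of or parent not in namespace_of:
            continue
        if namespace_of[child] != namespace_of[parent]:
            logger.warning(
                "dropping cross-namespace %s edge %s -> %s", relation, child, parent
            )
            continue
        parents[child].add(parent)

    return OntologyGraph(
        namespace_of=namespace_of,
        parents_of={t: frozenset(ps) for t, ps in parents.items()},
        names=names,
        obsolete=frozenset(obsolete),
        alt_ids=alt_ids,
    )


def _prescan_stanzas(text: str) -> None:
    """Cheap structural check so malformed stanzas fail with a line number."""
    in_term = False
    has_id = False
    start_line = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if line == "[Term]":
            if in_term and not has_id:
                raise ParseError(f"line {start_line}: [Term] stanza without id")
            in_term, has_id, start_line = True, False, lineno
        elif line.startswith("["):
            in_term = False
        elif in_term and line.startswith("id:"):
            value = line[3:].strip()
            if not _TERM_ID.match(value.split("!")[0].strip()):
                raise ParseError(f"line {lineno}: malformed term id {value!r}")
            has_id = True
    if in_term and not has_id:
        raise ParseError(f"line {start_line}: [Term] stanza without id")


# ----------------------------------------------------------------- functions
def ancestors(graph: OntologyGraph, term: str) -> frozenset[str]:
    return graph.ancestors(term)


def term_depth(graph: OntologyGraph, term: str) -> int:
    return graph.depth(term)


def propagate_labels(graph: OntologyGraph, annotations) -> "AnnotationSet":
    """Close an annotation set upward under the true-path rule.

    Every (protein, term) pair implies (protein, ancestor) for all ancestors,
    up to and including the namespace root.  Annotations to obsolete terms
    are dropped with a warning; the operation is idempotent.
    """
    from .annotations import AnnotationSet  # local import avoids a cycle

    closed: dict[str, set[str]] = {}
    for protein, terms in annotations.by_protein.items():
        out: set[str] = set()
        for term in terms:
            if term in graph.obsolete:
                logger.warning("dropping annotation of %s to obsolete %s", protein, term)
                continue
            term = graph.resolve(term)
            out.add(term)
            out |= graph.ancestors(term)
        if out:
            closed[protein] = out
    return AnnotationSet(closed)


def propagate_scores(graph: OntologyGraph, scores) -> "ScoreMatrix":
    """Make a score matrix consistent with the hierarchy.

    The output score of (protein, term) is the maximum input score over the
    term and all of its descendants, so along every path the scores are
    non-increasing from root to leaf.
    """
    from .scores import ScoreMatrix

    out = ScoreMatrix(source=scores.source, namespace=scores.namespace)
    for protein, row in scores.rows():
        new_row: dict[str, float] = {}
        for term, score in row.items():
            if not 0.0 <= score <= 1.0:
                raise ValidationError(
                    f"score {score} for ({protein}, {term}) outside [0, 1]"
                )
            term = graph.resolve(term)
            for t in (term, *graph.ancestors(term)):
                if score > new_row.get(t, 0.0):
                    new_row[t] = score
        out.set_row(protein, new_row)
    return out


# --------------------------------------------------------- information accretion
@dataclass(frozen=True)
class ICTable:
    """Per-term information accretion in bits, plus the corpus size used."""

    ia_of: Mapping[str, float]
    corpus_size: int

    def __getitem__(self, term: str) -> float:
        return self.ia_of[term]

    def __contains__(self, term: str) -> bool:
        return term in self.ia_of

    def get(self, term: str, default: float | None = None) -> float | None:
        return self.ia_of.get(term, default)


def information_accretion(
    graph: OntologyGraph, annotations, *, conditional: bool = True
) -> ICTable:
    """Estimate information accretion from a propagated annotation corpus.

    In the conditional (default) form::

        ia(t) = -log2( n(t) / n(parents(t)) )

    where ``n(t)`` counts proteins annotated with ``t`` and ``n(parents(t))``
    counts proteins annotated with *all* parents of ``t``.  Roots get 0.
    Terms never seen in the corpus receive an add-one pseudocount on both
    numerator and denominator so the value stays finite.

    With ``conditional=False`` the plain information content
    ``-log2(n(t) / corpus_size)`` is returned instead (same pseudocount rule).
    """
    protein_terms = annotations.by_protein
    if not protein_terms:
        raise ValidationError("empty annotation corpus")
    # propagation check: child present without parent is an error
    for protein, terms in protein_terms.items():
        for term in terms:
            missing = graph.parents(term) - terms
            if missing:
                raise ValidationError(
                    f"annotations not propagated: {protein} has {term} "
                    f"but not parent(s) {sorted(missing)}"
                )

    proteins_with: dict[str, set[str]] = {}
    for protein, terms in protein_terms.items():
        for term in terms:
            proteins_with.setdefault(term, set()).add(protein)

    corpus = len(protein_terms)
    ia: dict[str, float] = {}
    for term in graph.terms:
        if graph.is_root(term):
            ia[term] = 0.0
            continue
        n_t = len(proteins_with.get(term, ()))
        if conditional:
            parent_sets = [proteins_with.get(p, set()) for p in graph.parents(term)]
            inter = set.intersection(*parent_sets) if parent_sets else set()
            n_par = len(inter)
        else:
            n_par = corpus
        if n_t == 0:
            n_t, n_par = 1, n_par + 1
        if n_par == 0:  # parents never co-annotated; nothing to condition on
            ia[term] = 0.0
        else:
            ia[term] = max(0.0, -math.log2(n_t / n_par))
    return ICTable(ia_of=ia, corpus_size=corpus)
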