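"""Brute-force reference implementations used to check the library.

Everything here is written as directly as possible from the definitions
(loops and explicit enumeration), independently of the library code paths
it is used to verify.
"""

from __future__ import annotations

import math


# ------------------------------------------------------------ graph oracles
def reachable_ancestors(parents: dict[str, set[str]], term: str) -> set[str]:
    """Transitive closure over parent edges by repeated expansion."""
    out: set[str] = set()
    frontier = set(parents.get(term, ()))
    while frontier:
        out |= frontier
        frontier = set().union(*(parents.get(t, set()) for t in frontier)) - out
    return out


def bfs_depth(parents: dict[str, set[str]], term: str) -> int:
    """Shortest path to a parentless node, breadth-first."""
    level, depth = {term}, 0
    while level:
        if any(not parents.get(t) for t in level):
            return depth
        level = set().union(*(parents[t] for t in level))
        depth += 1
    raise AssertionError("no root reachable")


def closure_oracle(
    parents: dict[str, set[str]], annotations: dict[str, set[str]]
) -> dict[str, set[str]]:
    return {
        p: set().union(ts, *(reachable_ancestors(parents, t) for t in ts))
        for p, ts in annotations.items()
    }


def max_over_descendants(
    parents: dict[str, set[str]], row: dict[str, float]
) -> dict[str, float]:
    """Expected propagated scores: max of a term's own score and every
    score below it, by exhaustive descendant enumeration."""
    terms = set(parents)
    out: dict[str, float] = {}
    for t in terms:
        below = [s for d, s in row.items() if t in reachable_ancestors(parents, d)]
        candidates = below + ([row[t]] if t in row else [])
        if candidates:
            out[t] = max(candidates)
    return out


# ----------------------------------------------------------- metric oracles
def fmax_oracle(
    truth: dict[str, set[str]],
    pred: dict[str, dict[str, float]],
    grid,
    roots: set[str] = frozenset(),
) -> float:
    proteins = sorted(p for p in truth if truth[p] - roots)
    best = 0.0
    for tau in grid:
        precisions, recalls = [], []
        for p in proteins:
            true_terms = truth[p] - roots
            predicted = {
                t for t, s in pred.get(p, {}).items() if s >= tau and t not in roots
            }
            tp = len(predicted & true_terms)
            if predicted:
                precisions.append(tp / len(predicted))
            recalls.append(tp / len(true_terms))
        if not precisions:
            continue
        pr = sum(precisions) / len(precisions)
        rc = sum(recalls) / len(recalls)
        if pr + rc > 0:
            best = max(best, 2 * pr * rc / (pr + rc))
    return best


def smin_oracle(
    truth: dict[str, set[str]],
    pred: dict[str, dict[str, float]],
    ia: dict[str, float],
    grid,
    roots: set[str] = frozenset(),
) -> float:
    proteins = sorted(p for p in truth if truth[p] - roots)
    best = math.inf
    for tau in grid:
        ru_total, mi_total = 0.0, 0.0
        for p in proteins:
            true_terms = truth[p] - roots
            predicted = {
                t for t, s in pred.get(p, {}).items() if s >= tau and t not in roots
            }
            ru_total += sum(ia[t] for t in true_terms - predicted)
            mi_total += sum(ia[t] for t in predicted - true_terms)
        n = len(proteins)
        best = min(best, math.hypot(ru_total / n, mi_total / n))
    return best


def micro_auprc_oracle(
    truth: dict[str, set[str]],
    pred: dict[str, dict[str, float]],
    grid,
    roots: set[str] = frozenset(),
) -> float:
    proteins = sorted(p for p in truth if truth[p] - roots)
    terms: set[str] = set()
    for p in proteins:
        terms |= truth[p] - roots
        terms |= {t for t in pred.get(p, {}) if t not in roots}
    pairs = [(p, t) for p in proteins for t in sorted(terms)]
    n_pos = sum(1 for p, t in pairs if t in truth[p])
    ap, prev_rc = 0.0, 0.0
    for tau in sorted(grid, reverse=True):
        hit = [(p, t) for p, t in pairs if pred.get(p, {}).get(t, 0.0) >= tau]
        if not hit:
            continue
        tp = sum(1 for p, t in hit if t in truth[p])
        pr, rc = tp / len(hit), tp / n_pos
        if rc > prev_rc:
            ap += (rc - prev_rc) * pr
            prev_rc = rc
    return ap


def rank_auprc_oracle(
    truth: dict[str, set[str]], pred: dict[str, dict[str, float]],
    roots: set[str] = frozenset(),
) -> float:
    """Continuous (rank-by-rank) average precision, no threshold grid.

    Ties are broken by (protein, term) so the value is well defined.
    """
    proteins = sorted(p for p in truth if truth[p] - roots)
    terms: set[str] = set()
    for p in proteins:
        terms |= truth[p] - roots
        terms |= {t for t in pred.get(p, {}) if t not in roots}
    scored = [
        (pred.get(p, {}).get(t, 0.0), p, t) for p in proteins for t in sorted(terms)
    ]
    n_pos = sum(1 for _, p, t in scored if t in truth[p])
    ranked = sorted(scored, key=lambda x: (-x[0], x[1], x[2]))
    ap, tp = 0.0, 0
    for i, (score, p, t) in enumerate(ranked, start=1):
        if score <= 0.0:
            break
        if t in truth[p]:
            tp += 1
            ap += (tp / i) / n_pos
    return ap


# -------------------------------------------------------- component oracles
def blast_vote_oracle(
    hits: list[tuple[str, str, float]],  # (query, subject, bitscore), pre-cut
    annotations: dict[str, set[str]],
) -> dict[str, dict[str, float]]:
    """Per-term weighted-vote loop over an explicit retained-hit list."""
    out: dict[str, dict[str, float]] = {}
    by_query: dict[str, list[tuple[str, float]]] = {}
    for q, s, b in hits:
        by_query.setdefault(q, []).append((s, b))
    for q, pairs in by_query.items():
        denom = sum(b for _, b in pairs)
        terms = set().union(*(annotations.get(s, set()) for s, _ in pairs))
        out[q] = {
            t: sum(b for s, b in pairs if t in annotations.get(s, set())) / denom
            for t in terms
        }
    return out
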