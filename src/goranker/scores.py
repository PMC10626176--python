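"""Sparse protein x GO-term score matrices.

:class:`ScoreMatrix` is the interchange type between component predictors,
the ranking ensemble and the evaluation stack.  Stored entries are scores in
``(0, 1]``; an absent entry means a score of exactly 0.  A matrix covers a
single namespace.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Mapping

import pandas as pd

from .exceptions import ValidationError


class ScoreMatrix:
    """Sparse mapping ``(protein, term) -> score in (0, 1]``."""

    __slots__ = ("source", "namespace", "_data")

    def __init__(
        self,
        entries: Mapping[str, Mapping[str, float]] | None = None,
        *,
        source: str = "",
        namespace: str | None = None,
    ) -> None:
        self.source = source
        self.namespace = namespace
        self._data: dict[str, dict[str, float]] = {}
        if entries:
            for protein, row in entries.items():
                self.set_row(protein, row)

    # ------------------------------------------------------------- mutation
    def set(self, protein: str, term: str, score: float) -> None:
        if not 0.0 <= score <= 1.0:
            raise ValidationError(
                f"score {score} for ({protein}, {term}) outside [0, 1]"
            )
        if score > 0.0:
            self._data.setdefault(protein, {})[term] = float(score)

    def set_row(self, protein: str, row: Mapping[str, float]) -> None:
        clean = {}
        for term, score in row.items():
            if not 0.0 <= score <= 1.0:
                raise ValidationError(
                    f"score {score} for ({protein}, {term}) outside [0, 1]"
                )
            if score > 0.0:
                clean[term] = float(score)
        if clean:
            self._data[protein] = clean
        else:
            self._data.pop(protein, None)

    def drop_below(self, floor: float) -> "ScoreMatrix":
        """Return a copy without entries strictly below ``floor``."""
        out = ScoreMatrix(source=self.source, namespace=self.namespace)
        for protein, row in self._data.items():
            out.set_row(protein, {t: s for t, s in row.items() if s >= floor})
        return out

    def drop_terms(self, terms: Iterable[str]) -> "ScoreMatrix":
        drop = set(terms)
        out = ScoreMatrix(source=self.source, namespace=self.namespace)
        for protein, row in self._data.items():
            out.set_row(protein, {t: s for t, s in row.items() if t not in drop})
        return out

    # --------------------------------------------------------------- access
    @property
    def proteins(self) -> list[str]:
        return sorted(self._data)

    @property
    def terms(self) -> list[str]:
        seen: set[str] = set()
        for row in self._data.values():
            seen.update(row)
        return sorted(seen)

    def get(self, protein: str, term: str, default: float = 0.0) -> float:
        return self._data.get(protein, {}).get(term, default)

    def row(self, protein: str) -> dict[str, float]:
        return dict(self._data.get(protein, {}))

    def rows(self) -> Iterator[tuple[str, dict[str, float]]]:
        for protein in sorted(self._data):
            yield protein, dict(self._data[protein])

    def items(self) -> Iterator[tuple[str, str, float]]:
        for protein in sorted(self._data):
            row = self._data[protein]
            for term in sorted(row):
                yield protein, term, row[term]

    def __len__(self) -> int:
        return sum(len(row) for row in self._data.values())

    def __bool__(self) -> bool:
        return bool(self._data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ScoreMatrix):
            return NotImplemented
        return self._data == other._data

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"ScoreMatrix(source={self.source!r}, namespace={self.namespace!r}, "
            f"proteins={len(self._data)}, entries={len(self)})"
        )

    # ------------------------------------------------------------ conversion
    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame with columns protein, term, score."""
        records = [
            {"protein": p, "term": t, "score": s} for p, t, s in self.items()
        ]
        return pd.DataFrame(records, columns=["protein", "term", "score"])

    def check_hierarchy(self, graph) -> None:
        """Assert parent >= child monotonicity over all stored entries."""
        for protein, row in self._data.items():
            for term, score in row.items():
                for parent in graph.parents(term):
                    if row.get(parent, 0.0) < score - 1e-12:
                        raise ValidationError(
                            f"hierarchy violated for {protein}: "
                            f"{parent}={row.get(parent, 0.0)} < {term}={score}"
                        )
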