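"""Sequence-derived protein features.

Three representations feed the logistic-regression components:

* overlapping k-mer relative frequencies (default k = 3),
* sparse binary domain/motif features read from a two-column table,
* fixed-length embeddings obtained by mean-pooling per-residue vectors from
  a pluggable embedding backend (the production backend is a protein
  language model with 1280-dimensional residue embeddings; tests use
  deterministic synthetic backends).

Long sequences are truncated before embedding: sequences longer than 1024
residues are cut to their first 1000 residues, matching the input limit of
the transformer backend.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Protocol, Sequence, TextIO

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from scipy import sparse

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
EXTENDED_AA = STANDARD_AA + "XBZU"

#: Transformer input limit and the truncation length applied beyond it.
MAX_MODEL_LEN = 1024
KEEP_LEN = 1000


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence over the 20-letter alphabet plus X/B/Z/U."""

    accession: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"{self.accession}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class EmbeddingMatrix:
    """Dense per-protein embeddings with provenance.

    All rows share the same dimensionality and contain no non-finite
    entries.
    """

    accessions: list[str]
    vectors: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or len(self.accessions) != self.vectors.shape[0]:
            raise ValidationError(
                f"embedding shape {self.vectors.shape} does not match "
                f"{len(self.accessions)} accessions"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise ValidationError("embedding matrix contains non-finite entries")
        self._index = {a: i for i, a in enumerate(self.accessions)}

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __contains__(self, accession: str) -> bool:
        return accession in self._index

    def vector(self, accession: str) -> np.ndarray:
        return self.vectors[self._index[accession]]

    def subset(self, accessions: Sequence[str]) -> "EmbeddingMatrix":
        idx = [self._index[a] for a in accessions]
        return EmbeddingMatrix(
            accessions=list(accessions),
            vectors=self.vectors[idx],
            provenance=self.provenance,
        )

    def design_matrix(self, accessions: Sequence[str]) -> np.ndarray:
        return self.vectors[[self._index[a] for a in accessions]]


@dataclass
class FeatureTable:
    """Sparse non-negative protein x feature matrix (k-mers or domains)."""

    accessions: list[str]
    columns: list[str]
    values: sparse.csr_matrix
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = sparse.csr_matrix(self.values)
        if self.values.shape != (len(self.accessions), len(self.columns)):
            raise ValidationError("feature table shape mismatch")
        if self.values.nnz and self.values.data.min() < 0:
            raise ValidationError("feature values must be non-negative")
        self._index = {a: i for i, a in enumerate(self.accessions)}

    def __contains__(self, accession: str) -> bool:
        return accession in self._index

    def design_matrix(self, accessions: Sequence[str]) -> sparse.csr_matrix:
        return self.values[[self._index[a] for a in accessions]]


# ---------------------------------------------------------------- operations
def truncate_for_embedding(
    seq: SequenceRecord,
    max_model_len: int = MAX_MODEL_LEN,
    keep_len: int = KEEP_LEN,
) -> SequenceRecord:
    """Truncate a sequence for the embedding backend.

    Sequences strictly longer than ``max_model_len`` are cut to their first
    ``keep_len`` residues; shorter sequences pass through unchanged.
    """
    if len(seq.sequence) > max_model_len:
        return SequenceRecord(seq.accession, seq.sequence[:keep_len])
    return seq


def mean_pool(residue_embeddings: np.ndarray) -> np.ndarray:
    """Average pooling over residue positions (rows)."""
    arr = np.asarray(residue_embeddings, dtype=float)
    if arr.ndim != 2 or arr.shape[0] == 0:
        raise ValidationError("mean_pool needs a non-empty L x d matrix")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("non-finite residue embedding")
    return arr.mean(axis=0)


def kmer_feature_table(
    seqs: Iterable[SequenceRecord],
    k: int = 3,
    normalized: bool = True,
    vocabulary: Sequence[str] | None = None,
) -> FeatureTable:
    """Overlapping k-mer frequencies over the 20-letter alphabet.

    Each entry is (count of the k-mer) / (L - k + 1); windows containing a
    non-standard letter are skipped but still counted in the denominator, so
    rows of fully standard sequences sum to 1.  Sequences shorter than k get
    a zero row and a warning.  Passing ``vocabulary`` fixes the column set
    (k-mers outside it are dropped), which lets a trained model featurize
    new sequences in its own feature space.
    """
    seqs = list(seqs)
    standard = set(STANDARD_AA)
    counts: list[dict[str, float]] = []
    seen: dict[str, int] = {}
    keep = set(vocabulary) if vocabulary is not None else None
    for rec in seqs:
        s = rec.sequence
        n_windows = len(s) - k + 1
        row: dict[str, float] = {}
        if n_windows < 1:
            logger.warning("%s shorter than k=%d; zero feature row", rec.accession, k)
        else:
            for i in range(n_windows):
                kmer = s[i : i + k]
                if set(kmer) <= standard and (keep is None or kmer in keep):
                    row[kmer] = row.get(kmer, 0.0) + 1.0
            denom = float(n_windows) if normalized else 1.0
            row = {m: c / denom for m, c in row.items()}
            for m in row:
                seen.setdefault(m, len(seen))
        counts.append(row)

    columns = list(vocabulary) if vocabulary is not None else sorted(seen)
    col_index = {m: j for j, m in enumerate(columns)}
    mat = sparse.lil_matrix((len(seqs), len(columns)))
    for i, row in enumerate(counts):
        for m, v in row.items():
            mat[i, col_index[m]] = v
    return FeatureTable(
        accessions=[r.accession for r in seqs],
        columns=columns,
        values=mat.tocsr(),
        normalized=normalized,
    )


class EmbeddingProvider(Protocol):
    """Backend contract: per-residue embeddings for one sequence.

    The returned matrix has one row per residue position of the (already
    truncated) sequence; any special begin/end tokens the backend uses
    internally must not appear in the output.
    """

    dim: int

    def residue_embeddings(self, seq: SequenceRecord) -> np.ndarray: ...


class OneHotProvider:
    """Deterministic test backend: residue -> one-hot over the 20 letters.

    Mean pooling then yields the amino-acid composition vector exactly.
    Non-standard letters map to the zero vector.
    """

    def __init__(self) -> None:
        self.dim = len(STANDARD_AA)
        self._index = {aa: i for i, aa in enumerate(STANDARD_AA)}

    def residue_embeddings(self, seq: SequenceRecord) -> np.ndarray:
        out = np.zeros((len(seq.sequence), self.dim))
        for i, aa in enumerate(seq.sequence):
            j = self._index.get(aa)
            if j is not None:
                out[i, j] = 1.0
        return out


class SeededGaussianProvider:
    """Deterministic synthetic backend: each letter gets a fixed Gaussian
    vector drawn once from a seeded generator."""

    def __init__(self, dim: int = 32, seed: int = 0) -> None:
        self.dim = dim
        rng = np.random.default_rng(seed)
        self._table = {aa: rng.normal(size=dim) for aa in EXTENDED_AA}

    def residue_embeddings(self, seq: SequenceRecord) -> np.ndarray:
        return np.stack([self._table.get(aa, np.zeros(self.dim)) for aa in seq.sequence])


class TableProvider:
    """Backend serving precomputed per-protein vectors (already pooled)."""

    def __init__(self, table: EmbeddingMatrix) -> None:
        self.dim = table.dim
        self._table = table

    def residue_embeddings(self, seq: SequenceRecord) -> np.ndarray:
        return self._table.vector(seq.accession)[None, :]


def embed_proteins(
    seqs: Iterable[SequenceRecord],
    provider: EmbeddingProvider,
    on_error: Callable[[str, Exception], None] | None = None,
) -> EmbeddingMatrix:
    """Truncate, embed and mean-pool each sequence.

    Proteins for which the provider fails are omitted from the output; the
    failure is reported through ``on_error`` (default: logged).
    """
    accessions: list[str] = []
    rows: list[np.ndarray] = []
    for rec in seqs:
        try:
            truncated = truncate_for_embedding(rec)
            rows.append(mean_pool(provider.residue_embeddings(truncated)))
            accessions.append(rec.accession)
        except Exception as exc:  # noqa: BLE001 - provider contract is opaque
            if on_error is not None:
                on_error(rec.accession, exc)
            else:
                logger.error("embedding failed for %s: %s", rec.accession, exc)
    vectors = np.stack(rows) if rows else np.zeros((0, provider.dim))
    return EmbeddingMatrix(
        accessions=accessions,
        vectors=vectors,
        provenance=f"{type(provider).__name__}+mean_pool",
    )


# ----------------------------------------------------------------------- I/O
def read_fasta(path_or_handle) -> list[SequenceRecord]:
    return [
        SequenceRecord(accession=r.id, sequence=str(r.seq).upper())
        for r in SeqIO.parse(path_or_handle, "fasta")
    ]


def write_fasta(seqs: Iterable[SequenceRecord], handle: TextIO) -> None:
    SeqIO.write(
        (SeqRecord(Seq(s.sequence), id=s.accession, description="") for s in seqs),
        handle,
        "fasta",
    )


def read_embedding_table(path_or_handle) -> EmbeddingMatrix:
    """TSV with an ``accession`` column followed by numeric dimension columns."""
    df = pd.read_csv(path_or_handle, sep="\t", index_col=0)
    return EmbeddingMatrix(
        accessions=[str(a) for a in df.index],
        vectors=df.to_numpy(dtype=float),
        provenance="table",
    )


def write_embedding_table(emb: EmbeddingMatrix, handle: TextIO) -> None:
    df = pd.DataFrame(
        emb.vectors,
        index=pd.Index(emb.accessions, name="accession"),
        columns=[f"d{i}" for i in range(emb.dim)],
    )
    df.to_csv(handle, sep="\t", float_format="%.8g")


def read_domain_table(path_or_handle) -> FeatureTable:
    """Two-column TSV (protein, feature accession) -> sparse binary table."""
    df = pd.read_csv(
        path_or_handle, sep="\t", header=None, names=["protein", "feature"],
        dtype=str, comment="#",
    )
    accessions = sorted(df["protein"].unique())
    columns = sorted(df["feature"].unique())
    ai = {a: i for i, a in enumerate(accessions)}
    ci = {c: j for j, c in enumerate(columns)}
    mat = sparse.lil_matrix((len(accessions), len(columns)))
    for p, f in zip(df["protein"], df["feature"]):
        mat[ai[p], ci[f]] = 1.0
    return FeatureTable(
        accessions=accessions, columns=columns, values=mat.tocsr(), normalized=False
    )
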