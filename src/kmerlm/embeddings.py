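"""Labelled k-mer embedding tables and word2vec-text serialization.

An :class:`EmbeddingTable` is a matrix of per-token vectors from any
source: extracted from a trained model, one-hot, or loaded from an
external word2vec-format text file (header ``"V d"``, then one
``token v1 ... vd`` row per line).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kmer_tokens import ALPHABET


class EmbeddingParseError(ValueError):
    """Malformed word2vec text file."""


@dataclass
class EmbeddingTable:
    row_labels: list[str]
    matrix: np.ndarray
    source: str = "model"  # one of {model, one_hot, external}
    includes_specials: bool = False
    index: dict[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if len(self.row_labels) != self.matrix.shape[0]:
            raise ValueError("one label per matrix row required")
        if len(set(self.row_labels)) != len(self.row_labels):
            dup = [t for t in self.row_labels
                   if self.row_labels.count(t) > 1][0]
            raise ValueError(f"duplicate token label {dup!r}")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("matrix contains non-finite entries")
        if self.matrix.shape[1] < 1:
            raise ValueError("embedding dimension must be >= 1")
        if not self.index:
            self.index = {t: i for i, t in enumerate(self.row_labels)}

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    def vector(self, token: str) -> np.ndarray:
        return self.matrix[self.index[token]]

    def kmers_only(self) -> "EmbeddingTable":
        """Drop special-token rows (labels not over the ACGT alphabet)."""
        keep = [i for i, t in enumerate(self.row_labels)
                if all(c in ALPHABET for c in t)]
        return EmbeddingTable(
            row_labels=[self.row_labels[i] for i in keep],
            matrix=self.matrix[keep],
            source=self.source,
            includes_specials=False,
        )


def save_embedding_table(table: EmbeddingTable, path) -> None:
    """Write in word2vec text format: ``V d`` header then token rows."""
    with open(path, "w") as fh:
        fh.write(f"{table.n_rows} {table.dim}\n")
        for label, row in zip(table.row_labels, table.matrix):
            vals = " ".join(repr(float(v)) for v in row)
            fh.write(f"{label} {vals}\n")


def load_embedding_table(path, expected_k: int | None = None,
                         source: str = "external") -> EmbeddingTable:
    """Parse a word2vec text file into an EmbeddingTable.

    Raises
    ------
    EmbeddingParseError
        On a malformed header or a row with the wrong number of values
        (the message carries the 1-based line number).
    ValueError
        If ``expected_k`` is given and a label is not a k-mer of that
        length, or labels are duplicated.
    """
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise EmbeddingParseError(
                "line 1: expected header 'V d' with two integers")
        try:
            n_rows, dim = int(header[0]), int(header[1])
        except ValueError:
            raise EmbeddingParseError(
                "line 1: expected header 'V d' with two integers")
        labels: list[str] = []
        rows = np.empty((n_rows, dim), dtype=float)
        for i in range(n_rows):
            line = fh.readline()
            lineno = i + 2
            parts = line.split()
            if len(parts) != dim + 1:
                raise EmbeddingParseError(
                    f"line {lineno}: expected 1 token + {dim} values, "
                    f"got {len(parts)} fields")
            labels.append(parts[0])
            try:
                rows[i] = [float(v) for v in parts[1:]]
            except ValueError:
                raise EmbeddingParseError(
                    f"line {lineno}: non-numeric embedding value")
    if expected_k is not None:
        for label in labels:
            if len(label) != expected_k or any(c not in ALPHABET
                                               for c in label):
                raise ValueError(
                    f"label {label!r} is not a {expected_k}-mer over ACGT")
    return EmbeddingTable(row_labels=labels, matrix=rows, source=source,
                          includes_specials=any(t.startswith("[")
                                                for t in labels))
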