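"""Word vectors and description-derived label embeddings.

Word vectors are consumed in the word2vec text or binary interchange layout
(header line ``<count> <dim>``, then one token per row). Label embeddings
place each ICD-9 category in the same vector space as the words by averaging
the embedding vectors of its description tokens, so that word-label and
text-label cosine similarities are well defined.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus import CodeDescription, PAD_TOKEN, UNK_TOKEN, tokenize

logger = logging.getLogger(__name__)


@dataclass
class EmbeddingMatrix:
    """Token embedding table: row ``i`` is the vector for ``vocab[i]``.

    Always contains the reserved padding row (index 0, all zeros) and
    unknown row (index 1, the mean of all loaded vectors).
    """

    vocab: list[str]
    vectors: np.ndarray  # (len(vocab), e)

    def __post_init__(self) -> None:
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.vocab):
            raise ValueError("vectors must be (len(vocab), e)")
        self.index = {tok: i for i, tok in enumerate(self.vocab)}

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def lookup(self, token: str) -> np.ndarray:
        """Vector for ``token``; the unknown row when absent."""
        return self.vectors[self.index.get(token, self.index[UNK_TOKEN])]

    def encode(self, tokens: Sequence[str]) -> np.ndarray:
        """Integer ids for a token sequence (unknown id when absent)."""
        unk = self.index[UNK_TOKEN]
        return np.array([self.index.get(t, unk) for t in tokens], dtype=np.int64)


@dataclass
class LabelEmbeddingMatrix:
    """Label embedding table: row ``i`` is the vector for ``labels[i]``,
    in the same space (same dimension) as the word embeddings."""

    labels: list[str]
    vectors: np.ndarray  # (L, e)

    def __post_init__(self) -> None:
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.labels):
            raise ValueError("vectors must be (len(labels), e)")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


def _open_maybe_gzip(path: Path, mode: str):
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _with_reserved(vocab: list[str], vectors: np.ndarray) -> EmbeddingMatrix:
    e = vectors.shape[1]
    unk = vectors.mean(axis=0) if len(vectors) else np.zeros(e)
    full = np.vstack([np.zeros(e), unk, vectors])
    return EmbeddingMatrix(vocab=[PAD_TOKEN, UNK_TOKEN] + vocab, vectors=full)


def load_word_vectors(path: str | Path, format: str = "word2vec-text") -> EmbeddingMatrix:
    """Load pretrained word vectors, prepending the padding and unknown rows.

    ``format`` is ``word2vec-text`` (one ``token v1 .. ve`` line per row,
    after a ``count dim`` header) or ``word2vec-binary`` (same header, then
    ``token`` + space + ``dim`` little-endian float32 values per row).
    Optionally gzip-compressed (``.gz`` suffix).
    """
    path = Path(path)
    if format == "word2vec-text":
        with _open_maybe_gzip(path, "rt") as fh:
            header = fh.readline().split()
            if len(header) != 2:
                raise ValueError(f"{path}: malformed word2vec header {header!r}")
            n, e = int(header[0]), int(header[1])
            vocab, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                if len(parts) < 2:
                    continue
                vals = np.array(parts[1:], dtype=np.float64)
                if vals.shape[0] != e:
                    raise ValueError(
                        f"{path}: token {parts[0]!r} has {vals.shape[0]} values, expected {e}"
                    )
                vocab.append(parts[0])
                rows.append(vals)
        if len(vocab) != n:
            logger.warning("%s: header declares %d rows, read %d", path, n, len(vocab))
        vectors = np.array(rows) if rows else np.zeros((0, e))
    elif format == "word2vec-binary":
        with _open_maybe_gzip(path, "rb") as fh:
            header = fh.readline().split()
            n, e = int(header[0]), int(header[1])
            vocab, rows = [], []
            for _ in range(n):
                tok = bytearray()
                while True:
                    ch = fh.read(1)
                    if not ch or ch == b" ":
                        break
                    if ch != b"\n":
                        tok.extend(ch)
                buf = fh.read(4 * e)
                if len(buf) != 4 * e:
                    raise ValueError(f"{path}: truncated vector for {tok.decode()!r}")
                vocab.append(tok.decode("utf-8"))
                rows.append(np.frombuffer(buf, dtype=np.float32).astype(np.float64))
        vectors = np.array(rows) if rows else np.zeros((0, e))
    else:
        raise ValueError(f"unknown format {format!r}")
    return _with_reserved(vocab, vectors)


def save_word_vectors(
    vocab: Sequence[str], vectors: np.ndarray, path: str | Path, format: str = "word2vec-text"
) -> None:
    """Write vectors in the word2vec interchange layout (reserved rows excluded)."""
    path = Path(path)
    n, e = vectors.shape
    if format == "word2vec-text":
        with _open_maybe_gzip(path, "wt") as fh:
            fh.write(f"{n} {e}\n")
            for tok, row in zip(vocab, vectors):
                fh.write(tok + " " + " ".join(f"{x:.8g}" for x in row) + "\n")
    elif format == "word2vec-binary":
        with _open_maybe_gzip(path, "wb") as fh:
            fh.write(f"{n} {e}\n".encode())
            for tok, row in zip(vocab, vectors):
                fh.write(tok.encode("utf-8") + b" ")
                fh.write(row.astype(np.float32).tobytes())
    else:
        raise ValueError(f"unknown format {format!r}")


def build_label_embeddings(
    descriptions: Sequence[CodeDescription],
    emb: EmbeddingMatrix,
    labels: Sequence[str] | None = None,
    missing: str = "error",
) -> LabelEmbeddingMatrix:
    """Embed each label as the mean of its description's token vectors.

    Description text is tokenised like note text; tokens absent from the
    vocabulary fall back to the unknown row, and a label whose description is
    entirely out-of-vocabulary gets the unknown row itself. ``labels`` fixes
    the row order (the canonical label index); by default the description
    table's code order is used. ``missing`` controls labels without any
    description row: ``"error"`` (default) or ``"unknown"`` (warn and use the
    unknown row).
    """
    by_code = {d.code: d.description for d in descriptions}
    label_order = list(labels) if labels is not None else [d.code for d in descriptions]
    unk_row = emb.vectors[emb.index[UNK_TOKEN]]
    rows = []
    for code in label_order:
        if code not in by_code:
            if missing == "unknown":
                logger.warning("label %s has no description; using the unknown vector", code)
                rows.append(unk_row.copy())
                continue
            raise ValueError(f"label {code} has no description row")
        toks = tokenize(by_code[code])
        if not toks:
            rows.append(unk_row.copy())
            continue
        rows.append(np.mean([emb.lookup(t) for t in toks], axis=0))
    return LabelEmbeddingMatrix(labels=label_order, vectors=np.array(rows))
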