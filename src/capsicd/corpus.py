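"""Corpus ingestion and preparation for medical-code prediction.

Reads the three tables the pipeline consumes — free-text notes, per-admission
ICD-9 diagnoses, and ICD-9 category descriptions — normalises and rolls the
codes up to 3-digit category roots, tokenises the notes, selects the label
space, and splits the corpus into train/validation/test.
"""

from __future__ import annotations

import json
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Reserved vocabulary entries. Index 0 is padding, index 1 the unknown token.
PAD_TOKEN = "<pad>"
UNK_TOKEN = "<unk>"

#: Valid ICD-9 code shapes after whitespace/dot stripping: numeric (3-5
#: digits), V-codes (V + 2-4 digits) and E-codes (E + 3-4 digits).
ICD9_PATTERN = re.compile(r"^(?:[0-9]{3,5}|V[0-9]{2,4}|E[0-9]{3,4})$")

_WORD_RE = re.compile(r"[a-z0-9]+")


@dataclass
class RawNote:
    """One clinical note row: patient id, admission id, free text."""

    subject_id: str
    hadm_id: str
    text: str


@dataclass
class DiagnosisRecord:
    """One admission-level diagnosis: admission id, priority, ICD-9 code."""

    hadm_id: str
    seq_num: int
    icd9_code: str


@dataclass
class CodeDescription:
    """Textual description of a 3-digit ICD-9 category root."""

    code: str
    description: str


@dataclass
class TokenizedNote:
    """A preprocessed note: token sequence plus its gold 3-digit code set."""

    hadm_id: str
    tokens: list[str]
    codes: set[str] = field(default_factory=set)


@dataclass
class DatasetSplit:
    """Disjoint, exhaustive train/validation/test partition of the notes."""

    train: list[TokenizedNote]
    valid: list[TokenizedNote]
    test: list[TokenizedNote]
    seed: int

    def __iter__(self):
        return iter((self.train, self.valid, self.test))


class SchemaError(ValueError):
    """A required column is missing from an input table."""


def _read_table(path: str | Path, required: Mapping[str, str]) -> pd.DataFrame:
    """Read a CSV/TSV and rename ``required`` (role -> column name) to roles."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [col for col in required.values() if col not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    return df.rename(columns={v: k for k, v in required.items()})


def read_notes(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[RawNote]:
    """Read the notes table into :class:`RawNote` rows, preserving order.

    ``column_map`` maps the roles ``subject_id``, ``hadm_id``, ``text`` to
    the file's column names; the default follows the MIMIC-III NOTEEVENTS
    convention (SUBJECT_ID, HADM_ID, TEXT). Quoted multi-line text fields
    are preserved verbatim. Empty texts are kept but counted in a warning.
    """
    cols = dict(column_map or {"subject_id": "SUBJECT_ID", "hadm_id": "HADM_ID", "text": "TEXT"})
    df = _read_table(path, cols)
    notes = [
        RawNote(subject_id=row.subject_id, hadm_id=row.hadm_id, text=row.text)
        for row in df.itertuples(index=False)
    ]
    n_empty = sum(1 for n in notes if not n.text.strip())
    if n_empty:
        logger.warning("%d of %d notes have empty text", n_empty, len(notes))
    return notes


def normalize_icd9(code: str) -> str:
    """Strip whitespace and dots and uppercase an ICD-9 code string."""
    return code.strip().replace(".", "").replace(" ", "").upper()


def read_diagnoses(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[DiagnosisRecord]:
    """Read the diagnosis table; malformed codes are rejected with a warning."""
    cols = dict(
        column_map
        or {"hadm_id": "HADM_ID", "seq_num": "SEQ_NUM", "icd9_code": "ICD9_CODE"}
    )
    df = _read_table(path, cols)
    records: list[DiagnosisRecord] = []
    n_bad = 0
    for row in df.itertuples(index=False):
        code = normalize_icd9(row.icd9_code)
        if not ICD9_PATTERN.match(code):
            n_bad += 1
            logger.warning("rejecting malformed ICD-9 code %r (hadm %s)", row.icd9_code, row.hadm_id)
            continue
        records.append(
            DiagnosisRecord(hadm_id=row.hadm_id, seq_num=int(row.seq_num), icd9_code=code)
        )
    if n_bad:
        logger.warning("rejected %d malformed diagnosis rows", n_bad)
    return records


def read_descriptions(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[CodeDescription]:
    """Read the code-description table (CSV, or two-column TSV), keyed by root."""
    cols = dict(column_map or {"code": "ICD9_CODE", "description": "DESCRIPTION"})
    path = Path(path)
    if path.suffix.lower() in {".tsv", ".tab"}:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        if df.shape[1] < 2:
            raise SchemaError(f"{path}: expected two columns (code, description)")
        df = df.iloc[:, :2]
        df.columns = ["code", "description"]
    else:
        df = _read_table(path, cols)
    out: dict[str, CodeDescription] = {}
    for row in df.itertuples(index=False):
        code = normalize_icd9(row.code)
        if not row.description.strip():
            logger.warning("empty description for code %s", code)
            continue
        out[code] = CodeDescription(code=code, description=row.description)
    return list(out.values())


def truncate_icd9(code: str, scheme: str = "icd9cm") -> str:
    """Roll an ICD-9 code up to its 3-digit category root.

    Numeric codes keep their first three digits (45829 -> 458). Under the
    default ``icd9cm`` scheme, V-codes roll to V + two digits (V4501 -> V45)
    and E-codes to E + three digits (E9342 -> E934), matching the ICD-9-CM
    category convention; ``scheme="first3"`` takes the literal first three
    characters for every code.
    """
    code = normalize_icd9(code)
    if not ICD9_PATTERN.match(code):
        raise ValueError(f"not a valid ICD-9 code: {code!r}")
    if scheme == "first3":
        return code[:3]
    if scheme != "icd9cm":
        raise ValueError(f"unknown rollup scheme: {scheme!r}")
    if code.startswith("E"):
        return code[:4]
    return code[:3]  # numeric and V-codes: three characters


def tokenize(text: str) -> list[str]:
    """Lowercase and split on alphanumeric runs (punctuation discarded)."""
    return _WORD_RE.findall(text.lower())


def preprocess_text(
    text: str,
    stopwords: Iterable[str] | None = None,
    min_token_freq: int = 1,
    max_len: int = 2500,
    token_freqs: Mapping[str, int] | None = None,
) -> list[str]:
    """Tokenise one note: lowercase, strip punctuation, drop stopwords,
    replace rare tokens by the unknown token, truncate to ``max_len``.

    ``token_freqs`` holds corpus-level token counts and is required whenever
    ``min_token_freq`` > 1; tokens with corpus frequency below the cut are
    mapped to :data:`UNK_TOKEN` rather than dropped, preserving positions.
    """
    if min_token_freq > 1 and token_freqs is None:
        raise ValueError("min_token_freq > 1 requires corpus-level token_freqs")
    stop = set(stopwords or ())
    out: list[str] = []
    for tok in tokenize(text):
        if tok in stop:
            continue
        if min_token_freq > 1 and token_freqs.get(tok, 0) < min_token_freq:
            tok = UNK_TOKEN
        out.append(tok)
        if len(out) >= max_len:
            break
    if not out:
        logger.warning("note reduced to an empty token sequence")
    return out


def corpus_token_frequencies(texts: Iterable[str]) -> Counter:
    """Corpus-level token counts over raw (tokenised, unfiltered) texts."""
    freqs: Counter = Counter()
    for text in texts:
        freqs.update(tokenize(text))
    return freqs


def select_label_space(code_counts: Mapping[str, int], k: int) -> list[str]:
    """The ``k`` most frequent 3-digit roots, ties broken lexicographically.

    The returned order is the canonical label index used everywhere
    downstream (label-embedding rows, score columns, tie-breaks).
    """
    if k > len(code_counts):
        raise ValueError(f"k={k} exceeds the {len(code_counts)} distinct roots")
    ranked = sorted(code_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [code for code, _ in ranked[:k]]


def split_dataset(
    notes: Sequence[TokenizedNote],
    ratios: tuple[float, float, float] = (0.7, 0.1, 0.2),
    seed: int = 0,
) -> DatasetSplit:
    """Randomly partition notes into train/valid/test at the given ratios.

    Deterministic for a fixed seed; the partition is exhaustive and disjoint,
    with split sizes within one note of the exact fractions.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    n = len(notes)
    order = np.random.default_rng(seed).permutation(n)
    n_train = int(round(ratios[0] * n))
    n_valid = int(round(ratios[1] * n))
    n_train = min(n_train, n)
    n_valid = min(n_valid, n - n_train)
    idx_train = order[:n_train]
    idx_valid = order[n_train : n_train + n_valid]
    idx_test = order[n_train + n_valid :]
    return DatasetSplit(
        train=[notes[i] for i in idx_train],
        valid=[notes[i] for i in idx_valid],
        test=[notes[i] for i in idx_test],
        seed=seed,
    )


def build_corpus(
    notes: Sequence[RawNote],
    diagnoses: Sequence[DiagnosisRecord],
    n_labels: int,
    stopwords: Iterable[str] | None = None,
    min_token_freq: int = 3,
    max_len: int = 2500,
    rollup_scheme: str = "icd9cm",
) -> tuple[list[TokenizedNote], list[str], Counter]:
    """Assemble the processed corpus: tokenised notes with rolled-up gold
    code sets restricted to the selected label space.

    Multiple note rows for one admission are concatenated in file order.
    Notes left with no gold code after label-space filtering are dropped
    with a logged count. Returns (tokenized notes, label space, corpus
    token frequencies).
    """
    texts: dict[str, list[str]] = {}
    for note in notes:
        if not note.hadm_id:
            raise ValueError("note with empty hadm_id")
        texts.setdefault(note.hadm_id, []).append(note.text)
    merged = {hadm: "\n".join(parts) for hadm, parts in texts.items()}

    codes_by_hadm: dict[str, set[str]] = {}
    root_counts: Counter = Counter()
    for rec in diagnoses:
        root = truncate_icd9(rec.icd9_code, scheme=rollup_scheme)
        if rec.hadm_id in merged:
            codes_by_hadm.setdefault(rec.hadm_id, set()).add(root)
    # label frequency counted over admissions (one count per admission-root pair)
    for roots in codes_by_hadm.values():
        root_counts.update(roots)

    label_space = select_label_space(root_counts, min(n_labels, len(root_counts)))
    label_set = set(label_space)

    freqs = corpus_token_frequencies(merged.values())
    tokenized: list[TokenizedNote] = []
    n_dropped = 0
    for hadm, text in merged.items():
        codes = codes_by_hadm.get(hadm, set()) & label_set
        if not codes:
            n_dropped += 1
            continue
        tokens = preprocess_text(
            text, stopwords=stopwords, min_token_freq=min_token_freq,
            max_len=max_len, token_freqs=freqs,
        )
        tokenized.append(TokenizedNote(hadm_id=hadm, tokens=tokens, codes=codes))
    if n_dropped:
        logger.info("dropped %d notes with no gold code in the label space", n_dropped)
    return tokenized, label_space, freqs


def save_tokenized(notes: Iterable[TokenizedNote], path: str | Path) -> None:
    """Serialise tokenised notes to JSON-lines (one note per line)."""
    with open(path, "w") as fh:
        for note in notes:
            fh.write(
                json.dumps(
                    {"hadm_id": note.hadm_id, "tokens": note.tokens, "codes": sorted(note.codes)}
                )
                + "\n"
            )


def load_tokenized(path: str | Path) -> list[TokenizedNote]:
    """Load tokenised notes from JSON-lines written by :func:`save_tokenized`."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            out.append(
                TokenizedNote(hadm_id=obj["hadm_id"], tokens=obj["tokens"], codes=set(obj["codes"]))
            )
    return out
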