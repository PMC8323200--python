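"""Synthetic clinical corpora with planted label-keyword structure.

Every label owns a small disjoint set of signature tokens; its description
is composed of exactly those tokens, so description-derived label embeddings
carry real signal. Each note draws a label multiset from a power-law
popularity distribution and plants each chosen label's signature tokens at
random positions (at a configurable insertion rate) among background tokens
drawn from a Zipf distribution — so rare-token filtering, skewed label
frequencies, multi-label notes and label-description fusion are all
exercised without any restricted data.

With an insertion rate of 1 the corpus is perfectly identifiable: a trivial
keyword-matching classifier reaches micro F1 = 1.0, the ceiling against
which trained models are judged.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus import (
    CodeDescription,
    DiagnosisRecord,
    RawNote,
    TokenizedNote,
    tokenize,
    truncate_icd9,
)
from .embeddings import save_word_vectors

logger = logging.getLogger(__name__)


@dataclass
class SyntheticSpec:
    """Generator condition. Defaults emulate the broad shape of a rolled-up
    hospital coding corpus (many labels, skewed popularity, ~8 codes per
    admission) at a size that keeps note length short for tests; note_length
    can be raised toward ~1500 to emulate full discharge summaries."""

    n_labels: int = 50
    vocab_size: int = 5000
    n_notes: int = 1000
    note_length_mean: float = 200.0
    labels_per_note_mean: float = 8.0
    signature_tokens_per_label: int = 3
    signal_insertion_rate: float = 0.8
    label_popularity: float = 1.5  # power-law exponent over label ranks

    def __post_init__(self) -> None:
        for name in ("n_labels", "vocab_size", "n_notes", "signature_tokens_per_label"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.signal_insertion_rate <= 1.0):
            raise ValueError("signal_insertion_rate must lie in (0, 1]")
        if self.note_length_mean <= 0 or self.labels_per_note_mean <= 0:
            raise ValueError("means must be positive")
        if self.n_labels * self.signature_tokens_per_label >= self.vocab_size:
            raise ValueError(
                f"vocab_size={self.vocab_size} too small for {self.n_labels} disjoint "
                f"signatures of {self.signature_tokens_per_label} tokens plus background"
            )

    @property
    def labels(self) -> list[str]:
        return [f"{i + 1:03d}" for i in range(self.n_labels)]


def benchmark_spec() -> SyntheticSpec:
    """The scaled planted-signal benchmark condition used by the learning
    checks: a 20-label, 3000-note corpus of ~120-token notes over a
    400-token vocabulary, ~3 codes per note with mild popularity skew so
    that no label's presence rate exceeds one half (a marginals-only
    predictor then carries no signal at the 0.5 decision threshold), and
    full signature insertion so the keyword-matching identifiability
    ceiling is exactly micro F1 = 1.0."""
    return SyntheticSpec(
        n_labels=20,
        vocab_size=400,
        n_notes=3000,
        note_length_mean=120.0,
        labels_per_note_mean=3.0,
        signature_tokens_per_label=3,
        signal_insertion_rate=1.0,
        label_popularity=0.5,
    )


def _truncated_poisson(rng: np.random.Generator, mean: float, size: int, low: int = 1) -> np.ndarray:
    out = rng.poisson(mean, size=size)
    while np.any(out < low):
        bad = out < low
        out[bad] = rng.poisson(mean, size=int(bad.sum()))
    return out


def generate_corpus(
    spec: SyntheticSpec, seed: int, with_ledger: bool = False
):
    """Generate (notes, diagnoses, descriptions); deterministic in the seed.

    With ``with_ledger=True`` a fourth element holds the generator's own
    bookkeeping (per-label admission counts, note lengths, codes per note)
    for cross-checking against :func:`corpus_stats`.
    """
    rng = np.random.default_rng(seed)
    labels = spec.labels
    sig = spec.signature_tokens_per_label
    vocab = [f"w{i:05d}" for i in range(spec.vocab_size)]
    signatures = {
        lab: vocab[i * sig : (i + 1) * sig] for i, lab in enumerate(labels)
    }
    background = vocab[spec.n_labels * sig :]
    # Zipf-like background so low-frequency-token filtering has something to do
    bg_p = 1.0 / np.arange(1, len(background) + 1) ** 1.1
    bg_p /= bg_p.sum()
    pop = 1.0 / np.arange(1, spec.n_labels + 1) ** spec.label_popularity
    pop /= pop.sum()

    n_codes = _truncated_poisson(rng, spec.labels_per_note_mean, spec.n_notes)
    lengths = _truncated_poisson(rng, spec.note_length_mean, spec.n_notes, low=10)

    notes: list[RawNote] = []
    diagnoses: list[DiagnosisRecord] = []
    label_counts: Counter = Counter()
    codes_per_note: list[int] = []
    note_lengths: list[int] = []
    for n in range(spec.n_notes):
        hadm = f"H{n:06d}"
        drawn = rng.choice(spec.n_labels, size=n_codes[n], replace=True, p=pop)
        gold = sorted({labels[i] for i in drawn})
        planted: list[str] = []
        for lab in gold:
            keep = rng.random(sig) < spec.signal_insertion_rate
            planted.extend(tok for tok, k in zip(signatures[lab], keep) if k)
        length = max(int(lengths[n]), len(planted) + 1)
        body = list(rng.choice(background, size=length, p=bg_p))
        pos = rng.choice(length, size=len(planted), replace=False)
        for p, tok in zip(pos, planted):
            body[p] = tok
        notes.append(RawNote(subject_id=f"S{n:06d}", hadm_id=hadm, text=" ".join(body)))
        for s, lab in enumerate(gold, start=1):
            diagnoses.append(DiagnosisRecord(hadm_id=hadm, seq_num=s, icd9_code=lab))
        label_counts.update(gold)
        codes_per_note.append(len(gold))
        note_lengths.append(length)

    descriptions = [
        CodeDescription(code=lab, description=" ".join(signatures[lab])) for lab in labels
    ]
    if with_ledger:
        ledger = {
            "label_counts": label_counts,
            "codes_per_note": codes_per_note,
            "note_lengths": note_lengths,
            "signatures": signatures,
        }
        return notes, diagnoses, descriptions, ledger
    return notes, diagnoses, descriptions


def corpus_stats(notes: Sequence[RawNote], diagnoses: Sequence[DiagnosisRecord]) -> dict:
    """Descriptive statistics: per-root admission counts, note token-length
    distribution, codes-per-note distribution."""
    label_counts: Counter = Counter()
    by_hadm: dict[str, set[str]] = {}
    for rec in diagnoses:
        by_hadm.setdefault(rec.hadm_id, set()).add(truncate_icd9(rec.icd9_code))
    for roots in by_hadm.values():
        label_counts.update(roots)
    note_lengths = [len(tokenize(n.text)) for n in notes]
    codes_per_note = [len(by_hadm.get(n.hadm_id, set())) for n in notes]
    return {
        "label_counts": label_counts,
        "note_lengths": note_lengths,
        "codes_per_note": codes_per_note,
        "n_notes": len(notes),
        "mean_codes_per_note": float(np.mean(codes_per_note)) if codes_per_note else 0.0,
        "mean_note_length": float(np.mean(note_lengths)) if note_lengths else 0.0,
    }


def keyword_match_predict(
    notes: Sequence[TokenizedNote] | Sequence[Sequence[str]],
    descriptions: Sequence[CodeDescription],
    labels: Sequence[str],
) -> np.ndarray:
    """Trivial keyword classifier: predict a label whenever any of its
    description tokens occurs in the note. On a corpus with insertion rate 1
    this is the micro-F1 = 1.0 identifiability ceiling."""
    token_to_labels: dict[str, set[int]] = {}
    idx = {lab: j for j, lab in enumerate(labels)}
    for d in descriptions:
        if d.code not in idx:
            continue
        for tok in tokenize(d.description):
            token_to_labels.setdefault(tok, set()).add(idx[d.code])
    out = np.zeros((len(notes), len(labels)))
    for i, note in enumerate(notes):
        toks = note.tokens if isinstance(note, TokenizedNote) else note
        for tok in toks:
            for j in token_to_labels.get(tok, ()):
                out[i, j] = 1.0
    return out


def write_corpus_files(
    out_dir: str | Path,
    notes: Sequence[RawNote],
    diagnoses: Sequence[DiagnosisRecord],
    descriptions: Sequence[CodeDescription],
    embedding_dim: int = 32,
    seed: int = 0,
) -> dict[str, Path]:
    """Write the three CSV tables plus a random word2vec-text embedding file
    covering the corpus vocabulary; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "notes": out_dir / "notes.csv",
        "diagnoses": out_dir / "diagnoses.csv",
        "descriptions": out_dir / "descriptions.csv",
        "embeddings": out_dir / "embeddings.w2v.txt",
    }
    pd.DataFrame(
        {"SUBJECT_ID": [n.subject_id for n in notes],
         "HADM_ID": [n.hadm_id for n in notes],
         "TEXT": [n.text for n in notes]}
    ).to_csv(paths["notes"], index=False)
    pd.DataFrame(
        {"HADM_ID": [d.hadm_id for d in diagnoses],
         "SEQ_NUM": [d.seq_num for d in diagnoses],
         "ICD9_CODE": [d.icd9_code for d in diagnoses]}
    ).to_csv(paths["diagnoses"], index=False)
    pd.DataFrame(
        {"ICD9_CODE": [d.code for d in descriptions],
         "DESCRIPTION": [d.description for d in descriptions]}
    ).to_csv(paths["descriptions"], index=False)
    vocab = sorted({tok for n in notes for tok in tokenize(n.text)}
                   | {tok for d in descriptions for tok in tokenize(d.description)})
    rng = np.random.default_rng(seed + 7)
    vectors = rng.normal(0.0, 1.0, size=(len(vocab), embedding_dim))
    save_word_vectors(vocab, vectors, paths["embeddings"])
    return paths
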