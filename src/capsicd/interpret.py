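"""N-gram attribution from routing couplings.

Each primary capsule corresponds to one n-gram window of the note. The
final-iteration coupling coefficient c_ij measures how strongly that window
supported class j, so summing couplings over the capsule channels at a
position yields a per-(window, label) connection strength — an attention-like
attribution that requires no gradients. Ranked n-grams per label can be
exported as word-cloud weight files (ngram, weight in [0, 1]).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .capsule import RoutingState


@dataclass
class AttributionRecord:
    """One (note, label, window) attribution: the n-gram at ``position``
    supported ``label`` with routing ``strength`` (>= 0)."""

    label: str
    ngram: tuple[str, ...]
    position: int
    strength: float
    note_id: str = ""


def connection_strengths(
    trace: RoutingState,
    tokens: Sequence[str],
    kernel_size: int,
    n_channels: int = 1,
    labels: Sequence[str] | None = None,
    note_id: str = "",
    aggregate: str = "sum",
) -> list[AttributionRecord]:
    """Per-(window, label) strengths from a routing trace of the same note.

    ``aggregate`` combines the channels at one position: ``sum`` (default;
    preserves the property that mean-coupling strengths at a position sum to
    1 over labels) or ``max``. Records are sorted by descending strength
    within each label.
    """
    n_windows = len(tokens) - kernel_size + 1
    C_p, k = trace.c.shape
    if n_windows < 1 or C_p != n_windows * n_channels:
        raise ValueError(
            f"trace has {C_p} capsules but the note yields {max(n_windows, 0)} windows "
            f"x {n_channels} channels"
        )
    if aggregate not in {"sum", "max"}:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    names = list(labels) if labels is not None else [str(j) for j in range(k)]
    c = trace.c.reshape(n_windows, n_channels, k)
    strength = c.sum(axis=1) if aggregate == "sum" else c.max(axis=1)
    records: list[AttributionRecord] = []
    for j, label in enumerate(names):
        order = np.argsort(-strength[:, j], kind="stable")
        for w in order:
            records.append(
                AttributionRecord(
                    label=label,
                    ngram=tuple(tokens[w : w + kernel_size]),
                    position=int(w),
                    strength=float(strength[w, j]),
                    note_id=note_id,
                )
            )
    return records


def top_ngrams(
    records: Sequence[AttributionRecord], label: str, n: int
) -> list[tuple[tuple[str, ...], float]]:
    """The ``n`` strongest distinct n-grams for ``label``; repeated n-grams
    are merged by their maximum strength."""
    if n < 1:
        raise ValueError("n must be >= 1")
    known = {r.label for r in records}
    if label not in known:
        raise ValueError(f"unknown label {label!r}; records cover {sorted(known)}")
    best: dict[tuple[str, ...], float] = {}
    for r in records:
        if r.label != label:
            continue
        if r.ngram not in best or r.strength > best[r.ngram]:
            best[r.ngram] = r.strength
    ranked = sorted(best.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:n]


def export_wordcloud_weights(
    records: Sequence[AttributionRecord], label: str, path: str | Path
) -> None:
    """Write a two-column CSV (ngram, weight) for ``label`` with weights
    scaled to [0, 1] (the strongest n-gram gets exactly 1); any word-cloud
    renderer can consume it."""
    ranked = top_ngrams(records, label, n=len(records))
    top = ranked[0][1]
    scale = 1.0 / top if top > 0 else 0.0
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["ngram", "weight"])
        for ngram, strength in ranked:
            writer.writerow([" ".join(ngram), f"{strength * scale:.6f}"])


def export_attributions(records: Sequence[AttributionRecord], path: str | Path) -> None:
    """Write the full attribution table (note_id, label, position, ngram,
    strength) as CSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["note_id", "label", "position", "ngram", "strength"])
        for r in records:
            writer.writerow([r.note_id, r.label, r.position, " ".join(r.ngram), f"{r.strength:.8g}"])
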