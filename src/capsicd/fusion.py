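"""Joint label-embedding fusion.

Label information enters the classifier twice: before encoding, each token's
cosine similarity to every label vector (G = C (x) V) is concatenated onto
its word embedding, so the encoder sees which words resemble which code
descriptions; after encoding, the cosine similarity between the pooled text
representation and each label vector (D = Z (x) C) is concatenated onto the
capsule features feeding the classification head. Zero-norm vectors (the
padding row) have similarity 0 by convention.
"""

from __future__ import annotations

import numpy as np

EPS = 1e-12


def cosine(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity in [-1, 1]; 0 when either vector has zero norm."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def cosine_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarities: (n, e) x (m, e) -> (n, m), with the
    zero-norm-maps-to-zero convention applied row/column-wise."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"dimension mismatch: {A.shape[1]} vs {B.shape[1]}")
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    out = (A @ B.T) / np.maximum(na[:, None] * nb[None, :], EPS)
    out[na == 0.0, :] = 0.0
    out[:, nb == 0.0] = 0.0
    return out


def word_label_similarity(C: np.ndarray, V_seq: np.ndarray) -> np.ndarray:
    """G[i, t] = cosine(C_i, V_t) for label vectors C (L, e) and token
    embeddings V_seq (T, e); returns (L, T)."""
    return cosine_matrix(C, V_seq)


def augment_tokens(G: np.ndarray, V_seq: np.ndarray) -> np.ndarray:
    """Concatenate each token's label-similarity column onto its embedding:
    (L, T) similarities + (T, e) embeddings -> (T, e + L)."""
    G = np.asarray(G, dtype=float)
    V_seq = np.asarray(V_seq, dtype=float)
    if G.shape[1] != V_seq.shape[0]:
        raise ValueError(f"G has {G.shape[1]} positions but V_seq has {V_seq.shape[0]}")
    return np.concatenate([V_seq, G.T], axis=1)


def sentence_label_similarity(
    z: np.ndarray, C: np.ndarray, projection: np.ndarray | None = None
) -> np.ndarray:
    """D[i] = cosine(project(z), C_i) for a pooled text vector z.

    ``projection`` (len(z), e) maps the text representation into the shared
    embedding space; identity (z already e-dimensional) when omitted.
    """
    z = np.asarray(z, dtype=float)
    p = z if projection is None else z @ np.asarray(projection, dtype=float)
    C = np.asarray(C, dtype=float)
    if p.shape[0] != C.shape[1]:
        raise ValueError(f"projected z has dim {p.shape[0]}, labels have {C.shape[1]}")
    return cosine_matrix(p[None, :], C)[0]


def fuse_for_classification(capsule_features: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Concatenate flattened class-capsule features with the label-similarity
    vector; the result feeds the classification head."""
    return np.concatenate([np.ravel(capsule_features), np.ravel(D)])
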