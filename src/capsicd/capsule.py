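"""Capsule layers: n-gram convolution, primary capsules, dynamic routing.

An n-gram convolution turns the encoded sequence into window features; each
window is mapped to one or more pose vectors (primary capsules) through a
shared transform followed by the squashing nonlinearity

    v = (|s|^2 / (1 + |s|^2)) * (s / |s|),

whose output length lies in [0, 1) and preserves direction. Class capsules
are then computed by routing-by-agreement: prediction vectors
u_hat_{j|i} = W_ij u_i are combined with coupling coefficients c_ij obtained
by softmaxing logits b_ij over classes; per iteration

    c_ij = exp(b_ij) / sum_k exp(b_ik)
    s_j  = sum_i c_ij u_hat_{j|i}
    v_j  = squash(s_j)
    b_ij <- b_ij + u_hat_{j|i} . v_j      (skipped after the final iteration)

with b initialised to zero. The class score is |v_j|. The final couplings
are kept as a trace: they say how strongly each n-gram window supported each
class and drive the attribution module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EPS = 1e-12


def squash(s: np.ndarray, axis: int = -1) -> np.ndarray:
    """Squashing nonlinearity applied along ``axis``; squash(0) = 0."""
    s = np.asarray(s, dtype=float)
    norm = np.linalg.norm(s, axis=axis, keepdims=True)
    scale = (norm * norm) / (1.0 + norm * norm) / (norm + EPS)
    return scale * s


def _softmax_classes(b: np.ndarray) -> np.ndarray:
    """Softmax over the class axis (last), max-subtracted for stability."""
    z = b - b.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class FeatureMap:
    """Convolutional n-gram feature maps: positions x filters."""

    M: np.ndarray  # (T - K1 + 1, n_filters)
    K1: int


@dataclass
class PrimaryCapsules:
    """Squashed pose vectors, one row per (window, channel) capsule."""

    P: np.ndarray  # (C_p, d)
    d: int
    n_channels: int = 1

    def window_of(self, i: int) -> int:
        """Window (position) index of capsule ``i`` under channel tiling."""
        return i // self.n_channels


@dataclass
class RoutingState:
    """Full trace of the dynamic-routing procedure.

    ``b``, ``c``, ``v`` are the final logits, couplings and class capsules;
    ``history`` stores (b, c, s, v) per iteration for inspection.
    """

    u_hat: np.ndarray  # (C_p, k, d)
    b: np.ndarray  # (C_p, k)
    c: np.ndarray  # (C_p, k)
    v: np.ndarray  # (k, d)
    iterations: int
    history: list[dict] = field(default_factory=list)

    def to_jsonable(self) -> dict:
        return {
            "iterations": self.iterations,
            "couplings": self.c.tolist(),
            "class_norms": np.linalg.norm(self.v, axis=-1).tolist(),
        }


def conv_ngram(
    X: np.ndarray, W_a: np.ndarray, b_0: np.ndarray | float = 0.0, activation: str = "relu"
) -> FeatureMap:
    """Valid n-gram convolution: filters W_a (n_filters, K1, e_in) slide over
    the (T, e_in) sequence; m_i^a = f(<X_i, W^a> + b_0)."""
    X = np.asarray(X, dtype=float)
    W_a = np.asarray(W_a, dtype=float)
    if W_a.ndim != 3 or X.ndim != 2 or W_a.shape[2] != X.shape[1]:
        raise ValueError(f"incompatible shapes X {X.shape}, W_a {W_a.shape}")
    n_filters, K1, _ = W_a.shape
    T = X.shape[0]
    if T < K1:
        raise ValueError(f"sequence length {T} shorter than window {K1}")
    windows = sliding_windows(X, K1)  # (N_w, K1*e_in)
    raw = windows @ W_a.reshape(n_filters, -1).T + np.asarray(b_0)
    if activation == "relu":
        M = np.maximum(raw, 0.0)
    elif activation == "tanh":
        M = np.tanh(raw)
    else:
        raise ValueError(f"unknown activation {activation!r}")
    return FeatureMap(M=M, K1=K1)


def sliding_windows(X: np.ndarray, K1: int) -> np.ndarray:
    """All length-K1 windows of a (T, e) sequence, flattened: (T-K1+1, K1*e)."""
    T, e = X.shape
    view = np.lib.stride_tricks.sliding_window_view(X, (K1, e))[:, 0]
    return view.reshape(T - K1 + 1, K1 * e)


def primary_capsules(
    M: FeatureMap | np.ndarray, W_b: np.ndarray, b_1: np.ndarray | float = 0.0, d: int | None = None
) -> PrimaryCapsules:
    """Map each window's feature column to capsule pose vectors and squash.

    ``W_b`` has shape (n_filters, n_channels * d): every window yields
    ``n_channels`` capsules of dimension ``d`` (n_channels = 1 reproduces the
    single-capsule-per-window layout).
    """
    Mm = M.M if isinstance(M, FeatureMap) else np.asarray(M, dtype=float)
    W_b = np.asarray(W_b, dtype=float)
    if Mm.shape[1] != W_b.shape[0]:
        raise ValueError(f"feature dim {Mm.shape[1]} != W_b rows {W_b.shape[0]}")
    if d is None:
        d = W_b.shape[1]
    if W_b.shape[1] % d:
        raise ValueError("W_b columns must be a multiple of d")
    n_channels = W_b.shape[1] // d
    raw = Mm @ W_b + np.asarray(b_1)  # (N_w, n_channels*d)
    P = squash(raw.reshape(-1, d))
    return PrimaryCapsules(P=P, d=d, n_channels=n_channels)


def dynamic_routing(u_hat: np.ndarray, iterations: int) -> RoutingState:
    """Routing-by-agreement over prediction vectors u_hat (C_p, k, d)."""
    u_hat = np.asarray(u_hat, dtype=float)
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if not np.all(np.isfinite(u_hat)):
        raise ValueError("u_hat must be finite")
    C_p, k, d = u_hat.shape
    b = np.zeros((C_p, k))
    history: list[dict] = []
    for it in range(iterations):
        c = _softmax_classes(b)
        s = np.einsum("ij,ijd->jd", c, u_hat)
        v = squash(s)
        history.append({"b": b.copy(), "c": c.copy(), "s": s.copy(), "v": v.copy()})
        if it < iterations - 1:
            b = b + np.einsum("ijd,jd->ij", u_hat, v)
    return RoutingState(u_hat=u_hat, b=history[-1]["b"], c=history[-1]["c"], v=history[-1]["v"], iterations=iterations, history=history)


def class_scores(
    P: PrimaryCapsules | np.ndarray, W_ij: np.ndarray, iterations: int = 3
) -> tuple[np.ndarray, RoutingState]:
    """Class-capsule scores |v_j| from primary capsules.

    ``W_ij`` is (C_p, k, d_out, d_in), or (k, d_out, d_in) to share one
    transform per class across all capsules.
    """
    Pm = P.P if isinstance(P, PrimaryCapsules) else np.asarray(P, dtype=float)
    W_ij = np.asarray(W_ij, dtype=float)
    if W_ij.ndim == 3:
        u_hat = np.einsum("jab,ib->ija", W_ij, Pm)
    elif W_ij.ndim == 4:
        if W_ij.shape[0] != Pm.shape[0]:
            raise ValueError(f"W_ij has {W_ij.shape[0]} capsules, P has {Pm.shape[0]}")
        u_hat = np.einsum("ijab,ib->ija", W_ij, Pm)
    else:
        raise ValueError("W_ij must be (k,d,d) or (C_p,k,d,d)")
    trace = dynamic_routing(u_hat, iterations)
    return np.linalg.norm(trace.v, axis=-1), trace


# ---------------------------------------------------------------------------
# Batched forward/backward used by the trainable network


def squash_forward(s: np.ndarray):
    norm = np.linalg.norm(s, axis=-1, keepdims=True)
    scale = (norm * norm) / (1.0 + norm * norm) / (norm + EPS)
    return scale * s, (s, norm)


def squash_backward(dv: np.ndarray, cache) -> np.ndarray:
    """Jacobian-vector product of the squash along the last axis."""
    s, norm = cache
    n = norm + EPS
    # v = scale(|s|) * s with scale(n) = n / (1 + n^2); hence
    # dL/ds = scale * dL/dv + scale'(|s|) * (s . dL/dv) * s / |s|,
    # scale'(n) = (1 - n^2) / (1 + n^2)^2. The second term vanishes at s = 0.
    scale = (norm * norm) / (1.0 + norm * norm) / n
    dscale_dnorm = (1.0 - norm * norm) / (1.0 + norm * norm) ** 2
    sdotdv = np.sum(s * dv, axis=-1, keepdims=True)
    return scale * dv + dscale_dnorm * sdotdv * s / n


def routing_forward(u_hat: np.ndarray, iterations: int):
    """Batched routing: u_hat (B, C_p, k, d) -> v (B, k, d) plus cache."""
    B, C_p, k, d = u_hat.shape
    b = np.zeros((B, C_p, k), dtype=u_hat.dtype)
    steps = []
    for it in range(iterations):
        c = _softmax_classes(b)
        s = np.einsum("bij,bijd->bjd", c, u_hat)
        v, sq_cache = squash_forward(s)
        steps.append({"b": b, "c": c, "s": s, "v": v, "sq": sq_cache})
        if it < iterations - 1:
            b = b + np.einsum("bijd,bjd->bij", u_hat, v)
    return steps[-1]["v"], (u_hat, steps)


def routing_backward(dv_final: np.ndarray, cache) -> np.ndarray:
    """Gradient wrt u_hat of a scalar loss, through the unrolled iterations."""
    u_hat, steps = cache
    du_hat = np.zeros_like(u_hat)
    db_next = None  # gradient wrt the logits entering the *next* iteration
    for it in range(len(steps) - 1, -1, -1):
        st = steps[it]
        dv = dv_final if it == len(steps) - 1 else np.zeros_like(st["v"])
        if db_next is not None:
            # b_{it+1} = b_it + u_hat . v_it
            dv = dv + np.einsum("bij,bijd->bjd", db_next, u_hat)
            du_hat += db_next[..., None] * st["v"][:, None, :, :]
        ds = squash_backward(dv, st["sq"])
        dc = np.einsum("bjd,bijd->bij", ds, u_hat)
        du_hat += st["c"][..., None] * ds[:, None, :, :]
        # softmax over classes
        db = st["c"] * (dc - np.sum(dc * st["c"], axis=-1, keepdims=True))
        if db_next is not None:
            db = db + db_next  # identity path b_{it+1} = b_it + ...
        db_next = db
    # b_0 is a constant zero; db_next is dropped.
    return du_hat
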