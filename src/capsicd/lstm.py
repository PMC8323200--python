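"""Bidirectional LSTM sequence encoder.

Two views of the same recurrence are provided. The functional form
(:func:`lstm_step`, :func:`bilstm_encode`) states the per-step equations

    f_t = sigma(W_f x_t + U_f h_{t-1} + b_f)
    g_t = tanh (W_g x_t + U_g h_{t-1} + b_g)
    o_t = sigma(W_o x_t + U_o h_{t-1} + b_o)
    i_t = sigma(W_i x_t + U_i h_{t-1} + b_i)
    c_t = f_t * c_{t-1} + i_t * g_t
    h_t = o_t * tanh(c_t)

directly and is the reference the trainable layer is checked against.
:class:`BiLstmLayer` is the batched, mask-aware version with backpropagation
through time, used inside the full network. Initial states are zero; padded
positions carry the previous state through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class LstmParams:
    """One direction's gate weights: W_* (u, in), U_* (u, u), b_* (u,)."""

    W_i: np.ndarray
    W_f: np.ndarray
    W_o: np.ndarray
    W_g: np.ndarray
    U_i: np.ndarray
    U_f: np.ndarray
    U_o: np.ndarray
    U_g: np.ndarray
    b_i: np.ndarray
    b_f: np.ndarray
    b_o: np.ndarray
    b_g: np.ndarray

    def __post_init__(self) -> None:
        u, n_in = self.W_i.shape
        for name in ("W_f", "W_o", "W_g"):
            if getattr(self, name).shape != (u, n_in):
                raise ValueError(f"{name} shape mismatch")
        for name in ("U_i", "U_f", "U_o", "U_g"):
            if getattr(self, name).shape != (u, u):
                raise ValueError(f"{name} shape mismatch")
        for name in ("b_i", "b_f", "b_o", "b_g"):
            if getattr(self, name).shape != (u,):
                raise ValueError(f"{name} shape mismatch")

    @property
    def hidden_units(self) -> int:
        return self.W_i.shape[0]

    @property
    def input_dim(self) -> int:
        return self.W_i.shape[1]

    @classmethod
    def random(cls, input_dim: int, hidden_units: int, rng: np.random.Generator, scale: float | None = None) -> "LstmParams":
        s_w = scale if scale is not None else 1.0 / np.sqrt(input_dim)
        s_u = scale if scale is not None else 1.0 / np.sqrt(hidden_units)
        mk_w = lambda: rng.normal(0.0, s_w, size=(hidden_units, input_dim))
        mk_u = lambda: rng.normal(0.0, s_u, size=(hidden_units, hidden_units))
        mk_b = lambda: np.zeros(hidden_units)
        return cls(mk_w(), mk_w(), mk_w(), mk_w(), mk_u(), mk_u(), mk_u(), mk_u(), mk_b(), mk_b(), mk_b(), mk_b())


def lstm_step(
    x_t: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray, params: LstmParams
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM cell update; returns (h_t, c_t)."""
    if x_t.shape != (params.input_dim,):
        raise ValueError(f"x_t has shape {x_t.shape}, expected ({params.input_dim},)")
    if h_prev.shape != (params.hidden_units,) or c_prev.shape != (params.hidden_units,):
        raise ValueError("state shape mismatch")
    f_t = _sigmoid(params.W_f @ x_t + params.U_f @ h_prev + params.b_f)
    g_t = np.tanh(params.W_g @ x_t + params.U_g @ h_prev + params.b_g)
    o_t = _sigmoid(params.W_o @ x_t + params.U_o @ h_prev + params.b_o)
    i_t = _sigmoid(params.W_i @ x_t + params.U_i @ h_prev + params.b_i)
    c_t = f_t * c_prev + i_t * g_t
    h_t = o_t * np.tanh(c_t)
    return h_t, c_t


def bilstm_encode(
    X: np.ndarray, fwd_params: LstmParams, bwd_params: LstmParams
) -> np.ndarray:
    """Encode a (T, in) sequence to (T, 2u): forward and backward hidden
    states concatenated per position, with zero initial states."""
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("X must be a non-empty (T, in) sequence")
    T = X.shape[0]
    u = fwd_params.hidden_units

    def run(params: LstmParams, seq: np.ndarray) -> np.ndarray:
        h = np.zeros(params.hidden_units)
        c = np.zeros(params.hidden_units)
        out = np.empty((T, params.hidden_units))
        for t in range(T):
            h, c = lstm_step(seq[t], h, c, params)
            out[t] = h
        return out

    h_fwd = run(fwd_params, X)
    h_bwd = run(bwd_params, X[::-1])[::-1]
    return np.concatenate([h_fwd, h_bwd], axis=1)


# ---------------------------------------------------------------------------
# Batched trainable layer


def reverse_padded(X: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Reverse each row's first ``lengths[b]`` positions, keeping padding
    at the tail. Works on (B, T, ...) arrays; an involution."""
    B, T = X.shape[:2]
    t_idx = np.arange(T)[None, :]
    rev = np.where(t_idx < lengths[:, None], lengths[:, None] - 1 - t_idx, t_idx)
    return X[np.arange(B)[:, None], rev]


def _pack(params: LstmParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pack per-gate matrices into (in,4u), (u,4u), (4u,) with gate order i,f,o,g."""
    W = np.concatenate([params.W_i.T, params.W_f.T, params.W_o.T, params.W_g.T], axis=1)
    U = np.concatenate([params.U_i.T, params.U_f.T, params.U_o.T, params.U_g.T], axis=1)
    b = np.concatenate([params.b_i, params.b_f, params.b_o, params.b_g])
    return W, U, b


class BiLstmLayer:
    """Batched bidirectional LSTM with backpropagation through time.

    Parameters are packed per direction as ``W`` (in, 4u), ``U`` (u, 4u) and
    ``b`` (4u,), gate order (input, forget, output, candidate). Positions
    beyond a sequence's length carry the state through and emit zeros.
    """

    param_names = ("W_f0", "U_f0", "b_f0", "W_b0", "U_b0", "b_b0")

    def __init__(self, input_dim: int, hidden_units: int, rng: np.random.Generator):
        self.input_dim = input_dim
        self.hidden_units = hidden_units
        s_w, s_u = 1.0 / np.sqrt(input_dim), 1.0 / np.sqrt(hidden_units)
        u = hidden_units
        self.params = {}
        for tag in ("f0", "b0"):
            self.params["W_" + tag] = rng.normal(0.0, s_w, size=(input_dim, 4 * u))
            self.params["U_" + tag] = rng.normal(0.0, s_u, size=(u, 4 * u))
            self.params["b_" + tag] = np.zeros(4 * u)

    @classmethod
    def from_functional(
        cls, fwd: LstmParams, bwd: LstmParams
    ) -> "BiLstmLayer":
        layer = cls.__new__(cls)
        layer.input_dim = fwd.input_dim
        layer.hidden_units = fwd.hidden_units
        layer.params = {}
        for tag, p in (("f0", fwd), ("b0", bwd)):
            W, U, b = _pack(p)
            layer.params["W_" + tag], layer.params["U_" + tag], layer.params["b_" + tag] = W, U, b
        return layer

    def _run_dir(self, X: np.ndarray, mask: np.ndarray, tag: str):
        W, U, b = self.params["W_" + tag], self.params["U_" + tag], self.params["b_" + tag]
        B, T, _ = X.shape
        u = self.hidden_units
        Xp = X @ W.astype(X.dtype, copy=False) + b.astype(X.dtype, copy=False)  # (B, T, 4u)
        h = np.zeros((B, u), dtype=X.dtype)
        c = np.zeros((B, u), dtype=X.dtype)
        gates = np.empty((B, T, 4 * u), dtype=X.dtype)
        cs = np.empty((B, T, u), dtype=X.dtype)  # post-mask cell states
        hs = np.empty((B, T, u), dtype=X.dtype)  # post-mask hidden states
        tanh_c = np.empty((B, T, u), dtype=X.dtype)
        for t in range(T):
            a = Xp[:, t] + h @ U
            i = _sigmoid(a[:, :u])
            f = _sigmoid(a[:, u : 2 * u])
            o = _sigmoid(a[:, 2 * u : 3 * u])
            g = np.tanh(a[:, 3 * u :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            m = mask[:, t][:, None]
            c = m * c_new + (1.0 - m) * c
            h = m * h_new + (1.0 - m) * h
            gates[:, t, :u], gates[:, t, u : 2 * u] = i, f
            gates[:, t, 2 * u : 3 * u], gates[:, t, 3 * u :] = o, g
            cs[:, t] = c
            hs[:, t] = h
            tanh_c[:, t] = tc
        out = hs * mask[..., None]  # padded positions emit zeros
        cache = (X, mask, gates, cs, hs, tanh_c, tag)
        return out, cache

    def _backward_dir(self, dout: np.ndarray, cache) -> tuple[np.ndarray, dict]:
        X, mask, gates, cs, hs, tanh_c, tag = cache
        W, U = self.params["W_" + tag], self.params["U_" + tag]
        B, T, _ = X.shape
        u = self.hidden_units
        dW = np.zeros_like(W)
        dU = np.zeros_like(U)
        db = np.zeros(4 * u, dtype=W.dtype)
        dX = np.zeros_like(X)
        dh = np.zeros((B, u), dtype=X.dtype)
        dc = np.zeros((B, u), dtype=X.dtype)
        dout = dout * mask[..., None]
        for t in range(T - 1, -1, -1):
            m = mask[:, t][:, None]
            dh = dh + dout[:, t]
            c_prev = cs[:, t - 1] if t > 0 else np.zeros((B, u), dtype=X.dtype)
            h_prev = hs[:, t - 1] if t > 0 else np.zeros((B, u), dtype=X.dtype)
            i = gates[:, t, :u]
            f = gates[:, t, u : 2 * u]
            o = gates[:, t, 2 * u : 3 * u]
            g = gates[:, t, 3 * u :]
            tc = tanh_c[:, t]
            dh_new = m * dh
            dh_prev = (1.0 - m) * dh
            dc_new = m * dc
            dc_prev = (1.0 - m) * dc
            do = dh_new * tc
            dc_new = dc_new + dh_new * o * (1.0 - tc * tc)
            df = dc_new * c_prev
            dc_prev = dc_prev + dc_new * f
            di = dc_new * g
            dg = dc_new * i
            da = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), do * o * (1 - o), dg * (1 - g * g)],
                axis=1,
            )
            dW += X[:, t].T @ da
            dU += h_prev.T @ da
            db += da.sum(axis=0)
            dX[:, t] = da @ W.T
            dh = dh_prev + da @ U.T
            dc = dc_prev
        return dX, {"W_" + tag: dW, "U_" + tag: dU, "b_" + tag: db}

    def forward(self, X: np.ndarray, lengths: np.ndarray):
        """Encode (B, T, in) to (B, T, 2u); returns (H, cache)."""
        B, T, _ = X.shape
        mask = (np.arange(T)[None, :] < lengths[:, None]).astype(X.dtype)
        out_f, cache_f = self._run_dir(X, mask, "f0")
        X_rev = reverse_padded(X, lengths)
        out_br, cache_b = self._run_dir(X_rev, mask, "b0")
        out_b = reverse_padded(out_br, lengths)
        H = np.concatenate([out_f, out_b], axis=2)
        return H, (cache_f, cache_b, lengths)

    def backward(self, dH: np.ndarray, cache):
        """Gradients of a scalar loss wrt inputs and parameters."""
        cache_f, cache_b, lengths = cache
        u = self.hidden_units
        dX_f, grads_f = self._backward_dir(dH[..., :u], cache_f)
        dXr_b, grads_b = self._backward_dir(reverse_padded(dH[..., u:], lengths), cache_b)
        dX = dX_f + reverse_padded(dXr_b, lengths)
        return dX, {**grads_f, **grads_b}
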