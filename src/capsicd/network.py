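"""The full medical-coding network and its training loop.

`CapsuleCoder` is an sklearn-style estimator wiring the pipeline

    token embedding -> label-similarity augmentation -> Bi-LSTM ->
    n-gram convolution -> primary capsules -> dynamic routing ->
    [class-capsule features ; text-label similarity D] -> dense head

for multi-label code prediction. The `bilstm` and `label_fusion` flags
produce the ablation variants (capsule-only, Bi-LSTM + capsules, and the
full fused model). Forward and backward passes are written directly in
numpy; training uses Adam with early stopping on validation loss.

Word embeddings and label embeddings are frozen inputs by default: the
gradient stops at the encoder, which keeps the label-similarity features an
honest function of the description-derived label space.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import capsule as caps
from .corpus import TokenizedNote, DatasetSplit
from .embeddings import EmbeddingMatrix, LabelEmbeddingMatrix
from .lstm import BiLstmLayer

logger = logging.getLogger(__name__)

EPS = 1e-12


@dataclass
class ModelConfig:
    """Hyperparameters of the coder; defaults follow the reference setting
    (embedding 200, Bi-LSTM hidden 300, capsule dim 50, 3 routing
    iterations, batch 16, Adam at 0.01)."""

    embedding_dim: int = 200
    hidden_units: int = 300
    capsule_dim: int = 50
    routing_iters: int = 3
    kernel_size: int = 3
    n_filters: int = 64
    n_channels: int = 32
    batch_size: int = 16
    learning_rate: float = 0.01
    loss_mode: str = "sigmoid-bce"
    label_fusion: bool = True
    bilstm: bool = True
    max_len: int = 2500
    max_epochs: int = 50
    patience: int = 3
    threshold: float = 0.5
    top_k: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.loss_mode not in {"sigmoid-bce", "softmax-ce"}:
            raise ValueError(f"unknown loss_mode {self.loss_mode!r}")
        for name in ("embedding_dim", "hidden_units", "capsule_dim", "routing_iters",
                     "kernel_size", "n_filters", "n_channels", "batch_size", "max_len",
                     "max_epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if not (0.0 < self.learning_rate):
            raise ValueError("learning_rate must be positive")

    def estimator_kwargs(self) -> dict:
        kw = asdict(self)
        kw.pop("embedding_dim")
        return kw


def scores_to_codes(
    scores: np.ndarray,
    labels: Sequence[str],
    threshold: float | None = 0.5,
    top_k: int | None = None,
) -> list[set[str]]:
    """Turn per-note scores into code sets.

    Threshold policy keeps labels with score >= threshold; top-k keeps the k
    highest-scoring labels per note, ties broken by label order. Exactly one
    policy must be selected.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if (top_k is None) == (threshold is None):
        raise ValueError("choose exactly one of threshold or top_k")
    out: list[set[str]] = []
    if top_k is not None:
        if top_k < 1:
            raise ValueError("top_k must be >= 1")
        for row in scores:
            order = np.argsort(-row, kind="stable")[:top_k]
            out.append({labels[i] for i in order})
    else:
        if not (0.0 < threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")
        for row in scores:
            out.append({labels[i] for i in np.flatnonzero(row >= threshold)})
    return out


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class AdamOptimizer:
    """Adam with bias correction, one slot per named parameter array."""

    def __init__(self, params: dict[str, np.ndarray], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


class CapsuleCoder(BaseEstimator, ClassifierMixin):
    """Multi-label ICD coder: Bi-LSTM + label-embedding fusion + capsules.

    Parameters
    ----------
    embedding : EmbeddingMatrix
        Frozen word vectors (with padding/unknown rows).
    label_embeddings : LabelEmbeddingMatrix
        Description-derived label vectors; fixes the label order
        (``classes_`` after fit). Required even when ``label_fusion`` is
        off, since it carries the canonical label space.
    bilstm, label_fusion : bool
        Ablation switches: both off yields the plain capsule network, bilstm
        alone the Bi-LSTM capsule network, both on the full fused model.

    After ``fit``: ``classes_`` (label order), ``params_`` (weight arrays),
    ``loss_curve_`` (per-epoch train/validation loss), ``best_epoch_``,
    ``n_iter_``.
    """

    def __init__(
        self,
        embedding: EmbeddingMatrix | None = None,
        label_embeddings: LabelEmbeddingMatrix | None = None,
        hidden_units: int = 300,
        capsule_dim: int = 50,
        routing_iters: int = 3,
        kernel_size: int = 3,
        n_filters: int = 64,
        n_channels: int = 32,
        batch_size: int = 16,
        learning_rate: float = 0.01,
        loss_mode: str = "sigmoid-bce",
        label_fusion: bool = True,
        label_sim_reduce: str = "none",
        label_sim_m: int = 16,
        fusion_mode: str = "concat",
        pooled_source: str = "bilstm",
        bilstm: bool = True,
        max_len: int = 2500,
        max_epochs: int = 50,
        patience: int = 3,
        threshold: float = 0.5,
        top_k: int | None = None,
        validation_fraction: float = 0.1,
        dtype: str = "float64",
        seed: int = 0,
        verbose: int = 0,
    ):
        self.embedding = embedding
        self.label_embeddings = label_embeddings
        self.hidden_units = hidden_units
        self.capsule_dim = capsule_dim
        self.routing_iters = routing_iters
        self.kernel_size = kernel_size
        self.n_filters = n_filters
        self.n_channels = n_channels
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.loss_mode = loss_mode
        self.label_fusion = label_fusion
        self.label_sim_reduce = label_sim_reduce
        self.label_sim_m = label_sim_m
        self.fusion_mode = fusion_mode
        self.pooled_source = pooled_source
        self.bilstm = bilstm
        self.max_len = max_len
        self.max_epochs = max_epochs
        self.patience = patience
        self.threshold = threshold
        self.top_k = top_k
        self.validation_fraction = validation_fraction
        self.dtype = dtype
        self.seed = seed
        self.verbose = verbose

    # -- construction ------------------------------------------------------

    def initialize(self) -> "CapsuleCoder":
        """Build and seed all parameter arrays (idempotent once called)."""
        if self.embedding is None or self.label_embeddings is None:
            raise ValueError("embedding and label_embeddings are required")
        e = self.embedding.dim
        if self.label_embeddings.dim != e:
            raise ValueError(
                f"label embeddings have dim {self.label_embeddings.dim}, word embeddings {e}: "
                "the two must share one space"
            )
        if self.loss_mode not in {"sigmoid-bce", "softmax-ce"}:
            raise ValueError(f"unknown loss_mode {self.loss_mode!r}")
        if self.label_sim_reduce not in {"none", "top-m", "max"}:
            raise ValueError(f"unknown label_sim_reduce {self.label_sim_reduce!r}")
        if self.fusion_mode not in {"concat", "additive"}:
            raise ValueError(f"unknown fusion_mode {self.fusion_mode!r}")
        if self.pooled_source not in {"bilstm", "capsule"}:
            raise ValueError(f"unknown pooled_source {self.pooled_source!r}")
        rng = np.random.default_rng(self.seed)
        L = len(self.label_embeddings.labels)
        self.classes_ = list(self.label_embeddings.labels)
        if self.label_sim_reduce == "none":
            self._sim_width = L
        elif self.label_sim_reduce == "max":
            self._sim_width = 1
        else:
            self._sim_width = min(self.label_sim_m, L)
        in_dim = e + (self._sim_width if self.label_fusion else 0)
        h_dim = 2 * self.hidden_units if self.bilstm else in_dim
        K1, F = self.kernel_size, self.n_filters
        ch, d = self.n_channels, self.capsule_dim
        params: dict[str, np.ndarray] = {}
        if self.bilstm:
            self._lstm = BiLstmLayer(in_dim, self.hidden_units, rng)
            for name, arr in self._lstm.params.items():
                params["lstm." + name] = arr
        else:
            self._lstm = None
        params["conv.W"] = rng.normal(0.0, 1.0 / np.sqrt(K1 * h_dim), size=(K1 * h_dim, F))
        params["conv.b"] = np.zeros(F)
        params["caps.W"] = rng.normal(0.0, 1.0 / np.sqrt(F), size=(F, ch * d))
        params["caps.b"] = np.zeros(ch * d)
        params["route.W"] = rng.normal(0.0, 1.0 / np.sqrt(d), size=(ch, L, d, d))
        if self.label_fusion:
            z_dim = h_dim if self.pooled_source == "bilstm" else L * d
            params["proj.W"] = rng.normal(0.0, 1.0 / np.sqrt(z_dim), size=(z_dim, e))
            params["proj.b"] = np.zeros(e)
        head_in = L * d + (L if self.label_fusion and self.fusion_mode == "concat" else 0)
        params["head.W"] = rng.normal(0.0, 1.0 / np.sqrt(head_in), size=(head_in, L))
        params["head.b"] = np.zeros(L)
        dt = np.dtype(self.dtype)
        self.params_ = {k: v.astype(dt) for k, v in params.items()}
        if self._lstm is not None:
            # the layer shares storage with params_ so optimizer updates both
            for name in list(self._lstm.params):
                self._lstm.params[name] = self.params_["lstm." + name]
        self._emb_vectors = self.embedding.vectors.astype(dt)
        # normalised label vectors for the similarity features
        C = self.label_embeddings.vectors
        cn = np.linalg.norm(C, axis=1)
        self._C = C.astype(dt)
        self._C_unit = np.where(cn[:, None] > 0, C / np.maximum(cn, EPS)[:, None], 0.0).astype(dt)
        return self

    # -- data plumbing -----------------------------------------------------

    @staticmethod
    def _tokens_of(x) -> list[str]:
        return x.tokens if isinstance(x, TokenizedNote) else list(x)

    def _encode_batch(self, X: Sequence) -> tuple[np.ndarray, np.ndarray]:
        """Token sequences -> (ids (B, T), lengths (B,)); every note is
        given at least one full convolution window via padding."""
        seqs = [self.embedding.encode(self._tokens_of(x)[: self.max_len]) for x in X]
        lengths = np.array([max(len(s), self.kernel_size) for s in seqs], dtype=np.int64)
        T = int(lengths.max())
        ids = np.zeros((len(seqs), T), dtype=np.int64)  # 0 = padding row
        for i, s in enumerate(seqs):
            ids[i, : len(s)] = s
        return ids, lengths

    def _multi_hot(self, y: Sequence) -> np.ndarray:
        idx = {c: i for i, c in enumerate(self.classes_)}
        Y = np.zeros((len(y), len(self.classes_)))
        for i, codes in enumerate(y):
            if isinstance(codes, (set, frozenset, list, tuple)):
                for c in codes:
                    if c in idx:
                        Y[i, idx[c]] = 1.0
            else:
                Y[i] = np.asarray(codes, dtype=float)
        return Y

    # -- forward / backward ------------------------------------------------

    def _forward(self, ids: np.ndarray, lengths: np.ndarray, with_cache: bool = False):
        p = self.params_
        B, T = ids.shape
        dt = self._emb_vectors.dtype
        mask = (np.arange(T)[None, :] < lengths[:, None]).astype(dt)
        V = self._emb_vectors[ids]  # (B, T, e) frozen
        if self.label_fusion:
            vn = np.linalg.norm(V, axis=2)
            Vu = V / np.maximum(vn, EPS)[..., None]
            Vu[vn == 0.0] = 0.0
            G = Vu @ self._C_unit.T  # (B, T, L): cosine(V_t, C_i)
            if self.label_sim_reduce == "max":
                G = G.max(axis=2, keepdims=True)
            elif self.label_sim_reduce == "top-m":
                G = -np.sort(-G, axis=2)[:, :, : self._sim_width]
            X_in = np.concatenate([V, G], axis=2)
        else:
            X_in = V
        if self.bilstm:
            H, lstm_cache = self._lstm.forward(X_in, lengths)
        else:
            H, lstm_cache = X_in * mask[..., None], None
        h_dim = H.shape[2]
        K1 = self.kernel_size
        N_w = T - K1 + 1
        windows = np.lib.stride_tricks.sliding_window_view(H, (K1,), axis=1)
        # (B, N_w, h_dim, K1) -> (B, N_w, K1*h_dim) in (position, feature) order
        windows = np.ascontiguousarray(windows.transpose(0, 1, 3, 2)).reshape(B, N_w, K1 * h_dim)
        wmask = (np.arange(N_w)[None, :] <= (lengths - K1)[:, None]).astype(dt)
        raw_conv = windows @ p["conv.W"] + p["conv.b"]
        m = np.maximum(raw_conv, 0.0) * wmask[..., None]  # (B, N_w, F)
        ch, d = self.n_channels, self.capsule_dim
        raw_caps = (m @ p["caps.W"] + p["caps.b"]) * wmask[..., None]  # (B, N_w, ch*d)
        u4 = raw_caps.reshape(B, N_w, ch, d)
        u_sq, sq_cache = caps.squash_forward(u4)
        u_hat5 = np.einsum("bwci,cjoi->bwcjo", u_sq, p["route.W"])
        u_hat = u_hat5.reshape(B, N_w * ch, len(self.classes_), d)
        v, route_cache = caps.routing_forward(u_hat, self.routing_iters)
        caps_feat = v.reshape(B, -1)
        if self.label_fusion:
            if self.pooled_source == "bilstm":
                z = (H * mask[..., None]).sum(axis=1) / lengths[:, None]
            else:
                z = caps_feat
            proj = z @ p["proj.W"] + p["proj.b"]
            pn = np.linalg.norm(proj, axis=1, keepdims=True)
            D = (proj @ self._C_unit.T) / np.maximum(pn, EPS)
            if self.fusion_mode == "concat":
                head_in = np.concatenate([caps_feat, D], axis=1)
            else:
                head_in = caps_feat
        else:
            z = proj = pn = D = None
            head_in = caps_feat
        logits = head_in @ p["head.W"] + p["head.b"]
        if self.label_fusion and self.fusion_mode == "additive":
            logits = logits + D
        if not with_cache:
            return logits
        cache = dict(
            mask=mask, lengths=lengths, H=H, lstm_cache=lstm_cache, windows=windows,
            wmask=wmask, raw_conv=raw_conv, m=m, sq_cache=sq_cache, u_sq=u_sq,
            route_cache=route_cache, caps_feat=caps_feat, z=z, proj=proj, pn=pn, D=D,
            head_in=head_in, h_dim=h_dim, N_w=N_w, B=B, T=T,
        )
        return logits, cache

    def _scores_from_logits(self, logits: np.ndarray) -> np.ndarray:
        if self.loss_mode == "softmax-ce":
            zz = logits - logits.max(axis=1, keepdims=True)
            ez = np.exp(zz)
            return ez / ez.sum(axis=1, keepdims=True)
        return _sigmoid(logits)

    def _loss_and_dlogits(self, logits: np.ndarray, Y: np.ndarray):
        B, L = logits.shape
        Y = np.asarray(Y, dtype=logits.dtype)
        if self.loss_mode == "sigmoid-bce":
            s = _sigmoid(logits)
            loss = np.mean(
                np.maximum(logits, 0.0) - logits * Y + np.log1p(np.exp(-np.abs(logits)))
            )
            dlogits = (s - Y) / (B * L)
        else:  # softmax-ce with multi-hot targets normalised to sum 1
            tsum = np.maximum(Y.sum(axis=1, keepdims=True), 1.0)
            t = Y / tsum
            zz = logits - logits.max(axis=1, keepdims=True)
            lse = np.log(np.exp(zz).sum(axis=1, keepdims=True))
            logp = zz - lse
            loss = -np.mean((t * logp).sum(axis=1))
            dlogits = (np.exp(logp) - t) / B
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite training loss; training aborted")
        return float(loss), dlogits

    def _backward(self, dlogits: np.ndarray, cache) -> dict[str, np.ndarray]:
        p = self.params_
        B = cache["B"]
        N_w = cache["N_w"]
        ch, d = self.n_channels, self.capsule_dim
        L = len(self.classes_)
        K1 = self.kernel_size
        h_dim = cache["h_dim"]
        grads: dict[str, np.ndarray] = {}
        grads["head.W"] = cache["head_in"].reshape(B, -1).T @ dlogits
        grads["head.b"] = dlogits.sum(axis=0)
        dhead_in = dlogits @ p["head.W"].T
        dH = np.zeros_like(cache["H"])
        if self.label_fusion:
            if self.fusion_mode == "concat":
                dcaps_feat = dhead_in[:, : L * d].copy()
                dD = dhead_in[:, L * d :]
            else:  # additive: D enters the logits directly
                dcaps_feat = dhead_in.copy()
                dD = dlogits
            proj, pn, z = cache["proj"], cache["pn"], cache["z"]
            npn = np.maximum(pn, EPS)
            # D_i = (proj . C_unit_i) / |proj|
            dproj = (dD @ self._C_unit) / npn - (
                np.sum(dD * cache["D"], axis=1, keepdims=True) * proj / (npn * npn)
            )
            grads["proj.W"] = z.T @ dproj
            grads["proj.b"] = dproj.sum(axis=0)
            dz = dproj @ p["proj.W"].T
            if self.pooled_source == "bilstm":
                dH += (dz / cache["lengths"][:, None])[:, None, :] * cache["mask"][..., None]
            else:  # z was the flattened class capsules
                dcaps_feat = dcaps_feat + dz
        else:
            dcaps_feat = dhead_in
        dv = dcaps_feat.reshape(B, L, d)
        du_hat = caps.routing_backward(dv, cache["route_cache"])
        du_hat5 = du_hat.reshape(B, N_w, ch, L, d)
        grads["route.W"] = np.einsum("bwcjo,bwci->cjoi", du_hat5, cache["u_sq"])
        du_sq = np.einsum("bwcjo,cjoi->bwci", du_hat5, p["route.W"])
        draw_caps = caps.squash_backward(du_sq, cache["sq_cache"]).reshape(B, N_w, ch * d)
        draw_caps = draw_caps * cache["wmask"][..., None]
        m = cache["m"]
        grads["caps.W"] = m.reshape(-1, m.shape[2]).T @ draw_caps.reshape(-1, ch * d)
        grads["caps.b"] = draw_caps.sum(axis=(0, 1))
        dm = draw_caps @ p["caps.W"].T
        draw_conv = dm * (cache["raw_conv"] > 0) * cache["wmask"][..., None]
        win = cache["windows"]
        grads["conv.W"] = win.reshape(-1, win.shape[2]).T @ draw_conv.reshape(-1, draw_conv.shape[2])
        grads["conv.b"] = draw_conv.sum(axis=(0, 1))
        dwin = (draw_conv @ p["conv.W"].T).reshape(B, N_w, K1, h_dim)
        for j in range(K1):
            dH[:, j : j + N_w, :] += dwin[:, :, j, :]
        if self.bilstm:
            _, lstm_grads = self._lstm.backward(dH, cache["lstm_cache"])
            for name, g in lstm_grads.items():
                grads["lstm." + name] = g
        return grads

    def _loss_and_grads(self, ids: np.ndarray, lengths: np.ndarray, Y: np.ndarray):
        logits, cache = self._forward(ids, lengths, with_cache=True)
        loss, dlogits = self._loss_and_dlogits(logits, Y)
        return loss, self._backward(dlogits, cache)

    # -- training ----------------------------------------------------------

    def fit(self, X: Sequence, y: Sequence, validation_data: tuple | None = None):
        """Train on token sequences (or TokenizedNotes) X with gold code
        sets y; early-stops on validation loss and restores the best epoch."""
        if len(X) != len(y):
            raise ValueError("X and y must have equal length")
        if len(X) == 0:
            raise ValueError("empty training set")
        self.initialize()
        rng = np.random.default_rng(self.seed + 1)
        if validation_data is None:
            n_val = max(1, int(round(self.validation_fraction * len(X))))
            order = rng.permutation(len(X))
            val_idx, tr_idx = order[:n_val], order[n_val:]
            X_tr = [X[i] for i in tr_idx]
            y_tr = [y[i] for i in tr_idx]
            X_val = [X[i] for i in val_idx]
            y_val = [y[i] for i in val_idx]
        else:
            X_tr, y_tr = list(X), list(y)
            X_val, y_val = validation_data
        if len(X_tr) == 0 or len(X_val) == 0:
            raise ValueError("train and validation sets must be non-empty")
        Y_tr = self._multi_hot(y_tr)
        opt = AdamOptimizer(self.params_, self.learning_rate)
        best_loss = np.inf
        best_params = None
        best_epoch = 0
        bad_epochs = 0
        self.loss_curve_ = []
        for epoch in range(1, self.max_epochs + 1):
            order = rng.permutation(len(X_tr))
            total, nb = 0.0, 0
            for start in range(0, len(order), self.batch_size):
                sel = order[start : start + self.batch_size]
                ids, lengths = self._encode_batch([X_tr[i] for i in sel])
                loss, grads = self._loss_and_grads(ids, lengths, Y_tr[sel])
                opt.step(self.params_, grads)
                total += loss
                nb += 1
            val_loss = self.evaluate_loss(X_val, y_val)
            self.loss_curve_.append(
                {"epoch": epoch, "train_loss": total / nb, "val_loss": val_loss}
            )
            if self.verbose:
                logger.info("epoch %d train %.4f val %.4f", epoch, total / nb, val_loss)
            if val_loss < best_loss - 1e-9:
                best_loss = val_loss
                best_params = copy.deepcopy(self.params_)
                best_epoch = epoch
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs >= self.patience:
                    break
        if best_params is not None:
            self.params_ = best_params
            if self._lstm is not None:
                for name in list(self._lstm.params):
                    self._lstm.params[name] = self.params_["lstm." + name]
        self.best_epoch_ = best_epoch
        self.n_iter_ = len(self.loss_curve_)
        return self

    def evaluate_loss(self, X: Sequence, y: Sequence) -> float:
        """Mean loss (current loss_mode) over a dataset, without updates."""
        Y = self._multi_hot(y)
        total, n = 0.0, 0
        for start in range(0, len(X), self.batch_size):
            xs = X[start : start + self.batch_size]
            ids, lengths = self._encode_batch(xs)
            logits = self._forward(ids, lengths)
            loss, _ = self._loss_and_dlogits(logits, Y[start : start + self.batch_size])
            total += loss * len(xs)
            n += len(xs)
        return total / n

    # -- inference ---------------------------------------------------------

    def predict_proba(self, X: Sequence) -> np.ndarray:
        """Per-note, per-label scores in [0, 1] (N, L)."""
        if not hasattr(self, "params_"):
            raise RuntimeError("model is not fitted")
        n_empty = sum(1 for x in X if not self._tokens_of(x))
        if n_empty:
            logger.warning("%d notes are empty after preprocessing", n_empty)
        rows = []
        for start in range(0, len(X), self.batch_size):
            ids, lengths = self._encode_batch(X[start : start + self.batch_size])
            rows.append(self._scores_from_logits(self._forward(ids, lengths)))
        return np.vstack(rows)

    decision_function = predict_proba

    def predict(self, X: Sequence) -> np.ndarray:
        """Binary (N, L) decisions under the configured policy."""
        scores = self.predict_proba(X)
        sets = scores_to_codes(
            scores, self.classes_,
            threshold=None if self.top_k is not None else self.threshold,
            top_k=self.top_k,
        )
        idx = {c: i for i, c in enumerate(self.classes_)}
        out = np.zeros_like(scores)
        for i, codes in enumerate(sets):
            for c in codes:
                out[i, idx[c]] = 1.0
        return out

    def predict_codes(self, X: Sequence) -> list[set[str]]:
        """Per-note predicted code sets under the configured policy."""
        scores = self.predict_proba(X)
        return scores_to_codes(
            scores, self.classes_,
            threshold=None if self.top_k is not None else self.threshold,
            top_k=self.top_k,
        )

    def routing_trace(self, x) -> caps.RoutingState:
        """Run one note and return its dynamic-routing trace (final
        couplings per (window, channel) capsule and class)."""
        ids, lengths = self._encode_batch([x])
        _, cache = self._forward(ids, lengths, with_cache=True)
        u_hat, steps = cache["route_cache"]
        last = steps[-1]
        n_valid = int(cache["wmask"][0].sum()) * self.n_channels
        state = caps.RoutingState(
            u_hat=u_hat[0, :n_valid],
            b=last["b"][0, :n_valid],
            c=last["c"][0, :n_valid],
            v=last["v"][0],
            iterations=self.routing_iters,
            history=[{k: st[k][0] for k in ("b", "c", "s", "v")} for st in steps],
        )
        return state

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: config, vocabulary, label order, weights."""
        meta = {
            "config": {k: v for k, v in self.get_params().items()
                       if k not in ("embedding", "label_embeddings")},
            "vocab": self.embedding.vocab,
            "labels": self.classes_,
            "loss_curve": getattr(self, "loss_curve_", []),
            "best_epoch": getattr(self, "best_epoch_", None),
        }
        arrays = {"param:" + k: v for k, v in self.params_.items()}
        arrays["emb.vectors"] = self.embedding.vectors
        arrays["label.vectors"] = self.label_embeddings.vectors
        np.savez_compressed(path, meta=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "CapsuleCoder":
        with np.load(path, allow_pickle=False) as npz:
            meta = json.loads(str(npz["meta"]))
            emb = EmbeddingMatrix(vocab=meta["vocab"], vectors=npz["emb.vectors"])
            lab = LabelEmbeddingMatrix(labels=meta["labels"], vectors=npz["label.vectors"])
            model = cls(embedding=emb, label_embeddings=lab, **meta["config"])
            model.initialize()
            for key in npz.files:
                if key.startswith("param:"):
                    model.params_[key[len("param:"):]] = npz[key].copy()
        if model._lstm is not None:
            for name in list(model._lstm.params):
                model._lstm.params[name] = model.params_["lstm." + name]
        model.loss_curve_ = meta["loss_curve"]
        model.best_epoch_ = meta["best_epoch"]
        return model


def build_model(
    config: ModelConfig, emb: EmbeddingMatrix, C: LabelEmbeddingMatrix
) -> CapsuleCoder:
    """Construct and initialise a coder from a config; deterministic in the
    config seed (two builds give identical initial parameters)."""
    if emb.dim != config.embedding_dim:
        raise ValueError(
            f"config.embedding_dim={config.embedding_dim} but word vectors have dim {emb.dim}"
        )
    model = CapsuleCoder(embedding=emb, label_embeddings=C, **config.estimator_kwargs())
    return model.initialize()


def train_on_split(model: CapsuleCoder, split: DatasetSplit) -> CapsuleCoder:
    """Fit on a DatasetSplit's train notes, early-stopping on its validation
    notes."""
    return model.fit(
        split.train,
        [n.codes for n in split.train],
        validation_data=(split.valid, [n.codes for n in split.valid]),
    )
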