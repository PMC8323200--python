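"""Independent scalar-loop oracles shared across test modules.

These re-derive the recurrence and routing arithmetic with plain Python
loops, deliberately avoiding the vectorised code paths they are used to
check.
"""

import math

import numpy as np


def scalar_lstm_oracle(X, params):
    """Per-component evaluation of the LSTM gate equations; returns the
    hidden-state sequence for a (T, in) input with zero initial state."""
    u, n_in = params.W_i.shape
    h = [0.0] * u
    c = [0.0] * u
    out = []
    for t in range(len(X)):
        h_new, c_new = [], []
        for r in range(u):
            zi = params.b_i[r] + sum(params.W_i[r][k] * X[t][k] for k in range(n_in))
            zf = params.b_f[r] + sum(params.W_f[r][k] * X[t][k] for k in range(n_in))
            zo = params.b_o[r] + sum(params.W_o[r][k] * X[t][k] for k in range(n_in))
            zg = params.b_g[r] + sum(params.W_g[r][k] * X[t][k] for k in range(n_in))
            for k in range(u):
                zi += params.U_i[r][k] * h[k]
                zf += params.U_f[r][k] * h[k]
                zo += params.U_o[r][k] * h[k]
                zg += params.U_g[r][k] * h[k]
            sig = lambda x: 1.0 / (1.0 + math.exp(-x))
            ct = sig(zf) * c[r] + sig(zi) * math.tanh(zg)
            c_new.append(ct)
            h_new.append(sig(zo) * math.tanh(ct))
        h, c = h_new, c_new
        out.append(list(h))
    return np.array(out)


def scalar_routing_oracle(u_hat, iterations):
    """Hand-unrolled routing-by-agreement; returns the per-iteration
    (b, c, s, v) trace for nested-list predictions u_hat (C_p, k, d)."""
    C_p, k, d = len(u_hat), len(u_hat[0]), len(u_hat[0][0])
    b = [[0.0] * k for _ in range(C_p)]
    trace = []
    for it in range(iterations):
        c = []
        for i in range(C_p):
            mx = max(b[i])
            exps = [math.exp(x - mx) for x in b[i]]
            tot = sum(exps)
            c.append([x / tot for x in exps])
        s = [
            [sum(c[i][j] * u_hat[i][j][r] for i in range(C_p)) for r in range(d)]
            for j in range(k)
        ]
        v = []
        for j in range(k):
            n = math.sqrt(sum(x * x for x in s[j]))
            scale = (n * n) / (1 + n * n) / (n + 1e-12)
            v.append([scale * x for x in s[j]])
        trace.append(
            (np.array([row[:] for row in b]), np.array(c), np.array(s), np.array(v))
        )
        if it < iterations - 1:
            for i in range(C_p):
                for j in range(k):
                    b[i][j] += sum(u_hat[i][j][r] * v[j][r] for r in range(d))
    return trace


def counting_f1_oracle(gold, pred):
    """Cell-by-cell confusion counting; returns (micro F1, macro F1)."""
    n, L = gold.shape
    tp = fp = fn = 0
    per_label = []
    for j in range(L):
        tpj = fpj = fnj = 0
        for i in range(n):
            if gold[i][j] and pred[i][j]:
                tpj += 1
            elif pred[i][j] and not gold[i][j]:
                fpj += 1
            elif gold[i][j] and not pred[i][j]:
                fnj += 1
        tp, fp, fn = tp + tpj, fp + fpj, fn + fnj
        denom = 2 * tpj + fpj + fnj
        per_label.append(2 * tpj / denom if denom else 0.0)
    micro = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    return micro, sum(per_label) / L


def pairwise_auc_oracle(scores, gold):
    """All-pairs comparison AUC (ties count one half)."""
    pos = [s for s, g in zip(scores, gold) if g]
    neg = [s for s, g in zip(scores, gold) if not g]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def rank_recall_oracle(scores, gold, k=10):
    """Rank-then-count evaluation of the top-max(k, |M|) recall."""
    vals = []
    for srow, grow in zip(scores, gold):
        m = int(sum(grow))
        if m == 0:
            continue
        kk = min(max(k, m), len(srow))
        order = sorted(range(len(srow)), key=lambda j: (-srow[j], j))[:kk]
        vals.append(sum(grow[j] for j in order) / m)
    return sum(vals) / len(vals)
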