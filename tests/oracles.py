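"""Independent brute-force reference implementations.

Everything here is written with explicit Python loops and scalar math so
the reference path shares no code with the package's vectorised/autodiff
implementations.
"""

import math

import numpy as np


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def gru_step_oracle(x, h, Wz, Uz, Wr, Ur, Wx, Ux, bz=None, br=None, bx=None):
    """Scalar-loop evaluation of one gated-recurrence step."""
    x, h = np.asarray(x, float), np.asarray(h, float)
    d_in, d_h = len(x), len(h)
    out = np.zeros(d_h)
    for j in range(d_h):
        zj = sum(x[i] * Wz[i][j] for i in range(d_in))
        zj += sum(h[i] * Uz[i][j] for i in range(d_h))
        rj_pre = [
            sum(x[i] * Wr[i][k] for i in range(d_in))
            + sum(h[i] * Ur[i][k] for i in range(d_h))
            for k in range(d_h)
        ]
        if bz is not None:
            zj += bz[j]
            rj_pre = [v + br[k] for k, v in enumerate(rj_pre)]
        z = _sigmoid(zj)
        r = [_sigmoid(v) for v in rj_pre]
        cj = sum(x[i] * Wx[i][j] for i in range(d_in))
        cj += sum(r[i] * h[i] * Ux[i][j] for i in range(d_h))
        if bx is not None:
            cj += bx[j]
        out[j] = (1.0 - z) * h[j] + z * math.tanh(cj)
    return out


def gru_weight_arrays(w):
    """Extract plain arrays from a package GRUWeights object."""
    kw = {}
    for name in ("b_z", "b_r", "b_x"):
        b = getattr(w, name)
        if b is not None:
            kw[name.replace("_", "")] = b.data
    return (
        (w.W_z.data, w.U_z.data, w.W_r.data, w.U_r.data, w.W_x.data, w.U_x.data),
        kw,
    )


def bigru_oracle(X, fwd_list, bwd_list):
    """Stacked bidirectional recurrence via the scalar-step oracle."""
    X = [np.asarray(row, float) for row in X]
    for wf, wb in zip(fwd_list, bwd_list):
        (af, kf), (ab, kb) = gru_weight_arrays(wf), gru_weight_arrays(wb)
        d_h = wf.U_z.shape[0]
        h = np.zeros(d_h)
        forward = []
        for x in X:
            h = gru_step_oracle(x, h, *af, **kf)
            forward.append(h)
        h = np.zeros(d_h)
        backward = [None] * len(X)
        for t in range(len(X) - 1, -1, -1):
            h = gru_step_oracle(X[t], h, *ab, **kb)
            backward[t] = h
        X = [np.concatenate([f, b]) for f, b in zip(forward, backward)]
    return np.stack(X)


def attention_oracle(H, Wa, Ua):
    """Explicit-exponential soft attention: returns (context, weights)."""
    H = np.asarray(H, float)
    scores = []
    for row in H:
        t = [math.tanh(sum(Wa[k][i] * row[i] for i in range(len(row))))
             for k in range(len(Ua))]
        scores.append(sum(Ua[k] * t[k] for k in range(len(Ua))))
    m = max(scores)
    e = [math.exp(s - m) for s in scores]
    total = sum(e)
    alpha = [v / total for v in e]
    context = np.zeros(H.shape[1])
    for a, row in zip(alpha, H):
        context += a * row
    return context, np.array(alpha)


def sage_aggregate_oracle(v, H, edges, Wpool, b):
    """Mean over neighbours of ReLU(Wpool h_u + b), by explicit loops."""
    H = np.asarray(H, float)
    neigh = [u for (u, w) in edges if w == v]
    if not neigh:
        return np.zeros(len(b))
    acc = np.zeros(len(b))
    for u in neigh:
        t = [max(0.0, sum(Wpool[o][i] * H[u][i] for i in range(H.shape[1])) + b[o])
             for o in range(len(b))]
        acc += np.array(t)
    return acc / len(neigh)


def sage_update_oracle(h_v, h_n, Wu):
    cat = list(h_v) + list(h_n)
    return np.array(
        [max(0.0, sum(Wu[o][i] * cat[i] for i in range(len(cat))))
         for o in range(Wu.shape[0])]
    )


def ann_fuse_oracle(y_d, y_t, Ua, Wa):
    """Per-dimension fusion attention with explicit exponentials."""
    cat = list(y_d) + list(y_t)
    scores = []
    for k in range(len(Ua)):
        pre = sum(Wa[k][i] * cat[i] for i in range(len(cat)))
        scores.append(Ua[k] * max(0.0, pre))
    m = max(scores)
    e = [math.exp(s - m) for s in scores]
    alpha = [v / sum(e) for v in e]
    V = [alpha[k] * y_d[k] * y_t[k] for k in range(len(y_d))]
    return np.array(V), np.array(alpha)


def ci_oracle(y, p):
    """O(n^2) double-loop concordance index."""
    num, z = 0.0, 0
    for i in range(len(y)):
        for j in range(len(y)):
            if y[i] > y[j]:
                z += 1
                if p[i] > p[j]:
                    num += 1.0
                elif p[i] == p[j]:
                    num += 0.5
    return num / z


def rm2_oracle(y, p):
    """Least-squares evaluation of r^2, r0^2 and the rm^2 statistic."""
    y, p = np.asarray(y, float), np.asarray(p, float)
    r = np.corrcoef(y, p)[0, 1]
    r2 = r * r
    k = float(np.sum(y * p) / np.sum(p * p))
    r02 = 1.0 - np.sum((y - k * p) ** 2) / np.sum((y - y.mean()) ** 2)
    return r2 * (1.0 - math.sqrt(max(r2 - r02, 0.0)))


def spearman_oracle(y, p):
    """Average-rank transform followed by Pearson correlation."""

    def ranks(v):
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for idx in order[i : j + 1]:
                r[idx] = avg
            i = j + 1
        return r

    ry, rp = ranks(np.asarray(y, float)), ranks(np.asarray(p, float))
    return float(np.corrcoef(ry, rp)[0, 1])
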