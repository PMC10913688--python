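"""Independent brute-force reference implementations.

Everything here is written with explicit python loops over scalars (or the
closed-form definition), deliberately sharing no code with the package, so
tests can compare the vectorised implementations against a second route.
"""

from __future__ import annotations

import math

import numpy as np


def sigmoid(v: float) -> float:
    return 1.0 / (1.0 + math.exp(-v))


def mlp2(v, W1, b1, W2, b2):
    """Two-layer bottleneck: relu(v @ W1 + b1) @ W2 + b2, all loops."""
    d_in, d_hidden = W1.shape
    d_out = W2.shape[1]
    hidden = [max(0.0, sum(v[i] * W1[i, j] for i in range(d_in)) + b1[j])
              for j in range(d_hidden)]
    return [sum(hidden[j] * W2[j, k] for j in range(d_hidden)) + b2[k]
            for k in range(d_out)]


def channel_attention(x, W1, b1, W2, b2):
    """(weights, y): global max/avg pooling, shared bottleneck, sum, logistic,
    per-channel scaling."""
    n, c, h, w = x.shape
    weights = np.zeros((n, c))
    y = np.zeros_like(x)
    for s in range(n):
        mx = [max(x[s, ch].ravel()) for ch in range(c)]
        av = [float(np.mean(x[s, ch])) for ch in range(c)]
        z_mx = mlp2(mx, W1, b1, W2, b2)
        z_av = mlp2(av, W1, b1, W2, b2)
        for ch in range(c):
            weights[s, ch] = sigmoid(z_mx[ch] + z_av[ch])
            y[s, ch] = x[s, ch] * weights[s, ch]
    return weights, y


def conv2d(x, w, b, pad):
    """Stride-1 zero-padded cross-correlation, all loops."""
    n, c, h, wd = x.shape
    f, _, kh, kw = w.shape
    ph, pw = pad
    ho, wo = h + 2 * ph - kh + 1, wd + 2 * pw - kw + 1
    out = np.zeros((n, f, ho, wo))
    for s in range(n):
        for fo in range(f):
            for oh in range(ho):
                for ow in range(wo):
                    acc = 0.0 if b is None else float(b[fo])
                    for ch in range(c):
                        for i in range(kh):
                            for j in range(kw):
                                hi, wi = oh + i - ph, ow + j - pw
                                if 0 <= hi < h and 0 <= wi < wd:
                                    acc += x[s, ch, hi, wi] * w[fo, ch, i, j]
                    out[s, fo, oh, ow] = acc
    return out


def spatial_attention(x, conv_w, conv_b, kernel):
    """(weights, y): channel max/mean maps, stacked, convolved, logistic."""
    n, c, h, w = x.shape
    pad = kernel // 2
    weights = np.zeros((n, 1, h, w))
    y = np.zeros_like(x)
    for s in range(n):
        mx = x[s].max(axis=0)
        av = x[s].mean(axis=0)
        stacked = np.stack([mx, av])[None]           # (1, 2, H, W)
        conv = conv2d(stacked, conv_w, conv_b, (pad, pad))[0, 0]
        for oh in range(h):
            for ow in range(w):
                weights[s, 0, oh, ow] = sigmoid(conv[oh, ow])
        y[s] = x[s] * weights[s, 0]
    return weights, y


def batchnorm_eval(x, gamma, beta, running_mean, running_var, eps=1e-5):
    n, c, h, w = x.shape
    out = np.zeros_like(x)
    for ch in range(c):
        scale = 1.0 / math.sqrt(running_var[ch] + eps)
        out[:, ch] = (x[:, ch] - running_mean[ch]) * scale * gamma[ch] + beta[ch]
    return out


def gru_step(x_t, h_prev, p):
    """Scalar-loop GRU update; ``p`` maps names W_r..b_h to arrays with
    layout (d_in, d_h) for W and (d_h, d_h) for U."""
    d_in = len(x_t)
    d_h = len(h_prev)

    def affine(W, U, b, gated_h=None):
        hh = h_prev if gated_h is None else gated_h
        return [sum(x_t[i] * W[i, j] for i in range(d_in))
                + sum(hh[i] * U[i, j] for i in range(d_h)) + b[j]
                for j in range(d_h)]

    r = [sigmoid(v) for v in affine(p["W_r"], p["U_r"], p["b_r"])]
    z = [sigmoid(v) for v in affine(p["W_z"], p["U_z"], p["b_z"])]
    rh = [r[i] * h_prev[i] for i in range(d_h)]
    h_cand = [math.tanh(v) for v in affine(p["W_h"], p["U_h"], p["b_h"], gated_h=rh)]
    return np.array([(1 - z[i]) * h_prev[i] + z[i] * h_cand[i] for i in range(d_h)])


def self_attention(x, Wq, bq, Wk, bk, Wv, bv, scale):
    """(context, attn) per the QK^T / softmax / weighted-V definition."""
    t, d = x.shape
    da = Wq.shape[1]
    Q = np.array([[sum(x[p, i] * Wq[i, j] for i in range(d)) + bq[j] for j in range(da)]
                  for p in range(t)])
    K = np.array([[sum(x[p, i] * Wk[i, j] for i in range(d)) + bk[j] for j in range(da)]
                  for p in range(t)])
    V = np.array([[sum(x[p, i] * Wv[i, j] for i in range(d)) + bv[j] for j in range(da)]
                  for p in range(t)])
    attn = np.zeros((t, t))
    for p in range(t):
        logits = [scale * sum(Q[p, j] * K[q, j] for j in range(da)) for q in range(t)]
        m = max(logits)
        e = [math.exp(v - m) for v in logits]
        s = sum(e)
        attn[p] = [v / s for v in e]
    context = np.array([[sum(attn[p, q] * V[q, j] for q in range(t)) for j in range(da)]
                        for p in range(t)])
    return context, attn


def softmax_head(v, W, b):
    logits = [sum(v[i] * W[i, j] for i in range(len(v))) + b[j] for j in range(W.shape[1])]
    m = max(logits)
    e = [math.exp(z - m) for z in logits]
    s = sum(e)
    return np.array([z / s for z in e])


# -- metric oracles ---------------------------------------------------------

def confusion_loop(labels, scores, threshold):
    tp = tn = fp = fn = 0
    for lab, sc in zip(labels, scores):
        pred = 1 if sc >= threshold else 0
        if pred == 1 and lab == 1:
            tp += 1
        elif pred == 0 and lab == 0:
            tn += 1
        elif pred == 1 and lab == 0:
            fp += 1
        else:
            fn += 1
    return tp, tn, fp, fn


def eq3_metrics(tp, tn, fp, fn):
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / (tp + tn + fp + fn)
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(den) if den else 0.0
    return sn, sp, acc, mcc


def pairwise_auc(labels, scores):
    """P(random positive outscores random negative), ties counting half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def stepwise_pr_auc(labels, scores):
    """Step-wise precision-recall area via an exhaustive threshold sweep."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    n_pos = int(labels.sum())
    area, prev_recall = 0.0, 0.0
    for t in sorted(set(scores.tolist()), reverse=True):
        pred = scores >= t
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        precision = tp / (tp + fp)
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area
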