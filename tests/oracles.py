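"""Independent straight-line reference implementations used only by tests.

Everything here is written as naive loops directly from the mathematical
definitions, deliberately sharing no code with the package.
"""

import math

import numpy as np


def mlp_oracle(x, weights, biases, hidden_act=math.tanh, final_act=None):
    """Apply a chain of affine layers with tanh between them to one vector."""
    v = list(x)
    for li, (W, b) in enumerate(zip(weights, biases)):
        out = []
        for j in range(W.shape[1]):
            s = b[j]
            for i in range(W.shape[0]):
                s += v[i] * W[i, j]
            out.append(s)
        if li < len(weights) - 1:
            out = [hidden_act(o) for o in out]
        v = out
    if final_act is not None:
        v = [final_act(o) for o in v]
    return np.array(v)


def summary_tokens_oracle(A, use_mean, use_variance, genmean_powers):
    """Mean / population-variance / power-mean rows computed by loops."""
    N, H = A.shape
    tokens = []
    if use_mean:
        tokens.append(np.array([sum(A[i, j] for i in range(N)) / N for j in range(H)]))
    if use_variance:
        var = []
        for j in range(H):
            mu = sum(A[i, j] for i in range(N)) / N
            var.append(sum((A[i, j] - mu) ** 2 for i in range(N)) / N)
        tokens.append(np.array(var))
    for p in genmean_powers:
        tokens.append(np.array([
            (sum(A[i, j] ** p for i in range(N)) / N) ** (1.0 / p) for j in range(H)]))
    return tokens


def attention_oracle(seq, Wq, bq, Wk, bk, Wv, bv, Wo, bo, n_heads):
    """Multi-head self-attention (no residual), explicit loops.

    Returns (output sequence, attention probabilities (T, T, heads)).
    """
    T, H = seq.shape
    dh = H // n_heads
    Q = seq @ Wq + bq
    K = seq @ Wk + bk
    V = seq @ Wv + bv
    probs = np.zeros((T, T, n_heads))
    merged = np.zeros((T, H))
    for h in range(n_heads):
        sl = slice(h * dh, (h + 1) * dh)
        for i in range(T):
            scores = np.array([np.dot(Q[i, sl], K[j, sl]) / math.sqrt(dh)
                               for j in range(T)])
            e = np.exp(scores - scores.max())
            a = e / e.sum()
            probs[i, :, h] = a
            merged[i, sl] = sum(a[j] * V[j, sl] for j in range(T))
    return merged @ Wo + bo, probs


def caremil_forward_oracle(model, bag_X):
    """Full CAREMIL forward pass re-derived step by step from the model's
    parameter arrays; returns (logits, attention probabilities)."""
    cfg = model.config
    p = {k: v.data for k, v in model.params.items()}
    acfg = cfg.aggregator_config

    n_agg = len(cfg.aggregator_hidden) + 1
    agg_W = [p[f"agg_W{i}"] for i in range(n_agg)]
    agg_b = [p[f"agg_b{i}"] for i in range(n_agg)]
    final = (lambda v: max(v, 0.0)) if acfg.genmean_powers else None
    A = np.array([mlp_oracle(x, agg_W, agg_b, final_act=final) for x in bag_X])

    tokens = summary_tokens_oracle(A, acfg.use_mean, acfg.use_variance,
                                   acfg.genmean_powers)

    n_par = len(cfg.parallel_hidden) + 1
    par_W = [p[f"par_W{i}"] for i in range(n_par)]
    par_b = [p[f"par_b{i}"] for i in range(n_par)]
    P = np.array([mlp_oracle(x, par_W, par_b) for x in bag_X])

    seq = np.vstack([np.array(tokens), P])
    out, probs = attention_oracle(seq, p["attn_Wq"], p["attn_bq"], p["attn_Wk"],
                                  p["attn_bk"], p["attn_Wv"], p["attn_bv"],
                                  p["attn_Wo"], p["attn_bo"], cfg.n_heads)
    K = len(tokens)
    cls = out[:K].reshape(-1)
    n_head = len(cfg.mlp_hidden) + 1
    head_W = [p[f"head_W{i}"] for i in range(n_head)]
    head_b = [p[f"head_b{i}"] for i in range(n_head)]
    logits = mlp_oracle(cls, head_W, head_b)
    return logits, probs


def gated_forward_oracle(model, bag_X):
    """Gated-attention MIL forward pass, explicit loops."""
    cfg = model.config
    p = {k: v.data for k, v in model.params.items()}
    n_inst = len(cfg.instance_hidden) + 1
    inst_W = [p[f"inst_W{i}"] for i in range(n_inst)]
    inst_b = [p[f"inst_b{i}"] for i in range(n_inst)]
    H = np.array([mlp_oracle(x, inst_W, inst_b) for x in bag_X])

    def logistic(x):
        return 1.0 / (1.0 + math.exp(-x))

    scores = []
    for h in H:
        t = np.array([math.tanh(v) for v in (h @ p["gate_V"])])
        s = np.array([logistic(v) for v in (h @ p["gate_U"])])
        scores.append(float(((t * s) @ p["gate_w"])[0]))
    scores = np.array(scores)
    e = np.exp(scores - scores.max())
    a = e / e.sum()
    z = sum(a[i] * H[i] for i in range(len(H)))
    n_head = len(cfg.mlp_hidden) + 1
    head_W = [p[f"head_W{i}"] for i in range(n_head)]
    head_b = [p[f"head_b{i}"] for i in range(n_head)]
    return mlp_oracle(z, head_W, head_b), a


def auroc_pairs_oracle(scores, labels):
    """AUROC by exhaustive positive/negative pair enumeration."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def chi2_oracle(table):
    """Textbook Pearson chi-squared statistic on a 2x2 table."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    stat = 0.0
    for i in range(2):
        for j in range(2):
            expected = table[i].sum() * table[:, j].sum() / total
            stat += (table[i, j] - expected) ** 2 / expected
    return stat
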