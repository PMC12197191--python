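"""Independent brute-force implementations used as test oracles.

Everything here is written as literal nested loops over samples, directly
from the definitions, and shares no code with the package implementation.
"""

import numpy as np


def kernel_value(x, y, sigmas):
    """Mean over sigmas of exp(-||x-y||^2 / (2 sigma^2))."""
    d2 = float(np.sum((np.asarray(x, float) - np.asarray(y, float)) ** 2))
    return float(np.mean([np.exp(-d2 / (2.0 * s**2)) for s in sigmas]))


def mmd_loops(Xs, Xt, sigmas):
    """Biased MMD by explicit double loops (self-pairs included)."""
    ns, nt = len(Xs), len(Xt)
    t1 = sum(kernel_value(Xs[i], Xs[j], sigmas) for i in range(ns) for j in range(ns))
    t2 = sum(kernel_value(Xt[i], Xt[j], sigmas) for i in range(nt) for j in range(nt))
    t3 = sum(kernel_value(Xs[i], Xt[j], sigmas) for i in range(ns) for j in range(nt))
    return t1 / ns**2 + t2 / nt**2 - 2.0 * t3 / (ns * nt)


def class_discrepancy_loops(Xs, ys, Xt, yt, c1, c2, sigmas):
    """e1 + e2 - 2 e3 with indicator-weighted sums, literal quadruple loops."""
    ns, nt = len(Xs), len(Xt)

    def weighted(A, ya, B, yb, ca, cb):
        num = den = 0.0
        for i in range(len(A)):
            for j in range(len(B)):
                mu = 1.0 if (ya[i] == ca and yb[j] == cb) else 0.0
                num += mu * kernel_value(A[i], B[j], sigmas)
                den += mu
        if den == 0:
            raise ZeroDivisionError("empty class mask")
        return num / den

    e1 = weighted(Xs, ys, Xs, ys, c1, c1)
    e2 = weighted(Xt, yt, Xt, yt, c2, c2)
    e3 = weighted(Xs, ys, Xt, yt, c1, c2)
    return e1 + e2 - 2.0 * e3


def cdd_loops(Xs, ys, Xt, yt, classes, sigmas):
    """Mean intra-class term minus mean inter-class term, skipping classes
    absent from either domain."""
    intra, inter = [], []
    for c1 in classes:
        for c2 in classes:
            try:
                d = class_discrepancy_loops(Xs, ys, Xt, yt, c1, c2, sigmas)
            except ZeroDivisionError:
                continue
            (intra if c1 == c2 else inter).append(d)
    value = np.mean(intra)
    if inter:
        value -= np.mean(inter)
    return float(value)


def slide_window_starts(n_samples, window, stride):
    """All valid half-open window start positions by explicit enumeration."""
    return [s for s in range(0, n_samples + 1) if s % stride == 0 and s + window <= n_samples]


def gelu_exact(x):
    from scipy.stats import norm

    return x * norm.cdf(x)


def mixer_hand_forward(x, p):
    """Fully hand-unrolled single-layer mixer on one sample.

    ``x``: [T, D_in]; p: dict of arrays.  Mirrors: encoder FC -> pre-norm
    temporal MLP with residual -> pre-norm channel MLP with residual ->
    mean-pool over time -> head.
    """
    def ln(v, g, b, eps=1e-5):
        mu = v.mean(-1, keepdims=True)
        var = ((v - mu) ** 2).mean(-1, keepdims=True)
        return (v - mu) / np.sqrt(var + eps) * g + b

    h = x @ p["encoder.w"] + p["encoder.b"]  # [T, C]
    u = ln(h, p["layer0.ln1.gain"], p["layer0.ln1.bias"])
    u = u.T  # [C, T]
    u = gelu_exact(u @ p["layer0.temporal.w1"] + p["layer0.temporal.b1"]) @ p[
        "layer0.temporal.w2"
    ] + p["layer0.temporal.b2"]
    h = h + u.T
    v = ln(h, p["layer0.ln2.gain"], p["layer0.ln2.bias"])
    v = gelu_exact(v @ p["layer0.channel.w1"] + p["layer0.channel.b1"]) @ p[
        "layer0.channel.w2"
    ] + p["layer0.channel.b2"]
    h = h + v
    pooled = h.mean(axis=0)
    return pooled @ p["head.w"] + p["head.b"]


def macs_by_layer_list(config):
    """Independent MAC tally: enumerate every linear map explicitly."""
    layers = [("encoder", config.T, config.input_width, config.C)]
    for n in range(config.N):
        # temporal MLP applied per channel row
        layers.append((f"l{n}.t1", config.C, config.T, config.T_h))
        layers.append((f"l{n}.t2", config.C, config.T_h, config.T))
        # channel MLP applied per timestep
        layers.append((f"l{n}.c1", config.T, config.C, config.C_h))
        layers.append((f"l{n}.c2", config.T, config.C_h, config.C))
    layers.append(("head", 1, config.C, config.n_classes))
    return sum(rows * fan_in * fan_out for _, rows, fan_in, fan_out in layers)
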