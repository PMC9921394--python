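"""Independent brute-force oracles shared across test modules.

Deliberately written with explicit loops and no code shared with the
implementation they check.
"""

import numpy as np


def loop_forward(model, window):
    """Per-element forward pass of the window classifier."""
    K, b, W, c = model.K, model.b, model.W, model.c
    T, C = window.shape
    conv = np.zeros((T - 6, C, 5))
    for f in range(5):
        for t in range(T - 6):
            for ch in range(C):
                acc = b[f]
                for k in range(7):
                    acc += K[f, k] * window[t + k, ch]
                conv[t, ch, f] = max(acc, 0.0)
    pooled = np.zeros(((T - 6) // 2, C, 5))
    for t in range(pooled.shape[0]):
        for ch in range(C):
            for f in range(5):
                pooled[t, ch, f] = max(conv[2 * t, ch, f],
                                       conv[2 * t + 1, ch, f])
    flat = pooled.reshape(-1)
    logits = np.array([sum(flat[i] * W[i, j] for i in range(flat.size)) + c[j]
                       for j in range(4)])
    e = np.exp(logits - logits.max())
    return e / e.sum()


def runs(b):
    """Maximal runs of a sequence as (value, start, end) triples."""
    out, i = [], 0
    while i < len(b):
        j = i
        while j < len(b) and b[j] == b[i]:
            j += 1
        out.append((b[i], i, j))
        i = j
    return out


def epg_oracle(b, value, threshold):
    """Keep runs of ``value`` only when strictly longer than ``threshold``."""
    out = list(b)
    for v, i, j in runs(b):
        if v == value and (j - i) <= threshold:
            out[i:j] = [1 - value] * (j - i)
    return np.array(out, dtype=np.int8)
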