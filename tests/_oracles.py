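"""Shared independent oracles used by more than one test module."""

import numpy as np


def brute_force_otsu(hist):
    """Exhaustive maximizer of the between-class variance over all 256 splits."""
    total = hist.sum()
    levels = np.arange(256)
    best_t, best_v = 0, -1.0
    for t in range(256):
        w0 = hist[: t + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[: t + 1] * levels[: t + 1]).sum() / w0
        mu1 = (hist[t + 1 :] * levels[t + 1 :]).sum() / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t
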