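"""Independent oracles shared between the unit and acceptance suites.

Everything here is deliberately naive: explicit loops, closed forms, and
set arithmetic that cannot share code paths with the implementations they
check.
"""

import numpy as np


class LinearPixelModel:
    """Frozen per-pixel linear softmax classifier.

    Logits are ``x @ A + b`` per pixel, so the input gradient of any loss on
    the logits is exactly ``dlogits @ A.T`` — a closed form against which
    the attack machinery can be verified.
    """

    def __init__(self, A, b):
        self.A = A  # (3, L)
        self.b = b  # (L,)

    def forward(self, x, train=False):
        return np.asarray(x, dtype=np.float64) @ self.A + self.b

    def backward(self, dlogits, want_param_grads=True):
        return np.asarray(dlogits, dtype=np.float64) @ self.A.T


def oracle_boundary(mask):
    """Boundary pixels via explicit neighbour checks; border is background."""
    h, w = mask.shape
    out = []
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ni, nj = i + di, j + dj
                if not (0 <= ni < h and 0 <= nj < w) or not mask[ni, nj]:
                    out.append((i, j))
                    break
    return out


def oracle_nsd(pred, gt, tau):
    """NSD by all-pairs Euclidean distances between boundary sets."""
    p_any, g_any = bool(np.any(pred)), bool(np.any(gt))
    if not p_any and not g_any:
        return 1.0
    if p_any != g_any:
        return 0.0
    bp = oracle_boundary(pred)
    bg = oracle_boundary(gt)

    def hits(src, dst):
        count = 0
        for (i, j) in src:
            best = min((i - a) ** 2 + (j - b) ** 2 for a, b in dst)
            if best <= tau * tau + 1e-12:
                count += 1
        return count

    return (hits(bp, bg) + hits(bg, bp)) / (len(bp) + len(bg))
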