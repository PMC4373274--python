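"""Independent oracles shared across test modules.

These are deliberately naive (loops, full enumeration) and independent of
the vectorized/DP implementation paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import rankdata

from tablet_vfhp.segmentation import SkinRule, classify_skin_pixel


def per_pixel_mask_oracle(frame: np.ndarray, rule: SkinRule) -> np.ndarray:
    """Brute-force per-pixel loop over the scalar classifier."""
    h, w, _ = frame.shape
    out = np.zeros((h, w), dtype=np.uint8)
    for i in range(h):
        for j in range(w):
            out[i, j] = classify_skin_pixel(tuple(int(c) for c in frame[i, j]), rule)
    return out


def enumerate_signed_rank_p(differences: np.ndarray) -> float:
    """Exact two-sided signed-rank p by full 2^n sign enumeration."""
    d = np.asarray(differences, dtype=float)
    d = d[d != 0.0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    center = ranks.sum() / 2.0
    dev = abs(w_obs - center)
    hits = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - center) >= dev - 1e-9:
            hits += 1
    return hits / 2.0**n
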