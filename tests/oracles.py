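"""Brute-force reference implementations used as independent oracles.

Every oracle is a direct, loop-level transcription of the defining formula,
kept deliberately independent of the vectorized implementation it checks.
"""

import numpy as np


def conv2d_bruteforce(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Nested-loop mathematical convolution with edge-replicate padding.

    Assumes an odd-sized kernel centered on each output pixel.
    """
    h, w = img.shape
    kh, kw = kernel.shape
    cy, cx = kh // 2, kw // 2
    out = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            acc = 0.0
            for u in range(kh):
                for v in range(kw):
                    rr = min(max(r - (u - cy), 0), h - 1)
                    cc = min(max(c - (v - cx), 0), w - 1)
                    acc += img[rr, cc] * kernel[u, v]
            out[r, c] = acc
    return out


def forward_diff_bruteforce(img: np.ndarray):
    h, w = img.shape
    mh = np.zeros((h, w))
    mv = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            if c < w - 1:
                mh[r, c] = img[r, c + 1] - img[r, c]
            if r < h - 1:
                mv[r, c] = img[r + 1, c] - img[r, c]
    return mh, mv


def argmax12_bruteforce(stack: np.ndarray) -> np.ndarray:
    """Per-pixel first-maximum index over a (12, H, W) stack."""
    _, h, w = stack.shape
    out = np.zeros((h, w), dtype=int)
    for r in range(h):
        for c in range(w):
            best, best_i = -np.inf, 0
            for i in range(stack.shape[0]):
                if stack[i, r, c] > best:
                    best, best_i = stack[i, r, c], i
            out[r, c] = best_i
    return out
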