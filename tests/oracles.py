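"""Independent brute-force oracles used by the unit and acceptance tests.

Each function recomputes a quantity by direct enumeration or an alternative
construction, deliberately avoiding the library's code paths.
"""

import math

import numpy as np


def atgp_oracle_indices(X: np.ndarray, n_targets: int) -> list[int]:
    """Per-iteration exhaustive argmax target generation.

    Projects every pixel onto the orthogonal complement of the targets found
    so far using an orthonormal basis from QR (not the normal-equations
    projector), and scans pixels one by one.
    """
    idx = [max(range(X.shape[0]), key=lambda i: float(X[i] @ X[i]))]
    while len(idx) < n_targets:
        Q, _ = np.linalg.qr(X[idx].T)
        best_score, best_i = -1.0, None
        for i in range(X.shape[0]):
            if i in idx:
                continue
            res = X[i] - Q @ (Q.T @ X[i])
            score = float(res @ res)
            if score > best_score:
                best_score, best_i = score, i
        idx.append(best_i)
    return idx


def cooccurrence_oracle(levels: np.ndarray, G: int) -> np.ndarray:
    """Loop-based symmetric co-occurrence counts over 4-neighbor pairs."""
    C = np.zeros((G, G), dtype=np.int64)
    rows, cols = levels.shape
    for r in range(rows):
        for c in range(cols):
            for dr, dc in ((0, 1), (1, 0)):
                rr, cc = r + dr, c + dc
                if rr < rows and cc < cols:
                    a, b = levels[r, c], levels[rr, cc]
                    C[a, b] += 1
                    C[b, a] += 1
    return C


def local_entropy_oracle(levels: np.ndarray, G: int) -> int:
    """Exhaustive-search local-entropy threshold on a 2-D level image."""
    C = cooccurrence_oracle(levels, G)

    def quadrant_h(block):
        s = block.sum()
        if s == 0:
            return 0.0
        h = 0.0
        for v in block.ravel():
            if v > 0:
                p = v / s
                h -= p * math.log2(p)
        return h

    best_t, best_h = None, -1.0
    for t in range(int(levels.min()), int(levels.max())):
        h = quadrant_h(C[: t + 1, : t + 1]) + quadrant_h(C[t + 1 :, t + 1 :])
        if h > best_h:
            best_h, best_t = h, t
    return best_t


def otsu_oracle(levels: np.ndarray) -> int:
    """Exhaustive between-class-variance search directly on pixel values."""
    vals = levels.ravel().astype(float)
    best_t, best_v = None, -1.0
    for t in range(int(vals.min()), int(vals.max())):
        lo = vals[vals <= t]
        hi = vals[vals > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size / vals.size, hi.size / vals.size
        v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t
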