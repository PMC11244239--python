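"""Independent brute-force oracles used to validate the implementations.

These deliberately re-derive each quantity from its definition with the
most literal (loop-based or two-line) formulation, independent of the
vectorized code paths under test.
"""

import numpy as np
from scipy.signal import hilbert


def pli_oracle(x: np.ndarray, y: np.ndarray, tol: float = 1e-9) -> float:
    """|mean sign of wrapped Hilbert-phase difference| -- direct form."""
    d = np.angle(hilbert(np.asarray(x, float))) - np.angle(hilbert(np.asarray(y, float)))
    d = np.mod(d, 2 * np.pi)
    d = np.where(d > np.pi, d - 2 * np.pi, d)
    s = np.sign(d)
    s[np.abs(d) < tol] = 0.0
    return abs(float(np.mean(s)))


def saen_oracle(x: np.ndarray, m: int, radius: float) -> float:
    """Brute-force O(K^2) sample entropy with absolute radius.

    Chebyshev distance over templates of length m and m+1, template
    starts 0..K-m-1, strict d < radius, self-pairs excluded.
    """
    x = np.asarray(x, dtype=np.float64)
    K = x.size
    n = K - m
    b = a = 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            dm = max(abs(x[i + k] - x[j + k]) for k in range(m))
            if dm < radius:
                b += 1
                if max(dm, abs(x[i + m] - x[j + m])) < radius:
                    a += 1
    if a == 0 or b == 0:
        return float(np.log(K - m))
    return float(-np.log(a / b))


def saen_oracle_rowwise(x: np.ndarray, m: int, radius: float) -> float:
    """Same brute-force definition with the inner loop vectorized
    (for the larger oracle-equivalence sweeps)."""
    x = np.asarray(x, dtype=np.float64)
    K = x.size
    n = K - m
    b = a = 0
    for i in range(n):
        dm = np.zeros(n)
        for k in range(m):
            dm = np.maximum(dm, np.abs(x[i + k] - x[k:k + n]))
        dm1 = np.maximum(dm, np.abs(x[i + m] - x[m:m + n]))
        b += int((dm < radius).sum()) - 1     # exclude self
        a += int((dm1 < radius).sum()) - 1
    if a == 0 or b == 0:
        return float(np.log(K - m))
    return float(-np.log(a / b))


def se_block_oracle(u: np.ndarray, w1: np.ndarray, b1: np.ndarray,
                    w2: np.ndarray, b2: np.ndarray) -> np.ndarray:
    """Loop implementation of squeeze -> two-layer gate -> rescale."""
    n, C, H, W = u.shape
    out = np.zeros_like(u, dtype=np.float64)
    for b in range(n):
        z = np.array([u[b, c].mean() for c in range(C)])
        h = np.maximum(z @ w1 + b1, 0.0)
        s = 1.0 / (1.0 + np.exp(-(h @ w2 + b2)))
        for c in range(C):
            out[b, c] = s[c] * u[b, c]
    return out


def auc_concordance_oracle(scores: np.ndarray, labels: np.ndarray) -> float:
    """O(n^2) pairwise concordance count (ties count one half)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
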