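"""Independent brute-force oracles used by the test suite.

These are deliberately naive scalar-loop transcriptions of the definitions
(the slowest, most literal implementations we could write) and must stay
independent of the vectorized library code they check.
"""

import math

import numpy as np


def coherence_oracle(block: np.ndarray) -> np.ndarray:
    """Triple-loop normalized spatial correlation of one [k, N] kernel."""
    block = np.asarray(block, dtype=float)
    k, n = block.shape
    z = np.empty_like(block)
    for i in range(n):
        mean = sum(block[t, i] for t in range(k)) / k
        for t in range(k):
            z[t, i] = block[t, i] - mean
    out = np.zeros(n)
    for m in range(1, n):
        acc = 0.0
        for i in range(n - m):
            num = sum(z[t, i] * z[t, i + m] for t in range(k))
            d1 = sum(z[t, i] ** 2 for t in range(k))
            d2 = sum(z[t, i + m] ** 2 for t in range(k))
            if d1 > 0 and d2 > 0:
                acc += num / math.sqrt(d1 * d2)
        out[m - 1] = acc / (n - m)
    return out


def slsc_image_oracle(samples: np.ndarray, kernel_len: int, short_lag: int,
                      edge_skip=None) -> np.ndarray:
    """Per-pixel scalar-loop SLSC image of [axial, channel, line] data."""
    a, n, lines = samples.shape
    h = (kernel_len - 1) // 2
    skip = max(h, h if edge_skip is None else edge_skip)
    rows = []
    for center in range(skip, a - skip):
        row = []
        for line in range(lines):
            block = samples[center - h : center + h + 1, :, line]
            coh = coherence_oracle(block)
            row.append(sum(coh[m - 1] for m in range(1, short_lag + 1)))
        rows.append(row)
    return np.asarray(rows)


def forward_oracle(weights, activations, x: np.ndarray) -> np.ndarray:
    """Row-by-row scalar transcription of the dense stack + average pool."""
    k = x.shape[0]
    rows = []
    for r in range(k):
        v = [float(val) for val in x[r]]
        for (w, b), act in zip(weights, activations):
            out = []
            for j in range(w.shape[1]):
                s = float(b[j])
                for i in range(w.shape[0]):
                    s += v[i] * float(w[i, j])
                out.append(max(s, 0.0) if act == "relu" else math.tanh(s))
            v = out
        rows.append(v)
    pooled = [sum(rows[r][j] for r in range(k)) / k for j in range(len(rows[0]))]
    return np.asarray(pooled)


def pearson_oracle(a: np.ndarray, b: np.ndarray) -> float:
    """Scalar covariance-formula Pearson coefficient."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    ma = sum(a) / len(a)
    mb = sum(b) / len(b)
    cov = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    va = sum((x - ma) ** 2 for x in a)
    vb = sum((y - mb) ** 2 for y in b)
    return cov / math.sqrt(va * vb)
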