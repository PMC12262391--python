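"""Brute-force reference implementations used as independent oracles.

Everything here enumerates loops the slow, obvious way; the library's
vectorized code must agree with these on small inputs.
"""

from __future__ import annotations

import math

import numpy as np

from chromsaliency.core import AnnotationMatrix, GenomeBins, StateModel


def matrix_from_rows(rows, n_states=None, bin_size=200, quiescent_index=None):
    """Build an AnnotationMatrix from a list of per-biosample state-index lists."""
    states = np.asarray(rows, dtype=np.int16)
    n = n_states if n_states is not None else int(states.max()) + 1
    model = StateModel(
        labels=tuple(chr(ord("A") + i) for i in range(n)),
        quiescent_index=quiescent_index,
    )
    bins = GenomeBins.single(states.shape[1], bin_size)
    ids = [f"s{i}" for i in range(states.shape[0])]
    return AnnotationMatrix(states, ids, bins, model)


def xlog2(p, q):
    return p * math.log2(p / q) if p > 0 else 0.0


def s1_bruteforce(matrix, q=None):
    m, T, n = matrix.m, matrix.total_bins, matrix.n_states
    if q is None:
        counts = np.zeros(n)
        for row in matrix.states:
            for s in row:
                counts[s] += 1
        q = counts / counts.sum()
    out = np.zeros((T, n))
    for b in range(T):
        for i in range(n):
            p = sum(1 for a in range(m) if matrix.states[a, b] == i) / m
            out[b, i] = xlog2(p, q[i])
    return out


def pair_q_bruteforce(matrix):
    m, T, n = matrix.m, matrix.total_bins, matrix.n_states
    q = np.zeros((n, n))
    for b in range(T):
        for a in range(m):
            for c in range(m):
                if a != c:
                    q[matrix.states[a, b], matrix.states[c, b]] += 1
    return q / (T * m * (m - 1))


def s2_bruteforce(matrix, pair_q=None):
    m, T, n = matrix.m, matrix.total_bins, matrix.n_states
    if pair_q is None:
        pair_q = pair_q_bruteforce(matrix)
    out = np.zeros((T, n))
    for b in range(T):
        p = np.zeros((n, n))
        for a in range(m):
            for c in range(m):
                if a != c:
                    p[matrix.states[a, b], matrix.states[c, b]] += 1
        p /= m * (m - 1)
        for i in range(n):
            for j in range(n):
                out[b, i] += xlog2(p[i, j], pair_q[i, j]) if p[i, j] > 0 else 0.0
    return out


def pair_sample_q_bruteforce(matrix):
    m, T, n = matrix.m, matrix.total_bins, matrix.n_states
    q = np.zeros((n, n, m, m))
    for b in range(T):
        for a in range(m):
            for c in range(m):
                if a != c:
                    q[matrix.states[a, b], matrix.states[c, b], a, c] += 1
    return q / (T * m * (m - 1))


def s3_bruteforce(matrix, psq=None):
    m, T, n = matrix.m, matrix.total_bins, matrix.n_states
    if psq is None:
        psq = pair_sample_q_bruteforce(matrix)
    M = m * (m - 1)
    out = np.zeros((T, n))
    for b in range(T):
        for a in range(m):
            for c in range(m):
                if a != c:
                    i, j = matrix.states[a, b], matrix.states[c, b]
                    out[b, i] += (1 / M) * math.log2((1 / M) / psq[i, j, a, c])
    return out


def ssed_bruteforce(matrix, rows_a, rows_b):
    """SSED per bin via the S1 brute force on each group against the pooled q."""
    pooled = matrix.subset(list(rows_a) + list(rows_b))
    counts = np.zeros(matrix.n_states)
    for row in pooled.states:
        for s in row:
            counts[s] += 1
    q = counts / counts.sum()
    sa = s1_bruteforce(matrix.subset(rows_a), q)
    sb = s1_bruteforce(matrix.subset(rows_b), q)
    dist = ((sa - sb) ** 2).sum(axis=1)
    sign = np.where(sa.sum(axis=1) >= sb.sum(axis=1), 1.0, -1.0)
    return sign * dist


def max_sum_window_bruteforce(scores, width):
    """Best-scoring window of the given width (ties to the lowest start)."""
    best_start, best = 0, -np.inf
    for s in range(len(scores) - width + 1):
        total = float(np.sum(scores[s : s + width]))
        if total > best:
            best_start, best = s, total
    return best_start, best
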