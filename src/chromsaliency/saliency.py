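"""Per-bin, per-state saliency scores for multi-biosample state annotations.

Three nested background models quantify how unexpected the state configuration
at a genomic bin is, relative to genome-wide averages, in bits:

* **S1** — relative entropy (Kullback–Leibler divergence) of the per-bin state
  frequency vector ``p`` against the genome-wide state frequency vector ``q``::

      S1_i = p_i * log2(p_i / q_i)

  The total over states is ``KL(p || q) >= 0``, with equality iff ``p == q``.
  Rare states (enhancers, promoters) receive large per-observation weight;
  ubiquitous states (quiescent, transcribed) are down-weighted.

* **S2** — adds pairwise state co-occurrence.  At each bin the distribution of
  ordered pairs of distinct biosamples over state pairs ``(i, j)`` is scored
  against the genome-wide mean pair distribution::

      S2_i = sum_j p_ij * log2(p_ij / q_ij)

* **S3** — additionally conditions on *which* biosample pair produced the state
  pair, capturing that related biosamples share configurations more often::

      S3_i = sum_j sum_{a,b} p_ij^{ab} * log2(p_ij^{ab} / q_ij^{ab})

Pair distributions run over ordered distinct biosample pairs (no self-pairs);
the normalizer is ``m * (m - 1)``.  The convention ``0 * log2(0/q) = 0``
applies throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import AnnotationMatrix, GenomeBins, StateModel

__all__ = [
    "StateBackground",
    "ScoreTrack",
    "expected_frequencies",
    "observed_frequencies",
    "expected_pair_frequencies",
    "expected_pair_sample_frequencies",
    "s1_scores",
    "s2_scores",
    "s3_scores",
    "compute_scores",
    "consensus_states",
    "dominant_states",
]


@dataclass
class StateBackground:
    """Expected genome-wide state frequencies at one or more orders.

    ``q[i]`` — marginal state frequencies; ``pair_q[i, j]`` — state-pair
    frequencies over ordered distinct biosample pairs; ``pair_sample_q[i, j,
    a, b]`` — the same resolved per ordered biosample pair.
    """

    q: np.ndarray
    pair_q: Optional[np.ndarray] = None
    pair_sample_q: Optional[np.ndarray] = None

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        if self.q.ndim != 1 or np.any(self.q < 0):
            raise ValueError("q must be a non-negative vector")
        if abs(self.q.sum() - 1.0) > 1e-9:
            raise ValueError(f"q sums to {self.q.sum()}, expected 1")
        if self.pair_q is not None:
            self.pair_q = np.asarray(self.pair_q, dtype=float)
            if abs(self.pair_q.sum() - 1.0) > 1e-9:
                raise ValueError("pair_q must sum to 1")
        if self.pair_sample_q is not None:
            self.pair_sample_q = np.asarray(self.pair_sample_q, dtype=float)
            if abs(self.pair_sample_q.sum() - 1.0) > 1e-9:
                raise ValueError("pair_sample_q must sum to 1")


@dataclass
class ScoreTrack:
    """Saliency levels in bits: ``per_state[b, i]`` plus per-bin totals."""

    per_state: np.ndarray
    metric: str
    bins: GenomeBins
    model: StateModel

    def __post_init__(self):
        self.per_state = np.asarray(self.per_state, dtype=float)
        if self.per_state.ndim != 2:
            raise ValueError("per_state must be 2-D (bins x states)")
        if self.per_state.shape[0] != self.bins.total_bins:
            raise ValueError("per_state rows must equal total_bins")
        if self.per_state.shape[1] != self.model.n_states:
            raise ValueError("per_state columns must equal n_states")
        if self.metric not in {"S1", "S2", "S3"}:
            raise ValueError("metric must be one of S1, S2, S3")

    @property
    def total(self) -> np.ndarray:
        return self.per_state.sum(axis=1)


def _xlog2x_over(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """``p * log2(p / q)`` with ``0 * log2(0/q) := 0``; raises on q=0 with p>0."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    out = np.zeros(np.broadcast_shapes(p.shape, q.shape))
    mask = p > 0
    qb = np.broadcast_to(q, out.shape)
    if np.any(mask & (qb == 0)):
        raise ValueError(
            "background frequency is zero where an observed frequency is positive; "
            "supply a pseudocount or a background covering all observed states"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.broadcast_to(p, out.shape) * np.log2(
            np.where(mask, np.broadcast_to(p, out.shape), 1.0) / np.where(qb > 0, qb, 1.0)
        )
    out[mask] = vals[mask]
    return out


def expected_frequencies(matrix: AnnotationMatrix, pseudocount: float = 0.0) -> StateBackground:
    """Genome-wide expected state frequencies ``q_i`` (counts over all m*T entries)."""
    n = matrix.n_states
    counts = np.bincount(matrix.states.ravel().astype(np.int64), minlength=n).astype(float)
    counts += pseudocount
    return StateBackground(q=counts / counts.sum())


def observed_frequencies(matrix: AnnotationMatrix, bin: int) -> np.ndarray:
    """Per-bin observed state frequencies ``p_i`` across biosamples."""
    col = matrix.states[:, bin].astype(np.int64)
    return np.bincount(col, minlength=matrix.n_states) / matrix.m


def s1_scores(
    matrix: AnnotationMatrix, background: Optional[StateBackground] = None
) -> ScoreTrack:
    """Relative-entropy saliency against the genome-wide state background."""
    if background is None:
        background = expected_frequencies(matrix)
    counts = matrix.state_counts()
    p = counts / matrix.m
    per_state = _xlog2x_over(p, background.q[None, :])
    return ScoreTrack(per_state=per_state, metric="S1", bins=matrix.bins, model=matrix.model)


def _pair_counts_per_bin(counts: np.ndarray) -> np.ndarray:
    """Ordered-distinct-pair counts per bin from occupancy counts.

    ``out[b, i, j] = c_i * c_j - delta_ij * c_i`` — the number of ordered
    biosample pairs (a != b) with states (i, j) at bin b.
    """
    c = counts.astype(np.int64)
    out = c[:, :, None] * c[:, None, :]
    diag = np.arange(counts.shape[1])
    out[:, diag, diag] -= c
    return out


def expected_pair_frequencies(matrix: AnnotationMatrix) -> StateBackground:
    """Mean over bins of the per-bin ordered-distinct-pair state distribution."""
    if matrix.m < 2:
        raise ValueError("pair metrics require at least 2 biosamples")
    counts = matrix.state_counts()
    pair = _pair_counts_per_bin(counts).astype(float) / (matrix.m * (matrix.m - 1))
    pair_q = pair.mean(axis=0)
    q = expected_frequencies(matrix).q
    return StateBackground(q=q, pair_q=pair_q)


def s2_scores(
    matrix: AnnotationMatrix, background: Optional[StateBackground] = None
) -> ScoreTrack:
    """Co-occurrence-adjusted saliency: per-bin pair distribution vs genome-wide."""
    if matrix.m < 2:
        raise ValueError("S2 requires at least 2 biosamples")
    if background is None or background.pair_q is None:
        background = expected_pair_frequencies(matrix)
    counts = matrix.state_counts()
    p_pair = _pair_counts_per_bin(counts).astype(float) / (matrix.m * (matrix.m - 1))
    terms = _xlog2x_over(p_pair, background.pair_q[None, :, :])
    per_state = terms.sum(axis=2)  # sum over j
    return ScoreTrack(per_state=per_state, metric="S2", bins=matrix.bins, model=matrix.model)


def expected_pair_sample_frequencies(matrix: AnnotationMatrix) -> StateBackground:
    """Per-ordered-biosample-pair expected state-pair frequencies.

    ``pair_sample_q[i, j, a, b]`` is the fraction of (bin, ordered pair)
    events in which biosample ``a`` shows state ``i`` while ``b`` shows ``j``;
    the tensor sums to 1 over all four axes.
    """
    m, n, T = matrix.m, matrix.n_states, matrix.total_bins
    if m < 2:
        raise ValueError("pair metrics require at least 2 biosamples")
    psq = np.zeros((n, n, m, m), dtype=float)
    states = matrix.states.astype(np.int64)
    for a in range(m):
        for b in range(m):
            if a == b:
                continue
            joint = np.bincount(states[a] * n + states[b], minlength=n * n).reshape(n, n)
            psq[:, :, a, b] = joint
    psq /= T * m * (m - 1)
    bg = expected_pair_frequencies(matrix)
    return StateBackground(q=bg.q, pair_q=bg.pair_q, pair_sample_q=psq)


def s3_scores(
    matrix: AnnotationMatrix, background: Optional[StateBackground] = None
) -> ScoreTrack:
    """Saliency adjusted for state *and* biosample pair co-occurrence.

    Streams over ordered biosample pairs; per-bin joint (i, j, a, b) tensors
    are never materialized genome-wide (memory stays O(T*n + n^2 m^2)).
    """
    m, n, T = matrix.m, matrix.n_states, matrix.total_bins
    if m < 2:
        raise ValueError("S3 requires at least 2 biosamples")
    if background is None or background.pair_sample_q is None:
        background = expected_pair_sample_frequencies(matrix)
    psq = background.pair_sample_q
    M = m * (m - 1)
    states = matrix.states.astype(np.int64)
    per_state = np.zeros((T, n), dtype=float)
    bins_idx = np.arange(T)
    # At a bin, p_ij^{ab} is 1/M for the single observed (i,j) of pair (a,b):
    # the (a,b) term is (1/M) * log2((1/M) / q[s_a, s_b, a, b]).
    for a in range(m):
        for b in range(m):
            if a == b:
                continue
            qab = psq[states[a], states[b], a, b]
            if np.any(qab <= 0):
                raise ValueError(
                    f"zero background for an observed state pair of biosamples ({a},{b})"
                )
            term = (1.0 / M) * np.log2((1.0 / M) / qab)
            np.add.at(per_state, (bins_idx, states[a]), term)
    return ScoreTrack(per_state=per_state, metric="S3", bins=matrix.bins, model=matrix.model)


_METRICS = {"S1": s1_scores, "S2": s2_scores, "S3": s3_scores}


def compute_scores(
    matrix: AnnotationMatrix,
    metric: str = "S1",
    background: Optional[StateBackground] = None,
) -> ScoreTrack:
    """Dispatch to :func:`s1_scores`, :func:`s2_scores` or :func:`s3_scores`."""
    try:
        fn = _METRICS[metric.upper()]
    except KeyError:
        raise ValueError(f"unknown saliency metric {metric!r}; choose S1, S2 or S3")
    return fn(matrix, background)


def consensus_states(scores: ScoreTrack) -> np.ndarray:
    """Most salient state per bin (the consensus epigenome).

    Unlike the per-bin *dominant* (most frequent) state, the consensus
    preferentially surfaces rare regulatory states whose presence in even a
    minority of biosamples is highly informative.  Ties break to the lowest
    state index.
    """
    per_state = scores.per_state
    consensus = per_state.argmax(axis=1)
    ties = (per_state == per_state.max(axis=1, keepdims=True)).sum(axis=1) > 1
    if ties.any():
        warnings.warn(
            f"{int(ties.sum())} bins had tied maximal saliency; ties break to the lowest state index",
            stacklevel=2,
        )
    return consensus.astype(np.int64)


def dominant_states(matrix: AnnotationMatrix) -> np.ndarray:
    """Most frequent state per bin across biosamples (ties to lowest index)."""
    return matrix.state_counts().argmax(axis=1).astype(np.int64)
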