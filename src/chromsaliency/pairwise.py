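"""Differential chromatin-state analysis between two biosample groups.

At every genomic bin the two groups' per-state S1 saliency vectors (computed
against a background of expected state frequencies pooled over *both* groups)
are compared with a signed squared Euclidean distance::

    SSED_{A,B} = sign * sum_i (p_i^A log2(p_i^A / q_i^AB)
                               - p_i^B log2(p_i^B / q_i^AB))^2

where the sign is positive when group A's total saliency at the bin exceeds
group B's.  Significance comes from a permutation scheme: biosample group
labels are permuted (preserving group sizes), SSED recomputed genome-wide,
all-quiescent bins excluded, and a three-parameter generalized normal
distribution (location mu, scale alpha, shape beta; beta=2 is Gaussian,
beta=1 Laplace) is fitted by maximum likelihood to repeated subsamples of the
pooled permuted scores.  The fit with median negative log-likelihood becomes
the null; two-sided empirical p-values are read off its tails and adjusted by
Benjamini-Hochberg over non-excluded bins.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .core import AnnotationMatrix, GenomeBins, Region, RegionSet
from .saliency import StateBackground, _xlog2x_over, expected_frequencies

__all__ = [
    "GroupPair",
    "GeneralizedNormalFit",
    "DifferentialTrack",
    "joint_background",
    "ssed_scores",
    "fit_generalized_normal",
    "permutation_null",
    "empirical_pvalues",
    "bh_fdr",
    "differential_analysis",
    "top_differential_regions",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupPair:
    """Two disjoint, non-empty sets of biosample row indices."""

    group_a: tuple[int, ...]
    group_b: tuple[int, ...]

    def __post_init__(self):
        a = tuple(int(i) for i in self.group_a)
        b = tuple(int(i) for i in self.group_b)
        object.__setattr__(self, "group_a", a)
        object.__setattr__(self, "group_b", b)
        if not a or not b:
            raise ValueError("both groups must be non-empty")
        if set(a) & set(b):
            raise ValueError("groups must be disjoint")

    @property
    def all_rows(self) -> tuple[int, ...]:
        return self.group_a + self.group_b

    def swapped(self) -> "GroupPair":
        return GroupPair(self.group_b, self.group_a)


@dataclass
class GeneralizedNormalFit:
    """A fitted symmetric generalized normal null: f(x) ∝ exp(-(|x-mu|/alpha)^beta)."""

    loc: float
    scale: float
    shape: float
    nll: float = math.nan

    def __post_init__(self):
        if self.scale <= 0 or self.shape <= 0:
            raise ValueError("scale and shape must be positive")

    def sf_two_sided(self, x: np.ndarray) -> np.ndarray:
        """P(|X - mu| >= |x - mu|) under the fitted density."""
        z = np.abs(np.asarray(x, dtype=float) - self.loc) / self.scale
        return special.gammaincc(1.0 / self.shape, z ** self.shape)


@dataclass
class DifferentialTrack:
    """Per-bin signed differential scores with significance annotations."""

    ssed: np.ndarray
    bins: GenomeBins
    excluded: np.ndarray
    per_state_sq: Optional[np.ndarray] = None
    pvalue: Optional[np.ndarray] = None
    qvalue: Optional[np.ndarray] = None
    fit: Optional[GeneralizedNormalFit] = None


def joint_background(matrix: AnnotationMatrix, pair: GroupPair) -> StateBackground:
    """Expected state frequencies pooled over both groups' biosamples."""
    return expected_frequencies(matrix.subset(pair.all_rows))


def _group_counts(states: np.ndarray, n: int) -> np.ndarray:
    T = states.shape[1]
    flat = (states.astype(np.int64) + np.arange(T, dtype=np.int64)[None, :] * n).ravel()
    return np.bincount(flat, minlength=T * n).reshape(T, n)


def _ssed_from_states(
    states_a: np.ndarray,
    states_b: np.ndarray,
    q: np.ndarray,
    return_per_state: bool = False,
):
    n = q.shape[0]
    pa = _group_counts(states_a, n) / states_a.shape[0]
    pb = _group_counts(states_b, n) / states_b.shape[0]
    sa = _xlog2x_over(pa, q[None, :])
    sb = _xlog2x_over(pb, q[None, :])
    diff_sq = (sa - sb) ** 2
    dist = diff_sq.sum(axis=1)
    # ties (equal totals) get a positive sign
    sign = np.where(sa.sum(axis=1) >= sb.sum(axis=1), 1.0, -1.0)
    ssed = sign * dist
    if return_per_state:
        return ssed, diff_sq
    return ssed


def _excluded_mask(matrix: AnnotationMatrix, rows: Sequence[int]) -> np.ndarray:
    """Bins where all of the given biosamples carry the quiescent state."""
    qi = matrix.model.quiescent_index
    if qi is None:
        warnings.warn(
            "no quiescent state designated; quiescent-bin exclusion is skipped",
            stacklevel=3,
        )
        return np.zeros(matrix.total_bins, dtype=bool)
    return (matrix.states[list(rows), :] == qi).all(axis=0)


def ssed_scores(matrix: AnnotationMatrix, pair: GroupPair) -> DifferentialTrack:
    """Signed squared Euclidean distance between group saliency profiles per bin."""
    q = joint_background(matrix, pair).q
    ssed, diff_sq = _ssed_from_states(
        matrix.states[list(pair.group_a), :],
        matrix.states[list(pair.group_b), :],
        q,
        return_per_state=True,
    )
    excluded = _excluded_mask(matrix, pair.all_rows)
    return DifferentialTrack(ssed=ssed, bins=matrix.bins, excluded=excluded,
                             per_state_sq=diff_sq)


def _gennorm_nll(params: np.ndarray, x: np.ndarray) -> float:
    mu, log_alpha, log_beta = params
    alpha, beta = math.exp(log_alpha), math.exp(log_beta)
    if alpha <= 0 or not math.isfinite(alpha):
        return math.inf
    z = np.abs(x - mu) / alpha
    # -log f = -log(beta / (2 alpha Gamma(1/beta))) + z^beta
    const = math.log(beta) - math.log(2 * alpha) - special.gammaln(1.0 / beta)
    return float(np.sum(z ** beta) - x.size * const)


def _kurtosis_to_beta(kurt: float) -> float:
    """Invert the generalized-normal excess kurtosis for a moment-based beta init."""

    def excess(beta):
        return math.exp(
            special.gammaln(5 / beta) + special.gammaln(1 / beta) - 2 * special.gammaln(3 / beta)
        ) - 3.0

    lo, hi = 0.2, 10.0
    if kurt >= excess(lo):
        return lo
    if kurt <= excess(hi):
        return hi
    return float(optimize.brentq(lambda b: excess(b) - kurt, lo, hi))


def fit_generalized_normal(values: np.ndarray) -> GeneralizedNormalFit:
    """Maximum-likelihood fit of the 3-parameter generalized normal.

    Initialization is method-of-moments (mu from the median, beta by inverting
    the excess kurtosis, alpha from the variance identity
    ``var = alpha^2 Gamma(3/beta)/Gamma(1/beta)``); optimization is bounded
    L-BFGS-B on (mu, log alpha, log beta) with beta restricted to [0.2, 10].
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise ValueError("too few values to fit a null distribution")
    mu0 = float(np.median(x))
    var = float(np.var(x))
    if var == 0:
        raise ValueError("degenerate (constant) values; cannot fit a null")
    kurt = float(stats.kurtosis(x, fisher=True))
    beta0 = _kurtosis_to_beta(kurt)
    alpha0 = math.sqrt(
        var * math.exp(special.gammaln(1 / beta0) - special.gammaln(3 / beta0))
    )
    # scale is kept within 12 decades of its moment estimate to stop the
    # optimizer collapsing alpha to 0 on samples with a heavy point mass
    la0 = math.log(alpha0)
    bounds = [(None, None), (la0 - 30, la0 + 30), (math.log(0.2), math.log(10.0))]

    inits = [
        (mu0, math.log(alpha0), math.log(beta0)),
        (mu0, math.log(math.sqrt(2 * var)), math.log(2.0)),  # Gaussian-shaped fallback
    ]
    best = None
    for init in inits:
        # the |x - mu|^beta cusp is non-differentiable at mu for beta < 1, so
        # follow the quasi-Newton pass with a gradient-free polish
        for method in ("L-BFGS-B", "Nelder-Mead"):
            res = optimize.minimize(
                _gennorm_nll, np.array(init), args=(x,), method=method, bounds=bounds
            )
            if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
                best = res
    if best is None:
        raise RuntimeError("generalized normal MLE failed to converge")
    mu, log_alpha, log_beta = best.x
    return GeneralizedNormalFit(
        loc=float(mu), scale=math.exp(log_alpha), shape=math.exp(log_beta), nll=float(best.fun)
    )


def permutation_null(
    matrix: AnnotationMatrix,
    pair: GroupPair,
    n_perms: int = 100,
    sample_size: int = 100_000,
    n_fits: int = 11,
    seed: Optional[int] = None,
) -> GeneralizedNormalFit:
    """Fit the differential null by permuting group labels.

    Each permutation reassigns the pooled biosamples to pseudo-groups of the
    original sizes and recomputes SSED genome-wide (against the same joint
    background, which is permutation-invariant).  Permuted scores from
    non-excluded bins are pooled; ``n_fits`` subsamples of up to
    ``sample_size`` values are each fitted by maximum likelihood, and the fit
    with the median negative log-likelihood is returned.
    """
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    if sample_size < 100:
        raise ValueError("sample_size must be >= 100")
    rows = np.array(pair.all_rows)
    m_a = len(pair.group_a)
    n_distinct = math.comb(len(rows), m_a)
    if n_distinct < 2:
        raise ValueError("fewer than 2 distinct group assignments; cannot permute")
    rng = np.random.default_rng(seed)
    q = joint_background(matrix, pair).q
    keep = ~_excluded_mask(matrix, pair.all_rows)
    pooled = []
    for _ in range(n_perms):
        perm = rng.permutation(rows)
        ssed = _ssed_from_states(
            matrix.states[perm[:m_a], :], matrix.states[perm[m_a:], :], q
        )
        pooled.append(ssed[keep])
    pooled = np.concatenate(pooled)
    if pooled.size == 0:
        raise ValueError("no non-excluded bins; cannot fit a null")

    fits = []
    for _ in range(n_fits):
        k = min(sample_size, pooled.size)
        sample = rng.choice(pooled, size=k, replace=False)
        fits.append(fit_generalized_normal(sample))
    fits.sort(key=lambda f: f.nll)
    # median by NLL; even n_fits -> lower median element
    return fits[(len(fits) - 1) // 2]


def empirical_pvalues(track: DifferentialTrack, fit: GeneralizedNormalFit) -> DifferentialTrack:
    """Two-sided p-values from the fitted null; excluded bins get p = 1."""
    p = fit.sf_two_sided(track.ssed)
    p = np.clip(p, 0.0, 1.0)
    p[track.excluded] = 1.0
    track.pvalue = p
    track.fit = fit
    return track


def bh_fdr(pvalues: np.ndarray, exclude_mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment over non-excluded bins.

    Excluded bins do not enter the adjustment and come back with q = 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if exclude_mask is None:
        exclude_mask = np.zeros(p.shape, dtype=bool)
    q = np.ones_like(p)
    keep = ~np.asarray(exclude_mask, dtype=bool)
    if keep.any():
        _, q_keep, _, _ = multipletests(p[keep], method="fdr_bh")
        q[keep] = q_keep
    return q


def differential_analysis(
    matrix: AnnotationMatrix,
    pair: GroupPair,
    n_perms: int = 100,
    sample_size: int = 100_000,
    n_fits: int = 11,
    seed: Optional[int] = None,
) -> DifferentialTrack:
    """SSED scores, permutation null, p-values and BH q-values in one call."""
    track = ssed_scores(matrix, pair)
    fit = permutation_null(
        matrix, pair, n_perms=n_perms, sample_size=sample_size, n_fits=n_fits, seed=seed
    )
    empirical_pvalues(track, fit)
    track.qvalue = bh_fdr(track.pvalue, track.excluded)
    return track


def top_differential_regions(
    track: DifferentialTrack,
    region_size: int = 25_000,
    k: int = 100,
    model=None,
) -> RegionSet:
    """Greedy top-k differential regions on |SSED|.

    Each region's score is its signed SSED aggregate; the name encodes the
    rank, the direction (``A>`` when group A is the more salient side of the
    aggregate, else ``B>``) and, when a state model and per-state
    contributions are available, the maximally contributing state.
    """
    from .regions import recommend_regions

    raw = recommend_regions(np.abs(track.ssed), track.bins, region_size, k)
    regions = []
    for r in raw:
        sl = slice(
            track.bins.bin_index(r.chrom, r.start),
            track.bins.bin_index(r.chrom, r.end - 1) + 1,
        )
        signed = float(track.ssed[sl].sum())
        direction = "A>" if signed >= 0 else "B>"
        name = f"{r.rank}|{direction}"
        if track.per_state_sq is not None and model is not None:
            top_state = int(track.per_state_sq[sl].sum(axis=0).argmax())
            name += f"|{model.labels[top_state]}"
        regions.append(Region(r.chrom, r.start, r.end, signed, r.rank, name=name))
    return RegionSet(regions=regions, provenance="differential")
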