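"""Region recommendation and scale-normalized similarity search.

Recommendation greedily grows fixed-size windows around the highest-scoring
bins of a saliency track, producing a ranked, non-overlapping set of salient
intervals.  Similarity search reduces any query region (5–100 kb) to a
scale-free representation — 25 consecutive blocks, per-state max-pooled —
and ranks all same-size windows genome-wide by Euclidean distance, keeping
hits closer than half the mode of the genome-wide distance distribution
(i.e. regions more similar than dissimilar to the query).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .core import GenomeBins, Region, RegionSet
from .saliency import ScoreTrack

__all__ = [
    "N_BLOCKS",
    "MIN_QUERY_BP",
    "MAX_QUERY_BP",
    "BlockVector",
    "recommend_regions",
    "reduce_region",
    "build_search_index",
    "similarity_threshold",
    "similarity_search",
]

log = logging.getLogger(__name__)

N_BLOCKS = 25
MIN_QUERY_BP = 5_000
MAX_QUERY_BP = 100_000


@dataclass
class BlockVector:
    """A region reduced to 25 per-state max-pooled saliency blocks."""

    values: np.ndarray  # 25 x n_states
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != N_BLOCKS:
            raise ValueError(f"expected {N_BLOCKS} blocks, got {self.values.shape[0]}")

    @property
    def scale(self) -> int:
        return self.end - self.start

    def flat(self) -> np.ndarray:
        return self.values.ravel()


def recommend_regions(
    total_scores: np.ndarray,
    bins: GenomeBins,
    region_size: int,
    k: int = 100,
) -> RegionSet:
    """Greedy ranked list of non-overlapping high-saliency regions.

    Repeatedly seeds at the highest-scoring available bin (ties to the lower
    coordinate) and grows a window one bin at a time toward whichever side
    adds the larger score (ties extend right); chromosome edges and
    previously claimed bins force the other side.  A window that cannot
    reach ``region_size`` is discarded.  Stops after ``k`` regions or when
    no strictly positive seed remains.
    """
    total_scores = np.asarray(total_scores, dtype=float)
    if total_scores.shape[0] != bins.total_bins:
        raise ValueError("score vector length must equal total_bins")
    if region_size <= 0 or region_size % bins.bin_size:
        raise ValueError(f"region_size must be a positive multiple of bin_size={bins.bin_size}")
    w = region_size // bins.bin_size
    if not any(nb >= w for nb in bins.bins_per_chrom):
        raise ValueError("no chromosome is long enough for the requested region size")

    offsets = bins.offsets
    chrom_of = np.searchsorted(offsets, np.arange(bins.total_bins), side="right") - 1
    available = np.ones(bins.total_bins, dtype=bool)
    scores = total_scores.copy()
    regions: list[Region] = []
    NEG = -np.inf

    while len(regions) < k:
        masked = np.where(available, scores, NEG)
        seed = int(masked.argmax())  # argmax ties -> lowest coordinate
        if not available[seed] or masked[seed] <= 0:
            break
        ci = int(chrom_of[seed])
        lo_bound, hi_bound = int(offsets[ci]), int(offsets[ci + 1])
        left = right = seed
        ok = True
        while right - left + 1 < w:
            can_left = left - 1 >= lo_bound and available[left - 1]
            can_right = right + 1 < hi_bound and available[right + 1]
            if not can_left and not can_right:
                ok = False
                break
            if can_left and can_right:
                go_right = scores[right + 1] >= scores[left - 1]  # tie -> right
            else:
                go_right = can_right
            if go_right:
                right += 1
            else:
                left -= 1
        if not ok:
            # blocked on both sides before reaching full size: give up on this seed
            available[seed] = False
            continue
        available[left : right + 1] = False
        aggregate = float(scores[left : right + 1].sum())
        chrom = bins.chrom_names[ci]
        start = (left - lo_bound) * bins.bin_size
        end = (right + 1 - lo_bound) * bins.bin_size
        regions.append(Region(chrom, start, end, aggregate, rank=0))

    regions.sort(key=lambda r: -r.score)
    regions = [Region(r.chrom, r.start, r.end, r.score, i + 1) for i, r in enumerate(regions)]
    return RegionSet(regions=regions, provenance="recommendation")


def _region_to_bins(bins: GenomeBins, chrom: str, start: int, end: int) -> slice:
    if start % bins.bin_size or end % bins.bin_size:
        raise ValueError(f"{chrom}:{start}-{end} is not aligned to bin_size={bins.bin_size}")
    lo = bins.bin_index(chrom, start)
    hi = bins.bin_index(chrom, end - 1) + 1
    return slice(lo, hi)


def reduce_region(scores: ScoreTrack, chrom: str, start: int, end: int) -> BlockVector:
    """Reduce a region to 25 per-state max-pooled blocks.

    The region must span ``25 * c`` bins for integer ``c >= 1``; each block's
    value for state i is the maximum per-state saliency over its ``c`` bins,
    so the representation is independent of region size and tolerant of
    small within-block shifts of the pattern.
    """
    sl = _region_to_bins(scores.bins, chrom, start, end)
    n_bins = sl.stop - sl.start
    if n_bins % N_BLOCKS:
        raise ValueError(
            f"region length {end - start} bp is not a multiple of "
            f"{N_BLOCKS} x {scores.bins.bin_size} bp"
        )
    c = n_bins // N_BLOCKS
    block = scores.per_state[sl].reshape(N_BLOCKS, c, -1).max(axis=1)
    return BlockVector(values=block, chrom=chrom, start=start, end=end)


def build_search_index(
    scores: ScoreTrack, region_size: int, stride: int | None = None
) -> list[BlockVector]:
    """Block vectors for all windows of ``region_size`` tiled genome-wide.

    The default stride is half the window (a compromise between alignment
    tolerance and index size); windows overhanging chromosome ends are
    dropped.
    """
    bs = scores.bins.bin_size
    if stride is None:
        stride = max(bs, region_size // 2 // bs * bs)
    if stride <= 0 or stride % bs:
        raise ValueError(f"stride must be a positive multiple of bin_size={bs}")
    index: list[BlockVector] = []
    for chrom, nb in zip(scores.bins.chrom_names, scores.bins.bins_per_chrom):
        L = nb * bs
        for start in range(0, L - region_size + 1, stride):
            index.append(reduce_region(scores, chrom, start, start + region_size))
    return index


def similarity_threshold(index: list[BlockVector], query: BlockVector) -> float:
    """Half the mode of the query-to-genome distance distribution.

    The mode is estimated as the midpoint of the tallest Freedman–Diaconis
    histogram bin (ties to the lower bin).  With fewer than 10 windows the
    histogram is unreliable and half the median is used instead.
    """
    if not index:
        raise ValueError("empty search index")
    qv = query.flat()
    d = np.array([np.linalg.norm(bv.flat() - qv) for bv in index])
    if d.size < 10:
        warnings.warn("fewer than 10 indexed windows; using median/2 as threshold", stacklevel=2)
        return float(np.median(d) / 2)
    if np.ptp(d) == 0:
        return float(d[0] / 2)
    iqr = np.subtract(*np.percentile(d, [75, 25]))
    width = 2 * iqr / d.size ** (1 / 3)
    if width <= 0:
        width = np.ptp(d) / int(np.sqrt(d.size))
    n_bins = max(1, int(np.ceil(np.ptp(d) / width)))
    hist, edges = np.histogram(d, bins=n_bins)
    tallest = int(hist.argmax())  # argmax ties -> lower bin
    mode = (edges[tallest] + edges[tallest + 1]) / 2
    return float(mode / 2)


def similarity_search(
    scores: ScoreTrack,
    chrom: str,
    start: int,
    end: int,
    max_hits: int = 5,
    stride: int | None = None,
    index: list[BlockVector] | None = None,
) -> RegionSet:
    """Genome-wide search for regions resembling the query.

    Supported query sizes are multiples of ``25 * bin_size`` between 5 kb and
    100 kb.  Windows overlapping the query are excluded; the remaining
    windows are ranked by ascending Euclidean distance between flattened
    block vectors and returned (up to ``max_hits``) when their distance is
    at most the half-mode threshold.  Region scores are the distances.
    """
    size = end - start
    if not (MIN_QUERY_BP <= size <= MAX_QUERY_BP):
        raise ValueError(
            f"query size {size} bp outside the supported range "
            f"[{MIN_QUERY_BP}, {MAX_QUERY_BP}]"
        )
    query = reduce_region(scores, chrom, start, end)
    if index is None:
        index = build_search_index(scores, size, stride=stride)
    threshold = similarity_threshold(index, query)
    qv = query.flat()
    hits = []
    for bv in index:
        if bv.chrom == chrom and bv.start < end and start < bv.end:
            continue  # overlaps the query itself
        dist = float(np.linalg.norm(bv.flat() - qv))
        if dist <= threshold:
            hits.append((dist, bv))
    hits.sort(key=lambda t: (t[0], t[1].chrom, t[1].start))
    regions = [
        Region(bv.chrom, bv.start, bv.end, dist, rank=i + 1)
        for i, (dist, bv) in enumerate(hits[:max_hits])
    ]
    return RegionSet(regions=regions, provenance="similarity")
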