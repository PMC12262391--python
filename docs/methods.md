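# Methods

## Data model

The unit of analysis is a fixed-width genomic bin (default 200 bp, the
native resolution of ChromHMM-style segmentations; any resolution is
accepted). A dataset is an `m × T` matrix of categorical state indices —
`m` biosamples by `T` bins — together with a state model (the alphabet of
`n` states, display metadata, and an optional designated quiescent state).
All coordinates are 0-based half-open; bin `b` covers
`[b·bin_size, (b+1)·bin_size)`. Chromosomes whose length is not a multiple
of the bin size are truncated at the final partial bin (logged). Bins left
uncovered by a segmentation file are filled with the quiescent state when
one is designated, otherwise reading fails: ChromHMM segmentations are
genome-covering, so gaps indicate assembly gaps or truncated input, and
silently inventing a state would be worse than refusing.

## Saliency metrics

All scores are in bits (base-2 logarithms) and use the convention
`0·log2(0/q) = 0`.

**S1 (relative entropy).** With `p_i` the observed frequency of state `i`
at a bin (across biosamples) and `q_i` its genome-wide expected frequency,
`S1_i = p_i log2(p_i/q_i)`. The per-bin total is `KL(p‖q)`: non-negative
when the background derives from the same matrix, zero exactly when the
bin's state distribution matches the background. Per-state entries may be
negative (a state that is *under*-saliently common at a bin); they are
reported raw, not clipped.

**S2 (state co-occurrence).** The per-bin distribution of state pairs over
*ordered distinct* biosample pairs, `p_ij = #{(α,β): α≠β, s_α=i, s_β=j} /
(m(m−1))`, is scored against the genome-wide mean pair distribution:
`S2_i = Σ_j p_ij log2(p_ij/q_ij)`. Self-pairs are excluded because a
biosample trivially co-occurs with itself and their inclusion would only
inflate diagonal mass; the ordered-pair convention keeps the normalizer
simple and makes `p` and `q` symmetric automatically.

**S3 (state and biosample co-occurrence).** The background is resolved per
ordered biosample pair: `q_ij^{αβ}` is the fraction of (bin, pair) events
in which biosample α shows `i` while β shows `j`. At a bin, each of the
`m(m−1)` pair events carries mass `1/(m(m−1))`, so
`S3_i = Σ_j Σ_{αβ} p_ij^{αβ} log2(p_ij^{αβ}/q_ij^{αβ})` reduces to a sum of
`(1/M)·log2(T/n_{αβ}(s_α,s_β))` terms. The implementation streams over
biosample pairs, holding only an `n²m²` background tensor and a `T×n`
output; per-bin joint tensors are never materialized genome-wide.

A useful identity, and the property test we use in place of a naive
"S2 = S3 under exchangeability" expectation: when all biosample pairs share
one pair background (`q_ij^{αβ} = q_ij/M`), the fine-grained per-bin KL
decomposes exactly as `S3_total = S2_total + H(p_pair)`, where `H` is the
entropy of the bin's pair distribution. On i.i.d. synthetic data this holds
to within the per-pair background sampling noise.

**Backgrounds.** Expected frequencies are computed genome-wide over *all*
bins, including all-quiescent ones (the quiescent exclusion applies only to
the differential null, below). An optional pseudocount (default 0) guards
`log(·/0)` when scoring one dataset against another dataset's background.

**Consensus vs dominant.** The consensus epigenome takes the argmax of
per-state saliency at each bin; the dominant track takes the argmax of
`p_i`. Ties break to the lowest state index and are logged. Because rare
states carry large per-observation weight, a rare regulatory state present
in a minority of biosamples can beat a quiescent majority in the consensus
while being invisible in the dominant call — the qualitative divergence the
package's acceptance checks reproduce on planted rare-state islands.

## Pairwise differential analysis

For two disjoint biosample groups A and B, per-bin group saliency vectors
`s^A, s^B` are S1 scores computed with each group's own `p` against a
single background pooled over A ∪ B (so that differences reflect the
groups, not their backgrounds). The signed squared Euclidean distance is

    SSED = sign(Σ_i s^A_i − Σ_i s^B_i) · Σ_i (s^A_i − s^B_i)²

with exact total ties taking the positive sign (deterministic; affects only
exactly-tied bins, and makes SSED symmetric rather than antisymmetric at
those bins).

**Null model.** Group labels are permuted uniformly at random preserving
group sizes (default 100 permutations; 50 suffice in all our simulations),
SSED is recomputed genome-wide per permutation, and bins where *every*
pooled biosample is quiescent are excluded to avoid a structural zero
spike. From the pooled permuted scores, 11 subsamples of up to 100,000
values (both configurable) are each fitted with a three-parameter
generalized normal density `f(x) ∝ exp(−(|x−μ|/α)^β)` by maximum
likelihood; the fit with the median negative log-likelihood is the null.
The MLE is initialized by moments (μ from the median, β by inverting the
excess-kurtosis relation, α from `var = α²Γ(3/β)/Γ(1/β)`) and optimized by
L-BFGS-B over `(μ, log α, log β)` with β bounded in [0.2, 10], followed by
a gradient-free Nelder–Mead polish because the `|x−μ|^β` cusp is
non-differentiable at μ for β < 1; the scale is kept within 12 decades of
its moment estimate so heavy point masses cannot collapse α to zero.

**Inference.** p-values are two-sided under the symmetric fitted null,
`p = Γ_upper(1/β, (|x−μ|/α)^β)/Γ(1/β)`; direction is carried by the sign.
Excluded bins get p = 1 and are flagged. Benjamini–Hochberg runs over
non-excluded bins only. Top differential regions apply the greedy
recommender to `|SSED|` (default 25 kb, top 100) and label each region with
its signed aggregate, direction, and the state with the largest summed
squared saliency difference.

**Calibration.** Under exchangeable groups (5 vs 5 biosamples, 50,000 i.i.d.
bins with the default 15-state frequency spectrum) the measured fraction of
non-excluded bins at p ≤ 0.05 falls within three binomial standard errors
of 0.05. Deeper in the tail the parametric approximation frays: at nominal
0.01 the measured fraction is ≈ 0.012, slightly anti-conservative, because
a three-parameter unimodal density cannot exactly represent the discrete,
zero-inflated SSED distribution that small groups produce. The acceptance
script reports both fractions. With very few biosamples and very few states
SSED is supported on a handful of atoms and no continuous null can place
tail thresholds reliably; the defaults below avoid that regime.

## Regions and similarity search

**Recommendation.** Seeds are taken at the highest-scoring available bin
(ties → lowest coordinate); a window grows one bin at a time toward
whichever side adds the larger score (ties → right), with chromosome edges
and previously claimed bins blocking extension, until it spans the target
size (default 10 kb single-group, 25 kb pairwise). Claimed bins are then
unavailable; a seed whose window cannot reach full size is discarded. The
loop stops at k regions (default 100) or when no strictly positive seed
remains, and regions are ranked by aggregate score. On unimodal tracks the
rank-1 region provably coincides with the maximum-sum window; in general
the greedy rule is not globally optimal, which we accept for determinism
and speed.

**Block reduction.** Any region spanning `25·c` bins (`c ≥ 1`; 5 kb to
100 kb at 200-bp bins) is reduced to exactly 25 blocks; each block's value
for state `i` is the *maximum* per-state saliency over its `c` bins.
Per-state max-pooling (rather than pooling totals) preserves which states
are strongly present anywhere in the block — the identity of the pattern,
not just its intensity — and confers tolerance to sub-block shifts in
pattern alignment, which is the point of the scale normalization.

**Search.** The genome is tiled with windows of the query's size at a
stride of half the window (rounded to a bin multiple) — a compromise
between alignment tolerance and index size. Windows overlapping the query
are excluded. Distances are Euclidean between flattened 25×n block
matrices. The similarity threshold is half the mode of the query-to-genome
distance distribution, the mode estimated as the midpoint of the tallest
Freedman–Diaconis histogram bin (ties → lower bin); with fewer than 10
windows the histogram is unreliable and half the median is used, with a
warning. Hits at or below the threshold are returned in ascending distance
order (ties → coordinate order), up to 5 by default. The distance
distribution is computed per query rather than precomputed over all window
pairs; at desk scale the index is rebuilt per call.

## Synthetic data

The generator emulates the input side of a segmentation pipeline: i.i.d.
per-(biosample, bin) background draws from a target state-frequency vector,
optionally with geometric run lengths (mean run length parameter) to mimic
ChromHMM segment structure, then deterministic planted features. The
default conditions mirror published chromatin-state maps: 15 states, a
quiescent state at genome-wide frequency 0.8, and the remaining 0.2 spread
geometrically (ratio 0.7) so that a few states are common and most are
rare. Defaults of 10 biosamples and 200-bp bins; sizes are set per
experiment. Planted recurrent-pattern copies are placed at deterministic
positions aligned to half the pattern width, so every copy falls on the
search index's default tiling grid.

What the generator does *not* emulate: correlation of states across
biosamples at a position (real biosamples share biology; i.i.d. draws make
every position exchangeable), spatial autocorrelation beyond optional
geometric runs, chromosome-scale domain structure, and assembly gaps.
Passing tests therefore demonstrate correctness of the computations and
calibration under exchangeability — not performance on correlated real
epigenomes, where the permutation null remains valid by construction but
effect sizes and backgrounds differ.

## Problem sizes and numerical choices

The test suite and acceptance script run on simulations of 10⁴–10⁵ bins
and 5–10 biosamples — sizes chosen so the full pipeline (including 50
permutations and 100,000-sample null fits) completes in seconds while
leaving every statistical check well-powered. Tolerances: vectorized-vs-
brute-force comparisons at 1e-9 (pure floating-point reordering);
generalized-normal recovery at 5% relative (1-e5 samples; 10% for the
heavy-tailed Laplace case, whose shape estimate is noisier); calibration at
three binomial standard errors. Degenerate inputs are errors, not guesses:
constant samples cannot be fitted, empty groups are rejected, misaligned
intervals and unknown state labels name the offending file and coordinate.

## Known limitations

* S2 materializes a `T×n×n` pair-count array; fine to ~10⁵ bins at 15–25
  states, but a chunked variant would be needed at genome scale (15 M bins).
* The parametric null's far tail is approximate (see calibration above);
  empirical permutation p-values are exact but far costlier at genome scale.
* The greedy recommender and half-window tiling are deterministic
  heuristics; neither is globally optimal, and search recall degrades for
  patterns that fall between tiles and lack internal repetition for
  max-pooling to absorb.
* `m(m−1)` pair enumeration makes S3 quadratic in biosamples; practical to
  a few hundred biosamples, not thousands, without further streaming.
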