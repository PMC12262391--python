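"""Synthetic multi-biosample chromatin-state annotations with planted structure.

The generator emulates the input a ChromHMM-style segmentation pipeline
produces: an ``m x T`` matrix of categorical state labels at a fixed bin
resolution.  Background labels are drawn i.i.d. per (biosample, bin) from
target genome-wide state frequencies (optionally with geometric run lengths
to mimic segment structure); planted features then overwrite their bins
deterministically:

* ``recurrent_pattern`` — the same multi-biosample state block copied at
  several loci (exercises similarity search);
* ``group_differential`` — a region where one biosample group carries one
  state and the other group another (exercises pairwise analysis);
* ``rare_state_island`` — bins where a subset of biosamples shares a
  globally rare state (exercises consensus-vs-dominant divergence).

Everything is seed-deterministic; matrices can also be written as BED
segmentation files to exercise the full read path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .core import AnnotationMatrix, GenomeBins, StateModel

__all__ = [
    "PlantedFeature",
    "SimulationSpec",
    "default_state_model",
    "simulate_matrix",
    "plant_recurrent_pattern",
    "plant_group_differential",
    "plant_rare_state_island",
]

_CANONICAL_STATES = [
    ("TssA", "#ff0000"),
    ("Enh", "#ffc34d"),
    ("Tx", "#008000"),
    ("ReprPC", "#808080"),
    ("Het", "#8a91d0"),
    ("Biv", "#cd5c5c"),
]


def default_state_model(n_states: int = 15) -> StateModel:
    """A small ChromHMM-flavoured alphabet whose last state is quiescent."""
    if n_states < 2:
        raise ValueError("need at least 2 states")
    named = _CANONICAL_STATES[: n_states - 1]
    labels = [name for name, _ in named]
    colors = [col for _, col in named]
    while len(labels) < n_states - 1:
        labels.append(f"State{len(labels) + 1}")
        colors.append("#000000")
    labels.append("Quies")
    colors.append("#ffffff")
    return StateModel(
        labels=tuple(labels), colors=tuple(colors), quiescent_index=n_states - 1
    )


@dataclass(frozen=True)
class PlantedFeature:
    """A deterministic overwrite of a span of bins.

    ``pattern`` is ``rows x width`` of state indices; ``rows`` selects the
    biosample rows it applies to (all rows when ``None``).  ``positions``
    are the start bins of each copy.
    """

    kind: str
    positions: tuple[int, ...]
    pattern: np.ndarray
    rows: Optional[tuple[int, ...]] = None

    def __post_init__(self):
        if self.kind not in {"recurrent_pattern", "group_differential", "rare_state_island"}:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        object.__setattr__(self, "pattern", np.asarray(self.pattern, dtype=np.int16))
        if self.pattern.ndim != 2:
            raise ValueError("pattern must be 2-D (rows x bins)")
        object.__setattr__(self, "positions", tuple(int(p) for p in self.positions))

    @property
    def width(self) -> int:
        return self.pattern.shape[1]

    def spans(self) -> list[tuple[int, int]]:
        return [(p, p + self.width) for p in self.positions]


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of a synthetic dataset; same spec + seed => same matrix."""

    n_states: int = 15
    m_biosamples: int = 10
    n_bins: int = 10_000
    bin_size: int = 200
    state_freqs: Optional[tuple[float, ...]] = None
    seed: int = 0
    plants: tuple[PlantedFeature, ...] = field(default_factory=tuple)
    mean_run_length: Optional[float] = None
    chrom: str = "chrS"

    def resolved_freqs(self) -> np.ndarray:
        if self.state_freqs is None:
            # emulate a 15-state-style frequency spectrum: the quiescent
            # state covers ~80% of the genome and the non-quiescent states
            # decay geometrically (a few common, many rare)
            n = self.n_states
            w = 0.7 ** np.arange(n - 1)
            f = np.concatenate([0.2 * w / w.sum(), [0.8]])
            return f / f.sum()
        f = np.asarray(self.state_freqs, dtype=float)
        if f.shape != (self.n_states,) or np.any(f < 0):
            raise ValueError("state_freqs must be non-negative with one entry per state")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("state_freqs must sum to 1")
        return f

    def validate(self) -> None:
        self.resolved_freqs()
        spans = []
        for plant in self.plants:
            rows = plant.rows if plant.rows is not None else tuple(range(self.m_biosamples))
            if plant.pattern.size and (plant.pattern.min() < 0 or plant.pattern.max() >= self.n_states):
                raise ValueError("planted pattern references an invalid state")
            if plant.rows is not None and plant.pattern.shape[0] != len(plant.rows):
                raise ValueError("pattern rows do not match the row selection")
            if plant.rows is None and plant.pattern.shape[0] != self.m_biosamples:
                raise ValueError("pattern rows do not match m_biosamples")
            if any(r < 0 or r >= self.m_biosamples for r in rows):
                raise ValueError("planted rows out of range")
            for s, e in plant.spans():
                if s < 0 or e > self.n_bins:
                    raise ValueError(f"planted span [{s}, {e}) outside the genome")
                for ps, pe in spans:
                    if s < pe and ps < e:
                        raise ValueError(f"planted spans [{ps},{pe}) and [{s},{e}) overlap")
                spans.append((s, e))


def simulate_matrix(spec: SimulationSpec, model: Optional[StateModel] = None) -> AnnotationMatrix:
    """Draw the background and apply plants; deterministic in ``spec.seed``."""
    spec.validate()
    if model is None:
        model = default_state_model(spec.n_states)
    if model.n_states != spec.n_states:
        raise ValueError("state model size does not match spec.n_states")
    rng = np.random.default_rng(spec.seed)
    freqs = spec.resolved_freqs()
    m, T = spec.m_biosamples, spec.n_bins
    if spec.mean_run_length is None or spec.mean_run_length <= 1:
        states = rng.choice(spec.n_states, size=(m, T), p=freqs).astype(np.int16)
    else:
        states = np.empty((m, T), dtype=np.int16)
        p_end = 1.0 / spec.mean_run_length
        for row in range(m):
            pos = 0
            while pos < T:
                run = int(rng.geometric(p_end))
                states[row, pos : pos + run] = rng.choice(spec.n_states, p=freqs)
                pos += run
    for plant in spec.plants:
        rows = list(plant.rows) if plant.rows is not None else list(range(m))
        for s, e in plant.spans():
            states[np.ix_(rows, range(s, e))] = plant.pattern
    bins = GenomeBins.single(T, spec.bin_size, spec.chrom)
    ids = [f"sample{i:03d}" for i in range(m)]
    return AnnotationMatrix(states, ids, bins, model)


def _placements(spec: SimulationSpec, width: int, n_copies: int, min_gap: int) -> list[int]:
    """Deterministic, evenly spaced non-overlapping start bins avoiding existing plants."""
    taken = [span for plant in spec.plants for span in plant.spans()]
    # align copy starts to half the pattern width so that every copy falls on
    # the default half-window tiling grid of the similarity-search index
    align = max(1, width // 2)
    stride = max(width + min_gap, spec.n_bins // (n_copies + 1))
    stride = (stride + align - 1) // align * align
    positions = []
    pos = (min_gap + align - 1) // align * align
    while len(positions) < n_copies and pos + width <= spec.n_bins:
        clash = any(pos < e and s < pos + width for s, e in taken)
        if not clash:
            positions.append(pos)
            taken.append((pos, pos + width))
            pos += stride
        else:
            pos += align
    if len(positions) < n_copies:
        raise ValueError(
            f"could not place {n_copies} copies of width {width} with gap {min_gap} "
            f"in {spec.n_bins} bins"
        )
    return positions


def plant_recurrent_pattern(
    spec: SimulationSpec,
    pattern: np.ndarray,
    n_copies: int,
    min_gap: int,
) -> SimulationSpec:
    """Add ``n_copies`` of the same multi-biosample pattern at deterministic loci."""
    pattern = np.asarray(pattern, dtype=np.int16)
    positions = _placements(spec, pattern.shape[1], n_copies, min_gap)
    feature = PlantedFeature(
        kind="recurrent_pattern", positions=tuple(positions), pattern=pattern
    )
    out = replace(spec, plants=spec.plants + (feature,))
    out.validate()
    return out


def plant_group_differential(
    spec: SimulationSpec,
    group_a: Sequence[int],
    group_b: Sequence[int],
    start_bin: int,
    width: int,
    state_a: int,
    state_b: int,
) -> SimulationSpec:
    """Plant a region where group A carries ``state_a`` and group B ``state_b``."""
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b or set(group_a) & set(group_b):
        raise ValueError("groups must be non-empty and disjoint")
    rows = tuple(group_a + group_b)
    pattern = np.empty((len(rows), width), dtype=np.int16)
    pattern[: len(group_a), :] = state_a
    pattern[len(group_a) :, :] = state_b
    feature = PlantedFeature(
        kind="group_differential", positions=(int(start_bin),), pattern=pattern, rows=rows
    )
    out = replace(spec, plants=spec.plants + (feature,))
    out.validate()
    return out


def plant_rare_state_island(
    spec: SimulationSpec,
    positions: Sequence[int],
    rare_state: int,
    carrier_rows: Sequence[int],
    common_state: Optional[int] = None,
    width: int = 1,
) -> SimulationSpec:
    """Plant bins where ``carrier_rows`` share a rare state and the rest a common one.

    The common state defaults to the last (quiescent) state, mimicking loci
    where a regulatory state appears in a minority of biosamples on an
    otherwise quiescent background.
    """
    if common_state is None:
        common_state = spec.n_states - 1
    carriers = set(int(r) for r in carrier_rows)
    rows = tuple(range(spec.m_biosamples))
    pattern = np.full((spec.m_biosamples, width), common_state, dtype=np.int16)
    pattern[sorted(carriers), :] = rare_state
    feature = PlantedFeature(
        kind="rare_state_island",
        positions=tuple(int(p) for p in positions),
        pattern=pattern,
        rows=rows,
    )
    out = replace(spec, plants=spec.plants + (feature,))
    out.validate()
    return out
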