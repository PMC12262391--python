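"""Core domain types: state alphabets, genome binning, annotation matrices, region sets.

The central object is the :class:`AnnotationMatrix`: an ``m x T`` table of
categorical chromatin-state indices, one row per biosample and one column per
fixed-width genomic bin (200 bp by default, the resolution of ChromHMM-style
segmentations).  All coordinates are 0-based half-open (BED convention); the
bin holding base-pair position ``x`` has index ``x // bin_size``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "StateModel",
    "GenomeBins",
    "AnnotationMatrix",
    "Region",
    "RegionSet",
]


@dataclass(frozen=True)
class StateModel:
    """The alphabet of ``n`` chromatin states.

    Parameters
    ----------
    labels
        Ordered, unique state identifiers (e.g. ``"1_TssA"`` or ``"E1"``).
    abbreviations
        Short display names, one per state; defaults to the labels.
    colors
        Hex color strings for display, one per state.
    quiescent_index
        Index of the designated low-signal quiescent state, if any.  The
        quiescent state fills segmentation gaps on read and defines which
        bins are excluded from the differential null fit.
    aliases
        Optional mapping of alternative spellings to canonical labels, so
        that both ``"E7"``-style and ``"7_Enh"``-style files resolve to the
        same state.
    """

    labels: tuple[str, ...]
    abbreviations: tuple[str, ...] = ()
    colors: tuple[str, ...] = ()
    quiescent_index: Optional[int] = None
    aliases: dict = field(default_factory=dict)

    def __post_init__(self):
        labels = tuple(str(x) for x in self.labels)
        object.__setattr__(self, "labels", labels)
        if len(labels) == 0:
            raise ValueError("StateModel needs at least one state")
        if len(set(labels)) != len(labels):
            raise ValueError("state labels must be unique")
        abbrev = tuple(self.abbreviations) or labels
        if len(abbrev) != len(labels):
            raise ValueError("abbreviations must match labels in length")
        object.__setattr__(self, "abbreviations", abbrev)
        colors = tuple(self.colors)
        if colors and len(colors) != len(labels):
            raise ValueError("colors must match labels in length")
        object.__setattr__(self, "colors", colors)
        if self.quiescent_index is not None:
            if not (0 <= self.quiescent_index < len(labels)):
                raise ValueError(
                    f"quiescent_index {self.quiescent_index} out of range "
                    f"for {len(labels)} states"
                )

    @property
    def n_states(self) -> int:
        return len(self.labels)

    def state_index(self, label: str) -> int:
        """Resolve a label, abbreviation or alias to its state index."""
        label = str(label)
        try:
            return self.labels.index(label)
        except ValueError:
            pass
        if label in self.aliases:
            return self.labels.index(self.aliases[label])
        try:
            return self.abbreviations.index(label)
        except ValueError:
            raise KeyError(f"unknown state label {label!r}")

    def to_json(self, path) -> None:
        payload = {
            "labels": list(self.labels),
            "abbreviations": list(self.abbreviations),
            "colors": list(self.colors),
            "quiescent_index": self.quiescent_index,
            "aliases": dict(self.aliases),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "StateModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            labels=tuple(payload["labels"]),
            abbreviations=tuple(payload.get("abbreviations") or ()),
            colors=tuple(payload.get("colors") or ()),
            quiescent_index=payload.get("quiescent_index"),
            aliases=payload.get("aliases") or {},
        )


@dataclass(frozen=True)
class GenomeBins:
    """Fixed-width binning of one or more chromosomes.

    Bin ``b`` of a chromosome covers ``[b * bin_size, (b+1) * bin_size)``.
    Global bin indices concatenate chromosomes in ``chrom_names`` order.
    """

    chrom_names: tuple[str, ...]
    bin_size: int
    bins_per_chrom: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "chrom_names", tuple(self.chrom_names))
        object.__setattr__(self, "bins_per_chrom", tuple(int(b) for b in self.bins_per_chrom))
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if len(self.chrom_names) != len(self.bins_per_chrom):
            raise ValueError("chrom_names and bins_per_chrom lengths differ")
        if any(b < 0 for b in self.bins_per_chrom):
            raise ValueError("negative bin count")

    @property
    def total_bins(self) -> int:
        return int(sum(self.bins_per_chrom))

    @property
    def offsets(self) -> np.ndarray:
        """Global bin index of the first bin of each chromosome."""
        return np.concatenate([[0], np.cumsum(self.bins_per_chrom)]).astype(np.int64)

    def chrom_slice(self, chrom: str) -> slice:
        i = self.chrom_names.index(chrom)
        off = self.offsets
        return slice(int(off[i]), int(off[i + 1]))

    def bin_location(self, global_bin: int) -> tuple[str, int, int]:
        """Return ``(chrom, start_bp, end_bp)`` for a global bin index."""
        off = self.offsets
        if not (0 <= global_bin < self.total_bins):
            raise IndexError(f"bin {global_bin} out of range")
        i = int(np.searchsorted(off, global_bin, side="right") - 1)
        local = global_bin - off[i]
        return self.chrom_names[i], int(local * self.bin_size), int((local + 1) * self.bin_size)

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global bin index containing base-pair position ``pos``."""
        i = self.chrom_names.index(chrom)
        local = pos // self.bin_size
        if not (0 <= local < self.bins_per_chrom[i]):
            raise IndexError(f"{chrom}:{pos} outside binned range")
        return int(self.offsets[i] + local)

    @classmethod
    def single(cls, n_bins: int, bin_size: int = 200, chrom: str = "chrS") -> "GenomeBins":
        return cls(chrom_names=(chrom,), bin_size=bin_size, bins_per_chrom=(n_bins,))


class AnnotationMatrix:
    """Chromatin-state labels for ``m`` biosamples over ``total_bins`` bins.

    ``states[s, b]`` is the state index of biosample ``s`` at global bin ``b``.
    """

    def __init__(
        self,
        states: np.ndarray,
        biosample_ids: Sequence[str],
        bins: GenomeBins,
        model: StateModel,
    ):
        states = np.asarray(states)
        if states.ndim != 2:
            raise ValueError("states must be 2-D (biosamples x bins)")
        if states.shape[0] < 1:
            raise ValueError("need at least one biosample")
        if states.shape[1] != bins.total_bins:
            raise ValueError(
                f"states has {states.shape[1]} bins but GenomeBins has {bins.total_bins}"
            )
        if len(biosample_ids) != states.shape[0]:
            raise ValueError("biosample_ids length must match number of rows")
        if states.size and (states.min() < 0 or states.max() >= model.n_states):
            bad = states[(states < 0) | (states >= model.n_states)].flat[0]
            raise ValueError(f"state index {bad} outside [0, {model.n_states})")
        self.states = states.astype(np.int16, copy=False)
        self.biosample_ids = list(biosample_ids)
        self.bins = bins
        self.model = model

    @property
    def m(self) -> int:
        return self.states.shape[0]

    @property
    def total_bins(self) -> int:
        return self.states.shape[1]

    @property
    def n_states(self) -> int:
        return self.model.n_states

    def subset(self, rows: Iterable[int]) -> "AnnotationMatrix":
        rows = list(rows)
        return AnnotationMatrix(
            self.states[rows, :],
            [self.biosample_ids[r] for r in rows],
            self.bins,
            self.model,
        )

    def state_counts(self) -> np.ndarray:
        """Per-bin state occupancy: ``counts[b, i]`` biosamples in state i at bin b."""
        n = self.n_states
        T = self.total_bins
        flat = (self.states.astype(np.int64) + np.arange(T, dtype=np.int64)[None, :] * n).ravel()
        return np.bincount(flat, minlength=T * n).reshape(T, n).astype(np.int32)

    def __repr__(self):
        return (
            f"AnnotationMatrix(m={self.m}, bins={self.total_bins}, "
            f"n_states={self.n_states}, bin_size={self.bins.bin_size})"
        )


@dataclass(frozen=True)
class Region:
    chrom: str
    start: int
    end: int
    score: float
    rank: int
    name: str = ""

    def overlaps(self, other: "Region") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass
class RegionSet:
    """Ranked genomic intervals: recommendations, differential hits or search matches."""

    regions: list[Region]
    provenance: str = "recommendation"

    def __post_init__(self):
        allowed = {"recommendation", "differential", "similarity"}
        if self.provenance not in allowed:
            raise ValueError(f"provenance must be one of {sorted(allowed)}")
        self.regions = sorted(self.regions, key=lambda r: r.rank)

    def __len__(self):
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def __getitem__(self, i):
        return self.regions[i]
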