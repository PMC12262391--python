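"""Reading and writing genome-browser formats.

Segmentations come in as BED4+ files (chrom, start, end, state label), one
file per biosample, plain or gzipped.  Score tracks go out as per-state TSV
or total-saliency bedGraph; region sets as BED6.  All coordinates are 0-based
half-open.
"""

from __future__ import annotations

import logging
import os
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import AnnotationMatrix, GenomeBins, Region, RegionSet, StateModel
from .saliency import ScoreTrack

__all__ = [
    "read_segmentations",
    "write_segmentations",
    "write_score_track",
    "read_score_track",
    "write_regions",
]

log = logging.getLogger(__name__)

_BED_COLS = ["chrom", "start", "end", "state"]


def _read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2, 3],
        names=_BED_COLS,
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "state": str},
    )
    if (df["end"] <= df["start"]).any():
        bad = df[df["end"] <= df["start"]].iloc[0]
        raise ValueError(f"{path}: empty or inverted interval {bad.chrom}:{bad.start}-{bad.end}")
    return df


def read_segmentations(
    paths: Sequence,
    bin_size: int,
    model: StateModel,
    fill_state: Optional[int] = None,
) -> AnnotationMatrix:
    """Read per-biosample BED4 segmentations into an annotation matrix.

    The chromosome universe is the union across files, ordered by first
    appearance in the first file (then subsequent files).  Chromosome lengths
    are the maximum interval end seen; a final partial bin (length not a
    multiple of ``bin_size``) is truncated with a log message.  Bins left
    uncovered by a file are filled with ``fill_state`` (default: the model's
    quiescent state) or raise if no fill state is available.
    """
    if not paths:
        raise ValueError("no segmentation files given")
    frames = [_read_bed(p) for p in paths]

    chrom_order: list[str] = []
    chrom_len: dict[str, int] = {}
    for df in frames:
        for chrom in df["chrom"]:
            if chrom not in chrom_len:
                chrom_order.append(chrom)
                chrom_len[chrom] = 0
        ends = df.groupby("chrom")["end"].max()
        for chrom, end in ends.items():
            chrom_len[chrom] = max(chrom_len[chrom], int(end))

    bins_per_chrom = []
    for chrom in chrom_order:
        length = chrom_len[chrom]
        if length % bin_size:
            log.info(
                "%s length %d is not a multiple of %d bp; truncating the final partial bin",
                chrom, length, bin_size,
            )
        bins_per_chrom.append(length // bin_size)
    bins = GenomeBins(tuple(chrom_order), bin_size, tuple(bins_per_chrom))

    if fill_state is None:
        fill_state = model.quiescent_index

    m = len(paths)
    states = np.full((m, bins.total_bins), -1, dtype=np.int16)
    for row, (path, df) in enumerate(zip(paths, frames)):
        for chrom, sub in df.groupby("chrom", sort=False):
            sl = bins.chrom_slice(chrom)
            n_bins = sl.stop - sl.start
            track = states[row, sl]
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            bad_start = starts % bin_size != 0
            # an unaligned end is tolerated only at the chromosome terminus
            bad_end = (ends % bin_size != 0) & (ends != chrom_len[chrom])
            if bad_start.any() or bad_end.any():
                i = int(np.flatnonzero(bad_start | bad_end)[0])
                raise ValueError(
                    f"{path}: interval {chrom}:{starts[i]}-{ends[i]} not aligned to "
                    f"bin_size={bin_size}"
                )
            order = np.argsort(starts)
            prev_end = -1
            for s, e, label in zip(starts[order], ends[order], sub["state"].to_numpy()[order]):
                if s < prev_end:
                    raise ValueError(f"{path}: overlapping intervals on {chrom} at {s}")
                prev_end = e
                try:
                    idx = model.state_index(label)
                except KeyError:
                    raise ValueError(f"{path}: unknown state label {label!r}") from None
                track[s // bin_size : min(e // bin_size, n_bins)] = idx
    uncovered = states < 0
    if uncovered.any():
        if fill_state is None:
            row, b = np.argwhere(uncovered)[0]
            chrom, s, e = bins.bin_location(int(b))
            raise ValueError(
                f"{paths[row]}: bin {chrom}:{s}-{e} is uncovered and no fill state "
                "is configured (designate a quiescent state or pass fill_state)"
            )
        states[uncovered] = fill_state
    ids = [os.path.basename(str(p)).split(".")[0] for p in paths]
    return AnnotationMatrix(states, ids, bins, model)


def write_segmentations(matrix: AnnotationMatrix, out_dir, gzip: bool = False) -> list[str]:
    """Write one BED4 file per biosample, merging runs of equal states."""
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    bs = matrix.bins.bin_size
    for row, sample in enumerate(matrix.biosample_ids):
        records = []
        for ci, chrom in enumerate(matrix.bins.chrom_names):
            sl = matrix.bins.chrom_slice(chrom)
            track = matrix.states[row, sl]
            if track.size == 0:
                continue
            breaks = np.flatnonzero(np.diff(track)) + 1
            starts = np.concatenate([[0], breaks])
            ends = np.concatenate([breaks, [track.size]])
            for s, e in zip(starts, ends):
                records.append((chrom, int(s) * bs, int(e) * bs, matrix.model.labels[track[s]]))
        ext = ".bed.gz" if gzip else ".bed"
        path = os.path.join(out_dir, f"{sample}{ext}")
        pd.DataFrame(records, columns=_BED_COLS).to_csv(path, sep="\t", header=False, index=False)
        paths.append(path)
    return paths


def _bin_coordinates(bins: GenomeBins) -> pd.DataFrame:
    chroms = np.repeat(np.array(bins.chrom_names, dtype=object), bins.bins_per_chrom)
    local = np.concatenate([np.arange(nb, dtype=np.int64) for nb in bins.bins_per_chrom]) \
        if bins.total_bins else np.array([], dtype=np.int64)
    starts = local * bins.bin_size
    return pd.DataFrame({"chrom": chroms, "start": starts, "end": starts + bins.bin_size})


def write_score_track(scores: ScoreTrack, path, format: str = "tsv", merge: bool = True) -> None:
    """Write a score track as per-state TSV or total-saliency bedGraph.

    TSV: chrom, start, end, then one column per state (model order), with a
    commented header.  bedGraph: chrom, start, end, total saliency; adjacent
    bins with equal values are merged when ``merge`` is true.
    """
    coords = _bin_coordinates(scores.bins)
    if format == "tsv":
        df = pd.concat(
            [coords, pd.DataFrame(scores.per_state, columns=list(scores.model.labels))],
            axis=1,
        )
        with open(path, "w") as fh:
            fh.write("#" + "\t".join(df.columns) + "\n")
            df.to_csv(fh, sep="\t", header=False, index=False, float_format="%.6f")
    elif format == "bedgraph":
        df = coords.assign(value=scores.total)
        if merge and len(df):
            same = (
                (df["value"].values[1:] == df["value"].values[:-1])
                & (df["chrom"].values[1:] == df["chrom"].values[:-1])
                & (df["start"].values[1:] == df["end"].values[:-1])
            )
            group = np.concatenate([[0], np.cumsum(~same)])
            df = df.groupby(group).agg(
                chrom=("chrom", "first"), start=("start", "first"),
                end=("end", "last"), value=("value", "first"),
            )
        df.to_csv(path, sep="\t", header=False, index=False, float_format="%.6f")
    else:
        raise ValueError(f"unknown score format {format!r}; use 'tsv' or 'bedgraph'")


def read_score_track(path, model: StateModel, metric: str = "S1") -> ScoreTrack:
    """Read a per-state TSV written by :func:`write_score_track` back into a track."""
    df = pd.read_csv(path, sep="\t", comment=None, header=0)
    df.columns = [c.lstrip("#") for c in df.columns]
    missing = [lab for lab in model.labels if lab not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing state columns {missing}")
    chrom_order = list(dict.fromkeys(df["chrom"]))
    bin_size = int((df["end"] - df["start"]).iloc[0])
    bins_per_chrom = tuple(int((df["chrom"] == c).sum()) for c in chrom_order)
    bins = GenomeBins(tuple(chrom_order), bin_size, bins_per_chrom)
    per_state = df[list(model.labels)].to_numpy(dtype=float)
    return ScoreTrack(per_state=per_state, metric=metric, bins=bins, model=model)


def write_regions(regions: RegionSet, path) -> None:
    """Write a region set as BED6 (name = rank or provided name), sorted by rank."""
    rows = [
        (r.chrom, r.start, r.end, r.name or str(r.rank), f"{r.score:.6g}", ".")
        for r in sorted(regions.regions, key=lambda r: r.rank)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_regions(path, provenance: str = "recommendation") -> RegionSet:
    """Read a BED6 file written by :func:`write_regions`."""
    try:
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "name", "score", "strand"])
    except pd.errors.EmptyDataError:
        return RegionSet(regions=[], provenance=provenance)
    regions = [
        Region(chrom=row.chrom, start=int(row.start), end=int(row.end),
               score=float(row.score), rank=i + 1, name=str(row.name))
        for i, row in enumerate(df.itertuples())
    ]
    return RegionSet(regions=regions, provenance=provenance)
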