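"""Track-versus-track comparison: correlation, density grids, region reports.

All comparisons restrict to the positions defined in every input track
("common positions"), mirroring how coverage and occupancy maps with
different undefined sets must be compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .track_io import RegionAnnotation, Track


@dataclass
class CorrelationResult:
    r: float
    n_positions: int


@dataclass
class DensityGrid:
    """2-D base-pair density histogram of one track against another."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray

    @property
    def n_positions(self) -> int:
        return int(self.counts.sum())


def common_positions(tracks: list[Track]) -> dict[str, np.ndarray]:
    """Boolean mask per chromosome of positions defined in every track."""
    if not tracks:
        raise ValueError("no tracks given")
    chroms = set(tracks[0].chromosomes)
    for t in tracks[1:]:
        if set(t.chromosomes) != chroms or t.lengths != tracks[0].lengths:
            raise ValueError("tracks do not share the genome frame")
    masks = {}
    total = 0
    for chrom in tracks[0].chromosomes:
        m = np.ones(tracks[0].lengths[chrom], dtype=bool)
        for t in tracks:
            m &= t.mask[chrom]
        masks[chrom] = m
        total += int(m.sum())
    if total == 0:
        raise ValueError("no positions are defined in all tracks")
    return masks


def _paired_values(a: Track, b: Track) -> tuple[np.ndarray, np.ndarray]:
    masks = common_positions([a, b])
    xs = np.concatenate([a.values[c][masks[c]] for c in a.chromosomes])
    ys = np.concatenate([b.values[c][masks[c]] for c in a.chromosomes])
    return xs, ys


def correlate(a: Track, b: Track) -> CorrelationResult:
    """Pearson r over the positions defined in both tracks."""
    xs, ys = _paired_values(a, b)
    if len(xs) < 3:
        raise ValueError("need at least 3 common positions")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("zero variance over common positions")
    r = stats.pearsonr(xs, ys).statistic
    return CorrelationResult(r=float(r), n_positions=len(xs))


def density_grid(a: Track, b: Track, n_bins: int = 100) -> DensityGrid:
    """2-D histogram of paired base values (the density-plot data)."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    xs, ys = _paired_values(a, b)
    counts, x_edges, y_edges = np.histogram2d(xs, ys, bins=n_bins)
    return DensityGrid(x_edges=x_edges, y_edges=y_edges, counts=counts)


def region_report(
    region: tuple[str, int, int],
    tracks: dict[str, Track],
    gc: Track | None = None,
    annotations: RegionAnnotation | None = None,
) -> pd.DataFrame:
    """Per-base table over a region, one column per named track.

    Rows are the region's bases (0-based positions); undefined track
    positions appear as NaN. The optional GC column and overlapping
    annotation labels support region profile plots with the 1.0
    genome-average reference line.
    """
    chrom, start, end = region
    if not tracks:
        raise ValueError("no tracks given")
    some = next(iter(tracks.values()))
    if chrom not in some.lengths:
        raise ValueError(f"chromosome {chrom!r} not in tracks")
    length = some.lengths[chrom]
    if not (0 <= start < end <= length):
        raise ValueError(
            f"region {chrom}:{start}-{end} outside chromosome (length {length})"
        )
    positions = np.arange(start, end)
    data: dict[str, np.ndarray | list] = {"position": positions}
    for name, track in tracks.items():
        vals = track.values[chrom][start:end].astype(float).copy()
        vals[~track.mask[chrom][start:end]] = np.nan
        data[name] = vals
    if gc is not None:
        vals = gc.values[chrom][start:end].astype(float).copy()
        vals[~gc.mask[chrom][start:end]] = np.nan
        data["gc"] = vals
    if annotations is not None:
        hits = annotations.overlapping(chrom, start, end)
        labels = [""] * len(positions)
        for row in hits.itertuples(index=False):
            lo = max(int(row.start), start) - start
            hi = min(int(row.end), end) - start
            for i in range(lo, hi):
                labels[i] = f"{labels[i]},{row.label}" if labels[i] else row.label
        data["annotations"] = labels
    return pd.DataFrame(data)
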