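"""Coverage maps from single-end read starts.

The coverage (occupancy) map is built by extending every read to a fixed
150 bp footprint in its strand direction and summing footprints per
base. Two normalizations are provided:

- ``normalize_log2``: binary log of the counts, genome-wide mean set to
  zero by subtraction; zero-coverage bases become undefined (no
  pseudocount), so downstream comparisons use only positions covered in
  every data set.
- ``normalize_linear``: counts divided by the genome-wide mean, zeros
  kept as defined values (the "dashed line at 1.0" scale of region
  profiles).

The average fragment length of a library is estimated without paired
ends from the histogram of +/- read start distances within a window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .genome import Genome
from .track_io import ReadStartTable, Track

logger = logging.getLogger(__name__)

DEFAULT_EXTENSION = 150
DEFAULT_FRAGLEN_WINDOW = 300


@dataclass
class FragmentLengthEstimate:
    """Abundance-weighted mean of +/- read-start distances.

    ``histogram`` maps the inclusive distance d = q - p + 1 between a
    +-strand read at p and a --strand read at q (same chromosome,
    0 < d <= window) to its pair count. For reads marking the two ends
    of ~150 bp fragments the histogram peaks at the fragment length.
    """

    mean_length: float
    histogram: dict[int, int]
    window: int

    @property
    def n_pairs(self) -> int:
        return int(sum(self.histogram.values()))


def estimate_fragment_length(
    reads: ReadStartTable, window: int = DEFAULT_FRAGLEN_WINDOW
) -> FragmentLengthEstimate:
    """Histogram every +/- read pair within ``window`` bp and average.

    Every +-strand read is paired with every --strand read at inclusive
    distance 1..window downstream on the same chromosome; pairs where
    the - read lies upstream of the + read are skipped. Errors when no
    pair qualifies.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    hist = np.zeros(window + 1, dtype=np.int64)
    for chrom in reads.chromosomes:
        plus = reads.plus.get(chrom, np.empty(0, dtype=np.int64))
        minus = reads.minus.get(chrom, np.empty(0, dtype=np.int64))
        if len(plus) == 0 or len(minus) == 0:
            continue
        length = int(max(plus.max(), minus.max())) + 1
        p_counts = np.bincount(plus, minlength=length).astype(float)
        m_counts = np.bincount(minus, minlength=length).astype(float)
        # cross-correlation: pairs[lag] = sum_p p_counts[p] * m_counts[p + lag]
        cc = signal.correlate(m_counts, p_counts, mode="full", method="fft")
        center = len(p_counts) - 1
        max_lag = min(window - 1, len(cc) - 1 - center)
        lags = np.rint(cc[center : center + max_lag + 1]).astype(np.int64)
        hist[1 : max_lag + 2] += lags  # distance = lag + 1
    total = int(hist.sum())
    if total == 0:
        raise ValueError("no +/- pairs within window")
    distances = np.arange(window + 1)
    mean = float((distances * hist).sum() / total)
    histogram = {int(d): int(c) for d, c in zip(distances, hist) if c > 0}
    return FragmentLengthEstimate(mean_length=mean, histogram=histogram, window=window)


def pileup(
    reads: ReadStartTable, genome: Genome, extension: int = DEFAULT_EXTENSION
) -> Track:
    """Sum fixed-length read footprints into a raw-count coverage track.

    A + read at p covers [p, p + extension); a - read at p covers
    (p - extension, p]. Footprints overhanging a chromosome end are
    truncated (the truncated base count is logged). All positions are
    defined, including zeros.
    """
    if extension < 1:
        raise ValueError("extension must be >= 1")
    reads.validate_against(genome)
    values = {}
    truncated = 0
    for name in genome.names:
        length = genome.length(name)
        diff = np.zeros(length + 1)
        plus = reads.plus.get(name)
        if plus is not None and len(plus):
            ends = np.minimum(plus + extension, length)
            truncated += int((plus + extension - ends).sum())
            np.add.at(diff, plus, 1.0)
            np.add.at(diff, ends, -1.0)
        minus = reads.minus.get(name)
        if minus is not None and len(minus):
            starts = np.maximum(minus - extension + 1, 0)
            truncated += int((starts - (minus - extension + 1)).sum())
            np.add.at(diff, starts, 1.0)
            np.add.at(diff, minus + 1, -1.0)
        values[name] = np.cumsum(diff[:-1])
    if truncated:
        logger.info("pileup truncated %d overhanging footprint bases", truncated)
    return Track.from_values(values, state="raw_counts")


def normalize_log2(track: Track) -> Track:
    """Binary-log transform and genome-wide mean-centering.

    Zero-count positions become undefined; the mean of log2(count) over
    all defined positions, pooled across chromosomes, is subtracted so
    the output mean over defined positions is zero.
    """
    if track.state != "raw_counts":
        raise ValueError("normalize_log2 expects a raw_counts track")
    mask = {
        n: track.mask[n] & (track.values[n] > 0) for n in track.chromosomes
    }
    n_defined = sum(int(m.sum()) for m in mask.values())
    if n_defined == 0:
        raise ValueError("all positions have zero coverage; nothing to transform")
    logs = {}
    for name in track.chromosomes:
        vals = np.zeros_like(track.values[name])
        m = mask[name]
        vals[m] = np.log2(track.values[name][m])
        logs[name] = vals
    mean = sum(float(logs[n][mask[n]].sum()) for n in logs) / n_defined
    values = {n: np.where(mask[n], logs[n] - mean, 0.0) for n in logs}
    return Track(values=values, mask=mask, state="log2_centered")


def normalize_linear(track: Track) -> Track:
    """Divide by the genome-wide mean so the average is exactly 1.

    Zeros stay defined; the reference level 1.0 is the genome-wide
    average coverage.
    """
    if track.state != "raw_counts":
        raise ValueError("normalize_linear expects a raw_counts track")
    pooled = track.defined_values()
    mean = float(pooled.mean())
    if mean <= 0:
        raise ValueError("genome-wide mean coverage is zero")
    values = {n: track.values[n] / mean for n in track.chromosomes}
    return Track(
        values=values,
        mask={n: track.mask[n].copy() for n in track.chromosomes},
        state="linear_normalized",
    )
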