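"""Windowed GC-content tracks and read-start-aligned GC profiles.

Nucleosomal DNA is ~147 bp, so local GC content is measured in 147-bp
windows assigned to the central base: the value at (1-based) position 74
is the GC fraction of bases 1..147. In centered mode the track is
log2-transformed and the genome-wide mean subtracted, putting it on the
same scale as a log2-centered coverage map.

The GC profile aligns all reads at their start coordinate (minus-strand
reads reverse-complemented, which leaves G/C status unchanged) and
reports the per-offset G+C frequency from -flank to +flank, optionally
smoothed with a short moving average to suppress the 3-bp codon
periodicity of coding genomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .genome import Genome, N_CODE
from .track_io import ReadStartTable, Track

logger = logging.getLogger(__name__)

DEFAULT_GC_WINDOW = 147
DEFAULT_PROFILE_FLANK = 2000
DEFAULT_PROFILE_SMOOTH = 3


def gc_window_track(
    genome: Genome, window: int = DEFAULT_GC_WINDOW, centered: bool = False
) -> Track:
    """GC fraction in a sliding window, assigned to the central base.

    ``window`` must be odd so the center is a single base. Positions
    whose window overhangs a chromosome end are undefined, so every
    defined value is a same-width statistic. N bases are excluded from
    both numerator and denominator; an all-N window is undefined.

    With ``centered=True`` the defined values are log2-transformed and
    mean-centered genome-wide (windows with zero GC become undefined).
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    half = (window - 1) // 2
    values = {}
    mask = {}
    for name in genome.names:
        codes = genome.codes(name)
        length = len(codes)
        vals = np.zeros(length)
        msk = np.zeros(length, dtype=bool)
        if length < window:
            logger.warning(
                "chromosome %r (length %d) shorter than window %d; all undefined",
                name, length, window,
            )
            values[name], mask[name] = vals, msk
            continue
        is_gc = ((codes == 1) | (codes == 2)).astype(np.int64)
        non_n = (codes != N_CODE).astype(np.int64)
        gc_cs = np.concatenate(([0], np.cumsum(is_gc)))
        nn_cs = np.concatenate(([0], np.cumsum(non_n)))
        gc_sum = gc_cs[window:] - gc_cs[:-window]  # exact integer window sums
        nn_sum = nn_cs[window:] - nn_cs[:-window]
        centers = np.arange(half, length - half)
        vals[centers] = gc_sum / np.maximum(nn_sum, 1)
        msk[centers] = nn_sum > 0
        values[name], mask[name] = vals, msk
    track = Track(values=values, mask=mask, state="raw_counts")
    if centered:
        track = _log2_center(track)
    return track


def _log2_center(track: Track) -> Track:
    """Log2 + genome-wide mean-centering (zero values become undefined)."""
    mask = {n: track.mask[n] & (track.values[n] > 0) for n in track.chromosomes}
    n_defined = sum(int(m.sum()) for m in mask.values())
    if n_defined == 0:
        raise ValueError("no positive values to center")
    logs = {}
    for name in track.chromosomes:
        vals = np.zeros_like(track.values[name])
        m = mask[name]
        vals[m] = np.log2(track.values[name][m])
        logs[name] = vals
    mean = sum(float(logs[n][mask[n]].sum()) for n in logs) / n_defined
    return Track(
        values={n: np.where(mask[n], logs[n] - mean, 0.0) for n in logs},
        mask=mask,
        state="log2_centered",
    )


@dataclass
class GCProfile:
    """Per-offset G+C frequency around aligned read starts.

    Offset 0 is the first base of the read; positive offsets run into
    the fragment, negative offsets upstream. For minus-strand reads the
    aligned sequence is the reverse complement, so offset o maps to
    genome base p - o (G/C status is complement-invariant).
    """

    offsets: np.ndarray
    raw_gc: np.ndarray  # per-offset frequency before smoothing
    gc_frequency: np.ndarray  # after moving-average smoothing
    n: np.ndarray  # bases contributing per offset
    n_reads: int

    def mean_over(self, lo: int, hi: int, smoothed: bool = True) -> float:
        """Mean GC frequency over offsets lo..hi inclusive."""
        sel = (self.offsets >= lo) & (self.offsets <= hi) & (self.n > 0)
        src = self.gc_frequency if smoothed else self.raw_gc
        return float(src[sel].mean())


def moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average with a shrinking window at the edges."""
    if width < 1 or width % 2 == 0:
        raise ValueError("smoothing width must be odd and >= 1")
    if width == 1:
        return x.copy()
    kernel = np.ones(width)
    sums = signal.convolve(x, kernel, mode="same")
    counts = signal.convolve(np.ones_like(x), kernel, mode="same")
    return sums / counts


def gc_profile_around_read_starts(
    genome: Genome,
    reads: ReadStartTable,
    flank: int = DEFAULT_PROFILE_FLANK,
    smooth: int = DEFAULT_PROFILE_SMOOTH,
) -> GCProfile:
    """Aggregate the GC frequency at each offset around read starts.

    Offsets beyond a chromosome end, and N bases, contribute to neither
    numerator nor denominator. Computed by FFT cross-correlation of the
    per-base G/C indicator with the read-start count vectors, so it
    scales to genome-sized inputs.
    """
    if reads.n_reads == 0:
        raise ValueError("read table is empty")
    reads.validate_against(genome)
    n_off = 2 * flank + 1
    gc_sum = np.zeros(n_off)
    n_sum = np.zeros(n_off)
    for name in genome.names:
        codes = genome.codes(name)
        is_gc = ((codes == 1) | (codes == 2)).astype(float)
        valid = (codes != N_CODE).astype(float)
        length = len(codes)
        for strand, positions in (
            ("+", reads.plus.get(name)),
            ("-", reads.minus.get(name)),
        ):
            if positions is None or len(positions) == 0:
                continue
            counts = np.bincount(positions, minlength=length).astype(float)
            # corr[lag] = sum_p counts[p] * x[p + lag], lag in [-(L-1), L-1]
            center = length - 1
            gc_cc = signal.correlate(is_gc, counts, mode="full", method="fft")
            nn_cc = signal.correlate(valid, counts, mode="full", method="fft")
            lags = np.arange(-flank, flank + 1)
            if strand == "-":
                lags = -lags  # offset o reads genome base p - o
            idx = center + lags
            inside = (idx >= 0) & (idx < len(gc_cc))
            gc_sum[inside] += gc_cc[idx[inside]]
            n_sum[inside] += nn_cc[idx[inside]]
    n_sum = np.rint(n_sum)
    gc_sum = np.rint(gc_sum)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where(n_sum > 0, gc_sum / np.maximum(n_sum, 1), np.nan)
    smoothed = _smooth_ignoring_nan(raw, smooth)
    return GCProfile(
        offsets=np.arange(-flank, flank + 1),
        raw_gc=raw,
        gc_frequency=smoothed,
        n=n_sum.astype(np.int64),
        n_reads=reads.n_reads,
    )


def _smooth_ignoring_nan(x: np.ndarray, width: int) -> np.ndarray:
    if width == 1:
        return x.copy()
    filled = np.where(np.isnan(x), 0.0, x)
    weight = (~np.isnan(x)).astype(float)
    kernel = np.ones(width)
    sums = signal.convolve(filled, kernel, mode="same")
    counts = signal.convolve(weight, kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(counts > 0, sums / np.maximum(counts, 1e-300), np.nan)
    return out
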