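"""Genome-wide average track value over all occurrences of each k-mer.

For every forward-strand occurrence of a length-k sequence whose k
covered positions are all defined in the track, the occurrence
contributes the mean of those k values; the table entry for the k-mer
is the average contribution over all qualifying occurrences. With a
linear-normalized coverage track this is the "relative coverage" of the
k-mer: values below 1 mark sequences depleted of recovered fragments
(AAAAA/TTTTT under AT-biased digestion), values above 1 enriched ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import Genome, N_CODE, reverse_complement
from .track_io import Track

DEFAULT_K = 5


@dataclass
class KmerCoverageTable:
    """Mean track value and occurrence count per k-mer.

    ``entries`` has index = k-mer string, columns ``mean`` and ``n``.
    k-mers containing N never appear; absent k-mers had no qualifying
    occurrence.
    """

    k: int
    entries: pd.DataFrame

    def mean(self, kmer: str) -> float:
        return float(self.entries.loc[kmer, "mean"])

    def lowest(self, n: int = 2) -> list[str]:
        """The n k-mers with the smallest mean coverage."""
        return list(self.entries["mean"].nsmallest(n).index)

    def to_tsv(self, path) -> None:
        self.entries.to_csv(path, sep="\t", index_label="kmer")

    @classmethod
    def from_tsv(cls, path) -> "KmerCoverageTable":
        df = pd.read_csv(path, sep="\t", index_col="kmer")
        k = len(str(df.index[0]))
        return cls(k=k, entries=df)


def _kmer_ids(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(ids, valid) for each forward-strand offset; invalid where any N."""
    n = len(codes) - k + 1
    ids = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    clean = np.where(codes == N_CODE, 0, codes).astype(np.int64)
    has_n = codes == N_CODE
    for j in range(k):
        ids = ids * 4 + clean[j : j + n]
        valid &= ~has_n[j : j + n]
    return ids, valid


def _id_to_kmer(idx: int, k: int) -> str:
    bases = "ACGT"
    out = []
    for _ in range(k):
        out.append(bases[idx % 4])
        idx //= 4
    return "".join(reversed(out))


def kmer_mean_coverage(
    track: Track, genome: Genome, k: int = DEFAULT_K, collapse_strands: bool = False
) -> KmerCoverageTable:
    """Average a track over every qualifying occurrence of each k-mer.

    Occurrences are forward-strand at every offset; an occurrence
    qualifies only if all k of its positions are defined in the track.
    Each qualifying occurrence is weighted equally. With
    ``collapse_strands`` a k-mer and its reverse complement share one
    entry (labelled by the lexicographically smaller of the two).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    shortest = min(genome.lengths.values())
    if k > shortest:
        raise ValueError(f"k={k} exceeds the shortest chromosome ({shortest} bp)")
    if set(track.lengths.items()) != set(genome.lengths.items()):
        raise ValueError("track and genome must share chromosomes and lengths")

    sums = np.zeros(4**k)
    counts = np.zeros(4**k, dtype=np.int64)
    for name in genome.names:
        codes = genome.codes(name)
        if len(codes) < k:
            continue
        ids, valid = _kmer_ids(codes, k)
        vals = np.where(track.mask[name], track.values[name], 0.0)
        defined = track.mask[name].astype(np.int64)
        v_cs = np.concatenate(([0.0], np.cumsum(vals)))
        d_cs = np.concatenate(([0], np.cumsum(defined)))
        win_sum = v_cs[k:] - v_cs[:-k]
        win_def = d_cs[k:] - d_cs[:-k]
        ok = valid & (win_def == k)
        occ_means = win_sum[ok] / k
        np.add.at(sums, ids[ok], occ_means)
        np.add.at(counts, ids[ok], 1)

    if collapse_strands:
        collapsed_s = np.zeros(4**k)
        collapsed_c = np.zeros(4**k, dtype=np.int64)
        for idx in np.flatnonzero(counts):
            kmer = _id_to_kmer(int(idx), k)
            canon = min(kmer, reverse_complement(kmer))
            cidx = _kmer_to_id(canon)
            collapsed_s[cidx] += sums[idx]
            collapsed_c[cidx] += counts[idx]
        sums, counts = collapsed_s, collapsed_c

    present = np.flatnonzero(counts)
    entries = pd.DataFrame(
        {
            "mean": sums[present] / counts[present],
            "n": counts[present],
        },
        index=pd.Index([_id_to_kmer(int(i), k) for i in present], name="kmer"),
    )
    return KmerCoverageTable(k=k, entries=entries)


def _kmer_to_id(kmer: str) -> int:
    idx = 0
    for base in kmer:
        idx = idx * 4 + "ACGT".index(base)
    return idx


def kmer_table_correlation(
    a: KmerCoverageTable, b: KmerCoverageTable
) -> tuple[float, int]:
    """Pearson r of mean coverages over k-mers present in both tables."""
    if a.k != b.k:
        raise ValueError("tables have different k")
    common = a.entries.index.intersection(b.entries.index)
    if len(common) < 3:
        raise ValueError("fewer than 3 common k-mers")
    r = stats.pearsonr(
        a.entries.loc[common, "mean"], b.entries.loc[common, "mean"]
    ).statistic
    return float(r), int(len(common))
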