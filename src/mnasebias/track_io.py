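"""Per-base track data model and the text formats the pipeline touches.

Containers
----------
``Track``            per-base real signal with a defined-position mask
``ReadStartTable``   multiset of single-end read 5' start coordinates
``FragmentSet``      digestion fragments as 0-based half-open intervals
``RegionAnnotation`` labelled intervals (genes, elements) for region reports

Formats: FASTA (genome, via Biopython), BED3 (fragments), BED6 (read
starts, annotations), bedGraph and fixedStep wiggle (tracks). All files
use their standard coordinate conventions (BED/bedGraph 0-based
half-open, wiggle 1-based); the internal frame is 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import Genome

TRACK_STATES = ("raw_counts", "linear_normalized", "log2_centered")


@dataclass
class Track:
    """Per-base real-valued signal with a defined-position mask.

    ``values[c][i]`` is meaningful only where ``mask[c][i]`` is True.
    ``state`` records which normalisation has been applied:

    - ``raw_counts``: nonnegative, fully defined signal (pileup counts,
      windowed GC fractions);
    - ``linear_normalized``: divided by the genome-wide mean (mean 1);
    - ``log2_centered``: binary log, genome-wide mean subtracted (mean 0
      over defined positions; zeros of the raw signal become undefined).
    """

    values: dict[str, np.ndarray]
    mask: dict[str, np.ndarray]
    state: str = "raw_counts"

    def __post_init__(self) -> None:
        if self.state not in TRACK_STATES:
            raise ValueError(f"unknown track state {self.state!r}")
        if set(self.values) != set(self.mask):
            raise ValueError("values and mask must cover the same chromosomes")
        for name, vals in self.values.items():
            vals = np.asarray(vals, dtype=float)
            msk = np.asarray(self.mask[name], dtype=bool)
            if vals.shape != msk.shape:
                raise ValueError(f"values/mask length mismatch on {name!r}")
            if not np.isfinite(vals[msk]).all():
                raise ValueError(f"non-finite defined values on {name!r}")
            if self.state == "raw_counts" and (vals[msk] < 0).any():
                raise ValueError("raw_counts state must be nonnegative")
            self.values[name] = vals
            self.mask[name] = msk

    @classmethod
    def from_values(
        cls, values: dict[str, np.ndarray], state: str = "raw_counts"
    ) -> "Track":
        """Fully defined track from plain per-chromosome arrays."""
        return cls(
            values={n: np.asarray(v, dtype=float) for n, v in values.items()},
            mask={n: np.ones(len(v), dtype=bool) for n, v in values.items()},
            state=state,
        )

    @property
    def chromosomes(self) -> list[str]:
        return list(self.values)

    @property
    def lengths(self) -> dict[str, int]:
        return {n: len(v) for n, v in self.values.items()}

    def defined_values(self) -> np.ndarray:
        """All defined values pooled genome-wide, chromosome order."""
        parts = [self.values[n][self.mask[n]] for n in self.values]
        return np.concatenate(parts) if parts else np.empty(0)

    def n_defined(self) -> int:
        return int(sum(m.sum() for m in self.mask.values()))

    def copy(self) -> "Track":
        return Track(
            values={n: v.copy() for n, v in self.values.items()},
            mask={n: m.copy() for n, m in self.mask.items()},
            state=self.state,
        )


@dataclass
class ReadStartTable:
    """Multiset of single-end read 5' starts, split by strand.

    ``plus[c]`` / ``minus[c]`` are sorted integer position arrays (with
    repeats) of the 5'-most genome coordinate of each read.
    """

    plus: dict[str, np.ndarray]
    minus: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for d in (self.plus, self.minus):
            for name, pos in d.items():
                d[name] = np.sort(np.asarray(pos, dtype=np.int64))

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, int, str]]
    ) -> "ReadStartTable":
        plus: dict[str, list[int]] = {}
        minus: dict[str, list[int]] = {}
        for chrom, pos, strand in records:
            if strand == "+":
                plus.setdefault(chrom, []).append(pos)
            elif strand == "-":
                minus.setdefault(chrom, []).append(pos)
            else:
                raise ValueError(f"malformed strand {strand!r}")
        chroms = sorted(set(plus) | set(minus))
        return cls(
            plus={c: np.array(plus.get(c, []), dtype=np.int64) for c in chroms},
            minus={c: np.array(minus.get(c, []), dtype=np.int64) for c in chroms},
        )

    @property
    def chromosomes(self) -> list[str]:
        return sorted(set(self.plus) | set(self.minus))

    @property
    def n_reads(self) -> int:
        return int(
            sum(len(p) for p in self.plus.values())
            + sum(len(m) for m in self.minus.values())
        )

    @property
    def n_plus(self) -> int:
        return int(sum(len(p) for p in self.plus.values()))

    def validate_against(self, genome: Genome) -> None:
        unknown = [c for c in self.chromosomes if c not in genome]
        if unknown:
            raise ValueError(f"read chromosomes not in genome: {unknown}")
        for d in (self.plus, self.minus):
            for name, pos in d.items():
                if len(pos) and (pos.min() < 0 or pos.max() >= genome.length(name)):
                    raise ValueError(f"read position out of bounds on {name!r}")

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for chrom in self.chromosomes:
            for pos in self.plus.get(chrom, ()):
                rows.append((chrom, int(pos), "+"))
            for pos in self.minus.get(chrom, ()):
                rows.append((chrom, int(pos), "-"))
        return pd.DataFrame(rows, columns=["chrom", "pos", "strand"])


@dataclass
class FragmentSet:
    """Digestion fragments per chromosome as (n, 2) start/end arrays."""

    fragments: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for name, arr in self.fragments.items():
            arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            if len(arr) and (arr[:, 0] >= arr[:, 1]).any():
                raise ValueError(f"empty or inverted fragment on {name!r}")
            self.fragments[name] = arr

    @property
    def n_fragments(self) -> int:
        return int(sum(len(a) for a in self.fragments.values()))

    def lengths(self) -> np.ndarray:
        parts = [a[:, 1] - a[:, 0] for a in self.fragments.values()]
        return np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)

    @classmethod
    def concatenate(cls, sets: Sequence["FragmentSet"]) -> "FragmentSet":
        chroms = sorted({c for s in sets for c in s.fragments})
        merged = {
            c: np.concatenate(
                [s.fragments[c] for s in sets if c in s.fragments]
                or [np.empty((0, 2), dtype=np.int64)]
            )
            for c in chroms
        }
        return cls(merged)


@dataclass
class RegionAnnotation:
    """Labelled intervals used to annotate region reports."""

    intervals: pd.DataFrame  # columns: chrom, start, end, label, strand

    def __post_init__(self) -> None:
        required = ["chrom", "start", "end", "label", "strand"]
        missing = [c for c in required if c not in self.intervals.columns]
        if missing:
            raise ValueError(f"annotation table missing columns {missing}")
        if (self.intervals["start"] >= self.intervals["end"]).any():
            raise ValueError("annotation intervals must satisfy start < end")

    def overlapping(self, chrom: str, start: int, end: int) -> pd.DataFrame:
        df = self.intervals
        hit = (df["chrom"] == chrom) & (df["start"] < end) & (df["end"] > start)
        return df[hit]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> Genome:
    """Load a genome FASTA. Lowercase is folded to uppercase; characters
    outside {A,C,G,T,N} are rejected; duplicate headers and empty records
    are errors."""
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA header {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for FASTA record {rec.id!r}")
        records.append((rec.id, seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return Genome.from_records(records)


def write_fasta(genome: Genome, path: str | Path) -> None:
    """Write the genome as FASTA wrapped at 60 columns."""
    recs = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.chromosomes.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def write_fragments_bed(fragments: FragmentSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, arr in fragments.fragments.items():
            for start, end in arr:
                fh.write(f"{chrom}\t{start}\t{end}\n")


def read_fragments_bed(path: str | Path, genome: Genome | None = None) -> FragmentSet:
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2],
        names=["chrom", "start", "end"], dtype={0: str},
    )
    if genome is not None:
        unknown = sorted(set(df["chrom"]) - set(genome.names))
        if unknown:
            raise ValueError(f"fragment chromosomes not in genome: {unknown}")
    return FragmentSet(
        {
            chrom: grp[["start", "end"]].to_numpy(dtype=np.int64)
            for chrom, grp in df.groupby("chrom", sort=True)
        }
    )


def write_read_starts_bed(reads: ReadStartTable, path: str | Path) -> None:
    """BED6; the interval is the single 5' start base, strand in column 6."""
    with open(path, "w") as fh:
        for chrom in reads.chromosomes:
            for pos in reads.plus.get(chrom, ()):
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\t.\t0\t+\n")
            for pos in reads.minus.get(chrom, ()):
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\t.\t0\t-\n")


def read_read_starts(path: str | Path, genome: Genome) -> ReadStartTable:
    """Read a BED6 file of mapped reads into a ReadStartTable.

    Each line contributes one record at its 5' coordinate: chromStart for
    + strand reads, chromEnd - 1 for - strand reads (the 5'-most base of
    a minus-strand read is the rightmost base of its interval).
    """
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2, 5],
        names=["chrom", "start", "end", "strand"], dtype={0: str, 5: str},
    )
    unknown = sorted(set(df["chrom"]) - set(genome.names))
    if unknown:
        raise ValueError(f"read chromosomes not in genome: {unknown}")
    bad = sorted(set(df["strand"]) - {"+", "-"})
    if bad:
        raise ValueError(f"malformed strand values: {bad}")
    pos = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    table = ReadStartTable.from_records(
        zip(df["chrom"], pos.astype(int), df["strand"])
    )
    table.validate_against(genome)
    return table


def read_annotations_bed(path: str | Path) -> RegionAnnotation:
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2, 3, 5],
        names=["chrom", "start", "end", "label", "strand"], dtype={0: str},
    )
    return RegionAnnotation(df.reset_index(drop=True))


# ---------------------------------------------------------------------------
# bedGraph / wiggle tracks
# ---------------------------------------------------------------------------


def _runs(mask: np.ndarray) -> Iterable[tuple[int, int]]:
    """Yield (start, end) of maximal True runs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    for start, end in zip(idx[::2], idx[1::2]):
        yield int(start), int(end)


def write_track(track: Track, path: str | Path, format: str = "bedgraph") -> None:
    """Serialize a track; undefined positions are omitted from the file."""
    if format == "bedgraph":
        _write_bedgraph(track, path)
    elif format == "wiggle":
        _write_wiggle(track, path)
    else:
        raise ValueError(f"unknown track format {format!r}")


def _write_bedgraph(track: Track, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chromosomes:
            vals = track.values[chrom]
            msk = track.mask[chrom]
            for rstart, rend in _runs(msk):
                seg = vals[rstart:rend]
                # run-length merge equal consecutive values
                brk = np.flatnonzero(seg[1:] != seg[:-1]) + 1
                edges = np.concatenate(([0], brk, [len(seg)]))
                for a, b in zip(edges[:-1], edges[1:]):
                    fh.write(
                        f"{chrom}\t{rstart + a}\t{rstart + b}\t{seg[a]:.6g}\n"
                    )


def _write_wiggle(track: Track, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chromosomes:
            vals = track.values[chrom]
            for rstart, rend in _runs(track.mask[chrom]):
                fh.write(f"fixedStep chrom={chrom} start={rstart + 1} step=1\n")
                fh.writelines(f"{v:.6g}\n" for v in vals[rstart:rend])


def read_track(path: str | Path, genome: Genome, state: str = "raw_counts") -> Track:
    """Read a bedGraph or fixedStep wiggle track onto the genome frame.

    Positions absent from the file are undefined. Overlapping bedGraph
    intervals are an error. The format is sniffed from the first line.
    """
    path = Path(path)
    values = {n: np.zeros(genome.length(n)) for n in genome.names}
    mask = {n: np.zeros(genome.length(n), dtype=bool) for n in genome.names}

    with open(path) as fh:
        first = fh.readline()
    is_wiggle = first.startswith(("fixedStep", "track", "variableStep"))

    if is_wiggle:
        chrom, pos = None, 0
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("track"):
                    continue
                if line.startswith("fixedStep"):
                    fields = dict(kv.split("=") for kv in line.split()[1:])
                    chrom = fields["chrom"]
                    pos = int(fields["start"]) - 1  # wiggle is 1-based
                    if int(fields.get("step", 1)) != 1:
                        raise ValueError("only step=1 fixedStep wiggle supported")
                    if chrom not in values:
                        raise ValueError(f"unknown chromosome {chrom!r} in {path}")
                    continue
                if chrom is None:
                    raise ValueError("wiggle data before any fixedStep header")
                values[chrom][pos] = float(line)
                mask[chrom][pos] = True
                pos += 1
    else:
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "value"], dtype={0: str},
        )
        unknown = sorted(set(df["chrom"]) - set(genome.names))
        if unknown:
            raise ValueError(f"unknown chromosomes in {path}: {unknown}")
        for chrom, start, end, value in df.itertuples(index=False):
            if mask[chrom][start:end].any():
                raise ValueError(
                    f"overlapping bedGraph intervals on {chrom} near {start}"
                )
            values[chrom][start:end] = value
            mask[chrom][start:end] = True

    return Track(values=values, mask=mask, state=state)


def track_info(track: Track) -> pd.DataFrame:
    """Per-chromosome defined fraction and mean, plus a genome-wide row."""
    rows = []
    for chrom in track.chromosomes:
        msk = track.mask[chrom]
        vals = track.values[chrom][msk]
        rows.append(
            {
                "chrom": chrom,
                "length": len(msk),
                "defined_fraction": float(msk.mean()),
                "mean": float(vals.mean()) if len(vals) else float("nan"),
            }
        )
    pooled = track.defined_values()
    rows.append(
        {
            "chrom": "__genome__",
            "length": sum(track.lengths.values()),
            "defined_fraction": track.n_defined() / max(sum(track.lengths.values()), 1),
            "mean": float(pooled.mean()) if len(pooled) else float("nan"),
        }
    )
    return pd.DataFrame(rows)
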