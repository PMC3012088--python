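"""Genome container and low-level sequence utilities.

The genome is the coordinate frame for every track, fragment and read in
the package. Internally every interval is 0-based, half-open; conversion
to 1-based conventions happens only at file-format boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

# Numeric base codes used by all vectorised sequence code paths.
# N (real-data assemblies only) gets a sentinel outside the A/C/G/T range.
BASE_ORDER = "ACGT"
N_CODE = 4

_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASE_ORDER):
    _CODE_LUT[ord(_b)] = _i
_CODE_LUT[ord("N")] = N_CODE

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def encode_sequence(seq: str) -> np.ndarray:
    """Map a sequence string to uint8 codes (A=0, C=1, G=2, T=3, N=4).

    Raises ``ValueError`` on any character outside {A, C, G, T, N}.
    """
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE_LUT[raw]
    if (codes == 255).any():
        bad = sorted({seq[i] for i in np.flatnonzero(codes == 255)[:10]})
        raise ValueError(f"sequence contains invalid characters: {bad}")
    return codes


def decode_sequence(codes: np.ndarray) -> str:
    lut = np.frombuffer((BASE_ORDER + "N").encode("ascii"), dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Genome:
    """Ordered collection of named chromosome sequences over {A,C,G,T[,N]}.

    Parameters
    ----------
    chromosomes
        Mapping chromosome name -> uppercase sequence. Insertion order is
        the canonical chromosome order.
    """

    chromosomes: dict[str, str]
    _codes: dict[str, np.ndarray] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("genome must contain at least one chromosome")
        for name, seq in self.chromosomes.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} has an empty sequence")
            encode_sequence(seq)  # validates alphabet

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str]]) -> "Genome":
        chroms: dict[str, str] = {}
        for name, seq in records:
            if name in chroms:
                raise ValueError(f"duplicate chromosome name {name!r}")
            chroms[name] = seq.upper()
        return cls(chroms)

    # -- basic accessors -------------------------------------------------

    @property
    def names(self) -> list[str]:
        return list(self.chromosomes)

    def __contains__(self, name: str) -> bool:
        return name in self.chromosomes

    def __iter__(self) -> Iterator[str]:
        return iter(self.chromosomes)

    def length(self, name: str) -> int:
        return len(self.chromosomes[name])

    @property
    def lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self.chromosomes.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def codes(self, name: str) -> np.ndarray:
        """Cached uint8 base codes for one chromosome."""
        if name not in self._codes:
            self._codes[name] = encode_sequence(self.chromosomes[name])
        return self._codes[name]

    # -- composition -----------------------------------------------------

    def gc_fraction(self) -> float:
        """Genome-wide G+C fraction over non-N bases."""
        gc = 0
        total = 0
        for name in self.chromosomes:
            codes = self.codes(name)
            non_n = codes != N_CODE
            gc += int(((codes == 1) | (codes == 2)).sum())
            total += int(non_n.sum())
        if total == 0:
            raise ValueError("genome contains no A/C/G/T bases")
        return gc / total

    def reverse_complemented(self) -> "Genome":
        """Mirror-image genome (used by strand-symmetry checks)."""
        return Genome.from_records(
            (name, reverse_complement(seq)) for name, seq in self.chromosomes.items()
        )
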