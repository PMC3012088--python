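"""Synthetic genomes and sequence-biased MNase digestion.

Micrococcal nuclease cuts internucleotide bonds with a strong preference
for A/T; gel size selection then keeps only fragments in a narrow length
band (140-170 bp by default). This module generates genomes with
controlled local base composition (poly-A/T tracts, GC-rich elements)
and simulates that digestion so every downstream coverage analysis can
be exercised without any external data.

Model
-----
Each internucleotide bond ``b`` between bases ``i`` and ``i+1`` carries a
relative cut weight ``w_b``: ``cut_weight_at`` if either flanking base is
A or T, else ``cut_weight_gc``. Bonds are cut independently with
probability ``p_b = c * w_b`` where the scale ``c`` is set per chromosome
so the expected cut count equals ``mean_cuts_per_kb * length / 1000``.
Consecutive cuts (plus chromosome ends) delimit fragments; only those
inside the size band survive selection. One randomly chosen end of each
surviving fragment is "sequenced" to a single-base read start.

Everything is a pure function of (inputs, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genome import Genome, N_CODE
from .track_io import FragmentSet, ReadStartTable

logger = logging.getLogger(__name__)

#: Digestion extent. The size-selection bias requires an over-digestion
#: regime: typical AT-rich stretches must be cut below the 140-170 bp
#: band while relatively GC-rich stretches survive inside it. A mean
#: inter-cut spacing of 40 bp (well under the band) achieves that; at a
#: spacing near the band itself, GC-rich regions yield over-long
#: fragments instead and the bias vanishes.
DEFAULT_MEAN_CUTS_PER_KB = 25.0


# ---------------------------------------------------------------------------
# Composition plans and genome generation
# ---------------------------------------------------------------------------


@dataclass
class ChromosomePlan:
    """Blueprint for one synthetic chromosome.

    ``segments`` is an ordered list of (length, gc_fraction) blocks drawn
    i.i.d. with P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2. ``motifs`` are fixed
    sequences (e.g. poly-A tracts) that overwrite the drawn bases at
    their 0-based positions; they must fit inside the chromosome and not
    overlap each other.
    """

    name: str
    segments: list[tuple[int, float]]
    motifs: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError(f"chromosome {self.name!r} has no segments")
        for length, gc in self.segments:
            if length <= 0:
                raise ValueError("segment lengths must be positive")
            if not 0.0 <= gc <= 1.0:
                raise ValueError("gc_fraction must lie in [0, 1]")
        total = self.length
        occupied: list[tuple[int, int]] = []
        for pos, seq in self.motifs:
            if pos < 0 or pos + len(seq) > total:
                raise ValueError(
                    f"motif at {pos} (length {len(seq)}) extends past the "
                    f"end of chromosome {self.name!r} (length {total})"
                )
            occupied.append((pos, pos + len(seq)))
        occupied.sort()
        for (s1, e1), (s2, e2) in zip(occupied, occupied[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping motifs on {self.name!r}")

    @property
    def length(self) -> int:
        return sum(length for length, _ in self.segments)


@dataclass
class CompositionPlan:
    """Seeded multi-chromosome genome blueprint."""

    chromosomes: list[ChromosomePlan]
    seed: int = 0

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(names) != len(set(names)):
            raise ValueError("chromosome names in plan must be unique")


def generate_genome(plan: CompositionPlan) -> Genome:
    """Realize a composition plan into a concrete genome.

    Identical plan (including seed) always yields the identical genome.
    """
    rng = np.random.default_rng(plan.seed)
    records = []
    for chrom in plan.chromosomes:
        parts = []
        for length, gc in chrom.segments:
            # base order A, C, G, T
            probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
            parts.append(rng.choice(np.array(list("ACGT")), size=length, p=probs))
        seq = np.concatenate(parts)
        for pos, motif in chrom.motifs:
            seq[pos : pos + len(motif)] = list(motif.upper())
        records.append((chrom.name, "".join(seq)))
    return Genome.from_records(records)


# ---------------------------------------------------------------------------
# Digestion
# ---------------------------------------------------------------------------


@dataclass
class DigestionParams:
    """Parameters of the biased-cutting + size-selection model.

    cut_weight_at
        Relative cut propensity of a bond with at least one A/T flank.
    cut_weight_gc
        Propensity when both flanking bases are G or C. The enzyme's
        strong A/T preference means ``cut_weight_at >> cut_weight_gc``.
    mean_cuts_per_kb
        Digestion extent; expected cuts per chromosome kilobase.
    size_min, size_max
        Retained fragment length band in bp (gel excision window).
    seed
        Seed for the per-bond Bernoulli draws.
    """

    cut_weight_at: float = 50.0
    cut_weight_gc: float = 1.0
    mean_cuts_per_kb: float = DEFAULT_MEAN_CUTS_PER_KB
    size_min: int = 140
    size_max: int = 170
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.cut_weight_at >= self.cut_weight_gc >= 0:
            raise ValueError("require cut_weight_at >= cut_weight_gc >= 0")
        if self.size_min > self.size_max:
            raise ValueError("require size_min <= size_max")
        if self.mean_cuts_per_kb <= 0:
            raise ValueError("mean_cuts_per_kb must be positive")


def bond_cut_probabilities(genome: Genome, params: DigestionParams) -> dict[str, np.ndarray]:
    """Per-bond cut probabilities for each chromosome.

    Bond ``i`` sits between bases ``i`` and ``i+1``. Raises when the
    required probability would exceed 1 (parameter overflow) rather than
    silently clipping.
    """
    probs = {}
    for name in genome.names:
        codes = genome.codes(name)
        if (codes == N_CODE).any():
            raise ValueError("digestion simulation requires an N-free genome")
        length = len(codes)
        if length < 2:
            probs[name] = np.empty(0)
            continue
        is_at = (codes == 0) | (codes == 3)  # A or T
        at_flank = is_at[:-1] | is_at[1:]
        weights = np.where(at_flank, params.cut_weight_at, params.cut_weight_gc)
        wsum = weights.sum()
        if wsum == 0:
            probs[name] = np.zeros(length - 1)
            continue
        target_cuts = params.mean_cuts_per_kb * length / 1000.0
        c = target_cuts / wsum
        pmax = c * weights.max()
        if pmax > 1.0:
            raise ValueError(
                f"cut probability overflow on {name!r}: mean_cuts_per_kb="
                f"{params.mean_cuts_per_kb} with cut weights "
                f"({params.cut_weight_at}, {params.cut_weight_gc}) requires "
                f"a per-bond probability of {pmax:.3g} > 1"
            )
        probs[name] = c * weights
    return probs


def _fragments_from_cuts(cut_bonds: np.ndarray, length: int) -> np.ndarray:
    """Fragment intervals delimited by cut bond indices and chromosome ends.

    A cut at bond ``i`` separates base ``i`` from base ``i+1``.
    """
    boundaries = np.concatenate(([0], cut_bonds + 1, [length]))
    return np.column_stack((boundaries[:-1], boundaries[1:]))


def simulate_digestion(genome: Genome, params: DigestionParams) -> FragmentSet:
    """Digest one copy of the genome and size-select the fragments."""
    rng = np.random.default_rng(params.seed)
    probs = bond_cut_probabilities(genome, params)
    fragments = {}
    for name in genome.names:
        p = probs[name]
        cuts = np.flatnonzero(rng.random(len(p)) < p)
        frags = _fragments_from_cuts(cuts, genome.length(name))
        sizes = frags[:, 1] - frags[:, 0]
        keep = (sizes >= params.size_min) & (sizes <= params.size_max)
        fragments[name] = frags[keep]
    return FragmentSet(fragments)


def digest_library(
    genome: Genome, params: DigestionParams, n_copies: int, seed: int
) -> FragmentSet:
    """Digest ``n_copies`` independent genome molecules and pool fragments.

    A sequencing library digests many identical genome copies; each copy
    realizes its own stochastic cut pattern. Per-copy seeds are derived
    from ``seed`` via a SeedSequence spawn, so the result is reproducible
    and independent of batching.
    """
    if n_copies < 1:
        raise ValueError("n_copies must be >= 1")
    probs = bond_cut_probabilities(genome, params)
    rng = np.random.default_rng(seed)
    pooled: dict[str, list[np.ndarray]] = {n: [] for n in genome.names}
    for name in genome.names:
        p = probs[name]
        length = genome.length(name)
        for _ in range(n_copies):
            cuts = np.flatnonzero(rng.random(len(p)) < p)
            frags = _fragments_from_cuts(cuts, length)
            sizes = frags[:, 1] - frags[:, 0]
            keep = (sizes >= params.size_min) & (sizes <= params.size_max)
            pooled[name].append(frags[keep])
    return FragmentSet(
        {
            n: np.concatenate(parts) if parts else np.empty((0, 2), dtype=np.int64)
            for n, parts in pooled.items()
        }
    )


# ---------------------------------------------------------------------------
# Read emission
# ---------------------------------------------------------------------------


def emit_reads(fragments: FragmentSet, seed: int) -> ReadStartTable:
    """Sequence one randomly chosen end of every fragment.

    With probability 1/2 a fragment yields a +-strand read starting at
    its leftmost base, otherwise a --strand read starting at its
    rightmost base (end - 1 of the half-open interval). One read per
    fragment, exact coordinates, no duplicates or errors.
    """
    rng = np.random.default_rng(seed)
    plus = {}
    minus = {}
    for name, arr in fragments.fragments.items():
        take_plus = rng.random(len(arr)) < 0.5
        plus[name] = arr[take_plus, 0]
        minus[name] = arr[~take_plus, 1] - 1
    return ReadStartTable(plus=plus, minus=minus)


# ---------------------------------------------------------------------------
# Fragment composition helpers
# ---------------------------------------------------------------------------


def fragment_gc_fraction(genome: Genome, fragments: FragmentSet) -> float:
    """Pooled G+C fraction of all retained fragment bases."""
    gc = 0
    total = 0
    for name, arr in fragments.fragments.items():
        codes = genome.codes(name)
        is_gc = np.concatenate(([0], np.cumsum((codes == 1) | (codes == 2))))
        gc += int((is_gc[arr[:, 1]] - is_gc[arr[:, 0]]).sum())
        total += int((arr[:, 1] - arr[:, 0]).sum())
    if total == 0:
        raise ValueError("no fragments to measure")
    return gc / total


# ---------------------------------------------------------------------------
# Default demonstration genome
# ---------------------------------------------------------------------------


def default_plan(seed: int = 0, length: int = 100_000) -> CompositionPlan:
    """Yeast-like single-chromosome demo plan.

    Background composition is chosen so the realized genome-wide GC
    fraction emulates budding yeast (~38.3%): the background blocks are
    drawn at GC 0.3977, compensating for 80 embedded 50-bp poly-A/T
    tracts (GC 0, ~4% of the genome, emulating the long A/T runs of
    yeast intergenic DNA) and one 300-bp GC-rich UAS-like element
    (GC 0.80, emulating a regulatory region such as the Gal1-10 UAS).
    """
    if length < 20_000:
        raise ValueError("demo plan needs at least 20 kb")
    bg = 0.3977
    uas_start = int(length * 0.70)
    segments = [
        (uas_start, bg),
        (300, 0.80),
        (length - uas_start - 300, bg),
    ]
    # 80 tracts, alternating poly-A / poly-T, evenly spaced, skipping
    # the UAS-like element.
    motifs = []
    n_tracts, tract_len = 80, 50
    spacing = length // (n_tracts + 1)
    for i in range(n_tracts):
        pos = (i + 1) * spacing
        if uas_start - tract_len - 10 < pos < uas_start + 300 + 10:
            pos = uas_start + 300 + 200 + i * (tract_len + 5)  # displace clear
        base = "A" if i % 2 == 0 else "T"
        motifs.append((pos, base * tract_len))
    chrom = ChromosomePlan(name="chrS", segments=segments, motifs=motifs)
    return CompositionPlan(chromosomes=[chrom], seed=seed)
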