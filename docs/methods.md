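# Methods

## The problem

Nucleosome occupancy maps are routinely produced by digesting chromatin
with micrococcal nuclease (MNase), excising the ~150 bp protected band
from a gel, and sequencing one end of each recovered fragment. MNase,
however, cuts almost exclusively at A/T base pairs. Combined with the
size-selection step this creates a purely sequence-dependent bias: a
~150 bp stretch rich in A/T is likely to receive an internal cut and
drop below the excised band, while a relatively GC-rich stretch
survives into it. Digestion of *naked* (protein-free) DNA therefore
yields a coverage profile that already looks nucleosome-like — enriched
at GC-rich sequence, depleted over poly-A/T tracts — without any
nucleosomes present. This package simulates that process end to end and
implements the analyses used to quantify the bias signal.

## The digestion model

Each internucleotide bond `b` between bases `i` and `i+1` carries a
relative weight

* `cut_weight_at` (default 50) if base `i` or base `i+1` is A or T,
* `cut_weight_gc` (default 1) if both flanking bases are G or C.

Bonds are cut independently (Bernoulli) with probability
`p_b = c · w_b`, where `c` is chosen per chromosome so that the
expected number of cuts equals `mean_cuts_per_kb · length / 1000`.
Requesting probabilities above 1 is an error, not a silent clip.
Consecutive cuts plus the chromosome ends delimit fragments; size
selection retains fragments of 140–170 bp (the gel band). One end of
each retained fragment, chosen with probability ½, is "sequenced" into
a single-base read start; reads carry exact coordinates, so no mapping
step is needed.

The two-level flank rule is the simplest model expressing the enzyme's
stated A/T preference; dinucleotide-resolved weights are a possible
extension. There is no re-cutting kinetics and no end-nibbling:
independent Bernoulli cuts are sufficient to produce the
size-selection bias under study.

### Digestion extent

`mean_cuts_per_kb` is the one genuinely free parameter: the wet-lab
enzyme units and digestion time do not translate into a cut density.
Two observations pin the default:

1. Under independent Bernoulli cuts, inter-cut spacings are geometric,
   so the *modal* pre-selection fragment length is always the minimum —
   only the mean spacing can be set meaningfully.
2. The bias mechanism requires an **over-digestion** regime. If the
   mean spacing equals the band size (~150 bp), AT-rich regions
   fragment *into* the band while GC-rich regions yield over-long
   fragments, and the GC enrichment vanishes or reverses. The mechanism
   — AT-rich ~150-mers destroyed by internal cuts, GC-rich ones
   surviving — operates when typical spacing is well below the band.

The default is `mean_cuts_per_kb = 25` (mean spacing 40 bp). At this
setting the retained-fragment GC excess on a GC-0.40 test genome is
~+0.4 percentage points per single-copy digest and grows with further
digestion; at spacing 150 it is ~0.

## The synthetic demo genome

`default_plan()` builds a 100-kb single-chromosome genome that
emulates the compositional contrasts of budding yeast:

* background drawn i.i.d. at GC 0.3977, chosen so the realized
  genome-wide GC is ~38.3%, the yeast value, after accounting for the
  embedded elements;
* 80 poly-A/poly-T tracts of 50 bp (~4% of the genome), emulating the
  long A/T runs of yeast intergenic DNA. Tract length matters: with
  the either-flank weight rule, ~84% of background bonds already carry
  the full A/T weight, so only extended tracts raise the local cut
  density enough to create the strong depletion seen at real poly-A
  runs;
* one 300-bp GC-0.80 element at position 70,000, emulating a GC-rich,
  nucleosome-free regulatory region (a UAS). Under biased digestion it
  attracts a coverage *peak* — the hallmark artifact at such elements.

What the generator does **not** emulate: real chromosomal k-mer
composition beyond these elements, replication-origin or telomeric
structure, mappability, PCR duplicates, or sequencing error. Passing
tests therefore demonstrate the internal consistency and the direction
and mechanism of the bias, not its genome-wide magnitude on real data
(real-data correlations between naked-DNA coverage and GC content are
reported around 0.76–0.80; the synthetic analogue at default depth is
~0.6 and depends on depth and genome design).

## Library depth

A "library" digests `copies` independent genome molecules and pools
the fragments (`digest_library`). The default, 2000 copies, yields
~80,000 reads on the demo genome, i.e. ~0.8 reads per genome base —
the same order as deep MNase experiments (~11 M mapped reads on the
12 Mb yeast genome). Replicate-rate analyses use 30-copy libraries
(~1200 fragments each) so that each replicate is an independent,
modestly sized experiment.

## Analyses

* **Coverage map**: each + read is extended to a 150-bp footprint
  starting at its 5′ base; each − read to 150 bp ending at its 5′
  base, so the two reads of one ~150 bp fragment produce matching
  footprints. Footprints overhanging a chromosome end are truncated
  and counted in a log line.
* **log2-centered state**: binary log of counts, genome-wide (pooled,
  not per-chromosome) mean subtracted. Zero-coverage bases become
  undefined — no pseudocount is offered, because a pseudocount would
  silently change every downstream correlation; comparisons instead
  restrict to positions defined in all tracks.
* **linear-normalized state**: counts divided by the genome-wide mean;
  zeros stay defined; the value 1.0 is the genome-average reference
  line of region profiles.
* **147-bp GC track**: GC fraction of each full 147-bp window assigned
  to the central base (0-based center `i + 73` for the window starting
  at `i`). End windows are undefined rather than shrunken so every
  defined value is a same-width statistic. N bases (real assemblies
  only; the simulator never emits N) are excluded from numerator and
  denominator.
* **GC profile**: all reads aligned at their start (− reads reverse
  complemented; G/C status is complement-invariant), per-offset GC
  frequency over −2000..+2000, then a 3-bp moving average (shrinking
  at the edges) to suppress codon periodicity. Off-chromosome offsets
  contribute to neither numerator nor denominator.
* **Fragment-length estimate**: histogram of inclusive distances
  `q − p + 1` between every +-read at `p` and −-read at `q` on the
  same chromosome with `0 < d ≤ 300`, abundance-weighted mean. With
  one sequenced end per fragment there are no same-fragment pairs; the
  estimator works because many genome copies share cut boundaries at
  the same loci. With uniformly random cut sites the histogram is
  flat and the estimator is uninformative — the recovery test
  therefore tiles fixed-length fragments at fixed loci.
* **5-mer relative coverage**: every forward-strand occurrence of a
  5-mer whose 5 positions are all defined contributes the mean of
  those 5 values; the table entry averages over occurrences, each
  weighted equally. The linear-normalized track is the default input —
  "relative coverage" — so fully depleted tract interiors (coverage 0)
  count, which is what drives AAAAA/TTTTT to the bottom of the table.
  A strand-collapsed mode (k-mer merged with its reverse complement)
  is available and off by default.
* **Comparisons**: Pearson correlation and 2-D density grids over the
  positions defined in every track, via the standard two-pass formula
  with no subsampling; region reports emit per-base tables (plotting
  is a thin optional layer in `mnasebias.plotting`).

## Numerical and design choices

* Coordinates are 0-based half-open internally; BED/bedGraph files use
  their native 0-based and wiggle its 1-based convention.
* Window sums and k-mer statistics use exact integer cumulative sums;
  FFT cross-correlation (SciPy) is used for the read-distance
  histogram and GC profile, with results rounded back to the integer
  counts they represent.
* bedGraph output is run-length merged and written to 6 significant
  digits; round trips preserve defined values to that precision and
  never change the defined mask. Overlapping bedGraph intervals are an
  error.
* Determinism: every simulation is a pure function of (inputs, seed).
  The pipeline derives one sub-seed per stage from the global seed via
  `numpy.random.SeedSequence`, so stages can be re-run in isolation;
  `digest_library` draws per-copy cut patterns from a single seeded
  generator, making the pooled library reproducible.
* Degenerate inputs: an uncuttable chromosome (all weights 0) yields
  no cuts rather than an error; a chromosome shorter than the GC
  window is fully undefined with a warning; an all-zero coverage track
  cannot be log-normalized (error).

## Known limitations

* The two-level bond-weight model saturates at AT-rich composition:
  nearly every bond in a GC-0.38 background carries the full A/T
  weight, so discrimination *within* AT-rich sequence is weak and the
  depletion at short (<30 bp) tracts is modest. Dinucleotide-resolved
  weights would sharpen this.
* Digestion is single-pass Bernoulli; there is no time course, so
  "digestion extent" collapses enzyme concentration and time into one
  cut density.
* The fragment-length estimator is biased toward the window midpoint
  when boundary clustering is weak (see above).
* Real-data mode consumes mapped read starts as BED; SAM/BAM input and
  bigWig tracks are out of scope in this version.
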