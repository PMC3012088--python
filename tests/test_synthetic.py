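"""Generator and digestion-simulator behaviour.

Covers degenerate compositions, motif placement, the bond-weight cut
model with its expected-cut calibration, size selection, and read
emission -- plus the seeded-determinism contract shared by all of them.
"""

import numpy as np
import pytest
from scipy import stats

from mnasebias import (
    ChromosomePlan,
    CompositionPlan,
    DigestionParams,
    Genome,
    digest_library,
    emit_reads,
    fragment_gc_fraction,
    generate_genome,
    simulate_digestion,
)
from mnasebias.synthetic import bond_cut_probabilities


def plan_of(segments, motifs=(), seed=0, name="c1"):
    return CompositionPlan(
        chromosomes=[ChromosomePlan(name=name, segments=list(segments), motifs=list(motifs))],
        seed=seed,
    )


class TestGenerateGenome:
    def test_pure_gc_segment(self):
        genome = generate_genome(plan_of([(10, 1.0)]))
        assert set(genome.chromosomes["c1"]) <= {"G", "C"}
        assert genome.length("c1") == 10

    def test_motif_overwrites_drawn_bases(self):
        genome = generate_genome(plan_of([(8, 0.0)], motifs=[(2, "GGG")]))
        seq = genome.chromosomes["c1"]
        assert seq[2:5] == "GGG"
        assert set(seq[:2]) <= {"A", "T"} and set(seq[5:]) <= {"A", "T"}

    def test_realized_gc_within_binomial_bound(self):
        n, gc = 100_000, 0.383
        genome = generate_genome(plan_of([(n, gc)], seed=7))
        se = np.sqrt(gc * (1 - gc) / n)
        assert abs(genome.gc_fraction() - gc) < 3 * se

    def test_same_seed_same_genome(self):
        a = generate_genome(plan_of([(500, 0.5)], seed=3))
        b = generate_genome(plan_of([(500, 0.5)], seed=3))
        assert a.chromosomes == b.chromosomes

    def test_motif_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="extends past"):
            plan_of([(10, 0.5)], motifs=[(8, "AAAA")])

    def test_overlapping_motifs_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            plan_of([(20, 0.5)], motifs=[(2, "AAAA"), (4, "TTTT")])

    def test_invalid_gc_fraction_rejected(self):
        with pytest.raises(ValueError):
            plan_of([(10, 1.5)])


class TestDigestion:
    def test_uncuttable_genome_yields_nothing(self):
        genome = Genome.from_records([("c1", "G" * 1000)])
        params = DigestionParams(cut_weight_at=1.0, cut_weight_gc=0.0, seed=1)
        frags = simulate_digestion(genome, params)
        # the intact 1000-bp piece fails the 140-170 size selection
        assert frags.n_fragments == 0

    def test_expected_cut_count_calibration(self):
        # uniform-weight genome: empirical cuts across 200 seeds should
        # match mean_cuts_per_kb * length / 1000 to 3 SE
        genome = Genome.from_records([("c1", "A" * 2000)])
        params_proto = dict(
            cut_weight_at=1.0, cut_weight_gc=0.0, mean_cuts_per_kb=25.0,
            size_min=1, size_max=2000,
        )
        expected = 25.0 * 2000 / 1000
        counts = []
        for seed in range(200):
            frags = simulate_digestion(genome, DigestionParams(seed=seed, **params_proto))
            counts.append(frags.n_fragments - 1)  # k cuts -> k+1 pieces
        p = expected / 1999
        se = np.sqrt(1999 * p * (1 - p) / 200)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_interior_lengths_geometric(self):
        # with uniform bond weights, inter-cut spacings are geometric;
        # check the empirical mean spacing against 1/p
        genome = Genome.from_records([("c1", "A" * 50_000)])
        params = DigestionParams(
            cut_weight_at=1.0, cut_weight_gc=0.0, mean_cuts_per_kb=25.0,
            size_min=1, size_max=50_000, seed=9,
        )
        frags = simulate_digestion(genome, params)
        interior = frags.fragments["c1"][1:-1]
        lengths = interior[:, 1] - interior[:, 0]
        p = 25.0 / 1000
        mean, sd = 1 / p, np.sqrt(1 - p) / p
        assert abs(lengths.mean() - mean) < 3 * sd / np.sqrt(len(lengths))

    def test_gc_enrichment_of_retained_fragments(self):
        # the central mechanism: biased cutting + size selection enrich
        # retained fragments for GC relative to the genome
        plan = plan_of([(100_000, 0.5)], seed=21)
        genome = generate_genome(plan)
        params = DigestionParams(cut_weight_at=50.0, cut_weight_gc=1.0, seed=4)
        frags = digest_library(genome, params, n_copies=40, seed=31)
        assert frags.n_fragments >= 1000
        frag_gc = fragment_gc_fraction(genome, frags)
        genome_gc = genome.gc_fraction()
        n_bases = int(frags.lengths().sum())
        se = np.sqrt(genome_gc * (1 - genome_gc) / n_bases)
        assert frag_gc - genome_gc > 3 * se

    def test_size_selection_band_respected(self, demo_genome):
        params = DigestionParams(seed=5)
        frags = simulate_digestion(demo_genome, params)
        lengths = frags.lengths()
        assert lengths.min() >= params.size_min
        assert lengths.max() <= params.size_max

    def test_fragments_inside_chromosome(self, demo_genome):
        frags = simulate_digestion(demo_genome, DigestionParams(seed=6))
        for name, arr in frags.fragments.items():
            assert arr[:, 0].min() >= 0
            assert arr[:, 1].max() <= demo_genome.length(name)

    def test_same_seed_same_fragments(self, demo_genome):
        a = simulate_digestion(demo_genome, DigestionParams(seed=8))
        b = simulate_digestion(demo_genome, DigestionParams(seed=8))
        for name in a.fragments:
            np.testing.assert_array_equal(a.fragments[name], b.fragments[name])

    def test_probability_overflow_raises(self):
        genome = Genome.from_records([("c1", "A" * 1000)])
        params = DigestionParams(mean_cuts_per_kb=2000.0, seed=0)
        with pytest.raises(ValueError, match="overflow"):
            simulate_digestion(genome, params)

    def test_bond_probabilities_keyed_on_flanks(self):
        genome = Genome.from_records([("c1", "GGAAGG")])
        params = DigestionParams(cut_weight_at=10.0, cut_weight_gc=1.0,
                                 mean_cuts_per_kb=1.0)
        p = bond_cut_probabilities(genome, params)["c1"]
        # bonds: GG, GA, AA, AG, GG -> weights 1, 10, 10, 10, 1
        np.testing.assert_allclose(p / p.min(), [1, 10, 10, 10, 1])
        assert p.sum() == pytest.approx(1.0 * 6 / 1000)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DigestionParams(cut_weight_at=1.0, cut_weight_gc=2.0)
        with pytest.raises(ValueError):
            DigestionParams(size_min=170, size_max=140)
        with pytest.raises(ValueError):
            DigestionParams(mean_cuts_per_kb=0.0)


class TestEmitReads:
    def test_single_fragment_gives_one_end_read(self):
        from mnasebias import FragmentSet

        frags = FragmentSet({"c1": np.array([[100, 250]])})
        reads = emit_reads(frags, seed=0)
        assert reads.n_reads == 1
        if reads.n_plus == 1:
            assert reads.plus["c1"][0] == 100  # leftmost base
        else:
            assert reads.minus["c1"][0] == 249  # rightmost base of [100, 250)

    def test_reads_map_one_to_one_onto_fragments(self, demo_genome):
        frags = digest_library(demo_genome, DigestionParams(seed=1), 20, seed=2)
        reads = emit_reads(frags, seed=3)
        assert reads.n_reads == frags.n_fragments
        starts = set(frags.fragments["chrS"][:, 0])
        ends = set(frags.fragments["chrS"][:, 1] - 1)
        assert set(reads.plus["chrS"]) <= starts
        assert set(reads.minus["chrS"]) <= ends

    def test_strand_fraction_binomial_bound(self, demo_library):
        fragments, reads = demo_library
        assert reads.n_reads >= 10_000
        frac = reads.n_plus / reads.n_reads
        se = 0.5 / np.sqrt(reads.n_reads)
        assert abs(frac - 0.5) < 3 * se

    def test_same_seed_same_reads(self, demo_genome):
        frags = digest_library(demo_genome, DigestionParams(seed=1), 5, seed=2)
        a = emit_reads(frags, seed=9)
        b = emit_reads(frags, seed=9)
        for name in a.plus:
            np.testing.assert_array_equal(a.plus[name], b.plus[name])
            np.testing.assert_array_equal(a.minus[name], b.minus[name])


class TestNeutralityControl:
    def test_equal_weights_give_unbiased_fragment_gc(self):
        """With no cutting preference the retained fragments' GC matches
        the genome's within binomial noise (z-test at alpha=0.01 passes
        in >= 95% of replicates)."""
        plan = plan_of([(100_000, 0.40)], seed=17)
        genome = generate_genome(plan)
        genome_gc = genome.gc_fraction()
        passes = 0
        n_reps = 40
        for rep in range(n_reps):
            params = DigestionParams(cut_weight_at=1.0, cut_weight_gc=1.0, seed=rep)
            frags = digest_library(genome, params, n_copies=10, seed=700 + rep)
            n = int(frags.lengths().sum())
            z = (fragment_gc_fraction(genome, frags) - genome_gc) / np.sqrt(
                genome_gc * (1 - genome_gc) / n
            )
            passes += abs(z) < stats.norm.ppf(0.995)
        assert passes >= 0.95 * n_reps
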