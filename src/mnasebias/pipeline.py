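"""End-to-end pipeline: simulate -> pileup -> normalize -> GC -> k-mers.

One ``RunConfig`` drives a full run; every intermediate is written to
the output directory and a JSON manifest records the resolved
configuration, derived seeds and summary statistics. A single global
seed deterministically derives one sub-seed per stage (via
``numpy.random.SeedSequence(seed).generate_state``), so any stage can be
re-run in isolation and two runs with the same config are identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .comparison import correlate
from .coverage import (
    DEFAULT_EXTENSION,
    DEFAULT_FRAGLEN_WINDOW,
    estimate_fragment_length,
    normalize_linear,
    normalize_log2,
    pileup,
)
from .gc_tracks import (
    DEFAULT_GC_WINDOW,
    DEFAULT_PROFILE_FLANK,
    DEFAULT_PROFILE_SMOOTH,
    gc_profile_around_read_starts,
    gc_window_track,
)
from .kmer_coverage import DEFAULT_K, kmer_mean_coverage
from .synthetic import (
    CompositionPlan,
    DigestionParams,
    default_plan,
    digest_library,
    emit_reads,
    fragment_gc_fraction,
    generate_genome,
)
from .track_io import read_fasta, write_fasta, write_fragments_bed, write_read_starts_bed, write_track

logger = logging.getLogger(__name__)

#: Library depth: genome copies digested per run. The default gives
#: roughly one read per genome base on the 100-kb demo genome, emulating
#: deep-sequencing read density.
DEFAULT_COPIES = 2000

_STAGES = ("genome", "digestion", "reads")


@dataclass
class RunConfig:
    """Resolved parameter set of one pipeline run.

    Defaults are the analysis constants used throughout: 150-bp read
    extension, 147-bp GC window, 300-bp fragment-length window,
    +/-2000-bp GC profile with 3-bp smoothing, k = 5, and a 140-170 bp
    size-selection band inside ``digestion``.
    """

    outdir: str = "mnasebias_run"
    seed: int = 0
    genome_fasta: str | None = None  # if None, generate from plan
    plan: CompositionPlan | None = None  # if None too, use default_plan
    digestion: DigestionParams = field(default_factory=DigestionParams)
    copies: int = DEFAULT_COPIES
    extension: int = DEFAULT_EXTENSION
    gc_window: int = DEFAULT_GC_WINDOW
    kmer_k: int = DEFAULT_K
    profile_flank: int = DEFAULT_PROFILE_FLANK
    profile_smooth: int = DEFAULT_PROFILE_SMOOTH
    fraglen_window: int = DEFAULT_FRAGLEN_WINDOW

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "digestion" in kwargs and isinstance(kwargs["digestion"], dict):
            kwargs["digestion"] = DigestionParams(**kwargs["digestion"])
        if "plan" in kwargs and isinstance(kwargs["plan"], dict):
            kwargs["plan"] = plan_from_dict(kwargs["plan"])
        return cls(**kwargs)

    def resolved(self) -> dict:
        out = asdict(self)
        if self.plan is not None:
            out["plan"] = asdict(self.plan)
        return out


def plan_from_dict(raw: dict) -> CompositionPlan:
    """Build a CompositionPlan from the YAML mapping layout."""
    from .synthetic import ChromosomePlan

    chroms = []
    for c in raw["chromosomes"]:
        segments = [(int(s["length"]), float(s["gc"])) for s in c["segments"]]
        motifs = [
            (int(m["position"]), str(m["sequence"]).upper())
            for m in c.get("motifs", [])
        ]
        chroms.append(ChromosomePlan(name=c["name"], segments=segments, motifs=motifs))
    return CompositionPlan(chromosomes=chroms, seed=int(raw.get("seed", 0)))


def derive_stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage sub-seeds from the global seed."""
    state = np.random.SeedSequence(seed).generate_state(len(_STAGES))
    return {stage: int(s) for stage, s in zip(_STAGES, state)}


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages, write intermediates, return the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = derive_stage_seeds(config.seed)
    manifest: dict = {
        "version": __version__,
        "config": config.resolved(),
        "stage_seeds": seeds,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    def stage(name):
        logger.info("pipeline stage: %s", name)

    try:
        stage("genome")
        if config.genome_fasta is not None:
            genome = read_fasta(config.genome_fasta)
        else:
            plan = config.plan or default_plan(seed=seeds["genome"])
            genome = generate_genome(plan)
        write_fasta(genome, outdir / "genome.fa")
        genome_gc = genome.gc_fraction()

        stage("digestion")
        fragments = digest_library(
            genome, config.digestion, n_copies=config.copies, seed=seeds["digestion"]
        )
        write_fragments_bed(fragments, outdir / "fragments.bed")
        if fragments.n_fragments == 0:
            raise RuntimeError("digestion produced no size-selected fragments")
        frag_gc = fragment_gc_fraction(genome, fragments)

        stage("reads")
        reads = emit_reads(fragments, seed=seeds["reads"])
        write_read_starts_bed(reads, outdir / "reads.bed")

        stage("fragment_length")
        fraglen = estimate_fragment_length(reads, window=config.fraglen_window)
        with open(outdir / "fragment_length.tsv", "w") as fh:
            fh.write("distance\tcount\n")
            for d, c in sorted(fraglen.histogram.items()):
                fh.write(f"{d}\t{c}\n")

        stage("coverage")
        raw = pileup(reads, genome, extension=config.extension)
        write_track(raw, outdir / "coverage_raw.bedgraph")
        cov_log2 = normalize_log2(raw)
        write_track(cov_log2, outdir / "coverage_log2.bedgraph")
        cov_linear = normalize_linear(raw)
        write_track(cov_linear, outdir / "coverage_linear.bedgraph")

        stage("gc_tracks")
        gc_raw = gc_window_track(genome, window=config.gc_window, centered=False)
        write_track(gc_raw, outdir / "gc_window.bedgraph")
        gc_centered = gc_window_track(genome, window=config.gc_window, centered=True)
        write_track(gc_centered, outdir / "gc_window_log2.bedgraph")

        stage("gc_profile")
        profile = gc_profile_around_read_starts(
            genome, reads, flank=config.profile_flank, smooth=config.profile_smooth
        )
        _write_profile(profile, outdir / "gc_profile.tsv")

        stage("kmers")
        kmers = kmer_mean_coverage(cov_linear, genome, k=config.kmer_k)
        kmers.to_tsv(outdir / "kmer_coverage.tsv")

        stage("comparison")
        cov_vs_gc = correlate(cov_log2, gc_centered)
    except Exception as exc:  # annotate with the failing stage
        raise RuntimeError(f"pipeline failed: {exc}") from exc

    frag_band = profile.mean_over(0, config.extension - 1)
    upstream = profile.mean_over(-500, -200)
    manifest["summary"] = {
        "n_fragments": fragments.n_fragments,
        "n_reads": reads.n_reads,
        "mean_fragment_length_true": float(fragments.lengths().mean()),
        "mean_fragment_length_estimate": fraglen.mean_length,
        "genome_gc": genome_gc,
        "fragment_gc": frag_gc,
        "fragment_gc_excess": frag_gc - genome_gc,
        "gc_profile_fragment_band": frag_band,
        "gc_profile_upstream": upstream,
        "coverage_vs_gc_r": cov_vs_gc.r,
        "coverage_vs_gc_n": cov_vs_gc.n_positions,
        "kmer_lowest_two": kmers.lowest(2),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _write_profile(profile, path) -> None:
    with open(path, "w") as fh:
        fh.write("offset\traw_gc\tsmoothed_gc\tn\n")
        for o, r, s, n in zip(
            profile.offsets, profile.raw_gc, profile.gc_frequency, profile.n
        ):
            fh.write(f"{o}\t{r:.6g}\t{s:.6g}\t{n}\n")
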