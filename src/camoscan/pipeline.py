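"""End-to-end orchestration with a single config, fixed seeds and manifests.

``synthetic`` mode needs no external files: the generator produces the
reference, panel and population. ``replication`` mode points the same
stages at user-supplied FASTA/BED/VCF files instead (external genomes are
never fetched here).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .evaluate import (CamoRegion, call_camo_regions, camo_regions_to_frame,
                       classify_reads, correctness_summary, depth_track,
                       read_length_rescue_table, summaries_by_population,
                       write_camo_bed)
from .formats import write_bed, write_vcf
from .homology import (compute_mappability, exon_mean_mappability, flag_panel,
                       search_panel)
from .intervals import GenomicInterval, Panel
from .mapping import AlignmentSet, GenomeIndex, MapperConfig, map_batch
from .popgen import (depth_fst_correlation, fst_windows, genotype_pca,
                     pairwise_fst)
from .reference import Reference
from .rescue import (Scenario, build_scenarios, run_all_strategies,
                     verdicts_to_frame)
from .simulate import ReadBatch, SimulationConfig, simulate_individual
from .synth import (PopulationConfig, PopulationGenotypes,
                    SyntheticGenomeConfig, make_reference,
                    simulate_population_genotypes)

READ_LENGTHS = (70, 100, 150, 250)


@dataclass
class RunConfig:
    mode: str = "synthetic"
    seed: int = 0
    read_lengths: tuple[int, ...] = READ_LENGTHS
    genome: SyntheticGenomeConfig = field(default_factory=SyntheticGenomeConfig)
    population: PopulationConfig = field(default_factory=PopulationConfig)
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    mapper: MapperConfig = field(default_factory=MapperConfig)
    n_individuals: int = 1        # individuals carried through sim/eval
    # replication-mode inputs
    reference_fasta: str | None = None
    exon_bed: str | None = None

    def __post_init__(self):
        if self.mode not in ("synthetic", "replication"):
            raise ValueError("mode must be 'synthetic' or 'replication'")
        if self.mode == "replication" and not (
            self.reference_fasta and self.exon_bed
        ):
            raise ValueError(
                "replication mode requires reference_fasta and exon_bed"
            )
        bad = set(self.read_lengths) - set(READ_LENGTHS)
        if bad:
            raise ValueError(f"unsupported read lengths: {sorted(bad)}")

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(
            self, seed=seed,
            genome=replace(self.genome, seed=seed),
            population=replace(self.population, seed=seed + 1),
            sim=replace(self.sim, seed=seed + 2),
        )


def config_manifest(config: RunConfig) -> dict:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return dict(
        version=__version__,
        seed=config.seed,
        config=json.loads(blob),
        config_sha256=hashlib.sha256(blob.encode()).hexdigest(),
        created=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )


def load_inputs(config: RunConfig):
    """(reference, panel, camo_truth) for the configured mode."""
    if config.mode == "synthetic":
        return make_reference(config.genome)
    from .formats import read_bed

    reference = Reference.from_fasta(config.reference_fasta)
    exons = read_bed(config.exon_bed)
    from .intervals import Gene, merge_intervals

    genes = []
    by_gene: dict[str, list[GenomicInterval]] = {}
    for ex in exons:
        by_gene.setdefault(ex.name.split(".")[0] or "GENE", []).append(ex)
    for name, exs in by_gene.items():
        exs = merge_intervals(exs)
        hull = GenomicInterval(exs[0].contig, exs[0].start, exs[-1].end, name)
        genes.append(Gene(name, hull, tuple(exs)))
    return reference, Panel(tuple(genes)), []


# ----------------------------------------------------------------- stages

@dataclass
class FlagResult:
    exon_mappability: pd.DataFrame
    hits: pd.DataFrame
    flags: pd.DataFrame

    @property
    def flagged_genes(self) -> list[str]:
        return self.flags.loc[self.flags["flagged"], "gene"].tolist()


def run_flag(reference: Reference, panel: Panel, k: int = 75) -> FlagResult:
    """Mappability + homology screen -> per-gene flags."""
    track = compute_mappability(reference, k=k)
    buffered = panel.buffered_exons(reference.lengths)
    exon_mapp = exon_mean_mappability(track, buffered)
    hits = search_panel(panel, reference)
    return FlagResult(exon_mapp, hits, flag_panel(panel, exon_mapp, hits))


@dataclass
class LengthEval:
    read_length: int
    aset: AlignmentSet
    categories: np.ndarray
    summary: pd.DataFrame
    depth: "object"      # DepthTrack at MAPQ >= 10
    camo_depth: "object"  # DepthTrack at MAPQ >= 20
    camo: list[CamoRegion]


@dataclass
class SimEvalResult:
    per_length: dict[int, LengthEval]
    rescue_table: pd.DataFrame | None


def run_simeval(
    reference: Reference, panel: Panel, config: RunConfig,
    genotypes: PopulationGenotypes | None = None,
    annotation: list[GenomicInterval] | None = None,
    keep_alignments: bool = False,
) -> SimEvalResult:
    """Simulate, map and evaluate at each configured read length.

    Reads come from the first ``n_individuals`` of the population (their
    genotypes become haplotype variants); with no population, a single
    reference-homozygous individual is used.
    """
    regions = panel.simulation_regions(reference.lengths)
    index = GenomeIndex(reference, config.mapper.seed_length)
    per_length: dict[int, LengthEval] = {}
    individuals = [("REF_I01", [])]
    if genotypes is not None:
        individuals = [
            (ind, genotypes.vcf_records(ind))
            for ind in genotypes.individuals[:config.n_individuals]
        ]
    for li, rl in enumerate(sorted(config.read_lengths)):
        sim = replace(config.sim, read_length=rl,
                      seed=config.sim.seed + 1000 * li)
        batches = []
        for ii, (ind, records) in enumerate(individuals):
            one = replace(sim, seed=sim.seed + ii)
            batches.append(
                simulate_individual(reference, records, regions, one,
                                    individual=ind)
            )
        batch = ReadBatch.concat(batches)
        aset = map_batch(batch, index, config.mapper,
                         fragment_mean=2 * rl + sim.inner_distance_mean,
                         fragment_sd=sim.inner_distance_sd)
        categories = classify_reads(aset)
        summary = correctness_summary(categories, aset, read_length=rl)
        depth10 = depth_track(aset, regions, mq_min=10)
        depth20 = depth_track(aset, regions, mq_min=20)
        camo = call_camo_regions(depth20, panel, aset, annotation=annotation)
        per_length[rl] = LengthEval(
            rl, aset if keep_alignments else None, categories, summary,
            depth10, depth20, camo,
        )
    rescue = None
    if set(config.read_lengths) >= set(READ_LENGTHS):
        rescue = read_length_rescue_table(
            {rl: ev.camo for rl, ev in per_length.items()}, panel,
        )
    return SimEvalResult(per_length, rescue)


@dataclass
class PopgenResult:
    pca: "object"
    pairwise: pd.DataFrame
    windows: pd.DataFrame


def run_popgen(genotypes: PopulationGenotypes, panel: Panel,
               window_size: int = 1000) -> PopgenResult:
    pca = genotype_pca(genotypes.genotypes, genotypes.labels)
    pw = pairwise_fst(genotypes)
    site_pos = np.array([s.pos for s in genotypes.sites])
    windows = fst_windows(
        genotypes.genotypes, genotypes.labels, site_pos,
        panel.gene_bodies(), window_size=window_size,
    )
    return PopgenResult(pca, pw, windows)


def run_rescue(reference: Reference, panel: Panel, pairs,
               gene: str | None = None, n_scenarios: int = 11,
               seed: int = 0,
               sim: SimulationConfig | None = None) -> pd.DataFrame:
    """Strategy-verdict table over the scenario library of one camo gene."""
    pair = next(
        (p for p in pairs if gene is None or p.gene == gene), None
    )
    if pair is None:
        raise ValueError("no camo gene available for rescue scenarios")
    scenarios = build_scenarios(reference, panel, pair, n=n_scenarios,
                                seed=seed, sim=sim)
    verdicts = []
    for sc in scenarios:
        verdicts.extend(run_all_strategies(sc, seed=seed).values())
    return verdicts_to_frame(verdicts)


# ---------------------------------------------------------------- outputs

def write_flag_artifacts(outdir: Path, result: FlagResult) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.exon_mappability.to_csv(
        outdir / "exon_mappability.tsv", sep="\t", index=False
    )
    result.hits.to_csv(outdir / "homology_hits.tsv", sep="\t", index=False)
    result.flags.to_csv(outdir / "gene_flags.tsv", sep="\t", index=False)


def write_simeval_artifacts(outdir: Path, result: SimEvalResult) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    summaries = pd.concat(
        [ev.summary for ev in result.per_length.values()], ignore_index=True
    )
    summaries.to_csv(outdir / "mapping_accuracy.tsv", sep="\t", index=False)
    for rl, ev in result.per_length.items():
        camo_regions_to_frame(ev.camo).to_csv(
            outdir / f"camo_regions_{rl}bp.tsv", sep="\t", index=False
        )
        write_camo_bed(outdir / f"camo_regions_{rl}bp.bed", ev.camo)
    if result.rescue_table is not None:
        result.rescue_table.to_csv(
            outdir / "read_length_rescue.tsv", sep="\t", index=False
        )


def write_generate_artifacts(outdir: Path, reference: Reference,
                             panel: Panel, camo_truth,
                             genotypes: PopulationGenotypes | None) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    reference.to_fasta(outdir / "reference.fasta")
    write_bed(outdir / "exons.bed", panel.all_exons())
    write_bed(outdir / "genes.bed", panel.gene_bodies())
    truth = [p.gene_tract for p in camo_truth] + \
        [p.pseudo_tract for p in camo_truth]
    write_bed(outdir / "camo_truth.bed", truth)
    if genotypes is not None:
        vcf_dir = outdir / "vcf"
        vcf_dir.mkdir(exist_ok=True)
        lengths = reference.lengths
        for ind in genotypes.individuals:
            write_vcf(vcf_dir / f"{ind}.vcf", genotypes.vcf_records(ind),
                      lengths, sample=ind)
        with open(outdir / "individuals.tsv", "w") as fh:
            fh.write("individual\tpopulation\n")
            for ind, lab in zip(genotypes.individuals, genotypes.labels):
                fh.write(f"{ind}\t{lab}\n")
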