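"""Ploidy-aware pileup genotyping and pseudogene-aware rescue strategies.

Four calling strategies are compared on planted-variant scenarios in a gene
with a high-identity pseudogene copy:

* ``standard``       — default fragment model, calls at ploidy 2, MQ >= 20;
* ``lowered_mq``     — same, but reads down to MQ 10 enter the pileup;
* ``long_inner_distance`` — re-simulate with the pair inner distance raised
  to 255 bp so mates reach unique sequence and rescue ambiguous reads;
* ``masked_ploidy4`` — hard-mask the pseudogene tract (plus 2 kb flanks) in
  the reference, simulate reads from BOTH the gene and the pseudogene
  (residual capture of the pseudogene is expected even when the gene is
  targeted), and call the combined pileup at ploidy 4. A gene variant also
  present in the pseudogene then appears at full dosage (1/1/1/1) while
  pseudogene-divergence sites appear at half dosage (0/0/1/1).

The genotyper is a pileup caller: with substitution-only reads at a known
low error rate, coverage- and MAPQ-driven phenomena — the ones studied
here — are fully captured without local reassembly. Allele-dosage
likelihood for dosage d at ploidy P over e = base error:
P(alt read) = (d/P)(1-e) + (1-d/P)(e/3), flat prior over dosages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _seq
from .intervals import GenomicInterval, Panel
from .mapping import AlignmentSet, GenomeIndex, MapperConfig, map_batch
from .reference import Reference
from .simulate import SimulationConfig, make_variant_readset
from .synth import CamoPair, PlantedVariant, plant_variant

STRATEGIES = ("standard", "lowered_mq", "long_inner_distance",
              "masked_ploidy4")


@dataclass(frozen=True)
class CallerConfig:
    ploidy: int = 2
    mq_min: int = 20
    base_error: float = 0.0024   # matches the simulator's substitution rate
    min_depth: int = 4
    min_call_qual: float = 30.0  # Phred posterior margin

    def __post_init__(self):
        if self.ploidy < 1:
            raise ValueError("ploidy must be >= 1")
        if self.mq_min < 0 or self.min_depth < 0 or self.min_call_qual < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass(frozen=True)
class PloidyGenotype:
    """Allele-dosage genotype at arbitrary ploidy with Phred quality."""

    contig: str
    pos: int
    ref: str
    alt: str
    dosage: int
    ploidy: int
    qual: float

    @property
    def gt_string(self) -> str:
        return "/".join(
            ["0"] * (self.ploidy - self.dosage) + ["1"] * self.dosage
        )


@dataclass(frozen=True)
class NoCall:
    contig: str
    pos: int
    reason: str


def _clip_bounds(read_row: np.ndarray, genome: np.ndarray, gpos: int
                 ) -> tuple[int, int]:
    """Soft-clip emulation: the maximum-scoring contiguous read segment.

    The gapless mapper reports full-length placements; reads that run off a
    homology tract into unrelated sequence carry junk tails a production
    aligner would soft-clip. Scoring match +1 / mismatch -5 per base, the
    best-scoring contiguous segment (Kadane) defines the usable span;
    bases outside it are excluded from pileups.
    """
    seg = genome[gpos:gpos + read_row.size]
    vals = np.where((read_row == seg) & (seg < 4), 1, -5)
    prefix = np.concatenate([[0], np.cumsum(vals)])
    run_min = np.minimum.accumulate(prefix[:-1])
    gains = prefix[1:] - run_min
    hi = int(np.argmax(gains)) + 1
    lo = int(np.argmin(prefix[:hi]))
    return lo, hi


def pileup(aset: AlignmentSet, contig: str, pos: int, mq_min: int = 20
           ) -> dict[str, int]:
    """Base counts at one site over alignments with MAPQ >= mq_min.

    Bases outside a read's best-scoring contiguous segment (the soft-clip
    emulation, see ``_clip_bounds``) are excluded.
    """
    g = aset.index.to_global(contig, pos)
    reads = aset.reads_overlapping(g, g + 1)
    genome = aset.index.genome
    counts = {b: 0 for b in "ACGT"}
    for r in reads.tolist():
        if aset.mapq[r] < mq_min:
            continue
        off = int(g - aset.gpos[r])
        lo, hi = _clip_bounds(aset.oriented[r], genome, int(aset.gpos[r]))
        if not (lo <= off < hi):
            continue
        base = int(aset.oriented[r, off])
        if base < 4:
            counts[_seq.BASES[base]] += 1
    return counts


def call_genotype(counts: dict[str, int], config: CallerConfig,
                  ref: str, alt: str | None = None,
                  contig: str = ".", pos: int = 0
                  ) -> PloidyGenotype | NoCall:
    """Maximum-likelihood allele dosage from a biallelic pileup.

    ``alt`` defaults to the most frequent non-reference base. No-call when
    covering reads are below ``min_depth`` or the Phred posterior margin
    between the best and second-best dosage is below ``min_call_qual``.
    """
    if alt is None:
        others = {b: c for b, c in counts.items() if b != ref}
        alt = max(others, key=others.get) if any(others.values()) else None
        if alt is None:
            alt = next(b for b in "ACGT" if b != ref)
    n_ref, n_alt = counts.get(ref, 0), counts.get(alt, 0)
    depth = n_ref + n_alt
    if depth == 0:
        return NoCall(contig, pos, "no coverage")
    if depth < config.min_depth:
        return NoCall(contig, pos, "below min depth")
    e = config.base_error
    P = config.ploidy
    logliks = []
    for d in range(P + 1):
        f = d / P
        p_alt = f * (1 - e) + (1 - f) * (e / 3)
        p_ref = (1 - f) * (1 - e) + f * (e / 3)
        ll = (n_alt * math.log(max(p_alt, 1e-300))
              + n_ref * math.log(max(p_ref, 1e-300)))
        logliks.append(ll)
    order = sorted(range(P + 1), key=lambda d: -logliks[d])
    best, second = order[0], order[1]
    margin = 10.0 / math.log(10) * (logliks[best] - logliks[second])
    if margin < config.min_call_qual:
        return NoCall(contig, pos, "low genotype quality")
    return PloidyGenotype(contig, pos, ref, alt, best, P, round(margin, 2))


def mask_reference(reference: Reference,
                   intervals: list[GenomicInterval],
                   flank: int = 0) -> Reference:
    """Hard-mask intervals (plus flanks) with N so no seed can anchor there."""
    return reference.mask(intervals, flank=flank)


def scan_variants(aset: AlignmentSet, reference: Reference,
                  region: GenomicInterval, config: CallerConfig,
                  min_alt_reads: int = 3
                  ) -> list[PloidyGenotype]:
    """Call every site in ``region`` showing non-reference evidence.

    A site enters genotyping when at least ``min_alt_reads`` MAPQ-passing
    reads carry the same non-reference base; emitted calls have dosage > 0.
    """
    idx = aset.index
    g0 = idx.to_global(region.contig, region.start)
    L = len(region)
    counts = np.zeros((4, L), dtype=np.int32)
    reads = aset.reads_overlapping(g0, g0 + L)
    rl = aset.read_length
    for r in reads.tolist():
        if aset.mapq[r] < config.mq_min:
            continue
        start = int(aset.gpos[r]) - g0
        clo, chi = _clip_bounds(aset.oriented[r], aset.index.genome,
                                int(aset.gpos[r]))
        lo, hi = max(0, start + clo), min(L, start + chi)
        if lo >= hi:
            continue
        seg = aset.oriented[r, lo - start:hi - start]
        valid = seg < 4
        cols = np.arange(lo, hi)[valid]
        counts[seg[valid], cols] += 1
    ref_codes = reference.fetch(region)
    out: list[PloidyGenotype] = []
    for j in range(L):
        rc = int(ref_codes[j])
        if rc >= 4:
            continue
        col = counts[:, j]
        alt_counts = [(int(col[b]), b) for b in range(4) if b != rc]
        best_alt = max(alt_counts)
        if best_alt[0] < min_alt_reads:
            continue
        site_counts = {_seq.BASES[b]: int(col[b]) for b in range(4)}
        call = call_genotype(
            site_counts, config, _seq.BASES[rc], _seq.BASES[best_alt[1]],
            region.contig, region.start + j,
        )
        if isinstance(call, PloidyGenotype) and call.dosage > 0:
            out.append(call)
    return out


def discriminate_calls(calls: list[PloidyGenotype]) -> dict[str, list]:
    """Partition ploidy-4 calls: dosage 4 = target gene, 2 = pseudogene-only.

    Other dosages are ambiguous; interpreting them is unreliable when many
    additional variants are called.
    """
    out: dict[str, list] = {"target": [], "pseudogene": [], "ambiguous": []}
    for c in calls:
        if c.ploidy != 4:
            raise ValueError("discrimination applies to ploidy-4 call sets")
        if c.dosage == 4:
            out["target"].append(c)
        elif c.dosage == 2:
            out["pseudogene"].append(c)
        else:
            out["ambiguous"].append(c)
    return out


# --------------------------------------------------------------- scenarios

@dataclass
class Scenario:
    """A planted-variant calling scenario on one camo gene."""

    reference: Reference
    panel: Panel
    pair: CamoPair
    variant: PlantedVariant
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    name: str = ""


@dataclass
class StrategyVerdict:
    scenario: str
    strategy: str
    called: bool
    genotype: str | None
    site_depth: int
    n_extra_calls: int
    extra_calls: list[PloidyGenotype]


def run_strategy(scenario: Scenario, strategy: str,
                 mapper: MapperConfig | None = None,
                 seed: int | None = None) -> StrategyVerdict:
    """Execute one calling strategy end to end and record the verdict."""
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    mapper = mapper or MapperConfig()
    ref = scenario.reference
    panel = scenario.panel
    gene = panel.gene(scenario.pair.gene)
    flank = panel.flank
    clens = ref.lengths
    gene_region = gene.interval.pad(flank, contig_length=clens[
        gene.interval.contig])
    regions = [gene_region]
    sim = scenario.sim
    if seed is not None:
        sim = replace(sim, seed=seed)
    caller = CallerConfig(ploidy=2, mq_min=20, base_error=sim.error_rate)

    map_ref = ref
    if strategy == "lowered_mq":
        caller = replace(caller, mq_min=10)
    elif strategy == "long_inner_distance":
        sim = replace(sim, inner_distance_mean=255.0)
    elif strategy == "masked_ploidy4":
        caller = replace(caller, ploidy=4)
        map_ref = mask_reference(ref, [scenario.pair.pseudo_tract],
                                 flank=2000)
        regions = regions + [
            scenario.pair.pseudo_tract.pad(
                flank, contig_length=clens[scenario.pair.pseudo_tract.contig]
            )
        ]

    records = plant_variant(ref, gene, scenario.variant)
    batch = make_variant_readset(ref, records, regions, sim,
                                 individual=scenario.name or "scenario")
    index = GenomeIndex(map_ref, mapper.seed_length)
    aset = map_batch(batch, index, mapper,
                     fragment_mean=2 * sim.read_length
                     + sim.inner_distance_mean,
                     fragment_sd=sim.inner_distance_sd)

    calls = scan_variants(aset, map_ref, gene.interval, caller)
    site = scenario.variant.site
    target = [c for c in calls
              if c.pos == site.start and c.alt == scenario.variant.alt]
    extras = [c for c in calls if c.pos != site.start]
    site_counts = pileup(aset, site.contig, site.start, caller.mq_min)
    return StrategyVerdict(
        scenario=scenario.name, strategy=strategy,
        called=bool(target),
        genotype=target[0].gt_string if target else None,
        site_depth=sum(site_counts.values()),
        n_extra_calls=len(extras), extra_calls=extras,
    )


def run_all_strategies(scenario: Scenario,
                       mapper: MapperConfig | None = None,
                       seed: int | None = None) -> dict[str, StrategyVerdict]:
    return {s: run_strategy(scenario, s, mapper, seed) for s in STRATEGIES}


def verdicts_to_frame(verdicts: list[StrategyVerdict]) -> pd.DataFrame:
    rows = [
        dict(scenario=v.scenario, strategy=v.strategy, called=v.called,
             genotype=v.genotype or ".", site_depth=v.site_depth,
             n_extra_calls=v.n_extra_calls)
        for v in verdicts
    ]
    cols = ["scenario", "strategy", "called", "genotype", "site_depth",
            "n_extra_calls"]
    return pd.DataFrame(rows, columns=cols)


def build_scenarios(reference: Reference, panel: Panel, pair: CamoPair,
                    n: int = 11, seed: int = 0,
                    sim: SimulationConfig | None = None) -> list[Scenario]:
    """Scenario library for one camo gene: a mix of converting and
    non-converting, homozygous and heterozygous planted SNVs."""
    from .synth import make_converting_variant, make_nonconverting_variant

    rng = np.random.default_rng(seed)
    sim = sim or SimulationConfig()
    variants: list[PlantedVariant] = []
    try:
        variants.append(make_converting_variant(reference, pair, "hom"))
        variants.append(make_converting_variant(reference, pair, "het"))
    except ValueError:
        pass
    gene = panel.gene(pair.gene)
    while len(variants) < n:
        zyg = "hom" if len(variants) % 2 == 0 else "het"
        variants.append(
            make_nonconverting_variant(reference, gene, pair, rng, zyg)
        )
    return [
        Scenario(reference, panel, pair, v, sim,
                 name=f"{pair.gene}.v{i + 1}"
                 + (".conv" if v.converting else "")
                 + f".{v.zygosity}")
        for i, v in enumerate(variants[:n])
    ]
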