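"""Synthetic reference panels, population genotypes and planted variants.

The generator emulates the study system: a screening-panel-like set of genes
laid out on one contig, a few of which carry a high-identity pseudogene copy
of a central tract placed in nearby intergenic sequence; multi-population
diploid genotypes with tunable differentiation (Balding–Nichols); and
pathogenic SNVs that do or do not convert the gene toward the pseudogene
sequence.

Real gene/pseudogene homology tracts contain long exactly-identical
stretches flanked by scattered differences. To reproduce that feature with
a controlled geometry, each planted tract of length >= 1 kb keeps a
divergence-free "clear zone" around its centre containing exactly one
isolated divergence site; the total mismatch count is still drawn
Binomial(length, 1 - identity), only the positions are constrained to fall
outside the zone. The clear-zone half-widths of the default tracts are
chosen from paired-end fragment geometry so that the three read-length
regimes occur: camouflage rescued by longer reads, camouflage gone at
150 bp, and camouflage at every read length up to 250 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _seq
from .formats import VcfRecord
from .intervals import Gene, GenomicInterval, Panel
from .reference import Reference


@dataclass(frozen=True)
class TractSpec:
    """Geometry of one planted gene/pseudogene homology tract.

    ``clear_zone`` is the half-width (bp) of the divergence-free region kept
    around the tract centre; ``centre_diff`` plants one isolated divergence
    site exactly at the centre of that zone (the substrate for converting
    variants).
    """

    length: int
    identity: float
    clear_zone: int
    centre_diff: bool = True

    def __post_init__(self):
        if not (0 < self.identity <= 1):
            raise ValueError("identity must be in (0, 1]")
        if 2 * self.clear_zone >= self.length:
            raise ValueError("clear zone wider than tract")


#: Default tracts: a short tract whose camouflage longer reads rescue, a
#: CYP21A2-like 3 kb / 97.7% tract that is clean at 150 bp, and a long
#: near-identical tract no tested read length can span.
DEFAULT_TRACTS = (
    TractSpec(length=400, identity=0.995, clear_zone=190, centre_diff=False),
    TractSpec(length=3000, identity=0.977, clear_zone=450, centre_diff=True),
    TractSpec(length=6000, identity=0.999, clear_zone=1200, centre_diff=True),
)


@dataclass(frozen=True)
class SyntheticGenomeConfig:
    n_genes: int = 80
    gene_length: int = 8000
    exons_per_gene: int = 5
    exon_length: int = 250
    camo_tracts: tuple[TractSpec, ...] = DEFAULT_TRACTS
    intergenic_spacer: int = 12000
    pseudogene_offset: int = 3000  # gene end -> pseudogene tract start
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    contig: str = "chr1"
    margin: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.n_camo_genes > self.n_genes:
            raise ValueError("more camo tracts than genes")
        for t in self.camo_tracts:
            if t.length > self.gene_length:
                raise ValueError("pseudogene tract longer than gene")
            if (self.pseudogene_offset + t.length + 2000
                    > self.intergenic_spacer):
                raise ValueError("spacer too short for pseudogene + mask flank")
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base composition must sum to 1")
        if self.exons_per_gene * self.exon_length > self.gene_length:
            raise ValueError("exons do not fit in gene")

    @property
    def n_camo_genes(self) -> int:
        return len(self.camo_tracts)


@dataclass(frozen=True)
class CamoPair:
    """Truth record pairing a gene tract with its planted pseudogene copy."""

    gene: str
    gene_tract: GenomicInterval
    pseudo_tract: GenomicInterval
    identity: float

    def diff_sites(self, reference: Reference) -> np.ndarray:
        """Gene-coordinate positions where gene and pseudogene copies differ."""
        g = reference.fetch(self.gene_tract)
        p = reference.fetch(self.pseudo_tract)
        return self.gene_tract.start + np.nonzero(g != p)[0]

    def gene_to_pseudo(self, gene_pos: int) -> int:
        return self.pseudo_tract.start + (gene_pos - self.gene_tract.start)


def _camo_gene_indices(n_genes: int, n_camo: int) -> list[int]:
    return [(2 * i + 1) * n_genes // (2 * n_camo) for i in range(n_camo)]


def make_reference(
    config: SyntheticGenomeConfig,
) -> tuple[Reference, Panel, list[CamoPair]]:
    """Generate the synthetic reference, its gene panel and camo truth.

    Genes are i.i.d. random sequence; each camo gene's central tract is
    copied into the downstream intergenic spacer and mutated at
    ``1 - identity`` (mismatch count Binomial, positions outside the clear
    zone, plus the optional isolated centre difference).
    """
    rng = np.random.default_rng(config.seed)
    unit = config.gene_length + config.intergenic_spacer
    total = config.margin + config.n_genes * unit
    probs = np.asarray(config.base_composition, dtype=float)
    code = rng.choice(4, size=total, p=probs).astype(np.uint8)

    camo_idx = _camo_gene_indices(config.n_genes, config.n_camo_genes)
    genes: list[Gene] = []
    pairs: list[CamoPair] = []
    exon_step = config.gene_length / config.exons_per_gene

    for gi in range(config.n_genes):
        gstart = config.margin + gi * unit
        gend = gstart + config.gene_length
        name = f"GENE{gi + 1:03d}"
        exons = []
        for ei in range(config.exons_per_gene):
            centre = gstart + int((ei + 0.5) * exon_step)
            half = config.exon_length // 2
            exons.append(
                GenomicInterval(
                    config.contig, centre - half,
                    centre - half + config.exon_length, f"{name}.ex{ei + 1}",
                )
            )
        genes.append(
            Gene(name, GenomicInterval(config.contig, gstart, gend, name),
                 tuple(exons))
        )

        if gi in camo_idx:
            spec = config.camo_tracts[camo_idx.index(gi)]
            centre = gstart + config.gene_length // 2
            t0 = centre - spec.length // 2
            t1 = t0 + spec.length
            tract = code[t0:t1].copy()
            n_mm = rng.binomial(spec.length, 1.0 - spec.identity)
            zone_lo = spec.length // 2 - spec.clear_zone
            zone_hi = spec.length // 2 + spec.clear_zone
            allowed = np.concatenate(
                [np.arange(0, zone_lo), np.arange(zone_hi + 1, spec.length)]
            )
            n_mm = min(n_mm, allowed.size)
            mm_pos = rng.choice(allowed, size=n_mm, replace=False)
            if spec.centre_diff:
                # the isolated centre site plus a PAIR of pinned divergences
                # just outside each zone edge: rescue geometry then is a
                # property of the tract spec, not of the binomial draw, and
                # a mate spanning the zone edge carries enough divergence
                # (two sites) to outweigh a single converting mismatch
                mid = spec.length // 2
                pinned = [mid,
                          mid - spec.clear_zone - 10, mid - spec.clear_zone - 25,
                          mid + spec.clear_zone + 10, mid + spec.clear_zone + 25]
                mm_pos = np.unique(np.concatenate([mm_pos, pinned]))
            shifts = rng.integers(1, 4, size=mm_pos.size).astype(np.uint8)
            tract[mm_pos] = (tract[mm_pos] + shifts) % 4
            p0 = gend + config.pseudogene_offset
            code[p0:p0 + spec.length] = tract
            pairs.append(
                CamoPair(
                    gene=name,
                    gene_tract=GenomicInterval(config.contig, t0, t1, name),
                    pseudo_tract=GenomicInterval(
                        config.contig, p0, p0 + spec.length, f"{name}.pseudo"
                    ),
                    identity=spec.identity,
                )
            )

    reference = Reference({config.contig: code})
    panel = Panel(tuple(genes))
    return reference, panel, pairs


# ------------------------------------------------------- population model

@dataclass(frozen=True)
class PopulationConfig:
    """Balding–Nichols multi-population diploid genotype model.

    Each site draws an ancestral frequency p ~ U(ancestral_freq_range); each
    population's frequency is Beta(p(1-F)/F, (1-p)(1-F)/F) (p itself when
    F = 0); individual genotypes are Binomial(2, population frequency).
    F = 0.1 places pairwise FST estimates inside the differentiation band
    observed between human super-populations over such panels.
    """

    n_populations: int = 5
    n_per_population: int = 10
    n_sites_per_gene: int = 25
    differentiation_F: float = 0.1
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.differentiation_F < 1):
            raise ValueError("F must be in [0, 1)")
        lo, hi = self.ancestral_freq_range
        if not (0 < lo < hi < 1):
            raise ValueError("ancestral frequency range must be within (0, 1)")


@dataclass(frozen=True)
class Site:
    contig: str
    pos: int  # 0-based
    ref: str
    alt: str


@dataclass
class PopulationGenotypes:
    """Genotype table (individuals x sites, dosages in {0,1,2}) plus metadata."""

    genotypes: np.ndarray
    individuals: list[str]
    labels: list[str]
    sites: list[Site]

    def vcf_records(self, individual: str) -> list[VcfRecord]:
        """Non-reference records for one individual (0/0 omitted)."""
        i = self.individuals.index(individual)
        out = []
        for j, site in enumerate(self.sites):
            d = int(self.genotypes[i, j])
            if d == 0:
                continue
            gt = "0/1" if d == 1 else "1/1"
            out.append(VcfRecord(site.contig, site.pos, site.ref, site.alt, gt))
        return out

    def populations(self) -> list[str]:
        seen: list[str] = []
        for lab in self.labels:
            if lab not in seen:
                seen.append(lab)
        return seen


def simulate_population_genotypes(
    panel: Panel,
    config: PopulationConfig,
    reference: Reference,
) -> PopulationGenotypes:
    """Draw Balding–Nichols genotypes at sites uniform within gene bodies."""
    rng = np.random.default_rng(config.seed)
    F = config.differentiation_F
    lo, hi = config.ancestral_freq_range

    sites: list[Site] = []
    for g in panel.genes:
        span = g.interval
        pos = np.sort(
            rng.choice(len(span), size=config.n_sites_per_gene, replace=False)
        ) + span.start
        for p in pos:
            ref_code = int(reference.contig(span.contig)[p])
            if ref_code >= 4:
                continue
            alt_code = (ref_code + int(rng.integers(1, 4))) % 4
            sites.append(
                Site(span.contig, int(p), _seq.BASES[ref_code],
                     _seq.BASES[alt_code])
            )

    n_sites = len(sites)
    n_ind = config.n_populations * config.n_per_population
    genotypes = np.zeros((n_ind, n_sites), dtype=np.int8)
    individuals: list[str] = []
    labels: list[str] = []

    p_anc = rng.uniform(lo, hi, size=n_sites)
    for k in range(config.n_populations):
        pop = f"POP{k + 1}"
        if F == 0:
            p_pop = p_anc
        else:
            a = p_anc * (1 - F) / F
            b = (1 - p_anc) * (1 - F) / F
            p_pop = rng.beta(a, b)
        block = rng.binomial(2, p_pop, size=(config.n_per_population, n_sites))
        row = k * config.n_per_population
        genotypes[row:row + config.n_per_population] = block
        for i in range(config.n_per_population):
            individuals.append(f"{pop}_I{i + 1:02d}")
            labels.append(pop)

    return PopulationGenotypes(genotypes, individuals, labels, sites)


# ------------------------------------------------------- planted variants

@dataclass(frozen=True)
class PlantedVariant:
    """A single SNV planted in one gene.

    ``converting`` marks variants whose alternate allele equals the
    homologous pseudogene base at the aligned position, locally erasing the
    gene/pseudogene difference.
    """

    site: GenomicInterval
    ref: str
    alt: str
    zygosity: str  # {"hom", "het"}
    converting: bool

    def __post_init__(self):
        if len(self.site) != 1:
            raise ValueError("variant site must have length 1")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.zygosity not in ("hom", "het"):
            raise ValueError("zygosity must be 'hom' or 'het'")


def converting_sites(reference: Reference, pair: CamoPair) -> list[tuple[int, int]]:
    """Gene/pseudogene difference positions with their isolation distance.

    Returns (gene position, distance to the nearest other difference or
    tract edge) sorted by isolation, most isolated first. Converting
    variants at highly isolated sites produce the longest locally-identical
    windows and hence the strongest read-diversion effect.
    """
    diffs = pair.diff_sites(reference)
    out = []
    for d in diffs:
        others = diffs[diffs != d]
        bounds = [d - pair.gene_tract.start, pair.gene_tract.end - 1 - d]
        if others.size:
            bounds.append(int(np.min(np.abs(others - d))))
        out.append((int(d), int(min(bounds))))
    out.sort(key=lambda t: -t[1])
    return out


def make_converting_variant(
    reference: Reference,
    pair: CamoPair,
    zygosity: str = "hom",
    site: int | None = None,
) -> PlantedVariant:
    """Converting variant at the most isolated gene/pseudogene difference."""
    sites = converting_sites(reference, pair)
    if not sites:
        raise ValueError(
            f"no gene/pseudogene difference exists for {pair.gene}; "
            "a converting variant cannot be constructed"
        )
    pos = site if site is not None else sites[0][0]
    gene_base = reference.contig(pair.gene_tract.contig)[pos]
    pseudo_base = reference.contig(pair.pseudo_tract.contig)[
        pair.gene_to_pseudo(pos)
    ]
    if gene_base == pseudo_base:
        raise ValueError(f"gene and pseudogene agree at {pos}: not converting")
    return PlantedVariant(
        site=GenomicInterval(pair.gene_tract.contig, pos, pos + 1),
        ref=_seq.BASES[int(gene_base)],
        alt=_seq.BASES[int(pseudo_base)],
        zygosity=zygosity,
        converting=True,
    )


def make_nonconverting_variant(
    reference: Reference,
    gene: Gene,
    pair: CamoPair | None,
    rng: np.random.Generator,
    zygosity: str = "hom",
) -> PlantedVariant:
    """Random exonic SNV whose alt differs from any homologous base."""
    for _ in range(1000):
        exon = gene.exons[int(rng.integers(len(gene.exons)))]
        pos = int(rng.integers(exon.start, exon.end))
        ref_code = int(reference.contig(exon.contig)[pos])
        if ref_code >= 4:
            continue
        alt_code = (ref_code + int(rng.integers(1, 4))) % 4
        if pair is not None and pair.gene_tract.start <= pos < pair.gene_tract.end:
            pseudo = int(
                reference.contig(exon.contig)[pair.gene_to_pseudo(pos)]
            )
            if alt_code == pseudo:
                continue
        return PlantedVariant(
            site=GenomicInterval(exon.contig, pos, pos + 1),
            ref=_seq.BASES[ref_code],
            alt=_seq.BASES[alt_code],
            zygosity=zygosity,
            converting=False,
        )
    raise RuntimeError("could not place a non-converting variant")


def plant_variant(
    reference: Reference, gene: Gene, variant: PlantedVariant
) -> list[VcfRecord]:
    """Per-individual VCF records applying one planted variant to a gene."""
    if not gene.interval.contains(variant.site):
        raise ValueError(f"variant site {variant.site} outside gene {gene.name}")
    ref_base = _seq.BASES[int(reference.fetch(variant.site)[0])]
    if ref_base != variant.ref:
        raise ValueError(
            f"variant REF {variant.ref} does not match reference {ref_base} "
            f"at {variant.site.contig}:{variant.site.start}"
        )
    gt = "1/1" if variant.zygosity == "hom" else "0/1"
    return [
        VcfRecord(variant.site.contig, variant.site.start, variant.ref,
                  variant.alt, gt)
    ]
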