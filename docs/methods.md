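# Methods

`camoscan` studies a failure mode of short-read sequencing in gene screening
panels: when a gene shares a long, nearly identical tract with a pseudogene
or paralog, reads from that tract cannot be placed uniquely, MAPQ-filtered
coverage collapses ("camouflaged" regions), and variants inside the tract
can silently disappear from a calling pipeline. The package generates a
synthetic panel with controlled homology, simulates truth-labelled
paired-end reads, maps them with an internal aligner that reproduces
paired-end placement ambiguity, quantifies accuracy and coverage, and
evaluates rescue strategies for variants lost to a pseudogene.

## Synthetic panel and homology model

The default panel is one contig carrying 80 genes of 8 kb (5 exons of
250 bp each), separated by 12 kb intergenic spacers, i.i.d. uniform base
composition. Three genes carry a *camo tract*: a centred stretch copied
into the downstream spacer and mutated per site at rate `1 − identity`,
with the mismatch count drawn `Binomial(L, 1 − identity)`. Default tracts:

| tract | identity | clear zone (half-width) | behaviour |
|------:|---------:|---------:|-----------|
| 400 bp | 99.5% | 190 bp | camouflaged at 70 bp, rescued by longer reads |
| 3 kb  | 97.7% | 450 bp | camouflaged at 70/100 bp, clean at 150 bp |
| 6 kb  | 99.9% | 1200 bp | camouflaged at every read length up to 250 bp |

Real gene/pseudogene homology is not uniform: alignments show long exactly
identical stretches between clustered differences. The generator encodes
that feature explicitly as a divergence-free *clear zone* around the tract
centre. Tracts of ≥1 kb keep exactly one isolated divergence site at the
centre of the zone (the substrate for converting variants) plus a pinned
pair of divergences just outside each zone edge; all remaining mismatch
positions are drawn uniformly outside the zone. Pinning makes the
paired-end rescue geometry a property of the tract specification rather
than of where a binomial draw happens to land: a mate spanning the zone
edge always crosses two divergences, enough to outweigh one converting
mismatch during joint pair scoring (see below).

Zone half-widths follow from fragment geometry. A pair is trapped (both
mates ambiguous) when its whole fragment fits inside a divergence-free span
`S`; with fragment length `F = 2·read_length + inner_distance` the filtered
depth at the span centre falls below half its nominal value when
`S > 2F − read_length`. The three defaults place the spans on either side
of that inequality for the four fragment sizes (190/250/350/550 bp), which
is what produces the three read-length regimes above.

With 80 genes, homologous tracts are 0.98% of the 960 kb of simulated
sequence — small enough that panel-wide accuracy is dominated by clean
sequence, as in a real screening panel.

## Population model

Genotypes follow a Balding–Nichols model: per site an ancestral frequency
`p ~ U(0.05, 0.95)`; each of 5 populations draws its frequency from
`Beta(p(1−F)/F, (1−p)(1−F)/F)` with `F = 0.1` (F = 0 means all populations
share `p`); 10 diploid individuals per population draw genotypes
`Binomial(2, p_pop)`. 25 sites per gene are placed uniformly in gene
bodies. `F = 0.1` puts pairwise Weir–Cockerham estimates in the 0.05–0.16
band typical of human super-population comparisons over such panels. Sites
are unlinked; linkage disequilibrium, sex chromosomes and realistic allele
frequency spectra are not modelled.

Differentiation uses the Weir & Cockerham (1984) variance-components
estimator (per site `a/(a+b+c)`; multi-site and windowed estimates as
`Σa / Σ(a+b+c)`). PCA runs on true genotypes standardized per site by
`2p̂` and `√(2p̂(1−p̂))`, eigendecomposing the individual×individual
covariance — the synthetic pipeline knows genotypes exactly, so no
genotype-likelihood layer is interposed. Windows default to 1 kb
(150 bp available via the window-size argument).

## Read simulation

Per individual: heterozygous SNVs become IUPAC codes in a consensus
sequence, which splits into two haplotypes (alphabetically first base to
haplotype 1). Each haplotype is sampled at 20× expected depth (pairs =
coverage × region length / (2 × read length)) over each gene ± 2 kb flank;
the two sets combine to 40×. Fragments are `2·read_length + inner`,
`inner ~ round(N(50, 10))` truncated at 0, placed uniformly and wholly
inside the region; read-1 strand is Bernoulli(½); substitutions occur
i.i.d. at 0.0024 per base (uniform over the three alternatives); no indels,
no quality profile (constant Q40), reads with more than 5 N are redrawn.
Read names encode (individual, haplotype, contig, both true start
coordinates, strand, serial) losslessly. The simulator intentionally
produces uniform coverage — capture/amplicon bias, GC bias and PCR
duplicates are out of scope, so passing results bound what an idealized
library can achieve, not what a particular wet-lab protocol will.

## Mapper

A seed-and-extend paired-end mapper over an exact 19-mer index (both
strands; N-containing k-mers excluded). Scoring: match +1, mismatch 4, gap
open 6, gap extend 1. Candidates are scored ungapped over the full read —
with substitution-only reads a gap (≥7) can never beat a mismatch (4) — and
re-scored with a banded affine-gap alignment (band 10) when the ungapped
fit is poor. Alignments scoring below 30 are suppressed (the conventional
output floor of short-read mappers), which discards placements dominated by
unrelated sequence.

MAPQ is `min(60, 6·(S1 − S2))` with `S2 = 0` for a single candidate and 0
on ties. Pairs are resolved jointly: every combination of the top per-mate
candidates is scored as `S_a + S_b + 17·proper`, where a combination is
proper when the mates face each other within the fragment window
(mean ± 4 sd); the best combination wins (ties broken toward the lowest
coordinates) and each mate's MAPQ is the margin over the best combination
that places it elsewhere. Joint scoring is what reproduces the two central
phenomena: a mate anchored in unique sequence rescues an ambiguous mate
onto the correct copy, and a converting variant flips the optimal pairing
onto the pseudogene copy, diverting coverage away from the gene.

Pileups exclude bases outside a read's maximum-scoring contiguous segment
(match +1 / mismatch −5, Kadane), emulating the soft-clipping a production
aligner would apply where a read runs off a homology tract into unrelated
sequence.

## Evaluation

A read is *unmapped* when absent or MAPQ < 10 (such reads are filtered in
routine analyses), *correct* when on the true contig and strand within
20 bp of the true start, else *incorrect*. The 20 bp tolerance is smaller
than the shortest read and absorbs clip-induced shifts. Depth tracks count
alignments with MAPQ ≥ 10 (accuracy/coverage) or ≥ 20 (camouflage calling)
per base, all region bases reported.

Camouflaged regions are runs of bases with filtered depth < 20 at 40×,
merged when separated by ≤ 50 bp and restricted to gene bodies (flanks
exist only to keep gene-boundary coverage uniform). Two noise guards
separate camouflage from binomial sampling: a region must contain ≥ 20
sub-threshold bases and must reach a minimum depth ≤ 10 (half the
threshold). At 40×, sampling dips graze the threshold at ~1e-4 per base but
essentially never reach 10× (left-tail probability ~4e-9 per base), whereas
ambiguity-trapped cores lose unique mapping entirely and sit at 0×. Regions
are annotated with read counts, non-unique (MAPQ < 10) read counts, the
alternate candidate loci of those reads, and an exonic flag; per-gene
status across read lengths classifies genes as never-low, rescued-by-longer
or low-at-all-lengths.

## Variant rescue

The genotyper is a pileup caller: for allele dosage `d` at ploidy `P` with
base error `e`, each alt read contributes `(d/P)(1−e) + (1−d/P)e/3` and
each ref read the complement; flat prior over dosages; no call below 4
covering reads or below a Phred posterior margin of 30 between the top two
dosages. With SNV-only, low-error simulated reads this captures the
coverage- and MAPQ-driven phenomena under study without local reassembly;
the depth and quality floors stand in for the emission defaults of
production callers and are configurable.

Four strategies run end to end on planted-variant scenarios (a scenario =
reference + one planted SNV + simulation config; the library plants 11 per
camo gene, mixing converting/non-converting and hom/het):

* **standard** — inner distance 50, ploidy 2, pileup MQ ≥ 20;
* **lowered_mq** — pileup MQ ≥ 10;
* **long_inner_distance** — re-simulated at inner distance 255 so mates
  reach pinned divergences beyond the identical window and rescue the pair;
* **masked_ploidy4** — pseudogene tract + 2 kb flanks hard-masked with N,
  reads simulated from both the gene and the pseudogene (residual capture
  of the pseudogene is expected even under gene-targeted assays), calling
  at ploidy 4. A variant shared by gene and pseudogene appears at dosage 4
  (1/1/1/1); pseudogene-divergence sites appear at dosage 2 (0/0/1/1);
  other dosages are flagged ambiguous. Heterozygous plantings at ploidy 4
  yield dosage-3 calls and are supported but experimental.

## Determinism and problem sizes

Every stochastic step takes a `numpy` `default_rng` seed; fixed seeds give
byte-identical FASTA/FASTQ/SAM/TSV outputs. The default evaluation uses one
simulated individual at 40× over the 80-gene panel at all four read lengths
(~1.3 M reads in total) and completes in a few minutes on one CPU; the
population analyses use 50 individuals at 2 000 sites. These sizes were
chosen so that the full suite runs at interactive, desk scale while keeping
the homologous-tract fraction, coverage and error model at the study's
stated values.

## Known limitations

* Homology is substitution-only; indel divergence, structural variants and
  copy-number variation are out of scope (the homology search is
  correspondingly ungapped; the mapper's gapped extension exists but is
  exercised only by reads carrying indels relative to the reference).
* Exact k-mer counting underestimates the alignability of tracts diverged
  far beyond the panel's ≥97% identities.
* The MAPQ formula is a contract-preserving stand-in (ties → 0, unique →
  capped, 10/20 thresholds meaningful), not a reimplementation of any
  specific aligner's statistic.
* True genotypes replace genotype likelihoods in PCA/FST; with real
  low-coverage data an additional uncertainty layer would be required.
* Replication mode only loads user-supplied FASTA/BED inputs through the
  same stages; it fetches nothing and ships no external annotations.
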