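import numpy as np
import pytest

from camoscan import (GenomeIndex, Panel, Reference, SyntheticGenomeConfig,
                      make_reference)
from camoscan.synth import TractSpec


def small_genome_config(seed: int = 0, n_camo: int = 1) -> SyntheticGenomeConfig:
    """A few-gene panel small enough for exhaustive oracles."""
    tracts = (
        TractSpec(length=600, identity=0.98, clear_zone=150, centre_diff=True),
    )[:n_camo]
    return SyntheticGenomeConfig(
        n_genes=6, gene_length=3000, exons_per_gene=3, exon_length=200,
        camo_tracts=tracts, intergenic_spacer=6000, pseudogene_offset=2500,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_panel():
    ref, panel, truth = make_reference(small_genome_config())
    return ref, panel, truth


@pytest.fixture(scope="session")
def small_index(small_panel):
    ref, _, _ = small_panel
    return GenomeIndex(ref)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_reference(length: int, seed: int = 0, name: str = "chr1") -> Reference:
    rng = np.random.default_rng(seed)
    return Reference({name: rng.integers(0, 4, length).astype(np.uint8)})
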