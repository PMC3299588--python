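"""Shared fixtures: a small coalescent panel and a bred toy population."""

import pytest

from gsrelate.breeding import (advance_generation, assign_phenotypes,
                               compute_tbv, found_base_population)
from gsrelate.haplotypes import (sample_qtl_effects, select_loci,
                                 simulate_base_haplotypes)


@pytest.fixture(scope="session")
def small_panel():
    """3 chromosomes x 10 Mb (10 cM), 240 haplotypes, Ne = 100."""
    return simulate_base_haplotypes(
        n_haplotypes=240, n_chromosomes=3, chrom_length_bp=1e7,
        ne=100, mutation_rate=2.5e-8, seed=11)


@pytest.fixture(scope="session")
def small_selection(small_panel):
    return select_loci(small_panel, n_markers=600, n_qtl=150, seed=12)


@pytest.fixture(scope="session")
def small_effects(small_selection):
    return sample_qtl_effects(150, seed=13)


@pytest.fixture(scope="session")
def small_pop(small_panel, small_selection, small_effects):
    """8 sires x 12 dams x 2 offspring per generation, 4 generations,
    h2 = 0.3; genotypes of every generation retained."""
    pop = found_base_population(small_panel, small_selection,
                                n_males=8, n_females=100, seed=14)
    compute_tbv(pop, small_effects)
    assign_phenotypes(pop, 0.3, seed=140)
    for g in range(1, 5):
        advance_generation(pop, n_sires=8, dams_per_sire=12,
                           offspring_per_dam=2, seed=14 + g)
        compute_tbv(pop, small_effects)
        assign_phenotypes(pop, 0.3, seed=140 + g)
    return pop
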