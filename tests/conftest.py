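"""Shared fixtures: a small hand-built genome and scaled populations."""

import numpy as np
import pytest

from chloroclade import (
    GenomeFeature,
    ReferenceGenome,
    default_table3_config,
    simulate_population,
)


def _mini_sequence() -> str:
    """100 bp genome with one feature of every class at known coordinates."""
    seq = list("ACGT" * 25)

    def put(start, fragment):           # 1-based start
        seq[start - 1: start - 1 + len(fragment)] = list(fragment)

    put(11, "ATGGCTTGGAAT")             # + strand CDS: M A W N (codons at 11,14,17,20)
    put(31, "AGGAGACAT")                # - strand CDS: coding revcomp = ATGTCTCCT (M S P)
    return "".join(seq)


@pytest.fixture(scope="session")
def mini_reference() -> ReferenceGenome:
    return ReferenceGenome("mini", _mini_sequence())


@pytest.fixture(scope="session")
def mini_features() -> list[GenomeFeature]:
    return [
        GenomeFeature("geneP", "CDS", "+", ((11, 22),), phase=0),
        GenomeFeature("geneM", "CDS", "-", ((31, 39),), phase=0),
        GenomeFeature("trnX", "tRNA", "+", ((51, 60),)),
        GenomeFeature("trnY-intron", "intron", "+", ((66, 70),)),
        GenomeFeature("rrn16", "rRNA", "+", ((76, 85),)),
    ]


@pytest.fixture(scope="session")
def tiny_population():
    """Scale-100 zero-background population: planted sites only."""
    config = default_table3_config(
        genome_length=5000, scale=100, zero_background=True, seed=11
    )
    alignment, metadata, reference, features = simulate_population(config)
    return config, alignment, metadata, reference, features


@pytest.fixture(scope="session")
def noisy_population():
    """Scale-50 population with default background divergence."""
    config = default_table3_config(genome_length=4000, scale=50, seed=23)
    alignment, metadata, reference, features = simulate_population(config)
    return config, alignment, metadata, reference, features


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
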