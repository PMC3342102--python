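import numpy as np
import pytest

from pirnaprofiler import (
    LibraryConfig,
    apply_preset,
    generate_references,
    simulate_library,
)
from pirnaprofiler.align import Reference, build_index


@pytest.fixture(scope="session")
def small_refs():
    """Five transposons embedded once each in a 30 kb genome."""
    return generate_references(
        n_transposons=5, length_range=(400, 800), genome_length=30_000, seed=42
    )


@pytest.fixture(scope="session")
def small_indexes(small_refs):
    genome_index = build_index([Reference("genome", small_refs.genome, "genome")])
    te_index = build_index(
        [Reference(m.id, m.consensus, "transposon") for m in small_refs.transposons]
    )
    return genome_index, te_index


@pytest.fixture(scope="session")
def small_library(small_refs):
    """Error-free wt-ovary library of 5,000 piRNA + 500 background + 50 junk reads."""
    models = apply_preset(small_refs.transposons, "wt-ovary")
    config = LibraryConfig(
        n_pirna_reads=5_000,
        n_background_reads=500,
        n_junk_reads=50,
        seed=7,
        library_id="wt_small",
    )
    reads, truth = simulate_library(small_refs, models, config)
    return config, reads, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20120328)
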