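import numpy as np
import pytest

from gonadmir.annotate import MatureIndex
from gonadmir.core import MatureMiRNARecord
from gonadmir.simdata import build_reference, default_config, make_sample_sheet


@pytest.fixture(scope="session")
def small_config():
    return default_config(n_mirna=8, seed=3)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return build_reference(small_config)


@pytest.fixture(scope="session")
def small_index(small_bundle):
    return MatureIndex(small_bundle.matures)


@pytest.fixture(scope="session")
def two_group_sheet():
    return make_sample_sheet([6], ["testis", "ovary"], n_replicates=3)


@pytest.fixture
def handmade_mature():
    """A mature anchored in a repeat-free precursor with 12 nt flanks."""
    rng = np.random.default_rng(42)
    bases = "ACGT"
    while True:
        precursor = "".join(bases[i] for i in rng.integers(0, 4, size=60))
        start, end = 19, 41
        mature = precursor[start:end]
        # avoid internal repeats that could alias shifted alignments
        kmers = {precursor[i : i + 8] for i in range(len(precursor) - 7)}
        if len(kmers) == len(precursor) - 7:
            return MatureMiRNARecord(
                "dre-miR-hand-5p", "dre-mir-hand", "5p", mature, start, end,
                precursor,
            )
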