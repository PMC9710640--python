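import numpy as np
import pytest

from ribresolve.ispcr import BUILTIN_PRIMERS, reverse_complement
from ribresolve.simulate import GenusDesign


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture
def rng():
    return np.random.default_rng(20210919)


@pytest.fixture
def v3v4():
    return BUILTIN_PRIMERS["V3V4"]


@pytest.fixture
def v1v9():
    return BUILTIN_PRIMERS["V1V9"]


@pytest.fixture
def v3v4_template(rng):
    """A template with one exact V3V4 product: fwd + 100 random nt + rc(rev)."""
    fwd = "CCTACGGGAGGCAGCAG"
    rev_rc = reverse_complement("GACTACAAGGGTATCTAATCC")
    return fwd + random_dna(rng, 100) + rev_rc


@pytest.fixture
def shared_allele_design():
    """Three one-genome species all carrying one identical allele: the
    motif of three species rendered indistinguishable by a shared allele."""
    return GenusDesign(
        n_species=3, genomes_per_species=1, rrn_copies=(5, 5),
        allele_pool_size=6, within_genome_variants=1,
        shared_allele_plan=((0, 1, 2),), seed=11,
    )
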