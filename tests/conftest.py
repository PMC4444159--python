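import numpy as np
import pytest

from rgikit.containers import GenotypeMatrix, Locus


def make_loci(n, chrom=1, annotation=None):
    """n distinct A/G loci on one chromosome (annotation-free by default)."""
    return [
        Locus(id=f"rs{i}", chromosome=chrom, position=100 * (i + 1),
              allele_a="A", allele_b="G", annotation=annotation)
        for i in range(n)
    ]


def matrix_from_calls(calls, chrom=1, sex=None, cohort=None):
    calls = np.asarray(calls, dtype=np.int8)
    loci = make_loci(calls.shape[1], chrom=chrom)
    samples = [f"s{i}" for i in range(calls.shape[0])]
    return GenotypeMatrix(calls, loci, samples, sex=sex, cohort=cohort)


def calls_from_counts(n_hom_a, n_het, n_hom_b):
    """Column of genotype codes realizing the given counts."""
    return np.concatenate(
        [np.zeros(n_hom_a, np.int8), np.ones(n_het, np.int8), np.full(n_hom_b, 2, np.int8)]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_matrix(rng):
    """50 samples x 30 loci, common variants, no missingness."""
    f = rng.uniform(0.2, 0.5, 30)
    return matrix_from_calls(rng.binomial(2, f, size=(50, 30)))
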