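import numpy as np
import pytest

from genomiss import Genotype, GenotypeMatrix, MISSING, Site


def gt(token: str) -> Genotype:
    """Build a Genotype from a VCF-style token like '0|1', './.', '0/.'."""
    phased = "|" in token
    left, right = token.replace("|", "/").split("/")
    conv = lambda p: MISSING if p == "." else int(p)
    return Genotype(conv(left), conv(right), phased)


def build_matrix(records, sample_names=None) -> GenotypeMatrix:
    """Build a matrix from (chrom, pos, alleles, [gt tokens]) records."""
    n = len(records[0][3])
    names = sample_names or [f"s{i}" for i in range(1, n + 1)]
    sites = [
        Site(chrom, pos, tuple(alleles), tuple(gt(t) for t in tokens))
        for chrom, pos, alleles, tokens in records
    ]
    return GenotypeMatrix.from_sites(names, sites)


@pytest.fixture
def tiny_matrix() -> GenotypeMatrix:
    """3 sites x 2 samples covering phased, unphased, half-missing, missing
    and multiallelic genotypes."""
    return build_matrix(
        [
            ("1", 101, ("A", "C"), ["0|1", "./."]),
            ("1", 205, ("G", "T", "TT"), ["1/2", "0/."]),
            ("1", 310, ("T", "A"), ["0|0", "1/1"]),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
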