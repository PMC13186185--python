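"""Replicating the spatial structure of missing genotypes.

The central idea: given an empirical segment of S samples at N sites, and a
smaller synthetic replicate of T samples at M < N sites, partition the N
empirical sites into M contiguous blocks and summarize each sample's
missing-genotype proportion per block.  Each replicate site then inherits one
block's statistics: for every replicate genotype, an empirical sample s is
drawn uniformly and the genotype is masked with probability p_sj, the
proportion of missing genotypes of sample s in block j.  This compresses the
empirical missingness pattern onto the replicate while preserving its
position along the segment and its variation across samples.

A simpler baseline is also provided: per-site missingness proportions drawn
from a Beta distribution parameterized (method of moments) by the mean and
standard deviation of the empirical per-site missingness.  The Beta baseline
reproduces the aggregate amount of missingness but not its position along
the segment.

PLINK-style summaries (per-site and per-sample missingness reports) round
out the module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


# ---------------------------------------------------------------------------
# Block partition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BlockPartition:
    """Partition of N empirical sites into M contiguous blocks.

    Each block holds floor(N/M) sites except the first N mod M blocks,
    which hold floor(N/M) + 1.
    """

    N: int
    M: int
    block_sizes: np.ndarray

    @property
    def starts(self) -> np.ndarray:
        """0-based start index of each block within the N empirical sites."""
        return np.concatenate(([0], np.cumsum(self.block_sizes)[:-1]))


def partition_blocks(N: int, M: int) -> BlockPartition:
    """Partition ``N`` sites into ``M`` ordered blocks of near-equal size.

    Raises ``ValueError`` when the replicate has more sites than the
    empirical segment (M > N) or either count is non-positive.
    """
    if N < 1 or M < 1:
        raise ValueError("N and M must be positive")
    if M > N:
        raise ValueError(
            f"replicate has more sites than empirical segment (M={M} > N={N})"
        )
    base, rem = divmod(N, M)
    sizes = np.full(M, base, dtype=np.int64)
    sizes[:rem] += 1
    return BlockPartition(N, M, sizes)


# ---------------------------------------------------------------------------
# Empirical missingness profile
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MissingnessProfile:
    """Per-sample, per-block missing-genotype proportions p_ij (S x M)."""

    S: int
    partition: BlockPartition
    p: np.ndarray

    @property
    def M(self) -> int:
        return self.partition.M


def fit_profile(empirical: GenotypeMatrix, M: int) -> MissingnessProfile:
    """Fit the S x M missingness profile of ``empirical`` over M blocks.

    p_ij is the proportion of sample i's genotypes that are fully missing
    within block j, blocks taken contiguously in genomic order.
    """
    partition = partition_blocks(empirical.n_sites, M)
    mask = empirical.missing_mask()  # (N, S)
    block_counts = np.add.reduceat(mask, partition.starts, axis=0)  # (M, S)
    p = (block_counts / partition.block_sizes[:, None]).T  # (S, M)
    return MissingnessProfile(empirical.n_samples, partition, p)


def apply_profile(
    replicate: GenotypeMatrix, profile: MissingnessProfile, rng
) -> GenotypeMatrix:
    """Mask a replicate according to a fitted empirical profile.

    For each replicate sample t and site j independently, an empirical
    sample s is drawn uniformly from the S profiled samples and the genotype
    (t, j) is set fully missing ("./.", unphased) with probability p_sj.
    Already-called genotypes that are not masked are untouched; masking never
    un-misses a genotype.  The replicate sample count T is unrestricted.
    """
    rng = _as_rng(rng)
    M = profile.M
    if replicate.n_sites != M:
        raise ValueError(
            f"replicate has {replicate.n_sites} sites but profile expects {M}"
        )
    T = replicate.n_samples
    s = rng.integers(0, profile.S, size=(T, M))
    probs = profile.p[s, np.arange(M)[None, :]]  # (T, M)
    mask = rng.random((T, M)) < probs
    out = replicate.copy()
    site_sample = mask.T  # (M, T)
    out.codes[site_sample] = MISSING
    out.phased[site_sample] = False
    return out


# ---------------------------------------------------------------------------
# Beta-distribution baseline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BetaMissingness:
    """Method-of-moments Beta parameters for per-site missingness.

    nu = mean(1-mean)/sd^2 - 1; alpha = mean*nu; beta = (1-mean)*nu.
    """

    mean: float
    sd: float
    alpha: float
    beta: float

    @classmethod
    def from_moments(cls, mean: float, sd: float) -> "BetaMissingness":
        if not 0.0 < mean < 1.0:
            raise ValueError(f"mean missingness must be in (0, 1), got {mean}")
        if sd <= 0.0:
            raise ValueError(f"sd must be positive, got {sd}")
        if sd * sd >= mean * (1.0 - mean):
            raise ValueError(
                f"variance incompatible with beta-distribution "
                f"(sd^2={sd * sd:.6g} >= mean(1-mean)={mean * (1 - mean):.6g})"
            )
        nu = mean * (1.0 - mean) / (sd * sd) - 1.0
        return cls(mean, sd, mean * nu, (1.0 - mean) * nu)


def fit_beta(source: GenotypeMatrix) -> BetaMissingness:
    """Fit Beta parameters from a genotype set's per-site missingness.

    The mean and (population) standard deviation of the proportion of
    missing samples per site give the method-of-moments shape parameters.
    """
    if source.n_sites < 2:
        raise ValueError("need at least 2 sites to fit a beta-distribution")
    per_site = source.missing_mask().mean(axis=1)
    mean = float(per_site.mean())
    sd = float(per_site.std(ddof=0))
    return BetaMissingness.from_moments(mean, sd)


def apply_beta(
    replicate: GenotypeMatrix, params: BetaMissingness, rng
) -> GenotypeMatrix:
    """Mask a replicate with Beta-distributed per-site missingness.

    For each site independently a proportion q ~ Beta(alpha, beta) is drawn,
    then each sample at that site is set fully missing with probability q
    (independent Bernoulli per sample).
    """
    rng = _as_rng(rng)
    q = rng.beta(params.alpha, params.beta, size=replicate.n_sites)
    mask = rng.random((replicate.n_sites, replicate.n_samples)) < q[:, None]
    out = replicate.copy()
    out.codes[mask] = MISSING
    out.phased[mask] = False
    return out


# ---------------------------------------------------------------------------
# PLINK-style summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MissingnessSummary:
    """Per-site and per-sample missing-genotype proportions plus moments."""

    per_site: np.ndarray
    per_sample: np.ndarray
    mean: float
    sd: float


def summarize_missingness(matrix: GenotypeMatrix) -> MissingnessSummary:
    """Per-site / per-sample missingness and the per-site mean and SD.

    The SD is the population SD (ddof=0) of the per-site vector.
    """
    if matrix.n_sites == 0 or matrix.n_samples == 0:
        raise ValueError("cannot summarize an empty matrix")
    mask = matrix.missing_mask()
    per_site = mask.mean(axis=1)
    per_sample = mask.mean(axis=0)
    return MissingnessSummary(
        per_site, per_sample, float(per_site.mean()), float(per_site.std(ddof=0))
    )


def write_site_missingness(matrix: GenotypeMatrix, path) -> None:
    """Write a per-site report (CHROM, POS, N_MISS, F_MISS), like PLINK .vmiss."""
    mask = matrix.missing_mask()
    n_miss = mask.sum(axis=1)
    pd.DataFrame(
        {
            "CHROM": matrix.chroms,
            "POS": matrix.positions,
            "N_MISS": n_miss,
            "F_MISS": n_miss / matrix.n_samples,
        }
    ).to_csv(path, sep="\t", index=False)


def write_sample_missingness(matrix: GenotypeMatrix, path) -> None:
    """Write a per-sample report (SAMPLE, N_MISS, F_MISS), like PLINK .smiss."""
    mask = matrix.missing_mask()
    n_miss = mask.sum(axis=0)
    pd.DataFrame(
        {
            "SAMPLE": matrix.sample_names,
            "N_MISS": n_miss,
            "F_MISS": n_miss / matrix.n_sites,
        }
    ).to_csv(path, sep="\t", index=False)
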