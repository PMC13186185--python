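"""In-memory model of diploid genotype data.

The central container is :class:`GenotypeMatrix`, an array-backed matrix of
ordered sites by samples.  Every sample is diploid; each allele of a genotype
is either a site-local allele index (0 = REF) or :data:`MISSING`.  A genotype
is *missing* only when BOTH alleles are uncalled ("./." in VCF); half-missing
calls such as "0/." are representable and are never counted as missing
genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

#: Sentinel allele code for an uncalled allele ("." in VCF).
MISSING: int = -1


@dataclass(frozen=True)
class Genotype:
    """A diploid genotype: two allele codes plus a phase flag.

    ``left`` and ``right`` are site-local allele indices (0 = reference) or
    :data:`MISSING`.
    """

    left: int
    right: int
    phased: bool = False


def is_missing(g: Genotype) -> bool:
    """True iff both alleles of ``g`` are uncalled.

    Half-missing genotypes (exactly one allele called) are NOT missing.
    """
    return g.left == MISSING and g.right == MISSING


def is_half_missing(g: Genotype) -> bool:
    """True iff exactly one allele of ``g`` is uncalled."""
    return (g.left == MISSING) != (g.right == MISSING)


@dataclass(frozen=True)
class Site:
    """One variant site: location, allele strings, and per-sample genotypes.

    ``alleles[0]`` is the reference (treated as ancestral when the data are
    polarized).  ``pos`` is 1-based.
    """

    chrom: str
    pos: int
    alleles: tuple[str, ...]
    genotypes: tuple[Genotype, ...]


def site_missing_proportion(site: Site) -> float:
    """Proportion of samples with a fully missing genotype at ``site``."""
    if len(site.genotypes) == 0:
        raise ValueError("site has no samples")
    n_miss = sum(1 for g in site.genotypes if is_missing(g))
    return n_miss / len(site.genotypes)


class GenotypeMatrix:
    """Ordered sites-by-samples diploid genotype matrix.

    Genotype calls are stored as an ``(n_sites, n_samples, 2)`` integer array
    of allele codes (``MISSING`` = -1) plus an ``(n_sites, n_samples)``
    boolean phase array.  Site metadata (chrom, pos, allele strings) is kept
    per site.  Sites are ordered by position, strictly increasing within a
    chromosome.
    """

    def __init__(
        self,
        sample_names: Sequence[str],
        chroms: Sequence[str],
        positions: Sequence[int],
        alleles: Sequence[tuple[str, ...]],
        codes: np.ndarray,
        phased: np.ndarray,
        validate: bool = True,
    ) -> None:
        self.sample_names: list[str] = list(sample_names)
        self.chroms: list[str] = list(chroms)
        self.positions: np.ndarray = np.asarray(positions, dtype=np.int64)
        self.alleles: list[tuple[str, ...]] = [tuple(a) for a in alleles]
        self.codes: np.ndarray = np.asarray(codes, dtype=np.int16)
        self.phased: np.ndarray = np.asarray(phased, dtype=bool)
        if validate:
            self.validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_sites(
        cls, sample_names: Sequence[str], sites: Iterable[Site]
    ) -> "GenotypeMatrix":
        """Build a matrix from :class:`Site` records (one genotype per sample)."""
        sites = list(sites)
        n_samples = len(sample_names)
        codes = np.full((len(sites), n_samples, 2), MISSING, dtype=np.int16)
        phased = np.zeros((len(sites), n_samples), dtype=bool)
        chroms, positions, alleles = [], [], []
        for i, site in enumerate(sites):
            if len(site.genotypes) != n_samples:
                raise ValueError(
                    f"site {site.chrom}:{site.pos} has {len(site.genotypes)} "
                    f"genotypes for {n_samples} samples"
                )
            chroms.append(site.chrom)
            positions.append(site.pos)
            alleles.append(site.alleles)
            for j, g in enumerate(site.genotypes):
                codes[i, j, 0] = g.left
                codes[i, j, 1] = g.right
                phased[i, j] = g.phased
        return cls(sample_names, chroms, positions, alleles, codes, phased)

    # -- basic properties -------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_samples(self) -> int:
        return len(self.sample_names)

    def genotype(self, site_index: int, sample_index: int) -> Genotype:
        return Genotype(
            int(self.codes[site_index, sample_index, 0]),
            int(self.codes[site_index, sample_index, 1]),
            bool(self.phased[site_index, sample_index]),
        )

    def site(self, site_index: int) -> Site:
        """Materialize one site as a :class:`Site` view."""
        gts = tuple(
            self.genotype(site_index, j) for j in range(self.n_samples)
        )
        return Site(
            self.chroms[site_index],
            int(self.positions[site_index]),
            self.alleles[site_index],
            gts,
        )

    @property
    def sites(self) -> list[Site]:
        return [self.site(i) for i in range(self.n_sites)]

    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n_sites, n_samples)`` mask of fully missing genotypes."""
        return (self.codes[:, :, 0] == MISSING) & (self.codes[:, :, 1] == MISSING)

    def is_biallelic(self) -> np.ndarray:
        """Boolean per-site mask of sites with exactly two alleles."""
        return np.array([len(a) == 2 for a in self.alleles], dtype=bool)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.sample_names),
            list(self.chroms),
            self.positions.copy(),
            list(self.alleles),
            self.codes.copy(),
            self.phased.copy(),
            validate=False,
        )

    # -- invariants -------------------------------------------------------

    def validate(self) -> None:
        n = self.n_sites
        if len(self.chroms) != n or len(self.alleles) != n:
            raise ValueError("site metadata lengths disagree")
        if self.codes.shape != (n, self.n_samples, 2):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"{n} sites x {self.n_samples} samples"
            )
        if self.phased.shape != (n, self.n_samples):
            raise ValueError("phased shape does not match matrix dimensions")
        for i in range(n):
            if not self.alleles[i] or any(a == "" for a in self.alleles[i]):
                raise ValueError(f"site index {i}: empty allele string")
            hi = self.codes[i].max(initial=MISSING)
            if hi >= len(self.alleles[i]):
                raise ValueError(
                    f"site {self.chroms[i]}:{self.positions[i]}: allele index "
                    f"{hi} out of range for {len(self.alleles[i])} alleles"
                )
            if self.codes[i].min(initial=0) < MISSING:
                raise ValueError(
                    f"site {self.chroms[i]}:{self.positions[i]}: negative allele code"
                )
            if i > 0 and self.chroms[i] == self.chroms[i - 1]:
                if self.positions[i] <= self.positions[i - 1]:
                    raise ValueError(
                        f"positions not strictly increasing at "
                        f"{self.chroms[i]}:{self.positions[i]}"
                    )

    # -- comparison -------------------------------------------------------

    def equals(self, other: "GenotypeMatrix") -> bool:
        """Content equality: samples, site metadata, genotypes and phase."""
        return (
            self.sample_names == other.sample_names
            and self.chroms == other.chroms
            and np.array_equal(self.positions, other.positions)
            and self.alleles == other.alleles
            and np.array_equal(self.codes, other.codes)
            and np.array_equal(self.phased, other.phased)
        )

    def __eq__(self, other: object) -> bool:  # pragma: no cover - thin alias
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return self.equals(other)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<GenotypeMatrix {self.n_sites} sites x {self.n_samples} samples>"
        )
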