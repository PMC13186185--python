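"""Genotype-degradation operators.

Five operators emulate artifacts of real (often ancient-DNA) genotype data
on clean simulated genotypes:

* ``unphase`` — erase phase, either by randomly swapping the two alleles of
  every genotype or by sorting them (smaller allele index first).
* ``depolarize`` — per biallelic site, swap ancestral/derived labels with a
  given probability (allele strings and codes are both swapped, so carried
  bases are preserved).
* ``deaminate`` — post-mortem cytosine deamination: a site is designated a
  transition with one probability; at transition sites every called
  reference allele flips to the alternative with a second probability.
* ``pseudohaploidize`` — collapse each genotype to a homozygote by picking
  one called allele at random, the standard low-coverage aDNA representation.
* ``add_sequencing_error`` — flip every called allele at biallelic sites
  with a given probability.

All operators return a new matrix, preserve site/sample counts and
positions, and never create or remove fully missing genotypes.  Deamination
and sequencing error are mutually exclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MISSING, GenotypeMatrix
from .missingness import _as_rng

UNPHASE_MODES = ("random_swap", "sort")


@dataclass(frozen=True)
class PerturbationConfig:
    """Parameters of the degradation pipeline.

    ``unphase_mode`` is one of {"none", "random_swap", "sort"}.  Probabilities
    are in [0, 1].  Deamination (either parameter nonzero) and sequencing
    error cannot be combined.
    """

    unphase_mode: str = "none"
    depolarize_prob: float = 0.0
    deam_transition_prob: float = 0.0
    deam_rate: float = 0.0
    seq_error_prob: float = 0.0
    pseudohaploid: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.unphase_mode not in ("none",) + UNPHASE_MODES:
            raise ValueError(f"unknown unphase mode '{self.unphase_mode}'")
        for name in ("depolarize_prob", "deam_transition_prob", "deam_rate",
                     "seq_error_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        deam = self.deam_transition_prob > 0 or self.deam_rate > 0
        if deam and self.seq_error_prob > 0:
            raise ValueError(
                "deamination and sequencing error cannot be combined"
            )


def unphase(matrix: GenotypeMatrix, mode: str, rng=None) -> GenotypeMatrix:
    """Erase phase from every genotype.

    ``random_swap`` exchanges left and right alleles with probability 0.5
    independently per genotype; ``sort`` places the smaller allele index
    first, with MISSING ordered last (so a half-missing call keeps its called
    allele on the left).  All genotypes are marked unphased.
    """
    if mode not in UNPHASE_MODES:
        raise ValueError(f"unphase mode must be one of {UNPHASE_MODES}")
    out = matrix.copy()
    left = out.codes[:, :, 0]
    right = out.codes[:, :, 1]
    if mode == "random_swap":
        rng = _as_rng(rng)
        swap = rng.random(left.shape) < 0.5
    else:
        big = np.iinfo(np.int16).max
        kl = np.where(left == MISSING, big, left)
        kr = np.where(right == MISSING, big, right)
        swap = kl > kr
    l, r = left[swap].copy(), right[swap].copy()
    left[swap], right[swap] = r, l
    out.phased[:] = False
    return out


def depolarize(matrix: GenotypeMatrix, prob: float, rng) -> GenotypeMatrix:
    """Swap ancestral/derived labels per biallelic site with probability ``prob``.

    At a swapped site the REF and ALT strings are exchanged and every called
    allele code flips 0 <-> 1, so each sample still carries the same base.
    Multiallelic sites are left untouched.
    """
    rng = _as_rng(rng)
    out = matrix.copy()
    swapped = (rng.random(out.n_sites) < prob) & out.is_biallelic()
    for i in np.flatnonzero(swapped):
        a = out.alleles[i]
        out.alleles[i] = (a[1], a[0])
    called = out.codes != MISSING
    flip = swapped[:, None, None] & called
    out.codes[flip] = 1 - out.codes[flip]
    return out


def deaminate(
    matrix: GenotypeMatrix, transition_prob: float, deam_rate: float, rng
) -> GenotypeMatrix:
    """Simulate deamination damage at biallelic sites.

    Each biallelic site is designated a transition once with probability
    ``transition_prob``; at transition sites every called reference allele
    (code 0) independently becomes the alternative (code 1) with probability
    ``deam_rate``.  Missing alleles and non-transition sites are untouched.
    The reverse (alternative -> reference) channel is not simulated.
    """
    rng = _as_rng(rng)
    out = matrix.copy()
    transition = (rng.random(out.n_sites) < transition_prob) & out.is_biallelic()
    u = rng.random(out.codes.shape)
    flip = transition[:, None, None] & (out.codes == 0) & (u < deam_rate)
    out.codes[flip] = 1
    return out


def pseudohaploidize(matrix: GenotypeMatrix, rng) -> GenotypeMatrix:
    """Collapse every genotype to a homozygote of one randomly chosen allele.

    Heterozygotes keep either allele with equal probability; half-missing
    calls keep their called allele; homozygotes and fully missing genotypes
    are unchanged.  Output is unphased.
    """
    rng = _as_rng(rng)
    out = matrix.copy()
    left = out.codes[:, :, 0]
    right = out.codes[:, :, 1]
    both_called = (left != MISSING) & (right != MISSING)
    het = both_called & (left != right)
    pick_right = het & (rng.random(left.shape) < 0.5)
    chosen = np.where(pick_right, right, left)
    # half-missing: the called allele wins regardless of side
    chosen = np.where(left == MISSING, right, chosen)
    keep_missing = (left == MISSING) & (right == MISSING)
    chosen = np.where(keep_missing, MISSING, chosen)
    out.codes[:, :, 0] = chosen
    out.codes[:, :, 1] = chosen
    out.phased[:] = False
    return out


def add_sequencing_error(
    matrix: GenotypeMatrix, error_prob: float, rng
) -> GenotypeMatrix:
    """Flip each called allele at biallelic sites with probability ``error_prob``.

    Missing alleles and multiallelic sites are untouched.
    """
    rng = _as_rng(rng)
    out = matrix.copy()
    biallelic = out.is_biallelic()
    u = rng.random(out.codes.shape)
    flip = biallelic[:, None, None] & (out.codes != MISSING) & (u < error_prob)
    out.codes[flip] = 1 - out.codes[flip]
    return out


def apply_perturbations(
    matrix: GenotypeMatrix, config: PerturbationConfig, rng=None
) -> GenotypeMatrix:
    """Run the degradation pipeline in its canonical order.

    Order: depolarize -> deaminate | sequencing error -> pseudohaploidize ->
    unphase.  Allele-level noise precedes genotype collapse; missingness
    masking (the missingness module) is applied after this pipeline by
    callers so that masked sites dominate.  With a fixed seed the output is
    bit-reproducible.
    """
    rng = _as_rng(config.seed if rng is None else rng)
    out = matrix
    if config.depolarize_prob > 0:
        out = depolarize(out, config.depolarize_prob, rng)
    if config.deam_transition_prob > 0 or config.deam_rate > 0:
        out = deaminate(out, config.deam_transition_prob, config.deam_rate, rng)
    elif config.seq_error_prob > 0:
        out = add_sequencing_error(out, config.seq_error_prob, rng)
    if config.pseudohaploid:
        out = pseudohaploidize(out, rng)
    if config.unphase_mode != "none":
        out = unphase(out, config.unphase_mode, rng)
    return out
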