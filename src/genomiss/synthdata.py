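"""Synthetic genotype fixtures with engineered missingness structure.

Real low-coverage data — ancient DNA in particular — shows long contiguous
runs ("tracks") of missing genotypes where mappability or sample quality is
poor, on top of a diffuse background of randomly missing calls.  This module
generates biallelic genotype matrices with exactly that structure:
independent per-site allele frequencies (no linkage), hard probability-1
missingness tracks per sample, and independent background missingness.  The
fixtures stand in for both the empirical segment and simulator output in
tests; they make no attempt at coalescent realism (no LD, no demography).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import MISSING, GenotypeMatrix
from .io_formats import write_ms
from .missingness import _as_rng
import io


@dataclass(frozen=True)
class Track:
    """A hard missingness run: 1-based sample index and inclusive site range."""

    sample: int
    start: int
    end: int


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic genotype matrix.

    ``maf_range`` bounds the per-site minor-allele frequency draw;
    ``tracks`` lists hard missing runs (1-based, inclusive);
    ``background_missing`` is the independent per-genotype missing
    probability applied everywhere.
    """

    S: int
    N: int
    maf_range: tuple[float, float] = (0.05, 0.5)
    tracks: tuple[Track, ...] = ()
    background_missing: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.S < 1 or self.N < 1:
            raise ValueError("S and N must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if not 0.0 <= self.background_missing <= 1.0:
            raise ValueError("background_missing must be in [0, 1]")
        for t in self.tracks:
            if not (1 <= t.sample <= self.S):
                raise ValueError(f"track sample {t.sample} outside [1, {self.S}]")
            if not (1 <= t.start <= t.end <= self.N):
                raise ValueError(
                    f"track [{t.start}, {t.end}] outside [1, {self.N}]"
                )


def generate_matrix(spec: FixtureSpec) -> GenotypeMatrix:
    """Generate a biallelic matrix per ``spec`` (deterministic in the seed).

    Sites sit at positions 1..N on chromosome "1" with alleles A (ancestral)
    and T (derived); alleles are drawn independently per site from
    Binomial(2, f) with f ~ Uniform(maf_range); genotypes start phased.
    Tracks then force fully missing runs, and background missingness masks
    additional genotypes independently.
    """
    rng = _as_rng(spec.seed)
    freqs = rng.uniform(spec.maf_range[0], spec.maf_range[1], size=spec.N)
    codes = (rng.random((spec.N, spec.S, 2)) < freqs[:, None, None]).astype(np.int16)
    phased = np.ones((spec.N, spec.S), dtype=bool)
    for t in spec.tracks:
        codes[t.start - 1 : t.end, t.sample - 1, :] = MISSING
        phased[t.start - 1 : t.end, t.sample - 1] = False
    if spec.background_missing > 0:
        bg = rng.random((spec.N, spec.S)) < spec.background_missing
        codes[bg] = MISSING
        phased[bg] = False
    names = [f"syn_{i}" for i in range(1, spec.S + 1)]
    return GenotypeMatrix(
        names,
        ["1"] * spec.N,
        np.arange(1, spec.N + 1, dtype=np.int64),
        [("A", "T")] * spec.N,
        codes,
        phased,
    )


def clustered_tracks(
    S: int,
    N: int,
    regions: list[tuple[int, int]],
    rng,
    track_prob: float = 0.8,
    min_frac: float = 0.4,
    max_frac: float = 1.0,
) -> tuple[Track, ...]:
    """Random per-sample tracks confined to heavy regions of the segment.

    For each sample and each 1-based inclusive region, with probability
    ``track_prob`` a contiguous missing run covering a Uniform(min_frac,
    max_frac) fraction of the region is placed at a random offset inside it.
    This concentrates missingness in the given regions, emulating shared
    low-mappability stretches, while leaving the rest of the segment to
    background missingness only.
    """
    rng = _as_rng(rng)
    tracks: list[Track] = []
    for sample in range(1, S + 1):
        for lo, hi in regions:
            if not (1 <= lo <= hi <= N):
                raise ValueError(f"region [{lo}, {hi}] outside [1, {N}]")
            if rng.random() >= track_prob:
                continue
            width = hi - lo + 1
            span = max(1, int(round(width * rng.uniform(min_frac, max_frac))))
            start = lo + int(rng.integers(0, width - span + 1))
            tracks.append(Track(sample, start, start + span - 1))
    return tuple(tracks)


def generate_ms_text(spec: FixtureSpec) -> str:
    """Generate ms-style text for a fully called fixture.

    ms format cannot encode missing alleles, so any requested missingness
    (tracks or background) raises ``ValueError``.  The written positions are
    pos / (N + 1); parsing the text back with segment_length_bp = N + 1
    recovers the original site positions 1..N.
    """
    if spec.tracks or spec.background_missing > 0:
        raise ValueError("ms text cannot encode missing genotypes")
    matrix = generate_matrix(spec)
    buf = io.StringIO()
    write_ms(matrix, spec.N + 1, buf)
    return buf.getvalue()
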