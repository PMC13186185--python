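"""Reading and writing VCF, ms-style, and EIGENSTRAT/ANCESTRYMAP text data.

Three interchange formats are supported:

* **VCF v4.x** (read and write).  Only the GT field is interpreted; sites may
  be multiallelic; "|" vs "/" carries the phase flag; "./." is a missing
  genotype.  Output is a minimal VCF v4.2 with a single GT FORMAT field and
  contig lines synthesized from the chromosomes present.
* **ms-style text** (read and write): Hudson-format replicates delimited by
  "//", with "segsites:", "positions:" in [0, 1), and one 0/1 haplotype row
  per lineage.  Multiallelic states (characters "2", "3") are accepted on
  input.  ms output cannot encode missing alleles and is refused when any
  allele is uncalled.
* **EIGENSTRAT/ANCESTRYMAP text triplets** (.geno/.snp/.ind), the format used
  by large ancient-DNA compendia.  Genotype codes count reference-allele
  copies: 2 -> 0/0, 1 -> 0/1, 0 -> 1/1, 9 -> "./.".  Only the unpacked text
  dialect is handled.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Sequence, TextIO, Union

import numpy as np

from .core import MISSING, GenotypeMatrix

# Allele labels assigned to ms states 0, 1, 2, 3 when synthesizing VCF
# alleles: ancestral -> "A", derived -> "T", further states -> "C", "G".
MS_ALLELE_LABELS = ("A", "T", "C", "G")

PathOrStream = Union[str, os.PathLike, TextIO]


def _open_text(path_or_stream: PathOrStream, mode: str = "r"):
    if hasattr(path_or_stream, "read") or hasattr(path_or_stream, "write"):
        return path_or_stream, False
    return open(path_or_stream, mode), True


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def _parse_gt_token(token: str, n_alleles: int, line_no: int, phased_out: list):
    """Parse one GT token ("0|1", "./.", "0/.") into two allele codes."""
    if "|" in token:
        parts = token.split("|")
        phased = True
    else:
        parts = token.split("/")
        phased = False
    if len(parts) != 2:
        raise ValueError(
            f"line {line_no}: genotype token '{token}' is not diploid"
        )
    codes = []
    for p in parts:
        if p == ".":
            codes.append(MISSING)
        else:
            try:
                a = int(p)
            except ValueError:
                raise ValueError(
                    f"line {line_no}: malformed genotype token '{token}'"
                ) from None
            if a < 0 or a >= n_alleles:
                raise ValueError(
                    f"line {line_no}: allele index {a} out of range in '{token}'"
                )
            codes.append(a)
    phased_out.append(phased)
    return codes


def read_vcf(path_or_stream: PathOrStream) -> GenotypeMatrix:
    """Read a VCF v4.x file with GT genotypes into a :class:`GenotypeMatrix`.

    Sites are kept in file order; multiallelic records are preserved.  A
    genotype written with "|" is flagged phased.  Records without a GT field
    and malformed genotype tokens raise ``ValueError`` naming the line.
    """
    fh, should_close = _open_text(path_or_stream)
    try:
        sample_names = None
        chroms, positions, alleles = [], [], []
        code_rows, phase_rows = [], []
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if len(cols) < 10:
                    raise ValueError("VCF has no sample columns")
                sample_names = cols[9:]
                continue
            if sample_names is None:
                raise ValueError(f"line {line_no}: data before #CHROM header")
            cols = line.split("\t")
            if len(cols) < 10:
                raise ValueError(f"line {line_no}: fewer than 10 VCF columns")
            chrom, pos, _id, ref, alt = cols[0], cols[1], cols[2], cols[3], cols[4]
            fmt = cols[8].split(":")
            if "GT" not in fmt:
                raise ValueError(f"line {line_no}: record has no GT field")
            gt_idx = fmt.index("GT")
            site_alleles = [ref] + ([] if alt in (".", "") else alt.split(","))
            row_codes, row_phase = [], []
            for sample_field in cols[9:]:
                token = sample_field.split(":")[gt_idx]
                codes = _parse_gt_token(token, len(site_alleles), line_no, row_phase)
                row_codes.append(codes)
            if len(row_codes) != len(sample_names):
                raise ValueError(
                    f"line {line_no}: {len(row_codes)} genotype columns for "
                    f"{len(sample_names)} samples"
                )
            chroms.append(chrom)
            positions.append(int(pos))
            alleles.append(tuple(site_alleles))
            code_rows.append(row_codes)
            phase_rows.append(row_phase)
        if sample_names is None:
            raise ValueError("no #CHROM header found")
        n_sites = len(chroms)
        codes = (
            np.array(code_rows, dtype=np.int16)
            if n_sites
            else np.empty((0, len(sample_names), 2), dtype=np.int16)
        )
        phased = (
            np.array(phase_rows, dtype=bool)
            if n_sites
            else np.empty((0, len(sample_names)), dtype=bool)
        )
        return GenotypeMatrix(sample_names, chroms, positions, alleles, codes, phased)
    finally:
        if should_close:
            fh.close()


def _format_gt(left: int, right: int, phased: bool) -> str:
    sep = "|" if phased else "/"
    l = "." if left == MISSING else str(left)
    r = "." if right == MISSING else str(right)
    return f"{l}{sep}{r}"


def write_vcf(matrix: GenotypeMatrix, path_or_stream: PathOrStream) -> None:
    """Write ``matrix`` as a minimal VCF v4.2 with GT-only FORMAT.

    Round-trips through :func:`read_vcf`: genotypes, phase flags, alleles
    and positions are reproduced exactly.
    """
    fh, should_close = _open_text(path_or_stream, "w")
    try:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        seen = []
        for c in matrix.chroms:
            if c not in seen:
                seen.append(c)
        for c in seen:
            fh.write(f"##contig=<ID={c}>\n")
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO",
                  "FORMAT"] + list(matrix.sample_names)
        fh.write("\t".join(header) + "\n")
        for i in range(matrix.n_sites):
            site_alleles = matrix.alleles[i]
            ref = site_alleles[0]
            alt = ",".join(site_alleles[1:]) if len(site_alleles) > 1 else "."
            fields = [
                matrix.chroms[i],
                str(int(matrix.positions[i])),
                ".",
                ref,
                alt,
                ".",
                ".",
                ".",
                "GT",
            ]
            left = matrix.codes[i, :, 0]
            right = matrix.codes[i, :, 1]
            ph = matrix.phased[i]
            fields.extend(
                _format_gt(int(left[j]), int(right[j]), bool(ph[j]))
                for j in range(matrix.n_samples)
            )
            fh.write("\t".join(fields) + "\n")
    finally:
        if should_close:
            fh.close()


# ---------------------------------------------------------------------------
# ms-style
# ---------------------------------------------------------------------------


@dataclass
class MsReplicate:
    """One Hudson-format replicate: segregating sites, positions, haplotypes."""

    segsites: int
    positions: list[float] = field(default_factory=list)
    haplotypes: list[str] = field(default_factory=list)

    def validate(self) -> None:
        if len(self.positions) != self.segsites:
            raise ValueError(
                f"{len(self.positions)} positions for segsites {self.segsites}"
            )
        for h in self.haplotypes:
            if len(h) != self.segsites:
                raise ValueError(
                    f"haplotype length {len(h)} != segsites {self.segsites}"
                )
        if any(b > a for a, b in zip(self.positions[1:], self.positions)):
            raise ValueError("positions not nondecreasing")


def read_ms(path_or_stream: PathOrStream) -> list[MsReplicate]:
    """Parse ms-style text into a list of :class:`MsReplicate`.

    Replicates are delimited by "//"; each consists of "segsites: k", a
    "positions:" line (absent when k = 0), and one haplotype row of state
    characters per lineage.
    """
    fh, should_close = _open_text(path_or_stream)
    try:
        lines = [ln.rstrip("\n") for ln in fh]
    finally:
        if should_close:
            fh.close()

    replicates: list[MsReplicate] = []
    i = 0
    n = len(lines)
    while i < n:
        if not lines[i].startswith("//"):
            i += 1
            continue
        i += 1
        while i < n and not lines[i].strip():
            i += 1
        if i >= n or not lines[i].startswith("segsites:"):
            raise ValueError("expected 'segsites:' after '//'")
        segsites = int(lines[i].split(":", 1)[1].strip())
        i += 1
        positions: list[float] = []
        if segsites > 0:
            while i < n and not lines[i].strip():
                i += 1
            if i >= n or not lines[i].startswith("positions:"):
                raise ValueError("expected 'positions:' after 'segsites:'")
            positions = [float(x) for x in lines[i].split(":", 1)[1].split()]
            i += 1
        haplotypes: list[str] = []
        # haplotype rows are pure state-digit strings; anything else (a blank
        # line, the next "//", or another simulator header) ends the block
        while i < n and lines[i].strip().isdigit() and not lines[i].startswith("//"):
            haplotypes.append(lines[i].strip())
            i += 1
        rep = MsReplicate(segsites, positions, haplotypes)
        rep.validate()
        replicates.append(rep)
    return replicates


def _positions_to_bp(positions: Sequence[float], segment_length_bp: int) -> np.ndarray:
    """Map ms unit-interval positions to strictly increasing 1-based bp.

    bp = max(1, round(p * L)); ties are broken by bumping each subsequent
    duplicate up by one so site order stays strictly increasing.
    """
    bp = []
    prev = 0
    for p in positions:
        v = max(1, round(p * segment_length_bp))
        if v <= prev:
            v = prev + 1
        bp.append(v)
        prev = v
    return np.asarray(bp, dtype=np.int64)


def ms_to_matrix(
    rep: MsReplicate,
    segment_length_bp: int,
    split_lineages: bool = False,
    chrom: str = "1",
) -> GenotypeMatrix:
    """Convert an ms replicate into a diploid :class:`GenotypeMatrix`.

    With ``split_lineages=False`` consecutive lineage pairs (2k-1, 2k) form
    diploid sample k (phased).  With ``split_lineages=True`` every lineage
    becomes its own sample, homozygous for the lineage's allele, so each
    lineage can be treated as an independent diploid individual.
    """
    rep.validate()
    n_lineages = len(rep.haplotypes)
    if not split_lineages and n_lineages % 2 != 0:
        raise ValueError(
            f"odd lineage count ({n_lineages}) cannot be paired into diploids"
        )
    positions = _positions_to_bp(rep.positions, segment_length_bp)

    states = np.zeros((rep.segsites, n_lineages), dtype=np.int16)
    for k, hap in enumerate(rep.haplotypes):
        for i, ch in enumerate(hap):
            states[i, k] = int(ch)
    max_state = int(states.max(initial=0))
    if max_state >= len(MS_ALLELE_LABELS):
        raise ValueError(f"ms state {max_state} exceeds supported allele labels")

    alleles = []
    for i in range(rep.segsites):
        k = max(1, int(states[i].max(initial=0)))
        alleles.append(tuple(MS_ALLELE_LABELS[: k + 1]))

    if split_lineages:
        n_samples = n_lineages
        codes = np.repeat(states[:, :, None], 2, axis=2)
    else:
        n_samples = n_lineages // 2
        codes = np.stack([states[:, 0::2], states[:, 1::2]], axis=2)
    phased = np.ones((rep.segsites, n_samples), dtype=bool)
    names = [f"sample_{k}" for k in range(1, n_samples + 1)]
    return GenotypeMatrix(names, [chrom] * rep.segsites, positions, alleles,
                          codes, phased)


def write_ms(
    matrix: GenotypeMatrix, segment_length_bp: int, path_or_stream: PathOrStream
) -> None:
    """Write a fully called biallelic matrix as one ms-style replicate block.

    Each diploid sample emits two haplotype rows; positions are
    ``pos / segment_length_bp``.  Missing alleles cannot be encoded and raise
    ``ValueError``, as do multiallelic sites.
    """
    if np.any(matrix.codes == MISSING):
        raise ValueError("ms output incompatible with missing data")
    if not np.all(matrix.is_biallelic()):
        raise ValueError("ms output requires biallelic sites")
    fh, should_close = _open_text(path_or_stream, "w")
    try:
        fh.write("genomiss write-ms\n\n//\n")
        fh.write(f"segsites: {matrix.n_sites}\n")
        pos = matrix.positions / segment_length_bp
        fh.write("positions: " + " ".join(f"{p:.6f}" for p in pos) + "\n")
        for j in range(matrix.n_samples):
            for h in (0, 1):
                fh.write("".join(str(int(c)) for c in matrix.codes[:, j, h]) + "\n")
    finally:
        if should_close:
            fh.close()


def split_matrix_lineages(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Split every diploid sample into two homozygous single-lineage samples.

    Sample ``x`` becomes ``x_1`` (left allele) and ``x_2`` (right allele);
    a lineage whose allele is uncalled becomes a missing genotype.
    """
    n = matrix.n_samples
    names = []
    for s in matrix.sample_names:
        names.extend([f"{s}_1", f"{s}_2"])
    codes = np.empty((matrix.n_sites, 2 * n, 2), dtype=np.int16)
    codes[:, 0::2, 0] = matrix.codes[:, :, 0]
    codes[:, 0::2, 1] = matrix.codes[:, :, 0]
    codes[:, 1::2, 0] = matrix.codes[:, :, 1]
    codes[:, 1::2, 1] = matrix.codes[:, :, 1]
    phased = np.ones((matrix.n_sites, 2 * n), dtype=bool)
    return GenotypeMatrix(names, matrix.chroms, matrix.positions.copy(),
                          matrix.alleles, codes, phased)


# ---------------------------------------------------------------------------
# EIGENSTRAT / ANCESTRYMAP text
# ---------------------------------------------------------------------------


@dataclass
class EigenstratTriplet:
    """Unpacked EIGENSTRAT text data: .geno lines, .snp records, .ind records.

    Genotype characters count reference-allele copies (9 = missing); a .snp
    record is (name, chrom, genetic-pos, physical-pos, ref, alt); an .ind
    record is (sample-name, sex, label).
    """

    geno_lines: list[str]
    snp_records: list[tuple[str, str, float, int, str, str]]
    ind_records: list[tuple[str, str, str]]

    def validate(self) -> None:
        if len(self.geno_lines) != len(self.snp_records):
            raise ValueError(
                f"{len(self.geno_lines)} geno lines vs "
                f"{len(self.snp_records)} snp records"
            )
        n_ind = len(self.ind_records)
        for i, line in enumerate(self.geno_lines):
            if len(line) != n_ind:
                raise ValueError(
                    f"geno line {i + 1} has {len(line)} characters for "
                    f"{n_ind} individuals"
                )


def read_eigenstrat(prefix: Union[str, os.PathLike]) -> EigenstratTriplet:
    """Read ``<prefix>.geno``, ``<prefix>.snp`` and ``<prefix>.ind``."""
    prefix = os.fspath(prefix)
    with open(prefix + ".geno") as fh:
        geno_lines = [ln.strip() for ln in fh if ln.strip()]
    snp_records = []
    with open(prefix + ".snp") as fh:
        for ln in fh:
            parts = ln.split()
            if not parts:
                continue
            if len(parts) < 6:
                raise ValueError(
                    f".snp record '{ln.strip()}' lacks REF/ALT columns"
                )
            snp_records.append(
                (parts[0], parts[1], float(parts[2]), int(parts[3]),
                 parts[4], parts[5])
            )
    ind_records = []
    with open(prefix + ".ind") as fh:
        for ln in fh:
            parts = ln.split()
            if not parts:
                continue
            if len(parts) != 3:
                raise ValueError(f".ind record '{ln.strip()}' is not 3 columns")
            ind_records.append((parts[0], parts[1], parts[2]))
    triplet = EigenstratTriplet(geno_lines, snp_records, ind_records)
    triplet.validate()
    return triplet


# geno code -> (left, right); the code counts reference-allele copies.
_EIGENSTRAT_CODE = {
    "2": (0, 0),
    "1": (0, 1),
    "0": (1, 1),
    "9": (MISSING, MISSING),
}


def eigenstrat_to_matrix(triplet: EigenstratTriplet) -> GenotypeMatrix:
    """Decode an EIGENSTRAT triplet into an unphased biallelic matrix."""
    triplet.validate()
    n_sites = len(triplet.geno_lines)
    n_samples = len(triplet.ind_records)
    codes = np.empty((n_sites, n_samples, 2), dtype=np.int16)
    for i, line in enumerate(triplet.geno_lines):
        for j, ch in enumerate(line):
            try:
                codes[i, j] = _EIGENSTRAT_CODE[ch]
            except KeyError:
                raise ValueError(
                    f"geno line {i + 1}, column {j + 1}: invalid genotype "
                    f"character '{ch}'"
                ) from None
    chroms = [rec[1] for rec in triplet.snp_records]
    positions = [rec[3] for rec in triplet.snp_records]
    alleles = [(rec[4], rec[5]) for rec in triplet.snp_records]
    names = [rec[0] for rec in triplet.ind_records]
    phased = np.zeros((n_sites, n_samples), dtype=bool)
    return GenotypeMatrix(names, chroms, positions, alleles, codes, phased)
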