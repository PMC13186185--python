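# Methods

## Model and assumptions

All samples are diploid. A genotype stores two site-local allele indices
(0 = REF, treated as ancestral while the data are polarized) or the
missing sentinel, plus a phase flag. A *missing genotype* requires both
alleles uncalled; half-missing calls ("0/.") are first-class citizens and
are preserved by every transform except pseudohaploidization, which
resolves them to a homozygote of the called allele. Sites may be
multiallelic; the allele-degradation operators (depolarize, deaminate,
sequencing error) act on biallelic sites only and leave multiallelic sites
untouched.

### Missingness replication

Given an empirical segment (S samples, N sites) and a replicate (T
samples, M ≤ N sites), the N sites are partitioned in genomic order into M
contiguous blocks of size ⌊N/M⌋, the first N mod M blocks one site larger.
The profile entry p_ij is the fraction of sample i's genotypes missing in
block j. Masking draws, independently for every replicate (sample, site)
pair, a uniform empirical sample s and masks with probability p_sj. Key
modelling consequences:

* the expected missing proportion at replicate site j is the across-sample
  mean of p_·j, so the empirical signal's shape is reproduced in
  expectation at block resolution;
* adjacent-site missingness is uncorrelated beyond what the block means
  impose — runs shorter than a block are not reproduced, and resolution
  degrades as N/M grows;
* T is unrestricted by S because each replicate sample resamples the
  empirical samples independently.

M = N is allowed as the degenerate identity partition (block size 1), in
which case the profile is exactly the per-sample missingness indicator —
useful both as a sanity check and for replaying a pattern 1:1. M > N is an
error.

Masking always overwrites the genotype to fully missing and clears the
phase flag, including genotypes that were half-missing before: a masked
site is fully uncalled.

### Beta baseline

The per-site proportion of missing samples is summarized by its mean and
population SD (ddof = 0 throughout, a fixed documented choice); the
method-of-moments map ν = m(1−m)/s² − 1, α = mν, β = (1−m)ν requires
0 < m < 1 and s² < m(1−m) and errors otherwise. Each site draws
q ~ Beta(α, β) and masks each sample by an independent Bernoulli(q) — a
Bernoulli allocation rather than choosing exactly round(qT) samples, which
matches the expectation and keeps sites independent.

### Degradation operators

* **unphase** — `random_swap` exchanges the two alleles with probability
  0.5 per genotype; `sort` puts the smaller allele index first with
  MISSING ordered last (so half-missing calls keep the called allele on
  the left). Both clear every phase flag; `sort` is idempotent.
* **depolarize** — per biallelic site, with the given probability, swap
  the REF/ALT strings *and* flip every called allele code, so each sample
  carries the same base before and after; applying a forced swap twice is
  the identity.
* **deaminate** — a site is designated a transition once (per-site
  Bernoulli label, not derived from the actual bases, so it applies
  equally to ms-derived synthetic alleles); at transition sites each
  called reference allele flips to the alternative with the damage rate.
  Only the reference→alternative channel is modelled.
* **pseudohaploidize** — heterozygotes keep either allele with equal
  probability, half-missing calls keep the called allele, homozygotes and
  missing genotypes pass through; output is homozygous, unphased,
  idempotent.
* **sequencing error** — each called allele at a biallelic site flips with
  the given probability.

Deamination and sequencing error are mutually exclusive (enforced in both
`PerturbationConfig` and the CLI). When several operators are requested
the pipeline order is fixed: depolarize → deaminate | sequencing error →
pseudohaploidize → unphase, with missingness masking applied last by the
caller. Allele-level noise precedes genotype collapse, and masking last
guarantees masked sites dominate; the order is a package convention (no
canonical order exists) and makes seeded runs bit-reproducible.

No operator creates or removes a fully missing genotype, and all preserve
site/sample counts and positions.

### Formats

VCF reading interprets GT only (any FORMAT position), preserves
multiallelic records, maps "|"/"/" to the phase flag, and errors with the
line number on malformed tokens. Writing emits a minimal v4.2 header (one
GT FORMAT line, contig lines from the observed chromosomes) so output is
byte-stable; read∘write is the identity on genotypes, phase, alleles and
positions. ms-style parsing accepts multiple "//" replicates and
multi-state haplotype characters; unit-interval positions map to base
pairs by bp = max(1, round(p·L)) with duplicate positions bumped by +1 to
keep strict ordering. ms states take allele labels A, T, C, G in order
(arbitrary but fixed). Lineage splitting produces homozygous diploid
samples — one per lineage — rather than haploid calls, keeping every
output diploid. ms output is refused when any allele is missing or any
site multiallelic, since the format cannot express either. EIGENSTRAT
support covers the unpacked text triplet only; the geno digit counts
reference-allele copies (2→0/0, 1→0/1, 0→1/1, 9→./.), and decoded data are
unphased and biallelic.

### Evaluation

The per-site proportion of missing samples is a 1-D signal; signals of
different lengths are compared with classic unnormalized DTW (local cost
|a−b|, cumulative recurrence over insert/delete/match moves, path anchored
at both ends, no band, no path-length normalization or squared costs —
fixed as the package's convention). The DP kernel is numba-compiled with a
two-row recurrence; `dtw_alignment` keeps the full matrix to backtrack a
path. `benchmark_masking` runs both masking methods n times, averages the
per-site signals across runs, and returns each average's DTW distance to
the empirical signal.

## Synthetic data

The fixture generator emulates the one property the method targets —
spatially clustered missing genotypes — without coalescent realism: sites
are independent (no LD), allele counts are Binomial(2, f) with per-site
f ~ Uniform over a minor-allele-frequency range, positions are 1..N.
Missingness is layered as hard probability-1 tracks (per-sample contiguous
runs, optionally confined to designated heavy regions by
`clustered_tracks`) over independent background Bernoulli missingness.
Passing tests therefore demonstrate that the machinery reproduces spatial
missingness structure, not that it captures LD-linked callability or any
demographic signal in real data.

The benchmark study conditions used in the tests are scaled down from a
chromosome-scale analysis to desk scale: empirical S = 40 samples at
N = 3,000 sites with two heavy regions and 5% background missingness,
replicate T = 50 samples at M = 600 sites, 10 masking runs averaged per
method, 10 independent trials. Under these conditions the profile method's
DTW is consistently several-fold smaller than the Beta baseline's; the
acceptance test asserts only the qualitative ordering (profile ≤ beta in
at least 8/10 trials) because individual distances are
fixture-dependent.

## Numerical and design choices

* Allele codes are int16; the missing sentinel is −1.
* All randomness flows through one `numpy.random.Generator`; vectorized
  draws are consumed in a documented order (for profile masking: the
  uniform sample indices for all (sample, site) pairs in row-major order,
  then the masking uniforms). Identical seeds give bit-identical outputs.
* SDs are population SDs (ddof = 0).
* `--blocks` on the CLI must equal the replicate's site count (the only
  value `apply_profile` accepts); it exists to make the block count
  explicit and to fail loudly on mismatched inputs.
* With a single input replicate the output is `<prefix>.vcf`; multiple ms
  replicates write `<prefix>_rep<k>.vcf`, k from 1.
* Summary reports mirror PLINK's `.vmiss` (CHROM, POS, N_MISS, F_MISS)
  and `.smiss` (SAMPLE, N_MISS, F_MISS) as TSV.

## Known limitations

* No correlated-missingness model: runs shorter than a block, and
  cross-sample correlation of runs, are reproduced only through the block
  means.
* Packed (binary) ANCESTRYMAP, BCF, and indexed access are out of scope.
* Deamination is a two-parameter site/allele model, not a read-level
  fragment-end damage simulator; genotype likelihoods and quality fields
  are not modelled.
* The Beta baseline cannot represent per-site missingness distributions
  whose variance exceeds m(1−m) — such inputs error rather than clip.
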