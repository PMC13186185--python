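# genomiss

Simulated genotypes are too clean: coalescent and forward simulators emit
fully called, phased, polarized diploids, while the empirical data a method
will actually face — ancient DNA above all — is riddled with missing
genotypes that cluster in long runs along the chromosome, pseudohaploid
calls, deamination damage and sequencing error. `genomiss` takes an
empirical genotype segment, extracts the *spatial structure* of its missing
genotypes, and replays that structure onto smaller simulated replicates, so
that downstream methods can be benchmarked under realistic data quality. It
also provides the standard degradation operators (unphasing,
depolarization, deamination, pseudohaploidization, sequencing error) and
converts between VCF, Hudson `ms`-style text, and EIGENSTRAT/ANCESTRYMAP
text — the format of the large ancient-DNA compendia.

It is written for population geneticists who simulate with `msprime`,
`ms`, SLiM or similar and need their replicates to *look like* a particular
empirical data set before testing inference software on them.

## The method

Let the empirical segment hold $S$ samples at $N$ sites and the replicate
$T$ samples at $M \le N$ sites ($T$ unrestricted). A *missing genotype* is
a site where a sample has **both** alleles uncalled (`./.` in VCF);
half-missing calls do not count.

1. Partition the $N$ empirical sites, in order, into $M$ contiguous
   blocks: each block holds $\lfloor N/M \rfloor$ sites, except the first
   $N \bmod M$ blocks, which hold $\lfloor N/M \rfloor + 1$.
2. For each empirical sample $i$ and block $j$, compute
   $p_{ij}$ = proportion of sample $i$'s genotypes missing within block
   $j$ (an $S \times M$ profile).
3. For every replicate sample $t$ and site $j$ independently, draw an
   empirical sample $s \sim \mathrm{Uniform}(1,\dots,S)$ and set genotype
   $(t, j)$ fully missing with probability $p_{sj}$.

The block partition compresses the empirical missingness pattern to the
replicate's resolution while preserving both its position along the
segment and its heterogeneity across samples. The conventional baseline —
drawing each site's missing proportion from a Beta distribution fitted by
method of moments ($\nu = \bar{q}(1-\bar{q})/s_q^2 - 1$,
$\alpha = \bar{q}\nu$, $\beta = (1-\bar{q})\nu$, with $\bar{q}, s_q$ the
mean and SD of per-site missingness) — reproduces the aggregate amount of
missingness but scatters it uniformly along the segment. The two are
compared by treating the per-site proportion of missing samples as a
signal and computing the unnormalized dynamic-time-warping (DTW) distance
between the empirical and replicate signals; lower is closer.

## Worked example

Build a synthetic "empirical" segment with clustered missingness tracks
and a clean replicate, then mask the replicate with the empirical profile,
pseudohaploidize and unphase it:

```python
import numpy as np, genomiss as g

rng = np.random.default_rng(7)
tracks = g.clustered_tracks(30, 2000, [(300, 800), (1400, 1800)], rng)
emp = g.generate_matrix(g.FixtureSpec(S=30, N=2000, tracks=tracks,
                                      background_missing=0.05, seed=7))
g.write_vcf(emp, "empirical.vcf")
rep = g.generate_matrix(g.FixtureSpec(S=50, N=400, seed=8))
g.write_vcf(rep, "replicate.vcf")
```

```sh
$ genomiss transform --input replicate.vcf --profile-vcf empirical.vcf \
      --out masked --pseudohaploid --unphase sort --seed 42 --summary
wrote masked.vcf (400 sites x 50 samples)
wrote masked.vmiss and masked.smiss
$ genomiss dtw empirical.vcf masked.vcf
49.066667
```

`masked.vcf` is the replicate with the empirical missingness structure
replayed onto it (here a mean per-site missingness of 0.281 with SD 0.288,
concentrated where the empirical tracks sit); `masked.vmiss` /
`masked.smiss` are PLINK-style per-site and per-sample missingness
reports. The DTW distance (49.07) measures how closely the masked
replicate's missingness signal follows the empirical one. Comparing both
masking methods directly:

```python
dp, db = g.benchmark_masking(emp, rep, 10, np.random.default_rng(42))
print(f"profile DTW {dp:.2f}  beta DTW {db:.2f}")
# profile DTW 43.90  beta DTW 197.31
```

The profile method tracks the empirical signal about 4–5× more closely
than the Beta baseline, because the baseline cannot place missingness
where the empirical tracks are.

Other CLI capabilities: `--format ms` splits multi-replicate `ms` input
into one VCF per replicate; `--split-lineages` turns each lineage into its
own homozygous diploid sample; `--input PREFIX --format eigenstrat`
decodes a `.geno/.snp/.ind` triplet; `--deaminate P_TS P_RATE`,
`--seq-error P` (mutually exclusive), `--depolarize P`; `--beta-mean/--beta-sd`
or `--beta-vcf` select the Beta baseline instead of a profile. `--out-format
ms` is refused whenever a missingness option is set, since `ms` text cannot
encode missing alleles.

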