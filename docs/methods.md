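# Methods

## The detection problem

A complementary sex-determination (CSD) locus is a single genomic region at
which heterozygosity triggers female development. Because homozygotes become
low-fitness diploid males, negative frequency-dependent selection maintains
many deeply divergent alleles. `csdscan` locates and characterizes such a
locus from three cohort types — females, diploid males, haploid males — using
only genotype calls (biallelic SNPs from a VCF) and a soft-masked reference.

## Coordinates and masking

All in-memory intervals are 1-based inclusive (length = end − start + 1),
matching how locus boundaries are conventionally printed; BED output is
0-based half-open, and the conversion round-trips exactly. Lowercase runs in
the reference FASTA (soft-masked repeats) are hard-masked: sites inside them
contribute to no statistic. `N` characters count as masked by default
(unsequenced ≡ unusable); `mask_n=False` disables this.

## Heterozygosity scan

Heterozygous SNPs per individual are counted in sliding windows (default
width w = 5000 bp, step s = 1000 bp). Missing genotypes and masked sites
contribute nothing to the count; a window that is more than half masked is
flagged NA (threshold configurable), and the truncated trailing window of
each chromosome keeps its true coordinates but is flagged not-full-width.
Normalization to (x − μ)/(x₉₉ − μ) makes scans comparable across genomes of
different baseline diversity; μ and x₉₉ (the 99th percentile, computed by
linear interpolation between order statistics — the common numpy default)
are taken over full-width non-NA windows only, so truncated or mostly-masked
windows cannot deflate them. A constant track makes the denominator zero and
raises an explicit degeneracy error.

Percentile rank of a focal window is 100 × |{windows with value ≥ focal}| /
|non-NA windows|: a strict maximum among N windows ranks 100/N %. Peak
finding searches windows whose start lies in (anchor_end, anchor_end +
span] on the anchor's chromosome — "downstream" is defined on the
plus strand of the reference, and the default span is 100 kb (the distance
from a flanking gene within which the locus is expected; configurable). The
candidate region is the coordinate span of the three most heterozygous
windows near the peak, ties broken toward smaller start.

## Ploidy classification and runs of homozygosity

Genome-wide heterozygosity (HET calls / callable unmasked sites) separates
haploid from diploid males: a male is called diploid at ≥ 0.5× the female
median rate, haploid at ≤ 0.1×, ambiguous between. The band edges are far
apart because the two biological classes are: a truly haploid genome shows
only error-driven heterozygosity, while a diploid male matches the female
baseline everywhere but the sex locus.

ROH detection uses a transparent scanning rule rather than emulating any
particular tool's sliding-hit heuristic: a greedy left-to-right scan builds
maximal runs of consecutive genotyped sites containing at most `max_het`
(default 1) heterozygous calls; runs are trimmed of HET calls at their
edges, then kept if they contain ≥ 50 SNPs and span ≥ 10 kb. Greedy
restarting at the blocking site makes the output deterministic, sorted and
non-overlapping. The downstream use — confirming that diploid males are
homozygous across the sex locus — needs nothing subtler.

## Sex contrast

Per SNP, the proportion of homozygous individuals among callable females is
compared to that among callable diploid males with the pooled two-proportion
Z-test (no continuity correction); two-sided p = 2Φ(−|z|). When both groups
are uniformly homozygous or uniformly heterozygous the pooled proportion is
0 or 1 and the statistic degenerates; such sites are flagged with z = 0,
p = 1 rather than dividing 0/0. z² equals the uncorrected 2×2 chi-square on
the same counts (property-tested). Raw p-values are reported (a Bonferroni
column is emitted for convenience but never used for interval calling).

The discordant interval is the maximal run of SNPs that are heterozygous in
at least `min_frac_het_female` of callable females and homozygous in at
least `min_frac_hom_male` of callable diploid males, tolerating up to
`max_gap_snps` non-qualifying SNPs inside; endpoints are the first and last
qualifying SNP positions. Defaults are strict (1.0/1.0/0): on real
inbred-cross data, families share haplotype pairs and the locus is
consistently heterozygous in every female. **On simulated cohorts the
female threshold must be relaxed** (the recovery study uses 0.5, gaps 10):
the simulator assigns female haplotype pairs uniformly from k alleles with
per-site independent allele draws, so the best possible per-site
heterozygote probability at k = 8 is 16/28 ≈ 0.57 and no single SNP is
heterozygous in all 30 females. The 0.5/1.0 combination keeps false
positives negligible — a background site qualifies only if all 20 diploid
males are homozygous by chance (≈10⁻⁶ per site at allele frequency ½) while
half the females are heterozygous.

The crossing-design check uses the exact two-tailed binomial test with the
minimum-likelihood convention (sum of all outcomes no more probable than the
observed count), which at p₀ = 0.5 equals doubling the tail; 18 successes in
30 trials gives p = 0.3616.

## Nucleotide diversity and region delineation

For a biallelic site with j ALT alleles among n called (haploid samples
contribute one allele, diploid samples two), π_site = j(n − j)/C(n, 2); the
window statistic is Σ π_site over unmasked sites (default 1 kb windows
overlapping by 200 bp, i.e. step 800 — the alternative step-200 reading is
available via config), with a per-site companion value divided by the
unmasked window length. Samples must be all-haploid or all-diploid.

The top-percentile region takes the (1 − q) linear-interpolation quantile of
all non-NA window values (default q = 0.01) and returns the longest run of
consecutive windows within the search interval whose values reach the
threshold. Exact ties at the threshold qualify, but a window must also
exceed the track minimum: otherwise a uniform or zero-inflated track
(where the quantile collapses onto the floor) would qualify everywhere.

## Phasing and haplogroups

Hemizygous haploid males and homozygous diploid males expose their sex-locus
haplotype directly (a heterozygous call in such a sample is a genotyping
error and becomes missing). Each female genotype is tested against every
unordered pair from the distinct male-derived sequences: heterozygous sites
require the pair to differ, homozygous sites require both alleles to match.
Exactly one consistent pair phases the female; with several consistent
pairs, only sites whose phase every solution fixes identically (same
homozygous allele pair) are kept and all others are scored missing —
heterozygous sites cannot survive, because distinct solutions admit no
canonical orientation of the two haplotypes. A female inconsistent with
every pair may still be rescued by complement derivation: if exactly one
pool haplotype matches her homozygous sites, her second haplotype is implied
(opposite allele at heterozygous sites); ambiguous derivations are dropped.
Ambiguously phased females are excluded from the pool used for clustering —
their mostly-missing sequences carry no linkage and would distort group
counts.

Haplogroups are counted by single-linkage clustering of pairwise Hamming
distances normalized by the number of mutually called sites, cut at 2%
divergence (half the simulated between-haplotype divergence; on real data
this should sit well below the between-haplogroup distance and above
within-group variation). Pairs with no overlapping called sites are treated
as unlinked. Clustering replaces maximum-likelihood tree building because
the quantity of interest is the haplogroup count, which a divergence
threshold reproduces deterministically.

## The simulator

`simulate_cohort` emulates the CSD architecture: a genome of `n_chrom`
chromosomes (default 2 × 1 Mb) with i.i.d. background SNPs at allele
frequency ½ placed at density 2 × `background_het` (so diploid per-bp
heterozygosity equals `background_het`, default 0.002); one locus interval
(default 5 kb) carrying `k_haplotypes` (default 8) allele strings whose
sites segregate at density 2 × `locus_divergence` with per-haplotype
Bernoulli(½) alleles, giving expected pairwise divergence `locus_divergence`
(default 0.02). Females draw two distinct haplotypes uniformly (optionally
frequency-skewed), diploid males one haplotype twice, haploid males one.
Within the locus all variation is carried by the haplotypes (complete
linkage); background sites are placed outside it. Genotyping error flips
HET↔HOM (and HAP_REF↔HAP_ALT) symmetrically at the configured rate. Masked
tracts (geometric lengths, mean 500 bp) are drawn outside the locus to the
target masked fraction (default 5%). Everything is deterministic given the
seed, and a TruthRecord stores the locus, per-sample haplotype labels,
ploidies and haplotype sequences.

What the simulator does **not** emulate — and hence what passing recovery
tests do not show about real data: linkage disequilibrium outside the locus,
within-haplogroup variation, allele-frequency spectra, family structure
from crosses, read-level artifacts (depth, allelic imbalance), indels and
structural variation, and reference bias. The windowed count statistics
under test are insensitive to LD at this level, but thresholds tuned on
simulations (ploidy bands, the 2% clustering cutoff, the 0.5 female-het
fraction) should be re-examined on real cohorts.

## Recovery study and problem sizes

`recovery_study` (shared by the test suite and `scripts/acceptance.py`) runs
20 independently seeded cohorts at the default conditions and measures: the
percentile rank of the best locus-overlapping window in a single-female scan
(expected ≤ 1%), whether the discordant interval intersects the true locus,
ploidy misclassifications over all 40 males, and whether clustering returns
exactly k groups. The 2 × 1 Mb scale keeps one replicate under a second
while leaving ~2,000 windows per scan — enough for a 0.05% rank to be
meaningful; at this scale the whole study completes in a few seconds.

## Numerical conventions

- Missing genotypes are excluded from both numerator and denominator of
  every rate (heterozygosity, homozygote proportions, π site counts).
- Missing QUAL in a VCF fails any positive quality threshold; indels and
  multiallelic records are dropped at read time.
- Declared ploidy in the sample table overrides GT arity on conflict (with a
  warning); haploid-coded samples are rejected by diploid-only operations.
- Ties: peak finding and top-3 ranking break toward the smaller window
  start; discordant-interval ranking is by qualifying-SNP count, then bp
  length, then position.
- All randomness flows from a single integer seed via numpy Generators;
  derived replicate seeds stay below 2³¹.
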