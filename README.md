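# csdscan

Detection and characterization of multiallelic **complementary
sex-determination (CSD) loci** from population genomic genotypes.

In haplodiploid Hymenoptera, females develop from fertilized diploid eggs and
males from unfertilized haploid eggs — except that fertilized eggs homozygous
at the sex locus develop into (usually sterile) diploid males. A functional
CSD locus therefore leaves four coupled genomic signatures:

1. **a heterozygosity peak** — every female carries two divergent sex-locus
   haplotypes, producing a sharp localized excess of heterozygous SNPs in a
   single female genome;
2. **a sex-genotype contrast** — the locus is heterozygous in females but
   homozygous in diploid males, detectable per SNP with a two-proportion
   Z-test, z = (p₁ − p₂) / √(p̂(1 − p̂)(1/n₁ + 1/n₂));
3. **a nucleotide-diversity maximum** — balancing selection maintains many
   alleles, so windowed π = Σₛ j(n − j)/C(n, 2) peaks genome-wide at the
   locus;
4. **a pool of deeply divergent haplotypes** — hemizygous haploid males and
   homozygous diploid males expose haplotypes directly; females can be
   phased against them, and single-linkage clustering of normalized Hamming
   distances counts the haplogroups (the approximate functional allele
   number).

`csdscan` implements all four as a tested library, plus a synthetic-cohort
simulator with recorded ground truth so the whole chain is verifiable
without sequencing data. Cross-genome comparability of heterozygosity scans
uses the normalization (x − μ)/(x₉₉ − μ), where x is the per-window
heterozygous-site count, μ the genome-wide mean and x₉₉ the 99th percentile.

## Worked example

```python
from csdscan import (SimulationConfig, simulate_cohort, count_het_windows,
                     normalize_track, find_peak_downstream, percentile_rank)
from csdscan.intervals import Interval

gm, samples, mask, truth = simulate_cohort(SimulationConfig(seed=1))
track = count_het_windows(gm, samples.females()[0], mask, w=5000, s=1000)
norm, params = normalize_track(track)
anchor = Interval(truth.locus.chrom, truth.locus.start - 7000, truth.locus.start - 5000)
peak = find_peak_downstream(norm, anchor, search_span=100_000)
print(peak, percentile_rank(norm, peak))
```

prints

```
Interval(chrom='chr1', start=500001, end=505000) 0.05037783375314862
```

— the scan recovers the simulated 5 kb locus exactly, and its percentile
rank of 0.05% marks it as the most heterozygous window genome-wide (rank =
100 × fraction of windows at least as heterozygous; smaller is more
extreme). Running the remaining stages on the same cohort
(`examples/map_sex_locus.py`, `examples/phase_and_cluster.py`) delineates a
4.9 kb discordant interval (Jaccard 0.86–0.98 with the truth locus), phases
all 30 females uniquely, and recovers exactly the 8 simulated haplogroups.

The `examples/` directory holds one short script per capability; each
simulates or loads a small input, runs one stage and prints what the numbers
mean. A thin CLI mirrors the library:

```bash
csdscan simulate --seed 1 --out cohort/
csdscan hetscan --vcf cohort/cohort.vcf --fasta cohort/reference.fa \
    --sample F01 --anchor cohort/anchors.bed --out track.tsv
csdscan contrast --vcf cohort/cohort.vcf --samples cohort/samples.tsv --out contrast.tsv
csdscan run --out run/   # full pipeline on a simulated cohort
```

## Layout

- `src/csdscan/` — library: `io_formats` (VCF/FASTA/BED/TSV), `synthetic`
  (cohort simulator + truth), `het_scan`, `ploidy`, `sex_contrast`,
  `diversity` (π, phasing, haplogroups), `recovery`, `pipeline`, `cli`.
- `docs/methods.md` — model, assumptions, parameter choices, limitations.
- `examples/` — narrative scripts, one per capability.
- `tests/` — unit, property and acceptance tests.
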