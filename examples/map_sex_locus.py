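"""Map the sex locus by female vs diploid-male contrast and nucleotide diversity.

Per SNP, the proportion of homozygous females is compared to that of diploid
males with a two-proportion Z-test; the discordant interval (mostly-het
females, all-hom males) is delineated, then the top-1% nucleotide-diversity
region is refined inside its neighborhood from haploid-male haplotypes.
"""
from csdscan import (
    SimulationConfig,
    find_discordant_interval,
    pi_windows,
    scan_sex_contrast,
    simulate_cohort,
    top_percentile_region,
)
from csdscan.intervals import Interval, jaccard

gm, samples, mask, truth = simulate_cohort(SimulationConfig(seed=1))

scan = scan_sex_contrast(gm, samples)
top = scan.loc[scan["p_value"].idxmin()]
print(f"strongest contrast: {top['chrom']}:{top['pos']} "
      f"(z={top['z']:.2f}, p={top['p_value']:.3g})")

intervals = find_discordant_interval(gm, samples, min_frac_het_female=0.5, max_gap_snps=10)
disc = intervals[0]
print(f"discordant interval: {disc.chrom}:{disc.start}-{disc.end} ({disc.length/1000:.1f} kb)")

track = pi_windows(gm, samples.haploid_males(), mask, w=1000, step=800)
search = Interval(disc.chrom, max(1, disc.start - 10_000), disc.end + 10_000)
region = top_percentile_region(track, q=0.01, search=search)
print(f"top-1% diversity region: {region.chrom}:{region.start}-{region.end}")
print(f"overlap with true locus: Jaccard={jaccard(region, truth.locus):.2f}")
# both delineations converge on the simulated 5 kb locus
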