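"""Phase females from male haplotypes and count haplogroups at the sex locus.

Hemizygous haploid males and homozygous diploid males reveal their sex-locus
haplotype directly; each female genotype is then matched against all
unordered pairs from that pool (ambiguous inferences scored missing).
Single-linkage clustering of normalized Hamming distances at a 2% divergence
cutoff counts the haplogroups.
"""
from collections import Counter

from csdscan import (
    SimulationConfig,
    build_haplotype_pool,
    haplogroup_clusters,
    simulate_cohort,
)

cfg = SimulationConfig(seed=1)
gm, samples, mask, truth = simulate_cohort(cfg)

pool, status = build_haplotype_pool(gm, samples, truth.locus)
print(f"pool: {len(pool)} haplotypes over {len(pool.snp_positions)} SNPs")
print(f"sources: {Counter(pool.source)}")
print(f"female phasing: {Counter(status.values())}")

labels = haplogroup_clusters(pool, max_within_dist=0.02)
print(f"haplogroups: {labels.max() + 1} (simulated with k={cfg.k_haplotypes})")
sizes = Counter(labels.tolist())
print(f"haplogroup sizes: {dict(sorted(sizes.items()))}")
# each cluster corresponds to one simulated haplotype lineage
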