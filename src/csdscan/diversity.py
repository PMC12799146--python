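"""Windowed nucleotide diversity, haplotype phasing and haplogroup clustering.

A multiallelic sex locus under balancing selection is hyperpolymorphic: the
per-window sum of per-site average pairwise differences (pi) peaks there,
and the locus region can be delineated as the run of windows ranking in the
top percentile genome-wide. Haplotypes are observed directly in hemizygous
(haploid) males and homozygous diploid males, and inferred for females by
exhaustive consistency search over pairs from the male-derived pool, with
ambiguous sites scored missing. Haplogroups are counted by single-linkage
clustering of normalized Hamming distances at a divergence threshold, a
deterministic stand-in for a phylogeny whose published use is haplogroup
counting.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .genotypes import Call, GenotypeMatrix
from .intervals import Interval, MaskTrack
from .windows import WindowTrack, make_windows

__all__ = [
    "HaplotypePool",
    "pi_windows",
    "top_percentile_region",
    "phase_female",
    "haplogroup_clusters",
    "pool_to_fasta",
]

MISS = np.int8(-1)  # missing allele in haplotype sequences (0=REF, 1=ALT)

_SOURCES = {"haploid_male", "diploid_male", "phased_female"}


@dataclass
class HaplotypePool:
    """Phased allele sequences over the SNPs of a focal region.

    `sequences` is an (n_haplotypes, n_sites) int8 array over {0 REF, 1 ALT,
    -1 missing}; `source` records where each haplotype came from (hemizygous
    haploid male, homozygous diploid male, or a phased female).
    """

    region: Interval
    snp_positions: np.ndarray
    sequences: np.ndarray
    names: list[str] = field(default_factory=list)
    source: list[str] = field(default_factory=list)
    ref: np.ndarray | None = None  # per-site REF nucleotide, for FASTA output
    alt: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sequences = np.asarray(self.sequences, dtype=np.int8)
        self.snp_positions = np.asarray(self.snp_positions, dtype=np.int64)
        if self.sequences.ndim != 2 or self.sequences.shape[1] != len(self.snp_positions):
            raise ValueError("sequences must be (n_haplotypes, n_sites)")
        bad = set(np.unique(self.sequences)) - {-1, 0, 1}
        if bad:
            raise ValueError(f"invalid allele codes: {sorted(bad)}")
        if not self.names:
            self.names = [f"hap{i + 1}" for i in range(len(self.sequences))]
        if not self.source:
            self.source = ["haploid_male"] * len(self.sequences)
        bad_src = set(self.source) - _SOURCES
        if bad_src:
            raise ValueError(f"invalid sources: {sorted(bad_src)}")

    def __len__(self) -> int:
        return len(self.sequences)


def _alt_counts(calls: np.ndarray, haploid: bool) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (n_alt_alleles, n_total_alleles) over a sample block."""
    if haploid:
        called = np.isin(calls, (Call.HAP_REF, Call.HAP_ALT))
        alt = (calls == Call.HAP_ALT).sum(axis=1)
        tot = called.sum(axis=1)
    else:
        called = np.isin(calls, (Call.HOM_REF, Call.HET, Call.HOM_ALT))
        alt = (calls == Call.HET).sum(axis=1) + 2 * (calls == Call.HOM_ALT).sum(axis=1)
        tot = 2 * called.sum(axis=1)
    return alt, tot


def pi_windows(
    gm: GenotypeMatrix,
    samples: list[str],
    mask: MaskTrack | None = None,
    w: int = 1000,
    step: int = 800,
) -> WindowTrack:
    """Nucleotide diversity summed over sliding windows (default 1 kb
    windows overlapping by 200 bp).

    Per biallelic site with j ALT alleles among n called, pi_site =
    j (n - j) / C(n, 2); the window value is the sum of pi_site over
    unmasked sites in the window (companion per-site value = value /
    unmasked window length, in ``meta``-documented column ``per_site``).
    Samples must be all haploid or all diploid; diploid genotypes contribute
    both alleles. Sites with fewer than two callable alleles are skipped;
    their count is recorded in ``meta['n_skipped']``.
    """
    if len(samples) < 1:
        raise ValueError("need at least one sample")
    hap_flags = [gm.is_haploid_coded(s) for s in samples]
    if len(set(hap_flags)) > 1:
        raise ValueError("samples must be all haploid or all diploid")
    haploid = hap_flags[0]
    if not haploid and len(samples) < 2:
        pass  # one diploid still yields two sequences
    cols = [gm.sample_index(s) for s in samples]
    alt, tot = _alt_counts(gm.calls[:, cols], haploid)
    ok = tot >= 2
    with np.errstate(divide="ignore", invalid="ignore"):
        pi_site = np.where(ok, alt * (tot - alt) / (tot * (tot - 1) / 2.0), 0.0)
    mask = mask or MaskTrack()
    chrom_lengths = gm.chrom_lengths or {
        c: int(gm.positions(c).max()) for c in gm.chroms
    }
    win = make_windows(chrom_lengths, w, step, mask)
    values = np.zeros(len(win), dtype=float)
    per_site = np.zeros(len(win), dtype=float)
    for chrom in chrom_lengths:
        on = gm.chrom_mask(chrom)
        pos = gm.sites.loc[on, "pos"].to_numpy()
        pv = pi_site[on]
        unmasked = ~mask.is_masked(chrom, pos)
        pos, pv = pos[unmasked], pv[unmasked]
        cum = np.concatenate([[0.0], np.cumsum(pv)])
        rows = (win["chrom"] == chrom).to_numpy()
        starts = win.loc[rows, "start"].to_numpy()
        ends = win.loc[rows, "end"].to_numpy()
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="right")
        values[rows] = cum[hi] - cum[lo]
        span = ends - starts + 1
        masked_bp = mask.overlap_bp(chrom, starts, ends)
        denom = np.maximum(span - masked_bp, 1)
        per_site[rows] = values[rows] / denom
    win = win.copy()
    win["value"] = values
    win["per_site"] = per_site
    return WindowTrack(
        win,
        label=",".join(samples[:3]) + ("..." if len(samples) > 3 else ""),
        meta={"w": w, "s": step, "stat": "pi", "n_skipped": int((~ok).sum())},
    )


def top_percentile_region(
    track: WindowTrack, q: float = 0.01, search: Interval | None = None
) -> Interval | None:
    """Region where all windows rank within the top `q` most diverse genome-wide.

    The threshold is the (1 - q) linear-interpolation quantile of all non-NA
    window values; a window qualifies when its value reaches the threshold
    (exact ties count) AND exceeds the track minimum — the second condition
    keeps degenerate tracks (uniform, or zero-inflated with a threshold at
    the floor) from qualifying everywhere. The returned interval spans the
    longest run of consecutive qualifying windows within `search` (whole
    genome if None); None when no window qualifies.
    """
    vals = track.non_na_values()
    if len(vals) == 0:
        return None
    threshold = float(np.quantile(vals, 1.0 - q))
    floor = float(vals.min())
    w = track.windows
    sel = np.ones(len(w), dtype=bool)
    if search is not None:
        sel = (
            (w["chrom"] == search.chrom)
            & (w["end"] >= search.start)
            & (w["start"] <= search.end)
        ).to_numpy()
    best: Interval | None = None
    best_len = 0
    for chrom in w.loc[sel, "chrom"].unique():
        rows = w.loc[sel & (w["chrom"] == chrom).to_numpy()]
        v = rows["value"].to_numpy()
        qual = (v >= threshold) & (v > floor) & ~np.isnan(v)
        idx = np.flatnonzero(qual)
        if len(idx) == 0:
            continue
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(idx) - 1]])
        for a, b in zip(starts, ends):
            i0, i1 = idx[a], idx[b]
            iv = Interval(chrom, int(rows.iloc[i0]["start"]), int(rows.iloc[i1]["end"]))
            if iv.length > best_len:
                best, best_len = iv, iv.length
    return best


def _pair_consistent(genotype: np.ndarray, a: np.ndarray, b: np.ndarray) -> bool:
    """Is the unordered haplotype pair (a, b) consistent with a genotype?

    Checked at every non-missing genotype site with both alleles called:
    HET requires the two alleles to differ; HOM requires both to equal the
    called allele.
    """
    het = genotype == Call.HET
    hom_ref = genotype == Call.HOM_REF
    hom_alt = genotype == Call.HOM_ALT
    known = (a != MISS) & (b != MISS)
    if np.any(het & known & (a == b)):
        return False
    if np.any(hom_ref & known & ((a != 0) | (b != 0))):
        return False
    if np.any(hom_alt & known & ((a != 1) | (b != 1))):
        return False
    return True


def phase_female(
    female_genotype: np.ndarray, pool: HaplotypePool
) -> tuple[np.ndarray, np.ndarray, str]:
    """Phase a diploid female against a pool of observed haplotypes.

    Searches unordered pairs (h_i, h_j), i <= j, whose site-wise combination
    matches the genotype at every non-missing site. Exactly one consistent
    pair -> that phase (status "unique"); multiple -> sites where all
    consistent pairs agree are phased, disagreeing sites set missing (status
    "ambiguous"); none -> both haplotypes all-missing (status "unphased").
    """
    if len(pool) == 0:
        raise ValueError("empty haplotype pool")
    g = np.asarray(female_genotype, dtype=np.int8)
    if g.shape != (pool.sequences.shape[1],):
        raise ValueError("genotype length does not match pool sites")
    # identical sequences (e.g. two males carrying the same haplotype) must
    # not create spurious extra solutions: search over distinct sequences
    uniq_seqs: list[np.ndarray] = []
    seen_keys: set[bytes] = set()
    for s in pool.sequences:
        key = s.tobytes()
        if key not in seen_keys:
            seen_keys.add(key)
            uniq_seqs.append(s)
    consistent: list[tuple[int, int]] = []
    n = len(uniq_seqs)
    for i in range(n):
        for j in range(i, n):
            if _pair_consistent(g, uniq_seqs[i], uniq_seqs[j]):
                consistent.append((i, j))
    n_sites = len(pool.snp_positions)
    if not consistent:
        miss = np.full(n_sites, MISS, dtype=np.int8)
        return miss, miss.copy(), "unphased"
    if len(consistent) == 1:
        i, j = consistent[0]
        return uniq_seqs[i].copy(), uniq_seqs[j].copy(), "unique"
    # Multiple consistent pairs: only sites whose phase every solution fixes
    # identically survive. Because distinct solutions admit no canonical
    # orientation of (hapA, hapB), a site is resolvable only when all
    # solutions give the same unordered allele pair and that pair is
    # homozygous; heterozygous or disagreeing sites are scored missing.
    lo = np.stack([np.minimum(uniq_seqs[i], uniq_seqs[j]) for i, j in consistent])
    hi = np.stack([np.maximum(uniq_seqs[i], uniq_seqs[j]) for i, j in consistent])
    resolved = (
        (lo == lo[0]).all(axis=0)
        & (hi == hi[0]).all(axis=0)
        & (lo[0] == hi[0])
        & (lo[0] != MISS)
    )
    hapA = np.where(resolved, lo[0], MISS).astype(np.int8)
    return hapA, hapA.copy(), "ambiguous"


def region_genotypes(
    gm: GenotypeMatrix, region: Interval
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(positions, ref, alt, calls) for the SNPs inside a region."""
    on = gm.chrom_mask(region.chrom)
    pos = gm.sites.loc[on, "pos"].to_numpy()
    inside = (pos >= region.start) & (pos <= region.end)
    rows = np.flatnonzero(on)[inside]
    return (
        pos[inside],
        gm.sites.loc[rows, "ref"].to_numpy(),
        gm.sites.loc[rows, "alt"].to_numpy(),
        gm.calls[rows],
    )


def _sample_sequence(calls: np.ndarray) -> np.ndarray:
    """Haplotype sequence carried by a hemizygous or homozygous sample.

    HAP_REF/HOM_REF -> 0, HAP_ALT/HOM_ALT -> 1; HET (impossible for a true
    single haplotype, i.e. genotyping error) and MISSING -> missing.
    """
    seq = np.full(len(calls), MISS, dtype=np.int8)
    seq[np.isin(calls, (Call.HAP_REF, Call.HOM_REF))] = 0
    seq[np.isin(calls, (Call.HAP_ALT, Call.HOM_ALT))] = 1
    return seq


def infer_novel_haplotype(
    genotype: np.ndarray, pool: HaplotypePool
) -> np.ndarray | None:
    """Derive a female's unobserved haplotype as the complement of a pool one.

    For a female whose genotype is inconsistent with every pool pair, each
    pool haplotype h consistent with her homozygous sites implies a partner:
    the called allele at HOM sites, the allele opposite h at HET sites.
    Returns the implied partner when exactly one pool haplotype works (and
    all candidates agree), else None (ambiguous inference scored missing).
    """
    g = np.asarray(genotype, dtype=np.int8)
    candidates = []
    for h in pool.sequences:
        hom_ref = g == Call.HOM_REF
        hom_alt = g == Call.HOM_ALT
        het = g == Call.HET
        known = h != MISS
        if np.any(hom_ref & known & (h != 0)) or np.any(hom_alt & known & (h != 1)):
            continue
        partner = np.full(len(g), MISS, dtype=np.int8)
        partner[hom_ref] = 0
        partner[hom_alt] = 1
        partner[het & known] = 1 - h[het & known]
        candidates.append(partner)
    if not candidates:
        return None
    first = candidates[0]
    for c in candidates[1:]:
        if not np.array_equal(c, first):
            return None
    return first


def build_haplotype_pool(
    gm: GenotypeMatrix,
    st,
    region: Interval,
    include_diploid_males: bool = True,
    phase_females: bool = True,
    infer_novel: bool = True,
) -> tuple[HaplotypePool, dict[str, str]]:
    """Assemble the focal-region haplotype pool from a cohort.

    Hemizygous haploid males and homozygous diploid males contribute their
    haplotypes directly; females are then phased against that male-derived
    pool (uniquely phased females contribute both haplotypes; for females
    inconsistent with every pool pair, `infer_novel` attempts the
    complement-derivation rescue). Returns the pool plus per-female phasing
    status.
    """
    pos, ref, alt, calls = region_genotypes(gm, region)
    seqs: list[np.ndarray] = []
    names: list[str] = []
    source: list[str] = []
    for s in st.haploid_males():
        seqs.append(_sample_sequence(calls[:, gm.sample_index(s)]))
        names.append(s)
        source.append("haploid_male")
    if include_diploid_males:
        for s in st.diploid_males():
            seqs.append(_sample_sequence(calls[:, gm.sample_index(s)]))
            names.append(s)
            source.append("diploid_male")
    if not seqs:
        raise ValueError("no male haplotype sources in cohort")
    male_pool = HaplotypePool(region, pos, np.stack(seqs), list(names), list(source), ref=ref, alt=alt)

    status: dict[str, str] = {}
    if phase_females:
        for s in st.females():
            g = calls[:, gm.sample_index(s)]
            hapA, hapB, stat = phase_female(g, male_pool)
            if stat == "unphased" and infer_novel:
                novel = infer_novel_haplotype(g, male_pool)
                if novel is not None:
                    # re-phase against the augmented pool to recover the pair
                    aug = HaplotypePool(
                        region,
                        pos,
                        np.vstack([male_pool.sequences, novel]),
                        names + [f"{s}_novel"],
                        source + ["phased_female"],
                        ref=ref,
                        alt=alt,
                    )
                    hapA, hapB, stat = phase_female(g, aug)
                    stat = "unique_novel" if stat == "unique" else stat
            status[s] = stat
            # ambiguously phased females are mostly-missing: they carry no
            # reliable linkage and would distort haplogroup counting
            if stat in ("unique", "unique_novel"):
                seqs.extend([hapA, hapB])
                names.extend([f"{s}_A", f"{s}_B"])
                source.extend(["phased_female", "phased_female"])
    pool = HaplotypePool(region, pos, np.stack(seqs), names, source, ref=ref, alt=alt)
    return pool, status


def hamming_matrix(sequences: np.ndarray) -> np.ndarray:
    """Pairwise Hamming distance over mutually non-missing sites, normalized
    by their count; NaN where two sequences share no called site."""
    seqs = np.asarray(sequences, dtype=np.int8)
    n = len(seqs)
    d = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            known = (seqs[i] != MISS) & (seqs[j] != MISS)
            k = int(known.sum())
            if k == 0:
                d[i, j] = d[j, i] = np.nan
            else:
                diff = int((seqs[i][known] != seqs[j][known]).sum())
                d[i, j] = d[j, i] = diff / k
    return d


def haplogroup_clusters(
    pool: HaplotypePool, max_within_dist: float = 0.02
) -> np.ndarray:
    """Single-linkage haplogroups at a normalized-divergence threshold.

    Pairs with an undefined distance (no overlapping called sites) are
    treated as unlinked. Labels are 0-based integers, deterministic,
    numbered by each cluster's first member in pool order.
    """
    n = len(pool)
    if n == 0:
        raise ValueError("empty haplotype pool")
    if n == 1:
        return np.zeros(1, dtype=np.int64)
    d = hamming_matrix(pool.sequences)
    d = np.where(np.isnan(d), 2.0, d)  # > any normalized distance: unlinked
    condensed = squareform(d, checks=False)
    raw = fcluster(linkage(condensed, method="single"), t=max_within_dist, criterion="distance")
    # relabel by first occurrence
    seen: dict[int, int] = {}
    out = np.empty(n, dtype=np.int64)
    for i, lab in enumerate(raw):
        if lab not in seen:
            seen[lab] = len(seen)
        out[i] = seen[lab]
    return out


def pool_to_fasta(pool: HaplotypePool, path: str | Path) -> None:
    """Write pool haplotypes as FASTA over the region's SNP positions.

    REF/ALT alleles are written as their nucleotides when the pool carries
    them, else as 0/1; missing calls become N.
    """
    if len(pool) == 0:
        raise ValueError("empty haplotype pool")
    n_sites = len(pool.snp_positions)
    if pool.ref is not None and pool.alt is not None:
        ref = np.asarray(pool.ref, dtype="U1")
        alt = np.asarray(pool.alt, dtype="U1")
    else:
        ref = np.full(n_sites, "0", dtype="U1")
        alt = np.full(n_sites, "1", dtype="U1")
    with open(path, "w") as fh:
        for name, seq in zip(pool.names, pool.sequences):
            chars = np.where(seq == 0, ref, np.where(seq == 1, alt, "N"))
            fh.write(f">{name}\n{''.join(chars)}\n")
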