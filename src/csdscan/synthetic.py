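"""Synthetic cohorts with a complementary sex-determination architecture.

The simulator emulates the genetic signal the pipeline is built to detect:
a genome with uniform background SNP heterozygosity plus one hyperpolymorphic
multiallelic locus carrying k divergent haplotypes. Females are heterozygous
at the locus (two distinct haplotypes), diploid males are homozygous (one
haplotype twice), haploid males hemizygous (one haplotype). Optional
genotyping noise and repeat-masked tracts complete the picture, and every
draw is recorded in a TruthRecord for recovery tests.

Background polymorphism is i.i.d. per site at allele frequency 1/2, so a
per-bp SNP density of 2x the target heterozygosity gives diploids the target
per-bp heterozygosity (P(het) = 1/2 at frequency 1/2). There is no linkage
disequilibrium: the windowed statistics under test are count-based and
insensitive to LD at this level.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import Call, GenotypeMatrix, SampleTable
from .intervals import Interval, MaskTrack
from .io_formats import write_bed, write_samples, write_vcf

__all__ = ["SimulationConfig", "TruthRecord", "simulate_haplotype_pool", "simulate_cohort", "emit_cohort"]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimulationConfig:
    """Study conditions for a simulated CSD cohort.

    Defaults are the scale used throughout testing: 2 chromosomes x 1 Mb,
    a 5 kb locus with k=8 haplotypes at 2% pairwise divergence over 0.2%
    background heterozygosity, 30 females, 20 diploid males, 20 haploid
    males, no genotyping error — a cohort that simulates in seconds while
    preserving every qualitative feature of the architecture.
    """

    n_chrom: int = 2
    chrom_length: int = 1_000_000
    background_het: float = 0.002
    locus_chrom: str = "chr1"
    locus_start: int = 500_001
    locus_end: int = 505_000
    k_haplotypes: int = 8
    locus_divergence: float = 0.02
    n_females: int = 30
    n_diploid_males: int = 20
    n_haploid_males: int = 20
    genotype_error: float = 0.0
    masked_fraction: float = 0.05
    skew_haplotype_freqs: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("background_het", "locus_divergence", "genotype_error", "masked_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.k_haplotypes < 1:
            raise ValueError("k_haplotypes must be >= 1")
        if not (1 <= self.locus_start <= self.locus_end <= self.chrom_length):
            raise ValueError("locus interval must lie within a chromosome")
        if self.locus_chrom not in self.chrom_names:
            raise ValueError(f"locus_chrom {self.locus_chrom!r} not among chromosomes")
        if self.n_females + self.n_diploid_males + self.n_haploid_males == 0:
            raise ValueError("cohort must contain at least one sample")
        if self.locus_divergence <= self.background_het:
            warnings.warn(
                "locus_divergence <= background_het: the locus will not "
                "stand out from background heterozygosity",
                stacklevel=2,
            )

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names}

    @property
    def locus(self) -> Interval:
        return Interval(self.locus_chrom, self.locus_start, self.locus_end)


@dataclass
class TruthRecord:
    """Ground truth emitted alongside a simulated cohort."""

    locus: Interval
    haplotype_labels: dict[str, tuple[int, ...]]  # one or two indices per sample
    ploidy: dict[str, int]
    haplotype_sequences: np.ndarray  # (k, n_locus_sites) int8 over {0, 1}
    locus_positions: np.ndarray  # 1-based positions of locus SNPs

    def to_json(self) -> str:
        return json.dumps(
            {
                "locus": {"chrom": self.locus.chrom, "start": self.locus.start, "end": self.locus.end},
                "haplotype_labels": {k: list(v) for k, v in self.haplotype_labels.items()},
                "ploidy": self.ploidy,
                "haplotype_sequences": self.haplotype_sequences.tolist(),
                "locus_positions": self.locus_positions.tolist(),
            },
            indent=0,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        d = json.loads(text)
        return cls(
            locus=Interval(**d["locus"]),
            haplotype_labels={k: tuple(v) for k, v in d["haplotype_labels"].items()},
            ploidy={k: int(v) for k, v in d["ploidy"].items()},
            haplotype_sequences=np.asarray(d["haplotype_sequences"], dtype=np.int8),
            locus_positions=np.asarray(d["locus_positions"], dtype=np.int64),
        )


def simulate_haplotype_pool(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw k divergent locus haplotypes.

    Sites segregating among the pool are placed with per-bp probability
    2 x locus_divergence; at each such site every haplotype draws REF or ALT
    with probability 1/2, so the expected pairwise per-bp difference rate is
    locus_divergence. Returns (positions within the locus, sequences) where
    sequences is a (k, n_sites) 0/1 array.
    """
    if cfg.k_haplotypes < 1:
        raise ValueError("k_haplotypes must be >= 1")
    rng = rng or np.random.default_rng(cfg.seed)
    L = cfg.locus_end - cfg.locus_start + 1
    p_site = min(1.0, 2.0 * cfg.locus_divergence)
    n_sites = rng.binomial(L, p_site)
    offsets = np.sort(rng.choice(L, size=n_sites, replace=False))
    positions = cfg.locus_start + offsets
    seqs = rng.integers(0, 2, size=(cfg.k_haplotypes, n_sites), dtype=np.int8)
    # drop sites monomorphic across the pool: they discriminate nothing
    if cfg.k_haplotypes > 1 and n_sites:
        poly = (seqs.min(axis=0) == 0) & (seqs.max(axis=0) == 1)
        positions, seqs = positions[poly], seqs[:, poly]
    return positions, seqs


def _assign_female_pairs(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Unordered distinct haplotype pairs for females, uniform by default."""
    k = cfg.k_haplotypes
    if k < 2:
        raise ValueError("females require k_haplotypes >= 2 (heterozygous at the locus)")
    if cfg.skew_haplotype_freqs:
        freqs = rng.dirichlet(np.ones(k) * 0.8)
    else:
        freqs = np.full(k, 1.0 / k)
    out = np.empty((cfg.n_females, 2), dtype=np.int64)
    for i in range(cfg.n_females):
        out[i] = rng.choice(k, size=2, replace=False, p=freqs)
    return out


def simulate_cohort(
    cfg: SimulationConfig,
) -> tuple[GenotypeMatrix, SampleTable, MaskTrack, TruthRecord]:
    """Simulate a full cohort: genotypes, metadata, mask and ground truth.

    Deterministic given the config (which carries the seed).
    """
    rng = np.random.default_rng(cfg.seed)
    locus_pos, hap_seqs = simulate_haplotype_pool(cfg, rng)

    names_f = [f"F{i + 1:02d}" for i in range(cfg.n_females)]
    names_dm = [f"DM{i + 1:02d}" for i in range(cfg.n_diploid_males)]
    names_hm = [f"HM{i + 1:02d}" for i in range(cfg.n_haploid_males)]
    samples = names_f + names_dm + names_hm
    n_dip = cfg.n_females + cfg.n_diploid_males
    is_hap = np.array([False] * n_dip + [True] * cfg.n_haploid_males)
    labels, locus_calls = _assign_locus_genotypes(cfg, rng, hap_seqs, is_hap)

    # --- background SNPs: i.i.d. allele frequency 1/2 -------------------
    site_frames = []
    call_blocks = []
    p_bg_site = min(1.0, 2.0 * cfg.background_het)
    for chrom in cfg.chrom_names:
        n_bg = rng.binomial(cfg.chrom_length, p_bg_site)
        pos = np.sort(rng.choice(cfg.chrom_length, size=n_bg, replace=False)) + 1
        if chrom == cfg.locus_chrom:
            # within the locus, all variation is carried by the haplotypes
            # themselves (complete linkage across the region); unlinked
            # background sites are placed outside it
            pos = pos[(pos < cfg.locus_start) | (pos > cfg.locus_end)]
            n_bg = len(pos)
        # two allele draws for diploids, one for haploids
        a = rng.integers(0, 2, size=(n_bg, len(samples)), dtype=np.int8)
        b = rng.integers(0, 2, size=(n_bg, len(samples)), dtype=np.int8)
        calls = np.where(a == b, np.where(a == 1, Call.HOM_ALT, Call.HOM_REF), Call.HET).astype(np.int8)
        calls[:, is_hap] = np.where(a[:, is_hap] == 1, Call.HAP_ALT, Call.HAP_REF)
        if chrom == cfg.locus_chrom and len(locus_pos):
            pos = np.concatenate([pos, locus_pos])
            order = np.argsort(pos, kind="stable")
            calls = np.vstack([calls, locus_calls])[order]
            pos = pos[order]
        site_frames.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
        call_blocks.append(calls)

    sites = pd.concat(site_frames, ignore_index=True)
    calls = np.vstack(call_blocks) if call_blocks else np.empty((0, len(samples)), np.int8)

    # REF/ALT nucleotides: distinct bases per site
    nref = rng.integers(0, 4, size=len(sites))
    nalt = (nref + rng.integers(1, 4, size=len(sites))) % 4
    sites["ref"] = _BASES[nref].astype("U1")
    sites["alt"] = _BASES[nalt].astype("U1")
    sites["qual"] = np.round(rng.uniform(30.0, 60.0, size=len(sites)), 1)

    # --- genotype errors: symmetric HET <-> HOM flips -------------------
    if cfg.genotype_error > 0:
        flip = rng.random(calls.shape) < cfg.genotype_error
        dip_cols = ~is_hap
        dip = calls[:, dip_cols]
        fd = flip[:, dip_cols]
        to_hom = rng.integers(0, 2, size=dip.shape).astype(np.int8) * 2  # HOM_REF or HOM_ALT
        new = dip.copy()
        new[fd & (dip == Call.HET)] = to_hom[fd & (dip == Call.HET)]
        new[fd & ((dip == Call.HOM_REF) | (dip == Call.HOM_ALT))] = Call.HET
        calls[:, dip_cols] = new
        hap = calls[:, is_hap]
        fh = flip[:, is_hap]
        hap[fh & (hap == Call.HAP_REF)] = Call.HAP_ALT
        hap[fh & (hap == Call.HAP_ALT)] = Call.HAP_REF
        calls[:, is_hap] = hap

    gm = GenotypeMatrix(sites, samples, calls, cfg.chrom_lengths)

    # --- mask: random tracts outside the locus --------------------------
    mask = _draw_mask(cfg, rng)

    # --- metadata and truth ---------------------------------------------
    st = SampleTable(
        pd.DataFrame(
            {
                "sex": ["female"] * cfg.n_females + ["male"] * (cfg.n_diploid_males + cfg.n_haploid_males),
                "ploidy": ["2"] * n_dip + ["1"] * cfg.n_haploid_males,
                "group": "sim",
                "role": "case",
            },
            index=pd.Index(samples, name="sample"),
        )
    )
    truth = TruthRecord(
        locus=cfg.locus,
        haplotype_labels=dict(zip(samples, labels)),
        ploidy={s: (1 if h else 2) for s, h in zip(samples, is_hap)},
        haplotype_sequences=hap_seqs,
        locus_positions=locus_pos,
    )
    return gm, st, mask, truth


def _assign_locus_genotypes(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    hap_seqs: np.ndarray,
    is_hap: np.ndarray,
) -> tuple[list[tuple[int, ...]], np.ndarray]:
    """Haplotype assignments and the locus-site calls they imply."""
    k, n_sites = hap_seqs.shape
    n_samples = len(is_hap)
    calls = np.empty((n_sites, n_samples), dtype=np.int8)
    labels: list[tuple[int, ...]] = []
    female_pairs = _assign_female_pairs(cfg, rng) if cfg.n_females and k >= 2 else np.empty((0, 2), np.int64)
    j = 0
    for _ in range(cfg.n_females):
        if k < 2:
            h = int(rng.integers(k))
            pair = (h, h)
        else:
            pair = tuple(sorted(map(int, female_pairs[j])))
        a, b = hap_seqs[pair[0]], hap_seqs[pair[1]]
        calls[:, j] = np.where(a != b, Call.HET, np.where(a == 1, Call.HOM_ALT, Call.HOM_REF))
        labels.append(pair)
        j += 1
    for _ in range(cfg.n_diploid_males):
        h = int(rng.integers(k))
        s = hap_seqs[h]
        calls[:, j] = np.where(s == 1, Call.HOM_ALT, Call.HOM_REF)
        labels.append((h, h))
        j += 1
    for _ in range(cfg.n_haploid_males):
        h = int(rng.integers(k))
        s = hap_seqs[h]
        calls[:, j] = np.where(s == 1, Call.HAP_ALT, Call.HAP_REF)
        labels.append((h,))
        j += 1
    return labels, calls


def _draw_mask(cfg: SimulationConfig, rng: np.random.Generator) -> MaskTrack:
    """Random repeat tracts (geometric lengths, mean 500 bp) totalling
    ~masked_fraction of the genome, never intersecting the locus."""
    target = cfg.masked_fraction * cfg.n_chrom * cfg.chrom_length
    ivals: list[Interval] = []
    total = 0
    guard = 0
    while total < target and guard < 100_000:
        guard += 1
        chrom = cfg.chrom_names[int(rng.integers(cfg.n_chrom))]
        length = int(rng.geometric(1 / 500.0))
        start = int(rng.integers(1, cfg.chrom_length - length + 2))
        iv = Interval(chrom, start, min(start + length - 1, cfg.chrom_length))
        if iv.overlaps(cfg.locus):
            continue
        ivals.append(iv)
        total += iv.length
    return MaskTrack.from_intervals(ivals)


def emit_cohort(
    gm: GenotypeMatrix,
    st: SampleTable,
    mask: MaskTrack,
    truth: TruthRecord,
    outdir: str | Path,
    seed: int = 0,
) -> dict[str, Path]:
    """Write VCF + soft-masked FASTA + sample TSV + truth JSON to `outdir`.

    The FASTA carries the REF allele at every SNP position and lowercase
    bases over masked tracts, so re-reading with the io layer reproduces the
    in-memory mask and genotypes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "cohort.vcf",
        "fasta": outdir / "reference.fa",
        "samples": outdir / "samples.tsv",
        "truth": outdir / "truth.json",
        "anchors": outdir / "anchors.bed",
    }
    write_vcf(gm, paths["vcf"])
    write_samples(st, paths["samples"])
    paths["truth"].write_text(truth.to_json())
    # anchor interval standing in for the flanking gene upstream of the locus
    a_end = max(1, truth.locus.start - 5000)
    anchor = Interval(truth.locus.chrom, max(1, a_end - 2000), a_end)
    write_bed([anchor], paths["anchors"], ["anchor"])

    rng = np.random.default_rng(seed + 7)
    with open(paths["fasta"], "w") as fh:
        for chrom, length in gm.chrom_lengths.items():
            seq = _BASES[rng.integers(0, 4, size=length)].copy()
            on_chrom = gm.chrom_mask(chrom)
            pos = gm.sites.loc[on_chrom, "pos"].to_numpy()
            refs = gm.sites.loc[on_chrom, "ref"].to_numpy().astype("S1")
            seq[pos - 1] = refs
            arr = np.frombuffer(seq.tobytes(), dtype=np.uint8).copy()
            for s, e in mask.intervals.get(chrom, []):
                arr[s - 1 : e] += 32  # ASCII lowercase
            text = arr.tobytes().decode("ascii")
            fh.write(f">{chrom}\n")
            for i in range(0, length, 80):
                fh.write(text[i : i + 80] + "\n")
    return paths
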