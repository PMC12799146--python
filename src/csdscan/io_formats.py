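"""Readers and writers for the standard formats the pipeline touches.

VCF v4.x genotypes (via cyvcf2) are filtered down to high-quality biallelic
SNPs at read time; soft-masked reference FASTA yields a hard-mask track from
its lowercase runs; window tracks and intervals round-trip through
BED-compatible TSV (0-based half-open on disk, 1-based inclusive in memory).
"""
from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from pyfaidx import Fasta

from .genotypes import Call, GenotypeMatrix, SampleTable
from .intervals import Interval, MaskTrack
from .windows import WindowTrack

logger = logging.getLogger(__name__)

__all__ = [
    "read_vcf",
    "write_vcf",
    "mask_from_fasta",
    "write_track",
    "read_track",
    "read_samples",
    "write_samples",
    "write_bed",
]

_NUCS = frozenset("ACGT")


def _map_genotype(gt: list) -> int:
    """Map a cyvcf2 genotype entry to a Call code.

    Diploid entries are [a, b, phased]; haploid entries are [a, phased].
    Any entry containing a missing allele maps to MISSING.
    """
    alleles = gt[:-1]
    if any(a < 0 for a in alleles):
        return Call.MISSING
    if len(alleles) == 1:
        return Call.HAP_ALT if alleles[0] else Call.HAP_REF
    a, b = alleles
    if a != b:
        return Call.HET
    return Call.HOM_ALT if a else Call.HOM_REF


def read_vcf(
    path: str | Path,
    min_qual: float = 20.0,
    biallelic_snps_only: bool = True,
) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix, applying quality and SNP filters.

    Records with QUAL below `min_qual` (missing QUAL fails any positive
    threshold), more than two alleles, or non-SNP alleles are dropped when
    `biallelic_snps_only` is set. Haploid GT fields map to HAP_* codes,
    "./." and "." to MISSING.
    """
    if min_qual < 0:
        raise ValueError("min_qual must be >= 0")
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError on bad input
        raise ValueError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    chrom_lengths = dict(zip(vcf.seqnames, vcf.seqlens)) if vcf.seqnames else {}

    recs: list[tuple] = []
    calls: list[np.ndarray] = []
    seen: set[tuple[str, int]] = set()
    for var in vcf:
        qual = var.QUAL
        if qual is None:
            if min_qual > 0:
                continue
            qual = 0.0
        elif qual < min_qual:
            continue
        if biallelic_snps_only:
            if len(var.ALT) != 1:
                continue
            if len(var.REF) != 1 or len(var.ALT[0]) != 1:
                continue
            if var.REF not in _NUCS or var.ALT[0] not in _NUCS:
                continue
        key = (var.CHROM, var.POS)
        if key in seen:
            raise ValueError(f"duplicate record at {var.CHROM}:{var.POS}")
        seen.add(key)
        recs.append((var.CHROM, var.POS, var.REF, var.ALT[0], float(qual)))
        calls.append(
            np.fromiter(
                (_map_genotype(g) for g in var.genotypes), dtype=np.int8, count=len(samples)
            )
        )
    sites = pd.DataFrame(recs, columns=["chrom", "pos", "ref", "alt", "qual"])
    mat = (
        np.vstack(calls) if calls else np.empty((0, len(samples)), dtype=np.int8)
    )
    order = sites.sort_values(["chrom", "pos"], kind="stable").index.to_numpy()
    sites = sites.iloc[order].reset_index(drop=True)
    mat = mat[order]
    return GenotypeMatrix(sites, samples, mat, chrom_lengths)


_GT_STR = {
    Call.MISSING: None,  # depends on sample ploidy
    Call.HOM_REF: "0/0",
    Call.HET: "0/1",
    Call.HOM_ALT: "1/1",
    Call.HAP_REF: "0",
    Call.HAP_ALT: "1",
}


def write_vcf(gm: GenotypeMatrix, path: str | Path, haploid_samples: set[str] | None = None) -> None:
    """Serialize a GenotypeMatrix as a minimal VCF v4.2 with GT fields."""
    haploid_samples = haploid_samples or {
        s for s in gm.samples if gm.is_haploid_coded(s)
    }
    hap = [s in haploid_samples for s in gm.samples]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in gm.chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for i, row in enumerate(gm.sites.itertuples()):
            gts = []
            for j, is_hap in enumerate(hap):
                c = Call(gm.calls[i, j])
                s = _GT_STR[c]
                if s is None:
                    s = "." if is_hap else "./."
                gts.append(s)
            qual = f"{row.qual:g}"
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t{qual}\t.\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


_LOWER_RE = re.compile(r"[a-z]+")
_N_RE = re.compile(r"[a-zNn]+")


def mask_from_fasta(
    path: str | Path,
    mask_n: bool = True,
    known_chroms: set[str] | None = None,
) -> MaskTrack:
    """Build a hard-mask track from the lowercase (soft-masked) runs of a FASTA.

    Maximal runs of lowercase characters become masked intervals (1-based
    inclusive). N characters count as masked by default (unsequenced is
    unusable); pass ``mask_n=False`` to mask lowercase only.
    """
    fa = Fasta(str(path), rebuild=False, as_raw=True)
    pat = _N_RE if mask_n else _LOWER_RE
    ivals: dict[str, np.ndarray] = {}
    for name in fa.keys():
        if known_chroms is not None and name not in known_chroms:
            raise ValueError(f"sequence {name!r} not among known chromosomes")
        seq = str(fa[name][:])
        runs = [(m.start() + 1, m.end()) for m in pat.finditer(seq)]
        if runs:
            ivals[name] = np.asarray(runs, dtype=np.int64)
    return MaskTrack(ivals)


def write_track(track: WindowTrack, path: str | Path) -> None:
    """Write a WindowTrack as BED-compatible TSV (0-based half-open starts)."""
    w = track.windows
    out = pd.DataFrame(
        {
            "chrom": w["chrom"],
            "start": w["start"] - 1,
            "end": w["end"],
            "value": w["value"],
            "masked_fraction": w["masked_fraction"],
            "full_width": w["full_width"].astype(int),
        }
    )
    with open(path, "w") as fh:
        fh.write(f"#label={track.label}\n")
        out.to_csv(fh, sep="\t", index=False)


def read_track(path: str | Path) -> WindowTrack:
    """Read a TSV written by :func:`write_track` back into a WindowTrack."""
    label = ""
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#label="):
            label = first.strip().split("=", 1)[1]
            df = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
    df["start"] = df["start"] + 1
    df["full_width"] = df["full_width"].astype(bool)
    return WindowTrack(df, label=label)


def write_bed(ivals: list[Interval], path: str | Path, names: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(ivals):
            chrom, s0, e0 = iv.to_bed_fields()
            name = names[i] if names else f"region{i + 1}"
            fh.write(f"{chrom}\t{s0}\t{e0}\t{name}\n")


def read_bed(path: str | Path) -> list[Interval]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append(Interval.from_bed_fields(f[0], int(f[1]), int(f[2])))
    return out


def read_samples(path: str | Path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("sample")
    return SampleTable(df)


def write_samples(st: SampleTable, path: str | Path) -> None:
    st.df.to_csv(path, sep="\t", index_label="sample")
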