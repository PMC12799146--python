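"""Ploidy classification from genome-wide heterozygosity, and runs of homozygosity.

In haplodiploid species, males normally develop from unfertilized haploid
eggs; diploid males (from eggs homozygous at the sex locus) are detected by
comparing each male's genome-wide heterozygosity with that of diploid
females. A truly haploid genome yields (almost) no heterozygous calls —
residual het comes from genotyping error — while a diploid male matches the
female baseline everywhere except the sex locus.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import Call, GenotypeMatrix
from .intervals import Interval, MaskTrack

__all__ = ["PloidyCall", "genomewide_het_rate", "classify_ploidy", "detect_roh"]


@dataclass(frozen=True)
class PloidyCall:
    sample: str
    het_rate: float
    call: str  # haploid | diploid | ambiguous
    reference_stat: float  # female median het rate used for thresholding


def genomewide_het_rate(
    gm: GenotypeMatrix, sample: str, mask: MaskTrack | None = None
) -> float:
    """HET calls per callable (non-missing, unmasked) genotyped site."""
    calls = gm.sample_calls(sample)
    callable_ = calls != Call.MISSING
    if mask is not None:
        masked = np.zeros(gm.n_sites, dtype=bool)
        for chrom in gm.chroms:
            on = gm.chrom_mask(chrom)
            masked[on] = mask.is_masked(chrom, gm.sites.loc[on, "pos"].to_numpy())
        callable_ &= ~masked
    n = int(callable_.sum())
    if n == 0:
        raise ValueError(f"sample {sample!r} has no callable sites")
    return float(np.sum(calls[callable_] == Call.HET)) / n


def classify_ploidy(
    rates: dict[str, float],
    female_rates: dict[str, float],
    low_frac: float = 0.1,
    high_frac: float = 0.5,
) -> list[PloidyCall]:
    """Classify each male as haploid / diploid / ambiguous.

    A male is diploid if his het rate reaches `high_frac` of the female
    median, haploid if it falls below `low_frac` of it, ambiguous between
    the bands.
    """
    if not female_rates:
        raise ValueError("need at least one female rate for the reference")
    ref = float(np.median(list(female_rates.values())))
    out = []
    for sample, r in rates.items():
        if r >= high_frac * ref:
            call = "diploid"
        elif r <= low_frac * ref:
            call = "haploid"
        else:
            call = "ambiguous"
        out.append(PloidyCall(sample, r, call, ref))
    return out


def detect_roh(
    gm: GenotypeMatrix,
    sample: str,
    min_snps: int = 50,
    max_het: int = 1,
    min_length: int = 10_000,
) -> list[Interval]:
    """Runs of homozygosity in a diploid sample.

    A greedy left-to-right scan over genotyped (non-missing) sites per
    chromosome builds maximal runs containing at most `max_het` HET calls;
    runs are trimmed of leading/trailing HET calls, then kept if they hold
    at least `min_snps` sites and span at least `min_length` bp. Output is
    sorted and non-overlapping.
    """
    calls = gm.sample_calls(sample)
    if gm.is_haploid_coded(sample) and (calls != Call.MISSING).any():
        raise ValueError(f"sample {sample!r} is haploid: ROH undefined")
    out: list[Interval] = []
    for chrom in gm.chroms:
        on = gm.chrom_mask(chrom)
        pos = gm.sites.loc[on, "pos"].to_numpy()
        c = calls[on]
        keep = c != Call.MISSING
        pos, c = pos[keep], c[keep]
        is_het = c == Call.HET
        i = 0
        n = len(pos)
        while i < n:
            het_used = 0
            j = i
            while j < n:
                if is_het[j]:
                    if het_used + 1 > max_het:
                        break
                    het_used += 1
                j += 1
            # run is sites [i, j); trim HET edges
            a, b = i, j - 1
            while a <= b and is_het[a]:
                a += 1
            while b >= a and is_het[b]:
                b -= 1
            if a <= b:
                n_snps = b - a + 1
                span = int(pos[b] - pos[a] + 1)
                if n_snps >= min_snps and span >= min_length:
                    out.append(Interval(chrom, int(pos[a]), int(pos[b])))
            i = j if j > i else i + 1
    return out
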