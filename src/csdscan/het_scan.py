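"""Sliding-window heterozygosity scans and candidate-locus delineation.

A female carrying two divergent haplotypes at a complementary
sex-determination locus shows a sharp localized excess of heterozygous SNPs.
This module counts heterozygous sites per individual in masked sliding
windows (default 5 kb windows, 1 kb steps), normalizes counts across genomes
with (x - mu) / (x99 - mu) so scans are comparable despite different
baseline diversity, ranks windows genome-wide, and delineates the candidate
region around an anchored peak as the span of the three most heterozygous
windows.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import Call, GenotypeMatrix
from .intervals import Interval, MaskTrack
from .windows import WindowTrack, make_windows

__all__ = [
    "NormalizationParams",
    "count_het_windows",
    "normalize_track",
    "percentile_rank",
    "find_peak_downstream",
    "candidate_region_top3",
]


@dataclass(frozen=True)
class NormalizationParams:
    """Genome-wide mean and 99th percentile of window het counts."""

    mu: float
    x99: float


def count_het_windows(
    gm: GenotypeMatrix,
    sample: str,
    mask: MaskTrack | None = None,
    w: int = 5000,
    s: int = 1000,
    na_mask_threshold: float = 0.5,
) -> WindowTrack:
    """Heterozygous-site count per sliding window for one diploid sample.

    Masked sites and MISSING calls contribute nothing. Windows with masked
    fraction above `na_mask_threshold` are flagged NA; trailing truncated
    windows keep their counts but are marked not full-width (both are
    excluded from normalization statistics).
    """
    if s < 1 or w < s:
        raise ValueError(f"require w >= s >= 1, got w={w}, s={s}")
    calls = gm.sample_calls(sample)
    if gm.is_haploid_coded(sample) and (calls != Call.MISSING).any():
        raise ValueError(f"sample {sample!r} is haploid: no heterozygosity scan")
    mask = mask or MaskTrack()
    chrom_lengths = gm.chrom_lengths or {
        c: int(gm.positions(c).max()) for c in gm.chroms
    }
    win = make_windows(chrom_lengths, w, s, mask)
    values = np.zeros(len(win), dtype=float)
    for chrom in chrom_lengths:
        on = gm.chrom_mask(chrom)
        pos = gm.sites.loc[on, "pos"].to_numpy()
        het = calls[on] == Call.HET
        if mask.intervals.get(chrom) is not None:
            het = het & ~mask.is_masked(chrom, pos)
        het_pos = pos[het]
        rows = (win["chrom"] == chrom).to_numpy()
        starts = win.loc[rows, "start"].to_numpy()
        ends = win.loc[rows, "end"].to_numpy()
        lo = np.searchsorted(het_pos, starts, side="left")
        hi = np.searchsorted(het_pos, ends, side="right")
        values[rows] = hi - lo
    win = win.copy()
    win["value"] = values
    win.loc[win["masked_fraction"] > na_mask_threshold, "value"] = np.nan
    return WindowTrack(win, label=sample, meta={"w": w, "s": s, "stat": "het_count"})


def normalize_track(track: WindowTrack) -> tuple[WindowTrack, NormalizationParams]:
    """Normalize window values to (x - mu) / (x99 - mu).

    mu is the genome-wide mean and x99 the 99th percentile (linear
    interpolation between order statistics) over full-width, non-NA windows.
    NA windows stay NA. A degenerate track (x99 == mu, e.g. constant counts)
    raises rather than dividing by zero.
    """
    w = track.windows
    usable = w["full_width"].to_numpy() & ~np.isnan(w["value"].to_numpy())
    vals = w.loc[usable, "value"].to_numpy(dtype=float)
    if len(vals) < 2:
        raise ValueError("need >= 2 usable windows to normalize")
    mu = float(np.mean(vals))
    x99 = float(np.percentile(vals, 99))
    if x99 == mu:
        raise ValueError(f"degenerate track: x99 == mu == {mu}")
    out = w.copy()
    out["value"] = (w["value"] - mu) / (x99 - mu)
    return (
        WindowTrack(out, label=track.label, meta={**track.meta, "stat": "het_norm"}),
        NormalizationParams(mu=mu, x99=x99),
    )


def percentile_rank(track: WindowTrack, focal: Interval) -> float:
    """Percent of non-NA windows with value >= the focal window's value.

    Small values mark genome-wide outliers (a strict maximum among N windows
    ranks 100/N %).
    """
    idx = track.window_index(focal)
    v = track.values
    focal_value = v[idx]
    if np.isnan(focal_value):
        raise ValueError("focal window is NA")
    ok = ~np.isnan(v)
    return 100.0 * float(np.sum(v[ok] >= focal_value)) / float(np.sum(ok))


def find_peak_downstream(
    track: WindowTrack, anchor: Interval, search_span: int = 100_000
) -> Interval | None:
    """Most heterozygous window downstream of an anchor gene.

    Considers windows whose start lies in (anchor.end, anchor.end +
    search_span] on the anchor's chromosome, in plus-strand orientation.
    Ties break toward the smaller start. Returns None when no non-NA window
    lies in the span (empty result, not an error).
    """
    w = track.windows
    sel = (
        (w["chrom"] == anchor.chrom)
        & (w["start"] > anchor.end)
        & (w["start"] <= anchor.end + search_span)
        & ~w["value"].isna()
    ).to_numpy()
    if not sel.any():
        return None
    sub = w.loc[sel]
    best = sub.loc[sub["value"].idxmax()]  # idxmax: first occurrence on ties
    return Interval(best["chrom"], int(best["start"]), int(best["end"]))


def candidate_region_top3(
    track: WindowTrack, peak: Interval, neighborhood: int = 10_000
) -> Interval:
    """Span of the three most heterozygous windows around a peak.

    Windows intersecting peak +/- neighborhood are ranked by value (ties to
    the smaller start); the returned interval runs from the smallest start
    to the largest end among the top three (fewer if fewer exist).
    """
    w = track.windows
    lo = max(1, peak.start - neighborhood)
    hi = peak.end + neighborhood
    sel = (
        (w["chrom"] == peak.chrom)
        & (w["end"] >= lo)
        & (w["start"] <= hi)
        & ~w["value"].isna()
    ).to_numpy()
    if not sel.any():
        return peak
    sub = w.loc[sel].sort_values(["value", "start"], ascending=[False, True], kind="stable")
    top = sub.head(3)
    return Interval(peak.chrom, int(top["start"].min()), int(top["end"].max()))
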