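"""Sex-locus mapping by contrasting homozygosity between females and diploid males.

Under complementary sex determination, females are heterozygous at the sex
locus while diploid males are homozygous there; everywhere else the two
groups look alike. Per SNP, the proportion of homozygous individuals in each
sex is compared with a two-proportion Z-test, the discordant interval
(consistently heterozygous females / homozygous diploid males) is
delineated, and an exact two-tailed binomial test supports crossing-design
checks (e.g. 18 of 30 sib-mated queens producing early males against a 50%
expectation gives P = 0.36).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import Call, GenotypeMatrix, SampleTable
from .intervals import Interval

__all__ = [
    "SnpContrast",
    "homozygote_proportions",
    "two_proportion_z",
    "scan_sex_contrast",
    "binomial_two_tailed",
    "find_discordant_interval",
]

_HOM = (int(Call.HOM_REF), int(Call.HOM_ALT))


@dataclass(frozen=True)
class SnpContrast:
    chrom: str
    pos: int
    p_hom_female: float
    n_female: int
    p_hom_male: float
    n_male: int
    z: float
    p_value: float
    degenerate: bool = False


def _group_counts(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (n_hom, n_callable) over a block of diploid samples."""
    callable_ = np.isin(calls, (Call.HOM_REF, Call.HET, Call.HOM_ALT))
    hom = np.isin(calls, _HOM)
    return hom.sum(axis=1), callable_.sum(axis=1)


def homozygote_proportions(
    gm: GenotypeMatrix, st: SampleTable
) -> pd.DataFrame:
    """Per-site homozygote proportions for females and diploid males.

    Denominators are per-site non-missing diploid calls; sites where a group
    has no callable individual get an NA proportion.
    """
    females = st.females()
    males = st.diploid_males()
    if not females or not males:
        raise ValueError("need >= 1 female and >= 1 diploid male")
    fi = [gm.sample_index(s) for s in females]
    mi = [gm.sample_index(s) for s in males]
    f_hom, f_n = _group_counts(gm.calls[:, fi])
    m_hom, m_n = _group_counts(gm.calls[:, mi])
    with np.errstate(divide="ignore", invalid="ignore"):
        p_f = np.where(f_n > 0, f_hom / np.maximum(f_n, 1), np.nan)
        p_m = np.where(m_n > 0, m_hom / np.maximum(m_n, 1), np.nan)
    return pd.DataFrame(
        {
            "chrom": gm.sites["chrom"],
            "pos": gm.sites["pos"],
            "p_hom_female": p_f,
            "n_female": f_n,
            "p_hom_male": p_m,
            "n_male": m_n,
        }
    )


def two_proportion_z(p1: float, n1: int, p2: float, n2: int) -> tuple[float, float]:
    """Two-proportion Z-test (pooled, no continuity correction).

    z = (p1 - p2) / sqrt(phat (1 - phat) (1/n1 + 1/n2)) with the pooled
    phat = (p1 n1 + p2 n2) / (n1 + n2); two-sided p = 2 Phi(-|z|). When the
    pooled proportion is 0 or 1 (both groups uniform), the statistic is
    degenerate: z = 0, p = 1 by convention.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be >= 1")
    phat = (p1 * n1 + p2 * n2) / (n1 + n2)
    if phat <= 0.0 or phat >= 1.0:
        return 0.0, 1.0
    se = math.sqrt(phat * (1.0 - phat) * (1.0 / n1 + 1.0 / n2))
    z = (p1 - p2) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return z, float(p)


def scan_sex_contrast(gm: GenotypeMatrix, st: SampleTable) -> pd.DataFrame:
    """Per-SNP two-proportion Z-tests of female vs diploid-male homozygosity.

    Returns a table with chrom, pos, the group proportions and sizes, z,
    p, -log10(p), a degenerate flag, and a Bonferroni-adjusted column for
    convenience. Sites with an NA proportion are skipped; the count of
    skipped sites is stored in ``df.attrs['n_skipped']``.
    """
    props = homozygote_proportions(gm, st)
    valid = (~props["p_hom_female"].isna()) & (~props["p_hom_male"].isna())
    df = props[valid].reset_index(drop=True).copy()
    n1 = df["n_female"].to_numpy(dtype=float)
    n2 = df["n_male"].to_numpy(dtype=float)
    p1 = df["p_hom_female"].to_numpy()
    p2 = df["p_hom_male"].to_numpy()
    phat = (p1 * n1 + p2 * n2) / (n1 + n2)
    degen = (phat <= 0.0) | (phat >= 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(phat * (1 - phat) * (1 / n1 + 1 / n2))
        z = np.where(degen, 0.0, (p1 - p2) / np.where(se > 0, se, 1.0))
    p = np.where(degen, 1.0, 2.0 * stats.norm.sf(np.abs(z)))
    df["z"] = z
    df["p_value"] = p
    with np.errstate(divide="ignore"):
        df["neglog10p"] = -np.log10(p)
    df["degenerate"] = degen
    df["p_bonferroni"] = np.minimum(1.0, p * len(df))
    df.attrs["n_skipped"] = int((~valid).sum())
    return df


def binomial_two_tailed(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-tailed binomial probability (minimum-likelihood method).

    Sums the probabilities of all outcomes no more probable than the
    observed k; at p0 = 0.5 this equals doubling the one-sided tail.
    """
    if not (0 <= k <= n) or not (0.0 < p0 < 1.0):
        raise ValueError(f"invalid binomial test domain: k={k}, n={n}, p0={p0}")
    return float(stats.binomtest(k, n, p0).pvalue)


def _discordant_flags(
    gm: GenotypeMatrix,
    st: SampleTable,
    min_frac_het_female: float,
    min_frac_hom_male: float,
) -> np.ndarray:
    females = st.females()
    males = st.diploid_males()
    if not females or not males:
        raise ValueError("need >= 1 female and >= 1 diploid male")
    fcalls = gm.calls[:, [gm.sample_index(s) for s in females]]
    mcalls = gm.calls[:, [gm.sample_index(s) for s in males]]
    f_call = np.isin(fcalls, (Call.HOM_REF, Call.HET, Call.HOM_ALT)).sum(axis=1)
    f_het = (fcalls == Call.HET).sum(axis=1)
    m_hom, m_call = _group_counts(mcalls)
    with np.errstate(invalid="ignore"):
        ok = (f_call > 0) & (m_call > 0)
        return (
            ok
            & (f_het >= min_frac_het_female * f_call)
            & (m_hom >= min_frac_hom_male * m_call)
        )


def find_discordant_interval(
    gm: GenotypeMatrix,
    st: SampleTable,
    min_frac_het_female: float = 1.0,
    min_frac_hom_male: float = 1.0,
    max_gap_snps: int = 0,
) -> list[Interval]:
    """Delineate interval(s) heterozygous in females, homozygous in diploid males.

    A SNP is discordant when at least `min_frac_het_female` of callable
    females are HET and at least `min_frac_hom_male` of callable diploid
    males are HOM. Runs of discordant SNPs (tolerating up to `max_gap_snps`
    non-discordant SNPs inside) are reported as intervals from first to last
    discordant SNP, sorted longest-first (by discordant-SNP count, then bp
    length, then position). Empty list when no SNP qualifies.
    """
    disc = _discordant_flags(gm, st, min_frac_het_female, min_frac_hom_male)
    runs: list[tuple[int, int, Interval]] = []
    for chrom in gm.chroms:
        on = gm.chrom_mask(chrom)
        pos = gm.sites.loc[on, "pos"].to_numpy()
        d = disc[on]
        idx = np.flatnonzero(d)
        if len(idx) == 0:
            continue
        start = idx[0]
        prev = idx[0]
        count = 1
        for i in idx[1:]:
            if i - prev - 1 <= max_gap_snps:
                count += 1
            else:
                runs.append(
                    (count, int(pos[prev] - pos[start] + 1), Interval(chrom, int(pos[start]), int(pos[prev])))
                )
                start = i
                count = 1
            prev = i
        runs.append(
            (count, int(pos[prev] - pos[start] + 1), Interval(chrom, int(pos[start]), int(pos[prev])))
        )
    runs.sort(key=lambda t: (-t[0], -t[1], t[2].chrom, t[2].start))
    return [iv for _, _, iv in runs]
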