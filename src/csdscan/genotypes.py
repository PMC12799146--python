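"""Genotype call codes, the sites x samples genotype matrix, and sample metadata.

Calls are stored as a compact int8 matrix. Diploid calls are HOM_REF / HET /
HOM_ALT; haploid (hemizygous) calls are HAP_REF / HAP_ALT; anything
uncallable is MISSING. A sample declared haploid never carries diploid codes.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd

from .intervals import Interval

__all__ = ["Call", "VariantSite", "GenotypeMatrix", "SampleTable"]


class Call(IntEnum):
    MISSING = -1
    HOM_REF = 0
    HET = 1
    HOM_ALT = 2
    HAP_REF = 3
    HAP_ALT = 4


DIPLOID_CALLS = (Call.HOM_REF, Call.HET, Call.HOM_ALT)
HAPLOID_CALLS = (Call.HAP_REF, Call.HAP_ALT)
HOM_CALLS = (Call.HOM_REF, Call.HOM_ALT)

_NUCS = frozenset("ACGT")


@dataclass(frozen=True)
class VariantSite:
    """A biallelic SNP: single-nucleotide REF and ALT at a 1-based position."""

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float = 0.0

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(f"not a SNP: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.qual < 0:
            raise ValueError("qual must be non-negative")


@dataclass
class GenotypeMatrix:
    """Biallelic-SNP genotype calls for a cohort.

    Attributes
    ----------
    sites : DataFrame with columns chrom, pos, ref, alt, qual, sorted by
        (chrom, pos) with no duplicate positions.
    samples : ordered sample identifiers.
    calls : int8 array of shape (n_sites, n_samples) holding `Call` codes.
    chrom_lengths : chromosome sizes in bp (from VCF contig headers or FASTA).
    """

    sites: pd.DataFrame
    samples: list[str]
    calls: np.ndarray
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        if len(self.sites):
            dup = self.sites.duplicated(subset=["chrom", "pos"])
            if dup.any():
                bad = self.sites[dup].iloc[0]
                raise ValueError(f"duplicate site {bad.chrom}:{bad.pos}")
            by = self.sites.sort_values(["chrom", "pos"], kind="stable")
            if not (by.index == self.sites.index).all():
                raise ValueError("sites must be sorted by (chrom, pos)")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.sites["chrom"])) if self.n_sites else []

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def sample_calls(self, sample: str) -> np.ndarray:
        return self.calls[:, self.sample_index(sample)]

    def chrom_mask(self, chrom: str) -> np.ndarray:
        return (self.sites["chrom"] == chrom).to_numpy()

    def positions(self, chrom: str) -> np.ndarray:
        return self.sites.loc[self.chrom_mask(chrom), "pos"].to_numpy()

    def is_haploid_coded(self, sample: str) -> bool:
        """True if the sample carries only HAP_*/MISSING codes."""
        c = self.sample_calls(sample)
        return not np.isin(c, [Call.HOM_REF, Call.HET, Call.HOM_ALT]).any()

    def site_interval(self, chrom: str) -> Interval | None:
        pos = self.positions(chrom)
        if len(pos) == 0:
            return None
        return Interval(chrom, int(pos[0]), int(pos[-1]))


_SEXES = {"female", "male"}
_PLOIDIES = {"1", "2", "unknown"}
_ROLES = {"case", "control", "unused"}


@dataclass
class SampleTable:
    """Per-sample metadata: sex, declared ploidy, group label, role.

    Backed by a DataFrame indexed by sample id with columns
    sex / ploidy / group / role.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"sex", "ploidy", "group", "role"}
        missing = need - set(self.df.columns)
        if missing:
            raise ValueError(f"sample table missing columns: {sorted(missing)}")
        self.df = self.df.copy()
        self.df["ploidy"] = self.df["ploidy"].astype(str)
        bad = set(self.df["sex"]) - _SEXES
        if bad:
            raise ValueError(f"invalid sex values: {sorted(bad)}")
        bad = set(self.df["ploidy"]) - _PLOIDIES
        if bad:
            raise ValueError(f"invalid ploidy values: {sorted(bad)}")
        bad = set(self.df["role"]) - _ROLES
        if bad:
            raise ValueError(f"invalid role values: {sorted(bad)}")
        if self.df.index.duplicated().any():
            raise ValueError("duplicate sample ids in sample table")

    @property
    def samples(self) -> list[str]:
        return list(self.df.index)

    def females(self) -> list[str]:
        return list(self.df.index[self.df["sex"] == "female"])

    def diploid_males(self) -> list[str]:
        sel = (self.df["sex"] == "male") & (self.df["ploidy"] == "2")
        return list(self.df.index[sel])

    def haploid_males(self) -> list[str]:
        sel = (self.df["sex"] == "male") & (self.df["ploidy"] == "1")
        return list(self.df.index[sel])

    def validate_against(self, gm: GenotypeMatrix) -> None:
        """Every genotyped sample must appear exactly once in the table.

        When a declared ploidy conflicts with the GT arity in the matrix,
        the declaration wins and a warning is logged.
        """
        missing = set(gm.samples) - set(self.df.index)
        if missing:
            raise ValueError(f"samples absent from table: {sorted(missing)}")
        import logging

        for s in gm.samples:
            declared = self.df.loc[s, "ploidy"]
            if declared == "unknown":
                continue
            coded_haploid = gm.is_haploid_coded(s)
            if (declared == "1") != coded_haploid:
                logging.getLogger(__name__).warning(
                    "sample %s declared ploidy %s but GT arity suggests %s; "
                    "declaration takes precedence",
                    s,
                    declared,
                    "1" if coded_haploid else "2",
                )
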