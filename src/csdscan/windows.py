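"""Sliding-window tracks of per-window statistics."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import Interval, MaskTrack

__all__ = ["WindowTrack", "make_windows"]

COLUMNS = ["chrom", "start", "end", "value", "masked_fraction", "full_width"]


@dataclass
class WindowTrack:
    """Per-window statistic values with genomic coordinates.

    `windows` columns: chrom, start, end (1-based inclusive), value (float,
    NaN = flagged NA), masked_fraction in [0, 1], full_width (False for
    trailing windows truncated at a chromosome end). `label` names the sample
    or aggregate the statistic was computed for.
    """

    windows: pd.DataFrame
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(COLUMNS) - set(self.windows.columns)
        if missing:
            raise ValueError(f"window track missing columns: {sorted(missing)}")
        mf = self.windows["masked_fraction"]
        if len(mf) and ((mf < 0) | (mf > 1)).any():
            raise ValueError("masked_fraction outside [0, 1]")

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def values(self) -> np.ndarray:
        return self.windows["value"].to_numpy(dtype=float)

    def non_na_values(self) -> np.ndarray:
        v = self.values
        return v[~np.isnan(v)]

    def intervals(self) -> list[Interval]:
        return [
            Interval(r.chrom, int(r.start), int(r.end))
            for r in self.windows.itertuples()
        ]

    def window_index(self, focal: Interval) -> int:
        w = self.windows
        hit = (
            (w["chrom"] == focal.chrom)
            & (w["start"] == focal.start)
            & (w["end"] == focal.end)
        )
        idx = np.flatnonzero(hit.to_numpy())
        if len(idx) == 0:
            raise KeyError(f"window {focal} not in track")
        return int(idx[0])

    def subset(self, rows: np.ndarray) -> "WindowTrack":
        return WindowTrack(
            self.windows.loc[rows].reset_index(drop=True), self.label, dict(self.meta)
        )


def make_windows(
    chrom_lengths: dict[str, int],
    w: int = 5000,
    s: int = 1000,
    mask: MaskTrack | None = None,
) -> pd.DataFrame:
    """Lay sliding windows of width `w` every `s` bp across each chromosome.

    Windows start at 1, 1+s, 2s+1, ... ; a trailing window shorter than `w`
    at the chromosome end keeps its true coordinates and is flagged
    full_width=False. Per-window masked fraction is annotated from `mask`.
    """
    if s < 1 or w < s:
        raise ValueError(f"require w >= s >= 1, got w={w}, s={s}")
    frames = []
    for chrom, length in chrom_lengths.items():
        starts = np.arange(1, length + 1, s, dtype=np.int64)
        ends = np.minimum(starts + w - 1, length)
        # drop windows fully implied by a previous identical trailing end
        keep = np.ones(len(starts), dtype=bool)
        full = (ends - starts + 1) == w
        # keep only the first trailing (truncated) window per chromosome
        trunc = ~full
        if trunc.sum() > 1:
            first_trunc = np.argmax(trunc)
            keep[first_trunc + 1 :] = False
        starts, ends, full = starts[keep], ends[keep], full[keep]
        if mask is not None:
            ov = mask.overlap_bp(chrom, starts, ends)
            mf = ov / (ends - starts + 1)
        else:
            mf = np.zeros(len(starts))
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": ends,
                    "value": np.nan,
                    "masked_fraction": mf,
                    "full_width": full,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=COLUMNS)
    return pd.concat(frames, ignore_index=True)
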