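"""Correlation between ROH incidence and local recombination rate.

A recombination map is a set of non-overlapping intervals per chromosome
with a rate in cM/Mb.  Each marker is assigned the rate of its containing
interval — half-open convention [start_bp, start_bp + span), so a marker
sitting exactly on an interval's end coordinate belongs to the next
interval.  Markers falling in map gaps get NaN and are excluded from the
correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .detection import IncidenceTrack
from .genotypes import MarkerMap


@dataclass
class RecombinationMap:
    """Columns: chrom, start_bp, end_bp, cM_per_Mb.

    Intervals are half-open [start_bp, end_bp): an interval ending at X
    and the next starting at X are adjacent, not overlapping.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "start_bp", "end_bp", "cM_per_Mb"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"recombination map needs columns {sorted(required)}")
        f = self.frame.reset_index(drop=True).copy()
        f["chrom"] = f["chrom"].astype(str)
        if (f["cM_per_Mb"] < 0).any():
            raise ValueError("negative recombination rate")
        for chrom, grp in f.groupby("chrom"):
            s = grp["start_bp"].to_numpy()
            e = grp["end_bp"].to_numpy()
            if (np.diff(s) < 0).any():
                raise ValueError(f"unsorted intervals on chromosome {chrom}")
            if (s[1:] < e[:-1]).any():
                raise ValueError(f"overlapping intervals on chromosome {chrom}")
        self.frame = f

    @classmethod
    def from_tsv(cls, path: str) -> "RecombinationMap":
        return cls(pd.read_csv(path, sep="\t", dtype={"chrom": str}))

    def to_tsv(self, path: str) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def rate_at_positions(R: RecombinationMap, M: MarkerMap) -> np.ndarray:
    """Per-marker cM/Mb rate; NaN for markers outside every interval."""
    rates = np.full(len(M), np.nan)
    pos_all = M.frame["pos"].to_numpy()
    chrom_all = M.frame["chrom"].to_numpy()
    for chrom, grp in R.frame.groupby("chrom"):
        idx = np.flatnonzero(chrom_all == chrom)
        if not len(idx):
            continue
        pos = pos_all[idx]
        starts = grp["start_bp"].to_numpy()
        ends = grp["end_bp"].to_numpy()
        vals = grp["cM_per_Mb"].to_numpy()
        # half-open: position p is in interval i iff start_i <= p < end_i
        which = np.searchsorted(starts, pos, side="right") - 1
        ok = (which >= 0) & (pos < ends[np.clip(which, 0, None)])
        rates[idx[ok]] = vals[which[ok]]
    return rates


def incidence_rate_correlation(track: IncidenceTrack, rates: np.ndarray,
                               scope: str = "genome") -> pd.DataFrame:
    """Spearman correlation of per-marker ROH incidence with local
    recombination rate, genome-wide or per chromosome."""
    counts = np.asarray(track.counts, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if counts.shape != rates.shape:
        raise ValueError("incidence and rate vectors differ in length")
    chroms = track.map.frame["chrom"].to_numpy()

    def _one(mask: np.ndarray, label: str) -> dict:
        c, r = counts[mask], rates[mask]
        ok = ~np.isnan(r)
        c, r = c[ok], r[ok]
        if len(c) < 3:
            raise ValueError(f"{label}: fewer than 3 positions with a rate")
        if np.ptp(c) == 0 or np.ptp(r) == 0:
            warnings.warn(f"{label}: constant vector, correlation undefined")
            return {"scope": label, "n": len(c),
                    "spearman_rho": np.nan, "p_value": np.nan}
        rho, p = sps.spearmanr(c, r)
        return {"scope": label, "n": len(c), "spearman_rho": rho, "p_value": p}

    if scope == "genome":
        rows = [_one(np.ones(len(counts), bool), "genome")]
    elif scope == "chromosome":
        rows = [_one(chroms == c, c) for c in track.map.chromosomes]
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return pd.DataFrame(rows)
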