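"""Genotype matrix, marker map, marker filtering and panel statistics.

Genotype codes: 0 = homozygous A1, 1 = heterozygous, 2 = homozygous A2,
-1 = missing.  Which allele is A1 is irrelevant to ROH analysis (both
homozygous states count as homozygous); the distinction is kept only so
that PLINK round-trips are bit-exact.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1
DEFAULT_AUTOSOMES = tuple(str(i) for i in range(1, 30))  # cattle: BTA1..BTA29


def _chrom_sort_key(name: str):
    return (0, int(name)) if name.isdigit() else (1, name)


@dataclass
class MarkerMap:
    """Ordered marker positions: columns chrom, marker_id, pos (1-based bp).

    Markers are sorted by (chromosome, position); positions are strictly
    increasing within a chromosome.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "marker_id", "pos"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"marker map needs columns {sorted(required)}")
        f = self.frame.reset_index(drop=True).copy()
        f["chrom"] = f["chrom"].astype(str)
        f["pos"] = f["pos"].astype(np.int64)
        if f["marker_id"].duplicated().any():
            dup = f.loc[f["marker_id"].duplicated(), "marker_id"].iloc[0]
            raise ValueError(f"duplicate marker id: {dup!r}")
        for chrom, grp in f.groupby("chrom", sort=False):
            d = np.diff(grp["pos"].to_numpy())
            if (d <= 0).any():
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom}")
        object.__setattr__(self, "frame", f)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.frame["chrom"]))

    def positions(self, chrom: str) -> np.ndarray:
        sel = self.frame["chrom"].to_numpy() == chrom
        if not sel.any():
            raise KeyError(f"chromosome {chrom!r} absent from marker map")
        return self.frame.loc[sel, "pos"].to_numpy()

    def indices(self, chrom: str) -> np.ndarray:
        sel = self.frame["chrom"].to_numpy() == chrom
        if not sel.any():
            raise KeyError(f"chromosome {chrom!r} absent from marker map")
        return np.flatnonzero(sel)

    def sorted_copy(self) -> tuple["MarkerMap", np.ndarray]:
        """Return a (chromosome, position)-sorted copy and the column order."""
        order = sorted(range(len(self.frame)),
                       key=lambda i: (_chrom_sort_key(self.frame["chrom"].iat[i]),
                                      self.frame["pos"].iat[i]))
        order = np.asarray(order)
        return MarkerMap(self.frame.iloc[order].reset_index(drop=True)), order


@dataclass
class GenotypeMatrix:
    """Individuals x markers call matrix, column order matching a MarkerMap."""

    individual_ids: list[str]
    calls: np.ndarray  # int8, shape (n_individuals, n_markers)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (individuals x markers)")
        if len(self.individual_ids) != self.calls.shape[0]:
            raise ValueError("individual_ids length mismatch")
        bad = ~np.isin(self.calls, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError(f"invalid genotype codes: {np.unique(self.calls[bad])}")

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def row(self, individual: str) -> np.ndarray:
        return self.calls[self.individual_ids.index(individual)]


@dataclass
class PanelStats:
    """Panel statistics parameterizing ROH detection.

    het: mean SNP heterozygosity, pooled over all non-missing calls.
    per_chromosome: for each chromosome, dS = mean inter-marker distance (bp)
    and mG = mean missing-genotype rate.
    """

    het: float
    per_chromosome: pd.DataFrame = field(repr=False)  # chrom, n_markers, dS, mG

    def dS(self, chrom: str) -> float:
        return float(self.per_chromosome.set_index("chrom").loc[chrom, "dS"])

    def mG(self, chrom: str) -> float:
        return float(self.per_chromosome.set_index("chrom").loc[chrom, "mG"])


_SEX_MT_PAT = re.compile(r"^(X|Y|XY|MT|M|30|31|32|33)$", re.IGNORECASE)


def filter_markers(G: GenotypeMatrix, M: MarkerMap,
                   autosomes: tuple[str, ...] = DEFAULT_AUTOSOMES,
                   ) -> tuple[GenotypeMatrix, MarkerMap]:
    """Drop markers on sex chromosomes, mitochondrial DNA, or unplaced
    scaffolds, keeping only the configured autosome list.

    No minor-allele-frequency filter is applied anywhere in the package:
    MAF pruning removes exactly the low-diversity markers that make up ROH
    and would bias detection downward.
    """
    keep = M.frame["chrom"].isin(set(autosomes)).to_numpy()
    if not keep.any():
        raise ValueError("no autosomal markers after filtering")
    if keep.all():
        return G, M
    newmap = MarkerMap(M.frame.loc[keep].reset_index(drop=True))
    newG = GenotypeMatrix(list(G.individual_ids), G.calls[:, keep])
    return newG, newmap


def compute_panel_stats(G: GenotypeMatrix, M: MarkerMap,
                        het_mode: str = "pooled") -> PanelStats:
    """Compute het (panel-wide), and per-chromosome dS and mG.

    het_mode="pooled" counts heterozygous calls over all non-missing calls
    in the panel; "per_snp" averages per-SNP heterozygosities (the two
    differ only under variable missingness).
    """
    calls = G.calls
    nonmiss = calls != MISSING
    het_calls = calls == 1
    if het_mode == "pooled":
        denom = nonmiss.sum()
        if denom == 0:
            raise ValueError("no non-missing calls in panel")
        het = float(het_calls.sum() / denom)
    elif het_mode == "per_snp":
        per_snp_nm = nonmiss.sum(axis=0)
        ok = per_snp_nm > 0
        het = float(np.mean(het_calls.sum(axis=0)[ok] / per_snp_nm[ok]))
    else:
        raise ValueError(f"unknown het_mode {het_mode!r}")

    rows = []
    for chrom in M.chromosomes:
        idx = M.indices(chrom)
        if len(idx) < 2:
            raise ValueError(
                f"chromosome {chrom} has {len(idx)} marker(s); need at least 2")
        pos = M.frame["pos"].to_numpy()[idx]
        dS = float(np.mean(np.diff(pos)))
        sub = calls[:, idx]
        mG = float((sub == MISSING).sum() / sub.size)
        rows.append({"chrom": chrom, "n_markers": len(idx), "dS": dS, "mG": mG})
    return PanelStats(het=het, per_chromosome=pd.DataFrame(rows))
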