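"""Runs-of-homozygosity detection.

The caller works in length-category rounds.  The minimum SNP count per run,

    L = ceil( ln(alpha / (ns * ni)) / ln(1 - het) ),

bounds the panel-wide expected number of chance homozygous runs by alpha
(ns SNPs per individual, ni individuals, het the mean SNP heterozygosity).
Each length category (lower bounds 1, 2, 4, 8, 16 Mb) is a separate
detection round with its own per-chromosome allowances for heterozygous
and missing calls inside a run:

    nH = round((mL / dS) * eG),    nM = round((mL / dS) * mG),

where mL is the round's minimum length, dS the chromosome's mean
inter-marker distance, eG the genotyping error rate and mG the
chromosome's missing-call rate.  Candidate runs from all rounds are then
unioned per individual and re-classified by merged length; merged runs
shorter than 1 Mb are discarded (they are dominated by shared allozygous
haplotypes rather than autozygosity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, MarkerMap, PanelStats, compute_panel_stats

MB = 1_000_000
CATEGORY_BOUNDS_MB: tuple[float, ...] = (1, 2, 4, 8, 16)
CATEGORY_LABELS: tuple[str, ...] = ("1-2 Mb", "2-4 Mb", "4-8 Mb", "8-16 Mb", ">16 Mb")

ROH_COLUMNS = ["individual", "chrom", "start_bp", "end_bp",
               "n_snps", "length_bp", "category"]


def classify_length(length_bp: int) -> str | None:
    """Length category of a run; None for runs shorter than 1 Mb."""
    mb = length_bp / MB
    if mb < 1:
        return None
    for lo, hi, label in zip(CATEGORY_BOUNDS_MB,
                             CATEGORY_BOUNDS_MB[1:] + (math.inf,),
                             CATEGORY_LABELS):
        if lo <= mb < hi:
            return label
    return CATEGORY_LABELS[-1]


def compute_min_snp_count(alpha: float, ns: int, ni: int, het: float) -> int:
    """Minimum number of SNPs per ROH controlling chance runs at level alpha."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if ns < 1 or ni < 1:
        raise ValueError("ns and ni must be >= 1")
    if not 0 < het < 1:
        raise ValueError("het must be strictly inside (0, 1)")
    L = math.log(alpha / (ns * ni)) / math.log(1.0 - het)
    return max(1, math.ceil(L))


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def compute_allowances(mL: float, dS: float, eG: float, mG: float,
                       rounding: str = "half_up") -> tuple[int, int]:
    """Heterozygous (nH) and missing (nM) calls allowed inside one run."""
    if mL <= 0 or dS <= 0:
        raise ValueError("mL and dS must be positive")
    if not (0 <= eG < 1 and 0 <= mG < 1):
        raise ValueError("eG and mG must be in [0, 1)")
    n_expected = mL / dS
    rounders = {"half_up": _round_half_up, "floor": math.floor, "ceil": math.ceil}
    try:
        rnd = rounders[rounding]
    except KeyError:
        raise ValueError(f"unknown rounding {rounding!r}")
    return int(rnd(n_expected * eG)), int(rnd(n_expected * mG))


@dataclass(frozen=True)
class DetectionParams:
    """Resolved detection parameters: L plus per (chromosome, category-bound)
    heterozygous/missing allowances."""

    alpha: float
    eG: float
    het: float
    ns: int
    ni: int
    L: int
    category_bounds_mb: tuple[float, ...] = CATEGORY_BOUNDS_MB
    allowances: dict = field(default_factory=dict)  # (chrom, mL_mb) -> (nH, nM)

    @classmethod
    def from_panel(cls, stats: PanelStats, ns: int, ni: int,
                   alpha: float = 0.05, eG: float = 0.0025,
                   category_bounds_mb: tuple[float, ...] = CATEGORY_BOUNDS_MB,
                   rounding: str = "half_up") -> "DetectionParams":
        L = compute_min_snp_count(alpha, ns, ni, stats.het)
        allow = {}
        for _, row in stats.per_chromosome.iterrows():
            for mb in category_bounds_mb:
                allow[(row["chrom"], mb)] = compute_allowances(
                    mb * MB, row["dS"], eG, row["mG"], rounding)
        return cls(alpha=alpha, eG=eG, het=stats.het, ns=ns, ni=ni, L=L,
                   category_bounds_mb=tuple(category_bounds_mb), allowances=allow)


def maximal_runs(genotypes: np.ndarray, positions: np.ndarray,
                 L: int, mL: float, nH: int, nM: int) -> list[tuple[int, int]]:
    """All maximal marker intervals [i, j] (inclusive indices) with
    homozygous non-missing endpoints, at most nH het and nM missing calls,
    at least L SNPs, and physical span >= mL base pairs.

    Maximal: no valid interval strictly contains another reported one.
    """
    g = np.asarray(genotypes)
    n = g.size
    if n == 0:
        return []
    hom = (g == 0) | (g == 2)
    if not hom.any():
        return []
    cum_het = np.concatenate(([0], np.cumsum(g == 1)))
    cum_mis = np.concatenate(([0], np.cumsum(g == -1)))
    # last homozygous index at or before each index (-1 if none)
    prev_hom = np.maximum.accumulate(np.where(hom, np.arange(n), -1))

    lefts = np.flatnonzero(hom)
    # furthest right endpoint keeping counts within budget, then trimmed
    # back to a homozygous call
    r_het = np.searchsorted(cum_het, cum_het[lefts] + nH, side="right") - 2
    r_mis = np.searchsorted(cum_mis, cum_mis[lefts] + nM, side="right") - 2
    r0 = np.minimum(r_het, r_mis)
    r0 = np.clip(r0, 0, n - 1)
    r = prev_hom[r0]

    ok = r >= lefts
    lefts, r = lefts[ok], r[ok]
    if lefts.size == 0:
        return []
    # r is non-decreasing in the left endpoint: an interval is maximal
    # exactly when its right end strictly exceeds every earlier one
    keep = np.concatenate(([True], r[1:] > r[:-1]))
    lefts, r = lefts[keep], r[keep]

    out = []
    for i, j in zip(lefts, r):
        if j - i + 1 >= L and positions[j] - positions[i] + 1 >= mL:
            out.append((int(i), int(j)))
    return out


def detect_category(G: GenotypeMatrix, M: MarkerMap, individual: str,
                    chromosome: str, L: int, mL: float, nH: int, nM: int
                    ) -> pd.DataFrame:
    """Candidate runs for one individual on one chromosome in one
    length-category round; columns individual, chrom, start_bp, end_bp."""
    idx = M.indices(chromosome)
    pos = M.frame["pos"].to_numpy()[idx]
    row = G.row(individual)[idx]
    runs = maximal_runs(row, pos, L, mL, nH, nM)
    return pd.DataFrame([{"individual": individual, "chrom": chromosome,
                          "start_bp": int(pos[i]), "end_bp": int(pos[j])}
                         for i, j in runs],
                        columns=["individual", "chrom", "start_bp", "end_bp"])


@dataclass
class ROHSet:
    """Merged, classified ROH calls; one row per segment."""

    frame: pd.DataFrame  # ROH_COLUMNS
    params: DetectionParams | None = None

    def __post_init__(self) -> None:
        missing = [c for c in ROH_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"ROHSet frame missing columns {missing}")
        self.frame = self.frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def for_individual(self, individual: str) -> pd.DataFrame:
        return self.frame[self.frame["individual"] == individual]

    def filter_min_length(self, min_length_mb: float | None) -> "ROHSet":
        if min_length_mb is None:
            return self
        keep = self.frame["length_bp"] >= min_length_mb * MB
        return ROHSet(self.frame[keep].reset_index(drop=True), self.params)

    def validate_disjoint(self) -> None:
        """Raise if any two segments of one individual on one chromosome
        overlap (ROH sets must be merged before use)."""
        for (ind, chrom), grp in self.frame.groupby(["individual", "chrom"]):
            g = grp.sort_values("start_bp")
            if (g["start_bp"].to_numpy()[1:] <= g["end_bp"].to_numpy()[:-1]).any():
                raise ValueError(
                    f"overlapping segments for individual {ind} on chrom {chrom};"
                    " merge first")

    def to_tsv(self, path: str) -> None:
        out = self.frame.copy()
        out["length_mb"] = out["length_bp"] / MB
        out[["individual", "chrom", "start_bp", "end_bp",
             "n_snps", "length_mb", "category"]].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str) -> "ROHSet":
        f = pd.read_csv(path, sep="\t", dtype={"chrom": str, "individual": str})
        f["length_bp"] = f["end_bp"] - f["start_bp"] + 1
        if "category" not in f.columns:
            f["category"] = [classify_length(l) for l in f["length_bp"]]
        return cls(f[ROH_COLUMNS] if "n_snps" in f.columns
                   else f.assign(n_snps=0)[ROH_COLUMNS])


def _union_intervals(starts: np.ndarray, ends: np.ndarray
                     ) -> list[tuple[int, int]]:
    """Union of 1-based inclusive intervals; abutting (zero-gap) intervals
    merge, intervals separated by >= 1 bp stay distinct."""
    order = np.argsort(starts, kind="stable")
    merged: list[list[int]] = []
    for s, e in zip(starts[order], ends[order]):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([int(s), int(e)])
    return [(s, e) for s, e in merged]


def merge_and_classify(candidates: pd.DataFrame, M: MarkerMap,
                       params: DetectionParams | None = None) -> ROHSet:
    """Union candidate runs from all category rounds per individual and
    chromosome, recount SNPs, classify by merged length, drop < 1 Mb."""
    rows = []
    if len(candidates):
        pos_all = M.frame["pos"].to_numpy()
        chrom_all = M.frame["chrom"].to_numpy()
        for (ind, chrom), grp in candidates.groupby(["individual", "chrom"],
                                                    sort=True):
            pos = pos_all[chrom_all == chrom]
            for s, e in _union_intervals(grp["start_bp"].to_numpy(),
                                         grp["end_bp"].to_numpy()):
                length = e - s + 1
                cat = classify_length(length)
                if cat is None:
                    continue
                n_snps = int(np.searchsorted(pos, e, "right")
                             - np.searchsorted(pos, s, "left"))
                rows.append({"individual": ind, "chrom": chrom,
                             "start_bp": s, "end_bp": e, "n_snps": n_snps,
                             "length_bp": length, "category": cat})
    return ROHSet(pd.DataFrame(rows, columns=ROH_COLUMNS), params)


def detect_roh(G: GenotypeMatrix, M: MarkerMap,
               alpha: float = 0.05, eG: float = 0.0025,
               params: DetectionParams | None = None,
               stats: PanelStats | None = None) -> ROHSet:
    """Full multi-round ROH detection for every individual.

    One detection round per length category; per-round minimum length is
    the category's lower bound; candidates are merged and re-classified.
    """
    if stats is None:
        stats = compute_panel_stats(G, M)
    if params is None:
        params = DetectionParams.from_panel(stats, ns=G.n_markers,
                                            ni=G.n_individuals,
                                            alpha=alpha, eG=eG)
    pos_all = M.frame["pos"].to_numpy()
    parts = []
    for chrom in M.chromosomes:
        idx = M.indices(chrom)
        pos = pos_all[idx]
        sub = G.calls[:, idx]
        for i, ind in enumerate(G.individual_ids):
            row = sub[i]
            for mb in params.category_bounds_mb:
                nH, nM = params.allowances[(chrom, mb)]
                for a, b in maximal_runs(row, pos, params.L, mb * MB, nH, nM):
                    parts.append((ind, chrom, int(pos[a]), int(pos[b])))
    candidates = pd.DataFrame(parts,
                              columns=["individual", "chrom", "start_bp", "end_bp"])
    return merge_and_classify(candidates, M, params)


@dataclass
class IncidenceTrack:
    """Per-marker count of individuals whose ROH cover the position."""

    map: MarkerMap
    counts: np.ndarray  # int, len == n_markers
    n_individuals: int
    min_length_mb: float | None = None

    def frame(self) -> pd.DataFrame:
        f = self.map.frame[["chrom", "pos"]].copy()
        f["count"] = self.counts
        return f


def build_incidence(roh: ROHSet, M: MarkerMap, n_individuals: int | None = None,
                    min_length_mb: float | None = None) -> IncidenceTrack:
    """Count, at every marker, the individuals with a covering ROH
    (optionally restricted to segments longer than `min_length_mb`)."""
    roh = roh.filter_min_length(min_length_mb)
    roh.validate_disjoint()
    counts = np.zeros(len(M), dtype=np.int64)
    pos_all = M.frame["pos"].to_numpy()
    chrom_all = M.frame["chrom"].to_numpy()
    for chrom, grp in roh.frame.groupby("chrom"):
        idx = np.flatnonzero(chrom_all == chrom)
        pos = pos_all[idx]
        lo = np.searchsorted(pos, grp["start_bp"].to_numpy(), "left")
        hi = np.searchsorted(pos, grp["end_bp"].to_numpy(), "right")
        delta = np.zeros(len(pos) + 1, dtype=np.int64)
        np.add.at(delta, lo, 1)
        np.add.at(delta, hi, -1)
        counts[idx] = np.cumsum(delta[:-1])
    if n_individuals is None:
        n_individuals = roh.frame["individual"].nunique()
    return IncidenceTrack(M, counts, n_individuals, min_length_mb)


def null_false_positive_rate(ns: int, ni: int, het: float, alpha: float,
                             n_replicates: int, seed: int | None = None
                             ) -> tuple[int, float]:
    """Empirical false-positive ROH rate under the panmictic null.

    Simulates `n_replicates` panels of ni individuals x ns independent
    SNPs with per-SNP heterozygosity het (no LD, no missingness), applies
    the minimum-SNP-count rule L = compute_min_snp_count(alpha, ns, ni,
    het), and reports (L, fraction of replicates in which any individual
    carries >= L consecutive homozygous calls).  The L formula bounds the
    expected panel-wide count of chance runs by alpha, so this fraction
    should not exceed alpha.
    """
    L = compute_min_snp_count(alpha, ns, ni, het)
    rng = np.random.default_rng(seed)
    pos = np.arange(1, ns + 1, dtype=np.int64)
    hits = 0
    for _ in range(n_replicates):
        u = rng.random((ni, ns))
        calls = np.where(u < het, 1,
                         np.where(u < het + (1 - het) / 2, 0, 2)).astype(np.int8)
        if any(maximal_runs(calls[i], pos, L, 1, 0, 0) for i in range(ni)):
            hits += 1
    return L, hits / n_replicates
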