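"""Permutation test for ROH hotspots.

Null hypothesis: ROH show no positional preference.  Each detected
segment is independently relocated to a uniform random start on its own
chromosome (length, individual and chromosome load preserved), the
per-marker incidence is recomputed, and the empirical p-value at each
marker is the add-one-corrected exceedance frequency

    p = (1 + #{randomizations with count >= observed}) / (N + 1),

upper tail by default (hotspots).  Significant markers closer than 1 Mb
chain into enriched intervals, exported as UCSC BED (0-based half-open).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detection import MB, ROHSet, build_incidence, IncidenceTrack
from .genome import Genome
from .genotypes import MarkerMap


def permute_segments(roh: ROHSet, genome: Genome,
                     rng: np.random.Generator) -> ROHSet:
    """Relocate every segment to a uniform random start on its own
    chromosome such that it fits entirely; lengths preserved."""
    f = roh.frame.copy()
    lengths = f["length_bp"].to_numpy()
    chrom_len = np.array([genome.length(c) for c in f["chrom"]])
    if (lengths > chrom_len).any():
        bad = f.loc[lengths > chrom_len].iloc[0]
        raise ValueError(f"segment longer than chromosome {bad['chrom']}")
    max_start = chrom_len - lengths + 1
    starts = rng.integers(1, max_start, endpoint=True)
    f["start_bp"] = starts
    f["end_bp"] = starts + lengths - 1
    return ROHSet(f, roh.params)


@dataclass
class PermutationResult:
    """Observed counts, exceedance counts and empirical p per marker."""

    frame: pd.DataFrame  # chrom, pos, observed, exceedance, p
    n_randomizations: int
    seed: int | None
    estimator: str = "add_one"

    def significant(self, threshold: float = 0.05) -> pd.DataFrame:
        return self.frame[self.frame["p"] <= threshold]


def empirical_pvalues(roh: ROHSet, M: MarkerMap, genome: Genome,
                      n_randomizations: int, seed: int | None = None,
                      tail: str = "upper", estimator: str = "add_one",
                      chunk_size: int = 2000) -> PermutationResult:
    """Permutation p-values for ROH enrichment at every marker.

    Randomized incidence counts individuals, like the observed track: if
    an individual's relocated segments overlap a marker twice it still
    counts once.  estimator="raw" gives the uncorrected exceedance
    frequency (can be 0); the default add-one correction cannot.
    """
    if n_randomizations < 1:
        raise ValueError("n_randomizations must be >= 1")
    roh.validate_disjoint()
    observed = build_incidence(roh, M).counts
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(M), dtype=np.int64)

    pos_all = M.frame["pos"].to_numpy()
    chrom_arr = M.frame["chrom"].to_numpy()
    by_chrom = {c: np.flatnonzero(chrom_arr == c) for c in M.chromosomes}

    done = 0
    while done < n_randomizations:
        nb = min(chunk_size, n_randomizations - done)
        for chrom, idx in by_chrom.items():
            pos = pos_all[idx]
            m = len(pos)
            seg = roh.frame[roh.frame["chrom"] == chrom]
            if not len(seg):
                # no segments can ever land here; exceedance only where
                # observed == 0 (counts tie at 0)
                exceed[idx] += nb * (observed[idx] == 0)
                continue
            clen = genome.length(chrom)
            # single-segment individuals accumulate as a difference array;
            # multi-segment individuals get per-individual 0/1 coverage so
            # overlapping relocated segments of one individual count once
            delta = np.zeros((nb, m + 1), dtype=np.int32)
            resolved = np.zeros((nb, m), dtype=np.int32)
            rows = np.arange(nb)
            for _, ind_seg in seg.groupby("individual"):
                lengths = ind_seg["length_bp"].to_numpy()
                if len(lengths) == 1:
                    starts = rng.integers(1, clen - lengths[0] + 1,
                                          size=nb, endpoint=True)
                    lo = np.searchsorted(pos, starts)
                    hi = np.searchsorted(pos, starts + lengths[0] - 1, "right")
                    np.add.at(delta, (rows, lo), 1)
                    np.add.at(delta, (rows, hi), -1)
                else:
                    own = np.zeros((nb, m + 1), dtype=np.int32)
                    for length in lengths:
                        starts = rng.integers(1, clen - length + 1,
                                              size=nb, endpoint=True)
                        lo = np.searchsorted(pos, starts)
                        hi = np.searchsorted(pos, starts + length - 1, "right")
                        np.add.at(own, (rows, lo), 1)
                        np.add.at(own, (rows, hi), -1)
                    resolved += np.cumsum(own[:, :-1], axis=1) > 0
            rand_counts = np.cumsum(delta[:, :-1], axis=1) + resolved
            if tail == "upper":
                exceed[idx] += (rand_counts >= observed[idx]).sum(axis=0)
            elif tail == "lower":
                exceed[idx] += (rand_counts <= observed[idx]).sum(axis=0)
            else:
                raise ValueError(f"unknown tail {tail!r}")
        done += nb

    N = n_randomizations
    if estimator == "add_one":
        p = (exceed + 1) / (N + 1)
    elif estimator == "raw":
        p = exceed / N
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    frame = pd.DataFrame({"chrom": chrom_arr, "pos": pos_all,
                          "observed": observed, "exceedance": exceed, "p": p})
    return PermutationResult(frame, N, seed, estimator)


@dataclass
class EnrichedInterval:
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    min_p: float


def call_enriched_intervals(result: PermutationResult,
                            threshold: float = 0.05,
                            max_gap_bp: int = MB) -> list[EnrichedInterval]:
    """Chain significant markers (p <= threshold) separated by at most
    `max_gap_bp` into maximal enriched intervals per chromosome."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    sig = result.frame[result.frame["p"] <= threshold]
    out: list[EnrichedInterval] = []
    for chrom, grp in sig.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        pvals = grp["p"].to_numpy()
        order = np.argsort(pos)
        pos, pvals = pos[order], pvals[order]
        breaks = np.flatnonzero(np.diff(pos) > max_gap_bp)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [len(pos) - 1]))
        for a, b in zip(starts, ends):
            out.append(EnrichedInterval(str(chrom), int(pos[a]), int(pos[b]),
                                        int(b - a + 1), float(pvals[a:b + 1].min())))
    return out


def write_bed(intervals: list[EnrichedInterval], path: str) -> None:
    """UCSC BED4+1: 0-based half-open, name = interval id,
    score = -log10(min p) scaled x100 (capped at 1000)."""
    with open(path, "w") as fh:
        fh.write("# ROH-enrichment intervals (BED: 0-based half-open)\n")
        for k, iv in enumerate(intervals, 1):
            score = min(1000, int(round(-100 * np.log10(iv.min_p))))
            fh.write(f"{iv.chrom}\t{iv.start_bp - 1}\t{iv.end_bp}\t"
                     f"roh_island_{k}\t{score}\n")


def read_bed(path: str) -> list[EnrichedInterval]:
    """Re-import intervals written by `write_bed` (1-based inclusive again);
    min_p is recovered from the score column."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, start, end, _name, score = line.split("\t")
            out.append(EnrichedInterval(chrom, int(start) + 1, int(end), 0,
                                        10 ** (-int(score) / 100)))
    return out
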