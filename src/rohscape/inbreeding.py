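"""Genomic and molecular inbreeding estimators and their comparison.

F_ROH is the fraction of the (autosomal) genome covered by ROH:
F_ROH = sum of ROH lengths / genome length, per individual, optionally
restricted to one chromosome or one length category.  F_MIC is the
microsatellite-based estimate via molecular self-coancestry
(f_ii = (1 + H_i)/2, so F = 2 f_ii - 1 = H_i, the observed fraction of
homozygous loci).  Estimators are compared by Spearman rank correlation;
a Kolmogorov-Smirnov normality diagnostic is attached because rank
correlation is the appropriate choice for non-normal F distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .detection import CATEGORY_LABELS, ROHSet
from .genome import Genome
from .pedigree import PedigreeTable, ecg, f_ped, f_ped_truncated


def f_roh(roh: ROHSet, genome: Genome, scope: str = "genome",
          min_length_mb: float | None = None,
          individuals: list[str] | None = None) -> pd.Series | pd.DataFrame:
    """F_ROH per individual.

    scope="genome" returns a Series (denominator = total autosome length);
    scope="chromosome" returns a DataFrame individuals x chromosomes, each
    column using that chromosome's length as denominator.
    """
    roh = roh.filter_min_length(min_length_mb)
    roh.validate_disjoint()
    if individuals is None:
        individuals = sorted(roh.frame["individual"].unique())
    if scope == "genome":
        total = genome.total_length_bp
        s = (roh.frame.groupby("individual")["length_bp"].sum()
             .reindex(individuals, fill_value=0) / total)
        return s.rename("F_ROH")
    if scope == "chromosome":
        out = pd.DataFrame(0.0, index=individuals, columns=genome.names)
        grp = roh.frame.groupby(["individual", "chrom"])["length_bp"].sum()
        for (ind, chrom), length in grp.items():
            if ind in out.index and chrom in out.columns:
                out.loc[ind, chrom] = length / genome.length(chrom)
        return out
    raise ValueError(f"unknown scope {scope!r}")


def f_roh_by_category(roh: ROHSet, genome: Genome,
                      individuals: list[str] | None = None) -> pd.DataFrame:
    """Per-individual F_ROH split by length category; columns are the five
    categories plus F_ROH_total (their exact sum, by partition)."""
    roh.validate_disjoint()
    if individuals is None:
        individuals = sorted(roh.frame["individual"].unique())
    total = genome.total_length_bp
    out = pd.DataFrame(0.0, index=individuals, columns=list(CATEGORY_LABELS))
    grp = roh.frame.groupby(["individual", "category"])["length_bp"].sum()
    for (ind, cat), length in grp.items():
        if ind in out.index:
            out.loc[ind, cat] = length / total
    out["F_ROH_total"] = out[list(CATEGORY_LABELS)].sum(axis=1)
    return out


@dataclass
class STRGenotypes:
    """Multi-allelic STR genotypes: individuals x loci, two integer alleles
    per locus; (-1, -1) = missing."""

    individual_ids: list[str]
    alleles: np.ndarray  # int, shape (n_individuals, n_loci, 2)

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles)
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise ValueError("alleles must have shape (n_ind, n_loci, 2)")
        half_missing = (self.alleles < 0).sum(axis=2) == 1
        if half_missing.any():
            raise ValueError("a locus must have both alleles present or both missing")

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]

    def to_tsv(self, path: str) -> None:
        cols = {}
        for k in range(self.n_loci):
            cols[f"locus{k + 1}_a"] = self.alleles[:, k, 0]
            cols[f"locus{k + 1}_b"] = self.alleles[:, k, 1]
        pd.DataFrame({"id": self.individual_ids, **cols}).to_csv(
            path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str) -> "STRGenotypes":
        f = pd.read_csv(path, sep="\t", dtype={"id": str})
        n_loci = (len(f.columns) - 1) // 2
        alleles = np.stack(
            [np.stack([f[f"locus{k + 1}_a"], f[f"locus{k + 1}_b"]], axis=1)
             for k in range(n_loci)], axis=1)
        return cls(list(f["id"]), alleles)


def f_mic(S: STRGenotypes, corrected: bool = False) -> pd.Series:
    """Molecular inbreeding from STR genotypes.

    Default (self-coancestry route): F_i = fraction of non-missing loci
    homozygous.  corrected=True rescales against the expected
    heterozygosity of the sample's allele frequencies,
    F_i = 1 - h_obs,i / h_exp (can be negative for outbred individuals).
    """
    nonmiss = S.alleles[:, :, 0] >= 0
    hom = (S.alleles[:, :, 0] == S.alleles[:, :, 1]) & nonmiss
    n_nm = nonmiss.sum(axis=1)
    with np.errstate(invalid="ignore"):
        H = np.where(n_nm > 0, hom.sum(axis=1) / np.maximum(n_nm, 1), np.nan)
    if not corrected:
        return pd.Series(H, index=S.individual_ids, name="F_MIC")
    h_exp = np.empty(S.n_loci)
    for k in range(S.n_loci):
        obs = S.alleles[:, k, :][nonmiss[:, k]]
        if obs.size == 0:
            h_exp[k] = np.nan
            continue
        freqs = np.bincount(obs.ravel()) / obs.size
        h_exp[k] = 1.0 - np.sum(freqs ** 2)
    mean_h_exp = np.nanmean(h_exp)
    return pd.Series(1.0 - (1.0 - H) / mean_h_exp,
                     index=S.individual_ids, name="F_MIC")


def compile_inbreeding(roh: ROHSet, genome: Genome,
                       pedigree: PedigreeTable | None = None,
                       strs: STRGenotypes | None = None,
                       truncation_generations: int = 3,
                       individuals: list[str] | None = None) -> pd.DataFrame:
    """Per-individual table of every available inbreeding estimate:
    F_ROH (total and by category), F_PED, F_PED3, ECG, F_MIC."""
    if individuals is None:
        individuals = sorted(roh.frame["individual"].unique())
    table = f_roh_by_category(roh, genome, individuals)
    if pedigree is not None:
        table = table.join(f_ped(pedigree))
        table = table.join(f_ped_truncated(pedigree, truncation_generations)
                           .rename(f"F_PED{truncation_generations}"))
        table = table.join(ecg(pedigree))
    if strs is not None:
        table = table.join(f_mic(strs))
    table.index.name = "individual"
    return table


def estimator_correlations(table: pd.DataFrame,
                           pairs: list[tuple[str, str]]) -> pd.DataFrame:
    """Spearman correlation for each requested pair of estimator columns,
    with a Kolmogorov-Smirnov normality diagnostic per variable."""
    rows = []
    for a, b in pairs:
        sub = table[[a, b]].dropna()
        if len(sub) < 3:
            raise ValueError(f"pair ({a}, {b}): need >= 3 complete pairs")
        x, y = sub[a].to_numpy(), sub[b].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn(f"pair ({a}, {b}): constant vector, "
                          "correlation undefined")
            rho, p = np.nan, np.nan
        else:
            rho, p = sps.spearmanr(x, y)
        rows.append({"x": a, "y": b, "n": len(sub),
                     "spearman_rho": rho, "p_value": p})
    out = pd.DataFrame(rows)
    # normality diagnostic (motivates rank correlation; not a gate)
    ks = {}
    for col in {c for pair in pairs for c in pair}:
        v = table[col].dropna().to_numpy()
        if len(v) >= 3 and np.std(v) > 0:
            z = (v - v.mean()) / v.std(ddof=1)
            ks[col] = sps.kstest(z, "norm").pvalue
        else:
            ks[col] = np.nan
    out.attrs["ks_normality_p"] = ks
    return out
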