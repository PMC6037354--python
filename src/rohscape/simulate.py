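"""Pedigree gene-dropping simulator with known autozygosity truth.

Founder haplotypes are labelled uniquely (two per founder) and dropped
through the pedigree: each meiosis draws a Poisson number of crossovers
per chromosome with mean equal to the genetic length in Morgans (Haldane
model, no interference), crossover positions uniform in genetic distance
(uniform cM/Mb by default, hence uniform in bp), and a fair coin picks
the starting strand.  An individual's true autozygous tracts are the
maximal intervals where its two haplotypes carry the same founder
haplotype label; their total length over the genome length is the true
autozygous fraction, whose expectation over offspring equals the
pedigree inbreeding coefficient -- the central recovery oracle.

SNP genotypes are read off the ancestry tracts: each founder haplotype
draws one allele per SNP from the allele-frequency law (complete linkage
within a founder tract, no mutation), so true IBD differs from observed
homozygosity only by identity-by-state noise, genotyping error (a call
flips to each of the other two states with probability eG/2) and missing
calls (probability mG).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import Genome
from .genotypes import GenotypeMatrix, MarkerMap
from .inbreeding import STRGenotypes
from .pedigree import UNKNOWN, PedigreeTable

# a haplotype is (ends, ids): tract k spans (ends[k-1], ends[k]] in bp
Haplotype = tuple[np.ndarray, np.ndarray]


@dataclass
class SimConfig:
    """Simulation parameters.

    cM_per_Mb: uniform genetic map rate (1 cM/Mb, the mammalian average).
    snps_per_chromosome: markers drawn uniformly per chromosome.
    founder_freq_range: allele frequencies uniform on this interval.
    eG / mG: genotyping error and missing-call rates per call.
    n_str_loci / n_str_alleles: ISAG-style STR panel (17 loci).
    """

    genome: Genome = field(default_factory=Genome.cattle_like)
    cM_per_Mb: float = 1.0
    snps_per_chromosome: int = 1000
    founder_freq_range: tuple[float, float] = (0.05, 0.5)
    eG: float = 0.0025
    mG: float = 0.01
    n_str_loci: int = 17
    n_str_alleles: int = 8

    def __post_init__(self) -> None:
        for r in (self.eG, self.mG):
            if not 0 <= r < 1:
                raise ValueError("rates must be in [0, 1)")
        if self.cM_per_Mb < 0:
            raise ValueError("cM_per_Mb must be >= 0")


def build_pedigree(design: str, n_offspring: int = 1, depth: int = 2
                   ) -> tuple[PedigreeTable, list[str], pd.Series | None]:
    """Construct a pedigree with a named inbreeding design.

    Returns (pedigree, focal offspring ids, group labels or None).
    Designs: outbred, half_sib (loop depth configurable: the common
    ancestor sits `depth` generations above the offspring, F =
    (1/2)^(2*depth - 1)), full_sib (F = 1/4), parent_offspring (F = 1/4),
    cousin (F = 1/16), mixed_HI_LI (half of the offspring from half-sib
    loops -> group HI, half outbred -> group LI).
    """
    if n_offspring < 1:
        raise ValueError("n_offspring must be >= 1")
    records: list[tuple[str, str, str]] = []
    focal: list[str] = []
    group: dict[str, str] = {}

    def founder(name: str) -> str:
        records.append((name, "0", "0"))
        return name

    def child(name: str, sire: str, dam: str) -> str:
        records.append((name, sire, dam))
        return name

    def half_sib_unit(tag: str, g: int) -> str:
        # common ancestor A, two lineages of length g down to the parents
        if g < 2:
            raise ValueError("half-sib loop needs depth >= 2")
        a = founder(f"{tag}A")
        line_ends = []
        for side in "LR":
            cur = a
            for step in range(g - 2):
                mate = founder(f"{tag}{side}m{step}")
                cur = child(f"{tag}{side}c{step}", cur, mate)
            line_ends.append(cur)
        dam1 = founder(f"{tag}D1")
        dam2 = founder(f"{tag}D2")
        p1 = child(f"{tag}P1", line_ends[0], dam1)
        p2 = child(f"{tag}P2", line_ends[1], dam2)
        return child(f"{tag}O", p1, p2)

    for k in range(n_offspring):
        tag = f"u{k}_"
        if design == "outbred":
            o = child(f"{tag}O", founder(f"{tag}S"), founder(f"{tag}D"))
        elif design == "half_sib":
            o = half_sib_unit(tag, depth)
        elif design == "full_sib":
            s, d = founder(f"{tag}S"), founder(f"{tag}D")
            a = child(f"{tag}A", s, d)
            b = child(f"{tag}B", s, d)
            o = child(f"{tag}O", a, b)
        elif design == "parent_offspring":
            s, d = founder(f"{tag}S"), founder(f"{tag}D")
            a = child(f"{tag}A", s, d)
            o = child(f"{tag}O", s, a)
        elif design == "cousin":
            gs, gd = founder(f"{tag}GS"), founder(f"{tag}GD")
            sib1 = child(f"{tag}A", gs, gd)
            sib2 = child(f"{tag}B", gs, gd)
            c1 = child(f"{tag}C1", sib1, founder(f"{tag}M1"))
            c2 = child(f"{tag}C2", sib2, founder(f"{tag}M2"))
            o = child(f"{tag}O", c1, c2)
        elif design == "mixed_HI_LI":
            if k < (n_offspring + 1) // 2:
                o = half_sib_unit(tag, depth)
                group[o] = "HI"
            else:
                o = child(f"{tag}O", founder(f"{tag}S"), founder(f"{tag}D"))
                group[o] = "LI"
        else:
            raise ValueError(f"unknown design {design!r}")
        focal.append(o)

    ped = PedigreeTable.from_records(records)
    groups = pd.Series(group, name="group") if group else None
    return ped, focal, groups


class AncestryGenome:
    """Founder-tract ancestry for every individual: two haplotypes per
    chromosome, each a tiling of (end_bp, founder_haplotype_id) tracts."""

    def __init__(self, genome: Genome):
        self.genome = genome
        self.haplotypes: dict[str, list[tuple[Haplotype, Haplotype]]] = {}
        self.n_founder_haplotypes = 0

    def individuals(self) -> list[str]:
        return list(self.haplotypes)


def _recombine(hapA: Haplotype, hapB: Haplotype, chrom_len: int,
               morgans: float, rng: np.random.Generator) -> Haplotype:
    """One meiosis: Haldane crossovers, fair start strand."""
    k = rng.poisson(morgans) if morgans > 0 else 0
    use_a = bool(rng.integers(2))
    if k == 0:
        return hapA if use_a else hapB
    xs = rng.integers(1, chrom_len, size=k)  # crossover after bp x
    # coincident crossovers cancel pairwise (no net strand switch)
    xs, mult = np.unique(xs, return_counts=True)
    xs = xs[mult % 2 == 1]
    if xs.size == 0:
        return hapA if use_a else hapB
    ends_out: list[int] = []
    ids_out: list[int] = []
    bounds = np.concatenate((xs, [chrom_len]))
    prev = 0
    for b in bounds:
        ends, ids = hapA if use_a else hapB
        i0 = int(np.searchsorted(ends, prev + 1))
        i1 = int(np.searchsorted(ends, b))
        for t in range(i0, i1 + 1):
            e = min(int(ends[t]), int(b))
            if e > prev:
                if ids_out and ids_out[-1] == ids[t] and ends_out:
                    ends_out[-1] = e
                else:
                    ends_out.append(e)
                    ids_out.append(int(ids[t]))
                prev = e
        use_a = not use_a
    return np.asarray(ends_out, dtype=np.int64), np.asarray(ids_out, dtype=np.int64)


def gene_drop(P: PedigreeTable, config: SimConfig,
              rng: np.random.Generator) -> AncestryGenome:
    """Drop uniquely labelled founder haplotypes through the pedigree."""
    sire, dam = P.parents_of()
    genome = config.genome
    anc = AncestryGenome(genome)
    labels = P.labels
    hap_count = 0
    store: dict[int, list[tuple[Haplotype, Haplotype]]] = {}
    for i in P.frame["id"]:
        per_chrom = []
        if sire[i] == UNKNOWN and dam[i] == UNKNOWN:
            h1, h2 = hap_count, hap_count + 1
            hap_count += 2
            for chrom in genome:
                e = np.array([chrom.length_bp], dtype=np.int64)
                per_chrom.append(((e, np.array([h1], dtype=np.int64)),
                                  (e.copy(), np.array([h2], dtype=np.int64))))
        elif sire[i] == UNKNOWN or dam[i] == UNKNOWN:
            raise ValueError(
                f"individual {labels[i]} has exactly one known parent; "
                "gene dropping needs both or neither")
        else:
            sh, dh = store[sire[i]], store[dam[i]]
            for c, chrom in enumerate(genome):
                morgans = chrom.length_bp * config.cM_per_Mb / 1e8
                pat = _recombine(sh[c][0], sh[c][1], chrom.length_bp,
                                 morgans, rng)
                mat = _recombine(dh[c][0], dh[c][1], chrom.length_bp,
                                 morgans, rng)
                per_chrom.append((pat, mat))
        store[i] = per_chrom
        anc.haplotypes[labels[i]] = per_chrom
    anc.n_founder_haplotypes = hap_count
    return anc


@dataclass
class TruthSet:
    """True autozygous tracts and fractions, plus the genome they tile."""

    tracts: pd.DataFrame  # individual, chrom, start_bp, end_bp
    fractions: pd.Series  # individual -> autozygous genome fraction
    genome: Genome

    def to_tsv(self, path: str) -> None:
        self.tracts.to_csv(path, sep="\t", index=False)


def _autozygous_intervals(hap1: Haplotype, hap2: Haplotype
                          ) -> list[tuple[int, int]]:
    """Maximal intervals where the two haplotypes carry the same founder id."""
    e1, i1 = hap1
    e2, i2 = hap2
    out: list[list[int]] = []
    a = b = 0
    prev = 0
    while a < len(e1) and b < len(e2):
        end = min(e1[a], e2[b])
        if i1[a] == i2[b] and end > prev:
            if out and out[-1][1] == prev:
                out[-1][1] = int(end)
            else:
                out.append([prev + 1, int(end)])
        prev = int(end)
        if e1[a] == end:
            a += 1
        if e2[b] == end:
            b += 1
    return [(s, e) for s, e in out]


def true_autozygosity(A: AncestryGenome, genome: Genome | None = None
                      ) -> TruthSet:
    if genome is None:
        genome = A.genome
    rows = []
    fracs = {}
    for ind, per_chrom in A.haplotypes.items():
        total = 0
        for chrom, (h1, h2) in zip(genome, per_chrom):
            for s, e in _autozygous_intervals(h1, h2):
                rows.append({"individual": ind, "chrom": chrom.name,
                             "start_bp": s, "end_bp": e})
                total += e - s + 1
        fracs[ind] = total / genome.total_length_bp
    tracts = pd.DataFrame(rows, columns=["individual", "chrom",
                                         "start_bp", "end_bp"])
    return TruthSet(tracts, pd.Series(fracs, name="true_autozygosity"), genome)


def _sample_positions(length_bp: int, n: int,
                      rng: np.random.Generator) -> np.ndarray:
    """n distinct sorted positions uniform on [1, length_bp]."""
    if n > length_bp:
        raise ValueError("more SNPs requested than base pairs")
    uniq = np.unique(rng.integers(1, length_bp + 1, size=n + max(10, n // 10)))
    while uniq.size < n:
        uniq = np.union1d(uniq, rng.integers(1, length_bp + 1, size=n))
    return np.sort(rng.choice(uniq, size=n, replace=False))


def derive_genotypes(A: AncestryGenome, config: SimConfig,
                     rng: np.random.Generator,
                     individuals: list[str] | None = None
                     ) -> tuple[GenotypeMatrix, MarkerMap, STRGenotypes]:
    """Read SNP and STR genotypes off the ancestry tracts, then apply
    genotyping error and missingness."""
    if individuals is None:
        individuals = A.individuals()
    genome = config.genome
    n_hap = A.n_founder_haplotypes
    lo, hi = config.founder_freq_range

    all_calls = []
    map_rows = []
    for c, chrom in enumerate(genome):
        n_snps = config.snps_per_chromosome
        pos = _sample_positions(chrom.length_bp, n_snps, rng)
        freqs = rng.uniform(lo, hi, size=n_snps)
        founder_alleles = (rng.random((n_hap, n_snps)) < freqs).astype(np.int8)
        calls = np.empty((len(individuals), n_snps), dtype=np.int8)
        for r, ind in enumerate(individuals):
            h1, h2 = A.haplotypes[ind][c]
            a1 = founder_alleles[h1[1][np.searchsorted(h1[0], pos)],
                                 np.arange(n_snps)]
            a2 = founder_alleles[h2[1][np.searchsorted(h2[0], pos)],
                                 np.arange(n_snps)]
            calls[r] = a1 + a2
        all_calls.append(calls)
        for j, p in enumerate(pos):
            map_rows.append((chrom.name, f"snp_{chrom.name}_{j}", int(p)))

    calls = np.concatenate(all_calls, axis=1)
    # genotyping error: flip to each of the two other states w.p. eG/2
    if config.eG > 0:
        err = rng.random(calls.shape) < config.eG
        shift = rng.integers(1, 3, size=calls.shape)
        calls = np.where(err, (calls + shift) % 3, calls).astype(np.int8)
    if config.mG > 0:
        calls[rng.random(calls.shape) < config.mG] = -1

    M = MarkerMap(pd.DataFrame(map_rows, columns=["chrom", "marker_id", "pos"]))
    G = GenotypeMatrix(list(individuals), calls)

    strs = _derive_strs(A, config, rng, individuals)
    return G, M, strs


def _derive_strs(A: AncestryGenome, config: SimConfig,
                 rng: np.random.Generator, individuals: list[str]
                 ) -> STRGenotypes:
    genome = config.genome
    n_loci = config.n_str_loci
    chrom_idx = rng.integers(0, len(genome), size=n_loci)
    chrom_lens = np.array([c.length_bp for c in genome])
    loci_pos = rng.integers(1, chrom_lens[chrom_idx] + 1)
    founder_alleles = rng.integers(1, config.n_str_alleles + 1,
                                   size=(A.n_founder_haplotypes, n_loci))
    alleles = np.empty((len(individuals), n_loci, 2), dtype=np.int64)
    for r, ind in enumerate(individuals):
        for k in range(n_loci):
            c, p = int(chrom_idx[k]), int(loci_pos[k])
            h1, h2 = A.haplotypes[ind][c]
            f1 = h1[1][np.searchsorted(h1[0], p)]
            f2 = h2[1][np.searchsorted(h2[0], p)]
            alleles[r, k, 0] = founder_alleles[f1, k]
            alleles[r, k, 1] = founder_alleles[f2, k]
    if config.mG > 0:
        miss = rng.random((len(individuals), n_loci)) < config.mG
        alleles[miss] = -1
    return STRGenotypes(list(individuals), alleles)


@dataclass
class SimulatedCohort:
    pedigree: PedigreeTable
    focal: list[str]
    groups: pd.Series | None
    genotypes: GenotypeMatrix
    marker_map: MarkerMap
    strs: STRGenotypes
    truth: TruthSet
    config: SimConfig


def simulate_cohort(design: str, n_offspring: int, config: SimConfig,
                    seed: int | None = None, depth: int = 2) -> SimulatedCohort:
    """End-to-end convenience: pedigree -> gene drop -> truth + genotypes
    for the focal offspring only."""
    rng = np.random.default_rng(seed)
    ped, focal, groups = build_pedigree(design, n_offspring, depth)
    anc = gene_drop(ped, config, rng)
    focal_anc = AncestryGenome(config.genome)
    focal_anc.haplotypes = {i: anc.haplotypes[i] for i in focal}
    focal_anc.n_founder_haplotypes = anc.n_founder_haplotypes
    truth = true_autozygosity(focal_anc)
    G, M, strs = derive_genotypes(focal_anc, config, rng)
    return SimulatedCohort(ped, focal, groups, G, M, strs, truth, config)
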