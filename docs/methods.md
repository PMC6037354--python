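# Methods

## Scope and data model

The package analyses autosomal SNP genotypes (codes 0 = hom A1, 1 = het,
2 = hom A2, −1 = missing) with a strictly ordered marker map, 1-based
inclusive base-pair coordinates throughout (PLINK convention); only BED
export converts to 0-based half-open. Sex-chromosome, mitochondrial and
unplaced markers are removed before analysis (configurable autosome list,
default 1–29 as in cattle). No minor-allele-frequency filter exists
anywhere in the pipeline: MAF pruning removes exactly the low-diversity
markers that constitute ROH and would bias detection downward.

The hom-A1/hom-A2 distinction never matters to ROH (both are
homozygous); it is kept only for faithful PLINK round-trips. In PED input
the A1 allele is chosen as the lexicographically smaller observed allele —
a canonical rule that makes write∘read the identity, which a "first
observed allele" rule cannot guarantee. BIM files keep their stated
allele order.

## Detection model

`L = ceil(ln(α/(n_s·n_i)) / ln(1−het))` is the smallest run length whose
expected panel-wide count of chance homozygous runs, under independent
markers with mean heterozygosity `het`, is at most α. `het` is pooled
over all non-missing calls (a per-SNP-averaged mode exists as an option;
the two differ only under variable missingness) and is computed after
marker filtering. α defaults to 0.05 and e_G to 0.0025, the error rate of
standard high-density array chemistry.

Each length category (lower bounds 1, 2, 4, 8, 16 Mb) is its own
detection round with per-chromosome allowances n_H = round((m_L/d_S)·e_G)
and n_M = round((m_L/d_S)·m_G): the count of markers expected inside a
minimum-length run times the corruption rate. The published description
of the missing-call allowance is typographically truncated; n_M is
implemented symmetrically to n_H. Rounding is half-up by default with
floor/ceil options, since integer allowances are conventional but no
rounding rule is standard.

A candidate run is a *maximal* marker interval with homozygous
non-missing endpoints, at most n_H het and n_M missing calls, at least L
SNPs and span ≥ m_L. Maximality is inclusion-maximality: no valid
interval strictly contains a reported one. The scanner exploits that for
a fixed left endpoint the furthest feasible right endpoint is monotone,
giving an O(n log n) pass whose output is proven (in tests) identical to
exhaustive subinterval enumeration. Candidates from all rounds are
unioned per individual × chromosome — abutting (zero-gap) intervals
merge, intervals separated by ≥ 1 bp do not — then re-classified by
merged length; merged runs < 1 Mb are dropped, because sub-megabase
homozygosity is dominated by shared ancient haplotypes rather than
recent autozygosity.

## Inbreeding estimators

* **F_ROH** = Σ segment lengths / genome length, per individual; also per
  chromosome (chromosome-length denominator) and per length category.
  The five categories partition every ROH set, so category-wise F_ROH
  sums exactly to the total. The genome-length denominator comes from a
  configurable chromosome table; simulated data use the simulated
  lengths.
* **F_PED** by the Meuwissen–Luo L·D·L′ traversal of the numerator
  relationship matrix, O(ancestors) per individual; validated against an
  independent O(n²) recursive-kinship oracle. **F_PED3** truncates each
  focal individual's pedigree at 3 parent-steps (ancestors at the cut
  depth become founders; depth is minimum path length when an ancestor
  appears at several depths). **ECG** uses the recursion
  ECG_i = Σ_{known parents} (1 + ECG_parent)/2.
* **F_MIC**: molecular self-coancestry gives f_ii = (1 + H_i)/2, hence
  F = H_i, the observed homozygous fraction over non-missing STR loci
  (17-locus ISAG-style panel by default). An allele-frequency-corrected
  variant, F = 1 − h_obs/h_exp with h_exp from sample allele frequencies,
  is available behind a flag; the uncorrected form is the default
  because it requires no frequency estimates from small samples.
* Estimator agreement uses Spearman rank correlation (F distributions
  are typically non-normal; a Kolmogorov–Smirnov diagnostic is attached
  to every correlation table). The informative pairs are
  F_ROH(≥8 Mb) vs F_PED and F_ROH(≥16 Mb) vs F_PED3, since longer ROH
  reflect more recent common ancestors.

## Enrichment permutation test

Null: ROH have no positional preference. Each segment is independently
relocated to a uniform random start on its own chromosome such that it
fits — preserving segment lengths, per-individual burden and
per-chromosome load. Alternative nulls (whole-genome relocation, count
shuffling, circular rotation) exist in the literature; within-chromosome
relocation is the most conservative standard choice and the one
implemented. Randomized incidence counts individuals, exactly like the
observed track: when one individual's relocated segments overlap a
marker, they count once (a vectorised difference-array path handles the
common single-segment case).

Empirical p = (1 + exceedances)/(N + 1), upper tail; the add-one
correction avoids zero p-values and makes the p-values valid
(super-uniform under the null), at the cost of a floor of 1/(N+1). A raw
(r/N) mode and a lower-tail ("cold spot") mode exist behind flags.
N defaults to 10⁶; tests use 10⁴–10⁵, which bounds attainable
significance but not calibration. Significant markers (p ≤ 0.05 default,
no multiple-testing correction by default) separated by ≤ 1 Mb chain
into enriched intervals; the pipeline ends at BED export of those
intervals.

## Recombination correlation

A recombination map is a per-chromosome set of half-open
[start, end) intervals in cM/Mb; each marker takes its containing
interval's rate (markers in gaps are excluded). Incidence–rate
association uses Spearman correlation at SNP resolution, genome-wide or
per chromosome, for all ROH and for the ≥8 Mb subset; an optional 1 Mb
binned mode trades resolution for speed. Because both tracks are
spatially autocorrelated, the effective sample size is far below the
marker count; correlations should be read as descriptive.

## The simulator: what it does and does not emulate

Gene dropping assigns two uniquely labelled haplotypes per founder and
transmits recombinant haplotypes down the pedigree: crossover counts per
meiosis are Poisson with mean = genetic length in Morgans (Haldane, no
interference — interference is irrelevant to the tract-length
expectations tested and keeps the oracle analytic), positions uniform in
genetic distance (uniform 1 cM/Mb by default), start strand fair.
Coincident crossover pairs cancel. True autozygous tracts are the
maximal intervals where the two haplotype labels agree; the expectation
of the autozygous fraction over offspring equals pedigree F, and mean
tract length shrinks as the inbreeding loop moves deeper (≈100/(2g) cM
for a loop g generations back) — both checked in tests.

Genotypes: SNP positions uniform per chromosome; allele frequencies
uniform on [0.05, 0.5]; each founder haplotype draws one allele per SNP
(complete linkage within a founder tract, no mutation), so true IBD and
observed homozygosity differ only through identity-by-state noise — the
realistic confounder for short ROH. Genotyping error flips a call to
each of the two other states with probability e_G/2 (so a homozygous
call inside a true tract turns heterozygous at rate e_G/2); missingness
is i.i.d. at rate m_G (default 1%). STR loci are placed at random
genomic positions with 8 equifrequent founder alleles.

Pedigree designs: outbred, full-sib (F = 1/4), parent–offspring (1/4),
half-sib loop with configurable depth g (F = (1/2)^(2g−1); g = 2 gives
the classic 1/8), first cousins (1/16), and a mixed design of half-sib
(HI) plus outbred (LI) cohorts emulating a population with divergent
recent inbreeding.

Not emulated: background linkage disequilibrium beyond founder tracts,
mutation, allele-frequency spectra from real ascertainment, selection,
non-uniform recombination maps (supported by configuration but not
defaulted), and genotype-intensity-level artefacts. Passing tests
therefore demonstrate correctness of the algorithms and calibration
under the stated generative model, not robustness to array-specific
artefacts in real data.

## Problem sizes and numerical choices

Validation runs use deliberately scaled designs chosen to give tight
Monte-Carlo error at desk scale: 1,000 offspring for the
autozygosity-recovery check (3-SE window ≈ 0.004), 1,000 replicates of
20 × 10,000 null panels for false-positive calibration, 10⁵
randomizations for permutation calibration on a 10-SNP toy genome, and a
100-individual mixed cohort on a 6 × 100 Mb genome at 10 kb marker
spacing for the end-to-end group contrast (the spacing is what lets
1–2 Mb runs contain the ~40–50 SNP minimum).

Ties and degenerate inputs: constant vectors make rank correlations
undefined (NaN with a warning); zero-variance t-tests return p = 1 for
equal means and a flagged degenerate p = 0 otherwise; individuals with
F_ROH = 0 are excluded (with a warning) from the category-percentage
decomposition; a chromosome needs ≥ 2 markers for panel statistics.
All stochastic code takes a NumPy Generator or integer seed and is
bit-reproducible given it.
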