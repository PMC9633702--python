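# Methods

This note documents the models, parameter choices and numerical
conventions behind `larvkin`, and what the synthetic-data tests do and
do not demonstrate about real data.

## Kinship model and the PLOD statistic

A pair's joint genotype probability at a biallelic locus with
alternate-allele frequency `p` is the Cotterman IBD mixture

    P(g_i, g_j) = κ0·P(g_i)P(g_j) + κ1·P(g_i)T(g_j|g_i) + κ2·P(g_i)·1[g_i=g_j]

with Hardy–Weinberg marginals `P(·)` and the one-shared-allele
transition `T(g_j|g_i)`: the shared (IBD) allele is a uniform draw from
`g_i`'s two alleles and the other allele is a population draw at
frequency `p`. Canonical coefficients: UP (1,0,0), HSP (½,½,0),
FSP (¼,½,¼), POP (0,1,0), and DUP (0,0,1) for the same individual
genotyped twice. Genotyping error is a symmetric per-allele miscall
channel with rate ε applied independently to each sample's two alleles;
the 3×3 channel matrix is convolved into both margins of the joint
table. The tables are symmetrized bitwise after construction so that
PLOD(i,j) equals PLOD(j,i) exactly, not just to rounding.

The PLOD is the sum over co-observed loci of the log-ratio of the HSP
to the UP table entry; loci with a missing call in either sample
contribute nothing. Class-conditional means and variances are computed
by exact 3×3 enumeration per locus (no sampling), summed over the locus
set. All logs are natural.

**Classification.** Because 15–40% missingness makes raw PLOD sums
incomparable across pairs, cutoffs are expressed per locus and scaled
to each pair's co-observed count. The default places cutoffs midway
between adjacent class means (UP/HSP, HSP/FSP, and FSP/DUP for
duplicate flagging). An alternative `fpr` mode places the UP/HSP cutoff
at `mean_UP + z·sd_UP`, with `z` chosen so the Gaussian-tail expectation
of false HSPs over all pairs stays below 0.1; it exists because the
huge number of UP pairs, not the kin pairs, controls the false-positive
budget. Second-order kin other than half-siblings (grandparent–
grandchild, thiatic pairs) are not modelled as separate classes: in a
larvae-only sample collected over a couple of years they are
demographically negligible, and any present would classify as HSP.

ε defaults to 0.01 per allele — consistent with the high (but imperfect)
technical-replicate reproducibility typical of reduced-representation
genotyping — and is configurable everywhere it enters.

## Genotype quality control

Pipeline order is fixed: locus filters → secondary-SNP thinning →
allele-frequency estimation → duplicate removal → sample-outlier
removal. Boundary semantics are strict-inequality removal exactly as
stated by the filter: MAF < 0.05 and mean depth < 25 are removed, so a
locus at exactly the threshold is retained; polyploid-flagged loci are
removed outright. One SNP per sequenced fragment is retained (seeded
random draw by default; a best-call-rate mode exists).

Allele frequencies are estimated after temporarily excluding samples
whose mean observed heterozygosity lies outside the inclusive [Q1, Q3]
sample interval — the high side flags cross-contamination, the low side
degradation — and every sample is re-incorporated afterwards.
Frequencies are alternate-allele counts over twice the non-missing
sample count per locus; loci with no usable call get NaN and are
excluded downstream, as are loci whose *estimated* MAF falls back below
the floor.

Duplicate detection calls pairs whose genotype concordance over
co-observed loci is ≥ 0.95 (default): far above the unrelated-pair
expectation `Σ_g P(g)²` at any realistic allele-frequency spectrum, and
below the worst plausible replicate discordance. Pairs sharing fewer
than 100 loci are not called. The member with more missing data is the
one removed. Missing calls never count as concordant or discordant.

Sample outliers are scored by two statistics — mean per-locus genotype
log-probability under HWE, and observed/expected heterozygosity ratio —
with robust z-scores (median ± 3.5 × scaled MAD) as the default policy.
The likelihood rule fires on the low side only (improbable genotypes,
e.g. another species); the heterozygosity rule fires high
(contamination) and low (degradation). The thresholds are policy, not
estimates: the source study reports only the resulting removal counts,
which are data-dependent, so the z-cutoffs are exposed as configuration.

## Distinct parent groups

Each larva has one mother and one father — two "parent slots". FSP
edges force both slot pairs to coincide, HSP edges exactly one, UP
(non-edges within a component) none, and a larva's two slots must stay
distinct. An additional structural constraint matters: the graph whose
vertices are parent labels and whose edges are larvae must be
two-colorable, because labels must admit a consistent sexing. This is
what makes an HSP triangle resolve to one shared parent plus three
singletons (4 parents) rather than three pairwise-shared parents (3
parents, but it would require a same-sex mating).

Among feasible assignments the package returns one minimizing the
number of distinct parents. Parsimony is the right tie-break because
with ~10⁵ adults the prior odds of two independent co-parentage
coincidences are negligible next to a single shared parent; the
truth-recovery tests (below) confirm that on simulated data with
perfect pairwise classification the parsimonious tabulation equals the
true one. The search is exact branch-and-bound over larvae in
deterministic BFS order for components of ≤ 12 larvae (observed
components are far smaller) and greedy cheapest-merge-first above, with
a candidate set restricted to the groups of already-placed neighbours —
any other group is excluded by the UP constraint, which keeps the exact
search fast. Infeasible components (possible only through upstream
misclassification) raise a conflict listing the component's edges;
dropping the weakest edge (smallest |PLOD| margin) until feasibility is
available but only on explicit request, because conflicts should
surface, not be hidden. Cross-cohort FSP calls are reported as
anomalies rather than merged: cross-year full siblings would imply the
same pair re-mating a year apart.

## Effective sample sizes

With group-size counts `g_s`: `VIF = Σs²g_s / Σs g_s` is the ratio of
the actual to the independent-juvenile variance of the cartoon POP
count, and `m_Jeff = m_J / VIF`. Both follow from writing the POP count
as `K = Σ_p s_p · 1[parent p sampled]` over distinct parents p: each
sampled parent contributes its whole group at once, so the Bernoulli
variance is weighted by `s_p²` instead of `s_p`.

For the XHSP-only model the implemented closed form is

    m_Jeff(XHSP) = (NDP/2) / VIF²

i.e. the DPG-condensed ceiling NDP/2 discounted by the squared
inflation factor — sibship enters once per cohort side of a
cross-cohort comparison, since a shared parent between groups of sizes
s and s′ shifts the XHSP count by s·s′. It reduces to `m_J` exactly
when sibship is absent. The Monte-Carlo cross-check simulates the
cross-cohort shared-parent count under a pairwise independent-match
model (each cohort's distinct parents occupy distinct uniform adult
identities; the number of shared identities is hypergeometric) and
recovers the VIF² inflation; the sharing model is recorded in the
function's output metadata because a fully specified joint treatment of
correlated mother/father groups (FSPs couple the two) is a genuinely
open modelling choice.

The cartoon abundance estimator is `N̂ = 2·m_A·m_J / K`, the solution of
the unbiased estimating equation `E[K] = 2·m_A·m_J/N` with two parents
per juvenile and uniform adult sampling without replacement. `K = 0` is
reported as undefined rather than as a number: the estimating equation
is unbiased on the 1/N scale, which is also the scale on which the
bias tests operate. Monte-Carlo adult sampling draws the number of
tracked parents in the sample hypergeometrically and a uniform subset,
exactly matching without-replacement sampling.

## Synthetic data generator

The generator reproduces the statistical structure the analysis
assumes, under one master seed with per-stage substreams (pedigree,
tows, genotypes), so identical configuration and seed give bit-identical
output at every stage.

- **Spawning.** Nightly small groups (default 50 groups/night over a
  21-night season, group sizes uniform on 6–40 — free parameters, since
  group composition is not observable in this kind of study). A group
  persists to the next night with probability 0.3, which is what
  produces full-sibling pairs born weeks apart. Group membership is
  sampled proportionally to fecundity (size^1 by default), and each
  larva draws its mother and father uniformly within its group; adult
  sizes are lognormal.
- **Patchiness.** Patch intensities are Gamma(shape = 0.04) — the shape
  was set so that the top decile of tows holds ~90% of sampled larvae,
  the degree of skew the analysis is designed for — and spawning events
  co-locate in rich patches (that is *why* a patch is rich), with
  larvae spread roughly evenly across events. A rich tow therefore
  contains many moderate families, not one huge family, which matches
  the observed maximum group size of ~5 out of hundreds.
- **Surveys.** Grid mode assigns tows to patches drawn uniformly;
  targeted mode puts every tow on the richest patch, sequentially
  depleting it. Per-tow catch probability defaults to 0.01 and a lab
  subsampling cap (default 500 genotyped larvae) mirrors the fact that
  surveys genotype a subsample of the catch; the catch-to-cap ratio
  controls how much of the within-patch sibship survives subsampling.
- **Genotypes.** Founder genotypes are HWE draws at MAFs uniform on
  [0.05, 0.5]; larvae inherit Mendelian alleles; ε and depth-driven
  missingness (per-individual target uniform on [0.15, 0.40], allocated
  to loci inversely to mean depth) are applied on top. 41% of loci
  share a sequenced fragment with another SNP; 2% are polyploid-flagged.
  Injected challenges: near-identical duplicates; contaminated samples
  modelled as pooled reads (a het is called wherever the two source
  individuals jointly carry both alleles, which inflates
  heterozygosity); degraded samples with 80% allelic dropout of hets
  and +0.2 missingness; off-target species drawn from a shifted
  allele-frequency spectrum.

**What the generator does not emulate:** linkage between loci,
oceanographic transport, larval mortality, age structure within a
cohort, read-level depth variation within a locus, and null alleles.
Tests passing on this generator therefore demonstrate the correctness
of the inference pipeline under its stated assumptions, not robustness
to (for example) linked markers or allele-frequency misspecification.

## Problem sizes and numerical conventions

The test suite and the acceptance script run the statistical checks at
sizes chosen to keep the whole suite fast while leaving comfortable
Monte-Carlo margins: classifier confusion at the study's 6,641 retained
loci with 100 FSP + 100 HSP + ~19,700 UP pairs; parsimony against the
exhaustive-minimum oracle on hundreds of random ≤8-larva graphs;
variance ratios at 50,000 replicates (MC standard error ≈ 1%, checked
at 5%); cartoon-estimator bias over 1,500–2,000 full sampling
replicates (SE of the harmonic-scale mean ≈ 0.8%, checked at 2%); and
the survey-mode contrast as a one-sided sign test over 60–100 matched
pedigrees. Reported VIFs are rounded to two decimals and effective
sizes to one, matching the reporting convention of the source tables;
all internal arithmetic is full precision. Empty tows, zero co-observed
loci, loci with undefined frequencies, and K = 0 are all explicit,
tested degenerate cases rather than silent ones.
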