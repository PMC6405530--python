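# Methods

This note records the statistical models implemented in `invadepop`, the
conventions and defaults chosen where the standard definitions leave
room, and what the simulation-backed tests do and do not establish.

## Data model

Genotypes are diploid biallelic calls stored as counts of a designated
alternate allele (0/1/2) with a distinct missing sentinel (never 0,
which is a valid homozygote). When reading STRUCTURE-style two-row
files, the alternate allele at a locus is the lexicographically larger
of the observed symbols — deterministic without an external reference.
A locus showing a single symbol is read as monomorphic reference; such
degenerate loci are the only case where a written file does not
round-trip call-for-call, since the dialect cannot distinguish "all
homozygous reference" from "all homozygous alternate" when only one
symbol appears.

## Clone detection

Within each population, loci with any missing call *in that population*
are discarded and individuals identical at all retained loci form one
clone group (transitive closure of pairwise identity; exact matching,
no mismatch tolerance — genotyping-error-tolerant matching is out of
scope). The first individual in input order represents each group.
Clonal diversity is R = (G−1)/(N−1), undefined for N < 2. The
between-range contingency table counts N−G clone individuals per
population (every duplicate beyond the representative) and G unique
genotypes, omitting populations grown from seed (common garden,
laboratory seedlings), which are expected clone-free and are verified
rather than tested. The test is Pearson's χ² with Yates continuity
correction, df = 1; it is undefined (error) when a margin is zero.

## Diversity statistics

Per locus and population with n non-missing diploids, Ho is the
heterozygote proportion and Hs is Nei's unbiased gene diversity
Hs = n/(n−1) · (1 − Σ p̂² − Ho/(2n)). Population values average over all
loci with n ≥ 2 (monomorphic loci contribute zero — excluding them
would bias F_IS in near-monomorphic panels). F_IS is the multilocus
ratio of averages 1 − mean(Ho)/mean(Hs), stable where per-locus ratios
are not; it is reported as NaN (not an error) when mean Hs = 0.
Confidence intervals are percentile bootstraps over loci (default
1,000 replicates). Percentile rather than BCa intervals are used; the
method is the simplest defensible choice and is recorded in outputs.

F_ST is the Weir & Cockerham (1984) estimator: per-locus variance
components a (among populations), b (among individuals within
populations), c (within individuals), computed from per-population
sample sizes, allele frequencies and heterozygote proportions using
non-missing calls only; loci observable in fewer than two populations,
or with a mean sample size of one, contribute zeros. The multilocus
estimate is the ratio of component sums, bootstrap CIs resample loci.
The estimator can legitimately go slightly negative for undifferentiated
populations.

Allelic richness uses the hypergeometric rarefaction hurdle
AR = Σₐ [1 − C(2n−nₐ, g)/C(2n, g)]. The rarefaction depth g defaults to
twice the smallest per-locus non-missing diploid count across the
compared groups — a single global depth keeps loci comparable; loci
that cannot supply g copies in a group are NaN and are dropped pairwise
from the Wilcoxon signed-rank comparison (exact null for ≤ 25
informative pairs, normal approximation with continuity correction
beyond). TNA counts distinct observed alleles summed over loci; its
bootstrap jointly resamples individuals (within group) and loci, and
the two ranges' bootstrap distributions are compared by Mann–Whitney U.
Comparing bootstrap replicates overstates significance — this mirrors
the analysis pipeline the package reproduces and is flagged here as a
known caveat rather than silently corrected.

MAF histograms use half-open bins [k·w, (k+1)·w) of width 0.05; a value
exactly on an edge belongs to the upper bin (guarded against float
truncation).

## Admixture model

The sampler implements the classic admixture model: each of the two
gene copies at each locus of individual i originates from cluster k
with probability q_ik; cluster k carries allele frequency p_kl. Priors:
Beta(1,1) on frequencies (no correlated-frequencies F-model),
symmetric Dirichlet(α) on ancestries, α uniform on (0, 10]. Updates are
collapsed-count Gibbs steps (multinomial origin counts via a
conditional-binomial chain, so the whole sweep vectorises), conjugate
Beta and Dirichlet draws, and a random-walk Metropolis step (sd 0.05)
for α. Missing calls contribute no gene copies. Model evidence is
estimated as mean(ln L) − var(ln L)/2 over retained samples — the
harmonic-style estimator that ΔK is defined on. ΔK(K) =
|L(K+1) − 2L(K) + L(K−1)| / sd(L(K)) with L averaged over ≥ 2
replicates of ≥ 3 consecutive K; it is NaN at boundary K and where the
replicate sd is zero.

Label switching across replicates is resolved by permuting each run's
cluster columns to minimise the total L1 distance to a reference run.
Minimising over column permutations is a linear assignment problem and
is solved exactly for any K (the Hungarian algorithm); brute-force
enumeration over K! permutations is retained as a test oracle.

Assignment: an individual's top cluster (posterior-mean argmax) is
called only when its equal-tailed credible interval (default 90%)
overlaps no other cluster's interval; argmax ties are conservatively
admixed. A population is assigned to the cluster with the largest
share of significantly assigned individuals; equality, or a population
with no assigned individuals, yields an admixed call.

Desk-scale defaults (burn-in 2,000, 5,000 iterations, thin 5,
5 replicates) are deliberately far below production MCMC lengths;
all are flags. The α trace is flagged non-converged when it spans more
than 0.2 over the second half of sampling, the usual rule of thumb for
this parameter.

## Spatial analysis

Geographic distances are great-circle (haversine, Earth radius
6,371 km) between population centroids (mean of member coordinates, for
designs that record per-tree GPS). The Rousset regression fits
F_ST/(1−F_ST) against the natural logarithm of distance by OLS over all
population pairs; the Pearson test uses standard OLS degrees of freedom
even though pairs sharing a population are not independent — the
permutation-based Mantel test is the robust companion. Zero-distance
pairs and pairs at F_ST = 1 are excluded with warnings. The chord
distance averages Σₐ √(pₐqₐ) over shared non-missing loci before the
square root: D = (2/π)·√(2(1 − f̄)). The Mantel test permutes rows and
columns of one matrix jointly; p = (1 + #{r_perm ≥ r_obs})/(n_perm + 1),
one-sided "greater" because isolation by distance predicts a positive
association.

## PCA

Missing calls are mean-imputed per locus, columns centered (optionally
unit-scaled), and components taken from the SVD of the centered matrix;
each component's sign is fixed so its largest-magnitude loading is
positive. Group summaries are χ²(2 df) concentration ellipses of the
score covariance at the 95% level — a documented choice, since "roughly
95% of individuals" does not pin down a unique construction.

## Simulator

The generator draws ancestral frequencies Uniform(0.05, 0.95), then
per-deme frequencies by Balding–Nichols Beta(p(1−F)/F, (1−p)(1−F)/F)
with F = `F_native` (default 0.15). Demes sit on a 1-D gradient;
independent draws are kernel-smoothed with weights exp(−d/λ),
λ = `ibd_strength` (default 1.0), so neighbouring demes stay correlated
and a positive Rousset slope emerges (λ = 0 disables smoothing exactly,
which the drift-recovery tests rely on). Smoothing shrinks realised
differentiation somewhat relative to F; F is therefore a drift scale,
only exactly the expected F_ST when λ = 0.

The invasive gene pool is the allele-frequency vector of
`founder_size` (default 10) founder genotypes drawn from the
`founder_demes` (default the two demes at one end of the gradient) —
binomial founder sampling is what loses rare alleles, i.e. the
bottleneck. Each invasive population then re-drifts from the pool with
`extra_drift_invasive` = 0.10, reflecting strong local drift when
discrete plantations are established from a small introduced pool; this
level makes the bottleneck reliably detectable by the Wilcoxon AR
comparison at the package's desk scale (~16 populations, 251 loci)
while the high-MAF panel still masks it.

Clones replace (not augment) a fraction of each natural population's
individuals, so sizes match the configuration; the defaults
(`clonal_rate` 0.25 invasive, `clonal_rate_native` 0.08) are anchored
to the observed clone fractions of the motivating field survey (68/280
and 30/356). Seed-grown populations (`n_common_garden`, default 2) are
generated clone-free. Missing calls are masked independently at
`missing_rate` = 0.02, typical of MassARRAY-style genotyping. The
ascertained panel keeps loci whose MAF in a fresh discovery sample of
`discovery_panel_size` = 9 native individuals reaches
`maf_threshold` = 0.2, subsampled to `n_loci_ascertained` = 113 of the
`n_loci_full` = 251 loci when more pass.

What the simulator does *not* emulate: linkage, mutation, selection,
realistic 2-D geography, multi-generation pedigree clonality, and
genotyping error. Passing tests therefore demonstrate the estimators'
correctness and the qualitative mechanisms (founder signal, IBD
contrast, ascertainment masking), not calibrated performance on real
SNP data.

## Problem sizes and numerics

The test suite and examples run the founder scenario at 8 native demes
+ 8 invasive populations of 10–20 individuals, drift recovery at 20
demes × 20 individuals × 200 loci × 50 replicates, and MCMC at
2,000 + 5,000 iterations × 3 replicates — sizes chosen so the full
suite completes in a couple of minutes on one core while leaving the
statistical checks well-powered. Degenerate inputs follow one rule:
statistics that are mathematically undefined on valid data (F_IS with
zero gene diversity, ΔK with zero replicate variance, Pearson r of a
constant response) are reported as NaN markers; structurally invalid
inputs (a population with no complete locus, a single population for
F_ST, fewer than 4 populations for a Mantel test) raise errors naming
the offender.

## Known limitations

- The Mann–Whitney comparison of bootstrap TNA distributions inflates
  significance (see above); interpret its p-values as descriptive.
- lnPD is a rough evidence proxy; ΔK inherits its known tendency to
  favour K = 2 on hierarchical data.
- The CI-overlap assignment rule is conservative and its calls depend
  on MCMC length through credible-interval width.
- Population-level heterogeneity χ² tests of clonality (beyond the
  two-range test) are not implemented; their published construction is
  not reproducible from the available description.
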