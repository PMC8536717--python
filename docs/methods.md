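# Methods

This note documents the statistical model, the numerical choices, and the
synthetic-data generator behind `multifm`, including the places where the
design was genuinely open and what the evaluation studies do and do not
demonstrate.

## Single-trait fine-mapping

The single-trait engine scores multi-SNP causal models from marginal GWAS
summary statistics. Marginal effects are standardised to per-SNP scores
r_j = β_j √(2f_j(1−f_j)) / sd(y) — the correlation between genotype and
trait under Hardy–Weinberg genotype variance — and a model γ is scored by
the BIC-based approximate Bayes factor

    log ABF(γ) = −½ [ N log(1 − r_γᵀ R_γ⁻¹ r_γ) + m log N ],   m = |γ|,

where R is the reference-panel SNP correlation matrix. The quantity
r_γᵀR_γ⁻¹r_γ is the fraction of trait variance explained by the joint fit
of γ, so this is exactly the BIC difference between γ and the null model of
an ordinary least-squares fit; the unit tests pin the construction against
explicit OLS BIC computations on individual-level data (agreement to
better than 1e−3 on samples engineered to have exact Hardy–Weinberg
genotype counts, where the summary-statistic algebra is exact).

Model search follows the expanded-JAM workflow: the panel is tag-thinned
greedily at r² ≥ 0.99 (descending minor-allele frequency, ties broken by
SNP id), models over tags are searched exhaustively up to the configured
maximum size whenever that is affordable (a beam search seeded by the top
50 single-SNP models otherwise, retaining models within log(10⁶) of the
running best posterior score), and each tag model is expanded by every
combination of its tags' tagged SNPs. Every expanded model is re-scored
individually — tagged SNPs are near-proxies, not copies, and their ABFs
differ.

Priors over models are uniform within a size class, p(γ) = w_m / C(P, m),
with default size weights proportional to a Poisson(1) truncated at the
maximum model size (expecting about one causal variant per region). Both
the weights and the maximum size are configurable.

Numerical choices: a ridge of 1e−6 is added to LD submatrices of size ≥ 2
before solving; marginal scores are clipped to |r| ≤ 0.999; explained
fractions are capped just below 1. Posterior normalisation is carried out
in log space; models carrying less than 1e−12 of the maximum posterior
mass are dropped before the final renormalisation.

## The joint engine

For M traits measured on overlapping individuals, the joint log Bayes
factor of a configuration decomposes as Σ_k log ABF_k + D_M with

    D_M = −N/2 ( log|Ĉ_M| − log|C_M| ),

C_M(k,l) = Cov(y_k,y_l)/Var(y_k). Ĉ_M applies the same normalisation to
the configuration-specific residual covariance, reconstructed from summary
statistics: with joint standardised effects b_k = R_{γk}⁻¹ r_{γk},

    RC(k,l)/(sd_k sd_l) = ρ_kl − b_kᵀ r^{(l)}_{γk} − b_lᵀ r^{(k)}_{γl}
                          + b_kᵀ R_{γk,γl} b_l ,

where r^{(l)} is trait l's score vector. Determinant ratios involve only
the residual correlation, so trait scales cancel; N is the count of
individuals observed for all the configuration's traits. This
reconstruction is pinned by two oracles in the test suite: the normalised
empirical residual covariance of explicit per-trait OLS fits (entrywise
agreement within 0.02) and the multivariate-regression BIC (the D-term
route reproduces the joint-model BIC difference; the m log N penalties
cancel exactly between the joint and marginal BICs).

With missing trait measurements, D decomposes over missingness strata:
individuals observed for exactly the trait subset S contribute a D_S term
on the sub-configuration restricted to S (|S| ≥ 2; single-trait strata are
already carried by the marginal ABFs), each individual entering exactly
one stratum. When only per-trait totals and pairwise overlaps are known,
pattern counts are reconstructed by inclusion–exclusion and clipped at
zero with a warning.

### Sharing prior

Joint configurations receive prior Π_k p_k · κ^e · τ(sizes). For two
traits e is the indicator of a shared SNP; for M > 2 we define e as the sum
over connected components of the trait-sharing graph of (component size −
1), which reduces to the printed two-trait indicator and multiplies in one
factor of κ for each trait that joins a sharing cluster. Anchoring — the
requirement that prior mass per model-size combination not depend on κ —
forces τ(sizes) = 1/E[κ^e] under uniform-within-size model priors; for two
traits this is the closed form 1/(1 + (κ−1)q) with
q = 1 − C(P−m₁, m₂)/C(P, m₂). The expectation is computed exactly by
enumeration for small P and otherwise by seeded Monte Carlo with 10⁵
draws. Anchoring is verified by exhaustive enumeration in the tests.

κ is calibrated by solving, with bisection on [1, 10⁶] (odds tolerance
1e−8), for the target odds (TO) of no-sharing versus sharing; the sharing
probability is monotone in κ so the root is unique. One subtlety: the size
prior places mass on the null model, and no κ can make traits share a
variant one of them does not have, so the unconditional sharing
probability is bounded above by the probability that at least two traits
are non-null — below ½ under the default size prior. The calibration
therefore targets the sharing probability conditional on sharing being
possible (at least two non-null traits); TO = 1 then means a 50/50 chance
of sharing given that both traits carry a signal, which is the regime in
which fine-mapping is applied (the method is recommended only for regions
with association in every trait).

### Trait-adjusted posteriors

Writing W_i(κ) = Σ over configurations containing model i for trait k of
δ·τ·κ^e·Π_{l≠k} PP_l, the adjusted posterior is

    PP_i^k ∝ PP_i · W_i(κ) / W_i(1).

For two traits this is precisely the closed form
PP_i{1 + (κ−1)·Σ_{sharing} δτPP_j / Σ_j δτPP_j}, and it reduces to the
single-trait posteriors exactly at κ = 1 for any M — the property that
makes κ = 1 a true no-sharing baseline. (Plain marginalisation of
Π PP·δ·τ·κ^e would not have this property, because the δτ-weighted
average varies across models; the W-ratio normalises it out.) Per trait,
models are selected by cumulative posterior probability (cpp, default
0.99, capped at 1000 models); the discarded tail is reported as
unallocated posterior mass. The two-trait path is fully vectorised over
the configuration grid with log-space sums; an explicit general-M grid
route handles up to six traits and doubles as an internal cross-check —
the tests verify both paths against a scalar configuration-by-configuration
enumeration on random instances.

## Effective sample size

Mixed-model GWAS of related cohorts report standard errors that reflect
fewer effective observations than the nominal N. Inverting the
simple-regression identity se² = (var_y − β²v_x)/((N−2)v_x), v_x =
2f(1−f), gives a per-SNP N_e = (var_y − β²v_x)/(se²v_x) + 2 (floored at
1); the trait-level estimate is the untrimmed median over SNPs, reported
with its interquartile range and a warning below 30 SNPs. The estimate is
invariant to trait rescaling and is validated by recovery simulations
(unrelated cohorts: within 2%; fully duplicated cohorts: near half the
nominal roster).

## SNP groups

SNPs with marginal posterior probability (MPP) above 0.001 are grouped
agglomeratively: starting from singletons, the admissible pair of groups
with the highest mean cross-group r² is merged, a merge being admissible
when every cross pair has r² ≥ 0.5 and model-selection correlation ≤ 0
(zero-variance inclusion indicators are flagged and treated as 0). If the
mean between-group r² of the result reaches 0.6 the r² floor is raised by
0.05 and the build repeated, at most eight times. The merge objective and
the 0.5 floor are this package's choices; the constraints (high within-
group LD, negative model-selection correlation, between-group mean r²
below 0.6) are the method's stated contract. Groups are built per trait
and per method; joint-method groups are relabelled by their single-trait
counterparts (largest member overlap, ties by mean cross r²; a split group
becomes A.1, A.2, … in decreasing group-MPP order). For simulation
scoring, a group containing a known causal variant inherits its name, or
failing that the group holding the strongest proxy at r² > 0.7.

## Synthetic data

The generator emulates the study design used to evaluate the method:
LD-structured genotypes, correlated multi-trait phenotypes
y_kj = Σ_i β_ik x_ij + ε_kj with multivariate-normal errors, and
missing-completely-at-random masks per trait.

Haplotypes come from a latent-Gaussian threshold model. Each SNP carries a
loading vector on a small set of block factors with factor correlation Ψ,
making the latent correlation positive-definite by construction; an allele
is 1 where the latent normal falls below Φ⁻¹(MAF). Latent correlations for
targeted pairs are obtained by inverting the tetrachoric relationship
(bivariate normal CDF via 64-node Gauss–Legendre quadrature, bisection to
1e−4 in allele correlation); realised allele-level r² in a drawn pool is
checked against every target with tolerance 0.05. Genotypes are sums of
two independent haplotypes; cohorts are drawn without replacement from a
pool of 100,000 individuals.

The packaged 60-SNP region reproduces the joint-tagging motif that makes
some real regions hard to fine-map: a non-causal variant B correlated with
two causal variants A and D, so the 1-SNP model B competes with the true
2-SNP model A+D. Thresholded Gaussians attenuate extreme correlations — a
B with r² 0.55 to both A and D while A–D r² stays below 0.2 is infeasible
for any latent correlation (the required latent values violate positive
definiteness) — so the joint tags are generated conditionally on their
parent alleles per haplotype: B is 1 whenever both parents are 1, carriers
of exactly one parent allele transmit with probabilities solved to sit at
the binary feasibility frontier (capped at r² 0.7), plus a 1% baseline.
This reaches r² ≈ 0.59 from B to each of A and D with A–D r² = 0.19. J
plays the same role for A and the second trait's causal variant C (at its
own feasibility maximum, r² ≈ 0.51). Block structure: each causal variant carries a tail of 7–9 LD
proxies at r² 0.55–0.92, and four independent background blocks of
moderate LD fill the region to 60 SNPs.

Free parameters of the region were fixed once against the qualitative
behaviour reported for the method's evaluation region: causal variants A,
C and D sit at MAF 0.10 so that with effect sizes
β_A = log(1.4), β_D = β_C = log(1.25) single-trait fine-mapping prefers
the tag B at small samples and switches clearly to A+D around N = 3000,
with joint fine-mapping switching earlier; single-trait group A holds
roughly four to seven SNPs with coverage near 1 at N = 5000. Trait error
covariance is a correlation matrix (unit variances) with the configured
correlation (default 0.4).

What the generator does not emulate: realistic recombination-driven LD
decay (blocks are exchangeable within factors), allele-frequency spectra,
population structure or cryptic relatedness (relatedness enters only
through the duplicated-roster effective-N check), genotyping error, and
the full 345-SNP scale of the original evaluation region. Passing studies
on this region therefore demonstrate the machinery and the direction and
approximate size of the method's gains at desk scale, not the exact
magnitudes attainable in larger, denser regions — in particular, the
sharing upweight κ calibrated at TO = 1 grows with the number of region
SNPs (κ ≈ 31 at P = 60 versus ≈ 180 at P = 345), so gains over
single-trait fine-mapping are systematically smaller here than in the
full-scale design.

## Evaluation studies

The replication harness runs, per replication: cohort sampling, trait
simulation, per-trait GWAS on non-missing individuals, effective-N
estimation, single-trait fine-mapping (exhaustive over tags, maximum model
size 3), joint fine-mapping (TO = 1, cpp = 0.99, missingness strata from
the realised masks, trait covariance estimated pairwise-complete from the
realised traits), SNP-group construction for both methods, and
causal-labelled summaries. Methods are compared over the same
(cpp-truncated) model universe, so that the κ = 1 identity holds exactly
in the summaries. Group-level model posteriors aggregate all models with
one SNP from each causal group; group sizes and coverage exclude
replications where a group's marginal PP falls below 0.1, while model-PP
summaries include all replications. The acceptance script runs 100
replications per simulation setting (the full design used 300) to stay
within a desk-scale compute footprint; summaries are medians/means over
replications and are deterministic given the seed.
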