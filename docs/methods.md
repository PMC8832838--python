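# Methods

`xgrr` estimates how much of the individual variation in global
recombination rate (GRR) — the number of crossovers (CO) a parent
transmits per gamete — is attributable to the X chromosome, and maps the
X-linked loci responsible. Because the motivating cattle data set is
access-restricted, the package ships a first-class synthetic-data module
that generates cohorts with the same statistical structure, so every
stage runs end-to-end against known truth.

## The observation model

One record is one parent–offspring pair: the CO count observed in one
gamete of a genotyped parent. Parents with many genotyped offspring have
many records. The base model for the records **y** of one sex is the
Gaussian linear mixed model

    y = 1 mu + P c + Z_u u + Z_p p + e

with breed covariates **c** (four admixture coordinates standing in for
the leading principal components of genetic structure), an autosomal
polygenic effect u ~ N(0, A sigma2_a) with **A** the pedigree numerator
relationship matrix, a permanent-environment effect p ~ N(0, I sigma2_p)
defined per parent (it absorbs the covariance among a parent's repeated
gametes that genetics does not), and residual e ~ N(0, I sigma2_e).
The X contribution is tested by adding s ~ N(0, S sigma2_s) with **S**
the X-linked relationship matrix, and the Y contribution by a lineage
effect i ~ N(0, I sigma2_i) constant within each patriline. Models are
compared by likelihood-ratio tests referred to chi-square with 1 df
(the study's convention); the boundary-correct 50:50 mixture of a point
mass and chi-square(1) is available behind a `mixture` flag, and the
plain chi-square convention is conservative by about a factor two in
tail area.

Derived parameters: heritability h2 = genetic/total variance,
repeatability = (genetic + permanent environment)/total, and the X share
sigma2_s / (sigma2_a + sigma2_s [+ sigma2_i]). Their SDs come from 10,000
draws of the variance vector from its asymptotic normal distribution
(negative draws truncated at zero), the ratio recomputed per draw.

## The X-linked relationship matrix S

S is built by a gametic recursion: a male carries one X gamete, a female
two; a daughter's paternal gamete is an exact copy of the sire's single
gamete; any maternal gamete relates to others as the average of the
dam's two gametes. Individual entries combine gametic IBD r as

* male–male: r(g, g')
* female–female: (sum over the four gamete pairs)/2
* male–female: (sum over the female's two gametes)/sqrt(2)
* male diagonal: exactly 1; female diagonal 1 + f_X.

This equal-variance convention (unit expected diagonal in both sexes,
sqrt(2) cross-sex factor) is chosen to match the SNP dosage scaling
below: it is the unique convention under which the realized matrix XX'
has unit expected diagonal in both sexes and the SNP-effect variance
equals the X-linked individual variance. Where the source literature is
ambiguous about whether dosages are scaled by sum p(1-p) or its square
root, we divide by the square root — the only reading consistent with
reported XX' diagonals near 1. Textbook consequences used as oracles:
sire–son 0, sire–daughter 1/sqrt(2), dam–son 1/sqrt(2), full sisters
0.75, full brothers 0.5.

## SNP-BLUP estimation of the X variance

Male dosage at a marker is 0/1 (haploid X), female 0/1/2. Dosages are
centered by p (males) or 2p (females), with frequencies counted as one
allele per male and two per female, and scaled by sqrt(sum p(1-p))
(males) or sqrt(2 sum p(1-p)) (females) over the MAF-filtered markers
(MAF >= 0.01 by default). Fitting all marker effects m ~ N(0, I sigma2_m)
jointly, sigma2_m estimates the X-linked individual variance sigma2_s
directly. The model is algebraically equivalent to an individual effect
with covariance XX'; the implementation verifies this numerically by
evaluating the restricted likelihood through two routes (dense
individual-side algebra and marker-side mixed-model equations) that agree
to ~1e-9.

## REML implementation

Every fixed covariate and every random term except the residual is
constant within parent in this model class. The restricted likelihood
therefore factorizes exactly into within-parent contrasts (a closed-form
term in sigma2_e: (n - J) log sigma2_e + SS_within/sigma2_e) and the
parent-mean model with covariance sum_k sigma2_k K_k + sigma2_e
diag(1/m_j), where K_k is the structure marginalized to recorded parents
and m_j the record count. REML is maximized on this collapsed form —
identical to record-level REML, but the per-iteration cost scales with
the number of parents (~10^3) rather than records (~10^4-10^5).

Updates are average-information (AI) Newton steps with step halving;
after five consecutive rejected steps, or on request, the monotone EM
update theta + 2 theta^2/q * score is used. Variances are floored at
1e-8 times the phenotypic variance (boundary estimates are flagged);
convergence requires |delta logL| < 1e-8 and relative parameter change
< 1e-6. The asymptotic covariance of the estimates is the inverse AI
matrix over off-boundary components. A blocked Gibbs sampler (joint
Gaussian draw of all location effects through the mixed-model equations,
scaled-inverse-chi-square full conditionals for each variance with
weakly informative priors: df 4, scale an equal split of the sample
variance) provides posterior intervals when wanted.

## Haplotype-cluster scan

Phased X-specific haplotypes (one per male, two per female) are
clustered with a localized haplotype-cluster HMM: K clusters (default
40), per-marker Bernoulli emissions theta[k,m] floored at 1e-4,
per-interval jump probability rho_m with jump destinations drawn from
per-marker weights alpha[:,m]. The stay-or-jump transition structure is
rank-one plus identity, so forward, backward and Viterbi all run in O(K)
per marker. EM uses the exact jump-posterior updates for rho and alpha;
emission centers are seeded by greedy max-min-Hamming selection
(k-means++-style), which avoids the label-switching local optima the
per-interval jump parameterization admits. Haplotypes get hard Viterbi
cluster states; at each marker the parent loads on its one (male) or two
(female) states.

The scan adds a random cluster effect h ~ N(0, I sigma2_h) at each
position to the background model y = X beta + P c + Z_u u + Z_s s + e
(no permanent-environment term, matching the scan design; a flag adds
it). Background variances are estimated once under the null and held
fixed — per-position profiling of sigma2_h only, through a whitened
representation where the position test is K x K algebra (Woodbury).
Re-estimating the full background per position would cost three orders
of magnitude more for no perceptible change in the test. Significance is
declared at the Bonferroni threshold alpha/n_tests = 0.05/30,000 =
1.67e-6, the genome-wide convention for this trait.

## Sequence scan, conditional analysis, credible sets

Variant dosages (with per-variant imputation accuracy supplied; the
synthetic data assigns accuracy 1) are filtered at r2 >= 0.80 and
MAF >= 0.01, then tested one at a time as a fixed regressor by GLS with
the covariance fixed at the null REML estimates; the effect is tested
with a two-sided Z-test. Conditional analysis appends lead dosages to
the fixed effects (collinear leads dropped and logged) and iterates
while any variant passes the threshold. Each QTL is summarized by the
LD-based credible set: all variants with squared dosage correlation
r2 > 0.90 with the lead, computed across recorded parents. Identified
variants are finally fitted jointly; each contributes variance p q a^2
(exact for the haploid male X), reported as a share of the additive
genetic variance of the model without the variants, alongside the
percent reduction in the polygenic sigma2_a and sigma2_s.

## Synthetic data

* **Pedigree** — discrete generations; cohort size = dams x mean gametes
  per dam (cattle dams leave ~1.3-2.6 recorded offspring); sires are a
  subset of the previous generation's males sized cohort/mean-offspring-
  per-sire, so sire usage is heavy (~10-24 gametes each), emulating the
  AI-sire structure of the motivating cohort. The real data's
  overlapping generations are compressed into discrete ones.
* **Haplotypes** — founders are mosaics of a small ancestral panel
  (switch rate 1/5 cM), which produces realistic LD; meioses then follow
  X biology: female recombination per the female genetic map (interval
  crossover counts Poisson with mean = Morgan length, Haldane, no
  interference), males transmit the X-specific haplotype unrecombined to
  daughters and nothing X-specific to sons, and the PAR recombines in
  both sexes (a long male PAR map, reflecting the obligate male PAR
  crossover). A causal variant is planted as a young mutation on one
  local haplotype background at its target frequency (0.057 by default).
* **Phenotypes** — Gaussian LMM draws rounded to the nearest
  non-negative integer. Defaults: mean 25 CO, total variance 6.25 CO^2
  split 11.1% autosomal, 4.7% X, 0.5% Y, 1.0% permanent environment,
  remainder residual — the partition estimated for male GRR in dairy
  cattle. Rounding adds ~1/12 CO^2 of variance (~1.3% of total), which
  the tests account for. How CO counts distribute around the LMM mean is
  not identified by the fitted model; Gaussian-with-rounding is our
  choice. Polygenic values are generated by the exact pedigree
  recursions (the gametic recursion for X); for pedigrees beyond ~4,000
  ancestors the Mendelian-sampling inbreeding correction uses f = 0,
  adequate because simulated random-mating pedigrees are essentially
  non-inbred.
* **Covariates** — founder admixture from a 5-component Dirichlet,
  averaged down the pedigree; only the fixed-effect role of the real
  breed PCs matters here.

What passing tests show — and do not. The generator reproduces the
variance structure, X inheritance, LD and record design the method
assumes, so the tests demonstrate internal statistical correctness
(calibration, recovery, equivalences) at realistic scale. They do not
probe phasing or genotyping error, crossover interference, imputation
error (accuracy is taken as a supplied column), or model misspecification
in real data.

## Problem sizes used by the reference checks

Chosen to keep the full verification run on a single CPU within minutes
while preserving the power and precision each check needs:

* XX' diagonal: 5,000 HWE females x 300 markers (Monte-Carlo SE ~0.001).
* S oracle: ~220-individual 5-generation pedigree, 100,000 independent
  loci (per-entry SE ~0.003, so the +/-0.02 band is a >6-sigma check).
* SNP-BLUP equivalence: 20 instances, 200 males x 50 markers.
* REML recovery: ~940 recorded sires x 20 gametes (~18,000 records),
  truth (11, 5, 1, 83), 50 phenotype replicates over one pedigree.
* Scans: ~1,100 recorded sires x 20 gametes, 150 X-specific markers,
  K = 40; 10 power replicates, 20 permutation replicates. At this scale
  the planted QTL's noncentrality for the sequence test is ~60-80,
  far above the chi-square threshold (~23.9) at 1.67e-6, so detection
  power is high; the haplotype scan localizes the QTL but — exactly as
  in the motivating data, where this QTL's haplotype-based p sat within
  4x of the threshold — its LRT is the weaker of the two tests, and the
  decisive p-value comes from the sequence-based fine-mapping.

## Known limitations

* Dense matrix algebra throughout: intended for cohorts up to a few
  thousand recorded parents, not national evaluations.
* The X-specific region and PAR are modelled separately; no PAR
  relationship matrix and no joint PAR/X-specific cluster model.
* The haplotype-cluster parameterization follows the localized-cluster
  description (marker-specific jump and weight parameters); other
  dialects of the model differ in how alpha is tied across markers.
* Sex-specific analyses are run separately; no cross-sex genetic
  correlation is estimated.
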