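# Methods

## Scope and model

`giltgwas` analyses a quantitative trait — age at puberty in gilts, in
days — with Bayesian whole-genome regression and window-based QTL
testing.  The observation model is

    y = X β + Z u + e

with `X` the fixed-effect design (intercept plus year-season-of-birth
dummies, first class absorbed as reference), `Z` the n×m matrix of
centred allele dosages, and `e ~ N(0, I σ²_e)`.  Under BayesC each SNP
effect is exactly zero with probability π and otherwise drawn from a
common normal `N(0, σ²_u)`; BayesCπ places a uniform prior on π.
σ²_u and σ²_e carry scaled-inverse-χ² priors (ν_u, S_u), (ν_e, S_e).

The assumptions to keep in mind: additive allele dosage effects only
(no dominance/epistasis), a single common effect variance across
included SNPs, homoscedastic residuals, and fixed-effect classes that
are exchangeable with the genetic signal (year-season is assumed
orthogonal to family structure in expectation).  The X chromosome is
treated as autosomal dosage.

## Gibbs sampler

One iteration sweeps, in order: each fixed effect from its normal full
conditional (flat prior); each SNP j in column order — the inclusion
indicator from its Bernoulli full conditional with u_j integrated out
(log Bayes factor `0.5·log(λ/(c_j+λ)) + r_j²/(2σ²_e(c_j+λ))` with
`λ = σ²_e/σ²_u`, `c_j = z_j'z_j`, `r_j` the residual right-hand side),
then the effect from its normal conditional when included; σ²_u from
scaled-inv-χ²(ν_u + k, ·) combining S_u with the sum of squared included
effects; σ²_e from scaled-inv-χ²(ν_e + n, ·) with the residual sum of
squares; and, in π-estimation mode, π ~ Beta(m−k+1, k+1).  The residual
vector is updated incrementally, so a sweep is O(nm); the loop is
numba-compiled.  Setting π = 0 keeps every SNP in the model, which is
the SNP-BLUP/ridge limit used by the equivalence tests.

Per retained iteration the sampler records the genetic variance as the
empirical variance across animals of the genomic values `Zu` (an
alternative `Σ 2p_j q_j u_j²` definition is available via
`genvar_mode="sum2pq"`), the total variance as genetic + σ²_e, and the
number of included SNPs.  Marker heritability is the posterior mean of
genetic/(genetic+residual).  Defaults: thinning 1; burn-in below the
total iterations; seeds fix the chain bit-for-bit.  Because the sweep
visits SNPs in column order with a single RNG stream, permuting columns
changes the chain realisation; posterior summaries are permutation
equivariant only up to Monte-Carlo error.

### Prior scales and the π/σ²_u degeneracy

When both σ²_u and π are free and per-SNP effects are weak, the sampler
has a second, polygenic mode: σ²_u collapses toward zero, inclusion
becomes likelihood-free, and π random-walks toward ≈ 1 − k/m with k of
order n.  π is then meaningless.  The package's two-stage design avoids
this by anchoring σ²_u before estimating π: the per-SNP scale is set to
the heritability-implied value

    E[σ²_u] = h²_prior · var(y) / ((1 − π₀) · m · mean_het)

with `h²_prior` taken from the pedigree REML analysis (or the analyst's
prior belief), `π₀` the starting sparsity, and `mean_het` the average
2p(1−p) of the panel, and ν_u set large (≈100) so the anchor holds.
With this anchor, π is recovered within ±0.02 at n = 500, m = 2,000 in
the acceptance suite.  At the emulated study's own sparsity
(π ≈ 0.9935), the REML-derived scales with the weak default ν_u = 4 are
already sufficient because m(1−π) is small and S_u correspondingly
large.  `variance_priors` converts REML components by prior-mean
matching: `S_u = σ²_a (ν_u−2)/(ν_u · m(1−π) · mean_het)`,
`S_e = σ²_e (ν_e−2)/ν_e`.  Defaults ν_u = 4, ν_e = 10 (configurable).

## Pedigree variance components

The numerator relationship matrix is built by the tabular method
(founders diagonal 1; `A_ii = 1 + 0.5·A(sire,dam)`;
`A_ij = 0.5(A(j,sire_i)+A(j,dam_i))`), validated against a Monte-Carlo
gene-dropping estimate of twice the kinship.  REML for the animal model
uses the marginal form on the phenotyped subset,
`V = A_obs σ²_a + I σ²_e`, iterated by EM in the eigenbasis of `A_obs`
(one eigendecomposition, then O(n) per EM step):

    σ²_i ← σ²_i + (σ⁴_i / n) (y'P V_i P y − tr(P V_i))

which increases the restricted likelihood monotonically.  Convergence is
declared when successive log-likelihoods change by < 1e−5 (EM crawls
geometrically near the σ²_a → 0 boundary; at that tolerance the
estimates are stable to ~3 significant digits).  The h² standard error
is an average-information approximation with a delta-method transform,
and the component covariance is exposed for 3-SE recovery checks; both
are approximations, not exact REML curvature.

## Quality control

SNPs are removed for unknown map position, Y linkage, call rate
**< 0.95**, or folded MAF **< 0.05**; animals for missingness
**> 0.05**; inequalities are strict, so values exactly at a threshold
survive.  The Mendelian (parentage) test counts opposing-homozygote
conflicts between an offspring and each genotyped parent over loci where
both are called, failing an animal when the conflict fraction exceeds
1% (default; the threshold is a package choice, as array error rates
vary).  Missing dosages are imputed to the column mean and columns
centred; a genotype PCA (exact SVD) is provided for stratification
inspection.  Each removed SNP is attributed to the first rule it fails,
in the order unknown-chromosome, Y, call-rate, MAF, so report counts add
up to the input dimension.

## Windows, bootstrap, PFP

Windows are five consecutive SNPs per chromosome, non-overlapping
(stride 5, trailing partial discarded) by default, stride-1 sliding
optionally; they never span chromosomes.  Window genetic variance is the
variance across animals of the window's genomic values computed from
posterior-mean effects, expressed as % of the total `var(Z u_mean)`;
ties in the share are ranked deterministically by (chromosome,
start position).  K = round(m(1−π)) top windows are the putative QTL.

The parametric bootstrap simulates each null replicate as
`y* = X β̂ + Z û(window zeroed) + e*`, `e* ~ N(0, σ̂²_e I)` — only the
residuals differ between replicates — refits the same BayesC model with
a shortened chain, and recomputes the tested window's variance.  With k
replicates at or above the observed statistic (ties count as
exceedances, conservative), the p-value is the interval
`(k/B, (k+1)/B)`; classification uses the upper end.  The proportion of
false positives is `π₀Σα / (π₀Σα + (1−π₀)·n_tests·γ)` — expected false
positives over expected total positives — with user-supplied true-null
proportion π₀ and per-test power γ; it is reported alongside the raw
interval p-values rather than used to re-threshold them.

## LD

The default `em` method estimates two-locus haplotype frequencies from
unphased diplotypes by EM (only the double heterozygote is
phase-ambiguous; the update converges to the closed-form count whenever
none are present), then `D = p_AB − p_A p_B` and
`r² = D²/(p_A q_A p_B q_B)`.  Convergence: absolute frequency change
< 1e−8 or 1,000 iterations; biallelic pairs are unimodal in practice so
a single start suffices.  `genotype_corr` is the squared Pearson
correlation of dosages (composite LD), which matches EM within ~0.02
under Hardy-Weinberg.  Monomorphic pairs are reported as missing with a
reason.  Haplotype-block calling is out of scope.

## Synthetic data

The generator emulates the study design: configurable chromosome plan
(default 18 autosomes + X), allele frequencies uniform on the MAF range
(default [0.05, 0.5]), year-season classes (default 8), baseline age
200 d, sparse architecture with `pi_true` (default 0.9935) and common
per-effect variance, residual variance defaulting to the pedigree-model
scale (134.8 days²).  Adjacent-SNP LD follows a first-order Markov
haplotype model implemented as a latent Gaussian AR(1) with parameter
`ld_rho`, thresholded to each SNP's frequency: `ld_rho = 0` gives exact
independence; as `ld_rho → 1` neighbours become near copies.  Two
caveats: thresholding attenuates the realised allelic correlation
slightly below `ld_rho`, and LD decays with marker index, not physical
distance.  Pedigree genotypes transmit alleles per locus independently
(no within-gamete linkage), which suffices for parentage testing and
A-matrix work but not for haplotype-sharing analyses.  Mendelian errors
flip a fraction of offspring calls to a different code; missingness is
uniform at random (real call failure is clustered, so QC tests here
probe the filters' arithmetic, not realistic missingness patterns).
Phenotypes are uncensored by default; `truncate_phenotypes` optionally
drops records above a cutoff (default 240 d) to probe the selection
effect of the study's right-censored design — the censored animals' age
distribution is unknowable, so any censoring emulation is a modelling
choice.  Passing tests on these data show the algorithms are correct
under the stated model; they do not certify behaviour under real-array
artefacts (clustered missingness, genotyping batch effects, distance-
dependent LD).

## Desk-scale test sizes

The acceptance suite runs each statistical check at sizes chosen for a
single CPU: SNP-BLUP equivalence at n = 200, m = 300 (π = 0, variances
fixed, 3 Monte-Carlo-SE agreement with the mixed-model-equation
solution); π/heritability recovery at n = 500, m = 2,000 with the
anchored prior; the planted-QTL power test at n = 500, m = 1,000 with a
constructed sparse background (10 SNPs at ±3 d/allele, overall h² ≈
0.31, study-like π = 0.99) and a planted SNP sized to 5% of genetic
variance — a diffuse background at the same total h² would make a
5%-of-GV window statistically undetectable at this n (marginal t ≈ 1.9),
so the constructed architecture is what makes the criterion a test of
the pipeline rather than of sample size; bootstrap type-I calibration
over 100 null datasets at n = 120, m = 200, B = 99 with 500-iteration
chains; REML recovery at n = 2,000 phenotyped offspring in full-sib
litters (100 sires, 400 dams, 5 per litter).  The acceptance script uses
a 2,000-SNP panel at n = 759 as a scaled stand-in for the 41k array.

## Known limitations

* π and σ²_u are jointly identified only through the prior anchor at
  desk-scale n; report both, and treat π̂ as prior-sensitive.
* The bootstrap conditions on posterior means from the real-data fit
  (as the emulated procedure does); it does not propagate their
  uncertainty, so p-values are approximate and mildly optimistic for
  windows selected by rank.
* EM-REML standard errors are average-information approximations.
* Candidate intervals are exported for external annotation; no gene
  lookup is performed.
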