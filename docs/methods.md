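# Methods

This note documents the models, estimators and numerical choices behind
sweepscan, and what the synthetic testbed does and does not establish.

## Sweep model and composite likelihood ratio

The scan follows the composite-likelihood approach of SweepFinder-style
methods. The genome-wide background site-frequency spectrum (SFS)
p_bg(j), j = 1..n−1, is estimated by normalized counts of derived alleles
over polymorphic sites; sites with missing genotypes can be folded in by
hypergeometric projection to a common haploid size (default: the minimum
observed size), or excluded. In the pipeline, imputation runs before the
scan, so projection is rarely exercised there.

At a test position, a site at distance d is modelled by the lineage-escape
mixture: each of the n sampled lineages escapes the sweep independently
with probability p_e = 1 − exp(−α d). Given e escaped lineages, the e
escapees plus the single sweep ancestor form an ancestral sample of size
e+1 whose derived count j follows the background SFS projected to e+1
lineages; with probability j/(e+1) the sweep ancestor carries the derived
allele, in which case the modern count is b = (j−1) + (n−e), otherwise
b = j. The case e = n (every lineage escaped) is the pure background draw —
the sweep ancestor has no modern descendants. The resulting distribution is
conditioned on polymorphism (b ∈ 1..n−1). A site exactly at the test
position has polymorphism probability zero under the model and is excluded
(rather than jittered).

Implementation note: the per-escape-count table Q[e, b] depends only on the
SFS, so it is computed once (vectorized log-gamma combinatorics) and reused
across every α, distance and grid point; a scan position then costs one
binomial-weight tensor and two contractions.

CLR(x) = 2 [max_α Σᵢ log P(bᵢ | α, dᵢ) − Σᵢ log p_bg(bᵢ)], maximized over a
log-spaced grid of 20 α values spanning p_e(nearest site) from 0.01
(engulfing sweep) to 0.999 (near-neutral), with ties broken toward the
smallest α. Because the neutral model is the α → ∞ limit, the score is
clipped at zero and α̂ = ∞ reported when no grid α beats the background.
Sites enter a grid point's likelihood within radius
min(1 Mb, ln(1000)/α_min) — the range over which the *smallest* grid α
(the widest sweep the grid can fit) still distorts the spectrum
appreciably; beyond it every admissible model reduces to the background
and sites contribute nothing but runtime.

The spectrum is unfolded: the synthetic data knows ancestral states, and
alt alleles are treated as derived when reading a VCF. A folded background
can be built for descriptive use, but the sweep mixture itself requires the
unfolded spectrum, and the scan refuses folded input rather than guess a
polarization.

## Weir–Cockerham F_ST

Per site, the r = 2 variance components of Weir & Cockerham (1984):

- a — among populations; b — among individuals within populations; c —
  within individuals; θ̂ = a/(a+b+c), undefined when the denominator is 0
  (site monomorphic in both populations).

θ̂ is reported unclamped; negative estimates are retained in window means
because clamping at zero biases them. Two distinct summaries are exposed
deliberately:

- **window score** (default `mean_theta`): arithmetic mean of per-site θ̂
  in 25-kb windows. This is the genome-wide ranking statistic; its
  expectation is *below* the differentiation parameter F because the
  per-site ratio is a nonlinear function of noisy components (measured on
  the Balding–Nichols testbed: grand mean ≈ 0.15 at F = 0.2, ≈ 0.26 at
  F = 0.4). Ranking is unaffected because the bias is shared genome-wide.
- **parameter estimate** (`multilocus_fst`, also per-window via
  `method="ratio_of_sums"`): Σa/Σ(a+b+c), the combination Weir & Cockerham
  recommend, which recovers F to well within 0.02 at 5,000 sites in the
  recovery checks.

## Region calling

Empirical p-values are descending ranks divided by the number of scored
windows, ties sharing the group's maximum rank. "Above the 98th
percentile" is operationalized as strictly greater than the ⌈0.98·N⌉-th
smallest score, which with all-distinct scores selects exactly
N − ⌈0.98·N⌉ windows (1,811 of 90,588; 1,806 of 90,322) and selects fewer
under ties. Selected windows merge into a CSR while consecutive gaps are
< 200 kb. A CLR CSR contributes CASRs wherever it overlaps the union of
the F_ST CSR tracks by ≥ 1 bp (a `require_both` switch demands overlap
with every reference track); emitted CASRs are the intersection intervals.
Genes are attached within region ± 100 kb — a 200-kb window around the
signature, the span suggested by LD decay — and significant associated
SNPs are assigned to their nearest region, flagged when within 1 Mb
(configurable; no principled value exists for "close", so the default is
deliberately generous and always reported alongside the distance).

## Quality control

Filters run in a fixed order — per-site depth ≥ 4, RMS mapping quality
≥ 20, adjacent-SNP distance ≥ 5 bp, within-population missingness < 50%
(20% for the scan input), pooled MAF ≥ 0.01, and (GWAS input only) an
exact-test HWE floor of 1e-6 — with each removed site charged to the first
criterion it fails, so the report columns sum exactly to the sites lost.
The adjacency rule is greedy left-to-right against the last *retained*
site; symmetric pair-dropping was rejected because removals cascade.
The HWE exact test is the standard conditional test on heterozygote counts
given allele counts, and is evaluated **within each population**: pooling
differentiated populations fails HWE at precisely the divergent sites
(Wahlund effect), which would delete the most interesting part of the
input (verified on the default design, where pooled testing removed ~8% of
sites including the planted causal variant).

Missing genotypes are imputed by drawing from Binomial(2, within-population
allele frequency) under the run seed. This is a deliberately simple,
fully-documented imputer: it preserves frequencies but not haplotype
structure, which is out of scope; observed genotypes are never altered, and
a site with no observations in some population is an error rather than a
guess.

## Linkage disequilibrium

r² is the squared Pearson correlation of dosages over samples non-missing
at both sites (genotypes are unphased; no haplotype-EM estimator is
attempted), undefined when a site is monomorphic among complete pairs.
Curves average defined r² in half-open 1000-bp distance bins.

## Mixed-model GWAS

For each chromosome, G is the standardized GRM (columns centered, scaled to
unit variance; ZZᵀ/m) built from all *other* chromosomes (LOCO), removing
proximal contamination without per-SNP GRMs. After one eigendecomposition
per (chromosome, trait), each SNP's variance ratio δ = σ²ₑ/σ²ₐ is estimated
by maximizing the restricted likelihood on a 21-point log₁₀ δ grid over
[−5, 5] refined by bounded scalar minimization (tolerance 1e-6 in log δ);
fixed effects (intercept, batch dummies, SNP) are then estimated by GLS and
b tested against χ²₁ (Wald). With G = I the procedure reduces exactly to
ordinary least squares for every δ, which is verified to 1e-6. Null
calibration on the synthetic testbed gives a rejection rate statistically
indistinguishable from 0.05 and λ_GC ≈ 1.

SimpleM computes, per chromosome, the eigenvalues of the SNP correlation
matrix (via the sample-side Gram matrix when SNPs outnumber samples) and
counts the leading components reaching 99% of total variance; M_eff is the
sum over chromosomes — the established block-wise form of the procedure,
used because a whole-genome correlation matrix is both impractical and
unnecessary when chromosomes are unlinked. The genome-wide threshold is
0.05/M_eff.

## Synthetic testbed

The generator emulates the statistical structure the pipeline assumes:

- **Differentiation**: ancestral frequency p ~ Uniform(0.05, 0.95) (the
  bounds avoid near-fixed sites with undefined θ̂), population frequencies
  Beta(p(1−F)/F, (1−p)(1−F)/F) (Balding–Nichols; F = 0 uses p exactly),
  genotypes Binomial(2, freq). Sites are independent — there is no
  background LD, recombination map or demography.
- **Sweep**: focal-population derived counts on the sweep chromosome are
  redrawn from the CLR sweep model itself (background = the population's
  own genome-wide SFS), making parameter recovery a well-posed closed loop.
  This is a deliberate choice over forward simulation: it tests the
  estimator, not the model's fit to coalescent reality.
- **Missingness**: uniform at random (real GBS missingness is structured;
  no public description of that structure exists for this design).
- **Phenotypes**: y = μ + batch + Σ causal dosage·effect + polygenic +
  noise, the polygenic term drawn MVN with covariance proportional to the
  realized standardized GRM (matching the GWAS model exactly). Causal and
  polygenic parts are rescaled to explain exactly h²_snp and h²_poly of the
  realized variance — exact in-sample rather than in expectation, which
  makes recovery checks sharper. When a sweep is planted, the (single, by
  default) causal SNP is the site nearest the sweep center with MAF ≥ 0.1:
  a variant dragged to near-fixation has no dosage variance left to test,
  so an unconstrained choice would plant an undetectable signal.

Default design (one choice, stated here): 200 focal + 50 reference
diploids, three 5-Mb chromosomes of 1,500 sites, F = 0.2, sweep α = 2e-5/bp
at chr1:2.5 Mb, 5% missingness, one causal SNP with h²_snp = 0.3,
h²_poly = 0.3, three batches with effects −0.5/0/0.5. The CLR scan inside
the pipeline uses a fixed 25-diploid subsample of the focal population,
mirroring the common situation where the whole-genome scan panel is far
smaller than the genotyped GWAS cohort, and keeping the scan cost linear in
a quantity that does not grow with cohort size.

Because sites are unlinked and the sweep is generated from the fitted
model, passing tests demonstrate correctness and calibration of the
estimators under their own assumptions — not robustness to LD,
demographic history, B-value variation or structured missingness in real
data.

## Problem sizes and numerical details

Validation runs use: F recovery at 2×50 diploids × 5,000 sites; CLR
localization on a 10-Mb chromosome (n = 40 haploids, 5,000 sites, α =
1e-5, 50 replicates, success = argmax window center within 100 kb); LMM
null calibration on 2,000 tests over 10 seeds; end-to-end joint recovery
over 20 seeds of the default design. Degenerate inputs are errors, not
silent results: empty datasets, all-monomorphic sites, single-chromosome
LOCO (an explicit `no_loco` override exists), fully-missing sites, d = 0
sweep sites. Probability sums are kept exact to ~1e-12 by working with raw
(unconditioned) class masses and renormalizing once; binomial escape
weights are computed in log space with log(1−p_e) = −αd taken exactly.

## Known limitations

- No recombination-map distances; α is per physical bp.
- The composite likelihood ignores invariant sites and inter-site
  correlation, as is standard; CLR magnitudes are therefore not
  chi-square-calibrated, which is why significance is empirical-rank-based.
- The imputer does not use haplotypes; at high missingness it attenuates
  LD and association signal.
- Weir–Cockerham machinery is specialized to two populations (r = 2).
- The GWAS assumes a single quantitative trait measured once per animal;
  no repeated measures, dominance or epistasis.
- CASR calling requires a literal >= 1 bp intersection of CLR and F_ST
  candidate regions on the shared 25-kb window grid. When both statistics
  flag the sweep but their few selected windows land on adjacent grid
  windows (most likely when the sweep sits near a window boundary, as the
  default design's chromosome-midpoint sweep does), no CASR forms even
  though both tracks localized the signal; in end-to-end runs this is the
  dominant failure mode, affecting roughly a quarter of seeds.
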