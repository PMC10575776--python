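# Methods

## Study design

The package analyses proband–parent trios with a binary proband phenotype
(1 = lower school performance). Every genetic predictor is tested against
that outcome in a fixed battery: 6 common-variant tests (transmitted and
non-transmitted PRS for three GWAS traits) by ordinary binomial logistic
regression, and 12 rare-variant burden tests (6 mutation classes × 2 gene
sets) by Firth penalised logistic regression, all adjusting for sex and 10
principal components. With 18 primary tests the Bonferroni threshold is
0.05/18 ≈ 0.0027. Secondary analyses — pTDT group comparisons and
rare-variant TDT — probe transmission directly and are not
multiplicity-corrected against the primary battery.

## Inheritance classification

Rare-variant trio genotypes must pass joint QC before classification:
depth ≥ 10, GQ ≥ 30, het allele balance in [0.2, 0.8], hom-alt ≥ 0.9,
hom-ref ≤ 0.1, applied to *all three members* of any carrier trio. A
variant failing QC in any member is dropped for the whole trio
(`filtered`), which avoids spurious de novo calls from parental dropout.

Classification from dosages (proband p, father f, mother m): p>0 with
f=m=0 is `de_novo`; otherwise a Mendelian-impossible triple (p not
reachable from the parents' transmissible alleles) is `mendelian_error`;
otherwise p>0 is `transmitted`, parent-only carriage is
`non_transmitted`, no carriage is `absent`. The de novo rule is applied
before the consistency check, so the (2,0,0) double-hit triple is called
de novo rather than an error; all 27 triples are pinned by a committed
truth table. CNVs are classified by ≥1 bp same-type interval overlap
with parental CNVs (a deletion cannot transmit as a duplication);
intervals are BED half-open, conversions confined to the I/O layer.

For common SNPs the pseudo-control dosage is f + m − p. Mendelian errors
at common SNPs mask the SNP for that trio only (set missing); nothing is
removed cohort-wide, matching a design in which overall Mendelian
consistency is high (the `mendelian_screen` flags SNPs or trios below 90%).

## Damaging-variant prioritisation and burden

Damaging PTVs: any frameshift; stop-gain or splice donor/acceptor with
scaled CADD ≥ 20. Damaging missense: MPC ≥ 1 and CADD ≥ 20. Missing
scores are conservatively non-damaging (logged). Inherited (transmitted /
non-transmitted) analyses additionally require ultra-rarity: parental
allele count exactly 1 and absence from the external reference; de novo
variants bypass this filter. CNV filters: cohort frequency ≤ 1%, ≥ 15
probes, segmental-duplication overlap ≤ 50%, length ≥ 15 kb, plus
≥ 100 kb for inherited CNVs. Gene-set membership is by gene symbol for
coding variants and by ≥1 bp exon overlap for CNVs. Counts are of
variants, not genes; CNV cohort frequency is computed across all
individuals (probands and parents), an explicitly documented choice since
"the sample" is ambiguous.

## Polygenic scores and pTDT

Summary statistics are allele-aligned to the panel (direct or strand-
complement match; swapped alleles negate β; strand-ambiguous A/T and C/G
SNPs are dropped). Clumping is greedy: best remaining p first (ties by
chromosome, position), removing SNPs within 250 kb at r² > 0.2. LD is
estimated from parental genotypes only, so transmitted alleles are not
double-counted. Scores sum β × dosage over clumped SNPs below the
p-threshold; missing dosages contribute the SNP's mean dosage. The
primary threshold is 0.05, with 0.001 and 0.5 as sensitivity outputs.
Scores are standardised cohort-wide per threshold and score type before
association. The pTDT deviation divides (proband − midparent) score by
the across-trio SD of the midparent score; the transmission identity
(proband + pseudo-control = father + mother) holds exactly for raw
scores and is asserted exactly in tests.

A structural note: the pseudo-control score is uncorrelated with the
*transmitted* score (cov = var(midparent) − var(deviation) = 0 per SNP),
which is the independence the design exploits; it is necessarily
anti-correlated with the transmission deviation itself (r → −1/√2), so
the deviation, not the nt-score, carries the within-family signal.

## Association statistics

Firth regression maximises ℓ(β) + ½ log det I(β) by Newton iteration on
the hat-adjusted score U*_j = Σ_i (y_i − π_i + h_i(½ − π_i)) x_ij with
step-halving; convergence at max |U*| < 1e−6 or step < 1e−8.
Probabilities are clipped to [1e−12, 1 − 1e−12] and likelihoods kept in
log space. Standard errors come from the inverse information at the
estimate; the p-value for the term of interest is the penalised-
likelihood-ratio test (refit with that coefficient fixed at 0); other
terms use Wald p. CIs are Wald by default with profile-penalised CIs
available. For a single binary predictor the estimate coincides with the
add-½-to-each-cell odds ratio, which the tests exploit as a closed-form
oracle. Ordinary binomial fits use statsmodels; if the ML fit diverges
(non-convergence or |β| > 15, i.e. separation) the fit falls back to
Firth and is flagged in the result's `method`.

Nagelkerke R² is (1 − exp(2(ℓ₀ − ℓ)/n)) / (1 − exp(2ℓ₀/n)); ΔR² between
nested fits quantifies each factor's contribution. In the multivariable
model the outcome is coded 1 = higher performance; the joint Firth fit
supplies betas and p-values while nested binomial fits supply ΔR².
Exact binomial CIs use the beta-quantile characterisation of
Clopper–Pearson. Fisher's exact test reports the two-tailed hypergeometric
p, the conditional-MLE odds ratio (mean-matching under Fisher's
noncentral hypergeometric, the convention of R's `fisher.test`), and the
exact CI from inverting the one-sided conditional tests. The TDT is
(T − NT)²/(T + NT) on χ²₁; group comparisons use the pooled two-sample
t-test. The pTDT group comparison is unadjusted for covariates (a
covariate-adjusted comparison can be run through the regression layer if
needed).

## Liability-model power simulation

Per replicate, independent standard normals (PRS, V2) form
L = √r²·PRS + √(1 − r²)·V2; draws with L < 0 fill the lower group and
L > 0 the higher group until the target sizes (default 347/346) are
reached, overflow discarded; the groups' PRS values are compared by a
pooled t-test and power is the rejection fraction over replicates
(default 10,000), with an exact binomial CI. The pooled (not Welch) test
matches the near-equal conditional variances. A closed-form normal
approximation (group mean shift 2√r²·√(2/π), within-group variance
1 − r²·(2/π)) serves as an independent cross-check; it ignores the
skewness of the sign-conditioned PRS distribution, which costs it up to
~1.5 percentage points near mid-power, so simulation is the reported
estimator.

## Synthetic cohort generator

The generator emulates, on a single pseudo-chromosome with uniformly
spaced genes (fixed-width exon blocks) and SNPs:

* parental haplotypes at Uniform(0.05, 0.5) MAFs, per-SNP uniform
  transmission (Mendelian-consistent probands by construction), with an
  optional block-correlated haplotype mode (Gaussian copula) so clumping
  has LD to remove — the default is independent SNPs;
* liability = −√r²_prs·z_PRS + dn_effect·D + s·noise with s² chosen so
  total variance ≈ 1, where D is the proband's damaging DD de novo count;
  phenotype 1 when liability exceeds the cohort median (configurable
  quantile), giving near-balanced groups;
* Poisson de novo damaging variants in DD genes (rate 0.02/proband ⇒
  ~13 per 656 trios) and LoFi-only genes (0.08 ⇒ ~53), plus benign de
  novos (0.3) so prioritisation has non-trivial work; annotations are
  sampled from class proportions (frameshift 0.35, stop-gain 0.20,
  splice 0.15, missense 0.30) with CADD/MPC drawn inside or outside the
  damaging thresholds as appropriate;
* ultra-rare damaging inherited singletons at 1.5/parent in LoFi genes,
  each transmitted with probability ½ (matching the ~1000 transmitted
  LoFi singletons per cohort at study scale), plus non-ultra-rare
  damaging variants (0.3/parent) exercising the singleton filter;
* CNVs at 0.2/parent (log-uniform lengths 20 kb–1 Mb, del/dup equally),
  transmitted with probability ½, and de novo proband CNVs at 0.03;
* GWAS summary statistics for three traits: two (EA, intelligence) as
  noisy estimates of the true liability weights, one (schizophrenia) as
  permuted-null weights;
* genotype QC fields (DP, GQ, AD) sampled to pass the trio filters, with
  knobs to inject QC failures and Mendelian errors at configured rates.

Gene sets default to 300 LoFi genes with a 72-gene DD subset (the study's
3063/726 at one tenth, preserving the DD:LoFi ratio so singleton gene
assignment reproduces the DD share of inherited burden). Randomness uses
one master seed with fixed per-stage substreams (documented in the module
docstring), so cohorts are bit-reproducible.

What the generator does **not** emulate: realistic human LD structure,
chromosome-level annotation, imputation error, genotyping batch effects,
population stratification correlated with phenotype (PCs are pure noise),
assortative mating, or a graded (non-binary) phenotype. Passing tests
therefore demonstrate correctness of the pipeline's logic and calibration
of its statistics under the stated generative model, not robustness to
those real-data complications.

## Problem sizes in the test suite

Property tests use cohorts of 60–656 trios with 80–200 SNPs; directional
parameter-recovery runs use 4000–5000 trios with reduced SNP panels; the
null calibration of the 18-test battery uses 150 cohorts of 240 trios;
Monte-Carlo suites use 600–10,000 replicates as noted in each test. These
sizes were chosen so the full suite completes in about two minutes while
keeping Monte-Carlo error well below the asserted tolerances.

## Known limitations

* De novo calls are re-derived from trio genotypes; studies that import
  validated de novo calls from prior sequencing would bypass
  `classify_snv` for those variants.
* The alternative damaging-variant definitions used in sensitivity
  analyses of the source literature are not hard-coded; the damage rules
  are small pure functions and can be swapped.
* The Fisher conditional-MLE CI uses the central (tail-inverting)
  construction; other software may report the slightly different
  unconditional or mid-p intervals.
* `binomial_logistic`'s separation detector is heuristic (non-convergence
  or |β| > 15); pathological near-separation below that bound is reported
  as an ML fit.
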