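# Methods

This note records the models, defaults and design decisions behind
`rdvload`, and what the synthetic-data tests do and do not demonstrate
about real cohorts.

## The statistical model

### Carrier collapsing and Firth-penalized burden tests

Rare-variant association at a single site is hopeless at realistic
cohort sizes, so the unit of analysis is a *gene* or *gene-set*
collapsed to a binary exposure per participant: carrying at least one
qualifying RDV allele anywhere in the unit (dominant coding; a
homozygous carrier counts once, as does a carrier of several RDVs in one
gene when tallying carriers).  Case status is regressed on the carrier
indicator with covariates by maximizing the Firth-penalized
log-likelihood

    l*(β) = l(β) + τ·log det(XᵀW(β)X),   W = diag(π(1−π)),   τ = ½.

With τ = ½ the penalty is the Jeffreys-prior mode and removes the
O(1/n) bias of the MLE; its operationally important property here is
that estimates stay finite under complete separation (e.g., all unit
carriers are cases), the regime sparse carrier tables live in.  On a
2×2 table the estimator reduces to the classical half-cell-corrected
cross ratio, which the tests exploit as an exact oracle.  Setting τ = 0
recovers ordinary logistic regression and is cross-checked against
statsmodels.

Optimization is Newton iteration on the modified score
U*(β) = Xᵀ(y − π + 2τh(½ − π)) (h the hat diagonal), with step-halving
on the penalized objective, convergence at max |U*| < 1e−6, and a cap of
50 iterations.  Constrained fits (one coefficient fixed) reuse the same
iteration on the free coordinates with the penalty still computed from
the full design; they provide profile penalized likelihoods.

Inference defaults to the profile penalized likelihood: 95% limits are
the coefficient values where the profile drops by χ²₁(0.95)/2 (roots
bracketed by doubling steps and polished with Brent's method; a root not
bracketed within ±20 log-odds is reported as an open interval and
flagged), and the p-value is the penalized likelihood-ratio test of
β = 0.  Wald intervals from the inverse Fisher information are also
emitted (`p_method="wald"`), since published tables of this kind rarely
state which convention they used; the LRT is primary because it is the
default of the standard R implementation of this estimator.

Covariates: the synonymous background load (below), the first two
ancestry PCs recomputed on the gated participants, and optionally a
gender indicator (participants with missing gender are dropped only in
that mode).  Covariates that are constant in a given cohort (common for
the background load in small simulated cohorts, where any carried
variant already exceeds the ultra-rare cohort-frequency gate) are
dropped with a warning rather than fitted as collinear columns.
Catalog scans append Benjamini–Hochberg q-values over the testable
units and order rows by (p, unit id) for reproducibility.

### RDV classification

A QC-passed variant qualifies as an RDV when it is rare *and*
deleterious:

* **Rarity** — not above 2% MAF in both cohort arms simultaneously
  (≤ 2% in at least one arm keeps it), and ≤ 1% in each of two reference
  populations (ExAC non-TCGA NFE, gnomAD ASJ).  A reference frequency
  absent from the annotation is treated as 0 (unobserved ⇒ rare);
  `absent_ref_maf_is_zero=False` excludes such variants instead.  The
  sensitivity mode lowers the cohort gate to 1% and can only shrink the
  RDV set (asserted as a property test).  Cohort MAFs are computed on
  the QC-passed, kinship-pruned, gated participants — i.e., after sample
  QC — matching the pipeline's stage order.
* **Deleteriousness** — ClinVar P/LP, or a frameshift/stopgain variant
  lying 5′ of a ClinVar pathogenic (by default also likely-pathogenic,
  configurable) nonsense/frameshift record in the same gene.  "5′ of"
  is evaluated in transcript CDS coordinates, which absorb strand; for
  genes with several anchor records the most 3′ anchor defines the
  boundary.  A coding LOF variant lacking a CDS coordinate is skipped
  for this rule and logged.  No ClinVar review-star filtering is
  applied.  The rule is applied as stated regardless of any conflicting
  benign assertion on the variant itself.

### Synonymous background load

Sequencing platform and coverage differences between cohorts shift
overall variant yield; the correction covariate is the per-participant
count of distinct autosomal genes carrying ≥ 1 ultra-rare synonymous
variant (ExAC global ≤ 0.005%, full-cohort MAF ≤ 0.05%).  Note the
cohort gate is an *absolute frequency*: in cohorts much smaller than
~2000 participants a single carrier already exceeds it, so the covariate
degenerates to zero — expected, and handled by the constant-covariate
drop above.

### Variant and sample QC

Genotype-level masks: GQ ≥ 20, DP ≥ 10, alt-allele depth ≥ 4, and for
heterozygotes an alternate-allele fraction within [0.30, 0.70]
(inclusive at both ends; homozygotes exempt).  Site-level filters:
QUAL ≥ 50, QD ≥ 2, MQ ≥ 40, ReadPosRankSum > −3, MQRankSum > −10
(absent rank sums do not fail a site), and VQSR tranche < 99% — a site
fails when its FILTER names a tranche whose lower sensitivity bound is
≥ 99.0; PASS always passes.  Case-control screens: differential
missingness ≤ 0.05 between arms and completeness ≥ 88% in both arms,
evaluated *after* genotype masking.  Inclusive/strict boundaries follow
the symbols above literally and every threshold is configurable.
Samples with ≥ 15% missing genotypes are removed first, because the
missingness fractions downstream depend on the order.  The cascade is
idempotent and monotone in its thresholds (property-tested).
Multi-allelic records are expected to be decomposed upstream; the VCF
reader rejects them.

Kinship uses the KING-robust estimator
φ̂ = (N_Aa,Aa − 2N_AA,aa)/(N_Aa(i) + N_Aa(j)) over co-called sites of a
common-SNP panel (biallelic SNPs, MAF ≥ 5%, call rate ≥ 0.99, LD-pruned
at pairwise r² > 0.2 in 50-SNP windows, step 5 — standard defaults, all
configurable).  Pairs with φ̂ > 0.0884 (the conventional 2nd-degree
bound) are flagged; greedy pruning drops the member with higher
missingness, ties broken toward the lexicographically larger id (logged),
and the postcondition that no retained pair stays flagged is asserted on
every run.  The homogeneous-population KING variant is not implemented;
the robust form is the safe default when ancestry is mixed.

Ancestry control standardizes the panel by (g − 2p̂)/√(2p̂(1−p̂)) with
mean imputation of residual missingness, runs one SVD over study plus
labeled reference samples, and gates a rectangle on (PC1, PC2) — either
explicit bounds or reference-centroid ± 3 SD.  The original procedure
chose bounds by eye; the derived gate makes that reproducible.  PCs used
as burden covariates are recomputed on the gated participants only.

### Load groups and phenotype contrasts

RDV load within a gene-set counts *distinct carrier genes* (not
variants), grouped zero / one / multi (≥ 2).  Dose-response on case
status refits the burden model with one-vs-zero and multi-vs-zero
indicator exposures; monotonicity is reported, never enforced, and an
empty multi group is skipped with a log entry.  Phenotype contrasts
emit any-vs-zero, one-vs-zero and multi-vs-zero Mann–Whitney tests plus
the 3-group Kruskal–Wallis, since published figures of this kind mix
both styles.

Mann–Whitney uses midrank ties; p-values are exact by full enumeration
of rank assignments when both samples have ≤ 8 observations
(extremeness: |U − n₁n₂/2|), otherwise a tie-corrected normal
approximation *without* continuity correction — chosen so that the
two-group Kruskal–Wallis χ² p equals the two-sided normal
Mann–Whitney p exactly, a cross-check in the tests.  The normal
approximation differs from the exact p by up to ~0.05 at n = 8+8; use
the exact mode at small n.  All observations tied gives p = 1 by
convention.  Kruskal–Wallis applies the standard tie correction with a
χ²(k−1) reference and offers exact enumeration for tiny instances.

TMB = (missense + nonsense + frameshift + inframe) / 38 Mb; synonymous
and any other consequence classes are excluded by the definition, and
"inframe" covers both insertions and deletions.  Absolute immune-cell
fractions are the 22 relative fractions times the leukocyte fraction
(rows then sum to the leukocyte fraction — property-tested); immune
deconvolution itself is out of scope, its output table is an input.
Participants with hematological malignancies are excluded from immune
analyses by a case-label filter flag (default on).  The M1–survival
model is a Cox proportional-hazards fit (via lifelines) of survival on
the absolute M1 fraction, stratified by cancer type, with Wald p-values
and no multiple-testing correction by default (BH available in the scan
machinery).  lifelines handles tied event times with Efron's method;
simulated survival times are continuous, so this is indistinguishable
from Breslow here.  Strata without events are dropped with a log entry,
and a covariate without variation yields a flagged, undefined result.

## The synthetic cohort generator

`simulate_cohort` draws, from one integer seed (byte-identical outputs
per seed):

* **Genes and variants** — 60 genes by default in four disjoint
  "pathway" sets (12 CPD-like, 10 DDR-like, 15 SCD-like, 6 FA-like) plus
  17 null genes.  Each gene carries 3 deleterious candidates (ClinVar
  P/LP with probability 0.7, otherwise an unlabeled LOF placed 5′ of a
  pathogenic anchor), one 3′-of-anchor LOF that must *not* qualify, one
  benign and one VUS missense, and a share of ultra-rare synonymous
  sites; ~5% of candidates are made reference-common to exercise the
  rarity gates.  Rare frequencies are log-uniform on [0.01%, 0.5%] —
  the rare-variant regime — and a 3000-SNP common panel (MAF 5–50%)
  supports PCA and kinship; the panel size is chosen so that the
  KING φ̂ noise (SE ≈ 0.02) sits well below the 0.0884 threshold, as
  the much larger panels of real exomes do.
* **Planted effects** — per planted gene-set the case-arm allele
  frequencies at qualifying variants are scaled (root-finding on the
  HWE carrier probability) so the *population* carrier odds ratio equals
  exp(planted log-odds) exactly; the empirical carrier OR then converges
  to the target, which is verified at n = 20,000 within 3 MC standard
  errors.  Planted sets must be gene-disjoint for per-set odds to be
  exact (validated).  Defaults ln 1.5 / ln 1.5 / ln 1.4 / ln 2.0 sit in
  the odds-ratio range such burden studies report (≈1.2–2.5); they are
  study conditions for the tests, not claims about any real cohort.
* **Structure** — two ancestry strata (weights 0.8/0.2) shift
  common-SNP frequencies by N(0, 0.08) offsets; a labeled reference
  panel (80 per stratum) is emitted for gating.  Two duplicate, two
  first-degree (one shared gamete) and two second-degree (one shared
  grandparental gamete) pairs are planted among controls — the minimal
  Mendelian scheme that exercises the kinship thresholds.  Per-call
  GQ/DP/AD are drawn around realistic sequencing values with a 1%
  injected failure rate, and 8 sites receive failing site statistics or
  tranche labels, one per QC rule.
* **Phenotypes** — case onset ages N(62, 11) shifted by 0 / −3 / −6
  years per load group (clipped at 18, clip count logged); somatic
  consequence counts Poisson with per-group multipliers 1 / 1.5 / 2;
  22 immune fractions Dirichlet with the M1 concentration scaled
  1 / 1.5 / 2 per group; leukocyte fraction Beta(2, 3); survival
  exponential with log-hazard 3.0 per unit absolute M1 fraction and
  uniform censoring.  Phenotype effects key on the load group of one
  configured gene-set (default the CPD-like set).

`simulate_burden_replicates` is the reduced form of the same
retrospective carrier model — carrier indicators and covariates drawn
directly, without per-variant genotypes — used where thousands of
replicate units are needed (null calibration, CI coverage) and the
variant layer would add nothing but runtime.

**What the generator does not emulate:** linkage disequilibrium beyond
independence, sequencing reads and alignment error, callable-fraction
heterogeneity, realistic gene-length/constraint distributions,
population-specific rare-variant sharing, or correlated phenotype
batteries.  Passing tests therefore demonstrate the *statistical
machinery* (calibration, effect recovery, rule correctness), not
robustness to real-data artifacts such as batch effects between
sequencing centers — which is exactly what the synonymous-background
covariate exists to absorb in real cohorts, and which the simulation
cannot certify.

## Numerical choices and degenerate inputs

* Firth convergence: max |score| < 1e−6, ≤ 50 Newton iterations with up
  to 25 halvings; rank-deficient designs raise with the collinear
  columns named; a response without both classes raises.
* Profile roots: bracket by doubling from ±0.25, Brent to 1e−6; open
  intervals flagged, never silently truncated.
* Zero carriers in a unit: reported with OR = NaN and skipped in scans
  rather than raised; zero-variant gene-sets in the simulator warn and
  skip their planted effect.
* KING with no co-called heterozygous sites: pair reported unevaluable
  (NaN), never 0.
* PCA: monomorphic sites dropped with a log entry; k above the matrix
  rank raises; duplicated participants coincide in score space to 1e−8.
* Rank tests: all-tied inputs give p = 1; exact enumeration thresholds
  (n ≤ 8 per arm for U, opt-in for H) keep worst cases ≤ ~12,870
  combinations.
* Problem sizes in the acceptance computations — 1000 null units at
  n = 2000+2000, 500 coverage replicates at n = 5000+5000, and a
  full-pipeline run at n = 1200+1200 — are the package's chosen
  simulation scales for stable Monte-Carlo checks on a single CPU.

## Known limitations

* The 5′-LOF rule trusts single-transcript CDS coordinates from the
  annotation input; transcript selection and multi-transcript genes are
  out of scope.
* The gene-level scan reports BH q-values, but rare-carrier counts at
  realistic gene frequencies leave it underpowered — mirroring why
  collapsing to gene-sets is the primary analysis.
* The validation-cohort-specific QC variant (allele-balance window
  0.3–0.8, site missingness < 12%) is reachable through the threshold
  config rather than hard-coded as a second mode.
* Cancer-type groupings (pan-gastrointestinal etc.) are configurable
  case-label filters; no grouping taxonomy ships with the package.
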