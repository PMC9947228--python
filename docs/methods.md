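# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `biclink`. It is written for someone who wants to judge
what a passing test suite does — and does not — establish.

## Analysis model

### Quality control

Filters run in a fixed order so per-SNP statistics are always computed on
the retained samples: sample call rate (< 0.95 excluded) → relatedness →
SNP call rate (< 0.95) → Hardy–Weinberg exact test (p ≤ 1e−6) → MAF
(< 0.01). Missing genotypes are ignored in every statistic; nothing is
imputed at this stage.

The HWE test is the exact conditional test in the PLINK tradition:
conditioning on the observed allele counts, the probability of every
attainable heterozygote count `h` is
`P(h) ∝ n! 2^h / (n_AA! h! n_aa!)`, and the p-value sums `P(h')` over all
`h'` whose probability does not exceed the observed one (probability
ordering). Computation is in log-gamma space; the test is exact but
discrete, hence conservative — its null p-values are *not* Uniform(0,1),
and the generator's HWE conformance is therefore validated against the
test's own null distribution (two-sample KS vs freshly simulated binomial
genotypes) rather than against the uniform.

Relatedness uses the method-of-moments IBD decomposition from
identity-by-state counts: with per-SNP allele frequency `p`, the expected
IBS-class probabilities given IBD state (e.g. `P(IBS=0|IBD=0) = 2p²q²`)
are summed over SNPs, the three IBD proportions are solved sequentially
from observed IBS counts, clamped to [0,1] and renormalized, and
`π̂ = P(IBD=1)/2 + P(IBD=2)`. A pair with π̂ > 0.2 loses its
lower-call-rate member (ties: the later identifier).

**Desk-scale caveat.** π̂ has sampling s.d. ≈ `O(1/√M_eff)` over effective
independent SNPs. At genome scale (≈5×10⁵ SNPs) the 0.2 threshold is
sharp; at the 2,000-SNP scale of the synthetic validation cohorts the
estimator's noise flags a few percent of truly unrelated pairs, which
would cascade into mass removal. Since the generator plants no related
pairs and no ancestry structure, the validation configurations disable
the relatedness filter (`pi_hat_max=1.0`); the estimator itself is
validated at 10,000–20,000 independent SNPs (duplicates ≥ 0.9,
parent–child ≈ 0.5, unrelated ≤ 0.05, a true-π̂-0.25 pair exceeds 0.2).

### Association scan and preselection

Each (SNP, lipid) pair is fit by OLS on complete cases,
`lipid ~ 1 + dosage + covariates`, with the dosage coefficient's
two-sided p from the t distribution at `n − p_model` degrees of freedom.
For fully observed dosage columns the scan is reformulated via
Frisch–Waugh–Lovell — residualize dosages and lipids against the
covariate design once (QR), then sweep all pairs with three matrix
products — which is algebraically identical to the per-pair fit (the
tests verify agreement to 1e−10) and reduces a 2,000 × 120 scan to well
under a second. SNPs with missing dosages fall back to per-pair
complete-case statsmodels fits.

Lipids are regressed on their raw concentration scale by default (a
log-transform switch exists). Raw-scale lognormal phenotypes make the
t-test only asymptotically calibrated — a single extreme concentration
can visibly distort the null p distribution at n ≈ 300 — so the
calibration tests use Gaussian phenotypes to isolate implementation
correctness from this (real) modeling caveat.

Preselection keeps every SNP with any association p < 5e−4; if more than
20,000 qualify, the smallest per-SNP minimum p wins (ties by identifier).
The study-wide threshold is Bonferroni over phenotypes,
`5e−8 / 437 = 1.1e−10` to two significant figures.

Genetic PCs come from the SVD of the standardized, mean-imputed dosage
matrix, by default after LD-thinning at r² = 0.5. **Desk-scale caveat:**
on a 2,000-SNP cohort whose only structure is the planted subgroups, the
top PCs *are* the subgroup memberships (|r| up to ≈0.75), and adjusting
for them removes the signal under study. The validation configurations
therefore set `n_pcs=0`; with real genotype data, where ancestry
dominates the spectrum, the default of 10 PCs applies.

### Fuzzy NMF biclustering

Each domain's participants-by-features matrix is made non-negative
(genotypes: per-SNP mean imputation on the 0–2 dosage scale; lipids:
per-lipid min–max to [0,1], constant columns → 0) and factorized at every
rank in a grid (default 2–20) by Frobenius multiplicative updates from an
NNDSVDa initialization (non-negative double SVD with zero entries filled
by the matrix mean — exact zeros are absorbing under multiplicative
updates and trap poor local minima; components the SVD leaves empty get a
random-uniform fallback). Updates use an epsilon floor of 1e−12;
iteration stops at relative error change < 1e−6 or 500 iterations; the
recorded error history is non-increasing by the standard MU guarantee.

Factor `k` becomes a bicluster containing every participant with
`W[i,k] ≥ f · max_i' W[i',k]` (and `W[i,k] > 0`), features analogously
from `H`; the default membership fraction `f` is 0.5. The threshold is
relative to the factor's strongest loading, not to the entity's own
maximum across factors: the row-relative variant admits every
low-loading background participant (whose row maximum is itself tiny)
and empirically caps planted-subgroup recovery at Jaccard ≈ 0.5, while
the factor-relative rule reaches 0.75–0.97 on the same data. Membership
remains fuzzy — an entity can clear the threshold in several factors —
and shrinks monotonically as `f` rises.

Biclusters from all ranks are pooled and deduplicated: when two have
participant-set *and* feature-set Jaccard ≥ 0.9 (configurable), the one
with the larger mean normalized loading survives. Ids encode domain,
rank and factor (`G12.1`, `P20.18`).

### Relations, distinctness, clinical comparison

Every genotype × lipidome bicluster pair is tested with the
hypergeometric upper tail `P(X ≥ k)` (survival function evaluated in log
space; `k = 0` gives p = 1), where N is the number of participants
present in both analysis matrices. Pairs with raw p < 0.01 are
significant — uncorrected by choice, mirroring standard practice for
this analysis; a Benjamini–Hochberg switch exists but is off by default
since 10⁴ dependent tests at 0.01 uncorrected is knowingly
anticonservative (the negative-control test budgets a small multiple of
α for this). Relation ids are assigned by ascending p.

A relation is *distinct* when more than half of its genotype bicluster's
SNPs and more than half of its participants appear in no other
significant relation's genotype bicluster. Uniqueness is computed
against the genotype biclusters of all other significant relations
jointly (not sequentially), and participant uniqueness uses the genotype
bicluster's membership, not the shared-participant set; both choices are
deliberate where the convention is ambiguous. Note the screen inherently
penalizes multifinality — a genotype bicluster in two relations has zero
uniqueness by definition — so a rank grid that yields several redundant
biclusters per true subgroup produces many significant but few distinct
relations; the focused validation run uses a single rank near the
planted subgroup count plus aggressive dedup (0.5) to demonstrate the
distinct screen firing at truth Jaccard ≈ 0.97.

Clinical comparison is Welch's unequal-variance two-sample t-test,
members of the relation's genotype bicluster vs all other participants,
two-sided, per numeric clinical variable; zero-variance groups yield NaN
for that variable only.

### LD tools

r² is the squared Pearson correlation of dosage vectors over pairwise
complete entries. Pruning slides a 50-SNP window stepping by 5
(geometry configurable; only the r² threshold itself is standard): while
any within-window, within-chromosome pair exceeds r² = 0.5, the
smaller-MAF member is dropped (tie: later position) — keeping the
larger-MAF SNP is the standard pruning convention. Clumping walks SNPs
by ascending per-SNP minimum p; each unassigned best SNP founds a clump
and absorbs unassigned SNPs within 250 kb on the same chromosome with
r² ≥ 0.1. Per-relation pruning treats each bicluster's SNP set
independently.

### Overrepresentation analysis

Bicluster SNPs (pruned when available) map to gene symbols via a
user-supplied table (VEP-style TSV) or a positional fallback that tiles
chromosomes with synthetic gene intervals. Each gene set within size
bounds 10–500 (conventional ORA practice) is tested with the
hypergeometric upper tail — identical to a one-sided Fisher exact test,
which the suite verifies on 500 random configurations — and BH-adjusted
within each relation × collection; q < 0.05 is reported. The universe
defaults to all genes mappable from the preselected SNP set, conditioning
on the selection step (switchable to the whole map).

## Synthetic cohort generator

The generator defines the study conditions for every validation claim.
Defaults: 1,426 participants (age 38 ± 5 y, BMI ≈ 26 ± 5 kg/m²,
53 % female), a 437-species lipid panel, SNP MAFs uniform on
[0.05, 0.5].

* **Genotypes** are sums of two independent haplotypes, so HWE holds by
  construction. Within an LD block (20 SNPs) each haplotype allele copies
  its left neighbour with probability 0.9, giving realistic dosage-r²
  decay; blocks are independent. SNPs are laid out on chromosomes 1–22
  with 2–10 kb spacing.
* **Subgroups** (default 3) draw members uniformly (overlap arises
  naturally), plus disjoint private SNP and lipid sets. Members'
  haplotype alleles at subgroup SNPs are redrawn with probability
  `min(MAF + 0.3, 0.98)` — at zero effect this is the null law, so
  planted structure vanishes identically. The 0.3 boost and the +1.0
  log-unit lipid shift are strong, method-validation-grade effects: they
  test the machinery, not its detection limit.
* **Lipids** are exponentiated Gaussians: per-lipid baseline
  `N(1, 0.5)`, a per-participant class factor (four lipid classes,
  loading 0.3) inducing within-class correlation, residual s.d. 0.5,
  and the additive subgroup shift on the log scale before
  exponentiation.
* **Covariates and clinical chemistry** are drawn independently of both
  domains at adult-population scales (total cholesterol 5.0 ± 0.9 mmol/l,
  systolic BP 120 ± 14 mmHg, …); an optional age→lipid slope (default 0)
  provides a confounding hook.
* `couple_domains=False` draws the lipid-effect membership sets
  independently of the genotype sets — the negative control for relation
  detection.
* All randomness flows from one seed through `SeedSequence` substreams;
  identical configurations give bit-identical matrices and files.

What the generator does *not* emulate: ancestry/population structure,
cryptic relatedness, genotyping batch effects, mass-spectrometric
measurement error structure, LD between blocks, and any real
genotype–lipid biology. Passing the planted-recovery tests shows the
pipeline recovers subgroups of the planted geometry at these effect
sizes; it does not certify performance on real cohort data, where
effects are weaker and the nuisance structure above is present.

## Validation problem sizes

The planted-recovery and negative-control checks run the full pipeline
on 400-participant, 2,000-SNP, 120-lipid cohorts with three overlapping
subgroups over 20 (positive) and 10 (negative) seeds, rank grid 2–8 —
sizes chosen so the whole suite and the acceptance script each finish in
minutes on one CPU while every stage still operates in its intended
regime. The acceptance script uses 10 positive and 5 negative seeds.

## Known limitations

* Raw-scale lipid regression is exact only under Gaussian errors;
  heavy-tailed concentrations at modest n distort tail p-values (use the
  log switch for real data).
* Hypergeometric relation p-values treat biclusters as fixed sets; they
  are selected by the same data, so the 0.01 threshold is a ranking
  device, not a calibrated error rate (the negative control measures
  ~1.5–2 % of candidates significant at α = 0.01).
* The multilayer consensus used here is pooling-plus-deduplication;
  no cross-rank consensus factorization is attempted.
* ORA results depend on the supplied SNP→gene map and collections;
  nothing is downloaded.
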