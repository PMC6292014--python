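# Methods

## Scope and data model

The package implements an integrative case-control strategy over three data
layers: per-sample variant calls (VCF 4.x), a differential-expression (DE)
table (Cuffdiff-style `.diff` or a generic TSV), and pathway gene sets (GMT),
tied together by a phenotype sample sheet that assigns every subject a
phenotype (`case`, `control`, `unknown`) and a role (`discovery`,
`verification`, `replication`). Coordinates are 1-based and fully closed
(VCF convention); BED exports from the seed scanner are converted to 0-based
half-open intervals. Gene symbols are uppercased on load. Phased genotype
separators (`|`) are treated like unphased ones: the method is
genotype-based, not phase-based. Multi-allelic sites are split into one
record per alternate allele with per-alt dosages, which conserves the total
number of alt-allele observations across derived records.

## Differential expression and enrichment

The DE filter retains genes with q < q_max strictly (default 0.05) whose
status is `OK`; `LOWDATA`, `HIDATA` and `FAIL` rows are excluded by default
(Cuffdiff's `NOTEST` is mapped to `FAIL` on load). Over-representation of
the retained genes in a pathway uses the right-tailed hypergeometric tail
P(X ≥ overlap) with `pathway_size` draws from the universe containing
`query_size` successes. The universe defaults to the genes that were
successfully tested (status `OK`) in the DE table, not the genome: the
background of a curated-knowledge-base enrichment is generally unpublished,
and the tested-gene universe is the reproducible choice; it is configurable.
Pathway significance is judged on the raw p at α = 0.05 (−log10 p ≥ 1.301),
with no multiple-testing correction across pathways; BH-adjusted pathway
q-values are reported alongside for transparency but do not drive decisions.

## The funnel

Candidate variants must be called in every discovery case (intersection on
locus identity; per-case genotypes are retained and analysed downstream, so
two cases may carry different genotypes of the same candidate). Genotype
quality stratification requires every non-missing call to satisfy GQ ≥ 20
and DP ≥ 10 by default; calls lacking GQ/DP pass unless configured otherwise.
Integration emits one candidate per (variant, gene) pair whose gene passed
the DE filter and belongs to at least one significant pathway. The `rare`
flag is MAF < 0.01 when a population-MAF annotation is present and undefined
otherwise — absence of an annotation is never silently treated as "common".

Funnel bookkeeping: `total` ≥ `intersection` ≥ `dbsnp_known` (rsID present),
and `intersection` ≥ `in_de_genes` ≥ {`rare`, `in_pathways`}. `rare` and
`in_pathways` are sibling refinements of `in_de_genes` (a pathway candidate
need not be rare), so counts are monotone non-increasing along each
parent-child path rather than along the printed order. `dbsnp_known`,
`in_de_genes` and `rare` are counted on the intersection before quality
stratification; `in_pathways` counts the integrated candidates, which are
quality-passing.

## Verification

Verification cohorts are pedigree cases plus population controls. A
candidate found with the required genotype (`hom_alt` by default, `carrier`
configurable) in at least one member of at least one pedigree and in no
control is a *possible putative mutation*; found in pedigree cases and in at
least one control, a *potential putative effect modifier*; otherwise
*unsupported*. Subjects with `unknown` phenotype (population panels without
medical records) are counted on the control side of this rule, which is how
such panels are used in practice as the no-disease comparator.

## Chi-square battery and classification

All contingency tests are Pearson chi-square with upper-tail p from the χ²
distribution. Yates' continuity correction applies to 2×2 tables by default
(configurable `on`/`off`), with the correction term clamped at |O − E|:
χ² = Σ (max(|O−E|−0.5, 0))²/E, so perfectly proportional tables give exactly
zero — matching the mainstream statistical environments. Expected cells
below 5 raise a warning flag, not an automatic exact test. The
goodness-of-fit variant is χ² = Σ (Oᵢ − Npᵢ)²/(Npᵢ) with df = k − 1 and an
explicit expected-probability argument. Missing genotypes are excluded
pairwise-complete from every table; all-zero rows are dropped, which is what
produces irregular degrees of freedom on sparse joint-genotype tables.

Classification of a candidate against the replication cohort:

* **Direct association** is decided by the genotype-level omnibus test
  (observed genotype classes × disease state). p < α ⇒ *putative mutation*.
  Carrier-level and per-genotype-stratum 2×2 tests are computed and reported
  alongside to localise which genotype drives the association, but they do
  not drive the verdict: a battery of correlated 2×2 tests would inflate the
  family-wise false-positive rate well above α, and the genotype-level test
  is what distinguishes an allele-frequency artefact from a genotype effect.
  Direct effects take precedence over modifier status.
* Otherwise each partner variant is screened: the variant is a *putative
  effect modifier* when, for some partner, both the genotype × genotype
  dependence test and the joint-genotype-combination × disease test have
  p < α; the recorded partner is the one with the smallest joint-test p.
  Note that a true disease variant is often the winning partner — its joint
  table with anything correlated to it in the ascertained sample is
  overwhelmingly significant — so the reported partner is "the strongest
  interactor", not necessarily the planted pair member; restricting
  `partner_set` recovers pair-internal naming.
* Neither ⇒ *unclassified*.

Verdicts use raw p at α = 0.05; BH-adjusted direct p-values across the
candidate family are reported alongside but are not decisive.

## Linkage disequilibrium

Haplotype frequencies for a variant pair are estimated from unphased dosage
vectors by EM. Only the double-heterozygote cell is phase-ambiguous; the
E-step splits it between the coupling (AB/ab) and repulsion (Ab/aB)
resolutions in proportion to f_AB·f_ab versus f_Ab·f_aB. Initialisation is
the linkage-equilibrium point (products of observed allele frequencies) —
deterministic and symmetric, so a degenerate all-double-het sample stays at
the symmetric point rather than breaking ties by chance. Convergence is
max |Δf| < 1e-8 or 1000 iterations; the log-likelihood trace is recorded and
is non-decreasing. D = f(AB)f(ab) − f(Ab)f(aB); D_max = min(p_A q_b, p_a q_B)
for D > 0 and min(p_A q_B, p_a q_b) otherwise; D′ = |D|/D_max;
r² = D²/(p_A p_a q_B q_b). For a monomorphic locus D′ and r² are reported as
undefined (None/NA), not zero, so degenerate cohorts stay visible. Note
that D′ is a folded statistic: at true equilibrium its estimate is
non-negatively biased in finite samples (mean ≈ 0.1 at n = 300 for the
default frequencies), which the tests account for by checking signed D at
the null.

## microRNA seed sites

For a mature miRNA read 5′→3′, site types on the UTR are: `8mer` = reverse
complement of miRNA positions 2–8 followed by an A at target position 1 (the
3′ end of the site); `7mer-m8` = reverse complement of positions 2–8 alone;
`7mer-1A` = reverse complement of positions 2–7 followed by an A. The
position-1 A is required as a literal A in the UTR (the TargetScan
convention), not as complementarity to miRNA position 1. Overlapping sites
at different offsets are all reported; at a single locus only the strongest
type is reported (8mer > 7mer-m8 > 7mer-1A, where an 8mer at offset i shadows
the 7mer-m8 at i and the 7mer-1A at i+1). U/T are normalised internally and
the reported site sequence echoes the input alphabet.

## Synthetic cohorts and what they do (and do not) show

The generator is a pure function of its configuration, seed included; the
same seed yields byte-identical files.

* **Genotypes.** Independent loci under Hardy-Weinberg at their allele
  frequencies; the designated LD pair is drawn as two-locus haplotypes
  constructed to a target D′ (default 1.0, with frequencies 0.30/0.20 so the
  pair is coupled but not a literal copy, r² ≈ 0.58).
* **Penetrance.** Disease probability is logistic: logit(0.05) baseline,
  + log(8) for the required mutation genotype (hom-alt by default), + log(8)
  when both modifier-pair members are carried. Because an interaction term
  alone *does* induce marginal risk for each modifier (carrying A raises risk
  through the chance of also carrying B), per-modifier offsets are solved
  numerically (two equations, `scipy.optimize.fsolve`, residual < 1e-10) so
  that each modifier's marginal carrier-level — hence genotype-level —
  association with disease is exactly null in the population. This is what
  "pure effect modifier" means statistically, and it is what makes the
  modifier-versus-mutation distinction testable at all.
* **Ascertainment.** Replication cohorts (default 500 + 500) are collected
  by rejection sampling until the requested case and control counts are
  reached, mirroring case-control designs.
* **Discovery cohort.** 6 cases / 4 controls. Planted candidate variants
  are forced to be carried by every discovery case (an all-case intersection
  candidate is, by definition, carried by all cases); the mutation is made
  homozygous in cases. One null variant is emitted with failing genotype
  quality in the cases to exercise the quality filter. Per-sample VCFs
  contain only the loci each sample actually carries, mimicking a caller.
* **Verification.** Three pedigrees (3/5/5 cases) plus 9 unknown-phenotype
  population subjects and 1 control. The mutation is planted in two members
  of one pedigree and kept out of all controls; each modifier is guaranteed
  at least one pedigree carrier and one control carrier.
* **DE table.** Per-gene log-normal FPKMs (gene means 2^N(4,1)), planted
  genes shifted by log2(4) in cases, per-sample noise sd 0.3 on the log2
  scale, 6 vs 4 samples. Significance is a pooled-variance two-sample t-test
  on log2(FPKM+1) (the noise model is homoscedastic, so the pooled test is
  the correct one) with BH q-values across genes. The dispersion default was
  set by a power calculation so that a four-fold planted change reliably
  dominates the q < 0.05 set at these sample sizes, which is the regime the
  strong DE hits of such studies occupy. Five genes are emitted as LOWDATA.
* **Pathways.** 8 sets of 15 genes; the hub gene sits in 3 sets enriched for
  planted DE genes (which also cover every variant-bearing planted gene);
  the rest draw from non-DE genes.
* **Truth manifest.** Roles per variant, planted and realized DE genes, the
  hub, realized significant sets, and funnel counts recomputed directly from
  the generated matrices (an independent recount the pipeline must match).
  Expected verdicts are stated only for the planted-effect variants: a null
  variant's verdict is a random variable with ≈ α probability of crossing
  the threshold at any given seed, so null behaviour is validated as a rate
  across seeds, not per seed.

What passing tests on these cohorts show: correct bookkeeping of the funnel,
correct operating characteristics of the tests (type I ≈ α, high power at the
planted effect sizes), and exact recovery of planted structure. What they do
not show: robustness to population stratification, genotyping error,
LD between candidates and unmodelled causal loci, non-log-normal expression
noise, or annotation errors — none of which the generator emulates.

## Operating characteristics (computed by the test suite)

Over 200 seeded replication cohorts at the default settings: the planted
mutation is recovered as a putative mutation in ≥ 95% of seeds (observed
100%), each modifier-pair member as a putative effect modifier in about
1 − α of seeds (the direct test fires at its nominal rate and then takes
precedence), and variants with no planted effect are labelled putative
mutations at a rate statistically compatible with α = 0.05. These rates are
recomputed, not quoted, by `tests/test_acceptance.py` and
`scripts/acceptance.py`.

## Numerical and design choices

* Chi-square correction clamped at |O − E| (proportional tables ⇒ χ² = 0).
* EM defaults tol = 1e-8, max_iter = 1000, equilibrium initialisation.
* BH adjustment is the standard step-up, monotone, capped at 1.
* Enrichment ties are broken by pathway name for deterministic ordering;
  hub ranking orders by (membership count desc, min pathway p asc, gene).
* Reports are fixed-format (`%.6g` floats, sorted JSON keys, no timestamps):
  identical inputs give byte-identical bytes.
* `hub_min` defaults to 2 ("several pathways" is not a sharp number; the
  exemplar hub of such studies sits in 3); configurable.
* Quality thresholds (GQ 20 / DP 10) are ordinary short-read defaults; the
  upstream studies name no thresholds, so they are configuration, and the
  provenance block records the values used.
* The dbSNP-known funnel stage uses rsID presence in the ID column, not a
  live lookup.
* Intersection keys on locus identity (chrom, pos, ref, alt), not genotype:
  genotype heterogeneity across cases is analysed downstream by the
  stratified association battery, not used to discard candidates.

## Known limitations

* The classification engine is a battery of marginal and two-locus
  chi-square tests, not a joint regression model; three-way interactions are
  represented as joint-genotype-category × disease tables.
* EM haplotype estimation is for variant pairs only; no multi-locus phasing.
* The enrichment universe policy matters and real knowledge-base backgrounds
  are unpublished; only threshold-level behaviour of enrichment is
  comparable across tools.
* Verification is presence/absence per cohort, not pedigree-aware
  segregation analysis.
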