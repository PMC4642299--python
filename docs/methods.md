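# Methods

`famseq` implements a pedigree-aware prioritization chain for rare, putatively
causal coding variants in small cohorts of multiplex families — the setting of
familial Hirschsprung disease (HSCR) exome studies, where each family
contributes two affected relatives of varying kinship and no single known gene
explains the cohort. This note documents the models, the statistics, the
synthetic-data generator, and the numerical and design choices.

## The analysis chain

1. **Quality control** (`variant_qc`). Site-level hard filters re-apply the
   GATK-style labels used upstream of the pipeline, with strict inequalities
   exactly as the labels are written: SNVs fail on `QD < 2.0`, `MQ < 40.0`,
   `FS > 60.0`, `HaplotypeScore > 13.0`, `MQRankSum < −12.5`,
   `ReadPosRankSum < −8.0`; indels on `QD < 2.0`, `ReadPosRankSum < −20.0`,
   `InbreedingCoeff < −0.8`, `FS > 200.0`. A missing metric never triggers its
   clause (label semantics: an absent annotation cannot match a label).
   Genotype-level acceptance: a heterozygote is kept only when supported by
   more than 4 reads with an alt-allele ratio above 0.25; a homozygote when
   supported by more than 4 reads with a supporting-allele ratio above 0.95.
   All bounds are strict. Whether "supported by > 4 reads" means total or
   alt-supporting reads is ambiguous for heterozygotes; both are implemented
   (`het_depth_mode`), defaulting to total depth because the phrasing parallels
   the homozygote rule, which necessarily concerns total depth. Variant-set
   evaluation reports size, known-site (dbSNP-like) coverage, and Ti/Tv over
   SNVs.

2. **Rare-damaging filtering** (`rare_damaging`). Exonic restriction (from the
   annotation input), rarity (MAF < 0.01 in *every* frequency resource, with
   absence counting as rare), and a damaging consensus: loss-of-function is
   damaging outright, synonymous never, missense when at least 3 of the 5
   non-unknown predictor calls (Polyphen2, SIFT, MutationTaster, PhyloP,
   likelihood ratio) vote damaging. KGGSeq-style fitted logistic combinations of
   these predictors depend on coefficients that are not portable; the
   ≥3-of-5 vote (configurable `min_votes`) is the documented
   stand-in. The three per-variant predicates commute; the one cohort-level
   predicate runs last: an identical variant key carried (by any member,
   affected or not) in ≥ 2 of the families is removed as a likely platform
   artifact, since independent recurrence of an identical rare damaging allele
   across unrelated families is improbable.

3. **Kinship and IBD** (`pedigree_kinship`). Pedigree kinship φ by the
   standard recursion (founders unrelated, non-inbred); relationship degree is
   `round(−log2(2φ))`, making "fourth-degree" φ = 1/32. Realized sharing is
   estimated from common markers by the classic method-of-moments IBD-state
   estimator: observed IBS-state counts against allele-frequency expectations,
   solved sequentially for Z0, Z1, Z2, clipped to [0, 1] and renormalized;
   π̂ = Z1/2 + Z2. Marker selection greedily prunes markers with sample
   MAF ≤ 0.01 or squared genotype correlation > 0.2 with a retained marker in
   a trailing window. Two finite-sample effects matter at this cohort size and
   are handled explicitly:
   - allele frequencies estimated from the ~20 cohort founders make the
     plug-in expectations visibly biased; when the number of frequency-source
     chromosomes is supplied, frequency powers are replaced by their unbiased
     falling-factorial estimates (the small-sample correction used by standard
     GWAS toolkits);
   - r² computed over related samples reflects family sharing, and pruning on
     it selectively discards markers informative about that sharing, biasing
     π̂ toward intermediate values. The pruning window therefore defaults to
     10, and `select_ibd_markers(ld_cols=...)` can restrict the correlation to
     unrelated founders.
   Pedigree verification compares π̂ with 2φ for every within-family pair and
   flags deviations beyond a tolerance of 0.15 — a deliberate default that cleanly separates adjacent relationship
   degrees down to the third.

4. **Cosegregation** (`cosegregation`). Within each family, the shared set is
   the variants carried by every affected; strict mode drops sites where an
   affected's genotype is missing, lenient mode treats missing as unknown
   (shared iff every *genotyped* affected carries and at least one does).
   Model fits follow one rule throughout: **missing genotypes never count as
   violations** — an unsequenced parent or a QC-dropped call cannot disqualify
   a candidate. Dominant (full penetrance): every genotyped affected carries,
   no genotyped unaffected does; a relaxed mode tolerates up to `m` unaffected
   carriers (default 0), reported separately, because incomplete penetrance is
   the norm for HSCR genes. Recessive: affecteds hom-alt, genotyped parents
   het, no unaffected hom-alt; a parent genotyped hom-ref under a hom-alt
   child is a Mendelian inconsistency. Compound heterozygotes: pairs of
   distinct same-gene variants with every genotyped affected het at both;
   phase is resolved *trans* when one parent carries v1-but-not-v2 and the
   other the converse, and the pair is rejected when any parent of an affected
   carries both (cis-ambiguous). X-linked: hemizygous affected males, carrier
   het mothers, no unaffected male carriers. Joint (oligogenic) cosegregation
   formalizes the "combined cosegregation" narrative: for each affected,
   connected groups of carried candidate genes with ≥ k qualifying variants
   (k = 2 default); two genes are connected when they share a direct
   interaction edge or both lie within one edge of (or are) a seed gene. The
   family is explained when every affected has at least one combination —
   identical across affecteds or patient-specific. Genotyped unaffecteds
   carrying a full combination are flagged, not excluded — flagging preserves
   information that outright exclusion would discard. The
   missing-is-unknown rule extends here: an affected's missing genotype counts
   as carried only when every other genotyped affected carries the variant.

5. **Recurrence statistics** (`recurrence_stats`). A gene is recurrent when
   shared variants appear in ≥ 2 families. External linkage/association tools of the
   pVAAST and raremetal/SKAT kind are out of scope; the
   statistics below are fully specified stand-ins with the same inputs and
   outputs:
   - *Per-family sharing probability.* For a rare allele present in exactly
     one founder copy, p_f = P(all affected carry | ≥ 1 affected carries),
     with the founder origin uniform over founder copies; exact by depth-first
     enumeration of carrier configurations (Monte-Carlo gene dropping beyond
     a configurable pedigree size). Sib pair: 1/3. When an affected is itself
     a founder the origin is conditioned to be that founder and the result is
     flagged degenerate (affected parent-offspring pair: 1/2). The
     single-founder-copy conditioning is the rare-variant assumption
     (MAF < 0.01); multi-founder introgression is ignored.
   - *Cross-family combination.* p = P(X ≥ observed sharing families) for X
     Poisson-binomial over the carrier families' p_f, computed exactly by
     convolution. Testing every gene carried by ≥ 1 affected keeps the
     statistic super-uniform under the null; conditioning the tested set on
     the sharing count itself would not.
   - *Sharing LOD.* Σ over sharing families of log10(1/p_f) — positive
     exactly when p < 1.
   - *Burden.* One-sided exact hypergeometric tail on the 2×2 carrier table
     (case founders vs background genomes), mid-p by default to reduce
     conservativeness at founder-scale counts; a flag restores the standard
     Fisher tail.
   - *Bonferroni.* adjusted p = min(1, p·m), significant iff p·m < α.

6. **Network prioritization** (`network_prioritize`). Candidates link to seed
   (known-disease) genes by shortest path ≤ 1 (configurable) over a
   user-supplied edge list; no network is ever fetched. The shipped default
   seed list contains the 25 HSCR candidate genes enumerated in the
   introductory literature and is user-replaceable. Per family, explanations
   are ranked recurrent gene > monogenic full cosegregation > compound het >
   joint combination — a convention reflecting decreasing cross-family
   support — with lexicographic tie-breaks, so reports are deterministic.

## The synthetic-data generator

`synthetic_data` emulates the study design so every stage is testable without
downloads: 8 two-patient families (48 sequenced individuals, 16 affected)
whose affected pairs span siblings (5 families), parent-offspring (2, one with
the affected parent a sequenced founder and one whose top generation is
unsequenced), and first cousins once removed (fourth-degree, φ = 1/32).

- **Variants.** Genes carry Poisson-distributed variant counts; rare alt
  alleles draw from a log-uniform AF spectrum on [1e-5, 5e-3] with a 5%
  common contaminant fraction (AF 0.05–0.30) to exercise the rarity filter.
  SNVs are transition-biased (0.76, giving Ti/Tv ≈ 3.2); 10% of sites are
  1-bp indels. Consequences: 8% LOF, 62% missense, 25% synonymous, 5% other.
  35% of background missense variants are latently damaging; predictors call
  "damaging" with probability 0.90 on those and 0.15 otherwise, 5% unknown.
  With the default 17,000 genes × 20 expected variants, these rates leave
  each patient ~130–210 rare damaging variants after the cascade (the
  regime this design targets); the panel scales down via `SimulationConfig.scaled`.
- **Transmission.** Founder haplotypes (two per founder) drop through each
  pedigree as unrecombined gene blocks, so cis/trans is well defined within
  genes; genes are mutually independent, and the separate common-marker panel
  (default 5,000 markers, MAF 0.05–0.50) is unlinked. On disk the markers are
  written into the cohort VCF as ordinary intergenic SNV records with
  read-backed calls, so the kinship stage can extract them back out the way
  it would from real data.
- **Reads and calls.** Per-genotype depth is negative-binomial with mean 35
  (dispersion size 8 — depth variation around the target mean; systematic
  capture dropout is deliberately not modelled); alt reads are binomial with
  per-read error 0.005. Calls are thresholded on the alt ratio (het > 0.2,
  hom-alt > 0.8, zero depth missing) *before* QC, so the QC stage sees
  realistic borderline calls.
- **Planted architectures.** Dominant alleles are placed on an
  affected-to-affected ancestor chain, extended upward through unsequenced
  ancestors (a sequenced unaffected forced carrier raises an error naming the
  family, since full penetrance would be unsatisfiable); recessive and
  compound-het/digenic architectures require full-sib affected pairs with
  both parents present. Planted variants are novel in every frequency
  resource, and all five predictors call them damaging. A truth table records
  the planted keys, model, and expected carriers.
- **Resources.** Three frequency databases carry each variant with
  probability 0.98 (common) or 0.50 (rare) at its true AF; known-site lists
  sample background variants at rate 0.95; the interaction graph holds random
  background edges plus any planted digenic edge.

What passing tests on this generator do **not** show about real data: capture
bias and systematically missing regions, batch effects between cases and
databases, population stratification in the frequency resources, within-gene
recombination, and annotation error are all absent by construction.

## Problem sizes in the evaluation experiments

All evaluation routines live in `famseq.experiments` and are shared by the
test suite and `scripts/acceptance.py`; sizes are chosen for stable
Monte-Carlo estimates at interactive runtimes.

- Gene-dropping vs exact sharing probability: 1e5 drops per family template
  (agreement well within 0.01).
- Planted-architecture recovery: 100 seeded two-family cohorts per model at
  depth 35×, error 0.005, 24-gene background.
- Null calibration: 500 eight-family null cohorts (150 genes × Poisson(3)
  variants); every gene carried by ≥ 1 affected is tested (~1,000+ p-values
  pooled), and the fraction below 0.05 is compared against the one-sided
  binomial 99% bound. The discrete statistic is conservative, so observed
  fractions sit well below 0.05.
- IBD: 50 replicates of the 8-family cohort with 5,000 unlinked markers;
  founder-frequency bias correction as above. Misspecification detection uses
  10 replicates of an unrelated pair recorded as siblings.
- Burden agreement: exhaustive enumeration of all carrier tables with total
  ≤ 40 plus 1,000 random tables with group sizes up to 200, against an
  integer-arithmetic brute-force tail (exact suffix sums of binomial-
  coefficient products — int64 overflows silently on these, hence Python
  integers).
- The end-to-end default cohort runs once at full scale (~350k variants,
  ~25 s).

## Degenerate inputs and numerical notes

Empty variant sets report undefined metrics rather than NaN; zero
transversions yield an infinite Ti/Tv flag. Poisson-binomial tails are exact
convolutions (no normal approximation). Z-state clipping always renormalizes
to sum 1. Families with fewer than two genotyped affecteds are skipped by the
sharing/cosegregation stages; single-individual families produce empty IBD
reports. Two affected founders in one family make the single-origin sharing
model ill-posed and raise an error. All randomness descends from one integer
seed per run; reruns are byte-identical.

## Known limitations

The sharing statistic conditions on a single founder origin and full
genotyping of affecteds; it is conservative when sharing is destroyed by QC
missingness. The burden test needs an externally supplied background carrier
rate and does not adjust for covariates or relatedness in the background.
The joint-cosegregation rule (connected ≥ k-hit gene sets) is one
formalization of an informally described procedure; other connectivity radii
are configurable but unexplored. Published real-data quantities that depend
on the original raw exomes or external tool internals (per-patient totals,
the pVAAST p = 0.0040 and LOD = 1.25 as real-data values, SKAT and
validation rates) are reproduced here only at the level of their worked-table
arithmetic, not re-derived from sequence data.
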