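# Methods

## The prioritization model

The pipeline targets a specific inheritance architecture: *trans digenic*
heterozygosity. Two variants in two different genes of one functional
pathway, one transmitted by each parent, are jointly causal; each parent
carries only one of the two and is (at most mildly) affected, while every
affected child carries both. The scan therefore composes five filters whose
order is fixed only for funnel comparability — the surviving pair set is
order-invariant:

1. **Region**: `region_class ∈ {exonic, splicing}`. The annotation source
   (an ANNOVAR-style TSV) is authoritative; VCF `GENE`/`REGION` INFO keys
   are used only as fallback.
2. **Rarity**: novel (no frequency on record) or MAF strictly below
   `rarity.max_af` (default 0.01). The default frequency field is the
   *global* database frequency, not popmax: the motivating kindred's KLB
   variant has global MAF 0.002 but African-subset MAF 0.02, so a popmax
   rule at 0.01 would have discarded a true causal allele; popmax mode
   remains available as a stricter option.
3. **Deleteriousness**: strict majority vote over seven predictors. Raw
   scores are thresholded at each tool's conventional published operating
   point — CADD phred ≥ 20, SIFT ≤ 0.05, PolyPhen2 ≥ 0.446 ("possibly
   damaging" boundary), LRT call "D", MutationTaster call in {"A", "D"},
   GERP++ RS ≥ 2.0, PhyloP ≥ 1.5 — all overridable in config. Missing calls
   count toward neither side; ties are NOT deleterious ("majority" read
   strictly); fewer than `vote.min_informative` (default 4) informative
   calls yields a conservative false verdict flagged as insufficient
   evidence, so sparsely annotated variants are dropped rather than guessed.
4. **Segregation**: the shared-monoallelic scan keeps variants heterozygous
   in *every* affected member whose parental origin, re-derived by
   transmission, is unambiguous and identical across affecteds: the allele
   is carried by exactly one parent and absent (hom-ref) in the other.
   Requiring absence in the other parent is what makes the later trans
   assignment well-defined; a permissive mode (`segregation.
   allow_other_parent_carrier`) ignores the other parent's genotype, which
   in practice tolerates a MISSING genotype there but still treats
   two-carrier configurations as ambiguous. Any MISSING genotype in a
   member a pattern needs disqualifies the variant for that pattern — no
   imputation; the target use case has complete quartet data. Only
   autosomes are scanned by default (the hemizygous X model is out of
   scope); excluded counts are logged.
5. **Pairing and restriction**: Cartesian maternal x paternal pairing in
   distinct genes (same-gene cross-parental pairs are compound
   heterozygotes and are reported by the recessive scan only — this
   prevents double counting), requiring the shared affected-carrier set to
   equal the full affected set by default. Gene-set restriction is pure
   *membership*: a pair survives `both_in_same_set` iff its two genes
   co-occur in at least one supplied set. No enrichment statistic is
   computed — the supplied sets are a user input, and implementing a
   particular enrichment method would add an unvalidatable degree of
   freedom to a membership decision.

De novo and recessive scans are provided to establish that no monogenic
model fits before the digenic scan is interpreted; they are not part of the
pair-generating path.

**Ranking** is deliberately minimal plumbing, not part of the model: score
= mean over the two variants of (damaging fraction of informative
predictors) x (1 − global AF, missing AF as 0), descending, ties broken
lexicographically for run-to-run determinism. Real candidate selection is
expected to weigh biological knowledge the pipeline does not encode.

## The simulator

The generator emulates the statistical structure the scan assumes, not real
exome content:

- **Allele-frequency spectrum**: Beta(0.2, 6) rejection-truncated to
  [1e-5, 0.5] (median ≈ 0.005), rare-skewed so the MAF filter is
  consequential. A degenerate window (`af_min == af_max`) yields that
  constant, making fixed-frequency edge cases expressible.
- **Founders**: genotype = sum of two Bernoulli(AF) alleles (Hardy-Weinberg).
- **Transmission**: each non-founder draws one allele per parent uniformly
  from that parent's two alleles, independently across variants. Variants
  are unlinked — no LD or recombination map, since every downstream
  decision is per-variant or per-pair.
- **Gene model**: a synthetic catalog (default 1,000 genes tiled across the
  22 autosomes at deterministic coordinates); one designated pathway set of
  20 genes stands in for the user-supplied candidate gene sets. Region
  classes are drawn exonic/splicing/other at 0.85/0.05/0.10.
- **Planted pair**: two new exonic variants in two distinct pathway genes
  with true AF ≤ 0.002 (the rarer of the kindred's two printed
  frequencies as an upper bound), heterozygous in one designated parent
  each; every affected child is forced to carry both, unaffected children
  at most one. Affection is fully penetrant for double carriers and
  independent of background variants; carrier parents are labeled
  unaffected, matching the phenotype labels such pedigrees carry in
  practice.
- **Annotation noise**: per predictor, calls are missing with probability
  0.05; otherwise damaging with probability 0.9 for planted variants
  (sensitivity) and 0.1 for background (false-damaging rate). Raw scores
  are then drawn from windows strictly on the damaging or benign side of
  each default cutoff, so the noise model and the thresholds cannot
  disagree. Recorded AF equals the true simulation AF.
- **Determinism**: a single `numpy` Generator seeded from `SimConfig.seed`
  drives everything, and all writers emit fixed, date-free headers, so a
  given configuration is byte-reproducible file-for-file.
- **Fault injection**: optional Mendelian-violation variants (child het,
  parents hom-ref) and a per-genotype error rate (uniform flip/drop) stress
  the scans; both default to 0.

What passing simulator-based tests does **not** show: real exome annotation
density (the simulator makes no attempt to reproduce the ~1,100 shared
deleterious variants a real quartet yields before gene-set narrowing),
predictor correlation (real predictors are strongly correlated; simulated
calls are independent, which makes the Binomial(7, p) background analysis
exact but is optimistic about ensemble error rates), linkage, population
structure, or sequence context. Recovery results quantify the pipeline's
behavior under its own stated assumptions, not clinical sensitivity.

## Numerical and design choices

- Genotypes are alt-allele dosages {0, 1, 2, −1=missing} against a single
  alternate allele; multiallelic sites are split upstream with other
  alternates counted as reference (the logic is purely carrier/non-carrier).
  Coordinates are 1-based; the canonical key is `chrom:pos:ref:alt`.
  Inputs are assumed normalized/left-aligned; the reader does not realign.
- VCF phase separators are accepted and ignored; origin is always
  re-derived by transmission.
- The expected background deleterious rate with false-damaging rate p and
  no missing calls is the exact binomial tail P(Bin(7, p) ≥ 4); at p = 0.1
  this is 0.0027279, the yardstick used in the tests.
- Funnel counts are asserted non-increasing across variant stages at run
  time; zero candidates is a valid, successful outcome (exit 0).
- Unaffected siblings do not veto shared-monoallelic variants (incomplete
  penetrance is tolerated, as carrier parents themselves show mild
  phenotypes) but do veto compound-het pairs, mirroring standard recessive
  filtering.

## Problem sizes used in tests and the acceptance script

Recovery benchmarking uses 100 seeds x 5,000 background variants (the
default generator size); the background-rate check uses one 50,000-variant
cohort; transmission fairness uses 10,000 het-by-hom-ref meioses;
brute-force equivalence uses 50 random instances of ≤ 200 variants checked
against an independent quadratic reference that re-implements every
predicate naively. Under the default conditions the planted pair is
recovered in ≈ 98–99 of 100 seeds with a median of exactly one candidate
pair; the measured background deleterious rate at 50,000 variants falls
within four Monte-Carlo standard errors of the analytic 0.27%.

## Known limitations

- Trios/quartets with an affected founder (no genotyped parents) cannot be
  phased by transmission; such affected members disable the trio-based
  scans with a logged warning.
- The shared-monoallelic definition requires strict heterozygosity in
  affecteds; hom-alt affecteds at a candidate site are treated as
  non-matching rather than being modeled.
- Gene-set files define the candidate universe; results are only as good
  as the supplied sets, and no enrichment statistic corrects for set size.
- X-linked and mitochondrial inheritance are not modeled.
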