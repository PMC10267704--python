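# Methods

`famvar` implements the downstream analysis of a family-based rare-variant
study of Crohn's disease (CD): prioritization of shared protein-altering
variants in affected relatives, followed by carrier-collapsed case-control
replication statistics, plus the descriptive clinical summaries and a
synthetic-data generator that stands in for the (unavailable) raw
sequencing cohort. This note records the model, the parameters that
matter, the numerical choices, and what the synthetic data does and does
not establish.

## Prioritization cascade

The cascade operates on annotated per-alt variant records plus per-sample
calls (genotype, total reads, variant reads) and applies, in order:

1. **Coding/splice + quality.** The variant's consequence class must be
   coding or canonical-splice (frameshift, nonsense, canonical splice,
   missense, synonymous), and at least one cohort member must carry the
   alternate allele with a *high-confidence* call: total reads ≥ 10,
   variant reads ≥ 5, and variant-read fraction ≥ 20%. All three bounds
   are inclusive and configurable (`QualityThresholds`).
2. **Non-synonymous.** Synonymous changes are dropped.
3. **Family sharing + protein alteration.** A variant is retained when, in
   at least one family, *every* index patient carries ≥ 1 alternate allele
   with a high-confidence call, and the variant is protein-altering:
   truncating consequences (frameshift, nonsense, canonical splice)
   unconditionally; missense only at highly conserved positions, phyloP ≥
   3.0 (inclusive; `ConservationThreshold`). An index patient with no call
   record or a missing genotype counts as a non-carrier — absence of
   evidence is not evidence of sharing. Missense records with no phyloP
   annotation are excluded by default (conservative) with a config
   override, since the retention rule cannot be evaluated for them.
4. **Rarity.** Every reference-panel frequency that is *present* (dbSNP,
   ESP, ExAC, 1000 Genomes) must be ≤ 0.001 (inclusive: the removal rule
   targets frequencies strictly above the ceiling), and the variant must
   be absent from the in-house exome database. Absence from a panel counts
   as passing; "absent" and "frequency 0" are deliberately distinct
   encodings, because an annotation pipeline distinguishes "never seen"
   from "seen at 0.0005". The in-house database itself is not
   distributable, so it enters as a boolean presence flag in the
   annotations.
5. **Candidate-gene categorization.** Each survivor is labelled by gene
   panel with precedence GWAS-IBD > primary immunodeficiency (PID) >
   IBD-pathway, else `novel` when protein-altering, else `none`; only
   `none` is removed. Note that every variant reaching this stage is
   protein-altering by stage 3, so under this rule the stage is a pure
   labelling step — the original study applied additional, unpublished
   judgement here, which we do not attempt to reverse-engineer.
6. **Optional externally supplied lists.** A pass-list (surrogate for a
   manual IGV review of alignments) and a cap-list (genotyping-assay
   capacity); both are identity filters over supplied variant keys and are
   skipped by default, since neither is a computation.

Stage counts are recorded after every filter, so the report has the shape
of a prioritization-scheme table: counts are monotone non-increasing by
construction. Stages 3 and 4 are independent per-variant predicates and
commute; the cascade exposes a swapped order for exactly that check.

**Sharing semantics.** "Shared" is interpreted per family — all index
patients within one family must carry the variant — and a variant
survives if this holds in at least one family. Recurrence across families
is not required; requiring it would make a single-family causal variant
(the motivating case) unfindable.

**Carrier definition.** Throughout, a carrier is a subject with ≥ 1
alternate allele (dominant model). This matches the replication module's
carrier-vs-wild-type collapsing.

## Replication association

Per variant, genotype tallies (hom_ref / het / hom_alt / missing, per
group) are collapsed to a 2×2 carrier table; missing genotypes leave both
margins, so denominators vary across variants and are never renormalized
to the cohort size.

* **Test selection.** Fisher's exact test when any expected cell count
  under independence is below 5, otherwise Pearson's chi-square with 1 df
  and no continuity correction. This classical rule reproduces every
  arithmetically consistent published p-value we checked in the source
  tables, on both branches. The threshold is configurable.
* **Fisher's exact test** is two-sided by summation of hypergeometric
  probabilities no greater than the observed table's (scipy's
  implementation; its tie rule admits tables within relative 1e-14 of the
  observed probability). The unit tests hold it to an exhaustive
  enumeration oracle written in exact rational arithmetic, to 1e-12, for
  random tables with total ≤ 200.
* **Odds ratio.** Sample OR = ad/bc with a Woolf (log-normal) interval,
  exp(ln OR ± z·√(1/a+1/b+1/c+1/d)), z = 1.96 by default. Any zero cell
  makes the Woolf standard error undefined; such rows report NA with a
  reason code rather than a continuity-corrected estimate (haldane-style
  corrections reproduce none of the published entries for those rows, so
  we do not guess).
* **Degenerate rows** (a single observed genotype class, or a zero 2×2
  margin) are flagged `not_available` and never abort a batch.
* **Significance** is the uncorrected per-variant p < 0.05, matching the
  replication design (a fixed, pre-selected variant panel). Bonferroni and
  Benjamini–Hochberg columns are emitted alongside for transparency but do
  not drive the flag.
* **Carrier composition** (percent of carriers who are cases vs. percent
  of non-carriers who are cases) is reported per variant; for the
  frameshift signal in the packaged table this is the published
  81.82% vs. 49.53% pair.

## Clinical summaries

Montreal-coded records: location is a *set* of codes (L4, upper GI, is a
modifier that only occurs in combination), behavior a single code. A
patient with L3+L4 counts toward both L3 and the upper-GI tally, so
location percentages can exceed 100% while behavior percentages sum to
100%. Age is summarized as median and range. Disease durations printed as
"<1 year" are stored as a left-open interval and excluded from numeric
aggregation; no duration aggregate is reported.

## Synthetic cohort generator

`simulate_families` emulates *post-calling* output — an annotated
multi-sample VCF, pedigree, panels, and a truth manifest — at desk scale.
Defaults mirror the study design: 12 families × 2 affected index
patients, and one planted rare frameshift in an innate-immunity pathway
gene shared by the index patients of one family. Acceptance runs use
5,000 background variants (a size chosen to exercise the cascade well
beyond the final candidate scale while keeping a run in seconds); the
whole-genome variant count of the real study is deliberately not
reproduced.

Key modelling choices:

* **Designed failure, not random failure.** Every background variant is
  assigned one predicate to fail (non-coding, synonymous, low read
  support, not shared, under-conserved missense, too common, in-house
  present) and is otherwise constructed to pass everything else. The
  truth manifest is then computed by direct per-variant predicate
  evaluation, independent of the cascade's bookkeeping, so cascade tests
  assert exact set equality (recall = precision = 1) rather than
  probabilistic recovery.
* **Read depths** follow a gamma-Poisson (negative-binomial-shaped) model
  with mean 30 and shape 5; carrier variant reads are binomial(depth,
  0.5). Planted carriers are nudged up to the minimum read support the
  quality thresholds require, implementing the contract that planted
  variants satisfy the quality model.
* **Reference frequencies** mix a point mass at "absent" (probability
  0.4) with a log-uniform draw over [1e-5, 0.05]; backgrounds meant to
  pass rarity draw below the 0.001 ceiling.
* **Determinism.** All sampling flows through one `numpy` generator with
  a mandatory seed, in a fixed order; writers emit sorted, byte-stable
  text. Same seed ⇒ byte-identical output files.

`simulate_replication` draws per-subject carrier status: controls at a
configured frequency f, cases at p = r·f/(1 − f + r·f) for a configured
odds ratio r, making r exactly the estimand of the association module;
genotyping missingness is independent per subject. Defaults are the
381-case / 381-control design. Carriers are emitted as heterozygotes —
at the rare frequencies of interest hom-alt carriers are negligible, and
the dominant-model collapse is invariant to the split anyway.

**What passing tests show, and what they do not.** The synthetic data
establishes that the cascade implements its stated predicates exactly and
that the association estimators are calibrated (type-I error ≈ 5% at
adequate expected counts; Woolf 95% coverage ≈ 96.7% at the replication
design point, measured over 20,000 replicates so the Monte-Carlo error is
small against the 94–97% acceptance band). It does not model linkage
disequilibrium, population stratification, relatedness beyond the shared
/ not-shared dichotomy, annotation error, or calling error — so passing
tests say nothing about the upstream quality of a real callset, only
about the downstream analysis applied to it.

## Numerical and format choices

* Variant keys are VCF-style: 1-based, anchored-base indels; the string
  form `chrom:posREF>ALT` matches replication-table unique ids, and a
  whitespace dialect (`chr19:10079057 TCACAGG…>T`) is accepted on input
  and normalized on output.
* `VariantKey.trimmed()` reduces to the minimal representation
  (right-trim, then left-trim advancing the position). Full
  left-alignment of indels would additionally require the reference
  sequence, which is not a pipeline input; keys are otherwise taken as
  given.
* Multi-allelic sites are decomposed on read into per-alt records;
  genotypes are collapsed per alt allele, and phased/unphased separators
  are treated identically.
* Annotation floats round-trip exactly through the writers (shortest
  round-trip `repr`).

## Known limitations

* The candidate-gene stage cannot reproduce the original study's manual
  narrowing (its published counts conflate reviewer judgement with the
  stated criteria); the cascade reports it as a labelling stage.
* Published OR/CI entries for zero-cell rows ("1.00, 1.00–1.01") match no
  standard estimator and are reported as NA instead.
* One published replication p-value (the common MUC19 indel) is not
  reproducible from its printed counts by either test; the package
  reports the computed value.
* The association module implements carrier collapsing only — no allele
  dose, recessive, or covariate-adjusted models.
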