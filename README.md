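# famvar

Family-based rare-variant prioritization and case-control replication
analysis, built around the study design that identified a rare
*SIRPB1* frameshift (c.1143_1144insG) associated with Crohn's disease in
Han Chinese families.

**Who it is for.** Analysts working with small family cohorts of a
complex disease who need (a) a reproducible, staged filter cascade that
takes an annotated multi-sample callset of affected relatives down to a
candidate list, (b) dominant-model 2×2 replication statistics for a
genotyped validation cohort, and (c) seeded synthetic cohorts with known
ground truth for validating the whole pipeline.

## The analysis

**Prioritization.** Starting from per-alt variant records with per-sample
read evidence, the cascade keeps variants that are, in order: coding or
canonical-splice with at least one high-confidence carrier call (≥ 10
reads, ≥ 5 variant reads, ≥ 20% variant fraction); non-synonymous;
shared by *all* index patients of at least one family **and**
protein-altering (truncating always; missense only at phyloP ≥ 3.0);
rare (≤ 0.001 in every reference panel where seen, absent in-house); and
on a candidate-gene panel (GWAS-IBD / primary immunodeficiency /
IBD-pathway) or novel protein-altering. Per-stage surviving counts are
reported as a prioritization-scheme table.

**Replication.** Per variant, genotype tallies collapse to carriers
(≥ 1 alternate allele) vs. non-carriers. With the 2×2 table
(a = case carriers, b = case non-carriers, c = control carriers,
d = control non-carriers):

* test: Fisher's exact (two-sided) when any expected cell < 5, else
  Pearson's χ² (1 df, no continuity correction);
* effect: OR = ad/bc with Woolf 95% CI
  `exp(ln OR ± 1.96·√(1/a + 1/b + 1/c + 1/d))`;
* carrier composition: 100·a/(a+c) vs. 100·b/(b+d).

See `docs/methods.md` for the full model, parameter and edge-case
documentation.

## Worked example

Run the pipeline end to end on a synthetic cohort, then analyze the
packaged replication counts:

```bash
$ famvar run-all --seed 7 --out-dir run/
wrote 9 files to run
final candidate set: 1 variants (run/cascade_report.tsv)
1 variants analyzed, 0 significant at alpha=0.05 -> run/association.tsv
summarized 24 patients -> run/cohort_summary.tsv
pipeline complete: run

$ cat run/cascade_report.tsv
stage	remaining_variants
all_variants	501
coding_splice_quality	357
non_synonymous	285
family_shared_protein_altering	143
rare	1
candidate_gene	1
```

The seeded simulation plants one causal frameshift shared by the index
patients of one family among 500 background variants, each constructed to
fail exactly one filter; the cascade recovers exactly the planted variant
(compare `run/truth.json` with `run/cascade_detail.json`).

Association on the packaged published genotype counts:

```bash
$ famvar associate --out table3.tsv
34 variants analyzed, 4 significant at alpha=0.05 -> table3.tsv
```

For the *SIRPB1* frameshift row (9/381 case carriers vs. 2/381 control
carriers) the output contains

```
test_used=chi_square  p_value=0.0335049  odds_ratio=4.58468
ci_low=0.983984  ci_high=21.3614
pct_cases_among_carriers=81.8182  pct_cases_among_noncarriers=49.534
```

i.e. χ² p = 0.034, OR 4.59 (95% CI 0.98–21.36), with 81.82% of carriers
being cases against 49.53% of non-carriers — the headline replication
numbers of the study design this package reimplements. The clinical
summary of the packaged 24-patient familial cohort reports ileocolonic
disease (L3) in 83.33% and a median age of 22 years:

```bash
$ famvar summarize --out-dir summary/
summarized 24 patients -> summary/cohort_summary.tsv
```

Everything is also available as a library:

```python
from famvar.association import GenotypeCounts, chi_square_2x2, odds_ratio_woolf

counts = GenotypeCounts(9, 372, 2, 379)
print(chi_square_2x2(counts))        # 0.03350...
print(odds_ratio_woolf(counts))      # (4.5847, 0.9840, 21.3614)
```

## Layout

```
src/famvar/
  variant_io.py        VCF/pedigree/panel/annotation readers and writers
  prioritization.py    filter predicates and the staged cascade
  association.py       carrier collapsing, 2x2 tests, Woolf intervals
  cohort_stats.py      Montreal-classification clinical summaries
  synthetic_cohort.py  seeded family + replication cohort generators
  cli.py               famvar simulate/prioritize/associate/summarize/run-all
  data/                packaged clinical and replication count tables
```
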