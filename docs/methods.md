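# Methods

## Procedure

The analysis is deterministic set algebra over four inputs, executed in
a fixed order.

1. **Ingest and merge.** Risk-gene tables (one row per gene × study ×
   TWAS panel) are validated row-by-row; rows with malformed *P* values
   or flags go to a rejects report, never silently dropped. Duplicate
   (gene, study, panel) rows collapse with a warning. Symbols are
   normalized (uppercase, stripped) and mapped to protein accessions
   through a supplied table only — no live lookups — with one-to-many
   mappings expanded one association per accession and recorded in a
   provenance column. Associations sharing an accession merge into one
   gene entity whose evidence classes are the union over its
   associations; the evidence class is a deterministic function of the
   analysis kind (GWAS/PheWAS → common, CNV/exome → rare,
   TWAS/expression profiling → expression).
2. **Genome-wide subset.** Entities with at least one genome-wide
   significant association from a whitelisted study, with per-source
   (GWAS/TWAS/CNV) unique-gene counts. Significance is carried as
   −log₁₀ *P*, kept per study and per TWAS panel, and never ranked
   across analysis types; within a study the minimum *P* over panels is
   the derived ranking value.
3. **Drug catalog and trial curation.** The approved-drug catalog is
   grouped drug-wise; an accession → drugs index is built from human
   annotations only. Trial drugs are annotated from the same catalog by
   normalized name (case-insensitive, punctuation stripped; salts are
   distinct unless the input maps them). Drugs with only microbial
   targets gain human annotations from a mechanism-of-action table when
   present, otherwise they are excluded ("no human target"). Subunit
   annotations sharing a complex identifier (or, when absent, a ChEMBL
   target id) and protein class consolidate to one representative. For
   multi-target drugs at most two class entries are retained, ranked by
   (1) risk-gene membership of the accession, (2) the integer
   therapeutic-relevance rank from the input (1 = primary; missing
   ranks last), (3) lexicographic accession then ChEMBL id; the second
   slot prefers a different level-1 class when one exists (mechanistic
   diversity, applied per drug). Every selection carries its reason for
   audit.
4. **Cross-referencing.** Druggable genes = risk accessions present in
   the catalog index. The evidence partition assigns each druggable
   gene to unique-common/rare/expression or multi-class; the four cells
   are disjoint and cover the set. Repurposing status splits the
   druggable set by membership in the trial-target accession set. The
   trial-target set used for status and for genetic support is the full
   post-remap human annotation set of non-excluded trial drugs — the
   "unique human targets" a trial pipeline maps to — while the ≤2
   curated class entries feed only the class distribution and the
   drugs-per-target weights. Class distributions are tallied per gene
   (genetic side, `by_target`) and per retained drug-entry (trial side,
   `by_drug`), at level-1 ChEMBL classes with 7TM receptors broken out;
   a gene with conflicting class paths across drugs resolves to the
   most frequent path (ties lexicographic, logged).
5. **Target development levels.** For each genome-wide gene: Tclin_RP
   if it is an approved-drug target that is also a trial target; Tclin
   if an approved-drug target only; otherwise the base label from the
   metadata snapshot. Metadata claiming Tclin for a non-approved
   accession is a stale-snapshot inconsistency: approved-set membership
   wins and the target is demoted to Tchem (logged). Removing the trial
   list collapses Tclin_RP into Tclin and changes nothing else.
6. **Prioritization.** One table row per gene × genome-wide association
   (source/panel), carrying approved-drug count, all metadata axes and
   the neurophenotype score: NA when no mouse phenotype data exists,
   otherwise the count (0–2) of the two Mammalian Phenotype index terms
   present. Score 2 requires *both* index terms — the "and" reading —
   since score 1 already covers "either". Tier counts and shortlists
   deduplicate at gene level; missing metadata propagates as null and is
   excluded from threshold counts (null is not zero).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `study_whitelist` | the three genome-wide-reporting studies | studies whose genome-wide flag admits a gene to prioritization |
| `hda_threshold` | 10 (HDA score units) | below this a gene joins the low-information shortlist |
| `chembl_label_threshold` | 10 activities | plot-labelling cutoff; the tier count itself uses activity > 0 |
| curation rank order | fixed | risk match → therapeutic rank → lexicographic; not configurable, it *is* the method |

## Synthetic data and what passing tests show

`druggenome.synth` generates all four inputs from a reserved namespace
(SYNG/SYNP/SYNCHEMBL…) so fixtures can never be mistaken for real
annotations, using one explicitly passed seeded generator. It emulates
the *statistical and relational* structure the pipeline consumes:
per-class gene lists with planted pairwise/triple overlaps, genome-wide
fractions per class, multi-panel TWAS entries, a drug catalog with
planted risk-gene targets, subunit complexes, microbial-only trial
drugs with partial remappability, long-tailed activity counts
(geometric), lognormal HDA scores, and per-term neurophenotype
probabilities. It does **not** emulate LD or locus structure, realistic
pathway biology, effect sizes, or name-level messiness beyond what the
normalizers handle — so green tests demonstrate the set algebra,
curation rules and bookkeeping are correct, not that real supplementary
tables are clean.

During generation every downstream count is enumerated directly from
the generator's internal bookkeeping — including an exhaustive
application of the curation rules — and written to `manifest.json`.
The acceptance suite regenerates bundles for 20 seeds with varied
overlap structure and requires every pipeline count to equal the
manifest exactly.

The default profile (~300 genes, 80 drugs, 30 trial drugs) keeps a full
run under a second. The `study_scale` profile fixes the study
conditions: per-class listings 435/246/338 with overlap fractions tuned
so the merged set lands near 748 unique genes (the sampled value with
the default seed is 752), genome-wide fractions giving ≈573 unique
genome-wide genes, a druggable overlap of 7.5%, 89 trial drugs with
7 microbial (4 remappable) and ≈20 multi-target, and a
Tchem/Tbio/Tdark mixture of 8/63/24% for targets outside the approved
set (approved targets are Tclin by construction, so the mixture's Tclin
share is realized structurally rather than sampled).

## Numerical choices and degenerate inputs

- All tie-breaks are lexicographic (accession, then ChEMBL id); with a
  fixed configuration every operation is deterministic and invariant to
  input row order, and full runs are byte-identical.
- Proportions are exported raw; the report rounds percentages to
  integers. Distribution normalization is asserted to |Σp − 1| ≤ 0.01.
- Empty inputs produce empty outputs, not errors: an empty trial list
  makes every druggable gene `T_clinical`, a disjoint catalog empties
  the druggable set.
- *P* values must lie in (0, 1]; 0 and values above 1 are row-level
  rejects at parse time and domain errors in `neglog_p`.
- The genetically-supported percentage has two defensible denominators
  (trial drugs vs unique trial targets); both are reported, labelled.

## Known limitations

- Drug-name joining is exact after normalization; brand/synonym
  resolution must happen upstream in the inputs.
- "Primary therapeutic relevance" is consumed as an integer rank
  column; the package does not parse mechanism-of-action free text.
- Mechanistic diversity is enforced per drug (second entry from a
  different level-1 class when possible), an approximation of set-level
  diversity across the whole trial pipeline.
- The HDA score and all ChEMBL-derived counts are snapshot-dependent
  inputs, consumed as given; no enrichment statistics are computed on
  the class-distribution comparison, which is descriptive.
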