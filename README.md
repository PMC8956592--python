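# druggenome

Cross-referencing of disease risk-gene lists with the druggable genome:
drug-repurposing overlap statistics, target development levels, and
multi-axis target prioritization. Built for the schizophrenia genome but
generic over any disease whose risk genes arrive as per-study lists.

## The problem

Genetic association studies of schizophrenia implicate hundreds of genes
through three largely independent evidence classes — common variation
(GWAS/PheWAS), rare variation (CNV and exome studies), and gene
expression (TWAS). Separately, dozens of approved drugs are being tested
in clinical repurposing trials for schizophrenia. This package answers,
as reproducible set algebra over four tabular inputs:

- which risk genes are *druggable* (encode a protein target of an
  approved drug), and by how many drugs;
- which druggable genes are already targeted by trial drugs
  (`T_clinical_repurposing`) versus untested novel opportunities
  (`T_clinical`), and conversely which trial targets carry direct
  genetic support;
- how the protein-class spectrum (ChEMBL classification: ion channels,
  7TM receptors, transporters, enzymes, ...) of genetically implicated
  targets compares with the spectrum actually being tested in trials;
- where every genome-wide significant risk gene sits on the IDG target
  development ladder — Tclin (approved-drug mechanism-of-action target),
  Tchem (potent small-molecule binder known), Tbio (bioactivity
  evidence), Tdark (unexplored) — extended with Tclin_RP for Tclin
  targets already in a repurposing trial;
- which underexplored targets score on CNS-relevance axes: ChEMBL
  activity counts, synaptic pathway annotations, mouse neurophenotypes
  (count of Mammalian Phenotype index terms MP:0003631 "nervous system
  phenotype" and MP:0005386 "behavior/neurological phenotype" — 0, 1, 2
  or NA), and the Harmonizome data-availability (HDA) score.

Risk genes are merged on UniProt accessions; all significance values are
−log₁₀ *P* and are only ever compared within one analysis type. Trial
drugs with exclusively microbial targets are remapped through a human
mechanism-of-action table or excluded; multi-target drugs retain at most
two protein-class entries, ranked by risk-gene match, primary
therapeutic relevance, then mechanistic diversity.

Because the real inputs are curated supplementary tables, the package
ships a first-class synthetic generator (`druggenome.synth`) that
emulates all four inputs with configurable overlap structure and writes
a ground-truth manifest of every downstream count, computed by direct
enumeration during generation. The whole pipeline is validated against
that manifest.

## Worked example

```sh
druggenome all --seed 17 --out results/
```

runs the default synthetic profile end-to-end and prints (excerpt):

```
risk-gene associations ingested:  346
unique risk genes (accessions):   275
genome-wide significant genes:    194  (GWAS 122, TWAS 42, CNV 37)

druggable risk genes:             22  (targeted by 34 approved drugs)
evidence partition (unique C/R/E/multi): 13/3/4/2
already in repurposing trials:    9
novel repurposing opportunities:  13

trial drugs: 30 (1 excluded, no human target)
unique human trial targets:       37
genetically supported targets:    9  (30% of trial drugs; 24% of trial targets)
mean curated entries per drug:    1.28

target development levels (genome-wide subset):
  Tclin_RP   7
  Tclin      12
  Tchem      16
  Tbio       114
  Tdark      45
```

Reading this: of 275 merged risk genes, 22 are targets of approved
drugs; 9 of those are already being hit by repurposing-trial drugs while
13 are untested repurposing opportunities. The supported-target
percentage is reported against both denominators (trial drugs and
unique trial targets) because they differ. Among the 194 genome-wide
significant genes, 45 are Tdark — unexplored proteins with no drug,
ligand or bioactivity annotation — of which the shortlists single out
those with mouse neurophenotypes or low HDA scores as characterization
gaps. Full tables land in `results/` (`druggable_genes.tsv`,
`trial_targets.tsv`, `class_distribution.tsv`, `priority_table.tsv`,
`shortlists/`, `summary.json`).

Real inputs are supplied through a YAML config instead of the synthetic
profile:

```yaml
schema_version: 1
inputs:
  evidence: data/risk_genes.tsv
  symbol_map: data/hgnc_to_uniprot.tsv
  catalog: data/approved_drug_targets.tsv
  trial_list: data/repurposing_trials.tsv
  human_moa: data/drugbank_moa.tsv
  target_meta: data/idg_metadata.tsv
study_whitelist: [GWAS_META, CNV_META, TWAS_META]
hda_threshold: 10.0
```

then `druggenome all --config run.yaml --out results/`.

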