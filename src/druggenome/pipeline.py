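"""End-to-end orchestration: ingest, cross-reference, TDL, prioritize, report.

Runs the full analysis from a configuration (real input tables or a
synthetic profile) and writes every module's tabular output plus a
``summary.json`` holding the headline counts and a provenance block.
Machine outputs are byte-identical across repeated runs on identical
inputs and configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import catalog as cat
from . import evidence as ev
from . import overlap as ov
from . import synth
from . import tdl as tdlmod

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "write_report"]


@dataclass
class RunConfig:
    """Run configuration; either real input paths or a synthetic profile."""

    inputs: dict = field(default_factory=dict)  # evidence, symbol_map, catalog,
    # trial_list, human_moa, target_meta
    synthetic: bool = False
    synthetic_profile: str = "default"  # default | study_scale
    seed: int = 17
    study_whitelist: set = field(
        default_factory=lambda: set(synth.STUDY_WHITELIST))
    hda_threshold: float = 10.0
    chembl_label_threshold: int = 10
    outdir: str = "results"
    verbosity: int = 1

    def validate(self) -> None:
        if self.synthetic and self.inputs:
            raise ValueError("specify either input paths or a synthetic "
                             "profile, not both")
        if not self.synthetic and not self.inputs:
            raise ValueError("no inputs configured")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.pop("schema_version", None)
        if "study_whitelist" in raw:
            raw["study_whitelist"] = set(raw["study_whitelist"])
        return cls(**raw)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _resolve_inputs(config: RunConfig, outdir: Path) -> tuple[dict, dict | None]:
    if not config.synthetic:
        return dict(config.inputs), None
    if config.synthetic_profile == "study_scale":
        sc = synth.study_scale_profile(seed=config.seed)
    else:
        sc = synth.SyntheticConfig(seed=config.seed)
    paths, manifest = synth.generate(sc, outdir / "inputs")
    return paths, manifest


def run_all(config: RunConfig) -> dict:
    """Execute all stages in order and write the output bundle.

    Returns the summary dictionary (also written to ``summary.json``).
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs, manifest = _resolve_inputs(config, outdir)

    # a: ingest and merge risk-gene lists
    associations, rejects = ev.parse_evidence_table(inputs["evidence"])
    if "symbol_map" in inputs:
        mapping = pd.read_csv(inputs["symbol_map"], sep="\t", dtype=str)
        associations, unmapped = ev.map_to_accessions(associations, mapping)
    else:
        unmapped = pd.DataFrame(
            columns=["gene_symbol", "study_id", "analysis_kind", "reason"])
    entities = ev.merge_by_accession(associations)
    gw_entities, gw_counts = ev.genome_wide_subset(
        entities, set(config.study_whitelist))

    # b: approved-drug catalog
    drug_catalog = cat.parse_drug_catalog(inputs["catalog"])
    catalog_index = cat.index_by_accession(drug_catalog)
    approved_accessions = set(catalog_index)

    # c: trial-drug annotation and curation
    trial_list = cat.parse_trial_list(inputs["trial_list"])
    trial_drugs = cat.annotate_trial_drugs(trial_list, drug_catalog)
    human_moa = (pd.read_csv(inputs["human_moa"], sep="\t", dtype=str)
                 if "human_moa" in inputs else pd.DataFrame())
    trial_drugs = cat.remap_microbial(trial_drugs, human_moa)
    risk_accessions = set(entities)
    trial_drugs = [cat.curate_multi_target(d, risk_accessions)
                   for d in trial_drugs]
    trial_accs = cat.trial_target_accessions(trial_drugs)

    # d/e: cross-reference risk genes with catalog and trial pipeline
    druggable, druggable_drugs = ov.druggable_genes(entities, catalog_index)
    partition = ov.partition_by_evidence(druggable, entities)
    status = ov.repurposing_status(druggable, trial_accs)
    supported = ov.genetically_supported_trial_targets(trial_accs,
                                                       risk_accessions)
    gdist = ov.genetic_distribution(druggable, drug_catalog)
    tdist = ov.trial_distribution(trial_drugs)
    comparison = ov.compare_distributions(gdist, tdist)

    # f: target development levels over the genome-wide subset
    meta_table = tdlmod.parse_target_meta(inputs["target_meta"])
    labels = {}
    for acc in gw_entities:
        meta = meta_table.get(acc)
        if meta is None:
            labels[acc] = tdlmod.TDLLabel.TDARK
            logger.info("no metadata for %s; defaulting to Tdark", acc)
        else:
            labels[acc] = tdlmod.assign_tdl(meta, approved_accessions,
                                            trial_accs)
    tdl_summary = tdlmod.tdl_distribution(gw_entities, labels)

    # g/h: prioritization table, tier counts, shortlists
    status_str = {k: v.value for k, v in status.items()}
    table = tdlmod.build_priority_table(
        gw_entities, catalog_index, meta_table, labels, status_str,
        set(config.study_whitelist))
    tiers = tdlmod.annotation_tier_counts(table)
    sl_dark = tdlmod.shortlist_tdark_neuro(table)
    sl_hda = tdlmod.shortlist_low_hda(table, config.hda_threshold)
    inter = tdlmod.multi_source_intersection(gw_entities,
                                             set(config.study_whitelist))
    n_tf, n_tf_neuro = tdlmod.transcription_factor_summary(table)

    # ---------------------------------------------------------------- outputs
    ev.entities_to_frame(entities).to_csv(outdir / "merged_entities.tsv",
                                          sep="\t", index=False)
    rejects.to_csv(outdir / "evidence_rejects.tsv", sep="\t", index=False)
    unmapped.to_csv(outdir / "unmapped_report.tsv", sep="\t", index=False)

    drows = []
    for acc in sorted(druggable):
        ent = entities[acc]
        letters = "".join(l for l, c in (("C", ev.EvidenceClass.COMMON),
                                         ("R", ev.EvidenceClass.RARE),
                                         ("E", ev.EvidenceClass.EXPRESSION))
                          if c in ent.evidence_classes)
        drows.append({"accession": acc, "symbol": min(ent.symbols),
                      "evidence": letters, "status": status[acc].value,
                      "drugs": ";".join(sorted(catalog_index[acc]))})
    pd.DataFrame(drows, columns=["accession", "symbol", "evidence", "status",
                                 "drugs"]).to_csv(
        outdir / "druggable_genes.tsv", sep="\t", index=False)

    trows, xrows = [], []
    for d in sorted(trial_drugs, key=lambda d: d.drug_name):
        if d.excluded:
            xrows.append({"drug_name": d.drug_name,
                          "exclusion_reason": d.exclusion_reason})
            continue
        for ann, reason in d.curated_class_entries:
            trows.append({"drug_name": d.drug_name,
                          "accession": ann.accession,
                          "protein_class": ann.protein_class.display_class(),
                          "selection_reason": reason,
                          "trial_weight": d.trial_weight,
                          "genetically_supported": ann.accession in risk_accessions})
    pd.DataFrame(trows, columns=["drug_name", "accession", "protein_class",
                                 "selection_reason", "trial_weight",
                                 "genetically_supported"]).to_csv(
        outdir / "trial_targets.tsv", sep="\t", index=False)
    pd.DataFrame(xrows, columns=["drug_name", "exclusion_reason"]).to_csv(
        outdir / "trial_exclusions.tsv", sep="\t", index=False)

    cd = pd.concat([gdist.to_frame().assign(side="genetic"),
                    tdist.to_frame().assign(side="trial")])
    cd.to_csv(outdir / "class_distribution.tsv", sep="\t", index=False)
    comparison.to_csv(outdir / "comparison.tsv", sep="\t", index=False)

    tdlmod.priority_table_to_frame(table).to_csv(
        outdir / "priority_table.tsv", sep="\t", index=False)
    (outdir / "shortlists").mkdir(exist_ok=True)
    sl_dark.to_csv(outdir / "shortlists" / "tdark_neurophenotype.tsv",
                   sep="\t", index=False)
    sl_hda.to_csv(outdir / "shortlists" / "low_hda.tsv", sep="\t", index=False)

    n_trial_total = len(trial_drugs)
    n_trial_retained = sum(1 for d in trial_drugs if not d.excluded)
    n_entries = sum(len(d.curated_class_entries) for d in trial_drugs
                    if not d.excluded)
    summary = {
        "version": __version__,
        "counts": {
            "n_associations": len(associations),
            "n_rejected_rows": len(rejects),
            "n_unmapped": len(unmapped),
            "n_unique_genes": len(entities),
            "genome_wide": {"n_unique": len(gw_entities),
                            "per_source": gw_counts},
            "druggable": {"n_genes": len(druggable),
                          "n_drugs": len(druggable_drugs)},
            "partition_sizes": partition.sizes,
            "status_counts": {
                "T_clinical_repurposing": sum(
                    1 for s in status.values()
                    if s is ov.RepurposingStatus.T_CLINICAL_REPURPOSING),
                "T_clinical": sum(
                    1 for s in status.values()
                    if s is ov.RepurposingStatus.T_CLINICAL),
            },
            "trial": {
                "n_drugs": n_trial_total,
                "n_excluded": n_trial_total - n_trial_retained,
                "n_targets": len(trial_accs),
                "n_supported": len(supported),
                "supported_pct_of_drugs": round(
                    100 * len(supported) / n_trial_total) if n_trial_total else 0,
                "supported_pct_of_targets": round(
                    100 * len(supported) / len(trial_accs)) if trial_accs else 0,
                "mean_curated_entries_per_drug": (
                    n_entries / n_trial_retained if n_trial_retained else 0.0),
            },
            "class_distribution_genetic": {
                k: c for k, (c, _) in sorted(gdist.entries.items())},
            "class_distribution_trial": {
                k: c for k, (c, _) in sorted(tdist.entries.items())},
            "tdl_counts": {
                r["label"]: int(r["count"])
                for _, r in tdl_summary.iterrows()
                if not str(r["label"]).endswith("background")},
            "tier_counts": {"chembl": tiers[0], "neurophenotype": tiers[1],
                            "synaptic": tiers[2]},
            "shortlist_tdark_neuro": {
                "members": sl_dark["accession"].tolist(),
                "multi_source": sl_dark.loc[sl_dark["multi_source"],
                                            "accession"].tolist()},
            "shortlist_low_hda": sl_hda["accession"].tolist(),
            "intersections": {k: len(v) for k, v in inter.items()
                              if "&" in k},
            "tf_summary": {"n_tf": n_tf, "n_tf_neuro": n_tf_neuro},
            "n_priority_rows": len(table),
        },
        "provenance": {
            "inputs": {k: _sha256(v) for k, v in sorted(inputs.items())
                       if Path(str(v)).is_file()},
            "config": {
                "synthetic": config.synthetic,
                "synthetic_profile": config.synthetic_profile,
                "seed": config.seed,
                "study_whitelist": sorted(config.study_whitelist),
                "hda_threshold": config.hda_threshold,
                "chembl_label_threshold": config.chembl_label_threshold,
            },
        },
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    with open(outdir / "report.txt", "w") as fh:
        fh.write(write_report(summary))
    return summary


def write_report(summary: dict) -> str:
    """Render the headline counts as a plain-text report."""
    lines = ["druggable-genome analysis report",
             "=" * 32, ""]
    c = summary.get("counts")
    if not c:
        return "\n".join(lines) + "\n"
    lines += [
        f"risk-gene associations ingested:  {c['n_associations']}",
        f"unique risk genes (accessions):   {c['n_unique_genes']}",
        f"genome-wide significant genes:    {c['genome_wide']['n_unique']}"
        f"  (GWAS {c['genome_wide']['per_source']['GWAS']},"
        f" TWAS {c['genome_wide']['per_source']['TWAS']},"
        f" CNV {c['genome_wide']['per_source']['CNV']})",
        "",
        f"druggable risk genes:             {c['druggable']['n_genes']}"
        f"  (targeted by {c['druggable']['n_drugs']} approved drugs)",
        "evidence partition (unique C/R/E/multi): "
        + "/".join(str(c['partition_sizes'][k]) for k in
                   ("unique_common", "unique_rare", "unique_expression",
                    "multi_class")),
        f"already in repurposing trials:    "
        f"{c['status_counts']['T_clinical_repurposing']}",
        f"novel repurposing opportunities:  {c['status_counts']['T_clinical']}",
        "",
        f"trial drugs: {c['trial']['n_drugs']}"
        f" ({c['trial']['n_excluded']} excluded, no human target)",
        f"unique human trial targets:       {c['trial']['n_targets']}",
        f"genetically supported targets:    {c['trial']['n_supported']}"
        f"  ({c['trial']['supported_pct_of_drugs']}% of trial drugs;"
        f" {c['trial']['supported_pct_of_targets']}% of trial targets)",
        f"mean curated entries per drug:    "
        f"{c['trial']['mean_curated_entries_per_drug']:.2f}",
        "",
        "target development levels (genome-wide subset):",
    ]
    for label, n in c["tdl_counts"].items():
        lines.append(f"  {label:<10} {n}")
    lines += [
        "",
        f"genes with ChEMBL activity:       {c['tier_counts']['chembl']}",
        f"genes with mouse neurophenotypes: {c['tier_counts']['neurophenotype']}",
        f"genes with synaptic pathways:     {c['tier_counts']['synaptic']}",
        f"Tdark + neurophenotype shortlist: "
        f"{len(c['shortlist_tdark_neuro']['members'])}"
        f" ({len(c['shortlist_tdark_neuro']['multi_source'])} multi-source)",
        f"low-HDA shortlist:                {len(c['shortlist_low_hda'])}",
        f"transcription factors:            {c['tf_summary']['n_tf']}"
        f" ({c['tf_summary']['n_tf_neuro']} with neurophenotypes)",
        "",
        "source intersections:",
    ]
    for k, n in c["intersections"].items():
        lines.append(f"  {k:<15} {n}")
    lines += [
        "",
        "class distributions (genetic by target / trial by drug):",
    ]
    classes = sorted(set(c["class_distribution_genetic"])
                     | set(c["class_distribution_trial"]))
    for cls in classes:
        lines.append(f"  {cls:<28} {c['class_distribution_genetic'].get(cls, 0):>4}"
                     f" {c['class_distribution_trial'].get(cls, 0):>4}")
    return "\n".join(lines) + "\n"
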