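"""Synthetic input bundles with an enumerated ground-truth manifest.

Generates the four tables the pipeline consumes -- risk-gene association
lists, approved-drug target catalog, clinical repurposing trial list, and
per-target IDG metadata -- from a reserved synthetic namespace
(SYNG/SYNP/... identifiers), with configurable overlap structure between
evidence classes, between risk genes and drug targets, and between trial
targets and risk genes.

Every downstream count the pipeline can produce is also computed here by
direct set enumeration over the generator's internal bookkeeping (never
by calling the pipeline) and written to ``manifest.json``, so the whole
pipeline can be validated end to end without external downloads.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["SyntheticConfig", "generate", "study_scale_profile"]

_CLASSES = ("common", "rare", "expression")

# study ids per evidence class: (genome-wide-reporting study + analysis
# kind, non-genome-wide study + kind)
_STUDIES = {
    "common": (("GWAS_META", "GWAS"), ("PHEWAS_01", "PheWAS")),
    "rare": (("CNV_META", "CNV"), ("EXOME_01", "exome")),
    "expression": (("TWAS_META", "TWAS"), ("EXPRPROF_01", "expression_profiling")),
}
STUDY_WHITELIST = frozenset({"GWAS_META", "CNV_META", "TWAS_META"})
_SOURCE_OF_CLASS = {"common": "GWAS", "rare": "CNV", "expression": "TWAS"}

_TWAS_PANELS = ("ADIPOSE", "BLOOD", "BRAIN")

_LEVEL1 = (
    "ion channel", "membrane receptor", "transporter", "enzyme",
    "transcription factor", "secreted", "structural", "surface antigen",
    "enzyme modulator", "epigenetic regulator", "auxiliary transport protein",
)
# sampling weights loosely shaped like an approved-drug target catalog:
# receptors, channels, enzymes and transporters dominate
_LEVEL1_W = np.array([0.18, 0.26, 0.12, 0.24, 0.06, 0.04, 0.02, 0.02,
                      0.03, 0.02, 0.01])

_NON_INDEX_MP = ("MP:0001262", "MP:0002169", "MP:0005375", "MP:0005378")
_INDEX_MP = ("MP:0003631", "MP:0005386")


@dataclass
class SyntheticConfig:
    """Generator knobs; defaults give a small, fast, fully-exercised bundle."""

    n_genes_per_class: dict = field(default_factory=lambda: {
        "common": 130, "rare": 80, "expression": 90})
    # fraction of the smaller class shared by exactly that pair / by all three
    cross_class_overlap: dict = field(default_factory=lambda: {
        "common|rare": 0.10, "common|expression": 0.10,
        "rare|expression": 0.08, "triple": 0.03})
    genome_wide_fraction: dict = field(default_factory=lambda: {
        "common": 0.9, "rare": 0.5, "expression": 0.5})
    n_multi_map_symbols: int = 2          # symbols expanding to two accessions
    n_catalog_drugs: int = 80
    n_background_targets: int = 120       # approved targets outside the risk set
    druggable_overlap: float = 0.08       # fraction of risk genes planted as targets
    n_trial_drugs: int = 30
    trial_target_overlap: float = 0.4     # trial drugs drawn from risk-hitting drugs
    microbial_fraction: float = 0.1
    remappable_fraction: float = 0.5
    multi_target_fraction: float = 0.25
    n_complexes: int = 2
    tdl_mixture: dict = field(default_factory=lambda: {
        "Tclin": 0.05, "Tchem": 0.08, "Tbio": 0.63, "Tdark": 0.24})
    activity_mean: float = 40.0           # geometric mean for Tclin/Tchem activity
    neuro_term_probabilities: dict = field(default_factory=lambda: {
        "no_data": 0.25, "MP:0003631": 0.35, "MP:0005386": 0.35})
    hda_log_mean: float = 3.0             # lognormal parameters of the HDA score
    hda_log_sigma: float = 1.2
    tf_probability: float = 0.08
    seed: int = 17

    def validate(self) -> None:
        for c in _CLASSES:
            if self.n_genes_per_class.get(c, -1) < 0:
                raise ValueError(f"n_genes_per_class[{c}] must be >= 0")
        fracs = [*self.cross_class_overlap.values(),
                 *self.genome_wide_fraction.values(),
                 self.druggable_overlap, self.trial_target_overlap,
                 self.microbial_fraction, self.remappable_fraction,
                 self.multi_target_fraction, self.tf_probability]
        if any(not (0.0 <= f <= 1.0) for f in fracs):
            raise ValueError("all overlap/fraction parameters must be in [0,1]")
        if abs(sum(self.tdl_mixture.values()) - 1.0) > 1e-9:
            raise ValueError("tdl_mixture proportions must sum to 1")
        self._overlap_counts()  # raises on infeasible overlap structure

    def _overlap_counts(self) -> dict:
        n = self.n_genes_per_class
        ov = self.cross_class_overlap
        t = round(ov.get("triple", 0.0) * min(n[c] for c in _CLASSES))
        pairs = {}
        for key in ("common|rare", "common|expression", "rare|expression"):
            a, b = key.split("|")
            pairs[key] = round(ov.get(key, 0.0) * min(n[a], n[b]))
        unique = {}
        for c in _CLASSES:
            shared = t + sum(v for k, v in pairs.items() if c in k.split("|"))
            unique[c] = n[c] - shared
            if unique[c] < 0:
                raise ValueError(
                    f"overlap structure infeasible: class {c!r} needs "
                    f"{shared} shared genes but has only {n[c]}")
        return {"triple": t, "pairs": pairs, "unique": unique}


def study_scale_profile(seed: int = 17) -> SyntheticConfig:
    """Configuration matching the study conditions at full scale.

    Per-class gene-list sizes 435/246/338, overlap fractions tuned so the
    merged unique-gene count lands near 748, an approved-drug catalog
    spanning roughly 667 human targets, 89 trial drugs with ~7 microbial
    (4 remappable) and ~20 multi-target, and a Tchem/Tbio/Tdark mixture
    of roughly 8/63/24 percent for targets outside the approved set.
    """
    return SyntheticConfig(
        n_genes_per_class={"common": 435, "rare": 246, "expression": 338},
        cross_class_overlap={"common|rare": 0.35, "common|expression": 0.25,
                             "rare|expression": 0.33, "triple": 0.04},
        genome_wide_fraction={"common": 0.956, "rare": 0.455,
                              "expression": 0.45},
        n_multi_map_symbols=4,
        n_catalog_drugs=250,
        n_background_targets=611,
        druggable_overlap=0.075,
        n_trial_drugs=89,
        trial_target_overlap=0.35,
        microbial_fraction=7 / 89,
        remappable_fraction=4 / 7,
        multi_target_fraction=20 / 89,
        n_complexes=4,
        seed=seed,
    )


def _display_class(levels: tuple[str, ...]) -> str:
    # independent copy of the level-1/7TM display convention
    if levels[0] == "membrane receptor" and len(levels) > 1 and "7TM" in levels[1]:
        return "membrane receptor:7TM"
    return levels[0]


def generate(config: SyntheticConfig, outdir: str | Path) -> tuple[dict, dict]:
    """Write the input bundle and manifest; return (paths, manifest)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # ------------------------------------------------------------------ genes
    counts = config._overlap_counts()
    genes: list[dict] = []  # symbol, accessions, classes

    def _new_gene(classes: frozenset) -> dict:
        i = len(genes) + 1
        g = {"symbol": f"SYNG{i:06d}", "accessions": [f"SYNP{i:06d}"],
             "classes": classes}
        genes.append(g)
        return g

    for _ in range(counts["triple"]):
        _new_gene(frozenset(_CLASSES))
    for key, k in counts["pairs"].items():
        pair = frozenset(key.split("|"))
        for _ in range(k):
            _new_gene(pair)
    for c in _CLASSES:
        for _ in range(counts["unique"][c]):
            _new_gene(frozenset({c}))

    # one-to-many symbol mappings: extra accessions sharing the symbol's rows
    n_extra = min(config.n_multi_map_symbols, len(genes))
    extra_idx = sorted(rng.choice(len(genes), size=n_extra, replace=False)) \
        if n_extra else []
    for j, gi in enumerate(extra_idx, start=1):
        genes[gi]["accessions"].append(f"SYNPX{j:05d}")

    # per-gene associations: one listing per class; TWAS panels may add rows
    evidence_rows: list[dict] = []
    gene_gw_sources: dict[str, set[str]] = {}  # accession -> {GWAS,TWAS,CNV}
    n_gw_rows_by_acc: dict[str, int] = {}
    listings = {c: 0 for c in _CLASSES}
    for g in genes:
        for c in sorted(g["classes"]):
            listings[c] += 1
            gw = bool(rng.random() < config.genome_wide_fraction[c])
            (study, kind) = _STUDIES[c][0] if gw else _STUDIES[c][1]
            if gw and c == "expression":
                k = int(rng.integers(1, len(_TWAS_PANELS) + 1))
                panels = sorted(rng.choice(_TWAS_PANELS, size=k, replace=False))
            else:
                panels = [""]
            for panel in panels:
                if gw:
                    p = 10.0 ** rng.uniform(-30.0, math.log10(5e-8))
                else:
                    p = 10.0 ** rng.uniform(math.log10(5e-8), math.log10(0.05))
                evidence_rows.append({
                    "gene_symbol": g["symbol"], "analysis_kind": kind,
                    "study_id": study, "p_value": f"{p:.6e}",
                    "expression_panel": panel, "genome_wide": str(gw).lower(),
                })
            if gw:
                for acc in g["accessions"]:
                    gene_gw_sources.setdefault(acc, set()).add(_SOURCE_OF_CLASS[c])
                    n_gw_rows_by_acc[acc] = n_gw_rows_by_acc.get(acc, 0) + len(panels)

    risk_accessions = sorted(a for g in genes for a in g["accessions"])
    classes_of_acc = {a: g["classes"] for g in genes for a in g["accessions"]}

    # --------------------------------------------------------------- targets
    n_druggable = int(math.floor(config.druggable_overlap * len(risk_accessions)))
    planted = sorted(rng.permutation(risk_accessions)[:n_druggable].tolist())
    background = [f"SYNPB{i:05d}" for i in range(1, config.n_background_targets + 1)]
    target_pool = planted + background

    target_class: dict[str, tuple[str, ...]] = {}
    target_chembl: dict[str, str] = {}
    target_complex: dict[str, str | None] = {}
    for i, acc in enumerate(target_pool, start=1):
        l1 = str(rng.choice(_LEVEL1, p=_LEVEL1_W / _LEVEL1_W.sum()))
        levels = (l1, "7TM receptor") if (
            l1 == "membrane receptor" and rng.random() < 0.6) else (l1,)
        target_class[acc] = levels
        target_chembl[acc] = f"SYNCHEMBL{i:05d}"
        target_complex[acc] = None

    # subunit complexes: groups of background targets sharing complex id + class
    complex_members: list[list[str]] = []
    pool = [a for a in background if target_complex[a] is None]
    for ci in range(1, config.n_complexes + 1):
        size = int(rng.integers(2, 4))
        if len(pool) < size:
            break
        members = [pool.pop(0) for _ in range(size)]
        for m in members:
            target_complex[m] = f"SYNCPLX{ci:03d}"
            target_class[m] = target_class[members[0]]
        complex_members.append(members)

    # ----------------------------------------------------------- drug catalog
    drug_targets: dict[str, list[str]] = {}
    drug_rank: dict[str, dict[str, int]] = {}
    names = [f"syndrug{i:03d}" for i in range(1, config.n_catalog_drugs + 1)]
    # guarantee every planted risk target is hit by at least one drug
    for j, acc in enumerate(planted):
        drug_targets.setdefault(names[j % len(names)], []).append(acc)
    simple_pool = [a for a in target_pool if target_complex[a] is None]
    for name in names:
        tgts = drug_targets.setdefault(name, [])
        n_t = int(rng.choice([1, 2, 3], p=[0.65, 0.25, 0.10]))
        while len(tgts) < n_t:
            if complex_members and rng.random() < 0.08:
                grp = complex_members[int(rng.integers(len(complex_members)))]
                if not set(grp) & set(tgts):
                    tgts.extend(grp)
                    continue
            acc = simple_pool[int(rng.integers(len(simple_pool)))]
            if acc not in tgts:
                tgts.append(acc)
        order = rng.permutation(len(tgts))
        # subunits of one complex share a therapeutic rank
        ranks: dict[str, int] = {}
        next_rank = 1
        for idx in order:
            acc = tgts[idx]
            cid = target_complex[acc]
            if cid is not None:
                grp_rank = next((ranks[a] for a in tgts
                                 if target_complex[a] == cid and a in ranks), None)
                if grp_rank is not None:
                    ranks[acc] = grp_rank
                    continue
            ranks[acc] = next_rank
            next_rank += 1
        drug_rank[name] = ranks

    # microbial-only trial drugs (approved antimicrobials in the catalog)
    n_microbial = round(config.microbial_fraction * config.n_trial_drugs)
    n_remappable = round(config.remappable_fraction * n_microbial)
    microbial_names = [f"synmicro{i:02d}" for i in range(1, n_microbial + 1)]
    microbial_targets = {name: f"SYNMB{i:03d}"
                         for i, name in enumerate(microbial_names, start=1)}
    remap_table: dict[str, str] = {}
    for name in microbial_names[:n_remappable]:
        remap_table[name] = background[int(rng.integers(len(background)))]

    # consolidated human target-entry count per drug (complex = one entry)
    def _consolidated(accs: list[str]) -> list[str]:
        seen, out = set(), []
        for a in accs:
            key = (target_complex[a] or target_chembl[a], target_class[a])
            if key not in seen:
                seen.add(key)
                out.append(a)
        return out

    # -------------------------------------------------------- trial selection
    risk_hitting = sorted(n for n, t in drug_targets.items()
                          if set(t) & set(planted))
    others = sorted(set(names) - set(risk_hitting))
    n_trial_human = config.n_trial_drugs - n_microbial
    k_overlap = min(round(config.trial_target_overlap * n_trial_human),
                    len(risk_hitting))
    trial_human = list(rng.permutation(risk_hitting)[:k_overlap])
    want_multi = round(config.multi_target_fraction * config.n_trial_drugs)
    have_multi = sum(1 for n in trial_human if len(_consolidated(drug_targets[n])) >= 2)
    rest_multi = [n for n in rng.permutation(others)
                  if len(_consolidated(drug_targets[n])) >= 2]
    rest_single = [n for n in rng.permutation(others)
                   if len(_consolidated(drug_targets[n])) < 2]
    for n in rest_multi:
        if len(trial_human) >= n_trial_human or have_multi >= want_multi:
            break
        trial_human.append(n)
        have_multi += 1
    for n in rest_single + [n for n in rest_multi if n not in trial_human]:
        if len(trial_human) >= n_trial_human:
            break
        trial_human.append(n)
    trial_human = sorted(trial_human)
    trial_names = trial_human + microbial_names
    trial_weight = {n: int(1 + rng.geometric(0.7) - 1) for n in sorted(trial_names)}

    # ------------------------------------------------------------ metadata
    universe = sorted(set(risk_accessions) | set(target_pool)
                      | set(remap_table.values()))
    approved_set = set(target_pool)
    mix_labels = ("Tchem", "Tbio", "Tdark")
    mix_p = np.array([config.tdl_mixture[l] for l in mix_labels])
    mix_p = mix_p / mix_p.sum()
    meta: dict[str, dict] = {}
    for acc in universe:
        if acc in approved_set:
            base = "Tclin"
        else:
            base = str(rng.choice(mix_labels, p=mix_p))
        if base in ("Tclin", "Tchem"):
            activity = int(rng.geometric(1.0 / config.activity_mean))
            selective = int(rng.poisson(2))
        elif base == "Tbio":
            activity = int(rng.geometric(0.5) - 1)
            selective = 0
        else:
            activity = 0
            selective = 0
        p = config.neuro_term_probabilities
        if rng.random() < p["no_data"]:
            mp_terms = None
        else:
            terms = [t for t in _INDEX_MP if rng.random() < p[t]]
            n_other = int(rng.integers(0, 4))
            terms += list(rng.choice(_NON_INDEX_MP, size=n_other, replace=False))
            if not terms:
                terms = [_NON_INDEX_MP[0]]
            mp_terms = sorted(set(terms))
        levels = target_class.get(acc)
        is_tf = (levels is not None and levels[0] == "transcription factor") \
            or bool(rng.random() < config.tf_probability)
        meta[acc] = {
            "tdl": base,
            "chembl_activity_count": activity,
            "selective_compound_count": selective,
            "pathway_count_total": int(rng.poisson(15)),
            "synaptic_pathway_count": int(rng.integers(1, 6))
            if rng.random() < 0.15 else 0,
            "disease_count": int(rng.poisson(3)),
            "mp_terms": mp_terms,
            "grant_dollars": round(float(rng.lognormal(13, 1.5)), 2),
            "patent_count": int(rng.poisson(5)),
            "hda_score": round(float(rng.lognormal(config.hda_log_mean,
                                                   config.hda_log_sigma)), 3),
            "is_tf": is_tf,
        }

    paths = _write_bundle(outdir, evidence_rows, genes, names, drug_targets,
                          drug_rank, target_class, target_chembl,
                          target_complex, microbial_names, microbial_targets,
                          remap_table, trial_names, trial_weight, meta, rng)

    manifest = _enumerate_manifest(
        config, evidence_rows, genes, listings, risk_accessions,
        classes_of_acc, gene_gw_sources, n_gw_rows_by_acc, planted,
        drug_targets, drug_rank, target_class, target_chembl, target_complex,
        microbial_names, remap_table, trial_names, meta, approved_set)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    paths["manifest"] = str(outdir / "manifest.json")
    return paths, manifest


def _write_bundle(outdir, evidence_rows, genes, names, drug_targets,
                  drug_rank, target_class, target_chembl, target_complex,
                  microbial_names, microbial_targets, remap_table,
                  trial_names, trial_weight, meta, rng) -> dict:
    paths = {}

    def _tsv(name: str, header: list[str], rows: list[list]) -> None:
        path = outdir / name
        with open(path, "w") as fh:
            fh.write("\t".join(header) + "\n")
            for r in rows:
                fh.write("\t".join("" if v is None else str(v) for v in r) + "\n")
        paths[name.rsplit(".", 1)[0]] = str(path)

    _tsv("evidence.tsv",
         ["gene_symbol", "analysis_kind", "study_id", "p_value",
          "expression_panel", "genome_wide"],
         [[r["gene_symbol"], r["analysis_kind"], r["study_id"], r["p_value"],
           r["expression_panel"], r["genome_wide"]] for r in evidence_rows])

    _tsv("symbol_map.tsv", ["gene_symbol", "accession"],
         [[g["symbol"], a] for g in genes for a in g["accessions"]])

    cat_rows = []
    for name in names:
        for acc in drug_targets[name]:
            levels = target_class[acc]
            cat_rows.append([
                name, "small molecule", f"{levels[0]} modulator", acc,
                target_chembl[acc], levels[0],
                levels[1] if len(levels) > 1 else "",
                "", "human", target_complex[acc] or "",
                "N05A", 1950 + int(rng.integers(0, 70)),
                drug_rank[name][acc]])
    for name in microbial_names:
        cat_rows.append([name, "small molecule", "antimicrobial",
                         microbial_targets[name], f"SYNCHEMBLM{name[-2:]}",
                         "enzyme", "", "", "microbial", "", "J01X",
                         1950 + int(rng.integers(0, 70)), 1])
    _tsv("drug_catalog.tsv", ["drug_name", "molecule_type", "moa", "accession",
                              "chembl_target_id", "class_l1", "class_l2",
                              "class_l3", "organism", "complex_id", "atc",
                              "approval_year", "therapeutic_rank"], cat_rows)

    _tsv("trial_list.tsv", ["drug_name", "n_trial_listings"],
         [[n, trial_weight[n]] for n in sorted(trial_names)])

    _tsv("human_moa.tsv", ["drug_name", "accession", "chembl_target_id",
                           "class_l1", "class_l2", "class_l3",
                           "therapeutic_rank"],
         [[n, acc, target_chembl[acc], target_class[acc][0],
           target_class[acc][1] if len(target_class[acc]) > 1 else "", "", 1]
          for n, acc in sorted(remap_table.items())])

    meta_rows = []
    for acc in sorted(meta):
        m = meta[acc]
        meta_rows.append([
            acc, m["tdl"], m["chembl_activity_count"],
            m["selective_compound_count"], m["pathway_count_total"],
            m["synaptic_pathway_count"], m["disease_count"],
            "NA" if m["mp_terms"] is None else ";".join(m["mp_terms"]),
            m["grant_dollars"], m["patent_count"], m["hda_score"],
            str(m["is_tf"]).lower()])
    _tsv("target_meta.tsv",
         ["accession", "tdl", "chembl_activity_count",
          "selective_compound_count", "pathway_count_total",
          "synaptic_pathway_count", "disease_count", "mp_terms",
          "grant_dollars", "patent_count", "hda_score", "is_tf"], meta_rows)
    paths["catalog"] = paths.pop("drug_catalog")
    return paths


def _curate_oracle(cands: list[str], risk: set[str], ranks: dict[str, int],
                   target_class: dict, target_chembl: dict) -> list[str]:
    """Exhaustive application of the two-entry selection rules."""
    def key(a):
        return (0 if a in risk else 1, ranks.get(a, 10**6), a, target_chembl[a])

    best = None
    for a in cands:
        if best is None or key(a) < key(best):
            best = a
    if len(cands) == 1:
        return [best]
    rest = [a for a in cands if a != best]
    diverse = [a for a in rest if target_class[a][0] != target_class[best][0]]
    pool = diverse if diverse else rest
    second = None
    for a in pool:
        if second is None or key(a) < key(second):
            second = a
    return [best, second]


def _enumerate_manifest(config, evidence_rows, genes, listings,
                        risk_accessions, classes_of_acc, gene_gw_sources,
                        n_gw_rows_by_acc, planted, drug_targets, drug_rank,
                        target_class, target_chembl, target_complex,
                        microbial_names, remap_table, trial_names, meta,
                        approved_set) -> dict:
    risk_set = set(risk_accessions)
    druggable = sorted(risk_set & approved_set)

    # evidence-class partition of the druggable set
    part = {"unique_common": [], "unique_rare": [], "unique_expression": [],
            "multi_class": []}
    for acc in druggable:
        cl = classes_of_acc[acc]
        if cl == frozenset({"common"}):
            part["unique_common"].append(acc)
        elif cl == frozenset({"rare"}):
            part["unique_rare"].append(acc)
        elif cl == frozenset({"expression"}):
            part["unique_expression"].append(acc)
        else:
            part["multi_class"].append(acc)

    # drugs hitting the druggable set
    drugs_hit = sorted(n for n, t in drug_targets.items()
                       if set(t) & set(druggable))

    # trial drugs: human target sets after microbial remapping
    trial_targets_by_drug: dict[str, list[str]] = {}
    excluded = []
    for name in trial_names:
        if name in microbial_names:
            if name in remap_table:
                trial_targets_by_drug[name] = [remap_table[name]]
            else:
                excluded.append(name)
        else:
            trial_targets_by_drug[name] = list(drug_targets[name])
    trial_target_accs = sorted({a for t in trial_targets_by_drug.values()
                                for a in t})
    supported = sorted(set(trial_target_accs) & risk_set)

    # curated class entries per retained drug (exhaustive rule oracle)
    curated: dict[str, list[list[str]]] = {}
    dpt: dict[str, int] = {}
    for name in sorted(trial_targets_by_drug):
        accs = trial_targets_by_drug[name]
        seen, cands = set(), []
        for a in accs:  # consolidate complex subunits
            k = (target_complex.get(a) or target_chembl.get(a, a),
                 target_class.get(a, ("enzyme",)))
            if k not in seen:
                seen.add(k)
                cands.append(a)
        ranks = drug_rank.get(name, {})
        chembl = {a: target_chembl.get(a, a) for a in cands}
        chosen = _curate_oracle(cands, risk_set, ranks, target_class, chembl)
        curated[name] = [[a, _display_class(target_class[a])] for a in chosen]
        for a, cls in curated[name]:
            dpt[f"{a}|{cls}"] = dpt.get(f"{a}|{cls}", 0) + 1

    n_retained = len(trial_targets_by_drug)
    mean_entries = (sum(len(v) for v in curated.values()) / n_retained
                    if n_retained else 0.0)

    status_rp = sorted(set(druggable) & set(trial_target_accs))
    status_clin = sorted(set(druggable) - set(trial_target_accs))

    genetic_dist: dict[str, int] = {}
    for acc in druggable:
        cls = _display_class(target_class[acc])
        genetic_dist[cls] = genetic_dist.get(cls, 0) + 1
    trial_dist: dict[str, int] = {}
    for key, n in dpt.items():
        cls = key.split("|", 1)[1]
        trial_dist[cls] = trial_dist.get(cls, 0) + n

    # genome-wide subset and TDL labels
    gw_accs = sorted(gene_gw_sources)
    per_source = {s: sorted(a for a, src in gene_gw_sources.items() if s in src)
                  for s in ("GWAS", "TWAS", "CNV")}
    tdl_of: dict[str, str] = {}
    for acc in gw_accs:
        if acc in approved_set:
            tdl_of[acc] = ("Tclin_RP" if acc in set(trial_target_accs)
                           else "Tclin")
        else:
            tdl_of[acc] = meta[acc]["tdl"]
    tdl_counts: dict[str, int] = {l: 0 for l in
                                  ("Tclin_RP", "Tclin", "Tchem", "Tbio", "Tdark")}
    for acc in gw_accs:
        tdl_counts[tdl_of[acc]] += 1

    def _neuro(acc) -> int | None:
        terms = meta[acc]["mp_terms"]
        if terms is None:
            return None
        return sum(1 for t in _INDEX_MP if t in terms)

    n_chembl = sum(1 for a in gw_accs if meta[a]["chembl_activity_count"] > 0)
    n_neuro = sum(1 for a in gw_accs if _neuro(a) in (1, 2))
    n_synaptic = sum(1 for a in gw_accs if meta[a]["synaptic_pathway_count"] >= 1)

    tdark_neuro = sorted(a for a in gw_accs
                         if tdl_of[a] == "Tdark" and _neuro(a) in (1, 2))
    tdark_neuro_multi = sorted(a for a in tdark_neuro
                               if len(gene_gw_sources[a]) >= 2)
    low_hda = sorted(a for a in gw_accs if meta[a]["hda_score"] < 10.0)
    n_tf = sum(1 for a in gw_accs if meta[a]["is_tf"])
    n_tf_neuro = sum(1 for a in gw_accs
                     if meta[a]["is_tf"] and _neuro(a) in (1, 2))

    inter = {
        "GWAS&TWAS": sorted(set(per_source["GWAS"]) & set(per_source["TWAS"])),
        "GWAS&CNV": sorted(set(per_source["GWAS"]) & set(per_source["CNV"])),
        "TWAS&CNV": sorted(set(per_source["TWAS"]) & set(per_source["CNV"])),
        "GWAS&TWAS&CNV": sorted(set(per_source["GWAS"])
                                & set(per_source["TWAS"])
                                & set(per_source["CNV"])),
    }

    return {
        "config_seed": config.seed,
        "n_evidence_rows": len(evidence_rows),
        "listings_per_class": listings,
        "n_unique_genes": len(risk_accessions),
        "genome_wide": {
            "n_unique": len(gw_accs),
            "per_source": {s: len(v) for s, v in per_source.items()},
        },
        "druggable": {
            "genes": druggable,
            "n_genes": len(druggable),
            "drugs": drugs_hit,
            "n_drugs": len(drugs_hit),
        },
        "partition": {k: sorted(v) for k, v in part.items()},
        "partition_sizes": {k: len(v) for k, v in part.items()},
        "trial": {
            "n_drugs": len(trial_names),
            "excluded": sorted(excluded),
            "n_excluded": len(excluded),
            "target_accessions": trial_target_accs,
            "n_targets": len(trial_target_accs),
            "supported_targets": supported,
            "n_supported": len(supported),
            "curated": curated,
            "drugs_per_target": dpt,
            "mean_curated_entries_per_drug": mean_entries,
        },
        "status_counts": {
            "T_clinical_repurposing": len(status_rp),
            "T_clinical": len(status_clin),
        },
        "class_distribution_genetic": genetic_dist,
        "class_distribution_trial": trial_dist,
        "tdl_counts": tdl_counts,
        "tier_counts": {"chembl": n_chembl, "neurophenotype": n_neuro,
                        "synaptic": n_synaptic},
        "shortlist_tdark_neuro": {"members": tdark_neuro,
                                  "multi_source": tdark_neuro_multi},
        "shortlist_low_hda": low_hda,
        "intersections": {k: len(v) for k, v in inter.items()},
        "tf_summary": {"n_tf": n_tf, "n_tf_neuro": n_tf_neuro},
        "n_priority_rows": sum(n_gw_rows_by_acc.get(a, 0) for a in gw_accs),
    }
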