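"""Target development levels and multi-axis prioritization.

Every genome-wide significant risk gene is placed on the IDG target
development ladder -- Tclin (approved-drug mechanism-of-action target),
Tchem (potent small-molecule binder known), Tbio (bioactivity evidence),
Tdark (unexplored) -- extended with Tclin_RP for Tclin targets already
hit by a schizophrenia repurposing-trial drug.  Per-target IDG metadata
(ChEMBL activity, synaptic pathway counts, mouse neurophenotypes,
Harmonizome data-availability score, grant/patent metrics) then drives
the prioritization table and the shortlists of underexplored targets.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from ._vocab import (DRUGGABLE_GENOME_SIZE, NEURO_INDEX_TERMS,
                     TOTAL_GENOME_SIZE)
from .evidence import SOURCE_OF_KIND, GeneEntity, neglog_p

logger = logging.getLogger(__name__)

__all__ = [
    "TDLLabel",
    "TargetMeta",
    "PriorityRecord",
    "parse_target_meta",
    "assign_tdl",
    "tdl_distribution",
    "neurophenotype_score",
    "build_priority_table",
    "annotation_tier_counts",
    "shortlist_tdark_neuro",
    "shortlist_low_hda",
    "multi_source_intersection",
    "transcription_factor_summary",
]


class TDLLabel(str, enum.Enum):
    """Target development level, ordered by decreasing characterization."""

    TCLIN_RP = "Tclin_RP"
    TCLIN = "Tclin"
    TCHEM = "Tchem"
    TBIO = "Tbio"
    TDARK = "Tdark"


_TDL_PRECEDENCE = {l: i for i, l in enumerate(TDLLabel)}
_BASE_LABELS = {l.value: l for l in (TDLLabel.TCLIN, TDLLabel.TCHEM,
                                     TDLLabel.TBIO, TDLLabel.TDARK)}
_MP_RE = re.compile(r"^MP:\d{7}$")

#: sentinel for "no mouse phenotype data available" (distinct from an
#: empty phenotype set, which would mean data with no terms)
NO_PHENOTYPE_DATA = None


@dataclass(frozen=True)
class TargetMeta:
    """IDG-style per-target metadata consumed (never computed) here."""

    accession: str
    tdl_base: TDLLabel
    chembl_activity_count: int = 0
    selective_compound_count: int = 0
    pathway_count_total: int = 0
    synaptic_pathway_count: int = 0
    disease_count: int = 0
    mouse_phenotype_terms: frozenset[str] | None = NO_PHENOTYPE_DATA
    grant_dollars: float = 0.0
    patent_count: int = 0
    hda_score: float | None = None
    is_transcription_factor: bool = False


META_COLUMNS = (
    "accession", "tdl", "chembl_activity_count", "selective_compound_count",
    "pathway_count_total", "synaptic_pathway_count", "disease_count",
    "mp_terms", "grant_dollars", "patent_count", "hda_score", "is_tf",
)


def parse_target_meta(source: str | Path) -> dict[str, TargetMeta]:
    """Load the per-target metadata TSV keyed by accession."""
    df = pd.read_csv(Path(source), sep="\t", dtype=str,
                     keep_default_na=False, na_values=[""])
    missing = [c for c in ("accession", "tdl") if c not in df.columns]
    if missing:
        raise ValueError(f"metadata missing column(s): {', '.join(missing)}")
    out: dict[str, TargetMeta] = {}
    for _, row in df.iterrows():
        terms: frozenset[str] | None
        raw = row.get("mp_terms")
        if pd.isna(raw) or str(raw).strip() in {"NA", "na"}:
            terms = NO_PHENOTYPE_DATA
        else:
            parsed = []
            for t in str(raw).split(";"):
                t = t.strip()
                if not t:
                    continue
                if _MP_RE.match(t):
                    parsed.append(t)
                else:
                    logger.warning("ignoring malformed MP term %r for %s",
                                   t, row["accession"])
            terms = frozenset(parsed)

        def _int(col, default=0):
            v = row.get(col)
            return int(float(v)) if pd.notna(v) else default

        hda = float(row["hda_score"]) if pd.notna(row.get("hda_score")) else None
        out[str(row["accession"]).strip()] = TargetMeta(
            accession=str(row["accession"]).strip(),
            tdl_base=_BASE_LABELS[str(row["tdl"]).strip()],
            chembl_activity_count=_int("chembl_activity_count"),
            selective_compound_count=_int("selective_compound_count"),
            pathway_count_total=_int("pathway_count_total"),
            synaptic_pathway_count=_int("synaptic_pathway_count"),
            disease_count=_int("disease_count"),
            mouse_phenotype_terms=terms,
            grant_dollars=float(row["grant_dollars"]) if pd.notna(row.get("grant_dollars")) else 0.0,
            patent_count=_int("patent_count"),
            hda_score=hda,
            is_transcription_factor=str(row.get("is_tf", "")).strip().lower()
            in {"true", "1", "yes"},
        )
    return out


def assign_tdl(
    meta: TargetMeta,
    approved_target_accessions: set[str],
    trial_target_accessions: set[str],
) -> TDLLabel:
    """Assign the (extended) target development level for one target.

    Approved-set membership takes precedence over the base label: a
    target of an approved drug is Tclin, promoted to Tclin_RP when it is
    also a repurposing-trial target.  Otherwise the base label stands.
    """
    acc = meta.accession
    if acc in approved_target_accessions:
        if acc in trial_target_accessions:
            return TDLLabel.TCLIN_RP
        return TDLLabel.TCLIN
    if meta.tdl_base is TDLLabel.TCLIN:
        # stale snapshot: metadata says Tclin but the catalog disagrees;
        # approved-set membership wins, so demote to Tchem
        logger.info("metadata lists %s as Tclin but it is not an approved-drug "
                    "target; demoting to Tchem", acc)
        return TDLLabel.TCHEM
    return meta.tdl_base


def tdl_distribution(
    entities: dict[str, GeneEntity],
    labels: dict[str, TDLLabel],
) -> pd.DataFrame:
    """Counts and integer percentages per TDL, with genome background rows."""
    n = len(entities)
    rows = []
    for label in TDLLabel:
        c = sum(1 for acc in entities if labels[acc] is label)
        rows.append({"label": label.value, "count": c,
                     "percent": round(100 * c / n) if n else 0,
                     "fraction": c / n if n else 0.0})
    rows.append({"label": "T_druggable_background", "count": DRUGGABLE_GENOME_SIZE,
                 "percent": None, "fraction": None})
    rows.append({"label": "T_total_background", "count": TOTAL_GENOME_SIZE,
                 "percent": None, "fraction": None})
    return pd.DataFrame(rows, columns=["label", "count", "percent", "fraction"])


def neurophenotype_score(terms: frozenset[str] | None) -> int | None:
    """Count of the two neurophenotype index terms present (0-2), or None.

    None (no mouse phenotype data at all) is distinct from 0 (phenotype
    data exists but neither index term is annotated).  Monotone in the
    index-term subset and invariant to non-index terms.
    """
    if terms is NO_PHENOTYPE_DATA:
        return None
    return len(NEURO_INDEX_TERMS & terms)


@dataclass
class PriorityRecord:
    """One row of the prioritization table: gene x source x panel."""

    accession: str
    symbol: str
    source: str  # GWAS | TWAS | CNV
    study_id: str
    expression_panel: str | None
    neglog_p: float | None
    approved_drug_count: int
    repurposing_status: str | None
    tdl: TDLLabel
    meta: TargetMeta | None
    neurophenotype: int | None

    @property
    def has_meta(self) -> bool:
        return self.meta is not None


def build_priority_table(
    entities: dict[str, GeneEntity],
    catalog_index: dict[str, set[str]],
    meta_table: dict[str, TargetMeta],
    labels: dict[str, TDLLabel],
    status: dict[str, str] | None = None,
    study_whitelist: set[str] | None = None,
) -> list[PriorityRecord]:
    """Cross-reference genome-wide entities with all prioritization axes.

    One record per entity x genome-wide association (source/panel);
    targets with no metadata are flagged (``meta is None``) rather than
    imputed to zero.
    """
    status = status or {}
    records: list[PriorityRecord] = []
    for acc in sorted(entities):
        ent = entities[acc]
        meta = meta_table.get(acc)
        if meta is None:
            logger.info("no metadata for %s; metrics null", acc)
        neuro = neurophenotype_score(meta.mouse_phenotype_terms) if meta else None
        for a in sorted(ent.associations,
                        key=lambda a: (a.study_id, a.expression_panel or "")):
            if not a.genome_wide:
                continue
            if study_whitelist is not None and a.study_id not in study_whitelist:
                continue
            records.append(PriorityRecord(
                accession=acc,
                symbol=min(ent.symbols),
                source=SOURCE_OF_KIND[a.analysis_kind],
                study_id=a.study_id,
                expression_panel=a.expression_panel,
                neglog_p=neglog_p(a.p_value) if a.p_value is not None else None,
                approved_drug_count=len(catalog_index.get(acc, ())),
                repurposing_status=status.get(acc),
                tdl=labels[acc],
                meta=meta,
                neurophenotype=neuro,
            ))
    return records


def _unique_by_gene(table: list[PriorityRecord]) -> dict[str, PriorityRecord]:
    uniq: dict[str, PriorityRecord] = {}
    for rec in table:
        uniq.setdefault(rec.accession, rec)
    return uniq


def annotation_tier_counts(table: list[PriorityRecord]) -> tuple[int, int, int]:
    """Unique genes with ChEMBL activity, neurophenotypes, synaptic pathways.

    Counts genes with activity count > 0, neurophenotype score in {1, 2},
    and at least one synaptic pathway annotation.  Missing metadata never
    contributes (null is not zero).
    """
    uniq = _unique_by_gene(table)
    n_chembl = sum(1 for r in uniq.values()
                   if r.meta and r.meta.chembl_activity_count > 0)
    n_neuro = sum(1 for r in uniq.values() if r.neurophenotype in (1, 2))
    n_synaptic = sum(1 for r in uniq.values()
                     if r.meta and r.meta.synaptic_pathway_count >= 1)
    return n_chembl, n_neuro, n_synaptic


def shortlist_tdark_neuro(table: list[PriorityRecord]) -> pd.DataFrame:
    """Unexplored (Tdark) genes with mouse neurophenotypes.

    ``multi_source`` marks genes implicated by at least two of GWAS,
    TWAS and CNV.
    """
    uniq = _unique_by_gene(table)
    sources: dict[str, set[str]] = {}
    for rec in table:
        sources.setdefault(rec.accession, set()).add(rec.source)
    rows = []
    for acc in sorted(uniq):
        rec = uniq[acc]
        if rec.tdl is TDLLabel.TDARK and rec.neurophenotype in (1, 2):
            rows.append({"accession": acc, "symbol": rec.symbol,
                         "neurophenotype": rec.neurophenotype,
                         "sources": ";".join(sorted(sources[acc])),
                         "multi_source": len(sources[acc]) >= 2})
    return pd.DataFrame(rows, columns=["accession", "symbol", "neurophenotype",
                                       "sources", "multi_source"])


def shortlist_low_hda(table: list[PriorityRecord], threshold: float = 10.0) -> pd.DataFrame:
    """Unique genes with a Harmonizome data-availability score below threshold."""
    uniq = _unique_by_gene(table)
    rows = [{"accession": acc, "symbol": r.symbol, "tdl": r.tdl.value,
             "hda_score": r.meta.hda_score}
            for acc, r in sorted(uniq.items())
            if r.meta and r.meta.hda_score is not None
            and r.meta.hda_score < threshold]
    return pd.DataFrame(rows, columns=["accession", "symbol", "tdl", "hda_score"])


def multi_source_intersection(
    entities: dict[str, GeneEntity],
    study_whitelist: set[str] | None = None,
) -> dict[str, set[str]]:
    """Genes shared between the genome-wide evidence sources.

    Returns per-source gene sets plus all pairwise intersections and the
    triple intersection, keyed e.g. ``"GWAS&TWAS"`` and ``"GWAS&TWAS&CNV"``.
    """
    per_source: dict[str, set[str]] = {"GWAS": set(), "TWAS": set(), "CNV": set()}
    for acc, ent in entities.items():
        for a in ent.associations:
            if not a.genome_wide:
                continue
            if study_whitelist is not None and a.study_id not in study_whitelist:
                continue
            per_source[SOURCE_OF_KIND[a.analysis_kind]].add(acc)
    out = dict(per_source)
    out["GWAS&TWAS"] = per_source["GWAS"] & per_source["TWAS"]
    out["GWAS&CNV"] = per_source["GWAS"] & per_source["CNV"]
    out["TWAS&CNV"] = per_source["TWAS"] & per_source["CNV"]
    out["GWAS&TWAS&CNV"] = (per_source["GWAS"] & per_source["TWAS"]
                            & per_source["CNV"])
    return out


def transcription_factor_summary(table: list[PriorityRecord]) -> tuple[int, int]:
    """(unique TF genes, TF genes with a mouse neurophenotype)."""
    uniq = _unique_by_gene(table)
    tfs = [r for r in uniq.values()
           if r.meta and r.meta.is_transcription_factor]
    n_tf = len(tfs)
    n_tf_neuro = sum(1 for r in tfs if r.neurophenotype in (1, 2))
    return n_tf, n_tf_neuro


def priority_table_to_frame(table: list[PriorityRecord]) -> pd.DataFrame:
    """Flatten priority records for TSV export."""
    rows = []
    for r in table:
        m = r.meta
        rows.append({
            "accession": r.accession, "symbol": r.symbol, "source": r.source,
            "study_id": r.study_id, "expression_panel": r.expression_panel or "",
            "neglog_p": r.neglog_p, "approved_drug_count": r.approved_drug_count,
            "repurposing_status": r.repurposing_status or "",
            "tdl": r.tdl.value,
            "chembl_activity_count": m.chembl_activity_count if m else None,
            "selective_compound_count": m.selective_compound_count if m else None,
            "pathway_count_total": m.pathway_count_total if m else None,
            "synaptic_pathway_count": m.synaptic_pathway_count if m else None,
            "disease_count": m.disease_count if m else None,
            "neurophenotype": r.neurophenotype if r.neurophenotype is not None else "NA",
            "grant_dollars": m.grant_dollars if m else None,
            "patent_count": m.patent_count if m else None,
            "hda_score": m.hda_score if m else None,
            "is_tf": m.is_transcription_factor if m else None,
        })
    return pd.DataFrame(rows)
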