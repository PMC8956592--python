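"""Ingest, accession-mapping and merging of risk-gene association lists.

Risk genes arrive as per-study tables from three evidence classes --
common variation (GWAS/PheWAS), rare variation (CNV/exome) and gene
expression (TWAS/expression profiling).  Gene symbols are normalised and
mapped to protein accessions, associations sharing an accession are merged
into one entity, and the genome-wide significant subset is isolated for
downstream prioritization.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

__all__ = [
    "EvidenceClass",
    "AnalysisKind",
    "GeneAssociation",
    "GeneEntity",
    "EVIDENCE_CLASS_OF",
    "parse_evidence_table",
    "map_to_accessions",
    "merge_by_accession",
    "genome_wide_subset",
    "neglog_p",
]


class EvidenceClass(str, enum.Enum):
    """Source class of a genetic association."""

    COMMON = "common"
    RARE = "rare"
    EXPRESSION = "expression"


class AnalysisKind(str, enum.Enum):
    GWAS = "GWAS"
    PHEWAS = "PheWAS"
    CNV = "CNV"
    EXOME = "exome"
    TWAS = "TWAS"
    EXPRESSION_PROFILING = "expression_profiling"


# The evidence class is a deterministic function of the analysis type.
EVIDENCE_CLASS_OF: dict[AnalysisKind, EvidenceClass] = {
    AnalysisKind.GWAS: EvidenceClass.COMMON,
    AnalysisKind.PHEWAS: EvidenceClass.COMMON,
    AnalysisKind.CNV: EvidenceClass.RARE,
    AnalysisKind.EXOME: EvidenceClass.RARE,
    AnalysisKind.TWAS: EvidenceClass.EXPRESSION,
    AnalysisKind.EXPRESSION_PROFILING: EvidenceClass.EXPRESSION,
}


@dataclass(frozen=True)
class GeneAssociation:
    """One row of a risk-gene list: a gene implicated by one study.

    ``accession`` is absent until symbol-to-accession mapping has run;
    ``mapping_provenance`` records how a one-to-many symbol mapping was
    expanded.  ``genome_wide`` marks associations reported at genome-wide
    significance by their study.
    """

    gene_symbol: str
    analysis_kind: AnalysisKind
    study_id: str
    p_value: float | None = None
    expression_panel: str | None = None
    genome_wide: bool = False
    accession: str | None = None
    mapping_provenance: str | None = None

    @property
    def evidence_class(self) -> EvidenceClass:
        return EVIDENCE_CLASS_OF[self.analysis_kind]


@dataclass
class GeneEntity:
    """A merged risk gene keyed by protein accession."""

    accession: str
    symbols: set[str]
    associations: list[GeneAssociation] = field(default_factory=list)

    @property
    def evidence_classes(self) -> set[EvidenceClass]:
        return {a.evidence_class for a in self.associations}

    @property
    def significance_by_study(self) -> dict[str, list[float]]:
        """P values per study, one entry per TWAS panel where applicable."""
        out: dict[str, list[float]] = {}
        for a in self.associations:
            if a.p_value is not None:
                out.setdefault(a.study_id, []).append(a.p_value)
        return out

    def min_p(self, study_id: str) -> float | None:
        """Minimum P within one study (used for within-study ranking only)."""
        ps = self.significance_by_study.get(study_id)
        return min(ps) if ps else None


REQUIRED_COLUMNS = (
    "gene_symbol",
    "analysis_kind",
    "study_id",
    "p_value",
    "expression_panel",
    "genome_wide",
)


class SchemaError(ValueError):
    """A required column is missing from an input table."""


def _normalise_symbol(symbol: str) -> str:
    return str(symbol).strip().upper()


def _read_table(source: str | Path) -> pd.DataFrame:
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".xlsx", ".xlsm"}:
        return pd.read_excel(path, dtype=str)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                       na_values=[""])


_TRUE = {"true", "1", "yes", "y", "t"}
_FALSE = {"false", "0", "no", "n", "f", ""}


def parse_evidence_table(
    source: str | Path,
    schema: dict[str, str] | None = None,
) -> tuple[list[GeneAssociation], pd.DataFrame]:
    """Parse a risk-gene table into associations plus a rejects report.

    Parameters
    ----------
    source
        TSV/CSV/xlsx file with the columns in :data:`REQUIRED_COLUMNS`
        (an optional ``accession`` column bypasses symbol mapping).
    schema
        Optional mapping from canonical column name to the column name
        used in the file.

    Returns
    -------
    (associations, rejects)
        Rows failing validation are collected in the rejects frame with a
        ``reject_reason`` column rather than silently dropped.
    """
    df = _read_table(source)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    associations: list[GeneAssociation] = []
    rejects: list[dict] = []
    seen: set[tuple] = set()
    for _, row in df.iterrows():
        reason = None
        symbol = _normalise_symbol(row["gene_symbol"]) if pd.notna(row["gene_symbol"]) else ""
        if not symbol:
            reason = "empty gene_symbol"
        kind = None
        if reason is None:
            try:
                kind = AnalysisKind(str(row["analysis_kind"]).strip())
            except ValueError:
                reason = f"unknown analysis_kind {row['analysis_kind']!r}"
        p: float | None = None
        if reason is None and pd.notna(row["p_value"]):
            try:
                p = float(row["p_value"])
            except (TypeError, ValueError):
                reason = f"unparseable p_value {row['p_value']!r}"
            else:
                if not (0.0 < p <= 1.0):
                    reason = f"p_value out of (0,1]: {p}"
        if reason is None:
            gw_raw = str(row["genome_wide"]).strip().lower()
            if gw_raw in _TRUE:
                gw = True
            elif gw_raw in _FALSE or pd.isna(row["genome_wide"]):
                gw = False
            else:
                reason = f"unparseable genome_wide flag {row['genome_wide']!r}"
        if reason is not None:
            rec = row.to_dict()
            rec["reject_reason"] = reason
            rejects.append(rec)
            continue

        panel = row["expression_panel"] if pd.notna(row["expression_panel"]) else None
        assoc = GeneAssociation(
            gene_symbol=symbol,
            analysis_kind=kind,
            study_id=str(row["study_id"]).strip(),
            p_value=p,
            expression_panel=panel,
            genome_wide=gw,
            accession=(str(row["accession"]).strip()
                       if "accession" in df.columns and pd.notna(row.get("accession"))
                       else None),
        )
        # Duplicated (gene, study, panel) rows collapse with a warning.
        key = (assoc.gene_symbol, assoc.study_id, assoc.expression_panel,
               assoc.analysis_kind)
        if key in seen:
            rec = row.to_dict()
            rec["reject_reason"] = "duplicate row (gene, study, panel) collapsed"
            rejects.append(rec)
            continue
        seen.add(key)
        associations.append(assoc)

    reject_df = pd.DataFrame(rejects, columns=list(df.columns) + ["reject_reason"])
    return associations, reject_df


def map_to_accessions(
    associations: list[GeneAssociation],
    mapping: pd.DataFrame,
) -> tuple[list[GeneAssociation], pd.DataFrame]:
    """Attach protein accessions to associations via a symbol table.

    ``mapping`` needs columns ``gene_symbol`` and ``accession``; a symbol
    mapping to several accessions expands to one association per accession
    with the expansion recorded in ``mapping_provenance``.  Associations
    that already carry an accession pass through unchanged.

    Returns the mapped associations and an unmapped report (one row per
    association whose symbol is absent from the table).
    """
    if mapping is None or mapping.empty:
        raise ValueError("empty symbol-to-accession mapping table")
    table: dict[str, list[str]] = {}
    for _, row in mapping.iterrows():
        table.setdefault(_normalise_symbol(row["gene_symbol"]), []).append(
            str(row["accession"]).strip()
        )

    mapped: list[GeneAssociation] = []
    unmapped: list[dict] = []
    for assoc in associations:
        if assoc.accession:
            mapped.append(assoc)
            continue
        accs = table.get(assoc.gene_symbol)
        if not accs:
            unmapped.append({
                "gene_symbol": assoc.gene_symbol,
                "study_id": assoc.study_id,
                "analysis_kind": assoc.analysis_kind.value,
                "reason": "symbol not in mapping table",
            })
            continue
        uniq = sorted(set(accs))
        for acc in uniq:
            prov = None if len(uniq) == 1 else f"1:{len(uniq)} expansion of {assoc.gene_symbol}"
            mapped.append(replace(assoc, accession=acc, mapping_provenance=prov))
    report = pd.DataFrame(
        unmapped, columns=["gene_symbol", "study_id", "analysis_kind", "reason"]
    )
    return mapped, report


def merge_by_accession(associations: list[GeneAssociation]) -> dict[str, GeneEntity]:
    """Merge accession-mapped associations into one entity per accession.

    Idempotent and order-independent: the entity set depends only on the
    set of associations.  Raises if any association is still unmapped.
    """
    entities: dict[str, GeneEntity] = {}
    for assoc in associations:
        if not assoc.accession:
            raise ValueError(
                f"unmapped association for {assoc.gene_symbol}; run map_to_accessions first"
            )
        ent = entities.get(assoc.accession)
        if ent is None:
            ent = GeneEntity(accession=assoc.accession, symbols=set())
            entities[assoc.accession] = ent
        ent.symbols.add(assoc.gene_symbol)
        if assoc not in ent.associations:
            ent.associations.append(assoc)
    return entities


#: analysis kinds whose genome-wide associations feed each prioritization
#: source axis
SOURCE_OF_KIND = {
    AnalysisKind.GWAS: "GWAS",
    AnalysisKind.PHEWAS: "GWAS",
    AnalysisKind.TWAS: "TWAS",
    AnalysisKind.EXPRESSION_PROFILING: "TWAS",
    AnalysisKind.CNV: "CNV",
    AnalysisKind.EXOME: "CNV",
}


def genome_wide_subset(
    entities: dict[str, GeneEntity],
    study_whitelist: set[str],
) -> tuple[dict[str, GeneEntity], dict[str, int]]:
    """Restrict to entities with a genome-wide hit from a whitelisted study.

    Returns the subset plus per-source unique-gene counts (GWAS/TWAS/CNV).
    """
    if not study_whitelist:
        raise ValueError("study whitelist must be non-empty")
    subset: dict[str, GeneEntity] = {}
    per_source: dict[str, set[str]] = {"GWAS": set(), "TWAS": set(), "CNV": set()}
    for acc, ent in entities.items():
        hits = [a for a in ent.associations
                if a.genome_wide and a.study_id in study_whitelist]
        if not hits:
            continue
        subset[acc] = ent
        for a in hits:
            per_source[SOURCE_OF_KIND[a.analysis_kind]].add(acc)
    counts = {src: len(accs) for src, accs in per_source.items()}
    return subset, counts


def neglog_p(p: float) -> float:
    """-log10 transform of a P value; defined on (0, 1]."""
    if not (0.0 < p <= 1.0):
        raise ValueError(f"p must be in (0, 1], got {p}")
    return -math.log10(p)


def entities_to_frame(entities: dict[str, GeneEntity]) -> pd.DataFrame:
    """Export merged entities, one row per accession x study x panel."""
    rows = []
    for acc in sorted(entities):
        ent = entities[acc]
        for a in sorted(ent.associations,
                        key=lambda a: (a.study_id, a.expression_panel or "", a.gene_symbol)):
            rows.append({
                "accession": acc,
                "gene_symbol": a.gene_symbol,
                "evidence_class": a.evidence_class.value,
                "analysis_kind": a.analysis_kind.value,
                "study_id": a.study_id,
                "expression_panel": a.expression_panel or "",
                "p_value": a.p_value,
                "genome_wide": a.genome_wide,
                "mapping_provenance": a.mapping_provenance or "",
            })
    return pd.DataFrame(rows, columns=[
        "accession", "gene_symbol", "evidence_class", "analysis_kind",
        "study_id", "expression_panel", "p_value", "genome_wide",
        "mapping_provenance",
    ])
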