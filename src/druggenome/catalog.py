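"""Approved-drug target catalog and clinical-trial drug curation.

The approved-drug catalog links each drug to its efficacy targets (protein
accession, ChEMBL target id, protein-class hierarchy).  Trial drugs are
annotated from the same catalog and then curated: drugs with only
microbial targets are remapped through a human mechanism-of-action table
or excluded, subunit annotations of one target complex are consolidated,
and for multi-target drugs at most two protein-class entries are retained
by a fixed priority (risk-gene match, primary therapeutic relevance,
mechanistic diversity; ties broken lexicographically).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinClassPath",
    "TargetAnnotation",
    "DrugRecord",
    "TrialDrugRecord",
    "parse_drug_catalog",
    "parse_trial_list",
    "index_by_accession",
    "annotate_trial_drugs",
    "remap_microbial",
    "consolidate_subunits",
    "curate_multi_target",
    "drugs_per_target",
]

_PUNCT = re.compile(r"[^a-z0-9]+")


def normalise_drug_name(name: str) -> str:
    """Case-insensitive, punctuation-stripped drug-name key."""
    return _PUNCT.sub("", str(name).lower())


@dataclass(frozen=True)
class ProteinClassPath:
    """Ordered protein-class labels, broadest first."""

    levels: tuple[str, ...]

    def __post_init__(self):
        if not self.levels:
            raise ValueError("protein class path must be non-empty")

    @property
    def level1(self) -> str:
        return self.levels[0]

    def display_class(self) -> str:
        """Level-1 class, with 7TM receptors broken out."""
        if self.level1 == "membrane receptor" and len(self.levels) > 1 \
                and "7TM" in self.levels[1]:
            return "membrane receptor:7TM"
        return self.level1


@dataclass(frozen=True)
class TargetAnnotation:
    """One efficacy-target annotation of a drug."""

    accession: str
    chembl_target_id: str
    protein_class: ProteinClassPath
    organism: str = "human"  # human | microbial | other
    complex_id: str | None = None

    def __post_init__(self):
        if self.organism == "human" and not self.accession:
            raise ValueError("human target annotation requires an accession")

    def sort_key(self) -> tuple[str, str]:
        return (self.accession, self.chembl_target_id)


@dataclass
class DrugRecord:
    """An approved drug with its efficacy-target annotations."""

    drug_name: str
    molecule_type: str
    moa: str = ""
    atc_codes: list[str] = field(default_factory=list)
    approval_year: int | None = None
    targets: list[TargetAnnotation] = field(default_factory=list)
    therapeutic_rank: dict[str, int] = field(default_factory=dict)  # accession -> rank


@dataclass
class TrialDrugRecord:
    """A repurposing-trial drug through the curation stages."""

    drug_name: str
    trial_weight: int = 1
    raw_targets: list[TargetAnnotation] = field(default_factory=list)
    curated_class_entries: list[tuple[TargetAnnotation, str]] = field(default_factory=list)
    excluded: bool = False
    exclusion_reason: str | None = None
    therapeutic_rank: dict[str, int] = field(default_factory=dict)

    def human_targets(self) -> list[TargetAnnotation]:
        return [t for t in self.raw_targets if t.organism == "human"]


CATALOG_COLUMNS = (
    "drug_name", "molecule_type", "moa", "accession", "chembl_target_id",
    "class_l1", "class_l2", "class_l3", "organism", "complex_id", "atc",
    "approval_year", "therapeutic_rank",
)


def _class_path(row) -> ProteinClassPath:
    levels = [str(row[c]).strip() for c in ("class_l1", "class_l2", "class_l3")
              if pd.notna(row.get(c)) and str(row[c]).strip()]
    return ProteinClassPath(tuple(levels))


def parse_drug_catalog(source: str | Path) -> list[DrugRecord]:
    """Load the approved-drug target-efficacy catalog from TSV.

    One input row per (drug, target); targets are grouped under each drug.
    A drug appearing with conflicting molecule types is a hard error.
    """
    path = Path(source)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     na_values=[""])
    missing = [c for c in ("drug_name", "molecule_type", "accession",
                           "chembl_target_id", "class_l1", "organism")
               if c not in df.columns]
    if missing:
        raise ValueError(f"catalog missing column(s): {', '.join(missing)}")

    records: dict[str, DrugRecord] = {}
    for _, row in df.iterrows():
        key = normalise_drug_name(row["drug_name"])
        rec = records.get(key)
        if rec is None:
            rec = DrugRecord(
                drug_name=str(row["drug_name"]).strip(),
                molecule_type=str(row["molecule_type"]).strip(),
                moa=str(row["moa"]).strip() if pd.notna(row.get("moa")) else "",
                atc_codes=str(row["atc"]).split(";") if pd.notna(row.get("atc")) else [],
                approval_year=(int(float(row["approval_year"]))
                               if pd.notna(row.get("approval_year")) else None),
            )
            records[key] = rec
        elif rec.molecule_type != str(row["molecule_type"]).strip():
            raise ValueError(
                f"drug {rec.drug_name!r} listed with conflicting molecule types"
            )
        organism = str(row["organism"]).strip().lower()
        accession = str(row["accession"]).strip() if pd.notna(row["accession"]) else ""
        ann = TargetAnnotation(
            accession=accession,
            chembl_target_id=str(row["chembl_target_id"]).strip(),
            protein_class=_class_path(row),
            organism=organism,
            complex_id=(str(row["complex_id"]).strip()
                        if pd.notna(row.get("complex_id")) else None),
        )
        rec.targets.append(ann)
        if pd.notna(row.get("therapeutic_rank")) and accession:
            rec.therapeutic_rank[accession] = int(float(row["therapeutic_rank"]))
    return list(records.values())


def parse_trial_list(source: str | Path) -> pd.DataFrame:
    """Load the clinical repurposing trial drug list (drug_name, n_trial_listings)."""
    df = pd.read_csv(Path(source), sep="\t", dtype=str)
    if "drug_name" not in df.columns:
        raise ValueError("trial list missing drug_name column")
    if "n_trial_listings" not in df.columns:
        df["n_trial_listings"] = "1"
    return df


def index_by_accession(catalog: list[DrugRecord]) -> dict[str, set[str]]:
    """Map human target accession -> set of approved drug names."""
    index: dict[str, set[str]] = {}
    for rec in catalog:
        for ann in rec.targets:
            if ann.organism == "human":
                index.setdefault(ann.accession, set()).add(rec.drug_name)
    return index


def annotate_trial_drugs(
    trial_list: pd.DataFrame,
    catalog: list[DrugRecord],
) -> list[TrialDrugRecord]:
    """Attach catalog target annotations to each trial drug by name."""
    by_name = {normalise_drug_name(r.drug_name): r for r in catalog}
    out: list[TrialDrugRecord] = []
    for _, row in trial_list.iterrows():
        key = normalise_drug_name(row["drug_name"])
        cat = by_name.get(key)
        rec = TrialDrugRecord(
            drug_name=str(row["drug_name"]).strip(),
            trial_weight=int(float(row.get("n_trial_listings", 1) or 1)),
        )
        if cat is not None:
            rec.raw_targets = list(cat.targets)
            rec.therapeutic_rank = dict(cat.therapeutic_rank)
        out.append(rec)
    return out


HUMAN_MOA_COLUMNS = ("drug_name", "accession", "chembl_target_id",
                     "class_l1", "class_l2", "class_l3", "therapeutic_rank")


def remap_microbial(
    trial_drugs: list[TrialDrugRecord],
    human_moa_table: pd.DataFrame,
) -> list[TrialDrugRecord]:
    """Give anti-microbial trial drugs human targets where a MOA source has them.

    Drugs whose raw targets are exclusively non-human gain the human
    annotations listed for them in ``human_moa_table`` (a DrugBank-style
    mechanism-of-action source).  Drugs left without any human annotation
    are excluded with reason "no human target".  Idempotent.
    """
    moa_by_drug: dict[str, list[tuple[TargetAnnotation, int | None]]] = {}
    if human_moa_table is not None and not human_moa_table.empty:
        for _, row in human_moa_table.iterrows():
            ann = TargetAnnotation(
                accession=str(row["accession"]).strip(),
                chembl_target_id=str(row["chembl_target_id"]).strip(),
                protein_class=_class_path(row),
                organism="human",
            )
            rank = (int(float(row["therapeutic_rank"]))
                    if pd.notna(row.get("therapeutic_rank")) else None)
            moa_by_drug.setdefault(normalise_drug_name(row["drug_name"]), []).append(
                (ann, rank))

    out: list[TrialDrugRecord] = []
    for drug in trial_drugs:
        if drug.excluded or drug.human_targets():
            out.append(drug)
            continue
        additions = moa_by_drug.get(normalise_drug_name(drug.drug_name), [])
        if additions:
            existing = {t.sort_key() for t in drug.raw_targets}
            for ann, rank in additions:
                if ann.sort_key() not in existing:
                    drug.raw_targets.append(ann)
                if rank is not None:
                    drug.therapeutic_rank[ann.accession] = rank
            logger.info("remapped microbial drug %s to %d human target(s)",
                        drug.drug_name, len(additions))
            out.append(drug)
        else:
            drug.excluded = True
            drug.exclusion_reason = "no human target"
            drug.curated_class_entries = []
            logger.info("excluded trial drug %s: no human target", drug.drug_name)
            out.append(drug)
    return out


def consolidate_subunits(targets: list[TargetAnnotation]) -> list[TargetAnnotation]:
    """Collapse subunit annotations of one target complex to one entry.

    Annotations sharing a ``complex_id`` (falling back to the ChEMBL
    target id when absent) and protein class collapse to the
    lexicographically first representative; input order is otherwise
    preserved.
    """
    seen: set[tuple] = set()
    groups: dict[tuple, TargetAnnotation] = {}
    order: list[tuple] = []
    for ann in targets:
        cid = ann.complex_id or ann.chembl_target_id
        key = (ann.organism, cid, ann.protein_class)
        if key not in seen:
            seen.add(key)
            order.append(key)
            groups[key] = ann
        elif ann.sort_key() < groups[key].sort_key():
            groups[key] = ann
    return [groups[k] for k in order]


def curate_multi_target(
    drug: TrialDrugRecord,
    risk_accessions: set[str],
) -> TrialDrugRecord:
    """Retain at most two protein-class entries for a trial drug.

    Entries are ranked by (1) whether the target accession is a risk
    gene, (2) the primary-therapeutic-relevance rank from the input
    metadata (1 = primary; missing ranks last), (3) lexicographic
    accession then ChEMBL id.  When more than one entry remains after the
    first pick, the second slot prefers a different level-1 protein class
    (mechanistic diversity) at equal precedence within the remaining
    ranking.  Excluded drugs pass through unchanged.
    """
    if drug.excluded:
        return drug
    candidates = consolidate_subunits(drug.human_targets())
    if not candidates:
        drug.excluded = True
        drug.exclusion_reason = "no human target"
        drug.curated_class_entries = []
        return drug

    def rank_key(ann: TargetAnnotation):
        in_risk = ann.accession in risk_accessions
        rank = drug.therapeutic_rank.get(ann.accession, 10**6)
        return (0 if in_risk else 1, rank, ann.accession, ann.chembl_target_id)

    ordered = sorted(candidates, key=rank_key)
    if len(ordered) == 1:
        drug.curated_class_entries = [(ordered[0], "sole target")]
        return drug

    first = ordered[0]
    entries = [(first, _reason(first, drug, risk_accessions))]
    rest = ordered[1:]
    diverse = [a for a in rest if a.protein_class.level1 != first.protein_class.level1]
    second = diverse[0] if diverse else rest[0]
    reason = _reason(second, drug, risk_accessions)
    if second.protein_class.level1 != first.protein_class.level1:
        reason += "; mechanistic diversity"
    entries.append((second, reason))
    drug.curated_class_entries = entries
    return drug


def _reason(ann: TargetAnnotation, drug: TrialDrugRecord,
            risk_accessions: set[str]) -> str:
    if ann.accession in risk_accessions:
        return "risk gene match"
    if drug.therapeutic_rank.get(ann.accession) == 1:
        return "primary therapeutic relevance"
    return "rank order"


def drugs_per_target(trial_drugs: list[TrialDrugRecord]) -> dict[tuple[str, str], int]:
    """Count non-excluded drugs per curated target (accession, class)."""
    counts: dict[tuple[str, str], int] = {}
    for drug in trial_drugs:
        if drug.excluded:
            continue
        for ann, _ in drug.curated_class_entries:
            key = (ann.accession, ann.protein_class.display_class())
            counts[key] = counts.get(key, 0) + 1
    return counts


def trial_target_accessions(trial_drugs: list[TrialDrugRecord]) -> set[str]:
    """All human target accessions mapped by non-excluded trial drugs.

    Uses the full post-remap annotation set (not just the two curated
    class entries), mirroring how the trial pipeline's unique human
    targets are counted before class-level curation.
    """
    out: set[str] = set()
    for drug in trial_drugs:
        if drug.excluded:
            continue
        out.update(t.accession for t in drug.human_targets())
    return out
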