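"""Cross-referencing of risk genes with the drug catalog and trial pipeline.

Produces the druggable risk-gene set, its evidence-class partition,
repurposing-status labels (already in trials vs novel opportunity), and
the protein-class distributions of genetic vs clinical-trial targets.
"""

from __future__ import annotations

import enum
import logging
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .catalog import DrugRecord, TrialDrugRecord, drugs_per_target
from .evidence import EvidenceClass, GeneEntity

logger = logging.getLogger(__name__)

__all__ = [
    "RepurposingStatus",
    "EvidencePartition",
    "ClassDistribution",
    "druggable_genes",
    "partition_by_evidence",
    "repurposing_status",
    "genetically_supported_trial_targets",
    "genetic_distribution",
    "trial_distribution",
    "compare_distributions",
]


class RepurposingStatus(str, enum.Enum):
    """Whether a druggable risk gene is already a repurposing-trial target."""

    T_CLINICAL_REPURPOSING = "T_clinical_repurposing"
    T_CLINICAL = "T_clinical"


@dataclass
class EvidencePartition:
    """Disjoint split of the druggable set by evidence-class membership."""

    unique_common: set[str]
    unique_rare: set[str]
    unique_expression: set[str]
    multi_class: set[str]

    @property
    def sizes(self) -> dict[str, int]:
        return {
            "unique_common": len(self.unique_common),
            "unique_rare": len(self.unique_rare),
            "unique_expression": len(self.unique_expression),
            "multi_class": len(self.multi_class),
        }

    def all_genes(self) -> set[str]:
        return (self.unique_common | self.unique_rare
                | self.unique_expression | self.multi_class)


@dataclass
class ClassDistribution:
    """Protein-class counts/proportions under one weighting.

    ``by_target``: each gene counts once.  ``by_drug``: each retained
    (drug, class entry) pair counts once, so a class's weight reflects
    how many drugs hit it.
    """

    weighting: str  # by_target | by_drug
    entries: dict[str, tuple[int, float]]

    @property
    def proportions(self) -> dict[str, float]:
        return {k: v[1] for k, v in self.entries.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [{"protein_class": k, "count": c, "proportion": p}
                for k, (c, p) in sorted(self.entries.items())]
        return pd.DataFrame(rows, columns=["protein_class", "count", "proportion"])


def druggable_genes(
    entities: dict[str, GeneEntity],
    catalog_index: dict[str, set[str]],
) -> tuple[set[str], set[str]]:
    """Risk genes hit by approved drugs, and the drugs hitting them.

    Returns (accession set, drug-name set).
    """
    genes = {acc for acc in entities if acc in catalog_index}
    drugs: set[str] = set()
    for acc in genes:
        drugs |= catalog_index[acc]
    return genes, drugs


def partition_by_evidence(
    druggable: set[str],
    entities: dict[str, GeneEntity],
) -> EvidencePartition:
    """Assign each druggable gene to its unique evidence class or multi-class."""
    part = EvidencePartition(set(), set(), set(), set())
    buckets = {
        frozenset({EvidenceClass.COMMON}): part.unique_common,
        frozenset({EvidenceClass.RARE}): part.unique_rare,
        frozenset({EvidenceClass.EXPRESSION}): part.unique_expression,
    }
    for acc in druggable:
        classes = frozenset(entities[acc].evidence_classes)
        buckets.get(classes, part.multi_class).add(acc)
    return part


def repurposing_status(
    druggable: set[str],
    trial_target_accessions: set[str],
) -> dict[str, RepurposingStatus]:
    """Label each druggable gene by repurposing-trial membership."""
    return {
        acc: (RepurposingStatus.T_CLINICAL_REPURPOSING
              if acc in trial_target_accessions
              else RepurposingStatus.T_CLINICAL)
        for acc in druggable
    }


def genetically_supported_trial_targets(
    trial_targets: set[str],
    risk_accessions: set[str],
) -> set[str]:
    """Trial targets that are themselves risk genes."""
    return trial_targets & risk_accessions


def gene_class_paths(
    druggable: set[str],
    catalog: list[DrugRecord],
) -> dict[str, str]:
    """One display protein class per druggable gene, from its catalog annotations.

    A gene annotated with conflicting class paths across drugs resolves
    to the most frequent one (ties broken lexicographically), logged.
    """
    paths: dict[str, Counter] = {}
    for rec in catalog:
        for ann in rec.targets:
            if ann.organism == "human" and ann.accession in druggable:
                paths.setdefault(ann.accession, Counter())[
                    ann.protein_class.display_class()] += 1
    out: dict[str, str] = {}
    for acc, counter in paths.items():
        if len(counter) > 1:
            logger.info("gene %s has conflicting class paths %s; using most frequent",
                        acc, dict(counter))
        best = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        out[acc] = best
    return out


def _normalise(counts: Counter) -> dict[str, tuple[int, float]]:
    total = sum(counts.values())
    if total == 0:
        return {}
    return {k: (c, c / total) for k, c in counts.items()}


def genetic_distribution(
    druggable: set[str],
    catalog: list[DrugRecord],
) -> ClassDistribution:
    """Protein-class distribution of druggable risk genes (each gene once)."""
    classes = gene_class_paths(druggable, catalog)
    counts = Counter(classes.values())
    return ClassDistribution("by_target", _normalise(counts))


def trial_distribution(trial_drugs: list[TrialDrugRecord]) -> ClassDistribution:
    """Protein-class distribution of trial targets, weighted by drug count."""
    counts: Counter = Counter()
    for (_, cls), n in drugs_per_target(trial_drugs).items():
        counts[cls] += n
    return ClassDistribution("by_drug", _normalise(counts))


def compare_distributions(
    a: ClassDistribution,
    b: ClassDistribution,
) -> pd.DataFrame:
    """Per-class proportion comparison, ordered by |difference| descending.

    Classes absent on one side are imputed at 0.  Comparing different
    weightings is legitimate (targets vs drugs) and only warned about.
    """
    if a.weighting == b.weighting:
        pass
    else:
        logger.warning("comparing distributions with different weightings: %s vs %s",
                       a.weighting, b.weighting)
    keys = sorted(set(a.entries) | set(b.entries))
    rows = []
    for k in keys:
        pa = a.entries.get(k, (0, 0.0))[1]
        pb = b.entries.get(k, (0, 0.0))[1]
        rows.append({"protein_class": k, "proportion_a": pa,
                     "proportion_b": pb, "difference": pa - pb})
    df = pd.DataFrame(rows, columns=["protein_class", "proportion_a",
                                     "proportion_b", "difference"])
    return df.reindex(df["difference"].abs().sort_values(
        ascending=False, kind="stable").index).reset_index(drop=True)
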