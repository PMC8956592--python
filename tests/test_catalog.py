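"""Drug catalog parsing and clinical-trial drug curation rules."""

import numpy as np
import pandas as pd
import pytest

from druggenome import catalog as cat

CAT_HEADER = ("drug_name\tmolecule_type\tmoa\taccession\tchembl_target_id\t"
              "class_l1\tclass_l2\tclass_l3\torganism\tcomplex_id\tatc\t"
              "approval_year\ttherapeutic_rank\n")


def _catalog_file(tmp_path, rows):
    p = tmp_path / "cat.tsv"
    p.write_text(CAT_HEADER + "".join("\t".join(map(str, r)) + "\n" for r in rows))
    return p


def _ann(acc, l1="enzyme", l2="", chembl=None, organism="human", complex_id=None):
    levels = (l1, l2) if l2 else (l1,)
    return cat.TargetAnnotation(acc, chembl or f"CH_{acc}",
                                cat.ProteinClassPath(levels), organism,
                                complex_id)


class TestParseCatalog:
    def test_empty_catalog(self, tmp_path):
        assert cat.parse_drug_catalog(_catalog_file(tmp_path, [])) == []

    def test_targets_grouped_under_drug(self, tmp_path):
        rows = [["drugA", "small molecule", "x", "P1", "C1", "enzyme", "", "",
                 "human", "", "N05A", 1990, 1],
                ["drugA", "small molecule", "x", "P2", "C2", "ion channel", "",
                 "", "human", "", "N05A", 1990, 2],
                ["drugB", "antibody", "y", "P3", "C3", "secreted", "", "",
                 "human", "", "L01X", 2005, 1]]
        recs = cat.parse_drug_catalog(_catalog_file(tmp_path, rows))
        by_name = {r.drug_name: r for r in recs}
        assert len(recs) == 2 and len(by_name["drugA"].targets) == 2
        assert by_name["drugA"].therapeutic_rank == {"P1": 1, "P2": 2}

    def test_conflicting_molecule_type_is_hard_error(self, tmp_path):
        rows = [["drugA", "small molecule", "", "P1", "C1", "enzyme", "", "",
                 "human", "", "", "", ""],
                ["drugA", "antibody", "", "P2", "C2", "enzyme", "", "",
                 "human", "", "", "", ""]]
        with pytest.raises(ValueError, match="conflicting molecule types"):
            cat.parse_drug_catalog(_catalog_file(tmp_path, rows))

    def test_drug_name_matching_ignores_case_and_punctuation(self):
        assert cat.normalise_drug_name("N-Acetyl cysteine") == \
            cat.normalise_drug_name("nacetylcysteine")


class TestIndex:
    def test_drug_with_two_targets_appears_under_both(self):
        rec = cat.DrugRecord("d", "small molecule",
                             targets=[_ann("P1"), _ann("P2")])
        idx = cat.index_by_accession([rec])
        assert idx == {"P1": {"d"}, "P2": {"d"}}

    def test_microbial_only_drug_contributes_no_keys(self):
        rec = cat.DrugRecord("d", "small molecule",
                             targets=[_ann("M1", organism="microbial")])
        assert cat.index_by_accession([rec]) == {}


class TestRemapMicrobial:
    MOA = pd.DataFrame([{"drug_name": "minodrug", "accession": "PH1",
                         "chembl_target_id": "CH_PH1", "class_l1": "enzyme",
                         "class_l2": "", "class_l3": "", "therapeutic_rank": 1}])

    def test_microbial_drug_in_moa_table_gains_human_target(self):
        d = cat.TrialDrugRecord("minodrug",
                                raw_targets=[_ann("M1", organism="microbial")])
        out = cat.remap_microbial([d], self.MOA)[0]
        assert not out.excluded
        assert [t.accession for t in out.human_targets()] == ["PH1"]

    def test_microbial_drug_absent_from_table_is_excluded(self):
        d = cat.TrialDrugRecord("artedrug",
                                raw_targets=[_ann("M1", organism="microbial")])
        out = cat.remap_microbial([d], self.MOA)[0]
        assert out.excluded and out.exclusion_reason == "no human target"
        assert out.curated_class_entries == []

    def test_drug_with_human_targets_unchanged_and_idempotent(self):
        d = cat.TrialDrugRecord("plain", raw_targets=[_ann("P1")])
        once = cat.remap_microbial([d], self.MOA)
        twice = cat.remap_microbial(once, self.MOA)
        assert [t.accession for t in twice[0].raw_targets] == ["P1"]
        excl = cat.TrialDrugRecord("artedrug",
                                   raw_targets=[_ann("M1", organism="microbial")])
        again = cat.remap_microbial(cat.remap_microbial([excl], self.MOA), self.MOA)
        assert again[0].excluded


class TestConsolidateSubunits:
    def test_five_subunits_one_complex_collapse_to_one(self):
        subs = [_ann(f"P{i}", l1="ion channel", complex_id="NMDA")
                for i in range(5)]
        out = cat.consolidate_subunits(subs)
        assert len(out) == 1 and out[0].accession == "P0"

    def test_distinct_complexes_unchanged(self):
        anns = [_ann("P1", complex_id="A"), _ann("P2", complex_id="B"),
                _ann("P3")]
        assert cat.consolidate_subunits(anns) == anns

    def test_output_never_longer_than_input(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            anns = [_ann(f"P{i}", complex_id=str(rng.integers(3)))
                    for i in range(rng.integers(1, 10))]
            assert len(cat.consolidate_subunits(anns)) <= len(anns)


def _exhaustive_curation(targets, risk, ranks):
    """Independent brute-force application of the two-entry selection rules:
    scan every candidate (and candidate pair) and keep the best under the
    stated priority order."""
    def key(t):
        return (0 if t.accession in risk else 1,
                ranks.get(t.accession, 10**6), t.accession, t.chembl_target_id)

    if len(targets) == 1:
        return [targets[0].accession]
    first = None
    for t in targets:
        if first is None or key(t) < key(first):
            first = t
    best_second, best_score = None, None
    for t in targets:
        if t is first:
            continue
        diverse = 0 if t.protein_class.level1 != first.protein_class.level1 else 1
        score = (diverse, key(t))
        if best_score is None or score < best_score:
            best_second, best_score = t, score
    return [first.accession, best_second.accession]


class TestCurateMultiTarget:
    def test_single_target_reason_sole_target(self):
        d = cat.TrialDrugRecord("d", raw_targets=[_ann("P1")])
        out = cat.curate_multi_target(d, set())
        assert [(a.accession, r) for a, r in out.curated_class_entries] == \
            [("P1", "sole target")]

    def test_risk_gene_target_ranked_first(self):
        d = cat.TrialDrugRecord(
            "d", raw_targets=[_ann("P1"), _ann("P2"), _ann("P3"), _ann("P4")],
            therapeutic_rank={"P1": 1, "P2": 2, "P3": 3, "P4": 4})
        out = cat.curate_multi_target(d, {"P3"})
        assert out.curated_class_entries[0][0].accession == "P3"
        assert out.curated_class_entries[0][1] == "risk gene match"

    def test_second_entry_prefers_different_level1_class(self):
        d = cat.TrialDrugRecord(
            "d", raw_targets=[_ann("P1", l1="enzyme"), _ann("P2", l1="enzyme"),
                              _ann("P3", l1="ion channel")],
            therapeutic_rank={"P1": 1, "P2": 2, "P3": 3})
        out = cat.curate_multi_target(d, set())
        accs = [a.accession for a, _ in out.curated_class_entries]
        assert accs == ["P1", "P3"]
        assert "mechanistic diversity" in out.curated_class_entries[1][1]

    def test_excluded_drug_passes_through(self):
        d = cat.TrialDrugRecord("d", excluded=True, exclusion_reason="no human target")
        assert cat.curate_multi_target(d, set()).curated_class_entries == []

    def test_never_more_than_two_entries(self):
        d = cat.TrialDrugRecord("d", raw_targets=[_ann(f"P{i}") for i in range(8)])
        out = cat.curate_multi_target(d, set())
        assert len(out.curated_class_entries) == 2

    def test_matches_exhaustive_rule_oracle_on_20_drugs(self):
        """Selections over 20 random multi-target drugs equal a brute-force
        application of the stated priority rules."""
        rng = np.random.default_rng(42)
        classes = ["enzyme", "ion channel", "transporter", "membrane receptor"]
        for i in range(20):
            n = int(rng.integers(2, 6))
            accs = [f"P{j}" for j in rng.choice(50, size=n, replace=False)]
            targets = [_ann(a, l1=classes[int(rng.integers(4))]) for a in accs]
            ranks = {a: int(r + 1) for a, r in zip(accs, rng.permutation(n))}
            risk = {a for a in accs if rng.random() < 0.3}
            d = cat.TrialDrugRecord(f"d{i}", raw_targets=targets,
                                    therapeutic_rank=ranks)
            out = cat.curate_multi_target(d, risk)
            got = [a.accession for a, _ in out.curated_class_entries]
            assert got == _exhaustive_curation(targets, risk, ranks)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(7)
        targets = [_ann(f"P{i}", l1=c) for i, c in
                   enumerate(["enzyme", "enzyme", "transporter", "secreted"])]
        ranks = {"P0": 2, "P1": 1, "P2": 3, "P3": 4}
        ref = None
        for _ in range(5):
            perm = list(targets)
            rng.shuffle(perm)
            d = cat.TrialDrugRecord("d", raw_targets=perm, therapeutic_rank=ranks)
            got = [a.accession for a, _ in
                   cat.curate_multi_target(d, {"P2"}).curated_class_entries]
            ref = ref or got
            assert got == ref


class TestDrugsPerTarget:
    def test_no_drugs_empty_mapping(self):
        assert cat.drugs_per_target([]) == {}

    def test_counts_conserve_curated_entries(self):
        drugs = []
        for i in range(6):
            d = cat.TrialDrugRecord(f"d{i}", raw_targets=[
                _ann("P1", l1="enzyme"), _ann(f"Q{i}", l1="ion channel")])
            drugs.append(cat.curate_multi_target(d, set()))
        counts = cat.drugs_per_target(drugs)
        total_entries = sum(len(d.curated_class_entries) for d in drugs)
        assert sum(counts.values()) == total_entries
        assert counts[("P1", "enzyme")] == 6
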