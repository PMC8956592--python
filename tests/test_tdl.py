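"""Target development levels, neurophenotype scoring, shortlists."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from druggenome import evidence as ev
from druggenome import tdl
from druggenome._vocab import NEURO_INDEX_TERMS


def _meta(acc="P1", base=tdl.TDLLabel.TBIO, **kw):
    return tdl.TargetMeta(accession=acc, tdl_base=base, **kw)


class TestAssignTdl:
    def test_approved_and_trial_gives_tclin_rp(self):
        assert tdl.assign_tdl(_meta(), {"P1"}, {"P1"}) is tdl.TDLLabel.TCLIN_RP

    def test_approved_only_gives_tclin(self):
        assert tdl.assign_tdl(_meta(), {"P1"}, set()) is tdl.TDLLabel.TCLIN

    def test_unannotated_target_stays_dark(self):
        m = _meta(base=tdl.TDLLabel.TDARK)
        assert tdl.assign_tdl(m, set(), set()) is tdl.TDLLabel.TDARK

    def test_stale_tclin_metadata_demoted(self):
        m = _meta(base=tdl.TDLLabel.TCLIN)
        assert tdl.assign_tdl(m, set(), set()) is tdl.TDLLabel.TCHEM

    def test_removing_trial_set_collapses_rp_into_tclin_only(self):
        # with trials: Tclin_RP; without: Tclin; nothing else moves
        metas = {f"P{i}": _meta(f"P{i}", base=b) for i, b in enumerate(
            [tdl.TDLLabel.TBIO, tdl.TDLLabel.TDARK, tdl.TDLLabel.TCHEM])}
        approved, trial = {"P0", "P1"}, {"P0"}
        with_trial = {a: tdl.assign_tdl(m, approved, trial)
                      for a, m in metas.items()}
        without = {a: tdl.assign_tdl(m, approved, set())
                   for a, m in metas.items()}
        for a in metas:
            if with_trial[a] is tdl.TDLLabel.TCLIN_RP:
                assert without[a] is tdl.TDLLabel.TCLIN
            else:
                assert without[a] is with_trial[a]


class TestNeurophenotypeScore:
    def test_no_data_marker_gives_na(self):
        assert tdl.neurophenotype_score(None) is None

    @pytest.mark.parametrize("terms, expected", [
        (frozenset(), 0),
        (frozenset({"MP:0001262"}), 0),
        (frozenset({"MP:0003631"}), 1),
        (frozenset({"MP:0005386", "MP:0001262"}), 1),
        (frozenset({"MP:0003631", "MP:0005386", "MP:0001262"}), 2),
    ])
    def test_index_term_counting(self, terms, expected):
        assert tdl.neurophenotype_score(terms) == expected

    @settings(derandomize=True, max_examples=50)
    @given(index=st.frozensets(st.sampled_from(sorted(NEURO_INDEX_TERMS))),
           other=st.frozensets(st.sampled_from(
               ["MP:0001262", "MP:0002169", "MP:0005375"])))
    def test_monotone_in_index_subset_invariant_to_other_terms(self, index, other):
        base = tdl.neurophenotype_score(index)
        assert tdl.neurophenotype_score(index | other) == base
        for t in index:
            assert tdl.neurophenotype_score(index - {t}) <= base


def _records(n=10, seed=0):
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n):
        acc = f"P{i}"
        has_meta = rng.random() > 0.2
        terms = None if rng.random() < 0.3 else frozenset(
            t for t in ("MP:0003631", "MP:0005386") if rng.random() < 0.5)
        meta = _meta(acc,
                     base=tdl.TDLLabel(rng.choice(["Tchem", "Tbio", "Tdark"])),
                     chembl_activity_count=int(rng.geometric(0.2)) - 1,
                     synaptic_pathway_count=int(rng.integers(0, 3)),
                     hda_score=float(rng.uniform(0, 40)),
                     mouse_phenotype_terms=terms,
                     is_transcription_factor=bool(rng.random() < 0.3)) \
            if has_meta else None
        recs.append(tdl.PriorityRecord(
            accession=acc, symbol=f"G{i}",
            source=str(rng.choice(["GWAS", "TWAS", "CNV"])), study_id="S",
            expression_panel=None, neglog_p=float(rng.uniform(7.5, 30)),
            approved_drug_count=0, repurposing_status=None,
            tdl=meta.tdl_base if meta else tdl.TDLLabel.TDARK, meta=meta,
            neurophenotype=tdl.neurophenotype_score(terms) if meta else None))
    return recs


class TestTierCountsAndShortlists:
    def test_all_null_metadata_gives_zero_tiers(self):
        recs = [tdl.PriorityRecord(f"P{i}", f"G{i}", "GWAS", "S", None, 8.0,
                                   0, None, tdl.TDLLabel.TDARK, None, None)
                for i in range(4)]
        assert tdl.annotation_tier_counts(recs) == (0, 0, 0)

    def test_tier_counts_deduplicate_genes(self):
        meta = _meta("P1", chembl_activity_count=5, synaptic_pathway_count=1,
                     mouse_phenotype_terms=frozenset({"MP:0003631"}))
        rec = tdl.PriorityRecord("P1", "G1", "GWAS", "S", None, 8.0, 0, None,
                                 tdl.TDLLabel.TBIO, meta, 1)
        rec2 = tdl.PriorityRecord("P1", "G1", "TWAS", "S2", "BRAIN", 9.0, 0,
                                  None, tdl.TDLLabel.TBIO, meta, 1)
        assert tdl.annotation_tier_counts([rec, rec2]) == (1, 1, 1)

    def test_no_tdark_genes_gives_empty_shortlist(self):
        recs = [r for r in _records() if r.tdl is not tdl.TDLLabel.TDARK]
        assert tdl.shortlist_tdark_neuro(recs).empty

    def test_shortlists_are_stable_filters(self):
        recs = _records(30, seed=3)
        dark = tdl.shortlist_tdark_neuro(recs)
        hda = tdl.shortlist_low_hda(recs, 10.0)
        accs = {r.accession for r in recs}
        assert set(dark["accession"]) <= accs and set(hda["accession"]) <= accs
        rng = np.random.default_rng(1)
        perm = list(recs)
        rng.shuffle(perm)
        assert tdl.shortlist_tdark_neuro(perm).equals(dark)
        assert tdl.shortlist_low_hda(perm, 10.0).equals(hda)
        # every shortlisted Tdark gene really has a neurophenotype
        for _, row in dark.iterrows():
            assert row["neurophenotype"] in (1, 2)

    def test_zero_threshold_empties_hda_shortlist(self):
        assert tdl.shortlist_low_hda(_records(20, seed=2), 0.0).empty

    def test_transcription_factor_summary(self):
        recs = _records(40, seed=5)
        n_tf, n_tf_neuro = tdl.transcription_factor_summary(recs)
        uniq = {}
        for r in recs:
            uniq.setdefault(r.accession, r)
        expect_tf = sum(1 for r in uniq.values()
                        if r.meta and r.meta.is_transcription_factor)
        assert n_tf == expect_tf and 0 <= n_tf_neuro <= n_tf


class TestDistributionAndIntersection:
    def _entities(self):
        def e(acc, kinds, gw=True):
            assocs = [ev.GeneAssociation(f"G{acc}", k, f"S_{k.value}",
                                         p_value=1e-9, genome_wide=gw,
                                         accession=acc) for k in kinds]
            return ev.GeneEntity(acc, {f"G{acc}"}, assocs)
        return {
            "P1": e("P1", [ev.AnalysisKind.GWAS, ev.AnalysisKind.TWAS,
                           ev.AnalysisKind.CNV]),
            "P2": e("P2", [ev.AnalysisKind.GWAS, ev.AnalysisKind.TWAS]),
            "P3": e("P3", [ev.AnalysisKind.GWAS]),
            "P4": e("P4", [ev.AnalysisKind.CNV]),
        }

    def test_all_dark_input_is_100_percent_dark(self):
        ents = self._entities()
        labels = {a: tdl.TDLLabel.TDARK for a in ents}
        df = tdl.tdl_distribution(ents, labels).set_index("label")
        assert df.loc["Tdark", "percent"] == 100
        assert df.loc["T_druggable_background", "count"] == 667
        assert df.loc["T_total_background", "count"] == 20120

    def test_label_counts_sum_to_input_size(self):
        ents = self._entities()
        labels = {"P1": tdl.TDLLabel.TCLIN_RP, "P2": tdl.TDLLabel.TCLIN,
                  "P3": tdl.TDLLabel.TBIO, "P4": tdl.TDLLabel.TDARK}
        df = tdl.tdl_distribution(ents, labels)
        body = df[~df["label"].str.endswith("background")]
        assert body["count"].sum() == len(ents)

    def test_triple_and_pairwise_intersections(self):
        inter = tdl.multi_source_intersection(self._entities())
        assert inter["GWAS&TWAS&CNV"] == {"P1"}
        assert inter["GWAS&TWAS"] == {"P1", "P2"}
        assert inter["TWAS&CNV"] == {"P1"}

    def test_empty_source_empties_triple_intersection(self):
        ents = {k: v for k, v in self._entities().items() if k != "P1"}
        for e in ents.values():
            e.associations = [a for a in e.associations
                              if a.analysis_kind is not ev.AnalysisKind.CNV]
        inter = tdl.multi_source_intersection(ents)
        assert inter["GWAS&TWAS&CNV"] == set()


class TestPriorityTable:
    def test_empty_entity_set_gives_empty_table(self):
        assert tdl.build_priority_table({}, {}, {}, {}) == []

    def test_one_row_per_genome_wide_association(self):
        ents = {"P1": ev.GeneEntity("P1", {"G1"}, [
            ev.GeneAssociation("G1", ev.AnalysisKind.TWAS, "S_TWAS",
                               p_value=1e-10, expression_panel="BRAIN",
                               genome_wide=True, accession="P1"),
            ev.GeneAssociation("G1", ev.AnalysisKind.TWAS, "S_TWAS",
                               p_value=1e-8, expression_panel="BLOOD",
                               genome_wide=True, accession="P1"),
            ev.GeneAssociation("G1", ev.AnalysisKind.GWAS, "S_OTHER",
                               p_value=0.01, genome_wide=False,
                               accession="P1"),
        ])}
        meta = {"P1": _meta("P1")}
        labels = {"P1": tdl.TDLLabel.TBIO}
        table = tdl.build_priority_table(ents, {}, meta, labels)
        assert len(table) == 2
        by_panel = {r.expression_panel: r.neglog_p for r in table}
        assert by_panel == {"BRAIN": pytest.approx(10.0),
                            "BLOOD": pytest.approx(8.0)}

    def test_missing_metadata_flagged_not_zeroed(self):
        ents = {"P1": ev.GeneEntity("P1", {"G1"}, [
            ev.GeneAssociation("G1", ev.AnalysisKind.GWAS, "S", p_value=1e-9,
                               genome_wide=True, accession="P1")])}
        table = tdl.build_priority_table(ents, {}, {}, {"P1": tdl.TDLLabel.TDARK})
        assert table[0].meta is None and table[0].neurophenotype is None
        assert tdl.annotation_tier_counts(table) == (0, 0, 0)
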