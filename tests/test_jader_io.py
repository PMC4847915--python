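"""CSV reading, case assembly and cohort selection."""

import io

import pytest

import adrmine as am
from adrmine.jader_io import (
    ANTIDEPRESSANT_CLASSES,
    Causality,
    DrugClassConfig,
    Gender,
    JADER_COLUMNS,
    SchemaError,
    assemble_cases,
    filter_cohort,
    read_table,
)


def demo_csv(rows):
    return io.StringIO("case_id,gender,age,weight\n" + "\n".join(rows) + "\n")


class TestReadTable:
    def test_row_count_and_order_preserved(self):
        recs = read_table(demo_csv(["c1,female,20代,", "c2,male,,60kg", "c3,,,"]), "DEMO")
        assert [r.case_id for r in recs] == ["c1", "c2", "c3"]

    def test_unrecognized_gender_maps_to_unknown(self):
        recs = read_table(demo_csv(["c1,woman,20代,", "c2,,,"]), "DEMO")
        assert recs[0].gender is Gender.UNKNOWN
        assert recs[1].gender is Gender.UNKNOWN

    def test_japanese_gender_values_map(self):
        recs = read_table(demo_csv(["c1,女性,20代,", "c2,男性,,"]), "DEMO")
        assert [r.gender for r in recs] == [Gender.FEMALE, Gender.MALE]

    def test_missing_required_column_names_it(self):
        bad = io.StringIO("case_id,age,weight\nc1,20代,\n")
        with pytest.raises(SchemaError, match="gender"):
            read_table(bad, "DEMO")

    def test_extra_columns_ignored(self):
        f = io.StringIO("case_id,gender,age,weight,extra\nc1,female,20代,,zzz\n")
        assert read_table(f, "DEMO")[0].case_id == "c1"

    def test_empty_adr_term_cites_row_number(self):
        f = io.StringIO("case_id,adr_term,outcome\nc1,nausea,\nc2,,\n")
        with pytest.raises(SchemaError, match="row 3"):
            read_table(f, "REAC")

    def test_unknown_causality_maps_to_unknown(self):
        f = io.StringIO("case_id,drug_name,causality\nc1,paroxetine,maybe\n")
        assert read_table(f, "DRUG")[0].causality is Causality.UNKNOWN

    def test_japanese_headers_and_cp932(self, tmp_path):
        text = "識別番号,性別,年齢,体重\nc1,女性,20代,\n"
        p = tmp_path / "demo.csv"
        p.write_bytes(text.encode("cp932"))
        recs = read_table(p, "DEMO", encoding="cp932", columns=JADER_COLUMNS)
        assert recs[0] == am.DemoRecord("c1", Gender.FEMALE, "20代", "")

    def test_unknown_schema_rejected(self):
        with pytest.raises(ValueError, match="schema"):
            read_table(io.StringIO("x\n1\n"), "HIST")


class TestAssembleCases:
    def test_adr_terms_deduplicated(self):
        demo = read_table(demo_csv(["c1,female,20代,"]), "DEMO")
        reac = read_table(
            io.StringIO("case_id,adr_term,outcome\nc1,nausea,\nc1,nausea,\n"), "REAC")
        cases = assemble_cases(demo, reac, [])
        assert len(cases) == 1
        assert cases[0].adr_terms == frozenset({"nausea"})

    def test_unmatched_rows_dropped(self, caplog):
        demo = read_table(demo_csv(["c1,female,,", "c2,male,,"]), "DEMO")
        reac = read_table(io.StringIO("case_id,adr_term,outcome\nc3,rash,\n"), "REAC")
        import logging
        with caplog.at_level(logging.INFO, logger="adrmine.jader_io"):
            cases = assemble_cases(demo, reac, [])
        assert len(cases) == 2
        assert all(not c.adr_terms for c in cases)
        assert "dropped 1" in caplog.text

    def test_duplicate_demo_case_id_rejected(self):
        demo = read_table(demo_csv(["c1,female,,", "c1,male,,"]), "DEMO")
        with pytest.raises(SchemaError, match="duplicate case_id"):
            assemble_cases(demo, [], [])

    def test_idempotent_reassembly(self, small_cases):
        """Re-deriving records from assembled cases and assembling again
        reproduces identical cases."""
        demo = [am.DemoRecord(c.case_id, c.gender, c.age_raw) for c in small_cases]
        reac = [am.ReacRecord(c.case_id, t) for c in small_cases for t in sorted(c.adr_terms)]
        drug = [am.DrugRecord(c.case_id, n, caus) for c in small_cases
                for n, caus in sorted(c.drugs)]
        once = assemble_cases(demo, reac, drug)
        assert sorted(once, key=lambda c: c.case_id) == sorted(
            small_cases, key=lambda c: c.case_id)
        demo2 = [am.DemoRecord(c.case_id, c.gender, c.age_raw) for c in once]
        reac2 = [am.ReacRecord(c.case_id, t) for c in once for t in sorted(c.adr_terms)]
        drug2 = [am.DrugRecord(c.case_id, n, caus) for c in once
                 for n, caus in sorted(c.drugs)]
        assert assemble_cases(demo2, reac2, drug2) == once


class TestFilterCohort:
    def test_substring_match_absorbs_salt_suffix(self):
        case = am.Case("c1", Gender.FEMALE, "", frozenset(),
                       frozenset({("パロキセチン塩酸塩", Causality.SUSPECTED)}))
        cfg = DrugClassConfig("SSRI", ("パロキセチン",))
        assert filter_cohort([case], cfg) == [case]

    def test_exact_match_mode(self):
        case = am.Case("c1", Gender.FEMALE, "", frozenset(),
                       frozenset({("paroxetine hydrochloride", Causality.SUSPECTED)}))
        assert filter_cohort([case], DrugClassConfig("SSRI", ("paroxetine",),
                                                     match_mode="exact")) == []

    def test_causality_filter_excludes_concomitant_by_default(self, small_cases):
        cfg = DrugClassConfig("SSRI", ("paroxetine", "sertraline", "fluvoxamine"))
        cohort = filter_cohort(small_cases, cfg)
        assert [c.case_id for c in cohort] == ["c1", "c2", "c3"]  # c6 is concomitant
        cfg_any = DrugClassConfig(
            "SSRI", ("paroxetine", "sertraline", "fluvoxamine"),
            causality_filter=frozenset({Causality.SUSPECTED, Causality.CONCOMITANT}))
        assert [c.case_id for c in filter_cohort(small_cases, cfg_any)] == [
            "c1", "c2", "c3", "c6"]

    def test_empty_member_list_rejected(self):
        with pytest.raises(ValueError, match="empty member list"):
            DrugClassConfig("SSRI", ())

    def test_disjoint_classes_give_disjoint_cohorts(self, small_cases):
        ids = set()
        total = 0
        for cfg in ANTIDEPRESSANT_CLASSES:
            cohort = filter_cohort(small_cases, cfg)
            assert len(cohort) <= len(small_cases)
            total += len(cohort)
            ids |= {c.case_id for c in cohort}
        assert len(ids) == total  # single-drug cases: no overlap


class TestSyntheticRoundTrip:
    def test_reader_recovers_generator_manifest(self):
        spec = am.default_spec(n_cases=100)
        demo_csv_, drug_csv_, reac_csv_, man = am.generate(spec, seed=3)
        cases = assemble_cases(
            read_table(io.StringIO(demo_csv_), "DEMO"),
            read_table(io.StringIO(reac_csv_), "REAC"),
            read_table(io.StringIO(drug_csv_), "DRUG"),
        )
        assert len(cases) == 100
        by_id = {c.case_id: c for c in cases}
        gender_of = {"female": Gender.FEMALE, "male": Gender.MALE, "": Gender.UNKNOWN}
        for truth in man.cases:
            case = by_id[truth.case_id]
            assert case.gender is gender_of[truth.gender]
            assert case.age_raw == truth.age_raw
            assert case.adr_terms == frozenset(truth.adr_terms)
            assert case.drugs == frozenset({(truth.drug_name, Causality.SUSPECTED)})

    def test_cohort_sizes_match_manifest(self):
        spec = am.default_spec(n_cases=400)
        demo_csv_, drug_csv_, reac_csv_, man = am.generate(spec, seed=8)
        cases = assemble_cases(
            read_table(io.StringIO(demo_csv_), "DEMO"),
            read_table(io.StringIO(reac_csv_), "REAC"),
            read_table(io.StringIO(drug_csv_), "DRUG"),
        )
        for cfg in ANTIDEPRESSANT_CLASSES:
            cohort = filter_cohort(cases, cfg)
            assert {c.case_id for c in cohort} == set(
                man.class_cohort_ids(cfg.class_name))
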