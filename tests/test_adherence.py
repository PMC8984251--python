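"""Adherence feature sets against brute-force item recounts."""

from fractions import Fraction

import numpy as np
import pytest

from cohortjuxt.adherence import (
    adherence_features,
    adherence_table,
    feature_set_1,
    feature_set_2,
    feature_set_3,
    feature_set_4,
    item_adherence,
    summarize,
)
from cohortjuxt.cohort_model import (
    Cohort,
    QuestionnaireCatalog,
    QuestionnaireInfo,
    SchemaError,
    default_catalog,
)
from cohortjuxt.synthetic_cohort import generate_cohort

from .conftest import make_record, small_two_center_config


class TestItemAdherence:
    def test_three_of_four_items(self, mini_catalog):
        rec = make_record(responses={("TQ", "t0"): [1, None, 0, 1]})
        assert item_adherence(rec, mini_catalog, "TQ") == Fraction(75)

    def test_all_items_answered(self, mini_catalog):
        rec = make_record(responses={("TQ", "t0"): [1, 2, 0, 1]})
        assert item_adherence(rec, mini_catalog, "TQ") == Fraction(100)

    def test_absent_block_counts_zero(self, mini_catalog):
        rec = make_record(responses={})
        assert item_adherence(rec, mini_catalog, "TQ") == Fraction(0)

    def test_unknown_questionnaire_rejected(self, mini_catalog):
        with pytest.raises(SchemaError):
            item_adherence(make_record(), mini_catalog, "NOPE")

    def test_unavailable_at_center_rejected(self, mini_catalog):
        with pytest.raises(SchemaError):
            item_adherence(make_record(center="C1"), mini_catalog, "THI")

    def test_partial_tq_exact_fraction(self):
        cat = default_catalog()
        rec = make_record(
            center="CHA",
            responses={("TQ", "t0"): [1] * 40 + [None] * 12},
        )
        assert item_adherence(rec, cat, "TQ") == Fraction(100 * 40, 52)


class TestFeatureSets:
    def test_set1_mean_of_center_questionnaires(self, mini_catalog):
        rec = make_record(center="C2", responses={
            ("TQ", "t0"): [1, 1, 1, 1],        # 100%
            ("THI", "t0"): [1, None],          # 50%
            # MDI absent -> 0%
        })
        assert feature_set_1(rec, mini_catalog) == Fraction(150, 3)

    def test_set1_full_adherence_is_100(self, mini_catalog):
        rec = make_record(center="C2", responses={
            ("TQ", "t0"): [0, 0, 0, 0],
            ("THI", "t0"): [0, 0],
            ("MDI", "t0"): [0, 0],
        })
        assert feature_set_1(rec, mini_catalog) == Fraction(100)

    def test_set2_keys_are_shared_questionnaires(self, mini_catalog):
        rec = make_record(responses={("TQ", "t0"): [1, 1, None, 1]})
        out = feature_set_2(rec, mini_catalog)
        assert set(out) == {"TQ"}
        assert out["TQ"] == Fraction(75)

    def test_set2_all_keys_when_catalogs_identical(self):
        cat = QuestionnaireCatalog(entries={
            "Q1": QuestionnaireInfo(2, "a", frozenset({"A", "B"})),
            "Q2": QuestionnaireInfo(2, "b", frozenset({"A", "B"})),
        })
        rec = make_record(center="A", responses={("Q1", "t0"): [1, 1]})
        assert set(feature_set_2(rec, cat)) == {"Q1", "Q2"}

    def test_set3_keys_and_category_means(self, mini_catalog):
        rec = make_record(center="C1", responses={
            ("TQ", "t0"): [1, 1, 1, None],   # TD: TQ 75%, TLQ 0 -> 37.5
            ("ADSL", "t0"): [1, None],       # D: ADSL 50%
        })
        out = feature_set_3(rec, mini_catalog)
        assert set(out) == {"TD", "D"}
        assert out["TD"] == Fraction(75, 2)
        assert out["D"] == Fraction(50)

    def test_set3_single_questionnaire_category(self, mini_catalog):
        rec = make_record(center="C1", responses={("ADSL", "t0"): [1, 1]})
        out = feature_set_3(rec, mini_catalog)
        assert out["D"] == item_adherence(rec, mini_catalog, "ADSL")

    def test_set4_is_mean_of_set3(self, mini_catalog):
        rec = make_record(center="C1", responses={
            ("TQ", "t0"): [1, 1, 1, 1], ("TLQ", "t0"): [1, 1],  # TD = 100
            ("ADSL", "t0"): [1, None],                          # D = 50
        })
        assert feature_set_4(rec, mini_catalog) == Fraction(75)
        set3 = feature_set_3(rec, mini_catalog)
        assert feature_set_4(rec, mini_catalog) == sum(set3.values()) / len(set3)

    def test_set4_vector_mode_returns_set3(self, mini_catalog):
        rec = make_record(center="C1", responses={("TQ", "t0"): [1, 1, 1, 1]})
        assert feature_set_4(rec, mini_catalog, mode="vector") == feature_set_3(
            rec, mini_catalog
        )

    def test_values_bounded_and_t0_only(self, mini_catalog):
        # answering everything at t1 must not change any t0 feature
        rec = make_record(center="C1", responses={("TQ", "t0"): [1, None, 1, 1]})
        before = adherence_features(rec, mini_catalog)
        rec.responses[("TQ", "t1")] = [1, 1, 1, 1]
        after = adherence_features(rec, mini_catalog)
        assert before == after
        assert 0 <= before.set1 <= 100 and 0 <= before.set4 <= 100

    def test_answering_one_more_item_never_decreases_features(self, mini_catalog):
        rec = make_record(center="C1", responses={
            ("TQ", "t0"): [1, None, 1, None], ("ADSL", "t0"): [None, None],
        })
        before = adherence_features(rec, mini_catalog)
        rec.responses[("TQ", "t0")][1] = 2
        after = adherence_features(rec, mini_catalog)
        assert after.set1 >= before.set1
        assert after.set4 >= before.set4
        assert all(after.set2[q] >= before.set2[q] for q in before.set2)
        assert all(after.set3[c] >= before.set3[c] for c in before.set3)


def brute_force_features(rec, catalog):
    """Independent item-by-item recount of all four feature sets."""
    center = rec.center

    def adh(q):
        block = rec.responses.get((q, "t0"))
        answered = sum(a is not None for a in block) if block else 0
        return Fraction(100 * answered, catalog.entries[q].items)

    a_center = sorted(catalog.questionnaires(center))
    set1 = sum(adh(q) for q in a_center) / len(a_center)
    set2 = {q: adh(q) for q in sorted(catalog.shared_questionnaires())}
    set3 = {}
    for cat in sorted(catalog.shared_categories()):
        qs = sorted(
            q for q in a_center if catalog.entries[q].category == cat
        )
        set3[cat] = sum(adh(q) for q in qs) / len(qs)
    set4 = sum(set3.values()) / len(set3)
    return set1, set2, set3, set4


class TestBruteForceOracle:
    def test_feature_sets_match_recount_exactly(self):
        cohort = generate_cohort(small_two_center_config(seed=29, n1=60, n2=60))
        for rec in cohort.records:
            f = adherence_features(rec, cohort.catalog)
            set1, set2, set3, set4 = brute_force_features(rec, cohort.catalog)
            assert f.set1 == set1
            assert f.set2 == set2
            assert f.set3 == set3
            assert f.set4 == set4


class TestSummarize:
    def test_fully_adherent_cohort_is_100_everywhere(self, mini_catalog):
        recs = [
            make_record("a", "C1", "f", 30, {
                ("TQ", "t0"): [1] * 4, ("TLQ", "t0"): [1] * 2,
                ("ADSL", "t0"): [1] * 2, ("PSQ", "t0"): [1] * 2,
            }),
            make_record("b", "C1", "m", 40, {
                ("TQ", "t0"): [1] * 4, ("TLQ", "t0"): [1] * 2,
                ("ADSL", "t0"): [1] * 2, ("PSQ", "t0"): [1] * 2,
            }),
        ]
        out = summarize(Cohort(records=recs, catalog=mini_catalog))
        assert (out["mean"] == 100.0).all()
        assert (out["sd"] == 0.0).all()

    def test_pooled_column_is_not_mean_of_subgroup_means(self, mini_catalog):
        # 1 female at 100%, 3 males at 0% -> pooled set1 = 25, mean-of-means = 50
        full = {("TQ", "t0"): [1] * 4, ("TLQ", "t0"): [1] * 2,
                ("ADSL", "t0"): [1] * 2, ("PSQ", "t0"): [1] * 2}
        recs = [make_record("f1", "C1", "f", 30, full)] + [
            make_record(f"m{i}", "C1", "m", 40, {}) for i in range(3)
        ]
        out = summarize(Cohort(records=recs, catalog=mini_catalog))
        set1 = out[out.feature == "set1"].set_index("gender")
        assert set1.loc["all", "mean"] == pytest.approx(25.0)
        assert set1.loc["f", "mean"] == pytest.approx(100.0)

    def test_na_gender_column_only_when_present(self, mini_catalog):
        recs = [
            make_record("a", "C1", "f", 30, {}),
            make_record("b", "C2", "NA", 40, {}),
            make_record("c", "C2", "m", 41, {}),
            make_record("d", "C2", "f", 42, {}),
        ]
        out = summarize(Cohort(records=recs, catalog=mini_catalog))
        assert "NA" not in set(out[out.center == "C1"].gender)
        assert "NA" in set(out[out.center == "C2"].gender)

    def test_cell_means_track_configured_propensities(self):
        cohort = generate_cohort(small_two_center_config(seed=31, n1=400, n2=400))
        cfg = small_two_center_config(seed=31).centers["UHREG"]
        out = summarize(cohort)
        tq = out[(out.center == "UHREG") & (out.feature == "set2_TQ")
                 & (out.gender == "all")].iloc[0]
        assert tq["mean"] / 100 == pytest.approx(
            cfg.propensity("TQ").mean_adherence(), abs=0.03
        )

    def test_empty_cohort_rejected(self, mini_catalog):
        with pytest.raises(ValueError):
            summarize(Cohort(records=[], catalog=mini_catalog))


def test_adherence_table_columns(small_generated_cohort):
    table = adherence_table(small_generated_cohort)
    assert {"set1", "set2_TQ", "set3_depressivity", "set3_tinnitus_distress",
            "set4"} <= set(table.columns)
    vals = table[[c for c in table.columns if c.startswith("set")]]
    assert ((vals >= 0) & (vals <= 100)).all().all()
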