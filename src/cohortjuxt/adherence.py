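"""Adherence features: how completely each patient filled the questionnaires.

Adherence of a patient with respect to an item set I is the percentage of
items in I that were answered.  Four feature constructions are derived
from the per-questionnaire adherence values at admission (t0):

- set 1: the average adherence over all questionnaires of the patient's
  center (one number per patient),
- set 2: one adherence value per questionnaire shared by all centers,
- set 3: one value per shared topical category -- the average adherence of
  the center's own questionnaires in that category,
- set 4: the average of the set-3 category values (one number).

Only admission-time adherence is used: the features augment pre-treatment
predictors of the post-treatment score, and later-visit adherence would
leak information about the target.  A wholly absent response block counts
as adherence 0 rather than being dropped from the averages -- an
unanswered questionnaire is the strongest possible non-adherence signal,
and excluding it would bias center-wide averages upward.

Values are carried as exact rationals (:class:`fractions.Fraction`, scale
0-100) so that averages of averages introduce no rounding; summaries
render them as floats at the end.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .cohort_model import Cohort, PatientRecord, QuestionnaireCatalog, SchemaError

__all__ = [
    "AdherenceFeatures",
    "item_adherence",
    "feature_set_1",
    "feature_set_2",
    "feature_set_3",
    "feature_set_4",
    "adherence_features",
    "adherence_table",
    "summarize",
]


@dataclass(frozen=True)
class AdherenceFeatures:
    """The four adherence feature sets of one patient (t0, percent)."""

    patient_id: str
    set1: Fraction
    set2: dict[str, Fraction]
    set3: dict[str, Fraction]
    set4: Fraction


def item_adherence(
    record: PatientRecord,
    catalog: QuestionnaireCatalog,
    questionnaire: str,
    time_point: str = "t0",
) -> Fraction:
    """Percentage of the questionnaire's items the patient answered.

    An absent response block counts as 0 answered items.
    """
    if questionnaire not in catalog.entries:
        raise SchemaError(f"unknown questionnaire {questionnaire!r}")
    info = catalog.entries[questionnaire]
    if record.center not in info.centers:
        raise SchemaError(
            f"questionnaire {questionnaire!r} not available at center {record.center!r}"
        )
    return Fraction(100 * record.answered(questionnaire, time_point), info.items)


def feature_set_1(record: PatientRecord, catalog: QuestionnaireCatalog) -> Fraction:
    """Average adherence over all questionnaires of the patient's center."""
    qs = sorted(catalog.questionnaires(record.center))
    if not qs:
        raise SchemaError(f"center {record.center!r} has no questionnaires")
    return sum(item_adherence(record, catalog, q) for q in qs) / len(qs)


def feature_set_2(
    record: PatientRecord, catalog: QuestionnaireCatalog
) -> dict[str, Fraction]:
    """One adherence value per questionnaire shared by all centers."""
    shared = sorted(catalog.shared_questionnaires())
    if not shared:
        raise SchemaError("no questionnaire is shared by all centers")
    return {q: item_adherence(record, catalog, q) for q in shared}


def feature_set_3(
    record: PatientRecord, catalog: QuestionnaireCatalog
) -> dict[str, Fraction]:
    """Per shared category: average adherence over the center's questionnaires."""
    shared = sorted(catalog.shared_categories())
    if not shared:
        raise SchemaError("no category is shared by all centers")
    out: dict[str, Fraction] = {}
    for cat in shared:
        qs = sorted(catalog.in_category(cat, record.center))
        out[cat] = sum(item_adherence(record, catalog, q) for q in qs) / len(qs)
    return out


def feature_set_4(
    record: PatientRecord, catalog: QuestionnaireCatalog, mode: str = "average"
):
    """Average of the set-3 category values (``mode="average"``, default).

    ``mode="vector"`` instead returns the set-3 mapping itself, the
    alternative reading under which set 4 is the collection of shared-
    category adherence values rather than their mean.
    """
    set3 = feature_set_3(record, catalog)
    if mode == "vector":
        return set3
    if mode != "average":
        raise ValueError(f"unknown set-4 mode {mode!r}")
    return sum(set3.values()) / len(set3)


def adherence_features(
    record: PatientRecord, catalog: QuestionnaireCatalog
) -> AdherenceFeatures:
    set3 = feature_set_3(record, catalog)
    return AdherenceFeatures(
        patient_id=record.patient_id,
        set1=feature_set_1(record, catalog),
        set2=feature_set_2(record, catalog),
        set3=set3,
        set4=sum(set3.values()) / len(set3),
    )


def adherence_table(cohort: Cohort) -> pd.DataFrame:
    """Per-patient adherence feature table (percent, floats).

    Columns: ``set1``, ``set2_<questionnaire>``, ``set3_<category>``,
    ``set4``, plus demographics for joining onto score tables.
    """
    rows = []
    for rec in sorted(cohort.records, key=lambda r: r.patient_id):
        f = adherence_features(rec, cohort.catalog)
        row = {
            "patient_id": rec.patient_id,
            "center": rec.center,
            "gender": rec.gender,
            "set1": float(f.set1),
        }
        row.update({f"set2_{q}": float(v) for q, v in sorted(f.set2.items())})
        row.update({f"set3_{c}": float(v) for c, v in sorted(f.set3.items())})
        row["set4"] = float(f.set4)
        rows.append(row)
    return pd.DataFrame(rows)


def summarize(cohort: Cohort) -> pd.DataFrame:
    """Stratified adherence summary: mean and SD per center, gender and feature.

    Tidy output with one row per (center, feature, gender) where gender
    runs over f, m, NA (only when unknown-gender patients exist at that
    center) and the pooled "all" column, which is recomputed over all
    patients rather than averaged over subgroup means.
    """
    if not cohort.records:
        raise ValueError("empty cohort")
    table = adherence_table(cohort)
    feature_cols = [c for c in table.columns if c.startswith("set")]
    rows = []
    for center, per_center in table.groupby("center", sort=True):
        genders = ["f", "m"]
        if (per_center["gender"] == "NA").any():
            genders.append("NA")
        genders.append("all")
        for feature in feature_cols:
            for gender in genders:
                sub = (
                    per_center
                    if gender == "all"
                    else per_center[per_center["gender"] == gender]
                )
                if sub.empty:
                    continue
                vals = sub[feature].to_numpy()
                rows.append(
                    {
                        "center": center,
                        "feature": feature,
                        "gender": gender,
                        "mean": float(np.mean(vals)),
                        "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                        "n": int(len(vals)),
                    }
                )
    return pd.DataFrame(rows)
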