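"""Cohort data model: questionnaire catalog, patient records, and file I/O.

The in-memory containers are deliberately simple: a catalog describing which
questionnaire belongs to which topical category and which treatment center
administers it, and one record per patient carrying demographics plus
item-level responses at admission (``t0``) and at the final visit (``t1``).
Missing item answers are represented as ``None`` in memory and as an empty
field on disk -- never as a sentinel number, because downstream adherence
features must distinguish "answered 0" from "not answered".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

GENDERS = ("f", "m", "NA")
TIME_POINTS = ("t0", "t1")

#: Default plausible bounds for patient age in years.
DEFAULT_AGE_BOUNDS = (18, 100)

COHORT_COLUMNS = [
    "patient_id",
    "center",
    "gender",
    "age",
    "questionnaire",
    "time_point",
    "item_index",
    "answer",
]


class SchemaError(ValueError):
    """A catalog or cohort file violates the schema.

    ``rows`` lists the offending 1-based data-file line numbers when the
    error originates from specific rows of a cohort table.
    """

    def __init__(self, message: str, rows: Sequence[int] = ()):
        super().__init__(message)
        self.rows = list(rows)


@dataclass(frozen=True)
class QuestionnaireInfo:
    """Static description of one questionnaire instrument."""

    items: int
    category: str
    centers: frozenset[str]
    score_range: tuple[float, float] | None = None

    def __post_init__(self):
        if self.items < 1:
            raise SchemaError(f"item count must be >= 1, got {self.items}")
        if not self.category:
            raise SchemaError("questionnaire with no category")
        if not self.centers:
            raise SchemaError("questionnaire available at no center")
        if self.score_range is not None and self.score_range[0] >= self.score_range[1]:
            raise SchemaError(f"degenerate score range {self.score_range}")


@dataclass(frozen=True)
class QuestionnaireCatalog:
    """Catalog of questionnaires, their item counts, categories and centers.

    The shared sets are always recomputed from ``entries`` rather than
    stored, so they can never drift out of sync:

    - ``questionnaires(center)``: the instruments a center administers
      (A_center in the adherence notation),
    - ``shared_questionnaires()``: instruments administered by every center
      (S),
    - ``categories(center)`` / ``shared_categories()``: the analogous
      category sets (C_center and V),
    - ``in_category(category, center)``: the questionnaires of one category
      (Q_c), optionally restricted to one center.
    """

    entries: Mapping[str, QuestionnaireInfo]

    @property
    def centers(self) -> frozenset[str]:
        out: set[str] = set()
        for info in self.entries.values():
            out |= info.centers
        return frozenset(out)

    def questionnaires(self, center: str) -> frozenset[str]:
        return frozenset(q for q, info in self.entries.items() if center in info.centers)

    def shared_questionnaires(self) -> frozenset[str]:
        centers = self.centers
        if not centers:
            return frozenset()
        shared = set(self.entries)
        for center in centers:
            shared &= self.questionnaires(center)
        return frozenset(shared)

    def categories(self, center: str) -> frozenset[str]:
        return frozenset(self.entries[q].category for q in self.questionnaires(center))

    def shared_categories(self) -> frozenset[str]:
        centers = self.centers
        if not centers:
            return frozenset()
        shared: set[str] | None = None
        for center in centers:
            cats = set(self.categories(center))
            shared = cats if shared is None else shared & cats
        return frozenset(shared or set())

    def in_category(self, category: str, center: str | None = None) -> frozenset[str]:
        qs = (q for q, info in self.entries.items() if info.category == category)
        if center is None:
            return frozenset(qs)
        return frozenset(q for q in qs if center in self.entries[q].centers)


@dataclass
class PatientRecord:
    """One patient: demographics plus item-level questionnaire responses.

    ``responses`` maps ``(questionnaire_id, time_point)`` to a list whose
    length equals the catalog item count; an unanswered item is ``None``.
    A missing key means the whole response block is absent (for adherence
    purposes both conventions count as zero answered items).
    """

    patient_id: str
    center: str
    gender: str
    age: int
    responses: dict[tuple[str, str], list[float | None]] = field(default_factory=dict)

    def answered(self, questionnaire: str, time_point: str) -> int:
        block = self.responses.get((questionnaire, time_point))
        if block is None:
            return 0
        return sum(1 for a in block if a is not None)


@dataclass
class Cohort:
    """A set of patient records plus the catalog they are coded against."""

    records: list[PatientRecord]
    catalog: QuestionnaireCatalog
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [r.patient_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise SchemaError("duplicate patient ids in cohort")
        known = self.catalog.centers
        for r in self.records:
            if r.center not in known:
                raise SchemaError(
                    f"patient {r.patient_id!r} has center {r.center!r} not in catalog"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def centers(self) -> list[str]:
        return sorted({r.center for r in self.records})

    def stratum(self, center: str, gender: str | None = None) -> list[PatientRecord]:
        return [
            r
            for r in self.records
            if r.center == center and (gender is None or r.gender == gender)
        ]


def total_score(
    record: PatientRecord, catalog: QuestionnaireCatalog, questionnaire: str, time_point: str
) -> float | None:
    """Sum-of-items score, or ``None`` if any item is unanswered.

    Only the "sum" scoring rule ships; a score is considered computable only
    for a fully answered questionnaire, matching the convention under which
    analysis cohorts are restricted to patients with no missing values.
    """
    if questionnaire not in catalog.entries:
        raise SchemaError(f"unknown questionnaire {questionnaire!r}")
    block = record.responses.get((questionnaire, time_point))
    if block is None or any(a is None for a in block):
        return None
    s = sum(block)
    return int(s) if float(s).is_integer() else float(s)


# ---------------------------------------------------------------------------
# Catalog I/O


class _StrictLoader(yaml.SafeLoader):
    """YAML loader that rejects duplicate mapping keys."""


def _strict_mapping(loader, node, deep=False):
    seen = set()
    for key_node, _ in node.value:
        key = loader.construct_object(key_node, deep=deep)
        if key in seen:
            raise SchemaError(f"duplicate key {key!r} in catalog file")
        seen.add(key)
    return yaml.SafeLoader.construct_mapping(loader, node, deep)


_StrictLoader.add_constructor(
    yaml.resolver.BaseResolver.DEFAULT_MAPPING_TAG, _strict_mapping
)


def load_catalog(path: str | Path) -> QuestionnaireCatalog:
    """Read a questionnaire catalog from a YAML file.

    Expected layout::

        questionnaires:
          TQ: {items: 52, category: tinnitus_distress,
               centers: [CHA, UHREG], score_range: [0, 84]}
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.load(fh, Loader=_StrictLoader)
    if not isinstance(raw, dict) or "questionnaires" not in raw:
        raise SchemaError(f"{path}: missing top-level 'questionnaires' mapping")
    entries: dict[str, QuestionnaireInfo] = {}
    for qid, spec in raw["questionnaires"].items():
        if not isinstance(spec, dict):
            raise SchemaError(f"{path}: questionnaire {qid!r} is not a mapping")
        missing = {"items", "category", "centers"} - set(spec)
        if missing:
            raise SchemaError(f"{path}: questionnaire {qid!r} missing {sorted(missing)}")
        score_range = spec.get("score_range")
        entries[str(qid)] = QuestionnaireInfo(
            items=int(spec["items"]),
            category=str(spec["category"]),
            centers=frozenset(str(c) for c in spec["centers"]),
            score_range=tuple(float(x) for x in score_range) if score_range else None,
        )
    return QuestionnaireCatalog(entries=entries)


def default_catalog() -> QuestionnaireCatalog:
    """The bundled two-center catalog used by the synthetic generator.

    It mirrors the instrument layout of two German tinnitus centers: the
    Tinnitus Questionnaire (TQ) is the only instrument shared by both, and
    the only shared topical categories are tinnitus distress and
    depressivity.
    """
    from importlib import resources

    ref = resources.files("cohortjuxt") / "data" / "default_catalog.yaml"
    with resources.as_file(ref) as p:
        return load_catalog(p)


# ---------------------------------------------------------------------------
# Cohort I/O


def _format_answer(a: float | None) -> str:
    if a is None:
        return ""
    if float(a).is_integer():
        return str(int(a))
    return format(float(a), ".17g")


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as a long-format delimited text table.

    One row per (patient, questionnaire, time point, item); rows are sorted
    by patient id, questionnaire id, time point and item index so that the
    same cohort always serializes to byte-identical files.  Unanswered items
    are written as an empty ``answer`` field.
    """
    rows = []
    for rec in sorted(cohort.records, key=lambda r: r.patient_id):
        for (q, tp) in sorted(rec.responses):
            block = rec.responses[(q, tp)]
            for i, a in enumerate(block, start=1):
                rows.append(
                    (rec.patient_id, rec.center, rec.gender, rec.age, q, tp, i,
                     _format_answer(a))
                )
    df = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    df.to_csv(path, index=False, lineterminator="\n")


def load_cohort(
    path: str | Path,
    catalog: QuestionnaireCatalog,
    age_bounds: tuple[int, int] = DEFAULT_AGE_BOUNDS,
) -> Cohort:
    """Read a long-format cohort table and validate it against the catalog.

    Rows violating an invariant (unknown questionnaire, item index out of
    range, questionnaire not administered at the patient's center, invalid
    gender or out-of-bounds age) are reported with their 1-based data line
    numbers in a single :class:`SchemaError`.
    """
    df = pd.read_csv(
        path,
        dtype={
            "patient_id": str,
            "center": str,
            "gender": str,
            "questionnaire": str,
            "time_point": str,
        },
        keep_default_na=False,
        na_values=[""],
    )
    missing_cols = set(COHORT_COLUMNS) - set(df.columns)
    if missing_cols:
        raise SchemaError(f"{path}: missing columns {sorted(missing_cols)}")

    problems: list[str] = []
    bad_rows: list[int] = []

    def flag(idx: int, msg: str) -> None:
        row_no = idx + 1  # 1-based data row (header excluded)
        problems.append(f"row {row_no}: {msg}")
        bad_rows.append(row_no)

    records: dict[str, PatientRecord] = {}
    for idx, row in enumerate(df.itertuples(index=False)):
        q, tp = row.questionnaire, row.time_point
        if q not in catalog.entries:
            flag(idx, f"unknown questionnaire {q!r}")
            continue
        info = catalog.entries[q]
        if tp not in TIME_POINTS:
            flag(idx, f"invalid time point {tp!r}")
            continue
        if row.center not in info.centers:
            flag(idx, f"questionnaire {q!r} not available at center {row.center!r}")
            continue
        if row.gender not in GENDERS:
            flag(idx, f"invalid gender {row.gender!r}")
            continue
        age = int(row.age)
        if not (age_bounds[0] <= age <= age_bounds[1]):
            flag(idx, f"age {age} outside bounds {age_bounds}")
            continue
        item = int(row.item_index)
        if not (1 <= item <= info.items):
            flag(idx, f"item index {item} out of range 1..{info.items} for {q!r}")
            continue

        rec = records.get(row.patient_id)
        if rec is None:
            rec = PatientRecord(
                patient_id=row.patient_id, center=row.center, gender=row.gender, age=age
            )
            records[row.patient_id] = rec
        elif (rec.center, rec.gender, rec.age) != (row.center, row.gender, age):
            flag(idx, f"inconsistent demographics for patient {row.patient_id!r}")
            continue
        block = rec.responses.setdefault((q, tp), [None] * info.items)
        answer = row.answer
        value = None if pd.isna(answer) else float(answer)
        if value is not None and block[item - 1] is not None:
            flag(idx, f"duplicate item {item} for patient {row.patient_id!r} {q}/{tp}")
            continue
        if value is not None:
            block[item - 1] = int(value) if value.is_integer() else value

    if problems:
        raise SchemaError(
            f"{path}: {len(problems)} invalid rows:\n" + "\n".join(problems[:50]),
            rows=bad_rows,
        )
    return Cohort(records=list(records.values()), catalog=catalog)


# ---------------------------------------------------------------------------
# Filtering and derived tables


def filter_complete(
    cohort: Cohort, questionnaire: str, time_points: Iterable[str]
) -> Cohort:
    """Keep patients whose total score is computable at every requested time point.

    Passing an empty ``time_points`` set is the identity filter.  The filter
    parameters are appended to the cohort provenance.
    """
    if questionnaire not in cohort.catalog.entries:
        raise SchemaError(f"unknown questionnaire {questionnaire!r}")
    tps = sorted(set(time_points))
    for tp in tps:
        if tp not in TIME_POINTS:
            raise SchemaError(f"invalid time point {tp!r}")
    kept = [
        rec
        for rec in cohort.records
        if all(
            total_score(rec, cohort.catalog, questionnaire, tp) is not None for tp in tps
        )
    ]
    provenance = dict(cohort.provenance)
    provenance.setdefault("filters", []).append(
        {"filter_complete": {"questionnaire": questionnaire, "time_points": tps}}
    )
    return Cohort(records=kept, catalog=cohort.catalog, provenance=provenance)


def score_table(cohort: Cohort, questionnaire: str = "TQ") -> pd.DataFrame:
    """Derived per-patient table: demographics plus t0/t1 total scores.

    Scores that are not computable (missing items) come out as NaN.
    """
    rows = []
    for rec in sorted(cohort.records, key=lambda r: r.patient_id):
        rows.append(
            {
                "patient_id": rec.patient_id,
                "center": rec.center,
                "gender": rec.gender,
                "age": rec.age,
                f"{questionnaire}_t0": _score_or_nan(rec, cohort.catalog, questionnaire, "t0"),
                f"{questionnaire}_t1": _score_or_nan(rec, cohort.catalog, questionnaire, "t1"),
            }
        )
    return pd.DataFrame(rows)


def _score_or_nan(rec, catalog, questionnaire, tp):
    s = total_score(rec, catalog, questionnaire, tp)
    return math.nan if s is None else float(s)
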