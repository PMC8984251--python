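import pytest

from cohortjuxt.cohort_model import (
    Cohort,
    PatientRecord,
    QuestionnaireCatalog,
    QuestionnaireInfo,
)
from cohortjuxt.synthetic_cohort import (
    AdherencePropensity,
    CenterConfig,
    GeneratorConfig,
    default_paper_config,
    generate_cohort,
)


@pytest.fixture
def mini_catalog():
    """Two-center toy catalog: TQ shared; tinnitus distress and
    depressivity the shared categories; one center-specific category."""
    return QuestionnaireCatalog(
        entries={
            "TQ": QuestionnaireInfo(4, "TD", frozenset({"C1", "C2"}), (0.0, 8.0)),
            "TLQ": QuestionnaireInfo(2, "TD", frozenset({"C1"})),
            "THI": QuestionnaireInfo(2, "TD", frozenset({"C2"})),
            "ADSL": QuestionnaireInfo(2, "D", frozenset({"C1"})),
            "MDI": QuestionnaireInfo(2, "D", frozenset({"C2"})),
            "PSQ": QuestionnaireInfo(2, "stress", frozenset({"C1"})),
        }
    )


def make_record(pid="p1", center="C1", gender="f", age=50, responses=None):
    return PatientRecord(
        patient_id=pid, center=center, gender=gender, age=age,
        responses=dict(responses or {}),
    )


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def mini_cohort(mini_catalog):
    """Three patients at C1, two at C2, with varied TQ completeness."""
    recs = [
        make_record("C1-a", "C1", "f", 42, {
            ("TQ", "t0"): [1, 2, 0, 1], ("TQ", "t1"): [1, 1, 0, 0],
            ("TLQ", "t0"): [1, 0], ("ADSL", "t0"): [2, 2], ("PSQ", "t0"): [0, 1],
        }),
        make_record("C1-b", "C1", "m", 55, {
            ("TQ", "t0"): [2, 2, 1, 2], ("TQ", "t1"): [2, None, 1, 1],
            ("TLQ", "t0"): [None, None], ("ADSL", "t0"): [1, None],
        }),
        make_record("C1-c", "C1", "NA", 61, {
            ("TQ", "t0"): [0, None, 1, 1],
        }),
        make_record("C2-a", "C2", "f", 38, {
            ("TQ", "t0"): [1, 1, 1, 1], ("TQ", "t1"): [0, 1, 1, 0],
            ("THI", "t0"): [1, 1], ("MDI", "t0"): [0, 1],
        }),
        make_record("C2-b", "C2", "m", 47, {
            ("TQ", "t0"): [2, 0, 2, 1], ("THI", "t0"): [None, 1],
        }),
    ]
    return Cohort(records=recs, catalog=mini_catalog)


def small_two_center_config(seed=0, n1=120, n2=150, **center_kwargs):
    """Scaled-down version of the default two-center configuration."""
    from dataclasses import replace

    base = default_paper_config(seed=seed)
    centers = {
        "UHREG": replace(base.centers["UHREG"], n_patients=n1, **center_kwargs),
        "CHA": replace(base.centers["CHA"], n_patients=n2, **center_kwargs),
    }
    return GeneratorConfig(centers=centers, catalog=base.catalog, seed=seed)


def single_center_config(
    seed=0,
    n=400,
    center="CHA",
    noise_sd=7.0,
    clip=True,
    round_scores=True,
    dropout=0.0,
    full_adherence=True,
    **outcome_kwargs,
):
    """One-center configuration for regression experiments."""
    from dataclasses import replace

    from cohortjuxt.synthetic_cohort import OutcomeModel

    base = default_paper_config(seed=seed).centers[center]
    outcome = replace(
        base.outcome, noise_sd=noise_sd, clip=clip, **outcome_kwargs
    )
    kwargs = dict(
        n_patients=n, outcome=outcome, round_scores=round_scores, dropout_t1=dropout
    )
    if full_adherence:
        kwargs["adherence"] = {}
        kwargs["default_adherence"] = AdherencePropensity(1.0, 1.0, 10.0, 1.0)
    cfg = replace(base, **kwargs)
    return GeneratorConfig(
        centers={center: cfg},
        catalog=default_paper_config(seed=seed).catalog,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_generated_cohort():
    from cohortjuxt.synthetic_cohort import generate_cohort

    return generate_cohort(small_two_center_config(seed=11))
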