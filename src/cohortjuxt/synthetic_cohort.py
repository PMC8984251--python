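"""Synthetic two-center questionnaire cohorts.

The real two-center clinical datasets this pipeline is designed for are
restricted, so every downstream stage is exercised on synthetic cohorts
that reproduce the statistical structure the analysis relies on:

- two centers of unequal size with center-specific truncated-normal age
  distributions and gender mixes (including an unknown-gender fraction at
  one center),
- a bounded tinnitus-distress score (TQ, summed items on [0, 84]) at
  admission, and a post-treatment score generated by a linear-Gaussian
  response model ``TQ_t1 = b0 + b1*TQ_t0 + b2*age + gamma*1[male] + eps``
  with optional clipping to the score bounds,
- item-level missingness: each patient draws a per-questionnaire adherence
  propensity from a Beta distribution (with a point mass at full
  completion) and answers items independently given the propensity; whole
  response blocks can be absent, and the final visit can be missed
  entirely (dropout).

The linear outcome model is a deliberate choice: it makes the downstream
regression stage well-specified, so the achievable R-squared is exactly
signal variance over total variance and parameter recovery can be checked
to numerical precision.

One global seed is split deterministically into per-purpose substreams
(ages, genders, scores, missingness, item content), so changing one block
of the configuration does not perturb the draws of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort_model import (
    Cohort,
    PatientRecord,
    QuestionnaireCatalog,
    default_catalog,
)


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class OutcomeModel:
    """Linear-Gaussian treatment-response model for the t1 score."""

    intercept: float = 2.0
    slope_tq0: float = 0.75
    slope_age: float = 0.05
    gender_offset: float = 1.0  # added for male patients
    noise_sd: float = 7.0
    clip: bool = True  # clip TQ_t1 into the catalog score bounds


@dataclass(frozen=True)
class AdherencePropensity:
    """Per-questionnaire missingness model.

    With probability ``1 - present_prob`` the whole response block is
    unanswered.  Otherwise the patient is fully adherent with probability
    ``complete_prob``; with the remaining probability the per-item answer
    propensity is drawn from ``Beta(beta_a, beta_b)`` and items are
    answered independently.
    """

    present_prob: float = 1.0
    complete_prob: float = 0.9
    beta_a: float = 8.0
    beta_b: float = 2.0

    def mean_adherence(self) -> float:
        """Expected fraction of answered items."""
        beta_mean = self.beta_a / (self.beta_a + self.beta_b)
        return self.present_prob * (
            self.complete_prob + (1.0 - self.complete_prob) * beta_mean
        )


@dataclass(frozen=True)
class CenterConfig:
    """Generator block for one center."""

    n_patients: int
    age_mean: float
    age_sd: float
    age_bounds: tuple[float, float] = (18.0, 95.0)
    #: optional second age component (weight, mean, sd) to emulate the
    #: non-normal age distributions seen in real referral populations
    age_mixture: tuple[float, float, float] | None = None
    male_fraction: float = 0.5  # fraction of male among patients with known gender
    na_gender_fraction: float = 0.0
    tq0_mean: float = 42.0
    tq0_sd: float = 17.0
    outcome: OutcomeModel = field(default_factory=OutcomeModel)
    adherence: dict[str, AdherencePropensity] = field(default_factory=dict)
    default_adherence: AdherencePropensity = field(default_factory=AdherencePropensity)
    dropout_t1: float = 0.0
    #: round scores to integers (questionnaire convention); disable for
    #: exact parameter-recovery experiments
    round_scores: bool = True

    def propensity(self, questionnaire: str) -> AdherencePropensity:
        return self.adherence.get(questionnaire, self.default_adherence)

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be >= 0")
        for name, val in [("age_sd", self.age_sd), ("tq0_sd", self.tq0_sd)]:
            if val <= 0:
                raise ConfigError(f"{name} must be > 0")
        for name, val in [
            ("male_fraction", self.male_fraction),
            ("na_gender_fraction", self.na_gender_fraction),
            ("dropout_t1", self.dropout_t1),
        ]:
            if not (0.0 <= val <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {val}")
        if self.age_bounds[0] >= self.age_bounds[1]:
            raise ConfigError(f"degenerate age bounds {self.age_bounds}")


@dataclass(frozen=True)
class GeneratorConfig:
    centers: dict[str, CenterConfig]
    catalog: QuestionnaireCatalog = field(default_factory=default_catalog)
    seed: int = 0

    def validate(self) -> None:
        for name, block in self.centers.items():
            if name not in self.catalog.centers:
                raise ConfigError(f"center {name!r} not in catalog")
            block.validate()


# Table-derived defaults: cohort sizes and age moments per center, and the
# male fractions among patients with a complete admission record.
_UHREG_MALE_FRACTION = 473 / 733
_CHA_MALE_FRACTION = 1994 / 3822


def default_paper_config(seed: int = 0) -> GeneratorConfig:
    """Two-center default configuration.

    Center UHREG: 1,087 patients, age 53.7 +/- 12.9 years, male fraction
    473/733; sparse adherence outside the shared TQ and heavy final-visit
    dropout.  Center CHA: 3,822 patients before the 500-patient subsampling
    convention, age 50.3 +/- 12.2, male fraction 1,994/3,822, a small
    unknown-gender fraction, near-complete adherence and moderate dropout.
    Admission TQ moments are synthetic choices (nothing is published for
    the real cohorts); the response model gives a within-center signal
    fraction around 0.75.
    """
    catalog = default_catalog()
    uhreg = CenterConfig(
        n_patients=1087,
        age_mean=53.7,
        age_sd=12.9,
        male_fraction=_UHREG_MALE_FRACTION,
        na_gender_fraction=0.0,
        tq0_mean=42.0,
        tq0_sd=17.0,
        outcome=OutcomeModel(intercept=2.0, noise_sd=7.0),
        adherence={
            "TQ": AdherencePropensity(0.99, 0.90, 10.0, 1.0),
            "THI": AdherencePropensity(0.65, 0.60, 6.0, 2.0),
            "TFI": AdherencePropensity(0.65, 0.60, 6.0, 2.0),
            "TBF12": AdherencePropensity(0.65, 0.60, 6.0, 2.0),
            "CGI": AdherencePropensity(0.65, 0.60, 6.0, 2.0),
            "MDI": AdherencePropensity(0.90, 0.70, 6.0, 2.0),
        },
        dropout_t1=0.90,
    )
    cha = CenterConfig(
        n_patients=3822,
        age_mean=50.3,
        age_sd=12.2,
        male_fraction=_CHA_MALE_FRACTION,
        na_gender_fraction=0.03,
        tq0_mean=46.0,
        tq0_sd=17.0,
        outcome=OutcomeModel(intercept=4.0, noise_sd=7.0),
        default_adherence=AdherencePropensity(0.995, 0.92, 10.0, 1.0),
        dropout_t1=0.55,
    )
    return GeneratorConfig(
        centers={"UHREG": uhreg, "CHA": cha}, catalog=catalog, seed=seed
    )


# ---------------------------------------------------------------------------
# Generation


def _truncnorm(rng, mean, sd, bounds, size):
    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _draw_ages(rng, cfg: CenterConfig) -> np.ndarray:
    n = cfg.n_patients
    ages = _truncnorm(rng, cfg.age_mean, cfg.age_sd, cfg.age_bounds, n)
    if cfg.age_mixture is not None:
        w2, m2, s2 = cfg.age_mixture
        take = rng.random(n) < w2
        ages[take] = _truncnorm(rng, m2, s2, cfg.age_bounds, int(take.sum()))
    lo, hi = cfg.age_bounds
    return np.clip(np.rint(ages), np.ceil(lo), np.floor(hi)).astype(int)


def _compose_integer_items(rng, total: int, n_items: int, cap: int) -> np.ndarray:
    """Distribute ``total`` score units over items, each item <= cap."""
    slots = rng.permutation(n_items * cap)[:total]
    return np.bincount(slots // cap, minlength=n_items)


def _answer_mask(rng, prop: AdherencePropensity, n_items: int):
    """(present, mask of answered items) for one response block."""
    if rng.random() >= prop.present_prob:
        return False, np.zeros(n_items, dtype=bool)
    if rng.random() < prop.complete_prob:
        return True, np.ones(n_items, dtype=bool)
    p = rng.beta(prop.beta_a, prop.beta_b)
    return True, rng.random(n_items) < p


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Generate a cohort; identical (config, seed) yields identical output."""
    config.validate()
    catalog = config.catalog
    tq_range = catalog.entries["TQ"].score_range or (0.0, 84.0)
    records: list[PatientRecord] = []
    root = np.random.SeedSequence(config.seed)
    center_seeds = root.spawn(len(config.centers))

    for (center, cfg), cseed in zip(sorted(config.centers.items()), center_seeds):
        if cfg.round_scores and not cfg.outcome.clip:
            raise ConfigError("round_scores=True requires outcome clipping")
        r_age, r_gender, r_score, r_miss, r_items = (
            np.random.default_rng(s) for s in cseed.spawn(5)
        )
        n = cfg.n_patients
        ages = _draw_ages(r_age, cfg)
        p_na = cfg.na_gender_fraction
        p_m = cfg.male_fraction * (1.0 - p_na)
        p_f = (1.0 - cfg.male_fraction) * (1.0 - p_na)
        genders = r_gender.choice(["f", "m", "NA"], size=n, p=[p_f, p_m, p_na])

        tq0 = _truncnorm(r_score, cfg.tq0_mean, cfg.tq0_sd, tq_range, n)
        if cfg.round_scores:
            tq0 = np.rint(tq0)
        om = cfg.outcome
        eps = r_score.normal(0.0, om.noise_sd, size=n) if om.noise_sd > 0 else np.zeros(n)
        tq1 = (
            om.intercept
            + om.slope_tq0 * tq0
            + om.slope_age * ages
            + om.gender_offset * (genders == "m")
            + eps
        )
        if om.clip:
            tq1 = np.clip(tq1, tq_range[0], tq_range[1])
        if cfg.round_scores:
            tq1 = np.rint(tq1)
        dropout = r_miss.random(n) < cfg.dropout_t1

        tq_items = catalog.entries["TQ"].items
        for i in range(n):
            pid = f"{center}-{i:05d}"
            rec = PatientRecord(
                patient_id=pid, center=center, gender=str(genders[i]), age=int(ages[i])
            )
            for q in sorted(catalog.questionnaires(center)):
                info = catalog.entries[q]
                time_points = ("t0", "t1") if q == "TQ" else ("t0",)
                for tp in time_points:
                    if tp == "t1" and dropout[i]:
                        continue  # missed final visit: no block at all
                    _, mask = _answer_mask(r_miss, cfg.propensity(q), info.items)
                    if q == "TQ":
                        score = tq0[i] if tp == "t0" else tq1[i]
                        if cfg.round_scores:
                            values = _compose_integer_items(
                                r_items, int(score), info.items, cap=2
                            ).astype(float)
                        else:
                            values = np.full(info.items, score / info.items)
                    else:
                        values = r_items.integers(0, 4, size=info.items).astype(float)
                    block = [float(v) if m else None for v, m in zip(values, mask)]
                    rec.responses[(q, tp)] = [
                        (int(v) if v is not None and float(v).is_integer() else v)
                        for v in block
                    ]
            records.append(rec)

    provenance = {
        "generator": "cohortjuxt.synthetic_cohort",
        "seed": config.seed,
        "centers": {
            c: {"n_patients": cfg.n_patients} for c, cfg in sorted(config.centers.items())
        },
    }
    return Cohort(records=records, catalog=catalog, provenance=provenance)


def subsample(cohort: Cohort, center: str, n: int, seed: int) -> Cohort:
    """Uniform without-replacement subsample of one center's patients.

    Other centers are untouched.  ``n`` equal to the center size is the
    identity on that center; ``n = 0`` removes the center.
    """
    center_recs = [r for r in cohort.records if r.center == center]
    if n > len(center_recs):
        raise ValueError(
            f"cannot subsample {n} from {len(center_recs)} patients at {center!r}"
        )
    rng = np.random.default_rng(seed)
    keep_idx = set(rng.choice(len(center_recs), size=n, replace=False).tolist())
    keep_ids = {center_recs[i].patient_id for i in keep_idx}
    records = [
        r for r in cohort.records if r.center != center or r.patient_id in keep_ids
    ]
    provenance = dict(cohort.provenance)
    provenance.setdefault("subsample", []).append(
        {"center": center, "n": n, "seed": seed}
    )
    return Cohort(records=records, catalog=cohort.catalog, provenance=provenance)


# ---------------------------------------------------------------------------
# Analytic moments of the outcome model (used to set noise levels a priori)


def _truncnorm_var(mean, sd, bounds) -> float:
    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    return float(stats.truncnorm.var(a, b, loc=mean, scale=sd))


def analytic_signal_variance(cfg: CenterConfig, score_bounds=(0.0, 84.0)) -> float:
    """Variance of the linear predictor of TQ_t1 under the configuration.

    Age, admission score and gender are drawn independently, so the signal
    variance decomposes as ``b1^2 Var(TQ_t0) + b2^2 Var(age) +
    gamma^2 p(1-p)`` with truncated-normal variances and ``p`` the male
    fraction among patients with known gender.
    """
    om = cfg.outcome
    v_tq0 = _truncnorm_var(cfg.tq0_mean, cfg.tq0_sd, score_bounds)
    v_age = _truncnorm_var(cfg.age_mean, cfg.age_sd, cfg.age_bounds)
    p = cfg.male_fraction
    return (
        om.slope_tq0**2 * v_tq0
        + om.slope_age**2 * v_age
        + om.gender_offset**2 * p * (1.0 - p)
    )


def noise_sd_for_signal_fraction(
    cfg: CenterConfig, fraction: float, score_bounds=(0.0, 84.0)
) -> float:
    """Noise SD making signal variance / total variance equal ``fraction``."""
    if not (0.0 < fraction < 1.0):
        raise ConfigError("signal fraction must be in (0, 1)")
    sig = analytic_signal_variance(cfg, score_bounds)
    return float(np.sqrt(sig * (1.0 - fraction) / fraction))
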