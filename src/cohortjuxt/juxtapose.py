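"""Distribution juxtaposition between cohort strata and a reference population.

Age distributions of (center, gender) strata are compared pairwise with a
normality-gated two-sample test: Shapiro-Wilk on each sample decides
between Student's t test on the means (both samples compatible with
normality) and the Mann-Whitney U test otherwise.  Families of comparisons
are corrected with Bonferroni's adjustment of the critical value,
``p_crit = alpha / m``.  Kernel density curves and gender-proportion tables
support the visual juxtaposition against the general population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_model import Cohort

__all__ = [
    "ComparisonResult",
    "DensityCurve",
    "normality_test",
    "compare_two_samples",
    "bonferroni_critical",
    "default_comparisons",
    "run_family",
    "density_curve",
    "gender_proportions",
    "load_reference_population",
]


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one two-sample location comparison."""

    label1: str
    label2: str
    n1: int
    n2: int
    median1: float
    median2: float
    test_used: str  # "student-t" or "mann-whitney-u"
    statistic: float  # t statistic, or U of the first sample
    p_value: float
    alpha: float
    corrected_critical: float  # alpha / number of comparisons in the family
    significant_after_correction: bool


@dataclass(frozen=True)
class DensityCurve:
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float


def normality_test(sample, alpha: float = 0.05):
    """Shapiro-Wilk test; returns ``(statistic, p_value, normal)``.

    ``normal`` is the non-rejection decision ``p >= alpha``.  Constant
    samples and samples of fewer than 3 observations are rejected as
    degenerate input.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError(f"need at least 3 observations, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: normality is undefined")
    stat, p = stats.shapiro(x)
    return float(stat), float(p), bool(p >= alpha)


def bonferroni_critical(alpha: float, m: int) -> float:
    """Bonferroni-corrected critical value ``alpha / m`` for ``m`` comparisons."""
    if m < 1:
        raise ValueError(f"number of comparisons must be >= 1, got {m}")
    return alpha / m


#: per-group size up to which the Mann-Whitney null is enumerated exactly
#: (ties force the asymptotic branch, which corrects for them)
_EXACT_MW_MAX_N = 8


def compare_two_samples(
    s1,
    s2,
    alpha: float = 0.05,
    labels: tuple[str, str] = ("s1", "s2"),
    m_comparisons: int = 1,
    force: str = "auto",
) -> ComparisonResult:
    """Normality-gated two-sample comparison.

    Both samples are screened with Shapiro-Wilk at ``alpha``; if neither
    rejects, a two-sided Welch t test on the means is run, otherwise a
    two-sided Mann-Whitney U test.  The reported U statistic is U of the
    first sample, so ``U(s1, s2) + U(s2, s1) = n1 * n2`` up to ties.
    ``force`` overrides the gate with ``"student-t"`` or
    ``"mann-whitney-u"``.
    """
    if force not in ("auto", "student-t", "mann-whitney-u"):
        raise ValueError(f"unknown force option {force!r}")
    x1 = np.asarray(s1, dtype=float)
    x2 = np.asarray(s2, dtype=float)
    if force == "auto":
        _, _, normal1 = normality_test(x1, alpha)
        _, _, normal2 = normality_test(x2, alpha)
        use_t = normal1 and normal2
    else:
        use_t = force == "student-t"

    if use_t:
        test_used = "student-t"
        stat, p = stats.ttest_ind(x1, x2, equal_var=False)
    else:
        test_used = "mann-whitney-u"
        pooled = np.concatenate([x1, x2])
        no_ties = np.unique(pooled).size == pooled.size
        small = x1.size <= _EXACT_MW_MAX_N and x2.size <= _EXACT_MW_MAX_N
        method = "exact" if (small and no_ties) else "asymptotic"
        stat, p = stats.mannwhitneyu(x1, x2, alternative="two-sided", method=method)

    crit = bonferroni_critical(alpha, m_comparisons)
    return ComparisonResult(
        label1=labels[0],
        label2=labels[1],
        n1=int(x1.size),
        n2=int(x2.size),
        median1=float(np.median(x1)),
        median2=float(np.median(x2)),
        test_used=test_used,
        statistic=float(stat),
        p_value=float(p),
        alpha=alpha,
        corrected_critical=crit,
        significant_after_correction=bool(p < crit),
    )


def default_comparisons(cohort: Cohort) -> list[tuple[tuple[str, str], tuple[str, str]]]:
    """The standard six-fold age comparison family for a two-center cohort:

    female vs female and male vs male across centers, male vs female within
    each center, and the two cross-center mixed-gender pairs.
    """
    centers = cohort.centers
    if len(centers) != 2:
        raise ValueError(f"default comparison family needs 2 centers, got {centers}")
    c1, c2 = centers
    return [
        ((c1, "f"), (c2, "f")),
        ((c1, "m"), (c2, "m")),
        ((c1, "m"), (c1, "f")),
        ((c2, "m"), (c2, "f")),
        ((c1, "m"), (c2, "f")),
        ((c1, "f"), (c2, "m")),
    ]


def run_family(
    cohort: Cohort,
    comparisons=None,
    alpha: float = 0.05,
) -> list[ComparisonResult]:
    """Run a family of stratum age comparisons under one Bonferroni correction.

    Each comparison is a pair of (center, gender) strata; every result is
    flagged against ``alpha / len(comparisons)``.
    """
    if comparisons is None:
        comparisons = default_comparisons(cohort)
    m = len(comparisons)
    results = []
    for (st1, st2) in comparisons:
        ages = []
        for st in (st1, st2):
            recs = cohort.stratum(*st)
            if len(recs) < 3:
                raise ValueError(f"stratum {st} has fewer than 3 patients")
            ages.append([r.age for r in recs])
        results.append(
            compare_two_samples(
                ages[0],
                ages[1],
                alpha=alpha,
                labels=(f"{st1[0]}/{st1[1]}", f"{st2[0]}/{st2[1]}"),
                m_comparisons=m,
            )
        )
    return results


def density_curve(
    sample, bandwidth: float | None = None, n_points: int = 512
) -> DensityCurve:
    """Gaussian kernel density estimate of a sample.

    Bandwidth defaults to Scott's rule.  The grid spans the sample range
    padded by three bandwidths, so the returned curve integrates to 1 up to
    quadrature error.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise ValueError("zero-variance sample: bandwidth is undefined")
    if bandwidth is None:
        kde = stats.gaussian_kde(x)  # Scott's rule
    else:
        if bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        kde = stats.gaussian_kde(x, bw_method=bandwidth / sd)
    h = float(kde.factor * sd)
    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, n_points)
    return DensityCurve(grid=grid, density=kde(grid), bandwidth=h)


def gender_proportions(cohort: Cohort, reference: dict[str, float]) -> pd.DataFrame:
    """Per-center f/m proportions (over known genders) plus a reference row.

    ``reference`` maps gender to proportion and must sum to 1.
    """
    ref_total = sum(reference.values())
    if abs(ref_total - 1.0) > 1e-9:
        raise ValueError(f"reference proportions sum to {ref_total}, not 1")
    rows = []
    for center in cohort.centers:
        recs = [r for r in cohort.stratum(center) if r.gender in ("f", "m")]
        if not recs:
            raise ValueError(f"center {center!r} has no patients with known gender")
        n = len(recs)
        n_m = sum(1 for r in recs if r.gender == "m")
        rows.append({"source": center, "f": (n - n_m) / n, "m": n_m / n})
    rows.append({"source": "reference", "f": reference["f"], "m": reference["m"]})
    return pd.DataFrame(rows)


def load_reference_population() -> dict:
    """Bundled illustrative reference proportions for the general population.

    Returns ``{"gender": {gender: proportion}, "age": DataFrame}`` where the
    age table holds proportions per 10-year interval.  The numbers are
    rounded illustrative values for Germany, editable by replacing the
    bundled CSV; they are not an official census extract.
    """
    from importlib import resources

    ref = resources.files("cohortjuxt") / "data" / "reference_population.csv"
    with resources.as_file(ref) as p:
        df = pd.read_csv(p)
    gender = {
        row["key"]: float(row["proportion"])
        for _, row in df[df["kind"] == "gender"].iterrows()
    }
    age = df[df["kind"] == "age"][["key", "proportion"]].reset_index(drop=True)
    return {"gender": gender, "age": age}
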