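"""Cohort stratification, descriptive statistics and group comparisons."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .aggregate import SubjectSummary
from .errors import DegenerateTableError

AGE_BANDS = ("70.0-74.9", "75.0-79.9", "80.0-84.9", "85.0-89.9", "90.0-94.9", ">=95.0")
SPPB_BANDS = ("high", "moderate", "low")  # 12-10 / 9-7 / 6-0 points


@dataclass
class CohortRow:
    subject_id: str
    age: float  # years, continuous
    sex: str  # "female" | "male"
    sppb: int  # 0-12
    height: float | None = None  # cm
    summary: SubjectSummary | None = None


@dataclass(frozen=True)
class GroupLabel:
    age_band: str
    sppb_band: str


def assign_groups(age: float, sppb: int) -> GroupLabel:
    """Age band (5-year bands from 70, open-ended at 95) x SPPB band."""
    if not (0 <= sppb <= 12):
        raise ValueError("sppb must be an integer in 0..12")
    if age < 70:
        warnings.warn(f"age {age} below the study range; labelling out-of-range", stacklevel=2)
        age_band = "<70.0"
    elif age >= 95:
        age_band = AGE_BANDS[-1]
    else:
        age_band = AGE_BANDS[int((age - 70) // 5)]
    if sppb >= 10:
        sppb_band = "high"
    elif sppb >= 7:
        sppb_band = "moderate"
    else:
        sppb_band = "low"
    return GroupLabel(age_band=age_band, sppb_band=sppb_band)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann-Whitney U and two-sided p.

    Exact enumeration when min(n) <= 8 and there are no ties; otherwise the
    normal approximation with tie and continuity corrections.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if np.ptp(np.concatenate([x, y])) == 0:
        return float(x.size * y.size / 2.0), 1.0
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def chi2_independence(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence (no continuity correction)."""
    table = np.asarray(table, dtype=float)
    if (table < 0).any() or table.sum() <= 0:
        raise DegenerateTableError("counts must be non-negative with positive total")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateTableError("table has a zero margin")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def describe(values) -> dict[str, float]:
    """median, p25, p75 (linear interpolation), mean, sd (sample)."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    return {
        "median": float(np.percentile(v, 50, method="linear")),
        "p25": float(np.percentile(v, 25, method="linear")),
        "p75": float(np.percentile(v, 75, method="linear")),
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
    }


def sex_comparison_report(cohort: list[CohortRow], metric: str) -> dict:
    """Mann-Whitney comparison of one summary metric between sexes."""
    women = [getattr(r.summary, metric) for r in cohort if r.sex == "female" and r.summary]
    men = [getattr(r.summary, metric) for r in cohort if r.sex == "male" and r.summary]
    u, p = mann_whitney_u(women, men)
    return {
        "test": "mann_whitney_u",
        "metric": metric,
        "statistic": u,
        "p": p,
        "n_female": len(women),
        "n_male": len(men),
        "female": describe(women),
        "male": describe(men),
    }


def sppb_by_sex_table(cohort: list[CohortRow]) -> np.ndarray:
    """2 x 3 counts of sex by SPPB band (high / moderate / low)."""
    table = np.zeros((2, 3))
    for r in cohort:
        i = 0 if r.sex == "female" else 1
        j = SPPB_BANDS.index(assign_groups(max(r.age, 70.0), r.sppb).sppb_band)
        table[i, j] += 1
    return table
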