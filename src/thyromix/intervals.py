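"""Reference intervals, abnormal rates and group-comparison statistics.

The reference interval of an analyte is read off the fitted HEALTHY component
alone: its parametric 2.5th and 97.5th percentiles (for the default 95%
coverage).  Fitted intervals are compared against the guideline interval set
for Roche assay systems by the abnormal rate — the percent of subjects whose
value falls strictly outside an interval — with a chi-square test on the 2x2
classification table.  Age-band contrasts use the Kruskal-Wallis rank test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .cleaning import AGE_BAND_LABELS, StratifiedCohort
from .cohort import TRIMESTERS
from .errors import FitError, InsufficientDataError, InvalidParameterError
from .mixture import MixtureFit

#: display rounding per analyte (decimals)
ANALYTE_DECIMALS = {"TSH": 2, "FT4": 1}


@dataclass(frozen=True)
class ReferenceInterval:
    """Lower/upper reference limits of one analyte in one stratum."""

    analyte: str  # "TSH" | "FT4"
    lower: float
    upper: float
    trimester: Optional[str] = None
    age_band: Optional[str] = None
    coverage: float = 0.95
    source: str = "fitted"  # "fitted" | "guidelines"

    def __post_init__(self):
        if self.analyte not in ANALYTE_DECIMALS:
            raise InvalidParameterError(f"unknown analyte {self.analyte!r}")
        if not self.lower < self.upper:
            raise InvalidParameterError("lower limit must be below upper limit")
        if not 0 < self.coverage < 1:
            raise InvalidParameterError("coverage must lie in (0, 1)")

    def rounded(self) -> Tuple[float, float]:
        """Display limits at the analyte's conventional precision
        (TSH two decimals, FT4 one)."""
        d = ANALYTE_DECIMALS[self.analyte]
        return round(self.lower, d), round(self.upper, d)

    def contains(self, values) -> np.ndarray:
        """Abnormality is strict: a value exactly at a limit counts as
        inside the interval."""
        x = np.asarray(values, dtype=float)
        return (x >= self.lower) & (x <= self.upper)


def _guideline(analyte, trimester, lo, hi):
    return ReferenceInterval(analyte=analyte, lower=lo, upper=hi,
                             trimester=trimester, source="guidelines")


#: pregnancy guideline reference intervals for Roche assay systems
GUIDELINE_INTERVALS: Dict[Tuple[str, str], ReferenceInterval] = {
    ("TSH", "first"): _guideline("TSH", "first", 0.09, 4.52),
    ("TSH", "second"): _guideline("TSH", "second", 0.45, 4.32),
    ("TSH", "third"): _guideline("TSH", "third", 0.30, 4.98),
    ("FT4", "first"): _guideline("FT4", "first", 13.15, 20.78),
    ("FT4", "second"): _guideline("FT4", "second", 9.77, 18.89),
    ("FT4", "third"): _guideline("FT4", "third", 9.04, 15.22),
}


@dataclass
class ComparisonRow:
    """Abnormal rates of the same subjects under two interval sets, with the
    chi-square contrast."""

    rate_a: float  # %
    rate_b: float  # %
    chi_square: float
    p_value: float
    n: int
    trimester: Optional[str] = None
    analyte: Optional[str] = None
    exact_fallback: bool = False


def reference_limits(
    fit: MixtureFit,
    coverage: float = 0.95,
    analyte: str = "TSH",
    trimester: Optional[str] = None,
    age_band: Optional[str] = None,
) -> ReferenceInterval:
    """Parametric central-``coverage`` quantiles of the healthy component.

    Full precision is kept internally; use :meth:`ReferenceInterval.rounded`
    for display.  Refuses unconverged fits.
    """
    if not fit.converged:
        raise FitError("refusing to derive limits from an unconverged fit")
    if not 0 < coverage < 1:
        raise InvalidParameterError("coverage must lie in (0, 1)")
    alpha = (1.0 - coverage) / 2.0
    lo, hi = fit.healthy.ppf([alpha, 1.0 - alpha])
    return ReferenceInterval(
        analyte=analyte,
        lower=float(lo),
        upper=float(hi),
        trimester=trimester,
        age_band=age_band,
        coverage=coverage,
        source="fitted",
    )


def abnormal_rate(values, ri: ReferenceInterval) -> float:
    """Percent of values strictly outside the interval (a value exactly at a
    limit counts as normal)."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise InsufficientDataError("abnormal_rate needs at least one value")
    return float(100.0 * (~ri.contains(x)).mean())


def combined_abnormal_flags(
    tsh_values, ft4_values, ri_tsh: ReferenceInterval, ri_ft4: ReferenceInterval
) -> np.ndarray:
    """Per-subject TSH-and/or-FT4 abnormal flags (abnormal if either analyte
    is outside its interval); both vectors must be subject-aligned."""
    tsh = np.asarray(tsh_values, dtype=float)
    ft4 = np.asarray(ft4_values, dtype=float)
    if tsh.shape != ft4.shape:
        raise InvalidParameterError("analyte vectors must be subject-aligned")
    return ~ri_tsh.contains(tsh) | ~ri_ft4.contains(ft4)


def _rate_comparison(flags_a: np.ndarray, flags_b: np.ndarray, **meta) -> ComparisonRow:
    n = flags_a.size
    a_abn, b_abn = int(flags_a.sum()), int(flags_b.sum())
    table = np.array([[a_abn, n - a_abn], [b_abn, n - b_abn]], dtype=float)
    exact = False
    if table.sum(axis=0).min() == 0:  # a zero column makes expected cells zero
        exact = True
        _, p = stats.fisher_exact(table.astype(int))
        chi2 = 0.0 if a_abn == b_abn else np.inf
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return ComparisonRow(
        rate_a=100.0 * a_abn / n,
        rate_b=100.0 * b_abn / n,
        chi_square=float(chi2),
        p_value=float(p),
        n=n,
        exact_fallback=exact,
        **meta,
    )


def compare_abnormal_rates(
    values, ri_a: ReferenceInterval, ri_b: ReferenceInterval, mcnemar: bool = False, **meta
) -> ComparisonRow:
    """Abnormal rates of the same values under two interval sets with a 2x2
    chi-square (1 df, no continuity correction).

    The two classifications are of the same subjects; the chi-square on the
    pooled 2x2 table is the conventional presentation.  ``mcnemar=True``
    switches the p-value to the paired McNemar test instead.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise InsufficientDataError("need at least one value")
    flags_a = ~ri_a.contains(x)
    flags_b = ~ri_b.contains(x)
    row = _rate_comparison(flags_a, flags_b, **meta)
    if mcnemar:
        from statsmodels.stats.contingency_tables import mcnemar as _mcnemar

        paired = np.array(
            [
                [(~flags_a & ~flags_b).sum(), (~flags_a & flags_b).sum()],
                [(flags_a & ~flags_b).sum(), (flags_a & flags_b).sum()],
            ]
        )
        res = _mcnemar(paired, exact=True)
        row.p_value = float(res.pvalue)
        row.chi_square = float(res.statistic)
    return row


def compare_paired_flags(flags_a, flags_b, **meta) -> ComparisonRow:
    """As :func:`compare_abnormal_rates` but from precomputed per-subject
    abnormal flags (used for the combined TSH-and/or-FT4 contrast)."""
    a = np.asarray(flags_a, dtype=bool)
    b = np.asarray(flags_b, dtype=bool)
    if a.shape != b.shape or a.size == 0:
        raise InvalidParameterError("flag vectors must be non-empty and aligned")
    return _rate_comparison(a, b, **meta)


def kruskal_wallis(values, group_labels) -> Tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) across groups, p from chi-square with
    groups − 1 degrees of freedom."""
    x = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    if x.shape != labels.shape:
        raise InvalidParameterError("values and labels must be aligned")
    groups = [x[labels == g] for g in pd.unique(labels)]
    groups = [g for g in groups if g.size > 0]
    if len(groups) < 2:
        raise InsufficientDataError("Kruskal-Wallis needs at least two non-empty groups")
    if np.all(x == x[0]):
        return 0.0, 1.0  # every observation tied: no evidence of any contrast
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


# ---------------------------------------------------------------------------
# report assembly


@dataclass
class CohortReport:
    """Numeric report: population table, age-band medians with limits and
    Kruskal-Wallis p-values, abnormal-rate comparison against the guideline
    intervals, and the interval sets side by side."""

    population: pd.DataFrame
    age_bands: pd.DataFrame
    comparison: pd.DataFrame
    intervals: pd.DataFrame
    gaps: List[str] = field(default_factory=list)

    def to_text(self) -> str:
        parts = []
        if self.gaps:
            parts.append("MISSING STRATA: " + ", ".join(self.gaps) + "\n")
        for title, frame in (
            ("Population distribution by age and trimester", self.population),
            ("Age-band medians and reference limits", self.age_bands),
            ("Abnormal rates: guidelines vs fitted intervals", self.comparison),
            ("Reference intervals side by side", self.intervals),
        ):
            parts.append(f"== {title} ==\n{frame.to_string()}\n")
        return "\n".join(parts)


def population_table(cohort: StratifiedCohort) -> pd.DataFrame:
    """Counts and column percentages per age band x trimester, plus totals."""
    counts = cohort.counts()
    counts["all"] = counts.sum(axis=1)
    table = counts.copy().astype(object)
    for col in table.columns:
        total = counts[col].sum()
        for band in counts.index:
            n = int(counts.loc[band, col])
            pct = round(100.0 * n / total) if total else 0
            table.loc[band, col] = f"{n} ({pct})"
    table.loc["total"] = [f"{int(counts[c].sum())} (100)" for c in counts.columns]
    return table


def percentages_from_counts(counts: Sequence[int]) -> List[int]:
    """Column percentages as printed in a population table: 100*n/total,
    rounded to the nearest integer."""
    total = sum(counts)
    return [int(round(100.0 * c / total)) for c in counts]


def build_report(
    fits: Dict[Tuple[str, str], MixtureFit],
    cohort: StratifiedCohort,
    guidelines: Optional[Dict[Tuple[str, str], ReferenceInterval]] = None,
    coverage: float = 0.95,
) -> CohortReport:
    """Assemble the full numeric report from per-(analyte, trimester) fits and
    the cleaned stratified cohort.  Missing strata are flagged, not fatal."""
    guidelines = guidelines or GUIDELINE_INTERVALS
    gaps: List[str] = []
    fitted_ri: Dict[Tuple[str, str], ReferenceInterval] = {}
    for analyte in ("TSH", "FT4"):
        for trimester in TRIMESTERS:
            key = (analyte, trimester)
            if key not in fits or not fits[key].converged:
                gaps.append(f"{analyte}/{trimester}")
                continue
            fitted_ri[key] = reference_limits(
                fits[key], coverage=coverage, analyte=analyte, trimester=trimester
            )

    # (a) population distribution
    population = population_table(cohort)

    # (b) per-age-band medians with empirical central-95% ranges; the all-ages
    # row carries the fitted parametric limits and the Kruskal-Wallis contrast
    rows = []
    for analyte in ("TSH", "FT4"):
        d = ANALYTE_DECIMALS[analyte]
        for trimester in TRIMESTERS:
            all_values = cohort.values(analyte, trimester)
            if all_values.size == 0:
                if f"{analyte}/{trimester}" not in gaps:
                    gaps.append(f"{analyte}/{trimester}")
                continue
            for band in AGE_BAND_LABELS:
                v = cohort.values(analyte, trimester, band)
                if v.size == 0:
                    continue
                qlo, med, qhi = np.percentile(v, [2.5, 50, 97.5])
                rows.append(
                    dict(analyte=analyte, trimester=trimester, age_band=band,
                         n=v.size, median=round(float(med), d),
                         lower=round(float(qlo), d), upper=round(float(qhi), d),
                         kw_p=np.nan)
                )
            bands = [assign_band for assign_band in cohort.frame.loc[
                cohort.frame["trimester"] == trimester, "age_band"]]
            h, p = kruskal_wallis(all_values, np.asarray(bands))
            key = (analyte, trimester)
            ri = fitted_ri.get(key)
            rows.append(
                dict(analyte=analyte, trimester=trimester, age_band="all",
                     n=all_values.size, median=round(float(np.median(all_values)), d),
                     lower=ri.rounded()[0] if ri else np.nan,
                     upper=ri.rounded()[1] if ri else np.nan,
                     kw_p=p)
            )
    age_bands = pd.DataFrame(rows)

    # (c) abnormal-rate comparison per trimester: each analyte and combined
    comp_rows = []
    for trimester in TRIMESTERS:
        per_analyte_flags = {}
        for analyte in ("TSH", "FT4"):
            key = (analyte, trimester)
            if key not in fitted_ri or key not in guidelines:
                continue
            v = cohort.values(analyte, trimester)
            if v.size == 0:
                continue
            row = compare_abnormal_rates(
                v, guidelines[key], fitted_ri[key], trimester=trimester, analyte=analyte
            )
            comp_rows.append(row)
            per_analyte_flags[analyte] = (
                ~guidelines[key].contains(v),
                ~fitted_ri[key].contains(v),
            )
        if len(per_analyte_flags) == 2:
            g_flags = per_analyte_flags["TSH"][0] | per_analyte_flags["FT4"][0]
            f_flags = per_analyte_flags["TSH"][1] | per_analyte_flags["FT4"][1]
            comp_rows.append(
                compare_paired_flags(g_flags, f_flags, trimester=trimester,
                                     analyte="TSH and/or FT4")
            )
    comparison = pd.DataFrame(
        [
            dict(trimester=r.trimester, analyte=r.analyte,
                 guideline_rate=round(r.rate_a, 2), fitted_rate=round(r.rate_b, 2),
                 chi_square=round(r.chi_square, 2), p_value=r.p_value, n=r.n)
            for r in comp_rows
        ]
    )

    # (d) interval sets side by side (the numeric content of an
    # interval-comparison display)
    int_rows = []
    for analyte in ("TSH", "FT4"):
        for trimester in TRIMESTERS:
            key = (analyte, trimester)
            g = guidelines.get(key)
            f = fitted_ri.get(key)
            int_rows.append(
                dict(
                    analyte=analyte,
                    trimester=trimester,
                    fitted_lower=f.rounded()[0] if f else np.nan,
                    fitted_upper=f.rounded()[1] if f else np.nan,
                    guideline_lower=g.lower if g else np.nan,
                    guideline_upper=g.upper if g else np.nan,
                )
            )
    intervals = pd.DataFrame(int_rows)

    return CohortReport(
        population=population,
        age_bands=age_bands,
        comparison=comparison,
        intervals=intervals,
        gaps=gaps,
    )


def intervals_to_frame(intervals: Sequence[ReferenceInterval]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(analyte=ri.analyte, trimester=ri.trimester, age_band=ri.age_band,
                 lower=ri.rounded()[0], upper=ri.rounded()[1],
                 lower_full=ri.lower, upper_full=ri.upper,
                 coverage=ri.coverage, source=ri.source)
            for ri in intervals
        ]
    )
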