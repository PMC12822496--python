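"""Record-cleaning cascade and trimester / age-band stratification.

Raw laboratory extracts mix usable specimens with records that must not enter
reference-interval estimation.  Cleaning applies seven exclusion criteria in a
fixed order, attributing each excluded record to the FIRST criterion it
violates so that the resulting funnel reconciles exactly:

1. missing values (any analyte or the patient identifier absent / malformed)
2. patient age missing
3. sex is not female
4. age outside 20-45 years (inclusive bounds retained)
5. more than one record for the same patient during the period
   (all records of such patients are dropped)
6. analyte outside the analytical measurement range
   (TSH outside [0.005, 100.00] mIU/L, FT4 outside [0.3, 100] pmol/L;
   strict inequalities — a value exactly at a bound is retained)
7. TPO-Ab strictly above the positivity cutoff (34 IU/ml)

Records with a missing gestational week or a week below 4 cannot be assigned
a trimester and are excluded separately from the seven criteria.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Tuple

import numpy as np

from .cohort import LabRecord, TRIMESTERS, records_to_frame
from .errors import InvalidParameterError, InvalidWeekError

CRITERIA = (
    "missing_values",
    "age_missing",
    "not_female",
    "age_out_of_range",
    "multiple_records",
    "out_of_amr",
    "tpoab_positive",
)

AGE_BAND_LABELS = ("20-25", "26-30", "31-35", "36-40", "41-45")


@dataclass(frozen=True)
class CleaningConfig:
    """Thresholds of the exclusion cascade."""

    age_min: int = 20
    age_max: int = 45
    tsh_amr: Tuple[float, float] = (0.005, 100.00)  # mIU/L
    ft4_amr: Tuple[float, float] = (0.3, 100.0)  # pmol/L
    tpoab_cutoff: float = 34.0  # IU/ml, exclusive
    require_female: bool = True
    dedup_policy: str = "drop_all_rows_of_multi_record_patients"

    def __post_init__(self):
        if self.age_min >= self.age_max:
            raise InvalidParameterError("age_min must be below age_max")
        for name in ("tsh_amr", "ft4_amr"):
            lo, hi = getattr(self, name)
            if lo >= hi:
                raise InvalidParameterError(f"{name} lower bound must be below upper")


@dataclass
class ExclusionReport:
    """Per-criterion exclusion counts; the funnel's audit trail."""

    counts: dict = field(default_factory=lambda: {c: 0 for c in CRITERIA})
    invalid_week: int = 0
    n_input: int = 0
    n_retained: int = 0

    @property
    def total_excluded(self) -> int:
        return sum(self.counts.values()) + self.invalid_week

    def reconciles(self) -> bool:
        return self.n_input == self.n_retained + self.total_excluded

    def to_text(self) -> str:
        lines = [f"records in\t{self.n_input}"]
        for crit in CRITERIA:
            lines.append(f"excluded: {crit}\t{self.counts[crit]}")
        lines.append(f"excluded: invalid_gestational_week\t{self.invalid_week}")
        lines.append(f"records retained\t{self.n_retained}")
        return "\n".join(lines) + "\n"


def assign_trimester(gestational_week: Optional[int]) -> str:
    """Map a completed gestational week to its trimester.

    Weeks 4-12 are the first trimester, 13-27 the second, 28 and beyond the
    third.  Weeks below 4, or missing, cannot be assigned.
    """
    if gestational_week is None:
        raise InvalidWeekError("gestational week missing")
    week = int(gestational_week)
    if week < 4:
        raise InvalidWeekError(f"gestational week {week} below first-trimester start")
    if week <= 12:
        return "first"
    if week <= 27:
        return "second"
    return "third"


def assign_age_band(age: float) -> str:
    """Map an age in [20, 45] to one of the five 5-year bands (closed
    integer intervals; non-integer ages floored)."""
    a = math.floor(age)
    if a < 20 or a > 45:
        raise InvalidParameterError(f"age {age} outside [20, 45]; cleaning should prevent this")
    if a <= 25:
        return "20-25"
    if a <= 30:
        return "26-30"
    if a <= 35:
        return "31-35"
    if a <= 40:
        return "36-40"
    return "41-45"


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    if isinstance(value, str) and value.strip() == "":
        return True
    return False


def _first_violated(rec: LabRecord, cfg: CleaningConfig, multiplicity) -> Optional[str]:
    if (
        _is_missing(rec.patient_id)
        or _is_missing(rec.tsh)
        or _is_missing(rec.ft4)
        or _is_missing(rec.tpo_ab)
    ):
        return "missing_values"
    if _is_missing(rec.age):
        return "age_missing"
    if cfg.require_female and rec.sex != "female":
        return "not_female"
    age = math.floor(rec.age)
    if age < cfg.age_min or age > cfg.age_max:
        return "age_out_of_range"
    if multiplicity[rec.patient_id] > 1:
        return "multiple_records"
    if not (cfg.tsh_amr[0] <= rec.tsh <= cfg.tsh_amr[1]) or not (
        cfg.ft4_amr[0] <= rec.ft4 <= cfg.ft4_amr[1]
    ):
        return "out_of_amr"
    if rec.tpo_ab > cfg.tpoab_cutoff:
        return "tpoab_positive"
    return None


def clean_cohort(
    records: Iterable[LabRecord], config: Optional[CleaningConfig] = None
) -> Tuple[List[LabRecord], ExclusionReport]:
    """Apply the exclusion cascade; return retained records and the funnel.

    Patient multiplicity is counted over the whole input (any patient with
    more than one row loses all rows).  An empty input yields an empty output
    with a zeroed report.
    """
    cfg = config or CleaningConfig()
    records = list(records)
    report = ExclusionReport(n_input=len(records))

    multiplicity = Counter(
        r.patient_id for r in records if not _is_missing(r.patient_id)
    )

    retained: List[LabRecord] = []
    for rec in records:
        crit = _first_violated(rec, cfg, multiplicity)
        if crit is not None:
            report.counts[crit] += 1
            continue
        try:
            assign_trimester(rec.gestational_week)
        except InvalidWeekError:
            report.invalid_week += 1
            continue
        retained.append(rec)
    report.n_retained = len(retained)
    return retained, report


@dataclass
class StratifiedCohort:
    """Retained records indexed by trimester and 5-year maternal age band."""

    records: List[LabRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        frame = records_to_frame(self.records)
        if len(frame):
            frame["trimester"] = [
                assign_trimester(r.gestational_week) for r in self.records
            ]
            frame["age_band"] = [assign_age_band(r.age) for r in self.records]
        else:
            frame["trimester"] = []
            frame["age_band"] = []
        self._frame = frame

    @property
    def frame(self):
        return self._frame

    def values(self, analyte: str, trimester: str, age_band: Optional[str] = None) -> np.ndarray:
        """Value vector of one (analyte, trimester[, age band]) stratum."""
        col = analyte.lower()
        if col not in ("tsh", "ft4"):
            raise InvalidParameterError(f"unknown analyte {analyte!r}")
        if trimester not in TRIMESTERS:
            raise InvalidParameterError(f"unknown trimester {trimester!r}")
        mask = self._frame["trimester"] == trimester
        if age_band is not None:
            mask &= self._frame["age_band"] == age_band
        return self._frame.loc[mask, col].to_numpy(dtype=float)

    def counts(self) -> "np.ndarray":
        """Trimester x age-band record counts as a pandas crosstab."""
        import pandas as pd

        return pd.crosstab(self._frame["age_band"], self._frame["trimester"]).reindex(
            index=list(AGE_BAND_LABELS), columns=list(TRIMESTERS), fill_value=0
        )


def stratify(records: List[LabRecord], provenance: Optional[dict] = None) -> StratifiedCohort:
    """Build the stratified view of an already-cleaned cohort."""
    return StratifiedCohort(records=list(records), provenance=provenance or {})
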