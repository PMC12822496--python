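"""Synthetic laboratory cohorts with known ground truth.

Real thyroid-function records from routine care are a mixture: a dominant
non-pathologic pregnant population, smaller hypothyroid / hyperthyroid and
TPO-Ab-positive subpopulations, and administrative noise (duplicate requests,
out-of-range instrument values, missing fields, records from non-obstetric
patients).  This module generates such cohorts from explicit generating
parameters so that every downstream stage — cleaning, mixture estimation,
interval reporting — can be tested against a known truth.

Per trimester the healthy population is modelled as

* TSH  ~ Gamma(shape k, rate r)        (right-skewed, units mIU/L)
* FT4  ~ Normal(mu + b*(age - 28), sd) (approximately symmetric, pmol/L,
                                        with a small negative age slope b)

Default parameters are calibrated so the healthy component's central 95%
range reproduces published trimester-specific limits for a Roche assay
population (e.g. first trimester TSH 0.40-4.09 mIU/L, FT4 12.2-20.5 pmol/L).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .errors import InvalidParameterError

TRIMESTERS = ("first", "second", "third")

#: gestational-week span (completed weeks, inclusive) per trimester
TRIMESTER_WEEKS = {"first": (4, 12), "second": (13, 27), "third": (28, 40)}

#: central-95% healthy limits the default truth is calibrated to, per trimester
TSH_HEALTHY_LIMITS = {"first": (0.40, 4.09), "second": (0.57, 4.04), "third": (0.73, 4.07)}
FT4_HEALTHY_LIMITS = {"first": (12.2, 20.5), "second": (10.2, 18.2), "third": (9.0, 15.5)}

AGE_BANDS = ((20, 25), (26, 30), (31, 35), (36, 40), (41, 45))
#: maternal-age band proportions typical of a large obstetric laboratory
AGE_BAND_PROBS = (0.22, 0.44, 0.23, 0.09, 0.02)

#: per-trimester stratum sizes of a six-year single-centre extraction
DEFAULT_N_PER_TRIMESTER = (33382, 18804, 3137)

TPOAB_CUTOFF = 34.0  # IU/ml

DIRTY_TRIGGERS = (
    "missing_value",
    "male_sex",
    "age_out_of_range",
    "duplicate_patient",
    "out_of_amr",
    "tpoab_high",
)

COHORT_COLUMNS = (
    "patient_id",
    "age",
    "sex",
    "gestational_week",
    "tsh",
    "ft4",
    "tpo_ab",
    "truth_label",
)


@dataclass(frozen=True)
class StratumTruth:
    """Generating parameters of one trimester stratum."""

    trimester: str
    tsh_shape: float  # gamma shape k, dimensionless
    tsh_rate: float  # gamma rate r, per mIU/L
    ft4_mean: float  # pmol/L, at the reference age of 28 years
    ft4_sd: float  # pmol/L
    hypo_fraction: float = 0.0
    hyper_fraction: float = 0.0
    tpoab_pos_fraction: float = 0.0
    age_slope_ft4: float = -0.05  # pmol/L per year, non-positive
    hypo_tsh_shift: float = 4.0  # multiplicative, > 1
    hyper_tsh_scale: float = 0.05  # multiplicative, in (0, 1)
    ft4_patho_shift: float = 3.0  # pmol/L, subtracted for hypo / added for hyper
    tpoab_tsh_shift: float = 1.5  # multiplicative TSH elevation in TPO-Ab+ records

    def __post_init__(self):
        if self.trimester not in TRIMESTERS:
            raise InvalidParameterError(f"unknown trimester {self.trimester!r}")
        for name in ("tsh_shape", "tsh_rate", "ft4_sd"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be strictly positive")
        for name in ("hypo_fraction", "hyper_fraction", "tpoab_pos_fraction"):
            frac = getattr(self, name)
            if not 0 <= frac < 1:
                raise InvalidParameterError(f"{name} must lie in [0, 1)")
        if self.hypo_fraction + self.hyper_fraction >= 1:
            raise InvalidParameterError("hypo_fraction + hyper_fraction must be < 1")
        if self.age_slope_ft4 > 0:
            raise InvalidParameterError("age_slope_ft4 must be <= 0")
        if self.hypo_tsh_shift <= 1:
            raise InvalidParameterError("hypo_tsh_shift must exceed 1")
        if not 0 < self.hyper_tsh_scale < 1:
            raise InvalidParameterError("hyper_tsh_scale must lie in (0, 1)")

    def tsh_quantile(self, p) -> np.ndarray:
        """Healthy-TSH gamma quantile(s)."""
        return stats.gamma.ppf(p, self.tsh_shape, scale=1.0 / self.tsh_rate)

    def ft4_quantile(self, p) -> np.ndarray:
        """Healthy-FT4 normal quantile(s) at the reference age."""
        return stats.norm.ppf(p, loc=self.ft4_mean, scale=self.ft4_sd)


@dataclass(frozen=True)
class SyntheticTruth:
    """Full generating model of a synthetic cohort: one stratum per trimester,
    stratum sizes, the master seed and the rates of planted dirty records."""

    strata: tuple
    n_per_trimester: tuple
    seed: int = 1
    dirty_record_rates: dict = field(
        default_factory=lambda: {t: 0.01 for t in DIRTY_TRIGGERS}
    )

    def __post_init__(self):
        if len(self.strata) != len(TRIMESTERS):
            raise InvalidParameterError("need exactly one stratum per trimester")
        if tuple(s.trimester for s in self.strata) != TRIMESTERS:
            raise InvalidParameterError("strata must be ordered first/second/third")
        if len(self.n_per_trimester) != len(TRIMESTERS):
            raise InvalidParameterError("need one stratum size per trimester")
        if any(n < 0 for n in self.n_per_trimester):
            raise InvalidParameterError("stratum sizes must be non-negative")
        unknown = set(self.dirty_record_rates) - set(DIRTY_TRIGGERS)
        if unknown:
            raise InvalidParameterError(f"unknown dirty triggers {sorted(unknown)}")
        if any(not 0 <= r < 1 for r in self.dirty_record_rates.values()):
            raise InvalidParameterError("dirty record rates must lie in [0, 1)")

    def stratum(self, trimester: str) -> StratumTruth:
        return self.strata[TRIMESTERS.index(trimester)]


@dataclass
class LabRecord:
    """One specimen: demographics plus the three thyroid analytes.

    ``truth_label`` is set only on synthetic records and names the generating
    subpopulation (healthy / hypo / hyper / tpoab_pos / dirty).
    """

    patient_id: Optional[str]
    age: Optional[float]
    sex: str
    gestational_week: Optional[int]
    tsh: Optional[float]
    ft4: Optional[float]
    tpo_ab: Optional[float]
    truth_label: Optional[str] = None


def calibrate_gamma_to_limits(lower: float, upper: float, coverage: float = 0.95):
    """Solve for gamma (shape, rate) whose central ``coverage`` quantiles hit
    the given limits.  Deterministic two-dimensional root find in log space."""
    if not 0 < lower < upper:
        raise InvalidParameterError("need 0 < lower < upper")
    alpha = (1.0 - coverage) / 2.0

    def resid(logp):
        k, r = np.exp(logp)
        q = stats.gamma.ppf([alpha, 1.0 - alpha], k, scale=1.0 / r)
        return q - [lower, upper]

    # moment-flavoured start: treat the limits as mean +/- 2 sd
    mean0 = 0.5 * (lower + upper)
    sd0 = (upper - lower) / 4.0
    k0 = max((mean0 / sd0) ** 2, 0.2)
    sol = optimize.root(resid, np.log([k0, k0 / mean0]), tol=1e-12)
    if not sol.success:  # pragma: no cover - defensive
        raise InvalidParameterError(f"gamma calibration failed for ({lower}, {upper})")
    k, r = np.exp(sol.x)
    return float(k), float(r)


def calibrate_normal_to_limits(lower: float, upper: float, coverage: float = 0.95):
    """Normal (mean, sd) whose central ``coverage`` quantiles hit the limits."""
    if lower >= upper:
        raise InvalidParameterError("need lower < upper")
    z = stats.norm.ppf(1.0 - (1.0 - coverage) / 2.0)
    return float(0.5 * (lower + upper)), float((upper - lower) / (2.0 * z))


def default_truth_params(
    n_per_trimester: Sequence[int] = DEFAULT_N_PER_TRIMESTER,
    seed: int = 1,
    hypo_fraction: float = 0.05,
    hyper_fraction: float = 0.05,
    tpoab_pos_fraction: float = 0.05,
    dirty_record_rates: Optional[dict] = None,
) -> SyntheticTruth:
    """Generating truth calibrated to the published trimester-specific limits.

    The healthy TSH gamma and FT4 normal of each trimester are solved so their
    2.5th/97.5th percentiles equal the published limits; the implied medians
    then follow from the two-parameter families and are close to (but not
    exactly) the published medians.
    """
    strata = []
    for trimester in TRIMESTERS:
        k, r = calibrate_gamma_to_limits(*TSH_HEALTHY_LIMITS[trimester])
        mu, sd = calibrate_normal_to_limits(*FT4_HEALTHY_LIMITS[trimester])
        strata.append(
            StratumTruth(
                trimester=trimester,
                tsh_shape=k,
                tsh_rate=r,
                ft4_mean=mu,
                ft4_sd=sd,
                hypo_fraction=hypo_fraction,
                hyper_fraction=hyper_fraction,
                tpoab_pos_fraction=tpoab_pos_fraction,
            )
        )
    rates = {t: 0.01 for t in DIRTY_TRIGGERS}
    if dirty_record_rates is not None:
        rates.update(dirty_record_rates)
    return SyntheticTruth(
        strata=tuple(strata),
        n_per_trimester=tuple(int(n) for n in n_per_trimester),
        seed=int(seed),
        dirty_record_rates=rates,
    )


def _draw_ages(rng: np.random.Generator, n: int) -> np.ndarray:
    band_idx = rng.choice(len(AGE_BANDS), size=n, p=AGE_BAND_PROBS)
    lows = np.array([b[0] for b in AGE_BANDS])[band_idx]
    highs = np.array([b[1] for b in AGE_BANDS])[band_idx]
    return rng.integers(lows, highs + 1)


def _healthy_draw(rng, st: StratumTruth, n: int):
    """Ages, weeks and analyte values for n records from the healthy laws."""
    wk_lo, wk_hi = TRIMESTER_WEEKS[st.trimester]
    ages = _draw_ages(rng, n)
    weeks = rng.integers(wk_lo, wk_hi + 1, size=n)
    tsh = rng.gamma(st.tsh_shape, 1.0 / st.tsh_rate, size=n)
    ft4 = rng.normal(st.ft4_mean + st.age_slope_ft4 * (ages - 28), st.ft4_sd)
    tpo = rng.uniform(5.0, 30.0, size=n)  # TPO-Ab-negative range
    return ages, weeks, tsh, ft4, tpo


def generate_cohort(truth: SyntheticTruth) -> list:
    """Generate the full mixed cohort described by ``truth``.

    Healthy, hypothyroid (TSH multiplied up, FT4 shifted down), hyperthyroid
    (TSH scaled down, FT4 shifted up) and TPO-Ab-positive (TSH mildly
    elevated, TPO-Ab above the cutoff) records are drawn per trimester, then
    dirty records carrying exactly one cleaning trigger each are appended.
    Each trimester uses its own substream of the master seed, so regeneration
    with the same truth is bit-identical.
    """
    records: list = []
    for t_idx, trimester in enumerate(TRIMESTERS):
        st = truth.stratum(trimester)
        n = truth.n_per_trimester[t_idx]
        if n == 0:
            continue
        rng = np.random.default_rng([truth.seed, t_idx])

        n_hypo = int(round(n * st.hypo_fraction))
        n_hyper = int(round(n * st.hyper_fraction))
        n_tpo = int(round(n * st.tpoab_pos_fraction))
        n_healthy = n - n_hypo - n_hyper - n_tpo
        if n_healthy < 0:
            raise InvalidParameterError("contamination fractions exceed stratum size")

        stratum_records: list = []
        pid_counter = 0

        def new_pid():
            nonlocal pid_counter
            pid_counter += 1
            return f"P{t_idx}-{pid_counter:07d}"

        for label, count in (
            ("healthy", n_healthy),
            ("hypo", n_hypo),
            ("hyper", n_hyper),
            ("tpoab_pos", n_tpo),
        ):
            ages, weeks, tsh, ft4, tpo = _healthy_draw(rng, st, count)
            if label == "hypo":
                tsh = tsh * st.hypo_tsh_shift
                ft4 = ft4 - st.ft4_patho_shift
            elif label == "hyper":
                tsh = tsh * st.hyper_tsh_scale
                ft4 = ft4 + st.ft4_patho_shift
            elif label == "tpoab_pos":
                tsh = tsh * st.tpoab_tsh_shift
                tpo = rng.uniform(40.0, 400.0, size=count)
            for i in range(count):
                stratum_records.append(
                    LabRecord(
                        patient_id=new_pid(),
                        age=int(ages[i]),
                        sex="female",
                        gestational_week=int(weeks[i]),
                        tsh=float(tsh[i]),
                        ft4=float(ft4[i]),
                        tpo_ab=float(tpo[i]),
                        truth_label=label,
                    )
                )

        # dirty records: one trigger each, otherwise indistinguishable from healthy
        rates = truth.dirty_record_rates
        for trigger in DIRTY_TRIGGERS:
            count = int(round(rates.get(trigger, 0.0) * n))
            if trigger == "duplicate_patient":
                count -= count % 2  # planted as pairs sharing a patient_id
            if count == 0:
                continue
            ages, weeks, tsh, ft4, tpo = _healthy_draw(rng, st, count)
            if trigger == "duplicate_patient":
                for i in range(0, count, 2):
                    pid = new_pid()
                    for j in (i, i + 1):
                        stratum_records.append(
                            LabRecord(pid, int(ages[j]), "female", int(weeks[j]),
                                      float(tsh[j]), float(ft4[j]), float(tpo[j]),
                                      truth_label="dirty"))
                continue
            for i in range(count):
                rec = LabRecord(new_pid(), int(ages[i]), "female", int(weeks[i]),
                                float(tsh[i]), float(ft4[i]), float(tpo[i]),
                                truth_label="dirty")
                if trigger == "missing_value":
                    rec.tsh = None
                elif trigger == "male_sex":
                    rec.sex = "male"
                elif trigger == "age_out_of_range":
                    rec.age = int(rng.choice([18, 19, 46, 50]))
                elif trigger == "out_of_amr":
                    rec.tsh = 150.0
                elif trigger == "tpoab_high":
                    rec.tpo_ab = float(rng.uniform(40.0, 400.0))
                stratum_records.append(rec)

        order = rng.permutation(len(stratum_records))
        records.extend(stratum_records[i] for i in order)
    return records


# ---------------------------------------------------------------------------
# delimited-text round trip


def records_to_frame(records: Iterable[LabRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records], columns=list(COHORT_COLUMNS))


def frame_to_records(frame: pd.DataFrame) -> list:
    records = []
    for row in frame.itertuples(index=False):
        def get(name, cast=float):
            val = getattr(row, name, None)
            if val is None or (isinstance(val, float) and np.isnan(val)) or val == "":
                return None
            return cast(val)

        records.append(
            LabRecord(
                patient_id=get("patient_id", str),
                age=get("age", float),
                sex=get("sex", str) or "unknown",
                gestational_week=get("gestational_week", lambda v: int(float(v))),
                tsh=get("tsh"),
                ft4=get("ft4"),
                tpo_ab=get("tpo_ab"),
                truth_label=get("truth_label", str),
            )
        )
    return records


def write_cohort(records: Iterable[LabRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_cohort(path) -> list:
    return frame_to_records(pd.read_csv(path, dtype={"patient_id": str, "sex": str}))


def cohort_csv_bytes(records: Iterable[LabRecord]) -> bytes:
    buf = io.StringIO()
    records_to_frame(records).to_csv(buf, index=False)
    return buf.getvalue().encode()


def write_truth(truth: SyntheticTruth, path) -> None:
    doc = {
        "seed": truth.seed,
        "n_per_trimester": list(truth.n_per_trimester),
        "dirty_record_rates": dict(truth.dirty_record_rates),
        "strata": [asdict(s) for s in truth.strata],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_truth(path) -> SyntheticTruth:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return SyntheticTruth(
        strata=tuple(StratumTruth(**s) for s in doc["strata"]),
        n_per_trimester=tuple(doc["n_per_trimester"]),
        seed=doc["seed"],
        dirty_record_rates=doc.get("dirty_record_rates", {}),
    )
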