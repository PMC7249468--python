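"""Domain types and clinical-table utilities.

This module holds the study's basic vocabulary: single biomarker/albumin
measurements in canonical units, per-subject demographic records, the
age-dependent laboratory reference intervals, the CSF:blood albumin quotient
``Q_A`` (the standard index of blood-brain / blood-CSF barrier integrity), the
cohort summary table, and the Fisher-z power calculation used to size a
correlation study.

Canonical units
---------------
Biomarkers (S100B, NSE, in either compartment) are micrograms per litre;
CSF albumin is milligrams per litre; blood albumin is grams per litre.
``Q_A = albumin_CSF / albumin_blood`` is dimensionless and is computed after
converting CSF albumin from mg/L to g/L, so that ~0.005 is a typical normal
value and values above roughly 0.006-0.009 (age dependent) indicate barrier
disruption.
"""

from __future__ import annotations

import enum
import importlib.resources
import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "Analyte",
    "Measurement",
    "SubjectRecord",
    "ReferenceIntervals",
    "KAROLINSKA_REFERENCE",
    "PowerSpec",
    "Flag",
    "read_long_table",
    "write_long_table",
    "measurements_to_frame",
    "frame_to_measurements",
    "compute_qa",
    "flag_against_reference",
    "summarize_cohort",
    "required_sample_size",
    "correlation_power",
    "load_study_demographics",
    "round_half_away",
]


class Analyte(str, enum.Enum):
    """Measured analytes, tagged by compartment."""

    S100B_CSF = "S100B_CSF"
    S100B_BLOOD = "S100B_BLOOD"
    NSE_CSF = "NSE_CSF"
    NSE_BLOOD = "NSE_BLOOD"
    ALB_CSF = "ALB_CSF"
    ALB_BLOOD = "ALB_BLOOD"


#: canonical unit per analyte
CANONICAL_UNITS: dict[Analyte, str] = {
    Analyte.S100B_CSF: "ug/L",
    Analyte.S100B_BLOOD: "ug/L",
    Analyte.NSE_CSF: "ug/L",
    Analyte.NSE_BLOOD: "ug/L",
    Analyte.ALB_CSF: "mg/L",
    Analyte.ALB_BLOOD: "g/L",
}

# accepted unit spellings -> (canonical family, multiplier to that family's base)
# base units: ug/L for biomarkers, mg/L for mass-per-litre albumin units
_UNIT_SYNONYMS: dict[str, tuple[str, float]] = {
    "ug/l": ("ug/L", 1.0),
    "µg/l": ("ug/L", 1.0),
    "μg/l": ("ug/L", 1.0),
    "mcg/l": ("ug/L", 1.0),
    "ng/ml": ("ug/L", 1.0),
    "mg/l": ("mg/L", 1.0),
    "g/l": ("g/L", 1.0),
}

# conversion factors between mass-per-litre families, relative to mg/L
_MASS_PER_L = {"ug/L": 1e-3, "mg/L": 1.0, "g/L": 1e3}


@dataclass(frozen=True)
class Measurement:
    """One observation of one analyte in one compartment at one time.

    ``value`` is stored in the analyte's canonical unit; ``time_h`` is hours
    since trauma.
    """

    subject_id: str
    analyte: Analyte
    time_h: float
    value: float
    unit: str = ""

    def __post_init__(self) -> None:
        if self.time_h < 0:
            raise ValueError(f"time_h must be non-negative, got {self.time_h}")
        if not self.value > 0:
            raise ValueError(f"concentration must be positive, got {self.value}")
        canonical = CANONICAL_UNITS[Analyte(self.analyte)]
        if self.unit == "":
            object.__setattr__(self, "unit", canonical)
        elif self.unit != canonical:
            raise ValueError(
                f"{self.analyte}: unit {self.unit!r} is not canonical {canonical!r}"
            )


@dataclass(frozen=True)
class SubjectRecord:
    """Admission demographics and outcome for one study subject."""

    subject_id: str
    age: float
    sex: str  # 'M' or 'F'
    gcs: int  # Glasgow Coma Scale, 3-15
    pupils: int  # 0 both responsive, 1 unilateral, 2 bilateral unresponsive
    multitrauma: int  # 0/1
    ais_head: int  # Abbreviated Injury Scale 0-5 (6 unsurvivable, impossible at admission)
    ais_nonhead: int
    iss: int  # Injury Severity Score 1-75
    marshall: str  # admission CT classification I-VI (V/VI collapsed to mass lesion)
    rotterdam: int
    stockholm: float
    progression: int  # CT lesion progression 0/1
    gos: int  # Glasgow Outcome Scale 1-5 at 6 months

    def __post_init__(self) -> None:
        if not 3 <= self.gcs <= 15:
            raise ValueError(f"GCS must be in [3, 15], got {self.gcs}")
        if not 1 <= self.gos <= 5:
            raise ValueError(f"GOS must be in [1, 5], got {self.gos}")
        if self.ais_head > 5:
            raise ValueError("head AIS above 5 is impossible at admission")


class Flag(str, enum.Enum):
    """Classification of a value against its reference interval."""

    BELOW = "below"
    WITHIN = "within"
    ABOVE = "above"
    UNDEFINED_BAND = "undefined_band"


@dataclass(frozen=True)
class _Band:
    age_lo: float  # inclusive
    age_hi: float  # exclusive
    upper: float | None = None  # strict: value >= upper flags ABOVE
    lower: float | None = None  # strict: value <= ... no; value < lower flags BELOW


@dataclass(frozen=True)
class ReferenceIntervals:
    """Age-banded laboratory reference bounds.

    Upper bounds are strict ("< x"): a value equal to the bound is flagged
    ``above``.  Age bands the laboratory does not define (e.g. 30-49 years for
    CSF albumin and Q_A) yield :attr:`Flag.UNDEFINED_BAND` rather than a
    silently interpolated bound.
    """

    bands: Mapping[str, tuple[_Band, ...]]

    def classify(self, key: str, value: float, age: float | None = None) -> Flag:
        try:
            candidates = self.bands[key]
        except KeyError:
            raise KeyError(f"no reference interval defined for {key!r}") from None
        for b in candidates:
            if b.age_lo <= (age if age is not None else 0.0) < b.age_hi or (
                b.age_lo == -np.inf and b.age_hi == np.inf
            ):
                if b.lower is not None and value < b.lower:
                    return Flag.BELOW
                if b.upper is not None and value >= b.upper:
                    return Flag.ABOVE
                return Flag.WITHIN
        return Flag.UNDEFINED_BAND


_INF = np.inf

#: Karolinska University Laboratory intervals used by the study (Table-1-style)
KAROLINSKA_REFERENCE = ReferenceIntervals(
    bands={
        "ALB_CSF": (_Band(15, 30, upper=260.0), _Band(50, _INF, upper=400.0)),
        "ALB_BLOOD": (
            _Band(-_INF, 41, upper=48.0, lower=36.0),
            _Band(71, _INF, upper=45.0, lower=34.0),
        ),
        "QA": (_Band(15, 30, upper=0.006), _Band(50, _INF, upper=0.009)),
        "S100B_CSF": (_Band(-_INF, _INF, upper=5.0),),
        "S100B_BLOOD": (_Band(-_INF, _INF, upper=0.11),),
        "NSE_CSF": (_Band(-_INF, _INF, upper=13.0),),
        "NSE_BLOOD": (_Band(-_INF, _INF, upper=18.0),),
    }
)


# ---------------------------------------------------------------------------
# long-table I/O


def _normalize_unit(analyte: Analyte, value: float, unit: str) -> float:
    """Convert ``value`` expressed in ``unit`` to the analyte's canonical unit."""
    key = unit.strip().lower().replace("µ", "u").replace("μ", "u")
    if key not in _UNIT_SYNONYMS:
        raise ValueError(f"unparsable unit {unit!r}")
    family, mult = _UNIT_SYNONYMS[key]
    canonical = CANONICAL_UNITS[analyte]
    if canonical == "ug/L":
        if family != "ug/L":
            raise ValueError(f"unit {unit!r} invalid for biomarker {analyte}")
        return value * mult
    # albumin: any mass-per-litre unit is accepted and rescaled
    if family not in _MASS_PER_L:
        raise ValueError(f"unit {unit!r} invalid for {analyte}")
    in_mg_per_l = value * _MASS_PER_L[family]
    return in_mg_per_l / _MASS_PER_L[canonical]


def read_long_table(path_or_buf) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a long-format measurement CSV and normalize units.

    The file must have columns ``subject_id, analyte, time_hours, value, unit``.
    Returns ``(measurements, rejected)`` where ``measurements`` has columns
    ``subject_id, analyte, time_h, value, unit`` in canonical units and
    ``rejected`` lists dropped input rows with a ``reason`` column.  An empty
    file yields two empty frames.
    """
    try:
        raw = pd.read_csv(path_or_buf)
    except pd.errors.EmptyDataError:
        raw = pd.DataFrame(columns=["subject_id", "analyte", "time_hours", "value", "unit"])
    required = {"subject_id", "analyte", "time_hours", "value", "unit"}
    missing = required - set(raw.columns)
    if missing and len(raw):
        raise ValueError(f"long table is missing columns: {sorted(missing)}")

    rows, rejects = [], []
    for rec in raw.itertuples(index=False):
        reason = None
        try:
            analyte = Analyte(str(rec.analyte))
        except ValueError:
            reason = f"unknown analyte {rec.analyte!r}"
        if reason is None:
            value = float(rec.value)
            time_h = float(rec.time_hours)
            if not value > 0 or not np.isfinite(value):
                reason = f"non-positive value {rec.value!r}"
            elif time_h < 0:
                reason = f"negative time {rec.time_hours!r}"
            else:
                try:
                    value = _normalize_unit(analyte, value, str(rec.unit))
                except ValueError as exc:
                    reason = str(exc)
        if reason is None:
            rows.append(
                {
                    "subject_id": str(rec.subject_id),
                    "analyte": analyte.value,
                    "time_h": time_h,
                    "value": value,
                    "unit": CANONICAL_UNITS[analyte],
                }
            )
        else:
            rejects.append({**rec._asdict(), "reason": reason})
    meas = pd.DataFrame(rows, columns=["subject_id", "analyte", "time_h", "value", "unit"])
    rej = pd.DataFrame(rejects)
    return meas, rej


def write_long_table(measurements: pd.DataFrame, path_or_buf) -> None:
    """Write a canonical-unit measurement frame back to long-format CSV.

    Inverse of :func:`read_long_table` on canonical-unit data.
    """
    out = measurements.rename(columns={"time_h": "time_hours"})
    out = out[["subject_id", "analyte", "time_hours", "value", "unit"]]
    out.to_csv(path_or_buf, index=False)


def measurements_to_frame(measurements: Iterable[Measurement]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": m.subject_id,
            "analyte": Analyte(m.analyte).value,
            "time_h": m.time_h,
            "value": m.value,
            "unit": m.unit,
        }
        for m in measurements
    ]
    return pd.DataFrame(rows, columns=["subject_id", "analyte", "time_h", "value", "unit"])


def frame_to_measurements(frame: pd.DataFrame) -> list[Measurement]:
    return [
        Measurement(
            subject_id=str(r.subject_id),
            analyte=Analyte(r.analyte),
            time_h=float(r.time_h),
            value=float(r.value),
        )
        for r in frame.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# albumin quotient


def compute_qa(alb_csf_mg_per_l, alb_blood_g_per_l):
    """CSF:blood albumin quotient, ``(alb_csf/1000) / alb_blood``.

    CSF albumin is given in mg/L and blood albumin in g/L (the laboratory's
    reporting units); the quotient is dimensionless.  Accepts scalars or
    arrays; raises for non-positive concentrations.
    """
    csf = np.asarray(alb_csf_mg_per_l, dtype=float)
    blood = np.asarray(alb_blood_g_per_l, dtype=float)
    if np.any(csf <= 0) or np.any(blood <= 0):
        raise ValueError("albumin concentrations must be strictly positive")
    out = (csf / 1000.0) / blood
    return float(out) if out.ndim == 0 else out


def flag_against_reference(
    key: str | Analyte,
    value: float,
    age: float | None = None,
    reference: ReferenceIntervals = KAROLINSKA_REFERENCE,
) -> Flag:
    """Classify a measurement or a Q_A value against its reference interval.

    ``key`` is an analyte name or ``"QA"``.  Bounds are strict upper bounds:
    a value exactly at the bound flags ``above``.  Ages in an undefined band
    (e.g. 30-49 years for CSF albumin / Q_A) return ``undefined_band``.
    """
    key = key.value if isinstance(key, Analyte) else str(key)
    return reference.classify(key, float(value), age)


# ---------------------------------------------------------------------------
# cohort summary


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (so 31.25 -> 31.3 at one decimal)."""
    factor = 10.0**decimals
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


_CONTINUOUS = ["age", "gcs", "iss", "ais_head", "ais_nonhead", "rotterdam", "stockholm"]
_CATEGORICAL = ["sex", "pupils", "multitrauma", "marshall", "progression", "gos"]


def summarize_cohort(
    records: pd.DataFrame | Sequence[SubjectRecord],
    quantile_rule: str = "linear",
) -> pd.DataFrame:
    """Summarize a demographics table: median (IQR) and count (%).

    Continuous fields are reported as median with interquartile range
    (``quantile_rule`` is any interpolation accepted by
    :meth:`pandas.Series.quantile`; the quantile convention behind published
    IQRs is rarely stated, so it is exposed rather than fixed).  Categorical
    fields are reported per level as count with percentage rounded half away
    from zero to one decimal.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame([r.__dict__ for r in records])
    if len(records) == 0:
        raise ValueError("cannot summarize an empty cohort")
    rows = []
    for col in _CONTINUOUS:
        if col not in records.columns:
            continue
        s = records[col].astype(float)
        med = s.median()
        q1 = s.quantile(0.25, interpolation=quantile_rule)
        q3 = s.quantile(0.75, interpolation=quantile_rule)
        rows.append(
            {
                "variable": col,
                "level": "",
                "kind": "continuous",
                "median": med,
                "q1": q1,
                "q3": q3,
                "count": np.nan,
                "percent": np.nan,
                "display": f"{med:g} ({q1:g}-{q3:g})",
            }
        )
    n = len(records)
    for col in _CATEGORICAL:
        if col not in records.columns:
            continue
        counts = records[col].value_counts().sort_index()
        for level, cnt in counts.items():
            pct = round_half_away(100.0 * cnt / n, 1)
            rows.append(
                {
                    "variable": col,
                    "level": str(level),
                    "kind": "categorical",
                    "median": np.nan,
                    "q1": np.nan,
                    "q3": np.nan,
                    "count": int(cnt),
                    "percent": pct,
                    "display": f"{int(cnt)} ({pct}%)",
                }
            )
    return pd.DataFrame(rows)


def load_study_demographics() -> pd.DataFrame:
    """The 16-subject severe-TBI demographics table shipped with the package."""
    ref = importlib.resources.files("bbbflux.data") / "study_demographics.csv"
    return pd.read_csv(io.StringIO(ref.read_text()), dtype={"subject_id": str})


# ---------------------------------------------------------------------------
# sample size for a correlation study


@dataclass(frozen=True)
class PowerSpec:
    """Target effect size and error rates for a correlation power analysis."""

    r: float
    power: float = 0.80
    alpha: float = 0.05
    alternative: str = "one_sided"  # or "two_sided"

    def __post_init__(self) -> None:
        if not 0 < self.r < 1:
            raise ValueError("r must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")
        if not 0 < self.alpha < 0.5:
            raise ValueError("alpha must be in (0, 0.5)")
        if self.alternative not in ("one_sided", "two_sided"):
            raise ValueError("alternative must be one_sided or two_sided")


def correlation_power(n: float, spec: PowerSpec) -> float:
    """Power to detect a true Pearson correlation at sample size ``n``.

    Bias-corrected Fisher-z approximation: the test rejects when the sample
    correlation exceeds ``r_c``, the correlation equivalent of the t critical
    value with ``n - 2`` degrees of freedom, and the sampling distribution of
    ``atanh(r_hat)`` is taken as normal with mean ``atanh(r) + r / (2(n-1))``
    and standard deviation ``1 / sqrt(n - 3)``.
    """
    alpha = spec.alpha if spec.alternative == "one_sided" else spec.alpha / 2
    t_crit = stats.t.ppf(1 - alpha, n - 2)
    r_c = t_crit / np.sqrt(t_crit**2 + n - 2)
    z = (np.arctanh(spec.r) + spec.r / (2 * (n - 1)) - np.arctanh(r_c)) * np.sqrt(n - 3)
    return float(stats.norm.cdf(z))


def required_sample_size(spec: PowerSpec) -> int:
    """Subjects needed to reach the requested power, nearest integer.

    Solves ``correlation_power(n) = spec.power`` in continuous ``n`` and
    rounds to the nearest integer.  Raises if no solution with ``n >= 4``
    exists (power already above target at the minimum, or unreachable).
    """
    lo, hi = 4.0 + 1e-9, 1e7

    def gap(n: float) -> float:
        return correlation_power(n, spec) - spec.power

    if gap(lo) >= 0:
        raise ValueError("power target already met at n = 4; no interior solution")
    if gap(hi) < 0:
        raise ValueError("power target unreachable")
    n_cont = optimize.brentq(gap, lo, hi, xtol=1e-10)
    return int(np.floor(n_cont + 0.5))
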