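"""Non-genetic (PCE-style) risk scoring, eligibility filters, PRS
standardization and event-record classification.

The pooled-cohort-equation score is a sex-stratified proportional-hazards
risk: ``risk = 1 - S0 ** exp(xb - mean_lp)`` where ``xb`` applies a
stratum's coefficient map to log-transformed covariates and their
interactions, ``mean_lp`` is the stratum's mean linear predictor and
``S0`` its baseline survival.  Numeric coefficients are an external
configuration (JSON); the package ships a synthetic-labelled default
table, and the scoring contract is exercised with toy tables in tests.
"""

from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "PCECoefficients",
    "EventRecord",
    "ClassifiedEvent",
    "classify_events",
    "pce_eligibility",
    "compute_pce",
    "standardize_prs",
    "load_default_pce_coefficients",
    "events_from_csv",
]

DATED_CATEGORIES = frozenset({"ICD-10", "ICD-9", "OPCS-4"})
AGE_CODED_CATEGORIES = frozenset(
    {"self-report-illness", "self-report-operation", "vascular-heart-field"}
)

STATINS = ("atorvastatin", "simvastatin", "fluvastatin", "pravastatin", "rosuvastatin")


# ---------------------------------------------------------------------------
# PCE coefficients and scoring

@dataclass
class PCEStratum:
    coefficients: dict[str, float]
    mean_lp: float
    baseline_survival: float

    def validate(self) -> None:
        if not 0.0 < self.baseline_survival < 1.0:
            raise ValueError(
                f"baseline survival S0 must be in (0,1), got {self.baseline_survival}"
            )


@dataclass
class PCECoefficients:
    """Sex(/race)-stratified coefficient tables for the PCE-style score."""

    strata: dict[str, PCEStratum] = field(default_factory=dict)

    def validate(self) -> None:
        for s in self.strata.values():
            s.validate()

    def resolve(self, record: Mapping) -> PCEStratum:
        sex = record.get("sex")
        race = record.get("race")
        for key in (f"{sex}:{race}", str(sex)):
            if key in self.strata:
                return self.strata[key]
        raise KeyError(
            f"no coefficient stratum for sex={sex!r}, race={race!r}; "
            f"available: {sorted(self.strata)}"
        )

    @classmethod
    def from_dict(cls, d: Mapping) -> "PCECoefficients":
        strata = {
            k: PCEStratum(
                coefficients=dict(v["coefficients"]),
                mean_lp=float(v["mean_lp"]),
                baseline_survival=float(v["baseline_survival"]),
            )
            for k, v in d["strata"].items()
        }
        out = cls(strata=strata)
        out.validate()
        return out

    @classmethod
    def from_json(cls, path) -> "PCECoefficients":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def load_default_pce_coefficients() -> PCECoefficients:
    """Load the synthetic-labelled default coefficient table shipped as data."""
    text = (
        resources.files("groupwise_risk")
        .joinpath("data/pce_synthetic_coefficients.json")
        .read_text()
    )
    return PCECoefficients.from_dict(json.loads(text))


def _base_term(name: str, record: Mapping) -> float:
    """Evaluate one primitive coefficient term from an individual record."""

    def logfield(fieldname: str) -> float:
        v = record[fieldname]
        if v is None or not v > 0:
            raise ValueError(
                f"cannot log-transform non-positive {fieldname}={v!r}"
            )
        return math.log(v)

    treated = bool(record.get("htn_med", False))
    if name in ("ln_age", "log_age"):
        return logfield("age")
    if name in ("ln_age_sq", "log_age_sq"):
        return logfield("age") ** 2
    if name in ("ln_total_chol", "log_total_chol"):
        return logfield("total_chol")
    if name in ("ln_hdl", "log_hdl"):
        return logfield("hdl")
    if name in ("ln_sbp_treated", "log_sbp_treated"):
        return logfield("sbp") if treated else 0.0
    if name in ("ln_sbp_untreated", "log_sbp_untreated"):
        return logfield("sbp") if not treated else 0.0
    if name == "smoker":
        return float(bool(record.get("smoking", False)))
    if name == "diabetes":
        return float(bool(record.get("diabetes", False)))
    raise KeyError(f"unknown coefficient term {name!r}")


def evaluate_term(name: str, record: Mapping) -> float:
    """Evaluate a (possibly interaction) term like ``ln_age*smoker``."""
    name = name.strip().lower().replace("-", "_").replace(" ", "")
    value = 1.0
    for part in name.split("*"):
        value *= _base_term(part, record)
    return value


def compute_pce(record: Mapping, coef: PCECoefficients) -> float:
    """Proportional-hazards risk ``1 - S0**exp(xb - mean_lp)`` in (0, 1)."""
    stratum = coef.resolve(record)
    stratum.validate()
    xb = sum(
        c * evaluate_term(term, record)
        for term, c in stratum.coefficients.items()
    )
    return 1.0 - stratum.baseline_survival ** math.exp(xb - stratum.mean_lp)


# ---------------------------------------------------------------------------
# eligibility

_RANGE_RULES = (
    # field, lower, upper, reason (bounds are exclusive: exactly-at-bound is fine)
    ("total_chol", 130.0, 320.0, "total_cholesterol_extreme"),
    ("hdl", 20.0, 100.0, "hdl_extreme"),
    ("sbp", 90.0, 200.0, "sbp_extreme"),
)


def pce_eligibility(record: Mapping) -> tuple[bool, list[str]]:
    """Check every PCE eligibility rule; returns all violations, not the first.

    Rules: extreme total cholesterol (>320 or <130 mg/dl), HDL (>100 or
    <20 mg/dl) or systolic blood pressure (>200 or <90 mmHg); LDL-C
    >= 190 mg/dl; statin use; prior ASCVD.  Missing required measurements
    make the record ineligible with a ``missing:`` reason rather than
    being imputed.
    """
    reasons: list[str] = []
    for fieldname, lo, hi, reason in _RANGE_RULES:
        v = record.get(fieldname)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            reasons.append(f"missing:{fieldname}")
            continue
        if v < lo or v > hi:
            reasons.append(reason)
    ldl = record.get("ldl")
    if ldl is not None and not (isinstance(ldl, float) and math.isnan(ldl)):
        if ldl >= 190.0:
            reasons.append("ldl")
    if _is_statin_user(record):
        reasons.append("statin")
    if str(record.get("ascvd_status", "none")) == "prevalence":
        reasons.append("prior_ascvd")
    return (len(reasons) == 0, reasons)


def _is_statin_user(record: Mapping) -> bool:
    if bool(record.get("statin_user", False)):
        return True
    meds = record.get("medications")
    if meds:
        meds_lower = {str(m).lower() for m in meds}
        return any(s in meds_lower for s in STATINS)
    return False


# ---------------------------------------------------------------------------
# event classification

@dataclass(frozen=True)
class EventRecord:
    """One disease-event record from registry or self-report sources.

    Registry categories (ICD-10, ICD-9, OPCS-4) carry a calendar date;
    self-report categories carry an integer age at onset.
    """

    individual_id: object
    category: str
    code: str
    date: Optional[dt.date] = None
    age: Optional[int] = None

    def validate(self) -> None:
        if (self.date is None) == (self.age is None):
            raise ValueError(
                f"event for individual {self.individual_id!r} must have "
                "exactly one of date/age"
            )
        if self.category in DATED_CATEGORIES and self.date is None:
            raise ValueError(
                f"category {self.category} events carry dates "
                f"(individual {self.individual_id!r})"
            )
        if self.category in AGE_CODED_CATEGORIES and self.age is None:
            raise ValueError(
                f"category {self.category} events carry onset ages "
                f"(individual {self.individual_id!r})"
            )


@dataclass(frozen=True)
class ClassifiedEvent:
    individual_id: object
    status: str                      # "prevalence" | "incidence" | "none"
    earliest: Optional[EventRecord] = None
    event_date: Optional[dt.date] = None
    date_approximate: bool = False   # True when converted from an onset age


def _event_date(event: EventRecord, birth_year: int) -> tuple[dt.date, bool]:
    if event.date is not None:
        return event.date, False
    # onset age to date: mid-year (July 1) of birth_year + age; the true
    # date is ambiguous by about half a year either way
    return dt.date(int(birth_year) + int(event.age), 7, 1), True


def classify_events(
    events: Sequence[EventRecord],
    enrollment_date: dt.date,
    birth_year: int | Mapping[object, int],
    individual_ids: Optional[Iterable[object]] = None,
) -> dict[object, ClassifiedEvent]:
    """Resolve each individual's earliest event and prevalence/incidence status.

    The chronologically earliest event is kept per individual (ties broken
    by category then code, so the result is independent of input order);
    status is ``prevalence`` if it strictly precedes the enrollment date,
    else ``incidence``.  ``birth_year`` may be a single year or a map from
    individual id; it is only consulted for age-coded events.  Individuals
    listed in ``individual_ids`` with no events get status ``none``.
    """
    for e in events:
        e.validate()

    def year_for(ind) -> int:
        if isinstance(birth_year, Mapping):
            return int(birth_year[ind])
        return int(birth_year)

    out: dict[object, ClassifiedEvent] = {}
    by_individual: dict[object, list[tuple[dt.date, bool, EventRecord]]] = {}
    for e in events:
        d, approx = _event_date(e, year_for(e.individual_id))
        by_individual.setdefault(e.individual_id, []).append((d, approx, e))

    for ind, recs in by_individual.items():
        recs.sort(key=lambda t: (t[0], t[2].category, t[2].code))
        d, approx, earliest = recs[0]
        status = "prevalence" if d < enrollment_date else "incidence"
        out[ind] = ClassifiedEvent(ind, status, earliest, d, approx)

    if individual_ids is not None:
        for ind in individual_ids:
            if ind not in out:
                out[ind] = ClassifiedEvent(ind, "none")
    return out


def events_from_csv(path) -> list[EventRecord]:
    """Read event records from CSV with columns
    ``individual_id, category, code, date, age`` (one of date/age blank)."""
    import csv

    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            date = row.get("date") or None
            age = row.get("age") or None
            out.append(
                EventRecord(
                    individual_id=row["individual_id"],
                    category=row["category"],
                    code=row["code"],
                    date=dt.date.fromisoformat(date) if date else None,
                    age=int(age) if age else None,
                )
            )
    return out


# ---------------------------------------------------------------------------
# PRS standardization

def standardize_prs(values) -> np.ndarray:
    """Center and variance-standardize a score vector (sample SD, ddof=1)."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("standardize_prs needs a 1-d vector of length >= 2")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant vector (zero variance)")
    return (x - x.mean()) / sd
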