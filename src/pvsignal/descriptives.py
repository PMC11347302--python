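"""Descriptive summaries of a deduplicated report store.

Produces the standard "basic information" table of a pharmacovigilance
study: category counts with percentages for sex, age bands, reporter
occupation, country, route, serious outcomes, time-to-onset bands and
report year, plus median (Q1, Q3) for age and onset days.

Conventions
-----------
* Every percentage uses as denominator the sum of the category counts
  of its own characteristic.  For report-level characteristics that sum
  is the report total; for serious outcomes it is the number of outcome
  *entries* (one report may carry several outcomes); for onset it is
  the number of reports with therapy-date information.
* Percentages are rounded half-up to 2 decimals.
* Age bands are [<20, 20–30, ..., 70–80, ≥80), half-open on the right;
  onset bands are <7, 7–14, 14–28, 28–60, ≥60 days, also half-open.
* Time to onset is event date minus therapy start date in days; both
  dates must be complete to the day, and negative differences are
  counted as invalid rather than banded.
* Quantiles use the linear-interpolation convention
  (``numpy.percentile(method="linear")``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .faers_io import ReportCase, ReportStore, parse_faers_date

__all__ = [
    "DescriptiveSummary",
    "category_percentages",
    "quantiles",
    "onset_days",
    "age_band",
    "onset_band",
    "summarize",
]

AGE_EDGES = [0, 20, 30, 40, 50, 60, 70, 80]
AGE_LABELS = ["<20", "20-30", "30-40", "40-50", "50-60", "60-70", "70-80", ">=80"]
ONSET_EDGES = [0, 7, 14, 28, 60]
ONSET_LABELS = ["<7", "7-14", "14-28", "28-60", ">=60"]

_REPORTER_LABELS = {
    "consumer": "Consumer",
    "physician": "Physician",
    "pharmacist": "Pharmacist",
    "other_health_professional": "Other health-professional",
    "lawyer": "Lawyer",
    "unknown": "Unknown",
}
_OUTCOME_LABELS = {
    "other_serious": "Other serious",
    "hospitalization": "Hospitalization",
    "death": "Death",
    "life_threatening": "Life threatening",
    "disability": "Disability",
    "required_intervention": "Required intervention",
    "congenital_anomaly": "Congenital anomaly",
}


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (so 8.105 -> 8.11, not banker's 8.10)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def category_percentages(
    counts: list[tuple[str, int]],
) -> list[tuple[str, int, float]]:
    """Attach percentages to (category, count) pairs.

    The denominator is the sum of the supplied counts; percentages are
    rounded half-up to 2 decimals.  An all-zero characteristic yields
    0.0 percentages.
    """
    total = sum(c for _, c in counts)
    return [
        (cat, int(c), round_half_up(100.0 * c / total, 2) if total else 0.0)
        for cat, c in counts
    ]


def quantiles(values) -> tuple[float, float, float]:
    """(median, Q1, Q3) under linear interpolation; NaNs for empty input."""
    arr = np.asarray([v for v in values if v is not None and not np.isnan(v)], dtype=float)
    if arr.size == 0:
        return (float("nan"),) * 3
    med, q1, q3 = np.percentile(arr, [50, 25, 75], method="linear")
    return float(med), float(q1), float(q3)


def age_band(age_years: float | None) -> str | None:
    if age_years is None or np.isnan(age_years) or age_years < 0:
        return None
    for lo, hi, lab in zip(AGE_EDGES, AGE_EDGES[1:], AGE_LABELS):
        if lo <= age_years < hi:
            return lab
    return AGE_LABELS[-1]


def onset_band(days: float | None) -> str | None:
    if days is None or np.isnan(days) or days < 0:
        return None
    for lo, hi, lab in zip(ONSET_EDGES, ONSET_EDGES[1:], ONSET_LABELS):
        if lo <= days < hi:
            return lab
    return ONSET_LABELS[-1]


def onset_days(report: ReportCase) -> int | None:
    """Days from therapy start to the adverse event, if both dates are exact.

    Returns None when either date is missing or imprecise (year- or
    month-only).  A negative return value is the *invalid* marker: the
    event predates the recorded therapy start, and summaries count such
    reports separately instead of assigning a band.
    """
    start = parse_faers_date(report.therapy_start_date)
    event = parse_faers_date(report.event_date)
    if start is None or event is None or not (start[1] and event[1]):
        return None
    return int((event[0] - start[0]).days)


@dataclass
class DescriptiveSummary:
    """Category counts/percentages plus continuous summaries for one store."""

    n_reports: int
    characteristics: dict[str, list[tuple[str, int, float]]]
    age_median_q1_q3: tuple[float, float, float]
    onset_median_q1_q3: tuple[float, float, float]
    notes: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for char, cats in self.characteristics.items():
            for cat, count, pct in cats:
                rows.append(
                    {"characteristic": char, "category": cat, "count": count, "percent": pct}
                )
        return pd.DataFrame(rows, columns=["characteristic", "category", "count", "percent"])

    def save(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _vector_onsets(reports: pd.DataFrame) -> pd.Series:
    """Onset days per report; NaN when not computable, negatives kept."""
    start = reports["therapy_start_date"].astype("string")
    event = reports["event_date"].astype("string")
    ok = start.str.fullmatch(r"\d{8}").fillna(False) & event.str.fullmatch(r"\d{8}").fillna(False)
    s = pd.to_datetime(start.where(ok), format="%Y%m%d", errors="coerce")
    e = pd.to_datetime(event.where(ok), format="%Y%m%d", errors="coerce")
    return (e - s).dt.days.astype(float)


def summarize(store: ReportStore) -> DescriptiveSummary:
    """Compute the full descriptive summary of a deduplicated store."""
    rep = store.reports
    n = len(rep)
    chars: dict[str, list[tuple[str, int, float]]] = {}

    def add(name: str, counts: list[tuple[str, int]]) -> None:
        chars[name] = category_percentages(counts)

    # sex
    sex = rep["sex"].fillna("unknown") if n else pd.Series(dtype="string")
    add(
        "sex",
        [
            ("Female", int((sex == "F").sum())),
            ("Male", int((sex == "M").sum())),
            ("Unknown", int((~sex.isin(["F", "M"])).sum())),
        ],
    )

    # age bands
    age = pd.to_numeric(rep["age_years"], errors="coerce") if n else pd.Series(dtype=float)
    bands = pd.cut(
        age, bins=AGE_EDGES + [np.inf], labels=AGE_LABELS, right=False, include_lowest=True
    )
    age_counts = [(lab, int((bands == lab).sum())) for lab in AGE_LABELS]
    age_counts.append(("Unknown", int(age.isna().sum())))
    add("age", age_counts)

    # reporter
    reporter = rep["reporter"].fillna("unknown") if n else pd.Series(dtype="string")
    add(
        "reporter",
        [
            (label, int((reporter == key).sum()))
            for key, label in _REPORTER_LABELS.items()
        ],
    )

    # country (observed categories, missing -> Unknown)
    country = rep["country"].fillna("Unknown") if n else pd.Series(dtype="string")
    vc = country.value_counts()
    add("country", [(str(k), int(v)) for k, v in sorted(vc.items(), key=lambda kv: (-kv[1], kv[0]))])

    # route (missing folds into Others, matching spontaneous-report convention)
    route = rep["route"].fillna("Others") if n else pd.Series(dtype="string")
    route_counts = route.str.capitalize().value_counts()
    add("route", [(str(k), int(v)) for k, v in sorted(route_counts.items(), key=lambda kv: (-kv[1], kv[0]))])

    # serious outcomes: denominator is the outcome-entry total
    if n:
        entries = (
            rep["outcomes"].dropna().astype(str).str.split(";").explode()
        )
        entries = entries[entries != ""]
    else:
        entries = pd.Series(dtype="string")
    add(
        "serious_outcomes",
        [(label, int((entries == key).sum())) for key, label in _OUTCOME_LABELS.items()],
    )

    # onset: among reports with any therapy-date information
    onsets = _vector_onsets(rep) if n else pd.Series(dtype=float)
    has_ther = rep["therapy_start_date"].notna() if n else pd.Series(dtype=bool)
    valid = onsets[onsets >= 0]
    onset_bands = pd.cut(
        valid, bins=ONSET_EDGES + [np.inf], labels=ONSET_LABELS, right=False, include_lowest=True
    )
    n_invalid = int((onsets < 0).sum())
    n_unknown_onset = int((has_ther & onsets.isna()).sum()) if n else 0
    onset_counts = [(lab, int((onset_bands == lab).sum())) for lab in ONSET_LABELS]
    onset_counts.append(("Invalid", n_invalid))
    onset_counts.append(("Unknown", n_unknown_onset))
    add("onset_days", onset_counts)

    # report year
    if n:
        years = rep["receipt_date"].astype("string").str.slice(0, 4)
        years = years.where(years.str.fullmatch(r"\d{4}").fillna(False), "Unknown")
        yc = years.value_counts()
        add("report_year", [(str(k), int(v)) for k, v in sorted(yc.items())])
    else:
        add("report_year", [])

    return DescriptiveSummary(
        n_reports=n,
        characteristics=chars,
        age_median_q1_q3=quantiles(age.tolist() if n else []),
        onset_median_q1_q3=quantiles(valid.tolist() if n else []),
        notes={
            "n_invalid_onset": n_invalid,
            "n_with_therapy_date": int(has_ther.sum()) if n else 0,
        },
    )
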