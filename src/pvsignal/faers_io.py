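"""Reading, cleaning, deduplicating and linking FAERS-style quarterly ASCII tables.

FAERS distributes each quarter as six dollar-sign-delimited text tables
(DEMO, DRUG, REAC, OUTC, THER, RPSR).  Every report carries a ``caseid``
(the safety case) and a ``primaryid`` (a specific version of that case);
a case resubmitted with corrections appears several times with different
``primaryid`` values, so analyses keep only the most recent version per
case and then join the remaining tables on ``primaryid``.

This module parses the raw dialect, applies that deduplication rule,
standardizes free-text drug names through a user-supplied dictionary
(MedDRA and commercial drug thesauri are licensed, so the mapping is an
input), and links everything into a normalized :class:`ReportStore` whose
unit is the deduplicated report.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TABLE_NAMES",
    "FaersFormatError",
    "RejectedLine",
    "RawTableRow",
    "ParsedTable",
    "ReportCase",
    "ReportStore",
    "read_ascii_table",
    "deduplicate_cases",
    "standardize_drug_name",
    "load_drug_dictionary",
    "load_pt_to_soc",
    "link_reports",
    "ingest_quarters",
]

TABLE_NAMES = ("DEMO", "DRUG", "REAC", "OUTC", "THER", "RPSR")

#: FAERS serious-outcome codes -> normalized outcome names.
OUTCOME_CODES = {
    "DE": "death",
    "LT": "life_threatening",
    "HO": "hospitalization",
    "DS": "disability",
    "CA": "congenital_anomaly",
    "RI": "required_intervention",
    "OT": "other_serious",
}

#: FAERS reporter-occupation codes -> normalized categories.
OCCUPATION_CODES = {
    "CN": "consumer",
    "MD": "physician",
    "PH": "pharmacist",
    "OT": "other_health_professional",
    "HP": "other_health_professional",
    "LW": "lawyer",
}

#: Routes kept as named categories; everything else folds into "Others".
NAMED_ROUTES = {"ORAL", "OPHTHALMIC", "SUBCUTANEOUS", "PARENTERAL"}

DRUG_ROLES = ("PS", "SS", "C", "I")


class FaersFormatError(ValueError):
    """A table file violates the expected FAERS ASCII dialect."""


@dataclass(frozen=True)
class RejectedLine:
    """A data line that could not be parsed into the table's schema."""

    line_no: int
    raw: str
    reason: str


@dataclass(frozen=True)
class RawTableRow:
    """One raw line of a FAERS table, split but otherwise untouched."""

    table_name: str
    primary_id: str
    case_id: str
    payload: dict


@dataclass
class ParsedTable:
    """A parsed FAERS table: a string DataFrame plus the reject report.

    ``frame`` holds one row per well-formed data line with the header's
    (lower-cased) field names as columns; empty tokens are NaN.  Lines
    with the wrong field count are collected in ``rejects`` rather than
    silently dropped.
    """

    table_name: str
    frame: pd.DataFrame
    rejects: list[RejectedLine] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frame)

    def rows(self) -> Iterator[RawTableRow]:
        """Yield rows as :class:`RawTableRow` (convenience for small tables)."""
        cols = list(self.frame.columns)
        for rec in self.frame.itertuples(index=False):
            payload = dict(zip(cols, rec))
            pid = payload.get("primaryid")
            cid = payload.get("caseid")
            yield RawTableRow(
                table_name=self.table_name,
                primary_id="" if pid is None or pid != pid else str(pid),
                case_id="" if cid is None or cid != cid else str(cid),
                payload=payload,
            )


def _decode(data: bytes) -> str:
    try:
        return data.decode("utf-8")
    except UnicodeDecodeError:
        return data.decode("latin-1")


def read_ascii_table(path, table_name: str) -> ParsedTable:
    """Read one '$'-delimited FAERS quarterly table.

    The first line must be a header naming the fields.  Data lines with a
    field count different from the header's are collected into the
    table's reject report.  Empty tokens become missing values.
    """
    table_name = table_name.upper()
    if table_name not in TABLE_NAMES:
        raise ValueError(f"unknown table name {table_name!r}; expected one of {TABLE_NAMES}")
    text = _decode(Path(path).read_bytes())
    lines = text.splitlines()
    if not lines:
        raise FaersFormatError(f"{path}: empty file, no header line")
    header = [h.strip().lower() for h in lines[0].split("$")]
    if len(header) < 2 or any(not h for h in header) or len(set(header)) != len(header):
        raise FaersFormatError(
            f"{path}: malformed header at line 1: {lines[0]!r} "
            "(need >=2 unique, non-empty '$'-separated field names)"
        )
    n_fields = len(header)
    records: list[list[str]] = []
    rejects: list[RejectedLine] = []
    for line_no, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("$")
        if len(parts) != n_fields:
            rejects.append(
                RejectedLine(line_no, line, f"expected {n_fields} fields, got {len(parts)}")
            )
            continue
        records.append(parts)
    frame = pd.DataFrame(records, columns=header, dtype=object)
    if len(frame):
        frame = frame.apply(lambda s: s.str.strip())
        frame = frame.mask(frame == "")
    return ParsedTable(table_name=table_name, frame=frame, rejects=rejects)


# ---------------------------------------------------------------------------
# dates


def faers_date_sort_key(dates: pd.Series) -> pd.Series:
    """Map FAERS numeric date strings to sortable integers.

    Accepted precisions are YYYYMMDD, YYYYMM and YYYY; partial dates are
    truncated to the first month/day for ordering.  Unparseable dates map
    to -1, i.e. they sort as oldest and lose every recency comparison.
    """
    s = dates.astype("string").str.strip()
    digits = s.str.fullmatch(r"\d{4}|\d{6}|\d{8}").fillna(False)
    padded = s.where(digits).str.pad(8, side="right", fillchar="0")
    # "20230000"-style zero padding keeps year/month ordering correct
    return pd.to_numeric(padded, errors="coerce").fillna(-1).astype(np.int64)


def _plausible_date(s: pd.Series) -> pd.Series:
    return s.str.fullmatch(r"\d{4}|\d{6}|\d{8}").fillna(False)


def parse_faers_date(raw) -> tuple[pd.Timestamp, bool] | None:
    """Parse one FAERS date string.

    Returns ``(timestamp, precise)`` where ``precise`` is True only for
    full YYYYMMDD dates, or None when unparseable/missing.  Partial dates
    are truncated to the first day of their period.
    """
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    s = str(raw).strip()
    if len(s) == 4 and s.isdigit():
        s_full, precise = s + "0101", False
    elif len(s) == 6 and s.isdigit():
        s_full, precise = s + "01", False
    elif len(s) == 8 and s.isdigit():
        s_full, precise = s, True
    else:
        return None
    try:
        return pd.Timestamp(f"{s_full[:4]}-{s_full[4:6]}-{s_full[6:]}"), precise
    except ValueError:
        return None


# ---------------------------------------------------------------------------
# deduplication


def deduplicate_cases(demo: ParsedTable | pd.DataFrame) -> pd.DataFrame:
    """Keep one DEMO row per case: the most recent by FDA receipt date.

    Ties on the receipt date are broken by the larger ``primaryid``
    (numeric comparison when possible), which favours later-assigned
    report versions and is deterministic.  Rows with unparseable dates
    are treated as oldest.  Output rows are sorted by ``caseid``.
    """
    frame = demo.frame if isinstance(demo, ParsedTable) else demo
    required = {"caseid", "primaryid", "fda_dt"}
    missing = required - set(frame.columns)
    if missing:
        raise FaersFormatError(f"DEMO table lacks required fields: {sorted(missing)}")
    if frame.empty:
        return frame.copy()
    work = frame.copy()
    date_key = faers_date_sort_key(work["fda_dt"])
    n_bad = int((date_key == -1).sum() - work["fda_dt"].isna().sum())
    if n_bad > 0:
        warnings.warn(f"{n_bad} DEMO rows with unparseable fda_dt treated as oldest")
    pid = work["primaryid"].astype("string")
    pid_num = pd.to_numeric(pid, errors="coerce")
    work["_date_key"] = date_key
    work["_pid_num"] = pid_num.fillna(-1.0)
    work["_pid_str"] = pid.fillna("")
    work = work.sort_values(
        ["caseid", "_date_key", "_pid_num", "_pid_str"], kind="stable"
    ).drop_duplicates("caseid", keep="last")
    work = work.sort_values("caseid", kind="stable").reset_index(drop=True)
    return work.drop(columns=["_date_key", "_pid_num", "_pid_str"])


# ---------------------------------------------------------------------------
# drug-name standardization


def load_drug_dictionary(path) -> dict[str, str]:
    """Load a two-column delimited variant->canonical drug-name mapping.

    Tab- or '$'-delimited, optional header line ``variant<sep>canonical``.
    Keys are matched case-insensitively after whitespace trimming.
    """
    mapping: dict[str, str] = {}
    text = _decode(Path(path).read_bytes())
    for i, line in enumerate(text.splitlines()):
        if not line.strip():
            continue
        sep = "\t" if "\t" in line else "$"
        parts = [p.strip() for p in line.split(sep)]
        if len(parts) < 2:
            raise FaersFormatError(f"{path}: line {i + 1}: need two delimited columns")
        if i == 0 and parts[0].lower() in {"variant", "raw", "name"}:
            continue
        mapping[parts[0].upper()] = parts[1].upper()
    return mapping


def standardize_drug_name(raw: str, dictionary: Mapping[str, str]) -> str:
    """Map a verbatim drug name to its canonical form.

    Lookup is case-insensitive and whitespace-trimmed; names absent from
    the dictionary are returned upper-cased unchanged (the caller counts
    unmatched names).
    """
    key = str(raw).strip().upper()
    return dictionary.get(key, key)


def _standardize_series(raw: pd.Series, dictionary: Mapping[str, str]) -> tuple[pd.Series, int]:
    key = raw.astype("string").str.strip().str.upper()
    upper_map = {str(k).strip().upper(): v for k, v in dictionary.items()}
    std = key.map(upper_map)
    n_unmatched = int((std.isna() & key.notna()).sum())
    return std.fillna(key), n_unmatched


def load_pt_to_soc(path) -> dict[str, str]:
    """Load a two-column PT -> SOC mapping (tab- or '$'-delimited)."""
    mapping: dict[str, str] = {}
    text = _decode(Path(path).read_bytes())
    for i, line in enumerate(text.splitlines()):
        if not line.strip():
            continue
        sep = "\t" if "\t" in line else "$"
        parts = [p.strip() for p in line.split(sep)]
        if len(parts) < 2:
            raise FaersFormatError(f"{path}: line {i + 1}: need two delimited columns")
        if i == 0 and parts[0].lower() in {"pt", "term", "preferred_term"}:
            continue
        mapping[parts[0]] = parts[1]
    return mapping


# ---------------------------------------------------------------------------
# the normalized report store


@dataclass(frozen=True)
class ReportCase:
    """One deduplicated safety report with its linked drugs and reactions."""

    case_id: str
    primary_id: str
    receipt_date: str | None
    sex: str  # "F" | "M" | "unknown"
    age_years: float | None
    reporter: str
    country: str | None
    route: str | None
    outcomes: frozenset[str]
    event_date: str | None
    therapy_start_date: str | None
    pts: frozenset[str]
    drugs: tuple[tuple[str, str, str], ...]  # (raw, standardized, role)


_REPORT_COLUMNS = [
    "case_id",
    "primary_id",
    "receipt_date",
    "sex",
    "age_years",
    "reporter",
    "country",
    "route",
    "outcomes",
    "event_date",
    "therapy_start_date",
]


@dataclass
class ReportStore:
    """Normalized, deduplicated report store backing all downstream counting.

    ``reports`` has one row per case (columns ``_REPORT_COLUMNS``);
    ``report_pts`` one row per (case, PT) with PTs deduplicated within a
    report; ``report_drugs`` one row per (case, drug mention) with raw
    and standardized names and the FAERS role code.  ``meta`` carries the
    bookkeeping counters (orphans, rejects, unmatched drug names).
    """

    reports: pd.DataFrame
    report_pts: pd.DataFrame
    report_drugs: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def n_reports(self) -> int:
        return len(self.reports)

    def target_case_ids(self, drug: str, roles: Iterable[str] = ("PS",)) -> pd.Index:
        """Case ids whose standardized drug list contains *drug* in one of *roles*."""
        d = self.report_drugs
        mask = (d["drug_std"] == drug.upper()) & d["role"].isin(set(roles))
        return pd.Index(d.loc[mask, "case_id"].unique())

    def case(self, case_id: str) -> ReportCase:
        row = self.reports.loc[self.reports["case_id"] == case_id]
        if row.empty:
            raise KeyError(case_id)
        return self._build_case(row.iloc[0])

    def cases(self) -> Iterator[ReportCase]:
        for _, row in self.reports.iterrows():
            yield self._build_case(row)

    def _build_case(self, row: pd.Series) -> ReportCase:
        cid = row["case_id"]
        pts = frozenset(self.report_pts.loc[self.report_pts["case_id"] == cid, "pt"])
        d = self.report_drugs.loc[self.report_drugs["case_id"] == cid]
        drugs = tuple(
            (r["drug_raw"], r["drug_std"], r["role"]) for _, r in d.iterrows()
        )
        outs = row["outcomes"]
        outcomes = frozenset() if pd.isna(outs) or outs == "" else frozenset(str(outs).split(";"))
        age = row["age_years"]
        return ReportCase(
            case_id=cid,
            primary_id=row["primary_id"],
            receipt_date=_none(row["receipt_date"]),
            sex=row["sex"],
            age_years=None if pd.isna(age) else float(age),
            reporter=row["reporter"],
            country=_none(row["country"]),
            route=_none(row["route"]),
            outcomes=outcomes,
            event_date=_none(row["event_date"]),
            therapy_start_date=_none(row["therapy_start_date"]),
            pts=pts,
            drugs=drugs,
        )

    # -- persistence -------------------------------------------------------

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.reports.to_csv(out / "reports.tsv", sep="\t", index=False, na_rep="")
        self.report_pts.to_csv(out / "report_pts.tsv", sep="\t", index=False, na_rep="")
        self.report_drugs.to_csv(out / "report_drugs.tsv", sep="\t", index=False, na_rep="")
        (out / "store_meta.json").write_text(json.dumps(self.meta, indent=2, sort_keys=True))

    @classmethod
    def load(cls, in_dir) -> "ReportStore":
        src = Path(in_dir)
        str_cols = {
            c: "string"
            for c in _REPORT_COLUMNS
            if c != "age_years"
        }
        reports = pd.read_csv(
            src / "reports.tsv", sep="\t", dtype=str_cols, keep_default_na=True,
            na_values=[""],
        )
        reports["age_years"] = pd.to_numeric(reports["age_years"], errors="coerce")
        report_pts = pd.read_csv(src / "report_pts.tsv", sep="\t", dtype="string")
        report_drugs = pd.read_csv(src / "report_drugs.tsv", sep="\t", dtype="string")
        meta_path = src / "store_meta.json"
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(reports, report_pts.fillna(""), report_drugs.fillna(""), meta)

    def equals(self, other: "ReportStore") -> bool:
        """Value equality of the three tables (missing == missing)."""

        def norm(df: pd.DataFrame) -> pd.DataFrame:
            out = df.reset_index(drop=True).astype("string")
            return out.fillna("<NA>")

        if not norm(self.reports).equals(norm(other.reports)):
            return False
        key_pts = ["case_id", "pt"]
        if not norm(self.report_pts.sort_values(key_pts)).equals(
            norm(other.report_pts.sort_values(key_pts))
        ):
            return False
        key_d = list(self.report_drugs.columns)
        return norm(self.report_drugs.sort_values(key_d)).equals(
            norm(other.report_drugs.sort_values(key_d))
        )


def _none(v):
    return None if v is None or (isinstance(v, float) and np.isnan(v)) or pd.isna(v) else str(v)


# ---------------------------------------------------------------------------
# linking


def _convert_age(age: pd.Series, age_cod: pd.Series) -> pd.Series:
    """Convert FAERS (age, age_cod) pairs to years; implausible -> missing."""
    a = pd.to_numeric(age, errors="coerce")
    cod = age_cod.astype("string").str.strip().str.upper().fillna("YR")
    factor = cod.map(
        {"YR": 1.0, "DEC": 10.0, "MON": 1 / 12, "WK": 1 / 52.1775, "DY": 1 / 365.25, "HR": 1 / 8766.0}
    )
    years = a * factor
    return years.where((years >= 0) & (years < 150))


def _normalize_route(route: pd.Series) -> pd.Series:
    r = route.astype("string").str.strip().str.upper()
    return r.where(r.isna() | r.isin(NAMED_ROUTES), "Others")


def link_reports(
    demo: ParsedTable | pd.DataFrame,
    drug: ParsedTable | pd.DataFrame,
    reac: ParsedTable | pd.DataFrame,
    outc: ParsedTable | pd.DataFrame | None = None,
    ther: ParsedTable | pd.DataFrame | None = None,
    drug_dictionary: Mapping[str, str] | None = None,
) -> ReportStore:
    """Join the quarterly tables on ``primaryid`` into a :class:`ReportStore`.

    ``demo`` must already be deduplicated.  DRUG/REAC/OUTC/THER rows whose
    ``primaryid`` has no DEMO row are counted as orphans; reports with no
    reaction rows are dropped and counted.  Drug names are standardized
    through *drug_dictionary* (raw names are preserved alongside).
    """

    def _frame(x):
        if x is None:
            return pd.DataFrame(columns=["primaryid", "caseid"])
        return x.frame if isinstance(x, ParsedTable) else x

    demo_f = _frame(demo)
    drug_f, reac_f = _frame(drug), _frame(reac)
    outc_f, ther_f = _frame(outc), _frame(ther)
    dictionary = drug_dictionary or {}

    pid_to_case = demo_f.set_index("primaryid")["caseid"]
    known = pd.Index(pid_to_case.index)

    def _attach_case(f: pd.DataFrame) -> tuple[pd.DataFrame, int]:
        in_demo = f["primaryid"].isin(known)
        orphans = int((~in_demo).sum())
        g = f.loc[in_demo].copy()
        g["case_id"] = g["primaryid"].map(pid_to_case)
        return g, orphans

    drug_g, orphan_drug = _attach_case(drug_f)
    reac_g, orphan_reac = _attach_case(reac_f)
    outc_g, orphan_outc = _attach_case(outc_f)
    ther_g, orphan_ther = _attach_case(ther_f)

    # reactions: PT sets per report
    reac_g = reac_g.dropna(subset=["pt"]) if "pt" in reac_g.columns else reac_g
    report_pts = (
        reac_g[["case_id", "pt"]].drop_duplicates().reset_index(drop=True)
        if len(reac_g)
        else pd.DataFrame(columns=["case_id", "pt"])
    )
    cases_with_pts = pd.Index(report_pts["case_id"].unique())
    n_zero_reaction = int(len(demo_f) - len(cases_with_pts))

    keep = demo_f["caseid"].isin(cases_with_pts)
    demo_kept = demo_f.loc[keep].copy()

    # drugs
    if len(drug_g):
        std, n_unmatched = _standardize_series(drug_g["drugname"], dictionary)
        report_drugs = pd.DataFrame(
            {
                "case_id": drug_g["case_id"].astype("string"),
                "drug_seq": drug_g.get("drug_seq", pd.Series(index=drug_g.index, dtype="string")).astype("string"),
                "drug_raw": drug_g["drugname"].astype("string").fillna(""),
                "drug_std": std.astype("string").fillna(""),
                "role": drug_g.get("role_cod", pd.Series(index=drug_g.index, dtype="string"))
                .astype("string")
                .str.strip()
                .str.upper()
                .fillna(""),
            }
        )
        report_drugs = report_drugs[report_drugs["case_id"].isin(cases_with_pts)]
        report_drugs = report_drugs.reset_index(drop=True)
    else:
        n_unmatched = 0
        report_drugs = pd.DataFrame(
            columns=["case_id", "drug_seq", "drug_raw", "drug_std", "role"]
        )

    # outcomes: decoded, sorted, semicolon-joined per report
    if len(outc_g) and "outc_cod" in outc_g.columns:
        oc = outc_g.dropna(subset=["outc_cod"]).copy()
        oc["outcome"] = oc["outc_cod"].str.strip().str.upper().map(OUTCOME_CODES)
        oc = oc.dropna(subset=["outcome"]).drop_duplicates(["case_id", "outcome"])
        outcomes = oc.groupby("case_id")["outcome"].apply(lambda s: ";".join(sorted(s)))
    else:
        outcomes = pd.Series(dtype=object)

    # therapy start: prefer THER rows linked to a PS drug_seq, else earliest
    ther_start = _therapy_starts(ther_g, report_drugs)

    sex = (
        demo_kept.get("sex", pd.Series(index=demo_kept.index, dtype="string"))
        .astype("string")
        .str.strip()
        .str.upper()
    )
    sex = sex.where(sex.isin(["F", "M"]), "unknown").fillna("unknown")
    reporter = (
        demo_kept.get("occp_cod", pd.Series(index=demo_kept.index, dtype="string"))
        .astype("string")
        .str.strip()
        .str.upper()
        .map(OCCUPATION_CODES)
        .fillna("unknown")
    )
    age_years = _convert_age(
        demo_kept.get("age", pd.Series(index=demo_kept.index, dtype="string")),
        demo_kept.get("age_cod", pd.Series(index=demo_kept.index, dtype="string")),
    )

    # route of the suspect drug: first PS row per report
    if len(drug_g) and "route" in drug_g.columns and "role_cod" in drug_g.columns:
        role = drug_g["role_cod"].astype("string").str.strip().str.upper()
        ps_routes = (
            drug_g.loc[role == "PS"]
            .dropna(subset=["route"])
            .drop_duplicates("case_id")
            .set_index("case_id")["route"]
        )
        route = demo_kept["caseid"].map(_normalize_route(ps_routes))
    else:
        route = pd.Series(index=demo_kept.index, dtype="string")

    reports = pd.DataFrame(
        {
            "case_id": demo_kept["caseid"].astype("string"),
            "primary_id": demo_kept["primaryid"].astype("string"),
            "receipt_date": demo_kept.get("fda_dt", pd.Series(dtype="string")).astype("string"),
            "sex": sex.astype("string"),
            "age_years": age_years.astype(float).round(4),
            "reporter": reporter.astype("string"),
            "country": demo_kept.get(
                "reporter_country", pd.Series(index=demo_kept.index, dtype="string")
            ).astype("string"),
            "route": route.astype("string"),
            "outcomes": demo_kept["caseid"].map(outcomes).astype("string"),
            "event_date": demo_kept.get(
                "event_dt", pd.Series(index=demo_kept.index, dtype="string")
            ).astype("string"),
            "therapy_start_date": demo_kept["caseid"].map(ther_start).astype("string"),
        }
    ).reset_index(drop=True)

    meta = {
        "n_demo_rows": int(len(demo_f)),
        "n_reports": int(len(reports)),
        "n_zero_reaction_reports": n_zero_reaction,
        "n_orphan_drug_rows": orphan_drug,
        "n_orphan_reac_rows": orphan_reac,
        "n_orphan_outc_rows": orphan_outc,
        "n_orphan_ther_rows": orphan_ther,
        "n_unmatched_drug_names": n_unmatched,
    }
    report_pts = report_pts.astype({"case_id": "string", "pt": "string"})
    return ReportStore(reports, report_pts, report_drugs, meta)


def _therapy_starts(ther_g: pd.DataFrame, report_drugs: pd.DataFrame) -> pd.Series:
    """Earliest therapy start per case, preferring rows linked to a PS drug."""
    if not len(ther_g) or "start_dt" not in ther_g.columns:
        return pd.Series(dtype=object)
    t = ther_g.dropna(subset=["start_dt"]).copy()
    if not len(t):
        return pd.Series(dtype=object)
    t["_key"] = faers_date_sort_key(t["start_dt"])
    t = t[t["_key"] >= 0]
    ps_seq = report_drugs.loc[report_drugs["role"] == "PS", ["case_id", "drug_seq"]]
    if "dsg_drug_seq" in t.columns and len(ps_seq):
        merged = t.merge(
            ps_seq.rename(columns={"drug_seq": "dsg_drug_seq"}),
            on=["case_id", "dsg_drug_seq"],
            how="left",
            indicator=True,
        )
        is_ps = merged["_merge"] == "both"
        preferred = merged[is_ps]
        fallback = merged[~merged["case_id"].isin(preferred["case_id"])]
        t = pd.concat([preferred, fallback])
    first = t.sort_values(["case_id", "_key"], kind="stable").drop_duplicates("case_id")
    return first.set_index("case_id")["start_dt"]


# ---------------------------------------------------------------------------
# directory-level ingest


def ingest_quarters(
    quarters_dir,
    drug_dictionary: Mapping[str, str] | None = None,
) -> ReportStore:
    """Read every quarterly table file under *quarters_dir* and build the store.

    Files are matched case-insensitively by prefix (``DEMO*``, ``DRUG*``,
    ...).  All quarters are concatenated before deduplication, so a case
    resubmitted in a later quarter supersedes earlier versions.
    """
    root = Path(quarters_dir)
    parsed: dict[str, list[pd.DataFrame]] = {t: [] for t in TABLE_NAMES}
    rejects: dict[str, int] = {t: 0 for t in TABLE_NAMES}
    import re

    table_pat = re.compile(
        rf"^({'|'.join(TABLE_NAMES)})(\d{{2}}Q[1-4])?\.(TXT|ASC)$", re.IGNORECASE
    )
    for path in sorted(root.rglob("*")):
        if not path.is_file():
            continue
        m = table_pat.match(path.name)
        if m:
            t = m.group(1).upper()
            pt = read_ascii_table(path, t)
            parsed[t].append(pt.frame)
            rejects[t] += len(pt.rejects)
    if not parsed["DEMO"]:
        raise FaersFormatError(f"no DEMO table files found under {root}")

    def cat(t: str) -> pd.DataFrame:
        frames = parsed[t]
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=["primaryid", "caseid"]
        )

    demo = deduplicate_cases(cat("DEMO"))
    store = link_reports(
        demo, cat("DRUG"), cat("REAC"), cat("OUTC"), cat("THER"), drug_dictionary
    )
    store.meta["n_rejected_lines"] = rejects
    store.meta["n_raw_demo_rows"] = int(sum(len(f) for f in parsed["DEMO"]))
    return store
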