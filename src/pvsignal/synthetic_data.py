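"""FAERS-like synthetic quarterly tables with known ground truth.

The generator emits the same '$'-delimited quarterly ASCII file set the
ingest module reads (DEMO, DRUG, REAC, OUTC, THER, RPSR), emulating the
features of real spontaneous-report data that the pipeline must cope
with: duplicate case versions with differing receipt dates, a target
drug written as free-text misspelling variants, per-report PT lists,
heavily missing demographics, and therapy/event dates with partial
missingness.  A configurable set of drug–PT pairs carries *injected*
reporting-rate ratios, and the returned :class:`GroundTruth` records the
realized fourfold counts, so every downstream stage can be validated
against a known answer without any real FAERS download.

Signal-injection model
----------------------
Each report carries PT *j* independently with probability
``pi_j = background_pt_probs[j] * mean_pts_per_report``.  For reports on
the target drug, the odds ``pi_j / (1 - pi_j)`` of each injected PT are
multiplied by its rate ratio.  Because presence is independent per PT,
the injected rate ratio *is* the report-level reporting odds ratio
(the ROR estimand), which is what parameter-recovery checks measure.
Reports that draw no PT at all are redrawn (spontaneous reports without
a reaction do not enter an analysis), which perturbs the realized odds
ratio only at the third decimal for default-sized configurations.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .contingency import ContingencyTable
from .faers_io import NAMED_ROUTES, OCCUPATION_CODES, OUTCOME_CODES, ReportStore

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "default_pt_dictionary",
    "simulate_store",
    "generate",
    "realized_table",
    "TARGET_DRUG",
    "TARGET_VARIANTS",
]

TARGET_DRUG = "SACUBITRIL/VALSARTAN"

#: Free-text spellings under which the target drug appears in DRUG rows.
TARGET_VARIANTS = (
    "ENTRESTO",
    "Entresto",
    "SACUBITRIL/VALSARTAN",
    "sacubitril-valsartan",
    "SACUBITRIL AND VALSARTAN",
    "ENTRESTO (SACUBITRIL/VALSARTAN)",
    "ENTRESTO 24/26",
)


def default_pt_dictionary(n_pts: int = 100, n_socs: int = 10) -> tuple[tuple[str, str], ...]:
    """A toy MedDRA-like dictionary: PT_001..PT_n round-robin over SOC_01..SOC_m."""
    return tuple(
        (f"PT_{i + 1:03d}", f"SOC_{(i % n_socs) + 1:02d}") for i in range(n_pts)
    )


class ConfigError(ValueError):
    """A synthetic configuration violates its invariants."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic FAERS corpus.

    Defaults emulate the shape of a large post-marketing corpus for a
    widely-used cardiovascular drug: ~71% missing age, ~6.7% missing
    sex, ~2.6 distinct PTs per report, one third of reports with
    therapy-date information, and quarterly files spanning 2015Q3 to
    2023Q4.
    """

    n_reports: int = 20_000
    n_background_drugs: int = 20
    pt_dictionary: tuple[tuple[str, str], ...] = field(default_factory=default_pt_dictionary)
    background_pt_probs: tuple[float, ...] | None = None  # None -> uniform
    target_drug_prevalence: float = 0.05
    injected_signals: tuple[tuple[str, float], ...] = ()
    duplicate_rate: float = 0.1
    missing_age_rate: float = 0.71
    missing_sex_rate: float = 0.067
    mean_pts_per_report: float = 2.6
    therapy_record_rate: float = 0.335
    missing_event_date_rate: float = 0.667
    invalid_onset_rate: float = 0.01
    start_quarter: str = "2015Q3"
    end_quarter: str = "2023Q4"
    target_drug: str = TARGET_DRUG
    seed: int = 0

    def pt_probs(self) -> np.ndarray:
        if self.background_pt_probs is None:
            k = len(self.pt_dictionary)
            return np.full(k, 1.0 / k)
        return np.asarray(self.background_pt_probs, dtype=float)

    def validate(self) -> None:
        if self.n_reports < 0:
            raise ConfigError("n_reports must be non-negative")
        if self.n_background_drugs < 1:
            raise ConfigError("n_background_drugs must be positive")
        probs = self.pt_probs()
        if len(probs) != len(self.pt_dictionary):
            raise ConfigError(
                f"background_pt_probs has length {len(probs)}, "
                f"expected {len(self.pt_dictionary)}"
            )
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ConfigError(f"background_pt_probs sums to {probs.sum()!r}, not 1")
        if np.any(probs < 0):
            raise ConfigError("background_pt_probs must be non-negative")
        for name, rate in [
            ("target_drug_prevalence", self.target_drug_prevalence),
            ("duplicate_rate", self.duplicate_rate),
            ("missing_age_rate", self.missing_age_rate),
            ("missing_sex_rate", self.missing_sex_rate),
            ("therapy_record_rate", self.therapy_record_rate),
            ("missing_event_date_rate", self.missing_event_date_rate),
            ("invalid_onset_rate", self.invalid_onset_rate),
        ]:
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {rate}")
        if self.mean_pts_per_report <= 0:
            raise ConfigError("mean_pts_per_report must be positive")
        pts = {pt for pt, _ in self.pt_dictionary}
        for pt, rr in self.injected_signals:
            if pt not in pts:
                raise ConfigError(f"injected PT {pt!r} not in pt_dictionary")
            if not np.isfinite(rr) or rr < 0:
                raise ConfigError(f"rate ratio for {pt!r} must be finite and >= 0")
        hit_probs = probs * self.mean_pts_per_report
        if np.any(hit_probs >= 1.0):
            raise ConfigError(
                "background_pt_probs * mean_pts_per_report must stay below 1 per PT"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "pt_dictionary" in d:
            d["pt_dictionary"] = tuple((str(p), str(s)) for p, s in d["pt_dictionary"])
        if d.get("background_pt_probs") is not None:
            d["background_pt_probs"] = tuple(float(x) for x in d["background_pt_probs"])
        if "injected_signals" in d:
            d["injected_signals"] = tuple(
                (str(p), float(r)) for p, r in d["injected_signals"]
            )
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class GroundTruth:
    """Realized counts of the emitted corpus, the oracle for every stage.

    ``pt_target_counts``/``pt_background_counts`` hold, per PT, the
    number of post-dedup reports carrying the PT among target-drug and
    other reports; together with ``n_target_reports`` and ``n_reports``
    they determine every fourfold table bit-exactly.
    """

    n_reports: int
    n_target_reports: int
    n_duplicates: int
    pts: tuple[str, ...]
    pt_target_counts: dict[str, int]
    pt_background_counts: dict[str, int]
    injected: list[dict]
    seed: int

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        d["pts"] = tuple(d["pts"])
        return cls(**d)


def realized_table(truth: GroundTruth, pt: str) -> ContingencyTable:
    """The fourfold table realized in the emitted (post-dedup) corpus."""
    if truth.n_reports == 0:
        raise ValueError("empty synthetic corpus has no contingency tables")
    if pt not in truth.pt_target_counts:
        raise KeyError(f"PT {pt!r} not in the synthetic dictionary")
    a = truth.pt_target_counts[pt]
    c = truth.pt_background_counts[pt]
    return ContingencyTable(
        a=a,
        b=truth.n_target_reports - a,
        c=c,
        d=truth.n_reports - truth.n_target_reports - c,
    )


# ---------------------------------------------------------------------------
# simulation internals

_SEX_P_MALE = 0.643  # male share among reports with known sex

_COUNTRY_CATS = ["US", "GB", "CA", "FR", "JP", "PH", "DE"]
_COUNTRY_P = [0.530, 0.150, 0.140, 0.136, 0.021, 0.012, 0.011]

_ROUTE_CATS = ["ORAL", "", "INTRAVENOUS", "TRANSDERMAL", "OPHTHALMIC", "PARENTERAL", "SUBCUTANEOUS"]
_ROUTE_P = [0.520, 0.440, 0.025, 0.0141, 0.0003, 0.0003, 0.0003]

_OCCP_CATS = ["CN", "MD", "OT", "PH", "LW", ""]
_OCCP_P = [0.720, 0.158, 0.0705, 0.0512, 0.0001, 0.0002]

# report-level probability of each serious-outcome code (entries per report
# average ~0.57, matching large-corpus outcome-entry totals)
_OUTCOME_P = {"OT": 0.258, "HO": 0.145, "DE": 0.140, "LT": 0.0156,
              "DS": 0.0075, "RI": 0.00025, "CA": 0.00012}


def _quarter_bounds(label: str) -> tuple[np.datetime64, np.datetime64]:
    year, q = int(label[:4]), int(label[-1])
    start = np.datetime64(f"{year}-{3 * (q - 1) + 1:02d}-01")
    end = np.datetime64(f"{year + q // 4}-{(3 * q) % 12 + 1:02d}-01")
    return start, end


def _quarter_list(start: str, end: str) -> list[str]:
    y0, q0 = int(start[:4]), int(start[-1])
    y1, q1 = int(end[:4]), int(end[-1])
    out = []
    y, q = y0, q0
    while (y, q) <= (y1, q1):
        out.append(f"{y}Q{q}")
        q += 1
        if q == 5:
            y, q = y + 1, 1
    return out


def _digits(dates: np.ndarray) -> np.ndarray:
    return np.char.replace(np.datetime_as_string(dates, unit="D"), "-", "").astype(object)


@dataclass
class _RawCorpus:
    """Raw per-table frames (pre-dedup, duplicates included) ready to emit."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    ther: pd.DataFrame
    rpsr: pd.DataFrame


def _simulate(config: SyntheticConfig) -> tuple[ReportStore, GroundTruth, _RawCorpus]:
    config.validate()
    n = config.n_reports
    if n == 0:
        raise ConfigError("cannot simulate an empty corpus (n_reports = 0)")
    streams = np.random.SeedSequence(config.seed).spawn(7)
    rng_demo, rng_drug, rng_pt, rng_date, rng_outc, rng_ther, rng_dup = (
        np.random.default_rng(s) for s in streams
    )

    pts = np.array([pt for pt, _ in config.pt_dictionary], dtype=object)
    probs = config.pt_probs()
    pi_background = probs * config.mean_pts_per_report
    odds = pi_background / (1.0 - pi_background)
    odds_target = odds.copy()
    for pt_name, rr in config.injected_signals:
        j = int(np.where(pts == pt_name)[0][0])
        odds_target[j] = odds[j] * rr
    pi_target = odds_target / (1.0 + odds_target)

    # --- report-level attributes -----------------------------------------
    case_ids = np.array([f"{10_000_001 + i}" for i in range(n)], dtype=object)
    primary_ids = np.array([f"{10_000_001 + i}5" for i in range(n)], dtype=object)
    is_target = rng_drug.random(n) < config.target_drug_prevalence

    # receipt dates: uniform over the configured quarter span
    quarters = _quarter_list(config.start_quarter, config.end_quarter)
    q_idx = rng_date.integers(0, len(quarters), n)
    starts, ends = zip(*(_quarter_bounds(q) for q in quarters))
    starts = np.array(starts, dtype="datetime64[D]")
    spans = np.array(ends, dtype="datetime64[D]") - starts
    offs = (rng_date.random(n) * spans[q_idx].astype(int)).astype(int)
    fda_dates = starts[q_idx] + offs.astype("timedelta64[D]")

    # demographics
    sex_known = rng_demo.random(n) >= config.missing_sex_rate
    sex = np.where(
        sex_known, np.where(rng_demo.random(n) < _SEX_P_MALE, "M", "F"), ""
    ).astype(object)
    age_known = rng_demo.random(n) >= config.missing_age_rate
    ages = np.clip(np.round(rng_demo.normal(68.0, 13.0, n)), 18, 100).astype(int)
    age_str = np.where(age_known, ages.astype(str), "").astype(object)
    occp = rng_demo.choice(_OCCP_CATS, size=n, p=_OCCP_P).astype(object)
    country = rng_demo.choice(_COUNTRY_CATS, size=n, p=_COUNTRY_P).astype(object)

    # PT incidence matrix (report x PT), redrawing empty reports
    pi = np.where(is_target[:, None], pi_target[None, :], pi_background[None, :])
    hits = rng_pt.random((n, len(pts))) < pi
    empty = ~hits.any(axis=1)
    while empty.any():
        idx = np.flatnonzero(empty)
        hits[idx] = rng_pt.random((len(idx), len(pts))) < pi[idx]
        empty[idx] = ~hits[idx].any(axis=1)

    # drugs: one PS row per report plus 0-2 concomitants
    bg_names = np.array(
        [f"DRUG_{i + 1:02d}" for i in range(config.n_background_drugs)], dtype=object
    )
    ps_raw = np.where(
        is_target,
        rng_drug.choice(np.array(TARGET_VARIANTS, dtype=object), size=n),
        rng_drug.choice(bg_names, size=n),
    ).astype(object)
    ps_std = np.where(
        is_target, config.target_drug, np.char.upper(ps_raw.astype(str)).astype(object)
    ).astype(object)
    route = rng_drug.choice(_ROUTE_CATS, size=n, p=_ROUTE_P).astype(object)
    n_con = rng_drug.binomial(2, 0.3, size=n)

    # outcomes
    outc_codes = list(_OUTCOME_P)
    outc_hits = rng_outc.random((n, len(outc_codes))) < np.array(
        [_OUTCOME_P[c] for c in outc_codes]
    )

    # therapy dates and onset
    has_ther = rng_ther.random(n) < config.therapy_record_rate
    onset = np.where(
        rng_ther.random(n) < 0.15,
        0,
        np.round(rng_ther.lognormal(np.log(20.0), 1.6, n)),
    ).astype(int)
    invalid = rng_ther.random(n) < config.invalid_onset_rate
    onset = np.where(invalid, -rng_ther.integers(1, 30, n), onset)
    delay = rng_ther.integers(10, 400, n)
    start_dates = fda_dates - (delay + np.abs(onset)).astype("timedelta64[D]")
    event_dates = start_dates + onset.astype("timedelta64[D]")
    event_known = has_ther & (rng_ther.random(n) >= config.missing_event_date_rate)

    fda_str = _digits(fda_dates)
    start_str = np.where(has_ther, _digits(start_dates), "").astype(object)
    event_str = np.where(event_known, _digits(event_dates), "").astype(object)

    # --- normalized (post-dedup) store -----------------------------------
    route_norm = pd.Series(route, dtype="string").replace("", pd.NA)
    route_norm = route_norm.where(route_norm.isna() | route_norm.isin(NAMED_ROUTES), "Others")
    occp_map = pd.Series(occp, dtype="string").replace("", pd.NA).map(OCCUPATION_CODES)
    outc_joined = []
    name_of = [OUTCOME_CODES[c] for c in outc_codes]
    for row in outc_hits:
        names = sorted(name_of[j] for j in np.flatnonzero(row))
        outc_joined.append(";".join(names) if names else "")

    reports = pd.DataFrame(
        {
            "case_id": pd.array(case_ids, dtype="string"),
            "primary_id": pd.array(primary_ids, dtype="string"),
            "receipt_date": pd.array(fda_str, dtype="string"),
            "sex": pd.Series(sex, dtype="string").replace("", "unknown"),
            "age_years": np.where(age_known, ages.astype(float), np.nan),
            "reporter": occp_map.fillna("unknown").astype("string"),
            "country": pd.array(country, dtype="string"),
            "route": route_norm.astype("string"),
            "outcomes": pd.Series(outc_joined, dtype="string").replace("", pd.NA),
            "event_date": pd.Series(event_str, dtype="string").replace("", pd.NA),
            "therapy_start_date": pd.Series(start_str, dtype="string").replace("", pd.NA),
        }
    )

    rep_idx, pt_idx = np.nonzero(hits)
    report_pts = pd.DataFrame(
        {
            "case_id": pd.array(case_ids[rep_idx], dtype="string"),
            "pt": pd.array(pts[pt_idx], dtype="string"),
        }
    )

    drug_rows = [
        pd.DataFrame(
            {
                "case_id": case_ids,
                "drug_seq": "1",
                "drug_raw": ps_raw,
                "drug_std": ps_std,
                "role": "PS",
            }
        )
    ]
    for k in (1, 2):
        sel = n_con >= k
        if sel.any():
            con_raw = rng_drug.choice(bg_names, size=int(sel.sum())).astype(object)
            drug_rows.append(
                pd.DataFrame(
                    {
                        "case_id": case_ids[sel],
                        "drug_seq": str(k + 1),
                        "drug_raw": con_raw,
                        "drug_std": con_raw,
                        "role": "C",
                    }
                )
            )
    report_drugs = (
        pd.concat(drug_rows, ignore_index=True)
        .sort_values(["case_id", "drug_seq"], kind="stable")
        .reset_index(drop=True)
        .astype("string")
    )

    store = ReportStore(
        reports=reports,
        report_pts=report_pts.sort_values(["case_id", "pt"], kind="stable").reset_index(drop=True),
        report_drugs=report_drugs,
        meta={"synthetic": True, "seed": config.seed},
    )

    # --- ground truth -----------------------------------------------------
    a_counts = hits[is_target].sum(axis=0)
    c_counts = hits[~is_target].sum(axis=0)
    n_target = int(is_target.sum())
    pt_target = {str(p): int(v) for p, v in zip(pts, a_counts)}
    pt_background = {str(p): int(v) for p, v in zip(pts, c_counts)}
    n_dup = int(round(config.duplicate_rate * n))
    injected = []
    for pt_name, rr in config.injected_signals:
        a = pt_target[pt_name]
        c = pt_background[pt_name]
        injected.append(
            {
                "pt": pt_name,
                "rate_ratio": float(rr),
                "a": a,
                "b": n_target - a,
                "c": c,
                "d": n - n_target - c,
            }
        )
    truth = GroundTruth(
        n_reports=n,
        n_target_reports=n_target,
        n_duplicates=n_dup,
        pts=tuple(str(p) for p in pts),
        pt_target_counts=pt_target,
        pt_background_counts=pt_background,
        injected=injected,
        seed=config.seed,
    )

    # --- raw tables (with duplicate case versions) ------------------------
    demo = pd.DataFrame(
        {
            "primaryid": primary_ids,
            "caseid": case_ids,
            "fda_dt": fda_str,
            "sex": sex,
            "age": age_str,
            "age_cod": np.where(age_str != "", "YR", "").astype(object),
            "occp_cod": occp,
            "reporter_country": country,
            "event_dt": event_str,
        }
    )
    drug = pd.DataFrame(
        {
            "primaryid": report_drugs["case_id"].map(
                dict(zip(case_ids, primary_ids))
            ).astype(object),
            "caseid": report_drugs["case_id"].astype(object),
            "drug_seq": report_drugs["drug_seq"].astype(object),
            "role_cod": report_drugs["role"].astype(object),
            "drugname": report_drugs["drug_raw"].astype(object),
            "route": "",
        }
    )
    # route only on the PS row
    drug.loc[drug["role_cod"] == "PS", "route"] = route
    reac = pd.DataFrame(
        {
            "primaryid": np.array(primary_ids)[rep_idx],
            "caseid": case_ids[rep_idx],
            "pt": pts[pt_idx],
        }
    )
    o_rep, o_code = np.nonzero(outc_hits)
    outc = pd.DataFrame(
        {
            "primaryid": np.array(primary_ids)[o_rep],
            "caseid": case_ids[o_rep],
            "outc_cod": np.array(outc_codes, dtype=object)[o_code],
        }
    )
    ther_sel = has_ther
    ther = pd.DataFrame(
        {
            "primaryid": np.array(primary_ids)[ther_sel],
            "caseid": case_ids[ther_sel],
            "dsg_drug_seq": "1",
            "start_dt": start_str[ther_sel],
        }
    )
    rpsr = pd.DataFrame(
        {
            "primaryid": primary_ids,
            "caseid": case_ids,
            "rpsr_cod": rng_demo.choice(
                np.array(["FGN", "SDY", "HP", "CSM", "OTH"], dtype=object), size=n
            ),
        }
    )

    raw = _RawCorpus(demo, drug, reac, outc, ther, rpsr)
    _inject_duplicates(raw, config, n_dup, case_ids, fda_dates, rng_dup)
    return store, truth, raw


def _inject_duplicates(
    raw: _RawCorpus,
    config: SyntheticConfig,
    n_dup: int,
    case_ids: np.ndarray,
    fda_dates: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """Re-emit a fraction of cases as older report versions.

    Each duplicate clones all linked DRUG/REAC/OUTC/THER/RPSR rows under
    a new, smaller ``primaryid`` (version suffix < 5).  Three quarters of
    duplicates get an older receipt date; the rest share the original
    date so deduplication must fall back to the primaryid tie-break.
    Either way the original row wins, so the post-dedup corpus equals
    the pre-duplication one.
    """
    if n_dup == 0:
        return
    pick = rng.choice(len(case_ids), size=n_dup, replace=False)
    pick.sort()
    dup_cases = case_ids[pick]
    versions = rng.integers(1, 5, n_dup)  # suffix 1..4 < original's 5
    dup_pids = np.array(
        [f"{cid}{v}" for cid, v in zip(dup_cases, versions)], dtype=object
    )
    same_date = rng.random(n_dup) < 0.25
    back = rng.integers(30, 300, n_dup).astype("timedelta64[D]")
    dup_dates = np.where(same_date, fda_dates[pick], fda_dates[pick] - back)
    dup_date_str = _digits(dup_dates.astype("datetime64[D]"))

    pid_map = dict(zip(dup_cases, dup_pids))
    date_map = dict(zip(dup_cases, dup_date_str))

    def clone(frame: pd.DataFrame, with_date: bool = False) -> pd.DataFrame:
        sel = frame["caseid"].isin(set(dup_cases))
        d = frame.loc[sel].copy()
        d["primaryid"] = d["caseid"].map(pid_map)
        if with_date:
            d["fda_dt"] = d["caseid"].map(date_map)
        return pd.concat([frame, d], ignore_index=True)

    raw.demo = clone(raw.demo, with_date=True)
    raw.drug = clone(raw.drug)
    raw.reac = clone(raw.reac)
    raw.outc = clone(raw.outc)
    raw.ther = clone(raw.ther)
    raw.rpsr = clone(raw.rpsr)


def simulate_store(config: SyntheticConfig) -> tuple[ReportStore, GroundTruth]:
    """Simulate the post-dedup report store in memory (no files written).

    This is the fast path for replicate studies; :func:`generate` emits
    the equivalent quarterly ASCII files, and ingesting those recovers a
    store whose contingency tables match this one's bit-exactly.
    """
    store, truth, _ = _simulate(config)
    return store, truth


_TABLE_ATTR = {
    "DEMO": "demo", "DRUG": "drug", "REAC": "reac",
    "OUTC": "outc", "THER": "ther", "RPSR": "rpsr",
}


def generate(config: SyntheticConfig, out_dir) -> tuple[list[Path], GroundTruth]:
    """Emit the quarterly ASCII file set plus ground truth and dictionaries.

    Writes ``<TABLE><YY>Q<q>.txt`` per quarter touched by a receipt
    date, ``ground_truth.json``, a toy ``pt_to_soc.tsv`` and the
    ``drug_dict.tsv`` mapping the target drug's free-text variants to
    its canonical name.  Output is byte-identical for a fixed config.
    """
    store, truth, raw = _simulate(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for table, attr in _TABLE_ATTR.items():
        frame: pd.DataFrame = getattr(raw, attr)
        if table == "DEMO":
            dates = frame["fda_dt"]
        else:
            # place rows in their case's receipt quarter via primaryid join
            dates = frame["primaryid"].map(
                raw.demo.set_index("primaryid")["fda_dt"]
            )
        qlab = dates.str.slice(0, 4) + "Q" + (
            (dates.str.slice(4, 6).astype(int) - 1) // 3 + 1
        ).astype(str)
        for quarter, part in frame.groupby(qlab.values, sort=True):
            path = out / f"{table}{quarter[2:4]}Q{quarter[-1]}.txt"
            body = part.sort_values(["primaryid"], kind="stable")
            with open(path, "w", newline="\n") as fh:
                fh.write("$".join(body.columns) + "\n")
                for row in body.itertuples(index=False):
                    fh.write("$".join("" if pd.isna(v) else str(v) for v in row) + "\n")
            written.append(path)

    truth.to_json(out / "ground_truth.json")
    pd.DataFrame(list(config.pt_dictionary), columns=["pt", "soc"]).to_csv(
        out / "pt_to_soc.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [(v, config.target_drug) for v in TARGET_VARIANTS],
        columns=["variant", "canonical"],
    ).to_csv(out / "drug_dict.tsv", sep="\t", index=False)
    written += [out / "ground_truth.json", out / "pt_to_soc.tsv", out / "drug_dict.tsv"]
    return written, truth
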