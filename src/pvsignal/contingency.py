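"""Fourfold (2x2) drug-event contingency tables at PT and SOC level.

Disproportionality analysis reduces a spontaneous-report database to one
2x2 table per adverse-event term:

===========  =================  =====================
             term reported      term not reported
===========  =================  =====================
target drug        a                    b
all others         c                    d
===========  =================  =====================

with ``N = a + b + c + d``.  The counting unit is the deduplicated
report: a report contributes at most 1 to any cell, and a report with
two PTs inside one SOC adds 1 (not 2) to that SOC's ``a``.  An
event-row counting mode is available for comparison with analyses that
aggregate reaction rows at SOC level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import pandas as pd

from .faers_io import ReportStore

__all__ = [
    "ContingencyTable",
    "TermNotFoundError",
    "UNMAPPED_SOC",
    "build_contingency",
    "all_term_tables",
    "term_table_frame",
]

UNMAPPED_SOC = "UNMAPPED"

Level = Literal["PT", "SOC"]
Counting = Literal["reports", "event_rows"]


class TermNotFoundError(KeyError):
    """The requested term occurs neither in the store nor in the dictionary.

    Distinguishes a typo / wrong-level query from a legitimate a = 0
    (term known to the dictionary but never reported for the target drug).
    """


@dataclass(frozen=True)
class ContingencyTable:
    """The a/b/c/d fourfold table for one drug-event pair."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError(f"negative cell in {self}")

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def eligible(self) -> bool:
        """Initial screening eligibility: at least 3 target-drug reports."""
        return self.a >= 3

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


def _term_column(
    store: ReportStore,
    level: Level,
    pt_to_soc: Mapping[str, str] | None,
    counting: Counting,
) -> pd.DataFrame:
    """(case_id, term) occurrences at the requested level.

    At SOC level PTs are mapped through *pt_to_soc*; PTs missing from the
    mapping are grouped under the sentinel :data:`UNMAPPED_SOC` so that
    totals are conserved.  In report counting the (case, term) pairs are
    deduplicated; in event-row counting each reaction row survives.
    """
    occ = store.report_pts[["case_id", "pt"]].copy()
    if level == "PT":
        occ = occ.rename(columns={"pt": "term"})
    elif level == "SOC":
        mapping = pt_to_soc or {}
        occ["term"] = occ["pt"].map(mapping).fillna(UNMAPPED_SOC)
        occ = occ[["case_id", "term"]]
    else:
        raise ValueError(f"level must be 'PT' or 'SOC', got {level!r}")
    if counting == "reports":
        occ = occ.drop_duplicates(["case_id", "term"])
    elif counting != "event_rows":
        raise ValueError(f"counting must be 'reports' or 'event_rows', got {counting!r}")
    return occ


def term_table_frame(
    store: ReportStore,
    target_drug: str,
    level: Level = "PT",
    pt_to_soc: Mapping[str, str] | None = None,
    counting: Counting = "reports",
    roles: Iterable[str] = ("PS",),
    min_a_eligible: int = 3,
) -> pd.DataFrame:
    """Vectorized a/b/c/d for every term with at least one target-drug report.

    Returns a DataFrame indexed by term with columns
    ``a, b, c, d, n_total, eligible_a_ge_3``.  ``a + b`` is the
    target-drug report count (constant across terms) and ``c + d`` the
    background count; in event-row counting the margins are reaction-row
    counts instead.
    """
    target_ids = store.target_case_ids(target_drug, roles)
    occ = _term_column(store, level, pt_to_soc, counting)
    is_target = occ["case_id"].isin(target_ids)

    a = occ.loc[is_target, "term"].value_counts()
    term_totals = occ["term"].value_counts()
    if counting == "reports":
        n_target = len(target_ids)
        n_total = store.n_reports
    else:
        n_target = int(is_target.sum())
        n_total = len(occ)

    a = a[a > 0]
    c = term_totals.reindex(a.index).fillna(0).astype(int) - a
    frame = pd.DataFrame(
        {
            "a": a.astype(int),
            "b": (n_target - a).astype(int),
            "c": c,
            "d": (n_total - n_target - c).astype(int),
        }
    )
    frame["n_total"] = n_total
    frame["eligible_a_ge_3"] = frame["a"] >= min_a_eligible
    frame.index.name = "term"
    return frame.sort_index(kind="stable")


def build_contingency(
    store: ReportStore,
    target_drug: str,
    term: str,
    level: Level = "PT",
    pt_to_soc: Mapping[str, str] | None = None,
    counting: Counting = "reports",
    roles: Iterable[str] = ("PS",),
) -> ContingencyTable:
    """Build the fourfold table for one term.

    Raises :class:`TermNotFoundError` when the term occurs neither in the
    store (at the requested level) nor in the supplied dictionary, so the
    caller can tell a misspelled query from a true zero count.
    """
    target_ids = store.target_case_ids(target_drug, roles)
    occ = _term_column(store, level, pt_to_soc, counting)
    known_terms = set(occ["term"].unique())
    if term not in known_terms:
        mapping = pt_to_soc or {}
        dict_terms = set(mapping.values()) | {UNMAPPED_SOC} if level == "SOC" else set(mapping)
        if term not in dict_terms:
            raise TermNotFoundError(
                f"term {term!r} not present in store at {level} level nor in dictionary"
            )
    hits = occ.loc[occ["term"] == term]
    is_target = hits["case_id"].isin(target_ids)
    a = int(is_target.sum())
    c = int(len(hits) - a)
    if counting == "reports":
        n_target, n_total = len(target_ids), store.n_reports
    else:
        occ_target = occ["case_id"].isin(target_ids)
        n_target, n_total = int(occ_target.sum()), len(occ)
    return ContingencyTable(a=a, b=n_target - a, c=c, d=n_total - n_target - c)


def all_term_tables(
    store: ReportStore,
    target_drug: str,
    level: Level = "PT",
    pt_to_soc: Mapping[str, str] | None = None,
    counting: Counting = "reports",
    roles: Iterable[str] = ("PS",),
) -> dict[str, ContingencyTable]:
    """One :class:`ContingencyTable` per term seen in >=1 target-drug report.

    Terms below the a >= 3 screening floor are included (their
    ``eligible`` property is False); dropping them is the screening
    stage's decision, not the counting stage's.
    """
    frame = term_table_frame(store, target_drug, level, pt_to_soc, counting, roles)
    return {
        term: ContingencyTable(int(r.a), int(r.b), int(r.c), int(r.d))
        for term, r in frame.iterrows()
    }
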