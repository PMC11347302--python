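"""Signal screening and ranking.

Initial screening keeps terms with at least ``min_a`` (default 3)
target-drug reports; ranking orders the survivors by report count or by
ROR with deterministic tie-breaks; the "strongly positive" subset is the
conjunction of all four algorithms' thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .disproportionality import SignalResult

__all__ = ["ScreenedSignalSet", "screen", "rank_top", "flag_all_four"]

RankKey = Literal["case_reports", "ror"]


@dataclass
class ScreenedSignalSet:
    """Signal results that survived the minimum-count screen."""

    level: str
    results: list[SignalResult]
    min_a: int
    n_input: int
    n_dropped: int
    ranking_key: str | None = None
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.results)

    def terms(self) -> list[str]:
        return [r.term for r in self.results]

    def to_frame(self) -> pd.DataFrame:
        """Flat table of the retained results (the signals.tsv layout)."""
        rows = []
        for r in self.results:
            rows.append(
                {
                    "term": r.term,
                    "level": self.level,
                    "a": r.table.a,
                    "b": r.table.b,
                    "c": r.table.c,
                    "d": r.table.d,
                    "n_total": r.table.n_total,
                    "ror": r.ror,
                    "ror_lo95": r.ror_lo95,
                    "ror_hi95": r.ror_hi95,
                    "prr": r.prr,
                    "prr_lo95": r.prr_lo95,
                    "prr_hi95": r.prr_hi95,
                    "chi2": r.chi2,
                    "ic": r.ic,
                    "ic025": r.ic025,
                    "ebgm": r.ebgm,
                    "ebgm05": r.ebgm05,
                    "sig_ror": r.flags.ror,
                    "sig_prr": r.flags.prr,
                    "sig_bcpnn": r.flags.bcpnn,
                    "sig_ebgm": r.flags.ebgm,
                    "all_four_positive": r.flags.all_four_positive,
                }
            )
        cols = [
            "term", "level", "a", "b", "c", "d", "n_total",
            "ror", "ror_lo95", "ror_hi95", "prr", "prr_lo95", "prr_hi95",
            "chi2", "ic", "ic025", "ebgm", "ebgm05",
            "sig_ror", "sig_prr", "sig_bcpnn", "sig_ebgm", "all_four_positive",
        ]
        return pd.DataFrame(rows, columns=cols)


def screen(
    results: Mapping[str, SignalResult],
    min_a: int = 3,
    level: str = "PT",
) -> ScreenedSignalSet:
    """Drop terms reported fewer than *min_a* times for the target drug.

    All surviving terms are retained regardless of their flags (whether
    a retained term is a signal is a separate question); the number
    dropped is recorded.  Output order is lexical by term, so screening
    is a pure, idempotent function of the input set.
    """
    kept = sorted(
        (r for r in results.values() if r.table.a >= min_a), key=lambda r: r.term
    )
    return ScreenedSignalSet(
        level=level,
        results=kept,
        min_a=min_a,
        n_input=len(results),
        n_dropped=len(results) - len(kept),
    )


def _sort_key(result: SignalResult, key: RankKey) -> tuple:
    a = result.table.a
    ror = result.ror if np.isfinite(result.ror) else -np.inf
    if key == "case_reports":
        return (-a, -ror, result.term)
    if key == "ror":
        return (-ror, -a, result.term)
    raise ValueError(f"unknown ranking key {key!r}; use 'case_reports' or 'ror'")


def rank_top(
    screened: ScreenedSignalSet, key: RankKey = "case_reports", k: int = 30
) -> list[SignalResult]:
    """Top-*k* results, descending by *key*.

    Ties break on the other key (descending) and then on the term name,
    so the ranking is deterministic and independent of input order.
    """
    ordered = sorted(screened.results, key=lambda r: _sort_key(r, key))
    screened.ranking_key = key
    return ordered[: max(k, 0)]


def flag_all_four(screened: ScreenedSignalSet) -> list[SignalResult]:
    """Results positive on every algorithm (ROR, PRR, BCPNN, EBGM)."""
    return [r for r in screened.results if r.flags.all_four_positive]
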