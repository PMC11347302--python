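"""Disproportionality statistics on 2x2 drug-event tables.

Implements the four signal-detection algorithms routinely combined in
spontaneous-report mining, on the fourfold table (a, b, c, d) with
N = a + b + c + d:

* **ROR** — reporting odds ratio (a·d)/(b·c), with the Woolf lognormal
  95% CI: exp(ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d)).
* **PRR** — proportional reporting ratio (a/(a+b))/(c/(c+d)), CI via
  exp(ln PRR ± 1.96·√(1/a − 1/(a+b) + 1/c − 1/(c+d))).
* **χ²** — Pearson chi-square of the fourfold table, Yates-corrected by
  default (the pharmacovigilance convention for sparse cells).
* **BCPNN IC** — the information component log₂(a·N/((a+b)(a+c))) and
  its Bayesian credibility bound IC025 = E[IC] − 2·√V[IC] from the
  closed-form posterior moments of Bate et al. (1998) with the standard
  priors α₁ = β₁ = γ₁₁ = 1, α = β = 2 and γ scaled so that E[IC] = 0
  under independence.
* **EBGM** — here the relative reporting ratio a·N/((a+b)(a+c)) with a
  lognormal 95% interval using the same SE as the ROR; EBGM05 is the
  lower bound.  (No gamma-mixture shrinkage fit is performed; EBGM is
  numerically 2^IC by construction.)

Classical screening thresholds: ROR needs a ≥ 3, ROR ≥ 3 (configurable)
and CI lower bound > 1; PRR needs a ≥ 3, PRR ≥ 2 and CI lower bound > 1;
BCPNN needs IC025 > 0; EBGM needs EBGM05 > 2.

All point estimates and bounds are computed in log space, vectorized
over term tables.  With the default zero-cell policy a statistic whose
formula divides by an empty cell is an *undefined marker* (NaN plus a
reason code), never an exception; the optional Haldane–Anscombe policy
adds 0.5 to every cell of a table containing a zero before computing
the frequentist statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .contingency import ContingencyTable

__all__ = [
    "BcpnnPriors",
    "SignalConfig",
    "SignalFlags",
    "SignalResult",
    "ror_with_ci",
    "prr_with_ci",
    "chi_square",
    "ic_simple",
    "bcpnn_ic025",
    "ebgm_with_bound",
    "evaluate_thresholds",
    "score_frame",
    "compute_signals",
]

_LN2 = np.log(2.0)


@dataclass(frozen=True)
class BcpnnPriors:
    """Beta/Dirichlet prior constants of the BCPNN closed forms."""

    alpha1: float = 1.0
    beta1: float = 1.0
    gamma11: float = 1.0
    alpha: float = 2.0
    beta: float = 2.0


DEFAULT_PRIORS = BcpnnPriors()


@dataclass(frozen=True)
class SignalConfig:
    """Tunable knobs of the statistics and thresholds.

    ``ror_point_threshold`` may be set to None to drop the ROR point
    criterion and screen on the CI alone.
    """

    zero_cell_policy: Literal["none", "haldane"] = "none"
    yates: bool = True
    z: float = 1.96
    min_a: int = 3
    ror_point_threshold: float | None = 3.0
    prr_point_threshold: float = 2.0
    ic025_threshold: float = 0.0
    ebgm05_threshold: float = 2.0
    priors: BcpnnPriors = field(default_factory=BcpnnPriors)


@dataclass(frozen=True)
class SignalFlags:
    ror: bool
    prr: bool
    bcpnn: bool
    ebgm: bool
    reasons: tuple[str, ...] = ()

    @property
    def all_four_positive(self) -> bool:
        return self.ror and self.prr and self.bcpnn and self.ebgm


@dataclass(frozen=True)
class SignalResult:
    """All statistics for one term; NaN marks an undefined statistic."""

    term: str
    table: ContingencyTable
    ror: float
    ror_lo95: float
    ror_hi95: float
    prr: float
    prr_lo95: float
    prr_hi95: float
    chi2: float
    ic: float
    eic: float
    vic: float
    ic025: float
    ebgm: float
    ebgm05: float
    ebgm_hi95: float
    flags: SignalFlags


# ---------------------------------------------------------------------------
# vectorized core


def _cells(frame: pd.DataFrame, policy: str) -> tuple[np.ndarray, ...]:
    a = frame["a"].to_numpy(dtype=float)
    b = frame["b"].to_numpy(dtype=float)
    c = frame["c"].to_numpy(dtype=float)
    d = frame["d"].to_numpy(dtype=float)
    if policy == "haldane":
        has_zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
        corr = np.where(has_zero, 0.5, 0.0)
        return a + corr, b + corr, c + corr, d + corr
    if policy != "none":
        raise ValueError(f"unknown zero_cell_policy {policy!r}")
    return a, b, c, d


def score_frame(tables: pd.DataFrame, config: SignalConfig | None = None) -> pd.DataFrame:
    """Compute every statistic for a frame of tables (columns a, b, c, d).

    Returns a copy of *tables* extended with point estimates, bounds and
    per-algorithm flags.  Statistics undefined under the configured
    zero-cell policy come back NaN with their flag False.
    """
    cfg = config or SignalConfig()
    out = tables.copy()
    a, b, c, d = _cells(tables, cfg.zero_cell_policy)
    n = a + b + c + d
    a0 = tables["a"].to_numpy(dtype=float)  # uncorrected, for eligibility

    with np.errstate(divide="ignore", invalid="ignore"):
        # ROR
        ror_ok = (a > 0) & (b > 0) & (c > 0) & (d > 0)
        ln_ror = np.where(ror_ok, np.log(a) - np.log(b) - np.log(c) + np.log(d), np.nan)
        se_ror = np.where(ror_ok, np.sqrt(1 / a + 1 / b + 1 / c + 1 / d), np.nan)
        out["ror"] = np.exp(ln_ror)
        out["ror_lo95"] = np.exp(ln_ror - cfg.z * se_ror)
        out["ror_hi95"] = np.exp(ln_ror + cfg.z * se_ror)

        # PRR
        prr_ok = (a > 0) & (c > 0) & (a + b > 0) & (c + d > 0)
        ln_prr = np.where(
            prr_ok, np.log(a) - np.log(a + b) - np.log(c) + np.log(c + d), np.nan
        )
        se_prr = np.where(
            prr_ok, np.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d)), np.nan
        )
        out["prr"] = np.exp(ln_prr)
        out["prr_lo95"] = np.exp(ln_prr - cfg.z * se_prr)
        out["prr_hi95"] = np.exp(ln_prr + cfg.z * se_prr)

        # chi-square on the uncorrected integer cells
        out["chi2"] = _chi2_array(
            tables["a"].to_numpy(float),
            tables["b"].to_numpy(float),
            tables["c"].to_numpy(float),
            tables["d"].to_numpy(float),
            yates=cfg.yates,
        )

        # relative reporting ratio: EBGM point and the IC are one quantity
        rr_ok = a > 0
        ln_rr = np.where(rr_ok, np.log(a) + np.log(n) - np.log(a + b) - np.log(a + c), np.nan)
        rr = np.exp(ln_rr)
        out["ic"] = ln_rr / _LN2
        out["ebgm"] = rr
        se_rr = np.where(ror_ok, np.sqrt(1 / a + 1 / b + 1 / c + 1 / d), np.nan)
        out["ebgm05"] = np.exp(ln_rr - cfg.z * se_rr)
        out["ebgm_hi95"] = np.exp(ln_rr + cfg.z * se_rr)

        # BCPNN posterior moments on the raw (uncorrected) cells
        eic, vic = _bcpnn_moments(
            tables["a"].to_numpy(float),
            tables["b"].to_numpy(float),
            tables["c"].to_numpy(float),
            tables["d"].to_numpy(float),
            cfg.priors,
        )
        out["eic"] = eic
        out["vic"] = vic
        out["ic025"] = eic - 2.0 * np.sqrt(vic)

    # flags; NaN comparisons are False, so undefined statistics never signal
    sig_ror = (a0 >= cfg.min_a) & (out["ror_lo95"].to_numpy() > 1.0)
    if cfg.ror_point_threshold is not None:
        sig_ror &= out["ror"].to_numpy() >= cfg.ror_point_threshold
    sig_prr = (
        (a0 >= cfg.min_a)
        & (out["prr"].to_numpy() >= cfg.prr_point_threshold)
        & (out["prr_lo95"].to_numpy() > 1.0)
    )
    sig_bcpnn = out["ic025"].to_numpy() > cfg.ic025_threshold
    sig_ebgm = out["ebgm05"].to_numpy() > cfg.ebgm05_threshold
    out["sig_ror"] = sig_ror
    out["sig_prr"] = sig_prr
    out["sig_bcpnn"] = sig_bcpnn
    out["sig_ebgm"] = sig_ebgm
    out["all_four_positive"] = sig_ror & sig_prr & sig_bcpnn & sig_ebgm
    return out


def _chi2_array(a, b, c, d, yates: bool) -> np.ndarray:
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    denom = r1 * r2 * c1 * c2
    bad = denom == 0
    if np.any(bad & (n > 0)):
        warnings.warn("chi-square set to 0 for tables with an empty margin")
    diff = np.abs(a * d - b * c)
    if yates:
        diff = np.maximum(diff - n / 2.0, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = n * diff**2 / denom
    return np.where(bad, 0.0, chi2)


def _bcpnn_moments(a, b, c, d, priors: BcpnnPriors) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form posterior mean/variance of the information component."""
    p = priors
    n = a + b + c + d
    gamma = p.gamma11 * (n + p.alpha) * (n + p.beta) / ((a + b + p.alpha1) * (a + c + p.beta1))
    eic = (
        np.log(a + p.gamma11)
        + np.log(n + p.alpha)
        + np.log(n + p.beta)
        - np.log(n + gamma)
        - np.log(a + b + p.alpha1)
        - np.log(a + c + p.beta1)
    ) / _LN2
    vic = (
        (n - a + gamma - p.gamma11) / ((a + p.gamma11) * (1 + n + gamma))
        + (n - a - b + p.alpha - p.alpha1) / ((a + b + p.alpha1) * (1 + n + p.alpha))
        + (n - a - c + p.beta - p.beta1) / ((a + c + p.beta1) * (1 + n + p.beta))
    ) / (_LN2**2)
    return eic, vic


# ---------------------------------------------------------------------------
# scalar operations


def _one_row(t: ContingencyTable, config: SignalConfig) -> pd.Series:
    frame = pd.DataFrame([{"a": t.a, "b": t.b, "c": t.c, "d": t.d}])
    return score_frame(frame, config).iloc[0]


def ror_with_ci(
    t: ContingencyTable, config: SignalConfig | None = None
) -> tuple[float, float, float]:
    """Reporting odds ratio with its 95% CI; NaNs mark an undefined result."""
    r = _one_row(t, config or SignalConfig())
    return float(r["ror"]), float(r["ror_lo95"]), float(r["ror_hi95"])


def prr_with_ci(
    t: ContingencyTable, config: SignalConfig | None = None
) -> tuple[float, float, float]:
    """Proportional reporting ratio with its 95% CI."""
    r = _one_row(t, config or SignalConfig())
    return float(r["prr"]), float(r["prr_lo95"]), float(r["prr_hi95"])


def chi_square(t: ContingencyTable, yates: bool = True) -> float:
    """Pearson chi-square of the fourfold table (Yates-corrected by default)."""
    if t.n_total <= 0:
        raise ValueError("chi-square undefined for an empty table")
    return float(
        _chi2_array(
            np.array([t.a], float),
            np.array([t.b], float),
            np.array([t.c], float),
            np.array([t.d], float),
            yates=yates,
        )[0]
    )


def ic_simple(t: ContingencyTable) -> float:
    """Information component log2(a·N/((a+b)(a+c))); NaN when a = 0."""
    if t.a <= 0:
        return float("nan")
    return float(
        (np.log(t.a) + np.log(t.n_total) - np.log(t.a + t.b) - np.log(t.a + t.c)) / _LN2
    )


def bcpnn_ic025(
    t: ContingencyTable, priors: BcpnnPriors = DEFAULT_PRIORS
) -> tuple[float, float, float]:
    """Posterior (EIC, VIC) of the information component and IC025 = EIC − 2√VIC."""
    eic, vic = _bcpnn_moments(
        np.array([t.a], float),
        np.array([t.b], float),
        np.array([t.c], float),
        np.array([t.d], float),
        priors,
    )
    return float(eic[0]), float(vic[0]), float(eic[0] - 2.0 * np.sqrt(vic[0]))


def ebgm_with_bound(
    t: ContingencyTable, config: SignalConfig | None = None
) -> tuple[float, float, float]:
    """Relative reporting ratio (EBGM point) with lognormal (EBGM05, hi95)."""
    r = _one_row(t, config or SignalConfig())
    return float(r["ebgm"]), float(r["ebgm05"]), float(r["ebgm_hi95"])


def evaluate_thresholds(result: "SignalResult", config: SignalConfig | None = None) -> SignalFlags:
    """Re-evaluate the four screening rules on an already-computed result."""
    cfg = config or SignalConfig()
    reasons: list[str] = []
    a = result.table.a

    def _defined(x: float, name: str) -> bool:
        if np.isnan(x):
            reasons.append(f"{name}_undefined")
            return False
        return True

    ror_ok = _defined(result.ror, "ror") and _defined(result.ror_lo95, "ror_lo95")
    sig_ror = bool(
        ror_ok
        and a >= cfg.min_a
        and (cfg.ror_point_threshold is None or result.ror >= cfg.ror_point_threshold)
        and result.ror_lo95 > 1.0
    )
    prr_ok = _defined(result.prr, "prr") and _defined(result.prr_lo95, "prr_lo95")
    sig_prr = bool(
        prr_ok
        and a >= cfg.min_a
        and result.prr >= cfg.prr_point_threshold
        and result.prr_lo95 > 1.0
    )
    sig_bcpnn = bool(_defined(result.ic025, "ic025") and result.ic025 > cfg.ic025_threshold)
    sig_ebgm = bool(_defined(result.ebgm05, "ebgm05") and result.ebgm05 > cfg.ebgm05_threshold)
    if a < cfg.min_a:
        reasons.append(f"a_lt_{cfg.min_a}")
    return SignalFlags(sig_ror, sig_prr, sig_bcpnn, sig_ebgm, tuple(reasons))


def compute_signals(
    tables: Mapping[str, ContingencyTable] | pd.DataFrame,
    config: SignalConfig | None = None,
) -> dict[str, SignalResult]:
    """Score every table and bundle each term into a :class:`SignalResult`."""
    cfg = config or SignalConfig()
    if isinstance(tables, pd.DataFrame):
        frame = tables[["a", "b", "c", "d"]].copy()
        table_objs = {
            term: ContingencyTable(int(r.a), int(r.b), int(r.c), int(r.d))
            for term, r in frame.iterrows()
        }
    else:
        table_objs = dict(tables)
        frame = pd.DataFrame(
            {k: [t.a for t in table_objs.values()]
             if k == "a" else [getattr(t, k) for t in table_objs.values()]
             for k in ("a", "b", "c", "d")},
            index=list(table_objs),
        )
    scored = score_frame(frame, cfg)
    results: dict[str, SignalResult] = {}
    for term, r in scored.iterrows():
        res = SignalResult(
            term=str(term),
            table=table_objs[term],
            ror=float(r["ror"]),
            ror_lo95=float(r["ror_lo95"]),
            ror_hi95=float(r["ror_hi95"]),
            prr=float(r["prr"]),
            prr_lo95=float(r["prr_lo95"]),
            prr_hi95=float(r["prr_hi95"]),
            chi2=float(r["chi2"]),
            ic=float(r["ic"]),
            eic=float(r["eic"]),
            vic=float(r["vic"]),
            ic025=float(r["ic025"]),
            ebgm=float(r["ebgm"]),
            ebgm05=float(r["ebgm05"]),
            ebgm_hi95=float(r["ebgm_hi95"]),
            flags=SignalFlags(
                bool(r["sig_ror"]), bool(r["sig_prr"]),
                bool(r["sig_bcpnn"]), bool(r["sig_ebgm"]),
            ),
        )
        results[str(term)] = res
    return results
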