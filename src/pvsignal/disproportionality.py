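"""PRR, ROR and information-component estimators with interval bounds,
the minimum-case rule, and signal flagging.

Point estimates use the classical forms

* PRR = [a/(a+b)] / [c/(c+d)], Wald CI on the log scale with
  variance 1/a - 1/(a+b) + 1/c - 1/(c+d);
* ROR = (a*d)/(b*c), Wald CI with variance 1/a + 1/b + 1/c + 1/d;
* IC  = log2((a + 1/2) / (E + 1/2)) with E = n_drug * n_event / N; the
  lower 95% credibility bound uses the closed-form approximation
  IC025 = IC - 3.3*(a+1/2)^(-1/2) - 2*(a+1/2)^(-3/2), or the exact
  gamma-posterior quantile when requested.

No continuity correction is applied: a table with a zero cell where the
formula needs a positive one yields an undefined estimate, reported "NA".
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Optional

from scipy import stats

from .contingency import ContingencyTable
from .errors import EstimateUndefinedError

log = logging.getLogger(__name__)

#: two-sided 95% normal quantile
Z95 = 1.959964


@dataclass(frozen=True)
class DisproportionalityResult:
    """Estimates for one table; ``computed`` is False below the case
    threshold (estimates are then absent and the row prints as NA)."""

    table: ContingencyTable
    computed: bool
    signal: bool
    n_observed: int
    n_expected: float
    z: float = Z95
    prr: Optional[float] = None
    prr_low: Optional[float] = None
    prr_high: Optional[float] = None
    ror: Optional[float] = None
    ror_low: Optional[float] = None
    ror_high: Optional[float] = None
    ic: Optional[float] = None
    ic025: Optional[float] = None
    reason: Optional[str] = None


def prr_estimate(
    table: ContingencyTable, z: float = Z95
) -> tuple[float, float, float]:
    """Proportional reporting ratio with log-symmetric Wald CI."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if a < 1:
        raise EstimateUndefinedError("PRR undefined: no exposed cases (a = 0)")
    if c < 1:
        raise EstimateUndefinedError(
            "PRR undefined: event absent from comparator (c = 0)"
        )
    prr = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    lo = prr * math.exp(-z * se)
    hi = prr * math.exp(z * se)
    return prr, lo, hi


def ror_estimate(
    table: ContingencyTable, z: float = Z95
) -> tuple[float, float, float]:
    """Reporting odds ratio with log-symmetric Wald CI."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) < 1:
        raise EstimateUndefinedError(
            "ROR undefined: zero cell (no continuity correction applied)"
        )
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = ror * math.exp(-z * se)
    hi = ror * math.exp(z * se)
    return ror, lo, hi


def ic_estimate(
    table: ContingencyTable,
    method: Literal["approx", "gamma"] = "approx",
) -> tuple[float, float]:
    """Shrunken information component and its lower 95% credibility bound.

    The +1/2 shrinkage keeps the estimate finite for a = 0. ``gamma``
    computes the exact 2.5% quantile of the Gamma(a + 1/2, E + 1/2)
    posterior of the reporting-rate ratio instead of the closed-form
    approximation.
    """
    if table.n_total < 1:
        raise EstimateUndefinedError("IC undefined on an empty table")
    a = table.a
    e = table.expected
    ic = math.log2((a + 0.5) / (e + 0.5))
    if method == "approx":
        ic025 = ic - 3.3 * (a + 0.5) ** -0.5 - 2.0 * (a + 0.5) ** -1.5
    elif method == "gamma":
        q = stats.gamma.ppf(0.025, a + 0.5, scale=1.0 / (e + 0.5))
        ic025 = math.log2(q)
    else:
        raise ValueError(f"unknown IC method {method!r}")
    return ic, ic025


def screen(
    tables: Iterable[ContingencyTable],
    min_cases: int = 3,
    z: float = Z95,
    ic_method: Literal["approx", "gamma"] = "approx",
) -> list[DisproportionalityResult]:
    """Estimate all tables and flag signals.

    A pair is estimated only when it has at least ``min_cases`` exposed
    cases; it is flagged as a signal of disproportionate reporting when,
    additionally, the PRR lower confidence bound exceeds 1. ROR and IC
    are confirmatory and never gate the flag.
    """
    results: list[DisproportionalityResult] = []
    for t in tables:
        base = dict(table=t, n_observed=t.a, n_expected=t.expected, z=z)
        if t.a < min_cases:
            results.append(DisproportionalityResult(
                computed=False, signal=False,
                reason=f"fewer than {min_cases} exposed cases", **base,
            ))
            continue
        try:
            prr, prr_lo, prr_hi = prr_estimate(t, z)
        except EstimateUndefinedError as exc:
            log.info("table %s/%s/%s not computed: %s",
                     t.drug, t.event.label if t.event else "?", t.stratum, exc)
            results.append(DisproportionalityResult(
                computed=False, signal=False, reason=str(exc), **base,
            ))
            continue
        try:
            ror, ror_lo, ror_hi = ror_estimate(t, z)
        except EstimateUndefinedError as exc:
            ror = ror_lo = ror_hi = None
            log.info("ROR unavailable for %s/%s/%s: %s",
                     t.drug, t.event.label if t.event else "?", t.stratum, exc)
        ic, ic025 = ic_estimate(t, method=ic_method)
        results.append(DisproportionalityResult(
            computed=True,
            signal=prr_lo > 1.0,
            prr=prr, prr_low=prr_lo, prr_high=prr_hi,
            ror=ror, ror_low=ror_lo, ror_high=ror_hi,
            ic=ic, ic025=ic025,
            **base,
        ))
    return results
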