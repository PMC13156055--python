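"""Disproportionality statistics for drug–event pairs.

Four frequentist/Bayesian signal-detection statistics are computed from
a 2x2 contingency table built over a deduplicated report universe:

* ROR, the reporting odds ratio ``ad/bc`` with a 95% CI from the
  log-scale standard error ``sqrt(1/a + 1/b + 1/c + 1/d)``;
* PRR, the proportional reporting ratio ``[a/(a+b)] / [c/(c+d)]``,
  accompanied by the uncorrected Pearson chi-squared statistic;
* IC, the BCPNN information component
  ``log2((a + 0.5) / (aexp + 0.5))`` with the shrinkage-based lower
  bound ``IC025 = IC - 3.3 (a+0.5)^{-1/2} - 2 (a+0.5)^{-3/2}``, where
  ``aexp = (a+b)(a+c)/n`` is the expected count under independence;
* EBGM, computed here as the relative reporting ratio ``a / aexp``
  (observed over expected) with log-normal interval bounds — not the
  full gamma-Poisson mixture fit of the MGPS program.  The shrinkage-free
  form is deliberate; see the methods note.

Cell labels: a = target drug AND target event, b = target drug AND
other events, c = other drugs AND target event, d = neither.  Under
this convention PRR approaches ROR whenever the event is rare within
both the drug's and the comparator's reports, which is the regime
spontaneous-report data live in.

Statistics whose formula requires a positive cell return NaN for that
pair ("undefined"); no Haldane continuity correction is applied.
Undefined values never raise and always fail threshold flags.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError
from .reports import ReportSet

Z95 = 1.959963984540054  # two-sided 95% normal quantile


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (display convention for result tables)."""
    x = float(x)
    if not math.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 drug x event cell counts (real-valued to admit expectations)."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        for name in "abcd":
            if getattr(self, name) < 0:
                raise ValueError(f"cell {name} is negative")

    @property
    def n_total(self) -> float:
        return self.a + self.b + self.c + self.d

    @property
    def aexp(self) -> float:
        """Expected count of cell a under row/column independence."""
        return (self.a + self.b) * (self.a + self.c) / self.n_total


@dataclass(frozen=True)
class Thresholds:
    """Signal-detection criteria, one per algorithm.

    Defaults are the conventional published cut-offs: N >= 3 with
    ROR025 > 1; PRR >= 2 with chi2 >= 4 and N >= 3; IC025 > 0;
    EBGM05 > 2.  All comparisons against *_lower bounds are strict.
    """

    min_cases: int = 3
    ror_lower: float = 1.0
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ic_lower: float = 0.0
    ebgm_lower: float = 2.0


class RorEstimate(NamedTuple):
    ror: float
    ror025: float
    ror975: float


class PrrEstimate(NamedTuple):
    prr: float
    chi2: float


class IcEstimate(NamedTuple):
    ic: float
    ic025: float
    aexp: float


class EbgmEstimate(NamedTuple):
    ebgm: float
    ebgm05: float
    ebgm95: float


def _log_ci_halfwidth(t: ContingencyTable) -> float:
    return Z95 * math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)


def ror(t: ContingencyTable) -> RorEstimate:
    """Reporting odds ratio with 95% CI; NaN triple if any cell is zero."""
    if min(t.a, t.b, t.c, t.d) <= 0:
        return RorEstimate(math.nan, math.nan, math.nan)
    point = (t.a * t.d) / (t.b * t.c)
    half = _log_ci_halfwidth(t)
    return RorEstimate(point, point * math.exp(-half), point * math.exp(half))


def prr(t: ContingencyTable) -> PrrEstimate:
    """Proportional reporting ratio and uncorrected Pearson chi-squared.

    PRR needs a+b > 0, c+d > 0 and c > 0; chi2 needs all four margins
    positive.  Violations yield NaN for the affected value.
    """
    ab, cd, ac, bd = t.a + t.b, t.c + t.d, t.a + t.c, t.b + t.d
    prr_val = math.nan
    if ab > 0 and cd > 0 and t.c > 0:
        prr_val = (t.a / ab) / (t.c / cd)
    chi2_val = math.nan
    if min(ab, cd, ac, bd) > 0:
        chi2_val = (t.a * t.d - t.b * t.c) ** 2 * t.n_total / (ab * cd * ac * bd)
    return PrrEstimate(prr_val, chi2_val)


def information_component(a: float, aexp: float) -> tuple[float, float]:
    """BCPNN IC and its lower bound from an observed count and its
    independence expectation.  Total: well defined even at a = 0."""
    ic = math.log2((a + 0.5) / (aexp + 0.5))
    ic025 = ic - 3.3 * (a + 0.5) ** -0.5 - 2.0 * (a + 0.5) ** -1.5
    return ic, ic025


def bcpnn_ic(t: ContingencyTable) -> IcEstimate:
    if t.n_total <= 0:
        raise DegenerateInputError("empty contingency table")
    aexp = t.aexp
    ic, ic025 = information_component(t.a, aexp)
    return IcEstimate(ic, ic025, aexp)


def mgps_ebgm(t: ContingencyTable) -> EbgmEstimate:
    """Relative reporting ratio a/aexp with log-normal 90%-style bounds.

    The interval uses the same log-scale SE as the ROR and is undefined
    (NaN) when any cell is zero; the point estimate only needs both
    a-margins positive.
    """
    ab, ac = t.a + t.b, t.a + t.c
    if ab <= 0 or ac <= 0:
        return EbgmEstimate(math.nan, math.nan, math.nan)
    point = t.a * t.n_total / (ac * ab)
    if min(t.a, t.b, t.c, t.d) <= 0:
        return EbgmEstimate(point, math.nan, math.nan)
    half = _log_ci_halfwidth(t)
    return EbgmEstimate(point, point * math.exp(-half), point * math.exp(half))


@dataclass
class SignalResult:
    """All four statistics plus threshold flags for one drug–event pair."""

    drug: str
    event: str
    level: str  # "PT" or "HLGT"
    a: int
    ror: float
    ror025: float
    ror975: float
    prr: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    aexp: float
    ror_flag: bool = False
    prr_flag: bool = False
    bcpnn_flag: bool = False
    mgps_flag: bool = False

    @property
    def any_flag(self) -> bool:
        return self.ror_flag or self.prr_flag or self.bcpnn_flag or self.mgps_flag


def evaluate_thresholds(r: SignalResult, th: Thresholds = Thresholds()) -> SignalResult:
    """Set the four per-algorithm flags in place (NaN never flags)."""
    r.ror_flag = bool(r.a >= th.min_cases and not math.isnan(r.ror025) and r.ror025 > th.ror_lower)
    r.prr_flag = bool(
        r.a >= th.min_cases
        and not math.isnan(r.prr) and r.prr >= th.prr_min
        and not math.isnan(r.chi2) and r.chi2 >= th.chi2_min
    )
    r.bcpnn_flag = bool(not math.isnan(r.ic025) and r.ic025 > th.ic_lower)
    r.mgps_flag = bool(not math.isnan(r.ebgm05) and r.ebgm05 > th.ebgm_lower)
    return r


def compute_signal(drug: str, event: str, level: str, t: ContingencyTable,
                   th: Thresholds = Thresholds()) -> SignalResult:
    ror_e = ror(t)
    prr_e = prr(t)
    ic_e = bcpnn_ic(t)
    ebgm_e = mgps_ebgm(t)
    result = SignalResult(
        drug=drug, event=event, level=level, a=int(t.a),
        ror=ror_e.ror, ror025=ror_e.ror025, ror975=ror_e.ror975,
        prr=prr_e.prr, chi2=prr_e.chi2,
        ic=ic_e.ic, ic025=ic_e.ic025,
        ebgm=ebgm_e.ebgm, ebgm05=ebgm_e.ebgm05,
        aexp=ic_e.aexp,
    )
    return evaluate_thresholds(result, th)


def build_contingency(universe: ReportSet, drug: str, event_pts) -> ContingencyTable:
    """Count the 2x2 cells over a deduplicated universe.

    a counts reports whose PS drug is ``drug`` and that mention at
    least one PT from ``event_pts``; a report with several qualifying
    PTs counts once.  Cells partition the universe exactly.
    """
    n = len(universe)
    if n == 0:
        raise DegenerateInputError("empty report universe")
    if not event_pts:
        raise DegenerateInputError("empty event PT set")
    ps_ids = set(universe.ps_primaryids(drug))
    ev_ids = set(universe.event_primaryids(event_pts))
    a = len(ps_ids & ev_ids)
    b = len(ps_ids) - a
    c = len(ev_ids) - a
    d = n - a - b - c
    return ContingencyTable(a=a, b=b, c=c, d=d)


@dataclass
class ScreenCounts:
    """Per-drug before/after-screen accounting."""

    drug: str
    ps_reports: int            # deduplicated reports with the drug as PS
    cases_before: int          # of those, reports with >=1 target-set PT
    pairs_min_cases: int       # (drug, PT) pairs reaching min_cases
    pairs_ror_flagged: int     # of those, pairs passing the ROR criterion
    cases_after: int           # unique reports contributing to flagged pairs


@dataclass
class ScreenOutput:
    results: list[SignalResult]
    counts: list[ScreenCounts]
    thresholds: Thresholds = field(default_factory=Thresholds)

    def to_frame(self) -> pd.DataFrame:
        return results_to_frame(self.results)

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(c) for c in self.counts])


def screen(universe: ReportSet, drugs: Sequence[str], event_pts,
           th: Thresholds = Thresholds(),
           event_set_name: str = "Seizures (incl subtypes)") -> ScreenOutput:
    """Run the full disproportionality screen for each drug.

    Emits one SignalResult per (drug, PT) pair whose case count reaches
    ``th.min_cases``, plus one group-level result per drug over the
    whole PT set (counted as unique reports, so a report with two
    qualifying PTs contributes once).  Results are ordered by drug
    (input order) then descending case count.
    """
    event_pts = set(event_pts)
    results: list[SignalResult] = []
    counts: list[ScreenCounts] = []
    n = len(universe)
    ev_ids_all = set(universe.event_primaryids(event_pts))
    pt_ids = {pt: set(universe.event_primaryids([pt])) for pt in sorted(event_pts)}

    for drug in drugs:
        ps_ids = set(universe.ps_primaryids(drug))
        drug_results: list[SignalResult] = []
        flagged_ids: set = set()
        pairs_min = 0
        for pt in sorted(event_pts):
            ev = pt_ids[pt]
            a = len(ps_ids & ev)
            if a < th.min_cases:
                continue
            pairs_min += 1
            t = ContingencyTable(a=a, b=len(ps_ids) - a, c=len(ev) - a,
                                 d=n - a - (len(ps_ids) - a) - (len(ev) - a))
            r = compute_signal(drug, pt, "PT", t, th)
            drug_results.append(r)
            if r.ror_flag:
                flagged_ids |= ps_ids & ev
        drug_results.sort(key=lambda r: (-r.a, r.event))

        a_h = len(ps_ids & ev_ids_all)
        t_h = ContingencyTable(a=a_h, b=len(ps_ids) - a_h, c=len(ev_ids_all) - a_h,
                               d=n - a_h - (len(ps_ids) - a_h) - (len(ev_ids_all) - a_h))
        hlgt_result = compute_signal(drug, event_set_name, "HLGT", t_h, th)

        results.extend(drug_results)
        results.append(hlgt_result)
        counts.append(ScreenCounts(
            drug=drug,
            ps_reports=len(ps_ids),
            cases_before=a_h,
            pairs_min_cases=pairs_min,
            pairs_ror_flagged=sum(r.ror_flag for r in drug_results),
            cases_after=len(flagged_ids),
        ))
    return ScreenOutput(results=results, counts=counts, thresholds=th)


RESULT_COLUMNS = ["drug", "event", "level", "a", "ror", "ror025", "ror975",
                  "prr", "chi2", "ic", "ic025", "ebgm", "ebgm05",
                  "ror_flag", "prr_flag", "bcpnn_flag", "mgps_flag"]


def results_to_frame(results: Sequence[SignalResult]) -> pd.DataFrame:
    """Fixed-column-order result table (full precision; round only for
    display with :func:`round_half_up`)."""
    rows = [{c: getattr(r, c) for c in RESULT_COLUMNS} for r in results]
    frame = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if frame.empty:
        return frame
    return frame
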