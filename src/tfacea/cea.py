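"""Incremental cost-effectiveness analysis against the reference option.

For each EU-level action option the analysis computes the cost and DALY
differences to the no-EU-action reference.  Negative differences are savings
(costs) and health gains (DALYs averted).  An option is *dominant* when it
saves both; *dominated* when it loses both.  Otherwise the incremental
cost-effectiveness ratio ICER = delta_cost / delta_DALYs is reported with
the sign convention of the source tables (negative when DALYs are averted at
positive cost), and classified against the WHO GDP-per-capita thresholds on
its magnitude: |ICER| < 1 x GDP per capita is highly cost-effective,
< 3 x GDP cost-effective, otherwise not cost-effective (strict-less
boundaries for the better tier).
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .config import CEThresholds
from .outcomes import RunResult

__all__ = ["IncrementalResult", "incremental", "classify", "incremental_table"]

DOMINANT = "dominant"
DOMINATED = "dominated"
HIGHLY_CE = "highly_cost_effective"
CE = "cost_effective"
NOT_CE = "not_cost_effective"


@dataclass(frozen=True)
class IncrementalResult:
    """Cost/DALY differences of one option versus the reference."""

    option_id: str
    reference_id: str
    delta_cost: float
    delta_dalys: float
    icer: float | None
    ce_class: str

    @property
    def dalys_averted(self) -> float:
        return -self.delta_dalys

    @property
    def cost_saved(self) -> float:
        return -self.delta_cost


def incremental(option_result: RunResult, reference_result: RunResult) -> IncrementalResult:
    """Differences (option minus reference), dominance and raw ICER.

    The ICER is defined only when the DALY difference is nonzero and the
    option is neither dominant nor dominated; a zero DALY difference at
    nonzero cost difference yields class by the cost sign alone.
    """
    d_cost = option_result.total_cost - reference_result.total_cost
    d_dalys = option_result.dalys - reference_result.dalys

    if d_cost < 0 and d_dalys < 0:
        return IncrementalResult(option_result.option_id, reference_result.option_id,
                                 d_cost, d_dalys, None, DOMINANT)
    if d_cost > 0 and d_dalys > 0:
        return IncrementalResult(option_result.option_id, reference_result.option_id,
                                 d_cost, d_dalys, None, DOMINATED)
    if d_dalys == 0:
        cls = DOMINANT if d_cost < 0 else DOMINATED if d_cost > 0 else HIGHLY_CE
        return IncrementalResult(option_result.option_id, reference_result.option_id,
                                 d_cost, d_dalys, None, cls)
    icer = d_cost / d_dalys
    return IncrementalResult(option_result.option_id, reference_result.option_id,
                             d_cost, d_dalys, icer, "")


def classify(result: IncrementalResult, thresholds: CEThresholds) -> IncrementalResult:
    """Attach the WHO-threshold class; dominance markers pass through."""
    thresholds.validate()
    if result.ce_class in (DOMINANT, DOMINATED) or result.icer is None:
        return result if result.ce_class else replace(result, ce_class=HIGHLY_CE)
    gdp = thresholds.gdp_per_capita
    magnitude = abs(result.icer)
    if magnitude < gdp:
        cls = HIGHLY_CE
    elif magnitude < 3.0 * gdp:
        cls = CE
    else:
        cls = NOT_CE
    return replace(result, ce_class=cls)


def incremental_analysis(results: dict[str, RunResult], thresholds: CEThresholds,
                         reference_id: str = "reference") -> list[IncrementalResult]:
    """Classified incremental results for every non-reference option."""
    ref = results[reference_id]
    return [classify(incremental(res, ref), thresholds)
            for oid, res in results.items() if oid != reference_id]


def incremental_table(incrementals: list[IncrementalResult]) -> pd.DataFrame:
    """The incremental analysis as a DataFrame mirroring the reporting layout."""
    rows = [{
        "option": r.option_id,
        "reference": r.reference_id,
        "delta_cost_eur": r.delta_cost,
        "delta_dalys": r.delta_dalys,
        "icer_eur_per_daly": r.icer if r.icer is not None else r.ce_class,
        "ce_class": r.ce_class,
    } for r in incrementals]
    columns = ["option", "reference", "delta_cost_eur", "delta_dalys",
               "icer_eur_per_daly", "ce_class"]
    return pd.DataFrame(rows, columns=columns)
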