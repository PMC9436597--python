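"""Cohort state-transition engine and incremental cost-effectiveness.

Runs the four-state Markov cohort per arm over the configured horizon
(default 12 quarterly cycles = 3 years), accrues discounted costs by
component (drug, management, adverse events, exacerbations) and QALYs, and
compares arms via incremental cost, incremental QALYs, the ICER and a
dominance classification with net monetary benefit at the willingness-to-pay
threshold.

Reward conventions (state-at-entry vs half-cycle averaging, discount
indexing, optional cycle-0 accrual) are taken from
``ModelParameters.conventions``; the transition into cycle 1 uses the BASE
matrix and all later transitions the NEW matrix.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import (
    ALIVE_STATES,
    Arm,
    ModelParameters,
    Phase,
    STATE_INDEX,
    STATES,
    State,
)

__all__ = [
    "COST_COMPONENTS",
    "CohortTrace",
    "ArmResult",
    "Dominance",
    "CEResult",
    "discount_factor",
    "accrue_cycle_rewards",
    "run_cohort",
    "evaluate_arm",
    "compute_icer",
    "trace_to_frame",
    "ce_result_to_dict",
]

COST_COMPONENTS = ("drug", "management", "adverse_event", "exacerbation")

_ALIVE_IDX = [STATE_INDEX[s] for s in ALIVE_STATES]


def discount_factor(cycle_index: int, quarterly_rate: float) -> float:
    """Discount factor (1 + r)^-k for a quarterly rate r; cycle 0 -> 1."""
    if cycle_index < 0:
        raise ValueError("cycle index must be non-negative")
    if quarterly_rate < 0:
        raise ValueError("discount rate must be non-negative")
    return (1.0 + quarterly_rate) ** (-cycle_index)


def accrue_cycle_rewards(
    occupancy: np.ndarray, params: ModelParameters, arm: Arm
) -> dict[str, float]:
    """Undiscounted rewards for one cycle given its occupancy weights.

    With weight ``w_s`` on alive state ``s``: drug cost = sum_s w_s * drug
    per cycle; management = sum_s w_s * management(s); exacerbation cost =
    sum_s w_s * (n_severe(s) * c_severe + n_nonsevere(s) * c_nonsevere);
    adverse-event cost = (alive mass) * sum_events p_event * c_event; utility
    accrual = sum_s w_s * annual_utility(s) * cycle_years.  DEATH contributes
    nothing.  Events priced but flagged inactive are excluded.
    """
    w = np.asarray(occupancy, float)
    alive = float(w[_ALIVE_IDX].sum())
    drug = alive * params.costs.drug[arm].point
    management = sum(
        float(w[STATE_INDEX[s]]) * params.costs.management[s].point
        for s in ALIVE_STATES
    )
    c_sev = params.costs.exacerbation["severe"].point
    c_nsev = params.costs.exacerbation["nonsevere"].point
    exacerbation = sum(
        float(w[STATE_INDEX[s]])
        * (
            params.exacerbations.severe[s].point * c_sev
            + params.exacerbations.nonsevere[s].point * c_nsev
        )
        for s in ALIVE_STATES
    )
    ae_per_alive = sum(
        gp.point * params.costs.adverse_event[event].point
        for event, gp in params.adverse_events.per_cycle[arm].items()
    )
    adverse_event = alive * ae_per_alive
    qaly = sum(
        float(w[STATE_INDEX[s]]) * params.utilities.annual[s].point
        for s in ALIVE_STATES
    ) * params.cycle_years
    return {
        "drug": drug,
        "management": management,
        "adverse_event": adverse_event,
        "exacerbation": exacerbation,
        "qaly": qaly,
    }


@dataclass
class CohortTrace:
    """Per-cycle occupancy and reward ledger for one arm.

    ``occupancy`` has shape (horizon+1, 4) in canonical state order, row 0
    being the initial distribution.  ``ledger`` has one row per accrual
    cycle with each cost component and the utility accrual, undiscounted and
    discounted.
    """

    arm: Arm
    occupancy: np.ndarray
    ledger: pd.DataFrame

    @property
    def horizon_cycles(self) -> int:
        return self.occupancy.shape[0] - 1


@dataclass
class ArmResult:
    arm: Arm
    total_cost: float
    cost_components: dict[str, float]
    total_qalys: float
    trace: CohortTrace


class Dominance(str, enum.Enum):
    DOMINANT = "dominant"  # cheaper and more effective
    DOMINATED = "dominated"  # costlier and less effective
    ICER_DEFINED = "icer_defined"
    EQUIVALENT = "equivalent"


@dataclass
class CEResult:
    delta_cost: float
    delta_qaly: float
    icer: float | None
    dominance: Dominance
    wtp_per_qaly: float
    nmb_at_wtp: float


def run_cohort(params: ModelParameters, arm: Arm) -> CohortTrace:
    """Propagate the cohort and populate the reward ledger for ``arm``."""
    if params.horizon_cycles < 1:
        raise ValueError("horizon_cycles must be >= 1")
    H = params.horizon_cycles
    conv = params.conventions
    occ = np.zeros((H + 1, len(STATES)))
    occ[0] = params.initial.occupancy[arm]
    m_base = params.transitions[(arm, Phase.BASE)].probs
    m_new = params.transitions[(arm, Phase.NEW)].probs
    death = STATE_INDEX[State.DEATH]
    for k in range(1, H + 1):
        occ[k] = occ[k - 1] @ (m_base if k == 1 else m_new)
        total = occ[k].sum()
        if abs(total - 1.0) > 1e-9:
            raise AssertionError(f"probability not conserved at cycle {k}: {total}")
        if occ[k, death] < occ[k - 1, death] - 1e-12:
            raise AssertionError(f"DEATH occupancy decreased at cycle {k}")

    rows = []
    cycles = ([0] if conv.cycle0_accrual else []) + list(range(1, H + 1))
    for k in cycles:
        if k == 0:
            w = occ[0]
        elif conv.half_cycle:
            w = 0.5 * (occ[k - 1] + occ[k])
        else:
            w = occ[k - 1]
        rewards = accrue_cycle_rewards(w, params, arm)
        d = discount_factor(max(k - conv.discount_offset, 0), params.discount_quarterly)
        row = {"cycle": k, "discount": d}
        for comp in COST_COMPONENTS:
            row[comp] = rewards[comp]
            row[f"{comp}_disc"] = rewards[comp] * d
        row["cost"] = sum(rewards[c] for c in COST_COMPONENTS)
        row["cost_disc"] = row["cost"] * d
        row["qaly"] = rewards["qaly"]
        row["qaly_disc"] = rewards["qaly"] * d
        rows.append(row)
    ledger = pd.DataFrame(rows).set_index("cycle")
    return CohortTrace(arm=arm, occupancy=occ, ledger=ledger)


def evaluate_arm(params: ModelParameters, arm: Arm) -> ArmResult:
    """Total discounted costs (by component) and QALYs for one arm."""
    trace = run_cohort(params, arm)
    components = {
        comp: float(trace.ledger[f"{comp}_disc"].sum()) for comp in COST_COMPONENTS
    }
    return ArmResult(
        arm=arm,
        total_cost=float(trace.ledger["cost_disc"].sum()),
        cost_components=components,
        total_qalys=float(trace.ledger["qaly_disc"].sum()),
        trace=trace,
    )


def compute_icer(
    intervention: ArmResult,
    comparator: ArmResult,
    wtp_per_qaly: float,
    zero_tol: float = 1e-12,
) -> CEResult:
    """Incremental results (intervention minus comparator) with dominance.

    The ICER is left undefined when the QALY difference vanishes, and the
    dominance label carries the interpretation when one strategy is both
    cheaper and more effective.
    """
    if intervention.trace.horizon_cycles != comparator.trace.horizon_cycles:
        raise ValueError("arm results come from different horizons")
    d_cost = intervention.total_cost - comparator.total_cost
    d_qaly = intervention.total_qalys - comparator.total_qalys
    if abs(d_cost) <= zero_tol and abs(d_qaly) <= zero_tol:
        dominance, icer = Dominance.EQUIVALENT, None
    elif d_cost < 0 and d_qaly > 0:
        dominance, icer = Dominance.DOMINANT, d_cost / d_qaly
    elif d_cost > 0 and d_qaly < 0:
        dominance, icer = Dominance.DOMINATED, d_cost / d_qaly
    elif abs(d_qaly) <= zero_tol:
        dominance, icer = Dominance.ICER_DEFINED, None
    else:
        dominance, icer = Dominance.ICER_DEFINED, d_cost / d_qaly
    return CEResult(
        delta_cost=d_cost,
        delta_qaly=d_qaly,
        icer=icer,
        dominance=dominance,
        wtp_per_qaly=wtp_per_qaly,
        nmb_at_wtp=wtp_per_qaly * d_qaly - d_cost,
    )


def trace_to_frame(trace: CohortTrace) -> pd.DataFrame:
    """One row per cycle: occupancy per state plus the reward ledger."""
    occ = pd.DataFrame(
        trace.occupancy,
        columns=[f"occupancy_{s.value}" for s in STATES],
    )
    occ.index.name = "cycle"
    return occ.join(trace.ledger, how="left")


def ce_result_to_dict(
    result: CEResult, intervention: ArmResult, comparator: ArmResult
) -> dict:
    """JSON-ready summary of both arms and the incremental comparison."""

    def arm_block(r: ArmResult) -> dict:
        return {
            "arm": r.arm.value,
            "total_cost": r.total_cost,
            "cost_components": r.cost_components,
            "total_qalys": r.total_qalys,
        }

    return {
        "intervention": arm_block(intervention),
        "comparator": arm_block(comparator),
        "delta_cost": result.delta_cost,
        "delta_qaly": result.delta_qaly,
        "icer": result.icer,
        "dominance": result.dominance.value,
        "wtp_per_qaly": result.wtp_per_qaly,
        "nmb_at_wtp": result.nmb_at_wtp,
    }
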