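"""Second-order Monte-Carlo probabilistic sensitivity analysis.

Every uncertain input is drawn from its assigned distribution -- Dirichlet
transition rows from their counts, beta utilities, gamma adverse-event
probabilities (truncated to [0, 1] with the truncation fraction reported),
uniform costs and exacerbation counts -- the model is re-run per draw for
both arms, and the incremental (cost, QALY) cloud feeds the cost-
effectiveness plane, probability-cost-effective summaries and the
acceptability curve (CEAC).

Two correlation modes exist: in shared mode the health-state parameters
(utilities, unit costs, exacerbation counts) are drawn once per iteration
and applied to both arms; in arm-specific mode (the default of the bundled
configuration) every distribution is sampled independently per arm.
Transition rows and adverse-event probabilities are always arm-specific.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markov import evaluate_arm
from .parameters import (
    ALIVE_STATES,
    Arm,
    ModelParameters,
    Phase,
    STATE_INDEX,
    STATES,
)

__all__ = [
    "DistributionSpec",
    "PSASampleSet",
    "draw_parameter_set",
    "run_psa",
    "prob_cost_effective",
    "ceac",
    "default_wtp_grid",
    "scatter_frame",
]


@dataclass
class DistributionSpec:
    """Validated sampling spec: dirichlet_row, beta, gamma, uniform or fixed."""

    kind: str
    parameters: tuple[float, ...]

    def __post_init__(self):
        k, p = self.kind, self.parameters
        if k == "beta":
            if len(p) != 2 or p[0] <= 0 or p[1] <= 0:
                raise ValueError(f"invalid beta parameters {p}")
        elif k == "gamma":
            if len(p) != 2 or p[0] <= 0 or p[1] <= 0:
                raise ValueError(f"invalid gamma parameters {p}")
        elif k == "uniform":
            if len(p) != 2 or p[0] > p[1]:
                raise ValueError(f"invalid uniform bounds {p}")
        elif k == "dirichlet_row":
            if len(p) == 0 or any(c < 0 for c in p) or sum(p) <= 0:
                raise ValueError(f"invalid Dirichlet counts {p}")
        elif k != "fixed":
            raise ValueError(f"unknown distribution kind {k!r}")


@dataclass
class PSASampleSet:
    """Seeded (delta cost, delta QALY) draws: intervention minus comparator."""

    seed: int
    n_draws: int
    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    shared_params: bool
    wtp_per_qaly: float
    #: fraction of gamma AE draws that had to be truncated at 1
    gamma_truncated_fraction: float = 0.0
    arm_costs: dict = field(default_factory=dict)
    arm_qalys: dict = field(default_factory=dict)


class _TruncationCounter:
    def __init__(self):
        self.total = 0
        self.truncated = 0

    @property
    def fraction(self) -> float:
        return self.truncated / self.total if self.total else 0.0


def _sample_dirichlet_row(rng, counts, probs):
    """Sample one transition row; structural zeros stay exactly zero."""
    out = np.zeros_like(probs)
    nz = counts > 0
    if nz.sum() <= 1:
        return probs.copy()  # degenerate row: nothing to sample
    out[nz] = rng.dirichlet(counts[nz])
    return out


def _draw_state_block(rng, sampled: ModelParameters):
    """Draw the shared health-state parameters in place (fixed order)."""
    for s in ALIVE_STATES:
        bp = sampled.utilities.annual[s]
        bp.point = float(rng.beta(bp.alpha, bp.beta))
    for s in ALIVE_STATES:
        up = sampled.costs.management[s]
        up.point = float(rng.uniform(up.low, up.high))
    for name in sorted(sampled.costs.adverse_event):
        up = sampled.costs.adverse_event[name]
        up.point = float(rng.uniform(up.low, up.high))
    for kind in ("severe", "nonsevere"):
        up = sampled.costs.exacerbation[kind]
        up.point = float(rng.uniform(up.low, up.high))
    for kind in ("severe", "nonsevere"):
        table = getattr(sampled.exacerbations, kind)
        for s in ALIVE_STATES:
            up = table[s]
            up.point = float(rng.uniform(up.low, up.high))


def _draw_arm_block(rng, sampled: ModelParameters, arm: Arm, trunc):
    """Draw the arm-specific parameters (transitions, drug cost, AE risks)."""
    for phase in Phase:
        table = sampled.transitions[(arm, phase)]
        for s in ALIVE_STATES:
            i = STATE_INDEX[s]
            table.probs[i] = _sample_dirichlet_row(
                rng, table.counts[i], table.probs[i]
            )
    up = sampled.costs.drug[arm]
    up.point = float(rng.uniform(up.low, up.high))
    for event in sorted(sampled.adverse_events.per_cycle[arm]):
        gp = sampled.adverse_events.per_cycle[arm][event]
        draw = float(rng.gamma(gp.shape, gp.scale))
        trunc.total += 1
        if draw > 1.0:
            trunc.truncated += 1
            draw = 1.0
        gp.point = draw


def draw_parameter_set(
    params: ModelParameters,
    rng: np.random.Generator,
    trunc: _TruncationCounter | None = None,
) -> dict[Arm, ModelParameters]:
    """One coherent sampled parameter set, keyed by the arm it evaluates.

    In shared mode the state block (utilities, unit costs, exacerbation
    counts) is drawn once and both arms map to the same sampled object;
    in arm-specific mode each arm gets its own independently drawn block.
    Draw order is fixed so a seed fully determines the set.
    """
    trunc = trunc if trunc is not None else _TruncationCounter()
    if params.conventions.psa_shared_params:
        sampled = params.copy()
        _draw_state_block(rng, sampled)
        for arm in Arm:
            _draw_arm_block(rng, sampled, arm, trunc)
        return {arm: sampled for arm in Arm}
    per_arm: dict[Arm, ModelParameters] = {}
    for arm in Arm:
        block = params.copy()
        _draw_state_block(rng, block)
        _draw_arm_block(rng, block, arm, trunc)
        per_arm[arm] = block
    return per_arm


def run_psa(
    params: ModelParameters,
    n_draws: int = 1000,
    seed: int = 0,
) -> PSASampleSet:
    """Second-order Monte Carlo: ``n_draws`` model re-runs per arm."""
    rng = np.random.default_rng(seed)
    trunc = _TruncationCounter()
    d_cost = np.empty(n_draws)
    d_qaly = np.empty(n_draws)
    costs = {arm: np.empty(n_draws) for arm in Arm}
    qalys = {arm: np.empty(n_draws) for arm in Arm}
    for i in range(n_draws):
        sampled = draw_parameter_set(params, rng, trunc)
        results = {arm: evaluate_arm(sampled[arm], arm) for arm in Arm}
        d_cost[i] = results[Arm.UMEC_VI].total_cost - results[Arm.TIO].total_cost
        d_qaly[i] = results[Arm.UMEC_VI].total_qalys - results[Arm.TIO].total_qalys
        for arm in Arm:
            costs[arm][i] = results[arm].total_cost
            qalys[arm][i] = results[arm].total_qalys
    return PSASampleSet(
        seed=seed,
        n_draws=n_draws,
        delta_cost=d_cost,
        delta_qaly=d_qaly,
        shared_params=params.conventions.psa_shared_params,
        wtp_per_qaly=params.wtp_per_qaly,
        gamma_truncated_fraction=trunc.fraction,
        arm_costs={a.value: costs[a] for a in Arm},
        arm_qalys={a.value: qalys[a] for a in Arm},
    )


def prob_cost_effective(samples: PSASampleSet, wtp: float) -> float:
    """Fraction of draws with non-negative intervention NMB at ``wtp``.

    NMB = wtp * dQALY - dCost; a tie (NMB exactly 0) counts for the
    intervention by convention.
    """
    if samples.n_draws == 0:
        raise ValueError("empty PSA sample set")
    nmb = wtp * samples.delta_qaly - samples.delta_cost
    return float((nmb >= 0).mean())


def default_wtp_grid(wtp: float = 31554.0) -> np.ndarray:
    """0 to 3x the threshold in 64 uniform steps, always including it."""
    grid = np.linspace(0.0, 3.0 * wtp, 64)
    return np.unique(np.append(grid, wtp))


def ceac(samples: PSASampleSet, wtp_grid) -> pd.DataFrame:
    """Acceptability curve for both strategies over an ascending WTP grid."""
    grid = np.asarray(list(wtp_grid), float)
    if grid.size == 0:
        raise ValueError("empty WTP grid")
    if np.any(np.diff(grid) < 0):
        raise ValueError("WTP grid must be ascending")
    p_int = np.array([prob_cost_effective(samples, w) for w in grid])
    return pd.DataFrame(
        {
            "wtp": grid,
            "p_cost_effective_UMEC_VI": p_int,
            "p_cost_effective_TIO": 1.0 - p_int,
        }
    )


def scatter_frame(samples: PSASampleSet) -> pd.DataFrame:
    """Cost-effectiveness plane export: one row per draw."""
    return pd.DataFrame(
        {
            "draw": np.arange(samples.n_draws),
            "delta_cost": samples.delta_cost,
            "delta_qaly": samples.delta_qaly,
        }
    )
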