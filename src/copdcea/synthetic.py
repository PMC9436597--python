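"""Synthetic inputs and verification oracles.

Three generators, all deterministic under their seeds:

* multi-study two-arm binomial trials with a stated true relative risk and
  between-study log-RR heterogeneity, standing in for unpublished per-study
  outcome counts when exercising the meta-analysis;
* randomly perturbed but structurally valid Markov parameter sets
  (row-stochastic matrices with an absorbing death state and no improvement
  beyond one severity step, ordered utilities, +/-20% cost bounds) for
  engine property tests;
* a first-order patient-level microsimulation that replays the cohort
  engine's matrices and reward conventions on individual trajectories,
  giving an independent empirical check of occupancy, costs and QALYs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .markov import accrue_cycle_rewards, discount_factor
from .meta import TwoByTwoStudy
from .parameters import (
    AEInputs,
    ALIVE_STATES,
    Arm,
    BetaParam,
    Conventions,
    CostInputs,
    ExacerbationInputs,
    GammaParam,
    InitialDistribution,
    ModelParameters,
    Phase,
    STATE_INDEX,
    STATES,
    State,
    TransitionTable,
    UniformParam,
    UtilityInputs,
)

__all__ = [
    "TrialScenario",
    "gen_meta_studies",
    "gen_model_parameters",
    "MicrosimResult",
    "microsim_oracle",
]


@dataclass
class TrialScenario:
    """Ground truth for a set of synthetic two-arm trials.

    Study-level log relative risks are Normal(ln true_rr, tau2); events per
    arm are binomial at the implied risks.
    """

    true_rr: float
    baseline_risk: float
    tau2: float = 0.0
    k: int = 3
    n_per_arm: int = 500
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.baseline_risk < 1.0:
            raise ValueError("baseline_risk must lie in (0, 1)")
        if self.true_rr <= 0:
            raise ValueError("true_rr must be positive")
        if self.true_rr * self.baseline_risk > 1.0:
            raise ValueError("true_rr * baseline_risk exceeds 1: infeasible risk")
        if self.tau2 < 0:
            raise ValueError("tau2 must be non-negative")
        if self.k < 1:
            raise ValueError("need at least one study")
        if self.n_per_arm < 1:
            raise ValueError("n_per_arm must be >= 1")


def gen_meta_studies(scenario: TrialScenario) -> list[TwoByTwoStudy]:
    """Draw ``k`` synthetic trials under the scenario (seed-deterministic)."""
    rng = np.random.default_rng(scenario.seed)
    studies = []
    eps = 1e-12
    for i in range(scenario.k):
        theta = rng.normal(math.log(scenario.true_rr), math.sqrt(scenario.tau2))
        risk_ctrl = scenario.baseline_risk
        risk_trt = min(max(risk_ctrl * math.exp(theta), eps), 1.0 - eps)
        n = scenario.n_per_arm
        events_1 = int(rng.binomial(n, risk_trt))
        events_2 = int(rng.binomial(n, risk_ctrl))
        studies.append(TwoByTwoStudy(f"study_{i + 1}", events_1, n, events_2, n))
    return studies


def gen_model_parameters(seed: int, horizon: int = 12) -> ModelParameters:
    """Random valid parameter set exercising every engine invariant.

    Transitions allow stay, one-step worsening and death (no improvement);
    Dirichlet counts are drawn first as integers and probabilities defined
    as counts/total, so count-consistency holds exactly.
    """
    rng = np.random.default_rng(seed)

    def random_table() -> TransitionTable:
        probs = np.zeros((4, 4))
        counts = np.zeros((4, 4))
        probs[STATE_INDEX[State.DEATH], STATE_INDEX[State.DEATH]] = 1.0
        worse = {State.C: State.B, State.B: State.A, State.A: None}
        for s in ALIVE_STATES:
            i = STATE_INDEX[s]
            total = int(rng.integers(300, 2000))
            c_death = int(rng.integers(1, max(2, int(0.1 * total))))
            c_worse = 0
            if worse[s] is not None:
                c_worse = int(rng.integers(0, max(1, int(0.15 * total))))
            c_stay = total - c_death - c_worse
            counts[i, i] = c_stay
            counts[i, STATE_INDEX[State.DEATH]] = c_death
            if worse[s] is not None:
                counts[i, STATE_INDEX[worse[s]]] = c_worse
            probs[i] = counts[i] / total
        return TransitionTable(probs, counts)

    transitions = {
        (arm, phase): random_table() for arm in Arm for phase in Phase
    }

    def uni(point: float) -> UniformParam:
        return UniformParam(point, 0.8 * point, 1.2 * point)

    costs = CostInputs(
        drug={arm: uni(float(rng.uniform(50, 400))) for arm in Arm},
        management={
            s: uni(float(c))
            for s, c in zip(ALIVE_STATES, np.sort(rng.uniform(80, 500, 3)))
        },
        adverse_event={
            name: uni(float(rng.uniform(2, 60))) for name in ("ae_1", "ae_2")
        },
        exacerbation={
            "severe": uni(float(rng.uniform(800, 3000))),
            "nonsevere": uni(float(rng.uniform(20, 120))),
        },
    )

    raw_u = np.sort(rng.uniform(0.4, 0.95, 3))[::-1]  # u(C) >= u(B) >= u(A)
    utilities = UtilityInputs(
        annual={
            s: BetaParam(float(u), float(u * n), float((1 - u) * n))
            for s, u, n in zip(ALIVE_STATES, raw_u, rng.uniform(50, 500, 3))
        }
    )

    nonsevere = np.sort(rng.uniform(0.05, 0.5, 3))  # increasing with severity
    frac = float(rng.uniform(0.1, 0.6))  # severe <= nonsevere, order preserved
    exac = ExacerbationInputs(
        severe={
            s: uni(float(frac * v)) for s, v in zip(ALIVE_STATES, nonsevere)
        },
        nonsevere={s: uni(float(v)) for s, v in zip(ALIVE_STATES, nonsevere)},
    )

    ae = AEInputs(
        per_cycle={
            arm: {
                name: _gamma(float(rng.uniform(0.005, 0.06)), rng)
                for name in ("ae_1", "ae_2")
            }
            for arm in Arm
        }
    )

    stage_counts = {
        arm: {
            stage: int(rng.integers(50, 400)) for stage in ("II", "III", "IV")
        }
        for arm in Arm
    }
    from .parameters import initial_distribution

    occupancy = {
        arm: initial_distribution(sc, "severity") for arm, sc in stage_counts.items()
    }
    params = ModelParameters(
        transitions=transitions,
        costs=costs,
        utilities=utilities,
        exacerbations=exac,
        adverse_events=ae,
        initial=InitialDistribution(occupancy, stage_counts, "severity"),
        horizon_cycles=horizon,
        discount_quarterly=float(rng.uniform(0.0, 0.03)),
        wtp_per_qaly=float(rng.uniform(10000, 60000)),
        conventions=Conventions(),
        name=f"synthetic-{seed}",
    )
    return params.validate()


def _gamma(point: float, rng) -> GammaParam:
    shape = float(rng.uniform(5, 500))
    return GammaParam(point, shape, point / shape)


@dataclass
class MicrosimResult:
    arm: Arm
    n_patients: int
    occupancy: np.ndarray  # (H+1, 4) empirical fractions
    occupancy_se: np.ndarray  # binomial standard errors
    mean_cost: float
    se_cost: float
    mean_qaly: float
    se_qaly: float


def microsim_oracle(
    params: ModelParameters, arm: Arm, n_patients: int, seed: int
) -> MicrosimResult:
    """First-order microsimulation under the same matrices and rewards.

    Patients are independent; each follows the BASE matrix into cycle 1 and
    the NEW matrix afterwards.  Per-cycle rewards re-use
    ``accrue_cycle_rewards`` on one-hot occupancy (entry state, or the mean
    of entry and exit one-hots under the half-cycle convention), so any
    disagreement with the cohort engine beyond binomial noise indicates an
    engine defect.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    rng = np.random.default_rng(seed)
    H = params.horizon_cycles
    conv = params.conventions
    n_states = len(STATES)

    # per-state per-cycle reward lookup (identical to the cohort engine's)
    unit_cost = np.zeros(n_states)
    unit_qaly = np.zeros(n_states)
    for s in STATES:
        one_hot = np.zeros(n_states)
        one_hot[STATE_INDEX[s]] = 1.0
        r = accrue_cycle_rewards(one_hot, params, arm)
        unit_cost[STATE_INDEX[s]] = sum(
            r[c] for c in ("drug", "management", "adverse_event", "exacerbation")
        )
        unit_qaly[STATE_INDEX[s]] = r["qaly"]

    init = params.initial.occupancy[arm]
    states = rng.choice(n_states, size=n_patients, p=init)
    m_base = params.transitions[(arm, Phase.BASE)].probs
    m_new = params.transitions[(arm, Phase.NEW)].probs
    cum = {1: np.cumsum(m_base, axis=1)}
    cum_new = np.cumsum(m_new, axis=1)

    occ = np.zeros((H + 1, n_states))
    occ[0] = np.bincount(states, minlength=n_states) / n_patients
    cost = np.zeros(n_patients)
    qaly = np.zeros(n_patients)
    if conv.cycle0_accrual:
        cost += unit_cost[states]
        qaly += unit_qaly[states]
    for k in range(1, H + 1):
        cmat = cum.get(k, cum_new)
        u = rng.random(n_patients)
        nxt = (u[:, None] > cmat[states]).sum(axis=1)
        d = discount_factor(max(k - conv.discount_offset, 0), params.discount_quarterly)
        if conv.half_cycle:
            cost += d * 0.5 * (unit_cost[states] + unit_cost[nxt])
            qaly += d * 0.5 * (unit_qaly[states] + unit_qaly[nxt])
        else:
            cost += d * unit_cost[states]
            qaly += d * unit_qaly[states]
        states = nxt
        occ[k] = np.bincount(states, minlength=n_states) / n_patients
    occ_se = np.sqrt(occ * (1 - occ) / n_patients)
    return MicrosimResult(
        arm=arm,
        n_patients=n_patients,
        occupancy=occ,
        occupancy_se=occ_se,
        mean_cost=float(cost.mean()),
        se_cost=float(cost.std(ddof=1) / math.sqrt(n_patients)),
        mean_qaly=float(qaly.mean()),
        se_qaly=float(qaly.std(ddof=1) / math.sqrt(n_patients)),
    )
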