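"""Model inputs: types, loading, validation, and probability transforms.

The cost-effectiveness model compares two inhaled bronchodilator strategies
(UMEC/VI fixed-dose combination vs tiotropium) in symptomatic COPD with a
four-state Markov structure: three severity states defined by percent-predicted
FEV1 -- C moderate (50-80%), B severe (30-50%), A very severe (<30%) -- plus an
absorbing DEATH state.  Every engine symbol (transition rows with Dirichlet
counts, per-cycle costs with uniform bounds, annual utilities with beta
parameters, adverse-event probabilities with gamma parameters, expected
exacerbation counts, the initial GOLD-stage distribution, discounting and
horizon) lives here, together with a bundled configuration encoding the
published input tables.
"""

from __future__ import annotations

import copy
import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "Arm",
    "Phase",
    "State",
    "STATES",
    "ALIVE_STATES",
    "UniformParam",
    "BetaParam",
    "GammaParam",
    "TransitionTable",
    "CostInputs",
    "UtilityInputs",
    "ExacerbationInputs",
    "AEInputs",
    "InitialDistribution",
    "Conventions",
    "ModelParameters",
    "ConfigurationError",
    "ParameterValidationError",
    "load_parameters",
    "load_fixture",
    "FIXTURES",
    "params_to_dict",
    "params_to_yaml",
    "rescale_probability",
    "initial_distribution",
    "iter_parameters",
    "ParameterHandle",
]

# Validation tolerances.  Row sums must be exact to numerical noise; the
# moment checks compare point estimates against distribution parameters that
# the source tables print at 3-4 significant figures.  The Dirichlet
# count-consistency tolerance is 1e-3 because one published row (TIO, NEW
# phase, C->C) deviates from its printed probability by 5.7e-4.
ROW_SUM_TOL = 1e-9
DIRICHLET_TOL = 1e-3
MOMENT_TOL = 5e-4
BOUNDS_TOL = 1e-3


class ConfigurationError(ValueError):
    """A configuration document is missing sections or unparseable."""


class ParameterValidationError(ValueError):
    """One or more parameter invariants failed; message lists all of them."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__(
            "parameter validation failed:\n" + "\n".join(f"  - {p}" for p in problems)
        )


class Arm(str, enum.Enum):
    UMEC_VI = "UMEC_VI"
    TIO = "TIO"


class Phase(str, enum.Enum):
    """BASE governs the transition into cycle 1, NEW all later cycles."""

    BASE = "BASE"
    NEW = "NEW"


class State(str, enum.Enum):
    C = "C"  # moderate, 50% <= predicted FEV1 < 80%
    B = "B"  # severe, 30-50%
    A = "A"  # very severe, <30%
    DEATH = "DEATH"


#: Canonical state order used by every occupancy vector and matrix.
STATES: tuple[State, ...] = (State.C, State.B, State.A, State.DEATH)
ALIVE_STATES: tuple[State, ...] = (State.C, State.B, State.A)
STATE_INDEX = {s: i for i, s in enumerate(STATES)}
#: Severity rank (C < B < A); used by "more serious" ordering checks.
SEVERITY = {State.C: 0, State.B: 1, State.A: 2}

_GOLD_STAGES = ("II", "III", "IV")


@dataclass
class UniformParam:
    """Point estimate with uniform sampling bounds (the +/-20% rule)."""

    point: float
    low: float
    high: float


@dataclass
class BetaParam:
    """Point estimate with beta(alpha, beta) sampling parameters."""

    point: float
    alpha: float
    beta: float


@dataclass
class GammaParam:
    """Point estimate with gamma(shape, scale); shape*scale == point."""

    point: float
    shape: float
    scale: float


@dataclass
class TransitionTable:
    """Row-stochastic 4x4 matrix in STATES order plus Dirichlet counts.

    Structural zeros (probability 0, count 0) stay zero under any sampling;
    the DEATH row is absorbing.
    """

    probs: np.ndarray  # (4, 4) float
    counts: np.ndarray  # (4, 4) float, DEATH row all zero except diagonal

    def copy(self) -> "TransitionTable":
        return TransitionTable(self.probs.copy(), self.counts.copy())


@dataclass
class CostInputs:
    drug: dict[Arm, UniformParam]  # USD per 3-month cycle
    management: dict[State, UniformParam]  # USD per cycle, alive states
    adverse_event: dict[str, UniformParam]  # USD per event
    exacerbation: dict[str, UniformParam]  # keys "severe", "nonsevere"


@dataclass
class UtilityInputs:
    annual: dict[State, BetaParam]  # alive states; DEATH fixed at 0


@dataclass
class ExacerbationInputs:
    severe: dict[State, UniformParam]  # expected events per patient per cycle
    nonsevere: dict[State, UniformParam]


@dataclass
class AEInputs:
    per_cycle: dict[Arm, dict[str, GammaParam]]
    #: event types priced in CostInputs but with no probability in either arm;
    #: they contribute nothing to expected AE cost and are flagged, not priced.
    inactive: tuple[str, ...] = ()


@dataclass
class InitialDistribution:
    """Cycle-0 occupancy per arm (length-4 vectors in STATES order)."""

    occupancy: dict[Arm, np.ndarray]
    stage_counts: dict[Arm, dict[str, int]] = field(default_factory=dict)
    mapping: str = "severity"


@dataclass
class Conventions:
    """Reward/discount conventions the source analysis leaves unstated.

    half_cycle
        Accrue rewards on the mean of entry and exit occupancy of each cycle
        (True) or on the entry occupancy alone (False).
    discount_offset
        Discount cycle k at (1+r)^-(k-offset); offset 1 leaves the first
        cycle undiscounted.
    cycle0_accrual
        Whether an extra undiscounted reward is accrued at model entry.
    gold_state_mapping
        "severity" maps GOLD II->C, III->B, IV->A; "positional" maps the
        stage-ordered counts onto the state list (A, B, C) in written order,
        i.e. II->A, III->B, IV->C, which is the assignment that reproduces
        the published totals.
    psa_shared_params
        Draw utilities/unit costs/exacerbation counts once per PSA iteration
        and share them across arms (True) or draw every parameter
        independently per arm (False).
    """

    half_cycle: bool = False
    discount_offset: int = 1
    cycle0_accrual: bool = False
    gold_state_mapping: str = "severity"
    psa_shared_params: bool = False
    nmb_tie_is_cost_effective: bool = True


@dataclass
class ModelParameters:
    """The complete validated input set for both arms."""

    transitions: dict[tuple[Arm, Phase], TransitionTable]
    costs: CostInputs
    utilities: UtilityInputs
    exacerbations: ExacerbationInputs
    adverse_events: AEInputs
    initial: InitialDistribution
    horizon_cycles: int = 12
    cycle_years: float = 0.25
    discount_quarterly: float = 0.01
    wtp_per_qaly: float = 31554.0
    gdp_per_capita: float | None = 10518.0
    conventions: Conventions = field(default_factory=Conventions)
    name: str = "unnamed"
    currency: str = "USD"
    price_year: int | None = None

    def copy(self) -> "ModelParameters":
        return copy.deepcopy(self)

    def validate(self) -> "ModelParameters":
        problems = collect_validation_problems(self)
        if problems:
            raise ParameterValidationError(problems)
        return self


# ---------------------------------------------------------------------------
# Probability transforms
# ---------------------------------------------------------------------------

def rescale_probability(p1: float, t1: float, t2: float) -> float:
    """Convert a probability over duration ``t1`` to duration ``t2``.

    Uses the constant-rate identity r = -ln(1 - p1)/t1, p2 = 1 - exp(-r t2),
    i.e. ``1 - (1 - p1)**(t2/t1)``.  A certain event (p1 == 1, infinite rate)
    stays certain over any positive duration.
    """
    if not 0.0 <= p1 <= 1.0:
        raise ValueError(f"probability {p1!r} outside [0, 1]")
    if t1 <= 0 or t2 <= 0:
        raise ValueError("durations must be positive")
    if p1 == 1.0:
        return 1.0
    return 1.0 - (1.0 - p1) ** (t2 / t1)


def initial_distribution(
    stage_counts: Mapping[str, int] | Iterable[int],
    mapping: str = "severity",
) -> np.ndarray:
    """Normalize GOLD stage counts (II, III, IV) into a state occupancy vector.

    Only staged patients enter the model (the published stage counts do not
    sum to the randomized N); DEATH starts at 0.  ``mapping="severity"``
    assigns II->C, III->B, IV->A per the severity definitions;
    ``mapping="positional"`` assigns the stage-ordered counts to states
    A, B, C in list order (II->A, III->B, IV->C).
    """
    if isinstance(stage_counts, Mapping):
        counts = [float(stage_counts[s]) for s in _GOLD_STAGES]
    else:
        counts = [float(c) for c in stage_counts]
    if len(counts) != 3:
        raise ValueError("expected counts for GOLD stages II, III, IV")
    if any(c < 0 for c in counts):
        raise ValueError("stage counts must be non-negative")
    total = sum(counts)
    if total == 0:
        raise ValueError("all stage counts are zero")
    occ = np.zeros(len(STATES))
    if mapping == "severity":
        order = (State.C, State.B, State.A)
    elif mapping == "positional":
        order = (State.A, State.B, State.C)
    else:
        raise ValueError(f"unknown gold_state_mapping {mapping!r}")
    for stage_count, state in zip(counts, order):
        occ[STATE_INDEX[state]] = stage_count / total
    return occ


# ---------------------------------------------------------------------------
# Loading / serialization
# ---------------------------------------------------------------------------

#: Bundled configurations addressable by name.
FIXTURES = {"umec-vi-tio": "umec_vi_tio_china.yaml"}

_REQUIRED_SECTIONS = (
    "model",
    "population",
    "transitions",
    "adverse_events",
    "costs",
    "utilities",
    "exacerbations",
)


def load_fixture(name: str = "umec-vi-tio") -> ModelParameters:
    """Load a bundled configuration by name (validated)."""
    if name not in FIXTURES:
        raise ConfigurationError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        )
    ref = resources.files("copdcea.data") / FIXTURES[name]
    with ref.open("r", encoding="utf-8") as fh:
        return load_parameters(fh)


def load_parameters(source) -> ModelParameters:
    """Load and validate model parameters from YAML (path, file, or dict)."""
    if isinstance(source, Mapping):
        doc = source
    elif isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    else:  # file-like
        doc = yaml.safe_load(source)
    if not isinstance(doc, Mapping):
        raise ConfigurationError("configuration document is not a mapping")
    missing = [s for s in _REQUIRED_SECTIONS if s not in doc]
    if missing:
        raise ConfigurationError(f"missing configuration sections: {missing}")
    params = _params_from_dict(doc)
    return params.validate()


def _params_from_dict(doc: Mapping) -> ModelParameters:
    try:
        model = doc["model"]
        conv_doc = doc.get("conventions", {})
        conventions = Conventions(**conv_doc)

        transitions: dict[tuple[Arm, Phase], TransitionTable] = {}
        for arm_name, phases in doc["transitions"].items():
            arm = Arm(arm_name)
            for phase_name, rows in phases.items():
                phase = Phase(phase_name)
                probs = np.zeros((4, 4))
                counts = np.zeros((4, 4))
                probs[STATE_INDEX[State.DEATH], STATE_INDEX[State.DEATH]] = 1.0
                for src_name, dests in rows.items():
                    i = STATE_INDEX[State(src_name)]
                    for dst_name, (p, c) in dests.items():
                        j = STATE_INDEX[State(dst_name)]
                        probs[i, j] = float(p)
                        counts[i, j] = float(c)
                transitions[(arm, phase)] = TransitionTable(probs, counts)

        costs = CostInputs(
            drug={Arm(a): UniformParam(*v) for a, v in doc["costs"]["drug"].items()},
            management={
                State(s): UniformParam(*v)
                for s, v in doc["costs"]["management"].items()
            },
            adverse_event={
                k: UniformParam(*v) for k, v in doc["costs"]["adverse_event"].items()
            },
            exacerbation={
                k: UniformParam(*v) for k, v in doc["costs"]["exacerbation"].items()
            },
        )
        utilities = UtilityInputs(
            annual={State(s): BetaParam(*v) for s, v in doc["utilities"].items()}
        )
        exac = ExacerbationInputs(
            severe={
                State(s): UniformParam(*v)
                for s, v in doc["exacerbations"]["severe"].items()
            },
            nonsevere={
                State(s): UniformParam(*v)
                for s, v in doc["exacerbations"]["nonsevere"].items()
            },
        )
        ae_per_cycle: dict[Arm, dict[str, GammaParam]] = {}
        for arm_name, events in doc["adverse_events"].items():
            arm = Arm(arm_name)
            ae_per_cycle[arm] = {}
            for event, spec in events.items():
                point, shape = float(spec[0]), float(spec[1])
                scale = float(spec[2]) if len(spec) > 2 else point / shape
                ae_per_cycle[arm][event] = GammaParam(point, shape, scale)
        active = set().union(*(set(v) for v in ae_per_cycle.values()))
        inactive = tuple(sorted(set(costs.adverse_event) - active))
        adverse_events = AEInputs(per_cycle=ae_per_cycle, inactive=inactive)

        stage_counts = {
            Arm(a): {str(k): int(v) for k, v in sc.items()}
            for a, sc in doc["population"]["gold_stage_counts"].items()
        }
        occupancy = {
            arm: initial_distribution(sc, conventions.gold_state_mapping)
            for arm, sc in stage_counts.items()
        }
        initial = InitialDistribution(
            occupancy=occupancy,
            stage_counts=stage_counts,
            mapping=conventions.gold_state_mapping,
        )
    except ParameterValidationError:
        raise
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigurationError(f"malformed configuration: {exc}") from exc

    return ModelParameters(
        transitions=transitions,
        costs=costs,
        utilities=utilities,
        exacerbations=exac,
        adverse_events=adverse_events,
        initial=initial,
        horizon_cycles=int(model.get("horizon_cycles", 12)),
        cycle_years=float(model.get("cycle_years", 0.25)),
        discount_quarterly=float(model.get("discount_quarterly", 0.01)),
        wtp_per_qaly=float(model.get("wtp_per_qaly", 31554.0)),
        gdp_per_capita=model.get("gdp_per_capita"),
        conventions=conventions,
        name=str(doc.get("name", "unnamed")),
        currency=str(doc.get("currency", "USD")),
        price_year=doc.get("price_year"),
    )


def params_to_dict(params: ModelParameters) -> dict:
    """Serialize to the same document structure ``load_parameters`` reads."""
    doc: dict = {
        "name": params.name,
        "currency": params.currency,
        "price_year": params.price_year,
        "model": {
            "horizon_cycles": params.horizon_cycles,
            "cycle_years": params.cycle_years,
            "discount_quarterly": params.discount_quarterly,
            "gdp_per_capita": params.gdp_per_capita,
            "wtp_per_qaly": params.wtp_per_qaly,
        },
        "conventions": {
            "half_cycle": params.conventions.half_cycle,
            "discount_offset": params.conventions.discount_offset,
            "cycle0_accrual": params.conventions.cycle0_accrual,
            "gold_state_mapping": params.conventions.gold_state_mapping,
            "psa_shared_params": params.conventions.psa_shared_params,
            "nmb_tie_is_cost_effective": params.conventions.nmb_tie_is_cost_effective,
        },
        "population": {
            "gold_stage_counts": {
                arm.value: dict(sc) for arm, sc in params.initial.stage_counts.items()
            }
        },
        "transitions": {},
        "adverse_events": {},
        "costs": {
            "drug": {
                a.value: [p.point, p.low, p.high] for a, p in params.costs.drug.items()
            },
            "management": {
                s.value: [p.point, p.low, p.high]
                for s, p in params.costs.management.items()
            },
            "adverse_event": {
                k: [p.point, p.low, p.high]
                for k, p in params.costs.adverse_event.items()
            },
            "exacerbation": {
                k: [p.point, p.low, p.high]
                for k, p in params.costs.exacerbation.items()
            },
        },
        "utilities": {
            s.value: [p.point, p.alpha, p.beta]
            for s, p in params.utilities.annual.items()
        },
        "exacerbations": {
            "severe": {
                s.value: [p.point, p.low, p.high]
                for s, p in params.exacerbations.severe.items()
            },
            "nonsevere": {
                s.value: [p.point, p.low, p.high]
                for s, p in params.exacerbations.nonsevere.items()
            },
        },
    }
    for (arm, phase), table in params.transitions.items():
        arm_doc = doc["transitions"].setdefault(arm.value, {})
        rows = {}
        for src in ALIVE_STATES:
            i = STATE_INDEX[src]
            rows[src.value] = {
                dst.value: [
                    float(table.probs[i, STATE_INDEX[dst]]),
                    float(table.counts[i, STATE_INDEX[dst]]),
                ]
                for dst in STATES
            }
        arm_doc[phase.value] = rows
    for arm, events in params.adverse_events.per_cycle.items():
        doc["adverse_events"][arm.value] = {
            k: [g.point, g.shape] for k, g in events.items()
        }
    return doc


def params_to_yaml(params: ModelParameters) -> str:
    return yaml.safe_dump(params_to_dict(params), sort_keys=True)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def collect_validation_problems(params: ModelParameters) -> list[str]:
    """Check every invariant; return all violations (empty list = valid)."""
    out: list[str] = []
    death = STATE_INDEX[State.DEATH]

    if params.horizon_cycles < 1:
        out.append(f"horizon_cycles must be >= 1, got {params.horizon_cycles}")
    if params.wtp_per_qaly < 0:
        out.append("wtp_per_qaly must be >= 0")
    if params.discount_quarterly < 0:
        out.append("discount_quarterly must be >= 0")
    if params.conventions.discount_offset not in (0, 1):
        out.append("discount_offset must be 0 or 1")

    for arm in Arm:
        for phase in Phase:
            key = (arm, phase)
            if key not in params.transitions:
                out.append(f"missing transition table for {arm.value}/{phase.value}")
                continue
            table = params.transitions[key]
            label = f"{arm.value}/{phase.value}"
            if np.any(table.probs < 0) or np.any(table.probs > 1):
                out.append(f"transition probabilities outside [0,1] in {label}")
            if np.any(table.counts < 0):
                out.append(f"negative Dirichlet counts in {label}")
            if abs(table.probs[death, death] - 1.0) > ROW_SUM_TOL or np.any(
                np.abs(table.probs[death, :death]) > 0
            ):
                out.append(f"DEATH is not absorbing in {label}")
            for src in ALIVE_STATES:
                i = STATE_INDEX[src]
                row_sum = table.probs[i].sum()
                if abs(row_sum - 1.0) > ROW_SUM_TOL:
                    out.append(
                        f"transition row {label} {src.value} sums to {row_sum:.6f}"
                    )
                total = table.counts[i].sum()
                if total > 0:
                    dev = np.max(np.abs(table.counts[i] / total - table.probs[i]))
                    if dev > DIRICHLET_TOL:
                        out.append(
                            f"Dirichlet counts inconsistent with probabilities in "
                            f"{label} {src.value} (max deviation {dev:.2e})"
                        )
                zero_mismatch = (table.counts[i] == 0) & (table.probs[i] > 0)
                multi = (table.counts[i] > 0).sum() > 1
                if multi and np.any(zero_mismatch):
                    out.append(
                        f"structural zero with positive probability in {label} "
                        f"{src.value}"
                    )

    for label, item in _cost_items(params):
        if item.point < 0 or item.low < 0:
            out.append(f"negative cost {label}")
        if not (item.low <= item.point <= item.high):
            out.append(f"cost bounds do not bracket the point for {label}")
        if abs(item.low - 0.8 * item.point) > BOUNDS_TOL or abs(
            item.high - 1.2 * item.point
        ) > BOUNDS_TOL:
            out.append(f"cost bounds for {label} are not point*0.8/1.2")

    for s in ALIVE_STATES:
        if s not in params.utilities.annual:
            out.append(f"missing utility for state {s.value}")
    util = params.utilities.annual
    for s, bp in util.items():
        if not 0.0 <= bp.point <= 1.0:
            out.append(f"utility for {s.value} outside [0,1]")
        if bp.alpha <= 0 or bp.beta <= 0:
            out.append(f"non-positive beta parameters for utility {s.value}")
        else:
            mean = bp.alpha / (bp.alpha + bp.beta)
            if abs(mean - bp.point) > MOMENT_TOL:
                out.append(
                    f"beta mean {mean:.4f} does not match utility point "
                    f"{bp.point} for {s.value}"
                )
    if all(s in util for s in ALIVE_STATES):
        if not (
            util[State.C].point >= util[State.B].point >= util[State.A].point >= 0
        ):
            out.append("utilities are not ordered u(C) >= u(B) >= u(A) >= 0")

    for kind in ("severe", "nonsevere"):
        table = getattr(params.exacerbations, kind)
        for s, up in table.items():
            if up.point < 0:
                out.append(f"negative {kind} exacerbation count for {s.value}")
            if not (up.low <= up.point <= up.high):
                out.append(f"{kind} exacerbation bounds do not bracket {s.value}")
    sev, nsev = params.exacerbations.severe, params.exacerbations.nonsevere
    for s in ALIVE_STATES:
        if s in sev and s in nsev and sev[s].point > nsev[s].point:
            out.append(f"severe exacerbation count exceeds non-severe for {s.value}")
    for table, kind in ((sev, "severe"), (nsev, "nonsevere")):
        if all(s in table for s in ALIVE_STATES):
            if not (
                table[State.A].point >= table[State.B].point >= table[State.C].point
            ):
                out.append(f"{kind} exacerbation counts not increasing with severity")

    for arm, events in params.adverse_events.per_cycle.items():
        for event, gp in events.items():
            if not 0.0 <= gp.point <= 1.0:
                out.append(f"AE probability for {event}/{arm.value} outside [0,1]")
            if gp.shape <= 0 or gp.scale <= 0:
                out.append(f"non-positive gamma parameters for {event}/{arm.value}")
            elif abs(gp.shape * gp.scale - gp.point) > MOMENT_TOL:
                out.append(
                    f"gamma mean {gp.shape * gp.scale:.5f} does not match AE "
                    f"probability {gp.point} for {event}/{arm.value}"
                )
            if event not in params.costs.adverse_event:
                out.append(f"AE {event} has a probability but no unit cost")

    for arm, occ in params.initial.occupancy.items():
        if abs(occ.sum() - 1.0) > ROW_SUM_TOL:
            out.append(f"initial distribution for {arm.value} does not sum to 1")
        if occ[death] != 0:
            out.append(f"initial DEATH occupancy nonzero for {arm.value}")
        if np.any(occ < 0):
            out.append(f"negative initial occupancy for {arm.value}")
    return out


def _cost_items(params: ModelParameters):
    for arm, item in params.costs.drug.items():
        yield f"drug[{arm.value}]", item
    for s, item in params.costs.management.items():
        yield f"management[{s.value}]", item
    for k, item in params.costs.adverse_event.items():
        yield f"adverse_event[{k}]", item
    for k, item in params.costs.exacerbation.items():
        yield f"exacerbation[{k}]", item


# ---------------------------------------------------------------------------
# Parameter registry (shared by the one-way and probabilistic analyses)
# ---------------------------------------------------------------------------

@dataclass
class ParameterHandle:
    """Addressable scalar model input with its sampling distribution.

    ``kind`` is one of uniform/beta/gamma/dirichlet; ``shared`` marks
    health-state parameters that apply identically to both arms (utilities,
    unit costs, exacerbation counts); arm-specific handles carry their
    ``arm``.  ``set`` mutates a (caller-owned copy of a) ModelParameters;
    for Dirichlet destinations it renormalizes the remaining nonstructural
    destinations so the row stays stochastic.
    """

    id: str
    kind: str
    shared: bool
    arm: Arm | None
    point: float
    dist: tuple[float, ...]  # uniform: (low, high); beta: (a, b);
    # gamma: (shape, scale); dirichlet: (count, row_total)
    get: callable
    set: callable


def iter_parameters(params: ModelParameters) -> list[ParameterHandle]:
    """Enumerate every uncertain scalar input in a fixed, documented order.

    Order: utilities, drug costs, management costs, AE unit costs (active
    only), exacerbation unit costs, exacerbation counts, AE probabilities,
    transition-row destinations.  The order is deterministic so analyses are
    reproducible and independent of dict insertion details.
    """
    handles: list[ParameterHandle] = []

    for s in ALIVE_STATES:
        bp = params.utilities.annual[s]
        handles.append(
            ParameterHandle(
                id=f"utility[{s.value}]",
                kind="beta",
                shared=True,
                arm=None,
                point=bp.point,
                dist=(bp.alpha, bp.beta),
                get=lambda p, s=s: p.utilities.annual[s].point,
                set=lambda p, v, s=s: setattr(
                    p.utilities.annual[s], "point", float(v)
                ),
            )
        )
    for arm in Arm:
        up = params.costs.drug[arm]
        handles.append(
            ParameterHandle(
                id=f"cost.drug[{arm.value}]",
                kind="uniform",
                shared=False,
                arm=arm,
                point=up.point,
                dist=(up.low, up.high),
                get=lambda p, a=arm: p.costs.drug[a].point,
                set=lambda p, v, a=arm: setattr(p.costs.drug[a], "point", float(v)),
            )
        )
    for s in ALIVE_STATES:
        up = params.costs.management[s]
        handles.append(
            ParameterHandle(
                id=f"cost.management[{s.value}]",
                kind="uniform",
                shared=True,
                arm=None,
                point=up.point,
                dist=(up.low, up.high),
                get=lambda p, s=s: p.costs.management[s].point,
                set=lambda p, v, s=s: setattr(
                    p.costs.management[s], "point", float(v)
                ),
            )
        )
    for name in sorted(params.costs.adverse_event):
        if name in params.adverse_events.inactive:
            continue
        up = params.costs.adverse_event[name]
        handles.append(
            ParameterHandle(
                id=f"cost.adverse_event[{name}]",
                kind="uniform",
                shared=True,
                arm=None,
                point=up.point,
                dist=(up.low, up.high),
                get=lambda p, n=name: p.costs.adverse_event[n].point,
                set=lambda p, v, n=name: setattr(
                    p.costs.adverse_event[n], "point", float(v)
                ),
            )
        )
    for kind in ("severe", "nonsevere"):
        up = params.costs.exacerbation[kind]
        handles.append(
            ParameterHandle(
                id=f"cost.exacerbation[{kind}]",
                kind="uniform",
                shared=True,
                arm=None,
                point=up.point,
                dist=(up.low, up.high),
                get=lambda p, k=kind: p.costs.exacerbation[k].point,
                set=lambda p, v, k=kind: setattr(
                    p.costs.exacerbation[k], "point", float(v)
                ),
            )
        )
    for kind in ("severe", "nonsevere"):
        for s in ALIVE_STATES:
            up = getattr(params.exacerbations, kind)[s]
            handles.append(
                ParameterHandle(
                    id=f"exacerbations.{kind}[{s.value}]",
                    kind="uniform",
                    shared=True,
                    arm=None,
                    point=up.point,
                    dist=(up.low, up.high),
                    get=lambda p, k=kind, s=s: getattr(p.exacerbations, k)[s].point,
                    set=lambda p, v, k=kind, s=s: setattr(
                        getattr(p.exacerbations, k)[s], "point", float(v)
                    ),
                )
            )
    for arm in Arm:
        for event in sorted(params.adverse_events.per_cycle[arm]):
            gp = params.adverse_events.per_cycle[arm][event]
            handles.append(
                ParameterHandle(
                    id=f"ae_probability[{event}/{arm.value}]",
                    kind="gamma",
                    shared=False,
                    arm=arm,
                    point=gp.point,
                    dist=(gp.shape, gp.scale),
                    get=lambda p, a=arm, e=event: p.adverse_events.per_cycle[a][
                        e
                    ].point,
                    set=lambda p, v, a=arm, e=event: setattr(
                        p.adverse_events.per_cycle[a][e], "point", float(v)
                    ),
                )
            )
    for arm in Arm:
        for phase in Phase:
            table = params.transitions[(arm, phase)]
            for src in ALIVE_STATES:
                i = STATE_INDEX[src]
                nonzero = [
                    dst
                    for dst in STATES
                    if table.counts[i, STATE_INDEX[dst]] > 0
                ]
                if len(nonzero) < 2:
                    continue
                total = table.counts[i].sum()
                for dst in nonzero:
                    j = STATE_INDEX[dst]
                    handles.append(
                        ParameterHandle(
                            id=(
                                f"transition[{arm.value}/{phase.value}/"
                                f"{src.value}->{dst.value}]"
                            ),
                            kind="dirichlet",
                            shared=False,
                            arm=arm,
                            point=float(table.probs[i, j]),
                            dist=(float(table.counts[i, j]), float(total)),
                            get=lambda p, a=arm, ph=phase, i=i, j=j: float(
                                p.transitions[(a, ph)].probs[i, j]
                            ),
                            set=lambda p, v, a=arm, ph=phase, i=i, j=j: (
                                _set_transition_prob(p, a, ph, i, j, float(v))
                            ),
                        )
                    )
    return handles


def _set_transition_prob(params, arm, phase, i, j, value):
    """Set one destination probability, renormalizing the rest of the row.

    Structural zeros stay zero; the other nonstructural destinations are
    scaled by (1 - value) / (1 - old) so the row keeps summing to one.
    """
    probs = params.transitions[(arm, phase)].probs
    old = probs[i, j]
    if not 0.0 <= value <= 1.0:
        raise ValueError("transition probability must lie in [0, 1]")
    others = probs[i].sum() - old
    probs[i, j] = value
    if others > 0:
        mask = np.ones(len(STATES), bool)
        mask[j] = False
        probs[i, mask] = probs[i, mask] * (1.0 - value) / others
    elif value < 1.0:
        # row had all mass on j; push the remainder to DEATH
        probs[i, STATE_INDEX[State.DEATH]] += 1.0 - value
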