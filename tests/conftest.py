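import numpy as np
import pytest

from copdcea.parameters import (
    AEInputs,
    ALIVE_STATES,
    Arm,
    BetaParam,
    Conventions,
    CostInputs,
    ExacerbationInputs,
    InitialDistribution,
    ModelParameters,
    Phase,
    TransitionTable,
    UniformParam,
    UtilityInputs,
    load_fixture,
)


@pytest.fixture(scope="session")
def fixture_params():
    """The bundled published-table configuration (session-wide, read-only)."""
    return load_fixture("umec-vi-tio")


def build_params(
    matrix=None,
    matrix_new=None,
    utilities=(0.81, 0.72, 0.67),
    drug_cost=0.0,
    management=(0.0, 0.0, 0.0),
    exac_severe=(0.0, 0.0, 0.0),
    exac_nonsevere=(0.0, 0.0, 0.0),
    exac_costs=(0.0, 0.0),
    initial=(1.0, 0.0, 0.0),
    horizon=12,
    discount=0.0,
    conventions=None,
) -> ModelParameters:
    """Small fully-specified parameter set for closed-form engine checks.

    Defaults: identity transitions (nobody moves or dies), the whole cohort
    in state C, all costs zero, no discounting.
    """
    if matrix is None:
        matrix = np.eye(4)
    if matrix_new is None:
        matrix_new = matrix
    counts = np.asarray(matrix, float) * 1000.0
    counts_new = np.asarray(matrix_new, float) * 1000.0
    transitions = {
        (arm, Phase.BASE): TransitionTable(np.asarray(matrix, float).copy(),
                                           counts.copy())
        for arm in Arm
    }
    for arm in Arm:
        transitions[(arm, Phase.NEW)] = TransitionTable(
            np.asarray(matrix_new, float).copy(), counts_new.copy()
        )

    def uni(point):
        return UniformParam(point, 0.8 * point, 1.2 * point)

    occupancy = np.array([*initial, 0.0])
    params = ModelParameters(
        transitions=transitions,
        costs=CostInputs(
            drug={arm: uni(drug_cost) for arm in Arm},
            management={s: uni(v) for s, v in zip(ALIVE_STATES, management)},
            adverse_event={},
            exacerbation={"severe": uni(exac_costs[0]),
                          "nonsevere": uni(exac_costs[1])},
        ),
        utilities=UtilityInputs(
            annual={
                s: BetaParam(u, max(u, 1e-9) * 100.0, max(1.0 - u, 1e-9) * 100.0)
                for s, u in zip(ALIVE_STATES, utilities)
            }
        ),
        exacerbations=ExacerbationInputs(
            severe={s: uni(v) for s, v in zip(ALIVE_STATES, exac_severe)},
            nonsevere={s: uni(v) for s, v in zip(ALIVE_STATES, exac_nonsevere)},
        ),
        adverse_events=AEInputs(per_cycle={arm: {} for arm in Arm}),
        initial=InitialDistribution(
            occupancy={arm: occupancy.copy() for arm in Arm},
            stage_counts={arm: {"II": 1, "III": 0, "IV": 0} for arm in Arm},
        ),
        horizon_cycles=horizon,
        discount_quarterly=discount,
        conventions=conventions or Conventions(),
        name="toy",
    )
    return params.validate()


@pytest.fixture
def toy_params():
    return build_params()
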