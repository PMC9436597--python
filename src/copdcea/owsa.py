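"""One-way deterministic sensitivity analysis (tornado diagram).

Each uncertain input is moved to the ends of its range -- the 95% interval
of its sampling distribution where one exists (beta utilities, gamma AE
probabilities, Dirichlet transition rows via their marginal beta), otherwise
the +/-20% uniform bounds -- with everything else held at point values, both
arms re-run, and the chosen incremental outcome recorded.  Entries are
ranked by the absolute spread between the low and high outcome.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .markov import CEResult, compute_icer, evaluate_arm
from .parameters import Arm, ModelParameters, ParameterHandle, iter_parameters

__all__ = ["ParameterRange", "TornadoEntry", "derive_range", "run_owsa",
           "base_case", "tornado_frame"]

OUTCOMES = ("icer", "nmb", "delta_cost", "delta_qaly")


@dataclass
class ParameterRange:
    parameter: str
    low: float
    high: float
    source: str  # "ci95" or "pct20"
    clamped: bool = False


@dataclass
class TornadoEntry:
    parameter: str
    outcome_low: float | None
    outcome_high: float | None
    spread: float
    rank: int
    range: ParameterRange
    #: True when the requested outcome was undefined (zero QALY difference)
    #: at one of the extremes and the spread fell back to net monetary
    #: benefit.
    nmb_fallback: bool = False


def derive_range(handle: ParameterHandle, source: str = "preferred") -> ParameterRange:
    """Fluctuation range for one input.

    ``source="preferred"`` uses the 95% interval of the attached sampling
    distribution where one exists and +/-20% otherwise; ``source="pct20"``
    applies +/-20% to everything (the variant that reproduces the published
    tornado ordering).  Probability-valued ranges are clamped to [0, 1] and
    flagged.
    """
    clamped = False
    if source == "pct20":
        lo, hi = 0.8 * handle.point, 1.2 * handle.point
        if handle.kind in ("beta", "gamma", "dirichlet"):
            if hi > 1:
                clamped = True
            lo, hi = max(lo, 0.0), min(hi, 1.0)
        return ParameterRange(handle.id, float(lo), float(hi), "pct20", clamped)
    if source != "preferred":
        raise ValueError(f"unknown range source {source!r}")
    if handle.kind == "beta":
        a, b = handle.dist
        lo, hi = stats.beta.ppf([0.025, 0.975], a, b)
        source = "ci95"
    elif handle.kind == "gamma":
        shape, scale = handle.dist
        lo, hi = stats.gamma.ppf([0.025, 0.975], shape, scale=scale)
        source = "ci95"
    elif handle.kind == "dirichlet":
        count, total = handle.dist
        # marginal of one Dirichlet coordinate is beta(count, total - count)
        lo, hi = stats.beta.ppf([0.025, 0.975], count, total - count)
        source = "ci95"
    else:  # uniform bounds, the +/-20% rule
        lo, hi = handle.dist
        source = "pct20"
    if handle.kind in ("beta", "gamma", "dirichlet"):
        if lo < 0 or hi > 1:
            clamped = True
        lo, hi = max(lo, 0.0), min(hi, 1.0)
    return ParameterRange(handle.id, float(lo), float(hi), source, clamped)


def base_case(params: ModelParameters) -> CEResult:
    """Deterministic incremental result at point values (UMEC/VI vs TIO)."""
    return compute_icer(
        evaluate_arm(params, Arm.UMEC_VI),
        evaluate_arm(params, Arm.TIO),
        params.wtp_per_qaly,
    )


def _outcome(result: CEResult, outcome: str) -> float | None:
    if outcome == "icer":
        return result.icer
    if outcome == "nmb":
        return result.nmb_at_wtp
    if outcome == "delta_cost":
        return result.delta_cost
    if outcome == "delta_qaly":
        return result.delta_qaly
    raise ValueError(f"unknown outcome {outcome!r}; choose from {OUTCOMES}")


def run_owsa(
    params: ModelParameters,
    outcome: str = "icer",
    top_n: int | None = 10,
    range_source: str = "preferred",
    include_transitions: bool = True,
) -> list[TornadoEntry]:
    """Rank inputs by the spread of ``outcome`` over their ranges.

    Returns the ``top_n`` most sensitive entries (all of them when
    ``top_n`` is None or exceeds the parameter count), sorted by
    non-increasing spread with ties broken by parameter identifier.  If a
    perturbed run leaves the ICER undefined the entry's spread falls back
    to the net-monetary-benefit spread and is flagged.

    ``range_source`` and ``include_transitions`` select between the stated
    range rule (95% CI preferred, transitions perturbed per destination) and
    the variant that reproduces the published tornado (+/-20% everywhere,
    transition rows held fixed).
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}; choose from {OUTCOMES}")
    entries: list[TornadoEntry] = []
    for handle in iter_parameters(params):
        if not include_transitions and handle.kind == "dirichlet":
            continue
        rng = derive_range(handle, range_source)
        results = []
        for value in (rng.low, rng.high):
            perturbed = params.copy()
            # re-bind the handle on the copy (closures capture indices only)
            handle.set(perturbed, value)
            results.append(base_case(perturbed))
        lo_out = _outcome(results[0], outcome)
        hi_out = _outcome(results[1], outcome)
        fallback = False
        if outcome == "icer" and (lo_out is None or hi_out is None):
            lo_out = _outcome(results[0], "nmb")
            hi_out = _outcome(results[1], "nmb")
            fallback = True
        spread = abs(hi_out - lo_out)
        entries.append(
            TornadoEntry(
                parameter=handle.id,
                outcome_low=lo_out,
                outcome_high=hi_out,
                spread=spread,
                rank=0,
                range=rng,
                nmb_fallback=fallback,
            )
        )
    entries.sort(key=lambda e: (-e.spread, e.parameter))
    for i, e in enumerate(entries, start=1):
        e.rank = i
    if top_n is not None:
        entries = entries[: max(int(top_n), 0)]
    return entries


def tornado_frame(entries: list[TornadoEntry]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "range_low": e.range.low,
                "range_high": e.range.high,
                "range_source": e.range.source,
                "outcome_low": e.outcome_low,
                "outcome_high": e.outcome_high,
                "spread": e.spread,
                "rank": e.rank,
                "nmb_fallback": e.nmb_fallback,
            }
            for e in entries
        ]
    )
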