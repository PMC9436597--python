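"""Two-arm meta-analysis: relative risks, heterogeneity, DL pooling.

Binary outcomes are pooled on the log relative-risk scale with
inverse-variance weights (fixed effect) or DerSimonian-Laird random effects;
continuous outcomes (mean, SD, n per arm) are pooled as mean differences
through the same machinery.  Heterogeneity is summarized by Cochran's Q,
I-squared and the DL tau-squared, and the model-selection rule picks random
effects when the heterogeneity P value is below 0.1 or I-squared exceeds
50%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TwoByTwoStudy",
    "ContinuousStudy",
    "EffectEstimate",
    "PooledResult",
    "study_effect",
    "continuous_effect",
    "pool_fixed",
    "pool_random",
    "select_model",
    "pool_auto",
    "read_studies",
    "forest_frame",
]

Z95 = stats.norm.ppf(0.975)


@dataclass
class TwoByTwoStudy:
    """Events/totals per arm of one trial (arm 1 = intervention)."""

    study_id: str
    events_1: int
    total_1: int
    events_2: int
    total_2: int

    def __post_init__(self):
        for events, total, arm in (
            (self.events_1, self.total_1, 1),
            (self.events_2, self.total_2, 2),
        ):
            if total < 1:
                raise ValueError(f"{self.study_id}: arm {arm} total must be >= 1")
            if not 0 <= events <= total:
                raise ValueError(
                    f"{self.study_id}: arm {arm} events outside [0, total]"
                )


@dataclass
class ContinuousStudy:
    """Per-arm mean/SD/n for a continuous endpoint (pooled as mean diff)."""

    study_id: str
    mean_1: float
    sd_1: float
    n_1: int
    mean_2: float
    sd_2: float
    n_2: int

    def __post_init__(self):
        if self.n_1 < 2 or self.n_2 < 2:
            raise ValueError(f"{self.study_id}: each arm needs n >= 2")
        if self.sd_1 <= 0 or self.sd_2 <= 0:
            raise ValueError(f"{self.study_id}: SDs must be positive")


@dataclass
class EffectEstimate:
    study_id: str
    effect: float  # log RR or mean difference
    se: float
    scale: str  # "log_rr" or "mean_difference"
    continuity_corrected: bool = False


@dataclass
class PooledResult:
    estimate: float  # natural scale: RR, or mean difference
    ci_low: float
    ci_high: float
    q: float
    df: int
    i2: float  # percent
    tau2: float
    p_heterogeneity: float
    model: str  # "fixed" or "random"
    scale: str
    weights: np.ndarray  # normalized weights per study


def study_effect(study: TwoByTwoStudy, correct_zero: bool = True) -> EffectEstimate:
    """Log relative risk and its delta-method standard error.

    If any cell (events or non-events) of either arm is zero, 0.5 is added
    to all four cells of that study and the estimate is flagged.
    """
    a, n1 = float(study.events_1), float(study.total_1)
    c, n2 = float(study.events_2), float(study.total_2)
    corrected = False
    if min(a, n1 - a, c, n2 - c) == 0:
        if not correct_zero:
            raise ValueError(
                f"{study.study_id}: zero cell with continuity correction disabled"
            )
        a, c = a + 0.5, c + 0.5
        n1, n2 = n1 + 1.0, n2 + 1.0
        corrected = True
    log_rr = math.log((a / n1) / (c / n2))
    se = math.sqrt(1.0 / a - 1.0 / n1 + 1.0 / c - 1.0 / n2)
    return EffectEstimate(study.study_id, log_rr, se, "log_rr", corrected)


def continuous_effect(study: ContinuousStudy) -> EffectEstimate:
    """Raw mean difference (arm 1 minus arm 2) with its standard error."""
    diff = study.mean_1 - study.mean_2
    se = math.sqrt(study.sd_1**2 / study.n_1 + study.sd_2**2 / study.n_2)
    return EffectEstimate(study.study_id, diff, se, "mean_difference")


def _heterogeneity(effects, weights, pooled):
    q = float(sum(w * (e.effect - pooled) ** 2 for e, w in zip(effects, weights)))
    df = len(effects) - 1
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    p = float(stats.chi2.sf(q, df)) if df > 0 else 1.0
    return q, df, i2, p


def _finish(effects, weights, tau2, model) -> PooledResult:
    w = np.asarray(weights, float)
    pooled = float(np.sum(w * [e.effect for e in effects]) / w.sum())
    se = 1.0 / math.sqrt(w.sum())
    # heterogeneity is always reported from the fixed-effect weights
    w_fixed = np.array([1.0 / e.se**2 for e in effects])
    pooled_fixed = float(np.sum(w_fixed * [e.effect for e in effects]) / w_fixed.sum())
    q, df, i2, p = _heterogeneity(effects, w_fixed, pooled_fixed)
    scale = effects[0].scale
    lo, hi = pooled - Z95 * se, pooled + Z95 * se
    if scale == "log_rr":
        est, lo, hi = math.exp(pooled), math.exp(lo), math.exp(hi)
    else:
        est = pooled
    return PooledResult(
        estimate=est,
        ci_low=lo,
        ci_high=hi,
        q=q,
        df=df,
        i2=i2,
        tau2=tau2,
        p_heterogeneity=p,
        model=model,
        scale=scale,
        weights=w / w.sum(),
    )


def _check_effects(effects):
    if not effects:
        raise ValueError("no effect estimates to pool")
    scales = {e.scale for e in effects}
    if len(scales) > 1:
        raise ValueError(f"mixed effect scales {scales}")
    if any(e.se <= 0 for e in effects):
        raise ValueError("standard errors must be positive")


def pool_fixed(effects: list[EffectEstimate]) -> PooledResult:
    """Inverse-variance fixed-effect pooling."""
    _check_effects(effects)
    weights = [1.0 / e.se**2 for e in effects]
    return _finish(effects, weights, tau2=0.0, model="fixed")


def pool_random(effects: list[EffectEstimate]) -> PooledResult:
    """DerSimonian-Laird random-effects pooling.

    tau^2 = max(0, (Q - df) / (sum w - sum w^2 / sum w)) with fixed-effect
    weights w; the pooled estimate then uses weights 1 / (se^2 + tau^2).
    When Q <= df the estimator collapses onto the fixed-effect result.
    """
    _check_effects(effects)
    w = np.array([1.0 / e.se**2 for e in effects])
    pooled_fixed = float(np.sum(w * [e.effect for e in effects]) / w.sum())
    q, df, _, _ = _heterogeneity(effects, w, pooled_fixed)
    denom = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    weights = [1.0 / (e.se**2 + tau2) for e in effects]
    return _finish(effects, weights, tau2=tau2, model="random")


def select_model(pooled_fixed: PooledResult) -> str:
    """Heterogeneity rule: random iff P < 0.1 or I^2 > 50% (fixed if df=0)."""
    if pooled_fixed.df == 0:
        return "fixed"
    if pooled_fixed.p_heterogeneity < 0.1 or pooled_fixed.i2 > 50.0:
        return "random"
    return "fixed"


def pool_auto(effects: list[EffectEstimate]) -> PooledResult:
    """Pool under the model chosen by the heterogeneity rule."""
    fixed = pool_fixed(effects)
    return pool_random(effects) if select_model(fixed) == "random" else fixed


_BINARY_COLS = ["study_id", "events_1", "total_1", "events_2", "total_2"]
_CONT_COLS = ["study_id", "mean_1", "sd_1", "n_1", "mean_2", "sd_2", "n_2"]


def read_studies(path) -> list[TwoByTwoStudy] | list[ContinuousStudy]:
    """Read a delimited study table (header mandatory, binary or continuous)."""
    frame = pd.read_csv(path)
    cols = list(frame.columns)
    if all(c in cols for c in _BINARY_COLS):
        cls, fields = TwoByTwoStudy, _BINARY_COLS
    elif all(c in cols for c in _CONT_COLS):
        cls, fields = ContinuousStudy, _CONT_COLS
    else:
        raise ValueError(
            f"study table must have columns {_BINARY_COLS} or {_CONT_COLS}"
        )
    studies = []
    for idx, row in frame.iterrows():
        try:
            values = [row[f] for f in fields]
            studies.append(cls(str(values[0]), *[_num(v) for v in values[1:]]))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed study row {idx} ({row['study_id']}): {exc}")
    return studies


def _num(v):
    f = float(v)
    return int(f) if f == int(f) else f


def forest_frame(effects: list[EffectEstimate], pooled: PooledResult) -> pd.DataFrame:
    """Per-study effects with CIs and normalized pooled weights."""
    rows = []
    for e, w in zip(effects, pooled.weights):
        lo, hi = e.effect - Z95 * e.se, e.effect + Z95 * e.se
        if e.scale == "log_rr":
            est, lo, hi = math.exp(e.effect), math.exp(lo), math.exp(hi)
        else:
            est = e.effect
        rows.append(
            {
                "study_id": e.study_id,
                "estimate": est,
                "ci_low": lo,
                "ci_high": hi,
                "weight": float(w),
                "continuity_corrected": e.continuity_corrected,
            }
        )
    rows.append(
        {
            "study_id": f"pooled ({pooled.model})",
            "estimate": pooled.estimate,
            "ci_low": pooled.ci_low,
            "ci_high": pooled.ci_high,
            "weight": 1.0,
            "continuity_corrected": False,
        }
    )
    return pd.DataFrame(rows)
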