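"""Per-trial effect estimation and fixed-/random-effects pooling.

Binary-outcome two-arm trials are summarised as 2x2 tables and combined by
inverse-variance weighting, either under a common-effect (fixed) model or
under the DerSimonian-Laird random-effects model.  Besides Cochran's Q, the
inconsistency I^2 and the diversity D^2 are reported; diversity is the
relative variance inflation of the random-effects model, ``1 - v_F/v_R``,
and is never smaller than I^2.  D^2 is the heterogeneity measure that feeds
the required-information-size adjustment in :mod:`tsakit.information`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import norm

__all__ = [
    "TrialRecord",
    "EffectEstimate",
    "PooledResult",
    "trial_effect",
    "pool",
    "MEASURES",
    "MODELS",
]

MEASURES = ("odds_ratio", "risk_ratio", "risk_difference")
MODELS = ("fixed", "random_DL")

#: two-sided 95% normal quantile, used for naive confidence intervals and the
#: conventional test boundary
Z_CONVENTIONAL = float(norm.ppf(0.975))


@dataclass(frozen=True)
class TrialRecord:
    """One completed two-arm trial's binary-outcome 2x2 summary.

    ``order`` is the chronological rank of the trial; cumulative
    meta-analysis adds trials in increasing ``order``.
    """

    label: str
    order: int
    events_exp: int
    total_exp: int
    events_ctl: int
    total_ctl: int

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError(f"trial {self.label!r}: order must be a positive integer")
        if self.total_exp < 1 or self.total_ctl < 1:
            raise ValueError(f"trial {self.label!r}: arm totals must be >= 1")
        if not (0 <= self.events_exp <= self.total_exp):
            raise ValueError(
                f"trial {self.label!r}: events_exp={self.events_exp} outside "
                f"[0, {self.total_exp}]"
            )
        if not (0 <= self.events_ctl <= self.total_ctl):
            raise ValueError(
                f"trial {self.label!r}: events_ctl={self.events_ctl} outside "
                f"[0, {self.total_ctl}]"
            )

    @property
    def participants(self) -> int:
        """Total randomised participants (both arms)."""
        return self.total_exp + self.total_ctl


@dataclass(frozen=True)
class EffectEstimate:
    """A single trial's effect estimate with its standard error.

    ``point`` is on the log scale for ratio measures and on the natural
    (probability-difference) scale for the risk difference.  ``corrected``
    records whether a continuity correction was applied.
    """

    measure: str
    point: float
    se: float
    corrected: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise ValueError(f"unknown effect measure {self.measure!r}")
        if not (self.se > 0) or not math.isfinite(self.se):
            raise ValueError("standard error must be a positive finite number")


@dataclass(frozen=True)
class PooledResult:
    """Pooled effect with heterogeneity statistics.

    ``theta`` is on the same scale as the input effects (log scale for
    ratios).  ``var_fixed``/``var_random`` are the variances of the pooled
    estimate under the two models; ``z`` uses the variance of the requested
    model.  ``naive_ci`` is the conventional 95% interval on the effect
    scale (exponentiated for ratio measures).
    """

    model: str
    measure: str
    theta: float
    var_fixed: float
    var_random: float
    tau2: float
    Q: float
    I2: float
    D2: float
    k: int
    z: float
    naive_ci: tuple[float, float]

    @property
    def variance(self) -> float:
        return self.var_random if self.model == "random_DL" else self.var_fixed

    @property
    def se(self) -> float:
        return math.sqrt(self.variance)

    @property
    def effect(self) -> float:
        """Pooled effect on the reporting scale (OR/RR for ratio measures)."""
        return to_effect_scale(self.theta, self.measure)


def to_effect_scale(x: float, measure: str) -> float:
    return math.exp(x) if measure in ("odds_ratio", "risk_ratio") else x


def _corrected_cells(trial: TrialRecord, correction: bool) -> tuple[float, float, float, float, bool]:
    a = float(trial.events_exp)
    b = float(trial.total_exp - trial.events_exp)
    c = float(trial.events_ctl)
    d = float(trial.total_ctl - trial.events_ctl)
    if correction and 0.0 in (a, b, c, d):
        return a + 0.5, b + 0.5, c + 0.5, d + 0.5, True
    return a, b, c, d, False


def trial_effect(
    trial: TrialRecord,
    measure: str = "odds_ratio",
    correction: bool = True,
) -> EffectEstimate:
    """Estimate a single trial's effect from its 2x2 table.

    Parameters
    ----------
    trial:
        The trial summary.
    measure:
        ``odds_ratio`` (default, log scale), ``risk_ratio`` (log scale) or
        ``risk_difference`` (natural scale).
    correction:
        Apply the constant-0.5 continuity correction to all four cells when
        any cell is zero.  With the correction disabled, tables with a zero
        cell in a ratio measure (or double-zero/double-full tables for the
        risk difference) are inestimable and rejected.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown effect measure {measure!r}")
    a, b, c, d, corrected = _corrected_cells(trial, correction)
    if measure == "odds_ratio":
        if 0.0 in (a, b, c, d):
            raise ValueError(f"trial {trial.label!r}: inestimable effect (zero cell, correction off)")
        point = math.log(a * d / (b * c))
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    elif measure == "risk_ratio":
        if a == 0.0 or c == 0.0:
            raise ValueError(f"trial {trial.label!r}: inestimable effect (zero cell, correction off)")
        n1, n2 = a + b, c + d
        point = math.log((a / n1) / (c / n2))
        se = math.sqrt(1 / a - 1 / n1 + 1 / c - 1 / n2)
    else:  # risk_difference
        n1, n2 = a + b, c + d
        p1, p2 = a / n1, c / n2
        var = p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2
        if var <= 0:
            raise ValueError(f"trial {trial.label!r}: inestimable effect (degenerate arms, correction off)")
        point = p1 - p2
        se = math.sqrt(var)
    return EffectEstimate(measure=measure, point=point, se=se, corrected=corrected, label=trial.label)


def pool(effects: Sequence[EffectEstimate], model: str = "random_DL") -> PooledResult:
    """Pool trial effects by inverse-variance weighting.

    Fixed model: weights ``1/se^2``.  DerSimonian-Laird random-effects
    model: the between-trial variance tau^2 is the moment estimator
    ``max(0, (Q - (k-1)) / (sum(w) - sum(w^2)/sum(w)))`` with Q computed
    about the fixed-effect mean, and random weights ``1/(se^2 + tau^2)``.

    I^2 is ``max(0, (Q - (k-1))/Q)`` (0 when Q == 0 or k == 1) and diversity
    is ``D^2 = 1 - v_F/v_R``.  With one trial both are defined as 0 so the
    sequential machinery runs from the first look.
    """
    if model not in MODELS:
        raise ValueError(f"unknown pooling model {model!r}")
    effects = list(effects)
    k = len(effects)
    if k == 0:
        raise ValueError("empty meta-analysis")
    measures = {e.measure for e in effects}
    if len(measures) > 1:
        raise ValueError(f"cannot pool mixed effect measures {sorted(measures)}")
    measure = effects[0].measure

    theta_i = np.array([e.point for e in effects])
    w = 1.0 / np.array([e.se for e in effects]) ** 2

    sw = w.sum()
    theta_fixed = float((w * theta_i).sum() / sw)
    var_fixed = float(1.0 / sw)

    if k == 1:
        Q = 0.0
        tau2 = 0.0
    else:
        Q = float((w * (theta_i - theta_fixed) ** 2).sum())
        denom = sw - (w**2).sum() / sw
        tau2 = max(0.0, (Q - (k - 1)) / denom)

    wr = 1.0 / (np.array([e.se for e in effects]) ** 2 + tau2)
    theta_random = float((wr * theta_i).sum() / wr.sum())
    var_random = float(1.0 / wr.sum())

    I2 = max(0.0, (Q - (k - 1)) / Q) if (k > 1 and Q > 0) else 0.0
    D2 = max(0.0, 1.0 - var_fixed / var_random)

    if model == "fixed":
        theta, var = theta_fixed, var_fixed
    else:
        theta, var = theta_random, var_random
    z = theta / math.sqrt(var)
    half = Z_CONVENTIONAL * math.sqrt(var)
    naive_ci = (to_effect_scale(theta - half, measure), to_effect_scale(theta + half, measure))

    return PooledResult(
        model=model,
        measure=measure,
        theta=theta,
        var_fixed=var_fixed,
        var_random=var_random,
        tau2=tau2,
        Q=Q,
        I2=I2,
        D2=D2,
        k=k,
        z=z,
        naive_ci=naive_ci,
    )
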