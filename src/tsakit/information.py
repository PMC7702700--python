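"""Sample size and heterogeneity-adjusted required information size (RIS).

The required information size is the meta-analytic analogue of a single
trial's sample size: the number of randomised participants a cumulative
meta-analysis needs in order to detect (or reject) an anticipated difference
between two event proportions at a given two-sided type-I error and power.
Between-trial heterogeneity dilutes information, so the fixed-model size is
inflated by ``1/(1 - D^2)`` where D^2 is the diversity of the current
meta-analysis (or a user-supplied sensitivity value).

Information is measured in participants throughout: accrued information is
the running total of randomised participants, and the information fraction
``t`` (the time axis of the sequential design) is accrued / RIS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from scipy.stats import norm

from .meta import TrialRecord

__all__ = [
    "DesignSpec",
    "InformationState",
    "conventional_sample_size",
    "required_information_size",
    "accrue",
]


@dataclass(frozen=True)
class DesignSpec:
    """Design assumptions that define the required information size.

    Parameters
    ----------
    alpha:
        Two-sided maximum type-I error risk.
    power:
        1 - beta, the probability of detecting the anticipated difference.
    p_ctl, p_exp:
        Anticipated event proportions in the control and experimental arms.
        Their absolute difference is the minimally important effect.
    d2_override:
        Optional diversity value in [0, 1) used instead of the empirical D^2
        (sensitivity analysis with assumed heterogeneity).
    allocation:
        Randomisation ratio experimental:control.  Only 1:1 designs are
        supported; the field is validated so configs are explicit.
    """

    p_ctl: float
    p_exp: float
    alpha: float = 0.05
    power: float = 0.90
    d2_override: Optional[float] = None
    allocation: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if not (0 < self.power < 1):
            raise ValueError("power must lie in (0, 1)")
        for name in ("p_ctl", "p_exp"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.p_ctl == self.p_exp:
            raise ValueError("zero effect, sample size undefined (p_exp == p_ctl)")
        if self.d2_override is not None and not (0 <= self.d2_override < 1):
            raise ValueError("d2_override must lie in [0, 1)")
        if self.allocation != 1.0:
            raise ValueError("only 1:1 allocation is supported")

    @property
    def beta(self) -> float:
        return 1.0 - self.power

    @property
    def delta(self) -> float:
        """Anticipated absolute risk difference."""
        return self.p_exp - self.p_ctl

    @property
    def drift(self) -> float:
        """Design drift theta* = z_{1-alpha/2} + z_{1-beta}.

        The expected z-score of the design alternative at full information
        (t = 1); it parameterises the futility wedge.
        """
        return float(norm.ppf(1 - self.alpha / 2) + norm.ppf(self.power))


@dataclass(frozen=True)
class InformationState:
    """Accrued participants relative to the required information size."""

    ris: int
    accrued: int
    fractions: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.ris < 1:
            raise ValueError("ris must be a positive participant count")
        if any(b <= a for a, b in zip(self.fractions, self.fractions[1:])):
            raise ValueError("information fractions must be strictly increasing")


def conventional_sample_size(design: DesignSpec) -> int:
    """Total sample size of a single two-arm superiority trial.

    Standard two-proportion formula with pooled variance under the null:

    ``n_per_group = (z_{1-a/2} sqrt(2 pbar qbar) + z_{1-b} sqrt(p1 q1 + p2 q2))^2 / delta^2``

    with ``pbar = (p_exp + p_ctl)/2``.  The per-group size is ceiled and
    doubled (1:1 allocation); ceiling rather than rounding so the trial is
    never under-powered by truncation.
    """
    za = norm.ppf(1 - design.alpha / 2)
    zb = norm.ppf(design.power)
    p1, p2 = design.p_exp, design.p_ctl
    pbar = (p1 + p2) / 2
    num = za * math.sqrt(2 * pbar * (1 - pbar)) + zb * math.sqrt(p1 * (1 - p1) + p2 * (1 - p2))
    n_per_group = (num / (p1 - p2)) ** 2
    return 2 * math.ceil(n_per_group)


def required_information_size(design: DesignSpec, d2: float = 0.0) -> int:
    """Heterogeneity-adjusted required information size, in participants.

    The fixed-model information size is

    ``IS = 4 (z_{1-a/2} + z_{1-b})^2 pbar (1 - pbar) / delta^2``

    and the RIS divides it by ``(1 - D^2)`` before ceiling.  ``d2`` is the
    diversity of the current meta-analysis; ``design.d2_override`` takes
    precedence when set.
    """
    if design.d2_override is not None:
        d2 = design.d2_override
    if not (0 <= d2 < 1):
        raise ValueError("diversity adjustment undefined (need 0 <= D2 < 1)")
    za = norm.ppf(1 - design.alpha / 2)
    zb = norm.ppf(design.power)
    pbar = (design.p_exp + design.p_ctl) / 2
    fixed_is = 4 * (za + zb) ** 2 * pbar * (1 - pbar) / design.delta**2
    return math.ceil(fixed_is / (1 - d2))


def accrue(
    trials: Sequence[TrialRecord],
    ris: int,
    accrued_override: Optional[int] = None,
) -> InformationState:
    """Cumulative accrued participants and information fractions.

    ``accrued_override`` replaces the final cumulative total (e.g. analysed
    rather than randomised participants); interim totals keep the randomised
    running sums.  Fractions may exceed 1 when the RIS has been surpassed.
    """
    if ris < 1:
        raise ValueError("ris must be a positive participant count")
    cum: list[int] = []
    total = 0
    for tr in sorted(trials, key=lambda t: t.order):
        total += tr.participants
        cum.append(total)
    if accrued_override is not None:
        if not cum:
            raise ValueError("accrued_override needs at least one trial")
        if accrued_override <= (cum[-2] if len(cum) > 1 else 0):
            raise ValueError("accrued_override must exceed the previous cumulative total")
        cum[-1] = int(accrued_override)
    fractions = tuple(c / ris for c in cum)
    accrued = cum[-1] if cum else 0
    return InformationState(ris=int(ris), accrued=accrued, fractions=fractions)
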