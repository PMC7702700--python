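"""Cumulative z-curve, look classification, and adjusted confidence intervals.

Trials are added in chronological order; after each addition the
meta-analysis is re-pooled, the cumulative z-score is compared against the
monitoring boundaries solved on the realised look schedule, and the look is
classified.  When the required information size has not been reached, the
conventional 95% interval under-covers, so a repeated confidence interval is
reported alongside it: the fixed-sample critical value is replaced by the
current look's efficacy boundary, widening the interval by exactly
``boundary_z / z_0.975``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .boundaries import BoundarySet, SpendingSpec, efficacy_boundaries, futility_boundaries
from .information import DesignSpec, accrue, required_information_size
from .meta import (
    PooledResult,
    TrialRecord,
    Z_CONVENTIONAL,
    pool,
    to_effect_scale,
    trial_effect,
)

__all__ = ["Look", "SequentialResult", "run_sequential", "adjusted_ci", "CLASSIFICATIONS"]

CLASSIFICATIONS = (
    "efficacy_crossed",
    "futility_crossed",
    "conventional_only",
    "continue",
    "information_reached",
)


@dataclass(frozen=True)
class Look:
    """One interim analysis of the cumulative meta-analysis."""

    index: int
    trial_label: str
    t: float
    z: float
    pooled: PooledResult
    efficacy_z: float
    futility_z: Optional[float]
    classification: str
    ris: int
    accrued: int
    alpha_spent: float
    beta_spent: Optional[float] = None


@dataclass(frozen=True)
class SequentialResult:
    """Full trial sequential analysis of an ordered trial sequence."""

    looks: tuple[Look, ...]
    ris: int
    final_pooled: PooledResult
    naive_ci: tuple[float, float]
    adjusted_ci: tuple[float, float]
    verdict: str
    design: DesignSpec
    measure: str

    @property
    def final_look(self) -> Look:
        return self.looks[-1]


def adjusted_ci(
    theta: float,
    se: float,
    boundary_z: float,
    measure: str = "odds_ratio",
) -> tuple[float, float]:
    """Repeated confidence interval at the current look.

    ``exp(theta +/- boundary_z * se)`` for ratio measures (the natural scale
    for the risk difference).  With ``boundary_z`` equal to the fixed-sample
    critical value this is the conventional 95% interval; before the
    required information size is reached the boundary exceeds 1.96 and the
    interval is strictly wider, restoring honest coverage under repeated
    looking.
    """
    if se <= 0:
        raise ValueError("invalid standard error (need se > 0)")
    if boundary_z < Z_CONVENTIONAL - 1e-9:
        raise ValueError("boundary_z below the fixed-sample critical value")
    half = boundary_z * se
    return (to_effect_scale(theta - half, measure), to_effect_scale(theta + half, measure))


def _classify(z: float, eff: float, fut: Optional[float], t: float) -> str:
    if abs(z) >= eff:
        return "efficacy_crossed"
    if t >= 1.0:
        return "information_reached"
    if fut is not None and fut > 0 and abs(z) < fut:
        return "futility_crossed"
    if abs(z) >= Z_CONVENTIONAL:
        return "conventional_only"
    return "continue"


def run_sequential(
    trials: Sequence[TrialRecord],
    design: DesignSpec,
    accrued_override: Optional[int] = None,
    measure: str = "odds_ratio",
    model: str = "random_DL",
    spending: Optional[SpendingSpec] = None,
    with_futility: bool = True,
    freeze_d2: bool = False,
    grid: int = 2001,
) -> SequentialResult:
    """Run a trial sequential analysis over chronologically ordered trials.

    At each look ``j`` the first ``j`` trials are pooled (DerSimonian-Laird
    random effects by default); the diversity D^2 of that cumulative
    meta-analysis (or ``design.d2_override``) determines the current
    required information size, earlier accrual totals are re-expressed as
    fractions of that single scale, and the spending boundaries are solved
    on the realised schedule.  Looks at or beyond full information use the
    fixed-sample critical value.

    Parameters
    ----------
    accrued_override:
        Replace the final cumulative participant total (e.g. analysed
        rather than randomised participants).
    freeze_d2:
        Compute D^2 once from the complete trial list and use it at every
        look, instead of re-estimating as each trial is added.
    """
    trials = sorted(trials, key=lambda tr: tr.order)
    if not trials:
        raise ValueError("nothing to analyse (empty trial list)")
    spending = spending or SpendingSpec(total_error=design.alpha)
    if not math.isclose(spending.total_error, design.alpha):
        raise ValueError("spending total_error must equal the design alpha")

    frozen_d2: Optional[float] = None
    if freeze_d2:
        effects_all = [trial_effect(tr, measure) for tr in trials]
        frozen_d2 = pool(effects_all, model).D2

    looks: list[Look] = []
    pooled: Optional[PooledResult] = None
    for j in range(1, len(trials) + 1):
        effects = [trial_effect(tr, measure) for tr in trials[:j]]
        pooled = pool(effects, model)
        d2 = frozen_d2 if frozen_d2 is not None else pooled.D2
        ris = required_information_size(design, d2)
        state = accrue(
            trials[:j],
            ris,
            accrued_override if j == len(trials) else None,
        )
        fractions = state.fractions

        # schedule for the solver: strictly increasing, clamped at 1;
        # looks past the first full-information look use the fixed-sample value
        solver_idx = []
        for i, f in enumerate(fractions):
            solver_idx.append(i)
            if f >= 1.0:
                break
        sched = [min(fractions[i], 1.0) for i in solver_idx]
        if with_futility:
            bset = futility_boundaries(
                sched, spending, beta=design.beta, drift=design.drift, grid=grid
            )
        else:
            bset = efficacy_boundaries(sched, spending, grid=grid)

        i = j - 1
        if i < len(sched):
            eff_z = bset.efficacy_z[i]
            fut_z = bset.displayed_futility()[i]
            a_sp = bset.alpha_spent[i]
            b_sp = bset.beta_spent[i] if bset.beta_spent is not None else None
        else:  # information size surpassed at an earlier look
            eff_z = Z_CONVENTIONAL
            fut_z = None
            a_sp = design.alpha
            b_sp = design.beta if with_futility else None

        t_j = fractions[i]
        if t_j >= 1.0:
            eff_z = Z_CONVENTIONAL
        looks.append(
            Look(
                index=j,
                trial_label=trials[i].label,
                t=t_j,
                z=pooled.z,
                pooled=pooled,
                efficacy_z=float(eff_z),
                futility_z=fut_z,
                classification=_classify(pooled.z, float(eff_z), fut_z, t_j),
                ris=ris,
                accrued=state.accrued,
                alpha_spent=float(a_sp),
                beta_spent=float(b_sp) if b_sp is not None else None,
            )
        )

    assert pooled is not None
    final = looks[-1]
    # as a sequential decision, crossing only the conventional 1.96 threshold
    # is not decisive: further information is required
    verdict = "continue" if final.classification == "conventional_only" else final.classification
    adj = adjusted_ci(pooled.theta, pooled.se, max(final.efficacy_z, Z_CONVENTIONAL), measure)
    return SequentialResult(
        looks=tuple(looks),
        ris=final.ris,
        final_pooled=pooled,
        naive_ci=pooled.naive_ci,
        adjusted_ci=adj,
        verdict=verdict,
        design=design,
        measure=measure,
    )
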