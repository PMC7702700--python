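"""Sample-size planning for future trials from an existing meta-analysis.

The participants still needed to settle an intervention's effect are the gap
between the heterogeneity-adjusted required information size and the
participants already randomised into completed trials.  A conservative
variant excludes the trial whose data informed the design effect (it is used
twice otherwise: once to set the anticipated effect, once as evidence),
widening the gap by that trial's size.  A projection facility appends a
hypothetical future trial and reruns the sequential analysis to show how its
outcome would change the verdict and the remaining requirement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .information import DesignSpec, required_information_size
from .meta import TrialRecord, pool, trial_effect
from .sequential import SequentialResult, run_sequential

__all__ = ["PlanResult", "plan_next_trials", "plan_from_information", "project_scenario"]

NOTE_SURPASSED = "information size surpassed"


@dataclass(frozen=True)
class PlanResult:
    """Additional participants required for one or more future trials.

    ``per_arm`` is the 1:1 per-arm allocation, the ceiling of half the
    total; ``2 * per_arm`` may therefore exceed ``additional_total`` by one
    participant when the total is odd.
    """

    ris: int
    accrued: int
    additional_total: int
    per_arm: int
    mode: str = "standard"
    d2: float = 0.0
    note: str = ""


def plan_from_information(ris: int, accrued: int, mode: str = "standard", d2: float = 0.0) -> PlanResult:
    """Plan directly from a known RIS and accrued participant count."""
    if ris < 1:
        raise ValueError("ris must be a positive participant count")
    if accrued < 0:
        raise ValueError("accrued must be non-negative")
    additional = max(0, ris - accrued)
    return PlanResult(
        ris=int(ris),
        accrued=int(accrued),
        additional_total=additional,
        per_arm=math.ceil(additional / 2),
        mode=mode,
        d2=d2,
        note=NOTE_SURPASSED if additional == 0 else "",
    )


def plan_next_trials(
    design: DesignSpec,
    trials: Sequence[TrialRecord],
    accrued_override: Optional[int] = None,
    mode: str = "standard",
    exclude: Optional[str] = None,
    measure: str = "odds_ratio",
    model: str = "random_DL",
) -> PlanResult:
    """Estimate the sample size of (a) future trial(s).

    standard
        All completed trials contribute to the meta-analysis (hence to D^2
        and the RIS) and to the accrued information; ``accrued_override``
        replaces the randomised total with an analysed total if supplied.
    conservative
        The trial named by ``exclude`` — the one whose data informed the
        anticipated effect — contributes neither to the meta-analysis nor
        to the accrued information.
    """
    if mode not in ("standard", "conservative"):
        raise ValueError(f"unknown planning mode {mode!r}")
    trials = sorted(trials, key=lambda tr: tr.order)
    if mode == "conservative":
        if exclude is None:
            raise ValueError("conservative mode requires the label of the trial to exclude")
        labels = [tr.label for tr in trials]
        if exclude not in labels:
            raise ValueError(f"unknown trial {exclude!r}")
        trials = [tr for tr in trials if tr.label != exclude]

    if trials:
        pooled = pool([trial_effect(tr, measure) for tr in trials], model)
        d2 = pooled.D2
    else:
        d2 = 0.0
    ris = required_information_size(design, d2)
    accrued = accrued_override if accrued_override is not None else sum(tr.participants for tr in trials)
    res = plan_from_information(ris, accrued, mode=mode, d2=design.d2_override if design.d2_override is not None else d2)
    return res


def project_scenario(
    base: Sequence[TrialRecord],
    hypothetical: TrialRecord,
    design: DesignSpec,
    accrued_override: Optional[int] = None,
    measure: str = "odds_ratio",
    model: str = "random_DL",
    **sequential_kwargs,
) -> tuple[SequentialResult, PlanResult]:
    """Append a hypothetical trial and rerun the sequential analysis.

    The hypothetical trial is placed after all completed trials.  Its data
    enter the cumulative meta-analysis, so the recomputed diversity may
    raise the required information size; the returned plan reports the
    participants still needed on the new scale.  When the efficacy boundary
    is crossed the remaining requirement is zero — a firm conclusion does
    not need the z-curve to reach full information.
    """
    base = sorted(base, key=lambda tr: tr.order)
    if any(tr.order >= hypothetical.order for tr in base):
        raise ValueError("hypothetical trial must be ordered after all completed trials")
    seq_trials = list(base) + [hypothetical]

    # analysed-n override applies to the completed trials; the hypothetical
    # trial's participants are appended on top of it
    override_all: Optional[int] = None
    if accrued_override is not None:
        override_all = accrued_override + hypothetical.participants

    result = run_sequential(
        seq_trials,
        design,
        accrued_override=override_all,
        measure=measure,
        model=model,
        **sequential_kwargs,
    )
    final = result.final_look
    if final.classification == "efficacy_crossed":
        plan = PlanResult(
            ris=result.ris,
            accrued=final.accrued,
            additional_total=0,
            per_arm=0,
            mode="standard",
            d2=result.final_pooled.D2,
            note="efficacy boundary crossed",
        )
    else:
        plan = plan_from_information(result.ris, final.accrued, d2=result.final_pooled.D2)
    return result, plan
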