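"""Packaged worked-example data: the MiQuit smoking-cessation trials.

MiQuit is a text-message self-help smoking-cessation intervention for
pregnant women evaluated in a feasibility trial (207 women, cessation 12.5%
vs 7.8%) and a pilot trial (407 women, validated abstinence 5.4% vs 2.0%).

The publications report arm percentages and overall totals but not per-arm
event counts, so the packaged 2x2 tables are a *synthetic reconstruction*:
the unique integer counts consistent with the printed percentages under a
near-1:1 split (13/104 vs 8/103; 11/203 vs 4/204).  They reproduce the
printed feasibility odds ratio (1.68) but only approximate downstream pooled
quantities; analyses using them are approximate by construction.

Two hypothetical future-trial scenarios (630 women each, 1:1) are provided
the same way: an encouraging outcome with a +3.17% absolute difference
(16/315 vs 6/315) and a discouraging one at -0.63% (4/315 vs 6/315).
"""

from __future__ import annotations

from importlib import resources

from .information import DesignSpec
from .meta import TrialRecord

__all__ = [
    "miquit_trials",
    "miquit_design",
    "miquit_csv_path",
    "scenario_trial",
    "MIQUIT_ANALYSED",
]

#: participants the worked example treats as already recruited and analysed
#: across both completed trials (the randomised totals sum to 614)
MIQUIT_ANALYSED = 605


def miquit_trials() -> list[TrialRecord]:
    """The two completed MiQuit trials (reconstructed counts)."""
    return [
        TrialRecord("feasibility", 1, 13, 104, 8, 103),
        TrialRecord("pilot", 2, 11, 203, 4, 204),
    ]


def miquit_design() -> DesignSpec:
    """The worked example's design: 90% power, 5% two-sided significance,
    anticipated proportions 5.4% vs 2.0% (a 3.4% absolute difference,
    taken from the pilot trial)."""
    return DesignSpec(p_ctl=0.020, p_exp=0.054, alpha=0.05, power=0.90)


def scenario_trial(name: str) -> TrialRecord:
    """Hypothetical third trial C (favourable) or D (unfavourable)."""
    if name.upper() == "C":
        return TrialRecord("scenario_C", 3, 16, 315, 6, 315)
    if name.upper() == "D":
        return TrialRecord("scenario_D", 3, 4, 315, 6, 315)
    raise ValueError(f"unknown scenario {name!r} (expected 'C' or 'D')")


def miquit_csv_path():
    """Path to the packaged trial CSV (synthetic reconstruction)."""
    return resources.files("tsakit").joinpath("data/miquit_reconstructed.csv")
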