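"""Synthetic trial sequences and Monte-Carlo error-rate experiments.

The generator draws a sequence of two-arm binary-outcome trials around a
true odds ratio, with optional between-trial heterogeneity as a normal
random effect on the log-odds-ratio scale.  The experiment harness replays
cumulative meta-analysis over many replicate sequences and measures how
often a monitoring rule declares significance: naive repeated testing at
|z| >= 1.96 inflates the type-I error as looks accumulate, while
alpha-spending boundaries hold it at the nominal level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.special import expit, logit

from .boundaries import SpendingSpec, efficacy_boundaries
from .information import DesignSpec, required_information_size
from .meta import TrialRecord, Z_CONVENTIONAL

__all__ = ["SimSpec", "generate_sequence", "error_rate_experiment", "power_experiment"]

_MAX_RESAMPLE = 100


@dataclass(frozen=True)
class SimSpec:
    """Conditions for a simulated sequence of two-arm trials.

    ``true_or`` is the common odds ratio (1 under the null); ``tau`` the
    between-trial SD of the log odds ratio; ``n_per_trial`` the total
    participants per trial (scalar or one entry per trial), split 1:1.
    """

    true_or: float = 1.0
    p_ctl: float = 0.10
    tau: float = 0.0
    n_trials: int = 10
    n_per_trial: Union[int, Sequence[int]] = 202
    replicates: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_or <= 0:
            raise ValueError("true_or must be positive")
        if not (0 < self.p_ctl < 1):
            raise ValueError("p_ctl must lie in (0, 1)")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        if self.n_trials < 1 or self.replicates < 1:
            raise ValueError("counts must be >= 1")
        for n in self.sizes:
            if n < 2:
                raise ValueError("each trial needs at least 2 participants")

    @property
    def sizes(self) -> tuple[int, ...]:
        if isinstance(self.n_per_trial, int):
            return tuple([self.n_per_trial] * self.n_trials)
        sizes = tuple(int(n) for n in self.n_per_trial)
        if len(sizes) != self.n_trials:
            raise ValueError("n_per_trial list must have n_trials entries")
        return sizes


def _draw_counts(spec: SimSpec, rng: np.random.Generator, replicates: int) -> tuple[np.ndarray, ...]:
    """Event counts for all replicates; arrays of shape (replicates, n_trials)."""
    k = spec.n_trials
    lor = rng.normal(math.log(spec.true_or), spec.tau, size=(replicates, k))
    p_exp = expit(logit(spec.p_ctl) + lor)
    # the logistic link keeps probabilities inside (0,1); guard and resample
    # anyway in case of extreme overflow to exactly 0 or 1
    for _ in range(_MAX_RESAMPLE):
        bad = (p_exp <= 0) | (p_exp >= 1)
        if not bad.any():
            break
        lor[bad] = rng.normal(math.log(spec.true_or), spec.tau, size=int(bad.sum()))
        p_exp = expit(logit(spec.p_ctl) + lor)
    else:
        raise ValueError("arm probability outside (0,1) after bounded resampling")
    sizes = np.array(spec.sizes)
    n_exp = sizes // 2
    n_ctl = sizes - n_exp
    ev_exp = rng.binomial(n_exp[None, :], p_exp)
    ev_ctl = rng.binomial(n_ctl[None, :], spec.p_ctl, size=(replicates, k))
    return ev_exp, n_exp, ev_ctl, n_ctl


def generate_sequence(spec: SimSpec, rng: Optional[np.random.Generator] = None) -> list[TrialRecord]:
    """One synthetic chronological trial sequence, deterministic given the seed."""
    rng = rng or np.random.default_rng(spec.seed)
    ev_exp, n_exp, ev_ctl, n_ctl = _draw_counts(spec, rng, 1)
    return [
        TrialRecord(
            label=f"sim_{i + 1}",
            order=i + 1,
            events_exp=int(ev_exp[0, i]),
            total_exp=int(n_exp[i]),
            events_ctl=int(ev_ctl[0, i]),
            total_ctl=int(n_ctl[i]),
        )
        for i in range(spec.n_trials)
    ]


def _cumulative_z(
    ev_e: np.ndarray, n_e: np.ndarray, ev_c: np.ndarray, n_c: np.ndarray,
    measure: str, model: str,
) -> np.ndarray:
    """Cumulative-meta-analysis z at each look; shape (replicates, n_trials).

    Vectorised over replicates: per-trial effects with the 0.5 continuity
    correction where a cell is zero, then fixed or DerSimonian-Laird pooled
    z of trials 1..j for every j.
    """
    a = ev_e.astype(float)
    b = (n_e[None, :] - ev_e).astype(float)
    c = ev_c.astype(float)
    d = (n_c[None, :] - ev_c).astype(float)
    zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    a = a + 0.5 * zero
    b = b + 0.5 * zero
    c = c + 0.5 * zero
    d = d + 0.5 * zero
    if measure == "odds_ratio":
        theta = np.log(a * d / (b * c))
        var = 1 / a + 1 / b + 1 / c + 1 / d
    elif measure == "risk_difference":
        n1, n2 = a + b, c + d
        p1, p2 = a / n1, c / n2
        theta = p1 - p2
        var = p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2
    else:
        raise ValueError(f"unsupported simulation measure {measure!r}")

    reps, k = theta.shape
    w = 1.0 / var
    z = np.empty((reps, k))
    for j in range(1, k + 1):
        wj, thj, vj = w[:, :j], theta[:, :j], var[:, :j]
        sw = wj.sum(axis=1)
        theta_f = (wj * thj).sum(axis=1) / sw
        if model == "fixed" or j == 1:
            z[:, j - 1] = theta_f * np.sqrt(sw)
            continue
        Q = (wj * (thj - theta_f[:, None]) ** 2).sum(axis=1)
        denom = sw - (wj**2).sum(axis=1) / sw
        tau2 = np.maximum(0.0, (Q - (j - 1)) / denom)
        wr = 1.0 / (vj + tau2[:, None])
        swr = wr.sum(axis=1)
        z[:, j - 1] = (wr * thj).sum(axis=1) / swr * np.sqrt(swr)
    return z


def error_rate_experiment(
    spec: SimSpec,
    design: DesignSpec,
    monitor: str = "naive",
    measure: str = "odds_ratio",
    model: str = "random_DL",
    spending: Optional[SpendingSpec] = None,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Proportion of replicate sequences declared significant at any look.

    ``monitor='naive'`` tests every look against the fixed-sample +/-1.96;
    ``monitor='boundaries'`` tests against alpha-spending efficacy
    boundaries solved on the schedule of cumulative participants relative
    to the design's required information size (D^2 = 0 scale, so boundaries
    are common to all replicates).
    """
    if monitor not in ("naive", "boundaries"):
        raise ValueError(f"unknown monitor {monitor!r}")
    rng = rng or np.random.default_rng(spec.seed)
    ev_e, n_e, ev_c, n_c = _draw_counts(spec, rng, spec.replicates)
    z = _cumulative_z(ev_e, n_e, ev_c, n_c, measure, model)
    if monitor == "naive":
        thresholds = np.full(spec.n_trials, Z_CONVENTIONAL)
    else:
        ris = required_information_size(design, d2=0.0)
        t = np.cumsum(spec.sizes) / ris
        t = np.minimum(t, 1.0)
        keep = np.concatenate(([True], np.diff(t) > 0))
        sched = t[keep]
        bset = efficacy_boundaries(sched, spending or SpendingSpec(total_error=design.alpha))
        thresholds = np.empty(spec.n_trials)
        thresholds[keep] = bset.efficacy_z
        thresholds[~keep] = Z_CONVENTIONAL  # looks after full information
    crossed = (np.abs(z) >= thresholds[None, :]).any(axis=1)
    return float(crossed.mean())


def power_experiment(
    design: DesignSpec,
    n_looks: int = 10,
    replicates: int = 10_000,
    seed: int = 0,
    spending: Optional[SpendingSpec] = None,
) -> float:
    """Empirical power of boundary-monitored sequential meta-analysis at n = RIS.

    Simulates trial sequences under the design alternative (event
    proportions ``p_exp`` vs ``p_ctl``, no between-trial heterogeneity)
    totalling exactly the required information size, and measures how often
    the efficacy boundary is crossed by the final look.  The z-statistic is
    the pooled risk difference — the measure whose variance underlies the
    information-size formula.
    """
    ris = required_information_size(design, d2=0.0)
    base = ris // n_looks
    sizes = [base] * n_looks
    sizes[-1] += ris - base * n_looks
    true_or = (design.p_exp / (1 - design.p_exp)) / (design.p_ctl / (1 - design.p_ctl))
    spec = SimSpec(
        true_or=true_or,
        p_ctl=design.p_ctl,
        tau=0.0,
        n_trials=n_looks,
        n_per_trial=sizes,
        replicates=replicates,
        seed=seed,
    )
    return error_rate_experiment(
        spec, design, monitor="boundaries", measure="risk_difference",
        model="fixed", spending=spending,
    )
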