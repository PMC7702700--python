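"""Error-spending functions and group-sequential boundary computation.

Monitoring (efficacy) boundaries are the inflated z-thresholds that keep the
overall type-I error of a repeatedly tested cumulative meta-analysis at the
nominal two-sided alpha.  They are obtained from an alpha-spending function
evaluated at the realised information fractions, by inverting the joint
distribution of the cumulative z-statistics: under the null the z-sequence
is multivariate normal with ``corr(Z_i, Z_j) = sqrt(t_i / t_j)``.

The joint probabilities are computed with the classical sub-density
recursion on the score scale ``S_j = Z_j * sqrt(t_j)``, whose increments are
independent normals: the density of paths still inside the continuation
region is propagated look-to-look by numerical convolution (Simpson rule),
and each look's boundary is found by root-finding on the incremental
crossing probability.

Futility boundaries (the inner wedge) spend the type-II error the same way,
but under the design alternative: the score process drifts with the design
drift ``theta*`` and the wedge value at each look is chosen so that the
cumulative probability of dropping below it (without earlier efficacy
crossing) equals the beta spent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

__all__ = [
    "SpendingSpec",
    "BoundarySet",
    "spend",
    "efficacy_boundaries",
    "futility_boundaries",
    "crossing_probability",
]

SPENDING_FAMILIES = ("obrien_fleming_lan_demets", "pocock_lan_demets")

#: practical infinity for boundary z-values that spend essentially no error
_Z_MAX = 15.0


@dataclass(frozen=True)
class SpendingSpec:
    """An error-spending schedule: family plus total error to spend.

    Two conventions exist for two-sided symmetric designs.  The default
    (``per_side=False``) evaluates the spending function once at the total
    two-sided error (O'Brien-Fleming-type: ``a*(t) = 2(1 - Phi(z_{1-a/2} /
    sqrt(t)))``) and splits the spend equally between the tails.  With
    ``per_side=True`` each tail spends its own function at level ``a/2``,
    which reproduces the familiar tabulated Lan-DeMets O'Brien-Fleming
    two-sided boundaries (e.g. 4.877, 3.357, 2.680, 2.290, 2.031 at five
    equal looks, alpha = 0.05) and is slightly more conservative early.
    """

    total_error: float = 0.05
    family: str = "obrien_fleming_lan_demets"
    sides: int = 2
    per_side: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.total_error < 1):
            raise ValueError("total_error must lie in (0, 1)")
        if self.family not in SPENDING_FAMILIES:
            raise ValueError(f"unknown spending family {self.family!r}")
        if self.sides != 2:
            raise ValueError("only two-sided symmetric designs are supported")


@dataclass(frozen=True)
class BoundarySet:
    """Boundaries on a look schedule.

    All arrays are aligned with ``fractions``.  ``efficacy_z`` stores the
    upper threshold of the symmetric pair; ``futility_z`` stores the raw
    inner-wedge values (may be negative early on — by the display rule only
    positive values constitute an actual wedge).  ``drift`` is the design
    drift used for the futility part (0 when no wedge was solved).
    """

    fractions: tuple[float, ...]
    efficacy_z: tuple[float, ...]
    alpha_spent: tuple[float, ...]
    futility_z: Optional[tuple[float, ...]] = None
    beta_spent: Optional[tuple[float, ...]] = None
    drift: float = 0.0

    def displayed_futility(self) -> tuple[Optional[float], ...]:
        """Wedge values where they exist (f > 0), else None."""
        if self.futility_z is None:
            return tuple(None for _ in self.fractions)
        return tuple(f if f > 0 else None for f in self.futility_z)


def spend(t: float, spec: SpendingSpec) -> float:
    """Cumulative error spent by information fraction ``t``.

    O'Brien-Fleming-type Lan-DeMets: ``e*(t) = 2 (1 - Phi(z_{1-e/2} / sqrt(t)))``
    which spends almost nothing early and reaches the total error exactly at
    ``t = 1``.  Pocock-type: ``e*(t) = e ln(1 + (e^1 - 1) t)``.  ``t > 1`` is
    clamped to 1.
    """
    if t <= 0:
        raise ValueError("undefined spending time (need t > 0)")
    t = min(t, 1.0)
    e = spec.total_error
    if spec.per_side:
        # each tail spends its own function at level e/2; return the total
        e_side = e / 2
        if spec.family == "obrien_fleming_lan_demets":
            return float(2 * 2 * norm.sf(norm.ppf(1 - e_side / 2) / math.sqrt(t)))
        return float(2 * e_side * math.log(1 + (math.e - 1) * t))
    if spec.family == "obrien_fleming_lan_demets":
        return float(2 * norm.sf(norm.ppf(1 - e / 2) / math.sqrt(t)))
    return float(e * math.log(1 + (math.e - 1) * t))


def _simpson_weights(x: np.ndarray) -> np.ndarray:
    """Composite Simpson weights for an odd-length uniform grid."""
    n = x.size
    h = (x[-1] - x[0]) / (n - 1)
    w = np.ones(n)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    return w * h / 3.0


def _check_fractions(fractions: Sequence[float]) -> np.ndarray:
    t = np.asarray(fractions, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("invalid look schedule (empty)")
    if np.any(t <= 0):
        raise ValueError("invalid look schedule (fractions must be positive)")
    if np.any(np.diff(t) <= 0):
        raise ValueError("invalid look schedule (fractions must be strictly increasing)")
    t = np.minimum(t, 1.0)
    if np.any(np.diff(t) <= 0):
        raise ValueError("invalid look schedule (duplicate fractions after clamping at 1)")
    return t


class _ScoreRecursion:
    """Sub-density of the score process over a continuation region.

    Maintains, on a Simpson grid, the joint density of ``S_j`` and the event
    "no boundary crossing up to look j".  ``step_probability`` integrates an
    arbitrary tail functional of the next increment against the current
    sub-density without advancing; ``advance`` convolves onto a new grid.
    """

    def __init__(self, npoints: int = 2001) -> None:
        if npoints < 5:
            raise ValueError("grid too coarse")
        self.npoints = npoints if npoints % 2 == 1 else npoints + 1
        self.grid: Optional[np.ndarray] = None
        self.dens: Optional[np.ndarray] = None
        self.mass = 1.0

    def start(self, t1: float, lo: float, hi: float, drift: float) -> None:
        """Initialise with S_1 ~ N(drift * t1, t1) restricted to (lo, hi)."""
        sd = math.sqrt(t1)
        self.grid = np.linspace(lo, hi, self.npoints)
        self.dens = norm.pdf(self.grid, loc=drift * t1, scale=sd)
        self.mass = float(_simpson_weights(self.grid) @ self.dens)

    def step_probability(self, dt: float, drift: float, tail: Callable[[np.ndarray, float], np.ndarray]) -> float:
        """Integrate ``tail(mean_of_next_S, sd)`` against the sub-density."""
        assert self.grid is not None and self.dens is not None
        sd = math.sqrt(dt)
        mean = self.grid + drift * dt
        w = _simpson_weights(self.grid)
        return float(w @ (self.dens * tail(mean, sd)))

    def advance(self, dt: float, drift: float, lo: float, hi: float) -> None:
        """Convolve with the increment density and restrict to (lo, hi)."""
        assert self.grid is not None and self.dens is not None
        sd = math.sqrt(dt)
        new_grid = np.linspace(lo, hi, self.npoints)
        w = _simpson_weights(self.grid)
        # kernel[i, j] = phi(new_grid[i] - grid[j] - drift*dt; sd)
        kernel = norm.pdf(new_grid[:, None] - self.grid[None, :] - drift * dt, scale=sd)
        self.dens = kernel @ (w * self.dens)
        self.grid = new_grid
        self.mass = float(_simpson_weights(new_grid) @ self.dens)


def _first_look_z(target: float) -> float:
    """z such that the two-sided tail 2*Phi(-z) equals ``target``."""
    if target <= 0:
        return _Z_MAX
    return float(min(norm.isf(target / 2), _Z_MAX))


def efficacy_boundaries(
    fractions: Sequence[float],
    spec: Optional[SpendingSpec] = None,
    grid: int = 2001,
) -> BoundarySet:
    """Solve symmetric two-sided efficacy boundaries on a look schedule.

    At each look ``j`` the boundary ``b_j`` is chosen so that the null
    probability of first crossing at look ``j`` (either tail) equals the
    alpha spent between ``t_{j-1}`` and ``t_j``.  Solved look-by-look with
    the score-scale sub-density recursion and bisection-backed Brent
    root-finding to 1e-6 on z.
    """
    spec = spec or SpendingSpec()
    t = _check_fractions(fractions)
    spent = np.array([spend(tj, spec) for tj in t])

    b = np.empty_like(t)
    b[0] = _first_look_z(spent[0])
    rec = _ScoreRecursion(grid)
    c1 = b[0] * math.sqrt(t[0])
    rec.start(t[0], -c1, c1, drift=0.0)

    for j in range(1, t.size):
        dt = t[j] - t[j - 1]
        inc = spent[j] - spent[j - 1]
        sqt = math.sqrt(t[j])

        def crossing(z: float) -> float:
            c = z * sqt

            def tail(mean: np.ndarray, sd: float) -> np.ndarray:
                return norm.cdf((-c - mean) / sd) + norm.sf((c - mean) / sd)

            return rec.step_probability(dt, 0.0, tail)

        if inc <= crossing(_Z_MAX):
            b[j] = _Z_MAX
        else:
            b[j] = brentq(lambda z: crossing(z) - inc, 0.0, _Z_MAX, xtol=1e-6)
        cj = b[j] * sqt
        rec.advance(dt, 0.0, -cj, cj)

    return BoundarySet(
        fractions=tuple(float(x) for x in t),
        efficacy_z=tuple(float(x) for x in b),
        alpha_spent=tuple(float(x) for x in spent),
    )


def futility_boundaries(
    fractions: Sequence[float],
    alpha_spec: Optional[SpendingSpec] = None,
    beta: float = 0.10,
    drift: Optional[float] = None,
    grid: int = 2001,
    efficacy: Optional[BoundarySet] = None,
) -> BoundarySet:
    """Solve efficacy plus inner-wedge futility boundaries.

    The efficacy part is solved first (non-binding: ignoring the wedge, so
    type-I error control does not rely on stopping for futility).  The wedge
    value ``f_j`` then spends the type-II error under the design alternative
    ``drift``: the probability that the z-curve falls below ``f_j`` at look
    ``j`` without having crossed a boundary earlier equals the beta spent
    between looks, using the same spending family applied to ``beta``.

    ``drift`` defaults to ``z_{1-alpha/2} + z_{1-beta}``, the design drift
    for which the wedge closes the design at full information.
    """
    alpha_spec = alpha_spec or SpendingSpec()
    if not (0 < beta < 1):
        raise ValueError("beta must lie in (0, 1)")
    if drift is None:
        drift = float(norm.ppf(1 - alpha_spec.total_error / 2) + norm.ppf(1 - beta))
    if drift <= 0:
        raise ValueError("invalid design drift (need drift > 0)")

    eff = efficacy if efficacy is not None else efficacy_boundaries(fractions, alpha_spec, grid)
    t = np.asarray(eff.fractions)
    b = np.asarray(eff.efficacy_z)

    beta_spec = SpendingSpec(total_error=beta, family=alpha_spec.family)
    bspent = np.array([spend(tj, beta_spec) for tj in t])

    f = np.empty_like(t)
    # look 1: P(Z_1 <= f_1 | drift) = beta*(t_1)
    sq1 = math.sqrt(t[0])
    f[0] = float(norm.ppf(bspent[0])) + drift * sq1 if bspent[0] > 0 else -_Z_MAX
    f[0] = min(f[0], b[0])

    rec = _ScoreRecursion(grid)
    lo = max(f[0], -b[0]) * sq1
    hi = b[0] * sq1
    rec.start(t[0], lo, hi, drift=drift)

    for j in range(1, t.size):
        dt = t[j] - t[j - 1]
        inc = bspent[j] - bspent[j - 1]
        sqt = math.sqrt(t[j])

        def below_drift(z: float) -> float:
            c = z * sqt

            def tail(mean: np.ndarray, sd: float) -> np.ndarray:
                return norm.cdf((c - mean) / sd)

            return rec.step_probability(dt, drift, tail)

        if inc <= below_drift(-_Z_MAX):
            f[j] = -_Z_MAX
        elif inc >= below_drift(b[j]):
            f[j] = b[j]
        else:
            f[j] = brentq(lambda z: below_drift(z) - inc, -_Z_MAX, float(b[j]), xtol=1e-6)
        lo = max(f[j], -b[j]) * sqt
        hi = b[j] * sqt
        if j < t.size - 1:
            rec.advance(dt, drift, lo, hi)

    return replace(
        eff,
        futility_z=tuple(float(x) for x in f),
        beta_spent=tuple(float(x) for x in bspent),
        drift=float(drift),
    )


def crossing_probability(
    bset: BoundarySet,
    drift: float = 0.0,
    grid: int = 2001,
) -> float:
    """Probability that the z-sequence crosses the efficacy boundaries.

    Computed by the same sub-density recursion used to solve the
    boundaries: the mass still inside all continuation regions after the
    final look is the non-crossing probability.  With ``drift = 0`` this is
    the attained type-I error of the boundary set; with the design drift it
    is the power of the monitored design on this schedule.
    """
    t = np.asarray(bset.fractions)
    b = np.asarray(bset.efficacy_z)
    rec = _ScoreRecursion(grid)
    c = b[0] * math.sqrt(t[0])
    rec.start(t[0], -c, c, drift)
    for j in range(1, t.size):
        dt = t[j] - t[j - 1]
        cj = b[j] * math.sqrt(t[j])
        rec.advance(dt, drift, -cj, cj)
    return float(1.0 - rec.mass)
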