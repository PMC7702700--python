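"""Spending functions and the group-sequential boundary solver."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from tsakit.boundaries import (
    SpendingSpec,
    crossing_probability,
    efficacy_boundaries,
    futility_boundaries,
    spend,
)

# Five-equal-look boundaries frozen from an independent oracle: sequential
# root-finding on multivariate-normal rectangle probabilities with
# corr(Z_i, Z_j) = sqrt(t_i/t_j) (scipy multivariate_normal.cdf), solved so
# that P(no crossing through look j) = 1 - alpha*(t_j).
ORACLE_FIVE_LOOKS = [4.38261, 3.09973, 2.55314, 2.25389, 2.06354]
# Published two-sided Lan-DeMets O'Brien-Fleming table values (per-tail
# spending at alpha/2), e.g. gsDesign/ldbounds.
TABLE_FIVE_LOOKS_PER_SIDE = [4.8769, 3.3570, 2.6803, 2.2898, 2.0310]

T5 = [0.2, 0.4, 0.6, 0.8, 1.0]


class TestSpend:
    def test_full_spend_at_full_information(self):
        assert spend(1.0, SpendingSpec(0.05)) == pytest.approx(0.05, abs=1e-12)
        assert spend(1.0, SpendingSpec(0.10, family="pocock_lan_demets")) == pytest.approx(0.10)
        assert spend(1.0, SpendingSpec(0.05, per_side=True)) == pytest.approx(0.05, abs=1e-12)

    def test_quarter_information_closed_form(self):
        # 2*(1 - Phi(z_{0.975}/sqrt(0.25))) = 2*(1 - Phi(3.9199...))
        expected = 2 * norm.sf(norm.ppf(0.975) / 0.5)
        assert spend(0.25, SpendingSpec(0.05)) == pytest.approx(expected, rel=1e-12)

    def test_vanishes_at_zero_and_rejects_nonpositive(self):
        assert spend(1e-6, SpendingSpec(0.05)) < 1e-12
        with pytest.raises(ValueError, match="spending time"):
            spend(0.0, SpendingSpec(0.05))

    def test_clamps_beyond_full_information(self):
        assert spend(1.7, SpendingSpec(0.05)) == spend(1.0, SpendingSpec(0.05))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(0.01, 0.99), st.floats(0.01, 0.99))
    def test_monotone_in_t(self, a, b):
        lo, hi = sorted([a, b])
        for spec in (SpendingSpec(0.05), SpendingSpec(0.05, family="pocock_lan_demets")):
            assert spend(lo, spec) <= spend(hi, spec) + 1e-15


class TestEfficacyBoundaries:
    def test_single_look_is_fixed_sample_test(self):
        bs = efficacy_boundaries([1.0])
        assert bs.efficacy_z[0] == pytest.approx(1.95996, abs=1e-4)

    def test_five_equal_looks_match_mvn_oracle(self):
        bs = efficacy_boundaries(T5)
        assert np.allclose(bs.efficacy_z, ORACLE_FIVE_LOOKS, atol=1e-3)

    def test_per_side_convention_matches_published_table(self):
        bs = efficacy_boundaries(T5, SpendingSpec(per_side=True))
        assert np.allclose(bs.efficacy_z, TABLE_FIVE_LOOKS_PER_SIDE, atol=2e-3)

    def test_near_degenerate_schedule_collapses_to_single_look(self):
        bs = efficacy_boundaries([0.9999, 1.0])
        assert np.allclose(bs.efficacy_z, [1.96, 1.96], atol=0.03)

    def test_alpha_fully_spent_at_final_look(self):
        bs = efficacy_boundaries(T5)
        assert bs.alpha_spent[-1] == pytest.approx(0.05, abs=1e-12)
        assert np.all(np.diff(bs.alpha_spent) > 0)

    def test_grid_doubling_stability(self):
        coarse = efficacy_boundaries(T5, grid=2001)
        fine = efficacy_boundaries(T5, grid=4001)
        assert np.max(np.abs(np.array(coarse.efficacy_z) - fine.efficacy_z)) < 1e-4

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError, match="look schedule"):
            efficacy_boundaries([0.5, 0.5])
        with pytest.raises(ValueError, match="look schedule"):
            efficacy_boundaries([])
        with pytest.raises(ValueError, match="look schedule"):
            efficacy_boundaries([-0.2, 0.5])

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(
        st.lists(st.floats(0.1, 0.5), min_size=1, max_size=5),
        st.sampled_from([0.01, 0.05, 0.10]),
    )
    def test_boundary_invariants_on_random_schedules(self, increments, alpha):
        """Boundaries decrease in t and stay above the fixed-sample value
        before full information; attained type-I equals the spend.

        Schedules are built from increments of at least 0.1: when looks
        cluster more tightly the O'Brien-Fleming spend between them (order
        dt) falls below the crossing probability at an unchanged threshold
        (order sqrt(dt)) and the solved boundary can locally rise, so
        monotone decrease is only an invariant of separated schedules.
        """
        t = [x for x in np.cumsum(increments) if x < 1.0] or [min(increments[0], 1.0)]
        bs = efficacy_boundaries(t, SpendingSpec(alpha), grid=801)
        z_fixed = norm.ppf(1 - alpha / 2)
        assert all(b2 <= b1 + 1e-6 for b1, b2 in zip(bs.efficacy_z, bs.efficacy_z[1:]))
        for tt, b in zip(bs.fractions, bs.efficacy_z):
            if tt < 1:
                assert b >= z_fixed - 1e-6
        attained = crossing_probability(bs, drift=0.0, grid=801)
        assert attained == pytest.approx(bs.alpha_spent[-1], abs=5e-4)


class TestFutilityBoundaries:
    def test_single_look_boundaries_meet(self):
        bs = futility_boundaries([1.0], beta=0.10)
        assert bs.futility_z[0] == pytest.approx(bs.efficacy_z[0], abs=1e-6)

    def test_wedge_below_efficacy_and_nondecreasing(self):
        """The inner wedge rises toward the efficacy boundary.

        At full information the two approach each other but meet exactly
        only in a single-look design: with interim looks the monitored
        design's residual type-II error at the fixed-sample information
        exceeds beta (the information would need the usual group-sequential
        inflation for the boundaries to close), leaving a gap of ~0.2 on
        the z scale for five equal looks.
        """
        bs = futility_boundaries(T5, beta=0.10)
        f = np.array(bs.futility_z)
        b = np.array(bs.efficacy_z)
        assert np.all(f <= b + 1e-9)
        assert np.all(np.diff(f) > 0)
        assert b[-1] - f[-1] < 0.25

    def test_beta_fully_spent_at_final_look(self):
        bs = futility_boundaries(T5, beta=0.10)
        assert bs.beta_spent[-1] == pytest.approx(0.10, abs=1e-12)

    def test_wedge_spends_beta_against_independent_recursion(self):
        """Brute-force trapezoid recursion on a fine grid, written
        independently of the solver, reproduces the wedge to 1e-3."""
        beta = 0.10
        bs = futility_boundaries(T5, beta=beta)
        drift = bs.drift
        t = np.array(T5)
        b = np.array(bs.efficacy_z)
        f = np.array(bs.futility_z)
        # propagate the sub-density between (f, b) under the drift and
        # accumulate the mass leaking below the wedge at each look
        npts = 6000
        x = np.linspace(f[0] * math.sqrt(t[0]), b[0] * math.sqrt(t[0]), npts)
        dens = norm.pdf(x, loc=drift * t[0], scale=math.sqrt(t[0]))
        spent = norm.cdf(f[0], loc=drift * math.sqrt(t[0]))
        for j in range(1, len(t)):
            dt = t[j] - t[j - 1]
            xn = np.linspace(f[j] * math.sqrt(t[j]), b[j] * math.sqrt(t[j]), npts)
            kern = norm.pdf(xn[:, None] - x[None, :] - drift * dt, scale=math.sqrt(dt))
            below = norm.cdf((f[j] * math.sqrt(t[j]) - x - drift * dt) / math.sqrt(dt))
            spent += np.trapezoid(dens * below, x)
            dens = np.trapezoid(kern * dens[None, :] * np.ones_like(xn)[:, None], x, axis=1)
            x = xn
        expected = np.array([2 * norm.sf(norm.ppf(1 - beta / 2) / math.sqrt(tt)) for tt in t])[-1]
        assert spent == pytest.approx(expected, abs=1e-3)

    def test_invalid_drift_rejected(self):
        with pytest.raises(ValueError, match="drift"):
            futility_boundaries(T5, beta=0.10, drift=-1.0)


def test_null_crossing_frequency_matches_alpha():
    """Monte-Carlo z-paths on an uneven schedule cross the efficacy
    boundaries with frequency alpha within 3 MC standard errors."""
    t = np.array([0.15, 0.45, 0.7, 1.0])
    bs = efficacy_boundaries(t)
    rng = np.random.default_rng(2024)
    reps = 10_000
    dt = np.diff(np.concatenate(([0.0], t)))
    s = np.cumsum(rng.normal(0.0, np.sqrt(dt), size=(reps, t.size)), axis=1)
    z = s / np.sqrt(t)
    crossed = (np.abs(z) >= np.array(bs.efficacy_z)).any(axis=1)
    mc_se = math.sqrt(0.05 * 0.95 / reps)
    assert abs(crossed.mean() - 0.05) <= 3 * mc_se
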