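"""Effect algebra and DerSimonian-Laird pooling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tsakit import EffectEstimate, TrialRecord, pool, trial_effect


def dl_oracle(thetas, ses):
    """Spreadsheet-style evaluation of the DL formulas, independent of pool()."""
    w = [1 / s**2 for s in ses]
    k = len(thetas)
    sw = sum(w)
    theta_f = sum(wi * ti for wi, ti in zip(w, thetas)) / sw
    Q = sum(wi * (ti - theta_f) ** 2 for wi, ti in zip(w, thetas))
    tau2 = max(0.0, (Q - (k - 1)) / (sw - sum(wi**2 for wi in w) / sw)) if k > 1 else 0.0
    wr = [1 / (s**2 + tau2) for s in ses]
    theta_r = sum(wi * ti for wi, ti in zip(wr, thetas)) / sum(wr)
    vF, vR = 1 / sw, 1 / sum(wr)
    I2 = max(0.0, (Q - (k - 1)) / Q) if (k > 1 and Q > 0) else 0.0
    return theta_r, vF, vR, Q, tau2, I2, 1 - vF / vR


def effects(thetas, ses):
    return [EffectEstimate("odds_ratio", t, s) for t, s in zip(thetas, ses)]


class TestTrialEffect:
    def test_symmetric_table_gives_zero_log_or(self):
        tr = TrialRecord("t", 1, 10, 100, 10, 100)
        est = trial_effect(tr, "odds_ratio")
        assert est.point == pytest.approx(0.0)
        assert est.se == pytest.approx(math.sqrt(1 / 10 + 1 / 90 + 1 / 10 + 1 / 90))
        assert not est.corrected

    def test_feasibility_trial_odds_ratio(self):
        # hand arithmetic on the 2x2: (13*95)/(91*8) = 1.69643...
        est = trial_effect(TrialRecord("feas", 1, 13, 104, 8, 103))
        assert est.point == pytest.approx(math.log(13 * 95 / (91 * 8)), abs=1e-12)
        assert math.exp(est.point) == pytest.approx(1.6964, abs=1e-4)

    def test_continuity_correction_on_zero_cell(self):
        est = trial_effect(TrialRecord("z", 1, 0, 50, 5, 50), correction=True)
        assert est.corrected
        expected = math.log(0.5 * 45.5 / (50.5 * 5.5))
        assert est.point == pytest.approx(expected)
        assert math.isfinite(est.se)

    def test_zero_cell_rejected_when_correction_disabled(self):
        with pytest.raises(ValueError, match="inestimable"):
            trial_effect(TrialRecord("z", 1, 0, 50, 0, 50), correction=False)

    @pytest.mark.parametrize("measure", ["odds_ratio", "risk_ratio", "risk_difference"])
    def test_measures_estimable_on_regular_table(self, measure):
        est = trial_effect(TrialRecord("t", 1, 12, 100, 6, 100), measure)
        assert est.se > 0 and math.isfinite(est.point)

    def test_invalid_record_rejected(self):
        with pytest.raises(ValueError):
            TrialRecord("bad", 1, 11, 10, 0, 10)
        with pytest.raises(ValueError):
            TrialRecord("bad", 0, 1, 10, 0, 10)


class TestPool:
    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty meta-analysis"):
            pool([])

    def test_single_effect_is_identity(self):
        res = pool(effects([0.4], [0.2]))
        assert res.theta == pytest.approx(0.4)
        assert res.variance == pytest.approx(0.04)
        assert res.tau2 == res.I2 == res.D2 == 0.0

    def test_two_identical_effects_halve_variance(self):
        res = pool(effects([0.3, 0.3], [0.5, 0.5]))
        assert res.theta == pytest.approx(0.3)
        assert res.variance == pytest.approx(0.125)
        assert res.Q == pytest.approx(0.0, abs=1e-12)
        assert res.tau2 == 0.0

    def test_dispersed_pair_matches_frozen_oracle(self):
        # brute-force DL oracle on (0, 0.5), (1, 0.5):
        # w=4 each, Q=2, tau2=0.25, I2=0.5, D2=0.5
        res = pool(effects([0.0, 1.0], [0.5, 0.5]))
        assert res.Q == pytest.approx(2.0)
        assert res.tau2 == pytest.approx(0.25)
        assert res.I2 == pytest.approx(0.5)
        assert res.D2 == pytest.approx(0.5)
        assert res.theta == pytest.approx(0.5)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(-2, 2, allow_nan=False),
                st.floats(0.05, 2.0, allow_nan=False),
            ),
            min_size=1,
            max_size=8,
        )
    )
    def test_dl_matches_oracle_and_invariants(self, pairs):
        thetas = [p[0] for p in pairs]
        ses = [p[1] for p in pairs]
        res = pool(effects(thetas, ses))
        theta_r, vF, vR, Q, tau2, I2, D2 = dl_oracle(thetas, ses)
        assert res.theta == pytest.approx(theta_r, rel=1e-10, abs=1e-12)
        assert res.tau2 == pytest.approx(tau2, rel=1e-10, abs=1e-12)
        assert res.Q == pytest.approx(Q, rel=1e-10, abs=1e-10)
        # diversity dominates inconsistency; random variance dominates fixed
        assert res.D2 >= res.I2 - 1e-12
        assert res.var_random >= res.var_fixed - 1e-15
        if res.tau2 == 0:
            assert res.var_random == pytest.approx(res.var_fixed)
        # fixed-effect pooled estimate inside the convex hull of the inputs
        fixed = pool(effects(thetas, ses), "fixed")
        assert min(thetas) - 1e-9 <= fixed.theta <= max(thetas) + 1e-9

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.permutations(list(range(5))))
    def test_pooling_is_permutation_invariant(self, perm):
        thetas = [0.1, -0.4, 0.9, 0.3, -0.2]
        ses = [0.2, 0.5, 0.8, 0.3, 0.6]
        base = pool(effects(thetas, ses))
        shuffled = pool(effects([thetas[i] for i in perm], [ses[i] for i in perm]))
        assert shuffled.theta == pytest.approx(base.theta)
        assert shuffled.tau2 == pytest.approx(base.tau2)
        assert shuffled.D2 == pytest.approx(base.D2)

    def test_mixed_measures_rejected(self):
        bad = [EffectEstimate("odds_ratio", 0.1, 0.2), EffectEstimate("risk_ratio", 0.1, 0.2)]
        with pytest.raises(ValueError, match="mixed"):
            pool(bad)


def test_miquit_pooling_matches_metafor_style_values(miquit):
    """DL random-effects pooling of the reconstructed MiQuit trials.

    Frozen from an independent R metafor run (rma, method='DL',
    measure='OR'): OR 2.0797822927, z 1.9816558692, tau2 0, I2 0.
    """
    res = pool([trial_effect(tr) for tr in miquit])
    assert res.effect == pytest.approx(2.0797822927, abs=1e-8)
    assert res.z == pytest.approx(1.9816558692, abs=1e-8)
    assert res.tau2 == 0.0
    assert res.I2 == 0.0


def test_three_trial_heterogeneity_matches_metafor(miquit, scenario_d):
    """Frozen from R metafor: tau2 0.13164235357, I2 28.999293196%."""
    res = pool([trial_effect(tr) for tr in miquit + [scenario_d]])
    assert res.tau2 == pytest.approx(0.13164235357, abs=1e-8)
    assert res.I2 == pytest.approx(0.28999293196, abs=1e-8)
    assert res.D2 > res.I2
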