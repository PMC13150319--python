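"""Furcation baseline predictors: worked cases, series oracle, invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from widenedpipe import (
    BranchRecord,
    Dataset,
    FurcationScenario,
    SimConfig,
    compare_scenarios,
    l0_geometric,
    n_events_fixed,
    n_events_geometric,
    predict_conservation,
    predict_fixed,
    predict_geometric,
    simulate_dataset,
    sweep_fixed,
)
from widenedpipe.furcation import predict_record


class TestFixedSpacing:
    @pytest.mark.parametrize(
        "L_seg,L_b,expected",
        [(30, 3, 10.0), (100, 30, 10.0 / 3.0), (770, 3, 770.0 / 3.0)],
    )
    def test_event_count(self, L_seg, L_b, expected):
        assert n_events_fixed(L_seg, L_b) == pytest.approx(expected, rel=1e-12)

    def test_bifurcation_prediction(self):
        p = predict_fixed(100, L_segment=60, L_b=6, b=2)
        assert p.n_events == pytest.approx(10.0)
        assert p.n_tip_pred == pytest.approx(102_400.0, rel=1e-12)

    def test_zero_length_is_identity(self):
        p = predict_fixed(37, L_segment=0, L_b=5)
        assert p.n_tip_pred == pytest.approx(37.0)

    def test_overflow_stays_in_log_space(self):
        p = predict_fixed(100, L_segment=300, L_b=3)
        assert p.log10_n_tip_pred == pytest.approx(2 + 100 * math.log10(2), rel=1e-12)
        assert p.n_tip_pred == math.inf  # not materializable

    @given(
        st.floats(10, 770),
        st.floats(1, 30),
        st.integers(10, 10_000),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotonicity(self, L_seg, L_b, n_base):
        base = predict_fixed(n_base, L_seg, L_b).log10_n_tip_pred
        assert predict_fixed(n_base, L_seg, L_b * 1.5).log10_n_tip_pred <= base
        assert predict_fixed(n_base, L_seg * 1.5, L_b).log10_n_tip_pred >= base
        assert predict_fixed(n_base + 1, L_seg, L_b).log10_n_tip_pred >= base


class TestGeometricContraction:
    def test_worked_case_l0(self):
        assert l0_geometric(100, 0.7, 1.0) == pytest.approx(30.7, rel=1e-12)
        assert l0_geometric(770, 0.7, 1.0) == pytest.approx(231.7, rel=1e-12)

    def test_lambda_to_zero_limit_is_single_internode(self):
        assert l0_geometric(50, 1e-9, 1.0) == pytest.approx(50.0, rel=1e-6)

    def test_worked_case_events_and_distal_internode(self):
        n = n_events_geometric(100, 0.7, 1.0)
        assert n == pytest.approx(9.6005, abs=5e-4)
        L0 = l0_geometric(100, 0.7, 1.0)
        assert L0 * 0.7**n == pytest.approx(1.0, rel=1e-9)

    def test_two_internode_case(self):
        # L_segment = L_0*(1 + lambda) with L_0 = L_n/lambda gives n = 1
        lam, L_n = 0.7, 1.0
        L_seg = (L_n / lam) * (1 + lam)
        assert n_events_geometric(L_seg, lam, L_n) == pytest.approx(1.0, rel=1e-9)

    def test_closed_form_matches_direct_summation(self):
        # integer-n construction: sum the internodes explicitly
        rng = np.random.default_rng(8)
        for _ in range(200):
            lam = rng.uniform(0.05, 0.95)
            n_true = rng.integers(1, 40)
            L0 = rng.uniform(1.0, 50.0)
            internodes = [L0 * lam**k for k in range(n_true + 1)]
            L_seg = sum(internodes)
            L_n = internodes[-1]
            n = n_events_geometric(L_seg, lam, L_n)
            assert n == pytest.approx(n_true, rel=1e-9, abs=1e-9)

    def test_series_identity_over_random_draws(self):
        rng = np.random.default_rng(9)
        for _ in range(1000):
            lam = rng.uniform(0.05, 0.95)
            L_seg = rng.uniform(2.0, 800.0)
            L0 = l0_geometric(L_seg, lam, 1.0)
            n = n_events_geometric(L_seg, lam, 1.0)
            total = L0 * (1 - lam ** (n + 1)) / (1 - lam)
            assert total == pytest.approx(L_seg, rel=1e-9)

    def test_prediction_worked_case(self):
        p = predict_geometric(100, 100)
        assert p.n_tip_pred == pytest.approx(100 * 2**9.600513612701, rel=1e-9)
        assert p.n_tip_pred == pytest.approx(77_600, rel=0.01)

    def test_degenerate_segment_is_identity(self):
        p = predict_geometric(55, L_segment=1.0)
        assert p.n_events == 0.0
        assert p.n_tip_pred == pytest.approx(55.0)

    def test_exceeds_fixed_spacing_at_l0(self):
        # contraction packs more events into the same length than L_b = L_0
        for L_seg in (50, 100, 400, 770):
            L0 = l0_geometric(L_seg, 0.7, 1.0)
            geo = predict_geometric(100, L_seg).log10_n_tip_pred
            fixed = predict_fixed(100, L_seg, L0).log10_n_tip_pred
            assert geo > fixed


class TestConservation:
    def test_r_equals_two(self):
        davinci = predict_conservation(500, 40.0, 20.0, p=2)
        murray = predict_conservation(500, 40.0, 20.0, p=3)
        assert davinci.n_tip_pred == pytest.approx(2000.0, rel=1e-12)
        assert murray.n_tip_pred == pytest.approx(4000.0, rel=1e-12)

    def test_equal_diameters_identity(self):
        for p in (2, 3):
            pred = predict_conservation(123, 25.0, 25.0, p=p)
            assert pred.n_tip_pred == pytest.approx(123.0)

    def test_murray_above_davinci_iff_widening(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            db, dt = rng.uniform(10, 80, 2)
            d2 = predict_conservation(100, db, dt, p=2).log10_n_tip_pred
            d3 = predict_conservation(100, db, dt, p=3).log10_n_tip_pred
            if db / dt >= 1:
                assert d3 >= d2
            else:
                assert d3 <= d2

    def test_no_widening_flagged(self):
        pred = predict_conservation(100, 20.0, 25.0, p=2)
        assert "no-widening" in pred.flags
        assert pred.n_tip_pred < 100


class TestSweepAndCompare:
    def test_sweep_monotone_in_lb(self):
        ds = Dataset(records=[BranchRecord("s", 100, 100, 40.0, 20.0, 300.0, 10.0)])
        preds = sweep_fixed(ds, list(range(3, 31, 3)))
        assert len(preds) == 10
        vals = [p.log10_n_tip_pred for p in preds]
        assert vals == sorted(vals, reverse=True)

    def test_single_value_grid_matches_predict_fixed(self):
        rec = BranchRecord("s", 100, 100, 40.0, 20.0, 300.0, 10.0)
        (p,) = sweep_fixed(Dataset(records=[rec]), [12.0])
        q = predict_fixed(100, rec.segment_length_cm, 12.0)
        assert p.log10_n_tip_pred == q.log10_n_tip_pred

    def test_sweep_counts_and_finiteness(self, null_dataset):
        preds = sweep_fixed(null_dataset)
        assert len(preds) == 10 * 112
        assert all(np.isfinite(p.log10_n_tip_pred) for p in preds)

    def test_constructed_tie_excluded_from_overprediction(self):
        rec = BranchRecord("s", 500, 2000, 40.0, 20.0, 300.0, 10.0)  # obs = R^2*500
        detail, summary = compare_scenarios(
            Dataset(records=[rec]), [FurcationScenario(kind="davinci")]
        )
        assert summary.frac_overpredicted.iloc[0] == 0.0

    def test_empty_scenario_list(self, null_dataset):
        detail, summary = compare_scenarios(null_dataset, [])
        assert detail.empty and summary.empty

    def test_all_baselines_overpredict_noiseless_null(self, noiseless_dataset):
        from widenedpipe import default_scenarios

        detail, summary = compare_scenarios(noiseless_dataset, default_scenarios())
        assert (summary.frac_overpredicted == 1.0).all()


class TestScenarioValidation:
    def test_bad_parameters_raise(self):
        with pytest.raises(ValueError):
            FurcationScenario(kind="spiral")
        with pytest.raises(ValueError):
            FurcationScenario(kind="fixed")  # no L_b
        with pytest.raises(ValueError):
            FurcationScenario(kind="geometric", lambda_len=1.2)
        with pytest.raises(ValueError):
            FurcationScenario(kind="fixed", L_b=5.0, b=1)

    def test_identity_when_driver_vanishes(self):
        # every predictor returns n_base when n = 0 or R = 1
        rec = BranchRecord("s", 77, 77, 30.0, 30.0, 11.0, 10.0)
        fixed = predict_fixed(77, 0.0, 10.0)
        geo = predict_geometric(77, 0.5)
        cons = predict_record(rec, FurcationScenario(kind="murray"))
        for p in (fixed, geo, cons):
            assert p.n_tip_pred == pytest.approx(77.0)
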