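"""Risk-model statistics: AUC, DeLong, Youden, NRI, Cox, KM."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lge_radiomics.models import (
    auc,
    bootstrap_corrected_auc,
    categorical_reclassification,
    continuous_nri,
    cox_models,
    delong_test,
    fit_model,
    km_logrank,
    model_grid,
    youden_cutoff,
)

from . import oracles


def logistic_data(rng, n=200, beta=1.0):
    x = rng.standard_normal(n)
    p = 1.0 / (1.0 + np.exp(-(-1.0 + beta * x)))
    y = (rng.random(n) < p).astype(int)
    return pd.DataFrame({"x": x, "event": y})


class TestAUC:
    def test_exhaustive_pair_counting_example(self):
        assert auc([1, 2, 3, 4], [0, 1, 0, 1]) == pytest.approx(0.75)

    def test_perfect_separation_is_one(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_is_half(self):
        assert auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            risks = rng.integers(0, 5, 15).astype(float)  # forces ties
            events = rng.integers(0, 2, 15)
            if events.sum() in (0, 15):
                continue
            assert auc(risks, events) == pytest.approx(oracles.auc_brute(risks, events))

    @given(st.integers(0, 2**31 - 1))
    def test_invariant_to_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        risks = rng.random(20)
        events = np.r_[np.ones(5), np.zeros(15)].astype(int)
        a1 = auc(risks, events)
        a2 = auc(np.exp(3 * risks) + 7, events)
        assert a1 == pytest.approx(a2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([1.0, 2.0], [1, 1])


class TestDeLong:
    def test_identical_models_give_p_one(self):
        risks = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.array([0, 1, 0, 1])
        diff, p = delong_test(risks, risks, events)
        assert diff == 0.0 and p == 1.0

    def test_structural_components_match_brute_force(self, rng):
        from lge_radiomics.models import _delong_components

        for _ in range(10):
            risks = rng.random(20)
            events = np.r_[np.ones(8), np.zeros(12)].astype(bool)
            v10, v01, a = _delong_components(risks, events)
            bv10, bv01 = oracles.delong_components_brute(risks, events)
            assert np.allclose(v10, bv10)
            assert np.allclose(v01, bv01)
            assert a == pytest.approx(oracles.auc_brute(risks, events))

    def test_detects_a_real_auc_difference(self, rng):
        n = 400
        x = rng.standard_normal(n)
        y = (rng.random(n) < 1 / (1 + np.exp(-2 * x))).astype(int)
        good = x
        bad = rng.standard_normal(n)
        _, p = delong_test(good, bad, y)
        assert p < 0.01


class TestYouden:
    def test_worked_example(self):
        assert youden_cutoff([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 0.8

    def test_anti_predictive_warns_but_returns(self, caplog):
        t = youden_cutoff([0.9, 0.8, 0.2, 0.1], [0, 0, 1, 1])
        assert t is not None

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(50):
            risks = rng.integers(0, 8, 25).astype(float)
            events = rng.integers(0, 2, 25)
            if events.sum() in (0, 25):
                continue
            assert youden_cutoff(risks, events) == oracles.youden_brute(risks, events)


class TestNRI:
    def test_identity_is_zero(self):
        r = np.array([0.1, 0.4, 0.6, 0.9])
        nri, _, _ = continuous_nri(r, r, [0, 0, 1, 1], n_boot=100)
        assert nri == 0.0

    def test_maximum_improvement_is_two(self):
        old = np.array([0.5, 0.5, 0.5, 0.5])
        new = np.array([0.9, 0.8, 0.1, 0.2])  # events up, non-events down
        nri, _, _ = continuous_nri(old, new, [1, 1, 0, 0], n_boot=100)
        assert nri == pytest.approx(2.0)

    def test_balanced_moves_cancel(self):
        old = np.array([0.5] * 4)
        new = np.array([0.6, 0.4, 0.6, 0.4])  # one up one down per stratum
        nri, _, _ = continuous_nri(old, new, [1, 1, 0, 0], n_boot=100)
        assert nri == 0.0

    @given(st.integers(0, 2**31 - 1))
    def test_bounded_in_minus_two_two(self, seed):
        rng = np.random.default_rng(seed)
        old, new = rng.random(12), rng.random(12)
        ev = np.r_[np.ones(4), np.zeros(8)].astype(int)
        nri, (lo, hi), _ = continuous_nri(old, new, ev, n_boot=100)
        assert -2.0 <= nri <= 2.0
        assert lo <= hi


class TestReclassification:
    def test_identical_risks_never_move(self):
        r = np.array([0.1, 0.9, 0.2, 0.8])
        tab = categorical_reclassification(r, r, [0, 1, 0, 1], 0.5)
        assert (tab["up"] == 0).all() and (tab["down"] == 0).all()

    def test_hand_tabulated_six_patient_example(self):
        old = np.array([0.2, 0.2, 0.8, 0.8, 0.2, 0.8])
        new = np.array([0.8, 0.2, 0.2, 0.8, 0.8, 0.2])
        ev = np.array([1, 1, 1, 0, 0, 0])
        tab = categorical_reclassification(old, new, ev, 0.5).set_index("stratum")
        # events: P1 up (correct), P3 down (incorrect); P2 unchanged
        assert tab.loc["event", "correct"] == 1
        assert tab.loc["event", "incorrect"] == 1
        # non-events: P5 up (incorrect), P6 down (correct); P4 unchanged
        assert tab.loc["non-event", "correct"] == 1
        assert tab.loc["non-event", "incorrect"] == 1

    def test_counts_partition_each_stratum(self, rng):
        old, new = rng.random(40), rng.random(40)
        ev = rng.integers(0, 2, 40)
        tab = categorical_reclassification(old, new, ev, 0.5)
        for _, row in tab.iterrows():
            assert row["up"] + row["down"] + row["unchanged"] == row["n"]


class TestLogistic:
    def test_separation_is_flagged(self):
        df = pd.DataFrame({"x": [0, 0, 1, 1, 0, 1], "event": [0, 0, 1, 1, 0, 1]})
        m = fit_model(df, ["x"], quiet=True)
        assert m.separation_flagged
        assert np.all((0 < m.predict(df)) & (m.predict(df) < 1))

    def test_coefficient_recovery_in_simulation(self, rng):
        import statsmodels.api as sm

        hits = 0
        for _ in range(30):
            df = logistic_data(rng, n=2000, beta=1.0)
            res = sm.Logit(df["event"], sm.add_constant(df[["x"]])).fit(disp=0)
            lo, hi = res.conf_int().loc["x"]
            hits += int(lo <= 1.0 <= hi)
        assert hits >= 25

    def test_too_few_events_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "event": [1, 0, 0, 0]})
        with pytest.raises(ValueError, match="2 events"):
            fit_model(df, ["x"])


class TestBootstrapCorrection:
    def test_null_model_corrected_to_half(self, rng):
        n = 400
        df = pd.DataFrame({
            "n1": rng.standard_normal(n),
            "n2": rng.standard_normal(n),
            "event": rng.integers(0, 2, n),
        })
        ev = bootstrap_corrected_auc(df, ["n1", "n2"], n_boot=300, seed=1)
        assert ev.corrected_auc == pytest.approx(0.5, abs=0.04)
        assert ev.ci[0] <= ev.corrected_auc <= ev.ci[1]

    def test_overfit_model_is_corrected_downwards(self, rng):
        n, p = 100, 20
        cols = {f"n{i}": rng.standard_normal(n) for i in range(p)}
        cols["event"] = rng.integers(0, 2, n)
        df = pd.DataFrame(cols)
        ev = bootstrap_corrected_auc(df, [f"n{i}" for i in range(p)], n_boot=150, seed=2)
        assert ev.corrected_auc < ev.apparent_auc

    def test_fixed_seed_reproducible(self, rng):
        df = logistic_data(rng, n=150)
        e1 = bootstrap_corrected_auc(df, ["x"], n_boot=120, seed=3)
        e2 = bootstrap_corrected_auc(df, ["x"], n_boot=120, seed=3)
        assert e1.corrected_auc == e2.corrected_auc
        assert e1.ci == e2.ci


class TestSurvival:
    def test_cox_null_covariate_covers_hr_one(self, rng):
        df = pd.DataFrame({
            "time_years": rng.exponential(4, 300) + 1e-3,
            "event": rng.integers(0, 2, 300),
            "z": rng.standard_normal(300),
        })
        tab = cox_models(df, ["z"])
        row = tab.set_index("predictor").loc["z"]
        assert row["hr_ci_low"] <= 1.0 <= row["hr_ci_high"]
        assert np.isfinite(row["schoenfeld_p"])

    def test_km_identical_groups_not_significant(self, rng):
        t = rng.exponential(3, 200) + 1e-3
        e = rng.integers(0, 2, 200)
        g = np.arange(200) % 2
        fitters, chi2, p = km_logrank(t, e, g)
        assert p > 0.05
        for kmf in fitters.values():
            assert kmf.survival_function_.iloc[0, 0] == 1.0

    def test_km_separates_distinct_hazards(self, rng):
        g = np.repeat([0, 1], 250)
        lam = np.where(g == 0, 0.1, 0.3)
        t = rng.exponential(1 / lam)
        e = (t <= 8).astype(int)
        t = np.minimum(t, 8.0)
        _, _, p = km_logrank(t, e, g)
        assert p < 0.01

    def test_km_needs_two_groups(self, rng):
        with pytest.raises(ValueError, match="2 groups"):
            km_logrank(rng.exponential(2, 10), np.ones(10), np.zeros(10))


def test_model_grid_contains_paired_models():
    grid = model_grid(["sig1", "sig2"])
    assert set(grid) >= {
        "radiomics_only", "lge_presence", "clinical_lge_presence",
        "lge_presence_radiomics", "clinical_lge_presence_radiomics",
    }
    assert grid["clinical_lge_presence_radiomics"] == [
        "clinical_score", "lge_presence", "sig1", "sig2",
    ]
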