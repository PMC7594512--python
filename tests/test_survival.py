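import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from triomics.survival import (
    bh_adjust,
    cox_feature_select,
    cox_score_test,
    km_curve,
    logrank_test,
    median_split,
    univariate_cox_median,
)
from triomics.synthetic import SimulationParams, generate_cohort

from conftest import make_clinical, make_matrix


def exponential_cohort(rng, n, hazard, censor_rate=None):
    t = rng.exponential(1.0 / hazard, size=n)
    if censor_rate is None:
        return make_clinical(t, np.ones(n, bool))
    c = rng.exponential(1.0 / censor_rate, size=n)
    return make_clinical(np.minimum(t, c), t <= c)


class TestMedianSplit:
    def test_even_case(self):
        assert median_split([1, 2, 3, 4]).tolist() == ["down", "down", "up", "up"]

    def test_tie_goes_down(self):
        labels = median_split([1, 2, 3, 4, 5])
        assert labels[2] == "down"  # value equal to the median
        assert labels.tolist() == ["down", "down", "down", "up", "up"]

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            median_split([1, 2, 3])

    @settings(max_examples=50, deadline=None)
    @given(st.integers(4, 60), st.integers(0, 9999))
    def test_group_sizes_balanced_for_distinct_values(self, n, seed):
        v = np.random.default_rng(seed).permutation(np.arange(n, dtype=float))
        labels = median_split(v)
        n_up = int((labels == "up").sum())
        assert abs(n_up - (n - n_up)) <= 1


class TestBhAdjust:
    def test_hand_step_up(self):
        # step-up: q_i = min over j>=i of p_(j) * m / j
        # (0.01, 0.02, 0.03, 0.04): p*m/rank = 0.04, 0.04, 0.04, 0.04
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p_identity(self):
        assert bh_adjust([0.37]) == pytest.approx([0.37])

    def test_known_mixed_example(self):
        # hand computation: sorted (0.005, 0.04, 0.2); q3 = 0.2,
        # q2 = min(0.04*3/2, 0.2) = 0.06, q1 = min(0.005*3, 0.06) = 0.015
        assert bh_adjust([0.04, 0.2, 0.005]) == pytest.approx([0.06, 0.2, 0.015])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
    def test_q_at_least_p_and_capped(self, ps):
        q = bh_adjust(ps)
        assert np.all(q >= np.asarray(ps) - 1e-12)
        assert np.all(q <= 1.0)

    def test_order_invariance(self, rng):
        p = rng.random(25)
        perm = rng.permutation(25)
        q = bh_adjust(p)
        q_perm = bh_adjust(p[perm])
        assert q[perm] == pytest.approx(q_perm)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestLogrank:
    def test_identical_groups_p_near_one(self, rng):
        t = np.tile(rng.exponential(10, size=20), 2)
        e = np.ones(40, bool)
        clinical = make_clinical(t, e)
        _, p = logrank_test(["A"] * 20 + ["B"] * 20, clinical)
        assert p > 0.9

    def test_six_subject_hand_example(self):
        # times 1..6, events (1,1,1,1,0,1), groups (A,A,A,B,B,B)
        # observed-minus-expected tabulation for group A:
        #  t=1: O=1 E=3/6   V=(3/6)(3/6)(5/5)=0.25
        #  t=2: O=1 E=2/5   V=(2/5)(3/5)    =0.24
        #  t=3: O=1 E=1/4   V=(1/4)(3/4)    =0.1875
        #  t=4,6: group A exhausted, E=V=0
        # U = 3 - 1.15 = 1.85; chi2 = 1.85^2 / 0.6775
        clinical = make_clinical([1, 2, 3, 4, 5, 6], [1, 1, 1, 1, 0, 1])
        stat, p = logrank_test(["A", "A", "A", "B", "B", "B"], clinical)
        assert stat == pytest.approx(1.85**2 / 0.6775, rel=1e-9)

    def test_single_group_rejected(self):
        clinical = make_clinical([1, 2, 3, 4], [1, 1, 1, 1])
        with pytest.raises(ValueError):
            logrank_test(["A"] * 4, clinical)

    def test_power_at_hazard_ratio_three(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(20):
            t1 = rng.exponential(1.0, size=200)
            t2 = rng.exponential(1.0 / 3.0, size=200)
            clinical = make_clinical(np.r_[t1, t2], np.ones(400, bool))
            _, p = logrank_test(["A"] * 200 + ["B"] * 200, clinical)
            hits += p < 0.001
        assert hits >= 19


class TestKmCurve:
    def test_no_events_survival_constant_one(self):
        clinical = make_clinical([5, 6, 7, 8], [0, 0, 0, 0])
        (curve,) = km_curve(["A"] * 4, clinical).values()
        assert np.all(curve.survival == 1.0)

    def test_four_subject_product_limit(self):
        # events at 1 and 2, censored at 3 and 4:
        # S(1) = 3/4, S(2) = 3/4 * 2/3 = 1/2, then flat
        clinical = make_clinical([1, 2, 3, 4], [1, 1, 0, 0])
        (curve,) = km_curve(["A"] * 4, clinical).values()
        assert curve.at(0.5) == pytest.approx(1.0)
        assert curve.at(1.0) == pytest.approx(0.75)
        assert curve.at(2.0) == pytest.approx(0.5)
        assert curve.at(10.0) == pytest.approx(0.5)

    def test_at_risk_nonincreasing(self, rng):
        clinical = exponential_cohort(rng, 50, 0.1, censor_rate=0.05)
        (curve,) = km_curve(["A"] * 50, clinical).values()
        assert np.all(np.diff(curve.at_risk) <= 0)
        assert np.all(np.diff(curve.survival) <= 1e-12)

    def test_equals_one_minus_ecdf_without_censoring(self, rng):
        t = rng.exponential(5.0, size=30)
        clinical = make_clinical(t, np.ones(30, bool))
        (curve,) = km_curve(["A"] * 30, clinical).values()
        for q in [np.min(t), np.median(t), np.max(t)]:
            assert curve.at(q) == pytest.approx(np.mean(t > q), abs=1e-12)


class TestCoxFeatureSelect:
    def test_null_type_one_error(self, rng):
        n, n_genes = 200, 1000
        clinical = exponential_cohort(rng, n, 0.05, censor_rate=0.02)
        m = make_matrix(rng.normal(size=(n_genes, n)))
        selected = cox_feature_select(m, clinical)
        assert len(selected) / n_genes == pytest.approx(0.05, abs=0.02)

    def test_planted_gene_power(self):
        rng = np.random.default_rng(2)
        hits = 0
        n_rep = 50
        for _ in range(n_rep):
            n = 300
            x = rng.normal(size=n)
            hazard = 0.05 * np.exp(0.8 * x)
            t = rng.exponential(1.0 / hazard)
            c = np.quantile(t, 0.6) * np.ones(n)  # ~40% administratively censored
            clinical = make_clinical(np.minimum(t, c), t <= c)
            m = make_matrix(x[None, :])
            hits += bool(cox_feature_select(m, clinical))
        assert hits / n_rep >= 0.95

    def test_score_test_matches_binary_logrank(self, rng):
        # for a binary covariate the score test at beta=0 is the logrank test
        n = 60
        clinical = exponential_cohort(rng, n, 0.1, censor_rate=0.03)
        grp = rng.integers(0, 2, size=n)
        chi2, p = cox_score_test(grp[None, :].astype(float),
                                 clinical.data["os_time"].to_numpy(),
                                 clinical.data["os_event"].to_numpy(bool))
        stat_lr, p_lr = logrank_test(np.where(grp == 1, "up", "down"), clinical)
        assert chi2[0] == pytest.approx(stat_lr, rel=1e-6)
        assert p[0] == pytest.approx(p_lr, rel=1e-6)

    def test_no_events_rejected(self, rng):
        clinical = make_clinical(rng.exponential(5, 10), np.zeros(10, bool))
        m = make_matrix(rng.normal(size=(3, 10)))
        with pytest.raises(ValueError):
            cox_feature_select(m, clinical)


class TestUnivariateCoxMedian:
    def test_identical_survival_null(self, rng):
        n = 100
        t = np.tile(rng.exponential(10, size=n // 2), 2)
        clinical = make_clinical(t, np.ones(n, bool))
        x = np.r_[np.zeros(n // 2), np.ones(n // 2)]  # split uncorrelated with survival
        (rec,) = univariate_cox_median(make_matrix(x[None, :]), clinical)
        assert rec.hr == pytest.approx(1.0, abs=0.05)
        assert rec.p > 0.9

    def test_planted_hazard_ratio_recovered(self):
        rng = np.random.default_rng(3)
        n = 500
        x = rng.normal(size=n)
        up = x > np.median(x)
        hazard = np.where(up, 0.10, 0.05)  # true median-split HR = 2
        t = rng.exponential(1.0 / hazard)
        clinical = make_clinical(t, np.ones(n, bool))
        (rec,) = univariate_cox_median(make_matrix(x[None, :]), clinical)
        assert 1.6 <= rec.hr <= 2.5
        assert rec.ci_low <= rec.hr <= rec.ci_high
        assert rec.p < 0.001 and rec.q < 0.001

    def test_relabel_inverts_hr(self, rng):
        n = 200
        x = rng.normal(size=n)
        clinical = exponential_cohort(rng, n, 0.05, censor_rate=0.02)
        (rec,) = univariate_cox_median(make_matrix(x[None, :]), clinical)
        (rec_neg,) = univariate_cox_median(make_matrix(-x[None, :]), clinical)
        assert rec_neg.hr == pytest.approx(1.0 / rec.hr, rel=1e-3)
        assert rec_neg.p == pytest.approx(rec.p, rel=1e-6)

    def test_constant_gene_skipped(self, rng):
        clinical = exponential_cohort(rng, 20, 0.1)
        m = make_matrix(np.ones((1, 20)))
        with pytest.warns(UserWarning, match="degenerate"):
            records = univariate_cox_median(m, clinical)
        assert records == []

    def test_bh_family_is_per_call(self, rng):
        n = 80
        clinical = exponential_cohort(rng, n, 0.05)
        m = make_matrix(rng.normal(size=(6, n)))
        records = univariate_cox_median(m, clinical)
        assert len(records) == 6
        qs = bh_adjust([r.p for r in records])
        assert [r.q for r in records] == pytest.approx(list(qs))


def test_planted_prognostic_genes_have_hr_above_one():
    hrs = []
    for seed in range(5):
        cohort, truth = generate_cohort(
            SimulationParams(n_samples=250, n_genes=60, n_cnacor=5, n_metcor=5,
                             n_prognostic=5, log_hazard_effect=0.5,
                             subgroup_log_hazard=0.0, frac_subgroup_informative=0.0,
                             subgroup_effect=0.0, seed=seed)
        )
        records = univariate_cox_median(
            cohort.mrna.select_genes(truth.prognostic_genes), cohort.clinical
        )
        hrs.extend(r.hr for r in records)
    assert np.mean(np.log(hrs)) > 0


def test_cox_log_hr_recovery_bias():
    """Mean bias of the fitted log-HR on a correctly specified binary model."""
    from lifelines import CoxPHFitter
    import pandas as pd

    rng = np.random.default_rng(8)
    coefs = []
    for _ in range(60):
        n = 500
        grp = rng.integers(0, 2, size=n)
        hazard = 0.05 * np.exp(0.7 * grp)
        t = rng.exponential(1.0 / hazard)
        df = pd.DataFrame({"time": t, "event": 1, "grp": grp})
        cph = CoxPHFitter().fit(df, duration_col="time", event_col="event")
        coefs.append(float(cph.params_["grp"]))
    assert abs(np.mean(coefs) - 0.7) < 0.05
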