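import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from triomics.genecor import (
    fisher_z,
    intersect_gene_sets,
    pairwise_gene_correlation,
    select_correlated_genes,
    skewness_test,
)
from triomics.synthetic import SimulationParams, generate_cohort

from conftest import make_matrix


def brute_force_pearson(x, y):
    """Two-pass covariance / (sx * sy) oracle."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    mx, my = x.mean(), y.mean()
    cov = ((x - mx) * (y - my)).sum()
    return cov / np.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())


class TestPairwiseGeneCorrelation:
    def test_toy_pair_matches_closed_form(self):
        x = make_matrix([[1, 2, 3, 4, 5]])
        y = make_matrix([[2, 1, 4, 3, 6]])
        (rec,) = pairwise_gene_correlation(x, y)
        assert rec.r == pytest.approx(brute_force_pearson([1, 2, 3, 4, 5], [2, 1, 4, 3, 6]))

    def test_matches_brute_force_on_random_matrices(self, rng):
        x = make_matrix(rng.normal(size=(10, 8)))
        y = make_matrix(rng.normal(size=(10, 8)))
        for rec in pairwise_gene_correlation(x, y):
            expected = brute_force_pearson(
                x.values.loc[rec.gene].to_numpy(), y.values.loc[rec.gene].to_numpy()
            )
            assert rec.r == pytest.approx(expected, abs=1e-12)

    def test_perfect_correlation_dropped(self):
        x = make_matrix([[1.0, 2.0, 3.0, 4.0]])
        y = make_matrix([[2.0, 4.0, 6.0, 8.0]])
        with pytest.warns(UserWarning, match="degenerate"):
            records = pairwise_gene_correlation(x, y)
        assert records == []

    def test_zero_variance_dropped(self, rng):
        x = make_matrix(np.vstack([[1, 1, 1, 1], rng.normal(size=4)]))
        y = make_matrix(rng.normal(size=(2, 4)))
        with pytest.warns(UserWarning, match="degenerate"):
            records = pairwise_gene_correlation(x, y)
        assert [r.gene for r in records] == ["G1"]

    def test_misaligned_samples_rejected(self, rng):
        x = make_matrix(rng.normal(size=(2, 4)), samples=["A", "B", "C", "D"])
        y = make_matrix(rng.normal(size=(2, 4)), samples=["A", "B", "D", "C"])
        with pytest.raises(ValueError, match="sample-aligned"):
            pairwise_gene_correlation(x, y)

    def test_too_few_samples_rejected(self, rng):
        x = make_matrix(rng.normal(size=(2, 2)))
        y = make_matrix(rng.normal(size=(2, 2)))
        with pytest.raises(ValueError, match="at least 3"):
            pairwise_gene_correlation(x, y)

    def test_null_type_one_error(self, rng):
        n_genes = 400
        x = make_matrix(rng.normal(size=(n_genes, 200)))
        y = make_matrix(rng.normal(size=(n_genes, 200)))
        records = pairwise_gene_correlation(x, y)
        frac = np.mean([r.p <= 0.05 for r in records])
        assert frac == pytest.approx(0.05, abs=0.03)

    def test_invariant_to_consistent_sample_reordering(self, rng):
        x = make_matrix(rng.normal(size=(5, 12)))
        y = make_matrix(rng.normal(size=(5, 12)))
        perm = list(rng.permutation(x.sample_ids))
        rx = pairwise_gene_correlation(x, y)
        rp = pairwise_gene_correlation(x.select_samples(perm), y.select_samples(perm))
        for a, b in zip(rx, rp):
            assert a.r == pytest.approx(b.r, abs=1e-12)
            assert a.p == pytest.approx(b.p, abs=1e-12)


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_half_maps_to_printed_value(self):
        assert fisher_z(0.5) == pytest.approx(0.5 * np.log(1.5 / 0.5))
        assert fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)

    def test_odd_and_monotone_on_grid(self):
        grid = np.linspace(-0.99, 0.99, 199)
        z = fisher_z(grid)
        assert np.allclose(fisher_z(-grid), -z)
        assert np.all(np.diff(z) > 0)

    @pytest.mark.parametrize("bad", [1.0, -1.0, 1.5])
    def test_out_of_domain_rejected(self, bad):
        with pytest.raises(ValueError):
            fisher_z(bad)

    @settings(max_examples=50, deadline=None)
    @given(r=st.floats(-0.999, 0.999))
    def test_matches_formula(self, r):
        assert fisher_z(r) == pytest.approx(0.5 * np.log((1 + r) / (1 - r)), rel=1e-9)


class TestSkewnessTest:
    def test_symmetric_sample_not_rejected(self):
        z = np.random.default_rng(7).normal(size=5000)
        skew, p = skewness_test(z)
        assert abs(skew) < 0.1
        assert p > 0.05

    def test_right_skewed_sample_rejected(self):
        z = np.random.default_rng(7).chisquare(2, size=5000)
        skew, p = skewness_test(z)
        assert skew > 0
        assert p < 1e-3

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            skewness_test(np.arange(8))

    def test_zero_variance(self):
        with pytest.raises(ValueError):
            skewness_test(np.ones(20))

    def test_g1_is_moment_ratio(self, rng):
        z = rng.normal(size=200) ** 3
        skew, _ = skewness_test(z)
        c = z - z.mean()
        g1 = np.mean(c**3) / np.mean(c**2) ** 1.5
        assert skew == pytest.approx(g1, rel=1e-12)


class TestSelectCorrelatedGenes:
    def test_all_insignificant_empty_selection(self, rng):
        from triomics.genecor import GeneCorrelationRecord

        records = [GeneCorrelationRecord(f"G{i}", 0.01, 1.0) for i in range(20)]
        with pytest.warns(UserWarning, match="too few"):
            res = select_correlated_genes(records)
        assert res.selected == []
        assert np.isnan(res.skewness)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            select_correlated_genes([])

    def test_sign_constraint(self):
        from triomics.genecor import GeneCorrelationRecord

        records = [GeneCorrelationRecord("pos", 0.5, 0.001),
                   GeneCorrelationRecord("neg", -0.5, 0.001)]
        with pytest.warns(UserWarning):
            pos = select_correlated_genes(records, sign_constraint="positive")
            neg = select_correlated_genes(records, sign_constraint="negative")
        assert pos.selected == ["pos"]
        assert neg.selected == ["neg"]

    def test_planted_cnacor_power(self):
        cohort, truth = generate_cohort(
            SimulationParams(n_samples=200, n_genes=200, n_cnacor=50, n_metcor=0,
                             n_prognostic=0, frac_subgroup_informative=0.0,
                             subgroup_effect=0.0, coupling_slope=1.0,
                             coupling_noise_sd=0.5, seed=11)
        )
        records = pairwise_gene_correlation(cohort.cna, cohort.mrna)
        res = select_correlated_genes(records)
        recovered = set(res.selected) & set(truth.cnacor_genes)
        assert len(recovered) >= 45

    def test_closed_form_coupling_r(self):
        cohort, truth = generate_cohort(
            SimulationParams(n_samples=500, n_genes=150, n_cnacor=60, n_metcor=0,
                             n_prognostic=0, frac_subgroup_informative=0.0,
                             subgroup_effect=0.0, coupling_slope=1.0,
                             coupling_noise_sd=0.5, seed=5)
        )
        records = {r.gene: r for r in pairwise_gene_correlation(cohort.cna, cohort.mrna)}
        rs = [records[g].r for g in truth.cnacor_genes]
        assert truth.expected_coupling_r == pytest.approx(1 / np.sqrt(1.25))
        assert np.mean(rs) == pytest.approx(truth.expected_coupling_r, abs=0.02)

    def test_skew_computed_on_selected_z_only(self, rng):
        from triomics.genecor import GeneCorrelationRecord

        sig = [GeneCorrelationRecord(f"S{i}", r, 0.01) for i, r in
               enumerate(rng.uniform(0.3, 0.9, size=30))]
        insig = [GeneCorrelationRecord(f"N{i}", -0.9, 0.9) for i in range(30)]
        res = select_correlated_genes(sig + insig)
        expected_skew, expected_p = skewness_test([fisher_z(r.r) for r in sig])
        assert res.skewness == pytest.approx(expected_skew)
        assert res.skew_p == pytest.approx(expected_p)


class TestIntersectGeneSets:
    def test_basic(self):
        shared, n = intersect_gene_sets({"A", "B", "C"}, {"B", "C", "D"})
        assert shared == {"B", "C"} and n == 2

    def test_disjoint(self):
        shared, n = intersect_gene_sets({"A"}, {"B"})
        assert shared == set() and n == 0

    def test_planted_double_coupled_recovery(self):
        # genes coupled to CNA whose expression is also significantly
        # (anti-)correlated with an independent MET profile cannot be planted
        # directly; instead intersect two selections over the same cohort and
        # check the planted coupled genes dominate both when slopes are strong
        cohort, truth = generate_cohort(
            SimulationParams(n_samples=300, n_genes=100, n_cnacor=10, n_metcor=10,
                             n_prognostic=0, frac_subgroup_informative=0.0,
                             subgroup_effect=0.0, seed=13)
        )
        cna_sel = select_correlated_genes(pairwise_gene_correlation(cohort.cna, cohort.mrna))
        met_sel = select_correlated_genes(pairwise_gene_correlation(cohort.met, cohort.mrna))
        assert len(set(cna_sel.selected) & set(truth.cnacor_genes)) >= 8
        assert len(set(met_sel.selected) & set(truth.metcor_genes)) >= 8
        _, n_shared = intersect_gene_sets(cna_sel.selected, met_sel.selected)
        assert n_shared <= 10  # coupled sets are disjoint; overlap is chance only


def test_global_null_invariants(rng):
    """Under a global null, ~5% of genes significant and skew test well-behaved."""
    x = make_matrix(rng.normal(size=(2000, 60)))
    y = make_matrix(rng.normal(size=(2000, 60)))
    records = pairwise_gene_correlation(x, y)
    res = select_correlated_genes(records)
    frac = len(res.selected) / len(records)
    assert frac == pytest.approx(0.05, abs=0.01)
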