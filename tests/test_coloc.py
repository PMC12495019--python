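"""Tests of pixelwise and compartmental colocalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from epifocal import coloc, phantom


class TestCorrelation:
    def test_affine_relation(self):
        x = np.arange(10.0)
        assert coloc.correlation(x, 2 * x + 1) == pytest.approx(1.0)
        assert coloc.correlation(x, 2 * x + 1, "spearman") == pytest.approx(1.0)

    def test_monotone_nonlinear(self):
        x = np.linspace(-2, 2, 21)
        y = x**3
        assert coloc.correlation(x, y, "spearman") == pytest.approx(1.0)
        assert coloc.correlation(x, y) < 1.0

    def test_matches_textbook_formula(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0, 5.0, 3.0])
        y = np.array([2.0, 7.0, 1.0, 8.0, 2.0, 8.0, 1.0, 8.0, 2.0, 8.0])
        num = ((x - x.mean()) * (y - y.mean())).sum()
        den = np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert coloc.correlation(x, y) == pytest.approx(num / den, abs=1e-12)

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError, match="zero variance"):
            coloc.correlation(np.ones(5), np.arange(5.0))

    def test_pcc_affine_invariance_srcc_monotone_invariance(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 10, 200)
        y = rng.uniform(0, 10, 200)
        base_p = coloc.correlation(x, y)
        base_s = coloc.correlation(x, y, "spearman")
        assert coloc.correlation(3 * x + 2, y) == pytest.approx(base_p, abs=1e-12)
        assert coloc.correlation(np.exp(x), y, "spearman") == pytest.approx(
            base_s, abs=1e-12
        )


class TestTileShuffle:
    def test_identical_images_give_minimal_p(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 1, (32, 32))
        r, p = coloc.tile_shuffle_test(img, img, n_perm=99, seed=1)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1.0 / 100.0)

    def test_single_tile_rejected(self):
        img = np.random.default_rng(0).uniform(0, 1, (8, 8))
        with pytest.raises(ValueError, match="tile"):
            coloc.tile_shuffle_test(img, img, tile=8, n_perm=99)

    def test_too_few_permutations_rejected(self):
        img = np.random.default_rng(0).uniform(0, 1, (32, 32))
        with pytest.raises(ValueError, match="n_perm"):
            coloc.tile_shuffle_test(img, img, n_perm=10)

    def test_observed_r_matches_direct_pcc(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(0, 1, (40, 40))
        b = rng.uniform(0, 1, (40, 40))
        r, _ = coloc.tile_shuffle_test(a, b, n_perm=19, seed=0)
        assert r == pytest.approx(np.corrcoef(a.ravel(), b.ravel())[0, 1],
                                  abs=1e-10)

    def test_correlated_pair_detected(self):
        a, b = phantom.make_correlated_pair(0.6, (64, 64), 3)
        _, p = coloc.tile_shuffle_test(a, b, n_perm=99, seed=0)
        assert p <= 0.05


class TestPercentilePairing:
    def test_identity_pair_lies_on_diagonal(self):
        img = np.random.default_rng(0).uniform(0, 1, (32, 32))
        curve = coloc.percentile_pairing(img, img, np.linspace(1, 99, 50))
        np.testing.assert_allclose(curve[:, 0], curve[:, 1])

    def test_scaling_equivariance(self):
        img = np.random.default_rng(1).lognormal(0, 1, (32, 32))
        curve = coloc.percentile_pairing(img, 2 * img, np.linspace(1, 99, 50))
        np.testing.assert_allclose(curve[:, 1], 2 * curve[:, 0], rtol=1e-12)

    def test_matches_per_quantile_oracle(self):
        rng = np.random.default_rng(2)
        a = rng.lognormal(0, 1, 1000)
        b = rng.uniform(0, 5, 1000)
        grid = np.array([10.0, 50.0, 90.0, 99.0])
        curve = coloc.percentile_pairing(a, b, grid)
        for i, q in enumerate(grid):
            assert curve[i, 0] == pytest.approx(np.percentile(a, q))
            assert curve[i, 1] == pytest.approx(np.percentile(b, q))

    def test_monotone_curve(self):
        rng = np.random.default_rng(3)
        curve = coloc.percentile_pairing(
            rng.normal(size=500), rng.normal(size=500), np.linspace(1, 99, 99)
        )
        assert np.all(np.diff(curve[:, 0]) >= 0)
        assert np.all(np.diff(curve[:, 1]) >= 0)


def _two_population_pair(seed=2, h=128):
    """Uncorrelated dim background plus a correlated bright foreground."""
    rng = np.random.default_rng(seed)
    fg = np.zeros((h, h), bool)
    fg[h // 4 : 3 * h // 4, h // 4 : 3 * h // 4] = True
    x = rng.normal(0, 1, (h, h))
    a = np.where(fg, 120 + 20 * x + rng.normal(0, 5, (h, h)),
                 rng.normal(20, 5, (h, h)))
    b = np.where(fg, 120 + 20 * x + rng.normal(0, 5, (h, h)),
                 rng.normal(20, 5, (h, h)))
    return a, b, fg


class TestCostes:
    def test_two_population_phantom_recovered(self):
        a, b, fg = _two_population_pair()
        res = coloc.costes_thresholds(a, b)
        assert res.converged
        assert (res.m_co & fg).sum() >= 0.95 * fg.sum()
        assert res.pcc_outside <= 0.02

    def test_stopping_contract(self):
        a, b, _ = _two_population_pair(seed=9)
        res = coloc.costes_thresholds(a, b)
        outside = (a <= res.th_a) | (b <= res.th_b)
        r = np.corrcoef(a[outside], b[outside])[0, 1]
        assert r <= 0.02

    def test_independent_images_degenerate_with_warning(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(0, 1, (64, 64))
        b = rng.uniform(0, 1, (64, 64))
        # independent noise: outside PCC hovers near zero and crosses
        # immediately, or never stays positive; both accepted behaviors
        res = coloc.costes_thresholds(a, b)
        assert res.quantile >= 0.0

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            coloc.costes_thresholds(np.ones((8, 8)), np.random.rand(8, 8))


class TestManders:
    def test_full_mask_gives_one(self):
        a = np.random.default_rng(0).uniform(1, 2, (16, 16))
        b = np.random.default_rng(1).uniform(1, 2, (16, 16))
        m1, m2 = coloc.manders(a, b, np.ones((16, 16), bool))
        assert m1 == 1.0 and m2 == 1.0

    def test_empty_mask_gives_zero(self):
        a = np.random.default_rng(0).uniform(1, 2, (16, 16))
        m1, m2 = coloc.manders(a, a, np.zeros((16, 16), bool))
        assert m1 == 0.0 and m2 == 0.0

    def test_hand_summed_toy_example(self):
        a = np.array([[1.0, 2.0], [3.0, 4.0]])
        b = np.array([[4.0, 3.0], [2.0, 1.0]])
        mask = np.array([[True, False], [False, True]])
        m1, m2 = coloc.manders(a, b, mask)
        assert m1 == pytest.approx((1 + 4) / 10)
        assert m2 == pytest.approx((4 + 1) / 10)

    def test_zero_intensity_flagged(self):
        with pytest.raises(ValueError):
            coloc.manders(np.zeros((4, 4)), np.ones((4, 4)),
                          np.ones((4, 4), bool))

    @given(th=st.floats(min_value=0.0, max_value=1.0))
    @settings(deadline=None, max_examples=25)
    def test_m1_monotone_in_threshold(self, th):
        rng = np.random.default_rng(7)
        a = rng.uniform(0, 1, (32, 32))
        b = rng.uniform(0, 1, (32, 32))
        m_lo = (a > th * 0.5) & (b > 0.2)
        m_hi = (a > th) & (b > 0.2)
        m1_lo, _ = coloc.manders(a, b, m_lo)
        m1_hi, _ = coloc.manders(a, b, m_hi)
        assert 0.0 <= m1_hi <= m1_lo <= 1.0


class TestMaskedCorrelation:
    def test_full_mask_equals_unmasked(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 1, (24, 24))
        b = rng.uniform(0, 1, (24, 24))
        pcc, srcc = coloc.masked_correlation(a, b, np.ones((24, 24), bool))
        assert pcc == pytest.approx(coloc.correlation(a, b))
        assert srcc == pytest.approx(coloc.correlation(a, b, "spearman"))

    def test_correlated_subregion_found(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 1, (32, 32))
        b = rng.uniform(0, 1, (32, 32))
        mask = np.zeros((32, 32), bool)
        mask[:8] = True
        b[:8] = 2 * a[:8] + 0.5  # perfect correlation inside the mask
        pcc, _ = coloc.masked_correlation(a, b, mask)
        assert pcc == pytest.approx(1.0)
        assert abs(coloc.correlation(a, b)) < 0.9

    def test_tiny_mask_rejected(self):
        with pytest.raises(ValueError):
            coloc.masked_correlation(np.ones((4, 4)), np.ones((4, 4)),
                                     np.zeros((4, 4), bool))


class TestNuclearFractions:
    def _table(self, a_nuc, a_cyt):
        return pd.DataFrame(
            {"cell_id": range(1, len(a_nuc) + 1),
             "a_nuc_mean": a_nuc, "a_cyt_mean": a_cyt,
             "b_nuc_mean": a_nuc, "b_cyt_mean": a_cyt}
        )

    def test_equal_compartments_give_half(self):
        t = coloc.nuclear_fractions(self._table([5.0], [5.0]))
        assert t["a_nucfr"].iloc[0] == pytest.approx(0.5)

    def test_extremes(self):
        t = coloc.nuclear_fractions(self._table([0.0, 3.0], [4.0, 0.0]))
        assert t["a_nucfr"].iloc[0] == 0.0
        assert t["a_nucfr"].iloc[1] == 1.0

    def test_phantom_truth_fractions(self, flat_truth):
        t = coloc.nuclear_fractions(flat_truth.true_compartment_means)
        expect = phantom.NUCLEAR_RETENTION / (1 + phantom.NUCLEAR_RETENTION)
        np.testing.assert_allclose(t["a_nucfr"], expect, rtol=1e-12)
        np.testing.assert_allclose(t["b_nucfr"], expect, rtol=1e-12)


class TestCompartmentCorrelations:
    def test_proportional_channels_give_unit_pcc(self):
        rng = np.random.default_rng(3)
        a_nuc = rng.uniform(10, 30, 40)
        a_cyt = rng.uniform(50, 150, 40)
        table = pd.DataFrame(
            {"cell_id": range(1, 41), "a_nuc_mean": a_nuc, "a_cyt_mean": a_cyt,
             "b_nuc_mean": 2 * a_nuc, "b_cyt_mean": 2 * a_cyt}
        )
        res = coloc.compartment_correlations(table)
        direct = res[(res.x == "a_nuc_mean") & (res.y == "b_nuc_mean")].iloc[0]
        assert direct.pcc == pytest.approx(1.0)
        cytcyt = res[(res.x == "a_cyt_mean") & (res.y == "b_cyt_mean")].iloc[0]
        assert cytcyt.pcc == pytest.approx(1.0)

    def test_orthogonal_regression_exact_line(self):
        x = np.linspace(1, 10, 50)
        slope, intercept = coloc.orthogonal_regression(x, 3 * x)
        assert slope == pytest.approx(3.0, abs=1e-10)
        assert intercept == pytest.approx(0.0, abs=1e-9)

    def test_coefficients_match_columnwise_oracle(self):
        rng = np.random.default_rng(11)
        table = pd.DataFrame(
            {"cell_id": range(1, 31),
             "a_nuc_mean": rng.uniform(10, 30, 30),
             "a_cyt_mean": rng.uniform(50, 150, 30),
             "b_nuc_mean": rng.uniform(10, 30, 30),
             "b_cyt_mean": rng.uniform(50, 150, 30)}
        )
        res = coloc.compartment_correlations(table)
        for _, row in res.iterrows():
            x = (coloc.nuclear_fractions(table))[row.x]
            y = (coloc.nuclear_fractions(table))[row.y]
            assert row.pcc == pytest.approx(coloc.correlation(x, y), abs=1e-12)
            assert row.srcc == pytest.approx(
                coloc.correlation(x, y, "spearman"), abs=1e-12
            )


class TestHnfAnalysis:
    def _table(self, nucfr_b, a_cyt):
        n = len(nucfr_b)
        nucfr_b = np.asarray(nucfr_b, float)
        return pd.DataFrame(
            {"cell_id": range(1, n + 1),
             "a_nuc_mean": np.full(n, 10.0), "a_cyt_mean": a_cyt,
             "b_nuc_mean": nucfr_b, "b_cyt_mean": 1 - nucfr_b}
        )

    def test_no_hnf_cells_skips(self):
        rng = np.random.default_rng(0)
        t = self._table(np.full(20, 0.2), rng.uniform(90, 110, 20))
        res = coloc.hnf_analysis(t)
        assert not res.performed
        assert res.n_hnf == 0
        assert "HNF=0" in res.reason

    def test_doubled_cytoplasmic_a_gives_plus_100_percent(self):
        rng = np.random.default_rng(1)
        lnf = rng.uniform(99, 101, 20)
        hnf = 2 * lnf[:10] + (lnf[:10] - lnf[:10].mean())  # exactly 2x mean
        nucfr = np.concatenate([np.full(10, 0.8), np.full(20, 0.2)])
        a_cyt = np.concatenate([hnf, lnf])
        t = self._table(nucfr, a_cyt)
        res = coloc.hnf_analysis(t)
        assert res.performed
        assert res.percent_difference == pytest.approx(
            100.0 * (a_cyt[:10].mean() - lnf.mean()) / lnf.mean()
        )

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            coloc.hnf_analysis(self._table([0.5], [1.0]), nucfr_threshold=1.5)

    def test_null_table_calibration(self):
        """With no group effect, significant calls occur at roughly alpha."""
        hits = 0
        runs = 200
        for i in range(runs):
            rng = np.random.default_rng(i)
            nucfr = rng.uniform(0, 1, 40)
            a_cyt = rng.normal(100, 10, 40)  # independent of nucfr
            res = coloc.hnf_analysis(self._table(nucfr, a_cyt))
            if res.performed and res.p <= 0.05:
                hits += 1
        assert 0.01 <= hits / runs <= 0.10
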