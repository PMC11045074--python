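"""Δ longitude, rank test, tail quantile regression, ECDF comparison."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import kinlod as kl
from kinlod import spatial_stats as sp

from .oracles import wilcoxon_exact_two_sided


def _pair(dlon, same_day=False, lod_hs=0.0, ml="U", ids=("A", "B")):
    return sp.SpatialPair(ids[0], ids[1], dlon, same_day, lod_hs, float("nan"), ml)


def _pairs_from_values(values, ml, rng=None):
    return [_pair(v, ml=ml, ids=(f"{ml}{i}a", f"{ml}{i}b")) for i, v in enumerate(values)]


class TestDeltaLongitude:
    def test_published_style_coordinates(self):
        assert sp.delta_longitude(95.94, 108.86) == pytest.approx(12.92)

    def test_antimeridian_wraparound(self):
        assert sp.delta_longitude(-170.0, 170.0) == pytest.approx(20.0)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.floats(-180.0, 180.0, exclude_min=True),
           st.floats(-180.0, 180.0, exclude_min=True))
    def test_always_in_range(self, l1, l2):
        d = sp.delta_longitude(l1, l2)
        assert 0.0 <= d <= 180.0
        assert d == pytest.approx(sp.delta_longitude(l2, l1))


@pytest.fixture(scope="module")
def spatial(fixture_run):
    return sp.make_spatial_pairs(fixture_run["dedup"].unique_individuals,
                                 fixture_run["scores"])


class TestMakeSpatialPairs:
    def test_same_day_same_vessel_flag(self, fixture_run):
        """Planted mother-calf events share date and vessel."""
        pairs = sp.make_spatial_pairs(fixture_run["dedup"].unique_individuals,
                                      fixture_run["scores"], exclude_field_mc=False)
        by_ids = {tuple(sorted((p.id_i, p.id_j))): p for p in pairs}
        for mc in fixture_run["bundle"].mc_pairs:
            assert by_ids[tuple(sorted(mc))].same_day_pos

    def test_field_mc_pairs_dropped_by_default(self, fixture_run, spatial):
        ids = {tuple(sorted((p.id_i, p.id_j))) for p in spatial}
        for mc in fixture_run["bundle"].mc_pairs:
            assert tuple(sorted(mc)) not in ids

    def test_sector_filter_restricts_both_members(self, fixture_run):
        inside = sp.make_spatial_pairs(fixture_run["dedup"].unique_individuals,
                                       fixture_run["scores"], sector_filter=(85, 135))
        by_id = {r.sample_id: r for r in fixture_run["dedup"].unique_individuals}
        for p in inside:
            assert 85 <= by_id[p.id_i].lon <= 135
            assert 85 <= by_id[p.id_j].lon <= 135
        assert len(inside) < len(sp.make_spatial_pairs(
            fixture_run["dedup"].unique_individuals, fixture_run["scores"]))


class TestWilcoxon:
    def test_identical_groups_p_one(self):
        values = list(range(1, 9))
        pairs = _pairs_from_values(values, "PO") + _pairs_from_values(values, "U")
        res = sp.wilcoxon_delta_lon(pairs)
        assert res.method == "exact"
        assert res.pvalue == pytest.approx(1.0)

    def test_small_sample_exact_enumeration(self):
        pairs = _pairs_from_values([1, 2], "PO") + _pairs_from_values([3, 4], "U")
        res = sp.wilcoxon_delta_lon(pairs)
        assert res.method == "exact"
        assert res.pvalue == pytest.approx(1 / 3)
        assert res.pvalue == pytest.approx(wilcoxon_exact_two_sided([1, 2], [3, 4]))

    def test_large_groups_use_asymptotic(self):
        rng = np.random.default_rng(2)
        pairs = _pairs_from_values(rng.uniform(0, 50, 30), "PO") + \
            _pairs_from_values(rng.uniform(0, 50, 200), "U")
        assert sp.wilcoxon_delta_lon(pairs).method == "asymptotic"

    def test_empty_group_not_testable(self):
        pairs = _pairs_from_values([1, 2, 3], "U")
        res = sp.wilcoxon_delta_lon(pairs)
        assert not res.testable

    def test_power_against_shifted_po_pairs(self):
        """PO pairs drawn 20 degrees closer reject at alpha=0.05 most runs."""
        rejections = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            u = np.abs(rng.uniform(0, 50, 3000))
            po = np.abs(rng.uniform(0, 50, 60) - 20.0)
            pairs = _pairs_from_values(u, "U") + _pairs_from_values(po, "PO")
            if sp.wilcoxon_delta_lon(pairs).pvalue < 0.05:
                rejections += 1
        assert rejections / n_seeds > 0.8

    def test_type_i_error_near_nominal_under_null(self):
        """Kinship independent of geography: rejection rate ~ alpha."""
        alpha, reps = 0.05, 600
        rejections = 0
        for seed in range(reps):
            rng = np.random.default_rng(20000 + seed)
            u = rng.uniform(0, 50, 200)
            po = rng.uniform(0, 50, 20)
            pairs = _pairs_from_values(u, "U") + _pairs_from_values(po, "PO")
            if sp.wilcoxon_delta_lon(pairs).pvalue < alpha:
                rejections += 1
        rate = rejections / reps
        se = math.sqrt(alpha * (1 - alpha) / reps)
        assert abs(rate - alpha) < 4 * se


class TestQuantileRegression:
    def test_intercept_only_equals_empirical_quantile(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=200)
        pairs = [_pair(0.0, False, lod_hs=v, ids=(f"A{i}", f"B{i}"))
                 for i, v in enumerate(y)]
        fits = sp.quantile_regression(pairs, [0.5, 0.9, 0.95], n_boot=10, seed=0)
        for fit in fits:
            assert fit.terms == ("intercept",)
            expected = np.quantile(y, fit.tau, method="inverted_cdf")
            assert fit.coef["intercept"] == pytest.approx(expected, abs=1e-8)

    def test_intercept_only_residual_sign_balance(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=157)
        pairs = [_pair(0.0, False, lod_hs=v, ids=(f"A{i}", f"B{i}"))
                 for i, v in enumerate(y)]
        for fit in sp.quantile_regression(pairs, [0.25, 0.5, 0.9], n_boot=5, seed=0):
            q = fit.coef["intercept"]
            assert (y < q).mean() <= fit.tau <= (y <= q).mean()

    def test_noiseless_linear_response_recovered_at_every_tau(self):
        rng = np.random.default_rng(5)
        dlon = rng.uniform(0, 50, 300)
        same = rng.random(300) < 0.3
        y = 2.0 + 1.5 * same - 0.1 * dlon
        pairs = [_pair(d, bool(s), lod_hs=v, ids=(f"A{i}", f"B{i}"))
                 for i, (d, s, v) in enumerate(zip(dlon, same, y))]
        for fit in sp.quantile_regression(pairs, [0.3, 0.7, 0.95], n_boot=5, seed=0):
            assert fit.coef["intercept"] == pytest.approx(2.0, abs=1e-4)
            assert fit.coef["same_day_pos"] == pytest.approx(1.5, abs=1e-4)
            assert fit.coef["delta_lon"] == pytest.approx(-0.1, abs=1e-6)

    def test_full_model_residual_sign_balance_within_rank_slack(self):
        rng = np.random.default_rng(6)
        n = 400
        dlon = rng.uniform(0, 50, n)
        same = rng.random(n) < 0.2
        y = -5 + 0.02 * dlon + rng.normal(scale=2, size=n)
        pairs = [_pair(d, bool(s), lod_hs=v, ids=(f"A{i}", f"B{i}"))
                 for i, (d, s, v) in enumerate(zip(dlon, same, y))]
        p = 3  # fitted parameters; sign balance holds up to p/n
        for fit in sp.quantile_regression(pairs, [0.5, 0.9], n_boot=5, seed=0):
            resid = y - (fit.coef["intercept"] + fit.coef["same_day_pos"] * same
                         + fit.coef["delta_lon"] * dlon)
            assert (resid < 0).mean() <= fit.tau + p / n
            assert (resid <= 0).mean() >= fit.tau - p / n

    def test_bootstrap_bands_seed_reproducible(self):
        pairs = kl.planted_tail_shift_pairs(9, n=500)
        a = sp.quantile_regression(pairs, [0.9], n_boot=50, seed=7)[0]
        b = sp.quantile_regression(pairs, [0.9], n_boot=50, seed=7)[0]
        assert a == b

    def test_planted_tail_shift_detected_only_in_tail(self):
        """SameDayPos effect: band excludes 0 near 0.95, includes it at 0.90."""
        pairs = kl.planted_tail_shift_pairs(2026)
        fits = {f.tau: f for f in sp.quantile_regression(
            pairs, [0.90, 0.95], n_boot=150, seed=1)}
        assert fits[0.95].band_excludes_zero("same_day_pos")
        assert not fits[0.90].band_excludes_zero("same_day_pos")

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            sp.quantile_regression([_pair(1.0)] * 5, [0.9])


class TestECDF:
    def test_identical_strata_identical_ecdfs(self):
        values = np.linspace(-5, 5, 40)
        pairs = [_pair(0.0, True, lod_hs=v, ids=(f"A{i}", f"B{i}"))
                 for i, v in enumerate(values)]
        pairs += [_pair(0.0, False, lod_hs=v, ids=(f"C{i}", f"D{i}"))
                  for i, v in enumerate(values)]
        comp = sp.ecdf_compare(pairs)
        grid = np.linspace(-6, 6, 30)
        assert np.allclose(comp.evaluate("same_day_pos", grid),
                           comp.evaluate("other", grid))

    def test_shift_equivariance(self):
        rng = np.random.default_rng(8)
        base = rng.normal(size=60)
        c = 1.7
        pairs = [_pair(0.0, False, lod_hs=v, ids=(f"A{i}", f"B{i}"))
                 for i, v in enumerate(base)]
        pairs += [_pair(0.0, True, lod_hs=v + c, ids=(f"C{i}", f"D{i}"))
                  for i, v in enumerate(base)]
        comp = sp.ecdf_compare(pairs)
        grid = np.linspace(-3, 3, 25)
        assert np.allclose(comp.evaluate("other", grid),
                           comp.evaluate("same_day_pos", grid + c))

    def test_planted_effect_visible_in_upper_tail(self):
        pairs = kl.planted_tail_shift_pairs(12, n=4000)
        comp = sp.ecdf_compare(pairs, reference_lod=1.8)
        # around the upper tail the SameDayPos ECDF lies below the other
        grid = np.linspace(-3.0, 0.0, 10)  # the shifted region of the base normal
        upper = np.quantile(comp.strata["other"], [0.93, 0.95, 0.97])
        assert np.all(comp.evaluate("same_day_pos", upper)
                      <= comp.evaluate("other", upper) + 1e-9)
        assert comp.evaluate("same_day_pos", upper[1]) < comp.evaluate("other", upper[1])

    def test_empty_stratum_single_ecdf(self):
        pairs = [_pair(0.0, False, lod_hs=float(i), ids=(f"A{i}", f"B{i}"))
                 for i in range(5)]
        comp = sp.ecdf_compare(pairs)
        assert set(comp.strata) == {"other"}
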