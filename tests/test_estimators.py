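"""Product-moment correlation, eta and the two-predictor multiple R."""

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

import dircorr as dc
from dircorr import G_GIVEN_X, X_GIVEN_G, PairedSeries


def r3(v: float) -> float:
    """Half-even rounding to 3 decimals, as used for printed comparisons."""
    return float(np.round(v, 3))


class TestPMC:
    @pytest.mark.parametrize(
        "item, expected",
        [("A1", 0.759), ("A2", 0.721), ("A3", 0.117),
         ("B1", 0.747), ("B2", 0.603), ("B3", 0.610)],
    )
    def test_worked_example_item_score_correlations(self, pairs, item, expected):
        assert r3(dc.pmc(pairs[item]).value) == expected

    def test_matches_numpy_corrcoef(self, pairs):
        for pair in pairs.values():
            expected = np.corrcoef(pair.g, pair.x)[0, 1]
            assert dc.pmc(pair).value == pytest.approx(expected, abs=1e-12)

    def test_symmetric_in_arguments(self, pairs):
        p = pairs["B1"]
        swapped = PairedSeries(p.x.astype(int), p.g.astype(float))
        assert dc.pmc(swapped).value == pytest.approx(dc.pmc(p).value, abs=1e-12)

    def test_self_correlation_is_one(self):
        x = np.array([1, 4, 2, 8, 5])
        assert dc.pmc(PairedSeries(x, x.astype(float))).value == pytest.approx(1.0)

    def test_affine_invariance_of_score(self, pairs):
        p = pairs["B2"]
        shifted = PairedSeries(p.g, 3.5 * p.x + 11.0)
        assert dc.pmc(shifted).value == pytest.approx(dc.pmc(p).value, abs=1e-12)

    def test_constant_variable_raises(self):
        with pytest.raises(dc.DegenerateInputError):
            dc.pmc(PairedSeries(np.zeros(5, dtype=int), np.arange(5.0)))


class TestPointBiserial:
    def test_equals_pmc_on_worked_example(self, pairs):
        assert r3(dc.point_biserial(pairs["A1"]).value) == 0.759

    def test_reverse_coding_flips_sign(self, pairs):
        p = pairs["A1"]
        flipped = PairedSeries(1 - p.g, p.x)
        assert dc.point_biserial(flipped).value == pytest.approx(
            -dc.point_biserial(p).value, abs=1e-12
        )

    def test_equals_pmc_on_random_binary_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            g = rng.integers(0, 2, size=25)
            x = rng.normal(size=25) + g
            if np.ptp(g) == 0:
                continue
            pair = PairedSeries(g, x)
            assert abs(
                dc.point_biserial(pair).value - dc.pmc(pair).value
            ) < 1e-12

    def test_rejects_polytomous_item(self, pairs):
        with pytest.raises(dc.InvalidInputError):
            dc.point_biserial(pairs["B1"])


class TestEta:
    @pytest.mark.parametrize(
        "item, expected",
        [("A1", 0.759), ("A2", 0.721), ("A3", 0.117),
         ("B1", 0.820), ("B2", 0.606), ("B3", 0.614)],
    )
    def test_g_given_X_direction(self, pairs, item, expected):
        assert r3(dc.eta(pairs[item], G_GIVEN_X).value) == expected

    @pytest.mark.parametrize(
        "item, expected",
        [("A1", 1.0), ("A2", 1.0), ("A3", 0.856),
         ("B1", 1.0), ("B2", 1.0), ("B3", 0.985)],
    )
    def test_X_given_g_direction(self, pairs, item, expected):
        assert r3(dc.eta(pairs[item], X_GIVEN_G).value) == expected

    def test_directions_differ_on_polytomous_item(self, pairs):
        e1 = dc.eta(pairs["B1"], G_GIVEN_X).value
        e2 = dc.eta(pairs["B1"], X_GIVEN_G).value
        assert abs(e1 - e2) > 0.1

    @pytest.mark.parametrize("item, expected", [("B1", 0.672), ("A1", 0.577)])
    def test_eta_squared_explained_variance(self, pairs, item, expected):
        # Full-precision A1 eta is 0.75947, whose square rounds to 0.577;
        # squaring the 3-decimal display value 0.759 gives 0.576 instead.
        assert r3(dc.eta_squared(pairs[item], G_GIVEN_X)) == expected

    def test_eta_squared_equals_square_of_eta(self, pairs):
        for pair in pairs.values():
            assert dc.eta_squared(pair, G_GIVEN_X) == pytest.approx(
                dc.eta(pair, G_GIVEN_X).value ** 2, abs=1e-12
            )

    def test_constant_grouping_gives_zero(self):
        pair = PairedSeries(np.zeros(6, dtype=int), np.arange(6.0))
        assert dc.eta(pair, G_GIVEN_X).value == 0.0

    def test_perfect_group_separation_gives_one(self):
        pair = PairedSeries(np.array([0, 0, 1, 1]), np.array([1.0, 1, 5, 5]))
        assert dc.eta_squared(pair, G_GIVEN_X) == pytest.approx(1.0)

    def test_eta_squared_matches_f_oneway_oracle(self):
        from scipy.stats import f_oneway

        rng = np.random.default_rng(11)
        for _ in range(100):
            g = rng.integers(0, 4, size=40)
            x = rng.normal(size=40) + 0.7 * g
            if len(np.unique(g)) < 2:
                continue
            pair = PairedSeries(g, x)
            groups = [x[g == v] for v in np.unique(g)]
            f = f_oneway(*groups).statistic
            df1 = len(groups) - 1
            df2 = len(x) - len(groups)
            expected = df1 * f / (df1 * f + df2)
            assert dc.eta_squared(pair, G_GIVEN_X) == pytest.approx(
                expected, abs=1e-10
            )


class TestEtaSigned:
    def test_positive_on_worked_example(self, pairs):
        assert r3(dc.eta_signed(pairs["A1"]).value) == 0.759

    def test_reverse_coded_binary_item_is_negative(self, pairs):
        p = pairs["A1"]
        flipped = PairedSeries(1 - p.g, p.x)
        assert r3(dc.eta_signed(flipped).value) == -0.759

    def test_near_zero_under_independence(self):
        rng = np.random.default_rng(3)
        pair = PairedSeries(rng.integers(0, 2, 10_000), rng.normal(size=10_000))
        assert abs(dc.eta_signed(pair).value) < 0.05

    def test_polytomous_sign_follows_pmc(self, pairs):
        p = pairs["B1"]
        flipped = PairedSeries(p.g.max() - p.g, p.x)
        assert dc.eta_signed(flipped).value == pytest.approx(
            -dc.eta(p, G_GIVEN_X).value, abs=1e-12
        )


class TestSSDecomposition:
    def test_item_a3_grouped_by_score(self, pairs):
        p = pairs["A3"]
        dec = dc.ss_decomposition(p, X_GIVEN_G)
        assert dec.ss_total == pytest.approx(3.75)
        assert dec.ss_within == pytest.approx(1.0)
        assert dec.ss_between == pytest.approx(2.75)

    def test_single_group_puts_everything_within(self):
        pair = PairedSeries(np.ones(5, dtype=int), np.arange(5.0))
        dec = dc.ss_decomposition(pair, G_GIVEN_X)
        assert dec.ss_between == 0.0
        assert dec.ss_within == pytest.approx(dec.ss_total)

    def test_additivity_on_random_data(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            g = rng.integers(0, 5, size=30)
            x = rng.normal(size=30)
            dec = dc.ss_decomposition(PairedSeries(g, x), G_GIVEN_X)
            assert dec.ss_between + dec.ss_within == pytest.approx(
                dec.ss_total, rel=1e-9
            )


class TestBinaryEquivalenceAndInequality:
    """The algebraic backbone: |PMC| = eta(g|X) for binary g, <= in general."""

    def test_binary_equivalence_1000_datasets(self):
        rng = np.random.default_rng(21)
        checked = 0
        while checked < 1000:
            g = rng.integers(0, 2, size=rng.integers(5, 40))
            x = rng.normal(size=len(g)) + rng.uniform(0, 2) * g
            if np.ptp(g) == 0 or np.ptp(x) == 0:
                continue
            pair = PairedSeries(g, x)
            assert abs(
                abs(dc.pmc(pair).value) - dc.eta(pair, G_GIVEN_X).value
            ) < 1e-12
            checked += 1

    def test_pmc_bounded_by_eta_1000_polytomous_datasets(self):
        rng = np.random.default_rng(22)
        checked = 0
        while checked < 1000:
            g = rng.integers(0, rng.integers(3, 8), size=rng.integers(6, 40))
            x = rng.normal(size=len(g)) + rng.uniform(-1, 2) * g
            if len(np.unique(g)) < 2 or np.ptp(x) == 0:
                continue
            pair = PairedSeries(g, x)
            assert abs(dc.pmc(pair).value) <= dc.eta(pair, G_GIVEN_X).value + 1e-12
            checked += 1


class TestMultipleR:
    def test_printed_correlation_triple(self):
        r = dc.multiple_r_two_predictors(0.66055, 0.66055, 0.25313)
        assert r3(r) == 0.834
        assert r3(r**2) == 0.696

    def test_single_informative_predictor(self):
        assert dc.multiple_r_two_predictors(-0.4, 0.0, 0.0) == pytest.approx(0.4)

    def test_matches_least_squares_on_simulated_data(self):
        rng = np.random.default_rng(8)
        n = 500
        x = rng.normal(size=n)
        z = 0.4 * x + rng.normal(size=n)
        y = 0.5 * x - 0.3 * z + rng.normal(size=n)
        r_yx = np.corrcoef(y, x)[0, 1]
        r_yz = np.corrcoef(y, z)[0, 1]
        r_xz = np.corrcoef(x, z)[0, 1]
        design = np.column_stack([np.ones(n), x, z])
        fitted = design @ np.linalg.lstsq(design, y, rcond=None)[0]
        r_direct = np.corrcoef(y, fitted)[0, 1]
        assert dc.multiple_r_two_predictors(r_yx, r_yz, r_xz) == pytest.approx(
            r_direct, abs=1e-10
        )

    def test_collinear_predictors_rejected(self):
        with pytest.raises(dc.CollinearPredictorsError):
            dc.multiple_r_two_predictors(0.5, 0.5, 1.0)

    def test_non_psd_triple_rejected(self):
        with pytest.raises(dc.InvalidInputError):
            dc.multiple_r_two_predictors(0.9, -0.9, 0.9)

    @given(st.floats(-0.7, 0.7), st.floats(-0.7, 0.7))
    @settings(max_examples=50, deadline=None)
    def test_at_least_as_large_as_either_predictor_alone(self, r_yx, r_yz):
        assume(r_yx**2 + r_yz**2 <= 1.0)
        r = dc.multiple_r_two_predictors(r_yx, r_yz, 0.0)
        assert r >= max(abs(r_yx), abs(r_yz)) - 1e-12
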