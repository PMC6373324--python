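import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from arcseg import (
    ArcCurve,
    IdealizedArcCurve,
    SubseqParams,
    compute_arc_curve,
    compute_cac,
    extract_regimes,
    fluss,
    fuse_cacs,
    idealized_arc_curve,
    make_regime_series,
    RegimeSpec,
)
from arcseg.segmentation import _null_arc_curve_bidirectional

from oracles import naive_crossing_counts


class TestArcCurve:
    def test_two_mutual_arcs(self):
        np.testing.assert_array_equal(compute_arc_curve([1, 0], 2).counts, [2, 0])

    def test_crossing_example(self):
        np.testing.assert_array_equal(
            compute_arc_curve([2, 3, 0, 1], 4).counts, [2, 4, 2, 0]
        )

    def test_conservation_returns_to_zero(self, rng):
        idx = rng.integers(0, 50, size=50)
        counts = compute_arc_curve(idx, 50).counts
        assert counts[-1] == 0 or idx[-1] != 49  # no arc can span past the end
        # increments equal decrements: cumulative sum is 0 after all positions
        assert counts[np.max(np.maximum(idx, np.arange(50)))] == 0

    def test_matches_brute_force_crossings(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 60))
            idx = rng.integers(0, n, size=n)
            np.testing.assert_array_equal(
                compute_arc_curve(idx, n).counts, naive_crossing_counts(idx, n)
            )

    def test_sentinels_skipped(self):
        counts = compute_arc_curve([-1, 3, -1, 1], 4).counts
        np.testing.assert_array_equal(counts, naive_crossing_counts([-1, 3, -1, 1], 4))

    def test_out_of_range_names_position(self):
        with pytest.raises(ValueError, match=r"mp_index\[1\]"):
            compute_arc_curve([0, 7], 4)

    @given(st.lists(st.integers(0, 39), min_size=2, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_property_equals_oracle(self, idx):
        n = 40
        np.testing.assert_array_equal(
            compute_arc_curve(idx, n).counts, naive_crossing_counts(idx, n)
        )


class TestIdealizedArcCurve:
    def test_parabola_center_is_half_n(self):
        for n in [100, 777, 1000]:
            iac = idealized_arc_curve(n)
            assert iac.expected[n // 2] / n == pytest.approx(0.5, rel=1e-3)

    def test_parabola_zero_at_ends(self):
        iac = idealized_arc_curve(500)
        assert iac.expected[0] == 0.0
        assert iac.expected.max() <= 500 / 2 + 1e-9

    def test_parabola_matches_monte_carlo(self):
        n, trials = 1000, 200
        rng = np.random.default_rng(0)
        acc = np.zeros(n)
        for _ in range(trials):
            acc += _null_arc_curve_bidirectional(n, rng)
        empirical = acc / trials
        closed = idealized_arc_curve(n).expected
        sup = np.abs(empirical - closed).max() / closed.max()
        assert sup < 0.05

    def test_parabola_is_beta22_density(self):
        n = 400
        x = np.arange(n, dtype=float)
        parab = idealized_arc_curve(n).expected
        parab_density = parab / (n**2 / 3.0)  # analytic area of 2x(n-x)/n on [0, n]
        beta_density = stats.beta(2, 2).pdf(x / n) / n  # rescaled to [0, n]
        np.testing.assert_allclose(parab_density, beta_density, atol=1e-9)

    def test_one_directional_skewed_and_shorter(self):
        # with backward-pointing arcs the null curve is skewed (mirror of the
        # forward-arc picture): peak near n/e, well away from the center,
        # and lower than the bidirectional parabola's n/2
        n = 600
        iac1 = idealized_arc_curve(n, "one_directional", trials=100, seed=0)
        parab = idealized_arc_curve(n)
        assert iac1.expected.max() < parab.expected.max()
        peak = np.argmax(iac1.expected)
        assert abs(peak - n / np.e) < 0.05 * n

    def test_one_directional_cached_and_deterministic(self):
        a = idealized_arc_curve(300, "one_directional", trials=50, seed=3)
        b = idealized_arc_curve(300, "one_directional", trials=50, seed=3)
        assert a is b
        c = idealized_arc_curve(300, "one_directional", trials=50, seed=4)
        assert not np.array_equal(a.expected, c.expected)

    def test_constrained_uniform_interior_constant(self):
        iac = idealized_arc_curve(800, "constrained_uniform", trials=50, seed=0, tc_samples=100)
        interior = iac.expected[100:700]
        assert np.ptp(interior) == 0.0  # constant by construction
        assert iac.edge_region == (100, 100)

    def test_constrained_requires_tc(self):
        with pytest.raises(ValueError, match="tc_samples"):
            idealized_arc_curve(100, "constrained_uniform")

    def test_unknown_model(self):
        with pytest.raises(ValueError, match="unknown IAC model"):
            idealized_arc_curve(100, "gamma")


class TestCorrectedArcCurve:
    def test_ac_equal_iac_gives_one(self):
        iac = idealized_arc_curve(100)
        ac = ArcCurve(np.round(iac.expected).astype(int))
        cac = compute_cac(ac, iac)
        informative = iac.expected >= 1.0
        np.testing.assert_allclose(cac.values[informative], 1.0, atol=0.6 / 1.0)
        assert np.all(cac.values <= 1.0)

    def test_zero_ac_gives_zero(self):
        iac = idealized_arc_curve(100)
        cac = compute_cac(ArcCurve(np.zeros(100, dtype=int)), iac)
        informative = iac.expected >= 1.0
        assert np.all(cac.values[informative] == 0.0)

    def test_ac_above_iac_clamps_to_one(self):
        iac = idealized_arc_curve(100)
        huge = ArcCurve(np.full(100, 10_000))
        cac = compute_cac(huge, iac)
        np.testing.assert_array_equal(cac.values, 1.0)

    def test_bounds_on_random_inputs(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 200))
            ac = ArcCurve(rng.integers(0, 4 * n, size=n))
            iac = IdealizedArcCurve(rng.uniform(0, n, size=n), model="parabola")
            vals = compute_cac(ac, iac).values
            assert vals.min() >= 0.0 and vals.max() <= 1.0

    def test_floor_marks_edges_uninformative(self):
        iac = idealizec = idealized_arc_curve(100)
        cac = compute_cac(ArcCurve(np.zeros(100, dtype=int)), iac)
        assert cac.values[0] == 1.0  # IAC[0] = 0 < floor

    def test_edge_guard(self):
        iac = idealized_arc_curve(200)
        ac = ArcCurve(np.zeros(200, dtype=int))
        cac = compute_cac(ac, iac, edge_guard=30)
        assert np.all(cac.values[:30] == 1.0)
        assert np.all(cac.values[-30:] == 1.0)
        assert np.all(cac.values[30:170] == 0.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length mismatch"):
            compute_cac(ArcCurve(np.zeros(10, dtype=int)), idealized_arc_curve(12))


class TestFusion:
    def test_identity(self):
        from arcseg import CorrectedArcCurve

        c = CorrectedArcCurve(np.linspace(0, 1, 50))
        fused = fuse_cacs([c])
        np.testing.assert_array_equal(fused.values, c.values)

    def test_mean_of_constants(self):
        from arcseg import CorrectedArcCurve

        lo = CorrectedArcCurve(np.zeros(20))
        hi = CorrectedArcCurve(np.ones(20))
        np.testing.assert_array_equal(fuse_cacs([lo, hi]).values, 0.5)

    def test_length_mismatch_raises(self):
        from arcseg import CorrectedArcCurve

        with pytest.raises(ValueError, match="length"):
            fuse_cacs([CorrectedArcCurve(np.ones(10)), CorrectedArcCurve(np.ones(12))])

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            fuse_cacs([])

    def test_two_channel_fusion_recovers_both_boundaries(self):
        # each channel distinguishes only one of the two boundaries
        # (near-identical periods make two regimes look alike per channel)
        common = dict(duration=400, noise_db=25)
        ch1, truth = make_regime_series(
            [
                RegimeSpec("sine", period=20, seed=1, **common),
                RegimeSpec("sawtooth", period=30, seed=2, **common),
                RegimeSpec("sawtooth", period=31, seed=3, **common),
            ]
        )
        ch2, _ = make_regime_series(
            [
                RegimeSpec("square", period=25, seed=4, **common),
                RegimeSpec("square", period=26, seed=5, **common),
                RegimeSpec("pulse", period=40, seed=6, **common),
            ]
        )
        L = 25
        params = SubseqParams(L=L)
        fused = fluss([ch1.values, ch2.values], params)
        found = extract_regimes(fused, num_boundaries=2, L=L)
        errors = np.abs(found.positions - truth.positions)
        assert np.all(errors <= L), (found.positions, truth.positions)


class TestFluss:
    def test_boundary_within_L(self, two_regime):
        series, truth, params = two_regime
        cac = fluss(series, params)
        argmin = int(np.argmin(cac.values))
        assert abs(argmin - truth.positions[0]) <= params.L

    def test_scale_shift_invariance_exact(self, two_regime):
        series, _, params = two_regime
        a = fluss(series.values, params)
        b = fluss(3.0 * series.values + 7.0, params)
        np.testing.assert_array_equal(a.values, b.values)

    def test_bounds(self, two_regime):
        series, _, params = two_regime
        cac = fluss(series, params)
        assert cac.values.min() >= 0.0 and cac.values.max() <= 1.0

    def test_channel_length_mismatch(self, rng):
        with pytest.raises(ValueError, match="equal length"):
            fluss([rng.standard_normal(100), rng.standard_normal(90)], SubseqParams(L=8))

    def test_iid_noise_has_high_cac(self, rng):
        # no regime structure: few values dip low, and the minimum carries no
        # consistent location across seeds
        argmins = []
        for seed in range(5):
            x = np.random.default_rng(seed).standard_normal(800)
            cac = fluss(x, SubseqParams(L=20))
            frac_low = np.mean(cac.values < 0.2)
            assert frac_low < 0.05
            argmins.append(int(np.argmin(cac.values)))
        assert np.std(argmins) > 20  # scattered, not a consistent minimum
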