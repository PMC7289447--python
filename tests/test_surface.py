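import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chisquare

from cochap.constants import KB
from cochap.freenergy import (
    BiasGrid,
    FreeEnergySurface,
    average_fes_blocks,
    classify_state,
    fes_to_probability,
    integrate_state_populations,
    metad_bias_to_fes,
)


def grid(lo=0.3, hi=1.9, n=16):
    step = (hi - lo) / n
    return np.linspace(lo + step / 2, hi - step / 2, n)


class TestProbability:
    def test_flat_surface_uniform(self):
        f = FreeEnergySurface((grid(),), np.zeros(16))
        np.testing.assert_allclose(fes_to_probability(f), 1 / 16)

    def test_boltzmann_ratio(self):
        kT = KB * 310.0
        f = FreeEnergySurface((np.array([0.0, 1.0]),), np.array([0.0, kT * np.log(2)]))
        np.testing.assert_allclose(fes_to_probability(f), [2 / 3, 1 / 3], atol=1e-12)

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.floats(0, 50), min_size=2, max_size=40))
    def test_normalization(self, values):
        f = FreeEnergySurface((np.arange(len(values), dtype=float),), np.array(values))
        assert fes_to_probability(f).sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_infinite_rejected(self):
        f = FreeEnergySurface((grid(),), np.full(16, np.inf))
        with pytest.raises(ValueError):
            fes_to_probability(f)


class TestClassifyState:
    @pytest.mark.parametrize(
        "d1,d2,expected",
        [
            (0.40, 0.45, "both-bound"),
            (0.60, 0.60, "both-unbound"),
            (0.50, 0.40, "only-2"),  # boundary is unbound (strict <)
            (0.40, 0.50, "only-1"),
        ],
    )
    def test_quadrants(self, d1, d2, expected):
        assert classify_state(d1, d2) == expected

    def test_nonpositive_distances_rejected(self):
        with pytest.raises(ValueError):
            classify_state(-0.1, 0.4)


class TestStatePopulations:
    def test_flat_surface_area_fractions(self):
        f = FreeEnergySurface((grid(), grid()), np.zeros((16, 16)))
        pops = integrate_state_populations(f, 0.5)
        assert pops["both-bound"] == pytest.approx((0.2 / 1.6) ** 2)
        assert sum(pops.values()) == pytest.approx(1.0, abs=1e-12)

    def test_single_quadrant_well(self):
        values = np.full((16, 16), np.inf)
        b = grid() < 0.5
        values[np.ix_(b, b)] = 0.0
        f = FreeEnergySurface((grid(), grid()), values)
        pops = integrate_state_populations(f, 0.5)
        assert pops["both-bound"] == pytest.approx(1.0)

    @staticmethod
    def analytic(x, y):
        # double-well in each coordinate: minima inside and outside 0.5 nm
        return 8.0 * ((x - 0.45) * (x - 0.9)) ** 2 + 6.0 * ((y - 0.42) * (y - 1.1)) ** 2

    def test_refined_grid_riemann_oracle(self):
        xs, ys = grid(n=40), grid(n=40)
        f = FreeEnergySurface((xs, ys), self.analytic(xs[:, None], ys[None, :]))
        pops = integrate_state_populations(f, 0.5)
        xf, yf = grid(n=160), grid(n=160)
        ff = FreeEnergySurface((xf, yf), self.analytic(xf[:, None], yf[None, :]))
        fine = integrate_state_populations(ff, 0.5)
        for key in pops:
            assert pops[key] == pytest.approx(fine[key], abs=1e-3)

    def test_monte_carlo_cross_check(self):
        xs, ys = grid(n=60), grid(n=60)
        f = FreeEnergySurface((xs, ys), self.analytic(xs[:, None], ys[None, :]))
        pops = integrate_state_populations(f, 0.5)
        p = fes_to_probability(f).ravel()
        rng = np.random.default_rng(4)
        n = 20000
        draws = rng.choice(len(p), p=p, size=n)
        d1 = xs[draws // 60]
        d2 = ys[draws % 60]
        labels = [classify_state(a, b, 0.5) for a, b in zip(d1, d2)]
        observed = np.array([labels.count(k) for k in pops])
        expected = np.array([pops[k] * n for k in pops])
        keep = expected > 5
        stat = chisquare(observed[keep], expected[keep] * observed[keep].sum() / expected[keep].sum())
        assert stat.pvalue > 0.01

    def test_cutoff_outside_grid_rejected(self):
        f = FreeEnergySurface((grid(), grid()), np.zeros((16, 16)))
        with pytest.raises(ValueError):
            integrate_state_populations(f, 5.0)


class TestMetadBiasToFes:
    def test_zero_bias_flat(self):
        xs = grid(-0.3, 0.3, 20)
        b = BiasGrid((xs, xs), np.zeros((20, 20)), bias_factor=15.0)
        fes = metad_bias_to_fes(b)
        np.testing.assert_allclose(fes.values, 0.0)

    def test_single_gaussian_well_depth(self):
        # F = -(gamma/(gamma-1)) V: a lone hill of height h becomes a well
        # of depth (15/14) h relative to the untouched plateau
        xs = grid(-0.3, 0.3, 61)
        h, w = 1.0, 0.04
        V = h * np.exp(-(xs[:, None] ** 2 + xs[None, :] ** 2) / (2 * w * w))
        fes = metad_bias_to_fes(BiasGrid((xs, xs), V, bias_factor=15.0))
        depth = fes.values.max() - fes.values.min()
        assert depth == pytest.approx((15 / 14) * h, rel=1e-6)

    def test_gauge_invariance_under_constant_bias_shift(self):
        xs = grid(-0.3, 0.3, 21)
        rng = np.random.default_rng(0)
        V = rng.uniform(0, 2, (21, 21))
        f1 = metad_bias_to_fes(BiasGrid((xs, xs), V, bias_factor=15.0))
        f2 = metad_bias_to_fes(BiasGrid((xs, xs), V + 3.7, bias_factor=15.0))
        np.testing.assert_allclose(f1.values, f2.values, atol=1e-9)

    def test_invalid_bias_factor(self):
        xs = grid(-0.3, 0.3, 5)
        with pytest.raises(ValueError):
            BiasGrid((xs, xs), np.zeros((5, 5)), bias_factor=1.0)


class TestBlockAveraging:
    def test_identical_maps(self):
        xs = grid()
        vals = np.abs(np.sin(xs))[:, None] * np.ones(16)[None, :]
        maps = [FreeEnergySurface((xs, xs), vals.copy()) for _ in range(15)]
        avg = average_fes_blocks(maps)
        np.testing.assert_allclose(avg.values, maps[0].values, atol=1e-12)
        np.testing.assert_allclose(avg.sd, 0.0, atol=1e-12)

    def test_constant_offsets_removed_by_alignment(self):
        xs = grid()
        base = np.outer(np.linspace(0, 3, 16), np.ones(16))
        maps = [FreeEnergySurface((xs, xs), base + c) for c in (0.0, 5.0, 11.0)]
        avg = average_fes_blocks(maps)
        np.testing.assert_allclose(avg.sd, 0.0, atol=1e-12)

    def test_mean_matches_direct_recomputation(self):
        xs = grid()
        rng = np.random.default_rng(8)
        maps = [
            FreeEnergySurface((xs, xs), rng.uniform(0, 4, (16, 16))) for _ in range(5)
        ]
        avg = average_fes_blocks(maps)
        direct = np.mean([m.values for m in maps], axis=0)
        direct -= direct.min()
        np.testing.assert_allclose(avg.values, direct, atol=1e-12)

    def test_mismatched_grids_rejected(self):
        a = FreeEnergySurface((grid(),), np.zeros(16))
        b = FreeEnergySurface((grid(n=8),), np.zeros(8))
        with pytest.raises(ValueError, match="grid"):
            average_fes_blocks([a, b])
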