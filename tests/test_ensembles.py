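"""GA ensemble selection, Rg distributions and Gaussian decomposition."""

import numpy as np
import pytest

from confensa import (ScatteringCurve, select_ensemble, rg_distribution,
                      decompose_peaks, mixture_curve)
from confensa.ensembles import RgDistribution


def planted_experiment(pools, weights, rng, n_draw=40, rel_err=0.01,
                       mass_scales=None):
    """Average curve of random pool draws at the given pool weights."""
    q = pools[0].q_grid
    total = np.zeros_like(q)
    for k, (pool, wgt) in enumerate(zip(pools, weights)):
        idx = rng.choice(len(pool), min(n_draw, len(pool)), replace=False)
        curves = pool.curves[idx]
        curves = curves / curves[:, :1]
        if mass_scales is not None:
            curves = curves * mass_scales[k]
        total += wgt * curves.mean(axis=0)
    sig = rel_err * total
    noisy = total + rng.normal(0, sig)
    return ScatteringCurve(q, noisy, sig)


class TestSelectEnsemble:
    def test_planted_single_member(self, small_pools):
        pool_c, _ = small_pools
        q = pool_c.q_grid
        truth_idx = 17
        inten = pool_c.curves[truth_idx]
        sig = 0.01 * inten
        rng = np.random.default_rng(1)
        exp = ScatteringCurve(q, inten + rng.normal(0, sig), sig)
        fit = select_ensemble([pool_c], exp, generations=500, seed=2)
        assert fit.chi2 <= 1.1
        # the winning members are Rg-equivalents of the planted one
        rg_true = pool_c.rg_values[truth_idx]
        sel_rg = np.array([pool_c.rg_values[i] for _, i in fit.member_refs])
        close = np.abs(sel_rg - rg_true) < 1.0
        assert close.mean() >= 0.8

    def test_two_pool_fraction_recovery(self, small_pools):
        rng = np.random.default_rng(3)
        exp = planted_experiment(list(small_pools), [0.85, 0.15], rng)
        fit = select_ensemble(list(small_pools), exp, generations=200, seed=4)
        assert fit.pool_weights[0] == pytest.approx(0.85, abs=0.07)

    def test_pure_dimer_with_mass_scales(self, small_pools):
        # stand-in monomer/dimer: scale the extended pool as the "dimer"
        pool_m, pool_d = small_pools
        rng = np.random.default_rng(5)
        exp = planted_experiment([pool_m, pool_d], [0.0, 1.0], rng,
                                 mass_scales=(1.0, 2.0))
        fit = select_ensemble([pool_m, pool_d], exp, generations=200,
                              mass_scales=(1.0, 2.0), seed=6)
        assert fit.pool_weights[1] >= 0.95

    def test_same_seed_identical(self, small_pools):
        pool_c, _ = small_pools
        rng = np.random.default_rng(7)
        exp = planted_experiment([pool_c], [1.0], rng)
        a = select_ensemble([pool_c], exp, generations=50, seed=11)
        b = select_ensemble([pool_c], exp, generations=50, seed=11)
        assert a.member_refs == b.member_refs
        assert a.chi2 == b.chi2

    def test_more_generations_never_worse(self, small_pools):
        """Elitism makes best-so-far fitness monotone in generations."""
        pool_c, _ = small_pools
        rng = np.random.default_rng(8)
        exp = planted_experiment([pool_c], [1.0], rng)
        chi_prev = np.inf
        for gens in (10, 40, 160):
            fit = select_ensemble([pool_c], exp, generations=gens, seed=9)
            assert fit.chi2 <= chi_prev + 1e-12
            chi_prev = fit.chi2

    def test_seed_agreement_within_5pct(self, small_pools):
        rng = np.random.default_rng(9)
        exp = planted_experiment(list(small_pools), [0.85, 0.15], rng)
        chis = [select_ensemble(list(small_pools), exp, generations=200,
                                seed=s).chi2 for s in (1, 2, 3)]
        assert (max(chis) - min(chis)) / min(chis) < 0.05

    def test_empty_pool_rejected(self, small_pools):
        pool_c, _ = small_pools
        q = pool_c.q_grid
        exp = ScatteringCurve(q, np.ones_like(q), np.ones_like(q))
        with pytest.raises(ValueError):
            select_ensemble([], exp)
        with pytest.raises(ValueError):
            select_ensemble([pool_c], exp, generations=0)


class TestRgDistribution:
    def test_single_member_selected(self, small_pools):
        pool_c, _ = small_pools
        rng = np.random.default_rng(1)
        exp = planted_experiment([pool_c], [1.0], rng)
        fit = select_ensemble([pool_c], exp, generations=5, seed=1)
        fit.member_refs = [(0, 3)] * 20
        dist = rg_distribution(fit, [pool_c])
        assert (dist.selected_freq > 0).sum() == 1
        assert dist.selected_freq.max() == pytest.approx(1.0)

    def test_uniform_selection_matches_pool(self, small_pools):
        pool_c, _ = small_pools
        rng = np.random.default_rng(2)
        exp = planted_experiment([pool_c], [1.0], rng)
        fit = select_ensemble([pool_c], exp, generations=5, seed=1)
        fit.member_refs = [(0, i) for i in range(len(pool_c))]
        dist = rg_distribution(fit, [pool_c], bin_width=1.0)
        np.testing.assert_allclose(dist.selected_freq, dist.pool_freq,
                                   atol=1e-12)

    def test_frequencies_normalized(self, small_pools):
        pool_c, pool_e = small_pools
        rng = np.random.default_rng(3)
        exp = planted_experiment(list(small_pools), [0.85, 0.15], rng)
        fit = select_ensemble(list(small_pools), exp, generations=30, seed=2)
        dist = rg_distribution(fit, list(small_pools))
        assert dist.selected_freq.sum() == pytest.approx(1.0)
        assert dist.pool_freq.sum() == pytest.approx(1.0)


def gaussian_hist(x, specs):
    y = np.zeros_like(x)
    for frac, mu, s in specs:
        y += frac * np.exp(-0.5 * ((x - mu) / s) ** 2) / s
    return y / y.sum()


class TestDecomposePeaks:
    x = np.arange(26.0, 46.0, 0.25)

    def test_pure_gaussian(self):
        y = gaussian_hist(self.x, [(1.0, 33.0, 1.0)])
        pk = decompose_peaks(RgDistribution(self.x, y, y, 0.25))
        assert len(pk.peaks) == 1
        p = pk.peaks[0]
        assert p["center"] == pytest.approx(33.0, abs=0.1)
        assert p["fwhm"] == pytest.approx(2.355, abs=0.1)
        assert p["area_fraction"] == pytest.approx(100.0, abs=0.1)
        assert p["shape"] == "gaussian"

    @pytest.mark.parametrize("seed", [4, 5, 6])
    def test_two_state_fractions(self, seed):
        rng = np.random.default_rng(seed)
        p = gaussian_hist(self.x, [(0.85, 33.0, 1.0), (0.15, 38.5, 1.0)])
        y = rng.multinomial(2000, p).astype(float)
        y /= y.sum()
        pk = decompose_peaks(RgDistribution(self.x, y, p, 0.25))
        pk.peaks.sort(key=lambda d: d["center"])
        major, minor = pk.peaks[0], pk.peaks[-1]
        assert major["center"] == pytest.approx(33.0, abs=0.2)
        assert minor["center"] == pytest.approx(38.5, abs=0.2)
        assert major["area_fraction"] == pytest.approx(85.0, abs=3.0)

    def test_flat_top_reported_as_double(self):
        y = gaussian_hist(self.x, [(0.5, 33.0, 0.5), (0.5, 33.8, 0.5)])
        pk = decompose_peaks(RgDistribution(self.x, y, y, 0.25))
        assert len(pk.peaks) == 1
        assert pk.peaks[0]["shape"] == "double_gaussian"
        assert pk.peaks[0]["center"] == pytest.approx(33.4, abs=0.2)

    def test_bin_width_halving_invariance(self):
        areas = {}
        for bw in (0.25, 0.125):
            x = np.arange(26.0, 46.0, bw)
            p = gaussian_hist(x, [(0.85, 33.0, 1.0), (0.15, 38.5, 1.0)])
            rng = np.random.default_rng(9)
            y = rng.multinomial(4000, p).astype(float)
            y /= y.sum()
            pk = decompose_peaks(RgDistribution(x, y, p, bw))
            pk.peaks.sort(key=lambda d: d["center"])
            areas[bw] = pk.peaks[0]["area_fraction"]
        assert areas[0.25] == pytest.approx(areas[0.125], abs=2.0)

    def test_too_sparse_raises(self):
        y = np.zeros_like(self.x)
        y[10] = 0.6
        y[20] = 0.4
        with pytest.raises(ValueError, match="occupied"):
            decompose_peaks(RgDistribution(self.x, y, y, 0.25))
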