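"""Toy structures, simulated experiments and scenario ground truths."""

import warnings

import numpy as np
import pytest

from confensa import (CoordinateModel, ScatteringCurve, guinier_fit,
                      make_toy_multidomain, make_scenario, simulate_experiment,
                      subtract_buffer, radius_of_gyration, debye_intensity,
                      fit_scale)
from confensa.synth import GroundTruth, _globule, RESIDUE_VOLUME


class TestToyMultidomain:
    def test_extended_exceeds_closed(self):
        closed, _ = make_toy_multidomain(packing="closed", seed=3)
        extended, _ = make_toy_multidomain(packing="extended", seed=3)
        assert radius_of_gyration(extended) >= radius_of_gyration(closed) + 3.0

    def test_single_globule_rg_scaling(self):
        rng = np.random.default_rng(1)
        n = 300
        g = CoordinateModel(_globule(n, rng))
        r_eff = (3 * n * RESIDUE_VOLUME / (4 * np.pi)) ** (1 / 3)
        assert radius_of_gyration(g) == pytest.approx(
            np.sqrt(3 / 5) * r_eff, rel=0.2)

    def test_same_seed_identical(self):
        a, _ = make_toy_multidomain(seed=9)
        b, _ = make_toy_multidomain(seed=9)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_domain_map_covers_chain(self):
        model, dmap = make_toy_multidomain(seed=2)
        n = int(model.residue_numbers.max())
        assert max(hi for _, hi in dmap.domains.values()) == n
        for lo, hi in dmap.flexible:
            assert 1 <= lo <= hi <= n

    def test_too_few_domains_rejected(self):
        with pytest.raises(ValueError):
            make_toy_multidomain(domain_sizes=(100,))


class TestSimulateExperiment:
    def test_noiseless_pipeline_identity(self):
        """With noise -> 0, subtraction + Guinier reproduce the ideal
        mixture's apparent Rg to 0.1%."""
        truth = make_scenario("apo_two_state", {"n_draws": 5}, seed=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sample, buffer = simulate_experiment(truth, noise_floor=1e-8,
                                                 seed=6)
            sub, t = subtract_buffer(sample, buffer)
        # ideal mixture curve, same convention as the simulator
        q = sample.q
        ideal = np.zeros_like(q)
        for state, frac, mass in zip(truth.components, truth.fractions,
                                     truth.masses):
            sc = np.zeros_like(q)
            for comp in state:
                i = debye_intensity(comp.positions, q, method="histogram")
                sc += i / i[0] / len(state)
            ideal += frac * sc * mass
        g_sub = guinier_fit(sub.crop(0, 0.3))
        g_ideal = guinier_fit(ScatteringCurve(
            q, ideal, np.maximum(1e-6 * ideal[0] * np.sqrt(ideal / ideal[0]),
                                 1e-12)).crop(0, 0.3))
        assert g_sub.rg == pytest.approx(g_ideal.rg, rel=0.001)

    def test_transmission_recovered_in_noiseless_limit(self):
        truth = make_scenario("apo_two_state", {"n_draws": 5,
                                                "transmission": 0.97}, seed=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sample, buffer = simulate_experiment(truth, noise_floor=1e-8,
                                                 seed=7)
            _, t = subtract_buffer(sample, buffer)
        assert t == pytest.approx(0.97, abs=0.01)

    def test_chi2_realism_on_self_noise(self):
        """Fitting the generating model to its own noisy data gives
        reduced chi2 around 1 (the error bars mean what they claim)."""
        rng = np.random.default_rng(3)
        glob = CoordinateModel(_globule(400, rng))
        truth = GroundTruth([glob], [1.0], [1], 1.0,
                            {"noise_floor": 1.0, "exposure_factor": 0.1}, 3)
        q = np.linspace(0.012, 0.3, 200)
        model_i = debye_intensity(glob.positions, q, method="histogram")
        theory = ScatteringCurve(q, model_i, np.full(len(q), 1e-12))
        chi2s = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for rep in range(50):
                sample, buffer = simulate_experiment(
                    truth, q_grid=q, buffer_profile={"b0": 0.0, "b1": 1e-9},
                    seed=100 + rep)
                # buffer ~ 0: the sample is signal + noise directly
                chi2s.append(fit_scale(theory, sample).chi2)
        assert 0.85 <= np.mean(chi2s) <= 1.15

    def test_bad_noise_params_rejected(self):
        truth = make_scenario("ternary", seed=1)
        with pytest.raises(ValueError):
            simulate_experiment(truth, exposure_factor=0.0)


class TestScenarios:
    def test_fraction_passthrough(self):
        truth = make_scenario("apo_two_state", {"f": 0.85, "n_draws": 3},
                              seed=1)
        np.testing.assert_allclose(truth.fractions, [0.85, 0.15])
        assert truth.labels == ["closed", "extended"]

    def test_dimer_mass_convention(self):
        truth = make_scenario("dimer_equilibrium", {"m": 0.10, "n_draws": 3},
                              seed=1)
        # number fractions from a 10% monomer mass fraction
        n_mono = truth.fractions[0]
        assert n_mono == pytest.approx(0.1 / (0.1 + 0.45))
        masses = truth.masses
        assert masses[1] == pytest.approx(2 * masses[0], rel=0.01)
        # mixture I(0) per the calibrated convention
        i0 = (truth.fractions * masses).sum()
        assert i0 == pytest.approx(
            (n_mono * 1 + (1 - n_mono) * 2) * masses[0], rel=0.01)

    def test_ternary_larger_than_free_enzyme(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tern = make_scenario("ternary", seed=4)
            free = make_scenario("apo_two_state", {"n_draws": 3}, seed=4)
            s_t, b_t = simulate_experiment(tern, seed=8)
            s_f, b_f = simulate_experiment(free, seed=8)
            g_t = guinier_fit(subtract_buffer(s_t, b_t)[0].crop(0, 0.3))
            g_f = guinier_fit(subtract_buffer(s_f, b_f)[0].crop(0, 0.3))
        assert g_t.rg > g_f.rg

    def test_unknown_scenario(self):
        with pytest.raises(ValueError, match="unknown"):
            make_scenario("mystery")

    def test_truth_serializable(self, tmp_path):
        truth = make_scenario("apo_two_state", {"n_draws": 3}, seed=2)
        path = tmp_path / "truth.json"
        truth.to_json(path)
        import json
        doc = json.loads(path.read_text())
        np.testing.assert_allclose(doc["fractions"], [0.85, 0.15])
        assert len(doc["state_rg_means"]) == 2
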