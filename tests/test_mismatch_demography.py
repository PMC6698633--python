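"""Mismatch spectra, closed-form expectations, fitting, and bootstrap."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import chisquare, poisson

from rhizodem.coalescent_sim import Deme, DemographicScenario, Event, Locus, \
    simulate_dataset
from rhizodem.mlst_io import LocusAlignment
from rhizodem import mismatch_demography as md


class TestObservedSpectrum:
    def test_toy_frequencies(self, toy_aln):
        spec = md.observed_mismatch(toy_aln)
        assert spec.frequencies == pytest.approx([0, 0.5, 1 / 3, 1 / 6])
        assert spec.mean_differences == pytest.approx(10 / 6)

    def test_monomorphic_point_mass(self):
        spec = md.observed_mismatch(
            LocusAlignment("m", {"a": "AAA", "b": "AAA", "c": "AAA"}))
        assert spec.frequencies == pytest.approx([1.0])

    def test_two_sequences_single_class(self):
        spec = md.observed_mismatch(LocusAlignment("p", {"a": "AAT", "b": "ATT"}))
        assert spec.frequencies[-1] == 1.0


class TestClosedForms:
    def test_constant_geometric(self):
        p = md.expected_probs("constant", {"theta": 1.0}, 4)
        assert p[:3] == pytest.approx([0.5, 0.25, 0.125])

    def test_poisson_limit(self):
        # theta0 = 0 and theta1 -> infinity collapses to Poisson(tau)
        p = md.expected_probs("demographic_expansion",
                              {"tau": 5.0, "theta0": 0.0, "theta1": 1e12}, 30)
        assert np.abs(p - poisson.pmf(np.arange(31), 5.0)).max() < 1e-6

    def test_tau_zero_limit_is_constant(self):
        p1 = md.expected_probs("demographic_expansion",
                               {"tau": 0.0, "theta0": 2.0, "theta1": 77.0}, 20)
        p2 = md.expected_probs("constant", {"theta": 2.0}, 20)
        assert np.abs(p1 - p2).max() < 1e-9

    @pytest.mark.parametrize("model,params", [
        ("constant", {"theta": 3.0}),
        ("demographic_expansion", {"tau": 5, "theta0": 1, "theta1": 100}),
        ("demographic_expansion", {"tau": 22, "theta0": 0.1, "theta1": 2000}),
        ("spatial_expansion", {"tau": 5, "theta": 2, "M": 2}),
        ("spatial_expansion", {"tau": 18, "theta": 0.5, "M": 20}),
    ])
    def test_mass_sums_to_one(self, model, params):
        # adaptive window: far past the bulk of the distribution
        d_max = int(50 + 3 * (params.get("tau", 0) + params.get("theta1", 0) ** 0.5
                              + params.get("theta", 0) * 4))
        assert md.expected_probs(model, params, d_max).sum() == pytest.approx(
            1.0, abs=1e-6)

    def test_demographic_matches_numeric_integration(self):
        tau, th0, th1 = 4.0, 1.5, 20.0

        def f(j):
            rec = quad(lambda x: (1 / th1) * np.exp(-x / th1) * poisson.pmf(j, x),
                       0, tau)[0]
            anc = quad(lambda y: (1 / th0) * np.exp(-y / th0) * poisson.pmf(j, tau + y),
                       0, 300)[0]
            return rec + np.exp(-tau / th1) * anc

        closed = md.expected_probs("demographic_expansion",
                                   {"tau": tau, "theta0": th0, "theta1": th1}, 9)
        numeric = np.array([f(j) for j in range(10)])
        assert np.abs(closed - numeric).max() < 1e-10

    def test_spatial_matches_numeric_integration(self):
        tau, th, M = 3.0, 2.0, 1.5
        er = 1 + M

        def f(j):
            rec = quad(lambda x: (1 / th) * np.exp(-er * x / th) * poisson.pmf(j, x),
                       0, tau)[0]
            anc = quad(lambda y: (1 / th) * np.exp(-y / th) * poisson.pmf(j, tau + y),
                       0, 300)[0]
            surv = np.exp(-er * tau / th) + (M / er) * (1 - np.exp(-er * tau / th))
            return rec + surv * anc

        closed = md.expected_probs("spatial_expansion",
                                   {"tau": tau, "theta": th, "M": M}, 9)
        numeric = np.array([f(j) for j in range(10)])
        assert np.abs(closed - numeric).max() < 1e-10

    @pytest.mark.parametrize("model,params,n_demes", [
        ("constant", {"theta": 2.0}, 30),
        ("demographic_expansion", {"tau": 5.0, "theta0": 0.5, "theta1": 50.0}, 30),
        ("demographic_expansion", {"tau": 2.0, "theta0": 1.0, "theta1": 200.0}, 30),
        ("spatial_expansion", {"tau": 4.0, "theta": 2.0, "M": 1.0}, 60),
        ("spatial_expansion", {"tau": 6.0, "theta": 0.5, "M": 0.5}, 80),
    ])
    def test_agrees_with_simulation_oracle(self, model, params, n_demes):
        # chi-square GOF of 4000 simulated pair differences vs the closed
        # form; the island oracle needs enough demes that re-meeting of
        # separated lineages (a finite-deme artefact) is negligible
        d_max = 40
        mc = md.monte_carlo_expected(model, params, d_max, n_reps=4000, seed=1,
                                     n_demes=n_demes)
        expect = md.expected_probs(model, params, d_max)
        counts = mc.counts
        # lump classes with tiny expectation
        exp_counts = expect * counts.sum()
        keep = exp_counts >= 5
        obs = np.append(counts[keep], counts[~keep].sum())
        exp = np.append(exp_counts[keep], exp_counts[~keep].sum())
        exp = exp * obs.sum() / exp.sum()
        assert chisquare(obs, exp).pvalue > 1e-3


class TestRaggedness:
    def test_point_mass(self):
        assert md.raggedness(md.MismatchSpectrum([1.0])) == pytest.approx(1.0)

    def test_two_equal_classes(self):
        assert md.raggedness(md.MismatchSpectrum([0.5, 0.5])) == pytest.approx(0.25)

    def test_smooth_less_ragged_than_spiky(self):
        smooth = md.MismatchSpectrum(np.full(10, 0.1))
        spiky = md.MismatchSpectrum([0.5, 0, 0, 0, 0, 0, 0, 0, 0, 0.5])
        assert md.raggedness(smooth) < md.raggedness(spiky)


class TestFitting:
    def test_recovers_exact_constant(self):
        spec = md.expected_mismatch("constant", {"theta": 2.0}, 40)
        spec.mean_differences = 2.0
        fit = md.fit_mismatch(spec, "constant")
        assert fit.params["theta"] == pytest.approx(2.0, rel=1e-2)
        assert fit.ssd < 1e-10

    def test_recovers_exact_demographic(self):
        true = {"tau": 6.0, "theta0": 0.5, "theta1": 60.0}
        spec = md.expected_mismatch("demographic_expansion", true, 60)
        spec.mean_differences = 6.5
        fit = md.fit_mismatch(spec, "demographic_expansion")
        assert fit.params["tau"] == pytest.approx(6.0, rel=0.01)

    def test_monomorphic_boundary(self):
        spec = md.MismatchSpectrum([1.0])
        spec.mean_differences = 0.0
        fit = md.fit_mismatch(spec, "demographic_expansion")
        assert fit.params["tau"] < 0.05

    def test_simulated_expansion_recovery(self):
        # 100-fold growth, pooled loci, true pooled tau = 5
        taus = []
        for rep in range(30):
            loci = [Locus(f"l{i}", 1000, 0.05 / 1000) for i in range(10)]
            sc = DemographicScenario(
                [Deme("A", 50.0)], {"A": 50}, loci,
                events=[Event(time=5.0, kind="size", deme="A", value=0.5)])
            sim = simulate_dataset(sc, seed=rep)
            spec = md._matrix_spectrum(sim.concatenated())
            taus.append(md.fit_mismatch(spec, "demographic_expansion").params["tau"])
        assert 3.5 <= np.median(taus) <= 6.5


class TestBootstrap:
    def test_same_seed_identical(self):
        spec = md.expected_mismatch("constant", {"theta": 2.0}, 25)
        spec.n_pairs, spec.mean_differences = 190, 2.0
        fit = md.fit_mismatch(spec, "constant")
        b1 = md.bootstrap_gof(spec, fit, n=20, B=60, seed=4)
        b2 = md.bootstrap_gof(spec, fit, n=20, B=60, seed=4)
        assert b1.p_ssd == b2.p_ssd and b1.tau_ci == b2.tau_ci

    def test_two_wave_spectrum_rejected(self):
        # bimodal spectrum is a poor fit for a smooth expansion wave
        freqs = np.zeros(31)
        freqs[2], freqs[28] = 0.5, 0.5
        spec = md.MismatchSpectrum(freqs)
        spec.n_pairs, spec.mean_differences = 435, 15.0
        fit = md.fit_mismatch(spec, "demographic_expansion")
        boot = md.bootstrap_gof(spec, fit, n=30, B=80, seed=2)
        assert boot.p_ssd < 0.05

    def test_well_specified_p_not_extreme(self):
        # data simulated under the fitted model: p_ssd should not reject
        sc = DemographicScenario([Deme("A", 3.0)], {"A": 25},
                                 [Locus("l", 1000, 0.5 / 1000)])
        sim = simulate_dataset(sc, seed=8)
        spec = md._matrix_spectrum(sim.concatenated())
        fit = md.fit_mismatch(spec, "constant")
        boot = md.bootstrap_gof(spec, fit, n=25, B=100, seed=3)
        assert boot.p_ssd > 0.05
        assert boot.tau_ci[0] <= fit.params.get("tau", 0.0) <= boot.tau_ci[1]


class TestTimeConversions:
    def test_tau_to_generations(self):
        assert md.tau_to_generations(2.53, 1e-8, 3308) == pytest.approx(38240, rel=1e-3)

    def test_generations_to_years(self):
        assert md.generations_to_years(16_900, 30) == pytest.approx(563.3, rel=1e-3)

    def test_tau_zero(self):
        assert md.tau_to_generations(0.0, 1e-8, 1000) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            md.tau_to_generations(1.0, 0.0, 100)
        with pytest.raises(ValueError):
            md.generations_to_years(-5.0)
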