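"""Mechanism simulator: closed-form limits, conservation, and oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp
from scipy.stats import poisson

from prekin.mechanism import (
    ExtensionChain,
    KineticScheme,
    ParameterError,
    SpeciesState,
    chain_occupancy,
    gillespie_chain,
    primer_survival,
    simulate_scheme,
    unextended_band_fraction,
)


def preformed_ternary(dna: float = 50.0) -> SpeciesState:
    """All DNA starting in the open ternary complex (enzyme and dNTP pre-bound)."""
    return SpeciesState(DNA_Pol_dNTP=dna, dNTP=250e3)


class TestSimulateScheme:
    def test_two_step_erlang_closed_form(self):
        """With irreversible k3 = k4 = k from the ternary complex, product
        formation is the two-step Erlang 1 - (1 + kt) e^{-kt}."""
        k = 50.0
        scheme = KineticScheme(0, 0, 0, 0, k, 0, k, 0)
        t = np.linspace(0.0, 0.2, 41)
        states = simulate_scheme(scheme, preformed_ternary(), t)
        product = np.array([s.product_fraction for s in states])
        closed = 1.0 - (1.0 + k * t) * np.exp(-k * t)
        assert np.max(np.abs(product - closed)) <= 1e-6

    def test_product_fraction_zero_at_t0(self):
        states = simulate_scheme(
            KineticScheme(0, 0, 0, 0, 5, 0, 500, 0), preformed_ternary(), np.array([0.0])
        )
        assert states[0].product_fraction == 0.0

    def test_conformational_change_rate_limiting(self):
        """When k4 >> k3 and earlier steps are pre-saturated, the observed
        single-exponential rate approaches the slow conformational step k3."""
        from prekin.burst_fit import TimeCourse, fit_exponential

        scheme = KineticScheme(0, 0, 0, 0, 5.0, 0, 500.0, 0)
        t = np.concatenate([[0.0], np.geomspace(1e-3, 2.0, 25)])
        states = simulate_scheme(scheme, preformed_ternary(), t)
        y = np.array([s.product_fraction for s in states])
        fit = fit_exponential(TimeCourse(t[1:], y[1:]), n_phases=1)
        assert fit.k_fast == pytest.approx(5.0, rel=0.05)

    @pytest.mark.parametrize(
        "scheme",
        [
            KineticScheme(0.1, 10, 0.01, 100, 50, 5, 500, 1),
            KineticScheme(0.05, 1, 0.001, 0, 5, 0, 500, 0),
        ],
        ids=["fully-reversible", "mostly-irreversible"],
    )
    def test_conservation_of_dna_and_pol(self, scheme):
        init = SpeciesState(DNA=50.0, Pol=500.0, dNTP=250e3)
        t = np.concatenate([[0.0], np.geomspace(1e-4, 2.0, 30)])
        states = simulate_scheme(scheme, init, t)
        for s in states:
            assert s.total_dna == pytest.approx(init.total_dna, rel=1e-9)
            assert s.total_pol == pytest.approx(init.total_pol, rel=1e-9)

    def test_product_fraction_monotone_in_time(self):
        scheme = KineticScheme(0.1, 0, 0.01, 0, 50, 0, 500, 0)
        init = SpeciesState(DNA=50.0, Pol=500.0, dNTP=250e3)
        t = np.concatenate([[0.0], np.geomspace(1e-4, 2.0, 40)])
        states = simulate_scheme(scheme, init, t)
        product = np.array([s.product_fraction for s in states])
        assert np.all(np.diff(product) >= -1e-9)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ParameterError):
            KineticScheme(-1, 0, 0, 0, 5, 0, 5, 0)
        with pytest.raises(ParameterError):
            KineticScheme(0, 0, 0, 0, 0, 0, 0, 0)  # no productive forward rate
        with pytest.raises(ParameterError):
            SpeciesState(DNA=-1.0)
        with pytest.raises(ParameterError):
            simulate_scheme(
                KineticScheme(0, 0, 0, 0, 5, 0, 5, 0), preformed_ternary(),
                np.array([0.1, 0.2]),  # does not start at 0
            )


class TestChainOccupancy:
    def test_all_mass_at_zero_at_t0(self):
        dist = chain_occupancy(ExtensionChain(n_steps=20, k_step=500.0), 0.0)
        assert dist.probabilities[0] == 1.0
        assert dist.probabilities.sum() == pytest.approx(1.0)

    def test_poisson_mean_extension(self):
        """k_step * t = 4 gives a mean extension of four nucleotides (Poisson
        mean), well below the censoring length."""
        dist = chain_occupancy(ExtensionChain(n_steps=20, k_step=400.0), 0.010)
        assert dist.mean_length == pytest.approx(4.0, abs=1e-6)

    @pytest.mark.parametrize("k_off", [0.0, 25.0, 100.0])
    @pytest.mark.parametrize("k_step", [150.0, 500.0])
    def test_matches_chain_ode_oracle(self, k_step, k_off):
        """Analytic/stalled-state solution equals a directly integrated
        chain ODE (independent construction) to 1e-8."""
        n, t = 12, 0.015
        chain = ExtensionChain(n_steps=n, k_step=k_step, k_off=k_off)

        def rhs(_t, y):
            b, s = y[: n + 1], y[n + 1 :]
            db = np.zeros(n + 1)
            db[:n] = -(k_step + k_off) * b[:n]
            db[1:] += k_step * b[:n]
            return np.concatenate([db, k_off * b[:n]])

        y0 = np.zeros(2 * n + 1)
        y0[0] = 1.0
        sol = solve_ivp(rhs, (0, t), y0, t_eval=[t], rtol=1e-12, atol=1e-14)
        b, s = sol.y[: n + 1, -1], sol.y[n + 1 :, -1]
        expected = b.copy()
        expected[:n] += s

        dist = chain_occupancy(chain, t)
        assert dist.probabilities.sum() == pytest.approx(1.0, abs=1e-8)
        assert np.max(np.abs(dist.probabilities - expected)) <= 1e-8

    def test_mean_extension_monotone_in_time(self):
        chain = ExtensionChain(n_steps=20, k_step=400.0, k_off=30.0)
        means = [chain_occupancy(chain, t).mean_length
                 for t in np.linspace(0, 0.1, 21)]
        assert np.all(np.diff(means) >= -1e-9)

    def test_negative_time_rejected(self):
        with pytest.raises(ParameterError):
            chain_occupancy(ExtensionChain(n_steps=5, k_step=10.0), -0.01)

    @given(
        k_step=st.floats(50.0, 800.0),
        k_off=st.floats(0.0, 150.0),
        t=st.floats(0.0, 0.1),
    )
    @settings(max_examples=25, deadline=None)
    def test_distribution_is_normalized(self, k_step, k_off, t):
        dist = chain_occupancy(ExtensionChain(n_steps=10, k_step=k_step, k_off=k_off), t)
        assert dist.probabilities.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(dist.probabilities >= -1e-12)


class TestGillespieChain:
    def test_monte_carlo_matches_poisson_mean(self):
        """Empirical mean extension within 3 SE of the analytic value k*t = 5."""
        n_mol = 50_000
        chain = ExtensionChain(n_steps=40, k_step=500.0)
        (dist,) = gillespie_chain(chain, n_mol, [0.010], seed=42)
        lam = 5.0
        se = np.sqrt(lam / n_mol)  # Poisson variance, far from censoring
        assert abs(dist.mean_length - lam) <= 3 * se

    def test_matches_occupancy_with_dissociation(self):
        chain = ExtensionChain(n_steps=10, k_step=300.0, k_off=60.0)
        (emp,) = gillespie_chain(chain, 20_000, [0.02], seed=9)
        exact = chain_occupancy(chain, 0.02)
        # per-bin agreement within Monte-Carlo error (3 sigma, binomial)
        p = exact.probabilities
        se = np.sqrt(p * (1 - p) / 20_000)
        assert np.all(np.abs(emp.probabilities - p) <= 3 * se + 1e-3)

    def test_single_molecule_trajectory_is_monotone(self):
        t_grid = np.linspace(0.0, 0.05, 20)
        dists = gillespie_chain(ExtensionChain(n_steps=20, k_step=200.0), 1, t_grid, seed=3)
        lengths = [int(np.argmax(d.probabilities)) for d in dists]
        assert all(b >= a for a, b in zip(lengths, lengths[1:]))

    def test_fixed_seed_reproducible(self):
        chain = ExtensionChain(n_steps=15, k_step=400.0, k_off=20.0)
        a = gillespie_chain(chain, 500, [0.005, 0.02], seed=7)
        b = gillespie_chain(chain, 500, [0.005, 0.02], seed=7)
        for da, db in zip(a, b):
            np.testing.assert_array_equal(da.probabilities, db.probabilities)


class TestPrimerSurvival:
    def test_closed_form_without_dissociation(self):
        chain = ExtensionChain(n_steps=20, k_step=350.0)
        assert primer_survival(chain, 0.01) == pytest.approx(np.exp(-3.5), rel=1e-12)
        assert primer_survival(chain, 0.0) == 1.0

    def test_stalled_unextended_mass_at_long_times(self):
        """Competing risks: the trap strands k_off/(k_step+k_off) of molecules
        at length zero."""
        chain = ExtensionChain(n_steps=20, k_step=350.0, k_off=50.0)
        assert unextended_band_fraction(chain, 10.0) == pytest.approx(0.125, abs=1e-6)
        # band fraction exceeds bound survival once dissociation contributes
        assert unextended_band_fraction(chain, 0.01) > primer_survival(chain, 0.01)

    def test_band_fraction_matches_chain_occupancy(self):
        chain = ExtensionChain(n_steps=20, k_step=350.0, k_off=50.0)
        for t in (0.002, 0.01, 0.05):
            dist = chain_occupancy(chain, t)
            assert unextended_band_fraction(chain, t) == pytest.approx(
                dist.probabilities[0], abs=1e-8
            )
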