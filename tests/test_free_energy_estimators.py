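import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import logsumexp

from lambdahop import build_ladder, run_replica_exchange
from lambdahop.errors import EstimatorError
from lambdahop.free_energy_estimators import (
    MBARResult,
    ReducedEnergyMatrix,
    bar_delta_f,
    classify_isomer,
    delta_g_ez_from_populations,
    hydration_delta_g_from_f,
    hydration_delta_g_from_samples,
    mbar_pmf,
    mbar_solve,
    mixture_delta_g,
    mixture_delta_g_exact,
    neighbor_strata,
    pmf_barrier,
    ratio_from_delta_g_ez,
    reduced_energy_matrix,
    stratified_delta_f,
)
from lambdahop.surrogate_model import exact_delta_g_ez, exact_hydration_delta_g

RT300 = 0.59616


class TestPopulations:
    def test_balanced_zero(self):
        phi = np.array([0.1, -0.2, 3.0, -3.0])
        assert delta_g_ez_from_populations(phi).value == pytest.approx(0.0)

    def test_ratio_e(self):
        # N_E / N_Z = e  ->  dG = RT
        n_z = 1000
        n_e = int(round(n_z * np.e))
        phi = np.concatenate([np.zeros(n_z), np.full(n_e, np.pi)])
        assert delta_g_ez_from_populations(phi).value == pytest.approx(
            RT300 * np.log(n_e / n_z), abs=1e-12)
        assert delta_g_ez_from_populations(phi).value == pytest.approx(RT300, abs=1e-3)

    def test_na_when_single_isomer(self):
        res = delta_g_ez_from_populations(np.zeros(100))
        assert res.is_na and res.value is None and res.n_e == 0

    def test_empty_rejected(self):
        with pytest.raises(EstimatorError):
            delta_g_ez_from_populations(np.zeros(0))

    def test_classification_convention(self):
        assert classify_isomer([0.0, 1.57, 1.58, -3.0]).tolist() == [
            True, True, False, False]


class TestMBAR:
    def test_identical_states(self, rng):
        u = np.tile(rng.normal(size=200), (2, 1))
        res = mbar_solve(ReducedEnergyMatrix(u=u, n_k=[100, 100]))
        assert res.f_k == pytest.approx([0.0, 0.0], abs=1e-8)

    def test_single_state_gauge(self, rng):
        u = rng.normal(size=(1, 50))
        res = mbar_solve(ReducedEnergyMatrix(u=u, n_k=[50]))
        assert res.f_k == pytest.approx([0.0])

    def test_discrete_toy_vs_enumeration(self, rng):
        """3-microstate, 2-Hamiltonian toy: MBAR recovers brute-force ln(Z1/Z2).

        Samples are drawn i.i.d. from each state's exact Boltzmann weights;
        the oracle is the enumerated partition sum.
        """
        u1 = np.array([0.0, 1.0, 2.5])
        u2 = np.array([1.5, 0.2, 0.0])
        z1, z2 = np.exp(-u1).sum(), np.exp(-u2).sum()
        expected_f2 = -np.log(z2) + np.log(z1)  # f_2 - f_1 with f = -ln Z
        n = 20_000
        draws = []
        for u in (u1, u2):
            p = np.exp(-u) / np.exp(-u).sum()
            draws.append(rng.choice(3, size=n, p=p))
        states = np.concatenate(draws)
        mat = ReducedEnergyMatrix(u=np.stack([u1[states], u2[states]]), n_k=[n, n])
        res = mbar_solve(mat)
        # 3-sigma CLT gate from a quick bootstrap over the drawn microstates
        boot = []
        for _ in range(40):
            idx = np.concatenate([rng.integers(0, n, n), n + rng.integers(0, n, n)])
            bmat = ReducedEnergyMatrix(u=mat.u[:, idx], n_k=[n, n])
            boot.append(mbar_solve(bmat, tol=1e-8).f_k[1])
        sigma = np.std(boot, ddof=1)
        assert abs(res.f_k[1] - expected_f2) < 3 * max(sigma, 1e-3)

    def test_gauge_invariance(self, rng):
        u = rng.normal(size=(3, 300))
        mat = ReducedEnergyMatrix(u=u, n_k=[100, 100, 100])
        f0 = mbar_solve(mat).f_k
        # constant added to every entry
        f1 = mbar_solve(ReducedEnergyMatrix(u=u + 7.3, n_k=[100, 100, 100])).f_k
        assert f1 == pytest.approx(f0, abs=1e-9)
        # per-sample (column) shifts
        shift = rng.normal(size=300)
        f2 = mbar_solve(ReducedEnergyMatrix(u=u + shift[None, :], n_k=[100, 100, 100])).f_k
        assert f2 == pytest.approx(f0, abs=1e-9)

    def test_weights_normalized_nonnegative(self, rng):
        u = rng.normal(size=(2, 100))
        mat = ReducedEnergyMatrix(u=u, n_k=[50, 50])
        res = mbar_solve(mat)
        w = res.target_weights(mat, 0)
        assert np.all(w >= 0)
        assert w.sum() == pytest.approx(1.0)

    def test_invalid_matrix(self):
        with pytest.raises(EstimatorError):
            ReducedEnergyMatrix(u=np.zeros((2, 10)), n_k=[4, 4])
        with pytest.raises(EstimatorError):
            ReducedEnergyMatrix(u=np.full((1, 2), np.nan), n_k=[2])


class TestBAR:
    def test_identical_hamiltonians(self, rng):
        zeros = np.zeros(500)
        assert bar_delta_f(zeros, zeros) == pytest.approx(0.0, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(EstimatorError):
            bar_delta_f([], [1.0])

    def test_gaussian_toy(self, rng):
        """Crooks-consistent Gaussian work sets: w_F ~ N(dF + s2/2, s2),
        w_R ~ N(-dF + s2/2, s2) imply the known dF."""
        df, s2, n = 1.3, 1.0, 40_000
        w_f = rng.normal(df + s2 / 2, np.sqrt(s2), n)
        w_r = rng.normal(-df + s2 / 2, np.sqrt(s2), n)
        est = bar_delta_f(w_f, w_r)
        boot = [bar_delta_f(rng.choice(w_f, 2000), rng.choice(w_r, 2000))
                for _ in range(30)]
        sigma = np.std(boot, ddof=1) / np.sqrt(n / 2000)
        assert abs(est - df) < 3 * max(sigma, 5e-3)

    def test_equals_two_state_mbar(self, rng):
        u_i = rng.normal(0.0, 1.0, size=400)
        u_j = u_i + rng.normal(0.8, 0.7, size=400)
        u = np.stack([np.concatenate([u_i[:200], u_i[200:]]),
                      np.concatenate([u_j[:200], u_j[200:]])])
        mat = ReducedEnergyMatrix(u=u, n_k=[200, 200])
        f2 = mbar_solve(mat).f_k[1]
        w_f = u[1, :200] - u[0, :200]
        w_r = u[0, 200:] - u[1, 200:]
        assert bar_delta_f(w_f, w_r) == pytest.approx(f2, abs=1e-6)

    def test_poor_overlap_warns(self, rng):
        with pytest.warns(RuntimeWarning):
            bar_delta_f(rng.normal(100.0, 0.1, 50), rng.normal(100.0, 0.1, 50))


class TestStrata:
    def test_sum_of_zeros(self):
        assert stratified_delta_f(np.zeros(7)) == 0.0

    def test_telescoping_is_exact(self, rng):
        f = rng.normal(size=9)
        strata = f[:-1] - f[1:]  # dF_k = f_k - f_{k+1}
        assert stratified_delta_f(strata) == pytest.approx(f[0] - f[-1], abs=1e-14)

    def test_strata_match_mbar_on_run(self, calibrated_system):
        """BAR strata summed vs end-to-end MBAR on one lambda-hop run."""
        lad = build_ladder("lambda-hop", 8, lambda_min=0.05)
        samples, _ = run_replica_exchange(calibrated_system, lad, 50_000, 10, "Z", seed=31)
        dg_bar = hydration_delta_g_from_samples(samples, subsample=4, method="bar")
        dg_mbar = hydration_delta_g_from_samples(samples, subsample=4, method="mbar")
        assert dg_bar == pytest.approx(dg_mbar, abs=0.05)

    def test_hydration_oracle_recovery(self, calibrated_system):
        """Z-restricted lambda-hop hydration matches the Gaussian x quadrature
        closed form (the run never leaves the Z basin, so it samples the
        restricted partition functions)."""
        lad = build_ladder("lambda-hop", 8, lambda_min=0.05)
        samples, _ = run_replica_exchange(calibrated_system, lad, 100_000, 10, "Z", seed=32)
        est = hydration_delta_g_from_samples(samples, subsample=5)
        exact = exact_hydration_delta_g(calibrated_system, 1.0, 0.05, restrict="Z")
        assert est == pytest.approx(exact, abs=0.1)


class TestPMF:
    def test_uniform_weights_flat(self, rng):
        n = 200_000
        phi = rng.uniform(-np.pi, np.pi, n)
        u = np.zeros((1, n))
        mat = ReducedEnergyMatrix(u=u, n_k=[n], phi=phi)
        res = mbar_solve(mat)
        centers, prof = mbar_pmf(mat, res, n_bins=12)
        assert np.nanmax(prof) < 0.05

    def test_degenerate_warns(self):
        mat = ReducedEnergyMatrix(u=np.zeros((1, 5)), n_k=[5], phi=np.full(5, 0.1))
        res = mbar_solve(mat)
        with pytest.warns(RuntimeWarning):
            mbar_pmf(mat, res, n_bins=8)

    def test_pmf_vs_quadrature_small_system(self, small_system):
        lad = build_ladder("ST-HREM", 4, S_min=0.25)
        samples, _ = run_replica_exchange(small_system, lad, 150_000, 10, "Z", seed=33,
                                          sample_interval=5)
        mat = reduced_energy_matrix(samples, subsample=3)
        res = mbar_solve(mat)
        centers, prof = mbar_pmf(mat, res, n_bins=36, T=small_system.T0)
        from lambdahop.surrogate_model import exact_phi_free_energy_profile
        grid, exact = exact_phi_free_energy_profile(small_system, 1.0, 1.0)
        exact_at = np.interp(centers, grid, exact)
        ok = np.isfinite(prof)
        assert np.nanmax(np.abs(prof[ok] - exact_at[ok])) < 0.15

    def test_pmf_consistent_with_populations(self, small_system):
        """RT ln of PMF-integrated well masses equals the population estimate."""
        lad = build_ladder("ST-HREM", 4, S_min=0.25)
        samples, _ = run_replica_exchange(small_system, lad, 100_000, 10, "Z", seed=34)
        mat = reduced_energy_matrix(samples, subsample=2)
        res = mbar_solve(mat)
        w = res.target_weights(mat, 0)
        e_mass = w[np.abs(mat.phi) >= np.pi / 2].sum()
        z_mass = w[np.abs(mat.phi) < np.pi / 2].sum()
        dg_w = small_system.RT * np.log(e_mass / z_mass)
        pop = delta_g_ez_from_populations(samples.target_phi(), T=small_system.T0)
        assert dg_w == pytest.approx(pop.value, abs=3 * (pop.stderr or 0.05) + 0.05)


class TestMixture:
    def test_equal_isomers_identity(self):
        for r in (0.1, 1.0, 7.5):
            assert mixture_delta_g(-5.0, -5.0, r) == pytest.approx(-5.0, abs=1e-12)
            assert mixture_delta_g_exact(-5.0, -5.0, r) == pytest.approx(-5.0, abs=1e-12)

    def test_pure_e_limit(self):
        assert mixture_delta_g(-5.0, -2.0, 1e-12) == pytest.approx(-5.0, abs=1e-6)

    def test_invalid_ratio(self):
        with pytest.raises(EstimatorError):
            mixture_delta_g(-5.0, -2.0, 0.0)

    def test_published_worked_example(self):
        # 16 ns row with the time-matched lambda-hop ratio
        r_ze = 1.0 / ratio_from_delta_g_ez(0.68)
        assert mixture_delta_g(-18.57, -15.91, r_ze) == pytest.approx(-18.41, abs=0.03)

    def test_exact_form_matches_quadrature_mixture(self, calibrated_system):
        """The sign-conjugate identity reproduces the exact mixture oracle
        when fed exact per-isomer values and the exact coupled-state ratio."""
        dg_e = exact_hydration_delta_g(calibrated_system, 1.0, 0.05, restrict="E")
        dg_z = exact_hydration_delta_g(calibrated_system, 1.0, 0.05, restrict="Z")
        r_ez = ratio_from_delta_g_ez(exact_delta_g_ez(calibrated_system, 1.0, 1.0))
        mix = mixture_delta_g_exact(dg_e, dg_z, 1.0 / r_ez)
        assert mix == pytest.approx(
            exact_hydration_delta_g(calibrated_system, 1.0, 0.05), abs=1e-9)

    @given(dg_e=st.floats(-20, 5), dg_z=st.floats(-20, 5), r=st.floats(0.01, 100))
    @settings(max_examples=60, deadline=None)
    def test_exact_is_sign_conjugate(self, dg_e, dg_z, r):
        lhs = mixture_delta_g_exact(dg_e, dg_z, r)
        rhs = -mixture_delta_g(-dg_e, -dg_z, r)
        assert lhs == pytest.approx(rhs, rel=1e-12, abs=1e-12)


class TestRatio:
    def test_zero_is_unity(self):
        assert ratio_from_delta_g_ez(0.0) == 1.0

    def test_rt_ln_two(self):
        assert ratio_from_delta_g_ez(RT300 * np.log(2.0)) == pytest.approx(2.0)

    def test_sthrem_row_value(self):
        assert ratio_from_delta_g_ez(0.53) == pytest.approx(2.4327518886226622, abs=1e-9)

    def test_nonfinite_rejected(self):
        with pytest.raises(EstimatorError):
            ratio_from_delta_g_ez(np.inf)


class TestConversions:
    def test_hydration_direction(self):
        # dF = ln(Z_last/Z_first) = +2 -> F(first) - F(last) = +2 RT
        assert hydration_delta_g_from_f(2.0, T=300.0) == pytest.approx(2 * RT300)
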