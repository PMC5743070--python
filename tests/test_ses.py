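"""SES engine: chi metrics, design system, OMP vs exhaustive oracle,
l-curve, averaging, alpha scan."""

import itertools

import numpy as np
import pytest

from flexens import ses
from flexens.relax import DomainTauExperiment
from flexens.saxs import ScatteringProfile
from flexens.ses import SESError
from flexens.hydro import TauPrediction


def toy_profiles(n_q=12, n_ens=6, seed=0, decay_range=(50.0, 900.0)):
    rng = np.random.default_rng(seed)
    q = np.linspace(0.01, 0.3, n_q)
    scales = rng.uniform(*decay_range, size=n_ens)
    mat = np.exp(-np.outer(q ** 2, scales) / 3.0)
    return q, mat


def exp_from_weights(q, mat, w, sigma_frac=0.01):
    I = mat @ w
    sigma = sigma_frac * I + 1e-4 * I[0]
    return ScatteringProfile(q, I, sigma)


def toy_taus(n_ens, seed=0):
    rng = np.random.default_rng(seed)
    return [TauPrediction(f"m{k}", float(rng.uniform(8, 25)),
                          float(rng.uniform(4, 15))) for k in range(n_ens)]


def exhaustive_best(system, size):
    """Global NNLS optimum over all supports of the given size (oracle)."""
    best = (np.inf, None, None)
    for sup in itertools.combinations(range(system.n_ens), size):
        w, cost = ses._refit(system, list(sup))
        if cost < best[0]:
            best = (cost, sup, w)
    return best


class TestChiSaxs:
    def test_exact_member_zero(self):
        q, mat = toy_profiles()
        w = np.zeros(6)
        w[2] = 1.0
        exp = exp_from_weights(q, mat, w)
        assert ses.chi_saxs(w, mat, exp) == pytest.approx(0.0, abs=1e-12)

    def test_one_sigma_offset_gives_one(self):
        q, mat = toy_profiles()
        w = np.full(6, 1 / 6)
        exp = exp_from_weights(q, mat, w)
        exp.I = exp.I + exp.sigma
        assert ses.chi_saxs(w, mat, exp) == pytest.approx(1.0, rel=1e-12)

    def test_matches_direct_sum_oracle(self):
        q, mat = toy_profiles(n_ens=3, seed=4)
        w = np.array([0.2, 0.5, 0.3])
        exp = exp_from_weights(q, mat, np.array([0.3, 0.3, 0.4]))
        direct = 0.0
        for i in range(len(q)):
            model = sum(mat[i, k] * w[k] for k in range(3))
            direct += ((model - exp.I[i]) / exp.sigma[i]) ** 2
        direct = np.sqrt(direct / len(q))
        assert ses.chi_saxs(w, mat, exp) == pytest.approx(direct, rel=1e-12)

    def test_zero_sigma_rejected(self):
        q, mat = toy_profiles()
        exp = exp_from_weights(q, mat, np.full(6, 1 / 6))
        exp.sigma = np.zeros_like(exp.sigma)
        with pytest.raises(SESError):
            ses.chi_saxs(np.full(6, 1 / 6), mat, exp)


class TestChiRelax:
    def test_exact_average_zero(self):
        taus = toy_taus(4)
        w = np.array([0.4, 0.3, 0.2, 0.1])
        ta = sum(t.tau_A * wk for t, wk in zip(taus, w))
        tb = sum(t.tau_B * wk for t, wk in zip(taus, w))
        exp = DomainTauExperiment(ta, 1.0, tb, 1.0)
        assert ses.chi_relax(w, taus, exp) == pytest.approx(0.0, abs=1e-12)

    def test_sigma_offset_sqrt2(self):
        taus = [TauPrediction("a", 20.0, 10.0)]
        exp = DomainTauExperiment(21.0, 1.0, 11.0, 1.0)
        assert ses.chi_relax(np.array([1.0]), taus, exp) == pytest.approx(
            np.sqrt(2.0), rel=1e-12)

    def test_hand_computed_two_member(self):
        taus = [TauPrediction("a", 20.0, 8.0), TauPrediction("b", 10.0, 14.0)]
        w = np.array([0.25, 0.75])
        exp = DomainTauExperiment(14.0, 2.0, 11.0, 3.0)
        # hand: tauA = 0.25*20+0.75*10 = 12.5 -> (12.5-14)/2 = -0.75
        #       tauB = 0.25*8+0.75*14 = 12.5 -> (12.5-11)/3 = 0.5
        expected = np.sqrt(0.75 ** 2 + 0.5 ** 2)
        assert ses.chi_relax(w, taus, exp) == pytest.approx(expected,
                                                            rel=1e-12)


class TestDesignSystem:
    def test_shape(self):
        q, mat = toy_profiles(n_q=30, n_ens=100, seed=1)
        taus = toy_taus(100)
        exp = exp_from_weights(q, mat, np.full(100, 0.01))
        tau_exp = DomainTauExperiment(15.0, 1.0, 9.0, 1.0)
        system = ses.build_design_system(mat, taus, exp, tau_exp, 0.06)
        assert system.C.shape == (32, 100)
        assert len(system.B) == 32
        assert system.row_meta[-2:] == ["TAU_A", "TAU_B"]

    def test_alpha_zero_reduces_to_saxs(self):
        q, mat = toy_profiles()
        taus = toy_taus(6)
        w = np.full(6, 1 / 6)
        exp = exp_from_weights(q, mat, np.array([0.5, 0.5, 0, 0, 0, 0]))
        tau_exp = DomainTauExperiment(15.0, 1.0, 9.0, 1.0)
        system = ses.build_design_system(mat, taus, exp, tau_exp, 0.0)
        resid = system.C @ w - system.B
        assert float(resid @ resid) == pytest.approx(
            len(q) * ses.chi_saxs(w, mat, exp) ** 2, rel=1e-9)
        # tau rows are zero rows
        np.testing.assert_array_equal(system.C[-2:], 0.0)

    def test_alpha_doubling_scales_tau_rows(self):
        q, mat = toy_profiles()
        taus = toy_taus(6)
        exp = exp_from_weights(q, mat, np.full(6, 1 / 6))
        tau_exp = DomainTauExperiment(15.0, 1.0, 9.0, 1.0)
        s1 = ses.build_design_system(mat, taus, exp, tau_exp, 0.05)
        s2 = ses.build_design_system(mat, taus, exp, tau_exp, 0.10)
        w = np.full(6, 1 / 6)
        r1 = (s1.C @ w - s1.B)[-2:]
        r2 = (s2.C @ w - s2.B)[-2:]
        assert float(r2 @ r2) == pytest.approx(2.0 * float(r1 @ r1),
                                               rel=1e-9)

    def test_mismatched_members(self):
        q, mat = toy_profiles()
        exp = exp_from_weights(q, mat, np.full(6, 1 / 6))
        tau_exp = DomainTauExperiment(15.0, 1.0, 9.0, 1.0)
        with pytest.raises(SESError):
            ses.build_design_system(mat, toy_taus(5), exp, tau_exp, 0.1)


class TestOMP:
    def test_exact_support_recovery(self):
        q, mat = toy_profiles(n_q=15, n_ens=10, seed=2)
        w_true = np.zeros(10)
        w_true[[3, 7]] = [0.6, 0.4]
        exp = exp_from_weights(q, mat, w_true, sigma_frac=0.01)
        tau_exp = DomainTauExperiment(15.0, 1.0, 9.0, 1.0)
        system = ses.build_design_system(mat, toy_taus(10), exp, tau_exp, 0.0)
        sols = ses.omp_nonneg(system, max_size=4, beam_width=5)
        oracle_cost, oracle_sup, _ = exhaustive_best(system, 2)
        assert tuple(sols[1].support) == oracle_sup == (3, 7)
        assert sols[1].chi2_total <= oracle_cost * (1 + 1e-9)

    def test_chi2_nonincreasing(self):
        q, mat = toy_profiles(n_q=20, n_ens=15, seed=3)
        rng = np.random.default_rng(3)
        exp = exp_from_weights(q, mat, rng.dirichlet(np.ones(15)))
        tau_exp = DomainTauExperiment(15.0, 1.0, 9.0, 1.0)
        system = ses.build_design_system(mat, toy_taus(15), exp, tau_exp,
                                         0.02)
        sols = ses.omp_nonneg(system, max_size=10, beam_width=5)
        costs = [s.chi2_total for s in sols]
        assert all(a >= b - 1e-12 for a, b in zip(costs, costs[1:]))

    def test_oracle_equivalence_random_systems(self):
        # OMP within 1% of the exhaustive global optimum, sizes <= 3
        rng = np.random.default_rng(0)
        for trial in range(50):
            n_ens = int(rng.integers(8, 13))
            q, mat = toy_profiles(n_q=10, n_ens=n_ens, seed=trial + 100)
            w_true = rng.dirichlet(np.ones(n_ens))
            exp = exp_from_weights(q, mat, w_true, sigma_frac=0.02)
            exp.I = exp.I + rng.normal(size=len(q)) * exp.sigma
            taus = toy_taus(n_ens, seed=trial)
            ta = sum(t.tau_A * wk for t, wk in zip(taus, w_true))
            tb = sum(t.tau_B * wk for t, wk in zip(taus, w_true))
            tau_exp = DomainTauExperiment(ta, 0.05 * ta, tb, 0.05 * tb)
            system = ses.build_design_system(mat, taus, exp, tau_exp, 0.05)
            sols = ses.omp_nonneg(system, max_size=3, beam_width=10)
            for size in (1, 2, 3):
                oracle_cost, _, _ = exhaustive_best(system, size)
                assert sols[size - 1].chi2_total <= oracle_cost * 1.01 + 1e-9

    def test_zero_b_returns_empty(self):
        q, mat = toy_profiles()
        system = ses.DesignSystem(mat, np.zeros(len(q)), 0.0,
                                  [f"SAXS{i}" for i in range(len(q))],
                                  len(q), normalize_weights=False)
        sols = ses.omp_nonneg(system, max_size=3)
        assert sols[0].w.sum() == 0.0

    def test_weights_nonnegative_and_identity(self):
        q, mat = toy_profiles(n_q=20, n_ens=12, seed=5)
        rng = np.random.default_rng(5)
        exp = exp_from_weights(q, mat, rng.dirichlet(np.ones(12)))
        taus = toy_taus(12, seed=5)
        tau_exp = DomainTauExperiment(15.0, 1.0, 9.0, 1.0)
        system = ses.build_design_system(mat, taus, exp, tau_exp, 0.07)
        for sol in ses.omp_nonneg(system, max_size=8):
            assert np.all(sol.w >= 0)
            ident = sol.chi2_saxs + sol.alpha * sol.chi_relax ** 2
            assert ident == pytest.approx(sol.chi2_total, rel=1e-9)


class TestLCurve:
    def test_documented_sequence(self):
        # second difference of log chi maximal at s = 2
        assert ses.l_curve_select([10.0, 2.0, 1.9, 1.88, 1.87]) == 2

    def test_flat_sequence_warns(self):
        warnings = []
        size = ses.l_curve_select([1.0, 1.0, 1.0, 1.0], warn=warnings.append)
        assert size == 1
        assert warnings

    def test_truth_size_selection_simulation(self):
        # 3-member truth (well-separated sizes) at 1% noise: knee at 3 in
        # >= 90% of seeds
        hits = 0
        n_seeds = 100
        q = np.linspace(0.01, 0.3, 30)
        scales = np.linspace(60.0, 1600.0, 12)
        mat = np.exp(-np.outer(q ** 2, scales) / 3.0)
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            w_true = np.zeros(12)
            members = np.array([0, 5, 10]) + rng.integers(0, 2, size=3)
            w_true[members] = rng.dirichlet(np.ones(3) * 8.0)
            exp = exp_from_weights(q, mat, w_true, sigma_frac=0.01)
            exp.I = exp.I + rng.normal(size=len(q)) * exp.sigma
            tau_exp = DomainTauExperiment(15.0, 1.0, 9.0, 1.0)
            system = ses.build_design_system(mat, None, exp, tau_exp, 0.0)
            sols = ses.omp_nonneg(system, max_size=8, beam_width=5)
            if ses.l_curve_select([s.chi2_total for s in sols]) == 3:
                hits += 1
        assert hits >= 0.9 * n_seeds


class TestAveraging:
    def test_single_solution_populations(self):
        q, mat = toy_profiles()
        w = np.array([0.0, 2.0, 0.0, 1.0, 0.0, 1.0])
        sol = ses.SparseSolution(np.array([1, 3, 5]), w, 1.0, 0.5, 1.0, 0.0)
        model = ses.average_near_optimal([sol])
        np.testing.assert_allclose(model.populations,
                                   w / w.sum(), rtol=1e-12)

    def test_identical_solutions_unchanged(self):
        w = np.array([0.0, 2.0, 0.0, 1.0])
        sols = [ses.SparseSolution(np.array([1, 3]), w, 1.0, 0.5, 1.0, 0.0)
                for _ in range(2)]
        model = ses.average_near_optimal(sols)
        np.testing.assert_allclose(model.populations, w / w.sum(),
                                   rtol=1e-12)

    def test_populations_sum_to_one(self):
        rng = np.random.default_rng(7)
        sols = []
        for _ in range(5):
            w = np.zeros(8)
            sup = rng.choice(8, size=3, replace=False)
            w[sup] = rng.uniform(0.5, 2.0, size=3)
            sols.append(ses.SparseSolution(np.sort(sup), w, 1.0,
                                           0.5, 1.0 + rng.uniform(0, 0.01),
                                           0.0))
        model = ses.average_near_optimal(sols, rel_tol=0.05)
        assert model.populations.sum() == pytest.approx(1.0, abs=1e-12)


@pytest.fixture(scope="module")
def scan_setup():
    q, mat = toy_profiles(n_q=25, n_ens=20, seed=9,
                          decay_range=(60.0, 1600.0))
    rng = np.random.default_rng(9)
    w_true = np.zeros(20)
    w_true[[2, 9, 17]] = [0.5, 0.3, 0.2]
    exp = exp_from_weights(q, mat, w_true, sigma_frac=0.01)
    exp.I = exp.I + rng.normal(size=len(q)) * exp.sigma
    taus = toy_taus(20, seed=9)
    ta = sum(t.tau_A * wk for t, wk in zip(taus, w_true))
    tb = sum(t.tau_B * wk for t, wk in zip(taus, w_true))
    tau_exp = DomainTauExperiment(ta * 1.02, 0.05 * ta, tb * 0.98,
                                  0.05 * tb)
    return mat, taus, exp, tau_exp


class TestAlphaScan:
    def test_alpha_zero_is_saxs_only(self, scan_setup):
        mat, taus, exp, tau_exp = scan_setup
        rows = ses.alpha_scan(mat, taus, exp, tau_exp, [0.0, 0.1])
        m0, _ = ses.fit_ensemble(mat, None, exp, None, 0.0)
        assert rows[0]["chi_saxs"] == pytest.approx(m0.chi_saxs, rel=1e-9)

    def test_monotone_tradeoff(self, scan_setup):
        mat, taus, exp, tau_exp = scan_setup
        rows = ses.alpha_scan(mat, taus, exp, tau_exp,
                              [1e-4, 1e-2, 1.0, 100.0])
        # endpoints honour the trade-off even if the middle is solver-noisy
        assert rows[-1]["chi_relax"] <= rows[0]["chi_relax"] + 1e-6
        assert rows[-1]["chi_saxs"] >= rows[0]["chi_saxs"] - 1e-6

    def test_conflicting_pool_never_fits_both(self):
        # truth needs a tau mix the restricted pool cannot reach: the tau
        # misfit stays high at every alpha (two-observable conflict)
        q, mat = toy_profiles(n_q=25, n_ens=10, seed=10)
        rng = np.random.default_rng(10)
        w_true = rng.dirichlet(np.ones(10))
        exp = exp_from_weights(q, mat, w_true, sigma_frac=0.01)
        taus = [TauPrediction(f"m{k}", 10.0 + 0.1 * k, 5.0 + 0.05 * k)
                for k in range(10)]
        tau_exp = DomainTauExperiment(40.0, 1.0, 30.0, 0.5)  # unreachable
        rows = ses.alpha_scan(mat, taus, exp, tau_exp,
                              [0.0, 0.01, 0.1, 1.0])
        assert all(r["chi_relax"] > 3.0 for r in rows if r["alpha"] > 0)

    def test_equal_fit_alpha_exists_for_mixed_pool(self, scan_setup):
        mat, taus, exp, tau_exp = scan_setup
        grid = [0.0, 1e-3, 1e-2, 0.1, 1.0]
        rows = ses.alpha_scan(mat, taus, exp, tau_exp, grid)
        a = ses.select_equal_fit_alpha(rows)
        row = next(r for r in rows if r["alpha"] == a)
        chi_s0 = rows[0]["chi_saxs"]
        plateau_r = rows[-1]["chi_relax"]
        assert row["chi_saxs"] <= 1.10 * max(chi_s0, 1e-6) + 0.35
        assert row["chi_relax"] <= 1.10 * plateau_r + 1e-9

    def test_empty_grid_rejected(self, scan_setup):
        mat, taus, exp, tau_exp = scan_setup
        with pytest.raises(SESError):
            ses.alpha_scan(mat, taus, exp, tau_exp, [])


class TestScaleRobustness:
    def test_constraint_row_vs_rescaled_unconstrained(self):
        # well-posed system: toggling the sum-to-one row and rescaling the
        # experimental intensity changes populations by < 1%
        q, mat = toy_profiles(n_q=25, n_ens=8, seed=12,
                              decay_range=(80.0, 1200.0))
        w_true = np.zeros(8)
        w_true[[1, 4, 6]] = [0.5, 0.3, 0.2]
        exp = exp_from_weights(q, mat, w_true, sigma_frac=0.005)
        tau_exp = DomainTauExperiment(15.0, 1.0, 9.0, 1.0)
        m1, _ = ses.fit_ensemble(mat, None, exp, None, 0.0, max_size=5,
                                 normalize_weights=True)
        exp2 = ScatteringProfile(q, 3.0 * exp.I, 3.0 * exp.sigma)
        m2, _ = ses.fit_ensemble(mat, None, exp2, None, 0.0, max_size=5,
                                 normalize_weights=False)
        assert np.max(np.abs(m1.populations - m2.populations)) < 0.01
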