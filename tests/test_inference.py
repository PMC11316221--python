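"""Two-stage bias inference: closed-form updates, alternating optimization,
trend regression and the composed correction."""
import numpy as np
import pytest
from scipy import optimize

from rebar import (
    RebarConfig,
    compose_and_correct,
    correct_log_counts,
    estimate_trend,
    fit_loglinear,
    residual_projector,
    run_stage1,
    update_prevalence_deviations,
    update_susceptibilities,
)
from rebar.fitting import FitnessErrors


def projected_effect(logc, u, gamma):
    """The identifiable Stage-1 object: u x (residual-projected prevalence)."""
    out = np.zeros_like(logc.values)
    for assay, cols in logc.assay_slices():
        P = residual_projector(assay.times())
        out[:, cols] = np.outer(u, P @ gamma[cols])
    return out


class TestSusceptibilityUpdate:
    def test_linear_trajectories_give_zero(self, logc_from_values):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.outer([0.5, -1.0, 2.0], t) + np.array([[1.0], [2.0], [3.0]])
        logc = logc_from_values(y, [tuple(t)])
        u = update_susceptibilities(logc, v_hat=np.array([0.1, -0.2, 0.3, 0.4]), ridge=0.1)
        np.testing.assert_allclose(u, 0, atol=1e-12)

    def test_exact_recovery_for_projected_prevalence(self, logc_from_values):
        rng = np.random.default_rng(0)
        t = np.array([0.0, 1.0, 2.0, 3.0])
        P = residual_projector(t)
        v = P @ rng.normal(size=4)
        u_true = rng.normal(size=6)
        logc = logc_from_values(np.outer(u_true, v), [tuple(t)])
        u = update_susceptibilities(logc, v, ridge=0.0)
        np.testing.assert_allclose(u, u_true, atol=1e-10)

    def test_matches_bruteforce_scalar_minimizer(self, logc_from_values):
        """Closed form vs 1-D numerical minimization of the stated objective."""
        rng = np.random.default_rng(42)
        tps = [(0.0, 1.0, 2.0, 3.0), (0.0, 1.0, 2.0, 4.0, 6.0)]
        logc = logc_from_values(rng.normal(size=(4, 9)), tps)
        v_hat = rng.normal(size=9)
        ridge = 0.3
        u = update_susceptibilities(logc, v_hat, ridge)
        projectors = [residual_projector(a.times()) for a, _ in logc.assay_slices()]

        for i in range(4):
            def obj(ui):
                total = ridge * ui**2
                for (assay, cols), P in zip(logc.assay_slices(), projectors):
                    r = P @ (logc.values[i, cols] - ui * v_hat[cols])
                    total += float(r @ r)
                return total

            res = optimize.minimize_scalar(obj, bounds=(-10, 10), method="bounded",
                                           options={"xatol": 1e-10})
            assert u[i] == pytest.approx(res.x, abs=1e-6)

    def test_degenerate_prevalence_requires_ridge(self, logc_from_values):
        t = np.array([0.0, 1.0, 2.0])
        logc = logc_from_values(np.random.default_rng(1).normal(size=(3, 3)), [tuple(t)])
        v_in_span = 2.0 + 3.0 * t  # lies in span{1, t}
        with pytest.raises(ValueError, match="ridge"):
            update_susceptibilities(logc, v_in_span, ridge=0.0)


class TestPrevalenceDeviationUpdate:
    def test_zero_susceptibilities_warn_and_return_zero(self, logc_from_values):
        logc = logc_from_values(np.random.default_rng(2).normal(size=(3, 3)), [(0, 1, 2)])
        with pytest.warns(RuntimeWarning, match="unidentifiable"):
            g = update_prevalence_deviations(logc, np.zeros(3), "A1", ridge=0.1)
        np.testing.assert_array_equal(g, 0)

    def test_exact_recovery_by_construction(self, logc_from_values):
        rng = np.random.default_rng(3)
        t = np.array([0.0, 1.0, 2.0, 3.0])
        gamma_true = residual_projector(t) @ rng.normal(size=4)
        u = rng.normal(size=5)
        logc = logc_from_values(np.outer(u, gamma_true), [tuple(t)])
        g = update_prevalence_deviations(logc, u, "A1", ridge=0.0)
        np.testing.assert_allclose(g, gamma_true, atol=1e-10)

    def test_matches_numerical_quadratic_solution(self, logc_from_values):
        """Closed form vs an independent quadratic solve built from objective
        evaluations only (finite differences are exact for quadratics)."""
        rng = np.random.default_rng(7)
        t = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        P = residual_projector(t)
        logc = logc_from_values(rng.normal(size=(6, 5)), [tuple(t)])
        u = rng.normal(size=6)
        ridge = 0.1

        def obj(g_free):
            gamma = P @ g_free  # constrain to the range of the projector
            total = ridge * float(gamma @ gamma)
            for i in range(6):
                r = P @ (logc.values[i] - u[i] * gamma)
                total += float(r @ r)
            return total

        n = t.size
        e = np.eye(n)
        J0 = obj(np.zeros(n))
        H = np.empty((n, n))
        b = np.empty(n)
        for j in range(n):
            b[j] = -(obj(e[j]) - obj(-e[j])) / 2.0
            for k in range(n):
                H[j, k] = obj(e[j] + e[k]) - obj(e[j]) - obj(e[k]) + J0
        g_free, *_ = np.linalg.lstsq(H, b, rcond=None)
        gamma_numeric = P @ g_free

        gamma = update_prevalence_deviations(logc, u, "A1", ridge)
        np.testing.assert_allclose(gamma, gamma_numeric, atol=1e-8)

    def test_result_is_orthogonal_to_one_and_t(self, logc_from_values):
        rng = np.random.default_rng(8)
        t = np.array([0.0, 1.0, 2.0, 4.0])
        logc = logc_from_values(rng.normal(size=(5, 4)), [tuple(t)])
        g = update_prevalence_deviations(logc, rng.normal(size=5), "A1", ridge=0.05)
        assert g.sum() == pytest.approx(0, abs=1e-10)
        assert g @ t == pytest.approx(0, abs=1e-10)


class TestStage1:
    def test_no_bias_no_noise_gives_null_effect(self, logc_from_values):
        rng = np.random.default_rng(4)
        t = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.outer(rng.normal(size=10), t) + rng.normal(size=10)[:, None]
        logc = logc_from_values(y, [tuple(t)])
        with pytest.warns(RuntimeWarning, match="no bias mode"):
            s1 = run_stage1(logc, RebarConfig(seed=0))
        effect = projected_effect(logc, s1.u, s1.gamma)
        assert np.max(np.abs(effect)) < 1e-6

    def test_noiseless_rank_one_recovery_any_seed(self, noiseless_rank_one):
        logc, truth = noiseless_rank_one(seed=5)
        target = projected_effect(logc, truth["u"], truth["gamma"])
        for seed in (0, 1, 99):
            s1 = run_stage1(logc, RebarConfig(seed=seed, ridge=0.0))
            effect = projected_effect(logc, s1.u, s1.gamma)
            np.testing.assert_allclose(effect, target, atol=1e-6)

    def test_gamma_orthogonality_enforced(self, noiseless_rank_one):
        logc, _ = noiseless_rank_one(seed=6)
        s1 = run_stage1(logc, RebarConfig(seed=0))
        for assay, cols in logc.assay_slices():
            g = s1.gamma[cols]
            assert g.sum() == pytest.approx(0, abs=1e-9)
            assert g @ assay.times() == pytest.approx(0, abs=1e-9)

    def test_unit_rms_and_sign_convention(self, noiseless_rank_one):
        logc, _ = noiseless_rank_one(seed=7)
        s1 = run_stage1(logc, RebarConfig(seed=0))
        assert np.sqrt(np.mean(s1.u**2)) == pytest.approx(1.0, rel=1e-9)
        assert s1.u[np.argmax(np.abs(s1.u))] > 0

    def test_effect_is_seed_stable(self, logc_from_values):
        rng = np.random.default_rng(9)
        t = (0.0, 1.0, 2.0, 3.0)
        y = rng.normal(size=(30, 8)) * 0.02
        y += np.outer(rng.normal(size=30), np.r_[residual_projector(t) @ rng.normal(size=4) + 0.3,
                                                 residual_projector(t) @ rng.normal(size=4)])
        logc = logc_from_values(y, [t, t])
        cfg = dict(tol=1e-12, max_iter=2000)
        e1 = projected_effect(logc, *(lambda r: (r.u, r.gamma))(run_stage1(logc, RebarConfig(seed=1, **cfg))))
        e2 = projected_effect(logc, *(lambda r: (r.u, r.gamma))(run_stage1(logc, RebarConfig(seed=2, **cfg))))
        np.testing.assert_allclose(e1, e2, atol=1e-4)


class TestTrendRegression:
    def make_errors(self, delta):
        delta = np.asarray(delta, dtype=float)[:, None]
        ids = tuple(f"v{i}" for i in range(delta.shape[0]))
        return FitnessErrors(ids, ("A1",), delta)

    def test_exact_proportionality(self):
        lam, _ = estimate_trend(self.make_errors([2.0, 4.0]), np.array([1.0, 2.0]))
        assert lam[0] == pytest.approx(2.0, abs=1e-12)
        lam0, _ = estimate_trend(
            self.make_errors([2.0, 4.0]), np.array([1.0, 2.0]), fit_intercept=False
        )
        assert lam0[0] == pytest.approx(2.0, abs=1e-12)

    def test_zero_susceptibilities_warn(self):
        with pytest.warns(RuntimeWarning, match="unidentifiable"):
            lam, _ = estimate_trend(self.make_errors([1.0, 2.0]), np.zeros(2))
        assert lam[0] == 0.0

    def test_recovery_within_three_standard_errors(self):
        rng = np.random.default_rng(12)
        u = rng.normal(size=100)
        lam_true = 0.07
        delta = u * lam_true + rng.normal(0, 0.01, 100)
        delta -= delta.mean()  # group-mean centering, as in the pipeline
        lam, se = estimate_trend(self.make_errors(delta), u)
        assert abs(lam[0] - lam_true) < 3 * se[0]


class TestComposeAndCorrect:
    def test_zero_susceptibility_is_identity(self, logc_from_values):
        rng = np.random.default_rng(13)
        logc = logc_from_values(rng.normal(size=(4, 8)), [(0, 1, 2, 3)] * 2)
        res = compose_and_correct(logc, np.zeros(4), np.zeros(8), np.zeros(2))
        np.testing.assert_array_equal(res.corrected_log_counts.values, logc.values)
        np.testing.assert_array_equal(res.corrected_fits.slope, res.raw_fits.slope)

    def test_single_entry_arithmetic(self, logc_from_values):
        logc = logc_from_values(np.full((1, 3), 5.0), [(0, 1, 2)])
        # v = lambda * t with lambda = 0.5 -> v = [0, 0.5, 1]
        res = compose_and_correct(logc, np.array([2.0]), np.zeros(3), np.array([0.5]))
        assert res.corrected_log_counts.values[0, 1] == pytest.approx(4.0, abs=1e-12)

    def test_refit_matches_trend_subtraction(self, noiseless_rank_one):
        logc, truth = noiseless_rank_one(seed=14)
        res = compose_and_correct(logc, truth["u"], truth["gamma"], truth["lam"])
        shortcut = res.raw_fits.slope - np.outer(truth["u"], truth["lam"])
        np.testing.assert_allclose(res.corrected_fits.slope, shortcut, atol=1e-10)


class TestFullCorrection:
    def test_noiseless_recovery_of_true_fitness(self, noiseless_rank_one):
        logc, truth = noiseless_rank_one(seed=15)
        result = correct_log_counts(logc, truth["control_ids"], RebarConfig(seed=0, ridge=0.0))
        f_true = np.tile(truth["f"][:, None], (1, len(logc.assays)))
        np.testing.assert_allclose(result.corrected_fits.slope, f_true, atol=1e-6)

    def test_second_pass_is_near_noop(self, noiseless_rank_one):
        logc, truth = noiseless_rank_one(seed=16)
        cfg = RebarConfig(seed=0, ridge=0.0)
        first = correct_log_counts(logc, truth["control_ids"], cfg)
        first_effect = logc.values - first.corrected_log_counts.values
        second = correct_log_counts(first.corrected_log_counts, truth["control_ids"], cfg)
        second_effect = first.corrected_log_counts.values - second.corrected_log_counts.values
        assert np.linalg.norm(second_effect) < 0.1 * np.linalg.norm(first_effect)
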