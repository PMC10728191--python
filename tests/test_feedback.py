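"""Feasibility, stability, community feedback and dynamics of the model."""

import numpy as np
import pytest

import psfdilution as psf
from psfdilution.feedback import (
    InteractionMatrix,
    cramer_equilibrium,
    pairwise_feedback,
    replicator_jacobian,
    screen_summary,
)
from psfdilution.predictor import REFERENCE_COEFFICIENTS, reference_predictor


def im(sigma, w_mono=None):
    sigma = np.asarray(sigma, dtype=float)
    n = sigma.shape[0]
    return InteractionMatrix(
        species=tuple(f"s{i}" for i in range(n)),
        sigma=sigma,
        w_mono=float(sigma[0, 0]) if w_mono is None else w_mono,
    )


def random_symmetric_stable(rng, n):
    """Near-diagonal negative symmetric matrix: feasible and stable."""
    noise = rng.normal(0, 0.1, size=(n, n))
    sigma = -(np.eye(n)) + (noise + noise.T) / 2
    np.fill_diagonal(sigma, -1.0)
    return sigma


class TestConspecificSigma:
    def test_reference_coefficients(self):
        assert psf.conspecific_sigma(reference_predictor()) == pytest.approx(-1.7355)

    def test_arithmetic(self):
        pred = psf.PsfPredictor(coefficients={"a": -1.5, "b": -0.5}, intercept=0.0)
        assert psf.conspecific_sigma(pred) == pytest.approx(-1.0)
        neutral = psf.PsfPredictor(coefficients={"a": 0.0}, intercept=0.0)
        assert psf.conspecific_sigma(neutral) == 0.0


class TestBuildInteractionMatrix:
    def test_construction_identity(self, dissims):
        sub = {g: dissims[g] for g in REFERENCE_COEFFICIENTS}
        A = psf.build_interaction_matrix(reference_predictor(), sub)
        m = psf.predict_pairwise_psf(reference_predictor(), sub)
        for i in range(0, 18, 5):
            for j in range(i + 1, 18, 4):
                assert pairwise_feedback(A.sigma, i, j) == pytest.approx(
                    m.iloc[i, j], abs=1e-12
                )

    def test_fully_dissimilar_pair_has_zero_offdiagonal(self):
        import pandas as pd

        from psfdilution.microbiome import DissimilarityMatrix

        species = ["a", "b"]
        ones = np.ones((2, 2)) - np.eye(2)
        dis = {
            g: DissimilarityMatrix(
                group=g, d=pd.DataFrame(ones, index=species, columns=species)
            )
            for g in REFERENCE_COEFFICIENTS
        }
        A = psf.build_interaction_matrix(reference_predictor(), dis)
        assert A.sigma[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert A.sigma[0, 0] == pytest.approx(-1.7355)


class TestEquilibrium:
    def test_hand_cramer_negative_identity(self):
        res = psf.equilibrium(im([[-1.0, 0.0], [0.0, -1.0]]))
        assert np.allclose(res.P_hat, [0.5, 0.5])
        assert res.w_hat == pytest.approx(-0.5)
        assert res.feasible

    def test_hand_cramer_positive_identity(self):
        res = psf.equilibrium(im([[1.0, 0.0], [0.0, 1.0]]))
        assert np.allclose(res.P_hat, [0.5, 0.5])
        assert res.w_hat == pytest.approx(0.5)
        assert res.feasible

    def test_dominated_species_infeasible(self):
        # species 2 beats everyone everywhere: no interior equilibrium
        sigma = np.array([[-1.0, -1.0, -1.0],
                          [-1.0, -1.0, -1.0],
                          [0.5, 0.5, -1.0]])
        sym = (sigma + sigma.T) / 2
        np.fill_diagonal(sym, -1.0)
        res = psf.equilibrium(im(sym))
        assert not res.feasible

    def test_cramer_matches_direct_solve(self):
        rng = np.random.default_rng(0)
        for n in (2, 3, 4, 5):
            for _ in range(20):
                sigma = random_symmetric_stable(rng, n)
                P, w_hat, degenerate = cramer_equilibrium(sigma)
                assert not degenerate
                x = np.linalg.solve(sigma, np.ones(n))
                assert np.allclose(P, x / x.sum(), atol=1e-10)
                assert w_hat == pytest.approx(1.0 / x.sum(), abs=1e-10)


class TestStability:
    def test_negative_identity_stable(self):
        A = im(-np.eye(2))
        dom, stable = psf.stability(A, np.array([0.5, 0.5]))
        assert stable and dom < 0

    def test_positive_identity_unstable(self):
        A = im(np.eye(2))
        dom, stable = psf.stability(A, np.array([0.5, 0.5]))
        assert not stable and dom > 0

    def test_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        for n in (2, 3, 5):
            sigma = random_symmetric_stable(rng, n)
            res = psf.equilibrium(im(sigma))
            J = replicator_jacobian(sigma, res.P_hat)
            h = 1e-7

            def f_reduced(q):
                P = np.append(q, 1.0 - q.sum())
                w = sigma @ P
                return (P * (w - w @ P))[: n - 1]

            q0 = res.P_hat[: n - 1]
            J_fd = np.empty((n - 1, n - 1))
            for k in range(n - 1):
                e = np.zeros(n - 1)
                e[k] = h
                J_fd[:, k] = (f_reduced(q0 + e) - f_reduced(q0 - e)) / (2 * h)
            assert np.allclose(J, J_fd, atol=1e-5)

    def test_shift_invariance_of_dominant_eigenvalue(self):
        rng = np.random.default_rng(2)
        sigma = random_symmetric_stable(rng, 4)
        res = psf.equilibrium(im(sigma))
        dom1, _ = psf.stability(im(sigma), res.P_hat)
        shifted = sigma + 0.8
        res2 = psf.equilibrium(im(shifted))
        assert np.allclose(res.P_hat, res2.P_hat, atol=1e-9)
        dom2, _ = psf.stability(im(shifted), res2.P_hat)
        assert dom1 == pytest.approx(dom2, abs=1e-8)


class TestCommunityFeedback:
    def test_two_species_sign_matches_pairwise(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            sigma = rng.normal(size=(2, 2))
            i_c = psf.community_feedback(sigma)
            i_s = pairwise_feedback(sigma)
            assert np.sign(i_c) == np.sign(i_s) or abs(i_s) < 1e-12
            assert i_c == pytest.approx(i_s / 2)

    @pytest.mark.parametrize("n", [2, 4, 7])
    def test_negative_identity(self, n):
        assert psf.community_feedback(im(-np.eye(n))) == pytest.approx(-1.0)

    def test_constant_matrix_is_neutral(self):
        assert psf.community_feedback(np.full((4, 4), 2.3)) == pytest.approx(
            0.0, abs=1e-12
        )


class TestModelComplementarity:
    def test_hand_example(self):
        res = psf.equilibrium(im(-np.eye(2)))
        assert psf.model_complementarity(res, w_mono=-1.0) == pytest.approx(1.0)

    def test_constant_matrix_zero(self):
        sigma = np.full((3, 3), -0.7)
        res = psf.equilibrium(im(sigma, w_mono=-0.7))
        if res.feasible:
            assert psf.model_complementarity(res, -0.7) == pytest.approx(0.0, abs=1e-9)

    def test_shift_invariance(self):
        rng = np.random.default_rng(4)
        sigma = random_symmetric_stable(rng, 3)
        r1 = psf.equilibrium(im(sigma))
        r2 = psf.equilibrium(im(sigma + 1.3))
        ce1 = psf.model_complementarity(r1, sigma[0, 0])
        ce2 = psf.model_complementarity(r2, sigma[0, 0] + 1.3)
        assert ce1 == pytest.approx(ce2, abs=1e-8)


class TestEnumeration:
    @pytest.mark.parametrize("n,count", [(2, 1), (3, 4), (5, 26)])
    def test_small_counts(self, n, count):
        species = [f"s{i}" for i in range(n)]
        subsets = list(psf.enumerate_communities(species))
        assert len(subsets) == count == 2**n - n - 1

    def test_order_is_deterministic(self):
        subsets = list(psf.enumerate_communities(["a", "b", "c"]))
        assert subsets == [("a", "b"), ("a", "c"), ("b", "c"), ("a", "b", "c")]

    def test_guard_on_large_pools(self):
        with pytest.raises(ValueError, match="max 22"):
            next(psf.enumerate_communities([f"s{i}" for i in range(23)]))


class TestScreen:
    def _dissims(self, value, n=6):
        import pandas as pd

        from psfdilution.microbiome import DissimilarityMatrix

        species = [f"s{i}" for i in range(n)]
        m = np.full((n, n), float(value))
        np.fill_diagonal(m, 0.0)
        return {
            g: DissimilarityMatrix(
                group=g, d=pd.DataFrame(m, index=species, columns=species)
            )
            for g in REFERENCE_COEFFICIENTS
        }

    def test_fully_dissimilar_pool_all_pass_with_positive_ce(self):
        # pairwise PSF = -3.471 everywhere: strong stabilizing feedback
        screen = psf.screen_pool(reference_predictor(), self._dissims(1.0))
        assert screen["passes"].all()
        assert (screen["CE_model"] > 0).all()

    def test_positive_feedback_pool_never_stable(self):
        pred = psf.PsfPredictor(
            coefficients={g: 1.0 for g in REFERENCE_COEFFICIENTS}, intercept=0.0
        )
        screen = psf.screen_pool(pred, self._dissims(1.0))
        assert not screen["stable"].any()

    def test_passing_requires_all_three_conditions(self, dissims):
        sub = {g: dissims[g] for g in REFERENCE_COEFFICIENTS}
        screen = psf.screen_pool(reference_predictor(), sub, max_richness=5)
        expected = screen["feasible"] & screen["stable"] & (screen["I_c"] < 0)
        assert (screen["passes"] == expected).all()
        counts = screen.groupby("richness").size()
        assert counts[2] == 153 and counts[5] == 8568

    def test_screen_agrees_with_per_community_analysis(self, dissims):
        sub = {g: dissims[g] for g in REFERENCE_COEFFICIENTS}
        screen = psf.screen_pool(reference_predictor(), sub, max_richness=3)
        rows = screen.sample(20, random_state=0)
        for _, row in rows.iterrows():
            members = row["community"].split("|")
            A = psf.build_interaction_matrix(reference_predictor(), sub, members)
            res = psf.analyze_community(A)
            assert res.feasible == row["feasible"]
            assert res.community_feedback == pytest.approx(row["I_c"], abs=1e-9)
            if res.feasible:
                assert res.CE_model == pytest.approx(row["CE_model"], abs=1e-8)
                assert res.stable == row["stable"]

    def test_summary_counts(self, dissims):
        sub = {g: dissims[g] for g in REFERENCE_COEFFICIENTS}
        screen = psf.screen_pool(reference_predictor(), sub, max_richness=4)
        summary = screen_summary(screen)
        assert summary["n_communities"].tolist() == [153, 816, 3060]


class TestDynamics:
    def test_stationary_at_equilibrium(self):
        A = im(-np.eye(3))
        res = psf.equilibrium(A)
        _, traj = psf.integrate_dynamics(A, res.P_hat, t_max=50)
        assert np.allclose(traj[-1], res.P_hat, atol=1e-8)

    def test_convergence_to_cramer_equilibrium(self):
        A = im([[-1.0, 0.0], [0.0, -1.0]])
        _, traj = psf.integrate_dynamics(A, [0.9, 0.1], t_max=100)
        assert np.allclose(traj[-1], [0.5, 0.5], atol=1e-6)

    def test_simplex_conservation(self):
        rng = np.random.default_rng(5)
        sigma = random_symmetric_stable(rng, 4)
        P0 = np.array([0.4, 0.3, 0.2, 0.1])
        _, traj = psf.integrate_dynamics(im(sigma), P0, t_max=100)
        assert np.allclose(traj.sum(axis=1), 1.0, atol=1e-8)

    def test_off_simplex_start_rejected(self):
        with pytest.raises(ValueError, match="simplex"):
            psf.integrate_dynamics(im(-np.eye(2)), [0.9, 0.3])
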