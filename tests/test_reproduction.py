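"""Reproduction numbers: eigenvalue route vs factored closed forms."""

import numpy as np
import pytest

from glct.ctmc import absorption_probabilities
from glct.models import PredPreyModel, SEIRSModel
from glct.phasetype import erlang, exponential
from glct.reproduction import (
    block_lower_triangular_inverse,
    classify_threshold,
    predprey_ngm,
    r0_erlang_seirs_closed,
    r0_seirs_closed,
    rank_one_spectral_radius,
    seirs_ngm,
    survival_split,
)


class TestBlockInverse:
    def test_identity_blocks(self):
        out = block_lower_triangular_inverse(np.eye(2), np.zeros((3, 2)), np.eye(3))
        np.testing.assert_allclose(out, np.eye(5), atol=1e-14)

    def test_random_blocks_vs_dense_solve(self, rng):
        A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        C = rng.normal(size=(2, 3))
        D = rng.normal(size=(2, 2)) + 3 * np.eye(2)
        M = np.block([[A, np.zeros((3, 2))], [C, D]])
        np.testing.assert_allclose(
            block_lower_triangular_inverse(A, C, D), np.linalg.inv(M), atol=1e-10
        )

    def test_product_is_identity(self, seirs_draw):
        model = seirs_draw()
        res = seirs_ngm(model)
        np.testing.assert_allclose(res.V @ res.Vinv, np.eye(res.V.shape[0]), atol=1e-9)

    def test_singular_block_raises(self):
        with pytest.raises(np.linalg.LinAlgError):
            block_lower_triangular_inverse(
                np.zeros((2, 2)), np.zeros((2, 2)), np.eye(2)
            )


class TestRankOne:
    def test_alpha_against_ones(self, random_ph):
        ph = random_ph(max_defect=0.4)
        assert rank_one_spectral_radius(ph.alpha, np.ones(ph.k)) == pytest.approx(
            ph.alpha.sum(), rel=1e-12
        )

    def test_orthogonal_vectors(self):
        assert rank_one_spectral_radius([1, 0], [0, 1]) == 0.0

    def test_matches_eigenvalue_oracle(self, rng):
        u, v = rng.normal(size=6), rng.normal(size=6)
        rho = np.max(np.abs(np.linalg.eigvals(np.outer(u, v))))
        assert rank_one_spectral_radius(u, v) == pytest.approx(rho, abs=1e-12)


class TestSEIRS:
    def test_scalar_case_closed_form(self):
        rE, rI, mu, beta, Lam = 0.5, 0.25, 0.1, 0.001, 10.0
        model = SEIRSModel(
            exponential(rE), exponential(rI), exponential(0.05),
            beta=beta, Lambda=Lam, mu=mu,
        )
        S0 = Lam / mu
        expected = beta * S0 * rE / ((rE + mu) * (rI + mu))
        assert seirs_ngm(model).rho == pytest.approx(expected, rel=1e-10)

    def test_zero_transmission(self, seirs_draw):
        model = seirs_draw()
        model.beta = np.zeros_like(model.beta)
        assert seirs_ngm(model).rho == pytest.approx(0.0, abs=1e-14)

    def test_eigenvalue_equals_factored_form(self, seirs_draw):
        for _ in range(100):
            model = seirs_draw()
            res = seirs_ngm(model)
            R0, R0_new, P = r0_seirs_closed(model)
            assert res.rho == pytest.approx(R0, rel=1e-8)
            assert res.factors["R0_new"] * res.factors["P_E_to_I"] == pytest.approx(
                res.rho, rel=1e-8
            )

    def test_survival_probability_range_and_mu_zero(self, random_ph):
        phE = random_ph()
        model = SEIRSModel(
            phE, exponential(0.2), exponential(0.1),
            beta=0.01, Lambda=0.0, mu=0.0, S0=100.0,
        )
        R0, R0_new, P = r0_seirs_closed(model)
        assert P == pytest.approx(1.0, rel=1e-10)
        model.mu = 0.1
        _, _, P_mu = r0_seirs_closed(model, S0=100.0)
        assert 0.0 < P_mu < 1.0

    def test_survival_monotone_in_mu(self, seirs_draw):
        model = seirs_draw()
        mus = np.linspace(0.0, 1.0, 6)
        ps = []
        for mu in mus:
            model.mu = mu
            ps.append(r0_seirs_closed(model, S0=100.0)[2])
        assert np.all(np.diff(ps) < 0)

    def test_r0_monotone_in_beta_and_s0(self, seirs_draw):
        model = seirs_draw()
        base = r0_seirs_closed(model)[0]
        model.beta = model.beta * 2.0
        assert r0_seirs_closed(model)[0] == pytest.approx(2.0 * base, rel=1e-10)
        assert r0_seirs_closed(model, S0=2 * model.Lambda / model.mu)[0] == pytest.approx(
            4.0 * base, rel=1e-10
        )

    def test_fvinv_spectrum_from_upper_left_block(self, seirs_draw):
        model = seirs_draw()
        res = seirs_ngm(model)
        kE = model.k_E
        np.testing.assert_allclose(res.FVinv[kE:, :], 0.0, atol=1e-12)
        block = res.FVinv[:kE, :kE]
        assert np.max(np.abs(np.linalg.eigvals(block))) == pytest.approx(
            res.rho, rel=1e-8, abs=1e-12
        )


class TestErlangClosedForm:
    def test_scalar_limit_matches_simple_seirs(self):
        rE, rI, mu, beta, S0 = 0.5, 0.25, 0.1, 0.001, 100.0
        assert r0_erlang_seirs_closed(1, 1, 1 / rE, 1 / rI, beta, S0, mu) == (
            pytest.approx(beta * S0 * rE / ((rE + mu) * (rI + mu)), rel=1e-12)
        )

    def test_k3_k4_four_term_sum(self):
        kE, kI, tauE, tauI, beta, S0, mu = 3, 4, 3.0, 5.0, 0.002, 100.0, 0.05
        rE, rI = kE / tauE, kI / tauI
        explicit = (
            beta * S0 * (rE / (rE + mu)) ** 3
            * (
                1 / (rI + mu)
                + rI / (rI + mu) ** 2
                + rI**2 / (rI + mu) ** 3
                + rI**3 / (rI + mu) ** 4
            )
        )
        assert r0_erlang_seirs_closed(kE, kI, tauE, tauI, beta, S0, mu) == (
            pytest.approx(explicit, rel=1e-14)
        )

    @pytest.mark.parametrize("kE", range(1, 7))
    @pytest.mark.parametrize("kI", range(1, 7))
    def test_matches_matrix_route(self, kE, kI):
        tauE, tauI, beta, mu, Lam = 3.0, 5.0, 0.002, 0.05, 5.0
        model = SEIRSModel(
            erlang(kE, mean=tauE), erlang(kI, mean=tauI), exponential(0.02),
            beta=beta, Lambda=Lam, mu=mu,
        )
        closed = r0_erlang_seirs_closed(kE, kI, tauE, tauI, beta, Lam / mu, mu)
        assert seirs_ngm(model).rho == pytest.approx(closed, rel=1e-10)

    def test_mu_to_zero_limit_is_beta_s0_tau(self):
        beta, S0, tauI = 0.002, 100.0, 5.0
        vals = [
            r0_erlang_seirs_closed(3, 4, 3.0, tauI, beta, S0, mu)
            for mu in (1e-4, 1e-6, 1e-8)
        ]
        assert vals[-1] == pytest.approx(beta * S0 * tauI, rel=1e-6)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            r0_erlang_seirs_closed(0, 1, 1.0, 1.0, 0.1, 10.0, 0.0)
        with pytest.raises(ValueError):
            r0_erlang_seirs_closed(1, 1, -1.0, 1.0, 0.1, 10.0, 0.0)


class TestPredPrey:
    def test_exponential_example(self):
        model = PredPreyModel(
            exponential(1.0), exponential(0.1),
            r=1.0, K=100.0, a=2.0, h=50.0, chi=0.5,
        )
        res = predprey_ngm(model)
        assert res.rho == pytest.approx(0.5 * 2 * 100 / (150 * 0.1), rel=1e-10)
        assert res.factors["mean_adult_time"] == pytest.approx(10.0, rel=1e-12)

    def test_zero_conversion_limit(self, predprey_draw):
        model = predprey_draw()
        model.chi = 1e-300
        assert predprey_ngm(model).rho == pytest.approx(0.0, abs=1e-12)

    def test_eigenvalue_equals_three_factor_product(self, predprey_draw):
        for _ in range(100):
            model = predprey_draw(max_defect=0.5)
            res = predprey_ngm(model)
            f = res.factors
            closed = f["birth_rate"] * f["mean_adult_time"] * f["survival_to_immature"]
            assert res.rho == pytest.approx(closed, rel=1e-8, abs=1e-12)

    def test_defect_scales_r_pred(self, predprey_draw):
        from glct.phasetype import PhaseTypeRep

        model = predprey_draw()
        base = predprey_ngm(model).rho
        phX = model.ph_maturation
        model.ph_maturation = PhaseTypeRep(phX.alpha * 0.6, phX.A)
        assert predprey_ngm(model).rho == pytest.approx(0.6 * base, rel=1e-9)

    def test_eta_absent_from_r_pred(self, predprey_draw):
        model = predprey_draw()
        base = predprey_ngm(model).rho
        model.eta = model.eta + 5.0
        assert predprey_ngm(model).rho == pytest.approx(base, rel=1e-12)

    def test_evaluation_at_arbitrary_n(self, predprey_draw):
        model = predprey_draw()
        res = predprey_ngm(model, N=model.h)  # half-saturation point
        assert res.factors["birth_rate"] == pytest.approx(
            model.chi * model.a / 2.0, rel=1e-12
        )


class TestSurvivalTwoRoutes:
    def test_closed_form_equals_absorption_route(self, seirs_draw):
        model = seirs_draw()
        _, _, P = r0_seirs_closed(model)
        _, pi = absorption_probabilities(survival_split(model.ph_latent, model.mu))
        assert pi[0] == pytest.approx(P, abs=1e-10)

    @pytest.mark.parametrize("kE", [1, 2, 5])
    def test_erlang_latency_power_law(self, kE):
        rE, mu = 0.7, 0.2
        _, pi = absorption_probabilities(survival_split(erlang(kE, rate=rE), mu))
        assert pi[0] == pytest.approx((rE / (rE + mu)) ** kE, abs=1e-12)


def test_threshold_classification():
    assert classify_threshold(0.5) == "stable"
    assert classify_threshold(2.0) == "unstable"
    assert classify_threshold(1.0) == "marginal"
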