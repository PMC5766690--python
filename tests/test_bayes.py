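"""Conjugate NIG machinery: updates, evidence, harmonic selection, bands.

The closed-form posterior and evidence are checked against a dense
grid-quadrature oracle over (coefficients, noise variance), and the evidence
against its defining likelihood-prior-posterior identity.
"""

import math

import numpy as np
import pytest
from scipy.special import logsumexp

from phasebayes.bayes import (
    EstimatorConfig,
    NIGState,
    build_design,
    collapse_cycles,
    default_prior,
    gaussian_loglik,
    interaction_credible_band,
    log_evidence,
    nig_logpdf,
    nig_update,
    select_harmonics,
    sequential_update,
)
from phasebayes.reconstruct import RegressionData


# ---------------------------------------------------------------------------
# Independent oracle: dense grid quadrature of likelihood x prior

def quadrature_posterior(F, delta, prior, n_c=41, n_s=120, half_width=8.0):
    """Posterior moments and evidence by brute-force numerical integration.

    The grid is centred on the ordinary least-squares solution (not on the
    closed-form posterior, keeping the oracle independent of the code path it
    checks).
    """
    T, P = F.shape
    c_ls, *_ = np.linalg.lstsq(F, delta, rcond=None)
    resid = delta - F @ c_ls
    s2_ls = resid @ resid / max(T - P, 1)
    cov_ls = s2_ls * np.linalg.inv(F.T @ F)
    sds = np.sqrt(np.diag(cov_ls))

    axes = [
        np.linspace(c_ls[k] - half_width * sds[k], c_ls[k] + half_width * sds[k], n_c)
        for k in range(P)
    ]
    s2_axis = np.exp(
        np.linspace(np.log(s2_ls / 6.0), np.log(s2_ls * 6.0), n_s)
    )
    grids = np.meshgrid(*axes, indexing="ij")
    C = np.stack([g.ravel() for g in grids], axis=1)  # (Nc, P)

    # log lik + log prior on the product grid, vectorized through sufficient stats
    FtF = F.T @ F
    Ftd = F.T @ delta
    dd = delta @ delta
    quad_lik = dd - 2 * C @ Ftd + np.einsum("ij,jk,ik->i", C, FtF, C)
    Sig_inv = np.linalg.inv(prior.Sigma)
    dev = C - prior.chi
    quad_pri = np.einsum("ij,jk,ik->i", dev, Sig_inv, dev)
    logdet_pri = np.linalg.slogdet(prior.Sigma)[1]

    logpost = np.empty((C.shape[0], n_s))
    for k, s2 in enumerate(s2_axis):
        ll = -0.5 * T * np.log(2 * np.pi * s2) - quad_lik / (2 * s2)
        lp = (
            -0.5 * P * np.log(2 * np.pi * s2) - 0.5 * logdet_pri
            - quad_pri / (2 * s2)
            + prior.alpha * np.log(prior.beta) - math.lgamma(prior.alpha)
            - (prior.alpha + 1) * np.log(s2) - prior.beta / s2
        )
        logpost[:, k] = ll + lp

    dc = np.prod([ax[1] - ax[0] for ax in axes])
    dlogs = np.gradient(np.log(s2_axis))
    w_s = s2_axis * dlogs  # log-spaced trapezoid weights
    logw = np.log(w_s)
    log_norm = logsumexp(logpost + logw[None, :]) + np.log(dc)
    post = np.exp(logpost + logw[None, :] - log_norm)
    mass = post.sum()
    mean_c = (post.sum(axis=1) @ C) / mass
    var_c = (post.sum(axis=1) @ (C ** 2)) / mass - mean_c ** 2
    mean_s2 = (post.sum(axis=0) @ s2_axis) / mass
    return mean_c, var_c, mean_s2, float(log_norm)


class TestNIGUpdateOracle:
    def test_posterior_matches_quadrature(self, tiny_regression):
        F, delta = tiny_regression
        prior = default_prior(3, prior_scale=10.0, alpha0=2.0, beta0=0.5)
        post = nig_update(prior, F, delta)
        mean_c, var_c, mean_s2, _ = quadrature_posterior(F, delta, prior)

        assert np.allclose(post.chi, mean_c, rtol=1e-2, atol=1e-4)
        marg_var = post.beta / (post.alpha - 1) * np.diag(post.Sigma)
        assert np.allclose(marg_var, var_c, rtol=1e-2)
        assert post.expected_sigma2() == pytest.approx(mean_s2, rel=1e-2)

    def test_evidence_matches_quadrature(self, tiny_regression):
        F, delta = tiny_regression
        prior = default_prior(3, prior_scale=10.0, alpha0=2.0, beta0=0.5)
        lz = log_evidence(prior, F, delta)
        _, _, _, lz_quad = quadrature_posterior(F, delta, prior)
        assert lz == pytest.approx(lz_quad, rel=1e-2, abs=0.05)


class TestNIGUpdateAlgebra:
    def test_empty_data_returns_prior(self):
        prior = default_prior(4)
        post = nig_update(prior, np.zeros((0, 4)), np.zeros(0))
        assert np.allclose(post.chi, prior.chi)
        assert np.allclose(post.Sigma, prior.Sigma, rtol=1e-8)
        assert post.alpha == prior.alpha and post.beta == pytest.approx(prior.beta)

    @pytest.mark.parametrize("T", [1, 7, 40])
    def test_alpha_increment_is_half_T(self, rng, T):
        F = rng.normal(size=(T, 2))
        delta = rng.normal(size=T)
        prior = default_prior(2)
        assert nig_update(prior, F, delta).alpha - prior.alpha == pytest.approx(T / 2)

    def test_sequential_equals_batch(self, rng):
        F = rng.normal(size=(60, 3))
        delta = rng.normal(size=60)
        prior = default_prior(3, prior_scale=5.0, alpha0=1.0, beta0=1.0)
        batch = nig_update(prior, F, delta)
        seq = sequential_update(prior, [(F[:20], delta[:20]), (F[20:], delta[20:])])
        assert np.allclose(seq.chi, batch.chi, atol=1e-9)
        assert np.allclose(seq.Sigma, batch.Sigma, atol=1e-9)
        assert seq.beta == pytest.approx(batch.beta, abs=1e-9)

    def test_chunk_order_irrelevant(self, rng):
        F = rng.normal(size=(60, 3))
        delta = rng.normal(size=60)
        prior = default_prior(3, prior_scale=5.0)
        p1 = sequential_update(prior, [(F[:30], delta[:30]), (F[30:], delta[30:])])
        p2 = sequential_update(prior, [(F[30:], delta[30:]), (F[:30], delta[:30])])
        assert np.allclose(p1.chi, p2.chi, atol=1e-9)

    def test_inconsistent_chunk_widths_rejected(self, rng):
        prior = default_prior(3)
        with pytest.raises(ValueError):
            sequential_update(
                prior, [(rng.normal(size=(5, 3)), rng.normal(size=5)),
                        (rng.normal(size=(5, 2)), rng.normal(size=5))]
            )

    def test_posterior_contraction(self, rng):
        """trace(Sigma) is non-increasing as data accumulate."""
        prior = default_prior(3, prior_scale=5.0)
        state = prior
        for _ in range(5):
            F = rng.normal(size=(10, 3))
            delta = rng.normal(size=10)
            new = nig_update(state, F, delta)
            assert np.trace(new.Sigma) <= np.trace(state.Sigma) + 1e-12
            state = new


class TestEvidence:
    def test_identity_at_random_points(self, rng, tiny_regression):
        """log evidence == log lik + log prior - log posterior pointwise."""
        F, delta = tiny_regression
        prior = default_prior(3, prior_scale=10.0, alpha0=2.0, beta0=0.5)
        post = nig_update(prior, F, delta)
        lz = log_evidence(prior, F, delta)
        for _ in range(5):
            c = rng.normal(size=3)
            s2 = float(rng.uniform(0.05, 2.0))
            ident = (
                gaussian_loglik(F, delta, c, s2)
                + nig_logpdf(prior, c, s2)
                - nig_logpdf(post, c, s2)
            )
            assert lz == pytest.approx(ident, abs=1e-8)

    def test_irrelevant_columns_lower_evidence(self):
        """Adding pure-noise regressors lowers the evidence on average."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            T = 200
            F1 = np.column_stack([np.ones(T), np.sin(rng.uniform(0, 2 * np.pi, T))])
            delta = F1 @ np.array([1.0, 0.5]) + 0.3 * rng.standard_normal(T)
            F2 = np.column_stack([F1, rng.normal(size=(T, 2))])
            lz1 = log_evidence(default_prior(2, prior_scale=10.0), F1, delta)
            lz2 = log_evidence(default_prior(4, prior_scale=10.0), F2, delta)
            wins += lz1 > lz2
        assert wins >= 15


class TestDesignMatrix:
    def _reg(self, rng, T=30, n_send=2):
        return RegressionData(
            receiver=0,
            sender_ids=tuple(range(1, n_send + 1)),
            delta=rng.uniform(1, 2, T),
            dphi=rng.uniform(0, 2 * np.pi, (T, n_send)),
            dt=1.0,
            receiver_cycle=np.arange(T) // 5,
        )

    @pytest.mark.parametrize("n_send,M,width", [(1, 1, 3), (63, 5, 631), (3, 2, 13)])
    def test_width(self, rng, n_send, M, width):
        d = build_design(self._reg(rng, n_send=n_send), M)
        assert d.F.shape[1] == width

    def test_first_column_ones_and_bounded(self, rng):
        d = build_design(self._reg(rng), 3)
        assert np.all(d.F[:, 0] == 1.0)
        assert np.all(np.abs(d.F[:, 1:]) <= 1.0)

    def test_zero_phase_difference_columns(self, rng):
        reg = self._reg(rng, n_send=1)
        reg.dphi[:] = 0.0
        d = build_design(reg, 2)
        assert np.allclose(d.F[:, d.column_map[(1, 1, "cos")]], 1.0)
        assert np.allclose(d.F[:, d.column_map[(1, 1, "sin")]], 0.0)
        assert np.allclose(d.F[:, d.column_map[(1, 2, "cos")]], 1.0)

    def test_column_values_match_trig(self, rng):
        reg = self._reg(rng, n_send=2)
        d = build_design(reg, 3)
        for k, j in enumerate(reg.sender_ids):
            for m in range(1, 4):
                assert np.allclose(
                    d.F[:, d.column_map[(j, m, "cos")]], np.cos(m * reg.dphi[:, k])
                )

    def test_columns_for_smaller_M_prefix_per_sender(self, rng):
        d = build_design(self._reg(rng, n_send=2), 3)
        cols = d.columns_for_M(1)
        assert cols.tolist() == [0, d.column_map[(1, 1, "cos")], d.column_map[(1, 1, "sin")],
                                 d.column_map[(2, 1, "cos")], d.column_map[(2, 1, "sin")]]

    def test_collapse_cycles_averages(self, rng):
        reg = self._reg(rng, T=10, n_send=1)
        reg.receiver_cycle = np.array([0] * 5 + [1] * 5)
        d = build_design(reg, 1)
        F_c, d_c, mean_count = collapse_cycles(d, reg.delta, reg.receiver_cycle)
        assert F_c.shape == (2, 3)
        assert np.allclose(F_c[0], d.F[:5].mean(axis=0))
        assert d_c[1] == pytest.approx(reg.delta[5:].mean())
        assert mean_count == 5.0


class TestPriorAndState:
    def test_default_prior_shape(self):
        p = default_prior(3)
        assert np.allclose(p.Sigma, 1e6 * np.eye(3))
        assert p.alpha == pytest.approx(1e-3) and p.beta == pytest.approx(1e-3)

    def test_zero_prior_scale_rejected(self):
        with pytest.raises(ValueError):
            default_prior(3, prior_scale=0.0)

    def test_state_roundtrip(self, rng):
        A = rng.normal(size=(3, 3))
        s = NIGState(chi=rng.normal(size=3), Sigma=A @ A.T + np.eye(3),
                     alpha=2.0, beta=3.0)
        s2 = NIGState.from_dict(s.to_dict())
        assert np.allclose(s2.chi, s.chi) and np.allclose(s2.Sigma, s.Sigma)

    def test_asymmetric_sigma_rejected(self):
        with pytest.raises(ValueError):
            NIGState(chi=np.zeros(2), Sigma=np.array([[1.0, 0.5], [0.0, 1.0]]),
                     alpha=1.0, beta=1.0)


class TestSelectHarmonics:
    def _reg_from_model(self, seed, M_true, T=800):
        rng = np.random.default_rng(seed)
        dphi = rng.uniform(0, 2 * np.pi, (T, 1))
        b = [-0.05] + [0.0] * (M_true - 1)
        b[M_true - 1] = -0.05
        delta = 1.0 + sum(
            b[m] * np.sin((m + 1) * dphi[:, 0]) for m in range(M_true)
        ) + 0.01 * rng.standard_normal(T)
        return RegressionData(
            receiver=0, sender_ids=(1,), delta=delta, dphi=dphi, dt=1.0,
            receiver_cycle=np.arange(T),
        )

    @pytest.mark.parametrize("M_true", [1, 2])
    def test_recovers_true_harmonic_count(self, M_true):
        hits = 0
        for seed in range(6):
            reg = self._reg_from_model(seed, M_true)
            best, ev, *_ = select_harmonics(reg, EstimatorConfig(row_mode="grid"))
            hits += best == M_true
        assert hits >= 5

    def test_singleton_range(self, rng):
        reg = self._reg_from_model(0, 1)
        best, ev, *_ = select_harmonics(reg, EstimatorConfig(row_mode="grid"),
                                        M_range=[3])
        assert best == 3 and set(ev) == {3}
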