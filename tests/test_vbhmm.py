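"""Variational HMM inference: exact-enumeration and decomposition oracles.

The forward-backward E-step is validated against brute-force
enumeration over all K^T state paths on a 10-point toy problem, and the
free energy against an independently coded evaluation (log-space
forward plus scipy-based entropy/cross-entropy terms).
"""

import itertools

import numpy as np
import pytest
from scipy.special import gammaln, logsumexp, multigammaln
from scipy.stats import dirichlet as dirichlet_dist
from scipy.stats import wishart as wishart_dist

from stablefc.dataio import SessionedTimeSeries, standardize
from stablefc.synthetic import simulate
from stablefc.vbhmm import (
    HMMPosterior,
    HMMPriors,
    _emission_loglik,
    _expected_log_dirichlet,
    _kl_total,
    e_step,
    fit_hmm,
    free_energy,
    init_responsibilities,
    m_step,
)


# ---------------------------------------------------------------------------
# oracles


def enumerate_posterior(logb, elogA, elogpi, session_lengths):
    """Exact path posterior by summing over all K^T paths per session."""
    K = logb.shape[1]
    gamma = np.zeros_like(logb)
    xi = np.zeros((K, K))
    logZ = 0.0
    offset = 0
    for L in session_lengths:
        paths = list(itertools.product(range(K), repeat=L))
        logw = np.empty(len(paths))
        for i, path in enumerate(paths):
            w = elogpi[path[0]] + logb[offset, path[0]]
            for t in range(1, L):
                w += elogA[path[t - 1], path[t]] + logb[offset + t, path[t]]
            logw[i] = w
        logZ_sess = logsumexp(logw)
        logZ += logZ_sess
        w = np.exp(logw - logZ_sess)
        for i, path in enumerate(paths):
            for t in range(L):
                gamma[offset + t, path[t]] += w[i]
            for t in range(1, L):
                xi[path[t - 1], path[t]] += w[i]
        offset += L
    return gamma, xi, logZ


def toy_problem(session_lengths, seed=3):
    ts, _ = simulate(2, 3, session_lengths, stay_prob=0.8, separation=1.0,
                     seed=seed)
    ts = standardize(ts)
    priors = HMMPriors.default(ts)
    gamma0 = init_responsibilities(ts, 2, 0)
    starts = ts.session_starts
    xi0 = np.einsum("tj,tk->jk", gamma0[:-1][~starts[1:]],
                    gamma0[1:][~starts[1:]])
    post = m_step(ts, gamma0, xi0, priors)
    return ts, priors, post


class TestEStepEnumeration:
    @pytest.mark.parametrize("lengths", [[10], [5, 5]])
    def test_matches_exhaustive_path_sum(self, lengths):
        ts, _, post = toy_problem(lengths)
        gamma, xi, log_norm = e_step(ts, post)
        logb = _emission_loglik(ts.data, post)
        g_ref, xi_ref, logZ_ref = enumerate_posterior(
            logb,
            _expected_log_dirichlet(post.trans_counts),
            _expected_log_dirichlet(post.init_counts),
            lengths,
        )
        np.testing.assert_allclose(gamma, g_ref, atol=1e-10)
        np.testing.assert_allclose(xi, xi_ref, atol=1e-10)
        np.testing.assert_allclose(log_norm, logZ_ref, atol=1e-8)

    def test_session_split_changes_xi_by_boundary_transition(self):
        # same 10 points as one session vs two sessions of 5
        ts1, _, post = toy_problem([10])
        ts2 = SessionedTimeSeries(ts1.data, [5, 5])
        _, xi1, _ = e_step(ts1, post)
        _, xi2, _ = e_step(ts2, post)
        assert xi1.sum() == pytest.approx(9.0, abs=1e-10)
        assert xi2.sum() == pytest.approx(8.0, abs=1e-10)

    def test_single_state_degenerate(self):
        ts, _, _ = toy_problem([6, 6])
        priors = HMMPriors.default(ts)
        gamma0 = np.ones((12, 1))
        post = m_step(ts, gamma0, np.array([[10.0]]), priors)
        gamma, xi, _ = e_step(ts, post)
        np.testing.assert_array_equal(gamma, np.ones((12, 1)))
        assert xi.sum() == pytest.approx(12 - 2)

    def test_symmetric_parameters_give_uniform_gamma(self):
        ts, priors, _ = toy_problem([10])
        K, P = 3, ts.n_channels
        scale = np.repeat(np.eye(P)[None] * 20, K, axis=0)
        post = HMMPosterior(
            trans_counts=np.full((K, K), 2.0),
            init_counts=np.full(K, 1.0),
            nu=np.full(K, 20.0),
            scale=scale,
        )
        gamma, _, _ = e_step(ts, post)
        np.testing.assert_allclose(gamma, 1.0 / K, atol=1e-12)


class TestMStep:
    def test_state_without_evidence_keeps_prior(self, tiny_ts):
        priors = HMMPriors.default(tiny_ts)
        T = tiny_ts.n_timepoints
        gamma = np.zeros((T, 2))
        gamma[:, 0] = 1.0
        post = m_step(tiny_ts, gamma, np.zeros((2, 2)), priors)
        np.testing.assert_allclose(post.scale[1], priors.wishart_scale0)
        assert post.nu[1] == pytest.approx(priors.wishart_nu0)
        np.testing.assert_allclose(post.trans_counts, priors.trans_counts(2))

    def test_uniform_gamma_symmetric_states(self, tiny_ts):
        priors = HMMPriors.default(tiny_ts)
        gamma = np.full((tiny_ts.n_timepoints, 2), 0.5)
        post = m_step(tiny_ts, gamma, np.ones((2, 2)), priors)
        np.testing.assert_allclose(post.scale[0], post.scale[1], atol=1e-10)
        assert post.nu[0] == pytest.approx(post.nu[1])

    def test_hard_path_transition_counting(self, tiny_ts):
        priors = HMMPriors.default(tiny_ts)
        # hard path 0,0,1,1 -> counts {0->0: 1, 0->1: 1, 1->1: 1}
        path = np.array([0, 0, 1, 1])
        gamma_seg = np.eye(2)[path]
        xi = gamma_seg[:-1].T @ gamma_seg[1:]
        gamma = np.zeros((tiny_ts.n_timepoints, 2))
        gamma[:, 0] = 1.0
        post = m_step(tiny_ts, gamma, xi, priors)
        expected = priors.trans_counts(2) + np.array([[1.0, 1.0], [0.0, 1.0]])
        np.testing.assert_allclose(post.trans_counts, expected)

    def test_near_empty_state_warns(self, tiny_ts):
        priors = HMMPriors.default(tiny_ts)
        gamma = np.zeros((tiny_ts.n_timepoints, 2))
        gamma[:, 0] = 1.0
        with pytest.warns(RuntimeWarning, match="near-empty"):
            m_step(tiny_ts, gamma, np.zeros((2, 2)), priors)


class TestFreeEnergy:
    def test_matches_independent_decomposition(self):
        """F from scaled recursions equals -E[log joint] - H(path) + KL,
        with every term computed by an independent route."""
        ts, truth = simulate(2, 2, [50], stay_prob=0.85, separation=1.5, seed=0)
        ts = standardize(ts)
        priors = HMMPriors.default(ts)
        fit = fit_hmm(ts, 2, priors=priors, seed=0, max_iter=5)
        post = fit.posterior
        fe = free_energy(ts, post, priors)

        # log-space forward for the chain normalizer
        logb = _emission_loglik(ts.data, post)
        elogA = _expected_log_dirichlet(post.trans_counts)
        elogpi = _expected_log_dirichlet(post.init_counts)
        la = elogpi + logb[0]
        for t in range(1, 50):
            la = logsumexp(la[:, None] + elogA, axis=0) + logb[t]
        logZ = logsumexp(la)

        # KL terms: E_q[log q] from scipy entropies, E_q[log p] directly
        kl = 0.0
        for k in range(2):
            counts = post.trans_counts[k]
            prior = priors.trans_counts(2)[k]
            elog = _expected_log_dirichlet(counts)
            cross = (gammaln(prior.sum()) - gammaln(prior).sum()
                     + ((prior - 1) * elog).sum())
            kl += -dirichlet_dist(counts).entropy() - cross
        elog = _expected_log_dirichlet(post.init_counts)
        prior = priors.init_counts(2)
        cross = (gammaln(prior.sum()) - gammaln(prior).sum()
                 + ((prior - 1) * elog).sum())
        kl += -dirichlet_dist(post.init_counts).entropy() - cross
        P = ts.n_channels
        from scipy.special import digamma

        for k in range(2):
            nu, S = post.nu[k], post.scale[k]
            W = np.linalg.inv(S)
            elogdet = (digamma((nu - np.arange(P)) / 2.0).sum()
                       + P * np.log(2.0) + np.linalg.slogdet(W)[1])
            nu0, S0 = priors.wishart_nu0, priors.wishart_scale0
            lnZp = (nu0 * P / 2 * np.log(2.0)
                    - nu0 / 2 * np.linalg.slogdet(S0)[1]
                    + multigammaln(nu0 / 2, P))
            cross = ((nu0 - P - 1) / 2 * elogdet
                     - 0.5 * nu * np.trace(S0 @ W) - lnZp)
            kl += -wishart_dist(df=nu, scale=W).entropy() - cross

        np.testing.assert_allclose(fe, kl - logZ, atol=1e-6)

    def test_posterior_equal_to_prior_has_zero_kl(self, tiny_ts):
        priors = HMMPriors.default(tiny_ts)
        K, P = 2, tiny_ts.n_channels
        post = HMMPosterior(
            trans_counts=priors.trans_counts(K),
            init_counts=priors.init_counts(K),
            nu=np.full(K, priors.wishart_nu0),
            scale=np.repeat(priors.wishart_scale0[None], K, axis=0),
        )
        assert _kl_total(post, priors) == pytest.approx(0.0, abs=1e-10)

    def test_single_state_has_no_path_terms(self, tiny_ts):
        """With K=1 the transition/initial KLs vanish and F reduces to
        the Wishart KL minus the data term."""
        priors = HMMPriors.default(tiny_ts)
        fit = fit_hmm(tiny_ts, 1, priors=priors, seed=0, max_iter=3)
        post = fit.posterior
        from stablefc.vbhmm import _kl_dirichlet, _kl_wishart

        assert _kl_dirichlet(post.trans_counts[0],
                             priors.trans_counts(1)[0]) == pytest.approx(0.0)
        assert _kl_dirichlet(post.init_counts,
                             priors.init_counts(1)) == pytest.approx(0.0)
        _, _, log_norm = e_step(tiny_ts, post)
        expected = _kl_wishart(post.nu[0], post.scale[0], priors.wishart_nu0,
                               priors.wishart_scale0) - log_norm
        assert free_energy(tiny_ts, post, priors) == pytest.approx(expected)


class TestInitResponsibilities:
    def test_seed_determinism_and_row_sums(self, tiny_ts):
        a = init_responsibilities(tiny_ts, 4, 123)
        b = init_responsibilities(tiny_ts, 4, 123)
        np.testing.assert_array_equal(a, b)
        np.testing.assert_allclose(a.sum(axis=1), 1.0, atol=1e-12)
        assert not np.array_equal(a, init_responsibilities(tiny_ts, 4, 124))

    def test_single_state_column_of_ones(self, tiny_ts):
        np.testing.assert_array_equal(
            init_responsibilities(tiny_ts, 1, 0),
            np.ones((tiny_ts.n_timepoints, 1)),
        )

    def test_invalid_k(self, tiny_ts):
        with pytest.raises(ValueError):
            init_responsibilities(tiny_ts, 0, 0)


class TestFitHMM:
    def test_trace_monotone_and_deterministic(self, small_easy_ts):
        ts, _ = small_easy_ts
        fit1 = fit_hmm(ts, 2, seed=3)
        fit2 = fit_hmm(ts, 2, seed=3)
        np.testing.assert_array_equal(fit1.free_energy_trace,
                                      fit2.free_energy_trace)
        np.testing.assert_array_equal(fit1.gamma, fit2.gamma)
        assert np.all(np.diff(fit1.free_energy_trace) <= 1e-8)

    def test_gamma_and_transition_normalization(self, small_easy_ts):
        ts, _ = small_easy_ts
        fit = fit_hmm(ts, 3, seed=1)
        np.testing.assert_allclose(fit.gamma.sum(axis=1), 1.0, atol=1e-8)
        trans = fit.posterior.expected_transition()
        np.testing.assert_allclose(trans.sum(axis=1), 1.0, atol=1e-10)
        for C in fit.covariances:
            np.linalg.cholesky(C)  # SPD

    def test_single_state_closed_form_covariance(self, tiny_ts):
        priors = HMMPriors.default(tiny_ts)
        fit = fit_hmm(tiny_ts, 1, priors=priors, seed=0)
        X = tiny_ts.data
        expected = (priors.wishart_scale0 + X.T @ X) / (
            priors.wishart_nu0 + tiny_ts.n_timepoints
        )
        np.testing.assert_allclose(fit.covariances[0], expected, atol=1e-10)

    def test_session_order_invariance(self):
        """Swapping session order permutes gamma rows but leaves the
        transition statistics and parameter posteriors unchanged."""
        ts, _, post = toy_problem([5, 5], seed=9)
        swapped = SessionedTimeSeries(
            np.vstack([ts.data[5:], ts.data[:5]]), [5, 5]
        )
        g1, xi1, ln1 = e_step(ts, post)
        g2, xi2, ln2 = e_step(swapped, post)
        np.testing.assert_allclose(g2, np.vstack([g1[5:], g1[:5]]), atol=1e-8)
        np.testing.assert_allclose(xi1, xi2, atol=1e-8)
        assert ln1 == pytest.approx(ln2, abs=1e-8)
        priors = HMMPriors.default(ts)
        p1 = m_step(ts, g1, xi1, priors)
        p2 = m_step(swapped, g2, xi2, priors)
        np.testing.assert_allclose(p1.scale, p2.scale, atol=1e-8)
        np.testing.assert_allclose(p1.trans_counts, p2.trans_counts, atol=1e-8)

    def test_agrees_with_maximum_likelihood_oracle(self, small_easy_ts):
        """On easy data the hard path matches an independent ML HMM
        implementation (hmmlearn) in >= 95% of time points."""
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        ts, _ = small_easy_ts
        fit = fit_hmm(ts, 2, seed=2)
        model = hmmlearn.GaussianHMM(
            n_components=2, covariance_type="full", n_iter=100,
            random_state=0,
        )
        lengths = ts.session_lengths
        model.fit(ts.data, lengths)
        oracle_path = model.predict(ts.data, lengths)
        mine = fit.gamma.argmax(axis=1)
        agree = max(np.mean(mine == oracle_path),
                    np.mean(mine == 1 - oracle_path))
        assert agree >= 0.95
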