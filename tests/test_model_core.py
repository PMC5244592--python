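"""Domain types, Beta parameterization, quadrature and ELBO mathematics."""

import numpy as np
import pytest
from scipy import integrate, stats

from rarevar.model import (
    InputError,
    ModelParams,
    NumericalError,
    ReadCountMatrix,
    VariationalParams,
    _beta_entropy,
    _elbo_components,
    beta_mean_precision_from_shapes,
    beta_shapes_from_mean_precision,
    elbo,
    expected_log_beta_norm,
)
from conftest import make_counts, oracle_log_evidence


class TestBetaParameterization:
    @pytest.mark.parametrize(
        "mean,precision,expected",
        [(0.5, 2.0, (1.0, 1.0)), (0.1, 10.0, (1.0, 9.0)), (0.25, 8.0, (2.0, 6.0))],
    )
    def test_shapes_from_mean_precision(self, mean, precision, expected):
        assert beta_shapes_from_mean_precision(mean, precision) == pytest.approx(
            expected
        )

    @pytest.mark.parametrize("mean,precision", [(0.0, 10.0), (1.0, 10.0), (0.5, 0.0), (0.5, -1.0)])
    def test_domain_errors(self, mean, precision):
        with pytest.raises(InputError):
            beta_shapes_from_mean_precision(mean, precision)

    def test_round_trip(self, rng):
        mean = rng.uniform(0.01, 0.99, 20)
        precision = 10 ** rng.uniform(-2, 6, 20)
        a, b = beta_shapes_from_mean_precision(mean, precision)
        m2, p2 = beta_mean_precision_from_shapes(a, b)
        np.testing.assert_allclose(m2, mean, rtol=1e-12)
        np.testing.assert_allclose(p2, precision, rtol=1e-12)


class TestReadCountMatrix:
    def test_invariants_enforced(self):
        counts = make_counts([[3, 0]], [[10, 5]])
        assert counts.J == 1 and counts.N == 2
        with pytest.raises(InputError):
            ReadCountMatrix(
                positions=counts.positions,
                reference_base=counts.reference_base,
                base_counts=counts.base_counts,
                r=counts.r + 1,  # breaks r = sum of non-reference counts
                n=counts.n,
            )

    def test_positions_one_based(self):
        with pytest.raises(InputError):
            make_counts([[1]], [[2]], positions=[0])

    def test_nonref_split(self):
        counts = make_counts([[4]], [[10]], ref="G", alt="T")
        np.testing.assert_array_equal(counts.nonref_base_counts(), [[0, 0, 4]])
        assert list(counts.nonref_base_labels()[0]) == ["A", "C", "T"]


class TestExpectedLogBetaNorm:
    def test_raabe_closed_forms(self):
        # Uniform q: E[log(Gamma(M)/Gamma(mu M)Gamma((1-mu)M))] has closed
        # forms via int_0^1 log sin(pi x) dx and Raabe's formula.
        assert expected_log_beta_norm((1.0, 1.0), 1.0, 50) == pytest.approx(
            -np.log(2 * np.pi), abs=1e-6
        )
        assert expected_log_beta_norm((1.0, 1.0), 2.0, 50) == pytest.approx(
            1.0 - np.log(2 * np.pi), abs=1e-6
        )

    def test_degenerate_concentration(self):
        # q concentrated at 1/2: integrand value log Gamma(2) - 2 log Gamma(1) = 0.
        assert expected_log_beta_norm((1e6, 1e6), 2.0, 50) == pytest.approx(
            0.0, abs=1e-5
        )

    def test_swap_identity(self, rng):
        # The integrand is symmetric under mu -> 1 - mu, so swapping the
        # Beta shapes leaves the expectation unchanged.
        for _ in range(10):
            a, b = 10 ** rng.uniform(-0.5, 3, 2)
            M = 10 ** rng.uniform(-1, 4)
            v1 = expected_log_beta_norm((a, b), M)
            v2 = expected_log_beta_norm((b, a), M)
            assert v1 == pytest.approx(v2, rel=1e-9, abs=1e-12)

    def test_oracle_agreement(self, rng):
        # Dense adaptive quadrature oracle over moderate shapes.
        from scipy import special

        for _ in range(8):
            a, b = 10 ** rng.uniform(-0.3, 2.5, 2)
            M = 10 ** rng.uniform(-0.5, 3)

            def integrand(mu):
                return stats.beta.pdf(mu, a, b) * (
                    special.gammaln(M)
                    - special.gammaln(mu * M)
                    - special.gammaln((1 - mu) * M)
                )

            oracle, _ = integrate.quad(integrand, 0, 1, limit=300)
            assert expected_log_beta_norm((a, b), M) == pytest.approx(
                oracle, rel=1e-5, abs=1e-6
            )

    def test_domain_and_quad_order_errors(self):
        with pytest.raises(InputError):
            expected_log_beta_norm((0.0, 1.0), 1.0)
        with pytest.raises(InputError):
            expected_log_beta_norm((1.0, 1.0), -1.0)
        with pytest.raises(InputError):
            expected_log_beta_norm((1.0, 1.0), 1.0, quad_order=1)


class TestBetaEntropy:
    def test_matches_quadrature(self, rng):
        # -int q log q against the analytic Beta entropy used in the ELBO.
        for _ in range(20):
            a, b = 10 ** rng.uniform(0, 2, 2)

            def neg_qlogq(mu):
                return -stats.beta.pdf(mu, a, b) * stats.beta.logpdf(mu, a, b)

            oracle, _ = integrate.quad(neg_qlogq, 0, 1, limit=300)
            assert _beta_entropy(a, b) == pytest.approx(oracle, abs=1e-8)


class TestElbo:
    def setup_method(self):
        self.params = ModelParams(mu0=0.1, M0=10.0, M=np.array([10.0]))

    def test_empty_data_binomial_term_zero(self):
        counts = make_counts([[0]], [[0]])
        vp = VariationalParams(gamma=[[1.0, 1.0]], delta=[[[4.0, 8.0]]])
        parts = _elbo_components(counts, vp, self.params, 50)
        assert parts[0] == 0.0
        assert np.isfinite(elbo(counts, vp, self.params))

    def test_evidence_bound_small_instance(self):
        counts = make_counts([[3]], [[10]])
        vp = VariationalParams(gamma=[[1.0, 1.0]], delta=[[[4.0, 8.0]]])
        bound = elbo(counts, vp, self.params)
        evidence = oracle_log_evidence([3], [10], 0.1, 10.0, 10.0)
        assert bound <= evidence + 1e-6

    def test_conjugate_delta_does_not_decrease_bound(self):
        counts = make_counts([[3]], [[10]])
        vp = VariationalParams(gamma=[[1.0, 1.0]], delta=[[[4.0, 8.0]]])
        before = elbo(counts, vp, self.params)
        # Exact coordinate-ascent optimum of q(theta) at E_q[mu] = 1/2.
        e_mu, M = 0.5, 10.0
        vp_opt = VariationalParams(
            gamma=[[1.0, 1.0]],
            delta=[[[3 + M * e_mu, 7 + M * (1 - e_mu)]]],
        )
        assert elbo(counts, vp_opt, self.params) >= before

    def test_position_partition_additivity(self):
        # Positions are conditionally independent given (mu0, M0): the ELBO
        # of a two-position instance is the sum of the single-position ELBOs.
        counts2 = make_counts([[3], [1]], [[10], [8]])
        vp2 = VariationalParams(
            gamma=[[1.0, 2.0], [2.0, 5.0]], delta=[[[4.0, 8.0]], [[2.0, 7.0]]]
        )
        params2 = ModelParams(mu0=0.1, M0=10.0, M=np.array([10.0, 20.0]))
        total = elbo(counts2, vp2, params2)
        pieces = 0.0
        for j in range(2):
            cj = make_counts(counts2.r[j : j + 1], counts2.n[j : j + 1])
            vpj = VariationalParams(
                gamma=vp2.gamma[j : j + 1], delta=vp2.delta[j : j + 1]
            )
            pj = ModelParams(mu0=0.1, M0=10.0, M=params2.M[j : j + 1])
            pieces += elbo(cj, vpj, pj)
        assert total == pytest.approx(pieces, rel=1e-12)

    def test_conjugate_limit_of_log_beta_norm(self):
        # As q(mu) concentrates at m, the expected normalizer tends to the
        # plain log-normalizer at mu = m.
        from scipy import special

        m, M = 0.2, 35.0
        total = 1e6
        val = expected_log_beta_norm((m * total, (1 - m) * total), M)
        target = (
            special.gammaln(M)
            - special.gammaln(m * M)
            - special.gammaln((1 - m) * M)
        )
        assert val == pytest.approx(target, abs=1e-4)

    def test_shape_mismatch_rejected(self):
        counts = make_counts([[3]], [[10]])
        vp = VariationalParams(gamma=[[1.0, 1.0], [1.0, 1.0]], delta=[[[4.0, 8.0]], [[4.0, 8.0]]])
        with pytest.raises(InputError):
            elbo(counts, vp, self.params)


class TestEvidenceBoundProperty:
    def test_random_small_instances(self, rng):
        # ELBO never exceeds the log evidence (margin 1e-6), for random
        # data and random valid variational states.
        for _ in range(20):
            N = int(rng.integers(1, 3))
            n = rng.integers(0, 51, N)
            r = np.array([rng.integers(0, ni + 1) for ni in n])
            mu0 = rng.uniform(0.01, 0.9)
            M0 = 10 ** rng.uniform(-0.3, 2.7)
            M = 10 ** rng.uniform(0, 3.5)
            counts = make_counts(r[None, :], n[None, :])
            vp = VariationalParams(
                gamma=10 ** rng.uniform(-0.5, 2.5, (1, 2)),
                delta=10 ** rng.uniform(-0.5, 2.5, (1, N, 2)),
            )
            params = ModelParams(mu0=mu0, M0=M0, M=np.array([M]))
            bound = elbo(counts, vp, params)
            evidence = oracle_log_evidence(r, n, mu0, M0, M)
            assert bound <= evidence + 1e-6
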