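"""Posterior-difference test, chi-square promotion and variant calling."""

import numpy as np
import pytest
from scipy import stats

from rarevar.model import (
    InputError,
    ModelEstimate,
    ModelParams,
    NumericalError,
    VariationalParams,
)
from rarevar.testing import (
    GaussianPosterior,
    TestConfig,
    VariantCall,
    call_variants,
    chi2_nonuniform_test,
    gaussian_moments,
    posterior_difference_prob,
    scan_alpha,
)
from conftest import make_counts


def make_estimate(gamma, positions=None, counts_shape=None):
    gamma = np.asarray(gamma, dtype=float)
    J = gamma.shape[0]
    N = 2 if counts_shape is None else counts_shape[1]
    delta = np.tile([1.0, 9.0], (J, N, 1)).reshape(J, N, 2)
    return ModelEstimate(
        params=ModelParams(mu0=0.01, M0=10.0, M=np.full(J, 100.0)),
        vparams=VariationalParams(gamma=gamma, delta=delta),
        elbo_trace=[-1.0],
        converged=True,
        nraf=gamma[:, 0] / gamma.sum(axis=1),
        positions=np.arange(1, J + 1) if positions is None else np.asarray(positions),
        reference_base=np.array(["A"] * J),
        chrom="sim",
    )


class TestGaussianMoments:
    @pytest.mark.parametrize(
        "gamma,mean,var",
        [
            ((1, 1), 0.5, 1 / 12),
            ((2, 6), 0.25, 12 / (9 * 64)),
            ((50, 50), 0.5, 2500 / (101 * 1e4)),
        ],
    )
    def test_beta_moments(self, gamma, mean, var):
        post = gaussian_moments(gamma)
        assert post.mean[0] == pytest.approx(mean)
        assert post.variance[0] == pytest.approx(var, rel=1e-6)

    def test_rejects_bad_shapes(self):
        with pytest.raises(InputError):
            gaussian_moments((0.0, 1.0))
        with pytest.raises(InputError):
            GaussianPosterior(mean=0.5, variance=0.0)


class TestPosteriorDifference:
    def test_identical_posteriors_half(self):
        p = GaussianPosterior(mean=0.3, variance=0.01)
        assert posterior_difference_prob(p, p, 0.0, "one") == pytest.approx(0.5)

    def test_one_sided_value(self):
        case = GaussianPosterior(mean=0.6, variance=0.01)
        ctrl = GaussianPosterior(mean=0.4, variance=0.01)
        expected = stats.norm.cdf(0.2 / np.sqrt(0.02))
        assert posterior_difference_prob(case, ctrl, 0.0, "one") == pytest.approx(
            expected, abs=1e-6
        )
        assert expected == pytest.approx(0.92135, abs=1e-5)

    def test_two_sided_tau_zero_is_one(self):
        case = GaussianPosterior(mean=0.31, variance=0.004)
        ctrl = GaussianPosterior(mean=0.30, variance=0.004)
        assert posterior_difference_prob(case, ctrl, 0.0, "two") == pytest.approx(1.0)

    def test_two_sided_value(self):
        case = GaussianPosterior(mean=0.4, variance=0.01)
        ctrl = GaussianPosterior(mean=0.4, variance=0.01)
        p = posterior_difference_prob(case, ctrl, 0.1, "two")
        assert p == pytest.approx(2 * stats.norm.cdf(-0.1 / np.sqrt(0.02)), abs=1e-6)
        assert p == pytest.approx(0.47950, abs=1e-4)

    def test_one_sided_symmetry(self, rng):
        # Pr(case > ctrl) + Pr(ctrl > case) = 1 at tau = 0.
        for _ in range(10):
            a = GaussianPosterior(mean=rng.uniform(0.1, 0.9), variance=rng.uniform(0.001, 0.05))
            b = GaussianPosterior(mean=rng.uniform(0.1, 0.9), variance=rng.uniform(0.001, 0.05))
            total = posterior_difference_prob(a, b, 0.0, "one") + posterior_difference_prob(
                b, a, 0.0, "one"
            )
            assert total == pytest.approx(1.0, abs=1e-12)


class TestChiSquare:
    def test_uniform_counts(self):
        assert chi2_nonuniform_test((10, 10, 10)) == pytest.approx(1.0)

    def test_concentrated_counts(self):
        # statistic 60 on 2 df; chi2 survival is exp(-30)
        p = chi2_nonuniform_test((30, 0, 0))
        assert p == pytest.approx(np.exp(-30.0), rel=1e-9)

    def test_zero_total_undefined(self):
        with pytest.raises(NumericalError):
            chi2_nonuniform_test((0, 0, 0))


class TestTestConfig:
    def test_two_sided_requires_positive_tau(self):
        with pytest.raises(InputError):
            TestConfig(sided="two", tau=0.0)
        TestConfig(sided="two", tau=0.01)

    def test_alpha_bounds(self):
        with pytest.raises(InputError):
            TestConfig(alpha=0.0)
        with pytest.raises(InputError):
            TestConfig(alpha=1.0)


class TestCallVariants:
    def test_identical_fits_make_no_calls(self):
        gamma = np.array([[2.0, 98.0], [3.0, 97.0], [1.5, 98.5]])
        case = make_estimate(gamma)
        ctrl = make_estimate(gamma.copy())
        counts = make_counts([[5, 3], [4, 4], [2, 6]], [[100, 90], [110, 95], [80, 120]])
        calls = call_variants(case, ctrl, counts)
        assert all(c.diff_prob == pytest.approx(0.5) for c in calls)
        assert not any(c.provisional or c.called for c in calls)

    def test_uniform_base_split_blocks_promotion(self):
        case = make_estimate([[50.0, 50.0]])
        ctrl = make_estimate([[1.0, 99.0]])
        counts = make_counts([[30]], [[60]])
        counts.base_counts[0, 0] = [30, 10, 10, 10]  # ref A, uniform non-ref
        calls = call_variants(case, ctrl, counts)
        assert calls[0].provisional
        assert calls[0].chi2_p == pytest.approx(1.0)
        assert not calls[0].called

    def test_skewed_base_split_promotes(self):
        case = make_estimate([[50.0, 50.0]])
        ctrl = make_estimate([[1.0, 99.0]])
        counts = make_counts([[30]], [[60]], ref="A", alt="C")
        calls = call_variants(case, ctrl, counts)
        assert calls[0].provisional and calls[0].called
        assert calls[0].chi2_p < 1e-10

    def test_position_mismatch_rejected(self):
        case = make_estimate([[1.0, 9.0]], positions=[5])
        ctrl = make_estimate([[1.0, 9.0]], positions=[6])
        counts = make_counts([[1]], [[10]], positions=[5])
        with pytest.raises(InputError):
            call_variants(case, ctrl, counts)

    def test_called_implies_provisional_invariant(self):
        with pytest.raises(InputError):
            VariantCall(
                position=1,
                nraf_case=0.5,
                nraf_control=0.1,
                diff_prob=0.99,
                chi2_p=0.001,
                provisional=False,
                called=True,
            )


class TestScanAlpha:
    def setup_method(self):
        # Perfect separation: two clear variants among five positions.
        gamma_case = np.array(
            [[50.0, 50.0], [2.0, 98.0], [60.0, 40.0], [1.0, 99.0], [2.5, 97.5]]
        )
        gamma_ctrl = np.array(
            [[1.0, 99.0], [2.0, 98.0], [1.0, 99.0], [1.0, 99.0], [2.5, 97.5]]
        )
        self.case = make_estimate(gamma_case)
        self.ctrl = make_estimate(gamma_ctrl)
        self.counts = make_counts(
            [[30, 30], [3, 2], [40, 35], [2, 1], [3, 3]],
            [[60, 60], [100, 90], [70, 60], [100, 110], [90, 100]],
        )
        self.truth = {1, 3}

    def test_perfect_separation_operating_point(self):
        [(alpha, sens, spec)] = scan_alpha(
            self.case, self.ctrl, self.counts, self.truth, [0.05]
        )
        assert (sens, spec) == (1.0, 1.0)

    def test_alpha_monotonicity(self):
        alphas = [1e-300, 1e-3, 0.05, 0.5, 0.999]
        points = scan_alpha(self.case, self.ctrl, self.counts, self.truth, alphas)
        sens = [p[1] for p in points]
        spec = [p[2] for p in points]
        assert all(s2 >= s1 for s1, s2 in zip(sens, sens[1:]))
        assert all(s2 <= s1 for s1, s2 in zip(spec, spec[1:]))

    def test_tiny_alpha_no_calls(self):
        [(_, sens, spec)] = scan_alpha(
            self.case, self.ctrl, self.counts, self.truth, [1e-300]
        )
        assert sens == 0.0 and spec == 1.0

    def test_empty_alphas_rejected(self):
        with pytest.raises(InputError):
            scan_alpha(self.case, self.ctrl, self.counts, self.truth, [])


class TestGaussianApproximationFidelity:
    def test_beta_tail_close_to_gaussian_tail(self, rng):
        # For both shapes >= 5 the moment-matched Gaussian tail probability
        # stays within 0.05 of the exact Beta tail at mean +/- 2 sd.
        for _ in range(25):
            a, b = 10 ** rng.uniform(np.log10(5), 3, 2)
            post = gaussian_moments((a, b))
            mean, sd = post.mean[0], float(np.sqrt(post.variance[0]))
            for t in (mean - 2 * sd, mean + 2 * sd):
                exact = stats.beta.sf(t, a, b)
                approx = stats.norm.sf(t, loc=mean, scale=sd)
                assert abs(exact - approx) <= 0.05
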