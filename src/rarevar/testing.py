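"""Posterior-difference variant calling between a case and a control sample.

The variational posterior of each position's non-reference rate ``mu_j`` is a
Beta distribution; the case minus control difference of two Betas has no
closed form, so each side is approximated by a Gaussian matched to the Beta
mean and variance.  The difference is then Gaussian::

    delta_j | r_case, r_control ~ N(m_case - m_ctrl, v_case + v_ctrl)

A position is a *provisional* variant when the posterior probability that
the difference exceeds the effect-size threshold ``tau`` reaches
``1 - alpha/2``.  Provisional positions are *called* only if the pooled
non-reference base counts of the case sample reject uniformity in a Pearson
chi-square test — a uniform spread over the three non-reference bases is the
signature of indiscriminate sequencing error, not of a real variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model import InputError, ModelEstimate, NumericalError, ReadCountMatrix

__all__ = [
    "GaussianPosterior",
    "TestConfig",
    "VariantCall",
    "gaussian_moments",
    "posterior_difference_prob",
    "chi2_nonuniform_test",
    "call_variants",
    "scan_alpha",
]

logger = logging.getLogger("rarevar")


@dataclass
class GaussianPosterior:
    """Moment-matched Gaussian approximation of a Beta posterior."""

    mean: np.ndarray
    variance: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=np.float64))
        self.variance = np.atleast_1d(np.asarray(self.variance, dtype=np.float64))
        if np.any(self.variance <= 0):
            raise InputError("posterior variance must be positive")
        if np.any((self.mean <= 0) | (self.mean >= 1)):
            raise InputError("posterior mean must lie inside (0, 1)")


@dataclass
class TestConfig:
    """Test sizes and effect-size threshold for variant calling."""

    __test__ = False  # not a pytest collection target

    alpha: float = 0.05
    tau: float = 0.0
    sided: str = "one"
    chi2_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise InputError("alpha must lie inside (0, 1)")
        if self.tau < 0.0:
            raise InputError("tau must be non-negative")
        if self.sided not in ("one", "two"):
            raise InputError("sided must be 'one' or 'two'")
        if self.sided == "two" and self.tau == 0.0:
            # Pr(|delta| >= 0) = 1 identically: every position would be
            # provisional.  Refuse the degenerate combination.
            raise InputError("two-sided test requires tau > 0")
        if not (0.0 < self.chi2_alpha < 1.0):
            raise InputError("chi2_alpha must lie inside (0, 1)")


@dataclass
class VariantCall:
    """Per-position test result."""

    position: int
    nraf_case: float
    nraf_control: float
    diff_prob: float
    chi2_p: float | None
    provisional: bool
    called: bool

    def __post_init__(self) -> None:
        if self.called and not self.provisional:
            raise InputError("called implies provisional")


def gaussian_moments(gamma_j) -> GaussianPosterior:
    """Beta mean and variance for moment matching.

    ``mean = g1/(g1+g2)``; ``variance = g1 g2 / ((g1+g2+1)(g1+g2)^2)``.
    Accepts a single shape pair or a (J, 2) array.
    """
    g = np.atleast_2d(np.asarray(gamma_j, dtype=np.float64))
    if g.shape[-1] != 2 or np.any(g <= 0) or np.any(~np.isfinite(g)):
        raise InputError("gamma must be positive finite shape pairs")
    a, b = g[..., 0], g[..., 1]
    s = a + b
    return GaussianPosterior(mean=a / s, variance=a * b / ((s + 1.0) * s**2))


def posterior_difference_prob(case, control, tau=0.0, sided="one"):
    """Posterior probability that the case-control NRAF difference exceeds tau.

    One-sided: ``Pr(delta >= tau)``; two-sided: ``Pr(|delta| >= tau)``; both
    under the Gaussian difference distribution.
    """
    if sided not in ("one", "two"):
        raise InputError("sided must be 'one' or 'two'")
    if np.any(np.atleast_1d(case.variance) <= 0) or np.any(
        np.atleast_1d(control.variance) <= 0
    ):
        raise InputError("variances must be positive")
    mean_d = case.mean - control.mean
    sd_d = np.sqrt(case.variance + control.variance)
    if sided == "one":
        p = stats.norm.sf(tau, loc=mean_d, scale=sd_d)
    else:
        p = stats.norm.sf(tau, loc=mean_d, scale=sd_d) + stats.norm.cdf(
            -tau, loc=mean_d, scale=sd_d
        )
    p = np.clip(p, 0.0, 1.0)
    return float(p[0]) if p.size == 1 else p


def chi2_nonuniform_test(nonref_base_counts):
    """Pearson chi-square test of the three non-reference base counts
    against the uniform expectation (total/3 each), 2 degrees of freedom.

    Returns the upper-tail p-value.  A zero total makes the test undefined
    (the position cannot be promoted) and raises :class:`NumericalError`.
    """
    counts = np.asarray(nonref_base_counts, dtype=np.float64)
    if counts.shape != (3,) or np.any(counts < 0):
        raise InputError("expected 3 non-negative non-reference base counts")
    total = counts.sum()
    if total == 0:
        raise NumericalError("chi-square test undefined for zero counts")
    expected = total / 3.0
    statistic = float(np.sum((counts - expected) ** 2 / expected))
    return float(stats.chi2.sf(statistic, df=2))


def _chi2_pvalues(case_counts: ReadCountMatrix):
    """Vectorized chi-square p-values from pooled case non-reference counts.

    Returns (p, total); p is NaN where the total is zero.
    """
    nonref = case_counts.nonref_base_counts().astype(np.float64)  # (J, 3)
    total = nonref.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        expected = total[:, None] / 3.0
        statistic = np.sum((nonref - expected) ** 2 / expected, axis=1)
        p = stats.chi2.sf(statistic, df=2)
    p = np.where(total > 0, p, np.nan)
    return p, total


def call_variants(
    case_est: ModelEstimate,
    control_est: ModelEstimate,
    case_counts: ReadCountMatrix,
    config: TestConfig | None = None,
):
    """Run the posterior-difference test and chi-square promotion filter.

    For every position: the posterior difference probability is computed
    from the moment-matched variational posteriors; positions reaching
    ``1 - alpha/2`` are provisional; provisional positions are called when
    the case sample's pooled non-reference base counts reject uniformity at
    ``chi2_alpha``.  No multiple-testing correction is applied.
    """
    config = config or TestConfig()
    if case_est.positions is None or control_est.positions is None:
        raise InputError("estimates must carry positions")
    if not np.array_equal(case_est.positions, control_est.positions):
        raise InputError("case and control estimates cover different positions")
    if not np.array_equal(case_est.positions, case_counts.positions):
        raise InputError("case counts cover different positions than estimates")

    case_post = gaussian_moments(case_est.vparams.gamma)
    ctrl_post = gaussian_moments(control_est.vparams.gamma)
    diff_prob = np.atleast_1d(
        posterior_difference_prob(case_post, ctrl_post, config.tau, config.sided)
    )
    # Threshold on the complementary tail 1 - diff_prob, computed directly:
    # diff_prob saturates at 1.0 in double precision for well-separated
    # positions, which would make very small alpha (the high-specificity end
    # of an ROC sweep) inoperative.
    mean_d = case_post.mean - ctrl_post.mean
    sd_d = np.sqrt(case_post.variance + ctrl_post.variance)
    if config.sided == "one":
        complement = stats.norm.cdf((config.tau - mean_d) / sd_d)
    else:
        complement = stats.norm.cdf((config.tau - mean_d) / sd_d) - stats.norm.cdf(
            (-config.tau - mean_d) / sd_d
        )
    provisional = complement <= config.alpha / 2.0
    chi2_p, chi2_total = _chi2_pvalues(case_counts)

    low = provisional & (chi2_total > 0) & (chi2_total < 6)
    if low.any():
        logger.warning(
            "chi-square promotion test on %d provisional position(s) with "
            "fewer than 6 pooled non-reference reads (expected cell < 2)",
            int(low.sum()),
        )

    calls = []
    for j, pos in enumerate(case_est.positions):
        prov = bool(provisional[j])
        pj = None
        called = False
        if prov:
            if chi2_total[j] > 0:
                pj = float(chi2_p[j])
                called = pj < config.chi2_alpha
            else:
                logger.warning(
                    "position %d provisional but has no non-reference reads; "
                    "cannot run chi-square promotion test",
                    int(pos),
                )
        calls.append(
            VariantCall(
                position=int(pos),
                nraf_case=float(case_post.mean[j]),
                nraf_control=float(ctrl_post.mean[j]),
                diff_prob=float(diff_prob[j]),
                chi2_p=pj,
                provisional=prov,
                called=called,
            )
        )
    return calls


def scan_alpha(case_est, control_est, case_counts, truth, alphas, config=None):
    """Sensitivity/specificity operating points across test sizes (ROC scan).

    ``truth`` is the set of true variant positions; every position in the
    estimates is scored.  Returns a list of (alpha, sensitivity,
    specificity) tuples.
    """
    alphas = list(alphas)
    if not alphas:
        raise InputError("alphas must be non-empty")
    base = config or TestConfig()
    truth = set(int(p) for p in truth)
    total_true = len(truth)
    total_false = len(case_est.positions) - total_true
    out = []
    for alpha in alphas:
        cfg = TestConfig(
            alpha=alpha, tau=base.tau, sided=base.sided, chi2_alpha=base.chi2_alpha
        )
        calls = call_variants(case_est, control_est, case_counts, cfg)
        called = {c.position for c in calls if c.called}
        tp = len(called & truth)
        fp = len(called - truth)
        sens = tp / total_true if total_true else float("nan")
        spec = 1.0 - fp / total_false if total_false else float("nan")
        out.append((alpha, sens, spec))
    return out
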