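"""Hierarchical Beta-Binomial model for per-position non-reference read counts.

The generative model, per genomic position ``j`` and sequencing replicate ``i``::

    mu_j      ~ Beta(mu0, M0)          position-level non-reference read rate
    theta_ji  ~ Beta(mu_j, M_j)        replicate-level non-reference read rate
    r_ji | n_ji ~ Binomial(n_ji, theta_ji)

Beta distributions are written in mean/precision form throughout:
``Beta(m, M)`` has shape parameters ``(m*M, (1-m)*M)``.

This module holds the observed-data container, the parameter containers, and
all evidence-lower-bound (ELBO) mathematics used by the variational EM
algorithm, including the numerically integrated expectation of the log
Beta-function normalizer, which has no closed form under a Beta variational
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import special

__all__ = [
    "BASES",
    "InputError",
    "NumericalError",
    "ReadCountMatrix",
    "ModelParams",
    "VariationalParams",
    "ModelEstimate",
    "beta_shapes_from_mean_precision",
    "beta_mean_precision_from_shapes",
    "expected_log_beta_norm",
    "elbo",
]

BASES = "ACGT"

# Quantile that bounds the quadrature window in logit space (per tail).
_QUAD_TAIL = 1e-9
# Clips that keep log/gammaln arguments finite at the quadrature nodes.
_MU_FLOOR = 1e-280
_MU_CEIL = 1.0 - 1e-16


class InputError(ValueError):
    """Invalid observed data or configuration."""


class NumericalError(ArithmeticError):
    """A numerical computation produced a non-finite result."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ReadCountMatrix:
    """Observed per-position, per-replicate nucleotide read counts.

    Attributes
    ----------
    positions : (J,) int array of 1-based genomic coordinates.
    reference_base : (J,) array of single characters in {A, C, G, T}.
    base_counts : (J, N, 4) int array, count of each nucleotide (A, C, G, T
        order) at each position in each replicate.
    r : (J, N) int array, non-reference read count (sum of the three
        non-reference nucleotides).
    n : (J, N) int array, total read count (sum of all four nucleotides).
    chrom : sequence name the positions refer to (metadata only).
    """

    positions: np.ndarray
    reference_base: np.ndarray
    base_counts: np.ndarray
    r: np.ndarray
    n: np.ndarray
    chrom: str = "."

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.reference_base = np.asarray(self.reference_base, dtype="<U1")
        self.base_counts = np.asarray(self.base_counts, dtype=np.int64)
        self.r = np.asarray(self.r, dtype=np.int64)
        self.n = np.asarray(self.n, dtype=np.int64)
        J = self.positions.shape[0]
        if J < 1 or self.base_counts.ndim != 3 or self.base_counts.shape[0] != J:
            raise InputError("base_counts must have shape (J, N, 4) with J >= 1")
        N = self.base_counts.shape[1]
        if N < 1 or self.base_counts.shape[2] != 4:
            raise InputError("base_counts must have shape (J, N, 4) with N >= 1")
        if self.r.shape != (J, N) or self.n.shape != (J, N):
            raise InputError("r and n must have shape (J, N)")
        if np.any(self.base_counts < 0):
            raise InputError("negative base counts")
        if not np.all(np.isin(self.reference_base, list(BASES))):
            raise InputError("reference_base entries must be one of A, C, G, T")
        if np.any(self.positions < 1):
            raise InputError("positions must be 1-based (>= 1)")
        ref_idx = self._ref_index()
        total = self.base_counts.sum(axis=2)
        nonref = total - np.take_along_axis(
            self.base_counts, ref_idx[:, None, None], axis=2
        )[:, :, 0]
        if np.any(self.n != total):
            raise InputError("n must equal the sum of base counts")
        if np.any(self.r != nonref):
            raise InputError("r must equal the sum of non-reference base counts")
        if np.any(self.r < 0) or np.any(self.r > self.n):
            raise InputError("0 <= r <= n violated")

    def _ref_index(self) -> np.ndarray:
        lut = {b: k for k, b in enumerate(BASES)}
        return np.array([lut[b] for b in self.reference_base], dtype=np.int64)

    @property
    def J(self) -> int:
        return self.positions.shape[0]

    @property
    def N(self) -> int:
        return self.base_counts.shape[1]

    @classmethod
    def from_base_counts(cls, positions, reference_base, base_counts, chrom="."):
        """Build a matrix from base counts alone; derives ``r`` and ``n``."""
        base_counts = np.asarray(base_counts, dtype=np.int64)
        reference_base = np.asarray(reference_base, dtype="<U1")
        lut = {b: k for k, b in enumerate(BASES)}
        ref_idx = np.array([lut[b] for b in reference_base], dtype=np.int64)
        n = base_counts.sum(axis=2)
        ref_counts = np.take_along_axis(
            base_counts, ref_idx[:, None, None], axis=2
        )[:, :, 0]
        return cls(
            positions=np.asarray(positions),
            reference_base=reference_base,
            base_counts=base_counts,
            r=n - ref_counts,
            n=n,
            chrom=chrom,
        )

    def nonref_base_counts(self) -> np.ndarray:
        """Per-position counts of the three non-reference bases, pooled over
        replicates.  Returns a (J, 3) array ordered by base (A<C<G<T with the
        reference base removed) alongside nothing else; use
        :meth:`nonref_base_labels` for the base identities."""
        pooled = self.base_counts.sum(axis=1)  # (J, 4)
        ref_idx = self._ref_index()
        J = self.J
        out = np.empty((J, 3), dtype=np.int64)
        for j in range(J):
            out[j] = np.delete(pooled[j], ref_idx[j])
        return out

    def nonref_base_labels(self) -> np.ndarray:
        """(J, 3) array of the non-reference base characters, in A<C<G<T order."""
        ref_idx = self._ref_index()
        labels = np.empty((self.J, 3), dtype="<U1")
        base_arr = np.array(list(BASES))
        for j in range(self.J):
            labels[j] = np.delete(base_arr, ref_idx[j])
        return labels


@dataclass
class ModelParams:
    """Model parameters phi = {mu0, M0, M_1..J}."""

    mu0: float
    M0: float
    M: np.ndarray

    def __post_init__(self) -> None:
        self.mu0 = float(self.mu0)
        self.M0 = float(self.M0)
        self.M = np.asarray(self.M, dtype=np.float64)
        if not (0.0 < self.mu0 < 1.0):
            raise InputError("mu0 must lie strictly inside (0, 1)")
        if not (self.M0 > 0.0 and np.isfinite(self.M0)):
            raise InputError("M0 must be positive and finite")
        if self.M.ndim != 1 or np.any(~np.isfinite(self.M)) or np.any(self.M <= 0):
            raise InputError("M must be a 1-d array of positive finite precisions")


@dataclass
class VariationalParams:
    """Beta shape parameters of the factorized variational distribution.

    ``gamma[j] = (gamma_j1, gamma_j2)`` parameterizes ``q(mu_j)`` and
    ``delta[j, i] = (delta_ji1, delta_ji2)`` parameterizes ``q(theta_ji)``.
    """

    gamma: np.ndarray
    delta: np.ndarray

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=np.float64)
        self.delta = np.asarray(self.delta, dtype=np.float64)
        if self.gamma.ndim != 2 or self.gamma.shape[1] != 2:
            raise InputError("gamma must have shape (J, 2)")
        if self.delta.ndim != 3 or self.delta.shape[2] != 2:
            raise InputError("delta must have shape (J, N, 2)")
        if self.delta.shape[0] != self.gamma.shape[0]:
            raise InputError("gamma and delta disagree on J")
        for arr, name in ((self.gamma, "gamma"), (self.delta, "delta")):
            if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
                raise InputError(f"{name} shape parameters must be positive and finite")


@dataclass
class ModelEstimate:
    """Result of a variational EM fit."""

    params: ModelParams
    vparams: VariationalParams
    elbo_trace: list
    converged: bool
    nraf: np.ndarray
    positions: np.ndarray | None = None
    reference_base: np.ndarray | None = None
    chrom: str = "."
    warnings: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Beta parameterization and analytic expectations
# ---------------------------------------------------------------------------


def beta_shapes_from_mean_precision(mean, precision):
    """Map mean/precision Beta parameters to the shape pair (a, b).

    ``Beta(mean, precision)`` has shapes ``(mean*precision, (1-mean)*precision)``;
    the inverse mapping is ``mean = a/(a+b)``, ``precision = a+b``.
    """
    mean = np.asarray(mean, dtype=np.float64)
    precision = np.asarray(precision, dtype=np.float64)
    if np.any(mean <= 0.0) or np.any(mean >= 1.0):
        raise InputError("mean must lie strictly inside (0, 1)")
    if np.any(precision <= 0.0) or np.any(~np.isfinite(precision)):
        raise InputError("precision must be positive and finite")
    a = mean * precision
    b = (1.0 - mean) * precision
    if a.ndim == 0:
        return float(a), float(b)
    return a, b


def beta_mean_precision_from_shapes(a, b):
    """Inverse of :func:`beta_shapes_from_mean_precision`."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if np.any(a <= 0) or np.any(b <= 0):
        raise InputError("shape parameters must be positive")
    mean = a / (a + b)
    if mean.ndim == 0:
        return float(mean), float(a + b)
    return mean, a + b


def _beta_elog(a, b):
    """E[log mu] and E[log(1-mu)] under Beta(a, b)."""
    s = a + b
    ps = special.digamma(s)
    return special.digamma(a) - ps, special.digamma(b) - ps


def _beta_entropy(a, b):
    """Differential entropy of Beta(a, b)."""
    s = a + b
    return (
        special.betaln(a, b)
        - (a - 1.0) * special.digamma(a)
        - (b - 1.0) * special.digamma(b)
        + (s - 2.0) * special.digamma(s)
    )


# ---------------------------------------------------------------------------
# Quadrature for the expected log Beta-function normalizer
# ---------------------------------------------------------------------------


from functools import lru_cache


@lru_cache(maxsize=16)
def _leggauss_cached(order):
    return np.polynomial.legendre.leggauss(order)


class QuadNodes(NamedTuple):
    """Quadrature nodes with precision-safe tail values.

    ``mu1m`` is 1 - mu computed from the logit coordinate (no cancellation);
    ``L1 = log(mu)``, ``L2 = log(1 - mu)`` likewise.
    """

    mu: np.ndarray
    mu1m: np.ndarray
    L1: np.ndarray
    L2: np.ndarray
    w: np.ndarray


def _polygamma_asymptotic(x, order):
    """psi_1 (trigamma) or psi_2 (tetragamma), vectorized.

    Recurrence-shifts x above 10 and applies the standard asymptotic series;
    absolute accuracy ~1e-12, far faster than scipy's zeta-based polygamma
    on the small arrays used in the optimizer inner loops.
    """
    x = np.asarray(x, dtype=np.float64)
    shift = np.maximum(0, np.ceil(10.0 - x)).astype(np.int64)
    max_shift = int(shift.max()) if shift.size else 0
    acc = np.zeros_like(x)
    xs = x.copy()
    for _ in range(max_shift):
        active = shift > 0
        if order == 1:
            acc[active] += 1.0 / xs[active] ** 2
        else:
            acc[active] += -2.0 / xs[active] ** 3
        xs[active] += 1.0
        shift[active] -= 1
    z = 1.0 / (xs * xs)
    if order == 1:
        # psi_1(x) ~ 1/x + 1/(2x^2) + 1/(6x^3) - 1/(30x^5) + 1/(42x^7) - ...
        tail = 1.0 / xs + z * (
            0.5
            + (1.0 / xs)
            * (1.0 / 6.0 - z * (1.0 / 30.0 - z * (1.0 / 42.0 - z / 30.0)))
        )
        return acc + tail
    # psi_2(x) ~ -1/x^2 - 1/x^3 - 1/(2x^4) + 1/(6x^6) - 1/(6x^8) + 3/(10x^10)
    tail = -z - z / xs - z * z * (
        0.5 - z * (1.0 / 6.0 - z * (1.0 / 6.0 - 0.3 * z))
    )
    return acc + tail


def _trigamma(x):
    return _polygamma_asymptotic(x, 1)


def _tetragamma(x):
    return _polygamma_asymptotic(x, 2)


def _quad_nodes(a, b, quad_order):
    """Gauss-Legendre nodes/weights in logit space for E_{Beta(a,b)}[g(mu)].

    The window spans the Beta ``_QUAD_TAIL`` .. ``1 - _QUAD_TAIL`` quantiles
    and is split at the median into two panels of ``quad_order // 2`` nodes
    each, so that arbitrarily concentrated or skewed variational posteriors
    are resolved.  Returns ``mu`` (..., K) node positions and ``logw`` is not
    needed: weights ``w`` (..., K) already include the logit Jacobian folded
    into the density exponent convention used by :func:`_quad_expect`:
    the density-with-Jacobian at a node is ``exp(a*log(mu) + b*log1p(-mu) -
    betaln(a, b))``.
    """
    a = np.atleast_1d(np.asarray(a, dtype=np.float64))
    b = np.atleast_1d(np.asarray(b, dtype=np.float64))
    order = max(int(quad_order), 2)
    half = max(order // 2, 1)
    x, w = _leggauss_cached(half)

    # Window in logit space.  For shapes >= 4 the logit-transformed Beta is
    # close to Gaussian with mean psi(a) - psi(b) and variance
    # psi1(a) + psi1(b); a +/- 8.5 sd window (floored at 23/shape for the
    # exponential tails) covers the mass to ~1e-12 without the cost of
    # betaincinv.  Smaller shapes get exact 1e-9 .. 1-1e-9 quantiles.
    mean_logit = special.digamma(a) - special.digamma(b)
    sd_logit = np.sqrt(_trigamma(a) + _trigamma(b))
    spread = 8.5 * sd_logit
    xlo = mean_logit - np.maximum(spread, 23.0 / a)
    xhi = mean_logit + np.maximum(spread, 23.0 / b)
    # Panel split near the median (psi(a) - psi(b) is ample for partitioning
    # of near-Gaussian cases; heavily skewed small-shape cases get the exact
    # median below).
    xmed = mean_logit.copy()
    exact = (a < 4.0) | (b < 4.0)
    if exact.any():
        ae, be = a[exact], b[exact]
        lo = np.clip(special.betaincinv(ae, be, _QUAD_TAIL), _MU_FLOOR, _MU_CEIL)
        up = np.clip(special.betaincinv(be, ae, _QUAD_TAIL), _MU_FLOOR, _MU_CEIL)
        xlo[exact] = np.log(lo) - np.log1p(-lo)
        xhi[exact] = -(np.log(up) - np.log1p(-up))
        # Median in canonical (smaller shape first) orientation so that the
        # swap identity (a, b) <-> (b, a) holds to round-off.
        flip = ae > be
        med = np.clip(
            special.betaincinv(np.where(flip, be, ae), np.where(flip, ae, be), 0.5),
            _MU_FLOOR,
            _MU_CEIL,
        )
        xmed_exact = np.log(med) - np.log1p(-med)
        xmed[exact] = np.where(flip, -xmed_exact, xmed_exact)
    xmed = np.clip(xmed, xlo, xhi)
    # Guard degenerate windows (extreme concentration in float).
    xlo = np.minimum(xlo, xmed - 1e-12)
    xhi = np.maximum(xhi, xmed + 1e-12)

    def panel(plo, phi):
        mid = 0.5 * (phi + plo)[..., None]
        hw = 0.5 * (phi - plo)[..., None]
        return mid + hw * x, hw * w

    t1, w1 = panel(xlo, xmed)
    t2, w2 = panel(xmed, xhi)
    t = np.concatenate([t1, t2], axis=-1)
    ww = np.concatenate([w1, w2], axis=-1)
    # Evaluate both tails from the logit coordinate directly: expit(-t) and
    # log_expit keep full precision where mu or 1-mu underflows against 1.
    mu = np.clip(special.expit(t), _MU_FLOOR, _MU_CEIL)
    mu1m = np.clip(special.expit(-t), _MU_FLOOR, _MU_CEIL)
    L1 = special.log_expit(t)
    L2 = special.log_expit(-t)
    return QuadNodes(mu=mu, mu1m=mu1m, L1=L1, L2=L2, w=ww)


def _quad_density(a, b, nodes, normalize=True):
    """Quadrature weights times Beta(a,b) density (logit Jacobian included).

    With ``normalize`` the weights are rescaled to sum to one, which removes
    the first-order effect of quantile (window placement) error at extreme
    concentrations — without it, a relative mass defect epsilon biases
    E_q[g] by epsilon * |E_q[g]|, which is catastrophic when g is large.
    """
    logq = (
        a[..., None] * nodes.L1
        + b[..., None] * nodes.L2
        - special.betaln(a, b)[..., None]
    )
    Q = nodes.w * np.exp(logq)
    if normalize:
        Q = Q / np.sum(Q, axis=-1, keepdims=True)
    return Q


def _log_beta_norm_integrand(nodes, M):
    """g(mu) = log Gamma(M) - log Gamma(mu M) - log Gamma((1-mu) M)."""
    M = np.asarray(M, dtype=np.float64)
    Mb = M[..., None] if M.ndim else M
    return (
        special.gammaln(Mb)
        - special.gammaln(nodes.mu * Mb)
        - special.gammaln(nodes.mu1m * Mb)
    )


def _expected_log_beta_norm_vec(a, b, M, quad_order):
    """Vectorized E_q[-log B(mu M, (1-mu) M)] for arrays a, b, M of shape (J,)."""
    nodes = _quad_nodes(a, b, quad_order)
    Q = _quad_density(np.atleast_1d(a), np.atleast_1d(b), nodes)
    g = _log_beta_norm_integrand(nodes, np.atleast_1d(M))
    return np.sum(Q * g, axis=-1)


def expected_log_beta_norm(gamma_j, M_j, quad_order=50):
    """Expected log Beta-function normalizer under the variational posterior.

    Computes ``E_q[log(Gamma(M_j) / (Gamma(mu_j M_j) Gamma((1-mu_j) M_j)))]``
    where ``q(mu_j) = Beta(gamma_j1, gamma_j2)``, by Gauss-Legendre quadrature
    in logit space (see :func:`_quad_nodes`).

    Parameters
    ----------
    gamma_j : pair of positive Beta shape parameters.
    M_j : positive precision.
    quad_order : total number of quadrature nodes (>= 2).

    Returns
    -------
    float
    """
    a, b = float(gamma_j[0]), float(gamma_j[1])
    if not (a > 0 and b > 0 and np.isfinite(a) and np.isfinite(b)):
        raise InputError("gamma shape parameters must be positive and finite")
    if not (M_j > 0 and np.isfinite(M_j)):
        raise InputError("M_j must be positive and finite")
    if quad_order < 2:
        raise InputError("quad_order must be at least 2")
    val = _expected_log_beta_norm_vec(
        np.array([a]), np.array([b]), np.array([float(M_j)]), quad_order
    )[0]
    if not np.isfinite(val):
        raise NumericalError("expected_log_beta_norm evaluated non-finite")
    return float(val)


# ---------------------------------------------------------------------------
# ELBO
# ---------------------------------------------------------------------------


def _elbo_components(counts, vparams, params, quad_order):
    """Return the additive pieces of the ELBO as floats.

    Pieces: expected log-binomial, expected log p(theta|mu,M), expected
    log p(mu|mu0,M0), entropy of q(mu), entropy of q(theta).
    """
    r = counts.r.astype(np.float64)
    n = counts.n.astype(np.float64)
    ga, gb = vparams.gamma[:, 0], vparams.gamma[:, 1]
    da, db = vparams.delta[:, :, 0], vparams.delta[:, :, 1]
    M = params.M
    N = counts.N

    elog_t, elog_1mt = _beta_elog(da, db)  # (J, N)
    elog_m, elog_1mm = _beta_elog(ga, gb)  # (J,)
    e_mu = ga / (ga + gb)

    # (i) E_q[log Binomial(r | n, theta)]; zero-depth replicates contribute 0.
    log_choose = (
        special.gammaln(n + 1.0)
        - special.gammaln(r + 1.0)
        - special.gammaln(n - r + 1.0)
    )
    ll_binom = np.sum(log_choose + r * elog_t + (n - r) * elog_1mt)

    # (ii) E_q[log Beta(theta | mu, M)]; cross terms factor because q(mu) and
    # q(theta) are independent under the mean-field factorization.
    g = _expected_log_beta_norm_vec(ga, gb, M, quad_order)  # (J,)
    ll_theta = np.sum(
        (M[:, None] * e_mu[:, None] - 1.0) * elog_t
        + (M[:, None] * (1.0 - e_mu[:, None]) - 1.0) * elog_1mt
    ) + N * np.sum(g)

    # (iii) E_q[log Beta(mu | mu0, M0)] -- fully analytic.
    a0 = params.mu0 * params.M0
    b0 = (1.0 - params.mu0) * params.M0
    ll_mu = np.sum(
        (a0 - 1.0) * elog_m + (b0 - 1.0) * elog_1mm - special.betaln(a0, b0)
    )

    ent_mu = np.sum(_beta_entropy(ga, gb))
    ent_theta = np.sum(_beta_entropy(da, db))
    return ll_binom, ll_theta, ll_mu, ent_mu, ent_theta


def elbo(counts, vparams, params, quad_order=50):
    """Evidence lower bound L(q, phi) <= log p(r | n; phi).

    The bound decomposes position-wise (positions are conditionally
    independent given mu0 and M0), so the value is identical whether
    positions are processed serially or in any partition.
    """
    if vparams.gamma.shape[0] != counts.J or vparams.delta.shape[:2] != (
        counts.J,
        counts.N,
    ):
        raise InputError("variational parameter shapes do not match counts")
    if params.M.shape[0] != counts.J:
        raise InputError("params.M length does not match counts")
    parts = _elbo_components(counts, vparams, params, quad_order)
    val = float(sum(parts))
    if not np.isfinite(val):
        raise NumericalError("ELBO evaluated non-finite")
    return val
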