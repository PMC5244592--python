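"""Shared fixtures and independent oracles.

The oracles never touch the package's ELBO/quadrature code path: the
evidence and posterior moments for a single position come from the closed
form of the Beta-Binomial compound (theta integrates out exactly) and dense
adaptive quadrature over mu only.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import integrate, special

from rarevar.model import ReadCountMatrix


def make_counts(r, n, ref="A", alt="C", positions=None, chrom="sim"):
    """ReadCountMatrix with all non-reference reads on one base."""
    r = np.atleast_2d(np.asarray(r, dtype=np.int64))
    n = np.atleast_2d(np.asarray(n, dtype=np.int64))
    J, N = r.shape
    bases = "ACGT"
    base_counts = np.zeros((J, N, 4), dtype=np.int64)
    base_counts[:, :, bases.index(ref)] = n - r
    base_counts[:, :, bases.index(alt)] = r
    return ReadCountMatrix(
        positions=np.arange(1, J + 1) if positions is None else np.asarray(positions),
        reference_base=np.array([ref] * J),
        base_counts=base_counts,
        r=r,
        n=n,
        chrom=chrom,
    )


def _log_posterior_mu(mu, rs, ns, mu0, M0, M):
    """Unnormalized log posterior density of mu for one position (theta
    marginalized exactly through the Beta-Binomial compound)."""
    a0, b0 = mu0 * M0, (1.0 - mu0) * M0
    lp = (a0 - 1.0) * np.log(mu) + (b0 - 1.0) * np.log1p(-mu) - special.betaln(a0, b0)
    for r_i, n_i in zip(rs, ns):
        lp = lp + (
            special.gammaln(n_i + 1.0)
            - special.gammaln(r_i + 1.0)
            - special.gammaln(n_i - r_i + 1.0)
            + special.betaln(r_i + M * mu, n_i - r_i + M * (1.0 - mu))
            - special.betaln(M * mu, M * (1.0 - mu))
        )
    return lp


def _mu_integral(fn, rs, ns, mu0, M0, M):
    """log of integral of fn(mu) * posterior-numerator over (0, 1)."""
    grid = np.linspace(1e-6, 1.0 - 1e-6, 512)
    shift = np.max(_log_posterior_mu(grid, rs, ns, mu0, M0, M))

    def integrand(mu):
        return fn(mu) * np.exp(_log_posterior_mu(mu, rs, ns, mu0, M0, M) - shift)

    val, _ = integrate.quad(integrand, 0.0, 1.0, limit=300)
    return shift, val


def oracle_log_evidence(rs, ns, mu0, M0, M):
    """log p(r | n; phi) for one position by exact-theta + mu quadrature."""
    shift, val = _mu_integral(lambda mu: 1.0, rs, ns, mu0, M0, M)
    return shift + np.log(val)


def oracle_posterior_mean_mu(rs, ns, mu0, M0, M):
    """E[mu | r] for one position."""
    shift, z = _mu_integral(lambda mu: 1.0, rs, ns, mu0, M0, M)
    _, m = _mu_integral(lambda mu: mu, rs, ns, mu0, M0, M)
    return m / z


def oracle_posterior_mean_theta(r_i, n_i, rs, ns, mu0, M0, M):
    """E[theta_i | r]; theta_i | mu, r is Beta(r_i + M mu, ...) so
    E[theta_i | r] = (r_i + M E[mu | r]) / (n_i + M)."""
    e_mu = oracle_posterior_mean_mu(rs, ns, mu0, M0, M)
    return (r_i + M * e_mu) / (n_i + M)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260918)
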