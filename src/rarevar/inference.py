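"""Coordinate-ascent variational EM for the hierarchical Beta-Binomial model.

One EM iteration alternates

* E-step: maximize the ELBO over the variational parameters — the ``delta``
  (per replicate) block in closed form (it is the exact conjugate block
  maximizer), the ``gamma`` (per position) block by damped Newton ascent,
  vectorized across positions;
* M-step: maximize over the model parameters — ``(mu0, M0)`` jointly
  (analytic gradient, L-BFGS-B), each ``M_j`` by vectorized 1-d Newton
  ascent.

Every block update is monotone in the ELBO by construction (exact block
maximizer or backtracking line search), so the ELBO trace is non-decreasing
up to quadrature round-off.  Positions are conditionally independent given
``(mu0, M0)``; all per-position updates are elementwise, so permuting
positions permutes the result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .model import (
    InputError,
    _tetragamma,
    _trigamma,
    ModelEstimate,
    ModelParams,
    ReadCountMatrix,
    VariationalParams,
    _beta_elog,
    _log_beta_norm_integrand,
    _quad_density,
    _quad_nodes,
    beta_shapes_from_mean_precision,
    elbo,
)

__all__ = ["FitConfig", "initialize", "e_step", "m_step", "fit"]

logger = logging.getLogger("rarevar")

# Box bounds for all optimized quantities.  The lower bound on the local
# precisions M_j is 1: below it the replicate-rate prior Beta(mu M, (1-mu) M)
# has both shapes < 1, i.e. a bimodal density with atoms at 0 and 1, and the
# likelihood can exploit it as a zero-inflation switch that decouples theta
# from mu entirely (positions become data-blind).  That regime is outside the
# model's intent — M_j measures rate variation across replicates.
_DEFAULT_BOUNDS = {
    "mu0": (1e-6, 1.0 - 1e-6),
    "M0": (1e-3, 1e8),
    "M": (1.0, 1e8),
    "gamma": (1e-3, 1e10),
    "delta": (1e-3, 1e10),
}
# method-of-moments precision estimates at initialization are clipped tighter
_INIT_PREC_CLIP = (1e-3, 1e6)


@dataclass
class FitConfig:
    """Configuration of the variational EM fit.

    ``fix_M0`` pins the global precision during the M-step (used for
    sensitivity analysis of the regularizing prior).  ``seed`` is reserved
    for randomized restarts; the default algorithm is fully deterministic.
    """

    max_iterations: int = 100
    elbo_rel_tol: float = 1e-5
    quad_order: int = 50
    seed: int = 0
    fix_M0: float | None = None
    optimizer_bounds: dict = field(default_factory=lambda: dict(_DEFAULT_BOUNDS))
    e_step_cycles: int = 2
    newton_max_iter: int = 40

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise InputError("max_iterations must be >= 1")
        if not (self.elbo_rel_tol > 0):
            raise InputError("elbo_rel_tol must be positive")
        if self.quad_order < 2:
            raise InputError("quad_order must be >= 2")
        if self.fix_M0 is not None and not (self.fix_M0 > 0):
            raise InputError("fix_M0 must be positive")
        for key, (lo, hi) in self.optimizer_bounds.items():
            if not (0 < lo < hi):
                raise InputError(f"invalid bounds for {key}")


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------


def initialize(counts: ReadCountMatrix):
    """Method-of-moments initialization of model and variational parameters.

    delta is set to the prior-smoothed empirical Beta posterior with
    pseudocount 1; gamma by method of moments on the smoothed per-replicate
    rates (variance floored at 1e-10); mu0 is the median pooled non-reference
    rate; M0 and M_j are method-of-moments precisions, clipped to [1e-3, 1e6].
    """
    c = 1.0
    r = counts.r.astype(np.float64)
    n = counts.n.astype(np.float64)

    delta = np.stack([r + c, n - r + c], axis=-1)

    x = (r + c) / (n + 2.0 * c)  # (J, N), strictly inside (0, 1)
    m = x.mean(axis=1)
    # Floor the replicate variance at the binomial sampling noise: observed
    # scatter below that level carries no evidence of real over-dispersion,
    # and inverting it would produce absurdly confident precision estimates
    # (the raw floor 1e-10 yields precisions of 1e6 whenever replicates
    # happen to agree, which blinds the first EM iterations to the data).
    v_binom = m * (1.0 - m) * np.mean(1.0 / (n + 2.0 * c), axis=1)
    v = np.maximum.reduce([x.var(axis=1), v_binom, np.full_like(m, 1e-10)])
    prec = np.clip(m * (1.0 - m) / v - 1.0, *_INIT_PREC_CLIP)
    m_clip = np.clip(m, 1e-6, 1.0 - 1e-6)
    ga, gb = beta_shapes_from_mean_precision(m_clip, prec)
    glo, ghi = _DEFAULT_BOUNDS["gamma"]
    gamma = np.stack([np.clip(ga, glo, ghi), np.clip(gb, glo, ghi)], axis=-1)

    n_pool = n.sum(axis=1)
    r_pool = r.sum(axis=1)
    pooled = np.where(n_pool > 0, r_pool / np.maximum(n_pool, 1.0), 0.5)
    mu0 = float(np.clip(np.median(pooled), 1e-6, 1.0 - 1e-6))
    v0 = max(float(np.var(pooled)), 1e-10)
    M0 = float(np.clip(mu0 * (1.0 - mu0) / v0 - 1.0, *_INIT_PREC_CLIP))
    M = np.clip(prec, *_INIT_PREC_CLIP)

    return ModelParams(mu0=mu0, M0=M0, M=M), VariationalParams(
        gamma=gamma, delta=delta
    )


# ---------------------------------------------------------------------------
# E-step
# ---------------------------------------------------------------------------


def _update_delta(counts, gamma, params, bounds):
    """Exact conjugate block maximizer of the ELBO over q(theta)."""
    e_mu = gamma[:, 0] / (gamma[:, 0] + gamma[:, 1])
    r = counts.r.astype(np.float64)
    n = counts.n.astype(np.float64)
    da = r + (params.M * e_mu)[:, None]
    db = n - r + (params.M * (1.0 - e_mu))[:, None]
    lo, hi = bounds
    return np.stack([np.clip(da, lo, hi), np.clip(db, lo, hi)], axis=-1)


def _gamma_objective(a, b, consts, with_derivs, quad_order):
    """Per-position ELBO terms that depend on gamma_j = (a_j, b_j).

    Quadrature nodes are recomputed from (a, b) at every evaluation, so the
    value is accurate wherever the optimizer lands; the node-placement
    dependence of the derivatives is second-order in the quadrature error
    and is ignored.  ``consts`` holds (a0, b0, M, S1, S2, N).  Returns F or
    (F, grad, hess) in (a, b).
    """
    a0, b0, M, S1, S2, N = consts
    nodes = _quad_nodes(a, b, quad_order)
    L1, L2, w = nodes.L1, nodes.L2, nodes.w
    g = _log_beta_norm_integrand(nodes, M)
    s = a + b
    psa, psb, pss = special.digamma(a), special.digamma(b), special.digamma(s)
    T1 = psa - pss
    T2 = psb - pss
    Q = w * np.exp(a[:, None] * L1 + b[:, None] * L2 - special.betaln(a, b)[:, None])
    Q = Q / np.sum(Q, axis=1, keepdims=True)
    G = np.sum(Q * g, axis=1)
    e_mu = a / s
    H = (
        special.betaln(a, b)
        - (a - 1.0) * psa
        - (b - 1.0) * psb
        + (s - 2.0) * pss
    )
    F = (a0 - 1.0) * T1 + (b0 - 1.0) * T2 + M * (e_mu * S1 + (1.0 - e_mu) * S2) + N * G + H
    if not with_derivs:
        return F

    p1a, p1b, p1s = _trigamma(a), _trigamma(b), _trigamma(s)
    p2a, p2b, p2s = _tetragamma(a), _tetragamma(b), _tetragamma(s)
    T1a, T1b = p1a - p1s, -p1s
    T2a, T2b = -p1s, p1b - p1s
    # With self-normalized weights the derivative of the quadrature density
    # centers on the *quadrature* means of log(mu), log(1-mu) — the digamma
    # terms cancel exactly: d(Q_k/Z)/da = (Q_k/Z) (L1_k - Lbar1).
    Lbar1 = np.sum(Q * L1, axis=1)
    Lbar2 = np.sum(Q * L2, axis=1)
    R1 = L1 - Lbar1[:, None]
    R2 = L2 - Lbar2[:, None]
    Ga = np.sum(Q * R1 * g, axis=1)
    Gb = np.sum(Q * R2 * g, axis=1)
    Ha = -(a - 1.0) * p1a + (s - 2.0) * p1s
    Hb = -(b - 1.0) * p1b + (s - 2.0) * p1s
    dS = S1 - S2
    Fa = (a0 - 1.0) * T1a + (b0 - 1.0) * T2a + M * dS * b / s**2 + N * Ga + Ha
    Fb = (a0 - 1.0) * T1b + (b0 - 1.0) * T2b - M * dS * a / s**2 + N * Gb + Hb

    T1aa, T1ab, T1bb = p2a - p2s, -p2s, -p2s
    T2aa, T2ab, T2bb = -p2s, -p2s, p2b - p2s
    # Second derivatives of the normalized quadrature expectation use the
    # quadrature variance/covariance of L1, L2 in place of trigamma terms.
    v11 = np.sum(Q * R1 * R1, axis=1)
    v12 = np.sum(Q * R1 * R2, axis=1)
    v22 = np.sum(Q * R2 * R2, axis=1)
    Gaa = np.sum(Q * R1 * R1 * g, axis=1) - v11 * G
    Gab = np.sum(Q * R1 * R2 * g, axis=1) - v12 * G
    Gbb = np.sum(Q * R2 * R2 * g, axis=1) - v22 * G
    Haa = -p1a - (a - 1.0) * p2a + p1s + (s - 2.0) * p2s
    Hab = p1s + (s - 2.0) * p2s
    Hbb = -p1b - (b - 1.0) * p2b + p1s + (s - 2.0) * p2s
    Faa = (a0 - 1.0) * T1aa + (b0 - 1.0) * T2aa - M * dS * 2.0 * b / s**3 + N * Gaa + Haa
    Fab = (a0 - 1.0) * T1ab + (b0 - 1.0) * T2ab + M * dS * (a - b) / s**3 + N * Gab + Hab
    Fbb = (a0 - 1.0) * T1bb + (b0 - 1.0) * T2bb + M * dS * 2.0 * a / s**3 + N * Gbb + Hbb
    return F, (Fa, Fb), (Faa, Fab, Fbb)


def _newton_2d(a, b, consts, bounds, max_iter, quad_order):
    """Vectorized per-position damped Newton ascent in (log a, log b).

    Backtracking guarantees the frozen-node objective never decreases; a
    position where no improving step exists keeps its previous value.
    """
    lo, hi = np.log(bounds[0]), np.log(bounds[1])
    u, v = np.log(a), np.log(b)
    a0, b0, M, S1, S2, N = consts
    F = _gamma_objective(np.exp(u), np.exp(v), consts, False, quad_order)
    # Per-position active set: once a position's objective stops improving it
    # is frozen (its objective is fixed within this run, so a stall is
    # final).  All evaluations are restricted to the active subset.
    active = np.ones(u.shape, dtype=bool)
    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        sub = (a0, b0, M[idx], S1[idx], S2[idx], N)
        aa, bb = np.exp(u[idx]), np.exp(v[idx])
        Fcur, (Fa, Fb), (Faa, Fab, Fbb) = _gamma_objective(aa, bb, sub, True, quad_order)
        gu, gv = aa * Fa, bb * Fb
        Huu = aa * aa * Faa + gu
        Huv = aa * bb * Fab
        Hvv = bb * bb * Fbb + gv
        det = Huu * Hvv - Huv * Huv
        concave = (Huu < 0) & (det > 0)
        scale = np.abs(Huu) + np.abs(Hvv) + np.abs(Huv) + 1e-12
        du = np.where(concave, -(Hvv * gu - Huv * gv) / np.where(det != 0, det, 1.0), gu / scale)
        dv = np.where(concave, -(-Huv * gu + Huu * gv) / np.where(det != 0, det, 1.0), gv / scale)
        norm = np.maximum(np.abs(du), np.abs(dv))
        shrink = np.where(norm > 2.0, 2.0 / np.maximum(norm, 1e-300), 1.0)
        du *= shrink
        dv *= shrink

        u_sub, v_sub = u[idx].copy(), v[idx].copy()
        F_new = Fcur.copy()
        t = np.ones(idx.size)
        rem = np.arange(idx.size)
        for _bt in range(10):
            if rem.size == 0:
                break
            ut = np.clip(u[idx][rem] + t[rem] * du[rem], lo, hi)
            vt = np.clip(v[idx][rem] + t[rem] * dv[rem], lo, hi)
            sub2 = (a0, b0, M[idx][rem], S1[idx][rem], S2[idx][rem], N)
            Ft = _gamma_objective(np.exp(ut), np.exp(vt), sub2, False, quad_order)
            ok = np.isfinite(Ft) & (Ft >= Fcur[rem])
            hit = rem[ok]
            u_sub[hit] = ut[ok]
            v_sub[hit] = vt[ok]
            F_new[hit] = Ft[ok]
            rem = rem[~ok]
            t[rem] *= 0.5
        improvement = F_new - Fcur
        u[idx], v[idx], F[idx] = u_sub, v_sub, F_new
        stalled = improvement <= 1e-10 * (1.0 + np.abs(F_new))
        active[idx[stalled]] = False
    return np.exp(u), np.exp(v), F


def _update_gamma(counts, delta, gamma, params, config):
    """Newton ascent on q(mu_j) for all positions, with node refresh."""
    elog_t, elog_1mt = _beta_elog(delta[:, :, 0], delta[:, :, 1])
    S1 = elog_t.sum(axis=1)
    S2 = elog_1mt.sum(axis=1)
    a0, b0 = beta_shapes_from_mean_precision(params.mu0, params.M0)
    bounds = config.optimizer_bounds["gamma"]
    a, b = gamma[:, 0].copy(), gamma[:, 1].copy()
    consts = (a0, b0, params.M, S1, S2, counts.N)
    a_new, b_new, F = _newton_2d(a, b, consts, bounds, config.newton_max_iter, config.quad_order)
    bad = ~np.isfinite(F)
    if bad.any():
        idx = np.flatnonzero(bad)
        logger.warning(
            "gamma update non-finite at %d position(s) (e.g. index %d); "
            "keeping previous values",
            idx.size,
            idx[0],
        )
        a_new[bad], b_new[bad] = a[bad], b[bad]
    return np.stack([a_new, b_new], axis=-1)


def e_step(counts, vparams, params, config=None):
    """Maximize the ELBO over the variational parameters (gamma, delta).

    Cycles the exact delta update and the Newton gamma update; each block
    step is monotone, so ELBO(new) >= ELBO(old) up to quadrature round-off.
    """
    config = config or FitConfig()
    gamma = vparams.gamma.copy()
    delta = vparams.delta.copy()
    for cycle in range(config.e_step_cycles):
        previous = gamma
        delta = _update_delta(counts, gamma, params, config.optimizer_bounds["delta"])
        gamma = _update_gamma(counts, delta, gamma, params, config)
        # Later cycles only help while gamma is still moving appreciably.
        if cycle + 1 < config.e_step_cycles:
            rel = np.max(np.abs(gamma - previous) / previous)
            if rel < 1e-4:
                delta = _update_delta(
                    counts, gamma, params, config.optimizer_bounds["delta"]
                )
                break
    return VariationalParams(gamma=gamma, delta=delta)


# ---------------------------------------------------------------------------
# M-step
# ---------------------------------------------------------------------------


def _mu_prior_objective(mu0, M0, sum_T1, sum_T2, J):
    a0 = mu0 * M0
    b0 = (1.0 - mu0) * M0
    return a0 * sum_T1 + b0 * sum_T2 - J * special.betaln(a0, b0)


def _update_mu0_M0(gamma, params, config):
    """Maximize the E_q[log Beta(mu_j | mu0, M0)] terms over (mu0, M0)."""
    T1, T2 = _beta_elog(gamma[:, 0], gamma[:, 1])
    sum_T1, sum_T2 = float(T1.sum()), float(T2.sum())
    J = gamma.shape[0]
    mu_lo, mu_hi = config.optimizer_bounds["mu0"]
    M_lo, M_hi = config.optimizer_bounds["M0"]
    f_old = _mu_prior_objective(params.mu0, params.M0, sum_T1, sum_T2, J)

    if config.fix_M0 is not None:
        M0 = float(config.fix_M0)

        def neg(mu0):
            return -_mu_prior_objective(mu0, M0, sum_T1, sum_T2, J)

        res = optimize.minimize_scalar(
            neg, bounds=(mu_lo, mu_hi), method="bounded", options={"xatol": 1e-12}
        )
        mu0 = float(res.x)
        if _mu_prior_objective(mu0, M0, sum_T1, sum_T2, J) < _mu_prior_objective(
            params.mu0, M0, sum_T1, sum_T2, J
        ):
            mu0 = params.mu0
        return mu0, M0

    def neg(x):
        mu0, logM0 = x
        M0 = np.exp(logM0)
        a0, b0 = mu0 * M0, (1.0 - mu0) * M0
        val = a0 * sum_T1 + b0 * sum_T2 - J * special.betaln(a0, b0)
        pa, pb, pM = special.digamma(a0), special.digamma(b0), special.digamma(M0)
        d_mu0 = M0 * (sum_T1 - sum_T2) - J * M0 * (pa - pb)
        d_logM0 = M0 * (
            mu0 * sum_T1 + (1.0 - mu0) * sum_T2 - J * (mu0 * pa + (1.0 - mu0) * pb - pM)
        )
        return -val, -np.array([d_mu0, d_logM0])

    res = optimize.minimize(
        neg,
        x0=np.array([params.mu0, np.log(params.M0)]),
        jac=True,
        method="L-BFGS-B",
        bounds=[(mu_lo, mu_hi), (np.log(M_lo), np.log(M_hi))],
    )
    mu0, M0 = float(res.x[0]), float(np.exp(res.x[1]))
    if _mu_prior_objective(mu0, M0, sum_T1, sum_T2, J) < f_old:
        logger.warning("(mu0, M0) update did not improve; keeping previous values")
        return params.mu0, params.M0
    return mu0, M0


def _update_M(counts, vparams, params, config):
    """Vectorized 1-d Newton ascent on each local precision M_j (log scale)."""
    gamma, delta = vparams.gamma, vparams.delta
    elog_t, elog_1mt = _beta_elog(delta[:, :, 0], delta[:, :, 1])
    S1, S2 = elog_t.sum(axis=1), elog_1mt.sum(axis=1)
    e_mu = gamma[:, 0] / (gamma[:, 0] + gamma[:, 1])
    A = e_mu * S1 + (1.0 - e_mu) * S2
    N = counts.N
    nodes = _quad_nodes(gamma[:, 0], gamma[:, 1], config.quad_order)
    mu, mu1m = nodes.mu, nodes.mu1m
    Q = _quad_density(gamma[:, 0], gamma[:, 1], nodes)
    lo, hi = np.log(config.optimizer_bounds["M"][0]), np.log(config.optimizer_bounds["M"][1])

    def F_sub(M, rows):
        Mc = M[:, None]
        g = (
            special.gammaln(Mc)
            - special.gammaln(mu[rows] * Mc)
            - special.gammaln(mu1m[rows] * Mc)
        )
        return M * A[rows] + N * np.sum(Q[rows] * g, axis=1)

    wv = np.log(params.M.copy())
    F = F_sub(np.exp(wv), slice(None))
    active = np.ones(wv.shape, dtype=bool)
    for _ in range(config.newton_max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        M = np.exp(wv[idx])
        Mc = M[:, None]
        mu_s, mu1m_s, Q_s = mu[idx], mu1m[idx], Q[idx]
        d1 = A[idx] + N * np.sum(
            Q_s
            * (
                special.digamma(Mc)
                - mu_s * special.digamma(mu_s * Mc)
                - mu1m_s * special.digamma(mu1m_s * Mc)
            ),
            axis=1,
        )
        d2 = N * np.sum(
            Q_s
            * (
                _trigamma(Mc)
                - mu_s**2 * _trigamma(mu_s * Mc)
                - mu1m_s**2 * _trigamma(mu1m_s * Mc)
            ),
            axis=1,
        )
        gw = M * d1
        Hww = M * M * d2 + gw
        dw = np.where(Hww < 0, -gw / np.where(Hww != 0, Hww, 1.0), gw / (np.abs(Hww) + np.abs(gw) + 1e-12))
        dw = np.clip(dw, -2.0, 2.0)
        Fcur = F[idx]
        w_sub = wv[idx].copy()
        F_new = Fcur.copy()
        t = np.ones(idx.size)
        rem = np.arange(idx.size)
        for _bt in range(10):
            if rem.size == 0:
                break
            wt = np.clip(wv[idx][rem] + t[rem] * dw[rem], lo, hi)
            Ft = F_sub(np.exp(wt), idx[rem])
            ok = np.isfinite(Ft) & (Ft >= Fcur[rem])
            hit = rem[ok]
            w_sub[hit] = wt[ok]
            F_new[hit] = Ft[ok]
            rem = rem[~ok]
            t[rem] *= 0.5
        improvement = F_new - Fcur
        wv[idx], F[idx] = w_sub, F_new
        stalled = improvement <= 1e-10 * (1.0 + np.abs(F_new))
        active[idx[stalled]] = False
    return np.exp(wv)


def m_step(counts, vparams, params, config=None):
    """Maximize the ELBO over the model parameters phi = (mu0, M0, M)."""
    config = config or FitConfig()
    mu0, M0 = _update_mu0_M0(vparams.gamma, params, config)
    intermediate = ModelParams(mu0=mu0, M0=M0, M=params.M)
    M = _update_M(counts, vparams, intermediate, config)
    return ModelParams(mu0=mu0, M0=M0, M=M)


# ---------------------------------------------------------------------------
# Full fit
# ---------------------------------------------------------------------------


def fit(counts: ReadCountMatrix, config: FitConfig | None = None) -> ModelEstimate:
    """Run variational EM to convergence of the ELBO.

    Records the ELBO after every full (E-step + M-step) iteration and stops
    when the relative change drops below ``config.elbo_rel_tol`` or
    ``config.max_iterations`` is reached.
    """
    if not isinstance(counts, ReadCountMatrix):
        raise InputError("counts must be a ReadCountMatrix")
    config = config or FitConfig()
    params, vparams = initialize(counts)
    # Project the initialization into the configured box bounds.
    b = config.optimizer_bounds
    params = ModelParams(
        mu0=float(np.clip(params.mu0, *b["mu0"])),
        M0=float(np.clip(params.M0, *b["M0"])),
        M=np.clip(params.M, *b["M"]),
    )
    vparams = VariationalParams(
        gamma=np.clip(vparams.gamma, *b["gamma"]),
        delta=np.clip(vparams.delta, *b["delta"]),
    )
    if config.fix_M0 is not None:
        params = ModelParams(mu0=params.mu0, M0=float(config.fix_M0), M=params.M)

    trace: list[float] = []
    prev = elbo(counts, vparams, params, config.quad_order)
    converged = False
    for _ in range(config.max_iterations):
        vparams = e_step(counts, vparams, params, config)
        params = m_step(counts, vparams, params, config)
        current = elbo(counts, vparams, params, config.quad_order)
        trace.append(current)
        if abs(current - prev) < config.elbo_rel_tol * abs(prev):
            converged = True
            prev = current
            break
        prev = current

    nraf = vparams.gamma[:, 0] / (vparams.gamma[:, 0] + vparams.gamma[:, 1])
    return ModelEstimate(
        params=params,
        vparams=vparams,
        elbo_trace=trace,
        converged=converged,
        nraf=nraf,
        positions=counts.positions.copy(),
        reference_base=counts.reference_base.copy(),
        chrom=counts.chrom,
    )
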