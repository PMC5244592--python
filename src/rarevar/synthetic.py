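"""Simulators with the statistical structure the model assumes.

``simulate_from_model`` draws directly from the generative process
(mu_j ~ Beta(mu0, M0); theta_ji ~ Beta(mu_j, M_j); r_ji ~ Binomial) and
returns the latent draws for parameter-recovery tests.

``simulate_mixture_experiment`` emulates an in-vitro titration experiment:
two short synthetic sequences, one carrying variant loci, mixed at a defined
non-reference allele frequency and sequenced in replicates over a wide range
of depths.  The control sample sees sequencing error only; the case sample
additionally carries the variant base at the designated loci.  Position-
specific error rates are properties of the sequence context, so the case and
control share the latent per-position error rate mu_j; replicate-level rates
and reads are drawn independently per sample.

Defaults: 400 positions, 14 variant loci, 6 replicates per sample, error
rate mu0 = 0.5% with global precision 100 and local precision 1e4 —
realistic Illumina-class noise, consistent with a 0.1% NRAF being resolvable
only at tens of thousands of reads of depth.
"""

from __future__ import annotations

import numpy as np

from .model import BASES, InputError, ModelParams, ReadCountMatrix

__all__ = [
    "simulate_from_model",
    "simulate_mixture_experiment",
    "score_calls",
]


def _split_counts(rng, r, nonref_idx, p=None):
    """Distribute non-reference read counts over the three non-ref bases."""
    if p is None:
        p = np.full(3, 1.0 / 3.0)
    return rng.multinomial(r, p)


def simulate_from_model(params: ModelParams, depths, seed):
    """Draw counts (and the latent rates) from the hierarchical model.

    Parameters
    ----------
    params : ModelParams with M of length J.
    depths : (J, N) array of total read counts per position and replicate.
    seed : integer seed; identical seeds give identical output.

    Returns
    -------
    (ReadCountMatrix, mu, theta) — the observed counts plus the latent
    position rates (J,) and replicate rates (J, N).
    """
    depths = np.asarray(depths, dtype=np.int64)
    if depths.ndim != 2:
        raise InputError("depths must be a (J, N) array")
    if np.any(depths < 0):
        raise InputError("depths must be non-negative")
    J, N = depths.shape
    if params.M.shape[0] != J:
        raise InputError("params.M length must match depths")
    rng = np.random.default_rng(seed)

    mu = rng.beta(params.mu0 * params.M0, (1.0 - params.mu0) * params.M0, J)
    mu = np.clip(mu, 1e-12, 1.0 - 1e-12)
    theta = rng.beta(
        (mu * params.M)[:, None], ((1.0 - mu) * params.M)[:, None], (J, N)
    )
    theta = np.clip(theta, 0.0, 1.0)
    r = rng.binomial(depths, theta)

    reference_base = rng.choice(list(BASES), J)
    lut = {b: k for k, b in enumerate(BASES)}
    base_counts = np.zeros((J, N, 4), dtype=np.int64)
    for j in range(J):
        ref_k = lut[reference_base[j]]
        nonref = [k for k in range(4) if k != ref_k]
        for i in range(N):
            split = _split_counts(rng, r[j, i], nonref)
            base_counts[j, i, nonref] = split
            base_counts[j, i, ref_k] = depths[j, i] - r[j, i]
    counts = ReadCountMatrix.from_base_counts(
        positions=np.arange(1, J + 1),
        reference_base=reference_base,
        base_counts=base_counts,
        chrom="sim",
    )
    return counts, mu, theta


def simulate_mixture_experiment(
    nraf,
    median_depth,
    seed,
    J=400,
    n_variants=14,
    N=6,
    error_mu0=0.005,
    error_M0=100.0,
    M_j=1e4,
    variant_positions=None,
):
    """Simulate a case/control titration pair with designated variant loci.

    The control is pure sequencing error; the case is identical except at
    the variant loci, where the replicate-level non-reference rate is
    inflated to ``nraf + (1 - nraf) * theta_err`` before binomial sampling
    (a mixture at the rate level, keeping the data inside the model family).
    Per-replicate depths are log-normally jittered around ``median_depth``
    (sd 0.25 in log10).  Variant reads carry one designated non-reference
    base per locus; error reads split uniformly over the three non-reference
    bases.

    Returns (case ReadCountMatrix, control ReadCountMatrix, truth), where
    ``truth`` is the set of 1-based variant positions.
    """
    if not (0.0 < nraf <= 1.0):
        raise InputError("nraf must lie in (0, 1]")
    if median_depth < 1:
        raise InputError("median_depth must be >= 1")
    if not (0 <= n_variants <= J):
        raise InputError("n_variants must lie in [0, J]")
    rng = np.random.default_rng(seed)
    lut = {b: k for k, b in enumerate(BASES)}

    reference_base = rng.choice(list(BASES), J)
    if variant_positions is None:
        var_idx = np.sort(rng.choice(J, n_variants, replace=False))
    else:
        var_idx = np.sort(np.asarray(list(variant_positions), dtype=np.int64)) - 1
        if np.any(var_idx < 0) or np.any(var_idx >= J):
            raise InputError("variant_positions out of range")
    is_variant = np.zeros(J, dtype=bool)
    is_variant[var_idx] = True
    # One designated variant base per locus, distinct from the reference.
    variant_base_idx = np.full(J, -1, dtype=np.int64)
    for j in var_idx:
        choices = [k for k in range(4) if k != lut[reference_base[j]]]
        variant_base_idx[j] = rng.choice(choices)

    # Position-specific error rate: shared between samples (a property of
    # the sequence context, identical for the two in-vitro libraries).
    mu_err = np.clip(
        rng.beta(error_mu0 * error_M0, (1.0 - error_mu0) * error_M0, J),
        1e-12,
        1.0 - 1e-12,
    )

    def draw_sample(with_variants):
        n = np.maximum(
            1, np.round(median_depth * 10 ** rng.normal(0.0, 0.25, (J, N)))
        ).astype(np.int64)
        theta_err = np.clip(
            rng.beta((mu_err * M_j)[:, None], ((1.0 - mu_err) * M_j)[:, None], (J, N)),
            0.0,
            1.0,
        )
        theta = theta_err.copy()
        if with_variants and is_variant.any():
            theta[is_variant] = nraf + (1.0 - nraf) * theta_err[is_variant]
        r = rng.binomial(n, theta)
        base_counts = np.zeros((J, N, 4), dtype=np.int64)
        for j in range(J):
            ref_k = lut[reference_base[j]]
            nonref = [k for k in range(4) if k != ref_k]
            variant_here = with_variants and is_variant[j]
            for i in range(N):
                if variant_here and r[j, i] > 0:
                    # Each non-reference read is a variant-strand read with
                    # probability nraf/theta, otherwise a uniformly split
                    # error read (the variant base also receives error).
                    p_variant = nraf / theta[j, i]
                    v = rng.binomial(r[j, i], p_variant)
                    split = _split_counts(rng, r[j, i] - v, nonref)
                    base_counts[j, i, nonref] = split
                    base_counts[j, i, variant_base_idx[j]] += v
                else:
                    split = _split_counts(rng, r[j, i], nonref)
                    base_counts[j, i, nonref] = split
                base_counts[j, i, ref_k] = n[j, i] - r[j, i]
        return ReadCountMatrix.from_base_counts(
            positions=np.arange(1, J + 1),
            reference_base=reference_base,
            base_counts=base_counts,
            chrom="sim",
        )

    control = draw_sample(with_variants=False)
    case = draw_sample(with_variants=True)
    truth = set(int(p) for p in (var_idx + 1))
    return case, control, truth


def score_calls(calls, truth, J):
    """Sensitivity and specificity of a call set against truth positions.

    ``sensitivity = |called ∩ truth| / |truth|``;
    ``specificity = 1 - |called \\ truth| / (J - |truth|)``.
    """
    truth = set(int(p) for p in truth)
    if not truth:
        raise InputError("truth is empty; sensitivity undefined")
    if len(truth) >= J:
        raise InputError("J must exceed the number of true variants")
    called = {c.position for c in calls if getattr(c, "called", False)}
    tp = len(called & truth)
    fp = len(called - truth)
    sensitivity = tp / len(truth)
    specificity = 1.0 - fp / (J - len(truth))
    return sensitivity, specificity
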