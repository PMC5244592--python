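# Methods

## Model

`rarevar` estimates, at every genomic position `j`, the non-reference allele
frequency (NRAF) from the read counts of `N` sequencing replicates, and calls
single-nucleotide variants by comparing a case sample against a control
sample position by position. The hierarchical Beta-Binomial model is

```
mu_j        ~ Beta(mu0, M0)        position-specific non-reference read rate
theta_ji    ~ Beta(mu_j, M_j)      replicate-level rate at position j
r_ji | n_ji ~ Binomial(n_ji, theta_ji)
```

written in mean/precision form: `Beta(m, M)` has shapes `(mM, (1-m)M)`.
`mu0` is the global error rate, `M0` the global precision tying positions
together (small `M0` = heterogeneous error landscape), and `M_j` a local
precision describing replicate-to-replicate variation of the rate. The
hierarchy lets positions with weak data borrow strength from the rest of the
sequence, which is what makes rare-variant detection at low depth possible
at all.

## Variational EM

The posterior `p(mu, theta | r, n; phi)` is intractable; it is approximated
by a fully factorized family `q(mu) q(theta)` with per-position Beta factors
`q(mu_j) = Beta(gamma_j1, gamma_j2)` and per-replicate factors
`q(theta_ji) = Beta(delta_ji1, delta_ji2)`. Inference maximizes the evidence
lower bound (ELBO) by coordinate ascent, alternating

* **E-step** — `delta` in closed form (the log Beta density
  `log Beta(theta | mu, M)` is linear in `mu`, so the mean-field optimum is
  the conjugate update `delta = (r + M E[mu], n - r + M(1 - E[mu]))`,
  exactly); `gamma` by a damped Newton ascent with analytic gradient and
  Hessian, vectorized across positions;
* **M-step** — `(mu0, M0)` jointly by L-BFGS-B on the analytic
  (digamma-based) prior cross-entropy term; each `M_j` by a vectorized 1-d
  Newton ascent in `log M`.

Every block update either is an exact maximizer or uses a backtracking line
search, so the ELBO is non-decreasing up to quadrature round-off
(contractual slack `1e-6 |ELBO|`). All per-position work is elementwise, so
permuting positions permutes the result; the fit is fully deterministic.

The model is non-conjugate in one place: the expected log-normalizer
`E_q[log(Gamma(M) / (Gamma(mu M) Gamma((1-mu) M)))]` under `q(mu)` has no
closed form and is integrated numerically (below). It is needed by the
`gamma` and `M` updates and by the ELBO itself.

### Quadrature

A fixed Gauss-Legendre rule on (0, 1) cannot represent this integral: at
high read depth the variational posteriors concentrate (total shape 1e4-1e6,
means near 0.005), and every node of a fixed rule misses the mass. The
integral is instead computed in **logit space** on a per-position window:

* window = the Beta 1e-9 .. 1-1e-9 quantiles (via `betaincinv`) when either
  shape is below 4, else the cheaper logit-normal approximation
  `psi(a) - psi(b) +/- 8.5 sd`, `sd^2 = psi1(a) + psi1(b)` (floored at
  `23/shape` for the exponential tails);
* two Gauss-Legendre panels of `order/2` nodes split at the median;
* weights self-normalized to sum to one, which cancels the first-order
  effect of window-placement error (without it, a relative mass defect
  epsilon biases the result by `epsilon * |E[g]|` — catastrophic when the
  integrand is of order `M`).

At the default order 50 this reproduces the two closed forms available from
Raabe's formula (`E[.] = -log 2pi` for `q = Beta(1,1), M = 1`; `1 - log 2pi`
for `M = 2`) to ~4e-8, and matches adaptive quadrature to <1e-6 relative
over wide shape ranges. Known limitation: for extremely skewed factors
(one shape < 1 with the other > 1e4) accuracy degrades to ~3e-4 relative;
such factors arise only transiently in fits.

Tail quantities at the nodes (`1 - mu`, `log mu`, `log(1 - mu)`) are
evaluated from the logit coordinate (`expit(-t)`, `log_expit`) so that
nothing cancels against 1 in double precision; this also makes the
shape-swap symmetry `E(a,b) = E(b,a)` hold to round-off.

## Hypothesis testing

After fitting case and control independently, each `q(mu_j)` is
approximated by a Gaussian matched to its Beta mean and variance; the
case-control difference is then Gaussian and

```
Pr(mu_case - mu_ctrl >= tau | data)        (one-sided, default tau = 0)
Pr(|mu_case - mu_ctrl| >= tau | data)      (two-sided, requires tau > 0)
```

is thresholded at `1 - alpha/2` to flag **provisional** variants. The
threshold comparison is done on the complementary tail probability computed
directly from the normal CDF, because the probability itself saturates at
1.0 in double precision for well-separated positions (which would make the
high-specificity end of an ROC sweep inoperative). The two-sided test with
`tau = 0` is identically 1 and is rejected as a configuration error rather
than silently flagging everything.

A provisional position is **called** only if the case sample's non-reference
base counts, pooled across replicates, reject uniformity over the three
non-reference bases in a Pearson chi-square test (2 degrees of freedom,
default size 0.05). Uniform spread is the signature of indiscriminate
sequencing error; a real variant concentrates on one alternative base.
Design choices the literature leaves open, decided here: counts are pooled
across replicates before testing (maximizes power, matches the
single-statistic description); only the case sample feeds the test (the
variant signal lives there); positions with fewer than 6 pooled
non-reference reads still use the chi-square p-value but log a low-count
warning; no multiple-testing correction is applied (per-position
thresholding).

## Optimizer bounds and degenerate optima

Default box bounds: `mu0` in `[1e-6, 1-1e-6]`, `M0` in `[1e-3, 1e8]`,
`M_j` in `[1, 1e8]`, all Beta shape parameters in `[1e-3, 1e10]`.

The lower bound `M_j >= 1` is deliberate. For `M < 1` the replicate-rate
prior `Beta(mu M, (1-mu) M)` has both shapes below 1 — a bimodal density
with atoms at 0 and 1 — and the marginal likelihood can use it as a
zero-inflation switch: `p(r_i = 0) -> 1 - mu` regardless of depth. On
zero-heavy low-depth data this degenerate mode has genuinely higher
likelihood than any rate-model fit, the coordinate ascent walks into it,
`theta` decouples from `mu`, and every position becomes data-blind (even
loci where all reads are variant). Excluding `M < 1` removes the atomic
regime while still allowing rate dispersion far beyond anything a sequencer
produces.

A related benign degeneracy remains: on data with no detectable
position-to-position rate differences (a control sample at low depth), the
ELBO keeps creeping while `M0` grows toward a prior-collapse plateau —
statistically the data cannot exclude "all positions identical". Such fits
may exhaust `max_iterations` (default 100) with `converged = False`; the
collapse produces no variant calls and is harmless downstream, but the flag
is reported honestly.

### Initialization

Method of moments with pseudocount 1: `delta = (r + 1, n - r + 1)`;
`gamma` from the mean and variance of the smoothed per-replicate rates;
`mu0` = median pooled rate (clipped to the `mu0` box); `M0`, `M_j` from
inverted variances clipped to `[1e-3, 1e6]`. The replicate variance is
floored at the **binomial sampling variance** `m(1-m) mean(1/(n+2))`, not
at a token epsilon: observed scatter below sampling noise carries no
evidence about rate dispersion, and inverting it yields precisions of 1e6
that the data can never move (all-zero and all-variant positions would
otherwise start data-blind).

## Synthetic data

`simulate_mixture_experiment` emulates an in-vitro titration: `J = 400`
positions, 14 variant loci, 6 replicates per sample, defined NRAF, depths
log-normally jittered (sd 0.25 in log10) around a target median. Error
parameters default to `mu0 = 0.005`, `M0 = 100`, `M_j = 1e4` — Illumina-
class noise (~0.5% error) consistent with 0.1% NRAF being resolvable only
at tens of thousands of reads. The per-position error rate `mu_j` is shared
between case and control (sequence context is a property of the position,
identical for two libraries of the same construct); replicate rates and
reads are independent draws. Case variants inflate the latent rate to
`nraf + (1 - nraf) theta_err` before binomial sampling, keeping the data
inside the model family; variant reads carry one designated alternative
base, error reads split uniformly over the three non-reference bases.

What a green simulation test does establish: the full pipeline reproduces
the published sensitivity/specificity operating points under the model's
own noise assumptions at the stated design (positions, loci, replicates,
depths). What it does not: robustness to alignment artifacts, strand bias,
indel contamination, batch effects between case and control libraries, or
error-rate heterogeneity beyond the Beta hierarchy — none of which the
generator emulates.

## Null-test design

Type-I behaviour is checked on case/control pairs simulated with **zero
variant loci and shared position effects**. With independently drawn
`mu_j` per sample the true difference is nonzero almost surely and a
calibrated posterior rightly flags it — a "false-positive rate" is only
meaningful when the null difference is exactly zero, which requires the
shared-`mu_j` design.

## Defaults worth knowing

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.05 | posterior-difference test size; provisional at `1 - alpha/2` |
| `tau` | 0 | effect-size threshold on the NRAF difference |
| `chi2_alpha` | 0.05 | promotion-test size |
| `quad_order` | 50 | total Gauss-Legendre nodes (two panels) |
| `elbo_rel_tol` | 1e-5 | relative ELBO change declaring convergence |
| `max_iterations` | 100 | EM iteration cap |
| `fix_M0` | unset | pin the global precision (sensitivity analysis) |

The EM stopping rule, iteration cap and initialization are this package's
declared defaults — the upstream method description leaves them open.
`seed` in `FitConfig` is reserved for randomized restarts; the default
algorithm has no randomness.
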