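# rarevar

Rare single-nucleotide variant (SNV) calling from deep, replicated
sequencing data. `rarevar` is for experiments where the variant allele is a
small fraction of a heterogeneous DNA pool — viral quasispecies, tumor
subclones, directed-evolution time courses — and the question is whether
the non-reference allele frequency (NRAF) at a position truly differs
between a case sample and a matched control, or is just sequencing error.

## Model

Read counts are modeled hierarchically with Beta-Binomial layers, written
in mean/precision form (`Beta(m, M)` has shapes `(mM, (1-m)M)`):

```
mu_j        ~ Beta(mu0, M0)       position-specific non-reference rate
theta_ji    ~ Beta(mu_j, M_j)     rate at position j in replicate i
r_ji | n_ji ~ Binomial(n_ji, theta_ji)
```

`mu0` is the global error rate, `M0` ties positions together, and `M_j`
captures replicate-to-replicate variation. The posterior over `(mu, theta)`
is approximated with a factorized Beta variational family, fitted by a
coordinate-ascent variational EM that maximizes the evidence lower bound
(ELBO); the one non-conjugate integral — the expected log-Beta normalizer
under `q(mu_j)` — is computed by adaptive-window Gauss-Legendre quadrature
in logit space.

A position is called a variant in two stages: it is *provisional* when the
moment-matched Gaussian posterior of the case-control difference gives
`Pr(mu_case - mu_ctrl >= tau) >= 1 - alpha/2`, and *called* when the case
sample's pooled non-reference base counts additionally reject uniformity in
a chi-square test (uniform spread over the three non-reference bases is the
signature of indiscriminate error, not a variant).

See `docs/methods.md` for the full model, the numerical design and the
known limitations.

## Worked example

Simulate an in-vitro titration (400 positions, 14 variant loci at 100%
NRAF, 6 replicates per sample at ~30x), fit both samples and test:

```
rarevar simulate --nraf 1.0 --depth 30 --seed 7 -o sim/
rarevar fit sim/case_rep*.dc.tsv    -o case.est.json
rarevar fit sim/control_rep*.dc.tsv -o control.est.json
rarevar test --case case.est.json --control control.est.json \
    $(printf -- '--case-depth-chart %s ' sim/case_rep*.dc.tsv) \
    -o calls.vcf --report report.tsv
```

which logs

```
rarevar INFO: fit 400 positions x 6 replicates: ELBO -1933.4, NOT converged, mu0=0.0638 M0=4.18
rarevar INFO: fit 400 positions x 6 replicates: ELBO -938.818, NOT converged, mu0=0.0101 M0=9.18e+04
rarevar INFO: 15 called variants of 400 positions
```

The case fit lands on a small global precision `M0 = 4.18` — the 14
near-100% loci make the position landscape highly heterogeneous — and its
`mu0` averages the error floor with those loci. All 14 true loci appear in
`calls.vcf` (plus, at this seed, one false positive among the 386 null
positions), each record carrying the case/control NRAF estimates, posterior
difference probability and chi-square p-value in INFO. ("NOT converged" on
a control-like sample is expected and benign: with no detectable position
differences, the ELBO creeps while the prior tightens; the calls are
unaffected — see `docs/methods.md`.)

The same pipeline is available as a library:

```python
from rarevar import FitConfig, TestConfig, call_variants, fit
from rarevar import simulate_mixture_experiment, score_calls

case, control, truth = simulate_mixture_experiment(1.0, 30, seed=7)
calls = call_variants(fit(case), fit(control), case, TestConfig())
print(score_calls(calls, truth, case.J))   # (1.0, 0.9974093264248705)
```

Real data enter through `rarevar depthchart` (samtools text pileup ->
per-replicate depth-chart tables) or any tab-delimited table with columns
`chrom pos ref A C G T`.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the full pipeline from scratch on a simulated titration (100% NRAF
at ~30x median depth), prints the resulting sensitivity/specificity
operating point, and writes the JSON report to `--out`. The heavier checks
— titration operating points across NRAF and depth, evidence-bound and
closed-form quadrature oracles, ELBO monotonicity, posterior agreement,
parameter recovery, null type-I control — live in `tests/test_acceptance.py`.
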