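# maxerlb

Tools for the **Max Erlang Binomial (MaxErlB)** compound lifetime
distribution: the law of the longest-lived of a *random* number of
identical components.

A parallel system has `Z` working components, where `Z` follows a
zero-truncated binomial law `Binom*(n, p)` (at least one component is
always present), and each component lifetime `X_i` is Erlang
distributed, `X_i ~ Erlang(k, λ)`. The system lifetime is

    U = max(X_1, …, X_Z),    Z ~ Binom*(n, p),  X_i ~ Erlang(k, λ) i.i.d.

Writing `S_k(x) = e^{-λx} Σ_{i<k} (λx)^i/i!` for the Erlang survival
function, `U ~ MaxErlB(k, λ, n, p)` has

    F(x) = [(1 − p·S_k(x))^n − (1−p)^n] / [1 − (1−p)^n]
    f(x) = n p λ^k x^{k−1} e^{−λx} (1 − p·S_k(x))^{n−1} / [(k−1)!(1 − (1−p)^n)]

For `k = 1` this is the complementary exponential binomial
distribution; for `n = 1` it is plain Erlang. The same construction
works for any power-series count family with series function `A(Θ)`
(truncated Poisson, logarithmic, geometric, Pascal, negative binomial —
all registered in `maxerlb.psd`): the compound cdf is
`A(Θ·F_Erl(x))/A(Θ)`.

The package provides, for biostatisticians and reliability analysts
modelling positive durations (remission times, failure times):

- **`maxerlb.distribution`** — cdf, pdf, survival, quantile; moments by
  survival-function quadrature, cross-checked against an exact
  inclusion–exclusion mixture formula;
- **`maxerlb.simulate`** — seeded, reproducible variate generation
  (rejection-sampled truncated-binomial count, then the maximum of that
  many inverse-transform Erlang draws);
- **`maxerlb.gof`** — Pearson chi-square concordance test with
  equal-probability binning from the model quantiles and standard
  merge-to-expected-count-≥5 handling;
- **`maxerlb.em`** — EM estimation of `(λ, p)` with `k, n` known,
  treating `Z` as the latent variable, plus a direct numerical
  maximum-likelihood cross-check;
- **`maxerlb.datasets`** — the classic 128 bladder-cancer remission
  times (months), bundled and checksummed.

## Worked example

Moments of `MaxErlB(2, 10, 3, 0.2)`:

```bash
$ maxerlb moments --k 2 --lam 10 --n 3 --p 0.2
{
  "params": { "k": 2, "lam": 10.0, "n": 3, "p": 0.2 },
  "mean": 0.21674256223437363,
  "variance": 0.021474898106051313
}
```

The mean 0.2167 time units is what a large simulation converges to:
each system lives a bit longer than a single Erlang(2, 10) component
(mean 0.2) because with probability `1 − P(Z=1) ≈ 0.21` the maximum is
taken over two or three components.

Simulate, then test concordance of the sample with its own generator:

```bash
maxerlb simulate --k 2 --lam 10 --n 3 --p 0.2 --m 10000 --seed 12 --out sample.txt
maxerlb gof --input sample.txt --k 2 --lam 10 --n 3 --p 0.2 --bins 12 --L 4
```

The report shows the Pearson statistic against the 5% critical value
14.067 at `df = (12 − 1) − 4 = 7`; the null (sample follows the stated
MaxErlB law) is retained when the statistic stays below it.

Fit the bundled remission data by EM (`k = 2`, `n = 3` fixed):

```bash
$ maxerlb demo-remission
{ ...
  "fit": { "lam_hat": 0.2135, "p_hat": 6.45e-06, "converged": true,
           "iterations": 83, "loglik": -426.797 },
  "gof": { "statistic": 18.812, "df": 9, "critical": 16.919, "reject": true }
}
```

(numbers abbreviated). The estimate is informative: EM pushes `p̂` to
the boundary, i.e. the latent count collapses to `Z ≡ 1` and the fit
degenerates to a plain Erlang with rate `k/x̄ ≈ 0.2135` per month —
for this long-tailed dataset (0.08 to 79.05 months) the
maximum-of-Erlangs structure with `k = 2, n = 3` adds nothing, and the
chi-square test rejects the fitted model at the 5% level. The
distribution is a better description of short-tailed parallel-system
lifetimes than of these remission times.

The same functionality is available as a library:

```python
from maxerlb import MaxErlBParams, sample_maxerlb, em_fit, EMConfig

params = MaxErlBParams(k=2, lam=1.0, n=3, p=0.5)
fit = em_fit(sample_maxerlb(params, 100_000, seed=3), EMConfig())
print(fit.lam, fit.p, fit.iterations)   # ≈1.002  ≈0.506  174
```

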