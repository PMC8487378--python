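# Methods

## Model

`MaxErlB(k, λ, n, p)` is the distribution of `max(X_1, …, X_Z)` where
the `X_i ~ Erlang(k, λ)` are i.i.d. component lifetimes and
`Z ~ Binom*(n, p)` is a zero-truncated binomial count independent of
them. The assumptions are therefore: identically distributed,
independent component lifetimes with a common integer shape `k` and
rate `λ`; a component count that is at least 1 and at most `n`; and
independence between count and lifetimes.

The truncated binomial is one member of the zero-truncated power-series
class, with pmf `a_z Θ^z / A(Θ)` on `z ≥ 1`. `maxerlb.psd` registers
six families (binomial, Poisson, logarithmic, geometric, Pascal,
negative binomial) with analytic `A`, `A′`, `A′′`, because the compound
construction and the E-step identity are generic in `A`:

- compound cdf: `A(Θ·F_Erl(x)) / A(Θ)`,
- compound pdf: `Θ f_Erl(x) A′(Θ·F_Erl(x)) / A(Θ)`,
- latent-count mean: `E[Z | X=x] = Θw·A′′(Θw)/A′(Θw) + 1`, `w = F_Erl(x)`.

Only the binomial family is exercised against known results; the
others are provided with pmf/series support (and property-tested for
internal consistency) but without samplers.

## Parameters

| parameter | meaning | domain | default in CLI |
|---|---|---|---|
| `k` | Erlang shape (number of exponential phases per component) | integer ≥ 1 | 2 |
| `λ` | Erlang rate | > 0, units 1/time | — |
| `n` | maximum number of components | integer ≥ 1 | 3 |
| `p` | per-component presence probability | (0, 1) | — |
| `Θ` | power parameter `p/(1−p)` of the truncated binomial | (0, ∞) | derived |

`k = 2, n = 3` are the defaults because they are the configuration of
the simulation and estimation studies this package reproduces.

## Numerical choices

- **cdf/pdf.** The Erlang cdf/survival is evaluated as the regularized
  incomplete gamma (`scipy.special.gammainc/gammaincc`), identical to
  the finite exponential sum but stable for any `λx`. `(1 − p·S)^n` is
  computed as `exp(n·log1p(−p·S))` so large `n` cannot underflow.
  `x ≤ 0` returns cdf 0 and pdf 0 (support convention) rather than
  raising, so mixed grids vectorize.
- **Quantile.** Bracketed Brent root-finding on the monotone cdf; the
  upper bracket starts at the Erlang scale `k/λ` and doubles until it
  covers the requested level; tolerance `xtol = 1e-14`.
- **Moments.** Ground truth is adaptive quadrature of
  `r x^{r−1} S(x)` on `[0, s] ∪ [s, 10s] ∪ [10s, cutoff]` with `s = k/λ`
  with the cutoff where the integrand underflows (`λx ≈ 700`). The
  independent cross-check is the exact mixture
  `Σ_z P(Z=z)·E[(max of z Erlangs)^r]`, the inner moment expanded by
  inclusion–exclusion and polynomial convolution of the Erlang survival
  polynomial; the two routes agree to ~1e-15 and the printed series
  form was deliberately not used (see Discrepancies).
- **Simulation.** Counts by rejection (draw `Binom(n, p)`, redraw
  zeros); Erlang variates as sums of `k` inverse-transform unit
  exponentials, so streams depend only on the PCG64 uniform stream and
  the integer seed. The production path pre-draws `n` Erlangs per
  accepted count and takes the maximum of the first `z` — i.i.d.-ness
  makes this distributionally identical to drawing exactly `z` — and
  a literal one-at-a-time loop is kept as `method="loop"` for
  cross-checks. Work is chunked at 2²⁰ draws to bound memory.
- **Chi-square test.** `r` equal-probability bins from the model
  quantiles (default `r = 12`); greedy merging of the adjacent pair
  with the smallest combined expected count until all expected counts
  reach 5 (the merge rule is the standard Pearson prescription; the
  source text does not state one). `df = (r_merged − 1) − L` with `L`
  supplied by the caller: reproductions of the published study pass
  `L = 4` for fidelity even though its parameters were fixed rather
  than estimated, while `demo-remission` uses `L = 2` (λ and p really
  are estimated there). With `L = 0` the statistic's null law is
  chi-square(r−1), which the suite verifies by simulation.
- **EM.** E-step by the closed form above. M-step: given expected
  counts the complete-data log-likelihood separates, so the rate solves
  its score `k m/λ − Σx_j + Σ(z_j−1)·x_j e^{−λx_j}(λx_j)^{k−1}/((k−1)!·F_Erl(x_j)) = 0`
  by Brent iteration (bracket `[λ_prev/2, 2λ_prev]`, widened
  geometrically if needed; inside the solver the Erlang cdf uses its
  finite exponential sum, exact for integer `k` and much cheaper than
  the incomplete gamma); the success probability solves the monotone
  truncated-binomial moment equation `n p/(1−(1−p)^n) = z̄`, with the
  raw score checked to vanish at the root. Stopping:
  `max(|Δλ|, |Δp|) ≤ ε` (default `1e-6`) or 1000 sweeps, both
  overridable; defaults start at `λ₀ = k/x̄`, `p₀ = 0.5`. A latent
  mean at 1 (or n) is a genuine boundary — `p̂ → 0` (or 1) — and is
  raised as a degenerate-M-step error with context. Observations are
  required to exceed 1e-12 to protect the log terms.
- **Direct MLE.** Nelder-Mead on `(log λ, logit p)`; used only as an
  independent check on EM (agreement within 1e-3 at m = 10⁴ is
  asserted).

## Synthetic data and what the tests show

All stochastic tests draw from the package's own simulator at the
study conditions — `MaxErlB(2, 10, 3, 0.2)` for the simulation/GOF
study and `MaxErlB(2, 1, 3, 0.5)` for EM recovery — with fixed seeds.
The generator produces exactly the model: no censoring, no measurement
error, no covariates, no heterogeneity across units. Passing tests
therefore demonstrate internal correctness (formula identities, sampler
fidelity, estimator consistency and unbiasedness at the simulated
sizes), not that real lifetime data follow this law; the bundled
remission dataset illustrates the opposite case, where the fit
degenerates (below).

Problem sizes: the acceptance layer runs the published sizes (mean at
m = 10⁷, variance at 10⁶, GOF at 10⁴ × 50 replicates, EM at 10⁶); the
unit layer uses 10³–10⁵ draws and, for the multi-seed bias check,
12 seeds at m = 2·10⁴, which already pins the seed-averaged estimates
to within 0.01 of the truth.

## Discrepancies and limitations

- **Closed-form moment series.** The printed single-sum expressions for
  the `k = 2` mean and variance evaluate (per their published table) to
  0.2197 and 0.0202 at `(2, 10, 3, 0.2)`, while the distribution's own
  cdf/pdf — by quadrature, by the exact mixture formula, and by
  simulation at m up to 10⁷ — give 0.21674 and 0.02147. The package
  treats the quadrature/mixture value as authoritative; the series as
  typeset appears to drop all but the leading term of an inner
  binomial-expansion integral.
- **Degrees-of-freedom convention.** Comparing the `r = 12`-bin
  statistic with fully known parameters against the 7-df critical value
  14.067 retains the null in only ≈77% of replicates (the statistic is
  chi-square(11); `P(χ²₁₁ < 14.067) ≈ 0.77`), not ≈95%. The package
  exposes `L` so users can apply the convention they need; the
  published convention is reproduced verbatim where that study is
  re-run.
- **Remission-time fit.** On the bladder-cancer dataset with
  `k = 2, n = 3`, EM converges to the `p → 0` boundary: the compound
  structure degenerates to a single Erlang component
  (`λ̂ = k/x̄ ≈ 0.2135`/month) and the chi-square test rejects the
  fitted model. The demo fits the data afresh rather than asserting
  any previously displayed overlay parameters.
- **Identifiability.** For `n = 1`, `p` drops out of the likelihood;
  the direct maximizer flags it as unidentified and EM raises a
  boundary error. Standard errors and censoring are out of scope.
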