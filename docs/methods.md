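# Methods

## Model and procedure

`corrdistort` classifies an unlabeled sample into one of two groups by the
distortion it induces in each group's Pearson correlation structure.

**Pretreatment.** Compositional count tables pass through four stages, each
row (sample) independently:

1. *Bayesian-multiplicative zero replacement* with the Bayes–Laplace prior:
   zeros in a row with total `n` over `m` parts become `(1/m)·m/(n+m)`, and
   nonzero entries are multiplicatively shrunk by one minus the total
   imputed mass, so ratios among nonzero parts are preserved. Rows of all
   zeros are rejected (`degenerate sample`) since the prior weights are
   undefined. Other priors from the zero-replacement literature are not
   implemented.
2. *Closure* to a constant row sum `k` (default 100).
3. *clr transform*: `log(part / geometric mean of the row's parts)`, with
   the geometric mean over the `m` parts of the sample. clr is invariant to
   closure and to any positive rescaling of a row.
4. *Column standardization* to mean 0, sample standard deviation 1
   (ddof = 1, consistent with the `1/(n−1)` correlation estimator).

Non-compositional data (the Gaussian simulations) receives stage 4 only;
log-ratio machinery is undefined for negative values and unnecessary for
unconstrained data.

**Rank-one correlation update.** Incorporating a sample `x_p` into a group
summarized by `(n_g, b, σ, S)` yields closed-form distorted statistics
(`b̃`, `σ̃`, `S̃`; see README for the formulas). The algebra is exact: at
`n_eff = n_g` the update equals the recomputed correlation of the stacked
matrix to machine precision, which the test suite checks against
`np.corrcoef` over random instances. The diagonal of `S̃` is exactly 1 for
every `n_eff` because `σ̃²` is precisely the sum of the three diagonal
contributions; `S̃` is not re-standardized in any way before being scored.

**Artificial dimensional reduction.** The group size is replaced by a
reduced count `n_red` in *all* weight quotients of the update (the mean
weights `n/(n+1)` and `1/(n+1)`, the variance weights `(n−1)/n` and `1/n`,
and the correlation weights `(n−1)/n` and `1/n`), while `b`, `σ` and `S`
always remain the full-group statistics. A partial substitution would break
the bookkeeping that makes the three correlation terms sum to a unit
diagonal. `n_red` sweeps the ladder `2, 2+Δn, …, n_max`; `n_red = 2` is the
lower limit below which the group's own structure would drop out of the
update entirely.

**Distortion metric and decision rule.** For each rung, `φ` compares the
spectral decompositions of `S` and `S̃` over the leading eigenpairs
explaining 100(1−α)% of variance: eigenvalue difference × principal angle,
weighted by the larger eigenvalue, summed over ranks up to the larger of
the two retained counts. The affinity `ψ = 1/max(|φ|, ε)` is averaged over
the ladder (a true mean over the rungs actually evaluated; both groups
share the ladder, so any common divisor leaves the decision unchanged) and
the sample goes to the group with the larger `ψ̄`. Exact ties predict
control and log a warning.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.05 | variance share discarded when selecting leading eigenpairs |
| `delta_n` | 1 | step of the artificial-dimension ladder |
| `n_max` | `auto` | top of the ladder; `auto` = min group size, rounded down so `(n_max−2)` is divisible by `delta_n` |
| `epsilon` | 1e-12 | guard for `1/|φ|` when a distortion is numerically zero |
| `closure_k` | 100 | closure constant (any positive value; clr removes it) |
| `compositional` | off for simulations | whether the log-ratio pretreatment applies |

Leave-one-out evaluation (`--loo`) removes the sample from its own group's
summary before scoring; the default is resubstitution, i.e. samples are
scored against the groups exactly as given.

## Synthetic data

The generator draws each group from a zero-mean multivariate Normal with
equicorrelation (compound-symmetry) covariance `(1−ρ)I + ρ11ᵀ` — unit
variances, constant pairwise correlation (defaults ρ_c = 0.1, ρ_v = 0.2),
sampled via the Cholesky factor of the generatrix under a seeded generator.
Group means and marginal scales are identical by construction, so the only
signal is the correlation structure — precisely what the distortion metric
probes. What this does *not* emulate about real OTU data: compositional
closure, sparsity/zero inflation, overdispersion, heavy-tailed abundance
distributions, and block- or network-structured (rather than uniform)
correlations. Passing simulation tests therefore demonstrate the
correctness of the computational pipeline under a clean correlation-shift
model, not field performance on sequencing data.

Monte-Carlo assessment stacks each simulated pair, classifies all `2n` rows
one-by-one against the two full-group summaries, and reports
`100·N/(2n)` averaged over replicates with its Monte-Carlo standard error.
The bundled study runs configurations (20,20), (80,40), (100,20), (120,20)
and (160,20) at 25 replicates each, a problem size chosen to give standard
errors near one percentage point.

## Numerical choices

- **Eigenvector sign.** `cos⁻¹(vᵀṽ)` is ill-defined because eigenvector
  sign is arbitrary; the inner product is taken in absolute value (the
  principal angle, in [0, π/2]), the only sign-invariant choice. Inner
  products are clamped to [0, 1] before `arccos` to absorb floating-point
  overshoot. Stored eigenvector columns are canonicalized so their
  largest-magnitude entry is positive.
- **Eigenpair matching** is by descending-eigenvalue rank. Under exactly or
  nearly repeated eigenvalues the solver's basis for the shared eigenspace
  is arbitrary, so rank-matched angles — and hence `φ` — are unstable
  there. Equicorrelation matrices are the worst case: their bulk eigenvalue
  has multiplicity m−1.
- **Component count** is the smallest `a` whose cumulative eigenvalue
  fraction reaches `1−α` (with a 1e-12 slack so exact boundaries such as
  the identity spectrum are not missed); `a` is computed separately for the
  reference and each distorted matrix from its own spectrum.
- **Batching.** All distorted correlation matrices for a batch of samples ×
  ladder rungs are built by broadcasting and eigendecomposed with one
  batched `eigh` call, chunked to keep the work array near 64 MB; the
  batched path is tested to agree with the scalar route to 1e-10.

## Known limitations

- The product form of `φ` annihilates eigenvalue-only changes that occur
  along shared eigenvectors (the angle factor is zero). In the
  equicorrelation simulation the population-level group difference is
  exactly such a change — the top eigenvalue shifts along the common
  ones-direction — so `φ`'s discriminative signal there comes from
  sampling fluctuations rather than the designed structural difference.
  A likelihood-ratio oracle in the test suite shows that even the optimal
  classifier of a single fresh draw stays below 70% accuracy at m = 20
  under this design; the accuracies the bundled study computes should be
  read against that ceiling, and resubstitution scoring (the default, and
  the literal protocol of the assessment) adds only the weak leak that
  flows through the group summaries. Published figures for this family of
  benchmarks that exceed the single-sample ceiling cannot be reproduced by
  this implementation; `scripts/acceptance.py` reports what the pipeline
  actually achieves.
- `φ` is unstable under (near-)degenerate spectra, as above.
- The derivation is strictly rank-one: batch incorporation of several new
  samples is out of scope, as is multi-class assignment.
- `ψ̄` is a mean of reciprocals and is therefore dominated by the ladder
  rung with the smallest |φ| (usually the largest `n_red`); the `ε` guard
  caps the blow-up when a distortion underflows.
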