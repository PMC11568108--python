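# Methods

## The problem

Antibody-derived tags (ADTs) quantify cell-surface proteins by sequencing
DNA-barcoded antibodies alongside RNA or DNA in droplet-based single-cell
assays.  A large part of the per-cell signal is technical: droplets
encapsulate unbound antibody, so a cell that happened to capture more free
antibody reads higher on *every* tag.  Isotype controls — antibodies with no
target in the sample — measure exactly this ambient component, and their
counts correlate strongly between cells.  The prevailing normalization,
the per-cell centered log-ratio (CLR) across antibodies, ignores them, and
its `log(n+1)` transform misbehaves for low counts.

`isogp` instead models the raw counts and asks a conditional question: what
would each population's protein expression look like *if every droplet had
carried the same isotype-control noise*?

## Model

For one target protein in cells `i = 1..n`, with raw isotype-control counts
`IgG_i` and integer-coded covariates `X_ki`:

    y_i        ~ NB2(mu_i, phi)            Var[y] = mu + mu^2 / phi
    log(mu_i)  = mu0 + gamma_i + sum_k beta_k[X_ki]
    gamma      ~ MVN(0, K)
    K_ij       = eta_sq * exp(-(rho_sq / 2) * (IgG_i - IgG_j)^2)

`gamma_i` is the droplet-specific technical offset; the exponentiated
quadratic kernel makes offsets similar for cells with similar raw
isotype-control counts.  `eta_sq` is the maximum between-cell covariance and
`rho_sq` the rate at which covariance decays with isotype distance.

Default priors (weakly informative):

| parameter | prior | notes |
|---|---|---|
| `mu0` | Gamma(7, 2) | `exp(mu0)` spans averages of roughly 3–2000 counts (central 99%) |
| `phi` | Gamma(0.5, 0.5) | admits strong overdispersion |
| `eta_sq` | Normal(2, 1), truncated to (0, ∞) | a kernel amplitude must be positive |
| `rho_sq` | Uniform(0, 5000) | see tuning below |
| `beta_kl` | Normal(0, 1), first level pinned to 0 | identifiability against `mu0` |

**Tuning `rho_sq`.**  Kernel distances are raw counts, so a useful prior
range for `rho_sq` depends on the dataset's isotype count spread.
`tune_rhosq_upper(igg)` sets the Uniform upper bound so that at
`rho_sq = hi` the kernel correlation at the 90th percentile of observed
pairwise IgG distances has decayed to 0.01: the prior then spans everything
from a flat kernel to one that has effectively vanished across the span of
the data, without wasting mass on regimes where all cells are already
independent.  `prior_kernel_curves` draws covariance-versus-distance curves
from the joint prior for visual auditing.  The estimator front end
(`IsotypeGPRegressor`) applies this tuning by default.

## Inference

Posteriors are explored with a self-contained No-U-Turn sampler
(slice-variable doubling trees, dual-averaging step size toward 0.8
acceptance, Stan-style expanding adaptation windows), with analytic
gradients of the joint density compiled via numba.  Defaults follow the
workflow this package reimplements: 4 chains, 3000 warmup and 1000 sampling
iterations.  Runs are bit-reproducible given (inputs, priors, seed).

Three implementation choices matter and were made after profiling the
posterior geometry on the masked simulation (below):

* **Parameterization.**  The sampler state carries the *total* per-cell log
  level `g_i = mu0 + sum_k beta_k[X_ki] + gamma_i` with prior
  `MVN(mu0*1 + X beta, K)` — a centered parameterization with every mean
  component folded into the GP prior mean.  When counts are informative the
  likelihood pins each `g_i` and the kernel hyperparameters decouple from
  the latent field; the soft trade-offs of the intercept (and of each
  treatment coefficient) against blocks of offsets become single
  well-scaled coordinates.  The conventional whitened (non-centered) form
  `gamma = L z` is kept as an option, and the default `"auto"` mode falls
  back to it when centered diagnostics clearly fail (max split-Rhat >
  1.05), which happens in weak-data fits where the amplitude funnel
  reappears.
* **Nugget.**  The sampler adds `1e-3 * eta_sq` to the kernel diagonal —
  an i.i.d. relaxation of the offset prior with 0.1% of the kernel
  amplitude, scientifically negligible but decisive for conditioning the
  near-singular kernel directions the centered form exposes.  The public
  `build_kernel` keeps a `1e-6 * eta_sq` jitter, doubled up to three times
  on Cholesky failure before raising.
* **Metric.**  Mass-matrix adaptation is diagonal through warmup and
  switches to a dense estimate only in the final window, with the sample
  correlation spectrum clipped to the Marchenko–Pastur noise band so only
  genuinely measured cross-correlations survive.  Fully dense windowed
  adaptation is available but can self-reinforce a mis-estimated
  correlation; the default avoids it.

Divergent transitions use the standard Hamiltonian-error threshold (1000);
a fit warns when more than 10% of post-warmup transitions diverge.
Diagnostics are split-chain rank-normalized Rhat and bulk ESS (via arviz);
a fit is flagged converged when max Rhat ≤ 1.01 and every parameter keeps
≥ 100 effective draws.  With a single chain, Rhat is reported as missing,
never as 1.

## Conditional ("equal isotype noise") summaries

For each posterior draw and each covariate-level combination, the package
reports two matrices with columns in lexicographic combination order:

* `cond_means` — the expected count `exp(mu0 + sum_k beta_k[c_k])`, i.e.
  the GP offset held at its prior mean 0.  Zero is the natural common
  reference realizing "all cells share the same isotype noise" without
  privileging any observed IgG value.
* `cond_samples` — one NB2 predictive count per draw at that mean and the
  drawn `phi`, for density plots on the count scale.

Effect summaries (log2 fold change between two combinations, its central
intervals, and the pseudo p-value) are computed from paired draws of
`cond_means` by default: a fold change in *expected* expression.  Computing
it from `cond_samples` instead (supported via `use_count_draws`) adds the
full NB2 predictive noise to every draw, which inflates the spread of the
fold-change distribution by an order of magnitude and makes it a statement
about single future cells rather than about the populations.  A `+0.5`
half-count guard keeps count-draw ratios finite at zero.

The pseudo p-value is `2 * min(P(draws >= 0), P(draws <= 0))`, floored at
`1/n_draws` and capped at 1 — the usual two-sided posterior sign
probability used in Bayesian volcano plots.

## The CLR baseline

`clr_normalize` is the within-cell centered log-ratio across antibodies
with pseudocount 1: `clr(x_i)_j = log(x_ij + 1) - mean_j log(x_ij + 1)`;
every transformed cell sums to zero.  Group effects are differences in group means of the
transformed values with a Welch t-test (`equal_var=True` restores the
pooled-variance variant).  `differential_sweep` runs both methods per
antibody, keeps isotype controls in the table flagged as the
negative-control truth set, and emits a Benjamini–Hochberg column alongside
the raw significance values without using it for any flag.

## The masked-noise simulator

`run_simulation` emulates an experiment in which the true expression of a
protein X is two-fold higher in treatment 1 than treatment 2 while both
treatments share the same isotype-noise distribution:

    X1 ~ NB2(200, 1)    X2 ~ NB2(100, 1)    IgG ~ NB2(20, 5)

Within each treatment, protein and IgG are coupled comonotonically: one
shared Uniform(0,1) quantile per cell pushed through both marginal quantile
functions, so each margin is exactly NB2 and the pair is maximally
rank-correlated.  From a pool of 10,000 such cells per treatment, 50 cells
are sampled without replacement with probability weights `1/(IgG+1)` for
treatment 1 and `IgG+1` for treatment 2 (the `+1` keeps zero counts
samplable).  Treatment-2 cells therefore carry systematically more ambient
noise, and for most seeds the naive group comparison points the wrong way.

What the simulator does *not* emulate: multi-antibody panels with realistic
cross-antibody correlation, sequencing-depth variation, cell-type mixture
structure, or isotype controls whose noise is only partially shared with
the target antibody.  Passing the recovery tests therefore shows the model
corrects *this* noise mechanism under an exactly comonotone protein–noise
coupling; real data will sit somewhere short of that ideal.

## Problem sizes used by the tests and the acceptance script

The end-to-end study conditions are the simulator defaults: 100 cells, two
treatments, default priors with the tuned `rho_sq` bound, 4 chains × (3000
warmup + 1000 sampling).  One such fit takes roughly two minutes on a
single CPU.  The broader test suite exercises the same code paths on 20–80
cell fits with a few hundred iterations per chain, sizes at which posterior
contraction, effect recovery and diagnostics are already measurable; the
RMSE-dominance check across seeds uses 2 chains × (800 + 500) per seed.
The acceptance script repeats the full default-settings pipeline over five
simulation seeds and reports the median CLR-to-model RMSE ratio.

## Known limitations

* The Gaussian-process noise model assumes smooth covariance in raw
  isotype-count distance; sharp subpopulation changes or heavy-tailed
  noise violate it.
* One isotype control per fit; when several exist the caller selects one
  (or pre-averages).  Cross-control disagreement is not modeled.
* The centered default is tuned to informative counts; extremely sparse
  tags rely on the automatic non-centered fallback, which is slower per
  effective draw.
* `rho_sq` inference is only as good as its prior range; the tuning rule
  is a heuristic anchored at the observed distance spread, and datasets
  with a handful of extreme IgG outliers may warrant a manual bound.
* The RMSE comparison treats the CLR point estimate's absolute error as
  its RMSE; with a single dataset per seed no sampling distribution for
  CLR is available.
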