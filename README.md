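# isogp

Gaussian-process correction of droplet-specific technical noise in
single-cell antibody-derived-tag (ADT) counts.

In CITE-seq and single-cell DNA+protein assays, droplets encapsulate
unbound antibody along with each cell, so every tag's count carries a
droplet-specific ambient component.  Isotype (negative-control) antibodies
measure exactly that component — their counts correlate strongly between
cells — yet the standard centered log-ratio (CLR) workflow discards them.
`isogp` models raw protein counts with a negative-binomial likelihood whose
log mean carries a per-cell Gaussian-process offset learned from raw
isotype-control counts:

    y_i       ~ NB2(mu_i, phi),            Var[y] = mu + mu^2/phi
    log(mu_i) = mu0 + gamma_i + sum_k beta_k[X_ki]
    gamma     ~ MVN(0, K),    K_ij = eta^2 exp(-(rho^2/2)(IgG_i - IgG_j)^2)

The posterior is explored by a built-in No-U-Turn sampler with analytic
gradients.  A fit returns, for every combination of covariate levels, draws
of protein expression *conditioned on equal isotype-control noise across
cells* — the quantity a fold change should be computed from.  The package
also ships the masked-noise simulator used to validate the approach and the
CLR + t-test baseline for comparison.  It is aimed at anyone analyzing
ADT panels with isotype controls who wants count-scale, noise-adjusted
group comparisons instead of log-normalized heuristics.

## Worked example

Simulate the masking scenario — protein X truly two-fold higher in
treatment 1, but treatment-2 cells sampled toward noisier droplets — then
fit and compare against CLR:

```python
import numpy as np
from isogp import (SimulationConfig, run_simulation, DesignMatrix,
                   PriorConfig, tune_rhosq_upper, fit, log2fc_posterior,
                   clr_effect, rmse_comparison, ADTCountMatrix)

sim = run_simulation(SimulationConfig(seed=1))
print(f"true log2FC {sim.true_log2fc:.2f}, naive observed {sim.observed_log2fc():.2f}")

design = DesignMatrix.from_codes(100, T=sim.treatment)
priors = PriorConfig().with_rhosq(0.0, tune_rhosq_upper(sim.igg))
res = fit(sim.protein, sim.igg, design, priors=priors,
          chains=4, iter_warmup=3000, iter_sampling=1000, seed=1)
print(f"max Rhat {res.diagnostics['rhat'].max():.3f}, divergences {res.divergences}")

eff = log2fc_posterior(res.cond_means_frame(), "T=1", "T=2")
panel = ADTCountMatrix(np.column_stack([sim.protein, sim.igg]),
                       ["proteinX", "IgG1"], [f"c{i}" for i in range(100)])
clr = clr_effect(panel, "proteinX", sim.treatment)
cmp = rmse_comparison(eff, clr["estimate"], sim.true_log2fc)
print(f"posterior log2FC {eff.posterior_mean:.3f}  CLR estimate {clr['estimate']:.3f}")
print(f"RMSE model {cmp['rmse_adtgp']:.3f}  CLR {cmp['rmse_clr']:.3f}  ratio {cmp['ratio']:.1f}")
```

Output (seed 1, ~2 min on one CPU):

```
true log2FC 1.00, naive observed -0.56
max Rhat 1.009, divergences 0
posterior log2FC 0.986  CLR estimate -0.126
RMSE model 0.067  CLR 1.126  ratio 16.8
```

The raw data point the wrong way (−0.56): biased sampling loaded
treatment 2 with noisy droplets and the noise masks the biology.  The
GP-corrected posterior recovers the two-fold truth (0.986 ≈ log2 2), while
CLR's estimate keeps the wrong sign; against the known truth, the model's
fold-change error is ~17× smaller than CLR's here.

A scikit-learn-style front end wraps the same machinery
(`IsotypeGPRegressor(...).fit(design, protein, igg=igg)`), and
`CLRTransformer` exposes the baseline as a transformer.

### Command line

```sh
isogp simulate --seed 1 --out sim              # masked dataset + truth JSON
isogp fit --counts panel.tsv --design design.tsv \
          --protein CD11b --isotype IgG1 --out-dir run/
isogp de  --counts panel.tsv --design design.tsv --isotype IgG1 --out de.tsv
isogp clr --counts panel.tsv --out clr.tsv
isogp fixtures --out-dir fixtures/             # synthetic offline datasets
```

`isogp fit` writes the posterior-sample CSV (one column per covariate
combination), a diagnostics TSV, an effect-summary JSON and the resolved
run config next to it.

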