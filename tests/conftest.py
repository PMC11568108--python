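import numpy as np
import pytest

from isogp import (
    ADTCountMatrix,
    DesignMatrix,
    PriorConfig,
    SimulationConfig,
    fit,
    run_simulation,
    tune_rhosq_upper,
)


@pytest.fixture(scope="session")
def masked_sim():
    """The masked two-treatment dataset under default generative settings."""
    return run_simulation(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def masked_panel(masked_sim):
    n = masked_sim.protein.size
    return ADTCountMatrix(
        counts=np.column_stack([masked_sim.protein, masked_sim.igg]),
        antibody_names=["proteinX", "IgG1"],
        cell_ids=[f"cell{i:03d}" for i in range(n)],
    )


@pytest.fixture(scope="session")
def quick_fit():
    """A small but real two-level fit shared by shape/contract tests."""
    rng = np.random.default_rng(42)
    n = 60
    treatment = np.repeat([1, 2], n // 2)
    mu = np.exp(3.5 + 0.7 * (treatment == 1))
    y = rng.poisson(mu * rng.gamma(5.0, 0.2, n))
    igg = rng.poisson(20, n)
    design = DesignMatrix.from_codes(n, T=treatment)
    priors = PriorConfig().with_rhosq(0, tune_rhosq_upper(igg))
    res = fit(y, igg, design, priors=priors, chains=2, iter_warmup=400,
              iter_sampling=300, seed=7)
    return {"result": res, "y": y, "igg": igg, "design": design, "priors": priors}
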