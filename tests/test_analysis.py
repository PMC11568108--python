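"""Effect summaries, CLR baseline and the differential sweep."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from isogp import (
    ADTCountMatrix,
    CLRTransformer,
    DesignMatrix,
    EffectSummary,
    clr_effect,
    clr_normalize,
    differential_sweep,
    isotype_correlation,
    log2fc_posterior,
    pseudo_p,
    quantile_couple,
    rmse_comparison,
)


def _panel(counts, names=None):
    counts = np.asarray(counts)
    names = names or [f"ab{j}" for j in range(counts.shape[1])]
    return ADTCountMatrix(counts, names, [f"c{i}" for i in range(counts.shape[0])])


# ---------------------------------------------------------------------------
# log2 fold change and pseudo p-value
# ---------------------------------------------------------------------------
def test_log2fc_null_and_scaling_cases():
    col = np.random.default_rng(0).integers(50, 200, 400)
    same = pd.DataFrame({"T=1": col, "T=2": col})
    eff = log2fc_posterior(same, "T=1", "T=2")
    assert np.all(eff.log2fc_draws == 0)
    assert eff.pseudo_p == 1.0

    doubled = pd.DataFrame({"T=1": 2 * col, "T=2": col})
    eff2 = log2fc_posterior(doubled, "T=1", "T=2")
    assert np.allclose(eff2.log2fc_draws, 1.0, atol=0.02)  # +0.5 guard at counts >> 1


def test_log2fc_antisymmetry_and_summaries():
    rng = np.random.default_rng(1)
    draws = pd.DataFrame({"a": rng.poisson(100, 500), "b": rng.poisson(60, 500)})
    fwd = log2fc_posterior(draws, "a", "b")
    rev = log2fc_posterior(draws, "b", "a")
    assert np.allclose(fwd.log2fc_draws, -rev.log2fc_draws)
    lo, hi = fwd.central_interval(0.9)
    assert lo <= fwd.posterior_median <= hi
    with pytest.raises(KeyError):
        log2fc_posterior(draws, "a", "missing")


def test_pseudo_p_tail_definitions():
    assert pseudo_p(np.ones(1000)) == pytest.approx(1 / 1000)
    alternating = np.tile([1.0, -1.0], 500)
    assert pseudo_p(alternating) == 1.0
    draws = np.r_[np.ones(950), -np.ones(50)]
    assert pseudo_p(draws) == pytest.approx(0.10)
    with pytest.raises(ValueError):
        pseudo_p(np.ones(50))


@given(st.floats(0.01, 100.0), st.integers(0, 10_000))
@settings(max_examples=30, deadline=None)
def test_pseudo_p_invariant_to_positive_rescaling(scale, seed):
    draws = np.random.default_rng(seed).normal(0.3, 1.0, 200)
    assert pseudo_p(draws) == pseudo_p(scale * draws)


# ---------------------------------------------------------------------------
# CLR
# ---------------------------------------------------------------------------
def test_clr_constant_composition_is_zero():
    out = clr_normalize(np.array([[1, 1, 1]]))
    assert np.allclose(out, 0.0)


def test_clr_two_antibody_hand_computation():
    # log(4) - mean(log 4, log 1) = log(4)/2
    out = clr_normalize(np.array([[3, 0]]))
    assert out[0, 0] == pytest.approx(np.log(4) / 2, rel=1e-12)
    assert out[0, 1] == pytest.approx(-np.log(4) / 2, rel=1e-12)


def test_clr_rows_center_to_zero():
    rng = np.random.default_rng(3)
    x = rng.integers(0, 500, size=(40, 7))
    out = clr_normalize(x)
    assert np.max(np.abs(out.sum(axis=1))) < 1e-12


def test_clr_scale_invariance_in_large_count_limit():
    rng = np.random.default_rng(4)
    x = rng.integers(100, 1000, size=(20, 5))
    assert np.max(np.abs(clr_normalize(3 * x) - clr_normalize(x))) < 0.01


def test_clr_single_antibody_degenerate_warns():
    with pytest.warns(RuntimeWarning, match="degenerate"):
        out = clr_normalize(np.array([[5], [9]]))
    assert np.allclose(out, 0.0)


def test_clr_transformer_sklearn_surface():
    x = np.array([[10, 20], [5, 5]])
    tr = CLRTransformer()
    out = tr.fit_transform(x)
    assert np.allclose(out, clr_normalize(x))
    assert tr.get_params() == {"pseudocount": 1.0}


def test_clr_effect_identical_groups_null():
    cell = [10, 30, 5]
    panel = _panel([cell, cell, cell, cell])
    res = clr_effect(panel, "ab0", np.array([1, 1, 2, 2]))
    assert res["estimate"] == 0.0
    assert res["p_value"] == 1.0


def test_clr_effect_matches_bruteforce_on_four_cells():
    counts = np.array([[8, 2], [4, 4], [2, 2], [1, 7]])
    groups = np.array([1, 1, 2, 2])
    panel = _panel(counts)
    res = clr_effect(panel, "ab0", groups)
    logs = np.log(counts + 1.0)
    clr0 = logs[:, 0] - logs.mean(axis=1)
    expected = clr0[:2].mean() - clr0[2:].mean()
    assert res["estimate"] == pytest.approx(expected, rel=1e-12)
    assert 0 < res["p_value"] <= 1

    with pytest.raises(ValueError, match="at least 2 cells"):
        clr_effect(panel, "ab0", np.array([1, 2, 2, 2]))


# ---------------------------------------------------------------------------
# RMSE comparison
# ---------------------------------------------------------------------------
def test_rmse_comparison_closed_cases():
    exact = EffectSummary(np.full(200, 1.0), "a", "b")
    with pytest.warns(RuntimeWarning, match="ratio"):
        res = rmse_comparison(exact, clr_estimate=0.0, truth=1.0)
    assert res["rmse_adtgp"] == 0.0
    assert res["ratio"] == np.inf

    alternating = EffectSummary(1.0 + np.tile([1.0, -1.0], 100), "a", "b")
    res2 = rmse_comparison(alternating, clr_estimate=-0.5, truth=1.0)
    assert res2["rmse_adtgp"] == pytest.approx(1.0)
    assert res2["rmse_clr"] == pytest.approx(1.5)
    assert res2["ratio"] == pytest.approx(1.5)
    with pytest.raises(ValueError):
        rmse_comparison(alternating, 0.0, np.inf)


# ---------------------------------------------------------------------------
# isotype correlations
# ---------------------------------------------------------------------------
def test_isotype_correlation_modes():
    rng = np.random.default_rng(5)
    n = 10_000
    igg_a, igg_b = quantile_couple(20, 5, 20, 5, n=n, seed=2)  # comonotone pair
    indep = rng.poisson(20, n)
    const = np.full(n, 3)
    panel = ADTCountMatrix(
        np.column_stack([igg_a, igg_b, indep, const]),
        ["IgG1", "IgG2", "IgG3", "IgG4"],
        [f"c{i}" for i in range(n)],
    )
    table = isotype_correlation(panel).set_index(["antibody_a", "antibody_b"])
    assert table.loc[("IgG1", "IgG2"), "spearman"] > 0.95
    assert abs(table.loc[("IgG1", "IgG3"), "pearson"]) < 0.05
    assert np.isnan(table.loc[("IgG1", "IgG4"), "pearson"])

    dup = ADTCountMatrix(
        np.column_stack([indep, indep]), ["IgG1", "IgG2"], [f"c{i}" for i in range(n)]
    )
    t2 = isotype_correlation(dup)
    assert t2.loc[0, "pearson"] == pytest.approx(1.0)

    with pytest.raises(ValueError):
        isotype_correlation(_panel([[1, 2], [3, 4]], names=["a", "b"]))


# ---------------------------------------------------------------------------
# differential sweep (small but real fits)
# ---------------------------------------------------------------------------
@pytest.fixture(scope="module")
def sweep_table():
    rng = np.random.default_rng(6)
    n = 60
    treatment = np.repeat([1, 2], n // 2)
    igg = rng.poisson(20, n)
    shifted = rng.poisson(np.exp(3.0 + 0.7 * (treatment == 1)))
    null_ab = rng.poisson(np.exp(3.0), n)
    igg2 = rng.poisson(igg + 1.0)  # noisy copy of the control: a negative control
    panel = ADTCountMatrix(
        np.column_stack([shifted, null_ab, igg2, igg]),
        ["CD11b-like", "nullAb", "IgG2", "IgG1"],
        [f"c{i}" for i in range(n)],
    )
    design = DesignMatrix.from_codes(n, T=treatment)
    table = differential_sweep(
        panel, "IgG1", design,
        chains=2, iter_warmup=300, iter_sampling=250, seed=11,
    )
    return table


def test_sweep_shape_and_flags(sweep_table):
    # 3 analyzed antibodies x 2 methods; the selected control is excluded
    assert len(sweep_table) == 6
    assert set(sweep_table["method"]) == {"ADTGP", "CLR"}
    assert set(sweep_table.loc[sweep_table["is_isotype"], "antibody"]) == {"IgG2"}
    assert sweep_table["bh_fdr"].notna().all()
    assert (sweep_table.groupby("antibody").size() == 2).all()


def test_sweep_ranks_true_shift_first(sweep_table):
    for method in ("ADTGP", "CLR"):
        sub = sweep_table[sweep_table["method"] == method]
        top = sub.loc[sub["estimate"].abs().idxmax(), "antibody"]
        assert top == "CD11b-like"


def test_sweep_negative_control_is_not_called(sweep_table):
    row = sweep_table[(sweep_table["antibody"] == "IgG2") & (sweep_table["method"] == "ADTGP")]
    assert abs(float(row["estimate"].iloc[0])) < 0.5
    assert float(row["significance"].iloc[0]) > 0.01
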