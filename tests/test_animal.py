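import numpy as np
import pandas as pd
import pytest

import morphoquant.animal as animal_mod
from morphoquant.animal import (
    MixedModelSpec,
    _prepare,
    _theta_dict,
    compare_additive_dominance,
    fit_animal_model,
    length_genotype_interaction,
    satterthwaite_type3,
)
from morphoquant.pedigree import RelationshipMatrix
from morphoquant.simulate import SimulationConfig, simulate_breeding, simulate_traits


def test_fixed_effects_only_matches_ols(rng):
    n = 60
    X = rng.standard_normal((n, 2))
    y = 1.0 + X @ np.array([0.5, -0.3]) + rng.normal(0, 1, n)
    df = pd.DataFrame({"y": y, "x1": X[:, 0], "x2": X[:, 1]})
    fit = fit_animal_model(df, None, MixedModelSpec(trait="y", fixed=("x1", "x2"), random=()))
    b = np.linalg.lstsq(np.column_stack([np.ones(n), X]), y, rcond=None)[0]
    assert np.allclose(fit.coef.to_numpy(), b, atol=1e-8)
    assert fit.aic == pytest.approx(-2 * fit.loglik_ml + 2 * (3 + 1))


def test_balanced_oneway_reml_matches_anova(rng):
    g, n0 = 12, 8
    group = np.repeat(np.arange(g), n0)
    y = 5 + rng.normal(0, np.sqrt(2.0), g)[group] + rng.normal(0, 1.0, g * n0)
    df = pd.DataFrame({"id": [f"g{k:02d}" for k in group], "y": y})
    fit = fit_animal_model(df, None, MixedModelSpec(trait="y", fixed=(), random=("ID",)))
    gm = df.groupby("id")["y"].mean().to_numpy()
    msb = n0 * ((gm - y.mean()) ** 2).sum() / (g - 1)
    msw = ((y - df.groupby("id")["y"].transform("mean")) ** 2).sum() / (g * (n0 - 1))
    assert fit.varcomp["ID"] == pytest.approx((msb - msw) / n0, abs=1e-6)
    assert fit.varcomp["error"] == pytest.approx(msw, abs=1e-6)


def test_zero_animal_variance_hits_boundary(small_dataset):
    cfg = SimulationConfig(seed=77, n_units=4, offspring_per_family=8,
                           V_animal=0.0)
    ped, geno = simulate_breeding(cfg)
    table, _ = simulate_traits(ped, geno, cfg)
    from morphoquant.pedigree import additive_relationship_matrix
    A = additive_relationship_matrix(ped)
    fit = fit_animal_model(table, A, MixedModelSpec(trait="synthetic_trait"))
    assert fit.converged
    # estimate sits at/near the zero boundary, well below the other
    # planted components (V_ID = 0.3), and never goes negative
    assert 0.0 <= fit.varcomp["animal"] < 0.15


def test_collapsed_and_generic_engines_agree(small_dataset):
    spec = MixedModelSpec(trait="synthetic_trait")
    table, A = small_dataset["table"], small_dataset["A"]
    df, eng_c, _, _ = _prepare(table, A, spec)
    orig = animal_mod._collapsible
    animal_mod._collapsible = lambda *a: False
    try:
        _, eng_g, _, _ = _prepare(table, A, spec)
    finally:
        animal_mod._collapsible = orig
    assert type(eng_c).__name__ == "_CollapsedEngine"
    assert type(eng_g).__name__ == "_Engine"
    for th in ([0.2, 0.3, 0.1, 0.25], [0.0, 0.3, 0.0, 0.2], [0.5, 0.0, 0.1, 0.3]):
        theta = _theta_dict(eng_c.components, np.array(th))
        for reml in (True, False):
            fc, gc = eng_c.neg2ll_grad(theta, reml)
            fg, gg = eng_g.neg2ll_grad(theta, reml)
            assert fc == pytest.approx(fg, abs=1e-7)
            assert np.allclose(gc, gg, atol=1e-6)


def test_identity_A_animal_equals_iid_individual(rng):
    # with one observation per individual and A = I the animal term is
    # indistinguishable from an i.i.d. individual term
    n = 80
    ids = [f"i{k:03d}" for k in range(n)]
    y = 2 + rng.normal(0, 1.0, n) + rng.normal(0, 0.7, n)
    df = pd.DataFrame({"id": ids, "y": y, "x": rng.standard_normal(n)})
    A = RelationshipMatrix(ids, np.eye(n))
    fit_a = fit_animal_model(df, A, MixedModelSpec(trait="y", fixed=("x",), random=("animal",)))
    fit_i = fit_animal_model(df, None, MixedModelSpec(trait="y", fixed=("x",), random=("ID",)))
    assert fit_a.loglik == pytest.approx(fit_i.loglik, abs=1e-6)
    assert fit_a.varcomp["animal"] == pytest.approx(fit_i.varcomp["ID"], abs=1e-5)
    assert np.allclose(fit_a.coef, fit_i.coef, atol=1e-6)


def test_unmatched_ids_raise(small_dataset):
    table = small_dataset["table"]
    A = RelationshipMatrix(["nobody"], np.eye(1))
    with pytest.raises(ValueError, match="missing from the relationship"):
        fit_animal_model(table, A, MixedModelSpec(trait="synthetic_trait"))


def test_satterthwaite_exact_for_fixed_only(rng):
    n = 40
    df = pd.DataFrame({"y": rng.normal(0, 1, n), "x": rng.standard_normal(n)})
    fit = fit_animal_model(df, None, MixedModelSpec(trait="y", fixed=("x",), random=()))
    tab = satterthwaite_type3(fit).set_index("term")
    assert tab.loc["x", "df2"] == pytest.approx(n - 2)


def test_satterthwaite_two_group_classical(rng):
    n1 = n2 = 15
    df = pd.DataFrame(
        {
            "y": np.r_[rng.normal(0, 1, n1), rng.normal(0.8, 1, n2)],
            "grp": ["a"] * n1 + ["b"] * n2,
        }
    )
    fit = fit_animal_model(df, None, MixedModelSpec(trait="y", fixed=("grp",), random=()))
    tab = satterthwaite_type3(fit).set_index("term")
    assert tab.loc["grp", "df2"] == pytest.approx(n1 + n2 - 2)


def test_satterthwaite_split_plot_df(rng):
    # balanced split plot: whole-plot random effect, between-plot factor;
    # classical denominator df for the whole-plot factor is n_plots - 2
    n_plots, n_sub = 12, 6
    plot = np.repeat(np.arange(n_plots), n_sub)
    treat = (plot % 2).astype(float)
    y = 1.0 + 0.5 * treat + rng.normal(0, 1.0, n_plots)[plot] + rng.normal(0, 0.8, plot.size)
    df = pd.DataFrame({"y": y, "treat": treat, "id": [f"p{k:02d}" for k in plot]})
    fit = fit_animal_model(df, None, MixedModelSpec(trait="y", fixed=("treat",), random=("ID",)))
    tab = satterthwaite_type3(fit).set_index("term")
    assert tab.loc["treat", "df2"] == pytest.approx(n_plots - 2, abs=0.5)


def test_additive_vs_dominance_aic(rng):
    # planted full dominance (EL behaves like LL) at 0.5 SD should favour
    # the non-additive codings; purely additive data should not
    # genotype means 0 / 0.5 / 0.5: the heterozygote matches LL exactly
    cfg_dom = SimulationConfig(seed=9, n_units=8, offspring_per_family=12,
                               beta_vgll3=0.25, dominance_vgll3=0.25,
                               V_animal=0.05, V_ID=0.3, V_tank=0.05, V_error=0.2)
    ped, geno = simulate_breeding(cfg_dom)
    table, _ = simulate_traits(ped, geno, cfg_dom)
    from morphoquant.pedigree import additive_relationship_matrix
    A = additive_relationship_matrix(ped)
    res = compare_additive_dominance(table, A, "synthetic_trait")
    assert set(res["aic"]) == {"additive", "factor", "EL_equals_LL", "EL_equals_EE"}
    assert res["delta"] >= 2.0
    assert res["aic"]["EL_equals_LL"] < res["aic"]["EL_equals_EE"]

    cfg_add = SimulationConfig(seed=10, n_units=8, offspring_per_family=12,
                               V_animal=0.05, V_ID=0.3, V_tank=0.05, V_error=0.2)
    ped, geno = simulate_breeding(cfg_add)
    table, _ = simulate_traits(ped, geno, cfg_add)
    A = additive_relationship_matrix(ped)
    res_add = compare_additive_dominance(table, A, "synthetic_trait")
    assert res_add["delta"] < 2.0


def test_length_genotype_interaction_detection():
    cfg = SimulationConfig(seed=12, beta_length_x_vgll3=0.5)
    ped, geno = simulate_breeding(cfg)
    table, _ = simulate_traits(ped, geno, cfg)
    from morphoquant.pedigree import additive_relationship_matrix
    A = additive_relationship_matrix(ped)
    res = length_genotype_interaction(table, A, "synthetic_trait")
    assert abs(res["interaction_t"]["length_x_vgll3"]) > 2
    assert abs(res["interaction_t"]["length_x_six6"]) < 3

    cfg0 = SimulationConfig(seed=13, n_units=6, offspring_per_family=10)
    ped, geno = simulate_breeding(cfg0)
    table, _ = simulate_traits(ped, geno, cfg0)
    A = additive_relationship_matrix(ped)
    res0 = length_genotype_interaction(table, A, "synthetic_trait")
    assert abs(res0["interaction_t"]["length_x_vgll3"]) < 3
    # main genetic effects barely move when the interaction is truly absent
    assert abs(res0["main_effect_change"]["vgll3"]) < 0.2
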