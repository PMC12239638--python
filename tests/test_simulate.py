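import numpy as np
import pandas as pd
import pytest
from scipy import stats

from morphoquant.procrustes import (
    flag_outlier_configurations,
    generalized_procrustes,
    procrustes_distance,
)
from morphoquant.simulate import (
    SimulationConfig,
    body_template,
    simulate_breeding,
    simulate_landmarks,
    simulate_traits,
)


def test_breeding_design_counts():
    cfg = SimulationConfig(seed=1)
    ped, geno = simulate_breeding(cfg)
    parents = geno[geno["is_parent"]]
    assert len(parents) == 44  # 11 units x 4 parents
    assert geno["family"].nunique(dropna=True) == 44  # 4 crosses per unit
    # each unit: one EE and one LL parent per sex
    per_unit = parents.groupby("unit")
    for _, u in per_unit:
        assert sorted(u["vgll3"]) == [0, 0, 2, 2]
        assert sorted(u["sex"]) == ["female", "female", "male", "male"]


def test_mendelian_vgll3_fixed_within_family():
    cfg = SimulationConfig(seed=2, n_units=4, offspring_per_family=10)
    _, geno = simulate_breeding(cfg)
    off = geno[~geno["is_parent"]]
    # homozygote x homozygote crosses fix the offspring genotype per family
    assert (off.groupby("family")["vgll3"].nunique() == 1).all()
    per_unit = off.groupby("unit")["vgll3"].apply(lambda s: sorted(s.unique()))
    for u in per_unit:
        assert u == [0, 1, 2]  # EE, EL/LE, LL all present in each unit


def test_six6_mendelian_frequencies():
    cfg = SimulationConfig(seed=3, offspring_per_family=40)
    _, geno = simulate_breeding(cfg)
    off = geno[~geno["is_parent"]]
    par = geno[geno["is_parent"]]
    fam_parents = {}
    for _, row in off.iterrows():
        fam_parents.setdefault(row["family"], row["unit"])
    # chi-square goodness of fit of pooled offspring allele count against
    # the Mendelian expectation from the parental genotypes
    exp_freq = par["six6"].sum() / (2 * len(par))
    obs = off["six6"].sum()
    n_alleles = 2 * len(off)
    chi2 = (obs - n_alleles * exp_freq) ** 2 / (n_alleles * exp_freq * (1 - exp_freq))
    assert stats.chi2.sf(chi2, df=1) > 0.01


def test_same_seed_identical_outputs():
    cfg = SimulationConfig(seed=5, n_units=3, offspring_per_family=5)
    ped1, g1 = simulate_breeding(cfg)
    ped2, g2 = simulate_breeding(cfg)
    assert ped1.records == ped2.records
    pd.testing.assert_frame_equal(g1, g2)
    t1, tr1 = simulate_traits(ped1, g1, cfg)
    t2, tr2 = simulate_traits(ped2, g2, cfg)
    pd.testing.assert_frame_equal(t1, t2)
    assert tr1["planted_exclusions"] == tr2["planted_exclusions"]


def test_all_zero_variances_and_betas_give_constant_trait():
    cfg = SimulationConfig(
        seed=6, n_units=2, offspring_per_family=4,
        beta_length=0, beta_cf=0, beta_feed=0, beta_sex=0,
        beta_vgll3=0, beta_six6=0,
        V_animal=0, V_tank=0, V_ID=0, V_error=0,
    )
    ped, geno = simulate_breeding(cfg)
    table, _ = simulate_traits(ped, geno, cfg)
    assert np.allclose(table["synthetic_trait"], cfg.mu)


def test_fullsib_covariance_matches_half_animal_variance():
    # with only V_animal > 0, cov(full sibs) ~ 0.5 V_animal
    covs = []
    for seed in range(30):
        cfg = SimulationConfig(
            seed=seed, n_units=6, offspring_per_family=2,
            beta_length=0, beta_cf=0, beta_feed=0, beta_sex=0,
            beta_vgll3=0, beta_six6=0,
            V_animal=1.0, V_tank=0, V_ID=0, V_error=0,
            lower_mode_fraction=0.0, n_missing_vgll3=0, n_missing_six6=0,
            n_missing_sex=0, n_mature_males=0, replicate_fraction=0.0,
        )
        ped, geno = simulate_breeding(cfg)
        table, _ = simulate_traits(ped, geno, cfg)
        for _, fam in table.groupby("family"):
            v = fam["synthetic_trait"].to_numpy() - cfg.mu
            covs.append(v[0] * v[1])
    mean_cov = np.mean(covs)
    se = np.std(covs, ddof=1) / np.sqrt(len(covs))
    assert abs(mean_cov - 0.5) < 4 * se + 0.05


def test_allele_substitution_effect_recovered_in_means():
    diffs = []
    for seed in range(20):
        cfg = SimulationConfig(
            seed=seed + 100, n_units=6, offspring_per_family=8,
            beta_length=0, beta_cf=0, beta_feed=0, beta_sex=0,
            beta_vgll3=0.5, beta_six6=0.0,
            V_animal=0.0, V_tank=0, V_ID=0.2, V_error=0.1,
            lower_mode_fraction=0.0, n_missing_vgll3=0, n_missing_six6=0,
            n_missing_sex=0, n_mature_males=0,
        )
        ped, geno = simulate_breeding(cfg)
        table, _ = simulate_traits(ped, geno, cfg)
        per = table.drop_duplicates("id")
        diffs.append(
            per.loc[per["vgll3"] == 2, "synthetic_trait"].mean()
            - per.loc[per["vgll3"] == 0, "synthetic_trait"].mean()
        )
    assert np.mean(diffs) == pytest.approx(1.0, abs=0.1)  # 2 substitutions


def test_landmarks_zero_noise_recover_template():
    cfg = SimulationConfig(seed=8, n_units=2, offspring_per_family=3,
                           beta_vgll3=0.0, replicate_fraction=0.0)
    ped, geno = simulate_breeding(cfg)
    table, _ = simulate_traits(ped, geno, cfg)
    configs = simulate_landmarks(
        table, cfg, planes=("body",), noise_sd=0.0, displacement_locus="none"
    )
    tpl = body_template()
    for c in configs[:5]:
        assert procrustes_distance(c.coords, tpl) < 1e-8


def test_landmark_corruption_flagged():
    cfg = SimulationConfig(seed=9, n_units=4, offspring_per_family=6,
                           replicate_fraction=0.0)
    ped, geno = simulate_breeding(cfg)
    table, _ = simulate_traits(ped, geno, cfg)
    victim = table["id"].iloc[0]
    configs = simulate_landmarks(
        table, cfg, planes=("body",), noise_sd=0.02, corrupt={victim: 2}
    )
    al = generalized_procrustes(configs)
    flags = flag_outlier_configurations(al)
    flagged_ids = {al.ids[k] for k in np.flatnonzero(flags)}
    assert victim in flagged_ids


def test_replicate_fraction_controls_repeat_rows():
    cfg = SimulationConfig(seed=10, n_units=3, offspring_per_family=10,
                           replicate_fraction=1.0)
    ped, geno = simulate_breeding(cfg)
    table, truth = simulate_traits(ped, geno, cfg)
    counts = table.groupby("id")["replicate"].max()
    assert (counts == 2).all()
    assert truth["n_replicated"] == len(counts)
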