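"""Synthetic data with known ground truth for the full pipeline.

The generator mirrors the study's statistical structure: a biallelic
common-garden breeding design (11 two-by-two factorial units, 44
parents, each unit holding one EE and one LL parent of each sex at the
focal *vgll3* locus, so every full-sib family is fixed for one of the
EE/EL/LE/LL offspring genotypes), a second locus (*six6*) segregating
freely, offspring mixed across 8 rearing tanks with feed restriction on
half of them, a bimodal fork-length distribution whose lower mode falls
below the 9-cm analysis threshold, and trait values generated from the
same mixed model the pipeline fits:

    y = mu + b_L L + b_CF CF + b_feed + b_sex + b_v vgll3 + b_s six6
        + a_animal + u_tank + u_ID + e

with a ~ N(0, V_animal A), tank and ID effects i.i.d., and a fresh
error per replicate measurement. Landmark configurations are generated
from per-plane templates with allometric scaling, a per-genotype
displacement field, random rigid transforms and Gaussian digitising
noise, so the upstream readers, GPA and trait extraction can be
exercised end to end against planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .landmarks import LandmarkConfiguration
from .pedigree import Pedigree, additive_relationship_matrix

__all__ = [
    "SimulationConfig",
    "simulate_breeding",
    "simulate_traits",
    "simulate_landmarks",
    "body_template",
    "xsec_template",
]


@dataclass
class SimulationConfig:
    """Ground-truth parameters and design constants for one dataset."""

    seed: int
    n_units: int = 11
    offspring_per_family: int = 21
    n_tanks: int = 8
    # fixed effects (trait units; length/condition enter per SD)
    mu: float = 10.0
    beta_length: float = 0.8
    beta_cf: float = 0.1
    beta_feed: float = -0.3
    beta_sex: float = 0.15
    beta_vgll3: float = -0.42
    beta_six6: float = 0.30
    dominance_vgll3: float = 0.0  # extra heterozygote deviation
    beta_length_x_vgll3: float = 0.0
    beta_length_x_six6: float = 0.0
    # variance components (trait units squared)
    V_animal: float = 0.3
    V_tank: float = 0.1
    V_ID: float = 0.3
    V_error: float = 0.2
    # six6 parental genotype distribution over codes 0/1/2
    six6_parent_probs: tuple[float, float, float] = (0.25, 0.5, 0.25)
    # fork length: bimodal mixture, lower mode below the 9-cm filter
    lower_mode_fraction: float = 0.075
    length_lower_mean: float = 8.0
    length_lower_sd: float = 0.35
    length_upper_mean: float = 12.5
    length_upper_sd: float = 1.2
    length_threshold: float = 9.0  # analysis exclusion threshold (cm)
    condition_mean: float = 1.0
    condition_sd: float = 0.05
    # planted exclusions (beyond the lower length mode)
    n_missing_vgll3: int = 2
    n_missing_six6: int = 12
    n_missing_sex: int = 4
    n_mature_males: int = 19
    replicate_fraction: float = 0.25
    trait_name: str = "synthetic_trait"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for v in (self.V_animal, self.V_tank, self.V_ID, self.V_error):
            if v < 0:
                raise ValueError("variance components must be non-negative")
        if self.n_units < 1:
            raise ValueError("need at least one factorial unit")
        if abs(sum(self.six6_parent_probs) - 1.0) > 1e-9:
            raise ValueError("six6 parent probabilities must sum to 1")

    def ground_truth(self) -> dict:
        return asdict(self)


def simulate_breeding(config: SimulationConfig) -> tuple[Pedigree, pd.DataFrame]:
    """Parents, pedigree and genotypes of the factorial breeding design.

    Per unit: four parents (EE sire, LL sire, EE dam, LL dam at vgll3)
    and four full-sib families covering the EE x EE, EE x LL, LL x EE
    and LL x LL crosses, so each family is fixed for one offspring
    vgll3 genotype. six6 parental genotypes are drawn from the
    configured distribution and transmitted by Mendelian sampling.
    """
    rng = np.random.default_rng(config.seed)
    records: list[tuple[str, str | None, str | None]] = []
    rows: list[dict] = []
    for u in range(config.n_units):
        parents = {}
        for sex, tag in (("male", "sire"), ("female", "dam")):
            for geno, code in (("EE", 0), ("LL", 2)):
                pid = f"U{u:02d}_{tag}_{geno}"
                parents[(tag, geno)] = (pid, code)
                records.append((pid, None, None))
                rows.append(
                    {
                        "id": pid, "sex": sex, "vgll3": code,
                        "six6": int(rng.choice(3, p=config.six6_parent_probs)),
                        "family": None, "is_parent": True, "unit": u,
                    }
                )
        six6_of = {r["id"]: r["six6"] for r in rows if r.get("unit") == u}
        fam = 0
        for sire_geno in ("EE", "LL"):
            for dam_geno in ("EE", "LL"):
                sire, sire_code = parents[("sire", sire_geno)]
                dam, dam_code = parents[("dam", dam_geno)]
                fam_id = f"F{u:02d}_{fam}"
                for k in range(config.offspring_per_family):
                    oid = f"{fam_id}_o{k:03d}"
                    records.append((oid, sire, dam))
                    vg = (
                        rng.binomial(1, sire_code / 2.0)
                        + rng.binomial(1, dam_code / 2.0)
                    )
                    s6 = (
                        rng.binomial(1, six6_of[sire] / 2.0)
                        + rng.binomial(1, six6_of[dam] / 2.0)
                    )
                    rows.append(
                        {
                            "id": oid,
                            "sex": "male" if rng.random() < 0.5 else "female",
                            "vgll3": int(vg), "six6": int(s6),
                            "family": fam_id, "is_parent": False, "unit": u,
                        }
                    )
                fam += 1
    return Pedigree(records), pd.DataFrame(rows)


def simulate_traits(
    pedigree: Pedigree,
    genotypes: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, dict]:
    """Trait table for the offspring plus the ground-truth record.

    Animal effects are drawn jointly with covariance V_animal * A via a
    Cholesky factor of the full pedigree A; tank effects are shared
    within tanks, ID effects are per individual, and a fresh error is
    drawn per measurement row (a configured fraction of individuals is
    measured twice). Fixed effects follow the config; the length and
    condition covariates enter after scaling within the above-threshold
    (upper length mode) individuals, matching how the analysis scales
    covariates on the filtered dataset. Planted exclusions (lower
    length mode, missing genotypes/sex, precociously mature males) are
    disjoint by construction and their counts are recorded in the
    returned ground truth.
    """
    rng = np.random.default_rng(config.seed + 1)
    A = additive_relationship_matrix(pedigree)
    chol = np.linalg.cholesky(A.values + 1e-10 * np.eye(len(A.ids)))
    animal_all = np.sqrt(config.V_animal) * (chol @ rng.standard_normal(len(A.ids)))
    animal = dict(zip(A.ids, animal_all))

    off = genotypes[~genotypes["is_parent"]].reset_index(drop=True).copy()
    n = len(off)
    # rearing design: families spread over tanks with balanced proportions
    off["tank"] = [f"T{k % config.n_tanks}" for k in range(n)]
    restricted = {f"T{k}" for k in range(config.n_tanks // 2)}
    off["feed"] = [
        "restricted" if t in restricted else "ad_libitum" for t in off["tank"]
    ]
    # bimodal fork length
    lower = rng.random(n) < config.lower_mode_fraction
    length = np.where(
        lower,
        rng.normal(config.length_lower_mean, config.length_lower_sd, n),
        rng.normal(config.length_upper_mean, config.length_upper_sd, n),
    )
    length = np.maximum(length, 3.0)
    cf = rng.normal(config.condition_mean, config.condition_sd, n)
    weight = cf * length**3 / 100.0
    off["fork_length"] = length
    off["weight"] = weight
    # the modelled subset is defined by the analysis threshold, not the
    # mixture component, so planted exclusion counts are exact
    upper = length >= config.length_threshold
    ls = (length - length[upper].mean()) / length[upper].std(ddof=1)
    cs = (cf - cf[upper].mean()) / cf[upper].std(ddof=1)

    tank_eff = {
        f"T{k}": rng.normal(0.0, np.sqrt(config.V_tank))
        for k in range(config.n_tanks)
    }
    id_eff = rng.normal(0.0, np.sqrt(config.V_ID), n)
    male = (off["sex"] == "male").to_numpy()
    vg = off["vgll3"].to_numpy(float)
    s6 = off["six6"].to_numpy(float)
    signal = (
        config.mu
        + config.beta_length * ls
        + config.beta_cf * cs
        + config.beta_feed * (off["feed"] == "restricted").to_numpy(float)
        + config.beta_sex * male.astype(float)
        + config.beta_vgll3 * vg
        + config.beta_six6 * s6
        + config.dominance_vgll3 * (vg == 1).astype(float)
        + config.beta_length_x_vgll3 * ls * vg
        + config.beta_length_x_six6 * ls * s6
        + np.array([animal[i] for i in off["id"]])
        + np.array([tank_eff[t] for t in off["tank"]])
        + id_eff
    )

    # disjoint planted exclusions among upper-mode fish
    upper_idx = np.flatnonzero(upper)
    perm = rng.permutation(upper_idx)
    miss_vg = set(perm[: config.n_missing_vgll3])
    k0 = config.n_missing_vgll3
    miss_s6 = set(perm[k0 : k0 + config.n_missing_six6])
    k0 += config.n_missing_six6
    miss_sex = set(perm[k0 : k0 + config.n_missing_sex])
    k0 += config.n_missing_sex
    male_pool = [j for j in perm[k0:] if male[j]]
    mature = set(male_pool[: config.n_mature_males])

    off["mature_male"] = [j in mature for j in range(n)]
    off.loc[list(miss_vg), "vgll3"] = np.nan
    off.loc[list(miss_s6), "six6"] = np.nan
    off.loc[list(miss_sex), "sex"] = np.nan
    off["length"] = ls
    off["condition_factor"] = cs

    repl = rng.random(n) < config.replicate_fraction
    rows = []
    for j in range(n):
        for rep in range(1, 3 if repl[j] else 2):
            row = off.iloc[j].to_dict()
            row["replicate"] = rep
            row[config.trait_name] = signal[j] + rng.normal(
                0.0, np.sqrt(config.V_error)
            )
            rows.append(row)
    table = pd.DataFrame(rows).drop(columns=["is_parent", "unit"])

    truth = config.ground_truth()
    truth.update(
        {
            "animal_effects": animal,
            "tank_effects": tank_eff,
            "n_offspring": n,
            "planted_exclusions": {
                "length_below_min": int((~upper).sum()),
                "missing_vgll3": len(miss_vg),
                "missing_six6": len(miss_s6),
                "missing_sex": len(miss_sex),
                "mature_male": len(mature),
            },
            "n_after_filter": int(
                upper.sum() - len(miss_vg) - len(miss_s6) - len(miss_sex)
                - len(mature)
            ),
            "n_replicated": int(repl.sum()),
        }
    )
    return table, truth


def body_template(n_landmarks: int = 21) -> np.ndarray:
    """Fish-like lateral-body template: points on a tapered ellipse.

    Purely synthetic geometry (no digitised specimen behind it); spans
    roughly 10 cm by 2.4 cm so centroid sizes land in a realistic range.
    """
    t = np.linspace(0.0, 2.0 * np.pi, n_landmarks, endpoint=False)
    x = 5.0 * np.cos(t)
    y = 1.2 * np.sin(t) * (0.6 + 0.4 * (x / 5.0 + 1.0) / 2.0)
    return np.column_stack([x, y])


def xsec_template(n_landmarks: int) -> np.ndarray:
    """Cross-section template: points on an ellipse (synthetic geometry)."""
    t = np.linspace(0.0, 2.0 * np.pi, n_landmarks, endpoint=False)
    return np.column_stack([1.0 * np.cos(t), 0.8 * np.sin(t)])


_TEMPLATES = {
    "body": lambda: body_template(21),
    "small_xsec": lambda: xsec_template(9),
    "large_xsec": lambda: xsec_template(16),
}

#: planted per-unit-vgll3-code displacement field on the body plane:
#: head elongation (anterior landmarks pushed forward), orthogonalised
#: against the similarity modes (translation, scale, rotation) so the
#: planted pattern survives Procrustes superimposition intact
def _body_displacement(n_landmarks: int = 21) -> np.ndarray:
    tpl = body_template(n_landmarks)
    d = np.zeros_like(tpl)
    head = tpl[:, 0] > 3.0  # anterior landmarks
    d[head, 0] = 0.08
    centered = tpl - tpl.mean(axis=0)
    modes = np.stack(
        [
            np.tile([1.0, 0.0], (n_landmarks, 1)).ravel(),  # translation x
            np.tile([0.0, 1.0], (n_landmarks, 1)).ravel(),  # translation y
            centered.ravel(),  # uniform scaling
            np.column_stack([-centered[:, 1], centered[:, 0]]).ravel(),  # rotation
        ]
    )
    flat = d.ravel().astype(float)
    for mode in modes:
        mode = mode / np.linalg.norm(mode)
        flat = flat - (flat @ mode) * mode
    return flat.reshape(n_landmarks, 2)


def simulate_landmarks(
    table: pd.DataFrame,
    config: SimulationConfig,
    planes: tuple[str, ...] = ("body", "small_xsec", "large_xsec"),
    noise_sd: float = 0.02,
    displacement_locus: str = "vgll3",
    corrupt: dict | None = None,
) -> list[LandmarkConfiguration]:
    """Landmark configurations per specimen, plane and replicate.

    Each specimen's configuration is the plane template scaled
    allometrically with its fork length, displaced by the planted
    per-genotype field (body plane only), rigidly rotated and
    translated at random, and jittered with Gaussian digitising noise
    per replicate. ``corrupt`` maps specimen id to a number of
    landmarks to displace by 10 digitising-noise SDs per axis — a
    gross but local error for exercising the outlier filter.
    Replicate structure follows the table's ``replicate`` column.
    """
    rng = np.random.default_rng(config.seed + 2)
    disp = _body_displacement()
    out: list[LandmarkConfiguration] = []
    corrupt = corrupt or {}
    per_spec = table.drop_duplicates(subset=["id"]).set_index("id")
    reps = table.groupby("id")["replicate"].max() if "replicate" in table else None
    for sid, row in per_spec.iterrows():
        scale = row["fork_length"] / 12.5 if "fork_length" in row else 1.0
        code = row.get(displacement_locus, 0)
        code = 0.0 if pd.isna(code) else float(code)
        n_rep = int(reps[sid]) if reps is not None else 1
        for plane in planes:
            tpl = _TEMPLATES[plane]()
            base = tpl * scale
            if plane == "body":
                base = base + code * disp * scale
            for rep in range(1, n_rep + 1):
                ang = rng.uniform(0, 2 * np.pi)
                R = np.array(
                    [[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]]
                )
                coords = base @ R.T + rng.uniform(-5, 5, size=2)
                coords = coords + rng.normal(0.0, noise_sd, coords.shape)
                if sid in corrupt:
                    k = corrupt[sid]
                    coords[:k] = coords[:k] + 10.0 * noise_sd
                out.append(LandmarkConfiguration(str(sid), plane, rep, coords))
    return out
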