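"""Config-driven orchestration: filter -> impute -> GPA -> traits ->
shape MANOVA -> animal models -> variance decomposition.

Every stage reads and writes declared file artifacts under the output
directory, so the pipeline is restartable per stage and two runs with
the same inputs and seed produce byte-identical tables. The three
report tables mirror the study layout: a per-term MANOVA table (term,
df, Pillai, z, p per plane), a per-trait fixed-coefficient table
(coef, SE, p per term), and a per-trait decomposition table (V_A,
%V_A per locus, h2, I_A, % repeatability, each with a 95% CI).
Replicate measurements are averaged for the shape MANOVA but kept as
repeated rows in the univariate mixed models, where they separate the
between-individual (V_ID) and measurement (V_error) variances.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .animal import MixedModelSpec, fit_animal_model, satterthwaite_type3
from .landmarks import read_landmarks, write_landmarks_csv
from .pedigree import additive_relationship_matrix, read_pedigree_csv
from .procrustes import (
    flag_outlier_configurations,
    generalized_procrustes,
    impute_missing_landmarks,
)
from .shape_model import ShapeModelSpec, fit_shape_model, manova_table
from .traits import (
    default_trait_definitions,
    extract_traits,
    filter_individuals,
    fulton_condition_factor,
    load_trait_definitions,
    scale_covariate,
)
from .varcomp import decompose

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]


class PipelineConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    landmarks: list[str]
    pedigree: str
    specimens: str  # covariates + genotypes CSV
    outdir: str
    seed: int
    trait_definitions: str | None = None
    min_length_cm: float = 9.0
    sd_threshold: float = 4.0
    permutations: int = 999
    n_sims: int = 10_000
    n_starts: int = 3
    traits: list[str] | None = None  # subset of trait names to model

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        try:
            return cls(**doc)
        except TypeError as exc:
            raise PipelineConfigError(str(exc)) from None

    def validate(self) -> None:
        if self.seed is None:
            raise PipelineConfigError("seed is mandatory")
        for p in [self.pedigree, self.specimens, *(self.landmarks or [])]:
            if not Path(p).exists():
                raise PipelineConfigError(f"input file not found: {p}")
        if self.trait_definitions and not Path(self.trait_definitions).exists():
            raise PipelineConfigError(
                f"trait definition file not found: {self.trait_definitions}"
            )

    @property
    def out(self) -> Path:
        return Path(self.outdir)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _read_artifact(cfg: PipelineConfig, name: str) -> pd.DataFrame:
    path = cfg.out / name
    if not path.exists():
        raise PipelineConfigError(
            f"stage artifact {name} missing; run the producing stage first"
        )
    return pd.read_csv(path)


def stage_filter(cfg: PipelineConfig) -> pd.DataFrame:
    """Inputs -> specimens_filtered.csv + filter_audit.txt."""
    df = pd.read_csv(cfg.specimens)
    required = {"id", "fork_length", "weight", "feed", "sex", "tank", "vgll3", "six6"}
    missing = required - set(df.columns)
    if missing:
        raise PipelineConfigError(f"specimens CSV lacks columns {sorted(missing)}")
    df["id"] = df["id"].astype(str)
    df["condition_factor_raw"] = fulton_condition_factor(
        df["weight"], df["fork_length"]
    )
    # exclusion rules apply per individual; replicate rows follow their fish
    per_ind = df.drop_duplicates("id")
    kept_ind, audit = filter_individuals(per_ind, min_length_cm=cfg.min_length_cm)
    (cfg.out / "filter_audit.txt").write_text(str(audit) + "\n")
    kept = df[df["id"].isin(set(kept_ind["id"]))].copy()
    # covariates scaled over individuals, then broadcast to rows
    for src, dst in (("fork_length", "length"),
                     ("condition_factor_raw", "condition_factor")):
        scaled = pd.Series(
            scale_covariate(kept_ind[src]), index=kept_ind["id"].to_numpy()
        )
        kept[dst] = kept["id"].map(scaled)
    kept.to_csv(cfg.out / "specimens_filtered.csv", index=False)
    logger.info("filter: %d -> %d individuals", audit.n_in, audit.n_out)
    return kept


def stage_align(cfg: PipelineConfig) -> pd.DataFrame:
    """Impute, GPA, outlier-exclude, re-GPA; -> landmarks_imputed.csv,
    aligned_shapes.csv."""
    keep_ids = set(_read_artifact(cfg, "specimens_filtered.csv")["id"].astype(str))
    configs = []
    for path in cfg.landmarks:
        configs.extend(read_landmarks(path))
    configs = [c for c in configs if c.specimen_id in keep_ids]
    imputed_all, shape_rows = [], []
    for plane in sorted({c.plane for c in configs}):
        sub = [c for c in configs if c.plane == plane]
        complete = [c for c in sub if c.n_missing == 0]
        if len(complete) < 2:
            raise PipelineConfigError(f"plane {plane}: too few complete configurations")
        ref = generalized_procrustes(complete)
        consensus = ref.consensus * float(np.median(ref.centroid_sizes))
        sub = [
            impute_missing_landmarks(c, consensus) if c.n_missing else c
            for c in sub
        ]
        shapes = generalized_procrustes(sub)
        excl = flag_outlier_configurations(shapes, sd_threshold=cfg.sd_threshold)
        n_excl = int(excl.sum())
        if n_excl:
            sub = [c for c, e in zip(sub, excl) if not e]
            shapes = generalized_procrustes(sub)
        imputed_all.extend(sub)
        flat = shapes.flat()
        for i in range(shapes.n):
            row = {
                "id": shapes.ids[i], "plane": plane,
                "replicate": shapes.replicates[i],
                "centroid_size": shapes.centroid_sizes[i],
            }
            row.update({f"s{j}": flat[i, j] for j in range(flat.shape[1])})
            shape_rows.append(row)
        logger.info(
            "align %s: %d configs, %d outlier exclusions", plane, len(sub), n_excl
        )
    # one file per plane: landmark counts differ across planes
    for plane in sorted({c.plane for c in imputed_all}):
        write_landmarks_csv(
            [c for c in imputed_all if c.plane == plane],
            cfg.out / f"landmarks_imputed_{plane}.csv",
        )
    aligned = pd.DataFrame(shape_rows)
    aligned.to_csv(cfg.out / "aligned_shapes.csv", index=False)
    return aligned


def stage_traits(cfg: PipelineConfig) -> pd.DataFrame:
    """landmarks_imputed_<plane>.csv -> traits_by_replicate.csv (cm units)."""
    paths = sorted(cfg.out.glob("landmarks_imputed_*.csv"))
    if not paths:
        raise PipelineConfigError(
            "stage artifact landmarks_imputed_<plane>.csv missing; "
            "run the align stage first"
        )
    configs = []
    for path in paths:
        configs.extend(read_landmarks(path, format="csv"))
    defs = (
        load_trait_definitions(cfg.trait_definitions)
        if cfg.trait_definitions
        else default_trait_definitions()
    )
    tt = extract_traits(configs, defs)
    tt.to_csv(cfg.out / "traits_by_replicate.csv", index=False)
    return tt


# family deliberately last: its dummies absorb any rank deficiency with
# the genotype covariates (vgll3 is constant within full-sib families
# under the factorial breeding design), mirroring how a fixed-effect lm
# drops later aliased columns
_MANOVA_TERMS = ["length", "condition_factor", "feed", "tank", "sex",
                 "vgll3", "six6", "family"]


def stage_manova(cfg: PipelineConfig) -> pd.DataFrame:
    """aligned_shapes.csv + specimens_filtered.csv -> table2 CSV.

    Tank and family enter as fixed dummy-coded terms (the multivariate
    model takes no random effects); replicate shapes are averaged per
    individual first; aliased family levels are merged into the
    reference level before fitting.
    """
    aligned = _read_artifact(cfg, "aligned_shapes.csv")
    aligned["id"] = aligned["id"].astype(str)
    specimens = _read_artifact(cfg, "specimens_filtered.csv")
    specimens["id"] = specimens["id"].astype(str)
    spec_idx = specimens.drop_duplicates("id").set_index("id")
    rows = []
    for plane, sub in aligned.groupby("plane", sort=True):
        # planes have different landmark counts; keep this plane's columns
        shape_cols = [
            c for c in sub.columns
            if c.startswith("s") and c[1:].isdigit() and sub[c].notna().all()
        ]
        mean_shape = sub.groupby("id", sort=False)[shape_cols].mean()
        ids = [i for i in mean_shape.index.astype(str) if i in spec_idx.index]
        y = mean_shape.loc[ids].to_numpy()
        cov = spec_idx.loc[ids].reset_index()
        usable = [
            t for t in _MANOVA_TERMS
            if t in cov.columns and cov[t].astype(str).nunique() > 1
        ]
        from .shape_model import prune_aliased_levels

        cov, _merged = prune_aliased_levels(cov, usable)
        usable = [
            t for t in usable if cov[t].astype(str).nunique() > 1
        ]
        mspec = ShapeModelSpec(
            response=y, covariates=cov, terms=usable,
            permutations=cfg.permutations, seed=cfg.seed,
        )
        tab = manova_table(fit_shape_model(mspec))
        tab.insert(0, "plane", plane)
        rows.append(tab)
    table2 = pd.concat(rows, ignore_index=True)
    table2.to_csv(cfg.out / "table2_shape_manova.csv", index=False,
                  float_format="%.6g")
    return table2


def _model_frame(cfg: PipelineConfig) -> tuple[pd.DataFrame, list[str], object]:
    tt = _read_artifact(cfg, "traits_by_replicate.csv")
    specimens = _read_artifact(cfg, "specimens_filtered.csv")
    tt["id"] = tt["id"].astype(str)
    specimens["id"] = specimens["id"].astype(str)
    merged = tt.merge(specimens.drop_duplicates("id"), on="id", how="inner")
    trait_names = cfg.traits or [
        c for c in tt.columns if c not in ("id", "plane", "replicate")
    ]
    trait_names = [t for t in trait_names if t in merged.columns]
    A = additive_relationship_matrix(read_pedigree_csv(cfg.pedigree))
    return merged, trait_names, A


def stage_fit(cfg: PipelineConfig) -> pd.DataFrame:
    """Per-trait ML mixed models -> table1 CSV (coef, SE, p per term)."""
    merged, trait_names, A = _model_frame(cfg)
    rows = []
    for trait in trait_names:
        sub = merged.dropna(subset=[trait])
        if sub.empty:
            continue
        fit = fit_animal_model(
            sub, A, MixedModelSpec(trait=trait, estimation="ML",
                                   n_starts=cfg.n_starts)
        )
        tests = satterthwaite_type3(fit).set_index("term")
        name_of = {
            fit.coef.index[j]: term
            for term, cols in fit.term_cols.items() for j in cols
        }
        for name in fit.coef.index:
            term = name_of.get(name)
            rows.append(
                {
                    "trait": trait, "term": name,
                    "coef": fit.coef[name], "se": fit.se[name],
                    "p": tests.loc[term, "p"] if term in tests.index else np.nan,
                }
            )
    table1 = pd.DataFrame(rows)
    table1.to_csv(cfg.out / "table1_trait_coefficients.csv", index=False,
                  float_format="%.6g")
    return table1


def stage_decompose(cfg: PipelineConfig) -> pd.DataFrame:
    """REML fits with/without genotype fixed effects -> table3 CSV."""
    merged, trait_names, A = _model_frame(cfg)
    rows = []
    for k, trait in enumerate(trait_names):
        sub = merged.dropna(subset=[trait])
        if sub.empty:
            continue
        full = fit_animal_model(
            sub, A,
            MixedModelSpec(
                trait=trait, fixed=("length", "condition_factor", "feed", "sex"),
                estimation="REML", n_starts=cfg.n_starts,
            ),
        )
        geno = fit_animal_model(
            sub, A, MixedModelSpec(trait=trait, estimation="REML",
                                   n_starts=cfg.n_starts),
        )
        per_ind = sub.drop_duplicates("id")
        dec = decompose(
            full, geno,
            per_ind["vgll3"].dropna().to_numpy(),
            per_ind["six6"].dropna().to_numpy(),
            sub[trait].to_numpy(),
            n_sims=cfg.n_sims, seed=cfg.seed + 100 + k,
        )
        rows.append(dec.to_row())
    table3 = pd.DataFrame(rows)
    table3.to_csv(cfg.out / "table3_variance_decomposition.csv", index=False,
                  float_format="%.6g")
    return table3


STAGES = {
    "filter": stage_filter,
    "align": stage_align,
    "traits": stage_traits,
    "manova": stage_manova,
    "fit": stage_fit,
    "decompose": stage_decompose,
}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage in order; returns the manifest (also written)."""
    cfg.validate()
    cfg.out.mkdir(parents=True, exist_ok=True)
    results = {}
    for name, stage in STAGES.items():
        try:
            results[name] = stage(cfg)
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage {name!r} failed: {exc}"
            ) from exc
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "stage_rows": {k: int(len(v)) for k, v in results.items()},
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(cfg.out.iterdir())
            if p.suffix in (".csv", ".txt")
        },
    }
    (cfg.out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
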