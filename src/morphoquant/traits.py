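"""Trait extraction from landmark configurations, covariate scaling and
the study-design data filters.

Twenty-one linear and centroid-size traits are defined over three body
planes (whole body, small and large cross-sections). Linear traits are
inter-landmark distances in cm measured on the raw (unscaled)
coordinates; centroid-size traits are computed over a designated
landmark subset. Bilateral traits (measured on left and right sides)
are averaged prior to analysis. The default definition set ships as a
YAML config and can be overridden by the user.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .landmarks import LandmarkConfiguration, centroid_size

__all__ = [
    "TraitDefinition",
    "load_trait_definitions",
    "default_trait_definitions",
    "extract_traits",
    "average_replicates",
    "fulton_condition_factor",
    "scale_covariate",
    "filter_individuals",
    "FilterAudit",
]


@dataclass
class TraitDefinition:
    """One trait: a distance, a mean of distances, or a centroid size.

    ``landmarks`` is a list of index pairs for (mean-)distance traits,
    or a list of indices (or ``None`` for all) for centroid-size traits.
    ``bilateral`` marks traits measured on both left and right sides and
    averaged; computationally this is a mean over the listed pairs.
    """

    name: str
    plane: str
    kind: str  # distance | mean_distance | centroid_size
    landmarks: list | None = None
    bilateral: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("distance", "mean_distance", "centroid_size"):
            raise ValueError(f"{self.name}: unknown trait kind {self.kind!r}")
        if self.kind == "distance" and not self.bilateral:
            if self.landmarks is None or len(self.landmarks) != 1:
                raise ValueError(f"{self.name}: distance trait needs one landmark pair")

    def evaluate(self, coords: np.ndarray) -> float:
        coords = np.asarray(coords, float)
        k = coords.shape[0]
        if self.kind == "centroid_size":
            if self.landmarks is None:
                sub = coords
            else:
                idx = np.asarray(self.landmarks, int)
                if idx.max() >= k:
                    raise IndexError(
                        f"trait {self.name}: landmark {idx.max()} absent "
                        f"(plane has {k})"
                    )
                sub = coords[idx]
            return centroid_size(sub)
        dists = []
        for a, b in self.landmarks:
            if max(a, b) >= k:
                raise IndexError(
                    f"trait {self.name}: landmark {max(a, b)} absent (plane has {k})"
                )
            dists.append(float(np.linalg.norm(coords[a] - coords[b])))
        return float(np.mean(dists))


def load_trait_definitions(path) -> list[TraitDefinition]:
    """Load trait definitions from a YAML config (``traits:`` list)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _defs_from_doc(doc)


def _defs_from_doc(doc) -> list[TraitDefinition]:
    defs = []
    for entry in doc["traits"]:
        defs.append(
            TraitDefinition(
                name=entry["name"],
                plane=entry["plane"],
                kind=entry["kind"],
                landmarks=entry.get("landmarks"),
                bilateral=bool(entry.get("bilateral", False)),
            )
        )
    names = [d.name for d in defs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate trait names in definition config")
    return defs


def default_trait_definitions() -> list[TraitDefinition]:
    """The packaged default 21-trait definition set."""
    ref = importlib.resources.files("morphoquant") / "data" / "traits_default.yaml"
    return _defs_from_doc(yaml.safe_load(ref.read_text()))


def extract_traits(
    configs: list[LandmarkConfiguration],
    defs: list[TraitDefinition],
) -> pd.DataFrame:
    """Per-configuration trait values, one row per (id, plane, replicate).

    Configurations must be complete (imputed). Replicate measurements
    are kept as separate rows so downstream mixed models can separate
    between-individual and measurement variance; use
    :func:`average_replicates` where a single value per individual is
    required (as in the shape MANOVA).
    """
    by_plane: dict[str, list[TraitDefinition]] = {}
    for d in defs:
        by_plane.setdefault(d.plane, []).append(d)
    rows = []
    for c in configs:
        if c.n_missing:
            raise ValueError(f"{c.specimen_id}: impute missing landmarks first")
        row: dict = {"id": c.specimen_id, "plane": c.plane, "replicate": c.replicate}
        for d in by_plane.get(c.plane, []):
            row[d.name] = d.evaluate(c.coords)
        rows.append(row)
    return pd.DataFrame(rows)


def average_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Average numeric trait columns over replicates within (id, plane)."""
    keys = [c for c in ("id", "plane") if c in table.columns]
    num = table.select_dtypes(include=[np.number]).columns.difference(["replicate"])
    out = table.groupby(keys, as_index=False, sort=False)[list(num)].mean()
    return out


def fulton_condition_factor(weight_g, length_cm):
    """Fulton's condition factor K = 100 * W / L^3 (W in g, L in cm)."""
    w = np.asarray(weight_g, float)
    l = np.asarray(length_cm, float)
    if np.any(w <= 0) or np.any(l <= 0):
        raise ValueError("weight and length must be strictly positive")
    k = 100.0 * w / l**3
    return float(k) if k.ndim == 0 else k


def scale_covariate(values) -> np.ndarray:
    """Center to zero and scale to unit sample SD (n-1 denominator)."""
    v = np.asarray(values, float)
    if v.size < 2:
        raise ValueError("need at least 2 values to scale")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot scale a constant covariate")
    return (v - v.mean()) / sd


@dataclass
class FilterAudit:
    """Removal counts per filtering rule, in rule application order."""

    counts: dict[str, int] = field(default_factory=dict)
    n_in: int = 0
    n_out: int = 0

    def lines(self) -> list[str]:
        out = [f"rows in: {self.n_in}"]
        out += [f"removed ({rule}): {n}" for rule, n in self.counts.items()]
        out.append(f"rows out: {self.n_out}")
        return out

    def __str__(self) -> str:  # plain-text audit log
        return "\n".join(self.lines())


def filter_individuals(
    table: pd.DataFrame,
    min_length_cm: float = 9.0,
    require: tuple[str, ...] = ("vgll3", "six6", "sex"),
    drop_mature_males: bool = True,
) -> tuple[pd.DataFrame, FilterAudit]:
    """Apply the study's individual-level exclusion rules.

    Rules, in order: fork length strictly below ``min_length_cm``
    (avoids the lower mode of the bimodal juvenile length
    distribution); missing values in each ``require`` column; and
    precociously mature males (rows with a truthy ``mature_male``
    column) when ``drop_mature_males``. Each removed row is counted
    under the first rule it fails; counts sum to rows_in - rows_out.
    """
    audit = FilterAudit(n_in=len(table))
    keep = pd.Series(True, index=table.index)

    def apply_rule(name: str, bad: pd.Series) -> None:
        bad = bad & keep
        audit.counts[name] = int(bad.sum())
        keep[bad] = False

    if "fork_length" in table.columns:
        apply_rule("length_below_min", table["fork_length"] < min_length_cm)
    for col in require:
        if col in table.columns:
            apply_rule(f"missing_{col}", table[col].isna())
        else:
            apply_rule(f"missing_{col}", pd.Series(True, index=table.index))
    if drop_mature_males and "mature_male" in table.columns:
        apply_rule("mature_male", table["mature_male"].fillna(False).astype(bool))
    out = table[keep].copy()
    audit.n_out = len(out)
    return out, audit
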