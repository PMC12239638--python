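"""Landmark configurations and file I/O (TPS and wide CSV).

A configuration is one specimen x body plane x replicate set of 2-D
landmarks in centimetres. Landmark counts are fixed per plane; missing
landmarks are held as NaN (never silently zero-filled) and must be
imputed before Procrustes analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PLANES",
    "LandmarkConfiguration",
    "centroid_size",
    "read_landmarks",
    "write_landmarks_tps",
    "write_landmarks_csv",
]

#: canonical body planes: lateral whole body and the two cross-sections
PLANES = ("body", "small_xsec", "large_xsec")


class LandmarkFormatError(ValueError):
    """Raised for malformed landmark files or inconsistent landmark counts."""


@dataclass
class LandmarkConfiguration:
    specimen_id: str
    plane: str
    replicate: int
    coords: np.ndarray  # (k, 2), NaN rows = missing landmarks

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be a (k, 2) array")
        if self.replicate < 1:
            raise ValueError("replicate index must be >= 1")
        obs = self.observed_mask()
        if obs.sum() < 3:
            raise ValueError(
                f"{self.specimen_id}: fewer than 3 observed landmarks"
            )
        if not np.all(np.isfinite(self.coords[obs])):
            raise ValueError(f"{self.specimen_id}: non-finite coordinates")

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]

    def observed_mask(self) -> np.ndarray:
        return ~np.isnan(self.coords).any(axis=1)

    @property
    def n_missing(self) -> int:
        return int((~self.observed_mask()).sum())


def centroid_size(config: LandmarkConfiguration | np.ndarray) -> float:
    """Square root of summed squared landmark distances from the centroid.

    The standard geometric-morphometrics size measure; requires a
    complete configuration (impute missing landmarks first).
    """
    coords = config.coords if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    if np.isnan(coords).any():
        raise ValueError("centroid size undefined with missing landmarks; impute first")
    centered = coords - coords.mean(axis=0)
    return float(np.sqrt((centered**2).sum()))


def _parse_tps(path) -> list[LandmarkConfiguration]:
    configs: list[LandmarkConfiguration] = []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    i = 0
    rep_counter: dict[tuple[str, str], int] = {}
    while i < len(lines):
        if not lines[i].upper().startswith("LM="):
            raise LandmarkFormatError(f"{path}: expected LM= record at line {i + 1}")
        k = int(lines[i].split("=", 1)[1])
        i += 1
        pts = np.full((k, 2), np.nan)
        for j in range(k):
            fields = lines[i].split()
            if len(fields) != 2:
                raise LandmarkFormatError(f"{path}: bad coordinate line {lines[i]!r}")
            x, y = fields
            # TPS convention: "NA NA" (or 'missing') marks a missing landmark
            if x.upper() not in ("NA", "NAN", "MISSING"):
                pts[j] = (float(x), float(y))
            i += 1
        spec_id, plane, replicate, scale = None, "body", None, 1.0
        while i < len(lines) and "=" in lines[i] and not lines[i].upper().startswith("LM="):
            key, val = lines[i].split("=", 1)
            key = key.strip().upper()
            if key == "ID":
                spec_id = val.strip()
            elif key == "SCALE":
                scale = float(val)
            elif key == "PLANE":  # extension record; absent in classic TPS
                plane = val.strip()
            elif key == "REPLICATE":
                replicate = int(val)
            i += 1
        if spec_id is None:
            raise LandmarkFormatError(f"{path}: TPS block without ID= record")
        if replicate is None:
            rep_counter[(spec_id, plane)] = rep_counter.get((spec_id, plane), 0) + 1
            replicate = rep_counter[(spec_id, plane)]
        configs.append(
            LandmarkConfiguration(spec_id, plane, replicate, pts * scale)
        )
    return configs


def _parse_csv(path) -> list[LandmarkConfiguration]:
    df = pd.read_csv(path)
    meta = [c for c in ("id", "plane", "replicate") if c in df.columns]
    if "id" not in meta:
        raise LandmarkFormatError(f"{path}: wide CSV needs an 'id' column")
    xcols = sorted(
        (c for c in df.columns if c.startswith("x") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    k = len(xcols)
    configs = []
    for _, row in df.iterrows():
        pts = np.full((k, 2), np.nan)
        for j, xc in enumerate(xcols):
            yc = "y" + xc[1:]
            x, y = row.get(xc), row.get(yc)
            if pd.notna(x) and pd.notna(y):
                pts[j] = (float(x), float(y))
        configs.append(
            LandmarkConfiguration(
                str(row["id"]),
                str(row["plane"]) if "plane" in meta else "body",
                int(row["replicate"]) if "replicate" in meta else 1,
                pts,
            )
        )
    return configs


def read_landmarks(path, format: str | None = None) -> list[LandmarkConfiguration]:
    """Read landmark configurations from a TPS or wide-CSV file.

    Format is inferred from the extension when not given. Within each
    plane all configurations must agree on landmark count; a mismatch
    raises :class:`LandmarkFormatError` naming the offending specimen.
    """
    if format is None:
        format = "tps" if str(path).lower().endswith(".tps") else "csv"
    if format == "tps":
        configs = _parse_tps(path)
    elif format == "csv":
        configs = _parse_csv(path)
    else:
        raise ValueError(f"unknown landmark format {format!r}")
    counts: dict[str, int] = {}
    for c in configs:
        k = counts.setdefault(c.plane, c.n_landmarks)
        if c.n_landmarks != k:
            raise LandmarkFormatError(
                f"{path}: specimen {c.specimen_id} plane {c.plane} has "
                f"{c.n_landmarks} landmarks, expected {k}"
            )
    return configs


def write_landmarks_tps(configs, path) -> None:
    """Write configurations as TPS blocks (LM=, coords, ID=, extension records)."""
    with open(path, "w") as fh:
        for c in configs:
            fh.write(f"LM={c.n_landmarks}\n")
            for x, y in c.coords:
                if np.isnan(x) or np.isnan(y):
                    fh.write("NA NA\n")
                else:
                    fh.write(f"{x:.6f} {y:.6f}\n")
            fh.write(f"ID={c.specimen_id}\n")
            fh.write(f"PLANE={c.plane}\n")
            fh.write(f"REPLICATE={c.replicate}\n")


def write_landmarks_csv(configs, path) -> None:
    rows = []
    for c in configs:
        row = {"id": c.specimen_id, "plane": c.plane, "replicate": c.replicate}
        for j, (x, y) in enumerate(c.coords):
            row[f"x{j}"] = x
            row[f"y{j}"] = y
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
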