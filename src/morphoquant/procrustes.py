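"""Generalized Procrustes analysis, landmark imputation and outlier flags.

GPA iteratively removes translation, scale and rotation from a set of
landmark configurations: each configuration is centred, scaled to unit
centroid size (full Procrustes), rotated onto the running consensus by
the SVD-optimal proper rotation, and the consensus recomputed until the
summed squared deviation from the consensus stabilises. The resulting
Procrustes shape variables are the responses of the multivariate shape
models in :mod:`morphoquant.shape_model`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RBFInterpolator

from .landmarks import LandmarkConfiguration, centroid_size

__all__ = [
    "AlignedShapeSet",
    "optimal_rotation",
    "procrustes_distance",
    "generalized_procrustes",
    "impute_missing_landmarks",
    "flag_outlier_configurations",
]


class ProcrustesError(RuntimeError):
    pass


@dataclass
class AlignedShapeSet:
    """Procrustes-aligned configurations plus alignment metadata.

    ``aligned`` has shape (n, k, 2) with every configuration at unit
    centroid size; ``consensus`` is their coordinate-wise mean at
    convergence; ``centroid_sizes`` holds the original sizes in cm.
    """

    ids: list[str]
    planes: list[str]
    replicates: list[int]
    aligned: np.ndarray
    centroid_sizes: np.ndarray
    consensus: np.ndarray
    iterations: int
    objective_trace: list[float] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.aligned.shape[1]

    def flat(self) -> np.ndarray:
        """(n, 2k) matrix of shape variables (x0, y0, x1, y1, ...)."""
        return self.aligned.reshape(self.n, -1)


def optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Kabsch proper rotation R minimising ||source @ R - target||_F.

    Reflections are disallowed (biological landmarks have fixed
    chirality): if the unconstrained optimum is a reflection, the sign
    of the smallest singular vector is flipped.
    """
    u, _, vt = np.linalg.svd(source.T @ target)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, d]) @ vt


def _center_scale(coords: np.ndarray) -> np.ndarray:
    c = coords - coords.mean(axis=0)
    size = np.sqrt((c**2).sum())
    if size == 0:
        raise ProcrustesError("degenerate configuration: all landmarks coincide")
    return c / size


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Full Procrustes distance between two configurations."""
    a = _center_scale(np.asarray(a, float))
    b = _center_scale(np.asarray(b, float))
    r = optimal_rotation(a, b)
    return float(np.sqrt(((a @ r - b) ** 2).sum()))


def _canonical_rotation(consensus: np.ndarray) -> np.ndarray:
    """Proper rotation mapping the consensus to a canonical orientation.

    Aligns the consensus' principal axes with the coordinate axes and
    resolves the remaining pi ambiguity by making the x coordinate of
    the landmark farthest along the first axis positive.
    """
    _, _, vt = np.linalg.svd(consensus, full_matrices=False)
    R = vt.T
    if np.linalg.det(R) < 0:
        R = R @ np.diag([1.0, -1.0])
    rot = consensus @ R
    k = int(np.argmax(np.abs(rot[:, 0])))
    if rot[k, 0] < 0:
        R = R @ np.diag([-1.0, -1.0])  # rotate by pi, stays proper
    return R


def generalized_procrustes(
    configs: list[LandmarkConfiguration],
    tol: float = 1e-8,
    max_iter: int = 100,
) -> AlignedShapeSet:
    """Align complete configurations by iterative GPA.

    All configurations must be complete (no missing landmarks) and share
    a landmark count. Convergence: change in the summed squared
    deviation from the consensus below ``tol``.
    """
    if len(configs) < 2:
        raise ValueError("GPA needs at least 2 configurations")
    k = configs[0].n_landmarks
    for c in configs:
        if c.n_landmarks != k:
            raise ValueError(f"{c.specimen_id}: landmark count mismatch")
        if c.n_missing:
            raise ValueError(
                f"{c.specimen_id}: has missing landmarks; impute before GPA"
            )
    sizes = np.array([centroid_size(c) for c in configs])
    shapes = np.stack([_center_scale(c.coords) for c in configs])
    consensus = _center_scale(shapes.mean(axis=0))
    trace: list[float] = []
    prev_obj = np.inf
    for it in range(1, max_iter + 1):
        for i in range(shapes.shape[0]):
            shapes[i] = shapes[i] @ optimal_rotation(shapes[i], consensus)
        consensus = _center_scale(shapes.mean(axis=0))
        obj = float(((shapes - consensus) ** 2).sum())
        trace.append(obj)
        if prev_obj - obj < tol:
            break
        prev_obj = obj
    else:
        raise ProcrustesError(
            f"GPA did not converge in {max_iter} iterations; trace={trace}"
        )
    # canonical orientation: principal axes of the consensus on x/y, with a
    # deterministic sign rule, so the solution does not inherit the
    # arbitrary orientation of the inputs
    R = _canonical_rotation(consensus)
    consensus = consensus @ R
    shapes = shapes @ R
    return AlignedShapeSet(
        ids=[c.specimen_id for c in configs],
        planes=[c.plane for c in configs],
        replicates=[c.replicate for c in configs],
        aligned=shapes,
        centroid_sizes=sizes,
        consensus=consensus,
        iterations=it,
        objective_trace=trace,
    )


def impute_missing_landmarks(
    config: LandmarkConfiguration, reference: AlignedShapeSet | np.ndarray
) -> LandmarkConfiguration:
    """Fill missing landmarks by thin-plate-spline warp of the consensus.

    A TPS interpolant is fitted mapping the reference (consensus)
    positions of the observed landmarks onto the specimen's observed
    coordinates, and the missing positions are read off the warp.
    TPS reproduces affine maps exactly, so a specimen that is an affine
    image of the consensus is imputed without error. Observed landmarks
    are never altered.
    """
    obs = config.observed_mask()
    if obs.all():
        return config
    if obs.sum() < 3:
        raise ValueError(
            f"{config.specimen_id}: too few observed landmarks to impute"
        )
    ref = reference.consensus if isinstance(reference, AlignedShapeSet) else np.asarray(reference, float)
    if ref.shape != config.coords.shape:
        raise ValueError("reference consensus shape mismatch")
    coords = config.coords.copy()
    warp = RBFInterpolator(
        ref[obs], coords[obs], kernel="thin_plate_spline", degree=1
    )
    coords[~obs] = warp(ref[~obs])
    return LandmarkConfiguration(
        config.specimen_id, config.plane, config.replicate, coords
    )


def flag_outlier_configurations(
    shapes: AlignedShapeSet, sd_threshold: float = 4.0, max_outliers: int = 1
) -> np.ndarray:
    """Exclusion flags for configurations with too many outlier landmarks.

    Per landmark, the Euclidean deviation of every aligned configuration
    from the consensus landmark is computed; the landmark's scatter SD
    is the root-mean-square of those deviations (the SD of the 2-D
    scatter about its mean position). A landmark is an outlier when its
    deviation exceeds ``sd_threshold`` times that SD; a configuration is
    flagged for exclusion iff it carries more than ``max_outliers``
    outlier landmarks (i.e. >= 2 at the default), mirroring the "more
    than one landmark > 4 SD from the mean" rule.
    """
    if shapes.n == 0:
        return np.zeros(0, dtype=bool)
    dev = shapes.aligned - shapes.consensus  # (n, k, 2)
    dist = np.sqrt((dev**2).sum(axis=2))  # (n, k)
    sd = np.sqrt((dist**2).mean(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        outlier = dist > sd_threshold * sd
    return outlier.sum(axis=1) > max_outliers
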