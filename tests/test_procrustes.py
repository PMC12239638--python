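import numpy as np
import pytest

from morphoquant.landmarks import LandmarkConfiguration
from morphoquant.procrustes import (
    flag_outlier_configurations,
    generalized_procrustes,
    impute_missing_landmarks,
    optimal_rotation,
    procrustes_distance,
)


def _cfg(coords, sid="s", plane="body", rep=1):
    return LandmarkConfiguration(sid, plane, rep, np.asarray(coords, float))


def _similarity(coords, angle, scale, shift):
    R = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
    return coords @ R.T * scale + shift


@pytest.fixture
def noisy_set(rng):
    base = rng.standard_normal((10, 2)) * 2
    out = []
    for i in range(25):
        c = _similarity(
            base + rng.normal(0, 0.03, base.shape),
            rng.uniform(0, 2 * np.pi), rng.uniform(0.5, 2.0),
            rng.uniform(-5, 5, 2),
        )
        out.append(_cfg(c, f"s{i}"))
    return base, out


def test_identical_up_to_similarity_gives_zero_distance(rng):
    base = rng.standard_normal((8, 2))
    moved = _similarity(base, 1.1, 3.0, np.array([4.0, -2.0]))
    assert procrustes_distance(base, moved) == pytest.approx(0.0, abs=1e-10)


def test_gpa_unit_sizes_and_monotone_objective(noisy_set):
    _, configs = noisy_set
    al = generalized_procrustes(configs)
    sizes = np.sqrt((al.aligned**2).sum(axis=(1, 2)))
    assert np.allclose(sizes, 1.0, atol=1e-12)
    assert np.all(np.diff(al.objective_trace) <= 1e-12)
    assert np.allclose(al.consensus, al.aligned.mean(axis=0) /
                       np.sqrt((al.aligned.mean(axis=0)**2).sum()), atol=1e-8)


def test_gpa_invariant_to_input_similarity_transform(noisy_set, rng):
    _, configs = noisy_set
    al1 = generalized_procrustes(configs)
    configs2 = list(configs)
    configs2[3] = _cfg(
        _similarity(configs[3].coords, 2.2, 0.25, np.array([9.0, 9.0])), "s3"
    )
    al2 = generalized_procrustes(configs2)
    assert np.allclose(al1.aligned, al2.aligned, atol=1e-8)


def test_gpa_two_config_consensus_matches_pairwise_opa(rng):
    # with 2 shapes the consensus is the midpoint of the Kabsch-aligned pair
    a = rng.standard_normal((7, 2))
    b = a + rng.normal(0, 0.1, a.shape)
    al = generalized_procrustes([_cfg(a, "a"), _cfg(b, "b")])

    def unit(x):
        x = x - x.mean(0)
        return x / np.sqrt((x**2).sum())

    ua, ub = unit(a), unit(b)
    ub_rot = ub @ optimal_rotation(ub, ua)
    midpoint = unit((ua + ub_rot) / 2)
    d = min(
        np.abs(al.consensus - midpoint @ optimal_rotation(midpoint, al.consensus)).max(),
        np.abs(al.consensus - midpoint).max(),
    )
    assert d < 1e-6


def test_gpa_rejects_missing_and_single():
    good = _cfg(np.eye(2).repeat(2, 0) + np.arange(4)[:, None])
    with pytest.raises(ValueError):
        generalized_procrustes([good])
    bad = _cfg([[0, 0], [1, 0], [0, 1], [np.nan, np.nan]])
    with pytest.raises(ValueError, match="impute"):
        generalized_procrustes([good, bad])


def test_rotations_are_proper(rng):
    # reflected configuration must be aligned by rotation only (det +1)
    a = rng.standard_normal((6, 2))
    b = a.copy()
    b[:, 0] *= -1
    R = optimal_rotation(a, b)
    assert np.linalg.det(R) == pytest.approx(1.0)


def test_impute_identity_when_complete(noisy_set):
    base, configs = noisy_set
    al = generalized_procrustes(configs)
    out = impute_missing_landmarks(configs[0], al)
    assert out is configs[0]


def test_impute_exact_for_consensus_and_affine(noisy_set, rng):
    _, configs = noisy_set
    al = generalized_procrustes(configs)
    # specimen equal to the consensus with one landmark deleted
    coords = al.consensus.copy()
    coords[4] = np.nan
    imp = impute_missing_landmarks(_cfg(coords, "c"), al)
    assert np.allclose(imp.coords[4], al.consensus[4], atol=1e-6)
    # affine image of the consensus: TPS reproduces affine maps exactly
    Aff = np.array([[1.3, 0.4], [-0.2, 0.8]])
    warped = al.consensus @ Aff.T + np.array([0.5, -1.0])
    coords = warped.copy()
    coords[7] = np.nan
    imp = impute_missing_landmarks(_cfg(coords, "w"), al)
    assert np.allclose(imp.coords[7], warped[7], atol=1e-8)
    assert np.allclose(np.delete(imp.coords, 7, 0), np.delete(warped, 7, 0))


def test_impute_needs_three_observed():
    coords = np.array([[0, 0], [1, 0], [0, 1], [np.nan, np.nan]], float)
    cfg = _cfg(coords)
    ref = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], float)
    out = impute_missing_landmarks(cfg, ref)
    assert out.n_missing == 0
    with pytest.raises(ValueError):
        impute_missing_landmarks(
            _cfg([[0, 0], [1, 0], [0, 1], [np.nan, np.nan]]), np.zeros((3, 2))
        )


def test_outlier_rule_two_landmarks_excluded_one_retained(rng):
    base = rng.standard_normal((12, 2)) * 3
    configs = [_cfg(base + rng.normal(0, 0.02, base.shape), f"s{i}")
               for i in range(200)]
    # null: homogeneous digitising noise -> essentially no exclusions at 4 SD
    al = generalized_procrustes(configs)
    assert flag_outlier_configurations(al).sum() <= 1
    # one configuration with two grossly displaced landmarks -> excluded
    bad2 = base.copy()
    bad2[0] += 10 * 0.02
    bad2[1] += 10 * 0.02
    # one configuration with exactly one displaced landmark -> retained
    bad1 = base.copy()
    bad1[5] += 10 * 0.02
    al2 = generalized_procrustes(configs + [_cfg(bad2, "bad2"), _cfg(bad1, "bad1")])
    flags = flag_outlier_configurations(al2)
    assert flags[-2] and not flags[-1]


class _EmptyShapes:
    n = 0
    aligned = np.zeros((0, 3, 2))
    consensus = np.zeros((3, 2))


def test_outlier_empty_set():
    assert flag_outlier_configurations(_EmptyShapes()).size == 0
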