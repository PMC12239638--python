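import numpy as np
import pandas as pd
import pytest

from morphoquant.landmarks import LandmarkConfiguration
from morphoquant.traits import (
    TraitDefinition,
    average_replicates,
    default_trait_definitions,
    extract_traits,
    filter_individuals,
    fulton_condition_factor,
    scale_covariate,
)
from morphoquant.animal import composite_trait


def _cfg(coords, sid="s", plane="body", rep=1):
    return LandmarkConfiguration(sid, plane, rep, np.asarray(coords, float))


def test_distance_trait_three_four_five():
    d = TraitDefinition("hyp", "body", "distance", [[0, 1]])
    coords = np.array([[0, 0], [3, 4], [1, 1]], float)
    assert d.evaluate(coords) == pytest.approx(5.0)


def test_bilateral_trait_averages_sides():
    d = TraitDefinition(
        "bi", "body", "mean_distance", [[0, 1], [2, 3]], bilateral=True
    )
    coords = np.array([[0, 0], [1, 0], [0, 0], [2, 0]], float)  # left 1, right 2
    assert d.evaluate(coords) == pytest.approx(1.5)


def test_centroid_size_trait_subset():
    d = TraitDefinition("cs", "body", "centroid_size", [0, 1, 2, 3])
    coords = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [9, 9]], float)
    assert d.evaluate(coords) == pytest.approx(np.sqrt(2))


def test_trait_referencing_absent_landmark_errors():
    d = TraitDefinition("bad", "body", "distance", [[0, 7]])
    with pytest.raises(IndexError, match="bad"):
        d.evaluate(np.zeros((3, 2)))


def test_default_definitions_cover_21_traits():
    defs = default_trait_definitions()
    assert len(defs) == 21
    assert len({d.name for d in defs}) == 21
    assert {d.plane for d in defs} == {"body", "small_xsec", "large_xsec"}


def test_extract_traits_keeps_replicate_rows():
    defs = [TraitDefinition("seg", "body", "distance", [[0, 1]])]
    configs = [
        _cfg([[0, 0], [1, 0], [0, 1]], "a", rep=1),
        _cfg([[0, 0], [2, 0], [0, 1]], "a", rep=2),
        _cfg([[0, 0], [4, 0], [0, 1]], "b", rep=1),
    ]
    tt = extract_traits(configs, defs)
    assert len(tt) == 3
    avg = average_replicates(tt)
    assert avg.loc[avg["id"] == "a", "seg"].iloc[0] == pytest.approx(1.5)


@pytest.mark.parametrize(
    "w,l,k", [(10, 10, 1.0), (1.25, 5, 1.0), (2, 10, 0.2)]
)
def test_fulton_condition_factor(w, l, k):
    assert fulton_condition_factor(w, l) == pytest.approx(k)


def test_fulton_rejects_nonpositive():
    with pytest.raises(ValueError):
        fulton_condition_factor(0.0, 10.0)


def test_scale_covariate():
    assert np.allclose(scale_covariate([1, 2, 3]), [-1, 0, 1])
    assert np.allclose(scale_covariate([10, 20]),
                       [-np.sqrt(0.5), np.sqrt(0.5)])
    z = scale_covariate(np.random.default_rng(0).normal(3, 2, 50))
    assert np.allclose(scale_covariate(z), z, atol=1e-12)  # idempotent
    with pytest.raises(ValueError):
        scale_covariate([5.0, 5.0, 5.0])


def _spec_table():
    return pd.DataFrame(
        {
            "id": list("abcdef"),
            "fork_length": [8.9, 9.0, 9.1, 12.0, 13.0, 10.0],
            "vgll3": [1, 1, np.nan, 0, 2, 1],
            "six6": [0, 1, 1, np.nan, 2, 1],
            "sex": ["male", "female", "male", "male", None, "female"],
            "mature_male": [False, False, False, False, False, True],
        }
    )


def test_filter_rules_and_audit():
    out, audit = filter_individuals(_spec_table())
    # a: length 8.9 < 9 (strict); c: missing vgll3; d: missing six6;
    # e: missing sex; f: mature male; only b survives
    assert list(out["id"]) == ["b"]
    assert audit.counts == {
        "length_below_min": 1, "missing_vgll3": 1, "missing_six6": 1,
        "missing_sex": 1, "mature_male": 1,
    }
    assert sum(audit.counts.values()) == audit.n_in - audit.n_out
    assert "removed (length_below_min): 1" in str(audit)


def test_filter_boundary_is_strict():
    t = _spec_table().iloc[:3].copy()
    t["vgll3"] = 1
    t["six6"] = 1
    t["sex"] = "male"
    out, audit = filter_individuals(t)
    assert list(out["fork_length"]) == [9.0, 9.1]


def test_filter_identity_when_all_pass():
    t = _spec_table().iloc[[3]].copy()
    t["six6"] = 1.0
    out, audit = filter_individuals(t)
    pd.testing.assert_frame_equal(out, t)
    assert audit.n_in == audit.n_out == 1


def test_composite_trait():
    rng = np.random.default_rng(2)
    t = pd.DataFrame({"a": rng.normal(5, 2, 400), "b": rng.normal(-1, 0.5, 400)})
    t["twin"] = t["a"] * 3 + 1  # perfectly correlated with a
    comp = composite_trait(t, ["a", "twin"])
    za = (t["a"] - t["a"].mean()) / t["a"].std(ddof=1)
    assert np.allclose(comp, za)  # identical traits -> the shared z-score
    comp2 = composite_trait(t, ["a", "b"])
    rho = t["a"].corr(t["b"])
    assert comp2.var(ddof=1) == pytest.approx((1 + rho) / 2)
    t.loc[0, "a"] = np.nan
    assert np.isnan(composite_trait(t, ["a", "b"]).iloc[0])
    with pytest.raises(ValueError):
        composite_trait(t, ["a"])
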