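from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from netdissim import (
    DistanceMatrix,
    absolute_difference_distance,
    binary_membership_distance,
    build_predictor_matrices,
    environmental_distance,
    expand_to_networks,
    gower_mixed_distance,
    haversine_distance,
    methods_distance,
    pcoa,
    vectorize_lower_triangle,
)
from netdissim.distmat import EARTH_RADIUS_KM, devectorize_lower_triangle


class TestDistanceMatrixType:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(("a", "b"), np.array([[0, 1], [2, 0.0]]))
        with pytest.raises(ValueError, match="diagonal"):
            DistanceMatrix(("a", "b"), np.array([[1, 1], [1, 0.0]]))
        with pytest.raises(ValueError, match="binary"):
            DistanceMatrix(("a", "b"), np.array([[0, 0.5], [0.5, 0]]), kind="binary")

    def test_csv_round_trip(self, tmp_path):
        dm = DistanceMatrix(("a", "b", "c"), squareform([1.0, 2.0, 3.0]))
        dm.to_csv(tmp_path / "d.csv")
        back = DistanceMatrix.from_csv(tmp_path / "d.csv")
        assert back.labels == dm.labels
        assert np.allclose(back.values, dm.values)


class TestBinaryMembership:
    def test_same_and_distinct(self):
        dm = binary_membership_distance({"n1": "E1", "n2": "E1", "n3": "E2"})
        assert dm.value("n1", "n2") == 0
        assert dm.value("n1", "n3") == 1 and dm.value("n2", "n3") == 1

    def test_all_same_region_zero_matrix(self):
        dm = binary_membership_distance({"a": "E", "b": "E"})
        assert not dm.values.any()

    def test_nesting_same_ecoregion_implies_same_biome(self):
        meta = {"n1": ("E1", "B1"), "n2": ("E1", "B1"), "n3": ("E2", "B1"), "n4": ("E3", "B2")}
        eco = binary_membership_distance({k: v[0] for k, v in meta.items()})
        bio = binary_membership_distance({k: v[1] for k, v in meta.items()})
        same_eco = eco.values == 0
        assert (bio.values[same_eco] == 0).all()


class TestEnvironmentalDistance:
    def _table(self):
        rng = np.random.default_rng(0)
        return pd.DataFrame(
            rng.normal(0, 1, (6, 6)),
            columns=["mat", "tseas", "rain", "rseas", "slope", "footprint"],
            index=[f"E{i}" for i in range(6)],
        )

    def test_identical_rows_distance_zero(self):
        env = self._table()
        env.iloc[1] = env.iloc[0]
        dm = environmental_distance(env, n_components=4)
        assert dm.values[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_all_components_equal_zscore_euclidean(self):
        env = self._table()
        dm = environmental_distance(env, n_components=5)
        Z = (env - env.mean()) / env.std(ddof=1)
        expect = squareform(pdist(Z.to_numpy()))
        assert np.allclose(dm.values, expect, atol=1e-8)

    def test_single_informative_variable(self):
        env = self._table()
        env.iloc[:, 1:] = 1.0  # constant -> dropped
        with pytest.warns(UserWarning, match="constant"):
            dm = environmental_distance(env, n_components=1)
        z = (env.iloc[:, 0] - env.iloc[:, 0].mean()) / env.iloc[:, 0].std(ddof=1)
        expect = np.abs(z.to_numpy()[:, None] - z.to_numpy()[None, :])
        assert np.allclose(dm.values, expect, atol=1e-8)

    def test_expand_to_networks_lookup(self):
        region = DistanceMatrix(("E1", "E2"), np.array([[0, 3.0], [3.0, 0]]))
        dm = expand_to_networks(region, {"n1": "E1", "n2": "E1", "n3": "E2"})
        assert dm.value("n1", "n2") == 0.0
        assert dm.value("n1", "n3") == 3.0 and dm.value("n2", "n3") == 3.0

    def test_env_expansion_consistent_with_binary_zeros(self):
        env = self._table()
        memberships = {f"n{i}": f"E{i % 3}" for i in range(9)}
        region = environmental_distance(env.iloc[:3])
        quant = expand_to_networks(region, memberships)
        binary = binary_membership_distance(memberships)
        assert (quant.values[binary.values == 0] == 0).all()


class TestScalarAndSpatial:
    def test_absolute_difference(self):
        dm = absolute_difference_distance({"a": 3.0, "b": 7.0, "c": 7.0})
        assert dm.value("a", "b") == 4.0 and dm.value("b", "c") == 0.0

    def test_missing_values_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="missing"):
            dm = absolute_difference_distance({"a": 1.0, "b": np.nan, "c": 2.0})
        assert set(dm.labels) == {"a", "c"}

    def test_haversine_analytic_points(self):
        dm = haversine_distance({"o": (0, 0), "anti": (0, 180), "pole": (90, 0)})
        assert dm.value("o", "anti") == pytest.approx(np.pi * EARTH_RADIUS_KM, rel=1e-9)
        assert dm.value("o", "pole") == pytest.approx(np.pi * EARTH_RADIUS_KM / 2, rel=1e-9)

    def test_haversine_triangle_inequality(self):
        rng = np.random.default_rng(1)
        coords = {
            f"s{i}": (rng.uniform(-90, 90), rng.uniform(-180, 180)) for i in range(12)
        }
        v = haversine_distance(coords).values
        n = len(coords)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert v[i, j] <= v[i, k] + v[k, j] + 1e-6

    def test_invalid_coordinates_rejected(self):
        with pytest.raises(ValueError):
            haversine_distance({"a": (95.0, 0.0), "b": (0.0, 0.0)})


class TestGower:
    def test_identical_rows_zero(self):
        t = pd.DataFrame({"a": ["x", "x"], "b": [1.0, 1.0]})
        assert gower_mixed_distance(t).values[0, 1] == 0.0

    def test_all_categorical_total_mismatch(self):
        t = pd.DataFrame({"a": ["x", "y"], "b": ["u", "v"]})
        assert gower_mixed_distance(t).values[0, 1] == 1.0

    def test_mixed_half_range(self):
        t = pd.DataFrame({"cat": ["x", "x"], "num": [0.0, 1.0]}, index=["r1", "r2"])
        t.loc["r3"] = ["x", 2.0]
        dm = gower_mixed_distance(t)
        # categorical match (0) + quantitative at half range (0.5) -> 0.25
        assert dm.value("r1", "r2") == pytest.approx(0.25)

    def test_bounded_unit_interval(self):
        rng = np.random.default_rng(2)
        t = pd.DataFrame(
            {
                "c1": rng.choice(list("abc"), 10),
                "c2": rng.choice(list("uv"), 10),
                "n1": rng.normal(0, 5, 10),
            }
        )
        v = gower_mixed_distance(t).values
        assert (v >= 0).all() and (v <= 1 + 1e-12).all()


class TestPcoa:
    def test_recovers_euclidean_configuration(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(0, 2, (7, 2))
        dm = DistanceMatrix(tuple(f"s{i}" for i in range(7)), squareform(pdist(pts)))
        coords = pcoa(dm, 2).to_numpy()
        assert np.allclose(squareform(pdist(coords)), dm.values, atol=1e-8)

    def test_two_points_single_axis(self):
        dm = DistanceMatrix(("a", "b"), np.array([[0, 4.0], [4.0, 0]]))
        coords = pcoa(dm, 1).to_numpy().ravel()
        assert sorted(coords) == pytest.approx([-2.0, 2.0])

    def test_axis_count_error_names_limit(self):
        dm = DistanceMatrix(("a", "b"), np.array([[0, 4.0], [4.0, 0]]))
        with pytest.raises(ValueError, match="1 positive"):
            pcoa(dm, 3)

    def test_matches_skbio_reference(self):
        """Cross-check classical scaling against scikit-bio's PCoA."""
        from skbio.stats.ordination import pcoa as skbio_pcoa
        from skbio import DistanceMatrix as SkbioDM

        rng = np.random.default_rng(4)
        pts = rng.normal(0, 1, (8, 3))
        d = squareform(pdist(pts))
        mine = pcoa(DistanceMatrix(tuple(f"s{i}" for i in range(8)), d), 3).to_numpy()
        ref = skbio_pcoa(SkbioDM(d), method="eigh").samples.to_numpy()[:, :3]
        # axes are sign/rotation-free only up to reflection; compare distances
        assert np.allclose(squareform(pdist(mine)), squareform(pdist(ref)), atol=1e-8)


class TestMethodsDistance:
    def _methods(self):
        return pd.DataFrame(
            {
                "method_design": ["t", "t", "p", "p"],
                "method_focus": ["z", "z", "f", "f"],
                "method_frequency_type": ["v", "v", "w", "w"],
                "method_coverage": ["tot", "tot", "par", "par"],
            },
            index=[f"n{i}" for i in range(4)],
        )

    def test_identical_rows_zero(self):
        dm = methods_distance(self._methods())
        assert dm.value("n0", "n1") == pytest.approx(0.0, abs=1e-9)

    def test_two_classes_two_valued(self):
        dm = methods_distance(self._methods())
        cross = dm.value("n0", "n2")
        assert cross > 0
        assert dm.value("n1", "n3") == pytest.approx(cross, abs=1e-9)

    def test_column_order_invariant(self):
        m = self._methods()
        a = methods_distance(m)
        b = methods_distance(m[list(m.columns)[::-1]])
        assert np.allclose(a.values, b.values, atol=1e-9)


class TestVectorize:
    def test_length_and_round_trip(self):
        rng = np.random.default_rng(5)
        n = 7
        v0 = squareform(rng.random(n * (n - 1) // 2))
        dm = DistanceMatrix(tuple(f"s{i}" for i in range(n)), v0)
        vec, pairs = vectorize_lower_triangle(dm)
        assert vec.size == n * (n - 1) // 2 == len(pairs)
        back = devectorize_lower_triangle(vec, sorted(dm.labels))
        assert np.allclose(back.values, dm.reindex(sorted(dm.labels)).values)

    def test_label_mismatch_error(self):
        dm = DistanceMatrix(("a", "b"), np.array([[0, 1.0], [1.0, 0]]))
        with pytest.raises(ValueError, match="mismatch"):
            vectorize_lower_triangle(dm, ["a", "c"])

    def test_196_labels_gives_19110_pairs(self):
        n = 196
        dm = DistanceMatrix(
            tuple(f"s{i:03d}" for i in range(n)), np.zeros((n, n))
        )
        vec, pairs = vectorize_lower_triangle(dm)
        assert vec.size == 19110


class TestBuildPredictors:
    def test_standard_set_from_metadata(self, small_dataset):
        preds = build_predictor_matrices(small_dataset.metadata)
        assert set(preds) == {
            "ecoregion", "biome", "footprint", "spatial", "elevation",
            "hours", "months", "years", "intensity", "methods",
        }
        n = len(small_dataset.metadata)
        for dm in preds.values():
            assert dm.n == n
        assert preds["ecoregion"].kind == "binary"
        assert preds["spatial"].kind == "quantitative"
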