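"""Weighted Voronoi units, layers, the six structure indices, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import _oracles as oracle
from conftest import random_tree_frame, random_unit
from standalloc import structure, synthetic
from standalloc.structure import PlotGeometry


def frame(xy, height=None, dbh=None, cw=None):
    n = len(xy)
    xy = np.asarray(xy, dtype=float)
    return pd.DataFrame(
        {
            "tree_id": np.arange(1, n + 1),
            "x": xy[:, 0],
            "y": xy[:, 1],
            "height": height if height is not None else np.full(n, 15.0),
            "dbh": dbh if dbh is not None else np.full(n, 20.0),
            "crown_width": cw if cw is not None else np.full(n, 3.0),
        }
    )


class TestWeights:
    def test_identical_trees_uniform_weight_one(self):
        trees = frame([(5, 5), (10, 10), (15, 15)])
        np.testing.assert_allclose(structure.compute_weights(trees), 1.0)

    def test_dominant_tree_has_maximal_weight(self):
        trees = frame([(5, 5), (15, 15)], height=[10, 20], dbh=[15, 30], cw=[2, 4])
        w = structure.compute_weights(trees)
        assert w[1] == w.max() == 1.5
        assert w[0] == 0.5

    def test_matches_independent_recomputation(self):
        rng = np.random.default_rng(3)
        trees = random_tree_frame(rng, 10)
        w = structure.compute_weights(trees)
        attrs = trees[["height", "dbh", "crown_width"]].to_numpy()
        expect = []
        for row in attrs:
            norms = [
                (row[k] - attrs[:, k].min()) / (attrs[:, k].max() - attrs[:, k].min())
                for k in range(3)
            ]
            expect.append(0.5 + np.mean(norms))
        np.testing.assert_allclose(w, expect, atol=1e-12)


class TestWeightedVoronoi:
    def test_two_trees_single_pair_boundary_near_lighter(self):
        trees = frame([(8.0, 12.91), (18.0, 12.91)])
        labels, adj = structure.weighted_voronoi(trees, weights=np.array([0.6, 1.4]))
        assert adj == {(0, 1)}
        # heavier tree claims more ground
        assert (labels == 1).sum() > (labels == 0).sum()

    def test_three_collinear_outer_pair_not_adjacent(self):
        trees = frame([(4.0, 12.91), (12.91, 12.91), (21.0, 12.91)])
        _, adj = structure.weighted_voronoi(trees, weights=np.ones(3))
        assert (0, 1) in adj and (1, 2) in adj
        assert (0, 2) not in adj

    def test_each_tree_owns_its_position(self):
        rng = np.random.default_rng(8)
        trees = random_tree_frame(rng, 25)
        labels, _ = structure.weighted_voronoi(trees)
        from standalloc.raster import CHMRaster

        # reuse the raster pixel convention used internally
        nr = labels.shape[0]
        for i, (x, y) in enumerate(trees[["x", "y"]].to_numpy()):
            r = nr - 1 - int(y / 0.1)
            c = int(x / 0.1)
            assert labels[r, c] == i

    def test_coincident_positions_rejected(self):
        trees = frame([(5, 5), (5, 5), (10, 10)])
        with pytest.raises(ValueError, match="coincident"):
            structure.weighted_voronoi(trees)

    def test_equal_weights_match_geometry_oracle(self):
        mism, union = 0, 0
        for seed in (0, 1, 3):
            rng = np.random.default_rng(seed)
            trees = random_tree_frame(rng, 30)
            _, adj = structure.weighted_voronoi(trees, weights=np.ones(30))
            ref = oracle.clipped_voronoi_adjacency(trees[["x", "y"]].to_numpy(), 25.82, 25.82)
            mism += len(adj ^ ref)
            union += len(adj | ref)
        assert 1 - mism / union >= 0.99

    def test_adjacency_stable_under_resolution_refinement(self):
        rng = np.random.default_rng(12)
        trees = random_tree_frame(rng, 30)
        _, coarse = structure.weighted_voronoi(trees, resolution=0.1)
        _, fine = structure.weighted_voronoi(trees, resolution=0.05)
        assert len(coarse ^ fine) <= 0.02 * len(coarse | fine)


class TestStructuralUnits:
    def test_regular_grid_center_has_von_neumann_neighbors(self):
        coords = [(x, y) for y in (6.91, 12.91, 18.91) for x in (6.91, 12.91, 18.91)]
        trees = frame(coords)
        _, adj = structure.weighted_voronoi(trees, weights=np.ones(9))
        units = structure.structural_units(adj, trees)
        center = next(u for u in units if u.center_id == 5)
        assert set(center.neighbor_ids) == {2, 4, 6, 8}

    def test_buffer_trees_never_centers(self):
        trees = frame([(1.0, 1.0), (10.0, 10.0), (12.0, 14.0), (16.0, 10.0)])
        _, adj = structure.weighted_voronoi(trees)
        units = structure.structural_units(adj, trees, PlotGeometry())
        ids = {u.center_id for u in units}
        assert 1 not in ids  # inside the 2.91 m edge buffer
        assert ids == {2, 3, 4}
        # the buffer tree still serves as a neighbour
        assert any(1 in u.neighbor_ids for u in units)

    def test_azimuth_convention_north_clockwise(self):
        trees = frame([(12.91, 12.91), (12.91, 18.0), (18.0, 12.91), (12.91, 8.0), (8.0, 12.91)])
        _, adj = structure.weighted_voronoi(trees)
        units = structure.structural_units(adj, trees)
        center = next(u for u in units if u.center_id == 1)
        az = dict(zip(center.neighbor_ids, center.azimuths))
        assert az[2] == pytest.approx(0.0, abs=1e-9)    # due north
        assert az[3] == pytest.approx(90.0, abs=1e-9)   # due east
        assert az[4] == pytest.approx(180.0, abs=1e-9)
        assert az[5] == pytest.approx(270.0, abs=1e-9)

    def test_nearest_mode_fixed_neighbor_count(self):
        rng = np.random.default_rng(5)
        trees = random_tree_frame(rng, 40)
        units = structure.nearest_neighbor_units(trees, n_neighbors=4)
        assert all(u.n == 4 for u in units)


class TestLayers:
    def test_three_height_thirds(self):
        la = structure.assign_layers([10.0, 15.0, 20.0])
        assert list(la.layers) == ["lower", "middle", "upper"]
        assert la.h_dist == 10.0

    def test_equal_heights_single_upper_layer(self):
        la = structure.assign_layers([12.0, 12.0])
        assert set(la.layers) == {"upper"}
        assert la.n_layers == 1

    def test_two_extremes_middle_empty(self):
        la = structure.assign_layers([5.0, 20.0])
        assert list(la.layers) == ["lower", "upper"]


class TestIndices:
    def test_size_ratio_extremes_and_half(self):
        assert structure.index_U(20.0, [10, 11, 12, 13]) == 0.0
        assert structure.index_U(9.0, [10, 11, 12, 13]) == 1.0
        assert structure.index_U(11.5, [10, 11, 12, 13]) == 0.5

    def test_uniform_angle_square_cross_is_uniform(self):
        assert structure.index_W([0, 90, 180, 270]) == 0.0

    def test_uniform_angle_bunched_neighbors(self):
        # gaps {10,10,10,330}; standard angle 72 -> three small gaps
        assert structure.index_W([0, 10, 20, 30]) == 0.75

    def test_uci_hand_trigonometry(self):
        # taller single neighbour: alpha1=atan(10/4), alpha2=atan(2/4)
        got = structure.index_UCI(10.0, [12.0], [4.0])
        want = (np.degrees(np.arctan(10 / 4)) + np.degrees(np.arctan(2 / 4))) / 180
        assert got == pytest.approx(want, abs=1e-12)
        assert got == pytest.approx(0.5265, abs=1e-4)

    def test_uci_zero_when_center_tallest(self):
        assert structure.index_UCI(30.0, [10, 12, 14], [2, 3, 4]) == 0.0

    def test_openness_boundary_value(self):
        assert structure.index_K([3.0] * 4, [15.0] * 4) == pytest.approx(0.2)

    def test_openness_linear_in_distance(self):
        rng = np.random.default_rng(0)
        u = random_unit(rng, 5)
        k1 = structure.index_K(u["distances"], u["neighbor_h"])
        k2 = structure.index_K(2 * u["distances"], u["neighbor_h"])
        assert k2 == pytest.approx(2 * k1)

    def test_openness_ratio_extremes(self):
        assert structure.index_OP(15.0, [13.0] * 4, [5.0] * 4) == 1.0
        assert structure.index_OP(15.0, [18.0] * 4, [1.0] * 4) == 0.0
        assert structure.index_OP(15.0, [13.0, 13.0, 13.0, 18.0], [5, 5, 5, 1]) == 0.75

    def test_layer_index_cases(self):
        assert structure.index_S("upper", ["upper"] * 4) == pytest.approx(1 / 3)
        assert structure.index_S("upper", ["lower", "middle", "lower"]) == 0.0
        assert structure.index_S("upper", ["upper", "upper", "lower", "lower"]) == pytest.approx(1 / 3)
        # complementary convention counts differing neighbours
        assert structure.index_S("upper", ["lower"] * 2, same_layer=False) == pytest.approx(2 / 3)

    def test_all_indices_match_brute_force_on_random_units(self):
        rng = np.random.default_rng(99)
        layers = np.array(["lower", "middle", "upper"])
        for _ in range(1000):
            u = random_unit(rng)
            nh, d, az, ch = u["neighbor_h"], u["distances"], u["azimuths"], u["center_h"]
            assert structure.index_U(ch, nh) == pytest.approx(oracle.oracle_U(ch, nh), abs=1e-10)
            assert structure.index_UCI(ch, nh, d) == pytest.approx(oracle.oracle_UCI(ch, nh, d), abs=1e-10)
            assert structure.index_K(d, nh) == pytest.approx(oracle.oracle_K(d, nh), abs=1e-10)
            assert structure.index_OP(ch, nh, d) == pytest.approx(oracle.oracle_OP(ch, nh, d), abs=1e-10)
            if len(az) >= 2:
                assert structure.index_W(az) == pytest.approx(oracle.oracle_W(az), abs=1e-10)
            nl = rng.choice(layers, len(nh))
            cl = str(rng.choice(layers))
            assert structure.index_S(cl, nl) == pytest.approx(oracle.oracle_S(cl, nl), abs=1e-10)

    def test_indices_bounded_on_many_random_units(self):
        rng = np.random.default_rng(7)
        for _ in range(10000):
            u = random_unit(rng)
            nh, d, ch = u["neighbor_h"], u["distances"], u["center_h"]
            assert 0 <= structure.index_U(ch, nh) <= 1
            assert 0 <= structure.index_UCI(ch, nh, d) <= 1
            assert 0 <= structure.index_OP(ch, nh, d) <= 1
            assert structure.index_K(d, nh) > 0
            if len(nh) >= 2:
                assert 0 <= structure.index_W(u["azimuths"]) <= 1

    def test_distance_monotonicity(self):
        rng = np.random.default_rng(21)
        for _ in range(200):
            u = random_unit(rng, 5)
            nh, d, ch = u["neighbor_h"], u["distances"], u["center_h"]
            scale = 1.7
            assert structure.index_K(scale * d, nh) > structure.index_K(d, nh)
            assert structure.index_OP(ch, nh, scale * d) >= structure.index_OP(ch, nh, d)


class TestClassification:
    @pytest.mark.parametrize(
        "value,name,label",
        [
            (0.9, "OP", "(0.75,1]"),
            (0.0, "UCI", "0"),
            (0.25, "W", "(0,0.25]"),
            (0.26, "W", "(0.25,0.5]"),
            (0.2, "K", "(0,0.2]"),
            (0.55, "K", "(0.5,inf)"),
        ],
    )
    def test_interval_labels(self, value, name, label):
        assert structure.classify_index(value, name) == label

    def test_out_of_domain_rejected(self):
        with pytest.raises(ValueError):
            structure.classify_index(1.2, "OP")
        with pytest.raises(ValueError):
            structure.classify_index(0.0, "K")

    def test_bins_cover_domain(self):
        rng = np.random.default_rng(0)
        for v in rng.uniform(0, 1, 500):
            assert 0 <= structure.class_bin(v, "U") <= 4
        for v in rng.uniform(1e-9, 2, 500):
            assert 0 <= structure.class_bin(v, "K") <= 4


class TestSummaries:
    def test_known_group_difference_recovered(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "group": ["a"] * 30 + ["b"] * 30,
                "W": np.r_[rng.normal(0.5, 0.01, 30), rng.normal(0.9, 0.01, 30)],
            }
        )
        out = structure.summarize_plot(df, "group", value_cols=("W",))
        assert out["anova_p"].iloc[0] < 0.05
        letters = dict(zip(out["group"], out["letters_0.05"]))
        assert letters["a"] != letters["b"]

    def test_identical_groups_share_letters(self):
        rng = np.random.default_rng(2)
        base = rng.normal(0.5, 0.05, 25)
        df = pd.DataFrame({"group": ["a"] * 25 + ["b"] * 25, "W": np.r_[base, base]})
        out = structure.summarize_plot(df, "group", value_cols=("W",))
        letters = dict(zip(out["group"], out["letters_0.05"]))
        assert letters["a"] == letters["b"] != ""

    def test_single_group_skips_anova(self):
        df = pd.DataFrame({"group": ["a"] * 10, "W": np.linspace(0, 1, 10)})
        out = structure.summarize_plot(df, "group", value_cols=("W",))
        assert np.isnan(out["anova_F"].iloc[0])
        assert out["mean"].iloc[0] == pytest.approx(0.5)


@settings(max_examples=150, derandomize=True)
@given(
    az=st.lists(st.floats(0, 360, exclude_max=True, allow_nan=False), min_size=2, max_size=12)
)
def test_uniform_angle_bounded_and_gap_closure(az):
    # W stays in [0,1] and the azimuth gaps always close the circle
    assert 0 <= structure.index_W(az) <= 1
    srt = np.sort(np.asarray(az) % 360)
    gaps = np.diff(np.append(srt, srt[0] + 360))
    assert gaps.sum() == pytest.approx(360.0, abs=1e-9)


@settings(max_examples=150, derandomize=True)
@given(v=st.floats(0, 1, allow_nan=False))
def test_unit_interval_classification_total(v):
    # every admissible value falls in exactly one of the five classes
    b = structure.class_bin(v, "OP")
    assert 0 <= b <= 4
    if v == 0:
        assert b == 0
    else:
        assert b == next(
            i + 1 for i, edge in enumerate((0.25, 0.5, 0.75, 1.0)) if v <= edge
        )


def test_clustered_vs_hardcore_uniform_angle_trend():
    """Aggregated stands read as clustered (W > 0.5), hard-core as regular
    (W < 0.5) under the classical 4-nearest-neighbour convention."""
    means = {}
    for pattern, param in [("clustered", 1.5), ("regular", 1.0)]:
        vals = []
        for seed in range(3):
            cfg = synthetic.StandConfig.from_age_group(
                "young", seed=seed, pattern=pattern, pattern_param=param
            )
            trees = synthetic.generate_stand(cfg)
            idx = structure.compute_indices(trees, neighbor_mode="nearest", resolution=0.15)
            vals.append(idx["W"].mean())
        means[pattern] = np.mean(vals)
    assert means["clustered"] > 0.5
    assert means["regular"] < 0.5
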