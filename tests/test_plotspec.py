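"""Geometry dispatch, layouts, placement, ordering, downsampling, spec building."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from omicspanels.colormaps import MISSING_COLOR, VIRIDIS_256
from omicspanels.container import CONTINUOUS, VariableKind
from omicspanels.plotspec import (
    PanelConfig,
    build_plot_spec,
    dispatch_geometry,
    downsample_points,
    heatmap_spec,
    mirrored_bar_layout,
    order_samples_by_fields,
    place_points,
    rectangle_layout,
)


def cat(n):
    return VariableKind("categorical", tuple(f"L{i}" for i in range(n)))


class TestDispatchGeometry:
    @pytest.mark.parametrize(
        "x_kind, y_kind, expected",
        [
            (CONTINUOUS, CONTINUOUS, "scatter"),
            (cat(3), CONTINUOUS, "violin_vertical"),
            (CONTINUOUS, cat(3), "violin_horizontal"),
            (cat(2), cat(3), "rectangle"),
            (cat(1), cat(2), "mirrored_bar"),
            (cat(2), cat(1), "mirrored_bar"),
            (cat(1), cat(1), "mirrored_bar"),
            (cat(1), CONTINUOUS, "violin_vertical"),
        ],
    )
    def test_rules(self, x_kind, y_kind, expected):
        assert dispatch_geometry(x_kind, y_kind) == expected

    def test_exhaustive_over_kind_and_level_counts(self):
        # total over every combination of kind x level count 1..4
        kinds = [CONTINUOUS] + [cat(n) for n in range(1, 5)]
        for xk in kinds:
            for yk in kinds:
                geom = dispatch_geometry(xk, yk)
                if not xk.is_categorical and not yk.is_categorical:
                    assert geom == "scatter"
                elif xk.is_categorical != yk.is_categorical:
                    assert geom == (
                        "violin_vertical" if xk.is_categorical else "violin_horizontal"
                    )
                elif 1 in (xk.n_levels, yk.n_levels):
                    assert geom == "mirrored_bar"
                else:
                    assert geom == "rectangle"


class TestRectangleLayout:
    def test_fractions_follow_counts(self):
        rects = rectangle_layout({("A", "X"): 2, ("A", "Y"): 1, ("B", "X"): 1}, 4)
        fr = {(r["x_level"], r["y_level"]): r["fraction"] for r in rects}
        assert fr == {("A", "X"): 0.5, ("A", "Y"): 0.25, ("B", "X"): 0.25}

    def test_single_combination_fills_its_cell(self):
        (r,) = rectangle_layout({("A", "X"): 7}, 7)
        assert r["fraction"] == 1.0
        assert (r["x0"], r["x1"], r["y0"], r["y1"]) == (0.0, 1.0, 0.0, 1.0)

    def test_random_pairings_match_count_oracle(self):
        rng = np.random.default_rng(42)
        xs = rng.choice(list("ABC"), 100)
        ys = rng.choice(list("XY"), 100)
        counts = {}
        for x, y in zip(xs, ys):
            counts[(x, y)] = counts.get((x, y), 0) + 1
        rects = rectangle_layout(counts, 100, list("ABC"), list("XY"))
        # independent tally
        oracle = {}
        for x, y in zip(xs, ys):
            oracle[(x, y)] = oracle.get((x, y), 0) + 1
        assert abs(sum(r["fraction"] for r in rects) - 1.0) < 1e-12
        for r in rects:
            assert r["fraction"] == oracle[(r["x_level"], r["y_level"])] / 100
        # geometric area proportional to fraction
        areas = {
            (r["x_level"], r["y_level"]): (r["x1"] - r["x0"]) * (r["y1"] - r["y0"])
            for r in rects
        }
        fracs = {(r["x_level"], r["y_level"]): r["fraction"] for r in rects}
        ratios = {k: areas[k] / fracs[k] for k in areas}
        assert max(ratios.values()) - min(ratios.values()) < 1e-12

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            rectangle_layout({}, 0)

    def test_mirrored_bar_lengths_proportional_to_counts(self):
        bars = mirrored_bar_layout(
            {("only", "a"): 3, ("only", "b"): 1}, 4, ["only"], ["a", "b"]
        )
        by = {b["y_level"]: b for b in bars}
        # widths along the single-level (x) axis scale with count
        assert by["a"]["x1"] - by["a"]["x0"] == pytest.approx(1.0)
        assert by["b"]["x1"] - by["b"]["x0"] == pytest.approx(1.0 / 3.0)
        # bars mirrored about the single level's cell centre
        for b in bars:
            assert b["x0"] + b["x1"] == pytest.approx(1.0)


class TestPlacePoints:
    def test_scatter_is_identity(self):
        xs, ys = place_points("scatter", [1.0, 2.0], [3.0, 4.0], ["a", "b"], seed=0)
        np.testing.assert_array_equal(xs, [1.0, 2.0])
        np.testing.assert_array_equal(ys, [3.0, 4.0])

    def test_violin_jitter_is_seeded_and_bounded(self):
        ids = [f"s{i}" for i in range(50)]
        levels = VariableKind("categorical", ("u", "v"))
        xv = ["u", "v"] * 25
        yv = list(np.linspace(0, 1, 50))
        x1, y1 = place_points("violin_vertical", xv, yv, ids, 3, x_kind=levels)
        x2, y2 = place_points("violin_vertical", xv, yv, ids, 3, x_kind=levels)
        np.testing.assert_array_equal(x1, x2)
        np.testing.assert_array_equal(y1, yv)
        for x, lvl in zip(x1, xv):
            pos = 0 if lvl == "u" else 1
            assert abs(x - pos) <= 0.4

    def test_violin_jitter_changes_with_seed(self):
        ids = ["s0", "s1"]
        lv = VariableKind("categorical", ("u",))
        x1, _ = place_points("violin_vertical", ["u", "u"], [0.0, 1.0], ids, 1, x_kind=lv)
        x2, _ = place_points("violin_vertical", ["u", "u"], [0.0, 1.0], ids, 2, x_kind=lv)
        assert not np.array_equal(x1, x2)

    def test_placement_independent_of_point_order(self):
        ids = [f"s{i}" for i in range(20)]
        lv = VariableKind("categorical", ("u", "v"))
        xv = ["u", "v"] * 10
        yv = list(range(20))
        x1, _ = place_points("violin_vertical", xv, yv, ids, 9, x_kind=lv)
        perm = np.random.default_rng(0).permutation(20)
        x2, _ = place_points(
            "violin_vertical",
            [xv[i] for i in perm],
            [yv[i] for i in perm],
            [ids[i] for i in perm],
            9,
            x_kind=lv,
        )
        np.testing.assert_array_equal(x2, x1[perm])

    def test_rectangle_points_land_inside_their_rectangle(self):
        rng = np.random.default_rng(7)
        n = 1000
        xk, yk = cat(3), cat(2)
        xv = [f"L{i}" for i in rng.integers(3, size=n)]
        yv = [f"L{i}" for i in rng.integers(2, size=n)]
        ids = [f"p{i}" for i in range(n)]
        counts = {}
        for x, y in zip(xv, yv):
            counts[(x, y)] = counts.get((x, y), 0) + 1
        rects = rectangle_layout(counts, n, list(xk.levels), list(yk.levels))
        by_combo = {(r["x_level"], r["y_level"]): r for r in rects}
        xs, ys = place_points("rectangle", xv, yv, ids, 5, x_kind=xk, y_kind=yk)
        for i in range(n):
            r = by_combo[(xv[i], yv[i])]
            assert r["x0"] <= xs[i] <= r["x1"]
            assert r["y0"] <= ys[i] <= r["y1"]


class TestOrderSamples:
    def test_lexicographic_by_two_fields(self):
        cd = pd.DataFrame(
            {"group": ["B", "A", "A"], "batch": [1, 2, 1]}, index=["s1", "s2", "s3"]
        )
        perm = order_samples_by_fields(cd, ["group", "batch"])
        assert [cd.index[i] for i in perm] == ["s3", "s2", "s1"]

    def test_single_continuous_field_ascending(self):
        cd = pd.DataFrame({"v": [3.0, 1.0, 2.0]}, index=["s1", "s2", "s3"])
        perm = order_samples_by_fields(cd, ["v"])
        assert [cd.index[i] for i in perm] == ["s2", "s3", "s1"]

    def test_ties_keep_original_order(self):
        cd = pd.DataFrame({"v": [1.0, 1.0, 1.0]}, index=["s1", "s2", "s3"])
        assert list(order_samples_by_fields(cd, ["v"])) == [0, 1, 2]

    def test_empty_field_list_is_identity(self):
        cd = pd.DataFrame({"v": [2.0, 1.0]}, index=["s1", "s2"])
        assert list(order_samples_by_fields(cd, [])) == [0, 1]

    def test_categorical_sorts_by_level_order_not_alphabet(self):
        cd = pd.DataFrame(
            {"g": pd.Categorical(["b", "a"], categories=["b", "a"])}, index=["s1", "s2"]
        )
        assert list(order_samples_by_fields(cd, ["g"])) == [0, 1]


class TestBuildPlotSpec:
    def test_column_data_violin_per_cluster(self, container, registry):
        panel = PanelConfig("C1", "column_data", x_var="cluster", y_var="total_count")
        spec = build_plot_spec(panel, container, registry, seed=1)
        assert spec.geometry == "violin_vertical"
        assert [s["level"] for s in spec.shapes] == ["C1", "C2", "C3"]
        assert sum(s["n"] for s in spec.shapes) == container.n_samples
        assert all(np.isfinite([p["x"], p["y"]]).all() for p in spec.points)

    def test_colour_by_feature_is_monotone_continuous(self, container, registry):
        panel = PanelConfig(
            "R1",
            "reduced_dim",
            reduced_dim="tsne",
            colour_by={"slot": "feature", "feature": "G0005", "assay": "logcounts"},
        )
        spec = build_plot_spec(panel, container, registry, seed=1)
        assert spec.legend["kind"] == "continuous"
        from omicspanels.container import get_feature_values

        vals = get_feature_values(container, "logcounts", "G0005")
        vmin, vmax = vals.min(), vals.max()
        for p, v in zip(spec.points, vals):
            idx = int(np.floor((v - vmin) / (vmax - vmin) * 255 + 0.5))
            assert p["color"] == VIRIDIS_256[idx]

    def test_restrict_keeps_only_selected_points_included(self, container, registry):
        chosen = set(container.sample_ids[:3])
        panel = PanelConfig("C1", "column_data", x_var="cluster", y_var="total_count")
        spec = build_plot_spec(panel, container, registry, incoming=chosen, seed=1)
        assert spec.included_ids() == chosen
        assert len(spec.points) == container.n_samples  # excluded points retained, flagged

    def test_highlight_greys_out_unselected(self, container, registry):
        chosen = set(container.sample_ids[:5])
        panel = PanelConfig(
            "R1", "reduced_dim", reduced_dim="tsne", selection_effect="highlight"
        )
        spec = build_plot_spec(panel, container, registry, incoming=chosen, seed=1)
        assert spec.included_ids() == set(container.sample_ids)
        for p in spec.points:
            if p["id"] in chosen:
                assert p["opacity"] == 1.0
            else:
                assert p["color"] == MISSING_COLOR and p["opacity"] < 1.0

    def test_spec_document_is_deterministic(self, container, registry):
        panel = PanelConfig("C1", "column_data", x_var="cluster", y_var="total_count")
        d1 = build_plot_spec(panel, container, registry, seed=4).to_document()
        d2 = build_plot_spec(panel, container, registry, seed=4).to_document()
        assert d1 == d2

    def test_missing_variable_is_a_lookup_error(self, container, registry):
        panel = PanelConfig("C1", "column_data", x_var="cluster", y_var="nope")
        from omicspanels.container import LookupError_

        with pytest.raises(LookupError_, match="nope"):
            build_plot_spec(panel, container, registry)


class TestHeatmapSpec:
    def test_columns_grouped_by_cluster_with_annotation(self, container, registry):
        spec = heatmap_spec(
            container, container.feature_ids[:2], ["cluster"], "logcounts", registry
        )
        clusters = [
            container.col_data.loc[s, "cluster"] for s in spec.data["samples"]
        ]
        assert clusters == sorted(clusters, key=["C1", "C2", "C3"].index)
        (track,) = spec.data["annotations"]
        assert track["field"] == "cluster" and len(track["colors"]) == container.n_samples

    def test_single_feature_heatmap_valid(self, container, registry):
        spec = heatmap_spec(container, [container.feature_ids[0]], [], "counts", registry)
        assert len(spec.data["values"]) == 1
        assert len(spec.data["values"][0]) == container.n_samples

    def test_column_order_invariant_to_sample_permutation(self, container, registry):
        from omicspanels.container import OmicsContainer

        rng = np.random.default_rng(3)
        perm = rng.permutation(container.n_samples)
        shuffled = OmicsContainer(
            assays={k: np.asarray(v)[:, perm] for k, v in container.assays.items()},
            row_data=container.row_data,
            col_data=container.col_data.iloc[perm],
            reduced_dims={k: np.asarray(v)[perm] for k, v in container.reduced_dims.items()},
        )
        a = heatmap_spec(container, container.feature_ids[:3], ["cluster"], "logcounts", registry)
        b = heatmap_spec(shuffled, container.feature_ids[:3], ["cluster"], "logcounts", registry)
        assert a.data["samples"] == b.data["samples"]
        assert a.data["values"] == b.data["values"]

    def test_empty_feature_list_rejected(self, container, registry):
        with pytest.raises(ValueError):
            heatmap_spec(container, [], [], "counts", registry)


class TestDownsample:
    def test_identical_points_keep_only_first(self):
        kept = downsample_points([(1.0, 1.0)] * 100, resolution=10, cap=1)
        assert kept == [0]

    def test_distinct_bins_all_retained(self):
        pts = [(float(i), float(i)) for i in range(10)]
        assert downsample_points(pts, resolution=10, cap=1) == list(range(10))

    def test_matches_per_bin_tally_oracle(self):
        rng = np.random.default_rng(11)
        pts = rng.uniform(0, 1, size=(10_000, 2))
        resolution, cap = 50, 2
        kept = downsample_points([tuple(p) for p in pts], resolution, cap)
        # independent brute-force tally (plus the box-pinning extremes)
        lo = pts.min(0)
        span = pts.max(0) - lo
        expected, fill = set(), {}
        for i, p in enumerate(pts):
            b = tuple(
                min(int((p[d] - lo[d]) / span[d] * resolution), resolution - 1)
                for d in range(2)
            )
            if fill.get(b, 0) < cap:
                fill[b] = fill.get(b, 0) + 1
                expected.add(i)
        for d in range(2):
            expected.add(int(pts[:, d].argmin()))
            expected.add(int(pts[:, d].argmax()))
        assert kept == sorted(expected)

    def test_subset_coverage_idempotence(self):
        rng = np.random.default_rng(12)
        pts = [tuple(p) for p in rng.normal(size=(2000, 2))]
        kept = downsample_points(pts, 20, 1)
        assert set(kept) <= set(range(len(pts)))
        # idempotence: thinning the survivors again changes nothing
        survivors = [pts[i] for i in kept]
        again = downsample_points(survivors, 20, 1)
        assert again == list(range(len(survivors)))

    def test_empty_input_empty_output(self):
        assert downsample_points([], 10, 1) == []

    def test_bad_parameters_rejected(self):
        with pytest.raises(ValueError):
            downsample_points([(0, 0)], 0, 1)


class TestTablePanel:
    def test_row_table_lists_all_features(self, container, registry):
        spec = build_plot_spec(PanelConfig("T1", "row_table"), container, registry)
        assert spec.geometry == "table"
        assert spec.data["rows"] == container.feature_ids

    def test_restricted_table_flags_empty(self, container, registry):
        spec = build_plot_spec(
            PanelConfig("T1", "row_table"), container, registry, incoming=set()
        )
        assert spec.data["rows"] == []
        assert "warning" in spec.data
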