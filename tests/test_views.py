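"""Width model, view planning, glyph aggregation and SVG rendering."""

import re

import numpy as np
import pytest

import cortexflow as cf
from cortexflow.data_io import ValidationError
from cortexflow.views import (
    LayoutInfeasibleError,
    LayoutSpec,
    alluvial_scene,
    electrode_scene,
    heatmap_scene,
)

from conftest import dcs_from_label_matrix


class TestExpansionFactor:
    def test_direct_substitution(self):
        s_f, w_i = cf.expansion_factor(5, 5, 1000.0, 100.0, 1.0)
        assert s_f == 2.0 and w_i == 200.0

    def test_boundary_s_f_one(self):
        s_f, w_i = cf.expansion_factor(4, 2, 400.0, 100.0, 1.0)
        assert s_f == 1.0 and w_i == 100.0

    def test_denominator_uses_max_axis_count(self):
        s_f, _ = cf.expansion_factor(7, 3, 700.0, 100.0, 1.0)
        assert s_f == 1.0  # divided by 7, not 3

    def test_infeasible_names_feasible_wmin(self):
        with pytest.raises(LayoutInfeasibleError, match="100"):
            cf.expansion_factor(10, 10, 1000.0, 200.0, 1.0)


class TestPlanViews:
    def test_single_top_level_view(self):
        plans = cf.plan_views(30, 30)
        assert len(plans) == 1
        assert plans[0].span == (0, 30) and plans[0].axis == "x1"

    def test_bottom_level_alternates_axes(self):
        plans = cf.plan_views(4, 1)
        assert [p.axis for p in plans] == ["x1", "x2", "x1", "x2"]
        assert [p.span for p in plans] == [(0, 1), (1, 2), (2, 3), (3, 4)]

    def test_granularity_ten_of_thirty(self):
        plans = cf.plan_views(30, 10)
        assert [p.span for p in plans] == [(0, 10), (10, 20), (20, 30)]

    def test_short_final_span(self):
        plans = cf.plan_views(7, 3)
        assert [p.span for p in plans] == [(0, 3), (3, 6), (6, 7)]

    def test_invalid_granularity_rejected(self):
        with pytest.raises(ValueError):
            cf.plan_views(10, 0)


class TestAggregateGlyphs:
    def test_span_of_one_single_slice(self, small_tracked):
        dcs, act, _, _ = small_tracked
        glyphs = cf.aggregate_glyphs(dcs, act, (0, 1))
        assert all(len(g.slices) == 1 for g in glyphs.values())

    def test_stable_community_constant_color_and_opacity(self, small_tracked):
        dcs, act, _, truth = small_tracked
        glyphs = cf.aggregate_glyphs(dcs, act, (0, 3))  # stable interval
        for n, g in glyphs.items():
            colors = {c for c, _ in g.slices}
            assert len(colors) == 1
            idx = dcs.node_ids.index(n)
            for k, (_, op) in enumerate(g.slices):
                assert op == truth.activation[idx, k]

    def test_membership_change_switches_color_at_exact_timestep(self):
        # e0 defects from its community to the other at t=2; both host
        # communities persist, so e0's slice color must flip exactly there
        labels = np.array(
            [
                [0, 0, 1, 1],
                [0, 0, 0, 0],
                [0, 0, 0, 0],
                [1, 1, 1, 1],
                [1, 1, 1, 1],
            ]
        )
        dcs = dcs_from_label_matrix(labels)
        act = cf.ActivationSeries(np.full((5, 4), 0.5))
        glyphs = cf.aggregate_glyphs(dcs, act, (0, 4))
        g0 = glyphs["e0"].slices
        assert g0[0][0] == g0[1][0] and g0[2][0] == g0[3][0]
        assert g0[1][0] != g0[2][0]  # color flips exactly at t=2

    def test_slice_count_equals_span_length(self, small_tracked):
        dcs, act, _, _ = small_tracked
        for span in [(0, 2), (1, 5), (0, 6)]:
            glyphs = cf.aggregate_glyphs(dcs, act, span)
            assert all(len(g.slices) == span[1] - span[0] for g in glyphs.values())

    def test_bad_span_rejected(self, small_tracked):
        dcs, act, _, _ = small_tracked
        with pytest.raises(ValueError):
            cf.aggregate_glyphs(dcs, act, (4, 99))


class TestAlluvial:
    def test_single_community_unbroken_ribbon(self):
        labels = np.zeros((5, 4), dtype=int)
        dcs = dcs_from_label_matrix(labels)
        ordering = cf.barycenter_order(dcs)
        scene = alluvial_scene(dcs, ordering)
        assert len(scene["rects"]) == 4
        assert len(scene["ribbons"]) == 3
        assert all(rb["count"] == 5 for rb in scene["ribbons"])

    def test_block_heights_conserved_per_timestep(self, small_tracked):
        dcs, _, _, _ = small_tracked
        ordering = cf.barycenter_order(dcs)
        scene = alluvial_scene(dcs, ordering)
        totals = {}
        for rc in scene["rects"]:
            totals[rc["t"]] = totals.get(rc["t"], 0.0) + rc["h"]
        expected = len(dcs.node_ids) * scene["unit"]
        for t, h in totals.items():
            assert h == pytest.approx(expected)

    def test_byte_identical_rerender(self, small_tracked):
        dcs, _, _, _ = small_tracked
        ordering = cf.barycenter_order(dcs)
        a = cf.render_alluvial(dcs, ordering)
        b = cf.render_alluvial(dcs, ordering)
        assert a == b
        assert a.startswith('<?xml version="1.0"')

    def test_zero_canvas_rejected(self, small_tracked):
        dcs, _, _, _ = small_tracked
        ordering = cf.barycenter_order(dcs)
        with pytest.raises(ValueError):
            alluvial_scene(dcs, ordering, width=0.0)


class TestKHeatmap:
    def test_endpoint_colors(self):
        svg = cf.render_k_heatmap([{2: 1.0, 3: 0.0}])
        assert 'fill="#000000"' in svg
        assert 'fill="#ffffff"' in svg

    def test_degenerate_profile_all_white(self):
        scene = heatmap_scene([{2: 0.0, 3: 0.0, 4: 0.0}])
        assert all(c["fill"] == "#ffffff" for c in scene["cells"])

    def test_cell_count_per_timestep(self):
        profiles = [{2: 0.1, 3: 0.9, 4: 0.2}] * 5
        scene = heatmap_scene(profiles)
        assert len(scene["cells"]) == 5 * 3
        for t in range(5):
            assert sum(1 for c in scene["cells"] if c["t"] == t) == 3

    def test_mismatched_k_ranges_rejected(self):
        with pytest.raises(ValueError):
            heatmap_scene([{2: 0.1}, {3: 0.2}])


class TestElectrodeViews:
    def _setup(self, small_tracked, granularity=2):
        dcs, act, layout, _ = small_tracked
        plans = cf.plan_views(dcs.n_timesteps, granularity)
        views = [(p, cf.aggregate_glyphs(dcs, act, p.span)) for p in plans]
        n_x1 = sum(1 for p in plans if p.axis == "x1")
        spec = LayoutSpec.from_params(n_x1, len(plans) - n_x1, 900.0, 150.0, 1.0)
        return dcs, act, layout, views, spec

    def test_x_offsets_are_cumulative_widths(self, small_tracked):
        dcs, _, layout, views, spec = self._setup(small_tracked)
        scene = electrode_scene(views, layout, spec)
        widths = [p["w"] for p in scene["panels"]]
        xs = [p["x"] for p in scene["panels"]]
        for k in range(len(xs)):
            assert xs[k] == pytest.approx(xs[0] + sum(widths[:k]))

    def test_crop_remap_preserves_relative_distances(self, small_tracked):
        from cortexflow.views import _map_coordinates

        dcs, _, layout, _ = small_tracked
        ids = dcs.node_ids
        mapped = _map_coordinates(layout, ids, (10.0, 20.0, 200.0, 150.0))
        src = np.array([layout.coordinates[n] for n in ids])
        dst = np.array([mapped[n] for n in ids])
        d_src = np.linalg.norm(src[0] - src[1])
        for a in range(len(ids)):
            for b in range(a + 1, len(ids)):
                r_src = np.linalg.norm(src[a] - src[b]) / d_src
                r_dst = np.linalg.norm(dst[a] - dst[b]) / np.linalg.norm(dst[0] - dst[1])
                assert r_dst == pytest.approx(r_src, abs=1e-9)

    def test_all_zero_activation_transparent_fill_visible_outline(self, small_tracked):
        dcs, act, layout, views, spec = self._setup(small_tracked)
        zero = cf.ActivationSeries(np.zeros_like(act.values))
        plans = [p for p, _ in views]
        views0 = [(p, cf.aggregate_glyphs(dcs, zero, p.span)) for p in plans]
        svg = cf.render_electrode_views(views0, layout, spec)
        assert 'fill-opacity="0.00"' in svg
        assert 'stroke="#555555"' in svg

    def test_missing_coordinate_error_lists_ids(self, small_tracked):
        dcs, _, layout, views, spec = self._setup(small_tracked)
        broken = cf.ElectrodeLayout(
            {k: v for k, v in layout.coordinates.items() if k != "e3"}
        )
        with pytest.raises(ValidationError, match="e3"):
            cf.render_electrode_views(views, broken, spec)

    def test_byte_identical_rerender_with_central_band(self, small_tracked):
        dcs, _, layout, views, spec = self._setup(small_tracked)
        ordering = cf.barycenter_order(dcs)
        a = cf.render_electrode_views(views, layout, spec, dcs=dcs, ordering=ordering)
        b = cf.render_electrode_views(views, layout, spec, dcs=dcs, ordering=ordering)
        assert a == b

    def test_glyph_slice_count_matches_span(self, small_tracked):
        dcs, _, layout, views, spec = self._setup(small_tracked, granularity=3)
        scene = electrode_scene(views, layout, spec)
        for panel in scene["panels"]:
            span_len = panel["span"][1] - panel["span"][0]
            for g in panel["glyphs"]:
                assert len(g["slices"]) == span_len

    def test_unequal_span_gets_proportional_width(self, small_tracked):
        dcs, act, layout, _ = small_tracked
        plans = cf.plan_views(dcs.n_timesteps, 4)  # spans of 4 and 2
        views = [(p, cf.aggregate_glyphs(dcs, act, p.span)) for p in plans]
        spec = LayoutSpec.from_params(1, 1, 900.0, 150.0, 1.0)
        scene = electrode_scene(views, layout, spec)
        w = [p["w"] for p in scene["panels"]]
        assert w[1] == pytest.approx(w[0] / 2)
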