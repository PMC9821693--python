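"""Preprocessing: reading, smoothing, resampling, orientation, truncation."""

import io

import numpy as np
import pytest

import whiskerfit as wf
from whiskerfit import DegenerateTraceError, ConfigurationError, FormatError

from conftest import straight_trace


def _csv(rows):
    head = "species,animal_id,side,row,column,point_index,x,y\n"
    return io.StringIO(head + "\n".join(rows))


class TestReadTraces:
    def test_reads_mm_points_in_order(self, tmp_path):
        buf = _csv([
            "rat,r1,L,B,2,1,1.0,0.1",
            "rat,r1,L,B,2,0,0.0,0.0",
            "rat,r1,L,B,2,2,2.0,0.4",
        ])
        traces = wf.read_traces(buf)
        assert len(traces) == 1
        t = traces[0]
        assert t.unit == "mm"
        assert t.whisker_id == wf.WhiskerId("L", "B", 2)
        np.testing.assert_allclose(t.points[:, 0], [0.0, 1.0, 2.0])

    def test_pixel_coordinates_convert_at_dpi(self):
        buf = _csv([f"rat,r1,L,A,1,{i},{i * 100},0" for i in range(4)])
        traces = wf.read_traces(buf, unit="px", dpi=6400)
        pts = traces[0].points_mm()
        # 25.4/6400 mm per pixel
        np.testing.assert_allclose(pts[1, 0], 100 * 25.4 / 6400)

    def test_duplicate_consecutive_points_collapse_with_warning(self):
        buf = _csv([
            "rat,r1,L,A,1,0,0,0",
            "rat,r1,L,A,1,1,1,0",
            "rat,r1,L,A,1,2,1,0",
            "rat,r1,L,A,1,3,2,0",
        ])
        with pytest.warns(UserWarning, match="duplicate"):
            traces = wf.read_traces(buf)
        assert len(traces[0].points) == 3

    def test_missing_column_is_format_error(self):
        buf = io.StringIO("species,x,y\nrat,0,0\n")
        with pytest.raises(FormatError):
            wf.read_traces(buf)

    def test_too_few_points_is_degenerate(self):
        buf = _csv(["rat,r1,L,A,1,0,0,0", "rat,r1,L,A,1,1,1,0"])
        with pytest.raises(DegenerateTraceError):
            wf.read_traces(buf)

    def test_px_without_dpi_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            wf.read_traces(io.StringIO(""), unit="px")


class TestSmoothTrace:
    def test_straight_line_passes_through(self):
        t = np.linspace(0, 20, 200)
        pts = np.stack([t, 0.3 * t], axis=-1)
        out = wf.smooth_trace(pts, window_mm=4.0)
        assert np.abs(out - pts).max() < 1e-9

    def test_pixelation_noise_is_reduced(self):
        # oracle: the generator's noise-free curve at identical indices
        spec_clean = wf.SyntheticSpec("poly", {"orders": (2,), "coeffs": (0.02,)},
                                      S=30, noise_dpi=None)
        spec_noisy = wf.SyntheticSpec("poly", {"orders": (2,), "coeffs": (0.02,)},
                                      S=30, noise_dpi=6400)
        clean = wf.generate_whisker(spec_clean).points
        noisy = wf.generate_whisker(spec_noisy).points
        smoothed = wf.smooth_trace(noisy, window_mm=4.0)
        rms_before = np.sqrt(np.mean((noisy - clean) ** 2))
        rms_after = np.sqrt(np.mean((smoothed - clean) ** 2))
        assert rms_after < rms_before

    def test_short_trace_falls_back_to_global_quadratic(self):
        t = np.linspace(0, 1.0, 5)
        pts = np.stack([t, 0.2 * t], axis=-1)
        with pytest.warns(UserWarning, match="global quadratic"):
            out = wf.smooth_trace(pts, window_mm=4.0)
        assert np.abs(out - pts).max() < 1e-9  # line reproduced exactly


class TestResampleTrace:
    def test_straight_segment_node_count(self):
        pts = np.stack([np.linspace(0, 10, 1000), np.zeros(1000)], axis=-1)
        tr = wf.resample_trace(pts, spacing=0.25)
        assert tr.n_nodes == 41
        np.testing.assert_allclose(tr.S, 10.0, atol=1e-9)

    def test_quarter_circle_arc_length(self):
        t = np.linspace(0, np.pi / 2, 5000)
        pts = 10.0 * np.stack([np.sin(t), 1 - np.cos(t)], axis=-1)
        tr = wf.resample_trace(pts, spacing=0.25)
        assert abs(wf.arc_length(tr) - 10 * np.pi / 2) / (10 * np.pi / 2) < 1e-3

    def test_uniform_chord_spacing_invariant(self):
        t = np.linspace(0, np.pi / 2, 5000)
        pts = 10.0 * np.stack([np.sin(t), 1 - np.cos(t)], axis=-1)
        tr = wf.resample_trace(pts, spacing=0.25)
        chords = np.hypot(*np.diff(tr.nodes, axis=0).T)
        assert np.abs(chords[:-1] - 0.25).max() < 1e-6
        assert chords[-1] <= 0.25 + 1e-9

    def test_resampling_is_idempotent(self):
        t = np.linspace(0, np.pi / 2, 5000)
        pts = 20.0 * np.stack([np.sin(t), 1 - np.cos(t)], axis=-1)
        tr1 = wf.resample_trace(pts, spacing=0.25)
        tr2 = wf.resample_trace(tr1.nodes, spacing=0.25)
        assert len(tr1.nodes) == len(tr2.nodes)
        assert np.abs(tr1.nodes - tr2.nodes).max() < 1e-6

    def test_zero_spacing_rejected(self):
        with pytest.raises(ConfigurationError):
            wf.resample_trace(np.array([[0, 0], [1, 0]]), spacing=0.0)

    def test_spacing_longer_than_trace_rejected(self):
        with pytest.raises(DegenerateTraceError):
            wf.resample_trace(np.array([[0, 0], [1, 0]]), spacing=5.0)


class TestArcLength:
    def test_straight_line(self):
        tr = straight_trace(length=10.0)
        np.testing.assert_allclose(wf.arc_length(tr), 10.0, atol=1e-9)

    def test_half_circle(self):
        t = np.linspace(0, np.pi, 8000)
        pts = np.stack([np.sin(t), 1 - np.cos(t)], axis=-1)
        tr = wf.resample_trace(pts, spacing=0.05)
        assert abs(wf.arc_length(tr) - np.pi) / np.pi < 1e-3

    def test_arc_length_at_least_chord(self, quadratic_trace):
        chord = np.hypot(*(quadratic_trace.nodes[-1] - quadratic_trace.nodes[0]))
        assert wf.arc_length(quadratic_trace) >= chord


class TestOrientation:
    def test_straight_line_bounds_collapse(self):
        tr = straight_trace(angle=np.deg2rad(30.0), length=30.0)
        b = wf.orientation_bounds(tr)
        np.testing.assert_allclose(b.alpha_min, -np.deg2rad(30), atol=1e-6)
        np.testing.assert_allclose(b.alpha_max, -np.deg2rad(30), atol=1e-6)

    def test_parabola_bounds_bracket_zero_from_below(self):
        # oracle: per-fraction least-squares line angle computed directly
        x = np.linspace(0, 40, 4000)
        tr = wf.resample_trace(np.stack([x, 0.05 * x * x], axis=-1), 0.25)
        b = wf.orientation_bounds(tr)
        assert b.alpha_max <= 0
        assert b.alpha_min < b.alpha_max
        # |alpha| grows with fraction: smallest fraction gives the max
        a_small = wf.proximal_alignment_angle(tr, 0.01)
        a_large = wf.proximal_alignment_angle(tr, 0.20)
        assert abs(a_large) > abs(a_small)
        np.testing.assert_allclose(b.alpha_min, a_large, atol=1e-12)

    def test_too_short_trace_is_degenerate(self):
        tr = wf.Trace(nodes=np.array([[0, 0], [0.25, 0], [0.5, 0]]),
                      s=np.array([0, 0.25, 0.5]))
        with pytest.raises(DegenerateTraceError):
            wf.proximal_alignment_angle(tr, 0.01)


class TestStandardize:
    def test_identity_when_already_standard(self, quadratic_trace):
        out = wf.standardize(quadratic_trace, alpha=0.0)
        assert not out.flipped
        np.testing.assert_allclose(out.nodes, quadratic_trace.nodes, atol=1e-12)

    def test_concave_down_is_flipped(self):
        x = np.linspace(0, 20, 2000)
        tr = wf.resample_trace(np.stack([x, -0.02 * x * x], axis=-1), 0.25)
        out = wf.standardize(tr, alpha=0.0)
        assert out.flipped
        assert np.trapezoid(out.nodes[:, 1], out.nodes[:, 0]) > 0

    def test_translation_invariance(self, quadratic_trace):
        shifted = wf.Trace(nodes=quadratic_trace.nodes + [13.0, -4.0],
                           s=quadratic_trace.s)
        a = wf.standardize(quadratic_trace, alpha=0.1)
        b = wf.standardize(shifted, alpha=0.1)
        np.testing.assert_allclose(a.nodes, b.nodes, atol=1e-9)

    def test_rigid_transform_preserves_distances(self, quadratic_trace):
        out = wf.standardize(quadratic_trace, alpha=0.3)
        i, j = 5, 80
        d_in = np.hypot(*(quadratic_trace.nodes[i] - quadratic_trace.nodes[j]))
        d_out = np.hypot(*(out.nodes[i] - out.nodes[j]))
        assert abs(d_in - d_out) < 1e-9


class TestTruncateBackwards:
    def test_monotone_trace_unchanged(self, quadratic_trace):
        out = wf.truncate_backwards(quadratic_trace)
        assert out.n_nodes == quadratic_trace.n_nodes

    def test_half_circle_truncated_at_max_x(self):
        # oracle: running-max scan of the generated circle nodes
        t = np.linspace(0, 0.8 * np.pi, 8000)
        pts = 20.0 * np.stack([np.sin(t), 1 - np.cos(t)], axis=-1)
        tr = wf.resample_trace(pts, 0.25)
        std = wf.standardize(tr, 0.0)
        out = wf.truncate_backwards(std)
        x = std.nodes[:, 0]
        expected_cut = np.nonzero(x < np.maximum.accumulate(x) - 1e-12)[0][0]
        assert out.n_nodes == expected_cut
        assert np.all(np.diff(np.maximum.accumulate(out.nodes[:, 0])) >= 0)

    def test_early_backwards_curl_is_degenerate(self):
        nodes = np.array([[0, 0], [0.25, 0], [0.5, 0.05], [0.4, 0.2],
                          [0.2, 0.3], [0.0, 0.3]])
        d = np.hypot(*np.diff(nodes, axis=0).T)
        std = wf.StandardOrientedTrace(
            nodes=nodes, s=np.concatenate([[0], np.cumsum(d)]))
        with pytest.raises(DegenerateTraceError):
            wf.truncate_backwards(std)


class TestPreprocessPipeline:
    def test_full_pipeline_returns_standard_trace(self):
        spec = wf.SyntheticSpec("cesaro", {"A": 0.001, "B": 0.01}, S=40,
                                noise_dpi=6400, rotation=1.0, translation=(30, 5))
        pre = wf.preprocess(wf.generate_whisker(spec))
        assert np.allclose(pre.trace.nodes[0], [0, 0])
        assert abs(pre.trace.S - 40.0) / 40.0 < 0.01
        # proximal region roughly along +x
        k = max(2, int(0.05 * pre.trace.n_nodes))
        assert abs(np.arctan2(pre.trace.nodes[k, 1], pre.trace.nodes[k, 0])) < 0.2
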