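"""Strain-measure tests: closed forms, invariances, cross-checks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import meshstrain as ms
from conftest import tracks_from_positions

UNIT_CELL = [(0, 1, 2, 3)]
SQUARE = np.array([[0.0, 0.0], [10.0, 0.0], [10.0, 10.0], [0.0, 10.0]])


def _affine_tracks(F_list, points=SQUARE):
    pos = np.stack([points @ np.asarray(F).T for F in F_list])
    return tracks_from_positions(pos)


class TestSegmentStrain:
    @pytest.fixture()
    def line_graph(self):
        segs = [ms.Segment(0, 0, 1, "x", 100.0)]
        return ms.LatticeGraph(np.array([[0.0, 0.0], [100.0, 0.0]]), segs)

    def test_identity_gives_zero(self, line_graph):
        tracks = tracks_from_positions([line_graph.ref_positions] * 3)
        df = ms.segment_strain(tracks, line_graph)
        assert np.allclose(df["epsilon"], 0.0)
        assert np.allclose(df["lambda"], 1.0)

    def test_direct_formula(self, line_graph):
        pos = np.stack([line_graph.ref_positions,
                        np.array([[0.0, 0.0], [145.0, 0.0]])])
        df = ms.segment_strain(tracks_from_positions(pos), line_graph)
        row = df[df["frame"] == 1].iloc[0]
        assert row["epsilon"] == pytest.approx(0.45)
        assert row["lambda"] == pytest.approx(1.45)

    def test_3d_euclidean_lengths(self):
        # (0,0,0) -> (3,4,12) um with l0 = 10 um: l = 13, eps = 0.3
        ref = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]])
        cur = np.array([[0.0, 0.0, 0.0], [3.0, 4.0, 12.0]])
        graph = ms.LatticeGraph(ref, [ms.Segment(0, 0, 1, "x", 10.0)])
        df = ms.segment_strain(tracks_from_positions(np.stack([ref, cur])),
                               graph)
        row = df[df["frame"] == 1].iloc[0]
        assert row["l_um"] == pytest.approx(13.0)
        assert row["epsilon"] == pytest.approx(0.3)

    def test_short_reference_segment_excluded(self, line_graph):
        tracks = tracks_from_positions([line_graph.ref_positions] * 2)
        df = ms.segment_strain(tracks, line_graph, min_ref_length=200.0)
        assert df.empty

    def test_missing_endpoint_gives_absent_row(self, line_graph):
        pos = np.stack([line_graph.ref_positions] * 3)
        status = np.full((3, 2), ms.TRACKED, np.int8)
        status[1, 1] = ms.MISSING
        tracks = ms.NodeTracks(pos, status)
        df = ms.segment_strain(tracks, line_graph)
        assert sorted(df["frame"]) == [0, 2]


class TestElementStrain:
    def test_identity_motion(self):
        df = ms.element_strain(_affine_tracks([np.eye(2)] * 2), UNIT_CELL)
        row = df[df["frame"] == 1].iloc[0]
        for k in ("Exx", "Eyy", "Exy", "P1", "P2"):
            assert row[k] == pytest.approx(0.0, abs=1e-12)
        assert row["dilation"] == pytest.approx(1.0)

    def test_uniaxial_closed_form(self):
        # F = diag(1.45, 1.45**-0.5): E from the Green-Lagrange closed form
        lam1, lam2 = 1.45, 1.45 ** -0.5
        df = ms.element_strain(_affine_tracks([np.eye(2), np.diag([lam1, lam2])]),
                               UNIT_CELL)
        row = df[df["frame"] == 1].iloc[0]
        assert row["Exx"] == pytest.approx(0.5 * (lam1 ** 2 - 1))
        assert row["Eyy"] == pytest.approx(0.5 * (lam2 ** 2 - 1))
        assert row["Exy"] == pytest.approx(0.0, abs=1e-12)
        assert row["dilation"] == pytest.approx(lam1 * lam2)
        assert row["P1"] == pytest.approx(0.5 * (lam1 ** 2 - 1))
        assert row["theta_deg"] == pytest.approx(0.0, abs=1e-9)

    @given(st.floats(-180, 180))
    @settings(max_examples=25, deadline=None)
    def test_rigid_rotation_gives_zero_strain(self, angle):
        th = np.deg2rad(angle)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        df = ms.element_strain(_affine_tracks([np.eye(2), R]), UNIT_CELL)
        row = df[df["frame"] == 1].iloc[0]
        assert abs(row["Exx"]) < 1e-12
        assert abs(row["Eyy"]) < 1e-12
        assert abs(row["Exy"]) < 1e-12
        assert row["dilation"] == pytest.approx(1.0)

    def test_principal_strain_invariant_direction_rotates(self):
        # rotating the lab frame (reference and deformed alike) leaves the
        # principal strains unchanged and rotates the principal direction
        lam = np.diag([1.3, 0.9])
        th = np.deg2rad(30)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        plain = ms.element_strain(_affine_tracks([np.eye(2), lam]), UNIT_CELL)
        pos_rot = np.stack([SQUARE @ R.T, SQUARE @ lam.T @ R.T])
        rotated = ms.element_strain(tracks_from_positions(pos_rot), UNIT_CELL)
        a, b = plain.iloc[1], rotated.iloc[1]
        assert b["P1"] == pytest.approx(a["P1"])
        assert b["P2"] == pytest.approx(a["P2"])
        assert b["theta_deg"] == pytest.approx(a["theta_deg"] + 30.0)

    def test_segment_element_consistency(self):
        # uniaxial: E_xx = eps + eps^2/2 links the two strain measures
        lam = 1.25
        graph = ms.LatticeGraph(SQUARE,
                                [ms.Segment(0, 0, 1, "x", 10.0)],
                                cells=UNIT_CELL)
        tracks = _affine_tracks([np.eye(2), np.diag([lam, 1.0])])
        eps = ms.segment_strain(tracks, graph).query("frame == 1")["epsilon"].iloc[0]
        exx = ms.element_strain(tracks, UNIT_CELL).query("frame == 1")["Exx"].iloc[0]
        assert exx == pytest.approx(eps + eps ** 2 / 2)

    def test_degenerate_reference_cell_excluded(self):
        flat = SQUARE.copy()
        flat[:, 1] = 0.0
        df = ms.element_strain(tracks_from_positions([flat, flat]), UNIT_CELL)
        assert df.empty


class TestDilation:
    @given(st.floats(0.5, 2.0), st.floats(0.5, 2.0))
    @settings(max_examples=25, deadline=None)
    def test_affine_dilation_equals_det_F(self, lx, ly):
        df = ms.dilation(_affine_tracks([np.eye(2), np.diag([lx, ly])]),
                         UNIT_CELL)
        assert df.query("frame == 1")["dilation"].iloc[0] == \
            pytest.approx(lx * ly, rel=1e-9)

    def test_area_preserving_stretch(self):
        lam = 1.4
        df = ms.dilation(_affine_tracks([np.eye(2), np.diag([lam, 1 / lam])]),
                         UNIT_CELL)
        assert df.query("frame == 1")["dilation"].iloc[0] == pytest.approx(1.0)

    def test_centered_report(self):
        df = ms.dilation(_affine_tracks([np.eye(2), np.diag([1.2, 1.1])]),
                         UNIT_CELL, report="centered")
        assert df.query("frame == 1")["dilation"].iloc[0] == \
            pytest.approx(0.32)

    def test_self_intersecting_polygon_flagged(self):
        bow = SQUARE[[0, 1, 3, 2]]          # bow-tie ordering
        pos = np.stack([SQUARE, bow])
        df = ms.dilation(tracks_from_positions(pos), UNIT_CELL)
        row = df.query("frame == 1").iloc[0]
        assert row["flagged"]
        assert np.isnan(row["dilation"])

    def test_mask_projection_agrees_with_polygons(self, small_series,
                                                  small_result, mesh5):
        series, _ = small_series
        res = small_result
        poly = ms.dilation(res.tracks, res.graph.cells)
        mask = ms.dilation(res.tracks, res.graph.cells, mode="mask_projection",
                           masks=res.masks, pixel_size=series.pixel_size)
        t = series.n_frames - 1
        a = poly.query("frame == @t").set_index("cell_id")["dilation"]
        b = mask.query("frame == @t").set_index("cell_id")["dilation"]
        joined = pd.concat([a, b], axis=1, keys=["poly", "mask"]).dropna()
        assert len(joined) == 16
        rel = (joined["mask"] - joined["poly"]).abs() / joined["poly"]
        assert rel.max() < 0.05


class TestFractionalShortening:
    def _table(self, areas):
        rows = [(t, cid, a, a / areas[0][cid], False)
                for t, frame in enumerate(areas) for cid, a in frame.items()]
        return pd.DataFrame(rows, columns=["frame", "cell_id", "area_um2",
                                           "dilation", "flagged"])

    def test_constant_areas_give_zero(self):
        tab = self._table([{0: 50.0, 1: 50.0}] * 4)
        assert ms.fractional_shortening(tab, [0, 1]) == pytest.approx(0.0)

    def test_direct_formula(self):
        # combined area oscillating 100 <-> 96.16 -> 3.84 %
        tab = self._table([{0: 60.0, 1: 40.0}, {0: 57.7, 1: 38.46},
                           {0: 60.0, 1: 40.0}])
        assert ms.fractional_shortening(tab, [0, 1]) == pytest.approx(3.84)

    def test_empty_region_rejected(self):
        tab = self._table([{0: 1.0}])
        with pytest.raises(ValueError):
            ms.fractional_shortening(tab, [])

    def test_frame_range_restriction(self):
        tab = self._table([{0: 100.0}, {0: 50.0}, {0: 100.0}])
        assert ms.fractional_shortening(tab, [0], t_range=(2, 2)) == 0.0


class TestDisplacementVectors:
    def test_uniform_translation(self):
        pos = np.stack([SQUARE, SQUARE + [5.0, -2.0]])
        df = ms.displacement_vectors(tracks_from_positions(pos))
        sub = df.query("frame == 1")
        assert np.allclose(sub["dx_um"], 5.0)
        assert np.allclose(sub["dy_um"], -2.0)
        assert np.allclose(sub["magnitude_um"], np.hypot(5, 2))

    def test_identity_zero(self):
        df = ms.displacement_vectors(tracks_from_positions([SQUARE] * 2))
        assert np.allclose(df["magnitude_um"], 0.0)


class TestStress:
    def test_linear_arithmetic(self):
        assert ms.stress_estimate(0.0, 2000.0) == 0.0
        assert ms.stress_estimate(0.3288, 2000.0) == pytest.approx(657.6)
        assert abs(ms.stress_estimate(-0.2673, 2000.0)) == pytest.approx(534.6)

    @given(st.floats(-0.9, 5.0), st.floats(1.0, 1e6))
    @settings(max_examples=50, deadline=None)
    def test_sign_and_zero_correspondence(self, eps, mod):
        sigma = ms.stress_estimate(eps, mod)
        assert np.sign(sigma) == np.sign(eps)

    def test_table_and_summary(self):
        tab = pd.DataFrame({"segment_id": [0, 1], "epsilon": [0.1, 0.3]})
        out = ms.stress_estimate(tab, 1000.0)
        assert np.allclose(out["sigma_pa"], [100.0, 300.0])
        summ = ms.stress_summary(tab, 1000.0, segment_ids=[0, 1])
        assert summ["mean_pa"] == pytest.approx(200.0)
        assert summ["n"] == 2

    def test_modulus_must_be_positive(self):
        with pytest.raises(ValueError):
            ms.stress_estimate(0.1, -5.0)


class TestStretchSummary:
    def _segment_table(self, lam1, lam2):
        rows = []
        for t, (a, b) in enumerate(zip(lam1, lam2)):
            rows.append((t, 0, a, "x"))
            rows.append((t, 1, b, "y"))
        return pd.DataFrame(rows, columns=["frame", "segment_id", "lambda",
                                           "orientation"])

    def test_incompressible_identity(self):
        lam1 = 1 + 0.03 * np.arange(6)
        lam2 = lam1 ** -0.5
        macro = ms.MacroscopicSeries(frame=np.arange(6), lambda3=lam2,
                                     lambda1=lam1, lambda2=lam2)
        tab, stats = ms.stretch_summary(self._segment_table(lam1, lam2), macro)
        assert np.allclose(tab["product"], 1.0, atol=1e-12)
        assert stats["slope_lambda3_on_lambda2"] == pytest.approx(1.0)
        assert stats["pearson_lambda23"] == pytest.approx(1.0)
        assert stats["pearson_eps1"] == pytest.approx(1.0)

    def test_compressible_law_slope(self):
        k = np.arange(10)
        lam1 = 1 + 0.01 * k
        lam2 = 1 - 0.005 * k
        lam3 = 1 - 1.42 * (1 - lam2)
        macro = ms.MacroscopicSeries(frame=k, lambda3=lam3)
        tab, stats = ms.stretch_summary(self._segment_table(lam1, lam2), macro)
        assert stats["slope_lambda3_on_lambda2"] == pytest.approx(1.42)
        assert (tab["product"][1:] < 1.0).all()

    def test_too_few_steps_rejected(self):
        macro = ms.MacroscopicSeries(frame=np.arange(2), lambda3=np.ones(2))
        with pytest.raises(ValueError, match="3 steps"):
            ms.stretch_summary(self._segment_table([1.0, 1.1], [1.0, 0.95]),
                               macro)

    def test_nonpositive_stretch_rejected(self):
        with pytest.raises(ValueError):
            ms.MacroscopicSeries(frame=np.arange(3), lambda3=np.array([1, 0, 1.0]))
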