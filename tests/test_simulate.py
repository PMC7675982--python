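"""Synthetic-rendering tests: geometry, determinism, kinematic ground truth."""

import numpy as np
import pytest

import meshstrain as ms
from meshstrain.simulate import OscillatoryField, SmoothWarpField


class TestMeshSpec:
    @pytest.mark.parametrize("kwargs", [
        dict(pitch=2, line_width=2),          # pitch must exceed line width
        dict(pitch=2, line_width=-1),
        dict(pitch=10, line_width=1, rows=1),
        dict(pitch=10, line_width=1, cols=1),
    ])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ms.MeshSpec(**kwargs)

    def test_lattice_combinatorics(self, mesh5):
        # m*(n-1) + n*(m-1) segments and (m-1)(n-1) cells for m = n = 5
        assert mesh5.n_nodes == 25
        assert len(mesh5.segment_pairs()) == 40
        assert len(mesh5.cell_quads()) == 16


class TestRenderFrame:
    def test_foreground_area_fraction(self, mesh5):
        # closed form for a square lattice: 1 - ((pitch - w)/pitch)^2
        mesh = ms.MeshSpec(pitch=100, line_width=10, rows=5, cols=5)
        img = ms.render_frame(mesh, ms.IdentityField(), 0, pixel_size=1.0,
                              origin_um=(0, 0), shape=(401, 401), psf_sigma=0.0)
        frac = float((img >= 0.5).mean())
        assert frac == pytest.approx(1 - (90 / 100) ** 2, rel=0.15)

    def test_identity_peak_through_intersections(self, identity_render, true_nodes):
        # brightest pixels pass through (i*pitch, j*pitch) intersections
        for x, y in true_nodes:
            assert identity_render[int(round(y)), int(round(x))] >= \
                0.99 * identity_render.max()

    def test_deterministic_given_seed(self, mesh5):
        a = ms.render_frame(mesh5, ms.IdentityField(), 0, noise_sigma=0.1, rng=7)
        b = ms.render_frame(mesh5, ms.IdentityField(), 0, noise_sigma=0.1, rng=7)
        assert a.tobytes() == b.tobytes()

    def test_rot90_symmetry_of_square_mesh(self, mesh5):
        img = ms.render_frame(mesh5, ms.IdentityField(), 0, pixel_size=1.0,
                              origin_um=(-20, -20), shape=(201, 201))
        assert np.allclose(img, np.rot90(img), atol=1e-6)

    def test_noise_requires_seed(self, mesh5):
        with pytest.raises(ValueError, match="seed"):
            ms.render_frame(mesh5, ms.IdentityField(), 0, noise_sigma=0.1)

    def test_mesh_out_of_frame_rejected(self, mesh5):
        with pytest.raises(ValueError, match="out of frame"):
            ms.render_frame(mesh5, ms.IdentityField(), 0,
                            origin_um=(0, 0), shape=(50, 50))

    def test_fold_over_rejected(self, mesh5):
        flip = ms.AffineField(lambda t: np.diag([1.0, 1.0 - 2.0 * t]))
        with pytest.raises(ValueError, match="fold-over"):
            ms.render_frame(mesh5, flip, 1)
        warp = SmoothWarpField(amplitude=200.0, wavelength=30.0, seed=0)
        with pytest.raises(ValueError, match="fold-over"):
            ms.render_frame(mesh5, warp, 1)


class TestUniaxialSeries:
    def test_frame_count_and_reference(self, mesh5):
        series, truth = ms.make_uniaxial_series(mesh5, 0.45, 0.03,
                                                pixel_size=2.0)
        assert series.n_frames == 16          # 0.45/0.03 steps + reference
        assert np.allclose(truth.segment_lengths(0), truth.ref_lengths)

    def test_incompressible_kinematics(self, small_series):
        _, truth = small_series
        lam1 = truth.F[:, 0, 0]
        lam2 = truth.F[:, 1, 1]
        assert lam1[-1] == pytest.approx(1.45)
        assert lam2[-1] == pytest.approx(1.45 ** -0.5, abs=1e-12)
        product = lam1 * lam2 * truth.lambda3
        assert np.allclose(product, 1.0, atol=1e-12)

    def test_anisotropic_product_below_one(self):
        mesh = ms.MeshSpec(pitch=40, line_width=4, rows=3, cols=3)
        _, truth = ms.make_uniaxial_series(
            mesh, 0.05, 0.01, mode="anisotropic",
            lateral_law=lambda k: 1 - 0.005 * k,
            thickness_law=lambda k: 1 - 0.0071 * k, pixel_size=2.0)
        lam3 = truth.lambda3
        lam2 = truth.F[:, 1, 1]
        assert np.allclose(lam3, 1 - 1.42 * (1 - lam2), atol=1e-12)
        prod = truth.F[:, 0, 0] * lam2 * lam3
        assert (prod[1:] < 1).all()

    def test_bad_step_rejected(self, mesh5):
        with pytest.raises(ValueError):
            ms.make_uniaxial_series(mesh5, 0.45, -0.03)
        with pytest.raises(ValueError):
            ms.make_uniaxial_series(mesh5, 0.03, 0.45)

    def test_thickness_table(self, small_series):
        _, truth = small_series
        tab = truth.thickness_table()
        assert list(tab.columns) == ["frame", "lambda3", "epsilon3"]
        assert np.allclose(tab["lambda3"], tab["epsilon3"] + 1)


class TestOscillatoryMovie:
    def test_frame_count_and_true_frequency(self):
        mesh = ms.MeshSpec(pitch=40, line_width=4, rows=2, cols=2)
        series, truth = ms.make_oscillatory_movie(
            mesh, [(None, 5 / 7, 2.0)], duration=30, fps=20, pixel_size=2.0)
        assert series.n_frames == 600
        (mask, freq), = truth.region_freqs
        assert freq == pytest.approx(1.4)
        assert mask.all()

    def test_zero_amplitude_is_static(self):
        mesh = ms.MeshSpec(pitch=40, line_width=4, rows=2, cols=2)
        series, _ = ms.make_oscillatory_movie(
            mesh, [(None, 2.0, 0.0)], duration=6, fps=4, pixel_size=2.0)
        assert np.allclose(series.frames, series.frames[0])

    def test_two_regions_piecewise_truth(self):
        mesh = ms.MeshSpec(pitch=40, line_width=4, rows=2, cols=4)
        series, truth = ms.make_oscillatory_movie(
            mesh, [((-50.0, 60.0), 2.0, 2.0), ((60.0, 200.0), 3.0, 2.0)],
            duration=12, fps=4, pixel_size=2.0)
        (m1, f1), (m2, f2) = truth.region_freqs
        assert f1 == pytest.approx(0.5) and f2 == pytest.approx(1 / 3)
        assert not (m1 & m2).any()

    def test_short_recording_warns(self):
        mesh = ms.MeshSpec(pitch=40, line_width=4, rows=2, cols=2)
        with pytest.warns(UserWarning, match="cycles"):
            ms.make_oscillatory_movie(mesh, [(None, 10.0, 1.0)],
                                      duration=5, fps=4, pixel_size=2.0)

    def test_sub_nyquist_sampling_warns(self):
        mesh = ms.MeshSpec(pitch=40, line_width=4, rows=2, cols=2)
        with pytest.warns(UserWarning, match="alias"):
            ms.make_oscillatory_movie(mesh, [(None, 0.5, 1.0)],
                                      duration=10, fps=2, pixel_size=2.0)

    def test_displacement_is_sinusoidal(self):
        field = OscillatoryField([(None, 2.0, 3.0)], direction=(0, 1))
        pts = np.array([[5.0, 5.0]])
        t = 0.25
        u = field.displacement(pts, t)
        assert u[0, 1] == pytest.approx(3.0 * np.sin(2 * np.pi * t / 2.0))
        assert u[0, 0] == 0.0


class TestFieldFactory:
    def test_kinds_construct(self):
        assert ms.make_field("identity").kind == "identity"
        f = ms.make_field("incompressible_uniaxial", step=0.03)
        assert f.lambda3(15) == pytest.approx(1.45 ** -0.5)
        with pytest.raises(ValueError, match="unknown field kind"):
            ms.make_field("spline")

    def test_phi0_identity_enforced(self):
        with pytest.raises(ValueError):
            ms.AffineField(lambda t: np.diag([2.0, 1.0]) if t == 0 else np.eye(2))
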