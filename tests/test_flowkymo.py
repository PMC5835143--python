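"""Optical flow, kymographs, and directional decomposition."""

import numpy as np
import pytest

from synmesh.core import CalibratedImage, SynapseMovie
from synmesh.flowkymo import (
    FarnebackParams,
    component_energies,
    compute_flow,
    decompose_kymograph,
    extract_kymograph,
    line_profile,
    rim_kymograph,
    KymographBundle,
)
from synmesh.synthdata import FootprintSpec, SimulationConfig, render_mesh_movie
from conftest import disk_image, gaussian_spot_image


def textured_frame(seed=5, size=(160, 160)):
    cfg = SimulationConfig(
        image_size_px=size,
        n_frames=1,
        footprint_spec=FootprintSpec(60, 60, 1),
        psf_fwhm_um=0.13,
        recon_sigma_um=0.08,
        noise_gaussian_sd=0.05,
        rng_seed=seed,
    )
    movie, _ = render_mesh_movie(cfg)
    return movie.channels["actin"][0]


def movie_from(frames, px=0.04, dt=5.0):
    return SynapseMovie(
        channels={"actin": np.stack(frames)}, pixel_size_um=px, frame_interval_s=dt
    )


class TestFlow:
    def test_printed_parameter_defaults(self):
        p = FarnebackParams()
        assert (
            p.num_pyramid_levels,
            p.pyramid_scale,
            p.num_iterations,
            p.neighborhood_size,
            p.filter_size,
        ) == (3, 0.5, 3, 5, 15)

    def test_static_movie_near_zero_flow(self):
        base = textured_frame()
        fields = compute_flow(movie_from([base, base, base]))
        for f in fields:
            assert np.median(f.magnitude) < 0.05

    def test_rigid_translation_recovered(self):
        base = textured_frame()
        frames = [np.roll(base, i, axis=1) for i in range(3)]
        fields = compute_flow(movie_from(frames))
        interior = np.s_[30:-30, 30:-30]
        for f in fields:
            assert abs(np.median(f.dx[interior]) - 1.0) <= 0.2
            assert abs(np.median(f.magnitude[interior]) - 1.0) <= 0.2

    def test_pure_noise_no_systematic_drift(self):
        # temporally uncorrelated frames carry no true motion: individual
        # fields fluctuate, but across seeds the estimator must be unbiased
        # (no spurious drift) and frame pairs statistically alike
        drifts_x, drifts_y, mags = [], [], []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            frames = [rng.uniform(0, 1, (96, 96)) for _ in range(3)]
            fields = compute_flow(movie_from(frames))
            for f in fields:
                drifts_x.append(f.dx.mean())
                drifts_y.append(f.dy.mean())
            mags.append([f.magnitude.mean() for f in fields])
        assert abs(np.mean(drifts_x)) < 0.1
        assert abs(np.mean(drifts_y)) < 0.1
        mags = np.array(mags)
        # consecutive frame pairs have statistically indistinguishable
        # magnitude (paired across seeds)
        diff = mags[:, 0] - mags[:, 1]
        assert abs(diff.mean()) < 2 * diff.std(ddof=1) / np.sqrt(len(diff)) + 0.1

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            compute_flow(movie_from([textured_frame()]))


class TestKymograph:
    def _band_movie(self, v=1.0, n=40, ny=64, nx=128, sigma2=4.5):
        stack = np.zeros((n, ny, nx))
        xx = np.arange(nx)
        for t in range(n):
            stack[t] += np.exp(-((xx - (20 + v * t)) ** 2) / (2 * sigma2))[None, :]
        return movie_from(list(stack))

    def _hline(self, nx=128, y=32, px=0.04):
        return np.array([[0.2, y * px], [(nx - 2) * px, y * px]])

    def test_static_movie_columns_identical(self):
        frame = textured_frame(size=(96, 96))
        mv = movie_from([frame] * 5)
        line = np.array([[0.2, 1.9], [3.6, 1.9]])
        k = extract_kymograph(mv, line)
        assert np.allclose(k.total, k.total[:, :1])

    def test_moving_band_ridge_slope(self):
        mv = self._band_movie(v=1.0)
        k = extract_kymograph(mv, self._hline())
        peaks = np.argmax(k.total, axis=0)  # ridge position per frame
        slope = np.polyfit(np.arange(len(peaks)), peaks, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.1)

    def test_width_averaging_matches_on_uniform_structure(self):
        mv = self._band_movie()
        k1 = extract_kymograph(mv, self._hline(), width_px=1)
        k3 = extract_kymograph(mv, self._hline(), width_px=3)
        assert np.allclose(k1.total, k3.total, atol=1e-9)

    def test_line_outside_image_rejected(self):
        mv = self._band_movie()
        with pytest.raises(ValueError):
            extract_kymograph(mv, np.array([[0.0, 0.0], [50.0, 0.0]]))


class TestDecomposition:
    def _single_velocity(self, v=1.0, P=96, T=96):
        # high-spatial-frequency traveling wave: unambiguous direction
        p = np.arange(P)[:, None]
        t = np.arange(T)[None, :]
        return np.cos(2 * np.pi * 0.15 * (p - v * t))

    def _bundle(self, mat):
        return KymographBundle(
            line_um=np.array([[0, 0], [1, 0]]),
            total=mat,
            pixel_size_um=0.04,
            frame_interval_s=5.0,
        )

    def test_forward_pattern_energy_in_forward_component(self):
        b = decompose_kymograph(self._bundle(self._single_velocity(+1.0)))
        e = component_energies(b)
        frac = e["forward"] / (e["forward"] + e["backward"] + e["static"])
        assert frac >= 0.90

    def test_reconstruction_within_tolerance(self):
        rng = np.random.default_rng(4)
        b = decompose_kymograph(self._bundle(rng.uniform(0, 1, (48, 40))))
        recon = b.forward + b.backward + b.static
        err = np.linalg.norm(recon - b.total) / np.linalg.norm(b.total)
        assert err <= 0.05

    def test_time_constant_kymograph_static(self):
        mat = np.tile(np.sin(np.linspace(0, 8, 64))[:, None], (1, 32))
        b = decompose_kymograph(self._bundle(mat))
        e = component_energies(b)
        assert e["static"] / (e["forward"] + e["backward"] + e["static"]) >= 0.95

    def test_mirror_swaps_forward_backward(self):
        mat = self._single_velocity(+1.0)
        e1 = component_energies(decompose_kymograph(self._bundle(mat)))
        e2 = component_energies(
            decompose_kymograph(self._bundle(mat[::-1].copy()))
        )
        assert e1["forward"] == pytest.approx(e2["backward"], rel=0.01)
        assert e1["backward"] == pytest.approx(e2["forward"], rel=0.01)

    def test_too_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            decompose_kymograph(self._bundle(np.ones((4, 4))))

    def test_non_finite_rejected(self):
        mat = np.ones((16, 16))
        mat[3, 3] = np.nan
        with pytest.raises(ValueError):
            decompose_kymograph(self._bundle(mat))


class TestRim:
    def _cell_movie(self, intensity=None, n=3, size=128, r=50):
        mask = disk_image((size, size), [((size // 2, size // 2), r)])
        img = mask if intensity is None else intensity
        mv = movie_from([img] * n)
        masks = np.stack([mask.astype(bool)] * n)
        return mv, masks

    def test_uniform_cell_constant_matrix(self):
        mv, masks = self._cell_movie()
        mat = rim_kymograph(mv, masks, rim_width_um=1.0)
        vals = mat[np.isfinite(mat)]
        assert np.allclose(vals, vals[0])

    def test_bright_arc_occupies_matching_rows(self):
        size, r = 128, 50
        mask = disk_image((size, size), [((size // 2, size // 2), r)])
        yy, xx = np.mgrid[0:size, 0:size]
        ang = np.arctan2(yy - size // 2, xx - size // 2)
        arc = (np.abs(ang) < np.deg2rad(15)) & mask.astype(bool)  # 30 deg arc
        img = mask + 5.0 * arc
        mv = movie_from([img] * 2)
        masks = np.stack([mask.astype(bool)] * 2)
        mat = rim_kymograph(mv, masks, rim_width_um=1.0)
        hot = mat[:, 0] > 3.0
        frac = hot.sum() / np.isfinite(mat[:, 0]).sum()
        assert frac == pytest.approx(30 / 360, abs=0.03)

    def test_rim_wider_than_cell_rejected(self):
        mv, masks = self._cell_movie(r=10)
        with pytest.raises(ValueError):
            rim_kymograph(mv, masks, rim_width_um=3.0)


class TestLineProfile:
    def test_constant_image_flat(self):
        img = CalibratedImage(np.full((64, 64), 3.0), 0.04)
        prof = line_profile(img, np.array([[0.2, 1.0], [2.0, 1.0]]))
        assert np.allclose(prof["intensity"], 3.0)

    def test_gaussian_spot_fwhm_recovered(self):
        sigma_px = 5.0
        img = CalibratedImage(
            gaussian_spot_image((128, 128), [(64, 64, sigma_px, 1.0)]), 0.04
        )
        prof = line_profile(img, np.array([[0.2, 64 * 0.04], [5.0, 64 * 0.04]]))
        d = prof["distance_um"].to_numpy()
        v = prof["intensity"].to_numpy()
        # interpolate the half-maximum crossings on each side of the peak
        peak = int(np.argmax(v))
        left = np.interp(0.5, v[: peak + 1], d[: peak + 1])
        right = np.interp(0.5, v[peak:][::-1], d[peak:][::-1])
        expected = 2.355 * sigma_px * 0.04
        assert right - left == pytest.approx(expected, rel=0.10)

    def test_zero_length_line_rejected(self):
        img = CalibratedImage(np.ones((32, 32)), 0.04)
        with pytest.raises(ValueError):
            line_profile(img, np.array([[1.0, 1.0], [1.0, 1.0]]))
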