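"""Vesicle tracking and degranulation event calling."""

import numpy as np
import pytest

from synmesh.core import SynapseMovie
from synmesh.events import (
    Call,
    DegranulationConfig,
    VesicleTrack,
    VesicleTrackSet,
    call_degranulation,
    degranulation_rate,
    detect_and_track_vesicles,
    population_frequency,
    review_table,
)
from synmesh.synthdata import (
    BurstSpec,
    FootprintSpec,
    GranuleSpec,
    SimulationConfig,
    render_mesh_movie,
    render_trace_set,
)
from conftest import gaussian_spot_image


def make_track(tid, reporter, frames=None):
    n = len(reporter)
    return VesicleTrack(
        id=tid,
        frames=list(frames or range(n)),
        x_um=[1.0] * n,
        y_um=[1.0] * n,
        granule_intensity=[1.0] * n,
        reporter_intensity=list(reporter),
    )


def trackset(tracks, dt=1.0, n_frames=60):
    return VesicleTrackSet(tracks, dt, n_frames)


def vesicle_movie(n_spots=10, bursts=(), missing=(), n_frames=30, seed=6):
    granules = [
        GranuleSpec(0, n_frames, (2.0 + 1.5 * (i % 4), 2.0 + 1.5 * (i // 4)), 0.3)
        for i in range(n_spots)
    ]
    cfg = SimulationConfig(
        image_size_px=(160, 160),
        pixel_size_um=0.065,
        n_frames=n_frames,
        frame_interval_s=1.0,
        footprint_spec=FootprintSpec(60, 60, 1.0),
        granule_spec=granules,
        burst_spec=list(bursts),
        psf_fwhm_um=0.25,
        recon_sigma_um=0.0,
        noise_gaussian_sd=0.03,
        rng_seed=seed,
    )
    movie, truth = render_mesh_movie(cfg)
    for t in missing:  # blank the granule channel for specific frames
        movie.channels["granule"][t] = 0.0
    return movie, truth


class TestDetectionTracking:
    def test_planted_spots_tracked_with_subpixel_accuracy(self):
        movie, truth = vesicle_movie(n_spots=10)
        ts = detect_and_track_vesicles(movie)
        assert len(ts) == 10
        px = movie.pixel_size_um
        truth_pos = {
            (g.x_um, g.y_um) for g in truth.granules.itertuples()
        }
        for tr in ts.tracks:
            mx, my = np.mean(tr.x_um), np.mean(tr.y_um)
            err = min(np.hypot(mx - x, my - y) for x, y in truth_pos)
            assert err < 0.5 * px

    def test_empty_channel_empty_trackset(self):
        movie, _ = vesicle_movie(n_spots=1)
        movie.channels["granule"][:] = 0.0
        ts = detect_and_track_vesicles(movie)
        assert len(ts) == 0

    def test_one_frame_dropout_gap_closed(self):
        movie, _ = vesicle_movie(n_spots=4, missing=(10,))
        ts = detect_and_track_vesicles(movie)
        assert len(ts) == 4
        for tr in ts.tracks:
            assert 10 not in tr.frames
            assert tr.frames[0] < 10 < tr.frames[-1]

    def test_missing_channel_rejected(self):
        movie, _ = vesicle_movie(n_spots=1)
        del movie.channels["granule"]
        movie.channels.setdefault("actin", movie.channels["reporter"])
        with pytest.raises(ValueError, match="granule"):
            detect_and_track_vesicles(movie)


class TestCalls:
    def test_sd_rule_with_control_reference(self):
        rng = np.random.default_rng(0)
        sigma0 = 1.0
        control = make_track(0, rng.normal(0, sigma0, 200))
        mid = make_track(1, rng.normal(0, 1.5 * sigma0, 200))
        hot = make_track(2, rng.normal(0, 2.5 * sigma0, 200))
        cfg = DegranulationConfig(reference_mode="control_tracks")
        ts = call_degranulation(
            trackset([control, mid, hot]), cfg, control_track_ids=[0]
        )
        calls = {tr.id: tr.call for tr in ts.tracks}
        assert calls[1] is Call.NON_DEGRANULATING
        assert calls[2] is Call.DEGRANULATING

    def test_exactly_twice_reference_not_called(self):
        base = np.array([0.0, 2.0] * 30)  # SD = 1
        doubled = np.array([0.0, 4.0] * 30)  # SD exactly 2x
        cfg = DegranulationConfig(reference_mode="control_tracks")
        ts = call_degranulation(
            trackset([make_track(0, base), make_track(1, doubled)]),
            cfg,
            control_track_ids=[0],
        )
        assert ts.tracks[1].sd_ratio == pytest.approx(2.0)
        assert ts.tracks[1].call is Call.NON_DEGRANULATING

    def test_constant_traces_no_calls(self):
        tracks = [make_track(i, [3.0] * 50) for i in range(5)]
        ts = call_degranulation(trackset(tracks))
        assert all(tr.call is Call.NON_DEGRANULATING for tr in ts.tracks)

    def test_amplitude_monotonicity(self):
        # raising a burst amplitude never flips degranulating -> non
        rng = np.random.default_rng(1)
        noise = rng.normal(0, 0.05, 60)
        cfg = DegranulationConfig(reference_mode="control_tracks")
        prev_called = False
        for amp in (0.0, 0.2, 0.5, 1.0, 3.0, 10.0):
            trace = 1.0 + noise.copy()
            trace[30:] += amp
            ts = call_degranulation(
                trackset(
                    [make_track(0, 1.0 + noise), make_track(1, trace)]
                ),
                cfg,
                control_track_ids=[0],
            )
            called = ts.tracks[1].call is Call.DEGRANULATING
            assert called or not prev_called
            prev_called = called
        assert prev_called

    def test_missing_control_ids_rejected(self):
        cfg = DegranulationConfig(reference_mode="control_tracks")
        with pytest.raises(ValueError):
            call_degranulation(trackset([make_track(0, [1.0, 2.0])]), cfg)

    def test_perfect_separation_on_well_separated_sets(self):
        # burst SD >= 4x sigma_ref vs null SD ~1x: 100% sensitivity and
        # specificity across seeds
        for seed in range(5):
            granules = [
                GranuleSpec(0, 60, (2.0 + 0.5 * i, 2.0), 0.3) for i in range(40)
            ]
            bursts = [BurstSpec(i, 20, 20.0) for i in range(0, 40, 4)]
            cfg_sim = SimulationConfig(
                n_frames=60,
                granule_spec=granules,
                burst_spec=bursts,
                noise_gaussian_sd=0.05,
                rng_seed=seed,
            )
            traces, labels = render_trace_set(cfg_sim)
            tracks = [
                make_track(tid, grp["intensity"].to_numpy())
                for tid, grp in traces.groupby("track_id")
            ]
            ts = call_degranulation(trackset(tracks))
            truth = dict(zip(labels["track_id"], labels["is_burst"]))
            for tr in ts.tracks:
                assert (tr.call is Call.DEGRANULATING) == truth[tr.id]

    def test_review_table_not_autoconfirmed(self):
        ts = call_degranulation(
            trackset([make_track(0, [1.0, 5.0] * 10), make_track(1, [1.0] * 20)])
        )
        table = review_table(ts)
        assert not table["confirmed"].any()
        assert set(table.columns) >= {"track_id", "sd_ratio", "call"}


class TestPopulation:
    def _scene(self, event_areas_um2, px=0.02):
        # 4 cells side by side, one reporter blob each; fine pixels so the
        # rasterized blob areas stay close to the nominal values
        cells = np.zeros((100, 400), dtype=int)
        reporter = np.zeros((100, 400))
        for i, area in enumerate(event_areas_um2):
            cells[:, i * 100 : (i + 1) * 100] = i + 1
            r_px = np.sqrt(area / np.pi) / px
            yy, xx = np.mgrid[0:100, 0:400]
            blob = (yy - 50) ** 2 + (xx - (i * 100 + 50)) ** 2 <= r_px**2
            reporter[blob] = 10.0
        return reporter, cells, px

    def test_small_events_excluded(self):
        reporter, cells, px = self._scene([0.02, 0.04, 0.06, 0.10])
        freq, table = population_frequency(
            reporter, cells, pixel_size_um=px, intensity_threshold=5.0
        )
        assert freq == pytest.approx(2 / 4)
        kept = set(table[table["positive"]]["cell_id"])
        assert kept == {3, 4}

    def test_no_events_zero_frequency(self):
        reporter, cells, px = self._scene([0, 0, 0, 0])
        freq, _ = population_frequency(
            reporter, cells, pixel_size_um=px, intensity_threshold=5.0
        )
        assert freq == 0.0

    def test_all_cells_positive(self):
        reporter, cells, px = self._scene([1.0, 1.0, 1.0, 1.0])
        freq, _ = population_frequency(
            reporter, cells, pixel_size_um=px, intensity_threshold=5.0
        )
        assert freq == 1.0

    def test_zero_cells_rejected(self):
        with pytest.raises(ValueError):
            population_frequency(
                np.zeros((10, 10)),
                np.zeros((10, 10), dtype=int),
                pixel_size_um=0.1,
                intensity_threshold=1.0,
            )

    def test_invariant_to_uniform_rescaling(self):
        reporter, cells, px = self._scene([0.02, 0.04, 0.06, 0.10])
        f1, _ = population_frequency(
            reporter, cells, pixel_size_um=px, intensity_threshold=5.0
        )
        f2, _ = population_frequency(
            reporter * 7.3, cells, pixel_size_um=px, intensity_threshold=5.0 * 7.3
        )
        assert f1 == f2


class TestRate:
    def test_rate_arithmetic(self):
        tracks = [make_track(i, [1.0, 5.0] * 10) for i in range(3)]
        tracks += [make_track(i + 3, [1.0] * 20) for i in range(5)]
        ts = call_degranulation(trackset(tracks))
        assert degranulation_rate(ts, 300.0) == pytest.approx(0.6)

    def test_zero_events(self):
        ts = call_degranulation(trackset([make_track(0, [1.0] * 20)]))
        assert degranulation_rate(ts, 60.0) == 0.0

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            degranulation_rate(trackset([]), 0.0)

    def test_planted_burst_schedule_recovered(self):
        bursts = [BurstSpec(i, 30 + 60 * i, 8.0) for i in range(4)]
        movie, _ = vesicle_movie(n_spots=10, bursts=bursts, n_frames=300)
        ts = detect_and_track_vesicles(movie)
        ts = call_degranulation(ts)
        rate = degranulation_rate(ts, movie.duration_s)
        assert abs(rate - 0.8) <= 0.2  # 4 events in 5 min, within 1 event
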