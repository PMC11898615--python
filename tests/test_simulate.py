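"""Synthetic-data generator: geometry, diffusion physics, profiles, imaging."""

import numpy as np
import pytest
from scipy import stats as sps
from shapely.geometry import Point

from septrack.profiling import count_septa
from septrack.simulate import (
    SimCellConfig,
    SimMixtureConfig,
    simulate_cell_population,
    simulate_image_stack,
    simulate_profiles,
    simulate_tracks,
)


class TestCellPopulation:
    def test_empty_population(self):
        assert simulate_cell_population(SimCellConfig(n_cells=0, seed=1)) == []

    def test_degenerate_septum_probability(self):
        cells = simulate_cell_population(
            SimCellConfig(n_cells=10, septum_prob=1.0, seed=1)
        )
        assert all(c.septum for c in cells)
        cells = simulate_cell_population(
            SimCellConfig(n_cells=10, septum_prob=0.0, seed=1)
        )
        assert not any(c.septum for c in cells)

    def test_length_distribution_clt(self):
        cfg = SimCellConfig(n_cells=2000, length_mean=2.5, length_sd=0.4, seed=7)
        cells = simulate_cell_population(cfg)
        mean_len = np.mean([c.length for c in cells])
        assert abs(mean_len - 2.5) < 3 * 0.4 / np.sqrt(2000)

    def test_geometry(self):
        cells = simulate_cell_population(
            SimCellConfig(n_cells=5, length_mean=3.0, length_sd=0.2, seed=2)
        )
        for c in cells:
            poly = c.polygon
            assert poly.is_valid
            # pole-to-pole distance equals the recorded length
            assert np.linalg.norm(c.poles[1] - c.poles[0]) == pytest.approx(c.length)
            # area between rectangle-only and full bounding box
            a = (c.length - c.width) * c.width + np.pi * (c.width / 2) ** 2
            assert poly.area == pytest.approx(a, rel=0.01)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"width": -1.0},
            {"length_mean": 0.5, "width": 1.0},
            {"septum_prob": 1.5},
            {"n_cells": -1},
        ],
    )
    def test_invalid_config(self, kwargs):
        with pytest.raises(ValueError):
            simulate_cell_population(SimCellConfig(seed=0, **kwargs))

    def test_column_layout_does_not_overlap(self):
        cells = simulate_cell_population(SimCellConfig(n_cells=6, seed=3))
        for i in range(len(cells)):
            for j in range(i + 1, len(cells)):
                assert cells[i].polygon.intersection(cells[j].polygon).area < 1e-12


class TestTracks:
    def test_no_motion_no_noise(self, one_cell):
        mix = SimMixtureConfig(k=1, D=(0.0,), f=(1.0,), loc_sd=0.0,
                               n_tracks=20, seed=4)
        tracks, _ = simulate_tracks([one_cell], mix)
        for _, grp in tracks.groupby("track_id"):
            assert grp["x_um"].nunique() == 1
            assert grp["y_um"].nunique() == 1

    def test_positions_stay_inside_cells(self):
        cells = simulate_cell_population(
            SimCellConfig(n_cells=4, length_mean=2.0, length_sd=0.2, seed=5)
        )
        mix = SimMixtureConfig(
            k=1, D=(0.394,), f=(1.0,), loc_sd=0.0, p_survive=0.9,
            n_tracks=150, seed=6,
        )
        tracks, truth = simulate_tracks(cells, mix)
        # buffer by the cap-chord sagitta: motion is confined to the exact
        # spherocylinder, the polygon is its discretization
        polys = {c.cell_id: c.polygon.buffer(1e-3) for c in cells}
        merged = truth.true_positions.merge(
            tracks[["track_id", "frame", "cell_id"]], on=["track_id", "frame"]
        )
        for _, row in merged.iterrows():
            assert polys[row.cell_id].covers(Point(row.x_um, row.y_um))

    def test_seed_reproducibility(self, one_cell):
        mix = lambda s: SimMixtureConfig(k=2, D=(0.01, 0.1), f=(0.5, 0.5),
                                         n_tracks=50, seed=s)
        a, _ = simulate_tracks([one_cell], mix(9))
        b, _ = simulate_tracks([one_cell], mix(9))
        c, _ = simulate_tracks([one_cell], mix(10))
        assert a.equals(b)
        assert not a.equals(c)

    def test_msd_closed_form_free_diffusion(self):
        # mean squared frame-to-frame displacement = 4 D dt for unbounded motion
        D, dt = 0.1, 0.013
        mix = SimMixtureConfig(k=1, D=(D,), f=(1.0,), dt=dt, loc_sd=0.0,
                               p_survive=0.5, n_tracks=5000, seed=11)
        tracks, _ = simulate_tracks(None, mix)
        r2 = []
        for _, grp in tracks.groupby("track_id"):
            g = grp.sort_values("frame")
            r2.extend(
                np.diff(g["x_um"]) ** 2 + np.diff(g["y_um"]) ** 2
            )
        r2 = np.asarray(r2)
        se = r2.std(ddof=1) / np.sqrt(len(r2))
        assert abs(r2.mean() - 4 * D * dt) < 3 * se

    def test_pure_localization_noise(self, one_cell):
        # D = 0 with loc_sd > 0: mean r² = 4 loc_sd²
        loc_sd = 0.03
        mix = SimMixtureConfig(k=1, D=(0.0,), f=(1.0,), loc_sd=loc_sd,
                               p_survive=0.6, n_tracks=4000, seed=12)
        tracks, _ = simulate_tracks([one_cell], mix)
        r2 = []
        for _, grp in tracks.groupby("track_id"):
            g = grp.sort_values("frame")
            r2.extend(np.diff(g["x_um"]) ** 2 + np.diff(g["y_um"]) ** 2)
        r2 = np.asarray(r2)
        se = r2.std(ddof=1) / np.sqrt(len(r2))
        assert abs(r2.mean() - 4 * loc_sd**2) < 3 * se

    def test_population_frequencies_match_fractions(self):
        # chi-square goodness of fit on planted labels across 20 seeds
        from septrack.experiments import _subseeds

        f = (0.2, 0.3, 0.5)
        cells = simulate_cell_population(SimCellConfig(n_cells=10, seed=1))
        passed = 0
        for seed in _subseeds(1, 20):
            mix = SimMixtureConfig(k=3, D=(0.01, 0.05, 0.4), f=f,
                                   p_survive=0.3, n_tracks=5000, seed=seed)
            _, truth = simulate_tracks(cells, mix)
            counts = np.bincount(truth.labels, minlength=3)
            _, p = sps.chisquare(counts, 5000 * np.asarray(f))
            passed += p > 0.01
        assert passed >= 19

    def test_track_lengths_at_least_two_frames(self, one_cell):
        mix = SimMixtureConfig(k=1, D=(0.05,), f=(1.0,), p_survive=0.2,
                               n_tracks=200, seed=13)
        tracks, _ = simulate_tracks([one_cell], mix)
        assert (tracks.groupby("track_id")["frame"].size() >= 2).all()

    def test_invalid_mixture_config(self, one_cell):
        with pytest.raises(ValueError):
            simulate_tracks([one_cell], SimMixtureConfig(k=4, D=(1, 1, 1, 1),
                                                         f=(0.25,) * 4, seed=0))
        with pytest.raises(ValueError):
            simulate_tracks([one_cell], SimMixtureConfig(k=2, D=(0.1, 0.2),
                                                         f=(0.6, 0.6), seed=0))
        with pytest.raises(ValueError):
            simulate_tracks([], SimMixtureConfig(k=1, D=(0.1,), f=(1.0,), seed=0))


class TestProfiles:
    def test_noiseless_pole_peaks(self):
        profile, truth = simulate_profiles(
            true_length=2.0, n_septa=0, n_nucleoids=0, noise_sd=0.0,
            pixel_pitch=0.1,
        )
        peaks = profile.position[
            np.flatnonzero(
                (profile.membrane > np.roll(profile.membrane, 1))
                & (profile.membrane > np.roll(profile.membrane, -1))
            )
        ]
        assert len(peaks) == 2
        assert peaks[1] - peaks[0] == pytest.approx(2.0)

    def test_empty_dna_channel_is_flat(self):
        profile, _ = simulate_profiles(2.0, n_septa=0, n_nucleoids=0, noise_sd=0.0)
        assert np.ptp(profile.dna) == 0

    def test_septa_counted_downstream(self):
        profile, truth = simulate_profiles(
            true_length=3.0, n_septa=2, n_nucleoids=0, noise_sd=10.0, seed=21
        )
        assert count_septa(profile) == 2

    def test_impossible_geometry(self):
        with pytest.raises(ValueError):
            simulate_profiles(1.0, n_septa=3, n_nucleoids=0)
        with pytest.raises(ValueError):
            simulate_profiles(1.5, n_septa=0, n_nucleoids=6)
        with pytest.raises(ValueError):
            simulate_profiles(-1.0)


class TestImageStack:
    def test_empty_scene_is_poisson_background(self):
        stack = simulate_image_stack(None, background=20.0, seed=31,
                                     shape=(24, 24), n_frames=50)
        assert stack.shape == (50, 24, 24)
        assert abs(stack.mean() - 20.0) < 0.5
        # index of dispersion near 1 for Poisson
        assert 0.9 < stack.var() / stack.mean() < 1.1

    def test_single_emitter_centroid(self):
        import pandas as pd

        px = 0.0968
        x_px, y_px = 10.30, 7.75
        locs = pd.DataFrame(
            {"frame": [0], "x_um": [(x_px + 0.5) * px], "y_um": [(y_px + 0.5) * px]}
        )
        img = simulate_image_stack(
            locs, background=0.0, peak_photons=1000.0, pixel_size=px,
            shape=(24, 24), apply_noise=False,
        )[0]
        rows, cols = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
        cx = (cols * img).sum() / img.sum()
        cy = (rows * img).sum() / img.sum()
        assert abs(cx - x_px) < 0.01
        assert abs(cy - y_px) < 0.01

    def test_frame_count_from_data(self):
        import pandas as pd

        locs = pd.DataFrame({"frame": [0, 3], "x_um": [2.0, 2.0], "y_um": [2.0, 2.0]})
        stack = simulate_image_stack(locs, seed=1)
        assert stack.shape[0] == 4
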