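"""Jump distances, SQD mixture fitting, MSD, and dwell-time decomposition."""

import numpy as np
import pytest

from septrack.diffusion import (
    JumpData,
    compute_jump_distances,
    compute_msd,
    extract_dwell_events,
    fit_dwell_times,
    fit_sqd_mixture,
    select_mixture_order,
)
from septrack.simulate import SimMixtureConfig, simulate_tracks

DT = 0.013


class TestJumpDistances:
    def test_stationary_track(self, make_track_df):
        tr = make_track_df(0, range(5), [1.0] * 5, [2.0] * 5)
        jumps = compute_jump_distances(tr, dt=DT)
        assert jumps.n_jumps == 4
        assert np.all(jumps.r2 == 0)

    def test_three_four_five_triangle(self, make_track_df):
        tr = make_track_df(0, [0, 1], [0.0, 0.3], [0.0, 0.4])
        jumps = compute_jump_distances(tr, dt=DT)
        assert jumps.r2 == pytest.approx([0.25])

    def test_lag_larger_than_track(self, make_track_df):
        tr = make_track_df(0, [0, 1], [0.0, 0.1], [0.0, 0.0])
        assert compute_jump_distances(tr, lag=5, dt=DT).n_jumps == 0

    def test_invalid_inputs(self, make_track_df):
        tr = make_track_df(0, [0, 1], [0.0, 0.1], [0.0, 0.0])
        with pytest.raises(ValueError):
            compute_jump_distances(tr, lag=0, dt=DT)
        with pytest.raises(ValueError):
            JumpData(r2=np.array([-1.0]), dt=DT)


class TestSQDMixture:
    def test_k1_matches_moment_estimator(self, rng):
        r2 = rng.exponential(4 * 0.1 * DT, size=10000)
        fit = fit_sqd_mixture(JumpData(r2, DT), k=1)
        moment = r2.mean() / (4 * DT)
        assert abs(fit.D[0] - moment) / moment < 0.02

    def test_fraction_constraints(self, rng):
        lab = rng.choice(2, size=6000, p=[0.4, 0.6])
        r2 = rng.exponential(4 * np.array([0.02, 0.3])[lab] * DT)
        fit = fit_sqd_mixture(JumpData(r2, DT), k=2)
        assert fit.f.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(fit.f >= 0)
        assert np.all(np.diff(fit.D) >= 0)

    def test_shuffle_invariance(self, rng):
        lab = rng.choice(2, size=4000, p=[0.5, 0.5])
        r2 = rng.exponential(4 * np.array([0.02, 0.3])[lab] * DT)
        fit_a = fit_sqd_mixture(JumpData(r2, DT), k=2)
        fit_b = fit_sqd_mixture(JumpData(rng.permutation(r2), DT), k=2)
        assert fit_a.D == pytest.approx(fit_b.D, rel=1e-6)
        assert fit_a.f == pytest.approx(fit_b.f, abs=1e-6)

    def test_too_few_jumps_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_sqd_mixture(JumpData(rng.exponential(size=40), DT), k=1)

    def test_standard_errors_finite(self, rng):
        lab = rng.choice(2, size=8000, p=[0.5, 0.5])
        r2 = rng.exponential(4 * np.array([0.02, 0.3])[lab] * DT)
        fit = fit_sqd_mixture(JumpData(r2, DT), k=2)
        assert np.all(np.isfinite(fit.D_se))
        assert np.all(np.isfinite(fit.f_se))


class TestOrderSelection:
    def test_pure_population_selects_one(self, rng):
        r2 = rng.exponential(4 * 0.1 * DT, size=10000)
        k, fits = select_mixture_order(JumpData(r2, DT))
        assert k == 1
        assert set(fits) == {1, 2, 3}

    def test_well_separated_three_mixture(self, rng):
        lab = rng.choice(3, size=30000, p=[0.33, 0.33, 0.34])
        D = np.array([0.017, 0.0509, 0.394])
        r2 = rng.exponential(4 * D[lab] * DT)
        k, _ = select_mixture_order(JumpData(r2, DT))
        assert k == 3

    def test_k_max_one(self, rng):
        r2 = rng.exponential(4 * 0.1 * DT, size=1000)
        k, _ = select_mixture_order(JumpData(r2, DT), k_max=1)
        assert k == 1


class TestMSD:
    def test_ballistic_track_exact(self, make_track_df):
        # x = v t with v = 1 µm/s: MSD(tau) = (v tau)^2
        v = 1.0
        frames = np.arange(10)
        tr = make_track_df(0, frames, v * frames * DT, np.zeros(10))
        msd = compute_msd(tr, max_lag=4, dt=DT)
        assert msd.msd == pytest.approx((v * msd.lags_s) ** 2)

    def test_recovery_from_simulation(self):
        mix = SimMixtureConfig(k=1, D=(0.05,), f=(1.0,), dt=DT, loc_sd=0.0,
                               p_survive=0.8, n_tracks=5000, seed=42)
        tracks, _ = simulate_tracks(None, mix)
        msd = compute_msd(tracks, max_lag=4, dt=DT)
        assert abs(msd.D - 0.05) / 0.05 < 0.10

    def test_short_track_truncates_curve(self, make_track_df):
        tr = make_track_df(0, [0, 1], [0.0, 0.1], [0.0, 0.0])
        msd = compute_msd(tr, max_lag=3, dt=DT)
        assert len(msd.lags_s) == 1


class TestDwell:
    def test_stationary_track_single_event(self, make_track_df):
        tr = make_track_df(0, range(10), [1.0] * 10, [1.0] * 10)
        events = extract_dwell_events(tr, r_dwell=0.1, dt=DT)
        assert events == pytest.approx([9 * DT])

    def test_fast_directed_track_no_events(self, make_track_df):
        xs = 0.2 * np.arange(10)  # every step exceeds the radius
        tr = make_track_df(0, range(10), xs, np.zeros(10))
        assert len(extract_dwell_events(tr, r_dwell=0.1, dt=DT)) == 0

    def test_confined_population_dwells_longer(self, one_cell):
        mix = SimMixtureConfig(k=2, D=(0.017, 0.394), f=(0.5, 0.5), dt=DT,
                               loc_sd=0.0, p_survive=0.9, n_tracks=400, seed=8)
        tracks, truth = simulate_tracks([one_cell], mix)
        means = {}
        for pop in (0, 1):
            ids = np.flatnonzero(truth.labels == pop)
            sub = tracks[tracks["track_id"].isin(ids)]
            ev = extract_dwell_events(sub, r_dwell=0.1, dt=DT)
            means[pop] = np.mean(ev) if len(ev) else 0.0
        assert means[0] > means[1]

    def test_order1_closed_form(self, rng):
        t_min = 0.052
        d = t_min + rng.exponential(0.25, size=500)
        fit = fit_dwell_times(d, order=1, t_min=t_min)
        assert fit.tau[0] == pytest.approx(np.mean(d) - t_min, abs=1e-12)
        assert fit.percentages == (100.0,)

    def test_order2_recovery(self):
        rng = np.random.default_rng(77)
        lab = rng.choice(2, size=5000, p=[0.5, 0.5])
        d = 0.052 + rng.exponential(np.array([0.14, 0.33])[lab])
        fit = fit_dwell_times(d, order=2, t_min=0.052)
        assert fit.order == 2
        assert fit.tau[0] < fit.tau[1]
        assert np.abs(np.asarray(fit.tau) - [0.14, 0.33]).max() / 0.14 < 0.2
        assert abs(fit.percentages[0] - 50) <= 10
        assert sum(fit.percentages) == pytest.approx(100, abs=0.5)

    def test_degenerate_durations_fall_back(self):
        d = np.full(60, 0.1)
        with pytest.warns(UserWarning):
            fit = fit_dwell_times(d, order=2, t_min=0.0)
        assert fit.order == 1

    def test_too_few_durations(self):
        with pytest.raises(ValueError):
            fit_dwell_times(np.ones(5), order=1)
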