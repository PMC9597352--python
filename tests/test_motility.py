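"""Track filtering, MSD, exponent fitting, classification, phases, runs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vesiquant import (
    ClassifierConfig,
    MotilityClass,
    MSDCurve,
    MotionModel,
    PhaseState,
    Trajectory,
    classify_track,
    compute_msd,
    compute_run_lengths,
    fit_power_law,
    filter_tracks,
    segment_phases,
    simulate_population,
    simulate_trajectory,
    summarize_population,
)
from vesiquant.exceptions import DegenerateFitError, InvalidArgumentError

from conftest import brute_force_msd


def _track_of_length(n: int) -> Trajectory:
    rng = np.random.default_rng(n)
    return Trajectory(
        track_id=n, dt=1.0, frames=np.arange(n), xy=rng.normal(size=(n, 2))
    )


class TestFilter:
    def test_minimum_frame_boundary_is_inclusive(self):
        tracks = [_track_of_length(24), _track_of_length(25), _track_of_length(26)]
        kept = filter_tracks(tracks, ClassifierConfig(min_frames=25))
        assert [t.n_frames for t in kept] == [25, 26]

    def test_empty_input_gives_empty_output(self):
        assert filter_tracks([]) == []


class TestTrajectoryValidation:
    def test_frame_gaps_are_rejected_not_interpolated(self):
        with pytest.raises(InvalidArgumentError, match="gap"):
            Trajectory(track_id=0, dt=1.0, frames=[0, 1, 3], xy=np.zeros((3, 2)))

    def test_too_short_and_nonpositive_dt_rejected(self):
        with pytest.raises(InvalidArgumentError):
            Trajectory(track_id=0, dt=1.0, frames=[0], xy=np.zeros((1, 2)))
        with pytest.raises(InvalidArgumentError):
            Trajectory(track_id=0, dt=0.0, frames=[0, 1], xy=np.zeros((2, 2)))


class TestMSD:
    def test_stationary_track_has_zero_msd(self, stationary_track):
        msd = compute_msd(stationary_track, 1.0)
        assert np.all(msd.values == 0)

    def test_ballistic_msd_is_lag_squared(self, ballistic_track):
        msd = compute_msd(ballistic_track, 1.0)
        assert np.allclose(msd.values, msd.lags**2, rtol=0, atol=0)

    def test_pair_counts(self, ballistic_track):
        msd = compute_msd(ballistic_track, 1.0)
        n = ballistic_track.n_frames
        assert list(msd.n_pairs) == [n - k for k in range(1, n)]

    def test_zero_lags_is_an_error(self):
        with pytest.raises(InvalidArgumentError):
            compute_msd(_track_of_length(5), 0.1)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        n=st.integers(min_value=3, max_value=50),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_matches_brute_force_all_pairs_exactly(self, n, seed):
        """compute_msd equals an independent double-loop oracle bitwise."""
        rng = np.random.default_rng(seed)
        track = Trajectory(
            track_id=0, dt=0.5, frames=np.arange(n), xy=rng.normal(size=(n, 2))
        )
        msd = compute_msd(track, 1.0)
        lags, values, n_pairs = brute_force_msd(track)
        assert np.array_equal(msd.lags, lags)
        assert np.array_equal(msd.values, values)
        assert np.array_equal(msd.n_pairs, n_pairs)


class TestPowerLawFit:
    @pytest.mark.parametrize("alpha", [0.5, 1.0, 1.5, 2.0])
    def test_exact_power_law_recovered_to_machine_precision(self, alpha):
        lags = np.arange(1, 11, dtype=float)
        msd = MSDCurve(lags=lags, values=lags**alpha, n_pairs=np.ones(10, int))
        fit = fit_power_law(msd)
        assert abs(fit.alpha - alpha) < 1e-9
        assert abs(fit.intercept) < 1e-9
        assert fit.r_squared == pytest.approx(1.0)

    def test_linear_msd_intercept_is_log_coefficient(self):
        lags = np.arange(1, 11, dtype=float)
        msd = MSDCurve(lags=lags, values=0.4 * lags, n_pairs=np.ones(10, int))
        fit = fit_power_law(msd)
        assert fit.alpha == pytest.approx(1.0, abs=1e-12)
        assert fit.intercept == pytest.approx(np.log(0.4), abs=1e-12)

    def test_zero_msd_lags_are_dropped(self):
        lags = np.array([1.0, 2.0, 3.0, 4.0])
        values = np.array([0.0, 4.0, 9.0, 16.0])  # zero at lag 1
        fit = fit_power_law(MSDCurve(lags=lags, values=values, n_pairs=np.ones(4, int)))
        assert fit.n_lags_used == 3

    def test_stationary_msd_is_degenerate(self, stationary_track):
        with pytest.raises(DegenerateFitError):
            fit_power_law(compute_msd(stationary_track, 1.0))

    def test_brownian_ensemble_mean_alpha_near_one(self):
        tracks, _ = simulate_population(
            [(MotionModel("brownian", diffusion_coeff=0.1, localization_noise_sd=0), 1.0)],
            500,
            100,
            1.0,
            seed=42,
        )
        alphas = [fit_power_law(compute_msd(t)).alpha for t in tracks]
        assert np.mean(alphas) == pytest.approx(1.0, abs=0.05)


class TestClassification:
    @pytest.mark.parametrize(
        "alpha,expected",
        [
            (1.5, MotilityClass.PROCESSIVE),
            (1.46, MotilityClass.PROCESSIVE),
            (1.45, MotilityClass.DIFFUSIVE),  # upper boundary inclusive
            (1.2, MotilityClass.DIFFUSIVE),
            (1.0, MotilityClass.DIFFUSIVE),  # lower boundary inclusive
            (0.999, MotilityClass.NON_PROCESSIVE),
            (0.5, MotilityClass.NON_PROCESSIVE),
            (-0.2, MotilityClass.NON_PROCESSIVE),
        ],
    )
    def test_threshold_partition(self, alpha, expected):
        from vesiquant import PowerLawFit

        fit = PowerLawFit(alpha=alpha, intercept=0.0, r_squared=1.0, n_lags_used=5)
        assert classify_track(fit) is expected

    def test_degenerate_fit_maps_to_non_processive(self):
        assert classify_track(None) is MotilityClass.NON_PROCESSIVE

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(alpha=st.floats(allow_nan=False, allow_infinity=False, width=64))
    def test_every_finite_alpha_gets_exactly_one_label(self, alpha):
        from vesiquant import PowerLawFit

        fit = PowerLawFit(alpha=alpha, intercept=0.0, r_squared=1.0, n_lags_used=5)
        assert classify_track(fit) in set(MotilityClass)


class TestPhases:
    def test_pure_ballistic_track_is_one_active_phase(self, ballistic_track):
        phases = segment_phases(ballistic_track)
        assert len(phases) == 1
        assert phases[0].state is PhaseState.ACTIVE
        assert (phases[0].start_frame, phases[0].end_frame) == (0, 49)

    def test_stationary_track_is_one_passive_phase(self, stationary_track):
        phases = segment_phases(stationary_track)
        assert len(phases) == 1
        assert phases[0].state is PhaseState.PASSIVE

    def test_phases_tile_track_and_alternate(self):
        traj, _ = simulate_trajectory(MotionModel("switching"), 300, 0.5, seed=9)
        phases = segment_phases(traj)
        assert phases[0].start_frame == traj.frames[0]
        assert phases[-1].end_frame == traj.frames[-1]
        for prev, cur in zip(phases, phases[1:]):
            assert cur.start_frame == prev.end_frame + 1
            assert cur.state is not prev.state

    def test_ballistic_then_brownian_boundary_located(self):
        """30 directed frames then 30 diffusive frames: the recovered
        state change falls within one window of the true switch."""
        rng = np.random.default_rng(4)
        n1, n2, dt = 30, 30, 1.0
        active = np.column_stack([0.5 * dt * np.arange(n1), np.zeros(n1)])
        steps = rng.normal(0, np.sqrt(2 * 0.01 * dt), size=(n2, 2))
        passive = active[-1] + np.cumsum(steps, axis=0)
        xy = np.vstack([active, passive])
        traj = Trajectory(track_id=0, dt=dt, frames=np.arange(n1 + n2), xy=xy)
        config = ClassifierConfig()
        phases = segment_phases(traj, config)
        assert phases[0].state is PhaseState.ACTIVE
        assert phases[-1].state is PhaseState.PASSIVE
        boundary = phases[0].end_frame
        assert abs(boundary - (n1 - 1)) <= config.phase_window

    def test_short_track_collapses_to_whole_track_class(self):
        n = 8
        xy = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
        traj = Trajectory(track_id=0, dt=1.0, frames=np.arange(n), xy=xy)
        phases = segment_phases(traj, ClassifierConfig(phase_window=10))
        assert len(phases) == 1
        assert phases[0].state is PhaseState.ACTIVE  # ballistic => processive


class TestRunLengths:
    def test_ballistic_run_is_speed_times_duration(self):
        n = 11  # 10 s at 0.5 um/s
        xy = np.column_stack([0.5 * np.arange(n, dtype=float), np.zeros(n)])
        traj = Trajectory(track_id=0, dt=1.0, frames=np.arange(n), xy=xy)
        from vesiquant import Phase

        runs = compute_run_lengths(traj, [Phase(PhaseState.ACTIVE, 0, 10)])
        assert runs == [pytest.approx(5.0, abs=1e-9)]

    def test_all_passive_track_has_no_runs(self, stationary_track):
        runs = compute_run_lengths(
            stationary_track, segment_phases(stationary_track)
        )
        assert runs == []

    def test_switching_tracks_recover_ground_truth_runs(self):
        """Net displacement of recovered active phases within 10% of the
        noise-free ground truth for the bulk of phases."""
        tracks, gt = simulate_population(
            [(MotionModel("switching"), 1.0)], 30, 200, 0.5, seed=11
        )
        total, ok = 0, 0
        for traj, tg in zip(tracks, gt.tracks):
            phases = segment_phases(traj)
            recovered = [
                (p, compute_run_lengths(traj, [p])[0])
                for p in phases
                if p.state is PhaseState.ACTIVE
            ]
            for (a, b), true_len in zip(tg.active_phases(), tg.run_lengths()):
                if true_len == 0:
                    continue
                total += 1
                best, best_ov = None, 0
                for p, rl in recovered:
                    ov = min(p.end_frame, b) - max(p.start_frame, a) + 1
                    if ov > best_ov:
                        best_ov, best = ov, rl
                if best is not None and abs(best - true_len) / true_len <= 0.10:
                    ok += 1
        assert total > 10
        assert ok / total >= 0.9


class TestPopulation:
    def test_all_ballistic_population_is_processive(self):
        tracks, _ = simulate_population(
            [(MotionModel("ballistic", speed=1.0, localization_noise_sd=0), 1.0)],
            200,
            60,
            1.0,
            seed=1,
        )
        summary = summarize_population(tracks)
        assert summary.fractions["processive"] >= 0.95

    def test_confined_population_is_non_processive(self):
        model = MotionModel(
            "confined",
            diffusion_coeff=0.1,
            confinement_radius=0.3,
            localization_noise_sd=0,
        )
        tracks, _ = simulate_population([(model, 1.0)], 200, 100, 1.0, seed=2)
        summary = summarize_population(tracks)
        assert summary.fractions["non_processive"] >= 0.95

    def test_fractions_partition_to_one(self):
        mix = [
            (MotionModel("ballistic", localization_noise_sd=0), 1.0),
            (MotionModel("brownian", diffusion_coeff=0.05, localization_noise_sd=0), 1.0),
            (MotionModel("confined", diffusion_coeff=0.05, localization_noise_sd=0), 1.0),
        ]
        tracks, _ = simulate_population(mix, 60, 50, 1.0, seed=3)
        summary = summarize_population(tracks)
        assert sum(summary.fractions.values()) == pytest.approx(1.0, abs=1e-12)

    def test_three_component_mixture_recovery(self):
        """Equal-weight ballistic/Brownian/confined mixture: the directed
        component is recovered as processive within multinomial error, and
        the two non-directed components never leak into it.

        A finite Brownian track's fitted exponent is centred on 1 — the
        exact lower boundary of the diffusive interval — so individual
        Brownian tracks split between diffusive and non-processive by
        sampling noise; their aggregate is checked instead of a per-class
        1/3 share.
        """
        mix = [
            (MotionModel("ballistic", speed=0.5, localization_noise_sd=0), 1.0),
            (MotionModel("brownian", diffusion_coeff=0.05, localization_noise_sd=0), 1.0),
            (
                MotionModel(
                    "confined",
                    diffusion_coeff=0.05,
                    confinement_radius=0.3,
                    localization_noise_sd=0,
                ),
                1.0,
            ),
        ]
        tracks, gt = simulate_population(mix, 300, 100, 1.0, seed=5)
        summary = summarize_population(tracks)
        assert abs(summary.fractions["processive"] - 1 / 3) < 0.07
        assert abs(
            summary.fractions["diffusive"] + summary.fractions["non_processive"] - 2 / 3
        ) < 0.07
        kinds = [gt.models[i].kind for i in gt.assignments]
        for summary_track, kind in zip(summary.tracks, kinds):
            if kind == "ballistic":
                assert summary_track.motility_class is MotilityClass.PROCESSIVE
            elif kind == "confined":
                assert summary_track.motility_class is MotilityClass.NON_PROCESSIVE

    def test_processive_fraction_monotone_in_speed(self):
        """More directed speed at fixed noise never lowers the processive
        fraction (speed ladder against localization noise)."""
        fractions = []
        for speed in [0.02, 0.05, 0.1, 0.3, 0.8]:
            model = MotionModel(
                "ballistic", speed=speed, localization_noise_sd=0.05
            )
            tracks, _ = simulate_population([(model, 1.0)], 100, 60, 1.0, seed=8)
            fractions.append(summarize_population(tracks).fractions["processive"])
        assert all(b >= a for a, b in zip(fractions, fractions[1:]))

    def test_histogram_uses_unit_bins_and_counts_all_runs(self):
        tracks, _ = simulate_population(
            [(MotionModel("switching"), 1.0)], 20, 150, 0.5, seed=13
        )
        summary = summarize_population(tracks)
        assert np.array_equal(np.diff(summary.hist_edges_um), np.ones(summary.hist_edges_um.size - 1))
        assert summary.hist_counts.sum() == summary.run_lengths_um.size

    def test_zero_retained_tracks_flags_undefined_fractions(self):
        summary = summarize_population([_track_of_length(10)], ClassifierConfig(min_frames=25))
        assert summary.n_tracks_input == 1
        assert summary.n_tracks_retained == 0
        assert summary.fractions is None
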