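"""Generator-level checks: kinematics, chain statistics, image geometry."""

import numpy as np
import pytest
from scipy import linalg, stats

from mtdyn import mtsim


class TestSimulateTrajectory:
    def test_deterministic_kinematics(self, single_state_preset):
        traj = mtsim.simulate_trajectory(single_state_preset, duration=60, dt=3, seed=1)
        assert traj.positions[-1] == pytest.approx(1.0)
        assert np.allclose(np.diff(traj.positions), 1.0 * 3 / 60)

    def test_identical_seed_bitwise_identical(self, presets):
        a = mtsim.simulate_trajectory(presets["full_ctm"], seed=7)
        b = mtsim.simulate_trajectory(presets["full_ctm"], seed=7)
        assert np.array_equal(a.positions, b.positions)
        assert a.true_states == b.true_states
        c = mtsim.simulate_trajectory(presets["full_ctm"], seed=8)
        assert not np.array_equal(a.positions, c.positions)

    def test_positions_floored_at_seed(self, presets):
        traj = mtsim.simulate_trajectory(presets["control_shrink"], seed=3)
        assert traj.positions.min() >= 0.0

    def test_full_ctm_ground_truth_rate(self, presets):
        """Mean per-step velocity in slow-growth samples matches 0.19 µm/min."""
        vels = []
        for seed in range(25):
            traj = mtsim.simulate_trajectory(presets["full_ctm"], seed=seed)
            v = np.diff(traj.positions) / traj.dt * 60.0
            labels = np.array(traj.true_states[:-1])
            vels.append(v[labels == mtsim.SLOW_GROWTH])
        vels = np.concatenate(vels)
        sem = vels.std(ddof=1) / np.sqrt(vels.size)
        assert vels.mean() == pytest.approx(0.19, abs=max(3 * sem, 0.01))

    def test_dwell_times_exponential(self, two_state_preset):
        """Dwells out of growth follow Exponential(6 min^-1) (KS test, n≈1e4)."""
        dwells = []
        seed = 0
        while len(dwells) < 10_000:
            traj = mtsim.simulate_trajectory(
                two_state_preset, duration=3600, dt=3, seed=seed
            )
            dwells.extend(
                ev.t_end - ev.t_start
                for ev in traj.events[:-1]  # last dwell is censored
                if ev.state == mtsim.SLOW_GROWTH
            )
            seed += 1
        dwells = np.asarray(dwells[:10_000])
        # hazard 6 / min = 0.1 / s -> scale 10 s
        ks = stats.kstest(dwells, "expon", args=(0, 10.0))
        assert ks.pvalue > 1e-3

    def test_stationary_occupancy_matches_matrix_oracle(self, two_state_preset):
        """Sampled state occupancy converges to the CTMC stationary law.

        The oracle solves pi Q = 0 directly from the generator matrix.
        """
        q = two_state_preset.rate_matrix()
        ns = q.shape[0]
        a = np.vstack([q.T, np.ones(ns)])
        b = np.concatenate([np.zeros(ns), [1.0]])
        pi = np.linalg.lstsq(a, b, rcond=None)[0]
        traj = mtsim.simulate_trajectory(two_state_preset, duration=600_000, dt=3, seed=4)
        labels = np.array(traj.true_states)
        emp = np.array(
            [(labels == s).mean() for s in two_state_preset.states]
        )
        assert 0.5 * np.abs(emp - pi).sum() < 0.05  # total variation

    def test_invalid_inputs(self, single_state_preset):
        with pytest.raises(ValueError):
            mtsim.simulate_trajectory(single_state_preset, duration=-1)
        with pytest.raises(ValueError):
            mtsim.simulate_trajectory(single_state_preset, dt=0)

    def test_unreachable_state_warns(self):
        preset = mtsim.ConditionPreset(
            name="u",
            states=(mtsim.SLOW_GROWTH, mtsim.SHRINKAGE),
            velocity_mean={mtsim.SLOW_GROWTH: 0.2, mtsim.SHRINKAGE: -1.0},
            velocity_sd={},
            transition_rates={},
            initial_state=mtsim.SLOW_GROWTH,
        )
        with pytest.warns(UserWarning, match="never reachable"):
            mtsim.simulate_trajectory(preset, duration=30, seed=0)


class TestBuiltinPresets:
    @pytest.mark.parametrize(
        "name,state,value",
        [
            ("togaram1", mtsim.FAST_GROWTH, 2.27),
            ("full_ctm", mtsim.SLOW_GROWTH, 0.19),
            ("minimal_trio", mtsim.SLOW_GROWTH, 0.022),
            ("cep104_togaram1", mtsim.SLOW_GROWTH, 0.12),
            ("control_shrink", mtsim.SHRINKAGE, -36.91),
            ("ccdc66_cep104_shrink", mtsim.SHRINKAGE, -0.12),
        ],
    )
    def test_reported_condition_velocities(self, presets, name, state, value):
        assert presets[name].velocity_mean[state] == pytest.approx(value)

    def test_catalogue_complete_with_provenance(self, presets):
        expected = {
            "eb3_alone", "cep104_block", "togaram1", "cep104_togaram1",
            "full_ctm", "minimal_trio", "ccdc66_cep104_shrink", "control_shrink",
        }
        assert expected <= set(presets)
        for p in presets.values():
            assert p.provenance, p.name

    def test_preset_invariants(self, presets):
        for p in presets.values():
            if mtsim.PAUSE in p.states:
                assert p.velocity_mean[mtsim.PAUSE] == 0.0
            if mtsim.SHRINKAGE in p.states:
                assert p.velocity_mean[mtsim.SHRINKAGE] < 0
            for (a, b), r in p.transition_rates.items():
                assert r >= 0 and a != b


class TestRenderKymograph:
    def test_stationary_tip_column(self):
        traj = mtsim.Trajectory(
            times=np.arange(20) * 3.0, positions=np.full(20, 2.25)
        )
        kymo = mtsim.render_kymograph(traj, snr=None, pad_px=0, psf_sigma=0.0)
        assert np.argmax(kymo.pixel_values[0]) == 50  # 2.25 / 0.045

    def test_default_pixel_size(self):
        traj = mtsim.Trajectory(times=np.arange(5) * 3.0, positions=np.zeros(5))
        assert mtsim.render_kymograph(traj).pixel_size == pytest.approx(0.045)

    def test_row_per_frame(self, presets):
        traj = mtsim.simulate_trajectory(presets["full_ctm"], seed=0)
        kymo = mtsim.render_kymograph(traj, seed=0)
        assert kymo.pixel_values.shape[0] == traj.times.size


class TestSpotField:
    def test_monomers_without_noise_are_exact(self):
        _, recs = mtsim.simulate_spot_field(
            50, {1: 1.0}, monomer_intensity_mean=300.0, monomer_intensity_sd=0.0, seed=0
        )
        assert all(r.integrated_intensity == pytest.approx(300.0) for r in recs)
        assert all(r.truth_n == 1 for r in recs)

    def test_dimer_monomer_intensity_ratio(self):
        rng_means = []
        for n, seed in ((1, 10), (2, 11)):
            _, recs = mtsim.simulate_spot_field(
                10_000, {n: 1.0}, image_size=2048, seed=seed
            )
            rng_means.append(np.mean([r.integrated_intensity for r in recs]))
        assert rng_means[1] / rng_means[0] == pytest.approx(2.0, rel=0.1)

    def test_three_dimer_blocked_end_intensity(self):
        """~6 monomer equivalents for a 2-3 dimer blocked end."""
        _, recs = mtsim.simulate_spot_field(
            500, {6: 1.0}, monomer_intensity_mean=300.0, image_size=1024, seed=12
        )
        mean = np.mean([r.integrated_intensity for r in recs])
        assert mean == pytest.approx(6 * 300.0, rel=0.05)

    def test_density_limit_error(self):
        with pytest.raises(ValueError, match="separation"):
            mtsim.simulate_spot_field(10_000, {1: 1.0}, image_size=128, seed=0)

    def test_spacing_respected(self):
        _, recs = mtsim.simulate_spot_field(200, {1: 1.0}, seed=5)
        xy = np.array([[r.x, r.y] for r in recs])
        d = np.linalg.norm(xy[:, None] - xy[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 4 * 1.5


class TestFRAPTraceGenerator:
    def test_immobile_trace_flat_after_bleach(self):
        tr = mtsim.simulate_frap_trace(mobile_fraction=0.0, noise_sd=0.0)
        post = tr.intensities[tr.bleach_index :]
        assert np.allclose(post, post[0])

    def test_half_life_definition(self):
        k = np.log(2) / 30.0
        tr = mtsim.simulate_frap_trace(
            recovery_rate=k, mobile_fraction=0.8, duration=60, dt=1.0, noise_sd=0.0
        )
        t30 = tr.bleach_index + 30
        pre, post = 100.0, 20.0
        norm = (tr.intensities[t30] - post) / (pre - post)
        assert norm == pytest.approx(0.8 / 2, rel=1e-6)


class TestProtofilamentEndGenerator:
    def test_blunt_and_zero_raggedness(self):
        params = mtsim.FlareParams(
            flare_length_mean_nm=0.0, flare_length_sd_nm=0.0, raggedness_sd_nm=0.0
        )
        end = mtsim.simulate_protofilament_end(n_pf=13, params=params, seed=0)
        assert np.all(end.truth_flare_length == 0.0)
        assert np.std(end.truth_wall_exit_z, ddof=1) == pytest.approx(0.0)

    def test_negative_length_draws_clip_with_warning(self):
        params = mtsim.FlareParams(flare_length_mean_nm=0.0, flare_length_sd_nm=5.0)
        with pytest.warns(UserWarning, match="clipped"):
            end = mtsim.simulate_protofilament_end(n_pf=13, params=params, seed=0)
        assert np.all(end.truth_flare_length >= 0.0)

    def test_arc_curvature_closed_form(self):
        """R = 20 nm arc -> local curvature (180/pi)/20 deg/nm."""
        params = mtsim.FlareParams(
            flare_length_mean_nm=30.0,
            flare_length_sd_nm=0.0,
            curvature_deg_per_nm=np.degrees(1 / 20),
            curvature_sd_deg_per_nm=0.0,
            raggedness_sd_nm=0.0,
        )
        end = mtsim.simulate_protofilament_end(n_pf=13, params=params, seed=1)
        from mtdyn import flare

        tr = end.traces[0]
        k = flare.find_wall_exit(tr, np.array([0, 0, 1.0]), 10.0)
        _, mean_curv = flare.local_curvature(tr, k)
        assert mean_curv == pytest.approx(np.degrees(1 / 20), rel=0.05)

    def test_azimuthal_spacing_within_four_degrees(self):
        end = mtsim.simulate_protofilament_end(n_pf=13, seed=3)
        gaps = np.diff(np.sort(end.azimuths_deg))
        assert np.all(np.abs(gaps - 360.0 / 13) <= 4.0)

    def test_determinism(self):
        a = mtsim.simulate_protofilament_end(seed=9)
        b = mtsim.simulate_protofilament_end(seed=9)
        for ta, tb in zip(a.traces, b.traces):
            assert np.array_equal(ta.points, tb.points)
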