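"""Generators: determinism, ground-truth bookkeeping, physical limits."""

import numpy as np
import pytest
from scipy import stats

from nanotraffic import synthdata
from nanotraffic._utils import ValidationError
from nanotraffic.saxs import sphere_form_factor
from nanotraffic.synthdata import (
    PlateSim,
    ScatteringSimConfig,
    SpotFieldSim,
    TrajectorySimConfig,
    simulate_plate,
    simulate_scattering,
    simulate_spot_field,
    simulate_trajectories,
)


def msd(pos, lag):
    d = pos[lag:] - pos[:-lag]
    return float(np.mean(np.einsum("ij,ij->i", d, d)))


class TestTrajectories:
    def test_seed_reproducibility_bit_identical(self):
        cfg = TrajectorySimConfig(n_traj=5, duration=0.5, seed=42)
        a = simulate_trajectories(cfg)
        b = simulate_trajectories(cfg)
        for ta, tb in zip(a.trajectories, b.trajectories):
            np.testing.assert_array_equal(ta.pos, tb.pos)
        for la, lb in zip(a.state_labels, b.state_labels):
            np.testing.assert_array_equal(la, lb)

    def test_labels_align_with_points(self):
        out = simulate_trajectories(TrajectorySimConfig(n_traj=3, duration=0.2, seed=1))
        for traj, labels in zip(out.trajectories, out.state_labels):
            assert len(labels) == len(traj)
            assert set(labels) <= {"stationary", "mobile"}

    def test_msd_recovers_diffusivity(self):
        # closed-form oracle: isotropic diffusion has MSD(lag) = 6 D t
        D = 0.05
        cfg = TrajectorySimConfig(n_traj=1, duration=100.0, dt=0.001,
                                  mobile_fraction=0.0, D_stationary=D,
                                  loc_noise_sd=0.0, seed=3)
        traj = simulate_trajectories(cfg).trajectories[0]
        for lag in (1, 5, 20):
            expected = 6.0 * D * lag * cfg.dt
            assert msd(traj.pos, lag) == pytest.approx(expected, rel=0.05)

    def test_single_population_when_states_degenerate(self):
        # v = 0 and equal diffusivities: the 'mobile' class is physically
        # identical to 'stationary'; MSDs agree regardless of the labels
        cfg = TrajectorySimConfig(n_traj=40, duration=2.0, mobile_fraction=0.5,
                                  D_stationary=0.02, D_mobile=0.02, v_mobile=0.0,
                                  loc_noise_sd=0.0, seed=5)
        out = simulate_trajectories(cfg)
        msds = {"stationary": [], "mobile": []}
        for traj, state in zip(out.trajectories, out.trajectory_states):
            msds[state].append(msd(traj.pos, 10))
        assert np.mean(msds["mobile"]) == pytest.approx(np.mean(msds["stationary"]),
                                                        rel=0.15)

    def test_pure_directed_track_is_straight(self):
        cfg = TrajectorySimConfig(n_traj=1, duration=1.0, mobile_fraction=1.0,
                                  D_mobile=0.0, v_mobile=1.0, v_cv=0.0,
                                  turn_rate=0.0, loc_noise_sd=0.0, seed=0)
        traj = simulate_trajectories(cfg).trajectories[0]
        steps = np.diff(traj.pos, axis=0)
        np.testing.assert_allclose(steps, np.broadcast_to(steps[0], steps.shape),
                                   atol=1e-12)
        assert np.linalg.norm(steps[0]) == pytest.approx(1.0 * cfg.dt)

    def test_mobile_fraction_within_binomial_ci(self):
        # oracle: exact binomial 99% central interval for n = 500, p = 0.4
        cfg = TrajectorySimConfig(n_traj=500, duration=0.05, mobile_fraction=0.4,
                                  seed=11)
        states = simulate_trajectories(cfg).trajectory_states
        k = states.count("mobile")
        lo, hi = stats.binom.ppf([0.005, 0.995], 500, 0.4)
        assert lo <= k <= hi

    def test_state_switching_produces_mixed_labels(self):
        cfg = TrajectorySimConfig(n_traj=5, duration=5.0, dt=0.01,
                                  mobile_fraction=0.5, switch_rate_to_mobile=2.0,
                                  switch_rate_to_stationary=2.0, seed=2)
        out = simulate_trajectories(cfg)
        assert any(len(set(labels)) == 2 for labels in out.state_labels)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            TrajectorySimConfig(dt=-0.001)
        with pytest.raises(ValidationError):
            TrajectorySimConfig(mobile_fraction=1.5)
        with pytest.raises(ValidationError):
            TrajectorySimConfig(D_stationary=-1.0)


class TestScattering:
    def test_noiseless_profile_matches_analytic_model(self):
        cfg = ScatteringSimConfig(peak_amplitude=0.0, background_scale=0.0)
        profile = simulate_scattering(cfg)
        expected = cfg.form_factor_scale * sphere_form_factor(profile.q, cfg.sphere_radius)
        np.testing.assert_allclose(profile.I, expected, rtol=1e-14)

    def test_guinier_limit_of_sphere(self):
        # I(q)/I(0) ~ exp(-q^2 Rg^2 / 3) with Rg = sqrt(3/5) R for q*Rg < 1
        R = 15.0
        rg = np.sqrt(3.0 / 5.0) * R
        cfg = ScatteringSimConfig(sphere_radius=R, peak_amplitude=0.0,
                                  background_scale=0.0, q_min=0.001, q_max=1.0 / rg,
                                  peak_q=0.05, n_q=200)
        profile = simulate_scattering(cfg)
        guinier = cfg.form_factor_scale * np.exp(-profile.q ** 2 * rg ** 2 / 3.0)
        np.testing.assert_allclose(profile.I, guinier, rtol=0.01)

    def test_peak_sits_at_configured_q(self):
        cfg = ScatteringSimConfig(peak_q=1.1, peak_amplitude=8.0)
        profile = simulate_scattering(cfg)
        base = simulate_scattering(ScatteringSimConfig(peak_q=1.1, peak_amplitude=0.0))
        excess = profile.I - base.I
        dq = profile.q[1] - profile.q[0]
        assert abs(profile.q[np.argmax(excess)] - 1.1) <= dq

    def test_determinism_and_noise_models(self):
        for noise in ("gaussian", "poisson"):
            cfg = ScatteringSimConfig(noise=noise, noise_scale=0.05, seed=9)
            a, b = simulate_scattering(cfg), simulate_scattering(cfg)
            np.testing.assert_array_equal(a.I, b.I)
            assert a.sigma is not None

    def test_peak_outside_grid_rejected(self):
        with pytest.raises(ValidationError):
            ScatteringSimConfig(peak_q=5.0, q_max=4.0)


class TestSpotField:
    def test_zero_cv_gives_exact_intensities(self):
        cfg = SpotFieldSim(n_cells=3, intensity_cv=0.0, n_cytosolic_mrna=10,
                           n_entrapped_clusters=0, poisson_counts=False, seed=0)
        objects, truth = simulate_spot_field(cfg)
        fish = objects[objects.channel == "fish"]
        assert (fish.groupby("cell_id").size() == 10).all()
        assert (fish.intensity == cfg.single_mrna_intensity).all()
        assert (truth.n_cytosolic_mrna == 10).all()

    def test_cluster_intensity_is_multiple_of_unit(self):
        cfg = SpotFieldSim(n_cells=5, intensity_cv=0.0, n_cytosolic_mrna=0,
                           n_entrapped_clusters=3, poisson_counts=False, seed=1)
        objects, _ = simulate_spot_field(cfg)
        fish = objects[objects.channel == "fish"]
        ks = fish.intensity / cfg.single_mrna_intensity
        assert np.allclose(ks, np.round(ks))
        assert (ks >= 2).all()

    def test_determinism(self):
        cfg = SpotFieldSim(seed=4)
        (a, ta), (b, tb) = simulate_spot_field(cfg), simulate_spot_field(cfg)
        assert a.equals(b) and ta.equals(tb)

    def test_standard_channel_present(self):
        objects, _ = simulate_spot_field(SpotFieldSim(n_standard=50, seed=0))
        assert (objects.channel == "electroporation_standard").sum() == 50


class TestPlate:
    def test_full_encapsulation_reads_blank(self):
        wells = simulate_plate(PlateSim(true_ee=100.0, noise_sd=0.0, blank=7.0))
        unlysed = wells[(~wells.lysed) & (~wells.blank)]
        assert (unlysed.fluorescence == 7.0).all()

    def test_zero_encapsulation_reads_like_lysed(self):
        wells = simulate_plate(PlateSim(true_ee=0.0, noise_sd=0.0))
        unlysed = wells[(~wells.lysed) & (~wells.blank)].fluorescence.to_numpy()
        lysed = wells[wells.lysed & (~wells.blank)].fluorescence.to_numpy()
        np.testing.assert_allclose(unlysed, lysed)

    def test_determinism(self):
        cfg = PlateSim(noise_sd=2.0, seed=6)
        assert simulate_plate(cfg).equals(simulate_plate(cfg))

    def test_invalid_ee_rejected(self):
        with pytest.raises(ValidationError):
            PlateSim(true_ee=101.0)
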