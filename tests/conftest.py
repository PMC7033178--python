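"""Shared builders for trajectories and mixture samples used across tests."""

import numpy as np
import pytest

from nanotraffic.trajmetrics import Trajectory3D


def straight_trajectory(duration=60.0, dt=0.001, speed=1.0, direction=(1.0, 0.0, 0.0),
                        traj_id="straight"):
    """Noiseless constant-velocity 3D track."""
    t = np.arange(0.0, duration + dt / 2, dt)
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    pos = speed * np.outer(t, d)
    return Trajectory3D(traj_id, t, pos)


def brownian_trajectory(rng, duration=120.0, dt=0.001, D=0.1, traj_id="brownian"):
    """Pure isotropic 3D random walk with diffusivity D (µm²/s)."""
    t = np.arange(0.0, duration + dt / 2, dt)
    steps = rng.normal(0.0, np.sqrt(2.0 * D * dt), size=(t.size - 1, 3))
    pos = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    return Trajectory3D(traj_id, t, pos)


def mixture_efficiencies(rng, n, mobile_fraction, mu_stationary=-4.0, mu_mobile=-0.3,
                         sd=0.3):
    """Per-trajectory mean efficiencies drawn from two lognormal modes.

    Returns (values, realized_mobile_mask) — a direct stand-in for the
    bimodal log-efficiency populations the tracking experiment yields.
    """
    mobile = rng.random(n) < mobile_fraction
    logs = np.where(mobile, rng.normal(mu_mobile, sd, n), rng.normal(mu_stationary, sd, n))
    return 10.0 ** logs, mobile


@pytest.fixture
def rng():
    return np.random.default_rng(0)
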