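"""Seeded generators emulating the study's four instrument data products.

Each generator draws every random number from one integer seed through a
named substream, records its configuration and ground truth alongside the
data, and regenerates bit-identically under the same seed:

- :func:`simulate_trajectories` — 3D single-particle tracks at millisecond
  sampling with two motion classes: *stationary* particles (endosome-scale
  Brownian jitter) and *mobile* particles (constant-speed, microtubule-like
  directed runs with Poisson re-orientation plus Brownian jitter), blurred by
  Gaussian localization noise.
- :func:`simulate_scattering` — 1D SAXS profiles: sphere form factor (the
  Guinier regime), a Gaussian lamellar Bragg peak, and a power-law background.
- :func:`simulate_spot_field` — detected-object tables from smFISH imaging:
  cytosolic single-mRNA spots, brighter entrapped clusters, LNP spots and
  electroporation-standard spots, with per-cell ground-truth counts.
- :func:`simulate_plate` — RiboGreen-style plate reads with a known
  encapsulated fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._utils import ValidationError, require, substream
from .saxs import ScatteringProfile, sphere_form_factor
from .trajmetrics import Trajectory3D

__all__ = [
    "TrajectorySimConfig",
    "LabeledTrajectorySet",
    "ScatteringSimConfig",
    "SpotFieldSim",
    "PlateSim",
    "simulate_trajectories",
    "simulate_scattering",
    "simulate_spot_field",
    "simulate_plate",
]


# --------------------------------------------------------------------------
# trajectories


@dataclass(frozen=True)
class TrajectorySimConfig:
    """Two-state 3D trajectory generator settings.

    Defaults are chosen so the two motion classes separate cleanly in
    log-efficiency, mirroring endosome/motor-transport scales: a stalled
    endosome diffuses at ~0.01 µm²/s while motor-driven cargo runs at
    ~1 µm/s, re-orienting every ~10 s, under ~20 nm localization noise.
    """

    n_traj: int = 200
    duration: float = 12.0           # s
    dt: float = 0.001                # s; millisecond sampling
    mobile_fraction: float = 0.5
    D_stationary: float = 0.01       # µm²/s
    D_mobile: float = 0.01           # µm²/s jitter on top of the directed run
    v_mobile: float = 1.0            # µm/s, median across trajectories
    v_cv: float = 0.3                # per-trajectory lognormal speed spread
    turn_rate: float = 0.1           # 1/s Poisson re-orientation
    switch_rate_to_mobile: float = 0.0    # 1/s; 0 -> state fixed per trajectory
    switch_rate_to_stationary: float = 0.0
    loc_noise_sd: float = 0.02       # µm per axis
    seed: int = 0

    def __post_init__(self) -> None:
        require(self.n_traj >= 1, "n_traj must be >= 1")
        require(self.dt > 0, "dt must be > 0")
        require(self.duration >= self.dt, "duration must cover >= 1 step")
        require(0.0 <= self.mobile_fraction <= 1.0, "mobile_fraction in [0, 1]")
        for name in ("D_stationary", "D_mobile", "v_mobile", "v_cv", "turn_rate",
                     "switch_rate_to_mobile", "switch_rate_to_stationary",
                     "loc_noise_sd"):
            value = getattr(self, name)
            require(np.isfinite(value) and value >= 0, f"{name} must be finite and >= 0")


@dataclass(frozen=True)
class LabeledTrajectorySet:
    """Simulated trajectories with their per-point ground-truth state."""

    trajectories: list
    state_labels: list              # per trajectory: array of 'stationary'|'mobile'
    config: TrajectorySimConfig
    seed: int

    def __post_init__(self) -> None:
        require(len(self.trajectories) == len(self.state_labels),
                "labels must align with trajectories")
        for traj, labels in zip(self.trajectories, self.state_labels):
            require(len(labels) == len(traj), "labels align 1:1 with points")

    @property
    def trajectory_states(self) -> list:
        """Majority state per trajectory (the whole-trajectory label)."""
        out = []
        for labels in self.state_labels:
            mobile = np.count_nonzero(np.asarray(labels) == "mobile")
            out.append("mobile" if mobile * 2 >= len(labels) else "stationary")
        return out


def _random_unit_vector(rng: np.random.Generator, n: int = 1) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _state_per_step(cfg: TrajectorySimConfig, rng: np.random.Generator,
                    n_steps: int) -> np.ndarray:
    """Boolean mobile-state per step, from the two-state Markov switching."""
    mobile0 = bool(rng.random() < cfg.mobile_fraction)
    if cfg.switch_rate_to_mobile == 0.0 and cfg.switch_rate_to_stationary == 0.0:
        return np.full(n_steps, mobile0)
    out = np.empty(n_steps, dtype=bool)
    t, i, mobile = 0.0, 0, mobile0
    total = n_steps * cfg.dt
    while i < n_steps:
        rate = cfg.switch_rate_to_stationary if mobile else cfg.switch_rate_to_mobile
        hold = rng.exponential(1.0 / rate) if rate > 0 else total + 1.0
        j = min(n_steps, int(np.ceil((t + hold) / cfg.dt)))
        out[i:j] = mobile
        t, i, mobile = t + hold, j, not mobile
    return out


def simulate_trajectories(config: TrajectorySimConfig) -> LabeledTrajectorySet:
    """Generate a labeled set of two-state 3D trajectories.

    Each step of length dt adds, in the stationary state, isotropic Brownian
    displacement with variance 2*D_stationary*dt per axis; in the mobile
    state, v*dt along a persistent unit direction (re-drawn at Poisson turn
    events of rate turn_rate, and on every entry into the mobile state) plus
    Brownian jitter with D_mobile.  The run speed v is drawn once per
    trajectory from a lognormal with median v_mobile and coefficient of
    variation v_cv — motor-driven cargo speeds vary between particles, and
    this heterogeneity is what gives the mobile mode its width in
    log-efficiency.  I.i.d. Gaussian localization noise of SD loc_noise_sd is
    added per axis to every recorded position.
    """
    cfg = config
    rng = substream(cfg.seed, "trajectories")
    n_steps = int(round(cfg.duration / cfg.dt))
    n_pts = n_steps + 1
    t = np.arange(n_pts) * cfg.dt

    trajectories: list[Trajectory3D] = []
    labels: list[np.ndarray] = []
    for k in range(cfg.n_traj):
        mobile = _state_per_step(cfg, rng, n_steps)
        disp = np.zeros((n_steps, 3))

        n_stat = int(np.count_nonzero(~mobile))
        if n_stat:
            disp[~mobile] = rng.normal(0.0, np.sqrt(2.0 * cfg.D_stationary * cfg.dt),
                                       size=(n_stat, 3))
        n_mob = int(np.count_nonzero(mobile))
        if n_mob:
            # persistent direction, re-drawn at Poisson turn events and on
            # every stationary -> mobile transition
            entries = np.flatnonzero(mobile & ~np.roll(mobile, 1))
            if mobile[0]:
                entries = np.union1d(entries, [0])
            turn = rng.random(n_steps) < cfg.turn_rate * cfg.dt
            new_dir = np.zeros(n_steps, dtype=bool)
            new_dir[entries] = True
            new_dir |= turn & mobile
            seg = np.cumsum(new_dir) - 1
            dirs = _random_unit_vector(rng, max(int(seg.max()) + 1, 1))
            jitter = rng.normal(0.0, np.sqrt(2.0 * cfg.D_mobile * cfg.dt),
                                size=(n_mob, 3))
            if cfg.v_cv > 0:
                v = cfg.v_mobile * np.exp(rng.normal(0.0, np.sqrt(np.log1p(cfg.v_cv ** 2))))
            else:
                v = cfg.v_mobile
            disp[mobile] = v * cfg.dt * dirs[seg[mobile]] + jitter

        pos = np.vstack([np.zeros(3), np.cumsum(disp, axis=0)])
        if cfg.loc_noise_sd > 0:
            pos = pos + rng.normal(0.0, cfg.loc_noise_sd, size=pos.shape)

        point_state = np.empty(n_pts, dtype=object)
        point_state[:-1] = np.where(mobile, "mobile", "stationary")
        point_state[-1] = point_state[-2]
        trajectories.append(Trajectory3D(traj_id=f"traj{k:04d}", t=t, pos=pos))
        labels.append(point_state.astype(str))

    return LabeledTrajectorySet(trajectories=trajectories, state_labels=labels,
                                config=cfg, seed=cfg.seed)


# --------------------------------------------------------------------------
# scattering


@dataclass(frozen=True)
class ScatteringSimConfig:
    """Synthetic SAXS profile: sphere form factor + Bragg peak + background.

    I(q) = form_factor_scale * P_sphere(q; R) + peak_amplitude *
    exp(-(q - peak_q)^2 / (2 peak_width^2)) + background_scale * q^-background_exponent,
    with noise applied last.  The default grid matches the instrument's
    0.06-4 nm^-1 range.
    """

    sphere_radius: float = 15.0          # nm core radius; Rg = sqrt(3/5) * R
    form_factor_scale: float = 1000.0    # AU
    peak_q: float = 0.9462               # nm^-1
    peak_width: float = 0.05             # nm^-1 (Gaussian sigma)
    peak_amplitude: float = 5.0          # AU
    background_exponent: float = 1.5
    background_scale: float = 0.1        # AU at q = 1 nm^-1
    q_min: float = 0.06                  # nm^-1
    q_max: float = 4.0                   # nm^-1
    n_q: int = 1000
    noise: str = "none"                  # 'none' | 'gaussian' | 'poisson'
    noise_scale: float = 0.02            # rel. sigma (gaussian) or counts/AU (poisson)
    seed: int = 0

    def __post_init__(self) -> None:
        require(self.sphere_radius > 0, "sphere_radius must be > 0")
        require(0 < self.q_min < self.q_max, "need 0 < q_min < q_max")
        require(self.n_q >= 2, "n_q must be >= 2")
        require(self.q_min <= self.peak_q <= self.q_max,
                "peak_q must lie inside the q grid")
        require(self.peak_width > 0, "peak_width must be > 0")
        require(self.peak_amplitude >= 0 and self.form_factor_scale >= 0
                and self.background_scale >= 0, "amplitudes must be >= 0")
        require(self.noise in ("none", "gaussian", "poisson"),
                f"unknown noise model {self.noise!r}")


def simulate_scattering(config: ScatteringSimConfig) -> ScatteringProfile:
    """Generate one synthetic scattering profile (deterministic when noiseless)."""
    cfg = config
    q = np.linspace(cfg.q_min, cfg.q_max, cfg.n_q)
    I = (cfg.form_factor_scale * sphere_form_factor(q, cfg.sphere_radius)
         + cfg.peak_amplitude * np.exp(-0.5 * ((q - cfg.peak_q) / cfg.peak_width) ** 2)
         + cfg.background_scale * q ** (-cfg.background_exponent))
    sigma = None
    if cfg.noise == "gaussian":
        rng = substream(cfg.seed, "scattering")
        sigma = cfg.noise_scale * np.abs(I)
        I = I + rng.normal(0.0, 1.0, size=I.shape) * sigma
    elif cfg.noise == "poisson":
        rng = substream(cfg.seed, "scattering")
        counts = np.maximum(I * cfg.noise_scale, 0.0)
        I = rng.poisson(counts).astype(float) / cfg.noise_scale
        sigma = np.sqrt(np.maximum(counts, 1.0)) / cfg.noise_scale
    return ScatteringProfile(q=q, I=I, sigma=sigma, label="synthetic")


# --------------------------------------------------------------------------
# spot fields


@dataclass(frozen=True)
class SpotFieldSim:
    """smFISH / LNP object-table generator with known per-cell counts.

    Counts are exact per cell when ``poisson_counts`` is False, otherwise
    Poisson-distributed with the given means.  Intensities: cytosolic single
    molecules and electroporation standards share one lognormal distribution
    with median ``single_mrna_intensity`` and coefficient of variation
    ``intensity_cv``; an entrapped cluster of k mRNAs (k uniform in
    ``cluster_size_range``, k >= 2) is k times a single-molecule draw; LNP
    spots are Gaussian around ``lnp_unit_intensity``.
    """

    n_cells: int = 50
    single_mrna_intensity: float = 100.0   # AU, median
    intensity_cv: float = 0.2
    n_cytosolic_mrna: float = 10
    n_entrapped_clusters: float = 4
    cluster_size_range: tuple = (2, 6)     # inclusive k range, k >= 2
    n_lnp: float = 40
    lnp_unit_intensity: float = 50.0       # AU, single particle on glass
    n_standard: int = 300
    poisson_counts: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        require(self.n_cells >= 1, "n_cells must be >= 1")
        require(self.single_mrna_intensity > 0, "single_mrna_intensity must be > 0")
        require(self.lnp_unit_intensity > 0, "lnp_unit_intensity must be > 0")
        require(self.intensity_cv >= 0, "intensity_cv must be >= 0")
        for name in ("n_cytosolic_mrna", "n_entrapped_clusters", "n_lnp"):
            require(getattr(self, name) >= 0, f"{name} must be >= 0")
        kmin, kmax = self.cluster_size_range
        require(2 <= kmin <= kmax, "cluster sizes must satisfy 2 <= kmin <= kmax")
        require(self.n_standard >= 20, "need >= 20 standard objects")


def _lognormal_unit(rng: np.random.Generator, median: float, cv: float, n: int) -> np.ndarray:
    if cv == 0:
        return np.full(n, median)
    sigma = np.sqrt(np.log1p(cv ** 2))
    return median * np.exp(rng.normal(0.0, sigma, size=n))


def simulate_spot_field(config: SpotFieldSim) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate an object table plus per-cell ground truth.

    Returns
    -------
    objects : DataFrame
        Columns cell_id, channel, object_id, intensity, area — one row per
        detected spot, plus one nuclei object per cell.
    truth : DataFrame
        Columns cell_id, n_cytosolic_mrna, n_entrapped_clusters, n_lnp.
    """
    cfg = config
    rng = substream(cfg.seed, "spot_field")
    rows: list[tuple] = []
    truth_rows: list[tuple] = []
    oid = 0

    def draw_count(mean: float) -> int:
        if cfg.poisson_counts:
            return int(rng.poisson(mean))
        return int(round(mean))

    for c in range(cfg.n_cells):
        cell = f"cell{c:04d}"
        n_cyt = draw_count(cfg.n_cytosolic_mrna)
        n_clu = draw_count(cfg.n_entrapped_clusters)
        n_lnp = draw_count(cfg.n_lnp)
        truth_rows.append((cell, n_cyt, n_clu, n_lnp))

        for inten in _lognormal_unit(rng, cfg.single_mrna_intensity, cfg.intensity_cv, n_cyt):
            rows.append((cell, "fish", f"obj{oid:06d}", float(inten), 4.0)); oid += 1
        if n_clu:
            ks = rng.integers(cfg.cluster_size_range[0], cfg.cluster_size_range[1] + 1,
                              size=n_clu)
            noise = _lognormal_unit(rng, 1.0, cfg.intensity_cv, n_clu)
            for k, nz in zip(ks, noise):
                rows.append((cell, "fish", f"obj{oid:06d}",
                             float(k * cfg.single_mrna_intensity * nz), 9.0)); oid += 1
        if n_lnp:
            lnp_int = np.maximum(
                rng.normal(cfg.lnp_unit_intensity,
                           cfg.intensity_cv * cfg.lnp_unit_intensity, size=n_lnp), 0.0)
            for inten in lnp_int:
                rows.append((cell, "lnp", f"obj{oid:06d}", float(inten), 4.0)); oid += 1
        rows.append((cell, "nuclei", f"obj{oid:06d}", 1.0, 100.0)); oid += 1

    for inten in _lognormal_unit(rng, cfg.single_mrna_intensity, cfg.intensity_cv,
                                 cfg.n_standard):
        rows.append(("standard_sample", "electroporation_standard",
                     f"obj{oid:06d}", float(inten), 4.0)); oid += 1

    objects = pd.DataFrame(rows, columns=["cell_id", "channel", "object_id",
                                          "intensity", "area"])
    truth = pd.DataFrame(truth_rows, columns=["cell_id", "n_cytosolic_mrna",
                                              "n_entrapped_clusters", "n_lnp"])
    return objects, truth


# --------------------------------------------------------------------------
# plate assays


@dataclass(frozen=True)
class PlateSim:
    """RiboGreen-style plate with a known encapsulated fraction.

    Unlysed wells see only the unencapsulated mRNA, blank + (1 - EE/100) *
    total + noise; detergent-lysed wells see everything, blank + total +
    noise; blank wells see blank + noise.
    """

    true_ee: float = 94.0           # percent
    total_mrna_signal: float = 200.0  # AU above blank
    blank: float = 10.0             # AU
    noise_sd: float = 0.0           # AU
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        require(0.0 <= self.true_ee <= 100.0, "true_ee must be in [0, 100]")
        require(self.total_mrna_signal >= 0, "total_mrna_signal must be >= 0")
        require(self.blank >= 0, "blank must be >= 0")
        require(self.noise_sd >= 0, "noise_sd must be >= 0")
        require(self.n_replicates >= 1, "n_replicates must be >= 1")


def simulate_plate(config: PlateSim) -> pd.DataFrame:
    """Generate a plate table (schema of :data:`nanotraffic.formqc.PLATE_COLUMNS`)."""
    cfg = config
    rng = substream(cfg.seed, "plate")
    unenc = (1.0 - cfg.true_ee / 100.0) * cfg.total_mrna_signal
    rows = []
    for rep in range(1, cfg.n_replicates + 1):
        noise = rng.normal(0.0, cfg.noise_sd, size=3) if cfg.noise_sd > 0 else np.zeros(3)
        rows.append((f"U{rep}", max(cfg.blank + unenc + noise[0], 0.0), False, False, rep))
        rows.append((f"L{rep}", max(cfg.blank + cfg.total_mrna_signal + noise[1], 0.0),
                     True, False, rep))
        rows.append((f"B{rep}", max(cfg.blank + noise[2], 0.0), False, True, rep))
    return pd.DataFrame(rows, columns=["well", "fluorescence", "lysed", "blank",
                                       "replicate"])
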