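"""Sliding-window linear transport efficiency and mobility decomposition.

Intracellular cargo carried along microtubules moves in nearly straight runs,
while cargo stalled in (or tethered to) an organelle jitters diffusively.  The
linear transport efficiency separates the two regimes from a 3D trajectory
alone: for a window of ``w`` sampling intervals starting at point ``j``,

    E_j = |r_{j+w} - r_j|^2 / [ (w - 1) * sum_{i=j+1}^{j+w} |r_i - r_{i-1}|^2 ]

where ``r`` is the 3D position vector.  A particle moving unidirectionally at
constant speed gives E_j = w/(w-1) ~ 1; an ideal random walk gives
E[E_j] ~ 1/(w-1) ~ 0.  By Cauchy-Schwarz, 0 <= E_j <= w/(w-1) always.  The
window slides one sample at a time and the per-window values are averaged to
one efficiency per trajectory.

Across a population of tracked particles the per-trajectory mean efficiencies
are bimodal on a log scale — a "stationary" low-efficiency mode and a "mobile"
high-efficiency mode — and the two population fractions are obtained as the
areas of a two-component Gaussian fit to the log10-efficiency histogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from ._utils import ValidationError, data_substream, require

__all__ = [
    "Trajectory3D",
    "LinearEfficiencyResult",
    "MobilityDecomposition",
    "GroupComparison",
    "TrajectoryTooShortError",
    "NonUniformSamplingError",
    "linear_efficiency",
    "analyze_trajectories",
    "decompose_mobility",
    "compare_groups",
    "plot_decomposition",
]

#: squared-step sum (µm^2) below which a window is treated as motionless
DEGENERATE_DENOMINATOR = 1e-12

#: efficiencies are floored here before taking log10
LOG_FLOOR = 1e-8


class TrajectoryTooShortError(ValueError):
    """Trajectory has fewer points than one sliding window; skip, don't zero."""


class NonUniformSamplingError(ValueError):
    """Time stamps deviate from uniform sampling beyond tolerance."""


@dataclass(frozen=True)
class Trajectory3D:
    """One tracked particle: time stamps in seconds, positions in µm.

    Parameters
    ----------
    traj_id
        Identifier carried through to results tables.
    t
        Strictly increasing time stamps, seconds; nominally uniform
        (millisecond sampling for the tracking instrument emulated here).
    pos
        ``(n, 3)`` array of x, y, z positions in µm.
    """

    traj_id: str
    t: np.ndarray
    pos: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        pos = np.asarray(self.pos, dtype=float)
        require(t.ndim == 1 and t.size >= 2, "trajectory needs >= 2 time points")
        require(pos.shape == (t.size, 3), "pos must be (n, 3) matching t")
        require(np.all(np.isfinite(t)) and np.all(np.isfinite(pos)),
                "trajectory contains non-finite values")
        require(bool(np.all(np.diff(t) > 0)), "time stamps must be strictly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "pos", pos)

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.t)))


@dataclass(frozen=True)
class LinearEfficiencyResult:
    """Per-window efficiencies and their trajectory-level mean."""

    traj_id: str
    window_w: int
    E_series: np.ndarray
    E_mean: float
    n_windows: int


@dataclass(frozen=True)
class GaussianComponent:
    mean: float
    sd: float
    amplitude: float

    @property
    def area(self) -> float:
        return float(self.amplitude * self.sd * np.sqrt(2.0 * np.pi))


@dataclass(frozen=True)
class MobilityDecomposition:
    """Two-Gaussian fit of the log10 mean-efficiency histogram.

    ``stationary`` is the lower-mean component, ``mobile`` the higher; the
    population fractions are the components' analytic area shares.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    stationary: GaussianComponent
    mobile: GaussianComponent
    stationary_fraction: float
    mobile_fraction: float
    residual: float
    converged: bool
    message: str = ""

    def classify(self, E_means: Iterable[float]) -> np.ndarray:
        """Label each efficiency 'stationary' or 'mobile' by the nearer mode."""
        logs = np.log10(np.maximum(np.asarray(list(E_means), dtype=float), LOG_FLOOR))
        d_stat = np.abs(logs - self.stationary.mean)
        d_mob = np.abs(logs - self.mobile.mean)
        return np.where(d_mob < d_stat, "mobile", "stationary")

    def pdf(self, x: np.ndarray) -> np.ndarray:
        """Fitted two-component curve evaluated on ``x`` (counts scale)."""
        x = np.asarray(x, dtype=float)
        return _two_gauss(x, self.stationary.amplitude, self.stationary.mean,
                          self.stationary.sd, self.mobile.amplitude,
                          self.mobile.mean, self.mobile.sd)


@dataclass(frozen=True)
class GroupComparison:
    """Two-group mobile-fraction comparison with bootstrap standard errors."""

    labels: tuple[str, str]
    decompositions: Mapping[str, MobilityDecomposition]
    n_per_group: Mapping[str, int]
    mobile_fractions: Mapping[str, float]
    bootstrap_se: Mapping[str, float]
    bootstrap_samples: Mapping[str, np.ndarray]
    statistic: float
    p_value: float
    method: str = "bootstrap-SE Welch t on mobile fractions"


def linear_efficiency(
    traj: Trajectory3D,
    window: float = 10.0,
    *,
    include_entry_step: bool = False,
    uniformity_tol: float = 0.01,
) -> LinearEfficiencyResult:
    """Sliding-window linear transport efficiency of one 3D trajectory.

    Parameters
    ----------
    traj
        Trajectory with uniform sampling (within ``uniformity_tol`` relative
        deviation of any interval from the median interval).
    window
        Window length in seconds; converted to ``w = round(window / dt)``
        samples.  The default 10 s at 1 ms sampling gives w = 10000.
    include_entry_step
        If True, the denominator additionally includes the step *into* the
        window, ``|r_j - r_{j-1}|^2`` (the literal reading of a lower summation
        limit of i = j).  The default sums only the w steps inside the window.
    uniformity_tol
        Maximum relative deviation of sampling intervals from their median.

    Returns
    -------
    LinearEfficiencyResult
        Per-start-index efficiencies ``E_series`` and their mean ``E_mean``.

    Raises
    ------
    TrajectoryTooShortError
        If the trajectory spans fewer than one full window.  Callers iterating
        over populations should catch this and *count* the skip (see
        :func:`analyze_trajectories`) rather than report a silent zero.
    NonUniformSamplingError
        If sampling intervals deviate beyond tolerance.
    """
    dts = np.diff(traj.t)
    dt = float(np.median(dts))
    if np.max(np.abs(dts - dt)) > uniformity_tol * dt:
        raise NonUniformSamplingError(
            f"trajectory {traj.traj_id!r}: sampling non-uniform beyond "
            f"{uniformity_tol:.0%} of median dt = {dt:.6g} s"
        )
    w = int(round(window / dt))
    require(w >= 2, f"window of {window} s spans w = {w} < 2 samples at dt = {dt:.6g} s")

    n = len(traj)
    if n < w + 1:
        raise TrajectoryTooShortError(
            f"trajectory {traj.traj_id!r} has {n} points; window needs {w + 1}"
        )

    steps = np.diff(traj.pos, axis=0)               # steps[k] = r_{k+1} - r_k
    step_sq = np.einsum("ij,ij->i", steps, steps)
    csum = np.concatenate(([0.0], np.cumsum(step_sq)))

    j0 = 1 if include_entry_step else 0             # j = 0 has no entry step
    j = np.arange(j0, n - w)
    net = traj.pos[j + w] - traj.pos[j]
    num = np.einsum("ij,ij->i", net, net)
    denom_sum = csum[j + w] - csum[j]               # sum over i = j+1 .. j+w
    if include_entry_step:
        denom_sum = denom_sum + step_sq[j - 1]

    E = np.zeros_like(num)
    ok = denom_sum >= DEGENERATE_DENOMINATOR        # motionless window -> E := 0
    E[ok] = num[ok] / ((w - 1) * denom_sum[ok])

    return LinearEfficiencyResult(
        traj_id=traj.traj_id,
        window_w=w,
        E_series=E,
        E_mean=float(E.mean()),
        n_windows=int(E.size),
    )


def analyze_trajectories(
    trajectories: Sequence[Trajectory3D],
    window: float = 10.0,
    **kwargs,
) -> tuple[list[LinearEfficiencyResult], list[str]]:
    """Run :func:`linear_efficiency` over a population.

    Returns the per-trajectory results and the ids of trajectories shorter
    than one window, which are excluded and reported, never silently dropped.
    """
    results: list[LinearEfficiencyResult] = []
    skipped: list[str] = []
    for traj in trajectories:
        try:
            results.append(linear_efficiency(traj, window, **kwargs))
        except TrajectoryTooShortError:
            skipped.append(traj.traj_id)
    return results, skipped


def _two_means_1d(values: np.ndarray, n_iter: int = 25) -> tuple[float, float]:
    """Deterministic 1D two-means clustering (Lloyd from the outer deciles)."""
    m1, m2 = np.percentile(values, [10.0, 90.0])
    if m1 == m2:
        return float(m1), float(m2)
    for _ in range(n_iter):
        assign = np.abs(values - m2) < np.abs(values - m1)
        if assign.all() or (~assign).all():
            break
        n1, n2 = float(values[~assign].mean()), float(values[assign].mean())
        if (n1, n2) == (m1, m2):
            break
        m1, m2 = n1, n2
    return float(m1), float(m2)


def _two_gauss(x, a1, m1, s1, a2, m2, s2):
    return (a1 * np.exp(-0.5 * ((x - m1) / s1) ** 2)
            + a2 * np.exp(-0.5 * ((x - m2) / s2) ** 2))


def decompose_mobility(
    E_means: Iterable[float],
    n_bins: int | None = None,
    *,
    floor: float = LOG_FLOOR,
) -> MobilityDecomposition:
    """Fit a two-component Gaussian to the log10 efficiency histogram.

    Population fractions are the analytic areas (amplitude * sd * sqrt(2*pi))
    of the two components, normalised to sum to 1; the lower-mean component is
    reported as the stationary fraction, the higher as mobile.

    Parameters
    ----------
    E_means
        Per-trajectory mean efficiencies (>= 20 values required).  Values are
        floored at ``floor`` before taking log10.
    n_bins
        Histogram bin count.  Default: Freedman-Diaconis rule, floored at 20
        bins so that narrow, well-separated modes are still resolved.

    Returns
    -------
    MobilityDecomposition
        With ``converged=False`` and diagnostics in ``message`` when the
        nonlinear fit degenerates, rather than raising.
    """
    values = np.asarray(list(E_means), dtype=float)
    require(values.size >= 20, f"need >= 20 efficiencies, got {values.size}")
    require(bool(np.all(np.isfinite(values))), "efficiencies must be finite")
    logs = np.log10(np.maximum(values, floor))
    if np.ptp(logs) == 0.0:
        raise ValidationError("all efficiencies identical; histogram is degenerate")

    if n_bins is None:
        fd_edges = np.histogram_bin_edges(logs, bins="fd")
        n_bins = max(len(fd_edges) - 1, 20)
    counts, edges = np.histogram(logs, bins=int(n_bins))
    centers = 0.5 * (edges[:-1] + edges[1:])
    bin_w = float(edges[1] - edges[0])

    # init: 1D two-means split of the log values (robust to unequal mode
    # populations, unlike a quantile split), amplitudes from cluster sizes,
    # sigma bounded below by half a bin so a mode cannot collapse
    m1, m2 = _two_means_1d(logs)
    assign = np.abs(logs - m2) < np.abs(logs - m1)
    p0 = []
    for center, members in ((m1, logs[~assign]), (m2, logs[assign])):
        sd_c = max(float(np.std(members)) if members.size > 1 else bin_w, bin_w / 2.0)
        amp_c = max(members.size * bin_w / (sd_c * np.sqrt(2.0 * np.pi)), 1.0)
        p0.extend([amp_c, center, sd_c])
    a0 = max(counts.max(), 1.0)
    # means constrained inside the observed range so an edge spike cannot be
    # modelled by a component centered beyond the data; sigma capped at half
    # the range so one component cannot blanket both modes
    lo_m, hi_m = float(logs.min()), float(logs.max())
    sd_hi = max(np.ptp(logs) / 2.0, 2.0 * bin_w)
    lower = [0.0, lo_m, bin_w / 2.0, 0.0, lo_m, bin_w / 2.0]
    upper = [3.0 * a0, hi_m, sd_hi, 3.0 * a0, hi_m, sd_hi]
    p0 = list(np.clip(p0, lower, upper))
    bounds = (lower, upper)

    try:
        popt, _ = optimize.curve_fit(
            _two_gauss, centers, counts.astype(float), p0=p0, bounds=bounds,
            maxfev=20000,
        )
        fit_ok = True
        message = ""
    except (RuntimeError, optimize.OptimizeWarning) as exc:  # pragma: no cover - rare
        popt = np.asarray(p0, dtype=float)
        fit_ok = False
        message = f"fit did not converge: {exc}"

    a1, m1, s1, a2, m2, s2 = popt
    comps = sorted(
        [GaussianComponent(float(m1), float(s1), float(a1)),
         GaussianComponent(float(m2), float(s2), float(a2))],
        key=lambda c: c.mean,
    )
    stationary, mobile = comps
    total_area = stationary.area + mobile.area
    if not np.isfinite(total_area) or total_area <= 0.0:
        fit_ok = False
        message = message or "zero total component area"
        f_stat, f_mob = 0.5, 0.5
    else:
        f_stat = stationary.area / total_area
        f_mob = mobile.area / total_area

    resid = counts.astype(float) - _two_gauss(centers, *popt)
    residual = float(np.sum(resid ** 2))

    return MobilityDecomposition(
        bin_edges=edges,
        counts=counts,
        stationary=stationary,
        mobile=mobile,
        stationary_fraction=float(f_stat),
        mobile_fraction=float(f_mob),
        residual=residual,
        converged=bool(fit_ok),
        message=message,
    )


def compare_groups(
    groups: Mapping[str, Sequence[float]],
    n_boot: int = 200,
    *,
    seed: int = 0,
    n_bins: int | None = None,
) -> GroupComparison:
    """Compare the mobile fractions of two trajectory populations.

    The mobile fraction of each group comes from :func:`decompose_mobility` on
    the full group; its uncertainty from a seeded bootstrap over trajectories
    (re-running the decomposition per replicate).  The test statistic is

        t = (f_1 - f_2) / sqrt(SE_1^2 + SE_2^2)

    with SE_g the standard deviation of group g's bootstrap replicates, and a
    two-sided p-value from a t distribution with Welch-Satterthwaite degrees
    of freedom based on the group sizes.  Comparing a group against an exact
    copy of itself gives t = 0 and p = 1.
    """
    require(len(groups) == 2,
            f"exactly two groups required for the t comparison, got {len(groups)}")
    labels = tuple(groups.keys())

    decomps: dict[str, MobilityDecomposition] = {}
    fractions: dict[str, float] = {}
    ses: dict[str, float] = {}
    boots: dict[str, np.ndarray] = {}
    ns: dict[str, int] = {}

    for label in labels:
        values = np.asarray(list(groups[label]), dtype=float)
        require(values.size >= 20, f"group {label!r} needs >= 20 trajectories")
        try:
            decomp = decompose_mobility(values, n_bins=n_bins)
        except ValidationError as exc:
            raise ValidationError(f"group {label!r} failed decomposition: {exc}") from exc
        if not decomp.converged:
            raise ValidationError(
                f"group {label!r} failed decomposition: {decomp.message}")
        rng = data_substream(seed, values)
        samples = []
        for _ in range(int(n_boot)):
            resampled = rng.choice(values, size=values.size, replace=True)
            try:
                d = decompose_mobility(resampled, n_bins=n_bins)
            except ValidationError:
                continue
            if d.converged:
                samples.append(d.mobile_fraction)
        samples = np.asarray(samples, dtype=float)
        require(samples.size >= max(10, n_boot // 4),
                f"group {label!r}: too few converged bootstrap replicates")
        decomps[label] = decomp
        fractions[label] = decomp.mobile_fraction
        ses[label] = float(samples.std(ddof=1))
        boots[label] = samples
        ns[label] = int(values.size)

    l1, l2 = labels
    diff = fractions[l1] - fractions[l2]
    se = float(np.hypot(ses[l1], ses[l2]))
    if se == 0.0:
        t_stat = 0.0 if diff == 0.0 else np.inf * np.sign(diff)
    else:
        t_stat = diff / se
    v1, v2 = ses[l1] ** 2, ses[l2] ** 2
    n1, n2 = ns[l1], ns[l2]
    if v1 + v2 > 0.0:
        df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    else:
        df = n1 + n2 - 2
    p = float(2.0 * stats.t.sf(abs(t_stat), df)) if np.isfinite(t_stat) else 0.0

    return GroupComparison(
        labels=(l1, l2),
        decompositions=decomps,
        n_per_group=ns,
        mobile_fractions=fractions,
        bootstrap_se=ses,
        bootstrap_samples=boots,
        statistic=float(t_stat),
        p_value=min(max(p, 0.0), 1.0),
    )


def plot_decomposition(decomp: MobilityDecomposition, ax=None, label: str = ""):
    """Histogram of log10 efficiencies with the fitted two-mode curve."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    centers = 0.5 * (decomp.bin_edges[:-1] + decomp.bin_edges[1:])
    width = decomp.bin_edges[1] - decomp.bin_edges[0]
    ax.bar(centers, decomp.counts, width=width, alpha=0.4, label=label or None)
    xs = np.linspace(decomp.bin_edges[0], decomp.bin_edges[-1], 400)
    ax.plot(xs, decomp.pdf(xs), lw=2)
    ax.set_xlabel("log10 linear efficiency")
    ax.set_ylabel("trajectories")
    return ax
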