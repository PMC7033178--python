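"""Small-angle X-ray scattering reduction for lipid nanoparticles.

Works on 1D circularly-averaged profiles I(q), with the wave vector
q = 4*pi/lambda * sin(theta/2) in nm^-1 (Cu K-alpha, lambda = 0.154 nm, by
default).  Three operations: buffer/background subtraction, Guinier estimation
of the radius of gyration from the low-q decay ln I ~ ln I0 - q^2 Rg^2 / 3,
and detection of the lamellar Bragg peak near q ~ 1 nm^-1 whose position gives
the bilayer/mRNA repeat distance d = 2*pi/q_peak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._utils import ValidationError, require

__all__ = [
    "ScatteringProfile",
    "GuinierFit",
    "LamellarPeak",
    "GuinierError",
    "subtract_background",
    "guinier_fit",
    "find_lamellar_peak",
    "sphere_form_factor",
]

log = logging.getLogger(__name__)

DEFAULT_WAVELENGTH_NM = 0.154


class GuinierError(ValueError):
    """No usable Guinier regime (rising low-q intensity or non-convergence)."""


@dataclass(frozen=True)
class ScatteringProfile:
    """1D scattering profile: q (nm^-1, ascending), I (AU), optional sigma."""

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None = None
    wavelength_nm: float = DEFAULT_WAVELENGTH_NM
    label: str = ""

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        I = np.asarray(self.I, dtype=float)
        require(q.ndim == 1 and q.size == I.size, "q and I must be equal-length 1D")
        require(bool(np.all(q > 0)), "q must be positive")
        require(bool(np.all(np.diff(q) > 0)), "q must be strictly increasing")
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "I", I)
        if self.sigma is not None:
            s = np.asarray(self.sigma, dtype=float)
            require(s.shape == q.shape, "sigma must match q")
            object.__setattr__(self, "sigma", s)

    def __len__(self) -> int:
        return int(self.q.size)


@dataclass(frozen=True)
class GuinierFit:
    Rg_nm: float
    I0: float
    q_range: tuple[float, float]
    qmax_Rg: float
    r2: float
    n_points: int


@dataclass(frozen=True)
class LamellarPeak:
    q_peak: float          # nm^-1
    d_spacing_nm: float    # 2*pi / q_peak
    width_nm_inv: float    # FWHM of the detrended peak
    prominence: float      # detrended peak height, AU


def sphere_form_factor(q: np.ndarray, radius_nm: float) -> np.ndarray:
    """Normalised sphere form factor P(q) = [3 (sin x - x cos x) / x^3]^2.

    x = q * R; P(0) = 1 and the Guinier limit is exp(-q^2 Rg^2 / 3) with
    Rg = sqrt(3/5) * R.
    """
    x = np.asarray(q, dtype=float) * float(radius_nm)
    out = np.ones_like(x)
    nz = x != 0
    out[nz] = (3.0 * (np.sin(x[nz]) - x[nz] * np.cos(x[nz])) / x[nz] ** 3) ** 2
    return out


def subtract_background(
    sample: ScatteringProfile,
    buffer: ScatteringProfile,
    transmission_ratio: float = 1.0,
) -> ScatteringProfile:
    """Transmission-scaled buffer subtraction, I_corr = I - T * I_buffer.

    The buffer is linearly interpolated onto the sample grid when the grids
    differ; sample points outside the buffer's q-range are dropped.  Per-point
    uncertainties, when both profiles carry them, propagate in quadrature.
    """
    require(transmission_ratio > 0, "transmission ratio must be positive")
    inside = (sample.q >= buffer.q[0]) & (sample.q <= buffer.q[-1])
    if not np.any(inside):
        raise ValidationError("sample and buffer q grids do not overlap")
    q = sample.q[inside]
    I_buf = np.interp(q, buffer.q, buffer.I)
    I_corr = sample.I[inside] - transmission_ratio * I_buf
    sigma = None
    if sample.sigma is not None:
        s_smp = sample.sigma[inside]
        if buffer.sigma is not None:
            s_buf = np.interp(q, buffer.q, buffer.sigma)
            sigma = np.hypot(s_smp, transmission_ratio * s_buf)
        else:
            sigma = s_smp.copy()
    return ScatteringProfile(q=q, I=I_corr, sigma=sigma,
                             wavelength_nm=sample.wavelength_nm,
                             label=sample.label)


def _weighted_linfit(x, y, w):
    coeffs, res = np.polyfit(x, y, 1, w=w, full=False), None
    slope, intercept = float(coeffs[0]), float(coeffs[1])
    yhat = slope * x + intercept
    ss_res = float(np.sum(w ** 2 * (y - yhat) ** 2))
    ybar = float(np.sum(w ** 2 * y) / np.sum(w ** 2))
    ss_tot = float(np.sum(w ** 2 * (y - ybar) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return slope, intercept, r2


def guinier_fit(
    profile: ScatteringProfile,
    qrg_limit: float = 1.3,
    *,
    max_rounds: int = 20,
    min_points: int = 5,
) -> GuinierFit:
    """Radius of gyration from the low-q Guinier regime.

    Fits ln I against q^2 (weighted by sigma/I when uncertainties are
    present).  The fit range is chosen self-consistently: an initial fit on
    the lowest 10% of q points gives a provisional Rg, the range is then
    trimmed to q <= qrg_limit / Rg and refit until the included point set is
    stable, up to ``max_rounds`` iterations.  qrg_limit = 1.3 is the usual
    convention for globular particles.

    Raises
    ------
    GuinierError
        If the low-q slope is non-negative (no Guinier decay), fewer than
        ``min_points`` usable points remain, or the range iteration does not
        settle within ``max_rounds``.
    """
    positive = profile.I > 0
    if np.count_nonzero(positive) < min_points:
        raise GuinierError("fewer than %d points with positive intensity" % min_points)
    q = profile.q[positive]
    I = profile.I[positive]
    sig = profile.sigma[positive] if profile.sigma is not None else None

    n0 = max(min_points, int(np.ceil(0.10 * q.size)))
    mask = np.zeros(q.size, dtype=bool)
    mask[:n0] = True

    seen: set[bytes] = set()
    slope = intercept = r2 = 0.0
    for _ in range(max_rounds):
        x = q[mask] ** 2
        y = np.log(I[mask])
        if sig is not None:
            w = I[mask] / sig[mask]     # sigma_lnI = sigma / I
        else:
            w = np.ones_like(x)
        slope, intercept, r2 = _weighted_linfit(x, y, w)
        if slope >= 0:
            raise GuinierError("low-q intensity does not decay; no Guinier regime")
        rg = float(np.sqrt(-3.0 * slope))
        new_mask = q <= qrg_limit / rg
        if np.count_nonzero(new_mask) < min_points:
            new_mask = np.zeros(q.size, dtype=bool)
            new_mask[:min_points] = True
        # with noise the range can cycle between two nearby windows; a
        # revisited window counts as converged (the smaller one wins, since
        # it is the one satisfying the q*Rg limit most conservatively)
        if new_mask.tobytes() in seen and np.count_nonzero(new_mask) >= np.count_nonzero(mask):
            new_mask = mask
        if np.array_equal(new_mask, mask):
            qs = q[mask]
            return GuinierFit(
                Rg_nm=rg,
                I0=float(np.exp(intercept)),
                q_range=(float(qs[0]), float(qs[-1])),
                qmax_Rg=float(qs[-1] * rg),
                r2=r2,
                n_points=int(np.count_nonzero(mask)),
            )
        seen.add(mask.tobytes())
        mask = new_mask
    raise GuinierError(f"Guinier range selection did not converge in {max_rounds} rounds")


def find_lamellar_peak(
    profile: ScatteringProfile,
    q_window: tuple[float, float] = (0.5, 1.5),
    *,
    min_prominence: float = 0.0,
    flank_fraction: float = 0.15,
) -> LamellarPeak | None:
    """Locate the lamellar Bragg peak and convert to d-spacing.

    A power-law background I_bg = c * q^m is fit to the low- and high-q flanks
    of the search window (outer ``flank_fraction`` of window points on each
    side) and subtracted.  The peak position is refined to sub-grid precision
    by the vertex of a parabola through the three points around the detrended
    maximum; ties between equal maxima resolve to the lowest q (logged).  The
    repeat spacing is d = 2*pi / q_peak.

    Returns ``None`` (a no-peak signal, not an error) when the detrended
    maximum does not exceed ``min_prominence``.
    """
    lo, hi = q_window
    require(lo < hi, "q_window must be (low, high) with low < high")
    require(lo >= profile.q[0] and hi <= profile.q[-1],
            "q_window must lie inside the profile's q grid")
    sel = (profile.q >= lo) & (profile.q <= hi)
    q = profile.q[sel]
    I = profile.I[sel]
    require(q.size >= 7, "too few points inside the search window")

    n_flank = max(2, int(np.ceil(flank_fraction * q.size)))
    flank = np.zeros(q.size, dtype=bool)
    flank[:n_flank] = True
    flank[-n_flank:] = True
    with np.errstate(invalid="ignore", divide="ignore"):
        ok = flank & (I > 0)
        if np.count_nonzero(ok) >= 4:
            m, lnc = np.polyfit(np.log(q[ok]), np.log(I[ok]), 1)
            bg = np.exp(lnc) * q ** m
        else:                       # flat fallback for non-positive flanks
            bg = np.full_like(q, float(np.median(I[flank])))
    detrended = I - bg

    i_max = int(np.argmax(detrended))   # argmax -> first (lowest-q) maximum
    if np.count_nonzero(detrended == detrended[i_max]) > 1:
        log.info("tie between equal detrended maxima; taking lowest q")
    prominence = float(detrended[i_max])
    if prominence <= min_prominence:
        return None
    if i_max == 0 or i_max == q.size - 1:
        return None                      # maximum on window edge: not a peak

    # 3-point parabola vertex for sub-grid q_peak
    y0, y1, y2 = detrended[i_max - 1: i_max + 2]
    x0, x1, x2 = q[i_max - 1: i_max + 2]
    denom = (y0 - 2.0 * y1 + y2)
    if denom == 0.0:
        q_peak = float(x1)
    else:
        q_peak = float(x1 + 0.5 * (y0 - y2) / denom * (x2 - x1))

    # interpolated FWHM of the detrended peak
    half = prominence / 2.0
    left = q[i_max]
    for k in range(i_max, 0, -1):
        if detrended[k - 1] < half:
            left = float(np.interp(half, [detrended[k - 1], detrended[k]], [q[k - 1], q[k]]))
            break
    right = q[i_max]
    for k in range(i_max, q.size - 1):
        if detrended[k + 1] < half:
            right = float(np.interp(half, [detrended[k + 1], detrended[k]], [q[k + 1], q[k]]))
            break
    width = max(right - left, 0.0)

    return LamellarPeak(
        q_peak=q_peak,
        d_spacing_nm=float(2.0 * np.pi / q_peak),
        width_nm_inv=width,
        prominence=prominence,
    )
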