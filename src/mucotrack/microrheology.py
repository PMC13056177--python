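"""Passive microrheology: MSD curves and the generalized Stokes–Einstein relation.

A tracer bead of radius ``a`` embedded in a viscoelastic medium performs
thermal motion whose time-averaged mean squared displacement encodes the
medium's complex shear modulus. Following the local power-law (Mason)
approximation, the modulus magnitude at frequency ``omega = 1/tau`` is

    |G*(omega)| = 2 k_B T / (3 pi a <dr^2(tau)> Gamma[1 + alpha(omega)])

for a two-dimensional MSD (the 3/2 projection factor is folded in, so the
Newtonian identity eta*(omega) = eta holds exactly for MSD = 4 D tau),
with ``alpha`` the local logarithmic slope d ln MSD / d ln tau, clipped
to [0, 1]. The storage and loss moduli follow as G' = |G*| cos(pi alpha/2)
and G'' = |G*| sin(pi alpha/2), and the complex viscosity — the scalar
readout used to summarise each mucus sample — is eta* = |G*| / omega.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gamma as gamma_fn

from .core import Trajectory
from .sim import RheoParams

__all__ = [
    "MSDCurve",
    "ViscoelasticSpectrum",
    "RheologySummary",
    "compute_msd",
    "ensemble_msd",
    "subtract_ensemble_drift",
    "gser_spectrum",
    "eta_star_at",
    "bead_tracks_to_eta_star",
    "OMEGA_REF",
]

logger = logging.getLogger(__name__)

#: Default reporting frequency for the scalar eta*: 1 Hz, i.e. 2 pi rad/s.
OMEGA_REF = 2.0 * math.pi


@dataclass
class MSDCurve:
    """Time-averaged mean squared displacement versus lag time.

    lags : seconds, strictly increasing.
    msd : um^2 at each lag.
    n_obs : number of displacement pairs averaged at each lag.
    """

    lags: np.ndarray
    msd: np.ndarray
    n_obs: np.ndarray

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_obs = np.asarray(self.n_obs, dtype=np.int64)
        if not (len(self.lags) == len(self.msd) == len(self.n_obs)):
            raise ValueError("lags, msd and n_obs must have equal length")
        if len(self.lags) and np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.msd < 0):
            raise ValueError("msd values must be >= 0")
        if len(self.lags) and np.any(self.n_obs < 1):
            raise ValueError("each reported lag needs n_obs >= 1")

    def restrict(self, min_lag: float, max_lag: float) -> "MSDCurve":
        """Return the sub-curve with lags in [min_lag, max_lag]."""
        keep = (self.lags >= min_lag - 1e-12) & (self.lags <= max_lag + 1e-12)
        return MSDCurve(self.lags[keep], self.msd[keep], self.n_obs[keep])


@dataclass
class ViscoelasticSpectrum:
    """Frequency-resolved viscoelastic moduli from the GSER.

    omega : rad/s; alpha : local log-slope in [0, 1]; g_abs = |G*|,
    g_storage = G', g_loss = G'' (Pa); eta_star = |G*|/omega (Pa s).
    """

    omega: np.ndarray
    alpha: np.ndarray
    g_abs: np.ndarray
    g_storage: np.ndarray
    g_loss: np.ndarray
    eta_star: np.ndarray

    def __post_init__(self) -> None:
        for name in ("omega", "alpha", "g_abs", "g_storage", "g_loss", "eta_star"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))


@dataclass
class RheologySummary:
    """Scalar microrheology result for one sample/replicate."""

    sample_id: str
    dilution: float
    replicate: int
    eta_star: float
    omega_ref: float
    n_tracks: int

    def __post_init__(self) -> None:
        if self.eta_star <= 0:
            raise ValueError("eta_star must be positive")


def compute_msd(
    track: Trajectory,
    pixel_size: float | None = None,
    max_lag_fraction: float = 1.0,
) -> MSDCurve:
    """Time-averaged 2-D MSD of one trajectory over all overlapping pairs.

    For each integer-frame lag up to ``max_lag_fraction`` times the track
    span, every pair of observations separated by that lag contributes;
    gaps from linking memory simply contribute no pairs at the affected
    lags. Pixel-unit tracks require ``pixel_size`` for conversion to um.
    """
    if len(track) < 2:
        raise ValueError("track must have at least 2 points")
    if not (0.0 < max_lag_fraction <= 1.0):
        raise ValueError("max_lag_fraction must lie in (0, 1]")
    if track.units == "px":
        if pixel_size is None:
            raise ValueError("pixel-unit track needs pixel_size for um conversion")
        track = track.to_um(pixel_size)

    frames = track.frames - track.frames[0]
    span = int(frames[-1])
    max_lag = max(int(math.floor(max_lag_fraction * span)), 1)

    # positions indexed by frame offset; NaN marks gaps
    pos = np.full((span + 1, 2), np.nan)
    pos[frames] = track.positions

    lags, msds, counts = [], [], []
    for lag in range(1, max_lag + 1):
        disp = pos[lag:] - pos[:-lag]
        sq = disp[:, 0] ** 2 + disp[:, 1] ** 2
        valid = np.isfinite(sq)
        n = int(valid.sum())
        if n == 0:
            continue
        lags.append(lag / track.frame_rate)
        msds.append(float(sq[valid].mean()))
        counts.append(n)
    return MSDCurve(np.array(lags), np.array(msds), np.array(counts))


def ensemble_msd(curves: Sequence[MSDCurve]) -> MSDCurve:
    """Combine per-track MSD curves on their common lag grid.

    The ensemble value at each shared lag is the mean of the per-track
    values weighted by their observation counts; the combined count is
    the sum. Lags are matched by rounding to nanoseconds (they are all
    integer multiples of frame intervals).
    """
    if len(curves) == 0:
        raise ValueError("need at least one MSD curve")
    keys = [np.round(c.lags * 1e9).astype(np.int64) for c in curves]
    common = keys[0]
    for k in keys[1:]:
        common = np.intersect1d(common, k)
    if len(common) == 0:
        raise ValueError("curves share no common lags")

    msd_sum = np.zeros(len(common))
    n_sum = np.zeros(len(common), dtype=np.int64)
    for c, k in zip(curves, keys):
        idx = np.searchsorted(k, common)
        msd_sum += c.msd[idx] * c.n_obs[idx]
        n_sum += c.n_obs[idx]
    return MSDCurve(common / 1e9, msd_sum / n_sum, n_sum)


def subtract_ensemble_drift(
    tracks: Sequence[Trajectory], min_tracks: int = 5
) -> list[Trajectory]:
    """Remove common-mode drift by subtracting per-frame mean displacement.

    The mean frame-to-frame displacement across all tracks observed at
    both frames is accumulated into a drift curve and subtracted from
    every position. When fewer than ``min_tracks`` tracks are available
    the input is returned unchanged (a sparse field cannot distinguish
    drift from diffusion).
    """
    if len(tracks) < min_tracks:
        return list(tracks)
    f_min = min(int(t.frames[0]) for t in tracks)
    f_max = max(int(t.frames[-1]) for t in tracks)
    n_frames = f_max - f_min + 1

    disp_sum = np.zeros((n_frames - 1, 2))
    disp_n = np.zeros(n_frames - 1)
    for t in tracks:
        fr = t.frames - f_min
        consec = np.diff(t.frames) == 1
        idx = fr[:-1][consec]
        d = np.diff(t.positions, axis=0)[consec]
        np.add.at(disp_sum, idx, d)
        np.add.at(disp_n, idx, 1)
    mean_disp = np.divide(
        disp_sum, disp_n[:, None], out=np.zeros_like(disp_sum), where=disp_n[:, None] > 0
    )
    drift = np.vstack([[0.0, 0.0], np.cumsum(mean_disp, axis=0)])

    out = []
    for t in tracks:
        corr = drift[t.frames - f_min]
        out.append(
            Trajectory(
                particle_id=t.particle_id,
                frames=t.frames.copy(),
                x=t.x - corr[:, 0],
                y=t.y - corr[:, 1],
                frame_rate=t.frame_rate,
                units=t.units,
            )
        )
    return out


def _local_log_slope(ln_tau: np.ndarray, ln_msd: np.ndarray, window: int = 5) -> np.ndarray:
    """Local slope d ln MSD / d ln tau by windowed quadratic fits.

    Each point's slope is the analytic derivative at that point of a
    quadratic fitted to the ``window`` nearest points in log-log space
    (edge-truncated; linear fit when fewer than 3 points are available).
    """
    n = len(ln_tau)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        xs, ys = ln_tau[lo:hi], ln_msd[lo:hi]
        if len(xs) >= 3:
            c = np.polyfit(xs, ys, 2)
            out[i] = 2.0 * c[0] * ln_tau[i] + c[1]
        else:
            c = np.polyfit(xs, ys, 1)
            out[i] = c[0]
    return out


def gser_spectrum(
    msd: MSDCurve,
    params: RheoParams,
    dimensionality_factor: float = 1.5,
) -> ViscoelasticSpectrum:
    """Convert an MSD curve into viscoelastic moduli via the GSER.

    Each lag tau maps to omega = 1/tau. ``dimensionality_factor``
    rescales the 2-D MSD to its 3-D equivalent (3/2 for isotropic
    motion observed in projection); with the default, a Newtonian MSD
    of 4 D tau returns eta*(omega) = eta at every frequency. Raw local
    slopes outside [0, 1] are clipped with a warning. Non-positive MSD
    values are excluded; an all-excluded curve is an error.
    """
    if dimensionality_factor <= 0:
        raise ValueError("dimensionality_factor must be positive")
    keep = msd.msd > 0
    if not np.all(keep):
        logger.warning("excluding %d non-positive MSD lags", int((~keep).sum()))
    if not np.any(keep):
        raise ValueError("no positive MSD values; cannot compute a spectrum")
    tau = msd.lags[keep]
    m2 = msd.msd[keep]
    if len(tau) < 2:
        raise ValueError("need at least 2 usable lags for a spectrum")

    alpha_raw = _local_log_slope(np.log(tau), np.log(m2))
    # overshoot near the ends is routine estimation noise on poorly
    # averaged lags; warn only for clearly super-diffusive or
    # anti-correlated segments
    if np.any(alpha_raw > 1.3) or np.any(alpha_raw < -0.3):
        logger.warning(
            "local MSD slope outside [0, 1] (min %.3f, max %.3f); clipping",
            alpha_raw.min(), alpha_raw.max(),
        )
    elif np.any(alpha_raw > 1.0) or np.any(alpha_raw < 0.0):
        logger.debug(
            "clipping local MSD slopes to [0, 1] (min %.3f, max %.3f)",
            alpha_raw.min(), alpha_raw.max(),
        )
    alpha = np.clip(alpha_raw, 0.0, 1.0)

    omega = 1.0 / tau
    kT = params.boltzmann_constant * params.temperature
    msd_3d_m2 = dimensionality_factor * m2 * 1e-12  # um^2 -> m^2
    g_abs = kT / (math.pi * params.bead_radius * msd_3d_m2 * gamma_fn(1.0 + alpha))
    g_storage = g_abs * np.cos(0.5 * math.pi * alpha)
    g_loss = g_abs * np.sin(0.5 * math.pi * alpha)
    eta_star = g_abs / omega

    order = np.argsort(omega)
    return ViscoelasticSpectrum(
        omega=omega[order],
        alpha=alpha[order],
        g_abs=g_abs[order],
        g_storage=g_storage[order],
        g_loss=g_loss[order],
        eta_star=eta_star[order],
    )


def eta_star_at(spec: ViscoelasticSpectrum, omega_ref: float = OMEGA_REF) -> float:
    """Complex viscosity at a reference frequency, by log-log interpolation."""
    omega = spec.omega
    if not (omega.min() - 1e-12 <= omega_ref <= omega.max() + 1e-12):
        raise ValueError(
            f"omega_ref={omega_ref:.4g} rad/s outside the spectrum range "
            f"[{omega.min():.4g}, {omega.max():.4g}]"
        )
    return float(
        10.0 ** np.interp(np.log10(omega_ref), np.log10(omega), np.log10(spec.eta_star))
    )


def bead_tracks_to_eta_star(
    tracks: Sequence[Trajectory],
    params: RheoParams,
    pixel_size: float | None = None,
    omega_ref: float = OMEGA_REF,
    min_lag_frames: int = 3,
    max_lag_fraction: float = 0.3,
    drift_correction: bool = True,
    min_track_fraction: float = 0.5,
) -> tuple[float, int]:
    """Full per-replicate chain: tracks -> ensemble MSD -> GSER -> eta*.

    Lags are restricted to [min_lag_frames / frame_rate,
    max_lag_fraction * longest span] to avoid single-frame noise at
    short lags and poorly averaged long lags. Tracks spanning less than
    ``min_track_fraction`` of the longest span are dropped so the
    common-lag intersection stays informative. Returns (eta*, n_tracks
    used).
    """
    if len(tracks) == 0:
        raise ValueError("no tracks supplied")
    frame_rate = tracks[0].frame_rate
    longest = max(int(t.frames[-1] - t.frames[0]) for t in tracks)
    usable = [
        t for t in tracks if (t.frames[-1] - t.frames[0]) >= min_track_fraction * longest
    ]
    if drift_correction:
        usable = subtract_ensemble_drift(usable)
    curves = [
        compute_msd(t, pixel_size=pixel_size, max_lag_fraction=max_lag_fraction)
        for t in usable
    ]
    ens = ensemble_msd(curves)
    ens = ens.restrict(min_lag_frames / frame_rate, np.inf)
    spec = gser_spectrum(ens, params)
    return eta_star_at(spec, omega_ref), len(usable)
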