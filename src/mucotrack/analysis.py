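"""Dilution-series statistics.

Relates the two arms of the paired assay: complex viscosity eta* from
microrheology and sperm straight-line velocity from kinematics, each
measured at every animal x dilution point. Provides Anderson–Darling
based selection of the analysis scale (raw vs log10), replicate
aggregation by median of log10 values, the pooled Pearson correlation
between log10 velocity and log10 eta*, and the power-law fit of
velocity against relative concentration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "DilutionPoint",
    "AggregatedPoint",
    "CorrelationResult",
    "PowerLawFit",
    "AnalysisConfig",
    "FamilyChoice",
    "choose_transform_family",
    "aggregate_dilution_point",
    "correlate_log_values",
    "fit_power_law",
]

logger = logging.getLogger(__name__)

# significance levels offered by the Anderson-Darling normality tables
_AD_LEVELS = (0.15, 0.10, 0.05, 0.025, 0.01)


@dataclass(frozen=True)
class AnalysisConfig:
    """Statistical conventions for the dilution-series analysis."""

    alpha: float = 0.05
    stat: str = "median"
    transform: str = "log10"  # raw | log10 | auto

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.stat not in ("median", "mean"):
            raise ValueError("stat must be 'median' or 'mean'")
        if self.transform not in ("raw", "log10", "auto"):
            raise ValueError("transform must be raw|log10|auto")


@dataclass
class DilutionPoint:
    """One animal x dilution condition with replicate measurements."""

    animal: int
    dilution: float
    eta_star_replicates: list[float] = field(default_factory=list)
    velocity_replicates: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.dilution < 1:
            raise ValueError("dilution factor must be >= 1")

    @property
    def concentration(self) -> float:
        """Relative concentration c = 1/dilution, in (0, 1]."""
        return 1.0 / self.dilution


@dataclass
class AggregatedPoint:
    """Per-point log10 summaries used in the correlation."""

    animal: int
    dilution: float
    log_eta_star: float
    log_velocity: float
    n_eta_replicates: int
    n_velocity_replicates: int


@dataclass
class CorrelationResult:
    """Pearson correlation plus the log-log linear model."""

    r: float
    p: float
    slope: float
    intercept: float
    n: int


@dataclass
class PowerLawFit:
    """Least-squares power-law exponent from a log-log regression."""

    exponent: float  # |slope|
    sign: int
    stderr: float
    intercept: float
    r_squared: float
    n: int


@dataclass
class FamilyChoice:
    """Outcome of Anderson-Darling scale selection."""

    family: str  # 'raw' or 'log10'
    raw_nonrejections: int
    log_nonrejections: int
    n_tested: int
    n_skipped: int
    details: list[dict] = field(default_factory=list)


def _ad_rejects(values: np.ndarray, alpha: float) -> bool:
    """True when the AD normality test rejects at the given level."""
    try:
        res = stats.anderson(values, dist="norm", method="interpolate")
        return bool(res.pvalue < alpha)
    except TypeError:
        # older scipy: compare against the tabulated critical values
        res = stats.anderson(values, dist="norm")
        idx = int(np.argmin(np.abs(np.asarray(_AD_LEVELS) - alpha)))
        if not np.isclose(_AD_LEVELS[idx], alpha):
            raise ValueError(f"alpha must be one of {_AD_LEVELS} for the AD tables")
        return bool(res.statistic > res.critical_values[idx])


def choose_transform_family(
    ensembles: Sequence[Sequence[float]], alpha: float = 0.05
) -> FamilyChoice:
    """Pick the analysis scale (raw vs log10) by Anderson–Darling tests.

    Each ensemble (e.g. the per-track velocities of one sample) is
    tested for normality on the raw and the log10 scale; the scale with
    more non-rejections at ``alpha`` wins, with ties going to log10.
    Constant ensembles are skipped with a flag; ensembles containing
    non-positive values contribute no log-scale non-rejection. Every
    tested ensemble needs at least 8 finite values.
    """
    if len(ensembles) == 0:
        raise ValueError("need at least one ensemble")
    raw_ok = log_ok = tested = skipped = 0
    details: list[dict] = []
    for i, ens in enumerate(ensembles):
        vals = np.asarray(ens, dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) < 8:
            raise ValueError(f"ensemble {i} has fewer than 8 finite values")
        if np.ptp(vals) == 0:
            skipped += 1
            details.append({"index": i, "skipped": True})
            continue
        tested += 1
        raw_rej = _ad_rejects(vals, alpha)
        if not raw_rej:
            raw_ok += 1
        pos = vals[vals > 0]
        log_rej: bool | None = None
        if len(pos) >= 8 and np.ptp(pos) > 0:
            log_rej = _ad_rejects(np.log10(pos), alpha)
            if not log_rej:
                log_ok += 1
        details.append(
            {"index": i, "skipped": False, "raw_rejected": raw_rej, "log_rejected": log_rej}
        )
    if tested == 0:
        raise ValueError("all ensembles were constant; no scale can be selected")
    family = "log10" if log_ok >= raw_ok else "raw"
    logger.info(
        "scale selection: raw %d vs log10 %d non-rejections over %d ensembles -> %s",
        raw_ok, log_ok, tested, family,
    )
    return FamilyChoice(
        family=family,
        raw_nonrejections=raw_ok,
        log_nonrejections=log_ok,
        n_tested=tested,
        n_skipped=skipped,
        details=details,
    )


def aggregate_dilution_point(
    point: DilutionPoint, config: AnalysisConfig = AnalysisConfig()
) -> AggregatedPoint | None:
    """Summarise one dilution point as (log10 eta*, log10 velocity).

    Replicate values are log10-transformed then reduced with the
    configured statistic (median by default). Non-positive replicates
    cannot be log-transformed and are excluded with a log message. A
    point missing either modality entirely returns None (flagged and
    excluded from the correlation).
    """
    def _reduce(values: Sequence[float], label: str) -> tuple[float, int] | None:
        vals = np.asarray(values, dtype=float)
        ok = np.isfinite(vals) & (vals > 0)
        if int((~ok).sum()):
            logger.info(
                "point (animal %s, 1:%g): excluded %d non-positive %s replicate(s)",
                point.animal, point.dilution, int((~ok).sum()), label,
            )
        vals = np.log10(vals[ok])
        if len(vals) == 0:
            return None
        red = np.median if config.stat == "median" else np.mean
        return float(red(vals)), len(vals)

    eta = _reduce(point.eta_star_replicates, "eta*")
    vel = _reduce(point.velocity_replicates, "velocity")
    if eta is None or vel is None:
        logger.warning(
            "point (animal %s, 1:%g) lacks a modality; excluded from correlation",
            point.animal, point.dilution,
        )
        return None
    return AggregatedPoint(
        animal=point.animal,
        dilution=point.dilution,
        log_eta_star=eta[0],
        log_velocity=vel[0],
        n_eta_replicates=eta[1],
        n_velocity_replicates=vel[1],
    )


def correlate_log_values(points: Sequence[AggregatedPoint]) -> CorrelationResult:
    """Pearson test between log10 velocity and log10 eta* over all points.

    Returns the correlation coefficient with its two-sided p-value
    (t distribution, n-2 df) and the least-squares slope/intercept of
    log10 velocity on log10 eta*.
    """
    pts = [p for p in points if p is not None]
    x = np.array([p.log_eta_star for p in pts])
    y = np.array([p.log_velocity for p in pts])
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 finite points for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the axes")
    r, p = stats.pearsonr(x, y)
    fit = stats.linregress(x, y)
    return CorrelationResult(
        r=float(r), p=float(p), slope=float(fit.slope),
        intercept=float(fit.intercept), n=len(x),
    )


def fit_power_law(
    concentrations: Sequence[float], velocities: Sequence[float]
) -> PowerLawFit:
    """Fit v ~ c**slope by least squares in log10-log10 space.

    Reports the exponent as |slope| with the sign recorded separately,
    plus the regression standard error of the slope.
    """
    c = np.asarray(concentrations, dtype=float)
    v = np.asarray(velocities, dtype=float)
    if len(c) != len(v):
        raise ValueError("concentrations and velocities must have equal length")
    bad = np.nonzero(~((c > 0) & (v > 0) & np.isfinite(c) & np.isfinite(v)))[0]
    if len(bad):
        raise ValueError(f"non-positive or non-finite values at indices {bad.tolist()}")
    if len(c) < 3:
        raise ValueError("need at least 3 points to fit a power law")
    fit = stats.linregress(np.log10(c), np.log10(v))
    return PowerLawFit(
        exponent=abs(float(fit.slope)),
        sign=int(np.sign(fit.slope)) if fit.slope != 0 else 0,
        stderr=float(fit.stderr),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        n=len(c),
    )
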