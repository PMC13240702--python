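"""First-order dissipation kinetics for pesticide residue time series.

Field residue trials report concentrations ``C(t)`` in a matrix (soil,
straw or grain) at increasing times after application.  Under first-order
kinetics the residue decays as

    C(t) = C0 * exp(-k * t)

with dissipation rate constant ``k`` (day^-1) and half-life
``t_1/2 = ln 2 / k``.  This module fits that model to censoring-aware
residue series, computes half-lives, and expresses dissipation relative
to the initial deposit (conventionally the 2-hour sample, encoded as
t = 0.083 days).

Observations below the analytical limit of quantification (LOQ) are
left-censored.  Three conventional policies are supported when fitting:
drop them (``exclude``, the default — a censored tail point carries no
quantitative information), or substitute the LOQ or half the LOQ
(conservative conventions used in dietary-risk contexts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
from scipy.optimize import curve_fit

from .errors import NonConvergenceError, TooFewPointsError, ValidationError

__all__ = [
    "MATRICES",
    "CensoringPolicy",
    "ResidueObservation",
    "ResidueSeries",
    "DissipationFit",
    "half_life",
    "fit_first_order",
    "dissipation_ratio",
]

MATRICES = ("soil", "straw", "grain")

CensoringPolicy = Literal["exclude", "substitute_loq", "substitute_half_loq"]

#: Conventional encoding of the 2-hour "initial deposit" sample, in days.
TWO_HOURS_DAYS = 0.083


@dataclass(frozen=True)
class ResidueObservation:
    """One concentration measurement at a given time after application.

    For a censored observation (below LOQ) the ``concentration`` field
    holds the LOQ itself, not a measured value.
    """

    time_days: float
    concentration: float
    censored: bool = False
    loq: float = 0.01

    def __post_init__(self):
        problems = []
        if not math.isfinite(self.time_days) or self.time_days < 0:
            problems.append(f"time_days must be finite and >= 0, got {self.time_days}")
        if not math.isfinite(self.concentration) or self.concentration < 0:
            problems.append(
                f"concentration must be finite and >= 0, got {self.concentration}"
            )
        if not self.loq > 0:
            problems.append(f"loq must be > 0, got {self.loq}")
        if self.censored and not math.isclose(
            self.concentration, self.loq, rel_tol=1e-9
        ):
            problems.append(
                "censored observation must carry the LOQ as its concentration "
                f"(got {self.concentration}, loq {self.loq})"
            )
        if problems:
            raise ValidationError("invalid residue observation", problems)


@dataclass
class ResidueSeries:
    """Concentration-versus-time series for one site x matrix (x replicate)."""

    site_id: str
    matrix: str
    observations: list[ResidueObservation]
    replicate_id: str | None = None

    def __post_init__(self):
        if self.matrix not in MATRICES:
            raise ValidationError(
                f"matrix must be one of {MATRICES}, got {self.matrix!r}"
            )
        if not self.observations:
            raise ValidationError("a residue series needs at least one observation")
        self.observations = sorted(self.observations, key=lambda o: o.time_days)

    @property
    def times(self) -> np.ndarray:
        return np.array([o.time_days for o in self.observations])

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([o.concentration for o in self.observations])


@dataclass(frozen=True)
class DissipationFit:
    """First-order fit of one residue series.

    ``r_squared`` is the coefficient of determination on the natural
    concentration scale, computed over the points actually fitted.
    """

    c0: float
    k: float
    half_life_days: float
    r_squared: float
    n_used: int
    n_censored_excluded: int
    policy: str = "exclude"

    def predict(self, t) -> np.ndarray:
        """Fitted concentration C0 * exp(-k t)."""
        return self.c0 * np.exp(-self.k * np.asarray(t, dtype=float))


def half_life(k: float) -> float:
    """Dissipation half-life ln(2)/k for a first-order rate k (day^-1)."""
    if not k > 0:
        raise ValidationError(f"rate constant must be > 0, got {k}")
    return math.log(2.0) / k


def _apply_policy(
    series: ResidueSeries, policy: CensoringPolicy
) -> tuple[np.ndarray, np.ndarray, int]:
    """Return (times, concentrations, n_censored_excluded) after censoring."""
    t, c, n_excluded = [], [], 0
    for obs in series.observations:
        if obs.censored:
            if policy == "exclude":
                n_excluded += 1
                continue
            elif policy == "substitute_loq":
                value = obs.loq
            elif policy == "substitute_half_loq":
                value = obs.loq / 2.0
            else:
                raise ValidationError(f"unknown censoring policy {policy!r}")
        else:
            value = obs.concentration
        t.append(obs.time_days)
        c.append(value)
    return np.array(t), np.array(c), n_excluded


def _average_duplicates(t: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Arithmetic mean of replicate concentrations sharing a time point."""
    uniq, inverse = np.unique(t, return_inverse=True)
    means = np.zeros_like(uniq)
    for i in range(uniq.size):
        means[i] = c[inverse == i].mean()
    return uniq, means


def _loglinear_estimate(t: np.ndarray, c: np.ndarray) -> tuple[float, float]:
    """Ordinary least squares of ln C on t; returns (c0, k)."""
    if np.any(c <= 0):
        raise ValidationError("log-linear initialization needs positive concentrations")
    slope, intercept = np.polyfit(t, np.log(c), 1)
    k0 = max(-slope, 1e-12)
    return float(np.exp(intercept)), float(k0)


def _r_squared(observed: np.ndarray, predicted: np.ndarray) -> float:
    ss_res = float(np.sum((observed - predicted) ** 2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else float("-inf")
    return 1.0 - ss_res / ss_tot


def fit_first_order(
    series: ResidueSeries,
    policy: CensoringPolicy = "exclude",
    average_replicates: bool = True,
) -> DissipationFit:
    """Fit C(t) = C0 exp(-k t) to a residue series.

    Nonlinear least squares on the natural concentration scale with
    residuals weighted relative to the observed concentration (residue
    measurement error is multiplicative, so the error scale grows with
    the concentration), initialized from ordinary least squares on
    log-concentration; on noiseless exponential data the fit is exact.

    Parameters
    ----------
    series
        The residue series; replicate values at the same time point are
        averaged first unless ``average_replicates`` is False.
    policy
        How to treat censored (<LOQ) observations before fitting.

    Raises
    ------
    TooFewPointsError
        Fewer than 3 usable observations, or fewer than 2 distinct times.
    NonConvergenceError
        The nonlinear solver failed; the error carries the log-linear
        fallback estimate in its ``fallback`` attribute.
    """
    t, c, n_excluded = _apply_policy(series, policy)
    if average_replicates and t.size:
        t, c = _average_duplicates(t, c)
    if t.size < 3:
        raise TooFewPointsError(
            f"need >= 3 observations after censoring policy {policy!r}, "
            f"have {t.size}"
        )
    if np.unique(t).size < 2:
        raise TooFewPointsError("need at least two distinct time points")

    c0_init, k_init = _loglinear_estimate(t, c)

    def model(tt, c0, k):
        return c0 * np.exp(-k * tt)

    def _build(c0, k, n_used):
        pred = model(t, c0, k)
        return DissipationFit(
            c0=float(c0),
            k=float(k),
            half_life_days=half_life(float(k)),
            r_squared=_r_squared(c, pred),
            n_used=int(n_used),
            n_censored_excluded=n_excluded,
            policy=policy,
        )

    try:
        popt, _ = curve_fit(
            model,
            t,
            c,
            p0=[c0_init, k_init],
            sigma=c,  # relative (multiplicative-error) weighting
            bounds=([1e-300, 1e-300], [np.inf, np.inf]),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - hard to trigger
        raise NonConvergenceError(
            f"nonlinear fit did not converge: {exc}",
            fallback=_build(c0_init, k_init, t.size),
        ) from exc
    return _build(popt[0], popt[1], t.size)


def _interpolate_loglinear(series: ResidueSeries, t: float) -> float:
    """Concentration at t, log-linear between bracketing observations."""
    times = series.times
    concs = series.concentrations
    if t < times[0] or t > times[-1]:
        raise ValidationError(
            f"time {t} outside the observed range [{times[0]}, {times[-1]}]"
        )
    exact = np.isclose(times, t)
    if exact.any():
        return float(concs[exact].mean())
    hi = int(np.searchsorted(times, t))
    lo = hi - 1
    t0, t1 = times[lo], times[hi]
    c0, c1 = concs[lo], concs[hi]
    if c0 <= 0 or c1 <= 0:
        # degenerate zero residue: fall back to linear interpolation
        return float(c0 + (c1 - c0) * (t - t0) / (t1 - t0))
    log_c = np.log(c0) + (np.log(c1) - np.log(c0)) * (t - t0) / (t1 - t0)
    return float(np.exp(log_c))


def dissipation_ratio(series: ResidueSeries, t: float) -> float:
    """Fraction of the initial deposit dissipated by time t.

    Returns ``1 - C(t)/C(initial)`` where the initial deposit is the
    earliest observation of the series (nominally the 2-hour sample).
    When t falls between sampled times the concentration is interpolated
    log-linearly between the bracketing observations.
    """
    initial = series.observations[0]
    if initial.censored:
        raise ValidationError(
            "initial deposit is censored; dissipation ratio is undefined"
        )
    if initial.concentration <= 0:
        raise ValidationError("initial deposit concentration must be > 0")
    c_t = _interpolate_loglinear(series, t)
    return 1.0 - c_t / initial.concentration
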