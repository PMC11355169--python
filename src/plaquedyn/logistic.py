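"""Logistic-map model of atherosclerotic plaque burden.

The plaque burden ``P`` at surveillance visit ``t`` is the proportion of the
arterial lumen cross-section occupied by plaque and evolves by the logistic
map ``P_{t+1} = r * P_t * (1 - P_t)``.  The growth parameter ``r`` aggregates
hemodynamic, inflammatory, mechanical and metabolic influences and may itself
change from visit to visit.  This module provides:

* the map, its fixed point and a taxonomy of dynamical regimes,
* a dynamic growth-rate aggregate ``r(P) = alpha * (1 + sum_i beta_i f_i(P))``,
* positive lumen remodeling (geometric approach of the lumen area ``A`` from
  ``A0`` to ``Amax``),
* trajectory simulation over discrete surveillance visits,
* chaos diagnostics (Lyapunov exponent, onset of chaos, first period
  doubling),
* the closed-form instability proportion: the fraction of admissible growth
  rates that shrink the plaque at the next visit, and
* estimation of ``r`` from serial planimetric measurements together with a
  stable/unstable risk classification (unstable: r > 2).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np

from .exceptions import (
    AnalysisError,
    ClassificationError,
    DomainError,
    EvaluationError,
    SimulationError,
)

__all__ = [
    "CHAOS_ONSET",
    "Regime",
    "RegimeLabel",
    "GrowthAggregate",
    "RemodelingLumen",
    "PlaqueTrajectory",
    "GrowthRateEstimates",
    "logistic_step",
    "fixed_point",
    "classify_regime",
    "aggregate_growth_rate",
    "update_lumen",
    "simulate_trajectory",
    "instability_proportion",
    "instability_curve",
    "lyapunov_exponent",
    "attractor_period",
    "chaos_onset",
    "first_bifurcation",
    "estimate_r_series",
    "classify_plaque_risk",
    "factor_constant",
    "factor_linear",
    "factor_saturating",
]

#: Period-doubling accumulation point of the logistic map (onset of chaos).
CHAOS_ONSET = 3.56995


class Regime(enum.Enum):
    """Dynamical regimes of the logistic map as a function of ``r``.

    Boundary convention: the values r = 1, 2, 3 belong to the lower regime
    (each interval is closed on the right).
    """

    EXTINCTION = "EXTINCTION"  # 0 < r <= 1: P -> 0
    MONOTONE_CONVERGENCE = "MONOTONE_CONVERGENCE"  # 1 < r <= 2: P -> (r-1)/r
    TRANSIENT_FLUCTUATION = "TRANSIENT_FLUCTUATION"  # 2 < r <= 3: damped oscillation
    PERIODIC = "PERIODIC"  # 3 < r < chaos onset: period 2, 4, 8, ...
    CHAOTIC = "CHAOTIC"  # r >= chaos onset


@dataclass(frozen=True)
class RegimeLabel:
    """A regime classification with, where defined, the attracting fixed point."""

    label: Regime
    fixed_point: float | None


def logistic_step(P: float, r: float) -> float:
    """One iteration of the logistic map, ``r * P * (1 - P)``.

    Requires ``0 <= P <= 1`` and ``0 <= r <= 4`` so the image stays in [0, 1].
    """
    if not (0.0 <= P <= 1.0) or not math.isfinite(P):
        raise DomainError(f"P={P!r} outside [0, 1]")
    if not (0.0 <= r <= 4.0) or not math.isfinite(r):
        raise DomainError(f"r={r!r} outside [0, 4]")
    return r * P * (1.0 - P)


def fixed_point(r: float) -> float:
    """Attracting limit of the map: 0 for ``r <= 1``, else ``(r - 1) / r``."""
    if not (r > 0.0) or not math.isfinite(r):
        raise DomainError(f"r={r!r} must be a positive finite growth rate")
    if r <= 1.0:
        return 0.0
    return (r - 1.0) / r


def classify_regime(r: float, chaos_onset_value: float = CHAOS_ONSET) -> RegimeLabel:
    """Classify the long-run behaviour of the map at growth rate ``r``."""
    if not (r > 0.0) or not math.isfinite(r):
        raise DomainError(f"r={r!r} must be a positive finite growth rate")
    if not (3.0 < chaos_onset_value < 4.0):
        raise DomainError(
            f"chaos_onset_value={chaos_onset_value!r} must lie in (3, 4)"
        )
    if r <= 1.0:
        return RegimeLabel(Regime.EXTINCTION, 0.0)
    if r <= 2.0:
        return RegimeLabel(Regime.MONOTONE_CONVERGENCE, fixed_point(r))
    if r <= 3.0:
        return RegimeLabel(Regime.TRANSIENT_FLUCTUATION, fixed_point(r))
    if r < chaos_onset_value:
        return RegimeLabel(Regime.PERIODIC, None)
    return RegimeLabel(Regime.CHAOTIC, None)


# ---------------------------------------------------------------------------
# Growth-rate aggregate r(P)
# ---------------------------------------------------------------------------

FactorFunction = Callable[[float], float]


def factor_constant(value: float = 1.0) -> FactorFunction:
    """Factor that ignores the plaque burden (constant influence)."""
    return lambda P: value


def factor_linear(slope: float = 1.0) -> FactorFunction:
    """Factor proportional to the plaque burden, ``slope * P``."""
    return lambda P: slope * P


def factor_saturating(k: float = 0.5) -> FactorFunction:
    """Michaelis–Menten-style saturating factor, ``P / (P + k)``."""
    return lambda P: P / (P + k)


@dataclass
class GrowthAggregate:
    """The bundle defining the dynamic growth rate r(P).

    r(P) = alpha * (1 + beta_1 f_1(P) + beta_2 f_2(P) + beta_3 f_3(P)
                      + beta_4 f_4(P))

    The four factor functions conventionally represent hemodynamic,
    inflammatory, mechanical and metabolic influences; their functional forms
    are user-supplied (see :func:`factor_constant` and friends for a small
    shipped library).

    Parameters
    ----------
    alpha : baseline growth rate (> 0, dimensionless).
    betas : four weighting coefficients.
    factors : four callables mapping P in [0, 1] to a real number.
    r_lower_bound : optional floor on the emitted rate.  Established plaques
        rarely regress, so the clinically motivated default is 1.
    r_update_increment : optional per-visit change in the effective rate,
        emulating slow drift of the aggregate over a surveillance horizon.
    increment_mode : 'additive' adds ``increment * visit`` to r(P);
        'multiplicative' scales r(P) by ``increment ** visit``.
    """

    alpha: float = 1.0
    betas: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    factors: tuple[FactorFunction, ...] = field(
        default_factory=lambda: (
            factor_constant(),
            factor_constant(),
            factor_constant(),
            factor_constant(),
        )
    )
    r_lower_bound: float | None = 1.0
    r_update_increment: float = 0.0
    increment_mode: Literal["additive", "multiplicative"] = "additive"

    def __post_init__(self) -> None:
        if not (self.alpha > 0.0) or not math.isfinite(self.alpha):
            raise DomainError(f"alpha={self.alpha!r} must be positive and finite")
        if len(self.betas) != 4 or len(self.factors) != 4:
            raise DomainError("exactly four betas and four factor functions required")
        if not all(math.isfinite(b) for b in self.betas):
            raise DomainError("all betas must be finite")
        if self.increment_mode not in ("additive", "multiplicative"):
            raise DomainError(f"unknown increment_mode {self.increment_mode!r}")

    def raw_rate(self, P: float) -> float:
        """Evaluate r(P) without the floor/ceiling clamps."""
        total = 1.0
        for i, (beta, f) in enumerate(zip(self.betas, self.factors), start=1):
            value = f(P)
            if not math.isfinite(value):
                raise EvaluationError(
                    f"factor f{i} returned non-finite value {value!r} at P={P}"
                )
            total += beta * value
        return self.alpha * total


def aggregate_growth_rate(P: float, g: GrowthAggregate) -> float:
    """Evaluate the aggregate growth rate r(P), clamped at zero and at the
    configured lower bound."""
    if not (0.0 <= P <= 1.0):
        raise DomainError(f"P={P!r} outside [0, 1]")
    r = g.raw_rate(P)
    r = max(r, 0.0)
    if g.r_lower_bound is not None:
        r = max(r, g.r_lower_bound)
    return r


# ---------------------------------------------------------------------------
# Positive remodeling of the lumen
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RemodelingLumen:
    """Positive remodeling: the lumen area grows from A0 toward Amax.

    The approach is geometric with per-visit rate ``rate``:
    ``A_{t+1} = A_t + rate * (Amax - A_t)``, which is monotone non-decreasing
    and converges to Amax.
    """

    A0: float = 1.0
    Amax: float = 1.0
    rate: float = 0.0

    def __post_init__(self) -> None:
        if not (self.A0 > 0.0):
            raise DomainError(f"A0={self.A0!r} must be positive")
        if self.Amax < self.A0:
            raise DomainError(f"Amax={self.Amax!r} must be >= A0={self.A0!r}")
        if not (0.0 <= self.rate <= 1.0):
            raise DomainError(f"rate={self.rate!r} must lie in [0, 1]")


def update_lumen(A: float, lum: RemodelingLumen) -> float:
    """One remodeling step of the lumen area."""
    if not (lum.A0 <= A <= lum.Amax):
        raise DomainError(f"A={A!r} outside [A0={lum.A0}, Amax={lum.Amax}]")
    return A + lum.rate * (lum.Amax - A)


# ---------------------------------------------------------------------------
# Trajectory simulation
# ---------------------------------------------------------------------------


@dataclass
class PlaqueTrajectory:
    """A simulated plaque course over discrete surveillance visits.

    All three series share length ``n_visits + 1``; index 0 is the initial
    state.  ``r_series[t]`` (t >= 1) is the growth rate applied to advance
    from visit t-1 to t; ``r_series[0]`` is NaN since no growth produced the
    initial state.  ``oscillation_onset`` is the first visit at which P
    decreased after having previously increased — the model's marker for
    plaque erosion/rupture initiating the oscillatory (symptomatic-risk)
    phase — or None for a monotone course.  Requiring a prior increase
    distinguishes erosion of a grown plaque from simple regression of a
    small one (a trajectory that only ever shrinks is not oscillating).
    """

    P_series: np.ndarray
    r_series: np.ndarray
    A_series: np.ndarray
    oscillation_onset: int | None

    def __post_init__(self) -> None:
        if not (len(self.P_series) == len(self.r_series) == len(self.A_series)):
            raise ValueError("P, r and A series must share one length")

    @property
    def stenosis_vs_baseline(self) -> np.ndarray:
        """Plaque area relative to the baseline lumen, ``P * A(t) / A0``.

        P is defined against the current (remodeled) lumen; this derived
        series re-expresses the same plaque mass against the initial lumen.
        It is reported only — it never feeds back into the map.
        """
        return self.P_series * self.A_series / self.A_series[0]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "visit": np.arange(len(self.P_series)),
                "P": self.P_series,
                "r": self.r_series,
                "A": self.A_series,
                "stenosis_vs_baseline": self.stenosis_vs_baseline,
            }
        )


def simulate_trajectory(
    P0: float,
    n_visits: int,
    *,
    growth: GrowthAggregate | None = None,
    lumen: RemodelingLumen | None = None,
    r_schedule: float | Sequence[float] | None = None,
) -> PlaqueTrajectory:
    """Simulate a plaque trajectory over ``n_visits`` discrete visits.

    Exactly one of ``growth`` (dynamic aggregate mode) or ``r_schedule``
    (explicit-rate mode; a constant or one rate per visit) must be given.
    In aggregate mode the rate for visit t is r(P_{t-1}) plus the optional
    per-visit increment, then clamped at 0 and at the aggregate's lower
    bound.  The lumen is updated once per visit; if ``lumen`` is omitted the
    lumen is static at area 1.
    """
    if (growth is None) == (r_schedule is None):
        raise DomainError("exactly one of growth or r_schedule must be provided")
    if not (0.0 < P0 < 1.0):
        raise DomainError(f"P0={P0!r} must lie in (0, 1)")
    if n_visits < 1:
        raise DomainError(f"n_visits={n_visits!r} must be >= 1")
    lum = lumen if lumen is not None else RemodelingLumen()

    if r_schedule is not None:
        if np.isscalar(r_schedule):
            schedule = np.full(n_visits, float(r_schedule))  # type: ignore[arg-type]
        else:
            schedule = np.asarray(r_schedule, dtype=float)
            if schedule.shape != (n_visits,):
                raise DomainError(
                    f"r_schedule has length {schedule.size}, expected {n_visits}"
                )

    P = np.empty(n_visits + 1)
    r = np.empty(n_visits + 1)
    A = np.empty(n_visits + 1)
    P[0], r[0], A[0] = P0, np.nan, lum.A0
    onset: int | None = None
    grew = False

    for t in range(1, n_visits + 1):
        if growth is not None:
            rate = growth.raw_rate(P[t - 1])
            if growth.increment_mode == "additive":
                rate += growth.r_update_increment * (t - 1)
            elif growth.r_update_increment != 0.0:
                rate *= growth.r_update_increment ** (t - 1)
            rate = max(rate, 0.0)
            if growth.r_lower_bound is not None:
                rate = max(rate, growth.r_lower_bound)
        else:
            rate = schedule[t - 1]
        try:
            P[t] = logistic_step(P[t - 1], rate)
        except DomainError as exc:
            raise SimulationError(
                f"trajectory left its admissible range at visit {t}: {exc}", visit=t
            ) from exc
        r[t] = rate
        A[t] = update_lumen(A[t - 1], lum)
        if P[t] > P[t - 1]:
            grew = True
        elif grew and onset is None and P[t] < P[t - 1]:
            onset = t

    return PlaqueTrajectory(P, r, A, onset)


# ---------------------------------------------------------------------------
# Instability proportion (fraction of destabilizing growth rates)
# ---------------------------------------------------------------------------


def instability_proportion(P: float, r_max: float = 3.5) -> float:
    """Fraction of growth rates in [0, r_max] that shrink the plaque.

    A rate r decreases the burden iff r * P * (1 - P) < P, i.e. r < 1/(1-P),
    so the fraction is ``min(1, 1 / (r_max * (1 - P)))``.  It increases with
    P and saturates at 1 once P >= 1 - 1/r_max (~0.714 for the default bound
    3.5): large plaques become inevitably unstable.
    """
    if not (0.0 < P < 1.0):
        raise DomainError(f"P={P!r} must lie strictly in (0, 1)")
    if not (r_max > 0.0) or not math.isfinite(r_max):
        raise DomainError(f"r_max={r_max!r} must be positive and finite")
    return min(1.0, 1.0 / (r_max * (1.0 - P)))


def instability_curve(
    P_values: Sequence[float] | np.ndarray, r_max: float = 3.5
) -> np.ndarray:
    """Vectorized :func:`instability_proportion` over a grid of burdens."""
    P = np.asarray(P_values, dtype=float)
    if np.any((P <= 0.0) | (P >= 1.0)):
        raise DomainError("all P values must lie strictly in (0, 1)")
    if not (r_max > 0.0):
        raise DomainError(f"r_max={r_max!r} must be positive")
    return np.minimum(1.0, 1.0 / (r_max * (1.0 - P)))


# ---------------------------------------------------------------------------
# Chaos diagnostics
# ---------------------------------------------------------------------------


def lyapunov_exponent(
    r: float,
    burn_in: int = 1_000,
    n_iter: int = 100_000,
    P0: float = 0.1,
) -> float:
    """Largest Lyapunov exponent of the map at rate ``r`` (nats per step).

    Averages ``ln |r * (1 - 2 P_t)|`` along the orbit after discarding
    ``burn_in`` iterations.  Terms where the derivative is exactly zero
    (orbit hits P = 0.5) are skipped.  Negative values indicate a stable
    periodic attractor, positive values chaos.
    """
    if not (0.0 < r <= 4.0):
        raise DomainError(f"r={r!r} outside (0, 4]")
    if n_iter < 1:
        raise DomainError("n_iter must be >= 1")
    if not (0.0 < P0 < 1.0):
        raise DomainError(f"P0={P0!r} must lie in (0, 1)")
    P = P0
    for _ in range(burn_in):
        P = r * P * (1.0 - P)
    total = 0.0
    count = 0
    log = math.log
    for _ in range(n_iter):
        d = abs(r * (1.0 - 2.0 * P))
        if d > 0.0:
            total += log(d)
            count += 1
        P = r * P * (1.0 - P)
    if count == 0:
        raise AnalysisError("orbit derivative vanished at every sampled iterate")
    return total / count


def attractor_period(
    r: float,
    burn_in: int = 100_000,
    n_samples: int = 256,
    tol: float = 1e-8,
    P0: float = 0.1,
) -> int:
    """Number of distinct values visited by the post-transient orbit.

    Iterates ``burn_in`` steps, then clusters ``n_samples`` further iterates
    with absolute tolerance ``tol``.  Near bifurcation points transients decay
    slowly, so the burn-in must grow as the reciprocal of the distance to the
    bifurcation for the count to be trustworthy.
    """
    if not (0.0 < r <= 4.0):
        raise DomainError(f"r={r!r} outside (0, 4]")
    P = P0
    for _ in range(burn_in):
        P = r * P * (1.0 - P)
    samples = np.empty(n_samples)
    for i in range(n_samples):
        samples[i] = P
        P = r * P * (1.0 - P)
    samples.sort()
    return int(1 + np.count_nonzero(np.diff(samples) > tol))


def chaos_onset(
    tolerance: float = 1e-5,
    burn_in: int = 1_000,
    n_iter: int = 100_000,
    P0: float = 0.1,
    scan_step: float = 0.02,
) -> float:
    """Locate the onset of chaos: the smallest r with a positive Lyapunov
    exponent, approached from below.

    Scans r upward from 3 in steps of ``scan_step`` until the Lyapunov
    exponent turns positive, then bisects the bracketing interval down to
    ``tolerance``.  The reported value approximates the period-doubling
    accumulation point (~3.56995).  Periodic windows above the accumulation
    point are avoided by taking the first positive crossing from below.
    """
    if tolerance > 1e-4:
        raise DomainError("tolerance must be <= 1e-4")
    lam = lambda r: lyapunov_exponent(r, burn_in=burn_in, n_iter=n_iter, P0=P0)
    lo = 3.0
    hi = None
    r = lo + scan_step
    while r < 4.0:
        if lam(r) > 0.0:
            hi = r
            break
        lo = r
        r += scan_step
    if hi is None:
        raise AnalysisError("no positive Lyapunov exponent found in (3, 4)")
    while hi - lo > tolerance:
        mid = 0.5 * (lo + hi)
        if lam(mid) > 0.0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def first_bifurcation(
    resolution: float = 1e-4,
    burn_in: int | None = None,
    n_samples: int = 256,
    tol: float = 1e-8,
) -> float:
    """Locate the first period doubling: the boundary between a period-1 and
    a period-2 attractor (analytically at r = 3).

    Bisects on the attractor period over r in [2.5, 3.5].  Because the
    transient decay rate vanishes linearly at the bifurcation, the burn-in
    defaults to ``16 / resolution`` iterations so that residual transients at
    distance ``resolution`` from the boundary fall below the clustering
    tolerance.
    """
    if resolution > 1e-3:
        raise DomainError("resolution must be <= 1e-3")
    if burn_in is None:
        burn_in = int(16.0 / resolution)
    period = lambda r: attractor_period(
        r, burn_in=burn_in, n_samples=n_samples, tol=tol
    )
    lo, hi = 2.5, 3.5
    if period(lo) != 1 or period(hi) < 2:
        raise AnalysisError("bracket [2.5, 3.5] does not straddle the doubling")
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if period(mid) == 1:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Estimation of r from serial measurements, and risk classification
# ---------------------------------------------------------------------------


@dataclass
class GrowthRateEstimates:
    """Per-interval growth-rate estimates from serial measurements.

    ``r_hat[k]`` inverts the map over the k-th inter-visit interval:
    ``r_hat = P_{k+1} / (P_k * (1 - P_k))``.  Intervals whose starting
    measurement sits at the degenerate boundary (P = 0 or P = 1) have no
    defined estimate; they are flagged in ``undefined`` and carry NaN in
    ``r_hat`` rather than being dropped.
    """

    r_hat: np.ndarray
    undefined: np.ndarray

    def __len__(self) -> int:
        return len(self.r_hat)

    @property
    def defined(self) -> np.ndarray:
        """The defined estimates, in interval order."""
        return self.r_hat[~self.undefined]


def estimate_r_series(P_measurements: Sequence[float] | np.ndarray) -> GrowthRateEstimates:
    """Solve the logistic map for r over each consecutive measurement pair."""
    P = np.asarray(P_measurements, dtype=float)
    if P.ndim != 1 or P.size < 2:
        raise DomainError("need a 1-D series of at least two measurements")
    if np.any(~np.isfinite(P)) or np.any((P < 0.0) | (P > 1.0)):
        raise DomainError("all measurements must be finite and in [0, 1]")
    denom = P[:-1] * (1.0 - P[:-1])
    undefined = denom == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        r_hat = np.where(undefined, np.nan, P[1:] / np.where(undefined, 1.0, denom))
    return GrowthRateEstimates(r_hat=r_hat, undefined=undefined)


def classify_plaque_risk(
    r_estimates: GrowthRateEstimates | Sequence[float] | np.ndarray,
    threshold: float = 2.0,
    summary: Literal["latest", "trailing_mean"] = "latest",
    window: int = 3,
) -> str:
    """Classify a plaque as ``'STABLE'`` or ``'UNSTABLE'`` from its estimated
    growth rates.

    Unstable plaques are those whose growth rate strictly exceeds the
    threshold (default 2, the rate at which oscillations — erosion/rupture
    cycles — first appear).  The summary statistic is the latest defined
    estimate by default, or the mean of the trailing ``window`` defined
    estimates.
    """
    if isinstance(r_estimates, GrowthRateEstimates):
        values = r_estimates.defined
    else:
        arr = np.asarray(r_estimates, dtype=float)
        values = arr[np.isfinite(arr)]
    if values.size == 0:
        raise ClassificationError("no defined growth-rate estimates to classify")
    if summary == "latest":
        stat = values[-1]
    elif summary == "trailing_mean":
        stat = float(np.mean(values[-window:]))
    else:
        raise DomainError(f"unknown summary rule {summary!r}")
    return "UNSTABLE" if stat > threshold else "STABLE"
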