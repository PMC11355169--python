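"""Two-state Markov chain for plaque stability.

States are indexed 0 = Stable (S) and 1 = Unstable (U) everywhere in the
package (matrices, samplers, serialized files).  The probability of a
stable-to-unstable transition is a covariate-weighted linear form

    P(S -> U) = base + w1*I + w2*L + w3*S + w4*B  (+ w5*D on a lattice)

over inflammation I, lipid content L, shear stress S and plaque burden B,
clamped into [0, 1].  The chain's long-run behaviour is summarized by its
stationary distribution (left eigenvector for eigenvalue 1), and a
continuous-time reading of the instability rate gives exponential event
curves P(S->S) = exp(-hazard * t), P(S->U) = 1 - exp(-hazard * t).

The parameter governing S -> U appears in two guises — a one-step transition
probability (``p_su``) and a continuous-time hazard (``hazard_su``).  Both
readings are kept, in separate operations with distinct names; converting a
per-interval probability to a hazard is ``hazard = -ln(1 - p_su)`` (see
:func:`probability_to_hazard`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.special import expit, logit

from .exceptions import DomainError, ModelError

__all__ = [
    "STABLE",
    "UNSTABLE",
    "CovariateProfile",
    "TransitionWeights",
    "TwoStateMatrix",
    "StationaryDistribution",
    "ClampTracker",
    "transition_probability",
    "build_matrix",
    "stationary_distribution",
    "closed_form_stationary",
    "event_probabilities",
    "probability_to_hazard",
    "simulate_chain",
]

STABLE = 0
UNSTABLE = 1


@dataclass(frozen=True)
class CovariateProfile:
    """Per-site covariates: inflammation, lipid content, shear stress and
    plaque burden, as non-negative dimensionless scores."""

    I: float = 0.0
    L: float = 0.0
    S: float = 0.0
    B: float = 0.0

    def __post_init__(self) -> None:
        for name in ("I", "L", "S", "B"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0.0:
                raise DomainError(f"covariate {name}={v!r} must be finite and >= 0")


@dataclass(frozen=True)
class TransitionWeights:
    """Base probability and covariate weights for the S -> U transition.

    ``w5`` weights the spatial-dependence term and is only consulted on a
    lattice (see :mod:`plaquedyn.spatial`).
    """

    base: float = 0.1
    w1: float = 0.0
    w2: float = 0.0
    w3: float = 0.0
    w4: float = 0.0
    w5: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.base <= 1.0):
            raise DomainError(f"base={self.base!r} must lie in [0, 1]")
        for name in ("w1", "w2", "w3", "w4", "w5"):
            if not math.isfinite(getattr(self, name)):
                raise DomainError(f"weight {name} must be finite")


class ClampTracker:
    """Counts how often the linear transition form had to be clamped into
    [0, 1].  A high clamp rate signals misconfigured weights, so a warning is
    emitted once the rate exceeds 1% over at least 100 evaluations."""

    def __init__(self) -> None:
        self.total = 0
        self.clamped = 0
        self._warned = False

    def record(self, clamped: bool) -> None:
        self.total += 1
        self.clamped += clamped
        if (
            not self._warned
            and self.total >= 100
            and self.clamped / self.total > 0.01
        ):
            self._warned = True
            warnings.warn(
                f"{self.clamped}/{self.total} transition-probability evaluations "
                "were clamped into [0, 1]; check the weight configuration",
                stacklevel=3,
            )

    @property
    def rate(self) -> float:
        return self.clamped / self.total if self.total else 0.0


def transition_probability(
    c: CovariateProfile,
    w: TransitionWeights,
    D_term: float = 0.0,
    link: Literal["linear", "logistic"] = "linear",
    tracker: ClampTracker | None = None,
) -> float:
    """Covariate-weighted probability of the stable-to-unstable transition.

    The default ``linear`` link evaluates the literal linear form and clamps
    it into [0, 1] (clamping events are recorded on ``tracker`` if given).
    The ``logistic`` alternative maps the same linear predictor through the
    inverse-logit around ``logit(base)``, guaranteeing a probability without
    clamping.
    """
    if not math.isfinite(D_term):
        raise DomainError(f"D_term={D_term!r} must be finite")
    eta = w.w1 * c.I + w.w2 * c.L + w.w3 * c.S + w.w4 * c.B + w.w5 * D_term
    if link == "linear":
        p = w.base + eta
        clamped = p < 0.0 or p > 1.0
        if tracker is not None:
            tracker.record(clamped)
        return min(1.0, max(0.0, p))
    if link == "logistic":
        if not (0.0 < w.base < 1.0):
            raise DomainError("logistic link requires base strictly in (0, 1)")
        if tracker is not None:
            tracker.record(False)
        return float(expit(logit(w.base) + eta))
    raise DomainError(f"unknown link {link!r}")


@dataclass(frozen=True)
class TwoStateMatrix:
    """Row-stochastic 2x2 transition matrix over (Stable, Unstable).

    ``p_su`` is the off-diagonal S -> U entry, ``p_us`` the U -> S entry.
    """

    p_su: float
    p_us: float

    def __post_init__(self) -> None:
        for name, v in (("p_su", self.p_su), ("p_us", self.p_us)):
            if not (0.0 <= v <= 1.0) or not math.isfinite(v):
                raise DomainError(f"{name}={v!r} must lie in [0, 1]")

    @property
    def matrix(self) -> np.ndarray:
        return np.array(
            [[1.0 - self.p_su, self.p_su], [self.p_us, 1.0 - self.p_us]]
        )

    @property
    def is_ergodic(self) -> bool:
        """True when the chain is irreducible and aperiodic (a unique
        stationary distribution exists): the two off-diagonals must not both
        be 0 (reducible) nor both be 1 (period-2 alternation)."""
        return not (
            (self.p_su == 0.0 and self.p_us == 0.0)
            or (self.p_su == 1.0 and self.p_us == 1.0)
        )


def build_matrix(p_su: float, p_us: float) -> TwoStateMatrix:
    """Assemble the row-stochastic 2x2 matrix from its off-diagonal rates."""
    return TwoStateMatrix(p_su=float(p_su), p_us=float(p_us))


@dataclass(frozen=True)
class StationaryDistribution:
    """Long-run state-occupancy probabilities [pi_S, pi_U]."""

    pi_S: float
    pi_U: float
    eigenvalue: float = 1.0

    @property
    def as_array(self) -> np.ndarray:
        return np.array([self.pi_S, self.pi_U])


def closed_form_stationary(p_su: float, p_us: float) -> tuple[float, float]:
    """Closed form for the two-state stationary distribution:
    pi_S = p_us / (p_su + p_us), pi_U = p_su / (p_su + p_us)."""
    total = p_su + p_us
    if total == 0.0:
        raise ModelError("chain with p_su = p_us = 0 is reducible")
    return p_us / total, p_su / total


def stationary_distribution(m: TwoStateMatrix) -> StationaryDistribution:
    """Stationary distribution via the left eigenvector for eigenvalue 1.

    Requires an irreducible, aperiodic chain (a positive probability of
    reaching any state from any other, and no deterministic cycling);
    otherwise the stationary distribution is not unique and a
    :class:`~plaquedyn.exceptions.ModelError` is raised.
    """
    if not m.is_ergodic:
        raise ModelError(
            "stationary distribution requires an irreducible, aperiodic chain: "
            "p_su and p_us must not both be 0 (reducible) nor both be 1 (periodic)"
        )
    eigvals, eigvecs = np.linalg.eig(m.matrix.T)
    idx = int(np.argmin(np.abs(eigvals - 1.0)))
    vec = np.real(eigvecs[:, idx])
    vec = np.abs(vec)
    vec = vec / vec.sum()
    return StationaryDistribution(
        pi_S=float(vec[0]), pi_U=float(vec[1]), eigenvalue=float(np.real(eigvals[idx]))
    )


def event_probabilities(alpha_su: float, t: float) -> tuple[float, float]:
    """Exponential event curves under a constant instability hazard.

    Returns ``(P(S->S), P(S->U)) = (exp(-alpha_su * t), 1 - exp(-alpha_su * t))``;
    the two components sum to 1 exactly.
    """
    if alpha_su < 0.0 or not math.isfinite(alpha_su):
        raise DomainError(f"alpha_su={alpha_su!r} must be finite and >= 0")
    if t < 0.0 or not math.isfinite(t):
        raise DomainError(f"t={t!r} must be finite and >= 0")
    p_stay = math.exp(-alpha_su * t)
    return p_stay, 1.0 - p_stay


def probability_to_hazard(p_su: float) -> float:
    """Convert a per-interval transition probability to the equivalent
    continuous-time hazard, ``-ln(1 - p_su)`` per unit interval."""
    if not (0.0 <= p_su < 1.0):
        raise DomainError(f"p_su={p_su!r} must lie in [0, 1)")
    return -math.log1p(-p_su)


def simulate_chain(
    m: TwoStateMatrix,
    n_steps: int,
    seed: int,
    initial: int = STABLE,
) -> np.ndarray:
    """Simulate a seeded state sequence of length ``n_steps + 1`` (the
    initial state plus one state per step)."""
    if n_steps < 1:
        raise DomainError(f"n_steps={n_steps!r} must be >= 1")
    if initial not in (STABLE, UNSTABLE):
        raise DomainError(f"initial={initial!r} must be 0 (S) or 1 (U)")
    rng = np.random.default_rng(seed)
    u = rng.random(n_steps)
    states = np.empty(n_steps + 1, dtype=np.int8)
    states[0] = initial
    p_su, p_us = m.p_su, m.p_us
    s = initial
    for i in range(n_steps):
        if s == STABLE:
            s = UNSTABLE if u[i] < p_su else STABLE
        else:
            s = STABLE if u[i] < p_us else UNSTABLE
        states[i + 1] = s
    return states
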