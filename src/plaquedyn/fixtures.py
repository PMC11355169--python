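"""Seeded synthetic-data generators.

No clinical dataset accompanies these models, so every input the package
consumes can be generated here: serial planimetric surveillance series
(trajectories of plaque burden P observed with truncated Gaussian
measurement noise) and spatially correlated covariate grids for the lattice
models.  Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import DomainError
from .logistic import simulate_trajectory

__all__ = [
    "MeasurementSeriesSpec",
    "CovariateFieldSpec",
    "generate_measurement_series",
    "generate_covariate_grid",
]


@dataclass(frozen=True)
class MeasurementSeriesSpec:
    """Specification of a synthetic surveillance series.

    ``r_constant`` gives a constant growth rate; alternatively ``r0`` plus
    ``r_increment`` gives a linearly drifting rate (r0 + increment * visit),
    emulating slow progression of the growth aggregate.  Observation noise
    is additive Gaussian with standard deviation ``noise_sd``, truncated by
    resampling so observed P stays strictly inside (0, 1); the default 0.01
    is small relative to the burden scale, in the spirit of the ~2 mm
    planimetric resolution of surveillance ultrasound.
    """

    n_visits: int = 50
    P0: float = 0.1
    r_constant: float | None = 1.8
    r0: float | None = None
    r_increment: float = 0.0
    noise_sd: float = 0.01
    seed: int = 0
    patient_id: str = "synthetic-001"

    def __post_init__(self) -> None:
        if self.n_visits < 2:
            raise DomainError("n_visits must be >= 2")
        if self.noise_sd < 0.0:
            raise DomainError("noise_sd must be >= 0")
        if (self.r_constant is None) == (self.r0 is None):
            raise DomainError("exactly one of r_constant or r0 must be set")

    def r_schedule(self) -> np.ndarray:
        if self.r_constant is not None:
            return np.full(self.n_visits, self.r_constant)
        return self.r0 + self.r_increment * np.arange(self.n_visits)


def generate_measurement_series(
    spec: MeasurementSeriesSpec,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a trajectory and observe it with truncated Gaussian noise.

    Returns ``(measurements, truth)``: the measurement table with columns
    ``patient_id, visit_index, P`` and a sidecar truth table with columns
    ``patient_id, interval_index, r_true`` holding the growth rate that
    generated each inter-visit interval (for parameter-recovery tests).
    """
    schedule = spec.r_schedule()
    traj = simulate_trajectory(spec.P0, spec.n_visits, r_schedule=schedule)
    rng = np.random.default_rng(spec.seed)
    observed = traj.P_series.copy()
    if spec.noise_sd > 0.0:
        for i in range(observed.size):
            # truncate by resampling so the observed burden stays in (0, 1)
            for _ in range(1_000):
                candidate = traj.P_series[i] + rng.normal(0.0, spec.noise_sd)
                if 0.0 < candidate < 1.0:
                    observed[i] = candidate
                    break
            else:  # pragma: no cover - needs pathological noise_sd
                raise DomainError(
                    "could not draw an observation inside (0, 1); noise_sd too large"
                )
    measurements = pd.DataFrame(
        {
            "patient_id": spec.patient_id,
            "visit_index": np.arange(spec.n_visits + 1),
            "P": observed,
        }
    )
    truth = pd.DataFrame(
        {
            "patient_id": spec.patient_id,
            "interval_index": np.arange(spec.n_visits),
            "r_true": schedule,
        }
    )
    return measurements, truth


@dataclass(frozen=True)
class CovariateFieldSpec:
    """Specification of spatially correlated covariate grids.

    Each covariate (I, L, S, B) is mean plus moving-average-filtered white
    noise: filtering white noise with a uniform kernel of half-width
    ``correlation_range`` induces positive correlation out to roughly that
    many lattice sites, then the field is rescaled to the requested noise
    standard deviation and clipped at zero.  ``hotspot`` optionally raises
    one covariate inside a rectangular patch, emulating a focal inflamed
    region: ``(covariate, row0, col0, height, width, elevation)``.
    """

    height: int = 12
    width: int = 12
    means: dict[str, float] = field(
        default_factory=lambda: {"I": 1.0, "L": 1.0, "S": 1.0, "B": 1.0}
    )
    noise_sd: float = 0.25
    correlation_range: int = 2
    hotspot: tuple[str, int, int, int, int, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise DomainError("grid dimensions must be >= 1")
        if self.noise_sd < 0.0 or self.correlation_range < 0:
            raise DomainError("noise_sd and correlation_range must be >= 0")
        for name in ("I", "L", "S", "B"):
            if name not in self.means:
                raise DomainError(f"missing mean for covariate {name!r}")


def generate_covariate_grid(spec: CovariateFieldSpec) -> dict[str, np.ndarray]:
    """Generate one (height, width) array per covariate, deterministically
    from the spec's seed."""
    rng = np.random.default_rng(spec.seed)
    grids: dict[str, np.ndarray] = {}
    for name in ("I", "L", "S", "B"):
        noise = rng.standard_normal((spec.height, spec.width))
        if spec.correlation_range > 0:
            size = 2 * spec.correlation_range + 1
            noise = ndimage.uniform_filter(noise, size=size, mode="nearest")
            sd = noise.std()
            if sd > 0.0:
                noise = noise / sd
        grids[name] = np.clip(spec.means[name] + spec.noise_sd * noise, 0.0, None)
    if spec.hotspot is not None:
        name, row0, col0, h, w, elevation = spec.hotspot
        if name not in grids:
            raise DomainError(f"hotspot covariate {name!r} unknown")
        if not (
            0 <= row0 <= row0 + h <= spec.height and 0 <= col0 <= col0 + w <= spec.width
        ):
            raise DomainError("hotspot rectangle exceeds the grid")
        grids[name][row0 : row0 + h, col0 : col0 + w] += elevation
    return grids
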