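"""Spatial Markov model on a flattened plaque-surface lattice.

Each lattice site carries the four stability covariates and a binary
stability state.  The per-site transition probability extends the aspatial
linear form with a neighbor-dependence term ``w5 * D_i``, where ``D_i`` is
the dependence-weighted fraction of unstable neighbors of site i.  The
pairwise influence strengths form a site-by-site dependence matrix built
from a distance kernel.

Two readings of the coupling between the dependence matrix and the
transition matrix are provided:

* the scalar pathway (default): the dependence matrix collapses, per site,
  to the scalar ``D_i`` entering the linear form — this is what the
  instability heatmaps use;
* the literal matrix pathway: a per-site 2x2 modifier block is combined with
  the transition matrix by an element-wise (Hadamard) product followed by
  row renormalization (:func:`hadamard_combine`), since the raw element-wise
  product of a probability matrix with an arbitrary non-negative modifier is
  no longer row-stochastic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigError, DegenerateModelError, DomainError
from .markov import (
    STABLE,
    UNSTABLE,
    ClampTracker,
    CovariateProfile,
    TransitionWeights,
    TwoStateMatrix,
    transition_probability,
)

__all__ = [
    "PlaqueSurfaceGrid",
    "DependenceMatrix",
    "build_dependence_matrix",
    "neighbor_term",
    "site_transition_probability",
    "site_modifier_block",
    "hadamard_combine",
    "instability_heatmap",
    "evolve",
]

COVARIATE_NAMES = ("I", "L", "S", "B")


@dataclass
class PlaqueSurfaceGrid:
    """A height x width lattice of plaque-surface sites.

    ``covariates`` maps each covariate name (I, L, S, B) to a (height, width)
    array; ``states`` is a (height, width) integer array with 0 = stable,
    1 = unstable.  Sites are indexed 0-based as (row, col) and serialized
    row-major (site = row * width + col).  The boundary is non-periodic by
    default: a surface patch has edges.
    """

    height: int
    width: int
    covariates: dict[str, np.ndarray]
    states: np.ndarray
    adjacency: str = "von_neumann"
    periodic: bool = False

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise DomainError("grid dimensions must be >= 1")
        if self.adjacency not in ("von_neumann", "moore"):
            raise ConfigError(f"unknown adjacency rule {self.adjacency!r}")
        shape = (self.height, self.width)
        for name in COVARIATE_NAMES:
            if name not in self.covariates:
                raise DomainError(f"missing covariate grid {name!r}")
            arr = np.asarray(self.covariates[name], dtype=float)
            if arr.shape != shape:
                raise DomainError(
                    f"covariate {name} has shape {arr.shape}, expected {shape}"
                )
            if np.any(~np.isfinite(arr)) or np.any(arr < 0.0):
                raise DomainError(f"covariate {name} must be finite and >= 0")
            self.covariates[name] = arr
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.shape != shape:
            raise DomainError(f"states has shape {self.states.shape}, expected {shape}")
        if not np.isin(self.states, (STABLE, UNSTABLE)).all():
            raise DomainError("states must be 0 (stable) or 1 (unstable)")

    @classmethod
    def homogeneous(
        cls,
        height: int,
        width: int,
        profile: CovariateProfile = CovariateProfile(),
        adjacency: str = "von_neumann",
        periodic: bool = False,
    ) -> "PlaqueSurfaceGrid":
        """Grid with identical covariates everywhere and all sites stable."""
        cov = {
            name: np.full((height, width), getattr(profile, name))
            for name in COVARIATE_NAMES
        }
        return cls(
            height,
            width,
            cov,
            np.zeros((height, width), dtype=np.int8),
            adjacency=adjacency,
            periodic=periodic,
        )

    @property
    def n_sites(self) -> int:
        return self.height * self.width

    def site_index(self, row: int, col: int) -> int:
        return row * self.width + col

    def site_coords(self, site: int) -> tuple[int, int]:
        return divmod(site, self.width)

    def profile_at(self, site: int) -> CovariateProfile:
        row, col = self.site_coords(site)
        return CovariateProfile(
            **{name: float(self.covariates[name][row, col]) for name in COVARIATE_NAMES}
        )

    def coordinates(self) -> np.ndarray:
        """(n_sites, 2) array of (row, col) coordinates in site order."""
        rows, cols = np.divmod(np.arange(self.n_sites), self.width)
        return np.column_stack([rows, cols])

    def flat_states(self) -> np.ndarray:
        return self.states.reshape(-1)

    def lattice_edges(self) -> list[tuple[int, int]]:
        """Undirected adjacency edges (each pair once) under the grid's
        neighborhood rule."""
        offsets = [(0, 1), (1, 0)]
        if self.adjacency == "moore":
            offsets += [(1, 1), (1, -1)]
        edges = []
        for row in range(self.height):
            for col in range(self.width):
                for dr, dc in offsets:
                    nr, nc = row + dr, col + dc
                    if self.periodic:
                        nr %= self.height
                        nc %= self.width
                    elif not (0 <= nr < self.height and 0 <= nc < self.width):
                        continue
                    i, j = self.site_index(row, col), self.site_index(nr, nc)
                    if i != j:
                        edges.append((min(i, j), max(i, j)))
        return sorted(set(edges))


@dataclass
class DependenceMatrix:
    """Site-by-site spatial dependence strengths.

    ``d[i, j] >= 0`` quantifies the influence of site j on site i; entries
    beyond the kernel range are zero and the diagonal is 1 by convention
    (a site fully "depends" on itself; the diagonal is excluded from
    neighbor averaging).
    """

    d: np.ndarray
    kernel_spec: str = ""

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.ndim != 2 or self.d.shape[0] != self.d.shape[1]:
            raise DomainError("dependence matrix must be square")
        if np.any(~np.isfinite(self.d)) or np.any(self.d < 0.0):
            raise DomainError("dependence entries must be finite and >= 0")


def build_dependence_matrix(
    grid: PlaqueSurfaceGrid,
    kernel: str = "uniform",
    range_param: float = 1.0,
    cutoff: float | None = None,
) -> DependenceMatrix:
    """Build the dependence matrix from a distance kernel on the lattice.

    ``uniform`` sets d_ij = 1 for 0 < distance <= range_param (so the default
    range 1 reproduces the 4-neighborhood); ``exponential`` sets
    d_ij = exp(-distance / range_param) within ``cutoff`` (default
    3 * range_param).  Distances are Euclidean in lattice units.  The
    diagonal is 1 by convention.
    """
    if not (range_param > 0.0):
        raise DomainError(f"range_param={range_param!r} must be positive")
    coords = grid.coordinates().astype(float)
    if grid.periodic:
        # shortest wrap-around displacement per axis
        delta = np.abs(coords[:, None, :] - coords[None, :, :])
        delta[..., 0] = np.minimum(delta[..., 0], grid.height - delta[..., 0])
        delta[..., 1] = np.minimum(delta[..., 1], grid.width - delta[..., 1])
        dist = np.sqrt((delta**2).sum(axis=-1))
    else:
        diff = coords[:, None, :] - coords[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=-1))
    if kernel == "uniform":
        reach = cutoff if cutoff is not None else range_param
        d = ((dist > 0.0) & (dist <= reach)).astype(float)
        spec = f"uniform(range={range_param})"
    elif kernel == "exponential":
        reach = cutoff if cutoff is not None else 3.0 * range_param
        d = np.where(
            (dist > 0.0) & (dist <= reach), np.exp(-dist / range_param), 0.0
        )
        spec = f"exponential(range={range_param}, cutoff={reach})"
    else:
        raise ConfigError(f"unknown dependence kernel {kernel!r}")
    np.fill_diagonal(d, 1.0)
    return DependenceMatrix(d=d, kernel_spec=spec)


def neighbor_term(
    grid: PlaqueSurfaceGrid, dep: DependenceMatrix, site: int
) -> float:
    """Dependence-weighted fraction of unstable neighbors of ``site``.

    Returns sum_j d_ij * 1[state_j = U] / sum_j d_ij over neighbors j != i
    with positive dependence, which lies in [0, 1]; an isolated site
    contributes 0.
    """
    if not (0 <= site < grid.n_sites):
        raise DomainError(f"site {site} outside grid with {grid.n_sites} sites")
    weights = dep.d[site].copy()
    weights[site] = 0.0
    total = weights.sum()
    if total == 0.0:
        return 0.0
    unstable = grid.flat_states() == UNSTABLE
    return float(weights[unstable].sum() / total)


def _neighbor_terms(grid: PlaqueSurfaceGrid, dep: DependenceMatrix) -> np.ndarray:
    """Vectorized neighbor term for every site."""
    w = dep.d.copy()
    np.fill_diagonal(w, 0.0)
    totals = w.sum(axis=1)
    unstable = (grid.flat_states() == UNSTABLE).astype(float)
    with np.errstate(invalid="ignore"):
        terms = np.where(totals > 0.0, w @ unstable / np.where(totals > 0, totals, 1), 0.0)
    return terms


def site_transition_probability(
    grid: PlaqueSurfaceGrid,
    dep: DependenceMatrix,
    w: TransitionWeights,
    site: int,
    link: str = "linear",
    tracker: ClampTracker | None = None,
) -> float:
    """P(S -> U) at one site, with the spatial term from its neighbors."""
    return transition_probability(
        grid.profile_at(site),
        w,
        D_term=neighbor_term(grid, dep, site),
        link=link,  # type: ignore[arg-type]
        tracker=tracker,
    )


def site_modifier_block(D_i: float, gain: float = 1.0) -> np.ndarray:
    """Literal-Hadamard pathway: the 2x2 modifier block for a site with
    neighbor term ``D_i``.

    The S -> U element is amplified by ``1 + gain * D_i`` while the other
    elements are left at 1, so that after renormalization an unstable
    neighborhood raises the site's destabilization probability.  (Scaling a
    whole row would be invisible to the renormalization.)
    """
    if not (0.0 <= D_i <= 1.0):
        raise DomainError(f"D_i={D_i!r} must lie in [0, 1]")
    if gain < 0.0:
        raise DomainError(f"gain={gain!r} must be >= 0")
    return np.array([[1.0, 1.0 + gain * D_i], [1.0, 1.0]])


def hadamard_combine(dep_block: np.ndarray, m: TwoStateMatrix) -> TwoStateMatrix:
    """Element-wise (Hadamard) product of a non-negative 2x2 modifier with a
    transition matrix, followed by row renormalization.

    The raw element-wise product is generally not row-stochastic, so each row
    is divided by its sum; a row whose product is identically zero leaves no
    probability to renormalize and raises a
    :class:`~plaquedyn.exceptions.DegenerateModelError`.
    """
    block = np.asarray(dep_block, dtype=float)
    if block.shape != (2, 2):
        raise DomainError(f"modifier block has shape {block.shape}, expected (2, 2)")
    if np.any(~np.isfinite(block)) or np.any(block < 0.0):
        raise DomainError("modifier entries must be finite and >= 0")
    product = block * m.matrix
    row_sums = product.sum(axis=1)
    if np.any(row_sums == 0.0):
        raise DegenerateModelError(
            "Hadamard product produced an all-zero row; no probability left to renormalize"
        )
    normalized = product / row_sums[:, None]
    return TwoStateMatrix(p_su=float(normalized[0, 1]), p_us=float(normalized[1, 0]))


def instability_heatmap(
    grid: PlaqueSurfaceGrid,
    dep: DependenceMatrix,
    w: TransitionWeights,
    link: str = "linear",
    tracker: ClampTracker | None = None,
) -> np.ndarray:
    """Per-site P(S -> U) over the whole lattice, as a (height, width) array
    of probabilities suitable for heatmap rendering."""
    terms = _neighbor_terms(grid, dep)
    field = np.empty(grid.n_sites)
    for site in range(grid.n_sites):
        field[site] = transition_probability(
            grid.profile_at(site),
            w,
            D_term=float(terms[site]),
            link=link,  # type: ignore[arg-type]
            tracker=tracker,
        )
    return field.reshape(grid.height, grid.width)


def evolve(
    grid: PlaqueSurfaceGrid,
    dep: DependenceMatrix,
    w: TransitionWeights,
    p_us: float,
    n_steps: int,
    seed: int,
    mode: str = "synchronous",
    link: str = "linear",
) -> list[np.ndarray]:
    """Evolve the lattice states over time under the spatial transition model.

    Stable sites destabilize with their spatial S -> U probability; unstable
    sites restabilize with the constant ``p_us``.  ``synchronous`` updates
    every site from the previous step's neighbor states; ``asynchronous``
    sweeps sites in raster order using the freshest states.  Returns the list
    of (height, width) state arrays including the initial one; the input grid
    is left with the final states.
    """
    if not (0.0 <= p_us <= 1.0):
        raise DomainError(f"p_us={p_us!r} must lie in [0, 1]")
    if mode not in ("synchronous", "asynchronous"):
        raise ConfigError(f"unknown update mode {mode!r}")
    if n_steps < 1:
        raise DomainError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    history = [grid.states.copy()]
    for _ in range(n_steps):
        u = rng.random(grid.n_sites)
        if mode == "synchronous":
            field = instability_heatmap(grid, dep, w, link=link).reshape(-1)
            old = grid.flat_states()
            new = old.copy()
            for site in range(grid.n_sites):
                if old[site] == STABLE:
                    if u[site] < field[site]:
                        new[site] = UNSTABLE
                elif u[site] < p_us:
                    new[site] = STABLE
            grid.states = new.reshape(grid.height, grid.width)
        else:
            for site in range(grid.n_sites):
                row, col = grid.site_coords(site)
                if grid.states[row, col] == STABLE:
                    p = site_transition_probability(grid, dep, w, site, link=link)
                    if u[site] < p:
                        grid.states[row, col] = UNSTABLE
                elif u[site] < p_us:
                    grid.states[row, col] = STABLE
        history.append(grid.states.copy())
    return history
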