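"""Markov random field over the plaque-surface lattice.

A binary stability state (0 = stable, 1 = unstable) at each lattice site,
with the Gibbs distribution

    P(config) ∝ exp(-beta * E(config)),
    E(config) = sum_i V_i(s_i) + sum_{(i,j) in edges} U(s_i, s_j),

where V is a per-site potential, U a symmetric pair potential over the
undirected lattice edges (each edge counted once), and beta an optional
inverse temperature (default 1).  The shipped default family is Ising-like:
V(s) = v_u * 1[s = U] (optionally plus a covariate-linear term so the field
nests the aspatial covariate model) and U(s, s') = -J * 1[s = s'] with
J >= 0, i.e. attractive coupling — neighboring sites prefer to share a
stability state.

Inference: exact enumeration of all 2^n configurations for small lattices
(n <= 20), and a seeded systematic-scan single-site Gibbs sampler for larger
ones.  Sites may be clamped to a fixed state; both the enumerator and the
sampler then condition on the clamped values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .exceptions import DomainError, ModelError
from .markov import STABLE, UNSTABLE
from .spatial import PlaqueSurfaceGrid

__all__ = [
    "MRFModel",
    "energy",
    "exact_distribution",
    "exact_marginals",
    "gibbs_sample",
    "marginal_instability",
]

MAX_EXACT_SITES = 20


@dataclass
class MRFModel:
    """A binary Markov random field on an explicit undirected graph.

    Parameters
    ----------
    n_sites : number of sites.
    V : (n_sites, 2) array of site potentials, ``V[i, s]`` the energy
        contribution of site i in state s.
    U : (2, 2) symmetric array of pair potentials over edges.
    edges : undirected edges, each pair listed once.
    beta_temp : inverse-temperature scaling of the energy in the exponent.
    clamped : optional mapping site -> state fixing those sites.
    shape : optional (height, width) for reshaping marginal fields.
    """

    n_sites: int
    V: np.ndarray
    U: np.ndarray
    edges: list[tuple[int, int]]
    beta_temp: float = 1.0
    clamped: dict[int, int] = field(default_factory=dict)
    shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise DomainError("n_sites must be >= 1")
        self.V = np.asarray(self.V, dtype=float)
        if self.V.shape != (self.n_sites, 2):
            raise DomainError(f"V has shape {self.V.shape}, expected ({self.n_sites}, 2)")
        self.U = np.asarray(self.U, dtype=float)
        if self.U.shape != (2, 2):
            raise DomainError("U must be a 2x2 pair-potential table")
        if not np.all(np.isfinite(self.V)) or not np.all(np.isfinite(self.U)):
            raise DomainError("potentials must be finite")
        if not np.allclose(self.U, self.U.T):
            raise ModelError("pair potential U must be symmetric on an undirected graph")
        seen = set()
        for i, j in self.edges:
            if not (0 <= i < self.n_sites and 0 <= j < self.n_sites) or i == j:
                raise DomainError(f"invalid edge ({i}, {j})")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise DomainError(f"edge ({i}, {j}) listed more than once")
            seen.add(key)
        if not (self.beta_temp > 0.0) or not math.isfinite(self.beta_temp):
            raise DomainError(f"beta_temp={self.beta_temp!r} must be positive")
        for site, state in self.clamped.items():
            if not (0 <= site < self.n_sites):
                raise DomainError(f"clamped site {site} outside the lattice")
            if state not in (STABLE, UNSTABLE):
                raise DomainError(f"clamped state {state!r} must be 0 or 1")
        if self.shape is not None and self.shape[0] * self.shape[1] != self.n_sites:
            raise DomainError("shape inconsistent with n_sites")

    # -- constructors -------------------------------------------------------

    @classmethod
    def ising(
        cls,
        height: int,
        width: int,
        v_u: float = 0.0,
        J: float = 0.0,
        beta_temp: float = 1.0,
        adjacency: str = "von_neumann",
        periodic: bool = False,
        clamped: Mapping[int, int] | None = None,
    ) -> "MRFModel":
        """Ising-family field on a lattice: V(U) = v_u, V(S) = 0 and
        U(s, s') = -J if s = s' else 0 (attractive for J > 0)."""
        if J < 0.0:
            raise DomainError(f"J={J!r} must be >= 0 (attractive coupling)")
        grid = PlaqueSurfaceGrid.homogeneous(
            height, width, adjacency=adjacency, periodic=periodic
        )
        n = grid.n_sites
        V = np.zeros((n, 2))
        V[:, UNSTABLE] = v_u
        U = np.array([[-J, 0.0], [0.0, -J]])
        return cls(
            n_sites=n,
            V=V,
            U=U,
            edges=grid.lattice_edges(),
            beta_temp=beta_temp,
            clamped=dict(clamped or {}),
            shape=(height, width),
        )

    @classmethod
    def from_grid(
        cls,
        grid: PlaqueSurfaceGrid,
        v_u: float = 0.0,
        J: float = 0.0,
        covariate_weights: Mapping[str, float] | None = None,
        beta_temp: float = 1.0,
        clamped: Mapping[int, int] | None = None,
    ) -> "MRFModel":
        """Ising-family field whose unstable-state site potential is lowered
        by a covariate-linear term, so high-risk covariates favor
        instability: V_i(U) = v_u - sum_k w_k * x_ik."""
        n = grid.n_sites
        V = np.zeros((n, 2))
        V[:, UNSTABLE] = v_u
        if covariate_weights:
            for name, weight in covariate_weights.items():
                if name not in grid.covariates:
                    raise DomainError(f"unknown covariate {name!r}")
                V[:, UNSTABLE] -= weight * grid.covariates[name].reshape(-1)
        U = np.array([[-J, 0.0], [0.0, -J]])
        return cls(
            n_sites=n,
            V=V,
            U=U,
            edges=grid.lattice_edges(),
            beta_temp=beta_temp,
            clamped=dict(clamped or {}),
            shape=(grid.height, grid.width),
        )

    def neighbor_lists(self) -> list[list[int]]:
        nbrs: list[list[int]] = [[] for _ in range(self.n_sites)]
        for i, j in self.edges:
            nbrs[i].append(j)
            nbrs[j].append(i)
        return nbrs


def energy(states: Sequence[int] | np.ndarray, m: MRFModel) -> float:
    """Total energy of a complete configuration: site terms plus one term per
    undirected edge."""
    s = np.asarray(states, dtype=int).reshape(-1)
    if s.size != m.n_sites:
        raise DomainError(f"configuration has {s.size} states, expected {m.n_sites}")
    if not np.isin(s, (STABLE, UNSTABLE)).all():
        raise DomainError("states must be 0 (stable) or 1 (unstable)")
    e = float(m.V[np.arange(m.n_sites), s].sum())
    for i, j in m.edges:
        e += m.U[s[i], s[j]]
    return e


def _all_configurations(m: MRFModel) -> np.ndarray:
    """(2^n_free, n_sites) array of all configurations honoring the clamps."""
    free = [i for i in range(m.n_sites) if i not in m.clamped]
    n_free = len(free)
    codes = np.arange(1 << n_free, dtype=np.int64)
    configs = np.zeros((codes.size, m.n_sites), dtype=np.int8)
    for bit, site in enumerate(free):
        configs[:, site] = (codes >> bit) & 1
    for site, state in m.clamped.items():
        configs[:, site] = state
    return configs


def exact_distribution(m: MRFModel) -> tuple[np.ndarray, np.ndarray]:
    """Exact Gibbs distribution by enumeration of all configurations.

    Returns ``(configs, probs)`` where ``configs`` is a
    (n_configs, n_sites) state array and ``probs`` the corresponding
    probabilities (summing to 1).  Refuses lattices with more than 20 free
    sites; use :func:`gibbs_sample` there.
    """
    n_free = m.n_sites - len(m.clamped)
    if n_free > MAX_EXACT_SITES:
        raise ModelError(
            f"exact enumeration limited to {MAX_EXACT_SITES} free sites "
            f"(got {n_free}); use gibbs_sample instead"
        )
    configs = _all_configurations(m)
    energies = configs @ (m.V[:, 1] - m.V[:, 0]) + m.V[:, 0].sum()
    for i, j in m.edges:
        energies = energies + m.U[configs[:, i], configs[:, j]]
    # subtract the max of -beta*E before exponentiating for stability
    logw = -m.beta_temp * energies
    logw -= logw.max()
    w = np.exp(logw)
    return configs, w / w.sum()


def exact_marginals(m: MRFModel) -> np.ndarray:
    """Per-site P(state = unstable) under the exact Gibbs distribution."""
    configs, probs = exact_distribution(m)
    return probs @ configs


def gibbs_sample(
    m: MRFModel,
    n_sweeps: int,
    burn_in: int = 1_000,
    seed: int = 0,
    thin: int = 1,
    init: Sequence[int] | np.ndarray | None = None,
) -> np.ndarray:
    """Systematic-scan single-site Gibbs sampler for the field.

    Sites are resampled in fixed raster order; the conditional at site i
    depends only on V_i and the pair potentials with its neighbors.  Runs
    ``burn_in`` discarded sweeps then keeps one configuration every ``thin``
    sweeps until ``n_sweeps`` samples are collected.  Fully reproducible
    given ``seed``.  Returns an (n_sweeps, n_sites) int8 array.
    """
    if n_sweeps < 1:
        raise DomainError("n_sweeps must be >= 1")
    if burn_in < 0 or thin < 1:
        raise DomainError("burn_in must be >= 0 and thin >= 1")
    rng = np.random.default_rng(seed)
    n = m.n_sites
    if init is None:
        states = rng.integers(0, 2, size=n).tolist()
    else:
        states = [int(s) for s in np.asarray(init).reshape(-1)]
        if len(states) != n:
            raise DomainError("init must assign a state to every site")
    for site, state in m.clamped.items():
        states[site] = state

    beta = m.beta_temp
    dV = (beta * (m.V[:, 1] - m.V[:, 0])).tolist()
    # dU[s] = beta * (U[1, s] - U[0, s]): energy change of flipping the focal
    # site to unstable, per neighbor in state s
    dU = (beta * (m.U[1, 0] - m.U[0, 0]), beta * (m.U[1, 1] - m.U[0, 1]))
    nbrs = m.neighbor_lists()
    free_sites = [i for i in range(n) if i not in m.clamped]
    exp = math.exp

    total_sweeps = burn_in + n_sweeps * thin
    uniforms = rng.random((total_sweeps, len(free_sites)))
    samples = np.empty((n_sweeps, n), dtype=np.int8)
    kept = 0
    for sweep in range(total_sweeps):
        u_row = uniforms[sweep]
        for k, i in enumerate(free_sites):
            h = dV[i]
            for j in nbrs[i]:
                h += dU[states[j]]
            if h > 35.0:
                p1 = 0.0
            elif h < -35.0:
                p1 = 1.0
            else:
                p1 = 1.0 / (1.0 + exp(h))
            states[i] = 1 if u_row[k] < p1 else 0
        if sweep >= burn_in and (sweep - burn_in) % thin == 0:
            samples[kept] = states
            kept += 1
    return samples[:kept]


def marginal_instability(
    m: MRFModel,
    method: Literal["exact", "gibbs"] = "exact",
    n_sweeps: int = 5_000,
    burn_in: int = 1_000,
    seed: int = 0,
) -> np.ndarray:
    """Per-site probability of the unstable state under the Gibbs
    distribution, by exact enumeration or Gibbs sampling.

    Returns a (height, width) field when the model carries a lattice shape,
    else a flat (n_sites,) vector; renderable with the same heatmap
    interface as the spatial Markov model.
    """
    if method == "exact":
        marg = exact_marginals(m)
    elif method == "gibbs":
        samples = gibbs_sample(m, n_sweeps=n_sweeps, burn_in=burn_in, seed=seed)
        marg = samples.mean(axis=0)
    else:
        raise DomainError(f"unknown method {method!r}")
    if m.shape is not None:
        return marg.reshape(m.shape)
    return marg
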