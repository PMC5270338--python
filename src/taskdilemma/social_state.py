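"""Interaction network, reputation/reciprocity dynamics, and marginal gain.

Individuals 1..n communicate over an undirected graph.  Each individual i
keeps a *relative reputation* ``r_ij`` of every neighbour j, updated by
exponential smoothing with forgetting,

    r_ij(t+1) = (1 - tau_ij) r_ij(t) + tau_ij * (p_j(t) / P) * r_bar,

so ``r_ij`` tracks ``r_bar * p_j / P`` at rate ``tau_ij``.  Reciprocity is
the weighted neighbourhood sum ``r_i = sum_j delta_ij r_ij`` and enters the
individual's effective motivation ``b_i = gamma_i + r_i``.  With linear
participation costs ``c_i p_i`` the marginal gain is

    g_i(p_i) = b_i - c_i p_i   if b_i >= c_i P   (eligible),
    g_i(p_i) = 0               otherwise,

the gate ensuring that only individuals whose gain is positive over the whole
load range [0, P] take part in the load-passing process.  The gate is
non-strict at the boundary ``b_i = c_i P`` so that boundary-motivated
individuals participate (their gain reaches zero only at full load).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .production import as_load_vector

__all__ = [
    "NetworkTopology",
    "ReputationState",
    "GainModel",
    "line_topology",
    "complete_topology",
    "from_edge_list",
    "from_edge_list_file",
    "is_connected",
]


# ----------------------------------------------------------------------
# network topology
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkTopology:
    """Undirected interaction network on 1-based node labels 1..n."""

    n: int
    edges: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        seen: set[tuple[int, int]] = set()
        canonical: list[tuple[int, int]] = []
        for i, j in self.edges:
            i, j = int(i), int(j)
            if i == j:
                raise ValueError(f"self-loop on node {i} is not allowed")
            if not (1 <= i <= self.n and 1 <= j <= self.n):
                raise ValueError(f"edge ({i}, {j}) is outside node range 1..{self.n}")
            key = (min(i, j), max(i, j))
            if key not in seen:
                seen.add(key)
                canonical.append(key)
        canonical.sort()
        object.__setattr__(self, "edges", tuple(canonical))
        adj = np.zeros((self.n, self.n), dtype=bool)
        for i, j in canonical:
            adj[i - 1, j - 1] = True
            adj[j - 1, i - 1] = True
        adj.setflags(write=False)
        object.__setattr__(self, "_adj", adj)

    @property
    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(1, self.n + 1))
        g.add_edges_from(self.edges)
        return g

    def adjacency_matrix(self) -> np.ndarray:
        """Boolean (n, n) adjacency; row/column k corresponds to label k+1."""
        return self._adj  # type: ignore[attr-defined]

    def neighbors(self, i: int) -> tuple[int, ...]:
        if not 1 <= i <= self.n:
            raise ValueError(f"node label must be in 1..{self.n}, got {i}")
        row = self.adjacency_matrix()[i - 1]
        return tuple(int(k) + 1 for k in np.where(row)[0])

    def degree(self, i: int) -> int:
        return len(self.neighbors(i))


def line_topology(n: int) -> NetworkTopology:
    """Path 1-2-...-n (no edges when n == 1)."""
    return NetworkTopology(n, tuple((i, i + 1) for i in range(1, n)))


def complete_topology(n: int) -> NetworkTopology:
    """All n(n-1)/2 edges."""
    return NetworkTopology(
        n, tuple((i, j) for i in range(1, n + 1) for j in range(i + 1, n + 1))
    )


def from_edge_list(pairs: Iterable[tuple[int, int]], n: int | None = None) -> NetworkTopology:
    """Build a topology from 1-based edge pairs; duplicate reverses are ignored."""
    pairs = [(int(i), int(j)) for i, j in pairs]
    if n is None:
        if not pairs:
            raise ValueError("cannot infer n from an empty edge list; pass n explicitly")
        n = max(max(i, j) for i, j in pairs)
    return NetworkTopology(n, tuple(pairs))


def from_edge_list_file(path: str | Path, n: int | None = None) -> NetworkTopology:
    """Read a two-column whitespace- or comma-separated edge-list text file."""
    pairs: list[tuple[int, int]] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected two node labels, got {raw!r}")
        pairs.append((int(parts[0]), int(parts[1])))
    return from_edge_list(pairs, n=n)


def is_connected(topology: NetworkTopology) -> bool:
    """True iff there is a path between every pair of nodes."""
    return bool(nx.is_connected(topology.graph))


# ----------------------------------------------------------------------
# relative reputation and reciprocity
# ----------------------------------------------------------------------

def delta_matrix(topology: NetworkTopology, delta="uniform") -> np.ndarray:
    """Reciprocity weights ``delta_ij`` on edges.

    ``"uniform"`` sets ``delta_ij = 1/|N_i|`` (each neighbour contributes
    equally and reciprocity stays bounded by ``r_bar`` regardless of degree);
    ``"unit"`` sets ``delta_ij = 1``; a matrix is validated entrywise.
    """
    adj = topology.adjacency_matrix()
    if isinstance(delta, str):
        if delta == "unit":
            return adj.astype(float)
        if delta == "uniform":
            deg = adj.sum(axis=1, dtype=float)
            with np.errstate(divide="ignore"):
                inv = np.where(deg > 0, 1.0 / np.maximum(deg, 1.0), 0.0)
            return adj * inv[:, None]
        raise ValueError(f"delta must be 'uniform', 'unit', or a matrix, got {delta!r}")
    mat = np.asarray(delta, dtype=float)
    if mat.shape != adj.shape:
        raise ValueError(f"delta matrix must have shape {adj.shape}, got {mat.shape}")
    if np.any((mat < 0) | (mat > 1)):
        raise ValueError("delta entries must lie in [0, 1]")
    return np.where(adj, mat, 0.0)


def pair_rate_matrix(topology: NetworkTopology, tau) -> np.ndarray:
    """Reputation rates ``tau_ij in [0, 1]`` on edges (scalar broadcast or matrix)."""
    adj = topology.adjacency_matrix()
    mat = np.asarray(tau, dtype=float)
    if mat.ndim == 0:
        mat = np.full(adj.shape, float(mat))
    if mat.shape != adj.shape:
        raise ValueError(f"tau must be a scalar or a matrix of shape {adj.shape}")
    if np.any((mat[adj] < 0) | (mat[adj] > 1)):
        raise ValueError("tau entries must lie in [0, 1]")
    return np.where(adj, mat, 0.0)


def reputation_update(
    r: np.ndarray, taus: np.ndarray, mask: np.ndarray, p: np.ndarray, P: float, r_bar: float
) -> np.ndarray:
    """One smoothing step of the relative-reputation matrix (edges only)."""
    if P <= 0:
        raise ValueError("P must be > 0")
    # conservation arithmetic can leave p_j a few ulp past P; only reject
    # genuine violations and clip the ratio to its mathematical range
    if np.any(p < 0) or np.any(p > P * (1.0 + 1e-9)):
        raise ValueError("every p_j must lie in [0, P]")
    ratio = np.minimum(p / P, 1.0)
    new = (1.0 - taus) * r + taus * ratio[None, :] * r_bar
    # the update is a convex combination of points in [0, r_bar]; clipping
    # removes at most one ulp of rounding so the invariant holds exactly
    return np.where(mask, np.clip(new, 0.0, r_bar), 0.0)


@dataclass(frozen=True)
class ReputationState:
    """Relative reputations ``r_ij`` (of j from i's viewpoint) on network edges.

    Stored as an (n, n) matrix with zeros off-edge; ``r[i-1, j-1]`` is
    individual i's view of neighbour j.  Both ordered directions of every
    undirected edge carry their own value.
    """

    topology: NetworkTopology
    r: np.ndarray
    taus: np.ndarray
    deltas: np.ndarray
    r_bar: float

    def __post_init__(self) -> None:
        adj = self.topology.adjacency_matrix()
        if self.r_bar < 0 or not np.isfinite(self.r_bar):
            raise ValueError("r_bar must be finite and >= 0")
        r = np.asarray(self.r, dtype=float)
        if r.shape != adj.shape:
            raise ValueError(f"reputation matrix must have shape {adj.shape}")
        if np.any(r[~adj] != 0):
            raise ValueError("reputation is defined only on network edges")
        if np.any((r < 0) | (r > self.r_bar)):
            raise ValueError("every r_ij must lie in [0, r_bar]")
        for name, mat in (("taus", self.taus), ("deltas", self.deltas)):
            m = np.asarray(mat, dtype=float)
            if m.shape != adj.shape:
                raise ValueError(f"{name} must have shape {adj.shape}")
        for mat in (r, np.asarray(self.taus, float), np.asarray(self.deltas, float)):
            mat.setflags(write=False)
        object.__setattr__(self, "r", r)

    @classmethod
    def build(
        cls,
        topology: NetworkTopology,
        tau=0.5,
        delta="uniform",
        r_bar: float = 1.0,
        r0=0.0,
    ) -> "ReputationState":
        adj = topology.adjacency_matrix()
        r = np.asarray(r0, dtype=float)
        if r.ndim == 0:
            r = np.where(adj, float(r), 0.0)
        return cls(
            topology=topology,
            r=np.where(adj, r, 0.0),
            taus=pair_rate_matrix(topology, tau),
            deltas=delta_matrix(topology, delta),
            r_bar=float(r_bar),
        )

    def updated(self, p, P: float) -> "ReputationState":
        """Apply one reputation-smoothing step driven by the load vector ``p``."""
        p = as_load_vector(p, self.topology.n, "p")
        new_r = reputation_update(
            self.r, self.taus, self.topology.adjacency_matrix(), p, P, self.r_bar
        )
        return ReputationState(self.topology, new_r, self.taus, self.deltas, self.r_bar)

    def reciprocity(self, i: int) -> float:
        """``r_i = sum_{j in N_i} delta_ij r_ij`` for 1-based label ``i``."""
        if not 1 <= i <= self.topology.n:
            raise ValueError(f"node label must be in 1..{self.topology.n}, got {i}")
        return float(np.sum(self.deltas[i - 1] * self.r[i - 1]))

    def reciprocity_vector(self) -> np.ndarray:
        return (self.deltas * self.r).sum(axis=1)


# ----------------------------------------------------------------------
# motivation, costs, marginal gain, utility
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class GainModel:
    """Constant motivations ``gamma_i``, linear cost slopes ``c_i``, budget ``P``."""

    gammas: np.ndarray
    costs: np.ndarray
    P: float

    def __post_init__(self) -> None:
        gammas = as_load_vector(self.gammas, name="gammas")
        costs = as_load_vector(self.costs, n=gammas.shape[0], name="costs")
        if not np.all(np.isfinite(gammas)) or np.any(gammas < 0):
            raise ValueError("every gamma_i must be finite and >= 0")
        if not np.all(np.isfinite(costs)) or np.any(costs < 0):
            raise ValueError("every c_i must be finite and >= 0")
        if not (self.P > 0 and np.isfinite(self.P)):
            raise ValueError("P must be finite and > 0")
        gammas.setflags(write=False)
        costs.setflags(write=False)
        object.__setattr__(self, "gammas", gammas)
        object.__setattr__(self, "costs", costs)

    @property
    def n(self) -> int:
        return self.gammas.shape[0]

    def effective_motivation(self, reciprocity) -> np.ndarray:
        """``b_i = gamma_i + r_i``."""
        r = as_load_vector(reciprocity, self.n, "reciprocity")
        return self.gammas + r

    def eligibility(self, b) -> np.ndarray:
        """Non-strict gate: eligible iff ``b_i >= c_i P``."""
        b = as_load_vector(b, self.n, "b")
        return b >= self.costs * self.P

    def marginal_gain(self, reciprocity_i: float, i: int, p_i: float) -> float:
        """Gated marginal gain of 1-based individual ``i`` at load ``p_i``."""
        if not 1 <= i <= self.n:
            raise ValueError(f"individual label must be in 1..{self.n}, got {i}")
        if not 0.0 <= p_i <= self.P:
            raise ValueError(f"p_i must lie in [0, P] = [0, {self.P}], got {p_i}")
        b = float(self.gammas[i - 1]) + float(reciprocity_i)
        c = float(self.costs[i - 1])
        if b >= c * self.P:
            return b - c * p_i
        return 0.0

    def gain_vector(self, b, p) -> np.ndarray:
        """Vectorized gated gains for effective motivations ``b`` and loads ``p``."""
        b = as_load_vector(b, self.n, "b")
        p = as_load_vector(p, self.n, "p")
        return np.where(self.eligibility(b), b - self.costs * p, 0.0)

    def utility(self, b, p) -> float:
        """Community satisfaction ``U(p) = sum_i (b_i p_i - c_i p_i**2 / 2)``.

        The integrals of a constant motivation and a linear marginal cost;
        additive over individuals and strictly concave wherever ``c_i > 0``.
        """
        b = as_load_vector(b, self.n, "b")
        p = as_load_vector(p, self.n, "p")
        if np.any(p < 0):
            raise ValueError("participation loads must be non-negative")
        return float(np.sum(b * p - 0.5 * self.costs * p * p))
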