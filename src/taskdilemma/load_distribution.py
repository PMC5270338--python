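"""Decentralized participation-load passing.

Each round, every individual i looks at its neighbours' marginal gains and
passes load to the neighbours in

    S_i = { j in N_i : g_j > g_i  and  g_j = max_{l in N_i} g_l },

i.e. the strictly-better neighbours that are tied for the largest gain in
i's neighbourhood.  The donor budget ``p_i`` is split equally among the tied
targets, and each pairwise transfer is capped three ways:

    L = min( p_i / |S_i|,                 # cannot pass more than held
             (g_j - g_i) / (c_i + c_j),   # never overshoot the pairwise
                                          #   equal-gain point
             theta * (g_j - g_i) / c_j )  # theta-rate step: the receiver's
                                          #   gain drops by exactly a
                                          #   fraction theta of the gap

for linear gains with slopes ``c_i`` (ineligible donors have slope 0 and a
constant gain of 0, so they shed load at the theta rate but are never
selected as targets).  All plans in a round are computed from the same state
and applied synchronously, which conserves the total load exactly.

A *reservoir* holds the portion of the budget ``P`` not yet allocated to any
individual (scenarios start from ``p = 0``).  It behaves as a virtual
participant with constant gain 0 and slope 0, adjacent to everyone: each
individual with positive gain draws ``min(reservoir/k, theta * g_i / c_i)``
per round, and the reservoir never pulls load back.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import optimize

from .production import as_load_vector
from .social_state import NetworkTopology

__all__ = [
    "PassingPlan",
    "BalanceResult",
    "ContractViolationError",
    "select_targets",
    "compute_passes",
    "apply_passes",
    "reservoir_exchange",
    "balance_loads",
]

#: transfers below this are zeroed to avoid denormal churn
TRANSFER_GUARD = 1e-15


class ContractViolationError(ValueError):
    """A gain function violated the decreasing-in-own-load contract."""


@dataclass(frozen=True)
class PassingPlan:
    """Synchronous per-edge transfers for one round.

    ``transfers[i, j]`` (0-based) is the load individual ``i+1`` passes to
    ``j+1``; :meth:`as_dict` exposes the 1-based ``(receiver, donor)``
    mapping.
    """

    transfers: np.ndarray
    theta: float

    def __post_init__(self) -> None:
        t = np.asarray(self.transfers, dtype=float)
        if t.ndim != 2 or t.shape[0] != t.shape[1]:
            raise ValueError("transfers must be a square matrix")
        if not np.all(np.isfinite(t)) or np.any(t < 0):
            raise ValueError("transfer amounts must be finite and >= 0")
        if not (0.0 < self.theta <= 1.0):
            raise ValueError("theta must lie in (0, 1]")
        t.setflags(write=False)
        object.__setattr__(self, "transfers", t)

    @property
    def n(self) -> int:
        return self.transfers.shape[0]

    def total(self) -> float:
        return float(self.transfers.sum())

    def is_empty(self) -> bool:
        return bool(np.all(self.transfers == 0))

    def as_dict(self) -> dict[tuple[int, int], float]:
        """``{(j, i): L_ji}`` with 1-based labels — load moving from i to j."""
        out: dict[tuple[int, int], float] = {}
        for i, j in zip(*np.nonzero(self.transfers)):
            out[(int(j) + 1, int(i) + 1)] = float(self.transfers[i, j])
        return out


def select_targets(i: int, topology: NetworkTopology, gains) -> frozenset[int]:
    """Targets of 1-based donor ``i``: strictly-better neighbours tied at the max."""
    g = as_load_vector(gains, topology.n, "gains")
    if not 1 <= i <= topology.n:
        raise ValueError(f"node label must be in 1..{topology.n}, got {i}")
    nbrs = topology.neighbors(i)
    if not nbrs:
        return frozenset()
    best = max(g[j - 1] for j in nbrs)
    if best <= g[i - 1]:
        return frozenset()
    return frozenset(j for j in nbrs if g[j - 1] == best)


def _pairwise_caps_linear(
    g: np.ndarray, slopes: np.ndarray, theta: float
) -> tuple[np.ndarray, np.ndarray]:
    diff = g[None, :] - g[:, None]  # gap g_j - g_i, donor i rows
    with np.errstate(divide="ignore", invalid="ignore"):
        denom_eq = slopes[:, None] + slopes[None, :]
        l_eq = np.where(denom_eq > 0, diff / np.where(denom_eq > 0, denom_eq, 1.0), np.inf)
        l_th = np.where(slopes[None, :] > 0,
                        theta * diff / np.where(slopes[None, :] > 0, slopes[None, :], 1.0),
                        np.inf)
    return l_eq, l_th


def _pairwise_caps_bisect(
    p: np.ndarray,
    g: np.ndarray,
    gain_fns: Sequence[Callable[[float], float]],
    theta: float,
    i: int,
    j: int,
) -> tuple[float, float]:
    """Equalization and theta-rate caps for one donor/target pair, for
    arbitrary decreasing gain functions, by root bracketing to 1e-12."""
    gi, gj = g[i], g[j]
    fi, fj = gain_fns[i], gain_fns[j]
    upper = p[i]
    if upper <= 0:
        return 0.0, 0.0

    def eq_resid(L: float) -> float:
        return fj(p[j] + L) - fi(p[i] - L)

    if eq_resid(upper) > 0:
        l_eq = upper
    else:
        l_eq = float(optimize.brentq(eq_resid, 0.0, upper, xtol=1e-12, rtol=1e-15))

    target = gj - theta * (gj - gi)

    def th_resid(L: float) -> float:
        return fj(p[j] + L) - target

    hi = min(l_eq, upper)
    if hi <= 0:
        return l_eq, 0.0
    if th_resid(hi) > 0:
        l_th = hi
    else:
        l_th = float(optimize.brentq(th_resid, 0.0, hi, xtol=1e-12, rtol=1e-15))
    return l_eq, l_th


def compute_passes(
    p,
    gains,
    gain_slopes,
    topology: NetworkTopology,
    theta: float,
    gain_fns: Sequence[Callable[[float], float]] | None = None,
) -> PassingPlan:
    """One synchronous round of transfer amounts from the current state.

    ``gain_slopes`` are the (non-negative) decrease rates of each gain in its
    own load; pass 0 for gated individuals whose gain is identically zero.
    For non-linear gains supply ``gain_fns`` (one decreasing callable per
    individual) and the two caps are found by bisection instead of closed
    form.
    """
    n = topology.n
    p = as_load_vector(p, n, "p")
    g = as_load_vector(gains, n, "gains")
    slopes = as_load_vector(gain_slopes, n, "gain_slopes")
    if np.any(p < 0):
        raise ValueError("participation loads must be non-negative")
    if not (0.0 < theta <= 1.0):
        raise ValueError("theta must lie in (0, 1]")
    if np.any(slopes < 0):
        raise ContractViolationError("gain functions must be non-increasing in own load")

    adj = topology.adjacency_matrix()
    neigh_gain = np.where(adj, g[None, :], -np.inf)
    best = neigh_gain.max(axis=1)
    smask = adj & (g[None, :] == best[:, None]) & (best[:, None] > g[:, None])

    # every selected target has g_j > g_i >= 0, hence must have a strictly
    # decreasing gain (slope > 0) or transfers could never lower it
    target_cols = smask.any(axis=0)
    if gain_fns is None and np.any(target_cols & (slopes == 0)):
        raise ContractViolationError(
            "a selected target has zero gain slope; its gain cannot be equalized"
        )

    counts = smask.sum(axis=1)
    share = np.zeros(n)
    donors = counts > 0
    share[donors] = p[donors] / counts[donors]

    if gain_fns is None:
        l_eq, l_th = _pairwise_caps_linear(g, slopes, theta)
        transfers = np.where(smask, np.minimum(share[:, None], np.minimum(l_eq, l_th)), 0.0)
    else:
        if len(gain_fns) != n:
            raise ValueError(f"gain_fns must have length {n}")
        for k in range(n):
            probe = min(p[k] + 0.125, p[k] * 1.5 + 0.125)
            if gain_fns[k](probe) > gain_fns[k](p[k]) + 1e-12:
                raise ContractViolationError(
                    f"gain function of individual {k + 1} is increasing in its own load"
                )
        transfers = np.zeros((n, n))
        for i, j in zip(*np.nonzero(smask)):
            le, lt = _pairwise_caps_bisect(p, g, gain_fns, theta, int(i), int(j))
            transfers[i, j] = min(share[i], le, lt)

    transfers[transfers < TRANSFER_GUARD] = 0.0
    return PassingPlan(transfers=transfers, theta=theta)


def apply_passes(p, plan: PassingPlan) -> np.ndarray:
    """Apply a plan synchronously; total load is conserved exactly."""
    p = as_load_vector(p, plan.n, "p")
    out = plan.transfers.sum(axis=1)
    if np.any(out > p + 1e-9):
        raise ValueError("plan violates the donor-budget constraint sum_j L_ji <= p_i")
    new_p = p - out + plan.transfers.sum(axis=0)
    # equal-split rounding can leave a donor a few ulp below zero
    tiny_neg = (new_p < 0) & (new_p > -1e-12)
    new_p[tiny_neg] = 0.0
    if np.any(new_p < 0):
        raise ValueError("plan would drive a participation load negative")
    return new_p


def reservoir_exchange(
    p, reservoir: float, gains, gain_slopes, theta: float
) -> tuple[np.ndarray, float]:
    """Let positive-gain individuals draw unallocated load from the reservoir.

    The reservoir is a virtual neighbour of everyone with constant gain 0, so
    each drawer's caps reduce to ``L_eq = g_i / c_i`` and ``L_theta = theta *
    g_i / c_i``; the reservoir's stock is split equally among drawers.  Total
    ``sum(p) + reservoir`` is conserved exactly.
    """
    p = as_load_vector(p, name="p").copy()
    g = as_load_vector(gains, p.shape[0], "gains")
    slopes = as_load_vector(gain_slopes, p.shape[0], "gain_slopes")
    if not (0.0 < theta <= 1.0):
        raise ValueError("theta must lie in (0, 1]")
    if reservoir < 0:
        raise ValueError("reservoir must be >= 0")
    if reservoir == 0.0:
        return p, 0.0
    drawers = (g > 0) & (slopes > 0)
    k = int(drawers.sum())
    if k == 0:
        return p, float(reservoir)
    share = reservoir / k
    with np.errstate(divide="ignore", invalid="ignore"):
        rate_cap = np.where(drawers, theta * g / np.where(slopes > 0, slopes, 1.0), 0.0)
    draw = np.where(drawers, np.minimum(share, rate_cap), 0.0)
    draw[draw < TRANSFER_GUARD] = 0.0
    total = float(draw.sum())
    if total > reservoir:
        draw *= reservoir / total
        total = float(draw.sum())
    return p + draw, max(float(reservoir) - total, 0.0)


@dataclass(frozen=True)
class BalanceResult:
    """Fixed point of repeated passing rounds (no task/reputation coupling)."""

    p: np.ndarray
    rounds: int
    converged: bool
    gap_history: np.ndarray


def balance_loads(
    p0,
    b,
    c,
    P: float,
    topology: NetworkTopology,
    theta: float,
    max_rounds: int = 200_000,
    tol: float = 1e-10,
) -> BalanceResult:
    """Iterate passing rounds with fixed effective motivations ``b`` until the
    total movement per round falls below ``tol``.

    Gains are the gated linear family ``g_i = b_i - c_i p_i`` if
    ``b_i >= c_i P`` else 0; the gate is applied once (``b`` is constant
    here).  Tracks the max-minus-min gain gap over eligible individuals per
    round for convergence-rate analysis.
    """
    p = as_load_vector(p0, topology.n, "p0").copy()
    b = as_load_vector(b, topology.n, "b")
    c = as_load_vector(c, topology.n, "c")
    eligible = b >= c * P
    slopes = np.where(eligible, c, 0.0)
    gaps: list[float] = []
    converged = False
    rounds = 0
    for rounds in range(1, max_rounds + 1):
        g = np.where(eligible, b - c * p, 0.0)
        if eligible.any():
            ge = g[eligible]
            gaps.append(float(ge.max() - ge.min()))
        plan = compute_passes(p, g, slopes, topology, theta)
        p = apply_passes(p, plan)
        if plan.total() <= tol:
            converged = True
            break
    return BalanceResult(p=p, rounds=rounds, converged=converged, gap_history=np.asarray(gaps))
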