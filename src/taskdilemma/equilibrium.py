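"""KKT water-filling optimum of the community satisfaction function.

Maximizing the separable concave utility

    U(p) = sum_i (b_i p_i - c_i p_i**2 / 2)
    s.t.  sum_i p_i <= P,   p_i >= 0,

yields the water-filling structure: all individuals with positive optimal
load share one marginal gain ``g_i(p_i*) = b_i - c_i p_i* = mu*`` (the budget
multiplier), and inactive individuals carry a non-negativity multiplier
``lambda_i* = mu* - b_i``.  The active set is found by the standard
deactivation iteration; a simplex grid search provides an independent
brute-force oracle for small n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .production import as_load_vector

__all__ = [
    "EquilibriumSolution",
    "UnboundedGainError",
    "water_filling",
    "brute_force_optimum",
    "kkt_residuals",
]


class UnboundedGainError(ValueError):
    """A non-positive cost slope makes the utility unbounded on the simplex."""


@dataclass(frozen=True)
class EquilibriumSolution:
    """KKT point: optimal loads, budget multiplier, bound multipliers, common gain."""

    p_star: np.ndarray
    mu_star: float
    lambda_star: np.ndarray
    g_star: float


def water_filling(b, c, P: float) -> EquilibriumSolution:
    """Exact KKT point of the budgeted concave allocation problem.

    Starts with everyone active, computes the candidate multiplier

        mu = (sum_active b_i / c_i - P) / (sum_active 1 / c_i),

    drops any individual whose implied load ``(b_i - mu) / c_i`` is negative,
    and repeats until stable (at most n passes).
    """
    b = as_load_vector(b, name="b")
    c = as_load_vector(c, b.shape[0], "c")
    n = b.shape[0]
    if n == 0:
        raise ValueError("at least one individual is required")
    if not (P > 0 and np.isfinite(P)):
        raise ValueError("P must be finite and > 0")
    if np.any(c <= 0):
        raise UnboundedGainError("every active cost slope c_i must be > 0")

    active = np.ones(n, dtype=bool)
    mu = 0.0
    p = np.zeros(n)
    for _ in range(n + 1):
        mu = (np.sum(b[active] / c[active]) - P) / np.sum(1.0 / c[active])
        p = np.where(active, (b - mu) / c, 0.0)
        negative = active & (p < -1e-15)
        if not negative.any():
            break
        active &= ~negative
    p = np.clip(p, 0.0, None)
    lam = np.where(active, 0.0, mu - b)
    lam = np.clip(lam, 0.0, None)
    return EquilibriumSolution(p_star=p, mu_star=float(mu), lambda_star=lam, g_star=float(mu))


def _simplex_grid(n: int, k: int) -> np.ndarray:
    """All non-negative integer compositions of k into n parts, shape (m, n)."""
    if n == 1:
        return np.array([[k]])
    rows = []
    for first in range(k + 1):
        rest = _simplex_grid(n - 1, k - first)
        rows.append(np.column_stack([np.full(rest.shape[0], first), rest]))
    return np.vstack(rows)


def brute_force_optimum(b, c, P: float, resolution: float) -> np.ndarray:
    """Grid search over ``sum(p) = P`` maximizing U; oracle for :func:`water_filling`.

    By concavity the returned point is within one grid step of the true
    optimum in every coordinate.  Refuses n > 4 (combinatorial blow-up).
    """
    b = as_load_vector(b, name="b")
    c = as_load_vector(c, b.shape[0], "c")
    n = b.shape[0]
    if n > 4:
        raise ValueError("brute-force search is limited to n <= 4")
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    k = max(1, round(P / resolution))
    grid = _simplex_grid(n, k) * (P / k)
    utilities = grid @ b - 0.5 * (grid * grid) @ c
    return grid[int(np.argmax(utilities))]


def kkt_residuals(sol: EquilibriumSolution, b, c, P: float) -> dict[str, float]:
    """Residuals of the four KKT conditions at a candidate solution."""
    b = as_load_vector(b, name="b")
    c = as_load_vector(c, b.shape[0], "c")
    p, mu, lam = sol.p_star, sol.mu_star, sol.lambda_star
    gains = b - c * p
    return {
        "budget": abs(float(p.sum()) - P),
        "stationarity": float(np.max(np.abs(gains - (mu - lam)))),
        "complementary_slackness": float(np.max(np.abs(lam * p))),
        "dual_feasibility": float(max(0.0, -lam.min()) if lam.size else 0.0),
    }
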