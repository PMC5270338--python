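"""Additive power-law production functions.

The production function maps the vector of participation loads
``p = (p_1, ..., p_n)`` to the community's instantaneous contribution
toward completing the task,

    h(p) = sum_i beta_i * p_i**alpha_i,        alpha_i > 0, beta_i >= 0.

``alpha_i < 1`` gives a decelerating contribution (diminishing marginal
productivity), ``alpha_i = 1`` a linear one, and ``alpha_i > 1`` an
accelerating one.  The task-update rule requires ``h(p) < 1`` everywhere on
the feasible budget simplex ``{p >= 0 : sum(p) <= P}``; :meth:`ProductionFunction.validate_range`
certifies that condition by computing the exact supremum of ``h`` over the
simplex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "ProductionFunction",
    "RangeReport",
    "UnboundedDerivativeError",
]


class UnboundedDerivativeError(ValueError):
    """The marginal productivity diverges (``alpha_i < 1`` at ``p_i = 0``)."""


def as_load_vector(x, n: int | None = None, name: str = "p") -> np.ndarray:
    """Coerce to a 1-D float array, optionally checking its length."""
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 0:
        arr = arr.reshape(1)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if n is not None and arr.shape[0] != n:
        raise ValueError(f"{name} must have length {n}, got {arr.shape[0]}")
    return arr


@dataclass(frozen=True)
class RangeReport:
    """Result of checking ``h(p) < 1`` on the budget simplex."""

    valid: bool
    supremum: float
    argmax: np.ndarray


@dataclass(frozen=True)
class ProductionFunction:
    """Power family ``h(p) = sum_i beta_i p_i**alpha_i``.

    Parameters
    ----------
    alphas
        Per-individual exponents, all strictly positive.
    betas
        Per-individual non-negative weights.
    """

    alphas: np.ndarray
    betas: np.ndarray

    def __post_init__(self) -> None:
        alphas = as_load_vector(self.alphas, name="alphas")
        betas = as_load_vector(self.betas, n=alphas.shape[0], name="betas")
        if not np.all(np.isfinite(alphas)) or np.any(alphas <= 0):
            raise ValueError("every alpha_i must be finite and > 0")
        if not np.all(np.isfinite(betas)) or np.any(betas < 0):
            raise ValueError("every beta_i must be finite and >= 0")
        alphas.setflags(write=False)
        betas.setflags(write=False)
        object.__setattr__(self, "alphas", alphas)
        object.__setattr__(self, "betas", betas)

    @property
    def n(self) -> int:
        return self.alphas.shape[0]

    @classmethod
    def uniform(cls, n: int, alpha: float = 1.0, beta: float | None = None) -> "ProductionFunction":
        """Shared exponent/weight for all individuals; ``beta`` defaults to ``1/n``."""
        if n < 1:
            raise ValueError("n must be >= 1")
        if beta is None:
            beta = 1.0 / n
        return cls(np.full(n, float(alpha)), np.full(n, float(beta)))

    # ------------------------------------------------------------------
    def evaluate(self, p) -> float:
        """Contribution ``h(p)``; zero loads contribute zero (continuous extension)."""
        p = as_load_vector(p, self.n, "p")
        if np.any(p < 0):
            raise ValueError("participation loads must be non-negative")
        return float(np.sum(self.betas * p**self.alphas))

    def marginal_productivity(self, p, i: int) -> float:
        """``dh/dp_i = beta_i alpha_i p_i**(alpha_i - 1)`` for 1-based label ``i``.

        Raises
        ------
        UnboundedDerivativeError
            When ``alpha_i < 1`` and ``p_i = 0`` (the derivative diverges).
        """
        p = as_load_vector(p, self.n, "p")
        if np.any(p < 0):
            raise ValueError("participation loads must be non-negative")
        if not 1 <= i <= self.n:
            raise ValueError(f"individual label must be in 1..{self.n}, got {i}")
        idx = i - 1
        a = float(self.alphas[idx])
        b = float(self.betas[idx])
        if a == 1.0:
            return b
        if a < 1.0 and p[idx] == 0.0:
            if b == 0.0:
                return 0.0
            raise UnboundedDerivativeError(
                f"marginal productivity of individual {i} is unbounded at p_i = 0 "
                f"(alpha_i = {a} < 1)"
            )
        return float(b * a * p[idx] ** (a - 1.0))

    # ------------------------------------------------------------------
    def validate_range(self, P: float) -> RangeReport:
        """Exact supremum of ``h`` over ``{p >= 0 : sum(p) <= P}``.

        The maximum lies on ``sum(p) = P`` (``h`` is non-decreasing).  For the
        power family it is attained either at a vertex ``P e_i``, at the
        interior marginal-equalization point of the strictly concave
        coordinates, or at a split between one convex/linear coordinate and
        the concave pool (at most one coordinate with ``alpha >= 1`` can be
        positive at a maximizer because the restriction between two such
        coordinates is convex).
        """
        if not np.isfinite(P) or P < 0:
            raise ValueError("P must be finite and >= 0")
        n = self.n
        best_val = 0.0
        best_arg = np.zeros(n)
        if P > 0 and np.any(self.betas > 0):
            candidates: list[np.ndarray] = []
            for i in range(n):
                x = np.zeros(n)
                x[i] = P
                candidates.append(x)
            support = self.betas > 0
            concave = support & (self.alphas < 1.0)
            if concave.sum() >= 2:
                candidates.append(self._concave_fill(concave, P))
            if concave.any():
                for j in np.where(support & (self.alphas >= 1.0))[0]:
                    candidates.append(self._mixed_candidate(int(j), concave, P))
            for x in candidates:
                v = self.evaluate(x)
                if v > best_val:
                    best_val, best_arg = v, x
        return RangeReport(valid=bool(best_val < 1.0), supremum=float(best_val), argmax=best_arg)

    def _concave_fill(self, mask: np.ndarray, budget: float) -> np.ndarray:
        """Allocate ``budget`` among the masked alpha<1 coordinates so that the
        marginals ``beta_i alpha_i p_i**(alpha_i-1)`` are equal (Lagrange
        condition); solved by bisection on the log-multiplier."""
        x = np.zeros(self.n)
        if budget <= 0:
            return x
        idx = np.where(mask)[0]
        a = self.alphas[idx]
        b = self.betas[idx]
        log_ba = np.log(b * a)

        def loads(log_lam: float) -> np.ndarray:
            expo = (log_ba - log_lam) / (1.0 - a)
            return np.exp(np.clip(expo, -745.0, 700.0))

        lo, hi = -60.0, 60.0
        # total load is decreasing in the multiplier
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if loads(mid).sum() > budget:
                lo = mid
            else:
                hi = mid
        vals = loads(0.5 * (lo + hi))
        total = vals.sum()
        if total > 0:
            vals *= budget / total
        x[idx] = vals
        return x

    def _mixed_candidate(self, j: int, concave: np.ndarray, budget: float) -> np.ndarray:
        """Best split of the budget between convex/linear coordinate ``j`` and
        the concave pool: coarse scan refined by bounded 1-D optimization."""
        pool = concave.copy()
        pool[j] = False
        if not pool.any():
            x = np.zeros(self.n)
            x[j] = budget
            return x

        def value(s: float) -> float:
            x = self._concave_fill(pool, budget - s)
            x[j] = s
            return self.evaluate(x)

        grid = np.linspace(0.0, budget, 65)
        vals = [value(s) for s in grid]
        k = int(np.argmax(vals))
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, len(grid) - 1)]
        if hi > lo:
            res = optimize.minimize_scalar(
                lambda s: -value(s), bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-12},
            )
            s_best = float(res.x) if -res.fun >= vals[k] else float(grid[k])
        else:
            s_best = float(grid[k])
        x = self._concave_fill(pool, budget - s_best)
        x[j] = s_best
        return x


def finite_difference_marginal(pf: ProductionFunction, p, i: int, h: float = 1e-6) -> float:
    """Central finite difference of ``evaluate`` in coordinate ``i`` (1-based).

    Independent numerical check for :meth:`ProductionFunction.marginal_productivity`.
    """
    p = as_load_vector(p, pf.n, "p")
    step = h * max(1.0, abs(p[i - 1]))
    lo = p.copy()
    hi = p.copy()
    lo[i - 1] = max(p[i - 1] - step, 0.0)
    hi[i - 1] = p[i - 1] + step
    return (pf.evaluate(hi) - pf.evaluate(lo)) / (hi[i - 1] - lo[i - 1])
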