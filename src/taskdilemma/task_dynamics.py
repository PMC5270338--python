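"""Task-completion dynamics.

The task variable ``z`` grows from 0 toward the ceiling ``z_bar`` under the
first-order update

    z(t+1) = z(t) + phi * h(p(t)) * (z_bar - z(t)),     phi in (0, 1],

where ``h`` is the community's production value at time ``t``.  With a
constant contribution ``h`` the trajectory is the closed-form geometric decay
``z(t) = z_bar - (1 - phi h)**t (z_bar - z(0))``, and the minimum number of
steps to leave only a residual fraction ``sigma`` of the task is

    t* = ceil( log(sigma) / log(1 - phi h) ).

The residual-fraction convention for the numerator is the one consistent
with the geometric trajectory: the residual after ``t`` steps is exactly
``(1 - phi h)**t``, so requiring it to fall to ``sigma`` gives ``log(sigma)``
on top.  The brute-force iteration of the update rule is the oracle this
formula is tested against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .production import ProductionFunction

__all__ = [
    "TaskState",
    "CompletionGuaranteeReport",
    "NeverCompletesError",
    "step",
    "closed_form_trajectory",
    "min_iterations",
    "check_completion_guarantee",
]


class NeverCompletesError(ValueError):
    """No finite number of steps completes the task (``phi * h == 0``)."""


@dataclass(frozen=True)
class TaskState:
    """Task completion level ``z`` with ceiling ``z_bar``, scaling ``phi``, step ``t``."""

    z: float
    z_bar: float = 1.0
    phi: float = 0.1
    t: int = 0

    def __post_init__(self) -> None:
        if not (self.z_bar > 0 and math.isfinite(self.z_bar)):
            raise ValueError("z_bar must be finite and > 0")
        if not (0.0 <= self.z <= self.z_bar):
            raise ValueError(f"z must lie in [0, z_bar] = [0, {self.z_bar}], got {self.z}")
        if not (0.0 < self.phi <= 1.0):
            raise ValueError("phi must lie in (0, 1]")
        if self.t < 0:
            raise ValueError("t must be >= 0")

    @property
    def residual(self) -> float:
        """Remaining fraction of the task, ``(z_bar - z) / z_bar``."""
        return (self.z_bar - self.z) / self.z_bar


def _check_h(h_value: float) -> float:
    h = float(h_value)
    if not (0.0 <= h < 1.0):
        raise ValueError(f"production value must lie in [0, 1), got {h}")
    return h


def step(task: TaskState, h_value: float) -> TaskState:
    """One task update.  Fixed point iff ``h_value == 0`` or ``z == z_bar``."""
    h = _check_h(h_value)
    z_next = task.z + task.phi * h * (task.z_bar - task.z)
    # guard against rounding pushing z a few ulp past the ceiling
    z_next = min(z_next, task.z_bar)
    return TaskState(z=z_next, z_bar=task.z_bar, phi=task.phi, t=task.t + 1)


def closed_form_trajectory(task0: TaskState, h_const: float, t: int) -> float:
    """``z`` after ``t`` steps of a constant-contribution trajectory."""
    h = _check_h(h_const)
    if t < 0:
        raise ValueError("t must be >= 0")
    return task0.z_bar - (1.0 - task0.phi * h) ** t * (task0.z_bar - task0.z)


def min_iterations(phi: float, h_const: float, sigma: float) -> int:
    """Minimum steps so that the residual fraction falls to ``sigma``.

    Raises :class:`NeverCompletesError` when ``phi * h_const == 0`` and
    ``sigma < 1`` (the task never progresses).
    """
    if not (0.0 < phi <= 1.0):
        raise ValueError("phi must lie in (0, 1]")
    h = _check_h(h_const)
    if not (0.0 < sigma <= 1.0):
        raise ValueError("sigma must lie in (0, 1]")
    if sigma == 1.0:
        return 0
    rate = phi * h
    if rate == 0.0:
        raise NeverCompletesError("phi * h == 0: the task never progresses")
    ratio = math.log(sigma) / math.log1p(-rate)
    # tiny nudge so exact-integer ratios are not rounded up by float noise
    return max(0, math.ceil(ratio - 1e-12))


@dataclass(frozen=True)
class CompletionGuaranteeReport:
    """Sufficient-condition check for guaranteed task completion.

    ``certified`` holds when the production range is valid (supremum < 1 on
    the budget simplex) and the observed contribution trajectory stays at
    least ``epsilon`` away from zero, which supplies the linear certificate
    ``psi(x) = epsilon * x`` for the convergence argument.
    """

    range_valid: bool
    supremum: float
    h_inf: float
    epsilon: float
    certified: bool


def check_completion_guarantee(
    pf: ProductionFunction,
    P: float,
    trajectory_h: Sequence[float],
    epsilon: float = 1e-9,
) -> CompletionGuaranteeReport:
    """Check the completion-guarantee conditions against an observed trajectory."""
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    report = pf.validate_range(P)
    arr = np.asarray(trajectory_h, dtype=float)
    h_inf = float(arr.min()) if arr.size else math.inf
    certified = bool(report.valid and h_inf >= epsilon)
    return CompletionGuaranteeReport(
        range_valid=report.valid,
        supremum=report.supremum,
        h_inf=h_inf,
        epsilon=float(epsilon),
        certified=certified,
    )
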