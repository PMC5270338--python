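"""Coupled full-model simulation and Monte Carlo experiment harness.

One global time step runs, in order, all from the time-t state:

1. reciprocity ``r_i`` and gated marginal gains ``g_i`` from the current
   reputations and loads;
2. task update ``z(t+1)`` from the production value ``h(p(t))``;
3. reputation smoothing from ``p(t)``;
4. one reservoir exchange followed by one synchronous passing round, giving
   ``p(t+1)``.

Effective motivations ``b_i = gamma_i + r_i`` are frozen within a step, so
gains change during the round only through the loads.  A run terminates when
the task is complete to within the residual fraction ``sigma`` and the load
state has stopped moving, or at ``max_steps``.

The Monte Carlo harness re-samples, per run, which single individual is
motivated (``gamma_i = c_i P``, guaranteeing eligibility under the non-strict
gate), the cost slopes (uniform), and the per-pair reputation rates (uniform
on [0, 1]), then aggregates convergence times, task-trajectory percentiles,
per-individual total loads and terminal reciprocities across runs.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .equilibrium import water_filling
from .load_distribution import apply_passes, compute_passes, reservoir_exchange
from .production import ProductionFunction, as_load_vector
from .social_state import (
    GainModel,
    NetworkTopology,
    complete_topology,
    delta_matrix,
    from_edge_list,
    line_topology,
    pair_rate_matrix,
    reputation_update,
)

__all__ = [
    "ScenarioConfig",
    "Trajectory",
    "RunResult",
    "ConditionSummary",
    "MonteCarloSummary",
    "InequalityReport",
    "UndefinedInequalityError",
    "ConfigError",
    "run_scenario",
    "convergence_time",
    "sample_mc_params",
    "run_monte_carlo",
    "load_inequality",
]

logger = logging.getLogger("taskdilemma")


class ConfigError(ValueError):
    """A scenario parameter is missing, unknown, or outside its legal range."""


class UndefinedInequalityError(ValueError):
    """Load inequality is undefined when no individual carried any load."""


def _require(condition: bool, key: str, legal: str, value: Any) -> None:
    if not condition:
        raise ConfigError(f"config key '{key}' must be {legal}, got {value!r}")


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete, validated description of one simulation scenario.

    ``topology`` is ``"line"``, ``"complete"``, or a list of 1-based edge
    pairs.  Scalars for ``alpha``/``beta``/``gammas``/``costs``/``tau``/``r0``
    broadcast over individuals (or ordered pairs).  ``beta=None`` defaults to
    ``1/n``.  ``reputation=False`` freezes ``b_i = gamma_i`` (reciprocity
    identically zero), which is how fixed-motivation scenarios are expressed.
    """

    n: int
    topology: Any = "complete"
    P: float = 1.0
    phi: float = 0.1
    z_bar: float = 1.0
    z0: float = 0.0
    alpha: Any = 1.0
    beta: Any = None
    gammas: Any = 0.0
    costs: Any = 1.0
    tau: Any = 0.5
    delta: Any = "uniform"
    r_bar: float = 1.0
    r0: Any = 0.0
    theta: float = 0.005
    reputation: bool = True
    p0: Any = None
    max_steps: int = 5000
    sigma: float = 0.05
    stop_tol: float = 1e-10
    seed: int | None = None

    def __post_init__(self) -> None:
        _require(isinstance(self.n, int) and self.n >= 1, "n", "an integer >= 1", self.n)
        _require(self.P > 0 and math.isfinite(self.P), "P", "finite and > 0", self.P)
        _require(0.0 < self.phi <= 1.0, "phi", "in (0, 1]", self.phi)
        _require(self.z_bar > 0, "z_bar", "> 0", self.z_bar)
        _require(0.0 <= self.z0 <= self.z_bar, "z0", "in [0, z_bar]", self.z0)
        _require(0.0 < self.theta <= 1.0, "theta", "in (0, 1]", self.theta)
        _require(self.r_bar >= 0, "r_bar", ">= 0", self.r_bar)
        _require(isinstance(self.max_steps, int) and self.max_steps >= 1,
                 "max_steps", "an integer >= 1", self.max_steps)
        _require(0.0 < self.sigma <= 1.0, "sigma", "in (0, 1]", self.sigma)
        _require(self.stop_tol > 0, "stop_tol", "> 0", self.stop_tol)
        if self.seed is not None:
            _require(isinstance(self.seed, int) and self.seed >= 0, "seed",
                     "a non-negative integer or null", self.seed)
        # build the derived objects once so every range check fires here
        self.build_topology()
        self.build_production()
        gammas, costs = self.gain_arrays()
        _require(bool(np.all(gammas >= 0)), "gammas", "all >= 0", self.gammas)
        _require(bool(np.all(costs >= 0)), "costs", "all >= 0", self.costs)
        p0 = self.initial_loads()
        _require(bool(np.all(p0 >= 0)) and float(p0.sum()) <= self.P * (1 + 1e-12),
                 "p0", "non-negative with sum <= P", self.p0)
        try:
            pair_rate_matrix(self.build_topology(), np.asarray(self.tau, dtype=float))
        except ValueError as exc:
            raise ConfigError(f"config key 'tau' must be in [0, 1] per pair: {exc}") from exc
        try:
            delta_matrix(self.build_topology(), self.delta
                         if isinstance(self.delta, str) else np.asarray(self.delta, float))
        except ValueError as exc:
            raise ConfigError(f"config key 'delta' is invalid: {exc}") from exc

    # -- derived builders ------------------------------------------------
    def build_topology(self) -> NetworkTopology:
        if isinstance(self.topology, NetworkTopology):
            return self.topology
        if self.topology == "line":
            return line_topology(self.n)
        if self.topology == "complete":
            return complete_topology(self.n)
        if isinstance(self.topology, (list, tuple)):
            try:
                return from_edge_list([tuple(e) for e in self.topology], n=self.n)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"config key 'topology' has an invalid edge list: {exc}") from exc
        raise ConfigError(
            f"config key 'topology' must be 'line', 'complete', or an edge list, got {self.topology!r}"
        )

    def _broadcast(self, value: Any, key: str) -> np.ndarray:
        arr = np.asarray(value, dtype=float)
        if arr.ndim == 0:
            arr = np.full(self.n, float(arr))
        if arr.shape != (self.n,):
            raise ConfigError(f"config key '{key}' must be a scalar or length-{self.n} list")
        if not np.all(np.isfinite(arr)):
            raise ConfigError(f"config key '{key}' must be finite, got {value!r}")
        return arr

    def build_production(self) -> ProductionFunction:
        alphas = self._broadcast(self.alpha, "alpha")
        betas = (np.full(self.n, 1.0 / self.n) if self.beta is None
                 else self._broadcast(self.beta, "beta"))
        try:
            return ProductionFunction(alphas, betas)
        except ValueError as exc:
            raise ConfigError(f"production parameters are invalid: {exc}") from exc

    def gain_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return self._broadcast(self.gammas, "gammas"), self._broadcast(self.costs, "costs")

    def initial_loads(self) -> np.ndarray:
        if self.p0 is None:
            return np.zeros(self.n)
        return self._broadcast(self.p0, "p0")

    def gain_model(self) -> GainModel:
        gammas, costs = self.gain_arrays()
        return GainModel(gammas=gammas, costs=costs, P=self.P)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        if isinstance(d["topology"], NetworkTopology):
            d["topology"] = [list(e) for e in d["topology"].edges]
        for key in ("alpha", "beta", "gammas", "costs", "tau", "r0", "p0", "delta"):
            v = d[key]
            if isinstance(v, np.ndarray):
                d[key] = v.tolist()
            elif isinstance(v, (list, tuple)):
                d[key] = [list(x) if isinstance(x, (list, tuple, np.ndarray)) else x for x in v]
        return d


@dataclass(frozen=True)
class Trajectory:
    """Per-step record of a scenario run (time-t snapshots, inclusive of the end)."""

    config: ScenarioConfig
    t: np.ndarray
    z: np.ndarray
    p: np.ndarray
    g: np.ndarray
    r: np.ndarray
    reservoir: np.ndarray
    reputation: np.ndarray | None
    stopped: str

    @property
    def n(self) -> int:
        return self.p.shape[1]


@dataclass(frozen=True)
class RunResult:
    """Light-weight outcome of one run (used by the Monte Carlo harness)."""

    z: np.ndarray
    conv_time: int | None
    load_totals: np.ndarray
    terminal_reciprocity: np.ndarray
    final_p: np.ndarray
    censored: bool
    steps: int
    stopped: str


def _simulate(
    cfg: ScenarioConfig, record: bool, stop_at_conv: bool = False
) -> tuple[Trajectory | None, RunResult]:
    topology = cfg.build_topology()
    adj = topology.adjacency_matrix()
    n = cfg.n
    pf = cfg.build_production()
    range_report = pf.validate_range(cfg.P)
    if not range_report.valid:
        raise ConfigError(
            "production function violates h(p) < 1 on the budget simplex "
            f"(supremum {range_report.supremum:.6g}); rescale beta"
        )
    gammas, costs = cfg.gain_arrays()
    taus = pair_rate_matrix(topology, np.asarray(cfg.tau, dtype=float))
    deltas = delta_matrix(topology, cfg.delta if isinstance(cfg.delta, str)
                          else np.asarray(cfg.delta, float))
    r0 = np.asarray(cfg.r0, dtype=float)
    R = np.where(adj, r0 if r0.ndim == 2 else float(r0), 0.0)

    p = cfg.initial_loads().copy()
    reservoir = float(cfg.P - p.sum())
    z = float(cfg.z0)
    threshold = (1.0 - cfg.sigma) * cfg.z_bar

    hist_z: list[float] = []
    hist_p: list[np.ndarray] = []
    hist_g: list[np.ndarray] = []
    hist_r: list[np.ndarray] = []
    hist_res: list[float] = []
    hist_R: list[np.ndarray] = []
    ring = np.zeros((100, n))
    conv_time: int | None = None
    r_vec = np.zeros(n)
    g = np.zeros(n)
    stopped = "max_steps"
    moved = math.inf
    steps = 0

    for t in range(cfg.max_steps + 1):
        # (1) reciprocity and gated gains from the time-t state
        if cfg.reputation:
            r_vec = (deltas * R).sum(axis=1)
        else:
            r_vec = np.zeros(n)
        b = gammas + r_vec
        eligible = b >= costs * cfg.P
        g = np.where(eligible, b - costs * p, 0.0)

        hist_z.append(z)
        ring[t % 100] = p
        if record:
            hist_p.append(p.copy())
            hist_g.append(g.copy())
            hist_r.append(r_vec.copy())
            hist_res.append(reservoir)
            hist_R.append(R.copy())
        if conv_time is None and z >= threshold:
            conv_time = t
        steps = t

        h = pf.evaluate(p)
        if conv_time is not None and (stop_at_conv or moved <= cfg.stop_tol):
            stopped = "converged"
            break
        if moved == 0.0 and h == 0.0 and p.sum() == 0.0 and not eligible.any():
            # deficient equilibrium: nothing can ever change
            stopped = "deficient"
            break
        if t == cfg.max_steps:
            break

        # (2) task update from h(p(t))
        z = min(z + cfg.phi * h * (cfg.z_bar - z), cfg.z_bar)
        # (3) reputation smoothing from p(t)
        if cfg.reputation:
            R = reputation_update(R, taus, adj, p, cfg.P, cfg.r_bar)
        # (4) reservoir exchange then one synchronous passing round
        slopes = np.where(eligible, costs, 0.0)
        p_new, reservoir = reservoir_exchange(p, reservoir, g, slopes, cfg.theta)
        drawn = float(np.abs(p_new - p).sum())
        g_round = np.where(eligible, b - costs * p_new, 0.0)
        plan = compute_passes(p_new, g_round, slopes, topology, cfg.theta)
        p = apply_passes(p_new, plan)
        moved = drawn + plan.total()

    k = min(steps + 1, 100)
    load_totals = ring[:k].sum(axis=0) if steps + 1 <= 100 else ring.sum(axis=0)
    result = RunResult(
        z=np.asarray(hist_z),
        conv_time=conv_time,
        load_totals=load_totals,
        terminal_reciprocity=r_vec.copy(),
        final_p=p.copy(),
        censored=conv_time is None,
        steps=steps,
        stopped=stopped,
    )
    traj = None
    if record:
        traj = Trajectory(
            config=cfg,
            t=np.arange(len(hist_z)),
            z=np.asarray(hist_z),
            p=np.asarray(hist_p),
            g=np.asarray(hist_g),
            r=np.asarray(hist_r),
            reservoir=np.asarray(hist_res),
            reputation=np.asarray(hist_R),
            stopped=stopped,
        )
    return traj, result


def run_scenario(cfg: ScenarioConfig) -> Trajectory:
    """Run one scenario with full per-step records."""
    traj, _ = _simulate(cfg, record=True)
    assert traj is not None
    return traj


def convergence_time(traj: Trajectory, sigma: float | None = None) -> int | None:
    """First step with ``z >= (1 - sigma) z_bar``; ``None`` when censored."""
    if sigma is None:
        sigma = traj.config.sigma
    if not (0.0 < sigma <= 1.0):
        raise ValueError("sigma must lie in (0, 1]")
    threshold = (1.0 - sigma) * traj.config.z_bar
    hits = np.nonzero(traj.z >= threshold)[0]
    return int(hits[0]) if hits.size else None


@dataclass(frozen=True)
class InequalityReport:
    """Dispersion of per-individual total loads."""

    cv: float
    max_min_ratio: float


def load_inequality(totals) -> InequalityReport:
    """Coefficient of variation and max/min ratio of per-individual totals."""
    totals = as_load_vector(totals, name="totals")
    if np.any(totals < 0):
        raise ValueError("totals must be non-negative")
    if not np.any(totals > 0):
        raise UndefinedInequalityError("all per-individual totals are zero")
    mean = float(totals.mean())
    cv = float(totals.std() / mean)
    mn = float(totals.min())
    ratio = math.inf if mn == 0.0 else float(totals.max() / mn)
    return InequalityReport(cv=cv, max_min_ratio=ratio)


# ----------------------------------------------------------------------
# Monte Carlo harness
# ----------------------------------------------------------------------

def sample_mc_params(
    rng: np.random.Generator,
    base_cfg: ScenarioConfig,
    c_range: tuple[float, float] = (0.5, 1.5),
    gamma_mult: float = 1.0,
) -> ScenarioConfig:
    """Draw one Monte Carlo scenario from the base configuration.

    Exactly one uniformly chosen individual receives a non-zero constant
    motivation ``gamma = gamma_mult * c_i * P`` (eligible under the
    non-strict gate when ``gamma_mult >= 1``); all cost slopes are uniform on
    ``c_range`` and every ordered-pair reputation rate is uniform on [0, 1].
    Deterministic given the generator state.
    """
    n = base_cfg.n
    costs = rng.uniform(c_range[0], c_range[1], size=n)
    motivated = int(rng.integers(n))
    taus = rng.uniform(0.0, 1.0, size=(n, n))
    gammas = np.zeros(n)
    gammas[motivated] = gamma_mult * costs[motivated] * base_cfg.P
    return dataclasses.replace(
        base_cfg,
        gammas=gammas.tolist(),
        costs=costs.tolist(),
        tau=taus.tolist(),
    )


@dataclass(frozen=True)
class ConditionSummary:
    """Cross-run statistics for one (topology, production) condition."""

    condition: dict[str, Any]
    n_runs: int
    censored: int
    failures: int
    conv_times: np.ndarray          # +inf where censored
    conv_quartiles: tuple[float, float, float]
    high_censoring: bool
    z_time: np.ndarray
    z_q25: np.ndarray
    z_median: np.ndarray
    z_q75: np.ndarray
    load_totals: np.ndarray         # (runs, n)
    load_quartiles: np.ndarray      # (3, n): q25, median, q75
    reciprocity_terminal: np.ndarray
    reciprocity_quartiles: np.ndarray
    inequality_cv: np.ndarray
    inequality_cv_median: float
    child_seeds: tuple[int, ...]


@dataclass(frozen=True)
class MonteCarloSummary:
    master_seed: int
    n_runs: int
    conditions: tuple[ConditionSummary, ...]

    def by_condition(self, **kwargs) -> ConditionSummary:
        """Look up the summary whose condition dict contains all given items."""
        for cond in self.conditions:
            if all(cond.condition.get(k) == v for k, v in kwargs.items()):
                return cond
        raise KeyError(f"no condition matching {kwargs}")


def _quartiles(x: np.ndarray) -> tuple[float, float, float]:
    return (float(np.percentile(x, 25)), float(np.median(x)), float(np.percentile(x, 75)))


def run_monte_carlo(
    base_cfg: ScenarioConfig,
    n_runs: int,
    conditions: Sequence[dict[str, Any]],
    seed: int,
    c_range: tuple[float, float] = (0.5, 1.5),
    gamma_mult: float = 1.0,
) -> MonteCarloSummary:
    """Run ``n_runs`` sampled scenarios per condition and aggregate percentiles.

    Every condition is a dict of :class:`ScenarioConfig` field overrides
    (e.g. ``{"topology": "line", "alpha": 0.5}``).  Per-run seeds are spawned
    from the master seed with the (condition, run) counter pair, so any run
    can be reproduced in isolation.  Failed runs are excluded and counted,
    never silently dropped.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    summaries: list[ConditionSummary] = []
    for ci, cond in enumerate(conditions):
        cfg_c = dataclasses.replace(base_cfg, **cond)
        results: list[RunResult] = []
        child_seeds: list[int] = []
        failures = 0
        for run in range(n_runs):
            ss = np.random.SeedSequence(entropy=seed, spawn_key=(ci, run))
            child = int(ss.generate_state(1)[0] % 2**31)
            rng = np.random.default_rng(child)
            cfg_r = sample_mc_params(rng, cfg_c, c_range=c_range, gamma_mult=gamma_mult)
            cfg_r = dataclasses.replace(cfg_r, seed=child)
            try:
                _, res = _simulate(cfg_r, record=False, stop_at_conv=True)
            except Exception:
                failures += 1
                logger.exception("Monte Carlo run failed (condition %d, run %d)", ci, run)
                continue
            results.append(res)
            child_seeds.append(child)
        if not results:
            raise RuntimeError(f"every run failed for condition {cond!r}")

        conv = np.array([math.inf if r.censored else r.conv_time for r in results])
        censored = int(np.isinf(conv).sum())
        max_len = max(r.z.shape[0] for r in results)
        z_mat = np.empty((len(results), max_len))
        for k, r in enumerate(results):
            z_mat[k, : r.z.shape[0]] = r.z
            z_mat[k, r.z.shape[0]:] = r.z[-1]
        totals = np.vstack([r.load_totals for r in results])
        recs = np.vstack([r.terminal_reciprocity for r in results])
        cvs = []
        for r in results:
            try:
                cvs.append(load_inequality(r.load_totals).cv)
            except UndefinedInequalityError:
                cvs.append(math.nan)
        cvs_arr = np.asarray(cvs)
        finite_cv = cvs_arr[~np.isnan(cvs_arr)]
        summaries.append(
            ConditionSummary(
                condition=dict(cond),
                n_runs=len(results),
                censored=censored,
                failures=failures,
                conv_times=conv,
                conv_quartiles=_quartiles(conv),
                high_censoring=censored > 0.25 * len(results),
                z_time=np.arange(max_len),
                z_q25=np.percentile(z_mat, 25, axis=0),
                z_median=np.median(z_mat, axis=0),
                z_q75=np.percentile(z_mat, 75, axis=0),
                load_totals=totals,
                load_quartiles=np.vstack([
                    np.percentile(totals, 25, axis=0),
                    np.median(totals, axis=0),
                    np.percentile(totals, 75, axis=0),
                ]),
                reciprocity_terminal=recs,
                reciprocity_quartiles=np.vstack([
                    np.percentile(recs, 25, axis=0),
                    np.median(recs, axis=0),
                    np.percentile(recs, 75, axis=0),
                ]),
                inequality_cv=cvs_arr,
                inequality_cv_median=float(np.median(finite_cv)) if finite_cv.size else math.nan,
                child_seeds=tuple(child_seeds),
            )
        )
    return MonteCarloSummary(master_seed=seed, n_runs=n_runs, conditions=tuple(summaries))


def equilibrium_for_config(cfg: ScenarioConfig, b=None):
    """Water-filling solution for a scenario's gain model (fixed motivations)."""
    gammas, costs = cfg.gain_arrays()
    if b is None:
        b = gammas
    return water_filling(b, costs, cfg.P)
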