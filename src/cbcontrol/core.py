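"""Emergent collective biological control (CBC) of an occasionally toxic pest.

A two-level model of how prey-eating behaviour spreads, by social learning,
through a flock of great-tit-like birds foraging on a spotted-lanternfly-like
pest of which a proportion ``q`` is toxic (having fed on a quassinoid-producing
host plant):

1. A compartmental ODE for the proportion of prey eaters ``p``,

       dp/dt = r_i * p * (r_o * (1 - q - p) - q),

   where ``r_i`` is the predator-prey interaction rate (interactions per time
   step) and ``r_o`` the probability that an interaction is observed by
   another predator.  The equation has an explicit solution, two equilibria
   (extinction of the behaviour at ``p = 0`` and a collective-biological-
   control equilibrium at ``p = 1 - (r_o + 1) q / r_o``), and a sharp
   emergence threshold ``r_o = q / (1 - q)`` (equivalently
   ``q = r_o / (r_o + 1)``).

2. A spatially explicit agent-based model (ABM): self-propelled bird agents
   flock around a roost site, encounter stationary lanternfly agents, try
   them spontaneously with probability ``pi`` while undecided, adopt or
   abandon the eating behaviour from their own experience, and copy the
   outcome of eating events they observe within a radius ``R_o``.

The experiments layer sweeps the toxic proportion ``q``, estimates ``r_i``
and ``r_o`` from the simulation event logs, and overlays the analytic
predictions on the simulated long-term and transient behaviour.

The module is organised in the order the method runs: analytic model,
ABM state and kernels, experiments, then configuration / output plumbing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import os
import tempfile
import time as _time
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy.integrate import solve_ivp

__all__ = [
    # analytic model
    "ModelParams", "SolutionConstants", "Equilibrium", "EquilibriumReport",
    "SolutionCurve", "dpdt", "alpha", "solution_constants",
    "explicit_solution", "equilibria", "q_threshold", "integrate_numeric",
    # ABM
    "MovementParams", "AbmConfig", "WorldState", "EatEvent", "EventLog",
    "SimResult", "init_world", "make_world", "movement_step", "foraging_step",
    "observation_step", "advance", "run",
    # experiments
    "SweepTable", "TrajectoryTable", "RateEstimates", "ComparisonResult",
    "sweep_longterm", "trajectory_experiment", "estimate_rates",
    "overlay_comparison", "collapse_q",
    "desk_scale_settings", "paper_scale_settings",
    # config / io
    "ExperimentConfig", "OutputConfig", "RunConfig", "load_config",
    "config_hash", "write_outputs",
    "ValidationError", "IntegrationError",
    "configure_logging",
]

__version__ = "0.1.0"

logger = logging.getLogger("cbcontrol")


def configure_logging(verbosity: int = 0) -> None:
    """Configure package logging: 0 = warnings, 1 = run-level info, 2 = debug."""
    level = logging.WARNING
    if verbosity == 1:
        level = logging.INFO
    elif verbosity >= 2:
        level = logging.DEBUG
    logging.basicConfig(format="%(asctime)s %(name)s %(levelname)s %(message)s")
    logger.setLevel(level)


class ValidationError(ValueError):
    """A parameter or configuration field violates its documented bounds."""


class IntegrationError(RuntimeError):
    """Numerical integration of the ODE failed to produce a finite solution."""


# ======================================================================
# Section 1 — the analytic social-learning model
# ======================================================================

#: Relative tolerance (against r_o) below which alpha is treated as zero and
#: the degenerate closed form p(t) = p0 / (1 + r_i r_o p0 t) is used.
ALPHA_DEGENERATE_RTOL = 1e-12


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the social-learning ODE.

    Parameters
    ----------
    r_i
        Predator-prey interaction rate, interactions per time step (> 0).
        One ODE time unit is one ABM time step, so ABM-estimated rates plug
        in without rescaling.
    r_o
        Probability that an interaction is observed by another predator.
        Validated to (0, 1] unless ``allow_large_ro`` is set; the stability
        analysis itself only needs r_o > 0.
    q
        Proportion of the prey population rendered toxic by feeding on the
        toxicity-inducing host, in [0, 1].
    p0
        Initial proportion of prey eaters, in [0, 1].
    """

    r_i: float = 0.01
    r_o: float = 0.45
    q: float = 0.1
    p0: float = 0.02
    allow_large_ro: bool = False

    def __post_init__(self) -> None:
        if not (self.r_i > 0 and math.isfinite(self.r_i)):
            raise ValidationError(f"r_i must be a positive finite real, got {self.r_i}")
        hi = math.inf if self.allow_large_ro else 1.0
        if not (0 < self.r_o <= hi and math.isfinite(self.r_o)):
            raise ValidationError(
                f"r_o must be in (0, {'inf' if self.allow_large_ro else 1}], got {self.r_o}"
            )
        if not (0 <= self.q <= 1):
            raise ValidationError(f"q must be in [0, 1], got {self.q}")
        if not (0 <= self.p0 <= 1):
            raise ValidationError(f"p0 must be in [0, 1], got {self.p0}")

    def replace(self, **kw) -> "ModelParams":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class SolutionConstants:
    """Constants of the explicit solution.

    ``alpha = r_o (1 - q) - q`` selects the stable equilibrium by its sign.
    ``K = alpha / p0 - r_o`` is the coefficient of the exponential in the
    denominator of the particular solution
    ``p(t) = alpha / (r_o + K exp(-r_i alpha t))``; it is the negative of the
    integration constant of the separable-equation derivation.  ``K`` is
    undefined (``k_defined`` False, value NaN) when ``p0 = 0``, where the
    solution is identically the trivial equilibrium.
    """

    alpha: float
    K: float
    k_defined: bool


def alpha(params: ModelParams) -> float:
    """Composite constant ``alpha = r_o (1 - q) - q``.

    Its sign determines which equilibrium is stable: the collective control
    equilibrium for ``alpha > 0``, extinction of the behaviour for
    ``alpha < 0``.
    """
    return params.r_o * (1.0 - params.q) - params.q


def solution_constants(params: ModelParams) -> SolutionConstants:
    """Compute (alpha, K) for the explicit solution; flags K at ``p0 = 0``."""
    a = alpha(params)
    if params.p0 == 0:
        return SolutionConstants(alpha=a, K=math.nan, k_defined=False)
    return SolutionConstants(alpha=a, K=a / params.p0 - params.r_o, k_defined=True)


def _validate_p(p) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1) or not np.all(np.isfinite(arr)):
        raise ValidationError(f"p must lie in [0, 1], got {p}")
    return arr


def dpdt(p, params: ModelParams):
    """Rate of change of the eater proportion, ``r_i p (r_o(1-q-p) - q)``.

    Equals the compartmental decomposition
    ``r_i r_o p (1-q)(1-p) - (r_i r_o p q + r_i q) p``
    (inflow from observed positive interactions minus outflow from observed
    negative interactions and the eater's own toxic experiences).
    Accepts a scalar or array ``p`` in [0, 1].
    """
    arr = _validate_p(p)
    out = params.r_i * arr * (params.r_o * (1.0 - params.q - arr) - params.q)
    return float(out) if np.isscalar(p) or np.ndim(p) == 0 else out


@dataclass(frozen=True)
class SolutionCurve:
    """A solution ``p(t)`` sampled on an ordered time grid."""

    times: np.ndarray
    p_values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "p_values", np.asarray(self.p_values, dtype=float))
        if self.times.shape != self.p_values.shape:
            raise ValidationError("times and p_values must have equal length")

    def __len__(self) -> int:
        return len(self.times)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.times, "p": self.p_values})


def _explicit_p(t: np.ndarray, params: ModelParams) -> np.ndarray:
    a = alpha(params)
    p0, r_i, r_o = params.p0, params.r_i, params.r_o
    if p0 == 0.0:
        return np.zeros_like(t)
    if abs(a) < ALPHA_DEGENERATE_RTOL * r_o:
        # alpha = 0: dp/dt = -r_i r_o p^2, an algebraic decay.
        return p0 / (1.0 + r_i * r_o * p0 * t)
    expo = -r_i * a * t
    # For alpha < 0 the exponential diverges as t grows; the solution tends
    # to 0 from above.  Cap the exponent and patch the overflowed entries.
    capped = np.minimum(expo, 700.0)
    denom = r_o + (a / p0 - r_o) * np.exp(capped)
    with np.errstate(divide="ignore"):
        p = a / denom
    p = np.where(expo > 700.0, 0.0, p)
    return np.clip(p, 0.0, 1.0)


def explicit_solution(t, params: ModelParams):
    """Evaluate the explicit solution of the ODE.

    ``p(t) = alpha / (r_o + (alpha/p0 - r_o) exp(-r_i alpha t))`` for
    ``alpha != 0``; the algebraic limit ``p0 / (1 + r_i r_o p0 t)`` at
    ``alpha = 0``; identically ``0`` for ``p0 = 0`` (the trivial
    equilibrium).  At ``t = 0`` this returns ``p0`` exactly; as t grows it
    converges to ``alpha / r_o`` when ``alpha > 0`` and to ``0`` when
    ``alpha < 0``.

    Returns a float for scalar ``t``, a :class:`SolutionCurve` for a grid.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValidationError("t must be non-negative")
    p = _explicit_p(np.atleast_1d(t_arr), params)
    if t_arr.ndim == 0:
        return float(p[0])
    return SolutionCurve(times=t_arr, p_values=p)


@dataclass(frozen=True)
class Equilibrium:
    """One equilibrium of the ODE with its stability classification.

    ``stable`` is True/False for hyperbolic equilibria and None on the
    non-hyperbolic boundary ``r_o = q/(1-q)``, where the first-derivative
    test is indeterminate.  ``in_unit_interval`` flags whether the value is
    biologically attainable (a proportion in [0, 1]).
    """

    p_star: float
    stable: bool | None
    condition: str
    in_unit_interval: bool


@dataclass(frozen=True)
class EquilibriumReport:
    """Both equilibria plus the emergence thresholds.

    ``threshold_ro = q/(1-q)`` (infinite at q = 1, where p = 0 is globally
    stable) and ``threshold_q = r_o/(r_o+1)`` are the two renderings of the
    same boundary ``r_o = q/(1-q)``.
    """

    equilibria: tuple[Equilibrium, ...]
    threshold_ro: float
    threshold_q: float

    @property
    def stable_p(self) -> float:
        """The stable long-term eater proportion, clamped to [0, 1]."""
        for eq in self.equilibria:
            if eq.stable and eq.in_unit_interval:
                return eq.p_star
        return 0.0

    def to_dict(self) -> dict:
        return {
            "equilibria": [dataclasses.asdict(e) for e in self.equilibria],
            "threshold_ro": self.threshold_ro,
            "threshold_q": self.threshold_q,
        }


def q_threshold(r_o: float) -> float:
    """Toxic proportion above which no collective control emerges.

    Returns ``r_o / (r_o + 1)``, the unique q at which the collective
    control equilibrium ``1 - (r_o+1) q / r_o`` reaches zero — identically
    the q solving the stability boundary ``r_o = q / (1 - q)``.
    """
    if not r_o > 0:
        raise ValidationError(f"r_o must be positive, got {r_o}")
    return r_o / (r_o + 1.0)


def equilibria(params: ModelParams) -> EquilibriumReport:
    """Find both equilibria of the ODE and classify their stability.

    ``p = 0`` is stable iff ``r_o < q/(1-q)``; the collective control
    equilibrium ``p = 1 - (r_o+1) q / r_o`` is stable iff ``r_o > q/(1-q)``
    (and lies in [0, 1] exactly then).  On the boundary the first-derivative
    test is indeterminate and both are reported non-hyperbolic.
    """
    r_o, q = params.r_o, params.q
    if q >= 1.0:
        thr_ro = math.inf
    else:
        thr_ro = q / (1.0 - q)
    thr_q = q_threshold(r_o)
    p2 = 1.0 - (r_o + 1.0) * q / r_o

    boundary = math.isfinite(thr_ro) and r_o == thr_ro
    if boundary:
        s0 = s2 = None
        cond0 = cond2 = "non-hyperbolic: r_o = q/(1-q), first-derivative test indeterminate"
    else:
        s0 = r_o < thr_ro
        s2 = r_o > thr_ro
        cond0 = "p = 0 stable iff r_o < q/(1-q)"
        cond2 = "p = 1 - (r_o+1)q/r_o stable iff r_o > q/(1-q)"
    in_range2 = 0.0 <= p2 <= 1.0
    eq0 = Equilibrium(p_star=0.0, stable=s0, condition=cond0, in_unit_interval=True)
    eq2 = Equilibrium(
        p_star=p2,
        stable=s2,
        condition=cond2 if in_range2 or boundary
        else cond2 + " (not in [0,1]: not biologically attained)",
        in_unit_interval=in_range2,
    )
    return EquilibriumReport(equilibria=(eq0, eq2), threshold_ro=thr_ro, threshold_q=thr_q)


def integrate_numeric(params: ModelParams, t_grid) -> SolutionCurve:
    """Adaptive-step numerical solution of the ODE on ``t_grid``.

    An independent oracle for :func:`explicit_solution`: integrates
    ``dp/dt`` with LSODA at tight tolerances from ``p0`` at t = 0.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 1:
        raise ValidationError("t_grid must be a one-dimensional, non-empty grid")
    if np.any(np.diff(t_grid) <= 0) or t_grid[0] < 0:
        raise ValidationError("t_grid must be strictly increasing and non-negative")
    if params.p0 == 0.0:
        return SolutionCurve(times=t_grid, p_values=np.zeros_like(t_grid))

    def rhs(_t, y):
        p = y[0]
        return [params.r_i * p * (params.r_o * (1.0 - params.q - p) - params.q)]

    sol = solve_ivp(
        rhs,
        (0.0, float(t_grid[-1])),
        [params.p0],
        t_eval=t_grid if t_grid[0] > 0 or len(t_grid) > 1 else None,
        method="LSODA",
        rtol=1e-10,
        atol=1e-13,
    )
    if not sol.success:
        raise IntegrationError(f"ODE integration failed: {sol.message}")
    if t_grid[0] == 0 and len(t_grid) == 1:
        p_vals = np.array([params.p0])
    else:
        p_vals = sol.y[0]
    if not np.all(np.isfinite(p_vals)):
        raise IntegrationError("ODE integration produced non-finite values")
    return SolutionCurve(times=t_grid, p_values=np.clip(p_vals, 0.0, 1.0))


# ======================================================================
# Section 2 — ABM configuration and state
# ======================================================================

UNDECIDED, EATER, NON_EATER = 0, 1, 2
STATE_NAMES = {UNDECIDED: "undecided", EATER: "eater", NON_EATER: "non_eater"}
_TERMINATIONS = {0: "time_out", 1: "all_consumed", 2: "all_non_eaters"}


@dataclass(frozen=True)
class MovementParams:
    """Parameters of the stand-in zonal flocking model.

    The published roost-site flocking rule the simulations are meant to host
    is not restated here; this is a documented stand-in: a standard zonal
    self-propelled-particle model (short-range repulsion with priority,
    alignment plus attraction out to the interaction radius) with a homing
    turn toward the roost once a bird strays beyond ``home_radius``.  Birds
    cruise at constant ``speed`` with bounded rotational noise.  Quantitative
    rate estimates (r_i_hat, r_o_hat) depend on this stand-in; the weights
    were calibrated so the emergent observation rate sits near the reference
    operating point r_o ~= 0.45 of a loose swarm.
    """

    speed: float = 1.0
    repulsion_radius: float = 3.0
    w_repulsion: float = 2.0
    w_align: float = 0.4
    w_attract: float = 0.25
    home_radius: float = 85.0
    w_roost: float = 0.5
    noise: float = 0.3  # max rotation per step, radians, uniform

    def __post_init__(self):
        for name in ("speed", "repulsion_radius", "w_repulsion", "w_roost"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"movement.{name} must be positive")
        for name in ("w_align", "w_attract", "noise"):
            if getattr(self, name) < 0:
                raise ValidationError(f"movement.{name} must be non-negative")


@dataclass(frozen=True)
class AbmConfig:
    """Configuration of one agent-based simulation.

    Defaults are the reference simulation conditions: N = 50 birds, N_l =
    500 lanternfly scattered uniformly over a 150 x 150 arena centred on the
    roost, spontaneous-trial probability pi = 0.01, observation radius R_o =
    6 equal to the bird-bird interaction radius R, and T_max = 6e6 steps.
    ``R_c`` is the bird-lanternfly encounter (pecking) radius, small against
    the visual radius R_o.  ``record_stride`` subsamples the eater-proportion
    time series; the final value is always recorded exactly at termination.
    """

    N: int = 50
    N_l: int = 500
    q: float = 0.0
    pi: float = 0.01
    R_o: float = 6.0
    R: float = 6.0
    R_c: float = 1.0
    arena_half_width: float = 75.0
    T_max: int = 6_000_000
    movement: MovementParams = field(default_factory=MovementParams)
    seed: int = 0
    record_stride: int = 1000
    init_disc_radius: float = 10.0

    def __post_init__(self):
        if self.N <= 0:
            raise ValidationError(f"N must be a positive integer, got {self.N}")
        if self.N_l <= 0:
            raise ValidationError(f"N_l must be a positive integer, got {self.N_l}")
        if not (0 <= self.q <= 1):
            raise ValidationError(f"q must be in [0, 1], got {self.q}")
        if not (0 <= self.pi <= 1):
            raise ValidationError(f"pi must be in [0, 1], got {self.pi}")
        for name in ("R_o", "R", "R_c", "arena_half_width", "init_disc_radius"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive, got {getattr(self, name)}")
        if self.T_max < 1 or self.record_stride < 1:
            raise ValidationError("T_max and record_stride must be >= 1")

    def replace(self, **kw) -> "AbmConfig":
        return dataclasses.replace(self, **kw)


class WorldState:
    """Mutable state of the spatial world: birds, lanternfly, fly grid, clock.

    Bird feeding states are coded 0 = undecided, 1 = eater, 2 = non_eater.
    ``saw_good``/``saw_bad`` are the pending-outcome flags accumulated during
    the foraging and observation phases of one time step; all state updates
    commit together at the end of the observation phase so that simultaneous
    events resolve order-independently (with a negative outcome dominating).
    """

    def __init__(self, pos, vel, state, fly_pos, fly_toxic, fly_alive,
                 cell_start, cell_items, nx, ny, cell_size, t=0):
        self.pos = pos
        self.vel = vel
        self.state = state
        self.fly_pos = fly_pos
        self.fly_toxic = fly_toxic
        self.fly_alive = fly_alive
        self.cell_start = cell_start
        self.cell_items = cell_items
        self.nx = nx
        self.ny = ny
        self.cell_size = cell_size
        self.t = t
        self.saw_good = np.zeros(len(pos), dtype=np.bool_)
        self.saw_bad = np.zeros(len(pos), dtype=np.bool_)

    # -- derived counts ------------------------------------------------
    @property
    def n_birds(self) -> int:
        return len(self.pos)

    @property
    def n_eaters(self) -> int:
        return int(np.count_nonzero(self.state == EATER))

    @property
    def n_non_eaters(self) -> int:
        return int(np.count_nonzero(self.state == NON_EATER))

    @property
    def n_undecided(self) -> int:
        return int(np.count_nonzero(self.state == UNDECIDED))

    @property
    def n_flies_alive(self) -> int:
        return int(np.count_nonzero(self.fly_alive))

    @property
    def p(self) -> float:
        """Current proportion of eaters."""
        return self.n_eaters / self.n_birds

    def copy(self) -> "WorldState":
        w = WorldState(
            self.pos.copy(), self.vel.copy(), self.state.copy(),
            self.fly_pos.copy(), self.fly_toxic.copy(), self.fly_alive.copy(),
            self.cell_start, self.cell_items, self.nx, self.ny,
            self.cell_size, self.t,
        )
        w.saw_good = self.saw_good.copy()
        w.saw_bad = self.saw_bad.copy()
        return w


@dataclass
class EatEvent:
    """One consumed lanternfly: who ate it, whether it was toxic, who saw it."""

    t: int
    bird_id: int
    fly_id: int
    toxic: bool
    observers: tuple[int, ...] = ()


@dataclass
class EventLog:
    """Timestamped eating events of one run plus the exposure denominator.

    One record per consumed lanternfly; observer sets exclude the eater.
    ``n_bird_steps`` is N times the number of steps the run was live — the
    denominator of the interaction-rate estimator.
    """

    t: np.ndarray
    bird_id: np.ndarray
    fly_id: np.ndarray
    toxic: np.ndarray
    n_observers: np.ndarray
    observers: list[np.ndarray]
    n_birds: int
    n_steps: int

    @property
    def n_events(self) -> int:
        return len(self.t)

    @property
    def n_observed(self) -> int:
        """Events observed by at least one other bird."""
        return int(np.count_nonzero(self.n_observers >= 1))

    @property
    def n_bird_steps(self) -> int:
        return self.n_birds * self.n_steps

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.t,
            "bird_id": self.bird_id,
            "lanternfly_id": self.fly_id,
            "toxic": self.toxic,
            "n_observers": self.n_observers,
            "observer_ids": [";".join(map(str, o)) for o in self.observers],
        })


@dataclass
class SimResult:
    """Outcome of one simulation run.

    The recorded series share the grid ``times`` (every ``record_stride``
    steps plus the exact final step): the eater proportion plus the raw
    state counts; undecided birds are N minus eaters minus non-eaters.
    """

    times: np.ndarray
    p_series: np.ndarray
    final_p: float
    termination: str
    event_log: EventLog
    seed: int
    config: AbmConfig
    n_eaters_series: np.ndarray | None = None
    n_non_eaters_series: np.ndarray | None = None
    n_flies_alive_series: np.ndarray | None = None

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"t": self.times, "p": self.p_series})
        if self.n_eaters_series is not None:
            df["n_eaters"] = self.n_eaters_series
            df["n_non_eaters"] = self.n_non_eaters_series
            df["n_undecided"] = (self.config.N - self.n_eaters_series
                                 - self.n_non_eaters_series)
            df["n_lanternfly_alive"] = self.n_flies_alive_series
        return df


# ======================================================================
# Section 3 — numba kernels (the ABM inner loop)
# ======================================================================

@njit(cache=True)
def _nb_seed(seed):
    np.random.seed(seed)


@njit(cache=True, fastmath=True)
def _movement_kernel(pos, vel, newv, speed, R2, rrep2, w_rep, w_ali, w_att,
                     home_r, w_roost, noise):
    n = pos.shape[0]
    # symmetric pair sweep: acc columns are (rep_x, rep_y, ali_x, ali_y,
    # att_x, att_y); cnt columns are (n_repulsion, n_social)
    acc = np.zeros((n, 6))
    cnt = np.zeros((n, 2), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            d2 = dx * dx + dy * dy
            if d2 < R2:
                if d2 < rrep2:
                    d = math.sqrt(d2)
                    if d > 1e-12:
                        ux = dx / d
                        uy = dy / d
                    else:
                        # coincident birds: deterministic split along x
                        ux = 1.0
                        uy = 0.0
                    acc[i, 0] -= ux
                    acc[i, 1] -= uy
                    cnt[i, 0] += 1
                    acc[j, 0] += ux
                    acc[j, 1] += uy
                    cnt[j, 0] += 1
                else:
                    d = math.sqrt(d2)
                    ux = dx / d
                    uy = dy / d
                    acc[i, 2] += vel[j, 0]
                    acc[i, 3] += vel[j, 1]
                    acc[i, 4] += ux
                    acc[i, 5] += uy
                    cnt[i, 1] += 1
                    acc[j, 2] += vel[i, 0]
                    acc[j, 3] += vel[i, 1]
                    acc[j, 4] -= ux
                    acc[j, 5] -= uy
                    cnt[j, 1] += 1
    for i in range(n):
        xi = pos[i, 0]
        yi = pos[i, 1]
        hx = vel[i, 0] / speed
        hy = vel[i, 1] / speed
        if cnt[i, 0] > 0:
            # repulsion has priority over the social zone
            sx = w_rep * acc[i, 0] / cnt[i, 0]
            sy = w_rep * acc[i, 1] / cnt[i, 0]
        elif cnt[i, 1] > 0:
            sx = (w_ali * acc[i, 2] / speed + w_att * acc[i, 4]) / cnt[i, 1]
            sy = (w_ali * acc[i, 3] / speed + w_att * acc[i, 5]) / cnt[i, 1]
        else:
            sx = 0.0
            sy = 0.0
        dxr = hx + sx
        dyr = hy + sy
        dist = math.sqrt(xi * xi + yi * yi)
        if dist > home_r:
            dxr -= w_roost * xi / dist
            dyr -= w_roost * yi / dist
        nor = math.sqrt(dxr * dxr + dyr * dyr)
        if nor < 1e-12:
            dxr = hx
            dyr = hy
            nor = 1.0
        dxr /= nor
        dyr /= nor
        if noise > 0.0:
            th = (np.random.random() * 2.0 - 1.0) * noise
            c = math.cos(th)
            s = math.sin(th)
            tx = c * dxr - s * dyr
            dyr = s * dxr + c * dyr
            dxr = tx
        newv[i, 0] = speed * dxr
        newv[i, 1] = speed * dyr
    for i in range(n):
        vel[i, 0] = newv[i, 0]
        vel[i, 1] = newv[i, 1]
        pos[i, 0] += vel[i, 0]
        pos[i, 1] += vel[i, 1]


@njit(cache=True, fastmath=True)
def _forage_kernel(pos, state, fly_pos, fly_toxic, fly_alive,
                   cell_start, cell_items, nx, ny, cell_size, half,
                   Rc2, pi_prob, t, n_events,
                   ev_t, ev_bird, ev_fly, ev_toxic,
                   saw_good, saw_bad, order):
    n = pos.shape[0]
    # randomized bird order removes index bias among same-step claimants
    for i in range(n):
        order[i] = i
    for i in range(n - 1, 0, -1):
        j = np.random.randint(0, i + 1)
        tmp = order[i]
        order[i] = order[j]
        order[j] = tmp
    n_new = 0
    reach = half + cell_size
    for k in range(n):
        b = order[k]
        st = state[b]
        if st == NON_EATER:
            continue
        x = pos[b, 0]
        y = pos[b, 1]
        if x < -reach or x > reach or y < -reach or y > reach:
            continue
        ix0 = int((x + half) / cell_size)
        iy0 = int((y + half) / cell_size)
        if ix0 < 0:
            ix0 = 0
        if ix0 > nx - 1:
            ix0 = nx - 1
        if iy0 < 0:
            iy0 = 0
        if iy0 > ny - 1:
            iy0 = ny - 1
        best = -1
        bestd2 = Rc2
        for ix in range(max(0, ix0 - 1), min(nx, ix0 + 2)):
            for iy in range(max(0, iy0 - 1), min(ny, iy0 + 2)):
                c = ix * ny + iy
                for idx in range(cell_start[c], cell_start[c + 1]):
                    f = cell_items[idx]
                    if not fly_alive[f]:
                        continue
                    dx = fly_pos[f, 0] - x
                    dy = fly_pos[f, 1] - y
                    d2 = dx * dx + dy * dy
                    if d2 <= Rc2 and (best < 0 or d2 < bestd2
                                      or (d2 == bestd2 and f < best)):
                        best = f
                        bestd2 = d2
        if best < 0:
            continue
        if st == UNDECIDED:
            if np.random.random() >= pi_prob:
                continue
        # consume: first claimant wins; the fly can never be eaten twice
        fly_alive[best] = False
        e = n_events + n_new
        ev_t[e] = t
        ev_bird[e] = b
        ev_fly[e] = best
        ev_toxic[e] = fly_toxic[best]
        if fly_toxic[best]:
            saw_bad[b] = True
        else:
            saw_good[b] = True
        n_new += 1
    return n_new


@njit(cache=True, fastmath=True)
def _observe_kernel(pos, state, Ro2, e_lo, e_hi, ev_bird, ev_toxic,
                    obs_mat, obs_cnt, saw_good, saw_bad):
    n = pos.shape[0]
    for e in range(e_lo, e_hi):
        b = ev_bird[e]
        cnt = 0
        for j in range(n):
            if j == b:
                continue
            dx = pos[j, 0] - pos[b, 0]
            dy = pos[j, 1] - pos[b, 1]
            if dx * dx + dy * dy <= Ro2:
                obs_mat[e, cnt] = j
                cnt += 1
                if ev_toxic[e]:
                    saw_bad[j] = True
                else:
                    saw_good[j] = True
        obs_cnt[e] = cnt
    # commit all state updates of this step together; bad dominates good
    for i in range(n):
        if saw_bad[i]:
            state[i] = NON_EATER
        elif saw_good[i]:
            state[i] = EATER
        saw_bad[i] = False
        saw_good[i] = False


@njit(cache=True, fastmath=True)
def _run_kernel(pos, vel, state, fly_pos, fly_toxic, fly_alive,
                cell_start, cell_items, nx, ny, cell_size, half,
                speed, R2, rrep2, w_rep, w_ali, w_att, home_r, w_roost, noise,
                Rc2, Ro2, pi_prob, T_max, stride, seed,
                rec_t, rec_p, rec_eat, rec_non, rec_alive,
                ev_t, ev_bird, ev_fly, ev_toxic, obs_mat, obs_cnt):
    np.random.seed(seed)
    n = pos.shape[0]
    newv = np.empty_like(vel)
    saw_good = np.zeros(n, dtype=np.bool_)
    saw_bad = np.zeros(n, dtype=np.bool_)
    order = np.empty(n, dtype=np.int64)

    n_alive = 0
    for f in range(fly_alive.shape[0]):
        if fly_alive[f]:
            n_alive += 1
    n_eat = 0
    n_non = 0
    for i in range(n):
        if state[i] == EATER:
            n_eat += 1
        elif state[i] == NON_EATER:
            n_non += 1

    n_events = 0
    rec_t[0] = 0
    rec_p[0] = n_eat / n
    rec_eat[0] = n_eat
    rec_non[0] = n_non
    rec_alive[0] = n_alive
    n_rec = 1
    t = 0
    term = 0  # time_out
    while t < T_max:
        _movement_kernel(pos, vel, newv, speed, R2, rrep2, w_rep, w_ali,
                         w_att, home_r, w_roost, noise)
        n_new = _forage_kernel(pos, state, fly_pos, fly_toxic, fly_alive,
                               cell_start, cell_items, nx, ny, cell_size,
                               half, Rc2, pi_prob, t, n_events,
                               ev_t, ev_bird, ev_fly, ev_toxic,
                               saw_good, saw_bad, order)
        if n_new > 0:
            _observe_kernel(pos, state, Ro2, n_events, n_events + n_new,
                            ev_bird, ev_toxic, obs_mat, obs_cnt,
                            saw_good, saw_bad)
            n_events += n_new
            n_alive -= n_new
            n_eat = 0
            n_non = 0
            for i in range(n):
                if state[i] == EATER:
                    n_eat += 1
                elif state[i] == NON_EATER:
                    n_non += 1
        t += 1
        if t % stride == 0:
            rec_t[n_rec] = t
            rec_p[n_rec] = n_eat / n
            rec_eat[n_rec] = n_eat
            rec_non[n_rec] = n_non
            rec_alive[n_rec] = n_alive
            n_rec += 1
        if n_alive == 0:
            term = 1
            break
        if n_non == n:
            term = 2
            break
    if rec_t[n_rec - 1] != t:
        rec_t[n_rec] = t
        rec_p[n_rec] = n_eat / n
        rec_eat[n_rec] = n_eat
        rec_non[n_rec] = n_non
        rec_alive[n_rec] = n_alive
        n_rec += 1
    return t, n_events, n_rec, term


# ======================================================================
# Section 4 — ABM python surface
# ======================================================================

def _build_fly_grid(fly_pos: np.ndarray, half: float, cell_size: float):
    """Cell-list index over the (static) lanternfly positions."""
    nx = int(np.ceil(2.0 * half / cell_size)) + 1
    ny = nx
    ix = np.clip(((fly_pos[:, 0] + half) / cell_size).astype(np.int64), 0, nx - 1)
    iy = np.clip(((fly_pos[:, 1] + half) / cell_size).astype(np.int64), 0, ny - 1)
    cell_id = ix * ny + iy
    order = np.argsort(cell_id, kind="stable")
    counts = np.bincount(cell_id, minlength=nx * ny)
    cell_start = np.zeros(nx * ny + 1, dtype=np.int64)
    np.cumsum(counts, out=cell_start[1:])
    return cell_start, order.astype(np.int64), nx, ny


def init_world(config: AbmConfig, seed: int) -> WorldState:
    """Build the initial world, fully determined by ``seed``.

    Birds start undecided, uniform in a disc of ``init_disc_radius`` around
    the roost (the origin) with random headings at cruise speed; lanternfly
    are uniform in the arena square, each toxic independently with
    probability q.
    """
    rng = np.random.default_rng(seed)
    n, nl = config.N, config.N_l
    half = config.arena_half_width

    r = config.init_disc_radius * np.sqrt(rng.random(n))
    th = rng.random(n) * 2 * np.pi
    pos = np.column_stack([r * np.cos(th), r * np.sin(th)])
    hd = rng.random(n) * 2 * np.pi
    vel = config.movement.speed * np.column_stack([np.cos(hd), np.sin(hd)])
    state = np.full(n, UNDECIDED, dtype=np.int8)

    fly_pos = rng.uniform(-half, half, size=(nl, 2))
    fly_toxic = rng.random(nl) < config.q
    fly_alive = np.ones(nl, dtype=np.bool_)

    cell_start, cell_items, nx, ny = _build_fly_grid(fly_pos, half, config.R_c)
    return WorldState(pos, vel, state, fly_pos, fly_toxic, fly_alive,
                      cell_start, cell_items, nx, ny, config.R_c)


def make_world(config: AbmConfig, bird_pos, bird_vel, bird_state,
               fly_pos, fly_toxic) -> WorldState:
    """Build a world from explicit agent arrays (for crafted scenarios)."""
    pos = np.asarray(bird_pos, dtype=float).reshape(-1, 2).copy()
    vel = np.asarray(bird_vel, dtype=float).reshape(-1, 2).copy()
    state = np.asarray(bird_state, dtype=np.int8).copy()
    fpos = np.asarray(fly_pos, dtype=float).reshape(-1, 2).copy()
    ftox = np.asarray(fly_toxic, dtype=np.bool_).copy()
    if not (len(pos) == len(vel) == len(state)):
        raise ValidationError("bird arrays must have equal length")
    if len(fpos) != len(ftox):
        raise ValidationError("fly arrays must have equal length")
    cell_start, cell_items, nx, ny = _build_fly_grid(
        fpos, config.arena_half_width, config.R_c)
    return WorldState(pos, vel, state, fpos, ftox,
                      np.ones(len(fpos), dtype=np.bool_),
                      cell_start, cell_items, nx, ny, config.R_c)


def _seed_kernel_rng(rng) -> None:
    if rng is None:
        return
    if isinstance(rng, (int, np.integer)):
        _nb_seed(int(rng) & 0x7FFFFFFF)
    elif isinstance(rng, np.random.Generator):
        _nb_seed(int(rng.integers(0, 2**31)))
    else:
        raise TypeError("rng must be None, an int seed, or a numpy Generator")


def movement_step(world: WorldState, config: AbmConfig, rng=None) -> WorldState:
    """Advance every bird one movement update (stand-in zonal flocking).

    Velocities are rebuilt synchronously from neighbours within R (repulsion
    with priority at short range, alignment/attraction otherwise), a homing
    turn toward the roost beyond the home radius, and bounded rotational
    noise; positions advance one step at constant cruise speed.
    """
    w = world.copy()
    _seed_kernel_rng(rng)
    mp = config.movement
    _movement_kernel(w.pos, w.vel, np.empty_like(w.vel), mp.speed,
                     config.R ** 2, mp.repulsion_radius ** 2, mp.w_repulsion,
                     mp.w_align, mp.w_attract, mp.home_radius, mp.w_roost,
                     mp.noise)
    if not np.all(np.isfinite(w.pos)):
        raise RuntimeError("movement produced non-finite positions")
    return w


def foraging_step(world: WorldState, config: AbmConfig, rng=None):
    """One foraging sweep: birds try/eat lanternfly within the encounter radius.

    Undecided birds try a fly with probability pi per step; committed eaters
    eat deterministically; non-eaters never try.  Birds are visited in
    randomized order so simultaneous claims on one fly carry no index bias.
    Own outcomes are staged on the world's pending flags and commit in
    :func:`observation_step`.  Returns ``(world, events)``.
    """
    w = world.copy()
    _seed_kernel_rng(rng)
    n = w.n_birds
    ev_t = np.zeros(n, dtype=np.int64)
    ev_bird = np.zeros(n, dtype=np.int64)
    ev_fly = np.zeros(n, dtype=np.int64)
    ev_toxic = np.zeros(n, dtype=np.bool_)
    order = np.empty(n, dtype=np.int64)
    n_new = _forage_kernel(w.pos, w.state, w.fly_pos, w.fly_toxic, w.fly_alive,
                           w.cell_start, w.cell_items, w.nx, w.ny, w.cell_size,
                           config.arena_half_width, config.R_c ** 2, config.pi,
                           w.t, 0, ev_t, ev_bird, ev_fly, ev_toxic,
                           w.saw_good, w.saw_bad, order)
    events = [EatEvent(t=int(ev_t[i]), bird_id=int(ev_bird[i]),
                       fly_id=int(ev_fly[i]), toxic=bool(ev_toxic[i]))
              for i in range(n_new)]
    return w, events


def observation_step(events: Sequence[EatEvent], world: WorldState,
                     config: AbmConfig) -> WorldState:
    """Broadcast same-step eating outcomes to birds within R_o and commit states.

    Every other bird within R_o of an eater adopts the observed outcome
    (good -> eater, bad -> non_eater) regardless of its prior state; with
    several conflicting outcomes in one step the negative one dominates, so
    the result is invariant under permutation of the events.  Observer ids
    are appended to the event records (eater excluded).
    """
    w = world.copy()
    n_ev = len(events)
    if n_ev == 0:
        # still commit any pending own-outcome flags
        _observe_kernel(w.pos, w.state, config.R_o ** 2, 0, 0,
                        np.zeros(1, dtype=np.int64), np.zeros(1, dtype=np.bool_),
                        np.zeros((1, 1), dtype=np.int32),
                        np.zeros(1, dtype=np.int64), w.saw_good, w.saw_bad)
        return w
    ev_bird = np.array([e.bird_id for e in events], dtype=np.int64)
    ev_toxic = np.array([e.toxic for e in events], dtype=np.bool_)
    obs_mat = np.zeros((n_ev, max(1, w.n_birds - 1)), dtype=np.int32)
    obs_cnt = np.zeros(n_ev, dtype=np.int64)
    _observe_kernel(w.pos, w.state, config.R_o ** 2, 0, n_ev, ev_bird,
                    ev_toxic, obs_mat, obs_cnt, w.saw_good, w.saw_bad)
    for i, e in enumerate(events):
        e.observers = tuple(int(x) for x in obs_mat[i, : obs_cnt[i]])
    return w


def advance(world: WorldState, config: AbmConfig, rng=None):
    """One full time step: movement, foraging, observation, clock tick."""
    w = movement_step(world, config, rng)
    w, events = foraging_step(w, config, None)
    w = observation_step(events, w, config)
    w.t += 1
    return w, events


def run(config: AbmConfig, seed: int | None = None) -> SimResult:
    """Run one simulation to termination.

    Iterates movement -> foraging -> observation until all lanternfly are
    consumed, all birds are non-eaters, or T_max elapses.  The eater
    proportion is recorded every ``record_stride`` steps and exactly at
    termination.  Fully reproducible from ``seed``.
    """
    if seed is None:
        seed = config.seed
    world = init_world(config, seed)
    mp = config.movement
    n_rec_max = config.T_max // config.record_stride + 3
    rec_t = np.zeros(n_rec_max, dtype=np.int64)
    rec_p = np.zeros(n_rec_max, dtype=np.float64)
    rec_eat = np.zeros(n_rec_max, dtype=np.int64)
    rec_non = np.zeros(n_rec_max, dtype=np.int64)
    rec_alive = np.zeros(n_rec_max, dtype=np.int64)
    nl = config.N_l
    ev_t = np.zeros(nl, dtype=np.int64)
    ev_bird = np.zeros(nl, dtype=np.int64)
    ev_fly = np.zeros(nl, dtype=np.int64)
    ev_toxic = np.zeros(nl, dtype=np.bool_)
    obs_mat = np.zeros((nl, max(1, config.N - 1)), dtype=np.int32)
    obs_cnt = np.zeros(nl, dtype=np.int64)

    t_end, n_events, n_rec, term = _run_kernel(
        world.pos, world.vel, world.state, world.fly_pos, world.fly_toxic,
        world.fly_alive, world.cell_start, world.cell_items, world.nx,
        world.ny, world.cell_size, config.arena_half_width,
        mp.speed, config.R ** 2, mp.repulsion_radius ** 2, mp.w_repulsion,
        mp.w_align, mp.w_attract, mp.home_radius, mp.w_roost, mp.noise,
        config.R_c ** 2, config.R_o ** 2, config.pi,
        config.T_max, config.record_stride, int(seed) & 0x7FFFFFFF,
        rec_t, rec_p, rec_eat, rec_non, rec_alive,
        ev_t, ev_bird, ev_fly, ev_toxic, obs_mat, obs_cnt,
    )
    world.t = int(t_end)
    if not np.all(np.isfinite(world.pos)):
        raise RuntimeError("simulation produced non-finite positions")
    log = EventLog(
        t=ev_t[:n_events].copy(),
        bird_id=ev_bird[:n_events].copy(),
        fly_id=ev_fly[:n_events].copy(),
        toxic=ev_toxic[:n_events].copy(),
        n_observers=obs_cnt[:n_events].copy(),
        observers=[obs_mat[i, : obs_cnt[i]].astype(np.int64)
                   for i in range(n_events)],
        n_birds=config.N,
        n_steps=int(t_end),
    )
    termination = _TERMINATIONS[term]
    logger.info("run seed=%s q=%.3f ended at t=%d (%s), final p=%.3f",
                seed, config.q, t_end, termination, rec_p[n_rec - 1])
    return SimResult(
        times=rec_t[:n_rec].copy(),
        p_series=rec_p[:n_rec].copy(),
        final_p=float(rec_p[n_rec - 1]),
        termination=termination,
        event_log=log,
        seed=int(seed),
        config=config,
        n_eaters_series=rec_eat[:n_rec].copy(),
        n_non_eaters_series=rec_non[:n_rec].copy(),
        n_flies_alive_series=rec_alive[:n_rec].copy(),
    )


# ======================================================================
# Section 5 — experiments: sweeps, trajectories, rate estimation, overlay
# ======================================================================

def desk_scale_settings(config: AbmConfig | None = None):
    """Desk-scale study conditions: q in [0, 0.6] step 0.05, 50 replicates,
    N_l = 200, T_max = 2e5.  Returns ``(q_grid, n_replicates, abm_config)``."""
    base = config or AbmConfig()
    q_grid = np.round(np.arange(0.0, 0.6001, 0.05), 10)
    return q_grid, 50, base.replace(N_l=200, T_max=200_000)


def paper_scale_settings(config: AbmConfig | None = None):
    """Full-scale study conditions: q in [0, 1] step 0.01, 2000 replicates,
    N_l = 500, T_max = 6e6.  Orders of magnitude more compute than the
    desk-scale settings."""
    base = config or AbmConfig()
    q_grid = np.round(np.arange(0.0, 1.0001, 0.01), 10)
    return q_grid, 2000, base.replace(N_l=500, T_max=6_000_000)


@dataclass
class RateEstimates:
    """ODE rates counted from event logs.

    ``r_i_hat``: eating events per bird per live time step.  ``r_o_hat``:
    fraction of eating events observed by at least one other bird — NaN and
    ``defined`` False when there were no events at all.
    """

    r_i_hat: float
    r_o_hat: float
    defined: bool
    n_events: int
    n_observed: int
    n_bird_steps: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SweepTable:
    """Per-q long-term statistics of the eater proportion across replicates."""

    table: pd.DataFrame  # columns: q, n_replicates, mean_final_p, std_final_p
    finals: np.ndarray  # shape (n_q, n_replicates)
    rates: RateEstimates | None
    base_seed: int


@dataclass
class TrajectoryTable:
    """Per-q per-time mean/std of the eater proportion, plus a rolling mean.

    All series share one time grid; replicates that terminate early are
    right-padded with their final value so every replicate contributes to
    every time point.  The smoothed series is a centred rolling average of
    the mean with truncated edges (same length as the raw series).
    """

    times: np.ndarray
    mean_p: pd.DataFrame  # index: time, one column per q
    std_p: pd.DataFrame
    smoothed: pd.DataFrame
    window: int
    base_seed: int


def estimate_rates(event_logs: Iterable[EventLog], N: int,
                   total_steps: int) -> RateEstimates:
    """Count ODE rates from pooled event logs.

    ``r_i_hat = (total events) / (N * total_steps)`` — interactions per bird
    per live time step, plugging directly into the ODE.  ``r_o_hat`` is the
    fraction of events with at least one observer; with zero events it is
    flagged undefined (NaN), never silently 0.
    """
    n_events = 0
    n_observed = 0
    for log in event_logs:
        n_events += log.n_events
        n_observed += log.n_observed
    if N <= 0 or total_steps <= 0:
        raise ValidationError("N and total_steps must be positive")
    r_i_hat = n_events / (N * total_steps)
    if n_events == 0:
        return RateEstimates(r_i_hat=0.0, r_o_hat=math.nan, defined=False,
                             n_events=0, n_observed=0,
                             n_bird_steps=N * total_steps)
    return RateEstimates(r_i_hat=r_i_hat, r_o_hat=n_observed / n_events,
                         defined=True, n_events=n_events,
                         n_observed=n_observed, n_bird_steps=N * total_steps)


def _experiment_seed(base_seed: int, i_q: int, n_replicates: int, k: int) -> int:
    """Replicate k of grid row i_q: distinct, auditable seed streams."""
    return base_seed + i_q * n_replicates + k


def sweep_longterm(q_grid, n_replicates: int, config: AbmConfig,
                   base_seed: int, collect_rates: bool = True) -> SweepTable:
    """The long-term sweep: replicate runs per q, mean/std of the final p.

    Runs ``n_replicates`` simulations per q value (seeds
    ``base_seed + i_q * n_replicates + k``), collects each run's recorded
    final eater proportion, and aggregates mean and standard deviation
    (ddof=1, 0 for a single replicate).  With ``collect_rates`` the event
    logs are pooled on the fly into a single :class:`RateEstimates`.
    """
    q_grid = np.asarray(q_grid, dtype=float)
    if np.any(q_grid < 0) or np.any(q_grid > 1):
        raise ValidationError("q_grid values must lie in [0, 1]")
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    finals = np.zeros((len(q_grid), n_replicates))
    n_events = n_observed = steps_total = 0
    for i, q in enumerate(q_grid):
        cfg = config.replace(q=float(q))
        for k in range(n_replicates):
            seed = _experiment_seed(base_seed, i, n_replicates, k)
            try:
                res = run(cfg, seed)
            except Exception as exc:  # pragma: no cover - diagnostic path
                raise RuntimeError(f"ABM run failed at q={q}, seed={seed}") from exc
            finals[i, k] = res.final_p
            if collect_rates:
                n_events += res.event_log.n_events
                n_observed += res.event_log.n_observed
                steps_total += res.event_log.n_steps
        logger.info("sweep q=%.3f done: mean final p=%.3f", q, finals[i].mean())
    stds = finals.std(axis=1, ddof=1) if n_replicates > 1 else np.zeros(len(q_grid))
    table = pd.DataFrame({
        "q": q_grid,
        "n_replicates": n_replicates,
        "mean_final_p": finals.mean(axis=1),
        "std_final_p": stds,
    })
    rates = None
    if collect_rates:
        if n_events == 0:
            rates = RateEstimates(0.0, math.nan, False, 0, 0,
                                  config.N * steps_total)
        else:
            rates = RateEstimates(n_events / (config.N * steps_total),
                                  n_observed / n_events, True, n_events,
                                  n_observed, config.N * steps_total)
    return SweepTable(table=table, finals=finals, rates=rates,
                      base_seed=base_seed)


def _padded_series(res: SimResult, grid: np.ndarray) -> np.ndarray:
    """Sample a run's recorded p on the common grid, padding forward with the
    final value after termination (padding is a no-op for full-length runs)."""
    # recorded times are 0, stride, 2*stride, ..., plus the exact final t;
    # forward-fill between records, final value after termination
    idx = np.searchsorted(res.times, grid, side="right") - 1
    out = res.p_series[np.clip(idx, 0, len(res.p_series) - 1)]
    out[grid > res.times[-1]] = res.final_p
    return out


def trajectory_experiment(q_grid, n_replicates: int, config: AbmConfig,
                          base_seed: int, window: int = 10) -> TrajectoryTable:
    """Per-q mean/std trajectories of the eater proportion across replicates.

    Replicate runs are sampled on the common recording grid; early-terminated
    runs carry their final value forward.  A centred rolling average of width
    ``window`` (in recorded samples; edges truncated via min_periods=1)
    smooths the mean series.
    """
    q_grid = np.asarray(q_grid, dtype=float)
    if window < 1:
        raise ValidationError("window must be >= 1")
    grid = np.arange(0, config.T_max + 1, config.record_stride, dtype=np.int64)
    mean_cols, std_cols = {}, {}
    for i, q in enumerate(q_grid):
        cfg = config.replace(q=float(q))
        acc = np.zeros((n_replicates, len(grid)))
        for k in range(n_replicates):
            seed = _experiment_seed(base_seed, i, n_replicates, k)
            res = run(cfg, seed)
            acc[k] = _padded_series(res, grid)
        mean_cols[float(q)] = acc.mean(axis=0)
        std_cols[float(q)] = acc.std(axis=0, ddof=1) if n_replicates > 1 \
            else np.zeros(len(grid))
        logger.info("trajectories q=%.3f done", q)
    mean_df = pd.DataFrame(mean_cols, index=grid)
    std_df = pd.DataFrame(std_cols, index=grid)
    smoothed = mean_df.rolling(window, center=True, min_periods=1).mean()
    return TrajectoryTable(times=grid, mean_p=mean_df, std_p=std_df,
                           smoothed=smoothed, window=window,
                           base_seed=base_seed)


def collapse_q(sweep: SweepTable, level: float = 0.05) -> float:
    """First grid q at which the mean long-term eater proportion drops below
    ``level`` (NaN if it never does)."""
    below = sweep.table["mean_final_p"].to_numpy() < level
    if not below.any():
        return math.nan
    return float(sweep.table["q"].to_numpy()[np.argmax(below)])


@dataclass
class ComparisonResult:
    """ODE-vs-ABM overlay: table plus per-q discrepancy in std units."""

    table: pd.DataFrame
    r_i_hat: float
    r_o_hat: float
    threshold_q: float
    pooled_std: float  # pooled replicate std over below-threshold q rows

    def to_dict(self) -> dict:
        return {
            "r_i_hat": self.r_i_hat,
            "r_o_hat": self.r_o_hat,
            "threshold_q": self.threshold_q,
            "pooled_std": self.pooled_std,
        }


def overlay_comparison(sweep: SweepTable | TrajectoryTable,
                       rates: RateEstimates, p0: float | None = None,
                       config: AbmConfig | None = None):
    """Overlay the analytic prediction on simulated statistics.

    For a :class:`SweepTable`: the collective control equilibrium
    ``max(0, 1 - (r_o_hat + 1) q / r_o_hat)`` against per-q mean +/- std,
    with the per-q discrepancy in units of the replicate std and the pooled
    std over below-threshold rows.  For a :class:`TrajectoryTable`: the
    explicit solution with (r_i_hat, r_o_hat, p0) against smoothed means;
    ``p0`` defaults to one first convert, 1/N.  Refuses to overlay when
    r_o_hat is undefined.
    """
    if not rates.defined:
        raise ValidationError(
            "r_o_hat is undefined (no eating events); cannot overlay")
    r_o, r_i = rates.r_o_hat, rates.r_i_hat
    thr = q_threshold(r_o)
    if isinstance(sweep, SweepTable):
        tbl = sweep.table.copy()
        qs = tbl["q"].to_numpy()
        ode = np.maximum(0.0, 1.0 - (r_o + 1.0) * qs / r_o)
        diff = np.abs(ode - tbl["mean_final_p"].to_numpy())
        std = tbl["std_final_p"].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            disc = np.where(std > 0, diff / std,
                            np.where(diff == 0, 0.0, np.inf))
        tbl["ode_equilibrium"] = ode
        tbl["abs_diff"] = diff
        tbl["discrepancy_std_units"] = disc
        below = qs < thr
        pooled = float(np.sqrt(np.mean(std[below] ** 2))) if below.any() else 0.0
        return ComparisonResult(table=tbl, r_i_hat=r_i, r_o_hat=r_o,
                                threshold_q=thr, pooled_std=pooled)
    if isinstance(sweep, TrajectoryTable):
        n_birds = (config or AbmConfig()).N
        if p0 is None:
            p0 = 1.0 / n_birds  # one first convert ignites the ODE
        rows = []
        for q in sweep.mean_p.columns:
            params = ModelParams(r_i=r_i, r_o=r_o, q=float(q), p0=p0,
                                 allow_large_ro=True)
            ode_curve = explicit_solution(sweep.times.astype(float), params)
            rows.append(pd.DataFrame({
                "q": float(q),
                "t": sweep.times,
                "abm_mean": sweep.mean_p[q].to_numpy(),
                "abm_smoothed": sweep.smoothed[q].to_numpy(),
                "abm_std": sweep.std_p[q].to_numpy(),
                "ode_p": ode_curve.p_values,
            }))
        tbl = pd.concat(rows, ignore_index=True)
        return ComparisonResult(table=tbl, r_i_hat=r_i, r_o_hat=r_o,
                                threshold_q=thr, pooled_std=math.nan)
    raise TypeError("expected a SweepTable or TrajectoryTable")


def plot_sweep_comparison(comp: ComparisonResult):
    """Long-term eater proportion vs q: simulation mean +/- std with the
    analytic collective control equilibrium superimposed."""
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    t = comp.table
    ax.errorbar(t["q"], t["mean_final_p"], yerr=t["std_final_p"],
                fmt="ko-", capsize=3, label="simulation mean ± s.d.")
    ax.plot(t["q"], t["ode_equilibrium"], "b--", label="CBC equilibrium (ODE)")
    ax.axvline(comp.threshold_q, color="grey", ls=":", lw=1,
               label=f"q threshold = {comp.threshold_q:.3f}")
    ax.set_xlabel("proportion toxic lanternfly, q")
    ax.set_ylabel("long-term proportion of eaters, p")
    ax.legend(frameon=False)
    fig.tight_layout()
    return fig


def plot_trajectory_comparison(comp: ComparisonResult):
    """Eater proportion over time per q: smoothed simulation means with the
    explicit ODE solutions superimposed."""
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for q, grp in comp.table.groupby("q"):
        (line,) = ax.plot(grp["t"], grp["abm_smoothed"], label=f"q={q:g}")
        ax.plot(grp["t"], grp["ode_p"], color="black", lw=0.8)
        line.set_alpha(0.8)
    ax.set_xlabel("time step")
    ax.set_ylabel("proportion of eaters, p")
    ax.legend(frameon=False, fontsize=7, ncol=2)
    fig.tight_layout()
    return fig


# ======================================================================
# Section 6 — configuration files, manifests, atomic output
# ======================================================================

@dataclass(frozen=True)
class ExperimentConfig:
    """Grids and replication for the sweep/trajectory experiments."""

    q_min: float = 0.0
    q_max: float = 0.6
    q_step: float = 0.05
    n_replicates: int = 50
    window: int = 10
    paper_scale: bool = False

    def __post_init__(self):
        if not (0 <= self.q_min <= self.q_max <= 1):
            raise ValidationError("require 0 <= q_min <= q_max <= 1")
        if self.q_step <= 0:
            raise ValidationError("q_step must be positive")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if self.window < 1:
            raise ValidationError("window must be >= 1")

    def q_grid(self) -> np.ndarray:
        return np.round(np.arange(self.q_min, self.q_max + self.q_step / 2,
                                  self.q_step), 10)


@dataclass(frozen=True)
class OutputConfig:
    directory: str = "results"
    stride: int = 1000

    def __post_init__(self):
        if self.stride < 1:
            raise ValidationError("output.stride must be >= 1")


@dataclass(frozen=True)
class RunConfig:
    """Top-level configuration: model, ABM, experiment, output, seed."""

    model: ModelParams = field(default_factory=ModelParams)
    abm: AbmConfig = field(default_factory=AbmConfig)
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    output: OutputConfig = field(default_factory=OutputConfig)
    seed: int = 1

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _from_dict(cls, data: Mapping, path: str):
    if not isinstance(data, Mapping):
        raise ValidationError(f"{path or 'config'}: expected a mapping, got {type(data).__name__}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValidationError(
            f"{path or 'config'}: unknown key(s) {sorted(unknown)}; "
            f"valid keys are {sorted(fields)}")
    kwargs = {}
    for name, value in data.items():
        f = fields[name]
        sub = {"model": ModelParams, "abm": AbmConfig,
               "experiment": ExperimentConfig, "output": OutputConfig,
               "movement": MovementParams}.get(name)
        if sub is not None and dataclasses.is_dataclass(sub):
            kwargs[name] = _from_dict(sub, value, f"{path}{name}.")
        else:
            kwargs[name] = value
    try:
        return cls(**kwargs)
    except ValidationError as exc:
        raise ValidationError(f"{path}{exc}") from None
    except TypeError as exc:
        raise ValidationError(f"{path or 'config'}: {exc}") from None


def _deep_update(base: dict, overrides: Mapping) -> dict:
    for key, value in overrides.items():
        if isinstance(value, Mapping) and isinstance(base.get(key), dict):
            _deep_update(base[key], value)
        else:
            base[key] = value
    return base


def load_config(path: str | os.PathLike | None = None,
                overrides: Mapping | None = None) -> RunConfig:
    """Load a YAML config file, apply overrides, validate.

    An empty or absent file yields the reference defaults.  Unknown keys are
    rejected with their field path; overrides (e.g. from CLI flags) win over
    file values.
    """
    import yaml

    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValidationError(f"{path}: top level must be a mapping")
            data = loaded
    if overrides:
        _deep_update(data, dict(overrides))
    return _from_dict(RunConfig, data, "")


def config_hash(config: RunConfig) -> str:
    """Stable hash of the effective configuration, for provenance manifests."""
    payload = json.dumps(config.to_dict(), sort_keys=True, default=float)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _atomic_write(path: str, data: str) -> None:
    d = os.path.dirname(path) or "."
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_outputs(results: Mapping[str, object], config: RunConfig,
                  out_dir: str | os.PathLike | None = None) -> dict[str, str]:
    """Write result tables/summaries atomically with a provenance manifest.

    DataFrames become CSV, everything else JSON; each file is written to a
    temporary name and renamed, so partial writes are impossible.  The
    manifest records the effective config, its hash, the seed, a timestamp
    and the software version; re-running with the same inputs reproduces
    identical data files (only the manifest timestamp differs).
    """
    out_dir = str(out_dir or config.output.directory)
    if not os.path.isdir(out_dir):
        os.makedirs(out_dir, exist_ok=True)
        logger.info("created output directory %s", out_dir)
    written = {}
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            path = os.path.join(out_dir, f"{name}.csv")
            _atomic_write(path, obj.to_csv(index=False))
        else:
            path = os.path.join(out_dir, f"{name}.json")
            _atomic_write(path, json.dumps(obj, indent=2, default=float))
        written[name] = path
    manifest = {
        "config": config.to_dict(),
        "config_hash": config_hash(config),
        "seed": config.seed,
        "timestamp": _time.strftime("%Y-%m-%dT%H:%M:%S"),
        "version": __version__,
        "files": sorted(os.path.basename(p) for p in written.values()),
    }
    mpath = os.path.join(out_dir, "manifest.json")
    _atomic_write(mpath, json.dumps(manifest, indent=2, default=float))
    written["manifest"] = mpath
    return written
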