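"""Stochastic kinetics of the RTK/PI3K chemosensing network.

The cell senses a chemoattractant (PDGF, denoted F) through four reactions:

    R1:  RTK + F  -> RTKF          rate k1·[F]·X_RTK
    R2:  RTKF     -> RTK + F       rate k2·X_RTKF
    R3:  RTKF + PI3K -> RTKF + PI3K_A   rate k3·X_RTKF·X_PI3K
    R4:  PI3K_A   -> PI3K          rate k4·X_PI3KA

[F] is treated as an external, non-depleted parameter (cell consumption of
chemoattractant is negligible on the 4-h horizon).  The network conserves
RTK + RTKF and PI3K + PI3K_A exactly.

Three steppers are provided:

* :func:`ssa_step` — the exact Gillespie direct method (one event per call),
* :func:`tau_leap_step` — Poisson tau-leaping with reject-and-halve handling
  of negative excursions and an exact-SSA fallback for stiff sub-intervals,
* :func:`ode_limit` — the deterministic mass-action limit, used as a
  cross-checking oracle.

Tau selection follows the bounded relative-propensity-change criterion of
Cao-style leap control, clamped afterwards to the simulator's [0.5, 1.5] s
operating range (:class:`LeapPolicy`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "SPECIES",
    "STOICHIOMETRY",
    "DEFAULT_RTK_TOTAL",
    "DEFAULT_PI3K_TOTAL",
    "AbsorbingStateError",
    "ReactionNetwork",
    "ReactionState",
    "LeapPolicy",
    "propensities",
    "ssa_step",
    "ssa_advance",
    "select_tau",
    "select_tau_unclamped",
    "tau_leap_step",
    "advance",
    "ode_limit",
    "steady_state",
]

SPECIES = ("RTK", "RTKF", "PI3K", "PI3KA")

#: rows = reactions R1..R4, columns = species (RTK, RTKF, PI3K, PI3KA)
STOICHIOMETRY = np.array(
    [
        [-1, 1, 0, 0],
        [1, -1, 0, 0],
        [0, 0, -1, 1],
        [0, 0, 1, -1],
    ],
    dtype=np.int64,
)

DEFAULT_RTK_TOTAL = 4275
DEFAULT_PI3K_TOTAL = 75_000


class AbsorbingStateError(RuntimeError):
    """Raised when all propensities vanish and no further event can fire."""


@dataclass(frozen=True)
class ReactionNetwork:
    """Rate constants and the external chemoattractant concentration.

    Units follow the literal published values: ``k1`` in nM^-1 s^-1 applied as
    k1·[F in nM]·X_RTK, ``k3`` as a second-order stochastic constant per
    RTKF–PI3K pair per second.  Both interpretations are configuration-level
    choices so alternative unit readings can be tested.
    """

    k1: float = 735.0
    k2: float = 0.01
    k3: float = 4.0e-4
    k4: float = 1.0
    conc_nM: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3", "k4"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate constant {name} must be >= 0")
        if self.conc_nM < 0:
            raise ValueError("chemoattractant concentration must be >= 0")

    def with_concentration(self, conc_nM: float) -> "ReactionNetwork":
        return replace(self, conc_nM=conc_nM)


@dataclass
class ReactionState:
    """Molecule counts of the four species plus the simulation clock (s)."""

    counts: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (4,):
            raise ValueError("counts must have shape (4,)")
        if np.any(self.counts < 0):
            raise ValueError("molecule counts must be nonnegative")

    @classmethod
    def default(cls) -> "ReactionState":
        """Published initial condition: all receptors free, all PI3K inactive."""
        return cls(np.array([DEFAULT_RTK_TOTAL, 0, DEFAULT_PI3K_TOTAL, 0]))

    @property
    def rtk(self) -> int:
        return int(self.counts[0])

    @property
    def rtkf(self) -> int:
        return int(self.counts[1])

    @property
    def pi3k(self) -> int:
        return int(self.counts[2])

    @property
    def pi3ka(self) -> int:
        return int(self.counts[3])

    def copy(self) -> "ReactionState":
        return ReactionState(self.counts.copy(), self.t)


@dataclass(frozen=True)
class LeapPolicy:
    """Leap-control parameters: error level and the clamped tau range."""

    epsilon: float = 0.03
    tau_min: float = 0.5
    tau_max: float = 1.5
    tau_floor: float = 1.0e-3

    def __post_init__(self) -> None:
        if not (0 < self.tau_min <= self.tau_max):
            raise ValueError("require 0 < tau_min <= tau_max")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


def propensities(state: ReactionState, net: ReactionNetwork) -> np.ndarray:
    """Mass-action propensities (events/s) of R1..R4 at the current state."""
    x = state.counts
    if np.any(x < 0):
        raise ValueError("molecule counts must be nonnegative")
    if net.conc_nM < 0:
        raise ValueError("chemoattractant concentration must be >= 0")
    a = np.array(
        [
            net.k1 * net.conc_nM * x[0],
            net.k2 * x[1],
            net.k3 * x[1] * x[2],
            net.k4 * x[3],
        ],
        dtype=np.float64,
    )
    if not np.all(np.isfinite(a)):
        raise FloatingPointError("non-finite propensity")
    return a


def ssa_step(
    state: ReactionState, net: ReactionNetwork, rng: np.random.Generator
) -> tuple[ReactionState, float]:
    """One exact Gillespie event: returns the next state and the elapsed time."""
    a = propensities(state, net)
    a0 = a.sum()
    if a0 <= 0.0:
        raise AbsorbingStateError("all propensities are zero")
    tau = rng.exponential(1.0 / a0)
    j = int(np.searchsorted(np.cumsum(a), rng.random() * a0, side="right"))
    j = min(j, 3)
    nxt = ReactionState(state.counts + STOICHIOMETRY[j], state.t + tau)
    return nxt, tau


def select_tau_unclamped(
    state: ReactionState, net: ReactionNetwork, policy: LeapPolicy
) -> float:
    """Leap candidate from the bounded relative-propensity-change criterion.

    For each species i the expected drift mu_i and diffusion sigma2_i of the
    count over a leap are bounded so the relative change stays below
    ``epsilon``; the candidate is the tightest of those bounds.  The bound
    scales linearly with epsilon, so the candidate vanishes as epsilon -> 0.
    """
    a = propensities(state, net)
    if a.sum() <= 0.0:
        raise AbsorbingStateError("all propensities are zero")
    mu = STOICHIOMETRY.T.astype(float) @ a
    sig2 = (STOICHIOMETRY.T.astype(float) ** 2) @ a
    bound = policy.epsilon * np.maximum(state.counts, 1).astype(float)
    tau = np.inf
    for i in range(4):
        if mu[i] != 0.0:
            tau = min(tau, bound[i] / abs(mu[i]))
        if sig2[i] > 0.0:
            tau = min(tau, bound[i] ** 2 / sig2[i])
    return float(tau)


def select_tau(
    state: ReactionState, net: ReactionNetwork, policy: LeapPolicy
) -> float:
    """Clamped leap step: the Cao-style candidate limited to [tau_min, tau_max]."""
    return float(np.clip(select_tau_unclamped(state, net, policy), policy.tau_min, policy.tau_max))


def _ssa_interval(
    counts: np.ndarray,
    net: ReactionNetwork,
    duration: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact SSA over a fixed interval; returns final counts and firings."""
    x = counts.copy()
    firings = np.zeros(4, dtype=np.int64)
    t = 0.0
    while True:
        a = np.array(
            [
                net.k1 * net.conc_nM * x[0],
                net.k2 * x[1],
                net.k3 * x[1] * x[2],
                net.k4 * x[3],
            ]
        )
        a0 = a.sum()
        if a0 <= 0.0:
            break
        dt = rng.exponential(1.0 / a0)
        if t + dt > duration:
            break
        t += dt
        j = int(np.searchsorted(np.cumsum(a), rng.random() * a0, side="right"))
        j = min(j, 3)
        x += STOICHIOMETRY[j]
        firings[j] += 1
    return x, firings


def ssa_advance(
    state: ReactionState,
    net: ReactionNetwork,
    duration: float,
    rng: np.random.Generator,
) -> tuple[ReactionState, np.ndarray]:
    """Exact SSA over a fixed interval (oracle for the approximate steppers)."""
    if duration <= 0:
        raise ValueError("duration must be > 0")
    x, firings = _ssa_interval(state.counts, net, duration, rng)
    return ReactionState(x, state.t + duration), firings


def tau_leap_step(
    state: ReactionState,
    net: ReactionNetwork,
    tau: float,
    rng: np.random.Generator,
    policy: LeapPolicy | None = None,
) -> tuple[ReactionState, np.ndarray, float]:
    """One tau-leap attempt with reject-and-halve negativity handling.

    Firing counts are Poisson with mean a_j·tau at the entry state.  If the
    update would drive a species negative the draw is discarded and tau is
    halved; once tau falls below ``policy.tau_floor`` the (now tiny) interval
    is simulated exactly by SSA instead.  Returns the new state, the per-
    reaction firing counts, and the elapsed time (which may be shorter than
    the requested tau after rejections).
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    policy = policy or LeapPolicy()
    a = propensities(state, net)
    tau_cur = float(tau)
    while True:
        k = rng.poisson(a * tau_cur)
        delta = k @ STOICHIOMETRY
        new_counts = state.counts + delta
        if np.all(new_counts >= 0):
            return (
                ReactionState(new_counts, state.t + tau_cur),
                k.astype(np.int64),
                tau_cur,
            )
        tau_cur *= 0.5
        if tau_cur < policy.tau_floor:
            x, firings = _ssa_interval(state.counts, net, tau_cur, rng)
            return ReactionState(x, state.t + tau_cur), firings, tau_cur


def advance(
    state: ReactionState,
    net: ReactionNetwork,
    duration: float,
    policy: LeapPolicy,
    rng: np.random.Generator,
) -> tuple[ReactionState, np.ndarray, int]:
    """Tau-leap the system over ``duration`` seconds, tiling exactly.

    The final sub-step is truncated so the elapsed times sum to ``duration``.
    Returns the final state, total per-reaction firing counts and the number
    of sub-steps taken.  An absorbing state simply idles to the horizon.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    cur = state.copy()
    total = np.zeros(4, dtype=np.int64)
    remaining = float(duration)
    n_steps = 0
    while remaining > 1e-12:
        a = propensities(cur, net)
        if a.sum() <= 0.0:
            cur.t += remaining
            remaining = 0.0
            break
        tau = min(select_tau(cur, net, policy), remaining)
        cur, k, elapsed = tau_leap_step(cur, net, tau, rng, policy)
        total += k
        remaining -= elapsed
        n_steps += 1
    return cur, total, n_steps


def _mass_action_rhs(t: float, x: np.ndarray, net: ReactionNetwork) -> np.ndarray:
    a = np.array(
        [
            net.k1 * net.conc_nM * x[0],
            net.k2 * x[1],
            net.k3 * x[1] * x[2],
            net.k4 * x[3],
        ]
    )
    return a @ STOICHIOMETRY


def ode_limit(
    net: ReactionNetwork,
    state0: ReactionState,
    duration: float,
    n_eval: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic mass-action trajectory (test oracle for ensemble means).

    Returns (t, X) with X of shape (4, n_eval).
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    t_eval = np.linspace(0.0, duration, n_eval)
    sol = solve_ivp(
        _mass_action_rhs,
        (0.0, duration),
        state0.counts.astype(float),
        t_eval=t_eval,
        args=(net,),
        method="LSODA",
        rtol=1e-9,
        atol=1e-9,
    )
    if not sol.success:  # pragma: no cover - LSODA handles this stiffness fine
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.t, sol.y


def steady_state(
    net: ReactionNetwork,
    rtk_total: int = DEFAULT_RTK_TOTAL,
    pi3k_total: int = DEFAULT_PI3K_TOTAL,
) -> np.ndarray:
    """Closed-form deterministic steady state (RTK, RTKF, PI3K, PI3KA).

    Receptor binding equilibrates to RTKF* = R_tot·k1[F]/(k1[F]+k2); the PI3K
    cycle then balances at PI3KA* = P_tot·k3·RTKF*/(k3·RTKF*+k4).
    """
    k1f = net.k1 * net.conc_nM
    rtkf = rtk_total * k1f / (k1f + net.k2) if (k1f + net.k2) > 0 else 0.0
    denom = net.k3 * rtkf + net.k4
    pi3ka = pi3k_total * net.k3 * rtkf / denom if denom > 0 else 0.0
    return np.array([rtk_total - rtkf, rtkf, pi3k_total - pi3ka, pi3ka])
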