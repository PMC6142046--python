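"""Automated calibration of the migration model.

The fit between simulated and measured migration is scored on two competing
features of the trajectory checkpoints: the length of the longest protrusion
(llp) and the number of protrusions (np).  Each is summarised as a
normalised histogram and compared with the target histogram through the
Bhattacharyya coefficient

    BC = sum_i sqrt(hist_target_i * hist_sim_i)   in [0, 1],

averaged over an ensemble of seeded simulations.  The nine-dimensional mixed
search space (a log grid for the protrusion modulus, integer signal
thresholds, real strain-law constants and an arithmetic grid for s_binary)
is explored by multi-objective Bayesian optimization: independent Gaussian-
process surrogates per metric and expected improvement on a random
scalarization, with a hard biological-validity gate (s_ret < s_exp <
s_birth) applied before any simulation is spent.  The result is a history of
evaluated parametrizations, its Pareto front under joint maximization, and a
balanced selection (the Pareto point maximizing the worse of the two
metrics).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from .protrusions import ElasticityParams, StrainParams, ThresholdSet
from .simulator import RunConfig, run_simulation

__all__ = [
    "Histogram",
    "MetricPair",
    "Parametrization",
    "ParameterSpace",
    "CalibrationHistory",
    "InvalidParametrizationError",
    "RangeViolationError",
    "make_histogram",
    "bhattacharyya",
    "validity_filter",
    "evaluate_parametrization",
    "propose_next",
    "pareto_front",
    "run_calibration",
]

logger = logging.getLogger("mesomig.calibration")

LLP_EDGES = np.arange(0.0, 220.0, 20.0)  # 20-um bins over [0, 200], overflow folded
NP_EDGES = np.arange(-0.5, 21.5, 1.0)  # unit integer bins over [0, 20]


class InvalidParametrizationError(ValueError):
    """Biological validity (threshold ordering) violated."""


class RangeViolationError(ValueError):
    """A parameter lies outside its search-space range."""


class EmptyDataError(ValueError):
    """No observations to histogram."""


@dataclass(frozen=True)
class Histogram:
    """Normalised histogram over fixed bin edges."""

    edges: np.ndarray
    frequencies: np.ndarray
    feature: str

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        f = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "edges", e)
        object.__setattr__(self, "frequencies", f)
        if e.ndim != 1 or np.any(np.diff(e) <= 0):
            raise ValueError("edges must be strictly increasing")
        if f.shape != (e.size - 1,):
            raise ValueError("frequencies length must be n_edges - 1")
        if np.any(f < -1e-15):
            raise ValueError("frequencies must be >= 0")
        if abs(f.sum() - 1.0) > 1e-12:
            raise ValueError("frequencies must sum to 1")


def make_histogram(values, feature: str) -> Histogram:
    """Histogram checkpoint observations into the fixed calibration bins.

    llp uses 20-um bins over [0, 200] with overflow folded into the last bin
    (zero lengths count in the first bin); np uses unit-width integer bins
    over [0, 20], overflow likewise folded.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise EmptyDataError("cannot histogram an empty sample")
    if np.any(v < 0):
        raise ValueError("values must be nonnegative")
    if feature == "llp":
        edges = LLP_EDGES
    elif feature == "np":
        edges = NP_EDGES
    else:
        raise ValueError("feature must be 'llp' or 'np'")
    clipped = np.minimum(v, edges[-1] - 1e-9)
    counts, _ = np.histogram(clipped, bins=edges)
    return Histogram(edges, counts / counts.sum(), feature)


def bhattacharyya(h1: Histogram, h2: Histogram) -> float:
    """Bhattacharyya coefficient of two histograms on identical edges."""
    if h1.edges.shape != h2.edges.shape or not np.allclose(h1.edges, h2.edges):
        raise ValueError("histograms must share identical bin edges")
    return float(np.sum(np.sqrt(h1.frequencies * h2.frequencies)))


@dataclass(frozen=True)
class MetricPair:
    """The two calibration metrics for one parametrization."""

    bc_llp: float
    bc_np: float

    def __post_init__(self) -> None:
        for v in (self.bc_llp, self.bc_np):
            if not (-1e-12 <= v <= 1.0 + 1e-12):
                raise ValueError("Bhattacharyya coefficients must lie in [0, 1]")


# ---------------------------------------------------------------------------
# search space


E_GRID = 10.0 ** np.arange(4, 11)  # {1e4 .. 1e10} Pa
S_BINARY_GRID = 12500.0 + 2000.0 * np.arange(101)


@dataclass(frozen=True)
class Parametrization:
    """One point of the nine-parameter search space."""

    e_protrusion_Pa: float = 1.0e7
    s_birth: int = 85
    s_exp: int = 76
    s_ret: int = 0
    alpha_exp_mm: float = 0.14
    beta_exp: float = 100.0
    alpha_ret_mm: float = 0.05
    beta_ret: float = 54.86
    s_binary: float = 62500.0

    def check_ranges(self) -> None:
        if not np.any(np.isclose(self.e_protrusion_Pa, E_GRID, rtol=1e-9)):
            raise RangeViolationError("e_protrusion must lie on the 10^{4..10} Pa grid")
        for name in ("s_birth", "s_exp", "s_ret"):
            v = getattr(self, name)
            if not (0 <= v <= 100 and float(v).is_integer()):
                raise RangeViolationError(f"{name} must be an integer in [0, 100]")
        for name in ("alpha_exp_mm", "alpha_ret_mm"):
            if not (0.01 <= getattr(self, name) <= 0.2):
                raise RangeViolationError(f"{name} must lie in [0.01, 0.2] mm")
        for name in ("beta_exp", "beta_ret"):
            if not (0.1 <= getattr(self, name) <= 100.0):
                raise RangeViolationError(f"{name} must lie in [0.1, 100]")
        if not np.any(np.isclose(self.s_binary, S_BINARY_GRID, atol=1e-6)):
            raise RangeViolationError("s_binary must lie on the 12500 + 2000j grid")

    @property
    def is_valid(self) -> bool:
        return self.s_ret < self.s_exp < self.s_birth

    def to_vector(self) -> np.ndarray:
        """Unit-cube encoding for the GP surrogates."""
        return np.array(
            [
                (np.log10(self.e_protrusion_Pa) - 4.0) / 6.0,
                self.s_birth / 100.0,
                self.s_exp / 100.0,
                self.s_ret / 100.0,
                (self.alpha_exp_mm - 0.01) / 0.19,
                (self.beta_exp - 0.1) / 99.9,
                (self.alpha_ret_mm - 0.01) / 0.19,
                (self.beta_ret - 0.1) / 99.9,
                (self.s_binary - 12500.0) / 200000.0,
            ]
        )

    def apply(self, config: RunConfig) -> RunConfig:
        """Resolve this parametrization into a runnable configuration."""
        return config.replace(
            thresholds=ThresholdSet(
                s_birth=float(self.s_birth),
                s_exp=float(self.s_exp),
                s_ret=float(self.s_ret),
                s_binary=float(self.s_binary),
            ),
            strain=StrainParams(
                alpha_exp_mm=self.alpha_exp_mm,
                beta_exp=self.beta_exp,
                alpha_ret_mm=self.alpha_ret_mm,
                beta_ret=self.beta_ret,
            ),
            elasticity=ElasticityParams(
                e_protrusion_Pa=self.e_protrusion_Pa,
                e_matrix_Pa=config.elasticity.e_matrix_Pa,
                nu_protrusion=config.elasticity.nu_protrusion,
                nu_matrix=config.elasticity.nu_matrix,
                diameter_um=config.elasticity.diameter_um,
            ),
        )


def validity_filter(params: Parametrization) -> bool:
    """Hard biological gate: accept iff s_ret < s_exp < s_birth.

    Out-of-range fields raise :class:`RangeViolationError` (a distinct signal
    from validity rejection).
    """
    params.check_ranges()
    return params.is_valid


@dataclass(frozen=True)
class ParameterSpace:
    """Sampler over the mixed search space."""

    def sample(self, rng: np.random.Generator, require_valid: bool = True) -> Parametrization:
        """Uniform space-filling draw; rejection-samples until validity passes."""
        for _ in range(10_000):
            p = self.from_unit(rng.random(9))
            if not require_valid or p.is_valid:
                return p
        raise RuntimeError("could not draw a valid parametrization")  # pragma: no cover

    @staticmethod
    def from_unit(u: np.ndarray) -> Parametrization:
        u = np.clip(np.asarray(u, dtype=float), 0.0, 1.0)
        return Parametrization(
            e_protrusion_Pa=float(E_GRID[min(int(u[0] * 7), 6)]),
            s_birth=min(int(u[1] * 101), 100),
            s_exp=min(int(u[2] * 101), 100),
            s_ret=min(int(u[3] * 101), 100),
            alpha_exp_mm=0.01 + 0.19 * u[4],
            beta_exp=0.1 + 99.9 * u[5],
            alpha_ret_mm=0.01 + 0.19 * u[6],
            beta_ret=0.1 + 99.9 * u[7],
            s_binary=float(S_BINARY_GRID[min(int(u[8] * 101), 100)]),
        )


# ---------------------------------------------------------------------------
# evaluation


def trajectory_histograms(traj) -> tuple[Histogram, Histogram]:
    """Pool all checkpoints of one simulation into the two feature histograms."""
    return make_histogram(traj.llp_um, "llp"), make_histogram(traj.n_protrusions, "np")


def evaluate_parametrization(
    params: Parametrization,
    targets: tuple[Histogram, Histogram],
    base_config: RunConfig,
    seeds: list[int],
    pool_seeds: bool = False,
) -> MetricPair:
    """Score a parametrization against target histograms over a seed ensemble.

    Default (literal per-seed averaging): each seeded simulation yields its
    own checkpoint histograms, each is compared with the targets, and the BCs
    are averaged across seeds.  ``pool_seeds=True`` instead pools all
    checkpoints of all seeds into one histogram per feature before comparing.
    """
    if not validity_filter(params):
        raise InvalidParametrizationError(
            "invalid thresholds: require s_ret < s_exp < s_birth"
        )
    t_llp, t_np = targets
    cfg = params.apply(base_config)
    trajs = [run_simulation(cfg, s) for s in seeds]
    if pool_seeds:
        llp_all = np.concatenate([t.llp_um for t in trajs])
        np_all = np.concatenate([t.n_protrusions for t in trajs])
        return MetricPair(
            bhattacharyya(make_histogram(llp_all, "llp"), t_llp),
            bhattacharyya(make_histogram(np_all, "np"), t_np),
        )
    bcs = np.array(
        [
            (
                bhattacharyya(make_histogram(t.llp_um, "llp"), t_llp),
                bhattacharyya(make_histogram(t.n_protrusions, "np"), t_np),
            )
            for t in trajs
        ]
    )
    return MetricPair(float(bcs[:, 0].mean()), float(bcs[:, 1].mean()))


# ---------------------------------------------------------------------------
# Bayesian optimization


@dataclass
class CalibrationHistory:
    """Evaluated parametrizations with their metric pairs and Pareto flags."""

    params: list[Parametrization] = field(default_factory=list)
    metrics: list[MetricPair] = field(default_factory=list)

    def append(self, p: Parametrization, m: MetricPair) -> None:
        self.params.append(p)
        self.metrics.append(m)

    def metric_array(self) -> np.ndarray:
        return np.array([(m.bc_llp, m.bc_np) for m in self.metrics])

    def pareto_flags(self) -> np.ndarray:
        return _pareto_mask(self.metric_array())

    def pareto(self) -> list[tuple[Parametrization, MetricPair]]:
        mask = self.pareto_flags()
        return [
            (p, m) for p, m, keep in zip(self.params, self.metrics, mask) if keep
        ]

    def best_balanced(self) -> tuple[Parametrization, MetricPair]:
        """Pareto point maximizing min(BC_llp, BC_np); ties broken by the sum."""
        front = self.pareto()
        if not front:
            raise ValueError("empty history")
        return max(front, key=lambda pm: (min(pm[1].bc_llp, pm[1].bc_np), pm[1].bc_llp + pm[1].bc_np))

    def to_dataframe(self) -> pd.DataFrame:
        flags = self.pareto_flags() if self.params else np.array([], dtype=bool)
        rows = []
        for p, m, fl in zip(self.params, self.metrics, flags):
            rows.append(
                {
                    "e_protrusion_Pa": p.e_protrusion_Pa,
                    "s_birth": p.s_birth,
                    "s_exp": p.s_exp,
                    "s_ret": p.s_ret,
                    "alpha_exp_mm": p.alpha_exp_mm,
                    "beta_exp": p.beta_exp,
                    "alpha_ret_mm": p.alpha_ret_mm,
                    "beta_ret": p.beta_ret,
                    "s_binary": p.s_binary,
                    "bc_llp": m.bc_llp,
                    "bc_np": m.bc_np,
                    "pareto": bool(fl),
                }
            )
        return pd.DataFrame(rows)


def _pareto_mask(metrics: np.ndarray) -> np.ndarray:
    """Non-domination mask under joint maximization (ties kept)."""
    n = metrics.shape[0]
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        ge = np.all(metrics >= metrics[i], axis=1)
        gt = np.any(metrics > metrics[i], axis=1)
        mask[i] = not np.any(ge & gt)
    return mask


def pareto_front(history: CalibrationHistory) -> list[tuple[Parametrization, MetricPair]]:
    """Exactly the non-dominated (Pareto-optimal) evaluations."""
    return history.pareto()


def _fit_gp(X: np.ndarray, y: np.ndarray, seed: int) -> GaussianProcessRegressor:
    kernel = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
        length_scale=np.full(X.shape[1], 0.3), length_scale_bounds=(1e-2, 1e2), nu=2.5
    ) + WhiteKernel(1e-4, (1e-8, 1e-1))
    gp = GaussianProcessRegressor(
        kernel=kernel, normalize_y=True, n_restarts_optimizer=0, random_state=seed
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        gp.fit(X, y)
    return gp


def propose_next(
    history: CalibrationHistory,
    space: ParameterSpace,
    rng: np.random.Generator,
    n_initial: int = 10,
    n_candidates: int = 256,
) -> Parametrization:
    """Suggest the next parametrization to evaluate.

    While the history is short, draws are space-filling; afterwards two GP
    surrogates (one per metric) are fitted on the unit-cube encoding and the
    candidate maximizing expected improvement of a freshly drawn random
    scalarization w*BC_llp + (1-w)*BC_np is returned.  Only validity-passing
    candidates are ever considered.
    """
    if len(history.params) < n_initial:
        return space.sample(rng)
    X = np.array([p.to_vector() for p in history.params])
    m = history.metric_array()
    seed = int(rng.integers(2**31 - 1))
    gp1 = _fit_gp(X, m[:, 0], seed)
    gp2 = _fit_gp(X, m[:, 1], seed + 1)
    w = float(rng.random())
    best = float(np.max(w * m[:, 0] + (1.0 - w) * m[:, 1]))
    cands = [space.sample(rng) for _ in range(n_candidates)]
    Xc = np.array([c.to_vector() for c in cands])
    mu1, sd1 = gp1.predict(Xc, return_std=True)
    mu2, sd2 = gp2.predict(Xc, return_std=True)
    mu = w * mu1 + (1.0 - w) * mu2
    sd = np.sqrt((w * sd1) ** 2 + ((1.0 - w) * sd2) ** 2) + 1e-12
    z = (mu - best) / sd
    from scipy.stats import norm

    ei = (mu - best) * norm.cdf(z) + sd * norm.pdf(z)
    return cands[int(np.argmax(ei))]


def run_calibration(
    targets: tuple[Histogram, Histogram],
    base_config: RunConfig,
    budget: int = 300,
    n_sims: int = 20,
    master_seed: int = 0,
    space: ParameterSpace | None = None,
    n_initial: int = 10,
) -> tuple[CalibrationHistory, tuple[Parametrization, MetricPair]]:
    """Full calibration loop: propose -> evaluate (fixed seed set) -> record.

    The same simulation seeds are reused for every parametrization to reduce
    comparison noise.  Returns the history and the balanced selection.
    """
    if budget < 10:
        raise ValueError("budget must be >= 10")
    space = space or ParameterSpace()
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([master_seed, 777])))
    from .simulator import ensemble_seeds

    seeds = ensemble_seeds(master_seed, n_sims)
    history = CalibrationHistory()
    for it in range(budget):
        p = propose_next(history, space, rng, n_initial=n_initial)
        m = evaluate_parametrization(p, targets, base_config, seeds)
        history.append(p, m)
        logger.debug("iteration %d: BC_llp=%.3f BC_np=%.3f", it, m.bc_llp, m.bc_np)
    return history, history.best_balanced()
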