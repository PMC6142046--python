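"""Synthetic microscopy-derived target histograms.

Raw single-cell quantifications behind the published summary statistics are
not distributed with the study, so calibration targets are emulated here
from those printed summaries: longest-protrusion lengths are drawn from a
normal distribution truncated to (0, 140] um whose *truncated* mean and
standard deviation equal 63.71 / 31.20 um (the location/scale are solved
numerically; plugging the printed moments in directly would bias the
truncated mean), and protrusion counts come from the maximum-entropy
distribution on the integers 1..14 matching mean 7.57 and standard deviation
3.27 — the printed range and the two printed moments are all the experiment
reports, and maximum entropy adds nothing beyond them.

These are synthetic stand-ins for microscopy quantification; in production
use, target histograms come from real image analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, root
from scipy.stats import truncnorm

from .calibration import Histogram, make_histogram

__all__ = [
    "InfeasibleTargetError",
    "SyntheticTargetSpec",
    "sample_llp",
    "sample_np",
    "maxent_count_distribution",
    "generate_targets",
]


class InfeasibleTargetError(ValueError):
    """The requested moment pair cannot be realised on the stated support."""


@dataclass(frozen=True)
class SyntheticTargetSpec:
    """Printed summary statistics the generator reproduces."""

    llp_mean_um: float = 63.71
    llp_sd_um: float = 31.20
    llp_max_um: float = 140.0
    np_mean: float = 7.57
    np_sd: float = 3.27
    np_min: int = 1
    np_max: int = 14
    n_samples: int = 10_000

    def __post_init__(self) -> None:
        if self.n_samples < 100:
            raise ValueError("sample size must be >= 100")
        if self.llp_sd_um < 0 or self.np_sd < 0:
            raise ValueError("standard deviations must be nonnegative")


def _truncnorm_loc_scale(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Location/scale of a truncated normal whose truncated moments are (mean, sd)."""

    def eqs(v):
        loc, scale = v
        scale = abs(scale)
        a, b = (lo - loc) / scale, (hi - loc) / scale
        m, var = truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        return [m - mean, np.sqrt(var) - sd]

    sol = root(eqs, x0=[mean, sd], method="hybr")
    if not sol.success or not np.all(np.isfinite(sol.x)):
        raise InfeasibleTargetError(
            f"no truncated normal on ({lo}, {hi}] with mean {mean}, sd {sd}"
        )
    loc, scale = float(sol.x[0]), float(abs(sol.x[1]))
    return loc, scale


def sample_llp(spec: SyntheticTargetSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Longest-protrusion-length sample (um) from the truncated normal."""
    if spec.llp_sd_um == 0.0:  # degenerate: all mass at the mean
        return np.full(n, spec.llp_mean_um)
    loc, scale = _truncnorm_loc_scale(spec.llp_mean_um, spec.llp_sd_um, 0.0, spec.llp_max_um)
    a, b = (0.0 - loc) / scale, (spec.llp_max_um - loc) / scale
    return truncnorm.rvs(a, b, loc=loc, scale=scale, size=n, random_state=rng)


def maxent_count_distribution(
    mean: float, sd: float, lo: int, hi: int
) -> np.ndarray:
    """Maximum-entropy pmf on {lo..hi} with the given mean and sd.

    The maxent distribution under first- and second-moment constraints is the
    exponential family p_k proportional to exp(l1*k + l2*k^2); the Lagrange
    multipliers are solved numerically.
    """
    k = np.arange(lo, hi + 1, dtype=float)
    if not (lo <= mean <= hi):
        raise InfeasibleTargetError("mean outside the support")
    target_var = sd * sd
    max_var = (mean - lo) * (hi - mean)  # two-point bound
    if target_var >= max_var:
        raise InfeasibleTargetError("variance infeasible on the support")

    def pmf(lam):
        logits = lam[0] * k + lam[1] * k * k
        logits -= logits.max()
        p = np.exp(logits)
        return p / p.sum()

    def eqs(lam):
        p = pmf(lam)
        m = float(p @ k)
        v = float(p @ (k - m) ** 2)
        return [m - mean, v - target_var]

    sol = root(eqs, x0=[0.0, 0.0], method="hybr")
    if not sol.success:
        raise InfeasibleTargetError("maximum-entropy moment matching failed")
    return pmf(sol.x)


def sample_np(spec: SyntheticTargetSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Protrusion-count sample from the moment-matched maxent distribution."""
    p = maxent_count_distribution(spec.np_mean, spec.np_sd, spec.np_min, spec.np_max)
    return rng.choice(np.arange(spec.np_min, spec.np_max + 1), size=n, p=p)


def generate_targets(
    spec: SyntheticTargetSpec, rng: np.random.Generator
) -> tuple[Histogram, Histogram]:
    """Draw a synthetic in-vitro sample and bin it into target histograms."""
    llp = sample_llp(spec, spec.n_samples, rng)
    counts = sample_np(spec, spec.n_samples, rng)
    return make_histogram(llp, "llp"), make_histogram(counts, "np")
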