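"""Compiled inner loop for the chemistry epochs.

The simulator advances the reaction network for 300 s inside every 5-min
mechanical step.  The published rate constants make the receptor binding pair
R1/R2 extremely stiff (tens of thousands of binding events per second per
free receptor), so the leap loop alternates Poisson leaps with short exact-SSA
bursts; in pure Python that costs seconds per simulation, which is
prohibitive for calibration ensembles.  This module holds a numba-compiled
twin of :mod:`mesomig.chemistry`'s ``advance`` loop — same algorithm, same
reject-and-halve / SSA-fallback policy — used by the simulator's hot path.
Distributional equivalence with the reference path is covered by tests.

The numba RNG is a process-global stream; :func:`seed_rng` must be called
(with a per-window derived seed) immediately before :func:`advance_window`
for reproducibility.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["seed_rng", "advance_window"]


@njit(cache=False)
def seed_rng(seed):  # pragma: no cover - trivial
    np.random.seed(seed)


@njit(cache=False)
def advance_window(
    x,
    f_nM,
    k1,
    k2,
    k3,
    k4,
    duration,
    eps,
    tau_min,
    tau_max,
    tau_floor,
):
    """Advance counts ``x`` (int64[4], modified in place) by ``duration`` s.

    Returns the number of R3 firings (PI3K activations) in the window, the
    quantity the surface module deposits spatially.
    """
    r3 = 0
    t = 0.0
    while t < duration - 1e-12:
        rem = duration - t
        a1 = k1 * f_nM * x[0]
        a2 = k2 * x[1]
        a3 = k3 * x[1] * x[2]
        a4 = k4 * x[3]
        a0 = a1 + a2 + a3 + a4
        if a0 <= 0.0:
            break

        # Cao-style bounded relative-change candidate, then clamp.
        tau = 1.0e300
        # species drifts / diffusions: RTK, RTKF, PI3K, PI3KA
        mu0 = a2 - a1
        mu2 = a4 - a3
        s0 = a1 + a2
        s2 = a3 + a4
        for i in range(4):
            if i == 0 or i == 1:
                mu = mu0 if i == 0 else -mu0
                sig = s0
            else:
                mu = mu2 if i == 2 else -mu2
                sig = s2
            xi = x[i] if x[i] > 1 else 1
            bound = eps * xi
            if mu != 0.0:
                c = bound / abs(mu)
                if c < tau:
                    tau = c
            if sig > 0.0:
                c = bound * bound / sig
                if c < tau:
                    tau = c
        if tau < tau_min:
            tau = tau_min
        elif tau > tau_max:
            tau = tau_max
        if tau > rem:
            tau = rem

        # reject-and-halve leap attempt with exact-SSA fallback
        while True:
            n1 = np.random.poisson(a1 * tau)
            n2 = np.random.poisson(a2 * tau)
            n3 = np.random.poisson(a3 * tau)
            n4 = np.random.poisson(a4 * tau)
            y0 = x[0] - n1 + n2
            y1 = x[1] + n1 - n2
            y2 = x[2] - n3 + n4
            y3 = x[3] + n3 - n4
            if y0 >= 0 and y1 >= 0 and y2 >= 0 and y3 >= 0:
                x[0] = y0
                x[1] = y1
                x[2] = y2
                x[3] = y3
                r3 += n3
                t += tau
                break
            tau *= 0.5
            if tau < tau_floor:
                # exact SSA over the (tiny) current interval
                tl = 0.0
                while True:
                    b1 = k1 * f_nM * x[0]
                    b2 = k2 * x[1]
                    b3 = k3 * x[1] * x[2]
                    b4 = k4 * x[3]
                    b0 = b1 + b2 + b3 + b4
                    if b0 <= 0.0:
                        break
                    dt = np.random.exponential(1.0 / b0)
                    if tl + dt > tau:
                        break
                    tl += dt
                    u = np.random.random() * b0
                    if u < b1:
                        x[0] -= 1
                        x[1] += 1
                    elif u < b1 + b2:
                        x[0] += 1
                        x[1] -= 1
                    elif u < b1 + b2 + b3:
                        x[2] -= 1
                        x[3] += 1
                        r3 += 1
                    else:
                        x[2] += 1
                        x[3] -= 1
                t += tau
                break
    return r3
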