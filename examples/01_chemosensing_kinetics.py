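"""Stochastic RTK/PI3K chemosensing kinetics.

Advances the four-reaction network by tau-leaping at a fixed 50 nM PDGF
concentration and compares the endpoint with the exact SSA and the
deterministic mass-action steady state.
"""

import numpy as np

from mesomig.chemistry import (
    LeapPolicy,
    ReactionNetwork,
    ReactionState,
    advance,
    ssa_advance,
    steady_state,
)

net = ReactionNetwork(conc_nM=50.0)  # published rates, 50 nM ligand
policy = LeapPolicy()
rng = np.random.default_rng(0)

# 1/100-scaled copy numbers keep the exact SSA affordable for comparison
initial = np.array([42, 0, 750, 0])
leap_state, firings, n_steps = advance(ReactionState(initial.copy()), net, 300.0, policy, rng)
ssa_state, _ = ssa_advance(ReactionState(initial.copy()), net, 300.0, rng)
ss = steady_state(net, rtk_total=42, pi3k_total=750)

print(f"tau-leap endpoint (t=300 s): {dict(zip(('RTK','RTKF','PI3K','PI3KA'), leap_state.counts))}")
print(f"  reached in {n_steps} leaps; R3 (PI3K activation) firings: {firings[2]}")
print(f"exact SSA endpoint:          {dict(zip(('RTK','RTKF','PI3K','PI3KA'), ssa_state.counts))}")
print(f"deterministic steady state:  PI3KA* = {ss[3]:.1f}")
print(
    "\nBoth steppers fluctuate around the deterministic steady state; the"
    "\ntau-leap gets there in a few hundred clamped [0.5, 1.5] s leaps instead"
    "\nof thousands of single-reaction SSA events."
)
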