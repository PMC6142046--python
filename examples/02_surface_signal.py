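"""Membrane persistence signal under a chemoattractant gradient.

Distributes activation events over the membrane with intensity proportional
to the local ligand concentration, smooths them, and shows the resulting
front/back signal asymmetry.
"""

import numpy as np

from mesomig.surface import (
    ChemoattractantField,
    SignalField,
    SmoothingKernel,
    SurfaceGrid,
    allocate_event_counts,
    deposit_and_convolve,
    membrane_profile,
)

grid = SurfaceGrid()  # 72 x 36 chart of a 10-um-radius cell
field = ChemoattractantField(c0_uM=0.8, gradient_uM_per_mm=[1.0, 0.0, 0.0])
kernel = SmoothingKernel.gaussian(sigma_sites=2.0)
rng = np.random.default_rng(1)

profile_nM = membrane_profile(field, np.zeros(3), grid)
weights = profile_nM * grid.area_weights()
signal = SignalField(grid)
for _ in range(5):  # five epochs of 100k activation events each
    deposits = allocate_event_counts(100_000, weights, rng)
    signal.accumulate(deposit_and_convolve(deposits, kernel))

x = grid.unit_vectors()[..., 0]
front = signal.s[x > 0].sum()
back = signal.s[x < 0].sum()
print(f"ligand on membrane: {profile_nM.min():.1f} - {profile_nM.max():.1f} nM")
print(f"accumulated signal, +x hemisphere: {front:,.0f}")
print(f"accumulated signal, -x hemisphere: {back:,.0f}")
print(f"front/back ratio: {front / back:.4f}")
print(
    "\nThe ratio exceeds 1 because activation events are a non-homogeneous"
    "\nPoisson field biased toward the up-gradient side - this asymmetry is"
    "\nwhat ultimately steers the cell."
)
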