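"""A full 4-hour migration simulation and a small chemotaxis comparison.

Runs one cell in the gradient-free culture medium and one in a 1 uM/mm PDGF
gradient and prints the checkpointed migration summaries.
"""

import numpy as np

from mesomig.simulator import RunConfig, run_simulation
from mesomig.surface import ChemoattractantField

medium = RunConfig.reduced()  # gradient-free, 0.05 uM medium; 36x18 grid
gradient = medium.replace(
    field=ChemoattractantField(c0_uM=0.8, gradient_uM_per_mm=[1.0, 0.0, 0.0])
)

for name, cfg in [("culture medium (no gradient)", medium), ("1 uM/mm PDGF gradient", gradient)]:
    traj = run_simulation(cfg, seed=7)
    disp = (traj.position_mm[-1] - traj.position_mm[0]) * 1000.0
    print(f"\n{name}")
    print(f"  checkpoints: {traj.n_checkpoints} (every 5 min over 4 h)")
    print(f"  final longest protrusion: {traj.llp_um[-1]:.1f} um")
    print(f"  live protrusions at t_end: {traj.n_protrusions[-1]}")
    print(f"  net displacement: {np.linalg.norm(disp):.1f} um, x-component {disp[0]:+.1f} um")
    print(f"  mean v_x: {traj.velocity_um_min[1:, 0].mean():+.2f} um/min")

print(
    "\nWithout a gradient the migration direction is seed-random; with a"
    "\ngradient the leading protrusion aligns with +x and the cell"
    "\nchemotaxes up-gradient."
)
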