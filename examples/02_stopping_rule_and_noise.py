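"""How the stopping point shapes image noise and voxel correlations.

One reconstruction runs deep (r = 0.2) while snapshots are taken as r first
crosses 2.0, 0.75 and 0.5.  For each stopping point the script prints the
ROI noise (semi-convergence: it grows as r falls), the nearest-neighbor
autocorrelation rho(1) per axis (positive when stopped early, near zero in
the recommended 0.5-1 band, negative when iterated deep), and a central WET
line sum (which barely moves with r).
"""

import numpy as np

import pct

grid = pct.VoxelGrid.centered((96, 8, 96), voxel_size=2.0)
truth = pct.make_phantom(pct.water_cylinder(180, 16, 1.0), grid)
protons = pct.simulate_protons(truth, pct.SimulationConfig(seed=7))

result = pct.reconstruct(protons, grid,
                         pct.StoppingConfig(r_stop=0.2, max_iterations=2000),
                         snapshot_r=(2.0, 0.75, 0.5))
volumes = dict(result.snapshots)
volumes[0.2] = result.volume

roi = pct.ROISpec.centered(grid.shape, (30, 6, 30))
print(f"{'r':>5} {'ROI sigma':>10} {'rho1_x':>8} {'rho1_y':>8} {'rho1_z':>8} {'WET mm':>8}")
for r_value in (2.0, 0.75, 0.5, 0.2):
    vol = volumes[r_value]
    _, var = pct.roi_stats(vol, roi)
    ac = pct.autocorrelation(vol, roi, delta_max=5)
    wet = pct.wet_line_sum(vol, (48, 4, 10), "z", 84)
    print(f"{r_value:>5} {np.sqrt(var):>10.4f} "
          f"{ac.rho['x'][1]:>8.3f} {ac.rho['y'][1]:>8.3f} {ac.rho['z'][1]:>8.3f} "
          f"{wet:>8.2f}")

nps = pct.nps_from_autocorrelation(pct.autocorrelation(volumes[0.75], roi, 5))
df = abs(nps.frequencies["x"][1] - nps.frequencies["x"][0])
print(f"\nNPS integral (x axis) = {nps.power['x'].sum() * df:.6f} "
      f"= ROI variance {nps.variance:.6f}")
# rho(1) flips sign as iterations continue past the least-squares noise
# level; the WET column shows range-relevant sums are stable to ~0.5 mm.
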