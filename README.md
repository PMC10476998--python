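# pct-recon

List-mode proton CT (pCT) image reconstruction by iterative least squares,
with a **noise-relative stopping criterion** and the noise-analysis tooling
(ROI variance, per-axis voxel autocorrelation, noise power spectrum, WET
line sums) needed to characterize the images it produces.  A synthetic
list-mode proton simulator makes the whole pipeline testable without
scanner data.

## The problem

A list-mode pCT scanner records, for each proton, its trajectory through
the object and its water-equivalent path length (WEPL).  Reconstructing the
3-D map of relative stopping power (RSP) means solving the overdetermined
linear system

```
A x = b
```

where `b` holds one measured WEPL per proton (mm), `x` one RSP value per
voxel, and `A` the chord length of each proton's trajectory through each
voxel.  The iteration used here is

```
dp = A x − b                         # per-proton WEPL deviation
dv = V⁻¹ Aᵀ dp,  V = diag(Σₚ α_pv)   # chord-weighted mean deviation per voxel
x ← x − λ dv                         # λ from an exact line search
```

with the step size λ minimizing either `dp·dp` or `dv·dv` after the step
(the solver alternates between the two).  Because the WEPLs are noisy,
iterating "to convergence" fits noise (semi-convergence): starting from a
smooth initial guess the image first approaches the true RSP map and then
grows noisier.  The stopping statistic

```
r = rms(dv) / σ_v ,   σ_v = σ_p / (ᾱ √N_pv)
```

compares the remaining distance to the unique least-squares solution
(`dv = 0` there) against the estimated per-voxel RSP precision implied by
the per-proton noise `σ_p = std(dp)`, the mean protons per voxel `N_pv` and
the mean chord per voxel `ᾱ` (≈ the voxel size).  Stopping when `r` falls
into the band **0.5 ≤ r ≤ 1** yields images whose voxel noise is nearly
uncorrelated between neighbors; stopping earlier leaves smooth, positively
correlated residuals, iterating deeper (r ≈ 0.2) sharpens the image but
anticorrelates neighboring voxels.  The autocorrelation function and the
noise power spectrum (a Wiener–Khinchin transform pair) quantify this.

## Worked example

```python
import numpy as np, pct

grid   = pct.VoxelGrid.centered((96, 8, 96), voxel_size=2.0)
truth  = pct.make_phantom(pct.water_cylinder(diameter_mm=180, height_mm=16), grid)
protons = pct.simulate_protons(truth, pct.SimulationConfig(seed=42))  # 90 angles x 2000

result = pct.reconstruct(protons, grid, pct.StoppingConfig(r_stop=0.75))
roi    = pct.ROISpec.centered(grid.shape, (30, 6, 30))
mean, var = pct.roi_stats(result.volume, roi)
print(result.state.iteration, result.state.r, mean, np.sqrt(var))
```

prints (from `examples/01_simulate_and_reconstruct.py`):

```
simulated 180000 protons; mean measured WEPL 133.9 mm
stopped after 32 iterations at r = 0.651 (sigma_p = 2.69 mm, sigma_v = 0.0803)
central ROI: mean RSP = 0.9999 (truth 1.0), noise sigma = 0.0836
```

The reconstruction stops once `r` crosses 0.75; the recovered mean RSP in a
central region is accurate to ~1e-4 and the voxel noise (σ ≈ 0.084) is close
to the precision estimate σ_v that the stopping rule uses.
`examples/02_stopping_rule_and_noise.py` extends this to several stopping
points in one run and prints how ROI noise grows, how the nearest-neighbor
correlation ρ(1) flips from positive (+0.10 at r = 2) through ≈0 (at
r = 0.75) to negative (−0.19 at r = 0.2), and that a 150-mm WET line sum
moves by well under a millimetre across the whole range.
`examples/03_pipeline_and_files.py` shows the YAML-driven pipeline and the
on-disk formats.  The same workflow is available from the shell:

```bash
pct simulate --config sim.yaml --out protons.h5 --truth truth.nii.gz
pct reconstruct --protons protons.h5 --grid 96,8,96,2.0 --stop-r 0.75 --out recon.nii.gz
pct noise --volume recon.nii.gz --roi 33,1,33,30,6,30 --max-delta 10
pct wet --volume recon.nii.gz --line 48,4,10,84
pct run --config run.yaml --out report.json
```

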