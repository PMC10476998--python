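# Methods

## Model and solver

The measurement model is linear: each proton's measured water-equivalent
path length (WEPL, mm) is the line integral of relative stopping power
(RSP) along its trajectory, `b ≈ A x`, with `A` holding chord lengths (mm)
of the recorded straight trajectory through each voxel.  Trajectories are
straight chords throughout; the solver algebra only requires *some*
consistent chord model per proton, so a curved-path model could replace the
tracer without touching the iteration, but none is provided.

The iteration direction is the voxel deviation vector
`dv = V⁻¹ Aᵀ (A x − b)` with `V = diag(Σₚ α_pv)` — the chord-weighted mean
of the per-proton deviations `dp` over the protons crossing each voxel.
Normalizing by the chord sum makes the convergence rate roughly uniform
across the image, which is what makes a single global stopping rule
meaningful.  At the unique least-squares solution `dv = 0` and
`V⁻¹AᵀA x = V⁻¹Aᵀ b`; since `V` is a positive diagonal this is exactly the
normal-equations solution, and the chord-weighted mean of calculated WEPLs
through every voxel equals that of the measured WEPLs.

Each update `x ← x − λ dv` uses an exact line search.  Both stated
objectives are quadratics in λ with closed-form minimizers:

* `dp` objective: `λ = (dp · A dv) / ‖A dv‖²`
* `dv` objective: with `u = V⁻¹AᵀA dv`, `λ = (dv · u) / ‖u‖²`

The solver alternates dp → dv → dp → … (starting with dp; the alternation
escapes the slow single-objective steepest-descent zig-zag).  A step can
never increase its own objective; this is asserted in the tests.

## Stopping rule

`σ_p` is the sample standard deviation (ddof = 1) of the current `dp` over
protons that traverse the grid, re-estimated at every check: near the
solution it estimates the per-proton WEPL noise, away from it the residual
convergence error inflates it, which only makes the rule conservative.
The per-voxel precision estimate is `σ_v = σ_p / (ᾱ √N_pv)` with `ᾱ` taken
as the voxel edge length and `N_pv` the mean proton count over
reconstructable voxels, as measured from the data.  Iteration stops when
`r = rms(dv)/σ_v ≤ r_stop`; the default `r_stop = 0.75` is the midpoint of
the low-correlation band 0.5–1.  Checks happen every iteration (the needed
products are already computed); the stop is taken at the first check that
crosses the threshold, not interpolated.

Two degenerate regimes are handled explicitly.  For exactly consistent
(noiseless) data `σ_p` and `rms(dv)` shrink together, so `r` plateaus at an
O(1) constant and would never cross a small threshold; the solver therefore
also stops, reporting convergence, when `rms(dv) ≤ 1e-12` (machine-scale
consistency).  If `r` rises at 20 consecutive checks the solver aborts with
a divergence diagnostic.

The nominal value of `r` is not invariant under voxel size: `dv` carries a
factor of the mean chord `ᾱ`, so the same physical convergence state maps
to a larger `r` on a coarser grid.  On the 2-mm desk-scale study grid the
positive-correlation (over-smoothed) regime sits near nominal r ≈ 6–10
rather than r ≈ 2, while the low-correlation band and the anticorrelated
deep-iteration regime appear at the conventional values.  Comparisons of
`r` thresholds across grids of different voxel size should keep this in
mind.

The initial guess (`x0_mode="uniform"`) fills the reconstructable voxels
with (mean measured WEPL)/(mean per-proton path length through the grid) —
a smooth start, which is a precondition for the semi-convergence behavior
the stopping rule exploits.  `zero` and user-supplied volumes are also
accepted.

Masking is purely data-driven: voxels touched by at least one proton
(positive chord sum) are reconstructable; all others stay at RSP 0 and are
excluded from every statistic.  No object-hull detection is performed.
Protons that miss the grid are flagged and ignored by `σ_p`.  A warning is
issued when protons number fewer than 10× the masked voxels.

## Direct reference solve

`solve_direct` solves `AᵀA x = Aᵀ b` on the masked columns with a sparse
direct factorization.  It exists as an independent reference for tests and
small problems only; the reconstruction path never uses it.  Note that at a
given `r` the max-norm distance of the iterate from this solution depends
on the spectrum of `V⁻¹AᵀA` (modes with small eigenvalues barely show in
`dv`); empirically on the small test instance max|Δx|/σ_v ≈ 0.24 at
r = 1e-2 and ≈ 0.004 at r = 1e-4, so equivalence tests iterate to 1e-4.

## Noise analysis

All noise statistics are computed in a uniform ROI (axis-aligned voxel
box).  The ROI variance uses divisor N−1.  The per-axis autocorrelation
ρ(δ) averages the product of mean-centered voxel pairs separated by δ
voxels along one axis.  Two conventions needed fixing where the defining
sums are ambiguous at ROI edges: the pair average divides by the actual
number of valid (truncated, non-wrapping) pairs at each δ, and the
normalizer is the population (divisor-N) variance so that ρ(0) = 1 holds
exactly; at ROI sizes of interest the two variances differ by N/(N−1) ≈ 1.
A single shared ROI mean is used for both pair members.  The default
δmax = 10 voxels; the structure of interest lives at δ ≤ 5.

The 1-D noise power spectrum per axis is the DFT of the symmetrized
autocovariance ρ·σ² on a circular lattice of M = 2δmax+1 points, scaled by
the voxel size h; frequencies are k/(Mh) in mm⁻¹ and the spectrum
integrates exactly to the ROI variance (Wiener–Khinchin pairing, asserted
to 1e-8 in a round-trip test).  Truncating ρ at δmax can produce small
negative power values for strongly structured fields; the convention is
reported as-is.

WET line sums are inclusive voxel runs along an axis times the voxel size —
the quantity proton range calculations consume.  Endpoints are voxel
indices.

## Synthetic scanner

The simulator emulates a rotating-gantry list-mode acquisition at
deliberately simplified physics:

* **Geometry.** Protons travel nominally along +z between two tracker
  planes 300 mm apart (`tracker_separation`); the object rotates about the
  vertical y axis, implemented by rotating each ray by minus the gantry
  angle into the fixed object frame.  Per angle, lateral positions are
  uniform over the beam cross-section (`beam_extent`, default 190 × 15 mm)
  and true directions get a Gaussian tilt of `divergence_mrad` (default
  10 mrad) per transverse axis, standing in for pencil-beam divergence and
  coupling the vertical voxel layers as a real fan of trajectories does.
* **WEPL.** The true WEPL is the exact line integral of the ground-truth
  RSP volume along the unquantized ray; the measured WEPL adds a single
  Gaussian of `wepl_noise_sigma` (default 3 mm), absorbing range straggling
  and detector resolution.  Only the existence and scale of WEPL noise
  matter to the method, not its microphysical origin.  Multi-energy
  acquisition (energy layers chosen per object thickness) is not modeled.
* **Trackers.** Recorded x/y positions on both planes are quantized to
  `tracker_pitch` (default 0.5 mm, the offset-double-fiber-layer value);
  the recorded direction comes from the quantized endpoints, optionally
  perturbed by `scatter_sigma_mrad` (default 0).  Because the measured WEPL
  always belongs to the unquantized true ray, trajectory uncertainty enters
  reconstruction through the record/truth mismatch, as in a real scanner.
* **Determinism.** One master seed spawns independent per-angle child
  streams, so the protons of angle m are identical whatever the total
  number of angles.

The default schedule (90 angles × 4°, 2000 protons/angle) and the default
study phantom — an 18-cm diameter uniform water cylinder on a 96×8×96 grid
of 2-mm voxels — are the synthetic study conditions used by the acceptance
checks.  The cylinder height equals the 16-mm reconstructed slab so that
divergent rays never cross material outside the grid (full-object coverage
is a structural assumption of the linear model; a grid that cuts the
object produces systematically inconsistent equations).  The ROI for noise
statistics is a central 30×6×30-voxel box (60 mm transverse, matching the
physical scale of typical uniform-phantom ROIs), and WET stability is
measured on a central 150-mm run along z.

## What the simulator does and does not show

Passing the synthetic checks demonstrates the solver/stopping-rule
machinery: semi-convergence of ROI noise, 1/√N noise scaling with proton
count, near-zero inter-voxel correlations when stopping in the recommended
band, anticorrelations when iterating deep, and WET sums insensitive to the
stopping value.  Two real-scanner behaviors do **not** transfer:

* The strongly positive correlations that a real reconstruction shows when
  stopped very early appear here at larger nominal r (≈ 6–10) than on
  fine-voxel scanner grids (≈ 2), for the voxel-size scaling reason above.
* The noise benefit of distributing a fixed proton budget over more
  projection angles does not reproduce: with straight recorded
  trajectories and purely independent Gaussian WEPL noise, concentrating
  protons in fewer angles averages noise within highly redundant ray paths
  while azimuthally unconstrained modes remain at the smooth initial
  guess, so central-ROI noise *decreases* with fewer angles at fixed
  stopping value.  The real effect appears to ride on physics that is out
  of scope here (multiple-Coulomb-scattered, effectively distinct curved
  paths, and per-projection systematics).

## Numerical choices

* Voxel boxes are half-open per axis; boundary-grazing intersections have
  measure zero and chords below 1e-6 mm are dropped, keeping `A` sparse.
* `A` is CSR with float64 chords and int32 column indices, assembled in
  chunks (worst-case per-ray buffers stay small); the transpose used every
  iteration is a no-copy CSC view.
* The tie between the two line-search objectives on the first iteration is
  broken in favor of `dp` (recorded per iteration in the history).
* λ degeneracy (`A dv = 0` with `dv ≠ 0`) raises a stagnation error rather
  than dividing by zero.
* Reported per-iteration history: r, rms(dv), σ_p, σ_v, λ and the
  objective, machine-readable from the library, the pipeline report and
  `pct reconstruct --history`.

## Known limitations

No most-likely-path trajectories, no nuclear-event data cuts by default
(a 3σ WEPL-residual cut can be applied upstream by the caller), no hull
detection, no block-iterative/TVS/GPU variants, isotropic voxels only, and
the simulator's noise model is a single Gaussian rather than a detector
response.  Real-data acceptance surfaces (heterogeneous phantoms, absolute
WET tables) are out of scope; all quantitative checks run on the synthetic
study.
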