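import numpy as np
import pytest

import pct


@pytest.fixture()
def micro():
    """The 3-proton / 2-voxel worked system, built from real rays.

    Grid: two 1-mm voxels along x.  Proton A crosses only voxel 0, proton B
    crosses both (chords 1, 1), proton C only voxel 1; measured WEPLs are
    (1.0, 2.2, 1.0), so A = [[1,0],[1,1],[0,1]].
    """
    grid = pct.VoxelGrid(shape=(2, 1, 1), voxel_size=1.0, origin=(0.0, 0.0, 0.0))
    p_in = np.array([
        [0.5, 0.5, -1.0],   # A: along +z through voxel 0
        [-1.0, 0.5, 0.5],   # B: along +x through both voxels
        [1.5, 0.5, -1.0],   # C: along +z through voxel 1
    ])
    d_in = np.array([[0.0, 0.0, 1.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    p_out = p_in + 3 * d_in
    protons = pct.ProtonList(p_in=p_in, d_in=d_in, p_out=p_out, d_out=d_in.copy(),
                             wepl=np.array([1.0, 2.2, 1.0]),
                             angle_deg=np.zeros(3))
    system = pct.build_system_matrix(protons, grid)
    return grid, protons, system


@pytest.fixture(scope="session")
def small_sim():
    """A small but fully tomographic noisy scan of a water cylinder.

    24-mm cylinder on a 16x4x16 grid of 2-mm voxels, 36 angles x 10 deg,
    ~5e3 protons, 3-mm WEPL noise — small enough for direct least-squares
    reference solves.
    """
    grid = pct.VoxelGrid.centered((16, 4, 16), 2.0)
    truth = pct.make_phantom(pct.water_cylinder(24.0, 8.0, 1.0), grid)
    cfg = pct.SimulationConfig(
        protons_per_angle=140, n_angles=36, angle_spacing_deg=10.0,
        wepl_noise_sigma=3.0, tracker_pitch=0.5, beam_extent=(30.0, 7.0),
        divergence_mrad=10.0, seed=17,
    )
    protons = pct.simulate_protons(truth, cfg)
    system = pct.build_system_matrix(protons, grid)
    return {"grid": grid, "truth": truth, "cfg": cfg,
            "protons": protons, "system": system}
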