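"""Synthetic list-mode proton data.

Emulates a list-mode proton CT acquisition at simplified physics: straight
proton trajectories, a measured water-equivalent path length (WEPL) per
proton equal to the line integral of RSP along the true trajectory plus
Gaussian noise, tracker planes that quantize recorded positions to a finite
pitch, and optional small-angle perturbation of the recorded direction.

The acquisition geometry follows the usual gantry convention: protons travel
nominally along ``+z`` between two tracker planes placed symmetrically about
the isocenter, and the object rotates about the vertical ``y`` axis.
Equivalently (and as implemented) each ray is rotated by minus the gantry
angle into the fixed object frame before tracing.

WEPL measurement noise is modelled as a single Gaussian that absorbs range
straggling and detector resolution; its origin does not matter for the
reconstruction and noise analysis, only its existence and scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._tracing import line_integral_batch
from .grid import RSPVolume

__all__ = ["SimulationConfig", "ProtonList", "true_wepl", "simulate_protons"]


@dataclass(frozen=True)
class SimulationConfig:
    """Acquisition parameters for the synthetic scanner.

    Parameters
    ----------
    protons_per_angle, n_angles, angle_spacing_deg
        Projection schedule; the default 90 angles at 4 degrees covers a full
        rotation.
    wepl_noise_sigma
        Standard deviation (mm) of the Gaussian WEPL measurement noise.
    tracker_pitch
        Recorded x/y positions on each tracker plane are quantized to this
        pitch (mm); 0.5 mm corresponds to offset double fiber layers.
        Set to 0 for ideal trackers.
    beam_extent
        Lateral span of generated rays at the isocenter plane, mm: a scalar
        (same span in x and y) or an (x_span, y_span) pair.
    divergence_mrad
        Gaussian spread of the true ray direction about +z, per transverse
        axis (mrad).  Emulates pencil-beam divergence; couples vertical
        voxel layers the way a real fan of trajectories does.
    scatter_sigma_mrad
        Optional Gaussian perturbation of the *recorded* direction (mrad),
        on top of the quantization-induced direction error.  The measured
        WEPL is always computed on the unperturbed true ray, so trajectory
        uncertainty enters reconstruction through the mismatch.
    tracker_separation
        Distance between the two tracker planes, mm.
    """

    protons_per_angle: int = 2000
    n_angles: int = 90
    angle_spacing_deg: float = 4.0
    wepl_noise_sigma: float = 3.0
    tracker_pitch: float = 0.5
    beam_extent: float | tuple[float, float] = (190.0, 15.0)
    divergence_mrad: float = 10.0
    scatter_sigma_mrad: float = 0.0
    tracker_separation: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.protons_per_angle < 1:
            raise ValueError("protons_per_angle must be >= 1")
        if self.n_angles < 1:
            raise ValueError("n_angles must be >= 1")
        if self.wepl_noise_sigma < 0:
            raise ValueError("wepl_noise_sigma must be >= 0")
        if self.tracker_pitch < 0:
            raise ValueError("tracker_pitch must be >= 0")
        bx, by = self.beam_extent_xy
        if bx <= 0 or by <= 0:
            raise ValueError("beam_extent spans must be > 0")
        if self.n_angles * self.angle_spacing_deg < 360.0 - 1e-9:
            warnings.warn(
                "angular coverage "
                f"{self.n_angles * self.angle_spacing_deg:g} deg < 360 deg; "
                "the scan is tomographically incomplete",
                stacklevel=2,
            )

    @property
    def beam_extent_xy(self) -> tuple[float, float]:
        if np.isscalar(self.beam_extent):
            return float(self.beam_extent), float(self.beam_extent)
        bx, by = self.beam_extent
        return float(bx), float(by)


@dataclass
class ProtonList:
    """List-mode proton records in object-frame coordinates (mm, degrees).

    ``p_in``/``p_out`` are recorded positions on the entry/exit tracker
    planes; ``d_in``/``d_out`` are recorded unit directions; ``wepl`` is the
    measured WEPL (mm).  ``wepl_true`` (optional) carries the noiseless
    ground-truth line integral for simulation studies.
    """

    p_in: np.ndarray
    d_in: np.ndarray
    p_out: np.ndarray
    d_out: np.ndarray
    wepl: np.ndarray
    angle_deg: np.ndarray
    wepl_true: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.wepl)
        for name in ("p_in", "d_in", "p_out", "d_out"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            if arr.shape != (n, 3):
                raise ValueError(f"{name} must have shape ({n}, 3), got {arr.shape}")
            setattr(self, name, arr)
        self.wepl = np.asarray(self.wepl, dtype=np.float64)
        self.angle_deg = np.asarray(self.angle_deg, dtype=np.float64)
        if self.angle_deg.shape != (n,):
            raise ValueError("angle_deg must be 1-D, one entry per proton")
        if self.wepl_true is not None:
            self.wepl_true = np.asarray(self.wepl_true, dtype=np.float64)

    def __len__(self) -> int:
        return len(self.wepl)

    def select(self, mask) -> "ProtonList":
        wt = None if self.wepl_true is None else self.wepl_true[mask]
        return ProtonList(self.p_in[mask], self.d_in[mask], self.p_out[mask],
                          self.d_out[mask], self.wepl[mask],
                          self.angle_deg[mask], wepl_true=wt)


def true_wepl(volume: RSPVolume, point, direction) -> float:
    """Noiseless WEPL: line integral of RSP along a straight ray.

    The ray starts at ``point`` (mm) and extends forward along ``direction``;
    a ray that misses the grid integrates to 0.
    """
    d = np.asarray(direction, dtype=np.float64)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("direction vector must be nonzero")
    p = np.ascontiguousarray(np.asarray(point, dtype=np.float64).reshape(1, 3))
    u = np.ascontiguousarray((d / norm).reshape(1, 3))
    out = np.empty(1)
    g = volume.grid
    line_integral_batch(p, u, volume.data, g.origin[0], g.origin[1], g.origin[2],
                        g.voxel_size, out)
    return float(out[0])


def _rotate_y(points: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rotate vectors about the +y axis by ``angle_rad``."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    x, y, z = points[:, 0], points[:, 1], points[:, 2]
    return np.stack([c * x + s * z, y, -s * x + c * z], axis=1)


def _quantize(values: np.ndarray, pitch: float) -> np.ndarray:
    if pitch <= 0:
        return values
    return np.round(values / pitch) * pitch


def _tilt(dirs: np.ndarray, tx: np.ndarray, ty: np.ndarray) -> np.ndarray:
    """Apply small transverse tilts (rad) to unit vectors near +z."""
    d = dirs.copy()
    d[:, 0] += tx
    d[:, 1] += ty
    return d / np.linalg.norm(d, axis=1, keepdims=True)


def simulate_protons(volume: RSPVolume, cfg: SimulationConfig) -> ProtonList:
    """Generate a synthetic list-mode dataset for one full scan.

    For each projection angle, rays are sampled uniformly over the beam
    cross-section with Gaussian angular divergence, traced through the
    ground-truth volume for the noiseless WEPL, and then "measured": WEPL
    gets additive Gaussian noise and tracker positions are quantized.  Per
    angle the random stream is an independent child of the master seed, so
    the protons of angle ``m`` do not depend on ``n_angles``.
    """
    g = volume.grid
    bx, by = cfg.beam_extent_xy
    half_sep = cfg.tracker_separation / 2.0
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_angles)

    parts: list[dict[str, np.ndarray]] = []
    for m in range(cfg.n_angles):
        rng = np.random.default_rng(children[m])
        n = cfg.protons_per_angle
        theta = np.deg2rad(m * cfg.angle_spacing_deg)

        # ray through (x0, y0, 0) at the isocenter plane, tilted about +z
        x0 = rng.uniform(-bx / 2, bx / 2, n)
        y0 = rng.uniform(-by / 2, by / 2, n)
        tx = rng.normal(0.0, cfg.divergence_mrad * 1e-3, n)
        ty = rng.normal(0.0, cfg.divergence_mrad * 1e-3, n)
        u = _tilt(np.tile([0.0, 0.0, 1.0], (n, 1)), tx, ty)

        # positions on the tracker planes z = -+half_sep (gantry frame)
        def at_plane(zp):
            t = (zp - 0.0) / u[:, 2]
            return np.stack([x0 + t * u[:, 0], y0 + t * u[:, 1],
                             np.full(n, zp)], axis=1)

        p_in_g = at_plane(-half_sep)
        p_out_g = at_plane(half_sep)

        # true WEPL on the unquantized ray, rotated into the object frame
        p_true = np.ascontiguousarray(_rotate_y(p_in_g, -theta))
        u_true = np.ascontiguousarray(_rotate_y(u, -theta))
        wt = np.empty(n)
        line_integral_batch(p_true, u_true, volume.data,
                            g.origin[0], g.origin[1], g.origin[2],
                            g.voxel_size, wt)
        wepl = wt + rng.normal(0.0, cfg.wepl_noise_sigma, n)

        # recorded trajectory: quantized tracker hits, object frame
        q_in = p_in_g.copy()
        q_out = p_out_g.copy()
        q_in[:, :2] = _quantize(q_in[:, :2], cfg.tracker_pitch)
        q_out[:, :2] = _quantize(q_out[:, :2], cfg.tracker_pitch)
        d_rec = q_out - q_in
        d_rec /= np.linalg.norm(d_rec, axis=1, keepdims=True)
        if cfg.scatter_sigma_mrad > 0:
            d_rec = _tilt(d_rec,
                          rng.normal(0.0, cfg.scatter_sigma_mrad * 1e-3, n),
                          rng.normal(0.0, cfg.scatter_sigma_mrad * 1e-3, n))
        parts.append({
            "p_in": _rotate_y(q_in, -theta),
            "d_in": _rotate_y(d_rec, -theta),
            "p_out": _rotate_y(q_out, -theta),
            "d_out": _rotate_y(d_rec, -theta),
            "wepl": wepl,
            "angle_deg": np.full(n, m * cfg.angle_spacing_deg),
            "wepl_true": wt,
        })

    cat = {k: np.concatenate([p[k] for p in parts]) for k in parts[0]}
    return ProtonList(**cat)
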