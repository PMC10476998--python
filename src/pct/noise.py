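"""Image-noise structure: ROI statistics, voxel autocorrelation, NPS, WET sums.

All analyses run inside a uniform region of interest (ROI) where the true
RSP is constant, so that voxel-to-voxel fluctuations are noise.  The
per-axis autocorrelation function rho(delta) is the average correlation
coefficient of voxel pairs separated by delta voxels along x, y, or z; its
Fourier transform (of the autocovariance) is the noise power spectrum (NPS)
by the Wiener–Khinchin theorem, and the NPS integrates to the noise
variance.  Water-equivalent thickness (WET) line sums — RSP summed along a
voxel run times the voxel size — are what proton range calculations consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import RSPVolume

__all__ = [
    "ROISpec", "AutocorrelationResult", "NoisePowerSpectrum",
    "roi_stats", "autocorrelation", "nps_from_autocorrelation", "wet_line_sum",
]

_AXES = ("x", "y", "z")


@dataclass(frozen=True)
class ROISpec:
    """An axis-aligned voxel box: start indices and extents (voxels)."""

    start: tuple[int, int, int]
    extent: tuple[int, int, int]

    def __post_init__(self) -> None:
        if any(int(s) < 0 for s in self.start):
            raise ValueError(f"start indices must be >= 0, got {self.start}")
        if any(int(e) < 1 for e in self.extent):
            raise ValueError(f"ROI extent must be >= 1 per axis, got {self.extent}")
        object.__setattr__(self, "start", tuple(int(s) for s in self.start))
        object.__setattr__(self, "extent", tuple(int(e) for e in self.extent))

    @classmethod
    def centered(cls, shape: tuple[int, int, int],
                 extent: tuple[int, int, int]) -> "ROISpec":
        start = tuple((n - e) // 2 for n, e in zip(shape, extent))
        return cls(start=start, extent=extent)

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(s, s + e) for s, e in zip(self.start, self.extent))

    def validate(self, volume: RSPVolume, mask: np.ndarray | None = None) -> None:
        for s, e, n in zip(self.start, self.extent, volume.grid.shape):
            if s + e > n:
                raise ValueError(f"ROI {self} exceeds grid shape {volume.grid.shape}")
        if mask is not None:
            m = mask.reshape(volume.grid.shape)[self.slices()]
            if not m.all():
                raise ValueError("ROI contains voxels outside the reconstructable mask")


@dataclass
class AutocorrelationResult:
    """ROI mean/variance and per-axis correlation-vs-separation curves.

    ``rho[axis][delta]`` for delta = 0..delta_max; ``rho[axis][0] == 1``.
    ``variance`` is the N-1 (sample) ROI variance; ``variance_pop`` the
    population variance used to normalize rho so that rho(0) = 1 exactly.
    """

    mean_rsp: float
    variance: float
    variance_pop: float
    rho: dict[str, np.ndarray] = field(repr=False)
    voxel_size: float = 1.0

    @property
    def delta_max(self) -> int:
        return len(self.rho["x"]) - 1


@dataclass
class NoisePowerSpectrum:
    """Per-axis 1-D NPS: power (RSP^2 mm) vs spatial frequency (1/mm).

    Normalized so that the integral of each axis' spectrum over its full
    frequency band equals the ROI noise variance.
    """

    frequencies: dict[str, np.ndarray] = field(repr=False)
    power: dict[str, np.ndarray] = field(repr=False)
    variance: float = 0.0


def roi_stats(volume: RSPVolume, roi: ROISpec) -> tuple[float, float]:
    """Mean RSP and sample variance (divisor N-1) over the ROI voxels."""
    roi.validate(volume)
    vals = volume.data[roi.slices()]
    return float(vals.mean()), float(vals.var(ddof=1))


def autocorrelation(volume: RSPVolume, roi: ROISpec, delta_max: int = 10) -> AutocorrelationResult:
    """Per-axis voxel-pair correlation versus separation within a uniform ROI.

    For each axis and separation delta, averages the product of mean-centered
    RSPs over every voxel pair inside the ROI that is separated by delta
    voxels along that axis (pairs are truncated at the ROI faces, and the
    average divides by the actual pair count), normalized by the population
    ROI variance so that rho(0) = 1 exactly.
    """
    roi.validate(volume)
    if any(delta_max >= e for e in roi.extent):
        raise ValueError(f"delta_max={delta_max} must be < ROI extent {roi.extent}")
    vals = volume.data[roi.slices()]
    mean = float(vals.mean())
    var_pop = float(vals.var(ddof=0))
    if var_pop == 0.0:
        raise ValueError("ROI is degenerate (zero variance): correlation undefined")
    c = vals - mean
    rho: dict[str, np.ndarray] = {}
    for axis, name in enumerate(_AXES):
        out = np.empty(delta_max + 1)
        out[0] = 1.0
        for delta in range(1, delta_max + 1):
            lead = [slice(None)] * 3
            lag = [slice(None)] * 3
            lead[axis] = slice(0, c.shape[axis] - delta)
            lag[axis] = slice(delta, None)
            prod = c[tuple(lead)] * c[tuple(lag)]
            out[delta] = prod.mean() / var_pop
        rho[name] = out
    return AutocorrelationResult(mean_rsp=mean, variance=float(vals.var(ddof=1)),
                                 variance_pop=var_pop, rho=rho,
                                 voxel_size=volume.grid.voxel_size)


def nps_from_autocorrelation(ac: AutocorrelationResult,
                             voxel_size: float | None = None) -> NoisePowerSpectrum:
    """Noise power spectrum as the DFT of the symmetrized autocovariance.

    Per axis, the autocovariance ``C(delta) = rho(delta) * variance`` for
    delta = -delta_max..delta_max is transformed on a circular lattice of
    M = 2*delta_max + 1 points; the spectrum is sampled at frequencies
    k/(M*h) (1/mm) for k = 0..M-1 and scaled by the voxel size h so that
    sum(S) * df = C(0) = variance exactly.
    """
    h = float(voxel_size if voxel_size is not None else ac.voxel_size)
    freqs: dict[str, np.ndarray] = {}
    power: dict[str, np.ndarray] = {}
    for name, rho in ac.rho.items():
        cov = np.asarray(rho) * ac.variance
        m = 2 * len(cov) - 1
        sym = np.concatenate([cov, cov[:0:-1]])  # [C0..Cd, Cd..C1] circular
        spec = np.fft.fft(sym).real * h
        freqs[name] = np.fft.fftfreq(m, d=h)
        power[name] = spec
    return NoisePowerSpectrum(frequencies=freqs, power=power, variance=ac.variance)


def wet_line_sum(volume: RSPVolume, start: tuple[int, int, int], axis: int | str,
                 stop: int) -> float:
    """WET (mm) of the inclusive voxel run from ``start`` to index ``stop``
    along ``axis``: sum of RSP times the voxel size."""
    ax = _AXES.index(axis) if isinstance(axis, str) else int(axis)
    i0 = start[ax]
    lo, hi = (i0, stop) if i0 <= stop else (stop, i0)
    n = volume.grid.shape[ax]
    if lo < 0 or hi >= n:
        raise ValueError(f"line run {lo}..{hi} outside axis extent {n}")
    idx = list(start)
    idx[ax] = slice(lo, hi + 1)
    vals = volume.data[tuple(idx)]
    return float(vals.sum() * volume.grid.voxel_size)
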