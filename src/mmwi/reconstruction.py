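"""Monostatic 3-D reflectivity reconstruction from UWB aperture signals.

Primary method: frequency-domain back-propagation (matched-filter focusing)
that honors dispersive propagation.  Each voxel accumulates

    sum_positions sum_f  S(f, position) * exp(+i 2 k(f) d)

with k(f) = 2 pi f Re(sqrt(eps(f))) / c inside the tissue and free-space k
along the standoff above the surface; d splits into an air and a tissue
segment along the straight ray from antenna to voxel.  The voxel value is
the accumulated magnitude.  Focusing uses the real (phase) part of the
dispersive wavenumber only: inverting the imaginary part as well would
multiply every voxel by exp(2 |Im k| d), an exponential gain that amplifies
noise and clutter with depth far faster than it recovers signal.

Because the sub-band antennas are directive (a stated lateral field of view
on the skin rather than isotropic radiators), each position's return is
back-propagated only to voxels inside that position's footprint; spreading
it over voxels the antenna never illuminated would blur laterally without
adding signal.  The same gating is applied in the delay-and-sum reference so
the two independent methods remain comparable; it can be disabled with
``fov_gating=False`` to recover the plain isotropic accumulation.

A classical time-domain delay-and-sum (DAS) implementation with constant
permittivity is provided as an independent cross-check: with a nondispersive
medium the two must locate point targets at the same voxel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cohort import C_MM_PER_S, DebyeMedium, ScanGeometry, debye_permittivity
from .synthesis import UWBSignal

__all__ = [
    "VoxelSpec",
    "ReflectivityCube",
    "range_resolution_mm",
    "reconstruct_cube",
    "das_reference",
]


@dataclass(frozen=True)
class VoxelSpec:
    """Regular voxel grid: lateral (x, y) and depth (z) sampling in mm.

    z = 0 lies at the skin surface and increases into the tissue.
    """

    nx: int
    ny: int
    nz: int
    dx: float
    dy: float
    dz: float
    x0: float = 0.0
    y0: float = 0.0

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 1:
            raise ValueError("voxel grid needs nx, ny, nz >= 1")
        if min(self.dx, self.dy, self.dz) <= 0:
            raise ValueError("voxel pitches must be > 0")

    @property
    def xs(self) -> np.ndarray:
        return self.x0 + np.arange(self.nx) * self.dx

    @property
    def ys(self) -> np.ndarray:
        return self.y0 + np.arange(self.ny) * self.dy

    @property
    def zs(self) -> np.ndarray:
        return np.arange(self.nz) * self.dz

    @classmethod
    def for_aperture(
        cls,
        geometry: ScanGeometry,
        lateral_oversample: int = 1,
        nz: int = 20,
        dz: Optional[float] = None,
        bandwidth_ghz: float = 98.0,
        eps_real: float = 15.0,
    ) -> "VoxelSpec":
        """Voxel grid spanning the scan positions, optionally oversampled.

        Default depth pitch is half the in-tissue range resolution
        (c / (4 B sqrt(eps')), i.e. 2x oversampled along z).
        """
        m, n = geometry.shape
        inc = geometry.increment_mm
        if dz is None:
            dz = C_MM_PER_S / (4.0 * bandwidth_ghz * 1e9 * np.sqrt(eps_real))
        k = int(lateral_oversample)
        return cls(
            nx=(m - 1) * k + 1,
            ny=(n - 1) * k + 1,
            nz=nz,
            dx=inc / k,
            dy=inc / k,
            dz=float(dz),
        )


@dataclass
class ReflectivityCube:
    """Reconstructed 3-D reflectivity-magnitude image of one lesion."""

    data: np.ndarray  # (nx, ny, nz), nonnegative
    spec: VoxelSpec
    lesion_id: Optional[str] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (self.spec.nx, self.spec.ny, self.spec.nz):
            raise ValueError("cube data shape does not match its voxel spec")
        if np.any(self.data < 0):
            raise ValueError("reflectivity magnitudes must be >= 0")

    def copy(self) -> "ReflectivityCube":
        return ReflectivityCube(self.data.copy(), self.spec, self.lesion_id, dict(self.meta))


def range_resolution_mm(bandwidth_ghz: float, eps_real: float = 1.0) -> float:
    """Closed-form range (depth) resolution c / (2 B sqrt(eps'))."""
    return C_MM_PER_S / (2.0 * bandwidth_ghz * 1e9 * np.sqrt(eps_real))


def _check_signals(signals: Sequence[UWBSignal]) -> None:
    if not signals:
        raise ValueError("reconstruction needs at least one aperture signal")
    for sig in signals:
        if np.any(np.diff(sig.freq_ghz) <= 0):
            raise ValueError("signal frequencies must be strictly increasing")


def _warn_if_uncovered(signals, geometry: ScanGeometry, spec: VoxelSpec) -> None:
    xs = [geometry.position_xy(*s.position)[0] for s in signals]
    ys = [geometry.position_xy(*s.position)[1] for s in signals]
    if (
        spec.xs[0] > min(xs)
        or spec.xs[-1] < max(xs)
        or spec.ys[0] > min(ys)
        or spec.ys[-1] < max(ys)
    ):
        warnings.warn("voxel grid does not cover the aperture footprint", stacklevel=3)


def _fov_mask(x, y, px, py, geometry: ScanGeometry, enabled: bool):
    if not enabled:
        return 1.0
    fx, fy = geometry.fov_mm
    return ((np.abs(x - px) <= fx / 2.0) & (np.abs(y - py) <= fy / 2.0)).astype(float)


def _window(n: int, kind: Optional[str]) -> np.ndarray:
    if kind is None or kind == "none":
        return np.ones(n)
    if kind == "hann":
        return np.hanning(n)
    raise ValueError(f"unknown spectral window {kind!r}")


def reconstruct_cube(
    signals: Sequence[UWBSignal],
    geometry: ScanGeometry,
    spec: VoxelSpec,
    medium: Optional[DebyeMedium] = None,
    window: Optional[str] = "hann",
    lesion_id: Optional[str] = None,
    fov_gating: bool = True,
) -> ReflectivityCube:
    """Frequency-domain back-propagation of the aperture onto a voxel grid.

    ``medium`` is the Debye model used for in-tissue propagation; ``None``
    focuses in free space (eps = 1).  A Hann window is applied across the
    spectrum before accumulation to suppress range sidelobes; each position
    contributes only to voxels inside its antenna footprint unless
    ``fov_gating`` is disabled.
    """
    _check_signals(signals)
    _warn_if_uncovered(signals, geometry, spec)
    X, Y, Z = np.meshgrid(spec.xs, spec.ys, spec.zs, indexing="ij")
    x = X.ravel()
    y = Y.ravel()
    z = Z.ravel()
    standoff = geometry.standoff_mm
    acc = np.zeros(x.size, dtype=complex)
    for sig in signals:
        f = sig.freq_ghz
        w = _window(f.size, window)
        k0 = 2.0 * np.pi * f * 1e9 / C_MM_PER_S
        if medium is None:
            kt = k0
        else:
            n_tis = np.real(np.sqrt(debye_permittivity(medium, f)))
            kt = 2.0 * np.pi * f * 1e9 * n_tis / C_MM_PER_S
        px, py = geometry.position_xy(*sig.position)
        gate = _fov_mask(x, y, px, py, geometry, fov_gating)
        lat2 = (x - px) ** 2 + (y - py) ** 2
        total = standoff + z
        r = np.sqrt(lat2 + total**2)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac_air = np.where(total > 0, standoff / np.maximum(total, 1e-300), 1.0)
        l_air = r * frac_air
        l_tis = r - l_air
        s = sig.values * w
        # chunk frequencies to bound the nf x nvox phase matrix
        chunk = max(1, int(4e6 // max(x.size, 1)))
        for a in range(0, f.size, chunk):
            b = min(a + chunk, f.size)
            phase = np.exp(
                2j * (k0[a:b, None] * l_air[None, :] + kt[a:b, None] * l_tis[None, :])
            )
            acc += (s[a:b] @ phase) * gate
    data = np.abs(acc).reshape(spec.nx, spec.ny, spec.nz)
    return ReflectivityCube(data, spec, lesion_id=lesion_id, meta={"method": "freq-domain"})


def das_reference(
    signals: Sequence[UWBSignal],
    geometry: ScanGeometry,
    spec: VoxelSpec,
    epsilon: float = 1.0,
    window: Optional[str] = "hann",
    oversample: int = 4,
    fov_gating: bool = True,
) -> ReflectivityCube:
    """Time-domain delay-and-sum reconstruction at constant permittivity.

    Independent of :func:`reconstruct_cube`: each spectrum is resampled onto
    a uniform grid, turned into a complex (analytic) impulse response by an
    inverse FFT, and the responses are shifted to each voxel's round-trip
    delay and summed.  Serves as the oracle for the frequency-domain method.
    """
    _check_signals(signals)
    _warn_if_uncovered(signals, geometry, spec)
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    f_ref = signals[0].freq_ghz
    for sig in signals:
        if sig.freq_ghz.shape != f_ref.shape or not np.allclose(sig.freq_ghz, f_ref):
            raise ValueError("all signals must share one frequency grid")

    nf_u = oversample * f_ref.size
    f_u = np.linspace(f_ref[0], f_ref[-1], nf_u)
    df = f_u[1] - f_u[0]
    n0 = int(round(f_u[0] / df))
    nfft = 1 << int(np.ceil(np.log2((n0 + nf_u) * 2)))
    dt = 1.0 / (nfft * df * 1e9)  # seconds per time sample
    w = _window(nf_u, window)

    X, Y, Z = np.meshgrid(spec.xs, spec.ys, spec.zs, indexing="ij")
    x = X.ravel()
    y = Y.ravel()
    z = Z.ravel()
    standoff = geometry.standoff_mm
    n_tis = np.sqrt(epsilon)
    acc = np.zeros(x.size, dtype=complex)
    c_s = C_MM_PER_S  # mm/s
    for sig in signals:
        vals_u = np.interp(f_u, sig.freq_ghz, sig.values.real) + 1j * np.interp(
            f_u, sig.freq_ghz, sig.values.imag
        )
        spec_arr = np.zeros(nfft, dtype=complex)
        spec_arr[n0 : n0 + nf_u] = vals_u * w
        h = np.fft.ifft(spec_arr) * nfft  # analytic impulse response
        px, py = geometry.position_xy(*sig.position)
        gate = _fov_mask(x, y, px, py, geometry, fov_gating)
        lat2 = (x - px) ** 2 + (y - py) ** 2
        total = standoff + z
        r = np.sqrt(lat2 + total**2)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac_air = np.where(total > 0, standoff / np.maximum(total, 1e-300), 1.0)
        l_air = r * frac_air
        l_tis = r - l_air
        tau = 2.0 * (l_air + n_tis * l_tis) / c_s
        idx = tau / dt
        i0 = np.floor(idx).astype(int) % nfft
        i1 = (i0 + 1) % nfft
        wfrac = idx - np.floor(idx)
        acc += (h[i0] * (1.0 - wfrac) + h[i1] * wfrac) * gate
    data = np.abs(acc).reshape(spec.nx, spec.ny, spec.nz)
    return ReflectivityCube(data, spec, meta={"method": "das"})
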