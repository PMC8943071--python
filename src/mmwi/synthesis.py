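"""Ultra-wideband synthesis: calibration, sub-band merging, geometry, validity.

The two sub-band antennas (12-51 GHz, 51-110 GHz) each measure a complex
reflection sweep per scan position.  This module turns those raw sweeps into
calibrated reflectivity (ratio of reflected to incident fields, obtained as
the pointwise ratio against a reference sweep), concatenates the two bands
into one synthetic ultra-wideband spectrum spanning 98 GHz, and flags lesions
whose spectra carry narrow interference notches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy import ndimage

from .cohort import (
    C_MM_PER_S,
    FrequencyGrid,
    ScanDataset,
    ScanGeometry,
    SubBandSweep,
    metal_plate_sweep,
)

__all__ = [
    "ApertureGeometry",
    "UWBSignal",
    "calibrate_reflectivity",
    "synthesize_uwb",
    "synthesize_dataset",
    "max_nyquist_spacing",
    "illuminated_extent",
    "validity_filter",
]

# The scan geometry doubles as the synthesis-side aperture description.
ApertureGeometry = ScanGeometry


@dataclass
class UWBSignal:
    """Merged calibrated reflectivity spectrum at one scan position."""

    position: tuple
    freq_ghz: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.freq_ghz = np.asarray(self.freq_ghz, dtype=float)
        self.values = np.asarray(self.values, dtype=complex)
        if self.freq_ghz.shape != self.values.shape:
            raise ValueError("frequency and value arrays must align")
        if np.any(np.diff(self.freq_ghz) <= 0):
            raise ValueError("frequency grid must be strictly increasing")

    @property
    def span_ghz(self) -> float:
        return float(self.freq_ghz[-1] - self.freq_ghz[0])


def calibrate_reflectivity(raw: SubBandSweep, reference: SubBandSweep) -> SubBandSweep:
    """Pointwise complex ratio raw/reference (reflectivity calibration)."""
    g, gr = raw.grid, reference.grid
    if (g.start_ghz, g.stop_ghz, g.n_points) != (gr.start_ghz, gr.stop_ghz, gr.n_points):
        raise ValueError("raw and reference frequency grids do not match")
    zero = np.flatnonzero(reference.s11 == 0)
    if zero.size:
        f_bad = g.points[zero[0]]
        raise ValueError(f"reference magnitude is zero at {f_bad:.4f} GHz")
    return SubBandSweep(raw.position, raw.band, g, raw.s11 / reference.s11)


def synthesize_uwb(band1: SubBandSweep, band2: SubBandSweep, tol: float = 1e-9) -> UWBSignal:
    """Concatenate two adjacent sub-band sweeps into one UWB spectrum.

    The two grids must abut: at a shared junction frequency the two samples
    are averaged; a gap larger than one grid step, or overlapping interior
    ranges, is an error.  The merged span equals the sum of the sub-band
    spans (shared endpoint counted once).
    """
    if band1.position != band2.position:
        raise ValueError("sub-band sweeps belong to different scan positions")
    lo, hi = (band1, band2) if band1.grid.start_ghz <= band2.grid.start_ghz else (band2, band1)
    f1, f2 = lo.grid.points, hi.grid.points
    gap = f2[0] - f1[-1]
    step = max(lo.grid.step_ghz, hi.grid.step_ghz)
    if gap < -tol:
        raise ValueError("sub-band ranges overlap in their interiors")
    if gap > step + tol:
        raise ValueError(f"gap of {gap:.4f} GHz between sub-bands exceeds one grid step")
    if abs(gap) <= tol:  # shared junction sample: average the two bands
        freq = np.concatenate([f1[:-1], [f1[-1]], f2[1:]])
        vals = np.concatenate(
            [lo.s11[:-1], [(lo.s11[-1] + hi.s11[0]) / 2.0], hi.s11[1:]]
        )
    else:
        freq = np.concatenate([f1, f2])
        vals = np.concatenate([lo.s11, hi.s11])
    return UWBSignal(band1.position, freq, vals)


def synthesize_dataset(
    ds: ScanDataset,
    reference1: Optional[SubBandSweep] = None,
    reference2: Optional[SubBandSweep] = None,
) -> List[UWBSignal]:
    """Calibrate and merge every position of a scan dataset.

    By default each band is calibrated against the analytical metal-plate
    reference for the dataset's own geometry (a perfect reflector at the
    surface plane), which removes the standoff phase and normalizes to the
    incident field.
    """
    if reference1 is None:
        reference1 = metal_plate_sweep(ds.grid1, ds.geometry, 1)
    if reference2 is None:
        reference2 = metal_plate_sweep(ds.grid2, ds.geometry, 2)
    m, n = ds.geometry.shape
    out = []
    for i in range(m):
        for j in range(n):
            s1 = calibrate_reflectivity(
                ds.sweep(i, j, 1),
                SubBandSweep((i, j), 1, reference1.grid, reference1.s11),
            )
            s2 = calibrate_reflectivity(
                ds.sweep(i, j, 2),
                SubBandSweep((i, j), 2, reference2.grid, reference2.s11),
            )
            out.append(synthesize_uwb(s1, s2))
    return out


def max_nyquist_spacing(f_ref_ghz: float = 100.0) -> float:
    """Largest aperture sampling step satisfying Nyquist (~lambda/2), in mm.

    Free-space half wavelength c/(2 f) at the reference frequency.  At
    100 GHz this is 1.499 mm, matching the instrument's printed 1.5 mm step;
    at the band edge of 110 GHz it tightens to 1.363 mm.
    """
    if f_ref_ghz <= 0:
        raise ValueError("reference frequency must be > 0")
    return C_MM_PER_S / (2.0 * f_ref_ghz * 1e9)


def illuminated_extent(n_positions: int, increment_mm: float, fov_extent_mm: float) -> float:
    """Illuminated extent along one scan axis: (n-1) * increment + FOV."""
    if n_positions < 1:
        raise ValueError("n_positions must be >= 1")
    if increment_mm <= 0 or fov_extent_mm <= 0:
        raise ValueError("increment and FOV extent must be > 0")
    return (n_positions - 1) * increment_mm + fov_extent_mm


def validity_filter(
    signals: Sequence[UWBSignal],
    dip_depth_db: float = 6.0,
    dip_width: int = 5,
    baseline_window: int = 11,
):
    """Flag a lesion invalid if any spectrum shows a narrow interference notch.

    Each magnitude spectrum is compared against its running-median baseline
    (window ``baseline_window`` samples).  A dip is a contiguous run of
    samples whose deficit 20*log10(baseline/|S|) strictly exceeds
    ``dip_depth_db`` and whose run length is strictly less than ``dip_width``
    samples: deep *and* narrow, the signature of accidental interference
    rather than tissue response.  Returns ``(valid, report)`` where report
    lists the offending positions, frequencies, depths and widths.
    """
    if not signals:
        raise ValueError("validity_filter needs at least one signal")
    report = []
    tiny = 1e-300
    for sig in signals:
        mag = np.abs(sig.values)
        baseline = ndimage.median_filter(mag, size=baseline_window, mode="nearest")
        deficit = 20.0 * np.log10(np.maximum(baseline, tiny) / np.maximum(mag, tiny))
        above = deficit > dip_depth_db
        if not above.any():
            continue
        # contiguous runs of samples strictly deeper than the threshold
        edges = np.flatnonzero(np.diff(above.astype(int)))
        starts = [0] if above[0] else []
        starts += [e + 1 for e in edges if above[e + 1]]
        ends = [e + 1 for e in edges if above[e]]
        if above[-1]:
            ends.append(len(above))
        for s, e in zip(starts, ends):
            width = e - s
            if width < dip_width:
                k = s + int(np.argmax(deficit[s:e]))
                report.append(
                    {
                        "position": sig.position,
                        "freq_ghz": float(sig.freq_ghz[k]),
                        "depth_db": float(deficit[k]),
                        "width": int(width),
                    }
                )
    return len(report) == 0, report
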