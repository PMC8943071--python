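"""Penetration-depth estimation and cube truncation.

As the wave goes deeper into the tissue, the desired reflected signal weakens
and clutter dominates, so each reconstructed cube is truncated at a usable
penetration depth before feature extraction.  Two regions are probed per
image, one at the lesion center and one at its margin; for each, the depth
profiles ("columns") of ``n_columns`` adjacent lateral positions are averaged,
the profile's own depth-mean is taken as the threshold, and the region's
depth is the deepest point down to which the profile has stayed at or above
that threshold.  The two region depths are averaged per image.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .reconstruction import ReflectivityCube, VoxelSpec

__all__ = ["DepthEstimate", "estimate_depth", "truncate_to_depth"]


@dataclass(frozen=True)
class DepthEstimate:
    """Penetration depth of one cube (per region and averaged), in mm."""

    depth_center_mm: float
    depth_margin_mm: float
    depth_mm: float
    threshold_center: float
    threshold_margin: float
    n_columns: int
    mode: str = "profile-mean"


def _region_profile(cube: ReflectivityCube, spot, n_columns: int, mode: str):
    data = cube.data
    nx, ny, nz = data.shape
    i, j = int(spot[0]), int(spot[1])
    if not (0 <= i < nx and 0 <= j < ny):
        raise ValueError(f"spot {spot} lies outside the cube lateral grid {nx}x{ny}")
    axis = 0 if nx >= ny else 1  # columns taken along the longer lateral axis
    avail = data.shape[axis]
    if avail < n_columns:
        raise ValueError(
            f"need {n_columns} columns along axis {axis} but only {avail} are "
            f"available (deficit {n_columns - avail})"
        )
    center = i if axis == 0 else j
    start = int(np.clip(center - n_columns // 2, 0, avail - n_columns))
    if axis == 0:
        block = data[start : start + n_columns, j, :]
    else:
        block = data[i, start : start + n_columns, :]
    if mode == "profile-mean":
        profile = block.mean(axis=0)
    elif mode == "sum":
        profile = block.sum(axis=0)
    else:
        raise ValueError(f"unknown depth mode {mode!r}")
    return profile


def _region_depth(profile: np.ndarray, dz: float):
    """Depth to which the profile stays >= its own mean (>= keeps equality)."""
    threshold = float(profile.mean())
    below = np.flatnonzero(profile < threshold)
    n_keep = profile.size if below.size == 0 else int(below[0])
    return n_keep * dz, threshold


def estimate_depth(
    cube: ReflectivityCube,
    center_spot,
    margin_spot,
    n_columns: int = 30,
    mode: str = "profile-mean",
) -> DepthEstimate:
    """Two-region penetration-depth estimate of one reflectivity cube.

    ``center_spot`` and ``margin_spot`` are (i, j) lateral voxel indices of
    the lesion-center and lesion-margin probes.  For each region the mean
    depth profile over ``n_columns`` columns (adjacent lateral positions along
    the longer lateral axis, clipped at the cube edge) is thresholded at its
    own depth-mean; the region depth is the last depth down to which the
    profile stays at or above the threshold.  The result averages the two
    regions.  The estimate is invariant to scaling the cube by a positive
    constant, and the ``sum`` mode (column sums instead of per-depth means)
    yields identical depths since profile and threshold scale together.
    """
    dz = cube.spec.dz
    pc = _region_profile(cube, center_spot, n_columns, mode)
    pm = _region_profile(cube, margin_spot, n_columns, mode)
    d_c, t_c = _region_depth(pc, dz)
    d_m, t_m = _region_depth(pm, dz)
    return DepthEstimate(
        depth_center_mm=d_c,
        depth_margin_mm=d_m,
        depth_mm=(d_c + d_m) / 2.0,
        threshold_center=t_c,
        threshold_margin=t_m,
        n_columns=n_columns,
        mode=mode,
    )


def truncate_to_depth(cube: ReflectivityCube, estimate: DepthEstimate) -> ReflectivityCube:
    """Crop a cube along z at the averaged penetration depth.

    At least one depth sample is always retained; the number of kept samples
    is ceil(depth / dz), so truncating a second time with the same estimate is
    a no-op.
    """
    dz = cube.spec.dz
    nz = cube.spec.nz
    n_keep = math.ceil(estimate.depth_mm / dz - 1e-12)
    if n_keep < 1:
        warnings.warn("zero penetration depth; retaining a single surface slice")
        n_keep = 1
    n_keep = min(n_keep, nz)
    spec = VoxelSpec(
        nx=cube.spec.nx,
        ny=cube.spec.ny,
        nz=n_keep,
        dx=cube.spec.dx,
        dy=cube.spec.dy,
        dz=dz,
        x0=cube.spec.x0,
        y0=cube.spec.y0,
    )
    data = cube.data[:, :, :n_keep].copy()
    return ReflectivityCube(data, spec, cube.lesion_id, dict(cube.meta))
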