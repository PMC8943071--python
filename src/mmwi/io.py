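"""File formats: Touchstone one-port sweeps, scan containers, cubes, features.

Sweeps can be exchanged either as plain-text Touchstone .s1p files (one file
per position per band, frequency in GHz, real/imaginary columns) or as a
single NumPy .npz container per lesion holding both band arrays and the scan
geometry.  Cubes are stored as .npz with the voxel spec embedded.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .cohort import FrequencyGrid, ScanDataset, ScanGeometry
from .reconstruction import ReflectivityCube, VoxelSpec

__all__ = [
    "write_s1p",
    "read_s1p",
    "write_scan_touchstone",
    "save_scan",
    "load_scan",
    "save_cube",
    "load_cube",
]


def write_s1p(path, freq_ghz, s11, comment: str = "") -> None:
    """Write a one-port Touchstone file (GHz, S-parameters, real/imaginary)."""
    path = Path(path)
    lines = []
    if comment:
        lines.append(f"! {comment}")
    lines.append("# GHz S RI R 50")
    for f, s in zip(np.asarray(freq_ghz, float), np.asarray(s11, complex)):
        lines.append(f"{f:.9g} {s.real:.12e} {s.imag:.12e}")
    path.write_text("\n".join(lines) + "\n")


def read_s1p(path):
    """Read a one-port Touchstone file; returns (freq_ghz, s11)."""
    freq, vals = [], []
    unit_scale = 1.0
    fmt = "RI"
    for raw in Path(path).read_text().splitlines():
        line = raw.split("!", 1)[0].strip()
        if not line:
            continue
        if line.startswith("#"):
            tokens = line[1:].upper().split()
            scale = {"HZ": 1e-9, "KHZ": 1e-6, "MHZ": 1e-3, "GHZ": 1.0}
            for t in tokens:
                if t in scale:
                    unit_scale = scale[t]
                if t in ("RI", "MA", "DB"):
                    fmt = t
            continue
        parts = [float(p) for p in line.split()]
        freq.append(parts[0] * unit_scale)
        if fmt == "RI":
            vals.append(parts[1] + 1j * parts[2])
        elif fmt == "MA":
            vals.append(parts[1] * np.exp(1j * np.deg2rad(parts[2])))
        else:  # DB
            vals.append(10 ** (parts[1] / 20.0) * np.exp(1j * np.deg2rad(parts[2])))
    return np.asarray(freq), np.asarray(vals)


def write_scan_touchstone(directory, ds: ScanDataset) -> list:
    """Write one .s1p per scan position per band; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    m, n = ds.geometry.shape
    paths = []
    for band, grid, arr in ((1, ds.grid1, ds.band1), (2, ds.grid2, ds.band2)):
        for i in range(m):
            for j in range(n):
                p = directory / f"pos_{i}_{j}_band{band}.s1p"
                write_s1p(p, grid.points, arr[i, j],
                          comment=f"position ({i},{j}) band {band}")
                paths.append(p)
    return paths


def save_scan(path, ds: ScanDataset) -> None:
    np.savez(
        path,
        band1=ds.band1,
        band2=ds.band2,
        grid1=[ds.grid1.start_ghz, ds.grid1.stop_ghz, ds.grid1.n_points],
        grid2=[ds.grid2.start_ghz, ds.grid2.stop_ghz, ds.grid2.n_points],
        shape=ds.geometry.shape,
        increment_mm=ds.geometry.increment_mm,
        standoff_mm=ds.geometry.standoff_mm,
        fov_mm=ds.geometry.fov_mm,
        has_artifacts=ds.has_artifacts,
        lesion_id=str(ds.lesion_id),
    )


def load_scan(path) -> ScanDataset:
    z = np.load(path, allow_pickle=False)
    geometry = ScanGeometry(
        shape=tuple(int(v) for v in z["shape"]),
        increment_mm=float(z["increment_mm"]),
        standoff_mm=float(z["standoff_mm"]),
        fov_mm=tuple(float(v) for v in z["fov_mm"]),
    )
    g1 = FrequencyGrid(float(z["grid1"][0]), float(z["grid1"][1]), int(z["grid1"][2]))
    g2 = FrequencyGrid(float(z["grid2"][0]), float(z["grid2"][1]), int(z["grid2"][2]))
    lesion_id = str(z["lesion_id"])
    return ScanDataset(
        geometry, g1, g2, z["band1"], z["band2"],
        has_artifacts=bool(z["has_artifacts"]),
        lesion_id=None if lesion_id == "None" else lesion_id,
    )


def save_cube(path, cube: ReflectivityCube) -> None:
    spec = cube.spec
    np.savez(
        path,
        data=cube.data,
        dims=[spec.nx, spec.ny, spec.nz],
        pitches=[spec.dx, spec.dy, spec.dz],
        origin=[spec.x0, spec.y0],
        lesion_id=str(cube.lesion_id),
        meta=json.dumps(cube.meta),
    )


def load_cube(path) -> ReflectivityCube:
    z = np.load(path, allow_pickle=False)
    dims = [int(v) for v in z["dims"]]
    pitches = [float(v) for v in z["pitches"]]
    origin = [float(v) for v in z["origin"]]
    spec = VoxelSpec(dims[0], dims[1], dims[2], pitches[0], pitches[1], pitches[2],
                     origin[0], origin[1])
    lesion_id = str(z["lesion_id"])
    return ReflectivityCube(
        z["data"], spec,
        lesion_id=None if lesion_id == "None" else lesion_id,
        meta=json.loads(str(z["meta"])),
    )
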