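"""Physics-informed synthetic cohort generator for millimeter-wave skin imaging.

The in-vivo study this package emulates measured one-port complex reflection
sweeps (S11) of skin lesions over two frequency sub-bands (12-51 GHz and
51-110 GHz) on an 8 x 6 monostatic scanning aperture.  No measurement data are
public, so this module generates a stand-in cohort with the statistical
structure the downstream analysis assumes: layered-skin phantoms with a
single-relaxation (Debye) dielectric model per tissue, a lesion region whose
dielectric contrast distinguishes malignant from benign lesions, additive
complex receiver noise, and narrow interference notches injected into the
scans that the validity filter is meant to reject.

Sign convention: time-harmonic fields follow e^{+i omega t}, so lossy media
have permittivity with a negative imaginary part and plane waves propagate as
e^{-ikz} with Im(k) <= 0.  The reconstruction module uses the same convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

EPS0 = 8.8541878128e-12  # vacuum permittivity, F/m
C_MM_PER_S = 2.99792458e11  # speed of light, mm/s

__all__ = [
    "EPS0",
    "C_MM_PER_S",
    "DebyeMedium",
    "FrequencyGrid",
    "SubBandSweep",
    "ScanGeometry",
    "ScanDataset",
    "LesionRegion",
    "SkinPhantom",
    "BAND1",
    "BAND2",
    "DERMIS",
    "FAT",
    "LESION_BASE",
    "MALIGNANT_SUBTYPES",
    "BENIGN_SUBTYPES",
    "STUDY_COMPOSITION",
    "SITE_CLASSES",
    "SITE_FRACTIONS",
    "debye_permittivity",
    "layered_reflection",
    "metal_plate_sweep",
    "simulate_scan",
    "inject_interference_dips",
    "generate_cohort",
]


@dataclass(frozen=True)
class DebyeMedium:
    """Single-relaxation Debye model of one tissue's complex permittivity.

    Parameters
    ----------
    eps_inf : float
        High-frequency (optical) relative permittivity, >= 1.
    delta_eps : float
        Dispersion magnitude (eps_static - eps_inf), >= 0.
    tau_ps : float
        Relaxation time in picoseconds, > 0.
    sigma_s : float
        Static ionic conductivity in S/m, >= 0.
    """

    eps_inf: float
    delta_eps: float
    tau_ps: float
    sigma_s: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.eps_inf < 1:
            raise ValueError("eps_inf must be >= 1")
        if self.delta_eps < 0:
            raise ValueError("delta_eps must be >= 0")
        if self.tau_ps <= 0:
            raise ValueError("tau_ps must be > 0")
        if self.sigma_s < 0:
            raise ValueError("sigma_s must be >= 0")

    def scaled(self, factor: float) -> "DebyeMedium":
        """Return a copy with dispersion magnitude and conductivity scaled."""
        return replace(
            self, delta_eps=self.delta_eps * factor, sigma_s=self.sigma_s * factor
        )


def debye_permittivity(medium: DebyeMedium, f_ghz) -> np.ndarray:
    """Complex relative permittivity eps(f) of a Debye medium.

    eps(f) = eps_inf + delta_eps / (1 + i w tau) - i sigma_s / (w eps0),
    w = 2 pi f, under the e^{+i omega t} convention (Im eps <= 0).

    ``f_ghz`` may be a scalar or array of frequencies in GHz; all must be > 0.
    """
    f = np.asarray(f_ghz, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    w = 2.0 * np.pi * f * 1e9
    eps = (
        medium.eps_inf
        + medium.delta_eps / (1.0 + 1j * w * medium.tau_ps * 1e-12)
        - 1j * medium.sigma_s / (w * EPS0)
    )
    return eps


# Default tissue parameters, chosen from published millimeter-wave skin
# dielectric ranges (wet-skin-like dermis over a fat half-space).  Reported
# malignant-vs-benign dielectric contrasts vary across studies, so these
# defaults are tunable study conditions, not claims of fidelity.
DERMIS = DebyeMedium(4.0, 32.0, 6.9, 0.10, name="dermis")
FAT = DebyeMedium(2.5, 6.0, 13.0, 0.03, name="fat")
LESION_BASE = DebyeMedium(4.0, 36.0, 7.2, 0.20, name="lesion")


@dataclass(frozen=True)
class FrequencyGrid:
    """Uniform frequency grid of one sub-band, in GHz."""

    start_ghz: float
    stop_ghz: float
    n_points: int

    def __post_init__(self) -> None:
        if not self.start_ghz < self.stop_ghz:
            raise ValueError("start must be < stop")
        if self.n_points < 2:
            raise ValueError("grid needs at least 2 points")

    @property
    def points(self) -> np.ndarray:
        return np.linspace(self.start_ghz, self.stop_ghz, self.n_points)

    @property
    def step_ghz(self) -> float:
        return (self.stop_ghz - self.start_ghz) / (self.n_points - 1)


BAND1 = FrequencyGrid(12.0, 51.0, 128)
BAND2 = FrequencyGrid(51.0, 110.0, 128)


@dataclass
class SubBandSweep:
    """One scan position's complex reflection sweep in one sub-band."""

    position: tuple
    band: int
    grid: FrequencyGrid
    s11: np.ndarray

    def __post_init__(self) -> None:
        self.s11 = np.asarray(self.s11, dtype=complex)
        if self.s11.shape != (self.grid.n_points,):
            raise ValueError("coefficient count must equal grid point count")
        if not np.all(np.isfinite(self.s11)):
            raise ValueError("S11 must be finite")


@dataclass(frozen=True)
class ScanGeometry:
    """Monostatic raster-scan aperture geometry.

    Default: 8 x 6 positions at 1.5 mm increment, constant antenna standoff,
    and a 4 x 8 mm antenna field of view on the skin, so the illuminated area
    is (8-1)*1.5+4 = 14.5 mm by (6-1)*1.5+8 = 15.5 mm.
    """

    shape: tuple = (8, 6)
    increment_mm: float = 1.5
    standoff_mm: float = 20.0
    fov_mm: tuple = (4.0, 8.0)

    def __post_init__(self) -> None:
        if self.increment_mm <= 0:
            raise ValueError("scan increment must be > 0")
        if self.shape[0] < 1 or self.shape[1] < 1:
            raise ValueError("grid shape must be at least 1 x 1")
        if self.standoff_mm < 0:
            raise ValueError("standoff must be >= 0")

    def position_xy(self, i: int, j: int) -> tuple:
        return (i * self.increment_mm, j * self.increment_mm)

    @property
    def aperture_center(self) -> tuple:
        return (
            (self.shape[0] - 1) * self.increment_mm / 2.0,
            (self.shape[1] - 1) * self.increment_mm / 2.0,
        )


@dataclass
class ScanDataset:
    """Grid of per-position, per-sub-band reflection sweeps for one lesion."""

    geometry: ScanGeometry
    grid1: FrequencyGrid
    grid2: FrequencyGrid
    band1: np.ndarray  # (M, N, n1) complex
    band2: np.ndarray  # (M, N, n2) complex
    has_artifacts: bool = False
    lesion_id: Optional[str] = None

    def __post_init__(self) -> None:
        m, n = self.geometry.shape
        self.band1 = np.asarray(self.band1, dtype=complex)
        self.band2 = np.asarray(self.band2, dtype=complex)
        if self.band1.shape != (m, n, self.grid1.n_points):
            raise ValueError("band-1 array shape mismatch")
        if self.band2.shape != (m, n, self.grid2.n_points):
            raise ValueError("band-2 array shape mismatch")

    def sweep(self, i: int, j: int, band: int) -> SubBandSweep:
        if band == 1:
            return SubBandSweep((i, j), 1, self.grid1, self.band1[i, j])
        if band == 2:
            return SubBandSweep((i, j), 2, self.grid2, self.band2[i, j])
        raise ValueError("band must be 1 or 2")

    def copy(self) -> "ScanDataset":
        return ScanDataset(
            self.geometry,
            self.grid1,
            self.grid2,
            self.band1.copy(),
            self.band2.copy(),
            has_artifacts=self.has_artifacts,
            lesion_id=self.lesion_id,
        )


@dataclass(frozen=True)
class LesionRegion:
    """Lateral disc + depth extent occupied by the lesion medium."""

    center_mm: tuple
    radius_mm: float
    depth_mm: float
    medium: DebyeMedium

    def __post_init__(self) -> None:
        if self.radius_mm <= 0 or self.depth_mm <= 0:
            raise ValueError("lesion radius and depth must be > 0")


@dataclass
class SkinPhantom:
    """Layered skin model with an optional lesion disc.

    ``layers`` is an ordered list of (DebyeMedium, thickness_mm) pairs from the
    surface downward; the last layer's thickness must be ``None``
    (semi-infinite).
    """

    layers: list
    lesion: Optional[LesionRegion] = None
    label: str = "benign"
    subtype: str = ""
    site: str = ""

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("phantom needs at least one layer")
        for _, th in self.layers[:-1]:
            if th is None or th <= 0:
                raise ValueError("interior layer thicknesses must be > 0")
        if self.layers[-1][1] is not None and self.layers[-1][1] <= 0:
            raise ValueError("last layer thickness must be > 0 or None")


def layered_reflection(stack, f_ghz, standoff_mm: float = 0.0) -> np.ndarray:
    """Normal-incidence plane-wave reflection of a layered half-space.

    ``stack`` is an ordered list of (DebyeMedium, thickness_mm); a ``None`` or
    infinite thickness on the last layer means semi-infinite.  The incident
    medium is free space; an air gap of ``standoff_mm`` contributes a
    round-trip phase exp(-2 i k0 d).  Computed by the standard recursive
    (transfer-matrix equivalent) Fresnel combination from the deepest
    interface upward.  Returns the complex reflection coefficient, one value
    per frequency; |Gamma| <= 1 for passive media.
    """
    if not stack:
        raise ValueError("stack must contain at least one layer")
    f = np.asarray(f_ghz, dtype=float)
    scalar = f.ndim == 0
    f = np.atleast_1d(f)
    k0 = 2.0 * np.pi * f * 1e9 / C_MM_PER_S  # rad/mm in free space
    n_idx = [np.sqrt(debye_permittivity(m, f)) for m, _ in stack]

    # interface L-1 / L (last layer semi-infinite)
    def fresnel(na, nb):
        return (na - nb) / (na + nb)

    last = len(stack) - 1
    if last == 0:
        gamma = fresnel(np.ones_like(n_idx[0]), n_idx[0])
    else:
        gamma = fresnel(n_idx[last - 1], n_idx[last])
        for i in range(last - 1, 0, -1):
            d = stack[i][1]
            if d is None or not np.isfinite(d):
                raise ValueError("only the last layer may be semi-infinite")
            prop = np.exp(-2j * k0 * n_idx[i] * d)
            r = fresnel(n_idx[i - 1], n_idx[i])
            gamma = (r + gamma * prop) / (1.0 + r * gamma * prop)
        d0 = stack[0][1]
        if d0 is None or not np.isfinite(d0):
            raise ValueError("a multi-layer stack's first layer must be finite")
        prop = np.exp(-2j * k0 * n_idx[0] * d0)
        r = fresnel(np.ones_like(n_idx[0]), n_idx[0])
        gamma = (r + gamma * prop) / (1.0 + r * gamma * prop)
    gamma = gamma * np.exp(-2j * k0 * standoff_mm)
    return gamma[0] if scalar else gamma


def metal_plate_sweep(grid: FrequencyGrid, geometry: ScanGeometry, band: int) -> SubBandSweep:
    """Reference sweep of a perfect reflector at the phantom surface plane.

    Used to calibrate raw sweeps to reflectivity (ratio of reflected to
    incident fields): a metal plate reflects with Gamma = -1 at the surface,
    seen through the same free-space standoff as the tissue.
    """
    k0 = 2.0 * np.pi * grid.points * 1e9 / C_MM_PER_S
    s = -np.exp(-2j * k0 * geometry.standoff_mm)
    return SubBandSweep((-1, -1), band, grid, s)


def _footprint_overlaps(geometry: ScanGeometry, i: int, j: int, lesion: LesionRegion) -> bool:
    # lateral disc vs the antenna-FOV rectangle centered at the scan position
    x, y = geometry.position_xy(i, j)
    fx, fy = geometry.fov_mm
    dx = max(abs(lesion.center_mm[0] - x) - fx / 2.0, 0.0)
    dy = max(abs(lesion.center_mm[1] - y) - fy / 2.0, 0.0)
    return dx * dx + dy * dy <= lesion.radius_mm**2


def _lesion_stack(layers, lesion: LesionRegion):
    """Background stack with the top ``lesion.depth_mm`` replaced by lesion medium."""
    depth = lesion.depth_mm
    out = [(lesion.medium, depth)]
    z = 0.0
    for med, th in layers:
        if th is None:
            out.append((med, None))
            return out
        z2 = z + th
        if z2 > depth:
            out.append((med, z2 - max(z, depth)))
        z = z2
    return out


def simulate_scan(
    phantom: SkinPhantom,
    grid1: FrequencyGrid = BAND1,
    grid2: FrequencyGrid = BAND2,
    geometry: ScanGeometry = ScanGeometry(),
    noise_level: float = 0.0,
    seed: int = 0,
) -> ScanDataset:
    """Simulate the raster scan of one phantom over both sub-bands.

    At each scan position the reflection sweep is computed from the local
    layer stack (the lesion medium is substituted where the antenna footprint
    overlaps the lesion disc).  Additive circular complex Gaussian noise with
    standard deviation ``noise_level * mean |S11|`` (per band) models the
    receiver noise floor.  Deterministic given ``seed``.
    """
    if noise_level < 0:
        raise ValueError("noise_level must be >= 0")
    m, n = geometry.shape
    bands = []
    for grid in (grid1, grid2):
        f = grid.points
        bg = layered_reflection(phantom.layers, f, geometry.standoff_mm)
        les = None
        if phantom.lesion is not None:
            les = layered_reflection(
                _lesion_stack(phantom.layers, phantom.lesion), f, geometry.standoff_mm
            )
        arr = np.empty((m, n, grid.n_points), dtype=complex)
        for i in range(m):
            for j in range(n):
                if phantom.lesion is not None and _footprint_overlaps(
                    geometry, i, j, phantom.lesion
                ):
                    arr[i, j] = les
                else:
                    arr[i, j] = bg
        bands.append(arr)
    rng = np.random.default_rng(seed)
    if noise_level > 0:
        for arr in bands:
            sigma = noise_level * float(np.mean(np.abs(arr)))
            noise = rng.standard_normal(arr.shape) + 1j * rng.standard_normal(arr.shape)
            arr += sigma / math.sqrt(2.0) * noise
    return ScanDataset(geometry, grid1, grid2, bands[0], bands[1])


def inject_interference_dips(
    ds: ScanDataset,
    n_dips: int = 3,
    depth_fraction: float = 0.9,
    width: int = 3,
    seed: int = 0,
    edge_margin: int = 8,
) -> ScanDataset:
    """Multiply narrow interference notches into randomly chosen sweeps.

    Each notch is a Hann-shaped multiplicative window of ``width`` samples
    whose minimum magnitude is (1 - depth_fraction) times the original;
    ``depth_fraction=1`` drives the notch minimum to zero.  ``n_dips == 0``
    returns an unchanged copy; the returned dataset is flagged as
    artifact-bearing when any notch was applied.
    """
    if n_dips < 0:
        raise ValueError("n_dips must be >= 0")
    if not 0 < depth_fraction <= 1:
        raise ValueError("depth_fraction must be in (0, 1]")
    if width < 1:
        raise ValueError("width must be >= 1")
    out = ds.copy()
    if n_dips == 0:
        return out
    rng = np.random.default_rng(seed)
    m, n = ds.geometry.shape
    notch_shape = np.hanning(width + 2)[1:-1]  # interior samples, peak 1
    for _ in range(n_dips):
        i = int(rng.integers(m))
        j = int(rng.integers(n))
        band = int(rng.integers(1, 3))
        arr = out.band1 if band == 1 else out.band2
        npts = arr.shape[2]
        lo = edge_margin
        hi = npts - edge_margin - width
        c = int(rng.integers(lo, max(hi, lo + 1)))
        arr[i, j, c : c + width] *= 1.0 - depth_fraction * notch_shape
    out.has_artifacts = True
    return out


MALIGNANT_SUBTYPES = frozenset(
    {"melanoma", "basal_cell_carcinoma", "squamous_cell_carcinoma", "actinic_keratosis"}
)
BENIGN_SUBTYPES = frozenset(
    {
        "melanocytic_nevus",
        "seborrheic_keratosis",
        "solar_lentigo",
        "angioma_angiokeratoma",
        "dermatofibroma",
    }
)

# Validated-lesion composition of the emulated clinical cohort
# (93 benign / 43 malignant across 9 diagnosis types).
STUDY_COMPOSITION = {
    "melanocytic_nevus": 22,
    "seborrheic_keratosis": 25,
    "solar_lentigo": 24,
    "angioma_angiokeratoma": 12,
    "dermatofibroma": 10,
    "melanoma": 5,
    "basal_cell_carcinoma": 10,
    "squamous_cell_carcinoma": 8,
    "actinic_keratosis": 20,
}

SITE_CLASSES = (
    "non_glabrous_common_skin",
    "palmoplantar_skin",
    "facial_skin",
    "hairbearing_scalp",
)
# Per-class body-site proportions of the emulated cohort.
SITE_FRACTIONS = {
    "benign": np.array([43, 12, 28, 10], dtype=float) / 93.0,
    "malignant": np.array([22, 1, 15, 5], dtype=float) / 43.0,
}


def _sample_phantom(
    rng: np.random.Generator,
    label: str,
    subtype: str,
    site: str,
    contrast: float,
    geometry: ScanGeometry,
) -> SkinPhantom:
    cx0, cy0 = geometry.aperture_center
    dermis = replace(
        DERMIS,
        delta_eps=max(DERMIS.delta_eps * (1.0 + 0.05 * rng.standard_normal()), 0.0),
    )
    thickness = max(1.5 + 0.1 * rng.standard_normal(), 1.0)
    base = LESION_BASE.scaled(1.0 + contrast) if label == "malignant" else LESION_BASE
    jitter = max(1.0 + 0.05 * rng.standard_normal(), 0.5)
    lesion_medium = replace(base, delta_eps=base.delta_eps * jitter)
    lesion = LesionRegion(
        center_mm=(cx0 + rng.uniform(-1.5, 1.5), cy0 + rng.uniform(-1.5, 1.5)),
        radius_mm=rng.uniform(2.0, 4.0),
        depth_mm=rng.uniform(0.8, 1.4),
        medium=lesion_medium,
    )
    return SkinPhantom(
        layers=[(dermis, thickness), (FAT, None)],
        lesion=lesion,
        label=label,
        subtype=subtype,
        site=site,
    )


def generate_cohort(
    composition: Optional[dict] = None,
    contrast: float = 0.3,
    n_invalid: int = 10,
    noise_level: float = 0.02,
    seed: int = 0,
    geometry: ScanGeometry = ScanGeometry(),
    grid1: FrequencyGrid = BAND1,
    grid2: FrequencyGrid = BAND2,
    n_subjects: int = 71,
    out_dir: Optional[Path] = None,
):
    """Generate a full synthetic lesion cohort: metadata table plus scans.

    One scan dataset per lesion is produced for the requested subtype
    ``composition`` plus ``n_invalid`` additional lesions (subtypes drawn from
    the same proportions) that receive injected interference notches, mirroring
    a clinical acquisition in which some scans must later be invalidated.
    ``contrast`` is the fractional increase of the malignant lesion medium's
    dispersion magnitude and conductivity over the benign lesion medium;
    ``contrast=0`` makes the two classes statistically identical (a null
    cohort).  Deterministic given ``seed``.

    Returns ``(table, scans)`` where ``table`` is a pandas DataFrame (one row
    per lesion: lesion_id, subject_id, label, subtype, site, has_dips,
    lesion geometry columns, scan_path) and ``scans`` is a list of
    ScanDataset aligned with the rows.  If ``out_dir`` is given, each scan is
    also written there (NumPy .npz container) and the table as cohort.csv.
    """
    if contrast < 0:
        raise ValueError("contrast must be >= 0")
    if composition is None:
        composition = dict(STUDY_COMPOSITION)
    if any(v < 0 for v in composition.values()):
        raise ValueError("composition counts must be >= 0")
    total_valid = int(sum(composition.values()))
    if total_valid < 1:
        raise ValueError("composition must request at least one lesion")
    if n_invalid < 0:
        raise ValueError("n_invalid must be >= 0")

    rng = np.random.default_rng(seed)
    subtypes = [s for s, c in sorted(composition.items()) for _ in range(c)]
    names = sorted(composition)
    probs = np.array([composition[s] for s in names], dtype=float)
    probs /= probs.sum()
    extra = [str(rng.choice(names, p=probs)) for _ in range(n_invalid)]
    flags = [False] * len(subtypes) + [True] * len(extra)
    order = rng.permutation(len(flags))
    lesions = [(subtypes + extra)[k] for k in order]
    has_dips = [flags[k] for k in order]

    rows = []
    scans = []
    for idx, (subtype, dip) in enumerate(zip(lesions, has_dips)):
        label = "malignant" if subtype in MALIGNANT_SUBTYPES else "benign"
        site = str(rng.choice(SITE_CLASSES, p=SITE_FRACTIONS[label]))
        phantom = _sample_phantom(rng, label, subtype, site, contrast, geometry)
        scan_seed = int(rng.integers(0, 2**31 - 1))
        ds = simulate_scan(phantom, grid1, grid2, geometry, noise_level, scan_seed)
        if dip:
            dip_seed = int(rng.integers(0, 2**31 - 1))
            ds = inject_interference_dips(ds, n_dips=3, seed=dip_seed)
        lesion_id = f"L{idx + 1:04d}"
        ds.lesion_id = lesion_id
        subject = f"S{int(rng.integers(n_subjects)) + 1:03d}"
        path = ""
        if out_dir is not None:
            from . import io as _io

            out_dir = Path(out_dir)
            (out_dir / "scans").mkdir(parents=True, exist_ok=True)
            path = str(Path("scans") / f"{lesion_id}.npz")
            _io.save_scan(out_dir / path, ds)
        rows.append(
            {
                "lesion_id": lesion_id,
                "subject_id": subject,
                "label": label,
                "subtype": subtype,
                "site": site,
                "has_dips": dip,
                "lesion_cx_mm": phantom.lesion.center_mm[0],
                "lesion_cy_mm": phantom.lesion.center_mm[1],
                "lesion_radius_mm": phantom.lesion.radius_mm,
                "lesion_depth_mm": phantom.lesion.depth_mm,
                "scan_path": path,
            }
        )
        scans.append(ds)
    table = pd.DataFrame(rows)
    if out_dir is not None:
        table.to_csv(Path(out_dir) / "cohort.csv", index=False)
    return table, scans
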