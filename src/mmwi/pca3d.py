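"""Two-stage 3D-PCA feature extraction from reflectivity cubes.

Each lateral point (i, j) of a cube contributes its depth profile as one row
of a temporary 2-D structure (lesions x lateral points as rows, depth samples
as columns).  Stage 1 fits an ordinary PCA to that unfolded matrix and keeps
the smallest number of depth modes whose cumulative explained variance exceeds
a threshold (default 80%).  Each lesion's per-point stage-1 scores are then
concatenated into a single row and a second PCA across lesions reduces those
rows to ``k_final`` (default 6) principal-component scores per lesion, which
become the classifier features.  The composition of the two stages is an
exact linear map of the unfolded data, so held-out lesions can be projected
with the training means and loadings without refitting.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence

import numpy as np
from scipy.interpolate import interp1d

from .reconstruction import ReflectivityCube

__all__ = [
    "PCAModel",
    "FeatureMatrix",
    "ThreeDPCAModel",
    "fit_pca",
    "pca_transform",
    "select_components",
    "unfold_cubes",
    "refold_rows",
    "extract_features",
    "project",
]


@dataclass(frozen=True)
class PCAModel:
    """Mean, orthonormal loadings (variables x components), variance ratios.

    ``ratios`` are the normalized squared singular values in descending
    order; ``k`` is the number of retained components (<= total columns of
    ``components``).  Loading signs are fixed so each column's
    largest-magnitude element is positive, making results deterministic
    across platforms.
    """

    mean: np.ndarray
    components: np.ndarray
    ratios: np.ndarray
    k: int

    def __post_init__(self) -> None:
        if self.k < 1 or self.k > self.components.shape[1]:
            raise ValueError("k must be in [1, n_components]")


@dataclass(frozen=True)
class FeatureMatrix:
    """Per-lesion principal-component scores aligned with the cohort order."""

    scores: np.ndarray  # (lesions, k)
    lesion_ids: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.lesion_ids is not None and len(self.lesion_ids) != self.scores.shape[0]:
            raise ValueError("lesion ids must align with score rows")


def fit_pca(matrix) -> PCAModel:
    """Fit PCA by SVD of the column-mean-centered data matrix.

    Explained-variance ratios are the squared singular values normalized to
    sum to 1; components are ordered by decreasing singular value.  An
    all-constant matrix (zero variance) is an error.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("fit_pca needs a 2-D matrix with at least 2 rows")
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    if s.size == 0 or s[0] <= 0 or not np.isfinite(s[0]):
        raise ValueError("matrix has zero variance; PCA is undefined")
    keep = s > s[0] * 1e-12
    s = s[keep]
    vt = vt[keep]
    ratios = s**2 / np.sum(s**2)
    components = vt.T.copy()
    # deterministic sign: largest-magnitude element of each loading positive
    for c in range(components.shape[1]):
        col = components[:, c]
        if col[np.argmax(np.abs(col))] < 0:
            components[:, c] = -col
    return PCAModel(mean=mean, components=components, ratios=ratios, k=components.shape[1])


def pca_transform(model: PCAModel, X, k: Optional[int] = None) -> np.ndarray:
    """Project rows of X onto the first ``k`` (default ``model.k``) loadings."""
    k = model.k if k is None else k
    X = np.asarray(X, dtype=float)
    if X.shape[-1] != model.mean.size:
        raise ValueError("data dimensionality does not match the fitted model")
    return (X - model.mean) @ model.components[:, :k]


def select_components(model: PCAModel, threshold: float = 0.80) -> int:
    """Smallest k whose cumulative explained-variance ratio exceeds threshold."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    cum = np.cumsum(model.ratios)
    above = np.flatnonzero(cum > threshold)
    return int(above[0]) + 1 if above.size else int(model.ratios.size)


def _resample_depth(data: np.ndarray, target: int) -> np.ndarray:
    nz = data.shape[2]
    if nz == target:
        return data
    if nz == 1:
        return np.repeat(data, target, axis=2)
    xo = np.linspace(0.0, 1.0, nz)
    xn = np.linspace(0.0, 1.0, target)
    return interp1d(xo, data, axis=2, assume_sorted=True)(xn)


def unfold_cubes(cubes: Sequence[ReflectivityCube], target_depth_samples: int = 20):
    """Unfold cubes into the stage-1 matrix (lesion x lateral point rows).

    Depth axes are linearly resampled to ``target_depth_samples`` (cube depths
    differ after truncation).  Returns ``(matrix, index_map)`` where row r of
    the (lesions * lateral points) x depth matrix holds the depth profile of
    lateral point ``index_map[r] = (lesion, i, j)``.
    """
    if not cubes:
        raise ValueError("unfold_cubes needs at least one cube")
    lateral = cubes[0].data.shape[:2]
    for c in cubes:
        if c.data.shape[:2] != lateral:
            raise ValueError("all cubes must share the same lateral shape")
    rows = []
    index = []
    nx, ny = lateral
    for li, c in enumerate(cubes):
        arr = _resample_depth(c.data, target_depth_samples)
        rows.append(arr.reshape(nx * ny, target_depth_samples))
        for i in range(nx):
            for j in range(ny):
                index.append((li, i, j))
    return np.vstack(rows), np.asarray(index, dtype=int)


def refold_rows(matrix: np.ndarray, index_map: np.ndarray, lateral_shape) -> List[np.ndarray]:
    """Inverse of :func:`unfold_cubes` at the resampled depth (round-trip check)."""
    nx, ny = lateral_shape
    nz = matrix.shape[1]
    n_lesions = int(index_map[:, 0].max()) + 1
    out = [np.empty((nx, ny, nz)) for _ in range(n_lesions)]
    for row, (li, i, j) in zip(matrix, index_map):
        out[li][i, j] = row
    return out


@dataclass(frozen=True)
class ThreeDPCAModel:
    """Fitted two-stage (or flat) 3D-PCA feature model."""

    stage1: Optional[PCAModel]
    stage2: PCAModel
    k_final: int
    target_depth_samples: int
    lateral_shape: tuple
    scheme: str = "two-stage"


def extract_features(
    cubes: Sequence[ReflectivityCube],
    lesion_ids: Optional[Sequence[str]] = None,
    k_final: int = 6,
    stage1_threshold: float = 0.80,
    target_depth_samples: int = 20,
    scheme: str = "two-stage",
):
    """Fit the 3D-PCA feature model on a cohort of cubes.

    Two-stage scheme (default): stage 1 is a PCA on the unfolded
    (lesion x lateral point) x depth matrix, keeping the depth modes selected
    at ``stage1_threshold``; each lesion's per-point stage-1 scores are
    concatenated into one row and stage 2 is a PCA across lesions retaining
    ``k_final`` components.  ``scheme='flat'`` instead runs a single PCA on
    the flattened voxel vectors (for comparison).  Returns
    ``(model, FeatureMatrix)``.
    """
    if len(cubes) < 3:
        raise ValueError("feature extraction needs at least 3 lesions")
    if lesion_ids is None:
        lesion_ids = tuple(c.lesion_id for c in cubes)
    lateral = cubes[0].data.shape[:2]
    n_lesions = len(cubes)
    X, _ = unfold_cubes(cubes, target_depth_samples)
    if scheme == "flat":
        flat = X.reshape(n_lesions, -1)
        m2 = fit_pca(flat)
        if k_final > m2.k:
            raise ValueError(f"k_final={k_final} exceeds available rank {m2.k}")
        model = ThreeDPCAModel(None, replace(m2, k=k_final), k_final,
                               target_depth_samples, lateral, scheme="flat")
        scores = pca_transform(m2, flat, k_final)
        return model, FeatureMatrix(scores, tuple(lesion_ids))
    if scheme != "two-stage":
        raise ValueError(f"unknown scheme {scheme!r}")
    m1 = fit_pca(X)
    k1 = select_components(m1, stage1_threshold)
    s1 = pca_transform(m1, X, k1)
    rows2 = s1.reshape(n_lesions, -1)
    m2 = fit_pca(rows2)  # raises on a degenerate (identical-cube) cohort
    if k_final > m2.k:
        raise ValueError(f"k_final={k_final} exceeds available rank {m2.k}")
    model = ThreeDPCAModel(replace(m1, k=k1), replace(m2, k=k_final), k_final,
                           target_depth_samples, lateral)
    scores = pca_transform(m2, rows2, k_final)
    return model, FeatureMatrix(scores, tuple(lesion_ids))


def project(
    model: ThreeDPCAModel,
    cubes: Sequence[ReflectivityCube],
    lesion_ids: Optional[Sequence[str]] = None,
) -> FeatureMatrix:
    """Project new cubes with the training means and loadings (never refits)."""
    if lesion_ids is None:
        lesion_ids = tuple(c.lesion_id for c in cubes)
    for c in cubes:
        if c.data.shape[:2] != tuple(model.lateral_shape):
            raise ValueError("cube lateral shape does not match the fitted model")
    X, _ = unfold_cubes(cubes, model.target_depth_samples)
    n_lesions = len(cubes)
    if model.scheme == "flat":
        flat = X.reshape(n_lesions, -1)
        return FeatureMatrix(
            pca_transform(model.stage2, flat, model.k_final), tuple(lesion_ids)
        )
    s1 = pca_transform(model.stage1, X)
    rows2 = s1.reshape(n_lesions, -1)
    return FeatureMatrix(
        pca_transform(model.stage2, rows2, model.k_final), tuple(lesion_ids)
    )
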