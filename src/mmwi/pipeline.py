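"""End-to-end pipeline orchestration, cohort summaries, and reporting.

The pipeline chains simulate -> synthesize -> reconstruct -> depth ->
features -> classify -> report, with a single JSON-serializable configuration
object that is written (resolved) beside every run's outputs for provenance.
Each stage can also be invoked independently on a workspace directory (the
CLI wraps the stage functions one-to-one), with intermediates persisted as
CSV and .npz files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path


import numpy as np
import pandas as pd

from . import io as _io
from .classify import (
    ClassifierConfig,
    FeatureSource,
    confusion_at_cutoff,
    loocv,
    optimum_point,
    per_class_accuracy,
    roc_curve,
    round_half_away,
    search_pc_combinations,
)
from .cohort import (
    BAND1,
    BAND2,
    DERMIS,
    FrequencyGrid,
    MALIGNANT_SUBTYPES,
    ScanGeometry,
    STUDY_COMPOSITION,
    debye_permittivity,
    generate_cohort,
)
from .depth import estimate_depth, truncate_to_depth
from .pca3d import extract_features
from .reconstruction import VoxelSpec, reconstruct_cube
from .synthesis import synthesize_dataset, validity_filter

logger = logging.getLogger("mmwi")

__all__ = [
    "PipelineConfig",
    "CohortSummary",
    "summarize_cohort",
    "run_pipeline",
    "contrast_study",
    "stage_simulate",
    "stage_synthesize",
    "stage_reconstruct",
    "stage_depth",
    "stage_features",
    "stage_search",
    "stage_classify",
    "stage_report",
]


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run (JSON round-trippable)."""

    seed: int = 0
    output_dir: str = "mmwi_out"
    # generator
    composition: dict = field(default_factory=lambda: dict(STUDY_COMPOSITION))
    n_invalid: int = 10
    contrast: float = 0.3
    noise_level: float = 0.02
    n_freq: int = 128
    grid_shape: tuple = (8, 6)
    increment_mm: float = 1.5
    standoff_mm: float = 20.0
    fov_mm: tuple = (4.0, 8.0)
    # synthesis / validity
    dip_depth_db: float = 6.0
    dip_width: int = 5
    nyquist_ref_ghz: float = 100.0
    # reconstruction
    lateral_oversample: int = 4
    depth_samples: int = 20
    window: str = "hann"
    epsilon_model: str = "dermis"  # or "free-space"
    # depth estimation
    n_columns: int = 30
    depth_mode: str = "profile-mean"
    # features
    pca_threshold: float = 0.80
    k_final: int = 6
    target_depth_samples: int = 20
    pca_scheme: str = "two-stage"
    # classification
    families: tuple = ("LDA", "KNN", "LSVM", "GSVM", "MLP")
    knn_grid: tuple = (1, 3, 5, 7)
    svm_grid: tuple = (0.5, 1.0, 2.0, 4.0)
    mlp_max_iter: int = 500
    cutoff: float = 0.5

    def geometry(self) -> ScanGeometry:
        return ScanGeometry(
            shape=tuple(self.grid_shape),
            increment_mm=self.increment_mm,
            standoff_mm=self.standoff_mm,
            fov_mm=tuple(self.fov_mm),
        )

    def grids(self):
        return (
            FrequencyGrid(BAND1.start_ghz, BAND1.stop_ghz, self.n_freq),
            FrequencyGrid(BAND2.start_ghz, BAND2.stop_ghz, self.n_freq),
        )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        data = json.loads(text)
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in data:
                v = data[f.name]
                kwargs[f.name] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


@dataclass(frozen=True)
class CohortSummary:
    """Counts and integer percentages per subtype and site, within class.

    Percentages are a pure function of the counts: round(100 * count /
    class_total) with halves away from zero; for an empty class they are
    reported as missing (None).
    """

    subtype_counts: dict
    subtype_percent: dict
    site_counts: dict
    site_percent: dict
    class_totals: dict


def _count_block(frame: pd.DataFrame, column: str):
    counts: dict = {}
    percent: dict = {}
    totals: dict = {}
    for label, grp in frame.groupby("label"):
        total = len(grp)
        totals[label] = total
        counts[label] = grp[column].value_counts().to_dict()
        percent[label] = {
            k: (round_half_away(100.0 * v / total) if total > 0 else None)
            for k, v in counts[label].items()
        }
    return counts, percent, totals


def summarize_cohort(table: pd.DataFrame) -> CohortSummary:
    """Summarize a cohort table: per-class subtype and body-site breakdowns."""
    if table.empty:
        raise ValueError("cohort table is empty")
    sub_c, sub_p, totals = _count_block(table, "subtype")
    site_c, site_p, _ = _count_block(table, "site")
    return CohortSummary(sub_c, sub_p, site_c, site_p, totals)


# ---------------------------------------------------------------------------
# pipeline stages (workspace-backed; each loads what the previous stage wrote)
# ---------------------------------------------------------------------------


def _ws(cfg: PipelineConfig) -> Path:
    ws = Path(cfg.output_dir)
    ws.mkdir(parents=True, exist_ok=True)
    return ws


def load_config(workspace) -> PipelineConfig:
    return PipelineConfig.from_json((Path(workspace) / "config.json").read_text())


def stage_simulate(cfg: PipelineConfig):
    ws = _ws(cfg)
    (ws / "config.json").write_text(cfg.to_json())
    logger.info("simulate: seed=%d hash=%s", cfg.seed, cfg.config_hash)
    g1, g2 = cfg.grids()
    table, scans = generate_cohort(
        composition=dict(cfg.composition),
        contrast=cfg.contrast,
        n_invalid=cfg.n_invalid,
        noise_level=cfg.noise_level,
        seed=cfg.seed,
        geometry=cfg.geometry(),
        grid1=g1,
        grid2=g2,
        out_dir=ws,
    )
    return table, scans


def _load_scans(cfg, table):
    ws = Path(cfg.output_dir)
    return [_io.load_scan(ws / p) for p in table["scan_path"]]


def stage_synthesize(cfg: PipelineConfig, table=None, scans=None):
    """Calibrate, merge sub-bands, and flag invalid lesions."""
    ws = _ws(cfg)
    if table is None:
        table = pd.read_csv(ws / "cohort.csv")
    if scans is None:
        scans = _load_scans(cfg, table)
    signals = []
    valid_flags = []
    for ds in scans:
        sigs = synthesize_dataset(ds)
        ok, _report = validity_filter(sigs, cfg.dip_depth_db, cfg.dip_width)
        signals.append(sigs)
        valid_flags.append(ok)
    validity = table[["lesion_id"]].copy()
    validity["valid"] = valid_flags
    validity.to_csv(ws / "validity.csv", index=False)
    logger.info("synthesize: %d/%d lesions valid", int(np.sum(valid_flags)), len(scans))
    uwb_dir = ws / "uwb"
    uwb_dir.mkdir(exist_ok=True)
    for lesion_id, sigs in zip(table["lesion_id"], signals):
        np.savez(
            uwb_dir / f"{lesion_id}.npz",
            freq_ghz=sigs[0].freq_ghz,
            values=np.stack([s.values for s in sigs]),
            positions=np.array([s.position for s in sigs]),
        )
    return table, signals, np.asarray(valid_flags)


def _load_uwb(cfg, table):
    from .synthesis import UWBSignal

    ws = Path(cfg.output_dir)
    out = []
    for lesion_id in table["lesion_id"]:
        z = np.load(ws / "uwb" / f"{lesion_id}.npz")
        out.append(
            [
                UWBSignal(tuple(int(v) for v in pos), z["freq_ghz"], vals)
                for pos, vals in zip(z["positions"], z["values"])
            ]
        )
    return out


def stage_reconstruct(cfg: PipelineConfig, table=None, signals=None, valid=None):
    ws = _ws(cfg)
    if table is None:
        table = pd.read_csv(ws / "cohort.csv")
        validity = pd.read_csv(ws / "validity.csv")
        valid = validity["valid"].to_numpy()
    if signals is None:
        signals = _load_uwb(cfg, table)
    geometry = cfg.geometry()
    medium = DERMIS if cfg.epsilon_model == "dermis" else None
    eps_real = float(np.real(debye_permittivity(DERMIS, 61.0))) if medium else 1.0
    spec = VoxelSpec.for_aperture(
        geometry,
        lateral_oversample=cfg.lateral_oversample,
        nz=cfg.depth_samples,
        eps_real=eps_real,
    )
    cubes = []
    kept = table[valid].reset_index(drop=True)
    cube_dir = ws / "cubes"
    cube_dir.mkdir(exist_ok=True)
    for lesion_id, sigs in zip(table["lesion_id"], signals):
        if lesion_id not in set(kept["lesion_id"]):
            continue
        cube = reconstruct_cube(sigs, geometry, spec, medium=medium,
                                window=cfg.window, lesion_id=lesion_id)
        _io.save_cube(cube_dir / f"{lesion_id}.npz", cube)
        cubes.append(cube)
    logger.info("reconstruct: %d cubes on %dx%dx%d voxels",
                len(cubes), spec.nx, spec.ny, spec.nz)
    return kept, cubes


def _spots_for_lesion(row, spec: VoxelSpec):
    cx, cy = row["lesion_cx_mm"], row["lesion_cy_mm"]
    r = row["lesion_radius_mm"]
    ci = int(np.clip(round((cx - spec.x0) / spec.dx), 0, spec.nx - 1))
    cj = int(np.clip(round((cy - spec.y0) / spec.dy), 0, spec.ny - 1))
    mi = int(np.clip(round((cx + r - spec.x0) / spec.dx), 0, spec.nx - 1))
    return (ci, cj), (mi, cj)


def stage_depth(cfg: PipelineConfig, kept=None, cubes=None):
    ws = _ws(cfg)
    if kept is None or cubes is None:
        table = pd.read_csv(ws / "cohort.csv")
        validity = pd.read_csv(ws / "validity.csv")
        kept = table[validity["valid"].to_numpy()].reset_index(drop=True)
        cubes = [_io.load_cube(ws / "cubes" / f"{lid}.npz") for lid in kept["lesion_id"]]
    truncated = []
    rows = []
    tdir = ws / "cubes_truncated"
    tdir.mkdir(exist_ok=True)
    for (_, row), cube in zip(kept.iterrows(), cubes):
        center, margin = _spots_for_lesion(row, cube.spec)
        est = estimate_depth(cube, center, margin, n_columns=cfg.n_columns,
                             mode=cfg.depth_mode)
        t = truncate_to_depth(cube, est)
        _io.save_cube(tdir / f"{row['lesion_id']}.npz", t)
        truncated.append(t)
        rows.append(
            {
                "lesion_id": row["lesion_id"],
                "depth_center_mm": est.depth_center_mm,
                "depth_margin_mm": est.depth_margin_mm,
                "depth_mm": est.depth_mm,
            }
        )
    depth_table = pd.DataFrame(rows)
    depth_table.to_csv(ws / "depth.csv", index=False)
    return kept, truncated, depth_table


def stage_features(cfg: PipelineConfig, kept=None, truncated=None):
    ws = _ws(cfg)
    if kept is None or truncated is None:
        table = pd.read_csv(ws / "cohort.csv")
        validity = pd.read_csv(ws / "validity.csv")
        kept = table[validity["valid"].to_numpy()].reset_index(drop=True)
        truncated = [
            _io.load_cube(ws / "cubes_truncated" / f"{lid}.npz")
            for lid in kept["lesion_id"]
        ]
    model, fm = extract_features(
        truncated,
        lesion_ids=tuple(kept["lesion_id"]),
        k_final=cfg.k_final,
        stage1_threshold=cfg.pca_threshold,
        target_depth_samples=cfg.target_depth_samples,
        scheme=cfg.pca_scheme,
    )
    cols = {f"PC{i + 1}": fm.scores[:, i] for i in range(fm.scores.shape[1])}
    feats = pd.DataFrame({"lesion_id": kept["lesion_id"], **cols})
    feats.to_csv(ws / "features.csv", index=False)
    variance = {
        "stage1_ratios": None if model.stage1 is None else model.stage1.ratios.tolist(),
        "stage1_k": None if model.stage1 is None else model.stage1.k,
        "stage2_ratios": model.stage2.ratios.tolist(),
        "k_final": model.k_final,
    }
    (ws / "pca_variance.json").write_text(json.dumps(variance, indent=2))
    return kept, truncated, model, fm


def _source_from(cfg: PipelineConfig, kept, truncated) -> FeatureSource:
    labels = (kept["subtype"].isin(sorted(MALIGNANT_SUBTYPES))).astype(int).to_numpy()
    return FeatureSource(
        labels=labels,
        cubes=list(truncated),
        lesion_ids=tuple(kept["lesion_id"]),
        k_final=cfg.k_final,
        stage1_threshold=cfg.pca_threshold,
        target_depth_samples=cfg.target_depth_samples,
    )


def stage_search(cfg: PipelineConfig, kept=None, truncated=None) -> pd.DataFrame:
    ws = _ws(cfg)
    if kept is None or truncated is None:
        kept, truncated, _ = stage_depth(cfg)
    source = _source_from(cfg, kept, truncated)
    grids = {"KNN": tuple(cfg.knn_grid), "LSVM": tuple(cfg.svm_grid),
             "GSVM": tuple(cfg.svm_grid)}
    search = search_pc_combinations(
        source, families=tuple(cfg.families), grids=grids,
        mlp_max_iter=cfg.mlp_max_iter, seed=cfg.seed
    )
    search.to_csv(ws / "search.csv", index=False)
    return search


def stage_classify(cfg: PipelineConfig, config: ClassifierConfig, kept, truncated):
    """LOO-CV of one classifier configuration; writes scores and ROC tables."""
    ws = _ws(cfg)
    source = _source_from(cfg, kept, truncated)
    result = loocv(config, source)
    ok = ~np.isnan(result.scores)
    roc = roc_curve(result.scores[ok], source.labels[ok])
    scores = pd.DataFrame(
        {
            "lesion_id": kept["lesion_id"],
            "subtype": kept["subtype"],
            "label": source.labels,
            "malignancy_score": result.scores,
        }
    )
    scores.to_csv(ws / "scores.csv", index=False)
    pd.DataFrame(
        {"threshold": roc.thresholds, "sensitivity": roc.tpr,
         "one_minus_specificity": roc.fpr}
    ).to_csv(ws / "roc.csv", index=False)
    return scores, roc, source


def stage_report(cfg: PipelineConfig, table, valid, depth_table, search, scores,
                 roc, source) -> dict:
    ws = _ws(cfg)
    summary = summarize_cohort(table)
    counts, sens, spec = confusion_at_cutoff(
        scores["malignancy_score"].to_numpy()[~np.isnan(scores["malignancy_score"])],
        source.labels[~np.isnan(scores["malignancy_score"].to_numpy())],
        cfg.cutoff,
    )
    thr, osens, ospec = optimum_point(roc)
    ok = ~np.isnan(scores["malignancy_score"].to_numpy())
    acc = per_class_accuracy(
        scores["malignancy_score"].to_numpy()[ok],
        source.labels[ok],
        scores["subtype"].to_numpy()[ok],
        cfg.cutoff,
    )
    out = {
        "n_total": int(len(table)),
        "n_valid": int(np.sum(valid)),
        "cohort": {
            "subtype_counts": summary.subtype_counts,
            "subtype_percent": summary.subtype_percent,
            "site_counts": summary.site_counts,
            "site_percent": summary.site_percent,
        },
        "depth_mm": {
            "mean": float(depth_table["depth_mm"].mean()),
            "std": float(depth_table["depth_mm"].std(ddof=1))
            if len(depth_table) > 1
            else 0.0,
        },
        "search": search.to_dict(orient="records"),
        "best": search.iloc[0].to_dict(),
        "auc": roc.auc,
        "cutoff": cfg.cutoff,
        "sensitivity_at_cutoff": sens,
        "specificity_at_cutoff": spec,
        "optimum": {"threshold": thr, "sensitivity": osens, "specificity": ospec},
        "per_class_accuracy": {str(k): (None if pd.isna(v) else int(v))
                               for k, v in acc.items()},
        "non_discriminative": bool(roc.auc < 0.6),
        "seed": cfg.seed,
        "config_hash": cfg.config_hash,
    }
    (ws / "summary.json").write_text(json.dumps(out, indent=2, sort_keys=True))
    lines = [
        "# Millimeter-wave lesion pipeline report",
        "",
        f"- lesions scanned: {out['n_total']}",
        f"- lesions valid after spectral-dip filtering: {out['n_valid']}",
        f"- mean penetration depth: {out['depth_mm']['mean']:.2f} mm "
        f"(sd {out['depth_mm']['std']:.2f})",
        f"- best classifier: {out['best']['family']} {out['best']['pc_mask']} "
        f"AUC={out['best']['auc']:.3f}",
        f"- full-cohort AUC of the best configuration: {roc.auc:.3f}"
        + (" (non-discriminative)" if out["non_discriminative"] else ""),
        "",
        "## Cohort composition (count, percent within class)",
    ]
    for label in sorted(summary.subtype_counts):
        lines.append(f"### {label}")
        for sub, cnt in sorted(summary.subtype_counts[label].items()):
            pct = summary.subtype_percent[label][sub]
            lines.append(f"- {sub}: {cnt} ({pct}%)")
    lines += ["", "## Classifier search", search.to_markdown(index=False)]
    lines += ["", "## Per-diagnosis accuracy at cutoff "
              f"{cfg.cutoff}", acc.to_markdown()]
    (ws / "report.md").write_text("\n".join(lines) + "\n")
    return out


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages in order and return the summary dictionary.

    Rerunning with the same configuration reproduces identical tabular
    outputs (all randomness derives from ``cfg.seed``); per-stage wall times
    are logged, not written into the outputs.
    """
    import time

    t = time.perf_counter()

    def _tick(stage):
        nonlocal t
        now = time.perf_counter()
        logger.info("stage %s finished in %.1fs (seed=%d)", stage, now - t, cfg.seed)
        t = now

    table, scans = stage_simulate(cfg)
    _tick("simulate")
    table, signals, valid = stage_synthesize(cfg, table, scans)
    _tick("synthesize")
    kept, cubes = stage_reconstruct(cfg, table, signals, valid)
    _tick("reconstruct")
    kept, truncated, depth_table = stage_depth(cfg, kept, cubes)
    _tick("depth")
    stage_features(cfg, kept, truncated)
    _tick("features")
    search = stage_search(cfg, kept, truncated)
    _tick("search")
    best = search.iloc[0]
    kwargs = {}
    if best["family"] == "KNN":
        kwargs["k_neighbors"] = int(best["hyperparameter"])
    elif best["family"] in ("LSVM", "GSVM"):
        kwargs["c"] = float(best["hyperparameter"])
    config = ClassifierConfig(
        family=best["family"],
        pc_mask=tuple(int(ch) for ch in best["pc_mask"].strip("[]")),
        seed=cfg.seed,
        mlp_max_iter=cfg.mlp_max_iter,
        **kwargs,
    )
    scores, roc, source = stage_classify(cfg, config, kept, truncated)
    return stage_report(cfg, table, valid, depth_table, search, scores, roc, source)


def contrast_study(
    contrasts=(0.0, 0.2, 0.5),
    n_seeds: int = 20,
    n_per_class: int = 14,
    seed: int = 0,
    n_freq: int = 64,
    depth_samples: int = 12,
    n_columns: int = 5,
    k_final: int = 6,
) -> pd.DataFrame:
    """Small end-to-end cohorts at several dielectric contrasts.

    For each contrast level and replicate seed, a balanced benign/malignant
    cohort is generated, synthesized, reconstructed, depth-truncated,
    3D-PCA-featured, and scored by LDA under LOO-CV (with per-fold PCA
    refits); the LOO-CV AUC is recorded.  Used to verify that discrimination
    vanishes at zero contrast and grows monotonically with the malignant
    dielectric offset.
    """
    composition = {"melanocytic_nevus": n_per_class, "basal_cell_carcinoma": n_per_class}
    rows = []
    geometry = ScanGeometry()
    for ci, contrast in enumerate(contrasts):
        for rep in range(n_seeds):
            cohort_seed = (seed * 9973 + ci * 1009 + rep * 13 + 1) % (2**31 - 1)
            cfg = PipelineConfig(
                seed=cohort_seed,
                composition=composition,
                n_invalid=0,
                contrast=float(contrast),
                n_freq=n_freq,
                lateral_oversample=1,
                depth_samples=depth_samples,
                n_columns=n_columns,
                k_final=k_final,
            )
            g1, g2 = cfg.grids()
            table, scans = generate_cohort(
                composition=composition,
                contrast=float(contrast),
                n_invalid=0,
                noise_level=cfg.noise_level,
                seed=cohort_seed,
                geometry=geometry,
                grid1=g1,
                grid2=g2,
            )
            spec = VoxelSpec.for_aperture(geometry, 1, depth_samples, eps_real=15.0)
            cubes = []
            for ds, (_, row) in zip(scans, table.iterrows()):
                sigs = synthesize_dataset(ds)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cube = reconstruct_cube(sigs, geometry, spec, medium=DERMIS)
                center, margin = _spots_for_lesion(row, spec)
                est = estimate_depth(cube, center, margin, n_columns=n_columns)
                cubes.append(truncate_to_depth(cube, est))
            labels = (table["label"] == "malignant").astype(int).to_numpy()
            source = FeatureSource(labels=labels, cubes=cubes, k_final=k_final,
                                   target_depth_samples=depth_samples)
            config = ClassifierConfig(family="LDA", pc_mask=(1,) * k_final)
            result = loocv(config, source)
            ok = ~np.isnan(result.scores)
            auc = roc_curve(result.scores[ok], labels[ok]).auc
            rows.append({"contrast": float(contrast), "rep": rep, "auc": auc})
    return pd.DataFrame(rows)
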