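"""Classifier evaluation: LOO-CV malignancy scores, ROC, search, extrapolation.

Five classifier families (LDA, KNN, linear and Gaussian SVM, MLP) are
evaluated over every nonempty principal-component subset under leave-one-out
cross-validation.  The PCA feature model is refit on the training lesions of
every fold and the held-out lesion is projected with the training loadings, so
no test information leaks into the features.  Each classifier emits a
malignancy score in [0, 1] (a posterior probability for the malignant class);
scores are summarized as ROC curves, AUCs, Youden-optimal operating points,
confusion counts at the 0.5 cutoff, and per-diagnosis accuracies.  Learning
curves over random repeated subsampling (RRS) extrapolate the error rate to
large cohorts, and bootstrapped AUC differences compare two ROC curves.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import argrelmin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve as _sk_roc_curve
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .pca3d import extract_features, project
from .synthesis import UWBSignal

__all__ = [
    "FAMILIES",
    "DEFAULT_GRIDS",
    "ClassifierConfig",
    "ConfusionCounts",
    "CVResult",
    "ROCCurve",
    "FeatureSource",
    "train_and_score",
    "feature_folds",
    "loocv",
    "confusion_at_cutoff",
    "roc_curve",
    "optimum_point",
    "search_pc_combinations",
    "per_class_accuracy",
    "fit_learning_curve",
    "rrs_extrapolate",
    "RRSResult",
    "compare_roc",
    "CompareResult",
    "reproducibility_variance",
    "ReproducibilityResult",
    "round_half_away",
]

FAMILIES = ("LDA", "KNN", "LSVM", "GSVM", "MLP")
# Hyperparameter grids: K in {1,3,5,7}; SVM margin factor 0.1..4.0 step 0.1
# (an SVM requires C > 0, so the grid starts one step above zero).
DEFAULT_GRIDS = {
    "KNN": (1, 3, 5, 7),
    "LSVM": tuple(round(0.1 * i, 1) for i in range(1, 41)),
    "GSVM": tuple(round(0.1 * i, 1) for i in range(1, 41)),
}


def round_half_away(x: float) -> int:
    """Round to the nearest integer with halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class ClassifierConfig:
    """One classifier family with its hyperparameter and PC-subset mask."""

    family: str
    pc_mask: tuple
    k_neighbors: Optional[int] = None
    c: Optional[float] = None
    mlp_hidden: int = 10
    mlp_max_iter: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown classifier family {self.family!r}")
        if sum(self.pc_mask) < 1:
            raise ValueError("PC mask must select at least one component")
        if self.family == "KNN" and self.k_neighbors is None:
            raise ValueError("KNN requires k_neighbors")
        if self.family in ("LSVM", "GSVM") and (self.c is None or self.c <= 0):
            raise ValueError("SVMs require a margin factor C > 0")
        if self.family not in ("LSVM", "GSVM") and self.c is not None:
            raise ValueError("C is only meaningful for SVM families")
        if self.family != "KNN" and self.k_neighbors is not None:
            raise ValueError("k_neighbors is only meaningful for KNN")

    @property
    def mask_str(self) -> str:
        return "[" + "".join(str(int(b)) for b in self.pc_mask) + "]"


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class CVResult:
    """Per-lesion malignancy scores from cross-validation."""

    scores: np.ndarray
    folds: np.ndarray
    config: ClassifierConfig
    skipped_folds: list = field(default_factory=list)


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    tpr: np.ndarray  # sensitivity
    fpr: np.ndarray  # 1 - specificity
    auc: float


@dataclass
class FeatureSource:
    """Inputs to cross-validation: labels plus cubes or fixed features.

    With ``cubes`` set, the 3D-PCA feature model is refit inside every fold;
    with precomputed ``features``, folds only split rows (used when features
    were derived independently of the evaluation, e.g. in unit tests).
    """

    labels: np.ndarray
    cubes: Optional[list] = None
    features: Optional[np.ndarray] = None
    lesion_ids: Optional[tuple] = None
    k_final: int = 6
    stage1_threshold: float = 0.80
    target_depth_samples: int = 20

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if (self.cubes is None) == (self.features is None):
            raise ValueError("provide exactly one of cubes or features")
        if self.features is not None:
            self.features = np.asarray(self.features, dtype=float)
            if self.features.shape[0] != self.labels.size:
                raise ValueError("features and labels must align")
        elif len(self.cubes) != self.labels.size:
            raise ValueError("cubes and labels must align")

    @property
    def n(self) -> int:
        return self.labels.size


def _median_heuristic_gamma(X: np.ndarray) -> float:
    d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    med = np.median(d2[np.triu_indices_from(d2, k=1)])
    return 1.0 / med if med > 0 else 1.0


def train_and_score(
    config: ClassifierConfig,
    train_features: np.ndarray,
    train_labels: np.ndarray,
    test_features: np.ndarray,
) -> np.ndarray:
    """Train one configuration and return malignancy scores in [0, 1].

    LDA -> Gaussian posterior; KNN -> malignant fraction among the K nearest
    training lesions; SVMs -> Platt sigmoid (logistic fit on the training
    decision values) of the margin; MLP -> output activation of a single
    10-unit logistic hidden-layer network.
    """
    Xtr = np.asarray(train_features, dtype=float)
    Xte = np.atleast_2d(np.asarray(test_features, dtype=float))
    y = np.asarray(train_labels, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("training set must contain both classes")
    mask = np.asarray(config.pc_mask, dtype=bool)
    if mask.size != Xtr.shape[1]:
        raise ValueError("PC mask length does not match feature width")
    Xtr = Xtr[:, mask]
    Xte = Xte[:, mask]
    fam = config.family
    if fam == "LDA":
        clf = LinearDiscriminantAnalysis()
        clf.fit(Xtr, y)
        s = clf.predict_proba(Xte)[:, 1]
    elif fam == "KNN":
        k = min(config.k_neighbors, Xtr.shape[0])
        clf = KNeighborsClassifier(n_neighbors=k)
        clf.fit(Xtr, y)
        s = clf.predict_proba(Xte)[:, list(clf.classes_).index(1)]
    elif fam in ("LSVM", "GSVM"):
        if fam == "LSVM":
            clf = SVC(kernel="linear", C=config.c)
        else:
            clf = SVC(kernel="rbf", C=config.c, gamma=_median_heuristic_gamma(Xtr))
        clf.fit(Xtr, y)
        d_tr = clf.decision_function(Xtr).reshape(-1, 1)
        platt = LogisticRegression(C=1e3)
        platt.fit(d_tr, y)
        s = platt.predict_proba(clf.decision_function(Xte).reshape(-1, 1))[:, 1]
    elif fam == "MLP":
        clf = MLPClassifier(
            hidden_layer_sizes=(config.mlp_hidden,),
            activation="logistic",
            max_iter=config.mlp_max_iter,
            random_state=config.seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(Xtr, y)
        s = clf.predict_proba(Xte)[:, list(clf.classes_).index(1)]
    else:  # pragma: no cover - guarded by the config validator
        raise ValueError(fam)
    return np.clip(s, 0.0, 1.0)


def feature_folds(source: FeatureSource, refit_per_fold: bool = True):
    """Leave-one-out feature folds: (train X, train y, held-out x) per lesion.

    With a cube-backed source the PCA model is refit on each fold's training
    cubes and the held-out cube projected with those loadings.
    ``refit_per_fold=False`` deliberately fits the PCA once on all lesions (a
    leaky variant kept only for leakage diagnostics in tests).
    """
    n = source.n
    folds = []
    if source.features is not None:
        X = source.features
        for i in range(n):
            idx = np.arange(n) != i
            folds.append((X[idx], source.labels[idx], X[i]))
        return folds
    if not refit_per_fold:
        _, fm = extract_features(
            source.cubes,
            k_final=source.k_final,
            stage1_threshold=source.stage1_threshold,
            target_depth_samples=source.target_depth_samples,
        )
        X = fm.scores
        for i in range(n):
            idx = np.arange(n) != i
            folds.append((X[idx], source.labels[idx], X[i]))
        return folds
    for i in range(n):
        idx = [k for k in range(n) if k != i]
        train_cubes = [source.cubes[k] for k in idx]
        model, fm = extract_features(
            train_cubes,
            k_final=source.k_final,
            stage1_threshold=source.stage1_threshold,
            target_depth_samples=source.target_depth_samples,
        )
        x_te = project(model, [source.cubes[i]]).scores[0]
        folds.append((fm.scores, source.labels[np.asarray(idx)], x_te))
    return folds


def loocv(
    config: ClassifierConfig,
    source: FeatureSource,
    refit_per_fold: bool = True,
    folds: Optional[list] = None,
) -> CVResult:
    """Leave-one-out cross-validation: one malignancy score per lesion.

    The number of folds equals the number of lesions; each lesion is the test
    set exactly once.  A fold whose training set degenerates to one class is
    recorded, skipped with a warning, and scored NaN.  Precomputed ``folds``
    (from :func:`feature_folds`) may be passed to amortize PCA refits across
    many configurations.
    """
    if source.n < 3:
        raise ValueError("LOO-CV needs at least 3 lesions")
    if np.unique(source.labels).size < 2:
        raise ValueError("cohort must contain both classes")
    if folds is None:
        folds = feature_folds(source, refit_per_fold)
    scores = np.full(source.n, np.nan)
    skipped = []
    for i, (Xtr, ytr, xte) in enumerate(folds):
        if np.unique(ytr).size < 2:
            warnings.warn(f"fold {i} has a single-class training set; skipped")
            skipped.append(i)
            continue
        scores[i] = train_and_score(config, Xtr, ytr, xte[None, :])[0]
    return CVResult(scores=scores, folds=np.arange(source.n), config=config,
                    skipped_folds=skipped)


def confusion_at_cutoff(scores, labels, cutoff: float = 0.5):
    """Confusion counts with positives defined by score > cutoff (strict).

    Returns ``(ConfusionCounts, sensitivity, specificity)``; a metric whose
    denominator class is absent is reported as None.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must align")
    pred = s > cutoff
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    counts = ConfusionCounts(tp, fp, tn, fn)
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    spec = tn / (tn + fp) if (tn + fp) > 0 else None
    return counts, sens, spec


def roc_curve(scores, labels) -> ROCCurve:
    """ROC curve over all distinct score thresholds, AUC by trapezoidal rule.

    The AUC equals the probability of pairwise concordance with ties counted
    one half.  Requires both classes.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("ROC requires both classes")
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    auc = float(roc_auc_score(y, s))
    return ROCCurve(thresholds=thr, tpr=tpr, fpr=fpr, auc=auc)


def optimum_point(roc: ROCCurve):
    """Operating point maximizing the Youden index (sens + spec - 1).

    Ties are broken toward the higher-sensitivity point.  Returns
    ``(threshold, sensitivity, specificity)``.
    """
    youden = roc.tpr - roc.fpr
    best = np.max(youden)
    cand = np.flatnonzero(youden >= best - 1e-12)
    k = cand[np.argmax(roc.tpr[cand])]
    return float(roc.thresholds[k]), float(roc.tpr[k]), float(1.0 - roc.fpr[k])


def _all_masks(k: int):
    for bits in range(1, 2**k):
        yield tuple((bits >> (k - 1 - i)) & 1 for i in range(k))


def search_pc_combinations(
    source: FeatureSource,
    families: Sequence[str] = FAMILIES,
    grids: Optional[dict] = None,
    mlp_max_iter: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Exhaustive PC-subset x hyperparameter search per classifier family.

    Every nonempty PC mask (2^k - 1 of them) is evaluated under LOO-CV for
    every hyperparameter value of each family; the per-family winner by AUC
    (ties: fewer PCs, then lexicographic mask) is returned as one row with its
    Youden-optimal sensitivity and specificity.
    """
    if not families:
        raise ValueError("families must be nonempty")
    grids = dict(DEFAULT_GRIDS) if grids is None else grids
    folds = feature_folds(source)
    k = folds[0][0].shape[1]
    if k > 8:
        raise ValueError("exhaustive mask search is limited to k_final <= 8")
    masks = list(_all_masks(k))
    rows = []
    for family in families:
        if family == "KNN":
            hypers = [("k_neighbors", v) for v in grids.get("KNN", DEFAULT_GRIDS["KNN"])]
        elif family in ("LSVM", "GSVM"):
            hypers = [("c", v) for v in grids.get(family, DEFAULT_GRIDS[family])]
        else:
            hypers = [(None, None)]
        best = None
        for hp_name, hp_val in hypers:
            kwargs = {hp_name: hp_val} if hp_name else {}
            for mask in masks:
                config = ClassifierConfig(
                    family=family, pc_mask=mask, seed=seed,
                    mlp_max_iter=mlp_max_iter, **kwargs
                )
                result = loocv(config, source, folds=folds)
                ok = ~np.isnan(result.scores)
                roc = roc_curve(result.scores[ok], source.labels[ok])
                key = (-roc.auc, sum(mask), mask)
                if best is None or key < best[0]:
                    best = (key, config, roc)
        _, config, roc = best
        thr, sens, spec = optimum_point(roc)
        rows.append(
            {
                "family": config.family,
                "pc_mask": config.mask_str,
                "hyperparameter": config.k_neighbors
                if config.family == "KNN"
                else config.c,
                "auc": roc.auc,
                "sensitivity": sens,
                "specificity": spec,
                "threshold": thr,
            }
        )
    return pd.DataFrame(rows).sort_values("auc", ascending=False).reset_index(drop=True)


def per_class_accuracy(scores, labels, subtypes, cutoff: float = 0.5) -> pd.Series:
    """Percent correctly classified per diagnosis subtype (integer percent).

    Malignant subtypes are correct when score > cutoff, benign subtypes when
    score <= cutoff; percentages use half-away-from-zero rounding.  Subtypes
    with no lesions are reported as missing (NaN), not zero.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    st = np.asarray(subtypes)
    out = {}
    for sub in pd.unique(st):
        idx = st == sub
        if not idx.any():
            out[sub] = np.nan
            continue
        malignant = bool(y[idx][0])
        correct = (s[idx] > cutoff) if malignant else (s[idx] <= cutoff)
        out[sub] = round_half_away(100.0 * correct.mean())
    return pd.Series(out, name="percent_correct")


@dataclass
class RRSResult:
    sizes: np.ndarray
    mean_errors: np.ndarray
    a: float
    b: float
    alpha: float
    extrapolated_error: float
    fit_ok: bool
    diagnostic: str = ""


def fit_learning_curve(sizes, errors):
    """Least-squares fit of e(n) = a + b * n^(-alpha), constrained a >= 0.

    Returns ``(a, b, alpha)``; the plateau ``a`` is the extrapolated error for
    arbitrarily large cohorts.
    """
    n = np.asarray(sizes, dtype=float)
    e = np.asarray(errors, dtype=float)
    if n.size < 3:
        raise ValueError("need at least 3 subset sizes to fit the curve")

    def model(nn, a, b, alpha):
        return a + b * nn ** (-alpha)

    p0 = (max(float(e[-1]), 1e-3), max(float(e[0] - e[-1]), 1e-3), 0.5)
    popt, _ = curve_fit(
        model, n, e, p0=p0,
        bounds=([0.0, -2.0, 0.01], [1.0, 10.0, 5.0]),
        maxfev=20000,
    )
    return float(popt[0]), float(popt[1]), float(popt[2])


def rrs_extrapolate(
    config: ClassifierConfig,
    source: FeatureSource,
    subset_sizes: Sequence[int],
    reps: int = 20,
    seed: int = 0,
) -> RRSResult:
    """Random-repeated-subsampling learning curve and large-n extrapolation.

    For each subset size, ``reps`` stratified subsamples are drawn and the
    LOO-CV misclassification rate (0.5 cutoff) of ``config`` on each subsample
    is averaged; the mean error is then fit with e(n) = a + b n^(-alpha) and
    the plateau ``a`` reported as the extrapolated error.  Deterministic
    given ``seed``.
    """
    sizes = sorted(int(s) for s in subset_sizes)
    if len(sizes) < 3:
        raise ValueError("need at least 3 subset sizes")
    if any(s >= source.n for s in sizes):
        raise ValueError("subset sizes must be below the cohort size")
    if reps < 10:
        raise ValueError("need at least 10 repetitions per size")
    if source.features is None:
        _, fm = extract_features(
            source.cubes,
            k_final=source.k_final,
            stage1_threshold=source.stage1_threshold,
            target_depth_samples=source.target_depth_samples,
        )
        X = fm.scores
    else:
        X = source.features
    y = source.labels
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    mean_errors = []
    for size in sizes:
        n_pos = max(1, round(size * pos.size / y.size))
        n_neg = max(1, size - n_pos)
        errs = []
        for _ in range(reps):
            idx = np.concatenate(
                [rng.choice(pos, n_pos, replace=False), rng.choice(neg, n_neg, replace=False)]
            )
            sub = FeatureSource(labels=y[idx], features=X[idx])
            res = loocv(config, sub)
            ok = ~np.isnan(res.scores)
            pred = res.scores[ok] > 0.5
            errs.append(float(np.mean(pred != (y[idx][ok] == 1))))
        mean_errors.append(float(np.mean(errs)))
    sizes_arr = np.asarray(sizes, dtype=float)
    errors_arr = np.asarray(mean_errors)
    try:
        a, b, alpha = fit_learning_curve(sizes_arr, errors_arr)
        return RRSResult(sizes_arr, errors_arr, a, b, alpha, a, fit_ok=True)
    except Exception as exc:  # fit failure: report the raw curve
        return RRSResult(sizes_arr, errors_arr, np.nan, np.nan, np.nan, np.nan,
                         fit_ok=False, diagnostic=str(exc))


@dataclass
class CompareResult:
    p_value: float
    delta_auc: float
    n_boot: int
    n_redrawn: int = 0


def compare_roc(
    scores_a, labels_a, scores_b, labels_b, n_boot: int = 1000, seed: int = 0
) -> CompareResult:
    """Two-sided bootstrap p-value for the AUC difference of two ROC curves.

    Each result is resampled with stratification within class (so a resample
    can never lose a class; the redraw counter is kept for interface
    compatibility and is always zero), the AUC difference recomputed per
    resample, and the two-sided p-value taken from the bootstrap tail
    fractions with add-one smoothing.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    sa, ya = np.asarray(scores_a, float), np.asarray(labels_a, int)
    sb, yb = np.asarray(scores_b, float), np.asarray(labels_b, int)
    auc_a = roc_auc_score(ya, sa)
    auc_b = roc_auc_score(yb, sb)

    def strata(y):
        return np.flatnonzero(y == 1), np.flatnonzero(y == 0)

    pa, na = strata(ya)
    pb, nb = strata(yb)
    deltas = np.empty(n_boot)
    for t in range(n_boot):
        ia = np.concatenate([rng.choice(pa, pa.size), rng.choice(na, na.size)])
        ib = np.concatenate([rng.choice(pb, pb.size), rng.choice(nb, nb.size)])
        deltas[t] = roc_auc_score(ya[ia], sa[ia]) - roc_auc_score(yb[ib], sb[ib])
    lo = (np.sum(deltas <= 0) + 1) / (n_boot + 1)
    hi = (np.sum(deltas >= 0) + 1) / (n_boot + 1)
    p = min(1.0, 2.0 * min(lo, hi))
    return CompareResult(p_value=float(p), delta_auc=float(auc_a - auc_b),
                         n_boot=n_boot, n_redrawn=0)


def subgroup_compare(
    scores, labels, sites, site: str, n_boot: int = 1000, seed: int = 0
) -> "CompareResult":
    """Compare the ROC of one body-site subgroup against the full cohort.

    Filters the scored lesions to ``site`` (e.g. only head lesions) and
    bootstraps the AUC difference between the subgroup and the complete
    result via :func:`compare_roc`.
    """
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    mask = np.asarray(sites) == site
    if not mask.any():
        raise ValueError(f"no lesions with site {site!r}")
    if np.unique(y[mask]).size < 2:
        raise ValueError(f"subgroup {site!r} does not contain both classes")
    return compare_roc(s[mask], y[mask], s, y, n_boot=n_boot, seed=seed)


@dataclass
class ReproducibilityResult:
    freq_ghz: np.ndarray
    rel_variance_percent: np.ndarray
    max_percent: float
    minima_ghz: list


def reproducibility_variance(repeats: Sequence[UWBSignal]) -> ReproducibilityResult:
    """Per-frequency relative variance of repeated sweeps from one site.

    For >= 2 repeats on identical grids, computes the variance of the
    magnitude across repeats at each frequency as a percent of the squared
    mean magnitude, reports its maximum, and lists the spectral-minimum
    abscissas of each repeat (their stability across repeats indicates
    reproducible measurements).  Scale-invariant by construction.
    """
    if len(repeats) < 2:
        raise ValueError("need at least 2 repeated sweeps")
    f = repeats[0].freq_ghz
    for r in repeats:
        if r.freq_ghz.shape != f.shape or not np.allclose(r.freq_ghz, f):
            raise ValueError("repeats must share one frequency grid")
    mags = np.vstack([np.abs(r.values) for r in repeats])
    mean = mags.mean(axis=0)
    var = mags.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(mean > 0, 100.0 * var / mean**2, 0.0)
    minima = [f[argrelmin(m)[0]].tolist() for m in mags]
    return ReproducibilityResult(
        freq_ghz=f,
        rel_variance_percent=rel,
        max_percent=float(rel.max()),
        minima_ghz=minima,
    )
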