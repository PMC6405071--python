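"""Object-based random-forest classification, feature-set ablation and accuracy.

The experiment compares five feature sets on the same object geometry and
train/test split:

    set 1: 6 spectral indices + 15 GLCM textures            (21 layers)
    set 2: set 1 + MDIN                                     (22 layers)
    set 3: set 1 + MDRLR                                    (22 layers)
    set 4: set 1 + MDRRL                                    (22 layers)
    set 5: set 1 + MDI                                      (22 layers)

Each set trains a random forest on a stratified 30% sample of the labeled
objects and is assessed on the remaining 70%: confusion matrix, overall
accuracy (OA), per-class producer's/user's accuracy (PA/UA), kappa, a
permutation-based variable-importance ranking, and pairwise McNemar Z
statistics between the sets on the shared test objects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

from .containers import FeatureStack, HyperCube, PivotPair, SegmentMap
from .indices import INDEX_NAMES, BandRanges, index_stack
from .moment import MDMetric, md_cube
from .segmentation import majority_label, object_means, segment
from .texture import CooccurrenceConfig, texture_stack

__all__ = [
    "FeatureSetSpec",
    "feature_sets",
    "split_train_test",
    "run_set",
    "accuracy_assessment",
    "mcnemar_z",
    "RFParams",
    "ExperimentConfig",
    "run_experiment",
]

logger = logging.getLogger(__name__)

MD_LAYER_BY_SET = {2: "MDIN", 3: "MDRLR", 4: "MDRRL", 5: "MDI"}


@dataclass(frozen=True)
class FeatureSetSpec:
    """One of the five ablation feature sets."""

    set_id: int
    layers: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.set_id not in range(1, 6):
            raise ValueError("set_id must be 1..5")
        expected = 21 if self.set_id == 1 else 22
        if len(self.layers) != expected:
            raise ValueError(
                f"set {self.set_id} must have {expected} layers, got {len(self.layers)}"
            )


def feature_sets(
    index_names: tuple[str, ...] = INDEX_NAMES,
    texture_names: tuple[str, ...] | None = None,
) -> list[FeatureSetSpec]:
    """The five feature-set specifications of the ablation."""
    if texture_names is None:
        texture_names = tuple(
            f"{feat}(PCA{k})"
            for k in (1, 2, 3)
            for feat in ("VAR", "ENT", "COR", "CON", "ASM")
        )
    base = tuple(index_names) + tuple(texture_names)
    sets = [FeatureSetSpec(1, base)]
    for sid, md_name in MD_LAYER_BY_SET.items():
        sets.append(FeatureSetSpec(sid, base + (md_name,)))
    return sets


# ---------------------------------------------------------------------------
# train/test split


def split_train_test(
    objects: pd.DataFrame,
    labels: np.ndarray,
    fraction: float = 0.30,
    seed: int | None = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified per-class split of labeled objects into train and test.

    ``round(fraction * n_c)`` objects of each class c go to training (at
    least 1, at most ``n_c - 1`` so every class is tested), the rest to
    test.  Unlabeled objects (label 0) are excluded from both.

    Returns boolean masks (train, test) aligned with ``objects`` rows.
    """
    labels = np.asarray(labels)
    if len(labels) != len(objects):
        raise ValueError("labels length must equal number of objects")
    rng = np.random.default_rng(seed)
    train = np.zeros(len(labels), dtype=bool)
    test = np.zeros(len(labels), dtype=bool)
    for cls in np.unique(labels):
        if cls == 0:
            continue
        members = np.flatnonzero(labels == cls)
        if members.size < 2:
            raise ValueError(
                f"class {cls} has only {members.size} labeled object(s); "
                "need at least 2 to split"
            )
        n_train = int(round(fraction * members.size))
        n_train = min(max(n_train, 1), members.size - 1)
        chosen = rng.choice(members, size=n_train, replace=False)
        train[chosen] = True
        rest = np.setdiff1d(members, chosen)
        test[rest] = True
    return train, test


# ---------------------------------------------------------------------------
# per-set fit/predict/importance


def run_set(
    objects: pd.DataFrame,
    labels: np.ndarray,
    spec: "FeatureSetSpec | Sequence[str]",
    train: np.ndarray,
    test: np.ndarray,
    rf_params: "RFParams | None" = None,
    seed: int | None = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Train/evaluate the random forest on one feature set.

    ``spec`` is one of the five ablation sets or any plain sequence of
    layer names.  Returns ``(predictions, importance)`` where predictions
    align with the test objects (in ``objects`` row order) and importance
    is a DataFrame ordered by descending score (ties broken
    lexicographically by name).
    """
    rf_params = rf_params or RFParams()
    layers = spec.layers if isinstance(spec, FeatureSetSpec) else tuple(spec)
    missing = [name for name in layers if name not in objects.columns]
    if missing:
        raise ValueError(f"object table lacks feature layer(s): {missing}")
    x = objects.loc[:, list(layers)].to_numpy(dtype=float)
    y = np.asarray(labels)
    rf = RandomForestClassifier(
        n_estimators=rf_params.n_trees,
        max_features=rf_params.max_features,
        max_depth=rf_params.max_depth,
        oob_score=False,
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(x[train], y[train])
    pred = rf.predict(x[test])

    if rf_params.importance == "permutation":
        n_test = int(np.sum(test))
        perm = permutation_importance(
            rf,
            x[test],
            y[test],
            n_repeats=rf_params.n_permutations,
            random_state=seed,
            n_jobs=1,
            max_samples=min(rf_params.importance_max_samples, n_test),
        )
        mean, sd = perm.importances_mean, perm.importances_std
        with np.errstate(divide="ignore", invalid="ignore"):
            score = np.where(sd > 0, mean / sd, np.where(mean != 0, np.inf, 0.0))
        raw = mean
    elif rf_params.importance == "gini":
        score = rf.feature_importances_
        raw = score
        sd = np.zeros_like(score)
    else:
        raise ValueError("importance must be 'permutation' or 'gini'")

    imp = pd.DataFrame(
        {"layer": list(layers), "score": score, "mean_decrease": raw, "sd": sd}
    )
    imp = imp.sort_values(["score", "layer"], ascending=[False, True], kind="stable")
    imp = imp.reset_index(drop=True)
    imp.index = imp.index + 1
    imp.index.name = "rank"
    return pred, imp


# ---------------------------------------------------------------------------
# accuracy metrics


@dataclass(frozen=True)
class AccuracyReport:
    """Overall/producer's/user's accuracy (percent) and kappa."""

    oa: float
    kappa: float
    pa: dict[int, float]
    ua: dict[int, float]


def accuracy_assessment(
    truth: np.ndarray,
    predicted: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[pd.DataFrame, AccuracyReport]:
    """Confusion matrix (rows = reference, cols = predicted) and accuracies.

    OA = 100 * trace / total; PA_c = 100 * M_cc / row_c (omission);
    UA_c = 100 * M_cc / col_c (commission); kappa uses the usual
    chance-agreement correction p_e = sum(row_c * col_c) / total^2.
    Classes with an empty reference row (or predicted column) get NaN
    PA (or UA).  ``weights`` (e.g. object pixel counts) switch the counts
    from object-weighted to weighted totals.
    """
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.size == 0:
        raise ValueError("empty assessment input")
    if truth.shape != predicted.shape:
        raise ValueError("truth and prediction lengths differ")
    if weights is None:
        weights = np.ones(truth.size)
    classes = np.unique(np.concatenate([truth, predicted]))
    k = classes.size
    pos = {c: i for i, c in enumerate(classes)}
    mat = np.zeros((k, k))
    for t, p, w in zip(truth, predicted, weights):
        mat[pos[t], pos[p]] += w
    total = mat.sum()
    diag = np.diag(mat)
    rows = mat.sum(axis=1)
    cols = mat.sum(axis=0)
    oa = 100.0 * diag.sum() / total
    p_o = diag.sum() / total
    p_e = float((rows * cols).sum()) / total**2
    kappa = (p_o - p_e) / (1.0 - p_e) if p_e < 1.0 else float("nan")
    with np.errstate(divide="ignore", invalid="ignore"):
        pa = np.where(rows > 0, 100.0 * diag / np.maximum(rows, 1e-300), np.nan)
        ua = np.where(cols > 0, 100.0 * diag / np.maximum(cols, 1e-300), np.nan)
    cm = pd.DataFrame(mat, index=pd.Index(classes, name="reference"), columns=classes)
    report = AccuracyReport(
        oa=float(oa),
        kappa=float(kappa),
        pa={int(c): float(pa[i]) for i, c in enumerate(classes)},
        ua={int(c): float(ua[i]) for i, c in enumerate(classes)},
    )
    return cm, report


def mcnemar_z(
    pred_a: np.ndarray, pred_b: np.ndarray, truth: np.ndarray
) -> tuple[float, bool]:
    """McNemar's Z for two classifiers assessed on the same samples.

    With f12 = #(A correct, B wrong) and f21 = #(A wrong, B correct):

        Z = (f12 - f21) / sqrt(f12 + f21)

    Z > 0 means classifier A is the more accurate; the difference is
    significant at the 5% level when |Z| > 1.96.  Z = 0 when there are no
    discordant samples.  Returns ``(z, significant)``.
    """
    pred_a, pred_b, truth = map(np.asarray, (pred_a, pred_b, truth))
    if not (pred_a.shape == pred_b.shape == truth.shape):
        raise ValueError("prediction/truth vectors must share one length")
    a_ok = pred_a == truth
    b_ok = pred_b == truth
    f12 = int(np.sum(a_ok & ~b_ok))
    f21 = int(np.sum(~a_ok & b_ok))
    if f12 + f21 == 0:
        return 0.0, False
    z = (f12 - f21) / np.sqrt(f12 + f21)
    return float(z), bool(abs(z) > 1.96)


# ---------------------------------------------------------------------------
# configuration and the end-to-end experiment


@dataclass(frozen=True)
class RFParams:
    """Random-forest hyperparameters (defaults: 500 CART trees, sqrt(F)
    candidate features per split, unlimited depth, permutation importance
    normalized by its standard deviation)."""

    n_trees: int = 500
    max_features: str | int | float = "sqrt"
    max_depth: int | None = None
    importance: str = "permutation"
    n_permutations: int = 8
    #: cap on evaluation samples per permutation repeat (keeps the
    #: importance pass tractable on heavily over-segmented scenes)
    importance_max_samples: int = 256


@dataclass
class ExperimentConfig:
    """Everything an end-to-end run resolves; all defaults are logged."""

    abscissa_units: str = "index"
    pivots: tuple[float, float] | None = None  # None = full spectrum
    #: reflectance multiplier applied before MD computation; 1e4 puts a
    #: [0, 1] reflectance cube in the DN-like regime where the MD family is
    #: shape-sensitive against a band-index abscissa
    md_reflectance_scale: float = 1.0e4
    ranges: BandRanges = field(default_factory=BandRanges)
    standard_orientation: bool = False
    texture: CooccurrenceConfig = field(default_factory=CooccurrenceConfig)
    scale: float = 5.0
    connectivity: int = 4
    train_fraction: float = 0.30
    rf: RFParams = field(default_factory=RFParams)
    seed: int = 0

    def resolved(self) -> dict[str, object]:
        return {
            "abscissa_units": self.abscissa_units,
            "pivots": self.pivots,
            "md_reflectance_scale": self.md_reflectance_scale,
            "ranges": vars(self.ranges) | {},
            "standard_orientation": self.standard_orientation,
            "texture": {
                "levels": self.texture.levels,
                "distance": self.texture.distance,
                "window": self.texture.window,
            },
            "scale": self.scale,
            "connectivity": self.connectivity,
            "train_fraction": self.train_fraction,
            "rf": {
                "n_trees": self.rf.n_trees,
                "max_features": self.rf.max_features,
                "max_depth": self.rf.max_depth,
                "importance": self.rf.importance,
                "n_permutations": self.rf.n_permutations,
                "importance_max_samples": self.rf.importance_max_samples,
            },
            "seed": self.seed,
        }


@dataclass
class ExperimentReport:
    """Bundle returned by :func:`run_experiment`."""

    config: dict[str, object]
    features: FeatureStack
    segments: SegmentMap
    objects: pd.DataFrame
    object_labels: np.ndarray
    train_mask: np.ndarray
    test_mask: np.ndarray
    sets: dict[int, FeatureSetSpec]
    predictions: dict[int, np.ndarray]
    confusion: dict[int, pd.DataFrame]
    accuracy: dict[int, AccuracyReport]
    accuracy_pixel_weighted: dict[int, AccuracyReport]
    importance: dict[int, pd.DataFrame]
    mcnemar: pd.DataFrame
    maps: dict[int, np.ndarray]


def build_feature_stack(cube: HyperCube, cfg: ExperimentConfig) -> FeatureStack:
    """Indices + the four MD layers + 15 textures on one grid (25 layers)."""
    stack = FeatureStack(cube.rows, cube.cols)
    idx = index_stack(
        cube, INDEX_NAMES, cfg.ranges, standard_orientation=cfg.standard_orientation
    )
    for name in idx.names:
        stack.add(name, idx[name], **idx.provenance[name])
    pivots = PivotPair(*cfg.pivots) if cfg.pivots is not None else None
    for metric in (MDMetric.MDIN, MDMetric.MDRLR, MDMetric.MDRRL, MDMetric.MDI):
        layer = md_cube(
            cube,
            pivots,
            metric,
            units=cfg.abscissa_units,
            reflectance_scale=cfg.md_reflectance_scale,
        )
        stack.add(
            metric.name,
            layer,
            operation="moment_distance",
            metric=metric.name,
            units=cfg.abscissa_units,
            reflectance_scale=cfg.md_reflectance_scale,
            pivots=cfg.pivots or "full-spectrum",
        )
    tex = texture_stack(cube, cfg.texture)
    for name in tex.names:
        stack.add(name, tex[name], **tex.provenance[name])
    return stack


def run_experiment(
    cube: HyperCube, truth: np.ndarray, config: ExperimentConfig | None = None
) -> ExperimentReport:
    """The full object-based ablation experiment on one scene.

    Stages: spectral indices -> MD layers -> PCA textures -> segmentation
    (single geometry on the full stack) -> object table with majority
    ground-truth labels -> stratified 30/70 split -> five feature sets
    through the random forest -> accuracies (object- and pixel-weighted),
    importance rankings, pairwise McNemar matrix, and per-set classified
    maps painted back to pixels.
    """
    cfg = config or ExperimentConfig()
    truth = np.asarray(truth)
    if truth.shape != (cube.rows, cube.cols):
        raise ValueError("truth raster does not match cube geometry")
    logger.info("resolved configuration: %s", cfg.resolved())

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"experiment stage {name!r} failed: {exc}") from exc

    stack = _stage("features", build_feature_stack, cube, cfg)
    seg = _stage("segmentation", segment, stack, cfg.scale, cfg.connectivity)
    objects = _stage("object_means", object_means, stack, seg)
    labels = _stage("majority_label", majority_label, seg, truth)
    train, test = _stage(
        "split", split_train_test, objects, labels, cfg.train_fraction, cfg.seed
    )

    sets = {s.set_id: s for s in feature_sets()}
    predictions: dict[int, np.ndarray] = {}
    confusion: dict[int, pd.DataFrame] = {}
    accuracy: dict[int, AccuracyReport] = {}
    accuracy_px: dict[int, AccuracyReport] = {}
    importance: dict[int, pd.DataFrame] = {}
    maps: dict[int, np.ndarray] = {}
    sizes = objects["size"].to_numpy(dtype=float)
    y_test = labels[test]
    for sid, spec in sets.items():
        pred, imp = _stage(
            f"set {sid}", run_set, objects, labels, spec, train, test, cfg.rf, cfg.seed
        )
        predictions[sid] = pred
        importance[sid] = imp
        cm, rep = accuracy_assessment(y_test, pred)
        _, rep_px = accuracy_assessment(y_test, pred, weights=sizes[test])
        confusion[sid] = cm
        accuracy[sid] = rep
        accuracy_px[sid] = rep_px
        # paint object predictions (test) / training labels back to pixels
        object_class = np.zeros(seg.n_segments + 1, dtype=np.int64)
        object_class[1:][train] = labels[train]
        object_class[1:][test] = pred
        maps[sid] = object_class[seg.labels]
        logger.info("set %d: OA=%.1f%% kappa=%.3f", sid, rep.oa, rep.kappa)

    ids = sorted(sets)
    zmat = pd.DataFrame(np.zeros((5, 5)), index=ids, columns=ids)
    for i in ids:
        for j in ids:
            if i != j:
                z, _ = mcnemar_z(predictions[i], predictions[j], y_test)
                zmat.loc[i, j] = z
    return ExperimentReport(
        config=cfg.resolved(),
        features=stack,
        segments=seg,
        objects=objects,
        object_labels=labels,
        train_mask=train,
        test_mask=test,
        sets=sets,
        predictions=predictions,
        confusion=confusion,
        accuracy=accuracy,
        accuracy_pixel_weighted=accuracy_px,
        importance=importance,
        mcnemar=zmat,
        maps=maps,
    )
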