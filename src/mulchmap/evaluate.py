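"""Confusion-matrix accuracy assessment.

Implements every metric the mapping literature reports for land-cover
products: per-class recall (producer's accuracy), precision (user's
accuracy), F1, true-positive/true-negative rates, macro averages, overall
accuracy, and Cohen's kappa (chance-corrected agreement).  Also hosts the
SWIR-versus-VNIR benchmark harness used to check the qualitative claim that
shortwave-infrared bands outperform visible/near-infrared bands for
rock-garden classification on synthetic scenes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ConfusionMatrix:
    """Square count matrix indexed (true class, predicted class).

    Unclassified predictions are tallied separately in
    ``unclassified_by_true`` and excluded from metric denominators only when
    the matrix was built with ``ignore_unclassified=True``.
    """

    counts: np.ndarray
    class_names: list[str]
    unclassified_by_true: np.ndarray | None = None
    ignore_unclassified: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        C = len(self.class_names)
        if self.counts.shape != (C, C):
            raise ValueError("counts must be square over class_names")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.unclassified_by_true is None:
            self.unclassified_by_true = np.zeros(C, dtype=np.int64)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_matrix(truth, predicted, class_names,
                     unclassified: int = -1,
                     ignore_unclassified: bool = False) -> ConfusionMatrix:
    """Tally (true, predicted) label pairs.

    Labels are integer indices into ``class_names``; ``unclassified`` marks
    predictions outside the class list (e.g. nodata pixels).
    """
    truth = np.asarray(truth).ravel()
    predicted = np.asarray(predicted).ravel()
    if truth.shape != predicted.shape:
        raise ValueError("truth and predicted must have equal length")
    C = len(class_names)
    if ((truth < 0) | (truth >= C)).any():
        raise ValueError("truth contains labels outside the class list")
    bad = (predicted != unclassified) & ((predicted < 0) | (predicted >= C))
    if bad.any():
        raise ValueError("predicted contains unknown labels")
    is_uncls = predicted == unclassified
    counts = np.zeros((C, C), dtype=np.int64)
    np.add.at(counts, (truth[~is_uncls], predicted[~is_uncls]), 1)
    uncls = np.bincount(truth[is_uncls], minlength=C).astype(np.int64)
    if not ignore_unclassified and uncls.any():
        # unclassified counted as errors: keep them in a dedicated tally but
        # metrics below include them in denominators via recall's FN count.
        pass
    return ConfusionMatrix(counts, list(class_names), uncls,
                           ignore_unclassified)


@dataclass
class MetricsReport:
    """All per-class and aggregate accuracy metrics for one product."""

    class_names: list[str]
    recall: np.ndarray
    precision: np.ndarray
    f1: np.ndarray
    tpr: np.ndarray
    tnr: np.ndarray
    macro_recall: float
    macro_precision: float
    macro_f1: float
    overall_accuracy: float
    kappa: float
    undefined_flags: list[str] = field(default_factory=list)

    def per_class_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "class": self.class_names, "recall": self.recall,
            "precision": self.precision, "f1": self.f1,
            "tpr": self.tpr, "tnr": self.tnr,
        })

    def summary(self) -> dict:
        return {"recall": self.macro_recall,
                "precision": self.macro_precision,
                "f1": self.macro_f1,
                "overall_accuracy": self.overall_accuracy,
                "kappa": self.kappa}


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    s = precision + recall
    return 0.0 if s == 0 else 2.0 * precision * recall / s


def classification_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Compute the full metric set from a confusion matrix.

    recall_c = TP/(TP+FN), precision_c = TP/(TP+FP),
    F1_c = 2PR/(P+R), OA = trace/total,
    kappa = (p_o - p_e)/(1 - p_e) with p_e = sum_i row_i * col_i / total^2,
    TNR_c = TN/(TN+FP).  Zero-denominator ratios are reported as 0 and the
    affected quantity is listed in ``undefined_flags`` — never NaN.
    """
    M = cm.counts.astype(float)
    uncls = cm.unclassified_by_true.astype(float)
    if cm.ignore_unclassified:
        uncls = np.zeros_like(uncls)
    total = M.sum() + uncls.sum()
    if total <= 0:
        raise ValueError("confusion matrix total must be positive")
    C = len(cm.class_names)
    tp = np.diag(M)
    row = M.sum(axis=1) + uncls     # true-class totals (FN incl. unclass.)
    col = M.sum(axis=0)             # predicted-class totals
    flags: list[str] = []

    def safe_div(num, den, label):
        out = np.zeros_like(num, dtype=float)
        ok = den > 0
        out[ok] = num[ok] / den[ok]
        for i in np.nonzero(~ok)[0]:
            flags.append(f"{label}[{cm.class_names[i]}]")
        return out

    recall = safe_div(tp, row, "recall")
    precision = safe_div(tp, col, "precision")
    f1 = np.array([f1_score(precision[i], recall[i]) for i in range(C)])
    fp = col - tp
    tn = total - row - fp
    tnr = safe_div(tn, tn + fp, "tnr")
    oa = tp.sum() / total
    pe = float(np.sum(row * col)) / total ** 2
    if pe >= 1.0:
        kappa = 0.0
        flags.append("kappa")
    else:
        kappa = (oa - pe) / (1.0 - pe)
    return MetricsReport(
        class_names=list(cm.class_names), recall=recall, precision=precision,
        f1=f1, tpr=recall.copy(), tnr=tnr,
        macro_recall=float(recall.mean()),
        macro_precision=float(precision.mean()),
        macro_f1=float(f1.mean()), overall_accuracy=float(oa),
        kappa=float(kappa), undefined_flags=flags)


# ---------------------------------------------------------------------------
# SWIR vs VNIR benchmark harness
# ---------------------------------------------------------------------------

def _subsample_per_class(ts, cap: int, rng: np.random.Generator):
    keep = np.zeros(len(ts), dtype=bool)
    for c in np.unique(ts.y):
        idx = np.nonzero(ts.y == c)[0]
        if idx.size > cap:
            idx = rng.choice(idx, size=cap, replace=False)
        keep[idx] = True
    return ts.subset(keep)


def swir_vnir_benchmark(n_replicates: int = 20, base_seed: int = 0,
                        scene_config=None, plan=None,
                        samples_per_class: int = 1000,
                        rf_trees: int = 100,
                        rf_min_samples_leaf: int = 10,
                        rf_max_depth: int = 16) -> pd.DataFrame:
    """Held-out overall accuracy of MLC/MaxEnt/RF on SWIR vs VNIR bands.

    Each replicate generates a fresh synthetic scene and training-polygon
    set, extracts pixel samples from both band stacks, splits 80/20 at the
    polygon level, fits all three classifiers per band set, and scores them
    on the validation pixels.  Returns one row per (replicate, classifier,
    band set) with the overall accuracy and kappa.  ``samples_per_class``
    caps the extracted pixels (seeded subsample) and ``rf_trees`` sizes the
    forest so many replicates stay affordable.
    """
    from . import synthetic_scene as sc
    from .classify import SplitSpec, fit_maxent, fit_mlc, fit_rf, \
        split_train_val
    from .geo_io import extract_training_pixels

    rows = []
    for rep in range(n_replicates):
        seed = base_seed + rep
        cfg = scene_config if scene_config is not None else sc.SceneConfig()
        cfg = type(cfg)(**{**cfg.__dict__, "seed": seed})
        vnir, swir, truth = sc.generate_scene(cfg)
        rep_plan = plan if plan is not None else sc.scaled_training_plan()
        polys = sc.generate_training_polygons(truth, rep_plan, seed=seed + 1)
        rng = np.random.default_rng(seed + 2)
        for band_set, raster in (("swir", swir), ("vnir", vnir)):
            ts = extract_training_pixels(raster, polys,
                                         class_names=list(sc.CLASS_NAMES))
            ts = _subsample_per_class(ts, samples_per_class, rng)
            train, val = split_train_val(ts, SplitSpec(seed=seed + 3))
            models = {
                "mlc": fit_mlc(train),
                "maxent": fit_maxent(train),
                "rf": fit_rf(train, n_trees=rf_trees, seed=seed + 4,
                             min_samples_leaf=rf_min_samples_leaf,
                             max_depth=rf_max_depth),
            }
            for name, model in models.items():
                pred = model.predict(val.X)
                cm = confusion_matrix(val.y, pred, ts.class_names)
                rpt = classification_metrics(cm)
                rows.append({"replicate": rep, "classifier": name,
                             "bands": band_set,
                             "overall_accuracy": rpt.overall_accuracy,
                             "kappa": rpt.kappa,
                             "mulch_f1": rpt.f1[
                                 ts.class_names.index("mulch")]})
    return pd.DataFrame(rows)


def swir_win_fractions(bench: pd.DataFrame) -> pd.Series:
    """Per-classifier fraction of replicates where SWIR beats VNIR OA."""
    wide = bench.pivot_table(index=["replicate", "classifier"],
                             columns="bands", values="overall_accuracy")
    wins = (wide["swir"] > wide["vnir"]).groupby(level="classifier").mean()
    return wins
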