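"""Confusion-matrix metrics, ROC/AUC and the three-classifier comparison.

The positive class is the at-risk state (low situation awareness, label 1).
Metrics use the standard definitions:

    ACC = (TP+TN)/n,  TPR = TP/(TP+FN),  TNR = TN/(TN+FP),

plus Matthews correlation, F1 and Cohen's kappa by their textbook
formulas.  Undefined ratios (zero denominators) are reported as NaN, never
silently as 0.  ROC/AUC sweep all score thresholds; AUC equals the
probability that a positive outranks a negative (ties counted ½).

``compare_methods`` trains a plain random forest on all features, a plain
CNN on the unreduced feature maps, and the full hybrid (feature
elimination -> PCA -> fused CNN) on identical splits, and reports
per-method metric distributions plus a mean table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

from . import pca_comb, rf_select
from .cnn import CNNConfig, PCAFusedCNN

METRIC_NAMES = ("ACC", "TPR", "TNR", "MCC", "F1", "Kappa")


def confusion(
    labels: np.ndarray, predictions: np.ndarray, positive: int = 1
) -> dict[str, int]:
    """TP/FP/TN/FN counts for a binary problem (positive = low SA)."""
    y = np.asarray(labels)
    p = np.asarray(predictions)
    if y.shape != p.shape:
        raise ValueError("labels and predictions must align")
    classes = set(np.unique(y)) | set(np.unique(p))
    if len(classes) > 2:
        raise ValueError(f"non-binary input: classes {sorted(classes)}")
    pos_y, pos_p = y == positive, p == positive
    return {
        "TP": int(np.sum(pos_y & pos_p)),
        "FP": int(np.sum(~pos_y & pos_p)),
        "TN": int(np.sum(~pos_y & ~pos_p)),
        "FN": int(np.sum(pos_y & ~pos_p)),
    }


def metrics(counts: dict[str, int]) -> dict[str, float]:
    """ACC/TPR/TNR/MCC/F1/Kappa from confusion counts (NaN if undefined)."""
    tp, fp, tn, fn = counts["TP"], counts["FP"], counts["TN"], counts["FN"]
    n = tp + fp + tn + fn
    if n == 0:
        raise ValueError("empty confusion counts")

    def ratio(num: float, den: float) -> float:
        return num / den if den > 0 else float("nan")

    acc = (tp + tn) / n
    tpr = ratio(tp, tp + fn)
    tnr = ratio(tn, tn + fp)
    mcc_den = np.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = (tp * tn - fp * fn) / mcc_den if mcc_den > 0 else float("nan")
    f1 = ratio(2 * tp, 2 * tp + fp + fn)
    p_obs = acc
    p_exp = ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / (n * n)
    kappa = (p_obs - p_exp) / (1 - p_exp) if p_exp < 1 else float("nan")
    return {"ACC": acc, "TPR": tpr, "TNR": tnr, "MCC": mcc, "F1": f1, "Kappa": kappa}


def roc_auc(
    labels: np.ndarray, scores: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC points over all thresholds and the ranking AUC.

    Returns ``(fpr, tpr, auc)``.  The AUC is computed as the normalized
    Mann-Whitney U (pair-ranking probability, ties ½), which equals the
    trapezoidal area under the threshold-swept curve.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    pos = s[y == 1]
    neg = s[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("roc_auc needs both classes present")
    fpr, tpr, _ = _sk_roc_curve(y, s)
    # rank-based AUC via midranks: U statistic / (n_pos * n_neg)
    ranks = pd.Series(s).rank(method="average").to_numpy()
    u = ranks[y == 1].sum() - pos.size * (pos.size + 1) / 2.0
    auc = float(u / (pos.size * neg.size))
    return fpr, tpr, auc


@dataclass
class EvalReport:
    """Evaluation of one classifier on one test set."""

    counts: dict[str, int]
    scores: dict[str, float]
    roc_fpr: np.ndarray = field(default_factory=lambda: np.array([]))
    roc_tpr: np.ndarray = field(default_factory=lambda: np.array([]))
    auc: float = float("nan")

    def as_row(self) -> dict[str, float]:
        row = dict(self.scores)
        row["AUC"] = self.auc
        return row


def evaluate_predictions(
    labels: np.ndarray, predictions: np.ndarray, scores: np.ndarray | None = None
) -> EvalReport:
    counts = confusion(labels, predictions)
    report = EvalReport(counts=counts, scores=metrics(counts))
    if scores is not None:
        fpr, tpr, auc = roc_auc(labels, scores)
        report.roc_fpr, report.roc_tpr, report.auc = fpr, tpr, auc
    return report


# ---------------------------------------------------------------------------
# Method comparison harness


def _epoch_split(y: np.ndarray, fraction: float, rng: np.random.Generator) -> np.ndarray:
    mask = np.zeros(len(y), dtype=bool)
    for cls in np.unique(y):
        idx = np.where(y == cls)[0]
        n_test = max(1, int(round(fraction * idx.size)))
        mask[rng.permutation(idx)[:n_test]] = True
    return mask


def _subject_split(
    subjects: np.ndarray, y: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    mask = np.zeros(len(y), dtype=bool)
    for cls in np.unique(y):
        subj = pd.unique(subjects[y == cls])
        n_test = max(1, int(round(fraction * len(subj))))
        test_subj = set(rng.permutation(subj)[:n_test])
        mask |= np.isin(subjects, list(test_subj)) & (y == cls)
    return mask


def _feature_maps_plain(
    X: pd.DataFrame, subjects: np.ndarray, groups: np.ndarray,
    shape: tuple[int, int], stack: int, stride: int | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stacked z-scored raw features (no RF/PCA) for the plain CNN arm."""
    Xa = X.to_numpy(dtype=float)
    Xz = (Xa - Xa.mean(axis=0)) / np.where(Xa.std(axis=0) == 0, 1, Xa.std(axis=0))
    return pca_comb.build_cnn_inputs(Xz, subjects, groups, shape=shape, stack=stack, stride=stride)


def compare_methods(
    features: pd.DataFrame,
    forest_spec: rf_select.ForestSpec | None = None,
    cnn_config: CNNConfig | None = None,
    pca_threshold: float = 0.877,
    stack: int = 20,
    stack_stride: int | None = 5,
    repeats: int = 5,
    seed: int = 0,
    split: str = "epoch",
) -> "ComparisonReport":
    """RF vs plain CNN vs RF-CNN on identical repeated splits.

    ``features`` is an epoch-level feature table (meta columns subject_id,
    group, epoch_index, start_s + feature columns).  For each repeat a
    fresh 75/25 split is drawn (``split='epoch'`` stratified over epochs;
    ``split='subject'`` holds out whole subjects) and each method is
    trained and scored on it.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    from .spectral import feature_columns  # avoids cycle at import time

    feat_cols = feature_columns(features)
    X = features[feat_cols]
    y = (features["group"].to_numpy() == "low").astype(int)
    subjects = features["subject_id"].to_numpy()
    groups = features["group"].to_numpy()
    forest_spec = forest_spec or rf_select.ForestSpec()
    cnn_config = cnn_config or CNNConfig()
    rows = []
    errors: list[str] = []
    rng = np.random.default_rng(seed)
    for r in range(repeats):
        rep_seed = int(rng.integers(2**31))
        rep_rng = np.random.default_rng(rep_seed)
        if split == "subject":
            test_mask = _subject_split(subjects, y, 0.25, rep_rng)
        else:
            test_mask = _epoch_split(y, 0.25, rep_rng)
        tr, te = ~test_mask, test_mask
        try:
            # --- plain RF on all features
            forest = rf_select.BaggedForest(
                rf_select.ForestSpec(forest_spec.n_estimators, forest_spec.max_depth, rep_seed)
            ).fit(X.to_numpy()[tr], y[tr])
            pred = forest.predict(X.to_numpy()[te])
            score = forest.predict_score(X.to_numpy()[te])
            rows.append({"method": "RF", "repeat": r,
                         **evaluate_predictions(y[te], pred, score).as_row()})

            # --- plain CNN on unreduced features
            maps_p, labels_p, subj_p = _feature_maps_plain(
                X, subjects, groups, cnn_config.input_shape, stack, stack_stride
            )
            plain_cfg = CNNConfig(**{**cnn_config.__dict__, "fusion_components": 0,
                                     "seed": rep_seed})
            mask_p = _map_level_mask(subj_p, labels_p, subjects, y, test_mask,
                                     split, 0.25, rep_rng)
            res_p = PCAFusedCNN(plain_cfg).train(maps_p, labels_p, test_mask=mask_p)
            pred_p, score_p = res_p.model.predict(maps_p[mask_p])
            rows.append({"method": "CNN", "repeat": r,
                         **evaluate_predictions(labels_p[mask_p], pred_p, score_p).as_row()})

            # --- full hybrid
            report = rf_cnn_arm(
                features, y, forest_spec, cnn_config, pca_threshold,
                stack, stack_stride, rep_seed, split,
            )
            rows.append({"method": "RF-CNN", "repeat": r, **report.as_row()})
        except Exception as exc:  # noqa: BLE001 - harness records failures
            errors.append(f"repeat {r}: {exc!r}")
    dist = pd.DataFrame(rows)
    mean_table = (
        dist.drop(columns="repeat").groupby("method").mean().reindex(["RF", "CNN", "RF-CNN"])
        if not dist.empty
        else pd.DataFrame()
    )
    return ComparisonReport(distributions=dist, mean_table=mean_table, errors=errors)


def _map_level_mask(
    subj_map: np.ndarray, labels_map: np.ndarray,
    subjects: np.ndarray, y: np.ndarray, epoch_mask: np.ndarray,
    split: str, fraction: float, rng: np.random.Generator,
) -> np.ndarray:
    """Test mask for stacked maps consistent with the chosen split mode."""
    if split == "subject":
        test_subjects = set(pd.unique(subjects[epoch_mask]))
        mask = np.isin(subj_map, list(test_subjects))
        # guard: both classes must appear on each side
        if mask.all() or not mask.any():
            mask = _epoch_split(labels_map, fraction, rng)
        return mask
    return _epoch_split(labels_map, fraction, rng)


def rf_cnn_arm(
    features: pd.DataFrame,
    y: np.ndarray,
    forest_spec: rf_select.ForestSpec,
    cnn_config: CNNConfig,
    pca_threshold: float,
    stack: int,
    stack_stride: int | None,
    seed: int,
    split: str = "epoch",
) -> EvalReport:
    """One full RF-CNN pass: elimination -> PCA -> fused CNN -> report."""
    from .spectral import feature_columns

    feat_cols = feature_columns(features)
    X = features[feat_cols]
    subjects = features["subject_id"].to_numpy()
    groups = features["group"].to_numpy()
    trace = rf_select.backward_eliminate(
        X, y, rf_select.ForestSpec(forest_spec.n_estimators, forest_spec.max_depth, seed),
        seed=seed,
    )
    retained = trace.best_features
    basis = pca_comb.fit_pca(X[retained])
    k = pca_comb.select_k(basis, threshold=pca_threshold)
    scores = basis.transform(X[retained], k=k)
    maps, labels, subj_map = pca_comb.build_cnn_inputs(
        scores, subjects, groups, shape=cnn_config.input_shape,
        stack=stack, stride=stack_stride,
    )
    cfg = CNNConfig(**{**cnn_config.__dict__, "seed": seed})
    rng = np.random.default_rng(seed + 13)
    if split == "subject":
        mask = _subject_split(subj_map, labels, 0.25, rng)
    else:
        mask = _epoch_split(labels, 0.25, rng)
    res = PCAFusedCNN(cfg).train(maps, labels, test_mask=mask)
    pred, score = res.model.predict(maps[mask])
    return evaluate_predictions(labels[mask], pred, score)


@dataclass
class ComparisonReport:
    distributions: pd.DataFrame
    mean_table: pd.DataFrame
    errors: list[str] = field(default_factory=list)

    @property
    def complete(self) -> bool:
        return not self.errors
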