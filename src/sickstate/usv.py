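"""Ultrasonic-vocalization classification protocol.

Mouse ultrasonic calls are summarized by per-call acoustic features plus
four temporal metrics (forward onset differences at lags 1-3 and the
duration/onset ratio). Calls shorter than 5 ms are excluded as detection
artifacts. Classification of the sickness condition uses an ensemble of
random forests fitted to repeated balanced per-class subsamples of the
call table, each split 80/20 into train and test; a matching run with
jointly shuffled labels gives the chance baseline. Performance is macro F1
(mean +/- sd over subsample iterations) and the averaged row-normalized
confusion matrix.

Forest hyperparameters follow the protocol exactly: 500 trees, entropy
criterion, max depth 20, min_samples_split 2, min_samples_leaf 1, all
features considered at every split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from ._seeds import substream, substream_seed

MIN_CALL_DURATION_MS = 5.0

FOREST_PARAMS = {
    "n_estimators": 500,
    "criterion": "entropy",
    "max_depth": 20,
    "min_samples_split": 2,
    "min_samples_leaf": 1,
    "max_features": None,
}


def filter_calls(table: pd.DataFrame, duration_col: str = "duration_ms") -> pd.DataFrame:
    """Drop calls shorter than 5 ms (strict: exactly 5 ms is kept)."""
    if duration_col not in table.columns:
        raise ValueError(f"missing duration column {duration_col!r}")
    return table[table[duration_col] >= MIN_CALL_DURATION_MS].reset_index(drop=True)


def temporal_metrics(onsets, durations) -> pd.DataFrame:
    """Four per-call temporal metrics.

    For call n: onset_(n+1) - onset_n, onset_(n+2) - onset_n,
    onset_(n+3) - onset_n, and duration_n / onset_n. Metrics undefined at
    the end of the recording (or for onset 0 in the ratio) are NaN.
    """
    onsets = np.asarray(onsets, dtype=float)
    durations = np.asarray(durations, dtype=float)
    if onsets.ndim != 1 or onsets.shape != durations.shape:
        raise ValueError("onsets and durations must be equal-length 1-D arrays")
    if np.any(np.diff(onsets) < 0):
        raise ValueError("onsets must be sorted ascending")
    n = onsets.size
    out = {}
    for lag in (1, 2, 3):
        v = np.full(n, np.nan)
        if n > lag:
            v[: n - lag] = onsets[lag:] - onsets[:-lag]
        out[f"onset_diff_lag{lag}"] = v
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(onsets > 0, durations / onsets, np.nan)
    out["duration_onset_ratio"] = ratio
    return pd.DataFrame(out)


def macro_f1(y_true, y_pred) -> tuple[pd.Series, float]:
    """Per-class and macro F1 from precision = TP/(TP+FP) and
    recall = TP/(TP+FN); F1 = 2/(1/precision + 1/recall).

    A class with no true positives (precision or recall undefined or zero)
    scores F1 = 0. Macro F1 is the unweighted mean over the classes present
    in the true or predicted labels.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have the same length")
    classes = np.unique(np.concatenate([y_true, y_pred]))
    if classes.size < 1:
        raise ValueError("need at least one class")
    scores = {}
    for c in classes:
        tp = int(np.sum((y_true == c) & (y_pred == c)))
        fp = int(np.sum((y_true != c) & (y_pred == c)))
        fn = int(np.sum((y_true == c) & (y_pred != c)))
        if tp == 0:
            scores[c] = 0.0
            continue
        precision = tp / (tp + fp)
        recall = tp / (tp + fn)
        scores[c] = 2.0 / (1.0 / precision + 1.0 / recall)
    per_class = pd.Series(scores, name="f1")
    return per_class, float(per_class.mean())


@dataclass
class ClassificationReport:
    """Aggregate of the balanced-subsampling forest ensemble."""

    per_iteration_f1: list[float]
    f1_mean: float
    f1_sd: float
    confusion: pd.DataFrame  # averaged row-normalized
    classes: np.ndarray
    shuffled: bool
    config: dict = field(default_factory=dict)


def balanced_subsample_ensemble(
    table: pd.DataFrame,
    *,
    feature_cols: list[str] | None = None,
    label_col: str = "condition",
    n_forests: int = 50,
    subsample_per_class: int = 2500,
    train_fraction: float = 0.8,
    rf_params: dict | None = None,
    shuffle: bool = False,
    seed: int = 0,
) -> ClassificationReport:
    """Fit ``n_forests`` random forests to balanced per-class subsamples.

    Per iteration: draw ``subsample_per_class`` calls per class without
    replacement, optionally shuffle all subsampled labels jointly (the
    chance baseline), split 80/20 stratified, impute missing feature values
    by train medians, fit the forest, and score macro F1 on the test part.
    """
    if label_col not in table.columns:
        raise ValueError(f"missing label column {label_col!r}")
    if feature_cols is None:
        feature_cols = [
            c for c in table.columns
            if c not in (label_col, "onset_s") and pd.api.types.is_numeric_dtype(table[c])
        ]
    counts = table[label_col].value_counts()
    too_small = counts[counts < subsample_per_class]
    if not too_small.empty:
        raise ValueError(
            f"class {too_small.index[0]!r} has only {too_small.iloc[0]} calls, "
            f"fewer than subsample_per_class={subsample_per_class}"
        )
    classes = np.sort(counts.index.to_numpy())
    K = classes.size
    params = {**FOREST_PARAMS, **(rf_params or {})}

    by_class = {c: table.index[table[label_col] == c].to_numpy() for c in classes}
    f1s: list[float] = []
    conf_sum = np.zeros((K, K))
    conf_n = np.zeros(K)
    for i in range(n_forests):
        rng = substream(seed, "usv-subsample", i)
        idx = np.concatenate(
            [rng.choice(by_class[c], size=subsample_per_class, replace=False) for c in classes]
        )
        Xs = table.loc[idx, feature_cols].to_numpy(float)
        ys = table.loc[idx, label_col].to_numpy()
        if shuffle:
            ys = rng.permutation(ys)
        tr, te = train_test_split(
            np.arange(len(ys)),
            train_size=train_fraction,
            stratify=ys,
            random_state=substream_seed(seed, "usv-split", i),
        )
        X_tr, X_te, y_tr, y_te = Xs[tr], Xs[te], ys[tr], ys[te]
        med = np.nanmedian(X_tr, axis=0)
        med = np.where(np.isfinite(med), med, 0.0)
        X_tr = np.where(np.isnan(X_tr), med[None, :], X_tr)
        X_te = np.where(np.isnan(X_te), med[None, :], X_te)
        forest = RandomForestClassifier(
            random_state=substream_seed(seed, "usv-forest", i), n_jobs=1, **params
        )
        forest.fit(X_tr, y_tr)
        y_hat = forest.predict(X_te)
        _, f1 = macro_f1(y_te, y_hat)
        f1s.append(f1)
        cm = np.zeros((K, K))
        for t, p_ in zip(y_te, y_hat):
            cm[np.searchsorted(classes, t), np.searchsorted(classes, p_)] += 1
        rowsum = cm.sum(axis=1)
        present = rowsum > 0
        cm[present] /= rowsum[present, None]
        conf_sum[present] += cm[present]
        conf_n += present
    confusion = pd.DataFrame(
        conf_sum / np.maximum(conf_n[:, None], 1), index=classes, columns=classes
    )
    return ClassificationReport(
        per_iteration_f1=f1s,
        f1_mean=float(np.mean(f1s)),
        f1_sd=float(np.std(f1s, ddof=1)) if len(f1s) > 1 else 0.0,
        confusion=confusion,
        classes=classes,
        shuffled=shuffle,
        config={
            "n_forests": n_forests,
            "subsample_per_class": subsample_per_class,
            "train_fraction": train_fraction,
            "rf_params": params,
            "seed": seed,
        },
    )
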