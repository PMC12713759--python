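"""Multinomial logistic regression with an elastic-net penalty under
repeated nested stratified cross-validation.

The model is fitted in the symmetric (full K-class) parameterization: the
penalty, not a reference class, makes the coefficients identifiable, which
matches reporting one coefficient profile per sickness state. The convex
objective

    F(B, b) = -(1/n) sum_i log softmax(x_i B^T + b)_{y_i}
              + lambda * (alpha * ||B||_1 + (1 - alpha)/2 * ||B||_F^2)

(intercepts unpenalized) is minimized by accelerated proximal gradient
(FISTA with backtracking): the negative log-likelihood plus ridge term is
the smooth part, the L1 term is handled by soft-thresholding.

``nested_cv`` implements the evaluation protocol: a stratified 75-25 outer
train-test split, an inner stratified 4-fold cross-validation on the outer
training set to choose (lambda, alpha) by held-out log-likelihood, a refit
on the full outer training set, and held-out probabilities on the outer
test set — repeated (default 100 times) with fresh splits. Yeo-Johnson
standardization is refitted inside every training fold so held-out rows
never influence the normalization.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import transform as tf
from ._seeds import substream_seed

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# objective and solver


def _softmax(scores: np.ndarray) -> np.ndarray:
    z = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def objective(X, Y, B, b, lam, alpha) -> float:
    """Penalized negative log-likelihood per sample; Y is one-hot."""
    scores = X @ B.T + b
    z = scores - scores.max(axis=1, keepdims=True)
    log_norm = np.log(np.exp(z).sum(axis=1))
    nll = -(np.sum(Y * z) - np.sum(log_norm)) / X.shape[0]
    pen = lam * (alpha * np.abs(B).sum() + 0.5 * (1 - alpha) * np.sum(B**2))
    return float(nll + pen)


def _smooth_value_grad(X, Y, B, b, lam, alpha):
    n = X.shape[0]
    scores = X @ B.T + b
    z = scores - scores.max(axis=1, keepdims=True)
    expz = np.exp(z)
    P = expz / expz.sum(axis=1, keepdims=True)
    nll = -(np.sum(Y * z) - np.sum(np.log(expz.sum(axis=1)))) / n
    g = nll + 0.5 * lam * (1 - alpha) * np.sum(B**2)
    R = (P - Y) / n
    grad_B = R.T @ X + lam * (1 - alpha) * B
    grad_b = R.sum(axis=0)
    return g, grad_B, grad_b, P


@dataclass
class ModelCoefficients:
    """Coefficients of a fitted multinomial elastic-net model."""

    coef: np.ndarray  # (K, p)
    intercept: np.ndarray  # (K,)
    classes: np.ndarray
    feature_names: list | None = None
    n_iter: int = 0
    converged: bool = True

    def decision_scores(self, X_std: np.ndarray) -> np.ndarray:
        return np.asarray(X_std, float) @ self.coef.T + self.intercept

    def predict_proba(self, X_std: np.ndarray) -> np.ndarray:
        return _softmax(self.decision_scores(X_std))

    def predict(self, X_std: np.ndarray):
        return self.classes[np.argmax(self.predict_proba(X_std), axis=1)]


def fit_elastic_net_multinomial(
    X_std,
    y,
    lam: float,
    alpha: float,
    *,
    tol: float = 1e-7,
    max_iter: int = 10_000,
    feature_names=None,
) -> ModelCoefficients:
    """Fit the penalized multinomial model on a standardized matrix.

    Returns a stationary point of the convex composite objective; the
    objective at the solution never exceeds its value at the zero start.
    """
    X = np.asarray(X_std, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("X_std contains non-finite entries")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if not (0 <= alpha <= 1):
        raise ValueError("alpha must lie in [0, 1]")
    y = np.asarray(y)
    classes = np.unique(y)
    K = classes.size
    if K < 2:
        raise ValueError("need at least 2 classes")
    n, p = X.shape
    Y = (y[:, None] == classes[None, :]).astype(float)

    B = np.zeros((K, p))
    b = np.zeros(K)
    Bm, bm = B.copy(), b.copy()  # momentum iterates
    t_mom = 1.0
    L = 1.0
    F_prev = objective(X, Y, B, b, lam, alpha)
    thresh = lam * alpha
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        g, gB, gb, _ = _smooth_value_grad(X, Y, Bm, bm, lam, alpha)
        # backtracking on the smooth majorizer
        while True:
            B_new = Bm - gB / L
            b_new = bm - gb / L
            if thresh > 0:
                B_new = np.sign(B_new) * np.maximum(np.abs(B_new) - thresh / L, 0.0)
            dB, db = B_new - Bm, b_new - bm
            g_new = _smooth_value_grad(X, Y, B_new, b_new, lam, alpha)[0]
            bound = g + np.sum(gB * dB) + np.sum(gb * db) + 0.5 * L * (
                np.sum(dB**2) + np.sum(db**2)
            )
            if g_new <= bound + 1e-12 or L > 1e12:
                break
            L *= 2.0
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2))
        Bm = B_new + ((t_mom - 1.0) / t_next) * (B_new - B)
        bm = b_new + ((t_mom - 1.0) / t_next) * (b_new - b)
        B, b, t_mom = B_new, b_new, t_next
        L = max(L / 2.0, 1e-3)  # allow the step to grow again
        F = objective(X, Y, B, b, lam, alpha)
        if F > F_prev:  # momentum overshoot: restart
            Bm, bm, t_mom = B.copy(), b.copy(), 1.0
        if abs(F_prev - F) <= tol * max(1.0, abs(F_prev)):
            converged = True
            F_prev = F
            break
        F_prev = F
    if not converged:
        warnings.warn("elastic-net solver hit max_iter without meeting tol")
    return ModelCoefficients(
        coef=B,
        intercept=b,
        classes=classes,
        feature_names=list(feature_names) if feature_names is not None else None,
        n_iter=n_iter,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# nested cross-validation


@dataclass
class CVConfig:
    """Protocol parameters for the repeated nested cross-validation."""

    outer_train_fraction: float = 0.75
    inner_folds: int = 4
    n_repetitions: int = 100
    lambda_grid: tuple[float, ...] = tuple(np.logspace(-4, 1, 10))
    alpha_grid: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9)
    selection_metric: str = "loglik"  # or "accuracy"
    transform_mode: str = "per-fold"  # "per-fold" | "global" | "none"
    tol: float = 1e-7
    max_iter: int = 10_000
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.outer_train_fraction < 1):
            raise ValueError("outer_train_fraction must lie in (0, 1)")
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be at least 2")
        if not self.lambda_grid or not self.alpha_grid:
            raise ValueError("hyperparameter grids must be nonempty")
        if self.selection_metric not in {"loglik", "accuracy"}:
            raise ValueError("selection_metric must be 'loglik' or 'accuracy'")
        if self.transform_mode not in {"per-fold", "global", "none"}:
            raise ValueError("transform_mode must be per-fold, global or none")


@dataclass
class RepetitionRecord:
    model: ModelCoefficients
    chosen_lambda: float
    chosen_alpha: float
    test_index: np.ndarray
    test_proba: np.ndarray
    test_true: np.ndarray
    accuracy: float
    X_std_train: np.ndarray | None = None
    y_train: np.ndarray | None = None


@dataclass
class CVResult:
    classes: np.ndarray
    feature_names: list
    repetitions: list[RepetitionRecord]
    accuracy: float
    accuracy_sd: float
    per_class_mse: pd.Series
    confusion: pd.DataFrame  # averaged row-normalized
    mean_coef: pd.DataFrame  # features x classes, averaged across repetitions
    config: CVConfig | None = None

    @property
    def n_repetitions(self) -> int:
        return len(self.repetitions)


def _prepare_fold(X_train, X_test, mode):
    """Standardize train/test per the configured transform mode."""
    if mode == "none":
        return X_train.to_numpy(float), X_test.to_numpy(float), list(X_train.columns)
    params = tf.fit_transform_params(X_train)
    Xtr = tf.standardize(X_train, params).to_numpy()
    Xte = tf.standardize(X_test, params).to_numpy()
    return Xtr, Xte, params.feature_names


def _heldout_score(model, X_std, y, metric):
    proba = model.predict_proba(X_std)
    if metric == "accuracy":
        return float(np.mean(model.classes[np.argmax(proba, axis=1)] == y))
    idx = np.searchsorted(model.classes, y)
    p = np.clip(proba[np.arange(len(y)), idx], 1e-300, None)
    return float(np.mean(np.log(p)))


def nested_cv(X: pd.DataFrame, y, config: CVConfig | None = None) -> CVResult:
    """Run the repeated nested cross-validation protocol.

    ``X`` holds raw (untransformed) feature values; standardization is
    fitted inside each training fold unless ``config.transform_mode``
    says otherwise.
    """
    config = config or CVConfig()
    config.validate()
    X = pd.DataFrame(X)
    y = np.asarray(y)
    classes = np.unique(y)
    K = classes.size
    if K < 2:
        raise ValueError("need at least 2 classes")

    global_params = None
    if config.transform_mode == "global":
        global_params = tf.fit_transform_params(X)

    reps: list[RepetitionRecord] = []
    for r in range(config.n_repetitions):
        rseed = substream_seed(config.seed, "cv-rep", r)
        try:
            tr_idx, te_idx = train_test_split(
                np.arange(len(y)),
                train_size=config.outer_train_fraction,
                stratify=y,
                random_state=rseed,
            )
        except ValueError as exc:
            logger.warning("repetition %d skipped: %s", r, exc)
            continue
        y_tr, y_te = y[tr_idx], y[te_idx]
        counts = pd.Series(y_tr).value_counts()
        if counts.min() < config.inner_folds:
            logger.warning(
                "repetition %d skipped: class %r has %d < %d members in the outer train set",
                r, counts.idxmin(), counts.min(), config.inner_folds,
            )
            continue
        X_tr, X_te = X.iloc[tr_idx], X.iloc[te_idx]

        # inner CV over the (lambda, alpha) grid
        skf = StratifiedKFold(
            n_splits=config.inner_folds,
            shuffle=True,
            random_state=substream_seed(config.seed, "cv-inner", r),
        )
        folds = []
        for itr, iva in skf.split(X_tr, y_tr):
            if config.transform_mode == "global":
                Xi = tf.standardize(X_tr.iloc[itr], global_params).to_numpy()
                Xv = tf.standardize(X_tr.iloc[iva], global_params).to_numpy()
            else:
                Xi, Xv, _ = _prepare_fold(X_tr.iloc[itr], X_tr.iloc[iva], config.transform_mode)
            folds.append((Xi, y_tr[itr], Xv, y_tr[iva]))
        best = None
        for lam in config.lambda_grid:
            for al in config.alpha_grid:
                scores = [
                    _heldout_score(
                        fit_elastic_net_multinomial(
                            Xi, yi, lam, al, tol=config.tol, max_iter=config.max_iter
                        ),
                        Xv, yv, config.selection_metric,
                    )
                    for Xi, yi, Xv, yv in folds
                ]
                mean_score = float(np.mean(scores))
                if best is None or mean_score > best[0]:
                    best = (mean_score, lam, al)
        _, lam, al = best
        logger.debug("repetition %d chose lambda=%g alpha=%g", r, lam, al)

        if config.transform_mode == "global":
            Xtr_std = tf.standardize(X_tr, global_params).to_numpy()
            Xte_std = tf.standardize(X_te, global_params).to_numpy()
            feats = global_params.feature_names
        else:
            Xtr_std, Xte_std, feats = _prepare_fold(X_tr, X_te, config.transform_mode)
        model = fit_elastic_net_multinomial(
            Xtr_std, y_tr, lam, al,
            tol=config.tol, max_iter=config.max_iter, feature_names=feats,
        )
        proba = model.predict_proba(Xte_std)
        pred = model.classes[np.argmax(proba, axis=1)]
        reps.append(
            RepetitionRecord(
                model=model,
                chosen_lambda=lam,
                chosen_alpha=al,
                test_index=te_idx,
                test_proba=proba,
                test_true=y_te,
                accuracy=float(np.mean(pred == y_te)),
                X_std_train=Xtr_std,
                y_train=y_tr,
            )
        )

    if not reps:
        raise ValueError("all repetitions were skipped; check class sizes")

    feats = reps[0].model.feature_names or list(X.columns)
    acc = float(np.mean([rr.accuracy for rr in reps]))
    acc_sd = float(np.std([rr.accuracy for rr in reps], ddof=1)) if len(reps) > 1 else 0.0

    # pooled per-class Brier-style MSE over all held-out samples
    mse = {}
    for c_i, c in enumerate(classes):
        errs = []
        for rr in reps:
            mask = rr.test_true == c
            if mask.any():
                target = (classes[None, :] == c).astype(float)
                errs.append(np.sum((rr.test_proba[mask] - target) ** 2, axis=1))
        mse[c] = float(np.mean(np.concatenate(errs))) if errs else np.nan

    # averaged row-normalized confusion matrix
    conf_sum = np.zeros((K, K))
    conf_n = np.zeros(K)
    for rr in reps:
        pred = rr.model.classes[np.argmax(rr.test_proba, axis=1)]
        cm = np.zeros((K, K))
        for t, p_ in zip(rr.test_true, pred):
            cm[np.searchsorted(classes, t), np.searchsorted(classes, p_)] += 1
        rowsum = cm.sum(axis=1)
        present = rowsum > 0
        cm[present] /= rowsum[present, None]
        conf_sum[present] += cm[present]
        conf_n += present
    conf = conf_sum / np.maximum(conf_n[:, None], 1)
    confusion = pd.DataFrame(conf, index=classes, columns=classes)

    mean_coef = pd.DataFrame(
        np.mean([rr.model.coef for rr in reps], axis=0).T, index=feats, columns=classes
    )
    return CVResult(
        classes=classes,
        feature_names=feats,
        repetitions=reps,
        accuracy=acc,
        accuracy_sd=acc_sd,
        per_class_mse=pd.Series(mse, name="per_class_mse"),
        confusion=confusion,
        mean_coef=mean_coef,
        config=config,
    )


def class_probability_report(result: CVResult) -> pd.DataFrame:
    """Distribution of held-out predicted probabilities by (true, scored) class.

    One row per (true class, scored class) pair with mean, sd and quartiles
    of the probability assigned to the scored class across all held-out
    samples of the true class.
    """
    if not result.repetitions:
        raise ValueError("CVResult holds no repetitions")
    pooled: dict[tuple, list] = {}
    for rr in result.repetitions:
        for c_i, c in enumerate(result.classes):
            mask = rr.test_true == c
            if mask.any():
                for s_i, s in enumerate(result.classes):
                    pooled.setdefault((c, s), []).append(rr.test_proba[mask, s_i])
    rows = []
    for (true_c, scored_c), chunks in sorted(pooled.items(), key=lambda kv: (str(kv[0][0]), str(kv[0][1]))):
        v = np.concatenate(chunks)
        rows.append(
            {
                "true_class": true_c,
                "scored_class": scored_c,
                "mean": float(v.mean()),
                "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
                "q25": float(np.percentile(v, 25)),
                "median": float(np.percentile(v, 50)),
                "q75": float(np.percentile(v, 75)),
                "n": int(v.size),
            }
        )
    return pd.DataFrame(rows)
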