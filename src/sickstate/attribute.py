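"""Linear SHAP attribution and the hybrid importance score.

For a linear (pre-softmax) class score with standardized inputs the
Shapley attribution reduces to the exact closed form

    S(i, j, c) = X_std(i, j) * beta(j, c)

so that per sample and class the feature attributions sum to the linear
score minus the intercept (local accuracy). Signed attributions are
averaged over samples within a repetition and then across cross-validation
repetitions; the hybrid importance of a region for a state is

    H(j, c) = mean|S(., j, c)| * |Bbar(j, c)|

i.e. mean absolute attribution weighted by the magnitude of the
cross-repetition mean coefficient, so a region scores highly only if it is
both influential per sample and stable across refits. A dispersion-
penalized variant divides by the across-repetition coefficient sd.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import CVResult, ModelCoefficients


def linear_shap(X_std, model: ModelCoefficients) -> np.ndarray:
    """SHAP tensor S with shape (n_samples, n_features, n_classes)."""
    X = np.asarray(X_std, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.coef.shape[1]:
        raise ValueError(
            f"shape mismatch: X_std has {X.shape[1] if X.ndim == 2 else '?'} features, "
            f"model has {model.coef.shape[1]}"
        )
    return X[:, :, None] * model.coef.T[None, :, :]


def aggregate_shap(tensors: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Mean signed SHAP per (feature, class): mean over samples within each
    repetition, then over repetitions. Returns (mean, across-repetition sd).
    """
    if not tensors:
        raise ValueError("no SHAP tensors to aggregate")
    per_rep = np.stack([t.mean(axis=0) for t in tensors])  # (R, p, K)
    mean = per_rep.mean(axis=0)
    sd = per_rep.std(axis=0, ddof=1) if len(tensors) > 1 else np.zeros_like(mean)
    return mean, sd


def hybrid_importance(
    mean_abs_shap: np.ndarray,
    mean_coef: np.ndarray,
    *,
    stability_penalized: bool = False,
    coef_sd: np.ndarray | None = None,
    eps: float = 1e-8,
) -> np.ndarray:
    """H(j, c) = mean|S(., j, c)| * |Bbar(j, c)| (>= 0 everywhere).

    With ``stability_penalized=True`` the coefficient magnitude is divided
    by its across-repetition sd + eps, rewarding stable coefficients.
    """
    mean_abs_shap = np.asarray(mean_abs_shap, float)
    if np.any(mean_abs_shap < 0):
        raise ValueError("mean_abs_shap must be non-negative")
    weight = np.abs(np.asarray(mean_coef, float))
    if stability_penalized:
        if coef_sd is None:
            raise ValueError("stability_penalized=True requires coef_sd")
        weight = weight / (np.asarray(coef_sd, float) + eps)
    return mean_abs_shap * weight


@dataclass
class AttributionResult:
    """Per-(feature, class) attribution summary for a cross-validated model."""

    feature_names: list
    classes: np.ndarray
    mean_coef: pd.DataFrame  # Bbar, features x classes
    coef_sd: pd.DataFrame
    mean_shap: pd.DataFrame  # signed
    shap_sd: pd.DataFrame
    mean_abs_shap: pd.DataFrame
    hybrid: pd.DataFrame  # H, features x classes
    direction: pd.DataFrame  # promoting / suppressing / none

    def ranking(self, condition) -> pd.DataFrame:
        """Features ranked for one class by hybrid importance (desc, ties by id)."""
        df = pd.DataFrame(
            {
                "hybrid": self.hybrid[condition],
                "mean_shap": self.mean_shap[condition],
                "mean_coef": self.mean_coef[condition],
                "direction": self.direction[condition],
            }
        ).rename_axis("feature")
        return df.sort_values(["hybrid", "feature"], ascending=[False, True],
                              kind="mergesort")

    def to_frame(self) -> pd.DataFrame:
        """Long table: one row per (class, feature)."""
        rows = []
        for c in self.classes:
            for f in self.feature_names:
                rows.append(
                    {
                        "class": c,
                        "feature": f,
                        "mean_shap": self.mean_shap.loc[f, c],
                        "shap_sd": self.shap_sd.loc[f, c],
                        "mean_coef": self.mean_coef.loc[f, c],
                        "hybrid": self.hybrid.loc[f, c],
                        "direction": self.direction.loc[f, c],
                    }
                )
        return pd.DataFrame(rows)


def attribute_from_cv(result: CVResult, *, stability_penalized: bool = False) -> AttributionResult:
    """Compute the SHAP/hybrid attribution summary from a nested-CV result.

    Attribution uses each repetition's standardized outer-train matrix (the
    matrix whose columns are exactly mean 0), paired with that repetition's
    coefficients, then pools across repetitions. Because standardized
    columns have zero mean, the signed attribution averaged over *all*
    samples is identically near zero; the informative signed summary for
    class c therefore averages over the samples whose true label is c,
    while the magnitude summary mean|S| averages over all samples.
    """
    reps = [rr for rr in result.repetitions if rr.X_std_train is not None]
    if not reps:
        raise ValueError("CVResult does not retain standardized training matrices")
    feats = result.feature_names
    classes = result.classes

    tensors = [linear_shap(rr.X_std_train, rr.model) for rr in reps]
    per_rep_signed = []
    for rr, t in zip(reps, tensors):
        signed = np.empty(t.shape[1:])  # (p, K)
        for c_i, c in enumerate(classes):
            mask = rr.y_train == c
            signed[:, c_i] = t[mask, :, c_i].mean(axis=0) if mask.any() else np.nan
        per_rep_signed.append(signed)
    mean_shap = np.mean(per_rep_signed, axis=0)
    shap_sd = (
        np.std(per_rep_signed, axis=0, ddof=1)
        if len(reps) > 1
        else np.zeros_like(mean_shap)
    )
    mean_abs = np.mean([np.abs(t).mean(axis=0) for t in tensors], axis=0)

    coefs = np.stack([rr.model.coef for rr in reps])  # (R, K, p)
    mean_coef = coefs.mean(axis=0).T  # (p, K)
    coef_sd = coefs.std(axis=0, ddof=1).T if len(reps) > 1 else np.zeros_like(mean_coef)

    H = hybrid_importance(
        mean_abs, mean_coef,
        stability_penalized=stability_penalized,
        coef_sd=coef_sd if stability_penalized else None,
    )
    direction = np.where(mean_coef > 0, "promoting", np.where(mean_coef < 0, "suppressing", "none"))

    def frame(a):
        return pd.DataFrame(a, index=pd.Index(feats, name="feature"), columns=classes)

    return AttributionResult(
        feature_names=feats,
        classes=classes,
        mean_coef=frame(mean_coef),
        coef_sd=frame(coef_sd),
        mean_shap=frame(mean_shap),
        shap_sd=frame(shap_sd),
        mean_abs_shap=frame(mean_abs),
        hybrid=frame(H),
        direction=frame(direction),
    )
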