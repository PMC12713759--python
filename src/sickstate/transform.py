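"""Yeo-Johnson variance stabilization and per-feature standardization.

Regional immediate-early-gene intensity is strongly right-skewed; before
feature selection and classification each region column is mapped through
the Yeo-Johnson power transform (exponent fitted per column by maximum
likelihood) and then centered and scaled to unit variance. The fitted
parameters are frozen on the training rows and re-applied unchanged to
held-out rows, so no information leaks from test animals into the
normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats


class DegenerateFeatureError(ValueError):
    """Raised when a feature column is constant (zero variance)."""


def yeo_johnson(y, lmbda: float):
    """Yeo-Johnson transform of ``y`` with exponent ``lmbda``.

    Piecewise closed form: for y >= 0, ((y+1)^l - 1)/l (log(y+1) at l=0);
    for y < 0, -((1-y)^(2-l) - 1)/(2-l) (-log(1-y) at l=2). Strictly
    increasing in y for every lmbda and continuous in lmbda.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("yeo_johnson requires finite input values")
    if not np.isfinite(lmbda):
        raise ValueError("yeo_johnson requires a finite exponent")
    out = np.empty_like(y)
    pos = y >= 0
    # expm1/log1p forms are exact at the branch points and cancellation-free
    if abs(lmbda) < 1e-12:
        out[pos] = np.log1p(y[pos])
    else:
        out[pos] = np.expm1(lmbda * np.log1p(y[pos])) / lmbda
    if abs(lmbda - 2.0) < 1e-12:
        out[~pos] = -np.log1p(-y[~pos])
    else:
        out[~pos] = -np.expm1((2.0 - lmbda) * np.log1p(-y[~pos])) / (2.0 - lmbda)
    return out if out.ndim else float(out)


def fit_column(y: np.ndarray, bounds: tuple[float, float] = (-5.0, 5.0)) -> tuple[float, float, float]:
    """Fit (lambda, mu, sigma) for one column by profile maximum likelihood.

    lambda maximizes the Yeo-Johnson profile log-likelihood (Gaussian
    likelihood of the transformed values plus the log-Jacobian term) by
    bounded scalar optimization; mu and sigma are the mean and standard
    deviation of the transformed column.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("column contains non-finite values")
    if np.unique(y).size < 3:
        raise DegenerateFeatureError(
            "column has fewer than 3 distinct values; cannot fit a power transform"
        )
    res = optimize.minimize_scalar(
        lambda lm: -stats.yeojohnson_llf(lm, y),
        bounds=bounds,
        method="bounded",
        options={"xatol": 1e-5},
    )
    lmbda = float(res.x)
    z = yeo_johnson(y, lmbda)
    mu = float(np.mean(z))
    sigma = float(np.std(z, ddof=0))
    if sigma <= 0:
        raise DegenerateFeatureError("transformed column has zero variance")
    return lmbda, mu, sigma


@dataclass
class TransformParams:
    """Per-feature Yeo-Johnson exponents and post-transform location/scale."""

    feature_names: list[str]
    lambdas: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    dropped: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lambda": self.lambdas, "mu": self.means, "sigma": self.sds},
            index=pd.Index(self.feature_names, name="feature"),
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TransformParams":
        return cls(
            feature_names=list(frame.index),
            lambdas=frame["lambda"].to_numpy(float),
            means=frame["mu"].to_numpy(float),
            sds=frame["sigma"].to_numpy(float),
        )


def fit_transform_params(X: pd.DataFrame, on_degenerate: str = "drop") -> TransformParams:
    """Fit per-column transform parameters on a (training) matrix.

    on_degenerate: "drop" removes constant columns with a warning,
    "raise" propagates :class:`DegenerateFeatureError`.
    """
    names, lams, mus, sds, dropped = [], [], [], [], []
    for col in X.columns:
        try:
            lm, mu, sd = fit_column(X[col].to_numpy(float))
        except DegenerateFeatureError:
            if on_degenerate == "raise":
                raise
            warnings.warn(f"dropping degenerate (near-constant) feature {col!r}")
            dropped.append(col)
            continue
        names.append(col)
        lams.append(lm)
        mus.append(mu)
        sds.append(sd)
    return TransformParams(
        feature_names=names,
        lambdas=np.asarray(lams),
        means=np.asarray(mus),
        sds=np.asarray(sds),
        dropped=dropped,
    )


def standardize(X: pd.DataFrame, params: TransformParams) -> pd.DataFrame:
    """Apply fitted Yeo-Johnson + z-scaling, returning X_std.

    Columns must cover ``params.feature_names``; extra columns are ignored
    so a fit on selected features can be applied to the full table.
    """
    missing = [c for c in params.feature_names if c not in X.columns]
    if missing:
        raise ValueError(f"matrix is missing features required by params: {missing[:5]}")
    out = np.empty((len(X), len(params.feature_names)))
    for j, col in enumerate(params.feature_names):
        z = yeo_johnson(X[col].to_numpy(float), float(params.lambdas[j]))
        out[:, j] = (z - params.means[j]) / params.sds[j]
    return pd.DataFrame(out, index=X.index, columns=params.feature_names)
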