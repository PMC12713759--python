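"""Repeated Boruta feature selection with a frequency cut.

Boruta is an all-relevant wrapper: each iteration appends freshly permuted
"shadow" copies of the candidate features, fits a random forest, and scores
a hit for every candidate whose importance exceeds the best shadow
importance. Candidates are confirmed or rejected by a binomial test on the
hit count (Bonferroni-corrected over candidates). Because a single run is
noisy at this sample size, the whole procedure is repeated with fresh
forest/shadow randomness and features are retained by how often they are
confirmed: everything at or above the top-5% quantile of the nonzero
confirmation frequencies, ties kept. The tie-keeping quantile cut can
retain slightly more than 5% of the universe, which is how a 641-region
table yields retained sets like 36 or 25 regions rather than exactly 32.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.ensemble import RandomForestClassifier

from ._seeds import substream_seed


@dataclass
class BorutaResult:
    confirmed: list
    rejected: list
    tentative: list
    hits: pd.Series
    trials: int
    n_iter: int


@dataclass
class SelectionResult:
    """Outcome of ``repeated_selection``.

    ``selection_frequency[f]`` is the fraction of repetitions in which
    feature ``f`` was confirmed; ``retained`` is the final subset, sorted
    by (frequency desc, feature id asc).
    """

    per_rep_confirmed: list[frozenset]
    selection_frequency: pd.Series
    retained: list
    config: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frequency": self.selection_frequency,
                "retained": self.selection_frequency.index.isin(self.retained),
            }
        ).rename_axis("feature")


def boruta_run(
    X: pd.DataFrame,
    y,
    *,
    n_estimators: int = 500,
    max_iter: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    rf_params: dict | None = None,
) -> BorutaResult:
    """One Boruta pass over candidate features.

    Terminates when no feature is left tentative or after ``max_iter``
    iterations; tentative features at termination count as not confirmed.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("boruta_run requires at least 2 classes")
    counts = pd.Series(y).value_counts()
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 samples")
    n, p = X.shape
    if n < 2 * p:
        warnings.warn(
            f"only {n} samples for {p} features; shadow importances may be unstable"
        )

    features = list(X.columns)
    status = {f: "tentative" for f in features}
    hits = pd.Series(0, index=features, dtype=int)
    trials = 0
    Xv = X.to_numpy(float)
    rng = np.random.default_rng(substream_seed(seed, "boruta-shadow"))
    params = {
        "n_estimators": n_estimators,
        "max_features": "sqrt",
        "n_jobs": 1,
        **(rf_params or {}),
    }

    it = 0
    while it < max_iter and any(s == "tentative" for s in status.values()):
        active = [f for f in features if status[f] != "rejected"]
        ai = [features.index(f) for f in active]
        Xa = Xv[:, ai]
        shadows = np.column_stack([rng.permutation(Xa[:, j]) for j in range(Xa.shape[1])])
        design = np.hstack([Xa, shadows])
        forest = RandomForestClassifier(
            random_state=substream_seed(seed, "boruta-forest", it), **params
        )
        forest.fit(design, y)
        imp = forest.feature_importances_
        shadow_max = imp[Xa.shape[1] :].max()
        trials += 1
        for k, f in enumerate(active):
            if status[f] == "tentative" and imp[k] > shadow_max:
                hits[f] += 1
        # two-sided binomial test, Bonferroni over the candidate universe
        thresh = alpha / p
        for f in features:
            if status[f] != "tentative":
                continue
            pval = binomtest(int(hits[f]), trials, 0.5, alternative="two-sided").pvalue
            if pval < thresh:
                status[f] = "confirmed" if hits[f] > trials / 2 else "rejected"
        it += 1

    return BorutaResult(
        confirmed=[f for f in features if status[f] == "confirmed"],
        rejected=[f for f in features if status[f] == "rejected"],
        tentative=[f for f in features if status[f] == "tentative"],
        hits=hits,
        trials=trials,
        n_iter=it,
    )


def repeated_selection(
    X: pd.DataFrame,
    y,
    *,
    n_reps: int = 100,
    top_pct: float = 5.0,
    seed: int = 0,
    **boruta_kwargs,
) -> SelectionResult:
    """Run Boruta ``n_reps`` times and keep the top-``top_pct``% of features
    by confirmation frequency (quantile cut over nonzero frequencies, ties
    kept).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    if not (0 < top_pct <= 100):
        raise ValueError("top_pct must lie in (0, 100]")
    X = pd.DataFrame(X)
    confirmed_sets = []
    counts = pd.Series(0, index=X.columns, dtype=int)
    for r in range(n_reps):
        res = boruta_run(X, y, seed=substream_seed(seed, "selection-rep", r), **boruta_kwargs)
        confirmed_sets.append(frozenset(res.confirmed))
        counts[res.confirmed] += 1
    freq = counts / n_reps
    nonzero = freq[freq > 0]
    if nonzero.empty:
        retained: list = []
    else:
        cutoff = np.percentile(nonzero.to_numpy(), 100 - top_pct)
        kept = nonzero[nonzero >= cutoff]
        order = sorted(kept.index, key=lambda f: (-kept[f], str(f)))
        retained = list(order)
    return SelectionResult(
        per_rep_confirmed=confirmed_sets,
        selection_frequency=freq,
        retained=retained,
        config={"n_reps": n_reps, "top_pct": top_pct, "seed": seed, **boruta_kwargs},
    )
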