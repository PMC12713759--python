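"""Independent brute-force / general-purpose-solver oracles.

Each oracle evaluates a quantity straight from its textbook definition
(double loops, explicit confusion tables, grid search, or a generic
constrained solver) and shares no code with the implementation it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def silhouette_bruteforce(X, labels) -> float:
    """O(n^2) evaluation of s(i) = (b - a)/max(a, b); singletons score 0."""
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    n = len(labels)
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    svals = []
    for i in range(n):
        same = (labels == labels[i]) & (np.arange(n) != i)
        if same.sum() == 0:
            svals.append(0.0)
            continue
        a = D[i, same].mean()
        b = min(
            D[i, labels == c].mean() for c in np.unique(labels) if c != labels[i]
        )
        svals.append((b - a) / max(a, b))
    return float(np.mean(svals))


def calinski_harabasz_bruteforce(X, labels) -> float:
    """Explicit between/within sum-of-squares ratio."""
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    n = len(labels)
    grand = X.mean(axis=0)
    between = within = 0.0
    uniq = np.unique(labels)
    for c in uniq:
        Xi = X[labels == c]
        mu = Xi.mean(axis=0)
        between += len(Xi) * float(((mu - grand) ** 2).sum())
        within += float(((Xi - mu) ** 2).sum())
    k = len(uniq)
    return (between / (k - 1)) / (within / (n - k))


def morans_i_bruteforce(values, W) -> float:
    """Explicit double sum over all (i, j) pairs; W dense or sparse."""
    x = np.asarray(values, float)
    W = np.asarray(W.todense() if hasattr(W, "todense") else W, float)
    n = x.size
    z = x - x.mean()
    num = 0.0
    for i in range(n):
        for j in range(n):
            num += W[i, j] * z[i] * z[j]
    return (n / W.sum()) * num / float((z**2).sum())


def macro_f1_bruteforce(y_true, y_pred) -> float:
    """Macro F1 via an explicit confusion table and the printed formulas."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    classes = sorted(set(y_true) | set(y_pred))
    f1s = []
    for c in classes:
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
        if tp == 0:
            f1s.append(0.0)
            continue
        precision = tp / (tp + fp)
        recall = tp / (tp + fn)
        f1s.append(2.0 / (1.0 / precision + 1.0 / recall))
    return float(np.mean(f1s))


def yeojohnson_lambda_gridsearch(y, lo=-2.0, hi=3.0, step=0.001) -> float:
    """Profile-likelihood grid search for the Yeo-Johnson exponent."""
    from scipy.stats import yeojohnson_llf

    grid = np.arange(lo, hi + step / 2, step)
    lls = [yeojohnson_llf(lm, y) for lm in grid]
    return float(grid[int(np.argmax(lls))])


def elastic_net_multinomial_solver(X, y, lam, alpha):
    """General-purpose convex solver for the penalized multinomial objective.

    The L1 term is made smooth by the split B = P - Q with P, Q >= 0 and the
    bound-constrained problem is handed to L-BFGS-B; at the optimum the split
    formulation attains the same objective as the original composite problem.
    Returns (objective value, B, intercepts).
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    classes = np.unique(y)
    K, (n, p) = classes.size, X.shape
    Y = (y[:, None] == classes[None, :]).astype(float)

    def unpack(th):
        P = th[: K * p].reshape(K, p)
        Q = th[K * p : 2 * K * p].reshape(K, p)
        return P, Q, th[2 * K * p :]

    def value(th):
        P, Q, b = unpack(th)
        B = P - Q
        scores = X @ B.T + b
        z = scores - scores.max(axis=1, keepdims=True)
        nll = -(np.sum(Y * z) - np.sum(np.log(np.exp(z).sum(axis=1)))) / n
        return nll + lam * alpha * (P.sum() + Q.sum()) + 0.5 * lam * (1 - alpha) * np.sum(B**2)

    def grad(th):
        P, Q, b = unpack(th)
        B = P - Q
        scores = X @ B.T + b
        z = scores - scores.max(axis=1, keepdims=True)
        E = np.exp(z)
        Pr = E / E.sum(axis=1, keepdims=True)
        R = (Pr - Y) / n
        gB = R.T @ X + lam * (1 - alpha) * B
        return np.concatenate([(gB + lam * alpha).ravel(), (-gB + lam * alpha).ravel(), R.sum(axis=0)])

    th0 = np.zeros(2 * K * p + K)
    bounds = [(0, None)] * (2 * K * p) + [(None, None)] * K
    res = minimize(
        value, th0, jac=grad, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 20000, "ftol": 1e-15, "gtol": 1e-12},
    )
    P, Q, b = unpack(res.x)
    B = P - Q
    # objective of the original composite problem at the solver's solution
    scores = X @ B.T + b
    z = scores - scores.max(axis=1, keepdims=True)
    nll = -(np.sum(Y * z) - np.sum(np.log(np.exp(z).sum(axis=1)))) / n
    obj = nll + lam * (alpha * np.abs(B).sum() + 0.5 * (1 - alpha) * np.sum(B**2))
    return float(obj), B, b
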