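"""Partial least squares discriminant analysis with LOO cross-validation,
label-permutation testing, VIP scores and coefficient importance.

The classifier is PLS2 regression of the spectra against a one-hot class
matrix, solved by NIPALS with deflation of X only.  Each component's
weight vector is computed at the NIPALS fixed point — the dominant
eigenvector of XᵀYYᵀX, obtained from the g×g eigenproblem of (XᵀY)ᵀ(XᵀY)
— which is exactly what the iterative inner loop converges to, and cheap
enough to refit thousands of times inside permutation and power loops.
Class prediction is argmax over the continuous one-hot predictions, with
ties broken by class order (first appearance in the training labels).

Model selection follows the cross-validation-first convention: the
number of components A is the smallest one maximising leave-one-out
accuracy, and the permutation test re-selects A for every permuted label
vector so the null distribution sees the same selection optimism as the
observed statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PLSDAModel",
    "PLSDAPerformance",
    "encode_onehot",
    "fit_pls",
    "predict_class",
    "loo_cv",
    "permutation_test",
    "vip_scores",
    "coef_importance",
    "evaluate",
]

_EPS = 1e-12


def encode_onehot(labels) -> tuple[np.ndarray, list]:
    """One-hot response coding; class order = first appearance."""
    labels = np.asarray(labels, dtype=object)
    class_order: list = []
    for lab in labels:
        if lab not in class_order:
            class_order.append(lab)
    if len(class_order) < 2:
        raise ValueError("need at least 2 classes")
    Y = np.zeros((labels.size, len(class_order)))
    for k, c in enumerate(class_order):
        Y[labels == c, k] = 1.0
    return Y, class_order


@dataclass
class PLSDAModel:
    n_components: int
    x_weights: np.ndarray      # p×A, unit columns
    x_loadings: np.ndarray     # p×A
    y_loadings: np.ndarray     # g×A
    x_scores: np.ndarray       # n×A, mutually orthogonal
    x_rotations: np.ndarray    # p×A, W(PᵀW)⁻¹ — maps x directly to scores
    coefficients: np.ndarray   # p×g at n_components
    x_mean: np.ndarray
    y_mean: np.ndarray
    class_order: list
    ssy: np.ndarray            # per-component explained Y sum of squares

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.y_mean + (np.atleast_2d(X) - self.x_mean) @ self.coefficients


def fit_pls(X: np.ndarray, Y: np.ndarray, n_components: int,
            class_order: list | None = None) -> PLSDAModel:
    """NIPALS PLS2 (X-only deflation) of X against a one-hot Y."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n, p = X.shape
    g = Y.shape[1]
    if Y.shape[0] != n:
        raise ValueError("X and Y must have matching rows")
    if not (1 <= n_components <= min(n - 1, p)):
        raise ValueError(f"n_components must be in [1, {min(n - 1, p)}]")
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xd = X - x_mean
    Yc = Y - y_mean
    if not np.any(np.abs(Xd) > _EPS):
        raise ValueError("X has zero variance")

    W = np.empty((p, n_components))
    P = np.empty((p, n_components))
    C = np.empty((g, n_components))
    T = np.empty((n, n_components))
    R = np.empty((p, n_components))
    ssy = np.empty(n_components)
    A = 0
    for a in range(n_components):
        S = Xd.T @ Yc                              # p×g
        M = S.T @ S                                # g×g
        evals, evecs = np.linalg.eigh(M)
        if evals[-1] <= _EPS * max(1.0, evals.sum()):
            break                                  # X-Y covariance exhausted
        w = S @ evecs[:, -1]
        w /= np.linalg.norm(w)
        j = int(np.argmax(np.abs(w)))
        if w[j] < 0:
            w = -w
        t = Xd @ w
        tt = float(t @ t)
        if tt <= _EPS:
            break
        p_load = Xd.T @ t / tt
        c = Yc.T @ t / tt
        Xd = Xd - np.outer(t, p_load)
        r = w - R[:, :a] @ (P[:, :a].T @ w)
        W[:, a], P[:, a], C[:, a], T[:, a], R[:, a] = w, p_load, c, t, r
        ssy[a] = float(c @ c) * tt
        A = a + 1
    if A == 0:
        raise ValueError("no PLS component could be extracted (degenerate X or Y)")
    W, P, C, T, R, ssy = W[:, :A], P[:, :A], C[:, :A], T[:, :A], R[:, :A], ssy[:A]
    coef = R @ C.T
    if class_order is None:
        class_order = list(range(g))
    return PLSDAModel(A, W, P, C, T, R, coef, x_mean, y_mean, class_order, ssy)


def predict_class(model: PLSDAModel, X: np.ndarray) -> np.ndarray:
    """Argmax class prediction; ties resolve to the earliest class."""
    yhat = model.predict(X)
    idx = np.argmax(yhat, axis=1)
    return np.array([model.class_order[i] for i in idx], dtype=object)


def _fold_predictions(K: np.ndarray, Y: np.ndarray, i: int, a_max: int) -> np.ndarray:
    """Held-out nested predictions for fold ``i`` from the full Gram matrix.

    Dual-form NIPALS: with K = XXᵀ, each component's weight w = Xdᵀu never
    needs forming — the score is t = Kd·u and the held-out score is kd·u,
    where Kd and the held-out kernel row kd are deflated in n-space.
    Identical predictions to the primal algorithm (t's scale cancels
    between score and y-loading), at O(n²) per component instead of O(np).

    Returns an (a_fit × g) array of cumulative per-A predictions.
    """
    n, g = Y.shape
    keep = np.arange(n) != i
    m = n - 1
    Ksub = K[np.ix_(keep, keep)]
    row_means = Ksub.mean(axis=1)
    grand = row_means.mean()
    Kd = Ksub - row_means[:, None] - row_means[None, :] + grand
    krow = K[i, keep]
    kd = krow - krow.mean() - row_means + grand

    y_mean = Y[keep].mean(axis=0)
    Yc = Y[keep] - y_mean
    yhat = np.empty((a_max, g))
    last = y_mean.copy()
    a_fit = 0
    total0 = float(np.trace(Kd))
    for a in range(a_max):
        S = Yc.T @ Kd @ Yc                     # g×g: (XdᵀYc)ᵀ(XdᵀYc)
        evals, evecs = np.linalg.eigh(S)
        if evals[-1] <= _EPS * max(1.0, total0):
            break
        u = Yc @ evecs[:, -1]
        t = Kd @ u
        tt = float(t @ t)
        if tt <= _EPS * max(1.0, total0):
            break
        c = Yc.T @ t / tt
        t_new = float(kd @ u)
        last = last + t_new * c
        yhat[a] = last
        # deflate: Xd <- (I - ttT/tt) Xd, and the held-out sample
        # x_new <- x_new - t_new * p  (p = Xd't/tt), both in kernel space
        v = Kd @ t
        tv = float(t @ v)
        kd = kd - (t_new / tt) * v
        kd = kd - (float(kd @ t) / tt) * t
        Kd -= (np.outer(t, v) + np.outer(v, t)) / tt
        Kd += np.outer(t, t) * (tv / tt**2)
        a_fit = a + 1
    if a_fit == 0:
        yhat[0] = y_mean
        a_fit = 1
    yhat[a_fit:] = yhat[a_fit - 1]
    return yhat


try:  # jit-compiled inner loop; pure-numpy fallback below is identical
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap


@_njit(cache=True)
def _loo_all_jit(K, Y, y_idx, a_max):  # pragma: no cover - exercised via loo_cv
    n, g = Y.shape
    m = n - 1
    correct = np.zeros((a_max, n), dtype=np.bool_)
    press = np.zeros(a_max)
    idx = np.empty(m, np.int64)
    for i in range(n):
        k = 0
        for j in range(n):
            if j != i:
                idx[k] = j
                k += 1
        Kd = np.empty((m, m))
        for a in range(m):
            for b in range(m):
                Kd[a, b] = K[idx[a], idx[b]]
        row_means = np.empty(m)
        for a in range(m):
            row_means[a] = Kd[a].sum() / m
        grand = row_means.sum() / m
        for a in range(m):
            for b in range(m):
                Kd[a, b] += grand - row_means[a] - row_means[b]
        krow = np.empty(m)
        for a in range(m):
            krow[a] = K[i, idx[a]]
        kd = krow - krow.sum() / m - row_means + grand
        Yf = Y[idx].copy()
        y_mean = np.empty(g)
        for q in range(g):
            y_mean[q] = Yf[:, q].sum() / m
        Yc = Yf - y_mean
        last = y_mean.copy()
        yhat = np.empty((a_max, g))
        total0 = 0.0
        for a in range(m):
            total0 += Kd[a, a]
        eps = 1e-12 * max(1.0, total0)
        a_fit = 0
        for a in range(a_max):
            KY = Kd @ Yc
            S = Yc.T @ KY
            evals, evecs = np.linalg.eigh(S)
            if evals[g - 1] <= eps:
                break
            u = Yc @ evecs[:, g - 1].copy()
            t = Kd @ u
            tt = t @ t
            if tt <= eps:
                break
            c = (Yc.T @ t) / tt
            t_new = kd @ u
            for q in range(g):
                last[q] += t_new * c[q]
                yhat[a, q] = last[q]
            v = Kd @ t
            tv = t @ v
            kd -= (t_new / tt) * v
            kd -= ((kd @ t) / tt) * t
            for ai in range(m):
                for bi in range(m):
                    Kd[ai, bi] += (
                        -(t[ai] * v[bi] + v[ai] * t[bi]) / tt
                        + t[ai] * t[bi] * tv / (tt * tt)
                    )
            a_fit = a + 1
        if a_fit == 0:
            for q in range(g):
                yhat[0, q] = y_mean[q]
            a_fit = 1
        for a in range(a_fit, a_max):
            for q in range(g):
                yhat[a, q] = yhat[a_fit - 1, q]
        for a in range(a_max):
            best = 0
            for q in range(1, g):
                if yhat[a, q] > yhat[a, best]:
                    best = q
            correct[a, i] = best == y_idx[i]
            s = 0.0
            for q in range(g):
                s += (Y[i, q] - yhat[a, q]) ** 2
            press[a] += s
    return correct, press


def _loo_nested(X: np.ndarray, Y: np.ndarray, y_idx: np.ndarray, a_max: int,
                K: np.ndarray | None = None):
    """LOO predictions for every component count 1..a_max in one pass.

    Returns (correct: a_max×n boolean, press: a_max vector).
    """
    n, g = Y.shape
    if K is None:
        K = X @ X.T
    if _HAVE_NUMBA:
        return _loo_all_jit(
            np.ascontiguousarray(K), np.ascontiguousarray(Y),
            y_idx.astype(np.int64), a_max,
        )
    correct = np.zeros((a_max, n), dtype=bool)
    press = np.zeros(a_max)
    for i in range(n):
        yhat = _fold_predictions(K, Y, i, a_max)
        correct[:, i] = np.argmax(yhat, axis=1) == y_idx[i]
        press += np.sum((Y[i] - yhat) ** 2, axis=1)
    return correct, press


def loo_cv(X: np.ndarray, labels, a_max: int = 10, _gram: np.ndarray | None = None):
    """Leave-one-out CV over component counts 1..a_max.

    Returns ``(optimal_A, accuracy, q2, accuracy_per_A, q2_per_A)`` where
    ``optimal_A`` is the smallest component count maximising LOO accuracy
    and Q²(A) = 1 − PRESS(A)/TSS with TSS from the full-data centered Y.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n < 3:
        raise ValueError("LOO-CV needs at least 3 samples")
    Y, class_order = encode_onehot(labels)
    counts = Y.sum(axis=0)
    if np.any(counts < 2):
        short = [c for c, m in zip(class_order, counts) if m < 2]
        raise ValueError(
            f"classes {short} have fewer than 2 samples; LOO folds would lose a class"
        )
    a_max = int(min(a_max, n - 2, X.shape[1]))
    y_idx = np.argmax(Y, axis=1)
    correct, press = _loo_nested(X, Y, y_idx, a_max, _gram)
    acc_per_a = correct.mean(axis=1)
    tss = float(np.sum((Y - Y.mean(axis=0)) ** 2))
    q2_per_a = 1.0 - press / tss
    optimal_a = int(np.argmax(acc_per_a)) + 1        # first maximiser = smallest A
    return (
        optimal_a,
        float(acc_per_a[optimal_a - 1]),
        float(q2_per_a[optimal_a - 1]),
        acc_per_a,
        q2_per_a,
    )


def permutation_test(
    X: np.ndarray, labels, n_perm: int = 999, seed: int = 0, a_max: int = 10,
    observed_accuracy: float | None = None,
) -> tuple[float, float, np.ndarray]:
    """Label-permutation test of the LOO-accuracy statistic.

    The observed statistic is the LOO accuracy at the optimal A for the
    true labels; every permutation re-selects its own A by LOO, so the
    null distribution carries the same selection optimism.  The p-value
    uses the add-one correction ``(1 + #{perm ≥ observed}) / (1 + n_perm)``.

    Returns ``(p_value, observed_accuracy, permuted_accuracies)``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    labels = np.asarray(labels, dtype=object)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    K = X @ X.T                      # label-independent; shared by all refits
    if observed_accuracy is None:
        _, observed_accuracy, _, _, _ = loo_cv(X, labels, a_max, _gram=K)
    rng = np.random.default_rng(seed)
    perm_acc = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(labels)
        _, acc, _, _, _ = loo_cv(X, perm, a_max, _gram=K)
        perm_acc[b] = acc
    p = (1.0 + np.sum(perm_acc >= observed_accuracy - 1e-12)) / (1.0 + n_perm)
    return float(p), float(observed_accuracy), perm_acc


def vip_scores(model: PLSDAModel) -> np.ndarray:
    """Variable importance in projection.

    VIP_j = sqrt( p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a ); the scores
    square-average to 1 (Σ VIP² = p).
    """
    ssy_total = model.ssy.sum()
    if ssy_total <= 0:
        raise ValueError("zero explained Y sum of squares")
    W = model.x_weights / np.linalg.norm(model.x_weights, axis=0, keepdims=True)
    p = W.shape[0]
    return np.sqrt(p * (W**2 @ model.ssy) / ssy_total)


def coef_importance(model: PLSDAModel) -> np.ndarray:
    """Coefficient-based relevance: per-class squared regression
    coefficients normalised by the component count, averaged over classes."""
    B = model.coefficients
    return np.mean(B**2, axis=1) / model.n_components


@dataclass
class PLSDAPerformance:
    accuracy: float
    r2: float
    q2: float
    permutation_p: float
    n_permutations: int
    optimal_A: int
    vip: np.ndarray
    coef_importance: np.ndarray
    class_order: list
    accuracy_per_A: np.ndarray = field(default=None, repr=False)

    def summary(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "r2": self.r2,
            "q2": self.q2,
            "permutation_p": self.permutation_p,
            "n_permutations": self.n_permutations,
            "optimal_A": self.optimal_A,
            "classes": [str(c) for c in self.class_order],
        }


def evaluate(
    X: np.ndarray, labels, n_perm: int = 999, seed: int = 0, a_max: int = 10
) -> PLSDAPerformance:
    """Full PLS-DA assessment: LOO-CV accuracy and Q², training R²,
    permutation p-value, VIP and coefficient importance."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    optimal_a, acc, q2, acc_per_a, _ = loo_cv(X, labels, a_max)
    Y, class_order = encode_onehot(labels)
    model = fit_pls(X, Y, optimal_a, class_order)
    resid = Y - model.predict(X)
    tss = float(np.sum((Y - Y.mean(axis=0)) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / tss
    p, _, _ = permutation_test(
        X, labels, n_perm=n_perm, seed=seed, a_max=a_max, observed_accuracy=acc
    )
    return PLSDAPerformance(
        accuracy=acc,
        r2=r2,
        q2=q2,
        permutation_p=p,
        n_permutations=n_perm,
        optimal_A=optimal_a,
        vip=vip_scores(model),
        coef_importance=coef_importance(model),
        class_order=class_order,
        accuracy_per_A=acc_per_a,
    )
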