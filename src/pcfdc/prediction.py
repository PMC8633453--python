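"""Ridge-regression prediction of behaviour from lesion network maps.

Individual r-maps are reduced by PCA over brain voxels (components kept up
to 95% cumulative variance), the whole score matrix is z-normalized with a
single global mean/SD pair, and a closed-form ridge model

    W = (X'X + lambda I)^-1 X'Y

is trained inside a leave-one-subject-out loop.  The regularization
strength is tuned for every outer fold by an inner leave-one-out search
over 100 log-spaced values in [1e-5, 1e5], so each held-out prediction is
honest.  Accuracy uses the coefficient of determination in the form

    R2 = 1 - sum (Y - Y')^2 / sum (Y - Y'')^2

with Y'' the mean of the *predictions* — this differs from the textbook
R^2 (whose reference is the mean of Y) and can be negative; the
conventional form is available behind a flag.  Significance comes from
re-running the entire nested pipeline on permuted outcomes, and weight
reliability from comparing each component's fold-weight distribution to
the permutation null, FDR-corrected, before back-projecting the surviving
averaged weights to a brain map through the transposed PC loadings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .volumes import BinaryMask, TemplateGrid, Volume3D

__all__ = [
    "FeatureMatrix",
    "RidgePredictionResult",
    "PermutationTestResult",
    "default_lambda_grid",
    "pca_reduce_maps",
    "znormalize_features",
    "ridge_weights",
    "tune_lambda",
    "loocv_predict",
    "r_squared",
    "permutation_significance",
    "reliable_weight_map",
    "predict_behaviour",
]


def default_lambda_grid(n: int = 100, low: float = 1e-5, high: float = 1e5) -> np.ndarray:
    """100 logarithmically spaced regularization values in [1e-5, 1e5]."""
    return np.logspace(np.log10(low), np.log10(high), n)


@dataclass
class FeatureMatrix:
    """PC scores of subject maps plus the loadings for back-projection."""

    subjects: list[str]
    scores: np.ndarray  # (n subjects, k components)
    loadings: np.ndarray  # (v voxels in domain, k components)
    explained_variance_ratio: np.ndarray
    variance_retained: float
    grid: TemplateGrid
    domain: np.ndarray  # boolean voxel selector on the grid

    @property
    def n_components(self) -> int:
        return int(self.scores.shape[1])


@dataclass
class RidgePredictionResult:
    """Out-of-sample ridge predictions and everything derived from them."""

    subjects: list[str]
    predictions: np.ndarray
    per_fold_lambda: np.ndarray
    per_fold_weights: np.ndarray  # (n folds, k components)
    r2: float
    perm_p: float | None = None
    null_r2: np.ndarray | None = None
    reliable_weight_map: Volume3D | None = None

    def summary(self) -> str:
        lines = [
            "Ridge LOOCV behaviour prediction",
            f"  subjects:            {len(self.subjects)}",
            f"  components:          {self.per_fold_weights.shape[1]}",
            f"  lambda (median):     {np.median(self.per_fold_lambda):.4g}",
            f"  R2 (prediction-mean denominator): {self.r2:.4f}",
        ]
        if self.perm_p is not None:
            lines.append(
                f"  permutation p:       {self.perm_p:.4f} "
                f"({len(self.null_r2)} permutations)"
            )
        return "\n".join(lines)


@dataclass
class PermutationTestResult:
    p: float
    null_r2: np.ndarray
    null_mean_weights: np.ndarray  # (n_perm, k) across-fold averaged weights


# ---------------------------------------------------------------------------
# Feature construction


def pca_reduce_maps(
    maps: list,
    variance_threshold: float = 0.95,
    domain_mask: BinaryMask | None = None,
) -> FeatureMatrix:
    """PCA of subject maps: observations are subjects, variables voxels.

    Retains the smallest leading set of components whose cumulative
    explained variance reaches the threshold; loadings are kept so reliable
    weights can be projected back to the brain.
    """
    if len(maps) < 3:
        raise ValueError("PCA reduction needs at least 3 maps")
    if not 0 < variance_threshold <= 1:
        raise ValueError("variance_threshold must lie in (0, 1]")
    grid = maps[0].grid
    for m in maps[1:]:
        grid.require_match(m.grid, "map")
    if domain_mask is None:
        sel = np.ones(grid.shape, dtype=bool)
    else:
        grid.require_match(domain_mask.grid, "domain mask")
        sel = domain_mask.values
    X = np.stack([m.values[sel] for m in maps])  # (n, v)
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    nonzero = s > s[0] * 1e-12 if s[0] > 0 else s > 0
    if nonzero.sum() < 2:
        raise ValueError("fewer than 2 non-degenerate components")
    s, U, Vt = s[nonzero], U[:, nonzero], Vt[nonzero]
    evr = s**2 / (s**2).sum()
    k = int(np.searchsorted(np.cumsum(evr), variance_threshold - 1e-12) + 1)
    k = max(k, 2)
    subjects = [getattr(m, "subject", f"sub-{i}") for i, m in enumerate(maps)]
    return FeatureMatrix(
        subjects=subjects,
        scores=U[:, :k] * s[:k],
        loadings=Vt[:k].T.copy(),
        explained_variance_ratio=evr,
        variance_retained=float(np.cumsum(evr)[k - 1]),
        grid=grid,
        domain=sel,
    )


def znormalize_features(fm: FeatureMatrix) -> FeatureMatrix:
    """Z-normalize the score matrix with one global mean/SD pair.

    A single scalar mean and standard deviation of the whole matrix is
    used — not per-column scaling — so the relative variance ordering of
    the components is preserved.
    """
    mu = fm.scores.mean()
    sd = fm.scores.std()
    if sd == 0:
        raise ValueError("score matrix has zero global variance")
    return FeatureMatrix(
        subjects=fm.subjects,
        scores=(fm.scores - mu) / sd,
        loadings=fm.loadings,
        explained_variance_ratio=fm.explained_variance_ratio,
        variance_retained=fm.variance_retained,
        grid=fm.grid,
        domain=fm.domain,
    )


# ---------------------------------------------------------------------------
# Ridge core


def ridge_weights(X: np.ndarray, Y: np.ndarray, lam: float) -> np.ndarray:
    """Closed-form ridge solution (X'X + lambda I)^-1 X'Y, no intercept."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    k = X.shape[1]
    A = X.T @ X + lam * np.eye(k)
    b = X.T @ Y
    if lam == 0:
        return np.linalg.pinv(A) @ b
    return np.linalg.solve(A, b)


class _FoldCache:
    """Per-fold SVDs of the training design, reused across permutations.

    Leave-one-out residuals of a ridge smoother satisfy
    ``e_i = (y_i - yhat_i) / (1 - H_ii)`` exactly, so the inner tuning loop
    needs one SVD per fold, not one fit per (fold, left-out point, lambda).
    """

    def __init__(self, X: np.ndarray, grid: np.ndarray):
        self.X = X
        self.grid = np.asarray(grid, dtype=float)
        n = X.shape[0]
        self.folds = []
        for i in range(n):
            Xt = np.delete(X, i, axis=0)
            U, s, Vt = np.linalg.svd(Xt, full_matrices=False)
            d = s**2 / (s**2 + self.grid[:, None])  # (L, k) shrinkage factors
            hdiag = (U**2) @ d.T  # (n-1, L) leverage per lambda
            self.folds.append((U, s, Vt, d, hdiag))

    def predict_all(self, Y: np.ndarray):
        """Nested-LOOCV predictions for outcome Y; returns (pred, lambdas, weights)."""
        n = self.X.shape[0]
        preds = np.empty(n)
        lambdas = np.empty(n)
        weights = np.empty((n, self.X.shape[1]))
        for i in range(n):
            U, s, Vt, d, hdiag = self.folds[i]
            y = np.delete(Y, i)
            uty = U.T @ y
            yhat = U @ (d.T * uty[:, None])  # (n-1, L)
            denom = np.maximum(1.0 - hdiag, 1e-12)
            loo_err = (((y[:, None] - yhat) / denom) ** 2).sum(axis=0)
            j = int(np.argmin(loo_err))  # ties -> smallest lambda (grid ascending)
            lam = self.grid[j]
            w = Vt.T @ ((s / (s**2 + lam)) * uty)
            preds[i] = self.X[i] @ w
            lambdas[i] = lam
            weights[i] = w
        return preds, lambdas, weights


def tune_lambda(X_train: np.ndarray, Y_train: np.ndarray, grid: np.ndarray | None = None) -> float:
    """Regularization value minimizing leave-one-out squared error on the
    training set; ties break toward the smallest value."""
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    Y_train = np.asarray(Y_train, dtype=float)
    if X_train.shape[0] < 3:
        raise ValueError("need at least 3 training subjects")
    if grid is None:
        grid = default_lambda_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty lambda grid")
    U, s, _ = np.linalg.svd(X_train, full_matrices=False)
    uty = U.T @ Y_train
    d = s**2 / (s**2 + grid[:, None])
    yhat = U @ (d.T * uty[:, None])
    hdiag = (U**2) @ d.T
    denom = np.maximum(1.0 - hdiag, 1e-12)
    loo_err = (((Y_train[:, None] - yhat) / denom) ** 2).sum(axis=0)
    return float(grid[int(np.argmin(loo_err))])


def loocv_predict(
    X: np.ndarray,
    Y: np.ndarray,
    grid: np.ndarray | None = None,
    subjects: list[str] | None = None,
    conventional_r2: bool = False,
) -> RidgePredictionResult:
    """Nested leave-one-out ridge prediction.

    For each subject i, lambda is tuned by an inner leave-one-out search on
    the remaining n-1 subjects, the model is fitted on those n-1, and
    subject i is predicted — predictions are strictly out of sample.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    if n < 5:
        raise ValueError("nested LOOCV needs at least 5 subjects")
    if Y.shape != (n,):
        raise ValueError("one outcome per subject required")
    if Y.std() == 0:
        raise ValueError("constant outcome variable")
    if grid is None:
        grid = default_lambda_grid()
    cache = _FoldCache(X, grid)
    preds, lambdas, weights = cache.predict_all(Y)
    r2 = r_squared(Y, preds, conventional=conventional_r2)
    if subjects is None:
        subjects = [f"sub-{i}" for i in range(n)]
    return RidgePredictionResult(subjects, preds, lambdas, weights, r2)


def r_squared(Y, Y_pred, conventional: bool = False) -> float:
    """Coefficient of determination.

    Default form: ``1 - sum (Y - Y')^2 / sum (Y - mean(Y'))^2`` — the
    denominator references the mean of the predictions.  With
    ``conventional=True`` the denominator uses the mean of Y instead.
    Either form can be negative for poor predictions.
    """
    Y = np.asarray(Y, dtype=float)
    Y_pred = np.asarray(Y_pred, dtype=float)
    if Y.shape != Y_pred.shape or len(Y) < 2:
        raise ValueError("need equal-length vectors of length >= 2")
    ref = Y.mean() if conventional else Y_pred.mean()
    denom = ((Y - ref) ** 2).sum()
    if denom == 0:
        raise ValueError("zero denominator in R^2")
    return float(1.0 - ((Y - Y_pred) ** 2).sum() / denom)


def permutation_significance(
    X: np.ndarray,
    Y: np.ndarray,
    grid: np.ndarray | None = None,
    n_perm: int = 10000,
    rng_seed: int = 0,
    conventional_r2: bool = False,
    small_sample_correction: bool = False,
) -> PermutationTestResult:
    """Permutation p-value for the nested-LOOCV R².

    The outcomes are permuted across subjects and the entire nested
    pipeline (inner lambda tuning included) is re-run per permutation.
    The p-value is ``count(null R2 > observed R2) / n_perm``; with
    ``small_sample_correction`` the ``(count+1)/(n_perm+1)`` form is used.
    Across-fold mean weights of every null model are retained as the null
    distribution for weight-reliability testing.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if grid is None:
        grid = default_lambda_grid()
    cache = _FoldCache(X, grid)
    preds, _, _ = cache.predict_all(Y)
    obs = r_squared(Y, preds, conventional=conventional_r2)
    rng = np.random.default_rng(rng_seed)
    null_r2 = np.empty(n_perm)
    null_w = np.empty((n_perm, X.shape[1]))
    for p in range(n_perm):
        Yp = rng.permutation(Y)
        pr, _, w = cache.predict_all(Yp)
        null_r2[p] = r_squared(Yp, pr, conventional=conventional_r2)
        null_w[p] = w.mean(axis=0)
    count = int((null_r2 > obs).sum())
    if small_sample_correction:
        pval = (count + 1) / (n_perm + 1)
    else:
        pval = count / n_perm
    return PermutationTestResult(float(pval), null_r2, null_w)


def reliable_weight_map(
    per_fold_weights: np.ndarray,
    null_mean_weights: np.ndarray,
    fm: FeatureMatrix,
    fdr_q: float = 0.05,
) -> Volume3D:
    """Back-project FDR-reliable averaged ridge weights to the brain.

    Per component, a two-sample t-test compares the fold-weight
    distribution against the permutation-null mean weights; components
    surviving Benjamini-Hochberg at ``fdr_q`` keep their across-fold mean
    weight, the rest are zeroed, and the vector is mapped to voxel space
    through the transposed PC loadings.
    """
    W = np.asarray(per_fold_weights, dtype=float)
    N = np.asarray(null_mean_weights, dtype=float)
    if N.size == 0:
        raise ValueError("null weight distributions are required")
    k = W.shape[1]
    if N.shape[1] != k or fm.loadings.shape[1] != k:
        raise ValueError("component count mismatch between weights and loadings")
    pvals = np.empty(k)
    for j in range(k):
        if W[:, j].std() == 0 and N[:, j].std() == 0:
            pvals[j] = 0.0 if W[:, j].mean() != N[:, j].mean() else 1.0
        else:
            pvals[j] = sps.ttest_ind(W[:, j], N[:, j], equal_var=False).pvalue
    keep = multipletests(pvals, alpha=fdr_q, method="fdr_bh")[0]
    w_mean = W.mean(axis=0) * keep
    flat = fm.loadings @ w_mean
    vol = np.zeros(fm.grid.shape)
    vol[fm.domain] = flat
    return Volume3D(fm.grid, vol)


def predict_behaviour(
    maps: list,
    scores,
    variance_threshold: float = 0.95,
    lambda_grid: np.ndarray | None = None,
    n_perm: int = 10000,
    rng_seed: int = 0,
    fdr_q: float = 0.05,
    domain_mask: BinaryMask | None = None,
    conventional_r2: bool = False,
) -> RidgePredictionResult:
    """The full prediction workflow from r-maps and scores.

    PCA reduction -> global z-normalization of features and outcome ->
    nested-LOOCV ridge -> permutation significance -> reliable-weight
    brain map.
    """
    scores = np.asarray(scores, dtype=float)
    fm = znormalize_features(
        pca_reduce_maps(maps, variance_threshold, domain_mask=domain_mask)
    )
    if scores.std() == 0:
        raise ValueError("constant outcome variable")
    y = (scores - scores.mean()) / scores.std()
    res = loocv_predict(
        fm.scores, y, grid=lambda_grid, subjects=fm.subjects,
        conventional_r2=conventional_r2,
    )
    perm = permutation_significance(
        fm.scores, y, grid=lambda_grid, n_perm=n_perm, rng_seed=rng_seed,
        conventional_r2=conventional_r2,
    )
    res.perm_p = perm.p
    res.null_r2 = perm.null_r2
    res.reliable_weight_map = reliable_weight_map(
        res.per_fold_weights, perm.null_mean_weights, fm, fdr_q=fdr_q
    )
    return res
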