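"""L1-regularised logistic classification of genotypes from phenotype traits.

The task: given the pooled plant-day trait vectors of one treatment group,
distinguish wild type (label 0) from the heat-sensitive mutant (label 1),
and rank traits by the magnitude of their standardized lasso weights.

The optimisation problem is

    min_{w, b}  (1/n) sum_i log(1 + exp(-s_i (x_i . w + b)))  +  lam ||w||_1

with s_i in {-1, +1} and the intercept b unpenalised.  Two independent
solvers are provided — monotone proximal gradient (ISTA with backtracking)
and cyclic coordinate descent with a per-coordinate quadratic majorizer —
which agree at the (unique, convex) optimum and cross-validate each other.

Cross-validated accuracy uses stratified k-fold with *plant-level* fold
assignment: all days of a plant land in one fold, so no plant contributes
to both training and test (temporal leakage guard).  The penalty is chosen
per outer fold by an inner grouped CV over a log-spaced grid, and feature
standardization is always fitted on the training partition only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class FeatureMatrix:
    """Plant-day samples x trait columns with genotype labels."""

    X: np.ndarray  # (n_samples, n_features), unstandardized
    y: np.ndarray  # (n_samples,) in {0, 1}
    columns: list[str]
    plant_ids: np.ndarray  # (n_samples,) group key for fold assignment

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        self.plant_ids = np.asarray(self.plant_ids)
        if self.X.shape != (self.y.size, len(self.columns)):
            raise ValueError("inconsistent feature matrix dimensions")
        if np.isnan(self.X).any():
            raise ValueError("feature matrix contains missing values")


@dataclass
class ClassifierModel:
    """Fitted lasso-logistic model (weights on the standardized scale)."""

    weights: np.ndarray
    intercept: float
    lam: float
    columns: list[str]
    converged: bool
    n_iter: int
    objective: float
    kkt_residual: float
    feature_means: np.ndarray | None = None
    feature_sds: np.ndarray | None = None

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if self.feature_means is not None:
            X = (X - self.feature_means) / self.feature_sds
        return X @ self.weights + self.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(np.int64)


@dataclass
class CVResult:
    """Outer-fold cross-validation summary."""

    accuracy: float
    fold_accuracies: list[float]
    chosen_lambdas: list[float]
    n_samples: int
    n_plants: int
    models: list[ClassifierModel] = field(default_factory=list)


def build_features(
    table: pd.DataFrame,
    group: str,
    trait_subset: Sequence[str] | None = None,
    mutant_genotype: str = "hsp101",
    standardize: bool = False,
) -> FeatureMatrix:
    """Pivot the long trait table of one treatment group into a sample matrix.

    One sample per plant-day (days pooled); label 1 for the mutant genotype.
    Constant columns are dropped with a warning.  With ``standardize=True``
    the whole matrix is z-scored (single-fit use only — cross-validation
    standardizes per training fold instead).
    """
    sub = table[table["treatment"] == group]
    if sub.empty:
        raise ValueError(f"treatment group {group!r} not present in table")
    if trait_subset is not None:
        sub = sub[sub["trait"].isin(trait_subset)]
        if sub.empty:
            raise ValueError("trait subset removed every row")
    wide = sub.pivot_table(
        index=["plant_id", "genotype", "das"], columns="trait", values="value"
    ).dropna(axis=0)
    cols = list(wide.columns)
    X = wide.to_numpy(dtype=np.float64)
    sds = X.std(axis=0)
    keep = sds > 0
    if not keep.all():
        dropped = [c for c, k in zip(cols, keep) if not k]
        warnings.warn(f"dropping constant columns: {dropped}", stacklevel=2)
        X = X[:, keep]
        cols = [c for c, k in zip(cols, keep) if k]
    idx = wide.index.to_frame(index=False)
    y = (idx["genotype"] == mutant_genotype).to_numpy(dtype=np.int64)
    if standardize:
        X = (X - X.mean(axis=0)) / X.std(axis=0)
    return FeatureMatrix(X=X, y=y, columns=cols, plant_ids=idx["plant_id"].to_numpy())


def _objective(X: np.ndarray, s: np.ndarray, w: np.ndarray, b: float, lam: float) -> float:
    z = s * (X @ w + b)
    return float(np.mean(np.logaddexp(0.0, -z)) + lam * np.abs(w).sum())


def _loss_grad(X: np.ndarray, s: np.ndarray, w: np.ndarray, b: float) -> tuple[np.ndarray, float]:
    """Gradient of the unpenalized mean logistic loss w.r.t. (w, b)."""
    z = s * (X @ w + b)
    # sigma(-z) computed stably
    q = np.where(z >= 0, np.exp(-z) / (1.0 + np.exp(-z)), 1.0 / (1.0 + np.exp(z)))
    coef = -s * q / X.shape[0]
    return X.T @ coef, float(coef.sum())


def _soft(v: np.ndarray | float, t: float):
    return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)


def kkt_residual(X: np.ndarray, y: np.ndarray, w: np.ndarray, b: float, lam: float) -> float:
    """Max violation of the lasso stationarity conditions at (w, b).

    For active weights the loss gradient must equal -lam*sign(w_j); for
    zero weights it must lie in [-lam, lam]; the intercept gradient must
    vanish.
    """
    s = 2.0 * np.asarray(y, dtype=np.float64) - 1.0
    g, gb = _loss_grad(X, s, w, b)
    res = abs(gb)
    active = w != 0
    if active.any():
        res = max(res, float(np.max(np.abs(g[active] + lam * np.sign(w[active])))))
    if (~active).any():
        res = max(res, float(np.max(np.maximum(np.abs(g[~active]) - lam, 0.0))))
    return res


def _fit_proximal(
    X: np.ndarray, s: np.ndarray, lam: float, tol: float, max_iter: int,
    w0: np.ndarray | None = None, b0: float = 0.0,
) -> tuple[np.ndarray, float, int, bool]:
    n, p = X.shape
    w = np.zeros(p) if w0 is None else w0.copy()
    b = b0
    step = 1.0
    obj = _objective(X, s, w, b, lam)
    for it in range(1, max_iter + 1):
        g, gb = _loss_grad(X, s, w, b)
        # backtracking line search on the proximal step (monotone descent)
        while True:
            w_new = _soft(w - step * g, step * lam)
            b_new = b - step * gb
            obj_new = _objective(X, s, w_new, b_new, lam)
            dw = w_new - w
            db = b_new - b
            quad = (
                obj
                - lam * np.abs(w).sum()
                + g @ dw
                + gb * db
                + (dw @ dw + db * db) / (2.0 * step)
                + lam * np.abs(w_new).sum()
            )
            if obj_new <= quad + 1e-15 or step < 1e-12:
                break
            step *= 0.5
        delta = max(np.max(np.abs(w_new - w)), abs(b_new - b))
        w, b, obj = w_new, b_new, obj_new
        if delta < tol:
            return w, b, it, True
        step = min(step * 2.0, 1e4)
    return w, b, max_iter, False


def _fit_coordinate(
    X: np.ndarray, s: np.ndarray, lam: float, tol: float, max_iter: int,
    w0: np.ndarray | None = None, b0: float = 0.0,
) -> tuple[np.ndarray, float, int, bool]:
    n, p = X.shape
    w = np.zeros(p) if w0 is None else w0.copy()
    b = b0
    xw = X @ w
    # per-coordinate curvature upper bounds (|sigma'| <= 1/4)
    hj = np.maximum((X * X).sum(axis=0) / (4.0 * n), 1e-12)
    for it in range(1, max_iter + 1):
        delta = 0.0
        z = s * (xw + b)
        q = np.where(z >= 0, np.exp(-z) / (1.0 + np.exp(-z)), 1.0 / (1.0 + np.exp(z)))
        gb = float(np.sum(-s * q)) / n
        db = -gb * 4.0  # intercept curvature bound 1/4
        if db != 0.0:
            b += db
            delta = max(delta, abs(db))
            z = s * (xw + b)
            q = np.where(z >= 0, np.exp(-z) / (1.0 + np.exp(-z)), 1.0 / (1.0 + np.exp(z)))
        for j in range(p):
            gj = float(X[:, j] @ (-s * q)) / n
            wj_new = _soft(w[j] - gj / hj[j], lam / hj[j])
            dwj = wj_new - w[j]
            if dwj != 0.0:
                xw += dwj * X[:, j]
                w[j] = wj_new
                delta = max(delta, abs(dwj))
                z = s * (xw + b)
                q = np.where(z >= 0, np.exp(-z) / (1.0 + np.exp(-z)), 1.0 / (1.0 + np.exp(z)))
        if delta < tol:
            return w, b, it, True
    return w, b, max_iter, False


def fit_l1_logistic(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    tol: float = 1e-8,
    max_iter: int = 5000,
    method: str = "cd",
    columns: Sequence[str] | None = None,
    warm_start: tuple[np.ndarray, float] | None = None,
) -> ClassifierModel:
    """Fit the lasso-logistic model from a zero initialization.

    Parameters
    ----------
    X, y
        Feature matrix (already standardized by the caller) and 0/1 labels.
    lam
        L1 penalty weight on the mean-loss scale; ``lam >= lambda_max``
        (see :func:`lambda_max`) shrinks every weight to zero.
    method
        ``"cd"`` (cyclic coordinate descent, default) or ``"prox"``
        (monotone proximal gradient).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    s = 2.0 * y - 1.0
    w0, b0 = (None, 0.0) if warm_start is None else (np.asarray(warm_start[0], dtype=np.float64), float(warm_start[1]))
    if method == "cd":
        w, b, n_iter, ok = _fit_coordinate(X, s, lam, tol, max_iter, w0, b0)
    elif method == "prox":
        w, b, n_iter, ok = _fit_proximal(X, s, lam, tol, max_iter, w0, b0)
    else:
        raise ValueError(f"unknown method {method!r}")
    if not ok:
        warnings.warn(
            f"lasso-logistic did not converge in {max_iter} iterations", stacklevel=2
        )
    cols = list(columns) if columns is not None else [f"x{j}" for j in range(X.shape[1])]
    return ClassifierModel(
        weights=w,
        intercept=float(b),
        lam=float(lam),
        columns=cols,
        converged=ok,
        n_iter=n_iter,
        objective=_objective(X, s, w, b, lam),
        kkt_residual=kkt_residual(X, y, w, b, lam),
    )


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty that zeroes all weights (KKT bound at w=0, b fitted)."""
    y = np.asarray(y, dtype=np.float64)
    pbar = y.mean()
    b0 = np.log(pbar / (1.0 - pbar))
    s = 2.0 * y - 1.0
    g, _ = _loss_grad(np.asarray(X, dtype=np.float64), s, np.zeros(X.shape[1]), b0)
    return float(np.max(np.abs(g)))


def _standardize_on(train: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mu, sd


def stratified_group_folds(
    plant_ids: np.ndarray, y: np.ndarray, k: int, seed: int
) -> list[np.ndarray]:
    """Assign plants (groups) to k folds, stratified by the plant's label.

    Returns, per fold, the boolean sample mask of its test set.  Every
    sample of a plant is in exactly one fold.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    plants = pd.DataFrame({"plant": plant_ids, "y": y}).drop_duplicates("plant")
    if plants.groupby("plant").size().max() > 1:  # pragma: no cover - defensive
        raise ValueError("a plant has inconsistent labels")
    rng = np.random.default_rng(seed)
    fold_of: dict[object, int] = {}
    for label in np.unique(plants["y"]):
        ids = plants.loc[plants["y"] == label, "plant"].to_numpy()
        ids = ids[rng.permutation(ids.size)]
        for i, pid in enumerate(ids):
            fold_of[pid] = i % k
    assignments = np.array([fold_of[p] for p in plant_ids])
    masks = [assignments == f for f in range(k)]
    for f, m in enumerate(masks):
        if len(np.unique(y[~m])) < 2:
            raise ValueError(f"fold {f}: a class is absent from the training split")
    return masks


def default_lambda_grid(
    X: np.ndarray, y: np.ndarray, n: int = 8, floor: float = 1e-3
) -> np.ndarray:
    """Log-spaced penalty grid from lambda_max down to floor*lambda_max."""
    lmax = lambda_max(X, y)
    return lmax * np.logspace(0, np.log10(floor), n)


def cv_accuracy(
    fm: FeatureMatrix,
    lambda_grid: Sequence[float] | None = None,
    k: int = 5,
    seed: int = 0,
    inner_k: int = 3,
    tol: float = 1e-5,
    max_iter: int = 800,
    n_lambdas: int = 6,
) -> CVResult:
    """Nested, plant-grouped, stratified CV accuracy of the lasso classifier.

    Outer loop: k stratified folds of plants.  Inner loop (per outer
    training set): ``inner_k``-fold grouped CV over the penalty grid; the
    penalty with the best inner accuracy (ties -> stronger penalty) is
    refitted on the full outer-training set and scored on the held-out
    fold.  Standardization parameters are always estimated on the training
    partition only.
    """
    X, y, plants = fm.X, fm.y, fm.plant_ids
    masks = stratified_group_folds(plants, y, k, seed)
    fold_accs: list[float] = []
    chosen: list[float] = []
    models: list[ClassifierModel] = []
    for f, test_mask in enumerate(masks):
        train_mask = ~test_mask
        Xtr, ytr, ptr = X[train_mask], y[train_mask], plants[train_mask]
        mu, sd = _standardize_on(Xtr)
        Ztr = (Xtr - mu) / sd
        grid = (
            np.asarray(lambda_grid, dtype=float)
            if lambda_grid is not None
            else default_lambda_grid(Ztr, ytr, n=n_lambdas, floor=1e-2)
        )
        grid = np.sort(grid)[::-1]
        inner_masks = stratified_group_folds(ptr, ytr, inner_k, seed * 1000 + f + 1)
        scores = np.zeros(grid.size)
        for im in inner_masks:
            tr_i = ~im
            yi = ytr[tr_i]
            mu_i, sd_i = _standardize_on(Xtr[tr_i])
            Zi = (Xtr[tr_i] - mu_i) / sd_i
            Zi_test = (Xtr[im] - mu_i) / sd_i
            warm = None  # warm-start down the penalty path
            for gi, lam in enumerate(grid):
                model = fit_l1_logistic(
                    Zi, yi, lam, tol=tol, max_iter=max_iter, warm_start=warm
                )
                warm = (model.weights, model.intercept)
                pred = (Zi_test @ model.weights + model.intercept) > 0
                scores[gi] += float(np.mean(pred == ytr[im]))
        best = int(np.argmax(scores))  # ties -> first = largest penalty
        lam_star = float(grid[best])
        model = fit_l1_logistic(Ztr, ytr, lam_star, tol=tol, max_iter=max_iter, columns=fm.columns)
        model.feature_means, model.feature_sds = mu, sd
        Zte = (X[test_mask] - mu) / sd
        pred = (Zte @ model.weights + model.intercept) > 0
        fold_accs.append(float(np.mean(pred == y[test_mask])))
        chosen.append(lam_star)
        models.append(model)
    return CVResult(
        accuracy=float(np.mean(fold_accs)),
        fold_accuracies=fold_accs,
        chosen_lambdas=chosen,
        n_samples=y.size,
        n_plants=int(pd.unique(plants).size),
        models=models,
    )


def rank_traits(model: ClassifierModel, top_n: int | None = None) -> list[str]:
    """Traits ordered by |standardized weight| descending; zeros excluded.

    Ties are broken lexicographically by trait name.
    """
    pairs = [
        (name, abs(w))
        for name, w in zip(model.columns, model.weights)
        if w != 0.0
    ]
    if not pairs:
        warnings.warn("all weights are zero; no traits to rank", stacklevel=2)
        return []
    pairs.sort(key=lambda t: (-t[1], t[0]))
    names = [name for name, _ in pairs]
    return names[:top_n] if top_n is not None else names
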