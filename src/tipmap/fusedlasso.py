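"""Fused-lasso logistic regression over L-curve features; tile phenotyping.

The classifier distinguishes *inflamed* (coded 1) from *excluded* (coded 0)
tiles from the per-tile feature vector x_r = L(r) - r.  The objective is the
penalized negative mean log-likelihood

    -1/S * sum_s { y_s (b0 + b.x_s) - log(1 + exp(b0 + b.x_s)) }
        + lambda1 * sum_r |b_{r+1} - b_r| + lambda2 * sum_r |b_r|

with the intercept b0 unpenalized.  The fusion penalty encodes that
consecutive radii of the L curve carry highly correlated information, so the
coefficient curve should be piecewise constant.

Solved by a monotone accelerated proximal-gradient scheme: the proximal
operator of the 1-D fused penalty is evaluated exactly (total-variation
proximity by Condat's direct algorithm, followed by soft thresholding), and
the intercept is updated by an exact 1-D Newton step each iteration.

Tiles with at most ``t`` immune cells (default 5) are labelled *deserted*
before any model evaluation; tiles with fewer than 2 tumor cells cannot
produce an L curve and are *unclassifiable*.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .spatial import LCurveFeatures

LABELS = ("inflamed", "excluded", "deserted", "unclassifiable")


def tv1d_prox(y: np.ndarray, lam: float) -> np.ndarray:
    """Exact proximal operator of lam * total variation in 1-D.

    Direct non-iterative algorithm (running taut-string with restarts);
    O(n) in practice.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    x = np.empty(n)
    if n == 0:
        return x
    if lam <= 0 or n == 1:
        return y.copy()
    k = k0 = kminus = kplus = 0
    vmin = y[0] - lam
    vmax = y[0] + lam
    umin = lam
    umax = -lam
    while True:
        while k == n - 1:
            if umin < 0.0:
                # negative jump necessary
                while True:
                    x[k0] = vmin
                    k0 += 1
                    if k0 > kminus:
                        break
                k = kminus = kplus = k0
                vmin = y[k]
                umin = lam
                umax = vmin + lam - vmax
            elif umax > 0.0:
                # positive jump necessary
                while True:
                    x[k0] = vmax
                    k0 += 1
                    if k0 > kplus:
                        break
                k = kminus = kplus = k0
                vmax = y[k]
                umax = -lam
                umin = vmax - lam - vmin
            else:
                vmin += umin / (k - k0 + 1)
                x[k0 : k + 1] = vmin
                return x
        umin += y[k + 1] - vmin
        if umin < -lam:
            # segment ends with a negative jump
            while True:
                x[k0] = vmin
                k0 += 1
                if k0 > kminus:
                    break
            k = kminus = kplus = k0
            vmin = y[k]
            vmax = vmin + 2 * lam
            umin = lam
            umax = -lam
        else:
            umax += y[k + 1] - vmax
            if umax > lam:
                # segment ends with a positive jump
                while True:
                    x[k0] = vmax
                    k0 += 1
                    if k0 > kplus:
                        break
                k = kminus = kplus = k0
                vmax = y[k]
                vmin = vmax - 2 * lam
                umin = lam
                umax = -lam
            else:
                k += 1
                if umin >= lam:
                    kminus = k
                    vmin += (umin - lam) / (kminus - k0 + 1)
                    umin = lam
                if umax <= -lam:
                    kplus = k
                    vmax += (umax + lam) / (kplus - k0 + 1)
                    umax = -lam


def _soft_threshold(v: np.ndarray, t: float) -> np.ndarray:
    return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)


def fused_prox(v: np.ndarray, t_fuse: float, t_sparse: float) -> np.ndarray:
    """prox of t_fuse*TV + t_sparse*L1: TV proximity then soft thresholding."""
    return _soft_threshold(tv1d_prox(v, t_fuse), t_sparse)


@dataclass
class FusedLassoModel:
    """Fitted fused-lasso logistic classifier (excluded = 0, inflamed = 1)."""

    beta0: float
    beta: np.ndarray
    lambda1: float       # fusion penalty weight
    lambda2: float       # sparsity penalty weight
    r_grid: np.ndarray | None = None
    n_iter: int = 0
    converged: bool = True
    objective_history: list = None

    def decision(self, X: np.ndarray) -> np.ndarray:
        return self.beta0 + np.atleast_2d(X) @ self.beta

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return _sigmoid(self.decision(X))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "beta0": self.beta0,
                    "beta": self.beta.tolist(),
                    "lambda1": self.lambda1,
                    "lambda2": self.lambda2,
                    "r_grid": None if self.r_grid is None else self.r_grid.tolist(),
                    "class_coding": {"excluded": 0, "inflamed": 1},
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "FusedLassoModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            beta0=d["beta0"],
            beta=np.asarray(d["beta"]),
            lambda1=d["lambda1"],
            lambda2=d["lambda2"],
            r_grid=None if d.get("r_grid") is None else np.asarray(d["r_grid"]),
        )


def _sigmoid(z):
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _log1pexp(z):
    out = np.empty_like(z, dtype=float)
    big = z > 30
    out[big] = z[big]
    out[~big] = np.log1p(np.exp(z[~big]))
    return out


def _check_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("X must be S x n with len(y) == S")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be binary 0/1 (excluded=0, inflamed=1)")
    return X, y


def fl_objective(beta0, beta, X, y, lambda1, lambda2) -> float:
    """Penalized negative mean log-likelihood, exactly as defined above."""
    X, y = _check_xy(X, y)
    beta = np.asarray(beta, dtype=float)
    z = beta0 + X @ beta
    nll = -np.mean(y * z - _log1pexp(z))
    return float(
        nll + lambda1 * np.sum(np.abs(np.diff(beta))) + lambda2 * np.sum(np.abs(beta))
    )


def _newton_intercept(s, y, b0, iters=30):
    """Exact 1-D minimization over the (unpenalized) intercept."""
    for _ in range(iters):
        p = _sigmoid(b0 + s)
        g = np.mean(p - y)
        h = max(np.mean(p * (1 - p)), 1e-10)
        step = g / h
        b0 -= step
        if abs(step) < 1e-14:
            break
    return b0


def fit_fused_lasso(
    X,
    y,
    lambda1: float,
    lambda2: float,
    tol: float = 1e-8,
    max_iter: int = 5000,
    r_grid=None,
) -> FusedLassoModel:
    """Fit the fused-lasso logistic model by monotone accelerated prox-gradient.

    Iterates until the objective decrease stays below ``tol`` or ``max_iter``;
    both classes must be present in ``y``.
    """
    X, y = _check_xy(X, y)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to fit the classifier")
    S, n = X.shape
    L = np.linalg.norm(X, 2) ** 2 / (4.0 * S)
    step = 1.0 / max(L, 1e-12)
    ybar = np.clip(y.mean(), 1e-12, 1 - 1e-12)
    beta = np.zeros(n)
    beta0 = float(np.log(ybar / (1 - ybar)))
    obj = fl_objective(beta0, beta, X, y, lambda1, lambda2)
    history = [obj]
    z = beta.copy()
    beta_prev = beta.copy()
    t_mom = 1.0
    stall = 0
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        p = _sigmoid(beta0 + X @ z)
        grad = X.T @ (p - y) / S
        u = fused_prox(z - step * grad, step * lambda1, step * lambda2)
        b0_u = _newton_intercept(X @ u, y, beta0)
        obj_u = fl_objective(b0_u, u, X, y, lambda1, lambda2)
        # monotone step: keep the better of the prox point and the last iterate
        if obj_u <= obj:
            beta_new, b0_new, obj_new = u, b0_u, obj_u
        else:
            beta_new, b0_new, obj_new = beta, beta0, obj
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2))
        z = beta_new + (t_mom / t_new) * (u - beta_new) + ((t_mom - 1.0) / t_new) * (
            beta_new - beta_prev
        )
        decrease = obj - obj_new
        beta_prev, beta, beta0, obj, t_mom = beta, beta_new, b0_new, obj_new, t_new
        history.append(obj)
        if decrease < tol:
            stall += 1
            if stall >= 10:
                break
        else:
            stall = 0
    converged = n_iter < max_iter
    if not converged:
        import warnings

        warnings.warn(
            f"fused lasso did not converge in {max_iter} iterations "
            f"(last objective decrease {decrease:.3e})"
        )
    return FusedLassoModel(
        beta0=float(beta0),
        beta=beta,
        lambda1=lambda1,
        lambda2=lambda2,
        r_grid=None if r_grid is None else np.asarray(r_grid, float),
        n_iter=n_iter,
        converged=converged,
        objective_history=history,
    )


def cv_select(
    X,
    y,
    lambda1_grid,
    lambda2_grid,
    folds: int = 5,
    seed: int = 0,
    tol: float = 1e-7,
    max_iter: int = 2000,
):
    """Choose (lambda1, lambda2) by stratified 5-fold cross-validated accuracy.

    Ties are broken toward stronger regularization (larger lambda1 + lambda2,
    then larger lambda1).  Returns (lambda1, lambda2, table) where table rows
    are (lambda1, lambda2, mean accuracy).
    """
    X, y = _check_xy(X, y)
    if min(np.bincount(y.astype(int))) < folds:
        raise ValueError(f"each class needs at least {folds} tiles for {folds}-fold CV")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    table = []
    for l1 in lambda1_grid:
        for l2 in lambda2_grid:
            accs = []
            for tr, te in splits:
                model = fit_fused_lasso(X[tr], y[tr], l1, l2, tol=tol, max_iter=max_iter)
                pred = (model.predict_proba(X[te]) >= 0.5).astype(float)
                accs.append(np.mean(pred == y[te]))
            table.append((float(l1), float(l2), float(np.mean(accs))))
    best = max(table, key=lambda row: (row[2], row[0] + row[1], row[0]))
    return best[0], best[1], table


@dataclass
class TilePhenotype:
    """Classification outcome for one tile."""

    tile_id: int
    label: str
    probability: float | None = None  # P(inflamed), only for inflamed/excluded

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


def classify_tile(model: FusedLassoModel, features: LCurveFeatures, t: int = 5) -> TilePhenotype:
    """Phenotype one tile from its L-curve features.

    The deserted rule strictly precedes model evaluation: a tile with at most
    ``t`` immune cells is deserted regardless of the coefficients.  Tiles with
    fewer than 2 tumor cells are unclassifiable (the L curve is undefined
    without a tumor pattern to anchor it).
    """
    if features.n_j <= t:
        return TilePhenotype(tile_id=features.tile_id, label="deserted")
    if features.n_i < 2:
        return TilePhenotype(tile_id=features.tile_id, label="unclassifiable")
    if features.x is None or len(features.x) != len(model.beta):
        raise ValueError(
            f"feature length {None if features.x is None else len(features.x)} "
            f"does not match model dimension {len(model.beta)}"
        )
    p = float(_sigmoid(np.asarray([model.beta0 + model.beta @ features.x]))[0])
    label = "inflamed" if p >= 0.5 else "excluded"
    return TilePhenotype(tile_id=features.tile_id, label=label, probability=p)
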