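"""Two-component expression deconvolution, TIP gene signatures, predictor.

Bulk expression is modelled as a convex mixture of one immune and one cancer
prototype profile:

    X ~ X_hat = I * lambda^T + C * (1 - lambda)^T

where lambda_s is the per-sample immune cell fraction (taken from image cell
counts) and the prototypes I, C are probability vectors over genes
(non-negative, summing to 1).  The profiles are fit by constrained least
squares; the residual r_{g,s} = x_{g,s} - x_hat_{g,s} captures expression
variation not explained by cell-type composition.  Genes whose residuals
predict a TIP (no-intercept regression a_s = beta_g * r_{g,s}, Bonferroni
over all G tested genes) form the TIP's gene signature, and a radial-basis
support-vector regression on the signature genes predicts the TIP from
expression alone (cost 4, gamma 2**-10).

Before deconvolution the matrix is normalized first by samples (library-size
scaling to the mean column total) and then by genes: every gene is divided
by the square root of its mean, stabilizing the roughly Poisson
mean-variance relation of count data so that no highly expressed gene
dominates the quadratic fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import GridSearchCV
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .io import ExpressionMatrix


# ---------------------------------------------------------------------------
# Normalization and immune fractions
# ---------------------------------------------------------------------------

def normalize_expression(X: ExpressionMatrix) -> ExpressionMatrix:
    """Sample-then-gene normalization for deconvolution.

    Step 1 scales every sample column so its total equals the mean column
    total; step 2 divides every gene row by the square root of its
    (post-step-1) mean.  Genes with zero mean are dropped with a warning.
    """
    V = X.values
    if (V < 0).any():
        raise ValueError("expression values must be non-negative")
    totals = V.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("matrix contains an all-zero sample")
    V1 = V * (totals.mean() / totals)[None, :]
    means = V1.mean(axis=1)
    keep = means > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} gene(s) with zero mean")
    V2 = V1[keep] / np.sqrt(means[keep])[:, None]
    genes = [g for g, k in zip(X.genes, keep) if k]
    return ExpressionMatrix(genes, list(X.samples), V2)


def immune_fraction(counts: pd.DataFrame) -> np.ndarray:
    """lambda_s = (CD8 + CD4) / (tumor + CD8 + CD4) per sample.

    ``counts`` has one row per sample and columns tumor, CD8, CD4.
    """
    for col in ("tumor", "CD8", "CD4"):
        if col not in counts.columns:
            raise ValueError(f"counts needs a {col!r} column")
    tot = counts[["tumor", "CD8", "CD4"]].sum(axis=1).to_numpy(dtype=float)
    if (tot <= 0).any():
        raise ValueError("every sample needs a positive total cell count")
    imm = counts[["CD8", "CD4"]].sum(axis=1).to_numpy(dtype=float)
    return imm / tot


# ---------------------------------------------------------------------------
# Constrained mixture deconvolution
# ---------------------------------------------------------------------------

def project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the probability simplex (sorting algorithm)."""
    n = len(v)
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    rho = np.nonzero(u - css / np.arange(1, n + 1) > 0)[0][-1]
    theta = css[rho] / (rho + 1.0)
    return np.maximum(v - theta, 0.0)


@dataclass
class DeconvolutionResult:
    """Fitted two-component mixture of a normalized expression matrix."""

    genes: list[str]
    samples: list[str]
    immune_profile: np.ndarray     # I, simplex over genes
    cancer_profile: np.ndarray     # C, simplex over genes
    lam: np.ndarray                # per-sample immune fraction (input)
    fitted: np.ndarray             # X_hat = I lam^T + C (1-lam)^T
    residuals: np.ndarray          # R = X - X_hat
    objective: float               # squared Frobenius error
    kkt_residual: float
    identifiable: bool = True


def deconvolve(
    X: ExpressionMatrix,
    lam,
    kkt_tol: float = 1e-8,
    max_iter: int = 200000,
) -> DeconvolutionResult:
    """Fit simplex-constrained prototype profiles by accelerated projected gradient.

    Minimizes ||X - I lam^T - C (1-lam)^T||_F^2 subject to I and C lying on
    the gene simplex.  The problem is a convex QP; iterations stop when the
    projected-gradient (KKT) residual falls below ``kkt_tol``.
    """
    lam = np.asarray(lam, dtype=float).ravel()
    V = X.values
    G, S = V.shape
    if len(lam) != S:
        raise ValueError("lambda length must equal the number of samples")
    if (lam < 0).any() or (lam > 1).any():
        raise ValueError("lambda entries must lie in [0, 1]")
    identifiable = bool(np.var(lam) >= 1e-6)
    if not identifiable:
        warnings.warn(
            "immune fractions are (nearly) constant across samples; "
            "I and C are not identifiable (any split along the fitted line is optimal)"
        )
    mu = 1.0 - lam
    # Hessian of the per-gene quadratic is 2 * M for every gene
    M = np.array([[lam @ lam, lam @ mu], [lam @ mu, mu @ mu]])
    L = 2.0 * np.linalg.eigvalsh(M)[-1]
    step = 1.0 / L

    def grads(I, C):
        E = I[:, None] * lam[None, :] + C[:, None] * mu[None, :] - V
        return 2.0 * (E @ lam), 2.0 * (E @ mu), float(np.sum(E * E))

    def kkt(I, C, gI, gC):
        rI = I - project_simplex(I - gI)
        rC = C - project_simplex(C - gC)
        return max(np.abs(rI).max(), np.abs(rC).max())

    I = np.full(G, 1.0 / G)
    C = np.full(G, 1.0 / G)
    yI, yC = I.copy(), C.copy()
    t_mom = 1.0
    obj = np.inf
    kkt_res = np.inf
    for it in range(max_iter):
        gI, gC, _ = grads(yI, yC)
        I_new = project_simplex(yI - step * gI)
        C_new = project_simplex(yC - step * gC)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2))
        yI = I_new + ((t_mom - 1.0) / t_new) * (I_new - I)
        yC = C_new + ((t_mom - 1.0) / t_new) * (C_new - C)
        I, C, t_mom = I_new, C_new, t_new
        if it % 50 == 0 or it == max_iter - 1:
            gI, gC, obj = grads(I, C)
            kkt_res = kkt(I, C, gI, gC)
            if kkt_res < kkt_tol:
                break
    else:
        warnings.warn(f"deconvolution stopped at max_iter with KKT residual {kkt_res:.2e}")
    fitted = I[:, None] * lam[None, :] + C[:, None] * mu[None, :]
    residuals = V - fitted
    return DeconvolutionResult(
        genes=list(X.genes),
        samples=list(X.samples),
        immune_profile=I,
        cancer_profile=C,
        lam=lam,
        fitted=fitted,
        residuals=residuals,
        objective=float(np.sum(residuals**2)),
        kkt_residual=float(kkt_res),
        identifiable=identifiable,
    )


# ---------------------------------------------------------------------------
# TIP gene signatures
# ---------------------------------------------------------------------------

@dataclass
class GeneSignature:
    """Genes whose deconvolution residuals associate with a TIP."""

    tip_name: str
    table: pd.DataFrame  # columns: gene, beta, p_raw, significant, direction
    alpha: float
    n_tested: int

    @property
    def genes(self) -> list[str]:
        return list(self.table.loc[self.table["significant"], "gene"])


def signature_genes(
    residuals: np.ndarray,
    tip,
    genes: list[str] | None = None,
    alpha: float = 0.05,
    tip_name: str = "tip",
) -> GeneSignature:
    """No-intercept regression of the TIP on each gene's residuals.

    For gene g the model is a_s = beta_g * r_{g,s}; beta_g is tested against
    zero with a t statistic on S - 1 degrees of freedom, and genes passing
    the Bonferroni-corrected threshold (raw p * G < alpha, family size G =
    all tested genes) form the signature.  Zero-variance residual rows are
    skipped.
    """
    R = np.asarray(residuals, dtype=float)
    a = np.asarray(tip, dtype=float).ravel()
    G, S = R.shape
    if len(a) != S:
        raise ValueError("tip length must equal the number of samples")
    if S < 3:
        raise ValueError("need at least 3 samples")
    if genes is None:
        genes = [f"g{k}" for k in range(G)]
    ss_r = np.sum(R * R, axis=1)
    ok = ss_r > 0
    beta = np.zeros(G)
    pvals = np.ones(G)
    beta[ok] = (R[ok] @ a) / ss_r[ok]
    rss = np.sum((a[None, :] - beta[ok, None] * R[ok]) ** 2, axis=1)
    df = S - 1
    se = np.sqrt(np.maximum(rss, 0.0) / df / ss_r[ok])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta[ok] / se, np.inf * np.sign(beta[ok]))
    pvals[ok] = 2.0 * stats.t.sf(np.abs(tstat), df)
    n_tested = int(ok.sum())
    significant = ok & (pvals * n_tested < alpha)
    table = pd.DataFrame(
        {
            "gene": genes,
            "beta": beta,
            "p_raw": pvals,
            "significant": significant,
            "direction": np.where(beta > 0, "up", "down"),
        }
    )
    table = table[ok].reset_index(drop=True)
    return GeneSignature(tip_name=tip_name, table=table, alpha=alpha, n_tested=n_tested)


# ---------------------------------------------------------------------------
# TIP prediction from expression
# ---------------------------------------------------------------------------

@dataclass
class TipPredictor:
    """RBF support-vector regression of a TIP on signature-gene expression."""

    signature_genes: list[str]
    pipeline: Pipeline
    cost: float
    gamma: float
    train_score: float = np.nan


def fit_tip_predictor(
    expr: ExpressionMatrix,
    tip,
    signature: list[str] | GeneSignature,
    cost: float = 4.0,
    gamma: float = 0.0009765625,
    grid_search: bool = False,
    cv: int = 5,
) -> TipPredictor:
    """Train the TIP-from-expression predictor on signature genes.

    The response is the continuous TIP proportion, so an epsilon support
    vector regression with a radial-basis kernel is used; features are
    standardized inside the model.  ``grid_search=True`` tunes (cost, gamma)
    by cross-validation around the defaults.
    """
    genes = signature.genes if isinstance(signature, GeneSignature) else list(signature)
    if not genes:
        raise ValueError("signature is empty")
    tip = np.asarray(tip, dtype=float).ravel()
    if len(tip) != len(expr.samples):
        raise ValueError("tip length must equal the number of samples")
    if len(expr.samples) < 10:
        raise ValueError("need at least 10 samples to train the predictor")
    sub = expr.restrict(genes)
    F = sub.values.T  # samples x genes
    if grid_search:
        grid = {
            "svr__C": [cost / 4, cost, cost * 4],
            "svr__gamma": [gamma / 4, gamma, gamma * 4],
        }
        gs = GridSearchCV(
            Pipeline([("scale", StandardScaler()), ("svr", SVR(kernel="rbf"))]),
            grid,
            cv=cv,
        ).fit(F, tip)
        pipe = gs.best_estimator_
        cost = pipe.named_steps["svr"].C
        gamma = pipe.named_steps["svr"].gamma
    else:
        pipe = Pipeline(
            [("scale", StandardScaler()), ("svr", SVR(kernel="rbf", C=cost, gamma=gamma))]
        ).fit(F, tip)
    return TipPredictor(
        signature_genes=genes,
        pipeline=pipe,
        cost=float(cost),
        gamma=float(gamma),
        train_score=float(pipe.score(F, tip)),
    )


def predict_tip(model: TipPredictor, expr: ExpressionMatrix) -> np.ndarray:
    """Per-sample predicted TIP; all signature genes must be present."""
    missing = [g for g in model.signature_genes if g not in set(expr.genes)]
    if missing:
        raise KeyError(f"expression matrix is missing signature genes: {missing}")
    F = expr.restrict(model.signature_genes).values.T
    return model.pipeline.predict(F)
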