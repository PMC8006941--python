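"""Mutation/pathway associations with TIPs and biomarker-validation models.

Three layers:

* Pathway mutation scores: for patient i and pathway p, the fraction of the
  pathway's genes mutated in i.  Pathways are pre-filtered to those with at
  least 40% overlap with the sequencing panel; single genes to those mutated
  in at least 20% of patients.
* Lasso stability selection: the TIP (a continuous tile proportion) is
  regressed on mutation covariates with an L1 penalty on repeated random
  half-subsamples (200 runs); a covariate's selection frequency measures the
  robustness of its association.
* Biomarker validation: a base model (Age, stage >= IV, CD8 density, CD4
  density) is extended with TIP covariates; correlated TIPs (|rho| > 0.6)
  are pruned keeping the univariately stronger one, the extension is reduced
  by AIC forward-backward selection with the base forced in, and the final
  model is compared to the base by a likelihood-ratio test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LassoCV

from .io import MutationMatrix, PathwayCollection


# ---------------------------------------------------------------------------
# Pathway mutation scores and filters
# ---------------------------------------------------------------------------

@dataclass
class PathwayScores:
    """Patients x pathways matrix of pathway mutation scores in [0, 1]."""

    patients: list[str]
    pathways: list[str]
    values: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.patients, columns=self.pathways)


def pathway_mutation_score(mut: MutationMatrix, pathways: PathwayCollection) -> PathwayScores:
    """Score(i, p) = #mutated genes of patient i in pathway p / #genes in p.

    Pathway genes absent from the mutation panel count as unmutated but stay
    in the denominator.
    """
    gene_idx = {g: k for k, g in enumerate(mut.genes)}
    names = pathways.names()
    values = np.zeros((len(mut.patients), len(names)))
    for col, name in enumerate(names):
        genes = pathways[name]
        if not genes:
            raise ValueError(f"pathway {name!r} is empty")
        present = [gene_idx[g] for g in genes if g in gene_idx]
        if present:
            values[:, col] = mut.values[:, present].sum(axis=1) / len(genes)
    return PathwayScores(list(mut.patients), names, values)


def filter_mutations(mut: MutationMatrix, min_freq: float = 0.2) -> MutationMatrix:
    """Keep genes mutated in at least ``min_freq`` of patients (inclusive)."""
    if len(mut.patients) == 0:
        raise ValueError("mutation matrix has no patients")
    keep = mut.frequency() >= min_freq
    return MutationMatrix(
        patients=list(mut.patients),
        genes=[g for g, k in zip(mut.genes, keep) if k],
        values=mut.values[:, keep],
        tmb=mut.tmb,
    )


def filter_pathways(
    pathways: PathwayCollection, panel: list[str], min_overlap: float = 0.4
) -> PathwayCollection:
    """Keep pathways with |pathway ∩ panel| / |pathway| >= ``min_overlap``."""
    panel_set = set(panel)
    kept = {
        name: genes
        for name, genes in pathways.sets.items()
        if len(panel_set.intersection(genes)) / len(genes) >= min_overlap
    }
    return PathwayCollection(kept)


def median_split_test(scores, tip_values):
    """Wilcoxon rank-sum of a TIP between low/high score groups (median split).

    ``high`` is score strictly above the median.  Returns (statistic, p).
    """
    scores = np.asarray(scores, dtype=float)
    tip_values = np.asarray(tip_values, dtype=float)
    med = np.median(scores)
    high = scores > med
    if high.sum() < 2 or (~high).sum() < 2:
        raise ValueError("median split leaves a group with fewer than 2 samples")
    res = stats.mannwhitneyu(tip_values[high], tip_values[~high], alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Lasso stability selection
# ---------------------------------------------------------------------------

@dataclass
class StabilitySelectionResult:
    """Selection probability per covariate over subsampled lasso fits."""

    covariates: list[str]
    probability: np.ndarray
    n_runs: int
    subsample: float
    selected_sets: list[list[str]] = field(repr=False, default_factory=list)

    def to_series(self) -> pd.Series:
        return pd.Series(self.probability, index=self.covariates).sort_values(ascending=False)


def stability_selection(
    X,
    y,
    covariates: list[str] | None = None,
    n_runs: int = 200,
    subsample: float = 0.5,
    seed: int = 0,
    internal_cv: int = 5,
    n_alphas: int = 30,
) -> StabilitySelectionResult:
    """Selection probabilities from ``n_runs`` lasso fits on random subsamples.

    Per run, ceil(subsample * S) observations are drawn without replacement,
    covariates are standardized within the subsample, and an L1-penalized
    linear regression is fit with its penalty chosen by internal
    cross-validation; a covariate counts as selected when its coefficient is
    non-zero.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    S, P = X.shape
    if S < 10:
        raise ValueError("stability selection needs at least 10 observations")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if np.ptp(y) == 0:
        raise ValueError("response is constant")
    if covariates is None:
        covariates = [f"x{k}" for k in range(P)]
    m = int(np.ceil(subsample * S))
    rng = np.random.default_rng(seed)
    counts = np.zeros(P)
    selected_sets: list[list[str]] = []
    for _ in range(n_runs):
        idx = rng.choice(S, size=m, replace=False)
        Xs, ys = X[idx], y[idx]
        mu, sd = Xs.mean(axis=0), Xs.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (Xs - mu) / sd
        lcv = LassoCV(
            cv=internal_cv, alphas=n_alphas, random_state=0, max_iter=20000
        ).fit(Z, ys - ys.mean())
        sel = np.abs(lcv.coef_) > 1e-10
        counts += sel
        selected_sets.append([covariates[k] for k in np.nonzero(sel)[0]])
    return StabilitySelectionResult(
        covariates=list(covariates),
        probability=counts / n_runs,
        n_runs=n_runs,
        subsample=subsample,
        selected_sets=selected_sets,
    )


# ---------------------------------------------------------------------------
# Biomarker validation regressions
# ---------------------------------------------------------------------------

_FAMILIES = {
    "gaussian": sm.families.Gaussian,
    "binomial": sm.families.Binomial,
}


def _glm_fit(y, X, family):
    fam = _FAMILIES[family]()
    return sm.GLM(y, X, family=fam).fit()


@dataclass
class UnivariateFit:
    coefficient: float
    std_error: float
    deviance: float
    llf: float
    separation_flag: bool = False


def univariate_assoc(tip, endpoint, family: str = "gaussian") -> UnivariateFit:
    """Single-covariate GLM of an endpoint on one TIP."""
    tip = np.asarray(tip, dtype=float)
    endpoint = np.asarray(endpoint, dtype=float)
    if len(tip) != len(endpoint):
        raise ValueError("tip and endpoint lengths differ")
    if family == "binomial" and not np.isin(endpoint, (0, 1)).all():
        raise ValueError("binomial endpoint must be binary 0/1")
    X = sm.add_constant(tip)
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res = _glm_fit(endpoint, X, family)
        separation = any("erfectSeparation" in str(type(w.message)) or "separat" in str(w.message).lower() for w in caught)
    if family == "binomial" and np.abs(res.params[1]) > 50:
        separation = True
    return UnivariateFit(
        coefficient=float(res.params[1]),
        std_error=float(res.bse[1]),
        deviance=float(res.deviance),
        llf=float(res.llf),
        separation_flag=separation,
    )


def prune_correlated_tips(tips: pd.DataFrame, endpoint, family: str = "gaussian",
                          cutoff: float = 0.6) -> list[str]:
    """Drop TIP covariates correlated (|rho| > cutoff) with a stronger one.

    Greedy: TIPs are ranked by univariate deviance (lower = better); each TIP
    is kept only if it is not correlated above ``cutoff`` with an
    already-kept TIP.
    """
    if tips.shape[1] == 0:
        return []
    deviances = {
        name: univariate_assoc(tips[name].to_numpy(), endpoint, family).deviance
        for name in tips.columns
    }
    order = sorted(tips.columns, key=lambda n: deviances[n])
    corr = tips.corr().abs()
    kept: list[str] = []
    for name in order:
        if all(corr.loc[name, other] <= cutoff for other in kept):
            kept.append(name)
    return kept


@dataclass
class BiomarkerModelReport:
    """Base vs TIP-extended GLM comparison."""

    base_covariates: list[str]
    retained_tips: list[str]
    coefficients: pd.DataFrame       # term, estimate, ci_low, ci_high
    llf_base: float
    llf_extended: float
    lr_statistic: float
    lr_df: int
    lr_pvalue: float
    aic_extended: float


def stepwise_extend(
    base: pd.DataFrame,
    tips: pd.DataFrame,
    endpoint,
    family: str = "gaussian",
) -> BiomarkerModelReport:
    """Extend the forced-in base model with TIPs by AIC forward-backward.

    Base covariates are never eligible for removal.  The final extended model
    is compared with the base model by a likelihood-ratio chi-square test
    with df = number of retained TIP terms.
    """
    endpoint = np.asarray(endpoint, dtype=float)
    base_X = sm.add_constant(base)
    base_fit = _glm_fit(endpoint, base_X, family)

    def fit_with(tip_names):
        X = pd.concat([base_X, tips[list(tip_names)]], axis=1) if tip_names else base_X
        return _glm_fit(endpoint, X, family)

    current: list[str] = []
    current_fit = base_fit
    improved = True
    while improved:
        improved = False
        moves = []
        for name in tips.columns:
            if name not in current:
                moves.append(("add", name, current + [name]))
        for name in current:
            moves.append(("drop", name, [n for n in current if n != name]))
        best = (current_fit.aic, None, current, current_fit)
        for _, name, cand in moves:
            fit = fit_with(cand)
            if fit.aic < best[0] - 1e-10:
                best = (fit.aic, name, cand, fit)
        if best[1] is not None:
            current, current_fit = best[2], best[3]
            improved = True

    lr_df = len(current)
    lr_stat = max(0.0, 2.0 * (current_fit.llf - base_fit.llf))
    lr_p = 1.0 if lr_df == 0 else float(stats.chi2.sf(lr_stat, lr_df))
    ci = current_fit.conf_int()
    coefficients = pd.DataFrame(
        {
            "term": list(current_fit.params.index),
            "estimate": current_fit.params.to_numpy(),
            "ci_low": np.asarray(ci)[:, 0],
            "ci_high": np.asarray(ci)[:, 1],
        }
    )
    return BiomarkerModelReport(
        base_covariates=list(base.columns),
        retained_tips=current,
        coefficients=coefficients,
        llf_base=float(base_fit.llf),
        llf_extended=float(current_fit.llf),
        lr_statistic=float(lr_stat),
        lr_df=lr_df,
        lr_pvalue=lr_p,
        aic_extended=float(current_fit.aic),
    )
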