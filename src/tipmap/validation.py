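"""End-to-end validation experiments on synthetic data with known truth.

Each function runs one self-contained experiment — rule boundaries, oracle
comparisons, null calibrations, planted-truth recoveries — and returns the
measured quantities.  They are used both by the test suite and by the
reproduction script, and exist in the package so that the checks can be
rerun on any installation.
"""

from __future__ import annotations

import warnings

import numpy as np
import shapely
import shapely.geometry as sgeom

from .aggregate import classify_tiles, sample_tips
from .deconv import deconvolve, fit_tip_predictor, predict_tip, signature_genes
from .fusedlasso import cv_select, fit_fused_lasso
from .genomics import stability_selection
from .io import CellTable, Config, ExpressionMatrix, MutationMatrix, PathwayCollection, TissueWindow
from .simulate import (
    TileParams,
    _sample_in_polygon,
    planted_residuals,
    simulate_expression,
    simulate_mutations,
    simulate_sample,
    simulate_tile,
)
from .spatial import cross_k, iso_correction_weight, l_feature_vector
from .tessellation import SQRT3, build_tiles, hexagon


def derive_seed(seed: int, tag: int) -> int:
    """Deterministic sub-seed below 2**31 for experiment ``tag``."""
    return int(np.random.SeedSequence([int(seed), int(tag)]).generate_state(1)[0] % (2**31))


def _aligned_offset(edge: float) -> tuple[float, float]:
    return (edge, SQRT3 / 2.0 * edge)


def featurize_synthetic_tile(label: str, seed: int, config: Config,
                             params: TileParams | None = None, immune_type: str = "CD8"):
    """Generate one labeled tile and run it through the full spatial pipeline."""
    params = params or TileParams()
    cells = simulate_tile(label, params, seed=seed)
    window = TissueWindow(hexagon((0.0, 0.0), params.edge))
    tiles, _ = build_tiles(
        cells, window, edge=params.edge, offset=_aligned_offset(params.edge),
        subhex_edge=config.subhex_edge, subhex_min_cells=config.subhex_min_cells,
    )
    tile = max(tiles, key=lambda t: t.n_cells())
    return tile, l_feature_vector(tile, immune_type, config)


def train_synthetic_classifier(seed: int, config: Config, n_per_class: int = 30):
    """Fused-lasso tile classifier trained on simulated inflamed/excluded tiles."""
    feats = []
    for k in range(n_per_class):
        feats.append(featurize_synthetic_tile("inflamed", derive_seed(seed, 10_000 + k), config)[1])
    for k in range(n_per_class):
        feats.append(featurize_synthetic_tile("excluded", derive_seed(seed, 20_000 + k), config)[1])
    X = np.array([f.x for f in feats])
    y = np.r_[np.ones(n_per_class), np.zeros(n_per_class)]
    return fit_fused_lasso(X, y, 0.01, 0.001, r_grid=config.r_grid)


# ---------------------------------------------------------------------------
# Deserted-rule boundary
# ---------------------------------------------------------------------------

def deserted_rule_boundary(model, config: Config, k_max: int = 12, seed: int = 0) -> int:
    """Sweep tiles with k = 0..k_max immune cells; return the largest k
    classified deserted (the rule threshold)."""
    params = TileParams()
    window = TissueWindow(hexagon((0.0, 0.0), params.edge))
    max_deserted = -1
    for k in range(k_max + 1):
        rng = np.random.default_rng(derive_seed(seed, 30_000 + k))
        hexa = hexagon((0.0, 0.0), params.edge)
        tum = _sample_in_polygon(hexa, 120, rng)
        # immune cells sit next to tumor cells so the count is exactly k and
        # no immune cell is lost to the sparse-area exclusion
        imm = np.empty((0, 2))
        while len(imm) < k:
            cand = tum[rng.integers(0, len(tum), k)] + rng.normal(0, 5.0, (k, 2))
            ok = shapely.contains_xy(hexa, cand[:, 0], cand[:, 1])
            imm = np.vstack([imm, cand[ok]])
        imm = imm[:k]
        cells = CellTable(
            "sweep",
            np.r_[tum[:, 0], imm[:, 0]],
            np.r_[tum[:, 1], imm[:, 1]],
            np.r_[np.full(len(tum), "tumor"), np.full(k, "CD8")].astype(object),
        )
        tiles, _ = build_tiles(
            cells, window, edge=params.edge, offset=_aligned_offset(params.edge),
            subhex_edge=config.subhex_edge, subhex_min_cells=config.subhex_min_cells,
        )
        tile = max(tiles, key=lambda t: t.n_cells())
        label = classify_tiles([tile], model, "CD8", config)[0].label
        if label == "deserted":
            max_deserted = max(max_deserted, k)
    return max_deserted


# ---------------------------------------------------------------------------
# Spatial oracle and CSR calibration
# ---------------------------------------------------------------------------

def naive_cross_k(points_i, points_j, window, r_grid) -> np.ndarray:
    """Literal double-sum reference estimator (pure loops, per-pair weights)."""
    area = window.area
    n_i, n_j = len(points_i), len(points_j)
    k = np.zeros(len(r_grid))
    for a, r in enumerate(r_grid):
        total = 0.0
        for u in points_i:
            for v in points_j:
                d = float(np.hypot(u[0] - v[0], u[1] - v[1]))
                if 0.0 < d <= r:
                    total += iso_correction_weight(u, v, window)
        k[a] = area / (n_i * n_j) * total
    return k


def spatial_oracle_check(seed: int = 0, n_patterns: int = 50) -> dict:
    """Edge-corrected cross-K vs the naive reference; analytic half-plane weight."""
    rng = np.random.default_rng(derive_seed(seed, 40_000))
    win = hexagon((0.0, 0.0), 375.0)
    r_grid = np.linspace(20, 338, 6)
    max_rel = 0.0
    for _ in range(n_patterns):
        pi = _sample_in_polygon(win, int(rng.integers(2, 51)), rng)
        pj = _sample_in_polygon(win, int(rng.integers(2, 51)), rng)
        fast = cross_k(pi, pj, win, r_grid).k
        ref = naive_cross_k(pi, pj, win, r_grid)
        nz = ref > 0
        if nz.any():
            max_rel = max(max_rel, float(np.max(np.abs(fast[nz] - ref[nz]) / ref[nz])))
    big = sgeom.box(0, 0, 10000, 10000)
    w_half = iso_correction_weight((5000.0, 0.0), (5000.0, 100.0), big)
    return {"max_rel_err": max_rel, "halfplane_weight": float(w_half)}


def csr_calibration(seed: int = 0, n_sims: int = 200,
                    radii=(50.0, 100.0, 200.0), n_points: int = 100) -> dict:
    """Mean of L(r) - r over CSR simulations in a 375 um hexagon, with the
    Monte-Carlo standard error of that mean."""
    win = hexagon((0.0, 0.0), 375.0)
    r_grid = np.asarray(radii, dtype=float)
    rng = np.random.default_rng(derive_seed(seed, 50_000))
    devs = np.empty((n_sims, len(r_grid)))
    for s in range(n_sims):
        pi = _sample_in_polygon(win, n_points, rng)
        pj = _sample_in_polygon(win, n_points, rng)
        devs[s] = cross_k(pi, pj, win, r_grid).l - r_grid
    mean = devs.mean(axis=0)
    se = devs.std(axis=0, ddof=1) / np.sqrt(n_sims)
    return {
        "radii": list(r_grid),
        "mean_dev": list(mean),
        "mc_se": list(se),
        "abs_z": list(np.abs(mean) / se),
    }


# ---------------------------------------------------------------------------
# Fused-lasso solver benchmarks
# ---------------------------------------------------------------------------

def separable_curves(seed: int, S: int = 118, n: int = 50):
    """Balanced synthetic L-curve features with a planted step-shaped class
    difference (mimicking aggregation vs segregation signals)."""
    rng = np.random.default_rng(seed)
    y = np.r_[np.ones(S // 2), np.zeros(S - S // 2)]
    r = np.linspace(1, 338, n)
    step = 12.0 * ((r > 30) & (r < 150))
    X = np.empty((S, n))
    for s in range(S):
        smooth = np.cumsum(rng.normal(0, 1.0, n))
        X[s] = smooth + rng.normal(0, 2.0, n) + (2 * y[s] - 1) * step / 2.0
    return X, y


def fused_lasso_benchmarks(seed: int = 0) -> dict:
    """Solver checks: IRLS agreement, penalty limits, CV accuracy on
    separable synthetic curves."""
    import statsmodels.api as sm

    rng = np.random.default_rng(derive_seed(seed, 60_000))
    S, n = 200, 10
    X = rng.normal(size=(S, n))
    beta = rng.normal(size=n) * 0.5
    p = 1 / (1 + np.exp(-(0.3 + X @ beta)))
    y = (rng.uniform(size=S) < p).astype(float)
    m0 = fit_fused_lasso(X, y, 0.0, 0.0, tol=1e-12, max_iter=20000)
    irls = sm.GLM(y, sm.add_constant(X), family=sm.families.Binomial()).fit()
    irls_diff = float(np.abs(np.r_[m0.beta0, m0.beta] - irls.params).max())
    fusion_spread = float(np.ptp(fit_fused_lasso(X, y, 1e6, 0.0).beta))
    sparsity_norm = float(np.abs(fit_fused_lasso(X, y, 0.0, 1e6).beta).max())

    Xc, yc = separable_curves(derive_seed(seed, 61_000))
    l1, l2, table = cv_select(
        Xc, yc, [0.001, 0.01, 0.1], [0.0005, 0.005], seed=derive_seed(seed, 62_000)
    )
    cv_acc = max(row[2] for row in table if (row[0], row[1]) == (l1, l2))
    return {
        "irls_max_coef_diff": irls_diff,
        "fusion_limit_spread": fusion_spread,
        "sparsity_limit_norm": sparsity_norm,
        "cv_accuracy": float(cv_acc),
        "selected_penalties": (l1, l2),
    }


# ---------------------------------------------------------------------------
# End-to-end TIP recovery
# ---------------------------------------------------------------------------

def tip_recovery(seed: int = 0, config: Config | None = None, model=None) -> dict:
    """Recover planted (0.7, 0.3, 0) proportions on a ~100-tile sample."""
    config = config or Config()
    if model is None:
        model = train_synthetic_classifier(derive_seed(seed, 70_000), config)
    cells, window, truth = simulate_sample(
        (0.7, 0.3, 0.0), grid=(10, 10), seed=derive_seed(seed, 71_000)
    )
    res = sample_tips(cells, window, {"CD8": model}, config)
    sums = [sum(d.proportions.values()) for d in res.per_shift["tumor:CD8"]]
    return {
        "true_inflamed": 0.7,
        "recovered_inflamed": res.proportions["tumor:CD8"]["inflamed"],
        "recovered_excluded": res.proportions["tumor:CD8"]["excluded"],
        "max_proportion_sum_err": float(np.max(np.abs(np.asarray(sums) - 1.0))),
        "n_placements": len(res.per_shift["tumor:CD8"]),
    }


def shift_averaging_variance(seed: int = 0, config: Config | None = None,
                             model=None, n_anchors: int = 20) -> dict:
    """Variance of the inflamed TIP across random grid anchors, with and
    without the 5-placement averaging, on one fixed small synthetic sample."""
    config = config or Config()
    if model is None:
        model = train_synthetic_classifier(derive_seed(seed, 70_000), config)
    params = TileParams(mu_tumor=40, mu_immune=40)
    cells, window, _ = simulate_sample(
        (0.6, 0.4, 0.0), grid=(4, 4), params=params, seed=derive_seed(seed, 72_000)
    )
    rng = np.random.default_rng(derive_seed(seed, 73_000))
    single, averaged = [], []
    e = config.tile_edge
    for _ in range(n_anchors):
        base = (float(rng.uniform(0, 1.5 * e)), float(rng.uniform(0, SQRT3 * e)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = sample_tips(cells, window, {"CD8": model}, config,
                            base_offset=base, shifts=False)
            a = sample_tips(cells, window, {"CD8": model}, config,
                            base_offset=base, shifts=True)
        single.append(s.proportions["tumor:CD8"]["inflamed"])
        averaged.append(a.proportions["tumor:CD8"]["inflamed"])
    return {
        "var_single_grid": float(np.var(single, ddof=1)),
        "var_shift_averaged": float(np.var(averaged, ddof=1)),
    }


# ---------------------------------------------------------------------------
# Deconvolution, signatures, stability selection, pathway scores
# ---------------------------------------------------------------------------

def deconvolution_benchmark(seed: int = 0) -> dict:
    """Noiseless G=200, S=30 mixture recovery plus the degeneracy flag."""
    expr, _, truth = simulate_expression(G=200, S=30, seed=derive_seed(seed, 80_000))
    res = deconvolve(expr, truth.lam)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        degenerate = deconvolve(
            ExpressionMatrix(expr.genes, expr.samples, expr.values), np.full(30, 0.3)
        )
    flagged = (not degenerate.identifiable) and any(
        "identifiable" in str(w.message) for w in caught
    )
    return {
        "objective": res.objective,
        "max_immune_err": float(np.abs(res.immune_profile - truth.immune_profile).max()),
        "max_cancer_err": float(np.abs(res.cancer_profile - truth.cancer_profile).max()),
        "immune_sum_err": float(abs(res.immune_profile.sum() - 1.0)),
        "cancer_sum_err": float(abs(res.cancer_profile.sum() - 1.0)),
        "min_entry": float(min(res.immune_profile.min(), res.cancer_profile.min())),
        "constant_lambda_flagged": bool(flagged),
    }


def signature_benchmark(seed: int = 0) -> dict:
    """Planted 30-of-2000 signature recovery and held-out SVR prediction."""
    R, a, truth = planted_residuals(G=2000, S=40, n_signature=30,
                                    seed=derive_seed(seed, 81_000))
    sig = signature_genes(R, a)
    found = set(sig.genes)
    planted = set(truth.signature_genes)
    recall = len(found & planted) / len(planted)
    fp = len(found - planted)

    R2, a2, truth2 = planted_residuals(G=2000, S=150, n_signature=30,
                                       seed=derive_seed(seed, 82_000))
    genes = [f"g{k}" for k in range(2000)]
    samples = [f"s{k}" for k in range(150)]
    train = ExpressionMatrix(genes, samples[:100], R2[:, :100])
    test = ExpressionMatrix(genes, samples[100:], R2[:, 100:])
    model = fit_tip_predictor(train, a2[:100], truth2.signature_genes)
    pred = predict_tip(model, test)
    r = float(np.corrcoef(pred, a2[100:])[0, 1])
    return {"recall": recall, "false_positives": fp, "svr_heldout_pearson_r": r}


def stability_benchmark(seed: int = 0, n_reps: int = 20, n_runs: int = 200) -> dict:
    """Rate at which a planted mutation attains the top selection probability.

    60 patients, 19 binary covariates (mutation frequency 0.3), one covariate
    shifting the response by one response standard deviation.
    """
    # effect in noise-sd units such that the shift equals 1.0 * sd(y):
    # e = sigma / sqrt(1 - p(1-p)) with p = 0.3
    effect = 1.0 / np.sqrt(1.0 - 0.3 * 0.7)
    wins = 0
    margins = []
    for rep in range(n_reps):
        mut, tip, _ = simulate_mutations(
            S=60, genes=19, planted={"gene7": effect}, seed=derive_seed(seed, 90_000 + rep)
        )
        res = stability_selection(
            mut.values, tip, covariates=mut.genes, n_runs=n_runs,
            seed=derive_seed(seed, 91_000 + rep),
        )
        s = res.to_series()
        margins.append(float(s["gene7"] - s.drop("gene7").max()))
        wins += margins[-1] > 0
    return {"top_rate": wins / n_reps, "mean_margin": float(np.mean(margins))}


def pathway_score_checks() -> dict:
    """Closed-form pathway score cases and the inclusive filter boundaries."""
    from .genomics import filter_mutations, filter_pathways, pathway_mutation_score

    genes = [f"g{k}" for k in range(10)]
    mut = MutationMatrix(
        ["p0", "p1", "p2"],
        genes,
        np.vstack([
            np.r_[np.ones(2), np.zeros(8)],   # 2/10 mutated
            np.zeros(10),                      # none
            np.ones(10),                       # all
        ]).astype(int),
    )
    scores = pathway_mutation_score(mut, PathwayCollection({"p": genes})).values[:, 0]

    freq_matrix = np.zeros((10, 2), dtype=int)
    freq_matrix[:2, 0] = 1  # exactly 20%
    freq_matrix[:1, 1] = 1  # 10%
    kept_genes = filter_mutations(
        MutationMatrix([f"q{k}" for k in range(10)], ["at20", "at10"], freq_matrix)
    ).genes

    panel = genes[:4]
    pw = PathwayCollection({
        "at40": panel + [f"x{k}" for k in range(6)],
        "at30": panel[:3] + [f"y{k}" for k in range(7)],
    })
    kept_paths = filter_pathways(pw, panel).names()
    return {
        "score_two_of_ten": float(scores[0]),
        "score_none": float(scores[1]),
        "score_all": float(scores[2]),
        "gene_at_20pct_kept": "at20" in kept_genes,
        "gene_at_10pct_dropped": "at10" not in kept_genes,
        "pathway_at_40pct_kept": "at40" in kept_paths,
        "pathway_at_30pct_dropped": "at30" not in kept_paths,
    }
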