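"""Seeded generators for every input of the pipeline, with known ground truth.

Tile-level point patterns realize the three infiltration phenotypes:

* *inflamed* — tumor and immune offspring share the parents of a Thomas
  (Poisson-cluster) process, so the two types co-localize;
* *excluded* — tumor clusters live in one half of the hexagon and immune
  clusters in the complementary half, so the types occupy disjoint areas;
* *deserted* — an arbitrary tumor pattern with at most 5 immune cells.

Sample-level, expression and mutation generators compose these primitives
into full synthetic studies whose planted truth is returned alongside the
data.  Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
import shapely.geometry as sgeom

from .io import CellTable, ExpressionMatrix, MutationMatrix, TissueWindow
from .tessellation import hexagon, hex_tessellate, SQRT3

PHENOTYPES = ("inflamed", "excluded", "deserted")


@dataclass
class TileParams:
    """Point-process parameters for one synthetic tile.

    Counts are Poisson; offspring scatter around cluster parents with an
    isotropic Gaussian of standard deviation ``cluster_sd`` (um).
    """

    mu_tumor: float = 60.0
    mu_immune: float = 60.0
    cluster_sd: float = 20.0
    n_parents: int = 5
    edge: float = 375.0


@dataclass
class SimulationTruth:
    """Ground truth of a synthetic dataset (fully determined by the seed)."""

    seed: int
    tile_labels: dict = field(default_factory=dict)
    tip_proportions: dict = field(default_factory=dict)
    immune_profile: np.ndarray | None = None
    cancer_profile: np.ndarray | None = None
    lam: np.ndarray | None = None
    signature_genes: list = field(default_factory=list)
    signature_effect: float | None = None
    planted_mutations: dict = field(default_factory=dict)


def _sample_in_polygon(poly, n, rng, predicate=None):
    """Rejection-sample n points uniformly in poly (optionally also predicate)."""
    minx, miny, maxx, maxy = poly.bounds
    out = np.empty((0, 2))
    shapely.prepare(poly)
    while len(out) < n:
        m = max(4 * (n - len(out)), 16)
        cand = np.column_stack(
            [rng.uniform(minx, maxx, m), rng.uniform(miny, maxy, m)]
        )
        ok = shapely.contains_xy(poly, cand[:, 0], cand[:, 1])
        if predicate is not None:
            ok &= predicate(cand)
        out = np.vstack([out, cand[ok]])
    return out[:n]


def _thomas_points(poly, parents, n, sd, rng, predicate=None):
    """n offspring around uniformly chosen parents, resampled into poly."""
    pts = np.empty((0, 2))
    shapely.prepare(poly)
    while len(pts) < n:
        m = max(2 * (n - len(pts)), 8)
        par = parents[rng.integers(0, len(parents), m)]
        cand = par + rng.normal(0.0, sd, size=(m, 2))
        ok = shapely.contains_xy(poly, cand[:, 0], cand[:, 1])
        if predicate is not None:
            ok &= predicate(cand)
        pts = np.vstack([pts, cand[ok]])
    return pts[:n]


def simulate_tile(
    phenotype: str,
    params: TileParams | None = None,
    seed: int = 0,
    center: tuple[float, float] = (0.0, 0.0),
    sample_id: str = "tile",
) -> CellTable:
    """One synthetic tile's cells inside a flat-top hexagon at ``center``."""
    if phenotype not in PHENOTYPES:
        raise ValueError(f"unknown phenotype {phenotype!r}")
    params = params or TileParams()
    rng = np.random.default_rng(seed)
    hexa = hexagon(center, params.edge)
    cx = center[0]
    n_tum = int(rng.poisson(params.mu_tumor))
    n_imm = int(rng.poisson(params.mu_immune))

    if phenotype == "deserted":
        n_imm = int(rng.integers(0, 6))  # at most 5 immune cells by construction
        parents = _sample_in_polygon(hexa, max(params.n_parents, 1), rng)
        tum = _thomas_points(hexa, parents, n_tum, params.cluster_sd, rng)
        imm = _sample_in_polygon(hexa, n_imm, rng)
    elif phenotype == "inflamed":
        parents = _sample_in_polygon(hexa, max(params.n_parents, 1), rng)
        tum = _thomas_points(hexa, parents, n_tum, params.cluster_sd, rng)
        imm = _thomas_points(hexa, parents, n_imm, params.cluster_sd, rng)
    else:  # excluded: disjoint half-hexagon supports
        left = lambda pts: pts[:, 0] < cx
        right = lambda pts: pts[:, 0] >= cx
        par_t = _sample_in_polygon(hexa, max(params.n_parents, 1), rng, predicate=left)
        par_i = _sample_in_polygon(hexa, max(params.n_parents, 1), rng, predicate=right)
        tum = _thomas_points(hexa, par_t, n_tum, params.cluster_sd, rng, predicate=left)
        imm = _thomas_points(hexa, par_i, n_imm, params.cluster_sd, rng, predicate=right)

    # immune cells split between CD8 and CD4
    is_cd8 = rng.uniform(size=len(imm)) < 0.5
    x = np.concatenate([tum[:, 0], imm[:, 0]])
    y = np.concatenate([tum[:, 1], imm[:, 1]])
    ct = np.concatenate(
        [
            np.full(len(tum), "tumor", dtype=object),
            np.where(is_cd8, "CD8", "CD4").astype(object),
        ]
    )
    return CellTable(sample_id=sample_id, x=x, y=y, cell_type=ct)


def _exact_multinomial(proportions, n, rng):
    """Largest-remainder apportionment of n tiles, then a seeded shuffle."""
    props = np.asarray(proportions, dtype=float)
    if props.min() < 0 or abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must lie on the simplex")
    raw = props * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    labels = np.repeat(np.arange(len(props)), counts)
    rng.shuffle(labels)
    return [PHENOTYPES[k] for k in labels]


def simulate_sample(
    proportions=(0.7, 0.3, 0.0),
    grid: tuple[int, int] = (10, 10),
    params: TileParams | None = None,
    seed: int = 0,
    sample_id: str = "synthetic",
) -> tuple[CellTable, TissueWindow, SimulationTruth]:
    """A full synthetic sample with planted per-tile phenotypes.

    A rectangular region is tessellated with the standard grid (anchored at
    its lower-left corner); every tile of that tessellation receives a
    phenotype by exact multinomial rounding of ``proportions`` (inflamed,
    excluded, deserted) and is populated with the matching point pattern.
    """
    params = params or TileParams()
    rng = np.random.default_rng(seed)
    rows, cols = grid
    if rows * cols < 10:
        import warnings

        warnings.warn("grid smaller than 10 tiles; proportions will be coarse")
    e = params.edge
    window = TissueWindow(
        sgeom.box(0.0, 0.0, 1.5 * e * (cols - 1) + e * 0.75, SQRT3 * e * (rows - 0.5))
    )
    tiles = hex_tessellate(window, e, offset=(0.0, 0.0))
    labels = _exact_multinomial(proportions, len(tiles), rng)
    xs, ys, cts = [], [], []
    truth = SimulationTruth(seed=seed)
    for tile, label in zip(tiles, labels):
        truth.tile_labels[tile.tile_id] = label
        c = tile.raw_hexagon.centroid
        t = simulate_tile(
            label, params, seed=int(rng.integers(0, 2**31 - 1)), center=(c.x, c.y)
        )
        pts = t.coords()
        inside = shapely.contains_xy(window.geometry, pts[:, 0], pts[:, 1])
        xs.append(t.x[inside])
        ys.append(t.y[inside])
        cts.append(t.cell_type[inside])
    truth.tip_proportions = dict(zip(PHENOTYPES, np.asarray(proportions, float)))
    cells = CellTable(
        sample_id=sample_id,
        x=np.concatenate(xs),
        y=np.concatenate(ys),
        cell_type=np.concatenate(cts),
    )
    return cells, window, truth


def simulate_expression(
    G: int = 200,
    S: int = 30,
    lambda_range: tuple[float, float] = (0.05, 0.6),
    n_signature: int = 0,
    signature_effect: float = 1.5,
    noise_sd: float = 0.0,
    tip_noise: float = 0.05,
    seed: int = 0,
) -> tuple[ExpressionMatrix, np.ndarray, SimulationTruth]:
    """Expression as a convex mixture of two prototypes plus planted signal.

    Prototypes I*, C* are drawn from a Dirichlet over G genes; lambda_s is
    uniform on ``lambda_range`` and the TIP a_s is lambda_s plus Gaussian
    jitter, clipped to [0, 1].  The first ``n_signature`` genes carry a
    planted residual ``signature_effect * a_s`` (in units of the mean
    expression level 1/G); Gaussian noise with ``noise_sd`` (same units) is
    added everywhere.  Values are clipped at zero.
    """
    if G < 50 or S < 10:
        raise ValueError("need G >= 50 and S >= 10")
    lo, hi = lambda_range
    if not (0 <= lo <= hi <= 1):
        raise ValueError("lambda_range must lie inside [0, 1]")
    rng = np.random.default_rng(seed)
    I = rng.dirichlet(np.full(G, 5.0))
    C = rng.dirichlet(np.full(G, 5.0))
    lam = rng.uniform(lo, hi, S)
    tip = np.clip(lam + rng.normal(0.0, tip_noise, S), 0.0, 1.0)
    X = I[:, None] * lam[None, :] + C[:, None] * (1.0 - lam)[None, :]
    scale = 1.0 / G  # planted effects expressed in units of the mean level
    sig_genes = list(range(n_signature))
    if n_signature:
        X[:n_signature] += signature_effect * scale * tip[None, :]
    if noise_sd > 0:
        X += rng.normal(0.0, noise_sd * scale, size=(G, S))
        X = np.clip(X, 0.0, None)
    genes = [f"g{k}" for k in range(G)]
    samples = [f"s{k}" for k in range(S)]
    truth = SimulationTruth(
        seed=seed,
        immune_profile=I,
        cancer_profile=C,
        lam=lam,
        signature_genes=[genes[k] for k in sig_genes],
        signature_effect=signature_effect,
    )
    return ExpressionMatrix(genes, samples, X), tip, truth


def planted_residuals(
    G: int = 2000,
    S: int = 40,
    n_signature: int = 30,
    effect: float = 1.5,
    noise_signature: float = 0.3,
    noise_null: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, SimulationTruth]:
    """Residual matrix with a planted TIP association in the first genes.

    Signature rows are r_g = effect * a + noise(noise_signature); the rest
    are pure noise(noise_null).  The TIP a is uniform on [0, 1].
    """
    rng = np.random.default_rng(seed)
    a = rng.uniform(0.0, 1.0, S)
    R = rng.normal(0.0, noise_null, size=(G, S))
    R[:n_signature] = effect * a[None, :] + rng.normal(
        0.0, noise_signature, size=(n_signature, S)
    )
    truth = SimulationTruth(
        seed=seed,
        signature_genes=[f"g{k}" for k in range(n_signature)],
        signature_effect=effect,
    )
    return R, a, truth


def simulate_mutations(
    S: int = 60,
    genes: list[str] | int = 19,
    planted: dict[str, float] | None = None,
    base_freq: float = 0.3,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[MutationMatrix, np.ndarray, SimulationTruth]:
    """Binary mutation matrix with planted effects on a continuous TIP.

    Mutations are Bernoulli(``base_freq``); the TIP response is the sum of
    planted effects over mutated genes plus Gaussian noise (sd
    ``noise_sd``), i.e. effects are in noise-standard-deviation units.
    """
    if not 0 < base_freq < 1:
        raise ValueError("base_freq must be in (0, 1)")
    if isinstance(genes, int):
        genes = [f"gene{k}" for k in range(genes)]
    planted = planted or {}
    unknown = set(planted) - set(genes)
    if unknown:
        raise ValueError(f"planted genes not in panel: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    V = (rng.uniform(size=(S, len(genes))) < base_freq).astype(int)
    tip = rng.normal(0.0, noise_sd, S)
    for g, eff in planted.items():
        tip = tip + eff * noise_sd * V[:, genes.index(g)]
    mat = MutationMatrix([f"p{k}" for k in range(S)], list(genes), V)
    truth = SimulationTruth(seed=seed, planted_mutations=dict(planted))
    return mat, tip, truth
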