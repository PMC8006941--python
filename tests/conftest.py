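"""Shared fixtures: configuration, synthetic tiles, a trained classifier."""

import numpy as np
import pytest

from tipmap import Config, TissueWindow, fit_fused_lasso
from tipmap.simulate import TileParams, simulate_tile
from tipmap.spatial import l_feature_vector
from tipmap.tessellation import build_tiles, hexagon, SQRT3

# offset that centres the (0,0) grid hexagon on a hexagon-shaped window whose
# bounding box starts at (-edge, -sqrt(3)/2*edge)
def aligned_offset(edge: float = 375.0) -> tuple[float, float]:
    return (edge, SQRT3 / 2.0 * edge)


@pytest.fixture(scope="session")
def config() -> Config:
    return Config()


@pytest.fixture(scope="session")
def hex_window() -> TissueWindow:
    """A single 375 um hexagon centred at the origin."""
    return TissueWindow(hexagon((0.0, 0.0), 375.0))


def tile_features(label: str, seed: int, config: Config, immune_type: str = "CD8",
                  params: TileParams | None = None):
    """Featurize one simulated tile through the full tessellation pipeline."""
    params = params or TileParams()
    cells = simulate_tile(label, params, seed=seed)
    window = TissueWindow(hexagon((0.0, 0.0), params.edge))
    tiles, _ = build_tiles(
        cells, window, edge=params.edge, offset=aligned_offset(params.edge),
        subhex_edge=config.subhex_edge, subhex_min_cells=config.subhex_min_cells,
    )
    tile = max(tiles, key=lambda t: t.n_cells())
    return l_feature_vector(tile, immune_type, config)


@pytest.fixture(scope="session")
def training_features(config):
    """30 inflamed + 30 excluded featurized tiles (fixed seeds)."""
    inflamed = [tile_features("inflamed", 1000 + s, config) for s in range(30)]
    excluded = [tile_features("excluded", 2000 + s, config) for s in range(30)]
    X = np.array([f.x for f in inflamed + excluded])
    y = np.r_[np.ones(30), np.zeros(30)]
    return X, y


@pytest.fixture(scope="session")
def trained_model(training_features, config):
    """Fused-lasso classifier trained on the synthetic labeled tiles."""
    X, y = training_features
    return fit_fused_lasso(X, y, 0.01, 0.001, r_grid=config.r_grid)
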