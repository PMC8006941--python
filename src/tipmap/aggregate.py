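"""Sample-level tumor infiltration phenotypes (TIPs).

A sample's TIP for a cell pair (tumor, CD8) or (tumor, CD4) is the vector of
proportions of its tiles classified inflamed / excluded / deserted.  To make
the result robust against the exact placement of the hexagonal grid, the
grid is shifted by ``shift_fraction`` of the tile edge (default 10%, i.e.
37.5 um) in the four axis directions, the proportions are recomputed for
each placement, and the five proportion vectors are averaged.

Proportions are taken over *classifiable* tiles (inflamed + excluded +
deserted); tiles without enough tumor cells to anchor an L curve are counted
separately and excluded from the denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import CellTable, Config, TissueWindow
from .tessellation import Tile, build_tiles
from .spatial import l_feature_vector
from .fusedlasso import FusedLassoModel, TilePhenotype, classify_tile

PHENOTYPES = ("inflamed", "excluded", "deserted")


@dataclass
class ShiftDetail:
    """Raw classification result for one grid placement."""

    offset: tuple[float, float]
    proportions: dict[str, float]
    n_classifiable: int
    n_unclassifiable: int


@dataclass
class TIPResult:
    """Shift-averaged phenotype proportions for one sample.

    ``proportions[pair]`` maps phenotype -> final (mean over placements)
    proportion, with ``pair`` like ``"tumor:CD8"``.
    """

    sample_id: str
    proportions: dict[str, dict[str, float]]
    per_shift: dict[str, list[ShiftDetail]]

    def get(self, immune_type: str, phenotype: str) -> float:
        return self.proportions[f"tumor:{immune_type}"][phenotype]


def classify_tiles(
    tiles: list[Tile], model: FusedLassoModel, immune_type: str, config: Config
) -> list[TilePhenotype]:
    """Phenotype every tile of one placement for one cell pair."""
    out = []
    t = config.deserted_threshold
    for tile in tiles:
        # the abundance (deserted) rule counts every immune cell assigned to
        # the tile; the sparse-area exclusion only shapes the L statistic
        n_j_total = tile.n_cells_total(immune_type)
        n_i, n_j = tile.n_cells("tumor"), tile.n_cells(immune_type)
        if n_j_total <= t:
            out.append(TilePhenotype(tile.tile_id, "deserted"))
        elif n_i < 2 or n_j < 1 or tile.area_effective <= 0:
            out.append(TilePhenotype(tile.tile_id, "unclassifiable"))
        else:
            features = l_feature_vector(tile, immune_type, config)
            features.n_j = n_j_total
            out.append(classify_tile(model, features, t=t))
    return out


def _proportions(phenotypes: list[TilePhenotype]) -> tuple[dict[str, float], int, int]:
    labels = [p.label for p in phenotypes]
    n_uncl = labels.count("unclassifiable")
    counts = {ph: labels.count(ph) for ph in PHENOTYPES}
    n_cls = sum(counts.values())
    props = {ph: (counts[ph] / n_cls if n_cls else np.nan) for ph in PHENOTYPES}
    return props, n_cls, n_uncl


def grid_offsets(config: Config, base: tuple[float, float] = (0.0, 0.0)) -> list[tuple[float, float]]:
    """The unshifted anchor plus shifts at 0, 90, 180, 270 degrees."""
    s = config.shift_fraction * config.tile_edge
    bx, by = base
    return [(bx, by), (bx + s, by), (bx, by + s), (bx - s, by), (bx, by - s)]


def sample_tips(
    cells: CellTable,
    window: TissueWindow,
    models: dict[str, FusedLassoModel],
    config: Config,
    base_offset: tuple[float, float] = (0.0, 0.0),
    shifts: bool = True,
) -> TIPResult:
    """Compute shift-averaged TIP proportions for one sample.

    ``models`` maps immune type (``"CD8"``/``"CD4"``) to its trained tile
    classifier; a pair is reported for each entry.  Placements yielding zero
    classifiable tiles are dropped from the average with a warning; if all
    placements are empty an error is raised.  ``base_offset`` moves the whole
    grid anchor; ``shifts=False`` restricts the computation to the single
    unshifted placement (useful for studying the effect of the averaging).
    """
    per_shift: dict[str, list[ShiftDetail]] = {f"tumor:{it}": [] for it in models}
    offsets = grid_offsets(config, base_offset) if shifts else [base_offset]
    for offset in offsets:
        tiles, _ = build_tiles(
            cells,
            window,
            edge=config.tile_edge,
            offset=offset,
            subhex_edge=config.subhex_edge,
            subhex_min_cells=config.subhex_min_cells,
        )
        for immune_type, model in models.items():
            phen = classify_tiles(tiles, model, immune_type, config)
            props, n_cls, n_uncl = _proportions(phen)
            if n_cls == 0:
                warnings.warn(
                    f"placement {offset}: no classifiable tiles for tumor:{immune_type}; skipped"
                )
                continue
            per_shift[f"tumor:{immune_type}"].append(
                ShiftDetail(offset, props, n_cls, n_uncl)
            )
    proportions = {}
    for pair, details in per_shift.items():
        if not details:
            raise ValueError(f"no placement produced classifiable tiles for {pair}")
        proportions[pair] = {
            ph: float(np.mean([d.proportions[ph] for d in details])) for ph in PHENOTYPES
        }
    return TIPResult(sample_id=cells.sample_id, proportions=proportions, per_shift=per_shift)


def tip_concordance(values, groups):
    """Rank-sum comparison of a TIP between two annotation groups.

    ``values`` are per-sample TIP values, ``groups`` the per-sample labels
    (exactly two distinct values, each with at least 2 samples).  Returns the
    two-sided Wilcoxon rank-sum (Mann-Whitney) statistic and p-value.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    names = np.unique(groups)
    if len(names) != 2:
        raise ValueError(f"need exactly two groups, got {list(names)}")
    a = values[groups == names[0]]
    b = values[groups == names[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples")
    no_ties = len(np.unique(values)) == len(values)
    method = "exact" if (no_ties and max(len(a), len(b)) <= 25) else "auto"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def tile_map_geojson(tiles: list[Tile], phenotypes: list[TilePhenotype]) -> dict:
    """GeoJSON FeatureCollection of tiles with their phenotype label."""
    import shapely.geometry as sgeom

    by_id = {p.tile_id: p for p in phenotypes}
    features = []
    for tile in tiles:
        p = by_id.get(tile.tile_id)
        features.append(
            {
                "type": "Feature",
                "geometry": sgeom.mapping(tile.hexagon),
                "properties": {
                    "tile_id": tile.tile_id,
                    "phenotype": None if p is None else p.label,
                    "probability": None if p is None else p.probability,
                    "n_cells": {ct: tile.n_cells(ct) for ct in tile.cells},
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}
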