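"""Hexagonal tiling of the tumor region and sparse-area exclusion.

The annotated region is tessellated into flat-top hexagons (default side
length 375 um).  Within each tile, sub-hexagons of side 50 um containing
fewer than 2 cells are excluded from the analysis window, because near-empty
areas (tears, holes) would bias the Ripley statistics.

The grid is anchored at the window bounding-box lower-left corner plus a
configurable offset: the hexagon with axial index (0, 0) is centred there.
Sub-hexagon grids are anchored per tile at the tile hexagon's bounding box.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
import shapely.geometry as sgeom

from .io import CELL_TYPES, CellTable, TissueWindow, GeometryError

SQRT3 = np.sqrt(3.0)


def hexagon(center: tuple[float, float], edge: float) -> sgeom.Polygon:
    """Flat-top hexagon of given side length centred at ``center``."""
    cx, cy = center
    ang = np.arange(6) * (np.pi / 3.0)
    return sgeom.Polygon(np.column_stack([cx + edge * np.cos(ang), cy + edge * np.sin(ang)]))


def hexagon_area(edge: float) -> float:
    return 1.5 * SQRT3 * edge * edge


def _hex_centers(bounds, edge, anchor):
    """Centers of all flat-top hexagons that can intersect the bounding box.

    Columns are spaced 1.5*edge apart in x; rows sqrt(3)*edge in y, with odd
    columns shifted up by half a row ("odd-q" layout).  Returns (col, row, x, y)
    tuples sorted by (row, col) so tile ids are deterministic.
    """
    minx, miny, maxx, maxy = bounds
    ax, ay = anchor
    dx, dy = 1.5 * edge, SQRT3 * edge
    c_lo = int(np.floor((minx - edge - ax) / dx))
    c_hi = int(np.ceil((maxx + edge - ax) / dx))
    out = []
    for c in range(c_lo, c_hi + 1):
        yoff = ay + (abs(c) % 2) * (dy / 2.0)
        r_lo = int(np.floor((miny - dy / 2.0 - yoff) / dy))
        r_hi = int(np.ceil((maxy + dy / 2.0 - yoff) / dy))
        for r in range(r_lo, r_hi + 1):
            out.append((c, r, ax + c * dx, yoff + r * dy))
    out.sort(key=lambda t: (t[1], t[0]))
    return out


@dataclass
class Tile:
    """One hexagon of the tessellation, clipped to the tissue window.

    ``effective_window`` is the part of the tile used for spatial statistics:
    the clipped hexagon minus excluded sparse sub-hexagons.  ``cells`` holds
    per-type coordinate arrays of the member cells inside the effective window.
    """

    tile_id: int
    hexagon: sgeom.base.BaseGeometry          # clipped to the tissue window
    raw_hexagon: sgeom.Polygon                # full (unclipped) hexagon
    effective_window: sgeom.base.BaseGeometry = None
    cells: dict = field(default_factory=lambda: {t: np.empty((0, 2)) for t in CELL_TYPES})
    total_counts: dict = None  # per-type counts before sparse-area exclusion

    def __post_init__(self) -> None:
        if self.effective_window is None:
            self.effective_window = self.hexagon

    @property
    def area_effective(self) -> float:
        return float(self.effective_window.area)

    def n_cells(self, cell_type: str | None = None) -> int:
        if cell_type is None:
            return sum(len(v) for v in self.cells.values())
        return len(self.cells[cell_type])

    def n_cells_total(self, cell_type: str) -> int:
        """Cells of one type assigned to the tile, before sparse-area
        exclusion; this is the count abundance rules operate on."""
        if self.total_counts is None:
            return self.n_cells(cell_type)
        return self.total_counts[cell_type]

    def all_coords(self) -> np.ndarray:
        arrs = [v for v in self.cells.values() if len(v)]
        return np.vstack(arrs) if arrs else np.empty((0, 2))


def hex_tessellate(
    window: TissueWindow, edge: float = 375.0, offset: tuple[float, float] = (0.0, 0.0)
) -> list[Tile]:
    """Tessellate the window into flat-top hexagonal tiles of side ``edge``.

    Returns every hexagon whose intersection with the window has positive
    area, each clipped to the window.  Tile ids are sequential in a fixed
    (row, column) order, so the tiling is deterministic.
    """
    if edge <= 0:
        raise ValueError("edge must be positive")
    if window.area <= 0:
        raise GeometryError("degenerate window with zero area")
    minx, miny, _, _ = window.bounds
    anchor = (minx + offset[0], miny + offset[1])
    tiles: list[Tile] = []
    min_area = 1e-9 * hexagon_area(edge)  # discard boundary-contact slivers
    for _, _, cx, cy in _hex_centers(window.bounds, edge, anchor):
        hexa = hexagon((cx, cy), edge)
        clipped = hexa.intersection(window.geometry)
        if clipped.is_empty or clipped.area <= min_area:
            continue
        tiles.append(Tile(tile_id=len(tiles), hexagon=clipped, raw_hexagon=hexa))
    return tiles


def assign_cells(cells: CellTable, tiles: list[Tile]) -> int:
    """Assign each cell to exactly one tile by point-in-polygon.

    Cells on a shared tile edge go to the lowest tile_id; cells covered by no
    tile are dropped.  Returns the number of dropped cells.  Tiles are
    modified in place (their ``cells`` dict is filled; ``effective_window`` is
    reset to the clipped hexagon).
    """
    pts = cells.coords()
    assigned = np.full(len(pts), -1, dtype=int)
    if len(pts):
        tree = shapely.STRtree(shapely.points(pts[:, 0], pts[:, 1]))
        for tile in sorted(tiles, key=lambda t: t.tile_id):
            idx = tree.query(tile.hexagon, predicate="covers")
            free = idx[assigned[idx] < 0]
            assigned[free] = tile.tile_id
    by_id = {t.tile_id: t for t in tiles}
    for tile in tiles:
        tile.cells = {ct: np.empty((0, 2)) for ct in CELL_TYPES}
        tile.effective_window = tile.hexagon
    for ct in CELL_TYPES:
        mask_t = cells.cell_type == ct
        for tid in np.unique(assigned[mask_t]):
            if tid < 0:
                continue
            by_id[int(tid)].cells[ct] = pts[mask_t & (assigned == tid)]
    for tile in tiles:
        tile.total_counts = {ct: len(tile.cells[ct]) for ct in CELL_TYPES}
    return int(np.sum(assigned < 0))


def effective_window(tile: Tile, subhex_edge: float = 50.0, min_cells: int = 2) -> Tile:
    """Exclude sparse sub-hexagons (< ``min_cells`` cells of any type) in place.

    The tile hexagon is sub-tessellated with flat-top hexagons of side
    ``subhex_edge`` anchored at the raw hexagon's bounding box; sub-hexes whose
    intersection with the tile holds fewer than ``min_cells`` cells are removed
    from the effective window, along with any cells inside them (so member
    cells always lie inside the effective window).
    """
    pts = tile.all_coords()
    minx, miny, _, _ = tile.raw_hexagon.bounds
    sub_centers = _hex_centers(tile.hexagon.bounds, subhex_edge, (minx, miny))
    # Assign cells to sub-hexes with the same lowest-id tie rule.
    sub_polys = [hexagon((cx, cy), subhex_edge) for _, _, cx, cy in sub_centers]
    sub_assigned = np.full(len(pts), -1, dtype=int)
    if len(pts):
        tree = shapely.STRtree(shapely.points(pts[:, 0], pts[:, 1]))
        for k, poly in enumerate(sub_polys):
            idx = tree.query(poly, predicate="covers")
            free = idx[sub_assigned[idx] < 0]
            sub_assigned[free] = k
    counts = np.bincount(sub_assigned[sub_assigned >= 0], minlength=len(sub_polys))
    sparse = [
        poly
        for k, poly in enumerate(sub_polys)
        if counts[k] < min_cells and poly.intersection(tile.hexagon).area > 1e-9
    ]
    if sparse:
        tile.effective_window = tile.hexagon.difference(shapely.union_all(sparse))
    else:
        tile.effective_window = tile.hexagon
    # Drop cells that fell inside removed sub-hexes.
    keep = np.ones(len(pts), dtype=bool)
    for k, poly in enumerate(sub_polys):
        if counts[k] < min_cells:
            keep[sub_assigned == k] = False
    if not keep.all():
        offset = 0
        for ct in CELL_TYPES:
            n = len(tile.cells[ct])
            tile.cells[ct] = tile.cells[ct][keep[offset : offset + n]]
            offset += n
    return tile


def build_tiles(
    cells: CellTable,
    window: TissueWindow,
    edge: float = 375.0,
    offset: tuple[float, float] = (0.0, 0.0),
    subhex_edge: float = 50.0,
    subhex_min_cells: int = 2,
) -> tuple[list[Tile], int]:
    """Tessellate, assign cells, and compute effective windows in one call.

    Returns the tile list and the number of cells outside every tile.
    """
    tiles = hex_tessellate(window, edge, offset)
    dropped = assign_cells(cells, tiles)
    for tile in tiles:
        effective_window(tile, subhex_edge=subhex_edge, min_cells=subhex_min_cells)
    return tiles, dropped
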