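"""Data types, file readers/writers, and configuration shared by all stages.

Coordinates are real-valued micrometres in a Cartesian frame with y increasing
upward; converting from pixel units (microscope metadata) is the caller's
responsibility.  Cell types are restricted to ``tumor``, ``CD8`` and ``CD4``;
proliferation sub-states (e.g. Ki67+) are expected to be collapsed into their
parent type upstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
import shapely.geometry as sgeom

CELL_TYPES = ("tumor", "CD8", "CD4")
IMMUNE_TYPES = ("CD8", "CD4")


class FormatError(ValueError):
    """A file does not follow the documented format."""


class GeometryError(ValueError):
    """A region-of-interest geometry is invalid."""


# ---------------------------------------------------------------------------
# Cell tables
# ---------------------------------------------------------------------------

@dataclass
class CellTable:
    """Per-cell coordinates and types for one sample.

    Parameters
    ----------
    sample_id : str
        Identifier of the tissue sample the cells belong to.
    x, y : ndarray of float
        Cell centroid coordinates in micrometres.
    cell_type : ndarray of str
        One of ``tumor``, ``CD8``, ``CD4`` per cell.
    """

    sample_id: str
    x: np.ndarray
    y: np.ndarray
    cell_type: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.cell_type = np.asarray(self.cell_type, dtype=object)
        if not (len(self.x) == len(self.y) == len(self.cell_type)):
            raise ValueError("x, y and cell_type must have equal length")
        if len(self.x) and not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("cell coordinates must be finite")
        bad = [t for t in np.unique(self.cell_type) if t not in CELL_TYPES] if len(self.x) else []
        if bad:
            raise ValueError(f"unknown cell types {bad!r}; allowed: {CELL_TYPES}")

    def __len__(self) -> int:
        return len(self.x)

    def coords(self, cell_type: str | None = None) -> np.ndarray:
        """(n, 2) coordinate array, optionally restricted to one cell type."""
        pts = np.column_stack([self.x, self.y]) if len(self) else np.empty((0, 2))
        if cell_type is None:
            return pts
        return pts[self.cell_type == cell_type]

    def counts(self) -> dict[str, int]:
        return {t: int(np.sum(self.cell_type == t)) for t in CELL_TYPES}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_id, "x": self.x, "y": self.y, "cell_type": self.cell_type}
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, sample_id: str | None = None) -> "CellTable":
        if sample_id is None:
            ids = df["sample_id"].unique() if len(df) else []
            sample_id = str(ids[0]) if len(ids) else "sample"
        return cls(
            sample_id=sample_id,
            x=df["x"].to_numpy(dtype=float),
            y=df["y"].to_numpy(dtype=float),
            cell_type=df["cell_type"].to_numpy(dtype=object),
        )


def read_cell_table(path) -> CellTable:
    """Read a per-cell CSV with columns ``sample_id,x,y,cell_type``."""
    df = pd.read_csv(path, dtype={"sample_id": str, "cell_type": str})
    required = {"sample_id", "x", "y", "cell_type"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"cell table {path}: missing columns {sorted(missing)}")
    if len(df) == 0:
        return CellTable("sample", np.empty(0), np.empty(0), np.empty(0, dtype=object))
    for col in ("x", "y"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(df.index[vals.isna()][0])
            raise FormatError(f"cell table {path}: non-numeric {col!r} in row {row}")
        df[col] = vals
    bad = ~df["cell_type"].isin(CELL_TYPES)
    if bad.any():
        row = int(df.index[bad][0])
        raise FormatError(
            f"cell table {path}: unknown cell_type {df.loc[row, 'cell_type']!r} in row {row}"
        )
    return CellTable.from_dataframe(df)


def write_cell_table(table: CellTable, path) -> None:
    table.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Tissue windows (regions of interest)
# ---------------------------------------------------------------------------

@dataclass
class TissueWindow:
    """Pathologist-annotated tumor region: one or more simple polygons in um.

    Only cells inside the window take part in the analysis.  Holes are allowed
    (e.g. necrotic areas carved out of the annotation).
    """

    geometry: sgeom.base.BaseGeometry

    def __post_init__(self) -> None:
        geom = self.geometry
        if geom.geom_type == "Polygon":
            geom = sgeom.MultiPolygon([geom])
        if geom.geom_type != "MultiPolygon":
            raise GeometryError(f"expected Polygon/MultiPolygon, got {geom.geom_type}")
        if not geom.is_valid:
            raise GeometryError(f"invalid region geometry: {shapely.is_valid_reason(geom)}")
        if geom.area <= 0:
            raise GeometryError("region has zero area")
        self.geometry = geom

    @property
    def area(self) -> float:
        return float(self.geometry.area)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return self.geometry.bounds


def read_roi(path) -> TissueWindow:
    """Read a GeoJSON Polygon/MultiPolygon region of interest (um coordinates)."""
    with open(path) as fh:
        data = json.load(fh)
    if data.get("type") == "FeatureCollection":
        geoms = [sgeom.shape(f["geometry"]) for f in data["features"]]
        geom = shapely.union_all(geoms)
    elif data.get("type") == "Feature":
        geom = sgeom.shape(data["geometry"])
    else:
        geom = sgeom.shape(data)
    return TissueWindow(geom)


def write_roi(window: TissueWindow, path) -> None:
    with open(path, "w") as fh:
        json.dump(sgeom.mapping(window.geometry), fh)


# ---------------------------------------------------------------------------
# Expression / mutation matrices, gene sets
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with complete observations."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        self.samples = [str(s) for s in self.samples]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError("values shape must be (n_genes, n_samples)")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")
        if len(self.genes) < 2 or len(self.samples) < 2:
            raise ValueError("need at least 2 genes and 2 samples")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)

    def restrict(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in set(self.genes)]
        if missing:
            raise KeyError(f"genes not present in matrix: {missing}")
        idx = [self.genes.index(g) for g in genes]
        return ExpressionMatrix(list(genes), list(self.samples), self.values[idx])


def read_expression(path) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column gene id, header sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise FormatError(f"expression matrix {path}: missing values present")
    return ExpressionMatrix(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy())


def write_expression(mat: ExpressionMatrix, path) -> None:
    mat.to_dataframe().to_csv(path, sep="\t", index_label="gene")


@dataclass
class MutationMatrix:
    """Patients x genes binary mutation indicators, optional per-patient TMB."""

    patients: list[str]
    genes: list[str]
    values: np.ndarray
    tmb: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.patients = [str(p) for p in self.patients]
        self.genes = [str(g) for g in self.genes]
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.patients), len(self.genes)):
            raise ValueError("values shape must be (n_patients, n_genes)")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("mutation matrix entries must be 0 or 1")
        self.values = self.values.astype(int)
        if self.tmb is not None:
            self.tmb = np.asarray(self.tmb, dtype=float)
            if len(self.tmb) != len(self.patients):
                raise ValueError("tmb length must match number of patients")

    def frequency(self) -> np.ndarray:
        """Per-gene mutation frequency across patients."""
        return self.values.mean(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.patients, columns=self.genes)


def read_mutations(path) -> MutationMatrix:
    """Read a TSV mutation matrix (rows patients, columns genes, entries 0/1)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    tmb = None
    if "TMB" in df.columns:
        tmb = df.pop("TMB").to_numpy(dtype=float)
    return MutationMatrix(
        list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy(), tmb=tmb
    )


def write_mutations(mat: MutationMatrix, path) -> None:
    df = mat.to_dataframe()
    if mat.tmb is not None:
        df = df.copy()
        df["TMB"] = mat.tmb
    df.to_csv(path, sep="\t", index_label="patient")


@dataclass
class PathwayCollection:
    """Named gene sets (pathway name -> gene id list)."""

    sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


def read_gene_sets(path) -> PathwayCollection:
    """Read gene sets from a GMT file (name, description, gene ids, tab-separated)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
            name, genes = parts[0], [g for g in parts[2:] if g]
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no genes")
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            sets[name] = genes
    return PathwayCollection(sets)


def write_gene_sets(collection: PathwayCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class Config:
    """Pipeline constants.

    Defaults: 375 um hexagonal tiles, 50 um
    sub-hexagons with fewer than 2 cells excluded, the deserted threshold of
    5 immune cells, an equidistant radius grid from 1 to 338 um (about 90% of
    the tile size), 10% grid shifts, 200 stability-selection runs, the 20%
    mutation-frequency and 40% pathway-overlap filters, the 0.6 correlation
    cutoff for pruning phenotype covariates, SVM cost 4 / gamma 2**-10, and
    the TMB high/low cutoff of 20 mutations per megabase.
    """

    tile_edge: float = 375.0           # um, hexagon side length
    subhex_edge: float = 50.0          # um, sparse-area exclusion hexagons
    subhex_min_cells: int = 2          # sub-hexes with fewer cells are excluded
    deserted_threshold: int = 5        # tiles with <= t immune cells are deserted
    r_min: float = 1.0                 # um
    r_max: float = 338.0               # um
    r_points: int = 50                 # grid size n
    shift_fraction: float = 0.1        # grid shift as fraction of tile_edge
    n_stability_runs: int = 200
    mutation_min_freq: float = 0.2
    pathway_min_overlap: float = 0.4
    tip_corr_cutoff: float = 0.6
    svm_cost: float = 4.0
    svm_gamma: float = 0.0009765625
    bonferroni_alpha: float = 0.05
    tmb_high_cutoff: float = 20.0      # mutations per megabase
    seed: int = 0

    def __post_init__(self) -> None:
        positive = [
            "tile_edge", "subhex_edge", "subhex_min_cells", "r_min", "r_max",
            "r_points", "shift_fraction", "n_stability_runs", "mutation_min_freq",
            "pathway_min_overlap", "tip_corr_cutoff", "svm_cost", "svm_gamma",
            "bonferroni_alpha", "tmb_high_cutoff",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name} must be positive")
        if self.deserted_threshold < 0:
            raise ValueError("deserted_threshold must be >= 0")
        if not self.r_max < 2 * self.tile_edge:
            raise ValueError("r_max must be below the tile diameter (2 * tile_edge)")

    @property
    def r_grid(self) -> np.ndarray:
        """Equidistant radius grid in [r_min, r_max] with r_points values."""
        return np.linspace(self.r_min, self.r_max, self.r_points)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "Config":
        with open(path) as fh:
            return cls(**json.load(fh))
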