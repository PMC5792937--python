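"""Environmental raster stacks and occurrence records.

Handles the pre-processing stages of a presence-only distribution
modelling study: reading gridded environmental layers (ESRI ASCII
format), assigning point localities to grid cells, collapsing duplicate
records to one per species per cell, excluding species recorded at too
few unique localities, and pruning mutually correlated variables by
pairwise Pearson correlation.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, GeometryError

logger = logging.getLogger(__name__)

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"


# ---------------------------------------------------------------------------
# Raster grids
# ---------------------------------------------------------------------------

@dataclass
class RasterGrid:
    """A single gridded layer on a regular lon/lat (or planar) grid.

    ``values`` is a (n_rows, n_cols) float array ordered from the top
    row down (raster convention); ``nodata_mask`` is True where the cell
    carries no data.  ``x_min``/``y_min`` locate the lower-left corner
    of the grid in map units and ``cell_size`` is the square cell edge.
    """

    values: np.ndarray
    nodata_mask: np.ndarray
    x_min: float
    y_min: float
    cell_size: float
    name: str = "layer"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.values.ndim != 2:
            raise DataError(f"raster '{self.name}': values must be 2-D")
        if self.values.shape != self.nodata_mask.shape:
            raise DataError(f"raster '{self.name}': mask shape mismatch")
        if self.cell_size <= 0:
            raise DataError(f"raster '{self.name}': non-positive cell size")
        valid = self.values[~self.nodata_mask]
        if valid.size and not np.all(np.isfinite(valid)):
            raise DataError(f"raster '{self.name}': non-finite value on a valid cell")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def x_max(self) -> float:
        return self.x_min + self.n_cols * self.cell_size

    @property
    def y_max(self) -> float:
        return self.y_min + self.n_rows * self.cell_size

    def geometry(self) -> tuple:
        return (self.n_rows, self.n_cols, round(self.x_min, 9),
                round(self.y_min, 9), round(self.cell_size, 12))

    def same_geometry(self, other: "RasterGrid") -> bool:
        return self.geometry() == other.geometry()

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """Map coordinates of the center of cell (row, col)."""
        x = self.x_min + (col + 0.5) * self.cell_size
        y = self.y_max - (row + 0.5) * self.cell_size
        return x, y


def read_ascii_grid(path: str | Path, name: str | None = None) -> RasterGrid:
    """Read an ESRI ASCII grid (.asc).

    Header keys ncols/nrows/xllcorner/yllcorner/cellsize are required;
    ``xllcenter``/``yllcenter`` variants and ``nodata_value`` are honoured.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise DataError(f"cannot read raster file {path}: {exc}") from exc
    lines = text.splitlines()
    header: dict[str, float] = {}
    data_start = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0][0].isalpha():
            header[parts[0].lower()] = float(parts[1])
            data_start = i + 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise DataError(f"{path}: missing ESRI ASCII header key '{key}'")
    n_cols = int(header["ncols"])
    n_rows = int(header["nrows"])
    cell = header["cellsize"]
    if "xllcorner" in header:
        x_min = header["xllcorner"]
    elif "xllcenter" in header:
        x_min = header["xllcenter"] - cell / 2
    else:
        raise DataError(f"{path}: missing xllcorner/xllcenter")
    if "yllcorner" in header:
        y_min = header["yllcorner"]
    elif "yllcenter" in header:
        y_min = header["yllcenter"] - cell / 2
    else:
        raise DataError(f"{path}: missing yllcorner/yllcenter")
    nodata = header.get("nodata_value", -9999.0)
    try:
        flat = np.array(" ".join(lines[data_start:]).split(), dtype=float)
        values = flat.reshape(n_rows, n_cols)
    except ValueError as exc:
        raise DataError(f"{path}: malformed data block: {exc}") from exc
    mask = values == nodata
    values = np.where(mask, np.nan, values)
    return RasterGrid(values, mask, x_min, y_min, cell,
                      name=name or path.stem)


def write_ascii_grid(grid: RasterGrid, path: str | Path,
                     nodata_value: float = -9999.0, fmt: str = "%.10g") -> None:
    """Write a RasterGrid as an ESRI ASCII grid."""
    path = Path(path)
    out = np.where(grid.nodata_mask, nodata_value, grid.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.x_min:.10g}\n")
        fh.write(f"yllcorner {grid.y_min:.10g}\n")
        fh.write(f"cellsize {grid.cell_size:.10g}\n")
        fh.write(f"NODATA_value {nodata_value:.10g}\n")
        for row in out:
            fh.write(" ".join(fmt % v for v in row) + "\n")


# ---------------------------------------------------------------------------
# Environmental stacks
# ---------------------------------------------------------------------------

@dataclass
class EnvStack:
    """An ordered set of co-registered raster layers with a shared mask.

    The stack's ``mask`` is the union of the per-layer nodata masks: a
    cell belongs to the model domain only when every layer has data
    there.  ``kinds`` flags each layer as continuous or categorical;
    categorical layers must hold integer codes.
    """

    layers: list[RasterGrid]
    kinds: list[str]
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.layers:
            raise DataError("empty stack: at least one layer required")
        if not self.names:
            self.names = [g.name for g in self.layers]
        if not (len(self.layers) == len(self.kinds) == len(self.names)):
            raise DataError("layers, kinds and names must have equal length")
        ref = self.layers[0]
        for grid, name in zip(self.layers[1:], self.names[1:]):
            if not grid.same_geometry(ref):
                raise GeometryError(
                    f"layer '{name}' geometry {grid.geometry()} does not match "
                    f"'{self.names[0]}' geometry {ref.geometry()}")
        for kind, grid, name in zip(self.kinds, self.layers, self.names):
            if kind not in (CONTINUOUS, CATEGORICAL):
                raise DataError(f"layer '{name}': unknown kind '{kind}'")
            if kind == CATEGORICAL:
                vals = grid.values[~grid.nodata_mask]
                if vals.size and not np.allclose(vals, np.round(vals)):
                    raise DataError(f"categorical layer '{name}' holds non-integer codes")
        self.mask = np.logical_or.reduce([g.nodata_mask for g in self.layers])
        if self.mask.all():
            raise DataError("empty domain: every cell is nodata in some layer")

    @property
    def grid(self) -> RasterGrid:
        return self.layers[0]

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.mask

    @property
    def n_valid_cells(self) -> int:
        return int(self.valid_mask.sum())

    def valid_values(self) -> np.ndarray:
        """(n_valid_cells, n_layers) array of layer values on the shared domain,
        ordered by flattened (row-major) cell index."""
        cols = [g.values[self.valid_mask] for g in self.layers]
        return np.column_stack(cols)

    def valid_cell_indices(self) -> np.ndarray:
        """Flat (row-major) indices of the valid cells, ascending."""
        return np.flatnonzero(self.valid_mask.ravel())

    def subset(self, keep: Sequence[int]) -> "EnvStack":
        keep = list(keep)
        return EnvStack([self.layers[i] for i in keep],
                        [self.kinds[i] for i in keep],
                        [self.names[i] for i in keep])


def read_env_stack(paths: Sequence[str | Path], kinds: Sequence[str]) -> EnvStack:
    """Read a set of co-registered ESRI ASCII rasters into a stack.

    Raises GeometryError naming the first layer whose geometry differs
    from the first layer read.
    """
    if len(paths) != len(kinds):
        raise DataError("paths and kinds must have equal length")
    layers = [read_ascii_grid(p) for p in paths]
    return EnvStack(layers, list(kinds))


# ---------------------------------------------------------------------------
# Occurrence records
# ---------------------------------------------------------------------------

@dataclass
class OccurrenceSet:
    """Species-labelled point localities.

    Wraps a DataFrame with columns ``species``, ``longitude``,
    ``latitude`` and, after :func:`assign_cells`, integer ``row``/``col``
    cell indices.  After :func:`deduplicate` each (species, cell) pair is
    unique.
    """

    records: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self) -> None:
        required = {"species", "longitude", "latitude"}
        missing = required - set(self.records.columns)
        if missing:
            raise DataError(f"occurrence table missing columns: {sorted(missing)}")
        coords = self.records[["longitude", "latitude"]].to_numpy(dtype=float)
        if coords.size and not np.all(np.isfinite(coords)):
            raise DataError("non-finite coordinates in occurrence records")
        self.records = self.records.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def has_cells(self) -> bool:
        return {"row", "col"}.issubset(self.records.columns)

    @property
    def species(self) -> list[str]:
        return sorted(self.records["species"].unique())

    def cells_for(self, species: str) -> np.ndarray:
        """Unique (row, col) pairs for one species (requires assigned cells)."""
        if not self.has_cells:
            raise DataError("cells not assigned; call assign_cells first")
        sub = self.records.loc[self.records["species"] == species, ["row", "col"]]
        return sub.drop_duplicates().to_numpy(dtype=int)


def read_occurrences(path: str | Path) -> OccurrenceSet:
    """Read a `species,longitude,latitude` CSV (UTF-8, with header)."""
    df = pd.read_csv(path, encoding="utf-8")
    df.columns = [c.strip().lower() for c in df.columns]
    return OccurrenceSet(df)


def write_occurrences(occ: OccurrenceSet, path: str | Path) -> None:
    occ.records.to_csv(path, index=False, encoding="utf-8")


def assign_cells(occ: OccurrenceSet, grid: RasterGrid,
                 mask: np.ndarray | None = None) -> OccurrenceSet:
    """Map each record to its raster cell; drop records off-grid or on nodata.

    Binning is half-open [edge, edge) from the grid origin in both axes:
    a point on a shared vertical boundary falls in the higher column, a
    point on a horizontal boundary in the cell whose bottom edge it
    touches.  Rows are counted from the top edge (raster convention).
    Coordinates are treated as planar; no projection is applied.
    """
    if mask is None:
        mask = grid.nodata_mask
    df = occ.records.copy()
    x = df["longitude"].to_numpy(dtype=float)
    y = df["latitude"].to_numpy(dtype=float)
    col = np.floor((x - grid.x_min) / grid.cell_size).astype(int)
    iy = np.floor((y - grid.y_min) / grid.cell_size).astype(int)
    row = grid.n_rows - 1 - iy
    inside = (col >= 0) & (col < grid.n_cols) & (row >= 0) & (row < grid.n_rows)
    on_data = np.zeros(len(df), dtype=bool)
    on_data[inside] = ~mask[row[inside], col[inside]]
    keep = inside & on_data
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("assign_cells: dropped %d record(s) outside the extent "
                    "or on nodata cells", n_dropped)
    df = df.loc[keep].copy()
    df["row"] = row[keep]
    df["col"] = col[keep]
    return OccurrenceSet(df, n_dropped=n_dropped)


def deduplicate(occ: OccurrenceSet) -> OccurrenceSet:
    """Keep one record per (species, cell); localities in the same cell are
    not treated as separate. Requires assigned cells."""
    if not occ.has_cells:
        raise DataError("deduplicate requires cell-assigned records")
    before = len(occ.records)
    df = occ.records.drop_duplicates(subset=["species", "row", "col"], keep="first")
    removed = before - len(df)
    if removed:
        logger.info("deduplicate: removed %d duplicate record(s); "
                    "%d unique localities remain", removed, len(df))
    return OccurrenceSet(df.reset_index(drop=True), n_dropped=occ.n_dropped)


def filter_min_localities(occ: OccurrenceSet, min_localities: int = 4
                          ) -> tuple[list[str], list[str]]:
    """Split species into (retained, excluded) by unique-locality count.

    A species is retained when it occupies at least ``min_localities``
    unique grid cells (default four).
    """
    if not occ.has_cells:
        raise DataError("filter_min_localities requires cell-assigned records")
    counts = (occ.records.drop_duplicates(subset=["species", "row", "col"])
              .groupby("species").size())
    retained = sorted(counts.index[counts >= min_localities])
    excluded = sorted(counts.index[counts < min_localities])
    if excluded:
        logger.info("filter_min_localities: excluded %d species with fewer "
                    "than %d unique localities: %s",
                    len(excluded), min_localities, ", ".join(excluded))
    return retained, excluded


# ---------------------------------------------------------------------------
# Variable selection
# ---------------------------------------------------------------------------

def select_variables(stack: EnvStack, threshold: float = 0.7
                     ) -> tuple[EnvStack, pd.DataFrame]:
    """Greedily prune layers so no surviving pair has |Pearson r| >= threshold.

    Correlations are computed over the jointly valid cells, on raw layer
    values (categorical layers enter on their numeric codes).  Pairs at or
    above the threshold are visited in descending |r|; the later-listed
    layer of each pair is dropped.  Zero-variance layers are removed first
    with a warning (their correlation is undefined).

    Returns the reduced stack and a removal log with columns
    ``removed``, ``kept_partner``, ``r``, ``reason``.
    """
    values = stack.valid_values()
    n = stack.n_layers
    log_rows: list[dict] = []
    active = list(range(n))

    stds = values.std(axis=0)
    for i in range(n):
        if stds[i] == 0:
            warnings.warn(f"layer '{stack.names[i]}' has zero variance; removed "
                          "(correlation undefined)")
            log_rows.append({"removed": stack.names[i], "kept_partner": "",
                             "r": np.nan, "reason": "zero variance"})
            active.remove(i)
    if not active:
        raise DataError("no layers left after removing zero-variance layers")

    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(values.T) if n > 1 else np.ones((1, 1))
    pairs = [(abs(corr[i, j]), i, j)
             for ii, i in enumerate(active) for j in active[ii + 1:]
             if abs(corr[i, j]) >= threshold]
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))

    dropped: set[int] = set()
    for r_abs, i, j in pairs:
        if i in dropped or j in dropped:
            continue
        dropped.add(j)  # later-listed layer of the pair
        log_rows.append({"removed": stack.names[j], "kept_partner": stack.names[i],
                         "r": float(corr[i, j]), "reason": f"|r| >= {threshold}"})
        logger.info("select_variables: dropped '%s' (r=%.4f with '%s')",
                    stack.names[j], corr[i, j], stack.names[i])
    keep = [i for i in active if i not in dropped]
    return stack.subset(keep), pd.DataFrame(
        log_rows, columns=["removed", "kept_partner", "r", "reason"])
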