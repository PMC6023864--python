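"""Raster stacks, occurrence tables and their on-disk formats.

The in-memory containers used throughout the package live here:

* :class:`ClimateStack` — a set of named bioclimatic grids sharing one
  geometry and one nodata mask (the predictor space of the models).
* :class:`OccurrenceSet` — point records with a role (presence, fossil,
  background, pseudoabsence) and a period label, backed by a DataFrame.
* :class:`SuitabilityMap` — a single [0, 1] grid with the same geometry,
  the output of a projected distribution model.

Rasters are stored as single-band ESRI ASCII grids (``.asc``), occurrences
as comma-separated UTF-8 CSV with a header row, reports as JSON.

Grid conventions (fixed and round-trip tested):

* row 0 of every array is the northernmost row, matching the file layout;
* ``origin`` is the (x, y) of the grid's lower-left corner;
* cells are half-open: a point exactly on a boundary belongs to the cell
  to the right/above; point coordinates returned for cells are centers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_ROLES = ("presence", "fossil", "background", "pseudoabsence")

_ASCII_NODATA = -9999.0


@dataclass
class ClimateStack:
    """Named raster variables on a shared grid for one climate scenario."""

    variables: dict[str, np.ndarray]
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_mask: np.ndarray | None = None
    scenario_id: str = "scenario"

    def __post_init__(self) -> None:
        if not self.variables:
            raise ValueError("ClimateStack needs at least one variable")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        shapes = {v.shape for v in self.variables.values()}
        if len(shapes) != 1:
            raise ValueError(f"variable grids differ in shape: {shapes}")
        shape = shapes.pop()
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(shape, dtype=bool)
        elif self.nodata_mask.shape != shape:
            raise ValueError("nodata_mask shape does not match variables")
        self.variables = {k: np.asarray(v, dtype=float) for k, v in self.variables.items()}

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.variables.values())).shape

    @property
    def variable_names(self) -> list[str]:
        return list(self.variables)

    @property
    def n_unmasked(self) -> int:
        return int((~self.nodata_mask).sum())

    def env_table(self, names: Sequence[str] | None = None) -> np.ndarray:
        """Environment matrix (n_unmasked x n_vars) over unmasked cells."""
        names = list(names) if names is not None else self.variable_names
        ok = ~self.nodata_mask
        return np.column_stack([self.variables[n][ok] for n in names])

    def unmasked_indices(self) -> np.ndarray:
        """Flat indices (row-major) of unmasked cells."""
        return np.flatnonzero(~self.nodata_mask)

    def cell_centers(self, flat_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map row-major flat cell indices to center (x, y) coordinates."""
        nrows, ncols = self.shape
        rows, cols = np.unravel_index(np.asarray(flat_idx, dtype=int), (nrows, ncols))
        x = self.origin[0] + (cols + 0.5) * self.cell_size
        y = self.origin[1] + (nrows - rows - 0.5) * self.cell_size
        return x, y

    def cells_of_points(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of each point; half-open cells, boundary -> right/above."""
        nrows, ncols = self.shape
        col = np.floor((np.asarray(x, float) - self.origin[0]) / self.cell_size).astype(int)
        row_from_bottom = np.floor((np.asarray(y, float) - self.origin[1]) / self.cell_size).astype(int)
        row = nrows - 1 - row_from_bottom
        inside = (col >= 0) & (col < ncols) & (row >= 0) & (row < nrows)
        if not inside.all():
            bad = np.flatnonzero(~inside)
            raise ValueError(f"points outside grid extent at indices {bad.tolist()[:10]}")
        return row, col

    def env_at_points(self, x: np.ndarray, y: np.ndarray,
                      names: Sequence[str] | None = None) -> np.ndarray:
        """Environment vectors at point locations; masked cells raise."""
        names = list(names) if names is not None else self.variable_names
        row, col = self.cells_of_points(x, y)
        masked = self.nodata_mask[row, col]
        if masked.any():
            bad = np.flatnonzero(masked)
            raise ValueError(f"points on nodata cells at indices {bad.tolist()[:10]}")
        return np.column_stack([self.variables[n][row, col] for n in names])

    def subset(self, names: Sequence[str]) -> "ClimateStack":
        missing = [n for n in names if n not in self.variables]
        if missing:
            raise KeyError(f"variables not in stack: {missing}")
        return ClimateStack(
            variables={n: self.variables[n] for n in names},
            cell_size=self.cell_size,
            origin=self.origin,
            nodata_mask=self.nodata_mask.copy(),
            scenario_id=self.scenario_id,
        )


@dataclass
class OccurrenceSet:
    """Point records (x, y, role, period) with a free-text CRS note."""

    records: pd.DataFrame
    crs_note: str = "cartesian map units"

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records).copy()
        for col, default in (("role", "presence"), ("period", "current")):
            if col not in df.columns:
                df[col] = default
        missing = {"x", "y"} - set(df.columns)
        if missing:
            raise ValueError(f"occurrence table missing columns: {sorted(missing)}")
        bad_roles = set(df["role"]) - set(VALID_ROLES)
        if bad_roles:
            raise ValueError(f"invalid roles: {sorted(bad_roles)}; allowed {VALID_ROLES}")
        if not np.isfinite(df[["x", "y"]].to_numpy(float)).all():
            raise ValueError("non-finite coordinates in occurrence set")
        self.records = df.reset_index(drop=True)[["x", "y", "role", "period"]]

    def __len__(self) -> int:
        return len(self.records)

    @property
    def xy(self) -> tuple[np.ndarray, np.ndarray]:
        return self.records["x"].to_numpy(float), self.records["y"].to_numpy(float)

    def filter(self, role: str | None = None, period: str | None = None) -> "OccurrenceSet":
        df = self.records
        if role is not None:
            df = df[df["role"] == role]
        if period is not None:
            df = df[df["period"] == period]
        return OccurrenceSet(df.reset_index(drop=True), self.crs_note)

    @staticmethod
    def concat(sets: Iterable["OccurrenceSet"]) -> "OccurrenceSet":
        sets = list(sets)
        return OccurrenceSet(pd.concat([s.records for s in sets], ignore_index=True),
                             sets[0].crs_note if sets else "cartesian map units")


@dataclass
class SuitabilityMap:
    """A single habitat-suitability grid in [0, 1] with stack geometry."""

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_mask: np.ndarray | None = None
    model_id: str = "model"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        ok = ~self.nodata_mask
        v = self.values[ok]
        if v.size and (np.nanmin(v) < -1e-9 or np.nanmax(v) > 1 + 1e-9):
            raise ValueError("suitability values outside [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def values_at_points(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        helper = ClimateStack({"v": self.values}, self.cell_size, self.origin,
                              self.nodata_mask, self.model_id)
        return helper.env_at_points(x, y)[:, 0]


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

def write_ascii_grid(values: np.ndarray, path: str | Path, *, cell_size: float,
                     origin: tuple[float, float] = (0.0, 0.0),
                     nodata_mask: np.ndarray | None = None,
                     nodata_value: float = _ASCII_NODATA) -> Path:
    """Write one grid as an ESRI ASCII raster.

    Header keys are emitted in the canonical order
    ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value; row 0 of the
    array is written first (northernmost row).
    """
    values = np.asarray(values, dtype=float)
    nrows, ncols = values.shape
    out = values.copy()
    if nodata_mask is not None:
        out[nodata_mask] = nodata_value
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {origin[0]:.10g}\n")
        fh.write(f"yllcorner {origin[1]:.10g}\n")
        fh.write(f"cellsize {cell_size:.10g}\n")
        fh.write(f"NODATA_value {nodata_value:.10g}\n")
        np.savetxt(fh, out, fmt="%.9g")
    return path


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, np.ndarray, float, tuple[float, float]]:
    """Read an ESRI ASCII raster -> (values, nodata_mask, cell_size, origin)."""
    path = Path(path)
    header: dict[str, float] = {}
    with path.open("r", encoding="utf-8") as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in (
                    "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"):
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
            if key not in header:
                raise ValueError(f"{path}: missing ASCII-grid header key {key}")
        values = np.loadtxt(fh, dtype=float)
    values = np.atleast_2d(values)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (nrows, ncols):
        raise ValueError(f"{path}: data shape {values.shape} != header ({nrows}, {ncols})")
    nodata = header.get("nodata_value", _ASCII_NODATA)
    mask = np.isclose(values, nodata) | ~np.isfinite(values)
    return values, mask, header["cellsize"], (header["xllcorner"], header["yllcorner"])


def write_raster(obj: SuitabilityMap | ClimateStack, path: str | Path,
                 variable: str | None = None) -> Path:
    """Write a suitability map, or one variable of a stack, to an .asc file."""
    if isinstance(obj, ClimateStack):
        if variable is None:
            raise ValueError("variable name required when writing from a ClimateStack")
        values = obj.variables[variable]
    else:
        values = obj.values
    return write_ascii_grid(values, path, cell_size=obj.cell_size, origin=obj.origin,
                            nodata_mask=obj.nodata_mask)


def read_raster_stack(paths: Sequence[str | Path], labels: Sequence[str],
                      scenario_id: str = "scenario") -> ClimateStack:
    """Read single-band ASCII rasters into one stack.

    All layers must share geometry; the nodata mask is the union of the
    per-layer masks (a cell masked anywhere is masked everywhere).
    """
    if len(paths) != len(labels):
        raise ValueError("paths and labels differ in length")
    variables: dict[str, np.ndarray] = {}
    geometry: tuple | None = None
    mask = None
    for path, label in zip(paths, labels):
        values, m, cell_size, origin = read_ascii_grid(path)
        geo = (values.shape, cell_size, origin)
        if geometry is None:
            geometry, mask = geo, m
        elif geo != geometry:
            raise ValueError(f"layer {label!r} ({path}) geometry {geo} != first layer {geometry}")
        else:
            mask = mask | m
        variables[label] = values
    return ClimateStack(variables, geometry[1], geometry[2], mask, scenario_id)


def write_raster_stack(stack: ClimateStack, directory: str | Path) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    return [write_raster(stack, directory / f"{name}.asc", variable=name)
            for name in stack.variable_names]


# ---------------------------------------------------------------------------
# Occurrence CSV I/O
# ---------------------------------------------------------------------------

def read_occurrences(path: str | Path,
                     column_map: Mapping[str, str] | None = None) -> OccurrenceSet:
    """Read an occurrence CSV.

    ``column_map`` maps internal names (x, y, role, period) to file column
    names. x and y are mandatory; role defaults to presence, period to
    current. Rows with non-finite coordinates are dropped with a logged
    count.
    """
    column_map = dict(column_map or {})
    df = pd.read_csv(path)
    cols = {}
    for internal in ("x", "y", "role", "period"):
        src = column_map.get(internal, internal)
        if src in df.columns:
            cols[internal] = df[src]
        elif internal in ("x", "y"):
            raise ValueError(f"{path}: mandatory column {src!r} (for {internal}) not found")
    out = pd.DataFrame(cols)
    xy = out[["x", "y"]].apply(pd.to_numeric, errors="coerce")
    keep = np.isfinite(xy.to_numpy(float)).all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("read_occurrences: dropped %d rows with non-finite coordinates", dropped)
    out = out[keep].reset_index(drop=True)
    out[["x", "y"]] = xy[keep].reset_index(drop=True)
    return OccurrenceSet(out)


def write_occurrences(occ: OccurrenceSet, path: str | Path) -> Path:
    path = Path(path)
    occ.records.to_csv(path, index=False)
    return path


def write_report(report: Mapping, path: str | Path) -> Path:
    """Serialize a report mapping to pretty-printed JSON (numpy-safe)."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2, sort_keys=True, default=_default) + "\n",
                    encoding="utf-8")
    return path
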