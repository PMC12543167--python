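"""Domain types, raster I/O and dataset-harmonization transforms.

The simulation operates on a regular grid.  Row 0 is the northernmost row
and cells are addressed ``(row, col)``, 0-based, matching the usual raster
convention.  Two raster dialects are supported: ESRI ASCII grid
(``.asc``/``.txt``, ``NODATA_value`` honored) and plain (Geo)TIFF via
:mod:`tifffile`.

A landscape is described by its potential natural vegetation (PNV): the
climate-determined climax state a cell would hold absent disturbance.  Five
layers define it — dominant plant functional type (PFT), vegetation
openness (% of the cell not covered by trees or shrubs), net primary
productivity (NPP), the potential maximal plant consumption by wild
megafauna, and a land / water / high-mountain cell classification.  A
pollen-derived reconstruction (openness, dominant PFT, coverage mask)
serves as the calibration target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, ConsistencyError, DomainError, GridFormatError

__all__ = [
    "PFTCategory",
    "CellClass",
    "GridMeta",
    "PnvLandscape",
    "TargetVegetation",
    "TREE_PFTS",
    "WOODY_PFTS",
    "load_grid",
    "write_grid",
    "load_landscape",
    "write_landscape",
    "load_target",
    "write_target",
    "reduce_pft_fractions",
    "harmonize_openness_levels",
]


class PFTCategory(IntEnum):
    """Coarse plant functional type of a grid cell."""

    BARE_GROUND = 0
    HERBS = 1
    SHRUBS = 2
    BROADLEAF_TREES = 3
    NEEDLELEAF_TREES = 4


class CellClass(IntEnum):
    """Physiographic class of a grid cell; only LAND simulates vegetation."""

    LAND = 0
    WATER = 1
    HIGH_MOUNTAIN = 2


#: "Trees" in dominance statistics means broadleaf or needleleaf.
TREE_PFTS = frozenset({PFTCategory.BROADLEAF_TREES, PFTCategory.NEEDLELEAF_TREES})
#: PFTs that carry woody fuel (targets of anthropogenic burning).
WOODY_PFTS = frozenset(
    {PFTCategory.SHRUBS, PFTCategory.BROADLEAF_TREES, PFTCategory.NEEDLELEAF_TREES}
)

#: Tie-break priority for dominant-PFT reduction (woody over open).
_REDUCTION_PRIORITY = (
    PFTCategory.NEEDLELEAF_TREES,
    PFTCategory.BROADLEAF_TREES,
    PFTCategory.SHRUBS,
    PFTCategory.HERBS,
)


@dataclass(frozen=True)
class GridMeta:
    """Georeferencing metadata of a single raster layer.

    Attributes
    ----------
    cellsize : float
        Cell edge length in map units (the production configuration uses
        10 km cells).
    xllcorner, yllcorner : float
        Coordinates of the lower-left corner of the grid.
    nodata : float
        Sentinel written for absent cells.
    """

    cellsize: float = 10_000.0
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    nodata: float = -9999.0


# ---------------------------------------------------------------------------
# Raster I/O
# ---------------------------------------------------------------------------

_ASCII_HEADER_KEYS = {
    "ncols",
    "nrows",
    "xllcorner",
    "yllcorner",
    "xllcenter",
    "yllcenter",
    "cellsize",
    "nodata_value",
}


def load_grid(
    path: str | Path,
    variable: str | None = None,
    expect_shape: tuple[int, int] | None = None,
) -> tuple[np.ndarray, GridMeta]:
    """Read a single raster layer.

    Parameters
    ----------
    path : path-like
        ``.asc``/``.txt`` (ESRI ASCII grid) or ``.tif``/``.tiff``.
    variable : str, optional
        Name used in error messages only.
    expect_shape : (int, int), optional
        Shape of a previously loaded layer; a mismatch raises
        :class:`~humland.errors.ConsistencyError`.

    Returns
    -------
    grid : ndarray of float
        Row-major, row 0 = northernmost row; no-data cells are ``nan``.
    meta : GridMeta
    """
    path = Path(path)
    name = variable or path.stem
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        grid = np.asarray(tifffile.imread(str(path)), dtype=float)
        if grid.ndim != 2:
            raise GridFormatError(f"{name}: expected a single-band TIFF, got shape {grid.shape}")
        meta = GridMeta()
    else:
        grid, meta = _read_ascii_grid(path, name)
    if expect_shape is not None and grid.shape != tuple(expect_shape):
        raise ConsistencyError(
            f"layer {name!r} has shape {grid.shape}, expected {tuple(expect_shape)}"
        )
    return grid, meta


def _read_ascii_grid(path: Path, name: str) -> tuple[np.ndarray, GridMeta]:
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            tokens = line.split()
            if not tokens:
                continue
            key = tokens[0].lower()
            if not data_lines and key in _ASCII_HEADER_KEYS:
                if len(tokens) != 2:
                    raise GridFormatError(f"{name}: malformed header line {line.strip()!r}")
                try:
                    header[key] = float(tokens[1])
                except ValueError as exc:
                    raise GridFormatError(f"{name}: bad header value in {line.strip()!r}") from exc
            else:
                data_lines.append(line)
    for required in ("ncols", "nrows"):
        if required not in header:
            raise GridFormatError(f"{name}: missing {required} in ASCII grid header")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    nodata = header.get("nodata_value", -9999.0)
    rows: list[np.ndarray] = []
    for line in data_lines:
        tokens = line.split()
        try:
            row = np.array([float(t) for t in tokens])
        except ValueError as exc:
            raise GridFormatError(f"{name}: non-numeric token in data row") from exc
        if row.size != ncols:
            raise GridFormatError(
                f"{name}: data row has {row.size} values but NCOLS is {ncols}"
            )
        rows.append(row)
    if len(rows) != nrows:
        raise GridFormatError(f"{name}: found {len(rows)} data rows but NROWS is {nrows}")
    grid = np.vstack(rows) if rows else np.empty((0, ncols))
    grid[grid == nodata] = np.nan
    meta = GridMeta(
        cellsize=header.get("cellsize", 10_000.0),
        xllcorner=header.get("xllcorner", header.get("xllcenter", 0.0)),
        yllcorner=header.get("yllcorner", header.get("yllcenter", 0.0)),
        nodata=nodata,
    )
    return grid, meta


def write_grid(grid: np.ndarray, path: str | Path, meta: GridMeta | None = None) -> None:
    """Write a raster layer readable by :func:`load_grid`.

    ``nan`` cells are written as the no-data sentinel.  The dialect is
    chosen from the file suffix (ASCII grid by default, TIFF for
    ``.tif``/``.tiff``).
    """
    path = Path(path)
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 2:
        raise DomainError(f"grid must be 2-D, got shape {grid.shape}")
    meta = meta or GridMeta()
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(str(path), grid)
        return
    nrows, ncols = grid.shape
    try:
        with open(path, "w") as fh:
            fh.write(f"ncols {ncols}\n")
            fh.write(f"nrows {nrows}\n")
            fh.write(f"xllcorner {meta.xllcorner:.10g}\n")
            fh.write(f"yllcorner {meta.yllcorner:.10g}\n")
            fh.write(f"cellsize {meta.cellsize:.10g}\n")
            fh.write(f"NODATA_value {meta.nodata:.10g}\n")
            out = np.where(np.isnan(grid), meta.nodata, grid)
            for row in out:
                fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write raster to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Landscape containers
# ---------------------------------------------------------------------------


@dataclass
class PnvLandscape:
    """Immutable per-cell potential-natural state of the study area.

    All grids share one shape.  Vegetation layers must be finite on land
    cells; water and high-mountain cells carry no vegetation values used by
    the engine.  A cell missing any required layer is treated as outside
    the study area (reclassified as water at load time).

    Attributes
    ----------
    pnv_pft : ndarray of int8
        :class:`PFTCategory` codes (climax dominant PFT).
    pnv_openness : ndarray of float
        Climax vegetation openness, % in [0, 100].
    pnv_npp : ndarray of float
        Potential natural NPP (mass · area⁻¹ · yr⁻¹, ≥ 0).
    max_consumption : ndarray of float
        Potential maximal megafauna plant consumption (kg · km⁻² · yr⁻¹).
    cell_class : ndarray of int8
        :class:`CellClass` codes.
    human_exclusion : ndarray of bool
        Cells where foragers are absent (no campsites, no hunting
        pressure on megafauna), e.g. the British Isles in Last
        Interglacial runs.
    """

    pnv_pft: np.ndarray
    pnv_openness: np.ndarray
    pnv_npp: np.ndarray
    max_consumption: np.ndarray
    cell_class: np.ndarray
    human_exclusion: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pnv_pft = np.asarray(self.pnv_pft, dtype=np.int8)
        self.pnv_openness = np.asarray(self.pnv_openness, dtype=float)
        self.pnv_npp = np.asarray(self.pnv_npp, dtype=float)
        self.max_consumption = np.asarray(self.max_consumption, dtype=float)
        self.cell_class = np.asarray(self.cell_class, dtype=np.int8)
        if self.human_exclusion is None:
            self.human_exclusion = np.zeros(self.pnv_pft.shape, dtype=bool)
        else:
            self.human_exclusion = np.asarray(self.human_exclusion, dtype=bool)
        shape = self.pnv_pft.shape
        for label in ("pnv_openness", "pnv_npp", "max_consumption", "cell_class", "human_exclusion"):
            if getattr(self, label).shape != shape:
                raise ConsistencyError(f"layer {label} has shape {getattr(self, label).shape}, expected {shape}")
        land = self.land_mask
        for label in ("pnv_openness", "pnv_npp", "max_consumption"):
            if not np.all(np.isfinite(getattr(self, label)[land])):
                raise DomainError(f"layer {label} has non-finite values on land cells")
        if np.any((self.pnv_openness[land] < 0) | (self.pnv_openness[land] > 100)):
            raise DomainError("pnv_openness outside [0, 100] on land cells")
        if np.any(self.pnv_npp[land] < 0) or np.any(self.max_consumption[land] < 0):
            raise DomainError("pnv_npp / max_consumption must be non-negative on land cells")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pnv_pft.shape

    @property
    def n_rows(self) -> int:
        return self.shape[0]

    @property
    def n_cols(self) -> int:
        return self.shape[1]

    @property
    def land_mask(self) -> np.ndarray:
        return self.cell_class == CellClass.LAND


@dataclass
class TargetVegetation:
    """Pollen-based reference vegetation (the calibration target).

    ``target_openness`` and ``target_pft`` are defined wherever
    ``coverage`` is true; other cells are ignored by every comparison.
    """

    target_openness: np.ndarray
    target_pft: np.ndarray
    coverage: np.ndarray

    def __post_init__(self) -> None:
        self.target_openness = np.asarray(self.target_openness, dtype=float)
        self.target_pft = np.asarray(self.target_pft, dtype=np.int8)
        self.coverage = np.asarray(self.coverage, dtype=bool)
        shape = self.target_openness.shape
        if self.target_pft.shape != shape or self.coverage.shape != shape:
            raise ConsistencyError("target layers must share one shape")
        covered = self.coverage
        if not np.all(np.isfinite(self.target_openness[covered])):
            raise DomainError("target_openness undefined on covered cells")
        if np.any((self.target_openness[covered] < 0) | (self.target_openness[covered] > 100)):
            raise DomainError("target_openness outside [0, 100] on covered cells")

    @property
    def shape(self) -> tuple[int, int]:
        return self.target_openness.shape


_LANDSCAPE_LAYERS = ("pnv_pft", "pnv_openness", "pnv_npp", "max_consumption", "cell_class")
_TARGET_LAYERS = ("target_openness", "target_pft", "coverage")


def _find_layer(directory: Path, stem: str) -> Path | None:
    for suffix in (".asc", ".txt", ".tif", ".tiff"):
        candidate = directory / f"{stem}{suffix}"
        if candidate.exists():
            return candidate
    return None


def load_landscape(directory: str | Path) -> PnvLandscape:
    """Assemble a :class:`PnvLandscape` from a directory of rasters.

    Expects one layer per variable named after the landscape fields
    (``pnv_pft.asc`` etc.); ``human_exclusion`` is optional.  Cells with a
    no-data value in any required vegetation layer are reclassified as
    water, i.e. excluded from the simulation.
    """
    directory = Path(directory)
    grids: dict[str, np.ndarray] = {}
    shape: tuple[int, int] | None = None
    for stem in _LANDSCAPE_LAYERS:
        path = _find_layer(directory, stem)
        if path is None:
            raise GridFormatError(f"missing required layer {stem!r} in {directory}")
        grid, _ = load_grid(path, stem, expect_shape=shape)
        grids[stem] = grid
        shape = grid.shape
    exclusion_path = _find_layer(directory, "human_exclusion")
    if exclusion_path is not None:
        excl, _ = load_grid(exclusion_path, "human_exclusion", expect_shape=shape)
        grids["human_exclusion"] = np.nan_to_num(excl) > 0.5
    cell_class = np.nan_to_num(grids["cell_class"], nan=float(CellClass.WATER)).astype(np.int8)
    incomplete = np.zeros(shape, dtype=bool)
    for stem in ("pnv_pft", "pnv_openness", "pnv_npp", "max_consumption"):
        incomplete |= np.isnan(grids[stem])
    cell_class[incomplete & (cell_class == CellClass.LAND)] = CellClass.WATER
    return PnvLandscape(
        pnv_pft=np.nan_to_num(grids["pnv_pft"]).astype(np.int8),
        pnv_openness=np.nan_to_num(grids["pnv_openness"]),
        pnv_npp=np.nan_to_num(grids["pnv_npp"]),
        max_consumption=np.nan_to_num(grids["max_consumption"]),
        cell_class=cell_class,
        human_exclusion=grids.get("human_exclusion"),
    )


def write_landscape(pnv: PnvLandscape, directory: str | Path, meta: GridMeta | None = None) -> None:
    """Write all landscape layers as ASCII grids into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    layers = {
        "pnv_pft": pnv.pnv_pft,
        "pnv_openness": pnv.pnv_openness,
        "pnv_npp": pnv.pnv_npp,
        "max_consumption": pnv.max_consumption,
        "cell_class": pnv.cell_class,
        "human_exclusion": pnv.human_exclusion.astype(float),
    }
    for stem, grid in layers.items():
        write_grid(np.asarray(grid, dtype=float), directory / f"{stem}.asc", meta)


def load_target(directory: str | Path) -> TargetVegetation:
    """Assemble a :class:`TargetVegetation` from a directory of rasters."""
    directory = Path(directory)
    grids: dict[str, np.ndarray] = {}
    shape: tuple[int, int] | None = None
    for stem in _TARGET_LAYERS:
        path = _find_layer(directory, stem)
        if path is None:
            raise GridFormatError(f"missing required layer {stem!r} in {directory}")
        grid, _ = load_grid(path, stem, expect_shape=shape)
        grids[stem] = grid
        shape = grid.shape
    coverage = np.nan_to_num(grids["coverage"]) > 0.5
    coverage &= ~np.isnan(grids["target_openness"]) & ~np.isnan(grids["target_pft"])
    return TargetVegetation(
        target_openness=np.nan_to_num(grids["target_openness"]),
        target_pft=np.nan_to_num(grids["target_pft"]).astype(np.int8),
        coverage=coverage,
    )


def write_target(target: TargetVegetation, directory: str | Path, meta: GridMeta | None = None) -> None:
    """Write all target layers as ASCII grids into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_grid(target.target_openness, directory / "target_openness.asc", meta)
    write_grid(target.target_pft.astype(float), directory / "target_pft.asc", meta)
    write_grid(target.coverage.astype(float), directory / "coverage.asc", meta)


# ---------------------------------------------------------------------------
# Harmonization transforms
# ---------------------------------------------------------------------------


def reduce_pft_fractions(
    fractions: dict[str, np.ndarray | float],
    mapping: dict[str, PFTCategory],
) -> np.ndarray:
    """Reduce fine-PFT cover fractions to the dominant coarse category.

    Dynamic-vegetation-model output typically reports cover fractions for
    a few dozen fine PFTs; the engine works with four vegetated categories
    plus bare ground.  Per cell, the category with the largest summed
    fraction wins; exact ties break by a fixed woody-over-open priority
    (needleleaf > broadleaf > shrubs > herbs) and an all-zero cell is bare
    ground.  The fine-to-coarse correspondence is a user-supplied table.

    Parameters
    ----------
    fractions : dict
        Maps fine PFT name to a scalar or array of non-negative fractions.
    mapping : dict
        Maps each fine PFT name to a vegetated :class:`PFTCategory`.

    Returns
    -------
    ndarray of int8
        Dominant :class:`PFTCategory` per cell (0-d for scalar input).
    """
    if not fractions:
        raise ConfigurationError("fractions must name at least one fine PFT")
    unmapped = sorted(set(fractions) - set(mapping))
    if unmapped:
        raise ConfigurationError(f"fine PFTs missing from mapping: {unmapped}")
    arrays = {name: np.asarray(frac, dtype=float) for name, frac in fractions.items()}
    shape = np.broadcast_shapes(*(a.shape for a in arrays.values()))
    sums = np.zeros((len(_REDUCTION_PRIORITY),) + shape)
    for name, frac in arrays.items():
        if np.any(frac < 0):
            raise DomainError(f"negative fraction for fine PFT {name!r}")
        sums[_REDUCTION_PRIORITY.index(mapping[name])] += frac
    # argmax returns the first maximum, i.e. the highest-priority category.
    winner_idx = np.argmax(sums, axis=0)
    priority_codes = np.array([int(c) for c in _REDUCTION_PRIORITY], dtype=np.int8)
    result = priority_codes[winner_idx]
    result = np.where(np.max(sums, axis=0) == 0, np.int8(PFTCategory.BARE_GROUND), result)
    return result.astype(np.int8)


def harmonize_openness_levels(
    lower_openness: np.ndarray | float, upper_openness: np.ndarray | float
) -> np.ndarray | float:
    """Collapse two-level openness into a single comparable value.

    The PNV source reports openness separately for a lower vertical level
    (herbs, shrubs, bare ground) and an upper level (trees), each in
    [0, 100] — a completely open cell therefore scores 200 combined.  The
    pollen-based target reports one value.  The single harmonized value is
    the smaller of the two levels: the fraction of the area free of both
    trees and shrubs.
    """
    lower = np.asarray(lower_openness, dtype=float)
    upper = np.asarray(upper_openness, dtype=float)
    for name, arr in (("lower_openness", lower), ("upper_openness", upper)):
        if np.any((arr < 0) | (arr > 100) | ~np.isfinite(arr)):
            raise DomainError(f"{name} outside [0, 100]")
    out = np.minimum(lower, upper)
    if np.isscalar(lower_openness) and np.isscalar(upper_openness):
        return float(out)
    return out
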