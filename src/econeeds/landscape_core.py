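"""Shared raster/tabular data model for categorical land-use landscapes.

The package works on six land-use classes, coded 1..6 in a fixed canonical
order (arable, forest, grass, water, residential, industrial-mining-transport).
Grids are plain row-major integer matrices with a scalar cell area in km²;
there is deliberately no geodesy — all area accounting is cell counting, which
makes the whole pipeline projection-agnostic and directly testable on
synthetic landscapes.

Supported raster formats are single-band GeoTIFF (via :mod:`tifffile`) and
ESRI ASCII grid; area vectors travel as CSV with columns ``class,area_km2``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

NODATA = -1
N_CLASSES = 6

#: canonical class order; index i corresponds to code i+1
CLASS_LABELS: tuple[str, ...] = (
    "arable",
    "forest",
    "grass",
    "water",
    "residential",
    "industrial_mining_transport",
)

#: driver -> human-needs group(s); drivers serving two needs appear in both
NEEDS_GROUPS: dict[str, tuple[str, ...]] = {
    "dem": ("security",),
    "pop_density": ("security", "material"),
    "dist_river": ("spiritual",),
    "slope": ("spiritual", "material"),
    "dist_rail": ("material",),
    "dist_road": ("material",),
    "gdp": ("material",),
}


class RasterFormatError(ValueError):
    """Raised for unreadable rasters or codes outside the class map."""


@dataclass
class LandUseGrid:
    """Categorical land-use raster.

    Parameters
    ----------
    codes
        Integer matrix with values in ``{NODATA, 1..6}``.
    cell_area
        Area of one cell in km²; must be positive.
    epoch
        Year label (free-form, e.g. ``2020``).
    """

    codes: np.ndarray
    cell_area: float = 1.0
    epoch: str | int | None = None
    class_labels: tuple[str, ...] = CLASS_LABELS

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int32)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D matrix")
        if self.cell_area <= 0:
            raise ValueError("cell_area must be > 0")
        valid = self.codes != NODATA
        bad = valid & ((self.codes < 1) | (self.codes > N_CLASSES))
        if bad.any():
            raise ValueError(
                f"codes outside 1..{N_CLASSES}: {np.unique(self.codes[bad])}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of non-nodata cells."""
        return self.codes != NODATA

    def comparable(self, other: "LandUseGrid") -> bool:
        return self.shape == other.shape and self.cell_area == other.cell_area

    def copy(self, epoch: str | int | None = None) -> "LandUseGrid":
        return LandUseGrid(
            self.codes.copy(),
            cell_area=self.cell_area,
            epoch=self.epoch if epoch is None else epoch,
            class_labels=self.class_labels,
        )


@dataclass
class AreaVector:
    """Per-class areas in km², ordered as :data:`CLASS_LABELS`."""

    area_km2: np.ndarray
    class_labels: tuple[str, ...] = CLASS_LABELS

    def __post_init__(self) -> None:
        self.area_km2 = np.asarray(self.area_km2, dtype=float)
        if self.area_km2.shape != (N_CLASSES,):
            raise ValueError(f"expected {N_CLASSES} class areas")
        if (self.area_km2 < 0).any():
            raise ValueError("areas must be non-negative")

    @property
    def total(self) -> float:
        return float(self.area_km2.sum())

    def __getitem__(self, label: str) -> float:
        return float(self.area_km2[self.class_labels.index(label)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"class": list(self.class_labels), "area_km2": self.area_km2}
        )

    def to_csv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "AreaVector":
        df = pd.read_csv(path)
        order = {c: i for i, c in enumerate(CLASS_LABELS)}
        df = df.sort_values("class", key=lambda s: s.map(order))
        if list(df["class"]) != list(CLASS_LABELS):
            raise ValueError(f"CSV classes {list(df['class'])} != {CLASS_LABELS}")
        return cls(df["area_km2"].to_numpy())


@dataclass
class RedLineMask:
    """Boolean mask marking cells inside the ecological protection red line."""

    inside: np.ndarray

    def __post_init__(self) -> None:
        self.inside = np.asarray(self.inside)
        if self.inside.dtype != bool:
            raise ValueError("mask must be boolean")

    @property
    def shape(self) -> tuple[int, int]:
        return self.inside.shape


@dataclass
class DriverStack:
    """Co-registered continuous driver surfaces.

    ``surfaces`` maps driver name -> real matrix (all same shape);
    ``needs_group`` maps driver -> tuple of needs-group names.
    """

    surfaces: dict[str, np.ndarray]
    needs_group: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(NEEDS_GROUPS)
    )

    def __post_init__(self) -> None:
        shapes = {s.shape for s in self.surfaces.values()}
        if len(shapes) > 1:
            raise ValueError(f"driver surfaces disagree in shape: {shapes}")
        for name in self.surfaces:
            if not self.needs_group.get(name):
                raise ValueError(f"driver {name!r} assigned to no needs group")

    @property
    def names(self) -> list[str]:
        return sorted(self.surfaces)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.surfaces.values())).shape

    def matrix(self, names: Sequence[str] | None = None) -> np.ndarray:
        """Stack drivers as an (n_cells, n_drivers) design matrix."""
        names = list(names) if names is not None else self.names
        return np.column_stack([self.surfaces[n].ravel() for n in names])


# ---------------------------------------------------------------------------
# raster I/O
# ---------------------------------------------------------------------------

def _write_ascii_grid(path: str | os.PathLike, data: np.ndarray, nodata: int | float) -> None:
    rows, cols = data.shape
    header = (
        f"ncols {cols}\nnrows {rows}\nxllcorner 0.0\nyllcorner 0.0\n"
        f"cellsize 1.0\nNODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt="%d" if np.issubdtype(data.dtype, np.integer) else "%.8g")


def _read_ascii_grid(path: str | os.PathLike) -> tuple[np.ndarray, float]:
    meta: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0][0].isalpha():
            meta[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    data = np.loadtxt(lines[n_header:])
    data = np.atleast_2d(data)
    rows, cols = int(meta["nrows"]), int(meta["ncols"])
    if data.shape != (rows, cols):
        raise RasterFormatError(
            f"{path}: data shape {data.shape} != header ({rows}, {cols})"
        )
    return data, meta.get("nodata_value", float(NODATA))


def write_raster(path: str | os.PathLike, data: np.ndarray, nodata: int | float = NODATA) -> None:
    """Write a single-band raster; format chosen by extension (.tif/.asc)."""
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, data)
    elif ext in (".asc", ".txt"):
        _write_ascii_grid(path, data, nodata)
    else:
        raise RasterFormatError(f"unsupported raster extension: {ext}")


def read_raster(path: str | os.PathLike) -> tuple[np.ndarray, float]:
    """Read a single-band raster, returning (matrix, nodata value)."""
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".tif", ".tiff"):
        import tifffile

        data = tifffile.imread(path)
        if data.ndim != 2:
            raise RasterFormatError(f"{path}: expected single band, got shape {data.shape}")
        return data, float(NODATA)
    if ext in (".asc", ".txt"):
        return _read_ascii_grid(path)
    raise RasterFormatError(f"unsupported raster extension: {ext}")


def write_landuse_grid(path: str | os.PathLike, grid: LandUseGrid) -> None:
    write_raster(path, grid.codes.astype(np.int32), nodata=NODATA)


def read_landuse_grid(
    path: str | os.PathLike,
    class_map: Mapping[int, int] | None = None,
    cell_area: float = 1.0,
    epoch: str | int | None = None,
) -> LandUseGrid:
    """Read a categorical raster and remap raw codes to canonical 1..6.

    ``class_map`` maps raw file codes to canonical codes; by default the
    identity on 1..6. Codes absent from the map raise
    :class:`RasterFormatError`; nodata is preserved.
    """
    try:
        data, nodata = read_raster(path)
    except OSError as exc:
        raise RasterFormatError(f"cannot read raster {path}: {exc}") from exc
    codes = np.asarray(np.rint(data), dtype=np.int32)
    nodata = int(nodata)
    if class_map is None:
        class_map = {k: k for k in range(1, N_CLASSES + 1)}
    out = np.full(codes.shape, NODATA, dtype=np.int32)
    is_nodata = codes == nodata
    for raw in np.unique(codes[~is_nodata]):
        if int(raw) not in class_map:
            raise RasterFormatError(f"raster code {int(raw)} not in class_map")
        out[codes == raw] = class_map[int(raw)]
    return LandUseGrid(out, cell_area=cell_area, epoch=epoch)


# ---------------------------------------------------------------------------
# area accounting and agreement
# ---------------------------------------------------------------------------

def class_areas(grid: LandUseGrid) -> AreaVector:
    """Per-class area: cell count × cell area; nodata cells excluded."""
    counts = np.bincount(
        grid.codes[grid.valid].ravel(), minlength=N_CLASSES + 1
    )[1 : N_CLASSES + 1]
    return AreaVector(counts * grid.cell_area, class_labels=grid.class_labels)


def kappa_agreement(a: LandUseGrid, b: LandUseGrid) -> float:
    """Cohen's kappa between two comparable categorical grids.

    Computed over cells valid in both grids: ``(p_o - p_e) / (1 - p_e)``
    with expected agreement ``p_e`` from the marginal class frequencies.
    """
    if not a.comparable(b):
        raise ValueError("grids are not comparable (shape or cell_area differ)")
    joint = a.valid & b.valid
    n = int(joint.sum())
    if n == 0:
        raise ValueError("no overlapping valid cells")
    xa = a.codes[joint]
    xb = b.codes[joint]
    confusion = np.zeros((N_CLASSES, N_CLASSES))
    np.add.at(confusion, (xa - 1, xb - 1), 1)
    confusion /= n
    p_o = np.trace(confusion)
    p_e = float(confusion.sum(axis=1) @ confusion.sum(axis=0))
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return float((p_o - p_e) / (1 - p_e))


def apply_mask(grid: LandUseGrid, mask: RedLineMask) -> LandUseGrid:
    """Set cells outside the mask to nodata; inside cells unchanged."""
    if grid.shape != mask.shape:
        raise ValueError(f"grid shape {grid.shape} != mask shape {mask.shape}")
    codes = np.where(mask.inside, grid.codes, NODATA)
    return LandUseGrid(codes, cell_area=grid.cell_area, epoch=grid.epoch,
                       class_labels=grid.class_labels)
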