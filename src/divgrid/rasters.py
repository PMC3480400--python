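"""Grid-aligned raster products and ESRI ASCII grid text I/O.

Rasters are stored with global (col, row) cell indices of the underlying
:class:`~divgrid.grid.GridSpec`, an explicit nodata value (default -9999) and
written as plain-text ESRI ASCII grids (rows north to south, 6 significant
digits), a bit-exact interchange format any GIS reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import GridSpec

NODATA = -9999.0


@dataclass
class DiversityRaster:
    """A per-cell statistic surface aligned to a grid window.

    ``data[r, c]`` holds the value of global cell ``(col0 + c, row0 + r)``
    with row index increasing NORTHWARD internally; the ASCII writer emits
    rows north-to-south as the format requires.
    """

    grid: GridSpec
    col0: int
    row0: int
    data: np.ndarray
    statistic: str = "statistic"
    nodata: float = NODATA

    @property
    def n_cols(self) -> int:
        return self.data.shape[1]

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    def _local(self, col: int, row: int):
        c, r = col - self.col0, row - self.row0
        if not (0 <= c < self.n_cols and 0 <= r < self.n_rows):
            raise ValueError(f"cell ({col}, {row}) outside raster window")
        return c, r

    def set_value(self, col: int, row: int, value: float) -> None:
        c, r = self._local(col, row)
        self.data[r, c] = value

    def get_value(self, col: int, row: int) -> float:
        c, r = self._local(col, row)
        return float(self.data[r, c])

    def values_mask(self) -> np.ndarray:
        return self.data != self.nodata

    def cell_centers(self):
        """All cell centers in the window: ((N, 2) array, list of (col, row))."""
        cols = self.col0 + np.arange(self.n_cols)
        rows = self.row0 + np.arange(self.n_rows)
        cx = self.grid.origin[0] + (cols + 0.5) * self.grid.cell_size
        cy = self.grid.origin[1] + (rows + 0.5) * self.grid.cell_size
        gx, gy = np.meshgrid(cx, cy)
        centers = np.column_stack([gx.ravel(), gy.ravel()])
        cells = [(int(c), int(r)) for r in rows for c in cols]
        return centers, cells

    def to_ascii(self, path) -> None:
        s = self.grid.cell_size
        xll = self.grid.origin[0] + self.col0 * s
        yll = self.grid.origin[1] + self.row0 * s
        with open(path, "w") as fh:
            fh.write(f"ncols {self.n_cols}\n")
            fh.write(f"nrows {self.n_rows}\n")
            fh.write(f"xllcorner {xll:.10g}\n")
            fh.write(f"yllcorner {yll:.10g}\n")
            fh.write(f"cellsize {s:.12g}\n")
            fh.write(f"NODATA_value {self.nodata:.6g}\n")
            for r in range(self.n_rows - 1, -1, -1):
                fh.write(" ".join(f"{v:.6g}" for v in self.data[r]) + "\n")

    @classmethod
    def from_ascii(cls, path, grid: GridSpec | None = None,
                   statistic: str = "statistic") -> "DiversityRaster":
        header = {}
        rows = []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                if len(parts) == 2 and not _is_number(parts[0]):
                    header[parts[0].lower()] = float(parts[1])
                else:
                    rows.append([float(v) for v in parts])
        data = np.array(rows)[::-1]  # back to south-up
        s = header["cellsize"]
        if grid is None:
            grid = GridSpec(cell_size=s)
        col0 = int(round((header["xllcorner"] - grid.origin[0]) / s))
        row0 = int(round((header["yllcorner"] - grid.origin[1]) / s))
        return cls(grid=grid, col0=col0, row0=row0, data=data,
                   statistic=statistic, nodata=header.get("nodata_value", NODATA))

    def to_png(self, path, cmap: str = "viridis") -> None:
        """Quicklook image (nodata transparent)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        img = np.ma.masked_equal(self.data[::-1], self.nodata)
        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(img, cmap=cmap)
        fig.colorbar(im, ax=ax, label=self.statistic)
        ax.set_title(self.statistic)
        fig.savefig(path, dpi=120)
        plt.close(fig)


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def _empty_window(grid: GridSpec, col_min, col_max, row_min, row_max,
                  statistic: str, nodata: float = NODATA) -> DiversityRaster:
    data = np.full((row_max - row_min + 1, col_max - col_min + 1), nodata)
    return DiversityRaster(grid=grid, col0=int(col_min), row0=int(row_min),
                           data=data, statistic=statistic, nodata=nodata)


def raster_grid_for_points(coords, grid: GridSpec, pad: float = 0.0,
                           statistic_name: str = "statistic") -> DiversityRaster:
    """Empty raster window covering the points inflated by ``pad`` degrees."""
    coords = np.asarray(coords, dtype=float)
    s = grid.cell_size
    col_min = int(np.floor((coords[:, 0].min() - pad - grid.origin[0]) / s))
    col_max = int(np.floor((coords[:, 0].max() + pad - grid.origin[0]) / s))
    row_min = int(np.floor((coords[:, 1].min() - pad - grid.origin[1]) / s))
    row_max = int(np.floor((coords[:, 1].max() + pad - grid.origin[1]) / s))
    return _empty_window(grid, col_min, col_max, row_min, row_max, statistic_name)


def diversity_raster(cell_table: pd.DataFrame, grid: GridSpec,
                     statistic: str) -> DiversityRaster:
    """Place a per-cell statistic column on the grid (unfilled cells nodata).

    ``cell_table`` is indexed by (cell_col, cell_row) as produced by
    :func:`divgrid.bootstrap.gridwide_bootstrap`.
    """
    if statistic not in cell_table.columns:
        raise ValueError(f"no column {statistic!r} in cell table")
    cols = cell_table.index.get_level_values(0).to_numpy()
    rows = cell_table.index.get_level_values(1).to_numpy()
    raster = _empty_window(grid, cols.min(), cols.max(), rows.min(), rows.max(),
                           statistic)
    for (c, r), v in cell_table[statistic].items():
        raster.set_value(int(c), int(r), float(v))
    return raster


def cluster_membership_raster(model, coords, grid: GridSpec, diameter: float = 1.0,
                              threshold: float = 0.7) -> dict:
    """Per cluster: raster of the highest qualifying membership near each cell.

    A cell carries, for cluster j, the MAX membership among individuals
    within ``diameter/2`` of the cell center whose membership for j is at
    least ``threshold``; no qualifying individual means nodata.
    """
    from scipy.spatial import cKDTree

    coords = np.asarray(coords, dtype=float)
    member = np.asarray(model.membership, dtype=float)
    rasters = {}
    tree = cKDTree(coords)
    template = raster_grid_for_points(coords, grid, pad=diameter / 2.0)
    centers, cells = template.cell_centers()
    hits = tree.query_ball_point(centers, r=diameter / 2.0 * (1 + 1e-12))
    for j in range(model.k):
        raster = raster_grid_for_points(coords, grid, pad=diameter / 2.0,
                                        statistic_name=f"membership_cluster_{j}")
        mj = member[:, j]
        for (col, row), idx in zip(cells, hits):
            if not idx:
                continue
            vals = mj[idx]
            vals = vals[vals >= threshold]
            if vals.size:
                raster.set_value(col, row, float(vals.max()))
        rasters[j] = raster
    return rasters


def cluster_richness_raster(membership_rasters: dict) -> DiversityRaster:
    """Number of clusters present (non-nodata) per cell; zero -> nodata."""
    rasters = list(membership_rasters.values())
    first = rasters[0]
    for r in rasters[1:]:
        if (r.col0, r.row0, r.data.shape, r.grid.cell_size) != \
           (first.col0, first.row0, first.data.shape, first.grid.cell_size):
            raise ValueError("membership rasters are not on a shared grid window")
    counts = sum(r.values_mask().astype(int) for r in rasters)
    data = np.where(counts > 0, counts.astype(float), NODATA)
    return DiversityRaster(grid=first.grid, col0=first.col0, row0=first.row0,
                           data=data, statistic="cluster_richness", nodata=NODATA)
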