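"""stdev*coeff contour grids and favored/disfavored level extraction.

For each lattice column of a chosen field the product of the column's
standard deviation and its PLS coefficient is mapped back onto the
lattice (filtered-out columns contribute zero).  Favored and disfavored
iso-levels are the 80% and 20% linear-interpolation quantiles of the
nonzero grid values; points at or beyond those levels form the contour
point sets that, exported as cube/dx files, reproduce the classical
green/yellow (steric) and blue/red (electrostatic) QSAR maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

from fieldqsar import volio
from fieldqsar.fields import Lattice
from fieldqsar.qsar_pls import DescriptorMatrix, PLSModel

__all__ = ["ContourSet", "stdev_coeff_grid", "contour_levels", "extract_contours", "export_contours"]


@dataclass
class ContourSet:
    """A stdev*coeff grid with its favored/disfavored levels and point sets."""

    field: str
    lattice: Lattice
    grid: np.ndarray
    favored_level: float
    disfavored_level: float
    favored_points: np.ndarray
    disfavored_points: np.ndarray

    def __post_init__(self) -> None:
        if self.favored_level < self.disfavored_level:
            raise ValueError("favored level must be >= disfavored level")


def stdev_coeff_grid(model: PLSModel, dm: DescriptorMatrix, field: str) -> np.ndarray:
    """Per-lattice-point std_j * coeff_j for one field (0 at masked columns)."""
    blocks = dm.column_blocks()
    sel_field = blocks == field
    if not sel_field.any():
        raise ValueError(f"field {field!r} not present in the descriptor matrix")
    stds_all = dm.values.std(axis=0)
    coef_full = np.zeros(dm.n_columns)
    coef_full[dm.retained_mask] = model.coefficients
    product = stds_all * coef_full
    product[~dm.retained_mask] = 0.0
    n_points = int(sel_field.sum())
    grid = np.zeros(n_points)
    for meta, val in zip(
        [m for m, s in zip(dm.column_meta, sel_field) if s], product[sel_field]
    ):
        grid[int(meta[1])] = val
    return grid


def contour_levels(
    grid: np.ndarray, favored_pct: float = 0.80, disfavored_pct: float = 0.20
) -> tuple[float, float]:
    """Favored/disfavored levels as quantiles of the nonzero grid values."""
    grid = np.asarray(grid, dtype=float)
    nz = grid[grid != 0.0]
    if nz.size == 0:
        raise ValueError("grid is all zero; no contour levels can be derived")
    if np.ptp(nz) == 0:
        raise ValueError("grid is constant; no contour levels can be derived")
    fav = float(np.quantile(nz, favored_pct, method="linear"))
    dis = float(np.quantile(nz, disfavored_pct, method="linear"))
    return fav, dis


def extract_contours(
    model: PLSModel,
    dm: DescriptorMatrix,
    field: str,
    lattice: Lattice,
    favored_pct: float = 0.80,
    disfavored_pct: float = 0.20,
) -> ContourSet:
    """Build the full contour set for one field."""
    grid = stdev_coeff_grid(model, dm, field)
    fav, dis = contour_levels(grid, favored_pct, disfavored_pct)
    # masked columns (grid value exactly 0) carry no model information
    # and are excluded from both point sets, as from the quantiles
    favored = np.nonzero((grid >= fav) & (grid != 0.0))[0]
    disfavored = np.nonzero((grid <= dis) & (grid != 0.0))[0]
    return ContourSet(
        field=field,
        lattice=lattice,
        grid=grid,
        favored_level=fav,
        disfavored_level=dis,
        favored_points=favored,
        disfavored_points=disfavored,
    )


def export_contours(
    cs: ContourSet, path: str | Path, fmt: Literal["cube", "dx"] = "cube"
) -> None:
    """Write the stdev*coeff grid with the levels noted in the header."""
    comment = (
        f"field={cs.field} favored_level={cs.favored_level:.6g} "
        f"disfavored_level={cs.disfavored_level:.6g}"
    )
    if fmt == "cube":
        volio.write_cube(cs.lattice, cs.grid, path, comment)
    elif fmt == "dx":
        volio.write_dx(cs.lattice, cs.grid, path, comment)
    else:
        raise ValueError(f"unknown format {fmt!r}")
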