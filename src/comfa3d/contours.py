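"""StDev*Coeff contour maps from a fitted PLS model.

The displayed quantity at each lattice point is the product of the
descriptor column's standard deviation and its PLS regression coefficient:
regions where this product is large and positive mark field values whose
increase is associated with higher activity (sterically favored / where
positive charge helps), large negative values mark the opposite. Masked
(filtered-out) columns are exactly zero in the map. Default contour levels
sit at the 80th (favored) and 20th (disfavored) percentiles of the
retained-column values, which is the common display convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from gridData import Grid

from .fields import FIELD_NAMES, FieldMatrix, GridSpec
from .pls import PLSModel

__all__ = ["ContourMap", "stdev_coeff_map", "export_dx", "read_dx", "region_report"]


class ContourError(ValueError):
    pass


@dataclass
class ContourMap:
    grid: GridSpec
    field: str
    values: np.ndarray  # flat, one per lattice point; masked columns == 0
    favored_level: float
    disfavored_level: float

    def __post_init__(self) -> None:
        if self.favored_level < self.disfavored_level:
            raise ContourError("favored level below disfavored level")

    def values3d(self) -> np.ndarray:
        return self.values.reshape(self.grid.dims)

    def favored_mask(self) -> np.ndarray:
        return self.values >= self.favored_level

    def disfavored_mask(self) -> np.ndarray:
        return self.values <= self.disfavored_level


def stdev_coeff_map(
    model: PLSModel,
    fields: FieldMatrix,
    field: str,
    favored_percentile: float = 80.0,
    disfavored_percentile: float = 20.0,
) -> ContourMap:
    """Scatter StDev*Coeff values of one field back onto the lattice."""
    if field not in FIELD_NAMES:
        raise ContourError(f"unknown field {field!r}; expected one of {FIELD_NAMES}")
    sigma = fields.column_stdevs()
    contrib = sigma * model.coefficients
    block = fields.block_of_column()
    f_idx = FIELD_NAMES.index(field)
    values = np.zeros(fields.grid.n_points)
    labels = fields.column_labels()
    field_vals = []
    for col, (name, point) in enumerate(labels):
        if block[col] == f_idx:
            values[point] = contrib[col]
            field_vals.append(contrib[col])
    if field_vals:
        favored = float(np.percentile(field_vals, favored_percentile))
        disfavored = float(np.percentile(field_vals, disfavored_percentile))
    else:
        favored = disfavored = 0.0
    if favored < disfavored:
        favored, disfavored = disfavored, favored
    return ContourMap(
        grid=fields.grid,
        field=field,
        values=values,
        favored_level=favored,
        disfavored_level=disfavored,
    )


def export_dx(cmap: ContourMap, path: str | Path) -> None:
    """Write the map as an OpenDX scalar field (.dx)."""
    g = Grid(
        cmap.values3d(),
        origin=np.asarray(cmap.grid.origin, dtype=float),
        delta=cmap.grid.spacing,
    )
    g.export(str(path), file_format="dx")


def read_dx(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a .dx scalar field back: (values3d, origin, delta)."""
    g = Grid(str(path))
    return np.asarray(g.grid), np.asarray(g.origin), np.asarray(g.delta)


def region_report(
    maps: Sequence[ContourMap],
    regions: Mapping[str, np.ndarray],
) -> list[dict]:
    """Summarize each named lattice region against each map.

    ``regions`` maps a name to a boolean mask over flattened lattice points
    (or an index array). Reports mean StDev*Coeff plus the fraction of
    region points at or beyond the favored/disfavored levels.
    """
    rows = []
    for cmap in maps:
        n_pts = cmap.grid.n_points
        for name, mask in regions.items():
            mask = np.asarray(mask)
            if mask.dtype != bool:
                idx = mask.astype(int).ravel()
                if idx.size and (idx.min() < 0 or idx.max() >= n_pts):
                    raise ContourError(f"region {name!r}: index out of grid bounds")
                bmask = np.zeros(n_pts, dtype=bool)
                bmask[idx] = True
                mask = bmask
            if mask.shape != (n_pts,):
                raise ContourError(
                    f"region {name!r}: mask shape {mask.shape} != ({n_pts},)"
                )
            if not mask.any():
                raise ContourError(f"region {name!r} is empty")
            vals = cmap.values[mask]
            rows.append(
                {
                    "field": cmap.field,
                    "region": name,
                    "n_points": int(mask.sum()),
                    "mean_value": float(vals.mean()),
                    "frac_favored": float((vals >= cmap.favored_level).mean()),
                    "frac_disfavored": float((vals <= cmap.disfavored_level).mean()),
                }
            )
    return rows
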