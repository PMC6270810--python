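"""Molecular interaction fields on a lattice (the CoMFA descriptor block).

For every aligned molecule, a probe atom (sp3-carbon-like, +1 charge by
convention) is placed at each point of a rectangular lattice and two
interaction energies are recorded:

* steric: Lennard-Jones 6-12, ``sum eps_ij * ((r*_ij/d)^12 - 2 (r*_ij/d)^6)``
  with ``r*_ij`` the sum of probe and atom radii and
  ``eps_ij = sqrt(eps_probe * eps_atom)``;
* electrostatic: Coulomb with a distance-dependent dielectric (D = d, so
  the energy falls off as 1/d^2), ``sum 332.0 * q_i * q_probe / d^2``.

Values are truncated to ±cap (default 30 kcal/mol). Lattice points buried
inside a molecule (steric at the cap) carry no usable electrostatic signal;
their electrostatic entries are replaced by the column mean over the
non-buried molecules. Columns whose standard deviation falls below the
column filter (default 2.0 kcal/mol) are masked out of the descriptor
space, and each field block may be weighted by the inverse of its overall
standard deviation so neither field dominates purely through its units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .molecules import Molecule

__all__ = [
    "GridSpec",
    "ProbeSpec",
    "FieldMatrix",
    "make_grid",
    "steric_energy",
    "electrostatic_energy",
    "build_field_matrix",
]

COULOMB_CONSTANT = 332.0
FIELD_NAMES = ("steric", "electrostatic")


class FieldError(ValueError):
    pass


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned lattice: origin (Å), uniform spacing (Å), point counts."""

    origin: tuple[float, float, float]
    spacing: float
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise FieldError("spacing must be positive")
        if any(d < 1 for d in self.dims):
            raise FieldError("dims must each be >= 1")

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def points(self) -> np.ndarray:
        """All lattice coordinates, shape (n_points, 3), x fastest-varying last."""
        axes = [
            self.origin[k] + self.spacing * np.arange(self.dims[k])
            for k in range(3)
        ]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def index_to_point(self, ijk: Sequence[int]) -> np.ndarray:
        return np.asarray(self.origin) + self.spacing * np.asarray(ijk)

    def flat_index(self, ijk: Sequence[int]) -> int:
        i, j, k = ijk
        _, ny, nz = self.dims
        return (i * ny + j) * nz + k

    def unflatten(self, flat: int) -> tuple[int, int, int]:
        _, ny, nz = self.dims
        i, rem = divmod(flat, ny * nz)
        j, k = divmod(rem, nz)
        return i, j, k


@dataclass(frozen=True)
class ProbeSpec:
    """Probe atom: sp3-carbon vdW parameters and unit positive charge."""

    vdw_radius: float = 1.70
    vdw_epsilon: float = 0.107
    charge: float = 1.0

    def __post_init__(self) -> None:
        if self.vdw_radius <= 0 or self.vdw_epsilon < 0:
            raise FieldError("probe radius must be > 0 and epsilon >= 0")


def make_grid(mols: Sequence[Molecule], spacing: float = 2.0,
              margin: float = 4.0) -> GridSpec:
    """Lattice covering the union bounding box of all molecules plus margin.

    Bounds are snapped outward to whole multiples of the spacing, so
    translating every molecule by a lattice vector translates the grid
    identically.
    """
    if not mols:
        raise FieldError("need at least one molecule to define a grid")
    all_xyz = np.vstack([m.coords for m in mols])
    lo = np.floor((all_xyz.min(axis=0) - margin) / spacing) * spacing
    hi = np.ceil((all_xyz.max(axis=0) + margin) / spacing) * spacing
    dims = tuple(int(round((h - l) / spacing)) + 1 for l, h in zip(lo, hi))
    return GridSpec(origin=tuple(lo), spacing=spacing, dims=dims)


# ---------------------------------------------------------------------------
# probe energies

def _distances(points: np.ndarray, coords: np.ndarray) -> np.ndarray:
    diff = points[:, None, :] - coords[None, :, :]
    return np.sqrt(np.sum(diff * diff, axis=-1))


def steric_field(points: np.ndarray, mol: Molecule,
                 probe: ProbeSpec = ProbeSpec(),
                 cap: float = 30.0) -> np.ndarray:
    """LJ probe energy at each point, truncated to [-cap, +cap]."""
    radii = np.array([a.vdw_radius for a in mol.atoms], dtype=float)
    eps = np.array([a.vdw_epsilon for a in mol.atoms], dtype=float)
    if np.any(np.isnan(radii)) or np.any(np.isnan(eps)):
        raise FieldError(f"{mol.id}: vdW parameters not assigned")
    d = np.maximum(_distances(np.atleast_2d(points), mol.coords), 1e-12)
    rstar = probe.vdw_radius + radii
    eij = np.sqrt(probe.vdw_epsilon * eps)
    ratio6 = (rstar[None, :] / d) ** 6
    e = np.sum(eij[None, :] * (ratio6**2 - 2.0 * ratio6), axis=1)
    return np.clip(e, -cap, cap)


def electrostatic_field(points: np.ndarray, mol: Molecule,
                        probe: ProbeSpec = ProbeSpec(),
                        cap: float = 30.0) -> np.ndarray:
    """Coulomb probe energy (1/d^2, distance-dependent dielectric), ±cap."""
    q = mol.charges
    d = np.maximum(_distances(np.atleast_2d(points), mol.coords), 1e-12)
    e = np.sum(COULOMB_CONSTANT * q[None, :] * probe.charge / d**2, axis=1)
    return np.clip(e, -cap, cap)


def steric_energy(point: Sequence[float], mol: Molecule,
                  probe: ProbeSpec = ProbeSpec(), cap: float = 30.0) -> float:
    """Steric probe energy at a single point (kcal/mol)."""
    return float(steric_field(np.asarray(point, float)[None, :], mol, probe, cap)[0])


def electrostatic_energy(point: Sequence[float], mol: Molecule,
                         probe: ProbeSpec = ProbeSpec(),
                         cap: float = 30.0) -> float:
    """Electrostatic probe energy at a single point (kcal/mol)."""
    return float(
        electrostatic_field(np.asarray(point, float)[None, :], mol, probe, cap)[0]
    )


# ---------------------------------------------------------------------------
# descriptor matrix

@dataclass
class FieldMatrix:
    """Molecules × lattice-points descriptor block for both fields.

    ``steric``/``electrostatic`` hold the full (n_molecules, n_points)
    energy matrices; ``column_mask`` (2, n_points) is True for columns that
    survive the column filter; ``block_weights`` scale each field block in
    the descriptor matrix handed to PLS.
    """

    grid: GridSpec
    molecule_ids: list[str]
    steric: np.ndarray
    electrostatic: np.ndarray
    column_mask: np.ndarray
    block_weights: tuple[float, float]
    cap: float
    filter_sigma: float

    def _blocks(self) -> tuple[np.ndarray, np.ndarray]:
        return self.steric, self.electrostatic

    @property
    def n_retained(self) -> int:
        return int(self.column_mask.sum())

    def column_labels(self) -> list[tuple[str, int]]:
        """(field_name, flat_point_index) per retained descriptor column."""
        labels = []
        for f, name in enumerate(FIELD_NAMES):
            for p in np.flatnonzero(self.column_mask[f]):
                labels.append((name, int(p)))
        return labels

    def descriptor_matrix(self) -> np.ndarray:
        """Masked, block-weighted matrix (n_molecules, n_retained)."""
        parts = []
        for f, (block, w) in enumerate(zip(self._blocks(), self.block_weights)):
            cols = np.flatnonzero(self.column_mask[f])
            if cols.size:
                parts.append(block[:, cols] * w)
        if not parts:
            raise FieldError("no retained columns")
        return np.hstack(parts)

    def column_stdevs(self) -> np.ndarray:
        """Standard deviation of each retained descriptor column (weighted)."""
        X = self.descriptor_matrix()
        return X.std(axis=0, ddof=1)

    def block_of_column(self) -> np.ndarray:
        """0 (steric) / 1 (electrostatic) per retained descriptor column."""
        out = []
        for f in range(2):
            out.extend([f] * int(self.column_mask[f].sum()))
        return np.array(out)


def build_field_matrix(
    mols: Sequence[Molecule],
    grid: GridSpec,
    probe: ProbeSpec = ProbeSpec(),
    cap: float = 30.0,
    filter_sigma: float = 2.0,
    block_scaling: Literal["inverse_stdev", "none"] = "inverse_stdev",
) -> FieldMatrix:
    """Evaluate both fields for every molecule and assemble the descriptors.

    Applies, in order: energy truncation at ±cap; replacement of
    electrostatic values at buried points (steric == cap) by the column
    mean over non-buried molecules; the minimum-sigma column filter; and
    block weighting (``inverse_stdev``: each block scaled by 1/std over its
    retained entries; ``none``: weights of 1).
    """
    if not mols:
        raise FieldError("empty molecule list")
    points = grid.points()
    steric = np.vstack([steric_field(points, m, probe, cap) for m in mols])
    elec = np.vstack([electrostatic_field(points, m, probe, cap) for m in mols])

    buried = steric >= cap
    for col in range(elec.shape[1]):
        hit = buried[:, col]
        if hit.any():
            free = ~hit
            elec[hit, col] = elec[free, col].mean() if free.any() else 0.0

    mask = np.empty((2, grid.n_points), dtype=bool)
    for f, block in enumerate((steric, elec)):
        sigma = block.std(axis=0, ddof=1) if block.shape[0] > 1 else np.zeros(block.shape[1])
        mask[f] = sigma >= filter_sigma
    if not mask.any():
        raise FieldError(
            f"column filter {filter_sigma} kcal/mol masked every column; "
            "use a smaller filter_sigma"
        )

    weights = [1.0, 1.0]
    if block_scaling == "inverse_stdev":
        for f, block in enumerate((steric, elec)):
            cols = np.flatnonzero(mask[f])
            if cols.size:
                s = block[:, cols].std(ddof=1)
                weights[f] = 1.0 / s if s > 0 else 1.0
    elif block_scaling != "none":
        raise FieldError(f"unknown block_scaling {block_scaling!r}")

    return FieldMatrix(
        grid=grid,
        molecule_ids=[m.id for m in mols],
        steric=steric,
        electrostatic=elec,
        column_mask=mask,
        block_weights=(weights[0], weights[1]),
        cap=cap,
        filter_sigma=filter_sigma,
    )
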