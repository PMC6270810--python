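"""Conformer preparation: energy model, minimization, annealing, alignment.

The energy model is a deliberately light force field for pose relaxation:
Lennard-Jones 6-12 plus Coulomb nonbonded terms (1-2 and 1-3 pairs
excluded, distance-dependent dielectric) and a generic threefold torsion
barrier on every proper torsion. There are no bond-stretch or angle-bend
terms; minimization is therefore most meaningful for relaxing nonbonded
contacts, and large conformational moves are made in torsion space, where
bond lengths and angles are invariant by construction.

Annealing replaces time-integration molecular dynamics with Metropolis
Monte Carlo over torsion angles: a hot phase at ``t_hot`` followed by a
linear cool to ``t_cold``, one random rotatable bond per step, moves drawn
uniformly in ±30°. Alignment is rigid least-squares superposition (Kabsch)
over an explicit scaffold atom map, restricted to proper rotations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize as _scipy_minimize
from scipy.spatial.transform import Rotation

from .molecules import Molecule

__all__ = [
    "AnnealConfig",
    "MinimizeConfig",
    "ScaffoldMap",
    "energy",
    "EnergyModel",
    "minimize",
    "simulated_anneal",
    "atom_fit",
    "rotatable_bonds",
]

logger = logging.getLogger(__name__)

COULOMB_CONSTANT = 332.0  # kcal·Å/(mol·e²)
BOLTZMANN_KCAL = 0.0019872041  # kcal/(mol·K)
#: generic threefold torsion barrier, kcal/mol (staggered minima)
TORSION_V3 = 0.2
_MIN_DISTANCE = 1e-3  # Å floor against singularities


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class MinimizeConfig:
    max_cycles: int = 1000
    gradient_tol: float = 0.005  # kcal/(mol·Å)

    def __post_init__(self) -> None:
        if self.max_cycles < 1 or self.gradient_tol <= 0:
            raise GeometryError("max_cycles >= 1 and gradient_tol > 0 required")


@dataclass(frozen=True)
class AnnealConfig:
    t_hot: float = 700.0  # K
    t_cold: float = 200.0  # K
    steps_hot: int = 1000
    steps_cold: int = 1000
    seed: int = 0
    max_move_deg: float = 30.0

    def __post_init__(self) -> None:
        if not self.t_hot > self.t_cold > 0:
            raise GeometryError("need t_hot > t_cold > 0")
        if self.steps_hot < 1 or self.steps_cold < 1:
            raise GeometryError("step counts must be >= 1")


@dataclass(frozen=True)
class ScaffoldMap:
    """Explicit atom correspondence (template_index, molecule_index) pairs."""

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.pairs) < 3:
            raise GeometryError("scaffold map needs at least 3 atom pairs")
        t_idx = [p[0] for p in self.pairs]
        m_idx = [p[1] for p in self.pairs]
        if len(set(t_idx)) != len(t_idx) or len(set(m_idx)) != len(m_idx):
            raise GeometryError("scaffold map indices must be unique")

    @classmethod
    def identity(cls, n: int) -> "ScaffoldMap":
        return cls(tuple((i, i) for i in range(n)))

    @classmethod
    def from_file(cls, path: str | Path) -> "ScaffoldMap":
        """Two whitespace-delimited 1-based columns; '#' starts a comment."""
        pairs = []
        for line_no, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            try:
                t, m = line.split()
                pairs.append((int(t) - 1, int(m) - 1))
            except ValueError as exc:
                raise GeometryError(f"{path}:{line_no}: bad map line {raw!r}") from exc
        return cls(tuple(pairs))


# ---------------------------------------------------------------------------
# energy

def _excluded_pairs(mol: Molecule) -> set[tuple[int, int]]:
    """1-2 and 1-3 pairs (directly bonded or sharing a bonded neighbor)."""
    nbrs = mol.neighbors()
    excl: set[tuple[int, int]] = set()
    for i, j, _ in mol.bonds:
        excl.add((min(i, j), max(i, j)))
    for center, around in enumerate(nbrs):
        for a in around:
            for b in around:
                if a < b:
                    excl.add((a, b))
    return excl


def _proper_torsions(mol: Molecule) -> list[tuple[int, int, int, int]]:
    nbrs = mol.neighbors()
    torsions = []
    for j, k, _ in mol.bonds:
        for i in nbrs[j]:
            if i == k:
                continue
            for l in nbrs[k]:
                if l == j or l == i:
                    continue
                torsions.append((i, j, k, l))
    return torsions


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral in radians."""
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    return math.atan2(np.dot(m1, n2), np.dot(n1, n2))


class EnergyModel:
    """Precomputed energy evaluator for one molecule's topology.

    Pair lists, mixed LJ parameters and the proper-torsion list depend only
    on connectivity, so they are built once; evaluation then takes just the
    coordinates. Used heavily by annealing, which calls the energy once per
    Monte Carlo step.
    """

    def __init__(self, mol: Molecule):
        self.mol_id = mol.id
        n = mol.n_atoms
        radii = np.array([a.vdw_radius if a.vdw_radius else 0.0 for a in mol.atoms])
        eps = np.array([a.vdw_epsilon if a.vdw_epsilon else 0.0 for a in mol.atoms])
        q = mol.charges
        excl = _excluded_pairs(mol)
        if n >= 2:
            iu, ju = np.triu_indices(n, k=1)
            keep = np.array([(i, j) not in excl for i, j in zip(iu, ju)])
            self.iu, self.ju = iu[keep], ju[keep]
        else:
            self.iu = self.ju = np.empty(0, dtype=int)
        self.rstar = radii[self.iu] + radii[self.ju]
        self.eij = np.sqrt(eps[self.iu] * eps[self.ju])
        self.qq = COULOMB_CONSTANT * q[self.iu] * q[self.ju]
        self.torsions = np.array(_proper_torsions(mol), dtype=int).reshape(-1, 4)

    def __call__(self, coords: np.ndarray) -> float:
        total = 0.0
        if self.iu.size:
            d = np.linalg.norm(coords[self.iu] - coords[self.ju], axis=1)
            if np.any(d < 1e-6):
                logger.warning("%s: overlapping atoms, distances clamped",
                               self.mol_id)
            d = np.maximum(d, _MIN_DISTANCE)
            ratio6 = (self.rstar / d) ** 6
            total += float(np.sum(self.eij * (ratio6**2 - 2.0 * ratio6)))
            total += float(np.sum(self.qq / d**2))
        if self.torsions.size:
            t = self.torsions
            phi = _dihedral_array(coords[t[:, 0]], coords[t[:, 1]],
                                  coords[t[:, 2]], coords[t[:, 3]])
            total += float(np.sum(0.5 * TORSION_V3 * (1.0 + np.cos(3.0 * phi))))
        return total


def _dihedral_array(p0, p1, p2, p3) -> np.ndarray:
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    b1u = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    m1 = np.cross(n1, b1u)
    return np.arctan2(np.sum(m1 * n2, axis=-1), np.sum(n1 * n2, axis=-1))


def energy(mol: Molecule, coords: np.ndarray | None = None) -> float:
    """Total energy in kcal/mol (LJ + Coulomb + generic torsion)."""
    xyz = mol.coords if coords is None else np.asarray(coords, float)
    return EnergyModel(mol)(xyz)


# ---------------------------------------------------------------------------
# minimization

def minimize(mol: Molecule, cfg: MinimizeConfig | None = None) -> tuple[Molecule, float]:
    """Relax Cartesian coordinates; returns (molecule, final gradient norm).

    L-BFGS on the energy surface, stopping at ``gradient_tol`` (max
    component, kcal/mol/Å) or ``max_cycles``. The returned conformer never
    has higher energy than the input.
    """
    cfg = cfg or MinimizeConfig()
    evaluate = EnergyModel(mol)
    x0 = mol.coords.ravel()
    e0 = evaluate(x0.reshape(-1, 3))

    def objective(x: np.ndarray) -> float:
        value = evaluate(x.reshape(-1, 3))
        if not np.isfinite(value):
            raise GeometryError(f"{mol.id}: non-finite energy during minimization")
        return value

    result = _scipy_minimize(
        objective,
        x0,
        method="L-BFGS-B",
        options={"maxiter": cfg.max_cycles, "gtol": cfg.gradient_tol,
                 "ftol": 1e-12},
    )
    if not np.all(np.isfinite(result.x)):
        raise GeometryError(f"{mol.id}: minimization produced non-finite coordinates")
    out = mol.copy()
    if result.fun <= e0:
        out.coords = result.x.reshape(-1, 3)
    grad_norm = float(np.max(np.abs(result.jac))) if result.jac is not None else math.nan
    return out, grad_norm


# ---------------------------------------------------------------------------
# torsional simulated annealing

def rotatable_bonds(mol: Molecule) -> list[tuple[int, int]]:
    """Single acyclic bonds whose both ends have at least one other neighbor."""
    nbrs = mol.neighbors()
    out = []
    for i, j, order in mol.bonds:
        if order != 1:
            continue
        if len(nbrs[i]) < 2 or len(nbrs[j]) < 2:
            continue
        if _in_cycle(mol, i, j):
            continue
        out.append((i, j))
    return out


def _in_cycle(mol: Molecule, i: int, j: int) -> bool:
    """True if removing bond (i, j) leaves i and j connected."""
    adj = mol.neighbors()
    seen = {i}
    stack = [i]
    while stack:
        cur = stack.pop()
        for nxt in adj[cur]:
            if cur == i and nxt == j:
                continue
            if nxt == j:
                return True
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return False


def _moving_side(mol: Molecule, i: int, j: int) -> list[int]:
    """Atoms reachable from j without crossing bond (i, j); j itself stays
    on the rotation axis and is excluded."""
    adj = mol.neighbors()
    seen = {i, j}
    stack = [j]
    side = []
    while stack:
        cur = stack.pop()
        for nxt in adj[cur]:
            if nxt not in seen:
                seen.add(nxt)
                side.append(nxt)
                stack.append(nxt)
    return side


def rotate_torsion(coords: np.ndarray, i: int, j: int,
                   moving: list[int], angle: float) -> np.ndarray:
    axis = coords[j] - coords[i]
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        raise GeometryError("degenerate bond axis")
    rot = Rotation.from_rotvec(axis / norm * angle)
    out = coords.copy()
    out[moving] = rot.apply(coords[moving] - coords[j]) + coords[j]
    return out


def simulated_anneal(mol: Molecule, cfg: AnnealConfig | None = None) -> Molecule:
    """Metropolis annealing over torsions; deterministic for a fixed seed.

    ``steps_hot`` moves at ``t_hot``, then ``steps_cold`` moves while the
    temperature falls linearly to ``t_cold``. Bond lengths and angles are
    untouched (torsion-only move set). Molecules without rotatable bonds
    are returned unchanged.
    """
    cfg = cfg or AnnealConfig()
    bonds = rotatable_bonds(mol)
    if not bonds:
        logger.info("%s: no rotatable bonds, annealing is a no-op", mol.id)
        return mol.copy()
    movers = {b: _moving_side(mol, *b) for b in bonds}
    rng = np.random.default_rng(cfg.seed)
    evaluate = EnergyModel(mol)
    coords = mol.coords
    current = evaluate(coords)
    max_move = math.radians(cfg.max_move_deg)
    total = cfg.steps_hot + cfg.steps_cold
    for step in range(total):
        if step < cfg.steps_hot:
            temp = cfg.t_hot
        else:
            frac = (step - cfg.steps_hot + 1) / cfg.steps_cold
            temp = cfg.t_hot + frac * (cfg.t_cold - cfg.t_hot)
        bond = bonds[rng.integers(len(bonds))]
        angle = rng.uniform(-max_move, max_move)
        trial = rotate_torsion(coords, *bond, movers[bond], angle)
        e_trial = evaluate(trial)
        delta = e_trial - current
        if delta <= 0 or rng.random() < math.exp(-delta / (BOLTZMANN_KCAL * temp)):
            coords, current = trial, e_trial
    out = mol.copy()
    out.coords = coords
    return out


# ---------------------------------------------------------------------------
# rigid superposition (Kabsch / atom fit)

def atom_fit(mol: Molecule, template: Molecule,
             map: ScaffoldMap) -> tuple[Molecule, float]:
    """Superimpose ``mol`` onto ``template`` over the mapped scaffold atoms.

    Least-squares rigid fit (proper rotation + translation, no reflection);
    the whole molecule is transformed and the RMSD over mapped pairs is
    returned.
    """
    t_idx = [p[0] for p in map.pairs]
    m_idx = [p[1] for p in map.pairs]
    if max(t_idx) >= template.n_atoms or max(m_idx) >= mol.n_atoms:
        raise GeometryError("scaffold map index out of range")
    ref = template.coords[t_idx]
    mov = mol.coords[m_idx]
    ref_c = ref - ref.mean(axis=0)
    if np.linalg.matrix_rank(ref_c, tol=1e-8) < 2:
        raise GeometryError("template scaffold atoms are collinear; fit is degenerate")
    mov_c = mov - mov.mean(axis=0)
    rotation, rssd = Rotation.align_vectors(ref_c, mov_c)
    rmsd = rssd / math.sqrt(len(map.pairs))
    R = rotation.as_matrix()
    translation = ref.mean(axis=0) - R @ mov.mean(axis=0)
    fitted = mol.transformed(R, translation)
    return fitted, float(rmsd)
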