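"""Synthetic aligned molecule sets with known field→activity ground truth.

Real 3D-QSAR series rarely ship machine-readable structures, so this
module builds one from scratch: ~92 molecules sharing a rigid, planar
bicyclic scaffold (a fused 6-5 ring system, 9 heavy atoms, one pyrrole-like
nitrogen) decorated at three attachment regions with pseudo-substituents —
small element-typed groups of 1-6 atoms whose vdW parameters and PEOE
charges are fully determined. Because every molecule carries the scaffold
at identical coordinates, the set is pre-aligned by construction, and
randomly rotated/translated copies are emitted alongside for testing the
alignment stage.

Activities are a sparse linear function of the molecules' own grid-field
values: ``n_hotspots`` informative lattice columns (split between the
steric and electrostatic fields) get weights, the weighted sum is rescaled
so the noiseless activities span ``activity_span_target`` log units
(default 4, matching the dynamic range typical of a binding-affinity
series), centered at pKi 7, and Gaussian noise of ``noise_sigma`` log
units is added. The exact hotspots, weights and noiseless activities are
recorded as ground truth so recovery by the field/PLS/contour pipeline can
be scored.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .affinity import AffinityRecord, AffinityTable
from .fields import FieldMatrix, GridSpec, build_field_matrix, make_grid
from .geometry import ScaffoldMap
from .molecules import (
    Atom,
    Molecule,
    assign_atom_types,
    assign_vdw_params,
    gasteiger_charges,
    write_molecules,
)

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "SyntheticSet",
    "generate",
    "trainsplit",
    "scaffold_template",
    "SUBSTITUENT_LIBRARY",
]


class SyntheticError(ValueError):
    pass


# ---------------------------------------------------------------------------
# scaffold geometry: fused 6-5 bicyclic, planar, 9 heavy atoms

def _pentagon_fused(a: np.ndarray, b: np.ndarray, center: np.ndarray) -> list[np.ndarray]:
    """Three vertices completing a regular pentagon on edge (a, b), on the
    side of the edge away from ``center``."""
    s = np.linalg.norm(b - a)
    mid = (a + b) / 2
    u = (b - a) / s
    n = np.array([-u[1], u[0], 0.0])
    if np.dot(n, mid - center) < 0:
        n = -n
    apothem = s / (2 * math.tan(math.pi / 5))
    radius = s / (2 * math.sin(math.pi / 5))
    pc = mid + apothem * n
    ang_a = math.atan2(a[1] - pc[1], a[0] - pc[0])
    ang_b = math.atan2(b[1] - pc[1], b[0] - pc[0])
    # step from b away from a in 72° increments
    step = 2 * math.pi / 5
    diff = (ang_a - ang_b) % (2 * math.pi)
    direction = 1.0 if not math.isclose(diff, step, abs_tol=1e-6) else -1.0
    return [
        pc + radius * np.array([math.cos(ang_b + direction * step * k),
                                math.sin(ang_b + direction * step * k), 0.0])
        for k in (1, 2, 3)
    ]


def _scaffold_coords() -> np.ndarray:
    hexagon = np.array(
        [[1.4 * math.cos(math.radians(60 * k)),
          1.4 * math.sin(math.radians(60 * k)), 0.0] for k in range(6)]
    )
    penta = _pentagon_fused(hexagon[1], hexagon[0], np.zeros(3))
    return np.vstack([hexagon, penta])


SCAFFOLD_COORDS = _scaffold_coords()
SCAFFOLD_ELEMENTS = ["C", "C", "C", "C", "C", "C", "C", "N", "C"]
# kekulized ring bonds; pentagon atoms are 6, 7, 8 (7 = N)
SCAFFOLD_BONDS = [
    (0, 1, 2), (1, 2, 1), (2, 3, 2), (3, 4, 1), (4, 5, 2), (5, 0, 1),
    (0, 6, 1), (6, 7, 2), (7, 8, 1), (8, 1, 2),
]
N_SCAFFOLD = 9

#: (attachment atom, in-plane outward unit vector) per substitution region
REGIONS: list[tuple[int, np.ndarray]] = [
    (3, SCAFFOLD_COORDS[3] / np.linalg.norm(SCAFFOLD_COORDS[3])),   # benzo edge
    (7, (SCAFFOLD_COORDS[7] - SCAFFOLD_COORDS.mean(axis=0))
        / np.linalg.norm(SCAFFOLD_COORDS[7] - SCAFFOLD_COORDS.mean(axis=0))),  # ring N
    (4, SCAFFOLD_COORDS[4] / np.linalg.norm(SCAFFOLD_COORDS[4])),   # benzo flank
]

# Pseudo-substituents: (name, [(element, local xyz)...]); local +x points
# along the attachment vector, +y in-plane, +z out of the scaffold plane.
SUBSTITUENT_LIBRARY: list[tuple[str, list[tuple[str, tuple[float, float, float]]]]] = [
    ("hydro", [("H", (1.1, 0.0, 0.0))]),
    ("fluoro", [("F", (1.35, 0.0, 0.0))]),
    ("chloro", [("Cl", (1.75, 0.0, 0.0))]),
    ("bromo", [("Br", (1.9, 0.0, 0.0))]),
    ("methyl", [("C", (1.5, 0.0, 0.0))]),
    ("hydroxy", [("O", (1.4, 0.0, 0.0))]),
    ("ethyl", [("C", (1.5, 0.0, 0.0)), ("C", (2.4, 1.2, 0.0))]),
    ("aminomethyl", [("C", (1.5, 0.0, 0.0)), ("N", (2.4, 1.2, 0.0))]),
    ("thioether", [("S", (1.8, 0.0, 0.0)), ("C", (2.9, 1.3, 0.0))]),
    ("propyl", [("C", (1.5, 0.0, 0.0)), ("C", (2.4, 1.2, 0.0)),
                ("C", (3.9, 1.2, 0.0))]),
    ("methoxyethyl", [("C", (1.5, 0.0, 0.0)), ("O", (2.4, 1.1, 0.0)),
                      ("C", (3.8, 1.1, 0.0))]),
    ("isobutyl", [("C", (1.5, 0.0, 0.0)), ("C", (2.4, 1.2, 0.0)),
                  ("C", (3.5, 1.2, 1.1)), ("C", (3.5, 1.2, -1.1))]),
    ("pentyl", [("C", (1.5, 0.0, 0.0)), ("C", (2.4, 1.2, 0.0)),
                ("C", (3.9, 1.2, 0.0)), ("C", (4.8, 0.0, 0.0)),
                ("C", (6.3, 0.0, 0.0))]),
    ("bulky", [("C", (1.5, 0.0, 0.0)), ("C", (2.9, 0.6, 0.0)),
               ("C", (3.6, -0.6, 1.0)), ("C", (3.6, -0.6, -1.0)),
               ("C", (4.4, 1.4, 0.0)), ("C", (5.6, 0.4, 0.0))]),
]


def scaffold_template() -> Molecule:
    """The bare scaffold as a molecule (the alignment template)."""
    atoms = [
        Atom(element=el, coords=xyz.copy())
        for el, xyz in zip(SCAFFOLD_ELEMENTS, SCAFFOLD_COORDS)
    ]
    return Molecule(id="scaffold", atoms=atoms, bonds=list(SCAFFOLD_BONDS))


def scaffold_map() -> ScaffoldMap:
    """Identity correspondence over the 9 scaffold atoms."""
    return ScaffoldMap.identity(N_SCAFFOLD)


# ---------------------------------------------------------------------------
# configuration and outputs

@dataclass(frozen=True)
class GeneratorConfig:
    n_molecules: int = 92
    n_hotspots: int = 4
    noise_sigma: float = 0.2  # log units
    activity_span_target: float = 4.0  # log units
    seed: int = 0
    spacing: float = 2.0
    margin: float = 4.0
    cap: float = 30.0
    hotspot_min_sigma: float = 2.0  # candidate columns must beat this, kcal/mol
    activity_center: float = 7.0  # pKi-like offset

    def __post_init__(self) -> None:
        if self.n_molecules < 10:
            raise SyntheticError("n_molecules must be >= 10")
        if self.noise_sigma < 0:
            raise SyntheticError("noise_sigma must be >= 0")
        if self.n_hotspots < 1:
            raise SyntheticError("n_hotspots must be >= 1")


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside every generated set."""

    hotspots: list[tuple[str, int]]  # (field name, flat lattice index)
    weights: np.ndarray
    noiseless_activity: np.ndarray
    noisy_activity: np.ndarray
    grid: GridSpec

    def hotspot_ijk(self) -> list[tuple[str, tuple[int, int, int]]]:
        return [(f, self.grid.unflatten(p)) for f, p in self.hotspots]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "hotspots": [
                {"field": f, "flat_index": p, "ijk": list(self.grid.unflatten(p))}
                for f, p in self.hotspots
            ],
            "weights": self.weights.tolist(),
            "noiseless_activity": self.noiseless_activity.tolist(),
            "noisy_activity": self.noisy_activity.tolist(),
            "grid": {
                "origin": list(self.grid.origin),
                "spacing": self.grid.spacing,
                "dims": list(self.grid.dims),
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2))


@dataclass
class SyntheticSet:
    molecules: list[Molecule]        # aligned (scaffold at template coords)
    posed: list[Molecule]            # randomly rotated/translated copies
    activities: AffinityTable
    truth: SyntheticTruth
    fields: FieldMatrix              # the raw-field matrix truth was drawn from

    def export(self, outdir: str | Path) -> None:
        """SDF + activity CSV + truth JSON, as consumed by the CLI."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_molecules(self.molecules, outdir / "aligned.sdf")
        write_molecules(self.posed, outdir / "posed.sdf")
        self.activities.to_csv(outdir / "activities.csv")
        self.truth.to_json(outdir / "truth.json")


# ---------------------------------------------------------------------------
# generation

def _build_molecule(mol_id: str, choices: Sequence[int]) -> Molecule:
    atoms = [
        Atom(element=el, coords=xyz.copy())
        for el, xyz in zip(SCAFFOLD_ELEMENTS, SCAFFOLD_COORDS)
    ]
    bonds = list(SCAFFOLD_BONDS)
    for (attach_idx, direction), choice in zip(REGIONS, choices):
        _, group = SUBSTITUENT_LIBRARY[choice]
        xhat = direction
        zhat = np.array([0.0, 0.0, 1.0])
        yhat = np.cross(zhat, xhat)
        frame = np.column_stack([xhat, yhat, zhat])
        base = SCAFFOLD_COORDS[attach_idx]
        prev = attach_idx
        for element, local in group:
            pos = base + frame @ np.asarray(local)
            atoms.append(Atom(element=element, coords=pos))
            bonds.append((prev, len(atoms) - 1, 1))
            prev = len(atoms) - 1
    mol = Molecule(id=mol_id, atoms=atoms, bonds=bonds)
    mol = assign_atom_types(mol)
    mol = assign_vdw_params(mol)
    return gasteiger_charges(mol)


def _pick_hotspots(
    fm: FieldMatrix, cfg: GeneratorConfig, rng: np.random.Generator
) -> list[tuple[str, int]]:
    """Informative, spatially separated columns, split between the fields."""
    n_steric = (cfg.n_hotspots + 1) // 2
    quotas = {"steric": n_steric, "electrostatic": cfg.n_hotspots - n_steric}
    picked: list[tuple[str, int]] = []
    for name, block in (("steric", fm.steric), ("electrostatic", fm.electrostatic)):
        sigma = block.std(axis=0, ddof=1)
        candidates = np.flatnonzero(sigma >= cfg.hotspot_min_sigma)
        if candidates.size == 0:
            continue
        order = candidates[np.argsort(sigma[candidates])[::-1]]
        top = order[: max(quotas[name] * 5, 10)]
        top = rng.permutation(top)
        chosen: list[int] = []
        for col in top:
            ijk = np.array(fm.grid.unflatten(int(col)))
            if all(
                np.abs(ijk - np.array(fm.grid.unflatten(c))).max() > 1
                for c in chosen
            ):
                chosen.append(int(col))
            if len(chosen) == quotas[name]:
                break
        picked.extend((name, c) for c in chosen)
    if not picked:
        raise SyntheticError(
            "no lattice column has enough variance to host a hotspot"
        )
    return picked


def generate(cfg: GeneratorConfig | None = None) -> SyntheticSet:
    """Generate a synthetic study set; deterministic for a fixed seed."""
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)

    n_lib = len(SUBSTITUENT_LIBRARY)
    molecules = []
    for i in range(cfg.n_molecules):
        choices = rng.integers(0, n_lib, size=len(REGIONS))
        molecules.append(_build_molecule(f"syn-{i + 1:03d}", choices))

    grid = make_grid(molecules, spacing=cfg.spacing, margin=cfg.margin)
    fm = build_field_matrix(
        molecules, grid, cap=cfg.cap, filter_sigma=0.0, block_scaling="none"
    )

    hotspots = _pick_hotspots(fm, cfg, rng)
    weights = rng.uniform(0.5, 1.5, size=len(hotspots)) * rng.choice(
        [-1.0, 1.0], size=len(hotspots)
    )
    blocks = {"steric": fm.steric, "electrostatic": fm.electrostatic}
    basis = np.column_stack([blocks[f][:, p] for f, p in hotspots])
    raw = basis @ weights
    span = float(raw.max() - raw.min())
    if span <= 1e-9:
        warnings.warn(
            f"activity span target {cfg.activity_span_target} unreachable; "
            f"achieved span {span:.3g}"
        )
        scale = 1.0
    else:
        scale = cfg.activity_span_target / span
    weights = weights * scale
    noiseless = cfg.activity_center + scale * (raw - raw.mean())
    noisy = noiseless + rng.normal(0.0, cfg.noise_sigma, size=cfg.n_molecules)

    records = [
        AffinityRecord(
            molecule_id=i + 1,
            receptor="SYN",
            ki_nanomolar=10.0 ** (9.0 - noisy[i]),
            pki=float(noisy[i]),
            split="train",
            ki_decimals=6,
        )
        for i in range(cfg.n_molecules)
    ]
    activities = AffinityTable(receptor="SYN", records=records)

    posed = []
    for mol in molecules:
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.uniform(-10.0, 10.0, size=3)
        copy = mol.transformed(rot, shift)
        copy.id = f"{mol.id}-posed"
        posed.append(copy)

    truth = SyntheticTruth(
        hotspots=hotspots,
        weights=weights,
        noiseless_activity=noiseless,
        noisy_activity=noisy,
        grid=grid,
    )
    return SyntheticSet(
        molecules=molecules, posed=posed, activities=activities,
        truth=truth, fields=fm,
    )


# ---------------------------------------------------------------------------
# train/test split

def trainsplit(
    activities: AffinityTable, fraction_test: float, seed: int = 0
) -> AffinityTable:
    """Stratified split: test molecules drawn across the activity range.

    Records are ordered by activity and cut into ``n_test`` contiguous
    strata (n_test = nearest integer to n × fraction_test); one random
    molecule per stratum becomes a test record, so the test set spans the
    activity range by construction.
    """
    if not 0 < fraction_test < 0.5:
        raise SyntheticError("fraction_test must be in (0, 0.5)")
    n = len(activities.records)
    n_test = int(round(n * fraction_test))
    if n_test < 1:
        raise SyntheticError(f"too few molecules ({n}) for fraction {fraction_test}")
    rng = np.random.default_rng(seed)
    order = np.argsort([r.pki for r in activities.records], kind="stable")
    strata = np.array_split(order, n_test)
    if any(len(s) == 0 for s in strata):
        raise SyntheticError("too few molecules per stratum")
    test_idx = {int(rng.choice(s)) for s in strata}
    records = [
        AffinityRecord(
            molecule_id=r.molecule_id, receptor=r.receptor,
            ki_nanomolar=r.ki_nanomolar, pki=r.pki,
            predicted_pki=r.predicted_pki, residual=r.residual,
            split="test" if i in test_idx else "train",
            ki_decimals=r.ki_decimals,
        )
        for i, r in enumerate(activities.records)
    ]
    return AffinityTable(receptor=activities.receptor, records=records)
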