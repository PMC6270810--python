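"""Molecule data model, SDF/MOL2 I/O, vdW parameters and PEOE partial charges.

The in-memory model is deliberately small: an ordered list of atoms with 3D
coordinates (Å), element symbols, per-atom partial charges (e) and van der
Waals parameters (Å, kcal/mol), plus a bond list with integer orders
(1/2/3, 4 = aromatic). File I/O goes through RDKit; real-valued partial
charges ride in an ``ATOM_PARTIAL_CHARGES`` SD property block (V2000 has no
standard real-charge field) and come from the charge column of MOL2 files.

Partial charges are computed by PEOE (partial equalization of orbital
electronegativity): each atom's electronegativity is a quadratic in its
current charge, chi = a + b*q + c*q^2, and every bond transfers charge
toward the more electronegative end, scaled by ``damping**iteration``, so
the transfer series converges geometrically and total charge is conserved
exactly. An optional Hueckel-style pi correction spreads the formal charge
of a conjugated system uniformly over its atoms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem
from rdkit.Geometry import Point3D

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Atom",
    "Molecule",
    "ChargeConfig",
    "read_molecules",
    "write_molecules",
    "assign_vdw_params",
    "gasteiger_charges",
    "assign_atom_types",
    "load_vdw_table",
    "load_peoe_table",
]

CHARGE_PROPERTY = "ATOM_PARTIAL_CHARGES"

#: cation electronegativity used to normalize transfers involving hydrogen
HYDROGEN_CHI_PLUS = 20.02

_BOND_TYPES = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
    4: Chem.BondType.AROMATIC,
}
_BOND_ORDERS = {v: k for k, v in _BOND_TYPES.items()}


class MoleculeError(ValueError):
    pass


class ParseError(MoleculeError):
    pass


class ParameterError(MoleculeError):
    """An element or atom type has no entry in a parameter table."""


@dataclass
class Atom:
    element: str
    coords: np.ndarray
    partial_charge: float = 0.0
    formal_charge: int = 0
    vdw_radius: float | None = None
    vdw_epsilon: float | None = None
    type_label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise MoleculeError(f"bad coordinates for {self.element}: {self.coords}")


@dataclass
class Molecule:
    id: str
    atoms: list[Atom]
    bonds: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, j, order in self.bonds:
            if i == j:
                raise MoleculeError(f"{self.id}: self-bond on atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise MoleculeError(f"{self.id}: bond ({i},{j}) out of range")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def formal_charge(self) -> int:
        return sum(a.formal_charge for a in self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    @coords.setter
    def coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (self.n_atoms, 3):
            raise MoleculeError(f"{self.id}: coords shape {xyz.shape}")
        for atom, row in zip(self.atoms, xyz):
            atom.coords = row.copy()

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms])

    def neighbors(self) -> list[list[int]]:
        nbrs: list[list[int]] = [[] for _ in self.atoms]
        for i, j, _ in self.bonds:
            nbrs[i].append(j)
            nbrs[j].append(i)
        return nbrs

    def copy(self) -> "Molecule":
        return Molecule(
            id=self.id,
            atoms=[replace(a, coords=a.coords.copy()) for a in self.atoms],
            bonds=list(self.bonds),
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Molecule":
        """Return a copy with coordinates mapped through x -> R x + t."""
        out = self.copy()
        out.coords = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        return out


@dataclass(frozen=True)
class ChargeConfig:
    """PEOE settings: damping in (0,1), iteration count, optional pi spread."""

    damping: float = 0.5
    iterations: int = 6
    use_huckel_pi: bool = True
    electronegativity_params: dict[str, tuple[float, float, float]] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.damping < 1:
            raise MoleculeError(f"damping must be in (0,1), got {self.damping}")
        if self.iterations < 1:
            raise MoleculeError("iterations must be >= 1")


# ---------------------------------------------------------------------------
# parameter tables (packaged CSV, swappable)

def load_vdw_table(path: str | Path | None = None) -> pd.DataFrame:
    """Tripos-style per-element vdW radii (Å) and well depths (kcal/mol)."""
    if path is None:
        ref = resources.files("comfa3d.data").joinpath("vdw_params.csv")
        with resources.as_file(ref) as p:
            return pd.read_csv(p).set_index("element")
    return pd.read_csv(path).set_index("element")


def load_peoe_table(path: str | Path | None = None) -> dict[str, tuple[float, float, float]]:
    """PEOE electronegativity coefficients (a, b, c) per atom type."""
    if path is None:
        ref = resources.files("comfa3d.data").joinpath("peoe_params.csv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    return {row.type_label: (row.a, row.b, row.c) for row in df.itertuples()}


def assign_vdw_params(mol: Molecule, table: pd.DataFrame | None = None) -> Molecule:
    """Set vdw_radius/vdw_epsilon per atom from the parameter table.

    Unknown elements raise ParameterError listing every missing symbol; no
    silent defaults are substituted.
    """
    if table is None:
        table = load_vdw_table()
    out = mol.copy()
    missing = sorted({a.element for a in out.atoms if a.element not in table.index})
    if missing:
        raise ParameterError(
            f"{mol.id}: no vdW parameters for element(s) {missing}"
        )
    for atom in out.atoms:
        row = table.loc[atom.element]
        atom.vdw_radius = float(row.vdw_radius)
        atom.vdw_epsilon = float(row.vdw_epsilon)
    return out


# ---------------------------------------------------------------------------
# atom typing

_HALOGENS = {"F", "Cl", "Br", "I"}


def assign_atom_types(mol: Molecule) -> Molecule:
    """Derive simple Tripos-like type labels (C.3, N.ar, O.2, ...) from bonds.

    Typing only looks at the incident bond orders present in the input; no
    aromaticity perception is attempted beyond explicit order-4 bonds.
    """
    out = mol.copy()
    max_order = [0] * out.n_atoms
    n_multi = [0] * out.n_atoms
    for i, j, order in out.bonds:
        for k in (i, j):
            max_order[k] = max(max_order[k], order)
            if order >= 2:
                n_multi[k] += 1
    for idx, atom in enumerate(out.atoms):
        el = atom.element
        if el == "H" or el in _HALOGENS:
            atom.type_label = el
        elif el in ("C", "N"):
            if max_order[idx] == 4:
                atom.type_label = f"{el}.ar"
            elif max_order[idx] == 3 or n_multi[idx] >= 2:
                atom.type_label = f"{el}.1"
            elif max_order[idx] == 2:
                atom.type_label = f"{el}.2"
            else:
                atom.type_label = f"{el}.3"
        elif el == "O":
            atom.type_label = "O.2" if max_order[idx] >= 2 else "O.3"
        elif el in ("S", "P"):
            atom.type_label = f"{el}.3"
        else:
            atom.type_label = el
    return out


# ---------------------------------------------------------------------------
# PEOE partial charges

def gasteiger_charges(mol: Molecule, cfg: ChargeConfig | None = None) -> Molecule:
    """Assign PEOE sigma charges (plus optional uniform pi spread).

    The iteration seeds atom charges with formal charges, then for each
    bond transfers ``(chi_j - chi_i) / chi_plus * damping**k`` toward the
    more electronegative atom, where chi_plus is the cation
    electronegativity (a+b+c) of the donating atom (20.02 for H). Transfers
    are antisymmetric, so the total charge equals the molecular formal
    charge to machine precision.
    """
    cfg = cfg or ChargeConfig()
    params = cfg.electronegativity_params or load_peoe_table()
    out = mol.copy()
    if not any(a.type_label for a in out.atoms):
        out = assign_atom_types(out)

    labels = [a.type_label for a in out.atoms]
    missing = sorted({lab for lab in labels if lab not in params})
    if missing:
        raise ParameterError(f"{mol.id}: no PEOE parameters for type(s) {missing}")
    abc = np.array([params[lab] for lab in labels])
    chi_plus = np.where(
        np.array([a.element for a in out.atoms]) == "H",
        HYDROGEN_CHI_PLUS,
        abc.sum(axis=1),
    )

    q = np.array([float(a.formal_charge) for a in out.atoms])
    pi_charge = np.zeros_like(q)
    if cfg.use_huckel_pi:
        q, pi_charge = _split_pi_charge(out, q)

    for k in range(1, cfg.iterations + 1):
        chi = abc[:, 0] + abc[:, 1] * q + abc[:, 2] * q * q
        damp = cfg.damping**k
        dq = np.zeros_like(q)
        for i, j, _ in out.bonds:
            if chi[j] > chi[i]:
                donor, acceptor = i, j
            else:
                donor, acceptor = j, i
            t = (chi[acceptor] - chi[donor]) / chi_plus[donor] * damp
            dq[donor] += t
            dq[acceptor] -= t
        q = q + dq
        if not np.all(np.isfinite(q)):
            bad = int(np.flatnonzero(~np.isfinite(q))[0])
            raise MoleculeError(
                f"{mol.id}: PEOE diverged at iteration {k} (atom {bad}); "
                "check electronegativity parameters"
            )

    total = q + pi_charge
    for atom, value in zip(out.atoms, total):
        atom.partial_charge = float(value)
    if abs(total.sum() - out.formal_charge) > 1e-3:
        raise MoleculeError(
            f"{mol.id}: charge conservation violated "
            f"({total.sum():.6f} vs formal {out.formal_charge})"
        )
    return out


def _split_pi_charge(mol: Molecule, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Move formal charges of conjugated atoms into a uniform pi component.

    Conjugated systems are connected components over bonds of order >= 2
    (including aromatic order 4). The summed formal charge of each system is
    spread uniformly over its atoms; sigma PEOE then runs with those formal
    charges removed. For neutral systems this is a no-op.
    """
    n = mol.n_atoms
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    in_pi = [False] * n
    for i, j, order in mol.bonds:
        if order >= 2:
            in_pi[i] = in_pi[j] = True
            parent[find(i)] = find(j)

    sigma_q = q.copy()
    pi_q = np.zeros_like(q)
    groups: dict[int, list[int]] = {}
    for idx in range(n):
        if in_pi[idx]:
            groups.setdefault(find(idx), []).append(idx)
    for members in groups.values():
        total = sum(sigma_q[m] for m in members)
        if total != 0:
            share = total / len(members)
            for m in members:
                sigma_q[m] = 0.0
                pi_q[m] = share
    return sigma_q, pi_q


# ---------------------------------------------------------------------------
# RDKit conversion and file I/O

def to_rdkit(mol: Molecule) -> Chem.Mol:
    rw = Chem.RWMol()
    for atom in mol.atoms:
        a = Chem.Atom(atom.element)
        a.SetFormalCharge(atom.formal_charge)
        a.SetNoImplicit(True)
        rw.AddAtom(a)
    for i, j, order in mol.bonds:
        rw.AddBond(i, j, _BOND_TYPES[order])
    conf = Chem.Conformer(mol.n_atoms)
    for idx, atom in enumerate(mol.atoms):
        conf.SetAtomPosition(idx, Point3D(*map(float, atom.coords)))
    rw.AddConformer(conf)
    m = rw.GetMol()
    m.SetProp("_Name", mol.id)
    charges = " ".join(
        f"{idx + 1} {atom.partial_charge:.6f}" for idx, atom in enumerate(mol.atoms)
    )
    m.SetProp(CHARGE_PROPERTY, charges)
    m.UpdatePropertyCache(strict=False)
    return m


def from_rdkit(rdmol: Chem.Mol, mol_id: str | None = None) -> Molecule:
    if rdmol.GetNumConformers() == 0:
        raise ParseError("molecule has no 3D coordinates")
    conf = rdmol.GetConformer()
    atoms = []
    for idx, a in enumerate(rdmol.GetAtoms()):
        pos = conf.GetAtomPosition(idx)
        charge = 0.0
        if a.HasProp("_TriposPartialCharge"):
            charge = a.GetDoubleProp("_TriposPartialCharge")
        atoms.append(
            Atom(
                element=a.GetSymbol(),
                coords=np.array([pos.x, pos.y, pos.z]),
                partial_charge=charge,
                formal_charge=a.GetFormalCharge(),
                type_label=(a.GetProp("_TriposAtomType")
                            if a.HasProp("_TriposAtomType") else ""),
            )
        )
    bonds = []
    for b in rdmol.GetBonds():
        order = _BOND_ORDERS.get(b.GetBondType())
        if order is None:
            order = int(round(b.GetBondTypeAsDouble())) or 1
        bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    name = mol_id
    if name is None:
        name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else "mol"
    out = Molecule(id=name or "mol", atoms=atoms, bonds=bonds)
    if rdmol.HasProp(CHARGE_PROPERTY):
        _apply_charge_property(out, rdmol.GetProp(CHARGE_PROPERTY))
    return out


def _apply_charge_property(mol: Molecule, text: str) -> None:
    tokens = text.split()
    if len(tokens) % 2:
        raise ParseError(f"{mol.id}: malformed {CHARGE_PROPERTY} block")
    for idx_s, q_s in zip(tokens[::2], tokens[1::2]):
        idx = int(idx_s) - 1
        if not 0 <= idx < mol.n_atoms:
            raise ParseError(f"{mol.id}: charge index {idx + 1} out of range")
        mol.atoms[idx].partial_charge = float(q_s)


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt.upper()
    suffix = path.suffix.lower()
    if suffix in (".sdf", ".sd", ".mol"):
        return "SDF"
    if suffix == ".mol2":
        return "MOL2"
    raise ParseError(f"cannot infer format from {path.name}; pass format=")


def read_molecules(path: str | Path, format: str | None = None) -> list[Molecule]:
    """Read molecules from an SDF (V2000) or MOL2 file.

    MOL2 partial charges are imported from the charge column; SDF charges
    come from the ``ATOM_PARTIAL_CHARGES`` property block when present and
    are zero otherwise. Coordinates are in Å throughout.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    text = path.read_text()
    if not text.strip():
        raise ParseError(f"{path}: empty file")
    fmt = _infer_format(path, format)
    mols: list[Molecule] = []
    if fmt == "SDF":
        supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
        for rec, rdmol in enumerate(supplier):
            if rdmol is None:
                raise ParseError(f"{path}: malformed SDF record {rec + 1}")
            mols.append(from_rdkit(rdmol))
    elif fmt == "MOL2":
        for rec, block in enumerate(_split_mol2(text)):
            rdmol = Chem.MolFromMol2Block(block, sanitize=False, removeHs=False)
            if rdmol is None:
                raise ParseError(f"{path}: malformed MOL2 record {rec + 1}")
            mols.append(from_rdkit(rdmol))
    else:
        raise ParseError(f"unsupported format {fmt!r}")
    if not mols:
        raise ParseError(f"{path}: no molecules found")
    return mols


def _split_mol2(text: str) -> list[str]:
    marker = "@<TRIPOS>MOLECULE"
    chunks = text.split(marker)
    return [marker + c for c in chunks[1:]]


def write_molecules(mols: Sequence[Molecule] | Molecule, path: str | Path) -> None:
    """Write molecules to an SDF file, charges in the property block."""
    if isinstance(mols, Molecule):
        mols = [mols]
    path = Path(path)
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for mol in mols:
            writer.write(to_rdkit(mol))
    finally:
        writer.close()
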