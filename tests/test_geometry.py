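import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from comfa3d import geometry as geo
from comfa3d.molecules import Molecule
from conftest import make_atom, make_chain, make_dimer


class TestEnergy:
    def test_single_atom_zero(self):
        mol = Molecule(id="one", atoms=[make_atom()])
        assert geo.energy(mol) == 0.0

    def test_dimer_at_lj_minimum(self):
        """Two neutral atoms at r* separation sit exactly at -sqrt(e1*e2)."""
        e1, e2 = 0.107, 0.4
        mol = make_dimer(3.40, epsilon=0.107)
        mol.atoms[1].vdw_epsilon = e2
        assert geo.energy(mol) == pytest.approx(-math.sqrt(e1 * e2), abs=1e-10)

    def test_five_atom_brute_force(self, rng):
        """Energy equals a hand-summed pairwise loop (independent code path)."""
        coords = rng.uniform(-3, 3, size=(5, 3)) * 1.5 + np.arange(5)[:, None] * 2.0
        charges = rng.uniform(-0.3, 0.3, size=5)
        atoms = [
            make_atom(xyz=c, charge=q, radius=1.6, epsilon=0.2)
            for c, q in zip(coords, charges)
        ]
        mol = Molecule(id="five", atoms=atoms, bonds=[(0, 1, 1), (1, 2, 1)])
        # excluded: 1-2 pairs (0,1),(1,2); 1-3 pair (0,2)
        expected = 0.0
        for i in range(5):
            for j in range(i + 1, 5):
                if (i, j) in {(0, 1), (1, 2), (0, 2)}:
                    continue
                d = np.linalg.norm(coords[i] - coords[j])
                rstar = 3.2
                eij = 0.2
                expected += eij * ((rstar / d) ** 12 - 2 * (rstar / d) ** 6)
                expected += 332.0 * charges[i] * charges[j] / d**2
        # plus the single proper torsion 0-1-2 has no 4th atom: none exist
        assert geo.energy(mol) == pytest.approx(expected, abs=1e-8)

    def test_rigid_motion_invariance(self, rng):
        mol = make_chain(5, torsions_deg={(1, 2): 45})
        e0 = geo.energy(mol)
        for _ in range(5):
            R = Rotation.random(rng=rng).as_matrix()
            t = rng.uniform(-20, 20, 3)
            moved = mol.transformed(R, t)
            assert geo.energy(moved) == pytest.approx(e0, abs=1e-8)


class TestMinimize:
    def test_dimer_reaches_lj_separation(self):
        mol = make_dimer(5.2)
        out, grad = geo.minimize(mol, geo.MinimizeConfig(max_cycles=500))
        d = np.linalg.norm(out.coords[1] - out.coords[0])
        assert d == pytest.approx(3.40, abs=1e-3)

    def test_at_minimum_stays_put(self):
        mol = make_dimer(3.40)
        out, _ = geo.minimize(mol)
        assert np.allclose(out.coords, mol.coords, atol=1e-3)

    def test_descent_property(self, rng):
        """Minimization never raises the energy (50 random perturbations)."""
        for _ in range(50):
            mol = make_chain(5)
            mol.coords = mol.coords + rng.normal(0, 0.4, mol.coords.shape)
            e_in = geo.energy(mol)
            out, _ = geo.minimize(mol, geo.MinimizeConfig(max_cycles=50))
            assert geo.energy(out) <= e_in + 1e-9


class TestRotatableBonds:
    def test_chain_interior_bonds(self):
        mol = make_chain(4)
        assert geo.rotatable_bonds(mol) == [(1, 2)]

    def test_ring_bond_not_rotatable(self):
        atoms = [make_atom(xyz=(math.cos(a), math.sin(a), 0))
                 for a in np.linspace(0, 2 * math.pi, 6, endpoint=False)]
        ring = Molecule(id="ring", atoms=atoms,
                        bonds=[(i, (i + 1) % 6, 1) for i in range(6)])
        assert geo.rotatable_bonds(ring) == []


class TestSimulatedAnneal:
    def test_rigid_ring_is_identity(self):
        atoms = [make_atom(xyz=(2 * math.cos(a), 2 * math.sin(a), 0))
                 for a in np.linspace(0, 2 * math.pi, 6, endpoint=False)]
        ring = Molecule(id="ring", atoms=atoms,
                        bonds=[(i, (i + 1) % 6, 1) for i in range(6)])
        out = geo.simulated_anneal(ring, geo.AnnealConfig(seed=4))
        assert np.array_equal(out.coords, ring.coords)

    def test_seed_reproducibility(self):
        mol = make_chain(5, torsions_deg={(1, 2): 80})
        cfg = geo.AnnealConfig(seed=42, steps_hot=200, steps_cold=200)
        a = geo.simulated_anneal(mol, cfg)
        b = geo.simulated_anneal(mol, cfg)
        assert np.array_equal(a.coords, b.coords)

    def test_bond_lengths_preserved(self):
        mol = make_chain(6, torsions_deg={(1, 2): 70, (3, 4): -50})
        out = geo.simulated_anneal(
            mol, geo.AnnealConfig(seed=0, steps_hot=300, steps_cold=300)
        )
        for i, j, _ in mol.bonds:
            before = np.linalg.norm(mol.coords[i] - mol.coords[j])
            after = np.linalg.norm(out.coords[i] - out.coords[j])
            assert after == pytest.approx(before, abs=1e-9)

    def test_reaches_global_torsion_basin(self):
        """For a bulky 4-atom chain the 1-D torsion scan shows a single
        global basin at anti; annealing should land there from gauche."""
        mol = make_chain(4, radius=2.3, torsions_deg={(1, 2): 120})

        # independent oracle: exhaustive scan over the only torsion
        evaluate = geo.EnergyModel(mol)
        best_phi, best_e = None, np.inf
        base = mol.coords
        for ang in np.linspace(-180, 180, 361):
            trial = geo.rotate_torsion(base, 1, 2, [3], math.radians(ang))
            phi = math.degrees(
                geo.dihedral_angle(trial[0], trial[1], trial[2], trial[3])
            )
            e = evaluate(trial)
            if e < best_e:
                best_phi, best_e = phi, e
        assert abs(best_phi) > 150  # the global minimum is anti

        hits = 0
        n_seeds = 60
        for seed in range(n_seeds):
            out = geo.simulated_anneal(
                mol, geo.AnnealConfig(seed=seed, steps_hot=300, steps_cold=300)
            )
            out, _ = geo.minimize(out, geo.MinimizeConfig(max_cycles=100))
            phi = math.degrees(geo.dihedral_angle(*out.coords))
            if abs(phi) > 120:
                hits += 1
        assert hits >= 0.9 * n_seeds


class TestAtomFit:
    def test_identity_when_already_fitted(self):
        mol = make_chain(5)
        fitted, rmsd = geo.atom_fit(mol, mol, geo.ScaffoldMap.identity(5))
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(fitted.coords, mol.coords, atol=1e-9)

    def test_recovers_random_rigid_transform(self, rng):
        mol = make_chain(6, torsions_deg={(2, 3): 40})
        for _ in range(10):
            R = Rotation.random(rng=rng).as_matrix()
            t = rng.uniform(-15, 15, 3)
            moved = mol.transformed(R, t)
            fitted, rmsd = geo.atom_fit(moved, mol, geo.ScaffoldMap.identity(6))
            assert rmsd < 1e-6
            assert np.allclose(fitted.coords, mol.coords, atol=1e-6)

    def test_reflection_rejected(self):
        mol = make_chain(4, torsions_deg={(1, 2): 60})  # chiral pose
        mirrored = mol.copy()
        xyz = mol.coords.copy()
        xyz[:, 2] *= -1
        mirrored.coords = xyz
        _, rmsd = geo.atom_fit(mirrored, mol, geo.ScaffoldMap.identity(4))
        assert rmsd > 1e-3

    def test_fit_never_worse_than_input_pose(self, rng):
        mol = make_chain(5)
        smap = geo.ScaffoldMap.identity(5)
        for _ in range(10):
            moved = mol.transformed(
                Rotation.random(rng=rng).as_matrix(), rng.uniform(-5, 5, 3)
            )
            before = np.sqrt(np.mean(np.sum((moved.coords - mol.coords) ** 2, axis=1)))
            _, after = geo.atom_fit(moved, mol, smap)
            assert after <= before + 1e-12

    def test_too_few_pairs_rejected(self):
        with pytest.raises(geo.GeometryError):
            geo.ScaffoldMap(((0, 0), (1, 1)))

    def test_collinear_template_rejected(self):
        line = Molecule(
            id="line",
            atoms=[make_atom(xyz=(float(i), 0, 0)) for i in range(4)],
        )
        mol = make_chain(4)
        with pytest.raises(geo.GeometryError, match="collinear"):
            geo.atom_fit(mol, line, geo.ScaffoldMap.identity(4))

    def test_map_file_parsing(self, tmp_path):
        path = tmp_path / "map.txt"
        path.write_text("# template  molecule\n1 3\n2 2\n3 1\n")
        smap = geo.ScaffoldMap.from_file(path)
        assert smap.pairs == ((0, 2), (1, 1), (2, 0))
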