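import numpy as np
import pytest

from comfa3d.molecules import Atom, Molecule


def make_atom(element="C", xyz=(0.0, 0.0, 0.0), charge=0.0,
              radius=1.70, epsilon=0.107, formal=0):
    return Atom(
        element=element, coords=np.asarray(xyz, float), partial_charge=charge,
        formal_charge=formal, vdw_radius=radius, vdw_epsilon=epsilon,
    )


def make_dimer(distance, epsilon=0.107, radius=1.70, charges=(0.0, 0.0)):
    """Two nonbonded atoms on the x axis."""
    return Molecule(
        id="dimer",
        atoms=[
            make_atom(xyz=(0, 0, 0), charge=charges[0], radius=radius,
                      epsilon=epsilon),
            make_atom(xyz=(distance, 0, 0), charge=charges[1], radius=radius,
                      epsilon=epsilon),
        ],
    )


def make_chain(n=4, bond_length=1.54, angle_deg=111.0, radius=1.70,
               epsilon=0.107, torsions_deg=None):
    """Alkane-like heavy-atom zig-zag chain (all-anti backbone, xy plane).

    ``torsions_deg`` maps a backbone bond (i, j) to a rotation applied to
    the tail atoms, e.g. {(1, 2): 120} turns a 4-atom chain gauche.
    """
    from comfa3d.geometry import rotate_torsion

    half = np.radians(180.0 - angle_deg) / 2.0
    coords = [np.zeros(3)]
    for k in range(n - 1):
        sign = 1.0 if k % 2 == 0 else -1.0
        step = bond_length * np.array([np.cos(half), sign * np.sin(half), 0.0])
        coords.append(coords[-1] + step)
    mol = Molecule(
        id="chain",
        atoms=[make_atom(xyz=c, radius=radius, epsilon=epsilon) for c in coords],
        bonds=[(i, i + 1, 1) for i in range(n - 1)],
    )
    if torsions_deg:
        xyz = mol.coords
        for (i, j), ang in torsions_deg.items():
            moving = list(range(j + 1, n))
            xyz = rotate_torsion(xyz, i, j, moving, np.radians(ang))
        mol.coords = xyz
    return mol


@pytest.fixture(scope="session")
def noiseless_set():
    """Default-size synthetic set without noise (expensive; shared)."""
    from comfa3d.synthetic import GeneratorConfig, generate

    return generate(GeneratorConfig(noise_sigma=0.0, seed=11))


@pytest.fixture(scope="session")
def noisy_set():
    from comfa3d.synthetic import GeneratorConfig, generate

    return generate(GeneratorConfig(noise_sigma=0.2, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
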