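import numpy as np
import pytest

from metalsite import synthetic_fixtures as sf
from metalsite.fragment_transform import Triplet
from metalsite.structure_io import Atom, Chain, Residue


def make_residue(res_name, seq_num, offset, standard=True, drop=()):
    """A residue with idealized local backbone geometry at ``offset``."""
    base = {
        "N": np.array([0.0, 0.0, 0.0]),
        "CA": np.array([1.458, 0.0, 0.0]),
        "C": np.array([1.988, 1.430, 0.0]),
        "O": np.array([1.30, 2.40, 0.0]),
    }
    atoms = [
        Atom(name, "N" if name == "N" else ("O" if name == "O" else "C"),
             xyz + np.asarray(offset, dtype=float))
        for name, xyz in base.items()
        if name not in drop
    ]
    return Residue(res_name=res_name, seq_num=seq_num, atoms=atoms,
                   is_standard_aa=standard)


def make_chain(res_names, chain_id="A", spacing=4.0):
    residues = [
        make_residue(name, i + 1, (i * spacing, 0.0, 0.0))
        for i, name in enumerate(res_names)
    ]
    return Chain(chain_id=chain_id, residues=residues)


def random_triplet(rng, ref="q"):
    """A well-conditioned random triplet (never near-collinear)."""
    while True:
        coords = rng.uniform(-10, 10, (3, 3))
        v1, v2 = coords[1] - coords[0], coords[2] - coords[0]
        if 0.5 * np.linalg.norm(np.cross(v1, v2)) > 0.5:
            return Triplet(residue_index=0, res_name="ALA", one_letter="A",
                           ref=ref, coords=coords)


def horn_superpose(src, dst):
    """Independent closed-form superposition oracle (Horn 1987 quaternion
    method): returns (rotation, translation, rmsd)."""
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    sc, dc = src.mean(axis=0), dst.mean(axis=0)
    P, Q = src - sc, dst - dc
    M = P.T @ Q
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    w, v = np.linalg.eigh(K)
    q = v[:, np.argmax(w)]  # w, x, y, z
    w0, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w0 * z), 2 * (x * z + w0 * y)],
            [2 * (x * y + w0 * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w0 * x)],
            [2 * (x * z - w0 * y), 2 * (y * z + w0 * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = dc - R @ sc
    rmsd = float(np.sqrt(np.mean(np.sum((src @ R.T + t - dst) ** 2, axis=1))))
    return R, t, rmsd


@pytest.fixture(scope="session")
def helix_chain():
    return sf.make_backbone(sf.FixtureSpec(n_residues=30, conformation="helix", seed=7))


@pytest.fixture(scope="session")
def planted_structure():
    chain = sf.make_backbone(
        sf.FixtureSpec(n_residues=30, conformation="helix", seed=11,
                       sequence="A" * 12 + "CAACH" + "A" * 13)
    )
    return sf.plant_metal_site(chain, "ZN", [12, 15, 16], structure_id="PLNT")


@pytest.fixture(scope="session")
def small_benchmark():
    return sf.make_benchmark(n_structures=6, seed=202, metal_types=("ZN",),
                             n_residues=35, noise_sigma=0.1)
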