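"""Deterministic synthetic structures for testing and benchmarking.

Builds polypeptide chains with ideal backbone geometry (helix, strand, or
irregular), plants metal sites so that chosen residues — and only those —
fall within the binding cutoff of the ion, adds Gaussian coordinate noise,
applies rigid motions, and assembles labeled leave-one-out benchmarks whose
sites are noisy rigid copies of shared motifs.  Everything is seeded and
writes valid PDB text through structure_io.

The geometry emulates what the predictor assumes about real sites (three
or more spatially clustered residues around an ion at coordination-like
distances); it makes no attempt at physically realistic coordination
chemistry or side-chain rotamers (only a Cβ stub is built).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation
from scipy.spatial.distance import cdist

from .fragment_transform import RigidTransform
from .structure_io import (
    Atom,
    Chain,
    MetalIon,
    ProteinStructure,
    Residue,
    write_pdb,
)

# Ideal backbone geometry (Å / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.530
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA = 180.0

_DIHEDRALS = {"helix": (-57.0, -47.0), "strand": (-120.0, 120.0)}

_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}

#: Residue types each metal preferentially binds (used for planted sites).
PREFERRED_BINDERS = {
    "CA": "DEN", "CU": "HHH", "FE": "HEC", "MG": "DED", "MN": "DHE", "ZN": "CCH",
}

#: Decoy alphabet: residue types that score <= +1 in BLOSUM62 against every
#: preferred binder, so background never mimics site chemistry.
DECOY_ALPHABET = "AGSTVLIFP"


class GeometricInfeasibilityError(RuntimeError):
    """No metal placement satisfies the planted-site distance constraints."""


@dataclass
class FixtureSpec:
    n_residues: int = 30
    conformation: str = "helix"  # helix | strand | irregular
    sequence: str | None = None
    seed: int = 0
    noise_sigma: float = 0.0


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, dihedral_deg: float,
) -> np.ndarray:
    """Natural-extension placement: position d with |cd| = bond,
    angle(b,c,d) = angle and dihedral(a,b,c,d) = dihedral."""
    angle = np.deg2rad(angle_deg)
    dihedral = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(angle), np.sin(angle) * np.cos(dihedral), np.sin(angle) * np.sin(dihedral)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _random_sequence(n: int, rng: np.random.Generator) -> str:
    letters = list(_THREE)
    return "".join(rng.choice(letters) for _ in range(n))


def make_backbone(spec: FixtureSpec) -> Chain:
    """A chain of ``n_residues`` with ideal backbone geometry (N, CA, C, O
    and a Cβ stub for non-glycine), deterministic for a given seed."""
    if spec.n_residues < 1:
        raise ValueError("need at least one residue")
    rng = np.random.default_rng(spec.seed)
    if spec.conformation in _DIHEDRALS:
        phi0, psi0 = _DIHEDRALS[spec.conformation]
        phis = np.full(spec.n_residues, phi0)
        psis = np.full(spec.n_residues, psi0)
    elif spec.conformation == "irregular":
        phis = rng.uniform(-150.0, -50.0, spec.n_residues)
        psis = rng.uniform(-70.0, 150.0, spec.n_residues)
    else:
        raise ValueError(f"unknown conformation {spec.conformation!r}")

    seq = spec.sequence or _random_sequence(spec.n_residues, rng)
    if len(seq) != spec.n_residues:
        raise ValueError("sequence length must equal n_residues")

    # seed the first residue explicitly
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.deg2rad(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])

    backbone = [(n0, ca0, c0)]
    for i in range(1, spec.n_residues):
        n_prev, ca_prev, c_prev = backbone[-1]
        n_i = place_atom(n_prev, ca_prev, c_prev, BOND_C_N, ANGLE_CA_C_N, psis[i - 1])
        ca_i = place_atom(ca_prev, c_prev, n_i, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        c_i = place_atom(c_prev, n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phis[i])
        backbone.append((n_i, ca_i, c_i))

    residues = []
    for i, (n_i, ca_i, c_i) in enumerate(backbone):
        name = _THREE[seq[i]]
        atoms = [
            Atom("N", "N", n_i),
            Atom("CA", "C", ca_i),
            Atom("C", "C", c_i),
        ]
        if i + 1 < len(backbone):
            next_n = backbone[i + 1][0]
            o_i = place_atom(next_n, ca_i, c_i, BOND_C_O, ANGLE_CA_C_O, 180.0)
        else:
            o_i = place_atom(n_i, ca_i, c_i, BOND_C_O, ANGLE_CA_C_O, psis[i] + 180.0)
        atoms.append(Atom("O", "O", o_i))
        if name != "GLY":
            cb = place_atom(c_i, n_i, ca_i, BOND_CA_CB, 110.4, 122.55)
            atoms.append(Atom("CB", "C", cb))
        residues.append(
            Residue(res_name=name, seq_num=i + 1, atoms=atoms, is_standard_aa=True)
        )
    return Chain(chain_id="A", residues=residues)


def _residue_atom_arrays(chain: Chain) -> list[np.ndarray]:
    return [np.array([a.coords for a in r.atoms]) for r in chain.residues]


def plant_metal_site(
    target: Chain | ProteinStructure,
    metal_type: str,
    residue_indices: list[int],
    cutoff: float = 3.5,
    target_max: float = 2.8,
    margin: float = 0.8,
    structure_id: str = "SYNT",
) -> ProteinStructure:
    """Place a metal ion so the chosen residues (0-based indices) each have
    an atom within ``target_max`` Å and every other residue stays farther
    than ``cutoff + margin`` Å.

    The placement is found by a deterministic coarse-to-fine grid search
    and verified post hoc by a brute-force all-atom distance scan; if no
    grid point satisfies the constraints a GeometricInfeasibilityError with
    diagnostics is raised.  Planting fewer than three residues is refused
    (such a site could never become a template).
    """
    if len(residue_indices) < 3:
        raise ValueError("a planted site needs at least 3 residues")
    if isinstance(target, ProteinStructure):
        structure = target
        chain = structure.chains[0]
    else:
        chain = target
        structure = ProteinStructure(structure_id=structure_id, chains=[chain])
    if any(i < 0 or i >= len(chain.residues) for i in residue_indices):
        raise ValueError("planted residue index out of range")

    sel = set(residue_indices)
    res_xyz = _residue_atom_arrays(chain)
    sel_xyz = [res_xyz[i] for i in sorted(sel)]
    other_xyz = [res_xyz[i] for i in range(len(res_xyz)) if i not in sel]
    # existing ions must also stay clear of the new site's residues
    center = np.mean(np.vstack(sel_xyz), axis=0)

    def evaluate(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        d_sel = np.max(
            np.stack([cdist(points, xyz).min(axis=1) for xyz in sel_xyz]), axis=0
        )
        d_oth = np.min(
            np.stack([cdist(points, xyz).min(axis=1) for xyz in other_xyz]), axis=0
        ) if other_xyz else np.full(len(points), np.inf)
        return d_sel, d_oth

    best = None
    # coarse pass with slack (a strict pocket can slip between 0.5 Å grid
    # points), then a strict fine pass around the best coarse point
    for step, half, slack in ((0.5, 8.0, 0.3), (0.1, 1.2, 0.0)):
        if best is None:
            origin = center
        else:
            origin = best
        ax = np.arange(-half, half + step / 2, step)
        gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
        points = origin + np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
        d_sel, d_oth = evaluate(points)
        feasible = (d_sel <= target_max + slack) & (d_oth > cutoff + margin - slack)
        if not feasible.any():
            dmin = float(np.min(d_sel))
            raise GeometricInfeasibilityError(
                f"no placement for residues {sorted(sel)}: best max-distance to "
                f"selected residues {dmin:.2f} Å (need <= {target_max} Å) with "
                f"others > {cutoff + margin:.2f} Å"
            )
        score = d_oth[feasible] - d_sel[feasible]
        best = points[feasible][np.argmax(score)]

    # brute-force verification of the final placement
    d_sel, d_oth = evaluate(best[None, :])
    assert d_sel[0] <= target_max and d_oth[0] > cutoff + margin

    structure.metal_ions.append(
        MetalIon(
            metal_type=metal_type,
            coords=best,
            source_id=f"{structure.structure_id}:{metal_type}:{len(structure.metal_ions)}",
        )
    )
    return structure


def _copy_structure(structure: ProteinStructure) -> ProteinStructure:
    chains = [
        Chain(
            chain_id=c.chain_id,
            residues=[
                Residue(
                    res_name=r.res_name,
                    seq_num=r.seq_num,
                    insertion_code=r.insertion_code,
                    atoms=[
                        Atom(a.name, a.element, a.coords.copy(), a.altloc, a.occupancy,
                             a.is_hetero)
                        for a in r.atoms
                    ],
                    is_standard_aa=r.is_standard_aa,
                )
                for r in c.residues
            ],
        )
        for c in structure.chains
    ]
    ions = [
        MetalIon(i.metal_type, i.coords.copy(), i.source_id)
        for i in structure.metal_ions
    ]
    return ProteinStructure(
        structure_id=structure.structure_id, chains=chains, metal_ions=ions
    )


def perturb(structure: ProteinStructure, sigma: float, seed: int = 0) -> ProteinStructure:
    """Add i.i.d. Gaussian noise (std ``sigma`` Å per coordinate) to every
    atom and ion; seed-deterministic, input left untouched."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    out = _copy_structure(structure)
    for chain in out.chains:
        for res in chain.residues:
            for atom in res.atoms:
                atom.coords = atom.coords + rng.normal(0.0, sigma, 3)
    for ion in out.metal_ions:
        ion.coords = ion.coords + rng.normal(0.0, sigma, 3)
    return out


def random_rigid_transform(seed: int | np.random.Generator = 0,
                           max_translation: float = 20.0) -> RigidTransform:
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-max_translation, max_translation, 3)
    return RigidTransform(R, t)


def rigid_move(
    structure: ProteinStructure, transform: RigidTransform | int
) -> ProteinStructure:
    """Apply one proper rigid motion to all atoms and ions (new structure).

    An integer argument is taken as a seed for a random motion."""
    if isinstance(transform, (int, np.integer)):
        transform = random_rigid_transform(int(transform))
    out = _copy_structure(structure)
    for chain in out.chains:
        for res in chain.residues:
            for atom in res.atoms:
                atom.coords = transform.apply(atom.coords)
    for ion in out.metal_ions:
        ion.coords = transform.apply(ion.coords)
    return out


@dataclass
class BenchmarkSet:
    structures: list[ProteinStructure]
    truth: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    # truth[structure_id][metal] = residue refs within cutoff of that metal

    def truth_table(self) -> list[tuple[str, str, str]]:
        rows = []
        for sid in sorted(self.truth):
            for metal, refs in sorted(self.truth[sid].items()):
                rows.extend((sid, metal, ref) for ref in refs)
        return rows


def _site_sequence(n_residues: int, site_indices: list[int], metal: str,
                   rng: np.random.Generator) -> str:
    letters = [rng.choice(list(DECOY_ALPHABET)) for _ in range(n_residues)]
    binders = PREFERRED_BINDERS[metal.upper()]
    for k, idx in enumerate(site_indices):
        letters[idx] = binders[k % len(binders)]
    return "".join(letters)


def make_benchmark(
    n_structures: int = 20,
    seed: int = 42,
    metal_types: tuple[str, ...] = ("ZN", "CA"),
    n_residues: int = 40,
    site_indices: tuple[int, ...] = (12, 15, 16),
    noise_sigma: float = 0.1,
    conformation: str = "helix",
    cutoff: float = 3.5,
    out_dir: str | os.PathLike | None = None,
) -> BenchmarkSet:
    """A labeled benchmark of noisy rigid copies of shared site motifs.

    One base structure per metal type is built (deterministic per seed);
    each benchmark structure is a Gaussian-perturbed, rigidly moved copy of
    its metal's base, so templates extracted from one structure match the
    sites of every other structure of the same metal.  Truth labels are
    regenerated from the final geometry, never assumed from construction.
    """
    if n_structures < 2:
        raise ValueError("leave-one-out needs at least 2 structures")
    rng = np.random.default_rng(seed)
    bases = {}
    for m, metal in enumerate(metal_types):
        spec = FixtureSpec(
            n_residues=n_residues,
            conformation=conformation,
            sequence=_site_sequence(n_residues, list(site_indices), metal, rng),
            seed=seed + m,
        )
        chain = make_backbone(spec)
        bases[metal] = plant_metal_site(
            chain, metal, list(site_indices), cutoff=cutoff, structure_id=f"BASE{m}"
        )

    structures = []
    truth: dict[str, dict[str, list[str]]] = {}
    for k in range(n_structures):
        metal = metal_types[k % len(metal_types)]
        sid = f"SY{k:03d}"
        st = perturb(bases[metal], noise_sigma, seed=int(rng.integers(2**31)))
        st = rigid_move(st, random_rigid_transform(rng))
        st.structure_id = sid
        for ion in st.metal_ions:
            ion.source_id = f"{sid}:{ion.metal_type}"
        structures.append(st)

        from .template_library import find_binding_residues

        labels: dict[str, list[str]] = {}
        for ion in st.metal_ions:
            refs = [
                br.residue_ref
                for br in find_binding_residues(st.chains, ion, cutoff)
            ]
            labels.setdefault(ion.metal_type, []).extend(refs)
        truth[sid] = labels

    bench = BenchmarkSet(structures=structures, truth=truth)
    if out_dir is not None:
        out_dir = os.fspath(out_dir)
        os.makedirs(out_dir, exist_ok=True)
        for st in structures:
            write_pdb(st, os.path.join(out_dir, f"{st.structure_id}.pdb"))
        with open(os.path.join(out_dir, "truth.tsv"), "w") as fh:
            fh.write("structure_id\tmetal\tresidue_ref\n")
            for sid, metal, ref in bench.truth_table():
                fh.write(f"{sid}\t{metal}\t{ref}\n")
    return bench
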