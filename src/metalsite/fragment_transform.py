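"""Fragment transformation engine.

The rigid unit of alignment is the backbone triplet (N, Cα, C) of a single
residue — deliberately free of torsion information, since neither the
preceding carbonyl carbon nor the following amide nitrogen is included.
Every (query triplet, template triplet) pair defines a least-squares rigid
transform; pairs whose transforms map each other's triplets to within a
linkage distance d_c are single-linkage clustered, and each cluster yields
an aligned substructure pair (a one-to-one residue correspondence).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .structure_io import Chain

#: Default linkage threshold (Å) for single-linkage clustering of
#: transformation-compatible triplet pairs.  Stricter than the 3 Å
#: cluster-RMSD filter applied downstream.
DEFAULT_DC = 2.0

#: Clusters must align at least this many residues (the template rule:
#: a site has more than two binding residues).
DEFAULT_MIN_CLUSTER_SIZE = 3

_COLLINEAR_AREA = 1e-6


class DegenerateGeometryError(ValueError):
    """Raised when a triplet's three points are (nearly) collinear."""


@dataclass(frozen=True)
class Triplet:
    """Ordered N/Cα/C backbone coordinates of one residue."""

    residue_index: int
    res_name: str
    one_letter: str
    ref: str
    coords: np.ndarray  # (3, 3); rows = N, CA, C

    @property
    def ca(self) -> np.ndarray:
        return self.coords[1]

    def is_degenerate(self) -> bool:
        v1 = self.coords[1] - self.coords[0]
        v2 = self.coords[2] - self.coords[0]
        return 0.5 * np.linalg.norm(np.cross(v1, v2)) <= _COLLINEAR_AREA


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        R = self.rotation
        if R.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if np.linalg.norm(R.T @ R - np.eye(3)) > 1e-6:
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) <= 0:
            raise ValueError("improper rotation (det <= 0): reflections not allowed")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass(frozen=True)
class TripletPairAlignment:
    query_index: int
    template_index: int
    transform: RigidTransform
    fit_rmsd: float


@dataclass
class Cluster:
    """A set of mutually transformation-compatible triplet pairs, reduced to
    a one-to-one (query residue, template residue) correspondence."""

    pairs: list[TripletPairAlignment]
    correspondence: list[tuple[int, int]] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.correspondence)


def build_triplets(chain: Chain) -> list[Triplet]:
    """One triplet per residue with a complete N/Cα/C backbone, chain order."""
    triplets = []
    for idx, res in enumerate(chain.residues):
        if not res.has_backbone():
            continue
        coords = np.array([res.get_atom(n).coords for n in ("N", "CA", "C")])
        triplets.append(
            Triplet(
                residue_index=idx,
                res_name=res.res_name,
                one_letter=res.one_letter,
                ref=chain.residue_ref(res),
                coords=coords,
            )
        )
    return triplets


def kabsch(src: np.ndarray, dst: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares proper superposition of point set ``src`` onto ``dst``.

    Returns the transform and the residual RMSD.  det(R) = +1 is enforced,
    so mirror solutions are never produced.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    sc = src.mean(axis=0)
    dc = dst.mean(axis=0)
    H = (src - sc).T @ (dst - dc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = dc - R @ sc
    rmsd = float(np.sqrt(np.mean(np.sum((src @ R.T + t - dst) ** 2, axis=1))))
    return RigidTransform(R, t), rmsd


def superpose_triplet(src: Triplet, dst: Triplet) -> tuple[RigidTransform, float]:
    """Kabsch superposition of one backbone triplet onto another."""
    for tri in (src, dst):
        if tri.is_degenerate():
            raise DegenerateGeometryError(f"collinear triplet at {tri.ref}")
    return kabsch(src.coords, dst.coords)


def pair_distance(transform: RigidTransform, sigma_k: Triplet, tau_l: Triplet) -> float:
    """RMSD between a transformed query triplet and a template triplet."""
    moved = transform.apply(sigma_k.coords)
    return float(np.sqrt(np.mean(np.sum((moved - tau_l.coords) ** 2, axis=1))))


def enumerate_pairs(
    query_triplets: list[Triplet],
    template_triplets: list[Triplet],
    prefilter: bool = False,
) -> list[TripletPairAlignment]:
    """All m x n (query, template) triplet pairs with their rigid transforms.

    With ``prefilter`` the quadratic matrix is thinned by skipping residue
    pairs with a negative BLOSUM62 score; off by default (exhaustive matrix).
    """
    if prefilter:
        from .scoring import blosum62
    pairs = []
    for i, sigma in enumerate(query_triplets):
        for j, tau in enumerate(template_triplets):
            if prefilter and blosum62(sigma.one_letter, tau.one_letter) < 0:
                continue
            transform, rmsd = superpose_triplet(sigma, tau)
            pairs.append(TripletPairAlignment(i, j, transform, rmsd))
    return pairs


def _compatibility_matrix(
    pairs: list[TripletPairAlignment],
    query_triplets: list[Triplet],
    template_triplets: list[Triplet],
    d_c: float,
) -> np.ndarray:
    """Boolean P x P matrix: pairs p, q linked iff each pair's transform
    carries the other pair's query triplet to within d_c of its template
    triplet (symmetric two-sided criterion)."""
    P = len(pairs)
    R = np.stack([p.transform.rotation for p in pairs])  # (P,3,3)
    t = np.stack([p.transform.translation for p in pairs])  # (P,3)
    sig = np.stack([query_triplets[p.query_index].coords for p in pairs])  # (P,3,3)
    tau = np.stack([template_triplets[p.template_index].coords for p in pairs])

    linked = np.empty((P, P), dtype=bool)
    block = max(1, int(4.5e5 // max(P, 1)))
    for start in range(0, P, block):
        stop = min(start + block, P)
        # moved[p, q, a, :] = R[p] @ sig[q, a] + t[p]
        moved = np.einsum("pcb,qab->pqac", R[start:stop], sig) + t[start:stop, None, None, :]
        d2 = np.mean(np.sum((moved - tau[None, :, :, :]) ** 2, axis=3), axis=2)
        linked[start:stop] = d2 <= d_c * d_c
    return linked & linked.T


def _one_to_one(pairs: list[TripletPairAlignment]) -> list[tuple[int, int]]:
    """Greedy one-to-one correspondence: ascending fit_rmsd, ties broken by
    (query index, template index)."""
    used_q: set[int] = set()
    used_t: set[int] = set()
    corr = []
    for p in sorted(pairs, key=lambda p: (p.fit_rmsd, p.query_index, p.template_index)):
        if p.query_index in used_q or p.template_index in used_t:
            continue
        used_q.add(p.query_index)
        used_t.add(p.template_index)
        corr.append((p.query_index, p.template_index))
    corr.sort()
    return corr


def cluster_pairs(
    pairs: list[TripletPairAlignment],
    query_triplets: list[Triplet],
    template_triplets: list[Triplet],
    d_c: float = DEFAULT_DC,
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
) -> list[Cluster]:
    """Single-linkage clustering of triplet pairs under the two-sided
    transformation-compatibility criterion.

    Clusters are the connected components of the compatibility graph
    (transitive closure of the linkage relation); within each, a one-to-one
    correspondence is enforced and clusters aligning fewer than
    ``min_cluster_size`` residues are discarded.
    """
    if not pairs:
        return []
    linked = _compatibility_matrix(pairs, query_triplets, template_triplets, d_c)
    np.fill_diagonal(linked, True)
    _, labels = connected_components(csr_matrix(linked), directed=False)
    clusters = []
    for lab in range(labels.max() + 1):
        members = [pairs[i] for i in np.flatnonzero(labels == lab)]
        corr = _one_to_one(members)
        if len(corr) >= min_cluster_size:
            clusters.append(Cluster(pairs=members, correspondence=corr))
    clusters.sort(key=lambda c: c.correspondence[0] if c.correspondence else (0, 0))
    return clusters


def aligned_substructure(
    cluster: Cluster,
    query_triplets: list[Triplet],
    template_triplets: list[Triplet],
) -> tuple[list[Triplet], list[Triplet]]:
    """The order-matched (query, template) triplet lists of a cluster."""
    if not cluster.correspondence:
        raise ValueError("empty cluster has no aligned substructure")
    q = [query_triplets[i] for i, _ in cluster.correspondence]
    t = [template_triplets[j] for _, j in cluster.correspondence]
    return q, t
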