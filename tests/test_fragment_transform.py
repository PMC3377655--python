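import numpy as np
import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from conftest import horn_superpose, random_triplet
from metalsite import synthetic_fixtures as sf
from metalsite.fragment_transform import (
    DegenerateGeometryError,
    RigidTransform,
    Triplet,
    aligned_substructure,
    build_triplets,
    cluster_pairs,
    enumerate_pairs,
    pair_distance,
    superpose_triplet,
)


# ---------------------------------------------------------------------------
# build_triplets

def test_complete_chain_yields_one_triplet_per_residue(helix_chain):
    triplets = build_triplets(helix_chain)
    assert len(triplets) == len(helix_chain.residues)
    for idx, (tri, res) in enumerate(zip(triplets, helix_chain.residues)):
        assert tri.residue_index == idx
        np.testing.assert_array_equal(tri.coords[0], res.get_atom("N").coords)
        np.testing.assert_array_equal(tri.coords[1], res.get_atom("CA").coords)
        np.testing.assert_array_equal(tri.coords[2], res.get_atom("C").coords)


def test_residue_missing_backbone_atom_is_skipped(helix_chain):
    import copy

    chain = copy.deepcopy(helix_chain)
    chain.residues[4].atoms = [
        a for a in chain.residues[4].atoms if a.name != "C"
    ]
    triplets = build_triplets(chain)
    assert len(triplets) == len(chain.residues) - 1
    assert all(t.residue_index != 4 for t in triplets)


# ---------------------------------------------------------------------------
# superpose_triplet

def test_self_superposition_is_identity():
    tri = random_triplet(np.random.default_rng(0))
    transform, rmsd = superpose_triplet(tri, tri)
    np.testing.assert_allclose(transform.rotation, np.eye(3), atol=1e-9)
    np.testing.assert_allclose(transform.translation, 0.0, atol=1e-9)
    assert rmsd < 1e-8


def test_pure_translation_is_recovered():
    rng = np.random.default_rng(1)
    src = random_triplet(rng)
    dst = Triplet(0, "ALA", "A", "t", src.coords + np.array([1.0, 2.0, 3.0]))
    transform, rmsd = superpose_triplet(src, dst)
    np.testing.assert_allclose(transform.rotation, np.eye(3), atol=1e-9)
    np.testing.assert_allclose(transform.translation, [1.0, 2.0, 3.0], atol=1e-9)
    assert rmsd < 1e-8


def test_kabsch_matches_quaternion_oracle_on_100_random_pairs():
    rng = np.random.default_rng(12345)
    for _ in range(100):
        src, dst = random_triplet(rng), random_triplet(rng)
        transform, rmsd = superpose_triplet(src, dst)
        _, _, rmsd_oracle = horn_superpose(src.coords, dst.coords)
        assert abs(rmsd - rmsd_oracle) < 1e-6
        assert np.linalg.det(transform.rotation) > 0


def test_kabsch_is_globally_optimal_among_random_rigid_motions():
    rng = np.random.default_rng(7)
    src, dst = random_triplet(rng), random_triplet(rng)
    _, best = superpose_triplet(src, dst)
    from scipy.spatial.transform import Rotation

    for _ in range(10_000):
        R = Rotation.random(random_state=rng).as_matrix()
        moved = src.coords @ R.T
        moved += dst.coords.mean(axis=0) - moved.mean(axis=0)
        rmsd = np.sqrt(np.mean(np.sum((moved - dst.coords) ** 2, axis=1)))
        assert rmsd >= best - 1e-9


def test_collinear_triplet_rejected():
    coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
    bad = Triplet(0, "ALA", "A", "b", coords)
    good = random_triplet(np.random.default_rng(3))
    with pytest.raises(DegenerateGeometryError):
        superpose_triplet(bad, good)


def test_reflection_never_produced():
    with pytest.raises(ValueError):
        RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))


# ---------------------------------------------------------------------------
# pair_distance

def test_pair_distance_of_own_pair_equals_fit_rmsd():
    rng = np.random.default_rng(4)
    src, dst = random_triplet(rng), random_triplet(rng)
    transform, rmsd = superpose_triplet(src, dst)
    assert pair_distance(transform, src, dst) == pytest.approx(rmsd, abs=1e-12)


def test_pair_distance_equals_direct_arithmetic():
    rng = np.random.default_rng(5)
    for _ in range(20):
        transform = sf.random_rigid_transform(rng)
        a, b = random_triplet(rng), random_triplet(rng)
        moved = a.coords @ transform.rotation.T + transform.translation
        expected = np.sqrt(np.mean(np.sum((moved - b.coords) ** 2, axis=1)))
        assert pair_distance(transform, a, b) == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# enumerate_pairs

def test_enumerate_pairs_is_full_matrix():
    rng = np.random.default_rng(6)
    q = [random_triplet(rng) for _ in range(5)]
    t = [random_triplet(rng) for _ in range(4)]
    pairs = enumerate_pairs(q, t)
    assert len(pairs) == 20
    assert {(p.query_index, p.template_index) for p in pairs} == {
        (i, j) for i in range(5) for j in range(4)
    }
    assert enumerate_pairs([], t) == []


def test_prefilter_keeps_self_type_pairs(helix_chain):
    triplets = build_triplets(helix_chain)[:6]
    pairs = enumerate_pairs(triplets, triplets, prefilter=True)
    kept = {(p.query_index, p.template_index) for p in pairs}
    for i in range(6):
        assert (i, i) in kept  # self-scores are always positive


# ---------------------------------------------------------------------------
# cluster_pairs

def _exact_copy_setup(_unused=None, indices=(3, 7, 11, 15), seed=8):
    """Template = rigid copy of a subset of an irregular query (an ideal
    helix has exact screw periodicity, which makes the correct
    correspondence degenerate); returns triplet lists."""
    chain = sf.make_backbone(
        sf.FixtureSpec(n_residues=20, conformation="irregular", seed=77)
    )
    q_triplets = build_triplets(chain)
    transform = sf.random_rigid_transform(np.random.default_rng(seed))
    t_triplets = []
    for pos, idx in enumerate(indices):
        src = q_triplets[idx]
        t_triplets.append(
            Triplet(pos, src.res_name, src.one_letter, f"T:{pos}",
                    transform.apply(src.coords))
        )
    return q_triplets, t_triplets, indices


def test_exact_rigid_copy_forms_one_correct_cluster(helix_chain):
    q_triplets, t_triplets, indices = _exact_copy_setup(helix_chain)
    pairs = enumerate_pairs(q_triplets, t_triplets)
    clusters = cluster_pairs(pairs, q_triplets, t_triplets, d_c=0.5)
    # the correct correspondence must appear as one cluster
    wanted = {(idx, pos) for pos, idx in enumerate(indices)}
    assert any(wanted <= set(c.correspondence) for c in clusters)


def test_two_differently_moved_sites_give_two_clusters(helix_chain):
    q_triplets = build_triplets(helix_chain)[:8]
    rng = np.random.default_rng(9)
    t1 = sf.random_rigid_transform(rng)
    t2 = sf.random_rigid_transform(rng)
    t_triplets = []
    for pos, (idx, tr) in enumerate(
        [(0, t1), (1, t1), (2, t1), (4, t2), (5, t2), (6, t2)]
    ):
        src = q_triplets[idx]
        t_triplets.append(
            Triplet(pos, src.res_name, src.one_letter, f"T:{pos}",
                    tr.apply(src.coords))
        )
    pairs = enumerate_pairs(q_triplets, t_triplets)
    clusters = cluster_pairs(pairs, q_triplets, t_triplets, d_c=0.5)
    corr = [set(c.correspondence) for c in clusters]
    assert {(0, 0), (1, 1), (2, 2)} in [c & {(0, 0), (1, 1), (2, 2)} for c in corr]
    assert {(4, 3), (5, 4), (6, 5)} in [c & {(4, 3), (5, 4), (6, 5)} for c in corr]


def _connected_components_oracle(pairs, q_triplets, t_triplets, d_c):
    """Explicit compatibility graph + networkx components."""
    g = nx.Graph()
    g.add_nodes_from(range(len(pairs)))
    for a in range(len(pairs)):
        for b in range(len(pairs)):
            pa, pb = pairs[a], pairs[b]
            d_ab = pair_distance(
                pa.transform, q_triplets[pb.query_index], t_triplets[pb.template_index]
            )
            d_ba = pair_distance(
                pb.transform, q_triplets[pa.query_index], t_triplets[pa.template_index]
            )
            if d_ab <= d_c and d_ba <= d_c:
                g.add_edge(a, b)
    return {frozenset(comp) for comp in nx.connected_components(g)}


@pytest.mark.parametrize("case_seed", range(50))
def test_clustering_equals_connected_components_oracle(case_seed):
    rng = np.random.default_rng(1000 + case_seed)
    m, n = rng.integers(2, 6), rng.integers(2, 5)
    q = [random_triplet(rng, f"q{i}") for i in range(m)]
    t = [random_triplet(rng, f"t{j}") for j in range(n)]
    pairs = enumerate_pairs(q, t)[:20]
    d_c = float(rng.uniform(1.0, 8.0))
    clusters = cluster_pairs(pairs, q, t, d_c=d_c, min_cluster_size=1)
    got = set()
    index_of = {(p.query_index, p.template_index): k for k, p in enumerate(pairs)}
    for c in clusters:
        got.add(
            frozenset(index_of[(p.query_index, p.template_index)] for p in c.pairs)
        )
    assert got == _connected_components_oracle(pairs, q, t, d_c)


def test_cluster_partition_invariant_to_pair_order(helix_chain):
    q_triplets, t_triplets, _ = _exact_copy_setup(helix_chain, seed=10)
    pairs = enumerate_pairs(q_triplets, t_triplets)
    rng = np.random.default_rng(11)
    shuffled = [pairs[i] for i in rng.permutation(len(pairs))]
    c1 = cluster_pairs(pairs, q_triplets, t_triplets, d_c=0.5)
    c2 = cluster_pairs(shuffled, q_triplets, t_triplets, d_c=0.5)
    assert sorted(map(sorted, (c.correspondence for c in c1))) == sorted(
        map(sorted, (c.correspondence for c in c2))
    )


# ---------------------------------------------------------------------------
# aligned_substructure

def test_aligned_substructure_is_one_to_one(helix_chain):
    q_triplets, t_triplets, indices = _exact_copy_setup(helix_chain)
    pairs = enumerate_pairs(q_triplets, t_triplets)
    clusters = cluster_pairs(pairs, q_triplets, t_triplets, d_c=0.5)
    for cluster in clusters:
        q, t = aligned_substructure(cluster, q_triplets, t_triplets)
        assert len(q) == len(t)
        assert len({tri.residue_index for tri in q}) == len(q)
        assert len({tri.residue_index for tri in t}) == len(t)


def test_exact_copy_correspondence_is_identity_mapping(helix_chain):
    q_triplets, t_triplets, indices = _exact_copy_setup(helix_chain)
    pairs = enumerate_pairs(q_triplets, t_triplets)
    clusters = cluster_pairs(pairs, q_triplets, t_triplets, d_c=0.5)
    best = max(clusters, key=lambda c: c.size)
    expected = {(idx, pos) for pos, idx in enumerate(indices)}
    assert expected <= set(best.correspondence)


def test_one_to_one_keeps_smaller_fit_rmsd_pair():
    from metalsite.fragment_transform import TripletPairAlignment, _one_to_one

    ident = RigidTransform(np.eye(3), np.zeros(3))
    pairs = [
        TripletPairAlignment(0, 0, ident, 0.8),
        TripletPairAlignment(0, 1, ident, 0.2),  # same query residue, better fit
        TripletPairAlignment(1, 0, ident, 0.5),
    ]
    corr = _one_to_one(pairs)
    assert (0, 1) in corr and (1, 0) in corr and (0, 0) not in corr


def test_empty_cluster_errors():
    from metalsite.fragment_transform import Cluster

    with pytest.raises(ValueError):
        aligned_substructure(Cluster(pairs=[]), [], [])


# ---------------------------------------------------------------------------
# rigid invariance (property)

@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**20))
def test_fit_rmsd_and_pair_distance_rigid_invariant(seed):
    rng = np.random.default_rng(seed)
    a, b, c = (random_triplet(rng, r) for r in "abc")
    motion = sf.random_rigid_transform(rng)

    def move(tri):
        return Triplet(tri.residue_index, tri.res_name, tri.one_letter, tri.ref,
                       motion.apply(tri.coords))

    _, rmsd = superpose_triplet(a, b)
    tr_m, rmsd_m = superpose_triplet(move(a), b)
    assert rmsd_m == pytest.approx(rmsd, abs=1e-6)
    tr, _ = superpose_triplet(a, b)
    assert pair_distance(tr_m, move(c), b) == pytest.approx(
        pair_distance(tr, c, b), abs=1e-6
    )
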