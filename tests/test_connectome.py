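import numpy as np
import pytest

from tractonet import (
    Bundle,
    Connectome,
    PhantomSpec,
    ScalarField,
    Streamline,
    Tractogram,
    VoxelGrid,
    build_connectome,
    build_fa_connectome,
    characteristic_filter,
    edge_occupancy,
    edge_weight,
    fa_edge_weight,
    make_phantom,
    segment_tractogram,
)
from tractonet.connectome import EdgeOccupancy, InvalidGeometryError, UndefinedEdgeError
from tractonet.parcellation import NodeRegion


def _two_node_setup(p_voxel=1, lengths=(10.0,), area=100.0, edge=1.0):
    """Minimal hand-built tractogram: straight streamlines along x between
    two single-voxel nodes, seeded in the corridor."""
    nx = int(max(lengths) / edge) + 4
    grid = VoxelGrid((nx, 3, 3), (edge, edge, edge))
    mid = 1.5 * edge
    streamlines = []
    for L in lengths:
        pts = np.array([[0.5 * edge, mid, mid], [0.5 * edge + L, mid, mid]])
        seed_voxel = grid.voxel_of([0.5 * edge + L / 2, mid, mid])
        streamlines.append(Streamline(pts, seed_voxel))
    t = Tractogram(grid, streamlines, p_voxel)
    node_i = NodeRegion(0, "a", "none", area, frozenset({(0, 1, 1)}))
    node_j = NodeRegion(1, "b", "none", area, frozenset({grid.voxel_of([0.5 * edge + max(lengths), mid, mid])}))
    return t, node_i, node_j


def test_edge_weight_closed_form_single_streamline():
    # (2/200) * (1/1) * (1/10) = 1e-3
    t, ni, nj = _two_node_setup(p_voxel=1, lengths=(10.0,), area=100.0)
    pairs = segment_tractogram(t, [ni, nj])
    occ = edge_occupancy(t, {0: ni, 1: nj}, (0, 1), pairs[(0, 1)])
    assert edge_weight(t, occ, ni, nj) == pytest.approx(1.0e-3)


def test_edge_weight_empty_sum_is_zero():
    t, ni, nj = _two_node_setup()
    occ = EdgeOccupancy((0, 1), frozenset({(5, 1, 1)}), ())
    assert edge_weight(t, occ, ni, nj) == 0.0


def test_edge_weight_closed_form_bundle_vs_accumulation_oracle():
    # 50 streamlines of 20 mm, A=400 each, V=8, P=125 -> 4.0e-4
    t, ni, nj = _two_node_setup(p_voxel=125, lengths=(20.0,) * 50, area=400.0, edge=2.0)
    pairs = segment_tractogram(t, [ni, nj])
    occ = edge_occupancy(t, {0: ni, 1: nj}, (0, 1), pairs[(0, 1)])
    w = edge_weight(t, occ, ni, nj)
    assert w == pytest.approx(4.0e-4)
    # independent per-streamline accumulation
    acc = 0.0
    for ref in occ.streamline_refs:
        length = float(np.linalg.norm(np.diff(t.streamlines[ref].points, axis=0), axis=1).sum())
        acc += (2.0 / 800.0) * (8.0 / 125.0) * (1.0 / length)
    assert w == pytest.approx(acc)


def test_edge_weight_invalid_geometry():
    from types import SimpleNamespace

    t, ni, nj = _two_node_setup()
    occ = EdgeOccupancy((0, 1), frozenset(), ())
    bad = SimpleNamespace(surface_area_mm2=0.0)
    with pytest.raises(InvalidGeometryError):
        edge_weight(t, occ, bad, bad)


def test_segmentation_by_endpoint_containment():
    t, ni, nj = _two_node_setup(lengths=(10.0, 10.0))
    pairs = segment_tractogram(t, [ni, nj])
    assert set(pairs) == {(0, 1)} and len(pairs[(0, 1)]) == 2
    # a streamline with both endpoints in the same node is a dropped self-loop
    loop = Streamline(np.array([[0.4, 1.5, 1.5], [3.0, 1.5, 1.5], [0.6, 1.5, 1.5]]), (1, 1, 1))
    t2 = Tractogram(t.grid, t.streamlines + [loop], t.seeds_per_voxel)
    assert len(segment_tractogram(t2, [ni, nj])[(0, 1)]) == 2


def test_segmentation_rejects_overlapping_nodes():
    t, ni, _ = _two_node_setup()
    clash = NodeRegion(5, "clash", "none", 10.0, frozenset({(0, 1, 1)}))
    with pytest.raises(ValueError, match="belongs to both"):
        segment_tractogram(t, [ni, clash])


def test_segmentation_recovers_phantom_bundles():
    ph = make_phantom(PhantomSpec(
        n_nodes=3, bundles=(Bundle(0, 1, count=20), Bundle(1, 2, count=20)), seed=4
    ))
    pairs = segment_tractogram(ph.tractogram, ph.parcellation)
    assert set(pairs) == {(0, 1), (1, 2)}
    assert [len(pairs[k]) for k in sorted(pairs)] == [20, 20]


def test_characteristic_filter_membership(chain_phantom):
    t = chain_phantom.tractogram
    nodes = {n.node_id: n for n in chain_phantom.parcellation}
    pairs = segment_tractogram(t, chain_phantom.parcellation)
    occ = edge_occupancy(t, nodes, (0, 1), pairs[(0, 1)])
    s = t.streamlines[pairs[(0, 1)][0]]
    assert characteristic_filter(s, occ) == 1
    # seed inside a node's mask -> rejected
    node_voxel = next(iter(nodes[0].voxel_members))
    inside = Streamline(s.points, node_voxel)
    assert characteristic_filter(inside, occ) == 0
    # seed in a voxel no streamline of this edge traverses -> rejected
    outside = Streamline(s.points, (0, 0, 0))
    assert characteristic_filter(outside, occ) == 0


def test_node_seeded_streamlines_excluded_from_weight(chain_phantom):
    t = chain_phantom.tractogram
    nodes = {n.node_id: n for n in chain_phantom.parcellation}
    pairs = segment_tractogram(t, chain_phantom.parcellation)
    refs = pairs[(0, 1)]
    node_voxel = next(iter(nodes[0].voxel_members))
    bad = Streamline(t.streamlines[refs[0]].points, node_voxel)
    t2 = Tractogram(t.grid, t.streamlines + [bad], t.seeds_per_voxel)
    occ = edge_occupancy(t2, nodes, (0, 1), refs + [len(t2.streamlines) - 1])
    assert len(occ.streamline_refs) == len(refs)
    assert occ.voxels.isdisjoint(nodes[0].voxel_members)
    assert occ.voxels.isdisjoint(nodes[1].voxel_members)


def test_build_connectome_support_and_symmetry(chain_phantom):
    c = build_connectome(chain_phantom.tractogram, chain_phantom.parcellation)
    W = c.weights
    assert np.array_equal(W, W.T) and np.all(np.diag(W) == 0) and np.all(W >= 0)
    nz = {(i, j) for i in range(3) for j in range(i + 1, 3) if W[i, j] > 0}
    assert nz == set(chain_phantom.bundle_members)


def test_empty_tractogram_warns_and_zero_matrix():
    ph = make_phantom(PhantomSpec(n_nodes=2, bundles=(Bundle(0, 1, count=0),), seed=0))
    with pytest.warns(UserWarning, match="empty tractogram"):
        c = build_connectome(ph.tractogram, ph.parcellation)
    assert not c.weights.any()


def test_connectome_permutation_conjugation(chain_phantom):
    c = build_connectome(chain_phantom.tractogram, chain_phantom.parcellation)
    perm = [2, 0, 1]
    relabeled = [
        NodeRegion(perm[n.node_id], n.label, n.hemisphere, n.surface_area_mm2, n.voxel_members)
        for n in chain_phantom.parcellation
    ]
    c2 = build_connectome(chain_phantom.tractogram, relabeled)
    P = np.zeros((3, 3))
    for old, new in enumerate(perm):
        P[new, old] = 1.0
    np.testing.assert_allclose(c2.weights, P @ c.weights @ P.T)


def test_seeding_paradigm_invariance():
    """Proportional re-seeding (P_voxel and bundle counts scaled together)
    leaves the weights unchanged."""
    mats = []
    for p, count in [(1, 10), (5, 50), (25, 250)]:
        spec = PhantomSpec(n_nodes=3, p_voxel=p,
                           bundles=(Bundle(0, 1, count=count), Bundle(1, 2, count=count)),
                           seed=7)
        ph = make_phantom(spec)
        mats.append(build_connectome(ph.tractogram, ph.parcellation).weights)
    np.testing.assert_allclose(mats[0], mats[1], rtol=1e-12)
    np.testing.assert_allclose(mats[0], mats[2], rtol=1e-12)


def test_dimensional_invariance_mm_to_cm():
    """Scaling lengths by s, areas by s^2, volumes by s^3 leaves every
    weight unchanged up to roundoff."""
    base = PhantomSpec(n_nodes=4, seed=5)
    scaled = PhantomSpec(n_nodes=4, seed=5, voxel_edge_mm=base.voxel_edge_mm * 10,
                         node_spacing_mm=base.node_spacing_mm * 10)
    Wa = build_connectome(*_tract_parc(make_phantom(base))).weights
    Wb = build_connectome(*_tract_parc(make_phantom(scaled))).weights
    assert Wa.max() > 0
    np.testing.assert_allclose(Wa, Wb, rtol=1e-9)


def _tract_parc(ph):
    return ph.tractogram, ph.parcellation


def test_adding_retained_streamline_strictly_increases_weight(chain_phantom):
    t = chain_phantom.tractogram
    c = build_connectome(t, chain_phantom.parcellation)
    extra = t.streamlines[chain_phantom.bundle_members[(0, 1)][0]]
    t2 = Tractogram(t.grid, t.streamlines + [Streamline(extra.points, extra.seed_voxel)],
                    t.seeds_per_voxel)
    c2 = build_connectome(t2, chain_phantom.parcellation)
    assert c2.weights[0, 1] > c.weights[0, 1]
    mask = np.ones((3, 3), bool)
    mask[0, 1] = mask[1, 0] = False
    np.testing.assert_allclose(c2.weights[mask], c.weights[mask])


def test_spurious_single_streamline_edges_barely_move_node_strength():
    """False-positive connections carry one long streamline each and so get
    tiny weights: global mean node strength moves by well under 1%."""
    changes = []
    for seed in range(3):
        clean = make_phantom(PhantomSpec(seed=seed))
        noisy = make_phantom(PhantomSpec(seed=seed, spurious_rate=0.10))
        W0 = build_connectome(clean.tractogram, clean.parcellation).weights
        W1 = build_connectome(noisy.tractogram, noisy.parcellation).weights
        s0, s1 = W0.sum(1).mean(), W1.sum(1).mean()
        changes.append(100.0 * abs(s1 - s0) / s0)
    assert max(changes) < 1.0


# ---- FA weighting --------------------------------------------------------

def test_fa_edge_weight_examples(chain_phantom):
    t = chain_phantom.tractogram
    nodes = {n.node_id: n for n in chain_phantom.parcellation}
    pairs = segment_tractogram(t, chain_phantom.parcellation)
    occ = edge_occupancy(t, nodes, (0, 1), pairs[(0, 1)])
    uniform = ScalarField(t.grid, np.full(t.grid.shape, 0.5))
    assert fa_edge_weight(occ, uniform) == pytest.approx(0.5)
    two = list(occ.voxels)[:2]
    occ2 = EdgeOccupancy((0, 1), frozenset(two), ())
    field = np.zeros(t.grid.shape)
    field[two[0]] = 0.2
    field[two[1]] = 0.6
    assert fa_edge_weight(occ2, ScalarField(t.grid, field)) == pytest.approx(0.4)
    with pytest.raises(UndefinedEdgeError):
        fa_edge_weight(EdgeOccupancy((0, 1), frozenset(), ()), uniform)


def test_build_fa_connectome_uniform_field(chain_phantom):
    t = chain_phantom.tractogram
    fa = ScalarField(t.grid, np.full(t.grid.shape, 0.5))
    c = build_fa_connectome(t, chain_phantom.parcellation, fa)
    for pair in chain_phantom.bundle_members:
        assert c.weights[pair] == pytest.approx(0.5)


def test_connectome_io_roundtrip(tmp_path, chain_phantom):
    c = build_connectome(chain_phantom.tractogram, chain_phantom.parcellation)
    c.to_csv(tmp_path / "c.csv")
    back = Connectome.from_csv(tmp_path / "c.csv")
    assert back.labels == c.labels
    np.testing.assert_allclose(back.weights, c.weights)
    c.to_edgelist(tmp_path / "c.tsv")
    back2 = Connectome.from_edgelist(tmp_path / "c.tsv", c.labels)
    np.testing.assert_allclose(back2.weights, c.weights)
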