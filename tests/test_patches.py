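import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist

from mimomap.patches import (
    GraphParams,
    NoSurfaceResiduesError,
    average_cf,
    build_graph_adt,
    build_graph_fdt,
    compute_cf,
    generate_patches,
)

from conftest import all_surface, model_from_anchors


def adt_grid_oracle(patch, model, params):
    """Independent 0.01 Å grid scan reproducing the adaptive-threshold rule."""
    anchors = model.anchors()[patch.member_indices]
    k = len(patch.members)
    pd = pdist(anchors) if k > 1 else np.array([])
    lo_b, hi_b = params.band
    lo_t, hi_t = params.threshold_bounds

    def cf(t):
        return compute_cf(int((pd <= t).sum()), k, params.a_constant)

    t = params.start_threshold
    c = cf(t)
    if lo_b <= c <= hi_b:
        return t, True
    d = 1 if c < lo_b else -1
    while True:
        nt = round(t + d * params.step, 10)
        if nt < lo_t or nt > hi_t:
            t = min(max(nt, lo_t), hi_t)
            c = cf(t)
            return t, lo_b <= c <= hi_b
        prev_t, prev_c = t, c
        t, c = nt, cf(nt)
        if lo_b <= c <= hi_b:
            return t, True
        if (d > 0 and c > hi_b) or (d < 0 and c < lo_b):
            if abs(prev_c - params.cf_target) <= abs(c - params.cf_target):
                return prev_t, False
            return t, False


class TestComputeCf:
    @pytest.mark.parametrize(
        "e,k,a,expected",
        [(29, 10, 4, 0.725), (0, 7, 4, 0.0), (10, 5, 4, 0.5), (8, 2, 4, 1.0)],
    )
    def test_direct_arithmetic(self, e, k, a, expected):
        assert compute_cf(e, k, a) == pytest.approx(expected)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            compute_cf(1, 0, 4)
        with pytest.raises(ValueError):
            compute_cf(-1, 3, 4)


class TestGeneratePatches:
    def test_mutually_close_residues_share_members(self):
        model = model_from_anchors([[0, 0, 0], [5, 0, 0], [0, 5, 0]])
        patches = generate_patches(model, all_surface(model), radius=15.0)
        assert len(patches) == 3
        member_sets = {frozenset(p.members) for p in patches}
        assert len(member_sets) == 1
        assert {p.center for p in patches} == set(model.keys)

    def test_remote_residue_forms_singleton_patch(self):
        model = model_from_anchors([[0, 0, 0], [5, 0, 0], [100, 0, 0]])
        patches = generate_patches(model, all_surface(model), radius=15.0)
        lone = [p for p in patches if p.center == ("A", 3, "")][0]
        assert lone.members == [("A", 3, "")]

    def test_oversized_patches_are_precluded(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 10, size=(60, 3))  # 60 residues within 15 Å
        model = model_from_anchors(coords)
        patches = generate_patches(model, all_surface(model), radius=15.0, max_size=50)
        assert patches == []
        kept = generate_patches(model, all_surface(model), radius=15.0, max_size=60)
        assert len(kept) == 60

    def test_no_surface_residues_is_an_error(self):
        model = model_from_anchors([[0, 0, 0], [5, 0, 0], [9, 0, 0]])
        acc = all_surface(model)
        acc.is_surface[:] = False
        with pytest.raises(NoSurfaceResiduesError):
            generate_patches(model, acc)


class TestFixedThresholdGraphs:
    def test_edge_iff_within_threshold(self):
        model = model_from_anchors([[0, 0, 0], [5, 0, 0]])
        patch = generate_patches(model, all_surface(model))[0]
        g = build_graph_fdt(patch, model, threshold=6.5)
        assert g.n_edges == 1 and g.cf == pytest.approx(1 / 8)
        far = model_from_anchors([[0, 0, 0], [7, 0, 0]])
        patch = generate_patches(far, all_surface(far))[0]
        assert build_graph_fdt(patch, far, threshold=6.5).n_edges == 0

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_edges_monotone_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        model = model_from_anchors(rng.uniform(0, 15, size=(8, 3)))
        patch = generate_patches(model, all_surface(model), radius=50.0)[0]
        prev = set()
        for t in (3.0, 5.0, 7.0, 10.0, 14.0):
            edges = build_graph_fdt(patch, model, threshold=t).edges
            assert prev <= edges
            prev = edges

    def test_cf_matches_edge_list_recount(self):
        rng = np.random.default_rng(3)
        model = model_from_anchors(rng.uniform(0, 12, size=(9, 3)))
        patch = generate_patches(model, all_surface(model), radius=50.0)[0]
        g = build_graph_fdt(patch, model, threshold=6.5)
        assert g.cf == pytest.approx(len(g.edges) / (4 * g.n_vertices))


class TestAdaptiveThresholdGraphs:
    def test_in_band_start_keeps_default_threshold(self):
        # engineer a patch whose CF at 6.5 Å already falls in [0.67, 0.79]:
        # 10 vertices need 27..31 edges
        rng = np.random.default_rng(5)
        for seed in range(40):
            rng = np.random.default_rng(seed)
            model = model_from_anchors(rng.uniform(0, 11, size=(10, 3)))
            patch = generate_patches(model, all_surface(model), radius=50.0)[0]
            if 0.67 <= build_graph_fdt(patch, model, 6.5).cf <= 0.79:
                g = build_graph_adt(patch, model, GraphParams())
                assert g.threshold == pytest.approx(6.5)
                assert g.band_reached
                return
        pytest.fail("no in-band seed found")

    def test_two_vertex_patch_band_unreachable(self):
        model = model_from_anchors([[0, 0, 0], [5, 0, 0]])
        patch = generate_patches(model, all_surface(model))[0]
        g = build_graph_adt(patch, model, GraphParams())
        assert not g.band_reached
        assert g.threshold == pytest.approx(GraphParams().threshold_bounds[1])
        assert g.cf == pytest.approx(1 / 8)

    def test_dense_cluster_threshold_shrinks_into_band(self):
        rng = np.random.default_rng(11)
        model = model_from_anchors(rng.uniform(0, 9, size=(14, 3)))
        patch = generate_patches(model, all_surface(model), radius=50.0)[0]
        params = GraphParams()
        assert build_graph_fdt(patch, model, 6.5).cf > 0.79
        g = build_graph_adt(patch, model, params)
        assert g.threshold < 6.5
        t_oracle, reached_oracle = adt_grid_oracle(patch, model, params)
        assert g.threshold == pytest.approx(t_oracle)
        assert g.band_reached == reached_oracle
        if g.band_reached:
            assert 0.67 <= g.cf <= 0.79

    def test_sparse_cluster_threshold_grows_above_start(self):
        rng = np.random.default_rng(2)
        model = model_from_anchors(rng.uniform(0, 30, size=(12, 3)))
        patch = generate_patches(model, all_surface(model), radius=60.0)[0]
        g = build_graph_adt(patch, model, GraphParams())
        assert g.threshold > 6.5

    @settings(max_examples=15, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_adt_equals_grid_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 15))
        spread = float(rng.uniform(6, 25))
        model = model_from_anchors(rng.uniform(0, spread, size=(n, 3)))
        patch = generate_patches(model, all_surface(model), radius=100.0)[0]
        params = GraphParams()
        g = build_graph_adt(patch, model, params)
        t_oracle, reached = adt_grid_oracle(patch, model, params)
        assert g.threshold == pytest.approx(t_oracle)
        assert g.band_reached == reached
        if g.band_reached:
            assert 0.67 - 1e-12 <= g.cf <= 0.79 + 1e-12

    def test_fdt_and_adt_share_vertex_set(self):
        rng = np.random.default_rng(8)
        model = model_from_anchors(rng.uniform(0, 14, size=(10, 3)))
        patch = generate_patches(model, all_surface(model), radius=50.0)[0]
        g1 = build_graph_fdt(patch, model, 6.5)
        g2 = build_graph_adt(patch, model, GraphParams())
        assert g1.vertices == g2.vertices


class TestAverageCf:
    def test_mean_and_permutation_invariance(self):
        rng = np.random.default_rng(4)
        model = model_from_anchors(rng.uniform(0, 12, size=(8, 3)))
        patches = generate_patches(model, all_surface(model), radius=50.0)
        graphs = [build_graph_fdt(p, model, 6.5) for p in patches]
        assert average_cf(graphs) == pytest.approx(np.mean([g.cf for g in graphs]))
        assert average_cf(graphs[::-1]) == pytest.approx(average_cf(graphs))
        assert average_cf(graphs[:1]) == pytest.approx(graphs[0].cf)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            average_cf([])
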