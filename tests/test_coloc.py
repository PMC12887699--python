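import math

import numpy as np
import pandas as pd
import pytest

import stnichekit as sk


def _spatial(counts, coords=None):
    counts = np.asarray(counts)
    n = counts.shape[0]
    ids = pd.Index([f"s{i}" for i in range(n)])
    genes = pd.Index([f"g{j}" for j in range(counts.shape[1])])
    coords = coords if coords is not None else np.column_stack([np.arange(n), np.zeros(n)])
    cm = sk.CountMatrix(counts, ids, genes)
    return sk.SpatialDataset(matrix=cm, coords=coords, region_label=pd.Series(["r"] * n, index=ids))


class TestDepthNormalize:
    def test_depth_correction_doubles_shallower_spot(self):
        ds = _spatial([[10, 90], [10, 190]])
        sig = sk.depth_normalize(ds, ["g0"])
        assert sig[0] == pytest.approx(2 * sig[1])

    def test_single_gene_signal_is_normalized_value(self):
        ds = _spatial([[10, 90], [20, 80]])
        sig = sk.depth_normalize(ds, "g0")
        med = 100.0
        np.testing.assert_allclose(sig, [10 / 100 * med, 20 / 100 * med])

    def test_two_gene_mean_equals_midpoint(self):
        ds = _spatial([[4, 6, 90], [1, 1, 98]])
        sig = sk.depth_normalize(ds, ["g0", "g1"])
        assert sig[0] == pytest.approx(sk.depth_normalize(_spatial([[5, 5, 90]]), "g0")[0])

    def test_absent_genes_dropped_none_fatal(self):
        ds = _spatial([[1, 1]])
        sig = sk.depth_normalize(ds, ["g0", "missing"])
        assert len(sig) == 1
        with pytest.raises(ValueError, match="none of the listed genes"):
            sk.depth_normalize(ds, ["missing"])

    def test_zero_total_spot_is_zero_signal(self):
        ds = _spatial([[0, 0], [5, 5]])
        sig = sk.depth_normalize(ds, ["g0"])
        assert sig[0] == 0.0


def _oracle_scores(a, b, neighbors):
    out = []
    for i in range(len(a)):
        best = 0.0
        max_b = max(b[j] for j in neighbors[i])
        max_a = max(a[j] for j in neighbors[i])
        best = max(a[i] * max_b, b[i] * max_a)
        out.append(best)
    return np.array(out)


class TestColocScore:
    def test_two_spot_toy_scores_one(self):
        graph = sk.NeighborGraph(
            indices=np.array([[1], [0]]), distances=np.ones((2, 1)), k=1
        )
        scores = sk.coloc_score([1.0, 0.0], [0.0, 1.0], graph, trim_q=1.0)
        np.testing.assert_allclose(scores, [1.0, 1.0])

    def test_swapping_signals_leaves_scores_unchanged(self):
        rng = np.random.default_rng(1)
        a, b = rng.uniform(size=40), rng.uniform(size=40)
        coords = rng.uniform(0, 10, size=(40, 2))
        graph = sk.knn_graph(coords, k=5)
        np.testing.assert_allclose(
            sk.coloc_score(a, b, graph, trim_q=1.0), sk.coloc_score(b, a, graph, trim_q=1.0)
        )

    @pytest.mark.parametrize("n", [30, 100])
    def test_matches_loop_oracle_then_winsorizes(self, n):
        rng = np.random.default_rng(n)
        a, b = rng.exponential(size=n), rng.exponential(size=n)
        coords = rng.uniform(0, 20, size=(n, 2))
        graph = sk.knn_graph(coords, k=6)
        raw = sk.coloc_score(a, b, graph, trim_q=1.0)
        oracle = _oracle_scores(a, b, [list(row) for row in graph.indices])
        np.testing.assert_allclose(raw, oracle)
        trimmed = sk.coloc_score(a, b, graph, trim_q=0.99)
        cap = np.quantile(oracle, 0.99)
        np.testing.assert_allclose(trimmed, np.minimum(oracle, cap))

    def test_zero_own_signals_give_zero_score(self):
        rng = np.random.default_rng(2)
        coords = rng.uniform(0, 5, size=(20, 2))
        graph = sk.knn_graph(coords, k=4)
        a = np.zeros(20)
        a[:10] = rng.uniform(size=10)
        b = np.zeros(20)
        b[5:15] = rng.uniform(size=10)
        scores = sk.coloc_score(a, b, graph, trim_q=1.0)
        both_zero = (a == 0) & (b == 0)
        assert (scores[both_zero] == 0).all()

    def test_quadratic_scaling(self):
        rng = np.random.default_rng(3)
        a, b = rng.uniform(size=25), rng.uniform(size=25)
        graph = sk.knn_graph(rng.uniform(0, 5, size=(25, 2)), k=4)
        s1 = sk.coloc_score(a, b, graph, trim_q=1.0)
        s2 = sk.coloc_score(3 * a, 3 * b, graph, trim_q=1.0)
        np.testing.assert_allclose(s2, 9 * s1)

    def test_mismatched_lengths_fatal(self):
        graph = sk.NeighborGraph(np.array([[1], [0]]), np.ones((2, 1)), 1)
        with pytest.raises(ValueError, match="mismatch"):
            sk.coloc_score([1.0], [1.0, 2.0], graph)


class TestHighMask:
    def test_top_decile_of_ten_distinct_values(self):
        mask = sk.high_mask(np.arange(1, 11), top_frac=0.10)
        assert mask.sum() == 1 and mask[9]

    def test_all_equal_breaks_ties_by_index(self):
        mask = sk.high_mask(np.ones(20), top_frac=0.10)
        assert mask.sum() == math.ceil(2.0)
        assert mask[:2].all() and not mask[2:].any()

    def test_top_frac_one_selects_all(self):
        mask = sk.high_mask(np.arange(7), top_frac=1.0)
        assert mask.all()

    def test_ceil_rule(self):
        assert sk.high_mask(np.arange(15), top_frac=0.10).sum() == 2  # ceil(1.5)


class TestOverlapMap:
    def test_disjoint_masks(self):
        res = sk.overlap_map(np.array([1, 1, 0, 0], bool), np.array([0, 0, 1, 1], bool))
        assert res["count"] == 0 and res["jaccard"] == 0.0

    def test_identical_masks(self):
        m = np.array([1, 0, 1, 0, 1], bool)
        res = sk.overlap_map(m, m)
        assert res["count"] == 3 and res["jaccard"] == 1.0

    def test_expected_under_independence(self):
        a = np.zeros(100, bool)
        a[:10] = True
        b = np.zeros(100, bool)
        b[5:25] = True
        res = sk.overlap_map(a, b)
        assert res["expected"] == pytest.approx(100 * 0.1 * 0.2)
        assert res["count"] == 5


class TestNullOverlapCalibration:
    def test_independent_masks_match_closed_form(self):
        """Top-decile overlap of two background-gene signals on null tissue
        matches n*f_a*f_b once the cross-gene coupling through shared spot
        depth is broken by permuting one signal (mean over seeds within
        2 SE of the independence expectation)."""
        from conftest import make_config

        diffs = []
        for s in range(40):
            cfg = make_config(seed=3000 + s)
            spatial = sk.simulate_null_spatial(cfg)
            sig_a = sk.depth_normalize(spatial, ["g0030"])
            sig_b = sk.depth_normalize(spatial, ["g0031", "g0032"])
            rng = np.random.default_rng(9000 + s)
            sig_b = rng.permutation(sig_b)
            res = sk.overlap_map(sk.high_mask(sig_a), sk.high_mask(sig_b))
            diffs.append(res["count"] - res["expected"])
        diffs = np.asarray(diffs)
        sem = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) <= 2 * sem + 1e-9

    def test_shared_depth_couples_unpermuted_masks(self):
        """Without the permutation the same masks co-occur above chance:
        spot-level depth noise is shared between genes and survives
        total-count normalization.  This is the documented reason the
        closed form needs the independence premise."""
        from conftest import make_config

        cfg = make_config(seed=3000)
        spatial = sk.simulate_null_spatial(cfg)
        sig_a = sk.depth_normalize(spatial, ["g0030"])
        sig_b = sk.depth_normalize(spatial, ["g0031", "g0032"])
        res = sk.overlap_map(sk.high_mask(sig_a), sk.high_mask(sig_b))
        assert res["count"] > res["expected"]


class TestPlantedInterface:
    def test_interface_scores_exceed_background(self, sim):
        _, _, spatial, _, truth = sim
        graph = sk.knn_graph(spatial.coords, k=6)
        res = sk.colocalize(
            spatial,
            truth.marker_genes[truth.interface_pair[0]][:1],
            truth.marker_genes[truth.interface_pair[1]][:2],
            graph,
        )
        iface = (spatial.region_label == "interface").to_numpy()
        s = res.scores.to_numpy()
        assert s[iface].mean() > 2 * s[~iface].mean()

    def test_high_masks_concentrate_at_interface(self, sim):
        """Both partners' top-decile masks land in the interface ring (the
        planted adjacency is across neighboring spots, so the masks cluster
        in the same ring without needing to share identical spots)."""
        _, _, spatial, _, truth = sim
        graph = sk.knn_graph(spatial.coords, k=6)
        res = sk.colocalize(
            spatial,
            truth.marker_genes[truth.interface_pair[0]][:1],
            truth.marker_genes[truth.interface_pair[1]][:2],
            graph,
        )
        iface = (spatial.region_label == "interface").to_numpy()
        area_fraction = iface.mean()
        assert iface[res.mask_a].mean() > 2 * area_fraction
        assert iface[res.mask_b].mean() > 2 * area_fraction
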