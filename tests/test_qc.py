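import itertools

import numpy as np
import pandas as pd
import pytest

import stnichekit as sk
from stnichekit.core import NormalizedMatrix


def _norm(values, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{j}" for j in range(values.shape[1])]
    return NormalizedMatrix(
        values=values,
        obs_ids=pd.Index([f"o{i}" for i in range(values.shape[0])]),
        gene_ids=pd.Index(genes),
    )


class TestQcFilter:
    def test_threshold_pattern_keeps_cells_three_and_four(self, toy_counts):
        kept = sk.qc_filter(toy_counts, min_counts=1000, max_mito=0.15, min_cells_per_sample=1)
        assert list(kept.obs_ids) == ["c2", "c3"]

    def test_boundaries_are_inclusive(self):
        meta = pd.DataFrame(
            {"sample_id": ["s"], "mito_fraction": [0.15]}, index=pd.Index(["c"])
        )
        cm = sk.CountMatrix(np.array([[1000]]), pd.Index(["c"]), pd.Index(["g"]), meta)
        kept = sk.qc_filter(cm, min_counts=1000, max_mito=0.15, min_cells_per_sample=1)
        assert kept.n_obs == 1

    def test_undersized_sample_dropped_whole(self):
        n_small, n_big = 999, 1000
        ids = [f"a{i}" for i in range(n_small)] + [f"b{i}" for i in range(n_big)]
        meta = pd.DataFrame(
            {
                "sample_id": ["small"] * n_small + ["big"] * n_big,
                "mito_fraction": 0.0,
            },
            index=pd.Index(ids),
        )
        cm = sk.CountMatrix(np.full((n_small + n_big, 1), 5), pd.Index(ids), pd.Index(["g"]), meta)
        kept = sk.qc_filter(cm, min_counts=1, max_mito=1.0, min_cells_per_sample=1000)
        assert set(kept.obs_meta["sample_id"]) == {"big"}
        assert kept.n_obs == n_big

    def test_idempotent(self, sim):
        _, cells, *_ = sim
        once = sk.qc_filter(cells, min_counts=400, max_mito=0.15, min_cells_per_sample=50)
        twice = sk.qc_filter(once, min_counts=400, max_mito=0.15, min_cells_per_sample=50)
        assert list(once.obs_ids) == list(twice.obs_ids)

    def test_empty_result_fatal_with_tally(self, toy_counts):
        with pytest.raises(ValueError, match="tally"):
            sk.qc_filter(toy_counts, min_counts=10_000, max_mito=0.15, min_cells_per_sample=1)


class TestLognormalize:
    def test_zero_count_maps_to_zero_exactly(self, toy_counts):
        cm = sk.CountMatrix(
            np.array([[0, 10], [5, 5]]),
            pd.Index(["a", "b"]),
            pd.Index(["g1", "g2"]),
        )
        norm = sk.lognormalize(cm)
        assert norm.values[0, 0] == 0.0

    def test_deeper_cell_gets_smaller_value_for_same_count(self):
        cm = sk.CountMatrix(
            np.array([[10, 90], [10, 190]]), pd.Index(["a", "b"]), pd.Index(["g1", "g2"])
        )
        norm = sk.lognormalize(cm)
        assert norm.values[0, 0] > norm.values[1, 0]

    def test_worked_value(self):
        cm = sk.CountMatrix(np.array([[10, 90]]), pd.Index(["a"]), pd.Index(["g1", "g2"]))
        norm = sk.lognormalize(cm, scale=1e4)
        assert norm.values[0, 0] == pytest.approx(np.log(1 + 1000), abs=1e-9)

    def test_zero_total_cell_left_all_zero(self):
        cm = sk.CountMatrix(np.array([[0, 0], [1, 1]]), pd.Index(["a", "b"]), pd.Index(["g1", "g2"]))
        norm = sk.lognormalize(cm)
        assert (norm.values[0] == 0).all()


def _oracle_ranksum_p(x, y):
    """Independent exact rank-sum oracle: own midranks + full enumeration."""
    pooled = list(x) + list(y)
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and pooled[order[j]] == pooled[order[i]]:
            j += 1
        mid = (i + 1 + j) / 2.0
        for idx in order[i:j]:
            ranks[idx] = mid
        i = j
    nx, n = len(x), len(pooled)
    mu = nx * (n + 1) / 2.0
    w_obs = sum(ranks[:nx])
    count = total = 0
    for combo in itertools.combinations(range(n), nx):
        w = sum(ranks[i] for i in combo)
        total += 1
        count += abs(w - mu) >= abs(w_obs - mu) - 1e-9
    return count / total


class TestFindMarkers:
    def test_separated_toy_gene_exact_p(self):
        """[5,5,5] vs [0,0,0]: only 2 of C(6,3)=20 assignments are as
        extreme, so the exact two-sided rank-sum p is 0.1."""
        norm = _norm([[5], [5], [5], [0], [0], [0]])
        labels = ["A"] * 3 + ["B"] * 3
        table = sk.find_markers(norm, labels)
        assert list(table["cluster_label"]) == ["A"]
        assert table["p_value"].iloc[0] == pytest.approx(0.1)
        assert table["fraction_in"].iloc[0] == 1.0
        assert table["fraction_out"].iloc[0] == 0.0

    def test_identical_gene_absent_from_table(self):
        norm = _norm([[2, 5], [2, 5], [2, 5], [2, 0], [2, 0], [2, 0]])
        table = sk.find_markers(norm, ["A"] * 3 + ["B"] * 3)
        assert "g0" not in set(table["gene_id"])

    def test_exact_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            x = rng.integers(0, 4, size=4).astype(float)
            y = rng.integers(0, 4, size=5).astype(float)
            from stnichekit._stats import ranksum_exact_p

            assert ranksum_exact_p(x, y) == pytest.approx(_oracle_ranksum_p(x, y))

    def test_small_label_excluded_with_warning(self):
        norm = _norm([[5], [5], [5], [0], [0], [0], [9]])
        labels = ["A"] * 3 + ["B"] * 3 + ["C"]
        table = sk.find_markers(norm, labels)
        assert "C" not in set(table["cluster_label"])

    def test_requires_two_usable_labels(self):
        norm = _norm([[1], [2], [3], [4]])
        with pytest.raises(ValueError, match=">=2 labels"):
            sk.find_markers(norm, ["A", "A", "A", "B"])

    def test_q_at_least_p_and_sorted_within_cluster(self, sim):
        _, cells, *_ = sim
        kept = sk.qc_filter(cells, min_counts=400, max_mito=0.15, min_cells_per_sample=50)
        table = sk.find_markers(sk.lognormalize(kept), kept.obs_meta["cluster_label"])
        assert (table["q_value"] >= table["p_value"] - 1e-12).all()
        for _, grp in table.groupby("cluster_label"):
            q = grp["q_value"].to_numpy()
            assert (np.diff(q) >= -1e-12).all()

    def test_planted_markers_recovered(self, sim):
        _, cells, *_, truth = sim
        table = sk.find_markers(sk.lognormalize(cells), cells.obs_meta["cluster_label"])
        for t, genes in truth.marker_genes.items():
            hits = set(table[(table.cluster_label == t) & (table.q_value < 0.05)]["gene_id"])
            assert len(hits & set(genes)) / len(genes) >= 0.9


class TestFindMarkersCrossCheck:
    def test_asymptotic_p_tracks_scanpy_wilcoxon(self, sim):
        """Independent route: scanpy's tie-corrected Wilcoxon on the same
        normalized data should order and scale gene significance the same
        way for the genes our detector reports."""
        scanpy = pytest.importorskip("scanpy")
        _, cells, *_ = sim
        sub = cells.subset_obs(np.arange(600))
        adata = sub.to_anndata()
        scanpy.pp.normalize_total(adata, target_sum=1e4)
        scanpy.pp.log1p(adata)
        scanpy.tl.rank_genes_groups(
            adata, "cluster_label", method="wilcoxon", tie_correct=True, pts=False
        )
        ours = sk.find_markers(sk.lognormalize(sub), sub.obs_meta["cluster_label"])
        group = "lam"
        names = list(adata.uns["rank_genes_groups"]["names"][group])
        theirs = dict(zip(names, adata.uns["rank_genes_groups"]["pvals"][group]))
        sub_tab = ours[ours.cluster_label == group]
        checked = 0
        for _, row in sub_tab.iterrows():
            p_ours, p_sc = row["p_value"], theirs[row["gene_id"]]
            la, lb = -np.log10(max(p_ours, 1e-280)), -np.log10(max(p_sc, 1e-280))
            assert la == pytest.approx(lb, rel=0.15, abs=0.5)
            checked += 1
        assert checked >= 5


class TestSignatureScore:
    def test_mean_of_present_set_genes(self):
        norm = _norm([[1, 2, 3, 9]], genes=["a", "b", "c", "d"])
        score = sk.signature_score(norm, sk.GeneSet("s", ["a", "b", "c"]))
        assert score.iloc[0] == pytest.approx(2.0)

    def test_all_zero_cell_scores_zero(self):
        norm = _norm([[0, 0], [1, 3]], genes=["a", "b"])
        score = sk.signature_score(norm, sk.GeneSet("s", ["a", "b"]))
        assert score.iloc[0] == 0.0

    def test_invariant_to_order_and_absent_genes(self):
        norm = _norm([[1, 2, 3]], genes=["a", "b", "c"])
        s1 = sk.signature_score(norm, sk.GeneSet("s", ["a", "b", "c"]))
        s2 = sk.signature_score(norm, sk.GeneSet("s", ["c", "a", "b", "missing"]))
        assert s1.iloc[0] == s2.iloc[0]

    def test_no_gene_present_fatal(self):
        norm = _norm([[1]], genes=["a"])
        with pytest.raises(ValueError, match="no gene"):
            sk.signature_score(norm, sk.GeneSet("s", ["zz"]))

    def test_planted_type_scores_highest_on_own_markers(self, sim):
        _, cells, *_, truth = sim
        norm = sk.lognormalize(cells)
        for t in ("lam", "epithelial"):
            score = sk.signature_score(norm, sk.GeneSet(t, truth.marker_genes[t]))
            own = (truth.cell_types == t).to_numpy()
            assert np.quantile(score[own], 0.025) > np.quantile(score[~own], 0.975)
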