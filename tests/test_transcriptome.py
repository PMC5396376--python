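"""TPM, gene filtering, DEG calls, pi-values, persistence, clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exitkit import synthetic, transcriptome as tr


class TestTpm:
    def test_equal_counts_equal_lengths_split_evenly(self):
        counts = pd.DataFrame({"s1": [10, 10]}, index=["g1", "g2"])
        tpm = tr.counts_to_tpm(counts, pd.Series([100, 100], index=["g1", "g2"]))
        assert tpm["s1"].tolist() == [500_000.0, 500_000.0]

    def test_zero_count_gives_zero_tpm(self):
        counts = pd.DataFrame({"s1": [0, 10]}, index=["g1", "g2"])
        tpm = tr.counts_to_tpm(counts, pd.Series([100, 100], index=["g1", "g2"]))
        assert tpm.loc["g1", "s1"] == 0.0

    def test_five_gene_hand_oracle(self):
        counts = pd.DataFrame({"s1": [100, 200, 300, 0, 50]},
                              index=list("abcde"))
        lengths = pd.Series([1_000, 2_000, 500, 700, 250], index=list("abcde"))
        rates = counts["s1"] / lengths
        expected = 1e6 * rates / rates.sum()
        tpm = tr.counts_to_tpm(counts, lengths)
        np.testing.assert_allclose(tpm["s1"], expected, atol=1e-9)

    def test_zero_length_rejected(self):
        counts = pd.DataFrame({"s1": [1]}, index=["g1"])
        with pytest.raises(ValueError):
            tr.counts_to_tpm(counts, pd.Series([0], index=["g1"]))

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_columns_sum_to_one_million(self, seed):
        rng = np.random.default_rng(seed)
        counts = pd.DataFrame(
            rng.integers(1, 1_000, (20, 4)), index=[f"g{i}" for i in range(20)]
        )
        lengths = pd.Series(rng.integers(200, 5_000, 20), index=counts.index)
        tpm = tr.counts_to_tpm(counts, lengths)
        np.testing.assert_allclose(tpm.sum(axis=0), 1e6, rtol=1e-9)


class TestFilterGenes:
    def _data(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        tpm = pd.DataFrame(
            rng.uniform(0, 50, (n, 6)), index=[f"g{i:03d}" for i in range(n)]
        )
        biotypes = pd.Series("protein_coding", index=tpm.index)
        return tpm, biotypes

    def test_expression_boundary_inclusive(self):
        tpm = pd.DataFrame(
            {"s1": [5.0, 4.9], "s2": [5.0, 60.0], "s3": [5.0, 60.0], "s4": [0.0, 0.0]},
            index=["boundary", "two_samples"],
        )
        biotypes = pd.Series("protein_coding", index=tpm.index)
        kept = tr.filter_genes(tpm, biotypes, drop_low_variability_fraction=0.0)
        assert "boundary" in kept  # exactly 5 TPM in exactly 3 samples
        assert "two_samples" not in kept

    def test_biotype_filter_precedes_expression(self):
        tpm = pd.DataFrame({"s1": [1e4], "s2": [1e4], "s3": [1e4]}, index=["mi1"])
        kept = tr.filter_genes(tpm, pd.Series({"mi1": "miRNA"}))
        assert len(kept) == 0

    def test_exactly_eighty_of_hundred_survive_variability_step(self):
        tpm, biotypes = self._data(100)
        tpm = tpm + 5.0  # everything passes the expression step
        kept = tr.filter_genes(tpm, biotypes)
        assert len(kept) == 80

    def test_dropped_genes_are_the_least_variable(self):
        tpm, biotypes = self._data(50)
        tpm = tpm + 5.0
        kept = tr.filter_genes(tpm, biotypes)
        var = np.log2(tpm + 1).std(axis=1, ddof=1)
        assert var[~var.index.isin(kept)].max() <= var[var.index.isin(kept)].min()

    def test_fitted_filter_is_idempotent(self):
        tpm, biotypes = self._data(100)
        tpm = tpm + 5.0
        flt = tr.GeneFilter()
        kept = flt.apply(tpm, biotypes)
        again = flt.apply(tpm.loc[kept], biotypes.loc[kept])
        assert list(again) == list(kept)

    def test_missing_biotype_raises(self):
        tpm, biotypes = self._data(10)
        with pytest.raises(KeyError):
            tr.filter_genes(tpm, biotypes.iloc[:5])


class TestDegCall:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["log2fc", "p", "q"],
                            index=[f"g{i}" for i in range(len(rows))])

    def test_thresholds_are_strict(self):
        table = self._table([(1.0, 1e-5, 1e-4), (1.01, 0.01, 0.02), (1.01, 0.009, 0.02)])
        out = tr.deg_call(table)
        assert out["deg_status"].tolist() == ["ns", "ns", "up"]

    def test_down_call_and_binning(self):
        out = tr.deg_call(self._table([(-2.5, 1e-5, 1e-4)]))
        assert out.iloc[0]["deg_status"] == "down"
        assert out.iloc[0]["lfc_bin"] == "(2,4]"

    def test_missing_p_reported_ns(self):
        out = tr.deg_call(self._table([(3.0, np.nan, np.nan)]))
        assert out.iloc[0]["deg_status"] == "ns"

    def test_planted_degs_recovered(self):
        genes = [f"g{i}" for i in range(500)]
        planted = {f"g{i}": 2.5 if i % 2 else -2.5 for i in range(40)}
        sim = synthetic.make_counts(genes, planted, seed=21)
        out = tr.deg_call(sim.de_table)
        truth_status = pd.Series(
            {g: ("up" if lfc > 0 else "down") for g, lfc in planted.items()}
        )
        called = out.loc[truth_status.index, "deg_status"]
        assert (called == truth_status).mean() >= 0.9


class TestPiRank:
    def test_formula(self):
        table = pd.DataFrame({"log2fc": [2.0], "q": [0.01], "p": [0.001]}, index=["g1"])
        assert tr.pi_rank(table).iloc[0]["pi_value"] == pytest.approx(4.0)

    def test_q_of_one_gives_zero(self):
        table = pd.DataFrame({"log2fc": [7.0], "q": [1.0], "p": [0.9]}, index=["g1"])
        assert tr.pi_rank(table).iloc[0]["pi_value"] == 0.0

    def test_sign_follows_fold_change_and_order_descending(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(
            {"log2fc": rng.normal(0, 2, 50), "q": rng.uniform(1e-6, 1, 50)},
            index=[f"g{i}" for i in range(50)],
        )
        out = tr.pi_rank(table)
        assert (np.sign(out["pi_value"]) == np.sign(out["log2fc"])).all()
        assert out["pi_value"].is_monotonic_decreasing

    def test_zero_q_clamped_to_smallest_positive(self):
        table = pd.DataFrame(
            {"log2fc": [1.0, 1.0], "q": [0.0, 1e-10]}, index=["g1", "g2"]
        )
        out = tr.pi_rank(table)
        assert np.isfinite(out["pi_value"]).all()
        assert out.loc["g1", "pi_value"] == out.loc["g2", "pi_value"]


class TestPersistence:
    def _status(self, mapping):
        return pd.Series(mapping)

    def test_identical_sets_fully_persistent(self):
        s = self._status({"g1": "up", "g2": "down", "g3": "ns"})
        out = tr.deg_persistence(s, s.copy())
        assert out["persistence_up"] == 1.0 and out["persistence_down"] == 1.0

    def test_disjoint_sets_zero_persistence(self):
        t1 = self._status({"g1": "up", "g2": "down"})
        t2 = self._status({"g1": "ns", "g2": "ns"})
        out = tr.deg_persistence(t1, t2)
        assert out["persistence_up"] == 0.0 and out["persistence_down"] == 0.0

    def test_partition_of_t1_degs(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(300)]
        t1 = pd.Series(rng.choice(["up", "down", "ns"], 300), index=genes)
        t2 = pd.Series(rng.choice(["up", "down", "ns"], 300), index=genes)
        out = tr.deg_persistence(t1, t2)
        n_up = (t1 == "up").sum()
        persisters = round(out["persistence_up"] * out["n_up_t1"])
        assert persisters + out["switchers_up"] + out["dropouts_up"] == n_up

    def test_empty_t1_reported_missing(self):
        t1 = self._status({"g1": "ns"})
        out = tr.deg_persistence(t1, t1.copy())
        assert np.isnan(out["persistence_up"])


def brute_force_upgma(dist):
    """Textbook UPGMA on a dense matrix; returns sorted merge heights."""
    import itertools

    clusters = {i: [i] for i in range(len(dist))}
    d = {frozenset([i, j]): dist[i][j] for i, j in
         itertools.combinations(range(len(dist)), 2)}
    heights = []
    next_id = len(dist)
    while len(clusters) > 1:
        pair = min(d, key=lambda k: d[k])
        heights.append(d[pair])
        i, j = sorted(pair)
        merged = clusters[i] + clusters[j]
        del clusters[i], clusters[j]
        new_d = {}
        for k, members in clusters.items():
            val = np.mean([dist[a][b] for a in merged for b in members])
            new_d[frozenset([next_id, k])] = val
        d = {k: v for k, v in d.items() if i not in k and j not in k}
        d.update(new_d)
        clusters[next_id] = merged
        next_id += 1
    return sorted(heights)


class TestCorrelationCluster:
    def test_duplicate_item_distance_zero_merged_first(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.random((3, 6)), index=["a", "b", "c"])
        m.loc["c"] = m.loc["a"]
        res = tr.correlation_cluster(m, axis=0)
        assert res.distance.loc["a", "c"] == pytest.approx(0.0)
        assert res.linkage[0, 2] == pytest.approx(0.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.random((2, 8)), index=["a", "b"])
        m.loc["b"] = np.exp(3 * m.loc["a"])  # monotone transform of a
        res = tr.correlation_cluster(m, axis=0)
        assert res.distance.loc["a", "b"] == pytest.approx(0.0)

    def test_merge_heights_match_brute_force_upgma(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.random((5, 6)), index=list("abcde"))
        res = tr.correlation_cluster(m, axis=0)
        expected = brute_force_upgma(res.distance.to_numpy())
        np.testing.assert_allclose(sorted(res.linkage[:, 2]), expected, atol=1e-12)

    def test_zero_variance_item_named_in_error(self):
        m = pd.DataFrame({"o1": [1.0, 2.0], "o2": [1.0, 2.0], "o3": [1.0, 2.0]},
                         index=["flat", "ok"]).T.T
        m.loc["flat"] = 1.0
        with pytest.raises(ValueError, match="flat"):
            tr.correlation_cluster(m, axis=0)

    def test_newick_contains_all_leaves(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(rng.random((4, 6)), index=list("wxyz"))
        res = tr.correlation_cluster(m, axis=0)
        assert sorted(res.leaf_order) == list("wxyz")
        for leaf in "wxyz":
            assert leaf in res.newick
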