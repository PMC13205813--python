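"""NC scoring, NMF consensus clustering, cluster labelling and consensus."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from hypoxapa.enrichment import GeneSet
from hypoxapa.hypoxia_class import (
    consensus,
    label_clusters,
    nc_classify,
    nc_score,
    nmf_cluster,
)


def sig(*genes):
    return GeneSet.from_iterable("sig", genes)


class TestNcScore:
    def test_two_samples_one_gene(self):
        expr = pd.DataFrame({"a": [5.0], "b": [3.0]}, index=["g"])
        s = nc_score(expr, sig("g"))
        assert s["a"] == 1 and s["b"] == -1

    def test_scores_sum_to_zero_for_even_tie_free_samples(self, rng):
        expr = pd.DataFrame(rng.normal(size=(10, 8)),
                            index=[f"g{i}" for i in range(10)])
        assert nc_score(expr, sig(*expr.index)).sum() == 0

    def test_matches_bruteforce_median_split(self, rng):
        expr = pd.DataFrame(rng.normal(size=(10, 6)),
                            index=[f"g{i}" for i in range(10)])
        got = nc_score(expr, sig(*expr.index))
        for sample in expr.columns:
            expected = 0
            for g in expr.index:
                r = rankdata(expr.loc[g])[list(expr.columns).index(sample)]
                expected += 1 if r > 3 else -1
            assert got[sample] == expected

    def test_monotone_per_gene_transform_invariance(self, rng):
        expr = pd.DataFrame(rng.uniform(1, 10, size=(6, 8)),
                            index=[f"g{i}" for i in range(6)])
        assert nc_score(expr, sig(*expr.index)).equals(
            nc_score(np.exp(expr * 2), sig(*expr.index))
        )

    def test_absent_signature_rejected(self):
        expr = pd.DataFrame({"a": [1.0], "b": [2.0]}, index=["g"])
        with pytest.raises(ValueError):
            nc_score(expr, sig("other"))


class TestNcClassify:
    def test_all_positive_is_hypoxic(self):
        scores = pd.DataFrame({"s": [3, 1, 5]}, index=["w", "b", "r"]).T.T
        assert nc_classify(scores)["s"] == "hypoxic"

    def test_discordant_is_mixed_under_unanimity(self):
        scores = pd.DataFrame({"s": [3, -1, 5]}, index=["w", "b", "r"])
        assert nc_classify(scores)["s"] == "mixed"
        assert nc_classify(scores, rule="majority")["s"] == "hypoxic"

    def test_zero_score_is_mixed(self):
        scores = pd.DataFrame({"s": [3, 0, 5]}, index=["w", "b", "r"])
        assert nc_classify(scores)["s"] == "mixed"

    def test_all_negative_is_normoxic(self):
        scores = pd.DataFrame({"s": [-3, -1, -5]}, index=["w", "b", "r"])
        assert nc_classify(scores)["s"] == "normoxic"


class TestNmf:
    @pytest.fixture()
    def block_matrix(self, rng):
        """Two blocks of duplicated columns (plus tiny jitter-free structure)."""
        a = rng.uniform(1, 10, size=50)
        b = rng.uniform(1, 10, size=50)
        cols = {f"a{i}": a for i in range(6)} | {f"b{i}": b for i in range(6)}
        return pd.DataFrame(cols)

    def test_duplicated_blocks_recovered_exactly(self, block_matrix):
        assign = nmf_cluster(block_matrix, k=2, restarts=5, seed=0)
        a_lab = assign[[c for c in assign.index if c.startswith("a")]]
        b_lab = assign[[c for c in assign.index if c.startswith("b")]]
        assert a_lab.nunique() == 1 and b_lab.nunique() == 1
        assert a_lab.iloc[0] != b_lab.iloc[0]

    def test_same_seed_identical(self, block_matrix):
        a = nmf_cluster(block_matrix, k=2, restarts=3, seed=9)
        b = nmf_cluster(block_matrix, k=2, restarts=3, seed=9)
        assert a.equals(b)

    def test_restart_count_stable_for_separated_groups(self, block_matrix):
        a = nmf_cluster(block_matrix, k=2, restarts=1, seed=4)
        b = nmf_cluster(block_matrix, k=2, restarts=10, seed=4)
        # same partition up to cluster id permutation
        assert (a == a.iloc[0]).equals(b == b.iloc[0])

    def test_negative_entries_rejected(self):
        bad = pd.DataFrame({"a": [1.0, -1.0], "b": [2.0, 3.0], "c": [1.0, 1.0]})
        with pytest.raises(ValueError):
            nmf_cluster(bad, k=2)

    def test_bad_k_rejected(self, block_matrix):
        with pytest.raises(ValueError):
            nmf_cluster(block_matrix, k=1)
        with pytest.raises(ValueError):
            nmf_cluster(block_matrix, k=len(block_matrix.columns))


class TestLabelClusters:
    def test_three_clusters_high_low_mixed(self):
        assign = pd.Series([0, 0, 1, 1, 2, 2], index=list("abcdef"))
        scores = pd.Series([0.8, 0.8, 0.1, 0.1, 0.4, 0.4], index=list("abcdef"))
        lab, tie = label_clusters(assign, scores)
        assert not tie
        assert lab["a"] == "hypoxic" and lab["c"] == "normoxic" and lab["e"] == "mixed"

    def test_two_clusters_no_mixed(self):
        assign = pd.Series([0, 0, 1, 1], index=list("abcd"))
        scores = pd.Series([0.9, 0.7, 0.2, 0.1], index=list("abcd"))
        lab, _ = label_clusters(assign, scores)
        assert set(lab) == {"hypoxic", "normoxic"}

    def test_equal_means_tie_flagged_and_broken_by_index(self):
        assign = pd.Series([0, 1], index=["a", "b"])
        scores = pd.Series([0.5, 0.5], index=["a", "b"])
        lab, tie = label_clusters(assign, scores)
        assert tie
        assert lab["a"] == "hypoxic" and lab["b"] == "normoxic"

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            label_clusters(pd.Series([0, 0], index=["a", "b"]),
                           pd.Series([1.0, 2.0], index=["a", "b"]))


class TestConsensus:
    @pytest.mark.parametrize(
        "nc,nmf,expected",
        [("hypoxic", "hypoxic", "hypoxic"),
         ("normoxic", "normoxic", "normoxic"),
         ("hypoxic", "normoxic", "mixed"),
         ("mixed", "hypoxic", "mixed"),
         ("mixed", "mixed", "mixed")],
    )
    def test_concordance_rule(self, nc, nmf, expected):
        out = consensus(pd.Series({"s": nc}), pd.Series({"s": nmf}))
        assert out.loc["s", "consensus_label"] == expected

    def test_sample_mismatch_rejected(self):
        with pytest.raises(ValueError):
            consensus(pd.Series({"s": "hypoxic"}), pd.Series({"t": "hypoxic"}))

    def test_never_confident_unless_both_are(self, rng):
        labs = np.array(["hypoxic", "normoxic", "mixed"])
        nc = pd.Series(rng.choice(labs, 50), index=[f"s{i}" for i in range(50)])
        nmf = pd.Series(rng.choice(labs, 50), index=nc.index)
        out = consensus(nc, nmf)
        confident = out["consensus_label"].isin(["hypoxic", "normoxic"])
        assert (out.loc[confident, "nc_label"] == out.loc[confident, "nmf_label"]).all()
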