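"""Statistical core: matrix R, contingency tables, Fisher's exact test against an
enumeration oracle, BH correction, resampling, gene scores, and red-band clustering."""

import itertools
import random
from math import comb

import numpy as np
import pandas as pd
import pytest

from pathreach.reach import ReachProfile, assign_levels
from pathreach.stats import (
    ContingencyTable,
    adjust_matrix,
    bh_adjust,
    candidate_table,
    contingency,
    fisher_exact,
    gene_score,
    reach_similarity_matrix,
    red_band_cluster,
    resample_pvalues,
    select_candidates,
)


def fisher_oracle(a, b, c, d, alternative="greater"):
    """Full fixed-margin enumeration: exact hypergeometric tail/point sums."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    total = comb(n, c1)
    weights = {x: comb(r1, x) * comb(n - r1, c1 - x) for x in range(lo, hi + 1)}
    if alternative == "greater":
        num = sum(w for x, w in weights.items() if x >= a)
    elif alternative == "less":
        num = sum(w for x, w in weights.items() if x <= a)
    else:  # two-sided: sum of point probabilities not exceeding the observed one
        cutoff = weights[a] * (1 + 1e-9)
        num = sum(w for w in weights.values() if w <= cutoff)
    return num / total


def levels_from(mapping):
    prof = ReachProfile(m=2, values=pd.Series({g: 1.0 - lvl / 10 for g, lvl in mapping.items()}))
    return assign_levels(prof, n_levels=max(mapping.values()))


class TestReachSimilarityMatrix:
    def test_same_and_different_levels(self):
        levels = levels_from({"r1": 1, "r2": 2, "c1": 1, "c2": 2})
        mat = reach_similarity_matrix(levels, ["r1", "r2"], ["c1", "c2"])
        assert mat.at["r1", "c1"] == 1 and mat.at["r1", "c2"] == 0
        assert mat.at["r2", "c2"] == 1

    def test_matches_equality_oracle(self):
        rnd = random.Random(13)
        genes = [f"g{i}" for i in range(12)]
        lv = {g: rnd.randrange(1, 5) for g in genes}
        levels = levels_from(lv)
        mat = reach_similarity_matrix(levels, genes[:8], genes[8:])
        for r in genes[:8]:
            for c in genes[8:]:
                assert mat.at[r, c] == (1 if levels.assignment[r] == levels.assignment[c] else 0)

    def test_genes_absent_from_network_dropped(self):
        levels = levels_from({"a": 1, "b": 2})
        mat = reach_similarity_matrix(levels, ["a", "ghost"], ["b"])
        assert list(mat.index) == ["a"]

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            reach_similarity_matrix(levels_from({"a": 1, "b": 2}), [], ["a"])


class TestContingency:
    def test_balanced_example(self):
        p = pd.Series([1, 1, 0, 0], index=list("wxyz"))
        r = pd.Series([1, 0, 1, 0], index=list("wxyz"))
        t = contingency(p, r)
        assert (t.A, t.B, t.C, t.D) == (1, 1, 1, 1)

    def test_all_ones_concentrate_in_a(self):
        idx = [f"d{i}" for i in range(7)]
        ones = pd.Series(1, index=idx)
        t = contingency(ones, ones)
        assert (t.A, t.B, t.C, t.D) == (7, 0, 0, 0)

    def test_counts_sum_to_subset_size(self):
        rnd = random.Random(1)
        idx = [f"d{i}" for i in range(50)]
        p = pd.Series([rnd.randrange(2) for _ in idx], index=idx)
        r = pd.Series([rnd.randrange(2) for _ in idx], index=idx)
        subset = rnd.sample(idx, 20)
        t = contingency(p, r, columns=subset)
        assert t.total == 20
        # brute-force per-column scan
        expect = [0, 0, 0, 0]
        for c in subset:
            expect[{(1, 1): 0, (1, 0): 1, (0, 1): 2, (0, 0): 3}[(p[c], r[c])]] += 1
        assert [t.A, t.B, t.C, t.D] == expect

    def test_mismatched_labels_rejected(self):
        p = pd.Series([1], index=["a"])
        r = pd.Series([1], index=["b"])
        with pytest.raises(ValueError):
            contingency(p, r)


class TestFisherExact:
    def test_balanced_table_is_one(self):
        assert fisher_exact(ContingencyTable(1, 1, 1, 1), "two_sided") == pytest.approx(1.0)

    def test_diagonal_table_two_sided(self):
        assert fisher_exact(ContingencyTable(5, 0, 0, 5), "two_sided") == pytest.approx(2 / 252)

    def test_all_zero_table_degenerate(self):
        assert fisher_exact(ContingencyTable(0, 0, 0, 0)) == 1.0

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact(ContingencyTable(-1, 0, 0, 1))

    @pytest.mark.parametrize("alternative", ["greater", "less", "two_sided"])
    def test_random_tables_match_enumeration_oracle(self, alternative):
        rnd = random.Random(17)
        for _ in range(300):
            a, b, c, d = (rnd.randrange(0, 16) for _ in range(4))
            if a + b + c + d == 0:
                continue
            assert fisher_exact(ContingencyTable(a, b, c, d), alternative) == pytest.approx(
                fisher_oracle(a, b, c, d, alternative), abs=1e-12)

    def test_exhaustive_small_tables_greater(self):
        for a, b, c, d in itertools.product(range(7), repeat=4):
            if a + b + c + d == 0:
                continue
            assert fisher_exact(ContingencyTable(a, b, c, d), "greater") == pytest.approx(
                fisher_oracle(a, b, c, d, "greater"), abs=1e-12)


class TestBhAdjust:
    def test_single_test_unchanged(self):
        assert bh_adjust([0.05]) == pytest.approx([0.05])

    def test_hand_executed_step_up(self):
        # p(i) * n / i with monotone enforcement: all become 0.04
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_never_decreases_and_caps_at_one(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(1e-6, 1.0, size=50)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])

    def test_matrix_adjustment_per_replicate_column(self):
        pmat = pd.DataFrame({"rep1": [0.01, 0.02], "rep2": [0.5, 1.0]}, index=["g1", "g2"])
        adj = adjust_matrix(pmat)
        assert adj.at["g1", "rep1"] == pytest.approx(0.02)
        assert adj.at["g2", "rep2"] == pytest.approx(1.0)
        assert (adj.to_numpy() >= pmat.to_numpy() - 1e-15).all()


def _random_binary(genes, cols, seed, p=0.5):
    rng = np.random.default_rng(seed)
    return pd.DataFrame((rng.random((len(genes), len(cols))) < p).astype(int),
                        index=genes, columns=cols)


class TestResamplePvalues:
    genes = [f"g{i}" for i in range(12)]
    pool = [f"d{i}" for i in range(15)]

    def test_full_pool_subset_gives_identical_columns(self):
        P = _random_binary(self.genes, self.pool, 1)
        R = _random_binary(self.genes, self.pool, 2)
        mat = resample_pvalues(P, R, self.pool, reps=5, subset_size=len(self.pool), seed=0)
        assert (mat.nunique(axis=1) == 1).all()

    def test_seed_determinism(self):
        P = _random_binary(self.genes, self.pool, 1)
        R = _random_binary(self.genes, self.pool, 2)
        m1 = resample_pvalues(P, R, self.pool, reps=20, subset_size=8, seed=11)
        m2 = resample_pvalues(P, R, self.pool, reps=20, subset_size=8, seed=11)
        m3 = resample_pvalues(P, R, self.pool, reps=20, subset_size=8, seed=12)
        pd.testing.assert_frame_equal(m1, m2)
        assert not m1.equals(m3)

    def test_oversized_subset_rejected(self):
        P = _random_binary(self.genes, self.pool, 1)
        with pytest.raises(ValueError, match="exceeds driver pool"):
            resample_pvalues(P, P, self.pool, reps=2, subset_size=99)

    def test_entries_in_unit_interval_and_reproduce_fisher(self):
        P = _random_binary(self.genes, self.pool, 3)
        R = _random_binary(self.genes, self.pool, 4)
        mat = resample_pvalues(P, R, self.pool, reps=10, subset_size=10, seed=5)
        assert ((mat.to_numpy() > 0) & (mat.to_numpy() <= 1)).all()

    def test_null_inputs_are_super_uniform(self):
        # independent random P and R rows: an exact discrete test must not
        # exceed its nominal level at any threshold
        genes = [f"g{i}" for i in range(200)]
        pool = [f"d{i}" for i in range(40)]
        P = _random_binary(genes, pool, 21)
        R = _random_binary(genes, pool, 22)
        mat = resample_pvalues(P, R, pool, reps=50, subset_size=10, seed=23)
        pooled = mat.to_numpy().ravel()
        for alpha in (0.01, 0.05, 0.10, 0.25):
            se = np.sqrt(alpha * (1 - alpha) / pooled.size)
            assert (pooled <= alpha).mean() <= alpha + 3 * se


class TestGeneScore:
    def test_extremes(self):
        assert gene_score([0.0] * 10)[0] == 0.0
        assert gene_score([1.0] * 10)[0] == 2.0

    def test_mixed_example(self):
        pvals = [0.01] * 500 + [0.10] * 500
        gs, freq, mean = gene_score(pvals)
        assert gs == pytest.approx(0.555)
        assert freq == pytest.approx(0.5)
        assert mean == pytest.approx(0.055)

    def test_divisor_is_vector_length(self):
        gs, freq, _ = gene_score([0.5, 0.5])
        assert freq == 1.0 and 0 <= gs <= 2

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            gene_score([])


class TestSelection:
    def _table(self, gs_map):
        rows = [(g, gs, gs / 2, gs / 2, False) for g, gs in gs_map.items()]
        return pd.DataFrame(
            rows, columns=["gene", "gs", "freq_gt_alpha", "mean_p", "known_driver"]
        ).set_index("gene")

    def test_threshold_and_order(self):
        scores = self._table({"g1": 0.3, "g2": 1.4, "g3": 0.9})
        ranked, novel = select_candidates(scores)
        assert ranked == ["g1", "g3"]

    def test_known_drivers_removed_from_novel(self):
        scores = self._table({"g1": 0.3, "g2": 1.4, "g3": 0.9})
        _, novel = select_candidates(scores, known_drivers={"g1"})
        assert novel == ["g3"]

    def test_matches_filter_and_sort_oracle(self):
        rnd = random.Random(30)
        gs_map = {f"g{i}": round(rnd.uniform(0, 2), 6) for i in range(100)}
        ranked, _ = select_candidates(self._table(gs_map))
        oracle = sorted((g for g, v in gs_map.items() if v <= 1.0), key=lambda g: (gs_map[g], g))
        assert ranked == oracle

    def test_candidate_table_ranks_are_permutation(self):
        rng = np.random.default_rng(7)
        pmat = pd.DataFrame(rng.uniform(0.001, 1, (30, 20)),
                            index=[f"g{i}" for i in range(30)],
                            columns=[f"rep{i}" for i in range(20)])
        table = candidate_table(pmat)
        assert sorted(table["rank"]) == list(range(1, 31))
        assert ((table["gs"] >= 0) & (table["gs"] <= 2)).all()
        assert table["gs"].is_monotonic_increasing


class TestRedBandCluster:
    def test_two_planted_groups(self):
        rng = np.random.default_rng(1)
        low = rng.uniform(0.001, 0.02, (5, 30))
        high = rng.uniform(0.8, 1.0, (8, 30))
        pmat = pd.DataFrame(np.vstack([low, high]),
                            index=[f"low{i}" for i in range(5)] + [f"high{i}" for i in range(8)])
        assert red_band_cluster(pmat, n_clusters=2) == {f"low{i}" for i in range(5)}

    def test_single_row_returns_itself(self):
        pmat = pd.DataFrame([[0.5, 0.6]], index=["only"])
        assert red_band_cluster(pmat, n_clusters=2) == {"only"}

    def test_three_planted_groups_recovered(self):
        rng = np.random.default_rng(2)
        blocks = [rng.uniform(lo, lo + 0.02, (4, 25)) for lo in (0.01, 0.45, 0.9)]
        names = [f"b{k}_{i}" for k in range(3) for i in range(4)]
        pmat = pd.DataFrame(np.vstack(blocks), index=names)
        band = red_band_cluster(pmat, n_clusters=3)
        assert band == {f"b0_{i}" for i in range(4)}

    def test_more_clusters_than_rows_rejected(self):
        pmat = pd.DataFrame(np.eye(3))
        with pytest.raises(ValueError):
            red_band_cluster(pmat, n_clusters=5)
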