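"""Translatability metrics, decile normalization, group statistics, clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist

from polystall import translatability as tl
from polystall.records import CdsRecord

from oracles import brute_ks_statistic


@pytest.fixture
def codon_table():
    """A tiny CSC table covering the codons the tests use."""
    return pd.Series({"GCT": 0.2, "GGT": -0.2, "TTT": 0.1, "CCA": 0.05})


class TestCsc:
    def test_perfectly_proportional_codon_has_r_one(self, rng):
        freqs = pd.DataFrame(
            {"AAA": rng.uniform(0, 1, 10), "CCC": rng.uniform(0, 1, 10)},
            index=[f"g{i}" for i in range(10)],
        )
        half_lives = pd.Series(3.0 * freqs["AAA"].to_numpy(), index=freqs.index)
        csc = tl.compute_csc(freqs, half_lives)
        assert csc["AAA"] == pytest.approx(1.0)

    def test_constant_frequency_flagged_undefined(self, rng, caplog):
        freqs = pd.DataFrame(
            {"AAA": np.full(5, 0.3), "CCC": rng.uniform(0, 1, 5)},
            index=[f"g{i}" for i in range(5)],
        )
        half_lives = pd.Series(rng.uniform(1, 10, 5), index=freqs.index)
        with caplog.at_level("WARNING"):
            csc = tl.compute_csc(freqs, half_lives)
        assert np.isnan(csc["AAA"]) and "AAA" in caplog.text

    def test_matches_direct_pearson_formula(self, rng):
        genes = [f"g{i}" for i in range(10)]
        freqs = pd.DataFrame(
            rng.uniform(0, 1, (10, 4)), index=genes,
            columns=["AAA", "CCC", "GGG", "TTT"],
        )
        half_lives = pd.Series(rng.uniform(1, 60, 10), index=genes)
        csc = tl.compute_csc(freqs, half_lives)
        for codon in freqs.columns:
            x, y = freqs[codon].to_numpy(), half_lives.to_numpy()
            r = np.corrcoef(x, y)[0, 1]
            assert csc[codon] == pytest.approx(r)

    def test_too_few_genes_rejected(self):
        freqs = pd.DataFrame({"AAA": [0.1, 0.2]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match=">= 3"):
            tl.compute_csc(freqs, pd.Series([1.0, 2.0], index=["g1", "g2"]))


class TestCscg:
    def test_single_codon_gene_equals_its_csc(self, codon_table):
        cds = CdsRecord("g", "GCT" * 20 + "TAA")
        assert tl.compute_cscg(cds, codon_table) == pytest.approx(0.2)

    def test_balanced_codons_cancel(self, codon_table):
        cds = CdsRecord("g", "GCT" * 10 + "GGT" * 10 + "TAA")
        assert tl.compute_cscg(cds, codon_table) == pytest.approx(0.0)

    def test_random_gene_matches_occurrence_weighted_mean(self, rng, codon_table):
        codons = list(rng.choice(list(codon_table.index), size=50))
        cds = CdsRecord("g", "".join(codons) + "TAA")
        expected = np.mean([codon_table[c] for c in codons])
        assert tl.compute_cscg(cds, codon_table) == pytest.approx(expected)

    def test_concatenation_is_occurrence_weighted_mean_of_parts(self, codon_table):
        part1, part2 = "GCT" * 10, "TTT" * 30
        v1 = tl.compute_cscg(CdsRecord("g", part1), codon_table)
        v2 = tl.compute_cscg(CdsRecord("g", part2), codon_table)
        whole = tl.compute_cscg(CdsRecord("g", part1 + part2), codon_table)
        assert whole == pytest.approx((10 * v1 + 30 * v2) / 40)

    def test_missing_codon_named_in_error(self, codon_table):
        with pytest.raises(KeyError, match="ATG"):
            tl.compute_cscg(CdsRecord("g", "ATGGCT"), codon_table)


class TestTe:
    def test_ratio_and_zero_handling(self, caplog):
        rpf = pd.Series({"g1": 100, "g2": 0, "g3": 7}, dtype=float)
        mrna = pd.Series({"g1": 50, "g2": 10, "g3": 0}, dtype=float)
        with caplog.at_level("WARNING"):
            te = tl.compute_te(rpf, mrna)
        assert te["g1"] == 2.0
        assert te["g2"] == 0.0
        assert np.isnan(te["g3"]) and "undefined" in caplog.text

    def test_equal_vectors_give_unit_te(self, rng):
        counts = pd.Series(rng.integers(1, 100, 20).astype(float))
        assert (tl.compute_te(counts, counts) == 1.0).all()

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            tl.compute_te(pd.Series([-1.0]), pd.Series([1.0]))


class TestDecileScore:
    def test_extremes_map_to_zero_and_one(self, rng):
        values = pd.Series(rng.uniform(0, 100, 200))
        scores = tl.normalized_decile_score(values)
        assert scores[values.idxmin()] == 0.0
        assert scores[values.idxmax()] == 1.0

    def test_eighty_equally_spaced_values(self):
        """Hand-executed procedure: octiles of 10, extremes split 5+5,
        group-internal min-max mapped into the fixed bands."""
        values = pd.Series(np.arange(80, dtype=float))
        scores = tl.normalized_decile_score(values)
        group_sizes = [5, 5] + [10] * 6 + [5, 5]
        lows = [0, 1 / 16] + [1 / 16 + i * 7 / 64 for i in range(1, 8)] + [15 / 16]
        highs = lows[1:] + [1.0]
        expected = np.empty(80)
        pos = 0
        for size, lo, hi in zip(group_sizes, lows, highs):
            member = np.arange(pos, pos + size, dtype=float)
            expected[pos : pos + size] = lo + (member - member.min()) / (
                member.max() - member.min()
            ) * (hi - lo)
            pos += size
        assert np.allclose(scores.to_numpy(), expected)

    def test_all_equal_values_score_identically(self):
        scores = tl.normalized_decile_score(pd.Series(np.full(40, 3.14)))
        assert scores.nunique() == 1

    def test_orientation_flag_inverts(self, rng):
        values = pd.Series(rng.uniform(0, 10, 100))
        hi = tl.normalized_decile_score(values, higher_is_better=True)
        lo = tl.normalized_decile_score(values, higher_is_better=False)
        assert lo[values.idxmin()] == 1.0 and hi[values.idxmin()] == 0.0

    def test_monotone_in_raw_value(self, rng):
        values = pd.Series(rng.normal(size=150))  # continuous: no ties
        scores = tl.normalized_decile_score(values)
        order = values.sort_values().index
        assert scores[order].is_monotonic_increasing

    def test_band_assignment_invariant_to_monotone_transform(self, rng):
        """Group membership is rank-based, so a strictly monotone transform
        leaves every gene in its band; only the within-band interpolation
        (which follows the raw values) can move, by less than one band."""
        values = pd.Series(rng.uniform(1, 5, 120))
        direct = tl.normalized_decile_score(values)
        transformed = tl.normalized_decile_score(np.exp(values))
        assert np.all(np.abs(direct.to_numpy() - transformed.to_numpy()) < 7 / 64)
        assert (direct.rank() == transformed.rank()).all()

    def test_nan_passthrough_and_minimum_n(self):
        with pytest.raises(ValueError, match=">= 10"):
            tl.normalized_decile_score(pd.Series([1.0, 2.0, np.nan] * 3))


class TestCompareGroups:
    def test_identical_samples_d_zero_p_one(self):
        values = pd.Series(
            np.tile(np.arange(10.0), 2),
            index=[f"a{i}" for i in range(10)] + [f"b{i}" for i in range(10)],
        )
        res = tl.compare_groups(values, {"grp": [f"a{i}" for i in range(10)]})
        assert res.loc["grp", "ks_D"] == 0.0
        assert res.loc["grp", "ks_p"] == pytest.approx(1.0)

    def test_disjoint_supports_d_one(self):
        values = pd.Series(
            np.concatenate([np.arange(10.0), np.arange(100.0, 110.0)]),
            index=[f"a{i}" for i in range(10)] + [f"b{i}" for i in range(10)],
        )
        res = tl.compare_groups(values, {"grp": [f"a{i}" for i in range(10)]})
        assert res.loc["grp", "ks_D"] == 1.0
        assert res.loc["grp", "significant"]

    def test_d_matches_brute_force_ecdf(self, rng):
        values = pd.Series(
            np.concatenate([rng.normal(0, 1, 10), rng.normal(1, 1, 10)]),
            index=[f"a{i}" for i in range(10)] + [f"b{i}" for i in range(10)],
        )
        res = tl.compare_groups(values, {"grp": [f"a{i}" for i in range(10)]})
        brute = brute_ks_statistic(
            values.iloc[:10].to_numpy(), values.iloc[10:].to_numpy()
        )
        assert res.loc["grp", "ks_D"] == pytest.approx(brute)

    def test_label_swap_leaves_d_unchanged(self, rng):
        values = pd.Series(
            rng.normal(size=30), index=[f"g{i}" for i in range(30)]
        )
        ga = [f"g{i}" for i in range(12)]
        gb = [f"g{i}" for i in range(12, 30)]
        d1 = tl.compare_groups(values, {"grp": ga}).loc["grp", "ks_D"]
        d2 = tl.compare_groups(values, {"grp": gb}).loc["grp", "ks_D"]
        assert d1 == pytest.approx(d2)

    def test_empty_group_rejected(self, rng):
        values = pd.Series(rng.normal(size=10), index=[f"g{i}" for i in range(10)])
        with pytest.raises(ValueError, match="empty"):
            tl.compare_groups(values, {"none": ["missing"]})


class TestClusterGenes:
    def test_identical_rows_merge_first_at_zero(self):
        scores = pd.DataFrame(
            [[0.1, 0.2], [0.1, 0.2], [0.9, 0.9]],
            index=["g1", "g2", "g3"],
        )
        _, Z, _ = tl.cluster_genes(scores)
        assert Z[0, 2] == 0.0
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_line_points_join_near_pair_first(self):
        scores = pd.DataFrame([[0.0], [1.0], [10.0]], index=["a", "b", "c"])
        order, Z, _ = tl.cluster_genes(scores)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}
        assert order.index("c") in (0, 2)

    def test_distances_match_direct_euclidean(self, rng):
        scores = pd.DataFrame(
            rng.uniform(0, 1, (20, 5)), index=[f"g{i}" for i in range(20)]
        )
        _, Z, mat = tl.cluster_genes(scores)
        direct = pdist(scores.to_numpy(), metric="euclidean")
        # single-gene merges in the linkage are drawn from this distance set
        singleton_merges = Z[(Z[:, 0] < 20) & (Z[:, 1] < 20), 2]
        assert all(
            np.isclose(direct, d).any() for d in singleton_merges
        )
        assert mat.equals(scores)

    def test_all_missing_rows_excluded(self, caplog):
        scores = pd.DataFrame(
            [[0.1, 0.2], [np.nan, np.nan], [0.5, np.nan], [0.8, 0.9]],
            index=["g1", "g2", "g3", "g4"],
        )
        with caplog.at_level("WARNING"):
            order, _, mat = tl.cluster_genes(scores)
        assert "g2" not in order and len(order) == 3
        assert not mat.isna().any().any()

    def test_deterministic_leaf_order(self, rng):
        scores = pd.DataFrame(
            rng.uniform(0, 1, (15, 4)), index=[f"g{i}" for i in range(15)]
        )
        assert tl.cluster_genes(scores)[0] == tl.cluster_genes(scores)[0]
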