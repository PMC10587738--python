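from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom, rankdata

import circadyn as cd
from circadyn.abundance_differential import (AbundanceMatrix, abundance,
                                             abundance_matrix, differential,
                                             gene_counts,
                                             junction_concordance,
                                             rank_sum_exact_p, rank_sum_p,
                                             unique_genes)
from circadyn.io_formats import AnnotationSet

from conftest import SEED, make_catalog


def _gene_annot():
    rows = [("c", 0, 1000, "gene", "gene", "gA"),
            ("c", 2000, 2500, "gene", "gene", "gB")]
    return AnnotationSet(df=pd.DataFrame(
        rows, columns=["chrom", "start", "end", "track", "label", "parent"]))


class TestGeneCounts:
    def test_counts_by_start(self):
        annot = _gene_annot()
        starts = list(np.linspace(0, 900, 10).astype(int)) \
            + list(np.linspace(2000, 2400, 5).astype(int))
        cat = make_catalog("c", starts, [s + 50 for s in starts])
        counts = gene_counts(cat, annot)
        assert counts.to_dict() == {"gA": 10, "gB": 5}

    def test_duplicates_collapse_to_types(self):
        annot = _gene_annot()
        cat = make_catalog("c", [10, 10, 20], [60, 60, 70])
        assert gene_counts(cat, annot).to_dict() == {"gA": 2}

    def test_end_junction_coordinate(self):
        annot = _gene_annot()
        # starts outside gA, end-junction base (end-1) inside gA
        cat = make_catalog("c", [1500, 1500], [2400, 2600])
        assert gene_counts(cat, annot, junction="end").to_dict() == {"gB": 1}
        assert gene_counts(cat, annot, junction="start").to_dict() == {}


class TestAbundance:
    def test_equal_rates_split_the_million(self):
        col = abundance(pd.Series({"a": 10, "b": 5}),
                        pd.Series({"a": 1000, "b": 500}))
        assert col["a"] == pytest.approx(500_000)
        assert col["b"] == pytest.approx(500_000)

    def test_single_gene_takes_all(self):
        col = abundance(pd.Series({"a": 7}), pd.Series({"a": 123}))
        assert col["a"] == pytest.approx(1_000_000)

    def test_count_scale_invariance(self):
        counts = pd.Series({"a": 3, "b": 9, "c": 1})
        lengths = pd.Series({"a": 100, "b": 300, "c": 700})
        pd.testing.assert_series_equal(abundance(counts, lengths),
                                       abundance(counts * 3, lengths))

    def test_all_zero_warns(self):
        with pytest.warns(UserWarning):
            col = abundance(pd.Series({"a": 0}), pd.Series({"a": 100}))
        assert (col == 0).all()

    def test_columns_conserve_one_million(self, small_cohort):
        mat = abundance_matrix(small_cohort.catalogs, small_cohort.annot)
        sums = mat.values.sum(axis=0)
        assert np.allclose(sums, 1e6, rtol=1e-6)


def brute_force_rank_sum_p(x, y):
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1, n = len(x), len(pooled)
    center = n1 * (n + 1) / 2
    d_obs = abs(ranks[:n1].sum() - center)
    hits = 0
    labelings = list(combinations(range(n), n1))
    for idx in labelings:
        if abs(ranks[list(idx)].sum() - center) >= d_obs - 1e-9:
            hits += 1
    return hits / len(labelings)


class TestRankSum:
    def test_small_case_equals_one_third(self):
        assert rank_sum_p([1, 2], [3, 4]) == pytest.approx(1 / 3)

    def test_identical_groups_p_one(self):
        assert rank_sum_p([5.0, 5.0, 5.0], [5.0, 5.0]) == 1.0
        assert rank_sum_p([1, 2], [1, 2]) == 1.0

    @pytest.mark.parametrize("n1,n2", [(2, 2), (3, 3), (4, 4), (5, 5),
                                       (2, 5), (3, 5)])
    def test_matches_exhaustive_permutation_oracle(self, n1, n2):
        rng = np.random.default_rng(SEED + n1 * 10 + n2)
        for _ in range(20):
            x = rng.integers(0, 6, n1).astype(float)  # ties likely
            y = rng.integers(0, 6, n2).astype(float)
            if np.ptp(np.concatenate([x, y])) == 0:
                continue
            assert rank_sum_exact_p(x, y) == pytest.approx(
                brute_force_rank_sum_p(x, y), abs=1e-12)

    def test_large_n_uses_asymptotic_and_matches_scipy(self):
        rng = np.random.default_rng(SEED)
        x, y = rng.normal(0, 1, 40), rng.normal(0.5, 1, 40)
        from scipy.stats import mannwhitneyu
        assert rank_sum_p(x, y) == pytest.approx(
            mannwhitneyu(x, y, alternative="two-sided",
                         method="asymptotic").pvalue)


def _matrix(genes, samples, values):
    vals = pd.DataFrame(values, index=genes, columns=samples, dtype=float)
    return AbundanceMatrix(values=vals, counts=(vals > 0).astype(int),
                           gene_lengths=pd.Series(1000, index=genes))


class TestDifferential:
    def test_separated_gene_is_significant(self):
        groups = {f"p{i}": "pre" for i in range(4)}
        groups.update({f"q{i}": "post" for i in range(4)})
        mat = _matrix(["g1"], list(groups),
                      [[0, 0, 0, 0, 100, 110, 120, 130]])
        tab = differential(mat, groups)
        assert bool(tab["significant"].iloc[0])
        assert tab["log2FC"].iloc[0] > 1

    def test_identical_groups_p_exactly_one(self):
        groups = {"a": "pre", "b": "pre", "c": "post", "d": "post"}
        mat = _matrix(["g1"], ["a", "b", "c", "d"], [[7, 7, 7, 7]])
        tab = differential(mat, groups)
        assert tab["p"].iloc[0] == 1.0
        assert bool(tab["constant"].iloc[0])

    def test_label_swap_flips_log2fc_and_keeps_p(self):
        rng = np.random.default_rng(SEED)
        samples = [f"s{i}" for i in range(8)]
        groups = {s: ("pre" if i < 4 else "post")
                  for i, s in enumerate(samples)}
        swapped = {s: ("post" if g == "pre" else "pre")
                   for s, g in groups.items()}
        mat = _matrix(["g1", "g2", "g3"], samples, rng.uniform(0, 100, (3, 8)))
        t1 = differential(mat, groups)
        t2 = differential(mat, swapped)
        assert np.allclose(t1["log2FC"], -t2["log2FC"])
        assert np.allclose(t1["p"], t2["p"])

    def test_needs_two_samples_per_group(self):
        mat = _matrix(["g1"], ["a", "b", "c"], [[1, 2, 3]])
        with pytest.raises(ValueError):
            differential(mat, {"a": "pre", "b": "post", "c": "post"})


def fisher_two_sided_oracle(k_pre, n_pre, k_post, n_post):
    """Hypergeometric summation: sum of P(X=k) over tables with
    probability <= the observed table's."""
    K = k_pre + k_post
    N = n_pre + n_post
    rv = hypergeom(N, K, n_pre)
    p_obs = rv.pmf(k_pre)
    ks = np.arange(max(0, K - n_post), min(K, n_pre) + 1)
    return float(rv.pmf(ks)[rv.pmf(ks) <= p_obs * (1 + 1e-9)].sum())


class TestUniqueGenes:
    def _presence(self, n_pre_hits, n_post_hits, n=35):
        cols = [f"p{i}" for i in range(n)] + [f"q{i}" for i in range(n)]
        groups = {c: ("pre" if c.startswith("p") else "post") for c in cols}
        row = [i < n_pre_hits for i in range(n)] \
            + [i < n_post_hits for i in range(n)]
        return pd.DataFrame([row], index=["g1"], columns=cols), groups

    def test_six_vs_zero_matches_hypergeometric_oracle(self):
        presence, groups = self._presence(6, 0)
        tab = unique_genes(presence, groups)
        oracle = fisher_two_sided_oracle(6, 35, 0, 35)
        assert tab["fisher_p"].iloc[0] == pytest.approx(oracle, abs=1e-12)
        assert tab["unique_to"].iloc[0] == "pre"

    def test_everywhere_present_is_not_unique(self):
        presence, groups = self._presence(35, 35)
        tab = unique_genes(presence, groups)
        assert tab["fisher_p"].iloc[0] == 1.0
        assert tab["unique_to"].iloc[0] == "none"

    def test_below_min_support_not_unique(self):
        presence, groups = self._presence(1, 0)
        tab = unique_genes(presence, groups, min_samples=3)
        assert tab["unique_to"].iloc[0] == "none"

    @pytest.mark.parametrize("k_pre,k_post", [(4, 0), (10, 2), (0, 7)])
    def test_fisher_matches_oracle_generally(self, k_pre, k_post):
        presence, groups = self._presence(k_pre, k_post)
        tab = unique_genes(presence, groups)
        assert tab["fisher_p"].iloc[0] == pytest.approx(
            fisher_two_sided_oracle(k_pre, 35, k_post, 35), abs=1e-12)


class TestJunctionConcordance:
    def test_identical_vectors(self):
        s = pd.Series({"a": 1, "b": 5, "c": 9})
        r, _ = junction_concordance(s, s)
        assert r == pytest.approx(1.0)

    def test_reversed_vectors(self):
        r, _ = junction_concordance(pd.Series({"a": 1, "b": 2, "c": 3}),
                                    pd.Series({"a": 3, "b": 2, "c": 1}))
        assert r == pytest.approx(-1.0)

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError):
            junction_concordance(pd.Series({"a": 1, "b": 1}),
                                 pd.Series({"a": 1, "b": 2}))

    def test_short_in_gene_records_concord(self, small_cohort):
        sim = small_cohort
        sid = next(iter(sim.catalogs))
        by_start = gene_counts(sim.catalogs[sid], sim.annot, "start")
        by_end = gene_counts(sim.catalogs[sid], sim.annot, "end")
        r, _ = junction_concordance(by_start, by_end)
        assert r >= 0.95
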