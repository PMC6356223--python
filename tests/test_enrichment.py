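from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_h
from scipy import stats as sps

from cnvdrive.enrichment import (
    EnrichmentError,
    chi2_association,
    fisher_exact_2x2,
    gene_subgroup_enrichment,
    pathway_subgroup_enrichment,
    select_candidate_drivers,
)
from cnvdrive.expression import AlterationMatrix
from cnvdrive.io import PathwayCatalog
from cnvdrive.pathways import PathwayAlterationMatrix


def fisher_oracle(a, b, c, d):
    """Exact-rational two-sided Fisher p by hypergeometric enumeration."""
    n, row1, col1 = a + b + c + d, a + b, a + c
    denom = comb(n, col1)
    def pmf(k):
        return Fraction(comb(row1, k) * comb(n - row1, col1 - k), denom)
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    p_obs = pmf(a)
    return float(sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs))


class TestFisher:
    def test_three_three_diagonal(self):
        # margins (3,3,3,3): tail tables each carry 1/20
        p, oddsr = fisher_exact_2x2(3, 0, 0, 3)
        assert p == pytest.approx(0.1, abs=1e-12)
        assert np.isinf(oddsr)

    def test_balanced_table_is_null(self):
        p, oddsr = fisher_exact_2x2(5, 5, 5, 5)
        assert p == pytest.approx(1.0)
        assert oddsr == pytest.approx(1.0)

    def test_agrees_with_scipy_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 25, size=4)
            if a + b + c + d == 0:
                continue
            p, _ = fisher_exact_2x2(a, b, c, d)
            p_ref = sps.fisher_exact([[a, b], [c, d]])[1]
            assert p == pytest.approx(p_ref, rel=1e-9, abs=1e-12)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st_h.tuples(*[st_h.integers(0, 15)] * 4))
    def test_transpose_invariance(self, table):
        a, b, c, d = table
        if a + b + c + d == 0:
            return
        p1, _ = fisher_exact_2x2(a, b, c, d)
        p2, _ = fisher_exact_2x2(a, c, b, d)  # swap rows with columns
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_two_sided_p_decreases_away_from_expectation(self):
        """For fixed margins the p-value shrinks as a moves away from E[a]
        within either tail."""
        row1, col1, n = 10, 8, 24
        e_a = row1 * col1 / n
        lo, hi = max(0, row1 + col1 - n), min(row1, col1)

        def p_at(a):
            return fisher_exact_2x2(a, row1 - a, col1 - a, n - row1 - col1 + a)[0]

        upper = [p_at(a) for a in range(int(np.ceil(e_a)), hi + 1)]
        lower = [p_at(a) for a in range(int(np.floor(e_a)), lo - 1, -1)]
        assert all(np.diff(upper) <= 1e-12)
        assert all(np.diff(lower) <= 1e-12)
        assert min(upper + lower) > 0

    def test_all_zero_table_rejected(self):
        with pytest.raises(EnrichmentError):
            fisher_exact_2x2(0, 0, 0, 0)


class TestChi2:
    def test_balanced_table(self):
        stat, p = chi2_association(10, 10, 10, 10)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        a, b, c, d = 20, 12, 25, 49
        n = a + b + c + d
        expected = np.outer([a + b, c + d], [a + c, b + d]) / n
        observed = np.array([[a, b], [c, d]])
        stat_hand = ((observed - expected) ** 2 / expected).sum()
        stat, p = chi2_association(a, b, c, d, yates=False)
        assert stat == pytest.approx(stat_hand)
        assert 0 < p < 1

    def test_row_and_column_swap_invariance(self):
        s1, _ = chi2_association(7, 2, 3, 11)
        s2, _ = chi2_association(11, 3, 2, 7)  # both rows and columns swapped
        assert s1 == pytest.approx(s2)

    def test_zero_margin_rejected(self):
        with pytest.raises(EnrichmentError):
            chi2_association(0, 0, 5, 5)


def _alt(codes, genes, samples):
    return AlterationMatrix(
        codes=pd.DataFrame(
            np.asarray(codes, dtype=np.int8),
            index=pd.Index(genes, name="gene_id"), columns=samples,
        )
    )


class TestGeneEnrichment:
    def test_counts_match_hand_built_table(self):
        samples = [f"s{i}" for i in range(8)]
        subgroup = pd.Series([True] * 4 + [False] * 4, index=samples)
        codes = [
            [-1, -1, -1, 0, -1, 0, 0, 0],  # 3/4 vs 1/4 altered
            [0, 0, 0, 0, 0, 0, 0, 0],
        ]
        res = gene_subgroup_enrichment(_alt(codes, ["g1", "g2"], samples), subgroup)
        assert (res.loc["g1", ["a", "b", "c", "d"]] == [3, 1, 1, 3]).all()
        assert res.loc["g1", "direction"] == "enriched_in_subgroup"
        p_ref = fisher_oracle(3, 1, 1, 3)
        assert res.loc["g1", "p_fisher"] == pytest.approx(p_ref)
        assert res.loc["g2", "p_fisher"] == 1.0
        assert res.loc["g2", "direction"] == "neutral"

    def test_not_evaluable_samples_are_excluded(self):
        samples = ["s1", "s2", "s3", "s4"]
        subgroup = pd.Series([True, True, False, False], index=samples)
        codes = [[-1, 2, 0, 2]]  # s2, s4 not evaluable
        res = gene_subgroup_enrichment(_alt(codes, ["g1"], samples), subgroup)
        assert (res.loc["g1", ["a", "b", "c", "d"]] == [1, 0, 0, 1]).all()

    def test_bh_adjustment_is_monotone_and_conservative(self):
        rng = np.random.default_rng(5)
        samples = [f"s{i}" for i in range(40)]
        subgroup = pd.Series([True] * 15 + [False] * 25, index=samples)
        codes = rng.choice([-1, 0], size=(30, 40), p=[0.3, 0.7])
        res = gene_subgroup_enrichment(
            _alt(codes, [f"g{i}" for i in range(30)], samples), subgroup
        )
        assert (res["p_adjusted"] >= res["p_fisher"] - 1e-12).all()
        # sorted by raw p → adjusted p is non-decreasing down the list
        assert (np.diff(res["p_adjusted"].to_numpy()) >= -1e-12).all()

    def test_degenerate_subgroup_rejected(self):
        samples = ["s1", "s2"]
        alt = _alt([[0, 0]], ["g1"], samples)
        with pytest.raises(EnrichmentError):
            gene_subgroup_enrichment(alt, pd.Series([True, True], index=samples))


class TestDriverSelection:
    def _results(self):
        gene_results = pd.DataFrame(
            {
                "p_fisher": [0.01, 0.4, 0.02],
                "p_adjusted": [0.03, 0.6, 0.04],
                "direction": ["enriched_in_subgroup"] * 3,
                "odds_ratio": [4.0, 1.2, 3.0],
                "a": [5, 2, 4], "b": [1, 2, 1], "c": [2, 5, 3], "d": [6, 5, 6],
                "alteration_type": ["loss", "loss", "gain"],
            },
            index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
        )
        pathway_results = pd.DataFrame(
            {
                "p_fisher": [0.02, 0.8],
                "p_adjusted": [0.04, 0.8],
                "direction": ["enriched_in_subgroup", "neutral"],
            },
            index=pd.Index(["pA", "pB"], name="pathway_id"),
        )
        catalog = PathwayCatalog(
            gene_sets={"pA": frozenset({"g1"}), "pB": frozenset({"g2", "g3"})}
        )
        return gene_results, pathway_results, catalog

    def test_both_conditions_required(self):
        gene_results, pathway_results, catalog = self._results()
        out = select_candidate_drivers(gene_results, pathway_results, catalog)
        # g1: gene passes + pathway pA passes → candidate
        # g2: gene fails → excluded;  g3: passes but only in failing pB → excluded
        assert list(out.index) == ["g1"]
        assert out.loc["g1", "supporting_pathways"] == "pA"

    def test_always_pass_pathways_admit_universal_members(self):
        gene_results, pathway_results, catalog = self._results()
        out = select_candidate_drivers(
            gene_results, pathway_results, catalog,
            always_pass_pathways={"pB"},
        )
        assert list(out.index) == ["g1", "g3"]

    def test_adjusted_p_selection(self):
        gene_results, pathway_results, catalog = self._results()
        # at alpha=0.035 the raw p admits g1 (gene 0.01, pA 0.02) but the
        # adjusted p rejects pA (0.04) and hence leaves no candidates
        raw = select_candidate_drivers(
            gene_results, pathway_results, catalog, alpha=0.035
        )
        adj = select_candidate_drivers(
            gene_results, pathway_results, catalog, alpha=0.035, use_adjusted=True
        )
        assert list(raw.index) == ["g1"]
        assert len(adj) == 0


def test_null_calibration_matches_exact_test_size():
    """Under label permutation the rejection rate agrees with the exact
    attained size of the two-sided test given each gene's margins (Fisher is
    discrete, so the attained size sits below the nominal level)."""
    rng = np.random.default_rng(17)
    n, n_sub = 120, 40
    genes = [f"g{i:03d}" for i in range(400)]
    samples = [f"s{i}" for i in range(n)]
    codes = np.where(rng.random((400, n)) < 0.24, -1, 0)
    subgroup = pd.Series([True] * n_sub + [False] * (n - n_sub), index=samples)
    res = gene_subgroup_enrichment(_alt(codes, genes, samples), subgroup)
    observed = float((res["p_fisher"] < 0.05).mean())

    sizes = []
    for g in genes:
        k = int(res.loc[g, ["a", "b"]].sum())
        lo, hi = max(0, n_sub + k - n), min(n_sub, k)
        size = 0.0
        for a in range(lo, hi + 1):
            p, _ = fisher_exact_2x2(a, k - a, n_sub - a, n - n_sub - k + a)
            if p < 0.05:
                size += sps.hypergeom.pmf(a, n, k, n_sub)
        sizes.append(size)
    expected = float(np.mean(sizes))
    se = np.sqrt(expected * (1 - expected) / len(genes))
    assert observed == pytest.approx(expected, abs=4 * se + 1e-9)
    assert expected < 0.05  # discreteness ⇒ conservative
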