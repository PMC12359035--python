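"""Normalization, fold-change classification and stratified rank tests."""

import numpy as np
import pandas as pd
import pytest

from smsite.annotation_io import Region
from smsite.enrichment_stats import (
    CountMatrix,
    LfcTable,
    bh_adjust,
    candidate_intersection,
    classify_enrichment,
    kendall_tau,
    simple_lfc,
    site_density,
    size_factors,
    stratified_cdf_test,
)
from smsite.reference import exact_rank_sum_pvalue
from smsite.smsite_scan import GeneSiteSummary


def _matrix(data, conditions):
    df = pd.DataFrame(data)
    df.index = [f"g{i}" for i in range(len(df))]
    return CountMatrix(df, conditions)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        m = _matrix({"s1": [10, 20, 30], "s2": [10, 20, 30]}, {"s1": "A", "s2": "B"})
        assert np.allclose(size_factors(m), 1.0)

    def test_doubled_column_has_double_factor(self):
        col = [5, 17, 40, 8, 100]
        m = _matrix(
            {"s1": col, "s2": [2 * c for c in col]}, {"s1": "A", "s2": "B"}
        )
        sf = size_factors(m)
        assert sf["s2"] / sf["s1"] == pytest.approx(2.0)
        # geometric-mean centering: factors multiply to ~1 for a 2x shift
        assert np.prod(sf) == pytest.approx(1.0, rel=1e-6)

    def test_all_zero_column_rejected(self):
        m = _matrix({"s1": [10, 20], "s2": [0, 0]}, {"s1": "A", "s2": "B"})
        with pytest.raises(ValueError, match="pseudocount"):
            size_factors(m)


class TestSimpleLfc:
    def test_equal_means_give_zero(self):
        m = _matrix(
            {"a1": [10, 50], "a2": [10, 50], "b1": [10, 50], "b2": [10, 50]},
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
        )
        lfc = simple_lfc(m, ("A", "B"), pseudocount=0)
        assert np.allclose(lfc.table["lfc"], 0.0)

    def test_fourfold_ratio_gives_lfc_two(self):
        # background genes keep the size factors at 1
        bg = [100, 200, 300]
        m = _matrix(
            {"a1": bg + [8], "a2": bg + [8], "b1": bg + [2], "b2": bg + [2]},
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
        )
        lfc = simple_lfc(m, ("A", "B"), pseudocount=0)
        assert lfc.table["lfc"].iloc[-1] == pytest.approx(2.0)

    def test_unknown_condition_rejected(self):
        m = _matrix({"s1": [1], "s2": [1]}, {"s1": "A", "s2": "B"})
        with pytest.raises(ValueError, match="C"):
            simple_lfc(m, ("C", "B"))

    def test_internal_lfc_carries_no_padj(self):
        m = _matrix({"s1": [5, 5], "s2": [5, 5]}, {"s1": "A", "s2": "B"})
        assert not simple_lfc(m, ("A", "B")).has_padj


class TestClassify:
    def _table(self, rows):
        df = pd.DataFrame(rows, columns=["lfc", "padj"])
        df.index = [f"g{i}" for i in range(len(df))]
        return LfcTable(df)

    def test_threshold_examples(self):
        t = self._table([(1.2, 0.01), (0.61, 0.06), (-0.7, 0.001), (0.3, 0.001)])
        cls = classify_enrichment(t)
        assert list(cls) == ["enriched", "neither", "depleted", "neither"]

    def test_partition_is_exhaustive_and_exclusive(self, rng):
        rows = list(zip(rng.normal(0, 1, 500), rng.uniform(0, 1, 500)))
        cls = classify_enrichment(self._table(rows))
        assert set(cls.unique()) <= {"enriched", "depleted", "neither"}
        assert cls.notna().all()

    def test_missing_padj_directs_to_import(self):
        t = LfcTable(pd.DataFrame({"lfc": [1.0]}, index=["g0"]))
        with pytest.raises(ValueError, match="external"):
            classify_enrichment(t)


def _lfc_with_strata(rng, n=200, shift=0.0):
    a = rng.normal(0, 1, n)
    b = rng.normal(0, 1, n) + shift
    table = pd.DataFrame(
        {"lfc": np.concatenate([a, b])},
        index=[f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)],
    )
    strata = {f"a{i}": "A" for i in range(n)} | {f"b{i}": "B" for i in range(n)}
    return LfcTable(table), strata


class TestStratifiedCdf:
    def test_shifted_stratum_detected(self, rng):
        t, strata = _lfc_with_strata(rng, shift=1.0)
        (res,) = stratified_cdf_test(t, strata, [("B", "A")], "greater")
        assert res.p < 1e-6
        assert res.padj == res.p  # single pair: BH is identity

    def test_small_samples_match_exact_permutation(self, rng):
        for _ in range(10):
            t, strata = _lfc_with_strata(rng, n=6)
            (res,) = stratified_cdf_test(t, strata, [("B", "A")], "greater")
            exact = exact_rank_sum_pvalue(
                t.table.loc[[f"b{i}" for i in range(6)], "lfc"],
                t.table.loc[[f"a{i}" for i in range(6)], "lfc"],
                "greater",
            )
            assert abs(res.p - exact) <= 0.02

    def test_null_p_values_are_not_inflated(self):
        rejections = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            t, strata = _lfc_with_strata(r, shift=0.0)
            (res,) = stratified_cdf_test(t, strata, [("B", "A")], "greater")
            rejections += res.p < 0.05
        assert rejections <= 4

    def test_empty_stratum_named_in_error(self, rng):
        t, strata = _lfc_with_strata(rng)
        with pytest.raises(ValueError, match="C"):
            stratified_cdf_test(t, strata, [("C", "A")], "greater")

    def test_ecdf_coordinates_cover_both_strata(self, rng):
        t, strata = _lfc_with_strata(rng, n=10)
        (res,) = stratified_cdf_test(t, strata, [("B", "A")], "greater")
        assert set(res.ecdf["stratum"]) == {"A", "B"}
        assert res.ecdf["ecdf"].max() == 1.0


class TestBh:
    def test_monotone_and_at_least_raw(self, rng):
        for _ in range(50):
            p = rng.uniform(0, 1, int(rng.integers(1, 40)))
            q = bh_adjust(p)
            assert (q >= p - 1e-12).all()
            order = np.argsort(p)
            assert (np.diff(q[order]) >= -1e-12).all()

    def test_permutation_invariant_per_hypothesis(self, rng):
        p = rng.uniform(0, 1, 20)
        q = bh_adjust(p)
        perm = rng.permutation(20)
        assert np.allclose(bh_adjust(p[perm]), q[perm])


class TestKendall:
    def test_perfectly_concordant(self):
        tau, _ = kendall_tau([1, 2, 3, 4], [10, 20, 30, 40])
        assert tau == pytest.approx(1.0)

    def test_perfectly_discordant(self):
        tau, _ = kendall_tau([1, 2, 3, 4], [4, 3, 2, 1])
        assert tau == pytest.approx(-1.0)

    def test_tau_b_matches_pair_enumeration(self):
        x, y = [1, 2, 2, 3], [1, 2, 3, 3]
        conc = disc = tx = ty = 0
        for i in range(4):
            for j in range(i + 1, 4):
                dx, dy = x[j] - x[i], y[j] - y[i]
                if dx == 0 and dy == 0:
                    continue
                if dx == 0:
                    tx += 1
                elif dy == 0:
                    ty += 1
                elif dx * dy > 0:
                    conc += 1
                else:
                    disc += 1
        expected = (conc - disc) / np.sqrt(
            (conc + disc + tx) * (conc + disc + ty)
        )
        tau, _ = kendall_tau(x, y)
        assert tau == pytest.approx(expected)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            kendall_tau([1, 1, 1], [1, 2, 3])


def _summary(gene_id, canon_3utr=0, utr3=0, cds=0, canon_cds=0):
    s = GeneSiteSummary(gene_id=gene_id, transcript_id=gene_id + ".t")
    s.utr3_length = utr3
    s.cds_length = cds
    if canon_3utr:
        s.region_counts[("canonical", Region.THREE_UTR)] = canon_3utr
    if canon_cds:
        s.region_counts[("canonical", Region.CDS)] = canon_cds
    return s


class TestSiteDensity:
    def test_three_sites_per_ten_kb(self):
        d = site_density(
            [_summary("g1", canon_3utr=3, utr3=10_000)],
            regions=[Region.THREE_UTR],
        )
        assert d.table.loc["3UTR", "per_mb"] == pytest.approx(300.0)

    def test_zero_sites(self):
        d = site_density(
            [_summary("g1", utr3=5_000)], regions=[Region.THREE_UTR]
        )
        assert d.table.loc["3UTR", "per_mb"] == 0.0

    def test_length_ratio_scales_density(self):
        s = _summary("g1", canon_3utr=2, utr3=1_000, cds=3_000, canon_cds=2)
        d = site_density([s], regions=[Region.CDS, Region.THREE_UTR])
        assert d.table.loc["3UTR", "per_mb"] == pytest.approx(
            3 * d.table.loc["CDS", "per_mb"]
        )

    def test_invariant_to_splitting_a_gene(self):
        whole = [_summary("g1", canon_3utr=4, utr3=8_000)]
        split = [
            _summary("g1a", canon_3utr=1, utr3=3_000),
            _summary("g1b", canon_3utr=3, utr3=5_000),
        ]
        d1 = site_density(whole, regions=[Region.THREE_UTR])
        d2 = site_density(split, regions=[Region.THREE_UTR])
        assert d1.table.loc["3UTR", "per_mb"] == pytest.approx(
            d2.table.loc["3UTR", "per_mb"]
        )

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError, match="length"):
            site_density([_summary("g1")], regions=[Region.THREE_UTR])


class TestCandidateIntersection:
    def _tables(self):
        def tab(rows):
            df = pd.DataFrame(rows, columns=["lfc", "padj"])
            df.index = ["g1", "g2", "g3"]
            return LfcTable(df)

        return {
            "atp": tab([(1.5, 0.01), (1.0, 0.01), (2.0, 0.01)]),
            "input": tab([(1.2, 0.01), (0.2, 0.5), (1.8, 0.01)]),
            "sm": tab([(0.9, 0.02), (1.1, 0.01), (1.4, 0.01)]),
        }

    def test_all_comparison_intersection(self):
        df = candidate_intersection(self._tables())
        assert list(df["gene_id"]) == ["g3", "g1"]  # ordered by min lfc

    def test_partial_enrichment_dropped(self):
        df = candidate_intersection(self._tables())
        assert "g2" not in set(df["gene_id"])

    def test_ambiguous_genes_excluded(self):
        df = candidate_intersection(self._tables(), ambiguous={"g3"})
        assert list(df["gene_id"]) == ["g1"]
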