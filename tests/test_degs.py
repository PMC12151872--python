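"""DEG calling, BH, chi-square, abundance bins, Venn, Fisher enrichment."""

import math

import numpy as np
import pytest
from scipy import stats

from longescreen import (
    AbundanceBinning,
    DEGSet,
    GeneExpressionRecord,
    PromoterAnnotation,
    assign_abundance_bins,
    bh_adjust,
    call_degs,
    chi_square_2x2,
    fisher_enrichment,
    promoter_state_enrichment,
    shared_degs,
    two_group_gene_test,
    updown_ratio_by_bin,
)


class TestTwoGroupGeneTest:
    def test_identical_groups_are_null(self):
        r = two_group_gene_test(GeneExpressionRecord("g", [5, 7, 6], [5, 7, 6]))
        assert r.log2fc == 0.0
        assert r.p_value == pytest.approx(1.0)

    def test_fourfold_change_on_transform(self):
        ctrl = np.array([10, 10, 10, 10]) + np.array([0, 1e-9, -1e-9, 2e-9])
        trt = np.array([40, 40, 40, 40]) + np.array([0, 1e-9, -1e-9, 2e-9])
        r = two_group_gene_test(GeneExpressionRecord("g", ctrl, trt))
        assert r.log2fc == pytest.approx(np.log2(41 / 11), abs=1e-6)

    def test_matches_welch_formula_oracle(self, rng):
        for _ in range(25):
            c = rng.lognormal(2, 1, size=rng.integers(3, 8))
            t = rng.lognormal(2.5, 1, size=rng.integers(3, 8))
            r = two_group_gene_test(GeneExpressionRecord("g", c, t))
            lc, lt = np.log2(c + 1), np.log2(t + 1)
            v1, v2 = lt.var(ddof=1) / lt.size, lc.var(ddof=1) / lc.size
            tstat = (lt.mean() - lc.mean()) / np.sqrt(v1 + v2)
            df = (v1 + v2) ** 2 / (v1**2 / (lt.size - 1) + v2**2 / (lc.size - 1))
            assert r.p_value == pytest.approx(2 * stats.t.sf(abs(tstat), df), abs=1e-10)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="2 replicates"):
            two_group_gene_test(GeneExpressionRecord("g", [5.0], [7.0, 8.0]))

    def test_negative_fpkm_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            GeneExpressionRecord("g", [-1.0, 2.0], [1.0, 2.0])


class TestBHAdjust:
    def test_equal_ratio_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]).tolist() == pytest.approx([0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_matches_direct_definition(self, rng):
        p = rng.random(50)
        order = np.argsort(p)
        m = 50
        q_sorted = p[order] * m / np.arange(1, m + 1)
        q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(q_sorted, 1.0)
        assert bh_adjust(p) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_q_dominates_p_and_capped(self, rng):
        p = rng.random(200)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all() and (q <= 1.0).all()


class TestCallDegs:
    def _rec(self, gene, lfc, q):
        return GeneExpressionRecord(gene, log2fc=lfc, p_value=q, q_value=q)

    def test_threshold_application(self):
        ds = call_degs(
            [self._rec("a", 1.5, 0.01), self._rec("b", 0.5, 0.001), self._rec("c", -2.0, 0.2)]
        )
        assert ds.up == {"a"} and ds.down == set()

    def test_empty_input(self):
        ds = call_degs([])
        assert ds.up == set() and ds.down == set()

    def test_order_invariance_and_disjointness(self, rng):
        records = [
            self._rec(f"g{i}", float(l), float(q))
            for i, (l, q) in enumerate(zip(rng.normal(0, 2, 100), rng.random(100)))
        ]
        a = call_degs(list(records))
        shuffled = list(records)
        rng.shuffle(shuffled)
        b = call_degs(shuffled)
        assert a.up == b.up and a.down == b.down
        assert not (a.up & a.down)

    def test_planted_deg_recovery(self):
        """Recall >= 0.9 and empirical FDR <= 0.1 on a planted experiment."""
        from longescreen import simulate_expression_experiment

        records, _, _, truth = simulate_expression_experiment(n_deg=100, seed=31)
        ds = call_degs(records, tissue="syn")
        called = ds.up | ds.down
        planted = set(truth.planted_lfc)
        recall = len(called & planted) / len(planted)
        fdr = len(called - planted) / max(len(called), 1)
        assert recall >= 0.9
        assert fdr <= 0.1
        # directions must match the planted signs
        for g in called & planted:
            assert (g in ds.up) == (truth.planted_lfc[g] > 0)


class TestChiSquare2x2:
    def test_balanced_table_is_null(self):
        stat, p = chi_square_2x2(10, 10, 10, 10)
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_closed_form_value(self):
        stat, _ = chi_square_2x2(20, 10, 10, 20)
        assert stat == pytest.approx(60 * (400 - 100) ** 2 / 30**4)

    def test_random_tables_match_closed_form(self, rng):
        for _ in range(200):
            a, b, c, d = rng.integers(1, 60, size=4)
            stat, p = chi_square_2x2(a, b, c, d)
            n = a + b + c + d
            expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
            assert stat == pytest.approx(expected, abs=1e-10)
            assert p == pytest.approx(stats.chi2.sf(expected, 1), abs=1e-10)
            # transposition invariance
            assert chi_square_2x2(a, c, b, d)[0] == pytest.approx(stat, abs=1e-10)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_2x2(0, 0, 5, 7)


class TestPromoterStateEnrichment:
    @staticmethod
    def annotation(genes, states):
        return [PromoterAnnotation(g, s) for g, s in zip(genes, states)]

    def test_equal_proportions_give_zero_chi2(self):
        up = {f"u{i}" for i in range(20)}
        down = {f"d{i}" for i in range(20)}
        ann = {g: ("active" if int(g[1:]) < 10 else "inactive") for g in up | down}
        res = promoter_state_enrichment(DEGSet("t", up, down), ann)
        assert res.prop_active_up == res.prop_active_down == 0.5
        assert res.chi_square == pytest.approx(0.0)

    def test_contingency_matches_closed_form(self):
        up = [f"u{i}" for i in range(17)]
        down = [f"d{i}" for i in range(17)]
        ann = {g: ("active" if i < 12 else "inactive") for i, g in enumerate(up)}
        ann |= {g: ("active" if i < 3 else "inactive") for i, g in enumerate(down)}
        res = promoter_state_enrichment(DEGSet("t", set(up), set(down)), ann)
        a, b, c, d = 12, 5, 3, 14
        n = a + b + c + d
        assert res.chi_square == pytest.approx(
            n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        )
        assert res.counts.loc["up", "active"] == 12
        assert res.n_unannotated == 0

    def test_planted_active_fractions_recovered(self, rng):
        n = 150
        up = {f"u{i}" for i in range(n)}
        down = {f"d{i}" for i in range(n)}
        ann = {g: ("active" if rng.random() < 0.3 else "inactive") for g in up}
        ann |= {g: ("active" if rng.random() < 0.8 else "inactive") for g in down}
        res = promoter_state_enrichment(DEGSet("t", up, down), ann)
        for prop, target in ((res.prop_active_up, 0.3), (res.prop_active_down, 0.8)):
            assert abs(prop - target) < 1.96 * np.sqrt(target * (1 - target) / n) + 0.02
        assert res.p_value < 1e-3

    def test_zero_margin_returns_proportions_without_test(self):
        res = promoter_state_enrichment(
            DEGSet("t", {"u1"}, {"d1"}), {"u1": "active", "d1": "active"}
        )
        assert res.prop_active_up == 1.0 and res.prop_active_down == 1.0
        assert np.isnan(res.chi_square) and np.isnan(res.p_value)

    def test_unannotated_counted_separately(self):
        res = promoter_state_enrichment(
            DEGSet("t", {"a", "b"}, {"c"}), {"a": "active", "c": "inactive"}
        )
        assert res.n_unannotated == 1


class TestAbundanceBins:
    def test_strict_boundary_at_5000(self):
        binning = AbundanceBinning((10.0, 100.0, 5000.0))
        assert binning.assign(6000) == "extremely_high"
        assert binning.assign(5000) == "high"
        assert binning.assign(50) == "middle"
        assert binning.assign(10) == "low"

    def test_all_zero_totals_fall_in_low(self):
        binning = AbundanceBinning((10.0, 100.0, 5000.0))
        bins, _ = assign_abundance_bins({f"g{i}": 0.0 for i in range(5)}, binning)
        assert set(bins.values()) == {"low"}

    def test_non_monotone_edges_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            AbundanceBinning((100.0, 10.0, 5000.0))

    def test_default_edges_are_tertiles_of_body(self):
        totals = {f"g{i}": float(v) for i, v in enumerate([1, 2, 3, 4, 5, 6, 7000])}
        bins, binning = assign_abundance_bins(totals)
        assert binning.edges[2] == 5000.0
        assert bins["g6"] == "extremely_high"
        assert np.allclose(binning.edges[:2], np.quantile([1, 2, 3, 4, 5, 6], [1 / 3, 2 / 3]))


class TestUpdownRatio:
    def test_simple_ratio(self):
        bins = {f"u{i}": "high" for i in range(4)} | {f"d{i}": "high" for i in range(8)}
        table = updown_ratio_by_bin(
            DEGSet("t", {f"u{i}" for i in range(4)}, {f"d{i}" for i in range(8)}), bins
        ).set_index("bin")
        assert table.loc["high", "ratio"] == pytest.approx(0.5)

    def test_empty_bin_has_undefined_ratio(self):
        table = updown_ratio_by_bin(DEGSet("t", set(), set()), {}).set_index("bin")
        assert (table[["n_up", "n_down"]] == 0).all().all()
        assert table["ratio"].isna().all()

    def test_planted_abundance_down_bias_gives_decreasing_ratio(self):
        from longescreen import simulate_expression_experiment

        records, _, _, truth = simulate_expression_experiment(
            n_deg=300, abundance_down_bias=2.5, down_frac=0.5, seed=77
        )
        ds = call_degs(records)
        bins, _ = assign_abundance_bins(records)
        table = updown_ratio_by_bin(ds, bins).set_index("bin")
        populated = table[(table["n_up"] + table["n_down"]) >= 10]
        ratios = populated["ratio"].to_numpy()
        assert len(ratios) >= 2
        assert (np.diff(ratios) < 0).all()


class TestSharedDegs:
    @staticmethod
    def ds(tissue, down, up=()):
        return DEGSet(tissue, set(up), set(down))

    def test_three_way_intersection(self):
        table = shared_degs(
            [self.ds("k", {"a", "b", "c"}), self.ds("l", {"b", "c", "d"}), self.ds("m", {"c", "e"})]
        )
        row = table[(table["direction"] == "down") & (table["tissues"] == "k&l&m")]
        assert row["intersection"].item() == 1

    def test_identical_sets_share_everything(self):
        table = shared_degs([self.ds("a", {"x", "y"}), self.ds("b", {"x", "y"})])
        row = table[(table["direction"] == "down") & (table["n_tissues"] == 2)]
        assert row["intersection"].item() == 2

    def test_duplicate_tissue_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            shared_degs([self.ds("a", {"x"}), self.ds("a", {"y"})])

    def test_matches_brute_force_and_regions_sum_to_union(self, rng):
        universe = [f"g{i}" for i in range(40)]
        sets = {
            t: {g for g in universe if rng.random() < 0.3} for t in ("t1", "t2", "t3")
        }
        table = shared_degs([self.ds(t, s) for t, s in sets.items()])
        down = table[table["direction"] == "down"]
        union = set().union(*sets.values())
        assert down["exclusive"].sum() == len(union)
        for _, row in down.iterrows():
            inside = row["tissues"].split("&")
            brute = sum(
                1
                for g in universe
                if all(g in sets[t] for t in inside)
            )
            assert row["intersection"] == brute
            exact = sum(
                1
                for g in universe
                if all(g in sets[t] for t in inside)
                and not any(g in sets[t] for t in sets if t not in inside)
            )
            assert row["exclusive"] == exact


class TestFisherEnrichment:
    def test_term_identical_to_query_is_top(self):
        background = {f"g{i}" for i in range(100)}
        query = {f"g{i}" for i in range(10)}
        annotation = {g: ["match"] for g in query} | {f"g{i}": ["other"] for i in range(50, 70)}
        results = fisher_enrichment(query, annotation, background)
        assert results[0].term_id == "match"
        assert results[0].overlap == 10
        assert results[0].p_value < results[-1].p_value

    def test_disjoint_term_is_null(self):
        background = {f"g{i}" for i in range(50)}
        results = fisher_enrichment(
            {"g0", "g1"}, {f"g{i}": ["t"] for i in range(10, 20)}, background
        )
        assert results[0].odds_ratio == 0.0
        assert results[0].p_value == pytest.approx(1.0)

    def test_tail_sum_oracle(self):
        background = {f"g{i}" for i in range(400)}
        query = {f"g{i}" for i in range(20)}
        term = {f"g{i}" for i in range(12, 42)}  # overlap 8, size 30
        annotation = {g: ["T"] for g in term}
        res = fisher_enrichment(query, annotation, background)[0]
        assert (res.overlap, res.term_size) == (8, 30)
        N, K, n = 400, 30, 20
        tail = sum(
            math.comb(K, k) * math.comb(N - K, n - k) / math.comb(N, n)
            for k in range(8, min(K, n) + 1)
        )
        assert res.p_value == pytest.approx(tail, abs=1e-9)

    def test_random_tables_match_summation_oracle(self, rng):
        for _ in range(200):
            N = int(rng.integers(30, 120))
            n = int(rng.integers(5, N // 2))
            K = int(rng.integers(3, N // 2))
            genes = [f"g{i}" for i in range(N)]
            query = set(rng.choice(genes, size=n, replace=False))
            term = set(rng.choice(genes, size=K, replace=False))
            res = fisher_enrichment(query, {g: ["T"] for g in term}, set(genes))[0]
            k_obs = len(query & term)
            tail = sum(
                math.comb(K, k) * math.comb(N - K, n - k) / math.comb(N, n)
                for k in range(k_obs, min(K, n) + 1)
            )
            assert res.p_value == pytest.approx(tail, abs=1e-9)

    def test_query_outside_background_rejected(self):
        with pytest.raises(ValueError, match="outside background"):
            fisher_enrichment({"zz"}, {"a": ["t"]}, {"a", "b"})
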