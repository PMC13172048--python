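"""Bulk DET set algebra and single-cell ISG procedures."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ifnkit import (ValidationError, core_isg_set, det_filter,
                    eligible_cell_types, filter_robust_bulk, isg_score,
                    lineage_venn, mann_whitney_u, sc_log_normalise,
                    sc_wilcoxon_de, subtype_specific_sets, universal_sets)
from ifnkit.models import CORE_ISGS


def de_table(rows, contrast="ifnb"):
    return pd.DataFrame([
        {"transcript_id": tid, "log2fc": fc, "padj": padj,
         "contrast": contrast}
        for tid, fc, padj in rows])


class TestRobustBulk:
    COND = pd.Series({"s1": "mock", "s2": "mock", "s3": "ifnb", "s4": "ifnb"})

    def _counts(self, rows):
        return pd.DataFrame(rows, columns=["s1", "s2", "s3", "s4"])

    def test_one_condition_suffices(self):
        counts = self._counts([[25, 30, 0, 0]])
        assert filter_robust_bulk(counts, self.COND) == [0]

    def test_every_condition_has_a_low_sample(self):
        counts = self._counts([[19, 30, 19, 30]])
        assert filter_robust_bulk(counts, self.COND) == []

    def test_boundary_exactly_min_reads(self):
        counts = self._counts([[20, 20, 0, 0]])
        assert filter_robust_bulk(counts, self.COND) == [0]

    def test_unlabelled_sample_is_an_error(self):
        counts = self._counts([[1, 1, 1, 1]])
        with pytest.raises(ValidationError):
            filter_robust_bulk(counts, pd.Series({"s1": "mock"}))


class TestDetFilter:
    def test_boundaries_inclusive(self):
        up, down = det_filter(de_table([
            ("a", 0.585, 0.05),   # both boundaries: in
            ("b", -0.7, 0.01),    # down
            ("c", 3.0, 0.06),     # not significant
            ("d", 0.5, 0.01),     # below fold threshold
        ]))
        assert set(up.feature_ids) == {"a"}
        assert set(down.feature_ids) == {"b"}

    def test_missing_padj_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="missing padj"):
            up, _ = det_filter(de_table([("a", 2.0, np.nan), ("b", 2.0, 0.01)]))
        assert set(up.feature_ids) == {"b"}

    def test_up_down_disjoint(self):
        up, down = det_filter(de_table(
            [(f"t{i}", fc, 0.01) for i, fc in
             enumerate(np.linspace(-3, 3, 25))]))
        assert not (up.feature_ids & down.feature_ids)

    @given(st.floats(0.01, 0.2), st.floats(0.1, 1.5))
    @settings(max_examples=50, deadline=None)
    def test_relaxing_thresholds_never_shrinks(self, padj_max, min_fc):
        table = de_table([(f"t{i}", fc, p) for i, (fc, p) in enumerate(
            zip(np.linspace(-2, 2, 40), np.linspace(0.001, 0.3, 40)))])
        up1, _ = det_filter(table, padj_max=padj_max, min_abs_log2fc=min_fc)
        up2, _ = det_filter(table, padj_max=padj_max * 1.5,
                            min_abs_log2fc=min_fc * 0.5)
        assert up1.feature_ids <= up2.feature_ids


class TestSetAlgebra:
    def _sets(self, *memberships, direction="up"):
        from ifnkit.models import DetSet
        return [DetSet(contrast=f"t{i}", direction=direction,
                       feature_ids=frozenset(m), padj_max=0.05,
                       min_abs_log2fc=0.585)
                for i, m in enumerate(memberships)]

    def test_universal_intersection(self):
        assert universal_sets(self._sets({"A", "B"}, {"A", "C"})) == {"A"}

    def test_empty_member_empties_result(self):
        assert universal_sets(self._sets({"A"}, set())) == frozenset()

    def test_universal_subset_of_all_inputs(self):
        sets = self._sets({"A", "B", "C"}, {"B", "C", "D"}, {"C", "B"})
        uni = universal_sets(sets)
        assert all(uni <= s.feature_ids for s in sets)

    def test_subtype_specific(self):
        specific = subtype_specific_sets(self._sets({"A", "B"}, {"B", "C"}))
        assert specific == {"t0": {"A"}, "t1": {"C"}}

    def test_identical_sets_have_no_specific_members(self):
        specific = subtype_specific_sets(self._sets({"A", "B"}, {"A", "B"}))
        assert all(not v for v in specific.values())

    def test_specific_and_universal_disjoint(self):
        sets = self._sets({"A", "B"}, {"B", "C"}, {"B", "D"})
        uni = universal_sets(sets)
        for v in subtype_specific_sets(sets).values():
            assert not (v & uni)


class TestVenn:
    def test_published_scale_sizes(self):
        a = {f"g{i}" for i in range(229)}
        b = {f"g{i}" for i in range(229 - 111, 229 - 111 + 188)}
        only_a, both, only_b = lineage_venn(a, b)
        assert (len(only_a), len(both), len(only_b)) == (118, 111, 77)

    def test_disjoint_and_identical(self):
        assert lineage_venn({"a"}, {"b"})[1] == frozenset()
        only_a, both, only_b = lineage_venn({"a"}, {"a"})
        assert (only_a, both, only_b) == (frozenset(), {"a"}, frozenset())

    def test_conservation(self, rng):
        a = set(map(int, rng.integers(0, 50, size=30)))
        b = set(map(int, rng.integers(0, 50, size=30)))
        only_a, both, only_b = lineage_venn(a, b)
        assert len(only_a) + len(both) + len(only_b) == len(a | b)
        assert len(only_a) + len(both) == len(a)


class TestLogNormalise:
    def test_arithmetic(self):
        counts = np.array([[1, 9999]])
        norm = sc_log_normalise(counts)
        assert norm[0, 0] == pytest.approx(np.log(2.0))

    def test_zero_count_zero_value(self):
        norm = sc_log_normalise(np.array([[0, 5]]))
        assert norm[0, 0] == 0.0

    def test_depth_invariance(self):
        c = np.array([[2, 5, 13]])
        assert np.allclose(sc_log_normalise(c), sc_log_normalise(2 * c))

    def test_all_zero_cell_lists_barcode(self):
        with pytest.raises(ValidationError, match="badcell"):
            sc_log_normalise(np.array([[1, 1], [0, 0]]),
                             barcodes=["ok", "badcell"])


class TestScWilcoxon:
    def _toy(self, seed=11, n=30, effect=2.0):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(5.0, size=(2 * n, 4))
        counts[:n, 0] = rng.poisson(5.0 * effect, size=n)  # induced gene
        counts[:, 3] = 0
        counts[0, 3] = 1  # detected in ~3% of group a only
        norm = sc_log_normalise(counts)
        return counts, norm, np.arange(n), np.arange(n, 2 * n)

    def test_detection_filter(self):
        counts, norm, a, b = self._toy()
        res = sc_wilcoxon_de(norm, list("wxyz"), a, b, counts=counts)
        assert "z" not in set(res["transcript_id"])

    def test_logfc_prefilter(self):
        # identical group distributions -> |log2FC| = 0 < 0.25: not tested
        counts = np.tile(np.array([[3, 5], [7, 2]]), (10, 1))
        norm = sc_log_normalise(counts)
        res = sc_wilcoxon_de(norm, ["g0", "g1"], np.arange(10),
                             np.arange(10, 20), counts=counts)
        assert len(res) == 0

    def test_induced_gene_recovered(self):
        counts, norm, a, b = self._toy()
        res = sc_wilcoxon_de(norm, list("wxyz"), a, b, counts=counts)
        res = res.set_index("transcript_id")
        assert res.loc["w", "padj"] < 0.05 and res.loc["w", "log2fc"] > 0

    def test_p_matches_rank_sum_on_same_vectors(self):
        counts, norm, a, b = self._toy()
        res = sc_wilcoxon_de(norm, list("wxyz"), a, b,
                             counts=counts).set_index("transcript_id")
        j = 0  # gene "w"
        _, p = mann_whitney_u(norm[a, j], norm[b, j])
        m = len(res)
        assert res.loc["w", "pvalue"] == pytest.approx(p, rel=1e-9)
        assert res.loc["w", "padj"] == pytest.approx(min(p * m, 1.0))

    def test_permutation_oracle_on_tiny_groups(self, rng):
        from .test_association import permutation_p
        counts = rng.poisson(3.0, size=(14, 2)) + 1
        norm = sc_log_normalise(counts)
        a, b = np.arange(7), np.arange(7, 14)
        res = sc_wilcoxon_de(norm, ["g0", "g1"], a, b, counts=counts,
                             logfc_threshold=0.0)
        for _, row in res.iterrows():
            j = ["g0", "g1"].index(row["transcript_id"])
            assert row["pvalue"] == pytest.approx(
                permutation_p(norm[a, j], norm[b, j]), abs=0.02)

    def test_empty_group_is_an_error(self):
        _, norm, a, _ = self._toy()
        with pytest.raises(ValidationError):
            sc_wilcoxon_de(norm, list("wxyz"), a, np.array([], dtype=int))


class TestEligibility:
    def _meta(self, n_cells, n_samples=6):
        rows = []
        for i in range(n_cells):
            rows.append({"cell_type": "T", "treatment": f"s{i % n_samples}"})
        # make sure every sample label exists even if the type skips some
        for j in range(n_samples):
            rows.append({"cell_type": "other", "treatment": f"s{j}"})
        return pd.DataFrame(rows)

    def test_strictly_above_average(self):
        assert "T" in eligible_cell_types(self._meta(301))

    def test_boundary_exactly_average_excluded(self):
        assert "T" not in eligible_cell_types(self._meta(300))

    def test_denominator_is_all_samples(self):
        # 301 cells all in one sample still average 301/6 > 50
        meta = self._meta(0)
        extra = pd.DataFrame([{"cell_type": "T", "treatment": "s0"}] * 301)
        assert "T" in eligible_cell_types(pd.concat([meta, extra]))


class TestCoreIsg:
    def _tables(self, drop_pair=None):
        tables = {}
        for ct in ("mono", "T"):
            for trt in ("ifna1", "ifnb"):
                rows = [("core1", 1.0, 0.001), ("core2", 0.9, 0.001),
                        ("spec", 2.0, 0.001 if ct == "mono" else 0.9)]
                if (ct, trt) == drop_pair:
                    rows = [r for r in rows if r[0] != "core2"]
                tables[(ct, trt)] = de_table(rows, contrast=trt)
        return tables

    def test_intersection(self):
        assert core_isg_set(self._tables()) == {"core1", "core2"}

    def test_failing_one_pair_excludes(self):
        assert core_isg_set(self._tables(drop_pair=("T", "ifnb"))) == {"core1"}

    def test_strict_padj_and_fold(self):
        tables = {("m", "b"): de_table(
            [("a", np.log2(1.5), 0.01),   # fold boundary: included
             ("b", 1.0, 0.05),            # padj exactly 0.05: excluded
             ("c", 0.5, 0.001)])}         # below 1.5-fold
        assert core_isg_set(tables) == {"a"}

    def test_missing_table_is_an_error(self):
        with pytest.raises(ValidationError):
            core_isg_set({("m", "b"): None})

    def test_published_core_list_is_frozen(self):
        assert len(CORE_ISGS) == 10 and "IFI44L" in CORE_ISGS


class TestIsgScore:
    def test_two_cell_hand_oracle(self):
        counts = np.array([[5, 0, 5], [0, 10, 0]])
        norm = sc_log_normalise(counts)
        scores = isg_score(norm, ["a", "b", "c"], ["a", "c"])
        # cell 0: two genes at 5/10 counts each -> 2*ln(1+1e4*0.5)
        assert scores[0] == pytest.approx(2 * np.log(1 + 1e4 * 0.5))
        assert scores[1] == 0.0

    def test_additive_over_disjoint_sets(self, rng):
        counts = rng.poisson(3.0, size=(5, 6)) + 1
        norm = sc_log_normalise(counts)
        genes = list("abcdef")
        total = isg_score(norm, genes, ["a", "b", "c", "d"])
        s1 = isg_score(norm, genes, ["a", "c"])
        s2 = isg_score(norm, genes, ["b", "d"])
        assert np.allclose(total, s1 + s2)

    def test_missing_genes_warned_and_skipped(self):
        norm = sc_log_normalise(np.array([[1, 1]]))
        with pytest.warns(UserWarning):
            scores = isg_score(norm, ["a", "b"], ["a", "zzz"])
        assert len(scores) == 1

    def test_fully_missing_set_is_an_error(self):
        norm = sc_log_normalise(np.array([[1, 1]]))
        with pytest.raises(ValidationError):
            isg_score(norm, ["a", "b"], ["zzz"])
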