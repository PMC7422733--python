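"""Control-centered scoring, signed DE scores, and myeloid balancing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hamkit.core_data import ExpressionMatrix, GeneSet, SampleTable
from hamkit.geneset_scoring import (
    compare_groups,
    control_center,
    de_score,
    exclude_genes,
    gene_set_score,
    myeloid_balance,
    restrict_to_shared_genes,
    stratify_scores,
    ScoreTable,
)


def _logm(arr, genes, samples):
    return ExpressionMatrix(
        pd.DataFrame(np.asarray(arr, dtype=float), index=genes, columns=samples),
        layer="log2stab",
    )


class TestControlCenter:
    def test_control_mean_zero_per_gene(self):
        rng = np.random.default_rng(1)
        m = _logm(rng.normal(2, 1, (6, 8)), [f"g{i}" for i in range(6)],
                  [f"s{i}" for i in range(8)])
        centered = control_center(m, ["s0", "s1", "s2"])
        np.testing.assert_allclose(
            centered.values[["s0", "s1", "s2"]].mean(axis=1), 0.0, atol=1e-12
        )

    def test_hand_example(self):
        # control values (1, 3), AD value 4 -> centered AD value 2
        m = _logm([[1.0, 3.0, 4.0]], ["g"], ["c1", "c2", "ad"])
        centered = control_center(m, ["c1", "c2"])
        assert centered.values.at["g", "ad"] == pytest.approx(2.0)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        m = _logm(rng.normal(size=(4, 5)), list("abcd"), [f"s{i}" for i in range(5)])
        once = control_center(m, ["s0", "s1"])
        twice = control_center(once, ["s0", "s1"])
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_empty_control_set_rejected(self):
        m = _logm([[1.0, 2.0]], ["g"], ["a", "b"])
        with pytest.raises(ValueError, match="empty"):
            control_center(m, [])


class TestScores:
    def test_all_zero_matrix_scores_zero(self, plain_set):
        m = ExpressionMatrix(
            pd.DataFrame(np.zeros((3, 4)), index=["gA", "gB", "gC"],
                         columns=list("wxyz")), layer="centered")
        assert (gene_set_score(m, plain_set).scores == 0).all()

    def test_singleton_set_equals_gene_value(self, centered_matrix):
        gs = GeneSet(name="one", members=["gB"])
        out = gene_set_score(centered_matrix, gs)
        pd.testing.assert_series_equal(
            out.scores, centered_matrix.values.loc["gB"], check_names=False
        )

    def test_arithmetic_oracle_mean(self):
        m = ExpressionMatrix(
            pd.DataFrame({"s": [1.0, 2.0, 6.0]}, index=["a", "b", "c"]), "centered")
        out = gene_set_score(m, GeneSet(name="t", members=["a", "b", "c"]))
        assert out.scores["s"] == pytest.approx(3.0)

    def test_signed_score_arithmetic_oracle(self):
        # (+1: 2.0) and (-1: -4.0) -> (2 + 4) / 2 = 3
        m = ExpressionMatrix(
            pd.DataFrame({"s": [2.0, -4.0]}, index=["up", "down"]), "centered")
        gs = GeneSet(name="t", members=["up", "down"], direction={"up": 1, "down": -1})
        assert de_score(m, gs).scores["s"] == pytest.approx(3.0)

    def test_down_gene_sign_rule(self):
        m = ExpressionMatrix(pd.DataFrame({"s": [-1.0]}, index=["d"]), "centered")
        gs = GeneSet(name="t", members=["d"], direction={"d": -1})
        assert de_score(m, gs).scores["s"] == pytest.approx(1.0)

    def test_de_score_equals_gene_set_score_for_plain_sets(self, centered_matrix, plain_set):
        pd.testing.assert_series_equal(
            de_score(centered_matrix, plain_set).scores,
            gene_set_score(centered_matrix, plain_set).scores,
        )

    def test_absent_members_dropped_and_counted(self, centered_matrix):
        gs = GeneSet(name="t", members=["gA", "missing"])
        out = gene_set_score(centered_matrix, gs)
        assert out.n_genes_used == 1

    def test_no_members_present_is_error(self, centered_matrix):
        gs = GeneSet(name="ghost", members=["nope"])
        with pytest.raises(ValueError, match="ghost"):
            gene_set_score(centered_matrix, gs)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_control_mean_of_score_is_zero(self, seed):
        """Centering propagates: the mean score over the control set is 0."""
        rng = np.random.default_rng(seed)
        n_g, n_s = 8, 10
        m = _logm(rng.normal(3, 2, (n_g, n_s)), [f"g{i}" for i in range(n_g)],
                  [f"s{i}" for i in range(n_s)])
        controls = [f"s{i}" for i in range(4)]
        centered = control_center(m, controls)
        gs = GeneSet(name="t", members=[f"g{i}" for i in range(0, n_g, 2)])
        out = gene_set_score(centered, gs)
        assert abs(out.scores[controls].mean()) < 1e-9


class TestSetOperations:
    def test_restrict_noop_when_all_present(self, centered_matrix, plain_set):
        (out,) = restrict_to_shared_genes([plain_set], [centered_matrix])
        assert out.members == plain_set.members

    def test_restrict_removes_member_absent_from_one_dataset(self, centered_matrix):
        other = ExpressionMatrix(
            pd.DataFrame(np.zeros((2, 2)), index=["gA", "gB"], columns=["x", "y"]),
            "centered")
        gs = GeneSet(name="t", members=["gA", "gB", "gC"])
        (out,) = restrict_to_shared_genes([gs], [centered_matrix, other])
        assert out.members == ["gA", "gB"]

    def test_restrict_commutes_over_dataset_order(self, centered_matrix):
        other = ExpressionMatrix(
            pd.DataFrame(np.zeros((2, 2)), index=["gA", "gC"], columns=["x", "y"]),
            "centered")
        gs = GeneSet(name="t", members=["gA", "gB", "gC"])
        (a,) = restrict_to_shared_genes([gs], [centered_matrix, other])
        (b,) = restrict_to_shared_genes([gs], [other, centered_matrix])
        assert a.members == b.members

    def test_exclude_disjoint_unchanged(self, plain_set):
        assert exclude_genes(plain_set, ["other"]).members == plain_set.members

    def test_exclude_apoe_reduces_size_by_one(self):
        gs = GeneSet(name="dam", members=["APOE", "TREM2", "CST7"])
        out = exclude_genes(gs, ["APOE"])
        assert len(out) == len(gs) - 1 and "APOE" not in out.members

    def test_exclude_all_members_warns(self, plain_set):
        with pytest.warns(UserWarning, match="empty"):
            out = exclude_genes(plain_set, plain_set.members)
        assert len(out) == 0


def _score_table(values, ids):
    return ScoreTable(scores=pd.Series(values, index=ids, dtype=float),
                      gene_set_name="t", n_genes_used=1)


class TestMyeloidBalance:
    def test_already_balanced_nothing_discarded(self):
        ids = [f"s{i}" for i in range(8)]
        scores = _score_table(np.arange(8.0), ids)
        dx = pd.Series(["control", "AD"] * 4, index=ids)
        plan = myeloid_balance(scores, dx, n_bins=4, seed=0)
        assert plan.discarded_sample_ids == []
        assert sorted(plan.kept_sample_ids) == ids

    def test_pure_bin_dropped_mixed_bin_untouched(self):
        # bin1: 4 AD + 4 control at the target ratio -> untouched;
        # bin2: 4 AD, no control -> no achievable mix, dropped wholly
        ids = [f"s{i}" for i in range(12)]
        scores = _score_table([0.0] * 8 + [10.0] * 4, ids)
        dx = pd.Series(["AD", "control"] * 4 + ["AD"] * 4, index=ids)
        plan = myeloid_balance(scores, dx, n_bins=2, seed=1, binning="width")
        assert sorted(plan.kept_sample_ids) == sorted(ids[:8])
        assert sorted(plan.discarded_sample_ids) == sorted(ids[8:])

    def test_same_seed_identical_plan(self):
        rng = np.random.default_rng(0)
        ids = [f"s{i}" for i in range(40)]
        scores = _score_table(rng.normal(size=40), ids)
        dx = pd.Series(rng.choice(["AD", "control"], 40, p=[0.7, 0.3]), index=ids)
        p1 = myeloid_balance(scores, dx, n_bins=5, seed=9)
        p2 = myeloid_balance(scores, dx, n_bins=5, seed=9)
        assert p1.kept_sample_ids == p2.kept_sample_ids

    def test_different_seed_same_per_bin_kept_counts(self):
        rng = np.random.default_rng(1)
        ids = [f"s{i}" for i in range(60)]
        scores = _score_table(rng.normal(size=60), ids)
        dx = pd.Series(rng.choice(["AD", "control"], 60, p=[0.65, 0.35]), index=ids)
        p1 = myeloid_balance(scores, dx, n_bins=6, seed=1)
        p2 = myeloid_balance(scores, dx, n_bins=6, seed=2)
        for plan in (p1, p2):
            assert set(plan.kept_sample_ids) | set(plan.discarded_sample_ids) == set(ids)
        k1 = pd.Series(p1.bin_assignment[p1.kept_sample_ids]).value_counts().sort_index()
        k2 = pd.Series(p2.bin_assignment[p2.kept_sample_ids]).value_counts().sort_index()
        pd.testing.assert_series_equal(k1, k2)

    def test_balancing_never_increases_diagnosis_score_correlation(self):
        from hamkit.synthetic_data import SimConfig, simulate_whole_tissue
        from hamkit import normalization

        cfg = SimConfig(seed=11, n_genes=200, n_control_tissue=40, n_ad_tissue=40)
        expr, meta, _ = simulate_whole_tissue(cfg)
        logm = normalization.log_stabilize(expr)
        ctrl = [s for s in logm.sample_ids if meta["diagnosis"][s] == "control"]
        centered = control_center(logm, ctrl)
        mye = gene_set_score(centered, GeneSet(name="m", members=cfg.cell_types["microglia"]))
        dx_num = (meta["diagnosis"] == "AD").astype(float)
        before = abs(np.corrcoef(mye.scores, dx_num[mye.scores.index])[0, 1])
        plan = myeloid_balance(mye, meta["diagnosis"], n_bins=20, seed=3)
        kept = plan.kept_sample_ids
        after = abs(np.corrcoef(mye.scores[kept], dx_num[kept])[0, 1])
        assert after <= before + 1e-12

    def test_invalid_bins_rejected(self):
        scores = _score_table([1.0, 2.0], ["a", "b"])
        dx = pd.Series(["AD", "control"], index=["a", "b"])
        with pytest.raises(ValueError):
            myeloid_balance(scores, dx, n_bins=0, seed=0)


class TestCompareGroups:
    def test_identical_groups_delta_zero(self):
        ids = [f"s{i}" for i in range(8)]
        scores = _score_table([1, 2, 3, 4, 1, 2, 3, 4], ids)
        dx = pd.Series(["control"] * 4 + ["AD"] * 4, index=ids)
        cmp = compare_groups(scores, dx)
        assert cmp.delta == pytest.approx(0.0)
        assert cmp.p_value == pytest.approx(1.0)

    def test_swap_negates_delta_keeps_p(self):
        rng = np.random.default_rng(4)
        ids = [f"s{i}" for i in range(10)]
        scores = _score_table(rng.normal(size=10), ids)
        dx = pd.Series(["control"] * 5 + ["AD"] * 5, index=ids)
        fwd = compare_groups(scores, dx, group_a="control", group_b="AD")
        rev = compare_groups(scores, dx, group_a="AD", group_b="control")
        assert fwd.delta == pytest.approx(-rev.delta)
        assert fwd.p_value == pytest.approx(rev.p_value)

    def test_tiny_jitter_separation_is_significant(self):
        rng = np.random.default_rng(5)
        ids = [f"s{i}" for i in range(8)]
        vals = np.concatenate([np.zeros(4), np.ones(4)]) + rng.normal(0, 1e-6, 8)
        scores = _score_table(vals, ids)
        dx = pd.Series(["control"] * 4 + ["AD"] * 4, index=ids)
        cmp = compare_groups(scores, dx)
        assert cmp.p_value < 1e-6
        assert cmp.delta == pytest.approx(1.0, abs=1e-5)

    def test_welch_equals_student_for_balanced_equal_variance(self):
        ids = [f"s{i}" for i in range(8)]
        scores = _score_table([0, 1, 2, 3, 2, 3, 4, 5], ids)
        dx = pd.Series(["control"] * 4 + ["AD"] * 4, index=ids)
        s = compare_groups(scores, dx, variant="student")
        w = compare_groups(scores, dx, variant="welch")
        assert s.p_value == pytest.approx(w.p_value)


class TestStratify:
    def test_levels_partition_samples(self):
        ids = [f"s{i}" for i in range(9)]
        scores = _score_table(np.arange(9.0), ids)
        braak = pd.Series(["low", "mid", "high"] * 3, index=ids)
        strata = stratify_scores(scores, braak, ["low", "mid", "high"])
        assert sum(len(t.scores) for t in strata.values()) == 9

    def test_unknown_level_rejected(self):
        scores = _score_table([1.0, 2.0], ["a", "b"])
        by = pd.Series(["x", "y"], index=["a", "b"])
        with pytest.raises(ValueError, match="unknown"):
            stratify_scores(scores, by, ["x"])

    def test_empty_level_warns(self):
        scores = _score_table([1.0, 2.0], ["a", "b"])
        by = pd.Series(["x", "x"], index=["a", "b"])
        with pytest.warns(UserWarning, match="no samples"):
            strata = stratify_scores(scores, by, ["x", "y"])
        assert len(strata["y"].scores) == 0
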