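"""TPM, BH, DE calls, profile classes, PCA and heatmap ordering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import miteomics as m
from miteomics import expression as ex
from conftest import toy_em

GROUPS = ["larvae", "nymphs", "females", "males"]


def bh_stepup_reference(p):
    """Brute-force BH step-up: q_(i) = min_{j>=i} min(1, p_(j) * m / j)."""
    p = np.asarray(p, dtype=float)
    order = np.argsort(p, kind="stable")
    msize = len(p)
    q_sorted = np.empty(msize)
    running = 1.0
    for rank in range(msize, 0, -1):
        running = min(running, p[order[rank - 1]] * msize / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(msize)
    q[order] = q_sorted
    return q


class TestTpm:
    def test_equal_counts_equal_lengths(self):
        em = toy_em(np.array([[10, 10], [10, 10]]), [1000, 1000],
                    ["a", "a"])
        tpm = m.compute_tpm(em)
        assert np.allclose(tpm.to_numpy(), 5e5)

    def test_length_normalization_equalizes_rates(self):
        em = toy_em(np.array([[10], [20]]), [1000, 2000], ["a"])
        tpm = m.compute_tpm(em)
        assert np.allclose(tpm.iloc[:, 0], [5e5, 5e5])

    def test_single_gene_gets_everything(self):
        em = toy_em(np.array([[7]]), [500], ["a"])
        assert m.compute_tpm(em).iloc[0, 0] == pytest.approx(1e6)

    def test_columns_sum_to_one_million(self, small_em):
        tpm = m.compute_tpm(small_em)
        assert np.allclose(tpm.sum(axis=0), 1e6, rtol=1e-6)

    def test_all_zero_sample_stays_zero(self):
        em = toy_em(np.array([[0, 5], [0, 5]]), [1000, 1000], ["a", "a"])
        tpm = m.compute_tpm(em)
        assert (tpm.iloc[:, 0] == 0).all()

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            toy_em(np.array([[1]]), [0], ["a"])


class TestBhAdjust:
    def test_hand_worked_uniform_ladder(self):
        # p*(m/j) = .04, .04, .04, .04 -> running min keeps 0.04 everywhere
        np.testing.assert_allclose(
            m.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        assert m.bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(m.bh_adjust([0.2] * 5), [0.2] * 5)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            m.bh_adjust([0.5, 1.5])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50),
           st.integers(0, 2 ** 31 - 1))
    def test_matches_stepup_reference_and_dominates_p(self, base, seed):
        rng = np.random.default_rng(seed)
        p = np.concatenate([np.array(base), rng.uniform(size=20)])
        q = m.bh_adjust(p)
        np.testing.assert_allclose(q, bh_stepup_reference(p), atol=1e-12)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_agreement_on_many_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(m.bh_adjust(p), bh_stepup_reference(p),
                                       atol=1e-12)


class TestPairwiseDe:
    def _em_two_groups(self, a, b):
        counts = np.column_stack([a, b]).astype(int)
        return toy_em(counts, [1000] * counts.shape[0],
                      ["x"] * a.shape[1] + ["y"] * b.shape[1])

    def test_identical_groups_null(self):
        a = np.tile([[100], [50]], (1, 3))
        em = self._em_two_groups(a, a)
        de = m.pairwise_de(em, "x", "y")
        assert np.allclose(de["log2fc"], 0)
        assert np.allclose(de["pvalue"], 1)

    def test_log2fc_pseudocount_arithmetic(self):
        # mean TPM 100 vs 25 with c=1 -> log2(101/26)
        tpm = pd.DataFrame(
            [[100.0, 100.0, 100.0, 25.0, 25.0, 25.0],
             [1e6 - 100] * 3 + [1e6 - 25] * 3],
            index=["g0", "g1"], columns=[f"s{i}" for i in range(6)])
        em = toy_em(np.ones((2, 6), dtype=int), [1000, 1000],
                    ["x"] * 3 + ["y"] * 3)
        de = m.pairwise_de(em, "x", "y", tpm=tpm)
        assert de.loc[de.gene_id == "g0", "log2fc"].iloc[0] == \
            pytest.approx(np.log2(101 / 26))

    def test_strong_fold_change_called(self):
        # 10 genes 2^5-fold up against a large flat background (small
        # fraction keeps the TPM compositional shift negligible)
        rng = np.random.default_rng(0)
        base = rng.integers(90, 110, size=(600, 3))
        up = base.copy()
        up[:10] *= 2 ** 5
        em = self._em_two_groups(up, base)
        de = m.pairwise_de(em, "x", "y")
        hit = de.iloc[:10]
        assert (hit["qvalue"] <= 0.05).all()
        assert np.allclose(hit["log2fc"], 5, atol=0.8)

    def test_small_group_rejected(self):
        em = toy_em(np.ones((3, 3), dtype=int), [1000] * 3,
                    ["x", "x", "y"])
        with pytest.raises(ValueError):
            m.pairwise_de(em, "x", "y")

    def test_welch_method_available(self, small_em):
        de = m.pairwise_de(small_em, "larvae", "females", method="welch")
        assert de["pvalue"].between(0, 1).all()
        with pytest.raises(ValueError):
            m.pairwise_de(small_em, "larvae", "females", method="bogus")


def _de_row(gene, comparison, log2fc, qvalue):
    return {"gene_id": gene, "comparison": comparison, "log2fc": log2fc,
            "pvalue": qvalue / 2, "qvalue": qvalue}


def _null_de(gene):
    labels = [ex.comparison_label(x, y)
              for x, y in ex.canonical_comparisons(GROUPS)]
    return [_de_row(gene, lab, 0.0, 1.0) for lab in labels]


class TestAssignProfiles:
    def test_subthreshold_fold_change_is_no_call(self):
        rows = _null_de("g")
        rows[0].update(log2fc=np.log2(1.8), qvalue=0.04, pvalue=0.02)
        prof = m.assign_profiles(pd.DataFrame(rows), GROUPS)
        assert prof.loc["g", "venn_class"] == ""

    def test_female_flag_requires_all_three_comparisons(self):
        rows = _null_de("g")
        # females higher than each of larvae, nymphs, males
        for lab, fc in (("larvae_vs_females", -3.0),
                        ("nymphs_vs_females", -3.0),
                        ("females_vs_males", 3.0)):
            for r in rows:
                if r["comparison"] == lab:
                    r.update(log2fc=fc, qvalue=0.01, pvalue=0.005)
        prof = m.assign_profiles(pd.DataFrame(rows), GROUPS)
        assert prof.loc["g", "flag_females"]
        assert not prof.loc["g", "flag_males"]
        assert prof.loc["g", "venn_class"] == \
            "larvae_vs_females+nymphs_vs_females+females_vs_males"

    def test_all_null_gives_empty_classes(self):
        de = pd.DataFrame(_null_de("g1") + _null_de("g2"))
        prof = m.assign_profiles(de, GROUPS)
        assert (prof["venn_class"] == "").all()

    def test_missing_comparison_rejected(self):
        de = pd.DataFrame(_null_de("g")[:5])
        with pytest.raises(ValueError):
            m.assign_profiles(de, GROUPS)

    def test_inconsistent_signs_do_not_flag(self):
        rows = _null_de("g")
        for lab, fc in (("larvae_vs_females", -3.0),
                        ("nymphs_vs_females", 3.0),   # females LOWER here
                        ("females_vs_males", 3.0)):
            for r in rows:
                if r["comparison"] == lab:
                    r.update(log2fc=fc, qvalue=0.01, pvalue=0.005)
        prof = m.assign_profiles(pd.DataFrame(rows), GROUPS)
        assert not prof.loc["g", "flag_females"]


class TestVennCounts:
    def test_four_groups_enumerate_63_classes(self):
        assert len(ex.enumerate_profile_classes(GROUPS)) == 63
        assert len(ex.canonical_comparisons(GROUPS)) == 6

    def test_no_degs_all_zero(self):
        de = pd.DataFrame(_null_de("g"))
        counts = m.venn_counts(m.assign_profiles(de, GROUPS), GROUPS)
        assert len(counts) == 63
        assert (counts == 0).all()

    def test_single_class_bucket(self):
        rows = []
        for i in range(10):
            gr = _null_de(f"g{i}")
            gr[0].update(log2fc=2.0, qvalue=0.01, pvalue=0.005)
            rows += gr
        counts = m.venn_counts(
            m.assign_profiles(pd.DataFrame(rows), GROUPS), GROUPS)
        assert counts["larvae_vs_nymphs"] == 10
        assert counts.sum() == 10

    def test_partition_property(self, calibration_profiles):
        counts = m.venn_counts(calibration_profiles, GROUPS)
        n_deg = int((calibration_profiles["venn_class"] != "").sum())
        assert counts.sum() == n_deg


class TestCountFoldThreshold:
    def _table(self):
        rows = []
        for i, (fc, q) in enumerate([(7.0, 0.01), (np.log2(50.0), 0.01),
                                     (6.0, 0.5), (-7.0, 0.01), (5.4, 0.02)]):
            rows.append(_de_row(f"g{i}", "females_vs_males", fc, q))
        return pd.DataFrame(rows)

    def test_strict_exceedance_and_direction(self):
        de = self._table()
        # males-up means negative log2fc in the canonical (F, M) table
        assert m.count_fold_threshold(de, "males", "females", fold=50) == 1
        # exactly 50-fold (g1) excluded by the strict inequality
        assert m.count_fold_threshold(de, "females", "males", fold=50) == 1
        # at 40-fold the exactly-50-fold gene qualifies too
        assert m.count_fold_threshold(de, "females", "males", fold=40) == 3

    def test_empty_table_counts_zero(self):
        de = pd.DataFrame(columns=["gene_id", "comparison", "log2fc",
                                   "pvalue", "qvalue"])
        assert m.count_fold_threshold(de, "females", "males") == 0

    def test_unknown_comparison_rejected(self):
        with pytest.raises(ValueError):
            m.count_fold_threshold(self._table(), "larvae", "nymphs")

    def test_monotone_in_fold(self, calibration_sim, calibration_profiles):
        sim = calibration_sim
        em = m.ExpressionMatrix(sim.counts, sim.sample_groups, sim.lengths)
        de = m.all_pairwise_de(em)
        prev = None
        for fold in (2, 10, 50, 200):
            n = m.count_fold_threshold(de, "males", "females", fold=fold)
            if prev is not None:
                assert n <= prev
            prev = n

    def test_planted_high_fold_males_counted(self):
        # 20 of 4000 genes planted 2^7-fold male-up; the small fraction
        # keeps TPM fold changes close to the planted effect
        cfg = m.SimulationConfig(
            n_genes=4000, profile_fractions={"males_up": 0.005},
            effect_log2fc=7.0, seed=13)
        sim = m.simulate_counts(cfg)
        em = m.ExpressionMatrix(sim.counts, sim.sample_groups, sim.lengths)
        de = m.all_pairwise_de(em)
        n = m.count_fold_threshold(de, "males", "females", fold=50)
        planted = (sim.truth["planted_profile"] == "males_up").sum()
        assert n == planted == 20


class TestPcaScores:
    def test_two_samples_one_component(self):
        tpm = pd.DataFrame(np.random.default_rng(0).uniform(size=(30, 2)),
                           columns=["a", "b"])
        scores, frac = m.pca_scores(tpm)
        assert frac[0] == pytest.approx(1.0)

    def test_fractions_non_increasing_and_bounded(self):
        tpm = pd.DataFrame(np.random.default_rng(1).uniform(size=(50, 12)))
        _, frac = m.pca_scores(tpm)
        assert (np.diff(frac) <= 1e-12).all()
        assert frac.sum() <= 1 + 1e-9

    def test_replicates_cluster_in_pc_space(self, small_em):
        scores, frac = m.pca_scores(m.compute_tpm(small_em))
        coords = scores[["PC1", "PC2"]]
        groups = small_em.groups
        centroid = coords.groupby(groups).transform("mean")
        within = np.linalg.norm(coords - centroid, axis=1).mean()
        overall = np.linalg.norm(coords - coords.mean(), axis=1).mean()
        assert within < overall / 2

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            m.pca_scores(pd.DataFrame({"a": [1.0, 2.0]}))


class TestHclustOrder:
    def test_identical_rows_adjacent(self):
        mat = pd.DataFrame([[0, 0], [5, 5], [0, 0]], index=list("abc"))
        order, labels = m.hclust_order(mat, 2)
        ia, ic = order.index("a"), order.index("c")
        assert abs(ia - ic) == 1
        assert labels["a"] == labels["c"] != labels["b"]

    def test_k_equals_rows_gives_singletons(self):
        mat = pd.DataFrame([[0.0], [1.0], [2.0]], index=list("abc"))
        _, labels = m.hclust_order(mat, 3)
        assert sorted(labels) == [1, 2, 3]

    def test_line_points_split_at_gap(self):
        mat = pd.DataFrame([[0.0], [1.0], [10.0]], index=list("abc"))
        _, labels = m.hclust_order(mat, 2)
        assert labels["a"] == labels["b"] != labels["c"]

    def test_k_too_large_rejected(self):
        mat = pd.DataFrame([[0.0], [1.0]])
        with pytest.raises(ValueError):
            m.hclust_order(mat, 3)


class TestPlantedRecovery:
    """Pipeline-level calibration on the reference simulation."""

    def test_stage_flag_recovery_and_flat_fdr(self, calibration_sim,
                                              calibration_profiles):
        truth, prof = calibration_sim.truth, calibration_profiles
        fem = truth.index[truth["planted_profile"] == "females_up"]
        assert prof.loc[fem, "flag_females"].mean() >= 0.95
        male = truth.index[truth["planted_profile"] == "males_up"]
        assert prof.loc[male, "flag_males"].mean() >= 0.95
        flat = truth.index[truth["planted_profile"] == "flat"]
        assert (prof.loc[flat, "venn_class"] != "").mean() <= 0.01

    def test_deg_membership_is_exactly_nonempty_class(self, calibration_profiles):
        prof = calibration_profiles
        call_cols = [c for c in prof.columns if c.startswith("call_")]
        any_call = (prof[call_cols] != 0).any(axis=1)
        assert (any_call == (prof["venn_class"] != "")).all()
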