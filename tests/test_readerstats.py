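"""Reader-study statistics: aggregation, ICC, non-inferiority, ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from radnoise.readerstats import (ANATOMICAL_LANDMARKS, DoseRecord,
                                  NonInfResult, ReaderStudyConfig,
                                  aggregate_scores, group_homogeneity,
                                  hodges_lehmann, icc_band,
                                  icc_inter_observer, noninferiority_paired,
                                  noninferiority_table, normality_gate,
                                  reduction_rate, signed_rank_ci,
                                  synthesize_reader_scores)


def score_rows(subject, arm, item, scores):
    return [(subject, arm, reader, session, item, s)
            for (reader, session), s in zip(
                [(1, 1), (1, 2), (2, 1), (2, 2)], scores)]


def small_table(scores_base=(4, 4, 4, 4), scores_low=(4, 4, 3, 4)):
    rows = []
    for s in ("S1", "S2", "S3"):
        rows += score_rows(s, "baseline", "ND", scores_base)
        rows += score_rows(s, "low", "ND", scores_low)
    return pd.DataFrame(rows, columns=["subject_id", "arm", "reader",
                                       "session", "item", "score"])


class TestAggregate:
    def test_all_fours_average_to_four(self):
        agg = aggregate_scores(small_table())
        assert agg.loc[("S1", "baseline"), "ND"] == 4.0

    def test_quarter_granularity_like_reader_means(self):
        # four observations {4,4,3,4} average to 3.75, the granularity of a
        # two-reader x two-session mean
        agg = aggregate_scores(small_table())
        assert agg.loc[("S1", "low"), "ND"] == 3.75

    def test_al_total_maxes_at_35(self):
        rows = []
        for item in ANATOMICAL_LANDMARKS:
            for arm in ("baseline", "low"):
                rows += score_rows("S1", arm, item, (5, 5, 5, 5))
        agg = aggregate_scores(pd.DataFrame(
            rows, columns=["subject_id", "arm", "reader", "session",
                           "item", "score"]))
        assert agg.loc[("S1", "baseline"), "AL_total"] == 35.0

    def test_subject_missing_arm_excluded_with_warning(self):
        t = small_table()
        t = t[~((t.subject_id == "S3") & (t.arm == "low"))]
        with pytest.warns(UserWarning, match="missing a paired arm"):
            agg = aggregate_scores(t)
        assert "S3" not in agg.index.get_level_values(0)

    def test_out_of_range_scores_rejected(self):
        t = small_table()
        t.loc[t.index[0], "score"] = 6
        with pytest.raises(ValueError):
            aggregate_scores(t)


class TestDoseAccounting:
    @pytest.mark.parametrize("baseline,low,expected", [
        (42.9, 21.2, 49.4),
        (61.9, 30.2, 48.8),
        (54.2, 25.0, 46.1),
    ])
    def test_worked_reduction_rates(self, baseline, low, expected):
        assert reduction_rate((baseline, low)) == expected

    def test_dose_record_carries_group_cutoffs(self):
        rec = DoseRecord("P1", baseline_ese=47.0, low_ese=23.3, group="C")
        assert rec.aec_cutoff_baseline == 4.2
        assert rec.aec_cutoff_low == 1.78
        assert reduction_rate(rec) == pytest.approx(49.6)

    def test_invalid_doses_rejected(self):
        with pytest.raises(ValueError):
            DoseRecord("P1", baseline_ese=10.0, low_ese=12.0)
        with pytest.raises(ValueError):
            reduction_rate((0.0, 1.0))


class TestIcc:
    def test_band_boundaries_follow_convention(self):
        assert icc_band(0.39) == "poor"
        assert icc_band(0.40) == "fair"
        assert icc_band(0.59) == "fair"
        assert icc_band(0.60) == "good"
        assert icc_band(0.747) == "good"
        assert icc_band(0.75) == "excellent"
        assert icc_band(1.0) == "excellent"

    def test_identical_readers_give_icc_one(self):
        tab = synthesize_reader_scores(ReaderStudyConfig(n_subjects=15), 5)
        r1 = tab[tab.reader == 1]
        r2 = r1.copy()
        r2["reader"] = 2
        res = icc_inter_observer(pd.concat([r1, r2], ignore_index=True))
        assert res.icc_value == pytest.approx(1.0, abs=1e-6)
        assert res.band == "excellent"

    def test_variance_components_construction_gives_half(self):
        # between-image variance 1, reader-error variance 1 -> ICC ~ 0.5
        import pingouin as pg

        gen = np.random.default_rng(2)
        true = gen.normal(0, 1, 500)
        df = pd.DataFrame({
            "image": np.repeat(np.arange(500), 2),
            "reader": np.tile([1, 2], 500),
            "rating": np.repeat(true, 2) + gen.normal(0, 1, 1000),
        })
        res = pg.intraclass_corr(df, "image", "reader", "rating")
        val = float(res.loc[res["Type"].isin(["ICC2", "ICC(A,1)"]),
                            "ICC"].iloc[0])
        assert val == pytest.approx(0.5, abs=0.1)

    def test_reader_bias_lowers_absolute_agreement_icc(self):
        biased = icc_inter_observer(synthesize_reader_scores(
            ReaderStudyConfig(n_subjects=40, reader_bias=(0.0, 0.5)), 5))
        unbiased = icc_inter_observer(synthesize_reader_scores(
            ReaderStudyConfig(n_subjects=40), 5))
        assert biased.icc_value < unbiased.icc_value

    def test_single_reader_rejected(self):
        tab = synthesize_reader_scores(ReaderStudyConfig(n_subjects=5), 0)
        with pytest.raises(ValueError):
            icc_inter_observer(tab[tab.reader == 1])


class TestNormalityGate:
    def test_normal_draws_pass_in_most_seeds(self):
        passed = sum(
            normality_gate(np.random.default_rng(s).normal(0, 1, 200)).normal
            for s in range(50))
        assert passed >= 45

    def test_two_point_mass_fails_in_all_seeds(self):
        for s in range(50):
            d = np.random.default_rng(s).choice([-1.0, 1.0], size=200)
            assert not normality_gate(d).normal

    def test_constant_vector_flagged_degenerate(self):
        res = normality_gate(np.full(10, 0.25))
        assert res.degenerate and not res.normal


class TestHodgesLehmannCI:
    def test_matches_r_wilcox_test(self):
        # frozen from R: wilcox.test(d, conf.int=TRUE) ->
        # pseudomedian 1.725, 95% CI (1.165, 2.370)
        d = np.array([1.83, 0.50, 1.62, 2.48, 1.68, 1.88, 1.55, 3.06, 1.30])
        assert hodges_lehmann(d) == pytest.approx(1.725)
        lo, hi = signed_rank_ci(d)
        assert lo == pytest.approx(1.165)
        assert hi == pytest.approx(2.370)

    def test_large_n_normal_approximation_covers_truth(self):
        cover = 0
        for s in range(200):
            d = np.random.default_rng(s).normal(0.3, 1.0, 40)
            lo, hi = signed_rank_ci(d)
            cover += lo <= 0.3 <= hi
        assert 0.90 <= cover / 200 <= 0.99


class TestNonInferiority:
    def test_identical_arms_trivially_non_inferior(self):
        x = np.array([4.0, 3.5, 4.25, 3.75, 4.0])
        r = noninferiority_paired(x, x.copy(), margin=0.5)
        assert r.location_estimate == 0.0
        assert r.ci95 == (0.0, 0.0)
        assert r.test_used == "degenerate"
        assert r.non_inferior

    def test_decision_is_pure_function_of_upper_bound_and_margin(self):
        # upper bound 0.337 < margin 0.5 -> non-inferior; a margin below
        # the upper bound flips the decision
        r = NonInfResult(item="ND", n=28, location_estimate=0.167,
                         ci95=(-0.004, 0.337), margin=0.5,
                         test_used="paired_t", normality_p=0.2,
                         non_inferior=True)
        assert r.non_inferior == (r.ci95[1] < r.margin)
        assert not (r.ci95[1] < 0.3)

    def test_wilcoxon_branch_taken_iff_gate_fails(self):
        gen = np.random.default_rng(0)
        normal_low = gen.normal(4.0, 0.3, 30)
        r_norm = noninferiority_paired(normal_low + gen.normal(0.1, 0.3, 30),
                                       normal_low, margin=0.5)
        assert r_norm.test_used == "paired_t"
        base = np.full(30, 4.0)
        low = base - gen.choice([0.0, 1.0], size=30, p=[0.8, 0.2])
        r_skew = noninferiority_paired(base, low, margin=0.5)
        assert r_skew.test_used == "wilcoxon"
        assert r_skew.normality_p < 0.05

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError):
            noninferiority_paired(np.zeros(5), np.zeros(6))

    def test_type_one_error_at_margin_controlled(self):
        # true shift equal to the margin: the one-sided alpha = 0.025
        # procedure should wrongly conclude non-inferiority <= 3% of runs
        gen = np.random.default_rng(7)
        wrong = 0
        n_rep = 3000
        for _ in range(n_rep):
            base = gen.normal(0.5, 0.49, 23)
            wrong += noninferiority_paired(base, np.zeros(23),
                                           margin=0.5).non_inferior
        assert wrong / n_rep <= 0.03

    def test_full_table_runs_per_item_margins(self):
        tab = synthesize_reader_scores(ReaderStudyConfig(n_subjects=30), 3)
        out = noninferiority_table(aggregate_scores(tab))
        assert out.loc["AL1", "margin"] == 0.5
        assert out.loc["AL_total", "margin"] == 3.5
        assert set(out.columns) >= {"estimate", "ci_lower", "ci_upper",
                                    "non_inferior", "test"}


class TestGroupHomogeneity:
    def test_separated_group_flagged_by_tukey_only(self):
        gen = np.random.default_rng(1)
        groups = {"A": gen.normal(0, 1, 20), "B": gen.normal(0, 1, 20),
                  "C": gen.normal(5, 1, 20)}
        res = group_homogeneity(groups)
        assert res["anova_p"] < 0.001
        tukey = res["tukey"]
        assert tukey[("A", "B")] > 0.05
        assert tukey[("A", "C")] < 0.001
        assert tukey[("B", "C")] < 0.001

    def test_constant_groups_rejected(self):
        with pytest.raises(ValueError):
            group_homogeneity({"A": np.ones(5), "B": np.ones(5)})


class TestSynthesizeScores:
    def test_zero_noise_equal_arms_gives_zero_difference(self):
        cfg = ReaderStudyConfig(n_subjects=10, arm_shift=0.0,
                                sigma_subject=0.0, sigma_session=0.0)
        agg = aggregate_scores(synthesize_reader_scores(cfg, 0))
        base = agg.xs("baseline", level="arm")
        low = agg.xs("low", level="arm")
        assert (base - low).abs().to_numpy().max() == 0.0

    def test_arm_shift_recovered_on_average(self):
        diffs = []
        for seed in range(20):
            tab = synthesize_reader_scores(ReaderStudyConfig(arm_shift=0.15),
                                           seed)
            agg = aggregate_scores(tab)
            d = (agg.xs("baseline", level="arm")["AL_total"]
                 - agg.xs("low", level="arm")["AL_total"]) / 7.0
            diffs.append(d.mean())
        assert np.mean(diffs) == pytest.approx(0.15, abs=0.1)

    def test_reproducible_per_seed(self):
        cfg = ReaderStudyConfig(n_subjects=8)
        a = synthesize_reader_scores(cfg, 3)
        b = synthesize_reader_scores(cfg, 3)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_variances_rejected(self):
        with pytest.raises(ValueError):
            ReaderStudyConfig(sigma_subject=-1.0)
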