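"""Permutation tests, effect sizes, z-scores, and demographics statistics."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from intraconn.metrics import MetricTable
from intraconn.stats import (EffectResult, abnormality_distance,
                             bonferroni_correct, chi_square_2x2, cohens_d,
                             count_changed_regions, duration_association,
                             effect_size_label, match_controls,
                             permutation_test, weighted_cohens_d,
                             zscore_table)


class TestPermutationTest:
    def test_identical_groups_give_p_one(self):
        assert permutation_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0],
                                n_perm=99, seed=0) == 1.0

    def test_complete_separation_matches_exhaustive_enumeration(self):
        """3-vs-3 with disjoint constants: exhaustive label enumeration says
        2 of C(6,3)=20 partitions reach the observed statistic, p = 0.1."""
        x, y = [0.0, 0.0, 0.0], [10.0, 10.0, 10.0]
        pooled = x + y
        observed = abs(np.mean(x) - np.mean(y))
        hits = 0
        for idx in combinations(range(6), 3):
            gx = [pooled[i] for i in idx]
            gy = [pooled[i] for i in range(6) if i not in idx]
            if abs(np.mean(gx) - np.mean(gy)) >= observed:
                hits += 1
        oracle_p = hits / 20
        assert oracle_p == 0.1
        p = permutation_test(x, y, n_perm=4999, seed=1)
        assert p == pytest.approx(oracle_p, abs=0.02)

    def test_add_one_estimator_never_zero(self):
        p = permutation_test(np.arange(10.0), np.arange(10.0) + 100,
                             n_perm=199, seed=2)
        assert p >= 1 / 200

    def test_type_one_error_calibrated(self):
        """Null rejection rate at alpha=0.05 within its binomial CI."""
        rng = np.random.default_rng(10)
        rejections = 0
        n_rep = 400
        for i in range(n_rep):
            x = rng.normal(size=12)
            y = rng.normal(size=15)
            if permutation_test(x, y, n_perm=199, seed=i) < 0.05:
                rejections += 1
        rate = rejections / n_rep
        ci = 3 * np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) < ci + 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            permutation_test([], [1.0], n_perm=10, seed=0)


class TestCohensD:
    def test_identical_groups_zero(self):
        assert cohens_d([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_hand_arithmetic(self):
        # means 1 and 4, pooled SD = sqrt(2) -> d = -3/sqrt(2)
        assert cohens_d([0.0, 2.0], [3.0, 5.0]) == pytest.approx(
            -3 / np.sqrt(2))

    def test_scale_invariance(self):
        x = np.array([1.0, 3.0, 4.0])
        y = np.array([2.0, 5.0, 9.0])
        assert cohens_d(3 * x, 3 * y) == pytest.approx(cohens_d(x, y))

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError, match="pooled SD"):
            cohens_d([1.0, 1.0], [2.0, 2.0])


class TestWeightedCohensD:
    def test_equal_effects_identity(self):
        assert weighted_cohens_d(0.7, 5, 0.7, 9) == pytest.approx(0.7)

    def test_single_group_limit(self):
        assert weighted_cohens_d(0.9, 7, 123.0, 0) == pytest.approx(0.9)

    def test_table1_group_sizes(self):
        assert weighted_cohens_d(1.0, 19, 0.5, 14) == pytest.approx(26 / 33)

    def test_lies_between_components(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            d1, d2 = rng.normal(size=2)
            n1, n2 = rng.integers(1, 40, size=2)
            dw = weighted_cohens_d(d1, n1, d2, n2)
            assert min(d1, d2) - 1e-12 <= dw <= max(d1, d2) + 1e-12

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            weighted_cohens_d(1.0, 0, 1.0, 0)


class TestEffectSizeLabel:
    @pytest.mark.parametrize("d,label", [
        (2.1, "huge"), (2.0, "huge"), (1.5, "very large"), (0.9, "large"),
        (-0.5, "medium"), (0.3, "small"), (0.05, "very small"),
        (0.005, "negligible"),
    ])
    def test_bins(self, d, label):
        assert effect_size_label(d) == label


class TestBonferroni:
    def test_multiplies_and_caps(self):
        out = bonferroni_correct([0.01, 0.5, 0.002, 0.3, 0.04])
        assert out[0] == pytest.approx(0.05)
        assert out[1] == 1.0

    def test_single_test_identity(self):
        assert bonferroni_correct([0.3])[0] == pytest.approx(0.3)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_correct([1.2])


class TestChiSquare:
    @pytest.mark.parametrize("tab,chi2,p", [
        ([[17, 19], [15, 18]], 0.022, 0.883),    # controls vs all patients
        ([[17, 19], [7, 12]], 0.545, 0.460),     # controls vs left surgery
        ([[17, 19], [8, 6]], 0.397, 0.529),      # controls vs right surgery
        ([[12, 7], [9, 5]], 0.004, 0.947),       # outcome by surgery side
    ])
    def test_demographics_tables(self, tab, chi2, p):
        got_chi2, got_p = chi_square_2x2(tab)
        assert round(got_chi2, 3) == chi2
        assert round(got_p, 3) == p

    def test_gender_side_cell_recomputed(self):
        """The side-by-gender table gives chi2=1.340 whose p matches the
        published p=0.247, identifying the published statistic as a typo."""
        chi2, p = chi_square_2x2([[7, 12], [8, 6]])
        assert chi2 == pytest.approx(1.3398, abs=1e-4)
        assert p == pytest.approx(0.2471, abs=1e-4)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margins"):
            chi_square_2x2([[0, 0], [3, 4]])

    def test_yates_correction_not_applied(self):
        from scipy.stats import chi2_contingency

        tab = [[17, 19], [15, 18]]
        with_yates = chi2_contingency(tab, correction=True)[0]
        ours, _ = chi_square_2x2(tab)
        assert ours != pytest.approx(with_yates)


def small_ztable():
    rows = []
    rng = np.random.default_rng(4)
    subjects = [f"C{i}" for i in range(8)] + [f"P{i}" for i in range(4)]
    for s in subjects:
        for region in ("ipsi_00", "ipsi_01"):
            for metric in ("C", "L"):
                rows.append((s, region, metric, rng.normal()))
    table = MetricTable(pd.DataFrame(
        rows, columns=["subject", "region", "metric", "value"]))
    cohort = pd.DataFrame({
        "id": subjects,
        "group": ["control"] * 8 + ["patient"] * 4,
    })
    return table, cohort


class TestZScores:
    def test_control_mean_maps_to_zero_and_two_sd_to_two(self):
        table, cohort = small_ztable()
        data = table.data
        ctrl = data[data.subject.str.startswith("C")]
        stats = ctrl.groupby(["region", "metric"])["value"].agg(["mean", "std"])
        mu, sd = stats.loc[("ipsi_00", "C")]
        data.loc[(data.subject == "P0") & (data.region == "ipsi_00")
                 & (data.metric == "C"), "value"] = mu
        data.loc[(data.subject == "P1") & (data.region == "ipsi_00")
                 & (data.metric == "C"), "value"] = mu + 2 * sd
        z = zscore_table(table, cohort)
        zi = z.set_index(["subject", "region", "metric"])["z"]
        assert zi[("P0", "ipsi_00", "C")] == pytest.approx(0.0, abs=1e-12)
        assert zi[("P1", "ipsi_00", "C")] == pytest.approx(2.0, abs=1e-12)

    def test_full_table_matches_two_pass_recomputation(self):
        table, cohort = small_ztable()
        z = zscore_table(table, cohort)
        data = table.data
        ctrl = data[data.subject.str.startswith("C")]
        for _, row in z.sample(20, random_state=0).iterrows():
            ref = ctrl[(ctrl.region == row.region)
                       & (ctrl.metric == row.metric)]["value"]
            expected = (data[(data.subject == row.subject)
                             & (data.region == row.region)
                             & (data.metric == row.metric)]["value"].iloc[0]
                        - ref.mean()) / ref.std(ddof=1)
            assert row.z == pytest.approx(expected, abs=1e-12)

    def test_zero_control_sd_flagged(self):
        table, cohort = small_ztable()
        data = table.data
        sel = (data.region == "ipsi_01") & (data.metric == "L") \
            & data.subject.str.startswith("C")
        data.loc[sel, "value"] = 5.0
        z = zscore_table(table, cohort)
        cell = z[(z.region == "ipsi_01") & (z.metric == "L")]
        assert cell.z.isna().all()


class TestAbnormalityDistance:
    def test_absolute_sum(self):
        z = pd.DataFrame({
            "subject": ["P0", "P0"], "region": ["ipsi_00", "ipsi_00"],
            "metric": ["C", "L"], "z": [1.0, -1.0], "abs_z": [1.0, 1.0]})
        d = abnormality_distance(z, ["ipsi_00"], ["C", "L"])
        assert d["P0"] == 2.0

    def test_matches_brute_force_loop(self):
        table, cohort = small_ztable()
        z = zscore_table(table, cohort)
        d = abnormality_distance(z, ["ipsi_00", "ipsi_01"], ["C"])
        for s in d.index:
            manual = z[(z.subject == s) & (z.metric == "C")]["abs_z"].sum()
            assert d[s] == pytest.approx(manual)

    def test_empty_sets_rejected(self):
        z = pd.DataFrame(columns=["subject", "region", "metric", "z", "abs_z"])
        with pytest.raises(ValueError):
            abnormality_distance(z, [], ["C"])


class TestDurationAssociation:
    def test_identity_gives_perfect_correlation(self):
        x = np.arange(10.0)
        res = duration_association(x, x)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.spearman_rho == pytest.approx(1.0)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(5)
        hits = 0
        for i in range(100):
            res = duration_association(rng.normal(size=200),
                                       rng.normal(size=200))
            hits += int(abs(res.pearson_r) < 0.15)
        assert hits >= 95

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            duration_association([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestChangedRegions:
    def make_effects(self, specs):
        return [EffectResult(region=r, metric="C", d1=d, d2=d, n1=5, n2=5,
                             d_weighted=d, p=p) for r, d, p in specs]

    def test_threshold_monotonicity(self):
        effects = self.make_effects([
            ("r0", 0.7, 0.01), ("r1", 1.5, 0.01), ("r2", 2.5, 0.01),
            ("r3", 0.9, 0.3)])
        c_low = count_changed_regions(effects, 0.5, 0.05)
        c_high = count_changed_regions(effects, 1.2, 0.05)
        assert c_low >= c_high
        assert c_low == 3 and c_high == 2

    def test_requires_both_conditions(self):
        effects = self.make_effects([("r0", 2.0, 0.5), ("r1", 0.1, 0.001)])
        assert count_changed_regions(effects, 0.5, 0.05) == 0


class TestMatchControls:
    def test_matched_subset_size_and_composition(self):
        rng = np.random.default_rng(6)
        rows = []
        for i in range(20):
            rows.append((f"C{i}", "control", rng.uniform(20, 60),
                         "M" if i % 2 else "F", "none"))
        for i in range(8):
            rows.append((f"P{i}", "patient", rng.uniform(20, 60),
                         "M" if i % 2 else "F", "L"))
        cohort = pd.DataFrame(rows, columns=["id", "group", "age", "sex",
                                             "side"])
        ids = [f"P{i}" for i in range(8)]
        chosen = match_controls(cohort, ids, seed=1)
        assert len(chosen) == 8 and len(set(chosen)) == 8
        # same sex composition as the patient group
        sexes = cohort.set_index("id").loc[chosen, "sex"].value_counts()
        assert sexes["M"] == 4 and sexes["F"] == 4

    def test_overlap_between_subgroups(self):
        rng = np.random.default_rng(7)
        rows = [(f"C{i}", "control", rng.uniform(20, 60),
                 "M" if i % 2 else "F", "none") for i in range(12)]
        rows += [(f"P{i}", "patient", rng.uniform(20, 60),
                  "M" if i % 2 else "F", "L") for i in range(10)]
        cohort = pd.DataFrame(rows, columns=["id", "group", "age", "sex",
                                             "side"])
        g1 = match_controls(cohort, [f"P{i}" for i in range(6)], seed=3)
        g2 = match_controls(cohort, [f"P{i}" for i in range(3, 10)], seed=3)
        assert set(g1) & set(g2)
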