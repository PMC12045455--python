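import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from xenotrack import longitudinal as lg
from xenotrack.io import EmptySampleError

from conftest import make_sample, random_sample


class TestClonality:
    def test_uniform_repertoire_is_maximally_diverse(self):
        s = make_sample({f"C{i:03d}": 0.01 for i in range(100)})
        assert abs(lg.clonality(s)) < 1e-12

    def test_single_clone_is_one_by_convention(self):
        assert lg.clonality(make_sample({"A": 1.0})) == 1.0

    def test_two_clone_value_matches_hand_entropy(self):
        # H = -(0.9 ln 0.9 + 0.1 ln 0.1), R = 2
        h = -(0.9 * np.log(0.9) + 0.1 * np.log(0.1))
        expected = 1 - h / np.log(2)
        s = make_sample({"A": 0.9, "B": 0.1})
        assert abs(lg.clonality(s) - expected) < 1e-12
        assert abs(expected - 0.5310044064107189) < 1e-15

    def test_invariant_under_relabeling(self):
        rng = np.random.default_rng(5)
        s = random_sample(rng, 50, 5000, length=6)
        relabeled = s.with_clones(
            s.clones.assign(cdr3_nt=[f"R{i}" for i in range(len(s.clones))])
        )
        assert lg.clonality(s) == lg.clonality(relabeled)

    def test_bounds_on_random_repertoires(self):
        for seed in range(10):
            s = random_sample(np.random.default_rng(seed), 80, 4000, length=6)
            assert 0.0 <= lg.clonality(s) <= 1.0
            assert 0.0 < lg.r20(s) <= 1.0


class TestR20:
    def test_uniform_100_is_exactly_point_two(self):
        s = make_sample({f"C{i:03d}": 0.01 for i in range(100)})
        assert lg.r20(s) == 0.20

    def test_dominant_clone_reaches_threshold_alone(self):
        s = make_sample({"A": 0.5, "B": 0.3, "C": 0.2})
        assert lg.r20(s) == pytest.approx(1 / 3)

    def test_single_clone(self):
        assert lg.r20(make_sample({"A": 1.0})) == 1.0


class TestHyperexpanded:
    def test_no_clone_above_threshold(self):
        s = make_sample({f"C{i:03d}": 0.005 for i in range(200)})
        assert lg.hyperexpanded_fraction(s) == {"clone_count": 0, "template_fraction": 0.0}

    def test_strict_inequality_excludes_exactly_one_percent(self):
        freqs = {"BIG": 0.05, "MID": 0.02}
        freqs.update({f"C{i:02d}": 0.01 for i in range(93)})
        s = make_sample(freqs)
        res = lg.hyperexpanded_fraction(s)
        assert res["clone_count"] == 2
        assert res["template_fraction"] == pytest.approx(0.07)

    def test_monoclonal(self):
        res = lg.hyperexpanded_fraction(make_sample({"A": 1.0}))
        assert res == {"clone_count": 1, "template_fraction": 1.0}

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            lg.hyperexpanded_fraction(make_sample({"A": 1.0}), threshold=0.0)


class TestFisher:
    def test_identical_tables_give_p_one(self):
        s = make_sample({"A": 0.5, "B": 0.3, "C": 0.2})
        assert lg.fisher_hyperexpanded(s, s).pvalue == 1.0

    def test_matches_direct_hypergeometric_sum(self):
        """p for [[5,95],[0,100]] equals exhaustive enumeration of
        hypergeometric outcomes at least as extreme."""
        # 5 clones above the threshold, 95 below; baseline of 100 even
        # clones sits below an off-knife-edge threshold of 1.01%
        freqs = {f"H{i}": 0.02 for i in range(5)}
        freqs.update({f"S{i:02d}": 0.9 / 95 for i in range(95)})
        sample = make_sample(freqs, total=190000)
        base = make_sample({f"B{i:03d}": 0.01 for i in range(100)})
        res = lg.fisher_hyperexpanded(sample, base, threshold=0.0101)
        # oracle: two-sided Fisher by direct pmf summation
        n1, n2, k = 100, 100, 5
        pmf = [sps.hypergeom.pmf(x, n1 + n2, k, n1) for x in range(k + 1)]
        p_obs = pmf[5]
        expected = sum(p for p in pmf if p <= p_obs * (1 + 1e-9))
        assert res.pvalue == pytest.approx(expected, rel=1e-9)

    def test_row_swap_symmetry(self):
        a = make_sample({"A": 0.05, **{f"C{i:02d}": 0.95 / 95 for i in range(95)}},
                        total=190000)
        b = make_sample({f"B{i:03d}": 0.01 for i in range(100)})
        assert lg.fisher_hyperexpanded(a, b).pvalue == pytest.approx(
            lg.fisher_hyperexpanded(b, a).pvalue
        )

    def test_degenerate_margin_warns_p_one(self):
        a = make_sample({f"C{i}": 0.005 for i in range(200)})
        with pytest.warns(UserWarning, match="zero margin"):
            assert lg.fisher_hyperexpanded(a, a).pvalue == 1.0


class TestSubsetNormalize:
    def test_unit_fraction_is_identity(self):
        s = make_sample({"A": 0.6, "B": 0.4})
        out = lg.subset_normalize(s, 1.0)
        pd.testing.assert_frame_equal(out.clones, s.clones)

    def test_division_by_subset_fraction(self):
        s = make_sample({"A": 0.01, "B": 0.99})
        out = lg.subset_normalize(s, 0.5)
        assert out.clones.set_index("cdr3_nt").loc["A", "frequency"] == pytest.approx(0.02)

    def test_linearity_of_cumulative_frequency(self):
        s = make_sample({"A": 0.05, "B": 0.04, "C": 0.03, "D": 0.02, "E": 0.86})
        out = lg.subset_normalize(s, 0.4)
        raw = lg.cumulative_frequency({"A", "B", "C"}, s)
        assert lg.cumulative_frequency({"A", "B", "C"}, out) == pytest.approx(raw / 0.4)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            lg.subset_normalize(make_sample({"A": 1.0}), 0.0)


class TestCumulativeAndFold:
    def test_empty_and_full_sets(self):
        s = make_sample({"A": 0.6, "B": 0.4})
        assert lg.cumulative_frequency(set(), s) == 0.0
        assert lg.cumulative_frequency({"A", "B"}, s) == pytest.approx(1.0)

    def test_random_subset_matches_brute_force(self):
        rng = np.random.default_rng(17)
        s = random_sample(rng, 300, 20000, length=8)
        keys = set(rng.choice(s.clones["cdr3_nt"], size=100, replace=False))
        brute = sum(
            f for k, f in zip(s.clones["cdr3_nt"], s.clones["frequency"]) if k in keys
        )
        assert lg.cumulative_frequency(keys, s) == pytest.approx(brute)

    def test_fold_change_identity_and_eleven_fold(self):
        pre = make_sample({"R": 0.02, "F": 0.98})
        post = make_sample({"R": 0.22, "F": 0.78})
        assert lg.fold_change({"R"}, pre, pre) == 1.0
        assert lg.fold_change({"R"}, post, pre) == pytest.approx(11.0)
        assert lg.fold_change({"GONE"}, post, pre) in (0.0, np.nan) or np.isnan(
            lg.fold_change({"GONE"}, post, pre)
        )

    def test_fold_change_absent_post_is_zero(self):
        pre = make_sample({"R": 0.02, "F": 0.98})
        post = make_sample({"F": 1.0})
        assert lg.fold_change({"R"}, post, pre) == 0.0


class TestRelativeDetection:
    def test_identical_dynamics_give_one(self):
        pre = make_sample({"R": 0.1, "N": 0.1, "F": 0.8})
        post = make_sample({"R": 0.2, "N": 0.2, "F": 0.6})
        for level in ("clonal", "template"):
            assert lg.relative_detection({"R"}, {"N"}, post, pre, level) == pytest.approx(1.0)

    def test_template_level_matches_ratio_of_folds(self):
        """Reactive fold 11 against non-reactive fold 0.07 gives 157.14."""
        pre = make_sample({"R": 0.02, "N": 0.90, "F": 0.08})
        post = make_sample({"R": 0.22, "N": 0.063, "F": 0.717})
        val = lg.relative_detection({"R"}, {"N"}, post, pre, "template")
        assert val == pytest.approx(11.0 / 0.07, rel=1e-9)
        assert val == pytest.approx(157.142857, rel=1e-6)

    def test_zero_nonreactive_fold_flags_infinite(self):
        pre = make_sample({"R": 0.02, "N": 0.90, "F": 0.08})
        post = make_sample({"R": 0.22, "F": 0.78})
        with pytest.warns(UserWarning, match="nonreactive"):
            assert np.isinf(lg.relative_detection({"R"}, {"N"}, post, pre, "template"))


class TestTwoProportionZ:
    def test_equal_proportions(self):
        res = lg.two_proportion_z(30, 100, 30, 100)
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_matches_pooled_formula(self):
        x1, n1, x2, n2 = 30, 100, 10, 100
        p_pool = (x1 + x2) / (n1 + n2)
        z_hand = (x1 / n1 - x2 / n2) / np.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
        p_hand = 2 * sps.norm.sf(abs(z_hand))
        res = lg.two_proportion_z(x1, n1, x2, n2)
        assert res.statistic == pytest.approx(z_hand, rel=1e-12)
        assert res.pvalue == pytest.approx(p_hand, rel=1e-12)

    def test_swap_flips_sign_keeps_p(self):
        a = lg.two_proportion_z(30, 100, 10, 100)
        b = lg.two_proportion_z(10, 100, 30, 100)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.pvalue == pytest.approx(b.pvalue)

    def test_zero_sample_size_rejected(self):
        with pytest.raises(ValueError):
            lg.two_proportion_z(1, 0, 1, 10)


class TestConvergence:
    def test_one_nt_per_aa(self):
        s = make_sample({"TGTAAA": 0.5, "TGTCCC": 0.5})
        assert lg.convergence_ratio(s) == 1.0

    def test_group_sizes_three_and_one(self):
        s = make_sample({"A1": 0.3, "A2": 0.2, "A3": 0.1, "B1": 0.4})
        s.clones.loc[s.clones["cdr3_nt"].str.startswith("A"), "cdr3_aa"] = "CAAF"
        s.clones.loc[s.clones["cdr3_nt"] == "B1", "cdr3_aa"] = "CBBF"
        assert lg.convergence_ratio(s) == 2.0

    def test_empty_restriction_is_error(self):
        s = make_sample({"TGTAAA": 1.0})
        with pytest.raises(EmptySampleError):
            lg.convergence_ratio(s, keys={"ZZZ"}, key_mode="aa")


class TestTopClones:
    def test_n_larger_than_repertoire(self):
        s = make_sample({"A": 0.5, "B": 0.3, "C": 0.2})
        assert len(lg.top_clones(s, 10)) == 3

    def test_zero_n(self):
        assert lg.top_clones(make_sample({"A": 1.0}), 0).empty

    def test_matches_brute_force_sort(self):
        rng = np.random.default_rng(19)
        s = random_sample(rng, 200, 10000, length=8)
        top = lg.top_clones(s, 5)
        brute = s.clones.sort_values(
            ["frequency", "cdr3_nt"], ascending=[False, True]
        ).head(5)
        assert list(top["cdr3_nt"]) == list(brute["cdr3_nt"])


class TestOverlapMatrix:
    def test_disjoint_and_identical(self):
        a = make_sample({"A": 0.5, "B": 0.5})
        b = make_sample({"C": 0.5, "D": 0.5}, timepoint="POD14")
        m = lg.overlap_cumfreq_matrix([a, b])
        assert m.iloc[0, 1] == 0.0 and m.iloc[1, 0] == 0.0
        assert m.iloc[0, 0] == m.iloc[1, 1] == 1.0
        m2 = lg.overlap_cumfreq_matrix([a, a])
        assert (m2.to_numpy() == 1.0).all()

    def test_toy_triple_against_brute_force(self):
        a = make_sample({"x": 0.5, "y": 0.3, "z": 0.2})
        b = make_sample({"y": 0.6, "z": 0.4}, timepoint="POD14")
        c = make_sample({"z": 1.0}, timepoint="POD28")
        m = lg.overlap_cumfreq_matrix([a, b, c])
        assert m.iloc[0, 1] == pytest.approx(0.5)  # y+z within a
        assert m.iloc[0, 2] == pytest.approx(0.2)  # z within a
        assert m.iloc[1, 2] == pytest.approx(0.4)  # z within b
        assert m.iloc[2, 0] == 1.0  # all of c is in a
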