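"""Distances, eligibility, the regression itself, and the whole-tree scan."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import temposcan as ts
from temposcan.scan import (
    REASON_NONE,
    REASON_TOO_FEW_COMBOS,
    REASON_TOO_FEW_DATES,
    REASON_TOO_FEW_TIPS,
    _bh_adjust,
    all_node_tip_distances,
)
from temposcan.simulate import ClockSimConfig, simulate_clock_tree

from conftest import tree_from_newick


# -- distances ---------------------------------------------------------------


class TestDistances:
    def test_toy_root_and_mrca(self, toy_tree):
        assert ts.node_to_tip_distances(toy_tree, 0) == pytest.approx(
            {"A_2000": 0.15, "B_2001": 0.25, "C_2002": 0.3}
        )
        assert ts.node_to_tip_distances(toy_tree, 1) == pytest.approx(
            {"A_2000": 0.1, "B_2001": 0.2}
        )

    def test_tip_node_rejected(self, toy_tree):
        tip_id = next(
            n.node_id for n in toy_tree.preorder_nodes() if n.is_leaf()
        )
        with pytest.raises(ts.ValidationError, match="tip"):
            ts.node_to_tip_distances(toy_tree, tip_id)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_additivity_against_path_walk_oracle(self, seed):
        """d(node, tip) must equal the brute-force sum of edges walked
        tip -> node, and d(root, tip) = d(root, v) + d(v, tip)."""
        tree, _ = simulate_clock_tree(ClockSimConfig(n_tips=15, seed=seed))
        dist = all_node_tip_distances(tree)

        def walk_up(leaf, ancestor):
            total, node = 0.0, leaf
            while node is not ancestor:
                total += node.edge.length
                node = node.parent_node
            return total

        for node in tree.preorder_nodes():
            if node.is_leaf():
                continue
            for leaf in node.leaf_iter():
                oracle = walk_up(leaf, node)
                assert dist[node.node_id][leaf.taxon.label] == pytest.approx(
                    oracle, rel=1e-12
                )
                root_d = dist[0][leaf.taxon.label]
                via = walk_up(node, tree.root) + oracle if node.node_id else oracle
                assert root_d == pytest.approx(via, rel=1e-12)


# -- eligibility -------------------------------------------------------------


class TestEligibility:
    @pytest.mark.parametrize(
        "dates,dists,expected",
        [
            ([2000, 2001], [0.1, 0.2], (False, REASON_TOO_FEW_TIPS)),
            ([2000, 2000, 2000], [0.1, 0.2, 0.3], (False, REASON_TOO_FEW_DATES)),
            ([2000, 2000, 2001], [0.1, 0.1, 0.2], (False, REASON_TOO_FEW_COMBOS)),
            ([2000, 2000, 2001], [0.1, 0.2, 0.2], (True, REASON_NONE)),
        ],
    )
    def test_truth_table(self, dates, dists, expected):
        assert ts.check_eligibility(dates, dists) == expected

    def test_conditions_checked_in_order(self):
        # two tips with a single date: tip-count failure is reported first
        assert ts.check_eligibility([2000, 2000], [0.1, 0.1]) == (
            False, REASON_TOO_FEW_TIPS,
        )

    def test_length_mismatch(self):
        with pytest.raises(ts.ValidationError, match="length"):
            ts.check_eligibility([2000, 2001], [0.1])

    def test_combo_tolerance_merges_near_identical_pairs(self):
        cfg = ts.ScanConfig(combo_tolerance=1e-6)
        dates = [2000.0, 2000.0 + 1e-9, 2001.0]
        dists = [0.1, 0.1 + 1e-9, 0.2]
        assert ts.check_eligibility(dates, dists, cfg) == (
            False, REASON_TOO_FEW_COMBOS,
        )
        assert ts.check_eligibility(dates, dists)[0] is True  # exact mode


# -- the regression ----------------------------------------------------------


class TestFit:
    def test_hand_worked_example(self):
        """Closed-form OLS on dates [0,1,2,3], distances [0,1,1,2]:
        Sxy=3, Sxx=5, SSE=0.2, SStot=2; p from the df=2 t CDF
        F(t) = 1/2 + t/(2 sqrt(t^2+2))."""
        fit = ts.fit_rtt_regression([0, 1, 2, 3], [0, 1, 1, 2])
        assert fit.slope == pytest.approx(0.6, rel=1e-12)
        assert fit.intercept == pytest.approx(0.1, rel=1e-12)
        assert fit.r2 == pytest.approx(0.9, rel=1e-12)
        assert fit.adj_r2 == pytest.approx(0.85, rel=1e-12)
        assert fit.x_intercept == pytest.approx(-1 / 6, rel=1e-12)
        t = 0.6 / math.sqrt(0.02)
        p_closed = 2 * (1 - (0.5 + t / (2 * math.sqrt(t * t + 2))))
        assert fit.p_value == pytest.approx(p_closed, rel=1e-10)
        assert fit.p_value == pytest.approx(0.0513, abs=5e-5)

    def test_perfect_line(self):
        fit = ts.fit_rtt_regression([2000, 2001, 2002], [0.1, 0.2, 0.3])
        assert fit.slope == pytest.approx(0.1, rel=1e-12)
        assert fit.intercept == pytest.approx(-199.9, rel=1e-12)
        assert fit.adj_r2 == 1.0
        assert fit.p_value == 0.0
        assert fit.x_intercept == pytest.approx(1999, rel=1e-12)

    def test_constant_distances_convention(self):
        fit = ts.fit_rtt_regression([2000, 2001, 2002], [0.2, 0.2, 0.2])
        assert fit.slope == 0.0
        assert fit.p_value == 1.0
        assert fit.r2 == 0.0 and fit.adj_r2 == 0.0
        assert fit.x_intercept is None

    def test_all_dates_equal_is_defensive_error(self):
        with pytest.raises(ts.ValidationError, match="Sxx"):
            ts.fit_rtt_regression([2000, 2000, 2000], [0.1, 0.2, 0.3])

    def test_agrees_with_scipy_linregress(self):
        from scipy.stats import linregress

        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(3, 40))
            x = rng.uniform(1980, 2020, n)
            y = rng.uniform(0, 1, n)
            if len(set(x)) < 2 or np.var(y) == 0:
                continue
            fit = ts.fit_rtt_regression(x, y)
            ref = linregress(x, y)
            assert fit.slope == pytest.approx(ref.slope, rel=1e-10)
            assert fit.intercept == pytest.approx(ref.intercept, rel=1e-10)
            assert fit.p_value == pytest.approx(ref.pvalue, rel=1e-8)
            assert fit.r2 == pytest.approx(ref.rvalue**2, rel=1e-8)


@st.composite
def regression_data(draw):
    n = draw(st.integers(min_value=4, max_value=30))
    xs = draw(
        st.lists(
            st.floats(min_value=1900, max_value=2100), min_size=n, max_size=n,
            unique=True,
        )
    )
    ys = draw(
        st.lists(st.floats(min_value=0, max_value=1), min_size=n, max_size=n)
    )
    return xs, ys


class TestFitInvariances:
    @given(regression_data(), st.floats(min_value=-5, max_value=5))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_distance_offset_only_moves_intercept(self, data, c):
        xs, ys = data
        base = ts.fit_rtt_regression(xs, ys)
        shifted = ts.fit_rtt_regression(xs, [y + c for y in ys])
        assert shifted.slope == pytest.approx(base.slope, rel=1e-10, abs=1e-12)
        assert shifted.p_value == pytest.approx(base.p_value, rel=1e-9, abs=1e-12)
        assert shifted.adj_r2 == pytest.approx(base.adj_r2, rel=1e-9, abs=1e-12)
        assert shifted.intercept == pytest.approx(
            base.intercept + c, rel=1e-9, abs=1e-9
        )

    @given(regression_data(), st.floats(min_value=-1000, max_value=1000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_date_shift_moves_x_intercept(self, data, delta):
        xs, ys = data
        base = ts.fit_rtt_regression(xs, ys)
        shifted = ts.fit_rtt_regression([x + delta for x in xs], ys)
        assert shifted.slope == pytest.approx(base.slope, rel=1e-9, abs=1e-12)
        assert shifted.p_value == pytest.approx(base.p_value, rel=1e-8, abs=1e-12)
        assert shifted.adj_r2 == pytest.approx(base.adj_r2, rel=1e-8, abs=1e-10)
        if base.x_intercept is not None:
            assert shifted.x_intercept == pytest.approx(
                base.x_intercept + delta, rel=1e-8, abs=1e-6
            )

    @given(regression_data(), st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_distance_scaling_scales_slope(self, data, s):
        xs, ys = data
        base = ts.fit_rtt_regression(xs, ys)
        scaled = ts.fit_rtt_regression(xs, [y * s for y in ys])
        assert scaled.slope == pytest.approx(base.slope * s, rel=1e-10, abs=1e-15)
        assert scaled.intercept == pytest.approx(
            base.intercept * s, rel=1e-9, abs=1e-12
        )
        assert scaled.p_value == pytest.approx(base.p_value, rel=1e-9, abs=1e-12)
        assert scaled.adj_r2 == pytest.approx(base.adj_r2, rel=1e-9, abs=1e-12)


# -- whole-tree scan ---------------------------------------------------------


class TestScanTree:
    def test_toy_tree_one_eligible_node(self, toy_tree):
        res = ts.scan_tree(toy_tree)
        assert len(res.reports) == 2  # root + cherry
        root = res.report_for(0)
        cherry = res.report_for(1)
        assert cherry.eligible is False
        assert cherry.ineligibility_reason == REASON_TOO_FEW_TIPS
        assert root.eligible
        # distances {0.15, 0.25, 0.30} vs dates 2000..2002
        assert root.fit.slope == pytest.approx(0.075, rel=1e-12)
        assert root.fit.r2 == pytest.approx(27 / 28, rel=1e-9)
        # n=3 leaves 1 df: p ~ 0.12, so no signal at alpha=0.05
        assert root.fit.p_value == pytest.approx(0.1210377, abs=1e-6)
        assert not root.significant

    def test_perfect_root_is_significant(self, perfect_tree):
        res = ts.scan_tree(perfect_tree)
        root = res.report_for(0)
        assert root.significant
        assert root.fit.adj_r2 == 1.0 and root.fit.p_value == 0.0
        assert root.fit.slope == pytest.approx(0.1, rel=1e-12)

    def test_noise_free_simulation_every_eligible_node_perfect(self):
        tree, truth = simulate_clock_tree(ClockSimConfig(n_tips=16, seed=5))
        res = ts.scan_tree(tree)
        eligible = [r for r in res.reports if r.eligible]
        assert eligible, "simulation should produce eligible nodes"
        for rep in eligible:
            assert rep.fit.adj_r2 == 1.0
            assert rep.fit.p_value == 0.0
            assert rep.significant
            assert rep.fit.slope == pytest.approx(1e-3, rel=1e-9)
            assert rep.fit.x_intercept == pytest.approx(
                truth["node_dates"][rep.node_id], rel=1e-9
            )

    def test_child_order_invariance(self, tmp_path, toy_tree):
        flipped = tree_from_newick(
            tmp_path, "(C_2002:0.3,(B_2001:0.2,A_2000:0.1):0.05);"
        )
        res_a = ts.scan_tree(toy_tree)
        res_b = ts.scan_tree(flipped)

        def by_tipset(tree, res):
            return {
                frozenset(tree.descendant_tip_labels(r.node_id)): r
                for r in res.reports
            }

        map_a, map_b = by_tipset(toy_tree, res_a), by_tipset(flipped, res_b)
        assert map_a.keys() == map_b.keys()
        for key in map_a:
            ra, rb = map_a[key], map_b[key]
            assert ra.eligible == rb.eligible
            if ra.eligible:
                assert ra.fit.slope == pytest.approx(rb.fit.slope, rel=1e-12)
                assert ra.fit.p_value == pytest.approx(rb.fit.p_value, rel=1e-12)

    def test_clade_locality_under_grafting(self, tmp_path):
        """A clade's statistics depend only on its own (date, distance)
        pairs, so grafting it onto a different background changes nothing."""
        clade = "(X_2001:0.011,(Y_2005:0.014,Z_2009:0.019):0.004)"
        bg1 = f"({clade}:0.02,(P_1990:0.3,Q_1991:0.31):0.1);"
        bg2 = f"((P_1990:0.002,({clade}:0.5,Q_1991:0.001):0.004):0.9,R_1980:0.2);"
        t1 = tree_from_newick(tmp_path, bg1)
        t2 = tree_from_newick(tmp_path, bg2)
        key = frozenset({"X_2001", "Y_2005", "Z_2009"})

        def clade_report(tree):
            res = ts.scan_tree(tree)
            for r in res.reports:
                if frozenset(tree.descendant_tip_labels(r.node_id)) == key:
                    return r
            raise AssertionError("clade node not found")

        r1, r2 = clade_report(t1), clade_report(t2)
        assert r1.fit.slope == pytest.approx(r2.fit.slope, rel=1e-12)
        assert r1.fit.intercept == pytest.approx(r2.fit.intercept, rel=1e-12)
        assert r1.fit.p_value == pytest.approx(r2.fit.p_value, rel=1e-12)
        assert r1.fit.x_intercept == pytest.approx(r2.fit.x_intercept, rel=1e-12)
        assert r1.significant == r2.significant

    def test_under_three_tips_rejected(self, tmp_path):
        t = tree_from_newick(tmp_path, "(A_2000:0.1,B_2001:0.2);")
        with pytest.raises(ts.ValidationError, match="at least 3"):
            ts.scan_tree(t)

    def test_undated_tree_rejected(self, toy_tree_path):
        t = ts.read_tree(toy_tree_path)
        with pytest.raises(ts.ValidationError, match="dates"):
            ts.scan_tree(t)

    def test_one_sided_halves_positive_slope_p(self, toy_tree):
        two = ts.scan_tree(toy_tree, ts.ScanConfig()).report_for(0)
        one = ts.scan_tree(
            toy_tree, ts.ScanConfig(one_sided=True, alpha=0.07)
        ).report_for(0)
        # p two-sided ~0.121; one-sided decision uses p/2 ~0.060 <= 0.07
        assert one.significant
        assert not two.significant

    def test_bh_adjustment_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        pvals = list(rng.uniform(0, 1, 25))
        ours = _bh_adjust(pvals)
        _, ref, _, _ = multipletests(pvals, method="fdr_bh")
        assert ours == pytest.approx(list(ref), rel=1e-12)

    def test_bh_flags_are_subset_of_uncorrected(self):
        tree, _ = simulate_clock_tree(
            ClockSimConfig(n_tips=30, noise=("gaussian", 0.5), seed=9)
        )
        plain = ts.scan_tree(tree, ts.ScanConfig())
        bh = ts.scan_tree(tree, ts.ScanConfig(correction="benjamini-hochberg"))
        sig_plain = {r.node_id for r in plain.significant_reports()}
        sig_bh = {r.node_id for r in bh.significant_reports()}
        assert sig_bh <= sig_plain
        for r in bh.reports:
            if r.eligible:
                assert r.p_adjusted is not None
                assert r.p_adjusted >= r.fit.p_value - 1e-15

    def test_config_validation(self):
        with pytest.raises(ts.ValidationError):
            ts.ScanConfig(alpha=1.5)
        with pytest.raises(ts.ValidationError):
            ts.ScanConfig(min_tips=2)
        with pytest.raises(ts.ValidationError):
            ts.ScanConfig(correction="bonferroni")


# -- outliers ----------------------------------------------------------------


class TestResidualOutliers:
    def test_perfect_line_has_none(self):
        dates = [0, 1, 2, 3, 4]
        dists = [0.0, 0.1, 0.2, 0.3, 0.4]
        fit = ts.fit_rtt_regression(dates, dists)
        assert ts.residual_outliers(fit, dates, dists, list("abcde")) == []

    def test_gross_outlier_flagged_at_default_k(self):
        dates = [0, 1, 2, 3, 4]
        dists = [0.0, 0.1, 0.2, 0.3, 5.0]
        fit = ts.fit_rtt_regression(dates, dists)
        out = ts.residual_outliers(fit, dates, dists, list("abcde"), k=3.0)
        assert out == ["e"]

    def test_relabeling_invariance(self):
        dates = [0, 1, 2, 3, 4]
        dists = [0.0, 0.1, 0.2, 0.3, 5.0]
        fit = ts.fit_rtt_regression(dates, dists)
        a = ts.residual_outliers(fit, dates, dists, list("abcde"), k=3.0)
        b = ts.residual_outliers(fit, dates, dists, list("edcba"), k=3.0)
        assert a == ["e"] and b == ["a"]

    def test_small_n_warns_and_returns_empty(self):
        dates, dists = [0, 1, 2], [0.0, 0.2, 0.1]
        fit = ts.fit_rtt_regression(dates, dists)
        with pytest.warns(UserWarning, match="at least 4"):
            assert ts.residual_outliers(fit, dates, dists, list("abc")) == []
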