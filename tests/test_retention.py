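import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from washout.abundance import to_relative
from washout.retention import (
    RetentionSeries,
    assign_phase,
    pearson_trend,
    retention_ratio,
    retention_series,
    significance_stars,
    signed_rank_test,
    summarize_boxplot,
    wilcoxon_vs_one,
)
from washout.tables_io import CountTable, build_paired_index


def _series(days, ratios, phases=None):
    pts = pd.DataFrame(
        {
            "day": days,
            "ratio": ratios,
            "reason": [None if not math.isnan(r) else "zero_effluent" for r in ratios],
            "phase": phases or [assign_phase(d) for d in days],
        }
    )
    return RetentionSeries("g__Test", "R1", pts)


class TestAssignPhase:
    @pytest.mark.parametrize("day,expected", [(0, "startup"), (42, "startup"), (43, "steady"), (84, "steady")])
    def test_week_boundary(self, day, expected):
        assert assign_phase(day) == expected

    def test_configurable_boundary(self):
        assert assign_phase(50, startup_end_day=56) == "startup"

    def test_negative_day_rejected(self):
        with pytest.raises(ValueError):
            assign_phase(-1)


class TestRetentionRatio:
    def test_arithmetic(self):
        ratio, reason = retention_ratio(0.10, 0.05)
        assert ratio == pytest.approx(2.0) and reason is None

    def test_equal_abundances_give_one(self):
        for x in (0.001, 0.25, 1.0):
            assert retention_ratio(x, x)[0] == pytest.approx(1.0)

    def test_zero_effluent_flagged(self):
        ratio, reason = retention_ratio(0.02, 0.0)
        assert math.isnan(ratio) and reason == "zero_effluent"

    def test_zero_both_flagged(self):
        ratio, reason = retention_ratio(0.0, 0.0)
        assert math.isnan(ratio) and reason == "zero_both"

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            retention_ratio(1.2, 0.5)
        with pytest.raises(ValueError):
            retention_ratio(0.5, -0.1)


class TestRetentionSeries:
    def test_undefined_points_bookkeeping(self, small_meta):
        counts = pd.DataFrame(
            {
                "R1R_d10": [5, 95],
                "R1E_d10": [0, 100],
                "R2R_d10": [10, 90],
                "R2E_d10": [10, 90],
            },
            index=["g__A", "g__B"],
            dtype=np.int64,
        )
        ra = to_relative(CountTable(counts))
        pairs = build_paired_index(small_meta)
        series = {(s.taxon, s.reactor): s for s in retention_series(ra, pairs, ["g__A", "g__B"])}
        s = series[("g__A", "R1")]
        assert s.n_defined == 0 and s.n_undefined == 1
        assert s.points["reason"].iloc[0] == "zero_effluent"
        assert series[("g__A", "R2")].points["ratio"].iloc[0] == pytest.approx(1.0)

    def test_missing_taxon_listed_in_error(self, small_counts, small_meta):
        ra = to_relative(small_counts)
        pairs = build_paired_index(small_meta)
        with pytest.raises(KeyError, match="g__Nope"):
            retention_series(ra, pairs, ["g__Nope"])

    def test_two_taxon_closure(self, small_meta):
        # with exactly two taxa, one enriched in the granules forces the
        # other depleted: ratio_A > 1 <=> ratio_B < 1 at the same pair
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.integers(1, 1000, size=(2, 4)),
            index=["g__A", "g__B"],
            columns=small_meta["sample_id"],
            dtype=np.int64,
        )
        ra = to_relative(CountTable(counts))
        series = {
            (s.taxon, s.reactor): s
            for s in retention_series(ra, build_paired_index(small_meta), ["g__A", "g__B"])
        }
        for reactor in ("R1", "R2"):
            ra_a = series[("g__A", reactor)].points["ratio"].iloc[0]
            ra_b = series[("g__B", reactor)].points["ratio"].iloc[0]
            if ra_a != 1.0:
                assert (ra_a > 1.0) == (ra_b < 1.0)

    def test_ratios_invariant_to_effluent_library_size(self, small_counts, small_meta):
        pairs = build_paired_index(small_meta)
        base = retention_series(to_relative(small_counts), pairs, small_counts.taxa)
        scaled_counts = small_counts.data.copy()
        for col in ("R1E_d10", "R2E_d10"):
            scaled_counts[col] *= 7
        scaled = retention_series(to_relative(CountTable(scaled_counts)), pairs, small_counts.taxa)
        for s0, s1 in zip(base, scaled):
            np.testing.assert_allclose(s0.points["ratio"], s1.points["ratio"], rtol=1e-12)

    def test_effluent_weighted_ratios_conserve_unity(self, single_reactor_output):
        # sum_i effluent_ra_i * ratio_i = sum_i granular_ra_i = 1 on a full table
        out = single_reactor_output
        counts = CountTable(pd.concat([out.granular.data, out.effluent.data], axis=1))
        ra = to_relative(counts)
        pairs = build_paired_index(out.metadata)
        for p in pairs.pairs:
            g = ra.data[p.granular].to_numpy()
            e = ra.data[p.effluent].to_numpy()
            defined = e > 0
            total = (e[defined] * (g[defined] / e[defined])).sum() + g[~defined].sum()
            assert total == pytest.approx(1.0, abs=1e-12)


class TestPearsonTrend:
    def test_perfect_linear_relation(self):
        res = pearson_trend(_series([1, 2, 3], [1.0, 2.0, 3.0]))
        assert res.r == pytest.approx(1.0)

    def test_constant_ratio_not_computable(self):
        res = pearson_trend(_series([1, 2, 3], [2.0, 2.0, 2.0]))
        assert res.not_computable == "constant"

    def test_too_few_points_not_computable(self):
        res = pearson_trend(_series([1, 2], [1.0, 2.0]))
        assert res.not_computable == "too_few_points"

    def test_against_definitional_oracle(self):
        """r from covariance/sd products; p via the exact t CDF on n-2 dof."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(4, 14)
            days = np.sort(rng.choice(np.arange(1, 90), size=n, replace=False))
            ratios = np.exp(rng.normal(0, 0.5, size=n))
            res = pearson_trend(_series(days.tolist(), ratios.tolist()))
            x, y = days.astype(float), ratios
            r_oracle = ((x - x.mean()) * (y - y.mean())).sum() / math.sqrt(
                ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
            )
            t = r_oracle * math.sqrt((n - 2) / (1 - r_oracle**2))
            p_oracle = 2 * stats.t.sf(abs(t), df=n - 2)
            assert res.r == pytest.approx(r_oracle, abs=1e-12)
            assert res.p_value == pytest.approx(p_oracle, rel=1e-9)


class TestSignificanceStars:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (0.0007, "***"),
            (0.0008, "***"),
            (0.001, "**"),
            (0.009, "**"),
            (0.0099, "**"),
            (0.049, "*"),
            (0.05, "•"),
            (0.0999, "•"),
            (0.1, ""),
            (0.5, ""),
            (1.0, ""),
        ],
    )
    def test_strict_cutoffs(self, p, expected):
        assert significance_stars(p) == expected

    @pytest.mark.parametrize("p", [0.0, -0.1, 1.5])
    def test_out_of_range_rejected(self, p):
        with pytest.raises(ValueError):
            significance_stars(p)


class TestWilcoxonVsOne:
    def test_all_ratios_above_one_exact_p(self):
        s = _series([45, 52, 59, 66, 73, 80], [2.1, 1.8, 2.5, 1.9, 2.2, 2.0])
        res = wilcoxon_vs_one(s, "steady")
        assert res.wilcoxon_statistic == 0.0  # negative-rank sum
        assert res.p_value == pytest.approx(2 * (1 / 2**6))
        assert res.direction == "above_1"

    def test_all_ratios_exactly_one_degenerate(self):
        s = _series([45, 52, 59], [1.0, 1.0, 1.0])
        res = wilcoxon_vs_one(s, "steady")
        assert res.not_computable == "degenerate"

    def test_reciprocal_pair_is_asymmetric_on_raw_scale(self):
        # |0.5 - 1| < |2.0 - 1|: the raw-scale test is not symmetric for
        # reciprocal ratios, so the statistic is nonzero and p = 1
        s = _series([45, 52], [0.5, 2.0])
        res = wilcoxon_vs_one(s, "steady")
        assert res.wilcoxon_statistic == 1.0
        assert res.p_value == pytest.approx(1.0)
        # on the log scale the same data are perfectly symmetric: the two
        # |log-ratios| tie at midrank 1.5 and W+ = W-
        res_log = wilcoxon_vs_one(s, "steady", log_scale=True)
        assert res_log.wilcoxon_statistic == pytest.approx(1.5)
        assert res_log.p_value == pytest.approx(1.0)

    def test_no_defined_points(self):
        s = _series([45], [math.nan])
        res = wilcoxon_vs_one(s, "steady")
        assert res.not_computable == "no_defined_points"

    def test_exact_p_matches_full_sign_enumeration(self):
        """DP rank-sum null distribution == literal 2^n enumeration, n <= 10."""
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = int(rng.integers(1, 11))
            vals = np.round(np.exp(rng.normal(0, 0.6, size=n)), 2)
            vals = vals[vals != 1.0]
            if vals.size == 0:
                continue
            stat, p, n_used, reason = signed_rank_test(vals, 1.0)
            assert reason is None
            d = vals - 1.0
            ranks = stats.rankdata(np.abs(d))
            w_obs = ranks[d > 0].sum()
            dist = [sum(r for r, s in zip(ranks, signs) if s > 0)
                    for signs in itertools.product((-1, 1), repeat=n_used)]
            dist = np.asarray(dist)
            p_le = (dist <= w_obs + 1e-12).mean()
            p_ge = (dist >= w_obs - 1e-12).mean()
            p_oracle = min(1.0, 2 * min(p_le, p_ge))
            assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_matches_scipy_on_tie_free_input(self):
        rng = np.random.default_rng(9)
        vals = 1.0 + rng.normal(0.3, 0.4, size=12)
        vals = vals[vals != 1.0]
        stat, p, n, reason = signed_rank_test(vals, 1.0, mode="exact")
        ref = stats.wilcoxon(vals - 1.0, alternative="two-sided", method="exact")
        assert p == pytest.approx(ref.pvalue, abs=1e-12)
        assert stat == pytest.approx(ref.statistic)

    def test_normal_approximation_large_n(self):
        rng = np.random.default_rng(11)
        vals = np.exp(rng.normal(0.2, 0.3, size=40))
        stat, p, n, reason = signed_rank_test(vals, 1.0, mode="normal")
        ref = stats.wilcoxon(vals - 1.0, alternative="two-sided", method="approx", correction=False)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)


class TestBoxplotSummary:
    def test_outlier_beyond_whisker(self):
        s = _series([1, 2, 3, 4, 5], [1.0, 2.0, 3.0, 4.0, 100.0], phases=["steady"] * 5)
        box = summarize_boxplot(s, "steady")
        assert (box.q1, box.median, box.q3) == (2.0, 3.0, 4.0)
        assert box.whisker_high == 4.0
        assert box.outliers == (100.0,)

    def test_single_value_collapses(self):
        s = _series([45], [1.7])
        box = summarize_boxplot(s, "steady")
        assert box.median == box.q1 == box.q3 == box.whisker_low == box.whisker_high == 1.7
        assert box.outliers == ()

    def test_symmetric_data_centers_median(self):
        s = _series([1, 2, 3, 4, 5], [1.0, 2.0, 3.0, 4.0, 5.0], phases=["steady"] * 5)
        box = summarize_boxplot(s, "steady")
        assert box.median - box.q1 == pytest.approx(box.q3 - box.median)
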