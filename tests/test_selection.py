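"""ANOVA against reference implementations, Tukey homogeneous subsets against
an exhaustive all-pairs oracle, and the minimal-cardinality optimum rule."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import semgforce as sf
from semgforce.selection import SubsetGrouping, optimal_per_fixed


def all_pairs_subset_oracle(groups, alpha, higher_is_better=False):
    """Maximal sets of levels that are mutually non-significant under the
    pairwise Tukey HSD studentized-range test (balanced n)."""
    names = list(groups)
    k = len(names)
    means = {g: np.mean(groups[g]) for g in names}
    n = len(next(iter(groups.values())))
    df_w = sum(len(v) for v in groups.values()) - k
    ms_w = sum(((np.asarray(v) - np.mean(v)) ** 2).sum() for v in groups.values()) / df_w
    q_crit = stats.studentized_range.ppf(1 - alpha, k, df_w)
    se = np.sqrt(ms_w / n)

    def nonsig(a, b):
        return abs(means[a] - means[b]) / se <= q_crit

    feasible = []
    for r in range(1, k + 1):
        for combo in itertools.combinations(names, r):
            if all(nonsig(a, b) for a, b in itertools.combinations(combo, 2)):
                feasible.append(set(combo))
    maximal = [s for s in feasible if not any(s < t for t in feasible)]
    # order best-first by the subset's best mean
    sign = -1 if higher_is_better else 1
    maximal.sort(key=lambda s: min(sign * means[g] for g in s))
    return [set(s) for s in maximal]


class TestOneWayAnova:
    def test_matches_scipy_on_random_grouped_data(self, rng):
        for _ in range(100):
            k = int(rng.integers(2, 8))
            n = int(rng.integers(3, 12))
            groups = {
                f"L{i}": rng.normal(loc=rng.normal(), size=n) for i in range(k)
            }
            res = sf.one_way_anova(groups)
            ref = stats.f_oneway(*groups.values())
            assert res.f_statistic == pytest.approx(ref.statistic, rel=1e-8)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-8)

    def test_zero_within_variance_distinct_means(self):
        res = sf.one_way_anova({"a": [1.0, 1.0, 1.0], "b": [2.0, 2.0, 2.0]})
        assert np.isinf(res.f_statistic)
        assert res.p_value == 0.0

    def test_all_observations_equal(self):
        res = sf.one_way_anova({"a": [3.0, 3.0], "b": [3.0, 3.0]})
        assert res.f_statistic == 0.0
        assert res.p_value == 1.0

    def test_underreplicated_level_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            sf.one_way_anova({"a": [1.0], "b": [1.0, 2.0]})
        with pytest.raises(ValueError, match="levels"):
            sf.one_way_anova({"a": [1.0, 2.0]})


class TestTwoWayAnova:
    @staticmethod
    def factorial(rng, a=4, b=3, n=5, fa=0.0, fb=0.0, fab=0.0, noise=1.0):
        rows = []
        ea = rng.normal(scale=fa, size=a)
        eb = rng.normal(scale=fb, size=b)
        eab = rng.normal(scale=fab, size=(a, b))
        for i in range(a):
            for j in range(b):
                for r in range(n):
                    rows.append(
                        {
                            "mps": f"M{i}",
                            "fs": f"F{j}",
                            "repeat": r,
                            "nrms": ea[i] + eb[j] + eab[i, j]
                            + rng.normal(scale=noise),
                        }
                    )
        return pd.DataFrame(rows)

    def test_matches_statsmodels_reference(self, rng):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        df = self.factorial(rng, fa=1.0, fb=0.5, fab=0.5)
        res = sf.two_way_anova(df, "nrms")
        fitted = ols("nrms ~ C(mps) * C(fs)", data=df).fit()
        ref = sm.stats.anova_lm(fitted, typ=2)
        assert res["mps"]["F"] == pytest.approx(ref.loc["C(mps)", "F"], rel=1e-8)
        assert res["fs"]["F"] == pytest.approx(ref.loc["C(fs)", "F"], rel=1e-8)
        assert res["interaction"]["F"] == pytest.approx(
            ref.loc["C(mps):C(fs)", "F"], rel=1e-8
        )
        for key, ref_row in (
            ("mps", "C(mps)"), ("fs", "C(fs)"), ("interaction", "C(mps):C(fs)")
        ):
            assert res[key]["p"] == pytest.approx(ref.loc[ref_row, "PR(>F)"], abs=1e-8)

    def test_null_interaction_p_roughly_uniform(self, rng):
        rejections = 0
        n_sims = 100
        for _ in range(n_sims):
            df = self.factorial(rng, fa=1.0, fb=1.0, fab=0.0)
            if sf.two_way_anova(df, "nrms")["interaction"]["p"] < 0.05:
                rejections += 1
        # ~5% type-I error; allow generous binomial slack
        assert rejections <= 13

    def test_planted_interaction_detected(self, rng):
        df = self.factorial(rng, fa=0.5, fb=0.5, fab=5.0, noise=0.5)
        assert sf.two_way_anova(df, "nrms")["interaction"]["p"] < 0.05

    def test_all_equal_data_gives_zero_f(self):
        df = self.factorial(np.random.default_rng(0), noise=0.0)
        df["nrms"] = 1.0
        res = sf.two_way_anova(df, "nrms")
        assert res["mps"]["F"] == 0.0
        assert res["fs"]["F"] == 0.0
        assert res["interaction"]["F"] == 0.0

    def test_incomplete_factorial_rejected(self, rng):
        df = self.factorial(rng).iloc[:-5]
        with pytest.raises(ValueError, match="factorial"):
            sf.two_way_anova(df, "nrms")


class TestTukeySubsets:
    def test_indistinguishable_levels_form_one_subset(self, rng):
        groups = {
            "a": 10.0 + rng.normal(scale=5.0, size=10),
            "b": 10.001 + rng.normal(scale=5.0, size=10),
        }
        g = sf.tukey_subsets(groups, alpha=0.05)
        assert g.subsets == [["a", "b"]] or g.subsets == [["b", "a"]]

    def test_clearly_separated_level_gets_own_subset(self, rng):
        groups = {
            "a": 0.0 + rng.normal(scale=0.01, size=10),
            "b": 0.01 + rng.normal(scale=0.01, size=10),
            "c": 100.0 + rng.normal(scale=0.01, size=10),
        }
        g = sf.tukey_subsets(groups, alpha=0.05)
        assert [set(s) for s in g.subsets] == [{"a", "b"}, {"c"}]
        assert g.subset_p[-1] == 1.0  # singleton subset

    def test_subsets_match_exhaustive_all_pairs_oracle(self, rng):
        for _ in range(50):
            k = int(rng.integers(3, 7))
            n = int(rng.integers(4, 10))
            spread = rng.uniform(0.5, 3.0)
            groups = {
                f"L{i}": rng.normal(loc=spread * i * rng.random(), size=n)
                for i in range(k)
            }
            g = sf.tukey_subsets(groups, alpha=0.05)
            oracle = all_pairs_subset_oracle(groups, alpha=0.05)
            assert [set(s) for s in g.subsets] == oracle

    def test_cc_orientation_puts_largest_mean_first(self, rng):
        groups = {
            "lo": 0.2 + rng.normal(scale=0.01, size=8),
            "hi": 0.9 + rng.normal(scale=0.01, size=8),
        }
        g = sf.tukey_subsets(groups, alpha=0.05, metric="cc")
        assert g.subsets[0] == ["hi"]

    def test_membership_contiguous_across_subsets(self, rng):
        for trial in range(20):
            groups = {
                f"L{i}": rng.normal(loc=0.3 * i, size=6) for i in range(6)
            }
            g = sf.tukey_subsets(groups, alpha=0.05)
            order = {lvl: i for i, lvl in enumerate(g.ordered_levels())}
            for subset in g.subsets:
                idx = sorted(order[lvl] for lvl in subset)
                assert idx == list(range(idx[0], idx[-1] + 1))
            # every level appears in at least one subset
            covered = set().union(*map(set, g.subsets))
            assert covered == set(groups)

    def test_non_significant_anova_flagged_but_grouped(self, rng):
        groups = {f"L{i}": rng.normal(size=6) for i in range(3)}
        g = sf.tukey_subsets(groups, alpha=1e-6)
        assert not g.significant
        assert g.subsets


class TestPickOptimum:
    @staticmethod
    def grouping(subsets, means, metric="nrms"):
        return SubsetGrouping(
            metric=metric,
            level_means=means,
            level_n={k: 10 for k in means},
            subsets=subsets,
            subset_p=[0.5] * len(subsets),
            anova_p=0.001,
            significant=True,
            alpha=0.05,
        )

    def test_minimal_cardinality_then_accuracy(self):
        # best homogeneous subset of feature sets with published-style means
        means = {
            "VIWZ": 4.4103, "IWZ": 4.4113, "VIW": 4.5638,
            "IW": 4.5651, "VIZ": 4.9456, "IZ": 4.9508,
        }
        card = {k: len(k) for k in means}
        g = self.grouping([list(means)], means)
        sel = sf.pick_optimum(g, card)
        assert sel.optimal_level == "IW"
        assert sel.cardinality == 2
        assert sel.mean_metric == pytest.approx(4.5651)

    def test_single_level_best_subset(self):
        g = self.grouping([["W"], ["Z"]], {"W": 1.0, "Z": 2.0})
        assert sf.pick_optimum(g, {"W": 1, "Z": 1}).optimal_level == "W"

    def test_equal_cardinality_equal_mean_tie_breaks_by_name(self):
        g = self.grouping([["IZ", "IW"]], {"IW": 5.0, "IZ": 5.0})
        sel = sf.pick_optimum(g, {"IW": 2, "IZ": 2})
        assert sel.optimal_level == "IW"  # lexicographically first

    def test_cc_metric_prefers_larger_mean(self):
        g = self.grouping([["A", "B"]], {"A": 0.8, "B": 0.95}, metric="cc")
        assert sf.pick_optimum(g, {"A": 1, "B": 1}).optimal_level == "B"

    def test_winner_always_in_best_subset(self, rng):
        for _ in range(20):
            levels = [f"L{i}" for i in range(6)]
            means = {lvl: float(rng.random()) for lvl in levels}
            cut = int(rng.integers(1, 6))
            subsets = [levels[:cut], levels[cut:]]
            card = {lvl: int(rng.integers(1, 5)) for lvl in levels}
            sel = sf.pick_optimum(self.grouping(subsets, means), card)
            assert sel.optimal_level in subsets[0]


class TestBuildReports:
    def test_planted_informative_channels_win(self, planted_run):
        _, _, truth, table = planted_run
        from semgforce.features import feature_columns

        channels = tuple(
            sorted({c.split("_")[0] for c in feature_columns(table)})
        )
        specs = sf.enumerate_specs(channels, ("I", "W"))
        cfg = sf.RunConfig(n_repeats=5, seed=9)
        results = sf.run_trials(table, specs, cfg)
        fs_per_mps, mps_per_fs = sf.build_reports(results)
        assert len(fs_per_mps) == 63
        assert len(mps_per_fs) == 3
        informative = set(truth["informative_channels"])
        for _, row in mps_per_fs.iterrows():
            chosen = set(row["nrms"].split("+"))
            assert chosen <= informative, (
                f"FS {row['fs']}: optimal MPS {row['nrms']} uses noise channels"
            )

    def test_single_pair_run_yields_1x1_tables(self, rng):
        rows = [
            {"mps": "P1", "fs": "I", "repeat": r, "nrms": rng.random(),
             "nmae": rng.random(), "cc": rng.uniform(0, 1)}
            for r in range(10)
        ]
        fs_per_mps, mps_per_fs = sf.build_reports(pd.DataFrame(rows))
        assert list(fs_per_mps["mps"]) == ["P1"]
        assert list(mps_per_fs["fs"]) == ["I"]
        assert fs_per_mps.loc[0, "nrms"] == "I"
        assert mps_per_fs.loc[0, "nrms"] == "P1"
        assert not fs_per_mps.loc[0, "nrms_significant"]

    def test_rows_follow_enumeration_order(self, planted_run):
        _, _, _, table = planted_run
        specs = [
            sf.spec_from_name("P1:I"), sf.spec_from_name("P2:I"),
            sf.spec_from_name("P1+P2:I"), sf.spec_from_name("P1:W"),
            sf.spec_from_name("P2:W"), sf.spec_from_name("P1+P2:W"),
        ]
        cfg = sf.RunConfig(n_repeats=3, seed=2, grnn_spread=0.5)
        results = sf.run_trials(table, specs, cfg)
        fs_per_mps, _ = sf.build_reports(results)
        assert list(fs_per_mps["mps"]) == ["P1", "P2", "P1+P2"]
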