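import itertools
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from foldability import (
    DomainCatalog,
    SyntheticSpec,
    TrendConfig,
    binned_length_analysis,
    class_analysis,
    gen_catalog,
    loess_fit,
    resample_sem,
    screen_fast_folders,
    segmented_linear,
    trend_significance,
)
from foldability.trend_stats import rank_sum_test

from conftest import make_catalog

DATA = Path(__file__).parent / "data"


class TestLoess:
    def test_quadratic_is_reproduced_exactly(self):
        rng = np.random.default_rng(5)
        x = np.sort(rng.uniform(0, 4, 60))
        y = 1.2 - 0.8 * x + 0.3 * x**2
        fit = loess_fit(x, y, TrendConfig(degree=2))
        assert np.abs(fit.fitted - y).max() < 1e-8

    def test_constant_y(self):
        x = np.linspace(0, 3.8, 30)
        fit = loess_fit(x, np.full(30, 2.5))
        assert np.allclose(fit.fitted, 2.5)
        assert fit.delta == pytest.approx(0.0)

    def test_matches_frozen_reference_implementation(self):
        """Fitted values agree with an independently computed reference of
        Cleveland's algorithm (span 0.7, degree 2) on a frozen dataset."""
        rng = np.random.default_rng(2023)
        n = 200
        x = np.sort(rng.uniform(0, 3.8, n))
        y = 2.5 - 0.4 * x + 0.25 * np.sin(3 * x) + rng.normal(0, 0.3, n)
        ref = np.loadtxt(DATA / "loess_reference.tsv", skiprows=1)
        assert np.abs(ref[:, 0] - x).max() < 1e-9  # same frozen inputs
        assert np.abs(ref[:, 1] - y).max() < 1e-9
        fit = loess_fit(x, y, TrendConfig(span=0.7, degree=2))
        assert np.abs(fit.fitted - ref[:, 2]).max() < 1e-6

    def test_span_one_degree_one_on_linear_data_is_ols(self):
        rng = np.random.default_rng(8)
        x = np.sort(rng.uniform(0, 4, 40))
        y = 0.7 + 0.5 * x
        fit = loess_fit(x, y, TrendConfig(span=1.0, degree=1))
        res = stats.linregress(x, y)
        assert np.abs(fit.fitted - (res.intercept + res.slope * x)).max() < 1e-10

    def test_input_validation(self):
        with pytest.raises(ValueError, match="at least"):
            loess_fit([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError, match="identical"):
            loess_fit(np.ones(20), np.arange(20.0))
        with pytest.raises(ValueError, match="span"):
            loess_fit(np.arange(12.0), np.arange(12.0), TrendConfig(span=0.2, degree=2))


class TestTrendSignificance:
    def test_linear_f_equals_t_squared(self):
        """For a single predictor the F statistic is the squared slope t;
        compare against the closed-form F computed by hand."""
        rng = np.random.default_rng(10)
        x = rng.uniform(0, 4, 50)
        y = 1.0 + 0.3 * x + rng.normal(0, 0.5, 50)
        p = trend_significance(x, y, method="linear")
        # independent closed form
        n = x.size
        slope, intercept = np.polyfit(x, y, 1)
        rss1 = np.sum((y - intercept - slope * x) ** 2)
        rss0 = np.sum((y - y.mean()) ** 2)
        f = (rss0 - rss1) / (rss1 / (n - 2))
        p_ref = stats.f.sf(f, 1, n - 2)
        assert abs(p - p_ref) < 1e-10

    def test_constant_y_gives_p_one(self):
        assert trend_significance(np.arange(20.0), np.ones(20)) == 1.0

    def test_power_on_strong_slope(self):
        rng = np.random.default_rng(12)
        x = np.sort(rng.uniform(0, 4, 80))
        y = 10.0 * x + rng.normal(0, 1.0, 80)
        assert trend_significance(x, y) < 1e-6

    def test_type_one_error_calibration(self):
        """On pure noise the loess F-test rejects at ~the nominal 5% rate."""
        rng = np.random.default_rng(123)
        x = np.sort(rng.uniform(0, 3.8, 100))
        n_sim = 1000
        rej = sum(
            trend_significance(x, rng.normal(0, 1, 100)) < 0.05 for _ in range(n_sim)
        )
        assert abs(rej / n_sim - 0.05) <= 0.02


class TestSegmentedLinear:
    def test_noiseless_recovery(self):
        x = np.concatenate([np.linspace(0, 1.4, 20), np.linspace(1.5, 3.8, 20)])
        y = np.where(x >= 1.5, 2.0 - 0.5 * (x - 1.5), 2.0 + 0.3 * (1.5 - x))
        seg = segmented_linear(x, y, 1.5)
        assert seg.above.slope == pytest.approx(-0.5)
        assert seg.below.slope == pytest.approx(-0.3)

    def test_slope_p_equals_t_test(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(2, 4, 30)
        y = 1.0 + 0.2 * x + rng.normal(0, 0.3, 30)
        seg = segmented_linear(x, y, 1.5)
        res = stats.linregress(x, y)
        assert seg.above.p_slope == pytest.approx(res.pvalue, abs=1e-12)
        assert seg.below is None  # no points under the breakpoint

    def test_one_sided_data(self):
        x = np.linspace(0, 1.0, 10)
        seg = segmented_linear(x, x, 1.5)
        assert seg.above is None
        assert seg.below is not None


class TestBinnedLengthAnalysis:
    def test_null_catalog_is_mostly_insignificant(self):
        cat, _ = gen_catalog(
            SyntheticSpec(n_families=2000, slope_early=0.0, slope_late=0.0,
                          noise_sd=0.3, seed=21)
        )
        bs = binned_length_analysis(cat, (1.5, 3.8))
        assert bs.percentages["insignificant"] >= 80.0
        # each false-direction share stays within nominal level + MC slack
        assert bs.percentages["positive"] <= 10.0
        assert bs.percentages["negative"] <= 10.0

    def test_percentages_sum_and_order_invariance(self):
        cat, _ = gen_catalog(SyntheticSpec(n_families=800, seed=3))
        bs = binned_length_analysis(cat, (1.5, 3.8))
        assert sum(bs.percentages.values()) == pytest.approx(100.0)
        shuffled = DomainCatalog.from_frame(
            cat.domains.sample(frac=1.0, random_state=0).reset_index(drop=True)
        )
        bs2 = binned_length_analysis(shuffled, (1.5, 3.8))
        assert bs.percentages == bs2.percentages

    def test_epoch_restriction(self):
        cat = make_catalog([("a.1.1.1", 2.0, 3.0, 30), ("b.2.1.1", 2.0, 0.5, 30)])
        bs = binned_length_analysis(cat, (1.5, 3.8))
        assert bs.n_domains == 30  # only the early-epoch family

    def test_empty_epoch_is_an_error(self):
        cat = make_catalog([("a.1.1.1", 2.0, 0.5, 20)])
        with pytest.raises(ValueError, match="no domains"):
            binned_length_analysis(cat, (3.0, 3.8))

    def test_pooling_respects_minimum(self):
        cat, _ = gen_catalog(SyntheticSpec(n_families=500, seed=4))
        bs = binned_length_analysis(cat, (0.0, 3.8), TrendConfig(min_bin_n=10))
        assert (bs.table["n"] >= 10).all()


class TestClassAnalysis:
    def test_exact_wilcoxon_small_sample(self):
        """{1,2} vs {3,4}: enumeration of all 6 rank assignments gives 1/3."""
        u_obs = sum(1 for a in (1, 2) for b in (3, 4) if a > b)  # = 0
        more_extreme = 0
        for combo in itertools.combinations(range(4), 2):
            vals = [1, 2, 3, 4]
            x = [vals[i] for i in combo]
            y = [vals[i] for i in range(4) if i not in combo]
            u = sum(1 for a in x for b in y if a > b)
            if min(u, 4 - u) <= min(u_obs, 4 - u_obs):
                more_extreme += 1
        p_enum = more_extreme / 6
        assert p_enum == pytest.approx(1 / 3)
        assert rank_sum_test([1, 2], [3, 4]) == pytest.approx(p_enum)

    def test_planted_class_divergence(self):
        spec = SyntheticSpec(
            n_families=6000,
            class_mix=(0.5, 0.5, 0.0, 0.0),
            class_slopes={"a": (-0.5, -0.3), "b": (-0.5, 0.3)},
            noise_sd=0.3,
            seed=31,
        )
        cat, _ = gen_catalog(spec)
        cs = class_analysis(cat)
        late_a = cs.per_class["a"]["late"].percentages
        late_b = cs.per_class["b"]["late"].percentages
        assert late_a["negative"] > late_a["positive"]
        assert late_b["positive"] > late_b["negative"]
        assert cs.pairwise_p[("a", "b")] < 0.01

    def test_small_class_excluded(self):
        cat = make_catalog(
            [("a.1.1.1", 2.0, 3.0, 40), ("a.2.1.1", 2.5, 2.0, 40), ("b.1.1.1", 2.0, 2.0, 5)]
        )
        cs = class_analysis(cat, min_class_n=30)
        assert "b" in cs.excluded and cs.excluded["b"] == 5
        assert "b" not in cs.per_class


class TestResampleSem:
    @staticmethod
    def mean_smco(df):
        return {"mean_smco": float(df["smco"].mean())}

    def test_zero_variance_statistic(self):
        cat = make_catalog([("a.1.1.1", 2.0, 3.0, 50)])
        sems, dropped = resample_sem(cat, lambda df: {"const": 42.0}, n_resample=20, seed=1)
        assert sems["const"] == 0.0
        assert dropped == 0

    def test_seed_determinism(self):
        cat, _ = gen_catalog(SyntheticSpec(n_families=300, seed=6))
        s1, _ = resample_sem(cat, self.mean_smco, n_resample=30, seed=9)
        s2, _ = resample_sem(cat, self.mean_smco, n_resample=30, seed=9)
        assert s1 == s2

    def test_matches_independent_bootstrap_loop(self):
        """SEM equals a hand-written bootstrap loop with the same seed."""
        cat, _ = gen_catalog(SyntheticSpec(n_families=200, seed=7))
        sems, _ = resample_sem(cat, self.mean_smco, n_resample=50, seed=11)
        rng = np.random.default_rng(11)
        df = cat.domains
        vals = [
            float(df.iloc[rng.integers(0, len(df), size=len(df))]["smco"].mean())
            for _ in range(50)
        ]
        assert abs(sems["mean_smco"] - np.std(vals, ddof=1)) < 1e-12

    def test_failed_replicates_counted(self):
        cat, _ = gen_catalog(SyntheticSpec(n_families=100, seed=8))
        calls = {"n": 0}

        def flaky(df):
            calls["n"] += 1
            if calls["n"] % 4 == 0:
                raise RuntimeError("boom")
            return {"v": float(df["smco"].mean())}

        with pytest.warns(UserWarning, match="failed"):
            sems, dropped = resample_sem(cat, flaky, n_resample=20, seed=2)
        assert dropped == 5
        assert "v" in sems


class TestFastFolderScreen:
    def test_threshold_below_minimum(self):
        cat = make_catalog([("a.1.1.1", 2.0, 3.0, 5), ("b.1.1.1", 3.0, 1.0, 5)])
        screen = screen_fast_folders(cat, smco_threshold=0.5)
        assert len(screen.families) == 0
        assert screen.fraction == 0.0

    def test_planted_fast_families_recovered_exactly(self):
        fams = [(f"a.{i}.1.1", 1.2 if i <= 7 else 2.0 + 0.01 * i, 1.0, 2) for i in range(1, 101)]
        cat = make_catalog(fams)
        screen = screen_fast_folders(cat, smco_threshold=1.5)
        assert set(screen.families["family"]) == {f"a.{i}.1.1" for i in range(1, 8)}
        assert screen.fraction == pytest.approx(0.07)

    def test_known_downhill_families_flagged(self):
        fams = [("a.35.1.2", 1.3, 1.0, 3), ("b.72.1.1", 1.4, 0.8, 3), ("c.1.1.1", 3.0, 2.0, 3)]
        cat = make_catalog(fams)
        screen = screen_fast_folders(cat)
        assert screen.families["is_known_downhill"].all()
        assert len(screen.families) == 2
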