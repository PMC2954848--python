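"""Discovery: t-tests, balanced permutations, FDR calibration, ROC, ANOVA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import globinbench as gb
from globinbench.containers import DesignError
from globinbench.discovery import DEFAULT_THRESHOLD_GRID
from tests.conftest import make_expression

TISSUE_4V4 = np.array(["brain", "liver"] * 4, dtype=object)
GROUPS_4V4 = np.array(["A"] * 4 + ["B"] * 4, dtype=object)


def brute_force_balanced(tissues, g1):
    """Generate-and-filter oracle for unordered balanced partitions."""
    n = len(tissues)
    equal = g1 == n - g1
    found = set()
    for combo in itertools.combinations(range(n), g1):
        group = list(combo)
        rest = [i for i in range(n) if i not in combo]
        ga = [tissues[i] for i in group]
        gr = [tissues[i] for i in rest]
        if ga.count("brain") != ga.count("liver"):
            continue
        if gr.count("brain") != gr.count("liver"):
            continue
        key = tuple(sorted(group))
        if equal:
            key = min(key, tuple(sorted(rest)))
        found.add(key)
    return found


class TestTtestPerGene:
    def test_identical_groups_give_t_zero_p_one(self):
        half = np.random.default_rng(0).normal(8, 1, (10, 4))
        expr = make_expression(np.hstack([half, half]))
        out = gb.ttest_per_gene(expr, GROUPS_4V4)
        assert np.allclose(out["t"], 0.0)
        assert np.allclose(out["p_value"], 1.0)

    def test_label_swap_negates_t_and_effect(self):
        rng = np.random.default_rng(1)
        expr = make_expression(rng.normal(8, 1, (20, 8)))
        a = gb.ttest_per_gene(expr, GROUPS_4V4)
        swapped = np.where(GROUPS_4V4 == "A", "B", "A")
        b = gb.ttest_per_gene(expr, swapped)
        assert np.allclose(a["t"], -b["t"])
        assert np.allclose(a["effect"], -b["effect"])
        assert np.allclose(a["p_value"], b["p_value"])

    def test_matches_scipy_ttest_ind(self):
        rng = np.random.default_rng(2)
        expr = make_expression(rng.normal(8, 1, (30, 8)))
        ours = gb.ttest_per_gene(expr, GROUPS_4V4)
        welch = gb.ttest_per_gene(expr, GROUPS_4V4, equal_var=False)
        for i in range(30):
            t, p = sps.ttest_ind(expr.values[i, :4], expr.values[i, 4:])
            assert ours.loc[i, "t"] == pytest.approx(t, rel=1e-10)
            assert ours.loc[i, "p_value"] == pytest.approx(p, rel=1e-9)
            tw, pw = sps.ttest_ind(expr.values[i, :4], expr.values[i, 4:],
                                   equal_var=False)
            assert welch.loc[i, "p_value"] == pytest.approx(pw, rel=1e-9)

    def test_zero_variance_flags(self):
        values = np.array([[1.0] * 8, [1.0] * 4 + [2.0] * 4])
        out = gb.ttest_per_gene(make_expression(values), GROUPS_4V4)
        assert out.loc[0, "flag"] == "degenerate"
        assert out.loc[0, "p_value"] == 1.0
        assert out.loc[1, "flag"] == "zero_variance"
        assert out.loc[1, "p_value"] < 1e-300

    def test_agrees_with_exhaustive_relabeling_oracle(self):
        # exact permutation p over all 35 unordered 4v4 relabelings
        rng = np.random.default_rng(3)
        values = rng.normal(0, 1, (10, 8))
        values[:5] += np.array([0.0] * 4 + [1.5] * 4)
        expr = make_expression(values)
        out = gb.ttest_per_gene(expr, GROUPS_4V4)
        for i in range(10):
            x = values[i]
            t_obs = abs(sps.ttest_ind(x[:4], x[4:])[0])
            perm_t = []
            for combo in itertools.combinations(range(8), 4):
                if 0 not in combo:
                    continue  # unordered: fix sample 0 in group A
                rest = [j for j in range(8) if j not in combo]
                perm_t.append(abs(sps.ttest_ind(x[list(combo)], x[rest])[0]))
            assert len(perm_t) == 35
            p_perm = np.mean(np.array(perm_t) >= t_obs - 1e-12)
            assert abs(out.loc[i, "p_value"] - p_perm) < 0.15

    def test_rejects_small_groups(self):
        expr = make_expression(np.zeros((2, 4)))
        with pytest.raises(DesignError):
            gb.ttest_per_gene(expr, np.array(["A", "B", "B", "B"]))


class TestBalancedPermutations:
    def test_4v4_yields_18_exhaustive_partitions(self):
        scheme = gb.balanced_permutations(TISSUE_4V4)
        assert scheme.n_permutations == 18
        assert scheme.exhaustive

    def test_2v2_yields_2_partitions(self):
        tissues = np.array(["brain", "liver", "brain", "liver"], dtype=object)
        scheme = gb.balanced_permutations(tissues)
        assert scheme.n_permutations == 2
        assert scheme.exhaustive

    def test_every_partition_is_balanced(self):
        scheme = gb.balanced_permutations(TISSUE_4V4)
        for i in range(scheme.n_permutations):
            labels = scheme.labels(i)
            for side in ("A", "B"):
                tissues = TISSUE_4V4[labels == side]
                assert (tissues == "brain").sum() == (tissues == "liver").sum()

    @pytest.mark.parametrize("per_tissue,g1", [(2, 2), (3, 2), (4, 4)])
    def test_matches_brute_force_oracle(self, per_tissue, g1):
        # group sizes must be even for within-group tissue balance
        tissues = np.array(["brain", "liver"] * per_tissue, dtype=object)
        n = len(tissues)
        scheme = gb.balanced_permutations(tissues, group_sizes=(g1, n - g1),
                                          max_permutations=10_000)
        expected = brute_force_balanced(list(tissues), g1)
        assert set(scheme.assignments) == expected

    def test_sampling_mode_returns_distinct_balanced_partitions(self):
        tissues = np.array(["brain", "liver"] * 8, dtype=object)
        scheme = gb.balanced_permutations(tissues, max_permutations=50, seed=0)
        assert not scheme.exhaustive
        assert scheme.n_permutations == 50
        assert len(set(scheme.assignments)) == 50

    def test_rejects_unbalanceable_designs(self):
        with pytest.raises(DesignError):
            gb.balanced_permutations(
                np.array(["brain", "brain", "brain", "liver"], dtype=object))
        with pytest.raises(DesignError):
            gb.balanced_permutations(TISSUE_4V4, group_sizes=(3, 5))


def noise_free_fixture(n_genes, n_de, delta=1.5, seed=4):
    """Exactly noise-free 4v4 data: DE genes shifted on brain samples only."""
    rng = np.random.default_rng(seed)
    base = rng.uniform(4, 12, n_genes)
    values = np.tile(base[:, None], (1, 8))
    values[:n_de, TISSUE_4V4 == "brain"] += delta
    return make_expression(values)


class TestEstimateFdr:
    def test_strong_signal_gives_zero_fdr(self):
        expr = noise_free_fixture(100, 50)
        stats = gb.ttest_per_gene(expr, TISSUE_4V4)
        scheme = gb.balanced_permutations(TISSUE_4V4)
        fdr = gb.estimate_fdr(stats["p_value"].to_numpy(), scheme, expr, 0.01)
        assert fdr == 0.0

    def test_pure_null_self_consistency_near_one(self):
        rng = np.random.default_rng(6)
        expr = make_expression(rng.normal(8, 0.3, (20_000, 8)))
        scheme = gb.balanced_permutations(TISSUE_4V4)
        stats = gb.ttest_per_gene(expr, TISSUE_4V4)
        fdr = gb.estimate_fdr(stats["p_value"].to_numpy(), scheme, expr, 0.05)
        assert fdr == pytest.approx(1.0, abs=0.15)

    def test_zero_detection_convention(self):
        rng = np.random.default_rng(7)
        expr = make_expression(rng.normal(8, 0.3, (50, 8)))
        scheme = gb.balanced_permutations(TISSUE_4V4)
        observed = np.full(50, 0.9)
        fdr = gb.estimate_fdr(observed, scheme, expr, 1e-9)
        assert fdr in (0.0, 1.0)


class TestCalibrateThreshold:
    def test_noise_free_signal_recovers_planted_count(self):
        expr = noise_free_fixture(200, 20)
        stats = gb.ttest_per_gene(expr, TISSUE_4V4)
        scheme = gb.balanced_permutations(TISSUE_4V4)
        cal = gb.calibrate_threshold(stats["p_value"].to_numpy(), scheme, expr)
        assert cal.achieved
        assert cal.n_significant == 20

    def test_pure_null_declares_almost_nothing(self):
        rng = np.random.default_rng(8)
        expr = make_expression(rng.normal(8, 0.3, (5000, 8)))
        stats = gb.ttest_per_gene(expr, TISSUE_4V4)
        scheme = gb.balanced_permutations(TISSUE_4V4)
        cal = gb.calibrate_threshold(stats["p_value"].to_numpy(), scheme, expr)
        assert cal.n_significant <= 3

    def test_noisier_profile_calibrates_to_stricter_p(self, profiles):
        criticals = {}
        for name in ("no_treatment", "cdna"):
            design = gb.default_design(1, protocols=(name,))
            expr, _ = gb.generate_expression(design, profiles[name], 5000,
                                             seed=9)
            stats = gb.ttest_per_gene(expr, design.tissues)
            scheme = gb.balanced_permutations(design.tissues)
            criticals[name] = gb.calibrate_threshold(
                stats["p_value"].to_numpy(), scheme, expr).critical_p
        assert criticals["no_treatment"] <= criticals["cdna"]

    def test_grid_default_descends_from_005_to_1e6(self):
        grid = np.asarray(DEFAULT_THRESHOLD_GRID)
        assert grid[0] == pytest.approx(0.05)
        assert grid[-1] == pytest.approx(1e-6)
        assert (np.diff(grid) < 0).all()


class TestRocCurve:
    def test_saturation_and_monotonicity(self, cdna_sim, cdna_design):
        expr, _ = cdna_sim
        stats = gb.ttest_per_gene(expr, cdna_design.tissues)
        scheme = gb.balanced_permutations(cdna_design.tissues)
        curve = gb.roc_curve(stats["p_value"].to_numpy(), scheme, expr,
                             thresholds=np.array([1e-4, 1e-2, 0.5, 1.0]))
        assert curve["total_detections"].iloc[-1] == expr.n_genes
        assert curve["total_detections"].is_monotonic_increasing
        assert curve["mean_false_positives"].is_monotonic_increasing

    def test_null_curve_hugs_diagonal(self):
        rng = np.random.default_rng(10)
        expr = make_expression(rng.normal(8, 0.3, (10_000, 8)))
        stats = gb.ttest_per_gene(expr, TISSUE_4V4)
        scheme = gb.balanced_permutations(TISSUE_4V4)
        curve = gb.roc_curve(stats["p_value"].to_numpy(), scheme, expr,
                             thresholds=np.array([0.01, 0.05, 0.2]))
        ratio = curve["total_detections"] / curve["mean_false_positives"]
        assert np.allclose(ratio, 1.0, atol=0.25)

    def test_cdna_curve_dominates_no_treatment(self, profiles):
        curves = {}
        for name in ("no_treatment", "cdna"):
            totals = []
            for seed in range(3):
                design = gb.default_design(1, protocols=(name,))
                expr, _ = gb.generate_expression(design, profiles[name], 2000,
                                                 seed=seed)
                stats = gb.ttest_per_gene(expr, design.tissues)
                scheme = gb.balanced_permutations(design.tissues)
                curve = gb.roc_curve(stats["p_value"].to_numpy(), scheme, expr)
                totals.append(curve)
            curves[name] = totals
        for seed in range(3):
            nt, cd = curves["no_treatment"][seed], curves["cdna"][seed]
            # compare detections at matched false-positive levels
            fp_grid = np.linspace(1, 1500, 20)
            nt_det = np.interp(fp_grid, nt["mean_false_positives"],
                               nt["total_detections"])
            cd_det = np.interp(fp_grid, cd["mean_false_positives"],
                               cd["total_detections"])
            assert (cd_det >= nt_det).all()


class TestAnovaTimeDose:
    @staticmethod
    def _layout(r=2):
        times = np.repeat([0.0, 3.0, 6.0], 3 * r)
        doses = np.tile(np.repeat([0.0, 0.33, 3.3], r), 3)
        return times, doses

    def test_matches_statsmodels_extra_ss_oracle(self):
        smf = pytest.importorskip("statsmodels.formula.api")
        from statsmodels.stats.anova import anova_lm
        times, doses = self._layout()
        rng = np.random.default_rng(11)
        values = rng.normal(8, 0.3, (6, len(times)))
        expr = make_expression(values)
        ours = gb.anova_time_dose(expr, times, doses)
        for i in range(6):
            frame = pd.DataFrame({"y": values[i], "t": times.astype(str),
                                  "d": doses.astype(str)})
            full = smf.ols("y ~ C(t) * C(d)", frame).fit()
            reduced = smf.ols("y ~ C(t)", frame).fit()
            p_oracle = anova_lm(reduced, full)["Pr(>F)"].iloc[1]
            assert ours.loc[i, "p_value"] == pytest.approx(p_oracle, rel=1e-8)

    def test_high_dose_late_rise_is_significant_up(self):
        times, doses = self._layout()
        rng = np.random.default_rng(12)
        values = rng.normal(8, 0.2, (1, len(times)))
        values[0, (times == 6.0) & (doses == 3.3)] += 3.0
        out = gb.anova_time_dose(make_expression(values), times, doses)
        assert out.loc[0, "p_value"] < 0.001
        assert out.loc[0, "direction"] == "up"

    def test_dose_permutation_within_time_destroys_significance(self):
        expr, design, _ = gb.generate_time_dose(
            400, effect_sd=1.0, effect_min=0.5, noise_sd=0.2, seed=13)
        times = design.samples["time"].to_numpy(float)
        doses = design.samples["dose"].to_numpy(float)
        rng = np.random.default_rng(13)
        shuffled = doses.copy()
        for t in np.unique(times):
            mask = times == t
            shuffled[mask] = rng.permutation(shuffled[mask])
        out = gb.anova_time_dose(expr, times, shuffled)
        assert out["p_value"].median() > 0.3

    def test_null_pvalues_roughly_uniform(self):
        times, doses = self._layout()
        rng = np.random.default_rng(14)
        expr = make_expression(rng.normal(8, 0.3, (4000, len(times))))
        out = gb.anova_time_dose(expr, times, doses)
        ks = sps.kstest(out["p_value"], "uniform").statistic
        assert ks < 0.04

    def test_rejects_bad_layouts(self):
        times, doses = self._layout()
        expr = make_expression(np.zeros((2, len(times))))
        with pytest.raises(DesignError):
            gb.anova_time_dose(expr, times, np.full_like(doses, 1.0))
        with pytest.raises(DesignError):  # r=1 leaves no error df
            t1, d1 = self._layout(r=1)
            gb.anova_time_dose(make_expression(np.zeros((2, len(t1)))), t1, d1)
        with pytest.raises(DesignError):  # unbalanced cells
            bad = doses.copy()
            bad[0] = 3.3
            gb.anova_time_dose(expr, times, bad)
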