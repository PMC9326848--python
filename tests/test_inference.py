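import numpy as np
import pandas as pd
import pytest
from scipy import stats

from colocal.data_model import CellImage, ImageSet, Window
from colocal.inference import (
    CoLocModel,
    adjust_pvalues,
    fit_weighted_linear,
    fit_weighted_mixed,
)
from colocal.spatial import score_all


def two_group_design(n_per, rng=None, means=(0.0, 1.0), sd=1.0):
    y = np.concatenate([
        (rng.normal(means[0], sd, n_per) if rng is not None
         else np.full(n_per, means[0])),
        (rng.normal(means[1], sd, n_per) if rng is not None
         else np.full(n_per, means[1])),
    ])
    g = np.repeat([0.0, 1.0], n_per)
    X = np.column_stack([np.ones(2 * n_per), g])
    return y, X, g


class TestWeightedLinear:
    def test_equal_weights_reduce_to_pooled_t(self):
        rng = np.random.default_rng(0)
        y, X, g = two_group_design(10, rng)
        fit = fit_weighted_linear(y, X, np.ones(len(y)), ["intercept", "g"])
        t_ref, p_ref = stats.ttest_ind(y[g == 1], y[g == 0])
        assert fit.params[1] == pytest.approx(y[g == 1].mean() - y[g == 0].mean())
        assert fit.tvalues[1] == pytest.approx(t_ref)
        assert fit.pvalues[1] == pytest.approx(p_ref)
        assert fit.df_resid == 18

    def test_global_weight_rescale_invariance(self):
        rng = np.random.default_rng(1)
        y, X, _ = two_group_design(12, rng)
        w = rng.uniform(0.5, 2.0, len(y))
        f1 = fit_weighted_linear(y, X, w, ["c", "g"])
        f2 = fit_weighted_linear(y, X, 7.0 * w, ["c", "g"])
        np.testing.assert_allclose(f1.params, f2.params, rtol=1e-12)
        np.testing.assert_allclose(f1.bse, f2.bse, rtol=1e-12)
        np.testing.assert_allclose(f1.pvalues, f2.pvalues, rtol=1e-12)

    def test_weighting_reduces_sd_with_known_heteroscedasticity(self):
        """beta is unbiased and precision weighting shrinks its spread."""
        rng = np.random.default_rng(2)
        beta_w, beta_u = [], []
        n = 40
        prec = np.concatenate([np.full(n // 2, 0.04), np.full(n // 2, 4.0)])
        g = rng.permutation(np.repeat([0.0, 1.0], n // 2))
        X = np.column_stack([np.ones(n), g])
        for _ in range(500):
            y = 0.5 * g + rng.normal(0, 1 / np.sqrt(prec))
            beta_w.append(fit_weighted_linear(y, X, prec, None).params[1])
            beta_u.append(fit_weighted_linear(y, X, np.ones(n), None).params[1])
        assert np.mean(beta_w) == pytest.approx(0.5, abs=3 * np.std(beta_w) / np.sqrt(500))
        assert np.std(beta_w) < np.std(beta_u)


class TestWeightedMixed:
    def test_balanced_intercept_dominated_df(self):
        """With a dominant subject intercept, the effective df approaches
        the between-subject df m - 2."""
        rng = np.random.default_rng(3)
        m, k = 20, 4
        subj = np.repeat(np.arange(m), k)
        g = (subj >= m // 2).astype(float)
        y = 1.0 * g + rng.normal(0, 8.0, m)[subj] + rng.normal(0, 0.5, m * k)
        X = np.column_stack([np.ones(m * k), g])
        fit = fit_weighted_mixed(y, X, subj, np.ones(m * k))
        assert fit.df[1] == pytest.approx(m - 2, abs=0.1)

    def test_zero_variance_single_image_collapses_to_wls(self):
        # with one image per subject and equal weights the intercept
        # variance is unidentifiable and the fit collapses to (W)LS
        rng = np.random.default_rng(4)
        n = 30
        g = np.repeat([0.0, 1.0], n // 2)
        y = 0.3 * g + rng.normal(0, 1, n)
        X = np.column_stack([np.ones(n), g])
        w = np.ones(n)
        mixed = fit_weighted_mixed(y, X, np.arange(n), w)
        wls = fit_weighted_linear(y, X, w, None)
        assert mixed.boundary
        np.testing.assert_allclose(mixed.beta, wls.params, rtol=1e-6)
        np.testing.assert_allclose(mixed.se, wls.bse, rtol=1e-6)
        assert mixed.df[1] == pytest.approx(wls.df_resid)

    def test_global_weight_rescale_invariance(self):
        rng = np.random.default_rng(5)
        m, k = 12, 3
        subj = np.repeat(np.arange(m), k)
        g = (subj >= m // 2).astype(float)
        y = g + rng.normal(0, 1, m)[subj] + rng.normal(0, 1, m * k)
        X = np.column_stack([np.ones(m * k), g])
        w = rng.uniform(0.5, 2.0, m * k)
        f1 = fit_weighted_mixed(y, X, subj, w)
        f2 = fit_weighted_mixed(y, X, subj, w * 7.0)
        np.testing.assert_allclose(f1.beta, f2.beta, rtol=1e-8)
        np.testing.assert_allclose(f1.se, f2.se, rtol=1e-6)
        np.testing.assert_allclose(f1.df, f2.df, rtol=1e-4)

    def test_df_bounded_by_residual_df(self):
        rng = np.random.default_rng(6)
        m, k = 10, 3
        subj = np.repeat(np.arange(m), k)
        g = (subj >= m // 2).astype(float)
        y = rng.normal(0, 1, m)[subj] + rng.normal(0, 1, m * k)
        X = np.column_stack([np.ones(m * k), g])
        fit = fit_weighted_mixed(y, X, subj, np.ones(m * k))
        assert 0 < fit.df[1] <= m * k - 2

    def test_variance_component_recovery(self):
        """tau2 and sigma2 estimates centre on the generating values."""
        rng = np.random.default_rng(7)
        m, k, tau, sig = 30, 3, 2.0, 1.0
        subj = np.repeat(np.arange(m), k)
        X = np.column_stack([np.ones(m * k),
                             (subj >= m // 2).astype(float)])
        t2, s2 = [], []
        for _ in range(200):
            y = rng.normal(0, tau, m)[subj] + rng.normal(0, sig, m * k)
            fit = fit_weighted_mixed(y, X[:, :2], subj, np.ones(m * k))
            t2.append(fit.tau2)
            s2.append(fit.sigma2)
        assert np.mean(t2) == pytest.approx(tau**2, rel=0.15)
        assert np.mean(s2) == pytest.approx(sig**2, rel=0.1)


class TestPipeline:
    def test_four_pair_results_and_signal_pair(self, small_study):
        study, _ = small_study
        res = CoLocModel(study, types=["A", "B"]).fit(weights="fitted",
                                                      model="mixed")
        df = res.to_frame()
        assert len(df) == 4
        assert set(map(tuple, df[["type_i", "type_j"]].values)) == {
            ("A", "A"), ("A", "B"), ("B", "A"), ("B", "B")}
        assert df["p_raw"].between(0, 1).all()
        assert (df["df"] > 0).all()

    def test_condition_level_swap_flips_sign(self, small_study):
        study, _ = small_study
        m = CoLocModel(study, types=["A", "B"])
        scores = m._scores()
        r1 = m.fit(weights="none", scores=scores)
        m2 = CoLocModel(study, types=["A", "B"], reference="group2")
        r2 = m2.fit(weights="none", scores=scores)
        d1, d2 = r1.to_frame(), r2.to_frame()
        np.testing.assert_allclose(d1["beta"], -d2["beta"], rtol=1e-8)
        np.testing.assert_allclose(d1["p_raw"], d2["p_raw"], rtol=1e-6)

    def test_auto_model_selection(self, small_study):
        study, _ = small_study
        res = CoLocModel(study, types=["A", "B"]).fit(weights="none")
        assert res.config["model"] == "mixed"  # multiple images per subject
        res_lin = CoLocModel(study, subject=None, types=["A", "B"]).fit(
            weights="none")
        assert res_lin.config["model"] == "linear"

    def test_three_level_condition_contrasts(self):
        rng = np.random.default_rng(8)
        s = ImageSet()
        win = Window(0, 200, 0, 200)
        for k in range(12):
            n = 30
            img = CellImage(f"im{k}", rng.uniform(0, 200, 2 * n),
                            rng.uniform(0, 200, 2 * n),
                            np.array(["A"] * n + ["B"] * n, dtype=object), win)
            s.add_image(img, subject_id=f"p{k}",
                        condition=["ctrl", "onset", "late"][k % 3])
        res = CoLocModel(s, types=["A", "B"], reference="ctrl").fit(
            weights="none", model="linear")
        df = res.to_frame()
        assert sorted(df["contrast"].unique()) == [
            "condition[late-ctrl]", "condition[onset-ctrl]"]
        assert len(df) == 8  # 4 pairs x 2 contrasts

    def test_weights_none_vs_fitted_agree_on_homogeneous_counts(self):
        """With count-homogeneous images the fitted weights are near-uniform
        and both analyses agree."""
        from colocal.simulate import SimConfig, simulate_study

        cfg = SimConfig(n_subjects=10, images_per_subject=2,
                        cell_count_choices=(200,), density_grid=64)
        study, _ = simulate_study(cfg, "null", seed=21)
        m = CoLocModel(study, types=["A", "B"])
        scores = m._scores()
        p_f = m.fit(weights="fitted", scores=scores).to_frame()["p_raw"]
        p_n = m.fit(weights="none", scores=scores).to_frame()["p_raw"]
        np.testing.assert_allclose(p_f, p_n, atol=0.12)

    def test_untestable_pair_is_flagged_not_raised(self):
        rng = np.random.default_rng(9)
        s = ImageSet()
        win = Window(0, 100, 0, 100)
        for k in range(6):
            # type "C" appears in only one image: too few defined scores
            marks = ["A"] * 10 + (["C"] * 3 if k == 0 else [])
            n = len(marks)
            s.add_image(CellImage(f"im{k}", rng.uniform(0, 100, n),
                                  rng.uniform(0, 100, n),
                                  np.array(marks, dtype=object), win),
                        subject_id=f"p{k}", condition="g1" if k % 2 else "g2")
        res = CoLocModel(s, types=["A", "C"]).fit(weights="none", model="linear")
        df = res.to_frame()
        ac = df[(df.type_i == "A") & (df.type_j == "C")]
        assert ac["p_raw"].isna().all()

    def test_linear_vs_mixed_minority_driven_effect(self):
        """When a strong shift is carried by a minority of subjects, the
        image-level linear model overstates the evidence relative to the
        subject-aware mixed model."""
        rng = np.random.default_rng(10)
        m, k = 8, 6
        subj = np.repeat(np.arange(m), k)
        g = (subj >= m // 2).astype(float)
        # only 1 of 4 case subjects actually responds, but strongly
        shift = np.where(np.isin(subj, [4]), 6.0, 0.0) * g
        y = shift + rng.normal(0, 1.0, m * k)
        X = np.column_stack([np.ones(m * k), g])
        lin = fit_weighted_linear(y, X, np.ones(m * k), None)
        mix = fit_weighted_mixed(y, X, subj, np.ones(m * k))
        p_lin = lin.pvalues[1]
        p_mix = 2 * stats.t.sf(abs(mix.beta[1] / mix.se[1]), mix.df[1])
        assert p_lin < p_mix


class TestAdjustAndExport:
    def test_bh_step_up_hand_computed(self, small_study):
        study, _ = small_study
        res = CoLocModel(study, types=["A", "B"]).fit(weights="none",
                                                      model="linear")
        for r, p in zip(res.pair_results, [0.01, 0.02, 0.03, 0.04]):
            r.p_raw = p
        adjust_pvalues(res, "BH")
        assert [r.p_adjusted for r in res.pair_results] == pytest.approx([0.04] * 4)

    def test_bh_dominates_raw_and_none_copies(self, small_study):
        study, _ = small_study
        res = CoLocModel(study, types=["A", "B"]).fit(weights="none",
                                                      model="linear")
        raw = [r.p_raw for r in res.pair_results]
        adjust_pvalues(res, "BH")
        assert all(a >= p - 1e-15 for a, p in
                   zip([r.p_adjusted for r in res.pair_results], raw))
        adjust_pvalues(res, "none")
        assert [r.p_adjusted for r in res.pair_results] == pytest.approx(raw)

    def test_signed_logp_matrix_values(self, small_study):
        study, _ = small_study
        res = CoLocModel(study, types=["A", "B"]).fit(weights="none",
                                                      model="linear")
        res.pair_results[0].p_raw = 0.01
        res.pair_results[0].beta = 2.0
        res.pair_results[1].p_raw = 1.0
        mat = res.signed_logp_matrix()
        ti0, tj0 = res.pair_results[0].type_i, res.pair_results[0].type_j
        ti1, tj1 = res.pair_results[1].type_i, res.pair_results[1].type_j
        assert mat.loc[ti0, tj0] == pytest.approx(2.0)
        assert mat.loc[ti1, tj1] == pytest.approx(0.0)

    def test_export_writes_files(self, tmp_path, small_study):
        study, _ = small_study
        res = CoLocModel(study, types=["A", "B"]).fit(weights="none",
                                                      model="linear")
        res.export(tmp_path)
        assert (tmp_path / "results.csv").exists()
        mats = list(tmp_path.glob("signed_logp_*.csv"))
        plots = list(tmp_path.glob("heatmap_*.png"))
        assert mats and plots
        written = pd.read_csv(mats[0], index_col=0)
        assert written.shape == (2, 2)


class TestPermutationNull:
    def test_permuted_labels_give_uniform_p(self, small_null_study):
        """Permuting condition labels across subjects yields ~uniform
        p-values for the signal pair (KS not rejected at 0.01)."""
        study, _ = small_null_study
        m = CoLocModel(study, types=["A", "B"])
        scores = m._scores()
        rng = np.random.default_rng(13)
        subjects = study.subjects()
        original = dict(study.condition_of)
        ps = []
        try:
            for _ in range(120):
                perm = rng.permutation(len(subjects))
                for sid, k in zip(subjects, perm):
                    study.condition_of[sid] = (
                        "g1" if k < len(subjects) // 2 else "g2"
                    )
                res = m.fit(weights="none", model="mixed", scores=scores)
                row = [r for r in res.pair_results
                       if r.type_i == "A" and r.type_j == "B"][0]
                ps.append(row.p_raw)
        finally:
            study.condition_of.clear()
            study.condition_of.update(original)
        stat, p = stats.kstest(ps, "uniform")
        assert p > 0.01
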