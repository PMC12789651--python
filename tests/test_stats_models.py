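"""Mixed models with Satterthwaite df and Pillai-trace MANOVA."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from conftest import simulate_lmm_table
from ovicrypt import stats_models


class TestFitLmm:
    def test_zero_group_variance_degenerates_to_two_sample_t(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "resp": np.concatenate([rng.normal(0, 1, 10), rng.normal(1, 1, 10)]),
            "grp": ["a"] * 10 + ["b"] * 10,
            "nest_id": list(range(10)) * 2,     # groups orthogonal to grp
        })
        res = stats_models.fit_lmm(df, "resp", "grp")["grp[T.b]"]
        ols = df.loc[df.grp == "b", "resp"].mean() - df.loc[df.grp == "a", "resp"].mean()
        assert res.estimate == pytest.approx(ols, abs=1e-6)
        assert res.df == pytest.approx(18, abs=1)

    def test_constant_response_flagged_singular(self):
        df = pd.DataFrame({"resp": 1.0, "grp": ["a", "b"] * 20,
                           "nest_id": list(range(8)) * 5})
        res = stats_models.fit_lmm(df, "resp", "grp")["grp[T.b]"]
        assert res.estimate == pytest.approx(0.0, abs=1e-8)
        assert res.singular

    def test_recovers_configured_egg_background_offset(self):
        # short replicate check; the full 200-replicate calibration runs in
        # the acceptance suite
        ests = []
        for seed in range(20):
            table = simulate_lmm_table(seed=seed)
            res = stats_models.fit_lmm(table, "resp", "object_type")
            ests.append(res["object_type[T.egg]"].estimate)
        assert np.mean(ests) == pytest.approx(-0.10, abs=0.01)

    def test_estimate_invariance_to_row_order_and_affine_scaling(self):
        table = simulate_lmm_table(seed=3)
        base = stats_models.fit_lmm(table, "resp", "object_type")["object_type[T.egg]"]
        shuffled = table.sample(frac=1.0, random_state=1).reset_index(drop=True)
        perm = stats_models.fit_lmm(shuffled, "resp", "object_type")["object_type[T.egg]"]
        assert perm.estimate == pytest.approx(base.estimate, rel=1e-6)
        assert perm.tstat == pytest.approx(base.tstat, rel=1e-5)
        scaled = table.assign(resp=3.0 * table["resp"] + 1.0)
        aff = stats_models.fit_lmm(scaled, "resp", "object_type")["object_type[T.egg]"]
        assert aff.estimate == pytest.approx(3.0 * base.estimate, rel=1e-6)
        assert aff.tstat == pytest.approx(base.tstat, rel=1e-4)
        assert aff.pvalue == pytest.approx(base.pvalue, rel=1e-3)

    def test_satterthwaite_df_within_bounds(self):
        table = simulate_lmm_table(seed=4)
        res = stats_models.fit_lmm(table, "resp", "object_type")
        slope = res["object_type[T.egg]"]
        n = len(table)
        assert 1 <= slope.df <= n - 2
        intercept = res["Intercept"]
        # the intercept carries between-nest uncertainty: df near n_nests - 1
        assert intercept.df < 2 * table["nest_id"].nunique()

    def test_matches_lmerTest_reference(self, tmp_path):
        """Estimates, SEs and Satterthwaite dfs agree with lmerTest."""
        table = simulate_lmm_table(n_scenes=20, seed=12)
        res = stats_models.fit_lmm(table, "resp", "object_type")["object_type[T.egg]"]
        csv = tmp_path / "lmm.csv"
        table.to_csv(csv, index=False)
        script = (
            'suppressMessages({library(lmerTest)});'
            f'd <- read.csv("{csv}");'
            'm <- lmer(resp ~ object_type + (1|nest_id), data=d);'
            's <- coef(summary(m))["object_typeegg",];'
            'cat(s[["Estimate"]], s[["Std. Error"]], s[["df"]], s[["Pr(>|t|)"]], "\\n")'
        )
        out = subprocess.run([shutil.which("Rscript") or "Rscript", "-e", script],
                             capture_output=True, text=True, check=True)
        est, se, df, p = map(float, out.stdout.split())
        assert res.estimate == pytest.approx(est, rel=1e-4)
        assert res.se == pytest.approx(se, rel=1e-3)
        assert res.df == pytest.approx(df, rel=0.01)
        assert res.pvalue == pytest.approx(p, rel=0.05, abs=1e-12)


class TestManovaPillai:
    def test_univariate_pillai_equals_anova_r2(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "y": np.concatenate([rng.normal(0, 1, 30), rng.normal(0.8, 1, 30)]),
            "grp": ["a"] * 30 + ["b"] * 30,
        })
        res = stats_models.manova_pillai(df, ["y"], "grp", group="grp")
        grand = df["y"].mean()
        ss_between = sum(len(g) * (g["y"].mean() - grand) ** 2
                         for _, g in df.groupby("grp"))
        ss_total = ((df["y"] - grand) ** 2).sum()
        assert res.pillai == pytest.approx(ss_between / ss_total)

    def test_toy_table_matches_hand_eigendecomposition(self):
        # 2 groups x 3 obs, 2 responses; separation on response 1 only
        df = pd.DataFrame({
            "y1": [0.0, 0.1, -0.1, 2.0, 2.1, 1.9],
            "y2": [1.0, 0.8, 1.2, 1.1, 0.9, 1.0],
            "grp": ["a"] * 3 + ["b"] * 3,
        })
        res = stats_models.manova_pillai(df, ["y1", "y2"], "grp", group="grp")
        Y = df[["y1", "y2"]].to_numpy()
        grand = Y.mean(axis=0)
        H = np.zeros((2, 2))
        E = np.zeros((2, 2))
        for g in ("a", "b"):
            Yg = Y[(df.grp == g).to_numpy()]
            d = Yg.mean(axis=0) - grand
            H += len(Yg) * np.outer(d, d)
            E += (Yg - Yg.mean(axis=0)).T @ (Yg - Yg.mean(axis=0))
        eig = np.linalg.eigvals(H @ np.linalg.inv(H + E))
        assert res.pillai == pytest.approx(float(np.real(eig).sum()))

    def test_pillai_bounded_and_monotone_in_separation(self):
        rng = np.random.default_rng(2)
        vals = []
        for sep in (0.0, 0.5, 1.0, 2.0):
            df = pd.DataFrame({
                "y1": np.concatenate([rng.normal(0, 1, 40),
                                      rng.normal(sep, 1, 40)]),
                "y2": rng.normal(0, 1, 80),
                "grp": ["a"] * 40 + ["b"] * 40,
            })
            res = stats_models.manova_pillai(df, ["y1", "y2"], "grp", group="grp")
            assert 0.0 <= res.pillai <= 1.0
            vals.append(res.pillai)
        assert vals == sorted(vals)

    def test_parametric_p_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({
            "y1": rng.normal(0, 1, 60), "y2": rng.normal(0, 1, 60),
            "grp": ["a"] * 30 + ["b"] * 30,
        })
        obs = stats_models.manova_pillai(df, ["y1", "y2"], "grp", group="grp")
        perm_stats = []
        labels = df["grp"].to_numpy().copy()
        for _ in range(500):
            rng.shuffle(labels)
            dp = df.assign(grp=labels)
            perm_stats.append(
                stats_models.manova_pillai(dp, ["y1", "y2"], "grp", group="grp").pillai)
        perm_p = float(np.mean(np.asarray(perm_stats) >= obs.pillai))
        assert obs.pvalue == pytest.approx(perm_p, abs=0.05)


@pytest.fixture(scope="module")
def suite_table():
    rng = np.random.default_rng(0)
    table = simulate_lmm_table(n_scenes=12, seed=5,
                               habitat_effect_background=0.08)
    for col, _ in stats_models.COLOUR_METRICS:
        table[col] = table["resp"] + rng.normal(0, 0.01, len(table))
    for i in range(4):
        table[f"PC{i + 1}"] = rng.normal(0, 1, len(table))
    return table


class TestRunTableSuite:
    def test_grid_has_ten_metric_rows_per_split(self, suite_table):
        grid = stats_models.run_table_suite(suite_table)
        for split, grp in grid.groupby("split"):
            assert len(grp) == 10, split

    def test_habitat_effect_on_backgrounds_detected_not_on_eggs(self):
        hits_bg, hits_egg = 0, 0
        for seed in range(25):
            table = simulate_lmm_table(n_scenes=30, egg_offset=0.0,
                                       habitat_effect_background=0.08, seed=seed)
            bg = table[table.object_type == "background"]
            egg = table[table.object_type == "egg"]
            p_bg = stats_models.fit_lmm(bg, "resp", "habitat")[
                "habitat[T.saltmarsh]"].pvalue
            p_egg = stats_models.fit_lmm(egg, "resp", "habitat")[
                "habitat[T.saltmarsh]"].pvalue
            hits_bg += p_bg < 0.05
            hits_egg += p_egg >= 0.05
        assert hits_bg >= 23          # >= ~90 % power on the background side
        assert hits_egg >= 23         # eggs mostly non-significant under the null
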