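"""Leave-one-nest-out classification, confusion summaries and ROC curves."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from conftest import simulate_classifier_table
from ovicrypt import discriminate
from ovicrypt.discriminate import (
    ClassifierSpec,
    LOOResult,
    confusion_summary,
    fit_logistic_glmm,
    loo_cross_validate,
    roc_curve,
)


def _loo_from(labels, probs):
    df = pd.DataFrame({"nest_id": "n0", "y_true": labels, "p_egg": probs})
    return LOOResult(predictions=df, folds=1)


class TestLogisticGlmm:
    def test_matches_glmer_reference(self, tmp_path):
        rng = np.random.default_rng(42)
        G, n_per = 12, 20
        groups = np.repeat(np.arange(G), n_per)
        b = rng.normal(0, 0.8, G)
        X = rng.normal(size=(G * n_per, 2))
        eta = -1.0 + 1.2 * X[:, 0] - 0.7 * X[:, 1] + b[groups]
        y = (rng.random(G * n_per) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = fit_logistic_glmm(X, y, groups)
        slopes = fit.coef[1:] / fit.x_sd
        intercept = fit.coef[0] - np.sum(fit.coef[1:] * fit.x_mean / fit.x_sd)
        csv = tmp_path / "glmm.csv"
        pd.DataFrame({"y": y, "x1": X[:, 0], "x2": X[:, 1], "g": groups}).to_csv(
            csv, index=False)
        script = (
            'suppressMessages(library(lme4));'
            f'd <- read.csv("{csv}");'
            'm <- glmer(y ~ x1 + x2 + (1|g), data=d, family=binomial);'
            'cat(fixef(m), sqrt(unlist(VarCorr(m))), "\\n")'
        )
        out = subprocess.run([shutil.which("Rscript") or "Rscript", "-e", script],
                             capture_output=True, text=True, check=True)
        r_int, r_x1, r_x2, r_sigma = map(float, out.stdout.split())
        assert intercept == pytest.approx(r_int, abs=5e-3)
        assert slopes[0] == pytest.approx(r_x1, abs=5e-3)
        assert slopes[1] == pytest.approx(r_x2, abs=5e-3)
        assert fit.sigma == pytest.approx(r_sigma, abs=2e-2)

    def test_separable_data_triggers_ridge_flag(self):
        rng = np.random.default_rng(0)
        X = np.concatenate([rng.normal(-3, 0.3, 60), rng.normal(3, 0.3, 60)])[:, None]
        y = np.concatenate([np.zeros(60), np.ones(60)])
        groups = np.tile(np.arange(12), 10)
        fit = fit_logistic_glmm(X, y, groups)
        assert fit.separation_flag
        assert fit.ridge == discriminate.RIDGE_LAMBDA
        assert np.all(np.isfinite(fit.coef))


class TestLooCrossValidate:
    def test_separable_feature_classifies_perfectly(self):
        table = simulate_classifier_table(n_scenes=10, colour_sep=8.0, seed=1)
        loo = loo_cross_validate(table, ClassifierSpec("colour_avian"))
        conf = confusion_summary(loo)
        assert conf.accuracy == 1.0
        y = loo.predictions["y_true"] == "egg"
        assert ((loo.predictions["p_egg"] > 0.5) == y).all()

    def test_null_features_fall_back_to_majority_rule(self):
        table = simulate_classifier_table(n_scenes=30, seed=2)
        loo = loo_cross_validate(table, ClassifierSpec("colour_avian"))
        conf = confusion_summary(loo)
        assert conf.accuracy == pytest.approx(0.9, abs=0.03)

    def test_every_sample_predicted_exactly_once(self):
        table = simulate_classifier_table(n_scenes=8, seed=3)
        loo = loo_cross_validate(table, ClassifierSpec("pattern"))
        assert len(loo.predictions) == len(table)
        assert loo.folds == 8
        counts = loo.predictions.groupby("nest_id").size()
        assert (counts == 30).all()

    def test_row_order_invariance(self):
        table = simulate_classifier_table(n_scenes=6, seed=4)
        a = loo_cross_validate(table, ClassifierSpec("colour_carnivore"))
        shuffled = table.sample(frac=1.0, random_state=9).reset_index(drop=True)
        b = loo_cross_validate(shuffled, ClassifierSpec("colour_carnivore"))
        pa = a.predictions.sort_values(["nest_id", "p_egg"]).reset_index(drop=True)
        pb = b.predictions.sort_values(["nest_id", "p_egg"]).reset_index(drop=True)
        # row order only reorders floating-point accumulation; probabilities
        # agree to optimiser tolerance
        assert np.allclose(pa["p_egg"], pb["p_egg"], atol=1e-3)

    def test_too_few_nests_rejected(self):
        table = simulate_classifier_table(n_scenes=4, seed=5)
        with pytest.raises(ValueError, match="5 nests"):
            loo_cross_validate(table, ClassifierSpec("pattern"))


class TestConfusionSummary:
    def test_all_background_rule_scores_design_rates(self):
        labels = ["egg"] * 3 + ["background"] * 27
        loo = _loo_from(labels, [0.0] * 30)
        conf = confusion_summary(loo)
        assert conf.accuracy == pytest.approx(0.9)
        assert conf.sensitivity == 0.0
        assert conf.specificity == 1.0
        assert conf.no_information_rate == pytest.approx(0.9)

    def test_hand_counted_toy_example(self):
        labels = ["egg", "egg"] + ["background"] * 8
        probs = [0.6, 0.4] + [0.1] * 8
        conf = confusion_summary(_loo_from(labels, probs))
        assert conf.accuracy == pytest.approx(0.9)
        assert conf.sensitivity == pytest.approx(0.5)
        assert conf.specificity == pytest.approx(1.0)

    def test_perfect_classification_beats_nir_decisively(self):
        labels = (["egg"] * 3 + ["background"] * 27) * 30   # n = 900
        probs = [0.9 if lab == "egg" else 0.1 for lab in labels]
        conf = confusion_summary(_loo_from(labels, probs))
        assert conf.accuracy == 1.0
        # exact binomial tail with k = n at p = 0.9
        assert conf.pvalue == pytest.approx(0.9 ** 900)
        assert conf.pvalue < 0.001

    def test_single_class_rejected(self):
        with pytest.raises(discriminate.SingleClassError):
            confusion_summary(_loo_from(["background"] * 5, [0.1] * 5))


class TestRocCurve:
    def test_perfect_ranking_gives_auc_one(self):
        roc = roc_curve(_loo_from(["egg", "egg", "background", "background"],
                                  [0.9, 0.8, 0.2, 0.1]))
        assert roc.auc == 1.0

    def test_hand_counted_concordance(self):
        # 1 of 2 egg-background pairs concordant
        roc = roc_curve(_loo_from(["egg", "background", "background"],
                                  [0.7, 0.8, 0.2]))
        assert roc.auc == pytest.approx(0.5)

    def test_auc_equals_brute_force_pair_counting(self):
        rng = np.random.default_rng(7)
        n = 200
        labels = np.where(rng.random(n) < 0.3, "egg", "background")
        probs = rng.random(n)
        roc = roc_curve(_loo_from(list(labels), probs))
        eggs = probs[labels == "egg"]
        bgs = probs[labels == "background"]
        wins = sum((e > b) + 0.5 * (e == b) for e in eggs for b in bgs)
        assert roc.auc == pytest.approx(wins / (len(eggs) * len(bgs)))

    def test_roc_monotone_trade_off(self):
        rng = np.random.default_rng(8)
        labels = np.where(rng.random(300) < 0.2, "egg", "background")
        probs = rng.random(300) + 0.3 * (labels == "egg")
        roc = roc_curve(_loo_from(list(labels), probs))
        sens = roc.points["sensitivity"].to_numpy()
        spec = roc.points["specificity"].to_numpy()
        assert np.all(np.diff(sens) >= 0)
        assert np.all(np.diff(spec) <= 0)

    def test_label_permuted_null_auc_near_half(self):
        rng = np.random.default_rng(9)
        n = 3000
        labels = np.where(rng.permutation(n) < n * 0.2, "egg", "background")
        probs = rng.random(n)
        roc = roc_curve(_loo_from(list(labels), probs))
        assert 0.45 <= roc.auc <= 0.55


class TestDiscriminationSuite:
    def test_grid_shape_and_row_labels(self):
        table = simulate_classifier_table(n_scenes=12, colour_sep=1.0,
                                          pattern_sep=1.0, seed=10)
        bundle = discriminate.run_discrimination_suite(table)
        grid = bundle["grid"]
        assert len(grid) == 14
        assert set(grid["measure"]) == {m for m, _ in discriminate.GRID_ROWS}
        assert set(grid["habitat"]) == {"beach", "saltmarsh"}
        assert len(bundle["roc"]) == 14

    def test_colour_only_separation_ranks_colour_over_pattern(self):
        table = simulate_classifier_table(n_scenes=12, colour_sep=3.0,
                                          pattern_sep=0.0, seed=11)
        colour = loo_cross_validate(table, ClassifierSpec("colour_avian"))
        pattern = loo_cross_validate(table, ClassifierSpec("pattern"))
        assert roc_curve(colour).auc > 0.9
        assert roc_curve(pattern).auc == pytest.approx(0.5, abs=0.1)

    def test_missing_habitat_rejected(self):
        table = simulate_classifier_table(n_scenes=8, seed=12)
        with pytest.raises(discriminate.StratumError):
            discriminate.run_discrimination_suite(table[table.habitat == "beach"])
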