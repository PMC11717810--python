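import numpy as np
import pandas as pd
import pytest

from omicblup import (
    bootstrap_se,
    compare_models,
    corrected_phenotypes,
    dispersion_slope,
    make_folds,
    make_lbco,
    percent_change,
    run_cv,
)
from omicblup.validation import _pearson, audit_masking


class TestFolds:
    def test_ten_lines_five_folds_of_two(self):
        scheme = make_folds([f"L{i}" for i in range(10)], k=5, seed=0)
        sizes = [len(scheme.validation_lines(f)) for f in range(5)]
        assert sizes == [2] * 5

    def test_union_is_partition(self):
        lines = [f"L{i}" for i in range(23)]
        scheme = make_folds(lines, k=5, seed=3)
        seen = [ln for f in range(5) for ln in scheme.validation_lines(f)]
        assert sorted(seen) == sorted(lines)
        sizes = sorted(len(scheme.validation_lines(f)) for f in range(5))
        assert sizes[-1] - sizes[0] <= 1

    def test_stratified_folds_cover_both_cycles(self):
        lines = [f"L{i}" for i in range(40)]
        cycles = {ln: (0 if i < 20 else 1) for i, ln in enumerate(lines)}
        scheme = make_folds(lines, k=5, seed=1, cycles=cycles)
        for f in range(5):
            cyc = {cycles[ln] for ln in scheme.validation_lines(f)}
            assert cyc == {0, 1}

    def test_fewer_lines_than_folds_raises(self):
        with pytest.raises(ValueError, match="fewer lines"):
            make_folds(["a", "b"], k=5)

    def test_lbco_one_run_per_cycle(self):
        cyc = {"a": 2021, "b": 2021, "c": 2022}
        scheme = make_lbco(cyc)
        assert scheme.n_folds == 2
        assert sorted(scheme.validation_lines(0)) == ["a", "b"]
        assert scheme.validation_lines(1) == ["c"]

    def test_lbco_single_cycle_rejected(self):
        with pytest.raises(ValueError, match="2 cycles"):
            make_lbco({"a": 2021})


class TestCorrectedPhenotypes:
    def test_single_level_centering(self, dataset, kernels):
        ph = dataset.phenotypes.copy()
        yc = corrected_phenotypes(ph, "GY", kernels["G"], kernels["S"])
        assert isinstance(yc, pd.Series)
        assert set(yc.index) <= set(ph["line_id"])

    def test_trial_shift_absorbed(self, dataset, kernels):
        ph = dataset.phenotypes.copy()
        yc1 = corrected_phenotypes(ph, "GY", kernels["G"], kernels["S"])
        shifted = ph.copy()
        one_trial = shifted["trial"].iloc[0]
        shifted.loc[shifted["trial"] == one_trial, "GY"] += 5.0
        yc2 = corrected_phenotypes(shifted, "GY", kernels["G"], kernels["S"])
        # fixed-effect absorption: corrected values barely move (the REML
        # refit perturbs variance components slightly)
        assert (yc1 - yc2).abs().max() < 0.05 * yc1.std()

    def test_matches_two_step_residual_oracle(self, dataset, kernels):
        from omicblup import build_design, fit_gblup, model_spec
        from omicblup.models import ensure_env

        ph = ensure_env(dataset.phenotypes)
        _, blup = fit_gblup("GY", ph, kernels["G"], kernels["S"])
        yc = corrected_phenotypes(
            ph, "GY", kernels["G"], kernels["S"], blup=blup
        )
        d = build_design(ph, model_spec("GY", kernels["G"], kernels["S"]))
        resid = d.y - d.x @ blup.fixed.to_numpy()
        expected = (
            pd.DataFrame({"l": d.table["line_id"], "r": resid})
            .groupby("l")["r"].mean()
        )
        pd.testing.assert_series_equal(
            yc.sort_index(), expected.sort_index(), check_names=False
        )


class TestDispersion:
    def test_identical_vectors(self):
        v = np.array([1.0, 2.0, 3.0, 2.5])
        assert dispersion_slope(v, v) == pytest.approx(1.0)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        gp = rng.normal(size=50)
        assert dispersion_slope(0.5 * gp, gp) == pytest.approx(0.5)

    def test_matches_least_squares_oracle(self):
        rng = np.random.default_rng(1)
        gp = rng.normal(size=80)
        gw = 0.8 * gp + rng.normal(0, 0.3, 80)
        slope = np.polyfit(gp, gw, 1)[0]
        assert dispersion_slope(gw, gp) == pytest.approx(slope)

    def test_zero_variance_rejected(self):
        with pytest.raises(ZeroDivisionError):
            dispersion_slope(np.ones(5), np.ones(5))


class TestBootstrap:
    def test_constant_statistic_zero_se(self):
        se = bootstrap_se(lambda x: 1.0, np.arange(10.0), n_rep=200, seed=0)
        assert se == pytest.approx(0.0)

    def test_se_of_mean_matches_analytic(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(200)
        se = bootstrap_se(np.mean, x, n_rep=10000, seed=1)
        assert se == pytest.approx(x.std() / np.sqrt(200), rel=0.10)

    def test_seed_stability(self):
        rng = np.random.default_rng(3)
        x, y = rng.standard_normal((2, 60))
        se1 = bootstrap_se(_pearson, x, y, n_rep=2000, seed=1)
        se2 = bootstrap_se(_pearson, x, y, n_rep=2000, seed=2)
        assert se1 == pytest.approx(se2, rel=0.15)


class TestPercentChange:
    def test_published_yield_improvement(self):
        assert round(percent_change(0.42, 0.41), 1) == pytest.approx(2.4)

    def test_no_change(self):
        assert percent_change(0.3, 0.3) == pytest.approx(0.0)

    def test_exact_arithmetic(self):
        assert percent_change(0.30, 0.25) == pytest.approx(20.0)

    def test_zero_reference(self):
        with pytest.raises(ZeroDivisionError):
            percent_change(0.1, 0.0)


class TestCompareModels:
    def test_identical_folds_share_letter(self):
        pa = [0.5, 0.6, 0.55]
        letters = compare_models({"A": pa, "B": list(pa)})
        assert letters["A"] == letters["B"]

    def test_clear_shift_separates(self):
        pa = [0.50, 0.60, 0.55, 0.58, 0.52]
        shifted = [v + 0.2 for v in pa]
        letters = compare_models({"A": pa, "B": shifted})
        assert set(letters["A"]) != set(letters["B"])

    def test_three_models_a_a_b(self):
        rng = np.random.default_rng(4)
        base = 0.5 + 0.01 * rng.standard_normal(6)
        b = base + 0.005 * rng.standard_normal(6)
        pa = {"A": list(base), "B": list(b), "C": list(base - 0.3)}
        letters = compare_models(pa)
        assert letters["A"] == letters["B"]
        assert not set(letters["A"]) & set(letters["C"])

    def test_too_few_folds_all_share(self):
        letters = compare_models({"A": [0.5], "B": [0.9]})
        assert letters["A"] == letters["B"]


class TestMaskingAudit:
    def test_leak_detected(self, dataset):
        ph = dataset.phenotypes
        val = {str(ph["line_id"].iloc[0])}
        with pytest.raises(AssertionError, match="leaked"):
            audit_masking(ph, val)

    def test_clean_training_passes(self, dataset):
        ph = dataset.phenotypes
        val = {str(ph["line_id"].iloc[0])}
        train = ph[~ph["line_id"].astype(str).isin(val)]
        audit_masking(train, val)  # no raise


@pytest.fixture(scope="module")
def cv_results(dataset, kernels):
    scheme = make_folds(
        dataset.candidate_lines, k=5, seed=0,
        cycles=dataset.truth["cycle_of_line"],
    )
    res_g = run_cv(
        scheme, "GBLUP", "GY", dataset.phenotypes, kernels["G"],
        kernels["S"], controls=dataset.control_lines, compute_lr=True,
        bootstrap_reps=300,
    )
    res_o = run_cv(
        scheme, "GOBLUP-MI", "GY", dataset.phenotypes, kernels["G"],
        kernels["S"], omics_kernel=kernels["Q_MI"],
        controls=dataset.control_lines, compute_lr=True,
        bootstrap_reps=300,
    )
    return res_g, res_o


class TestRunCV:
    def test_pa_bounded_and_positive_on_heritable_trait(self, cv_results):
        res_g, res_o = cv_results
        for res in cv_results:
            assert -1 <= res.pa <= 1
            assert res.pa_se >= 0 and res.b_wp_se >= 0
        assert res_g.pa > 0

    def test_controls_never_validated(self, cv_results, dataset):
        res_g, _ = cv_results
        assert not set(res_g.gebv_partial.index) & set(dataset.control_lines)

    def test_lr_ratios_within_bounds(self, cv_results):
        res_g, res_o = cv_results
        assert res_g.lr_ratios["g/gp"] <= 1.0
        for key in ("g/gm", "gm/gmp", "g/gmp"):
            assert res_o.lr_ratios[key] <= 1.0

    def test_affine_response_invariance(self, dataset, kernels):
        scheme = make_folds(dataset.candidate_lines, k=3, seed=5)
        ph = dataset.phenotypes.copy()
        res1 = run_cv(
            scheme, "GBLUP", "GY", ph, kernels["G"], kernels["S"],
            controls=dataset.control_lines, bootstrap_reps=100,
        )
        ph2 = ph.assign(GY=2.0 * ph["GY"] + 10.0)
        res2 = run_cv(
            scheme, "GBLUP", "GY", ph2, kernels["G"], kernels["S"],
            controls=dataset.control_lines, bootstrap_reps=100,
        )
        assert res1.pa == pytest.approx(res2.pa, abs=0.02)
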