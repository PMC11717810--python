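import numpy as np
import pandas as pd
import pytest

from omicblup import (
    KernelMatrix,
    ModelSpec,
    RandomTerm,
    VCEstimates,
    blup_solve,
    build_design,
    reml_fit,
)


def one_way_table(n_groups=10, reps=5, sa=0.5, se=1.0, seed=3):
    rng = np.random.default_rng(seed)
    eff = rng.normal(0, np.sqrt(sa), n_groups)
    y = np.repeat(eff, reps) + rng.normal(0, np.sqrt(se), n_groups * reps)
    return pd.DataFrame(
        {"grp": np.repeat([f"g{i}" for i in range(n_groups)], reps), "y": y}
    )


class TestBuildDesign:
    def test_single_trial_single_fixed_column(self):
        tab = pd.DataFrame({"f": ["T1"] * 3, "y": [1.0, 2.0, 3.0]})
        d = build_design(tab, ModelSpec("y", ["f"], []))
        assert d.x.shape == (3, 1)

    def test_interaction_term_maps_to_distinct_columns(self):
        tab = pd.DataFrame(
            {"line_id": ["a", "a"], "env": ["e1", "e2"], "y": [1.0, 2.0]}
        )
        k = KernelMatrix(["a"], np.eye(1), "G")
        spec = ModelSpec(
            "y", [], [RandomTerm("i_g", ("line_id", "env"), k)]
        )
        d = build_design(tab, spec)
        bt = d.terms[0]
        assert bt.n_levels == 2
        assert bt.obs_level[0] != bt.obs_level[1]
        # independent copies per environment: zero cross-env covariance
        np.testing.assert_allclose(bt.vmat, np.eye(2))

    def test_crossproducts_match_tabulation_oracle(self):
        rng = np.random.default_rng(4)
        tab = pd.DataFrame(
            {
                "f": rng.choice(["A", "B", "C"], 30),
                "grp": rng.choice([f"g{i}" for i in range(5)], 30),
                "y": rng.normal(size=30),
            }
        )
        spec = ModelSpec("y", ["f"], [RandomTerm("a", "grp", None)])
        d = build_design(tab, spec)
        # X'X: brute-force dummy tabulation
        levels = sorted(tab["f"].unique())
        x = np.column_stack(
            [np.ones(30)] + [(tab["f"] == l).to_numpy(float) for l in levels[1:]]
        )
        np.testing.assert_allclose(d.x.T @ d.x, x.T @ x)
        # Z'Z diagonal = group counts
        counts = tab["grp"].value_counts().sort_index()
        z = np.zeros((30, 5))
        z[np.arange(30), d.terms[0].obs_level] = 1
        np.testing.assert_allclose(
            np.diag(z.T @ z), counts.to_numpy(float)
        )

    def test_missing_response_rows_dropped(self):
        tab = pd.DataFrame({"f": ["A"] * 5, "y": [1.0, np.nan, 2.0, 3.0, np.nan]})
        d = build_design(tab, ModelSpec("y", ["f"], []))
        assert d.n_obs == 3 and d.n_dropped_missing == 2

    def test_unknown_entity_raises(self):
        tab = pd.DataFrame({"grp": ["a", "zz"], "y": [1.0, 2.0]})
        k = KernelMatrix(["a"], np.eye(1), "G")
        with pytest.raises(KeyError, match="absent from kernel"):
            build_design(tab, ModelSpec("y", [], [RandomTerm("g", "grp", k)]))


class TestRemlFit:
    def test_fixed_effects_only_residual(self):
        rng = np.random.default_rng(0)
        tab = pd.DataFrame(
            {"f": ["A"] * 6 + ["B"] * 6, "y": rng.normal(size=12)}
        )
        d = build_design(tab, ModelSpec("y", ["f"], []))
        vc = reml_fit(d)
        resid = tab.groupby("f")["y"].transform(lambda s: s - s.mean())
        assert vc.estimates["sigma2_e"] == pytest.approx(
            (resid**2).sum() / (12 - 2), rel=1e-5
        )

    def test_balanced_one_way_anova_closed_form(self):
        tab = one_way_table()
        spec = ModelSpec("y", [], [RandomTerm("a", "grp", None, "sigma2_a")])
        vc = reml_fit(build_design(tab, spec))
        gm = tab.groupby("grp")["y"].agg(["mean", "count"])
        msb = 5 * gm["mean"].var(ddof=1)
        msw = (
            tab.assign(c=tab.y - tab.grp.map(gm["mean"])).c.pow(2).sum()
            / (10 * 4)
        )
        assert vc.estimates["sigma2_e"] == pytest.approx(msw, rel=1e-6)
        assert vc.estimates["sigma2_a"] == pytest.approx(
            (msb - msw) / 5, rel=1e-6
        )
        assert vc.converged

    def test_invariant_to_observation_order(self):
        tab = one_way_table(seed=8)
        spec = ModelSpec("y", [], [RandomTerm("a", "grp", None, "sigma2_a")])
        vc1 = reml_fit(build_design(tab, spec))
        perm = np.random.default_rng(1).permutation(len(tab))
        vc2 = reml_fit(build_design(tab.iloc[perm].reset_index(drop=True), spec))
        for k in vc1.estimates:
            assert vc1.estimates[k] == pytest.approx(vc2.estimates[k], rel=1e-6)

    def test_response_scaling_scales_variances(self):
        tab = one_way_table(seed=9)
        spec = ModelSpec("y", [], [RandomTerm("a", "grp", None, "sigma2_a")])
        vc1 = reml_fit(build_design(tab, spec))
        tab2 = tab.assign(y=tab.y * 3.0)
        vc2 = reml_fit(build_design(tab2, spec))
        for k in vc1.estimates:
            assert vc2.estimates[k] == pytest.approx(
                9.0 * vc1.estimates[k], rel=1e-4
            )

    def test_boundary_component_flagged(self):
        rng = np.random.default_rng(10)
        # pure-noise data: the group variance collapses to the boundary
        tab = pd.DataFrame(
            {
                "grp": np.repeat([f"g{i}" for i in range(20)], 3),
                "y": rng.normal(size=60),
            }
        )
        # shuffle responses so group effects carry nothing
        tab["y"] = rng.permutation(tab["y"].to_numpy())
        spec = ModelSpec("y", [], [RandomTerm("a", "grp", None, "sigma2_a")])
        vc = reml_fit(build_design(tab, spec))
        assert vc.converged
        if vc.boundary:
            assert "sigma2_a" in vc.boundary


class TestBlupSolve:
    def _identity_setup(self, n=30, seed=2):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=n)
        tab = pd.DataFrame({"id": [f"e{i}" for i in range(n)], "y": y})
        k = KernelMatrix([f"e{i}" for i in range(n)], np.eye(n), "identity")
        spec = ModelSpec("y", [], [RandomTerm("a", "id", k, "sigma2_a")])
        return tab, build_design(tab, spec)

    def test_zero_variance_shrinks_to_zero(self):
        tab, d = self._identity_setup()
        vc = VCEstimates(
            {"sigma2_a": 1e-12, "sigma2_e": 1.0}, {}, 0, True, [], 0, 30
        )
        sol = blup_solve(d, vc)
        assert np.max(np.abs(sol.effects["a"])) < 1e-10

    def test_ridge_shrinkage_closed_form(self):
        tab, d = self._identity_setup()
        vc = VCEstimates(
            {"sigma2_a": 0.4, "sigma2_e": 0.6}, {}, 0, True, [], 0, 30
        )
        sol = blup_solve(d, vc)
        mu = sol.fixed.iloc[0]
        expected = 0.4 / (0.4 + 0.6) * (tab["y"].to_numpy() - mu)
        np.testing.assert_allclose(
            sol.effects["a"].to_numpy(), expected, atol=1e-10
        )

    def test_masked_entity_predicted_through_kernel(self):
        # entity c has no observation; it is correlated with a, not with b
        k = np.array([[1.0, 0.0, 0.8], [0.0, 1.0, 0.0], [0.8, 0.0, 1.0]])
        kern = KernelMatrix(["a", "b", "c"], k, "G")
        tab = pd.DataFrame({"id": ["a", "b"], "y": [2.0, -1.0]})
        spec = ModelSpec("y", [], [RandomTerm("g", "id", kern, "sigma2_g")])
        d = build_design(tab, spec)
        vc = VCEstimates(
            {"sigma2_g": 1.0, "sigma2_e": 1.0}, {}, 0, True, [], 0, 2
        )
        sol = blup_solve(d, vc)
        assert sol.effects["g"]["c"] != 0.0
        # uncorrelated masked entity predicts zero
        k0 = np.eye(3)
        kern0 = KernelMatrix(["a", "b", "c"], k0, "G")
        d0 = build_design(
            tab, ModelSpec("y", [], [RandomTerm("g", "id", kern0, "sigma2_g")])
        )
        sol0 = blup_solve(d0, vc)
        assert sol0.effects["g"]["c"] == pytest.approx(0.0, abs=1e-12)

    def test_solution_satisfies_mixed_model_equations(self):
        rng = np.random.default_rng(6)
        n, q = 40, 8
        groups = rng.choice([f"g{i}" for i in range(q)], n)
        a = rng.normal(size=(q, q))
        kmat = a @ a.T / q + np.eye(q)  # invertible PSD kernel
        ids = [f"g{i}" for i in range(q)]
        kern = KernelMatrix(ids, kmat, "G")
        tab = pd.DataFrame({"grp": groups, "y": rng.normal(size=n)})
        spec = ModelSpec("y", [], [RandomTerm("g", "grp", kern, "sigma2_g")])
        d = build_design(tab, spec)
        sg, se = 0.7, 1.3
        vc = VCEstimates(
            {"sigma2_g": sg, "sigma2_e": se}, {}, 0, True, [], 0, n
        )
        sol = blup_solve(d, vc)
        z = np.zeros((n, q))
        z[np.arange(n), d.terms[0].obs_level] = 1
        x = d.x
        lam = se / sg
        lhs = np.block(
            [
                [x.T @ x, x.T @ z],
                [z.T @ x, z.T @ z + lam * np.linalg.inv(kmat)],
            ]
        )
        rhs = np.concatenate([x.T @ d.y, z.T @ d.y])
        est = np.concatenate(
            [sol.fixed.to_numpy(), sol.effects["g"].to_numpy()]
        )
        resid = lhs @ est - rhs
        assert np.linalg.norm(resid) < 1e-8 * max(np.linalg.norm(rhs), 1)


def test_parameter_recovery_two_component_gblup():
    """REML recovers the additive and residual variances on data simulated
    from the model itself (single quick replicate; the multi-seed coverage
    study lives in the acceptance suite)."""
    rng = np.random.default_rng(42)
    n_lines, reps = 150, 2
    p = rng.uniform(0.1, 0.5, 200)
    dos = rng.binomial(2, p, size=(n_lines, 200)).astype(float)
    q = dos - dos.mean(axis=0)
    g_mat = q @ q.T / (2 * np.sum(p * (1 - p)))
    ids = [f"L{i}" for i in range(n_lines)]
    kern = KernelMatrix(ids, g_mat, "G")
    w, u = np.linalg.eigh(g_mat)
    g_true = u @ (np.sqrt(np.clip(w, 0, None)) * rng.standard_normal(n_lines))
    g_true *= np.sqrt(0.3) / g_true.std(ddof=1)
    y = np.tile(g_true, reps) + rng.normal(0, np.sqrt(0.7), n_lines * reps)
    tab = pd.DataFrame({"line": np.tile(ids, reps), "y": y})
    spec = ModelSpec("y", [], [RandomTerm("g", "line", kern, "sigma2_g")])
    vc = reml_fit(build_design(tab, spec))
    assert abs(vc.estimates["sigma2_g"] - 0.3) < 3 * vc.se["sigma2_g"]
    assert abs(vc.estimates["sigma2_e"] - 0.7) < 3 * vc.se["sigma2_e"]
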