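"""Synthetic breeding-trial generator.

Generates a complete dataset with the statistical structure the analysis
assumes: a genotyped line panel from two (or more) breeding cycles, field
trials laid out as randomized incomplete blocks with replicated control
lines, plot-level metabolomic and near-infrared spectra, and phenotypes
produced by running the analysis model forward:

    y = mean + trial + g + l + i_g + i_l + s + m + (M beta) + e,

with g = Q alpha the additive genomic value (Gaussian SNP effects, scaled
so the realized variance matches the configured sigma_g2), independent
genomic-by-environment draws per year-location environment, spatial effects
drawn with the S kernel of the generated layout, malting-batch effects, and
an omics-mediated contribution M beta for traits with a nonzero omics
variance.

Defaults mirror a two-cycle commercial spring-barley programme: ~600 lines
over 2 years x 2 locations, inbred genotypes (mean G diagonal ~1.85),
0.3% missing SNP calls, a metabolomic feature-heritability mixture with a
~40% zero-heritability mass, and smooth NIR spectra built from eight latent
basis curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genomics import GenotypeMatrix, spatial_kernel
from .spectra import SpectraMatrix

__all__ = ["SimConfig", "SyntheticDataset", "generate_dataset", "truth_report"]


#: per-trait generative variance components; keys are the model symbols.
#: Magnitudes follow the scale of each trait (yield in kg/plot, beta-glucan
#: in mg/L, ...); FS and WC carry no omics-mediated signal, which is what
#: makes the NIR-augmented model degenerate for them.
DEFAULT_VARIANCE_COMPONENTS: dict[str, dict[str, float]] = {
    "GY": dict(sigma_g2=0.008, sigma_l2=0.005, sigma_ig2=0.012,
               sigma_il2=0.006, sigma_s2=0.008, sigma_m2=0.0,
               sigma_omics2=0.015, sigma_e2=0.080),
    "PC": dict(sigma_g2=0.009, sigma_l2=0.006, sigma_ig2=0.015,
               sigma_il2=0.008, sigma_s2=0.010, sigma_m2=0.0,
               sigma_omics2=0.030, sigma_e2=0.120),
    "WV": dict(sigma_g2=2.2e-4, sigma_l2=1e-4, sigma_ig2=2e-4,
               sigma_il2=1e-4, sigma_s2=1e-4, sigma_m2=2e-4,
               sigma_omics2=1e-4, sigma_e2=1.1e-3),
    "BG": dict(sigma_g2=1000.0, sigma_l2=500.0, sigma_ig2=1000.0,
               sigma_il2=500.0, sigma_s2=500.0, sigma_m2=1000.0,
               sigma_omics2=300.0, sigma_e2=7000.0),
    "EY": dict(sigma_g2=0.050, sigma_l2=0.030, sigma_ig2=0.050,
               sigma_il2=0.030, sigma_s2=0.040, sigma_m2=0.080,
               sigma_omics2=0.030, sigma_e2=0.370),
    "FS": dict(sigma_g2=0.010, sigma_l2=0.050, sigma_ig2=0.050,
               sigma_il2=0.050, sigma_s2=0.050, sigma_m2=0.100,
               sigma_omics2=0.0, sigma_e2=0.760),
    "WC": dict(sigma_g2=0.050, sigma_l2=0.010, sigma_ig2=0.020,
               sigma_il2=0.010, sigma_s2=0.010, sigma_m2=0.020,
               sigma_omics2=0.0, sigma_e2=0.120),
}

DEFAULT_TRAIT_MEANS = {
    "GY": 7.19, "PC": 10.75, "WV": 1.47, "BG": 153.0,
    "EY": 82.28, "FS": 4.91, "WC": 5.11,
}

#: feature-heritability mixture: a zero class (empty spectral regions), a
#: moderate class and a high class, with uniform draws inside each range
DEFAULT_OMICS_H2_MIXTURE = {
    "zero_fraction": 0.40,
    "moderate_fraction": 0.50,
    "moderate_range": (0.01, 0.20),
    "high_range": (0.20, 0.90),
}


@dataclass
class SimConfig:
    """Configuration of one synthetic breeding-trial dataset."""

    n_lines: int = 600
    n_snps: int = 8000
    n_cycles: int = 2
    locations: tuple[str, ...] = ("Odder", "Holeby")
    trials_per_env: int = 3
    plots_grid: tuple[int, int] = (10, 12)   # rows x columns per trial
    n_controls: int = 2
    reps_controls: int = 3
    n_mi_features: int = 30000
    n_nir_wavelengths: int = 141
    variance_components: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            t: dict(v) for t, v in DEFAULT_VARIANCE_COMPONENTS.items()
        }
    )
    trait_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRAIT_MEANS)
    )
    omics_h2_mixture: dict = field(
        default_factory=lambda: dict(DEFAULT_OMICS_H2_MIXTURE)
    )
    omics_channel: str = "MI"          # which spectra mediate trait effects
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.003
    inbreeding: float = 0.85           # F6-like panel; mean diag(G) ~ 1 + F
    batch_size: int = 24               # plots per micro-malting batch
    first_year: int = 2021
    fixed_effect_sd_frac: float = 0.5  # trial effect SD as fraction of sd(y)
    seed: int = 0

    def validate(self) -> None:
        for t, vcs in self.variance_components.items():
            for k, v in vcs.items():
                if v < 0:
                    raise ValueError(f"negative variance {k}={v} for {t}")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.omics_channel not in ("MI", "NIR"):
            raise ValueError("omics_channel must be 'MI' or 'NIR'")


@dataclass
class SyntheticDataset:
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    mi: SpectraMatrix
    nir: SpectraMatrix
    truth: dict
    config: SimConfig

    @property
    def candidate_lines(self) -> list[str]:
        return self.truth["candidate_lines"]

    @property
    def control_lines(self) -> list[str]:
        return self.truth["control_lines"]


def _scale_to_var(x: np.ndarray, target: float) -> np.ndarray:
    """Rescale a vector so its sample variance equals ``target`` exactly."""
    if target <= 0:
        return np.zeros_like(x)
    v = np.var(x, ddof=1) if x.size > 1 else 0.0
    if v <= 0:
        return np.zeros_like(x)
    return x * np.sqrt(target / v)


def _draw_genotypes(rng, n_lines, n_snps, maf_range, inbreeding):
    p = rng.uniform(*maf_range, size=n_snps)
    homo = rng.random((n_lines, n_snps)) < inbreeding
    d_out = 2.0 * (rng.random((n_lines, n_snps)) < p)
    d_het = rng.binomial(2, p, size=(n_lines, n_snps)).astype(float)
    return np.where(homo, d_out, d_het), p


def _make_layout(cfg: SimConfig, lines_by_cycle, controls, rng):
    """Randomized incomplete blocks: each candidate line gets one plot per
    environment of its own year; controls are replicated in every trial."""
    rows, cols = cfg.plots_grid
    capacity = rows * cols
    records = []
    plot_counter = 0
    for c in range(cfg.n_cycles):
        year = cfg.first_year + c
        cyc_lines = lines_by_cycle[c]
        for loc in cfg.locations:
            # split this cycle's lines over the trials of the environment
            perm = rng.permutation(len(cyc_lines))
            shuffled = [cyc_lines[i] for i in perm]
            per_trial = [
                shuffled[t :: cfg.trials_per_env]
                for t in range(cfg.trials_per_env)
            ]
            for t in range(cfg.trials_per_env):
                entries = list(per_trial[t]) + [
                    ctl for ctl in controls for _ in range(cfg.reps_controls)
                ]
                if len(entries) > capacity:
                    raise ValueError(
                        f"layout infeasible: trial needs {len(entries)} plots "
                        f"but the grid holds {capacity}"
                    )
                order = rng.permutation(len(entries))
                for k, ei in enumerate(order):
                    records.append(
                        dict(
                            plot_id=f"P{plot_counter + k:05d}",
                            line_id=entries[ei],
                            year=year,
                            location=loc,
                            trial=f"{year}:{loc}:T{t + 1}",
                            row=k // cols + 1,
                            col=k % cols + 1,
                        )
                    )
                plot_counter += len(entries)
    tab = pd.DataFrame.from_records(records)
    tab["env"] = tab["year"].astype(str) + ":" + tab["location"].astype(str)
    tab["batch"] = "B" + (np.arange(len(tab)) // cfg.batch_size).astype(str)
    return tab


def _feature_h2_draws(rng, n_feat, mixture):
    h2 = np.zeros(n_feat)
    u = rng.random(n_feat)
    zf = mixture["zero_fraction"]
    mf = mixture["moderate_fraction"]
    mod = (u >= zf) & (u < zf + mf)
    high = u >= zf + mf
    h2[mod] = rng.uniform(*mixture["moderate_range"], size=int(mod.sum()))
    h2[high] = rng.uniform(*mixture["high_range"], size=int(high.sum()))
    return h2


def _genetic_feature_matrix(rng, q_centered, h2, line_of_plot, env_idx, chunk=1024):
    """Plot x feature matrix with per-feature genomic signal g_f = Q alpha_f
    scaled so the realized plot-level heritability matches h2[f]; the
    non-genetic part is split between an environment-common component and
    plot residual noise."""
    n_snps = q_centered.shape[1]
    n_lines = q_centered.shape[0]
    n_plots = line_of_plot.size
    n_feat = h2.size
    n_env = int(env_idx.max()) + 1 if n_plots else 0
    out = np.empty((n_plots, n_feat))
    gen_lines = np.empty((n_lines, n_feat), dtype=np.float32)
    truth_h2 = np.empty(n_feat)
    for start in range(0, n_feat, chunk):
        stop = min(start + chunk, n_feat)
        m = stop - start
        alpha = rng.standard_normal((n_snps, m))
        gf = q_centered @ alpha                      # line level
        gv = gf.var(axis=0, ddof=1)
        gv[gv <= 0] = 1.0
        gf = gf * np.sqrt(np.where(h2[start:stop] > 0, h2[start:stop], 0.0) / gv)
        noise_var = 1.0 - h2[start:stop]
        env_part = rng.standard_normal((n_env, m)) * np.sqrt(0.3 * noise_var)
        res_part = rng.standard_normal((n_plots, m)) * np.sqrt(0.7 * noise_var)
        block = gf[line_of_plot] + env_part[env_idx] + res_part
        out[:, start:stop] = block
        gen_lines[:, start:stop] = gf
        g_plot_var = gf[line_of_plot].var(axis=0, ddof=1)
        tot = block.var(axis=0, ddof=1)
        truth_h2[start:stop] = np.where(tot > 0, g_plot_var / tot, 0.0)
    return out, gen_lines, truth_h2


def _nir_spectra(rng, cfg, q_centered, line_of_plot, env_idx):
    """Smooth spectra from 8 latent basis curves (low-order polynomials plus
    Gaussian bumps) whose coefficients carry genetic and environmental
    components."""
    n_wl = cfg.n_nir_wavelengths
    wl = np.linspace(950.0, 950.0 + 5.0 * (n_wl - 1), n_wl)
    x = np.linspace(-1.0, 1.0, n_wl)
    n_basis = 8
    basis = [np.polynomial.legendre.Legendre.basis(k)(x) for k in range(4)]
    centers = rng.uniform(-0.8, 0.8, size=n_basis - 4)
    widths = rng.uniform(0.05, 0.25, size=n_basis - 4)
    basis += [np.exp(-0.5 * ((x - c) / w) ** 2) for c, w in zip(centers, widths)]
    basis = np.array(basis)                          # 8 x n_wl
    n_plots = line_of_plot.size
    n_env = int(env_idx.max()) + 1 if n_plots else 0
    coef_h2 = rng.uniform(0.10, 0.35, size=n_basis)
    coefs = np.empty((n_plots, n_basis))
    g_coefs = np.empty((q_centered.shape[0], n_basis))
    for k in range(n_basis):
        g = q_centered @ rng.standard_normal(q_centered.shape[1])
        g = _scale_to_var(g, coef_h2[k])
        env_part = rng.standard_normal(n_env) * np.sqrt(0.3 * (1 - coef_h2[k]))
        res = rng.standard_normal(n_plots) * np.sqrt(0.7 * (1 - coef_h2[k]))
        coefs[:, k] = g[line_of_plot] + env_part[env_idx] + res
        g_coefs[:, k] = g
    values = coefs @ basis + 0.02 * rng.standard_normal((n_plots, n_wl))
    gen_lines = g_coefs @ basis                     # genetic part, line level
    return wl, values, gen_lines


def generate_dataset(cfg: SimConfig) -> SyntheticDataset:
    """Generate one complete synthetic dataset; fully determined by the seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    if cfg.n_lines == 0:
        empty_geno = GenotypeMatrix([], [f"S{i}" for i in range(cfg.n_snps)],
                                    np.empty((0, cfg.n_snps)))
        empty_ph = pd.DataFrame(
            columns=["plot_id", "line_id", "year", "location", "trial",
                     "row", "col", "env", "batch", *cfg.trait_means]
        )
        axis_mi = np.linspace(0.7, 9.0, max(cfg.n_mi_features, 2))[: cfg.n_mi_features]
        mi = SpectraMatrix([], axis_mi, np.empty((0, cfg.n_mi_features)), "MI")
        wl = np.linspace(950, 950 + 5 * (cfg.n_nir_wavelengths - 1),
                         cfg.n_nir_wavelengths)
        nir = SpectraMatrix([], wl, np.empty((0, cfg.n_nir_wavelengths)), "NIR")
        truth = {"candidate_lines": [], "control_lines": [], "traits": {},
                 "feature_h2": np.empty(0), "variance_components": {}}
        return SyntheticDataset(empty_geno, empty_ph, mi, nir, truth, cfg)

    candidates = [f"L{i + 1:04d}" for i in range(cfg.n_lines)]
    controls = [f"CTRL{i + 1}" for i in range(cfg.n_controls)]
    all_lines = candidates + controls
    cyc_of = {
        ln: min(i * cfg.n_cycles // cfg.n_lines, cfg.n_cycles - 1)
        for i, ln in enumerate(candidates)
    }
    lines_by_cycle = [
        [ln for ln in candidates if cyc_of[ln] == c] for c in range(cfg.n_cycles)
    ]

    dosages, p = _draw_genotypes(
        rng, len(all_lines), cfg.n_snps, cfg.maf_range, cfg.inbreeding
    )
    complete = dosages.copy()
    if cfg.missing_rate > 0:
        mask = rng.random(dosages.shape) < cfg.missing_rate
        dosages[mask] = np.nan
    geno = GenotypeMatrix(
        all_lines, [f"S{i + 1:05d}" for i in range(cfg.n_snps)], dosages
    )
    q_centered = complete - complete.mean(axis=0)

    table = _make_layout(cfg, lines_by_cycle, controls, rng)
    line_pos = {ln: i for i, ln in enumerate(all_lines)}
    line_of_plot = table["line_id"].map(line_pos).to_numpy()
    envs = sorted(table["env"].unique())
    env_idx = table["env"].map({e: i for i, e in enumerate(envs)}).to_numpy()
    n_plots = len(table)

    # spatial factor of the generated layout
    s_kern = spatial_kernel(table[["plot_id", "trial", "row", "col"]])
    w_s, u_s = np.linalg.eigh(s_kern.values)
    s_factor = u_s * np.sqrt(np.clip(w_s, 0.0, None))

    # omics features
    h2_feat = _feature_h2_draws(rng, cfg.n_mi_features, cfg.omics_h2_mixture)
    mi_values, mi_gen_lines, realized_feature_h2 = _genetic_feature_matrix(
        rng, q_centered, h2_feat, line_of_plot, env_idx
    )
    axis_mi = np.linspace(0.7, 9.0, cfg.n_mi_features)
    mi = SpectraMatrix(list(table["plot_id"]), axis_mi, mi_values, "MI")
    wl, nir_values, nir_gen_lines = _nir_spectra(
        rng, cfg, q_centered, line_of_plot, env_idx
    )
    nir = SpectraMatrix(list(table["plot_id"]), wl, nir_values, "NIR")

    if cfg.omics_channel == "MI":
        channel = mi_values
        channel_gen = mi_gen_lines
        channel_ok = h2_feat > 0
    else:
        channel = nir_values
        channel_gen = nir_gen_lines
        channel_ok = np.ones(nir_values.shape[1], dtype=bool)

    batches = table["batch"].to_numpy()
    batch_levels = pd.unique(batches)
    batch_idx = pd.Series(batches).map(
        {b: i for i, b in enumerate(batch_levels)}
    ).to_numpy()

    traits_truth = {}
    realized_vc = {}
    for trait, vcs in cfg.variance_components.items():
        g = _scale_to_var(
            q_centered @ rng.standard_normal(cfg.n_snps), vcs["sigma_g2"]
        )
        l_eff = (
            np.sqrt(vcs["sigma_l2"]) * rng.standard_normal(len(all_lines))
            if vcs["sigma_l2"] > 0 else np.zeros(len(all_lines))
        )
        ig = np.zeros((len(envs), len(all_lines)))
        for e in range(len(envs)):
            ig[e] = _scale_to_var(
                q_centered @ rng.standard_normal(cfg.n_snps), vcs["sigma_ig2"]
            )
        il = (
            np.sqrt(vcs["sigma_il2"])
            * rng.standard_normal((len(envs), len(all_lines)))
        )
        s_eff = _scale_to_var(
            s_factor @ rng.standard_normal(n_plots), vcs["sigma_s2"]
        )
        m_eff = (
            np.sqrt(vcs["sigma_m2"]) * rng.standard_normal(len(batch_levels))
            if vcs["sigma_m2"] > 0 else np.zeros(len(batch_levels))
        )
        if vcs.get("sigma_omics2", 0.0) > 0:
            beta = rng.standard_normal(channel.shape[1]) * channel_ok
            med_raw = channel @ beta
            v_raw = np.var(med_raw, ddof=1)
            s_med = np.sqrt(vcs["sigma_omics2"] / v_raw) if v_raw > 0 else 0.0
            med = s_med * (med_raw - med_raw.mean())
            med_gen = s_med * (channel_gen.astype(float) @ beta)
            med_gen -= med_gen.mean()
        else:
            med = np.zeros(n_plots)
            med_gen = np.zeros(len(all_lines))
        e_eff = np.sqrt(vcs["sigma_e2"]) * rng.standard_normal(n_plots)
        sd_y = np.sqrt(sum(vcs.values()))
        trial_levels = pd.unique(table["trial"])
        trial_eff = dict(
            zip(
                trial_levels,
                cfg.fixed_effect_sd_frac
                * sd_y
                * rng.standard_normal(len(trial_levels)),
            )
        )
        y = (
            cfg.trait_means.get(trait, 0.0)
            + table["trial"].map(trial_eff).to_numpy()
            + g[line_of_plot]
            + l_eff[line_of_plot]
            + ig[env_idx, line_of_plot]
            + il[env_idx, line_of_plot]
            + s_eff
            + m_eff[batch_idx]
            + med
            + e_eff
        )
        table[trait] = y
        traits_truth[trait] = {
            "g": pd.Series(g, index=all_lines),
            "g_mediated": pd.Series(med_gen, index=all_lines),
            "g_total": pd.Series(g + med_gen, index=all_lines),
            "omics_mediated": med,
        }
        realized_vc[trait] = {
            "sigma_g2": float(np.var(g, ddof=1)),
            "sigma_l2": float(np.var(l_eff, ddof=1)),
            "sigma_ig2": float(np.var(ig, ddof=1)),
            "sigma_il2": float(np.var(il, ddof=1)),
            "sigma_s2": float(np.var(s_eff, ddof=1)),
            "sigma_m2": float(np.var(m_eff, ddof=1)) if len(batch_levels) > 1 else 0.0,
            "sigma_omics2": float(np.var(med, ddof=1)),
            "sigma_e2": float(np.var(e_eff, ddof=1)),
        }

    truth = {
        "candidate_lines": candidates,
        "control_lines": controls,
        "cycle_of_line": cyc_of,
        "traits": traits_truth,
        "variance_components": realized_vc,
        "configured_vc": {t: dict(v) for t, v in cfg.variance_components.items()},
        "feature_h2_target": h2_feat,
        "feature_h2": realized_feature_h2,
    }
    return SyntheticDataset(geno, table, mi, nir, truth, cfg)


def truth_report(ds: SyntheticDataset) -> pd.DataFrame:
    """Realized variance components per trait and realized heritability per
    omics feature, for parameter-recovery checks."""
    if "traits" not in ds.truth:
        raise ValueError("dataset has no recorded truth")
    rows = []
    for trait, vcs in ds.truth["variance_components"].items():
        rows.append({"id": trait, "kind": "trait", **vcs})
    for f, h2 in enumerate(ds.truth["feature_h2"]):
        rows.append({"id": f"MI{f + 1}", "kind": "feature", "h2": float(h2)})
    return pd.DataFrame(rows)
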