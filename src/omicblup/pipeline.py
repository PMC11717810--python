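"""End-to-end orchestration: QC -> kernels -> fits -> heritability -> CV.

Every stage writes plain-TSV artefacts into the output directory and a
manifest records seeds, thresholds and every design switch in effect.
Numeric tables are written at full precision; presentation rounding (2
decimals for heritabilities, 1 for percent changes) happens only in the
summary tables, which declare it in a header comment.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .config import RunConfig
from .genomics import impute_mean_dosage, snp_qc, spatial_kernel, vanraden_g
from .heritability import h2_plot_level, round2
from .models import MALTING_TRAITS, ensure_env, fit_gblup, fit_goblup, gebv
from .simulate import generate_dataset
from .spectra import mi_kernel, nir_kernel, normalize_columns, savgol_first_derivative
from .validation import compare_models, make_folds, make_lbco, run_cv

__all__ = ["pipeline", "load_inputs", "build_kernels", "goblup_heritability"]

log = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "kernels", "fit", "h2", "cv", "report")


def load_inputs(cfg: RunConfig) -> dict:
    """Load files or generate the synthetic dataset declared in the config."""
    ctx: dict = {"config": cfg}
    if cfg.simulate is not None:
        ds = generate_dataset(cfg.sim_config())
        ctx.update(
            genotypes=ds.genotypes,
            phenotypes=ds.phenotypes,
            mi=ds.mi,
            nir=ds.nir,
            dataset=ds,
            controls=ds.control_lines,
            cycle_of_line=ds.truth.get("cycle_of_line", {}),
        )
    else:
        ctx["genotypes"] = tio.read_genotypes(cfg.genotypes, strict=False)
        ctx["phenotypes"] = tio.read_phenotypes(cfg.phenotypes)
        ctx["mi"] = (
            tio.read_spectra(cfg.mi_spectra, "MI") if cfg.mi_spectra else None
        )
        ctx["nir"] = (
            tio.read_spectra(cfg.nir_spectra, "NIR") if cfg.nir_spectra else None
        )
        ctx["controls"] = []
        ph = ctx["phenotypes"]
        first_year = {
            ln: int(min(g)) for ln, g in ph.groupby("line_id")["year"]
        }
        ctx["cycle_of_line"] = first_year
    ctx["phenotypes"] = ensure_env(ctx["phenotypes"])
    return ctx


def build_kernels(ctx: dict) -> dict:
    """SNP QC + imputation, then G, S and the omics kernels."""
    cfg: RunConfig = ctx["config"]
    geno = snp_qc(ctx["genotypes"], cfg.maf_min, cfg.callrate_min)
    geno = impute_mean_dosage(geno)
    ctx["genotypes_qc"] = geno
    ctx["G"] = vanraden_g(geno)
    ph = ctx["phenotypes"]
    ctx["S"] = spatial_kernel(ph[["plot_id", "trial", "row", "col"]])
    if ctx.get("mi") is not None and ctx["mi"].n_plots >= 2:
        ctx["Q_MI"] = mi_kernel(normalize_columns(ctx["mi"]))
    if ctx.get("nir") is not None and ctx["nir"].n_plots >= 2:
        nir = ctx["nir"]
        if cfg.nir_derivative_first:
            nir = normalize_columns(
                savgol_first_derivative(
                    nir, cfg.savgol_window, cfg.savgol_polyorder
                )
            )
        else:
            nir = savgol_first_derivative(
                normalize_columns(nir), cfg.savgol_window, cfg.savgol_polyorder
            )
            nir = normalize_columns(nir)
        ctx["Q_NIR"] = nir_kernel(nir, cfg.pca_var_target)
    return ctx


def _scalars(ctx: dict, omics: str | None = None) -> dict:
    sc = {
        "d_G": ctx["G"].mean_diag,
        "d_S": ctx["S"].mean_diag,
        "mean_S": ctx["S"].mean_all,
    }
    if omics is not None:
        sc["d_Q"] = ctx[omics].mean_diag
    return sc


def goblup_heritability(fit, scalars: dict, gxe_diag_weight: str = "dG") -> dict:
    """Decomposed heritability h2 = h2_d + c_m2 * h2_M from a two-step fit."""
    vc1, _ = fit.step1
    kind1 = "goblup1_batch" if "sigma2_m" in vc1.estimates else "goblup1"
    rep1 = h2_plot_level(vc1, scalars, kind1, gxe_diag_weight=gxe_diag_weight)
    c_m2 = scalars["d_Q"] * vc1.estimates["sigma2_u"] / rep1.sigma_p2
    vc2, _ = fit.step2
    kind2 = "model2" if "sigma2_m" in vc2.estimates else "model1"
    rep2 = h2_plot_level(vc2, scalars, kind2, gxe_diag_weight=gxe_diag_weight)
    return {
        "h2_d": rep1.h2,
        "c_m2": c_m2,
        "h2_M": rep2.h2,
        "h2": rep1.h2 + c_m2 * rep2.h2,
        "sigma_P1": rep1.sigma_p2,
        "sigma_P2_step2": rep2.sigma_p2,
    }


def _model_inputs(ctx: dict, model: str):
    if model == "GBLUP":
        return None, None
    key = "Q_MI" if model == "GOBLUP-MI" else "Q_NIR"
    if key not in ctx:
        raise ValueError(f"{model} requested but kernel {key} unavailable")
    return key, ctx[key]


def pipeline(cfg: RunConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Execute the requested stages and write artefacts under cfg.outdir."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": cfg.seed,
        "cv_seed": cfg.cv_seed,
        "maf_min": cfg.maf_min,
        "callrate_min": cfg.callrate_min,
        "savgol": [cfg.savgol_window, cfg.savgol_polyorder],
        "nir_derivative_first": cfg.nir_derivative_first,
        "pca_var_target": cfg.pca_var_target,
        "gxe_diag_weight": cfg.gxe_diag_weight,
        "models": cfg.models,
        "traits": cfg.traits,
        "stages": list(stages),
    }
    ctx = load_inputs(cfg)
    ph = ctx["phenotypes"]
    if "simulate" in stages and cfg.simulate is not None:
        tio.write_genotypes(ctx["genotypes"], out / "genotypes.tsv")
        tio.write_phenotypes(ph, out / "phenotypes.tsv")
        if ctx.get("mi") is not None:
            tio.write_spectra(ctx["mi"], out / "mi_spectra.tsv")
        if ctx.get("nir") is not None:
            tio.write_spectra(ctx["nir"], out / "nir_spectra.tsv")
    tio.descriptive_stats(ph, [t for t in cfg.traits if t in ph.columns]).to_csv(
        out / "descriptive_stats.tsv", sep="\t"
    )
    if not (set(stages) & {"qc", "kernels", "fit", "h2", "cv", "report"}):
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return ctx

    build_kernels(ctx)
    ctx["genotypes_qc"].qc_log and manifest.update(
        qc_log=ctx["genotypes_qc"].qc_log
    )
    if "kernels" in stages:
        tio.write_kernel(ctx["G"], out / "kernel_G.tsv")
        tio.write_kernel(ctx["S"], out / "kernel_S.tsv")
        for key in ("Q_MI", "Q_NIR"):
            if key in ctx:
                tio.write_kernel(ctx[key], out / f"kernel_{key}.tsv")

    fits: dict[tuple[str, str], object] = {}
    h2_rows = []
    if set(stages) & {"fit", "h2", "cv", "report"}:
        for trait in cfg.traits:
            for model in cfg.models:
                if model == "GOBLUP-NIR" and trait == "PC" and not cfg.force_pc_nir:
                    log.info(
                        "GOBLUP-NIR is not offered for PC (protein content is "
                        "itself predicted from NIR spectra); skipping"
                    )
                    continue
                key, q = _model_inputs(ctx, model)
                try:
                    if model == "GBLUP":
                        fits[(trait, model)] = fit_gblup(
                            trait, ph, ctx["G"], ctx["S"]
                        )
                    else:
                        fits[(trait, model)] = fit_goblup(
                            trait, ph, ctx["G"], ctx["S"], q,
                            force=cfg.force_pc_nir,
                        )
                except Exception as err:
                    raise RuntimeError(
                        f"stage 'fit' failed for {model}/{trait}: {err}"
                    ) from err
                # heritability per fit
                if model == "GBLUP":
                    vc, _ = fits[(trait, model)]
                    kind = "model2" if trait in MALTING_TRAITS else "model1"
                    rep = h2_plot_level(
                        vc, _scalars(ctx), kind, trait=trait, model=model,
                        gxe_diag_weight=cfg.gxe_diag_weight,
                    )
                    h2_rows.append(
                        dict(trait=trait, model=model, h2=rep.h2,
                             h2_d=np.nan, c_m2=np.nan, h2_M=np.nan,
                             sigma_P2=rep.sigma_p2, converged=vc.converged)
                    )
                else:
                    fit = fits[(trait, model)]
                    if fit.failed:
                        h2_rows.append(
                            dict(trait=trait, model=model, h2=np.nan,
                                 h2_d=np.nan, c_m2=np.nan, h2_M=np.nan,
                                 sigma_P2=np.nan, converged=False)
                        )
                        continue
                    dec = goblup_heritability(
                        fit, _scalars(ctx, key), cfg.gxe_diag_weight
                    )
                    h2_rows.append(
                        dict(trait=trait, model=model, h2=dec["h2"],
                             h2_d=dec["h2_d"], c_m2=dec["c_m2"],
                             h2_M=dec["h2_M"], sigma_P2=dec["sigma_P1"],
                             converged=True)
                    )
        ctx["fits"] = fits
        ctx["h2_table"] = pd.DataFrame(h2_rows)
        if "h2" in stages:
            path = out / "heritability.tsv"
            with open(path, "w") as fh:
                fh.write("# heritabilities rounded half-away-from-zero "
                         "to 2 decimals\n")
                disp = ctx["h2_table"].copy()
                for c in ("h2", "h2_d", "c_m2", "h2_M"):
                    disp[c] = disp[c].map(
                        lambda v: round2(v) if np.isfinite(v) else np.nan
                    )
                disp.to_csv(fh, sep="\t", index=False, na_rep="NA")
        # per-line breeding values
        gebv_rows = {}
        for (trait, model), fit in fits.items():
            if model != "GBLUP" and getattr(fit, "failed", False):
                continue
            gebv_rows[f"{trait}:{model}"] = gebv(fit)
        if gebv_rows:
            pd.DataFrame(gebv_rows).to_csv(
                out / "gebv.tsv", sep="\t", na_rep="NA",
                index_label="line_id", float_format="%.6g",
            )

    if set(stages) & {"cv", "report"} and cfg.cv_schemes:
        candidates = [
            ln for ln in ctx["G"].entity_ids
            if ln not in set(ctx["controls"])
            and ln in set(ph["line_id"].astype(str))
        ]
        cv_rows = []
        for scheme_name in cfg.cv_schemes:
            if scheme_name == "fivefold":
                scheme = make_folds(
                    candidates, cfg.cv_folds, cfg.cv_seed,
                    cycles={
                        ln: ctx["cycle_of_line"].get(ln, 0)
                        for ln in candidates
                    },
                )
            elif scheme_name == "lbco":
                scheme = make_lbco(
                    {ln: ctx["cycle_of_line"].get(ln, 0) for ln in candidates}
                )
            else:
                raise ValueError(f"unknown CV scheme {scheme_name!r}")
            for trait in cfg.traits:
                per_fold = {}
                for model in cfg.models:
                    if model == "GOBLUP-NIR" and trait == "PC" and not cfg.force_pc_nir:
                        continue
                    key, q = _model_inputs(ctx, model)
                    try:
                        res = run_cv(
                            scheme, model, trait, ph, ctx["G"], ctx["S"],
                            omics_kernel=q, controls=ctx["controls"],
                            compute_lr=True,
                            bootstrap_reps=cfg.bootstrap_reps,
                            bootstrap_seed=cfg.cv_seed,
                        )
                    except RuntimeError as err:
                        log.warning("CV failed: %s", err)
                        continue
                    per_fold[model] = res.pa_per_fold
                    cv_rows.append(
                        dict(scheme=scheme_name, trait=trait, model=model,
                             PA=res.pa, PA_se=res.pa_se, b_wp=res.b_wp,
                             b_wp_se=res.b_wp_se, n_lines=res.n_lines,
                             **{f"lr_{k.replace('/', '_')}": v
                                for k, v in res.lr_ratios.items()})
                    )
                if len(per_fold) >= 2 and all(
                    len(v) >= 2 for v in per_fold.values()
                ):
                    letters = compare_models(per_fold)
                    for row in cv_rows:
                        if row["scheme"] == scheme_name and row["trait"] == trait:
                            row["letters"] = letters.get(row["model"], "")
        ctx["cv_table"] = pd.DataFrame(cv_rows)
        with open(out / "cv_results.tsv", "w") as fh:
            fh.write("# full precision; round PA to 2 decimals for display\n")
            ctx["cv_table"].to_csv(fh, sep="\t", index=False, na_rep="NA")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return ctx
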