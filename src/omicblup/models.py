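"""Model families: GBLUP and the two-step omics-augmented GOBLUP.

GBLUP fits the multi-kernel mixed model with terms g (genomic, kernel G),
l (line, identity), i_g (genomic-by-environment, block-diagonal G), i_l
(line-by-environment, identity), s (spatial, kernel S) and, for malting
traits, m (malting batch, identity).

GOBLUP adds a plot-level omics term u with kernel Q (metabolomic
cross-product or NIR principal-component kernel) in step 1, then refits the
identical model structure (without the omics term) to the predicted omics
effects u-hat in step 2.  Combined breeding values are GEBV = g1 + g2: the
direct genomic effect plus the omics-mediated genomic effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .kernels import KernelMatrix
from .lmm import (
    BlupSolution,
    ModelSpec,
    RandomTerm,
    VCEstimates,
    blup_solve,
    build_design,
    reml_fit,
)

__all__ = [
    "TRAITS",
    "MALTING_TRAITS",
    "GoblupFit",
    "ensure_env",
    "model_spec",
    "fit_gblup",
    "fit_goblup",
    "gebv",
]

log = logging.getLogger(__name__)

TRAITS = ("GY", "PC", "WV", "BG", "EY", "FS", "WC")
#: traits measured after micro-malting; their models carry a batch term
MALTING_TRAITS = frozenset({"WV", "BG", "EY", "FS", "WC"})

FIXED_FACTORS = ["year", "location", "trial"]


def ensure_env(table: pd.DataFrame) -> pd.DataFrame:
    """Add the environment column (year x location) if absent."""
    if "env" not in table.columns:
        table = table.copy()
        table["env"] = (
            table["year"].astype(str) + ":" + table["location"].astype(str)
        )
    return table


def model_spec(
    trait: str,
    g_kernel: KernelMatrix,
    s_kernel: KernelMatrix,
    omics_kernel: KernelMatrix | None = None,
    malting_batch: bool | None = None,
    response: str | None = None,
) -> ModelSpec:
    """Assemble the declarative model for one trait.

    ``malting_batch`` defaults to whether the trait is a malting trait;
    passing an ``omics_kernel`` adds the plot-level omics term (step 1 of
    GOBLUP, or the feature-heritability models when the response is a
    spectral feature).
    """
    if malting_batch is None:
        malting_batch = trait in MALTING_TRAITS
    terms = []
    if omics_kernel is not None:
        terms.append(
            RandomTerm("u", "plot_id", omics_kernel, variance_symbol="sigma2_u")
        )
    terms += [
        RandomTerm("g", "line_id", g_kernel, variance_symbol="sigma2_g"),
        RandomTerm("l", "line_id", None, variance_symbol="sigma2_l"),
        RandomTerm("i_g", ("line_id", "env"), g_kernel, variance_symbol="sigma2_ig"),
        RandomTerm("i_l", ("line_id", "env"), None, variance_symbol="sigma2_il"),
        RandomTerm("s", "plot_id", s_kernel, variance_symbol="sigma2_s"),
    ]
    if malting_batch:
        terms.append(RandomTerm("m", "batch", None, variance_symbol="sigma2_m"))
    return ModelSpec(response=response or trait, fixed=FIXED_FACTORS, random=terms)


def fit_gblup(
    trait: str,
    table: pd.DataFrame,
    g_kernel: KernelMatrix,
    s_kernel: KernelMatrix,
    malting_batch: bool | None = None,
    **reml_kw,
) -> tuple[VCEstimates, BlupSolution]:
    """Fit the purely genomic model for one trait."""
    table = ensure_env(table)
    spec = model_spec(trait, g_kernel, s_kernel, malting_batch=malting_batch)
    if any(t.name == "m" for t in spec.random) and "batch" not in table.columns:
        raise KeyError("malting-batch term requested but 'batch' column absent")
    design = build_design(table, spec)
    vc = reml_fit(design, **reml_kw)
    blup = blup_solve(design, vc)
    return vc, blup


@dataclass
class GoblupFit:
    """Two-step omics-augmented fit."""

    trait: str
    omics_kind: str                   # "MI" or "NIR"
    step1: tuple[VCEstimates, BlupSolution]
    step2: tuple[VCEstimates, BlupSolution] | None
    gebv_combined: pd.Series | None
    failed: bool = False
    failure_reason: str = ""

    @property
    def uhat(self) -> pd.Series:
        return self.step1[1].effects["u"]


def fit_goblup(
    trait: str,
    table: pd.DataFrame,
    g_kernel: KernelMatrix,
    s_kernel: KernelMatrix,
    omics_kernel: KernelMatrix,
    malting_batch: bool | None = None,
    force: bool = False,
    step2_level: str = "plot",
    step2_table: pd.DataFrame | None = None,
    **reml_kw,
) -> GoblupFit:
    """Fit GOBLUP: step 1 with the omics term, step 2 on the predicted u-hat.

    The NIR variant is refused for protein content (PC is itself predicted
    from NIR spectra) unless ``force=True``.  When the omics variance
    collapses to the boundary in step 1 the fit is reported as failed for
    the trait, with step 2 skipped.  ``step2_table`` overrides the rows the
    step-2 refit sees: plots outside the step-1 training set receive their
    kernel-predicted u-hat as response (this is how omics information on
    unphenotyped material enters the combined breeding values).
    """
    omics_kind = "NIR" if omics_kernel.kind == "Q_NIR" else "MI"
    if trait == "PC" and omics_kind == "NIR" and not force:
        raise ValueError(
            "GOBLUP-NIR is not offered for PC: protein content is itself "
            "predicted from NIR spectra (pass force=True to override)"
        )
    table = ensure_env(table)
    spec1 = model_spec(
        trait, g_kernel, s_kernel, omics_kernel=omics_kernel,
        malting_batch=malting_batch,
    )
    design1 = build_design(table, spec1)
    vc1 = reml_fit(design1, **reml_kw)
    blup1 = blup_solve(design1, vc1)
    if "sigma2_u" in vc1.boundary:
        log.warning(
            "GOBLUP-%s %s: omics variance converged to the boundary; "
            "fit reported failed",
            omics_kind,
            trait,
        )
        return GoblupFit(
            trait,
            omics_kind,
            (vc1, blup1),
            None,
            None,
            failed=True,
            failure_reason="omics variance converged towards zero in step 1",
        )
    # step 2: same structure minus the omics term, response = predicted
    # omics effect at each observation (plot level), optionally aggregated
    # to line means first
    if step2_table is not None:
        t2 = ensure_env(step2_table.copy())
        uhat_all = blup1.effects["u"]
        t2["_uhat"] = t2["plot_id"].astype(str).map(uhat_all).to_numpy()
        if t2["_uhat"].isna().any():
            raise KeyError("step2_table contains plots absent from the omics kernel")
    else:
        t2 = design1.table.copy()
        t2["_uhat"] = blup1.fitted_random["u"]
    if step2_level == "line":
        t2["_uhat"] = t2.groupby("line_id")["_uhat"].transform("mean")
    elif step2_level != "plot":
        raise ValueError("step2_level must be 'plot' or 'line'")
    spec2 = model_spec(
        trait, g_kernel, s_kernel, malting_batch=malting_batch,
        response="_uhat",
    )
    design2 = build_design(t2, spec2)
    vc2 = reml_fit(design2, **reml_kw)
    blup2 = blup_solve(design2, vc2)
    g1 = blup1.effects["g"]
    g2 = blup2.effects["g"]
    combined = g1.add(g2, fill_value=0.0).reindex(g_kernel.entity_ids)
    return GoblupFit(trait, omics_kind, (vc1, blup1), (vc2, blup2), combined)


def gebv(fit: GoblupFit | tuple[VCEstimates, BlupSolution]) -> pd.Series:
    """Per-line breeding values: g for GBLUP, g1 + g2 for GOBLUP."""
    if isinstance(fit, GoblupFit):
        if fit.failed or fit.gebv_combined is None:
            raise ValueError(f"GOBLUP fit failed for {fit.trait}: {fit.failure_reason}")
        return fit.gebv_combined
    _, blup = fit
    return blup.effects["g"]
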