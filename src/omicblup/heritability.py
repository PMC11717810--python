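"""Heritability and variance-ratio computation.

Plot-level narrow-sense heritability is

    h2 = d(G) * sigma2_g / sigma2_P,

where d(G) is the mean diagonal of the genomic relationship matrix and the
assembled phenotypic variance weights each component by the mean diagonal of
its kernel:

    sigma2_P = d(G) sigma2_g + sigma2_l + w_ige * sigma2_ig + sigma2_il
               + (d(S) - mean(S)) * sigma2_s + sigma2_e
               [+ sigma2_m]  [+ d(Q) * sigma2_u],

with the batch term for malting traits and the omics term for the
omics-augmented step-1 model.  The G-by-environment weight ``w_ige``
defaults to d(G); a published variant uses 1, selectable via
``gxe_diag_weight``.  The omics-augmented decomposition is

    h2 = h2_d + c_m2 * h2_M,

direct heritability plus the omics variance ratio times the heritability of
the omics-predicted component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lmm import ModelSpec, VCEstimates, build_design, reml_fit

__all__ = [
    "HeritabilityReport",
    "assemble_sigma_p",
    "h2_plot_level",
    "goblup_decomposition",
    "h2_significance_threshold",
    "round2",
]


def round2(x: float, ndigits: int = 2) -> float:
    """Presentation rounding, half away from zero."""
    if not math.isfinite(x):
        return x
    factor = 10**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


@dataclass
class HeritabilityReport:
    trait: str
    model: str
    h2: float
    sigma_p2: float
    h2_d: float | None = None
    c_m2: float | None = None
    h2_M: float | None = None
    scalars: dict = field(default_factory=dict)
    weights: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        return {
            "trait": self.trait,
            "model": self.model,
            "h2": self.h2,
            "h2_d": self.h2_d,
            "c_m2": self.c_m2,
            "h2_M": self.h2_M,
            "sigma_P2": self.sigma_p2,
        }


def _component_weights(
    scalars: dict[str, float],
    model_kind: str,
    gxe_diag_weight: str = "dG",
) -> dict[str, float]:
    """Per-variance weights entering sigma2_P for a given model family.

    ``model_kind`` is one of {"model1", "model2", "goblup1", "goblup1_batch",
    "goblup2", "goblup2_batch"}; batch variants add sigma2_m, the omics
    step-1 variants add d(Q) * sigma2_u.  ``"auto"`` (resolved by
    ``assemble_sigma_p``) weights whichever components were fitted.
    """
    d_g = scalars["d_G"]
    w_ige = d_g if gxe_diag_weight == "dG" else 1.0
    w = {
        "sigma2_g": d_g,
        "sigma2_l": 1.0,
        "sigma2_ig": w_ige,
        "sigma2_il": 1.0,
        "sigma2_s": scalars["d_S"] - scalars["mean_S"],
        "sigma2_e": 1.0,
    }
    if "batch" in model_kind or model_kind == "model2":
        w["sigma2_m"] = 1.0
    if model_kind.startswith("goblup1"):
        w["sigma2_u"] = scalars["d_Q"]
    return w


def assemble_sigma_p(
    vc: VCEstimates | dict[str, float],
    scalars: dict[str, float],
    model_kind: str = "model1",
    gxe_diag_weight: str = "dG",
) -> tuple[float, dict[str, float]]:
    """Weighted sum of variance components: the assembled phenotypic variance.

    Returns (sigma2_P, weights used).  Components absent from ``vc`` with a
    defined weight raise; extra fitted components without a weight are
    ignored (they do not enter this model family's sigma2_P).
    """
    est = vc.estimates if isinstance(vc, VCEstimates) else dict(vc)
    if model_kind == "auto":
        d_g = scalars["d_G"]
        w_ige = d_g if gxe_diag_weight == "dG" else 1.0
        per = {
            "sigma2_g": d_g,
            "sigma2_ig": w_ige,
            "sigma2_s": lambda: scalars["d_S"] - scalars["mean_S"],
            "sigma2_u": lambda: scalars["d_Q"],
        }
        weights = {}
        for name in est:
            w = per.get(name, 1.0)
            weights[name] = w() if callable(w) else w
    else:
        weights = _component_weights(scalars, model_kind, gxe_diag_weight)
    total = 0.0
    for name, w in weights.items():
        if name not in est:
            raise KeyError(f"variance component '{name}' missing for {model_kind}")
        total += w * est[name]
    return total, weights


def h2_plot_level(
    vc: VCEstimates | dict[str, float],
    scalars: dict[str, float],
    model_kind: str = "model1",
    trait: str = "",
    model: str = "GBLUP",
    gxe_diag_weight: str = "dG",
) -> HeritabilityReport:
    """h2 = d(G) sigma2_g / sigma2_P at the single-plot level."""
    est = vc.estimates if isinstance(vc, VCEstimates) else dict(vc)
    sigma_p2, weights = assemble_sigma_p(est, scalars, model_kind, gxe_diag_weight)
    if sigma_p2 <= 0:
        raise ZeroDivisionError("assembled phenotypic variance is zero")
    h2 = scalars["d_G"] * est["sigma2_g"] / sigma_p2
    return HeritabilityReport(
        trait=trait,
        model=model,
        h2=h2,
        sigma_p2=sigma_p2,
        scalars=dict(scalars),
        weights=weights,
    )


def goblup_decomposition(h2_d: float, c_m2: float, h2_M: float) -> float:
    """Combined heritability h2 = h2_d + c_m2 * h2_M."""
    return h2_d + c_m2 * h2_M


def h2_significance_threshold(
    spec: ModelSpec,
    table: pd.DataFrame,
    vc_null: VCEstimates | dict[str, float],
    scalars: dict[str, float],
    alpha: float = 0.01,
    n_sim: int = 1000,
    seed: int = 0,
    model_kind: str = "auto",
    max_iter: int = 60,
) -> dict:
    """Simulation-based null threshold for feature heritability.

    Phenotype vectors are simulated from the fitted null model (additive
    genomic variance forced to zero; every other component drawn at its
    estimated variance on the real design), the full model is refitted to
    each, and the empirical (1 - alpha) quantile of the resulting h2
    estimates is the significance threshold.  Refit failures are counted;
    above 10% the threshold is flagged unreliable.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100")
    est = dict(vc_null.estimates if isinstance(vc_null, VCEstimates) else vc_null)
    est["sigma2_g"] = 0.0
    design = build_design(table, spec)
    rng = np.random.default_rng(seed)
    n = design.n_obs
    # factor each term's observation-level covariance once
    factors = []
    for bt in design.terms:
        sig = est.get(bt.term.variance_symbol, 0.0)
        if sig <= 0 or bt.term.name == "g":
            continue
        w, u = np.linalg.eigh(bt.vmat)
        w = np.clip(w, 0.0, None)
        factors.append((u * np.sqrt(w), sig))
    sigma_e = est.get("sigma2_e", 0.0)
    h2_null = []
    failures = 0
    for _ in range(n_sim):
        y = np.zeros(n)
        for l_fac, sig in factors:
            y += math.sqrt(sig) * (l_fac @ rng.standard_normal(n))
        y += math.sqrt(max(sigma_e, 1e-12)) * rng.standard_normal(n)
        sim = design.table.copy()
        sim[spec.response] = y
        try:
            d_sim = build_design(sim, spec)
            vc_sim = reml_fit(d_sim, max_iter=max_iter)
            rep = h2_plot_level(vc_sim, scalars, model_kind)
            h2_null.append(rep.h2)
        except Exception:
            failures += 1
    if not h2_null:
        raise RuntimeError("all null refits failed")
    h2_null = np.asarray(h2_null)
    threshold = float(np.quantile(h2_null, 1.0 - alpha))
    return {
        "threshold": threshold,
        "alpha": alpha,
        "n_sim": n_sim,
        "n_failures": failures,
        "reliable": failures <= 0.10 * n_sim,
        "null_h2": h2_null,
    }
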