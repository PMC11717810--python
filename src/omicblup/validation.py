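"""Cross-validation, predictive ability, dispersion, LR accuracy ratios.

Two masking schemes are supported: fivefold (random 20% of candidate lines
masked per fold, stratified by breeding cycle) and leave-one-breeding-cycle-
out (all lines of one crossing year masked together).  For omics-augmented
models, validation lines contribute neither phenotype nor omics rows to the
training fits.

Predictive ability is the Pearson correlation between masked lines'
breeding values and their fixed-effect-corrected phenotype line means y_c.
Dispersion is the regression b_wp = cov(g_w, g_p)/var(g_p) of whole- on
partial-information breeding values.  The LR-method ratios compare breeding
values across nested information states in the validation set: genomic
only (g), + omics (gm), + phenotypes (gp / gmp); ratios near one mean the
added information changes nothing.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .kernels import KernelMatrix
from .lmm import build_design
from .models import GoblupFit, ensure_env, fit_gblup, fit_goblup, gebv, model_spec

__all__ = [
    "CVScheme",
    "CVResult",
    "make_folds",
    "make_lbco",
    "corrected_phenotypes",
    "run_cv",
    "dispersion_slope",
    "bootstrap_se",
    "compare_models",
    "percent_change",
    "audit_masking",
]

log = logging.getLogger(__name__)


@dataclass
class CVScheme:
    kind: str                  # "fivefold" | "lbco"
    folds: dict[str, int]      # candidate line -> fold index
    n_folds: int
    seed: int | None = None

    def validation_lines(self, fold: int) -> list[str]:
        return [ln for ln, f in self.folds.items() if f == fold]


def make_folds(
    lines: list[str],
    k: int = 5,
    seed: int = 0,
    cycles: dict[str, int] | None = None,
) -> CVScheme:
    """Random near-equal partition of candidate lines into k folds.

    With ``cycles`` given, the partition is stratified by breeding cycle so
    every fold contains lines of every cycle (prevents a random fold from
    degenerating into a leave-cycle-out run).
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    if len(lines) < k:
        raise ValueError("fewer lines than folds")
    rng = np.random.default_rng(seed)
    folds: dict[str, int] = {}
    if cycles is None:
        strata = [list(lines)]
    else:
        by_cyc: dict[int, list[str]] = {}
        for ln in lines:
            by_cyc.setdefault(cycles[ln], []).append(ln)
        strata = list(by_cyc.values())
    counter = 0
    for group in strata:
        order = rng.permutation(len(group))
        for j, idx in enumerate(order):
            folds[group[idx]] = (counter + j) % k
        counter += len(group)
    return CVScheme("fivefold", folds, k, seed)


def make_lbco(cycle_of_line: dict[str, int]) -> CVScheme:
    """One run per breeding cycle; a line belonging to several cycles is
    masked with its first (earliest) cycle."""
    cycles = sorted(set(cycle_of_line.values()))
    if len(cycles) < 2:
        raise ValueError("leave-cycle-out needs at least 2 cycles")
    pos = {c: i for i, c in enumerate(cycles)}
    folds = {ln: pos[c] for ln, c in cycle_of_line.items()}
    return CVScheme("lbco", folds, len(cycles))


def corrected_phenotypes(
    table: pd.DataFrame,
    trait: str,
    g_kernel: KernelMatrix,
    s_kernel: KernelMatrix,
    blup=None,
    malting_batch: bool | None = None,
) -> pd.Series:
    """Fixed-effect-corrected phenotypes y_c, averaged per line.

    y_c(plot) = y - X b_hat with b_hat from the whole-data fit; pass an
    existing ``BlupSolution`` to reuse its fixed effects.
    """
    table = ensure_env(table)
    if blup is None:
        _, blup = fit_gblup(trait, table, g_kernel, s_kernel, malting_batch)
    spec = model_spec(trait, g_kernel, s_kernel, malting_batch=malting_batch)
    design = build_design(table, spec)
    xb = design.x @ blup.fixed.reindex(design.x_columns).to_numpy()
    yc = pd.DataFrame(
        {"line_id": design.table["line_id"].astype(str), "yc": design.y - xb}
    )
    return yc.groupby("line_id")["yc"].mean()


def dispersion_slope(gebv_whole: np.ndarray, gebv_partial: np.ndarray) -> float:
    """b_wp = cov(g_w, g_p) / var(g_p); 1 means no inflation, < 1 means the
    partial breeding values are over-dispersed."""
    gw = np.asarray(gebv_whole, float)
    gp = np.asarray(gebv_partial, float)
    if gw.shape != gp.shape or gw.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    v = np.var(gp, ddof=1)
    if v <= 0:
        raise ZeroDivisionError("partial breeding values have zero variance")
    return float(np.cov(gw, gp, ddof=1)[0, 1] / v)


def bootstrap_se(
    statistic,
    *vectors: np.ndarray,
    n_rep: int = 10000,
    seed: int = 0,
) -> float:
    """Ordinary non-parametric bootstrap SE: resample the paired vectors
    with replacement at full sample size, recompute the statistic per
    replicate; degenerate replicates (zero variance) are dropped."""
    arrs = [np.asarray(v, float) for v in vectors]
    n = arrs[0].size
    if n < 2:
        raise ValueError("need at least two observations")
    rng = np.random.default_rng(seed)
    vals = []
    dropped = 0
    for _ in range(n_rep):
        idx = rng.integers(0, n, size=n)
        try:
            s = statistic(*(a[idx] for a in arrs))
        except (ZeroDivisionError, FloatingPointError):
            dropped += 1
            continue
        if np.isfinite(s):
            vals.append(s)
        else:
            dropped += 1
    if dropped:
        log.info("bootstrap_se: dropped %d degenerate replicates", dropped)
    return float(np.std(vals, ddof=1))


def percent_change(pa_new: float, pa_ref: float) -> float:
    """100 (pa_new - pa_ref) / pa_ref."""
    if pa_ref == 0:
        raise ZeroDivisionError("reference predictive ability is zero")
    return 100.0 * (pa_new - pa_ref) / pa_ref


def audit_masking(train_table: pd.DataFrame, val_lines: set[str],
                  omics_kernel: KernelMatrix | None = None) -> None:
    """Raise if any validation line leaks a phenotype (or omics row) into
    the training data."""
    leak = set(train_table["line_id"].astype(str)) & set(val_lines)
    if leak:
        raise AssertionError(f"validation lines leaked into training: {sorted(leak)}")
    if omics_kernel is not None:
        train_plots = set(train_table["plot_id"].astype(str))
        extra = set(omics_kernel.entity_ids) - train_plots
        # omics kernel restricted to training must cover exactly those plots
        if set(omics_kernel.entity_ids) != train_plots:
            raise AssertionError(
                f"training omics kernel covers non-training plots: "
                f"{sorted(extra)[:5]}..."
            )


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
        raise ZeroDivisionError("degenerate correlation input")
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class CVResult:
    trait: str
    model: str
    scheme: str
    pa: float                         # pooled over all masked lines
    pa_per_fold: list[float]
    b_wp: float
    pa_se: float
    b_wp_se: float
    lr_ratios: dict[str, float] = field(default_factory=dict)
    gebv_partial: pd.Series | None = None
    gebv_whole: pd.Series | None = None
    yc: pd.Series | None = None
    n_lines: int = 0
    failed_folds: list[int] = field(default_factory=list)


def _fit_family(
    family: str,
    trait: str,
    table: pd.DataFrame,
    g_kernel: KernelMatrix,
    s_kernel: KernelMatrix,
    omics_kernel: KernelMatrix | None,
    step2_table: pd.DataFrame | None = None,
    **reml_kw,
) -> pd.Series:
    """Per-line breeding values for one information state."""
    if family == "GBLUP":
        fit = fit_gblup(trait, table, g_kernel, s_kernel, **reml_kw)
        return gebv(fit).reindex(g_kernel.entity_ids)
    if omics_kernel is None:
        raise ValueError(f"{family} requires an omics kernel")
    fit = fit_goblup(
        trait, table, g_kernel, s_kernel, omics_kernel,
        step2_table=step2_table, **reml_kw,
    )
    if fit.failed:
        raise RuntimeError(f"{family} failed for {trait}: {fit.failure_reason}")
    return gebv(fit)


def run_cv(
    scheme: CVScheme,
    family: str,
    trait: str,
    table: pd.DataFrame,
    g_kernel: KernelMatrix,
    s_kernel: KernelMatrix,
    omics_kernel: KernelMatrix | None = None,
    controls: list[str] | None = None,
    compute_lr: bool = False,
    bootstrap_reps: int = 10000,
    bootstrap_seed: int = 0,
    **reml_kw,
) -> CVResult:
    """Run one cross-validation for one trait and one model family.

    Per fold, variance components and effects are refitted on the training
    observations only (validation plots contribute neither phenotype nor
    omics rows), breeding values of masked lines are predicted through G,
    and the headline predictive ability is the pooled correlation over all
    masked candidate lines.  With ``compute_lr=True`` the additional
    information states needed for the LR accuracy ratios are fitted.
    """
    table = ensure_env(table)
    controls = set(map(str, controls or []))
    # whole-information fit (phenotypes (+ omics) for everyone)
    whole = _fit_family(
        family, trait, table, g_kernel, s_kernel, omics_kernel, **reml_kw
    )
    if family == "GBLUP":
        _, blup_whole = fit_gblup(trait, table, g_kernel, s_kernel, **reml_kw)
    else:
        blup_whole = None
    yc = corrected_phenotypes(
        table, trait, g_kernel, s_kernel, blup=blup_whole
    )

    partial = pd.Series(np.nan, index=g_kernel.entity_ids, dtype=float)
    partial_gm = pd.Series(np.nan, index=g_kernel.entity_ids, dtype=float)
    pa_per_fold = []
    failed_folds = []
    for fold in range(scheme.n_folds):
        val = [ln for ln in scheme.validation_lines(fold) if ln not in controls]
        if not val:
            continue
        val_set = set(val)
        train = table[~table["line_id"].astype(str).isin(val_set)].reset_index(
            drop=True
        )
        q_train = None
        if omics_kernel is not None:
            q_train = omics_kernel.reindex(list(train["plot_id"].astype(str)))
        audit_masking(train, val_set, q_train if family != "GBLUP" else None)
        try:
            g_p = _fit_family(
                family, trait, train, g_kernel, s_kernel, q_train, **reml_kw
            )
        except RuntimeError as err:
            log.warning("fold %d failed: %s", fold, err)
            failed_folds.append(fold)
            continue
        partial.loc[val] = g_p.reindex(val).to_numpy()
        in_yc = [ln for ln in val if ln in yc.index]
        if len(in_yc) >= 3:
            try:
                pa_per_fold.append(
                    _pearson(g_p.reindex(in_yc), yc.reindex(in_yc))
                )
            except ZeroDivisionError:
                pa_per_fold.append(float("nan"))
        if compute_lr and family != "GBLUP":
            # omics (but not phenotypes) available for validation plots:
            # step 1 trains on TP rows with the full-plot kernel, step 2
            # additionally sees the kernel-predicted u-hat of VP plots
            g_gm = _fit_family(
                family, trait, train, g_kernel, s_kernel, omics_kernel,
                step2_table=table, **reml_kw,
            )
            partial_gm.loc[val] = g_gm.reindex(val).to_numpy()

    masked = partial.dropna()
    eval_lines = [ln for ln in masked.index if ln in yc.index]
    if len(eval_lines) < 3:
        raise ValueError("too few masked lines with corrected phenotypes")
    gp_v = masked.reindex(eval_lines).to_numpy()
    yc_v = yc.reindex(eval_lines).to_numpy()
    gw_v = whole.reindex(eval_lines).to_numpy()
    pa = _pearson(gp_v, yc_v)
    b_wp = dispersion_slope(gw_v, gp_v)
    pa_se = bootstrap_se(
        _pearson, gp_v, yc_v, n_rep=bootstrap_reps, seed=bootstrap_seed
    )
    b_wp_se = bootstrap_se(
        dispersion_slope, gw_v, gp_v, n_rep=bootstrap_reps,
        seed=bootstrap_seed + 1,
    )
    lr = {}
    if compute_lr:
        if family == "GBLUP":
            lr["g/gp"] = _pearson(gp_v, gw_v)
        else:
            gm_v = partial_gm.reindex(eval_lines).to_numpy()
            lr["g/gm"] = _pearson(gp_v, gm_v)
            lr["gm/gmp"] = _pearson(gm_v, gw_v)
            lr["g/gmp"] = _pearson(gp_v, gw_v)
    return CVResult(
        trait=trait,
        model=family,
        scheme=scheme.kind,
        pa=pa,
        pa_per_fold=pa_per_fold,
        b_wp=b_wp,
        pa_se=pa_se,
        b_wp_se=b_wp_se,
        lr_ratios=lr,
        gebv_partial=masked,
        gebv_whole=whole.reindex(masked.index),
        yc=yc.reindex(eval_lines),
        n_lines=len(eval_lines),
        failed_folds=failed_folds,
    )


def compare_models(
    pa_per_fold: dict[str, list[float]], alpha: float = 0.01
) -> dict[str, str]:
    """Pairwise two-tailed paired t-tests on per-fold predictive ability
    with a compact letter display: models sharing a letter are not
    significantly different at ``alpha``.

    With fewer than 2 paired folds the test is not applicable and every
    model shares one letter.
    """
    models = list(pa_per_fold)
    n_folds = min(len(v) for v in pa_per_fold.values())
    different: set[tuple[str, str]] = set()
    if n_folds >= 2:
        for a, b in itertools.combinations(models, 2):
            x = np.asarray(pa_per_fold[a][:n_folds], float)
            y = np.asarray(pa_per_fold[b][:n_folds], float)
            d = x - y
            if np.allclose(d, 0):
                continue
            p = stats.ttest_rel(x, y).pvalue
            if np.isfinite(p) and p < alpha:
                different.add((a, b))
                different.add((b, a))
    # greedy compact-letter assignment: order-preserving insertion of each
    # model into the first letter group it does not conflict with
    groups: list[list[str]] = []
    for m in models:
        placed = False
        for grp in groups:
            if all((m, other) not in different for other in grp):
                grp.append(m)
                placed = True
        if not placed:
            groups.append([m])
    letters = {m: "" for m in models}
    for gi, grp in enumerate(groups):
        for m in grp:
            letters[m] += chr(ord("a") + gi)
    return letters
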