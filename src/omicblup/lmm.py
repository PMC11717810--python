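"""Linear mixed-model machinery: design construction, AI-REML, and BLUP.

The model is the standard multi-kernel mixed model

    y = X b + sum_i Z_i a_i + e,     a_i ~ N(0, K_i sigma_i^2),
                                     e   ~ N(0, I sigma_e^2),

where each random term binds an observation-to-entity incidence (line,
line-by-environment pair, plot, or malting batch) to a similarity kernel
(G, identity, block-diagonal copies of G over environments, spatial S, or
an omics kernel).  Variance components are estimated by restricted maximum
likelihood with average-information (AI) updates, step-halving, and an
EM-REML fallback; effects are solved as BLUPs at the fitted variances,
a_i = sigma_i^2 K_i Z_i' P y, which also yields predictions for kernel
entities that carry no observations (masked lines in cross-validation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .kernels import KernelMatrix

__all__ = [
    "RandomTerm",
    "ModelSpec",
    "VCEstimates",
    "BlupSolution",
    "DesignData",
    "build_design",
    "reml_fit",
    "blup_solve",
]

log = logging.getLogger(__name__)

#: a variance is pinned to BOUNDARY_FRAC * var(y) when it collapses
BOUNDARY_FRAC = 1e-6
REL_PARAM_TOL = 1e-8
LOGLIK_TOL = 1e-6
MAX_ITER = 200


@dataclass
class RandomTerm:
    """Declarative random term.

    ``key`` names the observation column mapping each row to an entity; a
    2-tuple ``(entity_col, env_col)`` declares an interaction whose kernel is
    block-diagonal over the second factor (independent copies of ``kernel``
    per environment).  ``kernel=None`` means an identity kernel over the
    observed levels of ``key``.
    """

    name: str
    key: str | tuple[str, str]
    kernel: KernelMatrix | None = None
    variance_symbol: str = ""

    def __post_init__(self) -> None:
        if not self.variance_symbol:
            self.variance_symbol = f"sigma2_{self.name}"


@dataclass
class ModelSpec:
    """Response column, fixed-factor columns (combined into one factor),
    and the list of random terms.  Residual variance symbol is implicit."""

    response: str
    fixed: list[str]
    random: list[RandomTerm]


@dataclass
class _BuiltTerm:
    term: RandomTerm
    levels: list           # labels of the kernel/identity levels
    obs_level: np.ndarray  # observation -> level index
    vmat: np.ndarray       # Z K Z' over kept observations
    n_levels: int
    # for interaction terms: (base kernel matrix, env of each level,
    # base-entity index of each level) to rebuild effects lazily
    structure: tuple | None = None


@dataclass
class DesignData:
    """Assembled numeric design for one response."""

    y: np.ndarray
    x: np.ndarray
    x_columns: list[str]
    terms: list[_BuiltTerm]
    obs_index: np.ndarray       # positions of kept rows in the input table
    table: pd.DataFrame         # kept rows
    n_dropped_missing: int

    @property
    def n_obs(self) -> int:
        return self.y.size


@dataclass
class VCEstimates:
    estimates: dict[str, float]
    se: dict[str, float]
    loglik: float
    converged: bool
    boundary: list[str]
    iterations: int
    n_obs: int

    def __getitem__(self, name: str) -> float:
        return self.estimates[name]


@dataclass
class BlupSolution:
    fixed: pd.Series
    effects: dict[str, pd.Series]
    fitted_random: dict[str, np.ndarray] = field(default_factory=dict)


def _fixed_design(table: pd.DataFrame, fixed: list[str]) -> tuple[np.ndarray, list[str]]:
    """Single combined fixed factor, reference-level parameterisation."""
    if not fixed:
        return np.ones((len(table), 1)), ["intercept"]
    combo = (
        table[fixed].astype(str).agg(":".join, axis=1)
        if len(fixed) > 1
        else table[fixed[0]].astype(str)
    )
    levels = sorted(combo.unique())
    cols = [np.ones(len(table))]
    names = ["intercept"]
    for lev in levels[1:]:
        cols.append((combo == lev).to_numpy(dtype=float))
        names.append(f"{':'.join(fixed)}[{lev}]")
    x = np.column_stack(cols)
    # drop linearly dependent columns (can appear after CV subsetting)
    q, r = np.linalg.qr(x)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    if not keep.all():
        x = x[:, keep]
        names = [n for n, k in zip(names, keep) if k]
    return x, names


def _build_term(term: RandomTerm, table: pd.DataFrame) -> _BuiltTerm:
    if isinstance(term.key, tuple):
        ent_col, env_col = term.key
        for c in (ent_col, env_col):
            if c not in table.columns:
                raise KeyError(f"term '{term.name}': column '{c}' missing")
        envs = sorted(table[env_col].astype(str).unique())
        env_obs = table[env_col].astype(str).to_numpy()
        env_idx = np.array([envs.index(e) for e in env_obs])
        if term.kernel is not None:
            base_ids = term.kernel.entity_ids
            pos = {e: i for i, e in enumerate(base_ids)}
            try:
                ent_idx = np.array(
                    [pos[str(v)] for v in table[ent_col]], dtype=int
                )
            except KeyError as err:
                raise KeyError(
                    f"term '{term.name}': entity {err} absent from kernel"
                ) from None
            kb = term.kernel.values
            vmat = kb[np.ix_(ent_idx, ent_idx)] * (
                env_idx[:, None] == env_idx[None, :]
            )
            levels = [(e, b) for e in envs for b in base_ids]
            obs_level = env_idx * len(base_ids) + ent_idx
            structure = (kb, envs, base_ids, ent_idx, env_idx)
            return _BuiltTerm(
                term, levels, obs_level, vmat, len(levels), structure
            )
        # identity kernel over observed (entity, env) combinations
        combo = list(zip(table[ent_col].astype(str), env_obs))
        levels = sorted(set(combo))
        pos = {c: i for i, c in enumerate(levels)}
        obs_level = np.array([pos[c] for c in combo])
        vmat = (obs_level[:, None] == obs_level[None, :]).astype(float)
        return _BuiltTerm(term, levels, obs_level, vmat, len(levels))
    # simple term
    col = term.key
    if col not in table.columns:
        raise KeyError(f"term '{term.name}': column '{col}' missing")
    vals = table[col].astype(str).to_numpy()
    if term.kernel is not None:
        ids = term.kernel.entity_ids
        pos = {e: i for i, e in enumerate(ids)}
        try:
            obs_level = np.array([pos[v] for v in vals], dtype=int)
        except KeyError as err:
            raise KeyError(
                f"term '{term.name}': entity {err} absent from kernel"
            ) from None
        vmat = term.kernel.values[np.ix_(obs_level, obs_level)]
        return _BuiltTerm(term, list(ids), obs_level, vmat, len(ids))
    levels = sorted(set(vals))
    pos = {v: i for i, v in enumerate(levels)}
    obs_level = np.array([pos[v] for v in vals])
    vmat = (obs_level[:, None] == obs_level[None, :]).astype(float)
    return _BuiltTerm(term, levels, obs_level, vmat, len(levels))


def build_design(table: pd.DataFrame, spec: ModelSpec) -> DesignData:
    """Assemble y, X and per-term covariance contributions.

    Rows with a missing response are dropped (and counted); every kept
    observation must map into every term's kernel.
    """
    if spec.response not in table.columns:
        raise KeyError(f"response column '{spec.response}' missing")
    resp = pd.to_numeric(table[spec.response], errors="coerce")
    keep = resp.notna().to_numpy()
    n_dropped = int((~keep).sum())
    kept = table.loc[keep].reset_index(drop=True)
    if len(kept) == 0:
        raise ValueError("no observations with a non-missing response")
    y = resp.to_numpy(dtype=float)[keep]
    x, x_names = _fixed_design(kept, spec.fixed)
    if len(kept) <= x.shape[1]:
        raise ValueError("fewer observations than fixed-effect rank")
    terms = [_build_term(t, kept) for t in spec.random]
    return DesignData(
        y=y,
        x=x,
        x_columns=x_names,
        terms=terms,
        obs_index=np.flatnonzero(keep),
        table=kept,
        n_dropped_missing=n_dropped,
    )


def _reml_pieces(design: DesignData, theta: np.ndarray):
    """V^{-1}, P y, restricted logL and helpers for a parameter vector.

    ``theta`` orders the term variances first, residual last.
    """
    n = design.n_obs
    v = np.zeros((n, n))
    for sig, bt in zip(theta[:-1], design.terms):
        v += sig * bt.vmat
    v[np.diag_indices_from(v)] += theta[-1]
    c, low = cho_factor(v, lower=True)
    logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
    vinv = cho_solve((c, low), np.eye(n))
    x = design.x
    xtvx = x.T @ vinv @ x
    cx = cho_factor(xtvx)
    logdet_xvx = 2.0 * np.sum(np.log(np.diag(cx[0])))
    vinv_x = vinv @ x
    p = vinv - vinv_x @ cho_solve(cx, vinv_x.T)
    py = p @ design.y
    loglik = -0.5 * (logdet_v + logdet_xvx + design.y @ py)
    return vinv, p, py, loglik


def _scores_ai(design: DesignData, p: np.ndarray, py: np.ndarray):
    k = len(design.terms) + 1
    t_cols = np.empty((design.n_obs, k))
    trs = np.empty(k)
    for i, bt in enumerate(design.terms):
        t_cols[:, i] = bt.vmat @ py
        trs[i] = np.sum(p * bt.vmat)
    t_cols[:, -1] = py
    trs[-1] = np.trace(p)
    score = -0.5 * (trs - t_cols.T @ py)
    ai = 0.5 * (t_cols.T @ p @ t_cols)
    return score, ai


def reml_fit(
    design: DesignData,
    start: dict[str, float] | None = None,
    max_iter: int = MAX_ITER,
    verbose: bool = False,
) -> VCEstimates:
    """AI-REML with step-halving and EM fallback.

    An AI step is accepted only if it keeps every variance inside the
    feasible region and does not decrease the restricted log-likelihood;
    otherwise the step is halved, and after repeated failures a classical
    EM-REML update is substituted.  Components collapsing to the boundary
    are pinned at ``1e-6 * var(y)`` and flagged.  Convergence is declared
    when the relative parameter change falls below 1e-8 or the restricted
    log-likelihood change falls below 1e-6.  Standard errors come from the
    inverse AI matrix at the optimum.
    """
    names = [bt.term.variance_symbol for bt in design.terms] + ["sigma2_e"]
    vary = float(np.var(design.y, ddof=1)) if design.n_obs > 1 else 1.0
    if vary <= 0:
        vary = 1.0
    bound = BOUNDARY_FRAC * vary
    k = len(names)
    if start is None:
        theta = np.full(k, vary / k)
    else:
        theta = np.array([max(start.get(nm, vary / k), bound) for nm in names])

    _, p, py, loglik = _reml_pieces(design, theta)
    n_levels = np.array(
        [bt.n_levels for bt in design.terms] + [design.n_obs], dtype=float
    )
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        score, ai = _scores_ai(design, p, py)
        # active set: components pinned at the boundary whose gradient
        # points further outward are frozen and removed from the AI system,
        # so the interior components keep quadratic convergence
        pinned = (theta <= bound * (1 + 1e-9)) & (score < 0)
        free = ~pinned
        if not free.any():
            converged = True
            break
        delta = np.zeros(k)
        ai_f = ai[np.ix_(free, free)]
        ridge = 1e-10 * np.eye(int(free.sum())) * max(
            np.trace(ai_f) / max(free.sum(), 1), 1.0
        )
        try:
            delta[free] = np.linalg.solve(ai_f + ridge, score[free])
        except np.linalg.LinAlgError:
            delta[free] = score[free] / np.maximum(np.diag(ai_f), 1e-8)

        accepted = False
        step = 1.0
        for _ in range(12):  # step-halving
            cand = np.maximum(theta + step * delta, bound)
            try:
                _, p_new, py_new, ll_new = _reml_pieces(design, cand)
            except np.linalg.LinAlgError:
                step *= 0.5
                continue
            if ll_new >= loglik - 1e-12:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            # classical EM-REML update:
            # sigma_i' = sigma_i + sigma_i^2 (y'P V_i P y - tr(P V_i)) / q_i
            quad = np.empty(k)
            trs = np.empty(k)
            for i, bt in enumerate(design.terms):
                t = bt.vmat @ py
                quad[i] = py @ t
                trs[i] = np.sum(p * bt.vmat)
            quad[-1] = py @ py
            trs[-1] = np.trace(p)
            cand = np.maximum(theta + theta**2 * (quad - trs) / n_levels, bound)
            cand[pinned] = bound
            _, p_new, py_new, ll_new = _reml_pieces(design, cand)
            if ll_new < loglik - 1e-8:
                # neither AI nor EM improves the restricted likelihood:
                # we are at a (possibly boundary) optimum
                converged = True
                break

        rel_change = np.max(np.abs(cand - theta) / np.maximum(theta, bound))
        dll = ll_new - loglik
        theta, p, py, loglik = cand, p_new, py_new, ll_new
        if verbose:
            log.info("iter %d logL %.6f theta %s", it, loglik, theta)
        if rel_change < REL_PARAM_TOL or abs(dll) < LOGLIK_TOL:
            converged = True
            break

    boundary = [nm for nm, th in zip(names, theta) if th <= bound * (1 + 1e-6)]
    _, ai = _scores_ai(design, p, py)
    se = {}
    try:
        ai_inv = np.linalg.inv(ai)
        dg = np.diag(ai_inv)
        for nm, v in zip(names, dg):
            se[nm] = float(np.sqrt(v)) if v > 0 else float("nan")
    except np.linalg.LinAlgError:
        se = {nm: float("nan") for nm in names}
    if not converged:
        log.warning(
            "AI-REML did not converge in %d iterations (logL %.4f)",
            max_iter,
            loglik,
        )
    return VCEstimates(
        estimates={nm: float(th) for nm, th in zip(names, theta)},
        se=se,
        loglik=float(loglik),
        converged=converged,
        boundary=boundary,
        iterations=it,
        n_obs=design.n_obs,
    )


def blup_solve(design: DesignData, vc: VCEstimates) -> BlupSolution:
    """Solve Henderson's equations at the fitted variances via the
    equivalent GLS/BLUP identities.

    Fixed effects: b = (X'V^{-1}X)^{-1} X'V^{-1} y.  Random effects:
    a_i = sigma_i^2 K_i Z_i' P y, defined for every kernel entity including
    those without observations (predicted through the kernel covariance).
    """
    names = [bt.term.variance_symbol for bt in design.terms] + ["sigma2_e"]
    theta = np.array([vc.estimates[nm] for nm in names])
    vinv, p, py, _ = _reml_pieces(design, theta)
    x, y = design.x, design.y
    xtvx = x.T @ vinv @ x
    bhat = np.linalg.solve(xtvx, x.T @ (vinv @ y))
    fixed = pd.Series(bhat, index=design.x_columns)
    effects: dict[str, pd.Series] = {}
    fitted: dict[str, np.ndarray] = {}
    for sig, bt in zip(theta[:-1], design.terms):
        if bt.structure is not None:
            kb, envs, base_ids, ent_idx, env_idx = bt.structure
            n_base = len(base_ids)
            sol = np.zeros(len(bt.levels))
            for ei in range(len(envs)):
                mask = env_idx == ei
                if not mask.any():
                    continue
                contrib = kb[:, ent_idx[mask]] @ py[mask]
                sol[ei * n_base : (ei + 1) * n_base] = sig * contrib
            idx = pd.MultiIndex.from_tuples(bt.levels, names=["env", "entity"])
            effects[bt.term.name] = pd.Series(sol, index=idx)
        elif bt.term.kernel is not None:
            zt_py = np.zeros(bt.n_levels)
            np.add.at(zt_py, bt.obs_level, py)
            sol = sig * (bt.term.kernel.values @ zt_py)
            effects[bt.term.name] = pd.Series(sol, index=bt.levels)
        else:
            zt_py = np.zeros(bt.n_levels)
            np.add.at(zt_py, bt.obs_level, py)
            sol = sig * zt_py
            effects[bt.term.name] = pd.Series(sol, index=bt.levels)
        fitted[bt.term.name] = effects[bt.term.name].to_numpy()[bt.obs_level]
    return BlupSolution(fixed=fixed, effects=effects, fitted_random=fitted)
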