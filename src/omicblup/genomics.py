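"""SNP quality control, mean-dosage imputation, and relationship kernels.

The genomic relationship matrix follows VanRaden's first method,

    G = QQ' / (2 Σ p_i (1 - p_i)),

with Q the dosage matrix column-centred by twice the allele frequency.  The
spatial kernel follows the neighbour-indicator construction

    S = WW' / (tr(WW') / n),

where W[i, j] = 1 iff plot j is one of the (at most eight) row/column
neighbours of plot i inside the same trial; the trace normalisation makes
d(S) = 1 exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kernels import KernelMatrix

__all__ = [
    "GenotypeMatrix",
    "snp_qc",
    "impute_mean_dosage",
    "allele_frequencies",
    "vanraden_g",
    "spatial_kernel",
]

log = logging.getLogger(__name__)


@dataclass
class GenotypeMatrix:
    """Line x SNP dosage matrix, values in {0, 1, 2} with NaN for missing."""

    line_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray
    qc_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.line_ids = [str(x) for x in self.line_ids]
        self.snp_ids = [str(x) for x in self.snp_ids]
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.line_ids), len(self.snp_ids)):
            raise ValueError("dosage shape does not match id lists")
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValueError("duplicate line ids")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate SNP ids")
        obs = self.dosages[~np.isnan(self.dosages)]
        if obs.size and (obs.min() < 0 or obs.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosages, index=self.line_ids, columns=self.snp_ids
        )


def allele_frequencies(geno: GenotypeMatrix) -> np.ndarray:
    """Observed reference-allele frequency per SNP (missing entries ignored)."""
    with np.errstate(invalid="ignore"):
        p = np.nanmean(geno.dosages, axis=0) / 2.0
    return p


def snp_qc(
    geno: GenotypeMatrix,
    maf_min: float = 0.05,
    callrate_min: float = 0.90,
) -> GenotypeMatrix:
    """Drop SNPs with low minor allele frequency or low call rate.

    MAF is computed on the observed (non-missing) calls.  SNP order is
    preserved; removals per rule are appended to the QC log.
    """
    d = geno.dosages
    n = geno.n_lines
    callrate = 1.0 - np.isnan(d).sum(axis=0) / max(n, 1)
    p = allele_frequencies(geno)
    maf = np.minimum(p, 1.0 - p)
    # a SNP with zero observed calls has undefined MAF: fails call rate anyway
    maf = np.where(np.isnan(maf), 0.0, maf)
    keep = (maf >= maf_min) & (callrate >= callrate_min)
    n_maf = int(np.sum(~(maf >= maf_min)))
    n_cr = int(np.sum(~(callrate >= callrate_min)))
    if not keep.any():
        raise ValueError("SNP QC removed every marker (empty panel)")
    out = GenotypeMatrix(
        geno.line_ids,
        [s for s, k in zip(geno.snp_ids, keep) if k],
        d[:, keep],
        qc_log=list(geno.qc_log),
    )
    out.qc_log.append(
        f"snp_qc: removed {n_maf} SNPs with MAF<{maf_min}, "
        f"{n_cr} with call rate<{callrate_min}; kept {out.n_snps}"
    )
    return out


def impute_mean_dosage(geno: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing dosage by 2p of its SNP (the observed mean dosage)."""
    d = geno.dosages.copy()
    missing = np.isnan(d)
    if missing.all(axis=0).any():
        bad = [s for s, m in zip(geno.snp_ids, missing.all(axis=0)) if m]
        raise ValueError(f"SNPs with no observed calls cannot be imputed: {bad}")
    if missing.any():
        col_mean = np.nanmean(geno.dosages, axis=0)
        d[missing] = np.broadcast_to(col_mean, d.shape)[missing]
    out = GenotypeMatrix(
        geno.line_ids, geno.snp_ids, d, qc_log=list(geno.qc_log)
    )
    out.qc_log.append(f"impute_mean_dosage: filled {int(missing.sum())} entries")
    return out


def vanraden_g(
    geno: GenotypeMatrix,
    freqs: np.ndarray | str = "observed",
) -> KernelMatrix:
    """Genomic relationship matrix G = QQ'/(2 Σ p(1-p)).

    Parameters
    ----------
    geno
        Imputed genotype matrix (no missing values).
    freqs
        ``"observed"`` to centre by the observed frequencies, or an explicit
        per-SNP frequency vector (e.g. training-set frequencies applied to a
        prediction set).
    """
    d = geno.dosages
    if np.isnan(d).any():
        raise ValueError("genotypes contain missing values; impute first")
    if isinstance(freqs, str):
        if freqs != "observed":
            raise ValueError(f"unknown frequency option {freqs!r}")
        p = d.mean(axis=0) / 2.0
    else:
        p = np.asarray(freqs, dtype=float)
        if p.shape != (geno.n_snps,):
            raise ValueError("frequency vector length mismatch")
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all SNPs monomorphic: VanRaden denominator is zero")
    q = d - 2.0 * p
    g = (q @ q.T) / denom
    return KernelMatrix(
        geno.line_ids,
        g,
        "G",
        meta={"n_snps": geno.n_snps, "denominator": float(denom)},
    )


def spatial_kernel(layout: pd.DataFrame) -> KernelMatrix:
    """Spatial similarity S = WW'/(tr(WW')/n) from a plot layout.

    ``layout`` needs columns ``plot_id``, ``trial``, ``row``, ``col``.  Two
    plots are neighbours when they sit in the same trial at Chebyshev
    distance 1 (the eight surrounding grid cells); the plot itself is
    excluded, and trials never share neighbours.  tr(S) = n exactly.
    """
    required = {"plot_id", "trial", "row", "col"}
    if not required.issubset(layout.columns):
        raise ValueError(f"layout needs columns {sorted(required)}")
    plot_ids = [str(x) for x in layout["plot_id"]]
    n = len(plot_ids)
    if len(set(plot_ids)) != n:
        raise ValueError("duplicate plot ids in layout")
    trial = layout["trial"].to_numpy()
    row = layout["row"].to_numpy(dtype=float)
    col = layout["col"].to_numpy(dtype=float)
    w = np.zeros((n, n))
    for t in pd.unique(trial):
        idx = np.flatnonzero(trial == t)
        if len(set(zip(row[idx], col[idx]))) != len(idx):
            raise ValueError(f"duplicate plot coordinates in trial {t!r}")
        dr = np.abs(row[idx, None] - row[None, idx])
        dc = np.abs(col[idx, None] - col[None, idx])
        adj = (np.maximum(dr, dc) == 1).astype(float)
        w[np.ix_(idx, idx)] = adj
    ww = w @ w.T
    tr = np.trace(ww)
    if tr <= 0:
        raise ValueError("degenerate layout: no plot has any neighbour")
    s = ww / (tr / n)
    return KernelMatrix(plot_ids, s, "S", meta={"n_plots": n})
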