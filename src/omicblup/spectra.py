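"""Spectral preprocessing and omics similarity kernels.

Metabolomic intensities (1D NMR bins) and near-infrared absorbances are both
handled as plot x feature matrices.  The metabolomic kernel is the scaled
cross-product Q_MI = M M'/q over centred-and-scaled intensities; the NIR
kernel Q_NIR = M M'/t is built from the leading principal-component scores
of the normalised, derivative-transformed spectra, keeping the smallest
number of components t whose cumulative explained variance reaches the
target (0.99 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .kernels import KernelMatrix

__all__ = [
    "SpectraMatrix",
    "normalize_columns",
    "savgol_first_derivative",
    "mi_kernel",
    "nir_kernel",
]

log = logging.getLogger(__name__)


@dataclass
class SpectraMatrix:
    """Plot-level spectra: metabolomic (kind='MI') or near-infrared ('NIR').

    ``feature_axis`` is the chemical shift in ppm (MI) or the wavelength in
    nm (NIR) and must be strictly increasing.  ``history`` records applied
    transforms in order.
    """

    plot_ids: list[str]
    feature_axis: np.ndarray
    values: np.ndarray
    kind: str
    history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.plot_ids = [str(x) for x in self.plot_ids]
        self.feature_axis = np.asarray(self.feature_axis, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("MI", "NIR"):
            raise ValueError("kind must be 'MI' or 'NIR'")
        if self.values.shape != (len(self.plot_ids), self.feature_axis.size):
            raise ValueError("spectra shape does not match ids/axis")
        if self.feature_axis.size > 1 and np.any(
            np.diff(self.feature_axis) <= 0
        ):
            raise ValueError("feature axis must be strictly increasing")
        if len(set(self.plot_ids)) != len(self.plot_ids):
            raise ValueError("duplicate plot ids")

    @property
    def n_plots(self) -> int:
        return len(self.plot_ids)

    @property
    def n_features(self) -> int:
        return self.feature_axis.size

    def _with(self, values, axis=None, extra_history=None) -> "SpectraMatrix":
        return SpectraMatrix(
            self.plot_ids,
            self.feature_axis if axis is None else axis,
            values,
            self.kind,
            self.history + ([extra_history] if extra_history else []),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.plot_ids, columns=self.feature_axis
        )


def normalize_columns(sp: SpectraMatrix) -> SpectraMatrix:
    """Centre each feature to mean 0 and scale to sample variance 1 (n-1).

    Zero-variance features carry no information under this scaling and are
    dropped with a logged count.
    """
    if sp.n_plots < 2:
        raise ValueError("normalisation needs at least two plots")
    mean = sp.values.mean(axis=0)
    sd = sp.values.std(axis=0, ddof=1)
    keep = sd > 0
    n_drop = int(np.sum(~keep))
    if not keep.any():
        raise ValueError("all features have zero variance")
    if n_drop:
        log.info("normalize_columns: dropped %d zero-variance features", n_drop)
    vals = (sp.values[:, keep] - mean[keep]) / sd[keep]
    return sp._with(
        vals,
        axis=sp.feature_axis[keep],
        extra_history=f"normalize(dropped={n_drop})",
    )


def savgol_first_derivative(
    sp: SpectraMatrix, window: int = 11, polyorder: int = 2
) -> SpectraMatrix:
    """Savitzky-Golay first derivative of each NIR spectrum.

    The derivative is taken with respect to the feature index (unit
    spacing); on a uniform wavelength grid this differs from d/dnm only by
    a constant factor that subsequent normalisation absorbs.  Edges are
    handled by fitting the boundary window and evaluating its derivative
    at the edge points (scipy's ``mode="interp"``), so output length equals
    input length.
    """
    if sp.kind != "NIR":
        raise ValueError("derivative preprocessing applies to NIR spectra")
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and larger than polyorder")
    if window > sp.n_features:
        raise ValueError("window exceeds number of wavelengths")
    vals = savgol_filter(
        sp.values, window, polyorder, deriv=1, delta=1.0, axis=1, mode="interp"
    )
    return sp._with(
        vals, extra_history=f"savgol_d1(window={window},order={polyorder})"
    )


def _require_normalized(sp: SpectraMatrix) -> None:
    if not any(h.startswith("normalize") for h in sp.history):
        raise ValueError("spectra must be normalised before kernel building")


def mi_kernel(sp: SpectraMatrix) -> KernelMatrix:
    """Metabolomic similarity Q_MI = M M'/q over centred/scaled intensities.

    With sample-variance scaling tr(Q_MI) = n - 1 exactly.
    """
    _require_normalized(sp)
    q = sp.n_features
    if q == 0:
        raise ValueError("no features left to build a kernel")
    k = (sp.values @ sp.values.T) / q
    return KernelMatrix(sp.plot_ids, k, "Q_MI", meta={"q_features": q})


def nir_kernel(sp: SpectraMatrix, var_target: float = 0.99) -> KernelMatrix:
    """NIR similarity Q_NIR = M M'/t from leading principal-component scores.

    PCA is taken over the (already centred/scaled) wavelength matrix for the
    complete set of plots; t is the smallest component count whose cumulative
    explained variance reaches ``var_target``.  Scores are not
    re-standardised.
    """
    if not 0 < var_target <= 1:
        raise ValueError("var_target must lie in (0, 1]")
    _require_normalized(sp)
    x = sp.values - sp.values.mean(axis=0)
    # SVD of the centred matrix == eigendecomposition of its covariance
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    var = s**2
    tol = var[0] * 1e-12 if var.size else 0.0
    var = var[var > tol]
    frac = np.cumsum(var) / var.sum()
    t = int(np.searchsorted(frac, var_target - 1e-12) + 1)
    t = min(t, var.size)
    scores = u[:, :t] * s[:t]
    k = (scores @ scores.T) / t
    return KernelMatrix(
        sp.plot_ids,
        k,
        "Q_NIR",
        meta={
            "t_components": t,
            "explained_variance": (np.cumsum(var) / var.sum()).tolist(),
        },
    )
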