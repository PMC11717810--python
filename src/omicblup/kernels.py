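"""Labelled similarity (kernel) matrices shared by the genomic and spectral modules.

A :class:`KernelMatrix` wraps a symmetric positive semi-definite similarity
matrix over named entities (breeding lines or field plots) together with the
scalar summaries the heritability formulas need: the mean diagonal ``d(K)``
and the overall mean ``mean(K)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["KernelMatrix"]

#: relative tolerance for the smallest admissible eigenvalue
_PSD_RTOL = 1e-8
_SYM_ATOL = 1e-10


@dataclass
class KernelMatrix:
    """Symmetric PSD similarity matrix over named entities.

    Parameters
    ----------
    entity_ids
        Labels of the rows/columns (line ids or plot ids), unique.
    values
        Square symmetric matrix aligned with ``entity_ids``.
    kind
        One of ``{"G", "Q_MI", "Q_NIR", "S", "identity"}``.
    meta
        Free-form provenance (marker count, PCA components retained, ...).
    """

    entity_ids: list[str]
    values: np.ndarray
    kind: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.entity_ids = [str(e) for e in self.entity_ids]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.entity_ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"kernel shape {self.values.shape} does not match "
                f"{n} entity ids"
            )
        if len(set(self.entity_ids)) != n:
            raise ValueError("duplicate entity ids in kernel")
        if n and not np.allclose(self.values, self.values.T, atol=_SYM_ATOL):
            raise ValueError("kernel matrix is not symmetric")
        # enforce exact symmetry so downstream eigen-solvers are stable
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def n(self) -> int:
        return len(self.entity_ids)

    @property
    def mean_diag(self) -> float:
        """d(K): average diagonal element."""
        return float(np.mean(np.diag(self.values))) if self.n else float("nan")

    @property
    def mean_all(self) -> float:
        """mean(K): average over all elements."""
        return float(np.mean(self.values)) if self.n else float("nan")

    def check_psd(self) -> None:
        """Raise if any eigenvalue is below ``-rtol * max_eigenvalue``."""
        if self.n == 0:
            return
        w = np.linalg.eigvalsh(self.values)
        lo, hi = w[0], max(w[-1], 1.0)
        if lo < -_PSD_RTOL * hi:
            raise ValueError(f"kernel '{self.kind}' not PSD: min eig {lo:g}")

    def reindex(self, ids: list[str]) -> "KernelMatrix":
        """Return the kernel restricted/permuted to ``ids``."""
        pos = {e: i for i, e in enumerate(self.entity_ids)}
        try:
            idx = np.array([pos[str(i)] for i in ids], dtype=int)
        except KeyError as err:
            raise KeyError(f"entity {err} not present in kernel") from None
        return KernelMatrix(
            list(map(str, ids)),
            self.values[np.ix_(idx, idx)],
            self.kind,
            dict(self.meta),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.entity_ids, columns=self.entity_ids
        )

    @classmethod
    def identity(cls, ids: list[str]) -> "KernelMatrix":
        return cls(list(ids), np.eye(len(ids)), "identity")
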