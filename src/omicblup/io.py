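"""Plain-TSV readers and writers plus descriptive statistics.

All artefacts are tab-separated text with a header row, decimal point "."
and "NA" for missing values: genotypes (lines x SNPs), phenotypes (one row
per plot), spectra (plots x feature axis), kernels (square with id header),
and the report tables.  Round-trips are numerically exact to 1e-12.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genomics import GenotypeMatrix
from .kernels import KernelMatrix
from .spectra import SpectraMatrix

__all__ = [
    "PHENOTYPE_META_COLUMNS",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_spectra",
    "write_spectra",
    "read_kernel",
    "write_kernel",
    "descriptive_stats",
]

PHENOTYPE_META_COLUMNS = [
    "plot_id", "line_id", "year", "location", "trial", "row", "col",
]
NA = "NA"
_FLOAT_FMT = "%.12g"


def write_genotypes(geno: GenotypeMatrix, path: str | Path) -> None:
    df = geno.to_frame()
    df.index.name = "line_id"
    df.to_csv(path, sep="\t", na_rep=NA, float_format="%.12g")


def read_genotypes(path: str | Path, strict: bool = True) -> GenotypeMatrix:
    """Read a genotype TSV.  With ``strict=True`` every token must be one of
    0, 1, 2 or NA; imputed (fractional) matrices need ``strict=False``."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA], dtype=str)
    vals = np.empty(df.shape)
    for j, col in enumerate(df.columns):
        for i, tok in enumerate(df[col]):
            if pd.isna(tok):
                vals[i, j] = np.nan
                continue
            if strict and tok not in ("0", "1", "2"):
                raise ValueError(
                    f"invalid genotype token {tok!r} at line "
                    f"{df.index[i]!r}, SNP {col!r}"
                )
            try:
                vals[i, j] = float(tok)
            except ValueError:
                raise ValueError(
                    f"invalid genotype token {tok!r} at line "
                    f"{df.index[i]!r}, SNP {col!r}"
                ) from None
    return GenotypeMatrix(list(df.index), list(df.columns), vals)


def write_phenotypes(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep=NA, float_format="%.12g")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[NA])
    missing = [c for c in PHENOTYPE_META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    if df["plot_id"].duplicated().any():
        dup = df.loc[df["plot_id"].duplicated(), "plot_id"].iloc[0]
        raise ValueError(f"duplicate plot_id {dup!r} in phenotype table")
    within = df.groupby("trial")[["row", "col"]].apply(
        lambda g: g.duplicated().any()
    )
    if within.any():
        bad = within[within].index[0]
        raise ValueError(f"duplicate (row, col) within trial {bad!r}")
    return df


def write_spectra(sp: SpectraMatrix, path: str | Path) -> None:
    df = sp.to_frame()
    df.index.name = "plot_id"
    df.to_csv(path, sep="\t", na_rep=NA, float_format="%.12g")


def read_spectra(path: str | Path, kind: str) -> SpectraMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA])
    axis = np.array([float(c) for c in df.columns])
    return SpectraMatrix(list(df.index), axis, df.to_numpy(dtype=float), kind)


def write_kernel(k: KernelMatrix, path: str | Path) -> None:
    df = k.to_frame()
    df.index.name = f"kind={k.kind}"
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_kernel(path: str | Path) -> KernelMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    kind = "unknown"
    if df.index.name and df.index.name.startswith("kind="):
        kind = df.index.name.split("=", 1)[1]
    return KernelMatrix(list(df.columns), df.to_numpy(dtype=float), kind)


def descriptive_stats(
    table: pd.DataFrame, traits: list[str] | None = None
) -> pd.DataFrame:
    """Per-trait minimum, mean, maximum, sample SD and CV% (= 100 SD/mean)."""
    if traits is None:
        traits = [
            c for c in table.columns
            if c not in PHENOTYPE_META_COLUMNS + ["env", "batch"]
            and pd.api.types.is_numeric_dtype(table[c])
        ]
    rows = []
    for t in traits:
        vals = pd.to_numeric(table[t], errors="coerce").dropna()
        if len(vals) < 2:
            raise ValueError(f"trait {t!r} has fewer than 2 observations")
        mean = vals.mean()
        sd = vals.std(ddof=1)
        cv = 100.0 * sd / mean if mean != 0 else float("nan")
        rows.append(
            dict(trait=t, minimum=vals.min(), mean=mean, maximum=vals.max(),
                 sd=sd, cv_percent=cv)
        )
    return pd.DataFrame(rows).set_index("trait")
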