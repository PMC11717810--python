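"""Run configuration: a nested key/value text file (YAML) mapped onto
dataclasses, covering data paths or simulation settings, QC thresholds,
spectral preprocessing, model/trait selection and cross-validation."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .simulate import SimConfig

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    # data: either file paths or a simulation block
    genotypes: str | None = None
    phenotypes: str | None = None
    mi_spectra: str | None = None
    nir_spectra: str | None = None
    simulate: dict | None = None

    # QC and preprocessing
    maf_min: float = 0.05
    callrate_min: float = 0.90
    savgol_window: int = 11
    savgol_polyorder: int = 2
    nir_derivative_first: bool = False  # True: derivative before normalisation
    pca_var_target: float = 0.99

    # modelling
    traits: list[str] = field(default_factory=lambda: ["GY", "PC"])
    models: list[str] = field(
        default_factory=lambda: ["GBLUP", "GOBLUP-MI", "GOBLUP-NIR"]
    )
    gxe_diag_weight: str = "dG"       # "dG" or "1"
    force_pc_nir: bool = False

    # cross-validation
    cv_schemes: list[str] = field(default_factory=lambda: ["fivefold"])
    cv_folds: int = 5
    cv_seed: int = 0
    bootstrap_reps: int = 1000

    seed: int = 0
    outdir: str = "omicblup_out"

    def sim_config(self) -> SimConfig:
        if self.simulate is None:
            raise ValueError("config has no 'simulate' block")
        return SimConfig(**self.simulate)

    def validate(self) -> None:
        if self.simulate is None and (
            self.genotypes is None or self.phenotypes is None
        ):
            raise ValueError(
                "config needs either a 'simulate' block or genotype and "
                "phenotype paths"
            )
        for p in (self.genotypes, self.phenotypes, self.mi_spectra,
                  self.nir_spectra):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if not 0 < self.pca_var_target <= 1:
            raise ValueError("pca_var_target must be in (0, 1]")
        if self.gxe_diag_weight not in ("dG", "1"):
            raise ValueError("gxe_diag_weight must be 'dG' or '1'")
        bad = [m for m in self.models
               if m not in ("GBLUP", "GOBLUP-MI", "GOBLUP-NIR")]
        if bad:
            raise ValueError(f"unknown models: {bad}")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)
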