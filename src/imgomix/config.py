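"""Run configuration: a single YAML file drives the whole pipeline.

Schema validation is strict (unknown keys are rejected) and reports every
violation at once. Thresholds default to the printed analysis settings:
|Z| > 3 for PLS genes, 80% cumulative variance for PCA, composite weight
0.2 for top DMPs, alpha 0.05 with BH FDR throughout, 5,000 coupling
permutations.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .errors import ConfigError


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(_Strict):
    enabled: bool = True
    n_parcels: int = 180
    n_genes: int = 2000
    n_subjects_mdd: int = 60
    n_subjects_hc: int = 60
    n_cpgs: int = 20000
    n_pathways: int = 50
    n_effect_parcels: int = 15
    gmv_effect_size: float = 0.8
    n_coupled_genes: int = 100
    coupling_r: float = 0.6
    n_true_dmps: int = 50
    dmp_delta_beta: float = 0.05
    smoothness_kappa: float = 0.5
    pcr_signal_r: float = 0.6
    clinical_signal_r: float = 0.6
    n_enriched_pathways: int = 5
    pathway_fold: float = 10.0
    pathway_size: int = 40


class GMVConfig(_Strict):
    covariates: list[str] = ["age", "gender", "education", "medication", "tiv"]
    alpha: float = 0.05
    fdr_method: str = "bh"


class PLSConfig(_Strict):
    n_components: int = 15
    n_spins: int = 1000
    n_boot: int = 1000
    z_threshold: float = 3.0
    alpha: float = 0.05
    spin_statistic: str = "varexp"


class DMPConfig(_Strict):
    covariates: list[str] = ["age", "gender", "education", "medication"]
    alpha: float = 0.05
    correction: str = "uncorrected"
    promoter_only: bool = True
    use_m_values: bool = False


class IntegrateConfig(_Strict):
    enrich_q: float = 0.05
    variance_threshold: float = 0.80
    p_enter: float = 0.05
    p_remove: float = 0.10
    alpha: float = 0.05
    weight_threshold: float = 0.2
    loocv_refit_pca: bool = True


class MethExprConfig(_Strict):
    n_perm: int = 5000
    method: str = "spearman"
    tail: str = "auto"


class RunConfig(_Strict):
    seed: int = 0
    out_dir: str = "imgomix_out"
    log_level: str = "INFO"
    input_dir: str | None = None  # pre-made study instead of simulation
    simulate: SimulateConfig = SimulateConfig()
    gmv: GMVConfig = GMVConfig()
    pls: PLSConfig = PLSConfig()
    dmp: DMPConfig = DMPConfig()
    integrate: IntegrateConfig = IntegrateConfig()
    methexpr: MethExprConfig = MethExprConfig()


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    try:
        raw = yaml.safe_load(p.read_text()) or {}
    except yaml.YAMLError as e:
        raise ConfigError(f"invalid YAML in {p}: {e}") from e
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    try:
        return RunConfig(**raw)
    except ValidationError as e:
        msgs = [f"{'.'.join(str(x) for x in err['loc'])}: {err['msg']}"
                for err in e.errors()]
        raise ConfigError("config validation failed:\n  " + "\n  ".join(msgs)) from e


def dump_config(cfg: RunConfig) -> dict:
    return cfg.model_dump()
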