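"""Run-level configuration shared by the pipeline and the CLI."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .maternal import EggIsotopeParams
from .niche import NIWPrior
from .preprocess import LipidParams
from .trophic import TPConfig


@dataclass
class NicheSettings:
    n_draws: int = 10000
    boundary_k: int = 1024
    corrected_overlap: bool = False
    prior: NIWPrior = field(default_factory=NIWPrior)


@dataclass
class AnalysisConfig:
    """Everything one pipeline run needs besides the data itself."""

    log_base: str = "natural"
    growth_scope: str = "pooled"
    lipid_larva: LipidParams = field(default_factory=lambda: LipidParams(tissue_class="larva_muscle"))
    lipid_zoo: LipidParams = field(default_factory=lambda: LipidParams(tissue_class="zooplankton"))
    egg: Optional[dict[str, EggIsotopeParams]] = None  # cohort -> egg params
    tp: TPConfig = field(default_factory=TPConfig)
    niche: NicheSettings = field(default_factory=NicheSettings)
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.seed < 0:
            raise ValueError(f"seed must be non-negative, got {self.seed}")


def _lipid_from(block: dict, tissue: str) -> LipidParams:
    return LipidParams(
        beta0=block.get("beta0", -3.32),
        beta1=block.get("beta1", 0.99),
        cn_threshold=block.get("cn_threshold", 3.5),
        enabled=block.get("enabled", True),
        tissue_class=tissue,
    )


def load_analysis_config(path: str | Path) -> AnalysisConfig:
    """Build an :class:`AnalysisConfig` from a YAML file.

    Recognised blocks: ``growth`` (log_base, scope), ``lipid`` (per tissue
    class), ``egg`` (per cohort mean/sd), ``tp``, ``niche``, plus top-level
    ``alpha`` and ``seed``.  Missing blocks fall back to defaults.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}

    lipid = raw.get("lipid", {})
    egg_raw = raw.get("egg")
    egg = None
    if egg_raw:
        egg = {
            cohort: EggIsotopeParams(
                mean_d15n_egg=b["mean_d15n"],
                sd_d15n_egg=b.get("sd_d15n", 0.0),
                mean_d13c_egg=b["mean_d13c"],
                sd_d13c_egg=b.get("sd_d13c", 0.0),
            )
            for cohort, b in egg_raw.items()
        }
    tp_raw = raw.get("tp", {})
    niche_raw = raw.get("niche", {})
    growth_raw = raw.get("growth", {})
    return AnalysisConfig(
        log_base=growth_raw.get("log_base", "natural"),
        growth_scope=growth_raw.get("scope", "pooled"),
        lipid_larva=_lipid_from(lipid.get("larva_muscle", {}), "larva_muscle"),
        lipid_zoo=_lipid_from(lipid.get("zooplankton", {}), "zooplankton"),
        egg=egg,
        tp=TPConfig(
            tef=tp_raw.get("tef", 1.46),
            tp_basal=tp_raw.get("tp_basal", 2.0),
            baseline_scope=tp_raw.get("baseline_scope", "station"),
        ),
        niche=NicheSettings(
            n_draws=niche_raw.get("n_draws", 10000),
            boundary_k=niche_raw.get("boundary_k", 1024),
            corrected_overlap=niche_raw.get("corrected_overlap", False),
        ),
        alpha=raw.get("alpha", 0.05),
        seed=raw.get("seed", 0),
    )
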