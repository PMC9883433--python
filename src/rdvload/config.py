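"""Threshold and settings containers for the RDV pipeline.

Every tunable used by the QC cascade, the rarity/deleteriousness
classification, sample QC and the burden models lives here, with the
study defaults pre-filled.  All containers are plain dataclasses and can
be overridden field-by-field from a YAML mapping via :func:`load_config`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


@dataclass(frozen=True)
class QcThresholds:
    """Genotype- and site-level QC cutoffs.

    Boundary semantics follow the symbols literally: ``*_min`` fields are
    inclusive (>=), rank-sum bounds are strict (>), the allele-balance
    window [ab_low, ab_high] is inclusive at both ends, and a VQSR
    tranche fails when its lower sensitivity bound is >= ``tranche_max``.
    """

    gq_min: float = 20.0
    dp_min: float = 10.0
    ad_alt_min: float = 4.0
    ab_low: float = 0.30
    ab_high: float = 0.70
    qual_min: float = 50.0
    qd_min: float = 2.0
    mq_min: float = 40.0
    rprs_min: float = -3.0
    mqrs_min: float = -10.0
    tranche_max: float = 99.0
    diff_miss_max: float = 0.05
    completeness_min: float = 0.88
    sample_miss_max: float = 0.15


@dataclass(frozen=True)
class RarityThresholds:
    """Rarity cascade for deleterious candidates and the synonymous background.

    Frequencies are fractions (0.01 == 1%).  A variant is *rare* when it
    is not common (> ``cohort_maf_max``) in both case and control arms,
    and its reference-population frequencies (ExAC non-TCGA NFE, gnomAD
    ASJ) are <= ``ref_maf_max``.  ``cohort_maf_max=0.01`` reproduces the
    sensitivity mode.  Synonymous background variants are ultra-rare:
    ExAC global <= 0.005% and full-cohort MAF <= 0.05%.
    """

    cohort_maf_max: float = 0.02
    ref_maf_max: float = 0.01
    syn_ref_maf_max: float = 0.00005
    syn_cohort_maf_max: float = 0.0005
    absent_ref_maf_is_zero: bool = True
    anchor_include_likely_pathogenic: bool = True


@dataclass(frozen=True)
class KinshipSettings:
    #: KING kinship above this flags a pair as <=2nd-degree related.
    phi_threshold: float = 0.0884


@dataclass(frozen=True)
class PcaSettings:
    maf_min: float = 0.05
    call_rate_min: float = 0.99
    ld_r2_max: float = 0.2
    ld_window: int = 50
    ld_step: int = 5
    n_components: int = 10


@dataclass(frozen=True)
class GateSettings:
    """Rectangular gate on (PC1, PC2).

    Explicit bounds win; otherwise the gate is derived from the reference
    samples carrying ``reference_label`` as centroid +/- ``sd_multiplier``
    standard deviations on each axis.
    """

    pc1_bounds: tuple[float, float] | None = None
    pc2_bounds: tuple[float, float] | None = None
    reference_label: str | None = None
    sd_multiplier: float = 3.0


@dataclass(frozen=True)
class BurdenSettings:
    covariates: tuple[str, ...] = ("n_syn_genes", "PC1", "PC2")
    include_gender: bool = False
    alpha: float = 0.05
    ci_level: float = 0.95
    p_method: str = "lrt"  # "lrt" (penalized likelihood ratio) or "wald"


@dataclass(frozen=True)
class AnalysisConfig:
    qc: QcThresholds = field(default_factory=QcThresholds)
    rarity: RarityThresholds = field(default_factory=RarityThresholds)
    kinship: KinshipSettings = field(default_factory=KinshipSettings)
    pca: PcaSettings = field(default_factory=PcaSettings)
    gate: GateSettings = field(default_factory=GateSettings)
    burden: BurdenSettings = field(default_factory=BurdenSettings)


def _build(cls, data: dict[str, Any]):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            v = data[f.name]
            kwargs[f.name] = tuple(v) if isinstance(v, list) else v
    return cls(**kwargs)


def load_config(source: str | Path | dict[str, Any]) -> AnalysisConfig:
    """Build an :class:`AnalysisConfig` from a YAML file or mapping."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(source)
    sections = {
        "qc": QcThresholds,
        "rarity": RarityThresholds,
        "kinship": KinshipSettings,
        "pca": PcaSettings,
        "gate": GateSettings,
        "burden": BurdenSettings,
    }
    kwargs = {}
    for key, cls in sections.items():
        if key in data:
            kwargs[key] = _build(cls, data[key] or {})
    unknown = set(data) - set(sections)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    return AnalysisConfig(**kwargs)
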