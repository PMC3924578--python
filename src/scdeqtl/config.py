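"""Run configuration objects.

Two dataclasses hold every tunable constant of the pipeline:

* :class:`SimulationConfig` — the synthetic-cohort generator's knobs
  (cohort composition, allele frequencies, effect-size distributions,
  planted eQTL structure).
* :class:`AnalysisConfig` — the analysis thresholds (SNP QC filters, the
  FDR level, LD-pruning parameters, the two-tier Bonferroni constants).

Both validate eagerly on construction and raise :class:`ConfigError`
naming the offending field.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Tuple

import yaml


class ConfigError(ValueError):
    """A configuration field is out of its valid range."""


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{name}: {msg}")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic SCD cohort.

    Default cohort composition mirrors the combined genotyped data set of
    the study design this package targets: 79 patients sampled at entry
    (E), 41 under follow-up (FU) and 53 healthy sibling controls (Ctls),
    n = 173 in total.
    """

    n_patients_E: int = 79
    n_patients_FU: int = 41
    n_controls: int = 53
    hbsc_fraction: float = 0.0
    n_snps: int = 1000
    n_probes: int = 200
    n_chromosomes: int = 22
    maf_range: Tuple[float, float] = (0.05, 0.5)
    sibling_fraction: float = 0.5
    n_local_esnps: int = 10
    n_distal_esnps: int = 2
    esnp_r2: float = 0.33
    n_interaction_effects: int = 0
    interaction_delta: float = 0.5
    clinstatus_effect_sd: float = 0.3
    de_fraction: float = 0.25
    hb_effect_sd: float = 0.4
    sex_effect_sd: float = 0.05
    wbc_slope_sd: float = 0.02
    rbc_slope_sd: float = 0.05
    noise_sd: float = 0.5
    missing_rate: float = 0.0
    ld_rho: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_patients_E",
            "n_patients_FU",
            "n_controls",
            "n_snps",
            "n_probes",
            "n_chromosomes",
            "n_local_esnps",
            "n_distal_esnps",
            "n_interaction_effects",
        ):
            _require(int(getattr(self, name)) >= 0, name, "must be >= 0")
        _require(self.n_chromosomes >= 1, "n_chromosomes", "must be >= 1")
        lo, hi = self.maf_range
        _require(0.0 < lo <= hi <= 0.5, "maf_range", "must lie in (0, 0.5]")
        _require(0.0 <= self.sibling_fraction <= 1.0, "sibling_fraction", "must be in [0,1]")
        _require(0.0 <= self.esnp_r2 < 1.0, "esnp_r2", "must be in [0,1)")
        _require(0.0 <= self.missing_rate <= 1.0, "missing_rate", "must be in [0,1]")
        _require(0.0 <= self.de_fraction <= 1.0, "de_fraction", "must be in [0,1]")
        _require(0.0 <= self.hbsc_fraction <= 1.0, "hbsc_fraction", "must be in [0,1]")
        _require(-1.0 < self.ld_rho < 1.0, "ld_rho", "must be in (-1,1)")
        _require(
            self.n_local_esnps + self.n_distal_esnps <= self.n_probes,
            "n_local_esnps",
            "n_local_esnps + n_distal_esnps must not exceed n_probes",
        )
        for name in ("clinstatus_effect_sd", "hb_effect_sd", "sex_effect_sd",
                     "wbc_slope_sd", "rbc_slope_sd", "noise_sd",
                     "interaction_delta"):
            _require(getattr(self, name) >= 0.0, name, "must be >= 0")

    @property
    def n_samples(self) -> int:
        return self.n_patients_E + self.n_patients_FU + self.n_controls


@dataclass
class AnalysisConfig:
    """Analysis thresholds and multiple-testing constants.

    Defaults are the published filter constants: MAF >= 5%, call rate
    >= 99%, exact HWE p >= 0.001, per-term FDR 1%, LD pruning at r^2 < 0.3
    with MAF >= 0.10, and an average of 200 local SNPs per probe for the
    local-tier Bonferroni threshold at alpha = 0.05.
    """

    maf_min: float = 0.05
    hwe_p_min: float = 0.001
    callrate_min: float = 0.99
    fdr_q: float = 0.01
    prune_r2: float = 0.3
    prune_maf_min: float = 0.10
    avg_local_snps: int = 200
    alpha: float = 0.05
    out_dir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        _require(0.0 <= self.maf_min <= 0.5, "maf_min", "must be in [0,0.5]")
        _require(0.0 < self.hwe_p_min < 1.0, "hwe_p_min", "must be in (0,1)")
        _require(0.0 <= self.callrate_min <= 1.0, "callrate_min", "must be in [0,1]")
        _require(0.0 < self.fdr_q < 1.0, "fdr_q", "must be in (0,1)")
        _require(0.0 < self.prune_r2 <= 1.0, "prune_r2", "must be in (0,1]")
        _require(0.0 <= self.prune_maf_min <= 0.5, "prune_maf_min", "must be in [0,0.5]")
        _require(self.avg_local_snps >= 1, "avg_local_snps", "must be >= 1")
        _require(0.0 < self.alpha < 1.0, "alpha", "must be in (0,1)")


def _from_mapping(cls, mapping: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ConfigError(f"unknown field(s): {sorted(unknown)}")
    kwargs = dict(mapping)
    if "maf_range" in kwargs:
        kwargs["maf_range"] = tuple(kwargs["maf_range"])
    return cls(**kwargs)


def load_config(path: str, kind: str = "simulation"):
    """Load a YAML config file into the requested config dataclass."""
    with open(path) as fh:
        mapping = yaml.safe_load(fh) or {}
    cls = SimulationConfig if kind == "simulation" else AnalysisConfig
    return _from_mapping(cls, mapping)
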