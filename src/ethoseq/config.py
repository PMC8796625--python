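"""Pipeline configuration with study defaults and validation.

Every default mirrors the value used in the study: 30 fps / 20 min
sessions, 15 PCA dimensions, 15 ARHMM states, 8 ensemble fits, 44
syllables, 200-550 Hz order-2 Butterworth detection band, 4 oscillations at
3x the 250 ms baseline SD, alpha 0.05, transition-edge threshold 0.01 %.
Configs round-trip losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "ConfigReport", "validate_config"]


@dataclass
class PipelineConfig:
    # synthetic cohort
    fps: float = 30.0
    session_minutes: float = 20.0
    n_per_genotype: dict = field(default_factory=lambda: {"wt": 6, "het": 10, "hom": 5})
    genotype_effects: dict = field(default_factory=dict)  # genotype -> {state: multiplier}
    sim_n_states: int = 5
    sim_n_dims: int = 5
    gap_block_s: float = 20.0
    gap_s_range: tuple = (1.0, 2.0)
    # embedding / state inference
    n_components: int = 15
    n_states: int = 15
    ar_order: int = 1
    n_fits: int = 8
    em_max_iter: int = 200
    em_tol: float = 1e-4
    # consensus
    n_syllables: int = 44
    linkage_method: str = "weighted"
    count_weighted: bool = False
    # analytics
    alpha: float = 0.05
    p_adjust: str | None = None
    edge_threshold: float = 0.01
    # EEG arm
    eeg_enabled: bool = False
    eeg_fs: float = 4000.0
    eeg_duration_s: float = 60.0
    eeg_channels: int = 4
    band_low_hz: float = 200.0
    band_high_hz: float = 550.0
    filter_order: int = 2
    min_oscillations: int = 4
    amplitude_ratio: float = 3.0
    baseline_window_ms: float = 250.0
    merge_gap_ms: float = 10.0
    # run control
    master_seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.gap_s_range, list):
            cfg.gap_s_range = tuple(cfg.gap_s_range)
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# study-default reference used for departure warnings
_REFERENCE = {
    "fps": 30.0,
    "session_minutes": 20.0,
    "n_components": 15,
    "n_states": 15,
    "n_fits": 8,
    "n_syllables": 44,
    "band_low_hz": 200.0,
    "band_high_hz": 550.0,
    "filter_order": 2,
    "min_oscillations": 4,
    "amplitude_ratio": 3.0,
    "baseline_window_ms": 250.0,
    "alpha": 0.05,
    "edge_threshold": 0.01,
}


@dataclass
class ConfigReport:
    errors: list[str]
    warnings: list[str]

    @property
    def ok(self) -> bool:
        return not self.errors

    def raise_if_invalid(self) -> None:
        if self.errors:
            raise ValueError("invalid config: " + "; ".join(self.errors))


def validate_config(cfg: PipelineConfig) -> ConfigReport:
    """Range-check every field; warn on departures from the study defaults.

    Nothing is silently corrected: every violation is enumerated.
    """
    errors: list[str] = []
    warnings: list[str] = []

    def positive(name):
        if getattr(cfg, name) <= 0:
            errors.append(f"{name} must be positive")

    for name in ("fps", "session_minutes", "eeg_fs", "eeg_duration_s", "em_tol", "amplitude_ratio", "baseline_window_ms"):
        positive(name)
    for name in ("n_components", "n_states", "sim_n_states", "sim_n_dims", "n_fits", "n_syllables", "ar_order", "min_oscillations", "em_max_iter"):
        if getattr(cfg, name) < 1:
            errors.append(f"{name} must be >= 1")
    if not (0 < cfg.alpha < 1):
        errors.append("alpha must be in (0, 1)")
    if cfg.edge_threshold < 0:
        errors.append("edge_threshold must be non-negative")
    if not (0 < cfg.band_low_hz < cfg.band_high_hz):
        errors.append("need 0 < band_low_hz < band_high_hz")
    if cfg.band_high_hz >= cfg.eeg_fs / 2:
        errors.append("band_high_hz must be below Nyquist (eeg_fs / 2)")
    if any(n < 1 for n in cfg.n_per_genotype.values()):
        errors.append("each genotype needs at least one animal")
    for geno, eff in cfg.genotype_effects.items():
        if eff and any(m <= 0 for m in dict(eff).values()):
            errors.append(f"genotype_effects[{geno}] multipliers must be positive")
    if len(cfg.gap_s_range) != 2 or cfg.gap_s_range[0] > cfg.gap_s_range[1]:
        errors.append("gap_s_range must be (low, high) with low <= high")

    for name, ref in _REFERENCE.items():
        val = getattr(cfg, name)
        if val != ref:
            warnings.append(f"{name}={val} departs from the study default {ref}")
    return ConfigReport(errors=errors, warnings=warnings)
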