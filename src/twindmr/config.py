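"""Analysis configuration: every tuning constant of the pipeline in one place.

Defaults reproduce the study conventions: 500/250 bp sliding-window bins,
FDR tiers 5/10/25%, a 100 bp TSS window, 20 kb extended promoters, 50 kb
GWAS flanks and cis windows, 20 TSS permutations (with a low-permutation
warning), 10,000 resampling draws, and 1,000 CIT permutations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

from .errors import ConfigurationError

log = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    bin_size: int = 500
    step: int = 250
    fdr_tiers: tuple = (0.05, 0.10, 0.25)
    tss_window: int = 100
    promoter_upstream: int = 20_000
    gwas_flank: int = 50_000
    cis_window: int = 50_000
    n_perm: int = 20
    n_draws: int = 10_000
    cit_permutations: int = 1000
    replication_alpha: float = 0.05
    normalization: str = "zscore"
    seed: int = 0

    def __post_init__(self):
        for name in ("bin_size", "step", "tss_window", "promoter_upstream",
                     "gwas_flank", "cis_window", "n_perm", "n_draws", "cit_permutations"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive, got {getattr(self, name)}")
        tiers = tuple(self.fdr_tiers)
        if not all(0 < a < 1 for a in tiers) or any(
                a >= b for a, b in zip(tiers, tiers[1:])):
            raise ConfigurationError(
                f"fdr_tiers must be strictly increasing within (0, 1), got {tiers}")
        self.fdr_tiers = tiers
        if self.normalization not in {"zscore", "inverse_normal"}:
            raise ConfigurationError(f"unknown normalization {self.normalization!r}")
        if not 0 < self.replication_alpha < 1:
            raise ConfigurationError("replication_alpha must be in (0, 1)")
        if self.n_perm < 999:
            log.warning("n_perm=%d permutations: minimum attainable empirical p is %.4g",
                        self.n_perm, 1 / (self.n_perm + 1))

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["fdr_tiers"] = list(d["fdr_tiers"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def load_config(path: str | Path | None) -> AnalysisConfig:
    """Load a YAML config; unknown keys are rejected, missing keys defaulted."""
    if path is None:
        return AnalysisConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"config file {path} must contain a mapping")
    known = {f.name: f for f in fields(AnalysisConfig)}
    unknown = sorted(set(data) - set(known))
    if unknown:
        raise ConfigurationError(f"unknown config keys: {unknown}")
    for key, value in data.items():
        expect = known[key].type
        if key == "fdr_tiers":
            if not isinstance(value, (list, tuple)):
                raise ConfigurationError("fdr_tiers must be a list")
            data[key] = tuple(value)
        elif expect == "int" and not isinstance(value, int):
            raise ConfigurationError(f"config key {key!r} expects an integer, got {value!r}")
        elif expect == "float" and not isinstance(value, (int, float)):
            raise ConfigurationError(f"config key {key!r} expects a number, got {value!r}")
        elif expect == "str" and not isinstance(value, str):
            raise ConfigurationError(f"config key {key!r} expects a string, got {value!r}")
    cfg = AnalysisConfig(**data)
    log.info("effective configuration: %s", asdict(cfg))
    return cfg
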